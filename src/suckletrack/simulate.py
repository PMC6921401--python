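"""Synthetic sow-piglet dyad datasets with known ground truth.

The generator emulates the design of a longitudinal mother-infant
transmission study in pigs: each of ``n_dyads`` sows contributes source
samples from maternal body sites (milk, vagina, areolar skin, feces) and the
birth environment (farrowing crate; a shared incubator without dyad
attribution), and on each sampling day one piglet per litter contributes
mucosal samples from four intestinal segments. Sink communities are
multinomial draws from a mixture of the dam's own source profiles plus an
"unknown" component supported on features reserved to never occur in any
source, with mixing weights that drift from milk-dominated at birth towards
feces-dominated at weaning.

Ground truth (true mixing proportions, planted transmitted OTUs, OTU-gene
links) is returned alongside the data and can be written as a JSON sidecar,
so every downstream stage can be scored without private APIs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .data_model import (
    SINK_SEGMENTS,
    SOURCE_ENVIRONMENTS,
    FeatureTable,
    PhyloTree,
    SampleMetadata,
    write_feature_table,
    write_metadata,
    write_newick,
)
from .errors import ValidationError

UNKNOWN = "unknown"


@dataclass
class TransmittedOtuSpec:
    """How transmitted OTUs are planted.

    Each planted OTU is carried by a random subset of sows (``carrier_prob``).
    A dam sheds an OTU in her ``route`` source samples iff she carries it;
    each of her piglets sampled within ``window`` days acquires it with
    probability ``p_share`` (gut-wide, all segments). Piglets of non-carrier
    dams pick it up from the environment at the ``background`` rate,
    independently per piglet. A further
    ``n_universal`` OTUs are planted in every dam and every piglet with
    dam-correlated abundance, exercising the rank-correlation detection path
    for OTUs that presence-based tests cannot see.
    """

    n_planted: int = 10
    p_share: float = 0.9
    background: float = 0.2
    carrier_prob: float = 0.5
    route: str = "milk"
    window: tuple[int, int] = (0, 3)
    boost: float = 0.02
    n_universal: int = 2
    universal_noise: float = 0.15


@dataclass
class ExpressionSpec:
    """Host-gene expression coupled to chosen OTUs.

    Expression (relative scale) per sink sample is
    ``exp(baseline + sum(strength * z(log abundance)) + noise)`` where ``z``
    standardises the log relative abundance of each linked OTU across
    samples; the link is therefore monotone in abundance. ``n_links`` genes
    are each tied to one planted OTU with alternating sign.
    """

    genes: tuple[str, ...] = (
        "PBD1", "PBD2", "REGIII", "MUC1", "MUC2", "MUC13", "AHR", "TLR4", "IL10",
    )
    n_links: int = 4
    strength: float = 1.0
    noise_scale: float = 0.3
    mode: str = "relative"  # or "ct"


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults follow the emulated study: 8 litters, sampling days 0-35, four
    intestinal segments, six source environments, sequencing depth equal to
    the rarefaction depth of 27,848 reads per sample.
    """

    n_dyads: int = 8
    n_features: int = 300
    n_unknown_features: int = 30
    source_environments: tuple[str, ...] = SOURCE_ENVIRONMENTS
    sink_segments: tuple[str, ...] = SINK_SEGMENTS
    days: tuple[int, ...] = (0, 1, 3, 7, 14, 28, 35)
    depth: int = 27848
    profile_concentration: float = 0.1
    host_jitter: float | None = 200.0
    overdispersion: float | None = 500.0
    mixing_schedule: dict | None = None
    transmitted: TransmittedOtuSpec | None = field(default_factory=TransmittedOtuSpec)
    expression: ExpressionSpec | None = field(default_factory=ExpressionSpec)
    n_incubator_samples: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValidationError("sequencing depth must be positive")
        if self.n_unknown_features >= self.n_features:
            raise ValidationError("n_unknown_features must be < n_features")
        if self.transmitted is not None:
            t = self.transmitted
            if t.route not in self.source_environments:
                raise ValidationError(f"transmitted route {t.route!r} not a source environment")
            for p in (t.p_share, t.background, t.carrier_prob):
                if not 0 <= p <= 1:
                    raise ValidationError("transmission probabilities must lie in [0,1]")


@dataclass
class GroundTruth:
    """What the generator knows: mixtures, planted OTUs, expression links."""

    mixing: dict[str, dict[str, float]]
    transmitted_otus: list[dict]
    expression_links: list[dict]

    def transmitted_ids(self) -> set[str]:
        return {rec["otu"] for rec in self.transmitted_otus}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class SimulatedDataset:
    table: FeatureTable
    metadata: SampleMetadata
    tree: PhyloTree
    expression: pd.DataFrame | None
    truth: GroundTruth

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_feature_table(self.table, outdir / "table.tsv")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        write_newick(self.tree, outdir / "tree.nwk")
        if self.expression is not None:
            with open(outdir / "expression.tsv", "w") as fh:
                fh.write("# mode=relative\n")
                self.expression.to_csv(fh, sep="\t")
        (outdir / "truth.json").write_text(self.truth.to_json())


def simulate_tree(n_tips: int, seed: int) -> PhyloTree:
    """Random rooted bifurcating tree by uniform random pairwise joins.

    Branch lengths are exponential(1); tip names are OTU0001..; deterministic
    for a given seed.
    """
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [skbio.TreeNode(name=f"OTU{i + 1:04d}", length=float(rng.exponential()))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(length=float(rng.exponential()), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def default_mixing_schedule(
    segments=SINK_SEGMENTS,
    days=(0, 1, 3, 7, 14, 28, 35),
    environments=SOURCE_ENVIRONMENTS,
    unknown_start: float = 0.05,
    unknown_end: float = 0.20,
) -> dict:
    """Milk-dominated at birth drifting linearly to sow-feces-dominated.

    Returns {(segment, day): {environment: weight, ..., "unknown": w}} with
    weights summing to 1 per sink condition.
    """
    max_day = max(days) or 1
    # the large intestine matures towards a feces-like community faster
    drift_exponent = {"jejunum": 1.5, "ileum": 1.2, "cecum": 0.7, "colon": 0.6}
    schedule = {}
    for seg in segments:
        for day in days:
            f = (day / max_day) ** drift_exponent.get(seg, 1.0)
            w = {env: 0.0 for env in environments}
            w["milk"] = 0.60 * (1 - f) + 0.05 * f
            w["sow_feces"] = 0.05 * (1 - f) + 0.50 * f
            w["vagina"] = 0.15 * (1 - f) + 0.05 * f
            if "areolar_skin" in w:
                w["areolar_skin"] = 0.05
            if "farrowing_crate" in w:
                w["farrowing_crate"] = 0.05
            if "incubator" in w:
                w["incubator"] = 0.05
            w[UNKNOWN] = unknown_start * (1 - f) + unknown_end * f
            total = sum(w.values())
            schedule[(seg, day)] = {k: v / total for k, v in w.items()}
    return schedule


def _validate_schedule(schedule: dict, environments) -> None:
    allowed = set(environments) | {UNKNOWN}
    for key, weights in schedule.items():
        extra = set(weights) - allowed
        if extra:
            raise ValidationError(f"mixing schedule for {key} names undeclared sources: {sorted(extra)}")
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValidationError(f"mixing weights for {key} do not sum to 1")
        if any(not 0 <= v <= 1 for v in weights.values()):
            raise ValidationError(f"mixing weights for {key} outside [0,1]")


def _dirichlet_around(rng, profile: np.ndarray, concentration: float) -> np.ndarray:
    """Resample a composition around ``profile`` with the given concentration."""
    alpha = np.maximum(profile * concentration, 1e-12)
    return rng.dirichlet(alpha)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full source/sink dataset plus ground truth from ``config``."""
    rng = np.random.default_rng(config.seed)
    F = config.n_features
    n_unknown = config.n_unknown_features
    feature_ids = [f"OTU{i + 1:04d}" for i in range(F)]
    known = np.arange(F - n_unknown)
    reserved = np.arange(F - n_unknown, F)

    schedule = config.mixing_schedule or default_mixing_schedule(
        config.sink_segments, config.days, config.source_environments
    )
    _validate_schedule(schedule, config.source_environments)

    # environment base profiles on the non-reserved features only
    base = {}
    for env in config.source_environments:
        p = np.zeros(F)
        p[known] = rng.dirichlet(np.full(len(known), config.profile_concentration))
        base[env] = p

    dyads = [f"sow{d + 1:02d}" for d in range(config.n_dyads)]

    # dam-specific source profiles (the "dam effect" when host_jitter is set)
    dam_profiles: dict[tuple[str, str], np.ndarray] = {}
    for dyad in dyads:
        for env in config.source_environments:
            if config.host_jitter is None:
                dam_profiles[(dyad, env)] = base[env]
            else:
                dam_profiles[(dyad, env)] = _dirichlet_around(rng, base[env], config.host_jitter)

    # dyad-specific unknown component on the reserved features
    unknown_profiles = {}
    for dyad in dyads:
        p = np.zeros(F)
        p[reserved] = rng.dirichlet(np.full(n_unknown, 0.5))
        unknown_profiles[dyad] = p

    # ---- planted transmitted OTUs -------------------------------------
    tspec = config.transmitted
    truth_transmitted: list[dict] = []
    planted_presence: dict[str, dict] = {}
    universal: list[dict] = []
    if tspec is not None and (tspec.n_planted or tspec.n_universal):
        pool = rng.choice(known, size=tspec.n_planted + tspec.n_universal, replace=False)
        for k in range(tspec.n_planted):
            fidx = int(pool[k])
            carriers = [d for d in dyads if rng.random() < tspec.carrier_prob]
            planted_presence[feature_ids[fidx]] = {
                "fidx": fidx,
                "carriers": set(carriers),
            }
            truth_transmitted.append({
                "otu": feature_ids[fidx],
                "route": tspec.route,
                "window": list(tspec.window),
                "mechanism": "presence",
                "carriers": sorted(carriers),
            })
        for k in range(tspec.n_universal):
            fidx = int(pool[tspec.n_planted + k])
            dam_level = {d: float(rng.lognormal(0.0, 0.8)) for d in dyads}
            universal.append({"fidx": fidx, "dam_level": dam_level})
            truth_transmitted.append({
                "otu": feature_ids[fidx],
                "route": tspec.route,
                "window": list(tspec.window),
                "mechanism": "abundance",
                "carriers": sorted(dyads),
            })
        # planted OTUs must not already ride along in the base profiles
        for env in config.source_environments:
            base[env][pool] = 0.0
            base[env] /= base[env].sum()
        for key, prof in dam_profiles.items():
            prof = prof.copy()
            prof[pool] = 0.0
            dam_profiles[key] = prof / prof.sum()

    def _with_planted_source(dyad: str, env: str) -> np.ndarray:
        """Dam source profile with planted-OTU mass added where it belongs."""
        prof = dam_profiles[(dyad, env)].copy()
        if tspec is None:
            return prof
        extra = np.zeros_like(prof)
        if env == tspec.route:
            # a dam sheds a planted OTU in the route environment iff she
            # carries it; piglet-side background is environmental acquisition
            for rec in planted_presence.values():
                if dyad in rec["carriers"]:
                    extra[rec["fidx"]] = tspec.boost
            for rec in universal:
                extra[rec["fidx"]] = tspec.boost * rec["dam_level"][dyad]
        total = extra.sum()
        if total > 0:
            prof = prof * (1 - total) + extra
        return prof

    # ---- assemble samples ---------------------------------------------
    counts: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    breeds = ["landrace", "rongchang"]

    def _draw(profile: np.ndarray) -> np.ndarray:
        p = profile
        if config.overdispersion is not None:
            p = _dirichlet_around(rng, p, config.overdispersion)
        return rng.multinomial(config.depth, p)

    for dyad in dyads:
        breed = breeds[dyads.index(dyad) % 2]
        for env in config.source_environments:
            if env == "incubator":
                continue
            sid = f"src_{env}_{dyad}"
            counts[sid] = _draw(_with_planted_source(dyad, env))
            meta_rows.append(dict(sample_id=sid, role="source", environment=env,
                                  host_id=dyad, dyad_id=dyad, day=0, breed=breed, sex=""))
    if "incubator" in config.source_environments:
        for i in range(config.n_incubator_samples):
            sid = f"src_incubator_{i + 1}"
            counts[sid] = _draw(base["incubator"])
            meta_rows.append(dict(sample_id=sid, role="source", environment="incubator",
                                  host_id=f"incubator_{i + 1}", dyad_id="", day=0,
                                  breed="", sex=""))

    truth_mixing: dict[str, dict[str, float]] = {}
    expr_abund: dict[str, np.ndarray] = {}  # per-sample planted relative abundances
    for dyad in dyads:
        breed = breeds[dyads.index(dyad) % 2]
        for day in config.days:
            piglet = f"piglet_{dyad}_d{day}"
            sex = "male" if rng.random() < 0.5 else "female"
            # transmission presence decided per piglet (gut-wide)
            acquired: set[str] = set()
            if tspec is not None:
                in_window = tspec.window[0] <= day <= tspec.window[1]
                for otu, rec in planted_presence.items():
                    if dyad in rec["carriers"] and in_window:
                        if rng.random() < tspec.p_share:
                            acquired.add(otu)
                    elif rng.random() < tspec.background:
                        acquired.add(otu)
            for seg in config.sink_segments:
                weights = schedule[(seg, day)]
                mix = np.zeros(F)
                for env, w in weights.items():
                    if env == UNKNOWN:
                        mix += w * unknown_profiles[dyad]
                    else:
                        mix += w * dam_profiles[(dyad, env)]
                if tspec is not None:
                    extra = np.zeros(F)
                    for otu in acquired:
                        extra[planted_presence[otu]["fidx"]] = tspec.boost
                    for rec in universal:
                        lvl = rec["dam_level"][dyad] * rng.lognormal(0.0, tspec.universal_noise)
                        extra[rec["fidx"]] = tspec.boost * lvl
                    total = extra.sum()
                    if total > 0:
                        mix = mix * (1 - total) + extra
                mix /= mix.sum()
                sid = f"snk_{dyad}_d{day}_{seg}"
                counts[sid] = _draw(mix)
                expr_abund[sid] = mix
                truth_mixing[sid] = {k: float(v) for k, v in weights.items()}
                meta_rows.append(dict(sample_id=sid, role="sink", environment=seg,
                                      host_id=piglet, dyad_id=dyad, day=day,
                                      breed=breed, sex=sex))

    table = FeatureTable(pd.DataFrame(counts, index=feature_ids))
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    tree = simulate_tree(F, seed=int(rng.integers(2**31)))

    # ---- host gene expression ------------------------------------------
    expression = None
    links: list[dict] = []
    espec = config.expression
    if espec is not None:
        sink_ids = [r["sample_id"] for r in meta_rows if r["role"] == "sink"]
        linked_pool = [rec["fidx"] for rec in universal] + [
            rec["fidx"] for rec in planted_presence.values()
        ]
        if not linked_pool:
            linked_pool = list(rng.choice(known, size=espec.n_links, replace=False))
        rows = {}
        for g, gene in enumerate(espec.genes):
            eta = np.full(len(sink_ids), 1.0)
            if g < espec.n_links:
                fidx = int(linked_pool[g % len(linked_pool)])
                sign = 1 if g % 2 == 0 else -1
                ab = np.array([expr_abund[s][fidx] for s in sink_ids])
                z = np.log10(ab + 1e-6)
                z = (z - z.mean()) / (z.std() or 1.0)
                eta = eta + sign * espec.strength * z
                links.append({"gene": gene, "otu": feature_ids[fidx],
                              "sign": sign, "strength": espec.strength})
            noise = rng.normal(0.0, espec.noise_scale, size=len(sink_ids))
            rows[gene] = np.exp(eta + noise)
        expression = pd.DataFrame(rows, index=sink_ids).T
        expression.index.name = "gene"
        if espec.mode == "ct":
            # fold change f shows up as a Ct shift of -log2(f) against a
            # flat reference gene
            expression = 22.0 - np.log2(expression)

    truth = GroundTruth(mixing=truth_mixing, transmitted_otus=truth_transmitted,
                        expression_links=links)
    return SimulatedDataset(table, metadata, tree, expression, truth)
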