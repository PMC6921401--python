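"""End-to-end orchestration: simulate/load -> rarefy -> diversity ->
ordination & PERMANOVA -> source tracking -> transmission -> host
association -> network, with a provenance manifest.

Every stage seed is derived deterministically from the global seed, so two
runs with the same configuration produce byte-identical outputs. The
manifest records each stage's parameters and the SHA-256 of its inputs and
outputs; a rerun skips a stage whose recorded input checksums still match.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, host_association, network, reporting, simulate, source_tracking
from . import stats as st
from . import transmission as tr
from .data_model import (
    align_table_metadata_tree,
    read_feature_table,
    read_metadata,
    read_newick,
    write_distance_matrix,
    write_feature_table,
)
from .errors import AnalysisError, SuckletrackError

logger = logging.getLogger(__name__)

METRICS = ("bray_curtis", "unweighted_unifrac", "weighted_unifrac")


@dataclasses.dataclass
class RunConfig:
    """Pipeline settings; unspecified blocks take stage defaults."""

    out_dir: str = "suckletrack_out"
    seed: int = 0
    # input paths; when table is None the simulate block is used instead
    table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    expression: str | None = None
    simulate: dict = dataclasses.field(default_factory=dict)
    rarefy_depth: int | None = None
    metrics: tuple[str, ...] = METRICS
    permanova_factors: tuple[str, ...] = ("environment", "day", "dyad_id")
    permanova_permutations: int = 999
    sourcetrack: dict = dataclasses.field(default_factory=dict)
    transmit: dict = dataclasses.field(default_factory=dict)
    network: dict = dataclasses.field(default_factory=dict)
    correlate_q_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise AnalysisError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)


def _stage_seed(global_seed: int, index: int) -> int:
    return int((global_seed * 100003 + 7919 * index) % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    """Stage provenance record; paths are stored relative to the run dir so
    identical runs in different locations stay byte-identical."""

    def __init__(self, path: Path):
        self.path = path
        self.root = path.parent
        self.stages = {}
        if path.exists():
            try:
                self.stages = json.loads(path.read_text()).get("stages", {})
            except json.JSONDecodeError:
                self.stages = {}

    def _rel(self, p: Path) -> str:
        p = Path(p)
        try:
            return str(p.resolve().relative_to(self.root.resolve()))
        except ValueError:
            return p.name

    def unchanged(self, stage: str, inputs: list[Path], outputs: list[str]) -> bool:
        rec = self.stages.get(stage)
        if not rec or rec.get("status") != "ok":
            return False
        want = {self._rel(p): _sha256(p) for p in inputs if Path(p).exists()}
        if rec.get("inputs") != want:
            return False
        return all((self.root / o).exists() for o in rec.get("outputs", []))

    def record(self, stage: str, params: dict, inputs: list[Path],
               outputs: list[Path], status: str = "ok") -> None:
        self.stages[stage] = dict(
            status=status,
            params=params,
            inputs={self._rel(p): _sha256(p) for p in inputs if Path(p).exists()},
            outputs=[self._rel(p) for p in outputs],
            output_checksums={self._rel(p): _sha256(p) for p in outputs if Path(p).exists()},
        )
        self.path.write_text(json.dumps({"stages": self.stages}, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serialized = dataclasses.asdict(config)
    serialized["out_dir"] = "."  # the directory the file lives in
    (out / "config.yaml").write_text(yaml.safe_dump(serialized, sort_keys=True))
    manifest = _Manifest(out / "manifest.json")

    # ---- stage 0: obtain data -----------------------------------------
    data_dir = out / "data"
    if config.table is None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", _stage_seed(config.seed, 0))
        if "transmitted" in sim_kwargs and isinstance(sim_kwargs["transmitted"], dict):
            sim_kwargs["transmitted"] = simulate.TransmittedOtuSpec(**sim_kwargs["transmitted"])
        if "expression" in sim_kwargs and isinstance(sim_kwargs["expression"], dict):
            sim_kwargs["expression"] = simulate.ExpressionSpec(**sim_kwargs["expression"])
        sim_cfg = simulate.SimulationConfig(**sim_kwargs)
        dataset = simulate.simulate_dataset(sim_cfg)
        dataset.write(data_dir)
        manifest.record("simulate", {"seed": sim_cfg.seed}, [],
                        sorted(data_dir.iterdir()))
        table_path = data_dir / "table.tsv"
        meta_path = data_dir / "metadata.tsv"
        tree_path = data_dir / "tree.nwk"
        expr_path = data_dir / "expression.tsv"
    else:
        table_path = Path(config.table)
        if config.metadata is None:
            raise AnalysisError("metadata path required when table is given")
        meta_path = Path(config.metadata)
        tree_path = Path(config.tree) if config.tree else None
        expr_path = Path(config.expression) if config.expression else None

    try:
        table = read_feature_table(table_path)
        metadata = read_metadata(meta_path)
        tree = read_newick(tree_path) if tree_path and tree_path.exists() else None
    except SuckletrackError as exc:
        manifest.record("validate", {}, [table_path, meta_path], [], status=f"failed: {exc}")
        raise
    bundle = align_table_metadata_tree(table, metadata, tree)
    table, metadata, tree = bundle.table, bundle.metadata, bundle.tree
    inputs = [table_path, meta_path] + ([tree_path] if tree_path else [])

    # ---- stage 1: rarefaction -----------------------------------------
    depth = config.rarefy_depth
    if depth is None:
        depth = int(table.counts.sum(axis=0).min())
    rare_path = out / "rarefied_table.tsv"
    if not manifest.unchanged("rarefy", inputs, [str(rare_path)]):
        table_r = diversity.rarefy(table, depth, seed=_stage_seed(config.seed, 1))
        write_feature_table(table_r, rare_path)
        manifest.record("rarefy", {"depth": depth}, inputs, [rare_path])
    table_r = read_feature_table(rare_path)
    metadata = metadata.subset(table_r.sample_ids)

    # ---- stage 2: alpha diversity -------------------------------------
    alpha_path = out / "alpha_diversity.tsv"
    alpha = pd.DataFrame({m: diversity.alpha_diversity(table_r, m)
                          for m in ("chao1", "shannon")})
    alpha.rename_axis("sample_id").to_csv(alpha_path, sep="\t")
    manifest.record("alpha", {"metrics": ["chao1", "shannon"]}, [rare_path], [alpha_path])

    # ---- stage 3: beta diversity + ordination + PERMANOVA -------------
    dms = {}
    permanova_results: dict[str, list[st.PermanovaResult]] = {}
    outputs3 = []
    sink_ids = list(metadata.sinks().index)
    for mi, metric in enumerate(config.metrics):
        dm = diversity.distance_matrix(table_r, metric, tree=tree)
        dms[metric] = dm
        dm_path = out / f"distance_{metric}.tsv"
        write_distance_matrix(dm, dm_path)
        pc = st.pcoa(dm)
        pc_path = out / f"pcoa_{metric}.tsv"
        pc.coordinates.iloc[:, :10].rename_axis("sample_id").to_csv(pc_path, sep="\t")
        outputs3 += [dm_path, pc_path]
        permanova_results[metric] = []
        sink_dm = dm.filter(sink_ids) if sink_ids else dm
        for fi, factor in enumerate(config.permanova_factors):
            grouping = metadata.frame.loc[list(sink_dm.ids), factor]
            if grouping.nunique() < 2:
                continue
            permanova_results[metric].append(st.permanova(
                sink_dm, grouping, n_permutations=config.permanova_permutations,
                seed=_stage_seed(config.seed, 30 + 10 * mi + fi), factor=factor))
        traj = diversity.beta_trajectory(sink_dm, metadata.subset(list(sink_dm.ids)),
                                         mode="from_day0")
        traj_path = out / f"trajectory_{metric}.tsv"
        traj.to_csv(traj_path, sep="\t", index=False)
        outputs3.append(traj_path)
    perm_path = out / "permanova.tsv"
    reporting.permanova_table(permanova_results).to_csv(perm_path, sep="\t", index=False)
    manifest.record("beta", {"metrics": list(config.metrics)}, [rare_path],
                    outputs3 + [perm_path])

    # ---- stage 4: source tracking -------------------------------------
    st_kwargs = dict(config.sourcetrack)
    st_kwargs.setdefault("seed", _stage_seed(config.seed, 4))
    gibbs = source_tracking.GibbsConfig(**st_kwargs)
    estimates, summary = source_tracking.track_all(table_r, metadata, gibbs)
    contrib = reporting.contribution_summary(estimates, metadata)
    contrib_path = out / "source_contributions.tsv"
    contrib.to_csv(contrib_path, sep="\t", index=False)
    per_sink = pd.DataFrame([
        dict(sink_id=e.sink_id, environment=env, mean=e.means[env], sd=e.sds[env])
        for e in estimates for env in e.environments])
    per_sink_path = out / "source_contributions_per_sink.tsv"
    per_sink.to_csv(per_sink_path, sep="\t", index=False)
    manifest.record("sourcetrack", dataclasses.asdict(gibbs), [rare_path],
                    [contrib_path, per_sink_path])

    # ---- stage 5: transmission ----------------------------------------
    tx_kwargs = dict(config.transmit)
    tx_kwargs.setdefault("seed", _stage_seed(config.seed, 5))
    records = tr.classify_transmitted(table_r, metadata, **tx_kwargs)
    tx_path = out / "transmission.tsv"
    records.to_csv(tx_path, sep="\t", index=False)
    tx_sum = tr.transmission_summary(records)
    tx_sum_path = out / "transmission_summary.tsv"
    tx_sum.to_csv(tx_sum_path, sep="\t", index=False)
    dyad_rows = []
    for metric, dm in dms.items():
        for env in sorted(metadata.sources()["environment"].unique()):
            try:
                t_mean, r_mean, p = tr.dyad_vs_random_distance(
                    dm, metadata, env, n_random=3,
                    seed=_stage_seed(config.seed, 6))
            except AnalysisError:
                continue
            dyad_rows.append(dict(metric=metric, source_env=env, true_pair_mean=t_mean,
                                  random_pair_mean=r_mean, p=p))
    dyad_path = out / "dyad_vs_random.tsv"
    pd.DataFrame(dyad_rows).to_csv(dyad_path, sep="\t", index=False)
    manifest.record("transmission", tx_kwargs, [rare_path],
                    [tx_path, tx_sum_path, dyad_path])

    # ---- stage 6: host association + network --------------------------
    if expr_path is not None and Path(expr_path).exists():
        expression, mode = host_association.read_expression(expr_path)
        if mode == "ct":
            expression = host_association.relative_expression_from_ct(
                expression, expression.index[-1], metadata)
        corr = host_association.correlate_otu_gene(table_r, expression)
        corr_path = out / "otu_gene_correlations.tsv"
        corr.to_csv(corr_path, sep="\t", index=False)
        sig_otus = sorted(corr.loc[corr["q"] < config.correlate_q_threshold, "otu"].unique())
        groups = host_association.assign_enrichment_group(table_r, metadata,
                                                          otus=sig_otus or None)
        groups_path = out / "enrichment_groups.tsv"
        groups.to_csv(groups_path, sep="\t", index=False)
        net_outputs = [corr_path, groups_path]
        if len(sig_otus) >= 3:
            # co-occurrence over the gut (sink) communities only
            sub = table_r.filter_samples(sink_ids).filter_features(sig_otus)
            clr = network.clr_transform(sub.counts.T.to_numpy())
            rel = table_r.filter_samples(sink_ids).relative_abundance()
            net_kwargs = dict(config.network)
            net_kwargs.setdefault("seed", _stage_seed(config.seed, 7))
            result = network.stars_select(
                clr, node_names=sub.feature_ids,
                mean_abundance=rel.loc[sub.feature_ids].mean(axis=1).to_numpy(),
                **net_kwargs)
            result.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            result.nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
            result.instability.to_csv(out / "network_instability.tsv", sep="\t", index=False)
            net_outputs += [out / "network_edges.tsv", out / "network_nodes.tsv",
                            out / "network_instability.tsv"]
        manifest.record("host_association", {}, [rare_path, Path(expr_path)], net_outputs)
    return out
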