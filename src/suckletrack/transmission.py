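"""Vertical-transmission detection between maternal sources and piglet guts.

The unit of analysis is the mother-infant dyad: each piglet sampled within a
day window forms a pair with its dam. For every candidate OTU on a route
(source environment -> intestinal segment, day window) we record, per pair,
presence in the dam's source samples and in the piglet's segment sample, and
combine four statistics:

* a sharing statistic — the fraction of pairs in which the OTU is present in
  both members;
* a pairing-permutation test — dams are randomly re-matched to piglets and
  the sharing statistic recomputed (one-sided, excess sharing);
* Fisher's exact test on the 2x2 presence table across pairs;
* Spearman rank correlation between paired source/sink relative abundances,
  the fallback for OTUs present in every animal, which the presence-based
  tests cannot see.

An OTU passes the prevalence filter when present in more than ``threshold``
of either the route's source samples or its sink samples (strict
inequality). It is called transmitted when both the permutation and Fisher
tests are significant, or when it is present in all source and all sink
samples of the route and the Spearman test is significant with positive
correlation (transmission, like excess sharing, is a directional
hypothesis). BH-adjusted
p-values are reported alongside but do not enter the decision rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import FeatureTable, SampleMetadata
from .errors import AnalysisError
from .stats import bh_adjust

DEFAULT_WINDOWS = ((0, 3), (4, None))


@dataclass
class TransmissionRecord:
    otu: str
    source_env: str
    segment: str
    window: str
    sharing: float
    p_perm: float
    p_fisher: float
    rho: float | None
    p_spearman: float | None
    prevalence_source: float
    prevalence_sink: float
    decision: str  # transmitted / not_transmitted / not_evaluated
    branch: str    # presence / abundance / none


def prevalence_filter(presence_source: np.ndarray, presence_sink: np.ndarray,
                      threshold: float = 0.2) -> np.ndarray:
    """Candidate mask: presence fraction strictly above ``threshold`` in
    either the source samples or the sink samples (features x samples in)."""
    if not 0 < threshold < 1:
        raise AnalysisError("prevalence threshold must lie in (0,1)")
    if presence_source.shape[1] == 0 or presence_sink.shape[1] == 0:
        raise AnalysisError("empty sample group in prevalence filter")
    prev_src = presence_source.mean(axis=1)
    prev_snk = presence_sink.mean(axis=1)
    return (prev_src > threshold) | (prev_snk > threshold)


def sharing_statistic(src_present, snk_present) -> float:
    """Fraction of mother-infant pairs with the OTU present in both members."""
    src_present = np.asarray(src_present, dtype=bool)
    snk_present = np.asarray(snk_present, dtype=bool)
    if src_present.size == 0:
        raise AnalysisError("no dyads")
    return float((src_present & snk_present).mean())


def sharing_permutation_test(
    src_present,
    snk_present,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive_when_small: bool = True,
) -> float:
    """One-sided p for excess sharing under shuffled mother-infant pairings.

    All n! re-pairings are enumerated when n <= 7 pairs; otherwise a
    Monte-Carlo estimate with the observed pairing included in numerator and
    denominator.
    """
    src = np.asarray(src_present, dtype=bool)
    snk = np.asarray(snk_present, dtype=bool)
    n = src.size
    if n < 2:
        raise AnalysisError("permutation test needs at least 2 pairs")
    obs = (src & snk).mean()
    if exhaustive_when_small and n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            stat = (src[list(perm)] & snk).mean()
            count += stat >= obs - 1e-12
            total += 1
        return count / total
    if n_permutations < 1:
        raise AnalysisError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_permutations, n))
    perms = np.argsort(keys, axis=1)
    stats = (src[perms] & snk).mean(axis=1)
    return float((1 + (stats >= obs - 1e-12).sum()) / (1 + n_permutations))


def fisher_dyad_test(src_present, snk_present) -> float:
    """Two-sided Fisher exact p on the 2x2 source x sink presence table."""
    src = np.asarray(src_present, dtype=bool)
    snk = np.asarray(snk_present, dtype=bool)
    if src.size == 0:
        raise AnalysisError("no dyads")
    a = int((src & snk).sum())
    b = int((src & ~snk).sum())
    c = int((~src & snk).sum())
    d = int((~src & ~snk).sum())
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def spearman_paired(x, y) -> tuple[float, float]:
    """Spearman rho with exact permutation p for n <= 7 tie-free pairs,
    t-approximation otherwise. Constant input is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise AnalysisError("Spearman needs at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("non-finite values in Spearman input")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AnalysisError("Spearman undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if tie_free and n <= 7:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        return rho, count / total
    # t approximation on average-ranked data
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def build_route_pairs(
    table: FeatureTable,
    metadata: SampleMetadata,
    source_env: str,
    segment: str,
    window: tuple[int, int | None],
    min_count: int = 1,
):
    """Presence/abundance matrices for one route.

    Returns a dict with per-pair arrays: ``src_present``/``snk_present``
    (features x pairs booleans), ``src_abund``/``snk_abund`` (features x
    pairs mean relative abundance), source/sink sample-level presence
    matrices for prevalence, and the pair bookkeeping (dyad per pair).
    """
    lo, hi = window[0], window[1] if window[1] is not None else np.inf
    meta = metadata.frame
    rel = table.relative_abundance()
    present = table.counts >= min_count

    src_meta = meta[(meta["role"] == "source") & (meta["environment"] == source_env)]
    if src_meta.empty:
        raise AnalysisError(f"no source samples for environment {source_env!r}")
    snk_meta = meta[(meta["role"] == "sink") & (meta["environment"] == segment)
                    & (meta["day"] >= lo) & (meta["day"] <= hi)]
    src_by_dyad = {d: [s for s in block.index if s in present.columns]
                   for d, block in src_meta.groupby("dyad_id")}
    src_by_dyad = {d: ids for d, ids in src_by_dyad.items() if ids}

    pairs = []
    for sid, row in snk_meta.iterrows():
        if sid in present.columns and row["dyad_id"] in src_by_dyad:
            pairs.append((row["dyad_id"], sid))
    if not pairs:
        raise AnalysisError(
            f"no mother-infant pairs for route {source_env}->{segment} window {window}")

    src_present = np.column_stack(
        [present[src_by_dyad[d]].any(axis=1).to_numpy() for d, _ in pairs])
    snk_present = np.column_stack([present[s].to_numpy() for _, s in pairs])
    src_abund = np.column_stack(
        [rel[src_by_dyad[d]].mean(axis=1).to_numpy() for d, _ in pairs])
    snk_abund = np.column_stack([rel[s].to_numpy() for _, s in pairs])
    return dict(
        feature_ids=table.feature_ids,
        dyads=[d for d, _ in pairs],
        sinks=[s for _, s in pairs],
        src_present=src_present,
        snk_present=snk_present,
        src_abund=src_abund,
        snk_abund=snk_abund,
        src_sample_presence=present[[s for ids in src_by_dyad.values() for s in ids]].to_numpy(),
        snk_sample_presence=present[[s for _, s in pairs]].to_numpy(),
    )


def _window_label(window) -> str:
    lo, hi = window
    return f"d{lo}-{hi}" if hi is not None else f"d{lo}+"


def classify_transmitted(
    table: FeatureTable,
    metadata: SampleMetadata,
    source_envs=None,
    segments=None,
    windows=DEFAULT_WINDOWS,
    alpha: float = 0.05,
    threshold: float = 0.2,
    n_permutations: int = 999,
    seed: int = 0,
    min_count: int = 1,
) -> pd.DataFrame:
    """Evaluate every (source env, segment, window) route and decide per OTU.

    Returns a long-format table with one row per evaluated (OTU, route);
    OTUs failing the prevalence filter on a route appear with decision
    ``not_evaluated``. BH-adjusted p-values (over all evaluated tests of
    each kind) are appended as ``q_perm``/``q_fisher``/``q_spearman``.
    """
    if not 0 < alpha < 1:
        raise AnalysisError("alpha must lie in (0,1)")
    meta = metadata.frame
    if source_envs is None:
        source_envs = sorted(meta.loc[meta["role"] == "source", "environment"].unique())
    if segments is None:
        segments = sorted(meta.loc[meta["role"] == "sink", "environment"].unique())
    rng = np.random.default_rng(seed)
    records: list[TransmissionRecord] = []
    for env in source_envs:
        for seg in segments:
            for window in windows:
                try:
                    route = build_route_pairs(table, metadata, env, seg, window,
                                              min_count=min_count)
                except AnalysisError:
                    continue
                candidates = prevalence_filter(route["src_sample_presence"],
                                               route["snk_sample_presence"], threshold)
                wlabel = _window_label(window)
                for f, otu in enumerate(route["feature_ids"]):
                    prev_src = float(route["src_sample_presence"][f].mean())
                    prev_snk = float(route["snk_sample_presence"][f].mean())
                    if not candidates[f]:
                        if prev_src > 0 or prev_snk > 0:
                            records.append(TransmissionRecord(
                                otu, env, seg, wlabel, np.nan, np.nan, np.nan,
                                None, None, prev_src, prev_snk, "not_evaluated", "none"))
                        continue
                    src_p = route["src_present"][f]
                    snk_p = route["snk_present"][f]
                    sharing = sharing_statistic(src_p, snk_p)
                    p_perm = sharing_permutation_test(
                        src_p, snk_p, n_permutations=n_permutations,
                        seed=int(rng.integers(2**31)))
                    p_fisher = fisher_dyad_test(src_p, snk_p)
                    rho = p_sp = None
                    universal = src_p.all() and snk_p.all()
                    if universal and len(src_p) >= 4:
                        try:
                            rho, p_sp = spearman_paired(route["src_abund"][f],
                                                        route["snk_abund"][f])
                        except AnalysisError:
                            rho = p_sp = None
                    if p_perm < alpha and p_fisher < alpha:
                        decision, branch = "transmitted", "presence"
                    elif universal and p_sp is not None and p_sp < alpha and rho > 0:
                        decision, branch = "transmitted", "abundance"
                    else:
                        decision, branch = "not_transmitted", "none"
                    records.append(TransmissionRecord(
                        otu, env, seg, wlabel, sharing, p_perm, p_fisher,
                        rho, p_sp, prev_src, prev_snk, decision, branch))
    frame = pd.DataFrame([r.__dict__ for r in records])
    if frame.empty:
        raise AnalysisError("no routes could be evaluated")
    for col in ("p_perm", "p_fisher", "p_spearman"):
        q = np.full(len(frame), np.nan)
        mask = frame[col].notna().to_numpy()
        if mask.any():
            q[mask] = bh_adjust(frame.loc[mask, col].to_numpy(dtype=float))
        frame["q" + col[1:]] = q
    if table.taxonomy:
        frame.insert(1, "taxonomy", frame["otu"].map(table.taxonomy).fillna(""))
    return frame


def transmission_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Event- and OTU-level transmission counts per route and window."""
    hits = records[records["decision"] == "transmitted"]
    rows = []
    for (env, seg, window), block in hits.groupby(["source_env", "segment", "window"]):
        rows.append(dict(source_env=env, segment=seg, window=window,
                         n_events=len(block), n_otus=block["otu"].nunique()))
    summary = pd.DataFrame(rows)
    summary.attrs["n_events_total"] = len(hits)
    summary.attrs["n_otus_total"] = hits["otu"].nunique() if len(hits) else 0
    return summary


def dyad_vs_random_distance(
    dm,
    metadata: SampleMetadata,
    source_env: str,
    segment: str | None = None,
    n_random: int = 1,
    seed: int = 0,
    n_permutations: int = 999,
) -> tuple[float, float, float]:
    """Do piglets resemble their own dam more than a random sow?

    For each sink (optionally restricted to one segment), the true-pair value
    is its mean distance to its own dam's ``source_env`` samples; the
    reported random-pair mean averages distances to ``n_random`` sampled
    non-dam sows per sink. Significance is a one-sided pairing-permutation
    test: the dam labels are shuffled across sinks and the mean true-pair
    distance recomputed; p is the fraction of shuffles at least as close as
    the observed pairing (+1/+1). A rank test between the two distance sets
    would share every sink between the sets and be conservative under the
    exchangeable null; the permutation test is exact there.

    Returns (mean true-pair distance, mean random-pair distance, p).
    """
    meta = metadata.frame
    ids = set(dm.ids)
    src = meta[(meta["role"] == "source") & (meta["environment"] == source_env)]
    src_by_dyad = {d: [s for s in block.index if s in ids]
                   for d, block in src.groupby("dyad_id")}
    src_by_dyad = {d: v for d, v in src_by_dyad.items() if v}
    if len(src_by_dyad) < 2:
        raise AnalysisError("dyad-vs-random comparison needs at least 2 dams")
    snk = meta[meta["role"] == "sink"]
    if segment is not None:
        snk = snk[snk["environment"] == segment]
    dams = sorted(src_by_dyad)
    dam_idx = {d: k for k, d in enumerate(dams)}
    rng = np.random.default_rng(seed)
    rows = []       # mean distance from each usable sink to every dam
    own = []        # index of the sink's own dam
    rand_vals = []
    for sid, row in snk.iterrows():
        dam = row["dyad_id"]
        if sid not in ids or dam not in src_by_dyad:
            continue
        rows.append([np.mean([dm[sid, s] for s in src_by_dyad[d]]) for d in dams])
        own.append(dam_idx[dam])
        others = [k for k in range(len(dams)) if k != dam_idx[dam]]
        chosen = rng.choice(len(others), size=min(n_random, len(others)), replace=False)
        rand_vals.extend(rows[-1][others[k]] for k in chosen)
    if not rows:
        raise AnalysisError("no sinks with matched dam sources in the distance matrix")
    matrix = np.asarray(rows)
    own = np.asarray(own)
    n = len(own)
    obs = matrix[np.arange(n), own].mean()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(own)
        count += matrix[np.arange(n), perm].mean() <= obs + 1e-12
    p = (1 + count) / (1 + n_permutations)
    return float(obs), float(np.mean(rand_vals)), float(p)
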