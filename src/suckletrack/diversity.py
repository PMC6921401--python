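"""Rarefaction, alpha diversity, and beta diversity.

Alpha metrics are bias-corrected Chao1 richness and Shannon entropy (base-2
by default, i.e. bits, following the QIIME 1.x convention). Beta metrics are
Bray-Curtis plus unweighted and weighted UniFrac; the UniFrac computations
are delegated to scikit-bio and cross-checked elsewhere against an
exhaustive per-branch enumeration. ``beta_trajectory`` condenses a distance
matrix into per-(group, day) summaries: either the mean distance of each
sample to its contemporaries, or the divergence of each day from that
group's day-0 community.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity
from skbio.diversity.beta import unweighted_unifrac as _skbio_uu
from skbio.diversity.beta import weighted_unifrac as _skbio_wu

from .data_model import FeatureTable, PhyloTree, SampleMetadata
from .errors import AnalysisError

logger = logging.getLogger(__name__)

METRICS = ("bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def rarefy(table: FeatureTable, depth: int, seed: int = 0, policy: str = "drop") -> FeatureTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (``policy='drop'``)
    or raise (``policy='strict'``); a sample already at ``depth`` passes
    through unchanged.
    """
    if depth <= 0:
        raise AnalysisError("rarefaction depth must be positive")
    if policy not in ("drop", "strict"):
        raise AnalysisError(f"unknown rarefaction policy {policy!r}")
    rng = np.random.default_rng(seed)
    cols = {}
    dropped = []
    for sid in table.sample_ids:
        counts = table.sample_counts(sid)
        total = int(counts.sum())
        if total < depth:
            if policy == "strict":
                raise AnalysisError(f"sample {sid!r} total {total} below depth {depth}")
            dropped.append(sid)
            continue
        if total == depth:
            cols[sid] = counts
        else:
            cols[sid] = rng.multivariate_hypergeometric(counts, depth)
    if not cols:
        raise AnalysisError(f"all samples below rarefaction depth {depth}")
    if dropped:
        logger.warning("rarefaction dropped %d samples below depth %d: %s",
                       len(dropped), depth, dropped)
    return FeatureTable(pd.DataFrame(cols, index=table.feature_ids), table.taxonomy)


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise AnalysisError("Chao1 undefined for an empty sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of the relative abundances (bits for ``base=2``)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise AnalysisError("Shannon entropy undefined for an empty sample")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(table: FeatureTable, metric: str = "chao1") -> pd.Series:
    """Per-sample alpha diversity as a Series indexed by sample ID."""
    fn = {"chao1": chao1, "shannon": shannon}.get(metric)
    if fn is None:
        raise AnalysisError(f"unknown alpha metric {metric!r}")
    return pd.Series({sid: fn(table.sample_counts(sid)) for sid in table.sample_ids},
                     name=metric)


def bray_curtis(x, y) -> float:
    """1 - 2*sum(min(x,y)) / (sum(x)+sum(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = x.sum() + y.sum()
    if denom == 0:
        raise AnalysisError("Bray-Curtis undefined when both samples are empty")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def _check_on_tree(counts, feature_ids, tree: PhyloTree, label: str):
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise AnalysisError(f"{label}: sample has no observed features")
    return counts


def unweighted_unifrac(tree: PhyloTree, x, y, feature_ids) -> float:
    """Fraction of observed branch length unique to one of the two samples."""
    x = _check_on_tree(x, feature_ids, tree, "unweighted UniFrac")
    y = _check_on_tree(y, feature_ids, tree, "unweighted UniFrac")
    return float(_skbio_uu(x, y, taxa=list(feature_ids), tree=tree.tree))


def weighted_unifrac(tree: PhyloTree, x, y, feature_ids, normalized: bool = False) -> float:
    """Abundance-weighted UniFrac; non-normalized by default."""
    x = _check_on_tree(x, feature_ids, tree, "weighted UniFrac")
    y = _check_on_tree(y, feature_ids, tree, "weighted UniFrac")
    return float(_skbio_wu(x, y, taxa=list(feature_ids), tree=tree.tree,
                           normalized=normalized))


def distance_matrix(
    table: FeatureTable,
    metric: str,
    tree: PhyloTree | None = None,
    normalized: bool = False,
) -> skbio.DistanceMatrix:
    """All-pairs dissimilarity matrix over the table's samples."""
    if metric not in METRICS:
        raise AnalysisError(f"unknown beta metric {metric!r}; choose from {METRICS}")
    data = table.counts.T  # samples x features for scikit-bio
    if metric == "bray_curtis":
        return beta_diversity("braycurtis", data.to_numpy(dtype=float), ids=table.sample_ids)
    if tree is None:
        raise AnalysisError(f"{metric} requires a phylogenetic tree")
    kwargs = dict(taxa=table.feature_ids, tree=tree.tree)
    if metric == "weighted_unifrac":
        kwargs["normalized"] = normalized
    name = {"unweighted_unifrac": "unweighted_unifrac",
            "weighted_unifrac": "weighted_unifrac"}[metric]
    return beta_diversity(name, data.to_numpy(dtype=float), ids=table.sample_ids, **kwargs)


def beta_trajectory(
    dm: skbio.DistanceMatrix,
    metadata: SampleMetadata,
    mode: str = "within",
    group_col: str = "environment",
    day_col: str = "day",
) -> pd.DataFrame:
    """Per-(group, day) beta-diversity summaries.

    mode='within': each sample's mean distance to all other samples of the
    same group and day, averaged per (group, day) with its standard error.
    Time points with a single sample are skipped with a warning.

    mode='from_day0': mean distance of each (group, day) sample to the
    group's day-0 samples, quantifying divergence from the birth community.
    """
    if mode not in ("within", "from_day0"):
        raise AnalysisError(f"unknown trajectory mode {mode!r}")
    meta = metadata.frame.loc[[s for s in dm.ids if s in metadata.frame.index]]
    rows = []
    for (group, day), block in meta.groupby([group_col, day_col], sort=True):
        ids = list(block.index)
        per_sample = []
        if mode == "within":
            if len(ids) < 2:
                logger.warning("trajectory point (%s, day %s) has <2 samples; skipped", group, day)
                continue
            for sid in ids:
                others = [o for o in ids if o != sid]
                per_sample.append(np.mean([dm[sid, o] for o in others]))
        else:
            day0 = meta[(meta[group_col] == group) & (meta[day_col] == 0)].index
            if len(day0) == 0:
                raise AnalysisError(f"group {group!r} has no day-0 samples for mode='from_day0'")
            for sid in ids:
                ref = [o for o in day0 if o != sid]
                if not ref:
                    continue
                per_sample.append(np.mean([dm[sid, o] for o in ref]))
        per_sample = np.asarray(per_sample)
        se = per_sample.std(ddof=1) / np.sqrt(len(per_sample)) if len(per_sample) > 1 else 0.0
        rows.append(dict(group=group, day=day, mean=float(per_sample.mean()),
                         se=float(se), n=len(per_sample)))
    return pd.DataFrame(rows)
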