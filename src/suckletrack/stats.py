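"""Ordination and nonparametric statistics on distance matrices.

PCoA is classical metric MDS (Gower double-centering + eigendecomposition).
PERMANOVA is the one-way pseudo-F permutation test of Anderson (2001),
applied one factor at a time; permutation p-values include the observed
statistic in numerator and denominator so they can never be 0. Rank tests
and the Benjamini-Hochberg step-up adjustment wrap scipy/statsmodels with
the exact-vs-approximate policies made explicit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError


@dataclass
class PcoaResult:
    """Sample coordinates with eigenvalues and proportion explained.

    Axes are ordered by eigenvalue, descending. Negative eigenvalues (which
    arise for semi-metric dissimilarities such as Bray-Curtis) are reported
    but excluded from the proportion-explained denominator, and contribute
    no coordinate axis.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class PermanovaResult:
    factor: str
    f_statistic: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def pcoa(dm: skbio.DistanceMatrix) -> PcoaResult:
    """Classical principal coordinates analysis of a distance matrix."""
    n = dm.shape[0]
    if n < 3:
        raise AnalysisError("PCoA needs at least 3 samples")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centerer @ d2 @ centerer
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = np.where(positive, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    frame = pd.DataFrame(coords, index=list(dm.ids),
                         columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
    return PcoaResult(frame, eigvals, proportion)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R-squared from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = n_groups
    if ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    dm: skbio.DistanceMatrix,
    grouping,
    n_permutations: int = 9999,
    seed: int = 0,
    factor: str = "group",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA of a single factor against a distance matrix.

    ``grouping`` is a sequence of labels aligned with ``dm.ids`` or a mapping
    / Series keyed by sample ID. ``exhaustive=True`` enumerates every
    relabeling (feasible for small n) and returns the exact permutation p.
    """
    ids = list(dm.ids)
    if isinstance(grouping, (pd.Series, dict)):
        labels = [grouping[i] for i in ids]
    else:
        labels = list(grouping)
        if len(labels) != len(ids):
            raise AnalysisError("grouping length does not match distance matrix")
    uniq = sorted(set(map(str, labels)))
    if len(uniq) < 2:
        raise AnalysisError("PERMANOVA needs at least 2 groups")
    codes = np.array([uniq.index(str(l)) for l in labels])
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _permanova_f(d2, codes, len(uniq))

    if exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(codes):
            f_p, _ = _permanova_f(d2, np.array(perm), len(uniq))
            count += f_p >= f_obs - 1e-12
            total += 1
        p = count / total
        n_perm_used = total
    else:
        if n_permutations < 1:
            raise AnalysisError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            f_p, _ = _permanova_f(d2, rng.permutation(codes), len(uniq))
            count += f_p >= f_obs - 1e-12
        p = (1 + count) / (1 + n_permutations)
        n_perm_used = n_permutations
    return PermanovaResult(factor, f_obs, r2, float(p), n_perm_used,
                           len(ids), len(uniq))


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k-1)."""
    if len(groups) < 2:
        raise AnalysisError("Kruskal-Wallis needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise AnalysisError("empty group in Kruskal-Wallis")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U; exact when n_x+n_y <= 12 and tie-free, else normal
    approximation with tie correction (no continuity correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise AnalysisError("Mann-Whitney requires nonempty samples")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 12) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
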