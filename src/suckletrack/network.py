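"""Compositionally-aware sparse co-occurrence network inference.

The pipeline is CLR transform -> Meinshausen-Buhlmann neighborhood selection
(an L1-penalised regression of each node's CLR profile on all others) ->
StARS model selection (the regularization whose edge set is stable under
subsampling). Edges are symmetrised by the OR rule with the mean of the two
directed coefficients as signed weight; weights below a display-magnitude
threshold are suppressed in the emitted edge list. Because the weights are
regression coefficients, not correlations, they are labelled
``mb_coefficient`` in outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .errors import AnalysisError

logger = logging.getLogger(__name__)


@dataclass
class NetworkResult:
    nodes: pd.DataFrame          # node, mean_abundance
    edges: pd.DataFrame          # source, target, weight (mb_coefficient), stability
    lambda_selected: float
    instability: pd.DataFrame    # lambda, instability, monotonized, n_edges


def clr_transform(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Centered log-ratio transform, rows = samples, columns = features."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise AnalysisError("counts must be non-negative")
    if pseudocount <= 0 and (x == 0).any():
        raise AnalysisError("zero counts require a positive pseudocount")
    logx = np.log(x + pseudocount)
    return logx - logx.mean(axis=1, keepdims=True)


def _mb_coefficients(X: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Directed MB coefficients for every lambda on a decreasing path.

    Returns array (n_lambdas, p, p); entry [l, j, k] is the coefficient of
    node k in the lasso regression of node j. Constant columns yield empty
    neighborhoods.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    coefs = np.zeros((len(lambdas), p, p))
    for j in range(p):
        y = Xc[:, j]
        others = np.delete(np.arange(p), j)
        if np.allclose(Xc[:, j].std(), 0):
            logger.warning("node %d is constant; left isolated", j)
            continue
        _, path_coefs, _ = lasso_path(Xc[:, others], y, alphas=lambdas)
        for li in range(len(lambdas)):
            coefs[li, j, others] = path_coefs[:, li]
    return coefs


def neighborhood_select(clr_matrix, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency (OR-merged) and symmetrised signed weights at one penalty."""
    X = np.asarray(clr_matrix, dtype=float)
    if X.shape[0] < 4:
        raise AnalysisError("need at least 4 samples for neighborhood selection")
    if lam < 0:
        raise AnalysisError("lambda must be non-negative")
    coefs = _mb_coefficients(X, np.array([max(lam, 1e-12)]))[0]
    adjacency = (coefs != 0) | (coefs.T != 0)
    np.fill_diagonal(adjacency, False)
    weights = (coefs + coefs.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    return adjacency, weights


def default_lambda_path(clr_matrix, n_lambda: int = 30, ratio: float = 0.01) -> np.ndarray:
    """Log-spaced decreasing path from the smallest fully-sparsifying
    penalty down to ``ratio`` times it."""
    X = np.asarray(clr_matrix, dtype=float)
    Xc = X - X.mean(axis=0)
    n, p = Xc.shape
    gram = np.abs(Xc.T @ Xc) / n
    np.fill_diagonal(gram, 0.0)
    lam_max = gram.max()
    if lam_max <= 0:
        raise AnalysisError("degenerate data: all columns uncorrelated/constant")
    return np.logspace(np.log10(lam_max), np.log10(lam_max * ratio), n_lambda)


def stars_select(
    clr_matrix,
    lambda_path=None,
    n_subsamples: int = 50,
    subsample_size: int | None = None,
    instability_threshold: float = 0.05,
    seed: int = 0,
    display_threshold: float = 0.05,
    node_names=None,
    mean_abundance=None,
) -> NetworkResult:
    """StARS-selected sparse network.

    For each penalty on the (decreasing) path, the edge selection frequency
    over ``n_subsamples`` subsamples of ``subsample_size`` rows (default
    ``min(floor(10*sqrt(n)), 0.8n)``) gives the total instability
    ``mean(2 f (1-f))``; the selected penalty is the smallest whose
    monotonized (running-max from the sparse end) instability stays at or
    below the threshold — i.e. the densest stable graph. The final fit on
    the full data at that penalty yields the emitted edges; edges with
    |weight| below ``display_threshold`` are suppressed.
    """
    X = np.asarray(clr_matrix, dtype=float)
    n, p = X.shape
    if lambda_path is None:
        lambda_path = default_lambda_path(X)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(lambda_path) > 0):
        raise AnalysisError("lambda path must be decreasing")
    if n_subsamples < 20:
        raise AnalysisError("StARS needs at least 20 subsamples")
    if subsample_size is None:
        subsample_size = int(min(np.floor(10 * np.sqrt(n)), np.floor(0.8 * n)))
    subsample_size = max(4, min(subsample_size, n))

    rng = np.random.default_rng(seed)
    freq = np.zeros((len(lambda_path), p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=subsample_size, replace=False)
        coefs = _mb_coefficients(X[idx], lambda_path)
        sel = (coefs != 0) | (np.transpose(coefs, (0, 2, 1)) != 0)
        freq += sel
    freq /= n_subsamples
    iu = np.triu_indices(p, k=1)
    f = freq[:, iu[0], iu[1]]
    instability = (2 * f * (1 - f)).mean(axis=1)
    monotonized = np.maximum.accumulate(instability)
    ok = monotonized <= instability_threshold
    if ok.any():
        sel_idx = int(np.flatnonzero(ok).max())
    else:
        sel_idx = 0
        logger.warning("no penalty met the instability threshold; using the sparsest")
    lam = float(lambda_path[sel_idx])

    coefs = _mb_coefficients(X, lambda_path)
    n_edges_path = [int(((c != 0) | (c.T != 0))[iu].sum()) for c in coefs]
    full = coefs[sel_idx]
    adjacency = (full != 0) | (full.T != 0)
    weights = (full + full.T) / 2.0

    if node_names is None:
        node_names = [f"node{i}" for i in range(p)]
    if mean_abundance is None:
        mean_abundance = np.full(p, np.nan)
    nodes = pd.DataFrame({"node": node_names, "mean_abundance": mean_abundance})
    rows = []
    stab = freq[sel_idx]
    for i, j in zip(*iu):
        if adjacency[i, j] and abs(weights[i, j]) >= display_threshold:
            rows.append(dict(source=node_names[i], target=node_names[j],
                             mb_coefficient=float(weights[i, j]),
                             stability=float(stab[i, j])))
    edges = pd.DataFrame(rows, columns=["source", "target", "mb_coefficient", "stability"])
    curve = pd.DataFrame({"lambda": lambda_path, "instability": instability,
                          "monotonized": monotonized, "n_edges": n_edges_path})
    return NetworkResult(nodes, edges, lam, curve)
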