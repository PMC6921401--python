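"""Bayesian microbial source tracking by collapsed Gibbs sampling.

Each sink community is modelled as a mixture of the collapsed taxon profiles
of the declared source environments plus a latent "Unknown" source with no
observed counts. Every sink read i (of taxon t_i) carries a latent source
label z_i, resampled one read at a time from

    P(z_i = v | rest) ∝  (m_vt + n^-i_vt + alpha_v) / (M_v + N^-i_v + alpha_v T)
                        * (N^-i_v + beta)

where m_vt are the collapsed source counts (zero for Unknown), n^-i_vt the
sink reads currently assigned to v with taxon t excluding read i, M_v and
N^-i_v the corresponding totals, T the number of taxa, alpha_v the per-taxon
Dirichlet pseudocount (``alpha1`` for known sources, ``alpha2`` for
Unknown), and beta the Dirichlet prior on the mixing proportions. Retained
draws record the assignment fractions N_v / N; independent restarts are
pooled. Defaults mirror SourceTracker v1.0.

The per-read sweep is compiled with numba; a pure-Python twin of the kernel
is kept for verification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .data_model import FeatureTable, SampleMetadata
from .errors import AnalysisError

logger = logging.getLogger(__name__)

UNKNOWN_LABEL = "Unknown"


@dataclass
class GibbsConfig:
    """Sampler settings; defaults follow SourceTracker v1.0."""

    alpha1: float = 0.001   # per-taxon pseudocount, known sources
    alpha2: float = 0.1     # per-taxon pseudocount, Unknown source
    beta: float = 10.0      # Dirichlet prior on mixing proportions
    n_restarts: int = 10
    n_burnin: int = 100     # sweeps discarded per restart
    n_draws: int = 1        # retained draws per restart
    draw_spacing: int = 10  # sweeps between retained draws
    depth: int = 1000       # sink rarefaction depth
    seed: int = 0

    def __post_init__(self):
        if min(self.alpha1, self.alpha2, self.beta) <= 0:
            raise AnalysisError("alpha1, alpha2 and beta must be positive")
        if self.n_draws < 1 or self.n_restarts < 1 or self.depth <= 0:
            raise AnalysisError("n_draws, n_restarts and depth must be positive")


@dataclass
class MixingEstimate:
    """Posterior mixing proportions of one sink over sources + Unknown."""

    sink_id: str
    environments: list[str]
    draws: np.ndarray  # (n_total_draws, n_environments), rows sum to 1
    means: dict[str, float] = field(init=False)
    sds: dict[str, float] = field(init=False)

    def __post_init__(self):
        mean = self.draws.mean(axis=0)
        sd = self.draws.std(axis=0, ddof=0)
        self.means = {e: float(m) for e, m in zip(self.environments, mean)}
        self.sds = {e: float(s) for e, s in zip(self.environments, sd)}


@njit(cache=True)
def _gibbs_kernel(taxa, m, M, alpha, beta, T, n_sweeps, z, n_vt, N_v, u, probs):
    """Run ``n_sweeps`` full Gibbs sweeps in place; u holds one uniform per
    read per sweep."""
    N = taxa.shape[0]
    V = N_v.shape[0]
    k = 0
    for _ in range(n_sweeps):
        for i in range(N):
            t = taxa[i]
            v_old = z[i]
            n_vt[v_old, t] -= 1.0
            N_v[v_old] -= 1.0
            tot = 0.0
            for v in range(V):
                p = ((m[v, t] + n_vt[v, t] + alpha[v])
                     / (M[v] + N_v[v] + alpha[v] * T)) * (N_v[v] + beta)
                tot += p
                probs[v] = tot
            r = u[k] * tot
            k += 1
            v_new = 0
            while probs[v_new] < r:
                v_new += 1
            z[i] = v_new
            n_vt[v_new, t] += 1.0
            N_v[v_new] += 1.0


def _gibbs_kernel_py(taxa, m, M, alpha, beta, T, n_sweeps, z, n_vt, N_v, u, probs):
    """Pure-Python twin of :func:`_gibbs_kernel` (reference/verification)."""
    _gibbs_kernel.py_func(taxa, m, M, alpha, beta, T, n_sweeps, z, n_vt, N_v, u, probs)


def collapse_sources(
    table: FeatureTable,
    metadata: SampleMetadata,
    dyad_id: str | None = None,
    day_window: tuple[int, int] | None = None,
) -> tuple[list[str], np.ndarray]:
    """Sum counts across source samples per environment.

    Returns environment names (sorted) and a (n_environments x n_features)
    count matrix. ``dyad_id`` restricts to one sow's own samples (plus
    sources with no dyad attribution); ``day_window`` restricts by sampling
    day.
    """
    src = metadata.sources()
    if day_window is not None:
        src = src[(src["day"] >= day_window[0]) & (src["day"] <= day_window[1])]
    if dyad_id is not None:
        src = src[(src["dyad_id"] == dyad_id) | src["dyad_id"].isna()]
    if src.empty:
        raise AnalysisError("no source samples after filtering")
    envs = sorted(src["environment"].unique())
    rows = []
    for env in envs:
        ids = [s for s in src.index[src["environment"] == env] if s in table.counts.columns]
        if not ids:
            raise AnalysisError(f"source environment {env!r} has no samples in the table")
        rows.append(table.counts[ids].sum(axis=1).to_numpy())
    return envs, np.asarray(rows, dtype=np.float64)


def fit_sink(
    sink_counts,
    source_matrix: np.ndarray,
    environments: list[str],
    config: GibbsConfig,
    rng: np.random.Generator | None = None,
    sink_id: str = "sink",
) -> MixingEstimate:
    """Posterior mixing proportions for one sink community."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sink_counts = np.asarray(sink_counts)
    source_matrix = np.asarray(source_matrix, dtype=np.float64)
    if source_matrix.ndim != 2 or source_matrix.shape[0] == 0:
        raise AnalysisError("need at least one source environment")
    total = int(sink_counts.sum())
    if total == 0:
        raise AnalysisError(f"sink {sink_id!r} has zero total count")
    if total > config.depth:
        sink_counts = rng.multivariate_hypergeometric(sink_counts.astype(np.int64),
                                                      config.depth)
    elif total < config.depth:
        logger.warning("sink %s total %d below depth %d; used at native depth",
                       sink_id, total, config.depth)

    T = len(sink_counts)
    S = source_matrix.shape[0]
    V = S + 1
    m = np.vstack([source_matrix, np.zeros(T)])
    M = m.sum(axis=1)
    alpha = np.array([config.alpha1] * S + [config.alpha2])
    taxa = np.repeat(np.arange(T, dtype=np.int64), sink_counts).astype(np.int64)
    N = taxa.shape[0]

    all_draws = []
    probs = np.empty(V)
    for _ in range(config.n_restarts):
        z = rng.integers(0, V, size=N).astype(np.int64)
        n_vt = np.zeros((V, T))
        np.add.at(n_vt, (z, taxa), 1.0)
        N_v = n_vt.sum(axis=1)
        phases = [config.n_burnin] + [config.draw_spacing] * (config.n_draws - 1)
        for sweeps in phases:
            u = rng.random(sweeps * N)
            _gibbs_kernel(taxa, m, M, alpha, config.beta, float(T), sweeps,
                          z, n_vt, N_v, u, probs)
            all_draws.append(N_v / N)
    draws = np.asarray(all_draws)
    return MixingEstimate(sink_id, list(environments) + [UNKNOWN_LABEL], draws)


def track_all(
    table: FeatureTable,
    metadata: SampleMetadata,
    config: GibbsConfig,
    dyad_only: bool = False,
    day_window: tuple[int, int] | None = None,
) -> tuple[list[MixingEstimate], pd.DataFrame]:
    """Run the sampler for every sink; summarise per (segment, day, source).

    The long-format summary holds one row per (segment, day, environment)
    with the mean and SE of the posterior-mean proportions across sinks —
    the numbers behind a stacked source-contribution chart.
    """
    sinks = metadata.sinks()
    if sinks.empty:
        raise AnalysisError("no sink samples in metadata")
    rng = np.random.default_rng(config.seed)
    if not dyad_only:
        envs, sources = collapse_sources(table, metadata, day_window=day_window)
    estimates = []
    for sid, row in sinks.iterrows():
        if sid not in table.counts.columns:
            continue
        if dyad_only:
            envs, sources = collapse_sources(table, metadata, dyad_id=row["dyad_id"],
                                             day_window=day_window)
        est = fit_sink(table.sample_counts(sid), sources, envs, config,
                       rng=rng, sink_id=sid)
        estimates.append(est)

    rows = []
    meta = metadata.frame
    for est in estimates:
        seg = meta.loc[est.sink_id, "environment"]
        day = meta.loc[est.sink_id, "day"]
        for env in est.environments:
            rows.append(dict(sink_id=est.sink_id, segment=seg, day=day,
                             environment=env, mean=est.means[env], sd=est.sds[env]))
    per_sink = pd.DataFrame(rows)
    summary = (per_sink.groupby(["segment", "day", "environment"])["mean"]
               .agg(["mean", "sem", "count"])
               .rename(columns={"mean": "mean_proportion", "sem": "se", "count": "n"})
               .reset_index())
    summary["se"] = summary["se"].fillna(0.0)
    return estimates, summary
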