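import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.stats import hypergeom

from suckletrack.data_model import SampleMetadata
from suckletrack.diversity import distance_matrix
from suckletrack.errors import AnalysisError
from suckletrack.simulate import SimulationConfig, TransmittedOtuSpec, simulate_dataset
from suckletrack.transmission import (
    classify_transmitted,
    dyad_vs_random_distance,
    fisher_dyad_test,
    prevalence_filter,
    sharing_permutation_test,
    sharing_statistic,
    spearman_paired,
    transmission_summary,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    n = a + b + c + d
    row = a + b
    col = a + c
    p_obs = hypergeom.pmf(a, n, row, col)
    p = 0.0
    for x in range(max(0, row + col - n), min(row, col) + 1):
        px = hypergeom.pmf(x, n, row, col)
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(p, 1.0)


class TestSharing:
    def test_all_dyads_share(self):
        assert sharing_statistic([1] * 8, [1] * 8) == 1.0

    def test_partial_overlap(self):
        src = [1, 1, 1, 0]
        snk = [0, 1, 1, 1]
        assert sharing_statistic(src, snk) == 0.5

    def test_absent_from_sinks(self):
        assert sharing_statistic([1, 1], [0, 0]) == 0.0

    def test_empty_errors(self):
        with pytest.raises(AnalysisError):
            sharing_statistic([], [])


class TestSharingPermutation:
    def test_degenerate_everywhere_present_p_one(self):
        p = sharing_permutation_test([1] * 5, [1] * 5)
        assert p == pytest.approx(1.0)

    def test_single_matching_pair_exact_p(self):
        # present in one source and the matching sink only: p = 1/n
        for n in (3, 5, 7):
            src = [1] + [0] * (n - 1)
            snk = [1] + [0] * (n - 1)
            assert sharing_permutation_test(src, snk) == pytest.approx(1 / n)

    def test_exhaustive_matches_montecarlo(self):
        src = np.array([1, 1, 1, 0])
        snk = np.array([1, 1, 1, 0])
        exact = sharing_permutation_test(src, snk)  # 24 pairings enumerated
        mc = sharing_permutation_test(src, snk, n_permutations=20000, seed=0,
                                      exhaustive_when_small=False)
        se = math.sqrt(exact * (1 - exact) / 20000)
        assert abs(mc - exact) < 2 * se + 2 / 20000

    def test_exhaustive_oracle_by_direct_enumeration(self):
        src = np.array([1, 0, 1, 0, 1])
        snk = np.array([1, 1, 0, 0, 1])
        obs = (src & snk).mean()
        count = total = 0
        for perm in itertools.permutations(range(5)):
            count += (src[list(perm)] & snk).mean() >= obs - 1e-12
            total += 1
        assert sharing_permutation_test(src, snk) == pytest.approx(count / total)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((3, 0, 0, 3), 0.1),            # 2/20
        ((5, 0, 0, 5), 2 / 252),
        ((4, 0, 4, 0), 1.0),            # zero margin
    ])
    def test_worked_examples(self, table, expected):
        a, b, c, d = table
        src = [1] * (a + b) + [0] * (c + d)
        snk = [1] * a + [0] * b + [1] * c + [0] * d
        assert fisher_dyad_test(src, snk) == pytest.approx(expected)

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every 2x2 table with n <= 12 agrees with the hypergeometric sum."""
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        src = [1] * (a + b) + [0] * (c + d)
                        snk = [1] * a + [0] * b + [1] * c + [0] * d
                        assert fisher_dyad_test(src, snk) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)


class TestSpearman:
    def test_monotone_is_one(self):
        rho, _ = spearman_paired([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_worked_example(self):
        rho, p = spearman_paired([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_errors(self):
        with pytest.raises(AnalysisError):
            spearman_paired([1, 2, 3, 4], [5, 5, 5, 5])

    def test_exact_p_matches_enumeration(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 5, 3, 4]
        rho, p = spearman_paired(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        obs = np.corrcoef(rx, ry)[0, 1]
        hits = total = 0
        for perm in itertools.permutations(ry):
            hits += abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12
            total += 1
        assert p == pytest.approx(hits / total)


class TestPrevalenceFilter:
    def test_either_group_branch(self):
        src = np.array([[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]])  # 3/10
        snk = np.zeros((1, 10))
        assert prevalence_filter(src > 0, snk > 0, 0.2)[0]

    def test_boundary_is_strict(self):
        src = np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 0]])  # exactly 0.2
        snk = np.array([[1, 1, 0, 0, 0, 0, 0, 0, 0, 0]])
        assert not prevalence_filter(src > 0, snk > 0, 0.2)[0]

    def test_absent_everywhere_excluded(self):
        src = np.zeros((1, 4), dtype=bool)
        snk = np.zeros((1, 4), dtype=bool)
        assert not prevalence_filter(src, snk, 0.2)[0]


def planted_config(seed, null=False, n_dyads=8):
    return SimulationConfig(
        n_dyads=n_dyads,
        n_features=150,
        days=(0, 1, 3),
        depth=2000,
        host_jitter=None,  # no dam effect: presence independent across dyads
        transmitted=None if null else TransmittedOtuSpec(
            n_planted=10, p_share=0.9, background=0.2, n_universal=0),
        expression=None,
        seed=seed,
    )


def run_classify(ds, seed=0, alpha=0.05):
    return classify_transmitted(
        ds.table, ds.metadata, source_envs=["milk"], windows=((0, 3),),
        alpha=alpha, n_permutations=999, seed=seed)


class TestClassify:
    def test_low_prevalence_not_evaluated(self, small_dataset):
        records = classify_transmitted(small_dataset.table, small_dataset.metadata,
                                       source_envs=["milk"], windows=((0, 3),),
                                       seed=0)
        sub = records[records["decision"] == "not_evaluated"]
        assert len(sub) > 0
        assert sub["p_perm"].isna().all()

    def test_alpha_monotonicity(self):
        ds = simulate_dataset(planted_config(3))
        strict = run_classify(ds, alpha=0.01)
        loose = run_classify(ds, alpha=0.05)
        s_set = set(map(tuple, strict.loc[strict.decision == "transmitted",
                                          ["otu", "segment", "window"]].to_numpy()))
        l_set = set(map(tuple, loose.loc[loose.decision == "transmitted",
                                         ["otu", "segment", "window"]].to_numpy()))
        assert s_set <= l_set

    def test_planted_otus_recovered_single_seed(self):
        ds = simulate_dataset(planted_config(5))
        records = run_classify(ds)
        planted = ds.truth.transmitted_ids()
        detected = set(records.loc[records.decision == "transmitted", "otu"])
        assert len(detected & planted) / len(planted) >= 0.7

    def test_universal_otu_detected_via_abundance_branch(self):
        cfg = planted_config(8)
        cfg.transmitted = TransmittedOtuSpec(n_planted=0, n_universal=3,
                                             universal_noise=0.05)
        ds = simulate_dataset(cfg)
        records = run_classify(ds)
        hits = records[(records.decision == "transmitted")
                       & (records.branch == "abundance")]
        assert len(set(hits["otu"]) & ds.truth.transmitted_ids()) >= 2

    def test_summary_counts_events_and_otus(self):
        ds = simulate_dataset(planted_config(5))
        records = run_classify(ds)
        summary = transmission_summary(records)
        assert summary.attrs["n_events_total"] >= summary.attrs["n_otus_total"]

    def test_invalid_alpha(self, small_dataset):
        with pytest.raises(AnalysisError):
            classify_transmitted(small_dataset.table, small_dataset.metadata,
                                 alpha=1.5)


class TestDyadVsRandom:
    def test_dam_effect_detected(self):
        cfg = SimulationConfig(n_dyads=8, n_features=120, days=(1, 3),
                               depth=2000, host_jitter=30.0,  # strong dam effect
                               transmitted=None, expression=None, seed=2)
        ds = simulate_dataset(cfg)
        dm = distance_matrix(ds.table, "bray_curtis")
        t_mean, r_mean, p = dyad_vs_random_distance(dm, ds.metadata, "milk",
                                                    n_random=3, seed=0)
        assert t_mean < r_mean
        assert p < 0.05

    def test_all_equal_distances_p_one(self):
        ids = ["src_milk_a", "src_milk_b", "snk1", "snk2"]
        data = 1 - np.eye(4)
        dm = skbio.DistanceMatrix(data, ids=ids)
        meta = SampleMetadata(pd.DataFrame([
            dict(sample_id="src_milk_a", role="source", environment="milk",
                 host_id="a", dyad_id="a", day=0),
            dict(sample_id="src_milk_b", role="source", environment="milk",
                 host_id="b", dyad_id="b", day=0),
            dict(sample_id="snk1", role="sink", environment="colon",
                 host_id="p1", dyad_id="a", day=1),
            dict(sample_id="snk2", role="sink", environment="colon",
                 host_id="p2", dyad_id="b", day=1),
        ]))
        _, _, p = dyad_vs_random_distance(dm, meta, "milk", seed=0)
        assert p == pytest.approx(1.0)

    def test_single_dam_errors(self, tiny_table, tiny_metadata):
        dm = distance_matrix(tiny_table, "bray_curtis")
        with pytest.raises(AnalysisError):
            dyad_vs_random_distance(dm, tiny_metadata, "milk")
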