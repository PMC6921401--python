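import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from suckletrack.data_model import FeatureTable, SampleMetadata, PhyloTree
from suckletrack.diversity import (
    alpha_diversity,
    beta_trajectory,
    bray_curtis,
    chao1,
    distance_matrix,
    rarefy,
    shannon,
    unweighted_unifrac,
    weighted_unifrac,
)
from suckletrack.errors import AnalysisError
from suckletrack.simulate import simulate_tree
import skbio
import io


def tree_from(newick: str) -> PhyloTree:
    return PhyloTree(skbio.TreeNode.read(io.StringIO(newick)))


# ---------------------------------------------------------------------------
# brute-force UniFrac oracle: enumerate every branch explicitly


def brute_force_unifrac(tree: PhyloTree, x, y, ids, weighted=False):
    xs = dict(zip(ids, np.asarray(x, dtype=float)))
    ys = dict(zip(ids, np.asarray(y, dtype=float)))
    totx = sum(xs.values())
    toty = sum(ys.values())
    unique = observed = wsum = 0.0
    for node in tree.tree.traverse(include_self=False):
        names = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        sx = sum(xs.get(n, 0.0) for n in names)
        sy = sum(ys.get(n, 0.0) for n in names)
        length = node.length or 0.0
        if weighted:
            wsum += length * abs(sx / totx - sy / toty)
        else:
            if sx > 0 or sy > 0:
                observed += length
            if (sx > 0) != (sy > 0):
                unique += length
    return wsum if weighted else (unique / observed if observed else 0.0)


class TestRarefy:
    def test_sample_at_depth_unchanged(self, tiny_table):
        out = rarefy(tiny_table, 8, seed=0)  # s1 and s3 total exactly 8
        assert (out.counts["s1"] == tiny_table.counts["s1"]).all()

    def test_counts_sum_to_depth_and_subsampling_is_hypergeometric(self):
        table = FeatureTable(pd.DataFrame({"s": [90, 10]}, index=["a", "b"]))
        draws = []
        for seed in range(1000):
            out = rarefy(table, 10, seed=seed)
            assert out.counts["s"].sum() == 10
            draws.append(out.counts.loc["a", "s"])
        mean = np.mean(draws)
        # hypergeometric: E = 9, Var = 10*.9*.1*90/99
        se = np.sqrt(10 * 0.9 * 0.1 * (90 / 99) / 1000)
        assert abs(mean - 9.0) < 2.58 * se

    def test_strict_policy_errors_below_depth(self, tiny_table):
        with pytest.raises(AnalysisError, match="below depth"):
            rarefy(tiny_table, 10, policy="strict")

    def test_all_samples_below_depth_error(self, tiny_table):
        with pytest.raises(AnalysisError):
            rarefy(tiny_table, 10_000)

    def test_presence_only_of_sampled_features(self, rng):
        counts = rng.integers(0, 50, size=(30, 4))
        table = FeatureTable(pd.DataFrame(counts, index=[f"f{i}" for i in range(30)],
                                          columns=list("abcd")))
        depth = int(table.counts.sum(axis=0).min())
        out = rarefy(table, depth, seed=1)
        assert ((out.counts > 0) <= (table.counts > 0)).all().all()


class TestAlpha:
    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 2, 3], 4.5),       # F1=2, F2=1
        ([1, 1, 1, 1], 10.0),      # F1=4, F2=0
        ([3, 3, 5], 3.0),          # no singletons -> S_obs
    ])
    def test_chao1_formula(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    def test_chao1_at_least_observed_richness(self, rng):
        for _ in range(50):
            v = rng.integers(0, 5, size=20)
            if v.sum() == 0:
                continue
            assert chao1(v) >= (v > 0).sum()

    @pytest.mark.parametrize("counts,expected", [
        ([5, 5], 1.0),
        ([0, 7, 0], 0.0),
        ([1, 1, 2], 1.5),
    ])
    def test_shannon_bits(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    def test_shannon_natural_log_option(self):
        assert shannon([1, 1], base=np.e) == pytest.approx(np.log(2))

    def test_empty_sample_errors(self):
        with pytest.raises(AnalysisError):
            chao1([0, 0])
        with pytest.raises(AnalysisError):
            shannon([0, 0])

    def test_alpha_diversity_series(self, tiny_table):
        s = alpha_diversity(tiny_table, "shannon")
        assert list(s.index) == tiny_table.sample_ids


class TestBrayCurtis:
    def test_identical_zero_disjoint_one(self):
        assert bray_curtis([3, 1], [3, 1]) == 0.0
        assert bray_curtis([3, 0], [0, 5]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([6, 2], [2, 2]) == pytest.approx(1 / 3)

    def test_both_empty_error(self):
        with pytest.raises(AnalysisError):
            bray_curtis([0], [0])


class TestUniFrac:
    def test_unweighted_worked_example(self):
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        d = unweighted_unifrac(tree, [1, 1, 0, 0], [1, 0, 1, 0], list("ABCD"))
        assert d == pytest.approx(0.6)  # unique 3 of observed 5

    def test_two_tips_disjoint_is_one(self):
        tree = tree_from("(A:1,B:1);")
        assert unweighted_unifrac(tree, [1, 0], [0, 1], ["A", "B"]) == pytest.approx(1.0)

    def test_weighted_scaling_invariance(self):
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        d1 = weighted_unifrac(tree, [4, 1, 0, 2], [1, 1, 3, 0], list("ABCD"))
        d2 = weighted_unifrac(tree, [40, 10, 0, 20], [1, 1, 3, 0], list("ABCD"))
        assert d1 == pytest.approx(d2)

    def test_zero_length_branch_contributes_nothing(self):
        # x and y differ only in tip B, whose branch has length 0
        tree = tree_from("((A:1,B:0):1,C:1);")
        d = unweighted_unifrac(tree, [1, 1, 1], [1, 0, 1], list("ABC"))
        assert d == pytest.approx(0.0)

    def test_empty_sample_errors(self):
        tree = tree_from("(A:1,B:1);")
        with pytest.raises(AnalysisError):
            unweighted_unifrac(tree, [0, 0], [1, 0], ["A", "B"])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        tree = simulate_tree(n, seed=seed)
        ids = tree.tip_names
        x = rng.integers(0, 5, size=n)
        y = rng.integers(0, 5, size=n)
        if x.sum() == 0:
            x[0] = 1
        if y.sum() == 0:
            y[-1] = 1
        assert unweighted_unifrac(tree, x, y, ids) == pytest.approx(
            brute_force_unifrac(tree, x, y, ids), abs=1e-10)
        assert weighted_unifrac(tree, x, y, ids) == pytest.approx(
            brute_force_unifrac(tree, x, y, ids, weighted=True), abs=1e-10)


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self):
        table = FeatureTable(pd.DataFrame({"a": [3, 1], "b": [3, 1], "c": [3, 1]},
                                          index=["f1", "f2"]))
        dm = distance_matrix(table, "bray_curtis")
        assert np.allclose(dm.data, 0)

    def test_matches_pairwise_function(self, rng):
        counts = rng.integers(1, 30, size=(6, 4))
        table = FeatureTable(pd.DataFrame(counts, index=[f"f{i}" for i in range(6)],
                                          columns=list("abcd")))
        dm = distance_matrix(table, "bray_curtis")
        for i, si in enumerate("abcd"):
            for j, sj in enumerate("abcd"):
                assert dm.data[i, j] == pytest.approx(
                    bray_curtis(counts[:, i], counts[:, j]))

    def test_unifrac_requires_tree(self, tiny_table):
        with pytest.raises(AnalysisError, match="tree"):
            distance_matrix(tiny_table, "weighted_unifrac")

    def test_sample_permutation_permutes_matrix(self, rng):
        counts = rng.integers(1, 20, size=(5, 3))
        t1 = FeatureTable(pd.DataFrame(counts, index=[f"f{i}" for i in range(5)],
                                       columns=["a", "b", "c"]))
        t2 = t1.filter_samples(["c", "a", "b"])
        d1 = distance_matrix(t1, "bray_curtis")
        d2 = distance_matrix(t2, "bray_curtis")
        assert d1["a", "c"] == pytest.approx(d2["a", "c"])


class TestTrajectory:
    def _dm_meta(self):
        ids = ["a", "b", "c", "d"]
        data = np.array([[0, .2, .5, .5], [.2, 0, .5, .5],
                         [.5, .5, 0, .4], [.5, .5, .4, 0]])
        dm = skbio.DistanceMatrix(data, ids=ids)
        meta = SampleMetadata(pd.DataFrame([
            dict(sample_id="a", role="sink", environment="colon", host_id="p1",
                 dyad_id="s1", day=0),
            dict(sample_id="b", role="sink", environment="colon", host_id="p2",
                 dyad_id="s1", day=0),
            dict(sample_id="c", role="sink", environment="colon", host_id="p3",
                 dyad_id="s1", day=7),
            dict(sample_id="d", role="sink", environment="colon", host_id="p4",
                 dyad_id="s1", day=7),
        ]))
        return dm, meta

    def test_within_mode_two_samples_mean_is_their_distance(self):
        dm, meta = self._dm_meta()
        out = beta_trajectory(dm, meta, mode="within")
        day0 = out[out["day"] == 0].iloc[0]
        assert day0["mean"] == pytest.approx(0.2)
        day7 = out[out["day"] == 7].iloc[0]
        assert day7["mean"] == pytest.approx(0.4)

    def test_from_day0_divergence(self):
        dm, meta = self._dm_meta()
        out = beta_trajectory(dm, meta, mode="from_day0")
        assert out[out["day"] == 7]["mean"].iloc[0] == pytest.approx(0.5)

    def test_unknown_mode_errors(self):
        dm, meta = self._dm_meta()
        with pytest.raises(AnalysisError):
            beta_trajectory(dm, meta, mode="sideways")
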