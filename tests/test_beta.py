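import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from skbio import DistanceMatrix

from aridnet.beta import (anosim, best_bioenv, env_distance, mantel, pcoa,
                          unifrac)
from aridnet.errors import ConfigurationError, ConstantInputError
from aridnet.io import OtuTable


def make_table(rows, samples, otus):
    return OtuTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestUnifrac:
    def test_identical_samples_zero(self, four_leaf_tree):
        t = make_table([[1, 1, 0, 0], [1, 1, 0, 0]], ["s1", "s2"],
                       list("ABCD"))
        dm = unifrac(t, four_leaf_tree)
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_clades_fully_distant(self, four_leaf_tree):
        # samples occupy disjoint clades: no shared observed branch
        t = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], ["s1", "s2"],
                       list("ABCD"))
        dm = unifrac(t, four_leaf_tree)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_shared_and_unique_branches_oracle(self, four_leaf_tree):
        # {A,B} vs {A,C}: observed branches differ in B:1, C:1 and the
        # two internal unit branches are split one each; union covers 5
        # -> unweighted = 3/5 by per-branch enumeration
        t = make_table([[1, 1, 0, 0], [1, 0, 1, 0]], ["s1", "s2"],
                       list("ABCD"))
        dm = unifrac(t, four_leaf_tree)
        assert dm["s1", "s2"] == pytest.approx(3.0 / 5.0)

    def test_weighted_bounded_and_zero_diagonal(self, four_leaf_tree):
        t = make_table([[5, 1, 0, 0], [0, 1, 5, 0]], ["s1", "s2"],
                       list("ABCD"))
        dm = unifrac(t, four_leaf_tree, weighted=True)
        assert 0.0 <= dm["s1", "s2"] <= 1.0


class TestPcoa:
    def test_points_on_a_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        props = res.proportion_explained
        assert props.iloc[0] == pytest.approx(1.0, abs=1e-9)
        pc1 = res.samples.iloc[:, 0].to_numpy()
        recovered = np.abs(pc1[:, None] - pc1[None, :])
        assert np.allclose(recovered, d, atol=1e-8)

    def test_all_zero_distances(self):
        res = pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))
        assert np.allclose(res.samples.to_numpy(), 0.0, atol=1e-12)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        coords = res.samples.to_numpy()
        rec = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(coords))
        assert np.allclose(rec, d, atol=1e-8)


class TestEnvDistance:
    def test_two_samples_one_sd_apart(self):
        meta = pd.DataFrame({"v": [0.0, 1.0]}, index=["a", "b"])
        sd = meta["v"].std(ddof=1)
        dm = env_distance(meta, ["v"])
        assert dm["a", "b"] == pytest.approx(1.0 / sd)

    def test_duplicate_variable_scales_by_sqrt2(self):
        meta = pd.DataFrame({"v": [0.0, 1.0, 3.0], "w": [0.0, 1.0, 3.0]},
                            index=list("abc"))
        d1 = env_distance(meta, ["v"])
        d2 = env_distance(meta, ["v", "w"])
        assert d2["a", "c"] == pytest.approx(math.sqrt(2) * d1["a", "c"])

    def test_hand_computed_three_variables(self):
        meta = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                             "y": [0.0, 0.0, 1.0, 1.0],
                             "z": [5.0, 1.0, 5.0, 1.0]},
                            index=list("abcd"))
        Z = (meta - meta.mean()) / meta.std(ddof=1)
        expected = np.linalg.norm(Z.loc["a"] - Z.loc["d"])
        dm = env_distance(meta, ["x", "y", "z"])
        assert dm["a", "d"] == pytest.approx(expected)

    def test_constant_variable_raises(self):
        meta = pd.DataFrame({"v": [2.0, 2.0, 2.0]}, index=list("abc"))
        with pytest.raises(ConstantInputError):
            env_distance(meta, ["v"])


def _mantel_enumeration_oracle(d1, d2):
    """Exact one-sided Mantel p by full enumeration of relabellings."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = scipy.stats.rankdata(d1[iu])

    def corr(perm):
        dp = d2[np.ix_(perm, perm)][iu]
        return scipy.stats.pearsonr(x, scipy.stats.rankdata(dp)).statistic

    r_obs = corr(np.arange(n))
    hits = sum(corr(np.array(p)) >= r_obs - 1e-12
               for p in itertools.permutations(range(n)))
    return r_obs, hits / math.factorial(n)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        d = scipy.spatial.distance.squareform(rng.uniform(0.1, 1, 10))
        dm = DistanceMatrix(d, ids=list("abcde"))
        r, _ = mantel(dm, dm, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exhaustive_p_matches_enumeration(self):
        rng = np.random.default_rng(3)
        d1 = scipy.spatial.distance.squareform(rng.uniform(0.1, 1, 10))
        d2 = scipy.spatial.distance.squareform(rng.uniform(0.1, 1, 10))
        ids = list("abcde")
        r, p = mantel(DistanceMatrix(d1, ids=ids),
                      DistanceMatrix(d2, ids=ids), n_perm=9999, seed=0)
        r_oracle, p_oracle = _mantel_enumeration_oracle(d1, d2)
        assert r == pytest.approx(r_oracle)
        assert p == pytest.approx(p_oracle)

    def test_agrees_with_skbio_statistic(self):
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(5)
        d1 = scipy.spatial.distance.squareform(rng.uniform(0.1, 1, 28))
        d2 = scipy.spatial.distance.squareform(
            d1[np.triu_indices(8, 1)] * 0.5 + rng.uniform(0, 0.3, 28))
        ids = [str(i) for i in range(8)]
        r, _ = mantel(DistanceMatrix(d1, ids=ids),
                      DistanceMatrix(d2, ids=ids), n_perm=99, seed=0)
        r_skbio, _, _ = skbio_mantel(DistanceMatrix(d1, ids=ids),
                                     DistanceMatrix(d2, ids=ids),
                                     method="spearman", permutations=0)
        assert r == pytest.approx(r_skbio, abs=1e-12)

    def test_mismatched_ids_raise(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(Exception):
            mantel(DistanceMatrix(d, ids=list("abc")),
                   DistanceMatrix(d, ids=list("abd")))


class TestAnosim:
    def test_perfectly_separated_groups(self):
        # all between-group distances exceed all within-group distances
        d = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.85, 0.95],
            [0.9, 0.85, 0.0, 0.2],
            [0.8, 0.95, 0.2, 0.0],
        ])
        dm = DistanceMatrix(d, ids=list("abcd"))
        R, _ = anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert R == pytest.approx(1.0)

    def test_statistic_matches_brute_force_ranks(self):
        rng = np.random.default_rng(2)
        d = scipy.spatial.distance.squareform(rng.uniform(0.1, 1, 15))
        dm = DistanceMatrix(d, ids=list("abcdef"))
        groups = np.array(["x", "x", "x", "y", "y", "y"])
        R, _ = anosim(dm, groups, n_perm=99, seed=0)
        iu = np.triu_indices(6, 1)
        ranks = scipy.stats.rankdata(d[iu])
        within = groups[iu[0]] == groups[iu[1]]
        expected = (ranks[~within].mean() - ranks[within].mean()) \
            / (6 * 5 / 4)
        assert R == pytest.approx(expected)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import anosim as skbio_anosim
        rng = np.random.default_rng(4)
        d = scipy.spatial.distance.squareform(rng.uniform(0.1, 1, 28))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(8)])
        groups = ["a"] * 4 + ["b"] * 4
        R, _ = anosim(dm, groups, n_perm=99, seed=0)
        expected = skbio_anosim(dm, grouping=groups, permutations=0)
        assert R == pytest.approx(expected["test statistic"], abs=1e-12)

    def test_singleton_group_raises(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ConfigurationError):
            anosim(DistanceMatrix(d, ids=list("abc")), ["a", "a", "b"])


class TestBestBioenv:
    def test_planted_single_driver_ranks_first(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame({
            "driver": np.linspace(0, 10, 8),
            "noise1": rng.normal(size=8),
            "noise2": rng.normal(size=8),
        }, index=[f"s{i}" for i in range(8)])
        dm = env_distance(meta, ["driver"])
        table = best_bioenv(dm, meta, ["driver", "noise1", "noise2"])
        assert table.iloc[0]["variables"] == "driver"
        assert table.iloc[0]["rs"] == pytest.approx(1.0)
        # exhaustive search over 2^3 - 1 subsets
        assert len(table) == 7
        assert (table["rs"] <= 1.0 + 1e-12).all()

    def test_subset_count_is_two_to_k_minus_one(self, tiny_dataset):
        dataset, _ = tiny_dataset
        from aridnet.beta import unifrac as uf
        dm = uf(dataset.table, dataset.tree)
        variables = ["elevation", "AvgSoilRH", "pH", "EC"]
        table = best_bioenv(dm, dataset.metadata, variables)
        assert len(table) == 2 ** 4 - 1

    def test_too_many_variables_raises(self):
        meta = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 20)),
                            columns=[f"v{i}" for i in range(20)])
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list(meta.index.astype(str)))
        with pytest.raises(ConfigurationError):
            best_bioenv(dm, meta, list(meta.columns))
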