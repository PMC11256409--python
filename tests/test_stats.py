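"""Diversity statistics: alpha, Bray-Curtis, PCoA, PERMANOVA, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from virowas.stats import alpha_diversity, bray_curtis, pcoa, permanova, spearman


class TestAlphaDiversity:
    def test_even_pair(self):
        observed, shannon = alpha_diversity(pd.Series({"a": 0.5, "b": 0.5}))
        assert observed == 2
        assert shannon == pytest.approx(np.log(2))

    def test_single_taxon_zero_entropy(self):
        observed, shannon = alpha_diversity(pd.Series({"a": 1.0, "b": 0.0}))
        assert (observed, shannon) == (1, 0.0)

    def test_uniform_four(self):
        row = pd.Series({f"v{i}": 0.25 for i in range(4)})
        assert alpha_diversity(row)[1] == pytest.approx(np.log(4))

    def test_subset_renormalizes(self):
        row = pd.Series({"e1": 0.05, "e2": 0.05, "p1": 0.9})
        kingdoms = {"e1": "eukaryotic", "e2": "eukaryotic", "p1": "prokaryotic"}
        observed, shannon = alpha_diversity(row, kingdoms, "eukaryotic")
        assert observed == 2
        assert shannon == pytest.approx(np.log(2))  # within-subset proportions

    def test_empty_subset(self):
        row = pd.Series({"p1": 1.0})
        assert alpha_diversity(row, {"p1": "prokaryotic"}, "eukaryotic") == (0, 0.0)

    def test_shannon_maximal_at_uniform(self, rng):
        uniform = pd.Series(np.full(12, 1 / 12))
        for _ in range(20):
            random_row = pd.Series(rng.dirichlet(np.ones(12)))
            assert alpha_diversity(random_row)[1] <= alpha_diversity(uniform)[1] + 1e-12


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        prof = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis(prof).loc["a", "b"] == pytest.approx(0.0)

    def test_disjoint_support_one(self):
        prof = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(prof).loc["a", "b"] == pytest.approx(1.0)

    def test_sqrt_worked_example(self):
        prof = pd.DataFrame([[4.0, 1.0], [1.0, 1.0]], index=["a", "b"])
        # sqrt -> (2,1) vs (1,1): d = (1+0)/(3+2)
        assert bray_curtis(prof).loc["a", "b"] == pytest.approx(0.2)

    def test_zero_rows_warn_and_get_zero_distance(self):
        prof = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]], index=list("abc"))
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(prof)
        assert d.loc["a", "b"] == 0.0

    def test_metric_properties_on_compositions(self, rng):
        prof = pd.DataFrame(rng.dirichlet(np.ones(10), size=8))
        d = bray_curtis(prof).to_numpy()
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.all(np.diag(d) == 0)
        assert np.all((d >= 0) & (d <= 1 + 1e-12))


class TestPcoa:
    def test_identical_samples_coincide(self):
        prof = pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]], index=list("abc")
        )
        coords, _ = pcoa(bray_curtis(prof))
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_equilateral_three_points(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        coords, explained = pcoa(d)
        assert coords.shape[1] == 2  # two positive eigenvalues
        assert explained == pytest.approx([0.5, 0.5])

    def test_euclidean_round_trip(self, rng):
        points = rng.normal(size=(6, 3))
        d = pd.DataFrame(squareform(pdist(points)))
        coords, _ = pcoa(d)
        recon = squareform(pdist(coords.to_numpy()))
        assert np.allclose(recon, d.to_numpy(), atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        prof = pd.DataFrame(rng.dirichlet(np.ones(12), size=9))
        d = bray_curtis(prof)
        coords, explained = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=[str(i) for i in d.index])
        )
        n_axes = min(coords.shape[1], 4)
        for axis in range(n_axes):
            mine = coords.iloc[:, axis].to_numpy()
            theirs = ref.samples.iloc[:, axis].to_numpy()
            sign = np.sign(np.dot(mine, theirs)) or 1.0
            assert np.allclose(mine, sign * theirs, atol=1e-6)

    def test_too_few_samples(self):
        d = pd.DataFrame(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            pcoa(d)


def _null_distance(rng, n=16, p=8):
    prof = pd.DataFrame(rng.dirichlet(np.ones(p), size=n),
                        index=[f"s{i:02d}" for i in range(n)])
    return bray_curtis(prof)


class TestPermanova:
    def test_separated_clusters_minimal_p(self, rng):
        a = rng.normal(0, 0.01, size=(12, 3)) + [0, 0, 0]
        b = rng.normal(0, 0.01, size=(12, 3)) + [5, 5, 5]
        pts = np.vstack([a, b])
        ids = [f"s{i}" for i in range(24)]
        d = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
        groups = pd.Series(["g1"] * 12 + ["g2"] * 12, index=ids)
        res = permanova(d, groups, n_perm=999, seed=5)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.R2 > 0.9

    def test_null_r2_near_expectation(self, rng):
        d = _null_distance(rng)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=d.index)
        res = permanova(d, groups, n_perm=99, seed=1)
        assert 0.0 <= res.R2 <= 1.0
        assert res.R2 < 0.3  # near 1/(N-1) for null data

    def test_invariant_to_sample_order(self, rng):
        d = _null_distance(rng)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=d.index)
        res1 = permanova(d, groups, n_perm=199, seed=3)
        perm = rng.permutation(len(d))
        shuffled = d.iloc[perm, perm]
        res2 = permanova(shuffled, groups, n_perm=199, seed=3)
        assert res1 == res2

    def test_matches_reference_pseudo_f(self, rng):
        skbio = pytest.importorskip("skbio")
        d = _null_distance(rng)
        groups = ["a"] * 8 + ["b"] * 8
        res = permanova(d, pd.Series(groups, index=d.index), n_perm=49, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            grouping=groups,
            permutations=0,
        )
        assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_small_group_rejected(self, rng):
        d = _null_distance(rng, n=5)
        groups = pd.Series(["a"] * 4 + ["b"], index=d.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, groups)


class TestSpearman:
    def test_monotone(self):
        rho, _ = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_rank_example(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(rho)
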