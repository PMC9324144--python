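import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr as scipy_spearmanr

from paleoresil.data_model import ValidationError
from paleoresil.multivariate import (
    DistanceMatrix,
    bray_curtis,
    distance_matrix,
    nmds,
    orient_axes,
    permanova,
    permanova_exhaustive_p,
    spearman,
)
from paleoresil.preprocess import transform
from paleoresil.data_model import CommunityMatrix


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((1, 0), (0, 1), 1.0),  # disjoint support
            ((3, 2), (3, 2), 0.0),  # identical
            ((2, 6, 0), (1, 3, 4), 0.5),  # 1 - 2*(1+3+0)/16
        ],
    )
    def test_known_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            x = rng.integers(0, 50, size=8).astype(float)
            y = rng.integers(0, 50, size=8).astype(float)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))

    def test_both_all_zero_is_an_error(self):
        with pytest.raises(ValidationError):
            bray_curtis((0, 0), (0, 0))

    @settings(max_examples=100, derandomize=True)
    @given(
        x=st.lists(st.integers(0, 100), min_size=2, max_size=6),
        y=st.lists(st.integers(0, 100), min_size=2, max_size=6),
        c=st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    def test_bounded_symmetric_scale_invariant(self, x, y, c):
        n = min(len(x), len(y))
        x, y = np.array(x[:n], float), np.array(y[:n], float)
        if x.sum() == 0 or y.sum() == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
        assert bray_curtis(x, x) == 0.0
        assert bray_curtis(c * x, c * y) == pytest.approx(d, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_samples_give_zero_matrix(self):
        cm = CommunityMatrix(
            pd.DataFrame([[1, 3], [1, 3]], index=["s1", "s2"], columns=["a", "b"], dtype=float)
        )
        dm = distance_matrix(transform(cm, "none"))
        assert np.allclose(dm.d, 0.0)

    def test_matches_scalar_calls(self, small_cm):
        pm = transform(small_cm, "fourth_root")
        dm = distance_matrix(pm)
        for i, j in itertools.combinations(range(len(dm.ids)), 2):
            expected = bray_curtis(pm.values.iloc[i].values, pm.values.iloc[j].values)
            assert dm.d[i, j] == pytest.approx(expected)

    def test_sample_permutation_permutes_entries(self, small_cm):
        pm = transform(small_cm, "fourth_root")
        dm = distance_matrix(pm)
        perm = [3, 1, 0, 2, 5, 4]
        cm2 = CommunityMatrix(small_cm.counts.iloc[perm])
        dm2 = distance_matrix(transform(cm2, "fourth_root"))
        assert np.allclose(dm2.d, dm.d[np.ix_(perm, perm)])

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 0.2], [0.3, 0.0]]))


class TestNmds:
    def test_equidistant_triple_embeds_exactly(self):
        d = np.full((3, 3), 0.5)
        np.fill_diagonal(d, 0.0)
        res = nmds(DistanceMatrix(ids=["a", "b", "c"], d=d), k=2, restarts=4, seed=0)
        assert res.stress < 0.01

    def test_recovers_planar_configuration(self, rng):
        pts = rng.uniform(size=(12, 2))
        d = squareform(pdist(pts))
        d = d / d.max()  # keep entries in [0, 1]
        res = nmds(DistanceMatrix(ids=[str(i) for i in range(12)], d=d), k=2,
                   restarts=8, seed=1)
        assert res.stress < 0.05

    def test_same_seed_reproduces_coordinates(self, small_cm):
        dm = distance_matrix(transform(small_cm, "fourth_root"))
        a = nmds(dm, k=2, restarts=3, seed=7)
        b = nmds(dm, k=2, restarts=3, seed=7)
        pd.testing.assert_frame_equal(a.coords, b.coords)
        assert a.stress == b.stress

    def test_returned_stress_is_minimum_over_restarts(self, small_cm):
        dm = distance_matrix(transform(small_cm, "fourth_root"))
        res = nmds(dm, k=2, restarts=5, seed=3)
        assert res.stress == pytest.approx(min(res.restart_stresses))

    def test_stress_invariant_under_orthogonal_map(self, rng, small_cm):
        # stress depends only on configuration distances, which any
        # rotation/reflection/translation preserves
        from sklearn.manifold import smacof

        dm = distance_matrix(transform(small_cm, "fourth_root"))
        res = nmds(dm, k=2, restarts=3, seed=5)
        q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        mapped = res.coords.values @ q + rng.standard_normal(2)
        d_orig = squareform(pdist(res.coords.values))
        d_mapped = squareform(pdist(mapped))
        assert np.allclose(d_orig, d_mapped)

    def test_orient_axes_flips_sign_toward_covariate(self, small_cm):
        dm = distance_matrix(transform(small_cm, "fourth_root"))
        res = nmds(dm, k=2, restarts=3, seed=2)
        cov = pd.Series(res.coords["NMDS1"].values, index=res.coords.index)
        flipped = orient_axes(res, -cov)
        assert np.allclose(flipped.coords["NMDS1"], -res.coords["NMDS1"])
        kept = orient_axes(res, cov)
        assert np.allclose(kept.coords["NMDS1"], res.coords["NMDS1"])


class TestPermanova:
    def _dm(self, d, ids=None):
        return DistanceMatrix(ids=ids or [str(i) for i in range(len(d))], d=np.asarray(d, float))

    def test_perfect_separation(self):
        # two groups of identical duplicates, nonzero between-group distance
        d = np.zeros((4, 4))
        for i, j in [(0, 2), (0, 3), (1, 2), (1, 3)]:
            d[i, j] = d[j, i] = 0.8
        res = permanova(self._dm(d), ["g1", "g1", "g2", "g2"], permutations=99, seed=0)
        assert res.pseudo_F == np.inf
        assert res.df_among == 1 and res.df_within == 2
        # only permutations reproducing the split attain SS_within = 0
        assert res.p_value <= 0.4

    def test_matches_exhaustive_enumeration(self, rng):
        n = 6
        pts = rng.uniform(size=(n, 3))
        d = squareform(pdist(pts))
        d /= d.max()
        labels = ["a", "a", "a", "b", "b", "b"]
        dm = self._dm(d)
        exact = permanova_exhaustive_p(dm, labels)
        mc = permanova(dm, labels, permutations=9999, seed=1)
        assert mc.p_value == pytest.approx(exact, abs=0.02)

    def test_statistic_matches_scikit_bio(self, small_cm, small_meta):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        dm = distance_matrix(transform(small_cm, "fourth_root"))
        labels = [small_meta.interval_of(s) for s in dm.ids]
        ours = permanova(dm, labels, permutations=99, seed=0)
        theirs = skbio_permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.ids), grouping=labels, permutations=0
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"])

    def test_pseudo_f_invariant_to_sample_reordering(self, rng):
        n = 8
        d = squareform(pdist(rng.uniform(size=(n, 2))))
        d /= d.max()
        labels = np.array(["a"] * 4 + ["b"] * 4)
        f1 = permanova(self._dm(d), list(labels), permutations=9, seed=0).pseudo_F
        perm = rng.permutation(n)
        f2 = permanova(
            self._dm(d[np.ix_(perm, perm)]), list(labels[perm]), permutations=9, seed=0
        ).pseudo_F
        assert f1 == pytest.approx(f2)

    def test_group_with_single_sample_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 0.5
        d[0, 2] = d[2, 0] = 0.5
        d[1, 2] = d[2, 1] = 0.5
        with pytest.raises(ValidationError, match="< 2"):
            permanova(self._dm(d), ["a", "a", "b"], permutations=9, seed=0)

    def test_p_uniform_under_null(self, rng):
        # exchangeable data: p-values should be roughly uniform
        from scipy.stats import kstest

        ps = []
        for rep in range(200):
            d = squareform(pdist(rng.uniform(size=(8, 2))))
            d /= d.max()
            res = permanova(self._dm(d), ["a"] * 4 + ["b"] * 4, permutations=99,
                            seed=rep)
            ps.append(res.p_value)
        stat, p = kstest(ps, "uniform")
        assert p > 0.001


class TestSpearman:
    def test_monotone_sequences(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_midrank_ties_match_hand_oracle(self):
        # ranks of x = (1, 2.5, 2.5, 4); ranks of y = (1, 3, 2, 4)
        x = [1, 2, 2, 4]
        y = [1, 3, 2, 4]
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 3.0, 2.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected)

    def test_rho_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        rho_sp, p_sp = scipy_spearmanr(x, y)
        assert rho == pytest.approx(rho_sp)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_exact_small_n_p_value_bounds(self):
        # n = 4, perfect concordance: only 1 of 24 permutations ties |rho| = 1
        # in each direction -> exact two-sided p = 2/24
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        assert p == pytest.approx(2 / 24)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            spearman([1, 1, 1], [1, 2, 3])
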