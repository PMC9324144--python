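import numpy as np
import pandas as pd
import pytest

from paleoresil.data_model import CommunityMatrix, SampleMetadata, ValidationError
from paleoresil.multivariate import bray_curtis
from paleoresil.null_models import (
    bc_permutation_test,
    mean_between_bc,
    pooled_abundance_envelope,
)
from paleoresil.null_models import _transform_rows


def _meta(intervals, ids):
    return SampleMetadata(
        pd.DataFrame(
            {
                "interval": intervals,
                "core_id": ["c"] * len(ids),
                "environment": ["nearshore"] * len(ids),
            },
            index=ids,
        )
    )


def _cm(rows, ids, species=None):
    species = species or [f"sp{i}" for i in range(len(rows[0]))]
    return CommunityMatrix(pd.DataFrame(rows, index=ids, columns=species, dtype=float))


class TestMeanBetweenBc:
    def test_identical_single_samples_give_zero(self):
        cm = _cm([[3, 2], [3, 2]], ["a1", "b1"])
        meta = _meta(["LIG", "CIG"], ["a1", "b1"])
        assert mean_between_bc(cm, meta, "LIG", "CIG") == pytest.approx(0.0)

    def test_matches_average_of_scalar_calls(self, rng):
        rows = rng.integers(1, 40, size=(5, 4)).astype(float)
        ids = [f"s{i}" for i in range(5)]
        cm = _cm(rows.tolist(), ids)
        meta = _meta(["LIG", "LIG", "CIG", "CIG", "CIG"], ids)
        values = _transform_rows(rows, "fourth_root")
        pairs = [
            bray_curtis(values[i], values[j]) for i in range(2) for j in range(2, 5)
        ]
        assert mean_between_bc(cm, meta, "LIG", "CIG") == pytest.approx(
            np.mean(pairs)
        )

    def test_empty_interval_is_an_error(self):
        cm = _cm([[3, 2]], ["a1"])
        meta = _meta(["LIG"], ["a1"])
        with pytest.raises(ValidationError, match="no retained samples"):
            mean_between_bc(cm, meta, "LIG", "CIG")


class TestBcPermutationTest:
    @pytest.fixture
    def homogeneous(self, rng):
        pi = np.array([0.6, 0.25, 0.1, 0.05])
        rows = [rng.multinomial(100, pi) for _ in range(8)]
        ids = [f"s{i}" for i in range(8)]
        cm = _cm([r.tolist() for r in rows], ids)
        meta = _meta(["LIG"] * 4 + ["CIG"] * 4, ids)
        return cm, meta

    def test_null_conserves_sample_sizes_and_species_totals(self, homogeneous):
        # reconstruct one null iteration with the test's own seed and verify
        # the conservation laws the permutation scheme guarantees
        cm, meta = homogeneous
        sizes = cm.sample_totals.values.astype(int)
        pooled = cm.counts.values.astype(int).sum(axis=0)
        labels = np.repeat(np.arange(len(pooled)), pooled)
        rng2 = np.random.default_rng(11)
        shuffled = rng2.permutation(labels)
        chunks = np.split(shuffled, np.cumsum(sizes)[:-1])
        synth = np.array([np.bincount(c, minlength=len(pooled)) for c in chunks])
        assert (synth.sum(axis=1) == sizes).all()
        assert (synth.sum(axis=0) == pooled).all()

    def test_extreme_observed_gives_minimum_p(self):
        # two intervals with disjoint support: observed mean BC = 1, the
        # maximum possible, so no null value can exceed it strictly
        cm = _cm([[50, 0], [45, 0], [0, 50], [0, 55]], ["a1", "a2", "b1", "b2"])
        meta = _meta(["LIG", "LIG", "CIG", "CIG"], ["a1", "a2", "b1", "b2"])
        res = bc_permutation_test(cm, meta, "LIG", "CIG", iterations=99, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_same_seed_identical_result(self, homogeneous):
        cm, meta = homogeneous
        r1 = bc_permutation_test(cm, meta, "LIG", "CIG", iterations=50, seed=5)
        r2 = bc_permutation_test(cm, meta, "LIG", "CIG", iterations=50, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_values, r2.null_values)

    def test_non_integer_counts_rejected(self):
        cm = _cm([[2.5, 1], [1, 1]], ["a1", "b1"])
        meta = _meta(["LIG", "CIG"], ["a1", "b1"])
        with pytest.raises(ValidationError, match="resolve_valves"):
            bc_permutation_test(cm, meta, "LIG", "CIG", iterations=10, seed=0)

    def test_type_one_error_near_alpha(self, rng):
        # samples drawn from one multinomial: rejection rate ~ alpha
        pi = np.array([0.5, 0.3, 0.15, 0.05])
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            rows = [r.multinomial(80, pi).tolist() for _ in range(8)]
            ids = [f"s{i}" for i in range(8)]
            cm = _cm(rows, ids)
            meta = _meta(["LIG"] * 4 + ["CIG"] * 4, ids)
            res = bc_permutation_test(cm, meta, "LIG", "CIG", iterations=99, seed=rep)
            rejections += res.p_value < 0.05
        # exact test: rate = P(p < .05) = 4/100 with B = 99; allow 3 sigma
        assert 0.005 <= rejections / n_rep <= 0.085

    def test_power_against_separated_compositions(self):
        # true mean BC separation >= 0.3: should reject essentially always
        pi_a = np.array([0.7, 0.2, 0.05, 0.05])
        pi_b = np.array([0.05, 0.05, 0.2, 0.7])
        assert bray_curtis(pi_a, pi_b) >= 0.3
        rejections = 0
        n_rep = 30
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            rows = [r.multinomial(60, pi_a).tolist() for _ in range(15)] + [
                r.multinomial(60, pi_b).tolist() for _ in range(15)
            ]
            ids = [f"s{i}" for i in range(30)]
            cm = _cm(rows, ids)
            meta = _meta(["LIG"] * 15 + ["CIG"] * 15, ids)
            res = bc_permutation_test(cm, meta, "LIG", "CIG", iterations=99, seed=rep)
            rejections += res.p_value < 0.05
        assert rejections / n_rep >= 0.9

    def test_all_scope_pools_third_interval(self, rng):
        rows = rng.integers(1, 30, size=(6, 3)).astype(float).tolist()
        ids = [f"s{i}" for i in range(6)]
        cm = _cm(rows, ids)
        meta = _meta(["LIG", "LIG", "LG", "LG", "CIG", "CIG"], ids)
        r_pair = bc_permutation_test(cm, meta, "LIG", "CIG", iterations=20, seed=1)
        r_all = bc_permutation_test(
            cm, meta, "LIG", "CIG", iterations=20, seed=1, pool_scope="all"
        )
        # same observed statistic, different null ensembles
        assert r_pair.observed == pytest.approx(r_all.observed)
        assert not np.array_equal(r_pair.null_values, r_all.null_values)


class TestPooledAbundanceEnvelope:
    def test_single_species_degenerate(self):
        # every simulated pair equals the interval grand totals exactly
        cm = _cm([[30], [20], [25]], ["a1", "a2", "b1"], species=["spA"])
        meta = _meta(["LIG", "LIG", "CIG"], ["a1", "a2", "b1"])
        env = pooled_abundance_envelope(cm, meta, "LIG", "CIG", iterations=10, seed=0)
        assert np.all(env.null_pairs[:, 0, 0] == 50)
        assert np.all(env.null_pairs[:, 0, 1] == 25)
        assert np.isnan(env.rho_observed)  # rho undefined for one species

    def test_single_species_pairs_equal_grand_totals(self):
        cm = _cm(
            [[30, 1], [20, 1], [25, 1], [25, 1]],
            ["a1", "a2", "b1", "b2"],
            species=["spA", "spB"],
        )
        meta = _meta(["LIG", "LIG", "CIG", "CIG"], ["a1", "a2", "b1", "b2"])
        env = pooled_abundance_envelope(cm, meta, "LIG", "CIG", iterations=20, seed=0)
        # per-iteration interval grand totals conserved exactly
        assert np.all(env.null_pairs[:, :, 0].sum(axis=1) == 52)
        assert np.all(env.null_pairs[:, :, 1].sum(axis=1) == 52)

    def test_self_consistency_coverage(self, rng):
        # both intervals drawn from the same composition at large n: observed
        # pairs should fall inside the central 95% envelope for most species
        pi = np.array([0.5, 0.2, 0.1, 0.08, 0.06, 0.04, 0.02])
        rows = [rng.multinomial(500, pi).tolist() for _ in range(20)]
        ids = [f"s{i}" for i in range(20)]
        cm = _cm(rows, ids)
        meta = _meta(["LIG"] * 10 + ["CIG"] * 10, ids)
        env = pooled_abundance_envelope(cm, meta, "LIG", "CIG", iterations=400, seed=3)
        assert env.coverage_fraction(0.95) >= 0.95 - 1e-9

    def test_seed_determinism_and_long_format(self, rng):
        rows = rng.integers(0, 20, size=(4, 3)) + 1
        ids = [f"s{i}" for i in range(4)]
        cm = _cm(rows.tolist(), ids)
        meta = _meta(["LIG", "LIG", "CIG", "CIG"], ids)
        e1 = pooled_abundance_envelope(cm, meta, "LIG", "CIG", iterations=15, seed=9)
        e2 = pooled_abundance_envelope(cm, meta, "LIG", "CIG", iterations=15, seed=9)
        assert np.array_equal(e1.null_pairs, e2.null_pairs)
        assert e1.rho_observed == e2.rho_observed
        long = e1.null_pairs_long()
        assert set(long.columns) == {"species_id", "iteration", "x", "y"}
        assert len(long) == 15 * 3
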