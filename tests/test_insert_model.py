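import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strlink.insert_model import (
    DiploidCall,
    InsertObservation,
    InsertSizeDistribution,
    InvalidObservationError,
    NoSpanningPairsError,
    STRRegion,
    basic_model_estimate,
    build_normalization_table,
    diploid_likelihood,
    diploid_loglik_grid,
    insert_likelihood,
    normalization_naive,
)

from conftest import make_obs


class TestSTRRegion:
    def test_basic_fields(self, toy_region):
        assert toy_region.length == 10
        assert toy_region.unit * toy_region.ref_repeat == 10

    def test_invalid_end(self):
        with pytest.raises(ValueError):
            STRRegion("c", 10, 5, 2, 3)

    def test_span_mismatch_warns_not_fails(self):
        with pytest.warns(UserWarning):
            STRRegion("c", 100, 120, 4, 10)  # 4*10 = 40 vs span 21


class TestInsertSizeDistribution:
    def test_pmf_normalized(self, toy_F):
        assert toy_F.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert toy_F(10) == pytest.approx(0.1)
        assert toy_F(20) == 0.0
        assert toy_F(0) == 0.0

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            InsertSizeDistribution({10: 0.5}, K=20)

    def test_rejects_out_of_range_mass(self):
        with pytest.raises(ValueError):
            InsertSizeDistribution({25: 1.0}, K=20)


class TestNormalizationNaive:
    def test_hand_sums(self, toy_region, toy_F):
        assert normalization_naive(95, 5, toy_region, toy_F) == pytest.approx(0.5)
        assert normalization_naive(95, 6, toy_region, toy_F) == pytest.approx(0.3)

    def test_empty_range_is_zero(self, toy_region, toy_F):
        # e_m - s + 1 > K - u(n - n_r): very large n empties the range
        assert normalization_naive(95, 10, toy_region, toy_F) == 0.0


class TestNormalizationTable:
    def test_recurrence_examples(self, toy_region, toy_F, toy_table):
        assert toy_table(96, 5) == pytest.approx(0.6)
        assert toy_table(95, 6) == pytest.approx(0.3)

    def test_zero_pmf_gives_zero_table(self, toy_region):
        F = InsertSizeDistribution({10: 1.0}, K=19)
        F.p[:] = 0.0  # deliberately break normalization after construction
        table = build_normalization_table(toy_region, F, 0, 5)
        assert np.all(table.values == 0.0)

    def test_matches_naive_everywhere_toy(self, toy_region, toy_F, toy_table):
        for s in range(toy_region.start - toy_F.K, toy_region.start):
            for n in range(0, 11):
                assert toy_table(s, n) == pytest.approx(
                    normalization_naive(s, n, toy_region, toy_F), abs=1e-9
                )

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_matches_naive_random_pmfs(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(15, 40))
        region = STRRegion("c", 100, 100 + int(rng.integers(2, 10)),
                           int(rng.integers(1, 4)), int(rng.integers(1, 6)))
        p = np.zeros(K + 1)
        p[1:] = rng.random(K)
        F = InsertSizeDistribution(p / p.sum(), K=K)
        n_lo, n_hi = 0, 8
        table = build_normalization_table(region, F, n_lo, n_hi)
        s_vals = rng.integers(region.start - K, region.start, size=8)
        n_vals = rng.integers(n_lo, n_hi + 1, size=8)
        for s, n in zip(s_vals, n_vals):
            assert table(int(s), int(n)) == pytest.approx(
                normalization_naive(int(s), int(n), region, F), abs=1e-9
            )

    def test_bounds_enforced(self, toy_table):
        with pytest.raises(KeyError):
            toy_table(50, 5)
        with pytest.raises(KeyError):
            toy_table(95, 99)


class TestInsertLikelihood:
    def test_examples(self, toy_region, toy_F, toy_table):
        assert insert_likelihood(15, 95, 5, toy_region, toy_F, toy_table) == pytest.approx(0.2)
        assert insert_likelihood(14, 95, 5, toy_region, toy_F, toy_table) == 0.0
        assert insert_likelihood(15, 95, 6, toy_region, toy_F, toy_table) == pytest.approx(1 / 3)

    def test_invalid_start_raises(self, toy_region, toy_F, toy_table):
        with pytest.raises(InvalidObservationError):
            insert_likelihood(15, 100, 5, toy_region, toy_F, toy_table)

    def test_sums_to_one_over_valid_range(self, toy_region, toy_F, toy_table):
        for s in (90, 95, 99):
            for n in range(0, 9):
                shift = toy_region.unit * (n - toy_region.ref_repeat)
                total = sum(
                    insert_likelihood(l, s, n, toy_region, toy_F, toy_table)
                    for l in range(1, toy_F.K - shift + 1)
                )
                N = normalization_naive(s, n, toy_region, toy_F)
                if N > 0:
                    assert total == pytest.approx(1.0, abs=1e-9)
                else:
                    assert total == 0.0


class TestDiploidLikelihood:
    def test_example_value(self, toy_region, toy_F, toy_table):
        obs = make_obs([(95, 15)])
        got = diploid_likelihood(obs, 5, 6, toy_region, toy_F, toy_table)
        assert got == pytest.approx(np.log(0.5 * (0.2 + 1 / 3)), abs=1e-12)

    def test_symmetry_exact(self, toy_region, toy_F, toy_table):
        obs = make_obs([(95, 15), (96, 16), (93, 17)])
        a = diploid_likelihood(obs, 4, 7, toy_region, toy_F, toy_table)
        b = diploid_likelihood(obs, 7, 4, toy_region, toy_F, toy_table)
        assert a == b

    def test_duplicated_observation_doubles(self, toy_region, toy_F, toy_table):
        one = diploid_likelihood(make_obs([(95, 15)]), 5, 6, toy_region, toy_F, toy_table)
        two = diploid_likelihood(make_obs([(95, 15), (95, 15)]), 5, 6,
                                 toy_region, toy_F, toy_table)
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_empty_obs_warns_and_returns_zero(self, toy_region, toy_F, toy_table):
        with pytest.warns(UserWarning):
            assert diploid_likelihood([], 5, 6, toy_region, toy_F, toy_table) == 0.0


class TestBasicModelEstimate:
    def test_peaked_example(self, toy_region, peaked_F):
        call = basic_model_estimate(make_obs([(95, 16)]), toy_region, peaked_F, 0, 10)
        assert (call.n1, call.n2) == (5, 5)

    def test_recovers_truth_from_draws(self, toy_region, rng):
        F = InsertSizeDistribution.normal(15.0, 1.0, K=25)
        table = build_normalization_table(toy_region, F, 0, 10)
        obs = []
        while len(obs) < 50:
            s = int(rng.integers(90, 100))
            l_true = int(np.rint(rng.normal(15, 1)))
            if l_true > toy_region.end - s and l_true <= 25:
                obs.append(InsertObservation(s, s + l_true))
        call = basic_model_estimate(obs, toy_region, F, 0, 10, table)
        assert (call.n1, call.n2) == (5, 5)

    def test_singleton_grid(self, toy_region, toy_F):
        call = basic_model_estimate(make_obs([(95, 15)]), toy_region, toy_F, 5, 5)
        assert (call.n1, call.n2) == (5, 5)

    def test_empty_obs_raises(self, toy_region, toy_F):
        with pytest.raises(NoSpanningPairsError):
            basic_model_estimate([], toy_region, toy_F, 0, 10)

    def test_matches_brute_force_double_loop(self, toy_region, peaked_F):
        obs = make_obs([(95, 16), (96, 15), (94, 17)])
        table = build_normalization_table(toy_region, peaked_F, 0, 10)
        call = basic_model_estimate(obs, toy_region, peaked_F, 0, 10, table)
        best, best_val = None, -np.inf
        for n1 in range(0, 11):
            for n2 in range(n1, 11):
                val = diploid_likelihood(obs, n1, n2, toy_region, peaked_F, table)
                if val > best_val:
                    best_val, best = val, (n1, n2)
        assert (call.n1, call.n2) == best
        assert call.loglik == pytest.approx(best_val)

    def test_canonicalized_order(self, toy_region, peaked_F):
        call = basic_model_estimate(make_obs([(95, 16), (95, 14)]),
                                    toy_region, peaked_F, 0, 10)
        assert call.n1 <= call.n2

    def test_flat_F_prefers_reference(self, toy_region):
        # all grid values tie => tie-break picks the reference call
        F = InsertSizeDistribution.uniform(1, 19, K=19)
        call = basic_model_estimate(make_obs([(95, 12)]), toy_region, F, 3, 8)
        assert (call.n1, call.n2) == (5, 5)


class TestTranslationInvariance:
    def test_shifting_repeats_and_reference(self, toy_F):
        # shifting n_r by delta and evaluating at n + delta leaves P(l|n) fixed
        base = STRRegion("c", 100, 109, 2, 5)
        shifted = STRRegion("c", 100, 109, 2, 8)
        tb = build_normalization_table(base, toy_F, 0, 12)
        ts = build_normalization_table(shifted, toy_F, 0, 12)
        for l, s in ((15, 95), (16, 94), (17, 96)):
            for n in range(0, 9):
                assert insert_likelihood(l, s, n, base, toy_F, tb) == pytest.approx(
                    insert_likelihood(l, s, n + 3, shifted, toy_F, ts), abs=1e-12
                )

    def test_loglik_grid_symmetric(self, toy_region, peaked_F):
        table = build_normalization_table(toy_region, peaked_F, 0, 10)
        L = diploid_loglik_grid(make_obs([(95, 16), (96, 15)]), toy_region, peaked_F, table)
        assert np.allclose(L, L.T)
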