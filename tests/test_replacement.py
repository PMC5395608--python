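import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fakesim import (
    SCENARIOS,
    Direction,
    OrdinalMatrix,
    ReplacementParams,
    dg_pmf,
    perturb_matrix,
    replacement_pmf,
    replacement_table,
    scenario_params,
)

PI_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


class TestDgPmf:
    def test_uniform_when_shapes_are_one(self):
        np.testing.assert_allclose(dg_pmf(1, 4, 1.0, 1.0), [0.25] * 4)

    def test_single_point_support(self):
        np.testing.assert_allclose(dg_pmf(3, 3, 4.0, 1.5), [1.0])

    def test_slight_shape_against_direct_computation(self):
        # oracle: unnormalized mass h^3 * (5 - h)^0.5 over h = 1..4
        h = np.arange(1, 5, dtype=float)
        w = h**3 * (5.0 - h) ** 0.5
        expected = w / w.sum()
        np.testing.assert_allclose(dg_pmf(1, 4, 4.0, 1.5), expected, atol=1e-12)
        np.testing.assert_allclose(
            expected, [0.0169, 0.1174, 0.3235, 0.5422], atol=5e-5
        )

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="empty support"):
            dg_pmf(4, 3, 1.0, 1.0)

    @pytest.mark.parametrize("gamma,delta", [(0.0, 1.0), (1.0, -2.0), (-1.0, -1.0)])
    def test_nonpositive_shapes_rejected(self, gamma, delta):
        with pytest.raises(ValueError, match="positive"):
            dg_pmf(1, 4, gamma, delta)

    @given(
        a=st.integers(-5, 5),
        width=st.integers(0, 10),
        gamma=st.floats(0.1, 20.0),
        delta=st.floats(0.1, 20.0),
    )
    def test_always_a_probability_vector(self, a, width, gamma, delta):
        p = dg_pmf(a, a + width, gamma, delta)
        assert len(p) == width + 1
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12


class TestReplacementPmf:
    def test_lowest_value_absorbing_under_reverse(self):
        p = replacement_pmf(1, scenario_params("slight", 0.7), 5)
        np.testing.assert_allclose(p, [1, 0, 0, 0, 0])

    def test_pi_zero_is_identity(self):
        p = replacement_pmf(4, ReplacementParams(4.0, 1.5, 0.0), 5)
        np.testing.assert_allclose(p, [0, 0, 0, 1, 0])

    def test_uniform_scenario_hand_example(self):
        p = replacement_pmf(5, ReplacementParams(1.0, 1.0, 0.6), 5)
        np.testing.assert_allclose(p, [0.15, 0.15, 0.15, 0.15, 0.40])

    def test_highest_value_absorbing_under_forward(self):
        p = replacement_pmf(5, scenario_params("extreme", 0.9, "forward"), 5)
        np.testing.assert_allclose(p, [0, 0, 0, 0, 1])

    def test_out_of_range_k_rejected(self):
        params = scenario_params("uninformative", 0.5)
        for k in (0, 6, -1):
            with pytest.raises(ValueError, match="outside"):
                replacement_pmf(k, params, 5)

    @pytest.mark.parametrize("q", range(2, 8))
    @pytest.mark.parametrize("scenario", sorted(SCENARIOS))
    @pytest.mark.parametrize("pi", PI_GRID)
    @pytest.mark.parametrize("direction", list(Direction))
    def test_normalization_exhaustive(self, q, scenario, pi, direction):
        params = scenario_params(scenario, pi, direction)
        for k in range(1, q + 1):
            p = replacement_pmf(k, params, q)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.all(p >= 0)

    @pytest.mark.parametrize("scenario", sorted(SCENARIOS))
    @pytest.mark.parametrize("pi", PI_GRID)
    def test_retention_mass_is_one_minus_pi(self, scenario, pi):
        params = scenario_params(scenario, pi)
        for q in range(2, 8):
            for k in range(2, q + 1):
                p = replacement_pmf(k, params, q)
                assert p[k - 1] == pytest.approx(1.0 - pi, abs=1e-15)

    def test_slight_mass_increases_toward_k(self):
        params = scenario_params("slight", 0.6)
        for k in range(3, 6):
            p = replacement_pmf(k, params, 5)[: k - 1]
            assert np.all(np.diff(p) > 0)

    def test_extreme_mass_decreases_away_from_one(self):
        params = scenario_params("extreme", 0.6)
        for k in range(3, 6):
            p = replacement_pmf(k, params, 5)[: k - 1]
            assert np.all(np.diff(p) < 0)

    @pytest.mark.parametrize("scenario", sorted(SCENARIOS))
    def test_forward_is_reflected_reverse(self, scenario):
        q = 5
        fwd = scenario_params(scenario, 0.6, "forward")
        rev = scenario_params(scenario, 0.6, "reverse")
        for k in range(1, q + 1):
            p_fwd = replacement_pmf(k, fwd, q)
            p_rev = replacement_pmf(q + 1 - k, rev, q)[::-1]
            np.testing.assert_allclose(p_fwd, p_rev, atol=1e-12)


class TestPerturbMatrix:
    def test_pi_zero_returns_input_unchanged(self, small_matrix):
        out = perturb_matrix(small_matrix, scenario_params("extreme", 0.0), 1)
        assert out == small_matrix

    def test_all_ones_absorbing_under_reverse(self):
        ones = OrdinalMatrix(np.ones((20, 6), dtype=int), q=5)
        out = perturb_matrix(ones, scenario_params("uninformative", 1.0), 5)
        assert out == ones

    def test_uniform_pooled_frequencies(self):
        # oracle: binomial sampling error of the uniform pmf at 1200 draws
        fives = OrdinalMatrix(np.full((100, 12), 5), q=5)
        out = perturb_matrix(fives, ReplacementParams(1.0, 1.0, 1.0), seed=77)
        freqs = np.bincount(out.values.ravel(), minlength=6)[1:5] / 1200
        se = np.sqrt(0.25 * 0.75 / 1200)
        np.testing.assert_allclose(freqs, 0.25, atol=3 * se)

    def test_seed_determinism(self, small_matrix):
        params = scenario_params("slight", 0.5)
        a = perturb_matrix(small_matrix, params, 123)
        b = perturb_matrix(small_matrix, params, 123)
        c = perturb_matrix(small_matrix, params, 124)
        assert a == b
        assert a != c

    def test_sampling_matches_pmf(self):
        # goodness-of-fit of pooled draws against the analytic pmf
        params = scenario_params("slight", 0.6)
        q, n_draws = 5, 40_000
        for k in (3, 5):
            mat = OrdinalMatrix(np.full((n_draws // 100, 100), k), q=q)
            out = perturb_matrix(mat, params, seed=9000 + k)
            counts = np.bincount(out.values.ravel(), minlength=q + 1)[1:]
            expected = replacement_pmf(k, params, q) * n_draws
            keep = expected > 0
            assert counts[~keep].sum() == 0
            _, pval = stats.chisquare(counts[keep], expected[keep])
            assert pval > 0.01

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 2**31),
        q=st.integers(2, 7),
        pi=st.floats(0.0, 1.0),
        scenario=st.sampled_from(sorted(SCENARIOS)),
        direction=st.sampled_from(list(Direction)),
    )
    def test_ordering_invariant(self, seed, q, pi, scenario, direction):
        rng = np.random.default_rng(seed)
        mat = OrdinalMatrix(rng.integers(1, q + 1, size=(8, 5)), q=q)
        out = perturb_matrix(mat, scenario_params(scenario, pi, direction), seed)
        if direction is Direction.REVERSE:
            assert np.all(out.values <= mat.values)
        else:
            assert np.all(out.values >= mat.values)


class TestScenarioParams:
    def test_canonical_shapes(self):
        p = scenario_params("uninformative", 0.25)
        assert (p.gamma, p.delta, p.pi) == (1.0, 1.0, 0.25)
        p = scenario_params("slight", 0.5)
        assert (p.gamma, p.delta) == (4.0, 1.5)
        p = scenario_params("extreme", 1.0)
        assert (p.gamma, p.delta, p.pi) == (1.5, 4.0, 1.0)

    def test_unknown_name(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            scenario_params("mild", 0.5)

    def test_invalid_pi(self):
        with pytest.raises(ValueError, match="pi"):
            scenario_params("slight", 1.5)

    def test_table_rows_match_pmf(self):
        params = scenario_params("extreme", 0.4)
        table = replacement_table(params, 6)
        for k in range(1, 7):
            np.testing.assert_array_equal(table[k - 1], replacement_pmf(k, params, 6))
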