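"""Simulator: trait rotation, item bank, RSM probabilities, response draws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimcoef import (
    DEFAULT_THRESHOLDS,
    LatentTraits,
    SimulationScenario,
    build_item_bank,
    draw_traits,
    read_responses_csv,
    rsm_category_probs,
    simulate_responses,
    simulate_scenario,
    write_responses_csv,
)


class TestDrawTraits:
    def test_correlation_one_gives_identical_traits(self):
        traits = draw_traits(100, 1.0, seed=0)
        assert traits.angle_degrees == pytest.approx(0.0)
        np.testing.assert_allclose(traits.theta1, traits.theta2)

    def test_correlation_zero_gives_independent_traits(self):
        traits = draw_traits(200_000, 0.0, seed=0)
        assert traits.angle_degrees == pytest.approx(90.0)
        r = np.corrcoef(traits.theta1, traits.theta2)[0, 1]
        assert abs(r) < 0.01

    def test_rotation_identity_sample_correlation(self):
        # corr(theta1, theta1*cos(a) + z*sin(a)) = cos(a); checked at large n
        traits = draw_traits(200_000, 0.7, seed=3)
        r = np.corrcoef(traits.theta1, traits.theta2)[0, 1]
        assert r == pytest.approx(0.7, abs=0.01)

    def test_theta2_marginal_is_standard_normal(self):
        traits = draw_traits(200_000, 0.5, seed=1)
        assert traits.theta2.mean() == pytest.approx(0.0, abs=0.01)
        assert traits.theta2.std() == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("bad", [-0.1, 1.5])
    def test_correlation_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            draw_traits(10, bad, seed=0)


class TestItemBank:
    def test_five_items_evenly_spaced(self):
        bank = build_item_bank(5)
        np.testing.assert_allclose(bank.difficulties, [-2, -1, 0, 1, 2])
        assert bank.n_trait_a == 1

    def test_two_items_are_the_endpoints(self):
        bank = build_item_bank(2)
        np.testing.assert_allclose(bank.difficulties, [-2, 2])

    @pytest.mark.parametrize("k, expected_a", [(5, 1), (6, 2), (100, 33)])
    def test_one_third_split(self, k, expected_a):
        bank = build_item_bank(k)
        assert bank.n_trait_a == expected_a
        assert (~bank.trait_assignment).sum() == k - expected_a

    def test_random_uniform_mode_stays_in_range(self):
        bank = build_item_bank(50, random_uniform=True, seed=0)
        assert bank.difficulties.min() >= -2 and bank.difficulties.max() <= 2

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            build_item_bank(1)


class TestCategoryProbs:
    @given(
        theta=st.floats(-4, 4),
        delta=st.floats(-2, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, theta, delta):
        p = rsm_category_probs(theta, delta)
        assert p.shape == (5,)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    def test_symmetry_at_theta_equals_delta(self):
        p = rsm_category_probs(0.7, 0.7, (-1.5, -0.5, 0.5, 1.5))
        assert p[0] == pytest.approx(p[4])
        assert p[1] == pytest.approx(p[3])

    def test_spot_values_match_closed_form(self):
        # eta = theta - delta = 1: logits are cumulative sums of (eta - tau)
        eta, tau = 1.0, (-1.5, -0.5, 0.5, 1.5)
        logits = [0.0]
        for j in range(4):
            logits.append(logits[-1] + eta - tau[j])
        expected = np.exp(logits) / np.exp(logits).sum()
        p = rsm_category_probs(2.0, 1.0, tau)
        np.testing.assert_allclose(p, expected, rtol=1e-12)

    def test_expected_score_monotone_in_eta(self):
        scores = np.arange(5)
        etas = np.linspace(-4, 4, 41)
        means = [rsm_category_probs(e, 0.0) @ scores for e in etas]
        assert np.all(np.diff(means) > 0)


class TestSimulateResponses:
    def test_deterministic_under_fixed_seed(self):
        sc = SimulationScenario(0.5, 10, 60, seed=11)
        a = simulate_scenario(sc)
        b = simulate_scenario(sc)
        np.testing.assert_array_equal(a.values, b.values)

    def test_category_frequencies_match_probabilities(self):
        # theta fixed at 0, one item at delta = 0: law of large numbers
        n = 100_000
        traits = LatentTraits(np.zeros(n), np.zeros(n), 1.0, 0.0)
        bank = build_item_bank(2)
        bank = type(bank)(
            difficulties=np.array([0.0, 0.0]),
            thresholds=np.asarray(DEFAULT_THRESHOLDS),
            trait_assignment=np.array([True, False]),
        )
        resp = simulate_responses(traits, bank, seed=5)
        freq = np.bincount(resp.values[:, 0], minlength=5) / n
        np.testing.assert_allclose(freq, rsm_category_probs(0.0, 0.0), atol=0.01)

    def test_unidimensional_scenario_has_dominant_first_eigenvalue(self):
        from dimcoef import eigen_spectrum

        sc = SimulationScenario(1.0, 30, 500, seed=2)
        spectrum = eigen_spectrum(simulate_scenario(sc))
        ev = spectrum.eigenvalues
        assert ev[0] > 3 * ev[1]

    def test_values_in_five_category_range(self):
        sc = SimulationScenario(0.3, 8, 50, seed=7)
        values = simulate_scenario(sc).values
        assert values.min() >= 0 and values.max() <= 4


class TestCsvRoundTrip:
    def test_round_trip_preserves_values_and_scenario(self, tmp_path):
        sc = SimulationScenario(0.9, 6, 40, seed=3)
        resp = simulate_scenario(sc)
        path = tmp_path / "responses.csv"
        write_responses_csv(resp, path)
        back = read_responses_csv(path)
        np.testing.assert_array_equal(back.values, resp.values)
        assert back.scenario == sc

    def test_one_to_five_coding_mapped_down(self, tmp_path):
        import pandas as pd

        path = tmp_path / "likert.csv"
        pd.DataFrame({"a": [1, 5, 3], "b": [2, 4, 5]}).to_csv(path, index=False)
        resp = read_responses_csv(path)
        assert resp.values.min() == 0 and resp.values.max() == 4
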