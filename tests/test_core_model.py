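"""Closed-form probabilities and the chi-square test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from misdiagpower import (
    ContingencyTable2x2,
    ScenarioParams,
    case_exposure_prob,
    case_exposure_prob_serology,
    control_observed_prob,
    invert_odds_ratio,
    pearson_chi2,
)
from misdiagpower.core_model import odds_ratio_of_probs, pearson_chi2_counts

probs = st.floats(0.0, 1.0, allow_nan=False)
interior_probs = st.floats(0.001, 0.999, allow_nan=False)


class TestInvertOddsRatio:
    @pytest.mark.parametrize(
        "delta_t, theta0, expected",
        [
            (1.0, 0.25, 0.25),
            (3.0, 0.25, 0.5),
            (10.0, 0.05, 10.0 / 29.0),
            (0.84, 0.0, 0.0),
            (0.84, 1.0, 1.0),
        ],
    )
    def test_values(self, delta_t, theta0, expected):
        assert invert_odds_ratio(delta_t, theta0) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("inf"), float("nan"), None])
    def test_rejects_nonpositive_or_nonfinite_odds_ratio(self, bad):
        with pytest.raises(ValueError):
            invert_odds_ratio(bad, 0.25)

    @settings(deadline=None, derandomize=True)
    @given(delta_t=st.floats(0.01, 100.0), theta0=interior_probs)
    def test_round_trip_with_odds_ratio(self, delta_t, theta0):
        """Inverting then recomputing the odds ratio is the identity."""
        theta1_star = invert_odds_ratio(delta_t, theta0)
        assert odds_ratio_of_probs(theta1_star, theta0) == pytest.approx(
            delta_t, rel=1e-12
        )


class TestMixtureProbabilities:
    @pytest.mark.parametrize(
        "gamma, expected", [(0.0, 0.5), (1.0, 0.25), (0.5, 0.375)]
    )
    def test_case_prob_is_convex_combination(self, gamma, expected):
        assert case_exposure_prob(gamma, 0.25, 0.5) == pytest.approx(expected)

    def test_case_prob_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            case_exposure_prob(1.5, 0.25, 0.5)

    @pytest.mark.parametrize(
        "gamma, pi, expected",
        [(0.0, 0.975, 0.975 * 0.5 + 0.025 * 0.5), (1.0, 0.9, 0.3)],
    )
    def test_serology_values(self, gamma, pi, expected):
        got = case_exposure_prob_serology(gamma, 0.25, 0.5, pi, pi)
        assert got == pytest.approx(expected)

    @pytest.mark.parametrize(
        "theta0, pi_se, pi_sp, expected",
        [(0.25, 1.0, 1.0, 0.25), (0.25, 0.9, 0.9, 0.3), (0.0, 0.8, 0.8, 0.2)],
    )
    def test_control_observed_prob(self, theta0, pi_se, pi_sp, expected):
        assert control_observed_prob(theta0, pi_se, pi_sp) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=1000)
    @given(gamma=probs, theta0=probs, theta1_star=probs)
    def test_perfect_classifier_reduces_to_plain_mixture(
        self, gamma, theta0, theta1_star
    ):
        """With pi_se = pi_sp = 1 the serology formula collapses exactly."""
        full = case_exposure_prob_serology(gamma, theta0, theta1_star, 1.0, 1.0)
        plain = case_exposure_prob(gamma, theta0, theta1_star)
        assert abs(full - plain) <= 1e-15

    @settings(deadline=None, derandomize=True)
    @given(gamma=probs, theta0=probs, theta1_star=probs, pi_se=probs, pi_sp=probs)
    def test_serology_prob_in_unit_interval(
        self, gamma, theta0, theta1_star, pi_se, pi_sp
    ):
        p = case_exposure_prob_serology(gamma, theta0, theta1_star, pi_se, pi_sp)
        assert -1e-12 <= p <= 1 + 1e-12

    def test_monotone_in_gamma(self):
        """For a risk factor, the case probability falls linearly with gamma."""
        gammas = np.linspace(0, 1, 21)
        vals = [case_exposure_prob(g, 0.25, 0.5) for g in gammas]
        assert np.all(np.diff(vals) < 0)
        # linear: second differences vanish
        assert np.allclose(np.diff(vals, 2), 0.0, atol=1e-12)
        flat = [case_exposure_prob(g, 0.25, 0.25) for g in gammas]
        assert np.allclose(flat, 0.25)


class TestScenarioParams:
    def test_derives_theta1_star_from_odds_ratio(self):
        p = ScenarioParams(theta0=0.25, delta_t=3.0, gamma=0.1, n0=100, n1=100)
        assert p.theta1_star == pytest.approx(0.5, rel=1e-12)

    def test_derives_odds_ratio_from_theta1_star(self):
        p = ScenarioParams(theta0=0.25, theta1_star=0.5, gamma=0.1, n0=100, n1=100)
        assert p.delta_t == pytest.approx(3.0, rel=1e-12)

    def test_rejects_both_or_neither_effect(self):
        with pytest.raises(ValueError, match="exactly one"):
            ScenarioParams(
                theta0=0.25, delta_t=3.0, theta1_star=0.5, gamma=0.0, n0=10, n1=10
            )
        with pytest.raises(ValueError, match="exactly one"):
            ScenarioParams(theta0=0.25, gamma=0.0, n0=10, n1=10)

    @pytest.mark.parametrize(
        "field, kwargs",
        [
            ("theta0", dict(theta0=1.2)),
            ("gamma", dict(gamma=-0.1)),
            ("pi_se", dict(pi_se=2.0)),
            ("alpha", dict(alpha=1.0)),
            ("n0", dict(n0=0)),
        ],
    )
    def test_validation_names_offending_field(self, field, kwargs):
        base = dict(theta0=0.25, delta_t=3.0, gamma=0.0, n0=100, n1=100)
        base.update(kwargs)
        with pytest.raises(ValueError, match=field):
            ScenarioParams(**base)

    def test_boundary_theta0_pins_theta1_star_with_warning(self):
        with pytest.warns(UserWarning):
            p = ScenarioParams(theta0=0.0, delta_t=5.0, gamma=0.0, n0=10, n1=10)
        assert p.theta1_star == 0.0

    def test_with_gamma_preserves_effect_parameterization(self):
        p = ScenarioParams(theta0=0.25, delta_t=3.0, gamma=0.0, n0=100, n1=200)
        q = p.with_gamma(0.4)
        assert q.gamma == 0.4
        assert q.delta_t == p.delta_t
        assert q.theta1_star == p.theta1_star
        assert (q.n0, q.n1) == (100, 200)


def _random_tables(rng, k, n_max=80):
    for _ in range(k):
        n0 = int(rng.integers(2, n_max))
        n1 = int(rng.integers(2, n_max))
        a = int(rng.integers(0, n0 + 1))
        b = int(rng.integers(0, n1 + 1))
        yield ContingencyTable2x2(a, n0 - a, b, n1 - b)


def _brute_force_chi2(obs, yates=False):
    """Textbook sum over cells, kept deliberately naive."""
    total = sum(sum(row) for row in obs)
    rows = [sum(row) for row in obs]
    cols = [sum(col) for col in zip(*obs)]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / total
            d = abs(obs[i][j] - e)
            if yates:
                d = max(d - 0.5, 0.0)
            stat += d * d / e
    return stat


class TestPearsonChi2:
    def test_known_table(self):
        stat, p, degenerate = pearson_chi2([[10, 20], [20, 10]])
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-10)
        assert p == pytest.approx(0.00982, abs=1e-5)
        assert not degenerate

    def test_balanced_table_has_zero_statistic(self):
        stat, p, _ = pearson_chi2([[15, 15], [15, 15]])
        assert stat == 0.0
        assert p == 1.0

    def test_zero_margin_is_degenerate_never_rejects(self):
        result = pearson_chi2([[0, 0], [20, 10]])
        assert result.degenerate
        assert result.p_value == 1.0

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [0, 0]])

    @pytest.mark.parametrize("yates", [False, True])
    def test_agrees_with_brute_force_oracle(self, rng, yates):
        for table in _random_tables(rng, 1000):
            obs = table.to_array().tolist()
            got = pearson_chi2(table, yates=yates)
            if got.degenerate:
                continue
            assert got.statistic == pytest.approx(
                _brute_force_chi2(obs, yates=yates), rel=1e-10, abs=1e-12
            )

    @pytest.mark.parametrize("yates", [False, True])
    def test_agrees_with_scipy(self, rng, yates):
        checked = 0
        for table in _random_tables(rng, 300):
            obs = table.to_array()
            if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
                continue
            ref_stat, ref_p, _, _ = chi2_contingency(obs, correction=yates)
            got = pearson_chi2(table, yates=yates)
            assert got.statistic == pytest.approx(ref_stat, rel=1e-10, abs=1e-12)
            assert got.p_value == pytest.approx(ref_p, rel=1e-8, abs=1e-12)
            checked += 1
        assert checked > 200

    def test_vectorized_matches_scalar_including_degenerate(self, rng):
        n0, n1 = 40, 60
        a = rng.integers(0, n0 + 1, size=500)
        b = rng.integers(0, n1 + 1, size=500)
        a[:5], b[:5] = 0, 0  # force some degenerate tables
        stats_v, pvals_v = pearson_chi2_counts(a, b, n0, n1)
        for i in range(500):
            table = ContingencyTable2x2(
                int(a[i]), n0 - int(a[i]), int(b[i]), n1 - int(b[i])
            )
            ref = pearson_chi2(table)
            assert stats_v[i] == pytest.approx(ref.statistic, rel=1e-10, abs=1e-12)
            assert pvals_v[i] == pytest.approx(ref.p_value, rel=1e-8, abs=1e-12)
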