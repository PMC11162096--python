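"""Admissibility, proof-of-concept, MED/MUD selection, and randomization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from bqdesign import (
    AdmissibleSet,
    DesignConfig,
    PosteriorDraws,
    UtilitySpec,
    admissible_set,
    poc_statistic,
    poc_test,
    randomization_probabilities,
    select_med,
    select_mud,
    target_dose_probabilities,
    utility_extended,
    utility_simple,
)


def make_draws(pi, mu):
    pi = np.asarray(pi, dtype=float)
    mu = np.asarray(mu, dtype=float)
    J = pi.shape[1]
    return PosteriorDraws(pi=pi, theta0=mu.copy(), theta1=mu.copy(), mu=mu,
                         bounds=np.tile([0.0, 1.0], (J, 1)))


def point_mass_draws(pi_vec, mu_vec, T=100):
    return make_draws(np.tile(pi_vec, (T, 1)), np.tile(mu_vec, (T, 1)))


def full_set(J=5):
    return AdmissibleSet(tuple(range(2, J + 1)), J)


class TestUtilities:
    @pytest.mark.parametrize(
        "mu, pi, w, expected",
        [(0.70, 0.11, 2, 0.48), (0.44, 0.07, 2, 0.30), (0.9, 0.0, 7, 0.9)],
    )
    def test_simple(self, mu, pi, w, expected):
        assert utility_simple(mu, pi, w) == pytest.approx(expected)

    def test_extended_indicator_off(self):
        assert utility_extended(0.5, 0.2, rho=0.3, w1=1, w2=5) == pytest.approx(0.3)

    def test_extended_indicator_on(self):
        assert utility_extended(0.5, 0.4, rho=0.3, w1=1, w2=5) == pytest.approx(-1.9)

    @given(
        mu=st.floats(-2, 2), pi=st.floats(0, 1),
        w=st.floats(0, 10), rho=st.floats(0, 1),
    )
    @settings(deadline=None)
    def test_extended_reduces_to_simple(self, mu, pi, w, rho):
        assert utility_extended(mu, pi, rho=rho, w1=w, w2=0.0) == pytest.approx(
            utility_simple(mu, pi, w)
        )


class TestAdmissibleSet:
    def test_vacuous_criteria_admit_everything(self, rng):
        draws = make_draws(rng.uniform(size=(500, 5)), rng.uniform(size=(500, 5)))
        cfg = DesignConfig(pi_bar=1.0, ce=0.999999, ct=0.999999)
        assert admissible_set(draws, cfg).members == (2, 3, 4, 5)

    def test_tiny_cutoffs_admit_nothing(self, rng):
        draws = make_draws(rng.uniform(size=(500, 5)), rng.uniform(size=(500, 5)))
        cfg = DesignConfig(ct=1e-9, ce=1e-9)
        assert admissible_set(draws, cfg).empty

    def test_monotone_in_cutoffs(self, rng):
        draws = make_draws(rng.uniform(size=(400, 5)), rng.uniform(size=(400, 5)))
        sets = []
        for ct, ce in [(0.2, 0.2), (0.5, 0.5), (0.9, 0.9), (0.999, 0.999)]:
            sets.append(set(admissible_set(draws, DesignConfig(ct=ct, ce=ce)).members))
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_matches_quadrature_on_independent_betas(self):
        """Draw proportions vs numerically integrated Beta tail probabilities."""
        T = 400_000
        rs = np.random.default_rng(77)
        pi_params = [(2, 30), (6, 26), (8, 24)]
        mu_params = [(10, 10), (11, 9), (14, 6)]
        pi = np.column_stack([rs.beta(a, b, T) for a, b in pi_params])
        mu = np.column_stack([rs.beta(a, b, T) for a, b in mu_params])
        draws = make_draws(pi, mu)
        pi_bar = 0.1

        def pr_unsafe(j):
            f1 = stats.beta(*pi_params[0])
            fj = stats.beta(*pi_params[j])
            val, _ = integrate.quad(lambda u: f1.pdf(u) * fj.sf(u + pi_bar), 0, 1)
            return val

        def pr_futile(j):
            f1 = stats.beta(*mu_params[0])
            fj = stats.beta(*mu_params[j])
            val, _ = integrate.quad(lambda u: f1.pdf(u) * fj.cdf(u), 0, 1)
            return val

        for j in (1, 2):
            emp_unsafe = (pi[:, j] > pi[:, 0] + pi_bar).mean()
            emp_futile = (mu[:, j] <= mu[:, 0]).mean()
            assert emp_unsafe == pytest.approx(pr_unsafe(j), abs=0.005)
            assert emp_futile == pytest.approx(pr_futile(j), abs=0.005)
            # and the rule itself flips exactly at those probabilities
            cfg = DesignConfig(n_arms=3, pi_bar=pi_bar,
                               ct=pr_unsafe(j) + 0.01, ce=pr_futile(j) + 0.01)
            assert (j + 1) in admissible_set(draws, cfg)
            cfg = DesignConfig(n_arms=3, pi_bar=pi_bar,
                               ct=max(pr_unsafe(j) - 0.01, 1e-6),
                               ce=max(pr_futile(j) - 0.01, 1e-6))
            assert (j + 1) not in admissible_set(draws, cfg)


class TestPoC:
    def test_identical_arms_never_establish(self, rng):
        mu = np.tile(rng.uniform(size=(300, 1)), (1, 5))
        draws = make_draws(np.zeros_like(mu), mu)
        assert poc_statistic(draws) == 0.0
        assert not poc_test(draws, DesignConfig(c_poc=0.05))

    def test_dominating_arm_establishes(self, rng):
        mu = rng.uniform(size=(300, 5))
        mu[:, 3] = mu[:, 0] + 1.0
        draws = make_draws(np.zeros_like(mu), mu)
        assert poc_statistic(draws) == 1.0
        assert poc_test(draws, DesignConfig(c_poc=0.999999))


class TestSelection:
    def test_med_on_concentrated_scenario_curve(self):
        # truth: efficacies (0.20, 0.57, 0.70, 0.76, 0.80), target 0.20+0.4
        draws = point_mass_draws([0.05, 0.10, 0.11, 0.30, 0.34],
                                 [0.20, 0.57, 0.70, 0.76, 0.80])
        assert select_med(draws, full_set(), DesignConfig(delta=0.4)) == 2

    def test_mud_on_concentrated_scenario_curve(self):
        draws = point_mass_draws([0.05, 0.10, 0.11, 0.30, 0.34],
                                 [0.20, 0.57, 0.70, 0.76, 0.80])
        cfg = DesignConfig(utility=UtilitySpec(w1=2.0))
        assert select_mud(draws, full_set(), cfg) == 3

    def test_ties_break_to_lower_dose(self):
        draws = point_mass_draws([0.1] * 5, [0.2, 0.5, 0.7, 0.7, 0.5])
        cfg = DesignConfig(delta=0.4)
        # doses 2 and 5 are equidistant from 0.6 -> dose 2
        assert select_med(draws, full_set(), cfg) == 2
        # doses 3 and 4 tie on utility -> dose 3
        assert select_mud(draws, full_set(), cfg) == 3

    def test_empty_admissible_set_selects_nothing(self):
        draws = point_mass_draws([0.1] * 5, [0.2, 0.3, 0.4, 0.5, 0.6])
        A = AdmissibleSet((), 5)
        cfg = DesignConfig()
        assert select_med(draws, A, cfg) is None
        assert select_mud(draws, A, cfg) is None

    @given(st.data())
    @settings(deadline=None, max_examples=200)
    def test_agrees_with_exhaustive_scan(self, data):
        J = data.draw(st.integers(2, 6))
        mu_hat = np.array(data.draw(st.lists(
            st.floats(-1, 1, allow_nan=False), min_size=J, max_size=J)))
        pi_hat = np.array(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=J, max_size=J)))
        members = tuple(sorted(data.draw(
            st.sets(st.integers(2, J), min_size=1, max_size=J - 1))))
        A = AdmissibleSet(members, J)
        cfg = DesignConfig(n_arms=J, delta=0.3, utility=UtilitySpec(w1=2.0))
        draws = point_mass_draws(pi_hat, mu_hat, T=3)

        target = mu_hat[0] + cfg.delta
        best_med = min(members, key=lambda j: (abs(mu_hat[j - 1] - target), j))
        best_mud = min(members, key=lambda j: (-(mu_hat[j - 1] - 2 * pi_hat[j - 1]), j))
        assert select_med(draws, A, cfg) == best_med
        assert select_mud(draws, A, cfg) == best_mud

    def test_mud_min_dose_restriction(self):
        draws = point_mass_draws([0.0] * 5, [0.2, 0.9, 0.5, 0.6, 0.4])
        cfg = DesignConfig(utility=UtilitySpec(w1=2.0))
        assert select_mud(draws, full_set(), cfg) == 2
        assert select_mud(draws, full_set(), cfg, min_dose=3) == 4


class TestTargetDoseProbabilities:
    def test_degenerate_draws_give_indicators(self):
        draws = point_mass_draws([0.05, 0.1, 0.1, 0.3, 0.3],
                                 [0.20, 0.57, 0.70, 0.76, 0.80])
        p1, p2 = target_dose_probabilities(draws, full_set(), DesignConfig())
        np.testing.assert_allclose(p1, [0, 1, 0, 0, 0])
        np.testing.assert_allclose(p2, [0, 0, 1, 0, 0])

    def test_sum_to_one_over_admissible(self, rng):
        draws = make_draws(rng.uniform(size=(1000, 5)), rng.uniform(size=(1000, 5)))
        A = AdmissibleSet((2, 4), 5)
        p1, p2 = target_dose_probabilities(draws, A, DesignConfig())
        for p in (p1, p2):
            assert p.sum() == pytest.approx(1.0)
            assert p[[0, 2, 4]].sum() == 0.0

    def test_empty_set_gives_zero_vectors(self, rng):
        draws = make_draws(rng.uniform(size=(50, 5)), rng.uniform(size=(50, 5)))
        p1, p2 = target_dose_probabilities(draws, AdmissibleSet((), 5), DesignConfig())
        assert not p1.any() and not p2.any()

    def test_symmetric_straddle_splits_evenly(self, rng):
        # two doses symmetric around the target: each is per-draw MED ~half the time
        T = 200_000
        mu = np.column_stack([
            np.full(T, 0.2),
            0.5 + 0.05 * rng.standard_normal(T),
            0.7 + 0.05 * rng.standard_normal(T),
        ])
        draws = make_draws(np.zeros_like(mu), mu)
        cfg = DesignConfig(n_arms=3, delta=0.4)
        p1, _ = target_dose_probabilities(draws, AdmissibleSet((2, 3), 3), cfg)
        assert p1[1] == pytest.approx(0.5, abs=0.01)
        assert p1[2] == pytest.approx(0.5, abs=0.01)

    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_per_draw_rule_agrees_with_scan(self, data):
        J = 4
        T = 20
        rs = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        mu = rs.uniform(size=(T, J))
        pi = rs.uniform(size=(T, J))
        members = (2, 3, 4)
        A = AdmissibleSet(members, J)
        cfg = DesignConfig(n_arms=J, delta=0.2, utility=UtilitySpec(w1=1.5))
        p1, p2 = target_dose_probabilities(make_draws(pi, mu), A, cfg)
        c1 = np.zeros(J)
        c2 = np.zeros(J)
        for t in range(T):
            med = min(members, key=lambda j: (abs(mu[t, j - 1] - (mu[t, 0] + 0.2)), j))
            mud = min(members, key=lambda j: (-(mu[t, j - 1] - 1.5 * pi[t, j - 1]), j))
            c1[med - 1] += 1
            c2[mud - 1] += 1
        np.testing.assert_allclose(p1, c1 / T)
        np.testing.assert_allclose(p2, c2 / T)


class TestAnalyze:
    def test_final_analysis_bundle_round_trips_to_json(self, tmp_path, rng):
        from bqdesign import analyze, sample_posterior
        from conftest import make_data

        dose = np.repeat(np.arange(1, 6), 40)
        tox = rng.binomial(1, 0.1, dose.size)
        eff = 0.2 + 0.15 * (dose - 1) + rng.normal(0, 1, dose.size)
        data = make_data(dose, tox, eff)
        cfg = DesignConfig(n_draws=1000)
        draws = sample_posterior(data, cfg, rng=7)
        decision = analyze(draws, cfg, final=True)
        assert decision.poc_established in (True, False)
        if not decision.admissible.empty:
            assert decision.randomization.sum() == pytest.approx(1.0)
        path = tmp_path / "decision.json"
        decision.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["admissible"] == list(decision.admissible.members)


class TestRandomization:
    def test_is_probability_vector(self, rng):
        p1 = np.array([0, 0.2, 0.3, 0.5, 0])
        p2 = np.array([0, 0.5, 0.1, 0.4, 0])
        A = AdmissibleSet((2, 3, 4), 5)
        probs = randomization_probabilities(p1, p2, A, DesignConfig())
        assert probs.sum() == pytest.approx(1.0)
        assert (probs >= 0).all()
        assert probs[4] == 0.0  # inadmissible dose gets nothing

    def test_control_capped_at_inverse_treatments(self):
        J = 5
        p = np.array([0, 0.9, 0.05, 0.03, 0.02])
        A = full_set(J)
        cfg = DesignConfig(tau=0.5, nu=1.0)
        probs = randomization_probabilities(p, p, A, cfg)
        # before normalization: control = min(0.9, 1/4) = 0.25, best dose = 0.9
        unnorm = np.array([0.25, 0.9, 0.05, 0.03, 0.02])
        np.testing.assert_allclose(probs, unnorm / unnorm.sum())

    def test_nu_zero_equalizes_before_boost(self):
        p1 = np.array([0, 0.7, 0.2, 0.1, 0.0])
        p2 = np.array([0, 0.1, 0.2, 0.7, 0.0])
        cfg = DesignConfig(tau=0.5, nu=0.0)
        probs = randomization_probabilities(p1, p2, full_set(), cfg)
        # every admissible dose scores 1 except the boosted argmax doses (0.7)
        unnorm = np.array([0.25, 0.7, 1.0, 0.7, 1.0])
        np.testing.assert_allclose(probs, unnorm / unnorm.sum())

    def test_tau_one_targets_med_only(self):
        p1 = np.array([0, 0.6, 0.3, 0.1, 0.0])
        p2 = np.array([0, 0.0, 0.1, 0.3, 0.6])
        cfg = DesignConfig(tau=1.0, nu=1.0)
        probs = randomization_probabilities(p1, p2, full_set(), cfg)
        unnorm = np.array([0.25, 0.6, 0.3, 0.1, 0.0])
        np.testing.assert_allclose(probs, unnorm / unnorm.sum())

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            randomization_probabilities(np.zeros(5), np.zeros(5),
                                        AdmissibleSet((), 5), DesignConfig())
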