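import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asyncoop.coalescence import RateProfile, solve_coalescence
from asyncoop.criticality import (
    GameParams,
    correction_terms,
    cstar_approx,
    cstar_asymptotic,
    cstar_exact,
    general_game_condition,
    rate_profile,
    rho_c_weak_selection,
    zeta,
)
from asyncoop.netio import generate_network
from conftest import random_connected_graph, random_rates


def regular_closed_form(n: int, k: int) -> float:
    # vertex-transitive graphs with identical rates
    return k * (n - 2) / (n - 2 * k)


class TestCstarExact:
    def test_triangle_hand_evaluation(self, k3):
        """η = 1 off-diagonal; hand matrix products give numerator 3 and
        denominator −1.5, so C* = −2 (spite regime: cooperation is never
        favoured on the complete graph)."""
        r = cstar_exact(k3, RateProfile.identical(3))
        assert r.numerator == pytest.approx(3.0, abs=1e-12)
        assert r.denominator == pytest.approx(-1.5, abs=1e-12)
        assert r.value == pytest.approx(-2.0, abs=1e-12)
        assert r.regime == "never_favoured"

    def test_cycle6(self, cycle6):
        r = cstar_exact(cycle6, RateProfile.identical(6))
        assert r.value == pytest.approx(4.0, abs=1e-10)
        assert r.regime == "finite_positive"

    @pytest.mark.parametrize("model,n,k", [
        ("cycle", 6, 2), ("cycle", 8, 2), ("cycle", 12, 2),
        ("complete", 3, 2), ("complete", 5, 4), ("complete", 8, 7),
    ])
    def test_vertex_transitive_closed_form(self, model, n, k):
        net = generate_network(model, n=n)
        r = cstar_exact(net, RateProfile.identical(n), with_components=False)
        assert r.value == pytest.approx(regular_closed_form(n, k), abs=1e-10)

    def test_divergence_at_n_equal_2k(self):
        net = generate_network("cycle", n=4)
        r = cstar_exact(net, RateProfile.identical(4), with_components=False)
        assert r.regime == "divergent"
        assert np.isnan(r.value)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rate_scaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        net = random_connected_graph(int(rng.integers(4, 9)), rng)
        rp = random_rates(net.n, rng)
        a = cstar_exact(net, rp, with_components=False)
        b = cstar_exact(net, RateProfile(rp.lam * 10), with_components=False)
        if np.isnan(a.value):
            assert np.isnan(b.value)
        else:
            assert b.value == pytest.approx(a.value, rel=1e-12)


class TestCstarApprox:
    def test_identical_rates_zero_corrections(self, ba100):
        """With λ_i = 1 every heterogeneity correction vanishes."""
        ct = correction_terms(ba100, RateProfile.identical(100))
        for key in ("delta_lambda1", "delta_lambda2",
                    "delta_eta_n", "delta_eta_d"):
            assert abs(ct[key]) <= 1e-12

    def test_zeta_identical_is_half(self, ba100, cycle6):
        assert zeta(ba100, RateProfile.identical(100)) == pytest.approx(
            0.5, abs=1e-14)
        assert zeta(cycle6, RateProfile.identical(6)) == pytest.approx(
            0.5, abs=1e-14)

    @pytest.mark.parametrize("model,n,k", [
        ("cycle", 6, 2), ("cycle", 10, 2), ("complete", 5, 4),
    ])
    def test_regular_identical_reduces_to_closed_form(self, model, n, k):
        """On k-regular graphs with identical rates the mean-field
        formula collapses algebraically to (N/2−1)/(N/(2k)−1)."""
        net = generate_network(model, n=n)
        r = cstar_approx(net, RateProfile.identical(n),
                         eta_bar_mode="supplied", eta_bar=1.0)
        assert r.value == pytest.approx(regular_closed_form(n, k), abs=1e-10)

    def test_matches_exact_on_regular_identical(self, cycle6):
        ex = cstar_exact(cycle6, RateProfile.identical(6))
        ap = cstar_approx(cycle6, RateProfile.identical(6))
        assert ap.value == pytest.approx(ex.value, abs=1e-10)

    def test_heterogeneous_ba_deviation_is_moderate(self, ba100):
        """Diagnostic: the mean-field estimate tracks the exact value on
        BA-100 with degree-inverse rates (loose bound, not a tolerance)."""
        rp = rate_profile(ba100, "power", gamma=1, sign=-1)
        ex = cstar_exact(ba100, rp, with_components=False)
        ap = cstar_approx(ba100, rp)
        rel = abs(ap.value - ex.value) / abs(ex.value)
        assert rel < 0.5

    def test_supplied_eta_bar_validated(self, cycle6):
        with pytest.raises(ValueError):
            cstar_approx(cycle6, RateProfile.identical(6),
                         eta_bar_mode="supplied", eta_bar=-1.0)


class TestCstarAsymptotic:
    def test_identical_rates_classified_at_mean_degree(self, ba100):
        r = cstar_asymptotic(ba100, RateProfile.identical(100), eta_bar=10.0)
        assert r.components["classification"] == "approx"
        assert r.value == pytest.approx(ba100.mean_degree, rel=1e-9)

    def test_inverse_degree_rates_below_mean_degree(self, ba100):
        rp = rate_profile(ba100, "power", gamma=1, sign=-1)
        r = cstar_asymptotic(ba100, rp, eta_bar=10.0)
        assert r.components["classification"] == "below"

    def test_degree_proportional_rates_above_mean_degree(self, ba100):
        rp = rate_profile(ba100, "power", gamma=1, sign=1)
        r = cstar_asymptotic(ba100, rp, eta_bar=10.0)
        assert r.components["classification"] == "above"

    def test_classification_independent_of_eta_bar(self, ba100):
        rp = rate_profile(ba100, "power", gamma=1, sign=-1)
        for eta_bar in (0.1, 10.0, 1000.0):
            assert cstar_asymptotic(ba100, rp, eta_bar) \
                .components["classification"] == "below"


class TestOrderings:
    def test_gamma_monotonicity(self, ba100):
        """C* under λ = k^(−γ) decreases with γ on the scale-free net."""
        values = [
            cstar_exact(ba100, rate_profile(ba100, "power", gamma=g, sign=-1),
                        with_components=False).value
            for g in (0, 1, 2, 3, 4)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_ordering_reversal_between_ba_and_lattice(self, ba100, lattice98):
        """Identical rates favour the lattice; degree-inverse rates make
        the scale-free network the easier home for cooperation."""
        ident_ba = cstar_exact(ba100, RateProfile.identical(100),
                               with_components=False).value
        ident_lat = cstar_exact(lattice98, RateProfile.identical(98),
                                with_components=False).value
        inv_ba = cstar_exact(ba100, rate_profile(ba100, "power", gamma=1,
                                                 sign=-1),
                             with_components=False).value
        inv_lat = cstar_exact(lattice98, rate_profile(lattice98, "power",
                                                      gamma=1, sign=-1),
                              with_components=False).value
        k_ba = cstar_exact(ba100, rate_profile(ba100, "power", gamma=1,
                                               sign=1),
                           with_components=False).value
        assert ident_ba > ident_lat
        assert inv_ba < inv_lat
        assert inv_ba < 6 < k_ba


class TestRateProfiles:
    def test_double_star_inverse_degree(self, double_star5):
        rp = rate_profile(double_star5, "power", gamma=1, sign=-1)
        k = double_star5.degrees
        assert rp.lam[np.argmax(k)] == pytest.approx(1 / 6)
        assert rp.lam[np.argmin(k)] == pytest.approx(1.0)

    def test_identical(self, cycle6):
        rp = rate_profile(cycle6, "identical")
        assert np.all(rp.lam == 1.0)
        assert rp.total == 6.0

    @pytest.mark.parametrize("dist", ["uniform", "normal", "exponential",
                                      "power_law"])
    def test_distributions_positive_and_seeded(self, ba100, dist):
        a = rate_profile(ba100, "distribution", distribution=dist, seed=1)
        b = rate_profile(ba100, "distribution", distribution=dist, seed=2)
        c = rate_profile(ba100, "distribution", distribution=dist, seed=1)
        assert np.all(a.lam > 0) and np.all(b.lam > 0)
        assert not np.array_equal(a.lam, b.lam)
        assert np.array_equal(a.lam, c.lam)

    def test_invalid_parameters(self, cycle6):
        with pytest.raises(ValueError):
            rate_profile(cycle6, "power", gamma=-1)
        with pytest.raises(ValueError):
            rate_profile(cycle6, "distribution", distribution="uniform",
                         low=2.0, high=1.0)


class TestGeneralGame:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=0.01, max_value=0.99),
           st.floats(min_value=1.5, max_value=50))
    def test_donation_game_reduces_to_bc_threshold(self, b, c_frac, cstar):
        """With R=b−c, S=−c, T=b, P=0 the general condition is exactly
        b/c > C*."""
        c = b * c_frac
        R, S, T, P = b - c, -c, b, 0.0
        favoured, _ = general_game_condition(R, S, T, P, cstar)
        assert favoured == (b / c > cstar)

    def test_cstar_one_gives_R_greater_P(self):
        favoured, thr = general_game_condition(2.0, -1.0, 3.0, 1.5, 1.0)
        assert thr == 1.5
        assert favoured

    def test_T_equals_S_gives_R_greater_P(self):
        _, thr = general_game_condition(2.0, 1.0, 1.0, 0.5, 7.3)
        assert thr == 0.5

    def test_undefined_at_minus_one(self):
        with pytest.raises(ZeroDivisionError):
            general_game_condition(1, 0, 2, 0, -1.0)

    def test_game_params_embedding(self):
        gp = GameParams(b=6, c=1)
        assert gp.as_general() == (5.0, -1.0, 6.0, 0.0)
        with pytest.raises(ValueError):
            GameParams(b=-1, c=1)


class TestWeakSelectionFixation:
    def test_neutral_is_one_over_n(self, cycle6):
        rho = rho_c_weak_selection(cycle6, RateProfile.identical(6), 3, 1, 0.0)
        assert rho == pytest.approx(1 / 6, abs=1e-15)

    def test_correction_vanishes_at_cstar(self, cycle6):
        r = cstar_exact(cycle6, RateProfile.identical(6))
        for delta in (0.005, 0.05):
            rho = rho_c_weak_selection(cycle6, RateProfile.identical(6),
                                       r.value, 1.0, delta)
            assert rho == pytest.approx(1 / 6, abs=1e-12)

    def test_single_edge_always_one_half(self, k2):
        """On K2, p² = I and p³ = p, so the first-order bracket vanishes
        for any b, c, δ."""
        for b, c, d in [(6, 1, 0.05), (2, 1.5, 0.1)]:
            rho = rho_c_weak_selection(k2, RateProfile.identical(2), b, c, d)
            assert rho == pytest.approx(0.5, abs=1e-15)

    def test_reuses_supplied_table(self, cycle6):
        rp = RateProfile.identical(6)
        table = solve_coalescence(cycle6, rp)
        a = rho_c_weak_selection(cycle6, rp, 5, 1, 0.01, table=table)
        b = rho_c_weak_selection(cycle6, rp, 5, 1, 0.01)
        assert a == b
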