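import numpy as np
import pytest

from asyncoop.coalescence import RateProfile
from asyncoop.criticality import rate_profile
from asyncoop.oracle import exact_fixation
from asyncoop.simulate import (
    measure_Q,
    simulate_fixation,
    simulate_longterm,
    trajectory,
)


def within_3se(estimate, target):
    se = max(estimate.std_error, 1e-12)
    return abs(estimate.rho_hat - target) <= 3 * se


class TestFixationRuns:
    def test_single_edge_is_one_half(self, k2):
        """The first updater copies the other node regardless of
        fitness, so ρ_C = 1/2 for any b, c, δ."""
        est = simulate_fixation(k2, RateProfile.identical(2), 6, 1, 0.05,
                                n_runs=4000, seed=1)
        assert within_3se(est, 0.5)

    def test_neutral_drift_matches_one_over_n(self, cycle6):
        est = simulate_fixation(cycle6, RateProfile.identical(6), 3, 1, 0.0,
                                n_runs=20_000, seed=2)
        assert within_3se(est, 1 / 6)

    def test_star_with_personalised_rates_matches_oracle(self, star4,
                                                         star4_rates):
        exact = exact_fixation(star4, star4_rates, 6, 1, 0.01).rho_c
        est = simulate_fixation(star4, star4_rates, 6, 1, 0.01,
                                n_runs=20_000, seed=3)
        assert within_3se(est, exact)

    @pytest.mark.parametrize("b,delta", [(2.0, 0.0), (6.0, 0.02),
                                         (1.0, 0.05)])
    def test_small_graph_grid_matches_oracle(self, path3, b, delta):
        rp = RateProfile(np.array([0.5, 1.0, 2.0]))
        exact = exact_fixation(path3, rp, b, 1.0, delta).rho_c
        est = simulate_fixation(path3, rp, b, 1.0, delta,
                                n_runs=10_000, seed=4)
        assert within_3se(est, exact)

    def test_rate_rescaling_bit_identical(self, star4, star4_rates):
        """λ and 10λ drive identical per-event probabilities, so shared
        seeds give identical trajectories, not merely equal statistics."""
        a = simulate_fixation(star4, star4_rates, 6, 1, 0.01, 3000, seed=5)
        b = simulate_fixation(star4, RateProfile(star4_rates.lam * 10.0),
                              6, 1, 0.01, 3000, seed=5)
        assert a.n_fix_c == b.n_fix_c
        assert a.mean_events == b.mean_events

    def test_seed_reproducibility(self, cycle6):
        rp = RateProfile.identical(6)
        a = simulate_fixation(cycle6, rp, 4, 1, 0.01, 1000, seed=7)
        b = simulate_fixation(cycle6, rp, 4, 1, 0.01, 1000, seed=7)
        c = simulate_fixation(cycle6, rp, 4, 1, 0.01, 1000, seed=8)
        assert a.n_fix_c == b.n_fix_c
        assert a.n_fix_c != c.n_fix_c or a.mean_events != c.mean_events

    def test_selection_strength_guard(self, k3):
        with pytest.raises(ValueError, match="delta"):
            simulate_fixation(k3, RateProfile.identical(3), 2, 1, 1.2, 10)

    def test_event_budget_enforced(self, cycle6):
        from asyncoop.simulate import EventBudgetError
        with pytest.raises(EventBudgetError, match="10"):
            simulate_fixation(cycle6, RateProfile.identical(6), 3, 1, 0.0,
                              n_runs=50, seed=0, budget=10)

    def test_trajectory_matches_engine(self, star4, star4_rates):
        """The python trajectory replay ends in the same absorbing state
        and event count as the compiled kernel for the same stream."""
        traj = trajectory(star4, star4_rates, 6, 1, 0.01, seed=9, run_index=0)
        assert traj[0, 1] == 1
        assert traj[-1, 1] in (0, 4)
        est = simulate_fixation(star4, star4_rates, 6, 1, 0.01, 1, seed=9)
        assert est.mean_events == traj[-1, 0]
        assert est.n_fix_c == (1 if traj[-1, 1] == 4 else 0)


class TestLocalFrequencyStats:
    def test_neutral_regular_graph_Q(self, regular100):
        """Neutral drift on a 6-regular graph: the edge-pooled Q sits
        well below the infinite-N pair-approximation value of 1 (the
        single-mutant transient dominates the event count), while the
        competition estimator recovers ⟨k⟩/C* ≈ 0.9."""
        rp = RateProfile.identical(100)
        pooled = measure_Q(regular100, rp, 0.0, 1500, seed=1)
        assert 0.6 < pooled.Q < 0.8
        comp = measure_Q(regular100, rp, 0.0, 1500, seed=1,
                         estimator="competition")
        cstar = 6 * 98 / 88  # k(N-2)/(N-2k)
        assert comp.Q == pytest.approx(6 / cstar, abs=0.03)

    def test_rate_ordering_of_Q(self, ba100):
        """Slow hubs accumulate cooperative neighbourhoods: Q is larger
        under λ = 1/k than under λ = k."""
        q_inv = measure_Q(ba100, rate_profile(ba100, "power", gamma=1,
                                              sign=-1),
                          0.01, 400, seed=2, estimator="competition").Q
        q_deg = measure_Q(ba100, rate_profile(ba100, "power", gamma=1,
                                              sign=1),
                          0.01, 400, seed=2, estimator="competition").Q
        assert q_inv > q_deg

    def test_bounds_and_degree_breakdown(self, regular100):
        stats = measure_Q(regular100, RateProfile.identical(100), 0.0, 200,
                          seed=3)
        assert 0 <= stats.q_cc <= 1 and 0 <= stats.q_cd <= 1
        assert set(stats.by_degree) == {6}
        qcc6, qcd6, n6 = stats.by_degree[6]
        assert 0 <= qcc6 <= 1 and 0 <= qcd6 <= 1 and n6 > 0


class TestLongTerm:
    def test_frozen_all_cooperators_payoff(self, star4, star4_rates):
        """With u = 0 from the all-C state nothing moves and every node
        earns exactly b − c per round."""
        with pytest.warns(RuntimeWarning, match="frozen"):
            lt = simulate_longterm(star4, star4_rates, 6, 1, 0.01, 0.0,
                                   n_events=50, seed=1, start="all_C")
        np.testing.assert_allclose(lt.payoff, 5.0, atol=1e-12)

    def test_payoff_ordering_under_rare_mutation(self, double_star5):
        """Slowly updating hubs raise everyone's long-term payoff:
        P(λ=1/k) > P(λ=1) > P(λ=k).  Checked on the double star in the
        rare-mutation regime, where the time shares of the monomorphic
        states are governed by the fixation probabilities and the exact
        chain predicts the same ordering (seed-averaged means)."""
        from asyncoop.oracle import exact_fixation as oracle_fix

        b, c, delta, u = 8.0, 1.0, 0.08, 0.02
        means, preds = [], []
        for scheme in ({"gamma": 1, "sign": -1}, None, {"gamma": 1, "sign": 1}):
            rp = (RateProfile.identical(12) if scheme is None
                  else rate_profile(double_star5, "power", **scheme))
            res = oracle_fix(double_star5, rp, b, c, delta)
            preds.append((b - c) * res.rho_c / (res.rho_c + res.rho_d))
            vals = [simulate_longterm(double_star5, rp, b, c, delta, u,
                                      500_000, seed=s).mean_payoff
                    for s in (1, 2, 3)]
            means.append(np.mean(vals))
        assert preds[0] > preds[1] > preds[2]
        assert means[0] > means[1] > means[2]

    def test_high_mutation_run_is_bounded_and_active(self, ba100):
        """With u = 1 the chain never freezes; payoffs stay within the
        attainable band (−c, b)."""
        lt = simulate_longterm(ba100, RateProfile.identical(100),
                               6.0, 1.0, 0.01, 1.0, 100_000, seed=4)
        assert np.all(lt.payoff > -1.0)
        assert np.all(lt.payoff < 6.0)
        assert 0.5 < lt.mean_payoff < 5.0

    def test_rare_mutation_time_split_tracks_fixation(self, star4,
                                                      star4_rates):
        """With rare mutations the chain sits almost always in the two
        monomorphic states; the cooperative share of time tracks
        ρ_C/(ρ_C+ρ_D) of the exact chain."""
        b, c, delta = 6.0, 1.0, 0.02
        res = exact_fixation(star4, star4_rates, b, c, delta)
        lt = simulate_longterm(star4, star4_rates, b, c, delta, u=0.002,
                               n_events=400_000, seed=6)
        # mean payoff ≈ (b−c) · fraction of time in all-C
        frac_c = lt.mean_payoff / (b - c)
        expected = res.rho_c / (res.rho_c + res.rho_d)
        assert frac_c == pytest.approx(expected, abs=0.1)
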