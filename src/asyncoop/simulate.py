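"""Event-driven Monte-Carlo engine for the evolutionary process.

The continuous-time picture — every node i carrying an independent
Poisson clock of rate λ_i — is simulated as a discrete event chain:
at each event the updating node is i with probability λ_i/Λ (competing
exponentials), and i copies the strategy of neighbour j with
probability proportional to j's fitness F_j = 1 + δ f_j.  All reported
quantities are event-indexed, so absolute time never needs to be drawn.

Runs are reproducible per (seed, run index): per-run streams are derived
from the master seed with ``np.random.SeedSequence``, making estimates
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from . import _kernels
from .coalescence import RateProfile
from .netio import Network

__all__ = [
    "FixationEstimate",
    "LocalFrequencyStats",
    "LongTermPayoffs",
    "simulate_fixation",
    "simulate_longterm",
    "measure_Q",
    "EventBudgetError",
]

DEFAULT_BUDGET = 100_000_000


class EventBudgetError(RuntimeError):
    """A run exceeded the per-run event budget."""


@dataclass(frozen=True)
class FixationEstimate:
    """MC estimate of the fixation probability of cooperation."""

    n_runs: int
    n_fix_c: int
    mean_events: float

    @property
    def rho_hat(self) -> float:
        return self.n_fix_c / self.n_runs

    @property
    def std_error(self) -> float:
        p = self.rho_hat
        return float(np.sqrt(p * (1.0 - p) / self.n_runs))


@dataclass(frozen=True)
class LocalFrequencyStats:
    """Edge-weighted conditional cooperator frequencies.

    q_cc (q_cd) is the pooled fraction of cooperators among the
    neighbours of cooperators (defectors), event-weighted over all
    update events at which both strategies coexist;
    Q = (q_cc − q_cd)(⟨k⟩ − 1) is the surplus of cooperative neighbours
    a cooperator holds over a defector.
    """

    q_cc: float
    q_cd: float
    mean_degree: float
    n_events_pooled: int
    by_degree: dict  # degree -> (q_cc, q_cd, n_events)

    @property
    def Q(self) -> float:
        return (self.q_cc - self.q_cd) * (self.mean_degree - 1.0)


@dataclass(frozen=True)
class LongTermPayoffs:
    """Event-averaged per-node payoffs of the mutation-driven process."""

    payoff: np.ndarray
    n_events: int
    u: float

    @property
    def mean_payoff(self) -> float:
        return float(self.payoff.mean())


def _prepare(network: Network, rates: RateProfile, b, c, delta):
    if rates.n != network.n:
        raise ValueError("rate profile length does not match network size")
    if delta < 0:
        raise ValueError("selection intensity must be non-negative")
    if delta * c >= 1.0:
        raise ValueError(
            f"selection too strong: delta*c = {delta * c} >= 1 makes some "
            "fitness non-positive"
        )
    indptr, indices = network.csr_neighbors()
    k_arr = network.degrees.astype(np.int64)
    lam_cum = np.cumsum(rates.lam / rates.total)
    lam_cum[-1] = 1.0
    return indptr, indices, k_arr, lam_cum


def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_runs, dtype=np.uint32)


def simulate_fixation(network: Network, rates: RateProfile, b: float,
                      c: float, delta: float, n_runs: int, seed: int = 0,
                      collect_stats: bool = False,
                      budget: int = DEFAULT_BUDGET):
    """Estimate ρ_C from ``n_runs`` independent absorption runs.

    Each run starts from one cooperator placed uniformly at random among
    N−1 defectors and ends at an absorbing state.  Returns a
    :class:`FixationEstimate`, or a ``(FixationEstimate,
    LocalFrequencyStats)`` pair with ``collect_stats=True``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    indptr, indices, k_arr, lam_cum = _prepare(network, rates, b, c, delta)
    seeds = _run_seeds(seed, n_runs)
    n_fix = 0
    total_events = 0
    if not collect_stats:
        for s in seeds:
            fixed, ev = _kernels.run_fixation(
                indptr, indices, k_arr, lam_cum, b, c, delta, s, budget)
            if fixed < 0:
                raise EventBudgetError(f"event budget {budget} exceeded")
            n_fix += fixed
            total_events += ev
        return FixationEstimate(n_runs=n_runs, n_fix_c=n_fix,
                                mean_events=total_events / n_runs)

    cap = int(k_arr.max())
    sum_qcc = sum_qcd = 0.0
    n_pooled = 0
    deg_qcc = np.zeros(cap + 1)
    deg_qcd = np.zeros(cap + 1)
    deg_cnt = np.zeros(cap + 1, dtype=np.int64)
    for s in seeds:
        fixed, ev, qcc, qcd, np_, dqcc, dqcd, dcnt = \
            _kernels.run_fixation_stats(
                indptr, indices, k_arr, lam_cum, b, c, delta, s, budget, cap)
        if fixed < 0:
            raise EventBudgetError(f"event budget {budget} exceeded")
        n_fix += fixed
        total_events += ev
        sum_qcc += qcc
        sum_qcd += qcd
        n_pooled += np_
        deg_qcc += dqcc
        deg_qcd += dqcd
        deg_cnt += dcnt
    est = FixationEstimate(n_runs=n_runs, n_fix_c=n_fix,
                           mean_events=total_events / n_runs)
    by_degree = {
        int(d): (deg_qcc[d] / deg_cnt[d], deg_qcd[d] / deg_cnt[d],
                 int(deg_cnt[d]))
        for d in range(cap + 1) if deg_cnt[d] > 0
    }
    stats = LocalFrequencyStats(
        q_cc=sum_qcc / n_pooled, q_cd=sum_qcd / n_pooled,
        mean_degree=network.mean_degree, n_events_pooled=n_pooled,
        by_degree=by_degree,
    )
    return est, stats


def measure_Q(network: Network, rates: RateProfile, delta: float,
              n_runs: int, seed: int = 0, b: float = 6.0, c: float = 1.0,
              estimator: str = "edge_pooled",
              budget: int = DEFAULT_BUDGET) -> LocalFrequencyStats:
    """Pooled Q = (q_C|C − q_C|D)(⟨k⟩−1) over ``n_runs`` absorption runs.

    ``estimator="edge_pooled"`` records, at every event where both
    strategies coexist, the edge-weighted fractions of cooperators
    opposite cooperators/defectors, pooled with equal weight per event.
    ``estimator="competition"`` instead samples only events whose
    updater has neighbours of both strategies and excludes the focal
    node from the neighbour counts — the quantity that actually drives
    the strategy competition; on a regular graph it equals ⟨k⟩/C*.
    Pair approximation predicts Q → 1 for identical rates at large N;
    both estimators carry finite-size deficits below that limit (the
    edge-pooled one also an absorbing-boundary transient bias), so at
    N = 100 values of roughly 0.7 (edge_pooled) and 0.9 (competition)
    are the expected neutral-drift outcomes on a 6-regular graph.
    The game parameters matter only for δ > 0.
    """
    if estimator == "edge_pooled":
        _, stats = simulate_fixation(network, rates, b, c, delta, n_runs,
                                     seed, collect_stats=True, budget=budget)
        return stats
    if estimator != "competition":
        raise ValueError(f"unknown estimator {estimator!r}")
    indptr, indices, k_arr, lam_cum = _prepare(network, rates, b, c, delta)
    seeds = _run_seeds(seed, n_runs)
    sum_qcc = sum_qcd = 0.0
    n_pooled = 0
    for s in seeds:
        fixed, _, qcc, qcd, np_ = _kernels.run_fixation_competition(
            indptr, indices, k_arr, lam_cum, b, c, delta, s, budget)
        if fixed < 0:
            raise EventBudgetError(f"event budget {budget} exceeded")
        sum_qcc += qcc
        sum_qcd += qcd
        n_pooled += np_
    return LocalFrequencyStats(
        q_cc=sum_qcc / n_pooled, q_cd=sum_qcd / n_pooled,
        mean_degree=network.mean_degree, n_events_pooled=n_pooled,
        by_degree={},
    )


def trajectory(network: Network, rates: RateProfile, b: float, c: float,
               delta: float, seed: int = 0, run_index: int = 0,
               budget: int = DEFAULT_BUDGET) -> np.ndarray:
    """(event, #cooperators) trajectory of one run, for inspection.

    Replays the run the engine would execute for (seed, run_index) —
    same derived stream, same draw order — recording the cooperator
    count after every event.  Returns an (n_events+1, 2) integer array
    starting at event 0.
    """
    indptr, indices, k_arr, lam_cum = _prepare(network, rates, b, c, delta)
    s = int(_run_seeds(seed, run_index + 1)[run_index])
    np.random.seed(s)
    n = network.n
    x = np.zeros(n, dtype=np.int64)
    ncoop_nb = np.zeros(n, dtype=np.int64)
    start = min(int(np.random.random() * n), n - 1)
    x[start] = 1
    for t in range(indptr[start], indptr[start + 1]):
        ncoop_nb[indices[t]] += 1
    ncoop = 1
    out = [(0, 1)]
    events = 0
    while 0 < ncoop < n:
        if events >= budget:
            raise EventBudgetError(f"event budget {budget} exceeded")
        u1 = np.random.random()
        u2 = np.random.random()
        i = int(np.searchsorted(lam_cum, u1))
        if delta == 0.0:
            span = indptr[i + 1] - indptr[i]
            j = indices[indptr[i] + min(int(u2 * span), span - 1)]
        else:
            j = _kernels._pick_neighbor(indptr, indices, x, ncoop_nb, k_arr,
                                        b, c, delta, i, u2)
        if x[j] != x[i]:
            d = x[j] - x[i]
            x[i] = x[j]
            for t in range(indptr[i], indptr[i + 1]):
                ncoop_nb[indices[t]] += d
            ncoop += d
        events += 1
        out.append((events, ncoop))
    return np.array(out, dtype=np.int64)


def simulate_longterm(network: Network, rates: RateProfile, b: float,
                      c: float, delta: float, u: float, n_events: int,
                      seed: int = 0, start: str = "all_D") -> LongTermPayoffs:
    """Long-run per-node payoffs of the process with mutation.

    Whenever the population is monomorphic, a mutant appears with
    probability ``u`` per event at a uniformly chosen node.  Payoffs of
    the post-event state are averaged over all ``n_events`` events.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 <= u <= 1:
        raise ValueError("mutation probability must lie in [0, 1]")
    indptr, indices, k_arr, lam_cum = _prepare(network, rates, b, c, delta)
    if u == 0.0:
        warnings.warn("u = 0 from an absorbing start: the run is frozen",
                      RuntimeWarning, stacklevel=2)
    s = int(_run_seeds(seed, 1)[0])
    payoff = _kernels.run_longterm(
        indptr, indices, k_arr, lam_cum, b, c, delta, u, n_events, s,
        1 if start == "all_C" else 0)
    return LongTermPayoffs(payoff=payoff, n_events=n_events, u=u)
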