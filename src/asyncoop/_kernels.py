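"""Event-loop kernels for the Monte-Carlo engine.

Written as plain NumPy functions against the legacy ``np.random``
global generator (MT19937) and jit-compiled with numba when it is
importable; numba implements the same Mersenne Twister streams, so the
compiled and interpreted paths draw identical random sequences and
produce bit-identical trajectories for a given seed.

Per update event exactly two uniform draws are consumed (updater, then
imitated neighbour), plus one draw for the initial mutant placement, so
trajectories are reproducible per (seed, run) regardless of rate
normalisation: only the probabilities λ_i/Λ and the fitness weights
enter, never the raw rates.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation test
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _pick_updater(lam_cum, u):
    """Index i with probability λ_i/Λ, via the cumulative profile."""
    return np.searchsorted(lam_cum, u)


@njit(cache=True)
def _pick_neighbor(indptr, indices, x, ncoop_nb, k_arr, b, c, delta, i, u):
    """Neighbour j of i chosen with probability ∝ F_j = 1 + δ f_j.

    ``ncoop_nb[j]`` caches the number of cooperating neighbours of j, so
    f_j = −c x_j + b ncoop_nb[j]/k_j is O(1) per neighbour.
    """
    start, end = indptr[i], indptr[i + 1]
    total = 0.0
    for t in range(start, end):
        j = indices[t]
        fj = -c * x[j] + b * ncoop_nb[j] / k_arr[j]
        total += 1.0 + delta * fj
    target = u * total
    acc = 0.0
    for t in range(start, end):
        j = indices[t]
        fj = -c * x[j] + b * ncoop_nb[j] / k_arr[j]
        acc += 1.0 + delta * fj
        if acc >= target:
            return j
    return indices[end - 1]  # numerical guard


@njit(cache=True)
def _flip(indptr, indices, x, ncoop_nb, i, new_state):
    """Set x_i and update the cached cooperating-neighbour counts."""
    d = new_state - x[i]
    x[i] = new_state
    for t in range(indptr[i], indptr[i + 1]):
        ncoop_nb[indices[t]] += d


@njit(cache=True)
def run_fixation(indptr, indices, k_arr, lam_cum, b, c, delta, seed, budget):
    """One absorption run from a uniformly placed single cooperator.

    Returns (fixed_c, n_events); fixed_c is 1 on all-C absorption, 0 on
    all-D, and -1 if the event budget was exhausted.
    """
    n = k_arr.shape[0]
    np.random.seed(seed)
    x = np.zeros(n, dtype=np.int64)
    ncoop_nb = np.zeros(n, dtype=np.int64)
    start = int(np.random.random() * n)
    if start == n:
        start = n - 1
    _flip(indptr, indices, x, ncoop_nb, start, 1)
    ncoop = 1
    events = 0
    while 0 < ncoop < n:
        if events >= budget:
            return -1, events
        u1 = np.random.random()
        u2 = np.random.random()
        i = _pick_updater(lam_cum, u1)
        if delta == 0.0:
            span = indptr[i + 1] - indptr[i]
            j = indices[indptr[i] + min(int(u2 * span), span - 1)]
        else:
            j = _pick_neighbor(indptr, indices, x, ncoop_nb, k_arr,
                               b, c, delta, i, u2)
        if x[j] != x[i]:
            _flip(indptr, indices, x, ncoop_nb, i, x[j])
            ncoop += x[j] * 2 - 1
        events += 1
    return (1 if ncoop == n else 0), events


@njit(cache=True)
def run_fixation_stats(indptr, indices, k_arr, lam_cum, b, c, delta, seed,
                       budget, degree_cap):
    """Absorption run that also pools the conditional-frequency statistics.

    At every event where both strategies coexist (i.e. every event of
    the run, since absorption ends it) the edge-weighted fractions
    q_C|C = #(C→C edge ends)/Σ_{u∈C} k_u  and
    q_C|D = #(D→C edge ends)/Σ_{u∈D} k_u
    of the *pre-update* state are recorded, pooled with equal weight per
    event, overall and per degree class.

    Returns (fixed_c, events, sum_qcc, sum_qcd, n_pooled,
             per-degree sums qcc_d, qcd_d, counts_d).
    """
    n = k_arr.shape[0]
    big_k = 0
    for i in range(n):
        big_k += k_arr[i]
    np.random.seed(seed)
    x = np.zeros(n, dtype=np.int64)
    ncoop_nb = np.zeros(n, dtype=np.int64)
    start = int(np.random.random() * n)
    if start == n:
        start = n - 1
    _flip(indptr, indices, x, ncoop_nb, start, 1)
    ncoop = 1

    # sc = Σ_{u: C} k_u ; ecc = #(ordered C→C edge ends)
    sc = k_arr[start]
    ecc = 0
    # per-degree-class tallies, indexed by degree
    sc_d = np.zeros(degree_cap + 1, dtype=np.int64)     # Σ k over C nodes of deg d
    sd_d = np.zeros(degree_cap + 1, dtype=np.int64)     # Σ k over D nodes of deg d
    ecc_d = np.zeros(degree_cap + 1, dtype=np.int64)    # C→C ends from deg-d C nodes
    ecd_d = np.zeros(degree_cap + 1, dtype=np.int64)    # D→C ends from deg-d D nodes
    for u in range(n):
        if x[u] == 1:
            sc_d[k_arr[u]] += k_arr[u]
        else:
            sd_d[k_arr[u]] += k_arr[u]
            ecd_d[k_arr[u]] += ncoop_nb[u]

    sum_qcc = 0.0
    sum_qcd = 0.0
    n_pooled = 0
    sum_qcc_deg = np.zeros(degree_cap + 1)
    sum_qcd_deg = np.zeros(degree_cap + 1)
    cnt_deg = np.zeros(degree_cap + 1, dtype=np.int64)

    events = 0
    while 0 < ncoop < n:
        if events >= budget:
            return -1, events, sum_qcc, sum_qcd, n_pooled, \
                sum_qcc_deg, sum_qcd_deg, cnt_deg
        # record the coexisting pre-update state
        sum_qcc += ecc / sc
        sum_qcd += (sc - ecc) / (big_k - sc)
        n_pooled += 1
        for d in range(degree_cap + 1):
            if sc_d[d] > 0 and sd_d[d] > 0:
                sum_qcc_deg[d] += ecc_d[d] / sc_d[d]
                sum_qcd_deg[d] += ecd_d[d] / sd_d[d]
                cnt_deg[d] += 1

        u1 = np.random.random()
        u2 = np.random.random()
        i = _pick_updater(lam_cum, u1)
        if delta == 0.0:
            span = indptr[i + 1] - indptr[i]
            j = indices[indptr[i] + min(int(u2 * span), span - 1)]
        else:
            j = _pick_neighbor(indptr, indices, x, ncoop_nb, k_arr,
                               b, c, delta, i, u2)
        if x[j] != x[i]:
            new = x[j]
            ki = k_arr[i]
            if new == 1:           # D -> C flip of node i
                sc += ki
                ecc += 2 * ncoop_nb[i]
                sc_d[ki] += ki
                sd_d[ki] -= ki
                ecc_d[ki] += ncoop_nb[i]
                ecd_d[ki] -= ncoop_nb[i]
            else:                  # C -> D flip
                sc -= ki
                ecc -= 2 * ncoop_nb[i]
                sc_d[ki] -= ki
                sd_d[ki] += ki
                ecc_d[ki] -= ncoop_nb[i]
                ecd_d[ki] += ncoop_nb[i]
            # neighbours of i see their opposite end flip
            for t in range(indptr[i], indptr[i + 1]):
                v = indices[t]
                if new == 1:
                    if x[v] == 1:
                        ecc_d[k_arr[v]] += 1
                    else:
                        ecd_d[k_arr[v]] += 1
                else:
                    if x[v] == 1:
                        ecc_d[k_arr[v]] -= 1
                    else:
                        ecd_d[k_arr[v]] -= 1
            _flip(indptr, indices, x, ncoop_nb, i, new)
            ncoop += new * 2 - 1
        events += 1
    return (1 if ncoop == n else 0), events, sum_qcc, sum_qcd, n_pooled, \
        sum_qcc_deg, sum_qcd_deg, cnt_deg


@njit(cache=True)
def run_fixation_competition(indptr, indices, k_arr, lam_cum, b, c, delta,
                             seed, budget):
    """Absorption run pooling the competition-centred q statistics.

    At every event whose updater has at least one cooperating and one
    defecting neighbour (the only events where the strategies actually
    compete for the site), record the mean fraction of cooperators
    among the k−1 *other* neighbours of the updater's cooperator
    neighbours (q_C|C) and of its defector neighbours (q_C|D) — the
    focal node is excluded from the counts exactly as in the
    competition argument behind the pair approximation.

    Returns (fixed_c, events, sum_qcc, sum_qcd, n_pooled).
    """
    n = k_arr.shape[0]
    np.random.seed(seed)
    x = np.zeros(n, dtype=np.int64)
    ncoop_nb = np.zeros(n, dtype=np.int64)
    start = int(np.random.random() * n)
    if start == n:
        start = n - 1
    _flip(indptr, indices, x, ncoop_nb, start, 1)
    ncoop = 1
    sum_qcc = 0.0
    sum_qcd = 0.0
    n_pooled = 0
    events = 0
    while 0 < ncoop < n:
        if events >= budget:
            return -1, events, sum_qcc, sum_qcd, n_pooled
        u1 = np.random.random()
        u2 = np.random.random()
        i = _pick_updater(lam_cum, u1)
        scc = 0.0
        ncc = 0
        scd = 0.0
        ncd = 0
        for t in range(indptr[i], indptr[i + 1]):
            v = indices[t]
            if k_arr[v] > 1:
                frac = (ncoop_nb[v] - x[i]) / (k_arr[v] - 1)
                if x[v] == 1:
                    scc += frac
                    ncc += 1
                else:
                    scd += frac
                    ncd += 1
        if ncc > 0 and ncd > 0:
            sum_qcc += scc / ncc
            sum_qcd += scd / ncd
            n_pooled += 1
        if delta == 0.0:
            span = indptr[i + 1] - indptr[i]
            j = indices[indptr[i] + min(int(u2 * span), span - 1)]
        else:
            j = _pick_neighbor(indptr, indices, x, ncoop_nb, k_arr,
                               b, c, delta, i, u2)
        if x[j] != x[i]:
            _flip(indptr, indices, x, ncoop_nb, i, x[j])
            ncoop += x[j] * 2 - 1
        events += 1
    return (1 if ncoop == n else 0), events, sum_qcc, sum_qcd, n_pooled


@njit(cache=True)
def run_longterm(indptr, indices, k_arr, lam_cum, b, c, delta, u_mut,
                 n_events, seed, start_all_c):
    """Ergodic run with mutation; event-averaged per-node payoffs.

    Whenever the state is absorbing, with probability u_mut a uniformly
    chosen node flips.  Payoffs f_i = −c x_i + b ncoop_nb[i]/k_i of the
    post-event state are accumulated over all events.
    """
    n = k_arr.shape[0]
    np.random.seed(seed)
    x = np.zeros(n, dtype=np.int64)
    ncoop_nb = np.zeros(n, dtype=np.int64)
    ncoop = 0
    if start_all_c == 1:
        for i in range(n):
            _flip(indptr, indices, x, ncoop_nb, i, 1)
        ncoop = n
    payoff = np.zeros(n)
    for _ in range(n_events):
        if ncoop == 0 or ncoop == n:
            if np.random.random() < u_mut:
                m = int(np.random.random() * n)
                if m == n:
                    m = n - 1
                _flip(indptr, indices, x, ncoop_nb, m, 1 - x[m])
                ncoop += x[m] * 2 - 1
        else:
            u1 = np.random.random()
            u2 = np.random.random()
            i = _pick_updater(lam_cum, u1)
            if delta == 0.0:
                span = indptr[i + 1] - indptr[i]
                j = indices[indptr[i] + min(int(u2 * span), span - 1)]
            else:
                j = _pick_neighbor(indptr, indices, x, ncoop_nb, k_arr,
                                   b, c, delta, i, u2)
            if x[j] != x[i]:
                _flip(indptr, indices, x, ncoop_nb, i, x[j])
                ncoop += x[j] * 2 - 1
        for i in range(n):
            payoff[i] += -c * x[i] + b * ncoop_nb[i] / k_arr[i]
    return payoff / n_events
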