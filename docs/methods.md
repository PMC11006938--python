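# Methods

## Model

A population of N players occupies the nodes of an undirected, simple,
connected network. Strategies are binary: x_i = 1 (cooperate) or 0
(defect). In the donation game each cooperator pays c per neighbour and
delivers b, so node i's average payoff is
f_i(x) = −c·x_i + b·Σ_j p_ij x_j with p_ij = e_ij/k_i.

Strategy revision is asynchronous. Node i carries an independent
Poisson clock of rate λ_i > 0; conditioning on an update event, the
updater is i with probability λ_i/Λ (Λ = Σ λ_i). The updater copies
neighbour j with probability proportional to j's fitness
F_j = 1 + δ f_j; the transmission probability is

    r_ji(x) = (λ_i/Λ) · e_ij F_j(x) / Σ_l e_il F_l(x).

δ ≥ 0 is the selection intensity; δ·c < 1 keeps all fitnesses positive.
Because only the normalised rates λ_i/Λ enter, every quantity in the
package is invariant under λ → a·λ (a > 0); this invariance is asserted
across the solver, the oracle and the simulator.

## Fixation and the critical ratio

Starting from one cooperator placed uniformly at random, the fixation
probability expands around neutrality as

    ρ_C = 1/N + δ/(Λ Σ_i k_i/λ_i) · [ −c Σ_ij k_i p²_ij η_ij
          + b (Σ_ij k_i p³_ij η_ij − Σ_ij k_i p_ij η_ij) ] + O(δ²),

with double sums over ordered pairs (diagonal terms vanish). The
meeting times η_ij solve the recurrence quoted in the README; the
package solves the N(N−1)/2-unknown pair system three ways:

* **direct** — sparse LU (SuperLU, AT+A minimum-degree ordering; the
  pair system is structurally symmetric). Default up to 160 nodes; the
  factorisation is cached and reused by the optimiser.
* **cg** — conjugate gradients after row-scaling by k_i k_j/(λ_i λ_j),
  which makes the pair matrix symmetric positive definite. Default
  beyond 160 nodes (N = 300 solves in tens of milliseconds).
* **iterative** — plain fixed-point sweeps of the recurrence; kept as a
  deliberately independent path for cross-checks.

Acceptance: the recurrence residual must not exceed 1e-10 (direct/cg)
relative to max(1, max η) — relative, because extreme rate ratios
(e.g. λ = k^−4 on a scale-free network) legitimately produce meeting
times of order 1e4 and absolute round-off grows with them. The
identical-rate special case is additionally solved by a dedicated dense
assembly (constant term 1/2) and compared to the general solver at
1e-12.

Setting the bracket to zero gives the critical ratio C* (README). The
denominator classifies the regime: positive → `finite_positive`;
negative with positive numerator → `never_favoured` (complete graphs:
K3 gives C* = −2, i.e. spite); zero within 1e-9 relative →
`divergent` (cycles with N = 2k; also star-like graphs where p³ = p
exactly). On vertex-transitive graphs with identical rates C* reduces
to the closed form k(N−2)/(N−2k), used as an exact test anchor
(cycle-6 → 4).

Reproductive values are π_i = (k_i/λ_i)/Σ_l(k_l/λ_l), the weights that
make x̂ = Σ π_i x_i a martingale of the neutral process; the martingale
identity is property-tested on random graphs, states and rates.

## Mean-field approximation and the ⟨k⟩ rule

The approximate critical ratio

    C* ≈ (N⟨k⟩²ζ/⟨k²⟩ − 1 + Δ_λ(1) + Δ_η̃n) / (N⟨k⟩ζ/⟨k²⟩ − 1 + Δ_λ(2) + Δ_η̃d)

avoids the pair solve. ζ = Σ_ij k_i k_j Λ/(N K²(λ_i+λ_j)) (ordered
pairs including i=j; equals 1/2 exactly at identical rates). The rate
corrections Δ_λ(1), Δ_λ(2) are exact closed forms; the meeting-time
corrections are assembled from Δ_η̃(n) = η̃^(n) − η^(n) with

    Δ_η̃n = −Δ_η̃(2) + (K²/Σk_i²)·Δ_η̃(∞)
    Δ_η̃d = −Δ_η̃(2) − Δ_η̃(3) + (KN/Σk_i²)·Δ_η̃(∞)

and the single edge sum

    Δ_η̃(∞) ≈ (η̄/K²) Σ_{i<j} (k_i−k_j)(λ_i−λ_j) e_ij/(λ_i+λ_j).

In the fast mode the large-network estimates Δ_η̃(2) ≈ N·Δ_η̃(∞)/⟨k⟩ and
Δ_η̃(3) ≈ N·Δ_η̃(∞)/⟨k⟩² are used and η̄ (the mean pairwise meeting
time) is supplied by the caller; with `eta_bar_mode="from_solve"` η̄ is
taken from an exact solve. `correction_terms` computes the η̃
differences exactly from a solved table. At identical rates every
correction vanishes identically and the formula collapses to the
regular-graph closed form — both asserted at 1e-12/1e-10.

For large heterogeneous networks the threshold sits at

    C* ≈ ⟨k⟩ + ⟨k⟩²⟨k²⟩Δ_η̃(∞) / (⟨k⟩³ζ + (⟨k⟩³ − ⟨k⟩⟨k²⟩ − ⟨k²⟩)Δ_η̃(∞)),

so only the **sign** of the edge sum decides the three-way
classification below/at/above ⟨k⟩. The magnitude of η̄ scales the
deviation but not the sign; because no fast η̄ estimator is part of the
public contract, magnitude uses of this formula take η̄ as a parameter
and only the sign rule is treated as exact.

## Monte-Carlo engine

Poisson clocks are simulated as a discrete event chain (competing
exponentials): per event, two uniform draws select the updater
(cumulative λ/Λ) and the imitated neighbour (fitness-weighted among
neighbours); payoffs are recomputed from the current state via cached
cooperating-neighbour counts, making an event O(k) — O(Σ_{j∈N(i)} 1)
for neutral runs. All reported quantities are event-indexed; absolute
time is never drawn. Kernels are plain NumPy code jit-compiled with
numba; the interpreted fallback draws the identical MT19937 stream.
Per-run seeds derive from `np.random.SeedSequence(seed)`, so estimates
are independent of execution order and bit-reproducible; shared seeds
give bit-identical trajectories under rate rescaling. The per-run event
budget (default 1e8) is a safety net — absorption is guaranteed on
connected graphs — and exceeding it raises rather than truncates.

Long-term payoffs: when the state is monomorphic, a mutant appears with
probability u per event at a uniform node. Per-node payoffs of the
post-event state are averaged over events (event- and time-averaging
coincide here because Λ is constant along a run). In the rare-mutation
regime the cooperative time share approaches ρ_C/(ρ_C+ρ_D), which the
tests verify against the exact chain on the 4-node star and the
12-node double star. At u = 1 the stationary mix is protocol-sensitive
and mixes slowly; the package asserts only boundedness there.

## The local statistic Q

Q = (q_C|C − q_C|D)(⟨k⟩−1) measures how many more cooperative
neighbours a cooperator has than a defector. Two estimators are
provided, both pooled over update events at which the two strategies
coexist:

* **edge_pooled** (default): per event, q_C|C = (C→C edge ends)/(edge
  ends leaving cooperators) and q_C|D analogously; per-event ratios are
  pooled with equal weight, overall and per degree class.
* **competition**: only events whose updater has neighbours of both
  strategies contribute; for the updater's cooperator (defector)
  neighbours the fraction of cooperators among their k−1 *other*
  neighbours is recorded, the focal node being excluded exactly as in
  the payoff-comparison argument that motivates Q.

Pair approximation predicts Q = 1 for identical rates on regular graphs
— an infinite-N statement equivalent to C* = ⟨k⟩. At finite N the
competition estimator measures the finite-size value ⟨k⟩/C* (with
C* = k(N−2)/(N−2k) on a regular graph): ≈ 0.898 on a 6-regular graph
of 100 nodes, 0.99 at N = 1000 — matching theory to three digits. The edge-pooled estimator
additionally carries a transient bias: most events of single-mutant
absorption runs occur near the absorbing boundaries where the local
surplus is far from its locally-equilibrated plateau, giving ≈ 0.70 at
N = 100. Both numbers are the honest neutral-drift outcomes at this
size; only as N → ∞ (and, for the edge-pooled variant, only after
removing the boundary transient) does Q approach 1. Slow hubs raise Q
and fast hubs lower it, which the tests assert as an ordering on the
scale-free network.

## Exact oracle

For N ≤ 12 the full 2^N transition kernel is assembled from r_ji and
the absorption system solved by direct elimination of the two
monomorphic states. The derivative dρ_C/dδ at 0 is computed
analytically (each fitness is affine in δ, so the kernel derivative is
exact) and guarded by a central finite-difference cross-check at 1e-6
relative. The empirical critical ratio bisects b at c = 1 for the sign
change of the derivative (tolerance 1e-8 on b); since the derivative is
affine in b, the bracket is extended to the extrapolated root when it
lies beyond the default 10N, and all-negative/all-positive derivatives
map to `never_favoured`/`divergent`. Formula-vs-oracle equivalence on
random graphs (N ∈ {4,5,6}, random rates) at 1e-6 relative is the
package's master consistency gate; formula regimes without a finite
positive threshold (`never_favoured`, `divergent`) correspond to an
everywhere-negative oracle derivative and are matched as one class.

## Rate optimisation

C* is minimised over θ with λ = exp(θ) (positivity for free). Writing
the pair system as A(λ)η = b(λ), each ∂η/∂λ_m solves
A·∂η/∂λ_m = ∂b/∂λ_m − (∂A/∂λ_m)η — the same operator, so one
factorisation per iteration serves all N right-hand sides. The chain
through ∂C*/∂η and ∂λ/∂θ = λ gives the full gradient, verified against
central finite differences at 1e-5 relative; by rate-scaling invariance
the gradient components sum to zero.

The update is RMSProp with the standard defaults: learning rate ε = 1,
decay ρ = 0.9, stabiliser δ_opt = 1e-6 inside the square root,
convergence when the mean |Δθ| falls to 1e-6, at most 1000 iterations.
Because the objective is flat along uniform θ shifts, θ may drift
without affecting C*; an optional centring step removes the drift and
an optional seeded perturbation (scale ~1e-3) breaks the exactly
symmetric stationary point that uniform initialisation occupies on
vertex-transitive graphs. Long runs push hub rates towards zero — C*
keeps improving while rate ratios grow very large — so the final C* is
evaluated through the optimiser's own solve path rather than the
residual-gated user API, and downstream consumers should treat extreme
optimised profiles as boundary-limit approximations.

## Synthetic networks

Generators cover the families used throughout: the "lattice" is a
periodic triangular lattice on an r×c torus (neighbour offsets (0,±1),
(±1,0), ±(1,1)), exactly 6-regular, default 7×14 = 98 nodes;
Barabási–Albert uses m = 3 so ⟨k⟩ ≈ 6; small-world rewiring defaults to
p = 0.7; Erdős–Rényi, random-regular and configuration-model draws are
resampled (up to 1000 attempts) until connected, keeping generation
deterministic per seed. Distribution-drawn rate profiles default to
uniform(0.5, 1.5), normal(1, 0.25) resampled below 0.05, exponential
(mean 1), and Pareto (tail exponent 2.5, minimum 0.1) — all strictly
positive, all configurable, all recorded in output metadata.

What the synthetic conditions do not emulate: real contact networks
(degree correlations, clustering, communities), temporal structure,
and any strong-selection regime (all guarantees are first order in δ).
Passing tests therefore establish the correctness of the machinery and
the qualitative rate rules at the stated sizes, not quantitative
predictions for empirical systems.

## Problem sizes

Tests and the acceptance script run at desk scale: Monte-Carlo
calibration uses 1e5 runs on the 4-node star (3-standard-error gates
against the exact chain), Q pooling uses 5000 neutral runs at N = 100,
the optimiser acceptance run uses 200 iterations on the 100-node
scale-free network, and oracle equivalence uses twenty random graphs
with N ≤ 6. These sizes give comfortable statistical margins for every
assertion made while keeping a full run in minutes on one CPU.
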