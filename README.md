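# asyncoop

Evolutionary dynamics of cooperation on networks whose members revise
their strategies at **personalised rates**.

## The problem

In the donation game on a network, each cooperator pays a cost *c* to
give a benefit *b* to every neighbour; defectors pay and give nothing.
Nodes revise their strategies asynchronously: node *i* carries a
Poisson clock of rate λ<sub>i</sub>, and when it fires, *i* copies a
neighbour *j* with probability proportional to *j*'s fitness
F<sub>j</sub> = 1 + δ·f<sub>j</sub> (weak selection, δ → 0).  Starting
from a single cooperator among N − 1 defectors, selection favours the
fixation of cooperation when ρ<sub>C</sub> > 1/N, which happens exactly
when *b*/*c* exceeds the **critical benefit-to-cost ratio**

```
        Σ_ij k_i p²_ij η_ij
C* = ───────────────────────────────
     Σ_ij k_i p³_ij η_ij − Σ_ij k_i p_ij η_ij
```

where p<sub>ij</sub> = e<sub>ij</sub>/k<sub>i</sub> is the one-step
random walk and η<sub>ij</sub> is the coalescence (meeting) time of two
rate-weighted random walkers, the solution of N(N−1)/2 linear
equations

```
η_ij = Λ/(N(λ_i+λ_j)) + Σ_k [λ_i p_ik η_kj + λ_j p_jk η_ki]/(λ_i+λ_j),   η_ii = 0.
```

With identical rates, heterogeneous (scale-free) networks demand a
*larger* C\* than regular ones.  The update rates change the picture:
when hubs update more slowly than their neighbours
((k<sub>i</sub>−k<sub>j</sub>)(λ<sub>i</sub>−λ<sub>j</sub>) < 0 across
edges), C\* drops below the mean degree ⟨k⟩ and scale-free networks
become the *most* hospitable to cooperation.  The package computes all
of this and also *designs* rates: an RMSProp descent on
λ<sub>i</sub> = exp(θ<sub>i</sub>) with implicit gradients through the
meeting-time system minimises C\* on any network.

## What's in the box

| module | contents |
| --- | --- |
| `asyncoop.netio` | `Network` container, ten generators (lattice torus, ER, small-world, BA, random-regular, configuration, uniform attachment, double star, cycle, complete), edge-list I/O |
| `asyncoop.coalescence` | walk operators, meeting-time solvers (sparse LU / CG / fixed point), reproductive values π<sub>i</sub> ∝ k<sub>i</sub>/λ<sub>i</sub> |
| `asyncoop.criticality` | exact C\* (above), mean-field approximation with heterogeneity corrections, asymptotic ⟨k⟩-comparison rule, rate profiles, general (R,S,T,P) games, first-order ρ<sub>C</sub> |
| `asyncoop.simulate` | event-driven Monte-Carlo engine (numba-accelerated): fixation runs, long-term payoffs under mutation, local cooperator statistics Q |
| `asyncoop.oracle` | exact 2^N Markov chain for N ≤ 12: absorption probabilities, analytic dρ<sub>C</sub>/dδ, brute-force critical ratio |
| `asyncoop.optimise` | OptUpRat: RMSProp descent with implicit gradients |
| `asyncoop.cli` | `asyncoop gen / cstar / simulate / oracle / optimise / fixtures` |

## Worked example

```python
from asyncoop import (RateProfile, cstar_exact, generate_network,
                      rate_profile)

ba = generate_network("scale_free_ba", n=100, m=3, seed=42)
lattice = generate_network("lattice", rows=7, cols=14)  # 6-regular torus

for label, net in [("scale-free", ba), ("lattice", lattice)]:
    ident = cstar_exact(net, RateProfile.identical(net.n)).value
    slow = cstar_exact(net, rate_profile(net, "power", gamma=1, sign=-1)).value
    print(f"{label:<11} C*(identical) = {ident:.3f}   C*(1/k) = {slow:.3f}")
```

prints

```
scale-free  C*(identical) = 7.109   C*(1/k) = 5.603
lattice     C*(identical) = 6.698   C*(1/k) = 6.698
```

With identical rates the scale-free network needs *b*/*c* > 7.11 — the
hardest of the two — but once hubs slow down (λ = 1/k) its threshold
falls to 5.60, below both the lattice (unchanged at 6.70, as rate
rules cannot matter on a regular graph where 1/k is constant) and its
own mean degree 5.82.  Running the optimiser
(`examples/optimise_rates.py`) pushes a 40-node scale-free network from
C\* = 8.27 (identical) to 5.08 in 60 iterations, with the final rates
strongly anticorrelated with degree (Spearman −0.88).

The `examples/` directory has one narrative script per capability:
`critical_ratio.py`, `fixation_simulation.py` (Monte-Carlo vs exact
chain vs first-order formula), `optimise_rates.py`, and
`local_cooperation.py` (the Q statistic behind the mechanism).

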