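"""Designing update rates that minimise the cooperation threshold.

Runs the RMSProp descent (implicit gradients through the meeting-time
system, rates parametrised as exp(θ)) on a 40-node scale-free network
and reports how far the critical ratio falls relative to the identical
and inverse-degree heuristics, and how the optimal rates relate to
node degree.
"""

import numpy as np
from scipy.stats import spearmanr

from asyncoop import (
    OptimizationConfig,
    RateProfile,
    cstar_exact,
    generate_network,
    optimise_rates,
    rate_profile,
)

net = generate_network("scale_free_ba", n=40, m=3, seed=7)
trace = optimise_rates(net, OptimizationConfig(max_iter=60))

ident = cstar_exact(net, RateProfile.identical(net.n),
                    with_components=False).value
inv = cstar_exact(net, rate_profile(net, "power", gamma=1, sign=-1),
                  with_components=False).value
rho = spearmanr(trace.final_rates.lam, net.degrees).statistic

print(f"network: N={net.n}, <k>={net.mean_degree:.2f}")
print(f"C* with identical rates     : {ident:.3f}")
print(f"C* with lambda = 1/k        : {inv:.3f}")
print(f"C* after {trace.n_iterations} iterations      : {trace.cstar[-1]:.3f} "
      f"({trace.status})")
print(f"Spearman(final rates, degree): {rho:.3f}")
print()
print("the optimiser beats both heuristics, and the optimal rates fall")
print("with degree: hubs should revise their strategies least often.")
hubs = np.argsort(net.degrees)[-3:]
leaves = np.argsort(net.degrees)[:3]
print(f"three largest hubs   k={net.degrees[hubs]}  "
      f"lambda={np.round(trace.final_rates.lam[hubs], 4)}")
print(f"three smallest nodes k={net.degrees[leaves]}  "
      f"lambda={np.round(trace.final_rates.lam[leaves], 4)}")
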