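"""Update-rate optimisation: minimise C* by RMSProp gradient descent.

The critical ratio is a smooth function of the update rates through the
meeting-time system, so its gradient is available by implicit
differentiation: writing the pair system as A(λ) η = b(λ), each
∂η/∂λ_m solves the *same* linear operator with a new right-hand side

    A ∂η/∂λ_m = ∂b/∂λ_m − (∂A/∂λ_m) η,

and one sparse LU factorisation per iteration serves all N solves.
Rates are parametrised as λ_i = exp(θ_i) so positivity is automatic,
and the chain rule appends a factor λ_i to each gradient component.

Because C* is invariant under uniform rescaling of λ, the objective is
flat along the all-ones direction in θ; convergence is therefore
declared on the mean absolute parameter step, which tolerates drift
along the flat direction.  On vertex-transitive graphs the uniform
point is a symmetric stationary point; an optional seeded perturbation
of the initial θ breaks that symmetry when wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescence import CoalescenceSystem, CoalescenceTable, RateProfile
from .criticality import CstarResult, cstar_exact
from .netio import Network

__all__ = [
    "OptimizationConfig",
    "OptimizationTrace",
    "cstar_gradient",
    "optimise_rates",
]


@dataclass(frozen=True)
class OptimizationConfig:
    """RMSProp hyper-parameters and stopping rule.

    Defaults follow the standard RMSProp choices: learning rate ε = 1,
    decay ρ = 0.9, stabiliser δ_opt = 1e-6, convergence when the mean
    absolute θ step falls to 1e-6, at most 1000 iterations.
    """

    epsilon: float = 1.0
    decay: float = 0.9
    delta_opt: float = 1e-6
    tol: float = 1e-6
    max_iter: int = 1000
    theta0: np.ndarray | None = None
    perturb_scale: float = 0.0
    seed: int = 0
    center: bool = False

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.decay < 1:
            raise ValueError("decay rate must lie in (0, 1)")
        if self.delta_opt <= 0 or self.tol <= 0:
            raise ValueError("delta_opt and tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class OptimizationTrace:
    """Per-iteration record of the descent."""

    theta: np.ndarray      # (n_iter+1, N) including the initial point
    cstar: np.ndarray      # (n_iter+1,)
    gradients: np.ndarray  # (n_iter, N)
    r: np.ndarray          # (n_iter, N) accumulated squared gradients
    status: str            # "converged" | "max_iter"

    @property
    def lam(self) -> np.ndarray:
        return np.exp(self.theta)

    @property
    def n_iterations(self) -> int:
        return self.gradients.shape[0]

    @property
    def final_rates(self) -> RateProfile:
        return RateProfile(np.exp(self.theta[-1]))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,cstar,mean_abs_step\n")
            for t in range(len(self.cstar)):
                step = (np.mean(np.abs(self.theta[t] - self.theta[t - 1]))
                        if t > 0 else float("nan"))
                fh.write(f"{t},{self.cstar[t]!r},{step!r}\n")


def _dcstar_deta_pairs(network: Network, system: CoalescenceSystem,
                       eta: np.ndarray) -> tuple[np.ndarray, CstarResult]:
    """∂C*/∂η_ij for unordered pairs, plus the current C*."""
    from .criticality import _weighted_sums  # shared sum convention
    from .coalescence import step_matrices

    walk = step_matrices(network)
    k = network.degrees.astype(float)
    s1, s2, s3 = _weighted_sums(network, walk, eta)
    num, den = s2, s3 - s1
    if den == 0:
        raise FloatingPointError("C* denominator vanished during optimisation")
    n = network.n
    iu, ju = np.triu_indices(n, k=1)
    w2 = k[iu] * walk.p2[iu, ju] + k[ju] * walk.p2[ju, iu]
    w31 = (k[iu] * (walk.p3 - walk.p)[iu, ju]
           + k[ju] * (walk.p3 - walk.p)[ju, iu])
    grad_pairs = (w2 * den - num * w31) / den**2
    result = cstar_exact(network, RateProfile(system.rates.lam),
                         table=CoalescenceTable(eta=eta, residual=0.0),
                         with_components=False)
    return grad_pairs, result


def cstar_gradient(network: Network, rates: RateProfile,
                   return_value: bool = False):
    """Gradient of C* with respect to θ (λ = exp θ) at the given rates.

    Solves the meeting-time system once, then reuses its factorisation
    for the N implicit-derivative systems.  Because of rate-scaling
    invariance the components sum to zero (up to round-off).
    """
    system = CoalescenceSystem(network, rates)
    h = system.solve()
    eta = system.pair_to_matrix(h)
    grad_pairs, result = _dcstar_deta_pairs(network, system, eta)

    from .coalescence import step_matrices

    p = step_matrices(network).p
    g_mat = eta - p @ eta                 # G_ij = η_ij − Σ_k p_ik η_kj
    n = network.n
    iu, ju = np.triu_indices(n, k=1)
    rhs = np.full((len(h), n), 1.0 / n)   # ∂b/∂λ_m = 1/N for every pair
    t = np.arange(len(h))
    # (∂A/∂λ_m η)_{(i,j)} = δ_im G_ij + δ_jm G_ji
    np.subtract.at(rhs, (t, iu), g_mat[iu, ju])
    np.subtract.at(rhs, (t, ju), g_mat[ju, iu])
    deta_dlam = system.solve_rhs(rhs)     # columns: ∂η_pairs/∂λ_m
    grad_theta = (grad_pairs @ deta_dlam) * rates.lam
    if return_value:
        return grad_theta, result
    return grad_theta


def optimise_rates(network: Network,
                   config: OptimizationConfig | None = None) -> OptimizationTrace:
    """Minimise C* over per-node update rates (the OptUpRat loop).

    Starting from θ = 0 (identical rates) unless configured otherwise,
    iterates: solve meeting times → C* and implicit gradient → RMSProp
    step, until the mean absolute step reaches the tolerance or the
    iteration budget is exhausted.
    """
    config = config or OptimizationConfig()
    n = network.n
    if config.theta0 is not None:
        theta = np.asarray(config.theta0, dtype=float).copy()
        if theta.shape != (n,):
            raise ValueError("theta0 must have one entry per node")
    else:
        theta = np.zeros(n)
    if config.perturb_scale > 0:
        rng = np.random.default_rng(config.seed)
        theta = theta + config.perturb_scale * rng.standard_normal(n)

    thetas = [theta.copy()]
    cstars = []
    grads = []
    rs = []
    r = np.zeros(n)
    status = "max_iter"
    for _ in range(config.max_iter):
        g, result = cstar_gradient(network, RateProfile(np.exp(theta)),
                                   return_value=True)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient at iteration {len(grads)}"
            )
        cstars.append(result.value)
        grads.append(g.copy())
        r = config.decay * r + (1.0 - config.decay) * g * g
        rs.append(r.copy())
        step = -config.epsilon / np.sqrt(config.delta_opt + r) * g
        theta = theta + step
        if config.center:
            theta = theta - theta.mean()
        thetas.append(theta.copy())
        if np.mean(np.abs(step)) <= config.tol:
            status = "converged"
            break
    # C* at the final point, via the same solve path as the iterations
    # (extreme optimised rate ratios are legitimate; the strict residual
    # gate of solve_coalescence is meant for user-facing tables)
    final_rates = RateProfile(np.exp(theta))
    system = CoalescenceSystem(network, final_rates)
    eta = system.pair_to_matrix(system.solve())
    _, final = _dcstar_deta_pairs(network, system, eta)
    cstars.append(final.value)
    return OptimizationTrace(
        theta=np.array(thetas), cstar=np.array(cstars),
        gradients=np.array(grads), r=np.array(rs), status=status,
    )
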