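"""Exact finite-state computations for small networks (N ≤ 12).

The evolutionary process is a Markov chain over the 2^N strategy
vectors: at each update event node i is chosen with probability λ_i/Λ
and copies neighbour j with probability proportional to j's fitness
F_j = 1 + δ f_j.  For N ≤ 12 the full transition kernel fits in memory,
so absorption probabilities, their exact derivative in the selection
intensity at δ = 0, and the empirical critical benefit-to-cost ratio
can all be computed to machine precision.  These serve as the
brute-force ground truth for the simulator and the closed-form theory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .coalescence import RateProfile
from .netio import Network

__all__ = [
    "OracleResult",
    "exact_fixation",
    "weak_selection_derivative",
    "empirical_cstar",
]

MAX_NODES = 12
FINITE_POSITIVE = "finite_positive"
NEVER_FAVOURED = "never_favoured"
DIVERGENT = "divergent"


@dataclass(frozen=True)
class OracleResult:
    """Exact absorption statistics averaged over single-mutant starts."""

    rho_c: float
    rho_d: float
    absorption: np.ndarray          # P[all-C | start state s], length 2^N
    d_rho_d_delta: float | None = None
    empirical_cstar: float | None = None
    regime: str | None = None


def _check_size(network: Network) -> None:
    if network.n > MAX_NODES:
        raise ValueError(
            f"exact chain limited to N <= {MAX_NODES} (2^N states); got {network.n}"
        )


def _payoffs(network: Network, b: float, c: float) -> np.ndarray:
    """f_i(x) = −c x_i + b Σ_j p_ij x_j for every state x (2^N × N)."""
    n = network.n
    states = np.arange(2 ** n)
    x = ((states[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    p = network.adjacency
    p = p / p.sum(axis=1, keepdims=True)
    return -c * x + b * (x @ p.T), x


def _kernel(network: Network, rates: RateProfile, b: float, c: float,
            delta: float) -> np.ndarray:
    """Dense transition matrix over all 2^N states."""
    n = network.n
    f, x = _payoffs(network, b, c)
    fit = 1.0 + delta * f
    if np.min(fit) <= 0:
        raise ValueError("selection too strong: some fitness non-positive "
                         "(need delta * c < 1)")
    lam = rates.lam / rates.total
    nbrs = network.neighbor_lists()
    m = 2 ** n
    t = np.zeros((m, m))
    for s in range(m):
        for i in range(n):
            w = fit[s, nbrs[i]]
            w = w / w.sum()
            for j, wj in zip(nbrs[i], w):
                new = (s | (1 << i)) if (s >> j) & 1 else (s & ~(1 << i))
                t[s, new] += lam[i] * wj
    return t


def _absorption(network: Network, rates: RateProfile, b: float, c: float,
                delta: float) -> np.ndarray:
    """Probability of reaching all-C from every state (direct elimination
    of the two absorbing states)."""
    n = network.n
    m = 2 ** n
    full = m - 1
    t = _kernel(network, rates, b, c, delta)
    transient = [s for s in range(m) if s not in (0, full)]
    a_tt = t[np.ix_(transient, transient)]
    r_full = t[transient, full]
    sol = sla.solve(np.eye(len(transient)) - a_tt, r_full)
    a = np.zeros(m)
    a[full] = 1.0
    a[transient] = sol
    return a


def _single_starts(n: int, cooperator: bool) -> np.ndarray:
    if cooperator:
        return np.array([1 << i for i in range(n)])
    full = (1 << n) - 1
    return np.array([full & ~(1 << i) for i in range(n)])


def exact_fixation(network: Network, rates: RateProfile, b: float, c: float,
                   delta: float) -> OracleResult:
    """Exact ρ_C and ρ_D by solving the absorption linear system.

    ρ_C averages P[all-C] over the N single-cooperator starts; ρ_D
    averages P[all-D] over the N single-defector starts.
    """
    _check_size(network)
    if rates.n != network.n:
        raise ValueError("rate profile length does not match network size")
    a = _absorption(network, rates, b, c, delta)
    n = network.n
    rho_c = float(a[_single_starts(n, True)].mean())
    rho_d = float(1.0 - a[_single_starts(n, False)].mean())
    return OracleResult(rho_c=rho_c, rho_d=rho_d, absorption=a)


def weak_selection_derivative(network: Network, rates: RateProfile,
                              b: float, c: float,
                              fd_check: bool = False,
                              fd_step: float = 1e-4) -> float:
    """Analytic dρ_C/dδ at δ = 0.

    Each fitness is affine in δ, so the kernel derivative T'(0) is exact:
    the absorption vector a(δ) solves (I − T_tt) a = r, and
    a'(0) = (I − T⁰_tt)⁻¹ (T'_tt a⁰ + r').  With ``fd_check`` a central
    finite difference at ±``fd_step`` is required to agree to 1e-6
    relative (guards the analytic path).
    """
    _check_size(network)
    n = network.n
    m = 2 ** n
    full = m - 1
    transient = [s for s in range(m) if s not in (0, full)]

    t0 = _kernel(network, rates, b, c, 0.0)
    t1 = _kernel_derivative(network, rates, b, c)
    a0 = _absorption(network, rates, b, c, 0.0)

    lhs = np.eye(len(transient)) - t0[np.ix_(transient, transient)]
    rhs = t1[np.ix_(transient, list(range(m)))] @ a0
    da = sla.solve(lhs, rhs)
    d_full = np.zeros(m)
    d_full[transient] = da
    deriv = float(d_full[_single_starts(n, True)].mean())

    if fd_check:
        hi = exact_fixation(network, rates, b, c, fd_step).rho_c
        lo = exact_fixation(network, rates, b, c, -fd_step).rho_c
        fd = (hi - lo) / (2 * fd_step)
        scale = max(abs(deriv), abs(fd), 1e-12)
        if abs(fd - deriv) / scale > 1e-6:
            raise RuntimeError(
                f"analytic derivative {deriv:.3e} disagrees with finite "
                f"difference {fd:.3e}"
            )
    return deriv


def _kernel_derivative(network: Network, rates: RateProfile,
                       b: float, c: float) -> np.ndarray:
    """dT/dδ at δ = 0: d/dδ [ (1+δf_j)/Σ_l (1+δf_l) ] = f_j/k_i − Φ_i/k_i²."""
    n = network.n
    f, _ = _payoffs(network, b, c)
    lam = rates.lam / rates.total
    nbrs = network.neighbor_lists()
    k = network.degrees.astype(float)
    m = 2 ** n
    t1 = np.zeros((m, m))
    for s in range(m):
        for i in range(n):
            phi = f[s, nbrs[i]].sum()
            for j in nbrs[i]:
                d = f[s, j] / k[i] - phi / k[i] ** 2
                new = (s | (1 << i)) if (s >> j) & 1 else (s & ~(1 << i))
                t1[s, new] += lam[i] * d
    return t1


def empirical_cstar(network: Network, rates: RateProfile,
                    b_max: float | None = None,
                    tol: float = 1e-8) -> OracleResult:
    """Critical b/c located from the exact chain (c = 1).

    Bisects b over (0, b_max] for the sign change of dρ_C/dδ at δ = 0.
    Returns regime "never_favoured" if the derivative is negative
    throughout and "divergent" if positive throughout.  The derivative
    is affine in b, so the bisection converges to the exact root.
    """
    _check_size(network)
    if b_max is None:
        b_max = 10.0 * network.n
    c = 1.0
    b_eps = tol

    def deriv(b):
        return weak_selection_derivative(network, rates, b, c)

    d_lo, d_hi = deriv(b_eps), deriv(b_max)
    neutral = exact_fixation(network, rates, 1.0, 1.0, 0.0)
    if np.sign(d_lo) == np.sign(d_hi) != 0:
        # the derivative is affine in b: extend the bracket to the
        # extrapolated root if one exists at positive b
        slope = (d_hi - d_lo) / (b_max - b_eps)
        root = b_eps - d_lo / slope if slope != 0 else -1.0
        if root <= 0 or slope == 0:
            regime = NEVER_FAVOURED if d_lo < 0 else DIVERGENT
            return OracleResult(rho_c=neutral.rho_c, rho_d=neutral.rho_d,
                                absorption=neutral.absorption, regime=regime)
        b_max = 2.0 * root
        d_hi = deriv(b_max)
        if np.sign(d_lo) == np.sign(d_hi):  # pragma: no cover - fp guard
            regime = NEVER_FAVOURED if d_lo < 0 else DIVERGENT
            return OracleResult(rho_c=neutral.rho_c, rho_d=neutral.rho_d,
                                absorption=neutral.absorption, regime=regime)
    lo, hi = b_eps, b_max
    sign_lo = np.sign(d_lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if np.sign(deriv(mid)) == sign_lo:
            lo = mid
        else:
            hi = mid
    root = 0.5 * (lo + hi)
    return OracleResult(rho_c=neutral.rho_c, rho_d=neutral.rho_d,
                        absorption=neutral.absorption,
                        d_rho_d_delta=0.0, empirical_cstar=float(root),
                        regime=FINITE_POSITIVE)
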