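"""Critical benefit-to-cost ratios for cooperation under personalised rates.

In the donation game on a network, weak selection favours the fixation
of cooperation (ρ_C > 1/N) exactly when b/c exceeds

    C* = Σ_ij k_i p²_ij η_ij / (Σ_ij k_i p³_ij η_ij − Σ_ij k_i p_ij η_ij),

where the double sums run over ordered node pairs (the i = j terms
vanish because η_ii = 0).  The denominator can be negative — then no
finite positive b/c helps cooperation ("never favoured", e.g. complete
graphs) — or zero ("divergent", e.g. a cycle with N = 2k).

This module computes C* three ways:

* exactly, from the solved meeting-time table (O(N³)–O(N⁶) depending on
  sparsity of the pair system);
* via a mean-field approximation that trades the meeting-time solve for
  closed-form heterogeneity corrections built from ζ and the Δ terms;
* asymptotically for large heterogeneous networks, where only the sign
  of the edge sum Σ_{i<j} (k_i−k_j)(λ_i−λ_j) e_ij/(λ_i+λ_j) decides
  whether C* sits below, at, or above the mean degree ⟨k⟩.

It also builds update-rate profiles (λ_i = k_i^±γ and distribution
draws), maps C* to arbitrary two-player (R,S,T,P) games, and evaluates
the first-order weak-selection fixation probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coalescence import (
    CoalescenceTable,
    RateProfile,
    WalkOperators,
    solve_coalescence,
    step_matrices,
)
from .netio import Network

__all__ = [
    "GameParams",
    "CstarResult",
    "cstar_exact",
    "cstar_approx",
    "cstar_asymptotic",
    "correction_terms",
    "rate_profile",
    "general_game_condition",
    "rho_c_weak_selection",
]

# regimes
FINITE_POSITIVE = "finite_positive"
NEVER_FAVOURED = "never_favoured"
DIVERGENT = "divergent"

_DEN_TOL = 1e-9  # relative scale below which the denominator counts as zero


@dataclass(frozen=True)
class GameParams:
    """Donation-game parameters, with the general-game embedding.

    The donation game (cooperators pay c to give b to each neighbour)
    embeds in the general two-player payoff matrix as
    R = b − c, S = −c, T = b, P = 0.
    """

    b: float
    c: float
    delta: float = 0.0
    u: float = 0.0
    R: float | None = None
    S: float | None = None
    T: float | None = None
    P: float | None = None

    def __post_init__(self):
        if self.b <= 0 or self.c <= 0:
            raise ValueError("donation game needs b > 0 and c > 0")
        if self.delta < 0:
            raise ValueError("selection intensity must be non-negative")
        if not 0 <= self.u <= 1:
            raise ValueError("mutation probability must lie in [0, 1]")

    def as_general(self) -> tuple[float, float, float, float]:
        if None not in (self.R, self.S, self.T, self.P):
            return (self.R, self.S, self.T, self.P)
        return (self.b - self.c, -self.c, self.b, 0.0)


@dataclass(frozen=True)
class CstarResult:
    """Critical ratio with regime classification and component breakdown."""

    value: float
    regime: str
    numerator: float
    denominator: float
    method: str
    components: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        out = {
            "value": None if np.isnan(self.value) else self.value,
            "regime": self.regime,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "method": self.method,
        }
        out["components"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.components.items()
        }
        return out


def _classify(num: float, den: float) -> tuple[float, str]:
    scale = max(abs(num), 1.0)
    if abs(den) <= _DEN_TOL * scale:
        return float("nan"), DIVERGENT
    value = num / den
    if den < 0 < num:
        return value, NEVER_FAVOURED
    return value, FINITE_POSITIVE


def _weighted_sums(network: Network, walk: WalkOperators,
                   eta: np.ndarray) -> tuple[float, float, float]:
    """(Σ k_i p_ij η_ij, Σ k_i p²_ij η_ij, Σ k_i p³_ij η_ij) over ordered pairs."""
    k = network.degrees.astype(float)[:, None]
    s1 = float(np.sum(k * walk.p * eta))
    s2 = float(np.sum(k * walk.p2 * eta))
    s3 = float(np.sum(k * walk.p3 * eta))
    return s1, s2, s3


def zeta(network: Network, rates: RateProfile) -> float:
    """ζ = Σ_ij k_i k_j Λ / (N K² (λ_i + λ_j)), ordered pairs incl. i = j.

    Collapses to exactly 1/2 for identical rates.
    """
    k = network.degrees.astype(float)
    lam = rates.lam
    lsum = lam[:, None] + lam[None, :]
    kk = k[:, None] * k[None, :]
    return float(np.sum(kk / lsum) * rates.total
                 / (network.n * network.degree_sum ** 2))


def _delta_lambda_terms(network: Network, walk: WalkOperators,
                        rates: RateProfile) -> tuple[float, float]:
    k = network.degrees.astype(float)
    n, big_k, lam = network.n, network.degree_sum, rates.lam
    total = rates.total
    lsum = lam[:, None] + lam[None, :]
    pair_factor = 1.0 - 2.0 * total / (n * lsum)
    d1 = float(np.sum(k / (2 * big_k) * (1.0 - total / (n * lam)))
               + np.sum(k[:, None] / (2 * big_k) * walk.p * pair_factor))
    d2 = float(np.sum(k[:, None] / (2 * big_k) * (walk.p + walk.p2) * pair_factor))
    return d1, d2


def _eta_tilde(network: Network, walk: WalkOperators, rates: RateProfile,
               eta: np.ndarray, n_step: int) -> float:
    """η̃^(n+1) = Σ_ijl (k_i/K) p^(n)_ij [2λ_j/(λ_i+λ_j)] p_jl η_il."""
    k = network.degrees.astype(float)
    lam = rates.lam
    pn = {1: walk.p, 2: walk.p2, 3: walk.p3}[n_step]
    w = pn * (2.0 * lam[None, :] / (lam[:, None] + lam[None, :]))
    inner = w @ walk.p                       # Σ_j w_ij p_jl
    return float(np.sum((k[:, None] / network.degree_sum) * inner * eta))


def edge_heterogeneity_sum(network: Network, rates: RateProfile) -> float:
    """Σ_{i<j} (k_i − k_j)(λ_i − λ_j) e_ij / (λ_i + λ_j).

    Negative whenever higher-degree nodes carry lower update rates on
    every edge; its sign decides whether C* falls below or above ⟨k⟩.
    """
    k = network.degrees.astype(float)
    lam = rates.lam
    total = 0.0
    for i, j in network.edges:
        total += (k[i] - k[j]) * (lam[i] - lam[j]) / (lam[i] + lam[j])
    return total


def correction_terms(network: Network, rates: RateProfile,
                     table: CoalescenceTable | None = None) -> dict:
    """All heterogeneity corrections of the mean-field C* formula.

    The η̃ differences are computed exactly from the solved meeting-time
    table (Δ_{η̃(n)} = η̃^(n) − η^(n)); a table is solved on demand if
    none is passed.  All four assembled terms (and every Δ) vanish
    identically when the update rates are identical.
    """
    walk = step_matrices(network)
    k = network.degrees.astype(float)
    n, big_k = network.n, network.degree_sum
    sum_k2 = float(np.sum(k * k))
    mean_k = network.mean_degree
    d1, d2 = _delta_lambda_terms(network, walk, rates)
    out = {"zeta": zeta(network, rates),
           "delta_lambda1": d1, "delta_lambda2": d2}

    if table is None:
        table = solve_coalescence(network, rates)
    eta = table.eta
    s1, s2, s3 = _weighted_sums(network, walk, eta)
    eta_n = {1: s1 / big_k, 2: s2 / big_k, 3: s3 / big_k}
    eta_bar = table.mean_pairwise()
    d_inf = eta_bar / big_k**2 * edge_heterogeneity_sum(network, rates)
    d_eta2 = _eta_tilde(network, walk, rates, eta, 1) - eta_n[2]
    d_eta3 = _eta_tilde(network, walk, rates, eta, 2) - eta_n[3]
    out.update({
        "eta1": eta_n[1], "eta2": eta_n[2], "eta3": eta_n[3],
        "eta_tilde2": d_eta2 + eta_n[2], "eta_tilde3": d_eta3 + eta_n[3],
        "eta_ii_plus": rates.total / (2 * n * rates.lam)
                       + (walk.p * eta).sum(axis=1),
    })

    out.update({
        "eta_bar": eta_bar,
        "delta_eta_inf": d_inf,
        "delta_eta2": d_eta2,
        "delta_eta3": d_eta3,
        "delta_eta_n": -d_eta2 + big_k**2 / sum_k2 * d_inf,
        "delta_eta_d": -d_eta2 - d_eta3 + big_k * n / sum_k2 * d_inf,
        "mean_degree": mean_k,
        "second_moment": network.second_moment,
    })
    return out


def cstar_exact(network: Network, rates: RateProfile,
                table: CoalescenceTable | None = None,
                with_components: bool = True) -> CstarResult:
    """Critical ratio from the exact meeting-time solve.

    A pre-computed :class:`CoalescenceTable` may be passed to avoid
    re-solving (the optimiser does this every iteration).
    """
    if table is None:
        table = solve_coalescence(network, rates)
    walk = step_matrices(network)
    s1, s2, s3 = _weighted_sums(network, walk, table.eta)
    num, den = s2, s3 - s1
    value, regime = _classify(num, den)
    components = correction_terms(network, rates, table) if with_components else {}
    return CstarResult(value=value, regime=regime, numerator=num,
                       denominator=den, method="exact", components=components)


def cstar_approx(network: Network, rates: RateProfile,
                 eta_bar_mode: str = "from_solve",
                 eta_bar: float | None = None) -> CstarResult:
    """Mean-field critical ratio (no meeting-time solve needed).

        C* ≈ (N⟨k⟩²ζ/⟨k²⟩ − 1 + Δ_{λ(1)} + Δ_{η̃_n})
             / (N⟨k⟩ζ/⟨k²⟩ − 1 + Δ_{λ(2)} + Δ_{η̃_d})

    The λ corrections are exact; the η̃ corrections are estimated from
    the single edge sum Δ_{η̃(∞)} scaled by the mean meeting time η̄.
    With ``eta_bar_mode="supplied"`` the caller provides η̄ (> 0) and the
    whole computation is dominated by the p², p³ matrix products;
    ``"from_solve"`` takes η̄ from an exact solve.
    """
    if eta_bar_mode == "supplied":
        if eta_bar is None or eta_bar <= 0:
            raise ValueError("supplied eta_bar must be positive")
    elif eta_bar_mode == "from_solve":
        eta_bar = solve_coalescence(network, rates).mean_pairwise()
    else:
        raise ValueError(f"unknown eta_bar_mode {eta_bar_mode!r}")

    walk = step_matrices(network)
    k = network.degrees.astype(float)
    n, big_k = network.n, network.degree_sum
    mean_k, k2 = network.mean_degree, network.second_moment
    sum_k2 = float(np.sum(k * k))
    z = zeta(network, rates)
    d1, d2 = _delta_lambda_terms(network, walk, rates)
    d_inf = eta_bar / big_k**2 * edge_heterogeneity_sum(network, rates)
    d_eta2 = n * d_inf / mean_k
    d_eta3 = n * d_inf / mean_k**2
    d_eta_n = -d_eta2 + big_k**2 / sum_k2 * d_inf
    d_eta_d = -d_eta2 - d_eta3 + big_k * n / sum_k2 * d_inf

    num = n * mean_k**2 * z / k2 - 1.0 + d1 + d_eta_n
    den = n * mean_k * z / k2 - 1.0 + d2 + d_eta_d
    value, regime = _classify(num, den)
    return CstarResult(
        value=value, regime=regime, numerator=num, denominator=den,
        method="approx",
        components={
            "zeta": z, "delta_lambda1": d1, "delta_lambda2": d2,
            "delta_eta_inf": d_inf, "delta_eta2": d_eta2, "delta_eta3": d_eta3,
            "delta_eta_n": d_eta_n, "delta_eta_d": d_eta_d,
            "eta_bar": eta_bar, "mean_degree": mean_k, "second_moment": k2,
        },
    )


def cstar_asymptotic(network: Network, rates: RateProfile,
                     eta_bar: float) -> CstarResult:
    """Large-heterogeneous-network critical ratio and its ⟨k⟩ comparison.

        C* ≈ ⟨k⟩ + ⟨k⟩²⟨k²⟩ Δ_{η̃(∞)}
                   / (⟨k⟩³ζ + (⟨k⟩³ − ⟨k⟩⟨k²⟩ − ⟨k²⟩) Δ_{η̃(∞)})

    The ``classification`` component is "below"/"approx"/"above" ⟨k⟩
    according to the sign of Δ_{η̃(∞)}; the sign — hence the
    classification — does not depend on the magnitude of η̄.
    """
    if eta_bar <= 0:
        raise ValueError("eta_bar must be positive")
    mean_k, k2 = network.mean_degree, network.second_moment
    big_k = network.degree_sum
    z = zeta(network, rates)
    edge_sum = edge_heterogeneity_sum(network, rates)
    d_inf = eta_bar / big_k**2 * edge_sum
    den = mean_k**3 * z + (mean_k**3 - mean_k * k2 - k2) * d_inf
    value = mean_k + mean_k**2 * k2 * d_inf / den
    if abs(edge_sum) <= 1e-12 * max(1.0, big_k):
        cls = "approx"
    else:
        cls = "below" if edge_sum < 0 else "above"
    return CstarResult(
        value=value, regime=FINITE_POSITIVE,
        numerator=mean_k * den + mean_k**2 * k2 * d_inf, denominator=den,
        method="asymptotic",
        components={"zeta": z, "delta_eta_inf": d_inf, "eta_bar": eta_bar,
                    "edge_sum": edge_sum, "mean_degree": mean_k,
                    "second_moment": k2, "classification": cls},
    )


# ---------------------------------------------------------------------------
# Rate profiles
# ---------------------------------------------------------------------------

_DIST_DEFAULTS = {
    "uniform": {"low": 0.5, "high": 1.5},
    "normal": {"mean": 1.0, "sd": 0.25, "floor": 0.05},
    "exponential": {"mean": 1.0},
    "power_law": {"exponent": 2.5, "minimum": 0.1},
}


def rate_profile(network: Network, scheme: str = "identical", *,
                 gamma: float = 1.0, sign: int = -1,
                 distribution: str | None = None, seed: int = 0,
                 **params) -> RateProfile:
    """Build an update-rate vector from a named scheme.

    Schemes
    -------
    ``identical``
        λ_i = 1 for every node.
    ``power``
        λ_i = k_i^{±γ}; ``sign=-1`` (default) gives the hub-slowing rule
        λ_i = 1/k_i^γ, ``sign=+1`` the hub-accelerating λ_i = k_i^γ.
    ``distribution``
        i.i.d. draws from ``uniform``, ``normal`` (truncated strictly
        positive by resampling below the floor), ``exponential`` or
        ``power_law`` (Pareto with the given tail exponent and minimum).
    """
    n = network.n
    if scheme == "identical":
        return RateProfile(np.ones(n))
    if scheme == "power":
        if gamma < 0:
            raise ValueError("gamma must be non-negative")
        if sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        k = network.degrees.astype(float)
        return RateProfile(k ** (sign * gamma))
    if scheme == "distribution":
        if distribution not in _DIST_DEFAULTS:
            raise ValueError(f"unknown distribution {distribution!r}")
        opts = {**_DIST_DEFAULTS[distribution], **params}
        rng = np.random.default_rng(seed)
        if distribution == "uniform":
            low, high = opts["low"], opts["high"]
            if not 0 < low < high:
                raise ValueError("uniform bounds must satisfy 0 < low < high")
            lam = rng.uniform(low, high, size=n)
        elif distribution == "normal":
            if opts["sd"] <= 0 or opts["floor"] <= 0:
                raise ValueError("normal needs sd > 0 and floor > 0")
            lam = rng.normal(opts["mean"], opts["sd"], size=n)
            while np.any(lam < opts["floor"]):   # resample the truncated tail
                bad = lam < opts["floor"]
                lam[bad] = rng.normal(opts["mean"], opts["sd"], size=bad.sum())
        elif distribution == "exponential":
            if opts["mean"] <= 0:
                raise ValueError("exponential mean must be positive")
            lam = rng.exponential(opts["mean"], size=n)
            while np.any(lam <= 0):  # guard against underflow to 0
                bad = lam <= 0
                lam[bad] = rng.exponential(opts["mean"], size=bad.sum())
        else:  # power_law: classical Pareto, pdf ∝ x^-(exponent) above minimum
            a = opts["exponent"] - 1.0
            if a <= 0 or opts["minimum"] <= 0:
                raise ValueError("power_law needs exponent > 1 and minimum > 0")
            lam = opts["minimum"] * (1.0 + rng.pareto(a, size=n))
        return RateProfile(lam)
    raise ValueError(f"unknown scheme {scheme!r}")


def parse_rate_spec(network: Network, spec: str, seed: int = 0) -> RateProfile:
    """Parse compact rate specifications like ``scheme:power:-1`` used by
    the CLI: ``scheme:identical``, ``scheme:power:<±γ>``,
    ``scheme:<distribution>`` or a path to a one-column CSV / JSON list."""
    if spec.startswith("scheme:"):
        parts = spec.split(":")[1:]
        name = parts[0]
        if name == "identical":
            return rate_profile(network, "identical")
        if name == "power":
            signed = float(parts[1]) if len(parts) > 1 else -1.0
            sign = -1 if signed < 0 else 1
            return rate_profile(network, "power", gamma=abs(signed), sign=sign)
        return rate_profile(network, "distribution", distribution=name, seed=seed)
    import json as _json
    from pathlib import Path as _Path

    text = _Path(spec).read_text()
    if spec.endswith(".json"):
        data = _json.loads(text)
        lam = np.array([data[str(i)] for i in range(network.n)], dtype=float) \
            if isinstance(data, dict) else np.asarray(data, dtype=float)
    else:
        lam = np.array([float(x) for x in text.split()], dtype=float)
    return RateProfile(lam)


# ---------------------------------------------------------------------------
# General games and weak-selection fixation
# ---------------------------------------------------------------------------

def general_game_condition(R: float, S: float, T: float, P: float,
                           cstar: float) -> tuple[bool, float]:
    """Cooperation-favoured test for a general (R,S,T,P) two-player game.

    Returns ``(favoured, R_threshold)`` with
    R* = P + (T − S)(C* − 1)/(C* + 1); cooperation is favoured over
    defection when R > R*.  For the donation game this reduces exactly
    to b/c > C*.
    """
    if not np.isfinite(cstar):
        raise ValueError("C* must be finite")
    if abs(cstar + 1.0) < 1e-12:
        raise ZeroDivisionError("threshold undefined at C* = -1")
    threshold = P + (T - S) * (cstar - 1.0) / (cstar + 1.0)
    return bool(R > threshold), float(threshold)


def rho_c_weak_selection(network: Network, rates: RateProfile,
                         b: float, c: float, delta: float,
                         table: CoalescenceTable | None = None) -> float:
    """First-order fixation probability of a lone cooperator.

        ρ_C = 1/N + δ/(Λ Σ_i k_i/λ_i) ·
              [ −c Σ k_i p²_ij η_ij + b (Σ k_i p³_ij η_ij − Σ k_i p_ij η_ij) ]

    The bracket vanishes exactly at b/c = C*, and at δ = 0 the neutral
    value 1/N is returned.
    """
    if delta < 0:
        raise ValueError("selection intensity must be non-negative")
    if table is None:
        table = solve_coalescence(network, rates)
    walk = step_matrices(network)
    s1, s2, s3 = _weighted_sums(network, walk, table.eta)
    k_over_lam = float(np.sum(network.degrees / rates.lam))
    bracket = -c * s2 + b * (s3 - s1)
    return 1.0 / network.n + delta * bracket / (rates.total * k_over_lam)
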