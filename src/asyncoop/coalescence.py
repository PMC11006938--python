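"""Random-walk operators, coalescence times and reproductive values.

The coalescence time η_ij is the expected meeting time of two random
walkers started at nodes i and j, each stepping when its node fires —
node i fires with probability λ_i/Λ per update event.  On a connected
graph the η_ij (i ≠ j) satisfy the linear recurrence

    η_ij = Λ / (N (λ_i + λ_j))
           + Σ_k [λ_i/(λ_i+λ_j)] p_ik η_kj
           + Σ_k [λ_j/(λ_i+λ_j)] p_jk η_ki,        η_ii = 0,

with p_ij = e_ij / k_i the one-step random-walk matrix.  These meeting
times are the only structure-dependent input to the critical
benefit-to-cost ratio, which is why this module sits underneath both the
critical-ratio calculator and the update-rate optimiser.

The system has N(N−1)/2 unknowns (η is symmetric) and O(k_i + k_j)
couplings per equation, so it is assembled as a sparse matrix and solved
with a sparse LU factorisation by default; the factorisation is reused
by the optimiser for its N gradient right-hand sides.  A Jacobi-style
fixed-point iteration of the recurrence is available for large N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .netio import Network

__all__ = [
    "WalkOperators",
    "RateProfile",
    "CoalescenceTable",
    "ReproductiveValues",
    "step_matrices",
    "solve_coalescence",
    "solve_coalescence_identical",
    "reproductive_values",
    "pair_index",
    "CoalescenceSystem",
]


class SolverError(RuntimeError):
    """Numerical failure in the coalescence solve."""


@dataclass(frozen=True)
class WalkOperators:
    """One-, two- and three-step random-walk probability matrices."""

    p: np.ndarray
    p2: np.ndarray
    p3: np.ndarray

    def __post_init__(self):
        for m in (self.p, self.p2, self.p3):
            rows = m.sum(axis=1)
            if np.max(np.abs(rows - 1.0)) > 1e-12:
                raise SolverError("walk matrix rows do not sum to 1")
            if np.min(m) < 0:
                raise SolverError("negative walk probability")


@dataclass(frozen=True)
class RateProfile:
    """Per-node strategy-update rates λ_i (> 0) with total Λ = Σ λ_i."""

    lam: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        object.__setattr__(self, "lam", lam)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("rate profile must be a 1-D vector of length >= 2")
        if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
            raise ValueError("update rates must be positive and finite")

    @property
    def total(self) -> float:
        """Λ, the total rate of update events."""
        return float(self.lam.sum())

    @property
    def n(self) -> int:
        return self.lam.size

    @classmethod
    def identical(cls, n: int) -> "RateProfile":
        return cls(np.ones(n))


@dataclass(frozen=True)
class CoalescenceTable:
    """Pairwise meeting times η_ij with the recurrence residual."""

    eta: np.ndarray
    residual: float

    def pair_vector(self) -> np.ndarray:
        """η_ij for unordered pairs i<j in row-major order."""
        n = self.eta.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        return self.eta[iu, ju]

    def mean_pairwise(self) -> float:
        """η̄, the mean of η_ij over unordered pairs."""
        return float(self.pair_vector().mean())

    def to_csv(self, path) -> None:
        n = self.eta.shape[0]
        with open(path, "w") as fh:
            fh.write("i,j,eta\n")
            for i in range(n):
                for j in range(i + 1, n):
                    fh.write(f"{i},{j},{self.eta[i, j]!r}\n")


@dataclass(frozen=True)
class ReproductiveValues:
    """π_i ∝ k_i/λ_i, normalised to Σ π_i = 1.

    π_i weights node i's contribution to the future composition of the
    population under neutral drift; the weighted cooperator frequency
    x̂ = Σ π_i x_i is a martingale of the neutral process.
    """

    pi: np.ndarray

    def __post_init__(self):
        if np.any(self.pi <= 0) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("reproductive values must be positive and sum to 1")


def step_matrices(network: Network) -> WalkOperators:
    """p_ij = e_ij/k_i and its second and third matrix powers."""
    a = network.adjacency
    p = a / a.sum(axis=1, keepdims=True)
    p2 = p @ p
    return WalkOperators(p=p, p2=p2, p3=p2 @ p)


def pair_index(n: int) -> dict[tuple[int, int], int]:
    """Row-major index of unordered pairs (i<j) into the pair vector."""
    idx = {}
    t = 0
    for i in range(n):
        for j in range(i + 1, n):
            idx[(i, j)] = t
            t += 1
    return idx


class CoalescenceSystem:
    """Assembled sparse pair system A η = b for the meeting-time recurrence.

    Row (i,j):  (λ_i+λ_j) η_ij − λ_i Σ_k p_ik η_kj − λ_j Σ_k p_jk η_ki = Λ/N.

    The LU factorisation is cached so the optimiser can solve the N
    derivative systems (same operator, new right-hand sides) at the cost
    of back-substitutions only.
    """

    def __init__(self, network: Network, rates: RateProfile):
        if rates.n != network.n:
            raise ValueError("rate profile length does not match network size")
        self.network = network
        self.rates = rates
        n = network.n
        lam = rates.lam
        nbrs = network.neighbor_lists()
        k = network.degrees.astype(float)
        idx = pair_index(n)
        rows, cols, vals = [], [], []
        for (i, j), t in idx.items():
            rows.append(t)
            cols.append(t)
            vals.append(lam[i] + lam[j])
            for u in nbrs[i]:
                if u == j:
                    continue  # η_jj = 0
                s = idx[(min(u, j), max(u, j))]
                rows.append(t)
                cols.append(s)
                vals.append(-lam[i] / k[i])
            for u in nbrs[j]:
                if u == i:
                    continue
                s = idx[(min(u, i), max(u, i))]
                rows.append(t)
                cols.append(s)
                vals.append(-lam[j] / k[j])
        m = n * (n - 1) // 2
        self.n_pairs = m
        self.matrix = sp.csc_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(m, m))
        )
        self.rhs = np.full(m, rates.total / n)
        self._lu = None

    @property
    def lu(self):
        if self._lu is None:
            try:
                # the pair system is structurally symmetric; the AT+A
                # minimum-degree ordering cuts fill (and factor time)
                # several-fold relative to the COLAMD default
                self._lu = spla.splu(self.matrix, permc_spec="MMD_AT_PLUS_A")
            except RuntimeError as exc:  # pragma: no cover - connected graphs
                raise SolverError(
                    f"coalescence system factorisation failed: {exc}"
                ) from exc
        return self._lu

    def solve(self) -> np.ndarray:
        """Pair vector of η (i<j, row-major)."""
        h = self.lu.solve(self.rhs)
        if not np.all(np.isfinite(h)):
            raise SolverError("non-finite coalescence times")
        return h

    def solve_rhs(self, rhs: np.ndarray) -> np.ndarray:
        """Solve with an arbitrary (possibly multi-column) right-hand side."""
        return self.lu.solve(rhs)

    def pair_to_matrix(self, h: np.ndarray) -> np.ndarray:
        n = self.network.n
        eta = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        eta[iu, ju] = h
        eta[ju, iu] = h
        return eta


def _recurrence_rhs(network: Network, rates: RateProfile,
                    eta: np.ndarray) -> np.ndarray:
    """One application of the meeting-time recurrence to η (off-diagonal)."""
    lam = rates.lam
    p = step_matrices(network).p
    ph = p @ eta                       # (PH)_ij = Σ_k p_ik η_kj
    li = lam[:, None]
    lj = lam[None, :]
    out = (rates.total / (network.n * (li + lj))
           + (li * ph + lj * ph.T) / (li + lj))
    np.fill_diagonal(out, 0.0)
    return out


def residual_norm(network: Network, rates: RateProfile, eta: np.ndarray) -> float:
    """Max absolute violation of the recurrence by the table ``eta``."""
    return float(np.max(np.abs(eta - _recurrence_rhs(network, rates, eta))))


_DIRECT_MAX_NODES = 160  # beyond this, LU fill makes conjugate gradients faster


def solve_coalescence(network: Network, rates: RateProfile,
                      method: str = "auto", tol: float = 1e-10,
                      max_iter: int = 200_000) -> CoalescenceTable:
    """Solve the meeting-time system for all unordered node pairs.

    Methods
    -------
    ``"direct"``
        Sparse LU factorisation of the pair system; exact up to
        round-off and reusable for many right-hand sides.
    ``"cg"``
        Conjugate gradients on the row-rescaled system: scaling row
        (i,j) by k_i k_j/(λ_i λ_j) makes the pair matrix symmetric
        (positive definite), which CG solves in a few hundred sparse
        products even for thousands of pair unknowns.
    ``"iterative"``
        Plain fixed-point sweeps of the recurrence (a deliberately
        simple independent path, used for cross-checks).
    ``"auto"``
        Direct up to 160 nodes, CG beyond.

    The returned table satisfies the recurrence to ``tol`` relative to
    the magnitude of the largest meeting time.
    """
    if rates.n != network.n:
        raise ValueError("rate profile length does not match network size")
    if method == "auto":
        method = "direct" if network.n <= _DIRECT_MAX_NODES else "cg"
    if method == "direct":
        system = CoalescenceSystem(network, rates)
        eta = system.pair_to_matrix(system.solve())
    elif method == "cg":
        system = CoalescenceSystem(network, rates)
        k = network.degrees.astype(float)
        lam = rates.lam
        iu, ju = np.triu_indices(network.n, k=1)
        s = k[iu] * k[ju] / (lam[iu] * lam[ju])
        sym = sp.diags(s) @ system.matrix.tocsr()
        precond = sp.diags(1.0 / sym.diagonal())
        h, info = spla.cg(sym, s * system.rhs, rtol=1e-14, atol=0.0,
                          maxiter=max_iter, M=precond)
        if info != 0:
            raise SolverError(f"conjugate gradients did not converge ({info=})")
        eta = system.pair_to_matrix(h)
    elif method == "iterative":
        eta = np.zeros((network.n, network.n))
        for _ in range(max_iter):
            new = _recurrence_rhs(network, rates, eta)
            if np.max(np.abs(new - eta)) <= tol:
                eta = new
                break
            eta = new
        else:
            raise SolverError(
                f"fixed-point iteration did not converge in {max_iter} sweeps"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    res = residual_norm(network, rates, eta)
    # the acceptance gate is relative to the size of the table: extreme
    # rate ratios legitimately produce meeting times of order 1e4 and more
    scale = max(1.0, float(np.max(np.abs(eta))))
    if method in ("direct", "cg") and res > tol * scale:
        raise SolverError(
            f"{method} solve residual {res:.3e} exceeds {tol:.1e} x scale {scale:.3e}"
        )
    return CoalescenceTable(eta=eta, residual=res)


def solve_coalescence_identical(network: Network) -> CoalescenceTable:
    """Independent dense solver for the identical-rate special case.

    With λ_i = λ for all i the recurrence collapses to
    η_ij = 1/2 + ½ Σ_k p_ik η_kj + ½ Σ_k p_jk η_ki, which is assembled
    here as a dense system over ordered pairs — a deliberately different
    code path used to cross-check the general solver.
    """
    n = network.n
    p = step_matrices(network).p
    # unknowns: full off-diagonal matrix entries, symmetry not imposed
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    pos = {ij: t for t, ij in enumerate(off)}
    m = len(off)
    a = np.eye(m)
    b = np.full(m, 0.5)
    for (i, j), t in pos.items():
        for u in range(n):
            if p[i, u] and u != j:
                a[t, pos[(u, j)]] -= 0.5 * p[i, u]
            if p[j, u] and u != i:
                a[t, pos[(u, i)]] -= 0.5 * p[j, u]
    h = np.linalg.solve(a, b)
    eta = np.zeros((n, n))
    for (i, j), t in pos.items():
        eta[i, j] = h[t]
    eta = 0.5 * (eta + eta.T)  # symmetric up to round-off
    return CoalescenceTable(
        eta=eta,
        residual=residual_norm(network, RateProfile.identical(n), eta),
    )


def reproductive_values(network: Network, rates: RateProfile) -> ReproductiveValues:
    """π_i = (k_i/λ_i) / Σ_l (k_l/λ_l)."""
    if rates.n != network.n:
        raise ValueError("rate profile length does not match network size")
    w = network.degrees / rates.lam
    return ReproductiveValues(pi=w / w.sum())
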