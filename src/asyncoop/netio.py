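"""Network containers, generators and edge-list I/O.

Every downstream quantity in this package (coalescence times, critical
ratios, simulations) is defined on an undirected, unweighted, simple,
connected graph.  This module is the single place where such graphs are
created and validated; all generators are deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "NetworkError",
    "GenerationError",
    "FormatError",
    "generate_network",
    "read_edge_list",
    "write_edge_list",
    "MODELS",
]

_CONNECT_RETRIES = 1000


class NetworkError(ValueError):
    """Invalid network input or parameters."""


class GenerationError(NetworkError):
    """A random generator failed to produce a valid (connected) graph."""


class FormatError(NetworkError):
    """Malformed edge-list file."""


@dataclass(frozen=True)
class Network:
    """Undirected simple connected graph with degree bookkeeping.

    Nodes are 0-based contiguous integers.  ``labels`` optionally maps the
    internal index back to the string label it carried in an input file.
    """

    n: int
    edges: tuple[tuple[int, int], ...]
    labels: tuple[str, ...] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        validate_network(self)

    # -- derived quantities -------------------------------------------------
    @property
    def adjacency(self) -> np.ndarray:
        """Dense adjacency indicator e_ij (float, symmetric, zero diagonal)."""
        a = np.zeros((self.n, self.n))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    @property
    def degrees(self) -> np.ndarray:
        """k_i = number of neighbours of node i."""
        k = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            k[i] += 1
            k[j] += 1
        return k

    @property
    def degree_sum(self) -> int:
        """K = sum of all degrees = 2 |edges|."""
        return 2 * len(self.edges)

    @property
    def mean_degree(self) -> float:
        return self.degree_sum / self.n

    @property
    def second_moment(self) -> float:
        """⟨k²⟩, the second moment of the degree distribution."""
        k = self.degrees.astype(float)
        return float(np.mean(k * k))

    def neighbor_lists(self) -> list[np.ndarray]:
        nbrs: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [np.array(sorted(v), dtype=np.int64) for v in nbrs]

    def csr_neighbors(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) CSR adjacency for the simulation kernels."""
        lists = self.neighbor_lists()
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        for i, v in enumerate(lists):
            indptr[i + 1] = indptr[i] + len(v)
        indices = np.concatenate(lists) if lists else np.empty(0, dtype=np.int64)
        return indptr, indices.astype(np.int64)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g


def _canonical_edges(edges) -> tuple[tuple[int, int], ...]:
    return tuple(sorted((min(i, j), max(i, j)) for i, j in edges))


def from_networkx(g: nx.Graph, meta: dict | None = None) -> Network:
    """Relabel an arbitrary networkx graph to contiguous ints and wrap it."""
    nodes = list(g.nodes())
    index = {u: i for i, u in enumerate(nodes)}
    edges = _canonical_edges((index[u], index[v]) for u, v in g.edges() if u != v)
    return Network(n=len(nodes), edges=edges, meta=meta or {})


def validate_network(net: Network) -> None:
    """Check all structural invariants; raise NetworkError on violation."""
    if net.n < 2:
        raise NetworkError(f"need at least 2 nodes, got {net.n}")
    seen = set()
    for i, j in net.edges:
        if i == j:
            raise NetworkError(f"self-loop at node {i}")
        if not (0 <= i < net.n and 0 <= j < net.n):
            raise NetworkError(f"edge ({i},{j}) out of range for n={net.n}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise NetworkError(f"duplicate edge {key}")
        seen.add(key)
    k = net.degrees
    if np.any(k < 1):
        isolated = np.flatnonzero(k < 1).tolist()
        raise NetworkError(f"isolated nodes: {isolated}")
    g = net.to_networkx()
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise NetworkError(
            f"graph is disconnected: {len(comps)} components, sizes "
            f"{[len(c) for c in comps]}"
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _triangular_torus(rows: int, cols: int) -> list[tuple[int, int]]:
    # periodic triangular lattice: every node has exactly 6 neighbours
    def idx(r, c):
        return (r % rows) * cols + (c % cols)

    edges = set()
    for r in range(rows):
        for c in range(cols):
            u = idx(r, c)
            for dr, dc in ((0, 1), (1, 0), (1, 1)):
                v = idx(r + dr, c + dc)
                if u != v:
                    edges.add((min(u, v), max(u, v)))
    return sorted(edges)


def _uniform_attachment(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    # growth without preferential attachment: each new node links to m
    # uniformly chosen distinct existing nodes
    if n < m + 1:
        raise NetworkError(f"uniform_attachment needs n > m (n={n}, m={m})")
    edges = [(i, j) for i in range(m + 1) for j in range(i + 1, m + 1)]
    for new in range(m + 1, n):
        targets = rng.choice(new, size=m, replace=False)
        edges.extend((int(t), new) for t in targets)
    return edges


def _retry_connected(build, retries: int = _CONNECT_RETRIES) -> nx.Graph:
    for _ in range(retries):
        g = build()
        if nx.is_connected(g):
            return g
    raise GenerationError(
        f"failed to obtain a connected graph within {retries} attempts"
    )


MODELS = (
    "lattice",
    "erdos_renyi",
    "small_world",
    "scale_free_ba",
    "random_regular",
    "configuration",
    "uniform_attachment",
    "double_star",
    "cycle",
    "complete",
)


def generate_network(model: str, seed: int = 0, **params) -> Network:
    """Generate a connected :class:`Network` from a named random-graph model.

    Parameters
    ----------
    model:
        One of :data:`MODELS`.
    seed:
        Seed for all randomness; equal seeds give bit-identical networks.
    params:
        Model-specific parameters, e.g. ``n``, ``m`` (BA attachment number,
        default 3 so ⟨k⟩ ≈ 6), ``p`` (ER edge / small-world rewiring
        probability), ``k`` (regular degree / small-world ring degree),
        ``rows``/``cols`` (triangular-torus lattice), ``leaves`` (double
        star), ``degree_sequence`` (configuration model).
    """
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    meta = {"model": model, "seed": seed, "params": dict(params)}

    if model == "lattice":
        rows = int(params.pop("rows", 7))
        cols = int(params.pop("cols", 14))
        if rows < 3 or cols < 3:
            raise NetworkError("lattice torus needs rows, cols >= 3")
        edges = _triangular_torus(rows, cols)
        return Network(rows * cols, _canonical_edges(edges), meta=meta)

    if model == "cycle":
        n = int(params.pop("n"))
        if n < 3:
            raise NetworkError("cycle needs n >= 3")
        edges = [(i, (i + 1) % n) for i in range(n)]
        return Network(n, _canonical_edges(edges), meta=meta)

    if model == "complete":
        n = int(params.pop("n"))
        if n < 2:
            raise NetworkError("complete graph needs n >= 2")
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
        return Network(n, _canonical_edges(edges), meta=meta)

    if model == "double_star":
        leaves = int(params.pop("leaves", params.pop("m", 5)))
        if leaves < 1:
            raise NetworkError("double_star needs >= 1 leaf per hub")
        # hubs 0 and 1 joined; hub 0 gets leaves 2..m+1, hub 1 the rest
        edges = [(0, 1)]
        edges += [(0, 2 + i) for i in range(leaves)]
        edges += [(1, 2 + leaves + i) for i in range(leaves)]
        return Network(2 * leaves + 2, _canonical_edges(edges), meta=meta)

    if model == "scale_free_ba":
        n = int(params.pop("n"))
        m = int(params.pop("m", 3))
        if not 1 <= m < n:
            raise NetworkError(f"BA needs 1 <= m < n (m={m}, n={n})")
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
        return from_networkx(g, meta)

    if model == "erdos_renyi":
        n = int(params.pop("n"))
        if "p" in params:
            p = float(params.pop("p"))
        else:
            p = float(params.pop("mean_degree", 6)) / (n - 1)
        if not 0 < p <= 1:
            raise NetworkError(f"ER probability out of range: {p}")
        g = _retry_connected(
            lambda: nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        )
        return from_networkx(g, meta)

    if model == "small_world":
        n = int(params.pop("n"))
        k = int(params.pop("k", 6))
        p = float(params.pop("p", 0.7))
        if k % 2 or k >= n:
            raise NetworkError(f"small_world ring degree must be even and < n, got {k}")
        g = _retry_connected(
            lambda: nx.watts_strogatz_graph(n, k, p, seed=int(rng.integers(0, 2**31 - 1)))
        )
        return from_networkx(g, meta)

    if model == "random_regular":
        n = int(params.pop("n"))
        k = int(params.pop("k", 6))
        if (n * k) % 2 or k >= n:
            raise NetworkError(f"random_regular infeasible: n={n}, k={k}")
        g = _retry_connected(
            lambda: nx.random_regular_graph(k, n, seed=int(rng.integers(0, 2**31 - 1)))
        )
        return from_networkx(g, meta)

    if model == "configuration":
        seq = params.pop("degree_sequence", None)
        if seq is None:
            n = int(params.pop("n"))
            exponent = float(params.pop("exponent", 2.5))
            k_min = int(params.pop("k_min", 3))
            seq = _powerlaw_degree_sequence(n, exponent, k_min, rng)
        seq = [int(d) for d in seq]
        if sum(seq) % 2:
            raise NetworkError("configuration model degree sum must be even")

        def build():
            s = int(rng.integers(0, 2**31 - 1))
            g = nx.configuration_model(seq, seed=s)
            g = nx.Graph(g)  # collapse multi-edges
            g.remove_edges_from(nx.selfloop_edges(g))
            return g

        g = _retry_connected(build)
        return from_networkx(g, meta)

    if model == "uniform_attachment":
        n = int(params.pop("n"))
        m = int(params.pop("m", 3))
        edges = _uniform_attachment(n, m, rng)
        return Network(n, _canonical_edges(edges), meta=meta)

    raise NetworkError(f"unknown model {model!r}; choose from {MODELS}")


def _powerlaw_degree_sequence(n, exponent, k_min, rng):
    for _ in range(_CONNECT_RETRIES):
        u = rng.random(n)
        seq = np.floor(k_min * (1 - u) ** (-1.0 / (exponent - 1))).astype(int)
        seq = np.minimum(seq, n - 1)
        if seq.sum() % 2 == 0:
            return seq.tolist()
    raise GenerationError("could not draw an even-sum degree sequence")


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def read_edge_list(path, dialect: str = "whitespace") -> Network:
    """Read a two-column edge list; labels are arbitrary strings.

    Labels are mapped to 0-based indices in first-appearance order, except
    when the labels are exactly the decimal integers 0..n-1, in which case
    their numeric values are used directly (so written files round-trip to
    an index-identical graph).  Duplicate edges are collapsed; self-loops
    raise :class:`FormatError`.
    """
    sep = "," if dialect == "csv" else None
    labels: dict[str, int] = {}
    edges = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in (line.split(sep) if sep else line.split())]
        parts = [p for p in parts if p]
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two labels, got {parts!r}")
        a, b = parts
        if a == b:
            raise FormatError(f"{path}:{lineno}: self-loop on {a!r}")
        for lab in (a, b):
            if lab not in labels:
                labels[lab] = len(labels)
        i, j = labels[a], labels[b]
        edges.append((min(i, j), max(i, j)))
    if not edges:
        raise FormatError(f"{path}: no edges found")
    n = len(labels)
    if all(lab.isdigit() for lab in labels) and \
            sorted(int(lab) for lab in labels) == list(range(n)):
        remap = {idx: int(lab) for lab, idx in labels.items()}
        edges = [(remap[i], remap[j]) for i, j in edges]
        names = tuple(str(i) for i in range(n))
    else:
        names = tuple(sorted(labels, key=labels.get))
    return Network(n, _canonical_edges(set(edges)), labels=names,
                   meta={"source": str(path)})


def write_edge_list(network: Network, path, dialect: str = "whitespace",
                    sidecar: bool = False) -> None:
    """Write one edge per line; round-trips through :func:`read_edge_list`.

    Labels, if present, are used; otherwise indices are written.  With
    ``sidecar=True`` a JSON provenance file ``<path>.json`` is written too.
    """
    sep = "," if dialect == "csv" else " "
    lab = network.labels or tuple(str(i) for i in range(network.n))
    path = Path(path)
    lines = [f"{lab[i]}{sep}{lab[j]}" for i, j in network.edges]
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        Path(str(path) + ".json").write_text(
            json.dumps({"n": network.n, **network.meta}, indent=1, default=str) + "\n"
        )
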