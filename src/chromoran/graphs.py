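"""Colored-graph data model for the birth-death Moran process.

A :class:`ColoredGraph` couples a dispersal graph (nonnegative edge
weights ``w_ij``, no self-loops, connected) with a two-coloring of its
nodes.  Colors stand for local environmental quality: a green node
(``"G"``) is resource-rich, a red node (``"R"``) resource-poor.  The
coloring is *proper* when no edge joins two same-colored nodes; on such
graphs the per-color degree structure (``k_G``, ``k_R`` in the
undirected case, weighted in/out degrees in the directed case) is what
the closed-form fixation results depend on.

The module also provides builders for the standard properly two-colored
families (cycle, complete bipartite, star, periodic square and hexagonal
lattices), random-walk edge weighting, the admissibility check for the
directed closed form, and enumeration of colorings with fixed color
counts, optionally reduced to one representative per orbit of the graph
automorphism group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import networkx as nx
import numpy as np

GREEN = "G"
RED = "R"
COLORS = (GREEN, RED)

__all__ = [
    "GREEN",
    "RED",
    "ColoredGraph",
    "DegreeProfile",
    "Coloring",
    "validate_proper_coloring",
    "degree_profile",
    "build_family",
    "random_walk_weights",
    "check_weight_condition",
    "enumerate_colorings",
    "recolor",
]


@dataclass
class ColoredGraph:
    """A dispersal graph with a two-coloring of its nodes.

    Parameters
    ----------
    weights
        ``(N, N)`` array of nonnegative dispersal weights ``w_ij`` (the
        propensity for an offspring born at ``i`` to replace the
        occupant of ``j``).  The diagonal must be zero and the pattern
        of nonzeros must be (strongly) connected.
    colors
        Length-``N`` array over ``{"G", "R"}``.
    directed
        If false, ``weights`` must be symmetric.
    """

    weights: np.ndarray
    colors: np.ndarray
    directed: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.colors = np.asarray(self.colors, dtype="U1")
        W = self.weights
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        n = W.shape[0]
        if n < 2:
            raise ValueError("a graph needs at least two nodes")
        if self.colors.shape != (n,):
            raise ValueError("colors must have one entry per node")
        if not set(self.colors) <= set(COLORS):
            raise ValueError(f"colors must be drawn from {COLORS}")
        if np.any(W < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-loops (w_ii != 0) are not allowed")
        if not self.directed and not np.allclose(W, W.T):
            raise ValueError("undirected graph requires symmetric weights")
        g = self.to_networkx()
        connected = (
            nx.is_strongly_connected(g) if self.directed else nx.is_connected(g)
        )
        if not connected:
            raise ValueError("graph must be (strongly) connected")

    # -- basic bookkeeping -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_green(self) -> int:
        return int(np.sum(self.colors == GREEN))

    @property
    def n_red(self) -> int:
        return int(np.sum(self.colors == RED))

    @property
    def adjacency(self) -> np.ndarray:
        """Binary adjacency pattern Gamma_ij = [w_ij > 0]."""
        return (self.weights > 0).astype(float)

    @property
    def is_unweighted(self) -> bool:
        """True when every weight is 0 or 1."""
        w = self.weights
        return bool(np.all((w == 0) | (w == 1)))

    def to_networkx(self) -> nx.Graph | nx.DiGraph:
        cls = nx.DiGraph if self.directed else nx.Graph
        g = nx.from_numpy_array(self.weights, create_using=cls)
        nx.set_node_attributes(
            g, {i: c for i, c in enumerate(self.colors)}, name="color"
        )
        return g

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: list[tuple],
        colors,
        directed: bool = False,
    ) -> "ColoredGraph":
        """Build from an edge list of ``(u, v)`` or ``(u, v, weight)``."""
        W = np.zeros((n_nodes, n_nodes))
        for edge in edges:
            u, v = edge[0], edge[1]
            w = float(edge[2]) if len(edge) > 2 else 1.0
            W[u, v] = w
            if not directed:
                W[v, u] = w
        return cls(W, np.asarray(colors, dtype="U1"), directed=directed)


@dataclass(frozen=True)
class DegreeProfile:
    """Per-color degree summary of a two-colored graph.

    ``k_G``/``k_R`` are the unweighted degrees shared by all green/red
    nodes (NaN if the color class is not degree-uniform); the ``w_*``
    fields are the analogous weighted in/out degrees.  ``biregular`` is
    true when both color classes are uniform in their unweighted
    degrees; for an undirected biregular proper coloring the handshake
    identity ``N_G * k_G = N_R * k_R`` follows.
    """

    k_G: float
    k_R: float
    w_G_in: float
    w_G_out: float
    w_R_in: float
    w_R_out: float
    biregular: bool


@dataclass(frozen=True)
class Coloring:
    """An assignment of ``{G, R}`` to the nodes of a fixed graph.

    ``orbit_size`` is the number of colorings equivalent to this one
    under the graph's automorphism group when produced by
    :func:`enumerate_colorings` with ``up_to_isomorphism=True`` (1
    otherwise).
    """

    assignment: tuple[str, ...]
    orbit_size: int = 1

    @property
    def n_green(self) -> int:
        return sum(1 for c in self.assignment if c == GREEN)

    @property
    def n_red(self) -> int:
        return len(self.assignment) - self.n_green

    def as_array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype="U1")


def validate_proper_coloring(graph: ColoredGraph) -> bool:
    """True iff no edge joins two same-colored nodes."""
    rows, cols = np.nonzero(graph.weights)
    return bool(np.all(graph.colors[rows] != graph.colors[cols]))


def _uniform(values: np.ndarray, rtol: float = 1e-9) -> float:
    """Common value of an array, or NaN when the entries differ."""
    if values.size == 0:
        return math.nan
    v0 = values[0]
    scale = max(abs(float(v0)), 1.0)
    if np.all(np.abs(values - v0) <= rtol * scale):
        return float(v0)
    return math.nan


def degree_profile(graph: ColoredGraph) -> DegreeProfile:
    """Per-color (weighted) degrees and the biregularity flag.

    Non-biregular graphs are not an error: the corresponding fields are
    NaN and ``biregular`` is false.
    """
    A = graph.adjacency
    W = graph.weights
    green = graph.colors == GREEN
    red = ~green
    # unweighted degree: out-degree of the adjacency pattern (equals the
    # ordinary degree for undirected graphs)
    deg_out = A.sum(axis=1)
    deg_in = A.sum(axis=0)
    k_G = _uniform(deg_out[green])
    k_R = _uniform(deg_out[red])
    uniform_in_G = not math.isnan(_uniform(deg_in[green]))
    uniform_in_R = not math.isnan(_uniform(deg_in[red]))
    biregular = (
        not math.isnan(k_G) and not math.isnan(k_R) and uniform_in_G and uniform_in_R
    )
    return DegreeProfile(
        k_G=k_G,
        k_R=k_R,
        w_G_in=_uniform(W.sum(axis=0)[green]),
        w_G_out=_uniform(W.sum(axis=1)[green]),
        w_R_in=_uniform(W.sum(axis=0)[red]),
        w_R_out=_uniform(W.sum(axis=1)[red]),
        biregular=biregular,
    )


# -- graph families --------------------------------------------------------


def _color_bipartite(g: nx.Graph) -> np.ndarray:
    """Proper two-coloring of a connected bipartite graph via BFS."""
    try:
        left, _right = nx.bipartite.sets(g)
    except nx.NetworkXError as exc:  # odd cycle somewhere
        raise ValueError("graph is not two-colorable (not bipartite)") from exc
    colors = np.full(g.number_of_nodes(), RED, dtype="U1")
    colors[sorted(left)] = GREEN
    return colors


def _from_networkx(g: nx.Graph, colors: np.ndarray | None = None) -> ColoredGraph:
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    W = nx.to_numpy_array(g, weight=None)
    np.fill_diagonal(W, 0.0)  # periodic builders can produce self-loops at size 2
    if colors is None:
        colors = _color_bipartite(nx.from_numpy_array(W))
    return ColoredGraph(W, colors, directed=False)


def build_family(family: str, *sizes: int) -> ColoredGraph:
    """Construct a standard properly two-colored graph.

    Supported families and their size arguments:

    - ``cycle`` (n, even): alternating colors.
    - ``complete_bipartite`` (n_g, n_r): greens on the first part.
    - ``star`` (n): red center, ``n - 1`` green leaves.
    - ``square_lattice`` (rows, cols, both even): periodic boundaries,
      von Neumann neighborhood, checkerboard coloring.
    - ``hex_lattice`` (m, n): periodic hexagonal (honeycomb) lattice.
    - ``path`` (n): path graph, alternating colors.

    Raises ``ValueError`` when the sizes do not admit a proper
    two-coloring (e.g. an odd cycle).
    """
    family = family.replace("-", "_")
    if family == "cycle":
        (n,) = sizes
        if n % 2 != 0:
            raise ValueError("odd cycles have chromatic number 3")
        if n < 4:
            raise ValueError("cycle needs at least 4 nodes")
        colors = np.where(np.arange(n) % 2 == 0, GREEN, RED)
        return _from_networkx(nx.cycle_graph(n), colors)
    if family == "complete_bipartite":
        n_g, n_r = sizes
        colors = np.array([GREEN] * n_g + [RED] * n_r, dtype="U1")
        return _from_networkx(nx.complete_bipartite_graph(n_g, n_r), colors)
    if family == "star":
        (n,) = sizes
        if n < 2:
            raise ValueError("star needs at least 2 nodes")
        colors = np.array([RED] + [GREEN] * (n - 1), dtype="U1")
        return _from_networkx(nx.star_graph(n - 1), colors)
    if family == "square_lattice":
        rows, cols = sizes
        if rows % 2 or cols % 2:
            raise ValueError("periodic square lattice needs even side lengths")
        g = nx.grid_2d_graph(rows, cols, periodic=True)
        colors = np.array(
            [GREEN if (i + j) % 2 == 0 else RED for i, j in sorted(g.nodes)],
            dtype="U1",
        )
        return _from_networkx(g, colors)
    if family == "hex_lattice":
        m, n = sizes
        g = nx.hexagonal_lattice_graph(m, n, periodic=True)
        return _from_networkx(g)
    if family == "path":
        (n,) = sizes
        colors = np.where(np.arange(n) % 2 == 0, GREEN, RED)
        return _from_networkx(nx.path_graph(n), colors)
    raise ValueError(f"unknown graph family: {family!r}")


def random_walk_weights(graph: ColoredGraph) -> ColoredGraph:
    """Replace weights by random-walk step probabilities p_ij = Gamma_ij / Gamma_i.

    Each row of the result sums to one.  The result carries the
    ``directed`` flag whenever the normalized matrix is asymmetric
    (which it is unless the graph is regular).
    """
    A = graph.adjacency
    row = A.sum(axis=1)
    if np.any(row == 0):
        raise ValueError("isolated node: cannot normalize a zero row")
    P = A / row[:, None]
    return ColoredGraph(P, graph.colors.copy(), directed=not np.allclose(P, P.T))


def check_weight_condition(graph: ColoredGraph, tol: float = 1e-9) -> bool:
    """Admissibility of the directed closed form.

    The per-color martingale solution extends to directed, weighted
    graphs only when every green-to-red edge pair satisfies
    ``w_ji / w_ij = w_G_in / w_G_out``.  Returns False (never raises)
    when the coloring is improper, the per-color degrees are not
    uniform, or some reverse edge is missing.
    """
    if not validate_proper_coloring(graph):
        return False
    prof = degree_profile(graph)
    if any(
        math.isnan(v)
        for v in (prof.w_G_in, prof.w_G_out, prof.w_R_in, prof.w_R_out)
    ):
        return False
    ratio = prof.w_G_in / prof.w_G_out
    W = graph.weights
    green = graph.colors == GREEN
    rows, cols = np.nonzero(W)
    for i, j in zip(rows, cols):
        if not green[i]:
            continue  # each unordered pair is checked once, from its green end
        if W[j, i] == 0:
            return False
        if abs(W[j, i] / W[i, j] - ratio) > tol * max(ratio, 1.0):
            return False
    return True


def recolor(graph: ColoredGraph, coloring: Coloring | np.ndarray) -> ColoredGraph:
    """The same dispersal graph with a different color assignment."""
    colors = coloring.as_array() if isinstance(coloring, Coloring) else coloring
    return replace(graph, weights=graph.weights.copy(), colors=np.asarray(colors))


_ISO_CAP = 12


def enumerate_colorings(
    graph: ColoredGraph,
    n_green: int,
    up_to_isomorphism: bool = False,
) -> list[Coloring]:
    """All colorings of ``graph`` with exactly ``n_green`` green nodes.

    With ``up_to_isomorphism=True`` the list is reduced to one canonical
    representative per orbit of the graph automorphism group (the
    lexicographically minimal color string in the orbit), with
    ``orbit_size`` recording the orbit cardinality; orbit sizes sum to
    ``C(N, n_green)``.  Orbit grouping is exact, via colored-graph
    isomorphism testing, and is capped at ``N <= 12``; above the cap
    only the full enumeration is offered.
    """
    n = graph.n_nodes
    if not 0 <= n_green <= n:
        raise ValueError("n_green must be between 0 and N")
    if not up_to_isomorphism:
        out = []
        for greens in combinations(range(n), n_green):
            assignment = [RED] * n
            for i in greens:
                assignment[i] = GREEN
            out.append(Coloring(tuple(assignment)))
        return out
    if n > _ISO_CAP:
        raise ValueError(
            f"isomorphism reduction is capped at N={_ISO_CAP}; "
            "request the full enumeration instead"
        )

    base = graph.to_networkx().to_undirected() if graph.directed else graph.to_networkx()
    deg = dict(base.degree())

    def invariant(greens: frozenset) -> tuple:
        # multiset of (is-green, degree) node labels: an automorphism
        # invariant used to bucket candidate orbits before VF2
        return tuple(sorted((i in greens, deg[i]) for i in base.nodes))

    def colored_copy(greens: frozenset) -> nx.Graph:
        g = base.copy()
        nx.set_node_attributes(
            g, {i: (i in greens) for i in g.nodes}, name="_green"
        )
        return g

    match = nx.algorithms.isomorphism.categorical_node_match("_green", False)
    buckets: dict[tuple, list[dict]] = {}
    for greens_t in combinations(range(n), n_green):
        greens = frozenset(greens_t)
        assignment = tuple(GREEN if i in greens else RED for i in range(n))
        g_c = colored_copy(greens)
        key = invariant(greens)
        for rep in buckets.setdefault(key, []):
            if nx.is_isomorphic(rep["graph"], g_c, node_match=match):
                rep["size"] += 1
                rep["min"] = min(rep["min"], assignment)
                break
        else:
            buckets[key].append({"graph": g_c, "size": 1, "min": assignment})
    reps = [rep for bucket in buckets.values() for rep in bucket]
    reps.sort(key=lambda rep: rep["min"])
    return [Coloring(rep["min"], orbit_size=rep["size"]) for rep in reps]
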