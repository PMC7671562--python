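"""Exact finite-Markov-chain engine for the colored Moran process.

The population configuration is a binary occupancy vector ``x`` (1 =
mutant) encoded as an integer bitmask, giving a chain on ``2^N`` states
with the all-zero and all-one states absorbing.  One time step picks a
reproducer with probability proportional to fitness times its total
outgoing dispersal weight and places the offspring on a neighbor drawn
from the reproducer's dispersal row, replacing the occupant there.

Three layers are provided:

- per-state transition probabilities (and their embedded, conditioned
  form, which shares absorption probabilities with the full chain);
- assembled sparse transition matrices, for a fixed coloring or for the
  product space (configuration x coloring) of the dynamic model in
  which colors are reshuffled with probability ``p`` per step;
- absorption solves (exact sparse linear algebra) and straight power
  iteration of the distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .closed_form import FitnessScheme, FixationResult
from .graphs import (
    GREEN,
    RED,
    ColoredGraph,
    Coloring,
    enumerate_colorings,
    random_walk_weights,
    recolor,
    validate_proper_coloring,
)

__all__ = [
    "encode_state",
    "decode_state",
    "TransitionModel",
    "DynamicColoringSpec",
    "step_probabilities",
    "conditioned_probabilities",
    "build_chain",
    "build_dynamic_chain",
    "absorption_solve",
    "distribution_power",
    "permuted_coloring_sweep",
]

STATIC_CAP = 14
DYNAMIC_NNZ_CAP = 2 * 10**7


def encode_state(x: np.ndarray) -> int:
    """Occupancy vector -> bitmask (bit i set iff node i holds a mutant)."""
    return int(np.sum((np.asarray(x).astype(np.int64)) << np.arange(len(x))))

def decode_state(s: int, n: int) -> np.ndarray:
    """Bitmask -> binary occupancy vector of length ``n``."""
    return (s >> np.arange(n)) & 1


@dataclass
class TransitionModel:
    """Sparse one-step transition matrix with absorbing bookkeeping.

    ``absorbing_A``/``absorbing_B`` index the states of the all-mutant /
    all-resident class (singletons for a static coloring, one state per
    coloring for the dynamic product chain).  ``initial`` is the default
    starting distribution: uniform over single-mutant configurations
    (under the initial coloring, for the dynamic chain).
    """

    P: sp.csr_matrix
    absorbing_A: np.ndarray
    absorbing_B: np.ndarray
    initial: np.ndarray
    n_nodes: int

    @property
    def n_states(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class DynamicColoringSpec:
    """Parameters of the dynamic (shuffled) coloring model.

    With probability ``p`` per time step the color assignment is
    replaced by a uniform draw from all assignments with the same color
    counts (equivalently, colors are permuted uniformly at random).
    ``shuffle_first=True`` (default) performs the potential shuffle at
    the start of the step, so the birth-death event sees the post-shuffle
    coloring; the alternative ordering shuffles after the event.
    """

    p: float
    shuffle_first: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("shuffle probability p must lie in [0, 1]")


def _dispersal_matrix(graph: ColoredGraph) -> np.ndarray:
    """Effective dispersal weights: random-walk rows for 0/1 adjacency."""
    if graph.is_unweighted:
        return random_walk_weights(graph).weights
    return graph.weights


def step_probabilities(
    x: np.ndarray, graph: ColoredGraph, f: FitnessScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node loss/gain probabilities ``(P_i^-, P_i^+)`` in state ``x``.

    ``P_i^-`` is the probability that node ``i`` loses a mutant this
    step (a resident neighbor reproduces into ``i``) and ``P_i^+`` that
    it gains one.  Rows of an unweighted graph are first normalized to
    random-walk weights.  Absorbing states return all zeros.
    """
    x = np.asarray(x, dtype=float)
    W = _dispersal_matrix(graph)
    a, b = f.node_fitness(graph.colors)
    res_b = (1.0 - x) * b
    mut_a = x * a
    denom = float((mut_a + res_b) @ W.sum(axis=1))
    loss = x * (res_b @ W) / denom
    gain = (1.0 - x) * (mut_a @ W) / denom
    return loss, gain


def conditioned_probabilities(
    x: np.ndarray, graph: ColoredGraph, f: FitnessScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Transition probabilities conditioned on a change in mutant count.

    The embedded chain ``Q_i^+- = P_i^+- / sum_k (P_k^+ + P_k^-)`` skips
    self-loop steps; it has the same absorption probabilities as the
    full chain.  Raises on an absorbing state (no change can occur).
    """
    loss, gain = step_probabilities(x, graph, f)
    total = loss.sum() + gain.sum()
    if total == 0.0:
        raise ValueError("state is absorbing: conditioning event has probability 0")
    return loss / total, gain / total


def _bd_matrix(
    W: np.ndarray, a_node: np.ndarray, b_node: np.ndarray, conditioned: bool = False
) -> sp.csr_matrix:
    """Assemble the 2^N x 2^N birth-death transition matrix.

    Vectorized over all states at once: for the (S, N) occupancy matrix
    ``X``, the loss/gain numerators are single matrix products with the
    dispersal matrix.
    """
    n = W.shape[0]
    if n > STATIC_CAP:
        raise ValueError(
            f"state space 2^{n} exceeds the cap (N <= {STATIC_CAP}); "
            "use Monte Carlo simulation instead"
        )
    S = 1 << n
    states = np.arange(S, dtype=np.int64)
    X = ((states[:, None] >> np.arange(n)) & 1).astype(float)
    res_b = (1.0 - X) * b_node
    mut_a = X * a_node
    denom = (mut_a + res_b) @ W.sum(axis=1)
    loss = X * (res_b @ W) / denom[:, None]
    gain = (1.0 - X) * (mut_a @ W) / denom[:, None]
    flip = loss + gain  # per (state, node): exclusive events
    if conditioned:
        tot = flip.sum(axis=1)
        nonabs = tot > 0
        flip[nonabs] /= tot[nonabs, None]
    targets = states[:, None] ^ (1 << np.arange(n, dtype=np.int64))
    rows = np.repeat(states, n)
    mask = flip.ravel() > 0
    off = sp.coo_matrix(
        (flip.ravel()[mask], (rows[mask], targets.ravel()[mask])), shape=(S, S)
    )
    diag = 1.0 - flip.sum(axis=1)
    diag[np.abs(diag) < 1e-15] = 0.0
    P = (off + sp.diags(diag)).tocsr()
    return P


def _single_mutant_initial(n: int) -> np.ndarray:
    init = np.zeros(1 << n)
    for i in range(n):
        init[1 << i] = 1.0 / n
    return init


def build_chain(
    graph: ColoredGraph, f: FitnessScheme, conditioned: bool = False
) -> TransitionModel:
    """Full transition matrix of the process under a fixed coloring.

    ``conditioned=True`` builds the embedded chain instead (self-loop
    mass removed from non-absorbing states); both have identical
    absorption probabilities.
    """
    n = graph.n_nodes
    W = _dispersal_matrix(graph)
    a_node, b_node = f.node_fitness(graph.colors)
    P = _bd_matrix(W, a_node, b_node, conditioned=conditioned)
    return TransitionModel(
        P=P,
        absorbing_A=np.array([(1 << n) - 1]),
        absorbing_B=np.array([0]),
        initial=_single_mutant_initial(n),
        n_nodes=n,
    )


def build_dynamic_chain(
    graph: ColoredGraph, f: FitnessScheme, spec: DynamicColoringSpec
) -> TransitionModel:
    """Product chain over (coloring, configuration) pairs.

    The coloring family is every assignment with the color counts of
    ``graph.colors`` (the family is closed under permutation); state
    index ``c * 2^N + x`` pairs coloring ``c`` with configuration ``x``.
    One step composes a shuffle (draw a uniform coloring with
    probability ``p``, else keep the current one) with one birth-death
    event, in the order set by ``spec.shuffle_first``.  Rows of absorbed
    configurations are unit self-loops regardless of coloring.  The
    initial coloring is ``graph.colors`` itself.
    """
    n = graph.n_nodes
    W = _dispersal_matrix(graph)
    colorings = enumerate_colorings(graph, graph.n_green, up_to_isomorphism=False)
    M = len(colorings)
    S = 1 << n
    if M * M * S * (n + 1) > DYNAMIC_NNZ_CAP:
        raise ValueError(
            f"dynamic product space too large ({M} colorings x 2^{n} states); "
            "use Monte Carlo simulation instead"
        )
    blocks = []
    init_block = None
    for c, col in enumerate(colorings):
        a_node, b_node = f.node_fitness(col.as_array())
        blocks.append(_bd_matrix(W, a_node, b_node))
        if tuple(graph.colors) == col.assignment:
            init_block = c
    if init_block is None:  # pragma: no cover - counts always match
        raise RuntimeError("initial coloring missing from its own family")
    T = sp.block_diag(blocks, format="csr")
    # shuffle operator on the coloring index, identity on configurations
    shuffle = sp.csr_matrix(
        (1.0 - spec.p) * sp.identity(M) + (spec.p / M) * np.ones((M, M))
    )
    mix = sp.kron(shuffle, sp.identity(S, format="csr"), format="csr")
    P = (mix @ T) if spec.shuffle_first else (T @ mix)

    abs_A = np.arange(M) * S + (S - 1)
    abs_B = np.arange(M) * S
    # force absorbed configurations to be pure self-loops
    keep = np.ones(M * S)
    keep[abs_A] = 0.0
    keep[abs_B] = 0.0
    P = sp.diags(keep) @ P
    P = P + sp.coo_matrix(
        (np.ones(2 * M), (np.r_[abs_A, abs_B], np.r_[abs_A, abs_B])),
        shape=P.shape,
    )
    initial = np.zeros(M * S)
    initial[init_block * S + (1 << np.arange(n))] = 1.0 / n
    return TransitionModel(
        P=P.tocsr(),
        absorbing_A=abs_A,
        absorbing_B=abs_B,
        initial=initial,
        n_nodes=n,
    )


def absorption_solve(
    model: TransitionModel, initial: Optional[np.ndarray] = None
) -> FixationResult:
    """Exact absorption probability into the all-mutant class.

    Solves the sparse linear system ``(I - Q) u = r`` on the transient
    states, where ``Q`` is the transient block and ``r`` the one-step
    probability of entering the mutant-fixed class, then averages over
    the initial distribution (default: uniform single mutant).
    """
    init = model.initial if initial is None else np.asarray(initial, dtype=float)
    S = model.n_states
    transient = np.ones(S, dtype=bool)
    transient[model.absorbing_A] = False
    transient[model.absorbing_B] = False
    P = model.P
    Q = P[transient][:, transient]
    rA = np.asarray(P[transient][:, model.absorbing_A].sum(axis=1)).ravel()
    A = (sp.identity(Q.shape[0], format="csc") - Q).tocsc()
    u = spla.spsolve(A, rA)
    if not np.all(np.isfinite(u)):
        raise ValueError("transient structure is reducible: absorption solve failed")
    rho = float(init[transient] @ u + init[model.absorbing_A].sum())
    return FixationResult(min(max(rho, 0.0), 1.0), method="exact-chain")


def distribution_power(
    model: TransitionModel,
    steps: int,
    initial: Optional[np.ndarray] = None,
    tol: float = 1e-12,
) -> dict:
    """Push the distribution ``steps`` times through the chain.

    Mirrors the brute-force procedure of iterating the transition matrix
    a large fixed number of times and reading off the absorbing masses.
    Stops early once the transient mass falls below ``tol``.  Returns
    the masses on the two absorbing classes, the residual transient
    mass, and the number of steps actually taken.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    v = (model.initial if initial is None else np.asarray(initial, dtype=float)).copy()
    PT = model.P.T.tocsr()
    absorbed = np.zeros(model.n_states, dtype=bool)
    absorbed[model.absorbing_A] = True
    absorbed[model.absorbing_B] = True
    taken = 0
    for _ in range(steps):
        v = PT @ v
        taken += 1
        if 1.0 - v[absorbed].sum() < tol:
            break
    return {
        "mass_A": float(v[model.absorbing_A].sum()),
        "mass_B": float(v[model.absorbing_B].sum()),
        "transient_mass": float(v[~absorbed].sum()),
        "steps": taken,
        "distribution": v,
    }


def permuted_coloring_sweep(
    graph: ColoredGraph,
    r: float,
    sigma_grid,
    up_to_isomorphism: bool = True,
    scheme: str = "mean",
) -> pd.DataFrame:
    """Exact fixation probability for every coloring across a sigma grid.

    Colors are permuted once at the outset and then held fixed; each
    (coloring, sigma) pair is solved exactly.  ``scheme`` selects the
    heterogeneity parametrization: ``"mean"`` keeps the population-mean
    fitness of each type at ``r`` (resp. 1) by scaling the red-node
    offset by ``N_G / N_R``; ``"plusminus"`` uses the symmetric table
    ``(r + sigma, r - sigma, 1 + sigma, 1 - sigma)``.  The two coincide
    for equal color counts.  Returns a long-format frame with one row
    per pair, flagging the proper coloring and the argmax/argmin
    coloring at each sigma.
    """
    from .closed_form import HeterogeneityParams, fitness_from_heterogeneity

    colorings = enumerate_colorings(
        graph, graph.n_green, up_to_isomorphism=up_to_isomorphism
    )
    rows = []
    for sigma in sigma_grid:
        if scheme == "mean":
            f = fitness_from_heterogeneity(
                HeterogeneityParams(
                    r, 1.0, float(sigma), float(sigma), graph.n_green, graph.n_red
                )
            )
        elif scheme == "plusminus":
            f = FitnessScheme.from_sigma(r, float(sigma))
        else:
            raise ValueError("scheme must be 'mean' or 'plusminus'")
        for idx, col in enumerate(colorings):
            g = recolor(graph, col)
            rho = absorption_solve(build_chain(g, f)).rho_A
            rows.append(
                {
                    "sigma": float(sigma),
                    "r": r,
                    "coloring_id": idx,
                    "coloring": "".join(col.assignment),
                    "is_proper": validate_proper_coloring(g),
                    "orbit_size": col.orbit_size,
                    "rho_A": rho,
                }
            )
    df = pd.DataFrame(rows)
    df["is_max"] = False
    df["is_min"] = False
    for sigma, grp in df.groupby("sigma"):
        df.loc[grp["rho_A"].idxmax(), "is_max"] = True
        df.loc[grp["rho_A"].idxmin(), "is_min"] = True
    return df
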