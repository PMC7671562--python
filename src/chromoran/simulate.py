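"""Monte Carlo estimation of fixation probabilities.

For graphs beyond the exact-chain cap the colored Moran process is
realized directly.  Two samplers are available:

- the *embedded chain* (default for static colorings): each draw is one
  change of the occupancy vector, conditioned on a change occurring.
  This is statistically exact for absorption probabilities and skips
  the self-loop steps that dominate wall-clock time near absorption;
- *direct stepping* (default, and required, when the coloring is
  dynamic): one draw per Moran time step, with the color labels
  reshuffled with probability ``p`` per step, matching the cadence of
  the dynamic model.

A single root seed spawns one independent stream per replicate, so a
given (seed, config) pair reproduces bit-identical estimates and the
result does not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .closed_form import FitnessScheme
from .graphs import RED, ColoredGraph
from .markov import DynamicColoringSpec, _dispersal_matrix

__all__ = ["SimulationConfig", "SimulationEstimate", "run_trajectory", "estimate_fixation"]


@dataclass(frozen=True)
class SimulationConfig:
    """Replication plan for a Monte Carlo estimate.

    ``embedded=None`` selects the embedded chain for static colorings
    (``p == 0``) and direct stepping otherwise.  ``max_steps`` is a
    guard against pathological trajectories; replicates that hit it are
    reported as censored, never silently dropped.
    """

    replicates: int
    seed: int
    p: float = 0.0
    shuffle_first: bool = True
    max_steps: int = 10**8
    embedded: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("shuffle probability p must lie in [0, 1]")

    def resolved_embedded(self) -> bool:
        if self.embedded is None:
            return self.p == 0.0
        if self.embedded and self.p > 0.0:
            raise ValueError("embedded-chain sampling requires a static coloring (p=0)")
        return self.embedded


@dataclass(frozen=True)
class SimulationEstimate:
    """Fixation fraction with its binomial standard error.

    ``mean_steps`` counts Moran time steps averaged over uncensored
    replicates (for the embedded sampler this is the expected wall-step
    count accumulated along the sampled change sequence).
    """

    rho_hat: float
    stderr: float
    replicates: int
    n_fixed: int
    n_censored: int
    mean_steps: float


def _csr_arrays(graph: ColoredGraph):
    W = _dispersal_matrix(graph)
    n = W.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices = []
    data = []
    for j in range(n):
        nz = np.nonzero(W[j])[0]
        indptr[j + 1] = indptr[j] + len(nz)
        indices.append(nz)
        data.append(W[j, nz])
    return indptr, np.concatenate(indices).astype(np.int64), np.concatenate(data)


def run_trajectory(
    graph: ColoredGraph,
    f: FitnessScheme,
    seed: int,
    p: float = 0.0,
    shuffle_first: bool = True,
    max_steps: int = 10**8,
    embedded: bool = False,
    start_node: Optional[int] = None,
) -> tuple[str, float]:
    """One trajectory from a single uniformly placed mutant.

    Returns ``(outcome, steps)`` with outcome in ``{"fixed", "extinct",
    "censored"}``.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_nodes
    x = np.zeros(n, dtype=np.int8)
    x[start_node if start_node is not None else rng.integers(n)] = 1
    kernel_seed = int(rng.integers(2**31 - 1))
    indptr, indices, data = _csr_arrays(graph)
    if embedded:
        if p > 0:
            raise ValueError("embedded sampling requires a static coloring")
        a_node, b_node = f.node_fitness(graph.colors)
        out, _events, steps = _kernels.embedded_trajectory(
            indptr, indices, data, a_node.astype(float), b_node.astype(float),
            x, kernel_seed, max_steps,
        )
    else:
        is_red = (graph.colors == RED).astype(np.int8)
        out, _n, steps = _kernels.direct_trajectory(
            indptr, indices, data, is_red,
            f.a_G, f.a_R, f.b_G, f.b_R,
            x, p, shuffle_first, kernel_seed, max_steps,
        )
    return {1: "fixed", 0: "extinct", -1: "censored"}[out], steps


def estimate_fixation(
    graph: ColoredGraph, f: FitnessScheme, config: SimulationConfig
) -> SimulationEstimate:
    """Monte Carlo fixation probability over independent replicates.

    Each replicate starts from one mutant placed uniformly at random
    (on the graph's own coloring, which the dynamic model then
    reshuffles at rate ``p``).  The estimate is the fixed fraction among
    uncensored replicates; ``stderr = sqrt(rho(1-rho)/m)``.
    """
    embedded = config.resolved_embedded()
    indptr, indices, data = _csr_arrays(graph)
    n = graph.n_nodes
    a_node, b_node = f.node_fitness(graph.colors)
    a_node = a_node.astype(float)
    b_node = b_node.astype(float)
    is_red0 = (graph.colors == RED).astype(np.int8)

    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    n_fixed = 0
    n_censored = 0
    total_steps = 0.0
    for child in children:
        rng = np.random.default_rng(child)
        start = int(rng.integers(n))
        kernel_seed = int(rng.integers(2**31 - 1))
        x = np.zeros(n, dtype=np.int8)
        x[start] = 1
        if embedded:
            out, _ev, steps = _kernels.embedded_trajectory(
                indptr, indices, data, a_node, b_node, x,
                kernel_seed, config.max_steps,
            )
        else:
            out, _s, steps = _kernels.direct_trajectory(
                indptr, indices, data, is_red0.copy(),
                f.a_G, f.a_R, f.b_G, f.b_R,
                x, config.p, config.shuffle_first, kernel_seed, config.max_steps,
            )
        if out == 1:
            n_fixed += 1
        elif out == -1:
            n_censored += 1
        if out != -1:
            total_steps += steps
    m = config.replicates - n_censored
    rho = n_fixed / m if m else float("nan")
    stderr = float(np.sqrt(rho * (1.0 - rho) / m)) if m else float("nan")
    return SimulationEstimate(
        rho_hat=rho,
        stderr=stderr,
        replicates=config.replicates,
        n_fixed=n_fixed,
        n_censored=n_censored,
        mean_steps=total_steps / m if m else float("nan"),
    )
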