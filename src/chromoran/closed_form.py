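"""Closed-form fixation probabilities on properly two-colored graphs.

For a birth-death Moran process on a graph whose nodes carry one of two
colors, the fitness of each type depends on the color of its node: a
mutant (type A) has fitness ``a_G`` on a green node and ``a_R`` on a red
node; a resident (type B) has ``b_G`` and ``b_R``.  On a properly
two-colored, biregular graph there exist per-color multipliers
``zeta_G``, ``zeta_R`` making ``prod_i zeta_i^{x_i}`` a martingale of
the process, which yields an exact fixation probability from any
starting configuration ``x``::

    rho_A(x) = (1 - prod_i zeta_i^{x_i}) / (1 - prod_i zeta_i)

Averaging over a uniformly placed single mutant gives the closed form
for the mean fixation probability ``rho_A`` (and ``rho_B`` by swapping
the roles of the two types).  Selection favors A relative to B exactly
when the product ``a_G * a_R`` exceeds ``b_G * b_R`` — equivalently,
when A's geometric-mean fitness over the two colors is larger.

All products of zetas are evaluated in log space (``log``/``expm1``) so
the formulas remain accurate near neutrality and for populations in the
hundreds of nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graphs import (
    GREEN,
    ColoredGraph,
    check_weight_condition,
    degree_profile,
    validate_proper_coloring,
)

__all__ = [
    "FitnessScheme",
    "HeterogeneityParams",
    "ZetaPair",
    "FixationResult",
    "fitness_from_heterogeneity",
    "zeta_biregular",
    "zeta_directed",
    "fixation_from_state",
    "fixation_uniform",
    "fixation_directed",
    "fixation_star",
    "fixation_symmetric",
    "fixation_closed_form",
    "selection_condition",
]

#: relative tolerance below which a_G*a_R and b_G*b_R are treated as equal
NEUTRAL_RTOL = 1e-12


@dataclass(frozen=True)
class FitnessScheme:
    """The 2x2 color-to-fitness table.

    ``a_*`` is the mutant's fitness, ``b_*`` the resident's, on green
    (``_G``) and red (``_R``) nodes.  All four values must be positive.
    """

    a_G: float
    a_R: float
    b_G: float
    b_R: float

    def __post_init__(self) -> None:
        for name in ("a_G", "a_R", "b_G", "b_R"):
            if not getattr(self, name) > 0:
                raise ValueError(f"fitness {name} must be strictly positive")

    def swapped(self) -> "FitnessScheme":
        """Roles of mutant and resident exchanged (used for rho_B)."""
        return FitnessScheme(self.b_G, self.b_R, self.a_G, self.a_R)

    def node_fitness(self, colors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-node fitness arrays (a_i, b_i) for a color vector."""
        green = np.asarray(colors) == GREEN
        a = np.where(green, self.a_G, self.a_R)
        b = np.where(green, self.b_G, self.b_R)
        return a, b

    @classmethod
    def neutral(cls) -> "FitnessScheme":
        return cls(1.0, 1.0, 1.0, 1.0)

    @classmethod
    def from_sigma(
        cls, r: float, sigma: float, sigma_B: Optional[float] = None
    ) -> "FitnessScheme":
        """Symmetric heterogeneity scheme a = r -+ sigma, b = 1 -+ sigma_B.

        Green nodes add the offset, red nodes subtract it; the
        resident's offset defaults to the mutant's (``sigma_B = sigma``,
        the "heterogeneous background fitness" case).  When the color
        classes have equal sizes this coincides with the mean-preserving
        parametrization of :func:`fitness_from_heterogeneity`.
        """
        if sigma_B is None:
            sigma_B = sigma
        return cls(r + sigma, r - sigma, 1.0 + sigma_B, 1.0 - sigma_B)


@dataclass(frozen=True)
class HeterogeneityParams:
    """Mean-preserving parametrization of background heterogeneity.

    ``r_A``/``r_B`` are the population-mean fitnesses of the two types;
    ``sigma_A``/``sigma_B`` the green-node offsets.  Keeping the means
    fixed forces the red-node offsets to be ``N_G * sigma / N_R``, so
    feasibility (positive fitness on red nodes) depends on the color
    counts.
    """

    r_A: float
    r_B: float
    sigma_A: float
    sigma_B: float
    N_G: int
    N_R: int

    def __post_init__(self) -> None:
        if self.N_G <= 0 or self.N_R <= 0:
            raise ValueError("color counts must be positive")


@dataclass(frozen=True)
class ZetaPair:
    """Per-color martingale multipliers (zeta_G, zeta_R)."""

    zeta_G: float
    zeta_R: float


@dataclass(frozen=True)
class FixationResult:
    """Fixation probabilities with provenance.

    ``method`` is one of ``"closed-form"``, ``"exact-chain"``,
    ``"monte-carlo"``; ``stderr`` is populated only by the latter.
    """

    rho_A: float
    rho_B: Optional[float] = None
    method: str = "closed-form"
    stderr: Optional[float] = None

    def __post_init__(self) -> None:
        for rho in (self.rho_A, self.rho_B):
            if rho is not None and not -1e-12 <= rho <= 1 + 1e-12:
                raise ValueError(f"probability out of range: {rho}")


def fitness_from_heterogeneity(h: HeterogeneityParams) -> FitnessScheme:
    """Fitness table induced by the mean-preserving offsets.

    ``a_G = r_A + sigma_A`` and ``a_R = r_A - N_G sigma_A / N_R`` (and
    likewise for B), so that the population mean of each type's fitness
    equals ``r``.  Raises when any induced fitness is nonpositive.
    """
    a_G = h.r_A + h.sigma_A
    a_R = h.r_A - h.N_G * h.sigma_A / h.N_R
    b_G = h.r_B + h.sigma_B
    b_R = h.r_B - h.N_G * h.sigma_B / h.N_R
    if min(a_G, a_R, b_G, b_R) <= 0:
        raise ValueError(
            "heterogeneity offsets induce a nonpositive fitness: "
            f"(a_G, a_R, b_G, b_R) = ({a_G}, {a_R}, {b_G}, {b_R})"
        )
    return FitnessScheme(a_G, a_R, b_G, b_R)


def zeta_biregular(f: FitnessScheme, k_G: float, k_R: float) -> ZetaPair:
    """Martingale multipliers on an undirected biregular proper coloring."""
    if not (k_G > 0 and k_R > 0):
        raise ValueError("degrees must be positive")
    zeta_G = (f.b_R * (f.a_R * k_G + f.b_G * k_R)) / (
        f.a_R * (f.a_G * k_R + f.b_R * k_G)
    )
    zeta_R = (f.b_G * (f.a_G * k_R + f.b_R * k_G)) / (
        f.a_G * (f.a_R * k_G + f.b_G * k_R)
    )
    return ZetaPair(zeta_G, zeta_R)


def zeta_directed(
    f: FitnessScheme,
    w_G_in: float,
    w_G_out: float,
    w_R_in: float,
    w_R_out: float,
) -> ZetaPair:
    """Martingale multipliers for the directed/weighted case.

    Unique solution of the per-color linear system

        b_R (1/zeta_G - 1) w_G_in + a_G (zeta_R - 1) w_G_out = 0
        b_G (1/zeta_R - 1) w_R_in + a_R (zeta_G - 1) w_R_out = 0

    Validity of the resulting fixation formula additionally requires the
    edge-ratio condition checked by
    :func:`chromoran.graphs.check_weight_condition`.
    """
    if min(w_G_in, w_G_out, w_R_in, w_R_out) <= 0:
        raise ValueError("weighted degrees must be positive")
    zeta_G = (f.b_R * w_G_in * (f.a_R * w_R_out + f.b_G * w_R_in)) / (
        f.a_R * w_R_out * (f.a_G * w_G_out + f.b_R * w_G_in)
    )
    zeta_R = (f.b_G * w_R_in * (f.a_G * w_G_out + f.b_R * w_G_in)) / (
        f.a_G * w_G_out * (f.a_R * w_R_out + f.b_G * w_R_in)
    )
    return ZetaPair(zeta_G, zeta_R)


def _is_neutral(f: FitnessScheme, rtol: float = NEUTRAL_RTOL) -> bool:
    pa = f.a_G * f.a_R
    pb = f.b_G * f.b_R
    return abs(pa - pb) <= rtol * max(pa, pb)


def selection_condition(f: FitnessScheme, rtol: float = NEUTRAL_RTOL) -> str:
    """Direction of selection: ``favors_A``, ``favors_B`` or ``neutral``.

    A is favored relative to B exactly when ``a_G a_R > b_G b_R``,
    i.e. when A's geometric-mean fitness over the two colors exceeds
    B's; this is independent of the graph (within the biregular,
    properly two-colored class) and of the selection intensity.
    """
    if _is_neutral(f, rtol):
        return "neutral"
    return "favors_A" if f.a_G * f.a_R > f.b_G * f.b_R else "favors_B"


def _rho_from_zetas(z: ZetaPair, N_G: int, N_R: int) -> float:
    """Mean single-mutant fixation probability from the zeta pair.

    Evaluates ``(1 - (N_G z_G + N_R z_R)/N) / (1 - z_G^N_G z_R^N_R)``
    with the denominator in log space: ``-expm1`` keeps precision near
    neutrality, and exponents are never formed directly so populations
    of hundreds of nodes do not overflow.
    """
    N = N_G + N_R
    num = 1.0 - (N_G * z.zeta_G + N_R * z.zeta_R) / N
    s = N_G * math.log(z.zeta_G) + N_R * math.log(z.zeta_R)
    if s > 700.0:  # zeta product astronomically large: rho -> 0
        return 0.0
    den = -math.expm1(s)
    return num / den


def fixation_from_state(
    x: np.ndarray,
    zetas: ZetaPair,
    colors: np.ndarray,
    neutral_weights: Optional[tuple[float, float]] = None,
) -> float:
    """Fixation probability of A from an arbitrary configuration ``x``.

    ``x`` is a binary occupancy vector (1 = mutant).  At exact
    neutrality (both zetas equal 1) the 0/0 form has a well-defined
    limit ``sum_i x_i lambda_i / sum_i lambda_i`` whose per-color
    weights ``(lambda_G, lambda_R)`` depend on the fitness table; pass
    them via ``neutral_weights`` (e.g. ``(a_G * k_R, b_R * k_G)``), else
    the unweighted count ``#mutants / N`` is used.
    """
    x = np.asarray(x)
    green = np.asarray(colors) == GREEN
    n_mut_G = int(np.sum(x[green]))
    n_mut_R = int(np.sum(x[~green]))
    N_G = int(np.sum(green))
    N_R = len(x) - N_G
    lg = math.log(zetas.zeta_G)
    lr = math.log(zetas.zeta_R)
    s_full = N_G * lg + N_R * lr
    if abs(s_full) < 1e-14:  # neutral: take the limit
        if neutral_weights is None:
            return (n_mut_G + n_mut_R) / (N_G + N_R)
        wG, wR = neutral_weights
        return (n_mut_G * wG + n_mut_R * wR) / (N_G * wG + N_R * wR)
    s_x = n_mut_G * lg + n_mut_R * lr
    if s_full > 700.0:
        return 0.0 if s_x <= 700.0 else float(math.exp(min(s_x - s_full, 0.0)))
    return math.expm1(s_x) / math.expm1(s_full)


def fixation_uniform(
    N_G: int, N_R: int, k_G: float, k_R: float, f: FitnessScheme
) -> FixationResult:
    """Mean fixation probabilities on a biregular proper two-coloring.

    ``rho_A`` is the probability that a single mutant placed uniformly
    at random fixes; ``rho_B`` is the analogous quantity for a single
    resident invading a mutant population (role swap of the fitness
    table).  Requires the handshake-consistent combination
    ``N_G k_G = N_R k_R``.
    """
    if N_G <= 0 or N_R <= 0:
        raise ValueError("both color counts must be positive")
    if not math.isclose(N_G * k_G, N_R * k_R, rel_tol=1e-9):
        raise ValueError(
            "inconsistent degrees: a biregular proper two-coloring requires "
            f"N_G*k_G == N_R*k_R (got {N_G}*{k_G} != {N_R}*{k_R})"
        )
    N = N_G + N_R
    if _is_neutral(f):
        return FixationResult(1.0 / N, 1.0 / N, method="closed-form")
    rho_A = _rho_from_zetas(zeta_biregular(f, k_G, k_R), N_G, N_R)
    rho_B = _rho_from_zetas(zeta_biregular(f.swapped(), k_G, k_R), N_G, N_R)
    return FixationResult(rho_A, rho_B, method="closed-form")


def fixation_directed(
    N_G: int,
    N_R: int,
    w_G_in: float,
    w_G_out: float,
    w_R_in: float,
    w_R_out: float,
    f: FitnessScheme,
) -> FixationResult:
    """Mean fixation probabilities in the directed/weighted case.

    Assumes the caller has verified the edge-ratio admissibility
    condition (:func:`chromoran.graphs.check_weight_condition`).
    """
    N = N_G + N_R
    if _is_neutral(f):
        return FixationResult(1.0 / N, 1.0 / N, method="closed-form")
    rho_A = _rho_from_zetas(
        zeta_directed(f, w_G_in, w_G_out, w_R_in, w_R_out), N_G, N_R
    )
    rho_B = _rho_from_zetas(
        zeta_directed(f.swapped(), w_G_in, w_G_out, w_R_in, w_R_out), N_G, N_R
    )
    return FixationResult(rho_A, rho_B, method="closed-form")


def fixation_star(N: int, f: FitnessScheme) -> FixationResult:
    """Star graph with a red center and ``N - 1`` green leaves.

    Specialization of the biregular formula with ``N_G = k_R = N - 1``
    and ``N_R = k_G = 1``.
    """
    if N < 2:
        raise ValueError("star needs at least 2 nodes")
    return fixation_uniform(N - 1, 1, 1.0, float(N - 1), f)


def fixation_symmetric(N: int, r: float, sigma: float) -> FixationResult:
    """Equal color classes under heterogeneous background fitness.

    With ``N_G = N_R = N/2`` and the symmetric scheme
    ``(r + sigma, r - sigma, 1 + sigma, 1 - sigma)`` the mean mutant
    fixation probability collapses to::

        rho_A = r (r - 1) / [ (r^2 - sigma^2) (1 - ((1 - sigma^2) / (r^2 - sigma^2))^{N/2}) ]

    which reduces to the classical Moran probability
    ``(1 - 1/r) / (1 - r^{-N})`` at ``sigma = 0`` and to ``1/N`` as
    ``r -> 1`` for any valid sigma.  It is increasing in sigma for an
    advantageous mutant (r > 1) and decreasing for a disadvantageous one.
    """
    if N < 2 or N % 2:
        raise ValueError("N must be even (equal color classes)")
    if not 0 <= sigma < min(r, 1.0):
        raise ValueError("need 0 <= sigma < min(r, 1) for positive fitness")
    if abs(r - 1.0) <= 1e-12:
        rho_A = 1.0 / N
    else:
        ratio = (1.0 - sigma**2) / (r**2 - sigma**2)
        den = (r**2 - sigma**2) * (-math.expm1((N / 2) * math.log(ratio)))
        rho_A = r * (r - 1.0) / den
    f = FitnessScheme.from_sigma(r, sigma)
    rho_B = fixation_uniform(N // 2, N // 2, 1.0, 1.0, f).rho_B
    return FixationResult(rho_A, rho_B, method="closed-form")


def fixation_closed_form(graph: ColoredGraph, f: FitnessScheme) -> FixationResult:
    """Dispatch the closed form appropriate to a concrete graph.

    Undirected unweighted graphs use the biregular formula; weighted or
    directed graphs the directed variant after verifying the edge-ratio
    admissibility condition.  Raises when the graph violates the
    assumptions (improper coloring, non-biregular degrees).
    """
    if not validate_proper_coloring(graph):
        raise ValueError(
            "closed form requires a proper two-coloring "
            "(no edge may join two same-colored nodes)"
        )
    prof = degree_profile(graph)
    if not graph.directed and graph.is_unweighted:
        if not prof.biregular:
            raise ValueError("closed form requires a biregular graph")
        return fixation_uniform(
            graph.n_green, graph.n_red, prof.k_G, prof.k_R, f
        )
    if not check_weight_condition(graph):
        raise ValueError(
            "weighted/directed closed form requires the edge-ratio "
            "admissibility condition w_ji/w_ij = w_G_in/w_G_out"
        )
    return fixation_directed(
        graph.n_green,
        graph.n_red,
        prof.w_G_in,
        prof.w_G_out,
        prof.w_R_in,
        prof.w_R_out,
        f,
    )
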