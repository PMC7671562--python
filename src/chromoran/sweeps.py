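"""Parameter-sweep drivers producing long-format tables.

Each preset reproduces the setup behind one of the standard figures of
the two-colored Moran model at desk scale: the selection-condition
heat map on a large regular bipartite graph, monotonicity of fixation
in background heterogeneity, permuted-coloring comparisons on the
cycle / star / asymmetric complete bipartite graph, and the dynamic
(shuffled) coloring model across redistribution rates ``p``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .closed_form import FitnessScheme, fixation_uniform
from .graphs import build_family
from .markov import (
    DynamicColoringSpec,
    absorption_solve,
    build_chain,
    build_dynamic_chain,
    permuted_coloring_sweep,
)

__all__ = ["selection_grid", "symmetric_sigma_sweep", "dynamic_sweep", "run_preset"]


def selection_grid(
    n_half: int = 50,
    r: float = 1.5,
    sigma_A_grid=None,
    sigma_B_grid=None,
) -> pd.DataFrame:
    """rho_A - rho_B over a (sigma_A, sigma_B) grid, N_G = N_R = n_half.

    Uses the closed form on a regular bipartite graph with fitness
    ``a = r -+ sigma_A``, ``b = 1 -+ sigma_B``; the sign of the
    difference flips exactly on the curve ``r^2 - sigma_A^2 = 1 -
    sigma_B^2``.
    """
    sigma_A_grid = np.linspace(0, 0.95, 20) if sigma_A_grid is None else sigma_A_grid
    sigma_B_grid = np.linspace(0, 0.95, 20) if sigma_B_grid is None else sigma_B_grid
    rows = []
    for sa in sigma_A_grid:
        for sb in sigma_B_grid:
            if sa >= r or sb >= 1:
                continue
            f = FitnessScheme(r + sa, r - sa, 1 + sb, 1 - sb)
            res = fixation_uniform(n_half, n_half, 1.0, 1.0, f)
            rows.append(
                {
                    "sigma_A": float(sa),
                    "sigma_B": float(sb),
                    "r": r,
                    "rho_A": res.rho_A,
                    "rho_B": res.rho_B,
                    "diff": res.rho_A - res.rho_B,
                }
            )
    return pd.DataFrame(rows)


def symmetric_sigma_sweep(
    n_half: int = 5, r_grid=(0.9, 1.1, 1.5), sigma_grid=None
) -> pd.DataFrame:
    """Closed-form rho_A against sigma on K_{n_half,n_half}."""
    sigma_grid = np.linspace(0, 0.85, 18) if sigma_grid is None else sigma_grid
    rows = []
    for r in r_grid:
        for sigma in sigma_grid:
            if sigma >= min(r, 1):
                continue
            f = FitnessScheme.from_sigma(r, float(sigma))
            res = fixation_uniform(n_half, n_half, float(n_half), float(n_half), f)
            rows.append(
                {"r": float(r), "sigma": float(sigma), "rho_A": res.rho_A, "rho_B": res.rho_B}
            )
    return pd.DataFrame(rows)


def dynamic_sweep(
    family: str = "complete_bipartite",
    sizes: tuple = (3, 3),
    r: float = 1.5,
    sigma_grid=None,
    p_grid=(0.0, 0.1, 0.5, 1.0),
    shuffle_first: bool = True,
) -> pd.DataFrame:
    """Exact dynamic-coloring rho_A over (sigma, p) grids."""
    sigma_grid = np.linspace(0, 0.8, 9) if sigma_grid is None else sigma_grid
    graph = build_family(family, *sizes)
    rows = []
    for p in p_grid:
        spec = DynamicColoringSpec(p=float(p), shuffle_first=shuffle_first)
        for sigma in sigma_grid:
            if sigma >= min(r, 1):
                continue
            f = FitnessScheme.from_sigma(r, float(sigma))
            if p == 0.0:
                rho = absorption_solve(build_chain(graph, f)).rho_A
            else:
                rho = absorption_solve(build_dynamic_chain(graph, f, spec)).rho_A
            rows.append({"p": float(p), "sigma": float(sigma), "r": r, "rho_A": rho})
    return pd.DataFrame(rows)


def run_preset(name: str) -> pd.DataFrame:
    """Named sweep presets (fig2 .. fig5 style setups, desk scale)."""
    from .graphs import GREEN, RED, recolor

    sigma = np.linspace(0, 0.6, 7)

    def star_green_center(n):
        star = build_family("star", n)
        colors = np.array([GREEN] + [RED] * (n - 1), dtype="U1")
        return recolor(star, colors)

    presets = {
        "fig2": lambda: selection_grid(),
        "fig3": lambda: symmetric_sigma_sweep(n_half=5),
        "fig4a": lambda: permuted_coloring_sweep(build_family("cycle", 6), 1.5, sigma),
        "fig4b": lambda: permuted_coloring_sweep(star_green_center(8), 1.5, sigma),
        "fig4c": lambda: permuted_coloring_sweep(
            build_family("complete_bipartite", 3, 7), 0.9, np.linspace(0, 2.0, 6)
        ),
        "fig5": lambda: dynamic_sweep(),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]()
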