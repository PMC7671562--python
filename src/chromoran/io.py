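"""File formats: TSV edge lists and color tables, JSON summaries.

Edge lists are ``u<TAB>v[<TAB>weight]`` rows; color tables are
``node<TAB>color`` rows with color in ``{G, R}``.  Node labels are
arbitrary strings, mapped to 0-based indices in first-seen order (the
color file is read first when present, so it fixes the ordering).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .graphs import COLORS, ColoredGraph, degree_profile, validate_proper_coloring

__all__ = [
    "read_colors",
    "read_graph",
    "write_graph",
    "write_colors",
    "graph_summary",
]


def _parse_rows(path, n_fields_min, n_fields_max, what):
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not n_fields_min <= len(fields) <= n_fields_max:
            raise ValueError(f"{path}:{lineno}: malformed {what} row: {line!r}")
        rows.append((lineno, fields))
    return rows


def read_colors(path) -> dict[str, str]:
    """Node -> color mapping from a two-column TSV."""
    out: dict[str, str] = {}
    for lineno, fields in _parse_rows(path, 2, 2, "color"):
        node, color = fields
        if color not in COLORS:
            raise ValueError(f"{path}:{lineno}: color must be one of {COLORS}")
        out[node] = color
    return out


def read_graph(
    edges_path, colors_path, undirected: bool = True
) -> tuple[ColoredGraph, list[str]]:
    """A ColoredGraph plus the node-label order used for indexing."""
    colors = read_colors(colors_path)
    labels: list[str] = list(colors)
    index = {lab: i for i, lab in enumerate(labels)}

    parsed = []
    for lineno, fields in _parse_rows(edges_path, 2, 3, "edge"):
        u, v = fields[0], fields[1]
        try:
            w = float(fields[2]) if len(fields) == 3 else 1.0
        except ValueError:
            raise ValueError(f"{edges_path}:{lineno}: bad weight {fields[2]!r}")
        for lab in (u, v):
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
        parsed.append((index[u], index[v], w))

    n = len(labels)
    missing = [lab for lab in labels if lab not in colors]
    if missing:
        raise ValueError(f"nodes missing from the color table: {missing}")
    W = np.zeros((n, n))
    for i, j, w in parsed:
        W[i, j] = w
        if undirected:
            W[j, i] = w
    color_vec = np.array([colors[lab] for lab in labels], dtype="U1")
    return ColoredGraph(W, color_vec, directed=not undirected), labels


def write_graph(graph: ColoredGraph, edges_path, colors_path, labels=None) -> None:
    labels = labels or [str(i) for i in range(graph.n_nodes)]
    lines = []
    W = graph.weights
    for i in range(graph.n_nodes):
        j_start = 0 if graph.directed else i + 1
        for j in range(j_start, graph.n_nodes):
            if W[i, j] > 0:
                lines.append(f"{labels[i]}\t{labels[j]}\t{W[i, j]:g}")
    Path(edges_path).write_text("\n".join(lines) + "\n")
    write_colors(graph, colors_path, labels)


def write_colors(graph: ColoredGraph, path, labels=None) -> None:
    labels = labels or [str(i) for i in range(graph.n_nodes)]
    Path(path).write_text(
        "\n".join(f"{lab}\t{c}" for lab, c in zip(labels, graph.colors)) + "\n"
    )


def graph_summary(graph: ColoredGraph) -> str:
    """JSON summary of size, color counts, degrees and properness."""
    prof = degree_profile(graph)
    return json.dumps(
        {
            "n_nodes": graph.n_nodes,
            "n_green": graph.n_green,
            "n_red": graph.n_red,
            "directed": graph.directed,
            "proper": validate_proper_coloring(graph),
            "biregular": prof.biregular,
            "k_G": None if np.isnan(prof.k_G) else prof.k_G,
            "k_R": None if np.isnan(prof.k_R) else prof.k_R,
        },
        indent=2,
    )
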