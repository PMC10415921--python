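"""Two-row bipartite diagrams of a graph under a candidate node ordering.

Every node is drawn twice, as a source (top row) and as a destination
(bottom row), left to right by rank; each edge is one straight line between
the rows, colored by its label.  Under a valid Wheeler ordering 0-indegree
nodes sit leftmost and no two same-color lines cross, which makes the
Wheeler conditions visually obvious; for an invalid ordering the crossings
are drawn as-is and counted.

The crossing count is combinatorial -- two distinct same-label edges
(u, v), (u', v') cross iff (rank u - rank u')(rank v - rank v') < 0 -- so
glyph styling cannot change it, and a zero count for every label is exactly
the same-label Wheeler condition.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .graph import LabeledDigraph, NodeOrdering, _require_bijection

#: Fixed palette, assigned to labels in alphabet order, cycling beyond.
PALETTE = [
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3",
    "#ff7f00", "#a65628", "#f781bf", "#17becf",
]

_UNIT = 60  # horizontal pixels per rank
_ROW_TOP = 70
_ROW_BOTTOM = 250
_RADIUS = 14


def count_same_label_crossings(g: LabeledDigraph, ordering: NodeOrdering) -> int:
    """Number of unordered pairs of distinct same-label edges that cross."""
    _require_bijection(g, ordering)
    total = 0
    by_label: Dict[str, List[Tuple[int, int]]] = {}
    for u, v, a in g.edges:
        by_label.setdefault(a, []).append((ordering[u], ordering[v]))
    for pairs in by_label.values():
        for x in range(len(pairs)):
            ru, rv = pairs[x]
            for y in range(x + 1, len(pairs)):
                ru2, rv2 = pairs[y]
                if (ru - ru2) * (rv - rv2) < 0:
                    total += 1
    return total


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def render_bipartite(
    g: LabeledDigraph, ordering: NodeOrdering, out_path: Optional[str] = None
) -> str:
    """Render the two-row diagram as SVG text; optionally write it to a file.

    Output is deterministic: identical graph and ordering yield byte-identical
    SVG.
    """
    _require_bijection(g, ordering)
    alphabet = g.alphabet
    color = {a: PALETTE[i % len(PALETTE)] for i, a in enumerate(alphabet)}
    by_rank = sorted(g.nodes, key=lambda v: ordering[v])
    n = len(by_rank)
    width = max(n, 1) * _UNIT + 220
    height = _ROW_BOTTOM + 70

    parts: List[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        '<style>text{font-family:monospace;font-size:11px}</style>',
        f'<text x="10" y="20">sources (top) and destinations (bottom) in rank order</text>',
    ]

    def x_of(node: str) -> int:
        return ordering[node] * _UNIT

    for u, v, a in g.edges:
        parts.append(
            f'<line x1="{x_of(u)}" y1="{_ROW_TOP + _RADIUS}" '
            f'x2="{x_of(v)}" y2="{_ROW_BOTTOM - _RADIUS}" '
            f'stroke="{color[a]}" stroke-width="1.5"/>'
        )
    for y in (_ROW_TOP, _ROW_BOTTOM):
        for node in by_rank:
            x = x_of(node)
            parts.append(
                f'<circle cx="{x}" cy="{y}" r="{_RADIUS}" fill="white" stroke="black"/>'
            )
            parts.append(
                f'<text x="{x}" y="{y + 4}" text-anchor="middle">{_esc(node)}</text>'
            )

    legend_x = max(n, 1) * _UNIT + 40
    parts.append(f'<text x="{legend_x}" y="{_ROW_TOP - 10}">labels</text>')
    for i, a in enumerate(alphabet):
        y = _ROW_TOP + 16 * (i + 1)
        parts.append(
            f'<line x1="{legend_x}" y1="{y - 4}" x2="{legend_x + 24}" y2="{y - 4}" '
            f'stroke="{color[a]}" stroke-width="3"/>'
        )
        parts.append(f'<text x="{legend_x + 30}" y="{y}">{_esc(a)}</text>')
    crossings = count_same_label_crossings(g, ordering)
    parts.append(
        f'<text x="10" y="{height - 15}">same-label crossings: {crossings}</text>'
    )
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(svg)
    return svg
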