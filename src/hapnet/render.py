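"""Deterministic layout and export of haplotype networks.

Layouts come from a seeded force-directed (Fruchterman–Reingold) run per
connected component, with components then placed side by side.  Export
targets are GraphML — attribute-complete and re-readable into an equal
graph — and SVG 1.1 with frequency-scaled circles (area proportional to
count), subset colouring, per-edge mutation marks, optional curved
co-occurrence connectors, and one grey hull polygon per field for
recombination.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .errors import ParseError
from .haploweb import FFR, CoOccurrence
from .networks import HaploGraph

#: fixed qualitative palette, assigned in subset order (Set2-like)
PALETTE = [
    "#66c2a5", "#fc8d62", "#8da0cb", "#e78ac3", "#a6d854",
    "#ffd92f", "#e5c494", "#b3b3b3", "#1b9e77", "#d95f02",
]

MIN_RADIUS = 6.0
INFERRED_RADIUS = 3.0
RADIUS_SCALE = 6.0


def node_radius(count: int, sampled: bool) -> float:
    """Area-proportional scaling with a floor; inferred nodes stay small."""
    if not sampled or count <= 0:
        return INFERRED_RADIUS
    return max(MIN_RADIUS, RADIUS_SCALE * math.sqrt(count))


def subset_colors(subsets: list[str],
                  overrides: Optional[dict[str, str]] = None) -> dict[str, str]:
    colors = {
        s: PALETTE[i % len(PALETTE)] for i, s in enumerate(subsets)
    }
    if overrides:
        colors.update(overrides)
    return colors


def read_color_config(path) -> dict[str, str]:
    """Plain ``subset<TAB>#RRGGBB`` lines."""
    out = {}
    with open(path) as fh:
        for num, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[1].startswith("#"):
                raise ParseError(f"color config line {num}: expected 'subset\\t#RRGGBB'")
            out[parts[0]] = parts[1]
    return out


@dataclass
class LayoutedGraph:
    graph: HaploGraph
    positions: dict[str, tuple[float, float]]
    colors: dict[str, str] = field(default_factory=dict)


def _component_layout(sub: nx.Graph, seed: int) -> dict:
    if sub.number_of_nodes() == 1:
        return {next(iter(sub.nodes)): (0.0, 0.0)}
    return nx.spring_layout(sub, seed=seed, weight="steps", scale=100.0)


def layout_graph(g: HaploGraph, seed: int = 42,
                 colors: Optional[dict[str, str]] = None) -> LayoutedGraph:
    """Seeded spring layout; disconnected components side by side."""
    positions: dict[str, tuple[float, float]] = {}
    offset_x = 0.0
    gap = 60.0
    comps = sorted(nx.connected_components(g.graph), key=lambda c: sorted(c)[0])
    if not comps:
        return LayoutedGraph(g, {}, colors or {})
    for k, comp in enumerate(comps):
        sub = g.graph.subgraph(comp)
        pos = _component_layout(sub, seed + k)
        xs = [p[0] for p in pos.values()]
        ys = [p[1] for p in pos.values()]
        shift = offset_x - min(xs)
        for n, (x, y) in pos.items():
            positions[n] = (round(x + shift, 6), round(y - min(ys), 6))
        offset_x += (max(xs) - min(xs)) + gap
    # guarantee distinct positions (degenerate layouts only)
    seen = {}
    for n in sorted(positions):
        p = positions[n]
        while p in seen:
            p = (p[0] + 1.0, p[1] + 1.0)
        positions[n] = p
        seen[p] = n
    subsets = sorted({
        s for _, d in g.graph.nodes(data=True) for s in d["per_subset"]
    })
    return LayoutedGraph(g, positions, subset_colors(subsets, colors))


# ---------------------------------------------------------------------------
# GraphML


def export_graphml(lg: LayoutedGraph, path) -> None:
    out = nx.Graph()
    for n in sorted(lg.graph.graph.nodes):
        d = lg.graph.graph.nodes[n]
        x, y = lg.positions[n]
        out.add_node(
            n,
            sequence=d["sequence"] or "",
            sampled=bool(d["sampled"]),
            count=int(d["count"]),
            per_subset=json.dumps(d["per_subset"], sort_keys=True),
            x=float(x),
            y=float(y),
        )
    for a, b, d in sorted(
        lg.graph.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
    ):
        out.add_edge(a, b, steps=int(d["steps"]))
    nx.write_graphml(out, path)


def import_graphml(path) -> tuple[HaploGraph, dict[str, tuple[float, float]]]:
    try:
        raw = nx.read_graphml(path)
    except Exception as exc:
        raise ParseError(f"cannot read GraphML {path}: {exc}") from exc
    g = HaploGraph()
    positions = {}
    for n, d in raw.nodes(data=True):
        g.add_node(
            n,
            sequence=d.get("sequence") or None,
            sampled=bool(d.get("sampled", False)),
            count=int(d.get("count", 0)),
            per_subset=json.loads(d.get("per_subset", "{}")),
        )
        positions[n] = (float(d.get("x", 0.0)), float(d.get("y", 0.0)))
    for a, b, d in raw.edges(data=True):
        g.add_edge(a, b, int(d["steps"]))
    return g, positions


# ---------------------------------------------------------------------------
# SVG


def _dominant_color(d: dict, colors: dict[str, str]) -> str:
    if not d["per_subset"]:
        return "#cccccc" if d["sampled"] else "#555555"
    subset = max(sorted(d["per_subset"]), key=lambda s: d["per_subset"][s])
    return colors.get(subset, "#cccccc")


def _edge_marks(x1, y1, x2, y2, steps: int, mode: str) -> list[str]:
    parts = []
    if mode == "labels":
        mx, my = (x1 + x2) / 2, (y1 + y2) / 2
        parts.append(
            f'<text x="{mx:.2f}" y="{my - 3:.2f}" font-size="9" '
            f'text-anchor="middle" class="steps">{steps}</text>'
        )
        return parts
    # ticks: short perpendicular dashes evenly spaced along the edge
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy) or 1.0
    px, py = -dy / norm * 4, dx / norm * 4
    for k in range(1, steps + 1):
        t = k / (steps + 1)
        cx, cy = x1 + t * dx, y1 + t * dy
        parts.append(
            f'<line x1="{cx - px:.2f}" y1="{cy - py:.2f}" '
            f'x2="{cx + px:.2f}" y2="{cy + py:.2f}" '
            f'stroke="#333333" stroke-width="1" class="tick"/>'
        )
    return parts


def _convex_hull(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Andrew's monotone chain; handles collinear and tiny inputs."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def _pad_polygon(points, pad: float):
    if not points:
        return []
    cx = sum(p[0] for p in points) / len(points)
    cy = sum(p[1] for p in points) / len(points)
    out = []
    for x, y in points:
        dx, dy = x - cx, y - cy
        norm = math.hypot(dx, dy)
        if norm == 0:
            out.extend([(x - pad, y - pad), (x + pad, y - pad),
                        (x + pad, y + pad), (x - pad, y + pad)])
        else:
            out.append((x + dx / norm * pad, y + dy / norm * pad))
    return out


def export_svg(
    lg: LayoutedGraph,
    path,
    mutation_marks: str = "ticks",
    ffr_hulls: bool = False,
    cooccurrence: bool = False,
    ffrs: Optional[list[FFR]] = None,
    cooc: Optional[CoOccurrence] = None,
) -> None:
    if mutation_marks not in ("ticks", "labels"):
        raise ValueError("mutation_marks must be 'ticks' or 'labels'")
    g = lg.graph.graph
    pos = lg.positions
    pad = 40.0
    xs = [p[0] for p in pos.values()] or [0.0]
    ys = [p[1] for p in pos.values()] or [0.0]
    minx, maxx = min(xs) - pad, max(xs) + pad
    miny, maxy = min(ys) - pad, max(ys) + pad
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="{minx:.2f} {miny:.2f} {maxx - minx:.2f} {maxy - miny:.2f}">',
    ]
    if ffr_hulls and ffrs:
        for ffr in ffrs:
            points = [pos[h] for h in sorted(ffr.haplotypes) if h in pos]
            if not points:
                continue
            hull = _pad_polygon(_convex_hull(points), 18.0)
            coords = " ".join(f"{x:.2f},{y:.2f}" for x, y in hull)
            parts.append(
                f'<polygon points="{coords}" fill="#dddddd" stroke="none" '
                f'class="ffr-hull" opacity="0.7"/>'
            )
    for a, b, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        (x1, y1), (x2, y2) = pos[a], pos[b]
        parts.append(
            f'<path d="M {x1:.2f} {y1:.2f} L {x2:.2f} {y2:.2f}" '
            f'stroke="#333333" stroke-width="1.5" fill="none" class="edge"/>'
        )
        parts.extend(_edge_marks(x1, y1, x2, y2, d["steps"], mutation_marks))
    if cooccurrence and cooc:
        for h1, h2, inds in cooc.pairs:
            if h1 not in pos or h2 not in pos:
                continue
            (x1, y1), (x2, y2) = pos[h1], pos[h2]
            mx, my = (x1 + x2) / 2, (y1 + y2) / 2 - 25.0
            dash = ' stroke-dasharray="4 3"' if len(inds) == 1 else ""
            parts.append(
                f'<path d="M {x1:.2f} {y1:.2f} Q {mx:.2f} {my:.2f} '
                f'{x2:.2f} {y2:.2f}" stroke="#884488" stroke-width="1.2" '
                f'fill="none" class="cooccurrence"{dash}/>'
            )
    for n in sorted(g.nodes):
        d = g.nodes[n]
        x, y = pos[n]
        r = node_radius(d["count"], d["sampled"])
        fill = _dominant_color(d, lg.colors)
        parts.append(
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{r:.2f}" fill="{fill}" '
            f'stroke="#222222" stroke-width="1" class="node"/>'
        )
        if d["sampled"]:
            parts.append(
                f'<text x="{x:.2f}" y="{y + 3:.2f}" font-size="9" '
                f'text-anchor="middle" class="label">{n}</text>'
            )
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")


def export_graph(
    lg: LayoutedGraph,
    path,
    format: str = "graphml",
    mutation_marks: str = "ticks",
    ffr_hulls: bool = False,
    cooccurrence: bool = False,
    ffrs: Optional[list[FFR]] = None,
    cooc: Optional[CoOccurrence] = None,
) -> None:
    """Write the layouted graph as GraphML or SVG."""
    if format == "graphml":
        export_graphml(lg, path)
    elif format == "svg":
        export_svg(lg, path, mutation_marks=mutation_marks,
                   ffr_hulls=ffr_hulls, cooccurrence=cooccurrence,
                   ffrs=ffrs, cooc=cooc)
    else:
        raise ValueError(f"unknown export format {format!r}")
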