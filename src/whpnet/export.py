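"""Gephi-compatible graph serialization and the temporal panel figure.

Graphs are written as GEXF (1.2draft schema, the broadest Gephi
compatibility), GraphML, or a paired node/edge CSV in Gephi's import
dialect (edge columns ``source,target,type,weight`` with
``type=Undirected``).  An internal reader covers the same three formats so
round trips can be verified without external tooling.

The panel figure mirrors the standard presentation of affiliation-network
development: one column per work step; top row the cumulative two-mode
network (organizations one color, events another), bottom row the one-mode
projection with edge thickness proportional to weight.  The layout is a
seeded force-directed (Fruchterman–Reingold) embedding — reproducible under
a fixed seed, but no attempt is made to match any particular GUI tool's
coordinates.
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .network import OneModeNetwork, TwoModeNetwork, build_two_mode, project_one_mode
from .participation import ParticipationTable

__all__ = [
    "GraphDoc",
    "FORMATS",
    "write_graph",
    "read_graph",
    "graph_doc",
    "spring_layout",
    "render_panels",
]

FORMATS = ("gexf", "graphml", "csv")

_GEXF_NS = "http://www.gexf.net/1.2draft"
_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


@dataclass(frozen=True)
class GraphDoc:
    """Format-independent view of a serialized graph, used for round trips."""

    nodes: dict[str, dict[str, str]]  # id -> {mode, stakeholder_group}
    edges: dict[tuple[str, str], float]  # sorted pair -> weight
    undirected: bool


def graph_doc(g: TwoModeNetwork | OneModeNetwork) -> GraphDoc:
    """The GraphDoc a writer will emit for ``g`` (ground truth for tests)."""
    nodes: dict[str, dict[str, str]] = {}
    edges: dict[tuple[str, str], float] = {}
    if isinstance(g, TwoModeNetwork):
        for org, group in g.org_groups.items():
            nodes[org] = {"mode": "organization",
                          "stakeholder_group": group.fine_label}
        for ev in g.event_ids:
            nodes[ev] = {"mode": "event", "stakeholder_group": ""}
        for org, ev in g.edges:
            key = (org, ev) if org < ev else (ev, org)
            edges[key] = 1.0
    elif isinstance(g, OneModeNetwork):
        for org, group in g.node_groups.items():
            nodes[org] = {"mode": "organization",
                          "stakeholder_group": group.fine_label}
        for pair, w in g.weights.items():
            edges[pair] = float(w)
    else:
        raise TypeError(f"cannot serialize {type(g).__name__}")
    return GraphDoc(nodes, edges, undirected=True)


def _csv_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("") if path.suffix.lower() == ".csv" else path
    return (stem.parent / f"{stem.name}_nodes.csv",
            stem.parent / f"{stem.name}_edges.csv")


def write_graph(g: TwoModeNetwork | OneModeNetwork, path: str | Path,
                format: str = "gexf") -> list[Path]:
    """Serialize a graph; returns the files written.

    ``csv`` writes two files (``<stem>_nodes.csv`` and ``<stem>_edges.csv``);
    the other formats write exactly ``path``.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    doc = graph_doc(g)
    path = Path(path)
    if format == "gexf":
        _write_gexf(doc, path)
        return [path]
    if format == "graphml":
        _write_graphml(doc, path)
        return [path]
    node_path, edge_path = _csv_paths(path)
    with node_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label", "mode", "stakeholder_group"])
        for nid in sorted(doc.nodes):
            attrs = doc.nodes[nid]
            w.writerow([nid, nid, attrs["mode"], attrs["stakeholder_group"]])
    with edge_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "type", "weight"])
        for (u, v), wt in sorted(doc.edges.items()):
            w.writerow([u, v, "Undirected", _fmt_weight(wt)])
    return [node_path, edge_path]


def _fmt_weight(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(w)


def _write_gexf(doc: GraphDoc, path: Path) -> None:
    ET.register_namespace("", _GEXF_NS)
    root = ET.Element(f"{{{_GEXF_NS}}}gexf", version="1.2")
    graph = ET.SubElement(root, f"{{{_GEXF_NS}}}graph",
                          defaultedgetype="undirected", mode="static")
    attrs = ET.SubElement(graph, f"{{{_GEXF_NS}}}attributes", attrib={"class": "node"})
    ET.SubElement(attrs, f"{{{_GEXF_NS}}}attribute",
                  id="0", title="mode", type="string")
    ET.SubElement(attrs, f"{{{_GEXF_NS}}}attribute",
                  id="1", title="stakeholder_group", type="string")
    nodes_el = ET.SubElement(graph, f"{{{_GEXF_NS}}}nodes")
    for nid in sorted(doc.nodes):
        node_el = ET.SubElement(nodes_el, f"{{{_GEXF_NS}}}node", id=nid, label=nid)
        av = ET.SubElement(node_el, f"{{{_GEXF_NS}}}attvalues")
        ET.SubElement(av, f"{{{_GEXF_NS}}}attvalue", attrib={
            "for": "0", "value": doc.nodes[nid]["mode"]})
        ET.SubElement(av, f"{{{_GEXF_NS}}}attvalue", attrib={
            "for": "1", "value": doc.nodes[nid]["stakeholder_group"]})
    edges_el = ET.SubElement(graph, f"{{{_GEXF_NS}}}edges")
    for i, ((u, v), w) in enumerate(sorted(doc.edges.items())):
        ET.SubElement(edges_el, f"{{{_GEXF_NS}}}edge", id=str(i),
                      source=u, target=v, weight=_fmt_weight(w))
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def _write_graphml(doc: GraphDoc, path: Path) -> None:
    ET.register_namespace("", _GRAPHML_NS)
    root = ET.Element(f"{{{_GRAPHML_NS}}}graphml")
    for key_id, name, typ, dom in (
        ("d_mode", "mode", "string", "node"),
        ("d_group", "stakeholder_group", "string", "node"),
        ("d_weight", "weight", "double", "edge"),
    ):
        ET.SubElement(root, f"{{{_GRAPHML_NS}}}key", attrib={
            "id": key_id, "attr.name": name, "attr.type": typ, "for": dom})
    graph = ET.SubElement(root, f"{{{_GRAPHML_NS}}}graph",
                          id="G", edgedefault="undirected")
    for nid in sorted(doc.nodes):
        node_el = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}node", id=nid)
        for key_id, attr in (("d_mode", "mode"), ("d_group", "stakeholder_group")):
            data = ET.SubElement(node_el, f"{{{_GRAPHML_NS}}}data", key=key_id)
            data.text = doc.nodes[nid][attr]
    for (u, v), w in sorted(doc.edges.items()):
        edge_el = ET.SubElement(graph, f"{{{_GRAPHML_NS}}}edge", source=u, target=v)
        data = ET.SubElement(edge_el, f"{{{_GRAPHML_NS}}}data", key="d_weight")
        data.text = _fmt_weight(w)
    ET.ElementTree(root).write(path, encoding="utf-8", xml_declaration=True)


def read_graph(path: str | Path, format: str = "gexf") -> GraphDoc:
    """Re-read a serialized graph (any of the supported formats)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if format == "gexf":
        return _read_gexf(path)
    if format == "graphml":
        return _read_graphml(path)
    return _read_csv(path)


def _sorted_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


def _read_gexf(path: Path) -> GraphDoc:
    root = ET.parse(path).getroot()
    ns = {"g": _GEXF_NS}
    graph = root.find("g:graph", ns)
    undirected = graph.get("defaultedgetype") == "undirected"
    titles = {a.get("id"): a.get("title")
              for a in graph.findall("g:attributes/g:attribute", ns)}
    nodes: dict[str, dict[str, str]] = {}
    for node in graph.findall("g:nodes/g:node", ns):
        attrs = {"mode": "", "stakeholder_group": ""}
        for av in node.findall("g:attvalues/g:attvalue", ns):
            attrs[titles[av.get("for")]] = av.get("value")
        nodes[node.get("id")] = attrs
    edges = {
        _sorted_pair(e.get("source"), e.get("target")): float(e.get("weight", 1.0))
        for e in graph.findall("g:edges/g:edge", ns)
    }
    return GraphDoc(nodes, edges, undirected)


def _read_graphml(path: Path) -> GraphDoc:
    root = ET.parse(path).getroot()
    ns = {"g": _GRAPHML_NS}
    names = {k.get("id"): k.get("attr.name") for k in root.findall("g:key", ns)}
    graph = root.find("g:graph", ns)
    undirected = graph.get("edgedefault") == "undirected"
    nodes: dict[str, dict[str, str]] = {}
    for node in graph.findall("g:node", ns):
        attrs = {"mode": "", "stakeholder_group": ""}
        for data in node.findall("g:data", ns):
            attrs[names[data.get("key")]] = data.text or ""
        nodes[node.get("id")] = attrs
    edges: dict[tuple[str, str], float] = {}
    for edge in graph.findall("g:edge", ns):
        w = 1.0
        for data in edge.findall("g:data", ns):
            if names[data.get("key")] == "weight":
                w = float(data.text)
        edges[_sorted_pair(edge.get("source"), edge.get("target"))] = w
    return GraphDoc(nodes, edges, undirected)


def _read_csv(path: Path) -> GraphDoc:
    node_path, edge_path = _csv_paths(path)
    nodes: dict[str, dict[str, str]] = {}
    with node_path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            nodes[row["id"]] = {"mode": row["mode"],
                                "stakeholder_group": row["stakeholder_group"]}
    edges: dict[tuple[str, str], float] = {}
    undirected = True
    with edge_path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            undirected &= row.get("type", "Undirected") == "Undirected"
            edges[_sorted_pair(row["source"], row["target"])] = float(row["weight"])
    return GraphDoc(nodes, edges, undirected)


# ---------------------------------------------------------------------------
# Layout and figure
# ---------------------------------------------------------------------------

def spring_layout(nodes: Sequence[str], edges: Mapping[tuple[str, str], float],
                  seed: int = 0, iterations: int = 60) -> dict[str, np.ndarray]:
    """Seeded Fruchterman–Reingold force-directed layout in the unit square.

    Deterministic for a given (nodes, edges, seed); edge weights act as
    spring strengths so repeatedly co-attending organizations sit closer.
    """
    n = len(nodes)
    if n == 0:
        return {}
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 2))
    if n == 1:
        return {nodes[0]: pos[0]}
    index = {node: i for i, node in enumerate(nodes)}
    k = 1.0 / np.sqrt(n)  # ideal pairwise distance
    adj = np.zeros((n, n))
    for (u, v), w in edges.items():
        adj[index[u], index[v]] = w
        adj[index[v], index[u]] = w
    t = 0.1
    dt = t / (iterations + 1)
    for _ in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        dist = np.clip(dist, 0.01, None)
        # repulsion k^2/d for all pairs, attraction w d^2/k along edges
        force = k * k / dist**2 - adj * dist / k
        disp = (delta * force[..., None]).sum(axis=1)
        length = np.clip(np.linalg.norm(disp, axis=1), 1e-9, None)
        pos += disp / length[:, None] * np.minimum(length, t)[:, None]
        t -= dt
    pos -= pos.min(axis=0)
    span = np.clip(pos.max(axis=0), 1e-9, None)
    pos /= span
    return {node: pos[i] for node, i in index.items()}


#: Default node colors: organizations vs events (two-mode row).
ORG_COLOR = "#c0392b"
EVENT_COLOR = "#27ae60"


def render_panels(table: ParticipationTable, out_path: str | Path,
                  layout_seed: int = 0, steps: Sequence[str] | None = None,
                  org_color: str = ORG_COLOR,
                  event_color: str = EVENT_COLOR) -> Path:
    """Render the two-row temporal panel figure.

    One column per cumulative work step; top row the two-mode network
    (organizations ``org_color``, events ``event_color``), bottom row the
    weighted one-mode projection with edge thickness proportional to
    weight.  Empty windows render as empty axes.  Node coordinates are
    deterministic for a given ``layout_seed``.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    step_ids = list(steps) if steps is not None else [
        e.id for e in sorted(table.events, key=lambda e: e.order)]
    ncol = len(step_ids)
    if ncol == 0:
        raise ValueError("need at least one work step to render")
    fig, axes = plt.subplots(2, ncol, figsize=(3.0 * ncol, 6.2), squeeze=False)
    for j, step_id in enumerate(step_ids):
        two = build_two_mode(table, step_id)
        one = project_one_mode(two)
        _draw_two_mode(axes[0][j], two, layout_seed, org_color, event_color)
        _draw_one_mode(axes[1][j], one, layout_seed, org_color)
        axes[0][j].set_title(step_id if step_id == table.events[0].id
                             else f"{table.events[0].id} to {step_id}", fontsize=10)
    axes[0][0].set_ylabel("two-mode", fontsize=10)
    axes[1][0].set_ylabel("one-mode", fontsize=10)
    out_path = Path(out_path)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _setup_axis(ax) -> None:
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_xlim(-0.1, 1.1)
    ax.set_ylim(-0.1, 1.1)
    for spine in ax.spines.values():
        spine.set_visible(False)


def _draw_two_mode(ax, g: TwoModeNetwork, seed: int,
                   org_color: str, event_color: str) -> None:
    _setup_axis(ax)
    nodes = sorted(g.org_groups) + list(g.event_ids)
    edges = {(org, ev): 1.0 for org, ev in g.edges}
    pos = spring_layout(nodes, edges, seed=seed)
    for org, ev in sorted(g.edges):
        p, q = pos[org], pos[ev]
        ax.plot([p[0], q[0]], [p[1], q[1]], color="0.7", lw=0.6, zorder=1)
    for node in nodes:
        is_event = node in set(g.event_ids)
        p = pos[node]
        ax.scatter([p[0]], [p[1]],
                   s=60 if is_event else 25,
                   color=event_color if is_event else org_color,
                   marker="s" if is_event else "o", zorder=2)


def _draw_one_mode(ax, g: OneModeNetwork, seed: int, org_color: str) -> None:
    _setup_axis(ax)
    nodes = g.nodes
    pos = spring_layout(nodes, g.weights, seed=seed)
    for (u, v), w in sorted(g.weights.items()):
        p, q = pos[u], pos[v]
        ax.plot([p[0], q[0]], [p[1], q[1]], color="0.6", lw=0.5 * w, zorder=1)
    for node in nodes:
        p = pos[node]
        ax.scatter([p[0]], [p[1]], s=25, color=org_color, zorder=2)
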