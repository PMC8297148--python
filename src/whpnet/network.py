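"""Two-mode affiliation networks and their weighted one-mode projections.

Organizations and events form a bipartite (two-mode) graph whose edges
record attendance.  Projecting the events away yields a one-mode network of
organizations in which two organizations are tied iff they co-attended at
least one event; the tie weight counts the co-attended events.  Network
views are always cumulative from the first work step, matching how the
monitoring compares each step against the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

from .participation import ParticipationTable, StakeholderGroup

__all__ = [
    "TwoModeNetwork",
    "OneModeNetwork",
    "build_two_mode",
    "project_one_mode",
    "weight_filtered_subgraph",
    "core_members",
]


@dataclass
class TwoModeNetwork:
    """Bipartite organization x event graph (edges unweighted)."""

    org_groups: Mapping[str, StakeholderGroup]
    event_ids: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)  # (org, event)

    def __post_init__(self) -> None:
        orgs = set(self.org_groups)
        events = set(self.event_ids)
        for org, ev in self.edges:
            if org not in orgs or ev not in events:
                raise ValueError(f"edge ({org!r}, {ev!r}) joins unknown nodes")
        deg = {org: 0 for org in orgs}
        for org, _ in self.edges:
            deg[org] += 1
        isolated = sorted(o for o, d in deg.items() if d == 0)
        if isolated:
            raise ValueError(f"organization nodes without attendance: {isolated}")

    @property
    def n_orgs(self) -> int:
        return len(self.org_groups)

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    def attendees(self, event_id: str) -> set[str]:
        return {org for org, ev in self.edges if ev == event_id}

    def events_of(self, org: str) -> set[str]:
        return {ev for o, ev in self.edges if o == org}


@dataclass
class OneModeNetwork:
    """Weighted undirected organization network.

    Edge keys are sorted 2-tuples of node ids; weights are positive integers
    (number of shared events).  No self-loops.
    """

    node_groups: Mapping[str, StakeholderGroup]
    weights: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed: dict[tuple[str, str], int] = {}
        for (u, v), w in self.weights.items():
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u not in self.node_groups or v not in self.node_groups:
                raise ValueError(f"edge ({u!r}, {v!r}) joins unknown nodes")
            if w < 1:
                raise ValueError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
            key = (u, v) if u < v else (v, u)
            if key in fixed and fixed[key] != w:
                raise ValueError(f"conflicting weights for edge {key}")
            fixed[key] = int(w)
        self.weights = fixed

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_groups)

    @property
    def n_nodes(self) -> int:
        return len(self.node_groups)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def weight(self, u: str, v: str) -> int:
        key = (u, v) if u < v else (v, u)
        return self.weights.get(key, 0)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.node_groups}
        for u, v in self.weights:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def build_two_mode(table: ParticipationTable, upto_step: str,
                   keep_empty_events: bool = False) -> TwoModeNetwork:
    """Cumulative two-mode network over the window T1..upto_step.

    Contains exactly the events with order <= order(upto_step) and the
    organizations with at least one attendance among them.  Events nobody in
    the table attended are dropped unless ``keep_empty_events`` (useful for
    visualization panels that should show every scheduled event).
    """
    window = table.steps_upto(upto_step)  # raises on unknown step
    edges = {
        (row.org, e.id)
        for row in table.rows
        for e in window
        if row.attended(e.id)
    }
    attending = {org for org, _ in edges}
    org_groups = {r.org: r.group for r in table.rows if r.org in attending}
    if keep_empty_events:
        event_ids = [e.id for e in window]
    else:
        used = {ev for _, ev in edges}
        event_ids = [e.id for e in window if e.id in used]
    return TwoModeNetwork(org_groups, event_ids, edges)


def project_one_mode(g: TwoModeNetwork) -> OneModeNetwork:
    """Project events onto weighted ties between organizations.

    Two organizations are adjacent iff they co-attend >= 1 event; the edge
    weight is the number of events both attend.  The organization node set
    is preserved (an organization whose events nobody shares stays as an
    isolated node).
    """
    weights: dict[tuple[str, str], int] = {}
    for ev in g.event_ids:
        for u, v in combinations(sorted(g.attendees(ev)), 2):
            weights[(u, v)] = weights.get((u, v), 0) + 1
    return OneModeNetwork(dict(g.org_groups), weights)


def weight_filtered_subgraph(g: OneModeNetwork, min_weight: int) -> OneModeNetwork:
    """Keep ties of weight >= min_weight and the nodes incident to one.

    With ``min_weight=1`` this is the restriction to non-isolated nodes
    (identity on any projection where everyone shares an event).
    """
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    kept = {e: w for e, w in g.weights.items() if w >= min_weight}
    nodes = {n for e in kept for n in e}
    return OneModeNetwork({n: g.node_groups[n] for n in nodes}, kept)


def core_members(g: OneModeNetwork, min_weight: int = 2) -> set[str]:
    """Organizations in the recurring core: tied by weight >= min_weight.

    The default of 2 captures organizations that met each other repeatedly
    at events, the operational definition of the network's stable core.
    """
    return set(weight_filtered_subgraph(g, min_weight).node_groups)
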