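import numpy as np
import pytest

from whpnet.network import OneModeNetwork
from whpnet.participation import (
    FINE_GROUPS,
    OrganizationRow,
    ParticipationTable,
    StakeholderGroup,
    WorkStep,
)


def make_events(n):
    return [WorkStep(f"T{i}", f"Event {i}", "conception", i, "") for i in range(1, n + 1)]


def random_table(rng, max_orgs=30, max_events=6):
    """Random organization-level participation table (every org attends >=1 event)."""
    n_events = int(rng.integers(1, max_events + 1))
    n_orgs = int(rng.integers(1, max_orgs + 1))
    events = make_events(n_events)
    p = rng.uniform(0.15, 0.85)
    rows = []
    for i in range(n_orgs):
        flags = {e.id: int(rng.random() < p) for e in events}
        if not any(flags.values()):
            flags[events[int(rng.integers(n_events))].id] = 1
        group = StakeholderGroup(FINE_GROUPS[int(rng.integers(len(FINE_GROUPS)))])
        rows.append(OrganizationRow(f"O{i:02d}", group, flags))
    return ParticipationTable(events, rows)


def random_one_mode(rng, max_nodes=30, max_weight=4):
    """Random weighted undirected graph wrapped as a OneModeNetwork."""
    n = int(rng.integers(1, max_nodes + 1))
    nodes = [f"N{i:02d}" for i in range(n)]
    group = StakeholderGroup("company")
    p = rng.uniform(0.05, 0.9)
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                weights[(nodes[i], nodes[j])] = int(rng.integers(1, max_weight + 1))
    return OneModeNetwork({v: group for v in nodes}, weights)


def to_networkx(g: OneModeNetwork):
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(g.node_groups)
    for (u, v), w in g.weights.items():
        G.add_edge(u, v, weight=w)
    return G


@pytest.fixture
def events5():
    return make_events(5)


@pytest.fixture
def rng():
    return np.random.default_rng(20210626)
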