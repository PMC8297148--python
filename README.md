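# whpnet

Monitoring the development of cross-company health-promotion networks with
social network analysis.

Cross-company networks — companies, exercise providers and local partners
(public bodies, society/politics, economy) jointly organizing workplace
health promotion — develop through a sequence of events: letters of intent,
on-site consultations, stakeholder workshops, steering-group meetings.
`whpnet` turns the participation records a network manager keeps at those
events into quantitative evidence of how the network grows and densifies,
for public-health practitioners and evaluators who need to monitor and
report that development without hand-driving a GUI tool.

## The model

Attendance defines an **affiliation (two-mode) network**: a bipartite graph
with organization nodes and event nodes, where an edge records that an
organization attended an event. Every organization that attended at least
one event is a network member; people are collapsed to their organization.
For each work step *Tk* the package builds the cumulative two-mode network
over the window *T1..Tk* and projects the events away, giving a weighted
**one-mode network** of organizations in which

* two organizations are tied iff they co-attended ≥ 1 event, and
* the tie weight is the number of co-attended events.

On each cumulative one-mode snapshot it computes the global measure suite,
all self-implemented: number of nodes *N* and edges *E*; average degree
2*E*/*N* and average weighted degree (mean of summed incident tie weights);
network diameter and average path length (unweighted shortest paths);
density 2*E*/(*N*(*N*−1)); triangle count; and the average local clustering
coefficient c(v) = (# edges among neighbors of v)/C(deg v, 2). The
**core network** is the subgraph of ties with weight ≥ 2 — organizations
that met repeatedly. A seedable growth simulator (Poisson newcomer
arrivals, Bernoulli repeat attendance) generates realistic tables for
testing and what-if exploration, and graphs export to GEXF / GraphML /
Gephi-style CSV plus a two-row temporal panel figure.

## Worked example

```python
from whpnet import build_two_mode, compute_all, fixture_t1_t2, project_one_mode

table = fixture_t1_t2()   # 2 events, 9 + 9 organizations, one shared
one = project_one_mode(build_two_mode(table, "T2"))
for key, value in compute_all(one).rounded().items():
    print(key, value)
```

prints

```
n_nodes 17
n_edges 72
avg_degree 8.5
avg_weighted_degree 8.5
diameter 2
avg_path_length 1.471
density 0.529
avg_clustering 0.969
n_triangles 168
```

Nine founding organizations all met at the first event, so that snapshot is
a complete graph (density 1, 84 triangles). The second event brought nine
attendees of which exactly one had been at the first, so the cumulative
network is two 9-cliques sharing a single bridging organization: 17 nodes,
72 edges, density 0.529, diameter 2 (any cross-clique pair is linked via
the bridge), clustering 0.969. More in `examples/` (parsing and
anonymization, five-step trajectories and core extraction, growth
simulation, Gephi export and panel figures), and on the command line:

```bash
whpnet fixtures five-step-study -o study.csv
whpnet trajectory study.csv
whpnet metrics study.csv --step T5 --min-weight 2
whpnet plot study.csv -o panels.png
```

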