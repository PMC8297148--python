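# Methods

## Data model

The unit of analysis is the **organization**; people appear only in the raw
collection sheet and are collapsed away. An organization's flag for an
event is the logical OR over its people's flags, and an organization with
no attendance at all is not a network member and is dropped during
aggregation. Two people of one organization carrying different fine
stakeholder groups is a hard error rather than a first-wins merge: the
group labels feed composition counts, and a silent pick would corrupt
them. Organization identity is exact string match after whitespace
trimming; deliberately no fuzzy matching, because silently merging two
distinct companies is worse than an occasional duplicate the validator can
surface.

Stakeholder roles come in five fine labels (company, exercise provider,
and network partners from the public, society/politics and economy) that
collapse deterministically to three coarse labels; composition reports use
the coarse level.

Work steps carry an explicit 1-based `order` that is authoritative for the
temporal sequence. Dates are display-only: event periods can genuinely
overlap (an on-site consultation round can span the month of a workshop),
so ordering by date would be ambiguous where the step numbering is not.

## Networks

For each step *Tk* the two-mode network contains the events of the
cumulative window *T1..Tk* and the organizations with ≥ 1 attendance in
it. Windows always start at the first step; sliding windows are out of
scope because the monitoring question is "how has the network developed
since the start". Events with no attendees in the window are dropped by
default (a flag retains them for visualization). The projection connects
two organizations iff they co-attended an event, weight = number of
co-attended events; weights count shared events, never shared people.
The projection preserves the organization node set.

The **core** is extracted by an edge filter: keep ties of weight ≥
`min_weight` (default 2) and the nodes incident to a kept tie. The
threshold is configurable rather than hard-coded because "met repeatedly"
admits both a node-frequency and a tie-weight reading; the tie-weight
reading is the default since the core is about pairs that re-met, not
individuals who re-attended. (The two readings genuinely differ: an
organization can attend twice without meeting anyone twice.)

## Measures and numerical conventions

All measures are computed on the simple unweighted skeleton except the
average weighted degree.

* Distances are hop counts via breadth-first search from every node
  (O(N·E), ample at this scale — tables here have tens of organizations).
  Edge weights encode repeated contact, not proximity, so weighting
  distances would invert their meaning; consistently, the diameter of a
  growing network can stay at 2 while weights grow.
* `avg_path_length` averages over connected pairs only. A disconnected
  snapshot still gets a finite value plus `is_connected=False`; an
  edgeless one reports both distance measures as missing (rendered `NA`,
  never 0 — a 0 would read as "everyone adjacent").
* Triangles are distinct 3-cliques counted once each (per-edge common
  neighbors summed, divided by 3).
* The local clustering coefficient of a degree-<2 node is undefined; by
  default it enters the mean as 0 (the convention of common GUI tools),
  `exclude_low_degree=True` drops such nodes instead. The forced
  early-network values cannot discriminate between the conventions (all
  degrees ≥ 8 there), so the choice is exposed.
* Full precision is kept internally; the report rendering rounds degrees
  to 1 decimal and density/clustering/path length to 3 decimals.
* Trajectories evaluate every configured step even if it added no members
  (the row repeats the previous counts), keeping report tables
  rectangular.

## Synthetic tables

No raw attendance matrix from the monitored project is published, only
summary totals. Two deterministic fixtures and one stochastic generator
stand in:

* `fixture_t1_t2()` — the first two steps are fully forced by the
  published totals (9 founders at the first event; 9 attendees at the
  second, exactly one of them a returnee), so every global measure of
  these snapshots is exactly reproducible: 9/17 nodes, 36/72 edges,
  density 1.000/0.529, clustering 1.000/0.969, 84/168 triangles,
  diameter 1/2, average (weighted) degree 8.0/8.5.
* `fixture_five_step_study()` — a hand-built 23-organization, 5-event
  table satisfying every published total through the fifth step:
  cumulative membership 9/17/20/22/23, initial composition 4 exercise
  providers + 5 partners, final composition 7/8/8, final attendance
  histogram {1:10, 2:5, 3:5, 4:3}, single T1/T2 returnee. The constructor
  re-asserts all of these on every call. Event sizes for the last three
  steps are **not** published; this table uses 10/12/7 so that per-event
  attendance rises to the fourth step and drops at the digital fifth,
  matching the reported qualitative pattern. Consequently cumulative edge
  and triangle counts for those steps are plausible but not exact
  (e.g. 151 edges at T5 vs the reported 153) — the attendance matrix is
  underdetermined by the published totals, and no attempt is made to
  search for one that happens to match.
* `generate(GrowthScenario(...))` — event 1 seats `founder_count`
  organizations; each later event draws Poisson(`arrival_rate`) newcomers
  and lets each existing member return with probability `repeat_prob`
  (optionally per coarse group). Defaults (5 events, 9 founders, rate 3.5,
  repeat 0.35) mirror the monitored project's scale: observed arrivals
  were 8/3/2/1 (mean 3.5) and observed return fractions ranged ~0.11–0.50.
  One explicitly passed, seeded generator; no global random state.

What the synthetic tables do not emulate: person-level multiplicity
(several representatives per company), organization covariates (size,
sector), inter-event contacts outside the formal events, and any
correlation between stakeholder role and attendance behaviour beyond the
optional per-group return probability. Tests passing on these tables
therefore validate the pipeline's arithmetic and invariants, not claims
about real attendance dynamics.

## Known divergence: the second-step average path length

The forced two-clique structure after the second step implies an average
path length of 200/136 ≈ 1.471 (136 pairs; 72 at distance 1, 64 cross-
clique pairs at distance 2), yet the historically reported table prints
1.400 for this cell while agreeing with every other forced value. The
convention behind that figure (possibly a directed-pair or component
averaging variant in the GUI tool used) is not recoverable, so this
package reports the computed value and treats the printed cell as
non-reproducible. It is the only forced cell that disagrees.

## Exports and layout

GEXF targets the 1.2draft schema for broadest Gephi compatibility;
GraphML and a paired node/edge CSV (`source,target,type=Undirected,weight`)
are alternatives. An internal reader for all three formats backs the
round-trip guarantee (node sets, attributes, edge sets and numeric weights
preserved exactly). The panel figure uses a self-implemented
Fruchterman–Reingold layout, deterministic under a seed; coordinates of
any particular GUI tool are explicitly not reproduced — only topology is
testable.

## Problem sizes

Deterministic checks run on the fixtures above (≤ 23 organizations,
5 events). Randomized oracle checks use ≥ 200 random weighted graphs of up
to 30 nodes against brute-force oracles (Floyd–Warshall distances,
trace(A³)/6 triangles, adjacency-list degree sums, set-intersection
projection weights), plus networkx as an independent cross-check in unit
tests. The simulator's Poisson arrival mechanism is checked over 500
replicates (mean newcomers per event within 3 standard errors of the
configured rate). The whole suite completes in well under a minute on one
CPU.
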