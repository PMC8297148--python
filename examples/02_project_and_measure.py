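"""Build the cumulative two-mode network, project it, and measure it.

Uses the built-in two-event table whose structure is fully forced by the
published totals of the monitored project: a first event with nine
organizations, then a second nine-organization event sharing exactly one
attendee with the first.
"""

from whpnet import build_two_mode, compute_all, fixture_t1_t2, project_one_mode

table = fixture_t1_t2()

for step in ("T1", "T2"):
    two = build_two_mode(table, step)            # cumulative window T1..step
    one = project_one_mode(two)                  # weight = shared events
    m = compute_all(one)
    print(f"window through {step}: {two.n_orgs} organizations, "
          f"{two.n_events} events")
    for key, value in m.rounded().items():
        print(f"  {key:20s} {value}")

# After T1 every founder met every other founder at the same event, so the
# one-mode network is complete: density 1.0, diameter 1, C(9,3)=84
# triangles.  After T2 the network is two 9-cliques sharing one bridging
# organization: 17 nodes, 72 edges, density 0.529, clustering 0.969.
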