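"""Export Gephi-compatible files and render the two-row panel figure.

Writes GEXF/GraphML/CSV for the final cumulative window and a figure with
one column per work step: top row the two-mode network (organizations vs
events), bottom row the weighted one-mode projection.
"""

from pathlib import Path

from whpnet import build_two_mode, fixture_five_step_study, project_one_mode
from whpnet.export import render_panels, write_graph

out_dir = Path("example_output")
out_dir.mkdir(exist_ok=True)

table = fixture_five_step_study()
two = build_two_mode(table, "T5")
one = project_one_mode(two)

for fmt, suffix in (("gexf", ".gexf"), ("graphml", ".graphml"), ("csv", ".csv")):
    files = write_graph(one, out_dir / f"network_t5{suffix}", format=fmt)
    print(f"{fmt}: " + ", ".join(str(f) for f in files))

fig = render_panels(table, out_dir / "panels.png", layout_seed=0)
print(f"panel figure: {fig}")
# The figure mirrors the standard presentation of affiliation-network
# development; edge thickness in the bottom row is proportional to how
# often a pair of organizations co-attended.
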