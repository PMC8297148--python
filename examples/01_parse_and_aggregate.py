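"""Parse a person-level participation sheet and aggregate to organizations.

The raw input is the sheet a network manager keeps during the project: one
row per person with affiliation, stakeholder group, and a 0/1 flag per
event.  The analysis runs on organizations, so person rows are OR-merged
per affiliation and the table is anonymized before sharing.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from whpnet import (
    aggregate_to_organizations,
    anonymize,
    default_work_steps,
    parse_person_table,
)

SHEET = """\
Name of the Person,Affiliation,Stakeholder Group,T1,T2,T3,T4,T5
AA,aa,Company,1,1,0,0,0
BB,bb,Exercise provider,0,1,0,1,0
CC,aa,Company,0,0,1,0,0
DD,cc,Network partner (public),1,0,1,0,1
"""

events = default_work_steps()
with TemporaryDirectory() as tmp:
    path = Path(tmp) / "sheet.csv"
    path.write_text(SHEET, encoding="utf-8")
    records = parse_person_table(path, events)

print(f"parsed {len(records)} person records")
table = aggregate_to_organizations(records, events)
anon, mapping = anonymize(table, prefix="ORG")

for row in anon.rows:
    flags = " ".join(str(row.flags[e.id]) for e in events)
    print(f"{row.org}  {row.group.fine_label:25s}  {flags}")
print("pseudonym mapping (store separately):", mapping)

# Organization 'aa' sent two different people to T1/T2 and T3: after the
# OR-merge it participates in all three events under one pseudonym.
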