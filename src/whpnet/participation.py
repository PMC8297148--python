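"""Reading, validating, anonymizing and aggregating event-participation data.

The raw material of the analysis is a participation sheet maintained by the
network manager: one row per person, with the person's organizational
affiliation, the organization's stakeholder group, and one 0/1 column per
work step (network event).  The analysis itself runs at the organization
level, so person rows are collapsed to an organization-level 0/1
participation matrix: an organization counts as having attended an event if
at least one of its people did, and an organization that never attended any
event is not a network member and is dropped.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "PHASES",
    "FINE_GROUPS",
    "COARSE_GROUPS",
    "WorkStep",
    "StakeholderGroup",
    "PersonRecord",
    "OrganizationRow",
    "ParticipationTable",
    "ParticipationError",
    "default_work_steps",
    "load_work_steps",
    "parse_person_table",
    "parse_participation_table",
    "aggregate_to_organizations",
    "anonymize",
    "write_aggregated",
    "write_mapping",
]

PHASES = ("pre_conception", "conception", "implementation")

#: Fine-grained stakeholder roles, and the coarse roles they collapse to.
#: The three ``partner_*`` roles are all "network partners" at the coarse
#: level used for reporting group composition.
FINE_GROUPS = (
    "company",
    "exercise_provider",
    "partner_public",
    "partner_society_politics",
    "partner_economy",
)
COARSE_GROUPS = ("company", "exercise_provider", "network_partner")

_COARSE_OF_FINE = {
    "company": "company",
    "exercise_provider": "exercise_provider",
    "partner_public": "network_partner",
    "partner_society_politics": "network_partner",
    "partner_economy": "network_partner",
}

# Human-readable spellings accepted on input, mapped to fine labels.
_GROUP_ALIASES = {
    "company": "company",
    "company_representative": "company",
    "exercise_provider": "exercise_provider",
    "partner_public": "partner_public",
    "network_partner_public": "partner_public",
    "partner_society_politics": "partner_society_politics",
    "network_partner_society_politics": "partner_society_politics",
    "partner_society": "partner_society_politics",
    "partner_politics": "partner_society_politics",
    "partner_economy": "partner_economy",
    "network_partner_economy": "partner_economy",
}


class ParticipationError(ValueError):
    """Raised for malformed or inconsistent participation data."""


def _norm_token(text: str) -> str:
    out = []
    for ch in text.strip().lower():
        out.append(ch if ch.isalnum() else "_")
    token = "".join(out)
    while "__" in token:
        token = token.replace("__", "_")
    return token.strip("_")


@dataclass(frozen=True)
class WorkStep:
    """One network event / measuring point (e.g. a stakeholder workshop).

    ``order`` is 1-based and authoritative for the temporal sequence; the
    free-text date is display-only (event periods may overlap, the step
    numbering never does).
    """

    id: str
    label: str = ""
    phase: str = "conception"
    order: int = 1
    date_text: str = ""

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ParticipationError(
                f"unknown phase {self.phase!r}; expected one of {PHASES}"
            )
        if self.order < 1:
            raise ParticipationError("work-step order must be a positive integer")


@dataclass(frozen=True)
class StakeholderGroup:
    """Stakeholder role of an organization.

    Five fine-grained roles collapse to three coarse roles (company,
    exercise provider, network partner); the coarse role is derived, never
    stored independently.
    """

    fine_label: str

    def __post_init__(self) -> None:
        if self.fine_label not in FINE_GROUPS:
            raise ParticipationError(
                f"unknown stakeholder group {self.fine_label!r}; "
                f"expected one of {FINE_GROUPS}"
            )

    @property
    def coarse_label(self) -> str:
        return _COARSE_OF_FINE[self.fine_label]

    @classmethod
    def parse(cls, text: str) -> "StakeholderGroup":
        token = _norm_token(text)
        if token in _GROUP_ALIASES:
            return cls(_GROUP_ALIASES[token])
        raise ParticipationError(f"unrecognized stakeholder group {text!r}")


@dataclass(frozen=True)
class PersonRecord:
    """One row of the person-level collection sheet."""

    person: str
    affiliation: str
    group: StakeholderGroup
    flags: Mapping[str, int]


@dataclass(frozen=True)
class OrganizationRow:
    org: str
    group: StakeholderGroup
    flags: Mapping[str, int]

    def attended(self, step_id: str) -> bool:
        return bool(self.flags.get(step_id, 0))


@dataclass
class ParticipationTable:
    """Organization-level 0/1 participation matrix over an ordered event list.

    Invariants (checked by :meth:`validate`): organization ids unique, every
    row carries a flag for every configured event, and every organization
    attended at least one event (non-attendees are not network members).
    """

    events: Sequence[WorkStep]
    rows: Sequence[OrganizationRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = list(self.events)
        self.rows = list(self.rows)
        self.validate()

    def validate(self) -> None:
        validate_work_steps(self.events)
        ids = [r.org for r in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParticipationError(f"duplicate organization ids: {dupes}")
        event_ids = {e.id for e in self.events}
        for row in self.rows:
            if set(row.flags) != event_ids:
                raise ParticipationError(
                    f"organization {row.org!r}: flags cover {sorted(row.flags)}, "
                    f"expected exactly {sorted(event_ids)}"
                )
            for step_id, v in row.flags.items():
                if v not in (0, 1):
                    raise ParticipationError(
                        f"organization {row.org!r}, event {step_id}: flag {v!r} is not 0/1"
                    )
            if not any(row.flags.values()):
                raise ParticipationError(
                    f"organization {row.org!r} attended no event and is not a member"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def organizations(self) -> list[str]:
        return [r.org for r in self.rows]

    def row(self, org: str) -> OrganizationRow:
        for r in self.rows:
            if r.org == org:
                return r
        raise KeyError(org)

    def step(self, step_id: str) -> WorkStep:
        for e in self.events:
            if e.id == step_id:
                return e
        raise ParticipationError(f"unknown work step {step_id!r}")

    def steps_upto(self, step_id: str) -> list[WorkStep]:
        """Cumulative window: all steps with order <= order(step_id)."""
        upto = self.step(step_id)
        return [e for e in self.events if e.order <= upto.order]

    def attendance_sets(self) -> dict[str, set[str]]:
        """Event id -> set of attending organization ids."""
        return {
            e.id: {r.org for r in self.rows if r.attended(e.id)} for e in self.events
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParticipationTable):
            return NotImplemented
        return list(self.events) == list(other.events) and {
            r.org: (r.group, dict(r.flags)) for r in self.rows
        } == {r.org: (r.group, dict(r.flags)) for r in other.rows}


def validate_work_steps(events: Sequence[WorkStep]) -> None:
    ids = [e.id for e in events]
    if len(ids) != len(set(ids)):
        raise ParticipationError(f"duplicate work-step ids: {ids}")
    orders = sorted(e.order for e in events)
    if orders != list(range(1, len(events) + 1)):
        raise ParticipationError(
            f"work-step orders must be contiguous from 1, got {orders}"
        )


def default_work_steps() -> list[WorkStep]:
    """The five-step schedule of the monitored model project.

    T1 letters of intent (pre-conception), T2 on-site consultation,
    T3/T4 stakeholder workshops (conception), T5 steering group
    (implementation).
    """
    return [
        WorkStep("T1", "Letter of Intent", "pre_conception", 1, "August 2018"),
        WorkStep("T2", "On-site information and consultation", "conception", 2,
                 "July-September 2019"),
        WorkStep("T3", "Stakeholder workshop", "conception", 3, "July 2019"),
        WorkStep("T4", "Stakeholder workshop II", "conception", 4, "January 2020"),
        WorkStep("T5", "Steering group (digital meeting)", "implementation", 5,
                 "October 2020"),
    ]


def load_work_steps(path: str | Path) -> list[WorkStep]:
    """Load an event schedule from a YAML or JSON configuration file.

    Expected structure: a top-level ``events`` list (or a bare list) of
    mappings with keys id, label, phase, order, date_text.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if isinstance(data, Mapping):
        data = data.get("events", data)
    if not isinstance(data, list):
        raise ParticipationError(f"{path}: expected a list of events")
    steps = [
        WorkStep(
            id=str(item["id"]),
            label=str(item.get("label", "")),
            phase=str(item.get("phase", "conception")),
            order=int(item["order"]),
            date_text=str(item.get("date_text", "")),
        )
        for item in data
    ]
    validate_work_steps(steps)
    return steps


# ---------------------------------------------------------------------------
# Delimited-text parsing
# ---------------------------------------------------------------------------

_PERSON_COLS = ("person", "name", "name_of_the_person")
_ORG_COLS = ("affiliation", "organization", "organisation", "org")
_GROUP_COLS = ("stakeholder_group", "group")


def _open_rows(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Read a comma- or tab-delimited UTF-8 file; dialect sniffed from header."""
    text = Path(path).read_text(encoding="utf-8-sig")
    if not text.strip():
        raise ParticipationError(f"{path}: empty file (no header row)")
    first_line = text.splitlines()[0]
    delim = "\t" if "\t" in first_line else ","
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = [row for row in reader if any(cell.strip() for cell in row)]
    header = [cell.strip() for cell in rows[0]]
    return header, rows[1:]


def _find_col(header_norm: list[str], candidates: Sequence[str], what: str,
              path: str | Path) -> int:
    for cand in candidates:
        if cand in header_norm:
            return header_norm.index(cand)
    raise ParticipationError(
        f"{path}: missing {what} column (accepted names: {', '.join(candidates)})"
    )


def _flag_cell(cell: str, row_no: int, step_id: str, path: str | Path) -> int:
    cell = cell.strip()
    if cell not in ("0", "1"):
        raise ParticipationError(
            f"{path}, row {row_no}: participation flag for {step_id} must be 0 "
            f"or 1, got {cell!r}"
        )
    return int(cell)


def parse_person_table(path: str | Path,
                       events: Sequence[WorkStep]) -> list[PersonRecord]:
    """Parse a person-level collection sheet into records.

    The file must carry a header with person / affiliation / stakeholder
    group columns and one column per configured event id.  Rows are numbered
    from 1 (first data row) in error messages.
    """
    validate_work_steps(events)
    header, data = _open_rows(path)
    header_norm = [_norm_token(h) for h in header]
    i_person = _find_col(header_norm, _PERSON_COLS, "person", path)
    i_org = _find_col(header_norm, _ORG_COLS, "affiliation", path)
    i_group = _find_col(header_norm, _GROUP_COLS, "stakeholder group", path)
    event_idx: dict[str, int] = {}
    for e in events:
        if e.id in header:
            event_idx[e.id] = header.index(e.id)
        elif _norm_token(e.id) in header_norm:
            event_idx[e.id] = header_norm.index(_norm_token(e.id))
        else:
            raise ParticipationError(f"{path}: missing event column {e.id!r}")

    records: list[PersonRecord] = []
    for row_no, row in enumerate(data, start=1):
        if len(row) < len(header):
            row = row + [""] * (len(header) - len(row))
        affiliation = row[i_org].strip()
        if not affiliation:
            raise ParticipationError(f"{path}, row {row_no}: empty affiliation")
        try:
            group = StakeholderGroup.parse(row[i_group])
        except ParticipationError as exc:
            raise ParticipationError(f"{path}, row {row_no}: {exc}") from None
        flags = {
            e.id: _flag_cell(row[event_idx[e.id]], row_no, e.id, path)
            for e in events
        }
        records.append(
            PersonRecord(row[i_person].strip(), affiliation, group, flags)
        )
    return records


def parse_participation_table(path: str | Path,
                              events: Sequence[WorkStep]) -> ParticipationTable:
    """Parse an organization-level aggregated table (the canonical format)."""
    validate_work_steps(events)
    header, data = _open_rows(path)
    header_norm = [_norm_token(h) for h in header]
    i_org = _find_col(header_norm, _ORG_COLS, "organization", path)
    i_group = _find_col(header_norm, _GROUP_COLS, "stakeholder group", path)
    event_idx = {}
    for e in events:
        if e.id in header:
            event_idx[e.id] = header.index(e.id)
        elif _norm_token(e.id) in header_norm:
            event_idx[e.id] = header_norm.index(_norm_token(e.id))
        else:
            raise ParticipationError(f"{path}: missing event column {e.id!r}")
    rows = []
    for row_no, row in enumerate(data, start=1):
        org = row[i_org].strip()
        if not org:
            raise ParticipationError(f"{path}, row {row_no}: empty organization id")
        try:
            group = StakeholderGroup.parse(row[i_group])
        except ParticipationError as exc:
            raise ParticipationError(f"{path}, row {row_no}: {exc}") from None
        flags = {
            e.id: _flag_cell(row[event_idx[e.id]], row_no, e.id, path)
            for e in events
        }
        rows.append(OrganizationRow(org, group, flags))
    return ParticipationTable(events, rows)


# ---------------------------------------------------------------------------
# Aggregation and anonymization
# ---------------------------------------------------------------------------

def aggregate_to_organizations(records: Iterable[PersonRecord],
                               events: Sequence[WorkStep]) -> ParticipationTable:
    """Collapse person rows to the organization-level participation matrix.

    An organization's flag for an event is the logical OR of its people's
    flags; organizations with all-zero flags are dropped (they never
    attended, hence are not network members).  Two people of one
    organization carrying different fine stakeholder groups is a hard error:
    the analysis assumes one role per organization, and silently picking one
    would corrupt group-composition counts.
    """
    validate_work_steps(events)
    order = {e.id: e.order for e in events}
    by_org: dict[str, dict] = {}
    for rec in records:
        org = rec.affiliation.strip()
        if not org:
            raise ParticipationError(f"person {rec.person!r}: empty affiliation")
        entry = by_org.setdefault(org, {"group": rec.group,
                                        "flags": {e.id: 0 for e in events}})
        if entry["group"] != rec.group:
            raise ParticipationError(
                f"organization {org!r}: conflicting stakeholder groups "
                f"{entry['group'].fine_label!r} vs {rec.group.fine_label!r}"
            )
        for step_id, v in rec.flags.items():
            if step_id not in order:
                raise ParticipationError(
                    f"person {rec.person!r}: flag for unconfigured step {step_id!r}"
                )
            entry["flags"][step_id] = entry["flags"][step_id] | int(bool(v))
    rows = [
        OrganizationRow(org, entry["group"], entry["flags"])
        for org, entry in sorted(by_org.items())
        if any(entry["flags"].values())
    ]
    return ParticipationTable(events, rows)


def anonymize(table: ParticipationTable,
              prefix: str = "ORG") -> tuple[ParticipationTable, dict[str, str]]:
    """Replace organization ids by deterministic pseudonyms.

    Pseudonyms are ``prefix`` + zero-padded index assigned in sorted order
    of the original ids; the original->pseudonym mapping is returned
    separately so it can be stored securely apart from the shared table.
    """
    originals = sorted(r.org for r in table.rows)
    width = max(2, len(str(len(originals))))
    mapping = {org: f"{prefix}{i:0{width}d}" for i, org in enumerate(originals, 1)}
    rows = [replace(r, org=mapping[r.org]) for r in table.rows]
    return ParticipationTable(table.events, rows), mapping


def write_aggregated(table: ParticipationTable, path: str | Path) -> None:
    """Write the organization-level table as CSV; round-trip safe."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["organization", "stakeholder_group",
                         *[e.id for e in table.events]])
        for row in table.rows:
            writer.writerow([row.org, row.group.fine_label,
                             *[row.flags[e.id] for e in table.events]])


def write_mapping(mapping: Mapping[str, str], path: str | Path) -> None:
    """Write the anonymization mapping as a two-column CSV."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["original", "pseudonym"])
        for org in sorted(mapping):
            writer.writerow([org, mapping[org]])
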