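"""Metric trajectories over cumulative work steps and attendance summaries.

A trajectory evaluates the full global-measure suite on the cumulative
network after every configured work step (window always T1..Tk), producing
one column per step in the familiar report layout — measures as rows,
steps as columns — plus a tidy long format for downstream plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .metrics import METRIC_FIELDS, GlobalMetrics, compute_all
from .network import build_two_mode, project_one_mode
from .participation import ParticipationTable

__all__ = [
    "MetricTrajectory",
    "ParticipationHistogram",
    "trajectory",
    "participation_frequency",
    "group_composition",
    "deltas",
]


@dataclass(frozen=True)
class MetricTrajectory:
    """Ordered (work-step id, metrics) rows over cumulative windows."""

    rows: tuple[tuple[str, GlobalMetrics], ...]

    @property
    def step_ids(self) -> list[str]:
        return [s for s, _ in self.rows]

    def metrics(self, step_id: str) -> GlobalMetrics:
        for s, m in self.rows:
            if s == step_id:
                return m
        raise KeyError(step_id)

    def to_wide_frame(self) -> pd.DataFrame:
        """Measures as rows, cumulative steps as columns (report layout)."""
        # object dtype keeps counts as integers next to the rounded reals
        data = {s: pd.Series(m.rounded(), dtype=object) for s, m in self.rows}
        return pd.DataFrame(data).reindex(list(METRIC_FIELDS))

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy (step, measure, value) rows; missing values are NaN."""
        records = []
        for s, m in self.rows:
            for field in METRIC_FIELDS:
                v = getattr(m, field)
                records.append({"step": s, "measure": field,
                                "value": float("nan") if v is None else v})
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class ParticipationHistogram:
    """Organizations by number of events attended within a window.

    ``counts[k]`` is the number of member organizations that attended
    exactly k events; ``by_group`` splits the same histogram by coarse
    stakeholder group.  Mass conservation: the counts sum to the number of
    members, and sum(k * counts[k]) equals the total attendance.
    """

    counts: dict[int, int]
    by_group: dict[str, dict[int, int]]

    @property
    def n_members(self) -> int:
        return sum(self.counts.values())

    @property
    def total_attendance(self) -> int:
        return sum(k * c for k, c in self.counts.items())


def trajectory(table: ParticipationTable,
               clustering_exclude_low_degree: bool = False) -> MetricTrajectory:
    """Global metrics of the cumulative one-mode network after every step.

    Every configured step gets a row even if it added no members (the row
    then repeats the previous counts), keeping the output rectangular.
    """
    if not table.events:
        raise ValueError("participation table has no configured events")
    rows = []
    for step in sorted(table.events, key=lambda e: e.order):
        g = project_one_mode(build_two_mode(table, step.id))
        rows.append((step.id, compute_all(g, clustering_exclude_low_degree)))
    return MetricTrajectory(tuple(rows))


def participation_frequency(table: ParticipationTable,
                            upto_step: str) -> ParticipationHistogram:
    """Attendance-count histogram over the cumulative window T1..upto_step."""
    window = table.steps_upto(upto_step)
    counts: dict[int, int] = {}
    by_group: dict[str, dict[int, int]] = {}
    for row in table.rows:
        k = sum(row.flags[e.id] for e in window)
        if k == 0:
            continue  # not a member within this window
        counts[k] = counts.get(k, 0) + 1
        grp = by_group.setdefault(row.group.coarse_label, {})
        grp[k] = grp.get(k, 0) + 1
    return ParticipationHistogram(counts, by_group)


def group_composition(table: ParticipationTable,
                      upto_step: str) -> dict[str, int]:
    """Member organizations per coarse stakeholder group in the window."""
    window = table.steps_upto(upto_step)
    comp: dict[str, int] = {}
    for row in table.rows:
        if any(row.flags[e.id] for e in window):
            comp[row.group.coarse_label] = comp.get(row.group.coarse_label, 0) + 1
    return comp


def deltas(tr: MetricTrajectory) -> list[dict[str, object]]:
    """Per-step first differences of node and edge counts.

    Useful for reading growth spurts off a trajectory (e.g. a non-linear
    increase in ties while membership grows steadily).  Empty for a
    single-row trajectory.
    """
    out = []
    for (s_prev, m_prev), (s, m) in zip(tr.rows, tr.rows[1:]):
        out.append({
            "step": s,
            "d_nodes": m.n_nodes - m_prev.n_nodes,
            "d_edges": m.n_edges - m_prev.n_edges,
        })
    return out
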