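"""Monthly count series per drug–event combination.

Aggregates report units into consecutive monthly counts under every
stratification/pooling variant of the screen: substance vs commercial
product on the drug axis; single PT, grouping term or all-PTs-pooled on the
event axis.  Months with no reports are materialised as explicit zeros —
the heuristic branch of the detector is defined on null months, so gaps
must be real zeros, not missing data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .report_store import ReportRecord, ScreenConfig, TermHierarchy

__all__ = [
    "CountSeries",
    "CoverageError",
    "monthly_counts",
    "slice_for_month",
    "write_counts",
    "load_counts",
]

POOLED_ALL_KEY = ("ALL", "ALL")


class CoverageError(ValueError):
    """A series does not cover the months required by a slice."""


def _as_period(month: str | pd.Period) -> pd.Period:
    return month if isinstance(month, pd.Period) else pd.Period(month, freq="M")


@dataclass
class CountSeries:
    """Ordered monthly counts for one drug–event combination.

    ``counts[i]`` is the count for month ``start_month + i``; months are
    consecutive with no gaps.
    """

    drug_key: tuple[str, str]
    event_key: tuple[str, str]
    start_month: pd.Period
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.start_month = _as_period(self.start_month)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def end_month(self) -> pd.Period:
        return self.start_month + (len(self.counts) - 1)

    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start_month, periods=len(self.counts), freq="M")


def slice_for_month(
    series: CountSeries, t0: str | pd.Period, window: int
) -> tuple[np.ndarray, int]:
    """History ``t₋w … t₋₁`` (time order) and the monitored count ``y₀``.

    Raises :class:`CoverageError` naming the missing months if the series
    does not cover ``t0 − window … t0``.
    """
    t0 = _as_period(t0)
    i0 = (t0 - series.start_month).n
    lo = i0 - window
    if lo < 0 or i0 >= len(series.counts):
        need = pd.period_range(t0 - window, t0, freq="M")
        have = series.months()
        missing = [str(m) for m in need if m not in have]
        raise CoverageError(
            f"series {series.drug_key}/{series.event_key} does not cover "
            f"months: {missing}"
        )
    history = series.counts[lo:i0].copy()
    return history, int(series.counts[i0])


def _grouping_membership(
    hierarchy: TermHierarchy,
    grouping_terms: Sequence[tuple[str, str]] | None,
) -> dict[str, list[tuple[str, str]]]:
    """Map each PT to the grouping keys whose expansion contains it."""
    if grouping_terms is None:
        grouping_terms = [("HLT", h) for h in sorted(hierarchy.hlt_to_hlgt)] + [
            ("SMQ", s) for s in sorted(hierarchy.smq_members)
        ]
    pt_to_groups: dict[str, list[tuple[str, str]]] = {}
    for level, term_id in grouping_terms:
        for pt in hierarchy.members(level, term_id):
            pt_to_groups.setdefault(pt, []).append((level, term_id))
    return pt_to_groups


def monthly_counts(
    reports: Iterable[ReportRecord],
    config: ScreenConfig,
    hierarchy: TermHierarchy,
    span: tuple[str | pd.Period, str | pd.Period],
    grouping_terms: Sequence[tuple[str, str]] | None = None,
) -> list[CountSeries]:
    """Tally report units into one series per observed (drug, event) key.

    A unit is one (case, drug, PT) report row.  Study records never reach
    this function's output; literature units are dropped when the config
    excludes them; with ``restrict_ime_dme`` only IME/DME PTs are counted.
    At ``event_level="grouping"`` a unit contributes to every grouping term
    whose expansion contains its PT (unit counting, which keeps grouping
    sums consistent with the PT-level series).

    ``grouping_terms`` narrows the grouping-key universe; by default every
    HLT and SMQ of the hierarchy is used.
    """
    first, last = _as_period(span[0]), _as_period(span[1])
    if last < first:
        raise ValueError("empty span: last month precedes first month")
    span_index = pd.period_range(first, last, freq="M")

    rows = []
    for r in reports:
        if r.module != "post_marketing":
            continue
        if r.literature and not config.include_literature:
            continue
        if config.restrict_ime_dme and r.event_pt not in hierarchy.serious_terms:
            continue
        if config.drug_level == "substance":
            drug_id = r.substance
        else:
            if r.product_name is None:
                continue
            drug_id = r.product_name
        month = pd.Period(r.receive_date.strftime("%Y-%m"), freq="M")
        if month < first or month > last:
            continue
        rows.append((drug_id, r.event_pt, month))
    if not rows:
        return []

    df = pd.DataFrame(rows, columns=["drug_id", "event_pt", "month"])
    drug_level = config.drug_level

    if config.event_level == "pt":
        df["event_level"] = "pt"
        df["event_id"] = df["event_pt"]
    elif config.event_level == "pooled_all":
        df["event_level"] = POOLED_ALL_KEY[0]
        df["event_id"] = POOLED_ALL_KEY[1]
    else:  # grouping
        membership = _grouping_membership(hierarchy, grouping_terms)
        df["groups"] = df["event_pt"].map(lambda pt: membership.get(pt, []))
        df = df.explode("groups").dropna(subset=["groups"])
        if df.empty:
            return []
        df["event_level"] = df["groups"].map(lambda g: g[0])
        df["event_id"] = df["groups"].map(lambda g: g[1])

    tallies = (
        df.groupby(["drug_id", "event_level", "event_id", "month"], observed=True)
        .size()
        .rename("count")
    )
    out: list[CountSeries] = []
    for (drug_id, ev_level, ev_id), sub in tallies.groupby(
        level=["drug_id", "event_level", "event_id"], observed=True
    ):
        per_month = sub.droplevel(["drug_id", "event_level", "event_id"])
        counts = per_month.reindex(span_index, fill_value=0).to_numpy()
        out.append(
            CountSeries(
                drug_key=(drug_level, drug_id),
                event_key=(ev_level, ev_id),
                start_month=first,
                counts=counts,
            )
        )
    out.sort(key=lambda s: (s.drug_key, s.event_key))
    return out


def write_counts(series: Iterable[CountSeries], path: str | Path) -> None:
    """Long-format counts.csv: drug_level,drug_id,event_level,event_id,month,count."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_level", "drug_id", "event_level", "event_id", "month", "count"])
        for s in series:
            for month, count in zip(s.months(), s.counts):
                writer.writerow(
                    [s.drug_key[0], s.drug_key[1], s.event_key[0], s.event_key[1], str(month), int(count)]
                )


def load_counts(path: str | Path) -> list[CountSeries]:
    df = pd.read_csv(path, dtype={"drug_id": str, "event_id": str})
    required = {"drug_level", "drug_id", "event_level", "event_id", "month", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts file missing column(s): {sorted(missing)}")
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    out: list[CountSeries] = []
    for (dl, did, el, eid), sub in df.groupby(
        ["drug_level", "drug_id", "event_level", "event_id"], observed=True
    ):
        sub = sub.sort_values("month")
        months = pd.PeriodIndex(sub["month"])
        full = pd.period_range(months.min(), months.max(), freq="M")
        counts = (
            sub.set_index("month")["count"].reindex(full, fill_value=0).to_numpy()
        )
        out.append(
            CountSeries(
                drug_key=(dl, did),
                event_key=(el, eid),
                start_month=full[0],
                counts=counts,
            )
        )
    out.sort(key=lambda s: (s.drug_key, s.event_key))
    return out
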