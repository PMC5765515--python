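"""Labelling detections against a historical-concern register and PPV.

A detection is a true positive when some registered concern matches its
drug scope, the concern's PT case definition covers the detected event,
and the detection month falls within the empirically chosen window of
12 months before to 6 months after the concern's index month (inclusive,
month granularity).  Detections on drugs outside the register are outside
the evaluation universe and excluded from the PPV denominator, which by
definition covers only the substances on the concern list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .counting import POOLED_ALL_KEY
from .report_store import (
    ConcernRecord,
    ScreenConfig,
    TermHierarchy,
    concern_case_definition,
    expand_grouping,
)
from .uif_detector import UifDetection

__all__ = [
    "LabeledDetection",
    "EvalReport",
    "label_detections",
    "compute_ppv",
    "write_labeled",
    "write_eval_report",
]

WINDOW_BEFORE_MONTHS = 12
WINDOW_AFTER_MONTHS = 6


@dataclass
class LabeledDetection:
    detection: UifDetection
    label: Literal["true_positive", "false_positive", "out_of_universe"]
    concern_id: str | None = None
    concern_type: str | None = None


@dataclass
class EvalReport:
    """PPV summary; proportions are None when their denominator is zero."""

    ppv_overall: float | None
    ppv_regression: float | None
    ppv_heuristic: float | None
    detected_concerns: set[str]
    detections_by_type: dict[str, int]
    n_true_positive: int
    n_false_positive: int
    n_out_of_universe: int
    first_detection: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ppv_overall": self.ppv_overall,
            "ppv_regression": self.ppv_regression,
            "ppv_heuristic": self.ppv_heuristic,
            "detected_concerns": sorted(self.detected_concerns),
            "detections_by_type": dict(sorted(self.detections_by_type.items())),
            "n_true_positive": self.n_true_positive,
            "n_false_positive": self.n_false_positive,
            "n_out_of_universe": self.n_out_of_universe,
            "first_detection": dict(sorted(self.first_detection.items())),
        }


def _month(m: str | pd.Period) -> pd.Period:
    return m if isinstance(m, pd.Period) else pd.Period(m, freq="M")


def month_in_window(detection_month: str | pd.Period, index_date) -> bool:
    """Month-granularity window test: index month -12 … +6, inclusive."""
    t0 = _month(detection_month)
    idx = pd.Period(f"{index_date.year:04d}-{index_date.month:02d}", freq="M")
    return idx - WINDOW_BEFORE_MONTHS <= t0 <= idx + WINDOW_AFTER_MONTHS


def _drug_matches(det: UifDetection, concern: ConcernRecord) -> bool:
    level, drug_id = det.drug_key
    if level == "substance":
        return drug_id == concern.substance
    # Product-level screens: abuse/misuse concerns are not product specific
    # and are skipped; other concerns match on their affected product names.
    if concern.concern_type == "AM" or concern.product_names is None:
        return False
    return drug_id in concern.product_names


def _event_matches(
    det: UifDetection,
    case_pts: set[str],
    hierarchy: TermHierarchy,
) -> bool:
    level, event_id = det.event_key
    if not case_pts:
        return False
    if (level, event_id) == POOLED_ALL_KEY:
        return True
    if level == "pt":
        return event_id in case_pts
    # Grouping-level screens: the event key's own expansion must intersect
    # the concern's case definition.
    return bool(expand_grouping(hierarchy, [(level, event_id)]) & case_pts)


def label_detections(
    detections: Iterable[UifDetection],
    concerns: Iterable[ConcernRecord],
    hierarchy: TermHierarchy,
    config: ScreenConfig,
) -> list[LabeledDetection]:
    """Assign exactly one label to every detection.

    Ties (a detection matching several concerns) resolve to the first
    matching concern in concern-id order.
    """
    concerns = sorted(concerns, key=lambda c: c.concern_id)
    case_defs = {
        c.concern_id: concern_case_definition(
            hierarchy, c, restrict_ime_dme=config.restrict_ime_dme
        )
        for c in concerns
    }
    labeled: list[LabeledDetection] = []
    for det in detections:
        in_scope = [c for c in concerns if _drug_matches(det, c)]
        if not in_scope:
            labeled.append(LabeledDetection(det, "out_of_universe"))
            continue
        hit: ConcernRecord | None = None
        for c in in_scope:
            if month_in_window(det.month, c.index_date) and _event_matches(
                det, case_defs[c.concern_id], hierarchy
            ):
                hit = c
                break
        if hit is not None:
            labeled.append(
                LabeledDetection(det, "true_positive", hit.concern_id, hit.concern_type)
            )
        else:
            labeled.append(LabeledDetection(det, "false_positive"))
    return labeled


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_ppv(labeled: Iterable[LabeledDetection]) -> EvalReport:
    """Pooled PPV over in-universe detections, overall and per branch."""
    labeled = list(labeled)
    in_univ = [l for l in labeled if l.label != "out_of_universe"]
    tp = [l for l in in_univ if l.label == "true_positive"]
    by_branch = {
        branch: [l for l in in_univ if l.detection.branch == branch]
        for branch in ("regression", "heuristic")
    }
    by_type: dict[str, int] = {}
    first: dict[str, str] = {}
    for l in tp:
        assert l.concern_id is not None and l.concern_type is not None
        by_type[l.concern_type] = by_type.get(l.concern_type, 0) + 1
        m = l.detection.month
        if l.concern_id not in first or m < first[l.concern_id]:
            first[l.concern_id] = m
    return EvalReport(
        ppv_overall=_ratio(len(tp), len(in_univ)),
        ppv_regression=_ratio(
            sum(1 for l in by_branch["regression"] if l.label == "true_positive"),
            len(by_branch["regression"]),
        ),
        ppv_heuristic=_ratio(
            sum(1 for l in by_branch["heuristic"] if l.label == "true_positive"),
            len(by_branch["heuristic"]),
        ),
        detected_concerns={l.concern_id for l in tp if l.concern_id},
        detections_by_type=by_type,
        n_true_positive=len(tp),
        n_false_positive=sum(1 for l in in_univ if l.label == "false_positive"),
        n_out_of_universe=len(labeled) - len(in_univ),
        first_detection=first,
    )


def write_labeled(labeled: Iterable[LabeledDetection], path: str | Path) -> None:
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "drug_level",
                "drug_id",
                "event_level",
                "event_id",
                "month",
                "y0",
                "branch",
                "label",
                "concern_id",
                "concern_type",
            ]
        )
        for l in labeled:
            d = l.detection
            writer.writerow(
                [
                    d.drug_key[0],
                    d.drug_key[1],
                    d.event_key[0],
                    d.event_key[1],
                    d.month,
                    d.y0,
                    d.branch,
                    l.label,
                    l.concern_id or "",
                    l.concern_type or "",
                ]
            )


def write_eval_report(report: EvalReport, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
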