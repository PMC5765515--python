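"""Synthetic spontaneous-report database with known ground truth.

Real pharmacovigilance databases are access-restricted and the MedDRA
terminology is licensed, so this module emulates both: a synthetic
single-axial term hierarchy, over-dispersed (negative binomial) monthly
background reporting per drug–event pair, and injected concern episodes
that elevate every PT of a grouping term simultaneously — the reporting
signature of a quality defect, medication error or abuse/misuse episode.

Counts are sampled with the same NB2 parameterisation the detector fits
(variance mu + alpha * mu**2), so calibration experiments against the
detector are exact.  Injections add reports on top of the background,
calibrated so an episode month's expected total is ``fold_increase`` times
the baseline mean; ground truth therefore stays unambiguous.
"""

from __future__ import annotations

import calendar
import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .report_store import (
    ConcernRecord,
    ReportRecord,
    ScreenConfig,
    TermHierarchy,
    expand_grouping,
)
from .uif_detector import detect, is_null_history

logger = logging.getLogger("uifscan")

__all__ = [
    "SimScenario",
    "InjectionSpec",
    "synthetic_hierarchy",
    "default_hierarchy",
    "default_scenario",
    "simulate_background",
    "inject_concern",
    "simulate",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "sample_nb_counts",
    "regression_false_alarm_rate",
    "spike_detection_rate",
]

# Fraction of reports that carry a commercial product name; the remainder
# participate only in substance-level analyses.
PRODUCT_RECORDED_FRACTION = 0.7


@dataclass(frozen=True)
class InjectionSpec:
    """One injected concern episode.

    Every PT grouped under ``grouping_term`` receives extra reports over
    ``duration_months`` starting at ``start_month`` so that episode months
    run at ``fold_increase`` times the background mean.  ``index_date``
    plays the role of the concern's registration date and anchors the
    true-positive window during evaluation.
    """

    substance: str
    grouping_term: tuple[str, str]
    start_month: str
    duration_months: int
    fold_increase: float
    concern_type: str  # QD | ME | AM
    index_date: dt.date
    product_name: str | None = None
    concern_id: str | None = None

    def __post_init__(self) -> None:
        if self.duration_months < 1:
            raise ValueError("duration_months must be >= 1")
        if self.fold_increase <= 1.0:
            raise ValueError("fold_increase must be > 1")


@dataclass
class SimScenario:
    """Study conditions for one simulated report database."""

    n_substances: int = 15
    pts_per_substance: int = 24
    baseline_mu: float = 2.0
    dispersion_alpha: float = 0.3
    trend_per_month: float = 1.0
    literature_fraction: float = 0.1
    months: tuple[str, str] = ("2008-01", "2015-06")
    injections: list[InjectionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mu <= 0:
            raise ValueError("baseline_mu must be > 0")
        if self.dispersion_alpha < 0:
            raise ValueError("dispersion_alpha must be >= 0")
        if not (0.0 <= self.literature_fraction <= 1.0):
            raise ValueError("literature_fraction must lie in [0, 1]")

    def substances(self) -> list[str]:
        return [f"sub{i:02d}" for i in range(1, self.n_substances + 1)]


def sample_nb_counts(
    rng: np.random.Generator,
    mu: float | np.ndarray,
    alpha: float,
    size: int | tuple[int, ...] | None = None,
) -> np.ndarray:
    """NB2 counts (variance mu + alpha mu^2) via the gamma–Poisson mixture."""
    mu = np.asarray(mu, dtype=float)
    if size is None:
        size = mu.shape
    if alpha == 0.0:
        return rng.poisson(np.broadcast_to(mu, size))
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu, size=size)
    return rng.poisson(lam)


def synthetic_hierarchy(
    n_socs: int = 4,
    hlgts_per_soc: int = 2,
    hlts_per_hlgt: int = 3,
    pts_per_hlt: int = 4,
    n_smqs: int = 6,
    smq_size: int = 8,
    ime_fraction: float = 0.75,
    dme_fraction: float = 0.10,
    seed: int = 7,
) -> TermHierarchy:
    """A regular synthetic stand-in for the licensed terminology.

    The clinical branch is a balanced tree; one extra branch
    (``hlt_quality_issues``) carries PTs that name product quality problems
    directly and is flagged ``quality_issue`` — those terms are excluded
    from quality-defect case definitions during evaluation.
    """
    rng = np.random.default_rng(seed)
    pt_to_hlt: dict[str, str] = {}
    hlt_to_hlgt: dict[str, str] = {}
    hlgt_to_soc: dict[str, str] = {}
    pt_counter = 0
    for s in range(1, n_socs + 1):
        soc = f"soc_{s:02d}"
        for g in range(1, hlgts_per_soc + 1):
            hlgt = f"hlgt_{s:02d}_{g}"
            hlgt_to_soc[hlgt] = soc
            for h in range(1, hlts_per_hlgt + 1):
                hlt = f"hlt_{s:02d}_{g}_{h}"
                hlt_to_hlgt[hlt] = hlgt
                for _ in range(pts_per_hlt):
                    pt_counter += 1
                    pt_to_hlt[f"pt_{pt_counter:04d}"] = hlt
    # Quality-issue branch.
    hlgt_to_soc["hlgt_product_quality"] = "soc_product_issues"
    hlt_to_hlgt["hlt_quality_issues"] = "hlgt_product_quality"
    quality_pts = [f"pt_q{i}" for i in range(1, 5)]
    for pt in quality_pts:
        pt_to_hlt[pt] = "hlt_quality_issues"

    clinical_pts = sorted(p for p in pt_to_hlt if not p.startswith("pt_q"))
    n_ime = int(round(ime_fraction * len(clinical_pts)))
    ime = set(rng.choice(clinical_pts, size=n_ime, replace=False))
    n_dme = int(round(dme_fraction * len(clinical_pts)))
    dme = set(rng.choice(sorted(ime), size=min(n_dme, len(ime)), replace=False))
    ime |= set(quality_pts)  # quality PTs stay countable for ME/AM screens

    smq_members: dict[str, dict[str, str]] = {}
    for k in range(1, n_smqs + 1):
        members = rng.choice(clinical_pts, size=smq_size, replace=False)
        scopes = rng.choice(["broad", "narrow"], size=smq_size, p=[0.6, 0.4])
        smq_members[f"smq_{k:02d}"] = {
            pt: scope for pt, scope in zip(sorted(members), scopes)
        }
    return TermHierarchy(
        pt_to_hlt=pt_to_hlt,
        hlt_to_hlgt=hlt_to_hlgt,
        hlgt_to_soc=hlgt_to_soc,
        smq_members=smq_members,
        ime_terms=frozenset(ime),
        dme_terms=frozenset(dme),
        quality_issue_terms=frozenset(quality_pts),
    )


def default_hierarchy() -> TermHierarchy:
    return synthetic_hierarchy(seed=7)


def default_scenario(seed: int = 0) -> SimScenario:
    """The packaged demo scenario: 13 injected concerns of mixed type.

    Mirrors the structure of a historical register — five quality defects,
    five medication errors and three abuse/misuse concerns with index dates
    spread over the simulated span — against a stationary over-dispersed
    background (mean 2 reports/month per drug–event, dispersion 0.3).
    """
    groupings = [
        ("SMQ", "smq_01"),
        ("SMQ", "smq_02"),
        ("HLT", "hlt_01_1_1"),
        ("SMQ", "smq_03"),
        ("HLT", "hlt_02_1_2"),
        ("SMQ", "smq_04"),
        ("HLT", "hlt_03_1_1"),
        ("SMQ", "smq_05"),
        ("HLT", "hlt_04_2_1"),
        ("SMQ", "smq_06"),
        ("HLT", "hlt_01_2_3"),
        ("SMQ", "smq_01"),
        ("HLT", "hlt_02_2_2"),
    ]
    types = ["QD"] * 5 + ["ME"] * 5 + ["AM"] * 3
    index_months = [
        "2009-06", "2010-02", "2010-09", "2011-05", "2011-12",
        "2012-06", "2012-11", "2013-04", "2013-09", "2014-02",
        "2014-07", "2014-11", "2015-02",
    ]
    injections = []
    for i, (grouping, ctype, month) in enumerate(
        zip(groupings, types, index_months), start=1
    ):
        sub = f"sub{i:02d}"
        injections.append(
            InjectionSpec(
                substance=sub,
                grouping_term=grouping,
                start_month=month,
                duration_months=3,
                fold_increase=6.0,
                concern_type=ctype,
                index_date=dt.date.fromisoformat(f"{month}-15"),
                product_name=None if ctype == "AM" else f"{sub} brand",
                concern_id=f"concern-{i:02d}",
            )
        )
    return SimScenario(injections=injections, seed=seed)


def _random_day(rng: np.random.Generator, period: pd.Period) -> dt.date:
    ndays = calendar.monthrange(period.year, period.month)[1]
    return dt.date(period.year, period.month, int(rng.integers(1, ndays + 1)))


def simulate_background(
    scenario: SimScenario,
    hierarchy: TermHierarchy,
    extra_pts: dict[str, set[str]] | None = None,
) -> list[ReportRecord]:
    """Draw the background reporting table.

    Each substance is assigned ``pts_per_substance`` PTs at random (plus
    any PTs listed in ``extra_pts``, used to guarantee injected groupings
    have a background law); each pair–month count is NB with mean
    ``baseline_mu * trend_per_month**m``.  Fully reproducible from
    ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    months = pd.period_range(scenario.months[0], scenario.months[1], freq="M")
    all_pts = sorted(hierarchy.pts)
    records: list[ReportRecord] = []
    case_counter = 0
    mu_months = scenario.baseline_mu * scenario.trend_per_month ** np.arange(
        len(months), dtype=float
    )
    for sub in scenario.substances():
        assigned = set(
            rng.choice(all_pts, size=min(scenario.pts_per_substance, len(all_pts)),
                       replace=False)
        )
        if extra_pts and sub in extra_pts:
            assigned |= extra_pts[sub]
        brand = f"{sub} brand"
        for pt in sorted(assigned):
            counts = sample_nb_counts(rng, mu_months, scenario.dispersion_alpha)
            for m_idx in np.nonzero(counts)[0]:
                period = months[m_idx]
                for _ in range(int(counts[m_idx])):
                    case_counter += 1
                    records.append(
                        ReportRecord(
                            case_id=f"C{case_counter:08d}",
                            receive_date=_random_day(rng, period),
                            substance=sub,
                            product_name=(
                                brand
                                if rng.random() < PRODUCT_RECORDED_FRACTION
                                else None
                            ),
                            event_pt=pt,
                            literature=bool(
                                rng.random() < scenario.literature_fraction
                            ),
                        )
                    )
    return records


def inject_concern(
    records: list[ReportRecord],
    spec: InjectionSpec,
    hierarchy: TermHierarchy,
    seed: int,
    baseline_mu: float,
    span: tuple[str, str] | None = None,
) -> tuple[list[ReportRecord], ConcernRecord]:
    """Append episode reports for one concern and return its ground truth.

    For every PT grouped under the injection's grouping term and every episode
    month, extra reports are drawn so the month's expected total is
    ``fold_increase * baseline_mu`` (additive on top of the background).
    An episode wholly outside ``span`` leaves the records unchanged (with a
    warning) but still returns the concern record.
    """
    pts = expand_grouping(hierarchy, [spec.grouping_term])
    if not pts:
        raise ValueError(f"grouping {spec.grouping_term} expands to no PTs")
    rng = np.random.default_rng(seed)
    episode = pd.period_range(
        pd.Period(spec.start_month, freq="M"), periods=spec.duration_months, freq="M"
    )
    if span is not None:
        lo, hi = pd.Period(span[0], freq="M"), pd.Period(span[1], freq="M")
        kept = [m for m in episode if lo <= m <= hi]
    else:
        kept = list(episode)
    concern = ConcernRecord(
        concern_id=spec.concern_id
        or f"{spec.substance}-{spec.concern_type}-{spec.start_month}",
        substance=spec.substance,
        index_date=spec.index_date,
        concern_type=spec.concern_type,  # type: ignore[arg-type]
        grouping_terms=(spec.grouping_term,),
        product_names=(
            frozenset({spec.product_name}) if spec.product_name else None
        ),
    )
    if not kept:
        logger.warning(
            "injection %s: episode %s..%s lies outside the simulated span",
            concern.concern_id,
            episode[0],
            episode[-1],
        )
        return records, concern
    out = list(records)
    extra_mu = (spec.fold_increase - 1.0) * baseline_mu
    counter = 0
    for pt in sorted(pts):
        for period in kept:
            n_extra = int(rng.poisson(extra_mu))
            for _ in range(n_extra):
                counter += 1
                out.append(
                    ReportRecord(
                        case_id=f"INJ-{concern.concern_id}-{counter:05d}",
                        receive_date=_random_day(rng, period),
                        substance=spec.substance,
                        product_name=(
                            spec.product_name
                            if spec.product_name
                            and rng.random() < PRODUCT_RECORDED_FRACTION
                            else None
                        ),
                        event_pt=pt,
                        literature=False,
                    )
                )
    return out, concern


def simulate(
    scenario: SimScenario, hierarchy: TermHierarchy | None = None
) -> tuple[list[ReportRecord], list[ConcernRecord], TermHierarchy]:
    """Background plus all injections; the full synthetic study."""
    if hierarchy is None:
        hierarchy = default_hierarchy()
    extra: dict[str, set[str]] = {}
    for spec in scenario.injections:
        extra.setdefault(spec.substance, set()).update(
            expand_grouping(hierarchy, [spec.grouping_term])
        )
    records = simulate_background(scenario, hierarchy, extra_pts=extra)
    concerns: list[ConcernRecord] = []
    for k, spec in enumerate(scenario.injections):
        records, concern = inject_concern(
            records,
            spec,
            hierarchy,
            seed=scenario.seed + 10_000 + k,
            baseline_mu=scenario.baseline_mu,
            span=scenario.months,
        )
        concerns.append(concern)
    records.sort(key=lambda r: (r.receive_date, r.case_id))
    return records, concerns, hierarchy


# --------------------------------------------------------------------------
# Scenario (de)serialisation


def scenario_to_yaml(scenario: SimScenario, path: str | Path) -> None:
    data = {
        "n_substances": scenario.n_substances,
        "pts_per_substance": scenario.pts_per_substance,
        "baseline_mu": scenario.baseline_mu,
        "dispersion_alpha": scenario.dispersion_alpha,
        "trend_per_month": scenario.trend_per_month,
        "literature_fraction": scenario.literature_fraction,
        "months": list(scenario.months),
        "seed": scenario.seed,
        "injections": [
            {
                "substance": s.substance,
                "grouping_term": list(s.grouping_term),
                "start_month": s.start_month,
                "duration_months": s.duration_months,
                "fold_increase": s.fold_increase,
                "concern_type": s.concern_type,
                "index_date": s.index_date.isoformat(),
                "product_name": s.product_name,
                "concern_id": s.concern_id,
            }
            for s in scenario.injections
        ],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scenario_from_yaml(path: str | Path) -> SimScenario:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh)
    injections = [
        InjectionSpec(
            substance=d["substance"],
            grouping_term=tuple(d["grouping_term"]),
            start_month=d["start_month"],
            duration_months=int(d["duration_months"]),
            fold_increase=float(d["fold_increase"]),
            concern_type=d["concern_type"],
            index_date=dt.date.fromisoformat(str(d["index_date"])),
            product_name=d.get("product_name"),
            concern_id=d.get("concern_id"),
        )
        for d in data.get("injections", [])
    ]
    return SimScenario(
        n_substances=int(data.get("n_substances", 15)),
        pts_per_substance=int(data.get("pts_per_substance", 24)),
        baseline_mu=float(data.get("baseline_mu", 2.0)),
        dispersion_alpha=float(data.get("dispersion_alpha", 0.3)),
        trend_per_month=float(data.get("trend_per_month", 1.0)),
        literature_fraction=float(data.get("literature_fraction", 0.1)),
        months=tuple(data.get("months", ("2008-01", "2015-06"))),
        injections=injections,
        seed=int(data.get("seed", 0)),
    )


# --------------------------------------------------------------------------
# Monte-Carlo operating characteristics of the detector


def regression_false_alarm_rate(
    n_reps: int = 10_000,
    mu: float = 10.0,
    alpha: float = 0.3,
    config: ScreenConfig | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Null false-alarm rate of the regression branch.

    Histories and the monitored count are drawn i.i.d. from a stationary
    NB(mu, alpha); any detection is by construction a false alarm.  Reps
    whose history is null (sparse) route to the heuristic branch and are
    excluded from the denominator.  Returns the rate, the Monte-Carlo
    standard error at the nominal level, and the denominator.
    """
    if config is None:
        config = ScreenConfig(threshold_tau=3, bound_type="prediction")
    rng = np.random.default_rng(seed)
    w = config.window_months
    n_eval = 0
    n_alarm = 0
    for _ in range(n_reps):
        history = sample_nb_counts(rng, np.full(w, mu), alpha)
        y0 = int(sample_nb_counts(rng, np.array([mu]), alpha)[0])
        if is_null_history(history, w):
            continue
        n_eval += 1
        if detect(history, y0, config) is not None:
            n_alarm += 1
    nominal = 1.0 - config.bound_level
    se_mc = math.sqrt(nominal * (1.0 - nominal) / max(n_eval, 1))
    return {
        "rate": n_alarm / max(n_eval, 1),
        "se_mc": se_mc,
        "n": float(n_eval),
        "nominal": nominal,
    }


def spike_detection_rate(
    n_reps: int = 1_000,
    mu: float = 10.0,
    alpha: float = 0.3,
    fold: float = 5.0,
    config: ScreenConfig | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Power against a deterministic spike of ``fold`` times the mean."""
    if config is None:
        config = ScreenConfig(threshold_tau=3, bound_type="prediction")
    rng = np.random.default_rng(seed)
    w = config.window_months
    y0 = int(round(fold * mu))
    n_eval = 0
    n_detect = 0
    for _ in range(n_reps):
        history = sample_nb_counts(rng, np.full(w, mu), alpha)
        if is_null_history(history, w):
            continue
        n_eval += 1
        if detect(history, y0, config) is not None:
            n_detect += 1
    return {"rate": n_detect / max(n_eval, 1), "n": float(n_eval), "y0": float(y0)}
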