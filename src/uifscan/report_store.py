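"""Report tables, term hierarchy and concern registers.

This module houses the shared domain types of the screening pipeline and the
readers/writers for the three flat-file inputs:

* ``reports.csv`` — individual case safety reports (ICSRs), one row per
  report–drug–event unit, with the receive date that defines the counting
  month;
* a hierarchy bundle — a MedDRA-like term hierarchy (PT → HLT → HLGT → SOC),
  SMQ memberships and IME/DME seriousness flags;
* ``concerns.csv`` — a register of historical safety concerns (index date,
  drug scope, event grouping terms, concern type) used to label detections.

The hierarchy here is deliberately single-axial: every preferred term (PT)
has exactly one HLT/HLGT/SOC path.  The screening algorithm only ever needs
PT-to-grouping membership, so multi-axiality is not modelled.
"""

from __future__ import annotations

import csv
import datetime as dt
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "ReportRecord",
    "TermHierarchy",
    "ConcernRecord",
    "ScreenConfig",
    "LoadReport",
    "FormatError",
    "RowValidationError",
    "IntegrityError",
    "load_reports",
    "write_reports",
    "load_hierarchy",
    "write_hierarchy",
    "load_concerns",
    "write_concerns",
    "packaged_concerns_path",
    "expand_grouping",
    "concern_case_definition",
]

GroupingLevel = Literal["PT", "HLT", "HLGT", "SOC", "SMQ"]

REPORT_COLUMNS = [
    "case_id",
    "receive_date",
    "substance",
    "product_name",
    "event_pt",
    "literature",
    "module",
]

CONCERN_COLUMNS = [
    "concern_id",
    "substance",
    "product_names",
    "index_date",
    "concern_type",
    "grouping_level",
    "grouping_id",
]


class FormatError(ValueError):
    """A file does not have the documented shape (e.g. missing columns)."""


class RowValidationError(ValueError):
    """One or more rows failed validation; ``rows`` holds 1-based row numbers."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {', '.join(map(str, rows))})")
        self.rows = list(rows)


class IntegrityError(ValueError):
    """A referential-integrity violation in the hierarchy or register."""


def normalize_name(name: str | None) -> str | None:
    """Case-fold and collapse whitespace; empty strings become None."""
    if name is None:
        return None
    collapsed = " ".join(str(name).split()).casefold()
    return collapsed or None


@dataclass(frozen=True)
class ReportRecord:
    """One report–drug–event observation: the atom of all counting.

    The receive date (the date the sender received the report) defines the
    calendar month the unit is counted in.  Records from the study module are
    never counted; only post-marketing spontaneous reports enter the screen.
    """

    case_id: str
    receive_date: dt.date
    substance: str
    product_name: str | None
    event_pt: str
    literature: bool
    module: Literal["post_marketing", "study"] = "post_marketing"

    @property
    def month(self) -> str:
        return f"{self.receive_date.year:04d}-{self.receive_date.month:02d}"


@dataclass
class LoadReport:
    """Bookkeeping produced by :func:`load_reports`."""

    n_rows: int = 0
    n_loaded: int = 0
    n_study_excluded: int = 0


@dataclass
class TermHierarchy:
    """A simplified single-axial MedDRA-like terminology.

    ``smq_members`` maps an SMQ id to ``{pt: scope}`` where scope is
    ``"broad"`` or ``"narrow"``.  ``ime_terms``/``dme_terms`` mark important
    and designated medical events; ``quality_issue_terms`` mark PTs that
    describe product quality problems directly (these are excluded from the
    case definitions of quality-defect concerns, which must be detectable
    from the reported harms alone).
    """

    pt_to_hlt: dict[str, str]
    hlt_to_hlgt: dict[str, str]
    hlgt_to_soc: dict[str, str]
    smq_members: dict[str, dict[str, str]] = field(default_factory=dict)
    ime_terms: frozenset[str] = frozenset()
    dme_terms: frozenset[str] = frozenset()
    quality_issue_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.ime_terms = frozenset(self.ime_terms)
        self.dme_terms = frozenset(self.dme_terms)
        self.quality_issue_terms = frozenset(self.quality_issue_terms)
        self.validate()

    @property
    def pts(self) -> frozenset[str]:
        return frozenset(self.pt_to_hlt)

    @property
    def serious_terms(self) -> frozenset[str]:
        """PTs flagged IME or DME — the event universe of the main analysis."""
        return self.ime_terms | self.dme_terms

    def validate(self) -> None:
        pts = set(self.pt_to_hlt)
        hlts = set(self.hlt_to_hlgt)
        hlgts = set(self.hlgt_to_soc)
        socs = set(self.hlgt_to_soc.values())
        # Disjoint level namespaces rule out cycles in the level maps.
        for a, b, what in [
            (pts, hlts, "PT/HLT"),
            (pts, hlgts, "PT/HLGT"),
            (hlts, hlgts, "HLT/HLGT"),
            (pts | hlts | hlgts, socs, "SOC"),
        ]:
            overlap = a & b
            if overlap:
                raise IntegrityError(
                    f"term(s) appear at two hierarchy levels ({what}): "
                    f"{sorted(overlap)[:5]}"
                )
        for pt, hlt in self.pt_to_hlt.items():
            if hlt not in self.hlt_to_hlgt:
                raise IntegrityError(f"PT {pt!r} maps to unknown HLT {hlt!r}")
        for hlt, hlgt in self.hlt_to_hlgt.items():
            if hlgt not in self.hlgt_to_soc:
                raise IntegrityError(f"HLT {hlt!r} maps to unknown HLGT {hlgt!r}")
        for smq, members in self.smq_members.items():
            unknown = set(members) - pts
            if unknown:
                raise IntegrityError(
                    f"SMQ {smq!r} lists unknown PT(s): {sorted(unknown)[:5]}"
                )
        for flag_name in ("ime_terms", "dme_terms", "quality_issue_terms"):
            unknown = set(getattr(self, flag_name)) - pts
            if unknown:
                raise IntegrityError(
                    f"{flag_name} lists unknown PT(s): {sorted(unknown)[:5]}"
                )

    def members(self, level: GroupingLevel, term_id: str) -> set[str]:
        """PTs grouped under one term of the hierarchy (or an SMQ)."""
        if level == "PT":
            if term_id not in self.pt_to_hlt:
                raise KeyError(f"unknown PT {term_id!r}")
            return {term_id}
        if level == "HLT":
            if term_id not in self.hlt_to_hlgt:
                raise KeyError(f"unknown HLT {term_id!r}")
            return {pt for pt, h in self.pt_to_hlt.items() if h == term_id}
        if level == "HLGT":
            if term_id not in self.hlgt_to_soc:
                raise KeyError(f"unknown HLGT {term_id!r}")
            hlts = {h for h, g in self.hlt_to_hlgt.items() if g == term_id}
            return {pt for pt, h in self.pt_to_hlt.items() if h in hlts}
        if level == "SOC":
            if term_id not in set(self.hlgt_to_soc.values()):
                raise KeyError(f"unknown SOC {term_id!r}")
            hlgts = {g for g, s in self.hlgt_to_soc.items() if s == term_id}
            hlts = {h for h, g in self.hlt_to_hlgt.items() if g in hlgts}
            return {pt for pt, h in self.pt_to_hlt.items() if h in hlts}
        if level == "SMQ":
            if term_id not in self.smq_members:
                raise KeyError(f"unknown SMQ {term_id!r}")
            return set(self.smq_members[term_id])
        raise KeyError(f"unknown grouping level {level!r}")


def expand_grouping(
    hierarchy: TermHierarchy,
    terms: Iterable[tuple[str, str]],
    restrict_ime_dme: bool = False,
) -> set[str]:
    """Union of member PTs across grouping terms.

    With ``restrict_ime_dme`` the result is intersected with the IME ∪ DME
    term set, mirroring the main analysis in which only clinically serious
    PTs are screened.
    """
    pts: set[str] = set()
    for level, term_id in terms:
        pts |= hierarchy.members(level, term_id)  # raises KeyError if unknown
    if restrict_ime_dme:
        pts &= hierarchy.serious_terms
    return pts


@dataclass(frozen=True)
class ConcernRecord:
    """A historical safety concern used as ground truth for evaluation.

    ``product_names is None`` means the concern is substance-wide (the
    register's "All" scope, typical of abuse/misuse concerns).  The index
    date anchors the true-positive window: a detection counts as true
    positive from 12 months before to 6 months after the index month.
    """

    concern_id: str
    substance: str
    index_date: dt.date
    concern_type: Literal["QD", "ME", "AM"]
    grouping_terms: tuple[tuple[str, str], ...]
    product_names: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.grouping_terms:
            raise ValueError(f"concern {self.concern_id!r} has no grouping terms")
        if self.concern_type not in ("QD", "ME", "AM"):
            raise ValueError(f"unknown concern type {self.concern_type!r}")

    @property
    def index_month(self) -> str:
        return f"{self.index_date.year:04d}-{self.index_date.month:02d}"


def concern_case_definition(
    hierarchy: TermHierarchy,
    concern: ConcernRecord,
    restrict_ime_dme: bool = True,
) -> set[str]:
    """PT set that defines a concern's events.

    Quality-defect concerns exclude PTs that name the quality issue itself:
    those would trigger regulatory action through other routes, and the
    algorithm's premise is that a quality defect is detectable through the
    reported harms.
    """
    pts = expand_grouping(hierarchy, concern.grouping_terms, restrict_ime_dme)
    if concern.concern_type == "QD":
        pts -= hierarchy.quality_issue_terms
    return pts


@dataclass
class ScreenConfig:
    """Configuration axes of the screen.

    Parameters
    ----------
    window_months:
        Length of the history window fitted by the forecast (default 6;
        at least 3, since the two-parameter trend model needs three usable
        points).
    threshold_tau:
        Minimum monthly report count for a combination to be eligible for
        detection.  Thresholds 3 and 5 bracket the range used in routine
        signal detection; 5 is the default.
    include_literature:
        Whether reports originating in the published literature enter the
        monthly counts.
    drug_level:
        Count per active substance or per commercial product name.  Records
        without a product name are excluded from product-level counting.
    event_level:
        ``pt`` — one series per preferred term; ``grouping`` — series per
        HLT/SMQ grouping term; ``pooled_all`` — a single series pooling
        every PT for the drug.
    restrict_ime_dme:
        Screen only PTs flagged as important/designated medical events.
    bound_level, bound_type:
        Probability level and flavour of the forecast's upper bound:
        ``ci_mean`` is a confidence bound on the expected count,
        ``prediction`` a count-scale quantile bound at the upper mean bound.
    """

    window_months: int = 6
    threshold_tau: int = 5
    include_literature: bool = True
    drug_level: Literal["substance", "product"] = "substance"
    event_level: Literal["pt", "pooled_all", "grouping"] = "pt"
    restrict_ime_dme: bool = True
    bound_level: float = 0.95
    bound_type: Literal["ci_mean", "prediction"] = "ci_mean"

    def __post_init__(self) -> None:
        if self.window_months < 3:
            raise ValueError("window_months must be >= 3")
        if self.threshold_tau < 1:
            raise ValueError("threshold_tau must be >= 1")
        if not (0.0 < self.bound_level < 1.0):
            raise ValueError("bound_level must lie in (0, 1)")
        if self.drug_level not in ("substance", "product"):
            raise ValueError(f"unknown drug_level {self.drug_level!r}")
        if self.event_level not in ("pt", "pooled_all", "grouping"):
            raise ValueError(f"unknown event_level {self.event_level!r}")
        if self.bound_type not in ("ci_mean", "prediction"):
            raise ValueError(f"unknown bound_type {self.bound_type!r}")


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(raw: str) -> bool:
    val = raw.strip().casefold()
    if val in _TRUE:
        return True
    if val in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def load_reports(
    path: str | Path, hierarchy: TermHierarchy
) -> tuple[list[ReportRecord], LoadReport]:
    """Read and validate a reports.csv table.

    Study-module rows are dropped (and tallied in the returned
    :class:`LoadReport`); rows with unparseable dates or PTs absent from the
    hierarchy raise :class:`RowValidationError` listing the offending
    1-based data row numbers.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REPORT_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"reports file missing column(s): {missing}")
        records: list[ReportRecord] = []
        report = LoadReport()
        bad_dates: list[int] = []
        bad_pts: list[int] = []
        bad_other: list[int] = []
        known_pts = hierarchy.pts
        for rownum, row in enumerate(reader, start=1):
            report.n_rows += 1
            module = (row["module"] or "").strip().casefold()
            if module == "study":
                report.n_study_excluded += 1
                continue
            if module != "post_marketing":
                bad_other.append(rownum)
                continue
            try:
                date = dt.date.fromisoformat(row["receive_date"].strip())
            except (ValueError, AttributeError):
                bad_dates.append(rownum)
                continue
            pt = (row["event_pt"] or "").strip()
            if pt not in known_pts:
                bad_pts.append(rownum)
                continue
            try:
                literature = _parse_bool(row["literature"] or "")
            except ValueError:
                bad_other.append(rownum)
                continue
            records.append(
                ReportRecord(
                    case_id=row["case_id"].strip(),
                    receive_date=date,
                    substance=normalize_name(row["substance"]) or "",
                    product_name=normalize_name(row["product_name"]),
                    event_pt=pt,
                    literature=literature,
                    module="post_marketing",
                )
            )
    if bad_dates:
        raise RowValidationError("unparseable receive_date", bad_dates)
    if bad_pts:
        raise RowValidationError("event_pt not in hierarchy", bad_pts)
    if bad_other:
        raise RowValidationError("invalid module or literature flag", bad_other)
    report.n_loaded = len(records)
    return records, report


def write_reports(records: Iterable[ReportRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.case_id,
                    r.receive_date.isoformat(),
                    r.substance,
                    r.product_name or "",
                    r.event_pt,
                    str(r.literature).lower(),
                    r.module,
                ]
            )


def load_hierarchy(path: str | Path) -> TermHierarchy:
    """Read a hierarchy bundle: a directory with ``pt.csv`` and ``smq.csv``.

    ``pt.csv`` columns: pt,hlt,hlgt,soc,ime,dme,quality_issue (one row per
    PT; the HLT→HLGT→SOC maps are induced and must be consistent across
    rows).  ``smq.csv`` columns: smq_id,pt,scope.
    """
    path = Path(path)
    pt_file = path / "pt.csv"
    smq_file = path / "smq.csv"
    if not pt_file.exists():
        raise FormatError(f"hierarchy bundle missing {pt_file}")
    pt_to_hlt: dict[str, str] = {}
    hlt_to_hlgt: dict[str, str] = {}
    hlgt_to_soc: dict[str, str] = {}
    ime: set[str] = set()
    dme: set[str] = set()
    quality: set[str] = set()
    with pt_file.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [
            c
            for c in ("pt", "hlt", "hlgt", "soc", "ime", "dme", "quality_issue")
            if c not in (reader.fieldnames or [])
        ]
        if missing:
            raise FormatError(f"pt.csv missing column(s): {missing}")
        for row in reader:
            pt, hlt, hlgt, soc = (row[c].strip() for c in ("pt", "hlt", "hlgt", "soc"))
            if pt in pt_to_hlt:
                raise IntegrityError(f"duplicate PT {pt!r} in pt.csv")
            if hlt in hlt_to_hlgt and hlt_to_hlgt[hlt] != hlgt:
                raise IntegrityError(f"HLT {hlt!r} mapped to two HLGTs")
            if hlgt in hlgt_to_soc and hlgt_to_soc[hlgt] != soc:
                raise IntegrityError(f"HLGT {hlgt!r} mapped to two SOCs")
            pt_to_hlt[pt] = hlt
            hlt_to_hlgt[hlt] = hlgt
            hlgt_to_soc[hlgt] = soc
            if _parse_bool(row["ime"]):
                ime.add(pt)
            if _parse_bool(row["dme"]):
                dme.add(pt)
            if _parse_bool(row["quality_issue"]):
                quality.add(pt)
    smq_members: dict[str, dict[str, str]] = {}
    if smq_file.exists():
        with smq_file.open(newline="") as fh:
            reader = csv.DictReader(fh)
            missing = [
                c for c in ("smq_id", "pt", "scope") if c not in (reader.fieldnames or [])
            ]
            if missing:
                raise FormatError(f"smq.csv missing column(s): {missing}")
            for row in reader:
                scope = row["scope"].strip().casefold() or "narrow"
                if scope not in ("broad", "narrow"):
                    raise FormatError(f"unknown SMQ scope {row['scope']!r}")
                smq_members.setdefault(row["smq_id"].strip(), {})[
                    row["pt"].strip()
                ] = scope
    return TermHierarchy(
        pt_to_hlt=pt_to_hlt,
        hlt_to_hlgt=hlt_to_hlgt,
        hlgt_to_soc=hlgt_to_soc,
        smq_members=smq_members,
        ime_terms=frozenset(ime),
        dme_terms=frozenset(dme),
        quality_issue_terms=frozenset(quality),
    )


def write_hierarchy(hierarchy: TermHierarchy, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with (path / "pt.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pt", "hlt", "hlgt", "soc", "ime", "dme", "quality_issue"])
        for pt in sorted(hierarchy.pt_to_hlt):
            hlt = hierarchy.pt_to_hlt[pt]
            hlgt = hierarchy.hlt_to_hlgt[hlt]
            soc = hierarchy.hlgt_to_soc[hlgt]
            writer.writerow(
                [
                    pt,
                    hlt,
                    hlgt,
                    soc,
                    str(pt in hierarchy.ime_terms).lower(),
                    str(pt in hierarchy.dme_terms).lower(),
                    str(pt in hierarchy.quality_issue_terms).lower(),
                ]
            )
    with (path / "smq.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smq_id", "pt", "scope"])
        for smq in sorted(hierarchy.smq_members):
            for pt in sorted(hierarchy.smq_members[smq]):
                writer.writerow([smq, pt, hierarchy.smq_members[smq][pt]])


_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def load_concerns(
    path: str | Path, hierarchy: TermHierarchy | None = None
) -> list[ConcernRecord]:
    """Read a concern register (one row per grouping term).

    If a hierarchy is supplied, each concern's grouping terms are resolved
    and the expansion checked non-empty; with ``hierarchy=None`` the register
    is loaded as documentation only (e.g. the packaged historical register,
    whose grouping terms name real-terminology groupings).
    """
    path = Path(path)
    rows_by_id: dict[str, list[dict[str, str]]] = {}
    order: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in CONCERN_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"concerns file missing column(s): {missing}")
        for row in reader:
            cid = row["concern_id"].strip()
            if cid not in rows_by_id:
                order.append(cid)
            rows_by_id.setdefault(cid, []).append(row)
    concerns: list[ConcernRecord] = []
    for cid in order:
        rows = rows_by_id[cid]
        first = rows[0]
        raw_date = first["index_date"].strip()
        if not _DATE_RE.match(raw_date):
            raise FormatError(f"concern {cid!r}: index_date must be ISO (YYYY-MM-DD)")
        ctype = first["concern_type"].strip().upper().replace("/", "").replace("-", "")
        products_raw = (first["product_names"] or "").strip()
        products: frozenset[str] | None = None
        if products_raw:
            names = [normalize_name(x) for x in products_raw.split(";")]
            products = frozenset(n for n in names if n is not None) or None
        grouping = tuple(
            (r["grouping_level"].strip().upper(), r["grouping_id"].strip())
            for r in rows
        )
        concern = ConcernRecord(
            concern_id=cid,
            substance=normalize_name(first["substance"]) or "",
            index_date=dt.date.fromisoformat(raw_date),
            concern_type=ctype,  # type: ignore[arg-type]
            grouping_terms=grouping,
            product_names=products,
        )
        if hierarchy is not None:
            try:
                pts = expand_grouping(hierarchy, concern.grouping_terms)
            except KeyError as exc:
                raise IntegrityError(
                    f"concern {cid!r} references unknown grouping term: {exc}"
                ) from exc
            if not pts:
                raise IntegrityError(f"concern {cid!r} expands to an empty PT set")
        concerns.append(concern)
    return concerns


def write_concerns(concerns: Iterable[ConcernRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CONCERN_COLUMNS)
        for c in concerns:
            products = ";".join(sorted(c.product_names)) if c.product_names else ""
            for level, term_id in c.grouping_terms:
                writer.writerow(
                    [
                        c.concern_id,
                        c.substance,
                        products,
                        c.index_date.isoformat(),
                        c.concern_type,
                        level,
                        term_id,
                    ]
                )


def packaged_concerns_path() -> Path:
    """Path of the packaged reference register of 13 historical EU concerns."""
    return Path(resources.files("uifscan") / "data" / "historical_concerns.csv")
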