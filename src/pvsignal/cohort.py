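"""Cohort construction: report-selection filters and descriptive summaries.

The analysis cohorts keep, per drug of interest, only deduplicated reports
where (i) the drug is the primary suspect, (ii) it was given by an accepted
route — intravenous only by default, which removes intraocular use of
agents that are also injected into the eye, and removes unspecified-route
reports, (iii) the reporter is a health professional, and (iv) the event
falls inside the study window when it is dated at all.

Retained reports are annotated with their thromboembolic classification,
fatal flag, age group, therapy class (with chemotherapy / other combined /
monotherapy) and onset interval, and summarised into a descriptive table
with counts and percentages per drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import onset_analysis
from .event_dictionary import EventDictionary, classify_report
from .faers_io import HEALTH_PROFESSIONAL, SafetyReport
from .signal_stats import LabeledReport

AGE_GROUPS = ("lt18", "18to64", "ge65", "unknown")
THERAPY_CLASSES = ("plus_chemotherapy", "other_combined", "monotherapy")

#: default brand/ingredient synonym table for the three antiangiogenic mAbs.
#: EYLEA is intentionally absent: intraocular use is removed by route, and the
#: intravenous product of the same ingredient is sold as ZALTREP/ZALTRAP.
DEFAULT_DRUG_SYNONYMS: dict[str, tuple[str, ...]] = {
    "BEVACIZUMAB": ("BEVACIZUMAB", "AVASTIN"),
    "RAMUCIRUMAB": ("RAMUCIRUMAB", "CYRAMZA"),
    "AFLIBERCEPT": ("AFLIBERCEPT", "ZALTRAP"),
}

#: default chemotherapy ingredients for therapy-class assignment
DEFAULT_CHEMOTHERAPY = (
    "OXALIPLATIN", "IRINOTECAN", "FLUOROURACIL", "CAPECITABINE", "PACLITAXEL",
    "DOCETAXEL", "CARBOPLATIN", "CISPLATIN", "GEMCITABINE", "PEMETREXED",
    "TEMOZOLOMIDE", "LEUCOVORIN", "FOLFIRI", "FOLFOX",
)
#: default non-chemotherapy antineoplastics (targeted / immune agents)
DEFAULT_OTHER_ANTINEOPLASTIC = (
    "PEMBROLIZUMAB", "NIVOLUMAB", "ATEZOLIZUMAB", "ERLOTINIB", "OSIMERTINIB",
    "CETUXIMAB", "TRASTUZUMAB", "INTERFERON",
)

#: default indication PT → group mapping (substring match, upper-case)
DEFAULT_INDICATION_GROUPS: dict[str, tuple[str, ...]] = {
    "colorectal": ("COLORECTAL", "COLON", "RECTAL"),
    "nsclc": ("NON-SMALL CELL LUNG",),
    "gastroesophageal": ("GASTRIC", "GASTROESOPHAGEAL", "OESOPHAGEAL"),
    "ovarian": ("OVARIAN",),
    "glioblastoma": ("GLIOBLASTOMA", "GLIOMA"),
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching printed-table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def age_group(age_years: float | None) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "lt18"
    if age_years < 65:
        return "18to64"
    return "ge65"


@dataclass
class CohortSpec:
    """Selection rules for one drug cohort."""

    drug_of_interest: str
    synonyms: tuple[str, ...] = ()
    required_role: str = "PS"
    route_filter: frozenset[str] | str = frozenset({"intravenous"})
    reporter_filter: frozenset[str] = frozenset(HEALTH_PROFESSIONAL)
    window: tuple[str, str] | None = None  # (start, end) quarter labels, inclusive

    def __post_init__(self) -> None:
        self.drug_of_interest = self.drug_of_interest.strip().upper()
        if not self.synonyms:
            if self.drug_of_interest not in DEFAULT_DRUG_SYNONYMS:
                raise ValueError(
                    f"unknown drug {self.drug_of_interest!r}: declare it with synonyms"
                )
            self.synonyms = DEFAULT_DRUG_SYNONYMS[self.drug_of_interest]
        self.synonyms = tuple(s.strip().upper() for s in self.synonyms)
        if self.route_filter != "any":
            self.route_filter = frozenset(self.route_filter)
            if not self.route_filter:
                raise ValueError("route_filter must be non-empty or 'any'")
        self.reporter_filter = frozenset(self.reporter_filter)
        if not self.reporter_filter:
            raise ValueError("reporter_filter must be non-empty")

    def matches_drug(self, entry) -> bool:
        """Case-insensitive containment of any synonym in the verbatim name
        or normalized ingredient."""
        hay = f"{entry.verbatim_name} {entry.normalized_ingredient}".upper()
        return any(syn in hay for syn in self.synonyms)


@dataclass
class CohortRow:
    primaryid: str
    drug: str
    labels: frozenset[str]
    sex: str
    age_group: str
    fatal: bool
    country: str
    indication_group: str
    therapy_class: str
    onset_days: int | None
    onset_reason: str | None = None
    reaction_pts: frozenset[str] = frozenset()


def _quarter_of(date) -> str | None:
    if date.year is None or date.month is None:
        return None
    return f"{date.year:04d}Q{(date.month - 1) // 3 + 1}"


def _in_window(report: SafetyReport, window: tuple[str, str] | None) -> bool:
    if window is None:
        return True
    q = _quarter_of(report.event_date)
    if q is None:
        return True  # undated events are retained
    return window[0] <= q <= window[1]


def therapy_class(
    report: SafetyReport,
    spec: CohortSpec,
    chemotherapy: Iterable[str] = DEFAULT_CHEMOTHERAPY,
    other_antineoplastic: Iterable[str] = DEFAULT_OTHER_ANTINEOPLASTIC,
) -> str:
    """Treatment-strategy class from co-reported drugs.

    ``plus_chemotherapy`` if any non-primary-suspect co-drug is in the
    chemotherapy list, else ``other_combined`` if any is in the
    non-chemotherapy antineoplastic list, else ``monotherapy``.
    """
    chemo = tuple(c.upper() for c in chemotherapy)
    other = tuple(o.upper() for o in other_antineoplastic)
    co_names = [
        f"{d.verbatim_name} {d.normalized_ingredient}".upper()
        for d in report.drugs
        if not (d.is_primary_suspect and spec.matches_drug(d))
    ]
    if any(any(c in name for c in chemo) for name in co_names):
        return "plus_chemotherapy"
    if any(any(o in name for o in other) for name in co_names):
        return "other_combined"
    return "monotherapy"


def indication_group(
    report: SafetyReport,
    groups: Mapping[str, tuple[str, ...]] = DEFAULT_INDICATION_GROUPS,
) -> str:
    """Tumour-indication group from INDI PTs (substring match); reports with
    no matching indication map to 'other', with none at all to 'unknown'."""
    pts = [pt for _, pt in report.indications]
    informative = [pt for pt in pts if "UNKNOWN" not in pt and pt != "PRODUCT USED FOR UNKNOWN INDICATION"]
    if not informative:
        return "unknown"
    for group, needles in groups.items():
        for pt in informative:
            if any(n in pt for n in needles):
                return group
    return "other"


def select_cohort(
    reports: Sequence[SafetyReport],
    spec: CohortSpec,
    dictionary: EventDictionary,
    chemotherapy: Iterable[str] = DEFAULT_CHEMOTHERAPY,
    other_antineoplastic: Iterable[str] = DEFAULT_OTHER_ANTINEOPLASTIC,
    indication_groups: Mapping[str, tuple[str, ...]] = DEFAULT_INDICATION_GROUPS,
) -> list[CohortRow]:
    """Apply the four selection filters and annotate retained reports.

    A report is retained iff some drug entry matches the drug of interest
    with the required role, that entry's route class passes the route
    filter (unspecified routes are excluded unless explicitly listed), the
    reporter qualification passes, and the event date is inside the window
    when dated.  The filters are pure predicates, so their order cannot
    change the result.
    """
    rows: list[CohortRow] = []
    for report in reports:
        matching = [
            d for d in report.drugs
            if d.role_code == spec.required_role and spec.matches_drug(d)
        ]
        if not matching:
            continue
        if spec.route_filter != "any":
            if not any(d.route_class in spec.route_filter for d in matching):
                continue
        if report.reporter_qualification not in spec.reporter_filter:
            continue
        if not _in_window(report, spec.window):
            continue
        onset = onset_analysis.onset_days(report)
        rows.append(
            CohortRow(
                primaryid=report.primaryid,
                drug=spec.drug_of_interest,
                labels=classify_report(report, dictionary),
                sex=report.sex,
                age_group=age_group(report.age_years),
                fatal=report.fatal,
                country=report.country,
                indication_group=indication_group(report, indication_groups),
                therapy_class=therapy_class(report, spec, chemotherapy, other_antineoplastic),
                onset_days=onset.days,
                onset_reason=onset.reason,
                reaction_pts=report.reaction_pts,
            )
        )
    return rows


def label_universe(
    reports: Sequence[SafetyReport],
    specs: Sequence[CohortSpec],
    dictionary: EventDictionary,
) -> list[LabeledReport]:
    """Reduce deduplicated reports to drug/event label sets for
    disproportionality, at both category and PT resolution.

    Drug labels follow each spec's role requirement and route filter, so the
    comparison universe's exposure definition matches the cohorts'.
    """
    out = []
    for report in reports:
        drugs = set()
        for spec in specs:
            matching = [
                d for d in report.drugs
                if d.role_code == spec.required_role and spec.matches_drug(d)
            ]
            if matching and (
                spec.route_filter == "any"
                or any(d.route_class in spec.route_filter for d in matching)
            ):
                drugs.add(spec.drug_of_interest)
        out.append(
            LabeledReport(
                primaryid=report.primaryid,
                drug_labels=frozenset(drugs),
                event_labels=classify_report(report, dictionary),
                pts=report.reaction_pts,
            )
        )
    return out


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

def _block(
    drug: str, block: str, counts: dict[str, int], denominator: int
) -> list[dict]:
    rows = []
    for level, count in counts.items():
        pct = None if denominator == 0 else round_half_up(100.0 * count / denominator, 1)
        rows.append(
            {
                "drug": drug, "block": block, "level": level,
                "count": count, "denominator": denominator, "value": pct,
            }
        )
    return rows


def descriptive_summary(
    rows: Sequence[CohortRow],
    top_countries: int = 4,
    quartile_convention: str = "linear",
) -> pd.DataFrame:
    """Per-drug descriptive table of the cohort rows.

    Percentages for sex, age group, outcome, countries, indication groups
    and therapy class are computed over the full cohort; onset-bin
    percentages over the subset with a computable onset (reported as the
    block's denominator).  Percentages are rounded half-up to one decimal.
    Empty cohorts yield zero counts and no division by zero.
    """
    records: list[dict] = []
    drugs = sorted({r.drug for r in rows})
    for drug in drugs:
        sub = [r for r in rows if r.drug == drug]
        n = len(sub)
        records.append(
            {"drug": drug, "block": "total", "level": "reports",
             "count": n, "denominator": n, "value": float(n)}
        )
        records += _block(
            drug, "sex",
            {lvl: sum(1 for r in sub if r.sex == lvl) for lvl in ("F", "M", "unknown")},
            n,
        )
        records += _block(
            drug, "age_group",
            {lvl: sum(1 for r in sub if r.age_group == lvl) for lvl in AGE_GROUPS},
            n,
        )
        records += _block(
            drug, "outcome",
            {"fatal": sum(1 for r in sub if r.fatal),
             "non_fatal": sum(1 for r in sub if not r.fatal)},
            n,
        )
        country_counts: dict[str, int] = {}
        for r in sub:
            if r.country:
                country_counts[r.country] = country_counts.get(r.country, 0) + 1
        top = dict(sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries])
        records += _block(drug, "country", top, n)
        indications = sorted({r.indication_group for r in sub})
        records += _block(
            drug, "indication_group",
            {lvl: sum(1 for r in sub if r.indication_group == lvl) for lvl in indications},
            n,
        )
        records += _block(
            drug, "therapy_class",
            {lvl: sum(1 for r in sub if r.therapy_class == lvl) for lvl in THERAPY_CLASSES},
            n,
        )
        onsets = [r.onset_days for r in sub if r.onset_days is not None]
        records += _block(
            drug, "onset_bin", onset_analysis.bin_counts(onsets), len(onsets)
        )
        mq = onset_analysis.median_iqr(onsets, convention=quartile_convention)
        for name, value in zip(("median", "q1", "q3"), mq or (None, None, None)):
            records.append(
                {"drug": drug, "block": "onset_summary", "level": name,
                 "count": len(onsets), "denominator": len(onsets), "value": value}
            )
    return pd.DataFrame(
        records, columns=["drug", "block", "level", "count", "denominator", "value"]
    )
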