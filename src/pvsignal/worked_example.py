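"""Worked example: published descriptive counts for the three mAb cohorts.

A large published FAERS analysis of thromboembolic events (TEEs) under the
three intravenous antiangiogenic monoclonal antibodies reports its
descriptive table as raw counts.  This module rebuilds cohort rows whose
marginal counts equal those printed numbers, so the package's summary
arithmetic (percentages, denominators, onset bins) can be exercised and
demonstrated against published values without access to the raw database.

Rows are synthetic: attributes are assigned independently by row index to
reproduce the marginal counts only, not any joint distribution.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CohortRow, descriptive_summary, round_half_up
from .onset_analysis import BIN_LABELS

#: representative onset day inside each printed bin
_BIN_REPRESENTATIVE = {"0-30d": 5, "31-60d": 40, "61-90d": 75,
                       "91-180d": 120, "181-365d": 250, ">365d": 500}

#: printed descriptive counts per drug cohort (reports with a TEE)
REFERENCE_COUNTS: dict[str, dict] = {
    "BEVACIZUMAB": {
        "n": 3117,
        "fatal": 949,
        "sex": {"F": 1359, "M": 1310, "unknown": 448},
        "age": {"lt18": 74, "18to64": 1187, "ge65": 1108, "unknown": 748},
        "indications": {"colorectal": 1085, "nsclc": 258, "gastroesophageal": 35,
                        "ovarian": 258, "glioblastoma": 227, "unknown": 139},
        "therapy": {"plus_chemotherapy": 1970, "other_combined": 165,
                    "monotherapy": 982},
        "onset_bins": dict(zip(BIN_LABELS, (660, 370, 205, 382, 248, 195))),  # n = 2060
        "pe_fatal": 180,  # fatal reports carrying the PE label
    },
    "RAMUCIRUMAB": {
        "n": 95,
        "fatal": 30,
        "sex": {"F": 32, "M": 54, "unknown": 9},
        "age": {"lt18": 0, "18to64": 30, "ge65": 45, "unknown": 20},
        "indications": {"gastroesophageal": 42, "colorectal": 11, "nsclc": 10,
                        "unknown": 12},
        "therapy": {"plus_chemotherapy": 54, "other_combined": 0, "monotherapy": 41},
        "onset_bins": dict(zip(BIN_LABELS, (31, 8, 7, 4, 2, 2))),  # n = 54
        "pe_fatal": 0,
    },
    "AFLIBERCEPT": {
        "n": 107,
        "fatal": 19,
        "sex": {"F": 34, "M": 59, "unknown": 14},
        "age": {"lt18": 1, "18to64": 36, "ge65": 54, "unknown": 16},
        "indications": {"colorectal": 83, "gastroesophageal": 4, "unknown": 16},
        "therapy": {"plus_chemotherapy": 80, "other_combined": 0, "monotherapy": 27},
        "onset_bins": dict(zip(BIN_LABELS, (42, 8, 5, 13, 13, 3))),  # n = 84
        "pe_fatal": 0,
    },
}


def _take(counter: dict[str, int], default: str):
    """Stateful level assigner: hands out each level `count` times, then the
    default."""
    remaining = dict(counter)

    def pick() -> str:
        for level, left in remaining.items():
            if left > 0:
                remaining[level] = left - 1
                return level
        return default

    return pick


def reference_cohort_rows() -> list[CohortRow]:
    """Cohort rows whose marginal counts equal the published table."""
    rows: list[CohortRow] = []
    for drug, spec in REFERENCE_COUNTS.items():
        onset_values: list[int] = []
        for label, count in spec["onset_bins"].items():
            onset_values += [_BIN_REPRESENTATIVE[label]] * count
        pick_sex = _take(spec["sex"], "unknown")
        pick_age = _take(spec["age"], "unknown")
        pick_ind = _take(spec["indications"], "other")
        pick_ther = _take(spec["therapy"], "monotherapy")
        for i in range(spec["n"]):
            fatal = i < spec["fatal"]
            labels = {"overall_TEE"}
            if fatal and i < spec["pe_fatal"]:
                labels |= {"PE", "VTE"}
            rows.append(CohortRow(
                primaryid=f"{drug}-{i}", drug=drug, labels=frozenset(labels),
                sex=pick_sex(), age_group=pick_age(), fatal=fatal, country="US",
                indication_group=pick_ind(), therapy_class=pick_ther(),
                onset_days=onset_values[i] if i < len(onset_values) else None,
                onset_reason=None if i < len(onset_values) else "missing",
            ))
    return rows


def reference_summary() -> pd.DataFrame:
    """Descriptive summary recomputed from the rebuilt reference rows."""
    return descriptive_summary(reference_cohort_rows())


def summary_value(summary: pd.DataFrame, drug: str, block: str, level: str) -> float:
    sub = summary[(summary.drug == drug) & (summary.block == block)
                  & (summary.level == level)]
    return float(sub["value"].iloc[0])


def onset_within_90d_pct(rows, drug: str) -> float:
    """Share of computable onsets at 90 days or less, as a printed percent."""
    days = [r.onset_days for r in rows if r.drug == drug and r.onset_days is not None]
    return round_half_up(100.0 * sum(d <= 90 for d in days) / len(days), 1)


def pe_share_of_fatal_pct(rows) -> float:
    """PE-labelled share of all fatal TEE rows, as a printed percent."""
    fatal = [r for r in rows if r.fatal]
    with_pe = sum(1 for r in fatal if "PE" in r.labels)
    return round_half_up(100.0 * with_pe / len(fatal), 2)
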