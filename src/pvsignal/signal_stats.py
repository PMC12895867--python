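"""Disproportionality statistics for drug–event report combinations.

Each drug × event comparison reduces the report universe to a 2×2 table

    a = target drug ∧ target event      b = target drug ∧ other events
    c = other drugs ∧ target event      d = other drugs ∧ other events

and two measures are computed on it:

* the reporting odds ratio, ROR = (a·d)/(b·c), with the usual Woolf
  log-scale 95% CI, exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); when any
  cell is zero the Haldane–Anscombe correction (+0.5 to all four cells) is
  applied, and only then, so non-degenerate tables are untouched;
* the Bayesian information component, IC = log2((a + 0.5)/(E + 0.5)) with
  E = (a+b)(a+c)/N, the shrinkage form used in Bayesian confidence
  propagation neural network screening, with the closed-form credibility
  interval approximation
      IC025 = IC − 3.3·(a+0.5)^(−1/2) − 2·(a+0.5)^(−3/2)
      IC975 = IC + 2.4·(a+0.5)^(−1/2) − 0.5·(a+0.5)^(−3/2).
  A full gamma-posterior quantile interval is available as an option.

A combination is evaluated only when it has at least three reports
(a ≥ 3), and flagged as a signal of disproportionate reporting when both
the ROR CI lower bound exceeds 1 and the IC interval lower bound exceeds 0.
No multiple-testing adjustment is applied across events or terms — each
flag is a screening signal, not a confirmatory test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

Z975 = 1.959963984540054

EVALUATION_MIN_REPORTS = 3


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of one drug × event disproportionality comparison."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("contingency table is empty (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def transpose(self) -> "ContingencyTable":
        """Swap the roles of drug and event (b ↔ c); leaves ROR unchanged."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass
class SignalEstimate:
    n_obs: int
    expected: float
    ror: float | None
    ror_ci: tuple[float, float] | None
    ic: float
    ic_ci: tuple[float, float]
    evaluated: bool
    signal: bool
    label: str = ""


def ror_estimate(
    t: ContingencyTable, zero_cell: str = "haldane"
) -> tuple[float, tuple[float, float]] | None:
    """ROR point estimate and two-sided 95% CI.

    ``zero_cell='haldane'`` adds 0.5 to every cell when any cell is zero
    (point and interval both computed on the corrected cells);
    ``zero_cell='none'`` returns None for tables with a zero cell instead
    of propagating infinities.
    """
    cells = (t.a, t.b, t.c, t.d)
    if 0 in cells:
        if zero_cell == "haldane":
            cells = tuple(x + 0.5 for x in cells)
        elif zero_cell == "none":
            return None
        else:
            raise ValueError(f"unknown zero-cell policy {zero_cell!r}")
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = Z975 * se
    return ror, (ror * math.exp(-half), ror * math.exp(half))


def ic_estimate(
    t: ContingencyTable, interval: str = "approximate"
) -> tuple[float, tuple[float, float]]:
    """Information component (bits) and 95% credibility interval.

    ``interval='approximate'`` uses the closed-form shrinkage approximation;
    ``interval='gamma'`` uses the quantiles of the
    Gamma(a + 0.5, rate = E + 0.5) posterior of the shrunk observed/expected
    ratio on the log2 scale.
    """
    e = t.expected
    a_s = t.a + 0.5
    ic = math.log2(a_s / (e + 0.5))
    if interval == "approximate":
        lower = ic - 3.3 * a_s ** -0.5 - 2.0 * a_s ** -1.5
        upper = ic + 2.4 * a_s ** -0.5 - 0.5 * a_s ** -1.5
    elif interval == "gamma":
        dist = stats.gamma(a_s, scale=1.0 / (e + 0.5))
        lower = math.log2(dist.ppf(0.025))
        upper = math.log2(dist.ppf(0.975))
    else:
        raise ValueError(f"unknown IC interval method {interval!r}")
    return ic, (lower, upper)


def evaluate_signal(
    t: ContingencyTable,
    label: str = "",
    zero_cell: str = "haldane",
    ic_interval: str = "approximate",
) -> SignalEstimate:
    """Combine both estimators and apply the dual-threshold signal rule.

    Combinations with fewer than three reports get ``evaluated=False`` and
    never a signal flag, whatever their point estimates.
    """
    ror_res = ror_estimate(t, zero_cell=zero_cell)
    ic, ic_ci = ic_estimate(t, interval=ic_interval)
    evaluated = t.a >= EVALUATION_MIN_REPORTS
    signal = bool(
        evaluated
        and ror_res is not None
        and ror_res[1][0] > 1.0
        and ic_ci[0] > 0.0
    )
    return SignalEstimate(
        n_obs=t.a,
        expected=t.expected,
        ror=None if ror_res is None else ror_res[0],
        ror_ci=None if ror_res is None else ror_res[1],
        ic=ic,
        ic_ci=ic_ci,
        evaluated=evaluated,
        signal=signal,
        label=label,
    )


# ---------------------------------------------------------------------------
# labeled universes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledReport:
    """One deduplicated report reduced to its drug and event memberships."""

    primaryid: str
    drug_labels: frozenset[str] = frozenset()
    event_labels: frozenset[str] = frozenset()
    pts: frozenset[str] = frozenset()


def build_contingency(
    universe: Sequence[LabeledReport],
    drug: str,
    event: str,
    at_pt_level: bool = False,
) -> ContingencyTable:
    """Count the 2×2 cells for one drug × event comparison.

    Each distinct report lands in exactly one cell.  The drug label must
    occur somewhere in the universe and, for category-level comparisons,
    so must the event label (raising otherwise guards against typos
    silently producing a = 0).  PT-level comparisons (``at_pt_level``)
    count membership in ``pts`` instead of ``event_labels``.
    """
    drug_vocab: set[str] = set()
    event_vocab: set[str] = set()
    for r in universe:
        drug_vocab |= r.drug_labels
        event_vocab |= r.pts if at_pt_level else r.event_labels
    if drug not in drug_vocab:
        raise ValueError(f"drug label {drug!r} absent from universe vocabulary")
    if event not in event_vocab:
        raise ValueError(f"event label {event!r} absent from universe vocabulary")
    a = b = c = d = 0
    for r in universe:
        has_drug = drug in r.drug_labels
        has_event = event in (r.pts if at_pt_level else r.event_labels)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


@dataclass
class PTScanResult:
    """Per-PT disproportionality scan for one drug."""

    drug: str
    evaluated: list[tuple[str, SignalEstimate]]  # a ≥ 3, sorted by IC025 desc
    audit: list[tuple[str, int]]  # every PT with its report count for the drug
    n_signals: int  # PTs with IC interval lower bound > 0


def pt_level_scan(
    universe: Sequence[LabeledReport],
    drug: str,
    pt_vocabulary: Iterable[str] | None = None,
    **signal_kwargs,
) -> PTScanResult:
    """Scan every PT for one drug against the rest of the universe.

    PTs with fewer than three reports for the drug are kept in the audit
    list but not evaluated.  Evaluated PTs are sorted by IC interval lower
    bound, descending.
    """
    if pt_vocabulary is None:
        vocab: set[str] = set()
        for r in universe:
            vocab |= r.pts
        pt_vocabulary = sorted(vocab)
    counts: dict[str, int] = {}
    for r in universe:
        if drug in r.drug_labels:
            for pt in r.pts:
                counts[pt] = counts.get(pt, 0) + 1
    audit = [(pt, counts.get(pt, 0)) for pt in pt_vocabulary]
    evaluated = []
    for pt, n in audit:
        if n < EVALUATION_MIN_REPORTS:
            continue
        table = build_contingency(universe, drug, pt, at_pt_level=True)
        evaluated.append((pt, evaluate_signal(table, label=f"{drug}×{pt}", **signal_kwargs)))
    evaluated.sort(key=lambda item: item[1].ic_ci[0], reverse=True)
    n_signals = sum(1 for _, est in evaluated if est.ic_ci[0] > 0)
    return PTScanResult(drug, evaluated, audit, n_signals)


def head_to_head(
    cohort_a: Sequence[LabeledReport],
    cohort_b: Sequence[LabeledReport],
    event: str,
    **signal_kwargs,
) -> SignalEstimate:
    """Direct comparison of two drug cohorts for one event.

    The universe is restricted to A ∪ B: a = A∧event, b = A∧¬event,
    c = B∧event, d = B∧¬event, with the same estimators and thresholds as
    the full-database comparison.  The cohorts must be disjoint by report
    id — a report that is primary-suspect for both drugs must be excluded
    upstream.
    """
    ids_a = {r.primaryid for r in cohort_a}
    ids_b = {r.primaryid for r in cohort_b}
    overlap = ids_a & ids_b
    if overlap:
        raise ValueError(
            f"cohorts overlap on {len(overlap)} report id(s), e.g. {sorted(overlap)[:3]}"
        )

    def count(cohort: Sequence[LabeledReport]) -> tuple[int, int]:
        with_event = sum(1 for r in cohort if event in r.event_labels or event in r.pts)
        return with_event, len(cohort) - with_event

    a, b = count(cohort_a)
    c, d = count(cohort_b)
    return evaluate_signal(ContingencyTable(a, b, c, d), label=f"A-vs-B×{event}", **signal_kwargs)
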