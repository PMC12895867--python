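"""Pre-specified simulation studies: calibration and parameter recovery.

These runners define, in one place, the simulation designs used to check
that the pipeline's estimators behave as advertised:

* **null calibration** — 2×2 tables drawn multinomially under drug–event
  independence; the 95% ROR interval should cover 1 at its nominal rate
  and the dual-threshold signal rule should fire rarely;
* **signal recovery** — a full archive with a ×3 odds multiplier planted
  on the pulmonary-embolism terms of one drug; the pipeline's ROR should
  recover the closed-form population ROR implied by the configuration;
* **mortality recovery** — an archive with an exposure-dependent fatal
  odds multiplier of 1.2; the logistic model's adjusted odds ratio should
  recover it.  This design raises the thromboembolic background so the
  exposed arm is large enough (≈20% of cohort rows) that the recovery
  band is several standard errors wide — a power choice, fixed up front;
* **onset separation** — two drugs with log-normal onset medians 60.5 and
  26.5 days; the Kruskal-Wallis test should detect the separation at
  500 onsets per group.

The study drugs are given elevated catalog prevalence (0.40 combined)
relative to realistic reporting shares for the same reason: at the study
size of 1e5 reports the drug–event cell then holds hundreds of reports and
sampling error is small against the recovery bands.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import faers_io
from .cohort import CohortSpec, label_universe, select_cohort
from .event_dictionary import example_dictionary
from .onset_analysis import kruskal_wallis
from .outcome_model import build_model_frame, fit_logistic
from .signal_stats import ContingencyTable, build_contingency, evaluate_signal
from .synthetic_faers import (
    DrugProfile,
    PlantedSignal,
    SimulationConfig,
    generate,
)

STUDY_DRUGS = ("BEVACIZUMAB", "RAMUCIRUMAB", "AFLIBERCEPT")


def _recovery_catalog() -> tuple[DrugProfile, ...]:
    return (
        DrugProfile("BEVACIZUMAB", ("AVASTIN",), 0.30,
                    routes=(("INTRAVENOUS", 0.90), ("INTRAVITREAL", 0.05), ("", 0.05)),
                    onset_median_days=60.5, onset_sigma=1.25, chemo_prob=0.6),
        DrugProfile("RAMUCIRUMAB", ("CYRAMZA",), 0.05,
                    routes=(("INTRAVENOUS", 0.92), ("", 0.08)),
                    onset_median_days=26.5, onset_sigma=1.25, chemo_prob=0.55),
        DrugProfile("AFLIBERCEPT", ("ZALTRAP",), 0.05,
                    routes=(("INTRAVENOUS", 0.70), ("INTRAVITREAL", 0.25), ("", 0.05)),
                    onset_median_days=31.5, onset_sigma=1.25, chemo_prob=0.75),
        DrugProfile("PACLITAXEL", ("TAXOL",), 0.20,
                    routes=(("INTRAVENOUS", 0.9), ("", 0.1)), onset_median_days=40.0),
        DrugProfile("PEMBROLIZUMAB", ("KEYTRUDA",), 0.15,
                    routes=(("INTRAVENOUS", 0.95), ("", 0.05)), onset_median_days=50.0),
        DrugProfile("METFORMIN", ("GLUCOPHAGE",), 0.25,
                    routes=(("ORAL", 0.9), ("", 0.1)), onset_median_days=90.0),
    )


def _scaled_tee_background(factor: float) -> tuple[tuple[str, float], ...]:
    base = SimulationConfig(seed=0).tee_background
    return tuple((pt, min(p * factor, 0.5)) for pt, p in base)


def _ingest(archive_dir: Path):
    sets, _ = faers_io.read_archive(archive_dir)
    reports, _ = faers_io.assemble_reports(sets)
    deduped, _ = faers_io.deduplicate(reports)
    return deduped


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_calibration(
    seed: int, n_replicates: int = 2000, n_reports: int = 100_000,
    p_drug: float = 0.10, p_event: float = 0.05,
) -> dict:
    """Coverage and false-signal rate under drug–event independence.

    Each replicate draws one multinomial 2×2 table with independent
    margins, so the true ROR is exactly 1.  Reported: the fraction of
    replicates whose 95% ROR CI contains 1, and the fraction flagged by
    the dual ROR/IC threshold rule.
    """
    rng = np.random.default_rng(seed)
    probs = np.array([
        p_drug * p_event, p_drug * (1 - p_event),
        (1 - p_drug) * p_event, (1 - p_drug) * (1 - p_event),
    ])
    draws = rng.multinomial(n_reports, probs, size=n_replicates)
    covered = flagged = 0
    for a, b, c, d in draws:
        est = evaluate_signal(ContingencyTable(int(a), int(b), int(c), int(d)))
        if est.ror_ci is not None and est.ror_ci[0] <= 1.0 <= est.ror_ci[1]:
            covered += 1
        flagged += est.signal
    return {
        "n_replicates": n_replicates,
        "coverage_pct": 100.0 * covered / n_replicates,
        "signal_rate_pct": 100.0 * flagged / n_replicates,
    }


# ---------------------------------------------------------------------------
# signal recovery
# ---------------------------------------------------------------------------

def signal_recovery_config(seed: int, n_reports: int = 100_000) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, n_reports=n_reports,
        drug_catalog=_recovery_catalog(),
        duplicate_rate=0.0,
        planted_signals=(PlantedSignal("BEVACIZUMAB", "PE", 3.0),),
    )


def run_signal_recovery(seed: int, work_dir: str | Path, n_reports: int = 100_000) -> dict:
    """Generate, ingest, and estimate the planted PE disproportionality."""
    config = signal_recovery_config(seed, n_reports)
    truth = generate(config, Path(work_dir), write_case_truth=False)
    deduped = _ingest(Path(work_dir))
    hp = {"physician", "pharmacist", "other_health_professional"}
    universe_reports = [r for r in deduped if r.reporter_qualification in hp]
    specs = [CohortSpec(drug_of_interest=d) for d in STUDY_DRUGS]
    universe = label_universe(universe_reports, specs, example_dictionary())
    table = build_contingency(universe, "BEVACIZUMAB", "PE")
    est = evaluate_signal(table)
    return {
        "n_reports": n_reports,
        "cells": (table.a, table.b, table.c, table.d),
        "ror": est.ror,
        "ror_ci": est.ror_ci,
        "theoretical_ror": truth.signals[0].theoretical_ror,
        "signal": est.signal,
    }


# ---------------------------------------------------------------------------
# mortality recovery
# ---------------------------------------------------------------------------

def mortality_recovery_config(seed: int, n_reports: int = 100_000) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, n_reports=n_reports,
        drug_catalog=_recovery_catalog(),
        tee_background=_scaled_tee_background(7.0),
        duplicate_rate=0.0,
        fatality_base=0.25,
        fatality_tee_odds_multiplier=1.2,
    )


def run_mortality_recovery(seed: int, work_dir: str | Path, n_reports: int = 100_000) -> dict:
    """Recover the planted fatal-outcome odds ratio from the fitted model."""
    config = mortality_recovery_config(seed, n_reports)
    generate(config, Path(work_dir), write_case_truth=False)
    deduped = _ingest(Path(work_dir))
    dictionary = example_dictionary()
    rows = []
    for drug in STUDY_DRUGS:
        rows += select_cohort(deduped, CohortSpec(drug_of_interest=drug), dictionary)
    fit = fit_logistic(build_model_frame(rows))
    point, lo, hi = fit.aor["exposure"]
    return {
        "n_rows": len(rows),
        "n_exposed": int(sum(1 for r in rows if "overall_TEE" in r.labels)),
        "aor": point, "aor_ci": (lo, hi),
        "true_aor": config.fatality_tee_odds_multiplier,
        "p": fit.p_values["exposure"],
    }


# ---------------------------------------------------------------------------
# onset separation
# ---------------------------------------------------------------------------

def onset_separation_config(seed: int, n_reports: int = 4000) -> SimulationConfig:
    catalog = (
        DrugProfile("BEVACIZUMAB", ("AVASTIN",), 0.5,
                    routes=(("INTRAVENOUS", 1.0),),
                    onset_median_days=60.5, onset_sigma=1.25),
        DrugProfile("RAMUCIRUMAB", ("CYRAMZA",), 0.5,
                    routes=(("INTRAVENOUS", 1.0),),
                    onset_median_days=26.5, onset_sigma=1.25),
    )
    return SimulationConfig(
        seed=seed, n_reports=n_reports, drug_catalog=catalog,
        duplicate_rate=0.0, partial_date_rate=0.0,
        missingness=(("age", 0.0), ("event_dt", 0.0), ("start_dt", 0.0)),
    )


def run_onset_separation(seed: int, work_dir: str | Path, n_per_group: int = 500) -> dict:
    """Kruskal-Wallis detection of a planted onset-median separation."""
    config = onset_separation_config(seed)
    generate(config, Path(work_dir), write_case_truth=False)
    deduped = _ingest(Path(work_dir))
    dictionary = example_dictionary()
    groups = []
    for drug in ("BEVACIZUMAB", "RAMUCIRUMAB"):
        rows = select_cohort(deduped, CohortSpec(drug_of_interest=drug), dictionary)
        days = [r.onset_days for r in rows if r.onset_days is not None]
        if len(days) < n_per_group:
            raise RuntimeError(f"only {len(days)} onsets for {drug}")
        groups.append(days[:n_per_group])
    res = kruskal_wallis(groups, labels=["BEVACIZUMAB", "RAMUCIRUMAB"])
    medians = [float(np.median(g)) for g in groups]
    return {
        "n_per_group": n_per_group,
        "medians": medians,
        "statistic": res.statistic,
        "p_value": res.p_value,
    }
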