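"""Synthetic FAERS-dialect archive generator with known ground truth.

The generator emits quarterly ``$``-delimited DEMO/DRUG/REAC/OUTC/THER/INDI
files in the modern dialect, sampling reports from an explicit statistical
model so every downstream estimate can be checked against a computable
truth:

* each case gets one primary-suspect drug from a catalog with configured
  prevalences, a route, a reporter qualification and demographics;
* thromboembolic-event PTs are Bernoulli draws at configured background
  probabilities; a planted signal multiplies the *odds* of its target PT
  (or of every PT in a target category) given the drug, so the implied
  population reporting odds ratio is available in closed form from the
  config — parameter-recovery tests compare against that, not against the
  raw multiplier;
* the fatal flag is drawn with exposure-dependent odds (a target adjusted
  odds ratio); onsets come from per-drug log-normal distributions;
* duplicate case versions (advanced receipt date, new primaryid), partial
  dates and missing fields are applied last, after the truth is recorded.

Identical (config, seed) pairs produce byte-identical archives.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .event_dictionary import CATEGORIES, SUBTYPES, EventDictionary, example_dictionary

DEMO_COLUMNS = ("PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
                "SEX", "OCC_COD", "REPORTER_COUNTRY")
DRUG_COLUMNS = ("PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME",
                "PROD_AI", "ROUTE")
REAC_COLUMNS = ("PRIMARYID", "CASEID", "PT")
OUTC_COLUMNS = ("PRIMARYID", "CASEID", "OUTC_COD")
THER_COLUMNS = ("PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT", "END_DT")
INDI_COLUMNS = ("PRIMARYID", "CASEID", "INDI_DRUG_SEQ", "INDI_PT")

_REPORTER_TO_OCC = {"physician": "MD", "pharmacist": "PH",
                    "other_health_professional": "OT", "consumer": "CN"}


@dataclass(frozen=True)
class DrugProfile:
    """One primary-suspect drug in the catalog."""

    ingredient: str
    brands: tuple[str, ...]
    prevalence: float
    routes: tuple[tuple[str, float], ...] = (("INTRAVENOUS", 1.0),)
    onset_median_days: float = 45.0
    onset_sigma: float = 1.25
    chemo_prob: float = 0.0
    other_combo_prob: float = 0.0
    indications: tuple[tuple[str, float], ...] = ()  # PT -> prob; rest unknown


@dataclass(frozen=True)
class PlantedSignal:
    """Odds multiplier on a PT (or every PT of a category) given a drug."""

    drug: str
    target: str  # a PT from the catalog, or a category/subtype name
    odds_multiplier: float


def _default_drug_catalog() -> tuple[DrugProfile, ...]:
    # Prevalences loosely follow the relative reporting volume of the three
    # antiangiogenic mAbs against a large "everything else" background; the
    # mAb onset medians/dispersions echo the printed descriptive table
    # (60.5 / 26.5 / 31.5 days; q3/median ratios near 2.4 ⇒ sigma ≈ 1.25).
    return (
        DrugProfile(
            "BEVACIZUMAB", ("AVASTIN",), 0.12,
            routes=(("INTRAVENOUS", 0.85), ("INTRAVITREAL", 0.10), ("", 0.05)),
            onset_median_days=60.5, onset_sigma=1.25, chemo_prob=0.6,
            other_combo_prob=0.05,
            indications=(("COLORECTAL CANCER", 0.35), ("NON-SMALL CELL LUNG CANCER", 0.08),
                         ("OVARIAN CANCER", 0.08), ("GLIOBLASTOMA", 0.07),
                         ("BREAST CANCER", 0.10)),
        ),
        DrugProfile(
            "RAMUCIRUMAB", ("CYRAMZA",), 0.04,
            routes=(("INTRAVENOUS", 0.92), ("", 0.08)),
            onset_median_days=26.5, onset_sigma=1.25, chemo_prob=0.55,
            indications=(("GASTRIC CANCER", 0.44), ("COLORECTAL CANCER", 0.12),
                         ("NON-SMALL CELL LUNG CANCER", 0.10)),
        ),
        DrugProfile(
            "AFLIBERCEPT", ("ZALTRAP",), 0.04,
            routes=(("INTRAVENOUS", 0.70), ("INTRAVITREAL", 0.25), ("", 0.05)),
            onset_median_days=31.5, onset_sigma=1.25, chemo_prob=0.75,
            indications=(("COLORECTAL CANCER", 0.78), ("GASTRIC CANCER", 0.04)),
        ),
        DrugProfile(
            "PACLITAXEL", ("TAXOL",), 0.20,
            routes=(("INTRAVENOUS", 0.9), ("", 0.1)),
            onset_median_days=40.0, chemo_prob=0.0,
            indications=(("BREAST CANCER", 0.5), ("OVARIAN CANCER", 0.2)),
        ),
        DrugProfile(
            "PEMBROLIZUMAB", ("KEYTRUDA",), 0.20,
            routes=(("INTRAVENOUS", 0.95), ("", 0.05)),
            onset_median_days=50.0,
            indications=(("NON-SMALL CELL LUNG CANCER", 0.4), ("MELANOMA", 0.3)),
        ),
        DrugProfile(
            "METFORMIN", ("GLUCOPHAGE",), 0.40,
            routes=(("ORAL", 0.9), ("", 0.1)),
            onset_median_days=90.0,
            indications=(("TYPE 2 DIABETES MELLITUS", 0.9),),
        ),
    )


def _default_tee_background() -> tuple[tuple[str, float], ...]:
    # background (no planted signal) per-report probabilities of TEE PTs
    return (
        ("PULMONARY EMBOLISM", 0.006),
        ("PULMONARY THROMBOSIS", 0.001),
        ("DEEP VEIN THROMBOSIS", 0.006),
        ("VENOUS THROMBOSIS", 0.002),
        ("JUGULAR VEIN THROMBOSIS", 0.0008),
        ("MYOCARDIAL INFARCTION", 0.005),
        ("ACUTE MYOCARDIAL INFARCTION", 0.002),
        ("CEREBRAL INFARCTION", 0.003),
        ("CEREBROVASCULAR ACCIDENT", 0.004),
        ("ARTERIAL THROMBOSIS", 0.001),
        ("EMBOLISM", 0.003),
        ("THROMBOSIS", 0.005),
        ("THROMBOEMBOLIC EVENT", 0.001),
    )


def _default_noise_pts() -> tuple[tuple[str, float], ...]:
    return (
        ("NAUSEA", 0.12), ("FATIGUE", 0.10), ("DIARRHOEA", 0.09),
        ("PYREXIA", 0.07), ("HEADACHE", 0.07), ("VOMITING", 0.06),
        ("RASH", 0.05), ("DECREASED APPETITE", 0.05), ("ANAEMIA", 0.04),
        ("HYPERTENSION", 0.04),
    )


@dataclass
class SimulationConfig:
    """Full description of one synthetic archive.

    ``seed`` is mandatory: the generator refuses silent nondeterminism.
    """

    seed: int
    n_reports: int = 20000
    quarters: tuple[str, ...] = ("2023Q1", "2023Q2", "2023Q3", "2023Q4")
    drug_catalog: tuple[DrugProfile, ...] = field(default_factory=_default_drug_catalog)
    tee_background: tuple[tuple[str, float], ...] = field(default_factory=_default_tee_background)
    noise_pts: tuple[tuple[str, float], ...] = field(default_factory=_default_noise_pts)
    planted_signals: tuple[PlantedSignal, ...] = ()
    fatality_base: float = 0.25
    fatality_tee_odds_multiplier: float = 1.2
    sex_dist: tuple[tuple[str, float], ...] = (("F", 0.44), ("M", 0.44), ("", 0.12))
    age_mean: float = 62.0
    age_sd: float = 14.0
    reporter_dist: tuple[tuple[str, float], ...] = (
        ("physician", 0.45), ("pharmacist", 0.15),
        ("other_health_professional", 0.20), ("consumer", 0.20),
    )
    countries: tuple[tuple[str, float], ...] = (
        ("US", 0.40), ("JP", 0.20), ("DE", 0.12), ("FR", 0.12), ("GB", 0.08),
        ("CN", 0.08),
    )
    duplicate_rate: float = 0.10
    missingness: tuple[tuple[str, float], ...] = (
        ("age", 0.20), ("event_dt", 0.10), ("start_dt", 0.15),
    )
    partial_date_rate: float = 0.05
    dictionary: EventDictionary | None = None  # defaults to the fixture dictionary

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.dictionary is None:
            self.dictionary = example_dictionary()
        prev = sum(d.prevalence for d in self.drug_catalog)
        if not math.isclose(prev, 1.0, abs_tol=1e-9):
            raise ValueError(f"drug prevalences must sum to 1, got {prev}")
        for name, p in list(self.tee_background) + list(self.noise_pts):
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name!r} outside [0,1]")
        known_drugs = {d.ingredient for d in self.drug_catalog}
        known_targets = (
            {pt for pt, _ in self.tee_background}
            | set(CATEGORIES) | set(SUBTYPES) | {"overall_TEE"}
        )
        for sig in self.planted_signals:
            if sig.drug not in known_drugs:
                raise ValueError(f"planted signal references unknown drug {sig.drug!r}")
            if sig.target not in known_targets:
                raise ValueError(f"planted signal references unknown target {sig.target!r}")
            if sig.odds_multiplier <= 0:
                raise ValueError("planted odds multiplier must be > 0")


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclass
class CaseTruth:
    caseid: str
    surviving_primaryid: str
    version_primaryids: list[str]
    drug: str
    route: str
    reporter: str
    exposed: bool  # carries any TEE PT
    fatal: bool
    onset_days_true: int
    tee_pts: list[str]


@dataclass
class SignalTruth:
    drug: str
    target: str
    odds_multiplier: float
    expected_cells: tuple[float, float, float, float]
    theoretical_ror: float


@dataclass
class GroundTruth:
    config_echo: dict
    cases: list[CaseTruth]
    signals: list[SignalTruth]

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def to_json(self) -> dict:
        return {
            "config": self.config_echo,
            "n_cases": self.n_cases,
            "signals": [dataclasses.asdict(s) for s in self.signals],
            "cases": [dataclasses.asdict(c) for c in self.cases],
        }


def _pt_probability(config: SimulationConfig, drug: str, pt: str) -> float:
    """Per-report probability of PT given primary-suspect drug, with every
    applicable planted odds multiplier applied on the odds scale."""
    base = dict(config.tee_background)[pt]
    odds = base / (1.0 - base)
    label_sets = config.dictionary.label_sets()
    for sig in config.planted_signals:
        if sig.drug != drug:
            continue
        if sig.target == pt or pt in label_sets.get(sig.target, frozenset()):
            odds *= sig.odds_multiplier
    return odds / (1.0 + odds)


def theoretical_signal_truth(config: SimulationConfig) -> list[SignalTruth]:
    """Closed-form expected 2×2 cells and population ROR per planted signal.

    For a PT target the event is that PT; for a category target the event
    is "any PT of the category", with per-PT independence as sampled.
    Cells are expected counts over the whole generated universe.
    """
    out = []
    label_sets = config.dictionary.label_sets()
    n = config.n_reports
    for sig in config.planted_signals:
        if sig.target in dict(config.tee_background):
            pts = [sig.target]
        else:
            pts = sorted(set(label_sets[sig.target]) & set(dict(config.tee_background)))

        def p_event(drug: str) -> float:
            miss = 1.0
            for pt in pts:
                miss *= 1.0 - _pt_probability(config, drug, pt)
            return 1.0 - miss

        a = b = c = d = 0.0
        for profile in config.drug_catalog:
            w = n * profile.prevalence
            pe = p_event(profile.ingredient)
            if profile.ingredient == sig.drug:
                a += w * pe
                b += w * (1 - pe)
            else:
                c += w * pe
                d += w * (1 - pe)
        out.append(
            SignalTruth(sig.drug, sig.target, sig.odds_multiplier,
                        (a, b, c, d), (a * d) / (b * c))
        )
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _choice_index(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    return rng.choice(len(probs), size=size, p=probs / probs.sum())


def _quarter_start(label: str) -> _dt.date:
    year, q = int(label[:4]), int(label[5])
    return _dt.date(year, 3 * (q - 1) + 1, 1)


def _fmt(d: _dt.date) -> str:
    return d.strftime("%Y%m%d")


def generate(
    config: SimulationConfig, out_dir: str | Path, write_case_truth: bool = True
) -> GroundTruth:
    """Write one synthetic archive under ``out_dir`` and return its truth.

    Layout: ``<out_dir>/<quarter>/{DEMO,DRUG,REAC,OUTC,THER,INDI}<qq>.txt``
    plus ``truth.json`` and a ``config_used.json`` echo.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_probs = np.array([d.prevalence for d in config.drug_catalog])
    drug_idx = _choice_index(rng, drug_probs, n)
    quarter_idx = rng.integers(0, len(config.quarters), size=n)
    sex_labels, sex_p = zip(*config.sex_dist)
    sex_idx = _choice_index(rng, np.array(sex_p), n)
    rep_labels, rep_p = zip(*config.reporter_dist)
    rep_idx = _choice_index(rng, np.array(rep_p), n)
    ctry_labels, ctry_p = zip(*config.countries)
    ctry_idx = _choice_index(rng, np.array(ctry_p), n)
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 1, 99)

    tee_names = [pt for pt, _ in config.tee_background]
    tee_u = rng.random((n, len(tee_names)))
    noise_names = [pt for pt, _ in config.noise_pts]
    noise_p = np.array([p for _, p in config.noise_pts])
    noise_hit = rng.random((n, len(noise_names))) < noise_p
    forced_noise = rng.integers(0, len(noise_names), size=n)

    fatal_u = rng.random(n)
    onset_z = rng.standard_normal(n)
    start_offset = rng.integers(0, 85, size=n)
    fda_lag = rng.integers(1, 60, size=n)
    dup_u = rng.random(n)
    dup_back = rng.integers(30, 200, size=n)
    miss = dict(config.missingness)
    miss_age = rng.random(n) < miss.get("age", 0.0)
    miss_event = rng.random(n) < miss.get("event_dt", 0.0)
    miss_start = rng.random(n) < miss.get("start_dt", 0.0)
    partial_event = rng.random(n) < config.partial_date_rate
    partial_start = rng.random(n) < config.partial_date_rate
    route_u = rng.random(n)
    chemo_u = rng.random(n)
    combo_u = rng.random(n)
    indi_u = rng.random(n)
    outc_u = rng.random(n)

    # per-drug per-PT probabilities, planted multipliers applied
    pt_prob_by_drug = {
        d.ingredient: np.array([_pt_probability(config, d.ingredient, pt) for pt in tee_names])
        for d in config.drug_catalog
    }

    overall_pts = config.dictionary.overall_tee
    base_odds = config.fatality_base / (1 - config.fatality_base)
    p_fatal_unexposed = config.fatality_base
    exp_odds = base_odds * config.fatality_tee_odds_multiplier
    p_fatal_exposed = exp_odds / (1 + exp_odds)

    tables: dict[str, dict[str, list[str]]] = {
        q: {t: [] for t in ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")}
        for q in config.quarters
    }
    cases: list[CaseTruth] = []

    for i in range(n):
        profile = config.drug_catalog[drug_idx[i]]
        quarter = config.quarters[quarter_idx[i]]
        caseid = str(10_000_000 + i)

        # route from the drug's route distribution
        cum, route = 0.0, profile.routes[-1][0]
        for r_name, r_p in profile.routes:
            cum += r_p
            if route_u[i] < cum:
                route = r_name
                break

        probs = pt_prob_by_drug[profile.ingredient]
        tee_pts = [tee_names[j] for j in range(len(tee_names)) if tee_u[i, j] < probs[j]]
        noise = [noise_names[j] for j in range(len(noise_names)) if noise_hit[i, j]]
        if not tee_pts and not noise:
            noise = [noise_names[forced_noise[i]]]
        exposed = any(pt in overall_pts for pt in tee_pts)
        fatal = fatal_u[i] < (p_fatal_exposed if exposed else p_fatal_unexposed)

        onset = int(round(profile.onset_median_days * math.exp(profile.onset_sigma * onset_z[i])))
        start = _quarter_start(quarter) + _dt.timedelta(days=int(start_offset[i]))
        event = start + _dt.timedelta(days=onset)
        fda = event + _dt.timedelta(days=int(fda_lag[i]))

        duplicated = dup_u[i] < config.duplicate_rate
        versions = []
        if duplicated:
            versions.append((f"{caseid}1", fda - _dt.timedelta(days=int(dup_back[i]))))
            versions.append((f"{caseid}2", fda))
        else:
            versions.append((f"{caseid}1", fda))
        surviving = versions[-1][0]

        event_tok = "" if miss_event[i] else (
            _fmt(event)[:6] if partial_event[i] else _fmt(event))
        start_tok = "" if miss_start[i] else (
            _fmt(start)[:6] if partial_start[i] else _fmt(start))
        age_tok = "" if miss_age[i] else str(int(round(ages[i])))
        sex_tok = sex_labels[sex_idx[i]]
        occ = _REPORTER_TO_OCC[rep_labels[rep_idx[i]]]
        country = ctry_labels[ctry_idx[i]]

        # indication for the PS drug
        indication = ""
        cum = 0.0
        for ind_pt, ind_p in profile.indications:
            cum += ind_p
            if indi_u[i] < cum:
                indication = ind_pt
                break

        chemo = chemo_u[i] < profile.chemo_prob
        other_combo = (not chemo) and combo_u[i] < profile.other_combo_prob

        tq = tables[quarter]
        for pid, fda_date in versions:
            tq["DEMO"].append("$".join((
                pid, caseid, _fmt(fda_date), event_tok, age_tok, "YR" if age_tok else "",
                sex_tok, occ, country)))
            tq["DRUG"].append("$".join((
                pid, caseid, "1", "PS", profile.brands[0], profile.ingredient, route)))
            if chemo:
                tq["DRUG"].append("$".join((
                    pid, caseid, "2", "SS", "OXALIPLATIN", "OXALIPLATIN", "INTRAVENOUS")))
            elif other_combo:
                tq["DRUG"].append("$".join((
                    pid, caseid, "2", "SS", "KEYTRUDA", "PEMBROLIZUMAB", "INTRAVENOUS")))
            for pt in tee_pts + noise:
                tq["REAC"].append("$".join((pid, caseid, pt)))
            if fatal:
                tq["OUTC"].append("$".join((pid, caseid, "DE")))
            else:
                tq["OUTC"].append("$".join((pid, caseid, "HO" if outc_u[i] < 0.4 else "OT")))
            tq["THER"].append("$".join((pid, caseid, "1", start_tok, "")))
            if indication:
                tq["INDI"].append("$".join((pid, caseid, "1", indication)))

        cases.append(
            CaseTruth(
                caseid=caseid,
                surviving_primaryid=surviving,
                version_primaryids=[v[0] for v in versions],
                drug=profile.ingredient,
                route=route,
                reporter=rep_labels[rep_idx[i]],
                exposed=exposed,
                fatal=bool(fatal),
                onset_days_true=onset,
                tee_pts=tee_pts,
            )
        )

    headers = {
        "DEMO": DEMO_COLUMNS, "DRUG": DRUG_COLUMNS, "REAC": REAC_COLUMNS,
        "OUTC": OUTC_COLUMNS, "THER": THER_COLUMNS, "INDI": INDI_COLUMNS,
    }
    for quarter in config.quarters:
        qdir = out_dir / quarter
        qdir.mkdir(parents=True, exist_ok=True)
        suffix = quarter[2:4] + quarter[4:]  # 2023Q1 -> 23Q1
        for table, lines in tables[quarter].items():
            path = qdir / f"{table}{suffix}.txt"
            with open(path, "w", newline="\n") as fh:
                fh.write("$".join(headers[table]) + "\n")
                for line in lines:
                    fh.write(line + "\n")

    config_echo = {
        "seed": config.seed, "n_reports": config.n_reports,
        "quarters": list(config.quarters),
        "duplicate_rate": config.duplicate_rate,
        "partial_date_rate": config.partial_date_rate,
        "fatality_base": config.fatality_base,
        "fatality_tee_odds_multiplier": config.fatality_tee_odds_multiplier,
        "planted_signals": [dataclasses.asdict(s) for s in config.planted_signals],
        "drug_prevalences": {d.ingredient: d.prevalence for d in config.drug_catalog},
    }
    truth = GroundTruth(
        config_echo=config_echo,
        cases=cases,
        signals=theoretical_signal_truth(config),
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = truth.to_json()
    if not write_case_truth:
        payload["cases"] = []
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    with open(out_dir / "config_used.json", "w") as fh:
        json.dump(config_echo, fh, indent=1, sort_keys=True)
    return truth


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def verify_against_truth(
    truth: GroundTruth,
    deduplicated_reports: Sequence | None = None,
    cohort_case_counts: Mapping[str, int] | None = None,
    signal_estimates: Mapping[tuple[str, str], object] | None = None,
) -> dict[str, dict]:
    """Check pipeline outputs against the generator's bookkeeping.

    Returns a mapping check-name → {passed, detail}.  Checks are only run
    for the outputs supplied:

    * ``dedup``: the deduplicated report set has exactly one survivor per
      true case, and each survivor is the true latest version;
    * ``cohort``: per-drug eligible case counts match the truth exactly
      (intravenous route, health-professional reporter, study drug PS);
    * ``signals``: each estimated ROR's 95% CI covers the theoretical
      population ROR implied by the planted multiplier.
    """
    report: dict[str, dict] = {}
    if deduplicated_reports is not None:
        got = {r.caseid: r.primaryid for r in deduplicated_reports}
        want = {c.caseid: c.surviving_primaryid for c in truth.cases}
        wrong = {k for k in want if got.get(k) != want[k]}
        report["dedup"] = {
            "passed": len(got) == len(want) and not wrong,
            "detail": f"{len(got)} survivors vs {len(want)} true cases, "
                      f"{len(wrong)} wrong versions",
        }
    if cohort_case_counts is not None:
        hp = {"physician", "pharmacist", "other_health_professional"}
        truth_counts: dict[str, int] = {}
        for c in truth.cases:
            if c.route.upper().startswith("INTRAVENOUS") and c.reporter in hp:
                truth_counts[c.drug] = truth_counts.get(c.drug, 0) + 1
        mismatches = {
            d: (cohort_case_counts.get(d), truth_counts.get(d, 0))
            for d in cohort_case_counts
            if cohort_case_counts.get(d) != truth_counts.get(d, 0)
        }
        report["cohort"] = {
            "passed": not mismatches,
            "detail": f"mismatches: {mismatches}" if mismatches else "all drug counts exact",
        }
    if signal_estimates is not None:
        failures = []
        for (drug, target), est in signal_estimates.items():
            matching = [s for s in truth.signals if s.drug == drug and s.target == target]
            if not matching or est.ror_ci is None:
                failures.append((drug, target, "no truth or no CI"))
                continue
            lo, hi = est.ror_ci
            if not (lo <= matching[0].theoretical_ror <= hi):
                failures.append((drug, target, f"CI ({lo:.3f},{hi:.3f}) misses "
                                               f"{matching[0].theoretical_ror:.3f}"))
        report["signals"] = {
            "passed": not failures,
            "detail": failures or "all CIs cover the theoretical ROR",
        }
    return report
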