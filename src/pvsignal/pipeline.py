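"""End-to-end orchestration: ingest → dedup → cohorts → analyses → tables.

The run configuration (a YAML file or equivalent dict) names either an
input archive directory or a ``simulate`` block, the event-dictionary
source, the drug cohorts, and toggles for the analysis stages.  Every
output table is TSV with a leading ``#`` metadata block, and a manifest
records input hashes, the config echo, the tool version and the seed so a
rerun with identical inputs reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__, cohort, faers_io, onset_analysis, outcome_model, signal_stats
from .event_dictionary import CATEGORIES, OVERALL, example_dictionary, load_dictionary
from .synthetic_faers import PlantedSignal, SimulationConfig, generate

logger = logging.getLogger(__name__)

DEFAULT_ANALYSES = ("signals", "pt_scan", "head_to_head", "onset", "outcomes")
EVENT_LABELS = ("PE", "MI", "cerebral_ATE") + CATEGORIES + (OVERALL,)
_SIGNAL_COLUMNS = ("drug", "event", "n", "expected", "ror", "ror_lower", "ror_upper",
                   "ic", "ic_lower", "ic_upper", "evaluated", "signal")


class ConfigError(ValueError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _fmt_value(v: Any) -> str:
    if v is None or v == "":
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return format(v, ".6g")
    return str(v)


def write_table(df: pd.DataFrame, path: Path, meta: Mapping[str, Any]) -> None:
    """TSV with a ``#``-prefixed metadata block and deterministic formatting."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt_value(v) for v in row) + "\n")


def load_run_config(source: str | Path | Mapping) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            config = yaml.safe_load(fh)
    else:
        config = dict(source)
    if not isinstance(config, Mapping):
        raise ConfigError("run config must be a mapping")
    config = dict(config)
    has_input = bool(config.get("input_dir"))
    has_sim = bool(config.get("simulate"))
    if has_input == has_sim:
        raise ConfigError("config must name exactly one of input_dir or simulate")
    config.setdefault("seed", 0)
    config.setdefault("cohorts", ["BEVACIZUMAB", "RAMUCIRUMAB", "AFLIBERCEPT"])
    config.setdefault("analyses", list(DEFAULT_ANALYSES))
    config.setdefault("dictionary", "builtin")
    # comparison universe provenance: "cohort" mirrors the cohorts' reporter
    # filter (the default), "all" keeps every deduplicated report
    config.setdefault("universe_reporters", "cohort")
    return config


def _simulation_config(block: Mapping, seed: int) -> SimulationConfig:
    kwargs = dict(block)
    kwargs.setdefault("seed", seed)
    signals = [
        PlantedSignal(**s) if isinstance(s, Mapping) else s
        for s in kwargs.pop("planted_signals", ())
    ]
    return SimulationConfig(planted_signals=tuple(signals), **kwargs)


def _cohort_specs(config: Mapping) -> list[cohort.CohortSpec]:
    specs = []
    window = tuple(config["window"]) if config.get("window") else None
    for entry in config["cohorts"]:
        if isinstance(entry, str):
            specs.append(cohort.CohortSpec(drug_of_interest=entry, window=window))
        else:
            entry = dict(entry)
            entry.setdefault("window", window)
            if "route_filter" in entry and entry["route_filter"] != "any":
                entry["route_filter"] = frozenset(entry["route_filter"])
            if "reporter_filter" in entry:
                entry["reporter_filter"] = frozenset(entry["reporter_filter"])
            if "synonyms" in entry:
                entry["synonyms"] = tuple(entry["synonyms"])
            specs.append(cohort.CohortSpec(**entry))
    return specs


def _signal_row(drug: str, event: str, est: signal_stats.SignalEstimate) -> dict:
    return {
        "drug": drug, "event": event, "n": est.n_obs,
        "expected": est.expected,
        "ror": est.ror,
        "ror_lower": None if est.ror_ci is None else est.ror_ci[0],
        "ror_upper": None if est.ror_ci is None else est.ror_ci[1],
        "ic": est.ic, "ic_lower": est.ic_ci[0], "ic_upper": est.ic_ci[1],
        "evaluated": est.evaluated, "signal": est.signal,
    }


def run(config: str | Path | Mapping, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages and write every output table.

    Returns a small in-memory summary (paths written, headline counts).
    Raises on hard errors; partial outputs are over-written on rerun.
    """
    config = load_run_config(config)
    if seed is not None:
        config["seed"] = seed
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analyses = set(config["analyses"])
    run_seed = int(config["seed"])

    # ---- ingest ----------------------------------------------------------
    if config.get("simulate"):
        sim_dir = out_dir / "archive"
        sim_config = _simulation_config(config["simulate"], run_seed)
        truth = generate(sim_config, sim_dir, write_case_truth=False)
        input_dir = sim_dir
    else:
        truth = None
        input_dir = Path(config["input_dir"])

    record_sets, parse_rejects = faers_io.read_archive(input_dir)
    reports, join_rejects = faers_io.assemble_reports(record_sets)
    deduped, dedup_flags = faers_io.deduplicate(reports)
    rejects = parse_rejects + join_rejects + dedup_flags
    faers_io.write_rejects_log(rejects, out_dir / "rejects.tsv")

    dictionary = (
        example_dictionary()
        if config["dictionary"] == "builtin"
        else load_dictionary(config["dictionary"])
    )
    specs = _cohort_specs(config)

    meta_base = {
        "tool": f"pvsignal {__version__}",
        "seed": run_seed,
        "reports_raw": len(reports),
        "reports_deduplicated": len(deduped),
    }
    written: list[Path] = []

    # ---- cohorts ---------------------------------------------------------
    all_rows: list[cohort.CohortRow] = []
    tee_rows: list[cohort.CohortRow] = []
    for spec in specs:
        rows = cohort.select_cohort(deduped, spec, dictionary)
        all_rows.extend(rows)
        tee_rows.extend(r for r in rows if OVERALL in r.labels)
    summary = cohort.descriptive_summary(tee_rows)
    path = out_dir / "cohort_summary.tsv"
    write_table(summary, path, {**meta_base, "table": "descriptive summary of TEE cohort rows"})
    written.append(path)

    if config["universe_reporters"] == "cohort":
        accepted = frozenset().union(*(s.reporter_filter for s in specs))
        universe_reports = [r for r in deduped if r.reporter_qualification in accepted]
    else:
        universe_reports = list(deduped)
    universe = cohort.label_universe(universe_reports, specs, dictionary)
    results: dict = {"n_reports": len(reports), "n_cases": len(deduped),
                     "n_cohort_rows": len(all_rows), "n_tee_rows": len(tee_rows),
                     "truth": truth}

    # ---- signals ---------------------------------------------------------
    if "signals" in analyses:
        rows = []
        for spec in specs:
            for event in EVENT_LABELS:
                try:
                    table = signal_stats.build_contingency(universe, spec.drug_of_interest, event)
                except ValueError:
                    continue
                rows.append(_signal_row(spec.drug_of_interest, event,
                                        signal_stats.evaluate_signal(table)))
        frame = pd.DataFrame(rows, columns=_SIGNAL_COLUMNS)
        path = out_dir / "signals.tsv"
        write_table(frame, path, {**meta_base, "table": "drug x event disproportionality vs full database"})
        written.append(path)
        results["signals"] = frame

    if "pt_scan" in analyses:
        rows = []
        for spec in specs:
            scan = signal_stats.pt_level_scan(universe, spec.drug_of_interest)
            for pt, est in scan.evaluated:
                rows.append({**_signal_row(spec.drug_of_interest, pt, est)})
        frame = pd.DataFrame(rows, columns=_SIGNAL_COLUMNS)
        path = out_dir / "pt_scan.tsv"
        write_table(frame, path, {**meta_base, "table": "per-PT scan, sorted by IC interval lower bound"})
        written.append(path)
        results["pt_scan"] = frame

    if "head_to_head" in analyses and len(specs) > 1:
        study_drugs = [s.drug_of_interest for s in specs]
        clean = [r for r in universe if len(r.drug_labels & set(study_drugs)) <= 1]
        dropped = len(universe) - len(clean)
        if dropped:
            logger.info("head-to-head: excluded %d reports suspect for multiple study drugs", dropped)
        rows = []
        for drug_a, drug_b in combinations(study_drugs, 2):
            ca = [r for r in clean if drug_a in r.drug_labels]
            cb = [r for r in clean if drug_b in r.drug_labels]
            if not ca or not cb:
                continue
            for event in (OVERALL,) + CATEGORIES:
                est = signal_stats.head_to_head(ca, cb, event)
                rows.append({**_signal_row(f"{drug_a} vs {drug_b}", event, est)})
        frame = pd.DataFrame(rows, columns=_SIGNAL_COLUMNS)
        path = out_dir / "head_to_head.tsv"
        write_table(frame, path, {**meta_base, "table": "direct drug-vs-drug comparisons"})
        written.append(path)
        results["head_to_head"] = frame

    # ---- onset -----------------------------------------------------------
    if "onset" in analyses:
        samples = [
            onset_analysis.OnsetSample(drug, [r.onset_days for r in tee_rows
                                              if r.drug == drug and r.onset_days is not None])
            for drug in sorted({r.drug for r in tee_rows})
        ]
        samples = [s for s in samples if s.days]
        test_rows = []
        if len(samples) >= 2:
            kw = onset_analysis.kruskal_wallis([s.days for s in samples],
                                               [s.group_label for s in samples])
            test_rows.append({"comparison": "onset by drug", "test": "kruskal_wallis",
                              "statistic": kw.statistic, "p_value": kw.p_value,
                              "n": ",".join(map(str, kw.n_per_group))})
        fatal = [r.onset_days for r in tee_rows if r.fatal and r.onset_days is not None]
        nonfatal = [r.onset_days for r in tee_rows if not r.fatal and r.onset_days is not None]
        if fatal and nonfatal:
            mw = onset_analysis.mann_whitney(fatal, nonfatal)
            test_rows.append({"comparison": "fatal vs non-fatal", "test": "mann_whitney",
                              "statistic": mw.statistic, "p_value": mw.p_value,
                              "n": ",".join(map(str, mw.n_per_group))})
        frame = pd.DataFrame(test_rows, columns=["comparison", "test", "statistic", "p_value", "n"])
        path = out_dir / "onset_tests.tsv"
        write_table(frame, path, {**meta_base, "table": "nonparametric onset comparisons"})
        written.append(path)
        results["onset_tests"] = frame
        if samples:
            ci = onset_analysis.cumulative_incidence(samples)
            path = out_dir / "cumulative_incidence.tsv"
            write_table(ci, path, {**meta_base, "table": "empirical cumulative incidence of onset"})
            written.append(path)

    # ---- outcomes --------------------------------------------------------
    if "outcomes" in analyses and all_rows:
        subgroups = sorted({r.indication_group for r in all_rows}
                           - {"unknown", "other"})
        forest = outcome_model.mortality_association(all_rows, subgroups=subgroups)
        path = out_dir / "mortality_forest.tsv"
        write_table(forest, path, {**meta_base, "table": "fatal-outcome association, TEE vs non-TEE"})
        written.append(path)
        results["mortality"] = forest

    # ---- manifest --------------------------------------------------------
    input_files = sorted(p for p in Path(input_dir).rglob("*.txt") if p.is_file())
    manifest = {
        "tool_version": __version__,
        "seed": run_seed,
        "config": {k: v for k, v in config.items() if k != "simulate"}
                  | ({"simulate": dict(config["simulate"])} if config.get("simulate") else {}),
        "inputs": {str(p.relative_to(input_dir)): _sha256(p) for p in input_files},
        "outputs": [p.name for p in written],
        "rejects": len(rejects),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    results["written"] = written + [out_dir / "manifest.json", out_dir / "rejects.tsv"]
    return results
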