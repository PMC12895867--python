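"""Multivariable logistic model of fatal outcome among drug-suspect reports.

The question is whether reports carrying a thromboembolic event (TEE) are
more often fatal than reports without one, among all reports where a study
drug is the primary suspect.  The model is

    logit P(fatal) = β0 + β_TEE·[TEE] + β_sex + β_age + β_drug

with declared reference levels (non-TEE, male, age 18–64, bevacizumab) and
unknown sex/age retained as explicit levels — dropping them would shrink
the cohort materially, since a quarter of reports lack age.  Effects are
reported as adjusted odds ratios, exp(β), with Wald 95% intervals
exp(β ± 1.96·se) and two-sided Wald p-values.

Estimation is maximum likelihood via iteratively reweighted least squares
(statsmodels GLM with a binomial family); standard errors come from the
inverse observed information.  Perfect separation is detected and reported
instead of returning runaway coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .signal_stats import Z975

logger = logging.getLogger(__name__)

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("M", "F", "unknown"),
    "age_group": ("18to64", "lt18", "ge65", "unknown"),
    "drug": ("BEVACIZUMAB", "RAMUCIRUMAB", "AFLIBERCEPT"),
}
#: first entry of each tuple above is the reference level
REFERENCE_LEVELS = {k: v[0] for k, v in CATEGORICAL_LEVELS.items()}


@dataclass
class ModelFrame:
    """Analysis rows plus the categorical levels actually retained."""

    data: pd.DataFrame  # columns: outcome, exposure, sex, age_group, drug, indication_group
    levels: dict[str, tuple[str, ...]]
    dropped_levels: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data)


@dataclass
class RegressionFit:
    coefficients: dict[str, tuple[float, float]]  # term -> (beta, se)
    aor: dict[str, tuple[float, float, float]]  # term -> (point, lower, upper)
    p_values: dict[str, float]
    converged: bool
    n_used: int
    log_likelihood: float
    diagnostics: str = ""


def build_model_frame(
    rows: Sequence,  # CohortRow-like: fatal, labels, sex, age_group, drug, indication_group
    covariates: Sequence[str] = ("sex", "age_group", "drug"),
) -> ModelFrame:
    """Build the regression frame from labelled cohort rows.

    ``exposure`` is membership in overall TEE; ``outcome`` the fatal flag.
    Levels declared but unobserved are dropped with a log entry.  A frame
    with no exposed or no unexposed rows cannot identify the exposure
    effect and is a hard error.
    """
    data = pd.DataFrame(
        {
            "outcome": [bool(r.fatal) for r in rows],
            "exposure": [("overall_TEE" in r.labels) for r in rows],
            "sex": [r.sex for r in rows],
            "age_group": [r.age_group for r in rows],
            "drug": [r.drug for r in rows],
            "indication_group": [getattr(r, "indication_group", "unknown") for r in rows],
        }
    )
    if len(data) == 0:
        raise ValueError("model frame is empty")
    n_exposed = int(data["exposure"].sum())
    if n_exposed == 0 or n_exposed == len(data):
        raise ValueError(
            f"frame has {n_exposed} exposed of {len(data)} rows; "
            "both exposure groups are required"
        )
    levels: dict[str, tuple[str, ...]] = {}
    dropped: list[tuple[str, str]] = []
    for cov in covariates:
        declared = CATEGORICAL_LEVELS[cov]
        present = set(data[cov])
        stray = present - set(declared)
        if stray:
            raise ValueError(f"{cov} values {sorted(stray)} not among declared levels")
        kept = tuple(lvl for lvl in declared if lvl in present)
        for lvl in declared:
            if lvl not in present:
                dropped.append((cov, lvl))
                logger.info("dropping empty level %s=%s", cov, lvl)
        levels[cov] = kept
    return ModelFrame(data=data, levels=levels, dropped_levels=dropped)


def _design_matrix(frame: ModelFrame) -> tuple[pd.DataFrame, list[str]]:
    cols: dict[str, np.ndarray] = {"intercept": np.ones(frame.n)}
    cols["exposure"] = frame.data["exposure"].to_numpy(dtype=float)
    for cov, kept in frame.levels.items():
        for lvl in kept[1:]:  # first retained level is the reference
            cols[f"{cov}[{lvl}]"] = (frame.data[cov] == lvl).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=frame.data.index)
    return X, list(cols)


def fit_logistic(frame: ModelFrame, max_iter: int = 100) -> RegressionFit:
    """Maximum-likelihood logistic fit with Wald intervals.

    Separation (a fitted probability within 1e-8 of 0 or 1 together with a
    runaway coefficient) yields ``converged=False`` with a diagnostic and
    no odds ratios, rather than meaningless huge intervals.
    """
    X, terms = _design_matrix(frame)
    y = frame.data["outcome"].to_numpy(dtype=float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=1e-10)
    mu = res.fittedvalues.to_numpy()
    beta = res.params
    separated = bool(
        ((mu < 1e-8) | (mu > 1 - 1e-8)).any() and np.abs(beta).max() > 15
    )
    converged = bool(res.converged) and not separated
    coefficients = {t: (float(beta[t]), float(res.bse[t])) for t in terms}
    if not converged:
        return RegressionFit(
            coefficients=coefficients,
            aor={},
            p_values={},
            converged=False,
            n_used=frame.n,
            log_likelihood=float(res.llf),
            diagnostics="separation detected" if separated else "did not converge",
        )
    aor = {}
    pvals = {}
    for t in terms:
        b, se = coefficients[t]
        aor[t] = (float(np.exp(b)), float(np.exp(b - Z975 * se)), float(np.exp(b + Z975 * se)))
        pvals[t] = float(res.pvalues[t])
    return RegressionFit(
        coefficients=coefficients,
        aor=aor,
        p_values=pvals,
        converged=True,
        n_used=frame.n,
        log_likelihood=float(res.llf),
    )


def _crude_pcts(data: pd.DataFrame) -> tuple[float | None, float | None]:
    def pct(mask: pd.Series) -> float | None:
        n = int(mask.sum())
        if n == 0:
            return None
        return 100.0 * float(data.loc[mask, "outcome"].mean())

    return pct(data["exposure"]), pct(~data["exposure"])


def mortality_association(
    rows: Sequence,
    subgroups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Forest-plot-ready association table.

    One row per stratum: overall (adjusted for sex, age and drug), per drug
    (sex and age), and per indication subgroup within each drug (sex and
    age, drug fixed by the restriction).  Strata where the fit is not
    estimable — no outcome variation in an exposure arm, or separation —
    are emitted with an ``estimable`` flag instead of being dropped.
    """
    out: list[dict] = []

    def one_stratum(name: str, sub_rows: Sequence, covariates: Sequence[str]) -> None:
        record: dict = {"stratum": name, "n": len(sub_rows), "estimable": False,
                        "pct_fatal_exposed": None, "pct_fatal_unexposed": None,
                        "aor": None, "ci_lower": None, "ci_upper": None, "p": None}
        try:
            frame = build_model_frame(sub_rows, covariates=covariates)
        except ValueError as exc:
            record["note"] = str(exc)
            out.append(record)
            return
        exp_pct, unexp_pct = _crude_pcts(frame.data)
        record["pct_fatal_exposed"] = exp_pct
        record["pct_fatal_unexposed"] = unexp_pct
        by_arm = frame.data.groupby("exposure")["outcome"].nunique()
        if (by_arm < 2).any():
            record["note"] = "no outcome variation in an exposure arm"
            out.append(record)
            return
        fit = fit_logistic(frame)
        if not fit.converged or "exposure" not in fit.aor:
            record["note"] = fit.diagnostics or "fit failed"
            out.append(record)
            return
        point, lo, hi = fit.aor["exposure"]
        record.update(
            estimable=True, aor=point, ci_lower=lo, ci_upper=hi,
            p=fit.p_values["exposure"], note="",
        )
        out.append(record)

    rows = list(rows)
    one_stratum("overall", rows, ("sex", "age_group", "drug"))
    for drug in sorted({r.drug for r in rows}):
        drug_rows = [r for r in rows if r.drug == drug]
        one_stratum(drug.lower(), drug_rows, ("sex", "age_group"))
        if subgroups:
            for grp in subgroups:
                sub = [r for r in drug_rows if getattr(r, "indication_group", None) == grp]
                if sub:
                    one_stratum(f"{drug.lower()}:{grp}", sub, ("sex", "age_group"))
    return pd.DataFrame(
        out,
        columns=["stratum", "n", "pct_fatal_exposed", "pct_fatal_unexposed",
                 "aor", "ci_lower", "ci_upper", "p", "estimable", "note"],
    )
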