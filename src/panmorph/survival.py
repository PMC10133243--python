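"""Prognostic modelling: Cox proportional hazards, VIF screening,
lower-quartile dichotomisation and Kaplan–Meier curves.

The multivariate model uses the colocalisation score on the 0–100 scale
(so hazard ratios are per one point of coloc100, i.e. per 0.01 of the raw
Morisita–Horn index), age in years and the lymphocyte percentage.
Covariates are screened for collinearity by variance inflation factor;
only covariates with VIF < 5 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter

VIF_THRESHOLD = 5.0
DEFAULT_COVARIATES = ("coloc100", "age", "lymphocyte_pct")


def dichotomize_lower_quartile(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Split subjects at the first quartile of the colocalisation score.

    Returns an array of ``"low"``/``"high"`` labels (low = value <= Q1,
    the lower quartile; high = upper three quartiles) and the cutoff.
    Quartiles use the linear-interpolation convention.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 subjects to form quartile groups")
    if np.ptp(values) == 0:
        raise ValueError("all values equal; no valid quartile split")
    q1 = float(np.quantile(values, 0.25))
    labels = np.where(values <= q1, "low", "high")
    if len(set(labels)) < 2:
        raise ValueError("degenerate split: one group is empty")
    return labels, q1


@dataclass
class CoxFit:
    """Per-covariate estimates plus model-level summaries."""

    table: pd.DataFrame  # index covariate; columns coef, hr, hr_lower, hr_upper, se, p
    log_likelihood: float
    n: int
    n_events: int
    model: CoxPHFitter

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def coef(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "coef"])


def fit_cox(
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Multivariate Cox PH fit (Efron tie handling, Wald CIs).

    ``records`` is a survival DataFrame (see
    :func:`panmorph.datamodel.survival_frame`) or any frame with duration,
    event and covariate columns.
    """
    covariates = list(covariates)
    df = records[[duration_col, event_col, *covariates]].copy()
    if df[covariates].isna().any().any() or not np.isfinite(df[covariates].to_numpy()).all():
        raise ValueError("covariates must be finite and non-missing")
    n_events = int(df[event_col].sum())
    if n_events < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "hr": summ["exp(coef)"],
            "hr_lower": summ["exp(coef) lower 95%"],
            "hr_upper": summ["exp(coef) upper 95%"],
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    return CoxFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=n_events,
        model=cph,
    )


@dataclass
class VifReport:
    table: pd.DataFrame  # index covariate; columns vif, retained

    @property
    def retained(self) -> list[str]:
        return list(self.table.index[self.table["retained"]])


def vif(records: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES) -> VifReport:
    """Variance inflation factors; covariates with VIF >= 5 are dropped.

    VIF_j = 1/(1 - R²_j) from an OLS regression of covariate j on the
    other covariates (with intercept).  Exact collinearity yields an
    infinite VIF and the covariate is flagged as dropped.
    """
    covariates = list(covariates)
    if len(records) < len(covariates) + 2:
        raise ValueError("need at least (number of covariates + 2) subjects")
    X = records[covariates].astype(float)
    rows = {}
    for j, name in enumerate(covariates):
        others = [c for c in covariates if c != name]
        if not others:
            rows[name] = 1.0
            continue
        design = sm.add_constant(X[others])
        r2 = sm.OLS(X[name], design).fit().rsquared
        rows[name] = float(np.inf) if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    table = pd.DataFrame(
        {"vif": rows, "retained": {k: v < VIF_THRESHOLD for k, v in rows.items()}}
    )
    return VifReport(table=table)


def apply_cause_specific_censoring(
    records: pd.DataFrame,
    cause_col: str = "tumour_related",
    event_col: str = "event",
) -> pd.DataFrame:
    """Treat deaths unrelated to the tumour as censoring events.

    ``cause_col`` is 1 when the death was tumour-related, 0 otherwise;
    subjects with an event but an unrelated cause get ``event`` set to 0.
    Returns a copy; the original frame is untouched.
    """
    out = records.copy()
    unrelated = (out[event_col] == 1) & (out[cause_col] == 0)
    out.loc[unrelated, event_col] = 0
    return out


@dataclass
class KmCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n: int
    n_events: int


def km(
    records: pd.DataFrame,
    groups: Sequence,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict[str, KmCurve]:
    """Product-limit survival curves per group."""
    if isinstance(groups, pd.Categorical):
        levels = list(groups.categories)
        groups = np.asarray(groups)
    else:
        groups = np.asarray(groups)
        levels = list(pd.unique(groups))
    out: dict[str, KmCurve] = {}
    for g in levels:
        sel = records[groups == g]
        if len(sel) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sel[duration_col], sel[event_col], label=str(g))
        times = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].reindex(times).to_numpy(dtype=float)
        out[str(g)] = KmCurve(
            group=str(g),
            times=times,
            survival=surv,
            n_at_risk=at_risk,
            n=len(sel),
            n_events=int(sel[event_col].sum()),
        )
    return out


def adjusted_km(
    fit: CoxFit,
    records: pd.DataFrame,
    group_col: str,
    adjust: str = "mean",
) -> dict[str, pd.Series]:
    """Covariate-adjusted survival curves from a fitted Cox model.

    For each level of ``group_col`` (which must be a covariate in the
    fit, e.g. a 0/1 dichotomised score), the model's survival function is
    evaluated at that level with the remaining covariates held either at
    their cohort mean (``adjust="mean"``) or at zero
    (``adjust="reference"``).
    """
    if adjust not in ("mean", "reference"):
        raise ValueError("adjust must be 'mean' or 'reference'")
    covs = list(fit.table.index)
    out: dict[str, pd.Series] = {}
    for level in sorted(pd.unique(records[group_col])):
        row = {}
        for c in covs:
            if c == group_col:
                row[c] = level
            else:
                row[c] = float(records[c].mean()) if adjust == "mean" else 0.0
        sf = fit.model.predict_survival_function(pd.DataFrame([row]))
        out[str(level)] = sf.iloc[:, 0]
    return out
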