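"""Triplet survival signatures: Cox coefficients, risk scores and log-rank tests.

Each detected triplet is turned into a composite risk score

    risk_i = alpha * lnc_i + beta * mir_i + gamma * mrna_i

with (alpha, beta, gamma) the Cox proportional-hazards coefficients of the
three members' log2 expression. By default the three coefficients come from
one joint three-covariate fit (standard for composite signatures); the
``univariate`` mode reuses the three single-covariate fits instead. Samples
are split at the mean risk score into high- and low-risk groups and compared
with a two-group log-rank test. A triplet whose risk grouping separates
survival (log-rank p < alpha) while no single member is individually
associated (all univariate Cox p >= alpha) is classified as
"functions_together".

Model fitting, the log-rank test and the Kaplan-Meier estimator are
delegated to ``lifelines``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .exceptions import DataError, FitError
from .layers import ExpressionLayer

SIGNATURE_ALPHA = 0.05

CATEGORY_NOT_SIGNIFICANT = "not_significant"
CATEGORY_TRIPLET_SIGNIFICANT = "triplet_significant"
CATEGORY_FUNCTIONS_TOGETHER = "functions_together"

PROGNOSIS_COLUMNS = [
    "lnc_id", "mir_id", "mrna_id", "alpha", "beta", "gamma",
    "p_lnc", "p_mir", "p_mrna", "logrank_p", "category",
]


@dataclass
class CoxElementResult:
    coefficient: float
    p: float
    classification: Literal["risk", "protective"]


@dataclass
class RiskModel:
    """Composite risk signature for one triplet."""

    lnc_id: str
    mir_id: str
    mrna_id: str
    alpha: float
    beta: float
    gamma: float
    risk_score: pd.Series
    group: pd.Series  # "high" / "low" per sample
    logrank_p: float
    element_cox_p: tuple[float, float, float]
    category: str = CATEGORY_NOT_SIGNIFICANT


def _check_survival(survival: pd.DataFrame) -> None:
    if not {"time", "event"}.issubset(survival.columns):
        raise DataError("survival table must have 'time' and 'event' columns")
    if (survival["time"] <= 0).any():
        raise DataError("survival times must be positive")


def element_cox(expr: pd.Series, survival: pd.DataFrame) -> CoxElementResult:
    """Univariate Cox fit of survival on one expression covariate.

    Positive coefficients classify the element as a risk factor (higher
    expression, shorter survival), negative ones as protective.
    """
    _check_survival(survival)
    common = survival.index.intersection(expr.index)
    if survival.loc[common, "event"].sum() < 2:
        raise DataError("need at least 2 events for a Cox fit")
    x = expr[common].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DataError(f"expression of {expr.name!r} is constant")
    df = pd.DataFrame(
        {"x": x, "time": survival.loc[common, "time"], "event": survival.loc[common, "event"]}
    )
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitError(f"univariate Cox fit failed to converge: {exc}") from exc
    coef = float(fitter.params_["x"])
    p = float(fitter.summary.loc["x", "p"])
    return CoxElementResult(coef, p, "risk" if coef > 0 else "protective")


def joint_cox(expr: pd.DataFrame, survival: pd.DataFrame) -> CoxPHFitter:
    """Joint Cox proportional-hazards fit on several expression covariates."""
    _check_survival(survival)
    common = survival.index.intersection(expr.index)
    df = expr.loc[common].copy()
    df["time"] = survival.loc[common, "time"]
    df["event"] = survival.loc[common, "event"]
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitError(f"joint Cox fit failed to converge: {exc}") from exc
    return fitter


def triplet_risk_score(
    coeffs: Sequence[float],
    lnc: pd.Series,
    mir: pd.Series,
    mrna: pd.Series,
) -> pd.Series:
    """Per-sample linear risk score alpha*lnc + beta*mir + gamma*mrna."""
    alpha, beta, gamma = (float(c) for c in coeffs)
    if not all(np.isfinite([alpha, beta, gamma])):
        raise DataError("risk coefficients must be finite")
    for s in (mir, mrna):
        if not lnc.index.equals(s.index):
            missing = lnc.index.difference(s.index).tolist()
            if missing:
                raise DataError(f"expression missing for samples: {missing[:10]}")
            s = s[lnc.index]
    score = alpha * lnc + beta * mir[lnc.index] + gamma * mrna[lnc.index]
    score.name = "risk_score"
    return score


def split_by_mean(scores: pd.Series) -> pd.Series:
    """Label samples 'high' (score > mean) or 'low' (score <= mean)."""
    vals = scores.to_numpy(dtype=float)
    if np.ptp(vals) == 0:
        raise DataError("all risk scores identical; mean split is degenerate")
    labels = np.where(vals > vals.mean(), "high", "low")
    return pd.Series(labels, index=scores.index, name="group")


def logrank(groups: pd.Series, survival: pd.DataFrame) -> float:
    """Two-group log-rank chi-square p-value."""
    _check_survival(survival)
    common = survival.index.intersection(groups.index)
    g = groups[common]
    names = sorted(g.unique())
    if len(names) != 2:
        raise DataError(f"log-rank needs exactly 2 groups, got {names}")
    a, b = (common[g == name] for name in names)
    if survival.loc[common, "event"].sum() < 1:
        raise DataError("log-rank needs at least one event")
    res = logrank_test(
        survival.loc[a, "time"], survival.loc[b, "time"],
        event_observed_A=survival.loc[a, "event"],
        event_observed_B=survival.loc[b, "event"],
    )
    return float(res.p_value)


def classify_signature(model: RiskModel, alpha: float = SIGNATURE_ALPHA) -> str:
    """Categorise the signature from its log-rank and element-wise p-values."""
    if not np.isfinite(model.logrank_p) or model.logrank_p >= alpha:
        return CATEGORY_NOT_SIGNIFICANT
    if all(p >= alpha for p in model.element_cox_p):
        return CATEGORY_FUNCTIONS_TOGETHER
    return CATEGORY_TRIPLET_SIGNIFICANT


def evaluate_triplet(
    lnc_id: str,
    mir_id: str,
    mrna_id: str,
    lnc_layer: ExpressionLayer,
    mir_layer: ExpressionLayer,
    mrna_layer: ExpressionLayer,
    survival: pd.DataFrame,
    cox_mode: Literal["joint", "univariate"] = "joint",
    alpha: float = SIGNATURE_ALPHA,
) -> RiskModel:
    """Fit the risk signature for one triplet and classify it."""
    lnc = lnc_layer.gene(lnc_id)
    mir = mir_layer.gene(mir_id)
    mrna = mrna_layer.gene(mrna_id)
    elements = [element_cox(s.rename(name), survival)
                for s, name in ((lnc, "lnc"), (mir, "mir"), (mrna, "mrna"))]
    if cox_mode == "joint":
        expr = pd.DataFrame({"lnc": lnc, "mir": mir, "mrna": mrna})
        fit = joint_cox(expr, survival)
        coeffs = tuple(float(fit.params_[c]) for c in ("lnc", "mir", "mrna"))
    elif cox_mode == "univariate":
        coeffs = tuple(e.coefficient for e in elements)
    else:
        raise DataError(f"cox_mode must be 'joint' or 'univariate', got {cox_mode!r}")
    score = triplet_risk_score(coeffs, lnc, mir, mrna)
    group = split_by_mean(score)
    p = logrank(group, survival)
    model = RiskModel(
        lnc_id=lnc_id, mir_id=mir_id, mrna_id=mrna_id,
        alpha=coeffs[0], beta=coeffs[1], gamma=coeffs[2],
        risk_score=score, group=group, logrank_p=p,
        element_cox_p=tuple(e.p for e in elements),
    )
    model.category = classify_signature(model, alpha)
    return model


def km_table(groups: pd.Series, survival: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier step-function table per group (long format)."""
    _check_survival(survival)
    frames = []
    for name, idx in groups.groupby(groups).groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(survival.loc[idx, "time"], survival.loc[idx, "event"], label=str(name))
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", str(name))
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


def single_gene_signature(
    expr: pd.Series, survival: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Mean-split a single gene's expression and log-rank the two groups.

    Returns the log-rank p-value and the per-group Kaplan-Meier table.
    """
    group = split_by_mean(expr)
    p = logrank(group, survival)
    return p, km_table(group, survival)


def models_to_frame(models: Sequence[RiskModel]) -> pd.DataFrame:
    """Tabulate risk models for TSV export."""
    rows = []
    for m in models:
        rows.append([
            m.lnc_id, m.mir_id, m.mrna_id, m.alpha, m.beta, m.gamma,
            m.element_cox_p[0], m.element_cox_p[1], m.element_cox_p[2],
            m.logrank_p, m.category,
        ])
    return pd.DataFrame(rows, columns=PROGNOSIS_COLUMNS)
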