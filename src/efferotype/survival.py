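"""Censored-survival evaluation: KM/log-rank, Cox models, nomogram,
time-dependent AUC, calibration, and the clinical association helpers.

Cox models are fit by partial likelihood with the Efron tie correction
(lifelines). The nomogram is an exact points-based reparameterization of
the multivariate Cox linear predictor: per-variable points are affine in
beta_i * x_i scaled so the widest-range variable spans 0-100, and total
points map to survival probabilities through the baseline cumulative
hazard, so nomogram predictions coincide with direct Cox predictions.
Time-dependent discrimination uses the Uno-type IPCW cumulative/dynamic
AUC (scikit-survival), which reduces to the plain ROC AUC when censoring
is absent.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .datatypes import ClinicalTable

log = logging.getLogger(__name__)


@dataclass
class SurvivalFit:
    mode: str  # 'univariate' | 'multivariate'
    variables: list[str]
    summary: pd.DataFrame  # coef, hr, ci lower/upper, p per term
    fitter: CoxPHFitter = field(repr=False, default=None)
    train_means: pd.Series = field(repr=False, default=None)
    train_design: pd.DataFrame = field(repr=False, default=None)

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.loc[term]
        return float(row["hr_lower"]), float(row["hr_upper"])


def km_logrank(clinical: ClinicalTable, group_labels):
    """Kaplan-Meier curves per group plus the two-sided log-rank test.

    Returns ``(curves, statistic, p_value)`` where curves maps each group to
    its product-limit survival function (a Series indexed by time).
    """
    labels = pd.Series(group_labels)
    df = clinical.table
    labels = labels.loc[df.index]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    curves = {}
    for g in groups:
        sub = df.loc[labels == g]
        if sub["os_event"].sum() == 0:
            warnings.warn(f"group {g!r} has no events; KM curve is flat")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"], label=str(g))
        curves[g] = kmf.survival_function_.iloc[:, 0]
    res = multivariate_logrank_test(df["os_time"], labels, df["os_event"])
    return curves, float(res.test_statistic), float(res.p_value)


def design_matrix(clinical: ClinicalTable, variables) -> pd.DataFrame:
    df = clinical.table.copy()
    design = pd.DataFrame(index=df.index)
    for var in variables:
        col = df[var]
        if col.dtype == object or str(col.dtype) == "category":
            # dummy coding against the lexicographically first level
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                design[f"{var}[{lev}]"] = (col.astype(str) == lev).astype(float)
        else:
            design[var] = col.astype(float)
    const = [c for c in design.columns if design[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates cannot enter a Cox model: {const}")
    return design


def cox_fit(clinical: ClinicalTable, variables, mode: str = "multivariate"):
    """Cox proportional-hazards fit(s) with Efron tie handling.

    ``mode='multivariate'`` fits one joint model and returns a SurvivalFit;
    ``mode='univariate'`` loops the variables independently and returns a
    dict of SurvivalFits. Categorical variables are dummy-coded against the
    lexicographically first level.
    """
    if mode == "univariate":
        return {v: _cox_single(clinical, [v], "univariate") for v in variables}
    if mode != "multivariate":
        raise ValueError(f"mode must be 'univariate' or 'multivariate', got {mode!r}")
    return _cox_single(clinical, list(variables), mode)


def _cox_single(clinical: ClinicalTable, variables, mode) -> SurvivalFit:
    design = design_matrix(clinical, variables)
    df = design.copy()
    df["os_time"] = clinical.table["os_time"].astype(float)
    df["os_event"] = clinical.table["os_event"].astype(int)
    n_events = int(df["os_event"].sum())
    if n_events < 5 * design.shape[1]:
        warnings.warn(f"only {n_events} events for {design.shape[1]} parameters; "
                      "estimates may be unstable")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="os_time", event_col="os_event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge for {variables}: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": s["exp(coef)"],
        "hr_lower": s["exp(coef) lower 95%"],
        "hr_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return SurvivalFit(mode=mode, variables=list(variables), summary=summary,
                       fitter=cph, train_means=design.mean(), train_design=design)


@dataclass
class NomogramModel:
    fit: SurvivalFit
    point_scales: dict  # var -> (beta, low_value, points_per_unit_range)
    scale: float  # points per unit of linear predictor
    horizons: list[float]
    baseline_cumhaz: pd.Series = field(repr=False, default=None)  # at train means

    def linear_predictor(self, covariates: pd.DataFrame) -> pd.Series:
        design = covariates[self.fit.summary.index.tolist()].astype(float)
        beta = self.fit.summary["coef"]
        return (design - self.fit.train_means).mul(beta).sum(axis=1)

    def points(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Per-variable and total points (widest-range variable spans 0-100)."""
        beta = self.fit.summary["coef"]
        out = pd.DataFrame(index=covariates.index)
        for var, (b, low, _) in self.point_scales.items():
            out[var] = (covariates[var].astype(float) * b - low) * self.scale
        out["total"] = out.sum(axis=1)
        return out

    def _cumhaz_at(self, t: float) -> float:
        ch = self.baseline_cumhaz
        if t > ch.index.max():
            raise ValueError(f"horizon {t} beyond observed follow-up {ch.index.max():.1f}")
        idx = ch.index.searchsorted(t, side="right") - 1
        return float(ch.iloc[idx]) if idx >= 0 else 0.0

    def predict_survival(self, covariates: pd.DataFrame, horizon: float) -> pd.Series:
        lp = self.linear_predictor(covariates)
        h0 = self._cumhaz_at(horizon)
        return np.exp(-h0 * np.exp(lp))


def build_nomogram(fit: SurvivalFit, horizons=(365.0, 1095.0, 1825.0)) -> NomogramModel:
    """Points-based reparameterization of a multivariate Cox fit.

    Each variable's points are beta_i * (x_i - x_i at minimal observed
    risk contribution), scaled so the widest-ranging contribution spans
    100 points; the total-points to survival map goes through the baseline
    cumulative hazard, making nomogram predictions identical to direct Cox
    predictions.
    """
    if fit.fitter is None or fit.train_design is None or len(fit.summary) < 2:
        raise ValueError("nomogram needs a fitted multivariate model with >= 2 terms")
    beta = fit.summary["coef"]
    point_scales: dict[str, tuple[float, float, float]] = {}
    ranges = {}
    for var in fit.summary.index:
        contrib = fit.train_design[var].astype(float) * beta[var]
        low, high = float(contrib.min()), float(contrib.max())
        point_scales[var] = (float(beta[var]), low, high - low)
        ranges[var] = high - low
    widest = max(ranges.values())
    if widest <= 0:
        raise ValueError("all covariate contributions are constant; nomogram undefined")
    scale = 100.0 / widest  # points per unit linear predictor

    cumhaz = fit.fitter.baseline_cumulative_hazard_.iloc[:, 0]
    max_follow = float(fit.fitter.durations.max())
    for t in horizons:
        if t > max_follow:
            raise ValueError(f"horizon {t} beyond observed follow-up {max_follow:.1f}")
    return NomogramModel(fit=fit, point_scales=point_scales, scale=scale,
                         horizons=list(horizons), baseline_cumhaz=cumhaz)


def time_dependent_auc(risk_scores, clinical: ClinicalTable, horizon_t: float) -> float:
    """IPCW cumulative/dynamic AUC at one horizon (Uno-type estimator).

    Cases are samples with an observed event by ``horizon_t``, controls are
    samples still at risk; inverse-probability-of-censoring weights come
    from the KM estimate of the censoring distribution. With no censoring
    this coincides with the plain ROC AUC of event-by-t against the score.
    """
    scores = pd.Series(risk_scores)
    df = clinical.table
    scores = scores.loc[df.index].astype(float)
    events_by_t = ((df["os_event"] == 1) & (df["os_time"] <= horizon_t)).sum()
    at_risk = (df["os_time"] > horizon_t).sum()
    if events_by_t == 0 or at_risk == 0:
        raise ValueError(
            f"no comparable pairs at horizon {horizon_t}: "
            f"{events_by_t} events by t, {at_risk} at risk")
    y = Surv.from_arrays(event=df["os_event"].astype(bool).to_numpy(),
                         time=df["os_time"].astype(float).to_numpy())
    auc, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(), [horizon_t])
    return float(auc[0])


def calibration_curve(nomogram: NomogramModel, clinical: ClinicalTable,
                      horizon_t: float, n_bins: int = 4) -> pd.DataFrame:
    """Predicted vs KM-observed survival at one horizon, in quantile bins.

    Returns one row per bin: mean predicted survival, KM-observed survival
    at the horizon with its 95% CI, and the bin size. Degenerate bins
    (tied prediction quantiles) are merged and logged.
    """
    design = design_matrix(clinical, nomogram.fit.variables)
    pred = nomogram.predict_survival(design, horizon_t)
    if len(pred) < n_bins * 20:
        warnings.warn(f"only {len(pred)} samples for {n_bins} calibration bins")
    bins = pd.qcut(pred, q=n_bins, labels=False, duplicates="drop")
    if bins.nunique() < n_bins:
        log.info("calibration: %d degenerate bins merged", n_bins - bins.nunique())
    rows = []
    for b in sorted(bins.unique()):
        members = pred.index[bins == b]
        sub = clinical.table.loc[members]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"])
        observed = float(kmf.survival_function_at_times(horizon_t).iloc[0])
        ci_df = kmf.confidence_interval_survival_function_
        idx = ci_df.index.searchsorted(horizon_t, side="right") - 1
        lo, hi = (float(ci_df.iloc[idx, 0]), float(ci_df.iloc[idx, 1])) if idx >= 0 else (0.0, 1.0)
        rows.append({"bin": int(b), "n": len(members),
                     "predicted": float(pred[members].mean()),
                     "observed": observed, "observed_lower": lo, "observed_upper": hi})
    return pd.DataFrame(rows)


def point_biserial(binary_labels, continuous_scores) -> tuple[float, float]:
    """Point-biserial correlation (Pearson with 0/1 coding) and t-based p."""
    y = np.asarray(binary_labels, dtype=float)
    x = np.asarray(continuous_scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both label values must be present")
    if np.ptp(x) == 0:
        raise ValueError("scores are constant; correlation undefined")
    r, p = stats.pointbiserialr(y, x)
    return float(r), float(p)


def classify_icb_response(tide_scores) -> pd.Series:
    """Threshold TIDE scores at zero: positive scores mark predicted
    immune-checkpoint-blockade non-responders, negative scores responders.
    A score of exactly 0 is classed non-responder with a warning; missing
    scores are excluded and listed in the log."""
    s = pd.Series(tide_scores, dtype=float)
    missing = s.index[s.isna()].tolist()
    if missing:
        log.warning("classify_icb_response: excluding samples without scores: %s", missing)
        s = s.dropna()
    zeros = int((s == 0).sum())
    if zeros:
        warnings.warn(f"{zeros} TIDE scores exactly 0; classed as non-responder")
    return pd.Series(np.where(s > 0, "non-responder",
                              np.where(s < 0, "responder", "non-responder")),
                     index=s.index, name="icb_response")


def compare_response_proportions(response_labels, group_labels) -> tuple[float, float]:
    """Chi-square test comparing responder proportions across groups."""
    tab = pd.crosstab(pd.Series(response_labels), pd.Series(group_labels))
    chi2, p, _, _ = stats.chi2_contingency(tab)
    return float(chi2), float(p)
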