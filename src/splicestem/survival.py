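"""Survival analysis: median splits, Cox models, KM/log-rank, C-index, IPCW ROC.

Cox models are fitted by partial likelihood with the Efron tie correction
(via lifelines); hazard ratios carry Wald 95% confidence intervals. The
concordance index is Harrell's C over usable pairs (the shorter time must be
an observed event; risk ties count 1/2). Time-dependent AUC at horizon ``t``
is the cumulative/dynamic estimator with inverse-probability-of-censoring
weights from the Kaplan-Meier estimate of the censoring distribution: cases
are subjects with an event at or before ``t``, controls those still at risk
after ``t``; with no censoring it reduces to the plain binary AUC of the
indicator (time <= t) against the risk score.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

from .differential import bh_adjust

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DEFAULT_HORIZONS_YEARS = (3.0, 4.5, 5.0)


@dataclass
class SurvivalResult:
    """Univariate Cox summary for one covariate."""

    covariate_id: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    flagged: bool = False  # monotone likelihood / separation suspicion
    logrank_p: float | None = None

    def to_row(self) -> dict:
        return dict(self.__dict__)


@dataclass
class MultivariateModel:
    """Joint Cox fit with its linear predictor and discrimination metrics."""

    covariate_ids: list[str]
    coefficients: pd.Series
    hazard_ratios: pd.DataFrame
    global_p: float
    linear_predictor: pd.Series
    c_index: float | None = None
    time_auc: dict[float, float] = field(default_factory=dict)


def _check_surv(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if (time <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(event, [0.0, 1.0]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """Split samples at the median: value > median -> 'high', <= -> 'low'.

    Missing values are excluded before the median and receive no label.
    """
    v = values.dropna().astype(float)
    if len(v) < 2:
        raise ValueError("need >= 2 non-missing values to dichotomize")
    if v.nunique() == 1:
        raise ValueError("degenerate split: all values identical")
    med = float(v.median())
    labels = pd.Series(np.where(v > med, "high", "low"), index=v.index, name="group")
    logger.debug("median split at %.4g: %d high / %d low", med,
                 (labels == "high").sum(), (labels == "low").sum())
    return labels


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> tuple[CoxPHFitter, bool]:
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df[["os_time", "os_event", *covariates]],
                duration_col="os_time", event_col="os_event",
                fit_options={"precision": 1e-9})
        flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return cph, flagged


def cox_univariate(clinical: pd.DataFrame, covariate: pd.Series,
                   covariate_id: str | None = None) -> SurvivalResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI)."""
    name = covariate_id or str(covariate.name or "covariate")
    df = pd.DataFrame({"os_time": clinical["os_time"], "os_event": clinical["os_event"],
                       "x": covariate}).dropna()
    time, event = _check_surv(df["os_time"], df["os_event"])
    if event.sum() < 2:
        raise ValueError("need >= 2 observed events")
    if df["x"].nunique() <= 1:
        raise ValueError(f"covariate {name!r} is constant")
    cph, flagged = _fit_cox(df, ["x"])
    s = cph.summary.loc["x"]
    return SurvivalResult(
        covariate_id=name,
        coef=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        n=len(df),
        n_events=int(event.sum()),
        flagged=flagged or abs(float(s["coef"])) > 50,
    )


def univariate_screen(clinical: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Univariate Cox over many covariates with BH adjustment of the p-values."""
    rows = []
    for col in covariates.columns:
        try:
            rows.append(cox_univariate(clinical, covariates[col], covariate_id=str(col)).to_row())
        except ValueError as exc:
            logger.debug("skipping covariate %s: %s", col, exc)
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out = out.set_index("covariate_id")
    return out


def cox_multivariate(clinical: pd.DataFrame, covariates: pd.DataFrame,
                     horizons_years=DEFAULT_HORIZONS_YEARS) -> MultivariateModel:
    """Joint Cox fit; exposes the linear predictor, Harrell's C and IPCW AUC.

    Preconditions: n_samples > 5 x n_covariates and at least as many events
    as covariates. Exactly collinear covariate pairs raise an error naming
    the pair.
    """
    cols = list(covariates.columns)
    if not cols:
        raise ValueError("need at least one covariate")
    df = pd.concat([clinical[["os_time", "os_event"]], covariates], axis=1).dropna()
    time, event = _check_surv(df["os_time"], df["os_event"])
    if len(df) <= 5 * len(cols):
        raise ValueError(f"{len(df)} samples insufficient for {len(cols)} covariates (need > 5x)")
    if event.sum() < len(cols):
        raise ValueError("fewer events than covariates")
    corr = df[cols].corr().abs()
    for a, b in itertools.combinations(cols, 2):
        if corr.loc[a, b] > 1 - 1e-10:
            raise ValueError(f"collinear covariates: {a!r} and {b!r}")
    cph, _ = _fit_cox(df, cols)
    lp = pd.Series(cph.predict_partial_hazard(df[cols]).to_numpy(float), index=df.index)
    lp = np.log(lp)
    lp.name = "linear_predictor"
    hr = cph.summary[["coef", "exp(coef)", "coef lower 95%", "coef upper 95%", "p"]].copy()
    hr["ci_low"] = np.exp(hr.pop("coef lower 95%"))
    hr["ci_high"] = np.exp(hr.pop("coef upper 95%"))
    model = MultivariateModel(
        covariate_ids=cols,
        coefficients=cph.params_.copy(),
        hazard_ratios=hr,
        global_p=float(cph.log_likelihood_ratio_test().p_value),
        linear_predictor=lp,
    )
    model.c_index = concordance_index(df["os_time"], df["os_event"], lp)
    model.time_auc = time_dependent_auc(
        df["os_time"], df["os_event"], lp,
        horizons=[h * DAYS_PER_YEAR for h in horizons_years],
    )
    model.time_auc = {h: model.time_auc[h * DAYS_PER_YEAR] for h in horizons_years}
    return model


def _prune_correlated(clinical: pd.DataFrame, covariates: pd.DataFrame,
                      max_abs_corr: float = 0.75) -> list[str]:
    """Greedily drop the worse (by univariate p) of any covariate pair whose
    |Pearson correlation| exceeds the cutoff."""
    screen = univariate_screen(clinical, covariates)
    cols = [c for c in covariates.columns if c in screen.index]
    cols.sort(key=lambda c: screen.loc[c, "p"])
    kept: list[str] = []
    corr = covariates[cols].corr().abs()
    for c in cols:
        if all(corr.loc[c, k] <= max_abs_corr for k in kept):
            kept.append(c)
    return kept


def backward_select_aic(clinical: pd.DataFrame, covariates: pd.DataFrame,
                        max_covariates: int | None = None) -> list[str]:
    """Backward elimination by AIC on the Cox partial likelihood.

    Mutually near-collinear covariates (common when events share a latent
    driver) are pruned first; fits that fail to converge count as infinite
    AIC so elimination routes around them.
    """
    from lifelines.exceptions import ConvergenceError as LLConvergenceError

    if covariates.shape[1] == 0:
        raise ValueError("need at least one covariate")
    cols = _prune_correlated(clinical, covariates)
    if max_covariates is not None and len(cols) > max_covariates:
        screen = univariate_screen(clinical, covariates[cols])
        cols = list(screen.loc[cols].sort_values("p").index[:max_covariates])
    df = pd.concat([clinical[["os_time", "os_event"]], covariates[cols]],
                   axis=1).dropna()

    def aic(subset: list[str]) -> float:
        try:
            cph, _ = _fit_cox(df, subset)
        except (LLConvergenceError, np.linalg.LinAlgError):
            return float("inf")
        return float(cph.AIC_partial_)

    current = cols
    best = aic(current)
    while not np.isfinite(best) and len(current) > 1:
        current = current[:-1]  # drop the weakest screened covariate
        best = aic(current)
    improved = True
    while improved and len(current) > 1:
        improved = False
        for drop in list(current):
            cand = [c for c in current if c != drop]
            a = aic(cand)
            if a < best - 1e-9:
                best, current, improved = a, cand, True
                break
    return current


def kaplan_meier_logrank(clinical: pd.DataFrame, groups: pd.Series
                         ) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier curves per group and the two-sided log-rank p-value.

    Returns a step-function table (group, time, survival, n_at_risk) and the
    log-rank chi-square p.
    """
    idx = groups.dropna().index.intersection(clinical.index)
    g = groups[idx]
    if g.nunique() < 2:
        raise ValueError("need >= 2 non-empty groups")
    time, event = _check_surv(clinical.loc[idx, "os_time"], clinical.loc[idx, "os_event"])
    curves = []
    for label in sorted(g.unique()):
        sel = (g == label).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=str(label))
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        curves.append(pd.DataFrame({
            "group": str(label),
            "time": surv.index.to_numpy(float),
            "survival": surv.to_numpy(float),
            "n_at_risk": tab["at_risk"].to_numpy(float),
        }))
    res = multivariate_logrank_test(time, g.to_numpy(), event)
    return pd.concat(curves, ignore_index=True), float(res.p_value)


def concordance_index(time, event, risk) -> float:
    """Harrell's C: fraction of usable pairs where the higher risk score has
    the shorter survival time; risk ties count 1/2.

    A pair is usable when the earlier time belongs to an observed event (and
    the times differ, or the later observation is censored at the tie).
    """
    time, event = _check_surv(time, event)
    risk = np.asarray(risk, dtype=float)
    n = len(time)
    concordant = 0.0
    usable = 0
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[j] > time[i] or (time[j] == time[i] and event[j] == 0):
                usable += 1
                if risk[i] > risk[j]:
                    concordant += 1.0
                elif risk[i] == risk[j]:
                    concordant += 0.5
    if usable == 0:
        raise ValueError("no comparable pairs")
    return concordant / usable


def _censoring_km(time: np.ndarray, event: np.ndarray):
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)  # censoring distribution G(t)
    return kmf


def time_dependent_auc(time, event, risk, horizons) -> dict[float, float]:
    """Cumulative/dynamic AUC(t) with Kaplan-Meier IPCW case weights.

    cases(t) = subjects with an observed event at time <= t, weighted by
    1 / G(T_i-); controls(t) = subjects with time > t, weighted by 1 / G(t).
    Horizons with no cases or no controls yield NaN with a warning.
    """
    time, event = _check_surv(time, event)
    risk = np.asarray(risk, dtype=float)
    ckm = _censoring_km(time, event)
    out: dict[float, float] = {}
    for t in horizons:
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            warnings.warn(f"horizon {t:g}: no cases or no controls; AUC undefined")
            out[float(t)] = float("nan")
            continue
        g_case = ckm.predict(np.maximum(time[cases] - 1e-9, 0.0)).to_numpy(float)
        g_case = np.where(g_case <= 0, np.nan, g_case)
        w = 1.0 / g_case
        w = np.where(np.isfinite(w), w, 0.0)
        rc = risk[cases]
        rk = risk[controls]
        greater = (rc[:, None] > rk[None, :]).astype(float)
        ties = (rc[:, None] == rk[None, :]).astype(float)
        num = float((w[:, None] * (greater + 0.5 * ties)).sum())
        den = float(w.sum() * len(rk))
        out[float(t)] = num / den if den > 0 else float("nan")
    return out


def sase_survival_screen(clinical: pd.DataFrame, psi: pd.DataFrame) -> pd.DataFrame:
    """Median-dichotomized KM log-rank plus continuous univariate Cox per event."""
    rows = []
    for eid in psi.index:
        vals = psi.loc[eid].dropna()
        try:
            res = cox_univariate(clinical, psi.loc[eid], covariate_id=str(eid))
            groups = dichotomize_by_median(vals)
            _, lr_p = kaplan_meier_logrank(clinical.loc[groups.index], groups)
            res.logrank_p = lr_p
            rows.append(res.to_row())
        except ValueError as exc:
            logger.debug("skipping event %s: %s", eid, exc)
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
        out = out.set_index("covariate_id")
    return out
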