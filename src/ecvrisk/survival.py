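"""Survival machinery for building and validating the risk score.

Kaplan–Meier curves, log-rank tests and Cox proportional-hazards fits are
delegated to lifelines (Efron handling of tied event times); the
time-dependent cumulative/dynamic AUC with inverse-probability-of-censoring
weights comes from scikit-survival.  The maximally-selected-rank-statistics
cutpoint search (with a seeded permutation p-value), bootstrap calibration
curves and horizon classification metrics are implemented here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalData",
    "KMCurve",
    "CoxFitResult",
    "TimeROCResult",
    "CutpointResult",
    "HorizonMetrics",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "univariate_screen",
    "time_dependent_auc",
    "maxstat_cutpoint",
    "calibration_curve",
    "horizon_classification_metrics",
]


@dataclass
class SurvivalData:
    """Right-censored survival outcomes with optional named covariates.

    ``time`` is progression-free survival in months (> 0); ``event`` is 1
    for observed progression and 0 for censoring.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise ValueError("times must be finite and positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)
            if len(self.covariates) != self.time.size:
                raise ValueError("covariate rows must match the number of subjects")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time_col: str = "pfs_months",
        event_col: str = "event",
        covariate_cols: Sequence[str] | None = None,
    ) -> "SurvivalData":
        cov = df[list(covariate_cols)] if covariate_cols else None
        return cls(time=df[time_col].to_numpy(), event=df[event_col].to_numpy(), covariates=cov)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, mask: np.ndarray) -> "SurvivalData":
        cov = self.covariates.loc[np.asarray(mask)] if self.covariates is not None else None
        return SurvivalData(self.time[mask], self.event[mask], cov)


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


@dataclass
class KMCurve:
    """Product-limit estimate: survival after each observed event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # np.inf when the curve never reaches 0.5
    _fitter: KaplanMeierFitter = field(repr=False)

    @property
    def median_reached(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, times: Sequence[float] | float) -> np.ndarray | float:
        out = self._fitter.predict(times)
        if np.isscalar(times):
            return float(out)
        return np.asarray(out, dtype=float)


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    With no censoring this equals the empirical survivor function; the median
    is the first time survival drops to 0.5 or below (infinity when never
    reached — reported, not extrapolated).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    med = kmf.median_survival_time_
    return KMCurve(
        event_times=ev.index.to_numpy(dtype=float),
        survival=kmf.survival_function_at_times(ev.index.to_numpy()).to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        median=float(med) if np.isfinite(med) else np.inf,
        _fitter=kmf,
    )


def logrank_test(a: SurvivalData, b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic on 1 df, p-value)."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(a.time, b.time, event_observed_A=a.event, event_observed_B=b.event)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxFitResult:
    """Per-covariate estimates from a Cox proportional-hazards fit."""

    summary: pd.DataFrame  # beta, hr, ci_lower, ci_upper, p
    log_likelihood: float

    @property
    def hazard_ratios(self) -> dict[str, float]:
        return self.summary["hr"].to_dict()

    @property
    def betas(self) -> dict[str, float]:
        return self.summary["beta"].to_dict()


def fit_cox(data: SurvivalData, covariates: Sequence[str] | None = None) -> CoxFitResult:
    """Maximize the Cox partial likelihood (Efron correction for ties)."""
    if data.covariates is None:
        raise ValueError("survival data carries no covariates")
    covariates = list(covariates) if covariates is not None else list(data.covariates.columns)
    if data.n_events < len(covariates) + 1:
        raise ValueError(
            f"{data.n_events} events are too few to fit {len(covariates)} covariates"
        )
    df = data.covariates[covariates].copy()
    df["_time"] = data.time
    df["_event"] = data.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "beta": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxFitResult(summary=summary, log_likelihood=float(cph.log_likelihood_))


def univariate_screen(
    data: SurvivalData, candidates: Sequence[str], alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame, CoxFitResult | None]:
    """Screen candidates one at a time and refit the retained set jointly.

    Fits a one-covariate Cox model per candidate, retains those with
    p < alpha, then fits the multivariable model on the retained set.
    Returns (retained names, per-candidate table, multivariable fit or None).
    """
    rows = []
    retained: list[str] = []
    for name in candidates:
        fit = fit_cox(data, [name])
        row = fit.summary.loc[name]
        rows.append({"candidate": name, **row.to_dict()})
        if row["p"] < alpha:
            retained.append(name)
    table = pd.DataFrame(rows).set_index("candidate")
    multi = fit_cox(data, retained) if retained else None
    return retained, table, multi


# ---------------------------------------------------------------------------
# Time-dependent ROC


@dataclass
class TimeROCResult:
    horizon: float
    auc: float
    weighting: str = "ipcw-cumulative/dynamic"


def time_dependent_auc(
    marker: Sequence[float], data: SurvivalData, horizon: float
) -> TimeROCResult:
    """Cumulative-cases / dynamic-controls AUC at a horizon, IPCW-weighted.

    Cases are subjects with an observed event by the horizon, controls those
    still event-free beyond it; censoring is handled by inverse probability
    of censoring weights from the censoring Kaplan–Meier.  Higher marker
    values must indicate higher risk.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    marker = np.asarray(marker, dtype=float)
    if marker.shape != data.time.shape:
        raise ValueError("marker must align with the survival data")
    n_cases = int(((data.time <= horizon) & (data.event == 1)).sum())
    n_controls = int((data.time > horizon).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"horizon {horizon}: need both cases ({n_cases}) and controls ({n_controls})"
        )
    y = Surv.from_arrays(event=data.event.astype(bool), time=data.time)
    auc, _ = cumulative_dynamic_auc(y, y, marker, [horizon])
    return TimeROCResult(horizon=float(horizon), auc=float(auc[0]))


# ---------------------------------------------------------------------------
# Maximally selected rank statistics


def _standardized_logrank_grid(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """|O - E| / sqrt(V) of the log-rank statistic for many group splits at once.

    ``groups`` is an (n, m) boolean matrix; column j defines membership of
    group 1 for split j.  Returns the m standardized statistics.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order].astype(float)
    g = groups[order].astype(float)
    n = t.size
    block_start = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e, block_start)  # events per distinct time
    d1 = np.add.reduceat(e[:, None] * g, block_start, axis=0)
    n_at_risk = (n - block_start).astype(float)
    g_suffix = np.cumsum(g[::-1], axis=0)[::-1]
    n1 = g_suffix[block_start]
    keep = d > 0
    d, n_at_risk = d[keep], n_at_risk[keep]
    d1, n1 = d1[keep], n1[keep]
    frac = n1 / n_at_risk[:, None]
    observed = d1.sum(axis=0)
    expected = (d[:, None] * frac).sum(axis=0)
    hyper = (d * (n_at_risk - d) / np.maximum(n_at_risk - 1.0, 1.0))[:, None]
    variance = (hyper * frac * (1.0 - frac)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(variance > 0, np.abs(observed - expected) / np.sqrt(variance), 0.0)
    return z


@dataclass
class CutpointResult:
    """Outcome-based optimal cutpoint for a score.

    ``cutpoint`` is reported as the smallest observed score value above the
    selected split, so groups are {score >= cutpoint} vs {score < cutpoint}.
    """

    cutpoint: float
    midpoint: float
    statistic: float
    p_value: float | None
    candidates: np.ndarray
    statistics: np.ndarray


def maxstat_cutpoint(
    score: Sequence[float],
    data: SurvivalData,
    quantile_window: tuple[float, float] = (0.10, 0.90),
    n_perm: int = 999,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected rank statistics cutpoint with a permutation p-value.

    Candidate cuts are the midpoints between consecutive distinct score
    values whose left-group proportion falls within the quantile window; the
    selected cut maximizes the standardized two-group log-rank statistic.
    The p-value is estimated by permuting score labels (``n_perm`` seeded
    resamples; ``n_perm = 0`` skips inference).
    """
    score = np.asarray(score, dtype=float)
    if score.shape != data.time.shape:
        raise ValueError("score must align with the survival data")
    values = np.unique(score)
    if values.size < 2:
        raise ValueError("score is constant: no cutpoint exists")
    mids = (values[:-1] + values[1:]) / 2.0
    prop_left = np.searchsorted(np.sort(score), mids, side="right") / score.size
    lo, hi = quantile_window
    in_window = (prop_left >= lo) & (prop_left <= hi)
    if not in_window.any():
        raise ValueError("no candidate cut inside the quantile window")
    mids = mids[in_window]
    groups = score[:, None] > mids[None, :]
    stats_obs = _standardized_logrank_grid(data.time, data.event, groups)
    best = int(np.argmax(stats_obs))
    best_mid = float(mids[best])
    cutpoint = float(values[values > best_mid].min())
    max_obs = float(stats_obs[best])

    p_value: float | None = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(score)
            g = perm[:, None] > mids[None, :]
            if _standardized_logrank_grid(data.time, data.event, g).max() >= max_obs:
                exceed += 1
        p_value = (1 + exceed) / (n_perm + 1)

    return CutpointResult(
        cutpoint=cutpoint,
        midpoint=best_mid,
        statistic=max_obs,
        p_value=p_value,
        candidates=mids,
        statistics=stats_obs,
    )


# ---------------------------------------------------------------------------
# Calibration


def calibration_curve(
    predicted: Sequence[float],
    data: SurvivalData,
    horizon: float,
    n_boot: int = 1000,
    n_bins: int = 4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Predicted vs KM-observed survival at a horizon, with bootstrap CIs.

    Patients are binned by quantiles of predicted survival; within each bin
    the observed value is the Kaplan–Meier estimate at the horizon and the
    CI is the 2.5/97.5 percentile over ``n_boot`` patient resamples
    (``n_boot = 0`` gives point estimates only).  Deterministic given seed.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != data.time.shape:
        raise ValueError("predictions must align with the survival data")
    if ((predicted < 0) | (predicted > 1)).any():
        raise ValueError("predicted survival probabilities must lie in [0, 1]")
    edges = np.unique(np.quantile(predicted, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 2:  # all predictions identical -> single bin
        bins = np.zeros(predicted.size, dtype=int)
        n_eff = 1
    else:
        if edges.size - 1 < n_bins:
            warnings.warn("empty calibration bins collapsed", stacklevel=2)
        bins = np.clip(np.digitize(predicted, edges[1:-1], right=True), 0, edges.size - 2)
        n_eff = edges.size - 1

    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_eff):
        mask = bins == b
        sub = data.subset(mask)
        observed = float(km_estimate(sub).survival_at(horizon))
        ci_low = ci_high = np.nan
        if n_boot > 0:
            boots = np.empty(n_boot)
            for i in range(n_boot):
                idx = rng.integers(0, sub.n, size=sub.n)
                boots[i] = float(km_estimate(sub.subset(idx)).survival_at(horizon))
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "bin": b,
                "n": int(mask.sum()),
                "mean_predicted": float(predicted[mask].mean()),
                "observed": observed,
                "ci_lower": float(ci_low),
                "ci_upper": float(ci_high),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Horizon classification metrics


@dataclass
class HorizonMetrics:
    """Confusion-matrix metrics for predicting progression-free status at a horizon.

    'Positive' means progression-free at the horizon.  Each metric is a
    (percent, ci_lower, ci_upper) triple on the percent scale, or None when
    its denominator is empty.  Subjects censored before the horizon cannot
    be classified and are excluded (counted in ``n_excluded``).
    """

    horizon: float
    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int
    n_excluded: int
    metrics: Mapping[str, tuple[float, float, float] | None]


def _proportion_with_ci(k: int, n: int) -> tuple[float, float, float] | None:
    from statsmodels.stats.proportion import proportion_confint

    if n == 0:
        return None
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")  # Clopper–Pearson
    return (100.0 * k / n, 100.0 * float(lo), 100.0 * float(hi))


def horizon_classification_metrics(
    predicted: Sequence[float],
    threshold: float,
    data: SurvivalData,
    horizon: float,
) -> HorizonMetrics:
    """Accuracy / sensitivity / specificity / PPV / NPV at a horizon.

    Predicted-positive: predicted survival >= threshold.  Observed-positive:
    progression-free at the horizon (followed beyond it).  95 % CIs are
    exact Clopper–Pearson.
    """
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != data.time.shape:
        raise ValueError("predictions must align with the survival data")
    classifiable = (data.time > horizon) | (data.event == 1)
    n_excluded = int((~classifiable).sum())
    pred_pos = predicted[classifiable] >= threshold
    obs_pos = data.time[classifiable] > horizon
    tp = int((pred_pos & obs_pos).sum())
    fn = int((~pred_pos & obs_pos).sum())
    fp = int((pred_pos & ~obs_pos).sum())
    tn = int((~pred_pos & ~obs_pos).sum())
    metrics = {
        "accuracy": _proportion_with_ci(tp + tn, tp + tn + fp + fn),
        "sensitivity": _proportion_with_ci(tp, tp + fn),
        "specificity": _proportion_with_ci(tn, tn + fp),
        "ppv": _proportion_with_ci(tp, tp + fp),
        "npv": _proportion_with_ci(tn, tn + fn),
    }
    return HorizonMetrics(
        horizon=float(horizon),
        threshold=float(threshold),
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        n_excluded=n_excluded,
        metrics=metrics,
    )
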