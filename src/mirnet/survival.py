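"""Median-split survival screening: KM curves, log-rank tests, Cox fits.

The biomarker screen dichotomizes each miRNA's normalized expression at the
cohort median ("high" strictly above the median, ties go low), then
contrasts the two strata with a univariate Cox proportional-hazards model
(hazard ratio with Wald 95% CI) and a two-group log-rank test, alongside
Kaplan-Meier curves per stratum. The reference level is the low-expression
group, so a hazard ratio below 1 means high expression is protective.

Tied event times use the Efron approximation to the partial likelihood.
The median-split labels are invariant under any strictly increasing
transform of expression, so the choice of variance-stabilizing transform
upstream cannot change the screen.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleAnnotation, ValidationError, ValueKind

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "CoxFit",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_score_test",
    "survival_screen",
    "records_from_annotations",
]

ENDPOINTS = ("pfs", "os")


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up: time in days, event=True if observed."""

    sample_id: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(
                f"sample {self.sample_id}: survival time must be positive"
            )


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI)."""

    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_logrank: float = float("nan")
    converged: bool = True
    n: int = 0
    n_events: int = 0


def median_split(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Boolean labels: True where the value is strictly above the median.

    For even n the median is the midpoint of the two central order
    statistics; values tied with the median go to the low group. All-equal
    input leaves nothing to split and is an error.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 4:
        raise ValidationError("median_split requires >= 4 values")
    if not np.all(np.isfinite(v)):
        raise ValidationError("median_split requires finite values")
    if np.all(v == v[0]):
        raise ValidationError("all values identical; median split undefined")
    return v > float(np.median(v))


def _as_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At each distinct event time t: S <- S * (1 - d_t / n_t) with n_t the
    number still at risk (time >= t); subjects censored at t remain in the
    risk set at t and leave afterwards.
    """
    if not records:
        raise ValidationError("km_estimate requires >= 1 record")
    times, events = _as_arrays(records)
    event_times = np.unique(times[events])
    survival = np.empty(event_times.size, dtype=float)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_t = int(np.sum(times >= t))
        d_t = int(np.sum((times == t) & events))
        s *= 1.0 - d_t / n_t
        survival[i] = s
        at_risk[i] = n_t
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df.

    At each distinct event time the observed events in group A are compared
    with their expectation under a common hazard, with the hypergeometric
    variance; the chi-square is (sum O - sum E)^2 / sum V.
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    ta, ea = _as_arrays(group_a)
    tb, eb = _as_arrays(group_b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    if not events.any():
        raise ValidationError("log-rank test requires at least one event")
    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (times == t) & events
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        expected = d * n_a / n
        o_minus_e += d_a - expected
        if n > 1:
            var += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    if var <= 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def _efron_quantities(
    beta: float,
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
) -> tuple[float, float, float]:
    """(log-likelihood, score, information) of the Efron partial likelihood."""
    order = np.argsort(-times, kind="mergesort")  # decreasing time
    t_sorted = times[order]
    e_sorted = events[order]
    x_sorted = x[order]
    w = np.exp(beta * x_sorted)
    # suffix-free: cumulative sums over the risk set {time >= t} as we walk
    # down from the largest time
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x_sorted)
    cwxx = np.cumsum(w * x_sorted * x_sorted)
    loglik = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = times.size
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        # block [i, j) shares this time; risk set = everything up to j-1
        dying = e_sorted[i:j]
        if dying.any():
            d_idx = np.flatnonzero(dying) + i
            d = d_idx.size
            s0 = cw[j - 1]
            s1 = cwx[j - 1]
            s2 = cwxx[j - 1]
            wd = w[d_idx]
            xd = x_sorted[d_idx]
            s0d = wd.sum()
            s1d = (wd * xd).sum()
            s2d = (wd * xd * xd).sum()
            frac = np.arange(d) / d
            phi = s0 - frac * s0d
            a1 = s1 - frac * s1d
            a2 = s2 - frac * s2d
            loglik += beta * xd.sum() - np.sum(np.log(phi))
            score += xd.sum() - np.sum(a1 / phi)
            info += np.sum(a2 / phi - (a1 / phi) ** 2)
        i = j
    return loglik, score, info


def cox_univariate(
    records: Sequence[SurvivalRecord],
    covariate: Sequence[float] | np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> CoxFit:
    """Univariate Cox PH fit by Newton-Raphson on the Efron partial likelihood.

    Convergence is declared when |score| < ``score_tol``. The standard error
    comes from the inverse observed information; the 95% CI is
    exp(log_hr -/+ 1.96 * se) and the p-value is the two-sided Wald test.
    A monotone likelihood (e.g. complete separation of risk sets) is
    returned as a flagged non-converged fit rather than raised.
    """
    x = np.asarray(covariate, dtype=float)
    if x.shape != (len(records),):
        raise ValidationError("covariate length must match records")
    times, events = _as_arrays(records)
    if not events.any():
        raise ValidationError("Cox fit requires at least one event")
    if np.all(x == x[0]):
        raise ValidationError("covariate is constant; effect not identifiable")
    levels = np.unique(x)
    if levels.size == 2:
        for lv in levels:
            if not events[x == lv].any():
                log.warning("cox_univariate: covariate level %g has no events", lv)
    beta = 0.0
    converged = False
    info = np.nan
    for _ in range(max_iter):
        _, score, info = _efron_quantities(beta, times, events, x)
        if info <= 0 or not np.isfinite(score):
            break
        if abs(score) < score_tol:
            converged = True
            break
        step = score / info
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(beta) > 50:  # monotone likelihood: estimate diverges
            break
    if converged and info > 0:
        se = float(1.0 / np.sqrt(info))
        # a score that flattens out at an absurd effect size is a monotone
        # likelihood in disguise: flag it rather than report exp(20)-scale
        # hazard ratios with astronomical intervals
        if abs(beta) > 15.0 or se > 100.0:
            converged = False
            se = float("inf")
    else:
        se = float("inf")
        converged = False
    hr = float(np.exp(beta))
    delta = 1.959963984540054 * se
    p_wald = float(2.0 * stats.norm.sf(abs(beta) / se)) if np.isfinite(se) else float("nan")
    return CoxFit(
        log_hr=float(beta),
        se=se,
        hr=hr,
        ci_low=float(np.exp(beta - delta)),
        ci_high=float(np.exp(beta + delta)),
        p_wald=p_wald,
        converged=converged,
        n=len(records),
        n_events=int(events.sum()),
    )


def cox_score_test(
    records: Sequence[SurvivalRecord], covariate: Sequence[float] | np.ndarray
) -> float:
    """Cox score test statistic U(0)^2 / I(0); equals log-rank without ties."""
    x = np.asarray(covariate, dtype=float)
    times, events = _as_arrays(records)
    _, score, info = _efron_quantities(0.0, times, events, x)
    if info <= 0:
        return 0.0
    return float(score * score / info)


def records_from_annotations(
    annotations: Sequence[SampleAnnotation], endpoint: str
) -> list[SurvivalRecord]:
    """Extract (time, event) records for one endpoint; skips missing times."""
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    time_field = f"{endpoint}_time"
    event_field = f"{endpoint}_event"
    records = []
    for a in annotations:
        t = getattr(a, time_field)
        if t is None:
            continue
        records.append(
            SurvivalRecord(sample_id=a.sample_id, time=t, event=bool(getattr(a, event_field)))
        )
    return records


def survival_screen(
    expr: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    mirna_list: Sequence[str],
    endpoint: str = "os",
) -> tuple[pd.DataFrame, dict[str, dict[str, KMCurve]]]:
    """Median-split screen of each miRNA against one survival endpoint.

    For every miRNA: split the cohort at the median of its normalized
    expression, fit a univariate Cox model of high vs low (low = reference)
    and a log-rank test, and estimate KM curves per stratum. Samples
    without the endpoint are dropped (logged). Returns the forest table and
    a per-miRNA dict of the 'high' / 'low' KM curves.
    """
    if expr.value_kind is not ValueKind.LOG2_NORM:
        log.warning(
            "survival_screen: expression is %s, not LOG2_NORM; the rank-based "
            "median split is still valid",
            expr.value_kind.value,
        )
    absent = [m for m in mirna_list if m not in expr.feature_ids]
    if absent:
        raise ValidationError(f"miRNAs absent from expression matrix: {absent}")
    by_sample = {a.sample_id: a for a in annotations}
    missing = [s for s in expr.sample_ids if s not in by_sample]
    if missing:
        raise ValidationError(f"samples without annotation: {missing}")
    records_all = records_from_annotations(
        [by_sample[s] for s in expr.sample_ids], endpoint
    )
    if len(records_all) < len(expr.sample_ids):
        log.info(
            "survival_screen: %d samples missing %s endpoint dropped",
            len(expr.sample_ids) - len(records_all),
            endpoint,
        )
    kept = [r.sample_id for r in records_all]
    if len(kept) < 4:
        raise ValidationError(f"only {len(kept)} samples with {endpoint} data")
    sub = expr.subset_samples(kept)
    rows = []
    curves: dict[str, dict[str, KMCurve]] = {}
    for m in mirna_list:
        high = median_split(sub.row(m))
        fit = cox_univariate(records_all, high.astype(float))
        rec_high = [r for r, h in zip(records_all, high) if h]
        rec_low = [r for r, h in zip(records_all, high) if not h]
        try:
            chi2, p_lr = logrank_test(rec_high, rec_low)
        except ValidationError:
            chi2, p_lr = float("nan"), float("nan")
        fit.p_logrank = p_lr
        curves[m] = {"high": km_estimate(rec_high), "low": km_estimate(rec_low)}
        rows.append(
            (
                m,
                endpoint,
                fit.hr,
                fit.ci_low,
                fit.ci_high,
                fit.p_wald,
                p_lr,
                int(high.sum()),
                int((~high).sum()),
                fit.converged,
            )
        )
    forest = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "endpoint",
            "hr",
            "ci_low",
            "ci_high",
            "p_wald",
            "p_logrank",
            "n_high",
            "n_low",
            "converged",
        ],
    )
    return forest, curves
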