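"""Survival statistics from first principles.

Median-split classification, the two-group log-rank test, Kaplan-Meier
product-limit curves/medians, and univariate Cox proportional hazards with
Efron (default) or Breslow tie handling.  These are deliberately
self-contained implementations; external survival libraries are used only
as independent oracles in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2, norm

from .errors import DegenerateSplitError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "median_split",
    "LogrankResult",
    "logrank",
    "km_curve",
    "km_median",
    "CoxResult",
    "cox_univariate",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Follow-up of one sample: time in months and event indicator."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self):
        if self.time <= 0:
            raise ValidationError(f"{self.sample_id}: survival time must be > 0")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: event must be 0 or 1")


def _align(labels: Mapping[str, str], surv: Sequence[SurvivalRecord]):
    """Times, events and 0/1 group indicator for samples present in both."""
    recs = [r for r in surv if r.sample_id in labels]
    if not recs:
        raise ValidationError("no survival records match the labels")
    levels = sorted({labels[r.sample_id] for r in recs})
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 group levels, got {levels}")
    if levels == ["high", "low"]:
        levels = ["low", "high"]  # covariate 1 = "high" so HR reads high vs low
    time = np.array([r.time for r in recs])
    event = np.array([r.event for r in recs])
    group = np.array([levels.index(labels[r.sample_id]) for r in recs])
    return time, event, group, levels


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------

def median_split(values: Mapping[str, float]) -> dict[str, str]:
    """Label samples ``high`` when strictly above the median, else ``low``.

    Ties at the median go to ``low`` (the "larger than median" rule).
    """
    if len(values) < 4:
        raise ValidationError("median split requires at least 4 samples")
    vals = np.array(list(values.values()), dtype=float)
    if np.ptp(vals) == 0:
        raise DegenerateSplitError("all values identical; median split undefined")
    med = float(np.median(vals))
    return {k: ("high" if v > med else "low") for k, v in values.items()}


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    observed_minus_expected: float  # for the second (sorted-last) group level
    zero_events: bool = False


def logrank(labels: Mapping[str, str], surv: Sequence[SurvivalRecord]) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time, accumulates observed-minus-expected events
    in group 1 with hypergeometric variance; the statistic is chi-square
    with 1 df.  Zero total events returns p = 1 with a flag.
    """
    time, event, group, _ = _align(labels, surv)
    if not (group == 0).any() or not (group == 1).any():
        raise ValidationError("both groups must be non-empty")

    if event.sum() == 0:
        return LogrankResult(0.0, 1.0, 0.0, zero_events=True)

    event_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)

    if variance <= 0:
        return LogrankResult(0.0, 1.0, float(o_minus_e), zero_events=False)
    stat = o_minus_e**2 / variance
    p = float(chi2.sf(stat, df=1))
    return LogrankResult(float(stat), p, float(o_minus_e))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate: step times and survival values S(t).

    Returns the curve evaluated at the distinct event times (right
    continuous; S(0) = 1 is implicit).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    event_times = np.unique(times[events == 1])
    s = 1.0
    surv = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        surv[i] = s
    return event_times, surv


def km_median(
    labels: Mapping[str, str], surv: Sequence[SurvivalRecord]
) -> dict[str, float | None]:
    """Kaplan-Meier median per group: earliest t with S(t) <= 0.5.

    ``None`` means the median was not reached (S never drops to 0.5).
    """
    by_group: dict[str, list[SurvivalRecord]] = {}
    for r in surv:
        if r.sample_id in labels:
            by_group.setdefault(labels[r.sample_id], []).append(r)
    out: dict[str, float | None] = {}
    for level, recs in sorted(by_group.items()):
        t = np.array([r.time for r in recs])
        e = np.array([r.event for r in recs])
        step_t, step_s = km_curve(t, e)
        hit = np.nonzero(step_s <= 0.5 + 1e-12)[0]
        out[level] = float(step_t[hit[0]]) if hit.size else None
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate, binary covariate)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_hr: float
    se: float
    divergent: bool = False


def _cox_derivatives(beta: float, time, event, x, ties: str):
    """Log partial likelihood and its first two derivatives.

    Binary covariate; Efron or Breslow handling of tied event times.
    """
    order = np.argsort(-time)  # decreasing time for running risk sums
    time, event, x = time[order], event[order], x[order]
    ex = np.exp(beta * x)

    loglik = dloglik = d2loglik = 0.0
    # running sums over the risk set, built by walking times downward
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(time)
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            s0 += ex[j]
            s1 += x[j] * ex[j]
            s2 += x[j] * x[j] * ex[j]
            j += 1
        # events at this time
        idx = [k for k in range(i, j) if event[k] == 1]
        d = len(idx)
        if d:
            xd = x[idx]
            exd = ex[idx]
            sd0, sd1, sd2 = exd.sum(), (xd * exd).sum(), (xd * xd * exd).sum()
            loglik += beta * xd.sum()
            for r in range(d):
                f = r / d if ties == "efron" else 0.0
                z0 = s0 - f * sd0
                z1 = s1 - f * sd1
                z2 = s2 - f * sd2
                loglik -= math.log(z0)
                dloglik_term = z1 / z0
                dloglik -= dloglik_term
                d2loglik -= z2 / z0 - dloglik_term**2
            dloglik += xd.sum()
        i = j
    return loglik, dloglik, d2loglik


def cox_univariate(
    labels: Mapping[str, str],
    surv: Sequence[SurvivalRecord],
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> CoxResult:
    """Univariate Cox model for a two-level grouping.

    The covariate is 1 for the ``high`` level of a high/low split (and for
    the lexicographically last level otherwise), so the hazard ratio reads
    "high vs low".  Newton-Raphson on the partial likelihood; complete separation is
    reported as divergent with an infinite/zero hazard ratio.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie method {ties!r}")
    time, event, x, levels = _align(labels, surv)
    if event[x == 0].sum() < 1 or event[x == 1].sum() < 1:
        raise ValidationError("both groups need at least one event")

    beta = 0.0
    divergent = False
    for _ in range(max_iter):
        _, score, hess = _cox_derivatives(beta, time, event, x, ties)
        if hess >= -1e-300:
            divergent = True
            break
        step = -score / hess
        step = max(-2.0, min(2.0, step))  # damp early oversized steps
        beta += step
        if abs(beta) > 20:
            divergent = True
            break
        if abs(step) < tol:
            break
    else:
        logger.warning("Cox Newton iteration did not converge; beta=%.3g", beta)

    _, _, hess = _cox_derivatives(beta, time, event, x, ties)
    se = math.sqrt(-1.0 / hess) if hess < 0 else math.inf
    if divergent:
        logger.warning("Cox fit divergent (separation); |beta| unbounded")
        hr = math.inf if beta > 0 else 0.0
        return CoxResult(hr, math.nan, math.nan, math.nan, beta, math.inf, divergent=True)
    z = beta / se if se > 0 else 0.0
    p = float(2 * norm.sf(abs(z)))
    return CoxResult(
        hazard_ratio=math.exp(beta),
        ci_lower=math.exp(beta - 1.959963984540054 * se),
        ci_upper=math.exp(beta + 1.959963984540054 * se),
        p_value=p,
        log_hr=beta,
        se=se,
    )
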