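"""Diagnostic-accuracy statistics with exact confidence intervals.

Point estimates are the conventional ratios — sensitivity tp/(tp+fn),
specificity tn/(fp+tn), PPV tp/(tp+fp), NPV tn/(tn+fn) — reported on the
percentage scale with exact (Clopper-Pearson) binomial intervals by
default.  A metric whose denominator is zero is reported absent, never
zero.  Group comparisons use Pearson's chi-squared (no continuity
correction) and McNemar's test (exact binomial by default); the crude
effect of size on malignancy is a univariable logistic odds ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import ConvergenceError
from .protocol import ThresholdCounts

__all__ = [
    "DiagnosticSummary",
    "RiskEstimate",
    "OddsRatioResult",
    "proportion_ci",
    "diagnostic_summary",
    "crude_risk",
    "pearson_chi2",
    "mcnemar",
    "univariable_logistic_or",
    "perifissural_risk",
    "false_positive_reduction",
    "clopper_pearson_coverage",
]

_CI_METHODS = {"clopper-pearson": "beta", "wilson": "wilson"}


def proportion_ci(
    events: int, n: int, ci_level: float = 0.95, method: str = "clopper-pearson"
) -> tuple[float, float]:
    """Binomial CI for events/n as a (lower, upper) fraction pair."""
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(
        events, n, alpha=1.0 - ci_level, method=_CI_METHODS[method]
    )
    return float(lo), float(hi)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sens/spec/PPV/NPV triples (point, lower, upper) on the percentage
    scale; any metric with an empty denominator is None."""

    sensitivity: tuple[float, float, float] | None
    specificity: tuple[float, float, float] | None
    ppv: tuple[float, float, float] | None
    npv: tuple[float, float, float] | None
    counts: ThresholdCounts
    ci_level: float = 0.95


@dataclass(frozen=True)
class RiskEstimate:
    """Crude risk: events/n as a percentage with binomial CI."""

    events: int
    n: int
    risk_pct: float
    ci: tuple[float, float]
    ci_level: float = 0.95


@dataclass(frozen=True)
class OddsRatioResult:
    """Univariable logistic odds ratio per ``unit_scale`` units of the
    predictor, with Wald CI and p-value; ``slope``/``slope_se`` are on the
    natural (per single unit) log-odds scale."""

    odds_ratio: float
    ci: tuple[float, float]
    p_value: float
    unit_scale: float
    slope: float
    slope_se: float


def _metric(
    events: int, n: int, ci_level: float, method: str
) -> tuple[float, float, float] | None:
    if n == 0:
        return None
    lo, hi = proportion_ci(events, n, ci_level, method)
    return (100.0 * events / n, 100.0 * lo, 100.0 * hi)


def diagnostic_summary(
    c: ThresholdCounts, ci_level: float = 0.95, method: str = "clopper-pearson"
) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV and NPV for one 2x2 table."""
    return DiagnosticSummary(
        sensitivity=_metric(c.tp, c.tp + c.fn, ci_level, method),
        specificity=_metric(c.tn, c.fp + c.tn, ci_level, method),
        ppv=_metric(c.tp, c.tp + c.fp, ci_level, method),
        npv=_metric(c.tn, c.tn + c.fn, ci_level, method),
        counts=c,
        ci_level=ci_level,
    )


def crude_risk(
    events: int,
    n: int,
    ci_level: float = 0.95,
    method: str = "clopper-pearson",
) -> RiskEstimate:
    """Crude risk events/n as a percentage with exact binomial CI."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= events <= n:
        raise ValueError(f"events must be in [0, n], got {events}/{n}")
    lo, hi = proportion_ci(events, n, ci_level, method)
    return RiskEstimate(
        events=events,
        n=n,
        risk_pct=100.0 * events / n,
        ci=(100.0 * lo, 100.0 * hi),
        ci_level=ci_level,
    )


def pearson_chi2(table) -> tuple[float, float]:
    """Classical Pearson chi-squared on a 2x2 table (no continuity
    correction); returns (statistic, p) with 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-squared test undefined: zero margin")
    statistic, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(statistic), float(p)


def mcnemar(b: int, c: int, variant: str = "exact") -> float:
    """McNemar's test p-value from the two discordant-pair counts.

    ``exact`` (default): two-sided binomial(b+c, 1/2) tail probability;
    ``chi2``: (b-c)^2/(b+c) against chi-squared(1); ``chi2-corrected``:
    with continuity correction.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise ValueError("McNemar's test undefined: no discordant pairs")
    table = [[0, b], [c, 0]]
    if variant == "exact":
        res = _sm_mcnemar(table, exact=True)
    elif variant == "chi2":
        res = _sm_mcnemar(table, exact=False, correction=False)
    elif variant == "chi2-corrected":
        res = _sm_mcnemar(table, exact=False, correction=True)
    else:
        raise ValueError(f"unknown McNemar variant {variant!r}")
    return float(min(res.pvalue, 1.0))


def univariable_logistic_or(
    x, y, unit_scale: float = 1.0, ci_level: float = 0.95
) -> OddsRatioResult:
    """Single-predictor logistic regression odds ratio per ``unit_scale``
    units, fitted by maximum likelihood (IRLS).  Perfect separation raises
    :class:`ConvergenceError` rather than diverging silently."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (
        PerfectSeparationError,
        PerfectSeparationWarning,
        np.linalg.LinAlgError,
    ) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return OddsRatioResult(
        odds_ratio=float(np.exp(slope * unit_scale)),
        ci=(
            float(np.exp((slope - z * se) * unit_scale)),
            float(np.exp((slope + z * se) * unit_scale)),
        ),
        p_value=float(fit.pvalues[1]),
        unit_scale=unit_scale,
        slope=slope,
        slope_se=se,
    )


def perifissural_risk(
    participants, extra_events: int = 0, ci_level: float = 0.95
) -> RiskEstimate:
    """Crude malignancy risk among participants with at least one nodule of
    typical perifissural (intrapulmonary lymph node) morphology.

    ``extra_events`` adds registry-identified cancer diagnoses made outside
    the screening programme to the in-study events.
    """
    if extra_events < 0:
        raise ValueError("extra_events must be >= 0")
    with_peri = [
        p
        for p in participants
        if any(n.perifissural_typical for n in p.nodules)
    ]
    events = sum(p.cancer_outcome for p in with_peri) + extra_events
    return crude_risk(events, len(with_peri), ci_level)


def false_positive_reduction(fp_before: int, fp_after: int) -> float:
    """Relative reduction in false-positive referrals, in percent."""
    if fp_before <= 0:
        raise ValueError("fp_before must be positive")
    return 100.0 * (fp_before - fp_after) / fp_before


def clopper_pearson_coverage(p: float, n: int, ci_level: float = 0.95) -> float:
    """Exact coverage probability of the Clopper-Pearson interval at a true
    proportion ``p`` and sample size ``n`` (sum of binomial probabilities
    over the outcomes whose interval covers ``p``)."""
    k = np.arange(n + 1)
    lo, hi = proportion_confint(k, n, alpha=1.0 - ci_level, method="beta")
    covered = (np.asarray(lo) <= p) & (p <= np.asarray(hi))
    return float(stats.binom.pmf(k[covered], n, p).sum())
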