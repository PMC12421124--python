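"""Weighted net-benefit comparison of two stratification rules.

Switching from a reference rule to a new rule trades sensitivity against
specificity.  The weighted net effect, in percentage points, is

    100 * [ (sens_new - sens_ref) + (spec_new - spec_ref) * (1/W) * (1-p)/p ]

where p is the cancer prevalence of the chosen reference population and W
weights down specificity gains: W true-negative reclassifications are
worth one true-positive at prevalence p.  Positive values favour the new
rule.  Confidence intervals come from a participant-level bootstrap
(resampling whole participants with replacement).

The prevalence entering p is a genuine analysis choice: the whole-cohort
rate, the nodule-participant rate, the rate among size-eligible (reference
rule positive) participants, or an externally fixed value.  It is
mandatory configuration and is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .cohort import IndexedParticipant
from .errors import ConfigurationError

__all__ = [
    "NetBenefitInput",
    "NetBenefitResult",
    "net_benefit_point",
    "bootstrap_net_benefit",
]

_PREVALENCE_SOURCES = (
    "whole_cohort",
    "nodule_participants",
    "size_eligible",
    "fixed_value",
)


@dataclass(frozen=True)
class NetBenefitInput:
    """Sens/spec of both rules (fractions), prevalence and weight."""

    sens_ref: float
    spec_ref: float
    sens_new: float
    spec_new: float
    prevalence_p: float
    weight_W: float

    def __post_init__(self) -> None:
        for name in ("sens_ref", "spec_ref", "sens_new", "spec_new"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.prevalence_p < 1.0:
            raise ValueError(
                f"prevalence_p must be in (0, 1), got {self.prevalence_p}"
            )
        if self.weight_W <= 0:
            raise ValueError(f"weight_W must be positive, got {self.weight_W}")


def net_benefit_point(inp: NetBenefitInput) -> float:
    """Weighted net effect of new vs reference rule, percentage points."""
    d_sens = inp.sens_new - inp.sens_ref
    d_spec = inp.spec_new - inp.spec_ref
    return 100.0 * (
        d_sens
        + d_spec * (1.0 / inp.weight_W) * (1.0 - inp.prevalence_p) / inp.prevalence_p
    )


@dataclass(frozen=True)
class NetBenefitResult:
    """Full-sample point estimate with percentile bootstrap CI."""

    point_estimate: float
    ci: tuple[float, float]
    n_bootstrap: int
    seed: int
    prevalence_source: str
    prevalence_p: float
    weight_W: float
    n_redrawn: int = 0
    ci_method: str = "percentile"


def _evaluate(
    pos_ref: np.ndarray,
    pos_new: np.ndarray,
    outcome: np.ndarray,
    has_nodule: np.ndarray,
    prevalence_source: str,
    weight_W: float,
    fixed_p: float | None,
) -> float:
    nod_out = outcome & has_nodule
    n_cancer = int(nod_out.sum())
    n_benign = int((has_nodule & ~outcome).sum())
    if n_cancer == 0 or n_benign == 0:
        raise ZeroDivisionError("a class is empty")
    sens_ref = float((pos_ref & nod_out).sum()) / n_cancer
    sens_new = float((pos_new & nod_out).sum()) / n_cancer
    spec_ref = float((~pos_ref & has_nodule & ~outcome).sum()) / n_benign
    spec_new = float((~pos_new & has_nodule & ~outcome).sum()) / n_benign
    if prevalence_source == "whole_cohort":
        p = float(outcome.mean())
    elif prevalence_source == "nodule_participants":
        p = n_cancer / float(has_nodule.sum())
    elif prevalence_source == "size_eligible":
        n_el = int(pos_ref.sum())
        if n_el == 0:
            raise ZeroDivisionError("no size-eligible participants")
        p = float((pos_ref & outcome).sum()) / n_el
    else:
        p = fixed_p
    return net_benefit_point(
        NetBenefitInput(
            sens_ref=sens_ref,
            spec_ref=spec_ref,
            sens_new=sens_new,
            spec_new=spec_new,
            prevalence_p=p,
            weight_W=weight_W,
        )
    )


def bootstrap_net_benefit(
    cohort: Iterable[IndexedParticipant],
    rule_ref,
    rule_new,
    weight_W: float,
    prevalence_source: str,
    B: int = 1000,
    seed: int = 0,
    fixed_p: float | None = None,
    brock: dict[str, float] | None = None,
    ci_level: float = 0.95,
    ci_method: str = "percentile",
) -> NetBenefitResult:
    """Net benefit of ``rule_new`` over ``rule_ref`` with a participant-
    level bootstrap CI (B resamples with replacement; percentile interval
    by default, 'basic' as the alternative).

    A resample in which either outcome class vanishes (or, under
    ``size_eligible`` prevalence, no participant meets the reference rule)
    is redrawn; the number of redraws is reported on the result.
    Sensitivity and specificity are computed over nodule participants;
    ``whole_cohort`` prevalence uses every participant in ``cohort``.
    """
    if prevalence_source not in _PREVALENCE_SOURCES:
        raise ConfigurationError(
            f"prevalence_source must be one of {_PREVALENCE_SOURCES}"
        )
    if prevalence_source == "fixed_value" and fixed_p is None:
        raise ConfigurationError("fixed_value prevalence requires fixed_p")
    if ci_method not in ("percentile", "basic"):
        raise ConfigurationError(f"unknown ci_method {ci_method!r}")

    cohort = list(cohort)
    pos_ref = np.array([rule_ref.is_positive(p, brock) for p in cohort], dtype=bool)
    pos_new = np.array([rule_new.is_positive(p, brock) for p in cohort], dtype=bool)
    outcome = np.array([p.outcome for p in cohort], dtype=bool)
    has_nodule = np.array([p.index_nodule is not None for p in cohort], dtype=bool)
    n = len(cohort)

    point = _evaluate(
        pos_ref, pos_new, outcome, has_nodule, prevalence_source, weight_W, fixed_p
    )

    rng = np.random.default_rng(seed)
    draws = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                draws[b] = _evaluate(
                    pos_ref[idx],
                    pos_new[idx],
                    outcome[idx],
                    has_nodule[idx],
                    prevalence_source,
                    weight_W,
                    fixed_p,
                )
                break
            except ZeroDivisionError:
                n_redrawn += 1

    alpha = 1.0 - ci_level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    if ci_method == "basic":
        lo, hi = 2.0 * point - hi, 2.0 * point - lo
    p_used = (
        fixed_p
        if prevalence_source == "fixed_value"
        else _prevalence_full(pos_ref, outcome, has_nodule, prevalence_source)
    )
    return NetBenefitResult(
        point_estimate=point,
        ci=(float(lo), float(hi)),
        n_bootstrap=B,
        seed=seed,
        prevalence_source=prevalence_source,
        prevalence_p=float(p_used),
        weight_W=weight_W,
        n_redrawn=n_redrawn,
        ci_method=ci_method,
    )


def _prevalence_full(pos_ref, outcome, has_nodule, prevalence_source) -> float:
    if prevalence_source == "whole_cohort":
        return float(outcome.mean())
    if prevalence_source == "nodule_participants":
        return float((outcome & has_nodule).sum() / has_nodule.sum())
    return float((pos_ref & outcome).sum() / pos_ref.sum())
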