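"""Brock (PanCan) malignancy probability for a baseline solid nodule.

The Brock model is a logistic regression developed on the Pan-Canadian
Early Detection of Lung Cancer study that predicts the probability that a
nodule found on a baseline screening CT is malignant, from participant
demographics (age, sex, family history of lung cancer), emphysema, and
nodule size, type, location, count and spiculation.  It is *applied* here
with its published coefficients, never refitted.

The size term is non-linear: the linear predictor contains
``-beta_size * ((d / 10)^(-1/2) - c_size)`` with ``d`` the nodule diameter
in mm, so predicted risk rises steeply through the clinically relevant
5-15 mm range and is strictly increasing in size.

The variant shipped as :data:`FULL_WITH_SPICULATION` is the full model
including spiculation — the variant the British Thoracic Society guideline
recommends for gating referral at 10% predicted risk.  Coefficients for
other published variants can be supplied through
:class:`BrockCoefficients`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import IndexedParticipant
from .errors import CohortValidationError, ConfigurationError

__all__ = [
    "BrockCovariates",
    "BrockCoefficients",
    "FULL_WITH_SPICULATION",
    "brock_probability",
    "brock_gate",
    "covariates_for_index",
    "brock_for_cohort",
]


@dataclass(frozen=True)
class BrockCovariates:
    """Inputs of the Brock model for one (solid) index nodule."""

    age_years: float
    sex: str  # "male" | "female"
    family_history: bool
    emphysema: bool
    size_mm: float  # long-axis diameter
    upper_lobe: bool
    nodule_count: int = 1
    spiculated: bool = False
    nodule_type: str = "solid"

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise CohortValidationError(f"size_mm must be > 0, got {self.size_mm!r}")
        if self.nodule_count < 1:
            raise CohortValidationError("nodule_count must be >= 1")
        if self.nodule_type != "solid":
            raise ConfigurationError(
                "this analysis is restricted to solid nodules; "
                f"got nodule_type={self.nodule_type!r}"
            )


@dataclass(frozen=True)
class BrockCoefficients:
    """Published coefficients of one Brock-model variant.

    The linear predictor is::

        intercept
        + b_age * (age - age_center)
        + b_female * [female]
        + b_family_history * [family history]
        + b_emphysema * [emphysema]
        - b_size * ((size_mm / 10)^(-1/2) - size_center)
        + b_upper_lobe * [upper lobe]
        + b_count * (nodule_count - count_center)
        + b_spiculation * [spiculated]
    """

    name: str
    intercept: float
    b_age: float
    age_center: float
    b_female: float
    b_family_history: float
    b_emphysema: float
    b_size: float
    size_center: float
    b_upper_lobe: float
    b_count: float
    count_center: float
    b_spiculation: float

    def linear_predictor(self, cov: BrockCovariates) -> float:
        return (
            self.intercept
            + self.b_age * (cov.age_years - self.age_center)
            + self.b_female * (cov.sex == "female")
            + self.b_family_history * cov.family_history
            + self.b_emphysema * cov.emphysema
            - self.b_size * ((cov.size_mm / 10.0) ** -0.5 - self.size_center)
            + self.b_upper_lobe * cov.upper_lobe
            + self.b_count * (cov.nodule_count - self.count_center)
            + self.b_spiculation * cov.spiculated
        )


# Full model with spiculation, transcribed from the model's original
# publication.  Age is centred at 62 years, nodule count at 4, and the size
# transform at (10 mm / 10)^(-1/2) scaled by 1.58113883 = (4 mm / 10)^(-1/2).
FULL_WITH_SPICULATION = BrockCoefficients(
    name="full-with-spiculation",
    intercept=-6.7892,
    b_age=0.0287,
    age_center=62.0,
    b_female=0.6011,
    b_family_history=0.2961,
    b_emphysema=0.2953,
    b_size=5.3854,
    size_center=1.58113883,
    b_upper_lobe=0.6581,
    b_count=-0.0824,
    count_center=4.0,
    b_spiculation=0.7729,
)


def brock_probability(
    cov: BrockCovariates, coef: BrockCoefficients = FULL_WITH_SPICULATION
) -> float:
    """Predicted malignancy probability (in (0, 1)) for one nodule."""
    lp = coef.linear_predictor(cov)
    return 1.0 / (1.0 + math.exp(-lp))


def brock_gate(prob: float, threshold: float = 0.10) -> bool:
    """Referral gate: true iff the predicted probability is >= threshold.

    Probabilities are compared at full precision (no rounding).  The study
    gate is 10%; 0.09905 is the Youden-optimal alternative and may be
    passed instead.
    """
    return prob >= threshold


def covariates_for_index(
    p: IndexedParticipant, use_equivalent_sphere: bool = False
) -> BrockCovariates:
    """Assemble Brock covariates for a participant's index nodule.

    Size is the long-axis diameter (the sizing this cohort records) by
    default; ``use_equivalent_sphere`` derives the diameter of a sphere of
    the nodule's volume instead, where a volume is available.
    """
    if p.index_nodule is None:
        raise ConfigurationError(
            f"participant {p.participant_id!r} has no index nodule"
        )
    if p.participant is None:
        raise ConfigurationError(
            f"participant {p.participant_id!r}: source record unavailable"
        )
    n = p.index_nodule
    size = n.diameter_mm
    if use_equivalent_sphere and n.volume_mm3 is not None:
        size = (6.0 * n.volume_mm3 / math.pi) ** (1.0 / 3.0)
    count = sum(1 for m in p.participant.nodules if not m.is_retronodule) or 1
    return BrockCovariates(
        age_years=p.participant.age_years,
        sex=p.participant.sex,
        family_history=p.participant.family_history_lung_cancer,
        emphysema=p.participant.emphysema,
        size_mm=size,
        upper_lobe=n.upper_lobe,
        nodule_count=count,
        spiculated=n.spiculated,
    )


def brock_for_cohort(
    cohort,
    coef: BrockCoefficients = FULL_WITH_SPICULATION,
    use_equivalent_sphere: bool = False,
) -> dict[str, float]:
    """Map participant_id -> Brock probability over indexed participants
    that carry a nodule (participants without one are omitted)."""
    out: dict[str, float] = {}
    for p in cohort:
        if p.index_nodule is not None:
            out[p.participant_id] = brock_probability(
                covariates_for_index(p, use_equivalent_sphere), coef
            )
    return out
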