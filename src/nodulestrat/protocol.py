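"""Baseline management classification and threshold 2x2 tables.

Under a baseline nodule-management protocol each indexed participant gets
exactly one action: routine recall to the next screening round (no nodule,
or rule-out-sized), a 3-month interval CT (intermediate size, or rule-in
size with a sub-threshold Brock score), or MDT referral for definitive
investigation (rule-in size with Brock score at or above the gate).

:func:`stratify` turns a cohort plus a threshold rule into the 2x2
contingency of rule positivity against malignancy, the raw material for
all diagnostic-accuracy statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .cohort import IndexedParticipant, ProtocolConfig, effective_size
from .errors import ConfigurationError

__all__ = [
    "ManagementAction",
    "ThresholdCounts",
    "SizeRule",
    "BrockGatedRule",
    "classify_baseline",
    "stratify",
]

ROUTINE_RECALL = "routine_recall"
INTERVAL_CT = "interval_ct_3month"
MDT_REFERRAL = "mdt_referral"


@dataclass(frozen=True)
class ManagementAction:
    """The single action assigned to a participant, with a rule trace."""

    action: str
    reason: str


@dataclass(frozen=True)
class ThresholdCounts:
    """2x2 contingency of a rule against malignancy at participant level.

    Positive = meets/exceeds the threshold (or is referred); condition =
    malignant outcome.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class SizeRule:
    """Positive iff the index nodule's size is at or above ``threshold``.

    Volume-scale rules fall back to ``fallback_diameter_mm`` for nodules
    without a reliable segmentation.  Participants without an index nodule
    are always negative.
    """

    threshold: float
    scale: str  # "mm3" | "mm"
    fallback_diameter_mm: float | None = None

    def is_positive(self, p: IndexedParticipant, brock=None) -> bool:
        n = p.index_nodule
        if n is None:
            return False
        if self.scale == "mm":
            return n.diameter_mm >= self.threshold
        if n.segmentation_reliable:
            return n.volume_mm3 >= self.threshold
        if self.fallback_diameter_mm is None:
            raise ConfigurationError(
                f"volume rule >= {self.threshold:g} mm3 needs a fallback "
                f"diameter for unsegmentable nodule of {p.participant_id!r}"
            )
        return n.diameter_mm >= self.fallback_diameter_mm

    def describe(self) -> str:
        unit = "mm3" if self.scale == "mm3" else "mm"
        return f">={self.threshold:g} {unit}"


@dataclass(frozen=True)
class BrockGatedRule:
    """Positive iff the size rule fires AND the Brock probability is at or
    above ``brock_threshold`` — referrals are a subset of size-positives."""

    size_rule: SizeRule
    brock_threshold: float = 0.10

    def is_positive(self, p: IndexedParticipant, brock=None) -> bool:
        if not self.size_rule.is_positive(p):
            return False
        if brock is None or p.participant_id not in brock:
            raise ConfigurationError(
                f"Brock probability required for participant "
                f"{p.participant_id!r} under a Brock-gated rule"
            )
        return brock[p.participant_id] >= self.brock_threshold

    def describe(self) -> str:
        return (
            f"{self.size_rule.describe()} & Brock>="
            f"{100 * self.brock_threshold:g}%"
        )


def classify_baseline(
    p: IndexedParticipant,
    protocol: ProtocolConfig,
    brock: float | None = None,
) -> ManagementAction:
    """Assign the baseline management action for one indexed participant.

    ``brock`` (a probability) is required only when the index nodule is
    rule-in-sized and the protocol carries a Brock gate.
    """
    if p.index_nodule is None:
        return ManagementAction(ROUTINE_RECALL, "no solid nodule at baseline")
    a = effective_size(p.index_nodule, protocol)
    size_txt = f"{a.size_value:g} {a.unit} ({a.mode})"
    if a.rule_out_pass:
        return ManagementAction(
            ROUTINE_RECALL, f"size {size_txt}: below rule-out cut-off"
        )
    if not a.rule_in_pass:
        return ManagementAction(
            INTERVAL_CT, f"size {size_txt}: intermediate; 3-month interval CT"
        )
    if brock is None:
        raise ConfigurationError(
            f"participant {p.participant_id!r}: rule-in-sized nodule "
            "requires a Brock probability under this protocol"
        )
    if brock >= protocol.brock_threshold:
        return ManagementAction(
            MDT_REFERRAL,
            f"size {size_txt}: rule-in; Brock {100 * brock:.2f}% >= "
            f"{100 * protocol.brock_threshold:g}%: refer",
        )
    return ManagementAction(
        INTERVAL_CT,
        f"size {size_txt}: rule-in; Brock {100 * brock:.2f}% < "
        f"{100 * protocol.brock_threshold:g}%: 3-month interval CT",
    )


def stratify(
    cohort: Iterable[IndexedParticipant],
    rule,
    brock: dict[str, float] | None = None,
    population: str = "nodule_participants",
) -> ThresholdCounts:
    """2x2 counts of rule positivity against malignancy.

    ``population='nodule_participants'`` (default) restricts denominators
    to participants with an index nodule, matching per-nodule-cohort
    sensitivity/specificity; ``'all'`` includes no-nodule participants as
    rule-negative.
    """
    if population not in ("nodule_participants", "all"):
        raise ConfigurationError(f"unknown population {population!r}")
    tp = fp = fn = tn = 0
    for p in cohort:
        if population == "nodule_participants" and p.index_nodule is None:
            continue
        pos = rule.is_positive(p, brock)
        if pos and p.outcome:
            tp += 1
        elif pos:
            fp += 1
        elif p.outcome:
            fn += 1
        else:
            tn += 1
    return ThresholdCounts(tp=tp, fp=fp, fn=fn, tn=tn)
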