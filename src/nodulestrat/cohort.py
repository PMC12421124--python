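"""Domain types, participant-level reduction and cohort table I/O.

A screening cohort is a collection of participants, each carrying zero or
more solid nodules found on the baseline low-dose CT.  All downstream
analyses are per participant: a participant with several nodules is
represented by a single *index* nodule — the malignant one if any nodule
proved malignant, otherwise the largest.

Sizes are fixed-unit: volumes in mm^3 (semi-automated volumetry), diameters
in mm (single long axis).  When volumetric segmentation is unreliable the
volume is absent and the manually measured diameter is the only size, so a
volumetric protocol falls back to diameter cut-offs for those nodules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import CohortValidationError, ConfigurationError, SchemaError

__all__ = [
    "NoduleRecord",
    "ParticipantRecord",
    "SizeAssessment",
    "IndexedParticipant",
    "ProtocolConfig",
    "BTS_PROTOCOL",
    "EUPS_PROTOCOL",
    "DIAMETER_PROTOCOL",
    "load_cohort",
    "write_cohort",
    "reduce_to_index",
    "effective_size",
]


@dataclass(frozen=True)
class NoduleRecord:
    """One solid nodule's size measurements and morphology/location flags.

    ``volume_mm3`` is absent exactly when ``segmentation_reliable`` is false:
    a reliable segmentation always yields a volume, and an unreliable one
    never does (a manual long-axis diameter is recorded instead).
    """

    nodule_id: str
    diameter_mm: float
    volume_mm3: float | None = None
    segmentation_reliable: bool = True
    spiculated: bool = False
    upper_lobe: bool = False
    perifissural_typical: bool = False
    is_retronodule: bool = False
    malignant: bool = False

    def __post_init__(self) -> None:
        if (self.volume_mm3 is None) != (not self.segmentation_reliable):
            raise CohortValidationError(
                f"nodule {self.nodule_id!r}: volume must be absent iff "
                "segmentation is unreliable "
                f"(volume_mm3={self.volume_mm3!r}, "
                f"segmentation_reliable={self.segmentation_reliable!r})"
            )
        if self.diameter_mm is None or self.diameter_mm < 0:
            raise CohortValidationError(
                f"nodule {self.nodule_id!r}: diameter_mm must be a "
                f"non-negative number, got {self.diameter_mm!r}"
            )
        if self.volume_mm3 is not None and self.volume_mm3 < 0:
            raise CohortValidationError(
                f"nodule {self.nodule_id!r}: volume_mm3 must be non-negative"
            )


@dataclass(frozen=True)
class ParticipantRecord:
    """One screening participant with Brock covariates and outcome.

    At most one nodule may be malignant (results are a 1:1:1 ratio of
    participants to nodules to cancer diagnoses); if the cancer outcome is
    positive and nodules are present, ``malignant_nodule_id`` must point at
    the malignant one.
    """

    participant_id: str
    age_years: float
    sex: str  # "male" | "female"
    family_history_lung_cancer: bool
    emphysema: bool
    nodules: tuple[NoduleRecord, ...] = ()
    cancer_outcome: bool = False
    malignant_nodule_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise CohortValidationError(
                f"participant {self.participant_id!r}: sex must be "
                f"'male' or 'female', got {self.sex!r}"
            )
        malignant = [n for n in self.nodules if n.malignant]
        if len(malignant) > 1:
            raise CohortValidationError(
                f"participant {self.participant_id!r}: more than one "
                "malignant nodule (must be at most one)"
            )
        if self.cancer_outcome and self.nodules:
            if not malignant:
                raise CohortValidationError(
                    f"participant {self.participant_id!r}: cancer outcome "
                    "with nodules present requires one malignant nodule"
                )
            if self.malignant_nodule_id != malignant[0].nodule_id:
                raise CohortValidationError(
                    f"participant {self.participant_id!r}: "
                    "malignant_nodule_id must reference the malignant nodule"
                )
        if malignant and not self.cancer_outcome:
            raise CohortValidationError(
                f"participant {self.participant_id!r}: malignant nodule "
                "present but cancer_outcome is false"
            )


@dataclass(frozen=True)
class SizeAssessment:
    """How a nodule's size compares with a protocol's rule-out/rule-in cuts.

    ``mode`` records whether the native volumetric measurement was used or
    the diameter fallback (unreliable segmentation under a volumetric
    protocol, or a diameter-primary protocol).
    """

    mode: str  # "volumetric" | "diameter_fallback"
    rule_out_pass: bool
    rule_in_pass: bool
    size_value: float
    unit: str  # "mm3" | "mm"


@dataclass(frozen=True)
class IndexedParticipant:
    """A participant reduced to their single index nodule.

    ``index_nodule`` is absent for participants with no (reportable) solid
    nodule.  ``participant`` keeps a reference to the source record so that
    Brock covariates remain reachable after reduction.
    """

    participant_id: str
    index_nodule: NoduleRecord | None
    outcome: bool
    participant: ParticipantRecord | None = field(
        default=None, compare=False, repr=False
    )

    @property
    def has_nodule(self) -> bool:
        return self.index_nodule is not None


@dataclass(frozen=True)
class ProtocolConfig:
    """Size/risk cut-offs of a baseline nodule-management protocol.

    ``mode`` selects the primary sizing method.  Under a volumetric protocol
    the fallback diameter cut-offs apply to nodules whose segmentation was
    unreliable.  Rule-out sets are strict (< cut-off); rule-in sets are
    inclusive (>= cut-off).  ``growth_referral_volume_mm3`` is carried for
    completeness (interval-scan growth referral); no interval-scan logic is
    executed here.
    """

    mode: str = "volumetric"  # "volumetric" | "diameter"
    rule_out_volume_mm3: float = 80.0
    rule_in_volume_mm3: float = 300.0
    rule_out_diameter_mm: float = 5.0
    rule_in_diameter_mm: float = 8.0
    fallback_rule_out_diameter_mm: float = 6.0
    fallback_rule_in_diameter_mm: float = 8.0
    brock_threshold: float = 0.10
    growth_referral_volume_mm3: float = 200.0

    def __post_init__(self) -> None:
        if self.mode not in ("volumetric", "diameter"):
            raise ConfigurationError(
                f"protocol mode must be 'volumetric' or 'diameter', got {self.mode!r}"
            )

    @classmethod
    def from_file(cls, path) -> "ProtocolConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown protocol keys: {sorted(unknown)}"
            )
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)},
                fh,
                sort_keys=False,
            )


#: British Thoracic Society baseline protocol: volume-primary, 80/300 mm^3,
#: 5/8 mm fallback at reporting but 6/8 mm fallback in the volumetric
#: analysis, Brock gate at 10%.
BTS_PROTOCOL = ProtocolConfig()

#: European Union position statement variant: 100 mm^3 rule-out.
EUPS_PROTOCOL = replace(BTS_PROTOCOL, rule_out_volume_mm3=100.0)

#: Diameter-primary protocol (long axis): 5 mm rule-out, 8 mm rule-in.
DIAMETER_PROTOCOL = replace(BTS_PROTOCOL, mode="diameter")


# ---------------------------------------------------------------------------
# Cohort file I/O
# ---------------------------------------------------------------------------

_PARTICIPANT_COLS = [
    "participant_id",
    "age_years",
    "sex",
    "family_history",
    "emphysema",
    "cancer_outcome",
]
_NODULE_COLS = [
    "volume_mm3",
    "diameter_mm",
    "segmentation_reliable",
    "spiculated",
    "upper_lobe",
    "perifissural",
    "retronodule",
    "malignant",
]

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(raw, line: int, col: str, default: bool | None = None) -> bool:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raw = ""
    s = str(raw).strip().lower()
    if s == "" and default is not None:
        return default
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise CohortValidationError(f"line {line}: column {col!r}: not a boolean: {raw!r}")


def _parse_float(raw, line: int, col: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise CohortValidationError(
            f"line {line}: column {col!r}: not a number: {raw!r}"
        ) from None


def _read_table(path) -> pd.DataFrame:
    # comma default, tab accepted; sniffed from the header line
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") > header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _nodule_from_row(row, line: int, nodule_id: str) -> NoduleRecord | None:
    diameter = _parse_float(row.get("diameter_mm"), line, "diameter_mm")
    volume = _parse_float(row.get("volume_mm3"), line, "volume_mm3")
    if diameter is None and volume is None:
        return None  # empty nodule slot (participant without nodules)
    if diameter is None:
        raise CohortValidationError(
            f"line {line}: diameter_mm is mandatory for every nodule "
            "(manual measurement when segmentation fails)"
        )
    reliable = _parse_bool(
        row.get("segmentation_reliable"),
        line,
        "segmentation_reliable",
        default=volume is not None,
    )
    if volume is not None and not reliable:
        raise CohortValidationError(
            f"line {line}: volume_mm3 present but segmentation_reliable is false"
        )
    if volume is None and reliable:
        raise CohortValidationError(
            f"line {line}: volume_mm3 absent but segmentation_reliable is true"
        )
    return NoduleRecord(
        nodule_id=nodule_id,
        diameter_mm=diameter,
        volume_mm3=volume,
        segmentation_reliable=reliable,
        spiculated=_parse_bool(row.get("spiculated"), line, "spiculated", False),
        upper_lobe=_parse_bool(row.get("upper_lobe"), line, "upper_lobe", False),
        perifissural_typical=_parse_bool(
            row.get("perifissural"), line, "perifissural", False
        ),
        is_retronodule=_parse_bool(row.get("retronodule"), line, "retronodule", False),
        malignant=_parse_bool(row.get("malignant"), line, "malignant", False),
    )


def load_cohort(path, layout: str = "participant_rows") -> list[ParticipantRecord]:
    """Read a delimited cohort table into participant records.

    ``layout='participant_rows'``: one row per participant carrying at most
    one (index) nodule.  ``layout='nodule_rows'``: one row per nodule with
    the participant columns repeated; rows are grouped by participant id (a
    row with empty nodule fields denotes a participant without nodules).
    Empty string means absent.  Errors carry 1-based file line numbers.
    """
    if layout not in ("participant_rows", "nodule_rows"):
        raise ConfigurationError(f"unknown layout {layout!r}")
    df = _read_table(path)
    missing = [c for c in _PARTICIPANT_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    groups: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after the header line
        pid = str(row["participant_id"]).strip()
        if not pid:
            raise CohortValidationError(f"line {line}: empty participant_id")
        if pid not in groups:
            age = _parse_float(row["age_years"], line, "age_years")
            if age is None:
                raise CohortValidationError(f"line {line}: age_years is mandatory")
            groups[pid] = dict(
                participant_id=pid,
                age_years=age,
                sex=str(row["sex"]).strip().lower(),
                family_history_lung_cancer=_parse_bool(
                    row["family_history"], line, "family_history"
                ),
                emphysema=_parse_bool(row["emphysema"], line, "emphysema"),
                cancer_outcome=_parse_bool(
                    row["cancer_outcome"], line, "cancer_outcome"
                ),
                nodules=[],
            )
            order.append(pid)
        elif layout == "participant_rows":
            raise CohortValidationError(
                f"line {line}: duplicate participant_id {pid!r} in "
                "participant_rows layout"
            )
        default_nid = f"{pid}-n{len(groups[pid]['nodules']) + 1}"
        nid = str(row.get("nodule_id", "") or "").strip() or default_nid
        nodule = _nodule_from_row(row, line, nid)
        if nodule is not None:
            groups[pid]["nodules"].append(nodule)

    out = []
    for pid in order:
        g = groups[pid]
        nodules = tuple(g.pop("nodules"))
        malignant = [n.nodule_id for n in nodules if n.malignant]
        out.append(
            ParticipantRecord(
                **g,
                nodules=nodules,
                malignant_nodule_id=malignant[0] if malignant else None,
            )
        )
    return out


def write_cohort(
    participants: Iterable[ParticipantRecord],
    path,
    layout: str = "participant_rows",
    sep: str = ",",
) -> None:
    """Write participants in the cohort file schema (inverse of load_cohort).

    In ``participant_rows`` layout each participant must carry at most one
    nodule; use ``nodule_rows`` for full fidelity on multi-nodule cohorts.
    """
    rows = []
    for p in participants:
        base = dict(
            participant_id=p.participant_id,
            age_years=p.age_years,
            sex=p.sex,
            family_history=p.family_history_lung_cancer,
            emphysema=p.emphysema,
            cancer_outcome=p.cancer_outcome,
        )
        if layout == "participant_rows" and len(p.nodules) > 1:
            raise CohortValidationError(
                f"participant {p.participant_id!r} has {len(p.nodules)} nodules; "
                "participant_rows layout holds at most one (use nodule_rows)"
            )
        nodules: Sequence[NoduleRecord | None] = p.nodules or (None,)
        for n in nodules:
            row = dict(base)
            if layout == "nodule_rows":
                row["nodule_id"] = "" if n is None else n.nodule_id
            row.update(
                volume_mm3="" if n is None or n.volume_mm3 is None else n.volume_mm3,
                diameter_mm="" if n is None else n.diameter_mm,
                segmentation_reliable="" if n is None else n.segmentation_reliable,
                spiculated="" if n is None else n.spiculated,
                upper_lobe="" if n is None else n.upper_lobe,
                perifissural="" if n is None else n.perifissural_typical,
                retronodule="" if n is None else n.is_retronodule,
                malignant="" if n is None else n.malignant,
            )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Participant-level reduction
# ---------------------------------------------------------------------------

def _size_sort_key(n: NoduleRecord, size_key: str):
    vol = n.volume_mm3 if n.volume_mm3 is not None else float("-inf")
    if size_key == "volume":
        primary, secondary = vol, n.diameter_mm
    else:
        primary, secondary = n.diameter_mm, vol
    # larger size first; lexicographically smallest id breaks residual ties
    return (-primary, -secondary, n.nodule_id)


def reduce_to_index(
    participants: Iterable[ParticipantRecord], size_key: str = "volume"
) -> list[IndexedParticipant]:
    """Reduce each participant to their index nodule.

    The index nodule is the malignant one if any, else the largest by
    ``size_key`` ('volume' or 'diameter'; tie-break: the other size, then
    smallest nodule id).  Benign retronodules (recognised only in
    retrospect) are never selected — a participant whose only nodules are
    benign retronodules is treated as having no reportable baseline nodule.
    """
    if size_key not in ("volume", "diameter"):
        raise ConfigurationError(f"size_key must be 'volume' or 'diameter'")
    out = []
    for p in participants:
        malignant = [n for n in p.nodules if n.malignant]
        if len(malignant) > 1:
            raise CohortValidationError(
                f"participant {p.participant_id!r}: two malignant nodules"
            )
        if malignant:
            index = malignant[0]
        else:
            eligible = [n for n in p.nodules if not n.is_retronodule]
            index = (
                min(eligible, key=lambda n: _size_sort_key(n, size_key))
                if eligible
                else None
            )
        out.append(
            IndexedParticipant(
                participant_id=p.participant_id,
                index_nodule=index,
                outcome=p.cancer_outcome,
                participant=p,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Effective size under a protocol
# ---------------------------------------------------------------------------

def effective_size(nodule: NoduleRecord, protocol: ProtocolConfig) -> SizeAssessment:
    """Compare a nodule's size with a protocol's rule-out/rule-in cut-offs.

    Volumetric protocol + reliable segmentation: the volume is compared with
    the volume cut-offs.  Unreliable segmentation: the diameter is compared
    with the fallback diameter cut-offs.  Diameter-primary protocol: always
    the diameter.  Rule-out passes strictly below the cut-off; rule-in
    passes at or above it.
    """
    if protocol.mode == "volumetric" and nodule.segmentation_reliable:
        size, unit, mode = nodule.volume_mm3, "mm3", "volumetric"
        out_cut = protocol.rule_out_volume_mm3
        in_cut = protocol.rule_in_volume_mm3
    else:
        size, unit, mode = nodule.diameter_mm, "mm", "diameter_fallback"
        if protocol.mode == "volumetric":
            out_cut = protocol.fallback_rule_out_diameter_mm
            in_cut = protocol.fallback_rule_in_diameter_mm
        else:
            out_cut = protocol.rule_out_diameter_mm
            in_cut = protocol.rule_in_diameter_mm
    return SizeAssessment(
        mode=mode,
        rule_out_pass=size < out_cut,
        rule_in_pass=size >= in_cut,
        size_value=size,
        unit=unit,
    )
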