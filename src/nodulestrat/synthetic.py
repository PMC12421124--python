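"""Synthetic screening cohorts and exact fixture reconstruction.

Two complementary sources of test data:

* :func:`generate_cohort` draws a stochastic cohort with the statistical
  structure the analysis assumes — a mixture of participants with and
  without solid nodules, log-normal nodule volumes with a separate (larger)
  malignant component, long-axis diameters derived from volume with
  multiplicative noise, independent segmentation failures, and Brock
  covariates whose prevalence is shifted among cancers by odds multipliers.

* :func:`reconstruct_fixture` builds a deterministic participant-level
  cohort that matches a set of *printed cumulative counts* (participants
  and cancers below each size threshold, on both the volume and the
  diameter scale) exactly.  The joint (volume, diameter) distribution is
  unidentified from cumulative marginals, so a modelling choice is
  required: within each outcome class the binned marginals are coupled
  comonotonically (northwest-corner transportation), which exists for any
  internally consistent count table and reproduces every cumulative cell on
  both scales simultaneously.  A single *global* rank coupling across
  classes is in general infeasible — real cohorts place some small-volume
  nodules above a diameter cut and vice versa — and is not attempted.

All randomness flows from one top-level seed; independent sub-streams are
spawned per purpose so that adding a covariate draw does not perturb
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .cohort import IndexedParticipant, NoduleRecord, ParticipantRecord
from .errors import InfeasibleSpecError

__all__ = [
    "GeneratorParams",
    "CovariateModel",
    "MarginalBin",
    "MarginalSpec",
    "FallbackRule",
    "generate_cohort",
    "reconstruct_fixture",
    "marginal_counts",
    "packaged_counts_spec",
]


# ---------------------------------------------------------------------------
# Stochastic generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateModel:
    """Brock-covariate prevalences, with odds multipliers applied to the
    malignant-nodule class so that risk-score gating has discriminative
    signal.  Prevalences refer to the benign/background class."""

    p_male: float = 0.577
    p_family_history: float = 0.15
    p_emphysema: float = 0.30
    p_upper_lobe: float = 0.45
    p_spiculation: float = 0.05
    cancer_odds: dict = field(
        default_factory=lambda: {
            "male": 1.0,
            "family_history": 1.3,
            "emphysema": 1.5,
            "upper_lobe": 1.8,
            "spiculation": 6.0,
        }
    )
    age_mean: float = 65.0
    age_sd: float = 6.0
    age_min: float = 55.0
    age_max: float = 77.0

    def shifted(self, name: str, p: float, malignant: bool) -> float:
        if not malignant:
            return p
        m = self.cancer_odds.get(name, 1.0)
        return p * m / (1.0 - p + p * m)


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults emulate the study conditions of a large UK screening
    baseline round: ~52% of participants with at least one solid nodule,
    crude malignancy risk 3.85% among nodule participants and 0.77% among
    participants without nodules, ~2.1% unreliable segmentation, and
    log-normal size components calibrated to the cohort's cumulative size
    counts (benign median ~52 mm^3, malignant median ~690 mm^3).

    Diameter is derived from volume as the equivalent-sphere diameter
    times a fixed elongation factor (long axis exceeds the sphere
    diameter) times multiplicative log-normal noise.
    """

    n_participants: int = 11355
    p_any_nodule: float = 0.522
    p_cancer_given_nodule: float = 0.0385
    p_cancer_no_nodule: float = 0.0077
    log_volume_mean: float = 3.96  # ln mm^3, benign
    log_volume_sd: float = 1.06
    cancer_log_volume_mean: float = 6.53
    cancer_log_volume_sd: float = 1.92
    diameter_elongation: float = 1.39
    volume_to_diameter_noise_sd: float = 0.125
    p_segmentation_failure: float = 0.021
    extra_nodule_rate: float = 0.25  # Poisson mean of additional benign nodules
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_any_nodule",
            "p_cancer_given_nodule",
            "p_cancer_no_nodule",
            "p_segmentation_failure",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "log_volume_sd",
            "cancer_log_volume_sd",
            "volume_to_diameter_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")


_STREAMS = (
    "presence",
    "outcome",
    "extra_nodules",
    "benign_volume",
    "cancer_volume",
    "diameter_noise",
    "segmentation",
    "covariates",
    "ages",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _diameter_from_volume(
    volume: float, elongation: float, noise: float
) -> float:
    return (6.0 * volume / math.pi) ** (1.0 / 3.0) * elongation * noise


def generate_cohort(params: GeneratorParams) -> list[ParticipantRecord]:
    """Draw a reproducible synthetic cohort (fixed seed => identical output)."""
    n = params.n_participants
    rng = _rngs(params.seed)
    cov = params.covariates

    has_nodule = rng["presence"].random(n) < params.p_any_nodule
    u_outcome = rng["outcome"].random(n)
    cancer = np.where(
        has_nodule,
        u_outcome < params.p_cancer_given_nodule,
        u_outcome < params.p_cancer_no_nodule,
    )
    n_extra = rng["extra_nodules"].poisson(params.extra_nodule_rate, size=n)
    ages = np.clip(
        rng["ages"].normal(cov.age_mean, cov.age_sd, size=n),
        cov.age_min,
        cov.age_max,
    )
    crng = rng["covariates"]

    out: list[ParticipantRecord] = []
    width = len(str(max(n, 1)))
    for i in range(n):
        pid = f"S{i:0{width}d}"
        is_cancer = bool(cancer[i] and has_nodule[i]) or bool(
            cancer[i] and not has_nodule[i]
        )
        male = crng.random() < cov.shifted(
            "male", cov.p_male, cancer[i] and has_nodule[i]
        )
        fh = crng.random() < cov.shifted(
            "family_history", cov.p_family_history, cancer[i] and has_nodule[i]
        )
        emph = crng.random() < cov.shifted(
            "emphysema", cov.p_emphysema, cancer[i] and has_nodule[i]
        )
        nodules: list[NoduleRecord] = []
        malignant_id = None
        if has_nodule[i]:
            k = 1 + int(n_extra[i])
            for j in range(k):
                malignant = bool(cancer[i]) and j == 0
                if malignant:
                    vol = float(
                        rng["cancer_volume"].lognormal(
                            params.cancer_log_volume_mean,
                            params.cancer_log_volume_sd,
                        )
                    )
                else:
                    vol = float(
                        rng["benign_volume"].lognormal(
                            params.log_volume_mean, params.log_volume_sd
                        )
                    )
                noise = float(
                    rng["diameter_noise"].lognormal(
                        0.0, params.volume_to_diameter_noise_sd
                    )
                )
                diam = _diameter_from_volume(
                    vol, params.diameter_elongation, noise
                )
                unseg = (
                    rng["segmentation"].random() < params.p_segmentation_failure
                )
                nid = f"{pid}-n{j + 1}"
                nodules.append(
                    NoduleRecord(
                        nodule_id=nid,
                        diameter_mm=round(diam, 2),
                        volume_mm3=None if unseg else round(vol, 1),
                        segmentation_reliable=not unseg,
                        spiculated=crng.random()
                        < cov.shifted("spiculation", cov.p_spiculation, malignant),
                        upper_lobe=crng.random()
                        < cov.shifted("upper_lobe", cov.p_upper_lobe, malignant),
                        malignant=malignant,
                    )
                )
                if malignant:
                    malignant_id = nid
        out.append(
            ParticipantRecord(
                participant_id=pid,
                age_years=float(round(ages[i], 1)),
                sex="male" if male else "female",
                family_history_lung_cancer=bool(fh),
                emphysema=bool(emph),
                nodules=tuple(nodules),
                cancer_outcome=bool(is_cancer),
                malignant_nodule_id=malignant_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Marginal-count specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarginalBin:
    """One cumulative count cell: participants and cancers whose index-
    nodule size falls strictly below ``threshold`` on ``scale``."""

    threshold: float
    scale: str  # "mm3" | "mm"
    participants_below: int
    cancers_below: int


@dataclass(frozen=True)
class FallbackRule:
    """How unsegmentable (diameter-only) nodules enter volume-scale counts:
    below a volume threshold smaller than ``rule_in_volume_mm3`` iff their
    diameter is below ``rule_out_diameter_mm``; below a volume threshold of
    at least ``rule_in_volume_mm3`` iff below ``rule_in_diameter_mm``."""

    rule_out_diameter_mm: float = 6.0
    rule_in_diameter_mm: float = 8.0
    rule_in_volume_mm3: float = 300.0

    def diameter_cut(self, volume_threshold: float) -> float:
        if volume_threshold < self.rule_in_volume_mm3:
            return self.rule_out_diameter_mm
        return self.rule_in_diameter_mm


@dataclass(frozen=True)
class MarginalSpec:
    """Cumulative participant/cancer counts at size thresholds on two
    scales, plus cohort totals and the number of unsegmentable nodules."""

    n_nodule_participants: int
    n_nodule_cancers: int
    bins: tuple[MarginalBin, ...]
    n_no_nodule_participants: int = 0
    n_no_nodule_cancers: int = 0
    unsegmentable_count: int = 0

    def sorted_bins(self, scale: str) -> list[MarginalBin]:
        return sorted(
            (b for b in self.bins if b.scale == scale), key=lambda b: b.threshold
        )

    @property
    def thresholds(self) -> list[tuple[float, str]]:
        return [(b.threshold, b.scale) for b in self.bins]

    def canonical(self) -> "MarginalSpec":
        """Bins in a fixed (scale, threshold) order, for comparisons."""
        return replace(
            self,
            bins=tuple(sorted(self.bins, key=lambda b: (b.scale, b.threshold))),
        )

    def validate(self) -> None:
        if self.n_nodule_cancers > self.n_nodule_participants:
            raise InfeasibleSpecError("more nodule cancers than participants")
        if self.n_no_nodule_cancers > self.n_no_nodule_participants:
            raise InfeasibleSpecError("more no-nodule cancers than participants")
        if self.unsegmentable_count > self.n_nodule_participants:
            raise InfeasibleSpecError("more unsegmentable nodules than participants")
        for scale in ("mm3", "mm"):
            prev = MarginalBin(0.0, scale, 0, 0)
            for b in self.sorted_bins(scale):
                label = f"bin (<{b.threshold:g} {b.scale})"
                if b.cancers_below > b.participants_below:
                    raise InfeasibleSpecError(
                        f"{label}: cancers_below exceeds participants_below"
                    )
                if b.participants_below < prev.participants_below:
                    raise InfeasibleSpecError(
                        f"{label}: participants_below decreases with threshold"
                    )
                if b.cancers_below < prev.cancers_below:
                    raise InfeasibleSpecError(
                        f"{label}: cancers_below decreases with threshold"
                    )
                dp = b.participants_below - prev.participants_below
                dc = b.cancers_below - prev.cancers_below
                if dc > dp:
                    raise InfeasibleSpecError(
                        f"{label}: interval holds more cancers than participants"
                    )
                if b.participants_below > self.n_nodule_participants:
                    raise InfeasibleSpecError(
                        f"{label}: participants_below exceeds the cohort total"
                    )
                if b.cancers_below > self.n_nodule_cancers:
                    raise InfeasibleSpecError(
                        f"{label}: cancers_below exceeds total cancers"
                    )
                prev = b

    @classmethod
    def from_file(cls, path) -> "MarginalSpec":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "MarginalSpec":
        bins = tuple(MarginalBin(**b) for b in raw.pop("bins", []))
        return cls(bins=bins, **raw)

    def to_file(self, path) -> None:
        data = dict(
            n_nodule_participants=self.n_nodule_participants,
            n_nodule_cancers=self.n_nodule_cancers,
            n_no_nodule_participants=self.n_no_nodule_participants,
            n_no_nodule_cancers=self.n_no_nodule_cancers,
            unsegmentable_count=self.unsegmentable_count,
            bins=[vars(b) for b in self.bins],
        )
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def packaged_counts_spec() -> MarginalSpec:
    """The marginal-count table shipped with the package (transcribed from
    the source cohort's published per-participant size-threshold counts)."""
    ref = resources.files("nodulestrat.data") / "baseline_cohort_counts.yaml"
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    spec = MarginalSpec.from_dict(raw)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Fixture reconstruction
# ---------------------------------------------------------------------------

def _intervals(thresholds: Sequence[float]) -> list[tuple[float, float]]:
    edges = [0.0, *thresholds, math.inf]
    return list(zip(edges[:-1], edges[1:]))


def _interval_counts(total: int, cumulative: Sequence[int]) -> list[int]:
    prev, out = 0, []
    for c in cumulative:
        out.append(c - prev)
        prev = c
    out.append(total - prev)
    if out[-1] < 0:
        raise InfeasibleSpecError("cumulative counts exceed the total")
    return out


def _log_mid(lo: float, hi: float, default: float) -> float:
    """Deterministic representative value strictly inside (lo, hi):
    geometric midpoint, with the open ends pulled in by a factor of 2."""
    if lo == 0.0 and math.isinf(hi):
        return default
    lo_eff = lo if lo > 0 else hi / 4.0
    hi_eff = hi if not math.isinf(hi) else 2.0 * lo
    return math.sqrt(lo_eff * hi_eff)


def _northwest_corner(rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
    """Comonotone (northwest-corner) coupling of two count marginals."""
    if sum(rows) != sum(cols):
        raise InfeasibleSpecError(
            f"marginal totals differ: {sum(rows)} vs {sum(cols)}"
        )
    table = np.zeros((len(rows), len(cols)), dtype=int)
    r = list(rows)
    c = list(cols)
    i = j = 0
    while i < len(r) and j < len(c):
        take = min(r[i], c[j])
        table[i, j] = take
        r[i] -= take
        c[j] -= take
        if r[i] == 0:
            i += 1
        if j < len(c) and c[j] == 0:
            j += 1
    return table


def reconstruct_fixture(
    spec: MarginalSpec,
    seed: int = 0,
    covariates: CovariateModel | None = None,
    fallback: FallbackRule = FallbackRule(),
) -> list[ParticipantRecord]:
    """Build a participant-level cohort matching ``spec`` exactly.

    Every cumulative (participants_below, cancers_below) cell of the spec
    is reproduced exactly by :func:`marginal_counts` on the result.  Sizes
    are placed at deterministic log-scale midpoints strictly inside each
    bin; the volume/diameter bin assignment is coupled comonotonically
    within each outcome class.  Unsegmentable nodules are emitted benign
    with a diameter strictly between the fallback rule-out and rule-in
    cut-offs, so both fallback conventions yield identical counts.  Brock
    covariates are drawn from ``covariates`` with the given seed; sizes and
    counts are seed-independent.
    """
    spec.validate()
    cov = covariates or CovariateModel()

    vol_bins = spec.sorted_bins("mm3")
    diam_bins = spec.sorted_bins("mm")
    vol_iv = _intervals([b.threshold for b in vol_bins])
    diam_iv = _intervals([b.threshold for b in diam_bins])
    n_cancer = spec.n_nodule_cancers
    n_part = spec.n_nodule_participants

    canc_v = _interval_counts(n_cancer, [b.cancers_below for b in vol_bins])
    canc_d = _interval_counts(n_cancer, [b.cancers_below for b in diam_bins])
    part_v = _interval_counts(n_part, [b.participants_below for b in vol_bins])
    part_d = _interval_counts(n_part, [b.participants_below for b in diam_bins])
    ben_v = [p - c for p, c in zip(part_v, canc_v)]
    ben_d = [p - c for p, c in zip(part_d, canc_d)]
    if min(ben_v, default=0) < 0 or min(ben_d, default=0) < 0:
        raise InfeasibleSpecError("an interval holds more cancers than participants")

    # Unsegmentable nodules: benign, diameter strictly between the fallback
    # cut-offs; on the volume scale they count below exactly the thresholds
    # of at least the rule-in volume, i.e. the interval just below it.
    unseg = spec.unsegmentable_count
    unseg_diam = math.sqrt(
        fallback.rule_out_diameter_mm * fallback.rule_in_diameter_mm
    )
    if unseg:
        vi = next(
            (
                k
                for k, (lo, hi) in enumerate(vol_iv)
                if hi >= fallback.rule_in_volume_mm3
            ),
            len(vol_iv) - 1,
        )
        di = next(
            k for k, (lo, hi) in enumerate(diam_iv) if lo <= unseg_diam < hi
        )
        if ben_v[vi] < unseg or ben_d[di] < unseg:
            raise InfeasibleSpecError(
                f"bin (<{vol_iv[vi][1]:g} mm3 / <{diam_iv[di][1]:g} mm): "
                "too few benign participants to hold the unsegmentable nodules"
            )
        ben_v[vi] -= unseg
        ben_d[di] -= unseg

    canc_table = _northwest_corner(canc_v, canc_d)
    ben_table = _northwest_corner(ben_v, ben_d)

    vol_rep = [_log_mid(lo, hi, 100.0) for lo, hi in vol_iv]
    diam_rep = [_log_mid(lo, hi, 6.0) for lo, hi in diam_iv]

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    width = len(str(max(n_part + spec.n_no_nodule_participants, 1)))
    out: list[ParticipantRecord] = []

    def covariate_draw(malignant: bool):
        age = float(
            round(
                min(
                    max(rng.normal(cov.age_mean, cov.age_sd), cov.age_min),
                    cov.age_max,
                ),
                1,
            )
        )
        return dict(
            age_years=age,
            sex="male"
            if rng.random() < cov.shifted("male", cov.p_male, malignant)
            else "female",
            family_history_lung_cancer=bool(
                rng.random()
                < cov.shifted("family_history", cov.p_family_history, malignant)
            ),
            emphysema=bool(
                rng.random() < cov.shifted("emphysema", cov.p_emphysema, malignant)
            ),
        )

    def nodule_flags(malignant: bool):
        return dict(
            spiculated=bool(
                rng.random() < cov.shifted("spiculation", cov.p_spiculation, malignant)
            ),
            upper_lobe=bool(
                rng.random() < cov.shifted("upper_lobe", cov.p_upper_lobe, malignant)
            ),
        )

    serial = 0

    def emit(volume, diameter, malignant, reliable=True):
        nonlocal serial
        pid = f"F{serial:0{width}d}"
        serial += 1
        nid = f"{pid}-n1"
        nodule = NoduleRecord(
            nodule_id=nid,
            diameter_mm=diameter,
            volume_mm3=volume if reliable else None,
            segmentation_reliable=reliable,
            malignant=malignant,
            **nodule_flags(malignant),
        )
        out.append(
            ParticipantRecord(
                participant_id=pid,
                nodules=(nodule,),
                cancer_outcome=malignant,
                malignant_nodule_id=nid if malignant else None,
                **covariate_draw(malignant),
            )
        )

    for i in range(len(vol_iv)):
        for j in range(len(diam_iv)):
            for _ in range(int(canc_table[i, j])):
                emit(vol_rep[i], diam_rep[j], True)
            for _ in range(int(ben_table[i, j])):
                emit(vol_rep[i], diam_rep[j], False)
    for _ in range(unseg):
        emit(None, unseg_diam, False, reliable=False)

    for k in range(spec.n_no_nodule_participants):
        pid = f"N{k:0{width}d}"
        out.append(
            ParticipantRecord(
                participant_id=pid,
                nodules=(),
                cancer_outcome=k < spec.n_no_nodule_cancers,
                **covariate_draw(False),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Marginal counting
# ---------------------------------------------------------------------------

def _below(
    p: IndexedParticipant, threshold: float, scale: str, fallback: FallbackRule
) -> bool:
    n = p.index_nodule
    if scale == "mm":
        return n.diameter_mm < threshold
    if n.segmentation_reliable:
        return n.volume_mm3 < threshold
    return n.diameter_mm < fallback.diameter_cut(threshold)


def marginal_counts(
    cohort: Iterable[IndexedParticipant],
    thresholds: Sequence[tuple[float, str]],
    fallback: FallbackRule = FallbackRule(),
) -> MarginalSpec:
    """Cumulative below-threshold participant and cancer counts, plus
    totals, over an index-reduced cohort.  Volume-scale counts categorise
    unsegmentable nodules by the fallback diameter cut-offs."""
    cohort = list(cohort)
    with_nodule = [p for p in cohort if p.index_nodule is not None]
    without = [p for p in cohort if p.index_nodule is None]
    bins = []
    for value, scale in thresholds:
        sel = [p for p in with_nodule if _below(p, value, scale, fallback)]
        bins.append(
            MarginalBin(
                threshold=float(value),
                scale=scale,
                participants_below=len(sel),
                cancers_below=sum(p.outcome for p in sel),
            )
        )
    bins.sort(key=lambda b: (b.scale, b.threshold))
    return MarginalSpec(
        n_nodule_participants=len(with_nodule),
        n_nodule_cancers=sum(p.outcome for p in with_nodule),
        bins=tuple(bins),
        n_no_nodule_participants=len(without),
        n_no_nodule_cancers=sum(p.outcome for p in without),
        unsegmentable_count=sum(
            not p.index_nodule.segmentation_reliable for p in with_nodule
        ),
    )
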