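"""Bayesian point-based ACMG/AMP classification.

Evidence criteria are scored as signed integer points by strength
(supporting +/-1, moderate +/-2, strong +/-4, very strong +/-8); positive
points indicate pathogenicity, negative points benignity. The engine scores
the four criteria relevant to a filtered family-exome candidate list:

* **PVS1** (+8): predicted null variants — nonsense, frameshift, or a
  canonical +/-1,2 splice-site variant whose SpliceAI delta score clears
  the splice threshold.
* **PM2_supporting** (+1): population frequency below 0.01% (strictly),
  with absence from the reference databases counting as frequency 0.
* **PP3** (+1) / **BP4** (-1): computational evidence for missense
  variants from REVEL (>= 0.75 pathogenic, <= 0.25 benign). When PVS1 is
  already applied the splice predictor evidence is considered consumed and
  PP3 is not added on top, so a canonical splice variant absent from the
  population scores +9, not +10.

The summed points are banded into five classes: pathogenic (>= 10),
likely pathogenic (6 to 9), uncertain significance (-1 to 5), likely
benign (-6 to -2) and benign (<= -7). The bands partition the integers.

This is deliberately not a full 28-criterion ACMG engine: segregation,
functional and hotspot evidence are out of scope here (co-segregation is
used as a ranking signal by :mod:`famvar.family`, not as points), and PVS1
is applied uniformly at very strong without the ClinGen strength-modulation
decision tree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .config import PipelineConfig
from .errors import ValidationError
from .models import CANONICAL_SPLICE_TERMS, NULL_CONSEQUENCES, VariantRecord


class Strength(enum.Enum):
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 4
    VERY_STRONG = 8


class Tier(enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    @property
    def severity(self) -> int:
        """Rank for sorting; 0 is most severe."""
        return _SEVERITY[self]

    @property
    def short(self) -> str:
        return _SHORT[self]


_SEVERITY = {
    Tier.PATHOGENIC: 0,
    Tier.LIKELY_PATHOGENIC: 1,
    Tier.VUS: 2,
    Tier.LIKELY_BENIGN: 3,
    Tier.BENIGN: 4,
}
_SHORT = {
    Tier.PATHOGENIC: "P",
    Tier.LIKELY_PATHOGENIC: "LP",
    Tier.VUS: "VUS",
    Tier.LIKELY_BENIGN: "LB",
    Tier.BENIGN: "B",
}

CRITERION_IDS = ("PVS1", "PM2_supporting", "PP3", "BP4")
_BENIGN_CRITERIA = frozenset({"BP4"})


@dataclass(frozen=True, slots=True)
class CriterionAssignment:
    """One applied criterion with its strength and signed points."""

    criterion: str
    strength: Strength
    points: int

    def __post_init__(self) -> None:
        if self.criterion not in CRITERION_IDS:
            raise ValidationError(f"unknown criterion {self.criterion!r}")
        if abs(self.points) != self.strength.value:
            raise ValidationError(
                f"{self.criterion}: points {self.points} inconsistent with strength "
                f"{self.strength.name} (magnitude {self.strength.value})"
            )
        benign = self.criterion in _BENIGN_CRITERIA
        if benign and self.points > 0 or not benign and self.points < 0:
            raise ValidationError(f"{self.criterion}: sign of points {self.points} is wrong")

    def __str__(self) -> str:
        return f"{self.criterion}:{self.points:+d}"


@dataclass(frozen=True, slots=True)
class ClassificationResult:
    assignments: tuple[CriterionAssignment, ...]
    total: int
    tier: Tier

    def criteria_string(self) -> str:
        return ";".join(str(a) for a in self.assignments) if self.assignments else "-"


def is_predicted_null(v: VariantRecord, cfg: PipelineConfig) -> bool:
    """Predicted complete loss of gene product.

    Nonsense and frameshift qualify by consequence alone. A splice
    donor/acceptor variant qualifies when it sits in the canonical +/-1,2
    dinucleotide and its SpliceAI delta score reaches the configured
    threshold — annotation without predictor support is not enough.
    """
    if v.consequence in NULL_CONSEQUENCES:
        return True
    if v.consequence in CANONICAL_SPLICE_TERMS:
        if v.splice_offset is None or abs(v.splice_offset) > 2:
            return False
        sai = v.annotations.spliceai_delta_max
        return sai is not None and sai >= cfg.spliceai_min
    return False


def evaluate_pvs1(v: VariantRecord, cfg: PipelineConfig) -> CriterionAssignment | None:
    if is_predicted_null(v, cfg):
        return CriterionAssignment("PVS1", Strength.VERY_STRONG, +8)
    return None


def evaluate_pm2_supporting(v: VariantRecord, cfg: PipelineConfig) -> CriterionAssignment | None:
    """Rarity criterion, applied at supporting strength.

    The frequency compared is the maximum of the overall and the
    subpopulation-maximum allele frequencies, with missing values counted
    as 0 (never observed). The comparison is strict: a frequency exactly at
    the bound does not score.
    """
    af = v.annotations.max_af() or 0.0
    if af < cfg.pm2_af_max:
        return CriterionAssignment("PM2_supporting", Strength.SUPPORTING, +1)
    return None


def evaluate_pp3_bp4(
    v: VariantRecord, cfg: PipelineConfig, pvs1_applied: bool = False
) -> CriterionAssignment | None:
    """Computational evidence for missense variants, from REVEL only.

    CADD gates the filter cascade but does not contribute points. Suppressed
    entirely when PVS1 is applied, so the same predictor evidence is never
    counted twice. REVEL values between the benign and pathogenic bounds,
    or missing, yield no criterion.
    """
    if pvs1_applied or v.consequence != "missense_variant":
        return None
    revel = v.annotations.revel
    if revel is None:
        return None
    if revel >= cfg.revel_pathogenic_min:
        return CriterionAssignment("PP3", Strength.SUPPORTING, +1)
    if revel <= cfg.revel_benign_max:
        return CriterionAssignment("BP4", Strength.SUPPORTING, -1)
    return None


def aggregate_points(assignments: list[CriterionAssignment]) -> int:
    seen = set()
    for a in assignments:
        if a.criterion in seen:
            raise ValidationError(f"criterion {a.criterion} assigned more than once")
        seen.add(a.criterion)
    return sum(a.points for a in assignments)


def classify_points(total: int, cfg: PipelineConfig) -> Tier:
    if total >= cfg.pathogenic_min:
        return Tier.PATHOGENIC
    if total >= cfg.likely_pathogenic_min:
        return Tier.LIKELY_PATHOGENIC
    if total >= cfg.vus_min:
        return Tier.VUS
    if total >= cfg.likely_benign_min:
        return Tier.LIKELY_BENIGN
    return Tier.BENIGN


def classify_variant(v: VariantRecord, cfg: PipelineConfig) -> ClassificationResult:
    """Run all criteria, sum the points and band into a five-tier class."""
    assignments: list[CriterionAssignment] = []
    pvs1 = evaluate_pvs1(v, cfg)
    if pvs1 is not None:
        assignments.append(pvs1)
    pm2 = evaluate_pm2_supporting(v, cfg)
    if pm2 is not None:
        assignments.append(pm2)
    pp3bp4 = evaluate_pp3_bp4(v, cfg, pvs1_applied=pvs1 is not None)
    if pp3bp4 is not None:
        assignments.append(pp3bp4)
    total = aggregate_points(assignments)
    return ClassificationResult(tuple(assignments), total, classify_points(total, cfg))
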