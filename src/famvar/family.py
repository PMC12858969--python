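"""Per-family analysis: co-segregation, candidate ranking, shared exposures.

The genetic and the environmental track of a family work-up are screened
side by side. A candidate variant is checked for co-segregation with the
affection status across genotyped family members; candidates are then
ranked by classification tier, points and segregation verdict. In
parallel, questionnaire exposures are screened for substances shared by
all affected — and no unaffected — family members, which can explain an
apparently heritable phenotype by a common occupational exposure instead.

Reduced penetrance is the rule rather than the exception in heritable
pulmonary arterial hypertension, so an unaffected carrier demotes a
candidate (verdict ``consistent_reduced_penetrance``) but never excludes
it; only an affected non-carrier is disqualifying. Individuals with
"suspected" or unknown affection status never constrain a verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .acmg import ClassificationResult
from .models import AffectionStatus, Pedigree, VariantRecord, Zygosity
from .errors import StructuralError, ValidationError


class SegregationVerdict(enum.Enum):
    CONSISTENT = "consistent"
    CONSISTENT_REDUCED_PENETRANCE = "consistent_reduced_penetrance"
    INCONSISTENT = "inconsistent"
    UNINFORMATIVE = "uninformative"

    @property
    def rank(self) -> int:
        """Sort rank for candidate ordering; 0 is the best verdict."""
        return _VERDICT_RANK[self]


_VERDICT_RANK = {
    SegregationVerdict.CONSISTENT: 0,
    SegregationVerdict.CONSISTENT_REDUCED_PENETRANCE: 1,
    SegregationVerdict.UNINFORMATIVE: 2,
    SegregationVerdict.INCONSISTENT: 3,
}


@dataclass(frozen=True, slots=True)
class SegregationStatus:
    verdict: SegregationVerdict
    carriers: tuple[str, ...]
    non_carriers: tuple[str, ...]
    untyped: tuple[str, ...]


def cosegregation_status(v: VariantRecord, ped: Pedigree) -> SegregationStatus:
    """Judge whether a variant tracks with affection status in a family.

    * ``consistent``: every genotyped affected carries; no genotyped
      unaffected carries.
    * ``consistent_reduced_penetrance``: every genotyped affected carries
      but at least one genotyped unaffected does too.
    * ``inconsistent``: any genotyped affected does not carry.
    * ``uninformative``: fewer than two genotyped individuals, or no
      genotyped affected.

    A genotype call of ``missing`` counts as untyped, as does absence from
    the genotype map. Suspected/unknown-status individuals are reported in
    the carrier lists but never constrain the verdict.
    """
    for iid in v.genotypes:
        if iid not in ped:
            raise StructuralError(f"genotype references unknown individual {iid!r}")

    carriers: list[str] = []
    non_carriers: list[str] = []
    untyped: list[str] = []
    affected_carriers = affected_noncarriers = 0
    unaffected_carriers = 0
    n_typed = n_typed_affected = 0

    for ind in ped:
        call = v.genotypes.get(ind.id, Zygosity.MISSING)
        if call is Zygosity.MISSING:
            untyped.append(ind.id)
            continue
        n_typed += 1
        (carriers if call.carries else non_carriers).append(ind.id)
        if ind.status is AffectionStatus.AFFECTED:
            n_typed_affected += 1
            if call.carries:
                affected_carriers += 1
            else:
                affected_noncarriers += 1
        elif ind.status is AffectionStatus.UNAFFECTED and call.carries:
            unaffected_carriers += 1

    if n_typed < 2 or n_typed_affected == 0:
        verdict = SegregationVerdict.UNINFORMATIVE
    elif affected_noncarriers > 0:
        verdict = SegregationVerdict.INCONSISTENT
    elif unaffected_carriers > 0:
        verdict = SegregationVerdict.CONSISTENT_REDUCED_PENETRANCE
    else:
        verdict = SegregationVerdict.CONSISTENT
    return SegregationStatus(verdict, tuple(carriers), tuple(non_carriers), tuple(untyped))


CandidateTriple = tuple[VariantRecord, ClassificationResult, SegregationStatus]


def rank_candidates(results: list[CandidateTriple]) -> list[CandidateTriple]:
    """Order candidates for reporting.

    Sort key: tier severity, then total points (descending), then
    segregation verdict (consistent best), then gene symbol, then
    position. The sort is stable and the output is a deterministic total
    order for any permutation of the input.
    """

    def key(item: CandidateTriple):
        v, cls, seg = item
        return (cls.tier.severity, -cls.total, seg.verdict.rank, v.gene, v.chrom, v.pos)

    return sorted(results, key=key)


# ---------------------------------------------------------------------------
# Shared environmental exposure screening
# ---------------------------------------------------------------------------

#: Substance-name normalization: maps questionnaire free text onto the
#: canonical substance the risk-tier table knows. Extend via the
#: ``synonyms`` argument of :func:`shared_exposure_screen`.
DEFAULT_SYNONYMS: dict[str, str] = {
    "paint dust": "organic solvents",
    "organic solvent": "organic solvents",
    "solvents": "organic solvents",
    "asbestos dust": "asbestos",
    "tramadol": "tramadol",
    "tce": "trichloroethylene",
}

#: Default risk tiers for substances with published PAH/PVOD associations.
#: Unlisted substances default to "possible".
DEFAULT_RISK_TIERS: dict[str, str] = {
    "trichloroethylene": "definite",
    "organic solvents": "definite",
    "anorexigens": "definite",
    "asbestos": "possible",
    "tramadol": "possible",
    "opioids": "possible",
}

_TIER_ORDER = {"definite": 0, "possible": 1}


@dataclass(frozen=True, slots=True)
class SharedExposure:
    substance: str
    risk_tier: str
    affected_ids: tuple[str, ...]


def _normalize(substance: str, synonyms: dict[str, str]) -> str:
    s = " ".join(substance.strip().lower().split())
    return synonyms.get(s, s)


def shared_exposure_screen(
    ped: Pedigree,
    synonyms: dict[str, str] | None = None,
    risk_tiers: dict[str, str] | None = None,
) -> list[SharedExposure]:
    """Substances reported by every affected and by no unaffected individual.

    Returns an empty list when any affected individual has no exposure
    data at all (the screen cannot establish a shared exposure without
    complete responses). Output is ordered by risk tier (definite before
    possible) and then substance name.
    """
    if not ped.affected:
        raise ValidationError(f"family {ped.family_id} has no affected individual")
    syn = dict(DEFAULT_SYNONYMS)
    if synonyms:
        syn.update({_normalize(k, {}): _normalize(v, {}) for k, v in synonyms.items()})
    tiers = dict(DEFAULT_RISK_TIERS)
    if risk_tiers:
        tiers.update({_normalize(k, syn): v for k, v in risk_tiers.items()})

    per_affected: dict[str, set[str]] = {}
    explicit_tiers: dict[str, str] = {}
    for ind in ped.affected:
        if not ind.exposures:
            return []
        subs = set()
        for exp in ind.exposures:
            name = _normalize(exp.substance, syn)
            subs.add(name)
            if exp.risk_tier is not None:
                explicit_tiers[name] = exp.risk_tier
        per_affected[ind.id] = subs

    shared = set.intersection(*per_affected.values())
    for ind in ped.unaffected:
        shared -= {_normalize(exp.substance, syn) for exp in ind.exposures}

    affected_ids = tuple(ind.id for ind in ped.affected)
    out = [
        SharedExposure(s, explicit_tiers.get(s) or tiers.get(s, "possible"), affected_ids)
        for s in shared
    ]
    out.sort(key=lambda e: (_TIER_ORDER.get(e.risk_tier, 2), e.substance))
    return out
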