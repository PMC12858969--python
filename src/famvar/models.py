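"""Core domain types: variants, annotations, genotypes, pedigrees, exposures.

Coordinates follow the 1-based VCF convention and inputs are assumed to be
left-aligned and bi-allelic (multi-allelic sites must be split upstream).
Missing annotation values are represented as ``None`` and are never coerced
to zero: "absent from gnomAD" is a distinct, meaningful state that the
frequency filter and the PM2 criterion interpret as zero *observations*,
not as an allele frequency of zero entered in the data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import StructuralError, ValidationError

# ---------------------------------------------------------------------------
# Consequence vocabulary (Sequence Ontology terms)
# ---------------------------------------------------------------------------

#: Loss-of-function consequences that predict a null allele outright.
NULL_CONSEQUENCES = frozenset({"stop_gained", "frameshift_variant"})

#: Canonical splice-site terms (donor/acceptor, the +/-1,2 dinucleotides).
CANONICAL_SPLICE_TERMS = frozenset({"splice_donor_variant", "splice_acceptor_variant"})

#: All splice-proximal terms the in-silico stage scores with SpliceAI.
SPLICE_SITE_TERMS = CANONICAL_SPLICE_TERMS | {"splice_region_variant"}

#: Promoter/regulatory terms, only retained for whitelisted genes.
PROMOTER_TERMS = frozenset({"regulatory_region_variant", "promoter_variant"})

#: Consequences with "possible functional consequences" kept by default:
#: nonsense, frameshift, in-frame indels, splice site and missense.
DEFAULT_KEPT_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "missense_variant",
    }
    | SPLICE_SITE_TERMS
)

#: Closed controlled vocabulary for :attr:`VariantRecord.consequence`.
CONSEQUENCE_VOCABULARY = frozenset(
    DEFAULT_KEPT_CONSEQUENCES
    | PROMOTER_TERMS
    | {
        "synonymous_variant",
        "intron_variant",
        "intergenic_variant",
        "non_coding_transcript_variant",
        "non_coding_transcript_exon_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
    }
)


class Zygosity(enum.Enum):
    """Per-individual genotype call for a single alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries(self) -> bool:
        """True if at least one alternate allele is present."""
        return self in (Zygosity.HET, Zygosity.HOM_ALT)


#: Alias used in signatures where the call, not the enum, is meant.
GenotypeCall = Zygosity


@dataclass(slots=True)
class AnnotationProfile:
    """Population frequencies and in-silico scores attached to one allele.

    ``gnomad_af_overall`` is the total minor allele frequency in the primary
    gnomAD release; ``gnomad_subpop_af_max`` the highest allele frequency
    among control subpopulations with at least 1000 alleles. ``None`` means
    the value was not observed/reported ("absent"), which downstream logic
    treats as zero observations, never as a measured frequency of zero.
    """

    gnomad_af_overall: float | None = None
    gnomad_ac: int | None = None
    gnomad_subpop_af_max: float | None = None
    inhouse_ac: int | None = None
    cadd_phred: float | None = None
    revel: float | None = None
    spliceai_delta_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("gnomad_af_overall", "gnomad_subpop_af_max", "revel", "spliceai_delta_max"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("gnomad_ac", "inhouse_ac"):
            v = getattr(self, name)
            if v is not None and (v < 0 or int(v) != v):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"cadd_phred must be non-negative, got {self.cadd_phred!r}")

    def max_af(self) -> float | None:
        """Highest of the overall and subpopulation-maximum frequencies.

        Returns ``None`` when both are missing (the allele was never
        observed in the population reference).
        """
        afs = [v for v in (self.gnomad_af_overall, self.gnomad_subpop_af_max) if v is not None]
        return max(afs) if afs else None


@dataclass(slots=True)
class VariantRecord:
    """One alternate allele in one transcript context.

    A VCF site annotated against several transcripts yields one record per
    (site, alt, transcript) tuple. HGVS strings are opaque labels; the
    machine-readable semantics live in ``consequence`` and ``splice_offset``
    (signed distance into the intron for splice-proximal variants, e.g. +1
    for the first donor base).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: str
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    splice_offset: int | None = None
    annotations: AnnotationProfile = field(default_factory=AnnotationProfile)
    genotypes: dict[str, Zygosity] = field(default_factory=dict)
    qual: float | None = None
    filter_status: str | None = None
    causal: bool = False  # ground-truth marker set by the simulator only

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt must differ at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCE_VOCABULARY:
            raise ValidationError(f"unknown consequence term {self.consequence!r}")

    @property
    def key(self) -> str:
        """Stable allele identifier, independent of transcript context."""
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def label(self) -> str:
        """Human-readable descriptor for reports (HGVS c. if available)."""
        return self.hgvs_c or self.key


# ---------------------------------------------------------------------------
# Pedigree and exposures
# ---------------------------------------------------------------------------


class AffectionStatus(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    #: Reported disease in a relative without medical records or DNA; such
    #: individuals never constrain co-segregation verdicts.
    SUSPECTED = "suspected"
    UNKNOWN = "unknown"


#: Closed questionnaire categories for drug/toxin exposures.
EXPOSURE_CATEGORIES = frozenset(
    {
        "anorexigen",
        "antidepressant",
        "interferon",
        "antiviral",
        "tyrosine-kinase inhibitor",
        "immunosuppressant",
        "herbal",
        "chemical agent",
        "opioid",
        "chemotherapeutic",
        "toxic dust",
        "smoking",
        "hormone therapy",
        "high altitude",
        "other",
    }
)

RISK_TIERS = ("definite", "possible")


@dataclass(slots=True)
class ExposureRecord:
    """A single reported drug or toxin exposure of one individual."""

    substance: str
    category: str = "other"
    risk_tier: str | None = None
    start_age: float | None = None
    end_age: float | None = None

    def __post_init__(self) -> None:
        if self.category not in EXPOSURE_CATEGORIES:
            raise ValidationError(f"unknown exposure category {self.category!r}")
        if self.risk_tier is not None and self.risk_tier not in RISK_TIERS:
            raise ValidationError(f"risk_tier must be one of {RISK_TIERS}, got {self.risk_tier!r}")
        if self.start_age is not None and self.end_age is not None and self.start_age > self.end_age:
            raise ValidationError("start_age must not exceed end_age")


@dataclass(slots=True)
class Individual:
    id: str
    sex: str = "unknown"
    status: AffectionStatus = AffectionStatus.UNKNOWN
    father: str | None = None
    mother: str | None = None
    age_at_diagnosis: float | None = None
    exposures: list[ExposureRecord] = field(default_factory=list)


class Pedigree:
    """A family: named individuals with parent links and affection status.

    Validates id uniqueness, parent resolution and acyclicity on
    construction.
    """

    def __init__(self, family_id: str, individuals: list[Individual]):
        self.family_id = family_id
        self.individuals = list(individuals)
        self._index: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._index:
                raise StructuralError(f"duplicate individual id {ind.id!r} in family {family_id}")
            self._index[ind.id] = ind
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._index:
                    raise StructuralError(
                        f"individual {ind.id!r} references unknown parent {parent!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise StructuralError(f"cyclic parentage involving {iid!r}")
            state[iid] = 0
            ind = self._index[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent)
            state[iid] = 1

        for ind in self.individuals:
            visit(ind.id)

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def individual(self, iid: str) -> Individual:
        try:
            return self._index[iid]
        except KeyError:
            raise StructuralError(f"unknown individual {iid!r} in family {self.family_id}") from None

    @property
    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.status is AffectionStatus.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [i for i in self.individuals if i.status is AffectionStatus.UNAFFECTED]

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.father is None and i.mother is None]
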