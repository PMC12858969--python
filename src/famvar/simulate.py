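"""Synthetic family-exome generator.

Emulates the statistical structure of an annotated whole-exome call set
for a small family with autosomal-dominant disease, at the scale the
filter cascade assumes (~37,000 annotated variants per family), so that
every downstream stage can be exercised without access-controlled data.

What is modeled per background variant: a population allele frequency
drawn from a three-part mixture (a small "absent from gnomAD" mass, a
log-uniform rare tail, and a common bulk), allele counts consistent with
that frequency, a consequence drawn from exome-plausible proportions, and
in-silico scores (CADD, REVEL, SpliceAI) conditional on consequence.
Founder genotypes are drawn per variant with one designated carrier
founder (the table contains only variants actually called in the family)
and transmitted to offspring by Mendelian sampling of one parental allele
each. An optional causal profile is implanted with strict AD genotypes:
heterozygous in every affected, absent in genotyped unaffecteds (with an
optional configured non-penetrant carrier), and a ground-truth marker for
recovery scoring.

Not modeled: linkage/haplotype structure, sequencing error, genotype
quality, relatedness beyond the declared pedigree, and any realism the
filters do not consume.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .models import (
    AffectionStatus,
    AnnotationProfile,
    ExposureRecord,
    Individual,
    Pedigree,
    VariantRecord,
    Zygosity,
)

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class FamilyMemberSpec:
    id: str
    sex: str = "unknown"
    status: str = "unaffected"  # affected | unaffected | suspected | unknown
    father: str | None = None
    mother: str | None = None
    genotyped: bool = True


#: Three-generation template mirroring a mother/daughter disease pair with
#: a healthy genotyped granddaughter; spouses are untyped married-in founders.
DEFAULT_FAMILY_TEMPLATE: tuple[FamilyMemberSpec, ...] = (
    FamilyMemberSpec("I:1", "male", "unaffected", genotyped=False),
    FamilyMemberSpec("I:2", "female", "affected"),
    FamilyMemberSpec("II:1", "male", "unaffected", genotyped=False),
    FamilyMemberSpec("II:2", "female", "affected", father="I:1", mother="I:2"),
    FamilyMemberSpec("III:1", "female", "unaffected", father="II:1", mother="II:2"),
)


#: Father/son disease pair (the occupational-exposure duo); the mother is
#: an untyped married-in founder.
FAMILY4_TEMPLATE: tuple[FamilyMemberSpec, ...] = (
    FamilyMemberSpec("II:1", "male", "affected"),
    FamilyMemberSpec("II:2", "female", "unaffected", genotyped=False),
    FamilyMemberSpec("III:1", "male", "affected", father="II:1", mother="II:2"),
)

#: Three brothers, two affected, one healthy (the paint-factory siblings).
FAMILY5_TEMPLATE: tuple[FamilyMemberSpec, ...] = (
    FamilyMemberSpec("I:1", "male", "unknown", genotyped=False),
    FamilyMemberSpec("I:2", "female", "unknown", genotyped=False),
    FamilyMemberSpec("II:1", "male", "affected", father="I:1", mother="I:2"),
    FamilyMemberSpec("II:2", "male", "affected", father="I:1", mother="I:2"),
    FamilyMemberSpec("II:3", "male", "unaffected", father="I:1", mother="I:2"),
)


@dataclass(frozen=True, slots=True)
class CausalProfile:
    """Annotation profile of the variant to implant, plus its locus."""

    gene: str
    consequence: str
    chrom: str = "16"
    pos: int = 88643400
    ref: str = "C"
    alt: str = "G"
    hgvs_c: str | None = None
    splice_offset: int | None = None
    gnomad_af: float | None = None
    gnomad_ac: int | None = None
    gnomad_subpop_af_max: float | None = None
    inhouse_ac: int | None = 0
    cadd_phred: float | None = None
    revel: float | None = None
    spliceai_delta_max: float | None = None
    #: id of one unaffected individual to make a non-penetrant carrier.
    nonpenetrant_carrier: str | None = None


# Profiles shaped like the three reported candidate variants.
CYBA_LIKE = CausalProfile(
    gene="CYBA", consequence="splice_donor_variant", chrom="16", pos=88643400,
    ref="C", alt="G", hgvs_c="c.203+1G>C", splice_offset=1, spliceai_delta_max=0.98,
)
FKBP1A_LIKE = CausalProfile(
    gene="FKBP1A", consequence="missense_variant", chrom="20", pos=1374218,
    ref="C", alt="G", hgvs_c="c.300C>G", revel=0.73, cadd_phred=23.5,
)
NPR2_LIKE = CausalProfile(
    gene="NPR2", consequence="missense_variant", chrom="9", pos=35800314,
    ref="C", alt="T", hgvs_c="c.934C>T", gnomad_af=0.000002, revel=0.558, cadd_phred=25.0,
)
PTGR2_LIKE = CausalProfile(
    gene="PTGR2", consequence="splice_donor_variant", chrom="14", pos=74069586,
    ref="G", alt="C", hgvs_c="c.37+1G>C", splice_offset=1,
    gnomad_af=0.000021, spliceai_delta_max=0.99,
)

#: Named exposure scenarios mirroring the two occupational-exposure families:
#: a father/son pair sharing trichloroethylene, asbestos dust and tramadol,
#: and a sibling pair from the same paint factory sharing organic solvents
#: against an unexposed healthy brother.
EXPOSURE_SCENARIOS: dict[str, dict[str, list[ExposureRecord]]] = {
    "family4": {
        "II:1": [
            ExposureRecord("trichloroethylene", "chemical agent", start_age=46, end_age=56),
            ExposureRecord("asbestos dust", "toxic dust", start_age=46, end_age=56),
            ExposureRecord("tramadol", "opioid", start_age=52, end_age=53),
        ],
        "III:1": [
            ExposureRecord("trichloroethylene", "chemical agent", start_age=16, end_age=23),
            ExposureRecord("asbestos dust", "toxic dust", start_age=23, end_age=26),
            ExposureRecord("tramadol", "opioid", start_age=42),
        ],
    },
    "family5": {
        "II:1": [
            ExposureRecord("organic solvents", "chemical agent", start_age=28, end_age=55),
            ExposureRecord("toxic dust", "toxic dust", start_age=28, end_age=55),
        ],
        "II:2": [
            ExposureRecord("organic solvents", "chemical agent", start_age=29, end_age=52),
        ],
        "II:3": [],
    },
}

#: Exome-plausible consequence proportions for annotated calls. These are
#: configuration, not estimates of any particular data set.
DEFAULT_CONSEQUENCE_MIX: dict[str, float] = {
    "missense_variant": 0.3455,
    "synonymous_variant": 0.28,
    "intron_variant": 0.25,
    "splice_region_variant": 0.03,
    "non_coding_transcript_variant": 0.05,
    "regulatory_region_variant": 0.02,
    "inframe_insertion": 0.0105,
    "inframe_deletion": 0.01,
    "stop_gained": 0.0015,
    "frameshift_variant": 0.0015,
    "splice_donor_variant": 0.0005,
    "splice_acceptor_variant": 0.0005,
}


@dataclass(frozen=True, slots=True)
class SimulationSpec:
    seed: int
    n_families: int = 1
    family_template: tuple[FamilyMemberSpec, ...] = DEFAULT_FAMILY_TEMPLATE
    background_variant_count: int = 37_000
    #: AF mixture masses; the remainder is the common bulk.
    af_absent_mass: float = 0.003
    af_rare_mass: float = 0.05
    rare_af_range: tuple[float, float] = (1e-6, 1e-2)
    common_af_range: tuple[float, float] = (0.01, 0.5)
    #: Reference-cohort allele numbers used to derive allele counts.
    gnomad_total_alleles: int = 152_000
    inhouse_total_alleles: int = 20_000
    consequence_mix: tuple[tuple[str, float], ...] = tuple(DEFAULT_CONSEQUENCE_MIX.items())
    causal_profile: CausalProfile | None = None
    exposure_scenario: str | None = None

    def __post_init__(self) -> None:
        if self.background_variant_count <= 0 or self.n_families <= 0:
            raise ConfigurationError("counts must be positive")
        if self.af_absent_mass < 0 or self.af_rare_mass < 0:
            raise ConfigurationError("mixture masses must be non-negative")
        if self.af_absent_mass + self.af_rare_mass > 1:
            raise ConfigurationError("AF mixture masses must sum to at most 1")
        total = sum(p for _, p in self.consequence_mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"consequence proportions must sum to 1, got {total}")
        if self.exposure_scenario is not None and self.exposure_scenario not in EXPOSURE_SCENARIOS:
            raise ConfigurationError(f"unknown exposure scenario {self.exposure_scenario!r}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_CHROMS = [str(i) for i in range(1, 23)] + ["X"]
_BASES = np.array(list("ACGT"))
_ZYG_LOOKUP = (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)


def _build_pedigree(spec: SimulationSpec, family_id: str) -> Pedigree:
    individuals = [
        Individual(
            id=m.id, sex=m.sex, status=AffectionStatus(m.status),
            father=m.father, mother=m.mother,
        )
        for m in spec.family_template
    ]
    return Pedigree(family_id, individuals)


def _gene_pool(rng: np.random.Generator, size: int) -> np.ndarray:
    """Plausible-looking gene symbols: 3-5 letters plus an optional digit."""
    letters = np.array(list(string.ascii_uppercase))
    lengths = rng.integers(3, 6, size=size)
    chars = letters[rng.integers(0, 26, size=(size, 5))]
    digits = rng.integers(0, 10, size=size)
    with_digit = rng.random(size) < 0.3
    symbols = []
    for i in range(size):
        s = "".join(chars[i, : lengths[i]])
        if with_digit[i]:
            s += str(digits[i])
        symbols.append(s)
    return np.array(symbols)


def simulate_family(
    spec: SimulationSpec,
    family_id: str = "FAM1",
    rng: np.random.Generator | None = None,
) -> tuple[Pedigree, list[VariantRecord]]:
    """Simulate one family: pedigree plus annotated variant table.

    Fully reproducible from the spec seed. Background genotypes are
    Mendelian-consistent by construction; the optional causal variant is
    implanted with strict autosomal-dominant genotypes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ped = _build_pedigree(spec, family_id)
    if spec.causal_profile is not None and not ped.affected:
        raise ConfigurationError("causal profile requires at least one affected individual")

    n = spec.background_variant_count
    members = list(spec.family_template)
    member_ids = [m.id for m in members]
    founders = [m.id for m in members if m.father is None and m.mother is None]

    # --- loci ---
    chrom_idx = np.sort(rng.integers(0, len(_CHROMS), size=n), kind="stable")
    pos = rng.integers(10_000, 240_000_000, size=n)
    order = np.lexsort((pos, chrom_idx))
    chrom_idx, pos = chrom_idx[order], pos[order]
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    genes = _gene_pool(rng, max(n // 8, 1))[rng.integers(0, max(n // 8, 1), size=n)]

    # --- consequences ---
    terms = [t for t, _ in spec.consequence_mix]
    probs = np.array([p for _, p in spec.consequence_mix])
    cons_idx = rng.choice(len(terms), size=n, p=probs / probs.sum())
    consequences = np.array(terms, dtype=object)[cons_idx]

    # --- allele frequencies and counts ---
    p_common = 1.0 - spec.af_absent_mass - spec.af_rare_mass
    af_class = rng.choice(3, size=n, p=[spec.af_absent_mass, spec.af_rare_mass, p_common])
    af = np.zeros(n)
    rare = af_class == 1
    lo, hi = spec.rare_af_range
    af[rare] = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=int(rare.sum()))
    common = af_class == 2
    clo, chi = spec.common_af_range
    af[common] = rng.uniform(clo, chi, size=int(common.sum()))
    absent = af_class == 0
    gnomad_ac = np.maximum(np.rint(af * spec.gnomad_total_alleles), 1).astype(int)
    # subpopulation maxima scatter around the overall frequency; reported
    # for about half of the observed alleles
    subpop_factor = np.exp(rng.normal(0.1, 0.4, size=n))
    subpop = np.minimum(af * subpop_factor, 1.0)
    has_subpop = (~absent) & (rng.random(n) < 0.5)
    inhouse_ac = rng.poisson(np.where(absent, 0.05, af * spec.inhouse_total_alleles))

    # --- in-silico scores conditional on consequence ---
    is_missense = consequences == "missense_variant"
    is_canon_splice = np.isin(consequences, ["splice_donor_variant", "splice_acceptor_variant"])
    is_splice_region = consequences == "splice_region_variant"
    cadd = rng.gamma(2.0, 5.0, size=n)  # heavy right tail, most mass below 15
    revel = rng.beta(1.2, 3.5, size=n)
    sai = np.zeros(n)
    sai[is_canon_splice] = rng.beta(6.0, 2.0, size=int(is_canon_splice.sum()))
    sai[is_splice_region] = rng.beta(1.2, 8.0, size=int(is_splice_region.sum()))
    splice_offset = np.zeros(n, dtype=int)
    splice_offset[is_canon_splice] = rng.integers(1, 3, size=int(is_canon_splice.sum()))
    splice_offset[is_splice_region] = rng.integers(3, 9, size=int(is_splice_region.sum()))
    is_acceptor = consequences == "splice_acceptor_variant"
    splice_offset[is_acceptor] *= -1

    # --- genotypes: designated carrier founder, then Mendelian transmission ---
    carrier_founder = rng.integers(0, len(founders), size=n)
    alleles: dict[str, np.ndarray] = {}
    for fi, fid in enumerate(founders):
        a = (rng.random((n, 2)) < af[:, None]).astype(np.int8)
        a[carrier_founder == fi, 0] = 1
        alleles[fid] = a
    for m in members:
        if m.father is None:
            continue
        pick_f = rng.integers(0, 2, size=n)
        pick_m = rng.integers(0, 2, size=n)
        child = np.empty((n, 2), dtype=np.int8)
        child[:, 0] = alleles[m.father][np.arange(n), pick_f]
        child[:, 1] = alleles[m.mother][np.arange(n), pick_m]
        alleles[m.id] = child

    genotyped = [m.id for m in members if m.genotyped]
    zyg_cols = {mid: alleles[mid].sum(axis=1).tolist() for mid in genotyped}

    # --- assemble records ---
    chroms = [_CHROMS[i] for i in chrom_idx.tolist()]
    pos_l = pos.tolist()
    ref_l = _BASES[ref_idx].tolist()
    alt_l = _BASES[alt_idx].tolist()
    genes_l = genes.tolist()
    cons_l = consequences.tolist()
    af_l = af.tolist()
    absent_l = absent.tolist()
    gnomad_ac_l = gnomad_ac.tolist()
    subpop_l = subpop.tolist()
    has_subpop_l = has_subpop.tolist()
    inhouse_l = inhouse_ac.tolist()
    cadd_l = np.round(cadd, 3).tolist()
    revel_l = np.round(np.clip(revel, 0, 1), 3).tolist()
    sai_l = np.round(np.clip(sai, 0, 1), 3).tolist()
    offset_l = splice_offset.tolist()
    is_missense_l = is_missense.tolist()
    splicey_l = (is_canon_splice | is_splice_region).tolist()
    geno_lists = [(mid, zyg_cols[mid]) for mid in genotyped]

    records: list[VariantRecord] = []
    for i in range(n):
        cons = cons_l[i]
        if absent_l[i]:
            prof = AnnotationProfile(
                inhouse_ac=inhouse_l[i],
                cadd_phred=cadd_l[i],
                revel=revel_l[i] if is_missense_l[i] else None,
                spliceai_delta_max=sai_l[i] if splicey_l[i] else None,
            )
        else:
            prof = AnnotationProfile(
                gnomad_af_overall=af_l[i],
                gnomad_ac=gnomad_ac_l[i],
                gnomad_subpop_af_max=subpop_l[i] if has_subpop_l[i] else None,
                inhouse_ac=inhouse_l[i],
                cadd_phred=cadd_l[i],
                revel=revel_l[i] if is_missense_l[i] else None,
                spliceai_delta_max=sai_l[i] if splicey_l[i] else None,
            )
        ref, alt = ref_l[i], alt_l[i]
        if cons == "frameshift_variant" or cons == "inframe_insertion":
            alt = ref + ("T" if cons == "frameshift_variant" else "TTT")
        elif cons == "inframe_deletion":
            ref = ref + "AGT"
            alt = ref[0]
        records.append(
            VariantRecord(
                chrom=chroms[i], pos=pos_l[i], ref=ref, alt=alt, gene=genes_l[i],
                transcript=f"TX{i:06d}", consequence=cons,
                splice_offset=offset_l[i] if splicey_l[i] else None,
                annotations=prof,
                genotypes={mid: _ZYG_LOOKUP[col[i]] for mid, col in geno_lists},
            )
        )

    if spec.causal_profile is not None:
        records = implant_causal_variant(records, ped, spec.causal_profile)

    if spec.exposure_scenario is not None:
        for iid, exps in EXPOSURE_SCENARIOS[spec.exposure_scenario].items():
            if iid in ped:
                ped.individual(iid).exposures.extend(exps)

    return ped, records


def implant_causal_variant(
    vs: list[VariantRecord], ped: Pedigree, profile: CausalProfile
) -> list[VariantRecord]:
    """Add one causal record with autosomal-dominant genotypes.

    Heterozygous in every affected individual, homozygous reference in
    genotyped unaffecteds (except an optionally configured non-penetrant
    carrier), marked with the ground-truth ``causal`` flag. The record is
    appended; input records are not modified.
    """
    if not profile.gene:
        raise ConfigurationError("causal profile must name a gene")
    if not ped.affected:
        raise ConfigurationError("cannot implant a causal variant without affected individuals")
    genotypes: dict[str, Zygosity] = {}
    for ind in ped:
        if ind.status is AffectionStatus.AFFECTED:
            genotypes[ind.id] = Zygosity.HET
        elif ind.id == profile.nonpenetrant_carrier:
            genotypes[ind.id] = Zygosity.HET
        elif ind.status is AffectionStatus.UNAFFECTED:
            genotypes[ind.id] = Zygosity.HOM_REF
    # restrict to members that are genotyped in the background table, when known
    typed: set[str] = set()
    for v in vs[:50]:
        typed.update(v.genotypes)
    if typed:
        affected_ids = {i.id for i in ped.affected}
        genotypes = {k: g for k, g in genotypes.items() if k in typed or k in affected_ids}
    causal = VariantRecord(
        chrom=profile.chrom, pos=profile.pos, ref=profile.ref, alt=profile.alt,
        gene=profile.gene, transcript=f"TX_{profile.gene}",
        consequence=profile.consequence, hgvs_c=profile.hgvs_c,
        splice_offset=profile.splice_offset,
        annotations=AnnotationProfile(
            gnomad_af_overall=profile.gnomad_af,
            gnomad_ac=profile.gnomad_ac,
            gnomad_subpop_af_max=profile.gnomad_subpop_af_max,
            inhouse_ac=profile.inhouse_ac,
            cadd_phred=profile.cadd_phred,
            revel=profile.revel,
            spliceai_delta_max=profile.spliceai_delta_max,
        ),
        genotypes=genotypes,
        causal=True,
    )
    return vs + [causal]


# ---------------------------------------------------------------------------
# Cohorts on disk
# ---------------------------------------------------------------------------


def family_seeds(seed: int, n_families: int) -> list[int]:
    """Independent, reproducible per-family seeds derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_families)]


def generate_cohort(spec: SimulationSpec, out_dir: str | Path) -> Path:
    """Write a cohort to disk: per-family VCF + PED (+ exposure CSV), plus
    a JSON-lines manifest recording paths and ground-truth causal keys.

    Returns the manifest path. Byte-identical across runs for a fixed spec.
    """
    from .io import write_annotated_vcf, write_pedigree  # local import, avoids cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.jsonl"
    seeds = family_seeds(spec.seed, spec.n_families)
    with open(manifest_path, "w") as mf:
        for k, fam_seed in enumerate(seeds, start=1):
            family_id = f"FAM{k}"
            ped, records = simulate_family(
                spec, family_id=family_id, rng=np.random.default_rng(fam_seed)
            )
            vcf_path = out_dir / f"{family_id}.vcf"
            ped_path = out_dir / f"{family_id}.ped"
            samples = [m.id for m in spec.family_template if m.genotyped]
            write_annotated_vcf(records, vcf_path, samples=samples)
            write_pedigree(ped, ped_path)
            entry = {
                "family_id": family_id,
                "vcf": vcf_path.name,
                "ped": ped_path.name,
                "exposures": None,
                "causal": records[-1].key if spec.causal_profile is not None else None,
            }
            if spec.exposure_scenario is not None:
                exp_path = out_dir / f"{family_id}.exposures.csv"
                _write_exposure_csv(spec.exposure_scenario, exp_path)
                entry["exposures"] = exp_path.name
            mf.write(json.dumps(entry, sort_keys=True) + "\n")
    return manifest_path


def _write_exposure_csv(scenario: str, path: Path) -> None:
    lines = ["individual_id,substance,category,start_age,end_age"]
    for iid, exps in EXPOSURE_SCENARIOS[scenario].items():
        for e in exps:
            start = "" if e.start_age is None else f"{e.start_age:g}"
            end = "" if e.end_age is None else f"{e.end_age:g}"
            lines.append(f"{iid},{e.substance},{e.category},{start},{end}")
    path.write_text("\n".join(lines) + "\n")


def spec_with(spec: SimulationSpec, **kwargs) -> SimulationSpec:
    """Convenience: a modified copy of a spec."""
    return replace(spec, **kwargs)
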