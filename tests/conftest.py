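import pytest

from famvar import (
    AffectionStatus,
    AnnotationProfile,
    Individual,
    Pedigree,
    PipelineConfig,
    VariantRecord,
    Zygosity,
)


def make_variant(
    consequence="missense_variant",
    gene="GENE1",
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    splice_offset=None,
    genotypes=None,
    **annotations,
):
    """Terse variant factory; annotation kwargs go to AnnotationProfile."""
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        transcript="TX1",
        consequence=consequence,
        splice_offset=splice_offset,
        annotations=AnnotationProfile(**annotations),
        genotypes=genotypes or {},
    )


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def table2_variants():
    """The four published candidate variants, built from their printed
    annotations (consequence, population frequency, in-silico scores)."""
    return {
        "CYBA": make_variant(
            "splice_donor_variant", gene="CYBA", chrom="16", pos=88643400, ref="C", alt="G",
            splice_offset=1, spliceai_delta_max=0.98,
        ),
        "NPR2": make_variant(
            "missense_variant", gene="NPR2", chrom="9", pos=35800314, ref="C", alt="T",
            gnomad_af_overall=0.000002, revel=0.558, cadd_phred=25.0,
        ),
        "FKBP1A": make_variant(
            "missense_variant", gene="FKBP1A", chrom="20", pos=1374218, ref="C", alt="G",
            revel=0.73, cadd_phred=23.5,
        ),
        "PTGR2": make_variant(
            "splice_donor_variant", gene="PTGR2", chrom="14", pos=74069586, ref="G", alt="C",
            splice_offset=1, gnomad_af_overall=0.000021, spliceai_delta_max=0.99,
        ),
    }


@pytest.fixture
def family1_pedigree():
    """Affected mother and daughter, healthy genotyped granddaughter."""
    return Pedigree(
        "FAM1",
        [
            Individual("I:1", "male", AffectionStatus.UNKNOWN),
            Individual("I:2", "female", AffectionStatus.AFFECTED),
            Individual("II:1", "male", AffectionStatus.UNKNOWN),
            Individual("II:2", "female", AffectionStatus.AFFECTED, father="I:1", mother="I:2"),
            Individual("III:1", "female", AffectionStatus.UNAFFECTED, father="II:1", mother="II:2"),
        ],
    )


@pytest.fixture
def family1_genotypes():
    return {"I:2": Zygosity.HET, "II:2": Zygosity.HET, "III:1": Zygosity.HOM_REF}
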