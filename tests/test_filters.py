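"""Unit and property tests for the staged filter cascade."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvar import PipelineConfig, apply_cascade
from famvar.errors import ValidationError
from famvar.filters import (
    UNSCORED_FLAG,
    consequence_filter,
    frequency_filter,
    insilico_filter,
    quality_filter,
)
from famvar.models import CONSEQUENCE_VOCABULARY

from conftest import make_variant


class TestFrequencyFilter:
    def test_absent_from_population_passes(self, cfg):
        assert frequency_filter(make_variant(), cfg).passed

    def test_common_allele_fails_with_frequency_reason(self, cfg):
        res = frequency_filter(make_variant(gnomad_af_overall=0.001), cfg)
        assert not res.passed and res.reason == "frequency"

    def test_inclusive_boundaries_pass(self, cfg):
        v = make_variant(gnomad_af_overall=0.0001, gnomad_ac=5, inhouse_ac=5)
        assert frequency_filter(v, cfg).passed

    def test_rare_allele_passes(self, cfg):
        assert frequency_filter(make_variant(gnomad_af_overall=0.000021), cfg).passed

    def test_subpopulation_frequency_counts(self, cfg):
        v = make_variant(gnomad_af_overall=0.00005, gnomad_subpop_af_max=0.002)
        assert not frequency_filter(v, cfg).passed

    @pytest.mark.parametrize("field", ["gnomad_ac", "inhouse_ac"])
    def test_allele_count_caps(self, cfg, field):
        assert not frequency_filter(make_variant(**{field: 6}), cfg).passed
        assert frequency_filter(make_variant(**{field: 5}), cfg).passed


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence, kept",
        [
            ("missense_variant", True),
            ("stop_gained", True),
            ("splice_donor_variant", True),
            ("splice_region_variant", True),
            ("inframe_deletion", True),
            ("synonymous_variant", False),
            ("intron_variant", False),
            ("intergenic_variant", False),
            ("non_coding_transcript_variant", False),
        ],
    )
    def test_functional_consequences_kept(self, cfg, consequence, kept):
        ref, alt = ("AAGT", "A") if consequence == "inframe_deletion" else ("A", "G")
        res = consequence_filter(make_variant(consequence, ref=ref, alt=alt), cfg)
        assert res.passed is kept
        if not kept:
            assert res.reason == "consequence"

    def test_promoter_only_for_whitelisted_gene(self, cfg):
        bmpr2 = make_variant("regulatory_region_variant", gene="BMPR2")
        cyba = make_variant("regulatory_region_variant", gene="CYBA")
        assert consequence_filter(bmpr2, cfg).passed
        assert not consequence_filter(cyba, cfg).passed


class TestInsilicoFilter:
    @pytest.mark.parametrize(
        "kwargs, passed",
        [
            (dict(consequence="missense_variant", cadd_phred=25.0), True),
            (dict(consequence="missense_variant", cadd_phred=15.0), True),
            (dict(consequence="missense_variant", cadd_phred=14.9), False),
            (dict(consequence="splice_donor_variant", splice_offset=1, spliceai_delta_max=0.98), True),
            (dict(consequence="splice_donor_variant", splice_offset=1, spliceai_delta_max=0.4), False),
            (dict(consequence="stop_gained"), True),  # no score required
        ],
    )
    def test_score_gates(self, cfg, kwargs, passed):
        res = insilico_filter(make_variant(**kwargs), cfg)
        assert res.passed is passed
        if not passed:
            assert res.reason == "insilico"

    def test_missing_required_score_passes_flagged(self, cfg):
        res = insilico_filter(make_variant("missense_variant"), cfg)
        assert res.passed and UNSCORED_FLAG in res.flags


class TestQualityGate:
    def test_disabled_by_default(self, cfg):
        v = make_variant()
        v.qual = 3.0
        v.filter_status = "LowQual"
        assert quality_filter(v, cfg).passed
        assert apply_cascade([v], cfg)[1].stages == ("frequency", "consequence", "insilico")

    def test_gate_applies_before_frequency(self):
        cfg = PipelineConfig(qual_min=20.0, require_filter_pass=True)
        bad = make_variant()
        bad.qual = 3.0
        survivors, trace = apply_cascade([bad], cfg)
        assert not survivors and trace.failures[0][0] == "quality"
        assert trace.stages[0] == "quality"


class TestCascade:
    def test_synonymous_only_input_all_dropped(self, cfg):
        vs = [make_variant("synonymous_variant", pos=p) for p in (100, 200, 300)]
        survivors, trace = apply_cascade(vs, cfg)
        assert survivors == []
        assert all(stage == "consequence" for stage, _ in trace.failures.values())

    def test_survivors_preserve_input_order(self, cfg):
        vs = [
            make_variant("missense_variant", pos=500, cadd_phred=20),
            make_variant("synonymous_variant", pos=100),
            make_variant("stop_gained", pos=50),
        ]
        survivors, _ = apply_cascade(vs, cfg)
        assert [v.pos for v in survivors] == [500, 50]

    def test_counts_non_increasing_and_partition(self, cfg):
        vs = [
            make_variant("missense_variant", cadd_phred=20),
            make_variant("missense_variant", cadd_phred=5),
            make_variant("synonymous_variant"),
            make_variant(gnomad_af_overall=0.4),
        ]
        survivors, trace = apply_cascade(vs, cfg)
        counts = [c for _, c in trace.stage_counts()]
        assert counts == sorted(counts, reverse=True)
        assert len(survivors) + len(trace.failures) == len(vs)

    def test_unknown_consequence_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            make_variant("weird_term")


# --- property tests -------------------------------------------------------

optional_fraction = st.one_of(st.none(), st.floats(0, 1, allow_nan=False))
optional_count = st.one_of(st.none(), st.integers(0, 1000))


@st.composite
def variants(draw):
    consequence = draw(st.sampled_from(sorted(CONSEQUENCE_VOCABULARY)))
    offset = None
    if consequence in ("splice_donor_variant", "splice_acceptor_variant", "splice_region_variant"):
        offset = draw(st.integers(-8, 8).filter(lambda x: x != 0))
    return make_variant(
        consequence,
        gene=draw(st.sampled_from(["BMPR2", "CYBA", "GENE1"])),
        pos=draw(st.integers(1, 10**6)),
        splice_offset=offset,
        gnomad_af_overall=draw(optional_fraction),
        gnomad_subpop_af_max=draw(optional_fraction),
        gnomad_ac=draw(optional_count),
        inhouse_ac=draw(optional_count),
        cadd_phred=draw(st.one_of(st.none(), st.floats(0, 60, allow_nan=False))),
        revel=draw(optional_fraction),
        spliceai_delta_max=draw(optional_fraction),
    )


@given(st.lists(variants(), max_size=30))
@settings(derandomize=True, max_examples=60)
def test_cascade_idempotent_and_partitioned(vs):
    cfg = PipelineConfig()
    survivors, trace = apply_cascade(vs, cfg)
    again, trace2 = apply_cascade(survivors, cfg)
    assert again == survivors
    assert not trace2.failures
    assert set(trace.failures).isdisjoint(
        i for i, v in enumerate(vs) if v in survivors
    )
    assert len(survivors) + len(trace.failures) == len(vs)


@given(st.lists(variants(), max_size=30))
@settings(derandomize=True, max_examples=60)
def test_stricter_thresholds_shrink_survivors(vs):
    base = PipelineConfig()
    strict = PipelineConfig(
        maf_max=1e-5, gnomad_ac_max=2, inhouse_ac_max=2,
        cadd_min_missense=25.0, spliceai_min=0.8,
        promoter_whitelist_genes=frozenset(),
    )
    loose_keys = {id(v) for v in apply_cascade(vs, base)[0]}
    strict_keys = {id(v) for v in apply_cascade(vs, strict)[0]}
    assert strict_keys <= loose_keys


@given(variants(), st.lists(variants(), max_size=10))
@settings(derandomize=True, max_examples=60)
def test_verdict_independent_of_batch(v, others):
    cfg = PipelineConfig()
    alone = bool(apply_cascade([v], cfg)[0])
    batched = v in apply_cascade(others + [v] + others, cfg)[0]
    assert alone == batched
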