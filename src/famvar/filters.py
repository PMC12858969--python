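"""Staged rare-variant filter cascade with a per-stage audit trace.

Stage order is fixed: an optional quality pre-gate, then frequency,
consequence and in-silico score stages. Each variant is judged
independently of the rest of the batch; a dropped variant records exactly
one (first) failing stage. On a raw annotated exome of tens of thousands
of calls the default thresholds reduce the list to double-digit counts of
rare candidates per family.

Missing values are fail-safe in both directions that matter: a variant
never seen in the population references passes the frequency stage (zero
observations cannot exceed a frequency bound), and a kept consequence
lacking its required in-silico score is retained with an ``unscored`` flag
rather than silently discarded for an annotation gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import PipelineConfig
from .errors import ValidationError
from .models import (
    CONSEQUENCE_VOCABULARY,
    PROMOTER_TERMS,
    SPLICE_SITE_TERMS,
    VariantRecord,
)

STAGE_QUALITY = "quality"
STAGE_FREQUENCY = "frequency"
STAGE_CONSEQUENCE = "consequence"
STAGE_INSILICO = "insilico"

UNSCORED_FLAG = "unscored"


@dataclass(frozen=True, slots=True)
class StageResult:
    passed: bool
    reason: str | None = None  # stage name of the failure, None when passed
    detail: str | None = None
    flags: tuple[str, ...] = ()


def quality_filter(v: VariantRecord, cfg: PipelineConfig) -> StageResult:
    """Optional pre-gate on the VCF QUAL and FILTER columns."""
    if cfg.qual_min is not None and v.qual is not None and v.qual < cfg.qual_min:
        return StageResult(False, STAGE_QUALITY, f"QUAL {v.qual} < {cfg.qual_min}")
    if cfg.require_filter_pass and v.filter_status not in (None, "PASS", "."):
        return StageResult(False, STAGE_QUALITY, f"FILTER is {v.filter_status!r}")
    return StageResult(True)


def frequency_filter(v: VariantRecord, cfg: PipelineConfig) -> StageResult:
    """Population-rarity gate: AF and allele counts, inclusive bounds.

    The allele frequency tested is the maximum of the overall and the
    subpopulation-maximum fields; a missing value means the allele was not
    observed and passes.
    """
    prof = v.annotations
    af = prof.max_af()
    if af is not None and af > cfg.maf_max:
        return StageResult(False, STAGE_FREQUENCY, f"AF {af:g} > {cfg.maf_max:g}")
    if prof.gnomad_ac is not None and prof.gnomad_ac > cfg.gnomad_ac_max:
        return StageResult(False, STAGE_FREQUENCY, f"gnomAD AC {prof.gnomad_ac} > {cfg.gnomad_ac_max}")
    if prof.inhouse_ac is not None and prof.inhouse_ac > cfg.inhouse_ac_max:
        return StageResult(False, STAGE_FREQUENCY, f"in-house AC {prof.inhouse_ac} > {cfg.inhouse_ac_max}")
    return StageResult(True)


def consequence_filter(v: VariantRecord, cfg: PipelineConfig) -> StageResult:
    """Keep possible functional consequences; promoter only for whitelisted genes."""
    c = v.consequence
    if c not in CONSEQUENCE_VOCABULARY:
        raise ValidationError(f"unknown consequence term {c!r}")
    if c in cfg.kept_consequences:
        return StageResult(True)
    if c in PROMOTER_TERMS and v.gene in cfg.promoter_whitelist_genes:
        return StageResult(True)
    return StageResult(False, STAGE_CONSEQUENCE, f"{c} not retained")


def insilico_filter(v: VariantRecord, cfg: PipelineConfig) -> StageResult:
    """Score gate for kept consequences: CADD for missense, SpliceAI for splice.

    Other kept consequences (nonsense, frameshift, in-frame indels) pass
    unconditionally. A missing required score passes with an ``unscored``
    flag.
    """
    c = v.consequence
    if c == "missense_variant":
        cadd = v.annotations.cadd_phred
        if cadd is None:
            return StageResult(True, flags=(UNSCORED_FLAG,))
        if cadd < cfg.cadd_min_missense:
            return StageResult(False, STAGE_INSILICO, f"CADD {cadd:g} < {cfg.cadd_min_missense:g}")
    elif c in SPLICE_SITE_TERMS:
        sai = v.annotations.spliceai_delta_max
        if sai is None:
            return StageResult(True, flags=(UNSCORED_FLAG,))
        if sai < cfg.spliceai_min:
            return StageResult(False, STAGE_INSILICO, f"SpliceAI {sai:g} < {cfg.spliceai_min:g}")
    return StageResult(True)


@dataclass(slots=True)
class FilterTrace:
    """Audit trail of one cascade run.

    ``counts`` maps each stage name to the number of variants surviving
    it (monotonically non-increasing); ``failures`` maps the input index
    of each dropped variant to its first failing stage and a free-text
    detail; ``flags`` carries advisory marks (e.g. ``unscored``) for
    survivors.
    """

    stages: tuple[str, ...]
    input_count: int
    counts: dict[str, int] = field(default_factory=dict)
    failures: dict[int, tuple[str, str]] = field(default_factory=dict)
    flags: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def stage_counts(self) -> list[tuple[str, int]]:
        out = [("input", self.input_count)]
        out.extend((s, self.counts[s]) for s in self.stages)
        return out


_STAGE_FUNCS = {
    STAGE_QUALITY: quality_filter,
    STAGE_FREQUENCY: frequency_filter,
    STAGE_CONSEQUENCE: consequence_filter,
    STAGE_INSILICO: insilico_filter,
}


def cascade_stages(cfg: PipelineConfig) -> tuple[str, ...]:
    stages = [STAGE_FREQUENCY, STAGE_CONSEQUENCE, STAGE_INSILICO]
    if cfg.qual_min is not None or cfg.require_filter_pass:
        stages.insert(0, STAGE_QUALITY)
    return tuple(stages)


def apply_cascade(
    vs: list[VariantRecord], cfg: PipelineConfig | None = None
) -> tuple[list[VariantRecord], FilterTrace]:
    """Run every variant through the staged cascade.

    Returns the survivors in input order and a :class:`FilterTrace`.
    Survivors and recorded failures partition the input exactly.
    """
    cfg = cfg or PipelineConfig()
    stages = cascade_stages(cfg)
    trace = FilterTrace(stages=stages, input_count=len(vs))
    alive: list[tuple[int, VariantRecord]] = list(enumerate(vs))
    for stage in stages:
        func = _STAGE_FUNCS[stage]
        next_alive: list[tuple[int, VariantRecord]] = []
        for idx, v in alive:
            res = func(v, cfg)
            if res.passed:
                if res.flags:
                    trace.flags[idx] = trace.flags.get(idx, ()) + res.flags
                next_alive.append((idx, v))
            else:
                trace.failures[idx] = (stage, res.detail or stage)
        alive = next_alive
        trace.counts[stage] = len(alive)
    return [v for _, v in alive], trace
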