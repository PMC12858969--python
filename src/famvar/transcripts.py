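"""Transcript-level differential-abundance flagging.

Used to corroborate splice variants with expression data from a single
affected/control pair: log2 fold changes with a pseudocount (so a complete
loss of a transcript stays finite), a one-decimal linear fold-change for
reporting, and a strict |log2 FC| > 1 with adjusted p < 0.05 flagging
rule. No p-values are computed here — a one-vs-one comparison carries no
replication — they are consumed as input columns when an upstream tool
provides them; flags raised without an adjusted p carry an ``unadjusted``
mark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .config import PipelineConfig
from .errors import ValidationError


@dataclass(slots=True)
class TranscriptAbundance:
    """Per-sample abundance (counts or TPM) for one transcript."""

    transcript_id: str
    abundances: dict[str, float] = field(default_factory=dict)
    pvalue: float | None = None
    padj: float | None = None

    def __post_init__(self) -> None:
        for sample, value in self.abundances.items():
            if value < 0:
                raise ValidationError(
                    f"{self.transcript_id}: abundance for {sample!r} must be >= 0, got {value}"
                )
        if self.padj is not None and not 0.0 <= self.padj <= 1.0:
            raise ValidationError(f"{self.transcript_id}: padj must lie in [0, 1]")


def log2_fold_change(case: float, control: float, pseudocount: float = 1.0) -> float:
    """log2((case + pseudocount) / (control + pseudocount))."""
    if case < 0 or control < 0:
        raise ValidationError("abundances must be non-negative")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    return math.log2((case + pseudocount) / (control + pseudocount))


@dataclass(frozen=True, slots=True)
class FoldChange:
    fold: float  # 2**|lfc|, half-up rounded to one decimal
    direction: str  # "up", "down" or "unchanged"

    def __str__(self) -> str:
        return f"{self.fold:.1f}x {self.direction}"


def fold_change_from_log2(lfc: float) -> FoldChange:
    """Linear fold change for report display.

    A log2 change of -1.3 reads as "2.5x down"; +1.9 as "3.7x up".
    Rounding is half-up to one decimal to match conventional reporting.
    """
    fold = float(Decimal(repr(2.0 ** abs(lfc))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    if lfc > 0:
        direction = "up"
    elif lfc < 0:
        direction = "down"
    else:
        direction = "unchanged"
    return FoldChange(fold, direction)


@dataclass(frozen=True, slots=True)
class FlaggedTranscript:
    transcript_id: str
    lfc: float
    fold: FoldChange
    padj: float | None
    unadjusted: bool


def flag_aberrant_transcripts(
    table: list[TranscriptAbundance],
    case_id: str,
    control_id: str,
    cfg: PipelineConfig | None = None,
) -> list[FlaggedTranscript]:
    """Flag transcripts with |log2 FC| above threshold and significant padj.

    Both inequalities are strict. Transcripts without an adjusted p-value
    are flagged on fold change alone, marked ``unadjusted``. Samples other
    than the case and control are ignored.
    """
    cfg = cfg or PipelineConfig()
    flagged: list[FlaggedTranscript] = []
    for t in table:
        for sample in (case_id, control_id):
            if sample not in t.abundances:
                raise ValidationError(f"{t.transcript_id}: unknown sample id {sample!r}")
        lfc = log2_fold_change(t.abundances[case_id], t.abundances[control_id], cfg.pseudocount)
        if abs(lfc) <= cfg.lfc_threshold:
            continue
        if t.padj is not None and not t.padj < cfg.padj_threshold:
            continue
        flagged.append(
            FlaggedTranscript(t.transcript_id, lfc, fold_change_from_log2(lfc), t.padj, t.padj is None)
        )
    return flagged
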