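"""Readers and writers for annotated variants, pedigrees, exposures, reports.

Variants arrive either as VCF 4.x with VEP-style per-transcript annotation
subfields packed into an INFO key (``CSQ``/``ANN``), or as a flat TSV
table. The subfield order is not standardized across annotation runs, so
it is declared explicitly by an :class:`AnnotationDialect`; the canonical
subfield names it maps onto are fixed.

Missing annotation values (empty subfield, ``.``, ``NA``, or the literal
token ``absent`` used for population frequencies) map to ``None`` and are
written back as ``.``, so missingness round-trips and is never conflated
with zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigurationError, ParseError, StructuralError
from .models import (
    AffectionStatus,
    AnnotationProfile,
    ExposureRecord,
    Individual,
    Pedigree,
    VariantRecord,
    Zygosity,
)

#: Canonical annotation subfield names an AnnotationDialect may map onto.
CANONICAL_FIELDS = frozenset(
    {
        "gene",
        "transcript",
        "consequence",
        "hgvs_c",
        "hgvs_p",
        "splice_offset",
        "gnomad_af",
        "gnomad_ac",
        "gnomad_subpop_af_max",
        "inhouse_ac",
        "cadd_phred",
        "revel",
        "spliceai_delta_max",
    }
)

#: Tokens that denote a missing value in annotation subfields and tables.
MISSING_TOKENS = frozenset({"", ".", "na", "nan", "absent", "-"})

_FLOAT_FIELDS = ("gnomad_af", "gnomad_subpop_af_max", "cadd_phred", "revel", "spliceai_delta_max")
_INT_FIELDS = ("gnomad_ac", "inhouse_ac")


@dataclass(frozen=True)
class AnnotationDialect:
    """Declares where per-transcript annotations live and their order.

    ``subfields`` names each ``|``-separated slot in the INFO entry using
    the canonical vocabulary; a ``-`` entry skips a slot.
    """

    info_key: str = "CSQ"
    subfields: tuple[str, ...] = (
        "gene",
        "transcript",
        "consequence",
        "hgvs_c",
        "hgvs_p",
        "splice_offset",
        "gnomad_af",
        "gnomad_ac",
        "gnomad_subpop_af_max",
        "inhouse_ac",
        "cadd_phred",
        "revel",
        "spliceai_delta_max",
    )

    def __post_init__(self) -> None:
        unknown = {f for f in self.subfields if f != "-"} - CANONICAL_FIELDS
        if unknown:
            raise ConfigurationError(f"unknown dialect subfield names: {sorted(unknown)}")
        for required in ("gene", "consequence"):
            if required not in self.subfields:
                raise ConfigurationError(f"dialect must include a {required!r} subfield")


DEFAULT_DIALECT = AnnotationDialect()

_ZYGOSITY_ALIASES = {
    "hom_ref": Zygosity.HOM_REF,
    "het": Zygosity.HET,
    "hom_alt": Zygosity.HOM_ALT,
    "missing": Zygosity.MISSING,
    "0/0": Zygosity.HOM_REF,
    "0|0": Zygosity.HOM_REF,
    "0/1": Zygosity.HET,
    "1/0": Zygosity.HET,
    "0|1": Zygosity.HET,
    "1|0": Zygosity.HET,
    "1/1": Zygosity.HOM_ALT,
    "1|1": Zygosity.HOM_ALT,
    "./.": Zygosity.MISSING,
    ".|.": Zygosity.MISSING,
}


def _is_missing(token: str | None) -> bool:
    return token is None or token.strip().lower() in MISSING_TOKENS


def _parse_float(token: str, context: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{context}: cannot parse {token!r} as a number") from None


def _parse_int(token: str, context: str) -> int:
    try:
        return int(float(token))
    except ValueError:
        raise ParseError(f"{context}: cannot parse {token!r} as an integer") from None


def _build_record(values: dict[str, str | None], chrom, pos, ref, alt, genotypes, qual, filt, context):
    kwargs_float = {}
    for name in _FLOAT_FIELDS:
        tok = values.get(name)
        kwargs_float[name] = None if _is_missing(tok) else _parse_float(tok, context)
    kwargs_int = {}
    for name in _INT_FIELDS:
        tok = values.get(name)
        kwargs_int[name] = None if _is_missing(tok) else _parse_int(tok, context)
    profile = AnnotationProfile(
        gnomad_af_overall=kwargs_float["gnomad_af"],
        gnomad_ac=kwargs_int["gnomad_ac"],
        gnomad_subpop_af_max=kwargs_float["gnomad_subpop_af_max"],
        inhouse_ac=kwargs_int["inhouse_ac"],
        cadd_phred=kwargs_float["cadd_phred"],
        revel=kwargs_float["revel"],
        spliceai_delta_max=kwargs_float["spliceai_delta_max"],
    )
    offset_tok = values.get("splice_offset")
    splice_offset = None if _is_missing(offset_tok) else _parse_int(offset_tok, context)
    return VariantRecord(
        chrom=str(chrom),
        pos=int(pos),
        ref=ref,
        alt=alt,
        gene=values.get("gene") or "",
        transcript="" if _is_missing(values.get("transcript")) else values["transcript"],
        consequence=values["consequence"],
        hgvs_c=None if _is_missing(values.get("hgvs_c")) else values["hgvs_c"],
        hgvs_p=None if _is_missing(values.get("hgvs_p")) else values["hgvs_p"],
        splice_offset=splice_offset,
        annotations=profile,
        genotypes=genotypes,
        qual=qual,
        filter_status=filt,
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_MAP = {0: Zygosity.HOM_REF, 1: Zygosity.HET, 2: Zygosity.MISSING, 3: Zygosity.HOM_ALT}


def read_annotated_vcf(
    path: str | Path, dialect: AnnotationDialect = DEFAULT_DIALECT
) -> list[VariantRecord]:
    """Parse an annotated, bi-allelic VCF into one record per annotation entry.

    Multi-allelic records are rejected (split them upstream). Each entry of
    the declared INFO key yields one :class:`VariantRecord`, so a site
    annotated against N transcripts yields N records sharing genotypes.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.readline()
    if not head.startswith(b"##fileformat=VCF"):
        raise ParseError(f"{path}: not a VCF file (missing ##fileformat header)", line=1)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exception subclasses
        raise ParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for recno, variant in enumerate(vcf, start=1):
        context = f"{path} record {recno} ({variant.CHROM}:{variant.POS})"
        if len(variant.ALT) != 1:
            raise ParseError(f"{context}: multi-allelic record; split alleles upstream")
        raw = variant.INFO.get(dialect.info_key)
        if raw is None:
            raise ParseError(f"{context}: missing INFO field {dialect.info_key!r}")
        genotypes = {
            sample: _GT_TYPE_MAP[gt] for sample, gt in zip(samples, variant.gt_types)
        }
        qual = variant.QUAL
        filt = variant.FILTER  # None means PASS in cyvcf2
        for entry in str(raw).split(","):
            parts = entry.split("|")
            if len(parts) != len(dialect.subfields):
                raise ParseError(
                    f"{context}: annotation entry has {len(parts)} subfields, "
                    f"dialect declares {len(dialect.subfields)}"
                )
            values = {
                name: part for name, part in zip(dialect.subfields, parts) if name != "-"
            }
            if _is_missing(values.get("consequence")):
                raise ParseError(f"{context}: annotation entry lacks a consequence")
            records.append(
                _build_record(
                    values, variant.CHROM, variant.POS, variant.REF, variant.ALT[0],
                    genotypes, qual, filt, context,
                )
            )
    vcf.close()
    return records


_ZYG_TO_GT = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


def _format_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_annotated_vcf(
    records: list[VariantRecord],
    path: str | Path,
    samples: list[str] | None = None,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
) -> None:
    """Write records as an uncompressed annotated VCF (one line per record)."""
    if samples is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.genotypes:
                seen.setdefault(s)
        samples = list(seen)
    contigs: dict[str, None] = {}
    for r in records:
        contigs.setdefault(r.chrom)
    field_map = {
        "gene": "gene", "transcript": "transcript", "consequence": "consequence",
        "hgvs_c": "hgvs_c", "hgvs_p": "hgvs_p", "splice_offset": "splice_offset",
    }
    lines = ["##fileformat=VCFv4.2", "##source=famvar"]
    lines.extend(f"##contig=<ID={c}>" for c in contigs)
    lines.append(
        f'##INFO=<ID={dialect.info_key},Number=.,Type=String,'
        f'Description="Consequence annotations. Format: {"|".join(dialect.subfields)}">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for r in records:
        prof = r.annotations
        values = {
            "gene": r.gene,
            "transcript": r.transcript,
            "consequence": r.consequence,
            "hgvs_c": r.hgvs_c,
            "hgvs_p": r.hgvs_p,
            "splice_offset": r.splice_offset,
            "gnomad_af": prof.gnomad_af_overall,
            "gnomad_ac": prof.gnomad_ac,
            "gnomad_subpop_af_max": prof.gnomad_subpop_af_max,
            "inhouse_ac": prof.inhouse_ac,
            "cadd_phred": prof.cadd_phred,
            "revel": prof.revel,
            "spliceai_delta_max": prof.spliceai_delta_max,
        }
        csq = "|".join(
            "" if name == "-" else _format_value(values.get(name)) for name in dialect.subfields
        )
        qual = "." if r.qual is None else _format_value(r.qual)
        filt = r.filter_status or "PASS"
        gts = "\t".join(_ZYG_TO_GT[r.genotypes.get(s, Zygosity.MISSING)] for s in samples)
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t{filt}\t"
            f"{dialect.info_key}={csq}\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Flat annotation tables (TSV)
# ---------------------------------------------------------------------------

_TSV_MANDATORY = ("chrom", "pos", "ref", "alt", "gene", "consequence")
_GT_PREFIX = "gt:"


def read_annotation_tsv(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[VariantRecord]:
    """Read a flat annotation table with a header row.

    ``column_map`` maps nonstandard file headers onto canonical names
    (``chrom, pos, ref, alt, gene, transcript, consequence, hgvs_c,
    hgvs_p, splice_offset, gnomad_af, gnomad_ac, gnomad_subpop_af_max,
    inhouse_ac, cadd_phred, revel, spliceai_delta_max``). Genotype columns
    are named ``gt:<individual id>`` and hold zygosity words or GT strings.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    for col in _TSV_MANDATORY:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: mandatory column {col!r} missing")
    gt_cols = [c for c in df.columns if c.startswith(_GT_PREFIX)]
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        context = f"{path} line {i}"
        genotypes: dict[str, Zygosity] = {}
        for col in gt_cols:
            tok = row_d[col].strip()
            if not tok:
                continue
            try:
                genotypes[col[len(_GT_PREFIX):]] = _ZYGOSITY_ALIASES[tok.lower()]
            except KeyError:
                raise ParseError(f"{context}: unknown genotype token {tok!r}") from None
        records.append(
            _build_record(
                row_d, row_d["chrom"], _parse_int(row_d["pos"], context), row_d["ref"],
                row_d["alt"], genotypes, None, None, context,
            )
        )
    return records


_TSV_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
    "hgvs_c", "hgvs_p", "splice_offset", "gnomad_af", "gnomad_ac",
    "gnomad_subpop_af_max", "inhouse_ac", "cadd_phred", "revel",
    "spliceai_delta_max",
)


def write_annotation_tsv(records: list[VariantRecord], path: str | Path) -> None:
    """Write records as a flat TSV; missing values become ``.``.

    The inverse of :func:`read_annotation_tsv`: a round trip preserves
    every field including missingness.
    """
    sample_ids: dict[str, None] = {}
    for r in records:
        for s in r.genotypes:
            sample_ids.setdefault(s)
    gt_cols = [f"{_GT_PREFIX}{s}" for s in sample_ids]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(_TSV_COLUMNS) + gt_cols)
        for r in records:
            prof = r.annotations
            row = [
                r.chrom, r.pos, r.ref, r.alt, r.gene, r.transcript or ".", r.consequence,
                r.hgvs_c, r.hgvs_p, r.splice_offset, prof.gnomad_af_overall, prof.gnomad_ac,
                prof.gnomad_subpop_af_max, prof.inhouse_ac, prof.cadd_phred, prof.revel,
                prof.spliceai_delta_max,
            ]
            row = ["." if v is None else (repr(v) if isinstance(v, float) else str(v)) for v in row]
            row.extend(
                r.genotypes[s].value if s in r.genotypes else "" for s in sample_ids
            )
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Pedigrees (PED)
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "male", "2": "female"}
_PED_PHENOTYPE = {
    "2": AffectionStatus.AFFECTED,
    "1": AffectionStatus.UNAFFECTED,
    "0": AffectionStatus.UNKNOWN,
    "-9": AffectionStatus.UNKNOWN,
}


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited PED file into a single-family pedigree.

    Columns: family, individual, father, mother, sex, phenotype, plus an
    optional seventh status word that can override the phenotype code with
    ``suspected`` (reported but unconfirmed disease).
    """
    path = Path(path)
    individuals: list[Individual] = []
    family_id: str | None = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise ParseError(f"{path}: expected >= 6 PED columns, got {len(parts)}", line=lineno)
        fam, iid, father, mother, sex, phenotype = parts[:6]
        if family_id is None:
            family_id = fam
        elif fam != family_id:
            raise ParseError(f"{path}: multiple family ids ({family_id!r}, {fam!r})", line=lineno)
        if phenotype not in _PED_PHENOTYPE:
            raise ParseError(f"{path}: unknown phenotype code {phenotype!r}", line=lineno)
        status = _PED_PHENOTYPE[phenotype]
        if len(parts) >= 7 and parts[6].lower() == "suspected":
            status = AffectionStatus.SUSPECTED
        individuals.append(
            Individual(
                id=iid,
                sex=_PED_SEX.get(sex, "unknown"),
                status=status,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
            )
        )
    if family_id is None:
        raise ParseError(f"{path}: empty pedigree file")
    return Pedigree(family_id, individuals)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    sex_code = {"male": "1", "female": "2"}
    status_code = {
        AffectionStatus.AFFECTED: ("2", ""),
        AffectionStatus.UNAFFECTED: ("1", ""),
        AffectionStatus.UNKNOWN: ("0", ""),
        AffectionStatus.SUSPECTED: ("0", "suspected"),
    }
    lines = []
    for ind in ped:
        code, extra = status_code[ind.status]
        cols = [
            ped.family_id, ind.id, ind.father or "0", ind.mother or "0",
            sex_code.get(ind.sex, "0"), code,
        ]
        if extra:
            cols.append(extra)
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Exposure tables (CSV)
# ---------------------------------------------------------------------------


def read_exposures(path: str | Path) -> dict[str, list[ExposureRecord]]:
    """Read a per-individual exposure CSV.

    Columns: ``individual_id, substance, category, start_age, end_age``
    (ages optional). Returns a map individual id -> exposure records.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("individual_id", "substance", "category"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: mandatory column {col!r} missing")
    out: dict[str, list[ExposureRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        start = d.get("start_age", "")
        end = d.get("end_age", "")
        rec = ExposureRecord(
            substance=d["substance"],
            category=d["category"] or "other",
            start_age=None if _is_missing(start) else float(start),
            end_age=None if _is_missing(end) else float(end),
        )
        out.setdefault(d["individual_id"], []).append(rec)
    return out


def attach_exposures(ped: Pedigree, exposures: dict[str, list[ExposureRecord]]) -> None:
    """Attach exposure records to pedigree individuals in place."""
    for iid, recs in exposures.items():
        if iid not in ped:
            raise StructuralError(f"exposure table references unknown individual {iid!r}")
        ped.individual(iid).exposures.extend(recs)


# ---------------------------------------------------------------------------
# Candidate report
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CandidateReportRow:
    """One line of the per-family candidate report.

    ``kind`` is ``variant`` for classified candidates and
    ``exposure_lead`` for shared-exposure findings; ``note`` carries the
    environmental-exposure-lead annotation for families whose variant
    section is empty.
    """

    family: str
    kind: str
    gene: str = ""
    variant: str = ""
    consequence: str = ""
    annotation_summary: str = ""
    criteria: str = ""
    total: str = ""
    tier: str = ""
    segregation: str = ""
    exposure: str = ""
    note: str = ""


REPORT_COLUMNS = (
    "family", "kind", "gene", "variant", "consequence", "annotation_summary",
    "criteria", "total", "tier", "segregation", "exposure", "note",
)


def write_candidate_report(rows: list[CandidateReportRow], path: str | Path) -> None:
    """Write the report TSV; byte-deterministic for fixed input."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for row in rows:
            writer.writerow([getattr(row, col) for col in REPORT_COLUMNS])
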