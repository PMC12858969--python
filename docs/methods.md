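# Methods

This note documents the models, thresholds and design choices behind
`famvar`, in the order data flows through the package.

## Filter cascade

The cascade operationalizes a staged rarity-and-impact reduction of an
annotated family exome. Stage order is frequency → consequence →
in-silico, optionally preceded by a quality gate.

* **Quality.** "High quality" is not a single published threshold, so
  the gate is configurable and off by default: `qual_min` (VCF QUAL) and
  `require_filter_pass` (FILTER column) can be enabled when raw caller
  output is used. The bundled simulator emits clean calls, so defaults
  leave the gate off.
* **Frequency.** Pass iff max(overall AF, subpopulation-max AF) ≤
  `maf_max` (default 1e-4), gnomAD AC ≤ 5 and in-house AC ≤ 5, each test
  skipped when the value is missing. The maximum over the two AF fields
  is used because candidate vetting considers both the overall and the
  highest qualifying subpopulation frequency. Missing means "never
  observed", which cannot exceed any bound; it is never coerced to 0.0
  as a data value. The in-house count is interpreted as an allele count
  (not carrier count); the choice is documented here because the
  semantics are not externally fixed.
* **Consequence.** The kept set is nonsense, frameshift, in-frame
  indels, splice donor/acceptor/region, missense. Promoter/regulatory
  variants pass only for genes on a whitelist (default {BMPR2}, the gene
  whose promoter variation has established disease relevance in this
  domain). "Splice site" is defined as the three splice SO terms;
  plain `intron_variant` without splice proximity is excluded.
* **In-silico.** Missense: CADD PHRED ≥ 15. Splice terms: SpliceAI
  delta ≥ 0.5. Other kept consequences carry their evidence in the
  consequence itself and pass. A kept consequence lacking its required
  score passes with an `unscored` flag: discarding a candidate because
  an annotator failed to emit a score is the worse failure mode for a
  diagnostic short-list, and the flag keeps the gap visible.

Each variant is judged alone, so survivorship is independent of batch
composition; the trace records the first failing stage only (a variant
fails at most one stage by construction), survivors ∪ failures partition
the input, and stage counts are non-increasing.

## Point-based classification

Criterion strengths map to signed points: supporting ±1, moderate ±2,
strong ±4, very strong ±8; positive = pathogenic, negative = benign.
Four criteria are implemented, which is exactly the evidence available
to a desk analysis of a filtered exome candidate without curated
gene–disease or case–control resources:

* **PVS1** (+8): nonsense, frameshift, or canonical ±1/2 splice-site
  variants. Splice variants additionally require SpliceAI ≥ the splice
  threshold: the annotation alone (a position) is weaker evidence than
  the predictor's judgment, and requiring both keeps PVS1 conservative.
  PVS1 is applied uniformly at very strong; the ClinGen
  strength-modulation decision tree (NMD escape, exon skipping rescue)
  is intentionally not implemented.
* **PM2_supporting** (+1): max AF (missing → 0) strictly < 1e-4
  (0.01%). Note the deliberate asymmetry with the frequency filter,
  which uses an inclusive ≤ on the same quantity: the filter bound and
  the criterion bound are stated with different comparators and both are
  kept exactly as stated.
* **PP3/BP4** (±1): missense only, from REVEL alone (≥ 0.75 / ≤ 0.25).
  CADD gates the cascade but contributes no points — otherwise every
  filter-surviving missense (CADD ≥ 15 by construction) could
  double-dip. Scores in (0.25, 0.75), or missing, yield no criterion.
  When PVS1 applies, PP3 is suppressed: the splice predictor evidence is
  already consumed at very strong, and adding PP3 would count it twice
  (a canonical splice variant absent from the population scores +9, not
  +10 — the difference between likely pathogenic and pathogenic).

Totals band as P ≥ 10, LP 6–9, VUS −1–5, LB −6 to −2, B ≤ −7; the bands
partition the integers and every band edge is tested. An alternative
REVEL banding (≥ 0.75 / ≤ 0.20 with an unassigned gap) circulates in the
literature; the engine exposes both bounds via configuration
(`revel_pathogenic_min`, `revel_benign_max`) and defaults to 0.75/0.25.

## Co-segregation and ranking

Verdicts are computed from the genotype/affection matrix only:
`consistent` (all genotyped affecteds carry, no genotyped unaffected
does), `consistent_reduced_penetrance` (all affecteds carry, ≥ 1
unaffected does), `inconsistent` (any genotyped affected non-carrier),
`uninformative` (< 2 genotyped individuals or no genotyped affected).
Suspected-status relatives (reported disease without records or DNA)
never constrain a verdict — they are exactly the individuals for whom a
segregation claim cannot be made. Reduced penetrance demotes rather than
excludes because non-penetrant carriers are the rule in dominant
pulmonary vascular disease. Segregation is used as a ranking signal
only; no PP1 points are awarded, avoiding a criterion whose strength
depends on meiosis counts the desk analysis cannot verify.

Ranking is a lexicographic total order: tier severity, total points
(desc), segregation verdict (consistent > reduced penetrance >
uninformative > inconsistent), then gene symbol and position as
deterministic tie-breaks.

## Exposure screening

Set logic over normalized substance strings: substances reported by all
affected and no unaffected family members, empty whenever any affected
lacks exposure data (an intersection over incomplete responses would
claim more than the data supports). A small synonym map folds free-text
variants ("paint dust" → organic solvents); risk tiers default to
definite for trichloroethylene, organic solvents and anorexigens and
possible for asbestos and opioids/tramadol, reflecting the strength of
their published associations with PAH/PVOD; both maps are
caller-extensible. No dose–response modeling and no statistical
case–control comparison is attempted — the screen generates leads, not
inference.

## Transcript fold changes

log2((case + c) / (control + c)) with pseudocount c = 1.0 by default, so
a complete transcript loss stays finite. Reported fold changes are
2^|lfc| rounded half-up to one decimal with the sign carried as a
direction word, matching conventional reporting. Flagging uses strict
inequalities (|lfc| > 1, padj < 0.05). For a one-vs-one design no
p-value is computed — there is no replication to estimate dispersion
from — so padj is consumed as an input column when present, and flags
without it carry an `unadjusted` mark.

## Synthetic cohort generator

The generator exists so the full pipeline can be exercised at realistic
scale; its defaults define the benchmark conditions and are not tuned
per test.

* **Scale**: 37,000 background variants per family, the upper end of an
  annotated exome call set.
* **Allele frequencies**: a mixture of a small "absent from gnomAD"
  mass (0.3%), a log-uniform rare tail on [1e-6, 1e-2] (5%), and a
  common bulk uniform on [0.01, 0.5] (94.7%). Allele counts derive from
  the frequency and a 152,000-allele reference cohort; the in-house
  count is Poisson around the frequency scaled to a 20,000-allele
  database. The mixture is chosen so the frequency stage removes the
  large majority of calls and the full cascade leaves low double-digit
  survivors per family (regression-pinned at seed 42: 82 survivors from
  37,001 records, within the reported 30–120 per-family range).
* **Consequences**: exome-plausible proportions (≈35% missense, 28%
  synonymous, 25% intronic, ~3% splice region, ~0.6% predicted-null
  terms). These are configuration constants, not estimates of any
  particular data set.
* **Scores conditional on consequence**: CADD ~ Gamma(2, 5) (≈20% of
  missense clears 15), REVEL ~ Beta(1.2, 3.5) (mostly benign-to-
  intermediate), SpliceAI ~ Beta(6, 2) at canonical splice sites and
  Beta(1.2, 8) at splice-region positions.
* **Genotypes**: each background variant designates one carrier founder
  (the table models variants called in the family, so somebody carries),
  other founder haplotypes are Bernoulli(AF), and offspring receive one
  uniformly chosen allele per parent — Mendelian by construction, which
  the test suite verifies exhaustively at full scale.
* **Causal implantation**: a profile (consequence, offset, frequencies,
  scores, locus) is appended with strict autosomal-dominant genotypes —
  heterozygous in all affecteds, reference in genotyped unaffecteds,
  optionally one configured non-penetrant carrier — and a ground-truth
  marker for recovery scoring.

What the simulator does *not* model: linkage and haplotype structure,
annotation errors, caller artifacts, population stratification,
relatedness beyond the pedigree, and enrichment of deleterious scores
among rare alleles. Consequently, passing recovery benchmarks show that
the pipeline's logic ranks a likely-pathogenic co-segregating variant
above a realistic background — they do not certify performance on real
exomes, where annotation noise dominates.

Recovery benchmarks run in memory (`pipeline.evaluate_recovery`), with
per-family seeds spawned from one seed via `numpy` `SeedSequence`; the
file-based path (`generate_cohort` + `run_cohort`) is exercised at small
scale in the tests. The standard benchmark uses 200 families at the
default 37,000-variant scale; the observed misses are genuine ties —
background predicted-null variants that happen to co-segregate and reach
the same +9/LP/consistent key, resolved lexicographically by gene
symbol.

## Numerical and degenerate-input conventions

* Missingness is `None` end to end; file formats write `.` (or accept
  `absent`) and readers never coerce missing to zero.
* Fold-change rounding is decimal half-up, not binary bankers'
  rounding.
* Multi-allelic VCF records are rejected rather than silently split;
  upstream normalization is assumed and coordinates are 1-based VCF.
* HGVS strings are opaque labels; `consequence` and `splice_offset`
  carry the semantics.
* Empty variant lists, header-only tables and families without
  genotyped members all produce empty-but-valid outputs rather than
  errors; a family with no affected individuals is a validation error
  for the exposure screen (the screen is undefined without cases).
* All randomness flows through a single integer seed; derived seeds are
  kept below 2^31.

## Known limitations

Only four ACMG criteria are scored, so totals are floors: real curation
with functional, case–control or segregation points could only raise
them. The PVS1 strength tree, CNV/SV handling, region-based filtering
and liftover are out of scope. The exposure screen is set logic over
self-reported questionnaires and inherits their recall bias.
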