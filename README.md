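# famvar

Rare-variant prioritization for family exomes with a paired
environmental-exposure screen.

`famvar` is aimed at the work-up of small disease families — the setting
of heritable pulmonary arterial hypertension (HPAH) and similar
dominant, low-penetrance conditions — where gene-panel testing was
negative and whole-exome sequencing of a handful of affected and
unaffected relatives is the next step. It takes annotated variant calls
(VCF with VEP-style subfields, or a flat TSV), a PED pedigree and an
optional exposure questionnaire table, and produces a ranked candidate
report per family. Because an apparently heritable phenotype can also be
produced by a shared occupational exposure, the exposure screen runs
alongside the genetic track and families without surviving variant
candidates but with a substance common to all affected members are
flagged with an environmental-exposure lead.

## What it computes

**Filter cascade.** Annotated exome calls (~37,000 per subject) are
reduced in fixed stages, each variant judged independently:

1. *frequency*: gnomAD allele frequency ≤ 1e-4 (maximum of overall and
   highest-subpopulation AF; absence = pass), gnomAD allele count ≤ 5,
   in-house allele count ≤ 5;
2. *consequence*: keep nonsense, frameshift, in-frame indels, splice
   donor/acceptor/region and missense; promoter/regulatory variants only
   for whitelisted genes (default *BMPR2*); synonymous, intronic,
   intergenic and non-coding variants drop;
3. *in-silico*: missense needs CADD PHRED ≥ 15, splice-site variants
   need a SpliceAI delta ≥ 0.5; a missing required score is retained
   with an `unscored` flag.

A `FilterTrace` records per-stage survivor counts and every variant's
first failing stage.

**Bayesian point-based ACMG/AMP classification.** Criteria carry signed
integer points by strength (supporting ±1, moderate ±2, strong ±4, very
strong ±8). The engine scores PVS1 (+8, predicted null: nonsense,
frameshift, or canonical ±1/2 splice site with SpliceAI support),
PM2_supporting (+1, population frequency strictly < 0.01%, absence
counting as zero observations) and PP3/BP4 (±1, REVEL ≥ 0.75 / ≤ 0.25
for missense; suppressed when PVS1 already consumed the predictor
evidence). Totals band into five classes:

| total  | class |
|--------|-------|
| ≥ 10   | pathogenic (P) |
| 6 … 9  | likely pathogenic (LP) |
| −1 … 5 | uncertain significance (VUS) |
| −6 … −2| likely benign (LB) |
| ≤ −7   | benign (B) |

**Family analysis.** Co-segregation verdicts (`consistent`,
`consistent_reduced_penetrance`, `inconsistent`, `uninformative`) from
the genotype/affection matrix — suspected or unknown-status relatives
never constrain the verdict, and an unaffected carrier demotes rather
than excludes, as expected under reduced penetrance. Candidates are
ranked by class, points, segregation, gene and position. The exposure
screen returns substances reported by *all* affected and *no* unaffected
members, tiered by published risk (e.g. trichloroethylene and organic
solvents as established triggers).

**Transcript corroboration.** Pseudocounted log2 fold changes between
one case and one control sample, reported as one-decimal linear factors
(log2 FC −1.3 → "2.5x down"), flagged when |log2 FC| > 1 with adjusted
p < 0.05.

**Synthetic cohorts.** `famvar.simulate` generates family exomes with
realistic frequency/consequence/score distributions, Mendelian
transmission and an implantable causal profile, so the whole pipeline is
testable and benchmarkable without access-controlled patient data.

## Worked example

```python
from famvar import (AnnotationProfile, VariantRecord, Zygosity,
                    Individual, Pedigree, AffectionStatus)
from famvar.pipeline import run_family
from famvar.io import write_candidate_report

gts = {"I:2": Zygosity.HET, "II:2": Zygosity.HET, "III:1": Zygosity.HOM_REF}
cyba = VariantRecord("16", 88643400, "C", "G", "CYBA", "NM_000101.4",
                     "splice_donor_variant", hgvs_c="c.203+1G>C", splice_offset=1,
                     annotations=AnnotationProfile(spliceai_delta_max=0.98),
                     genotypes=dict(gts))
npr2 = VariantRecord("9", 35800314, "C", "T", "NPR2", "NM_003995.4",
                     "missense_variant", hgvs_c="c.934C>T",
                     annotations=AnnotationProfile(gnomad_af_overall=0.000002,
                                                   revel=0.558, cadd_phred=25.0),
                     genotypes=dict(gts))
ped = Pedigree("FAM1", [
    Individual("I:1", "male", AffectionStatus.UNKNOWN),
    Individual("I:2", "female", AffectionStatus.AFFECTED),
    Individual("II:1", "male", AffectionStatus.UNKNOWN),
    Individual("II:2", "female", AffectionStatus.AFFECTED, father="I:1", mother="I:2"),
    Individual("III:1", "female", AffectionStatus.UNAFFECTED, father="II:1", mother="II:2"),
])
rows, manifest = run_family([npr2, cyba], ped)
write_candidate_report(rows, "report.tsv")
```

`report.tsv` then contains (columns abridged):

```
family  gene  variant      criteria                   total  tier  segregation
FAM1    CYBA  c.203+1G>C   PVS1:+8;PM2_supporting:+1  +9     LP    consistent
FAM1    NPR2  c.934C>T     PM2_supporting:+1          +1     VUS   consistent
```

The canonical splice-donor variant, absent from gnomAD, scores predicted
null (+8) plus rarity (+1) = +9, likely pathogenic; the missense variant
with intermediate REVEL 0.558 earns only the rarity point, a VUS. Both
track with disease across the three genotyped relatives, and the likely
pathogenic candidate ranks first.

The same analyses are scriptable from the shell:

```sh
famvar run --vcf fam1.vcf --ped fam1.ped --out report.tsv
famvar classify --tsv variants.tsv
famvar simulate --seed 3 --n-families 5 --out-dir cohort/
famvar cohort --manifest cohort/manifest.jsonl
famvar rnafc --table transcripts.tsv --case patient --control relative
```

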