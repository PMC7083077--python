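# Methods

## Scope and model

`exosf` models the post-calling stages of a secondary-findings analysis on
a jointly genotyped exome cohort. Read alignment, variant calling,
recalibration and CNV detection are out of scope: the input contract is a
VCF 4.x with per-genotype GT/DP/GQ/AD fields, plus three flat resource
tables (gene panel, variant assertions, variant frequencies). Assertions
and frequencies are consumed as versioned flat tables rather than live
database queries; this makes every run reproducible offline and makes the
annotation step a pure, representation-invariant lookup.

## Variant representation

All coordinates are 1-based on a single build (hg19 for the packaged
panel). Multi-allelic rows are decomposed into biallelic records; per-alt
zygosity is recomputed so that a genotype carrying only *other* alternate
alleles counts as hom_ref for the current alt, and the alt depth comes
from the matching AD entry. Keys are normalized by stripping a leading
`chr`, uppercasing alleles, and trimming shared trailing-then-leading
bases (position-adjusted, keeping one base per allele). Full
left-alignment against the reference sequence is not implemented — it
would require the genome FASTA, and the normalization above already makes
the common padded representations of one event collide on one key. Inputs
whose indels are denormalized by more than padding would need upstream
`bcftools norm`.

## Filter cascade

Stages run in a fixed order (panel → consequence → frequency → assertion →
genotype QC) for reproducible stage-count logs; the four variant-level
stages are pure predicates, so the surviving set is order-invariant (a
tested property). Decomposed alts that no sample carries are not counted
as candidates.

Numerical/boundary choices, with rationale:

| parameter | default | semantics |
|---|---|---|
| frequency threshold | 0.01 | keep iff **every** recorded source is strictly `< 0.01`; sources are open-ended labels, not a hard-coded trio |
| absent frequency record | keep | novel variants have no frequency entry; dropping them would defeat the rare-variant intent |
| min depth (DP) | 15 reads | drop strictly below; DP = 15 passes |
| min genotype quality (GQ) | 20 | drop strictly below; GQ = 20 passes |
| het allele-balance window | [0.30, 0.70] | inclusive on both ends — "between 0.3 and 0.7" read literally; the inclusive endpoints are a documented choice, not an external fact |
| hom-alt ratio bound | > 0.85 | strict, matching "above 0.85"; hemizygous calls use the hom bound |
| missing DP/GQ/AD on a carrier | fail QC | QC exists to remove artifacts; a call whose metrics are unknowable cannot be certified |
| accepted assertions | {pathogenic, likely_pathogenic} | `vus` and `conflicting` are distinct tokens and both fail |

The allele-balance denominator is AD-based (ref reads + alt reads), not
DP, because DP may include uninformative reads.

## Evidence-combining engine

The engine implements the published ACMG-AMP combining criteria verbatim
over evidence-strength counts; fired rules carry stable labels (P.i.a …
LB.ii) for auditability. Strength modification (e.g. PVS1 downgraded to
strong) is unsupported — the curated inputs this package targets never use
it. Conflict handling offers two modes:

* **combination** (default): a side wins only if a combination fires on it
  and none fires on the other side; both sides firing → VUS. A lone
  benign-side code that completes no combination does not veto a
  pathogenic verdict. This is the interpretation consistent with curated
  reference rows that reach *Pathogenic* while carrying a stray BS2 or BP4.
* **strict**: identical verdicts, but any opposite-side code annotates the
  fired rule with `+conflicting_evidence` for review.

The packaged 19-variant reference set contains two rows with the identical
strength multiset {1 PS, 2 PM, 2 PP} but different curated conclusions
(one Pathogenic, one Likely Pathogenic). No combining function of evidence
strengths can reproduce both; the engine grades both *Pathogenic* (rule
P.iii.b), reproducing 18 of the 19 stored conclusions. The discrepancy is
pinned in the test suite rather than special-cased in the engine: curated
archives do contain internally inconsistent rows, and a classifier that
silently bends its rules to match them would be worse than one that flags
them. Downstream analysis is unaffected because the cascade filters on the
stored assertion labels, and both verdicts pass the P/LP filter.

## Reporting rules

Statuses follow the gene's inheritance mode and zygosity (see README).
Compound heterozygotes are detected per (sample, gene): ≥2 distinct het
P/LP variants are presumed biallelic and flagged `phase_unknown`, because
unphased singleton exomes cannot establish trans configuration. Recessive
carriers and XLR het females are excluded from the default clinical report
but kept in the cohort summary (`report_carriers=True` includes them — the
relevant trade-off in populations with high consanguinity). Headline
buckets tally distinct individuals, not findings; an individual carrying
findings of different statuses appears once in the overall total and once
per bucket.

Proportions carry the exact fraction, a percent rounded to two decimals,
and a 2-significant-figure display string; prevalence ratios render
`1:k` with k = round(denominator / count), and fold increases return the
exact ratio alongside a nearest-integer display value (e.g. (1/70)/(1/2500)
= 35.71, display 36).

## Synthetic cohorts

The simulator is the package's test bed and its substitute for
non-shareable patient data. From a spike specification (variant key, gene,
consequence, assertion, evidence codes, carrier count, zygosity) and a
seed it emits a VCF, assertion/frequency tables and a truth table naming
each record's expected fate. Defaults encode the reference cohort
conditions: 280 samples; each of the 19 packaged variants heterozygous in
its recorded number of distinct carriers (24 total, no sample receiving
two spiked variants); spiked DP drawn uniformly in [20, 120] (bracketing a
realistic ~80× mean exome variant depth), GQ in [30, 99], het allele balance
in [0.35, 0.65] — deliberately inside the QC windows, because the fixture
exercises the cascade's logic while boundary behaviour lives in unit
tests. Background records (defaults: 3 too-common P/LP, 4 rare benign —
two sharing one multi-allelic site, 3 VUS/conflicting, 4 failing genotype
QC, 4 off-panel, 2 synonymous) each fail exactly one stage. Background
positions are offsets near the spiked coordinates within each gene; exon
structure is not modelled since consequences are assigned in the
annotation table, not derived from sequence.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: linkage and population structure, relatedness,
strand/alignment artifacts, multi-gene overlapping annotations,
denormalized indel representations beyond padding, and realistic
genome-wide variant density (background is tens of records, not the
thousands a real exome yields in 59 genes; the pre-cascade candidate count
is therefore a log field, not a reproduced statistic).

Determinism: identical (spec, seed) inputs yield byte-identical files; the
analysis path itself is seed-free. Headline counts derive from the spike
spec alone and are invariant to seed and cohort size (verified down to
n = 30); only cohort-denominator proportions change.

## Problem sizes in the test suite

The suite runs the full 280-sample reference cohort once (session fixture),
20 randomized truth-table simulations at 24–120 samples, a brute-force
(variant × sample) oracle comparison on 30 random cohorts of ≤5 samples ×
≤50 variants, and exhaustive engine/oracle agreement over all 4096
evidence multiplicity vectors with ≤3 codes per strength class. The whole
suite completes in well under a minute on one CPU.

## Known limitations

* Sex is not inferred; haploid GTs mark hemizygosity, and an optional
  sample sheet is the intended route for sex-aware XL interpretation.
* HGVS strings are opaque display labels; no syntax validation.
* The frequency filter treats all sources equally; no per-source
  thresholds or popmax logic.
* `conflicting` assertions are store labels, not computed verdicts, so
  `verify-table` reports them as discordant with the engine's VUS — by
  design, since the engine has no "conflicting" tier.
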