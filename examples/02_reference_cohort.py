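"""Run the full secondary-findings pipeline on the reference cohort.

Generates a 280-sample synthetic exome cohort carrying the 19 packaged
pathogenic/likely-pathogenic panel variants (24 carrier individuals, one
finding each) plus adversarial background, then filters it through the
panel / consequence / frequency / assertion / genotype-QC cascade and
prints the cohort summary.  The headline counts (24 individuals, 19
variants, 17 dominant, 7 recessive carriers, 12 genes) are properties of
the spiked variants and therefore independent of the seed.
"""

import tempfile

from exosf import build_reference_fixture, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    paths = build_reference_fixture(n_samples=280, seed=1, out_dir=tmp)
    result = run_pipeline(paths.vcf, paths.assertions, paths.frequencies)

s = result.summary
print(f"cohort size:                  {s.n_cohort}")
print(f"individuals with a finding:   {s.n_individuals_with_finding}")
print(f"distinct P/LP variants:       {s.n_variants_distinct}")
print(f"dominant-reportable:          {s.n_dominant_individuals} "
      f"({s.proportions['dominant_of_cohort']['percent']}% of cohort)")
print(f"recessive carriers:           {s.n_recessive_carrier_individuals} "
      f"({s.proportions['recessive_carrier_of_cohort']['percent']}% of cohort)")
print(f"genes with findings:          {s.n_genes} {s.n_genes_by_inheritance}")
print(f"cardiogenetic individuals:    {s.per_category_individuals['cardiogenetic']}")
print(f"oncogenetic dominant:         {s.per_category_dominant_individuals['oncogenetic']}")
print("per-gene individuals:        ", dict(sorted(
    s.per_gene_individuals.items(), key=lambda kv: (-kv[1], kv[0]))))
print("\nper-stage survivors (variants, carrier genotypes):")
for stage, tallies in result.stage_counts.as_dict().items():
    print(f"  {stage:12s} {tallies['variants']:4d} {tallies['carrier_genotypes']:4d}")
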