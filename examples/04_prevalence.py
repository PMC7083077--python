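"""Cohort prevalence arithmetic for selected disease groups.

Counts carriers of long-QT-syndrome variants (KCNQ1/KCNH2), familial
hypercholesterolemia (LDLR) and recessive disease alleles (MUTYH, ATP7B)
in the reference cohort, renders 1:k prevalence ratios, and compares the
long-QT carrier prevalence against a 1:2500 population estimate.
"""

import tempfile

from exosf import build_reference_fixture, fold_increase, prevalence_ratio, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    paths = build_reference_fixture(n_samples=280, seed=1, out_dir=tmp)
    result = run_pipeline(paths.vcf, paths.assertions, paths.frequencies)

n = result.summary.n_cohort


def carriers(*genes):
    return len({f.sample_id for f in result.findings if f.gene in genes})


for label, genes in [
    ("long-QT (KCNQ1/KCNH2)", ("KCNQ1", "KCNH2")),
    ("familial hypercholesterolemia (LDLR)", ("LDLR",)),
    ("Wilson disease carriers (ATP7B)", ("ATP7B",)),
    ("MUTYH polyposis carriers", ("MUTYH",)),
    ("BRCA1/2", ("BRCA1", "BRCA2")),
]:
    stmt = prevalence_ratio(carriers(*genes), n)
    print(f"{label:40s} {stmt.count}/{stmt.denominator}  ratio {stmt.ratio_text}")

lqts = carriers("KCNQ1", "KCNH2")
exact, display = fold_increase(lqts / n, 1 / 2500)
print(f"\nlong-QT carrier prevalence vs 1:2500 reference: "
      f"{exact:.2f}-fold (display {display})")
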