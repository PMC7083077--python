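"""Inheritance-aware status assignment, cohort summary, prevalence math."""

import json

import pytest

from exosf.annotations import VariantAnnotation
from exosf.cascade import FilteredFinding
from exosf.errors import ValidationError
from exosf.registry import load_default_panel
from exosf.reporting import (
    Finding,
    assign_reporting_status,
    fold_increase,
    prevalence_ratio,
    summarize_cohort,
    write_reports,
)
from exosf.variants import make_key
from exosf.vcfio import CohortMeta, GenotypeCall

PANEL = load_default_panel()


def _filtered(gene, pos, carriers, assertion="pathogenic", chrom="1"):
    key = make_key(chrom, pos, "A", "G")
    ann = VariantAnnotation(key=key, gene=gene, consequence="missense",
                           assertion=assertion)
    calls = tuple(GenotypeCall(s, z, 50, 99, 25, 25) for s, z in carriers)
    return FilteredFinding(key=key, annotation=ann, carriers=calls)


def test_dominant_het_is_reportable():
    findings = assign_reporting_status(
        [_filtered("LMNA", 156105714, [("P1", "het")])], PANEL
    )
    assert findings[0].status == "dominant_reportable"


def test_single_het_in_recessive_gene_is_carrier():
    findings = assign_reporting_status(
        [_filtered("ATP7B", 52511697, [("P1", "het")], "likely_pathogenic", "13")],
        PANEL,
    )
    assert findings[0].status == "recessive_carrier"


def test_two_het_variants_in_recessive_gene_presumed_biallelic():
    filtered = [
        _filtered("ATP7B", 52511697, [("P1", "het")], "likely_pathogenic", "13"),
        _filtered("ATP7B", 52515322, [("P1", "het")], "likely_pathogenic", "13"),
    ]
    findings = assign_reporting_status(filtered, PANEL)
    assert all(f.status == "recessive_biallelic_reportable" for f in findings)
    assert all("phase_unknown" in f.flags for f in findings)


def test_homozygous_recessive_is_biallelic():
    findings = assign_reporting_status(
        [_filtered("MUTYH", 45797228, [("P1", "hom_alt")], "pathogenic")], PANEL
    )
    assert findings[0].status == "recessive_biallelic_reportable"


def test_xl_statuses():
    hemi = assign_reporting_status(
        [_filtered("OTC", 38212000, [("P1", "hemizygous")], chrom="X")], PANEL
    )
    assert hemi[0].status == "xl_reportable"
    het_xlr = assign_reporting_status(
        [_filtered("OTC", 38212000, [("P2", "het")], chrom="X")], PANEL
    )
    assert het_xlr[0].status == "xl_carrier"
    het_xld = assign_reporting_status(
        [_filtered("GLA", 100653000, [("P3", "het")], chrom="X")], PANEL
    )
    assert het_xld[0].status == "xl_reportable"


def test_vus_verdict_rejected():
    with pytest.raises(ValidationError):
        assign_reporting_status(
            [_filtered("LMNA", 100, [("P1", "het")], assertion="vus")], PANEL
        )


def test_off_registry_gene_rejected():
    with pytest.raises(ValidationError):
        assign_reporting_status([_filtered("TTN", 100, [("P1", "het")])], PANEL)


# ------------------------------------------------------------------ summary

def _meta(n):
    return CohortMeta(sample_ids=tuple(f"S{i}" for i in range(n)))


def test_summary_on_mixed_findings():
    filtered = [
        _filtered("LMNA", 156105714, [("S0", "het")]),
        _filtered("ATP7B", 52511697, [("S1", "het")], "likely_pathogenic", "13"),
        _filtered("BRCA1", 41246531, [("S2", "het")], chrom="17"),
    ]
    findings = assign_reporting_status(filtered, PANEL)
    summary = summarize_cohort(findings, _meta(100), PANEL)
    assert summary.n_individuals_with_finding == 3
    assert summary.n_dominant_individuals == 2
    assert summary.n_recessive_carrier_individuals == 1
    assert summary.per_category_individuals["cardiogenetic"] == 1
    assert summary.per_category_dominant_individuals["oncogenetic"] == 1
    assert summary.n_genes_by_inheritance == {"AD": 2, "AR": 1}
    prop = summary.proportions["dominant_of_cohort"]
    assert prop["count"] == 2 and prop["denominator"] == 100
    assert prop["percent"] == 2.0


def test_individual_with_two_statuses_counted_once_in_total():
    filtered = [
        _filtered("LMNA", 156105714, [("S0", "het")]),
        _filtered("MUTYH", 45797228, [("S0", "het")]),
    ]
    findings = assign_reporting_status(filtered, PANEL)
    summary = summarize_cohort(findings, _meta(10), PANEL)
    assert summary.n_individuals_with_finding == 1
    assert summary.n_dominant_individuals == 1
    assert summary.n_recessive_carrier_individuals == 1


def test_empty_findings_all_zero():
    summary = summarize_cohort([], _meta(50), PANEL)
    assert summary.n_individuals_with_finding == 0
    assert summary.n_variants_distinct == 0
    assert all(
        p["percent"] == 0 for p in summary.proportions.values()
    )


# ------------------------------------------------------------- prevalence

@pytest.mark.parametrize(
    "count, denom, text",
    [(4, 280, "1:70"), (7, 280, "1:40"), (0, 280, "0"), (3, 280, "1:93")],
)
def test_prevalence_ratio(count, denom, text):
    assert prevalence_ratio(count, denom).ratio_text == text


def test_prevalence_ratio_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        prevalence_ratio(-1, 280)
    with pytest.raises(ValidationError):
        prevalence_ratio(4, 0)


def test_fold_increase_exact_and_display():
    exact, display = fold_increase(1 / 70, 1 / 2500)
    assert exact == pytest.approx(35.714285, abs=1e-4)
    assert display == 36
    assert fold_increase(0.01, 0.01) == (1.0, 1)
    exact, _ = fold_increase(1 / 90, 1 / 100)
    assert exact == pytest.approx(1.1111, abs=1e-3)


def test_fold_increase_zero_reference_rejected():
    with pytest.raises(ValidationError):
        fold_increase(0.01, 0.0)


# ------------------------------------------------------------------ reports

def test_write_reports_layout_and_carrier_exclusion(tmp_path):
    filtered = [
        _filtered("LDLR", 11231101, [("S0", "het"), ("S1", "het")], chrom="19"),
        _filtered("ATP7B", 52511697, [("S2", "het")], "likely_pathogenic", "13"),
    ]
    findings = assign_reporting_status(filtered, PANEL)
    summary = summarize_cohort(findings, _meta(20), PANEL)

    paths = write_reports(summary, findings, tmp_path / "default", registry=PANEL)
    rows = (tmp_path / "default" / "findings.tsv").read_text().strip().split("\n")
    assert len(rows) - 1 == 2  # carrier row excluded by default

    paths_all = write_reports(
        summary, findings, tmp_path / "carriers", registry=PANEL, report_carriers=True
    )
    rows_all = (tmp_path / "carriers" / "findings.tsv").read_text().strip().split("\n")
    assert len(rows_all) - 1 == 3

    payload = json.loads(paths["summary"].read_text())
    assert payload["n_individuals_with_finding"] == 3
    cat = paths["category_table"].read_text()
    assert "LDLR\t2" in cat


def test_write_reports_empty_findings(tmp_path):
    summary = summarize_cohort([], _meta(5), PANEL)
    paths = write_reports(summary, [], tmp_path, registry=PANEL)
    lines = paths["findings"].read_text().strip().split("\n")
    assert len(lines) == 1  # header only
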