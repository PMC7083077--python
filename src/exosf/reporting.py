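"""Inheritance-aware reporting and cohort summary statistics.

A filtered variant becomes one :class:`Finding` per carrier individual,
with a reporting status driven by the gene's inheritance mode and the
genotype's zygosity:

* AD gene, het or hom_alt ................ ``dominant_reportable``
* XLD/XLR gene, hemizygous or hom_alt,
  or het in an XLD gene .................. ``xl_reportable``
* XLR gene, het (presumed female) ........ ``xl_carrier``
* AR gene, hom_alt, or >= 2 distinct het
  variants in the same gene and sample ... ``recessive_biallelic_reportable``
  (unphased data: presumed biallelic, flagged "phase unknown")
* AR gene, single het .................... ``recessive_carrier``

Following the guideline recommendation to return only biallelic variants
in recessive genes, the default clinical report excludes
``recessive_carrier`` (and ``xl_carrier``) findings while the cohort
summary still tallies them; ``report_carriers=True`` includes them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cascade import FilteredFinding, StageCounts
from .errors import ValidationError
from .registry import CATEGORIES, GeneRegistry
from .variants import VariantKey
from .vcfio import CohortMeta

STATUSES = (
    "dominant_reportable",
    "xl_reportable",
    "recessive_biallelic_reportable",
    "recessive_carrier",
    "xl_carrier",
)

#: statuses included in the default clinical report
CLINICALLY_REPORTED = frozenset(
    {"dominant_reportable", "xl_reportable", "recessive_biallelic_reportable"}
)


@dataclass(frozen=True)
class Finding:
    """One reportable (individual, variant) pair."""

    sample_id: str
    key: VariantKey
    gene: str
    verdict: str  # pathogenic | likely_pathogenic
    zygosity: str
    status: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValidationError(f"invalid reporting status: {self.status!r}")


DEFAULT_REPORTABLE_VERDICTS = frozenset({"pathogenic", "likely_pathogenic"})


def assign_reporting_status(
    filtered: Sequence[FilteredFinding],
    registry: GeneRegistry,
    allowed_verdicts: frozenset = DEFAULT_REPORTABLE_VERDICTS,
) -> list[Finding]:
    """Expand filtered variants into per-individual findings with status.

    Compound-heterozygote detection in AR genes groups by (sample, gene):
    two or more distinct heterozygous variants are presumed biallelic
    ("phase unknown" — unphased exome data cannot establish trans).
    Findings whose verdict falls outside ``allowed_verdicts`` (default
    pathogenic / likely_pathogenic) violate the contract: the cascade's
    assertion filter must have admitted them deliberately.
    """
    per_sample_gene: dict[tuple[str, str], list[tuple[FilteredFinding, str]]] = {}
    for ff in filtered:
        gene = ff.annotation.gene
        if gene is None or gene not in registry:
            raise ValidationError(f"{ff.key}: gene {gene!r} not in registry")
        if ff.annotation.assertion not in allowed_verdicts:
            raise ValidationError(
                f"{ff.key}: verdict {ff.annotation.assertion!r} is not in the "
                f"allowed set {sorted(allowed_verdicts)}"
            )
        for call in ff.carriers:
            per_sample_gene.setdefault((call.sample_id, gene), []).append(
                (ff, call.zygosity)
            )

    findings: list[Finding] = []
    for (sample_id, gene), items in per_sample_gene.items():
        record = registry.lookup(gene)
        mode = record.inheritance
        n_distinct_het = len({ff.key for ff, zyg in items if zyg == "het"})
        for ff, zygosity in items:
            flags: tuple[str, ...] = ()
            if mode == "AD":
                status = "dominant_reportable"
            elif mode in ("XLD", "XLR"):
                if zygosity in ("hemizygous", "hom_alt") or mode == "XLD":
                    status = "xl_reportable"
                else:  # XLR het (presumed female carrier)
                    status = "xl_carrier"
            else:  # AR
                if zygosity == "hom_alt":
                    status = "recessive_biallelic_reportable"
                elif n_distinct_het >= 2:
                    status = "recessive_biallelic_reportable"
                    flags = ("phase_unknown",)
                else:
                    status = "recessive_carrier"
            findings.append(
                Finding(
                    sample_id=sample_id,
                    key=ff.key,
                    gene=gene,
                    verdict=ff.annotation.assertion,
                    zygosity=zygosity,
                    status=status,
                    hgvs_c=ff.annotation.hgvs_c,
                    hgvs_p=ff.annotation.hgvs_p,
                    flags=flags,
                )
            )
    findings.sort(key=lambda f: (f.sample_id, f.key.sort_key))
    return findings


# ---------------------------------------------------------------- summary

def _pct(numerator: int, denominator: int) -> dict:
    frac = Fraction(numerator, denominator) if denominator else Fraction(0)
    value = float(frac) * 100
    return {
        "count": numerator,
        "denominator": denominator,
        "fraction": None if denominator == 0 else f"{numerator}/{denominator}",
        "percent": round(value, 2),
        "display": _display_pct(value),
    }


def _display_pct(value: float) -> str:
    """Round to 2 significant figures and trim trailing zeros."""
    if value == 0:
        return "0%"
    import math

    ndigits = 1 - int(math.floor(math.log10(abs(value))))
    return f"{round(value, ndigits):g}%"


@dataclass
class CohortSummary:
    n_cohort: int
    n_individuals_with_finding: int
    n_variants_distinct: int
    n_dominant_individuals: int
    n_recessive_carrier_individuals: int
    n_recessive_biallelic_individuals: int
    n_xl_individuals: int
    n_genes: int
    n_genes_by_inheritance: dict[str, int]
    per_category_individuals: dict[str, int]
    per_category_dominant_individuals: dict[str, int]
    per_gene_individuals: dict[str, int]
    proportions: dict[str, dict]

    def to_dict(self) -> dict:
        return {
            "n_cohort": self.n_cohort,
            "n_individuals_with_finding": self.n_individuals_with_finding,
            "n_variants_distinct": self.n_variants_distinct,
            "n_dominant_individuals": self.n_dominant_individuals,
            "n_recessive_carrier_individuals": self.n_recessive_carrier_individuals,
            "n_recessive_biallelic_individuals": self.n_recessive_biallelic_individuals,
            "n_xl_individuals": self.n_xl_individuals,
            "n_genes": self.n_genes,
            "n_genes_by_inheritance": self.n_genes_by_inheritance,
            "per_category_individuals": self.per_category_individuals,
            "per_category_dominant_individuals": self.per_category_dominant_individuals,
            "per_gene_individuals": self.per_gene_individuals,
            "proportions": self.proportions,
        }


def summarize_cohort(
    findings: Sequence[Finding], meta: CohortMeta, registry: GeneRegistry
) -> CohortSummary:
    """Roll findings up into the cohort-level summary.

    Buckets tally distinct individuals, not findings; an individual
    appears in several buckets only when carrying findings of different
    statuses.  Proportions carry the exact fraction, a percent rounded to
    two decimals, and a 2-significant-figure display string.
    """
    for f in findings:
        if f.gene not in registry:
            raise ValidationError(f"finding references unknown gene {f.gene}")

    individuals = {f.sample_id for f in findings}
    variants = {f.key for f in findings}
    genes = {f.gene for f in findings}

    def bucket(statuses: set[str]) -> set[str]:
        return {f.sample_id for f in findings if f.status in statuses}

    dominant = bucket({"dominant_reportable"})
    carriers = bucket({"recessive_carrier"})
    biallelic = bucket({"recessive_biallelic_reportable"})
    xl = bucket({"xl_reportable", "xl_carrier"})

    per_cat = dict.fromkeys(CATEGORIES, 0)
    per_cat_dom = dict.fromkeys(CATEGORIES, 0)
    for category in CATEGORIES:
        cat_genes = {g for g in genes if registry.lookup(g).category == category}
        per_cat[category] = len({f.sample_id for f in findings if f.gene in cat_genes})
        per_cat_dom[category] = len(
            {
                f.sample_id
                for f in findings
                if f.gene in cat_genes and f.status == "dominant_reportable"
            }
        )

    per_gene: dict[str, int] = {}
    for gene in sorted(genes):
        per_gene[gene] = len({f.sample_id for f in findings if f.gene == gene})

    by_mode: dict[str, int] = {}
    for gene in genes:
        mode = registry.lookup(gene).inheritance
        by_mode[mode] = by_mode.get(mode, 0) + 1

    n = meta.n_samples
    n_with = len(individuals)
    proportions = {
        "individuals_with_finding_of_cohort": _pct(n_with, n),
        "dominant_of_cohort": _pct(len(dominant), n),
        "recessive_carrier_of_cohort": _pct(len(carriers), n),
        "cardiogenetic_of_cohort": _pct(per_cat["cardiogenetic"], n),
        "cardiogenetic_of_findings": _pct(per_cat["cardiogenetic"], n_with),
        "oncogenetic_dominant_of_cohort": _pct(per_cat_dom["oncogenetic"], n),
        "oncogenetic_dominant_of_findings": _pct(per_cat_dom["oncogenetic"], n_with),
    }

    return CohortSummary(
        n_cohort=n,
        n_individuals_with_finding=n_with,
        n_variants_distinct=len(variants),
        n_dominant_individuals=len(dominant),
        n_recessive_carrier_individuals=len(carriers),
        n_recessive_biallelic_individuals=len(biallelic),
        n_xl_individuals=len(xl),
        n_genes=len(genes),
        n_genes_by_inheritance=dict(sorted(by_mode.items())),
        per_category_individuals=per_cat,
        per_category_dominant_individuals=per_cat_dom,
        per_gene_individuals=per_gene,
        proportions=proportions,
    )


# ---------------------------------------------------------------- prevalence

@dataclass(frozen=True)
class PrevalenceStatement:
    count: int
    denominator: int
    ratio_text: str
    reference_prevalence: Optional[float] = None
    fold_increase: Optional[float] = None


def prevalence_ratio(count: int, denominator: int) -> PrevalenceStatement:
    """Express ``count`` affected out of ``denominator`` as a 1:k ratio."""
    if count < 0 or denominator <= 0:
        raise ValidationError("prevalence_ratio requires count >= 0 and denominator > 0")
    if count == 0:
        return PrevalenceStatement(count=0, denominator=denominator, ratio_text="0")
    k = round(denominator / count)
    return PrevalenceStatement(count=count, denominator=denominator, ratio_text=f"1:{k}")


def fold_increase(cohort_prev: float, reference_prev: float) -> tuple[float, int]:
    """Exact cohort/reference prevalence ratio plus nearest-integer display."""
    if reference_prev <= 0:
        raise ValidationError("reference prevalence must be > 0")
    if cohort_prev < 0:
        raise ValidationError("cohort prevalence must be >= 0")
    exact = cohort_prev / reference_prev
    return exact, round(exact)


# ---------------------------------------------------------------- reports

def write_reports(
    summary: CohortSummary,
    findings: Sequence[Finding],
    out_dir,
    stage_counts: Optional[StageCounts] = None,
    registry: Optional[GeneRegistry] = None,
    report_carriers: bool = False,
    provenance: Optional[dict] = None,
) -> dict[str, Path]:
    """Write findings TSV, summary JSON, category table and stage counts.

    Output is deterministic: rows ordered by (sample, chrom, pos); JSON
    keys sorted.  ``report_carriers=False`` (default) restricts the
    findings TSV to clinically reported statuses; the summary always
    covers all findings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    reported = [
        f
        for f in findings
        if report_carriers or f.status in CLINICALLY_REPORTED
    ]
    findings_path = out_dir / "findings.tsv"
    header = [
        "sample_id", "gene", "chrom", "pos", "ref", "alt",
        "hgvs_c", "hgvs_p", "zygosity", "verdict", "status", "flags",
    ]
    lines = ["\t".join(header)]
    for f in sorted(reported, key=lambda f: (f.sample_id, f.key.sort_key)):
        lines.append(
            "\t".join(
                [
                    f.sample_id, f.gene, f.key.chrom, str(f.key.pos),
                    f.key.ref, f.key.alt, f.hgvs_c, f.hgvs_p,
                    f.zygosity, f.verdict, f.status, ",".join(f.flags),
                ]
            )
        )
    findings_path.write_text("\n".join(lines) + "\n")
    paths["findings"] = findings_path

    summary_path = out_dir / "summary.json"
    payload = summary.to_dict()
    if provenance:
        payload["provenance"] = provenance
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["summary"] = summary_path

    if registry is not None:
        cat_path = out_dir / "category_table.tsv"
        cat_lines = ["category\tdisease\tgene\tindividuals"]
        for category in CATEGORIES:
            for gene, n in sorted(summary.per_gene_individuals.items()):
                rec = registry.lookup(gene)
                if rec and rec.category == category:
                    cat_lines.append(f"{category}\t{rec.disease_name}\t{gene}\t{n}")
        cat_path.write_text("\n".join(cat_lines) + "\n")
        paths["category_table"] = cat_path

    if stage_counts is not None:
        sc_path = out_dir / "stage_counts.json"
        sc_path.write_text(json.dumps(stage_counts.as_dict(), indent=2) + "\n")
        paths["stage_counts"] = sc_path

    return paths


def checksum_file(path) -> str:
    """SHA-256 of a file, for provenance manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
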