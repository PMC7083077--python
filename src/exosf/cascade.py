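"""The ordered secondary-findings filter cascade.

Stages, applied in a fixed order for reproducible logging (the variant-
level stages are pure predicates, so the surviving set is order-
invariant):

1. ``panel``        — gene resolves in the actionable-gene registry
2. ``consequence``  — protein-altering class (truncating, splice-region
                      within 10 bp, inframe indel, missense)
3. ``frequency``    — every recorded source frequency strictly below the
                      threshold (default 1%); absent frequencies keep
4. ``assertion``    — ClinVar-style assertion in the accepted set
                      (default pathogenic / likely_pathogenic)
5. ``genotype_qc``  — per-carrier depth/quality/allele-balance checks;
                      a variant survives only with >= 1 passing carrier

Boundary semantics: DP and GQ fail strictly below their minima (DP=15,
GQ=20 pass); the heterozygous allele-balance window [0.3, 0.7] is
inclusive at both ends; the homozygous bound (> 0.85) is strict.  A
carrier genotype missing any required metric fails QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotations import (
    ASSERTION_TOKENS,
    AssertionStore,
    FrequencyStore,
    VariantAnnotation,
    annotate_variant,
)
from .errors import ValidationError
from .registry import GeneRegistry
from .variants import PROTEIN_ALTERING, VariantKey
from .vcfio import GenotypeCall, compute_alt_ratio

logger = logging.getLogger(__name__)

STAGES = ("input", "panel", "consequence", "frequency", "assertion", "genotype_qc")


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the cascade (standard clinical exome QC defaults)."""

    frequency_threshold: float = 0.01
    min_depth: int = 15
    min_gq: int = 20
    het_ratio_low: float = 0.3
    het_ratio_high: float = 0.7
    hom_ratio_min: float = 0.85
    accepted_assertions: frozenset = frozenset({"pathogenic", "likely_pathogenic"})

    def __post_init__(self):
        if not 0 < self.frequency_threshold <= 1:
            raise ValidationError("frequency_threshold must be in (0, 1]")
        if not 0 <= self.het_ratio_low <= self.het_ratio_high <= 1:
            raise ValidationError("require 0 <= het_ratio_low <= het_ratio_high <= 1")
        if not 0 <= self.hom_ratio_min <= 1:
            raise ValidationError("hom_ratio_min must be in [0, 1]")
        unknown = set(self.accepted_assertions) - set(ASSERTION_TOKENS)
        if unknown:
            raise ValidationError(f"unknown assertion tokens in config: {sorted(unknown)}")
        object.__setattr__(self, "accepted_assertions", frozenset(self.accepted_assertions))


@dataclass
class StageCounts:
    """Ordered per-stage survivor tallies: (variants, carrier genotypes)."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def record(self, stage: str, n_variants: int, n_carriers: int) -> None:
        self.counts[stage] = (n_variants, n_carriers)

    def as_dict(self) -> dict:
        return {
            stage: {"variants": v, "carrier_genotypes": g}
            for stage, (v, g) in self.counts.items()
        }

    def check_monotone(self) -> bool:
        seq = list(self.counts.values())
        return all(a[0] >= b[0] and a[1] >= b[1] for a, b in zip(seq, seq[1:]))


@dataclass(frozen=True)
class FilteredFinding:
    """A variant that survived all stages, with its QC-passing carriers."""

    key: VariantKey
    annotation: VariantAnnotation
    carriers: tuple[GenotypeCall, ...]


# ---------------------------------------------------------------- predicates

def panel_filter(annotation: VariantAnnotation, registry: GeneRegistry) -> bool:
    return annotation.gene is not None and annotation.gene in registry


def consequence_filter(annotation: VariantAnnotation) -> bool:
    return annotation.consequence in PROTEIN_ALTERING


def frequency_filter(annotation: VariantAnnotation, config: FilterConfig) -> bool:
    if annotation.frequencies is None:
        return True
    return all(
        freq < config.frequency_threshold
        for freq in annotation.frequencies.per_source.values()
    )


def assertion_filter(annotation: VariantAnnotation, config: FilterConfig) -> bool:
    return annotation.assertion in config.accepted_assertions


def genotype_qc_filter(call: GenotypeCall, config: FilterConfig) -> bool:
    """QC for one carrier genotype (het / hom_alt / hemizygous)."""
    if not call.is_carrier:
        return False
    if call.depth is None or call.genotype_quality is None:
        return False
    if call.depth < config.min_depth or call.genotype_quality < config.min_gq:
        return False
    ratio = compute_alt_ratio(call)
    if ratio is None:
        return False
    if call.zygosity == "het":
        return config.het_ratio_low <= ratio <= config.het_ratio_high
    # hom_alt and hemizygous share the homozygous bound
    return ratio > config.hom_ratio_min


# ---------------------------------------------------------------- cascade

def run_cascade(
    stream: Iterable[tuple[VariantKey, list[GenotypeCall]]],
    assertions: AssertionStore,
    frequencies: FrequencyStore,
    registry: GeneRegistry,
    config: Optional[FilterConfig] = None,
) -> tuple[list[FilteredFinding], StageCounts]:
    """Run the full cascade over a decomposed variant stream.

    Returns the surviving findings sorted by (chrom, pos, alt) and the
    per-stage survivor counts.  Variants with no carrier genotype at all
    are not counted as candidates (a decomposed alt nobody carries is a
    bookkeeping artifact, not an observed variant).
    """
    config = config or FilterConfig()
    counts = StageCounts()

    candidates: list[tuple[VariantKey, VariantAnnotation, list[GenotypeCall]]] = []
    for key, calls in stream:
        carriers = [c for c in calls if c.is_carrier]
        if not carriers:
            continue
        annotation = annotate_variant(key, assertions, frequencies, registry)
        candidates.append((key, annotation, carriers))
    counts.record("input", len(candidates), sum(len(c) for _, _, c in candidates))

    stage_predicates = (
        ("panel", lambda ann: panel_filter(ann, registry)),
        ("consequence", consequence_filter),
        ("frequency", lambda ann: frequency_filter(ann, config)),
        ("assertion", lambda ann: assertion_filter(ann, config)),
    )
    surviving = candidates
    for stage, predicate in stage_predicates:
        surviving = [item for item in surviving if predicate(item[1])]
        counts.record(stage, len(surviving), sum(len(c) for _, _, c in surviving))
        logger.info(
            "stage %-12s: %d variants, %d carrier genotypes",
            stage, *counts.counts[stage],
        )

    findings = []
    for key, annotation, carriers in surviving:
        passing = tuple(c for c in carriers if genotype_qc_filter(c, config))
        if passing:
            findings.append(FilteredFinding(key=key, annotation=annotation, carriers=passing))
    counts.record(
        "genotype_qc", len(findings), sum(len(f.carriers) for f in findings)
    )
    logger.info(
        "stage %-12s: %d variants, %d carrier genotypes",
        "genotype_qc", *counts.counts["genotype_qc"],
    )

    findings.sort(key=lambda f: f.key.sort_key)
    return findings, counts
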