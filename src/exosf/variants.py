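"""Normalized variant keys and consequence vocabulary.

A :class:`VariantKey` identifies one biallelic substitution or indel on a
1-based genomic coordinate system (hg19 for the packaged panel).  Keys are
normalized so that lookups are representation-invariant: chromosome labels
lose any leading ``chr``, alleles are uppercased, and redundant shared
bases are trimmed (common suffix first, then common prefix, keeping at
least one base of each allele and adjusting the position).  Multi-allelic
records must be decomposed upstream (see :mod:`exosf.vcfio`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

_ALLELE_ALPHABET = set("ACGT")

#: Consequence vocabulary.  The first eight tokens are the protein-altering
#: classes retained by the consequence filter (truncating, splice-region
#: within 10 bp of an exon boundary, inframe indel, missense).
CONSEQUENCE_CLASSES = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "canonical_splice",
    "near_splice_within_10bp",
    "inframe_indel",
    "missense",
    "synonymous",
    "intronic_other",
    "utr",
    "intergenic",
    "other_noncoding",
)

PROTEIN_ALTERING = frozenset(CONSEQUENCE_CLASSES[:8])


def validate_consequence(token: str) -> str:
    if token not in CONSEQUENCE_CLASSES:
        raise ValidationError(f"unknown consequence class: {token!r}")
    return token


def normalize_chrom(chrom: str) -> str:
    chrom = chrom.strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if not chrom:
        raise ValidationError("empty chromosome label")
    return chrom


@dataclass(frozen=True, order=True)
class VariantKey:
    """One normalized biallelic variant: (chrom, pos, ref, alt), 1-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not set(allele) <= _ALLELE_ALPHABET:
                raise ValidationError(
                    f"{name} allele must be non-empty over A/C/G/T, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt are identical: {self.ref!r}")

    def __str__(self) -> str:  # e.g. "13:32968825:G>A"
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: 1..22, then X, Y, MT, then others."""
    if chrom.isdigit():
        return (int(chrom), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if chrom in special:
        return (special[chrom], "")
    return (100, chrom)


def make_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Build a normalized :class:`VariantKey`.

    Normalization: strip a leading ``chr``, uppercase alleles, trim shared
    trailing then leading bases (keeping one base per allele; leading trims
    advance the position).  Full left-alignment against the reference
    sequence is out of scope; trimming makes the common padded VCF
    representations of the same event collide on one key.
    """
    chrom = normalize_chrom(chrom)
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    pos = int(pos)
    # trim common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)
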