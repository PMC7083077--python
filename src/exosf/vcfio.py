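"""Multi-sample VCF ingestion.

Streams a VCF 4.x file (plain or bgzip) into normalized
(:class:`~exosf.variants.VariantKey`, per-sample :class:`GenotypeCall`)
pairs carrying the genotype-QC metrics (DP, GQ, AD) the filter cascade
needs.  Multi-allelic rows are decomposed into biallelic records; per-alt
zygosity is recomputed so a genotype carrying only *other* alternate
alleles counts as hom_ref for the current alt, and the alt depth is taken
from the matching AD entry.  Parsing is delegated to cyvcf2/htslib.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from cyvcf2 import VCF

from .errors import FormatError
from .variants import VariantKey, make_key

ZYGOSITIES = ("hom_ref", "het", "hom_alt", "hemizygous", "missing")

_CARRIER_ZYGOSITIES = frozenset({"het", "hom_alt", "hemizygous"})


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one (decomposed) variant."""

    sample_id: str
    zygosity: str
    depth: Optional[int] = None          # DP
    genotype_quality: Optional[int] = None  # GQ
    ref_depth: Optional[int] = None      # AD[0]
    alt_depth: Optional[int] = None      # AD for this alt

    @property
    def is_carrier(self) -> bool:
        return self.zygosity in _CARRIER_ZYGOSITIES

    @property
    def n_alt_alleles(self) -> int:
        return {"het": 1, "hom_alt": 2, "hemizygous": 1}.get(self.zygosity, 0)


@dataclass(frozen=True)
class CohortMeta:
    sample_ids: tuple[str, ...]
    build_tag: str = "hg19"

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers in VCF header")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class RawRecord:
    """A raw (possibly multi-allelic) VCF data line, ready to decompose.

    ``genotypes`` holds per-sample allele-index tuples (-1 = missing);
    ``ad`` holds per-sample allele-depth tuples aligned with [ref, alt1,
    alt2, ...] or None when AD is absent for that sample.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[tuple[int, ...], ...]
    depths: tuple[Optional[int], ...]
    quals: tuple[Optional[int], ...]
    ad: tuple[Optional[tuple[int, ...]], ...]


def compute_alt_ratio(call: GenotypeCall) -> Optional[float]:
    """alt_depth / (ref_depth + alt_depth); None when undefined."""
    if call.ref_depth is None or call.alt_depth is None:
        return None
    denom = call.ref_depth + call.alt_depth
    if denom == 0:
        return None
    return call.alt_depth / denom


def _zygosity_for_alt(alleles: tuple[int, ...], alt_index: int) -> str:
    """Zygosity of one genotype relative to one 1-based alt allele index."""
    known = [a for a in alleles if a >= 0]
    if not known:
        return "missing"
    n_this = sum(a == alt_index for a in known)
    if len(known) == 1:  # haploid call (e.g. male X)
        return "hemizygous" if n_this == 1 else "hom_ref"
    if n_this == 0:
        return "hom_ref"
    if n_this == 1:
        return "het"
    return "hom_alt"


def decompose_multiallelic(
    record: RawRecord, sample_ids: Sequence[str]
) -> list[tuple[VariantKey, list[GenotypeCall]]]:
    """Split a raw record into one biallelic (key, calls) pair per alt.

    Carrier conservation: for each sample, the total alt-allele count
    across the decomposed outputs equals the alt-allele count of the
    original genotype.
    """
    if len(record.genotypes) != len(sample_ids):
        raise FormatError(
            f"{record.chrom}:{record.pos}: genotype columns "
            f"({len(record.genotypes)}) do not match header samples ({len(sample_ids)})"
        )
    out = []
    for i, alt in enumerate(record.alts, start=1):
        calls = []
        for s, sample in enumerate(sample_ids):
            ad = record.ad[s]
            if ad is not None and len(ad) != 1 + len(record.alts):
                raise FormatError(
                    f"{record.chrom}:{record.pos} sample {sample}: AD has "
                    f"{len(ad)} entries for {len(record.alts)} alt allele(s)"
                )
            zyg = _zygosity_for_alt(record.genotypes[s], i)
            calls.append(
                GenotypeCall(
                    sample_id=sample,
                    zygosity=zyg,
                    depth=record.depths[s],
                    genotype_quality=record.quals[s],
                    ref_depth=None if ad is None else ad[0],
                    alt_depth=None if ad is None else ad[i],
                )
            )
        out.append((make_key(record.chrom, record.pos, record.ref, alt), calls))
    return out


def _int_or_none(value) -> Optional[int]:
    try:
        v = int(value)
    except (TypeError, ValueError):
        return None
    return None if v < 0 else v


def _raw_from_cyvcf2(variant, n_samples: int) -> RawRecord:
    genotypes = []
    for gt in variant.genotypes:  # [a1, a2, phased] or [a, phased]
        genotypes.append(tuple(int(a) for a in gt[:-1]))
    fmt_dp = variant.format("DP")
    fmt_gq = variant.format("GQ")
    fmt_ad = variant.format("AD")
    depths, quals, ads = [], [], []
    for s in range(n_samples):
        depths.append(None if fmt_dp is None else _int_or_none(fmt_dp[s][0]))
        quals.append(None if fmt_gq is None else _int_or_none(fmt_gq[s][0]))
        if fmt_ad is None:
            ads.append(None)
        else:
            row = [_int_or_none(x) for x in fmt_ad[s]]
            ads.append(None if any(x is None for x in row) else tuple(row))
    return RawRecord(
        chrom=variant.CHROM,
        pos=variant.POS,
        ref=variant.REF,
        alts=tuple(variant.ALT),
        genotypes=tuple(genotypes),
        depths=tuple(depths),
        quals=tuple(quals),
        ad=tuple(ads),
    )


def read_cohort_vcf(
    path,
) -> tuple[CohortMeta, Iterator[tuple[VariantKey, list[GenotypeCall]]]]:
    """Open a cohort VCF and stream decomposed biallelic records.

    Records are yielded in file order; reference-only sites (no alt
    allele) are skipped; sample order follows the header.  Raises
    :class:`FormatError` on files without genotype columns or with
    malformed per-sample fields.
    """
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = tuple(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample/genotype columns")
    meta = CohortMeta(sample_ids=samples)

    def _stream():
        for variant in vcf:
            if not variant.ALT:  # reference-only site
                continue
            raw = _raw_from_cyvcf2(variant, len(samples))
            yield from decompose_multiallelic(raw, samples)

    return meta, _stream()
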