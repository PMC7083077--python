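"""Variant-keyed assertion and frequency stores.

These flat-table stores stand in for live database lookups (a ClinVar-like
assertion archive and population allele-frequency resources such as
dbSNP / gnomAD / an in-house exome database).  Both stores key on the
normalized :class:`~exosf.variants.VariantKey`, so lookup is invariant to
allele-representation differences.  Absence is a value, never an error:
annotating an unknown key yields assertion ``absent`` and no frequencies.

Table layouts (TSV, UTF-8, header row):

* assertion table: chrom, pos, ref, alt, gene, consequence, assertion,
  evidence_codes (comma-joined), hgvs_c, hgvs_p
* frequency table: chrom, pos, ref, alt, then one column per frequency
  source (open-ended labels; e.g. dbsnp / gnomad / inhouse)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .acmg import EvidenceSet, parse_evidence
from .errors import FormatError, ValidationError
from .registry import GeneRegistry
from .variants import VariantKey, make_key, validate_consequence

ASSERTION_TOKENS = (
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "likely_benign",
    "benign",
    "conflicting",
    "absent",
)


@dataclass(frozen=True)
class AssertionRecord:
    key: VariantKey
    assertion: str
    gene: str
    consequence: str
    evidence_codes: EvidenceSet = field(default_factory=EvidenceSet)
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self):
        if self.assertion not in ASSERTION_TOKENS:
            raise ValidationError(f"unknown assertion token: {self.assertion!r}")
        validate_consequence(self.consequence)


@dataclass(frozen=True)
class FrequencyRecord:
    key: VariantKey
    per_source: Mapping[str, float]

    def __post_init__(self):
        for source, freq in self.per_source.items():
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(
                    f"{self.key}: frequency for source {source!r} outside [0,1]: {freq}"
                )


@dataclass(frozen=True)
class VariantAnnotation:
    """Merged annotation for one variant key."""

    key: VariantKey
    gene: Optional[str] = None
    consequence: str = "other_noncoding"
    assertion: str = "absent"
    evidence_codes: EvidenceSet = field(default_factory=EvidenceSet)
    frequencies: Optional[FrequencyRecord] = None
    hgvs_c: str = ""
    hgvs_p: str = ""


class _KeyedStore:
    def __init__(self, records: Mapping[VariantKey, object]):
        self._records = dict(records)

    def __len__(self):
        return len(self._records)

    def __contains__(self, key: VariantKey):
        return key in self._records

    def get(self, key: VariantKey):
        return self._records.get(key)

    def keys(self):
        return self._records.keys()


class AssertionStore(_KeyedStore):
    """Keyed store of :class:`AssertionRecord`."""


class FrequencyStore(_KeyedStore):
    """Keyed store of :class:`FrequencyRecord`."""

    @property
    def sources(self) -> tuple[str, ...]:
        labels: list[str] = []
        for rec in self._records.values():
            for s in rec.per_source:
                if s not in labels:
                    labels.append(s)
        return tuple(labels)


def _parse_key(row, path, line_no) -> VariantKey:
    try:
        return make_key(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
    except (ValidationError, ValueError, TypeError) as exc:
        raise FormatError(f"{path} line {line_no}: bad variant key ({exc})") from exc


def load_assertion_table(path) -> AssertionStore:
    """Load an assertion TSV; duplicate keys are rejected."""
    df = _read_tsv(path, ("chrom", "pos", "ref", "alt", "gene", "consequence", "assertion"))
    records: dict[VariantKey, AssertionRecord] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        key = _parse_key(row, path, line_no)
        if key in records:
            raise ValidationError(f"{path} line {line_no}: duplicate variant key {key}")
        try:
            records[key] = AssertionRecord(
                key=key,
                assertion=row["assertion"].strip(),
                gene=row["gene"].strip(),
                consequence=row["consequence"].strip(),
                evidence_codes=parse_evidence(row.get("evidence_codes", "") or ""),
                hgvs_c=row.get("hgvs_c", ""),
                hgvs_p=row.get("hgvs_p", ""),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} line {line_no}: {exc}") from exc
    return AssertionStore(records)


def load_frequency_table(path) -> FrequencyStore:
    """Load a frequency TSV; blank cells mean 'no record in that source'."""
    df = _read_tsv(path, ("chrom", "pos", "ref", "alt"))
    source_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    records: dict[VariantKey, FrequencyRecord] = {}
    for idx, row in df.iterrows():
        line_no = idx + 2
        key = _parse_key(row, path, line_no)
        if key in records:
            raise ValidationError(f"{path} line {line_no}: duplicate variant key {key}")
        per_source = {}
        for col in source_cols:
            cell = str(row[col]).strip()
            if not cell:
                continue
            try:
                per_source[col] = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"{path} line {line_no}: unparseable frequency {cell!r} in {col}"
                ) from exc
        try:
            records[key] = FrequencyRecord(key=key, per_source=per_source)
        except ValidationError as exc:
            raise ValidationError(f"{path} line {line_no}: {exc}") from exc
    return FrequencyStore(records)


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot read table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def annotate_variant(
    key: VariantKey,
    assertions: AssertionStore,
    frequencies: FrequencyStore,
    registry: Optional[GeneRegistry] = None,
) -> VariantAnnotation:
    """Merge assertion and frequency records for one key (pure lookup).

    The gene symbol is copied from the assertion record when present; the
    registry argument is accepted for interface symmetry (panel membership
    itself is decided by the filter cascade, not here).
    """
    arec = assertions.get(key)
    frec = frequencies.get(key)
    if arec is None:
        return VariantAnnotation(key=key, frequencies=frec)
    return VariantAnnotation(
        key=key,
        gene=arec.gene or None,
        consequence=arec.consequence,
        assertion=arec.assertion,
        evidence_codes=arec.evidence_codes,
        frequencies=frec,
        hgvs_c=arec.hgvs_c,
        hgvs_p=arec.hgvs_p,
    )
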