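"""Actionable gene panel registry.

The packaged default panel is the 59-gene ACMG secondary-findings list
(SF v2.0), one record per gene with its inheritance mode (AD/AR/XLD/XLR),
RefSeq transcript, disease label and disease category
(cardiogenetic / oncogenetic / connective_tissue / other).  Genes listed
in the source table under multiple disorders are normalized to a single
record; multiple MIM numbers collapse into a comma-joined list.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import FormatError, ValidationError

INHERITANCE_MODES = ("AD", "AR", "XLD", "XLR")
CATEGORIES = ("cardiogenetic", "oncogenetic", "connective_tissue", "other")
ONSETS = ("child", "adult", "child_or_adult", "unknown")

_REQUIRED_COLUMNS = ("symbol", "transcript", "inheritance", "category")


@dataclass(frozen=True)
class GeneRecord:
    """One actionable gene of the panel."""

    symbol: str
    transcript: str
    inheritance: str
    category: str
    mim_disorder: Optional[str] = None
    disease_name: str = ""
    typical_onset: str = "unknown"
    extra: tuple = field(default_factory=tuple)  # opaque (column, value) pairs

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_MODES:
            raise ValidationError(
                f"gene {self.symbol}: unrecognized inheritance {self.inheritance!r}"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"gene {self.symbol}: unrecognized category {self.category!r}"
            )
        if self.typical_onset not in ONSETS:
            raise ValidationError(
                f"gene {self.symbol}: unrecognized onset {self.typical_onset!r}"
            )


class GeneRegistry:
    """Collection of :class:`GeneRecord` keyed by unique gene symbol."""

    def __init__(self, records: Iterable[GeneRecord], build_tag: str = "hg19"):
        self._by_symbol: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.symbol in self._by_symbol:
                raise ValidationError(f"duplicate gene symbol: {rec.symbol}")
            self._by_symbol[rec.symbol] = rec
        self.build_tag = build_tag

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __iter__(self):
        return iter(self._by_symbol.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._by_symbol

    def lookup(self, symbol: str) -> Optional[GeneRecord]:
        """Case-sensitive lookup; returns None when the symbol is absent."""
        return self._by_symbol.get(symbol)

    def by_inheritance(self, mode: str) -> list[GeneRecord]:
        if mode not in INHERITANCE_MODES:
            raise ValidationError(f"invalid inheritance mode: {mode!r}")
        return [r for r in self if r.inheritance == mode]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "symbol": r.symbol,
                "transcript": r.transcript,
                "inheritance": r.inheritance,
                "mim": r.mim_disorder or "",
                "disease": r.disease_name,
                "category": r.category,
                "onset": r.typical_onset,
                **dict(r.extra),
            }
            for r in self
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_gene_table(path) -> GeneRegistry:
    """Load a gene-panel TSV into a :class:`GeneRegistry`.

    Required columns: symbol, transcript, inheritance, category.  Optional:
    mim, disease, onset.  Unknown extra columns are preserved as opaque
    metadata on each record.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise FormatError(f"cannot read gene table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table {path} missing required columns: {missing}")
    known = {"symbol", "transcript", "inheritance", "mim", "disease", "category", "onset"}
    extra_cols = [c for c in df.columns if c not in known]
    records = []
    for _, row in df.iterrows():
        records.append(
            GeneRecord(
                symbol=row["symbol"].strip(),
                transcript=row["transcript"].strip(),
                inheritance=row["inheritance"].strip(),
                category=row["category"].strip(),
                mim_disorder=(row.get("mim", "") or None),
                disease_name=row.get("disease", ""),
                typical_onset=row.get("onset", "") or "unknown",
                extra=tuple((c, row[c]) for c in extra_cols),
            )
        )
    return GeneRegistry(records)


def default_panel_path() -> Path:
    return Path(importlib.resources.files("exosf") / "data" / "acmg_sf_panel.tsv")


def load_default_panel() -> GeneRegistry:
    """The packaged 59-gene ACMG secondary-findings panel (hg19)."""
    return load_gene_table(default_panel_path())
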