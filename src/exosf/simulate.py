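"""Synthetic exome-cohort generator.

Builds, from a spike specification and a seed, a multi-sample VCF plus the
matching assertion and frequency tables and a truth table naming the
expected fate of every generated record in the filter cascade.  The
packaged reference spike spec embeds the 19 reference pathogenic / likely
pathogenic panel variants at their recorded carrier counts (24 carriers,
one finding per individual) into a 280-sample cohort; adversarial
background records are constructed so that each one fails exactly one
cascade stage (off-panel gene, non-protein-altering consequence, common
frequency, non-P/LP assertion, or failing genotype QC).

Determinism: the same (spec, seed) pair produces byte-identical output
files.  Spiked genotypes are drawn with DP in [20, 120] (bracketing a
realistic ~80x mean exome variant depth), GQ in [30, 99] and heterozygous
allele balance in [0.35, 0.65] — safely inside the QC windows, because
the fixture exercises the cascade's logic; its boundaries are covered by
unit tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .variants import chrom_sort_key, make_key, validate_consequence, VariantKey

FREQUENCY_SOURCES = ("dbsnp", "gnomad", "inhouse")

#: off-panel decoy genes with plausible hg19 anchor coordinates
_OFF_PANEL_GENES = (
    ("TTN", "2", 179400000),
    ("OBSCN", "1", 228400000),
    ("PLEC", "8", 144990000),
    ("AHNAK2", "14", 105400000),
)


@dataclass(frozen=True)
class SpikeEntry:
    key: VariantKey
    gene: str
    consequence: str
    assertion: str
    evidence_codes: str
    hgvs_c: str
    hgvs_p: str
    n_carriers: int
    zygosity: str = "het"

    def __post_init__(self):
        validate_consequence(self.consequence)
        if self.n_carriers < 0:
            raise ValidationError(f"{self.key}: negative carrier count")
        if self.zygosity not in ("het", "hom_alt"):
            raise ValidationError(f"{self.key}: spike zygosity must be het or hom_alt")


@dataclass(frozen=True)
class SpikeSpec:
    entries: tuple[SpikeEntry, ...]
    constraint_one_finding_per_sample: bool = True

    @property
    def total_carriers(self) -> int:
        return sum(e.n_carriers for e in self.entries)


@dataclass(frozen=True)
class BackgroundSpec:
    """Counts of adversarial background records, one cascade failure each."""

    n_common_pathogenic_annotated: int = 3   # fails: frequency
    n_rare_benign: int = 4                   # fails: assertion (benign/likely_benign)
    n_vus: int = 3                           # fails: assertion (vus/conflicting)
    n_low_qc: int = 4                        # fails: genotype_qc
    n_off_panel: int = 4                     # fails: panel
    n_synonymous: int = 2                    # fails: consequence
    seed: Optional[int] = None

    def __post_init__(self):
        for name in (
            "n_common_pathogenic_annotated", "n_rare_benign", "n_vus",
            "n_low_qc", "n_off_panel", "n_synonymous",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"BackgroundSpec.{name} must be >= 0")


@dataclass
class SimRecord:
    """One VCF row to emit (possibly multi-allelic)."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    # sample_id -> (genotype string, DP, GQ, AD tuple)
    calls: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TruthRow:
    record_class: str  # spike | common_pathogenic | rare_benign | ...
    key: VariantKey
    gene: str
    expected: str      # "survives" or "fails:<stage>"
    carrier_samples: tuple[str, ...]


@dataclass(frozen=True)
class FixturePaths:
    vcf: Path
    assertions: Path
    frequencies: Path
    truth: Path


def default_spike_spec_path() -> Path:
    return Path(importlib.resources.files("exosf") / "data" / "reference_spike_spec.tsv")


def load_spike_spec(path=None) -> SpikeSpec:
    """Load a spike spec TSV (defaults to the packaged reference set)."""
    path = path or default_spike_spec_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        entries.append(
            SpikeEntry(
                key=make_key(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                gene=row["gene"],
                consequence=row["consequence"],
                assertion=row["assertion"],
                evidence_codes=row["evidence_codes"],
                hgvs_c=row.get("hgvs_c", ""),
                hgvs_p=row.get("hgvs_p", ""),
                n_carriers=int(row["n_carriers"]),
                zygosity=row.get("zygosity", "het") or "het",
            )
        )
    return SpikeSpec(entries=tuple(entries))


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _good_genotype(rng: np.random.Generator, zygosity: str) -> tuple[str, int, int, tuple]:
    dp = int(rng.integers(20, 121))
    gq = int(rng.integers(30, 100))
    if zygosity == "het":
        ratio = float(rng.uniform(0.35, 0.65))
        alt = int(round(dp * ratio))
        alt = min(max(alt, 1), dp - 1)
        return "0/1", dp, gq, (dp - alt, alt)
    alt = dp - int(rng.integers(0, max(1, int(dp * 0.05))))
    return "1/1", dp, gq, (dp - alt, alt)


def _bad_genotype(rng: np.random.Generator, mode: int) -> tuple[str, int, int, tuple]:
    """A heterozygous call failing exactly one QC metric."""
    if mode % 3 == 0:  # low depth
        dp = int(rng.integers(4, 15))
        alt = max(1, dp // 2)
        return "0/1", dp, 90, (dp - alt, alt)
    if mode % 3 == 1:  # low GQ
        dp = int(rng.integers(20, 80))
        alt = dp // 2
        return "0/1", dp, int(rng.integers(0, 20)), (dp - alt, alt)
    dp = int(rng.integers(30, 80))  # allele balance outside [0.3, 0.7]
    alt = max(1, int(dp * 0.12))
    return "0/1", dp, 90, (dp - alt, alt)


class _PositionPool:
    """Allocates unused positions near per-gene anchor coordinates."""

    def __init__(self, anchors: dict[str, tuple[str, int]], taken: set):
        self.anchors = anchors
        self.taken = set(taken)

    def next_pos(self, gene: str, offset_seed: int) -> tuple[str, int]:
        chrom, anchor = self.anchors[gene]
        pos = anchor + 151 + 97 * offset_seed
        while (chrom, pos) in self.taken:
            pos += 97
        self.taken.add((chrom, pos))
        return chrom, pos


def simulate_background(
    n_samples: int,
    spec: BackgroundSpec,
    rng: np.random.Generator,
    panel_anchors: dict[str, tuple[str, int]],
    sample_ids: Sequence[str],
    taken_positions: Optional[set] = None,
) -> tuple[list[SimRecord], list[TruthRow], list[dict], list[dict]]:
    """Generate adversarial background records.

    Returns (vcf records, truth rows, assertion-table rows, frequency-table
    rows).  Each record is constructed to fail exactly one cascade stage,
    named in its truth row.  When two or more rare-benign records are
    requested, the first two are emitted as one multi-allelic VCF site.
    """
    records: list[SimRecord] = []
    truth: list[TruthRow] = []
    assertion_rows: list[dict] = []
    frequency_rows: list[dict] = []
    pool = _PositionPool(panel_anchors, taken=set(taken_positions or ()))
    panel_genes = sorted(panel_anchors)
    counter = 0
    _SNV_ALT = {"A": "G", "C": "T", "G": "A", "T": "C"}

    def _new_site(gene: str) -> tuple[str, int, str, str]:
        nonlocal counter
        chrom, pos = pool.next_pos(gene, counter)
        ref = "ACGT"[int(rng.integers(0, 4))]
        counter += 1
        return chrom, pos, ref, _SNV_ALT[ref]

    def _carriers(k: int) -> list[str]:
        idx = rng.choice(len(sample_ids), size=min(k, len(sample_ids)), replace=False)
        return [sample_ids[i] for i in sorted(idx)]

    def _add(record_class, gene, consequence, assertion, evidence, freqs,
             expected, good_qc=True, chrom=None, pos=None, ref=None, alt=None):
        nonlocal counter
        if chrom is None:
            chrom, pos, ref, alt = _new_site(gene)
        rec = SimRecord(chrom=chrom, pos=pos, ref=ref, alts=(alt,))
        carriers = _carriers(int(rng.integers(1, 4)))
        for j, sample in enumerate(carriers):
            if good_qc:
                rec.calls[sample] = _good_genotype(rng, "het")
            else:
                rec.calls[sample] = _bad_genotype(rng, j + counter)
        records.append(rec)
        key = make_key(chrom, pos, ref, alt)
        truth.append(TruthRow(record_class, key, gene, expected, tuple(carriers)))
        assertion_rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "gene": gene, "consequence": consequence, "assertion": assertion,
                "evidence_codes": evidence, "hgvs_c": "", "hgvs_p": "",
            }
        )
        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
        row.update(freqs)
        frequency_rows.append(row)

    def _rare_freqs() -> dict:
        return {
            "dbsnp": "",
            "gnomad": f"{float(rng.uniform(0, 0.005)):.6f}",
            "inhouse": f"{float(rng.uniform(0, 0.008)):.6f}",
        }

    for i in range(spec.n_common_pathogenic_annotated):
        gene = panel_genes[i % len(panel_genes)]
        freqs = {
            "dbsnp": f"{float(rng.uniform(0.02, 0.2)):.6f}",
            "gnomad": f"{float(rng.uniform(0.02, 0.2)):.6f}",
            "inhouse": f"{float(rng.uniform(0.01, 0.1)):.6f}",
        }
        _add("common_pathogenic", gene, "missense", "pathogenic",
             "PVS1,PS3", freqs, "fails:frequency")

    multiallelic_pending = spec.n_rare_benign >= 2
    for i in range(spec.n_rare_benign):
        gene = panel_genes[(i + 1) % len(panel_genes)]
        assertion = "benign" if i % 2 == 0 else "likely_benign"
        _add("rare_benign", gene, "missense", assertion,
             "BS1,BS2" if i % 2 == 0 else "BS1,BP4", _rare_freqs(),
             "fails:assertion")
    if multiallelic_pending:
        # merge the first two rare-benign sites into one multi-allelic row
        base = spec.n_common_pathogenic_annotated
        a, b = records[base], records[base + 1]
        alt2 = next(x for x in "ACGT" if x not in (a.ref, a.alts[0]))
        merged = SimRecord(chrom=a.chrom, pos=a.pos, ref=a.ref,
                           alts=(a.alts[0], alt2))
        for sample, (gt, dp, gq, ad) in a.calls.items():
            merged.calls[sample] = ("0/1", dp, gq, (ad[0], ad[1], 0))
        for sample, (gt, dp, gq, ad) in b.calls.items():
            if sample in merged.calls:
                _, dp0, gq0, ad0 = merged.calls[sample]
                merged.calls[sample] = ("1/2", dp0, gq0, (0, ad0[1], ad[1]))
            else:
                merged.calls[sample] = ("0/2", dp, gq, (ad[0], 0, ad[1]))
        records[base] = merged
        del records[base + 1]
        # rewrite truth/annotation/frequency rows of the second allele and
        # refresh the carrier lists of both alleles
        old_key = make_key(b.chrom, b.pos, b.ref, b.alts[0])
        key1 = make_key(merged.chrom, merged.pos, merged.ref, merged.alts[0])
        key2 = make_key(merged.chrom, merged.pos, merged.ref, merged.alts[1])
        for rows in (assertion_rows, frequency_rows):
            for row in rows:
                if (str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"]) == (
                    old_key.chrom, old_key.pos, old_key.ref, old_key.alt,
                ):
                    row["chrom"], row["pos"] = merged.chrom, merged.pos
                    row["ref"], row["alt"] = merged.ref, merged.alts[1]
        carriers1 = tuple(sorted(
            s for s, (gt, *_rest) in merged.calls.items() if "1" in gt.split("/")
        ))
        carriers2 = tuple(sorted(
            s for s, (gt, *_rest) in merged.calls.items() if "2" in gt.split("/")
        ))
        for t, row in enumerate(truth):
            if row.key == old_key:
                truth[t] = TruthRow(row.record_class, key2, row.gene,
                                    row.expected, carriers2)
            elif row.key == key1:
                truth[t] = TruthRow(row.record_class, key1, row.gene,
                                    row.expected, carriers1)

    for i in range(spec.n_vus):
        gene = panel_genes[(i + 2) % len(panel_genes)]
        assertion = "vus" if i % 2 == 0 else "conflicting"
        _add("vus", gene, "missense", assertion, "PM2,PP3",
             _rare_freqs(), "fails:assertion")

    for i in range(spec.n_low_qc):
        gene = panel_genes[(i + 3) % len(panel_genes)]
        _add("low_qc", gene, "missense", "pathogenic", "PVS1,PM1,PM2",
             _rare_freqs(), "fails:genotype_qc", good_qc=False)

    for i in range(spec.n_off_panel):
        gene, chrom, anchor = _OFF_PANEL_GENES[i % len(_OFF_PANEL_GENES)]
        pos = anchor + 211 * (i + 1)
        ref = "ACGT"[int(rng.integers(0, 4))]
        _add("off_panel", gene, "missense", "pathogenic", "PVS1,PS4",
             _rare_freqs(), "fails:panel",
             chrom=chrom, pos=pos, ref=ref, alt=_SNV_ALT[ref])

    for i in range(spec.n_synonymous):
        gene = panel_genes[(i + 4) % len(panel_genes)]
        _add("synonymous", gene, "synonymous", "likely_benign", "BP4,BP7",
             _rare_freqs(), "fails:consequence")

    return records, truth, assertion_rows, frequency_rows


def write_fixture_vcf(records: Sequence[SimRecord], sample_ids: Sequence[str], path) -> Path:
    """Emit a VCF 4.2 text file with GT:DP:GQ:AD per genotype.

    Records must already be sorted by (chrom, pos); unsorted input is
    rejected.  Non-carrier samples get a constant reference call
    (0/0, DP 50, GQ 99, AD 50,0).
    """
    order = [(chrom_sort_key(r.chrom), r.pos) for r in records]
    if order != sorted(order):
        raise ValidationError("records must be sorted by (chrom, pos) before writing")
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=exosf-simulate",
        *[f"##contig=<ID={c}>" for c in sorted(contigs, key=chrom_sort_key)],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT" +
        ("\t" + "\t".join(sample_ids) if sample_ids else ""),
    ]
    for rec in records:
        n_alleles = 1 + len(rec.alts)
        ref_ad = ",".join(["50"] + ["0"] * len(rec.alts))
        cols = [
            rec.chrom, str(rec.pos), ".", rec.ref, ",".join(rec.alts),
            ".", "PASS", ".", "GT:DP:GQ:AD",
        ]
        for sample in sample_ids:
            call = rec.calls.get(sample)
            if call is None:
                cols.append(f"0/0:50:99:{ref_ad}")
            else:
                gt, dp, gq, ad = call
                if len(ad) != n_alleles:
                    raise ValidationError(
                        f"{rec.chrom}:{rec.pos} {sample}: AD arity {len(ad)} != {n_alleles}"
                    )
                cols.append(f"{gt}:{dp}:{gq}:{','.join(str(x) for x in ad)}")
        lines.append("\t".join(cols))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def build_reference_fixture(
    n_samples: int = 280,
    seed: int = 1,
    out_dir=None,
    spike_spec: Optional[SpikeSpec] = None,
    background: Optional[BackgroundSpec] = None,
) -> FixturePaths:
    """Generate the full fixture: VCF + assertion/frequency/truth tables.

    Each spike-spec variant is placed heterozygous (or homozygous, per the
    spec) into its requested number of distinct samples; with the
    one-finding-per-sample constraint no sample receives two spiked
    variants.  Background records follow ``BackgroundSpec``.
    """
    spike_spec = spike_spec or load_spike_spec()
    background = background or BackgroundSpec()
    out_dir = Path(out_dir) if out_dir is not None else Path("exosf_fixture")
    out_dir.mkdir(parents=True, exist_ok=True)

    needed = spike_spec.total_carriers
    if spike_spec.constraint_one_finding_per_sample and n_samples < needed:
        raise ValidationError(
            f"n_samples={n_samples} is smaller than the {needed} distinct "
            "carrier samples the spike spec requires"
        )

    rng = np.random.default_rng(seed)
    bg_rng = np.random.default_rng(background.seed if background.seed is not None
                                   else seed + 10007)
    samples = _sample_ids(n_samples)

    # --- spikes ---------------------------------------------------------
    perm = rng.permutation(n_samples)
    cursor = 0
    records: list[SimRecord] = []
    truth: list[TruthRow] = []
    assertion_rows: list[dict] = []
    frequency_rows: list[dict] = []
    for entry in spike_spec.entries:
        if spike_spec.constraint_one_finding_per_sample:
            chosen = [samples[perm[cursor + j]] for j in range(entry.n_carriers)]
            cursor += entry.n_carriers
        else:
            idx = rng.choice(n_samples, size=entry.n_carriers, replace=False)
            chosen = [samples[i] for i in idx]
        chosen.sort()
        rec = SimRecord(
            chrom=entry.key.chrom, pos=entry.key.pos,
            ref=entry.key.ref, alts=(entry.key.alt,),
        )
        for sample in chosen:
            rec.calls[sample] = _good_genotype(rng, entry.zygosity)
        records.append(rec)
        truth.append(TruthRow("spike", entry.key, entry.gene, "survives", tuple(chosen)))
        assertion_rows.append(
            {
                "chrom": entry.key.chrom, "pos": entry.key.pos,
                "ref": entry.key.ref, "alt": entry.key.alt,
                "gene": entry.gene, "consequence": entry.consequence,
                "assertion": entry.assertion,
                "evidence_codes": entry.evidence_codes,
                "hgvs_c": entry.hgvs_c, "hgvs_p": entry.hgvs_p,
            }
        )
        frequency_rows.append(
            {
                "chrom": entry.key.chrom, "pos": entry.key.pos,
                "ref": entry.key.ref, "alt": entry.key.alt,
                "dbsnp": "",
                "gnomad": f"{float(rng.uniform(0, 0.003)):.6f}",
                "inhouse": f"{float(rng.uniform(0, 0.007)):.6f}",
            }
        )

    # --- background -----------------------------------------------------
    anchors: dict[str, tuple[str, int]] = {}
    for entry in spike_spec.entries:
        anchors.setdefault(entry.gene, (entry.key.chrom, entry.key.pos))
    if anchors:
        spiked_positions = {(e.key.chrom, e.key.pos) for e in spike_spec.entries}
        bg_records, bg_truth, bg_assert, bg_freq = simulate_background(
            n_samples, background, bg_rng, anchors, samples,
            taken_positions=spiked_positions,
        )
        records += bg_records
        truth += bg_truth
        assertion_rows += bg_assert
        frequency_rows += bg_freq

    # --- emit -----------------------------------------------------------
    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos))
    vcf_path = write_fixture_vcf(records, samples, out_dir / "cohort.vcf")

    def _table(rows, columns, path):
        df = pd.DataFrame(rows, columns=columns)
        df = df.sort_values(
            by=["chrom", "pos", "alt"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
        )
        df.to_csv(path, sep="\t", index=False)
        return Path(path)

    assertions_path = _table(
        assertion_rows,
        ["chrom", "pos", "ref", "alt", "gene", "consequence", "assertion",
         "evidence_codes", "hgvs_c", "hgvs_p"],
        out_dir / "assertions.tsv",
    )
    freq_cols = ["chrom", "pos", "ref", "alt", *FREQUENCY_SOURCES]
    for row in frequency_rows:
        for col in FREQUENCY_SOURCES:
            row.setdefault(col, "")
    frequencies_path = _table(frequency_rows, freq_cols, out_dir / "frequencies.tsv")

    truth_rows = [
        {
            "record_class": t.record_class,
            "chrom": t.key.chrom, "pos": t.key.pos,
            "ref": t.key.ref, "alt": t.key.alt,
            "gene": t.gene, "expected": t.expected,
            "carrier_samples": ",".join(t.carrier_samples),
        }
        for t in truth
    ]
    truth_path = _table(
        truth_rows,
        ["record_class", "chrom", "pos", "ref", "alt", "gene", "expected",
         "carrier_samples"],
        out_dir / "truth.tsv",
    )
    return FixturePaths(
        vcf=vcf_path, assertions=assertions_path,
        frequencies=frequencies_path, truth=truth_path,
    )
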