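"""End-to-end pipeline: VCF + resource tables -> findings, summary, reports."""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Optional

from . import __version__
from .annotations import load_assertion_table, load_frequency_table
from .cascade import FilterConfig, StageCounts, run_cascade
from .config import config_snapshot
from .registry import GeneRegistry, load_default_panel, load_gene_table
from .reporting import (
    CohortSummary,
    Finding,
    assign_reporting_status,
    checksum_file,
    summarize_cohort,
    write_reports,
)
from .vcfio import read_cohort_vcf


@dataclasses.dataclass
class PipelineResult:
    findings: list[Finding]
    summary: CohortSummary
    stage_counts: StageCounts
    meta: object
    report_paths: dict[str, Path]


def run_pipeline(
    vcf_path,
    assertion_path,
    frequency_path,
    panel_path=None,
    config: Optional[FilterConfig] = None,
    out_dir=None,
    report_carriers: bool = False,
    write_manifest: bool = True,
) -> PipelineResult:
    """Run the full secondary-findings analysis on one cohort VCF.

    Loads the gene panel (packaged 59-gene default unless overridden),
    the assertion and frequency tables, streams the VCF through the
    filter cascade, assigns inheritance-aware reporting statuses and
    summarizes the cohort.  When ``out_dir`` is given, reports and a run
    manifest (input checksums + config snapshot) are written there.
    """
    config = config or FilterConfig()
    registry: GeneRegistry = (
        load_default_panel() if panel_path is None else load_gene_table(panel_path)
    )
    assertions = load_assertion_table(assertion_path)
    frequencies = load_frequency_table(frequency_path)
    meta, stream = read_cohort_vcf(vcf_path)

    filtered, stage_counts = run_cascade(stream, assertions, frequencies, registry, config)
    findings = assign_reporting_status(
        filtered, registry, allowed_verdicts=config.accepted_assertions
    )
    summary = summarize_cohort(findings, meta, registry)

    report_paths: dict[str, Path] = {}
    if out_dir is not None:
        provenance = {
            "inputs": {
                "vcf": checksum_file(vcf_path),
                "assertions": checksum_file(assertion_path),
                "frequencies": checksum_file(frequency_path),
            },
            "config": config_snapshot(config),
        }
        report_paths = write_reports(
            summary,
            findings,
            out_dir,
            stage_counts=stage_counts,
            registry=registry,
            report_carriers=report_carriers,
            provenance=provenance,
        )
        if write_manifest:
            manifest = {
                "tool": "exosf",
                "version": __version__,
                "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                "inputs": provenance["inputs"],
                "config": provenance["config"],
                "stage_counts": stage_counts.as_dict(),
            }
            manifest_path = Path(out_dir) / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
            report_paths["manifest"] = manifest_path

    return PipelineResult(
        findings=findings,
        summary=summary,
        stage_counts=stage_counts,
        meta=meta,
        report_paths=report_paths,
    )
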