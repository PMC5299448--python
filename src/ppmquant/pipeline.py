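"""End-to-end orchestration: quantify -> QC -> differential -> panel -> pathway.

``run_pipeline`` reads a count matrix plus sidecar metadata, converts to
ppm, scores every profile against the housekeeping reference, runs the
paired differential analysis, selects the signature and marker panel,
optionally sums POC chains and overlaps published gene lists, and writes
every report plus a run manifest to the output directory.  Identical
inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, differential, io_formats, pathway, profile_qc, quantify

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run (YAML-loadable)."""

    count_table: str
    metadata: str
    out_dir: str
    housekeeping: str | None = None
    poc_definitions: str | None = None
    gene_lists: list[str] = field(default_factory=list)
    fold_changed: float = 2.0
    fold_signature: float = 4.0
    fold_overlap: float = 1.5
    p_threshold: float = 0.01
    min_panel_ppm: float = 20.0
    low_abundance_ppm: float = 1.0
    min_detected_for_t: int = 3

    def __post_init__(self) -> None:
        for name in (
            "fold_changed",
            "fold_signature",
            "fold_overlap",
            "p_threshold",
            "min_panel_ppm",
            "low_abundance_ppm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def require_inputs(self) -> None:
        """Fail fast, naming the first missing input file."""
        paths = [self.count_table, self.metadata]
        if self.housekeeping:
            paths.append(self.housekeeping)
        if self.poc_definitions:
            paths.append(self.poc_definitions)
        paths.extend(self.gene_lists)
        for p in paths:
            if not Path(p).is_file():
                raise FileNotFoundError(f"pipeline input not found: {p}")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full workflow; returns the output directory.

    Any stage failure aborts with the stage name attached to the error.
    """
    config.require_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "stages": [],
    }

    stage = "quantify"
    try:
        proteins, count_profiles = io_formats.read_count_table(
            config.count_table, config.metadata
        )
        abundances = quantify.quantify_cohort(count_profiles, proteins)
        io_formats.write_abundance_matrix(
            proteins, abundances, out / "abundance_ppm.tsv"
        )
        manifest["stages"].append(stage)
        logger.info("quantify: %d proteins x %d samples", len(proteins), len(abundances))

        stage = "qc"
        if config.housekeeping:
            reference = io_formats.read_reference_list(config.housekeeping)
            reports = [profile_qc.score_profile(a, reference) for a in abundances]
            io_formats.write_qc_reports(reports, out / "qc_scores.tsv")
            io_formats.write_group_coverage(reports, out / "qc_group_coverage.tsv")
            mean_score = sum(r.score for r in reports) / len(reports)
            manifest["mean_qc_score"] = round(mean_score, 3)
            logger.info("qc: mean housekeeping score %.1f", mean_score)
            manifest["stages"].append(stage)

        stage = "differential"
        records = differential.run_differential(
            abundances,
            low_abundance_ppm=config.low_abundance_ppm,
            min_detected_for_t=config.min_detected_for_t,
            fold_changed=config.fold_changed,
            fold_signature=config.fold_signature,
            p_threshold=config.p_threshold,
        )
        io_formats.write_differential_table(records, out / "differential.tsv")
        signature = [r for r in records if r.signature_flag]
        if signature:
            io_formats.write_differential_table(signature, out / "signature.tsv")
        manifest["n_proteins_compared"] = len(records)
        manifest["n_signature"] = len(signature)
        manifest["stages"].append(stage)
        logger.info("differential: %d proteins, %d signature", len(records), len(signature))

        stage = "panel"
        panel = differential.select_marker_panel(records, config.min_panel_ppm)
        if panel:
            io_formats.write_differential_table(panel, out / "marker_panel.tsv")
        manifest["n_panel"] = len(panel)
        manifest["stages"].append(stage)

        stage = "pathway"
        if config.poc_definitions:
            pocs = io_formats.read_poc_definitions(config.poc_definitions)
            poc_results = pathway.compare_poc(abundances, pocs)
            io_formats.write_poc_results(poc_results, out / "poc_results.tsv")
            manifest["stages"].append(stage)

        stage = "overlap"
        if config.gene_lists:
            summaries = []
            for path in config.gene_lists:
                gl = io_formats.read_gene_list(path)
                summaries.append(
                    differential.overlap_with_gene_list(
                        records, gl,
                        fold_de=config.fold_overlap,
                        p_threshold=config.p_threshold,
                    )
                )
            import pandas as pd

            pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
                out / "overlap_summary.tsv", sep="\t", index=False, lineterminator="\n"
            )
            manifest["stages"].append(stage)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
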