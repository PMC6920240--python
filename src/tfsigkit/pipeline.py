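"""Pipeline orchestration: run the full TF-characterization chain from a
single config, writing per-stage TSV tables and a machine-readable JSON
report. Identical configs produce byte-identical outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    ConfigurationError,
    GeneId,
    read_annotation,
    read_gmt,
    read_peaks,
    read_signature,
    write_table,
)
from .peak_to_target import assign_genes, filter_peaks, harmonize_studies, prioritize
from .qpcr_stats import anova_by_timepoint, normalize_ct
from .core_io import read_ct
from .target_enrichment import (
    enrich_tf_targets,
    overlap_with_signature_tfs,
    select_enriched,
)
from .tf_profiling import identify_tfs, partition_by_injury, summarize_profile

logger = logging.getLogger("tfsigkit")


@dataclass
class PipelineConfig:
    """All inputs and thresholds for a pipeline run.

    Threshold defaults are the study's: RF > 1.0, peak intensity >= 10 in
    >= 2 studies, 10 kb TSS window, 5 kb negative-control offset, ORA
    category sizes 2-700 at alpha 0.05, significance tiers
    {0.0005, 0.005, 0.05}, 1% ChIP input.
    """

    signature: str = ""
    tf_catalog: str = ""
    target_db: str = ""
    universe: str = ""                 # optional newline-delimited symbol list
    peaks: dict[str, str] = field(default_factory=dict)  # study_id -> path
    annotation: str = ""
    ct: str = ""
    ct_metadata: str = ""
    housekeeping: list[str] = field(default_factory=list)
    out_dir: str = "tfsigkit_out"
    seed: int = 0
    rf_threshold: float = 1.0
    min_intensity: float = 10.0
    min_studies: int = 2
    window: int = 10_000
    control_offset: int = 5_000
    ora_min_size: int = 2
    ora_max_size: int = 700
    alpha: float = 0.05
    input_fraction: float = 0.01

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _read_universe(path: str) -> list[GeneId]:
    with open(path) as fh:
        return [GeneId(line.strip()) for line in fh if line.strip()]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute profile -> enrichment -> overlap -> peak prioritization
    (qPCR stages when Ct inputs are configured) and write all outputs
    under ``config.out_dir``. Returns the JSON report as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "tfsigkit",
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "counts": {},
    }
    counts = report["counts"]

    signature = read_signature(config.signature)
    counts["n_signature"] = len(signature)
    counts["n_up"] = signature.d_up
    counts["n_down"] = signature.d_down

    # --- TF profile + injury partition -----------------------------------
    profile = None
    if config.tf_catalog:
        catalog = read_gmt(config.tf_catalog)
        profile = identify_tfs(signature, catalog)
        counts["n_tfs"] = len(profile)
        if len(profile):
            injury, _other = partition_by_injury(profile)
            summary = summarize_profile(profile)
            counts["n_injury_tfs"] = len(injury)
            counts["pct_injury"] = summary.pct_injury
        else:
            counts["n_injury_tfs"] = 0
        write_table(
            pd.DataFrame(
                [
                    {"tf": r.tf.symbol, "direction": r.direction.value,
                     "injury": int(r.injury), "source_sets": ";".join(r.source_sets)}
                    for r in profile
                ],
                columns=["tf", "direction", "injury", "source_sets"],
            ),
            out / "tf_profile.tsv",
            sort_by=["tf"],
        )

    # --- target enrichment + overlap -------------------------------------
    if config.target_db:
        target_db = read_gmt(config.target_db)
        if config.universe:
            universe = _read_universe(config.universe)
        else:
            universe = signature.genes
            logger.warning("no universe supplied; defaulting to the signature genes")
        rows = enrich_tf_targets(target_db, signature, universe)
        enriched = select_enriched(rows, config.rf_threshold)
        counts["n_enrichment_rows"] = len(rows)
        counts["n_enriched"] = len({r.tf.symbol for r in enriched})
        write_table(
            pd.DataFrame(
                [
                    {"set_id": r.set_id, "tf": r.tf.symbol, "direction": r.direction.value,
                     "x": r.x, "n": r.n, "D": r.D, "N": r.N, "rf": r.rf}
                    for r in rows
                ],
                columns=["set_id", "tf", "direction", "x", "n", "D", "N", "rf"],
            ),
            out / "enrichment.tsv",
        )
        if profile is not None:
            common = overlap_with_signature_tfs(enriched, profile)
            counts["n_overlap"] = len(common)
            (out / "overlap_tfs.txt").write_text(
                "".join(f"{g.symbol}\n" for g in common)
            )

    # --- peak prioritization ----------------------------------------------
    if config.peaks:
        peaksets = [
            read_peaks(path, study_id) for study_id, path in sorted(config.peaks.items())
        ]
        annotation = read_annotation(config.annotation)
        clusters = harmonize_studies(peaksets)
        kept = filter_peaks(clusters, config.min_intensity, config.min_studies)
        assignments = assign_genes(kept, annotation, config.window)
        targets = prioritize(assignments, signature)
        counts["n_clusters"] = len(clusters)
        counts["n_reproducible_clusters"] = len(kept)
        counts["n_assignments"] = len(assignments)
        counts["n_prioritized_targets"] = len(targets)
        write_table(targets, out / "prioritized_targets.tsv")

    # --- qPCR expression statistics ---------------------------------------
    if config.ct:
        ct = read_ct(config.ct, config.ct_metadata, config.housekeeping)
        norm = normalize_ct(ct)
        anova = anova_by_timepoint(norm)
        counts["n_anova_rows"] = len(anova)
        counts["n_significant_effects"] = int((anova["tier"] != "none").sum())
        write_table(anova, out / "anova.tsv")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("run_pipeline: report written to %s", out / "report.json")
    return report
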