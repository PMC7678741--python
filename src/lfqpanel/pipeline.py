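"""End-to-end pipeline: read, filter, search, test, integrate, report.

``run_pipeline`` chains the stages on real or simulated input files and
writes a single JSON results envelope (with the fully resolved
configuration embedded, so a run can be reproduced bit-for-bit from its
own output) plus per-stage TSV sidecars. ``make_fixture`` materializes
synthetic cohorts as the on-disk files the pipeline reads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from ._version import __version__
from .clinical import FeatureSpec, clinical_variable_search, combined_panel_accuracy
from .containers import ClinicalTable, LFQMatrix
from .errors import AlignmentError, ConfigurationError
from .io import (
    read_annotation,
    read_clinical,
    read_lfq_table,
    write_annotation,
    write_clinical,
    write_lfq_table,
)
from .preprocess import filter_common, filter_min_valid, log2_transform
from .search import search_panels
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    results_to_tsv,
    significant,
    welch_t_volcano,
    wilcoxon_volcano,
)
from .svm import SvmConfig

logger = logging.getLogger("lfqpanel")


@dataclass
class PipelineConfig:
    """Fully resolved settings of one pipeline run."""

    lfq_path: str
    annotation_path: str
    clinical_path: str | None = None
    output_dir: str = "results"
    k: int = 3
    regularization_c: float = 1.0
    svm_tol: float = 1e-6
    standardize: bool = True
    log2: bool = True
    min_valid_fraction: float = 0.5
    alpha: float = 0.05
    welch: bool = True
    chunk_size: int = 100_000
    checkpoint_path: str | None = None
    margin_percent: float = 0.0
    run_clinical: bool = False
    clinical_max_k: int = 3
    clinical_exclusions: list[str] = field(default_factory=list)
    combined_proteins: list[str] = field(default_factory=list)
    combined_clinical: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not os.path.exists(self.lfq_path):
            raise ConfigurationError(f"lfq_path does not exist: {self.lfq_path}")
        if not os.path.exists(self.annotation_path):
            raise AlignmentError(
                f"annotation_path does not exist: {self.annotation_path}"
            )
        if self.clinical_path and not os.path.exists(self.clinical_path):
            raise ConfigurationError(
                f"clinical_path does not exist: {self.clinical_path}"
            )
        if not 1 <= self.k <= 3:
            raise ConfigurationError("k must be in {1, 2, 3}")
        SvmConfig(self.regularization_c, self.svm_tol, self.standardize).validate()
        if not 0 < self.min_valid_fraction <= 1:
            raise ConfigurationError("min_valid_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def svm_config(self) -> SvmConfig:
        return SvmConfig(self.regularization_c, self.svm_tol, self.standardize)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the results envelope.

    Stages: read -> complete-case filter -> log2 -> exhaustive k-panel
    SVM search -> per-protein Wilcoxon on the common proteins ->
    min-valid filter + t-test volcano -> optional clinical-variable
    search and combined protein+clinical scoring. All outputs are
    buffered and written only after every stage succeeded.
    """
    config.validate()
    svm_config = config.svm_config()
    envelope: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    matrix = read_lfq_table(config.lfq_path, config.annotation_path)
    envelope["stages"]["input"] = {
        "n_proteins": matrix.n_proteins,
        "n_samples": matrix.n_samples,
        "n_group_c": int(len(matrix.group_indices("C"))),
        "n_group_a": int(len(matrix.group_indices("A"))),
    }

    common, common_report = filter_common(matrix)
    envelope["stages"]["filter_common"] = common_report.to_dict()
    common_log2 = log2_transform(common) if config.log2 else common

    summary = search_panels(
        common_log2,
        k=config.k,
        svm_config=svm_config,
        chunk_size=config.chunk_size,
        checkpoint_path=config.checkpoint_path,
        margin_percent=config.margin_percent,
    )
    envelope["stages"]["panel_search"] = summary.to_dict()

    wilcoxon = wilcoxon_volcano(common_log2)
    by_id = {r.protein_id: r for r in wilcoxon}
    top_protein_ids = sorted({p for panel in summary.top_panels for p in panel.protein_ids})
    envelope["stages"]["panel_univariate"] = {
        pid: {"p_value": by_id[pid].p_value, "difference": by_id[pid].difference}
        for pid in top_protein_ids
    }

    half, half_report = filter_min_valid(matrix, config.min_valid_fraction)
    half_log2 = log2_transform(half) if config.log2 else half
    volcano = welch_t_volcano(half_log2, alpha=config.alpha, welch=config.welch)
    hits = significant(volcano, config.alpha)
    envelope["stages"]["volcano"] = {
        "filter": half_report.to_dict(),
        "n_tested": sum(r.p_value is not None for r in volcano),
        "n_untestable": sum(r.untestable for r in volcano),
        "n_significant": len(hits),
        "significant_proteins": sorted(r.protein_id for r in hits),
    }

    clinical = read_clinical(config.clinical_path) if config.clinical_path else None
    if config.run_clinical and clinical is not None:
        summaries = clinical_variable_search(
            clinical,
            matrix.group_labels,
            max_k=config.clinical_max_k,
            exclusions=config.clinical_exclusions,
            svm_config=svm_config,
        )
        envelope["stages"]["clinical_search"] = {
            str(k): s.to_dict() for k, s in summaries.items()
        }
    if config.combined_proteins or config.combined_clinical:
        spec = FeatureSpec(
            protein_ids=list(config.combined_proteins),
            clinical_variables=list(config.combined_clinical),
        )
        result, excluded = combined_panel_accuracy(
            common_log2, clinical, spec, svm_config
        )
        envelope["stages"]["combined"] = {
            "feature_spec": dataclasses.asdict(spec),
            "accuracy_percent": result.accuracy_display,
            "n_samples_used": result.n_samples,
            "excluded_samples": excluded,
        }

    os.makedirs(config.output_dir, exist_ok=True)
    with open(os.path.join(config.output_dir, "results.json"), "w") as fh:
        json.dump(envelope, fh, indent=2, sort_keys=True)
    results_to_tsv(wilcoxon, os.path.join(config.output_dir, "wilcoxon_common.tsv"))
    results_to_tsv(volcano, os.path.join(config.output_dir, "volcano.tsv"))
    _panels_to_tsv(summary, os.path.join(config.output_dir, "top_panels.tsv"))
    logger.info(
        "pipeline complete: best %d-panel accuracy %.1f%% over %d combinations",
        config.k, summary.best_accuracy, summary.n_combinations_tested,
    )
    return envelope


def _panels_to_tsv(summary, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_ids", "accuracy_percent"])
        for panel in summary.top_panels:
            writer.writerow([";".join(panel.protein_ids), round(panel.accuracy_percent, 1)])


# ---------------------------------------------------------------------------
# fixture presets

PRESETS: dict[str, dict] = {
    # small enough to run every stage in well under a second
    "tiny": dict(
        n_group_c=5, n_group_a=5, n_proteins=25, n_planted=2,
        effect_size=2.5, missing_rate=0.1,
    ),
    # the cohort geometry the package defaults emulate
    "cohort-like": dict(),
    # nothing planted: group labels carry no proteomic signal
    "null": dict(
        n_group_c=10, n_group_a=10, n_proteins=50, n_planted=0,
        effect_size=0.0, missing_rate=0.1,
    ),
}


def make_fixture(preset: str, seed: int, out_dir: str) -> dict[str, str]:
    """Write a synthetic cohort (LFQ TSV, annotation CSV, clinical CSV,
    ground-truth JSON) for a named preset; returns the file paths."""
    if preset not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    config = SimulationConfig(seed=seed, **PRESETS[preset])
    matrix, clinical, truth = simulate_cohort(config)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "lfq": os.path.join(out_dir, "lfq.tsv"),
        "annotation": os.path.join(out_dir, "annotation.csv"),
        "clinical": os.path.join(out_dir, "clinical.csv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_lfq_table(matrix, paths["lfq"])
    write_annotation(matrix, paths["annotation"])
    write_clinical(clinical, paths["clinical"])
    truth.to_json(paths["ground_truth"])
    return paths
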