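"""SVM analyses of clinical covariates, alone or combined with proteins.

Clinical variables enter the same linear-SVM scoring path as proteins:
binary covariates are coded 0/1, quantitative ones passed through, and
standardization happens inside the SVM fit. Samples missing any selected
variable are excluded listwise *per analysis*, and the number of usable
samples is always part of the result — accuracies over 59 of 60 patients
and over 60 are different claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import ClinicalTable, LFQMatrix
from .errors import AlignmentError, ParameterError
from .search import SearchSummary, search_feature_block
from .svm import ClassificationResult, SvmConfig, fit_and_score

logger = logging.getLogger("lfqpanel")


@dataclass
class FeatureSpec:
    """A combined feature set: proteins plus clinical variables."""

    protein_ids: list[str] = field(default_factory=list)
    clinical_variables: list[str] = field(default_factory=list)
    exclusions: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.protein_ids and not self.clinical_variables:
            raise ParameterError("feature spec selects no features")
        overlap = set(self.exclusions) & set(self.clinical_variables)
        if overlap:
            raise ParameterError(
                f"variables both selected and excluded: {sorted(overlap)}"
            )


def encode_clinical(
    table: ClinicalTable, variables: list[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric sample x variable block for the selected variables.

    Returns ``(features, kept_sample_ids, excluded_sample_ids)`` where
    excluded samples are those missing at least one selected variable.
    """
    if not variables:
        raise ParameterError("no clinical variables selected")
    unknown = [v for v in variables if v not in table.variables]
    if unknown:
        raise ParameterError(
            f"unknown clinical variables {unknown}; available: {table.variables}"
        )
    block = table.data[variables].astype(float)
    complete = ~block.isna().any(axis=1)
    excluded = [str(s) for s in block.index[~complete]]
    if excluded:
        logger.info(
            "encode_clinical: excluded %d sample(s) with missing values: %s",
            len(excluded), excluded,
        )
    kept = block.loc[complete]
    return kept.to_numpy(), [str(s) for s in kept.index], excluded


def _labels_for(sample_ids: list[str], group_labels: dict[str, str]) -> np.ndarray:
    missing = [s for s in sample_ids if s not in group_labels]
    if missing:
        raise AlignmentError(f"samples without group label: {missing}")
    return np.array([group_labels[s] for s in sample_ids])


def clinical_variable_search(
    table: ClinicalTable,
    group_labels: dict[str, str],
    max_k: int = 3,
    exclusions: list[str] | None = None,
    svm_config: SvmConfig | None = None,
) -> dict[int, SearchSummary]:
    """Exhaustive SVM search over clinical-variable subsets of size 1..max_k.

    Excluded variables are removed from the search space before
    enumeration. One summary is returned per subset size, so "adding a
    variable did not improve the score" is directly checkable.
    """
    exclusions = exclusions or []
    usable = [v for v in table.variables if v not in exclusions]
    if len(usable) < 1:
        raise ParameterError("no usable variables after exclusions")
    features, kept_ids, excluded_samples = encode_clinical(table, usable)
    labels = _labels_for(kept_ids, group_labels)
    if excluded_samples:
        logger.info(
            "clinical_variable_search: scoring on %d samples", len(kept_ids)
        )
    summaries: dict[int, SearchSummary] = {}
    for k in range(1, min(max_k, len(usable)) + 1):
        summaries[k] = search_feature_block(
            features=features,
            labels=labels,
            feature_names=usable,
            k=k,
            svm_config=svm_config,
            sample_ids=kept_ids,
        )
    return summaries


def combined_panel_accuracy(
    matrix: LFQMatrix,
    table: ClinicalTable | None,
    spec: FeatureSpec,
    svm_config: SvmConfig | None = None,
) -> tuple[ClassificationResult, list[str]]:
    """Score one explicit protein + clinical feature combination.

    Protein columns are taken from the (filtered, log2) matrix; clinical
    columns from the table. Samples missing any selected clinical value
    are excluded listwise. Returns the classification result and the list
    of excluded sample ids. With an empty clinical list this degenerates
    exactly to the pure-proteome scoring path, and with an empty protein
    list to the pure-clinical path.
    """
    spec.validate()
    blocks: list[np.ndarray] = []
    if spec.clinical_variables:
        if table is None:
            raise ParameterError("clinical variables selected but no table given")
        clin, kept_ids, excluded = encode_clinical(table, spec.clinical_variables)
    else:
        kept_ids = list(matrix.sample_ids)
        excluded = []
        clin = None

    if spec.protein_ids:
        rows = [matrix.row_index(pid) for pid in spec.protein_ids]
        missing_cells = ~matrix.valid_mask[np.ix_(rows, range(matrix.n_samples))]
        if missing_cells.any():
            raise ParameterError(
                "selected proteins have missing values; filter the matrix first"
            )
        col_of = {s: j for j, s in enumerate(matrix.sample_ids)}
        absent = [s for s in kept_ids if s not in col_of]
        if absent:
            raise AlignmentError(
                f"samples in clinical table but not in LFQ matrix: {absent}"
            )
        cols = [col_of[s] for s in kept_ids]
        blocks.append(matrix.intensities[np.ix_(rows, cols)].T)
    if clin is not None:
        blocks.append(clin)

    features = np.hstack(blocks)
    labels = _labels_for(kept_ids, matrix.group_labels)
    _, result = fit_and_score(features, labels, svm_config, sample_ids=kept_ids)
    return result, excluded
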