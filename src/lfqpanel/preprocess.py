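"""Missing-value filtering and the log2 transform.

Two filtering regimes are used on LFQ cohorts:

* ``filter_common`` keeps only proteins quantified in *every* sample —
  required before SVM panel search, which cannot handle missing feature
  values;
* ``filter_min_valid`` keeps proteins with at least a given fraction of
  valid values (default 50%), the conventional pre-filter for univariate
  LFQ statistics.

No imputation is performed anywhere: downstream tests operate on valid
values only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import LFQMatrix
from .errors import ParameterError, PreconditionError

logger = logging.getLogger("lfqpanel")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    rule: str
    per_protein_valid_fraction: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "rule": self.rule,
        }


def filter_common(matrix: LFQMatrix) -> tuple[LFQMatrix, FilterReport]:
    """Retain proteins with a valid quantification in every sample."""
    fractions = matrix.valid_mask.mean(axis=1)
    keep = np.flatnonzero(matrix.valid_mask.all(axis=1))
    report = FilterReport(
        n_input=matrix.n_proteins,
        n_retained=len(keep),
        rule="valid in all samples",
        per_protein_valid_fraction=dict(zip(matrix.protein_ids, fractions)),
    )
    logger.info("filter_common: retained %d of %d proteins", len(keep), matrix.n_proteins)
    if len(keep) == 0:
        logger.warning("filter_common retained zero proteins")
    return matrix.subset_proteins(keep), report


def filter_min_valid(
    matrix: LFQMatrix,
    min_fraction: float = 0.5,
    per_group: bool = False,
) -> tuple[LFQMatrix, FilterReport]:
    """Retain proteins with >= ``min_fraction`` valid values (inclusive).

    By default the fraction is computed over all samples. With
    ``per_group=True`` the rule becomes "at least ``min_fraction`` valid
    in at least one group" (the common alternative in Perseus workflows).
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ParameterError(f"min_fraction must be in (0, 1], got {min_fraction}")
    fractions = matrix.valid_mask.mean(axis=1)
    if per_group:
        idx_c = matrix.group_indices("C")
        idx_a = matrix.group_indices("A")
        frac_c = matrix.valid_mask[:, idx_c].mean(axis=1)
        frac_a = matrix.valid_mask[:, idx_a].mean(axis=1)
        keep_mask = (frac_c >= min_fraction) | (frac_a >= min_fraction)
        rule = f"valid fraction >= {min_fraction} in at least one group"
    else:
        keep_mask = fractions >= min_fraction
        rule = f"valid fraction >= {min_fraction} over all samples"
    keep = np.flatnonzero(keep_mask)
    report = FilterReport(
        n_input=matrix.n_proteins,
        n_retained=len(keep),
        rule=rule,
        per_protein_valid_fraction=dict(zip(matrix.protein_ids, fractions)),
    )
    logger.info(
        "filter_min_valid(%.2f): retained %d of %d proteins",
        min_fraction, len(keep), matrix.n_proteins,
    )
    return matrix.subset_proteins(keep), report


def log2_transform(matrix: LFQMatrix) -> LFQMatrix:
    """Replace every valid intensity by its log2; the mask is unchanged."""
    valid_values = matrix.intensities[matrix.valid_mask]
    if np.any(valid_values <= 0):
        raise PreconditionError(
            "log2_transform: valid cells must be positive (zeros should be masked)"
        )
    out = np.zeros_like(matrix.intensities)
    out[matrix.valid_mask] = np.log2(valid_values)
    return LFQMatrix(
        protein_ids=list(matrix.protein_ids),
        sample_ids=list(matrix.sample_ids),
        intensities=out,
        valid_mask=matrix.valid_mask.copy(),
        group_labels=dict(matrix.group_labels),
    )
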