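"""In-memory containers for LFQ cohorts.

The central object is :class:`LFQMatrix`: a protein-by-sample intensity
matrix with an explicit validity mask (label-free quantification leaves a
protein unquantified in many samples; those cells carry no information and
must never leak into downstream statistics) plus a two-group sample
labelling, group ``"C"`` (cardioembolic-like) vs ``"A"``
(atherothrombotic-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError

GROUPS = ("C", "A")


@dataclass
class LFQMatrix:
    """Protein x sample LFQ intensities with missingness mask and labels.

    Parameters
    ----------
    protein_ids
        Row identifiers (leading-protein accessions), unique.
    sample_ids
        Column identifiers, unique.
    intensities
        ``(n_proteins, n_samples)`` float array. Cells where
        ``valid_mask`` is False are unquantified; their stored value is 0
        by convention and is ignored everywhere downstream.
    valid_mask
        Boolean array of the same shape; True where a quantification exists.
    group_labels
        Mapping ``sample_id -> "C" | "A"``; both groups must be non-empty.
    """

    protein_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    valid_mask: np.ndarray
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.sample_ids = list(self.sample_ids)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        shape = (len(self.protein_ids), len(self.sample_ids))
        if self.intensities.shape != shape:
            raise ConfigurationError(
                f"intensities shape {self.intensities.shape} != {shape}"
            )
        if self.valid_mask.shape != self.intensities.shape:
            raise ConfigurationError("valid_mask shape differs from intensities")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ConfigurationError("protein_ids contains duplicates")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError("sample_ids contains duplicates")
        missing = [s for s in self.sample_ids if s not in self.group_labels]
        if missing:
            raise AlignmentError(f"samples without group label: {missing}")
        bad = {g for g in self.group_labels.values() if g not in GROUPS}
        if bad:
            raise ConfigurationError(f"unknown group labels: {sorted(bad)}")
        labels = self.labels_array()
        for g in GROUPS:
            if not np.any(labels == g):
                raise ConfigurationError(f"group {g!r} has no samples")
        # Masked cells are normalised to 0 so serialized output is canonical.
        self.intensities = np.where(self.valid_mask, self.intensities, 0.0)

    # -- basic geometry -------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def labels_array(self) -> np.ndarray:
        return np.array([self.group_labels[s] for s in self.sample_ids])

    def group_indices(self, group: str) -> np.ndarray:
        """Column indices of samples belonging to *group*."""
        return np.flatnonzero(self.labels_array() == group)

    # -- derived views --------------------------------------------------
    def subset_proteins(self, row_indices: np.ndarray) -> "LFQMatrix":
        row_indices = np.asarray(row_indices, dtype=int)
        return LFQMatrix(
            protein_ids=[self.protein_ids[i] for i in row_indices],
            sample_ids=list(self.sample_ids),
            intensities=self.intensities[row_indices].copy(),
            valid_mask=self.valid_mask[row_indices].copy(),
            group_labels=dict(self.group_labels),
        )

    def row_index(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"protein {protein_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        """DataFrame view with NaN in unquantified cells."""
        values = np.where(self.valid_mask, self.intensities, np.nan)
        return pd.DataFrame(values, index=self.protein_ids, columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LFQMatrix):
            return NotImplemented
        return (
            self.protein_ids == other.protein_ids
            and self.sample_ids == other.sample_ids
            and self.group_labels == other.group_labels
            and np.array_equal(self.valid_mask, other.valid_mask)
            and np.array_equal(
                self.intensities[self.valid_mask], other.intensities[other.valid_mask]
            )
        )


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates aligned to an :class:`LFQMatrix`.

    ``data`` is indexed by sample identifier; ``kinds`` records, for each
    column, whether it is ``"binary"`` (coded 0/1) or ``"quantitative"``.
    Missing cells are NaN.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ConfigurationError(f"kinds for absent variables: {sorted(unknown)}")
        for col in self.data.columns:
            self.kinds.setdefault(col, _infer_kind(self.data[col]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def check_alignment(self, matrix: LFQMatrix) -> None:
        if list(self.data.index) != list(matrix.sample_ids):
            raise AlignmentError(
                "clinical table sample_ids do not match the LFQ matrix"
            )


def _infer_kind(column: pd.Series) -> str:
    observed = column.dropna().unique()
    if len(observed) and set(np.asarray(observed, dtype=float)) <= {0.0, 1.0}:
        return "binary"
    return "quantitative"
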