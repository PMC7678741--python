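"""Reading and writing LFQ protein tables and sample annotations.

The on-disk dialect follows MaxQuant's ``proteinGroups.txt``: a
tab-separated table with one row per protein group, a semicolon-separated
``Protein IDs`` column listing the candidate accessions of the group,
per-candidate ``Peptide counts``, optional annotation-quality columns, and
one ``LFQ intensity <sample>`` column per sample. A protein group is a set
of proteins indistinguishable by their identified peptides; one
representative ("leading") protein is selected per group by peptide count
and annotation quality.

Missing quantifications are written as 0 (MaxQuant's convention) or left
blank; both are read back as masked-invalid cells.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClinicalTable, LFQMatrix
from .errors import AlignmentError, ConfigurationError, FormatError

logger = logging.getLogger("lfqpanel")

LFQ_PREFIX = "LFQ intensity "
_TRUE_TOKENS = {"+", "yes", "true", "1"}


@dataclass
class ProteinGroupRecord:
    """One protein group with per-candidate selection metadata.

    ``existence_evidence`` is ordinal with lower = stronger evidence
    (1 = protein level, 5 = uncertain), as in UniProtKB.
    """

    group_id: str
    candidate_ids: list[str]
    peptide_counts: list[int]
    reviewed: list[bool] = field(default_factory=list)
    existence_evidence: list[int] = field(default_factory=list)
    go_annotation_count: list[int] = field(default_factory=list)
    is_contaminant: bool = False
    is_reverse: bool = False

    def __post_init__(self) -> None:
        n = len(self.candidate_ids)
        if n == 0:
            raise ConfigurationError(f"group {self.group_id!r}: no candidate ids")
        if len(self.peptide_counts) != n:
            raise ConfigurationError(
                f"group {self.group_id!r}: peptide_counts length != candidates"
            )
        if any(c < 0 for c in self.peptide_counts):
            raise ConfigurationError(f"group {self.group_id!r}: negative peptide count")
        if not self.reviewed:
            self.reviewed = [False] * n
        if not self.existence_evidence:
            self.existence_evidence = [5] * n
        if not self.go_annotation_count:
            self.go_annotation_count = [0] * n
        for name in ("reviewed", "existence_evidence", "go_annotation_count"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError(
                    f"group {self.group_id!r}: {name} length != candidates"
                )


def select_leading_protein(record: ProteinGroupRecord) -> str:
    """Pick the representative protein of a group.

    Candidates with the most identified peptides form the match group;
    ties are broken by annotation quality: reviewed (Swiss-Prot) entries
    first, then strongest protein-existence evidence (lowest ordinal),
    then the largest number of GO annotations, and finally the
    lexicographically smallest accession so the choice is deterministic.
    """
    order = sorted(
        range(len(record.candidate_ids)),
        key=lambda i: (
            -record.peptide_counts[i],
            not record.reviewed[i],
            record.existence_evidence[i],
            -record.go_annotation_count[i],
            record.candidate_ids[i],
        ),
    )
    return record.candidate_ids[order[0]]


# ---------------------------------------------------------------------------
# parsing helpers


def _split(cell: str) -> list[str]:
    return [tok.strip() for tok in str(cell).split(";")]


def _parse_counts(cell: str, n: int, default: int = 0) -> list[int]:
    toks = _split(cell)
    if len(toks) == 1 and n > 1:
        toks = toks * n
    out = []
    for tok in toks:
        try:
            out.append(int(float(tok)) if tok else default)
        except ValueError as exc:
            raise FormatError(f"unparseable count {tok!r}") from exc
    if len(out) != n:
        raise FormatError(f"expected {n} counts, got {len(out)}")
    return out


def _parse_flags(cell: str, n: int) -> list[bool]:
    toks = _split(cell)
    if len(toks) == 1 and n > 1:
        toks = toks * n
    return [tok.lower() in _TRUE_TOKENS for tok in toks]


def _record_from_row(row: pd.Series, group_id: str) -> ProteinGroupRecord:
    ids = _split(row["Protein IDs"])
    n = len(ids)
    counts = _parse_counts(row.get("Peptide counts", "0"), n)
    kwargs = {}
    if "Reviewed" in row and not pd.isna(row["Reviewed"]):
        kwargs["reviewed"] = _parse_flags(row["Reviewed"], n)
    if "Evidence" in row and not pd.isna(row["Evidence"]):
        kwargs["existence_evidence"] = _parse_counts(row["Evidence"], n, default=5)
    if "GO count" in row and not pd.isna(row["GO count"]):
        kwargs["go_annotation_count"] = _parse_counts(row["GO count"], n)
    contaminant = False
    for col in ("Contaminant", "Potential contaminant"):
        if col in row and not pd.isna(row[col]):
            contaminant = contaminant or str(row[col]).strip().lower() in _TRUE_TOKENS
    reverse = "Reverse" in row and str(row.get("Reverse", "")).strip().lower() in _TRUE_TOKENS
    return ProteinGroupRecord(
        group_id=group_id,
        candidate_ids=ids,
        peptide_counts=counts,
        is_contaminant=contaminant,
        is_reverse=reverse,
        **kwargs,
    )


def read_annotation(path) -> dict[str, str]:
    """Sample annotation CSV with columns ``sample_id, group`` (C or A)."""
    frame = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(frame.columns):
        raise FormatError(f"annotation must have columns {sorted(required)}")
    labels = dict(zip(frame["sample_id"], frame["group"].str.strip()))
    bad = {g for g in labels.values() if g not in ("C", "A")}
    if bad:
        raise FormatError(f"annotation groups must be C or A, got {sorted(bad)}")
    return labels


def read_lfq_table(path, annotation) -> LFQMatrix:
    """Read a MaxQuant-style LFQ table plus its sample annotation.

    Contaminant- and reverse-flagged rows are dropped (counts logged);
    zeros and blank cells become masked-invalid entries; the leading
    protein of each group becomes the row identifier.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "Protein IDs" not in table.columns:
        raise FormatError("LFQ table lacks a 'Protein IDs' column")
    lfq_cols = [c for c in table.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError("LFQ table has no 'LFQ intensity <sample>' columns")
    sample_ids = [c[len(LFQ_PREFIX):] for c in lfq_cols]

    labels = annotation if isinstance(annotation, dict) else read_annotation(annotation)
    unknown = [s for s in sample_ids if s not in labels]
    if unknown:
        raise AlignmentError(f"samples missing from annotation: {unknown}")

    kept_rows: list[int] = []
    protein_ids: list[str] = []
    n_dropped = 0
    seen: dict[str, int] = {}
    for i, (_, row) in enumerate(table.iterrows()):
        record = _record_from_row(row, group_id=str(i))
        if record.is_contaminant or record.is_reverse:
            n_dropped += 1
            continue
        leading = select_leading_protein(record)
        if leading in seen:
            seen[leading] += 1
            logger.warning("duplicate leading protein %s; suffixing", leading)
            leading = f"{leading}.{seen[leading]}"
        else:
            seen[leading] = 0
        kept_rows.append(i)
        protein_ids.append(leading)
    if n_dropped:
        logger.info("removed %d contaminant/reverse rows of %d", n_dropped, len(table))

    raw = table.iloc[kept_rows][lfq_cols].to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for idx, cell in np.ndenumerate(raw):
        text = str(cell).strip()
        if text in ("", "nan", "NaN"):
            values[idx] = 0.0
        else:
            try:
                values[idx] = float(text)
            except ValueError as exc:
                raise FormatError(f"unparseable intensity {text!r}") from exc
    if np.any(values < 0):
        raise FormatError("negative LFQ intensity encountered")
    mask = values > 0

    return LFQMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        intensities=values,
        valid_mask=mask,
        group_labels={s: labels[s] for s in sample_ids},
    )


def write_lfq_table(matrix: LFQMatrix, path) -> None:
    """Write the matrix in the dialect :func:`read_lfq_table` reads.

    Masked cells are written as 0; peptide counts are written as 1 (the
    table carries single-candidate groups after leading-protein selection).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["Protein IDs", "Peptide counts"] + [
            LFQ_PREFIX + s for s in matrix.sample_ids
        ]
        writer.writerow(header)
        for i, pid in enumerate(matrix.protein_ids):
            row = [pid, "1"] + [
                repr(float(v)) if m else "0"
                for v, m in zip(matrix.intensities[i], matrix.valid_mask[i])
            ]
            writer.writerow(row)


def write_annotation(matrix: LFQMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["sample_id", "group"])
        for s in matrix.sample_ids:
            writer.writerow([s, matrix.group_labels[s]])


def read_clinical(path) -> ClinicalTable:
    """Clinical covariates CSV; first column is ``sample_id``.

    Columns whose non-missing values are all 0/1 are treated as binary.
    """
    frame = pd.read_csv(path)
    if frame.columns[0] != "sample_id":
        raise FormatError("clinical table must start with a 'sample_id' column")
    frame = frame.set_index("sample_id")
    frame.index = frame.index.astype(str)
    return ClinicalTable(data=frame.astype(float))


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, index_label="sample_id")
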