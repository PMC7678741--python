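"""Per-protein two-group tests: Wilcoxon rank-sum and t-test volcano.

Conventions
-----------
* The Wilcoxon rank-sum (Mann-Whitney) test is two-sided ("bilateral"),
  exact when the smaller group has <= 10 observations and the pooled
  values contain no ties, and otherwise uses the normal approximation
  with midranks, tie correction, and continuity correction.
* The volcano difference axis is mean(log2 LFQ in A) - mean(log2 LFQ in
  C): proteins enriched in cardioembolic (C) thrombi have *negative*
  differences.
* ``neg_log10_p`` is -log10(p).
* Raw p-values are reported; Benjamini-Hochberg adjusted q-values are an
  optional extra column, not a filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .containers import LFQMatrix
from .errors import ParameterError

EXACT_MAX_N = 10


@dataclass
class UnivariateResult:
    """One protein's two-group test outcome."""

    protein_id: str
    statistic: float | None
    p_value: float | None
    difference: float | None  # mean(A) - mean(C) on the log2 scale
    n_valid_c: int
    n_valid_a: int
    untestable: bool = False
    q_value: float | None = None

    @property
    def neg_log10_p(self) -> float | None:
        if self.p_value is None:
            return None
        return float(-np.log10(self.p_value))

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "difference": self.difference,
            "neg_log10_p": self.neg_log10_p,
            "n_valid_c": self.n_valid_c,
            "n_valid_a": self.n_valid_a,
            "untestable": self.untestable,
            "q_value": self.q_value,
        }


def wilcoxon_rank_sum(
    values_c: np.ndarray, values_a: np.ndarray, protein_id: str = ""
) -> UnivariateResult:
    """Two-sided Wilcoxon rank-sum test between groups C and A.

    The reported statistic is the rank sum W of group C in the pooled
    midrank ranking. Degenerate input (every pooled value identical)
    carries no evidence and returns p = 1.
    """
    c = np.asarray(values_c, dtype=float)
    a = np.asarray(values_a, dtype=float)
    if c.size == 0 or a.size == 0:
        return UnivariateResult(
            protein_id=protein_id, statistic=None, p_value=None,
            difference=None, n_valid_c=c.size, n_valid_a=a.size, untestable=True,
        )
    pooled = np.concatenate([c, a])
    has_ties = len(np.unique(pooled)) < pooled.size
    diff = float(a.mean() - c.mean())
    ranks = sps.rankdata(pooled)
    w_c = float(ranks[: c.size].sum())

    if np.ptp(pooled) == 0:
        return UnivariateResult(
            protein_id=protein_id, statistic=w_c, p_value=1.0,
            difference=diff, n_valid_c=c.size, n_valid_a=a.size,
        )
    method = (
        "exact"
        if (min(c.size, a.size) <= EXACT_MAX_N and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(
        c, a, alternative="two-sided", method=method, use_continuity=True
    )
    return UnivariateResult(
        protein_id=protein_id,
        statistic=w_c,
        p_value=float(min(res.pvalue, 1.0)),
        difference=diff,
        n_valid_c=c.size,
        n_valid_a=a.size,
    )


def two_sample_t(
    values_c: np.ndarray, values_a: np.ndarray,
    protein_id: str = "", welch: bool = True,
) -> UnivariateResult:
    """Two-sided two-sample t-test (Welch by default, pooled optional).

    The statistic is oriented as A - C, matching the difference axis.
    Returns an untestable result when either group has < 2 valid values.
    """
    c = np.asarray(values_c, dtype=float)
    a = np.asarray(values_a, dtype=float)
    if c.size < 2 or a.size < 2:
        return UnivariateResult(
            protein_id=protein_id, statistic=None, p_value=None,
            difference=float(a.mean() - c.mean()) if c.size and a.size else None,
            n_valid_c=c.size, n_valid_a=a.size, untestable=True,
        )
    diff = float(a.mean() - c.mean())
    if np.ptp(np.concatenate([c, a])) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.ttest_ind(a, c, equal_var=not welch)
        if np.isnan(p):  # zero variance in both groups but unequal means
            stat, p = np.inf * np.sign(diff), 0.0
    return UnivariateResult(
        protein_id=protein_id,
        statistic=float(stat),
        p_value=float(min(p, 1.0)) if p is not None else None,
        difference=diff,
        n_valid_c=c.size,
        n_valid_a=a.size,
    )


def _per_protein(matrix: LFQMatrix):
    idx_c = matrix.group_indices("C")
    idx_a = matrix.group_indices("A")
    for i, pid in enumerate(matrix.protein_ids):
        row = matrix.intensities[i]
        ok = matrix.valid_mask[i]
        yield pid, row[idx_c][ok[idx_c]], row[idx_a][ok[idx_a]]


def add_bh_q_values(results: list[UnivariateResult]) -> list[UnivariateResult]:
    """Attach Benjamini-Hochberg adjusted q-values to testable results."""
    testable = [r for r in results if r.p_value is not None]
    if testable:
        q = sps.false_discovery_control(
            np.array([r.p_value for r in testable]), method="bh"
        )
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
    return results


def welch_t_volcano(
    matrix: LFQMatrix,
    alpha: float = 0.05,
    welch: bool = True,
    bh: bool = False,
) -> list[UnivariateResult]:
    """Volcano statistics for every protein of a log2-scale matrix.

    Valid values only (no imputation); the minimum-valid filter, if
    wanted, is applied upstream via ``filter_min_valid``. Proteins with
    fewer than two valid values in a group are flagged untestable, never
    silently dropped.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    results = [
        two_sample_t(vals_c, vals_a, protein_id=pid, welch=welch)
        for pid, vals_c, vals_a in _per_protein(matrix)
    ]
    if bh:
        add_bh_q_values(results)
    return results


def wilcoxon_volcano(matrix: LFQMatrix, bh: bool = False) -> list[UnivariateResult]:
    """Wilcoxon rank-sum applied to every protein of a matrix."""
    results = [
        wilcoxon_rank_sum(vals_c, vals_a, protein_id=pid)
        for pid, vals_c, vals_a in _per_protein(matrix)
    ]
    if bh:
        add_bh_q_values(results)
    return results


def significant(results: list[UnivariateResult], alpha: float = 0.05):
    """Testable results with p below alpha (no multiplicity correction)."""
    return [r for r in results if r.p_value is not None and r.p_value < alpha]


def results_to_tsv(results: list[UnivariateResult], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["protein_id", "n_valid_c", "n_valid_a", "statistic",
             "p_value", "q_value", "difference", "neg_log10_p", "untestable"]
        )
        for r in results:
            writer.writerow(
                [r.protein_id, r.n_valid_c, r.n_valid_a, r.statistic,
                 r.p_value, r.q_value, r.difference, r.neg_log10_p, r.untestable]
            )
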