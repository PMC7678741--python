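"""Exhaustive SVM panel search over protein combinations.

Every combination of ``k`` (default 3) proteins from a complete-case LFQ
matrix is scored by fitting a linear SVM on that combination's columns
and recording resubstitution accuracy. All combinations tied at the
maximum accuracy are retained (accuracy is an exact ratio of integers,
so ties are exact, not rounding artifacts), and the intersection of the
top panels — proteins recurring in every best panel — is reported.

The search streams combinations in chunks through a compiled batch
scorer; chunking changes neither the result nor its order (the reduction
is an order-independent max + tie collection), and progress can be
checkpointed to survive interruption of multi-hour runs.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import _smo
from .containers import LFQMatrix
from .errors import ParameterError, PreconditionError
from .svm import SvmConfig, fit_and_score, signed_labels, standardize

logger = logging.getLogger("lfqpanel")

DEFAULT_CHUNK = 100_000


def n_combinations(n: int, k: int) -> int:
    """Closed-form count of strictly increasing k-tuples from n items."""
    return math.comb(n, k)


def enumerate_combinations(n: int, k: int):
    """Yield every strictly increasing k-tuple of indices in [0, n).

    Lexicographic order; total count is the binomial coefficient C(n, k).
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of items n={n}")
    return itertools.combinations(range(n), k)


@dataclass
class PanelResult:
    """One scored feature combination (1-3 proteins)."""

    protein_ids: tuple[str, ...]
    accuracy_percent: float
    misclassified_ids: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_ids = tuple(sorted(self.protein_ids))

    def to_dict(self) -> dict:
        return {
            "protein_ids": list(self.protein_ids),
            "accuracy_percent": round(self.accuracy_percent, 1),
            "misclassified_ids": self.misclassified_ids,
        }


@dataclass
class SearchSummary:
    """Outcome of an exhaustive k-combination search."""

    n_combinations_tested: int
    best_accuracy: float
    top_panels: list[PanelResult]
    core_proteins: list[str]
    k: int
    n_features: int

    def to_dict(self) -> dict:
        return {
            "n_combinations_tested": self.n_combinations_tested,
            "best_accuracy_percent": round(self.best_accuracy, 1),
            "k": self.k,
            "n_features": self.n_features,
            "n_top_panels": len(self.top_panels),
            "top_panels": [p.to_dict() for p in self.top_panels],
            "core_proteins": self.core_proteins,
        }


def core_protein_summary(top_panels: list[PanelResult]) -> list[str]:
    """Proteins present in every top panel (exact set intersection)."""
    if not top_panels:
        raise ParameterError("top_panels must be non-empty")
    core = set(top_panels[0].protein_ids)
    for panel in top_panels[1:]:
        core &= set(panel.protein_ids)
    return sorted(core)


def _combo_chunks(n: int, k: int, chunk_size: int, skip: int = 0):
    """Yield (start_index, int64 array of shape (m, k)) chunks."""
    it = enumerate_combinations(n, k)
    if skip:
        next(itertools.islice(it, skip - 1, skip), None)
    start = skip
    while True:
        flat = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(it, chunk_size)),
            dtype=np.int64,
        )
        if flat.size == 0:
            return
        yield start, flat.reshape(-1, k)
        start += flat.size // k


def search_feature_block(
    features: np.ndarray,
    labels,
    feature_names: list[str],
    k: int,
    svm_config: SvmConfig | None = None,
    chunk_size: int = DEFAULT_CHUNK,
    checkpoint_path: str | None = None,
    margin_percent: float = 0.0,
    stream_path: str | None = None,
    sample_ids: list[str] | None = None,
) -> SearchSummary:
    """Score every k-subset of the columns of ``features``.

    The generic engine behind both the proteome trio search and the
    clinical-variable search. ``margin_percent`` widens tie collection to
    panels within that many accuracy points of the running best (0 =
    exact ties only).
    """
    config = svm_config or SvmConfig()
    config.validate()
    X = np.asarray(features, dtype=float)
    n_samples, n_feat = X.shape
    if len(feature_names) != n_feat:
        raise ParameterError("feature_names length != feature columns")
    if k > n_feat:
        raise ParameterError(f"k={k} exceeds {n_feat} available features")
    y = signed_labels(labels)
    if config.standardize:
        Z, _, _ = standardize(X)
    else:
        Z = X.copy()
    Z = np.ascontiguousarray(Z)

    total = n_combinations(n_feat, k)
    margin_counts = int(math.floor(margin_percent * n_samples / 100.0))

    n_done = 0
    best_count = -1
    kept: dict[tuple[int, ...], int] = {}
    if checkpoint_path and os.path.exists(checkpoint_path):
        with open(checkpoint_path) as fh:
            state = json.load(fh)
        if state.get("n_features") == n_feat and state.get("k") == k:
            n_done = state["n_done"]
            best_count = state["best_count"]
            kept = {tuple(c): cnt for c, cnt in state["kept"]}
            logger.info("resuming search at combination %d/%d", n_done, total)

    stream = open(stream_path, "a") if stream_path else None
    try:
        for start, combos in _combo_chunks(n_feat, k, chunk_size, skip=n_done):
            counts = _smo.batch_accuracy(
                Z, y, combos, float(config.regularization_c), float(config.tol),
                200_000,
            )
            if stream is not None:
                for combo, cnt in zip(combos, counts):
                    ids = ";".join(feature_names[i] for i in combo)
                    stream.write(f"{ids}\t{100.0 * cnt / n_samples:.1f}\n")
            chunk_best = int(counts.max())
            if chunk_best > best_count:
                best_count = chunk_best
                kept = {c: n for c, n in kept.items() if n >= best_count - margin_counts}
            threshold = best_count - margin_counts
            for idx in np.flatnonzero(counts >= threshold):
                kept[tuple(int(i) for i in combos[idx])] = int(counts[idx])
            n_done = start + len(combos)
            if checkpoint_path:
                with open(checkpoint_path, "w") as fh:
                    json.dump(
                        {
                            "n_features": n_feat,
                            "k": k,
                            "n_done": n_done,
                            "best_count": best_count,
                            "kept": [[list(c), n] for c, n in kept.items()],
                        },
                        fh,
                    )
            logger.info(
                "search: %d/%d combinations, best accuracy %.1f%%",
                n_done, total, 100.0 * best_count / n_samples,
            )
    finally:
        if stream is not None:
            stream.close()

    survivors = sorted(
        ((c, n) for c, n in kept.items() if n >= best_count - margin_counts),
        key=lambda item: (-item[1], item[0]),
    )

    top_panels = []
    for combo, count in survivors:
        cols = X[:, list(combo)]
        _, result = fit_and_score(cols, labels, config, sample_ids=sample_ids)
        panel = PanelResult(
            protein_ids=tuple(feature_names[i] for i in combo),
            accuracy_percent=result.accuracy_percent,
            misclassified_ids=result.misclassified_ids,
        )
        top_panels.append(panel)

    best_accuracy = 100.0 * best_count / n_samples
    exact_top = [p for p in top_panels if p.accuracy_percent == best_accuracy]
    return SearchSummary(
        n_combinations_tested=total,
        best_accuracy=best_accuracy,
        top_panels=top_panels,
        core_proteins=core_protein_summary(exact_top),
        k=k,
        n_features=n_feat,
    )


def search_panels(
    matrix: LFQMatrix,
    k: int = 3,
    svm_config: SvmConfig | None = None,
    chunk_size: int = DEFAULT_CHUNK,
    checkpoint_path: str | None = None,
    margin_percent: float = 0.0,
    stream_path: str | None = None,
) -> SearchSummary:
    """Exhaustive k-protein panel search on a complete-case matrix.

    The matrix must contain no masked cells (apply ``filter_common``
    first) and is used on whatever intensity scale it carries — the
    pipeline passes log2-transformed values by default.
    """
    if not matrix.valid_mask.all():
        raise PreconditionError(
            "matrix contains missing cells; apply filter_common before searching"
        )
    return search_feature_block(
        features=matrix.intensities.T,
        labels=matrix.labels_array(),
        feature_names=list(matrix.protein_ids),
        k=k,
        svm_config=svm_config,
        chunk_size=chunk_size,
        checkpoint_path=checkpoint_path,
        margin_percent=margin_percent,
        stream_path=stream_path,
        sample_ids=list(matrix.sample_ids),
    )
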