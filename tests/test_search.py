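"""Exhaustive panel search: enumeration, scoring, ties, reproducibility."""

import math

import numpy as np
import pytest

from lfqpanel import (
    LFQMatrix,
    PanelResult,
    ParameterError,
    PreconditionError,
    core_protein_summary,
    enumerate_combinations,
    filter_common,
    log2_transform,
    n_combinations,
    search_panels,
)


def _nested_loop_combos(n, k):
    out = []
    if k == 1:
        out = [(i,) for i in range(n)]
    elif k == 2:
        for i in range(n):
            for j in range(i + 1, n):
                out.append((i, j))
    elif k == 3:
        for i in range(n):
            for j in range(i + 1, n):
                for l in range(j + 1, n):
                    out.append((i, j, l))
    return out


@pytest.mark.parametrize("n,k", [(5, 2), (3, 3), (10, 3), (50, 3), (7, 1)])
def test_enumerator_matches_nested_loop_oracle(n, k):
    combos = list(enumerate_combinations(n, k))
    assert combos == _nested_loop_combos(n, k)
    assert len(combos) == n_combinations(n, k) == math.comb(n, k)


def test_enumerator_rejects_k_larger_than_n():
    with pytest.raises(ParameterError):
        list(enumerate_combinations(2, 3))


def test_trio_count_for_438_common_proteins():
    assert n_combinations(438, 3) == 13_908_836


def _perfect_indicator_matrix():
    rng = np.random.default_rng(5)
    labels = {f"S{i}": ("C" if i < 6 else "A") for i in range(12)}
    intensities = rng.uniform(10, 20, size=(5, 12))
    intensities[2] = [15.0] * 6 + [25.0] * 6  # perfect group indicator
    return LFQMatrix(
        protein_ids=[f"P{i}" for i in range(5)],
        sample_ids=list(labels),
        intensities=intensities,
        valid_mask=np.ones((5, 12), dtype=bool),
        group_labels=labels,
    )


def test_perfect_indicator_singleton_scores_100():
    summary = search_panels(_perfect_indicator_matrix(), k=1)
    assert summary.best_accuracy == 100.0
    assert summary.top_panels[0].protein_ids == ("P2",)


def test_missing_cells_rejected_before_search(tiny_cohort):
    _, matrix, _, _ = tiny_cohort
    with pytest.raises(PreconditionError):
        search_panels(matrix, k=2)


def test_recovers_planted_trio_from_synthetic_cohort(recovery_cohort):
    """With 3 proteins planted at d=2.5 among 30, the best trio holds at
    least two planted proteins."""
    _, matrix, _, truth = recovery_cohort
    common, _ = filter_common(matrix)
    summary = search_panels(log2_transform(common), k=3)
    assert summary.n_combinations_tested == 4060
    planted = set(truth.planted_protein_ids)
    top = summary.top_panels[0]
    assert len(planted & set(top.protein_ids)) >= 2


def test_chunked_and_serial_runs_identical(recovery_cohort):
    _, matrix, _, _ = recovery_cohort
    logm = log2_transform(matrix)
    serial = search_panels(logm, k=2, chunk_size=10**6)
    chunked = search_panels(logm, k=2, chunk_size=17)
    assert serial.best_accuracy == chunked.best_accuracy
    assert [p.protein_ids for p in serial.top_panels] == [
        p.protein_ids for p in chunked.top_panels
    ]
    assert serial.core_proteins == chunked.core_proteins


def test_search_invariant_under_protein_row_order(recovery_cohort):
    _, matrix, _, _ = recovery_cohort
    logm = log2_transform(matrix)
    perm = np.random.default_rng(1).permutation(matrix.n_proteins)
    shuffled = logm.subset_proteins(perm)
    a = search_panels(logm, k=2)
    b = search_panels(shuffled, k=2)
    assert a.best_accuracy == b.best_accuracy
    assert sorted(p.protein_ids for p in a.top_panels) == sorted(
        p.protein_ids for p in b.top_panels
    )


def test_checkpoint_resume_matches_uninterrupted_run(recovery_cohort, tmp_path):
    _, matrix, _, _ = recovery_cohort
    logm = log2_transform(matrix)
    full = search_panels(logm, k=2)
    ckpt = tmp_path / "state.json"
    # simulate an interrupted run: process only the first chunk, then resume
    try:
        search_panels(logm, k=2, chunk_size=50, checkpoint_path=str(ckpt),
                      stream_path=str(tmp_path / "halt"))
    except Exception:
        pass
    import json

    state = json.loads(ckpt.read_text())
    state["n_done"] = 100
    ckpt.write_text(json.dumps(state))
    resumed = search_panels(logm, k=2, chunk_size=50, checkpoint_path=str(ckpt))
    assert resumed.best_accuracy == full.best_accuracy
    assert [p.protein_ids for p in resumed.top_panels] == [
        p.protein_ids for p in full.top_panels
    ]


def test_monotone_recovery_in_effect_size():
    """Probability of planting members in the top panel does not decrease
    with effect size (checked at d in {0, 1, 2.5}, a few seeds each)."""
    from lfqpanel import SimulationConfig, simulate_cohort

    hits = {}
    for d in (0.0, 1.0, 2.5):
        count = 0
        for seed in range(4):
            config = SimulationConfig(
                n_group_c=12, n_group_a=12, n_proteins=15, n_planted=3,
                effect_size=d, missing_rate=0.0, seed=100 + seed,
            )
            matrix, _, truth = simulate_cohort(config)
            summary = search_panels(log2_transform(matrix), k=2)
            top = set(summary.top_panels[0].protein_ids)
            count += len(top & set(truth.planted_protein_ids))
        hits[d] = count
    assert hits[0.0] <= hits[2.5]
    assert hits[1.0] <= hits[2.5] + 1  # allow one-seed noise at mid effect


# --- core-protein summary ---------------------------------------------------


def _panel(*ids):
    return PanelResult(protein_ids=tuple(ids), accuracy_percent=88.3)


def test_core_is_intersection_of_top_panels():
    panels = [_panel("X", "Y", "Z"), _panel("X", "U", "V"), _panel("X", "P", "Q")]
    assert core_protein_summary(panels) == ["X"]


def test_core_of_single_panel_is_whole_panel():
    assert core_protein_summary([_panel("A", "B")]) == ["A", "B"]


def test_core_of_disjoint_panels_is_empty():
    assert core_protein_summary([_panel("A", "B"), _panel("C", "D")]) == []
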