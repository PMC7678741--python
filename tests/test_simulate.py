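"""Synthetic-cohort generator: determinism, planted effects, missingness."""

import numpy as np
import pytest
from scipy import stats as sps

from lfqpanel import (
    ConfigurationError,
    CovariateSpec,
    SimulationConfig,
    simulate_clinical,
    simulate_cohort,
)


def test_no_missingness_no_effect_case():
    config = SimulationConfig(
        n_group_c=2, n_group_a=2, n_proteins=5, n_planted=0,
        missing_rate=0.0, seed=1,
    )
    matrix, _, truth = simulate_cohort(config)
    assert matrix.intensities.shape == (5, 4)
    assert matrix.valid_mask.all()
    assert truth.planted_protein_ids == []


def test_same_seed_bit_identical():
    config = SimulationConfig(
        n_group_c=4, n_group_a=4, n_proteins=30, n_planted=2, seed=11,
        missing_rate=0.2,
    )
    m1, c1, t1 = simulate_cohort(config)
    m2, c2, t2 = simulate_cohort(config)
    assert np.array_equal(m1.intensities, m2.intensities)
    assert np.array_equal(m1.valid_mask, m2.valid_mask)
    assert c1.data.equals(c2.data)
    assert t1.planted_protein_ids == t2.planted_protein_ids


def test_planted_proteins_shift_group_c_by_stated_effect():
    config = SimulationConfig(
        n_group_c=400, n_group_a=400, n_proteins=20, n_planted=4,
        effect_size=2.0, base_log2_sd=1.5, missing_rate=0.0, seed=5,
    )
    matrix, _, truth = simulate_cohort(config)
    idx_c = matrix.group_indices("C")
    idx_a = matrix.group_indices("A")
    log2 = np.log2(matrix.intensities)
    se = config.base_log2_sd * np.sqrt(2 / 400)
    for pid in truth.planted_protein_ids:
        i = matrix.row_index(pid)
        observed = log2[i, idx_c].mean() - log2[i, idx_a].mean()
        assert observed == pytest.approx(
            truth.per_protein_effect[pid], abs=5 * se
        )
    unplanted = [p for p in matrix.protein_ids if p not in truth.planted_protein_ids]
    diffs = [
        log2[matrix.row_index(p), idx_c].mean() - log2[matrix.row_index(p), idx_a].mean()
        for p in unplanted
    ]
    assert np.all(np.abs(diffs) < 5 * se)


def test_null_wilcoxon_pvalues_uniform():
    """With effect_size=0 the per-protein p-value distribution is uniform."""
    config = SimulationConfig(
        n_group_c=15, n_group_a=15, n_proteins=1000, n_planted=0,
        effect_size=0.0, missing_rate=0.0, seed=2,
    )
    matrix, _, _ = simulate_cohort(config)
    idx_c = matrix.group_indices("C")
    idx_a = matrix.group_indices("A")
    pvals = [
        sps.mannwhitneyu(row[idx_c], row[idx_a], alternative="two-sided").pvalue
        for row in matrix.intensities
    ]
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


def test_missingness_monotone_in_intensity():
    """Low-abundance quartile drops out at least as often as the top quartile."""
    config = SimulationConfig(
        n_group_c=30, n_group_a=30, n_proteins=300, n_planted=0,
        missing_rate=0.3, missing_intensity_slope=1.5, seed=9,
    )
    matrix, _, _ = simulate_cohort(config)
    valid = matrix.valid_mask
    assert 0.2 < (~valid).mean() < 0.45  # marginal near the configured rate
    # oracle for the underlying abundances: the same seed with
    # missing_rate=0 draws identical intensities with nothing masked
    import dataclasses

    full, _, _ = simulate_cohort(dataclasses.replace(config, missing_rate=0.0))
    assert np.array_equal(
        full.intensities[valid], matrix.intensities[valid]
    )
    log2 = np.log2(full.intensities).ravel()
    missing = (~valid).ravel()
    q1, q3 = np.quantile(log2, [0.25, 0.75])
    low_rate = missing[log2 <= q1].mean()
    high_rate = missing[log2 >= q3].mean()
    assert low_rate > high_rate


def test_marginal_missing_rate_calibrated_for_any_slope():
    for slope in (0.0, 1.0, 3.0):
        config = SimulationConfig(
            n_group_c=50, n_group_a=50, n_proteins=200, n_planted=0,
            missing_rate=0.25, missing_intensity_slope=slope, seed=4,
        )
        matrix, _, _ = simulate_cohort(config)
        rate = (~matrix.valid_mask).mean()
        assert rate == pytest.approx(0.25, abs=0.02)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_group_c=0),
        dict(n_proteins=0),
        dict(n_planted=10, n_proteins=5),
        dict(missing_rate=1.5),
        dict(effect_size=float("inf")),
        dict(missing_intensity_slope=-1.0),
    ],
)
def test_invalid_config_rejected(kwargs):
    config = SimulationConfig(**kwargs)
    with pytest.raises(ConfigurationError):
        simulate_cohort(config)


# --- clinical covariates ----------------------------------------------------


def test_binary_covariate_prevalence_one_zero_equals_group_indicator():
    config = SimulationConfig(
        n_group_c=10, n_group_a=10, n_proteins=5, n_planted=0, seed=6,
        clinical_spec=[CovariateSpec("marker", "binary", p_c=1.0, p_a=0.0)],
    )
    matrix, clinical, truth = simulate_cohort(config)
    for sid in clinical.sample_ids:
        expected = 1.0 if truth.group_assignment[sid] == "C" else 0.0
        assert clinical.data.loc[sid, "marker"] == expected


def test_binary_covariate_counts_match_binomial_expectation():
    """Prevalence 0.625 in C (n=32) and 0.036 in A (n=28): replicate draws
    average ~20 and ~1 positives, within binomial standard error."""
    spec = [CovariateSpec("af", "binary", p_c=0.625, p_a=0.036)]
    counts_c, counts_a = [], []
    n_rep = 400
    for rep in range(n_rep):
        config = SimulationConfig(
            n_group_c=32, n_group_a=28, n_proteins=1, n_planted=0,
            seed=100_000 + rep, clinical_spec=spec,
        )
        _, clinical, truth = simulate_cohort(config)
        vals = clinical.data["af"]
        in_c = [s for s in clinical.sample_ids if truth.group_assignment[s] == "C"]
        in_a = [s for s in clinical.sample_ids if truth.group_assignment[s] == "A"]
        counts_c.append(vals[in_c].sum())
        counts_a.append(vals[in_a].sum())
    se_c = np.sqrt(32 * 0.625 * 0.375 / n_rep)
    se_a = np.sqrt(28 * 0.036 * 0.964 / n_rep)
    assert np.mean(counts_c) == pytest.approx(20.0, abs=4 * se_c)
    assert np.mean(counts_a) == pytest.approx(1.008, abs=4 * se_a)


def test_empty_clinical_spec_gives_ids_only():
    config = SimulationConfig(
        n_group_c=3, n_group_a=3, n_proteins=4, n_planted=0, seed=8,
        clinical_spec=[],
    )
    _, clinical, _ = simulate_cohort(config)
    assert clinical.variables == []
    assert len(clinical.sample_ids) == 6


def test_invalid_prevalence_rejected():
    config = SimulationConfig(
        n_group_c=3, n_group_a=3, n_proteins=4, n_planted=0, seed=8,
        clinical_spec=[CovariateSpec("bad", "binary", p_c=1.2, p_a=0.0)],
    )
    with pytest.raises(ConfigurationError):
        simulate_cohort(config)


def test_simulate_clinical_standalone_matches_cohort_call(tiny_cohort):
    config, _, clinical, truth = tiny_cohort
    again = simulate_clinical(config, truth)
    assert again.data.equals(clinical.data)
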