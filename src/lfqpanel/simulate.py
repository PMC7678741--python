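"""Synthetic LFQ cohorts with known ground truth.

The generator emulates the statistical structure of a two-group
thrombus-proteomics cohort: log2-normal protein intensities, a configurable
set of "planted" discriminative proteins whose group means differ by a
stated standardized effect size, intensity-dependent missingness (low-
abundance proteins drop out more often, as in data-dependent-acquisition
LFQ), and clinical covariates with configurable group association.

Defaults reproduce the cohort geometry this package was built around:
32 cardioembolic-like (group C) vs 28 atherothrombotic-like (group A)
samples, 2,455 proteins, and a marginal per-cell missingness of 2.8% —
chosen so that the expected number of proteins quantified in all 60
samples is ~438 of 2,455, matching the complete-case fraction of a real
mechanical-thrombectomy cohort.

Reproducibility: one :class:`numpy.random.SeedSequence` keyed by ``seed``
is split into named sub-streams (group layout, one per protein, clinical),
so the values drawn for protein *i* do not depend on how many proteins are
simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .containers import ClinicalTable, LFQMatrix
from .errors import ConfigurationError

import pandas as pd


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated clinical covariate.

    Binary covariates are Bernoulli per group with prevalences
    ``p_c`` / ``p_a``; quantitative covariates are normal with
    ``mean_c``/``sd_c`` and ``mean_a``/``sd_a``.
    """

    name: str
    kind: str  # "binary" | "quantitative"
    p_c: float | None = None
    p_a: float | None = None
    mean_c: float | None = None
    mean_a: float | None = None
    sd_c: float = 1.0
    sd_a: float = 1.0

    def validate(self) -> None:
        if self.kind not in ("binary", "quantitative"):
            raise ConfigurationError(
                f"covariate {self.name!r}: kind must be binary|quantitative"
            )
        if self.kind == "binary":
            for label, p in (("p_c", self.p_c), ("p_a", self.p_a)):
                if p is None or not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"covariate {self.name!r}: {label} must be in [0,1], got {p}"
                    )
        else:
            if self.mean_c is None or self.mean_a is None:
                raise ConfigurationError(
                    f"covariate {self.name!r}: mean_c and mean_a required"
                )
            if self.sd_c <= 0 or self.sd_a <= 0:
                raise ConfigurationError(
                    f"covariate {self.name!r}: sds must be positive"
                )


def default_clinical_spec() -> list[CovariateSpec]:
    """Covariates mirroring a cardioembolic/atherothrombotic stroke cohort.

    Prevalences and locations follow the descriptive statistics of such
    cohorts (atrial fibrillation strongly C-associated, cardiac failure
    C-only, atherothrombotic patients younger with higher platelets);
    interquartile ranges are converted to SDs via IQR/1.35.
    """
    return [
        CovariateSpec("age", "quantitative", mean_c=79.5, mean_a=67.5, sd_c=10.0, sd_a=14.8),
        CovariateSpec("male_sex", "binary", p_c=0.563, p_a=0.714),
        CovariateSpec("cardiac_failure", "binary", p_c=0.188, p_a=0.0),
        CovariateSpec("atrial_fibrillation", "binary", p_c=0.625, p_a=0.036),
        CovariateSpec("antithrombotic_medication", "binary", p_c=0.625, p_a=0.393),
        CovariateSpec("glycemia", "quantitative", mean_c=6.8, mean_a=6.8, sd_c=1.0, sd_a=1.8),
        CovariateSpec("weight", "quantitative", mean_c=71.0, mean_a=79.0, sd_c=15.6, sd_a=17.8),
        CovariateSpec("bmi", "quantitative", mean_c=24.4, mean_a=26.0, sd_c=3.5, sd_a=5.0),
        CovariateSpec("thrombus_weight", "quantitative", mean_c=31.2, mean_a=36.0, sd_c=20.0, sd_a=20.0),
        CovariateSpec("protein_concentration", "quantitative", mean_c=11.2, mean_a=11.1, sd_c=3.5, sd_a=4.0),
        CovariateSpec("hemoglobin", "quantitative", mean_c=13.5, mean_a=13.8, sd_c=1.9, sd_a=1.4),
        CovariateSpec("leucocytes", "quantitative", mean_c=8.9, mean_a=10.3, sd_c=4.0, sd_a=2.3),
        CovariateSpec("platelets", "quantitative", mean_c=203.0, mean_a=250.0, sd_c=44.0, sd_a=66.0),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` is a standardized mean difference (Cohen's d) on the
    log2 scale: planted proteins are shifted by
    ``effect_size * base_log2_sd`` log2 units in group C (sign
    configurable per protein through ``planted_signs``).

    ``missing_rate`` is the *marginal* probability that a cell is
    unquantified; ``missing_intensity_slope`` (>= 0) controls how strongly
    missingness concentrates in low-abundance cells (0 = completely at
    random). The logistic intercept is calibrated numerically so the
    marginal rate stays at ``missing_rate`` for any slope.
    """

    n_group_c: int = 32
    n_group_a: int = 28
    n_proteins: int = 2455
    n_planted: int = 3
    effect_size: float = 2.5
    base_log2_mean: float = 25.0
    base_log2_sd: float = 1.5
    missing_rate: float = 0.028
    missing_intensity_slope: float = 1.0
    seed: int = 0
    planted_signs: list[int] | None = None
    clinical_spec: list[CovariateSpec] = field(default_factory=default_clinical_spec)

    def validate(self) -> None:
        for name in ("n_group_c", "n_group_a", "n_proteins"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.n_planted <= self.n_proteins:
            raise ConfigurationError("n_planted must be in [0, n_proteins]")
        if not math.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")
        if self.missing_intensity_slope < 0:
            raise ConfigurationError("missing_intensity_slope must be >= 0")
        if self.base_log2_sd <= 0:
            raise ConfigurationError("base_log2_sd must be positive")
        if self.planted_signs is not None and len(self.planted_signs) != self.n_planted:
            raise ConfigurationError("planted_signs length must equal n_planted")
        for spec in self.clinical_spec:
            spec.validate()


@dataclass
class GroundTruth:
    """What was planted: discriminative proteins and the group layout."""

    planted_protein_ids: list[str]
    per_protein_effect: dict[str, float]  # signed log2 shift applied in group C
    group_assignment: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)


def _missingness_intercept(rate: float, slope: float) -> float:
    """Logistic intercept b with E_z[sigmoid(b - slope*z)] = rate, z ~ N(0,1)."""
    if rate <= 0.0:
        return -np.inf
    if rate >= 1.0:
        return np.inf
    if slope == 0.0:
        return float(logit(rate))
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()

    def marginal(b: float) -> float:
        return float(np.sum(weights * expit(b - slope * nodes)) - rate)

    hi = float(logit(rate)) + 5 * (1 + slope)
    lo = float(logit(rate)) - 5 * (1 + slope)
    return float(brentq(marginal, lo, hi, xtol=1e-12))


def _sample_ids(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    ids_c = [f"C{i + 1:02d}" for i in range(config.n_group_c)]
    ids_a = [f"A{i + 1:02d}" for i in range(config.n_group_a)]
    assignment = {s: "C" for s in ids_c} | {s: "A" for s in ids_a}
    return ids_c + ids_a, assignment


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[LFQMatrix, ClinicalTable, GroundTruth]:
    """Draw one cohort; identical seeds give bit-identical outputs.

    Returns the raw-scale LFQ matrix (masked cells stored as 0), the
    clinical table, and the ground truth of planted effects.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    # child 0: layout (planted choice), children 1..n_proteins: per protein,
    # child n_proteins+1: clinical covariates.
    children = master.spawn(config.n_proteins + 2)
    layout_rng = np.random.default_rng(children[0])

    sample_ids, assignment = _sample_ids(config)
    n_c = config.n_group_c
    n_samples = n_c + config.n_group_a

    width = len(str(config.n_proteins))
    protein_ids = [f"P{i + 1:0{width}d}" for i in range(config.n_proteins)]
    planted_idx = np.sort(
        layout_rng.choice(config.n_proteins, size=config.n_planted, replace=False)
    )
    signs = (
        np.asarray(config.planted_signs, dtype=float)
        if config.planted_signs is not None
        else np.ones(config.n_planted)
    )
    shift = config.effect_size * config.base_log2_sd
    effects = {int(i): float(s * shift) for i, s in zip(planted_idx, signs)}

    intercept = _missingness_intercept(
        config.missing_rate, config.missing_intensity_slope
    )

    log2 = np.empty((config.n_proteins, n_samples))
    valid = np.empty((config.n_proteins, n_samples), dtype=bool)
    for i in range(config.n_proteins):
        rng = np.random.default_rng(children[i + 1])
        z = rng.standard_normal(n_samples)
        row = config.base_log2_mean + config.base_log2_sd * z
        if i in effects:
            row[:n_c] += effects[i]
        # standardize against the base distribution, incl. any planted shift
        zscore = (row - config.base_log2_mean) / config.base_log2_sd
        p_miss = expit(intercept - config.missing_intensity_slope * zscore)
        valid[i] = rng.uniform(size=n_samples) >= p_miss
        log2[i] = row

    intensities = np.where(valid, np.exp2(log2), 0.0)
    matrix = LFQMatrix(
        protein_ids=protein_ids,
        sample_ids=sample_ids,
        intensities=intensities,
        valid_mask=valid,
        group_labels=assignment,
    )
    truth = GroundTruth(
        planted_protein_ids=[protein_ids[i] for i in planted_idx],
        per_protein_effect={protein_ids[i]: e for i, e in effects.items()},
        group_assignment=assignment,
    )
    clinical = simulate_clinical(config, truth, _seed_sequence=children[-1])
    return matrix, clinical, truth


def simulate_clinical(
    config: SimulationConfig,
    truth: GroundTruth,
    _seed_sequence: np.random.SeedSequence | None = None,
) -> ClinicalTable:
    """Draw clinical covariates per group as specified in ``clinical_spec``.

    Binary covariates are Bernoulli with per-group prevalence; quantitative
    covariates normal with per-group mean/SD. When called directly (outside
    :func:`simulate_cohort`) the stream is derived from ``config.seed`` the
    same way, so the same table is produced either way.
    """
    for spec in config.clinical_spec:
        spec.validate()
    if _seed_sequence is None:
        _seed_sequence = np.random.SeedSequence(config.seed).spawn(
            config.n_proteins + 2
        )[-1]
    rng = np.random.default_rng(_seed_sequence)

    sample_ids = sorted(truth.group_assignment, key=_cohort_order)
    is_c = np.array([truth.group_assignment[s] == "C" for s in sample_ids])
    n = len(sample_ids)

    columns: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for spec in config.clinical_spec:
        if spec.kind == "binary":
            p = np.where(is_c, spec.p_c, spec.p_a)
            columns[spec.name] = (rng.uniform(size=n) < p).astype(float)
        else:
            mean = np.where(is_c, spec.mean_c, spec.mean_a)
            sd = np.where(is_c, spec.sd_c, spec.sd_a)
            columns[spec.name] = mean + sd * rng.standard_normal(n)
        kinds[spec.name] = spec.kind

    data = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    return ClinicalTable(data=data, kinds=kinds)


def _cohort_order(sample_id: str) -> tuple[int, str]:
    # C-group first, then A-group, each in numeric order — the layout
    # simulate_cohort writes.
    return (0 if sample_id.startswith("C") else 1, sample_id)
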