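# Methods

`lfqpanel` implements a complete analysis chain for two-group label-free
quantification (LFQ) proteomics cohorts, built around an exhaustive
combinatorial search for small discriminative protein panels. The two
groups are labelled C (cardioembolic-like) and A (atherothrombotic-like)
throughout, after the stroke-etiology setting the pipeline was designed
for, but nothing in the code is specific to that application.

## Data model

An LFQ cohort is a protein × sample intensity matrix with an explicit
validity mask. In data-dependent-acquisition LFQ a protein is frequently
not quantified in a sample; the on-disk convention (MaxQuant
`proteinGroups`-style tables) writes such cells as 0, and hand-edited
tables may leave them blank. Both are read back as *masked-invalid*
cells that carry no information: no statistic, filter, or model in this
package ever consumes a masked value, and no imputation is performed
anywhere. Where an imputation-based workflow (e.g. a Perseus default)
would fill missing values before testing, this package instead tests on
the valid values only and reports per-group valid counts alongside every
p-value.

Each table row is a *protein group* — proteins indistinguishable by
their identified peptides. One representative is selected per group:
candidates with the most identified peptides form the match group, and
remaining ties are broken by annotation quality (reviewed entries first,
then strongest protein-existence evidence, then most GO annotations). A
final lexicographic tie-break is added so selection is fully
deterministic; annotation metadata are taken from table columns, not
from live database queries.

## Filtering and transformation

Two filtering regimes feed the two analysis branches:

* **Complete-case filter** (`filter_common`): keep proteins quantified
  in every sample. The SVM search cannot handle missing feature values,
  so it operates on this matrix.
* **Minimum-valid filter** (`filter_min_valid`, default fraction 0.5,
  inclusive boundary): the conventional pre-filter for univariate
  statistics. The fraction is counted over all samples by default; a
  per-group mode ("≥ fraction in at least one group") is available via
  a flag. The complete-case filter is exactly the min-valid filter at
  fraction 1.0, and both are idempotent.

All downstream statistics and the SVM operate on log2-transformed
intensities (raw scale available behind a flag).

## Linear SVM and resubstitution accuracy

Discriminability of a feature set is measured with the standard
soft-margin linear SVM: minimize ½‖w‖² + C·Σᵢ max(0, 1 − yᵢ(w·xᵢ + b)),
with group C coded +1. Features are z-score standardized before fitting
(LFQ intensities span orders of magnitude; standardization makes the
accuracy invariant to per-feature affine rescaling). Defaults: linear
kernel, C = 1, standardization on — all configurable, since none is
dictated by the problem.

The dual problem is solved by an in-house sequential minimal
optimization (SMO) routine with maximal-violating-pair working-set
selection, KKT tolerance 1e-6, no randomized initialization, and
first-index tie-breaking — fully deterministic, which matters because
the panel search ranking must be reproducible bit-for-bit. The solver is
JIT-compiled (numba) and scores a 60-sample, 3-feature subset in well
under a millisecond, which is what makes exhaustive trio enumeration
practical on one CPU. Correctness is cross-checked in the test suite
against an independent reference implementation (sklearn's libsvm-based
`SVC`) on random instances: predictions must agree on ≥95% of instances,
and in practice agree on all of them, with weight vectors matching to
~1e-6.

Panels are scored by **resubstitution accuracy**: the fraction of
training samples the fitted hyperplane classifies correctly. With
cohorts of a few dozen samples, held-out validation of an exhaustive
million-panel search is not meaningful; resubstitution answers the
narrower question "does a hyperplane exist that separates these
samples", and all reported accuracies must be read that way —
as descriptive separability of this cohort, never as expected
generalization. Accuracy is an exact ratio of integers; ranking and tie
detection use the full-precision value, and rounding to one decimal
happens only at display time.

## Exhaustive panel search

All C(n, k) combinations of k ≤ 3 proteins from the complete-case matrix
are enumerated in lexicographic order (438 common proteins give
13,908,836 trios) and scored. *All* combinations tied at the maximum
accuracy are retained — ties are exact, and with strong markers they are
common: any trio containing a single perfectly separating protein ties
at 100%. The intersection of the tied top panels ("core proteins")
identifies the members no best panel can do without. Because exact ties
are first-class results, ground-truth-recovery checks on synthetic data
are evaluated against the tie set, not against an arbitrary first
element of it.

The search streams combinations in chunks through the batch scorer; the
reduction (max + tie collection keyed by combination) is independent of
the chunking, so serial and chunked runs produce identical summaries,
and an optional JSON checkpoint makes multi-hour full-scale searches
restartable.

## Univariate statistics

* **Wilcoxon rank-sum (Mann-Whitney), two-sided**: exact enumeration
  when the smaller group has ≤10 observations and the pooled values are
  tie-free; otherwise the normal approximation with midranks, tie
  correction, and continuity correction. Degenerate input (all pooled
  values identical) returns p = 1. The exact path is verified against
  full permutation enumeration for every group split with n ≤ 10.
* **t-test volcano**: per protein, a two-sample t-test on valid values
  only. Welch (unequal variance) is the default; the pooled-variance
  Student form is a flag, since equal group variances should not be
  assumed for LFQ data. The difference axis is mean(log2 A) −
  mean(log2 C), so C-enriched proteins plot at negative differences;
  the p-value axis is −log10 p (base 10). Raw p-values are reported;
  Benjamini–Hochberg q-values are an opt-in column, not a filter.
  Proteins with fewer than two valid values in a group are flagged
  untestable rather than dropped.

## Clinical covariates

Clinical variables join the same scoring path: binary covariates coded
0/1, quantitative passed through, standardization shared with the
proteins inside the SVM. Samples missing any selected variable are
excluded listwise per analysis, and the excluded count is always part of
the result — an accuracy over 59 of 60 patients and over 60 are
different claims. The clinical search enumerates subsets of size
1..max_k and reports the best subset *per size*, so "adding a variable
did not improve the score" is directly checkable; excluded variables are
removed from the search space before enumeration. Combined
protein+clinical scoring concatenates the feature blocks and degenerates
exactly to the pure-proteome or pure-clinical path when one block is
empty (asserted in tests).

## Synthetic cohorts and what they do (not) show

The generator draws log2 intensities i.i.d. normal
(`base_log2_mean` = 25, `base_log2_sd` = 1.5, typical of MaxQuant LFQ on
the log2 scale). A configurable number of "planted" proteins get a group
C mean shift of `effect_size × base_log2_sd` (Cohen's d; sign
configurable per protein, C-upward by default so planted markers appear
cardioembolic-enriched, i.e. at negative volcano differences).

Missingness is intensity-dependent: cell i,j is masked with probability
σ(b − slope·z_ij), where z is the standardized log2 intensity and the
intercept b is calibrated by Gauss–Hermite quadrature so that the
*marginal* missing rate equals `missing_rate` for any slope. Real LFQ
missingness mechanisms are not characterized well enough to fix this
form from data; the logistic left-censoring model is an explicit
assumption. Default marginal rate 0.028 with slope 1 makes the expected
complete-case count ≈440 of 2,455 proteins over 60 samples, emulating
the complete-case structure of a real thrombectomy cohort (438/2,455).

Cohort defaults are 32 group-C and 28 group-A samples. Clinical
covariates are drawn per group — Bernoulli for binary, normal for
quantitative — with defaults mirroring the descriptive statistics of a
cardioembolic/atherothrombotic stroke cohort (atrial fibrillation
prevalence 0.625 vs 0.036, cardiac failure 0.188 vs 0, older age in the
cardioembolic group, higher platelets in the atherothrombotic group;
interquartile ranges converted to SDs as IQR/1.35).

Reproducibility: one `SeedSequence` keyed by the seed spawns named
sub-streams (layout, one per protein, clinical), so protein i's values
do not depend on how many proteins are simulated, and identical seeds
give bit-identical cohorts.

What the generator does **not** emulate: correlated proteins (real
proteomes are strongly co-regulated; panel redundancy is therefore
underestimated), batch effects and run-order drift, peptide-level
evidence, non-normal heavy-tailed intensity distributions, and more than
two groups. Passing recovery tests on this generator show the search
machinery finds planted univariately-shifted markers; they do not show
that the SVM exploits multivariate structure no univariate test could
see, nor anything about robustness to confounding.

## Numerical and design choices

* Zero-variance features get sd 1 after centering (warning logged);
  they carry no information and must not poison the z-score.
* Decision-function ties (exactly 0) predict group C; tie cells are
  measure-zero but the rule makes label-swap symmetry exact up to this
  boundary.
* SMO iteration cap 200,000 with a logged warning on non-convergence
  (never observed at tol 1e-6 on tested data).
* The pipeline buffers all outputs and writes only after every stage
  succeeds; the results envelope embeds the resolved configuration and
  package version, and rerunning from the same configuration produces a
  byte-identical envelope.
* Problem sizes in the test and acceptance runs are scaled to
  single-CPU minutes: the full-scale trio search is exercised at 100
  common proteins (161,700 fits, run twice to confirm chunking
  invariance), ground-truth recovery at 30 proteins × 40 samples
  (4,060 fits per seed, 10 seeds per condition), and null calibration
  at 2,000 simulated proteins. The 438-protein trio enumeration count
  is verified by streaming the full 13.9M combinations through the
  enumerator without scoring.

## Known limitations

* Resubstitution accuracy on dozens of samples with millions of
  candidate panels is an optimistic, overfitting-prone statistic by
  construction; the package reports it because it is the method's
  definition of separability, but any panel found this way needs
  independent validation before biological claims.
* The min-valid univariate branch tests proteins that are, by
  construction, missing in many samples; with intensity-dependent
  missingness the valid values are a biased (left-censored) subsample,
  and group differences on them conflate abundance with detectability.
* The Wilcoxon exact path switches to the asymptotic approximation in
  the presence of any tie, even at small n, where a mid-p or
  tie-permutation enumeration would be sharper.
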