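# Methods

## Synthetic screen model

The generator produces a cohort of `n_lines` cell lines (default 624) with
tissue of origin drawn multinomially over 22 tissue labels (uniform
proportions unless overridden). Genomic features are independent standard
normals for expression and copy number and Bernoulli(0.05) for mutations —
a sparse binary pattern typical of filtered exome calls. The latent drug
response of line *i* is

    log10 IC50_i = b0 + Σ_j β_j z_ij + ε_i,   ε_i ~ N(0, σ_res²)

where the sum runs over the *planted* features, `z` is the feature z-scored
across the cohort, and β is the signed effect per feature SD (negative =
sensitivity). Defaults: baseline b0 = 0 (1 µM, the center of the dose
range), σ_res = 0.3. For a binary mutation at prevalence π the z-scoring
means a planted β produces a mutant-vs-wild-type group difference of
β/√(π(1−π)) — low-prevalence mutations are amplified, which is the intended
reading of "effect per SD" and is what the group-mean oracle tests check.

**Dose series.** Seven doses by successive halving from 10.64 µM:
10.64, 5.32, 2.66, 1.33, 0.665, 0.3325, 0.16625 µM. The printed endpoints
0.16 and 10.64 of the emulated design are not an exact 2-fold pair
(0.16 × 2⁶ = 10.24); halving from the top dose reproduces the top exactly
and the bottom to within 0.01 µM. Dose count and top dose are configurable.

**Dichotomous response.** A `responder_fraction` (default 0.3) of lines
respond; the rest are flat at viability 1 at every dose. When latent scores
are supplied, the responders are the lines with the lowest latent
log10(IC50), so the dichotomy itself is driven by the planted genomics and
planted biomarkers survive the censoring step; without genomics, responder
status is an independent Bernoulli draw and responder IC50s are log-normal
(mean 10⁰ = 1 µM, sd 0.5 decades). Responders follow an exact 4PL curve
with top = 1, bottom = 0, hill = 1 and IC50 = 10^latent.

**Plates.** 384-well plates with 8 untreated-control and 8 blank wells
each; whole cell lines are assigned to plates so every curve is normalized
against its own plate. Raw signal is
`blank + viability × (control − blank) + N(0, (noise_sd × dynamic range)²)`,
truncated at zero, with noise_sd defaulting to 0.02. No edge effects,
spatial gradients or outlier wells are modeled — so passing tests show the
pipeline's arithmetic and statistics are right, not that it is robust to
plate artifacts real screens exhibit.

## Plate QC

Normalization anchors the control mean at viability 1 and the blank mean at
0; values are not clamped, so negative viabilities remain visible. The three
filters use strict inequalities, matching their verbal definitions: CV of
control wells (sample SD / mean) *below* 0.20, signal-over-noise *over*
5-fold, and directionality ratio (mean viability at the two lowest doses
over the two highest) at least 1.2 — exactly 20% CV, exactly 5-fold S/N and
a ratio of exactly 1.2 evaluate as fail, fail, pass respectively. A
non-positive high-dose mean is a degenerate denominator and fails with a
NaN ratio. Flat curves fail directionality by construction (ratio 1); they
are retained with `qc_status = fail_directionality`, skipped by the 4PL
fit, and given AUC/Emax from raw points with the IC50 right-censored, so
resistant lines stay representable in the response vector.

## Dose-response fitting

Bounded trust-region least squares on the 4PL, parametrized as
(top, bottom/top, hill, log10 IC50_fit) so that 0 ≤ bottom ≤ top ≤ 1.2 and
hill ∈ [0.1, 10] are box constraints. Three starts (hill ∈ {0.5, 1, 2},
midpoint at the geometric mean dose) guard against local minima; ties break
by lowest RSS then lowest hill. The reported IC50 is *absolute* — the dose
where the fitted curve crosses viability 0.5, found by bisection on
[d_min/10, 10·d_max] — rather than the 4PL inflection, because the
half-maximal concentration is defined on the control-normalized scale and
behaves sensibly for partial responders. No crossing above the window ⇒
IC50 = 10·d_max, censored; already below 0.5 at the bottom of the window ⇒
IC50 = d_min/10, censored. AUC is computed from the *observed* points
(trapezoid over log2-dose, normalized by the span) so it survives fit
failures and is invariant to dose units; Emax is the minimum of the
replicate-mean viabilities at the two top doses, exactly.

## Feature matrix

"CN genes whose alterations are translated into expression" is
operationalized as the top-`cn_cap` (default 1700) genes by |Pearson r|
between the CN column and the same-named expression column across the
retained lines; genes with no expression counterpart score 0 and ties break
lexicographically. Censored IC50s enter y at their censoring bound rather
than being dropped — removing them would delete the resistance signal the
selection is meant to find — and the censoring mask is exported for
sensitivity analyses. Columns are not standardized at assembly;
standardization happens inside each training split of the stability
selection to avoid information leakage from held-out lines. log10(IC50) is
the modeled response (AUC or Emax can be substituted by passing a different
fits column upstream).

## Stability selection

Each of the 100 runs draws ⌈0.1·n⌉ holdout lines uniformly (no tissue
stratification), z-scores columns on the training split (zero-variance
columns stay at zero), and fits `ElasticNetCV` with l1_ratio 0.5, the
penalty chosen as the minimum-CV-error point of a 60-point grid under
internal 5-fold CV. Freq is the fraction of runs with a nonzero
coefficient; weight averages coefficients over the runs where the feature
was selected (averaging over all runs is a config switch); effect divides
the weight by √(count of features of that type) — a declared approximation
to "normalized for the number of features of each type". All randomness
derives from one seed via spawned generator streams, so reruns are
bit-identical.

Minimum-CV-error penalty selection is anti-conservative: under a pure-null
response (y independent of X, n = 200, p = 100) roughly one experiment in
ten shows a single spurious feature above Freq 0.7, because consecutive
runs share 90% of the lines and a chance correlation persists across them.
The one-standard-error rule would be more conservative; the minimum-CV rule
is kept as the default because it is determinate and simple, and the null
behavior is documented by a property test at its measured rate.

## Connectivity and enrichment

The connectivity null samples node sets uniformly at random (no degree
matching — that is what "expected by chance" states; a degree-preserving
null would shrink the excess for hub-rich sets and is left to future work).
The p-value uses the add-one estimator (1 + #{null ≥ obs})/(1 + n_perm), so
it is never exactly zero and is valid by construction. Term enrichment is
the hypergeometric upper tail P(X ≥ k) on (N, K, n) with BH adjustment
across all tested terms; terms are restricted to the supplied universe and
the gene set must be contained in it — choosing the universe (network
nodes, all measured genes, …) is the caller's scientific decision.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale: recovery of a
planted mutation uses 300 lines × 101 mutation features with 100 elastic-net
runs (~5 s); null-control behavior uses 12 seeded experiments of 20 runs
each; permutation validity uses 150 repetitions of 200 permutations;
exhaustive hypergeometric oracles stop at universe size 12, where full
enumeration is cheap. Noiseless 4PL recovery is asserted to 1% relative
error; noisy recovery (noise_sd 0.02) to a median absolute log10 error of
0.05. Float comparisons in tests use relative tolerances near 1e-9 for
closed-form oracles.

## Limitations

- Gaussian feature and noise models; no copy-number segment structure,
  expression correlation blocks, or mutational signatures.
- Censored responses are treated as observed at the bound in the linear
  model; a Tobit-style likelihood would use the censoring mask properly.
- The uniform permutation null ignores degree bias in real interaction
  networks, so p-values on real data will differ from degree-aware nulls.
- No GO-DAG propagation: terms are tested as flat gene sets.
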