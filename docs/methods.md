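# Methods

This note documents the statistical models implemented in `pymbms`, the
defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Spectra and normalization

A py-MBMS spectrum is a vector of non-negative ion intensities on integer
*m/z* channels 30–450 (421 channels). Two normalizations are supported:
total-ion-current (TIC, channels sum to 1) and mean (channel mean equals
1). TIC is the default for all downstream scoring and modeling; mean
normalization is retained as an option. Analytical replicates are
normalized **before** averaging, so duplicate pyrolyses with unequal total
ion yield contribute equally to the sample mean; for replicates with equal
TIC the two orders commute exactly, and a test asserts this. Fractional
*m/z* columns in input files are rejected rather than silently rounded.

## Reduced-ion estimators

Lignin content, S/G ratio and single-point sugar estimates are pure ion
arithmetic on normalized spectra (see README for the ion lists, which ship
as a versioned YAML so alternative sets can be supplied). Two conventions
matter:

* The C5 and C6 sets intentionally share *m/z* 57 and 73; each estimator
  is applied independently, so no de-duplication is performed.
* Lignin ions without an S or G sublabel (120, 152, 180, 181) count toward
  lignin content but toward neither monomer pool.

The S/G ratio is scale-invariant, so the choice of normalization cannot
affect it (asserted by a property test). Single-point estimates are
exactly linear in the sample's ion sum.

## PLS1 calibration

`fit_pls1` implements the NIPALS recursion for a single response on
mean-centered data. Spectra are centered but **not** variance-scaled: all
channels share one intensity unit, and unit-variance scaling would inflate
noise-only channels. Factor counts default to 4 (glucose) and 5 (xylose).

Numerical choices:

* Weight vectors are normalized to unit length; score orthogonality is an
  invariant checked by tests (relative tolerance 1e-8).
* Deflation stops with a `RankDeficientError` carrying the achieved factor
  count when `‖Xᵀy‖` falls below 1e-12 of the problem scale.
* With factors equal to the rank of centered X, the composite coefficients
  equal the least-squares solution; this oracle equivalence is tested on
  100 random small problems at 1e-6 relative tolerance, and coefficients
  are cross-checked against scikit-learn's `PLSRegression` (which is never
  used in the implementation itself).

Cross-validation is leave-one-out for n ≤ 150 and 10 random segments with
a fixed seed above that. R² is reported as the squared Pearson correlation
of measured vs. predicted values, which keeps R² and PCC mutually
consistent; both calibration and cross-validated errors are available
because reported model statistics can legitimately be either. Relative
errors are percentages of the measured value; samples with a zero measured
value are excluded from relative-error summaries (with a warning) but kept
in RMSE/PCC. A constant measured or predicted vector makes the correlation
undefined; it is reported as 0 with an explicit `degenerate` flag rather
than NaN.

PCA is mean-centered SVD; explained-variance fractions are normalized
covariance eigenvalues (oracle-tested against a direct eigendecomposition)
and loading signs are fixed so each component's largest-magnitude element
is positive. Factor-1 PLS loadings are reported with the sign fixed so the
factor-1 y-loading is positive, making channels that increase with the
trait read as positive.

## Spatial correction and heritability

**Thin-plate spline.** Field phenotypes are corrected by fitting
f(row, col) as a low-rank thin-plate regression spline: radial basis
φ(r) = r² log r at up to 200 knots (deterministically thinned from the
unique coordinates), plus a linear polynomial, with the radial
coefficients constrained orthogonal to the polynomial at the knots. The
penalized system is solved over a 33-point log-spaced λ grid and smoothing
is chosen by GCV, `nRSS/(n − edf)²`; a fixed λ can be supplied instead.
The fitted surface is subtracted and the grand mean re-added, so the
correction never changes the trait mean. The solve is O(nm² + m³) for m
knots. On spatially unstructured data GCV drives the fit toward the
polynomial plane, and the correction removes well under 10% of the
variance (tested).

**Variance components.** Broad-sense heritability treats genotype as a
random group effect on ramet-level (not genotype-mean) phenotypes —
ramet-level data are required to identify σ²_E. The moments method uses
one-way ANOVA expectations with the unbalanced-design coefficient
n₀ = (N − Σnᵢ²/N)/(k − 1) and truncates negative σ²_G at zero, keeping
H² ∈ [0, 1]. The REML method maximizes the closed-form restricted
likelihood of the one-way model (Nelder–Mead on log variances, with an
explicit check of the σ²_G = 0 boundary); it agrees with statsmodels'
MixedLM to ~6 significant digits and with the moments method within 0.02
on balanced designs. Percentile bootstrap CIs resample genotypes with
replacement; resamples with zero total variance are uninformative about a
variance ratio and are skipped.

The estimator deliberately targets **total** genotypic variance with a
one-way model even though the simulator builds genotype values from
GCA/SCA family components: clonal replication identifies σ²_G directly,
which is exactly what broad-sense H² measures. Family structure only
shapes the covariance of the simulated genotype values.

An optional per-batch median-centering step stands in for instrument-drift
correction; it is off by default.

## Synthetic-data generator

The generator emulates the statistical structure of a py-MBMS field
campaign; its defaults are the study conditions used throughout the tests.

**Compositions.** (glucose, xylose, lignin, S/G) are drawn from a
multivariate normal — means (48, 17, 24.6, 2.1), SDs (2.3, 1.5, 1.0, 0.1),
correlations r(glc,xyl) = −0.76, r(glc,lig) = −0.61, r(xyl,lig) = +0.48,
S/G uncorrelated — rejection-sampled into the ranges (43–57, 11–20,
19.3–27.0, 1.4–2.6). The sugar SDs place the published ranges at roughly
±3 SD; lignin and S/G SDs are the published population values. Rejection
(rather than clipping) preserves the correlation structure; configurations
whose acceptance rate falls below 1% are refused. A user-edited
correlation matrix that is not positive semi-definite is repaired by
eigenvalue clipping, with a warning.

**Spectra.** Each spectrum is a linear mixture of five basis patterns (C6
sugar, C5 sugar, S-lignin, G-lignin, broadband background): 80% of each
component's yield sits on its annotated diagnostic ions (weighted to
mirror the observed correlation ordering) and 20% on a shared low-mass
exponential background; the residual non-sugar, non-lignin mass drives the
background component. Channel noise is multiplicative lognormal (σ = 0.08,
mean 1), and the result is TIC-normalized. Because S/G is operationally
defined as an intensity ratio, the lignin mass is split between the S and
G pools so the noise-free labeled-ion ratio equals the latent S/G exactly,
accounting for response-factor differences and for sugar/background
interference at the labeled channels (notably xylose mass at *m/z* 150).
The deliberate spectral overlap — sugar ions shared between C5 and C6
sets, xylose interference at G channels, a common background — is what
makes reduced-ion single-point estimators correlated but inferior to
full-spectrum PLS, reproducing the qualitative finding that single-point
methods underperform within a single biomass type.

**Reference measurements.** Hydrolysis/NMR-like values are truth plus
Gaussian error, SD 0.01 mg/mg (1 DW%) per sugar.

**Pedigree trials.** A 7 × 7 factorial cross with, by default, 10 progeny
per family and 5 clonal ramets per genotype on a 50 × 50 grid (2,450
trees, randomly placed). Genotype values are GCA(mother) + GCA(father) +
SCA + within-family deviation with variance fractions 0.25/0.25/0.20/0.30
of σ²_G, then standardized so the genotype population realizes exactly the
nominal σ²_G (founder-scaling, as quantitative-genetics simulators do —
with only 14 parents the family covariance would otherwise shrink the
realized variance ~7% below nominal and make the recorded "true H²"
inexact for the data actually generated). Ramet phenotypes add a smooth
spatial surface (superposed low-frequency cosine waves, SD 0.3, length
scale 10 grid units) and a residual, on a standard scale with
σ²_G + σ²_E = 1. Defaults: glucose σ²_G = 0.32, xylose σ²_G = 0.34.
Everything is reproducible from (seed, config), with a config hash stored
in the provenance sidecar.

**What the generator does not emulate.** Pyrolysis matrix effects
(component interactions) — spectra are strictly linear mixtures, which the
success of linear PLS on real data justifies only approximately; minor
sugars, ash, extractives; NMR spectra themselves (only their error);
instrument drift beyond optional batch medians; genotype-by-environment
interaction across sites. Passing tests therefore demonstrate estimator
correctness under the assumed mixture-plus-noise model, not robustness to
real-instrument nonlinearity.

## Problem sizes and recovery behavior

The natural-variant workflows use 500 accessions in duplicate with a
93-sample range-spanning calibration subset; heritability recovery uses
200 simulated trials of the default 2,450-tree design (the acceptance
script's sizes). Under these conditions the 4-/5-factor models recover
held-out truth with R² ≈ 0.8 and RMSE at or below twice the reference
noise floor, and the mean TPS-corrected moments estimate of H² is ~0.31
(glucose, nominal 0.32) and ~0.33 (xylose, nominal 0.34). The residual
~0.01 downward bias is expected: the fitted spline absorbs a fraction
(≈ edf/n) of every signal in the phenotype, genotypic signal included, so
smoothing slightly shrinks the between-genotype variance. Correcting at
the trait level is itself a simplification — spectra-level spatial
correction (correcting each ion channel before prediction) is a
documented alternative this package does not implement.

## Known limitations

* PLS1 only; no multi-response PLS, variable selection, or sparse
  variants.
* The TPS knot thinning is deterministic but coordinate-order based; very
  irregular layouts may warrant user-chosen knots.
* Narrow-sense heritability, pedigree-BLUP and GxE are out of scope; the
  one-way model cannot separate GCA/SCA components (by design).
* Reduced-ion lignin/S-G estimates inherit the instrument convention that
  defines them; they are comparable within, not across, calibrations.
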