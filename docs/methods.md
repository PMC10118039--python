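# Methods

`exometab` re-implements, as a tested pipeline, the data analysis of a
field-vs-hydroponics root-exudate comparison across four cover crop species
(white mustard, lacy phacelia, bristle oat, Egyptian clover). The untargeted
LC-MS part starts from vendor-exported feature tables (feature id, m/z,
retention time, per-sample peak heights), one per cultivation batch; the
targeted part starts from a long table of primary-metabolite exudation rates
(nmol g⁻¹ root dry weight h⁻¹). Everything upstream — acquisition, peak
picking, spectral-library annotation — is out of scope and consumed as input.

## Feature-table harmonization

Because the two batches were measured separately, their feature tables are
merged by m/z–RT identity: a FIELD and a HYDRO feature are adopted as the
same compound when |Δm/z| < 0.01 Th **and** |ΔRT| < 0.3 min (both strict).
The assignment is a deterministic greedy on the combined normalized distance
d = max(|Δm/z|/0.01, |ΔRT|/0.3): candidate pairs are accepted in ascending d
while d < 1, one-to-one, ties broken by smaller |Δm/z| then lexicographic
ids. Because the globally closest pair is accepted first, every accepted
pair is mutually nearest among the features still unmatched, and the result
is independent of input order and symmetric in the two tables. The consensus
m/z and RT of a matched pair is the arithmetic mean. Unmatched features are
carried through as single-batch features with zero heights in the other
batch's samples.

Only the tolerance is prescribed by the study design; the assignment
algorithm is our choice. A bipartite minimum-cost matching would differ only
on pathological clusters tighter than the tolerance, which real
chromatography rarely produces and the simulator does not generate.

## Blank filtering and presence calling

A merged feature is removed when its **mean** height strictly exceeds 500
counts in the water blanks or in the in-field blanks. The source protocol
phrases the two blank classes conjunctively ("and"), but the hydroponic
experiment has only water blanks, under which a conjunctive rule would never
fire there; we therefore default to the disjunctive reading (removal when
*either* blank class exceeds the threshold) and expose `blank_rule: and` as
a config switch.

Presence per species × condition group: a feature is present when its height
strictly exceeds 1000 (FIELD) or 3000 (HYDRO) counts in **strictly more than
half** of the group's samples (so 2 of 4 is absent). The threefold threshold
ratio mirrors the threefold higher concentration of hydroponic samples;
presence calls are invariant to jointly scaling one batch's heights and its
threshold. Per-sample presence — needed for the sample-level ordination and
Var[C] — uses the same batch thresholds on individual samples; the rule at
sample resolution is not stated by the source protocol, so this is a declared
assumption, chosen so that the group call equals the majority vote over the
sample calls.

## Richness and Venn overlaps

Per species, the FIELD and HYDRO presence columns give unique and shared
feature counts by set algebra, their totals, and the FIELD/HYDRO richness
ratio (reported at full precision and rounded to one decimal). Counts are
conserved: field-only + hydro-only + shared = |union|.

## Var[C]: constrained correspondence analysis

Var[C] is the fraction of a sample × variable matrix's χ² inertia explained
by the cultivation condition. With P = Y/N (N the grand total), row masses r
and column masses c,

    Q̄ᵢⱼ = (Pᵢⱼ − rᵢcⱼ) / √(rᵢcⱼ),   total inertia = Σ Q̄² = χ²(Y)/N.

The condition design (a two-level indicator) is weighted-centred with
weights r (absorbing the intercept), its rows scaled by √r, and Q̄ projected
onto it by least squares; the constrained inertia is the sum of squares of
the fitted matrix (equivalently of its singular values squared — one
constrained axis for a two-level factor). Var[C] = constrained/total ∈ [0, 1].
The implementation is validated three ways: against an independent
group-centroid oracle (Σ_g w_g‖q̄_g‖², agreement ≤ 1e−8), against the
Pearson-χ² identity for the total, and against the R reference
implementation `vegan::cca` (agreement ≤ 1e−6).

All-zero rows and columns are dropped before the transformation (CA is
undefined on them) and recorded in the result. For quantitative
primary-metabolite matrices, censored (not-detected) observations are imputed
as rate 0 — CA requires complete non-negative data; the source analysis does
not state its imputation, so this is a documented choice.

## Ordination

Quantitative primary data are standardized per metabolite to z-scores
(sample SD, denominator n−1; constant metabolites are rejected and dropped by
the caller) with censored values set to 0 beforehand; binary presence data
enter centred but unscaled ("without scaling" — whether the source analysis
centred is unstated; centring is assumed, as column means must be removed for
eigenvalues to measure variance). Components come from the SVD of the
processed matrix; explained fractions are eigenvalues over their total and
sum to one. PCA signs are arbitrary, so each loading column is flipped to
make its largest-magnitude entry positive, which makes outputs reproducible
bit-for-bit. The top 3 components are reported by default.

## Fixed-effects models and contrasts

Each metabolite's rates follow Y = μ + sᵢ + cⱼ + (sc)ᵢⱼ + e with species and
condition fixed. The fit is computed in the cell-means parametrization —
identical estimated means and contrasts to any coding of the saturated
model, which a test verifies against a statsmodels OLS fit of
`y ~ C(species) * C(condition)`. The pooled residual variance carries
Σ(n_cell − 1) degrees of freedom (homoscedastic classical ANOVA; no
Satterthwaite). Cells that are entirely zero are excluded as carrying no
detectable signal; censored observations are omitted, and a species missing
one condition contributes no contrast.

Residual normality is screened automatically — Shapiro–Wilk p < 0.05 or
|skewness| > 1 triggers a refit on log(x + offset), offset = half the
smallest positive value when zeros occur. (The source analysis used
diagnostic plots; a pipeline needs an automated rule.) The screen has the
usual ~5% false-trigger rate on Gaussian data; `fit_model1(...,
transform="never")` bypasses it, which parameter-recovery evaluations
against a raw-scale truth use.

FIELD − HYDRO contrasts are pooled-variance t tests on the estimated cell
means, two-sided, Benjamini–Hochberg-adjusted across the family of the
metabolite's (up to four) within-species contrasts — the contrasts the
study reports. A config switch (`fdr_family: all_pairwise`) widens the
family to all pairwise cell contrasts, the literal "pairwise" convention of
emmeans. Significance is adjusted p < α (default 0.05).

## Carbon accounting

rate (nmol g⁻¹ h⁻¹) × carbon atoms/molecule × 12.011 / 1000 = µg C g⁻¹ h⁻¹.
The 28-metabolite vocabulary (20 amino acids, 5 organic acids, 3 sugars)
carries the standard molecular carbon counts. Shares are percentages of a
total exuded-C mass supplied externally in mg; the packaged totals are the
rounded text-quoted values (1.5/1.0/0.2/0.4 mg HYDRO for
mustard/phacelia/oat/clover; 0.2/0.1 mg FIELD for phacelia/clover), so
shares computed against them inherit that rounding. Detection counting
treats a metabolite as detected in a cell when present in strictly more than
half the replicates (replicate data) or simply non-missing (summary data).

## Top-100 ranking and class tallies

Per species × condition group, features called present are ranked by mean
height over the group's samples (median by config; the source states only
"peak height" — the mean keeps one convention with the blank filter) with
deterministic lexicographic tie-breaks, and the top 100 selected (all, when
fewer are present). Tallies across the chemical-taxonomy hierarchy count
level-1/2 annotated features down to subclass, level-3 features at
superclass only, and unannotated features as Unknown; every classified
feature increments each prefix of its path, so child counts never exceed
their parent's and totals conserve the list size.

## Synthetic data

The generator plants features with true m/z (U(100, 1000) Th), RT
(U(0.5, 17.5) min) and a known species × condition membership, then renders
them into both batch tables with independent Gaussian jitter per batch
(default SD 0.002 Th / 0.05 min — well inside the matching tolerance, as a
stable instrument would be). Heights in member groups are log-normal
(meanlog log(2·10⁴), sdlog 0.8 — the source gives no height distribution;
log-normal is our configurable assumption), multiplied by 3 in HYDRO
(the batch concentration factor). Heights in non-member groups are drawn
uniformly on [0, 0.1 × threshold] rather than exactly 0, so that the strict
">" logic is genuinely exercised. A configurable fraction of features
(default 5%) contaminates blanks with mean height well above 500. Decoys are
feature pairs displaced across batches by twice the tolerance in m/z or RT;
a correct merge must leave all of them unmatched. Replicate counts default
to the study design: 10 FIELD / 4 HYDRO samples per species for untargeted
profiling, 10/20 per cell for primary rates.

Primary rates are generated from the two-way decomposition with sum-to-zero
effects (so μ is the grand mean and fitted cell means are directly
comparable to the truth ledger), truncated at 0, with independent per-cell
detection censoring. The default truth uses the packaged published group
means as cell means (non-detected cells at 0) with a pooled residual SD of
8 nmol g⁻¹ h⁻¹, of the order of the smaller published SDs.

What the simulation does *not* emulate: chromatographic peak shapes,
isotopes/adducts, retention-time drift (the merge uses fixed tolerances, as
did the source), correlated censoring, or species-specific richness
gradients. Consequently, passing tests demonstrate correctness of the
*computations* on data with known truth, not reproduction of the study's
dataset-dependent numbers (feature counts, published Var[C] values, PCA
percentages), which require the deposited raw data and are deliberately not
asserted anywhere. One visible consequence of the defaults: member-group
heights sit far above the presence thresholds, so within-group detection is
near-deterministic and the binary Var[C] of the synthetic defaults
saturates near 1; tests that need intermediate Var[C] values place heights
near the threshold (meanlog log(2000), sdlog 1) to make detection noisy.

## Numerical choices and degenerate inputs

- Constrained inertia is clipped at the total (guarding 1e−15-scale
  overshoot); constrained axes are singular values with λ > 1e−10·max λ.
- Zero-inertia matrices, single-level factors, rank-0 PCA inputs, constant
  variables under scaling, all-zero rows/columns after dropping: explicit
  errors naming the offender.
- A cell with one observation contributes its mean but no variance degrees
  of freedom (noted on the fit); zero pooled SE with a zero estimate yields
  p = 1.
- Heights parse missing as 0 (a non-detected peak has no height); primary
  rates parse missing as censored. The two missingness semantics are
  deliberately different.
- Atomic carbon mass 12.011 g/mol, configurable but fixed in all shipped
  analyses.

## Problem sizes used in shipped runs

The analysis drivers and the acceptance script simulate 300 planted features
+ 30 decoys over 65 samples, 500–1000 null metabolites for the false-positive
check, and 500 seeds for parameter recovery — sizes at which every
statistical property tested is comfortably resolved while the full suite
runs in well under a minute of compute per stage.
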