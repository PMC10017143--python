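# Methods

## Problem and model

The package analyses linked longitudinal primary-care tables — medication
events and diagnosis events sharing a patient identifier — to describe how
co-prescription patterns evolve over the 20 years before an index diagnosis.
The statistical core is the common-factor model for binary prescription
indicators: for period *t*, let x_ij ∈ {0,1} record whether patient *i* was
prescribed medication *j* at least once in the window. The p × p correlation
matrix R of these indicators is decomposed as

    R ≈ Λ Φ Λᵀ + Ψ

with Λ the p × F pattern loadings, Φ the F × F factor correlations and Ψ the
diagonal uniquenesses. Factors are read as co-prescription patterns; the
medications defining a pattern are those with |λ| > 0.30 (salience), and a
patient belongs to the pattern's *polypharmacy cluster* if at least three
distinct salient medications were prescribed to them in the window. Clusters
can overlap and need not exhaust the cohort.

## Pipeline stages and numerical choices

**Windowing.** Windows are half-open intervals [lower, upper) in exact
365.25-day years before the diagnosis date; the defaults [0,5), [5,10),
[10,15), [15,20) partition the 20-year span with no boundary gap. Events
after the diagnosis date are counted and discarded, not errors. Matrices are
binary by default (count coding retained for sensitivity analyses); patients
with no in-window medication event are excluded from the matrix rows but the
period cohort size is the default prevalence denominator. A minimum-support
filter (default 10 patients) removes medications too rare to correlate
stably; dropped codes are logged.

**Correlation.** Pearson (phi) correlation is the default input to
extraction: it is fast, always proper, and adequate for moderate-prevalence
indicators at p ≈ 30–150. Tetrachoric correlation — per-pair ML under a
bivariate-normal threshold model, thresholds fixed at the marginal probit
quantiles, 0.5 continuity correction for empty cells, optimised by bounded
scalar minimisation on (−0.999, 0.999) — is available and is exactly
model-consistent with the synthetic generator. Pairwise tetrachoric matrices
can be indefinite; they are repaired by clipping eigenvalues at 1e−6 and
rescaling to unit diagonal, with a flag recorded.

**Factor count.** Horn's parallel analysis with column-wise permutation of
the observed matrix (n_sims = 100, 95th percentile). Permutation rather than
Gaussian simulation preserves each indicator's marginal prevalence, which
matters for sparse binary data whose null eigenvalue spectrum is wider than
the Gaussian one. The suggested count is the number of leading observed
eigenvalues exceeding their reference, stopping at the first failure.

**Extraction.** minres by default: uniquenesses ψ are optimised by L-BFGS-B
(bounds [0.005, 1], start at 1 − squared multiple correlation); given ψ the
loadings are the top-F eigenvectors of R with the diagonal replaced by
communalities, scaled by the square-rooted (non-negative-clipped)
eigenvalues. ML extraction uses Jöreskog's concentrated criterion on the
ψ^−½ R ψ^−½ eigenvalues and is the path compared against R's `factanal` in
the tests. Rotation is gradient-projection via statsmodels: oblimin (γ=0)
by default — co-prescription patterns share medications, so orthogonality
would be an odd prior — with varimax available. After rotation, factors are
ordered by sum of squared loadings and sign-fixed so each column's
largest-|λ| entry is positive.

**Fit indices.** RMSR is the root mean square of off-diagonal residuals
R − (ΛΦΛᵀ + Ψ). The model χ² is the Bartlett-corrected ML discrepancy
(n − 1 − (2p+5)/6 − 2F/3) · F_ML evaluated at the solution (also for minres
fits, the standard convention); df = ((p−F)² − (p+F))/2. RMSEA =
√max((χ²−df)/(df(n−1)), 0), with a 90% CI by inverting the noncentral χ²;
fits are flagged "good" at RMSEA ≤ 0.05. TLI uses the independence baseline
χ²₀ = (n−1−(2p+5)/6)(−ln|R|), df₀ = p(p−1)/2, and is reported on both the
unit and ×100 scales. TLI slightly exceeds 1 when χ² < df (near-perfect
fits); that is expected behaviour, not an error.

**Factor scores.** Regression (Thurstone) weights W = R⁻¹ΛΦ applied to
column-standardised indicators. Under the Gaussian factor model this is the
posterior mean of the factors given the data, which coincides with the MAP
estimate. A singular R falls back to a ridge-regularised solve (1e−8) with
a warning. Scores are cohort-centred by construction.

**Cluster assignment and profiling.** Salience is strict (|λ| > 0.30,
configurable); membership counts *distinct* salient medications (≥ 3), so it
is monotone under added prescriptions and every member is by construction a
polypharmacy patient. Prevalence percentages use half-up rounding at the
printed precision (published tables round ties away from zero; banker's
rounding would disagree on exact .5 ties). Disease profiles are
presence-coded per (factor, patient, 3-character diagnosis code) within the
window, top-8 codes per cluster. Demographic composition stratifies by
gender and age at the diagnosis date in completed years, bands [0,65),
[65,75), [75,86), [86,∞) — closed so that the strata always sum to 100%.
Yearly visit series bucket events by ⌊years before diagnosis⌋ and a
user-supplied code → category map (unmapped codes go to "other" with a
warning).

## The synthetic generator

The generator emulates the *shape* of a GP dementia-cohort extract, with a
known truth for every downstream stage:

- **Cohort**: default 65.8% female; diagnosis age Gaussian with means
  82.2 (F) / 66.2 (M) years, sd 6; index dates uniform over 2005–2015.
- **History truncation**: 15% of patients have the full 20 years of records,
  the rest a Uniform(0, 20)-year history. This produces the monotone
  shrinking per-period cohorts characteristic of registry data (later
  windows predate many patients' registration).
- **Co-prescription**: per period, factor scores f ~ N(0, Φ), latent
  responses y = Λf + √ψ ε, prescription iff y_j exceeds the probit threshold
  for the target marginal prevalence (default 15%). This threshold (probit)
  construction makes tetrachoric correlations exactly model-consistent, so
  parameter recovery is a well-posed test. Each prescribed (patient,
  medication) yields 1 + Poisson(2) dated events (mean 3 — repeat
  prescriptions), uniform within the window and truncated to the patient's
  history; only presence matters downstream.
- **Diagnoses**: cluster members (by the same ≥3-salient-drugs rule applied
  to the planted salient sets) receive each linked 3-character code with a
  planned prevalence; non-members at a background rate (default 0). The
  default prevalence map mirrors the magnitudes of published cluster-disease
  tables (e.g. acute bronchitis ~27% in the largest cluster).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic medication vocabularies and their
heavy-tailed prevalence distribution; secular prescribing trends and
seasonality; dose/duration information; informative missingness (the
truncation is independent of health status); comorbidity-driven prescribing
feedback; and diagnosis codes outside the planted map. Recovery results on
planted structure demonstrate correctness of the machinery, not that real
EHR data contain factors this clean.

Two calibration caveats established empirically and reflected in the test
conditions: with rare indicators (~15% prevalence) the regression-score
correlation with true factor scores plateaus near 0.79 at any n (phi
attenuation — an information limit of sparse binary items), so score
recovery is demonstrated at 25% prevalence; and per-pair tetrachoric
sampling error at n = 5000 only drops below 0.06 for moderate (~40%)
marginals.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `windows` | [0,5), [5,10), [10,15), [15,20) years | pre-diagnosis periods |
| `min_meds` | 3 | distinct medications for the polypharmacy flag (≥) |
| `min_support` | 10 patients | medication column retention |
| `correlation_method` | pearson | phi; `tetrachoric` optional |
| `extraction` | minres | `ml` optional |
| `rotation` | oblimin (γ=0) | `varimax`, `none` optional |
| `pa_n_sims`, `pa_percentile` | 100, 95 | parallel-analysis reference |
| `salience_threshold` | 0.30 (strict >) | factor medication sets |
| `min_drugs` | 3 | cluster membership rule (≥, distinct) |
| `decimals` | 2 | half-up rounding of printed percentages |

All are named keys of the declarative run config; the bundled demo
(`rxpatterns.demo_config_path()`) uses n = 3000 patients, three planted
oblique factors per period, and seed 11. Problem sizes in the test suite and
acceptance script (n = 2000–3000, p = 30, 20 repeated draws) were chosen as
the smallest at which recovery statistics are stable.

## Determinism

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` children keyed by stage and period; identical
config + seed reproduces byte-identical report bundles (no timestamps in
outputs; provenance headers carry the config hash and seed).

## Known limitations

- Pairwise tetrachoric estimation is O(p²) scalar optimisations; at p ≈ 150
  expect minutes, not seconds. Pearson is the pragmatic default at scale.
- The membership rule needs ≥ 3 salient medications per factor; factors with
  fewer salient items produce empty clusters (warned, not fatal).
- No missing-data handling (presence matrices have no missingness by
  construction); no confirmatory models; no dose or duration analysis.
- Cluster labels ("CVD cluster" and similar) are analyst-supplied strings,
  not computed.
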