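# rxpatterns

Discovery of time-varying **polypharmacy patterns** in the years before an
index diagnosis, from linked primary-care medication and diagnosis event
tables.

People who go on to receive a dementia diagnosis accumulate medications for
years beforehand. Which medicines travel together, how prevalent each
co-prescription pattern is, and how the patterns reorganise as the diagnosis
approaches are questions for pharmacoepidemiologists and prescribing-safety
researchers. `rxpatterns` implements the full analysis pipeline for such
studies and, because real GP extracts are access-controlled, ships a
synthetic-data generator with *planted* latent structure so that every stage
can be validated against a known truth.

## The method

Given per-patient medication events dated relative to an index diagnosis
date (DoD), the pipeline:

1. **Windows** events into four 5-year periods before the DoD
   ([0,5), [5,10), [10,15), [15,20) years, 365.25-day years) and builds a
   binary patient × medication indicator matrix per period. Polypharmacy is
   flagged as ≥ 3 distinct medications in a window.
2. **Estimates correlations** between medication indicators — Pearson (phi)
   by default, maximum-likelihood tetrachoric as the latent-threshold-model
   alternative.
3. **Chooses the number of factors** by Horn's parallel analysis: observed
   correlation eigenvalues are compared with the 95th percentile of
   eigenvalues from column-permuted data (permutation preserves each
   medication's marginal prevalence).
4. **Fits the common-factor model** R ≈ ΛΦΛᵀ + Ψ by minres (ML optional),
   with gradient-projection rotation (oblimin γ=0 by default, varimax
   optional), and reports fit indices: RMSR, RMSEA with 90% CI (from the
   Bartlett-corrected χ² = (n−1−(2p+5)/6−2F/3)·F_ML), and the Tucker–Lewis
   index (also ×100). Per-patient factor scores use the regression
   (Thurstone) weights W = R⁻¹ΛΦ — the posterior mean, hence the MAP
   estimate, under the Gaussian factor model.
5. **Assigns patients to clusters**: a factor's medication set is its
   salient items (|λ| > 0.30); a patient joins the cluster if at least 3
   distinct salient medications were prescribed to them in the window.
   Clusters may overlap.
6. **Profiles each cluster** by merging memberships with the diagnosis
   table: top-8 disease prevalence, gender/age-band composition, and yearly
   visit-count series over the 20 pre-diagnosis years.

## Worked example

The bundled demo simulates 3,000 patients with three planted oblique
factors (10 salient medications each, |λ| = 0.8, factor correlations 0.3) in
every period, then runs the full analysis:

```bash
rxpatterns analyze --out demo_bundle
rxpatterns report --bundle demo_bundle
```

which prints (seed 11, the bundled default):

```
Period 1: cohort 2317, 30 medications, polypharmacy 67.50%, 3 factors
  (RMSR 0.013, RMSEA 0.008, TLI 99.6); cluster prevalence: F1=28.01%, F2=28.14%, F3=27.54%
Period 2: cohort 1836, 30 medications, polypharmacy 70.10%, 3 factors ...
```

Reading: period cohorts shrink (2317 → 872) because most simulated patients
contribute fewer than 20 years of history; parallel analysis recovers the
planted 3 factors in every period; the near-zero RMSR/RMSEA and TLI ≈ 100
say the 3-factor model reproduces the correlation matrix almost exactly; and
each planted cluster captures ~28% of the period cohort under the
≥3-salient-drugs rule — identical to the planted memberships (Jaccard 1.0,
see `analysis/04_assign_clusters.py`).

The same steps can be run piecewise as numbered drivers that write tables
under `results/` (bulky intermediates go to `scratch/`):

```bash
python analysis/01_simulate.py          # synthetic linked extract + truth
python analysis/02_window_matrices.py   # period matrices + polypharmacy table
python analysis/03_factor_analysis.py   # parallel analysis + EFA + fit indices
python analysis/04_assign_clusters.py   # salient sets, memberships, prevalence
python analysis/05_profile_clusters.py  # disease/demographic/yearly profiles
```

Equivalent CSV-in/CSV-out usage on your own extract: point `analyze
--data DIR` at a directory with `patients.csv` (patient_id, gender,
date_of_birth, diagnosis_date), `med_events.csv` (patient_id, event_date,
medication_code) and `dx_events.csv` (patient_id, event_date,
diagnosis_code).

## Layout

- `src/rxpatterns/` — the library: `synthetic` (generator), `windows`
  (periods and matrices), `correlation` / `parallel` / `factor` (EFA core),
  `assignment` (cluster rule), `profiles` (descriptive tables), `pipeline` +
  `cli` (orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
- `tests/` — pytest suite, including property tests (hypothesis) and
  independent oracles (brute-force enumeration, grid-search ML, R's
  `factanal` via Rscript).
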