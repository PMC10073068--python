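# solemetab

Case-control analysis of binned ¹H-NMR serum metabolomes for sole-lesion
outcomes in dairy cattle.

Sole hemorrhage (SH) and sole ulcers (SU) are major causes of lameness in
Holstein cows. A natural question is whether the serum metabolome — measured
as relative intensities of binned ¹H-NMR spectra — can predict which animals
will develop severe sole lesions in early lactation, and which metabolites
carry that signal. `solemetab` implements the complete analysis for this
question as a tested, reproducible pipeline:

1. **Spectral preprocessing** — non-positive bin integrals are replaced with
   one-fifth of the bin's minimum positive value, each spectrum is normalized
   by its total intensity, and redundant bins are reduced to one
   representative per annotated metabolite and one per complete-linkage
   cluster of mutually correlated unlabeled bins (Pearson |r| ≥ 0.9 merges).
2. **Cohort construction** — animals assessed at four time points
   (T1 precalving, T2 calving, T3 early lactation, T4 late lactation) are
   classified as *new SH*, *new SU*, *chronic SU*, *control*, or excluded;
   17 prespecified case-control subsets cross time point, parity cohort and
   outcome definition, with parity-stratified random control matching.
3. **Triangulated selection** — three methods with unrelated biases each
   predict case/control status and select variables: PLS-DA (selected when
   VIP > 1), L1-penalized logistic regression (nonzero coefficient), and
   Boruta shadow-feature selection over a random forest (binomial hit test at
   P < 0.01). Hyperparameters are tuned to out-of-fold balanced accuracy by
   stratified 5-fold cross-validation repeated 20 times.
4. **Stability inference** — per method, a variable's *stability* is the
   percentage of 200 stratified bootstrap resamples in which it is selected;
   the *observed stability* averages the three methods. Class labels are then
   permuted 10 times and the procedure repeated with 20 resamples each to
   obtain chance ("baseline") stabilities; the 99th and 100th percentiles,
   averaged over permutations, give the thresholds **T99** and **T100**
   (expected false-positive rates of about 1% and 0%). Variables whose
   observed stability strictly exceeds a threshold are flagged informative.

Because no real spectra ship with the package, a first-class synthetic-cohort
generator emulates the study conditions: log-normal latent metabolite
concentrations, sibling bins correlated at r ≥ 0.9, lesion prevalences per
parity cohort and time point, occasional negative baseline integrals,
hemolysis grades, and multiplicative case effects with configurable log₂
fold-changes.

## Worked example

```python
from solemetab import (
    SimulationConfig, InformativeEffect, simulate_cohort,
    AnalysisConfig, run_full_analysis,
)

cfg = SimulationConfig(
    n_animals=300,
    informative_set=(InformativeEffect(metabolite="phenylalanine", log2fc=0.8),),
    seed=21,
)
records, matrix, catalog = simulate_cohort(cfg)
config = AnalysisConfig.reduced(B_observed=20, n_permutations=2, B_baseline=10)
result = run_full_analysis(matrix, catalog, records, config=config, seed=5)
print(result.performance_table()[
    ["time_point", "parity", "outcome", "n_cases", "n_controls", "ba_combined"]
].head(4).to_string(index=False))
print(result.stability_table("T99").to_string(index=False))
```

prints (reduced-cost configuration, so accuracies are noisy):

```
time_point parity outcome  n_cases  n_controls  ba_combined
        T1  first  new_SH       15          18     0.731481
        T1  first  new_SU        3          18     0.611111
        T2  first  new_SH       15          18     0.675926
        T2  first  new_SU        3          18     0.555556

              subset variable    log2fc  observed_stability       T99      T100  above_T100
     T1_first_new_SH   bin091  1.084273           66.666667 58.166667 60.000000        True
     T1_first_new_SU   bin005 -0.583806           38.333333 38.266667 45.000000       False
     T1_first_new_SU   bin091  1.008103           65.000000 38.266667 45.000000        True
                 ...      ...       ...                 ...       ...       ...         ...
```

Each row of the first table is one of the 17 prespecified comparisons;
`ba_combined` is the mean out-of-fold balanced accuracy of PLS-DA, Lasso and
random forest (0.5 is chance). The second table (47 rows in this run,
truncated here) lists variables whose observed stability exceeds the
subset's T99 threshold, with their log₂ fold-change. `bin091` — the
representative bin of the planted phenylalanine effect — is flagged above
T100 in 13 of the 17 subsets, with fold-change estimates scattered around
the planted 0.8; `result.subsets[i].report` holds the full per-variable
stability breakdown.

The same pipeline is scriptable from a shell:

```bash
solemetab simulate --out-dir data --seed 3
solemetab preprocess --matrix data/intensities.tsv --catalog data/bin_catalog.tsv --out-dir prep
solemetab subsets --metadata data/metadata.tsv --seed 1 --out-dir subs
solemetab run --matrix data/intensities.tsv --catalog data/bin_catalog.tsv \
              --metadata data/metadata.tsv --reduced --seed 5 --out-dir run
solemetab report --run-dir run
```

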