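# neoscreen

Tools for studying how a multivariate risk model can cut false positives in
expanded newborn screening for inborn errors of metabolism (IEMs), without
sacrificing case detection.

Expanded newborn screening quantifies amino acids and acylcarnitines in
dried blood spots by tandem mass spectrometry (MS/MS) and flags newborns
whose analytes fall outside laboratory normal ranges.  Single-analyte
cutoffs are noisy: recall rates of ~2% are typical while confirmed disease
is rarer than 1 in 4,000, and some presentations (e.g. citrin deficiency
with citrulline still inside its normal range) are missed outright.  This
package implements, end to end and on simulated cohorts:

* a **synthetic cohort generator** — log-normal analyte concentrations with
  covariate effects (gestational week, birth weight, collection interval),
  laboratory batch effects, rare disease cases (prevalences 1:3,000 to
  1:100,000) carrying multiplicative marker signatures, and injectable
  borderline cases whose primary marker stays within its normal range;
* **multiple-of-median (MoM) standardization** — each analyte divided by
  its laboratory-batch median, removing multiplicative lab/regional scale
  differences, plus feature vectors combining MoMs, diagnostic ratios
  (Phe/Tyr, Cit/Arg, C3/C0, C8/C0) and covariates;
* a **multi-disease risk model** — information-gain + correlation feature
  screening; an 8:2 stratified split; one-vs-rest candidate models per
  disease group from three families (random forest, gradient-boosted
  trees, feedforward network); **quantile risk scores**
  `score = 100 · F̂(p)` mapping each probability onto its rank in the
  screened population; per-group cutoffs
  `cutoff_g = min(min score of training cases, score at the
  (1 − 10·prevalence_g) population quantile)`, so every training case is
  flagged by construction; and selection of the family with the fewest
  false positives among those attaining 100% training sensitivity;
* the **cutoff-screen baseline** — per-analyte normal ranges (inclusive
  bounds), with the initial-screen → recall → retest protocol that defines
  "suspected positive";
* **evaluation arithmetic** — recall rate, per-group positive rates,
  AI-vs-physician consistent rate `100·(ai − ai_first_neg)/phys`,
  false-positive reduction `100·(phys − ai)/phys`, incidence strings
  `1:N`, and mutation allele-frequency tables, all with half-up rounding
  at the printed precision, validated against the bundled count columns of
  a five-year regional screening programme (94,648 newborns, 23 confirmed
  cases).

## Worked example

```python
from neoscreen.pipeline import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=123, n_newborns=20000), "run1")
print(manifest.metrics)
```

prints (abridged):

```text
{'n_screened': 20000, 'n_cases': 23, 'initial_positive': 611,
 'suspected_positive': 451, 'ai_positive': 245,
 'recall_rate_percent': 3.1, 'ai_positive_rate_percent': 1.23,
 'unaffected_flag_rate_percent': 1.11,
 'overall_fp_reduction_percent': 45.68,
 'selected_family': 'tree_ensemble_bagged',
 'train_sensitivity_per_group': {'PAHD': 1.0, 'PCD': 1.0, 'NICCD': 1.0,
                                 'MMA_PA': 1.0, 'IVA': 1.0},
 'test_cases': 4, 'test_cases_flagged': 4,
 'test_sensitivity_percent': 100.0}
```

Reading: of 20,000 simulated newborns carrying 23 planted cases, the
cutoff baseline initially flagged 611 (3.1% recall) and retained 451
suspected positives after retest; the selected random forest flagged 245
samples (1.23%) — a 45.7% reduction — while flagging every planted
training case and all four held-out cases (no MCADD case was drawn at
this seed, so that group was dropped from the run with a warning).
The same run is available from the shell:

```bash
neoscreen run-all --seed 123 --out run1
```

Other subcommands (`simulate`, `train`, `screen`, `predict`, `evaluate`,
`reference-fixture`) expose the individual stages; see `neoscreen --help`.

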