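# lrpldx

Diagnostic-rule analysis for **lateral retropharyngeal lymph (LRPL) nodes in
nasopharyngeal carcinoma (NPC)**.

When an NPC patient is staged, the radiation dose delivered to each LRPL node
hinges on whether the node is called metastatic — and since these deep nodes
cannot be biopsied before chemoradiation, the call rests entirely on imaging.
Standard practice thresholds the node's **minimal axial diameter (MIAD)** on
MRI near 6 mm.  This package implements the full workflow for asking whether
the other measurable parameters — **maximal axial diameter (MAAD)**, **maximal
coronal diameter (MACD)**, and the PET/CT **mean standardized uptake value
(NSUVmean)** — buy any additional accuracy over the single MIAD cutoff:

* **Optimal single-parameter cutoffs** by accuracy and by Youden's index
  *J = Se + Sp − 1*, with empirical ROC curves and trapezoidal AUC
  (bootstrap 95% CI).  The orientation is fixed: *value ≥ cutoff ⇒ positive*.
* **Exhaustive combined-rule search** ("brute force attack") over
  multi-threshold decision rules, MIAD-first.  Three templates:

  ```
  AND:     positive ⇔ MIAD ≥ c₁ ∨ (MAAD ≥ c₂ ∧ MACD ≥ c₃)
  OR:      positive ⇔ MIAD ≥ c₁ ∨ (MAAD ≥ c₂ ∨ MACD ≥ c₃)
  STAGE2:  positive ⇔ MIAD ≥ c₁ ∨ NSUV ≥ c₄ ∨ (MACD ≥ c₃ ∧ MAAD ≥ c₂)
  ```

  Every cutoff vector on the measurement grid spanned by the observed values
  is evaluated (plus +∞ sentinels that disable a clause, so the MIAD-only
  baseline is inside the search space), with per-node error accounting
  against that baseline.
* **A shallow neural network** (one tanh hidden layer, linear output, MSE
  objective, half/half train–test split) evaluated over every parameter
  combination — 7 combinations for the three diameters, 15 with SUV added.
* **Paired bootstrap comparison** of two decision rules' accuracy
  (median or mean of replicate accuracies, percentile 95% CIs, optional
  paired *t*).
* **A synthetic cohort generator** that reproduces the statistical structure
  of such node cohorts (correlated lognormal diameters with MIAD ≤ MAAD by
  construction, a zero-inflated SUV channel from qualitatively negative PET
  reads, ~50.8% prevalence) and a planted-rule mode for exact
  parameter-recovery studies.

Analyses are node-level; two stages are distinguished: **stage I** (three MRI
diameters, n≈663 in the motivating cohort) and **stage II** (plus SUVmean,
n≈410).

## Worked example

Generate a synthetic stage I cohort and run the cutoff scan and rule search
from the shell (`lrpldx --help` lists all subcommands):

```
$ lrpldx synth --n 663 --seed 1 --out cohort.csv --truth-out truth.csv
wrote 663 nodes (346 positive, 317 negative, prevalence 52.2%) to cohort.csv

$ lrpldx cutoffs --input cohort.csv --stage 1
 MIAD: cutoff 6.3 accuracy 88.7% J 0.777 AUC 0.956 (95% CI 0.942-0.969)
 MAAD: cutoff 8.4 accuracy 84.5% J 0.684 AUC 0.917 (95% CI 0.896-0.937)
 MACD: cutoff 16.6 accuracy 71.0% J 0.427 AUC 0.768 (95% CI 0.733-0.802)

$ lrpldx synth --n 663 --seed 1 --stage 2 --stage2-n 410 --out cohort2.csv
wrote 410 nodes (212 positive, 198 negative, prevalence 51.7%) to cohort2.csv

$ lrpldx rulesearch --input cohort2.csv --stage 2
best rule (stage2): {'template': 'stage2', 'c_miad': 6.3, 'c_maad': inf, 'c_macd': inf, 'c_nsuv': 3.62}
accuracy 93.4% vs baseline MIAD>=6.3 90.0%; error reduction 34.1% (14/41)
```

Reading the output: on this seed the accuracy-optimal MIAD cutoff is 6.3 mm
(the generator is calibrated so it lands near 6 mm), MIAD dominates the other
diameters on AUC, and adding an SUV clause (`NSUV ≥ 3.62`) to the MIAD
threshold rescues a net 14 of the baseline's 41 errors on the stage II
cohort.  `inf` cutoffs are disabled clauses.  The same operations are
available as library functions (`scan_cutoffs`, `brute_force_search`,
`evaluate_all_combos`, `bootstrap_accuracy_compare`), and
`lrpldx run --config study.yaml` executes the whole pipeline into a
seed-stamped bundle of CSV/YAML artifacts.

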