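# Methods

## Setting and data model

The unit of analysis is a lymph node, not a patient.  Each node carries
three MRI diameters in millimetres — MIAD (minimal axial), MAAD (maximal
axial, measured first; MIAD is taken perpendicular to it, so MIAD ≤ MAAD is
a hard invariant), MACD (maximal coronal) — an optional PET/CT SUVmean, and
a binary reference label (positive/negative by follow-up MRI, the accepted
surrogate where histology is unobtainable).  Patient identifiers are kept
for provenance and for optional cluster resampling, but every analysis is
node-level, matching the field's practice.

Nodes read as *qualitatively negative* on PET carry no measured SUV; their
SUVmean is imputed to exactly 0 for analysis and flagged.  The imputation is
idempotent (an analysis-ready file re-reads bit-identically) and auditable
(the flag is stored next to the value).  Stage I uses the three diameters;
stage II additionally requires an SUV value (measured or imputed) for every
node.

All measurements live on a fixed grid — 0.1 mm for diameters, 0.01 for
SUV — reflecting electronic-caliper resolution.  Values and cutoffs are
snapped through one shared half-up rounding function, so `>=` comparisons
between data and thresholds are exact with no float drift between code
paths.  The note on rounding: half-up is applied at float-representation
precision (16.95 stored as 16.949 999… snaps to 16.9); since every value
passes through the same function, comparisons remain consistent.

## Single-parameter cutoffs and ROC

The decision orientation is fixed throughout: *value ≥ cutoff ⇒ positive*
(spreadsheet formulations of such rules often use strict `>`; on the
measurement grid `> (c − step)` and `≥ c` define the same classifier, so
the convention is immaterial once cutoffs are grid-aligned).  Candidate
cutoffs are all observed values, the grid-snapped midpoints between
adjacent observed values, and one grid step above the maximum (the
"call everything negative" rule) — exhaustive, because the decision
function only changes at observed values.  Two criteria are supported:
accuracy and Youden's *J* = Se + Sp − 1.  When several cutoffs tie, the
**largest** wins: the most conservative rule, calling the fewest nodes
positive (the literature's stated concern is overtreatment of negative
nodes).  When the two criteria disagree, both results are reported; the
pipeline's downstream default is the accuracy optimum.

ROC curves are empirical (scikit-learn), AUC by trapezoid; the AUC 95% CI
is a stratified bootstrap (positives and negatives resampled separately,
2000 replicates, percentile interval) — a CI construction had to be chosen,
and the percentile bootstrap makes no distributional assumption.  Tests
cross-check the AUC against the tie-corrected Mann–Whitney statistic
U/(n⁺n⁻), an independent identity.

All derived metrics (accuracy, Se, Sp, PPV, NPV, J) are exact rationals
internally; display rounding is half-up to one decimal percent, applied
only in the presentation layer.  A metric with an empty denominator (PPV
with no predicted positives, say) is UNDEFINED — a value, rendered as "—",
never coerced to 0.  Published tables of this workflow contain small
rounding inconsistencies (the same ratio printed as 89% in text and 88.6%
in a table; a cohort fraction printed as "337 of 523" where the
denominators elsewhere make it 337 of 663); keeping internal values exact
and rounding only at display absorbs the former, and the latter is treated
as a typo — 663 is used — without attempting to reverse-engineer it.

## Combined-rule search

Three MIAD-first rule templates are defined (see README).  The search
enumerates every cutoff vector on the grid spanned by observed values,
plus a +∞ sentinel per secondary parameter that disables its clause.
Consequences: the MIAD-only baseline is a point of the search space, so
the optimum can never fall below it; and the grid is exhaustive for the
same reason as in the single-parameter scan.

The MIAD cutoff is fixed *first* (default: the cohort's accuracy-optimal
single cutoff), and the secondary cutoffs are searched jointly — not
greedily — so a sequential narrative ("the SUV clause rescued four nodes,
the diameter clause three") can be audited from the per-node ledger rather
than assumed.  A `scan_miad` mode sweeps the MIAD cutoff as well.  Note
that fixing MIAD at a value other than the cohort's own optimum (a
deliberate option, mirroring the published protocol of carrying the larger
stage I cutoff into stage II) can make the search optimum fall below the
free-MIAD baseline; the error accounting reports this honestly as a
negative reduction.

Tie-break among equal-accuracy rules: higher specificity first, then the
lexicographically largest cutoff vector in the order (MIAD, NSUV, MACD,
MAAD) — again the most conservative choice.  The implementation evaluates
the full grid via 2-D suffix-sums of class histograms over the
(MAAD, MACD) grid with an outer sweep over SUV (and MIAD, if scanned)
cutoffs; it is exactly equivalent to the naive quadruple loop, and a
standing test asserts equality — optimum, tie-break and all — on small
cohorts.  The full audit table of evaluated rules is materialized when the
search space holds at most `audit_limit` combinations (default 200 000);
beyond that only the evaluated-rule count is reported, since a
billion-row table serves no audit purpose.

Error accounting against the baseline reports baseline errors, rescued
false negatives/positives, newly introduced errors, and the
**error-reduction rate** = net corrected / baseline errors, plus a
per-node ledger classifying every node as rescued / newly wrong /
unchanged.

## Neural-network evaluation

The classifier is the classical tabular setup: one hidden layer of tanh
units (default 5 — the width is not dictated by the workflow; a small
width resists overfitting ~300-row training sets and is configurable and
reported), a linear output unit, 0/1 targets, mean-squared-error
minimization, decision threshold 0.5 (the natural midpoint for 0/1 targets
under MSE).  Implementation is scikit-learn's `MLPRegressor` with the
L-BFGS solver, which is deterministic given the seed; the training log
records the final training MSE and iteration count (L-BFGS exposes no
per-iteration curve, so monotonicity is checked in tests by comparing
iteration budgets rather than reading a curve).

Inputs are z-scored with training-split statistics only, which subsumes
any per-channel unit scaling of the SUV channel.  The cohort is split
roughly in half at random — **not stratified**, faithfully reproducing the
original protocol; a single-class training draw is redrawn with the next
seed and a warning.  There is no validation set and no early stopping
beyond the iteration cap, again by protocol.  All 7 (stage I) or 15
(stage II) nonempty parameter combinations are evaluated, by default on
one shared split (the published tables imply a single split; per-combo
splits are a flag).

Zero-imputed SUV nodes enter training as true zeros.  Because only
label-negative nodes are ever qualitatively negative, the zero point mass
is label-informative and a flexible classifier exploits it — visible in
the synthetic results as SUV-containing combinations outperforming the
SUV cutoff rule.  This bias is a faithful property of the emulated design
and is deliberately not corrected.

## Bootstrap comparison

Each replicate draws `n` nodes with replacement (defaults n = 100 cases,
B = 100 replicates) and evaluates **both** rules on the same draw — a
paired design, so the difference distribution excludes between-draw
variance.  Summary is the median of replicate accuracies with percentile
95% CIs (the CI construction is unspecified in the motivating workflow;
percentile is the assumption-free default).  MEAN mode adds a paired
*t*-test across replicates.  That computation treats bootstrap replicates
as independent observations — they are resamples of one cohort, so the
*t* and its p-value are descriptive indices, not calibrated error rates;
this caveat is reproduced by design because the workflow being
implemented reports exactly that statistic.  Replicates containing a
single class are kept (accuracy remains defined).  The sampling unit is
the node; `cluster_by_patient=True` resamples whole patients instead,
acknowledging within-patient correlation, as a documented divergence
option.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, so the
whole pipeline is testable without any clinical data:

* **Diameters**: class-conditional correlated lognormals on
  (log MIAD, log MAAD, log MACD).  Sampling re-expresses the model as
  (log MAAD, log MACD, d = log MIAD − log MAAD) and clips d at 0, i.e.
  MAAD is drawn together with an eccentricity ratio in (0, 1] — so
  MIAD ≤ MAAD holds by construction, and the grid snap preserves it
  (rounding is monotone).
* **SUV**: class-conditional lognormal among measured nodes, plus a point
  mass at exactly 0 for the fraction of negative nodes read qualitatively
  on PET (default 0.6 of negatives, matching 120 unmeasured of ~199
  negative stage II nodes).  Since lognormal draws are almost surely
  nonzero, zeros in a generated cohort are exactly the imputed ones — a
  bookkeeping identity the sidecar records and tests assert.
* **Labels**: either the latent mixture class (realistic overlap), or a
  planted decision rule applied to the measurements with an optional
  label-noise rate.
* **Calibration**: defaults (prevalence 0.508, n 663; class means/SDs in
  the source) are set so the accuracy-optimal cutoffs land near the
  published optima — MIAD ≈ 6 mm with accuracy in the high 80s%,
  MAAD ≈ 8–10 mm, MACD ≈ 16 mm, SUV ≈ 1.8.  The real class-conditional
  distributions were never published; the calibration targets only these
  cutoff neighbourhoods, and nothing else about the real cohort's
  marginals should be read into the defaults.

**Planted-rule mode and identifiability.**  Because candidate cutoffs are
observed values, a planted threshold can only be recovered to within one
grid step if observed values straddle it *within the stratum where the
clause is decisive* (e.g. MACD near 25 mm among nodes with MIAD below the
primary cutoff and MAAD above its partner threshold).  Under the mixture
model such strata are sparse and the nearest observed gate value can sit
several grid steps away, making exact recovery impossible for any search
procedure — a property of the design, not the algorithm.  The planted
mode therefore dedicates a fraction of nodes (default 0.4) to "equivocal"
designs: one active threshold is chosen per node and the node is placed
uniformly within ±5 grid steps of it, with the remaining parameters set
so that threshold alone decides the node.  This is precisely the design
condition a parameter-recovery simulation requires, and it mirrors the
clinical reality that cohorts assembled for cutoff studies are enriched
for equivocal nodes.  Labels remain a pure function of the measurements.

The generator emulates the *statistical* structure only: no measurement
error model, no reader variability, no partial-volume or spill-in physics
on the SUV channel, no within-patient correlation of diameters (patients
are synthetic two-node groupings).  Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated model —
not clinical performance of any cutoff on real patients.

## Problem sizes, seeds, determinism

The default study sizes are those of the emulated design: 663 nodes
(stage I), a 410-node stage II subset, half/half NN splits, 100×100
bootstrap with a 10 000-replicate reference run in tests, 2000-replicate
AUC bootstrap.  Oracle-equivalence tests run on ≤ 30-node cohorts where
the naive quadruple loop is feasible.  Every stochastic component takes a
seed; the pipeline derives per-module seeds from one master seed via
`SeedSequence(master).generate_state(...) mod 2³¹`, recorded in every
artifact header together with a hash of the analysis configuration, and
reruns are byte-identical.

## Known limitations

* The reference standard is follow-up imaging, not histology; the
  generator inherits that definition.
* Node-level analyses ignore within-patient correlation (the cluster
  bootstrap flag is the one concession).
* The search optimizes in-sample accuracy; with four free thresholds it
  can overfit modestly (visible in synthetic runs as error-reduction
  rates above the published 13.3%), and the bootstrap comparison
  resamples the same cohort rather than validating externally.
* The NN reproduces an architecture, not published weights; its
  accuracies on synthetic cohorts are cohort-dependent and only the
  table *shapes* and sanity properties are contractual.
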