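# Methods

## Scope and data model

The package analyses a cohort table of subjects × features, where each
feature carries a kind tag (`clinical` ordinal descriptors, `analyte`
positive concentrations, `tf` simulated activations, `admin` flags) and a
declared ordinal range for clinical columns.  The seven descriptors follow
the instruments they emulate: WOMAC joint pain (5 Likert items, score
0–20), functionality (17 items, 0–68), rigidity (2 items, 0–8), a central
sensitization grade (0–3), HAD depression (0–21), pain catastrophizing
(0–52), and an echographic synovitis grade (0–3).  The analyte panel is
the 11-plex synovial-fluid set (IL-6, IL-8, IL-4, TNF-α, IL-18, IFN-γ,
IL-17, IL-1RA, MCP1, VEGF-A, leptin).

## Synthetic cohort generator

Real cohort data are access-restricted, so the generator emulates the
structure the analysis assumes rather than any measured distribution.

* **Latent-trait descriptors.** Each descriptor has a Gaussian latent
  trait; ordinal values are obtained by cutting the latent at *population*
  quantile cuts (located once by a 200 000-draw Monte-Carlo with a fixed
  internal seed, independent of the user's seed).  Using population rather
  than per-sample cuts makes "the planted cut" a well-defined object that
  a threshold search can recover.  Multi-item questionnaire scores sum
  items that share the latent trait plus item-specific noise, each item
  discretized at its own population cuts.
* **Planted effects.** An effect `(feature, descriptor, effect, direction,
  kind)` adds `direction · effect · noise_sd · g(z)` to the descriptor's
  latent, with `z` the feature's standardized driver and `g` either the
  identity (`kind="linear"`) or a step `1{z > 0}` (`kind="step"`).  Both
  are monotone.  The distinction matters for threshold recovery: under a
  linear effect every quantile cut of the latent is (to first order)
  equally discriminable from the feature, so no single cut is privileged;
  a step effect shifts the whole latent between the feature's low and high
  halves, making the cut at the mixture's median the uniquely recoverable
  one.  Effect sizes are expressed in latent-noise SDs.
* **Analytes** are log-normal (right-skewed, strictly positive, as Luminex
  panels are); the same standard-normal driver feeds the analyte value and
  any planted effect, so associations are exactly monotone.  Analytes are
  missing outside the first `n_sf_subset` subjects (the effusion subset).
* **Reproducibility.** One global seed expands into per-stream child seeds
  via `SeedSequence([seed, blake2s(stream_name)])`, so any column's values
  are independent of generation order, and the emitted CSV is
  byte-identical across runs.
* **Default study structure.** Leptin loads on every descriptor (2.0
  noise-SDs; 1.5 on synovitis, which MCP1 leads at 2.0 with VEGF-A at
  1.0), and each descriptor has a distinct secondary analyte driver at
  1.0.  The shared leptin axis makes each descriptor predictable from the
  remaining six — all seven clear the 0.75 binarization gate across seeds
  — while any descriptor pair shares only that axis, keeping expected
  pairwise correlations below the 0.7 redundancy cutoff.  This mirrors the
  qualitative account the pipeline is meant to probe (systemic low-grade
  inflammation as a common driver; macrophage recruitment/angiogenesis
  behind synovitis).
* **External table.** Features come in equicorrelated blocks (default 300
  features, block size 4, within-block r = 0.6 — deliberately below the
  0.7 pruning cutoff).  Six WOMAC-style targets (left/right pain 0–20,
  function 0–68, rigidity 0–8) are driven by a disjoint 8-feature
  informative set per subscale; left/right knees share the set but not the
  noise.  A surgery-history flag and per-cell missingness complete the
  protocol surface.  The default planted signal in the validation analyses
  is strong (16 noise-SDs): in real OAI tables the WOMAC subscale targets
  are *computed from* item columns present in the table, so the
  feature→target map is near-deterministic; a weak-signal table would
  emulate a different situation than the one the threshold-transfer
  protocol faces.

What the generator does **not** emulate: real OAI variable coding,
longitudinal visits, imaging variables, non-monotone or interaction
effects, heteroscedastic noise, and informative missingness.  Passing
tests therefore demonstrate that the pipeline recovers structure it is
pointed at, not that the original cohort's effect estimates are correct.

## Binarization

Candidate thresholds are the midpoints between consecutive distinct
observed values.  For each candidate, the descriptor is binarized
(label 1 = above threshold, the "worse symptoms" pole of the scales) and a
nested leave-one-out linear SVM predicts the labels from the supplied
feature set (by default the remaining descriptors in continuous form);
Youden's J is computed from the pooled held-out predictions, the least
optimistic convention, while the 0.75 retention gate uses the mean
train-fold accuracy, matching a train-set gate.  Ties in J resolve to the
smallest threshold.  Candidates leaving either class with fewer than two
members are skipped, since leave-one-out training folds would otherwise be
single-class.  The default classifier configuration for the threshold
search uses a single penalty value (C = 1, no inner tuning); the grid is a
config field.

Two caveats discovered during calibration, both properties of the gate
rather than of the implementation: (i) under a pure-noise feature the
J-maximizing cut is often an unbalanced one whose majority class alone
exceeds 0.75 train accuracy, so the gate rejects noise reliably only for
near-balanced splits; (ii) recovery of a planted cut at n = 51 requires a
step of roughly 4 noise-SDs — at 2 SDs the population J of adjacent
quantile cuts differs by less than its sampling SD, and selection between
them is near-random.

## Regulatory-network model

The simulator is topology-agnostic: a SIF-like TSV
(`source TAB sign TAB target [TAB weight]`) plus an optional YAML sidecar
for roles, gains `h` and decays `γ` (defaults: h = 10, γ = 1, weight = 1;
roles inferred as input = no in-edges, output = no out-edges when not
declared).  Non-input nodes follow the normalized-sigmoid rate law

    dx_i/dt = s(ω_i; h_i) − γ_i x_i,
    s(ω; h) = (−e^{h/2} + e^{−h(ω−1/2)}) / ((1 − e^{h/2})(1 + e^{−h(ω−1/2)})),

with total regulatory input ω = A·(1−I), where over activators
A = ((1+Σα)/Σα)·(Σα x_a)/(1+Σα x_a) (A = 1 with no activators) and I is
defined identically over inhibitors (I = 0 with none).  A node with no
regulators at all decays (ω = 0); the "A = 1" convention applies only to
inhibitor-only nodes — this matters in the inputs-as-initial-conditions
mode, where former input nodes must be allowed to decay.

Patient analytes are min-max rescaled across the cohort (a constant
analyte maps to 0.5, flagged) and by default **clamped** at the input
nodes for all t, so the steady state reflects the sustained patient
signal; `inputs_as_ic=True` instead only initializes them.  Integration
uses LSODA in windows of 25 time units until `max|dx/dt| < tol`
(tol = 1e-6) or `t_max = 500`; activations are clipped to [0,1] only to
absorb solver round-off, and non-converged patients are flagged, never
dropped.  Non-input nodes start at 0.5 (an unbiased mid-state) unless
overridden; for acyclic cascades the steady state is verified to be
initialization-independent.

The bundled 19-node chondrocyte-like network (8 analyte inputs, 3
signalling hubs, 8 output TFs: CITED2, CREB, Runx2, FOXO, SOX9, HIF2a,
NF-κB, AP1) is an illustrative example — pro-inflammatory inputs activate
the NF-κB/AP1 arm and repress the FOXO/SOX9 anabolic arm — not a validated
model of chondrocyte regulation.

## Classification

Features are z-scored with train-fold statistics inside every fold (SVM
weights are not comparable across unscaled features, so the importance
claim requires it).  The penalty C is tuned per outer fold by inner
stratified k-fold (k = 5, reduced to the minority count when necessary)
over the grid 10^−3 … 10^3, accuracy metric, ties to the smallest C
(strongest regularization).  Two outer fold modes: `standard` (N folds)
and `paper_compat` (subjects 1..N−1 held out, N−1 folds — the convention
that yields 50 fits for 51 subjects and 24 for 25, with the weight mean
divided by N−1).  Importances are |fold-mean weight| min-max mapped to
[0,1] (all-equal magnitudes map to 1, all-zero weights to 0 with a flag);
signed means are retained for audit.  The ROC-AUC is the Mann–Whitney
statistic over pooled held-out decision values — leave-one-out yields one
decision value per fold, so pooling is the only well-defined "nested" ROC;
ties count one half.  The solver is libsvm's exact hinge dual
(`SVC(kernel="linear")`); a liblinear hinge backend (iteration-capped) is
provided for thousand-row problems where the dual solver's cost is
prohibitive, and is the external-validation default.

## External validation

Stage order is fixed: surgery-flag exclusions → 80% completeness filter
(inclusive at exactly 0.8) → greedy pairwise Pearson pruning in column
order at |r| > 0.7 (absolute value: a strong negative correlation is
equally redundant) → information-gain ranking (base-2; continuous features
in 10 equal-frequency bins, ordinal features with ≤ 10 distinct values
used as-is) keeping the top 50 → per-target C-tuned linear SVM.  Each
WOMAC-style target is binarized at the transferred cohort threshold; a
declared ordinal range that cannot contain the threshold raises a
scale-mismatch error rather than silently rescaling.  Accuracy is
stratified 5-fold cross-validation (seeded) — a single train-set accuracy
would be optimistic — and the scheme is recorded in the report.  Remaining
missing feature cells are median-imputed after pruning.

## Numerical and design notes

* Youden's index requires both classes non-empty; callers skip undefined
  candidates.
* Pearson correlations use pairwise-complete observations and raise on
  constant input rather than returning NaN.
* The information-gain discretization and the pairwise-versus-target
  pruning split (cohort stage prunes against the target, validation stage
  prunes pairwise) are recorded in each SelectionReport.
* `sigmoid` satisfies its anchors s(0)=0, s(½)=½, s(1)=1 to 1e-12 across
  gains 1–50; trajectories remain in [0,1]^n.
* Problem sizes in the shipped analyses — 51/25-subject cohorts, 2000-row
  external tables, 50-seed recovery experiments — are the study's stated
  or emulated scales and keep every script in the minutes range on one
  CPU.

## Known limitations

* The pooled leave-one-out AUC at n = 50 has wide sampling variability:
  with a single 3-SD informative feature among 9 noise features its 5th
  percentile sits just below 0.9, so "AUC ≥ 0.9" cannot be guaranteed in
  more than ~90–94% of seeds even though the informative feature's
  importance reaches 1.0 essentially always.
* The retention gate inherits the majority-class inflation of train-set
  accuracy at unbalanced cuts (see Binarization).
* The bundled network is illustrative; TF-input results on synthetic
  cohorts probe the pipeline's mechanics, not chondrocyte biology.
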