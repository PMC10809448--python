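# Methods

## The measurement model

Every batch measures the same four reference materials (D5, D6, F7, M8) in
triplicate. On the log2 scale the package treats an observed abundance as

    log2 v(lab, metabolite k, group s, replicate r)
        = baseline_k + effect_{k,s} + offset_{lab,k} + ε,   ε ~ N(0, σ_rep²)

The decisive structural assumption is that `offset_{lab,k}` — ionisation
efficiency, calibration, column chemistry, any per-lab multiplicative
response — is shared by **all 12 samples of the batch**. Ratio scaling
(dividing each sample by the concurrently measured D6, metabolite by
metabolite) then removes it identically, not just in expectation. All
integration and reference machinery rests on that cancellation; where the
assumption fails (group-dependent batch distortions), ratio scaling cannot
fully repair the data, and the generator's
`group_dependent_batch_effects` mode exists to demonstrate exactly that.

## Metrics

**CV** is the sample SD over replicate abundances divided by their mean,
on the raw scale (a CV of a logged quantity is not meaningful). A
metabolite's filter value aggregates the four per-group CVs with the
maximum by default (the strict reading of "CV < 30%"); a mean aggregate is
available. Default threshold `cv_max = 0.30`.

**ICC** is the single-measure, two-way, absolute-agreement intraclass
correlation ICC(A,1), computed from the two-way ANOVA decomposition with
the four groups as subjects and the three replicates as raters, on log2
abundances (variance stabilization across groups): with n subjects and k
raters,

    ICC(A,1) = (MS_subj − MS_err) / (MS_subj + (k−1) MS_err
                                     + (k/n)(MS_rater − MS_err)).

The implementation is a vectorised closed form (one pass over all
metabolites at once); the test suite cross-checks it against pingouin's
two-way agreement ICC. Default threshold `icc_min = 0.4`. Agreement, not
consistency, is deliberate: a replicate with a constant offset is a real
reliability problem for quantification.

**SNR.** Metabolites present in all 12 samples (optionally further
filtered) are log2-transformed and autoscaled per metabolite, projected on
two principal components via SVD, and the decibel ratio of the weighted
mean squared between-group distance (54 pairs) to the within-group
distance (12 pairs) is reported, each squared coordinate difference
weighted by the component's explained variance fraction. Autoscaling is
the default preprocessing because metabolite intensities span orders of
magnitude; plain centering (`log2_center`) is offered for sensitivity
analysis. The PCA sign convention (largest-magnitude loading positive)
makes scores bit-reproducible; SNR itself is sign-invariant. Zero noise
(coincident replicates) raises a degenerate-input error rather than
returning +∞.

**DAM calling** is a two-sided t-test on the log2 replicate values with
raw p < 0.05; the log2 fold change is the difference of group means. Welch
(unequal variances) is the default — the safer choice when variances may
differ — with the pooled Student variant by config. At n = 3 per group
the Welch approximation is *conservative* under an equal-variance null
(observed type-I ≈ 0.035 at α = 0.05 in the calibration run), while the
pooled test is exact there (≈ 0.050); the calibration check therefore
asserts the nominal band on the pooled variant and only
non-anti-conservatism for Welch. No multiple-testing correction enters the
calling criterion; a Benjamini–Hochberg column is emitted for information.

**Ratio profiles** are stored as log2 ratios. Numerically, ratios are
formed by **dividing raw values before the log**: `mean_denominator`
computes `mean_i log2(v / d_i)` over the reference replicates (identical
to log2 of the value over the geometric mean of D6, but the division lets
shared factors cancel inside the quotient — power-of-two factors cancel
bit-exactly, arbitrary ones to an ulp), and `replicate_paired` computes
`log2(v_r / d_r)` with matched acquisition rounds. `mean_denominator` is
the default: it is robust to a single hot reference replicate and matches
the geometric-mean pooling used downstream.

**Reference datasets** follow a four-step consensus: (1) a metabolite is
*detected* in a group when all three replicates are measured; (2) it is
*reproducible* when detected in all four groups of the same batch in at
least two batches ("more than one dataset" is ≥2 throughout, and the
same-batch reading is used); (3) consensus DAMs have p < α in at least two
batches; (4) the reference value is the mean of the pooled per-replicate
log2 fold changes over all supporting batches — the log-space geometric
mean, pooled flat rather than as a mean of per-dataset means, so every
replicate-level estimate carries equal weight (per-dataset-mean-first
pooling is available). Replicate fold changes use matched replicate
indices; a supporting batch without matched replicates contributes its
mean-based fold change with a provenance note. CV/ICC filtering inside the
builder is off by default (the detection rule alone defines
reproducibility) and available behind a flag. Pooling iterates batches in
lexicographic batch-id order so results are exactly independent of input
order.

**Proficiency.** Recall is the fraction of reference DAMs the query also
calls, pooled over the three pairs; by default the denominator is
restricted to reference DAMs the query measured, so the metric reads as
calling sensitivity rather than panel coverage (the unrestricted
denominator is a config). Relative correlation pools the per-metabolite
measured log2 ratios (mean of the numerator group's ratio-to-D6 values)
against the reference values across the three pairs and takes one Pearson
coefficient. Each of SNR/RC/recall is min–max scaled to [0, 10] across the
scored cohort (anchors recorded in the report, so scores are reproducible
as the cohort grows), the total is their mean (staying on the 0–10 scale
when a metric is missing), and levels are the cohort quartiles of the
total score. Quartiles, not fixed cutoffs, because the level boundaries
are inherently cohort-relative; reports from different cohorts are not
comparable by level label.

**Levey–Jennings monitoring** tracks, per metabolite, the per-run mean of
the log2 group abundances (absolute level) or log2 pair ratios (ratio
level) and flags runs beyond ±3 SD of the across-run mean; a metabolite
is "deviated" when at least one of its runs is flagged (stricter
consecutive-run rules are available but non-default). Series whose
across-run SD is zero — to within a few ulp of the mean, since identical
runs leave rounding residue — are marked constant and never flagged.

## The synthetic generator

`simdata.simulate` draws the model above with a single integer seed
(per-lab substreams spawned deterministically, so output is bit-stable).
Defaults describe the multi-laboratory study setting the package targets:
7 laboratories, 200-metabolite panels, baseline log2 intensity
N(20, 2²), biological group effects N(0, 0.5²) for every metabolite plus
planted D5/F7/M8-vs-D6 contrasts of |log2 FC| ∈ [1, 3] on a 25% DAM
fraction, per-lab×metabolite batch offsets N(0, 1²) (large enough to
dominate absolute-level clustering), replicate noise SD 0.2 log2 units
(≈ 15% CV), and 10% whole-metabolite dropout per lab — mirroring the
panel selectivity of independently developed assays; per-cell dropout is
available for complete-case testing.

What the generator does **not** emulate: retention-time drift, ion
suppression and other intensity-dependent distortions, missingness that
depends on abundance (censoring at the detection limit), heavy-tailed or
correlated replicate noise, and spike-in controls. Passing tests therefore
demonstrate the algebraic and statistical behaviour of the methods under
the stated model — in particular that ratio scaling removes exactly the
batch effects it is designed to remove — not that any particular real
instrument meets the model.

## Numerical choices

- Deterministic SVD-based PCA with a fixed sign convention; constant
  metabolites are dropped before autoscaling.
- Division-before-log ratios and canonical batch-order pooling make the
  batch-cancellation invariants exact (see above); file writers emit
  shortest round-tripping float representations so write→read is
  bit-identical.
- Degenerate t-tests (both groups constant) get p = 1 when means are equal
  and p = 0 otherwise, keeping p ∈ [0, 1].
- Zero-variance metrics in a scored cohort scale to 10 for every batch
  (logged); rank ties break lexicographically on batch id.
- Missing values are never imputed; each operation declares its own
  completeness requirement (complete-case for PCA/SNR/ICC, ≥2 replicates
  per group for CV and t-tests, all-replicates for detection).

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run on simulated studies of
30–200 metabolites and 1–7 laboratories, 100-seed replications for
stochastic properties, and 10,000 metabolites for the null calibration of
DAM calling; these sizes make every property estimate stable while the
whole suite completes in well under a minute on one core.

## Known limitations

- Recall's denominator choice (measured reference DAMs) and the
  replicate-pairing convention for fold changes are field-ambiguous; both
  are configs with documented defaults, and results can shift slightly
  between conventions.
- Proficiency levels are cohort-relative quartiles; they are not portable
  across cohorts and are not intended to reproduce any externally
  published level labels.
- Harmonisation merges strictly by HMDB accession, then by exact
  (case/whitespace-folded) name — no fuzzy matching, so spelling variants
  of unannotated metabolites stay split.
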