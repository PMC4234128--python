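# Methods

## Measurement model and preprocessing

All signals are carried as log10 ELISA intensities. Replicates are averaged
arithmetically in the log10 domain (a geometric mean in linear units), which
treats measurement error as multiplicative — the natural model for
plate-based immunoassays.

For each (cell line, target) the unstimulated time-0 controls give a control
model: mean μ and sample SD s (ddof = 1; at least two control replicates are
required). A condition's fold-change trajectory is the averaged log10 level
minus μ at each post-stimulation time; its summary is the maximum over
times, and at reporting boundaries linear fold = 10^value.

**Significance rule.** A response is significant when its maximum averaged
level satisfies both `level ≥ μ + m·s` (m = 2 by default) and `level > μ`.
The first clause is the conventional rule — with `2s = log10(1.2)` the
smallest significant response is exactly a 1.2-fold change, which the
acceptance script verifies by bisection. The second clause matters only in
the degenerate case s = 0 (noiseless data, e.g. synthetic panels at σ = 0):
it keeps an exactly flat trajectory non-significant while any strictly
positive excursion remains significant. For any s > 0 the two rules are
identical. The boundary is inclusive: exactly m SDs above the mean counts
as significant.

Control statistics are pooled per (cell line, target) over all control
replicates; no further stratification (plate, batch) is attempted.

## Kinetic classification

Trajectories of log10 fold-change at (10, 30, 90) min are pooled across
cell lines, ligands, targets and doses and clustered with k-means, k = 4,
squared-Euclidean distance, 10 random restarts (best by within-cluster sum
of squares), fixed seed. Centroids are then named by shape:

* the lowest-peak centroid (ties broken toward the flattest) → **none**;
* an early peak (index 0 or 1) whose final value is below half the peak →
  **transient**;
* a final-time peak whose initial value is below half the peak → **late**;
* anything else → **sustained** (also the fallback for degenerate
  centroids).

Significance overrides geometry: a trajectory failing the 2-SD rule is
labeled `none` whatever its cluster.

**Feature scaling.** By default each trajectory is divided by its own peak
before clustering, with the divisor floored at the significance scale
(m times the panel-pooled control SD, the root mean square of the per-group
SDs). Responses of any amplitude then map onto a common unit-peak shape,
while sub-threshold trajectories stay near the origin and keep populating
the `none` cluster. We chose this over clustering raw pooled trajectories
because with a continuous amplitude distribution the raw feature space
cannot separate shape from amplitude: a weak sustained response lies closer
to the null cluster than to the sustained one, so shape classes are not
identifiable however the clusters fall. The floor is pooled rather than
per-group because an SD estimated from duplicate controls is far too
unstable to divide by. Raw clustering remains available
(`normalize_trajectories: false`).

## Dose-sensitivity classification

From the max fold-changes and significance calls at 1 and 100 ng/ml:
`none` if neither dose is significant; `high_only` if only the high dose
is; otherwise `equal` when the low-dose response is at least 75% of the
high-dose response, else `high_greater`. The ratio is taken on linear
fold-change minus one — the response magnitude above baseline — because a
null response has linear fold 1, and subtracting it makes the `none`/`equal`
boundary coherent (a pair of barely-above-baseline responses is not
"equal" merely because their raw folds are similar). The raw-fold ratio is
available via `sensitivity_mode: fold`. The 75% boundary is inclusive.
The rule is total: the four labels partition every input.

## Pathway scale and bias

pERK and pAKT are measured on different assay scales. The scale factor α is
fit by minimising the two-sample Cramér–von Mises distance between the
α-scaled pAKT and the pERK linear fold-change distributions, by default over
significant responses at 100 ng/ml (non-responses are noise around fold 1
and would dominate the ECDFs; a config switch includes them).

`cvm_distance` is the mean over the pooled sample of the squared difference
of the two empirical distribution functions. This normalisation vanishes as
the two empirical distributions converge and is zero exactly when they
coincide; for fixed sample sizes it is proportional to the classical
two-sample statistic, so the argmin over α is unchanged. Because the
objective is piecewise constant in α, the fit is a grid search (log-spaced,
0.1–10, 121 points) with one refinement pass around the coarse minimum —
deterministic, with a warning if the optimum sits on the grid boundary.

The pathway bias of a (cell line, ligand) pair is
`atan2(α·pAKT_fc, pERK_fc)` in degrees: 45° balanced, 0° pure ERK, 90° pure
AKT, undefined (NaN) when both responses are zero. The ratio is taken on
linear fold-changes by default (`bias_scale: log_fold` switches to log10
fold-changes). The angle is invariant under common positive rescaling of
both inputs.

## Statistical panels

Correlation panels relate a response descriptor (target, ligand, dose;
fold-change or absolute maximum post-stimulation level) to basal predictors
(analyte, expression/phosphorylation) across cell lines: Pearson or
Spearman coefficient with two-sided p-value, n ≥ 3 required, constant
predictors/responses reported as missing. p-values are unadjusted by
default (flagged at p < 0.05), with optional Benjamini–Hochberg adjustment
across a panel.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 8 tie-free observations, otherwise the
normal approximation with tie correction. Responder enrichment reports the
rank-sum p plus median/IQR per group, flags the comparison as undefined
when one group is empty and as low-power when a group has a single member.

## Signaling graphs

Nodes are ligands, receptors and the two targets; edges are unweighted
ligand→receptor binding edges and ligand→target response edges weighted by
the maximum induction across all times and doses. Node size encodes log10
expression, shading log10 phosphorylation. All drawn attributes are min–max
normalised to [0, 1] with panel-wide extrema per attribute class: all
expression values pooled, all phosphorylation values pooled, and response
edges per target across all cell lines and ligands. Below-detection basal
values are floored to the detection threshold upstream, so they sit at the
panel minimum and carry an explicit flag; analytes with no measurement are
marked unmeasured, which is distinct from below-detection. Response edges
carry a significance flag (significant at either dose).

Subtype-average graphs aggregate the raw per-line log10 values with the
interquartile mean and only then normalise with the same panel extrema, so
a singleton subtype reproduces its line's graph exactly. An aggregate edge
is flagged significant when at least half the subtype's lines respond
significantly; an aggregate node is below detection when all lines are.

**Interquartile mean.** Quartiles use linear interpolation between order
statistics (the "type 7" convention); membership in [q25, q75] is
inclusive. For n = 2 distinct values both quartiles fall strictly between
the points and the window is empty; the function then falls back to the
plain mean. The convention is frozen by a brute-force oracle test.

Exports are GraphML and JSON node-link (endpoint keys renamed `from`/`to`
so the `target` edge attribute survives); both round-trip all attributes
losslessly. Node positions and any drawing of diameters/shades are left to
viewers.

## Synthetic panel generator

The generator emulates the screen's statistical structure, not any real
dataset's values. Defaults: 39 cell lines × 15 ligands × 2 doses ×
3 post-stimulation times × 2 targets × 2 replicates plus duplicate time-0
controls.

* **Responder structure.** Each (cell line, ligand, target) responds with a
  ligand-dependent probability, linearly spaced from 0.95 (broadly active,
  ErbB-like) to 0.25 across the ligand panel — averaging ~60% responding
  combinations at pERK — times 50/60 for pAKT (~50%). The probability is
  modulated multiplicatively by the line's cognate-receptor and ErbB2
  deviation from the panel mean (slopes +0.35 / −0.15 per log10 unit), so
  responder lines have higher receptor levels, as responder-enrichment
  analyses expect. Multiplicative modulation keeps the responder amplitude
  distributions of the two targets identical, so the planted pathway scale
  remains recoverable from significant responses.
* **Kinetic templates.** Responders draw a class (sustained 0.5,
  transient 0.25, late 0.25 — about half of significant responses
  sustained, the rest split). For peak amplitude a (log10), trajectories at
  (10, 30, 90) min are sustained (a, a, a), transient (a, a/2, a/10), late
  (a/10, a/2, a); non-responders are flat.
* **Amplitude model.** The pERK peak is
  `1.3 + 0.8·(receptor − 3.0) − 0.65·(ErbB2 − panel mean) + N(0, 0.1)`,
  floored at 0.4 (~2.5-fold; every planted responder stays well above the
  1.2-fold significance scale, and the compressed pAKT folds stay above 1).
  Coefficients were chosen so receptor–response correlations across a
  39-line panel land around |r| ≈ 0.65, the magnitude such screens report.
  pAKT linear folds are an independent draw from the same distribution
  divided by α_true = 2.386.
* **Dose classes.** Responders draw equal/high_greater/high_only with
  probabilities 0.40/0.35/0.25; the low-dose response magnitude
  (fold − 1) is 0.85× / 0.5× / 0× the high-dose one, making the 75% rule
  exactly recoverable.
* **Basal profiles.** Receptor expression ~ N(3.0, 0.5) log10 units;
  phosphorylation = expression − 1 + N(0, 0.3); ErbB2 gains +1.0 in
  HER2-amplified lines (subtype proportions 0.45/0.30/0.25
  TNBC/HER2amp/HR+); basal pERK/pAKT ~ N(2.0, 0.3). Values below the
  detection threshold (default 1.2) are floored and flagged.
* **Noise.** i.i.d. Gaussian in log10 (multiplicative in linear units),
  SD σ = log10(1.2)/2 by default so that the 2-SD rule corresponds to the
  ~1.2-fold significance scale. Generation is a pure function of
  (seed, config).

The ground truth records per-dose expected calls: a trajectory is expected
significant iff its planted amplitude is positive, and its expected kinetic
label is the planted class when that dose responds (a `high_only` pair has
a genuinely flat low-dose trajectory whose correct call is `none`).

**What the generator does not emulate:** plate/batch effects, heteroscedastic
or correlated noise, multi-receptor ligand binding, receptor cross-talk
beyond the single ErbB2 term, and any calibration to a real screen's effect
sizes. Passing recovery tests therefore demonstrates that the pipeline's
inference is correct under its own assumptions, not that those assumptions
hold for any particular real dataset.

## Problem sizes and numerical choices

Recovery experiments run at the full default panel size (39 × 15; 2,340
conditions, ~28k measurements), which takes well under a second per panel:
zero-noise recovery on one panel, noisy kinetic recovery pooled over 10
seeded panels at σ = 0.05 (evaluated on significant trajectories with
planted amplitude ≥ 0.5, the regime where the three shapes are defined),
correlation sign recovery over 100 seeded panels, and scale recovery on
n = 500 fold-change samples. Oracle checks use 200 random CvM sample pairs
(n, m ≤ 12, with and without ties) and 500 random interquartile-mean
inputs.

Estimated control SDs from duplicate controls are highly variable; with the
default σ this yields a noticeable false-positive significance rate on null
trajectories (the measured significant fraction on noisy panels runs ~10
points above the planted responder rate). This is a property of the 2-SD
duplicate-control rule itself and is reported, not corrected.

Ties in k-means centroid naming are broken deterministically (flattest
centroid becomes `none`; `sustained` is the fallback); k-means itself is
seeded and restarted 10 times. Min–max normalisation of a constant
attribute class maps to 0.5. Every analysis constant (m = 2, k = 4, 75%,
the α grid, fixed-α override) is a `RunConfig` field, not a hard-coded
value.
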