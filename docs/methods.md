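# Methods

## The measurement model

A cell transiting a node-pore channel displaces electrolyte and raises the
channel resistance; under constant voltage the current drops while the cell
occupies a sensing segment. The relative drop in a node-pore segment follows
the classic resistive-pulse relation with the shape-correction factor

    ΔI/I = D_cell³ / (D_e² · L) · 1 / (1 − 0.8 (D_cell/D_e)³),

where D_e is the effective channel diameter (calibrated with polystyrene
microspheres of known size, by 1-D bounded least squares over D_e) and L the
effective sensing length, defaulting to the 700 μm pore length. The relation
is strictly increasing up to the pole D_e·(1/0.8)^{1/3}, so D_cell is
recovered by bracketed root finding (Brent, |ΔD| < 1e-6 μm) on (0, pole).
The admissible blockade range is capped at 99% of the pole diameter: the
correction factor diverges there, and blockades beyond the cap (or ≥ 1) are
reported as unattainable rather than inverted to an unphysical near-pole
diameter.

In the contraction channel the cell is modelled as an oblate spheroid,
V_deform = π·w_c·L_deform²/6. The contraction blockade ΔI_c/I is taken
proportional to V_deform/V_contraction with proportionality constant 1 and
V_contraction = L_c·w_c·h (the full channel volume), giving
L_deform = √(6·(ΔI_c/I)·V_cont/(π·w_c)) and δ_deform = L_deform/D_cell.
The constant is a convention, not a calibrated quantity: only relative
differences in L_deform and δ_deform carry information, and the choice is
recorded here because the sensing volume of the contraction region (and
hence the true constant) is not identifiable from the trace alone.

The whole-cell deformability index

    wCDI = (L_c / (U_flow · h)) · (D_cell / ΔT_cont)

is dimensionless and inversely related to cortical tension / Young's
modulus: softer cells transit faster (smaller ΔT_cont) and score higher,
while the D_cell factor removes the trivial tendency of larger cells to
transit more slowly. U_flow is estimated per cell as
L_pore / mean(pre-contraction sub-pulse duration).

Recovery time ΔT_r is the elapsed time from the onset of the first
post-contraction sub-pulse until the sub-pulse deficit first returns to
within 2% of ΔI_np (the source protocol defines "returned" qualitatively;
the 2% band is this package's choice). Cells still deformed at 120 ms — the
observation window for the default geometry and flow — are recorded as
`Inf`. The applied strain is ε = (D_cell − w_c)/D_cell, ≈ 0.4 for the
default 10.5 μm contraction width and ~17.5 μm cells.

## Pulse extraction

Detection needs no template: the baseline is anchored on the 99.5th
percentile of the current (cells only depress it), per-sample noise is
estimated from the MAD of first differences, and samples below
baseline − max(5σ, 0.1% of baseline) open a sub-pulse that closes with
hysteresis at half that depth. Sub-pulses closer than 25 ms (node transits)
form one cell event; dips shorter than 1 ms are discarded as noise blips.
An event is usable when its sub-pulse count matches the channel's segment
count and the deepest sub-pulse sits in the contraction slot. Events with
more sub-pulses than segments, or any sub-pulse longer than 100 ms (no
single segment transit lasts that long at the simulated flow range), are
flagged `coincident` — two cells in the channel produce merged or extra
drops — and events with missing segments are flagged `incomplete`; flagged
events are excluded from features, never silently dropped, and no
deconvolution is attempted.

The recovery crossing uses the midpoint between the unrecovered deficit
(measured at the start of the first post sub-pulse) and ΔI_np, never below
ΔI_np·(1 + 2%). On noiseless traces the per-sample crossing is exact to one
sampling interval; with appreciable noise the deficit is smoothed by a 3 ms
moving mean and the crossing reported at the window centre, which is
unbiased at a step-like relaxation.

## The synthetic-data generator

The generator is phenomenological at the sub-pulse level — it reproduces the
three-region pulse structure (pre-contraction pore drops, one contraction
drop, recovery drops relaxing to ΔI_np on a noisy baseline) without solving
channel electrokinetics or hydrodynamics. Defaults: 10 kHz sampling (ms
sub-pulses resolved at low cost), baseline 1.0 normalised with Gaussian
noise σ = 1e-4 of baseline, node-pore flow speed ~N(15, 0.8) μm/ms truncated
to [13, 17]; the 25 kPa drive and 1 V bias are geometry metadata only.

Populations draw the free diameter from a truncated normal (bounds
w_c + 0.5 μm and pore width − 0.5 μm, so strain and transit are always
defined), wCDI from a truncated normal, the recovery bin from a categorical
distribution over the five printed bins, and the in-bin recovery time
uniformly with a 1 ms edge guard (the 70–120 ms bin on [71, 114] ms) so that
every finite recovery is electrically observable inside the 120 ms window —
node transits can only delay a crossing, never advance it. ΔT_cont is then
implied by inverting the wCDI relation, and ΔI_np by the blockade relation,
so the analysis pipeline recovers the generating values on clean traces by
construction. The contraction blockade is drawn as ΔI_c = r·ΔI_np with
r ~ U(1.5, 2.2): with the constant-1 deformation convention a
volume-conserving spheroid would give ΔI_c < ΔI_np (the contraction channel
volume dwarfs the cell volume), which contradicts the deeper blockade the
narrower channel actually produces; the draw enforces the observed ordering
at sub-pulse level and is a deliberate phenomenological choice.

Default group parameters are stand-ins, not published distributions (the
emulated study reports none): younger cells 17.5 μm mean diameter (chosen so
mean strain ≈ 0.4 at w_c = 10.5 μm), soft (wCDI location 4.8) and mostly
fast-recovering; older cells equally sized but stiffer (wCDI location 3.8) with 55%
of mass on the 70–120 ms and infinite bins; high-risk cells ~0.5 μm smaller
with intermediate mechanics. Cohorts add donor-level variation (diameter
mean ± 0.2 μm, wCDI location ± 0.1, Dirichlet-perturbed recovery mixtures)
so that donor-held-out evaluation is not trivially identical to cell-held-out
evaluation. All generators are bit-reproducible: every draw flows from one
integer seed through named SHA-256-derived substreams.

The CyTOF-like generator emits log-normal intensities for a 27-marker panel
(log-means U(3.5, 5.5), σ = 0.4 in log units, so intensities sit well above
1 and log1p fold changes track planted shifts), with group- and
lineage-level shifts specified in natural-log units. Default "older" shifts
raise pRb, CD44 and pS6 and lower KRT19 by 0.8 log-units; these are
configuration, not constants of the method.

What passing tests on these data do **not** show: performance on real cells.
The generator has no doublets beyond explicit coincidence, no baseline
drift, no electrode fouling, no donor batch effects beyond the parameter
jitter above, and feature distributions are convenient parametric stand-ins.
Classifier AUCs on synthetic populations certify the pipeline's mechanics
(no leakage, correct stacking, calibrated nulls), not clinical accuracy.

## MechanoAge

Ten features per cell: D_cell, wCDI, ΔT_cont, L_deform, δ_deform plus the
five recovery-bin indicators (0 ms; 50–60; 60–70; 70–120; Inf). The source
protocol never enumerates its ten features; the fifth continuous feature is
taken as δ_deform here and is configurable. Recovery values in (0, 50) ms —
not covered by the printed bins and rare given the discrete recovery
segments — fall to the 0 ms bin and are logged; finite values at/past the
120 ms window are treated as infinite with a warning. Labels are "older"
(donor age > 50 y) and "younger" (< 35 y); cells from donors aged within
(35, 50] belong to neither class and are excluded with a logged count.
Continuous columns are Yeo-Johnson transformed (maximum-likelihood λ per
column, fitted on training data only; constant columns pass through with a
warning).

Training follows the stated protocol: bagged decision trees with 50
bootstrap resamples (untuned); a random forest tuned over the number of
variables sampled per split (tuning length 30, which collapses to the 10
distinct integer values available with 10 features) by repeated stratified
CV (10 folds × 5 repeats) maximising AUC; extremely randomised trees at
their default operating point. The majority class is down-sampled to the
minority size inside every training fold; validation and test rows are never
down-sampled. The meta-learner is a gradient-boosted classifier (grid over
tree count and depth, tuning length 10, 5-fold CV) trained on out-of-fold
base-learner probabilities — standard stacking, assumed since the source
names only the stacking tool. Class threshold 0.5 (the source is silent).
`TrainingConfig.fast()` (5-fold × 1 repeat, 25/60-tree forests, short grids)
is the protocol used by the test suite and simulation studies; the reduced
settings change runtime, not structure.

Evaluation: trapezoidal AUC with DeLong variance for the 95% CI; paired and
unpaired DeLong z-tests for comparing classifiers (paired covariance of the
structural components when score vectors share cells). Variable importance
is each learner's impurity-based importance rescaled to max 100, averaged
into a consensus; the five recovery dummies are additionally reported as one
cumulative group. Learning curves: cell-level (random subsamples per size,
mean AUC ± SE on a fixed held-out quarter) and donor-level (random inclusion
orders, leave-one-sample-out within each prefix, held-out predictions pooled
before AUC). Because labels attach at donor level, a prefix is evaluable
only once it holds two donors of each class; single-class training folds are
logged and skipped.

## Mechano-RISQ and inference

b is the fraction of average-risk *held-out* younger cells misclassified
"older" (reference cells must not have been used in training, otherwise b
collapses toward 0); RISQ = p_older/b, so 1.0 means no deviation. For
chronologically older samples (knock-down designs) the analogous baseline is
the AR-older predicted-older rate — an extension of the young-direction
definition, configurable. Per-sample inference uses the Crawford–Howell
single-case t-test, t = (x* − x̄)/(s·√((n+1)/n)), df = n − 1, two-sided by
default (one-sided available), with Benjamini–Hochberg correction across the
samples of one analysis panel. Its power is estimated by Monte Carlo
(default 10,000 iterations) as the rejection rate for a case displaced d
population-SDs from the normative mean; the test's type-I error is exact by
construction and verified by simulation. Group contrasts use the two-sided
Wilcoxon rank-sum test (exact for small tie-free samples); perturbation
contingency tables use Fisher's exact test.

## CyTOF signatures

Differential expression per marker: Wilcoxon rank-sum on log1p-transformed
intensities (arcsinh with cofactor 5 available; the LFC convention is not
fixed by the source), Bonferroni over the panel, significant iff adjusted
p < 0.05 **and** |LFC| > 0.5 — heavily powered comparisons with small shifts
are deliberately gated by the effect-size rule. Signatures are gradient
boosted classifiers trained once on unperturbed control luminal cells
(stratified 70/30 split, 5-fold CV grid over tree count/depth maximising
AUC) and then frozen: transfer evaluation scores perturbation-condition
cells without any parameter update (asserted via a model checksum) and
compares conditions to control with DeLong's test, paired only when cell
sets coincide.

## Numerical and degenerate-input conventions

Blockade inversion: Brent on (1e-9, 0.99·pole), xtol 1e-6 μm; forward/
inverse round trip < 1e-4 μm across 8–20 μm. D_e calibration: bounded scalar
minimisation, xatol 1e-8. Ties in Wilcoxon handled by scipy's tie-corrected
normal approximation. BH adjustment is the standard step-up with enforced
monotonicity. Empty feature tables keep the ten-column schema; empty traces
yield empty event lists; all-pulse traces, single-class folds, constant
normative samples, zero baselines and zero-duration sub-pulses raise typed
errors rather than propagating NaNs.

## Problem sizes

The test suite and acceptance checks run the classifier studies at 1000
cells (500 per class) with the reduced training protocol, the donor learning
curve at 8 donors × 40 cells × 2–3 orders, Crawford–Howell calibration at
10,000 simulations, and trace round-trips on batteries of 20–40 simulated
cells — sizes chosen to exercise every code path at interactive cost while
keeping Monte-Carlo standard errors well inside the asserted bands.

## Known limitations

No viscoelastic (frequency-dependent) mechanics; no multi-cell
deconvolution or drift correction beyond the robust baseline; the
contraction-blockade proportionality constant is conventional; the ten-
feature identity and the (0, 50) ms bin assignment are interpretations,
flagged above; synthetic defaults stand in for unpublished empirical
distributions, so numerical results on synthetic cohorts (AUCs, RISQ
magnitudes) characterise the pipeline, not any real population.
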