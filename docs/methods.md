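# Methods

This note documents the models, parameter choices and numerical decisions
behind `chemotax`, and what the synthetic-data validation does and does not
demonstrate.

## Gradient simulation (`chemotax.gradient`)

**Model.** The caged attractant sits in a thin agarose layer, so transport
is treated as two-dimensional free diffusion in a radially symmetric
geometry; convection is absent (the gel's purpose) and axial diffusion is
ignored because the layer is thin relative to lateral length scales. An
uncaging pulse converts a fraction of the *locally remaining* caged
reservoir, weighted by a Gaussian illumination profile:
released(r) = κ(r) · dose · exp(−r²/2σ²). Reservoir depletion is on by
default — repeated pulses of fixed exposure release progressively less —
and can be disabled, in which case fields superpose exactly.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| D (uncaged) | 300 μm²/s | order of magnitude for a small molecule in dilute gel; calibrated empirically in a real setup, so configurable |
| D (caged) | = D | the caged and uncaged forms are similar in size |
| illumination σ | 500 μm | out-of-focus illumination is smooth and roughly radially symmetric; no measured profile exists, so σ is a calibration knob |
| initial dose fraction | 0.5 | a deliberately strong initial exposure |
| recharge interval | 90 s | every 3 frames at 30 s/frame |
| recharge/initial dose ratio | 0.008 | the ratio of a 20 ms recharge to a 2.5 s initial exposure; the CV-optimal ratio for a given (D, σ) is found by `design_recharge` |

With these defaults the simulated gradient changes concentration by a few
percent over 30 μm (roughly one neutrophil length) near the working radius.

**Numerics.** Conservative finite-volume discretization on a uniform radial
grid (default 500 cells to r = 5 mm, far enough that the outer zero-flux
boundary is irrelevant on experiment timescales), Crank–Nicolson stepping
(substeps ≤ 1 s) solved with a banded tridiagonal solver. Because the flux
form telescopes, total mass is conserved to solver round-off; against the
closed-form Gaussian law s² → s² + 2Dt the spreading variance is accurate
to ~10⁻⁴ relative. Steepness is 100·(c(r) − c(r+L))/c(r); the sign is
positive for an inward-pointing gradient, and c(r) = 0 flags the report as
undefined rather than returning infinities. `design_recharge` is a
deterministic grid search (first minimum wins on ties) over candidate dose
ratios, scoring each by the temporal CV of steepness at the reference
radius from the first recharge onward.

## Image processing (`chemotax.imaging`)

Background is the 80th-percentile intensity of 32 × 32-px blocks (80 × 80 μm
at 2.5 μm/px), bilinearly interpolated between block centers. Decisions the
block rule leaves open: partial trailing blocks are used as-is; anchors sit
at block pixel-centers; pixels beyond the outermost centers clamp to the
nearest center (so interpolated values never leave the block-value range);
subtraction clamps at zero to keep one-sided threshold semantics.

Segmentation uses a single global intensity threshold (strict `>`) per
experiment — matching an assay where one manual threshold serves all wells
and time points; an Otsu helper exists for synthetic-data convenience. The
mask is split by a watershed on the inverted Euclidean distance transform,
seeded at distance maxima with ≥ 2 px separation. Seeds shallower than half
their component's distance maximum are suppressed: a thin bridge between
two touching nuclei has its own weak distance maxima, and without the floor
the bridge fragments into spurious objects. Centroids are unweighted
(binary) pixel means; sub-pixel values are kept; x = column, y = row,
0-based. The area filter retains 5 < area ≤ 75 px (≈ 31–470 μm²).

## Tracking (`chemotax.tracking`)

Links are mutual nearest neighbors between consecutive frames; anything
else — including exact distance ties — is ambiguous and produces no link.
No maximum displacement is imposed by default (a configurable cap exists
but is off), and there is no gap-closing or merge/split handling: fidelity
to the frame-to-frame design is the point, and a rejected link simply ends
one trajectory and starts another. The crowding filter removes a step only
when the cell's nearest same-frame neighbor is within 40 μm (16 px) in
*both* the prior and the latter frame. Distances are computed in μm;
populations (channels) are tracked independently. Trajectories whose cell
never exceeds 2 px (5 μm) displacement from its initial location are
removed as nonmovers (dead/undifferentiated cells); the comparison is
strict, so an excursion of exactly 2 px is still removed.

## Motility statistics (`chemotax.motility`)

Definitions are in the README. Boundary decisions:

- **Epochs.** A step is pre-stimulus iff both frames precede the uncaging
  frame and post-stimulus iff both are at/after it; the single spanning
  step is excluded, since it mixes the two regimes.
- **Radial bounds** (250–1,625 μm from the gradient center, applied to the
  step's origin) restrict only in-gradient statistics; basal speed uses all
  pre steps because pre-stimulus behavior is spatially homogeneous.
- Angular bias pools per-step angles across cells ("aggregated steps");
  a per-cell-mean variant would weight slow and fast cells equally and is
  not the default.
- Δt comes from frame timestamps when provided (imaging every ~30–40 s is
  not always exactly periodic), else from the nominal interval.
- A step originating exactly at the gradient center has no optimal
  direction; it is flagged and excluded from angle/directed statistics.
- Wells with zero qualifying steps report NaN, never 0 — a silent 0 would
  masquerade as "no movement".
- Time courses assign each step to its later frame, so a stimulus response
  appears at the uncaging frame, not one frame early.

## Screen statistics (`chemotax.screen`)

Normalization fits experimental ~ control across wells by IRLS with Tukey
bisquare weights (tuning constant 4.685, tol 1e-8, ≤ 50 iterations): robust
regression keeps strong true phenotypes from dragging the trendline, and
using a fitted line rather than dividing by the raw control tolerates
systematic experimental/control offsets and damps control-noise
over-correction. When Spearman(exp, ctrl) < 0.1 or the slope is negative
the in-well control carries no usable signal and the plate median of the
experimental values is the expected value instead (typical for angular
bias, whose well-to-well variation is below statistical noise). Expected
values ≤ 0 exclude the well. Scores are normalized − 1.

The chemokinesis residual is computed at the well level (trendline of
stimulated vs. basal score across wells, residual per well) so that every
score type has per-well replicate values feeding the same error-model
machinery; condition means are averages of well residuals. Constant basal
scores degenerate to residuals about a robust location.

**Error model.** Scores for a null condition are assumed to carry additive
zero-mean error from a two-component Gaussian scale mixture (a tight core
plus a wide outlier component; means are not identifiable from symmetric
difference data and are fixed at zero). Differences are all unordered
within-condition replicate pairs. The difference density is the
self-convolution of the mixture — weights (w₁², 2w₁w₂, w₂²), variances
(2σ₁², σ₁²+σ₂², 2σ₂²) — maximized over (logit w₁, log σ₁, log σ₂) by
Nelder–Mead from one moment-based start plus nine seeded random starts;
σ₁ ≤ σ₂ is enforced by relabeling. The mean of n replicates is an
(n+1)-component mixture with binomial weights, so interval bounds come from
bisection on its exact CDF and two-sided P-values are 2·(1 − F(|m|)).
Error models are fit separately per score type. No multiple-testing
correction is applied across conditions; calls are per-condition interval
exceedances only.

## Synthetic data (`chemotax.simulate`)

**Motion model.** Cells follow a biased persistent random walk: per frame a
target heading is drawn from a von Mises distribution — uniform before the
stimulus, concentrated (κ) around the direction to the gradient center
after it — and blended with the previous heading by a persistence weight
(0.5 default); κ at/above 10⁶ snaps steps exactly onto the optimal
direction. Step lengths are gamma (shape 2) with mean speed × Δt, so the
minimum-move and nonmover filters see a realistic spread of step sizes.
Defaults: 150 cells/well, basal 6 μm/min, stimulated 12 μm/min (a clear
stimulus-induced speed-up at plausible neutrophil-like magnitudes), κ = 1.5,
5% nonmovers pinned at their start, 0.3 px centroid localization noise.
Cells reflect at the field boundary. Acquisition defaults mirror the assay:
1,024 × 1,280 px at 2.5 μm/px, 30-s frames, 17 pre- + 33 post-stimulus
frames, gradient center at the image center.

**Rendering** places an isotropic Gaussian spot (σ = 1.5 px, amplitude 400)
per nucleus on a smoothly tilted background (level 100) with Poisson shot
noise — enough structure to exercise background estimation, thresholding
and the area filter. There is no PSF, bleaching, cell division, death or
collision mechanics, and spots are identical across cells; consequently,
passing segmentation/tracking tests demonstrates correctness of the
algorithms under the stated model, not robustness to real-image nuisances
(debris, focus drift, intensity heterogeneity).

**Plates.** Both populations of a well share one multiplicative lognormal
speed factor (log-sd 0.1 by default) — the structure that in-well-control
normalization exploits; the experimental population additionally gets its
condition's relative effect on basal speed, stimulated speed and/or bias
concentration. Per-well randomness derives from one root seed via
`SeedSequence.spawn`. Plate summaries are computed directly from simulated
trajectories (not via rendering/tracking), which keeps a 16-well plate
around a second; the imaging and tracking stages are validated separately
against rendered movies.

## Problem sizes in tests and validation

The test suite and acceptance script run at desk scale: rendered movies use
a 512 × 640 field with 15 frames and ~30 cells; oracle-equivalence suites
use 1,000 random instances of ≤ 20 objects (tracking) or ≤ 20 × 20-px
images (background); plates use 15–18 wells × 80–100 cells; error-model
validation uses 1,000 conditions × 3 replicates for fitting and 10,000
fresh null conditions for coverage. These sizes give Monte-Carlo precision
comfortably inside every asserted tolerance.

## Known limitations

- The gradient simulator's dose/σ/D defaults are plausible calibration
  values, not measurements; only qualitative conclusions (recharging
  stabilizes steepness; steepness magnitudes of a few %/30 μm) transfer.
- The von Mises post-stimulus heading distribution is a modeling stand-in;
  real cells' directional response distribution is not claimed.
- Tracking has no occlusion or gap handling by design; at high cell
  density the crowding filter discards most steps rather than risking
  identity swaps.
- The error model assumes symmetric, condition-independent score noise;
  heteroscedastic conditions would need a richer model.
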