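# Methods

This note documents the models implemented in `cyanocycle`, the
parameters that matter, the synthetic-data generator's scope, and the
numerical and design choices made where the design was genuinely open.

## Size-control simulator

Cells grow exponentially in volume, `V(t) = V_b exp(λ t_light)`, where
`t_light` is cumulative time spent under illumination; volume is constant
and divisions never fire strictly inside dark intervals (an event whose
light budget is exhausted exactly at a dark onset is stamped on the
boundary). Division triggers:

| rule  | trigger quantity            | `trigger_mean` units |
|-------|-----------------------------|----------------------|
| sizer | division volume `V_s`       | volume               |
| timer | light-time duration `T*`    | h                    |
| adder | added volume `Δ = V_d − V_b`| volume               |

Each cycle multiplies its trigger by `(1 + η)`, `η ~ N(0, trigger_cv)`,
redrawn (≤ 100 times) if non-positive — and, for the sizer, if the target
falls below the current volume, where it would be meaningless. Division
is near-symmetric: daughters receive `(1 ± a)/2` of `V_d`,
`a ~ N(0, asym_sd)`. Growth rates are drawn i.i.d. per cell from
`N(λ̄, cv_λ λ̄)` truncated at `0.1 λ̄`; no mother–daughter inheritance is
modeled because measured mother–daughter generation times are
uncorrelated, whereas both daughters of one division draw independently.
An optional `size_drift_rate` scales the trigger linearly with the
cell's wall-clock birth time (fraction per hour, default 0), emulating a
slow drift of mean cell size over an experiment; no measured drift
magnitude is bundled, so it stays off unless the user sets it.

Default parameter values describe the continuous-light measurements this
pipeline targets: `growth_rate_mean = 0.055 h⁻¹`, growth-rate CV 0.30,
division asymmetry SD 0.033, steady-state birth-volume CV 0.12, founder
volumes lognormal with that CV, and a 12 h : 12 h square LD schedule when
light-dark gating is wanted.

**Analytic slopes.** With all noise off, regressing division volume on
birth volume (both normalized by the mean birth volume) gives exactly 0
(sizer), +1 (adder) and +2 (timer run at its steady-state fold change
of 2, i.e. `T* = ln 2 / λ`). These are the discriminating signatures.
The generation-time slope of the noise-free adder is
`−1/(2 ln 2) ≈ −0.72` at the steady state (differentiate
`T = ln(1 + Δ/V_b)/λ` at `V_b = Δ` and normalize by `T̄ = ln 2/λ`), and
the within-pair sister statistic `(T₁−T₂)/(T₁+T₂)` against
`(V_b₁−V_b₂)/(V_b₁+V_b₂)` linearizes to the same value. Our stochastic
simulations reproduce both (≈ −0.73 and ≈ −0.70 under the calibrated
noise). A cross-sectional slope substantially shallower than the
within-pair slope (as reported in some datasets) indicates extra
birth-volume variance shared within pairs but varying across the
experiment — e.g. a drifting mean size — which the cross-sectional
regression dilutes but the within-pair statistic cancels; with
`size_drift_rate = 0` the simulator deliberately does not produce that
pattern.

**Calibration.** `calibrate_noise` bisects `trigger_cv` (fixed internal
seed schedule, tolerance 0.01 in CV) until the steady-state birth-volume
CV matches a target, holding growth-rate CV and asymmetry fixed. The
timer cannot be calibrated to small CVs: it applies no size correction,
so log birth volume random-walks and the CV at the measurement window
(generations 3–6) has a floor ≈ 0.5 under the default noise. The error
names the floor; `on_unreachable="floor"` falls back to zero trigger
noise, which is what the model comparison uses for the timer.

**Steady state and burn-in.** Population statistics discard 3
generations of burn-in (birth-volume means and CVs are stationary from
generation ~2 on when founders start near the fixed point; 3 is a safe
default). Replicate statistics simulate enough founders for ≥ 1.3× the
requested cycles and subsample exactly, so every replicate has identical
size. One RNG stream per replicate is spawned deterministically from the
model seed.

## Geometry

Volumes come from the standard rotational reconstruction for coccoid
cells: find the contour's principal axis from the exact polygon second
moments (Green's-theorem edge sums), slice perpendicular to it into
`n_slices = 200` equal bins, take each slice's disk radius as the mean of
the absolute perpendicular distances of the boundary crossings above and
below the axis (robust to slightly asymmetric halves), and sum
`π r² w`. Ellipsoid/sphere/cylinder oracles agree to < 1%/2%; doubling
`n_slices` moves smooth convex volumes by < 0.5%. Axis lengths use the
equivalent-ellipse convention (semi-axis = 2√eigenvalue of the region
covariance), matching how image-analysis packages report major/minor
axis lengths.

The daughter-ratio prediction is pure geometry: symmetric division
perpendicular to the major axis gives the daughter a major axis equal to
the mother's minor axis and a minor axis of half the mother's major
axis, hence ratio `0.5/r` (inverted into (0, 1] if needed). The measured
trajectory — ratio ≈ 0.77 at birth falling to ≈ 0.63 at division —
closes under this map (0.5/0.63 ≈ 0.79).

## Synthetic imaging

The renderer emulates the *statistical* structure of bright-field data,
not its optics: each cell is an ellipse with a dark Gaussian rim at its
boundary, a slightly bright interior, Gaussian PSF blur and additive
noise. Geometry is exact: the ellipse at time `t` carries the simulated
volume via `V = (4/3)π a b²`, the axis ratio follows a linear 0.77 → 0.63
trajectory over normalized cycle phase, daughters appear with major axes
perpendicular to the mother's, a division furrow ramps over the final
20% of the cycle (frozen, like growth, in the dark), and newly divided
sisters drift ~2 µm apart over ~15 min. A pairwise relaxation keeps
non-sister cells ≥ 1.2 µm clear of each other so their rims stay
optically separable; freshly divided sisters start in contact and form
genuine doublets. Dark frames differ only by increased motility jitter
(3× the light-phase value of 0.02 µm/frame).

Defaults: 10-min frame interval, `pixel_size = 0.32 µm/px` (a plausible
20× acquisition scale; the fixtures used for quantitative validation
render at 0.15 µm/px, where single-cell volume errors are ~±5% — at
0.32 µm/px cells are only 6–8 px across and bright-field sizing is
intrinsically poor, ±20% or worse). Stacks are deterministic for a fixed
seed (byte-identical TIFFs).

What the generator does **not** emulate: realistic optics (defocus,
shading, halo), phototaxis and genuine motility, chamber-scale crowding
mechanics, nutrient depletion, or segmentation-adversarial debris.
Passing pipeline tests on these fixtures therefore demonstrates the
correctness of the reconstruction logic, not robustness to every real
imaging pathology.

## Segmentation, classification, tracking

Binary segmentation flattens the background (difference of σ = 1 px and
σ = 25 px Gaussians), thresholds the dark rims at 4 robust SDs (MAD)
below background, fills and opens, and removes components below the area
of a 0.8-µm circle. The detected band straddles the rim, whose
centerline is the true boundary, so each component is eroded by half the
measured band thickness (capped at 45% of its inradius so small cells
survive; the un-erodable remainder is subtracted later from fitted
semi-axes). Fitted ellipses are finally refined by scaling onto the rim
intensity trough (parabolic sub-step over a 0.75–1.30 scale scan),
ignoring sample points whose nearest component is a different cell.

Clusters are scored by a Gaussian naive Bayes over five features —
area, equivalent-ellipse axis ratio, solidity, count of significant
convexity defects, and the two-ellipse/one-ellipse fit residual ratio —
trained on rendered singlets (including partially constricted ones,
which are still one cell), touching sister pairs, and clumps. No hard
threshold converts features to classes; the posteriors travel with each
cluster. Doublets are decomposed by an EM-style two-ellipse fit
initialized from the principal-axis bisection, with a
distance-transform-seeded watershed fallback flagged low-confidence.

Tracking links components by mask overlap (nearest centroid within
2.5 µm as fallback), then enforces, per component track, the
maximum-posterior **monotone** class sequence (cell count may only
increase) by dynamic programming — a track can progress
singlet → doublet but never revert, since cells divide and do not fuse.
A division is stamped at the first stable doublet frame (or at the
physical component split if no doublet phase was seen), with uncertainty
equal to half the dwell between the last confident singlet and first
confident doublet frame (~1 frame, i.e. ~10 min, on clean fixtures; the
convention targets the ~1 h scale of visual division-time ambiguity).
Colliding tracks (merges) and multiplets flag the affected cells, which
are excluded from cycle statistics. Greedy gated matching is used rather
than global assignment — adequate at the low densities these experiments
run at.

Per-cell volume curves apply a 3-frame running median before read-off
(the exact smoothing used in the original extraction procedure is not
specified anywhere; a short median is the mildest jitter-robust choice,
and `smooth_window=1` disables it).

## Growth analysis

`splice_dark` drops samples strictly inside dark intervals and re-indexes
to cumulative light hours; a volume jump > 10% across any spliced
junction contradicts dark growth arrest and flags the curve out of the
statistics (the 10% tolerance is a package choice; the underlying
biological statement is simply "no growth in the dark"). Exponential
fits are least squares on `ln V` vs time with residuals reported as
`V/V_fit − 1`, so the RMSE is a scale-free exponentiality measure.
Cycle extraction takes `V_b` at the first post-birth frame and `V_d` at
the last pre-division frame by default (`endpoint_from_fit=True` reads
both off the fitted exponential instead), `T` as light-time between
them, and `λ` from the spliced-cycle fit; founder cells, whose births
were not observed, never contribute cycles. Sister pairs with birth
asymmetry |a| > 0.07 are flagged as asymmetric divisions.

## Comparative statistics

Regressions normalize volumes by the mean birth volume and generation
times by the mean generation time, then use OLS with t-based standard
errors and p-values. The sister asymmetry regression symmetrizes each
pair (both orderings, signs flipped) so the fitted line respects the
cloud's origin symmetry; standard errors use pair-count degrees of
freedom to undo the doubling. The binned bootstrap randomizes pairings
within 5-h bins of birth (or division) time, so epoch effects survive in
the null and a small p-value isolates genuinely sister-specific
similarity; its p-values are uniform under independence (calibrated in
the test suite).

`compare_models` z-scores each observed slope against each rule's
simulated band and picks the rule minimizing mean |z| — an explicit,
testable criterion for "most consistent with". When a band is degenerate
(the floor-calibrated timer has exactly zero generation-time slope
variance) the observed slope's own standard error substitutes as the
scale. No multiple-testing correction is applied (raw p-values are
reported; the comparison metadata records this). Self-consistency: data
generated by any of the three rules at n = 278 cycles select the
generating rule in ≥ 95% of seeded runs.

**Sister generation-time correlation.** With i.i.d. per-cell growth
rates, size control alone produces a *positive* sister-T correlation
through the shared birth size (R ≈ 0.2 at the calibrated trigger noise
with growth-rate noise off), decreasing with division asymmetry. The
high correlations seen in real data (R ≈ 0.87) additionally require
sister-shared determinants that this model intentionally omits; the
package reproduces the sign and mechanism, not that magnitude.

## Validation scales

The default test suite runs at desk scale: the end-to-end closure
fixture is one founder for 60 h at 0.15 µm/px in a 192-px field with
noise 0.01 (15/15 divisions recovered within ±0.5 h; mean `V_b` and `T`
within 4% and 2% of truth on the reference seed); model recovery uses 20
seeded runs per rule against 60-replicate slope bands; the bootstrap
null calibration uses 200 trials of 1000 resamples; headline slope
statistics use 200 replicates of 278 cycles. These sizes are the
package's validation choices and can all be scaled up through the same
interfaces.

## Known limitations

- Bright-field sizing at the default 0.32 µm/px is intrinsically coarse;
  quantitative work should render (or acquire) at ≤ 0.2 µm/px.
- The morphology classifier is trained on this renderer's appearance;
  applying the segmentation stage to real images requires retraining on
  annotated real morphologies.
- Crowded colonies (≳ 16 cells in contact) degrade counting and are
  excluded via multiplet/merge flags rather than resolved.
- The simulator's timer rule has no steady state by construction; any
  statistic that presumes size homeostasis is undefined for it and is
  reported at the zero-trigger-noise floor.
- Mean-size drift is available but off by default, with no bundled
  magnitude; cross-sectional slopes from drifting experiments will not
  be matched by drift-free simulations.
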