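# Methods

This note documents the models and procedures implemented in `duobrain`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## Session model

A trial pairs a *stationary* and a *moving* mouse and walks through five
phases — `separate1 → translate_in → together → translate_out →
separate2`. Defaults follow the staged-interaction paradigm: 120 s
separate phases, 27.5 s stage translations, 120 s together
(`PhaseSchedule.from_durations()`). Brain cameras run at 28.9 fps
(256×256 native, 64×64 default in the generator), the behavior camera at
90 fps. All cameras are synchronized post hoc on the LED switch-on at
trial start; analysis time t = 0 is the detected onset frame.

## Synthetic-data generator

The generator exists so that every downstream stage can be tested against
known ground truth. It emulates the *statistical structure the analysis
assumes*, not the physics of the preparation:

* **Behavior bouts.** Whisker and forelimb bout onsets per mouse are a
  Poisson process (default 0.1 Hz per channel) with exponential durations
  (mean 1.5 s). These values put time-spent-behaving near 15 % per
  channel, matching the scale of head-fixed whisking/forelimb activity,
  with bout durations in the typical 1–2 s range for whisking bouts.
* **Social coupling.** While the mice are together, each stationary-mouse
  bout independently triggers a moving-mouse bout of the same channel and
  duration with probability `coupling` (default 0.5) at a lag drawn
  uniformly from 0–1 s. Outside the together phase the mice are
  independent. The lag model is a stand-in for the seconds-scale
  behavioral coordination seen in real encounters; the true lag
  distribution is not known, so it is exposed as `lag_range_s`.
* **Neural signal.** Each behavior channel drives a Gaussian blob
  (σ = 3 px at 64×64, scaled with image size) at a named region — own
  whisking → aBC, own forelimb → FL — plus a diffuse cortex-wide
  component (`global_gain`, default 0.02 ΔF/F₀) reflecting the
  observation that movements drive widespread cortical activity. While
  together, the partner's whisking additionally drives pBC
  (`partner_gain`, default 0.03), modeling mutual whisker touch; barrier
  conditions (`mesh`, `opaque`) zero both the behavioral coupling and the
  touch drive. Bout indicators are convolved with a difference-of-
  exponentials calcium kernel (0.2 s rise, 1.5 s decay — GCaMP6s-like
  literature values; the kernel is normalized to unit area so gains are
  sustained-bout plateau amplitudes in ΔF/F₀ units).
* **Hemodynamics.** A slow artifact (unit-SD noise low-passed below
  0.15 Hz, scaled by `hemo_gain` = 0.02) enters both the green and blue
  channels multiplicatively on the baseline. It is deliberately *shared
  between the two mice* — physically each animal's hemodynamics are
  independent, but sharing the artifact is the worst case for interbrain
  analysis: any residual after correction would masquerade as social
  coupling. `gfp_mode` zeroes all neural gains, leaving only artifact and
  noise, emulating an activity-independent fluorophore control.
* **Acquisition artifacts.** Per-pixel Gaussian sensor noise (1 % of
  baseline), 12 dark frames before the LED onset, and random dropped
  frames (0.1 % of frames, timestamps preserved) per camera.
* **Behavior video.** ROI mean-pixel traces are emitted directly (the
  analysis consumes only ROI means): jitter SD rises from 0.2 to 5
  intensity units during bouts, so motion energy is elevated throughout a
  bout. The moving mouse's trace is NaN outside the together phase (out
  of frame). Raw video frames are not rendered.

Not emulated: optics and photon statistics, vascular structure,
eye/ear/postural movements, vocalizations, freely-moving behavior, and
real spatiotemporal correlation structure of cortical activity beyond the
driven blobs + diffuse component. Passing tests therefore demonstrate
correctness of the *analysis* under the stated signal model, not
performance on real data.

## Preprocessing

Fixed order, recorded in each stack's provenance: LED-onset crop →
dropped-frame interpolation → ΔF/F₀ → clipping → hemodynamic subtraction →
spatial smoothing → temporal band-pass.

* **LED onset**: first frame whose mean intensity exceeds the midpoint of
  the dark and lit plateau levels; plateaus are estimated with medians so
  activity transients cannot bias them. A configurable amplitude floor
  (default 1.0 intensity unit) guards against detecting "transitions" in
  constant streams.
* **Dropped frames**: gaps > 1.5 frame periods are filled by per-pixel
  linear interpolation onto the nominal grid. Edge gaps would replicate
  the boundary frame (with a logged warning).
* **F₀** is the mean over the *entire* recording, including the together
  phase; no rolling baseline.
* **Clipping** precedes smoothing/filtering so isolated extreme pixels do
  not bleed into neighbors. GCaMP: per-pixel mean ± 3.5 SD. Reflectance:
  ±15 % ΔF/F₀, symmetric about zero (the band is far larger than
  physiological reflectance changes, so the centering convention is
  immaterial in practice; zero-centered was chosen and is noted here
  because the alternative — centering on the pixel mean — is defensible).
* **Temporal filtering** is zero-phase (forward–backward `sosfiltfilt`):
  the filter is named but its phase handling is an implementation choice,
  and lag/correlation analyses require no phase distortion. Recordings
  shorter than 3× the 0.01 Hz high-pass time constant (~48 s) trigger a
  warning but are still filtered.
* **Masking**: masks are user-supplied (the generator provides a
  superellipse covering both hemispheres); without one, an intensity
  threshold (25 % of the brightest mean pixel) is used. Masked-out pixels
  are zeroed and excluded from all statistics.
* **Clocks**: after LED alignment, behavior events are mapped to the
  brain clock by nearest-timestamp lookup; both mice are trimmed to their
  common frame count.

## Behavior quantification

Motion energy is the absolute temporal gradient of the ROI mean; it is
smoothed with a σ = 25-frame Gaussian (reflect padding — the edge rule is
unstated in the source protocol) and thresholded at mean + 1 SD *of the
smoothed trace* over the whole defined span. Detection is therefore
invariant to affine rescaling of the raw intensities. Events are maximal
supra-threshold runs; minimum length one sample, no merging. A practical
resolution limit follows from the smoothing: bouts shorter than about one
kernel σ (0.28 s at 90 fps) cannot survive the smoother, and recovery
tests count only resolvable bouts. Cross-correlation uses overlap-only
normalization per lag (default ±30 s); the Jaccard index is
intersection-over-union of the binary vectors, 0 when the union is empty.
Behavior statistics are computed on the 90 fps behavior clock.

## Registration

Three midline landmarks (bregma, a superior-sagittal-sinus point, the
olfactory-bulb/frontal boundary) are matched to atlas (ML, AP)
coordinates by closed-form Procrustes, yielding a similarity transform
(rotation + isotropic scale + translation; det = +1). A similarity rather
than affine transform because collinear midline points cannot constrain
shear; key-point alignment is approximate by nature. The ten region
coordinates shipped in `DEFAULT_REGIONS_MM` are editable defaults at
standard atlas positions — no authoritative per-region table exists for
this preparation, so they are defaults, not measured values. Image
convention: x = columns rightward, y = rows downward, 0-based pixel
centers.

## Interbrain statistics

* Global signal: spatial *median* ΔF/F₀ over the mask (robust to residual
  extreme pixels).
* Per-phase PCC: 60 s window, centered within the phase (placement within
  the phase is a package choice; centering avoids translation
  transients). Constant windows return NaN rather than raising. Missing
  samples are dropped pairwise, with a warning above 5 %.
* Fisher z = atanh r, domain |r| < 1.
* Trial-shuffle null: unordered cross-trial pairings A(i)×B(j), i < j —
  C(n, 2) values (595 at n = 35). The ordered variant would double the
  count; the combinatorial reading matches the cohort count n(n−1)/2.
* Region time series: median of the 5×5 pixel block centered on each
  placed region; inter- and intrabrain correlation matrices per phase,
  with change matrices (together − before) and per-region row means.
* Coherence: sliding DPSS multitaper windows (45 s, 22.5 s overlap,
  NW = 5, K = 9), coherence = |ΣₖS_ab|²/(ΣₖS_aa·ΣₖS_bb), clipped to
  [0, 1]. For independent signals the K-taper estimator has a bias floor
  near 1/K ≈ 0.11; band comparisons are made against that floor, not
  against zero. Windows are attributed to a phase by their centers.

A note on significance against the shuffle null: with sparse slow bouts,
a single trial's 60 s-window PCC has a wide sampling distribution, so
individual coupled trials need not exceed extreme quantiles of the null.
The meaningful statement — and the one the test suite and acceptance
script make — is that the *distribution* of true-pair PCCs sits above the
null distribution (one-sided Welch test at the 2.5 % level), alongside
the raw means and null quantiles for transparency.

## Encoding model

* Neural side: per-pixel mean-centering, then SVD of the time × pixels
  movie; top k = 200 components by default (exact decomposition when
  small, randomized SVD with 7 power iterations otherwise; the
  approximation is negligible for the steeply decaying spectra of real
  movies). `temporal = U·S`, `spatial = Vᵀ`.
* Design side: each variable's *onset* indicator expands into lagged
  columns — post-only windows (behavior, stage translation: 2 s) cover
  lags 0…⌈post·fs⌉−1 (58 columns at 28.9 fps), pre-windows (approach:
  5 s) cover −⌈pre·fs⌉…0. Kernels are zeroed at trial boundaries.
  Stationary whisking splits into alone/together variables by the phase
  at bout onset. Variables with no events are retained but flagged and
  excluded from fitting.
* Ridge: closed form per component; λ chosen by grid search over
  {0.1, 1, 10, 100, 1000} minimizing pooled CV error on the component
  time courses, or fixed by the caller.
* Cross-validation: 10 contiguous time-block folds (not random samples),
  limiting leakage of autocorrelated activity. Per fold, held-out
  component predictions are projected through the spatial components;
  per-pixel R² = 1 − SSE/SStot pools errors over folds (per-fold R² is
  also returned — pooling is the primary report). R² is measured against
  the rank-k reconstruction, i.e., the share of *capturable* variance the
  model explains.
* Unique contribution: the variable's onset series is circularly shifted
  by a seeded random offset within each trial and its lag block
  re-expanded — whole events move together, preserving kernel structure —
  then ΔR² = R²(full) − R²(permuted). ΔR² can slightly exceed the full R²
  where the permuted model overfits to negative held-out R²; tests allow
  a small sampling tolerance for this. Permutations are bit-reproducible
  under a fixed seed.

## Problem sizes in tests and the acceptance script

Monte-Carlo checks (hemodynamic rejection, coupling recovery, coherence
bands) run on 16 px sessions with 60–90 s phases and 10–20 seeds; the
encoding localization check runs one 48 px open session and one mesh
session with k = 150 components. These sizes were chosen because the
statistics under test — correlations of spatially-pooled signals,
coherence bands, peak locations relative to blob centers — are
resolution-independent in this signal model; coupling comparisons use
common random numbers across coupling levels to sharpen the paired
contrast.

## Known limitations

* The similarity transform cannot absorb anisotropic distortion or skew
  in the optical path.
* The subtraction-based hemodynamic correction assumes the artifact
  enters both channels with equal gain; wavelength-dependent absorption
  differences would leave a scaled residual (the generator's equal-gain
  artifact is exact by construction).
* The behavior detector cannot resolve bouts shorter than the smoothing
  kernel, and its threshold adapts per trial, so absolute event counts
  are not comparable across trials with very different activity levels.
* Ridge λ is selected on the same data used for the CV maps (standard
  practice for this model family, but the maps are therefore not fully
  nested).
* Single-trial interbrain PCC over 60 s windows has a wide sampling
  distribution when behavioral events are sparse; cohort-level
  comparisons are the intended use.
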