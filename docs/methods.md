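# Methods

`polcurve` simulates how clathrin-coated-pit membrane bending appears in
polarized total internal reflection fluorescence (pol-TIRF) imaging,
generates synthetic labelled time-lapse movies, and classifies single
endocytic events by when membrane curvature appears relative to clathrin
assembly. This note records the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## Membrane-bending models

The plasma membrane is a plane at the coverslip (z = 0) that locally deforms
into a ~100 nm vesicle by one of two idealized progressions:

* **Fixed-radius bending (class 1).** A sphere of fixed radius r = 50 nm
  intersects the plane; translating its center from z = −r (tangent below
  the plane, flat) to z = +r (resting on the plane) exposes a spherical cap
  that grows from nothing to the full vesicle. Clathrin covers the cap, so
  coat content grows together with curvature.
* **Constant-area bending (class 2).** A circular membrane patch of fixed
  area A (that of the final sphere, 4π·50² nm²) carries the full clathrin
  complement from the start and bends through spherical caps of decreasing
  curvature radius r_i. The cap height is z_shift = A/(2π·r_i) (cap area
  2πrh), swept from r_i = 25 000 nm (z_shift = 0.2 nm, essentially flat)
  down to r_i = 50 nm (z_shift = 100 nm, closed sphere).

A third observed behaviour (class 3) is intermediate: part of the clathrin
assembles flat, and the rest is recruited while the membrane bends.

Surfaces are discretized parametrically — sphere caps as θ-bands split
uniformly in φ, the plane as grid cells — with *exact* per-element area
weights, so cap-area conservation is testable to discretization tolerance
rather than voxel accuracy. Element linear size is bounded by the grid
spacing (default 2 nm). The stage progressions use 10 discrete stages by
default; the constant-area sweep is spaced linearly in z_shift so the apex
advances uniformly per stage, mirroring the linear center sweep of the
fixed-radius model. When a cap passes the hemisphere no neck membrane is
added; the plane hole equals the cap base circle (the base-radius rule is
exposed as a parameter since the plane–cap junction is a modeling choice).

## Image formation

The evanescent excitation decays as e^(−z/d) with penetration depth
d = 100 nm. The membrane dye (DiI) holds its transition dipole at a fixed
tilt β from the local membrane plane; β = 70° is calibrated from the planar
P/S ratio minimum of 0.26 via P/S|plane = cos²β / (½ sin²β) = 2 cot²β. The
per-unit-area excitation weights are, for a sphere element at spherical
angles (θ, φ) about its sphere center (θ = 0 at the apex):

    P: e^(−z/d) (sin²θ sin²β + cos²θ cos²β)        plane: cos²β
    S: ½ e^(−z/d) (cos²θ sin²φ sin²β + 2 sin²φ sin²θ cos²β + cos²φ sin²β)
                                                    plane: ½ sin²β

At the apex orientation both sphere weights reduce exactly to the plane
weights (an asserted property), so the weight functions are continuous
across the cap–plane junction. The azimuth origin is immaterial because φ
enters only through sin²/cos² integrated over the cap (asserted by a
rotation-invariance of the rendered images). The clathrin channel uses
360°-scanned illumination and carries no orientation dependence: clathrin
density × e^(−z/d). Depth-dependent emission collection is neglected
(approximately constant for a high-NA objective at these depths).

Rendering: per-element weight × area accumulated on the fine grid (2 nm),
projected along z, blurred with a 2D Gaussian PSF of FWHM 211 nm
(σ ≈ 89.6 nm), then block-*integrated* (summed, photon-additive) down to
125 nm camera pixels — the fractional 62.5-cell block size is handled
exactly through cumulative sums. Poisson noise is optional and applied to
the pixel image. An overall `photons` scale carries all brightness; plane
and sphere intensities per unit membrane are equal.

Known consequence of the model as printed: the P/S contrast at the pit
rises strictly while the dome forms but dips a few percent over the last
stages before closure, because once the apex sits deeper than ~85 nm the
e^(−z/d) decay outweighs the added vertical membrane. Tests assert the
monotone rise through the dome stages and the strong contrast at closure,
not strict monotonicity through the final translation.

## Synthetic movies

Movies superimpose event templates on a flat-membrane background whose P/S
is exactly 2 cot²β. Stage templates (channel images of every morphological
stage, as deltas against the plane) are rendered once through the full
optics pipeline and composited per frame, keeping movie generation at
seconds while remaining consistent with the single-surface renderer.

Event populations follow the live-cell numbers used throughout the
package: class mix 43/14/43 % (classes 1/2/3), clathrin lifetimes
80 ± 42 s (class 1) and 108 ± 39 s (classes 2/3), bending lag 25.5 s mean
(SD 6 s) for the delayed classes. Lifetimes and lags are truncated normals
whose *post-truncation* mean and SD are calibrated to these values (plain
truncation at the operational lower bounds would inflate the means by
several seconds). Lower bounds: class 1 lifetime ≥ 30 s, class 2/3 ≥ 56 s
(room for lag + bending), lag ≥ 10 s; lifetimes exceeding the movie are
redrawn, which truncates the tail only for short movies. Abortive
structures (flat, < 18 s, no dynamin) can be mixed in via the class mix.

Choices the source population numbers do not fix, set once to realistic
values for EMCCD live-cell endocytosis imaging:

* frame interval 2 s; bending duration 20 ± 4 s per event; clathrin
  assembly ramp ≈ 20 s in every class (so onset-detection latency is
  comparable across classes);
* dynamin: a Gaussian temporal pulse, FWHM 8 s, peaking 2 s before event
  end, rendered as a diffraction-limited spot;
* photon budget: S-channel planar membrane 2000 photons/pixel (P follows
  from β), uniform cytosolic background 50 photons/pixel in the clathrin
  and dynamin channels, clathrin peak amplitude 140 photons (≈ SNR 20 over
  the background shot noise) with 25 % per-event scatter;
* camera: gain 1 count/photon, constant offset 100 counts added after
  Poisson noise; 30 closed-shutter dark frames with 2-count read noise are
  emitted for the bias-calibration path;
* class-3 rendering: the flat pool (prebend fraction of the complement)
  stays at z = 0 while a fixed-radius cap grows and carries the remainder;
  the P/S delta follows the fixed-radius geometry. The coat's lateral
  redistribution during bending is not modeled.
* events are stationary, placed at pixel centers with ≥ 1 µm pairwise
  separation; no photobleaching, no membrane undulations besides the pit,
  and event end drops all channels to background in one frame.

What passing tests on these movies do *not* show about real data: real
events move laterally, crowd below the isolation radius, bleach, sit on
undulating membrane, and their bending need not follow either idealized
geometry — the generator probes the analysis logic, not biology.

## Event analysis

Pipeline: bias subtraction (mean of dark frames, clipped at zero) →
optional affine channel registration fitted to fiducial points by least
squares (applied to spot coordinates, not by resampling images) → spot
detection on the clathrin channel (difference-of-Gaussians band-pass,
local maxima above median + 5·MAD, center-of-mass refinement) → frame-to-
frame linking by Hungarian assignment within a 3 px search radius with
gap closing up to 2 frames → trace extraction (disc sum of radius 3 px
minus annulus-median background; the P/S trace divides the *raw* disc
sums, since planar membrane is the legitimate denominator, not
background) → filtering → classification.

Filtering keeps complete (not touching the movie ends), ≥ 5-frame,
isolated (no other track within 5 px during the lifetime), dynamin-
positive tracks; every rejection carries exactly one machine-readable
reason, and kept ∪ rejected partitions the input.

Onset detection: first frame above baseline median + k·MAD (k = 3) for
m = 3 consecutive frames, baseline from the 10 frames preceding the track
start. The raw crossing frame is biased late for shallow rises, so it is
refined by a hinge (baseline + ramp changepoint) regression over the
surrounding window; this makes onsets nearly slope-independent, which
matters because the clathrin rise speed differs between classes while the
reported lag statistics compare onsets across channels and classes. The
search for the P/S onset starts at the clathrin onset minus the
coincidence window — curvature preceding clathrin is outside the event
model, and an unrestricted search accumulates spurious crossings over long
pre-event stretches. Event ends use the same thresholds with hysteresis
(high threshold to arm, low threshold to release); lifetimes count from
the first signal frame to the last pre-drop frame, (end − onset − 1)·Δt,
which simulation shows centers the estimator.

Classification: class 1 if |P/S onset − clathrin onset| ≤ 2 frames;
otherwise class 2 when the clathrin trace shows no significant further
increase over the bending interval (one-sided least-squares slope test at
α = 0.05 over at most 12 frames from the P/S onset, or fitted relative
increase < 10 % of the pre-bending plateau), else class 3. Tracks without
a P/S onset are abortive. The class-1 vs class-2/3 lifetime comparison
uses the two-sided Mann–Whitney U (Welch's t available); its type-I error
is verified at ≈ 5 % by null simulation. Height–P/S association uses
Spearman's ρ with a seeded permutation p-value.

On generated movies at the default photon budget the pipeline recovers
≥ 95 % of non-abortive events as tracks and classifies ≥ 90 % of kept
events correctly; with noise off, single rendered events of each class are
classified exactly. These figures are recomputed by the test suite — the
numbers above are properties the tests assert, not external claims.

## Numerical choices and degenerate inputs

* Gaussian blur uses zero-padding; flux conservation is asserted only for
  sources ≥ 5 FWHM from the border (the infinite plane legitimately loses
  edge flux).
* The P/S ratio floors its denominator and flags sub-floor pixels invalid
  rather than emitting infinities; constant inputs to the correlation are
  rejected as undefined.
* MAD thresholds fall back to a tiny positive scale on exactly-constant
  baselines so noise-free traces remain detectable.
* Affine fits require ≥ 3 non-collinear pairs (rank check with a scaled
  tolerance).
* Seeds: every stochastic step takes an explicit seed; a movie rendered
  twice from the same seed is bit-identical, as is the CLI output.

## Problem sizes

Default test and verification sizes: 2 µm × 2 µm surfaces at a 2 nm grid
(10⁶ elements), 10-stage progressions, movies of 60 events
(128 px, 300 frames) for pipeline tests and 220 events (192 px, 320
frames) for the population-statistics checks, 12 replicates per SNR level
in the robustness sweep, and 1000 null simulations for the test
calibration. These sizes give standard errors comfortably inside the
asserted tolerances while keeping the full suite at a few minutes.

## Known limitations

* The excitation weights are implemented exactly as the printed model; no
  vectorial near-field emission, supercritical-angle collection, or
  interference fringes. Illumination is spatially uniform.
* No neck or scission geometry; the final stage is a sphere touching the
  plane.
* The class-3 composite (flat pool + growing cap) is one reasonable
  reading of "additional clathrin added during bending"; kymograph-level
  data do not constrain where that clathrin sits.
* Tracking assumes stationary, well-separated spots; it is not a general
  particle tracker.
* Registration is fitted and reported but the synthetic generator emits
  pre-registered channels, so the transform path is exercised only by its
  own unit tests.
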