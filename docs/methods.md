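# Methods

This note documents the models, parameter choices and numerical
conventions behind `nodoscope`, and what the synthetic fixtures do and do
not establish about real recordings.

## The measurement model

A one-photon miniscope recording of a peripheral ganglion is modelled as

F(x, t) = B(t) + Σᵢ bᵢ · wᵢ(x) · (1 + dᵢ(t)/s) + ε(x, t)

where `B(t)` is a diffuse background with slow drift, `wᵢ` is a Gaussian
soma profile (σ = diameter/4, truncated at one diameter; default diameter
12 px, matching somata after 2×2 pooling), `bᵢ` the soma's baseline
brightness, `dᵢ(t)` the neuron's ΔF/F trace on the output scale `s = 100`,
and `ε` shot-like white noise. Rigid per-frame jitter (integer px,
Gaussian-amplitude) and breathing-coupled global bumps — short, sharp ΔF/F
transients injected simultaneously into a ≥30% subset of neurons at
Poisson-scheduled times — model the two artifact families of an
anaesthetised preparation (respiratory rate held near 2 Hz, i.e.
100–150 breaths/min).

Because somata are only comparably bright to the diffuse background,
pixel-level ΔF/F is attenuated by roughly `b·w/(B + b·w)` relative to the
neuron's own ΔF/F. Footprint-weighted trace readout is linear, so this
dilution rescales traces without changing event timing or relative
features; detection thresholds are defined in units of each trace's own
baseline SD and are therefore scale-free.

## Transient kernels and class presets

A transient kernel rises linearly to its first (and global) sub-peak,
decays exponentially between sub-peaks with a short linear rise into each,
and closes with an exponential tail that a small linear ramp pins to
exactly zero at the event end. Sub-peaks sit ≥ 0.55 s apart in the middle
76% of the event; later sub-peaks are 55–90% of the first peak's height,
valleys 45% of the lower adjacent peak. Multi-peak events therefore ride
on a sustained plateau and do not return to baseline between sub-peaks —
the morphology seen in real GCaMP6f responses — which is what makes
duration and sub-peak count recoverable by threshold detection.

Class presets (capsaicin n=200, glutamate n=102, AITC n=51) are calibrated
so the *population* means of the analytic kernel features equal the
published group means of peak amplitude, duration and sub-peak count.
Published standard errors are converted to population SDs via SEM·√n;
amplitude and duration use log-normal marginals with SD clipped at the
mean (the unclipped capsaicin amplitude SD slightly exceeds its mean, and
CV > 1 log-normals produce unphysical tails), and the sub-peak count uses
a shifted negative-binomial (≥ 1) matched to the implied variance. The
three marginals are coupled by a Gaussian copula (rank correlations 0.30
amplitude–duration, 0.50 amplitude–peaks, 0.85 duration–peaks): weak
responses tend to be brief and single-peaked. The copula preserves the
calibrated marginal means exactly while making geometrically infeasible
draws (many sub-peaks in a brief event) rare; the residual feasibility
clip costs well under 1% of the mean count.

The rise and decay fractions (12% of the event each) give capsaicin-like
rise slopes of ≈ 38 ΔF/F/s at the calibrated amplitude and duration.
Integral, rise and decay are *not* jointly calibrated to published group
values: the published integrals (≈ 0.7–2.3 ΔF/F·s) are orders of magnitude
below amplitude×duration and evidently live on a different ΔF/F scale, so
the generator makes no attempt to force them; integral/rise/decay
correctness is instead established by closed-form oracle equivalence.

## Detection conventions

- Baseline statistics come from a user-chosen quiet window (default the
  first 55 s); threshold θ = mean + 3·SD.
- Events are maximal runs ≥ θ. Two runs belong to one response when the
  gap between them is < 2 s *or* the trace stays above the baseline mean
  throughout the gap. The long merge span reflects the event semantics of
  the emulated analysis, which treats a multi-peak burst (sub-peaks can
  sit > 1 s apart) as a single response with a sub-peak count, not as
  separate transients.
- Merged events whose suprathreshold samples span < 0.2 s are discarded:
  GCaMP6f transients last hundreds of milliseconds, so an isolated
  suprathreshold sample is a noise excursion. Without this floor a 3-SD
  threshold on white noise fabricates events by construction.
- Event boundaries extend outward to the crossings of the baseline mean,
  so duration covers the full response including its flanks.
- Sub-peaks are local maxima above θ with prominence ≥ 1 baseline SD and
  separation ≥ 0.5 s, counted on a lightly smoothed copy of the trace
  (Gaussian, σ = 0.1 s) so single-sample noise wiggles on plateaus are not
  counted; the event's global peak always counts.
- Features: amplitude = trace(peak) − baseline mean; duration =
  t_end − t_start; integral = trapezoid area of (trace − baseline mean)
  clipped below at zero; rise and decay are straight-line slopes
  start→peak and peak→end (decay as magnitude), with zero-length legs at
  event edges evaluated over one frame interval.
- Artifact windows: 1 s windows stepped frame-by-frame; flagged when the
  fraction of distinct ROIs with a peak inside reaches 0.30 (inclusive).
  Populations under 5 ROIs are never flagged — a coincidence fraction over
  one or two neurons is meaningless.

## Responder rule

For each application event, post_max is the largest transient amplitude
peaking in (onset, onset+100 s]. A neuron responds iff post_max exists and
pre-window activity is not *greater than* half of it (a pre maximum of
exactly 50% still responds — the exclusion quote is "greater than 50%").
Pre-window activity defaults to the largest detected transient amplitude
in the window, falling back to the maximum baseline-subtracted trace value
when no transient was detected there (subthreshold drive is still
activity); the fallback can be disabled. The pre-window length is not
specified by the emulated protocol and defaults to the post-window length
(clipped to the available recording). The feature table carries one row
per responding transient by default (matching per-response scatter
plots); per-responder averaging is available.

## Statistics and classification

Kruskal–Wallis H uses rank sums with tie correction and a chi-square
reference; an exact permutation option (full enumeration over distinct
group assignments) is provided for pooled n ≤ ~12. Pairwise comparisons
are Dunn's z-tests on the pooled ranking with Bonferroni adjustment
(Holm available) — the emulated analysis reports pairwise "Kruskal–Wallis"
p-values without naming its correction, so the conservative standard
choice is used and named in the output.

The classifier is a 500-tree random forest (library defaults otherwise,
seed logged) under stratified ten-fold cross-validation on amplitude,
duration, sub-peak count and integral (rise/decay optional). ROC curves
are one-vs-rest on pooled out-of-fold probabilities — one curve per class.
Feature attribution uses the tree-path (Saabas) decomposition, crediting
each split's change in class probability to the split feature and
averaging |contribution| over samples, classes and trees; it is exact for
a stump and additive by construction. Permutation importance is available
behind the same output contract. On the calibrated three-class fixture the
forest scores far above the 1/3 chance level and amplitude and duration
carry the largest attributions, in that qualitative sense reproducing the
finding that transient shape (not second-order measures) encodes the
stimulus; the real-data accuracy figure is not reproducible here because
the underlying recordings are not public.

## Fixture scale and runtimes

Fixtures are desk-scale by design: a 60 s quiet baseline stands in for the
30 min settling period, stimulus windows are 150 s (3000 frames at
20 fps), trace fixtures are one response per neuron at the published class
sizes, and movie fixtures default to ~10 neurons on 96×72 px for ~90 s.
Movie half-sizing pools 2×2 and halves both axes; the emulated protocol
prints 752×280 → 376×240, which is not consistent arithmetic — this
implementation produces 376×140 from a 752×280 field and documents the
discrepancy rather than matching the printed number.

## Known limitations

- The source extractor is a seeded correlation/PNR segmenter honoring the
  documented parameter surface (gSig/gSiz, patch/stride, correlation and
  PNR gates, 0.999 merge threshold); it is not a constrained NMF
  factorization and does not model background rings or indicator
  kinetics. Externally factorized footprint/trace matrices can be
  imported instead.
- Only rigid motion is corrected; piecewise/non-rigid correction is out
  of scope.
- Binned-percentile ΔF/F distorts events longer than the 5 s bin (the
  within-bin percentile rises during a sustained transient); fidelity
  claims about movie-level trace recovery are therefore made for
  sub-bin-length events.
- Estimated group means carry small systematic biases (boundary trimming
  shortens durations by a few percent; sub-threshold draws of the
  heavy-tailed amplitude law go undetected, nudging recovered amplitude
  means up). Both effects are well inside the recovery tolerances the
  test suite checks and are properties of threshold detection itself,
  not of the generator.
- The synthetic noise is white; real 1P noise has spatial structure
  (vasculature, hemodynamics) that the generator does not model, so
  passing fixtures demonstrates correctness of the pipeline's logic and
  calibration, not performance on arbitrary real recordings.
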