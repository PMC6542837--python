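# Methods

## Scope and model

The package quantifies two macroscopic signatures of biofilm formation on
dish surfaces: the optical density of crystal-violet staining, and the
change in surface wettability probed by squeezing the covering liquid with
an air-jet. Both chains start from ordinary images (scanner scans, camera
frames) and end in per-dish scalar summaries suitable for two-sample
statistics. No fluid dynamics of the jet–liquid interaction is modelled:
the synthetic trajectories are phenomenological templates of the observed
behaviours, not solutions of governing equations.

## Stain densitometry

Scanner output is display-gamma encoded; decompensation inverts it as
`I' = -(γ/ln 10)·ln(I/(2^b−1))`, i.e. `γ·log10` of the reflectance
fraction, so `I'` is proportional to optical density. Defaults γ = 1.8 and
b = 8 match a consumer flatbed scanner. Saturated-black pixels are clipped
to one count before the logarithm: the transform diverges at zero and a
fully black pixel carries no usable gradation anyway. RGB inputs are
collapsed with Rec. 601 luma weights before decompensation.

The calibration `d = c₁·I' + c₀` is an ordinary least-squares line through
neutral-density filter standards (the canonical set is OD 0.6 / 0.9 / 1.2).
Collinear standards give r² = 1 exactly; fewer than two standards or
identical readings are rejected.

The analysis region is the centred disc of **half** the dish-bottom radius,
which keeps the meniscus shadow and wall reflections out of the statistics.
Dish geometry is supplied in the run configuration; a Hough circular-edge
detector is available as a fallback, but manual geometry always wins
because dish rims photograph unreliably.

The stained/unstained threshold is data-driven: the midpoint between the
mean of the initial-state dish means and the mean of the incubated dish
means, pooled per dish type (bare vs plasma-treated polystyrene) since
comparisons are made within a type. Pixels strictly above the threshold
count as stained; ties are measure-zero on real data, so the convention
only needs to be fixed. Group statistics operate on per-dish means (N =
dishes), not on pooled pixels.

## Liquid-squeezing analysis

Frames before jet onset are averaged into a still-liquid baseline; each
later frame is segmented by Otsu-thresholding the absolute difference
against that baseline, closing with a 2-px disc, dropping specks under
16 px, and keeping the connected component containing (or nearest to) the
nozzle axis. The pre-jet frames double as a noise probe: the automatic
threshold is floored at 1.3 × the largest pre-jet |frame − baseline|
difference. Without this floor, Otsu on a frame where the liquid has fully
recovered would split pure sensor noise and report a spurious dry area; the
floor is what makes "residual diameter exactly 0" a measurable outcome
rather than a post-hoc rule. The floor needs at least two pre-jet frames;
with a single pre-jet frame the difference is identically zero and no floor
is applied.

The diameter is the equivalent-circle diameter `2·√(area/π)·scale`; a
maximum-Feret alternative exists behind a flag since the convention used by
commercial instruments is rarely documented. Timestamps are anchored so
t = 0 is jet onset (taken from the manifest, not the first frame).

The two indexes are arithmetic means over closed windows, t ∈ [0.63, 0.9] s
(late jet phase, after squeezing has settled) and t ∈ [1.23, 1.5] s (after
the 1 s jet ends), with 1 ns timestamp tolerance. If every in-window frame
segments to an empty mask the residual is reported as exactly 0 (full
recovery); otherwise the mean is reported even when small.

Oscillation frequency is the dominant nonzero periodogram peak of the
mean-detrended in-window samples, reported only when the peak power exceeds
4 × the median spectral power. The estimator refuses frame rates below
twice an 8 Hz detection band edge: squeezing oscillations live near 6 Hz,
and slower sampling cannot distinguish them from aliases. The convenience
wrapper `analyze_series` additionally requires 0.05 mm of in-window
standard deviation (below that the series is flat to within pixel
quantization) and evaluates the window t ∈ [0.45, 1.0] s so the two-step
spreading ramp cannot masquerade as a low-frequency peak; the bin width of
the estimate is the reciprocal window length.

## Captive-bubble contact angle

Bubbles of 2–5 µL are small enough that gravitational flattening is
negligible, so the silhouette is fitted as a circle (algebraic Kåsa least
squares) using contour points more than 5 px from the baseline, where the
optical contact-line distortion lives. The angle through the bubble is
`90° + asin(h/r)` with `h` the centre offset into the bubble phase; the RMS
contour-to-circle distance is reported so violations of the circular model
are visible. The bubble-side convention is used throughout (smaller angle =
more hydrophobic surface); `water_side_angle` converts as 180° − angle.
Surfaces that repel the bubble entirely produce a detection error — no
attachment model is attempted.

## Gated statistics

Homoscedasticity is tested with the variance-ratio F (larger variance in
the numerator, two-sided p = doubled tail capped at 1). At gate level 0.05
the pooled Student t-test is used when the gate is not rejected, Welch's
t-test otherwise; both two-sided. Constant samples are rejected rather than
assigned an infinite ratio. No multiple-testing correction is applied by
default, matching per-pair reporting practice; looping the full gated
procedure under the null (normal draws, n = 5 per group) reproduces the
nominal 5 % rejection rate within a percentage point.

## Synthetic phantoms

*Stained dishes* encode a known OD field through the inverse of the
densitometry chain, with optional Gaussian count noise (clipped to range)
and exact rejection of fields too dark to encode above one count. The
coverage phantom thresholds a Gaussian-smoothed random field at the ROI
quantile matching the requested coverage, so the true stained fraction is
pixel-exact and the patches are spatially correlated like real biofilm.

*Squeeze videos* render a dry disc (80 counts brighter than the liquid, a
visible but arbitrary contrast) whose diameter follows one of three
regimes: two-step spreading without recovery (ramp to a 5 mm shoulder held
until 0.2 s, then spread to the 17 mm plateau); a 6 Hz sinusoid about the
plateau with linear partial recovery; and a fast rise to a constant with
full linear recovery within 0.1 s. Plateaus for the four stock conditions
are 17, 6.8, 6.0 and 5.6 mm with residuals 17, 5.0, 0 and 0 mm. Camera
defaults (60 fps, 0.05 mm/px, 380×380 px frames, 2 s duration with jet on
over 0.3–1.3 s) are fixture conventions chosen so the largest dry area fits
the field of view and both index windows are fully sampled. Simulated
replicate suites jitter the plateau by 2 % (relative, Gaussian) to emulate
dish-to-dish variation, with 3-count pixel noise.

*Bubble stills* are exact circular caps below the baseline row, so the
stored truth is the analytic cap angle.

All generators draw from one `numpy` Generator seeded per call; identical
specs and seeds give bit-identical output.

What the phantoms do **not** emulate: uneven illumination, dish-wall
shadows and meniscus optics, motion blur, splashing and non-circular dry
regions, partial bubble attachment, and any dependence of the trajectories
on jet pressure, nozzle height or liquid volume (fixed metadata: 5 kPa,
15 mm, 1.5 mL). Passing tests therefore demonstrate that the measurement
chains are unbiased and stable under noise and quantization — not that
segmentation survives the full optics of a real rig.

## Problem sizes and numerical choices

The validation suite runs 20 seeded replicates per trajectory regime,
20 coverage phantoms, 10 seeds per noisy bubble angle, and 10,000
null replicates for the gated test; the acceptance script uses the study
replicate counts (N = 3, 3, 9, 6) for the four conditions. Per-frame
diameter tolerance is max(2 pixel pitches, 3 % of truth) — pixelation of
small discs dominates the first term, boundary quantization of large discs
the second. Index tolerances are 0.3 mm. Calibration recovery is checked to
1e-6 relative error on phantoms whose encoded counts are exact integers
(quantization-free by construction); with arbitrary OD values the chain is
limited by half-count quantization, bounded per pixel by
(γ/ln 10)·ln(I/(I−0.5)).

## Known limitations

* Equivalent-circle and Feret diameters differ by a shape factor on
  non-circular dry regions; comparisons across instruments need a fixed
  convention.
* The adaptive stain threshold depends on the batch composition: a batch
  without both initial and incubated dishes cannot be thresholded.
* The oscillation estimator's resolution is one spectral bin (reciprocal
  window length, ~1.2–1.8 Hz at 60 fps); it reports "around 6 Hz", not a
  precise frequency.
* The circle model biases the angle when bubbles are large enough to
  deform under gravity; `fit_residual` flags, but does not correct, this.
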