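# Methods

## Signal model and event detection

A lumbar-worn accelerometer tracks the body centre of mass (CoM), so the
vertical channel *a*ᵥ is a smooth oscillation at step frequency rather than
a sequence of sharp foot-contact transients. Detection therefore works on a
smoothed, differentiated version of the signal:

1. Remove the DC (gravity) component of *a*ᵥ by subtracting the recording
   mean. Any constant offset makes the subsequent integrals diverge, so
   this happens before every integration in the package.
2. Integrate (cumulative trapezoid) to a vertical-velocity trace.
3. Differentiate with a single-scale continuous wavelet transform using a
   first-derivative-of-Gaussian wavelet. For an antisymmetric wavelet the
   CWT of a rising slope is negative, so the minima of the coefficients
   mark maxima of the smoothed acceleration — the initial contacts (IC).
4. Differentiate the result once more the same way; maxima of that signal
   are the final-contact (FC) candidates.

The default "gaus1" path is computed as a negated
`scipy.ndimage.gaussian_filter1d(order=1)` convolution, which is exactly
the Gaussian-derivative CWT at scale σ and avoids the boundary handling of
a generic CWT routine; any other PyWavelets continuous wavelet can be
selected in `DetectorConfig` and is oriented to the same sign convention
with a linear-ramp probe. A wavelet that does not respond to a ramp
(symmetric) is rejected, since it cannot act as a differentiator.

**Scale selection.** No single scale suits all cadences, so `scale="auto"`
takes the dominant frequency f₀ of the integrated signal (FFT peak in
0.4–4 Hz, the locomotor band) and sets σ = fs/(10·f₀) samples — about a
tenth of a step period, wide enough to suppress sensor noise and narrow
enough not to merge neighbouring steps. An explicit scale overrides this.

**Candidate hygiene.** Extrema within 4σ of the signal edges are discarded
(wavelet edge effects). Candidates whose extremum magnitude falls below
0.2× the median candidate magnitude (per kind) are rejected: genuine step
extrema cluster around a common scale set by the CoM excursion, while
noise extrema in quiet stretches sit an order of magnitude below it. Both
rules are amplitude-relative, so detection is invariant to rescaling the
signal.

**Spurious-IC rule and bouts.** While any two consecutive ICs are closer
than 0.25 s, the one with the smaller detection magnitude is dropped (the
weaker extremum is taken to be the artefact — the choice of which peak to
discard is otherwise underdetermined). IC gaps above 2.25 s split the
series into bouts; treating the upper bound as a bout boundary rather than
an error keeps interrupted walks usable without ever fabricating a
2.5-second "step" across the gap. FCs are kept only inside a bout's IC
span.

**Foot assignment.** ICs alternate from a supplied first foot (one label,
or one per bout). Each FC takes the foot contralateral to the nearest
preceding IC; equivalently FC of foot X is the event just after the
opposite foot's IC, so stance_X = FC_X − IC_X spans roughly 60 % of the
stride and stance + swing = stride exactly.

## Per-step parameters

Rows are anchored at IC(k): step time = IC(k+1) − IC(k), stride time =
IC(k+2) − IC(k), stance from the FC between IC(k+1) and IC(k+2) (strongest
candidate if several; absent if none — never interpolated), swing as the
remainder of the stride. Quantities needing events beyond the bout edge
are absent.

**Vertical excursion.** *a*ᵥ is double-integrated (trapezoid); within each
IC-to-IC window the displacement is linearly detrended between the window
endpoints and h is the max−min of the detrended curve. Per-window linear
detrending is the drift control: double integration turns white sensor
noise and any residual bias into a low-frequency wander that grows with
integration time, and re-anchoring at every step keeps only the
within-step curvature the pendulum model needs. (A 0.1 Hz high-pass is an
obvious alternative; the per-window detrend was chosen because it has no
filter transient and its error resets each step.) Whether h should be
computed per step or per stride is an open modelling question; per step is
used, matching the step-level chord formula.

**Step length** = 2·√(2·l·h − h²) in cm, with l the sensor height. h
outside [0, l] is geometrically impossible and flags the step invalid
(h = l itself is allowed: it is the degenerate maximum chord 2l). The
generic multiplicative correction factor sometimes applied to
inverted-pendulum lengths is an explicit argument (default 1.0), never
silent. Step velocity = length/time, absent where either factor is.

**Pass segmentation** cuts the continuous step sequence into
walkway/circuit segments from externally counted steps, with any surplus
going to a trailing off-walkway segment. Shifting those counts by one step
exchanges every left/right label in the affected pass — the misallocation
failure mode studied in the agreement experiment.

## Summaries

Per characteristic: per-foot means and sample SDs (ddof = 1 — "standard
deviation" of a sampled walk is taken as the sample statistic), combined
mean over all steps (not the mean of foot means; the difference is
negligible for balanced walks but the all-steps definition is the honest
average), combined SD = √((var_L + var_R)/2), asymmetry = |mean_L −
mean_R|. The variance pooling keeps a systematic left/right offset out of
the variability estimate; on asymmetric walks the combined SD is strictly
below the naive all-steps SD, and the tests assert that inequality. A foot
with fewer than 2 steps has no SD; unlabelled tables yield combined
statistics only.

## Agreement protocol

ICC(2,k) is computed from the two-way ANOVA mean squares,
(MS_R − MS_E)/(MS_R + (MS_C − MS_E)/n) — two-way random effects, average
measures, absolute agreement, with k = 2 raters (reference and BWM). Fewer
than 3 subjects leaves it undefined; a zero-total-variance matrix is
perfect agreement (1.0) by convention. Bland–Altman limits use 1.96 ×
sample SD (ddof = 1) of the paired differences. Relative LoA% divides the
half-width by the grand mean of the two system means — this denominator,
rather than the reference mean alone, is what reproduces the published
swing-time percentages the convention was validated against. Rating bands:
ICC excellent strictly above 0.900, good from 0.750, moderate from 0.500,
else poor; LoA% bands [0, 5), [5, 10), [10, 50), [50, ∞) — half-open so
the printed band gaps (4.9→5.0 etc.) leave no value unrated. Group
inference (normality tests, t-tests, ANCOVA with height) is standard
statistics outside this package's scope and is left to statsmodels/scipy.

The subject-level summary (one row per subject) is the unit of analysis
for ICC and LoA; pooling step-level data across subjects would conflate
within- and between-subject variance.

`temporal_discrepancy(d, v) = d / v` documents the floor a reference
system's spatial resolution places on timing agreement: a walkway
resolving contact position to 1.27 cm at a 142 cm/s stepping speed blurs
event times by ≈ 9 ms, the order of the step/stance-time disagreements
such comparisons show.

## Simulator

Per step k a duration T_k and length SL_k are drawn from truncated normals
(±3 SD, durations clipped to the 0.25–2.25 s validity window), with L/R
means offset by ± asymmetry/2. The chord formula is inverted,
h_k = l − √(l² − SL_k²/4), and the CoM displacement over the step window is
a raised-cosine arc of height h_k: C¹-continuous across steps, lowest at
each IC, peaking mid-step. Any C¹ arc of that height preserves the chord
geometry the pipeline senses; the raised cosine is the simplest with
analytic derivatives. *a*ᵥ is the analytic second derivative plus gravity
(9.80665 m/s²), white noise, optional single-sample spikes (Poisson per
step), an optional linear drift term, and optional 16-bit ±8 g
quantisation. True FCs are placed at a configurable stance fraction of
each stride (default 0.62, the healthy-adult stance/stride ratio); the
generative model has no FC-specific signal feature, so FC *detection*
accuracy is not scored against truth — only the event-sequence algebra is.

Defaults describe a younger healthy adult at self-selected pace: 238 steps
(a 2-minute continuous walk), step time 0.535 ± 0.019 s with 0.008 s
left/right offset, step length 78.6 ± 4.9 cm, sensor height 0.91 m
(≈ 0.53 × a 1.72 m stature), 100 Hz sampling, 0.2 m/s² noise, 2 s quiet
pads. All randomness flows from one `numpy` generator seeded by the
mandatory `seed`; identical configs are bit-reproducible.

`simulate_two_systems` builds a cohort (default 20 subjects; subject-level
means drawn with between-subject SDs of 0.038 s step time, 5.8 cm step
length, and subject-specific variability/asymmetry spreads) and lets two
"systems" observe each subject's true step table with independent
per-step noise (SD expressed as a fraction of each characteristic's
mean). Optional misallocation shifts the test system's left/right labels
by ±n steps on every other pass, reproducing the segmentation failure
that leaves mean agreement excellent while asymmetry agreement collapses.

## What the simulation does and does not show

The generator reproduces the geometry the algorithms assume — pendulum
arcs, alternating feet, stationary noise — so passing tests demonstrate
the pipeline's internal correctness and its noise robustness, not
performance on real gait. Real signals add impact transients at IC,
mediolateral sway, turning segments and soft-tissue artefacts that are not
modelled; the problem sizes used in the tests and acceptance script
(20 walks × 238 steps, 20-subject cohorts, 300 randomized candidate
sequences) were chosen as the smallest that make the sampling error of
each check small against its tolerance.

## Known limitations

* Step width is not measurable from a single tri-axial accelerometer.
* FC placement in the simulator is a labelling convention, not a signal
  feature; stance/swing recovery is validated on constructed event
  sequences only.
* The bout-splitting behaviour at the 2.25 s bound, the weaker-extremum
  tie-break, and the grand-mean LoA% denominator are defined choices where
  the field's conventions are silent; each is documented above and pinned
  by tests.
* The step-length correction factor defaults to 1.0; calibrated deployments
  should set it explicitly.
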