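# Methods

## Scope and model

`fmposthoc` analyses one functional imaging experiment: a multi-frame
grayscale movie of FM1-43-loaded boutons acquired at `frame_rate_hz`
(default 1 Hz) with `n_baseline_frames` (default 30) pre-stimulus frames,
a high-K⁺ stimulation of `stim_duration_frames` (default 10) frames, and a
post-stimulus plateau; plus one or two single-frame immunofluorescence
images of the same field acquired after fixation and labelling, related to
the functional field by a small unknown translation. All images share one
coordinate convention: 0-based `(row, col)` indices with pixel centers at
integer coordinates. Pixel data are promoted to float64 once at read time;
the camera bit depth (14 bits in the modelled protocol) is metadata only
and nothing is ever clipped on input.

The per-bouton efficiency statistic is the unloaded fraction
`U = (F0 − ⟨F⟩_tail)/F0` with `F0` the baseline mean of the ROI's
mean-intensity trace and the tail a `tail_window_frames` (default 10,
chosen because the modelled recordings end in a ≈60 s plateau without a
published window definition) average of the last frames. ROI traces are
means, not sums, over ROI pixels, so every kinetic statistic is invariant
to ROI area and to overall intensity scale; the sum (integrated density)
is reserved for immunoreactivity, where punctum size is part of the
signal.

## Simulator

The generator renders each bouton as an isotropic Gaussian spot
(`psf_sigma_px`, default 1.5 px at the reduced default scale) whose
temporal amplitude follows

    F_i(t) = B_i · b(t)                                   t < t_stim
    F_i(t) = B_i · b(t) · [(1−u_i) + u_i·e^−(t−t_stim)/τ]  t ≥ t_stim

with multiplicative photobleaching `b(t) = (1−β)^t` (β default 5·10⁻⁴ per
frame, small enough to pass the baseline-slope QC) and a single-exponential
destaining time constant τ (`unload_tau_frames`, default 4). The
single-exponential form is the simplest monotone-decay model consistent
with published population traces, which do not constrain the functional
form; τ is configurable precisely because it is not a claim.

Population defaults are anchored to the printed population statistics of
the protocol the package models: per-bouton unloading fractions are
truncated-normal on (0, 1) with mean 0.34; peak brightnesses are lognormal
(median ≈ 2000 counts, σ_log 0.4, i.e. SNR ≫ 10 against the default
Poisson noise). The unloading spread (`unload_sd` = 0.18) and the marker
level distribution (lognormal, `marker_log_sd` = 0.6) were fixed once, by
design, as a compromise between two constraints that cannot be satisfied
simultaneously: distribution widths that exactly reproduce the published
tail occupancies (≈14 % of boutons above 2× mean IR, ≈35 % below 0.5×,
implying σ_log ≈ 0.9 and sd_u ≈ 0.16) leave a single 500-bouton experiment
with only ≈74 % power to detect the planted coupling, whereas the chosen
values give tail occupancies of the same order (≈8 % / ≈23 %) and ≈99 %
single-experiment power. The package's verification studies are designed
around single simulated experiments, so detectability won.

Marker-A spot amplitude is `base · (1 + marker_slope·(u_i − ū)) · ε`, with
`base` the lognormal level, the middle factor the planted linear coupling
between protein content and release efficiency (slope 0 plants a null,
Munc13-1-like marker; 1 a strongly coupled, RIM1α-like one; the factor is
floored at 0.01 to keep amplitudes positive under extreme slopes), and ε
lognormal measurement noise of CV `marker_noise_cv` (default 0.2).
Marker-B is marker-A times another ε draw, so normalized B-vs-A is linear
with slope 1 — the planted version of the two-channel validity control.
Both post-hoc channels are rendered at bouton positions translated by the
integer `channel_shift_px` (default (5, −3)). Every image receives a
background plane (level 100 plus a 20-count corner-to-corner gradient) and
Poisson noise by default (Gaussian and noise-free variants for controlled
tests).

Geometry: spot kernels are evaluated on ±4σ windows; centers keep a margin
of `⌈4σ⌉ + max|shift| + 1` from every border and a pairwise separation of
`min_separation_sigma·σ` (default 4σ, the no-merging floor). Because
windows are never clipped, the exported truth marker level equals the
rendered noise-free integrated spot intensity exactly; tests that require
zero cross-talk between truncated windows raise the separation to 10σ.
Placement is bounded rejection sampling and fails loudly if the density is
infeasible. A fixed seed reproduces every image bit-exactly.

What the simulator does *not* emulate: neurite morphology and
out-of-focus structure, spatially correlated background, non-Gaussian
PSFs, vesicle-level release stochasticity, rotation/scaling between
channels, and subpixel channel shifts. Passing tests therefore demonstrate
correctness of the measurement chain under the stated model, not
robustness to every property of real recordings.

## Segmentation and quality control

The destaining difference image `D = ⟨baseline⟩ − ⟨tail⟩` is bright
exactly on stimulus-responsive puncta; static background of any shape
cancels. Candidate pixels satisfy `D > median(D) + k·1.4826·MAD(D)`
(k = `threshold_k`, default 5); the robust scale is floored at 10⁻⁶ of the
dynamic range so noise-free images (MAD ≈ 0) still threshold sensibly.
Touching puncta are split by watershed on −D seeded at local maxima of D
with minimum separation `2·expected_sigma_px` (plateau ties resolve toward
larger D, then smaller (row, col)); components outside
`[min_area_px, max_area_px]` (defaults 4, 400) are dropped and labels are
relabelled consecutively. An empty result is a warning, not an error.

Quality classification uses three unitless statistics per trace: the
least-squares baseline slope divided by F0 (|slope| ≤ 0.002/frame by
default), the baseline sample CV (≤ 0.05), and the unloading extent
(≥ 0.05). The thresholds are this package's own operating point — the
modelled protocol names the three parameters but not their values — and
all are configurable. Quality-failing ROIs are excluded from *all*
downstream analysis, including the IR normalization denominator; the
published protocol does not state whether its exclusions propagate that
far, so the choice is recorded in the run metadata.

## Background subtraction

The rolling-ball background is the grayscale opening of the image by a
ball-shaped structuring function of radius `rolling_ball_radius` (default
12 px, with ball height in intensity units equal to pixel units): erosion
then dilation with heights `√(R²−r²)`, replicate boundary handling. The
estimate is anti-extensive (never exceeds the image) and idempotent;
features narrower than about the ball diameter survive subtraction.
ImageJ's implementation adds smoothing and shrinking heuristics at large
radii, so outputs may differ from it at the few-percent level — tests
verify against the morphological definition, computed brute-force, not
against ImageJ. The same operation can optionally be applied to the FM
frames (`subtract_fm_background`); it defaults to off because the modelled
acquisition chain performs its own (unspecified) FM background
subtraction, and the measured unloaded fraction is then diluted by the
residual background plane — an effect common to all groups that leaves
ordering and significance intact.

## Registration

Translation-only, integer-pixel: the capability of the alignment step it
replaces, after coarse manual re-positioning at the microscope. The
reference is the rolling-ball-subtracted time-average of the FM baseline
frames (the protocol says only "take the FM image as a reference"); each
IR channel is aligned to it independently. The estimator evaluates the
Pearson correlation over the overlap region for every displacement within
`±max_shift_px` (default 20) — computed in closed form from six FFT
correlations, algebraically identical to the exhaustive search — and
breaks ties toward smaller displacement magnitude, then smaller row, then
smaller col. Constant images are rejected; a peak correlation below
`min_correlation` (default 0.2) flags the transform and warns. Applying a
transform moves the image by −shift onto reference coordinates, zero-fills
the border that lost its source, and marks it invalid; every ROI touching
an invalid pixel is removed before quantification.

The linearity control regresses normalized channel-B IR on channel-A
(least squares) and passes when the slope lies in `qc_slope_band` (default
(0.5, 1.5)) with Pearson r ≥ `qc_min_r` (default 0.5) — deliberately loose
translations of "slope close to 1" and "strong correlation".

## Statistics

Groups are defined on mean-normalized IR of the grouping channel with
strict thresholds: high > 2, low < 0.5, boundary values mid. The compared
samples are the whole population, the high group and the low group —
overlapping by design, reproducing the comparison this pipeline exists to
replicate; because overlap violates ANOVA independence, the disjoint
high/mid/low ANOVA is always computed alongside and reported as the
statistically independent variant. The one-way ANOVA is implemented from
the textbook sums of squares with explicit degenerate conventions (all
group means equal → F = 0, p = 1; zero within-group variance with
distinct means → F = ∞, p = 0); pairwise comparisons are pooled-variance
two-sample t tests with p-values multiplied by the number of pairs tested,
capped at 1. SEMs use the n−1 sample standard deviation over ROIs (per-ROI
and per-coverslip dispersion are not distinguished in a single simulated
field). Unloaded fractions are fractions internally and percentages in all
outputs.

## Verification design and problem sizes

Every operation with a closed form or a cheap brute force is tested
against an independent oracle: per-ROI sums and traces against per-pixel
loops, the ANOVA against an independent implementation, the rolling ball
against a direct min/max opening, the shift estimator against exhaustive
search, and measured unloaded fractions against the analytic trace model
(`nominal_unloaded_fraction`), which on noise-free fields agrees to
better than 10⁻⁶ relative. Pipeline-level checks run at the package's
design scales — 256×256 fields with 50–100 boutons for segmentation and
null-calibration studies, 512×512 with 500 boutons for the
planted-coupling study — sizes chosen so the full suite completes in a few
minutes while keeping the statistical designs meaningful.

## Known limitations

* Integer-pixel translation only; no rotation, scaling, or subpixel
  registration.
* The destaining-difference segmentation finds stimulus-responsive
  puncta only; a bouton that does not destain is invisible to the mask
  (consistent with quality criteria that would reject it anyway).
* The rolling-ball radius/intensity unit coupling means very steep
  backgrounds (slope ≳ ball curvature) are tracked imperfectly near image
  borders, where boundary replication kinks the opening.
* Biological effect sizes in real cultures are smaller than the
  simulator's default planted coupling; at published effect sizes a
  single 500-bouton field is underpowered, which is why the published
  comparisons pool thousands of boutons across coverslips.
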