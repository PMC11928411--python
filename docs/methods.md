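# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about real ultrasound data.

## Flow-pixel classification and the area ratio

An SMI frame mixes an achromatic B-mode background with a saturated
red-orange flow overlay. `FlowColorModel` gates pixels in HSV space: hue
inside a band (default 340°–50°, wrapping through 0°), saturation ≥ 0.25,
value ≥ 0.15, and an RGB channel spread (chroma) ≥ 0.08 so that grayscale
speckle — whose chroma is exactly zero — can never pass regardless of
brightness. The gate is deterministic and per-pixel; scanners apply
proprietary gating internally, so these thresholds are calibration
parameters to be checked against a given device's overlay palette, not
physical constants.

The area ratio is exact integer-count arithmetic, `|flow ∩ ROI| / |ROI|`.
`area_ratio_series` classifies only the pixels belonging to some ROI, which
is algebraically identical to classifying the full frame and much cheaper.

## Cardiac cycles and the perfusion index

Cycle detection finds the dominant spectral peak of the mean-removed trace
inside a heart-rate band (default 250–400 beats/min, bracketing the
300–350 bpm regime maintained under anesthesia in the target experiments),
refines the frequency by parabolic interpolation of log-power, and places
cycle boundaries at troughs of a lightly smoothed copy of the trace
(window ≈ 1/8 period; the smoothed copy is used for boundaries only, never
for values). A constant trace raises a no-pulsatility error.

`compute_irpi` offers two extrema conventions:

- `per_cycle_median` (default): IRPI within each detected cycle, median
  across cycles. Robust to dropout spikes and drift; with ~20 cycles in a
  4 s clip the median is stable.
- `global`: extrema over the whole clip — the literal reading of the
  definition; sensitive to any single outlier frame.

Both are reported by the pipeline. The index inherits two exact
invariances from its ratio form: multiplying the trace by any c > 0 leaves
it unchanged, and enlarging the ROI with never-flow pixels rescales the
trace by a constant and therefore changes nothing (verified to 1e-12 in
the tests). Adding constantly-flowing pixels dilutes the pulsatile
fraction and strictly lowers the index — the reason interlobular,
interlobar, and combined ROIs are analyzed separately.

The combined ROI is computed as one area-ratio series over the union mask,
not as the mean of two indices; this reproduces the dilution behavior a
physically drawn "both vessels" ROI exhibits.

Smoothing of the area-ratio series is off by default. A centered boxcar of
width w attenuates a sinusoid of period T by sinc(w/T); keeping w < T/4
limits extremum attenuation to ~10%, so the window, when used, should stay
below a quarter cardiac period.

## Synthetic cine loops

Inside each vessel mask every pixel is independently a flow pixel in frame
i with probability p(t_i) = p0·(1 + m·cos(2π f_H t_i + φ)); the raised
cosine is the simplest zero-mean waveform with min −1/max +1, so the time
average of p is p0 and the true index has the closed form

    IRPI = (p_max − p_min)/p_max = 2m/(1+m),

strictly increasing in m on [0, 1). Defaults: 128×128 px, 120 fps, 4 s,
heart rate 330 bpm (≥ 10 frames per cycle, 22 full cycles), two
non-overlapping vessels of ≈ 2000 px each — a thin diagonal interlobular
segment (p0 = 0.5, m = 0.30) and a wider interlobar segment (p0 = 0.6,
m = 0.10), reflecting the higher interlobular pulsatility the index is
designed to detect. Noise controls: multiplicative speckle on the
background (SD 0.10), per-frame flow-pixel dropout (rate 0.05; a constant
thinning of p(t), to which the index is invariant by construction), and a
static background texture field. Flow pixels are painted in the overlay
hue with joint-channel brightness jitter, which preserves hue and
saturation exactly, so classification is exact on noise-free fields.

Estimator bias: per-cycle max/min of a binomially sampled trace are
extreme values; with ~2000-px ROIs and ~22 frames per cycle the expected
bias on the index is +0.02 to +0.035 (larger for small m), inside the
±0.05 recovery band used by the tests. The bias shrinks as 1/√(ROI px).

What the generator does **not** model — and what passing tests therefore
do not establish for real data: spatially correlated speckle and flow
(occupancy is independent per pixel per frame), wall motion and probe
drift, vendor-specific overlay gating, depth-dependent gain, aliasing.
Anatomically accurate vascular trees are out of scope.

## CEUS time-intensity curves and TTP

The bolus model is the peak-normalized gamma-variate

    I(t) = baseline + A·((t−t0)/(αβ))^α · exp(α − (t−t0)/β),   t > t0,

whose maximum (A above baseline) falls exactly at t0 + αβ; true TTP = αβ.
Defaults: α = 2, β = 1.5 s, A = 20 dB over a 10 dB baseline, 30 Hz,
additive Gaussian dB-domain noise (SD 0.3 dB). Averaging over the ROI is
done in dB (the workstation convention); a linear-power option exists.

Onset detection is two-stage. The coarse stage takes the first time the
curve exceeds baseline mean + k·SD (k = 3) and stays above for 3 samples
(baseline + machine epsilon when the baseline is exactly flat). Because a
gamma-variate rises from zero slope (∝ τ^α), that crossing systematically
lags the true arrival — by ≈ 0.27 s at the default SNR — so by default a
straight line fitted to the early-rise samples (between baseline + 1·SD
and baseline + 8·SD around the crossing) is back-extrapolated to the
baseline level, a standard bolus-arrival refinement. The refinement is
skipped for flat baselines (SD ≈ 0) and is disable-able (`refine="none"`).
Both stages are invariant under affine intensity maps I → aI + b (a > 0)
and time translation, and so is TTP.

The peak is the argmax of a 5-sample median-filtered copy (filter skipped
when the baseline is noiseless, where it could only displace the argmax),
refined to sub-sample precision by a parabolic vertex fitted over the
contiguous near-peak region (samples within 2 baseline-SD of the maximum).
On a noiseless curve that region collapses and no shift is applied, so
plateaus and asymmetric curves are not dragged sideways. Measured
performance at the default conditions: mean |TTP error| ≈ 0.12 s over 50
replicates; ≤ one frame interval on noise-free curves.

`fit_gamma_variate` least-squares fits the full model (scipy curve_fit,
initialized from the empirical onset/peak; α bounded to [0.2, 20]) and
reports model TTP = αβ alongside the empirical value; it recovers
noise-free parameters to better than 1%.

## Doppler indices and venous patterns

RI uses per-cycle systolic maxima and the velocity at the cycle-end trough
(the "end-diastolic" reading), median across cycles; VII uses per-cycle
max/min. Both lie in [0, 1] for nonnegative traces and are invariant under
velocity rescaling (up to one-sample boundary shifts in trough detection,
< 1e-3 in practice). A constant venous trace returns VII = 0 — physiologic
continuous flow, not an error — while a flat arterial trace is an error,
since RI is undefined without pulsatility.

Venous patterns are graded with configurable thresholds (the literature
names the categories but no cutoffs): continuous iff VII < 0.15;
monophasic iff the velocity falls to ≤ 5% of the cycle peak at least once
per cycle (flow interruption); otherwise biphasic when two descents per
cycle are present, and by convention also when a single uninterrupted
descent is (the ordinal severity scale has no finer slot).

## Teichholz volumes

V(D) = 7D³/(2.4 + D). Applied to rodent M-mode diameters the published
volume scale is reproduced by inserting the numeric millimetre value
directly (V(6.7) = 231.4 against a printed 230.6, a 0.35% difference
attributable to per-animal averaging); the centimetre convention (human,
volumes in mL) is selectable via `units="cm"`. The printed volume-unit
label "(mL)" is physiologically a microlitre scale for rats; values are
kept on the printed numeric scale without conversion. EF is invariant
under joint rescaling of both diameters only in the large-D limit (the
2.4 in the denominator breaks exact scale invariance); this is documented
rather than assumed anywhere. A zero-stroke beat (LVDs = LVDd) yields
SV = 0, EF = 0 rather than an error; only LVDs > LVDd is rejected.

## Histology segmentation

Pixels are assigned to background (value ≥ 0.88 and saturation ≤ 0.10),
red parenchyma (hue 320°–25°), or light-blue edema (hue 160°–260°);
residual off-gate pixels go to the nearer stain hue center (very dark
desaturated residuals to background), so the classification is total and
deterministic. The edema fraction divides edema pixels by tissue pixels
(parenchyma + edema), excluding background/lumen from the denominator.
Color gating was chosen over stain deconvolution because the reference
workflow is threshold-based; the two stain classes are far apart in hue,
so the simple gate is exact on clean fields. The synthetic generator
paints thresholded Gaussian random fields (tissue at scale 3×blob_scale,
edema blobs at blob_scale = 10 px) in reference colors with hue-preserving
brightness jitter and records the painted masks, so segmentation accuracy
is scored at pixel level. Real slides add stain variability, folds, and
out-of-gamut hues that the generator does not emulate.

## Cohort model and calibration

Congestion variables (CVP, RMP, TTP cortex/medulla, edema %) are lognormal
per group; perfusion indices are normal on the raw scale. Group
calibration is mean ± SE as printed for 5 control vs 9 HF animals, with
population SD = SE·√n_ref, where n_ref = (5, 9) are the group sizes behind
the reference SEs; simulating larger cohorts keeps the population fixed.
The combined-ROI SE is taken as 0.054 (the printed 0.54 exceeds its mean
and is treated as a misprint — flagged in the generator's CohortSpec.notes, not
silently corrected).

Subjects are coupled by a Gaussian copula. The planted correlations
(index vs ln CVP 0.75, ln RMP 0.84, ln TTP-medulla 0.60, ln edema 0.55)
are targets on the *pooled* two-group scale, the scale on which the
reference scatter plots report R. For each planted pair the generator
solves analytically for the within-group latent correlation that makes the
two-group mixture Pearson correlation (group-size weighted, on the
IRPI-raw × log-congestion scale) equal the target; infeasible targets
(|within ρ| > 1) are rejected. Non-planted entries follow a
single-congestion-factor structure (loadings: RMP 0.90, CVP 0.85,
TTP-medulla 0.80, edema 0.70, TTP-cortex 0.50, secondary indices
0.30–0.45), and the assembled matrix is validated positive semi-definite
(eigenvalue tolerance 1e-8), with the PSD factor taken by
eigendecomposition so ρ = ±1 edges are legal. Monte-Carlo check: the mean
pooled sample R against ln RMP over 500 seeded cohorts is within ±0.01 of
the 0.84 target.

Under these planted marginals, the exact Mann–Whitney comparison of the
interlobular index (5 vs 9) is significant at α = 0.05 in ≈ 60–65% of
replicates and the interlobar index in ≈ 3–5%. The separation-vs-overlap
contrast between vessel classes is robustly reproduced; a higher absolute
power would require tighter group SDs than the printed standard errors
imply, which is a property of the calibration itself, not of the test
implementation (the exact test's discreteness costs only a few points
relative to a t-test here).

Group differences can alternatively be planted at the imaging level — per
vessel class through the modulation depth m of the cine generator — and
recovered through the full pipeline; the cohort generator plants them
directly at the summary level. Both entry points exist because they answer
different questions (pipeline fidelity vs statistical calibration).

## Statistics

Shapiro–Wilk (scipy's Royston implementation) gates normality at
α = 0.05; the default log-transform set (CVP, RMP, TTP-medulla, edema)
is applied by default for correlation analysis (`force_log=True`), or
conditionally on the gate. Mann–Whitney comparisons always run on raw
values — ranks are invariant under monotone transforms, so the log policy
cannot affect them. The exact method (full enumeration) is used whenever
n_x + n_y ≤ 20 and the pooled sample is tie-free — the regime of the
target cohorts, where the smallest attainable two-sided p is
2/C(14,5) = 2/2002 ≈ 0.001 — and the mid-rank normal approximation with
tie correction otherwise; the method used is reported. The two-sided p is
min(1, 2·min(P(U ≤ u), P(U ≥ u))). Pearson p-values come from the t
distribution with n − 2 df. Correlation analyses pool both groups
(consistent with the degrees of freedom behind the reference p-values).
No multiple-testing correction is applied, matching the reference
analysis style. Reporting is mean ± SE with SE = SD/√n.

## Reproducibility

All generators take integer seeds into `numpy.random.default_rng`;
identical spec + seed is bit-identical. Pipeline runs derive per-stage
seeds as `SeedSequence(global_seed, spawn_key=(stage_index,))`, reduced
mod 2³¹, and write a manifest with the config hash, stage seeds, defaults
actually used, and SHA-256 digests of every output, so reruns are
verifiable byte-for-byte. CSV output uses shortest-repr floats and is read
back with round-trip float parsing, making read(write(x)) exact.

## Problem sizes used by the test suite

Cine recovery runs 20 seeds × 3 modulation depths at the default
128×128 / 4 s / 120 fps geometry; TTP recovery 50 seeds; cohort recovery
500 seeds; the Mann–Whitney null 2000 replicates; the enumeration oracle
covers all group sizes up to 6 + 6. These sizes give Monte-Carlo standard
errors comfortably below the acceptance bands they are checked against.

## Known limitations

- The color gates (flow overlay and stain classes) are calibrated to the
  synthetic palettes; real devices and stains need a one-time gate check.
- Cycle segmentation assumes a quasi-stationary heart rate inside the
  detection band; arrhythmia or double-peaked area-ratio waveforms would
  need a different boundary rule.
- The onset back-extrapolation assumes a locally linear early rise; very
  low SNR (< ~3 dB enhancement over noise) degrades it toward the coarse
  threshold crossing.
- Arteries and veins are not separated — SMI itself cannot distinguish
  them, so the flow mask is a single class by design.
- Motion compensation, vessel auto-detection, and absolute perfusion
  quantification (wash-in rate, AUC) are out of scope.
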