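# renalsmi

Quantification of renal congestion from microvascular ultrasound, for
researchers studying cardiorenal physiology in small-animal heart-failure
models (and for anyone who wants a reproducible, scriptable version of the
measurements those studies report).

Renal congestion — elevated central venous pressure backing up into the
kidney — raises renal medullary pressure (RMP), slows perfusion, and causes
interstitial edema. Clinically it is graded from intrarenal venous Doppler
patterns (continuous / biphasic / monophasic), but that scale is too coarse
for early congestion. Superb microvascular imaging (SMI) displays very slow
flow as a color overlay without contrast agent, and the pulsatility of the
overlay area carries the signal.

## The core statistic

Within a region of interest (ROI) drawn over interlobular or interlobar
vessels, the **area ratio** on frame *t* is

```
a(t) = (# flow-overlay pixels in ROI) / (# pixels in ROI)
```

which pulses with the cardiac cycle. The **intrarenal perfusion index** is

```
IRPI = (max a − min a) / max a        ∈ [0, 1]
```

computed per cardiac cycle and summarized by the median across cycles (a
global-extrema variant is available). Because IRPI is a ratio of area
ratios, enlarging the ROI with non-flowing tissue leaves it unchanged —
only the pulsatile vessels matter.

Companion measurements implemented alongside:

- **CEUS time-to-peak (TTP)**: onset-to-peak time of the ROI-mean
  time-intensity curve (dB) after a contrast bolus, with a gamma-variate
  model fit as a noise-robust alternative;
- **Doppler indices**: arterial resistive index RI = (Vs − Ved)/Vs, venous
  impedance index VII = (Vmax − Vmin)/Vmax, venous pattern grading;
- **Teichholz LV volumes**: V(D) = 7D³/(2.4 + D) from M-mode diameters,
  EDV/ESV/SV/EF;
- **Histology edema fraction**: trichrome color segmentation, edema pixels
  over tissue pixels;
- **Cohort statistics**: Shapiro–Wilk gating, natural-log transforms, exact
  Mann–Whitney comparisons, Pearson correlations, mean ± SE reporting.

A `renalsmi.simulate` subpackage generates every input — cine loops with
planted per-pixel flow occupancy `p(t) = p0(1 + m·cos(2πf_H t))` (so the
true index is exactly `2m/(1+m)`), gamma-variate bolus curves, velocity
waveforms, two-color histology fields, and calibrated two-group cohorts —
with machine-readable ground truth, so the entire pipeline is testable
without animal data.

## Worked example

```python
from renalsmi.simulate import CineSpec, generate_cine
from renalsmi.smi import area_ratio_series, compute_irpi
from renalsmi.hemodynamics import teichholz

cine, truth = generate_cine(CineSpec(seed=1))   # 128x128, 120 fps, 4 s, HR 330
series = area_ratio_series(cine, truth.roi_set())
for label in ("interlobular", "interlobar", "combined"):
    r = compute_irpi(series[label])
    print(f"{label:13s} irpi={r.irpi:.3f}  a_max={r.a_max:.3f} "
          f"a_min={r.a_min:.3f}  cycles={r.n_cycles}")

m = teichholz(6.7, 4.7)   # control-group mean LV diameters, mm
print(f"EDV={m.edv:.1f} ESV={m.esv:.1f} SV={m.sv:.1f} EF={m.ef:.1f}%")
```

prints

```
interlobular  irpi=0.475  a_max=0.635  a_min=0.334  cycles=21
interlobar    irpi=0.215  a_max=0.629  a_min=0.494  cycles=21
combined      irpi=0.318  a_max=0.616  a_min=0.420  cycles=21
EDV=231.4 ESV=102.4 SV=129.0 EF=55.8%
```

The default cine plants modulation depth m = 0.30 in the interlobular
vessel and m = 0.10 in the interlobar vessel, i.e. true indices 0.462 and
0.182: the estimates above recover them to within the binomial pixel-noise
bias (~0.02–0.03), and the combined ROI dilutes the interlobular signal
exactly as expected when pulsatile and steady vessels share one ROI. The
Teichholz volumes are on the published rodent scale (millimetre-numeric
convention; see `docs/methods.md`).

The same operations are scriptable from a shell:

```
renalsmi simulate cine --seed 1 --out out/
renalsmi analyze irpi --cine out/cine.tif --roi out/roi_labels.png --out out/
renalsmi analyze echo --lvdd 6.7 --lvds 4.7
renalsmi run --config run.yaml
```

## Layout

```
src/renalsmi/
  smi.py            flow-pixel classification, area-ratio series, cycles, IRPI
  ceus.py           time-intensity curves, onset, TTP, gamma-variate fit
  hemodynamics.py   RI, VII, venous patterns, Teichholz volumes
  histology.py      stain-class segmentation, edema fraction
  stats.py          normality gating, log policy, Mann-Whitney, Pearson
  simulate/         generators with planted ground truth for all of the above
  io.py             TIFF/PNG/GeoJSON/CSV readers and writers
  pipeline.py       end-to-end runs with seeds, manifests, reproducibility
  cli.py            `renalsmi` command-line interface
docs/methods.md     models, parameters, numerical choices, limitations
```
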