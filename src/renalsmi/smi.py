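"""Intrarenal perfusion index (IRPI) from microvascular-ultrasound cine loops.

Superb microvascular imaging (SMI) overlays slow-flow color pixels on a
grayscale B-mode image. Within a region of interest (ROI) drawn over a
vessel, the *area ratio*

    a(t) = (# flow pixels in ROI at frame t) / (# pixels in ROI)

pulses with the cardiac cycle. The intrarenal perfusion index summarizes
that pulsatility:

    IRPI = (max a - min a) / max a

which is dimensionless in [0, 1] and, being a ratio of area ratios, does not
depend on ROI size as long as the pulsatile vessel is contained in the ROI
(adding never-flow pixels rescales a(t) by a constant and cancels).

The module covers: color-gate classification of overlay pixels, per-ROI
area-ratio time series, cardiac-cycle detection on the series, and IRPI with
either per-cycle (median across cycles, the default) or global extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from skimage.color import rgb2hsv

from .errors import (
    DegenerateInputError,
    FormatError,
    NoPulsatilityError,
    ValidationError,
)

ROI_LABELS = ("interlobular", "interlobar", "combined")


# ---------------------------------------------------------------------------
# containers


@dataclass
class CineLoop:
    """Time-ordered RGB frame stack.

    Parameters
    ----------
    frames : (T, H, W, 3) array
        Intensity frames, uint8 or float.
    frame_rate : float
        Frames per second.
    pixel_size : float, optional
        mm per pixel (isotropic), if known.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise FormatError(
                f"frames: expected (T, H, W, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValidationError("frames: a cine loop needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ValidationError(f"frame_rate: must be > 0, got {self.frame_rate}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps, t_i = i / frame_rate (0-based)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class RoiSet:
    """Named boolean pixel masks over the frame grid.

    Labels follow the three ROI classes (interlobular, interlobar, combined);
    arbitrary extra labels are allowed. When all three canonical labels are
    present, ``combined`` must contain the union of the other two.
    """

    masks: dict[str, np.ndarray]
    provenance: str = "array"

    def __post_init__(self):
        shapes = set()
        for label, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            self.masks[label] = m
            if m.ndim != 2:
                raise FormatError(f"ROI '{label}': mask must be 2-D")
            if not m.any():
                raise ValidationError(f"ROI '{label}': mask is empty")
            shapes.add(m.shape)
        if len(shapes) > 1:
            raise FormatError(f"ROI masks have inconsistent shapes: {shapes}")
        if all(k in self.masks for k in ROI_LABELS):
            union = self.masks["interlobular"] | self.masks["interlobar"]
            if not self.masks["combined"][union].all():
                raise ValidationError(
                    "combined: must contain interlobular ∪ interlobar"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape


@dataclass(frozen=True)
class FlowColorModel:
    """Color gate separating the SMI flow overlay from grayscale tissue.

    The scanner's internal flow classification is proprietary; this gate
    reproduces it operationally: a pixel is *flow* iff its hue lies inside
    ``[hue_lo, hue_hi]`` degrees (wrapping through 0 allowed), its saturation
    and value exceed the minima, and its RGB channel spread (chroma) exceeds
    ``chroma_margin`` — grayscale speckle has zero chroma and never passes.
    Defaults match the red-orange SMI overlay hue band.
    """

    hue_lo: float = 340.0
    hue_hi: float = 50.0
    min_saturation: float = 0.25
    min_value: float = 0.15
    chroma_margin: float = 0.08

    def __post_init__(self):
        for name in ("hue_lo", "hue_hi"):
            h = getattr(self, name)
            if not (0.0 <= h < 360.0):
                raise ValidationError(f"{name}: must be in [0, 360), got {h}")
        for name in ("min_saturation", "min_value", "chroma_margin"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}: must be in [0, 1], got {v}")


@dataclass
class AreaRatioSeries:
    """Per-frame flow-pixel fraction a(t) within one ROI."""

    t: np.ndarray
    a: np.ndarray
    roi_label: str = ""
    n_roi_pixels: int = 0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.t.shape != self.a.shape:
            raise ValidationError("t and a must have equal length")
        if self.t.size >= 2 and not (np.diff(self.t) > 0).all():
            raise ValidationError("t: must be strictly increasing")
        if ((self.a < 0) | (self.a > 1)).any():
            raise ValidationError("a: area ratios must lie in [0, 1]")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class CycleDetection:
    """Cardiac cycles located on an area-ratio (or velocity) trace."""

    frequency_hz: float
    trough_times: np.ndarray
    trough_indices: np.ndarray

    @property
    def n_cycles(self) -> int:
        return max(len(self.trough_indices) - 1, 0)

    def segments(self) -> list[tuple[int, int]]:
        """(start, stop) index pairs, one per complete cycle (stop inclusive)."""
        idx = self.trough_indices
        return [(int(idx[i]), int(idx[i + 1])) for i in range(len(idx) - 1)]


@dataclass
class PerfusionIndexResult:
    irpi: float
    a_max: float
    a_min: float
    n_cycles: int
    method: str
    per_cycle: list[tuple[float, float, float, float]] = field(default_factory=list)
    """(cycle start time, a_max, a_min, irpi) per detected cycle."""


# ---------------------------------------------------------------------------
# operations


def classify_flow_pixels(frame: np.ndarray, model: FlowColorModel | None = None) -> np.ndarray:
    """Boolean flow mask for one RGB frame (or a (T, H, W, 3) stack).

    Deterministic color gating; see :class:`FlowColorModel`.
    """
    model = model or FlowColorModel()
    frame = np.asarray(frame)
    if frame.ndim not in (3, 4) or frame.shape[-1] != 3:
        raise FormatError(f"expected RGB (..., 3) input, got shape {frame.shape}")
    if not np.isfinite(np.asarray(frame, dtype=float)).all():
        raise FormatError("frame contains non-finite values")
    if frame.dtype == np.uint8:
        rgb = frame.astype(np.float32) / 255.0
    else:
        rgb = np.asarray(frame, dtype=np.float32)
        if rgb.max(initial=0.0) > 1.0:
            rgb = rgb / 255.0
    hsv = rgb2hsv(rgb)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    chroma = rgb.max(axis=-1) - rgb.min(axis=-1)
    if model.hue_lo <= model.hue_hi:
        in_band = (hue >= model.hue_lo) & (hue <= model.hue_hi)
    else:  # band wraps through 0 degrees
        in_band = (hue >= model.hue_lo) | (hue <= model.hue_hi)
    return (
        in_band
        & (sat >= model.min_saturation)
        & (val >= model.min_value)
        & (chroma >= model.chroma_margin)
    )


def area_ratio(flow_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """|flow ∩ roi| / |roi|, exact pixel-count arithmetic."""
    flow_mask = np.asarray(flow_mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if flow_mask.shape != roi_mask.shape:
        raise FormatError(
            f"mask shapes differ: {flow_mask.shape} vs {roi_mask.shape}"
        )
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise DegenerateInputError("ROI mask is empty")
    return int((flow_mask & roi_mask).sum()) / n_roi


def area_ratio_series(
    cine: CineLoop,
    roi: RoiSet,
    model: FlowColorModel | None = None,
    smoothing_window: float = 0.0,
) -> dict[str, AreaRatioSeries]:
    """Per-frame area ratio for every ROI label, with optional smoothing.

    Frames are classified once and the counts reused across ROIs. The
    optional centered moving average has width ``smoothing_window`` seconds
    (default 0 = off); to preserve cycle extrema keep the window below a
    quarter cardiac period.
    """
    if roi.shape != cine.shape:
        raise FormatError(
            f"cine frames {cine.shape} and ROI masks {roi.shape} disagree"
        )
    # classify only the pixels any ROI touches: identical result to a
    # full-frame classification (the gate is per-pixel), much less work
    union = np.zeros(cine.shape, dtype=bool)
    for mask in roi.masks.values():
        union |= mask
    flow_union = classify_flow_pixels(cine.frames[:, union, :], model)  # (T, n)
    t = cine.times
    out: dict[str, AreaRatioSeries] = {}
    for label, mask in roi.masks.items():
        n_roi = int(mask.sum())
        member = mask[union]  # ROI membership among union pixels
        counts = flow_union[:, member].sum(axis=1)
        a = counts / n_roi
        if smoothing_window > 0:
            w = max(int(round(smoothing_window * cine.frame_rate)), 1)
            if w > 1:
                kernel = np.ones(w) / w
                # reflect-pad so the average stays centered at the edges
                pad = w // 2
                ap = np.pad(a, pad, mode="reflect")
                a = np.convolve(ap, kernel, mode="same")[pad : pad + len(t)]
        out[label] = AreaRatioSeries(t=t, a=a, roi_label=label, n_roi_pixels=n_roi)
    return out


DEFAULT_HR_BAND = (250.0, 400.0)  # beats/min; brackets the 300-350 bpm regime


def detect_cycles(
    series: AreaRatioSeries,
    hr_band: tuple[float, float] = DEFAULT_HR_BAND,
) -> CycleDetection:
    """Locate cardiac cycles on a pulsatile trace.

    The dominant frequency is the spectral peak inside ``hr_band`` (beats/min,
    converted to Hz), refined by parabolic interpolation of log-power.
    Cycle boundaries are successive troughs of a lightly smoothed copy of the
    trace, found at least 0.6 periods apart.

    Raises
    ------
    NoPulsatilityError
        If the trace is constant, the band holds no spectral bin, or fewer
        than one complete cycle is found.
    """
    a = np.asarray(series.a, dtype=float)
    fs = series.frame_rate
    f_lo, f_hi = hr_band[0] / 60.0, hr_band[1] / 60.0
    if series.duration < 2.0 / f_lo:
        raise ValidationError(
            "series shorter than 2 cycles at the slow end of hr_band"
        )
    if np.ptp(a) == 0 or np.std(a) < 1e-12:
        raise NoPulsatilityError("trace is constant; no pulsatility to detect")

    x = a - a.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():
        raise NoPulsatilityError("hr_band contains no resolvable frequency bin")
    band_idx = np.flatnonzero(band)
    k = band_idx[np.argmax(power[band_idx])]
    if power[k] <= 0:
        raise NoPulsatilityError("no spectral peak inside hr_band")
    f0 = freqs[k]
    # parabolic refinement on log-power (guarded at spectrum edges)
    if 0 < k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        lp = np.log(power[k - 1 : k + 2])
        denom = lp[0] - 2 * lp[1] + lp[2]
        if denom < 0:
            delta = 0.5 * (lp[0] - lp[2]) / denom
            f0 = freqs[k] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])

    # troughs on a lightly smoothed copy (boundaries only; values stay raw)
    w = max(int(round(fs / (8.0 * f0))), 1)
    smooth = np.convolve(a, np.ones(w) / w, mode="same") if w > 1 else a
    distance = max(int(round(0.6 * fs / f0)), 1)
    troughs, _ = signal.find_peaks(-smooth, distance=distance)
    if len(troughs) < 2:
        raise NoPulsatilityError("fewer than one complete cycle detected")
    return CycleDetection(
        frequency_hz=float(f0),
        trough_times=series.t[troughs],
        trough_indices=np.asarray(troughs),
    )


def compute_irpi(
    series: AreaRatioSeries,
    method: str = "per_cycle_median",
    hr_band: tuple[float, float] = DEFAULT_HR_BAND,
) -> PerfusionIndexResult:
    """IRPI = (a_max - a_min) / a_max from an area-ratio trace.

    method="per_cycle_median" (default): the index is computed within each
    detected cardiac cycle and the median across cycles is reported, with
    a_max/a_min taken from the cycle closest to the median — robust to
    single-frame dropout spikes. method="global": extrema over the whole
    trace, the literal reading of the definition.
    """
    a = np.asarray(series.a, dtype=float)
    if method == "global":
        a_max, a_min = float(a.max()), float(a.min())
        if a_max == 0:
            raise DegenerateInputError("a_max = 0: perfusion index undefined")
        return PerfusionIndexResult(
            irpi=(a_max - a_min) / a_max,
            a_max=a_max,
            a_min=a_min,
            n_cycles=1,
            method="global",
        )
    if method != "per_cycle_median":
        raise ValidationError(f"method: unknown '{method}'")

    cycles = detect_cycles(series, hr_band)
    per_cycle: list[tuple[float, float, float, float]] = []
    for i0, i1 in cycles.segments():
        seg = a[i0 : i1 + 1]
        s_max, s_min = float(seg.max()), float(seg.min())
        if s_max == 0:
            continue
        per_cycle.append(
            (float(series.t[i0]), s_max, s_min, (s_max - s_min) / s_max)
        )
    if not per_cycle:
        raise DegenerateInputError("a_max = 0 in every cycle: index undefined")
    vals = np.array([c[3] for c in per_cycle])
    med = float(np.median(vals))
    rep = per_cycle[int(np.argmin(np.abs(vals - med)))]
    return PerfusionIndexResult(
        irpi=med,
        a_max=rep[1],
        a_min=rep[2],
        n_cycles=len(per_cycle),
        method="per_cycle_median",
        per_cycle=per_cycle,
    )
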