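"""Synthetic SMI cine loops with planted, known pulsatility.

The generator plants the exact signal structure the analysis pipeline
measures: inside each vessel mask, every pixel is independently a flow
pixel in frame i with probability

    p(t_i) = p0 * (1 + m * w(t_i)),      w(t) = cos(2*pi*HR/60*t + phase)

where p0 is the base occupancy and m the cardiac modulation depth. w is a
raised cosine normalized to [-1, +1] with zero mean, so the time-average
occupancy equals p0 and the true perfusion index has the closed form

    IRPI = (p_max - p_min) / p_max = 2 m / (1 + m).

Flow pixels are painted in the red-orange SMI overlay hue; everything else
is achromatic speckle, which the color gate in :mod:`renalsmi.smi` rejects.
Speckle amplitude, flow-pixel dropout, and background texture scale are
artifact controls; spatial correlation of occupancy is deliberately absent
(binomial thinning per pixel per frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import line
from skimage.morphology import disk

from ..errors import ValidationError
from ..smi import CineLoop, RoiSet

# Reference overlay color (red-orange, hue ~ 15 deg) and background gray.
OVERLAY_RGB = np.array([232.0, 92.0, 38.0])
BACKGROUND_GRAY = 90.0


@dataclass(frozen=True)
class VesselSpec:
    """One straight or polyline vessel segment with planted pulsatility."""

    vessel_class: str  # "interlobular" | "interlobar"
    path: tuple[tuple[int, int], ...]  # polyline vertices, (row, col)
    width: int  # full width in pixels
    p0: float  # base flow-pixel occupancy, (0, 1]
    m: float  # modulation depth, [0, 1)
    phase: float = 0.0  # cardiac waveform phase offset, radians

    def __post_init__(self):
        if self.vessel_class not in ("interlobular", "interlobar"):
            raise ValidationError(
                f"vessel_class: must be interlobular|interlobar, got "
                f"'{self.vessel_class}'"
            )
        if not (0.0 < self.p0 <= 1.0):
            raise ValidationError(f"p0: must be in (0, 1], got {self.p0}")
        if not (0.0 <= self.m < 1.0):
            raise ValidationError(f"m: must be in [0, 1), got {self.m}")
        if self.p0 * (1.0 + self.m) > 1.0 + 1e-12:
            raise ValidationError(
                f"p0*(1+m) = {self.p0 * (1 + self.m):.3f} exceeds 1"
            )
        if self.width < 1:
            raise ValidationError(f"width: must be >= 1, got {self.width}")
        if len(self.path) < 2:
            raise ValidationError("path: needs at least 2 vertices")

    @property
    def true_irpi(self) -> float:
        """Closed-form planted index, 2m/(1+m)."""
        return 2.0 * self.m / (1.0 + self.m)


@dataclass(frozen=True)
class NoiseSpec:
    speckle_sigma: float = 0.10  # multiplicative SD on background gray
    dropout_rate: float = 0.05  # fraction of flow pixels suppressed per frame
    background_texture_scale: float = 4.0  # Gaussian field scale, pixels

    def __post_init__(self):
        for name in ("speckle_sigma", "dropout_rate", "background_texture_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be >= 0")
        if self.dropout_rate >= 1:
            raise ValidationError(f"dropout_rate: must be < 1, got {self.dropout_rate}")

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(speckle_sigma=0.0, dropout_rate=0.0, background_texture_scale=0.0)


def default_vessels(
    height: int = 128,
    width: int = 128,
    m_interlobular: float = 0.30,
    m_interlobar: float = 0.10,
) -> tuple[VesselSpec, VesselSpec]:
    """Two non-overlapping default vessels (~2000 px each at 128x128).

    The thin diagonal segment models an interlobular artery/vein pair in the
    cortex; the wider straight segment an interlobar pair near the medulla.
    Modulation defaults reflect the higher pulsatility observed in the
    interlobular class.
    """
    h, w = height, width
    interlobular = VesselSpec(
        vessel_class="interlobular",
        path=((int(0.08 * h), int(0.10 * w)), (int(0.55 * h), int(0.92 * w))),
        width=max(int(round(0.09 * min(h, w))), 3),
        p0=0.50,
        m=m_interlobular,
        phase=0.0,
    )
    interlobar = VesselSpec(
        vessel_class="interlobar",
        path=((int(0.88 * h), int(0.08 * w)), (int(0.75 * h), int(0.94 * w))),
        width=max(int(round(0.12 * min(h, w))), 4),
        p0=0.60,
        m=m_interlobar,
        phase=0.6,
    )
    return interlobular, interlobar


@dataclass(frozen=True)
class CineSpec:
    """Synthetic cine-loop study conditions.

    Defaults mirror the imaging regime of the rat experiments: heart rate
    330 beats/min (anesthesia titrated to 300-350), a frame rate giving
    >= 10 frames per cardiac cycle, and a clip long enough for >= 3 cycles.
    """

    height: int = 128
    width: int = 128
    frame_rate: float = 120.0
    duration: float = 4.0
    heart_rate: float = 330.0
    vessels: tuple[VesselSpec, ...] = field(default_factory=default_vessels)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("height/width: must be > 0")
        f_heart = self.heart_rate / 60.0
        if self.frame_rate < 10.0 * f_heart:
            raise ValidationError(
                f"frame_rate: {self.frame_rate} Hz gives fewer than 10 frames "
                f"per cardiac cycle at heart_rate {self.heart_rate}"
            )
        if self.duration * f_heart < 3.0:
            raise ValidationError(
                f"duration: {self.duration} s covers fewer than 3 cardiac "
                f"cycles at heart_rate {self.heart_rate}"
            )
        if not self.vessels:
            raise ValidationError("vessels: at least one VesselSpec required")


@dataclass
class CineGroundTruth:
    """Everything the generator planted, for downstream validation."""

    vessel_specs: tuple[VesselSpec, ...]
    vessel_masks: list[np.ndarray]  # (H, W) bool per vessel
    occupancy: list[np.ndarray]  # planted p(t) per vessel, (T,)
    true_irpi: list[float]  # 2m/(1+m) per vessel
    flow_masks: np.ndarray  # (T, H, W) bool, painted flow pixels
    t: np.ndarray

    def roi_set(self) -> RoiSet:
        """ROI masks for the three canonical classes (exact vessel masks)."""
        shape = self.flow_masks.shape[1:]
        masks: dict[str, np.ndarray] = {}
        for label in ("interlobular", "interlobar"):
            m = np.zeros(shape, dtype=bool)
            for spec, vm in zip(self.vessel_specs, self.vessel_masks):
                if spec.vessel_class == label:
                    m |= vm
            if m.any():
                masks[label] = m
        union = np.zeros(shape, dtype=bool)
        for vm in self.vessel_masks:
            union |= vm
        masks["combined"] = union
        return RoiSet(masks=masks, provenance="generator")


def rasterize_vessel(spec: VesselSpec, height: int, width: int) -> np.ndarray:
    """Boolean mask of the vessel: polyline dilated to the requested width."""
    mask = np.zeros((height, width), dtype=bool)
    for (r0, c0), (r1, c1) in zip(spec.path[:-1], spec.path[1:]):
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
        mask[rr[keep], cc[keep]] = True
    radius = max(int(round((spec.width - 1) / 2)), 0)
    if radius:
        mask = binary_dilation(mask, structure=disk(radius))
    return mask


def cardiac_waveform(t: np.ndarray, heart_rate: float, phase: float = 0.0) -> np.ndarray:
    """Raised-cosine cardiac waveform, zero mean, min -1 / max +1."""
    return np.cos(2.0 * np.pi * (heart_rate / 60.0) * t + phase)


def generate_cine(spec: CineSpec) -> tuple[CineLoop, CineGroundTruth]:
    """Render a seeded synthetic SMI cine loop plus its ground truth.

    Identical spec (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    T = int(round(spec.duration * spec.frame_rate))
    H, W = spec.height, spec.width
    t = np.arange(T) / spec.frame_rate

    # static background texture, per-frame multiplicative speckle
    tex = np.full((H, W), BACKGROUND_GRAY)
    if spec.noise.background_texture_scale > 0:
        fielda = gaussian_filter(
            rng.standard_normal((H, W)), spec.noise.background_texture_scale
        )
        sd = fielda.std()
        if sd > 0:
            tex = tex * (1.0 + 0.25 * fielda / sd)
    gray = np.broadcast_to(tex, (T, H, W)).copy()
    if spec.noise.speckle_sigma > 0:
        gray *= 1.0 + spec.noise.speckle_sigma * rng.standard_normal((T, H, W))
    gray = np.clip(gray, 0.0, 200.0)

    frames = np.repeat(gray[..., None], 3, axis=-1)

    vessel_masks: list[np.ndarray] = []
    occupancy: list[np.ndarray] = []
    flow_masks = np.zeros((T, H, W), dtype=bool)
    for vessel in spec.vessels:
        vmask = rasterize_vessel(vessel, H, W)
        if not vmask.any():
            raise ValidationError(
                f"vessel path {vessel.path}: rasterizes to an empty mask"
            )
        p_t = vessel.p0 * (
            1.0 + vessel.m * cardiac_waveform(t, spec.heart_rate, vessel.phase)
        )
        n_pix = int(vmask.sum())
        draws = rng.random((T, n_pix)) < p_t[:, None]
        if spec.noise.dropout_rate > 0:
            draws &= rng.random((T, n_pix)) >= spec.noise.dropout_rate
        flow_masks[:, vmask] |= draws
        vessel_masks.append(vmask)
        occupancy.append(p_t)

    # paint flow pixels: overlay color with joint-channel brightness jitter
    # (scaling all channels together preserves hue and saturation exactly)
    n_flow = int(flow_masks.sum())
    if n_flow:
        scale = np.clip(1.0 + 0.12 * rng.standard_normal(n_flow), 0.55, 1.1)
        frames[flow_masks] = OVERLAY_RGB * scale[:, None]

    loop = CineLoop(
        frames=np.clip(frames, 0, 255).astype(np.uint8),
        frame_rate=spec.frame_rate,
    )
    truth = CineGroundTruth(
        vessel_specs=tuple(spec.vessels),
        vessel_masks=vessel_masks,
        occupancy=occupancy,
        true_irpi=[v.true_irpi for v in spec.vessels],
        flow_masks=flow_masks,
        t=t,
    )
    return loop, truth
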