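"""Interstitial edema area fraction from trichrome-stained sections.

Masson's trichrome renders renal parenchyma red and edematous/collagenous
interstitium light blue. Pixels are assigned to {background, parenchyma,
edema} by hue/saturation/value gates (no stain deconvolution; the gates
mirror how thresholding-based slide analysis is done in practice), and the
edema fraction is the exact pixel-count ratio

    edema_fraction = edema / (edema + parenchyma)

i.e. background and lumen are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .errors import DegenerateInputError, FormatError, ValidationError

CLASS_NAMES = ("background", "parenchyma", "edema")


def _hue_in_band(hue_deg: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if lo <= hi:
        return (hue_deg >= lo) & (hue_deg <= hi)
    return (hue_deg >= lo) | (hue_deg <= hi)


def _hue_dist(hue_deg: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(hue_deg - center) % 360.0
    return np.minimum(d, 360.0 - d)


@dataclass(frozen=True)
class StainColorReference:
    """Color gates for the three stain classes.

    Red (parenchyma) and blue (edema) hue bands must not overlap; pixels
    matching neither gate are resolved to the nearer of the two hue centers
    so that every pixel gets exactly one class.
    """

    red_hue_lo: float = 320.0
    red_hue_hi: float = 25.0
    blue_hue_lo: float = 160.0
    blue_hue_hi: float = 260.0
    min_saturation: float = 0.12
    background_min_value: float = 0.88
    background_max_saturation: float = 0.10

    def __post_init__(self):
        # disjointness of the two hue bands (red wraps through 0)
        grid = np.arange(0.0, 360.0, 0.5)
        red = _hue_in_band(grid, self.red_hue_lo, self.red_hue_hi)
        blue = _hue_in_band(grid, self.blue_hue_lo, self.blue_hue_hi)
        if (red & blue).any():
            raise ValidationError("red and blue hue gates overlap")

    @property
    def red_center(self) -> float:
        lo, hi = self.red_hue_lo, self.red_hue_hi
        span = (hi - lo) % 360.0
        return (lo + span / 2.0) % 360.0

    @property
    def blue_center(self) -> float:
        return 0.5 * (self.blue_hue_lo + self.blue_hue_hi)


@dataclass
class EdemaResult:
    edema_fraction: float
    n_edema: int
    n_parenchyma: int
    n_background: int
    tissue_area: int


def segment_stain_classes(
    image: np.ndarray, ref: StainColorReference | None = None
) -> dict[str, np.ndarray]:
    """Deterministic per-pixel classification into the three stain classes."""
    ref = ref or StainColorReference()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise FormatError(f"expected RGB (H, W, 3) image, got {image.shape}")
    rgb = image.astype(np.float32) / 255.0 if image.dtype == np.uint8 else np.asarray(
        image, dtype=np.float32
    )
    if rgb.max(initial=0.0) > 1.0:
        rgb = rgb / 255.0
    hsv = rgb2hsv(rgb)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]

    background = (val >= ref.background_min_value) & (
        sat <= ref.background_max_saturation
    )
    stained = ~background & (sat >= ref.min_saturation)
    red = stained & _hue_in_band(hue, ref.red_hue_lo, ref.red_hue_hi)
    blue = stained & _hue_in_band(hue, ref.blue_hue_lo, ref.blue_hue_hi)
    # leftover pixels (dim or off-band): nearest stain hue center; very dark
    # desaturated pixels count as background
    rest = ~(background | red | blue)
    faint = rest & (sat < ref.min_saturation / 2.0)
    background = background | faint
    rest = rest & ~faint
    to_red = rest & (
        _hue_dist(hue, ref.red_center) <= _hue_dist(hue, ref.blue_center)
    )
    red = red | to_red
    blue = blue | (rest & ~to_red)
    return {"background": background, "parenchyma": red, "edema": blue}


def edema_fraction(masks: dict[str, np.ndarray]) -> EdemaResult:
    """Exact pixel-count edema area ratio over tissue (parenchyma + edema)."""
    for name in CLASS_NAMES:
        if name not in masks:
            raise ValidationError(f"masks: missing class '{name}'")
    n_e = int(np.asarray(masks["edema"], dtype=bool).sum())
    n_p = int(np.asarray(masks["parenchyma"], dtype=bool).sum())
    n_b = int(np.asarray(masks["background"], dtype=bool).sum())
    tissue = n_e + n_p
    if tissue == 0:
        raise DegenerateInputError("zero tissue area: fraction undefined")
    return EdemaResult(
        edema_fraction=n_e / tissue,
        n_edema=n_e,
        n_parenchyma=n_p,
        n_background=n_b,
        tissue_area=tissue,
    )
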