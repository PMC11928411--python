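"""Synthetic trichrome histology fields with a known edema fraction.

A smooth Gaussian random field thresholded at a quantile carves a
parenchyma region out of a white background; a second, finer field carves
edema blobs covering a requested fraction of the parenchyma. The realized
fraction is recorded exactly from the painted masks, so downstream
segmentation can be scored against pixel-level truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import ValidationError

# reference stain colors (uint8 RGB)
PARENCHYMA_RGB = np.array([178.0, 58.0, 74.0])  # trichrome red
EDEMA_RGB = np.array([168.0, 205.0, 232.0])  # light blue
BACKGROUND_RGB = np.array([246.0, 246.0, 248.0])  # slide white


@dataclass
class HistologyGroundTruth:
    parenchyma_mask: np.ndarray
    edema_mask: np.ndarray
    realized_fraction: float  # edema / (edema + parenchyma), exact


def _blob_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    fraction: float,
    scale: float,
    within: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold a smoothed noise field so `fraction` of `within` is covered."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    fielda = gaussian_filter(rng.standard_normal(shape), scale)
    if within is None:
        within = np.ones(shape, dtype=bool)
    vals = fielda[within]
    if fraction >= 1:
        thr = -np.inf
    else:
        thr = np.quantile(vals, 1.0 - fraction)
    return within & (fielda >= thr)


def generate_histology(
    field_size: tuple[int, int] = (256, 256),
    parenchyma_fraction: float = 0.85,
    edema_fraction: float = 0.158,
    blob_scale: float = 10.0,
    seed: int = 0,
    color_jitter: float = 0.04,
) -> tuple[np.ndarray, HistologyGroundTruth]:
    """Seeded RGB histology field plus exact painted-mask ground truth.

    ``edema_fraction`` is the requested share of tissue painted light blue;
    the realized share (exact pixel counts of the painted masks) is
    returned, and differs from the request only by quantile-tie rounding.
    Color jitter scales all three channels jointly, preserving hue.
    """
    if not (0.0 <= edema_fraction <= 1.0):
        raise ValidationError(
            f"edema_fraction: must be in [0, 1], got {edema_fraction}"
        )
    if not (0.0 < parenchyma_fraction <= 1.0):
        raise ValidationError(
            f"parenchyma_fraction: must be in (0, 1], got {parenchyma_fraction}"
        )
    if blob_scale <= 0:
        raise ValidationError(f"blob_scale: must be > 0, got {blob_scale}")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in field_size)
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValidationError(f"field_size: must be positive, got {field_size}")

    tissue = _blob_mask(rng, shape, parenchyma_fraction, 3.0 * blob_scale)
    edema = _blob_mask(rng, shape, edema_fraction, blob_scale, within=tissue)
    parenchyma = tissue & ~edema

    image = np.empty((*shape, 3), dtype=float)
    image[:] = BACKGROUND_RGB
    for mask, color in ((parenchyma, PARENCHYMA_RGB), (edema, EDEMA_RGB)):
        n = int(mask.sum())
        if n:
            scale = np.clip(
                1.0 + color_jitter * rng.standard_normal(n), 0.7, 1.08
            )
            image[mask] = color * scale[:, None]
    image = np.clip(image, 0, 255).astype(np.uint8)

    n_e, n_p = int(edema.sum()), int(parenchyma.sum())
    realized = n_e / (n_e + n_p) if (n_e + n_p) else 0.0
    return image, HistologyGroundTruth(
        parenchyma_mask=parenchyma, edema_mask=edema, realized_fraction=realized
    )
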