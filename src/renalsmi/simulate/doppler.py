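"""Synthetic renal Doppler velocity traces with planted indices.

Four waveform kinds:

arterial            periodic systolic peak Vs with end-diastolic trough Ved;
                    planted RI = (Vs - Ved)/Vs.
venous_continuous   mean velocity V with a small ripple (< 15 % of V);
                    planted VII = 2r/(1+r) for ripple fraction r.
venous_biphasic     two descents per cardiac cycle, nonzero minimum.
venous_monophasic   one descent per cycle reaching <= 5 % of the peak.

All venous kinds record the planted VII = (Vmax - Vmin)/Vmax and the
pattern label used by the classifier tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError
from ..hemodynamics import VelocityTrace

TRACE_KINDS = (
    "arterial",
    "venous_continuous",
    "venous_biphasic",
    "venous_monophasic",
)


@dataclass(frozen=True)
class TraceSpec:
    """Shared sampling conditions for synthetic velocity traces."""

    heart_rate: float = 330.0  # beats/min
    duration: float = 3.0  # s
    sample_rate: float = 500.0  # Hz
    noise_sigma: float = 0.02  # multiplicative velocity noise SD
    phase: float = 0.0

    def __post_init__(self):
        if self.heart_rate <= 0 or self.duration <= 0 or self.sample_rate <= 0:
            raise ValidationError("heart_rate/duration/sample_rate: must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma: must be >= 0")


@dataclass
class TraceGroundTruth:
    kind: str
    ri: float | None
    vii: float | None
    pattern: str | None  # venous pattern label, None for arterial


def generate_velocity_trace(
    kind: str,
    peak: float = 100.0,
    trough: float = 39.0,
    spec: TraceSpec | None = None,
    seed: int = 0,
) -> tuple[VelocityTrace, TraceGroundTruth]:
    """Seeded synthetic velocity trace plus planted index/pattern.

    ``peak``/``trough`` are Vs/Ved (arterial) or Vmax/Vmin (venous), mm/s.
    For venous_continuous the ripple fraction is inferred from
    trough = V*(1-r)/(1+r) relative to peak = V*(1+r)... simpler: peak and
    trough are taken literally as the extremes of the ripple.
    """
    spec = spec or TraceSpec()
    if kind not in TRACE_KINDS:
        raise ValidationError(f"kind: must be one of {TRACE_KINDS}, got '{kind}'")
    if peak <= 0:
        raise ValidationError(f"peak: must be > 0, got {peak}")
    if trough < 0:
        raise ValidationError(f"trough: must be >= 0, got {trough}")
    if trough > peak:
        raise ValidationError("trough: must not exceed peak")

    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    phi = ((spec.heart_rate / 60.0) * t + spec.phase / (2 * np.pi)) % 1.0

    ri = vii = None
    pattern = None
    if kind == "arterial":
        # sharp systolic bump, cycle starts/ends at the end-diastolic trough
        v = trough + (peak - trough) * np.sin(np.pi * phi) ** 3
        ri = (peak - trough) / peak
    elif kind == "venous_continuous":
        mid = 0.5 * (peak + trough)
        ripple = 0.5 * (peak - trough)
        if mid <= 0 or ripple >= 0.15 * mid:
            raise ValidationError(
                "venous_continuous: ripple must stay below 15% of the mean"
            )
        v = mid + ripple * np.sin(2 * np.pi * phi)
        vii = (peak - trough) / peak
        pattern = "continuous"
    elif kind == "venous_biphasic":
        if trough <= 0:
            raise ValidationError("venous_biphasic: minimum must be nonzero")
        v = trough + (peak - trough) * (0.5 - 0.5 * np.cos(4 * np.pi * phi))
        vii = (peak - trough) / peak
        pattern = "biphasic"
    else:  # venous_monophasic
        floor = min(trough, 0.05 * peak)
        v = floor + (peak - floor) * (0.5 - 0.5 * np.cos(2 * np.pi * phi)) ** 2
        vii = (peak - floor) / peak
        pattern = "monophasic"

    if spec.noise_sigma > 0:
        v = v * (1.0 + spec.noise_sigma * rng.standard_normal(n))
    v = np.clip(v, 0.0, None)
    vessel_kind = "artery" if kind == "arterial" else "vein"
    return (
        VelocityTrace(t=t, v=v, vessel_kind=vessel_kind),
        TraceGroundTruth(kind=kind, ri=ri, vii=vii, pattern=pattern),
    )
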