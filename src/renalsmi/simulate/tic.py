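"""Synthetic CEUS time-intensity curves with a planted time-to-peak.

The bolus is the peak-normalized gamma-variate

    I(t) = baseline                                          t <= t0
    I(t) = baseline + A * ((t-t0)/(alpha*beta))^alpha
                        * exp(alpha - (t-t0)/beta)           t >  t0

whose maximum (value A above baseline) falls at t = t0 + alpha*beta, so the
true time-to-peak is exactly alpha*beta. Gaussian dB-domain noise is added
on top; the generator records t0 and TTP as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ceus import TimeIntensityCurve, gamma_variate
from ..errors import ValidationError


@dataclass(frozen=True)
class TicSpec:
    """Bolus-curve study conditions. Defaults give a 3 s TTP at 30 Hz."""

    t0: float = 1.0  # onset, s
    alpha: float = 2.0  # shape, dimensionless
    beta: float = 1.5  # scale, s
    amplitude: float = 20.0  # peak enhancement above baseline, dB
    baseline: float = 10.0  # pre-bolus intensity, dB
    noise_sigma: float = 0.3  # additive Gaussian noise, dB
    frame_rate: float = 30.0  # Hz
    duration: float = 10.0  # s
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha", "beta", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name}: must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma: must be >= 0")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate: must be > 0")
        if self.duration <= self.t0 + self.alpha * self.beta:
            raise ValidationError(
                f"duration: {self.duration} s must exceed t0 + alpha*beta = "
                f"{self.t0 + self.alpha * self.beta} s"
            )

    @property
    def true_ttp(self) -> float:
        return self.alpha * self.beta


@dataclass
class TicGroundTruth:
    t0: float
    ttp: float
    clean: np.ndarray  # noise-free curve


def generate_tic(spec: TicSpec) -> tuple[TimeIntensityCurve, TicGroundTruth]:
    """Seeded noisy gamma-variate curve plus planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n) / spec.frame_rate
    clean = gamma_variate(
        t, spec.t0, spec.alpha, spec.beta, spec.amplitude, spec.baseline
    )
    intensity = clean.copy()
    if spec.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sigma, n)
    return (
        TimeIntensityCurve(t=t, intensity=intensity),
        TicGroundTruth(t0=spec.t0, ttp=spec.true_ttp, clean=clean),
    )
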