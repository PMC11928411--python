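import numpy as np
import pytest

from renalsmi.simulate import (
    CineSpec,
    NoiseSpec,
    VesselSpec,
    default_vessels,
    generate_cine,
)


def small_cine_spec(m: float = 0.3, seed: int = 0, noise_off: bool = True) -> CineSpec:
    """A fast 64x64, 1 s cine with a single ~1000 px interlobular vessel."""
    vessel = VesselSpec(
        vessel_class="interlobular",
        path=((6, 6), (36, 58)),
        width=9,
        p0=0.5,
        m=m,
    )
    return CineSpec(
        height=64,
        width=64,
        frame_rate=120.0,
        duration=1.0,
        heart_rate=330.0,
        vessels=(vessel,),
        noise=NoiseSpec.off() if noise_off else NoiseSpec(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_cine():
    """Noise-free default-geometry cine (128x128, 4 s) plus ground truth."""
    spec = CineSpec(noise=NoiseSpec.off(), seed=7)
    return generate_cine(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
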