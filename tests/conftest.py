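import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import uvcentre as uc

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_frame(
    pixels: np.ndarray,
    *,
    pixel_size_um: float = 1.0,
    illumination: str = "visible",
    omega_deg: float = 0.0,
) -> uc.Frame:
    """Wrap a raw array as a Frame for unit tests."""
    return uc.Frame(
        pixels=np.asarray(pixels, float),
        pixel_size_um=pixel_size_um,
        illumination=illumination,
        omega_deg=omega_deg,
    )


NOISELESS = uc.NoiseModel(shot_scale=0.0, read_sigma=0.0)


@pytest.fixture
def noiseless_spec() -> uc.SceneSpec:
    """Default nylon-loop scene with a crystal offset and no camera noise."""
    return uc.SceneSpec(
        crystal_offset_um=(20.0, -15.0, 10.0),
        loop_offset_um=(5.0, -8.0, 12.0),
        noise=NOISELESS,
    )


def acceptance_scene(i: int, *, noisy: bool, pixel_size_um: float = 3.0) -> uc.SceneSpec:
    """The seeded random scene family used for the large end-to-end suites:
    160x160 px at 3 um/px, crystal offsets within +-30 um of the rotation
    axis, loop offsets within +-10 um, shapes cycling through the three
    crystal families. ``noisy`` selects read noise putting the UV crystal at
    SNR 5 (vs the noiseless limit)."""
    rng = np.random.default_rng(10_000 + i)
    noise = uc.NoiseModel(shot_scale=0.008, read_sigma=0.1386) if noisy else NOISELESS
    return uc.SceneSpec(
        crystal_shape=("box", "hexagon", "ellipse")[i % 3],
        crystal_offset_um=tuple(rng.uniform(-30, 30, 3)),
        loop_offset_um=tuple(rng.uniform(-10, 10, 3)),
        pixel_size_um=pixel_size_um,
        frame_shape_px=(160, 160),
        noise=noise,
        seed=i,
    )
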