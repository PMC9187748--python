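import numpy as np
import pytest

from dffoct.params import AcquisitionParams
from dffoct.profiler import RoiPolygon, ScratchLine
from dffoct.simulate import WoundSimConfig, simulate_wound_timelapse


def tilted_line(size: int, angle_deg: float) -> ScratchLine:
    """Scratch line through the image centre, tilted from vertical."""
    c0 = (size - 1) / 2.0
    dt = np.tan(np.deg2rad(angle_deg)) * c0
    return ScratchLine((0.0, c0 - dt), (float(size - 1), c0 + dt))


def centred_roi(size: int, half_width_px: float) -> RoiPolygon:
    c0 = (size - 1) / 2.0
    lo, hi = c0 - half_width_px, c0 + half_width_px
    return RoiPolygon(
        [(2.0, lo), (2.0, hi), (float(size - 10), hi), (float(size - 10), lo)]
    )


def closing_config(total_speed: float, noise_sigma: float, **overrides) -> WoundSimConfig:
    """Standard symmetric closing scenario used across the recovery tests.

    1 um/px sampling and a 3-degree tilt: the tilt staggers row widths so the
    measured mean width varies sub-pixel-smoothly, as in real scratches.
    """
    kwargs = dict(
        image_size=256,
        pixel_size=1.0,
        n_frames=60,
        initial_width=25.0,
        closing_limit=1.5,
        border_speeds=(total_speed / 2, total_speed / 2),
        noise_sigma=noise_sigma,
        texture_seed=3,
        wound_angle=3.0,
    )
    kwargs.update(overrides)
    return WoundSimConfig(**kwargs)


@pytest.fixture(scope="session")
def closing_stack_8():
    """Closing wound at 8 um/h total, 5% noise (shared: expensive to render)."""
    cfg = closing_config(8.0, 0.05)
    stack, truth = simulate_wound_timelapse(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def acquisition_1um():
    return AcquisitionParams(pixel_size=1.0, timelapse_interval=1.0)
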