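"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators are provided:

* :func:`simulate_wound_timelapse` renders a textured epithelial sheet (a
  seeded Voronoi mosaic with dark inter-cell borders and speckle, emulating a
  granular RPE monolayer) cut by a dark scratch whose two borders move with
  configurable kinetics — constant speed (um/h) or exponential decay toward
  the closing limit, an attempted closure followed by retraction, or steady
  expansion.  The cell sheets on either side translate rigidly with their
  border so that optical flow sees the same motion the segmentation does.
  Analytic border positions, widths and pixel-exact wound masks are recorded
  as ground truth.

* :func:`simulate_dynamic_burst` synthesises raw bursts whose per-pixel
  temporal signals have controlled centre frequency, bandwidth and amplitude
  (band-pass-filtered Gaussian noise, or a pure random-phase tone when the
  bandwidth is zero), the spectral ground truth for the dynamic-profile
  renderer.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, shift as nd_shift
from scipy.spatial import cKDTree

from .dynamics import RawBurst
from .errors import InvalidParameterError
from .params import AcquisitionParams, DEFAULT_PIXEL_SIZE_UM

_SCENARIOS = ("close", "attempt_then_retract", "expand")

#: Named geometries mirroring the observed wound regimes: small scratches
#: (< 25 um) close, medium ones (25-100 um) attempt to close then retract,
#: large ones (> 100 um) keep expanding.
PRESETS = {
    "small-close": dict(initial_width=15.0, scenario="close"),
    "medium-retract": dict(
        initial_width=60.0, scenario="attempt_then_retract",
        retract_onset=30.0, pixel_size=1.0,
    ),
    "large-expand": dict(initial_width=120.0, scenario="expand", pixel_size=1.0),
}


@dataclass
class WoundSimConfig:
    """Scratch time-lapse scenario.

    Border kinetics are set by exactly one of ``border_speeds`` (um/h per
    border, constant motion until the closing limit is reached) or
    ``border_rates`` (1/min, each half-width decaying exponentially toward
    closing_limit/2).  ``wound_angle`` tilts the scratch away from vertical
    (degrees).  ``noise_sigma`` is additive Gaussian noise as a fraction of
    the unit dynamic range.
    """

    image_size: int = 256
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 1.0  # min
    n_frames: int = 60
    initial_width: float = 15.0  # um
    closing_limit: float = 1.5  # um
    border_speeds: tuple[float, float] | None = (8.0, 8.0)  # um/h
    border_rates: tuple[float, float] | None = None  # 1/min
    scenario: str = "close"
    retract_onset: float = 30.0  # min
    texture_seed: int = 0
    noise_sigma: float = 0.05
    wound_angle: float = 0.0  # deg from vertical
    wound_level: float = 0.05  # intensity inside the wound

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise InvalidParameterError(
                f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}"
            )
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        if not self.initial_width > self.closing_limit >= 0:
            raise InvalidParameterError(
                "need initial_width > closing_limit >= 0 "
                f"(got {self.initial_width}, {self.closing_limit})"
            )
        if (self.border_speeds is None) == (self.border_rates is None):
            raise InvalidParameterError(
                "exactly one of border_speeds (um/h) or border_rates (1/min) "
                "must be given"
            )
        if self.image_size < 64:
            raise InvalidParameterError("image_size must be >= 64")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")


@dataclass
class SimTruth:
    """Analytic ground truth accompanying a simulated stack."""

    masks: np.ndarray  # (T, H, W) bool, pre-noise wound masks
    times: np.ndarray  # minutes
    width_um: np.ndarray  # analytic mean width per frame
    area_um2: np.ndarray  # pixel-count area of the truth masks, um^2
    border_left_um: np.ndarray  # half-width left of the axis
    border_right_um: np.ndarray
    closure_speed_um_h: float  # total closing speed (see generator docs)
    spectral_regions: list = field(default_factory=list)


def make_cell_texture(size: int, seed: int, psf_sigma: float = 1.0) -> np.ndarray:
    """Seeded Voronoi cell mosaic with dark borders and speckle, in [0, 1].

    ``psf_sigma`` is a Gaussian blur (px) emulating the diffraction-limited
    point-spread function; it keeps the texture band-limited so sub-pixel
    sheet translation is well defined.  Inter-cell borders stay distinctly
    darker than cell interiors but well above the signal-free scratch level.
    """
    if size < 64:
        raise InvalidParameterError("size must be >= 64")
    rng = np.random.default_rng(seed)
    n_cells = max(9, (size // 16) ** 2)
    pts = rng.uniform(0, size, size=(n_cells, 2))
    rr, cc = np.mgrid[0:size, 0:size]
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = cKDTree(pts).query(coords, k=2)
    cell_id = idx[:, 0].reshape(size, size)
    border = (dist[:, 1] - dist[:, 0]).reshape(size, size) < 2.0
    brightness = rng.uniform(0.5, 0.85, size=n_cells)
    tex = brightness[cell_id]
    tex[border] *= 0.35
    tex += gaussian_filter(rng.normal(0.0, 1.0, size=(size, size)), 1.0) * 0.06
    if psf_sigma > 0:
        tex = gaussian_filter(tex, psf_sigma)
    return np.clip(tex, 0.02, 1.0)


def _half_widths(cfg: WoundSimConfig, times: np.ndarray):
    """Analytic per-border half-widths (um from the wound axis) vs time (min)."""
    w0 = cfg.initial_width / 2.0
    floor = cfg.closing_limit / 2.0
    halves = []
    if cfg.border_speeds is not None:
        speeds = [abs(s) / 60.0 for s in cfg.border_speeds]  # um/min per border
    else:
        rates = [abs(r) for r in cfg.border_rates]
        # equivalent initial speed of an exponential border, for retraction
        speeds = [r * (w0 - floor) for r in rates]
    for i in (0, 1):
        if cfg.scenario == "expand":
            h = w0 + speeds[i] * times
        else:
            if cfg.border_speeds is not None:
                h = np.maximum(floor, w0 - speeds[i] * times)
            else:
                h = floor + (w0 - floor) * np.exp(-abs(cfg.border_rates[i]) * times)
            if cfg.scenario == "attempt_then_retract":
                onset = cfg.retract_onset
                h_onset = np.interp(onset, times, h) if times[-1] >= onset else h[-1]
                late = times > onset
                h = h.copy()
                h[late] = h_onset + speeds[i] * (times[late] - onset)
        halves.append(h)
    return halves[0], halves[1]


def simulate_wound_timelapse(cfg: WoundSimConfig):
    """Render a scratch time-lapse; returns ``(stack, truth)``.

    The stack is float32 in [0, 1], one frame per ``frame_interval`` minutes.
    ``truth.closure_speed_um_h`` is the total closing speed: the sum of the
    configured border speeds in constant-speed mode, or the realised mean
    shrinkage rate (w(0) - w(T)) / T over the acquisition in exponential mode.
    """
    n, size = cfg.n_frames, cfg.image_size
    px = cfg.pixel_size
    times = np.arange(n, dtype=float) * cfg.frame_interval
    w_left, w_right = _half_widths(cfg, times)

    theta = np.deg2rad(cfg.wound_angle)
    # wound axis through the centre; signed distance along the axis normal
    c0 = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size]
    s_um = ((rr - c0) * (-np.sin(theta)) + (cc - c0) * np.cos(theta)) * px
    normal = np.array([-np.sin(theta), np.cos(theta)])  # (drow, dcol), unit

    texture = make_cell_texture(size, cfg.texture_seed)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.texture_seed, 1]))

    stack = np.empty((n, size, size), dtype=np.float32)
    masks = np.empty((n, size, size), dtype=bool)
    for i in range(n):
        # sheets translate rigidly with their border
        d_left = (w_left[0] - w_left[i]) / px  # px, along +normal
        d_right = (w_right[0] - w_right[i]) / px  # px, along -normal
        left_tex = nd_shift(texture, d_left * normal, order=1, mode="reflect")
        right_tex = nd_shift(texture, -d_right * normal, order=1, mode="reflect")
        mask = (s_um >= -w_left[i]) & (s_um <= w_right[i])
        frame = np.where(s_um < 0, left_tex, right_tex)
        frame = np.where(mask, cfg.wound_level, frame)
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        stack[i] = np.clip(frame, 0.0, 1.0)
        masks[i] = mask

    width = w_left + w_right
    if cfg.border_speeds is not None:
        speed = float(abs(cfg.border_speeds[0]) + abs(cfg.border_speeds[1]))
    else:
        span = times[-1] if times[-1] > 0 else 1.0
        speed = float((width[0] - width[-1]) / span * 60.0)
    truth = SimTruth(
        masks=masks,
        times=times,
        width_um=width,
        area_um2=masks.reshape(n, -1).sum(axis=1) * px * px,
        border_left_um=w_left,
        border_right_um=w_right,
        closure_speed_um_h=speed,
    )
    return stack, truth


@dataclass
class BurstSimConfig:
    """Spectral scenario for a raw burst.

    ``regions`` is a list of ``(mask, center_freq_hz, bandwidth_hz,
    amplitude, baseline)`` tuples; masks must tile disjoint parts of the
    frame.  Each region's pixel traces are independent unit-variance Gaussian
    noise band-pass filtered to ``[f_c - bw/2, f_c + bw/2]`` (a pure
    random-phase tone when bw == 0), scaled by ``amplitude`` and offset by
    ``baseline``.
    """

    regions: list
    frame_rate: float = 100.0
    n_frames: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise InvalidParameterError("at least one region is required")
        nyq = self.frame_rate / 2.0
        for _, fc, bw, amp, _ in self.regions:
            if bw < 0 or amp < 0:
                raise InvalidParameterError("bandwidth and amplitude must be >= 0")
            if amp > 0 and not (0.0 < fc - bw / 2 and fc + bw / 2 < nyq):
                raise InvalidParameterError(
                    f"frequency band [{fc - bw / 2}, {fc + bw / 2}] must lie "
                    f"inside (0, {nyq}) Hz"
                )


def simulate_dynamic_burst(cfg: BurstSimConfig, params: AcquisitionParams | None = None):
    """Synthesize a raw burst with known per-region spectral content.

    Returns ``(burst, truth)`` where ``truth.spectral_regions`` echoes the
    region parameters.  Pixel traces are independent; a zero-bandwidth region
    is a pure tone with per-pixel random phase scaled so its (infinite-series)
    variance is ``amplitude**2``.
    """
    shape = np.asarray(cfg.regions[0][0]).shape
    t = cfg.n_frames
    fs = cfg.frame_rate
    if params is None:
        params = AcquisitionParams(frame_rate=fs, burst_length=t)
    frames = np.zeros((t, *shape), dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    tt = np.arange(t) / fs
    freqs = np.fft.rfftfreq(t, d=1.0 / fs)

    for mask, fc, bw, amp, baseline in cfg.regions:
        mask = np.asarray(mask, dtype=bool)
        n_pix = int(mask.sum())
        if n_pix == 0:
            continue
        if amp == 0:
            sig = np.full((t, n_pix), float(baseline))
        elif bw == 0:
            phase = rng.uniform(0, 2 * np.pi, size=n_pix)
            sig = baseline + amp * np.sqrt(2.0) * np.cos(
                2 * np.pi * fc * tt[:, None] + phase[None, :]
            )
        else:
            white = rng.normal(0.0, 1.0, size=(t, n_pix))
            spec = np.fft.rfft(white, axis=0)
            band = (freqs >= fc - bw / 2) & (freqs <= fc + bw / 2)
            if not band.any():
                band[np.argmin(np.abs(freqs - fc))] = True
            spec[~band] = 0.0
            filt = np.fft.irfft(spec, n=t, axis=0)
            sd = filt.std(axis=0)
            sd[sd == 0] = 1.0
            sig = baseline + amp * (filt - filt.mean(axis=0)) / sd
        frames[:, mask] = sig

    burst = RawBurst(frames=frames, params=params)
    truth = SimTruth(
        masks=np.zeros((0, *shape), dtype=bool),
        times=np.zeros(0),
        width_um=np.zeros(0),
        area_um2=np.zeros(0),
        border_left_um=np.zeros(0),
        border_right_um=np.zeros(0),
        closure_speed_um_h=0.0,
        spectral_regions=[
            dict(center_freq=fc, bandwidth=bw, amplitude=amp, baseline=bl)
            for _, fc, bw, amp, bl in cfg.regions
        ],
    )
    return burst, truth


def preset_config(name: str, **overrides) -> WoundSimConfig:
    """Build a :class:`WoundSimConfig` from a named preset plus overrides."""
    if name not in PRESETS:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return WoundSimConfig(**kwargs)
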