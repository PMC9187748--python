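"""Dynamic-profile computation from raw D-FFOCT bursts.

A raw burst is several hundred interferometric frames recorded at fixed camera
rate with the reference piezo at rest, so that all temporal modulation of a
pixel comes from sub-cellular motion in the sample.  Each pixel's time trace is
summarised by three spectral features estimated from its periodogram:

* mean frequency  — power-weighted mean of the positive-frequency spectrum,
* bandwidth       — power-weighted standard deviation of frequency,
* amplitude       — running standard deviation over a moving window, averaged.

These are rendered in HSV: Hue encodes mean frequency on a blue (slow) to red
(fast) arc, Saturation encodes the inverse bandwidth (narrow-band signals give
vivid colours, broadband ones wash out to grey), and Value encodes the motion
amplitude.  Static (coherent-amplitude) FFOCT from pi-shifted phase pairs and
axial plane matching by cross-correlation are also provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .errors import InvalidInputError, InvalidParameterError
from .params import AcquisitionParams

#: Hue angle (fraction of the colour circle) for the lowest mapped frequency.
#: 240/360 is pure blue; hue decreases linearly to 0 (red) at the highest
#: mapped frequency, so the arc never wraps through magenta and the
#: frequency -> colour ordering is unambiguous.
_HUE_BLUE = 240.0 / 360.0


@dataclass
class RawBurst:
    """A T x H x W stack of non-negative intensity frames plus its acquisition."""

    frames: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise InvalidInputError("burst frames must be a T x H x W array")
        if self.frames.shape[0] != self.params.burst_length:
            raise InvalidInputError(
                f"burst has {self.frames.shape[0]} frames but params.burst_length "
                f"is {self.params.burst_length}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("burst frames contain non-finite values")


@dataclass
class SpectralFeatures:
    """Per-pixel spectral feature maps (Hz, Hz, intensity units)."""

    mean_freq: np.ndarray
    bandwidth: np.ndarray
    amplitude: np.ndarray
    silent: np.ndarray  # True where the mean-removed trace has zero power


@dataclass
class DynamicImage:
    """HSV rendering of the dynamic profile plus the features behind it."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray
    rgb: np.ndarray
    features: SpectralFeatures
    hue_freq_range: tuple[float, float]
    bandwidth_scale: float
    value_clip_percentile: float


@dataclass
class PhasePair:
    """A pair of pi-phase-shifted interferometric frames."""

    i_plus: np.ndarray
    i_minus: np.ndarray

    def __post_init__(self) -> None:
        self.i_plus = np.asarray(self.i_plus, dtype=np.float64)
        self.i_minus = np.asarray(self.i_minus, dtype=np.float64)
        if self.i_plus.shape != self.i_minus.shape:
            raise InvalidInputError("phase pair images must have the same shape")
        if not (np.all(np.isfinite(self.i_plus)) and np.all(np.isfinite(self.i_minus))):
            raise InvalidInputError("phase pair images must be finite")


def pixel_power_spectrum(series, frame_rate: float):
    """One-sided periodogram of a single pixel trace, DC excluded.

    The mean is removed before the transform.  The normalisation is chosen so
    that the power summed over all returned bins equals the population
    variance of the mean-removed series (a one-sided Parseval identity):
    ``P_k = 2|X_k|^2 / T^2`` for interior bins and ``|X_k|^2 / T^2`` at the
    Nyquist bin when T is even.

    Returns
    -------
    frequencies : ndarray
        Positive frequency grid with spacing ``frame_rate / T``, in Hz.
    power : ndarray
        Non-negative power at those frequencies.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise InvalidInputError("series must be one-dimensional")
    t = x.shape[0]
    if t < 4:
        raise InvalidInputError(f"series too short for spectral analysis (T={t} < 4)")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains non-finite values")
    freqs, power = _power_spectrum_stack(x[:, None], frame_rate)
    return freqs, power[:, 0]


def _power_spectrum_stack(x: np.ndarray, frame_rate: float):
    """Vectorised periodogram along axis 0 of a (T, N) array."""
    t = x.shape[0]
    xc = x - x.mean(axis=0)
    spec = np.fft.rfft(xc, axis=0)
    freqs = np.fft.rfftfreq(t, d=1.0 / frame_rate)
    power = (np.abs(spec) ** 2) * (2.0 / t**2)
    if t % 2 == 0:
        power[-1] *= 0.5  # Nyquist bin appears once in the full spectrum
    return freqs[1:], power[1:]


def mean_frequency(frequencies, power) -> float:
    """Power-weighted mean frequency; 0.0 for a silent (zero-power) pixel."""
    f = np.asarray(frequencies, dtype=np.float64)
    p = np.asarray(power, dtype=np.float64)
    total = p.sum()
    if total <= 0:
        return 0.0
    return float((f * p).sum() / total)


def spectral_bandwidth(frequencies, power) -> float:
    """Power-weighted standard deviation of frequency; 0.0 for silent pixels."""
    f = np.asarray(frequencies, dtype=np.float64)
    p = np.asarray(power, dtype=np.float64)
    total = p.sum()
    if total <= 0:
        return 0.0
    mu = (f * p).sum() / total
    var = ((f - mu) ** 2 * p).sum() / total
    return float(np.sqrt(max(var, 0.0)))


def _spectral_moments_stack(freqs: np.ndarray, power: np.ndarray):
    """Weighted mean/std of frequency for a (F, N) power stack; silent mask."""
    total = power.sum(axis=0)
    silent = total <= 0
    safe = np.where(silent, 1.0, total)
    mu = (freqs[:, None] * power).sum(axis=0) / safe
    var = (((freqs[:, None] - mu[None, :]) ** 2) * power).sum(axis=0) / safe
    mu = np.where(silent, 0.0, mu)
    sd = np.where(silent, 0.0, np.sqrt(np.maximum(var, 0.0)))
    return mu, sd, silent


def running_std_amplitude(series, window: int):
    """Mean over all stride-1 windows of the population std within the window.

    Accepts a 1-D trace or a (T, ...) stack (reduced along axis 0).  Invariant
    to adding a constant to the series.
    """
    if window < 2:
        raise InvalidParameterError(f"window must be >= 2, got {window}")
    x = np.asarray(series, dtype=np.float64)
    t = x.shape[0]
    if t < window:
        raise InvalidInputError(f"series length {t} shorter than window {window}")
    # Windowed mean/variance via cumulative sums; centre first for stability.
    x = x - x.mean(axis=0)
    zeros = np.zeros((1,) + x.shape[1:], dtype=np.float64)
    c1 = np.concatenate([zeros, np.cumsum(x, axis=0)], axis=0)
    c2 = np.concatenate([zeros, np.cumsum(x * x, axis=0)], axis=0)
    s1 = c1[window:] - c1[:-window]
    s2 = c2[window:] - c2[:-window]
    var = s2 / window - (s1 / window) ** 2
    stds = np.sqrt(np.maximum(var, 0.0))
    return stds.mean(axis=0)


def compute_dynamic_image(
    burst: RawBurst,
    hue_freq_range: tuple[float, float] | None = None,
    bandwidth_scale: float | None = None,
    value_clip_percentile: float = 99.5,
) -> DynamicImage:
    """Render a raw burst as its HSV dynamic profile.

    Hue maps the per-pixel mean frequency linearly from ``f_lo`` (blue) to
    ``f_hi`` (red); saturation is ``1 - bandwidth / bandwidth_scale`` clamped
    to [0, 1]; value is the averaged running standard deviation normalised by
    its ``value_clip_percentile`` percentile over the frame and clamped to
    [0, 1].  Defaults: hue range (0, Nyquist), bandwidth_scale frame_rate/4.
    """
    fs = burst.params.frame_rate
    if hue_freq_range is None:
        hue_freq_range = (0.0, fs / 2.0)
    f_lo, f_hi = hue_freq_range
    if f_hi <= f_lo:
        raise InvalidParameterError(f"hue_freq_range must satisfy f_lo < f_hi, got {hue_freq_range}")
    if bandwidth_scale is None:
        bandwidth_scale = fs / 4.0
    if bandwidth_scale <= 0:
        raise InvalidParameterError("bandwidth_scale must be positive")
    if not 0 < value_clip_percentile <= 100:
        raise InvalidParameterError("value_clip_percentile must be in (0, 100]")

    t, h, w = burst.frames.shape
    flat = burst.frames.reshape(t, h * w)
    freqs, power = _power_spectrum_stack(flat, fs)
    mf, bw, silent = _spectral_moments_stack(freqs, power)
    amp = running_std_amplitude(flat, burst.params.value_window)

    mf = mf.reshape(h, w)
    bw = bw.reshape(h, w)
    amp = amp.reshape(h, w)
    silent = silent.reshape(h, w)
    features = SpectralFeatures(mean_freq=mf, bandwidth=bw, amplitude=amp, silent=silent)

    frac = np.clip((mf - f_lo) / (f_hi - f_lo), 0.0, 1.0)
    hue = _HUE_BLUE * (1.0 - frac)
    sat = np.clip(1.0 - bw / bandwidth_scale, 0.0, 1.0)
    norm = np.percentile(amp, value_clip_percentile)
    value = np.clip(amp / norm, 0.0, 1.0) if norm > 0 else np.zeros_like(amp)

    rgb = hsv_to_rgb(np.stack([hue, sat, value], axis=-1))
    return DynamicImage(
        hue=hue,
        saturation=sat,
        value=value,
        rgb=rgb,
        features=features,
        hue_freq_range=(f_lo, f_hi),
        bandwidth_scale=float(bandwidth_scale),
        value_clip_percentile=float(value_clip_percentile),
    )


def ffoct_static(pair: PhasePair) -> np.ndarray:
    """Coherent amplitude from a pi-shifted pair: |i_plus - i_minus| / 2."""
    return np.abs(pair.i_plus - pair.i_minus) / 2.0


def best_plane_by_crosscorrelation(zstack, reference) -> int:
    """Index of the z-plane best matching the reference image.

    Uses the zero-normalised cross-correlation coefficient at zero lateral
    lag (plane selection only, no lateral registration).  Ties break to the
    lowest index; zero-variance candidate planes score -inf.
    """
    z = np.asarray(zstack, dtype=np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if z.ndim != 3 or z.shape[0] < 1:
        raise InvalidInputError("zstack must be a K x H x W array with K >= 1")
    if z.shape[1:] != ref.shape:
        raise InvalidInputError("reference shape does not match zstack planes")
    r = ref - ref.mean()
    r_norm = np.sqrt((r * r).sum())
    if r_norm == 0:
        raise InvalidInputError("reference image has zero variance")
    flat = z.reshape(z.shape[0], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    norms = np.sqrt((flat * flat).sum(axis=1))
    scores = np.full(z.shape[0], -np.inf)
    ok = norms > 0
    scores[ok] = (flat[ok] @ r.ravel()) / (norms[ok] * r_norm)
    return int(np.argmax(scores))
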