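"""Acquisition and analysis parameter containers.

All physical calibration (pixel size, frame rate, time-lapse interval) lives in
:class:`AcquisitionParams` and is treated as instrument knowledge: when a stack
is read from disk, values configured here win over any TIFF metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .errors import InvalidParameterError

#: Lateral sampling of the reference instrument: a 320 um field imaged on a
#: 1440 px camera, i.e. ~0.222 um/px.
DEFAULT_PIXEL_SIZE_UM = 320.0 / 1440.0


@dataclass
class AcquisitionParams:
    """Physical acquisition settings of a D-FFOCT recording.

    Parameters
    ----------
    frame_rate : float
        Burst sampling rate in Hz.  Bursts of raw interferometric frames are
        recorded at this rate with the reference-arm piezo at rest.
    burst_length : int
        Number of frames per raw burst.
    value_window : int
        Length (frames) of the moving window used for the running standard
        deviation that forms the Value channel of the dynamic profile.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    timelapse_interval : float
        Minutes between consecutive dynamic-profile frames in a time-lapse.
    """

    frame_rate: float = 100.0
    burst_length: int = 512
    value_window: int = 50
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    timelapse_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.burst_length < 2 * self.value_window:
            raise InvalidParameterError(
                "burst_length must be at least twice value_window "
                f"({self.burst_length} < 2*{self.value_window})"
            )
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.timelapse_interval <= 0:
            raise InvalidParameterError("timelapse_interval must be positive")

    @property
    def nyquist(self) -> float:
        return self.frame_rate / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RenderingParams:
    """Display mapping of spectral features onto HSV channels.

    ``hue_freq_range`` sets the frequencies mapped to the blue and red ends of
    the hue arc; ``None`` endpoints default to 0 and the Nyquist frequency.
    ``bandwidth_scale`` normalises the saturation channel (S = 1 - bw/scale,
    clamped); ``None`` defaults to frame_rate / 4.  ``value_clip_percentile``
    is the per-frame percentile used to normalise the Value channel.
    """

    hue_freq_lo: float | None = None
    hue_freq_hi: float | None = None
    bandwidth_scale: float | None = None
    value_clip_percentile: float = 99.5

    def __post_init__(self) -> None:
        if not 0 < self.value_clip_percentile <= 100:
            raise InvalidParameterError("value_clip_percentile must be in (0, 100]")


@dataclass
class SegmentationParams:
    """SAVE-profiler segmentation and kinetics settings."""

    n_classes: int = 3
    closing_limit: float = 1.5  # um; mid-range of the 1-2 um inter-cell interstice
    remove_small_objects: int = 0  # px; 0 disables morphological cleanup

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InvalidParameterError("n_classes must be >= 2")
        if self.closing_limit < 0:
            raise InvalidParameterError("closing_limit must be >= 0")


@dataclass
class FlowParams:
    """Horn-Schunck optical-flow settings.

    alpha is the smoothness weight of the variational problem; n_iter the
    fixed number of Jacobi iterations; median_size the spatial median-filter
    width applied before flow to suppress camera line noise; block_avg the
    number of consecutive time-lapse frames averaged together; min_velocity
    the noise floor (um/h) below which pixels are excluded from both display
    and summary statistics.
    """

    alpha: float = 1.0
    n_iter: int = 200
    median_size: int = 3
    block_avg: int = 8
    min_velocity: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise InvalidParameterError("alpha must be positive")
        if self.n_iter < 1:
            raise InvalidParameterError("n_iter must be >= 1")
        if self.block_avg < 1:
            raise InvalidParameterError("block_avg must be >= 1")
        if self.median_size < 1:
            raise InvalidParameterError("median_size must be >= 1")
        if self.min_velocity < 0:
            raise InvalidParameterError("min_velocity must be >= 0")


@dataclass
class PipelineConfig:
    """Top-level configuration tying all stages together."""

    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    rendering: RenderingParams = field(default_factory=RenderingParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    flow: FlowParams = field(default_factory=FlowParams)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "acquisition": asdict(self.acquisition),
            "rendering": asdict(self.rendering),
            "segmentation": asdict(self.segmentation),
            "flow": asdict(self.flow),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {"acquisition", "rendering", "segmentation", "flow", "seed"}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown config section(s): {sorted(unknown)}; expected {sorted(known)}"
            )
        sections = {}
        for name, typ in (
            ("acquisition", AcquisitionParams),
            ("rendering", RenderingParams),
            ("segmentation", SegmentationParams),
            ("flow", FlowParams),
        ):
            sub = dict(data.get(name, {}))
            valid = {f for f in typ.__dataclass_fields__}
            bad = set(sub) - valid
            if bad:
                raise InvalidParameterError(
                    f"unknown key(s) in config section '{name}': {sorted(bad)}"
                )
            sections[name] = typ(**sub)
        return cls(seed=int(data.get("seed", 0)), **sections)
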