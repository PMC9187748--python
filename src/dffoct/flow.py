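"""Horn-Schunck optical flow and front-resolved speed summaries.

The flow stage validates the SAVE profiler: a grayscale time-lapse (typically
the Value channel of the dynamic profile) is median-filtered per frame to
suppress camera line noise, averaged in non-overlapping temporal blocks, and
dense flow is estimated on each consecutive pair with the classical
Horn-Schunck scheme (brightness constancy plus a quadratic smoothness prior,
solved by fixed-count Jacobi iteration).  Per-pixel velocities averaged over
the acquisition are converted to um/h; speeds are summarised per wound front
(left/right of the wound axis), and the total closure speed is twice the mean
per-front speed since two opposing fronts advance simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate, median_filter

from .errors import InvalidInputError, InvalidParameterError
from .params import FlowParams

# Original Horn-Schunck derivative estimators: forward differences averaged
# over the 2x2x2 space-time cube.
_KX = 0.25 * np.array([[-1.0, 1.0], [-1.0, 1.0]])
_KY = 0.25 * np.array([[-1.0, -1.0], [1.0, 1.0]])
_KT = 0.25 * np.ones((2, 2))
# Weighted 8-neighbour local-average kernel for the smoothness term.
_KAVG = np.array(
    [[1 / 12, 1 / 6, 1 / 12],
     [1 / 6, 0.0, 1 / 6],
     [1 / 12, 1 / 6, 1 / 12]]
)


@dataclass
class FlowField:
    """Dense velocity field; u along columns (x), v along rows (y)."""

    u: np.ndarray
    v: np.ndarray
    units: str = "px/frame"
    convergence: float = float("nan")  # mean update norm of the final iteration

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def angle(self) -> np.ndarray:
        return np.arctan2(self.v, self.u)

    def scaled(self, factor: float, units: str) -> "FlowField":
        return FlowField(u=self.u * factor, v=self.v * factor, units=units,
                         convergence=self.convergence)


@dataclass
class FlowSummary:
    """Front-resolved speed summary in um/h."""

    mean_speed: float
    left_front_speed: float
    right_front_speed: float
    total_closure_speed: float
    angle_histogram: np.ndarray
    angle_bin_edges: np.ndarray
    n_valid: int
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_speed_um_h": self.mean_speed,
            "left_front_speed_um_h": self.left_front_speed,
            "right_front_speed_um_h": self.right_front_speed,
            "total_closure_speed_um_h": self.total_closure_speed,
            "n_valid_pixels": self.n_valid,
            "empty": self.empty,
        }


def preprocess_for_flow(stack, params: FlowParams | None = None) -> np.ndarray:
    """Median-filter each frame, then average non-overlapping temporal blocks.

    Frames beyond the last full block are dropped; the effective frame
    interval of the result is ``block_avg`` times the input interval.
    """
    params = params or FlowParams()
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim != 3:
        raise InvalidInputError("stack must be T x H x W")
    if arr.shape[0] < 2 * params.block_avg:
        raise InvalidInputError(
            f"need at least {2 * params.block_avg} frames for block averaging "
            f"of {params.block_avg} (got {arr.shape[0]})"
        )
    if params.median_size > 1:
        arr = np.stack([median_filter(f, size=params.median_size) for f in arr])
    b = params.block_avg
    n_blocks = arr.shape[0] // b
    arr = arr[: n_blocks * b]
    return arr.reshape(n_blocks, b, *arr.shape[1:]).mean(axis=1)


def horn_schunck(frame_a, frame_b, params: FlowParams | None = None) -> FlowField:
    """Dense flow from frame_a to frame_b by the Horn-Schunck iteration.

    u <- u_avg - Ix (Ix u_avg + Iy v_avg + It) / (alpha^2 + Ix^2 + Iy^2), and
    symmetrically for v, from zero initialisation for a fixed ``n_iter``
    iterations.  Derivatives use the original forward-difference cube
    estimators; the local average is the weighted 8-neighbour kernel.
    """
    params = params or FlowParams()
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidInputError("frames must be two 2-D arrays of equal shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise InvalidInputError("frames must be finite")

    # Normalise the joint brightness range to [0, 255] so that the smoothness
    # weight alpha is calibrated against a standard image scale; this makes
    # the flow invariant under global intensity offset and rescaling.
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi > lo:
        scale = 255.0 / (hi - lo)
        a = (a - lo) * scale
        b = (b - lo) * scale

    ix = correlate(a, _KX, mode="nearest") + correlate(b, _KX, mode="nearest")
    iy = correlate(a, _KY, mode="nearest") + correlate(b, _KY, mode="nearest")
    it = correlate(b, _KT, mode="nearest") - correlate(a, _KT, mode="nearest")

    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = params.alpha**2 + ix**2 + iy**2
    update = float("nan")
    for _ in range(params.n_iter):
        u_avg = correlate(u, _KAVG, mode="nearest")
        v_avg = correlate(v, _KAVG, mode="nearest")
        t = (ix * u_avg + iy * v_avg + it) / denom
        u_new = u_avg - ix * t
        v_new = v_avg - iy * t
        update = float(np.mean(np.hypot(u_new - u, v_new - v)))
        u, v = u_new, v_new
    return FlowField(u=u, v=v, units="px/frame", convergence=update)


def accumulate_flow(
    stack,
    params: FlowParams | None = None,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
) -> FlowField:
    """Mean velocity field of a time-lapse in um/h.

    The stack is preprocessed (median filter + temporal block averaging),
    Horn-Schunck flow is computed on each consecutive pair of reduced frames,
    and the per-pixel temporal mean of (u, v) is converted from px per reduced
    frame to um/h with ``pixel_size * 60 / (frame_interval * block_avg)``
    (frame_interval in minutes of the *raw* time-lapse).
    """
    params = params or FlowParams()
    if pixel_size <= 0 or frame_interval <= 0:
        raise InvalidParameterError("pixel_size and frame_interval must be positive")
    reduced = preprocess_for_flow(stack, params)
    if reduced.shape[0] < 2:
        raise InvalidInputError("fewer than 2 frames after block averaging")
    u_sum = np.zeros(reduced.shape[1:])
    v_sum = np.zeros(reduced.shape[1:])
    n_pairs = reduced.shape[0] - 1
    conv = float("nan")
    for i in range(n_pairs):
        f = horn_schunck(reduced[i], reduced[i + 1], params)
        u_sum += f.u
        v_sum += f.v
        conv = f.convergence
    factor = pixel_size * 60.0 / (frame_interval * params.block_avg)
    return FlowField(
        u=u_sum / n_pairs * factor,
        v=v_sum / n_pairs * factor,
        units="um/h",
        convergence=conv,
    )


def summarize_fronts(
    field: FlowField,
    wound_axis_column: int,
    params: FlowParams | None = None,
    wound_mask=None,
    n_angle_bins: int = 16,
) -> FlowSummary:
    """Per-front and total closure speeds from a velocity field in um/h.

    Pixels with magnitude below ``min_velocity`` (and optionally inside the
    wound mask) are excluded.  Fronts are split by the side of the vertical
    wound axis; each front's speed is the mean magnitude of its side, and the
    total closure speed is twice the mean of the per-front speeds, since two
    opposing fronts approach each other.
    """
    params = params or FlowParams()
    mag = field.magnitude
    ang = field.angle
    if not np.all(np.isfinite(mag)):
        raise InvalidInputError("flow field must be finite")
    valid = mag >= params.min_velocity
    if wound_mask is not None:
        valid &= ~np.asarray(wound_mask, dtype=bool)
    edges = np.linspace(-np.pi, np.pi, n_angle_bins + 1)
    if not valid.any():
        return FlowSummary(
            mean_speed=0.0, left_front_speed=0.0, right_front_speed=0.0,
            total_closure_speed=0.0,
            angle_histogram=np.zeros(n_angle_bins, dtype=int),
            angle_bin_edges=edges, n_valid=0, empty=True,
        )
    cols = np.arange(mag.shape[1])[None, :] * np.ones_like(mag)
    left = valid & (cols < wound_axis_column)
    right = valid & (cols > wound_axis_column)
    left_speed = float(mag[left].mean()) if left.any() else 0.0
    right_speed = float(mag[right].mean()) if right.any() else 0.0
    fronts = [s for s, m in ((left_speed, left), (right_speed, right)) if m.any()]
    total = 2.0 * float(np.mean(fronts)) if fronts else 0.0
    hist, _ = np.histogram(ang[valid], bins=edges)
    return FlowSummary(
        mean_speed=float(mag[valid].mean()),
        left_front_speed=left_speed,
        right_front_speed=right_speed,
        total_closure_speed=total,
        angle_histogram=hist,
        angle_bin_edges=edges,
        n_valid=int(valid.sum()),
        empty=False,
    )


@dataclass
class Arrow:
    """One quiver arrow: origin (row, col), unit direction, length ~ speed."""

    origin: tuple[int, int]
    direction: tuple[float, float]  # (du, dv) unit vector
    length: float

    def to_dict(self) -> dict:
        return {
            "origin": [int(self.origin[0]), int(self.origin[1])],
            "direction": [float(self.direction[0]), float(self.direction[1])],
            "length": float(self.length),
        }


def export_arrow_field(
    field: FlowField,
    decimation: int = 8,
    min_velocity: float = 2.0,
    scale: float = 1.0,
) -> list[Arrow]:
    """Quiver-style arrows on a regular grid, omitting sub-floor pixels.

    One candidate arrow per ``decimation x decimation`` block (sampled at the
    block centre); arrow length is ``magnitude * scale``.
    """
    if decimation < 1:
        raise InvalidParameterError("decimation must be >= 1")
    mag = field.magnitude
    arrows: list[Arrow] = []
    off = decimation // 2
    for r in range(off, mag.shape[0], decimation):
        for c in range(off, mag.shape[1], decimation):
            m = mag[r, c]
            if m < min_velocity or m == 0:
                continue
            arrows.append(
                Arrow(
                    origin=(r, c),
                    direction=(float(field.u[r, c] / m), float(field.v[r, c] / m)),
                    length=float(m * scale),
                )
            )
    return arrows
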