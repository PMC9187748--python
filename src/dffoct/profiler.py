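"""SAVE profiler: scratch-assay segmentation and wound-closure kinetics.

The pipeline quantifies a wound in a dynamic-profile (or any grayscale)
time-lapse in four steps:

1. multi-level thresholding of the first and last frames, retaining the first
   (lowest) level, with thresholds interpolated linearly through the stack to
   absorb slow intensity drift;
2. rotation of the stack so the user-drawn scratch line is vertical, cropping
   away the rotation fill;
3. masking by a user-drawn wound ROI polygon (contoured on the first frame for
   closing wounds, the last for expanding ones), giving per-frame binary wound
   masks;
4. per-frame area and row-wise width statistics, the wound-closure percentage
   (area(0) - area(t)) / area(0) * 100, and a bi-exponential fit of the mean
   width from which a characteristic time and an average closing speed are
   derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from skimage.draw import polygon2mask
from skimage.filters import threshold_multiotsu
from skimage.morphology import remove_small_objects
from skimage.transform import rotate as _sk_rotate

from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from .params import AcquisitionParams, SegmentationParams


@dataclass
class ScratchLine:
    """User-drawn line along the scratch; (row, col), 0-based, origin top-left."""

    p0: tuple[float, float]
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise InvalidInputError("scratch line endpoints must differ")


@dataclass
class RoiPolygon:
    """Wound contour polygon; vertices as (row, col) in the rotated frame."""

    vertices: list[tuple[float, float]]
    reference_frame: str = "first"

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise InvalidInputError("ROI polygon needs at least 3 vertices")
        if self.reference_frame not in ("first", "last"):
            raise InvalidParameterError("reference_frame must be 'first' or 'last'")
        if not _polygon_is_simple(self.vertices):
            raise InvalidInputError("ROI polygon must be simple (non-self-intersecting)")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = polygon2mask(shape, np.asarray(self.vertices, dtype=float))
        if not mask.any():
            raise InvalidInputError("ROI polygon covers no pixels of the frame")
        return mask


def _polygon_is_simple(vertices) -> bool:
    try:
        from shapely.geometry import Polygon
    except ImportError:  # pragma: no cover
        return True
    return Polygon([(float(r), float(c)) for r, c in vertices]).is_valid


@dataclass
class WoundTrace:
    """Per-frame wound geometry in pixels and micrometres."""

    times: np.ndarray  # minutes
    area_px: np.ndarray
    area_um2: np.ndarray
    width_min_px: np.ndarray
    width_mean_px: np.ndarray
    width_max_px: np.ndarray
    width_min_um: np.ndarray
    width_mean_um: np.ndarray
    width_max_um: np.ndarray
    closure_pct: np.ndarray


@dataclass
class ClosureFit:
    """Bi-exponential wound-width kinetics w(t) = limit + a e^{bt} + c e^{dt}.

    ``characteristic_time`` is the first time at which the fitted excess width
    above the plateau has decayed to 1/e of its initial value; for a single
    exponential this is exactly its time constant.  ``average_speed`` is the
    initial excess width divided by the time the fitted excess takes to fall
    below the closing limit, in um/h; if that never happens within the
    acquisition the mean slope of the fitted width over the observed interval
    is reported instead and ``closed`` is False.
    """

    a: float
    b: float
    c: float
    d: float
    closing_limit: float
    characteristic_time: float
    average_speed: float
    t_reach: float
    closed: bool
    converged: bool
    residual_rms: float

    def width(self, t) -> np.ndarray:
        """Fitted mean width (um) at time t (minutes)."""
        t = np.asarray(t, dtype=float)
        return self.closing_limit + self.excess(t)

    def excess(self, t) -> np.ndarray:
        """Fitted width above the closing limit at time t (minutes)."""
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(self.b * t) + self.c * np.exp(self.d * t)

    def summary(self) -> str:
        lines = [
            "Bi-exponential wound-width fit: w(t) = limit + a*exp(b*t) + c*exp(d*t)",
            f"  a = {self.a:.6g} um      b = {self.b:.6g} 1/min",
            f"  c = {self.c:.6g} um      d = {self.d:.6g} 1/min",
            f"  closing limit       = {self.closing_limit:.3g} um",
            f"  characteristic time = {self.characteristic_time:.4g} min",
            f"  average speed       = {self.average_speed:.4g} um/h",
            f"  closed within acquisition: {self.closed}"
            + ("" if self.closed else " (speed over observed interval)"),
            f"  converged = {self.converged}   residual RMS = {self.residual_rms:.4g} um",
        ]
        return "\n".join(lines)


def multithreshold_first_level(image, n_classes: int = 3) -> float:
    """Lowest of the (n_classes - 1) multi-Otsu thresholds of an image.

    The first level separates the dark scratch from everything else while the
    higher levels absorb cytoplasm / bright organelles, so only the first is
    retained.
    """
    img = np.asarray(image)
    if n_classes < 2:
        raise InvalidParameterError("n_classes must be >= 2")
    n_distinct = np.unique(img).size
    if n_distinct < n_classes:
        raise DegenerateInputError(
            f"image has {n_distinct} distinct value(s); need >= {n_classes} for "
            f"{n_classes}-class thresholding"
        )
    try:
        thresholds = threshold_multiotsu(img, classes=n_classes)
    except ValueError as exc:
        raise DegenerateInputError(str(exc)) from exc
    return float(thresholds[0])


def interpolate_thresholds(t_first: float, t_last: float, n_frames: int) -> np.ndarray:
    """Arithmetic progression of thresholds from first to last frame inclusive."""
    if n_frames < 1:
        raise InvalidParameterError("n_frames must be >= 1")
    if n_frames == 1:
        return np.array([float(t_first)])
    return np.linspace(float(t_first), float(t_last), n_frames)


def _line_angle_deg(line: ScratchLine) -> float:
    """Rotation angle (deg, CCW as skimage rotates) making the line vertical.

    Normalised to (-90, 90] so the smaller-magnitude rotation is used when
    the line is vertical up to sign.
    """
    dr = float(line.p1[0]) - float(line.p0[0])
    dc = float(line.p1[1]) - float(line.p0[1])
    # angle of the line away from the row-axis (image-vertical) direction;
    # rotating the content by the negative of this angle makes it vertical
    ang = -math.degrees(math.atan2(dc, dr))
    ang = (ang + 90.0) % 180.0 - 90.0
    if ang == -90.0:
        ang = 90.0
    return ang


def _largest_interior_rect(valid: np.ndarray) -> tuple[slice, slice]:
    """Largest centred axis-aligned all-valid rectangle of a rotated frame.

    The valid region after rotating a full rectangle is convex and symmetric
    about the image centre, so the maximal inscribed axis-aligned rectangle
    can be taken centred; scan symmetric row margins and take the widest
    common column run.
    """
    h, w = valid.shape
    if valid.all():
        return slice(0, h), slice(0, w)
    first = np.full(h, w)
    last = np.full(h, -1)
    for r in range(h):
        cols = np.flatnonzero(valid[r])
        if cols.size:
            first[r] = cols[0]
            last[r] = cols[-1]
    best_area = -1
    best = (slice(0, 0), slice(0, 0))
    for m in range(h // 2 + 1):
        r0, r1 = m, h - m
        if r1 <= r0:
            break
        c0 = int(first[r0:r1].max())
        c1 = int(last[r0:r1].min())
        if c1 < c0:
            continue
        area = (r1 - r0) * (c1 - c0 + 1)
        if area > best_area:
            best_area = area
            best = (slice(r0, r1), slice(c0, c1 + 1))
    if best_area <= 0:
        raise InvalidInputError("rotation left no fill-free interior rectangle")
    return best


def rotate_to_vertical(stack, line: ScratchLine):
    """Rotate a stack so the scratch line is vertical and crop rotation fill.

    Intensity frames are interpolated bilinearly, boolean frames with nearest
    neighbour.  Returns ``(rotated_stack, angle_deg)`` where ``angle_deg`` is
    the applied rotation (0 leaves the stack untouched).
    """
    arr = np.asarray(stack)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidInputError("stack must be 2-D or 3-D")
    angle = _line_angle_deg(line)
    if angle == 0.0:
        out = arr[0] if squeeze else arr
        return out, 0.0
    is_bool = arr.dtype == bool
    order = 0 if is_bool else 1
    valid = _sk_rotate(
        np.ones(arr.shape[1:], dtype=float), angle, resize=True, order=0, cval=0.0
    ) > 0.5
    rows, cols = _largest_interior_rect(valid)
    frames = []
    for frame in arr:
        rot = _sk_rotate(
            frame.astype(float), angle, resize=True, order=order, cval=0.0,
            preserve_range=True,
        )
        frames.append(rot[rows, cols])
    out = np.stack(frames)
    if is_bool:
        out = out > 0.5
    if squeeze:
        out = out[0]
    return out, angle


def segment_wound(stack, thresholds, roi_mask, min_object_size: int = 0) -> np.ndarray:
    """Binary wound masks: (intensity < per-frame threshold) inside the ROI."""
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise InvalidInputError("stack must be T x H x W")
    thr = np.asarray(thresholds, dtype=float)
    if thr.shape[0] != arr.shape[0]:
        raise InvalidInputError("one threshold per frame required")
    roi = np.asarray(roi_mask, dtype=bool)
    if roi.shape != arr.shape[1:]:
        raise InvalidInputError("ROI mask shape does not match frames")
    if not roi.any():
        raise InvalidInputError("ROI mask is empty")
    masks = arr < thr[:, None, None]
    masks &= roi[None]
    if min_object_size > 0:
        masks = np.stack(
            [remove_small_objects(m, min_size=min_object_size) for m in masks]
        )
    return masks


def wound_closure(area_series) -> np.ndarray:
    """(area(0) - area(t)) / area(0) * 100; negative for expanding wounds."""
    areas = np.asarray(area_series, dtype=float)
    if areas.size == 0 or areas[0] <= 0:
        raise InvalidInputError("initial wound area must be positive")
    return (areas[0] - areas) / areas[0] * 100.0


def width_profile(binary_frame, roi_mask=None):
    """Row-wise wound widths of a scratch-vertical binary frame.

    Returns ``(widths, (min, mean, max))`` where widths counts wound pixels in
    every row and the summary is taken over rows intersecting the ROI (all
    rows when no ROI is given).
    """
    frame = np.asarray(binary_frame, dtype=bool)
    if frame.ndim != 2:
        raise InvalidInputError("binary frame must be 2-D")
    widths = frame.sum(axis=1).astype(float)
    if roi_mask is not None:
        rows = np.asarray(roi_mask, dtype=bool).any(axis=1)
        if not rows.any():
            raise InvalidInputError("ROI intersects no rows")
        sel = widths[rows]
    else:
        sel = widths
    return widths, (float(sel.min()), float(sel.mean()), float(sel.max()))


# ---------------------------------------------------------------------------
# bi-exponential kinetics


def _biexp(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, c, d = params
    # exponent clip keeps wayward optimizer starts finite; 1e21 um is far
    # beyond any physical width so the clip never binds on accepted fits
    return a * np.exp(np.minimum(b * t, 50.0)) + c * np.exp(np.minimum(d * t, 50.0))


def _first_crossing(fun, t_lo: float, t_hi: float, n_grid: int = 2048) -> float:
    """First t in [t_lo, t_hi] with fun(t) <= 0, refined by bisection; nan if none."""
    ts = np.linspace(t_lo, t_hi, n_grid)
    vals = fun(ts)
    below = vals <= 0
    if not below.any():
        return math.nan
    i = int(np.argmax(below))
    if i == 0:
        return float(ts[0])
    lo, hi = float(ts[i - 1]), float(ts[i])
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if fun(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return hi


def fit_biexponential(times, mean_width, closing_limit: float = 1.5) -> ClosureFit:
    """Fit w(t) = closing_limit + a e^{bt} + c e^{dt} to a mean-width trace.

    times in minutes, widths and the closing limit in micrometres.  The excess
    width above the closing limit is fitted by deterministic multi-start
    nonlinear least squares (amplitude splits {0.9, 0.5, 0.1} of the initial
    excess, rates {-1, -0.1, -0.01}/T, mirrored to positive rates when the
    trace is increasing); the start with the lowest residual wins.
    """
    t = np.asarray(times, dtype=float)
    w = np.asarray(mean_width, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise InvalidInputError("times and mean_width must be 1-D and equally long")
    if t.size < 8:
        raise InvalidInputError("need at least 8 timepoints for a bi-exponential fit")
    if np.any(w < 0):
        raise InvalidInputError("widths must be non-negative")
    if closing_limit < 0:
        raise InvalidParameterError("closing_limit must be >= 0")

    t0 = t[0]
    ts = t - t0  # fit in shifted time so e^{bt} is well scaled
    span = float(ts[-1]) if ts[-1] > 0 else 1.0
    y = w - closing_limit
    y0 = float(y[0])
    amp = y0 if abs(y0) > 1e-12 else (float(np.max(np.abs(y))) or 1.0)

    rates = [-1.0 / span, -0.1 / span, -0.01 / span]
    if y[-1] > y[0]:
        rates += [1.0 / span, 0.1 / span]
    splits = [0.9, 0.5, 0.1]

    fits = []
    for f in splits:
        for b0 in rates:
            for d0 in rates:
                x0 = np.array([f * amp, b0, (1 - f) * amp, d0])
                try:
                    res = least_squares(
                        lambda p: _biexp(p, ts) - y, x0, method="lm", max_nfev=5000
                    )
                except Exception:
                    continue
                if np.all(np.isfinite(res.x)):
                    fits.append(res)

    # a rate changing the term by more than e^30 across the observed window
    # is unidentifiable from the data; such solutions exploit floating-point
    # headroom (vanishing amplitude x exploding exponential) and corrupt
    # every quantity later derived from the fitted curve
    identifiable = [r for r in fits if max(abs(r.x[1]), abs(r.x[3])) * span <= 30.0]
    if identifiable:
        fits = identifiable

    best = None
    if fits:
        # among near-equal-cost solutions prefer the gentlest kinetics
        best_cost = min(r.cost for r in fits)
        tol = best_cost * 1.001 + 1e-12
        best = min(
            (r for r in fits if r.cost <= tol),
            key=lambda r: max(abs(r.x[1]), abs(r.x[3])),
        )

    if best is None or not np.all(np.isfinite(best.x)):
        return ClosureFit(
            a=math.nan, b=math.nan, c=math.nan, d=math.nan,
            closing_limit=closing_limit, characteristic_time=math.nan,
            average_speed=math.nan, t_reach=math.nan, closed=False,
            converged=False, residual_rms=math.nan,
        )

    a, b, c, d = (float(v) for v in best.x)
    resid = _biexp(best.x, ts) - y
    rms = float(np.sqrt(np.mean(resid**2)))

    excess = lambda tt: _biexp(best.x, np.asarray(tt, dtype=float))
    e0 = float(excess(0.0))

    # characteristic time: first 1/e decay of the excess above the plateau
    char_time = math.nan
    if e0 > 0:
        decay_scales = [abs(1.0 / r) for r in (b, d) if r < 0]
        horizon = max(span, 50.0 * max(decay_scales)) if decay_scales else span
        char_time = _first_crossing(lambda tt: excess(tt) - e0 / math.e, 0.0, horizon)
        if math.isnan(char_time):
            char_time = math.inf

    # time for the fitted excess to fall below the closing limit, i.e. the
    # width to come within one interstice-width of its plateau, searched
    # within the acquisition
    t_reach = math.nan
    closed = False
    if e0 > 0 and closing_limit > 0:
        t_reach = _first_crossing(lambda tt: excess(tt) - closing_limit, 0.0, span)
        closed = not math.isnan(t_reach) and t_reach > 0
    if closed:
        avg_speed = e0 / t_reach * 60.0
    else:
        # mean slope of the fitted width over the observed interval, um/h
        avg_speed = (e0 - float(excess(span))) / span * 60.0 if span > 0 else 0.0

    return ClosureFit(
        a=a, b=b, c=c, d=d, closing_limit=float(closing_limit),
        characteristic_time=char_time, average_speed=float(avg_speed),
        t_reach=t_reach, closed=closed,
        converged=bool(np.all(np.isfinite(best.x))), residual_rms=rms,
    )


# ---------------------------------------------------------------------------
# whole pipeline


@dataclass
class SaveProfilerResult:
    trace: WoundTrace
    fit: ClosureFit
    masks: np.ndarray | None = None  # per-frame wound masks, rotated frame
    report: dict = field(default_factory=dict)


def run_save_profiler(
    stack,
    line: ScratchLine,
    roi: RoiPolygon,
    acquisition: AcquisitionParams | None = None,
    segmentation: SegmentationParams | None = None,
) -> SaveProfilerResult:
    """Run the full SAVE pipeline on a grayscale time-lapse stack.

    Steps, in order: multi-level threshold of first/last frames (first level
    retained) -> linear threshold interpolation -> rotation to vertical with
    crop -> ROI masking -> per-frame area and width statistics -> closure
    percentage -> bi-exponential fit of mean width (um) against time (min).
    """
    acquisition = acquisition or AcquisitionParams()
    segmentation = segmentation or SegmentationParams()
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise InvalidInputError("need a T x H x W stack with at least 2 frames")
    n = arr.shape[0]

    t_first = multithreshold_first_level(arr[0], segmentation.n_classes)
    t_last = multithreshold_first_level(arr[-1], segmentation.n_classes)
    thresholds = interpolate_thresholds(t_first, t_last, n)

    rotated, angle = rotate_to_vertical(arr, line)
    roi_mask = roi.to_mask(rotated.shape[1:])
    masks = segment_wound(
        rotated, thresholds, roi_mask, min_object_size=segmentation.remove_small_objects
    )

    px = acquisition.pixel_size
    times = np.arange(n, dtype=float) * acquisition.timelapse_interval
    area_px = masks.reshape(n, -1).sum(axis=1).astype(float)
    wmin = np.empty(n)
    wmean = np.empty(n)
    wmax = np.empty(n)
    for i in range(n):
        _, (wmin[i], wmean[i], wmax[i]) = width_profile(masks[i], roi_mask)
    closure = wound_closure(area_px)

    trace = WoundTrace(
        times=times,
        area_px=area_px,
        area_um2=area_px * px * px,
        width_min_px=wmin, width_mean_px=wmean, width_max_px=wmax,
        width_min_um=wmin * px, width_mean_um=wmean * px, width_max_um=wmax * px,
        closure_pct=closure,
    )
    fit = fit_biexponential(times, trace.width_mean_um, segmentation.closing_limit)
    report = {
        "threshold_first": t_first,
        "threshold_last": t_last,
        "rotation_angle_deg": angle,
        "n_frames": n,
        "roi_area_px": int(roi_mask.sum()),
        "fit_summary": fit.summary(),
    }
    return SaveProfilerResult(trace=trace, fit=fit, masks=masks, report=report)
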