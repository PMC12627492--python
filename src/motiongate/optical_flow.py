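"""Markerless single-keypoint tracking by windowed Lucas–Kanade optical flow.

The brightness-constancy assumption I(x, y, t) = I(x+dx, y+dy, t+dt),
linearised to first order, gives the optical flow constraint equation

    Ix * u + Iy * v + It = 0,

one equation per pixel in two unknowns (u, v).  Lucas–Kanade resolves the
ambiguity by assuming the flow is constant over a small window around the
point of interest and solving the stacked system A v = b in least squares
via the Moore–Penrose pseudoinverse, v = (A^T A)^{-1} A^T b, where the
rows of A are (Ix, Iy) at the window pixels and b collects -It.

The normal matrix A^T A is the structure tensor of the window: its
smallest eigenvalue measures how well-conditioned the flow estimate is.
Below a threshold the window is aperture-limited (an edge or a flat
region) and the flow is reported as undefined rather than solved — for a
gating application a missed estimate is safer than a wrong one.

Units: one frame is the time unit, so (u, v) are px/frame; multiply by
the frame rate for px/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .frames import LOST, TRACKED, ImageFrame, Trajectory


class WindowOutsideFrameError(ValueError):
    """The sampling window left the valid image area (tracking failure at border)."""


def _pixels(frame) -> np.ndarray:
    return frame.pixels if isinstance(frame, ImageFrame) else np.asarray(frame, dtype=float)


def spatial_gradients(frame) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference spatial gradients (Ix, Iy) with replicated borders.

    The image is padded by edge replication before differencing, so border
    gradients are (f[1] - f[0]) / 2 — consistent with the interior stencil
    rather than switching to a one-sided scheme.
    """
    img = _pixels(frame)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("frame must be 2D and at least 3x3")
    padded = np.pad(img, 1, mode="edge")
    ix = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    iy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return ix, iy


def temporal_gradient(frame_a, frame_b) -> np.ndarray:
    """It = I_b - I_a per pixel (dt = 1 frame)."""
    a, b = _pixels(frame_a), _pixels(frame_b)
    if a.shape != b.shape:
        raise ValueError(f"frame shapes differ: {a.shape} vs {b.shape}")
    return b - a


@dataclass
class GradientField:
    """Spatial and temporal intensity derivatives on the frame grid."""

    ix: np.ndarray
    iy: np.ndarray
    it: np.ndarray

    def __post_init__(self) -> None:
        if not (self.ix.shape == self.iy.shape == self.it.shape):
            raise ValueError("gradient components must share one shape")


@dataclass
class FlowSystem:
    """The stacked window system A v = b around one point."""

    a: np.ndarray  # (n, 2) rows of (Ix, Iy)
    b: np.ndarray  # (n,) of -It, same pixel order as the rows of a
    window_halfwidth: int
    center: np.ndarray

    @property
    def n(self) -> int:
        return self.a.shape[0]


@dataclass
class FlowVector:
    """Lucas–Kanade flow estimate with its conditioning diagnostics."""

    u: float
    v: float
    min_eigenvalue: float
    residual: float
    valid: bool = True

    @property
    def displacement(self) -> np.ndarray:
        return np.array([self.u, self.v])


def _window_offsets(halfwidth: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    return dx.ravel(), dy.ravel()


def _sample(fieldarr: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Bilinear samples; caller guarantees coordinates are in bounds."""
    return map_coordinates(fieldarr, [ys, xs], order=1, mode="nearest")


def _check_window(shape, center, halfwidth) -> None:
    cx, cy = center
    ny, nx = shape
    if (
        cx - halfwidth < 0
        or cy - halfwidth < 0
        or cx + halfwidth > nx - 1
        or cy + halfwidth > ny - 1
    ):
        raise WindowOutsideFrameError(
            f"window of half-width {halfwidth} around ({cx:.2f}, {cy:.2f}) "
            f"leaves the {ny}x{nx} frame"
        )


def assemble_system(
    gradients: GradientField,
    center,
    window_halfwidth: int,
) -> FlowSystem:
    """Stack the window pixels of the gradient fields into A and b.

    At non-integer centers the fields are sampled bilinearly; at integer
    centers the rows are exact grid lookups.
    """
    if window_halfwidth < 1:
        raise ValueError("window_halfwidth must be >= 1")
    center = np.asarray(center, dtype=float)
    _check_window(gradients.ix.shape, center, window_halfwidth)
    dx, dy = _window_offsets(window_halfwidth)
    xs, ys = center[0] + dx, center[1] + dy
    a = np.column_stack([_sample(gradients.ix, xs, ys), _sample(gradients.iy, xs, ys)])
    b = -_sample(gradients.it, xs, ys)
    return FlowSystem(a=a, b=b, window_halfwidth=window_halfwidth, center=center)


def default_min_eig_threshold(window_halfwidth: int) -> float:
    """Scale-aware conditioning threshold: 1e-4 per window pixel."""
    n = (2 * window_halfwidth + 1) ** 2
    return 1e-4 * n


def lk_solve(system: FlowSystem, min_eig_threshold: float | None = None) -> FlowVector:
    """Solve A v = b by the normal equations, guarded by the structure tensor.

    Returns an invalid (aperture-limited) :class:`FlowVector` when the
    smallest eigenvalue of A^T A falls below the threshold; a solution is
    never produced from a near-singular normal matrix.
    """
    if min_eig_threshold is None:
        min_eig_threshold = default_min_eig_threshold(system.window_halfwidth)
    ata = system.a.T @ system.a
    min_eig = float(np.linalg.eigvalsh(ata)[0])
    if min_eig < min_eig_threshold:
        return FlowVector(
            u=math.nan, v=math.nan, min_eigenvalue=min_eig, residual=math.nan, valid=False
        )
    atb = system.a.T @ system.b
    sol = np.linalg.solve(ata, atb)
    residual = float(np.linalg.norm(system.a @ sol - system.b))
    return FlowVector(
        u=float(sol[0]),
        v=float(sol[1]),
        min_eigenvalue=min_eig,
        residual=residual,
        valid=True,
    )


@dataclass(frozen=True)
class TrackerParams:
    """Configuration of the iterative (optionally pyramidal) LK tracker."""

    window_halfwidth: int = 7
    max_iters: int = 10
    conv_tol_px: float = 0.01
    pyramid_levels: int = 2
    min_eig_threshold: float | None = None  # None -> scale-aware default


@dataclass
class StepDiagnostics:
    flow: FlowVector
    iterations: int
    converged: bool


def _lk_refine(
    img_a: np.ndarray,
    img_b: np.ndarray,
    point: np.ndarray,
    d0: np.ndarray,
    params: TrackerParams,
) -> tuple[np.ndarray, FlowVector, str, StepDiagnostics]:
    """Iterate solve-and-warp at one pyramid level, starting from guess d0."""
    hw = params.window_halfwidth
    thr = (
        params.min_eig_threshold
        if params.min_eig_threshold is not None
        else default_min_eig_threshold(hw)
    )
    ix, iy = spatial_gradients(img_a)
    try:
        _check_window(img_a.shape, point, hw)
    except WindowOutsideFrameError:
        flow = FlowVector(math.nan, math.nan, 0.0, math.nan, valid=False)
        return d0, flow, LOST, StepDiagnostics(flow, 0, False)
    dx, dy = _window_offsets(hw)
    xs, ys = point[0] + dx, point[1] + dy
    a = np.column_stack([_sample(ix, xs, ys), _sample(iy, xs, ys)])
    i_a = _sample(img_a, xs, ys)
    ata = a.T @ a
    min_eig = float(np.linalg.eigvalsh(ata)[0])
    if min_eig < thr:
        flow = FlowVector(math.nan, math.nan, min_eig, math.nan, valid=False)
        return d0, flow, LOST, StepDiagnostics(flow, 0, False)

    d = np.asarray(d0, dtype=float).copy()
    span = 2 * hw + 1
    converged = False
    it_count = 0
    last = np.zeros(2)
    for it_count in range(1, params.max_iters + 1):
        try:
            _check_window(img_b.shape, point + d, hw)
        except WindowOutsideFrameError:
            flow = FlowVector(d[0], d[1], min_eig, math.nan, valid=False)
            return d0, flow, LOST, StepDiagnostics(flow, it_count, False)
        i_b = _sample(img_b, xs + d[0], ys + d[1])
        b = -(i_b - i_a)
        step = np.linalg.solve(ata, a.T @ b)
        d += step
        last = step
        if np.linalg.norm(d - np.asarray(d0)) > span:
            flow = FlowVector(d[0], d[1], min_eig, math.nan, valid=False)
            return d0, flow, LOST, StepDiagnostics(flow, it_count, False)
        if np.linalg.norm(step) < params.conv_tol_px:
            converged = True
            break
    if not converged:
        flow = FlowVector(d[0], d[1], min_eig, float(np.linalg.norm(a @ last + b)), valid=False)
        return d0, flow, LOST, StepDiagnostics(flow, it_count, False)
    residual = float(np.linalg.norm(a @ (d - np.asarray(d0)) - b))
    flow = FlowVector(d[0], d[1], min_eig, residual, valid=True)
    return d, flow, TRACKED, StepDiagnostics(flow, it_count, True)


def _pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    """Coarse-to-fine pyramid: Gaussian smooth (sigma 1) then 2x decimation."""
    pyr = [img]
    for _ in range(levels - 1):
        prev = pyr[-1]
        if min(prev.shape) < 16:
            break
        pyr.append(gaussian_filter(prev, 1.0)[::2, ::2])
    return pyr


def track_step(
    frame_a,
    frame_b,
    point,
    params: TrackerParams = TrackerParams(),
) -> tuple[np.ndarray, FlowVector, str]:
    """Track one point from ``frame_a`` to ``frame_b``.

    Coarse-to-fine: the displacement found at each pyramid level seeds the
    next finer level; at each level the window of ``frame_b`` is warped by
    the running estimate and the system re-solved until the update falls
    below ``conv_tol_px``.  Divergence (displacement beyond the window
    span), aperture-limited windows, border exits and non-convergence all
    yield status ``"lost"`` with the position frozen at the input point.
    """
    img_a, img_b = _pixels(frame_a), _pixels(frame_b)
    point = np.asarray(point, dtype=float)
    pyr_a = _pyramid(img_a, params.pyramid_levels)
    pyr_b = _pyramid(img_b, params.pyramid_levels)
    levels = min(len(pyr_a), len(pyr_b))
    d = np.zeros(2)
    flow = FlowVector(0.0, 0.0, 0.0, 0.0, valid=False)
    for level in range(levels - 1, -1, -1):
        scale = 2.0**level
        pt = point / scale
        new_d, flow, status, _ = _lk_refine(pyr_a[level], pyr_b[level], pt, d / scale, params)
        if status == LOST and level == 0:
            return point, flow, LOST
        if status == LOST:
            # coarse failure: fall through with the current guess
            continue
        d = new_d * scale
    if not flow.valid:
        return point, flow, LOST
    total = FlowVector(d[0], d[1], flow.min_eigenvalue, flow.residual, valid=True)
    return point + d, total, TRACKED


def track_sequence(
    frames,
    initial_point,
    params: TrackerParams = TrackerParams(),
) -> Trajectory:
    """Chain :func:`track_step` over a frame sequence.

    Frame 0 carries the user-defined initial point.  After a lost frame
    the position is frozen and re-acquisition is attempted from the same
    point on every subsequent frame (no extrapolation): for gating, a
    closed gate is the safe failure mode.
    """
    frames = list(frames)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    pos = np.asarray(initial_point, dtype=float)
    idx = [frames[0].frame_index]
    ts = [frames[0].timestamp]
    xs, ys, status = [pos[0]], [pos[1]], [TRACKED]
    for prev, cur in zip(frames[:-1], frames[1:]):
        pos, _, st = track_step(prev, cur, pos, params)
        idx.append(cur.frame_index)
        ts.append(cur.timestamp)
        xs.append(pos[0])
        ys.append(pos[1])
        status.append(st)
    return Trajectory(
        frame_index=np.asarray(idx),
        t=np.asarray(ts),
        x=np.asarray(xs),
        y=np.asarray(ys),
        status=np.asarray(status, dtype=object),
    )
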