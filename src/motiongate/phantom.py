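"""Digital insect phantom with semi-periodic abdominal motion.

A segmented 2D phantom — head, thorax, abdomen and an internal feature,
each an intensity-weighted ellipse — stands in for a tethered insect on a
spherical treadmill.  The abdomen (and any feature inside it) flexes
rigidly in-plane about a pivot at the thorax–abdomen junction, while head
and thorax stay fixed; this reproduces the gross body-motion regime in
which abdominal flexion dominates and thorax motion is negligible.

The same phantom is rendered two ways: as camera video frames (the
tracker's input, with ground-truth keypoint positions) and as the
instantaneous object seen by the MRI simulator.

Coordinate conventions
----------------------
Physical coordinates are millimetres with the origin at the centre of
pixel (0, 0); x increases along columns (rightward), y along rows
(downward).  A positive rotation angle turns +x toward +y, i.e. clockwise
on screen.  Continuous pixel positions are pixel-center based:
``px = mm / pitch_mm``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .frames import ImageFrame, Trajectory

MOVING_LABELS = frozenset({"abdomen", "internal-feature"})
VALID_LABELS = frozenset({"head", "thorax", "abdomen", "internal-feature"})

#: micrometres per camera pixel implied by the paired benchmark statements
#: 2.04 px <-> 91 um (91 / 2.04 = 44.6); a configuration default, not a
#: measured camera property.
DEFAULT_PIXEL_PITCH_UM = 44.6

DEFAULT_FRAME_RATE_HZ = 30.0  # camera maximum frame rate


@dataclass(frozen=True)
class Segment:
    """One elliptical phantom segment."""

    label: str
    center_mm: tuple[float, float]
    semiaxes_mm: tuple[float, float]
    intensity: float

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError(f"segment {self.label!r}: intensity must be in [0, 1]")
        if min(self.semiaxes_mm) <= 0:
            raise ValueError(f"segment {self.label!r}: semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the segmented insect phantom.

    ``pivot_mm`` is the thorax–abdomen junction about which the abdomen
    rotates; ``keypoint_mm`` is the tracked point on the posterior abdomen
    boundary.
    """

    segments: tuple[Segment, ...]
    pivot_mm: tuple[float, float]
    keypoint_mm: tuple[float, float]
    body_frame_extent_mm: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)


def default_phantom_spec() -> PhantomSpec:
    """A beetle-like phantom in a 30 mm body frame.

    The abdomen is the largest, brightest segment; an internal feature
    (digestive tract) gives it interior texture so the tracker and the
    reconstruction both see structure, not just an outline.  The keypoint
    sits at the posterior abdomen tip, 10.2 mm behind the pivot.
    """
    return PhantomSpec(
        segments=(
            Segment("head", (7.5, 15.0), (2.0, 1.8), 0.55),
            Segment("thorax", (12.0, 15.0), (3.2, 2.6), 0.80),
            Segment("abdomen", (19.5, 15.0), (5.5, 3.4), 0.95),
            Segment("internal-feature", (19.5, 15.0), (3.2, 1.3), 0.05),
        ),
        pivot_mm=(14.8, 15.0),
        keypoint_mm=(25.0, 15.0),
        body_frame_extent_mm=30.0,
    )


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rigid motion: rotation about a pivot, then translation."""

    rotation_rad: float = 0.0
    translation_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def is_identity(self) -> bool:
        return self.rotation_rad == 0.0 and self.translation_mm == (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        # positive angle rotates +x toward +y
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "RigidTransform2D":
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        tx, ty = self.translation_mm
        # inverse of p -> R(p - pivot) + pivot + t, expressed in the same form
        itx = -(c * tx + s * ty)
        ity = -(-s * tx + c * ty)
        return RigidTransform2D(-self.rotation_rad, (itx, ity))


def apply_transform(
    transform: RigidTransform2D,
    point_mm: np.ndarray,
    pivot_mm: np.ndarray,
) -> np.ndarray:
    """Rotate ``point_mm`` about ``pivot_mm``, then translate.

    Works on a single (2,) point or an (n, 2) stack.
    """
    p = np.asarray(point_mm, dtype=float)
    pivot = np.asarray(pivot_mm, dtype=float)
    rotated = (p - pivot) @ transform.matrix().T + pivot
    return rotated + np.asarray(transform.translation_mm)


@dataclass(frozen=True)
class MotionModel:
    """Semi-periodic abdominal flexion.

    Each motion cycle consists of a rest (dwell) window followed by a
    raised-cosine flexion pulse rest -> flexed -> rest.  Semi-periodicity is
    realised by jittering every cycle's period with an independent Normal
    draw from a seeded stream, so the waveform never exactly repeats but
    keeps a characteristic rhythm.

    Parameters
    ----------
    angular_amplitude_deg : peak abdomen rotation about the pivot.
    base_period_s : nominal cycle length.
    period_jitter_sd_s : standard deviation of the per-cycle period jitter.
    translation_amplitude_mm : peak in-plane translation, applied with the
        same waveform as the rotation.
    dwell_fraction : fraction of each cycle spent exactly at the rest pose.
    phase_offset_rad : shifts the cycle phase at t = 0.
    rng_seed : seeds the jitter stream; fully determines the realisation.
    """

    angular_amplitude_deg: float = 20.0
    base_period_s: float = 1.0
    period_jitter_sd_s: float = 0.15
    translation_amplitude_mm: tuple[float, float] = (0.2, 0.1)
    dwell_fraction: float = 0.45
    phase_offset_rad: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_period_s <= 0:
            raise ValueError("base_period_s must be positive")
        if not 0.0 <= self.dwell_fraction < 1.0:
            raise ValueError("dwell_fraction must be in [0, 1)")
        if self.angular_amplitude_deg < 0 or self.period_jitter_sd_s < 0:
            raise ValueError("amplitudes and jitter must be non-negative")


class MotionSampler:
    """Evaluates a :class:`MotionModel` at arbitrary times.

    Cycle boundaries are generated lazily from the seeded stream and
    cached, so repeated evaluation is cheap and deterministic: the k-th
    cycle's period is the k-th draw regardless of query order.
    """

    _MIN_PERIOD_FACTOR = 0.1  # truncation keeping jittered periods positive

    def __init__(self, model: MotionModel):
        self.model = model
        self._rng = np.random.default_rng(model.rng_seed)
        self._edges = [0.0]  # cumulative cycle start times

    def _period(self, draw: float) -> float:
        m = self.model
        return max(m.base_period_s + draw, self._MIN_PERIOD_FACTOR * m.base_period_s)

    def _extend_to(self, t: float) -> None:
        m = self.model
        while self._edges[-1] <= t:
            draw = float(self._rng.normal(0.0, m.period_jitter_sd_s)) if (
                m.period_jitter_sd_s > 0
            ) else 0.0
            self._edges.append(self._edges[-1] + self._period(draw))

    def cycle_edges(self, t_max: float) -> np.ndarray:
        """Cycle start times covering [0, t_max]."""
        self._extend_to(t_max)
        return np.asarray(self._edges)

    def __call__(self, t: float) -> RigidTransform2D:
        if t < 0:
            raise ValueError("t must be non-negative")
        m = self.model
        t_eff = t + (m.phase_offset_rad % (2 * math.pi)) / (2 * math.pi) * m.base_period_s
        self._extend_to(t_eff)
        k = int(np.searchsorted(self._edges, t_eff, side="right")) - 1
        start = self._edges[k]
        period = self._edges[k + 1] - self._edges[k]
        tau = t_eff - start
        dwell = m.dwell_fraction * period
        if tau < dwell:
            return RigidTransform2D()
        s = (tau - dwell) / (period - dwell)
        w = 0.5 * (1.0 - math.cos(2.0 * math.pi * s))
        angle = math.radians(m.angular_amplitude_deg) * w
        tx, ty = m.translation_amplitude_mm
        if angle == 0.0 and w * tx == 0.0 and w * ty == 0.0:
            return RigidTransform2D()
        return RigidTransform2D(angle, (w * tx, w * ty))


def eval_motion(model: MotionModel, t: float) -> RigidTransform2D:
    """One-shot evaluation; use :class:`MotionSampler` inside loops."""
    return MotionSampler(model)(t)


class SegmentOutsideFOVError(ValueError):
    pass


@dataclass
class Phantom:
    """A phantom rendered onto a pixel grid, split into static and moving parts."""

    spec: PhantomSpec
    grid: tuple[int, int]
    fov_mm: float
    image: np.ndarray
    masks: dict
    static_image: np.ndarray
    moving_image: np.ndarray
    _coords: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def pitch_mm(self) -> float:
        return self.fov_mm / self.grid[1]

    @property
    def pitch_um(self) -> float:
        return 1000.0 * self.pitch_mm

    def mm_to_px(self, point_mm) -> np.ndarray:
        return np.asarray(point_mm, dtype=float) / self.pitch_mm

    def px_to_mm(self, point_px) -> np.ndarray:
        return np.asarray(point_px, dtype=float) * self.pitch_mm

    def _pixel_centers_mm(self) -> np.ndarray:
        """(2, ny, nx) stack of (x_mm, y_mm) pixel-centre coordinates."""
        if self._coords is None:
            ny, nx = self.grid
            ys, xs = np.mgrid[0:ny, 0:nx]
            self._coords = np.stack([xs * self.pitch_mm, ys * self.pitch_mm])
        return self._coords

    def warp_moving(self, transform: RigidTransform2D) -> np.ndarray:
        """Moving-part image with ``transform`` applied (bilinear, zeros outside)."""
        if transform.is_identity:
            return self.moving_image
        x_mm, y_mm = self._pixel_centers_mm()
        pts = np.stack([x_mm.ravel(), y_mm.ravel()], axis=1)
        inv = transform.inverse()
        src = apply_transform(inv, pts, np.asarray(self.spec.pivot_mm))
        cols = src[:, 0] / self.pitch_mm
        rows = src[:, 1] / self.pitch_mm
        warped = map_coordinates(
            self.moving_image,
            [rows.reshape(self.grid), cols.reshape(self.grid)],
            order=1,
            mode="constant",
            cval=0.0,
        )
        return warped

    def image_at(self, transform: RigidTransform2D) -> np.ndarray:
        """Instantaneous phantom image under ``transform`` of the abdomen."""
        return self.static_image + self.warp_moving(transform)


def _ellipse_coverage(
    segment: Segment, grid: tuple[int, int], pitch_mm: float, supersample: int = 4
) -> np.ndarray:
    """Fractional pixel coverage of one ellipse via supersampled indicators."""
    ny, nx = grid
    cx, cy = segment.center_mm
    ax, ay = segment.semiaxes_mm
    # bounding box in pixels, padded one pixel for anti-aliasing
    x0 = max(0, int(np.floor((cx - ax) / pitch_mm)) - 1)
    x1 = min(nx - 1, int(np.ceil((cx + ax) / pitch_mm)) + 1)
    y0 = max(0, int(np.floor((cy - ay) / pitch_mm)) - 1)
    y1 = min(ny - 1, int(np.ceil((cy + ay) / pitch_mm)) + 1)
    cov = np.zeros(grid)
    if x1 < x0 or y1 < y0:
        return cov
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    ys = (np.arange(y0, y1 + 1)[:, None] + offs[None, :]).ravel() * pitch_mm
    xs = (np.arange(x0, x1 + 1)[:, None] + offs[None, :]).ravel() * pitch_mm
    u = (xs[None, :] - cx) / ax
    v = (ys[:, None] - cy) / ay
    inside = (u * u + v * v) <= 1.0
    block = inside.reshape(y1 - y0 + 1, supersample, x1 - x0 + 1, supersample)
    cov[y0 : y1 + 1, x0 : x1 + 1] = block.mean(axis=(1, 3))
    return cov


def build_phantom(
    spec: PhantomSpec, grid: tuple[int, int], fov_mm: float, supersample: int = 4
) -> Phantom:
    """Render ``spec`` onto a grid as an anti-aliased intensity image.

    The image is the sum of the segments' ellipse indicator functions
    weighted by intensity (linear in intensities by construction).  Masks
    assign each claimed pixel (coverage >= 0.5) to the last-drawn segment
    label covering it.  Raises :class:`SegmentOutsideFOVError` naming any
    segment whose bounding box leaves the field of view.
    """
    ny, nx = grid
    if ny < 16 or nx < 16:
        raise ValueError("grid dimensions must be at least 16")
    pitch_mm = fov_mm / nx
    image = np.zeros(grid)
    static = np.zeros(grid)
    moving = np.zeros(grid)
    label_map = np.full(grid, "", dtype=object)
    for seg in spec.segments:
        cx, cy = seg.center_mm
        ax, ay = seg.semiaxes_mm
        if cx - ax < 0 or cx + ax > fov_mm or cy - ay < 0 or cy + ay > fov_mm:
            raise SegmentOutsideFOVError(
                f"segment {seg.label!r} extends outside the {fov_mm} mm FOV"
            )
        cov = _ellipse_coverage(seg, grid, pitch_mm, supersample)
        contrib = seg.intensity * cov
        image += contrib
        if seg.label in MOVING_LABELS:
            moving += contrib
        else:
            static += contrib
        label_map[cov >= 0.5] = seg.label
    masks = {
        seg.label: label_map == seg.label
        for seg in spec.segments
    }
    return Phantom(
        spec=spec,
        grid=grid,
        fov_mm=fov_mm,
        image=image,
        masks=masks,
        static_image=static,
        moving_image=moving,
    )


def render_frame(
    phantom: Phantom,
    transform: RigidTransform2D,
    t: float,
    frame_index: int = 0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[ImageFrame, np.ndarray]:
    """Render one camera frame and the ground-truth keypoint position (px).

    The abdomen (and internal feature) is drawn at its transformed
    position by bilinear resampling; head and thorax are static.  Additive
    zero-mean Gaussian noise comes from ``rng`` when ``noise_sd > 0``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    pixels = phantom.image_at(transform)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    kp_mm = apply_transform(
        transform, np.asarray(phantom.spec.keypoint_mm), np.asarray(phantom.spec.pivot_mm)
    )
    frame = ImageFrame(
        pixels=pixels,
        timestamp=t,
        frame_index=frame_index,
        pixel_pitch_um=phantom.pitch_um,
    )
    return frame, phantom.mm_to_px(kp_mm)


def generate_sequence(
    model: MotionModel,
    phantom: Phantom,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    duration_s: float = 1.0,
    noise_sd: float = 0.0,
    noise_seed: int = 0,
) -> tuple[list[ImageFrame], Trajectory]:
    """Film the moving phantom: ``floor(duration * rate) + 1`` uniform frames.

    Returns the frame stack and the ground-truth keypoint trajectory
    aligned by frame index (positions in pixels).
    """
    if frame_rate_hz <= 0 or duration_s < 0:
        raise ValueError("frame_rate_hz must be positive and duration_s >= 0")
    n_frames = int(math.floor(duration_s * frame_rate_hz)) + 1
    sampler = MotionSampler(model)
    rng = np.random.default_rng(noise_seed)
    frames: list[ImageFrame] = []
    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    ts = np.empty(n_frames)
    for k in range(n_frames):
        t = k / frame_rate_hz
        frame, kp = render_frame(
            phantom, sampler(t), t, frame_index=k, noise_sd=noise_sd, rng=rng
        )
        frames.append(frame)
        ts[k] = t
        xs[k], ys[k] = kp
    traj = Trajectory(frame_index=np.arange(n_frames), t=ts, x=xs, y=ys)
    return frames, traj


def frame_stream(
    model: MotionModel,
    phantom: Phantom,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    max_duration_s: float = math.inf,
    noise_sd: float = 0.0,
    noise_seed: int = 0,
):
    """Lazy generator of frames for open-ended (gated) sessions."""
    sampler = MotionSampler(model)
    rng = np.random.default_rng(noise_seed)
    k = 0
    while True:
        t = k / frame_rate_hz
        if t > max_duration_s:
            return
        frame, _ = render_frame(
            phantom, sampler(t), t, frame_index=k, noise_sd=noise_sd, rng=rng
        )
        yield frame
        k += 1
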