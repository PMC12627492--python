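"""Cartesian RARE k-space acquisition under inter-scan rigid motion.

The simulator adopts the inter-scan motion model: the object is frozen
for the duration of one shot (one excitation and its echo train — echo
sampling takes milliseconds, over which the abdominal motion is
negligible) but may move between shots.  Each shot therefore samples the
2D discrete Fourier transform of the *instantaneous* object at its fire
time and keeps only that shot's phase-encode lines; motion between shots
scrambles the phase consistency across k-space rows and produces the
familiar phase-encode ghosting.

Proton-density-only physics: no T1/T2 weighting or echo-train decay is
modeled, so image contrast is the phantom's intensity map.  k-space is
stored with the DC sample at the matrix centre (fftshift convention) and
phase encoding along axis 0 (each row is one PE line).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import phantom as ph
from .frames import Trajectory
from .gating import GateLog, GatingConfig, run_gated_session
from .optical_flow import TrackerParams


@dataclass(frozen=True)
class SequenceParams:
    """Cartesian RARE protocol parameters.

    Defaults follow the sagittal whole-body protocol: 256 x 256 matrix
    over a 30 mm FOV (117 um in-plane), TE 5 ms, TR 1000 ms, RARE factor
    1 — the single-echo choice that minimizes intra-train motion
    sensitivity during gated acquisition.
    """

    n_read: int = 256
    n_pe: int = 256
    fov_mm: tuple[float, float] = (30.0, 30.0)
    tr_ms: float = 1000.0
    te_ms: float = 5.0
    rare_factor: int = 1
    n_averages: int = 1
    pe_ordering: str = "linear-interleaved"
    slice_thickness_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.n_read < 8 or self.n_pe < 8:
            raise ValueError("matrix dimensions must be at least 8")
        if self.rare_factor < 1 or self.rare_factor > self.n_pe:
            raise ValueError("rare_factor must be in [1, n_pe]")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.pe_ordering not in ("linear-interleaved", "sequential"):
            raise ValueError(f"unknown pe_ordering {self.pe_ordering!r}")

    @property
    def shots_per_average(self) -> int:
        return self.n_pe // self.rare_factor

    @property
    def shot_duration_s(self) -> float:
        """The engine is busy one TR per shot (echo train plus recovery)."""
        return self.tr_ms / 1000.0


def scan_time(seq: SequenceParams) -> float:
    """Total acquisition time in seconds.

    ``floor(n_pe / rare_factor)`` shots per average, one TR each:
    256 PE / RARE 1 / TR 1000 ms -> 256 s; 512 PE / RARE 4 -> 128 s;
    1024 PE / RARE 3 / TR 3000 ms / 5 averages -> 5115 s.
    """
    return seq.shots_per_average * (seq.tr_ms / 1000.0) * seq.n_averages


def in_plane_resolution(fov_mm: float, n: int) -> tuple[float, int]:
    """In-plane resolution: exact value in um and the reported integer.

    The reported figure uses round-half-even, matching the printed
    protocol values (e.g. 40 mm / 128 = 312.5 -> 312 um).
    """
    if n < 1 or fov_mm <= 0:
        raise ValueError("need n >= 1 and fov_mm > 0")
    exact = 1000.0 * fov_mm / n
    return exact, int(round(exact))


def pe_schedule(n_pe: int, rare_factor: int, ordering: str = "linear-interleaved"):
    """Phase-encode line indices per shot.

    linear-interleaved (default): shot s acquires {s, s+S, s+2S, ...}
    with S = floor(n_pe / rare_factor) shots, so consecutive echoes of
    one train are spread S lines apart.  sequential: shot s acquires the
    contiguous block [s*rare, (s+1)*rare).  Remainder lines (when
    rare_factor does not divide n_pe) are never acquired and stay
    zero-filled, consistent with the floor in :func:`scan_time`.
    """
    if rare_factor < 1 or rare_factor > n_pe:
        raise ValueError("rare_factor must be in [1, n_pe]")
    n_shots = n_pe // rare_factor
    if ordering == "linear-interleaved":
        return [[s + j * n_shots for j in range(rare_factor)] for s in range(n_shots)]
    if ordering == "sequential":
        return [[s * rare_factor + j for j in range(rare_factor)] for s in range(n_shots)]
    raise ValueError(f"unknown pe_ordering {ordering!r}")


def image_to_kspace(image: np.ndarray) -> np.ndarray:
    """Centered 2D DFT: DC at the matrix centre in both domains."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def kspace_to_image(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`image_to_kspace` (complex image)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace)))


def acquire_shot(instantaneous_image: np.ndarray, pe_indices) -> np.ndarray:
    """Extract one shot's PE lines from the frozen object's k-space."""
    k = image_to_kspace(np.asarray(instantaneous_image, dtype=float))
    return k[np.asarray(pe_indices, dtype=int), :]


@dataclass
class KSpaceData:
    """Complex k-space with per-line acquisition provenance.

    ``samples`` is (n_pe, n_read) with phase encoding along axis 0.
    Unacquired lines are zero with ``line_time_s`` NaN and ``line_shot``
    -1.
    """

    samples: np.ndarray
    line_time_s: np.ndarray
    line_shot: np.ndarray
    seq: SequenceParams
    complete: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_acquired_lines(self) -> int:
        return int(np.sum(self.line_shot >= 0))


@dataclass
class ReconImage:
    """Magnitude reconstruction with its acquisition provenance."""

    magnitude: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude image must be non-negative")


def reconstruct(kspace: KSpaceData | np.ndarray, provenance: dict | None = None) -> ReconImage:
    """Magnitude of the inverse 2D DFT; zero-filled lines contribute zeros."""
    samples = kspace.samples if isinstance(kspace, KSpaceData) else np.asarray(kspace)
    prov = dict(provenance or {})
    if isinstance(kspace, KSpaceData):
        prov.setdefault("complete", kspace.complete)
        prov.update(kspace.meta)
    return ReconImage(magnitude=np.abs(kspace_to_image(samples)), provenance=prov)


class ShotEngine:
    """Acquisition back end: one trigger releases one RARE shot.

    Holds the shot schedule and fills k-space from the scene frozen at
    each shot's fire time.  With ``n_averages > 1`` the schedule repeats
    and coinciding lines are averaged.
    """

    def __init__(
        self,
        seq: SequenceParams,
        scene,
        noise_sd: float = 0.0,
        noise_seed: int = 0,
    ):
        self.seq = seq
        self.scene = scene  # callable t -> instantaneous image (n_pe, n_read)
        self.schedule = pe_schedule(seq.n_pe, seq.rare_factor, seq.pe_ordering)
        self.noise_sd = noise_sd
        self._rng = np.random.default_rng(noise_seed)
        self._acc = np.zeros((seq.n_pe, seq.n_read), dtype=complex)
        self._counts = np.zeros(seq.n_pe, dtype=int)
        self._line_time = np.full(seq.n_pe, np.nan)
        self._line_shot = np.full(seq.n_pe, -1, dtype=int)

    @property
    def shots_required(self) -> int:
        return len(self.schedule) * self.seq.n_averages

    @property
    def shot_duration_s(self) -> float:
        return self.seq.shot_duration_s

    def acquire(self, shot_index: int, fire_time: float) -> None:
        pe_indices = self.schedule[shot_index % len(self.schedule)]
        lines = acquire_shot(self.scene(fire_time), pe_indices)
        if self.noise_sd > 0:
            lines = lines + self.noise_sd * (
                self._rng.standard_normal(lines.shape)
                + 1j * self._rng.standard_normal(lines.shape)
            )
        rows = np.asarray(pe_indices, dtype=int)
        self._acc[rows, :] += lines
        self._counts[rows] += 1
        self._line_time[rows] = fire_time
        self._line_shot[rows] = shot_index

    def finalize(self, complete: bool) -> KSpaceData:
        samples = self._acc.copy()
        seen = self._counts > 0
        samples[seen, :] /= self._counts[seen, None]
        return KSpaceData(
            samples=samples,
            line_time_s=self._line_time.copy(),
            line_shot=self._line_shot.copy(),
            seq=self.seq,
            complete=complete,
        )


def make_scene(spec: ph.PhantomSpec, model: ph.MotionModel, seq: SequenceParams):
    """Instantaneous-object renderer on the MRI grid.

    Returns ``(scene, phantom)`` where ``scene(t)`` is the phantom image
    at time t on the (n_pe, n_read) grid; the same motion realisation
    (seeded jitter stream) drives both the camera and the scanner views.
    """
    mri_phantom = ph.build_phantom(spec, (seq.n_pe, seq.n_read), seq.fov_mm[0])
    sampler = ph.MotionSampler(model)

    def scene(t: float) -> np.ndarray:
        return mri_phantom.image_at(sampler(t))

    return scene, mri_phantom


def acquire_series(
    seq: SequenceParams,
    spec: ph.PhantomSpec,
    model: ph.MotionModel,
    gate: GatingConfig | None = None,
    tracker_params: TrackerParams | None = None,
    camera_grid: tuple[int, int] = (128, 128),
    camera_frame_rate_hz: float = ph.DEFAULT_FRAME_RATE_HZ,
    camera_noise_sd: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Acquire a full k-space series, ungated or prospectively gated.

    Ungated: shots fire on a fixed TR raster starting at t = 0, each
    sampling the object at its fire time.  Gated: camera frames of the
    same moving phantom feed the Lucas–Kanade tracker and the gating
    controller; triggers release shots per :mod:`motiongate.gating`.

    Returns ``(KSpaceData, GateLog | None, Trajectory | None)``.
    """
    scene, _ = make_scene(spec, model, seq)
    engine = ShotEngine(seq, scene, noise_sd=noise_sd, noise_seed=seed)

    if gate is None:
        tr_s = seq.tr_ms / 1000.0
        for s in range(engine.shots_required):
            engine.acquire(s, s * tr_s)
        return engine.finalize(True), None, None

    cam_phantom = ph.build_phantom(spec, camera_grid, spec.body_frame_extent_mm)
    stream = ph.frame_stream(
        model,
        cam_phantom,
        frame_rate_hz=camera_frame_rate_hz,
        max_duration_s=gate.timeout_s,
        noise_sd=camera_noise_sd,
        noise_seed=seed + 1,
    )
    sampler = ph.MotionSampler(model)
    pivot = np.asarray(spec.pivot_mm)
    keypoint = np.asarray(spec.keypoint_mm)

    def true_position_at(t: float) -> np.ndarray:
        return cam_phantom.mm_to_px(ph.apply_transform(sampler(t), keypoint, pivot))

    initial = cam_phantom.mm_to_px(keypoint)
    if tracker_params is None:
        tracker_params = TrackerParams()
    kspace, log, traj = run_gated_session(
        stream,
        tracker_params,
        gate,
        engine,
        initial_point=initial,
        true_position_at=true_position_at,
    )
    return kspace, log, traj


def reference_image(seq: SequenceParams, spec: ph.PhantomSpec) -> np.ndarray:
    """Motion-free rest-pose reconstruction target on the MRI grid."""
    mri_phantom = ph.build_phantom(spec, (seq.n_pe, seq.n_read), seq.fov_mm[0])
    return mri_phantom.image
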