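"""Canned closed-loop simulation studies: gated vs ungated imaging.

These are the package's reference experiments — the in-silico analogue
of imaging an inactive insect (motion-free reference), a behaving insect
without gating (ghosted) and the same insect with prospective gating
(artifact-reduced).  The default scenario uses a 128 x 128 matrix over
the 30 mm body frame with a desk-scale TR of 100 ms so that multi-seed
studies complete in minutes; sequence arithmetic for the real protocols
(TR 1000-3000 ms) lives in :mod:`motiongate.mri` and is checked
separately.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from . import metrics, mri, phantom as ph
from .gating import GatingConfig
from .optical_flow import TrackerParams


def demo_sequence() -> mri.SequenceParams:
    """Desk-scale sagittal protocol: 128 x 128 over 30 mm, RARE 1, TR 100 ms."""
    return mri.SequenceParams(
        n_read=128, n_pe=128, fov_mm=(30.0, 30.0), tr_ms=100.0, te_ms=5.0, rare_factor=1
    )


def demo_motion(seed: int = 0) -> ph.MotionModel:
    """Default semi-periodic abdominal flexion: 20 deg, ~1 s cycles, 45% dwell."""
    return ph.MotionModel(
        angular_amplitude_deg=20.0,
        base_period_s=1.0,
        period_jitter_sd_s=0.15,
        translation_amplitude_mm=(0.2, 0.1),
        dwell_fraction=0.45,
        rng_seed=seed,
    )


def fast_motion(seed: int = 0) -> ph.MotionModel:
    """Rapid flexion with a short rest window: the latency-sensitive regime.

    The 63 ms dwell is comparable to the 43 ms trigger latency, so the
    object can leave the reference pose between detection and firing.
    """
    return ph.MotionModel(
        angular_amplitude_deg=12.0,
        base_period_s=0.35,
        period_jitter_sd_s=0.05,
        translation_amplitude_mm=(0.1, 0.05),
        dwell_fraction=0.18,
        rng_seed=seed,
    )


def demo_tracker() -> TrackerParams:
    return TrackerParams(window_halfwidth=7, max_iters=10, conv_tol_px=0.01, pyramid_levels=3)


def demo_gate(tolerance_px: float = 2.0, latency_s: float = 0.043) -> GatingConfig:
    return GatingConfig(
        reference_position=None,  # captured from the first tracked frame
        tolerance_px=tolerance_px,
        latency_s=latency_s,
        timeout_s=300.0,
    )


def rois(seq: mri.SequenceParams, spec: ph.PhantomSpec):
    """Disjoint signal (phantom body) and background (air) ROIs.

    Background excludes a 6-pixel dilation of the body support so only
    ghost energy, not edge blur, is counted.
    """
    p = ph.build_phantom(spec, (seq.n_pe, seq.n_read), seq.fov_mm[0])
    support = p.image > 1e-6
    signal = support
    background = ~binary_dilation(support, iterations=6)
    return signal, background


def run_condition(
    seq: mri.SequenceParams,
    spec: ph.PhantomSpec,
    model: ph.MotionModel,
    gate: GatingConfig | None,
    seed: int = 0,
    tracker: TrackerParams | None = None,
):
    """One acquisition under one condition; returns (recon, kspace, log, traj)."""
    kspace, log, traj = mri.acquire_series(
        seq,
        spec,
        model,
        gate=gate,
        tracker_params=tracker or demo_tracker(),
        seed=seed,
    )
    recon = mri.reconstruct(
        kspace,
        provenance={"gated": gate is not None, "seed": seed},
    )
    return recon, kspace, log, traj


def gating_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    tolerance_px: float = 2.0,
    latency_s: float = 0.043,
) -> pd.DataFrame:
    """Gated vs ungated RMSE against the motion-free reference, per seed.

    Each seed draws an independent motion realisation; the same
    realisation is imaged once without gating and once with prospective
    gating at the given tolerance and latency.
    """
    seq = demo_sequence()
    spec = ph.default_phantom_spec()
    ref = mri.reference_image(seq, spec)
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        model = demo_motion(seed=seed)
        recon_u, *_ = run_condition(seq, spec, model, gate=None, seed=seed)
        recon_g, _, log, _ = run_condition(
            seq, spec, model, gate=demo_gate(tolerance_px, latency_s), seed=seed
        )
        rows.append(
            {
                "seed": seed,
                "rmse_ungated": metrics.rmse(recon_u.magnitude, ref),
                "rmse_gated": metrics.rmse(recon_g.magnitude, ref),
                "gated_complete": log.complete,
                "gated_duration_s": log.session_duration_s,
            }
        )
    return pd.DataFrame(rows)


def tolerance_study(
    tolerances=(math.inf, 8.0, 4.0, 2.0, 1.0),
    n_seeds: int = 8,
    base_seed: int = 100,
    latency_s: float = 0.043,
) -> pd.DataFrame:
    """Mean gated RMSE as the gate tolerance shrinks (common seeds per level)."""
    seq = demo_sequence()
    spec = ph.default_phantom_spec()
    ref = mri.reference_image(seq, spec)
    rows = []
    for tol in tolerances:
        for k in range(n_seeds):
            seed = base_seed + k
            model = demo_motion(seed=seed)
            recon, *_ = run_condition(
                seq, spec, model, gate=demo_gate(tol, latency_s), seed=seed
            )
            rows.append(
                {
                    "tolerance_px": tol,
                    "seed": seed,
                    "rmse": metrics.rmse(recon.magnitude, ref),
                }
            )
    return pd.DataFrame(rows)


def latency_study(
    n_seeds: int = 10,
    base_seed: int = 200,
    tolerance_px: float = 1.0,
    latencies=(0.0, 0.043),
) -> pd.DataFrame:
    """Gated RMSE under fast motion at zero vs modeled trigger latency."""
    seq = demo_sequence()
    spec = ph.default_phantom_spec()
    ref = mri.reference_image(seq, spec)
    rows = []
    for lat in latencies:
        for k in range(n_seeds):
            seed = base_seed + k
            model = fast_motion(seed=seed)
            recon, *_ = run_condition(
                seq, spec, model, gate=demo_gate(tolerance_px, lat), seed=seed
            )
            rows.append({"latency_s": lat, "seed": seed,
                         "rmse": metrics.rmse(recon.magnitude, ref)})
    return pd.DataFrame(rows)


def tracking_benchmark(
    n_frames: int = 100,
    seed: int = 0,
    noise_sd: float = 0.01,
    camera_grid=(128, 128),
) -> metrics.TrackingErrorReport:
    """Synthetic analogue of the 100-image annotation benchmark.

    The moving phantom is filmed with mild sensor noise, the tracker
    follows the keypoint from frame 1, and the detections are scored
    against the generator's ground truth (in place of human annotation).
    """
    spec = ph.default_phantom_spec()
    model = demo_motion(seed=seed)
    cam = ph.build_phantom(spec, camera_grid, spec.body_frame_extent_mm)
    duration = (n_frames - 1) / ph.DEFAULT_FRAME_RATE_HZ
    frames, truth = ph.generate_sequence(
        model, cam, duration_s=duration, noise_sd=noise_sd, noise_seed=seed + 1
    )
    detected = None
    from .optical_flow import track_sequence

    detected = track_sequence(frames, truth.positions[0], demo_tracker())
    return metrics.euclidean_errors(detected, truth, pixel_pitch_um=cam.pitch_um)
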