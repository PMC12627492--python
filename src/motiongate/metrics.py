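"""Quantitative evaluation: tracking-error benchmark and artifact metrics.

Tracking accuracy follows the annotation-benchmark protocol: per-frame
Euclidean distance between detected and annotated keypoint positions,
summarized as mean +/- standard deviation in pixels and micrometres,
with a histogram of the error distribution.  Image artifact levels are
quantified as RMSE against a motion-free reference, a ghost-to-signal
ratio over disjoint regions of interest, and 1D intensity profiles of
the kind used to compare gated and ungated reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .frames import LOST, TRACKED, Trajectory
from .phantom import DEFAULT_PIXEL_PITCH_UM


@dataclass
class TrackingErrorReport:
    """Euclidean keypoint error statistics over paired frames."""

    distances_px: np.ndarray
    distances_um: np.ndarray
    mean_px: float
    sd_px: float
    mean_um: float
    sd_um: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_frames: int
    n_excluded: int
    pixel_pitch_um: float


@dataclass
class ArtifactReport:
    """Artifact level of one reconstruction against a reference."""

    name: str
    rmse: float
    ghost_to_signal: float
    profile: np.ndarray = field(default=None)  # type: ignore[assignment]


def px_to_um(distance_px, pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM):
    """Convert a pixel distance to micrometres."""
    if pixel_pitch_um <= 0:
        raise ValueError("pixel_pitch_um must be positive")
    return np.asarray(distance_px, dtype=float) * pixel_pitch_um


def euclidean_errors(
    detections: Trajectory,
    annotations: Trajectory,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
    n_bins: int = 10,
) -> TrackingErrorReport:
    """Per-frame Euclidean distance between detections and annotations.

    Frames are matched on ``frame_index``; frames lost in either
    trajectory are excluded from the statistics and counted in
    ``n_excluded``.  Summary uses the sample standard deviation (n-1
    denominator; with one pair the sd is 0).
    """
    det = detections.to_dataframe().set_index("frame")
    ann = annotations.to_dataframe().set_index("frame")
    joined = det.join(ann, lsuffix="_det", rsuffix="_ann", how="inner")
    if len(joined) == 0:
        raise ValueError("no overlapping frame indices between trajectories")
    ok = (joined["status_det"] == TRACKED) & (joined["status_ann"] == TRACKED)
    n_excluded = int((~ok).sum())
    sub = joined[ok]
    if len(sub) == 0:
        raise ValueError("all overlapping frames are lost in one trajectory")
    d = np.hypot(sub["x_det"] - sub["x_ann"], sub["y_det"] - sub["y_ann"]).to_numpy()
    mean_px = float(np.mean(d))
    sd_px = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    hi = float(d.max()) if d.max() > 0 else 1.0
    counts, edges = np.histogram(d, bins=n_bins, range=(0.0, hi))
    return TrackingErrorReport(
        distances_px=d,
        distances_um=px_to_um(d, pixel_pitch_um),
        mean_px=mean_px,
        sd_px=sd_px,
        mean_um=mean_px * pixel_pitch_um,
        sd_um=sd_px * pixel_pitch_um,
        hist_counts=counts,
        hist_edges=edges,
        n_frames=int(len(d)),
        n_excluded=n_excluded,
        pixel_pitch_um=pixel_pitch_um,
    )


def rmse(image: np.ndarray, reference: np.ndarray) -> float:
    """Root mean squared pixel difference."""
    a = np.asarray(image, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def ghost_to_signal(image: np.ndarray, signal_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """Mean |background| over mean |signal| — ghost energy leaking into air."""
    img = np.asarray(image, dtype=float)
    sig = np.asarray(signal_roi, dtype=bool)
    bg = np.asarray(background_roi, dtype=bool)
    if sig.shape != img.shape or bg.shape != img.shape:
        raise ValueError("ROI masks must match the image shape")
    if not sig.any() or not bg.any():
        raise ValueError("ROIs must be non-empty")
    if np.any(sig & bg):
        raise ValueError("ROIs must be disjoint")
    return float(np.mean(np.abs(img[bg])) / np.mean(np.abs(img[sig])))


def line_profile(image: np.ndarray, axis: int | None = None, index: int | None = None,
                 polyline: np.ndarray | None = None) -> np.ndarray:
    """Intensity trace along a grid row/column or an arbitrary polyline.

    ``axis=0, index=i`` extracts row i; ``axis=1, index=j`` column j.
    A polyline — an (m, 2) array of (x, y) vertices — is sampled
    bilinearly at unit-pixel spacing along its segments.
    """
    img = np.asarray(image, dtype=float)
    if polyline is not None:
        pts = np.asarray(polyline, dtype=float)
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 1] < 0) or np.any(
            pts[:, 0] > img.shape[1] - 1
        ) or np.any(pts[:, 1] > img.shape[0] - 1):
            raise ValueError("polyline leaves the image bounds")
        samples = []
        for p0, p1 in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(p1 - p0)
            n = max(int(np.ceil(seg)), 1)
            ts = np.linspace(0.0, 1.0, n + 1)
            xs = p0[0] + ts * (p1[0] - p0[0])
            ys = p0[1] + ts * (p1[1] - p0[1])
            samples.append(map_coordinates(img, [ys, xs], order=1))
        return np.concatenate(samples)
    if axis is None or index is None:
        raise ValueError("give either axis+index or a polyline")
    if not 0 <= index < img.shape[axis]:
        raise ValueError(f"index {index} out of bounds for axis {axis}")
    return img[index, :].copy() if axis == 0 else img[:, index].copy()


def compare_conditions(
    reference: np.ndarray,
    conditions: dict,
    signal_roi: np.ndarray,
    background_roi: np.ndarray,
    profile_axis: int = 0,
    profile_index: int | None = None,
) -> tuple[pd.DataFrame, list[ArtifactReport]]:
    """Score each condition's reconstruction against the reference.

    ``conditions`` maps a condition name (e.g. "ungated", "gated-2px")
    to its magnitude image.  Returns a tidy table and the per-condition
    reports (with profiles along the chosen line).
    """
    ref = np.asarray(reference, dtype=float)
    if profile_index is None:
        profile_index = ref.shape[0] // 2
    reports = []
    for name, img in conditions.items():
        reports.append(
            ArtifactReport(
                name=name,
                rmse=rmse(img, ref),
                ghost_to_signal=ghost_to_signal(img, signal_roi, background_roi),
                profile=line_profile(img, axis=profile_axis, index=profile_index),
            )
        )
    table = pd.DataFrame(
        {
            "condition": [r.name for r in reports],
            "rmse": [r.rmse for r in reports],
            "ghost_to_signal": [r.ghost_to_signal for r in reports],
        }
    )
    return table, reports
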