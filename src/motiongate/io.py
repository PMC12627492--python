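"""Readers and writers: frame stacks, trajectories, k-space containers.

Frame stacks are zero-padded numbered TIFF files (float32, lossless)
with a JSON sidecar holding pixel pitch, frame rate and seed; k-space
goes to an HDF5 container carrying the complex samples, per-line
timestamps and shot map, the full sequence parameters and the seeds.
Every writer has a matching reader and CSV output is formatted so that
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd

from .frames import ImageFrame, Trajectory
from .gating import GateLog
from .mri import KSpaceData, SequenceParams

SIDE_CAR = "stack.json"


def write_frame_stack(frames, outdir, frame_rate_hz: float, seed: int | None = None) -> None:
    """Write frames as ``frame_000000.tif`` ... plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for f in frames:
        iio.imwrite(
            outdir / f"frame_{f.frame_index:06d}.tif",
            f.pixels.astype(np.float32),
        )
    meta = {
        "n_frames": len(frames),
        "frame_rate_hz": frame_rate_hz,
        "pixel_pitch_um": frames[0].pixel_pitch_um,
        "seed": seed,
    }
    (outdir / SIDE_CAR).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_frame_stack(indir) -> list[ImageFrame]:
    indir = Path(indir)
    meta_path = indir / SIDE_CAR
    if not meta_path.exists():
        raise FileNotFoundError(f"no {SIDE_CAR} sidecar in {indir}")
    meta = json.loads(meta_path.read_text())
    paths = sorted(indir.glob("frame_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.tif files in {indir}")
    frames = []
    for p in paths:
        k = int(p.stem.split("_")[1])
        frames.append(
            ImageFrame(
                pixels=np.asarray(iio.imread(p), dtype=float),
                timestamp=k / meta["frame_rate_hz"],
                frame_index=k,
                pixel_pitch_um=meta["pixel_pitch_um"],
            )
        )
    return frames


def write_gate_log(log: GateLog, path) -> None:
    df = log.to_dataframe()
    for col in ("detect_t", "fire_t", "x", "y", "displacement"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def write_gate_state(log: GateLog, path) -> None:
    df = pd.DataFrame({"t": log.frame_t, "state": log.frame_state})
    df["t"] = df["t"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)


def write_kspace(kspace: KSpaceData, path, seeds: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=kspace.samples)
        fh.create_dataset("line_time_s", data=kspace.line_time_s)
        fh.create_dataset("line_shot", data=kspace.line_shot)
        fh.attrs["complete"] = kspace.complete
        fh.attrs["kspace_convention"] = "DC at matrix centre (fftshift); PE along axis 0"
        grp = fh.create_group("sequence")
        for key, val in asdict(kspace.seq).items():
            grp.attrs[key] = val
        if seeds:
            sgrp = fh.create_group("seeds")
            for key, val in seeds.items():
                sgrp.attrs[key] = val


def read_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as fh:
        seq_attrs = dict(fh["sequence"].attrs)
        seq = SequenceParams(
            n_read=int(seq_attrs["n_read"]),
            n_pe=int(seq_attrs["n_pe"]),
            fov_mm=tuple(float(v) for v in seq_attrs["fov_mm"]),
            tr_ms=float(seq_attrs["tr_ms"]),
            te_ms=float(seq_attrs["te_ms"]),
            rare_factor=int(seq_attrs["rare_factor"]),
            n_averages=int(seq_attrs["n_averages"]),
            pe_ordering=str(seq_attrs["pe_ordering"]),
            slice_thickness_mm=float(seq_attrs["slice_thickness_mm"]),
        )
        meta = {}
        if "seeds" in fh:
            meta["seeds"] = dict(fh["seeds"].attrs)
        return KSpaceData(
            samples=fh["samples"][()],
            line_time_s=fh["line_time_s"][()],
            line_shot=fh["line_shot"][()],
            seq=seq,
            complete=bool(fh.attrs["complete"]),
            meta=meta,
        )


def write_recon(magnitude: np.ndarray, path_float_tif, path_png=None) -> None:
    """Float TIFF always; optional 16-bit PNG normalised to the image max."""
    iio.imwrite(path_float_tif, magnitude.astype(np.float32))
    if path_png is not None:
        peak = float(magnitude.max()) or 1.0
        img16 = np.clip(magnitude / peak * 65535.0, 0, 65535).astype(np.uint16)
        iio.imwrite(path_png, img16)


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_csv(path)


def read_trajectory(path) -> Trajectory:
    return Trajectory.from_csv(path)
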