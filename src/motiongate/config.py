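"""Run configuration: one YAML file, one master seed, full reproducibility.

The master seed is expanded deterministically into per-subsystem seeds
with :class:`numpy.random.SeedSequence` spawn keys — subsystem ``i``
gets ``SeedSequence([master_seed, i])`` — so a single integer reproduces
the motion realisation, the camera noise and the measurement noise
independently (changing one subsystem's consumption never perturbs the
others).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .gating import GatingConfig
from .mri import SequenceParams
from .optical_flow import TrackerParams
from .phantom import MotionModel, PhantomSpec, Segment, default_phantom_spec

SUBSYSTEMS = ("motion", "camera_noise", "measurement_noise")


def expand_seed(master_seed: int) -> dict:
    """Deterministic master-seed -> per-subsystem seed map (values < 2**31)."""
    out = {}
    for i, name in enumerate(SUBSYSTEMS):
        ss = np.random.SeedSequence([int(master_seed), i])
        out[name] = int(ss.generate_state(1)[0] % (2**31))
    return out


@dataclass
class RunConfig:
    """Everything one closed-loop run needs, serializable to YAML."""

    phantom: PhantomSpec = field(default_factory=default_phantom_spec)
    motion: MotionModel = field(default_factory=MotionModel)
    tracker: TrackerParams = field(default_factory=TrackerParams)
    gate: GatingConfig = field(default_factory=GatingConfig)
    sequence: SequenceParams = field(default_factory=SequenceParams)
    master_seed: int = 0
    camera_grid: tuple[int, int] = (128, 128)
    camera_frame_rate_hz: float = 30.0
    camera_noise_sd: float = 0.0
    duration_s: float = 3.0

    @property
    def seeds(self) -> dict:
        return expand_seed(self.master_seed)

    def seeded_motion(self) -> MotionModel:
        """The motion model with its jitter stream keyed off the master seed."""
        from dataclasses import replace

        return replace(self.motion, rng_seed=self.seeds["motion"])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["segments"] = [asdict(s) for s in self.phantom.segments]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            pd_ = dict(d["phantom"])
            pd_["segments"] = tuple(
                Segment(
                    label=s["label"],
                    center_mm=tuple(s["center_mm"]),
                    semiaxes_mm=tuple(s["semiaxes_mm"]),
                    intensity=s["intensity"],
                )
                for s in pd_["segments"]
            )
            pd_["pivot_mm"] = tuple(pd_["pivot_mm"])
            pd_["keypoint_mm"] = tuple(pd_["keypoint_mm"])
            d["phantom"] = PhantomSpec(**pd_)
        for key, typ in (
            ("motion", MotionModel),
            ("tracker", TrackerParams),
            ("gate", GatingConfig),
            ("sequence", SequenceParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = {
                    k: (tuple(v) if isinstance(v, list) else v) for k, v in d[key].items()
                }
                d[key] = typ(**sub)
        if "camera_grid" in d:
            d["camera_grid"] = tuple(d["camera_grid"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples/numpy scalars to YAML-friendly types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
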