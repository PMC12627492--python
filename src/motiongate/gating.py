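"""Prospective gating controller for triggered k-space acquisition.

The controller watches the tracked keypoint frame by frame and compares
it with a reference position.  Whenever the point is within a Euclidean
tolerance of the reference — and the acquisition engine is idle — it
fires a trigger that releases exactly one shot (one excitation and its
echo train), analogous to respiratory triggering in clinical MRI.  The
trigger reaches the scanner only after the modeled system latency
(camera readout, flow computation, serial link, TTL), so the object is
sampled at ``detect_time + latency``, not at detection: rapid motion
inside that delay is the residual-artifact mechanism this testbed
reproduces.

Gate states per frame: ``open`` (within tolerance, trigger fired or
would fire), ``closed`` (outside tolerance), ``refractory`` (engine
busy with the previous shot), ``lost`` (tracker lost the keypoint; a
closed gate is the safe failure mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .frames import LOST, TRACKED, Trajectory
from .optical_flow import TrackerParams, track_step

OPEN = "open"
CLOSED = "closed"
REFRACTORY = "refractory"

#: end-to-end trigger latency, seconds: camera frame readout, optical-flow
#: computation, serial link and TTL pulse combined.
DEFAULT_LATENCY_S = 0.043


@dataclass(frozen=True)
class GatingConfig:
    """Reference pose, tolerance and timing of the gate.

    ``tolerance_px`` is a Euclidean radius in camera pixels (``math.inf``
    keeps the gate always open).  ``refractory_s`` is the minimum spacing
    between trigger firings; ``None`` defers to the engine's shot
    duration.  ``reference_position`` of ``None`` means "capture from the
    first frame's tracked position".
    """

    reference_position: tuple[float, float] | None = None
    tolerance_px: float = 2.0
    latency_s: float = DEFAULT_LATENCY_S
    refractory_s: float | None = None
    timeout_s: float = 600.0
    axis: str | None = None  # None: Euclidean; "x"/"y": axis-wise tolerance

    def __post_init__(self) -> None:
        if self.tolerance_px < 0:
            raise ValueError("tolerance_px must be non-negative")
        if self.latency_s < 0:
            raise ValueError("latency_s must be non-negative")
        if self.refractory_s is not None and self.refractory_s < 0:
            raise ValueError("refractory_s must be non-negative")


@dataclass
class TriggerEvent:
    """One fired trigger and the shot it released."""

    detect_time: float
    fire_time: float
    detect_position: np.ndarray
    shot_index: int
    fire_displacement: float = math.nan  # true keypoint distance from reference
    # at fire_time, filled in when ground truth is available

    def __post_init__(self) -> None:
        if self.fire_time < self.detect_time:
            raise ValueError("fire_time must not precede detect_time")
        if self.shot_index < 0:
            raise ValueError("shot_index must be non-negative")


@dataclass
class GateLog:
    """Complete record of one gated session."""

    events: list = field(default_factory=list)
    frame_t: list = field(default_factory=list)
    frame_state: list = field(default_factory=list)
    session_duration_s: float = 0.0
    shots_completed: int = 0
    shots_required: int = 0
    complete: bool = False

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "shot": [e.shot_index for e in self.events],
                "detect_t": [e.detect_time for e in self.events],
                "fire_t": [e.fire_time for e in self.events],
                "x": [e.detect_position[0] for e in self.events],
                "y": [e.detect_position[1] for e in self.events],
                "displacement": [e.fire_displacement for e in self.events],
            }
        )


class RefractoryViolationError(RuntimeError):
    """emit_trigger was called while the controller was refractory (a bug guard)."""


def check_gate(position, config: GatingConfig) -> bool:
    """Gate open iff the keypoint is within tolerance of the reference."""
    pos = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    ref = np.asarray(config.reference_position, dtype=float)
    if config.axis == "x":
        dist = abs(pos[0] - ref[0])
    elif config.axis == "y":
        dist = abs(pos[1] - ref[1])
    else:
        dist = float(np.linalg.norm(pos - ref))
    return dist <= config.tolerance_px


def emit_trigger(
    detect_time: float,
    detect_position,
    config: GatingConfig,
    shot_index: int,
    last_fire_time: float | None = None,
    refractory_s: float = 0.0,
) -> TriggerEvent:
    """Fire one trigger: ``fire_time = detect_time + latency`` exactly."""
    if last_fire_time is not None and detect_time + config.latency_s < (
        last_fire_time + refractory_s
    ):
        raise RefractoryViolationError(
            f"trigger at t={detect_time} while refractory until "
            f"{last_fire_time + refractory_s}"
        )
    return TriggerEvent(
        detect_time=detect_time,
        fire_time=detect_time + config.latency_s,
        detect_position=np.asarray(detect_position, dtype=float),
        shot_index=shot_index,
    )


def latency_budget(segment_latencies) -> float:
    """Total pipeline latency from its individual segments."""
    total = 0.0
    for name, dt in segment_latencies:
        if dt < 0:
            raise ValueError(f"latency segment {name!r} is negative")
        total += dt
    return total


class AcquisitionEngine(Protocol):
    """What the controller needs from an acquisition back end."""

    @property
    def shots_required(self) -> int: ...

    @property
    def shot_duration_s(self) -> float: ...

    def acquire(self, shot_index: int, fire_time: float) -> None: ...

    def finalize(self, complete: bool): ...


def run_gated_session(
    frames,
    tracker_params: TrackerParams,
    config: GatingConfig,
    engine: AcquisitionEngine,
    initial_point,
    true_position_at=None,
):
    """Run the closed loop: track, gate, trigger, acquire.

    ``frames`` may be a lazy generator (sessions are open-ended until all
    shots are acquired or ``timeout_s`` elapses).  ``true_position_at``,
    when given, maps a time to the ground-truth keypoint position and is
    used only to record each trigger's fire-time displacement.

    Returns ``(result, GateLog, Trajectory)`` where ``result`` is
    ``engine.finalize(complete)``.
    """
    frames = iter(frames)
    try:
        first = next(frames)
    except StopIteration:
        raise ValueError("frame stream is empty") from None

    pos = np.asarray(initial_point, dtype=float)
    if config.reference_position is None:
        config = GatingConfig(
            reference_position=(float(pos[0]), float(pos[1])),
            tolerance_px=config.tolerance_px,
            latency_s=config.latency_s,
            refractory_s=config.refractory_s,
            timeout_s=config.timeout_s,
            axis=config.axis,
        )
    refractory = (
        config.refractory_s if config.refractory_s is not None else engine.shot_duration_s
    )
    refractory = max(refractory, engine.shot_duration_s)

    log = GateLog(shots_required=engine.shots_required)
    idx = [first.frame_index]
    ts = [first.timestamp]
    xs, ys, statuses = [pos[0]], [pos[1]], [TRACKED]

    shot = 0
    last_fire: float | None = None

    def consider(t: float, status: str) -> str:
        nonlocal shot, last_fire
        if status == LOST:
            return LOST
        fire_t = t + config.latency_s
        if last_fire is not None and fire_t < last_fire + refractory:
            return REFRACTORY
        if shot >= engine.shots_required:
            return CLOSED
        if not check_gate(pos, config):
            return CLOSED
        event = emit_trigger(t, pos, config, shot, last_fire, refractory)
        if true_position_at is not None:
            true_pos = np.asarray(true_position_at(event.fire_time), dtype=float)
            ref = np.asarray(config.reference_position, dtype=float)
            event.fire_displacement = float(np.linalg.norm(true_pos - ref))
        engine.acquire(shot, event.fire_time)
        log.events.append(event)
        last_fire = event.fire_time
        shot += 1
        return OPEN

    state = consider(first.timestamp, TRACKED)
    log.frame_t.append(first.timestamp)
    log.frame_state.append(state)

    prev = first
    t = first.timestamp
    while shot < engine.shots_required:
        try:
            cur = next(frames)
        except StopIteration:
            break
        t = cur.timestamp
        if t > config.timeout_s:
            break
        pos, _, status = track_step(prev, cur, pos, tracker_params)
        idx.append(cur.frame_index)
        ts.append(t)
        xs.append(pos[0])
        ys.append(pos[1])
        statuses.append(status)
        state = consider(t, status)
        log.frame_t.append(t)
        log.frame_state.append(state)
        prev = cur

    log.shots_completed = shot
    log.complete = shot >= engine.shots_required
    if log.complete and last_fire is not None:
        log.session_duration_s = last_fire + engine.shot_duration_s
    else:
        log.session_duration_s = t
    result = engine.finalize(log.complete)
    traj = Trajectory(
        frame_index=np.asarray(idx),
        t=np.asarray(ts),
        x=np.asarray(xs),
        y=np.asarray(ys),
        status=np.asarray(statuses, dtype=object),
    )
    return result, log, traj
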