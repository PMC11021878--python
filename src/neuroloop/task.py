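"""Radial-8 center-out-and-back cursor task.

The task alternates between eight peripheral targets arranged every 45° on
a ring and the central target.  A target is acquired when the cursor stays
inside its radius continuously for a hold period; a trial fails when the
timeout elapses first.  Cursor kinematics are explicit-Euler integration of
the decoded velocity at the bin rate, clamped to the workspace.  An
autopilot provides scripted cursor movement for open-loop calibration
blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "TaskConfig",
    "CursorState",
    "TaskState",
    "TrialOutcome",
    "generate_target_sequence",
    "update_task",
    "autopilot_velocity",
    "summarize_block",
    "PHASES",
]

PHASES = ("to_peripheral", "to_center", "acquired_hold", "inter_trial", "done")


@dataclass
class TaskConfig:
    """Geometry and timing of the radial-8 task.

    Workspace is the square ``[-half, half]^2``; the 8 peripheral targets sit
    on a ring of ``ring_radius`` at angles k*45°.
    """

    ring_radius: float = 0.4
    target_radius: float = 0.05
    hold_ms: int = 300
    timeout_ms: int = 10_000
    workspace_half: float = 0.5
    n_directions: int = 8
    dt_ms: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.target_radius < self.ring_radius <= self.workspace_half:
            raise ValueError("require 0 < target_radius < ring_radius <= workspace_half")
        if self.hold_ms < 0 or self.timeout_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("timing parameters must be positive")


@dataclass
class CursorState:
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    clamped: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)
        self.velocity = np.asarray(self.velocity, dtype=float).reshape(2)


@dataclass
class TrialOutcome:
    trial: int
    target: Tuple[float, float]
    acquire_time_ms: Optional[int]
    success: bool


@dataclass
class TaskState:
    """Task phase, active target and the running outcome log."""

    targets: List[np.ndarray]
    phase: str = "to_peripheral"
    trial_index: int = 0
    time_in_state_ms: int = 0
    hold_elapsed_ms: int = 0
    outcomes: List[TrialOutcome] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("need at least one target")
        self.targets = [np.asarray(t, dtype=float).reshape(2) for t in self.targets]
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def active_target(self) -> np.ndarray:
        return self.targets[min(self.trial_index, len(self.targets) - 1)]

    @property
    def done(self) -> bool:
        return self.phase == "done"


def generate_target_sequence(n_trials: int, cfg: TaskConfig,
                             order: str = "cycle",
                             seed: Optional[int] = None) -> List[np.ndarray]:
    """Alternating peripheral/center target list for center-out-and-back.

    Odd entries are the center; even entries are ring targets at k*45°.
    ``cycle`` visits the 8 directions in order; ``shuffled`` permutes each
    block of 8 with a seeded generator so every block still covers all
    directions.  ``n_trials`` counts peripheral trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if order not in ("cycle", "shuffled"):
        raise ValueError(f"unknown order {order!r}")
    angles = np.arange(cfg.n_directions) * (2 * np.pi / cfg.n_directions)
    rng = np.random.default_rng(seed)
    directions: List[int] = []
    while len(directions) < n_trials:
        block = np.arange(cfg.n_directions)
        if order == "shuffled":
            rng.shuffle(block)
        directions.extend(block.tolist())
    directions = directions[:n_trials]
    out: List[np.ndarray] = []
    for d in directions:
        out.append(cfg.ring_radius * np.array([np.cos(angles[d]), np.sin(angles[d])]))
        out.append(np.zeros(2))
    return out


def _advance_trial(task: TaskState, success: bool) -> None:
    was_peripheral = task.phase in ("to_peripheral", "acquired_hold") and \
        np.linalg.norm(task.active_target) > 0
    task.outcomes.append(TrialOutcome(
        trial=task.trial_index,
        target=tuple(task.active_target),
        acquire_time_ms=task.time_in_state_ms if success else None,
        success=success,
    ))
    task.trial_index += 1
    task.time_in_state_ms = 0
    task.hold_elapsed_ms = 0
    if task.trial_index >= len(task.targets):
        task.phase = "done"
    else:
        task.phase = "to_center" if was_peripheral else "to_peripheral"


def update_task(task: TaskState, cursor: CursorState, v_decoded: np.ndarray,
                cfg: TaskConfig) -> Tuple[TaskState, CursorState]:
    """Advance the FSM and cursor by one bin (``cfg.dt_ms``).

    Position integrates the decoded velocity (explicit Euler) and is clamped
    to the workspace; continuous residence inside the target for ``hold_ms``
    acquires it, ``timeout_ms`` in one trial fails it.  Deterministic in its
    inputs.  Mutates and returns ``task`` and ``cursor``.
    """
    if task.done:
        return task, cursor
    v = np.asarray(v_decoded, dtype=float).reshape(2)
    dt_s = cfg.dt_ms / 1000.0
    pos = cursor.position + v * dt_s
    half = cfg.workspace_half
    clamped = bool(np.any(pos < -half) or np.any(pos > half))
    cursor.position = np.clip(pos, -half, half)
    cursor.velocity = v
    cursor.clamped = clamped

    task.time_in_state_ms += cfg.dt_ms
    on_target = np.linalg.norm(cursor.position - task.active_target) <= cfg.target_radius
    if on_target:
        task.hold_elapsed_ms += cfg.dt_ms
        if task.phase in ("to_peripheral", "to_center"):
            task.phase = "acquired_hold"
        if task.hold_elapsed_ms >= cfg.hold_ms:
            _advance_trial(task, success=True)
            return task, cursor
    else:
        task.hold_elapsed_ms = 0
        if task.phase == "acquired_hold":
            task.phase = "to_peripheral" if np.linalg.norm(task.active_target) > 0 \
                else "to_center"
    if task.time_in_state_ms >= cfg.timeout_ms:
        _advance_trial(task, success=False)
    return task, cursor


def autopilot_velocity(cursor: np.ndarray, target: np.ndarray, speed: float,
                       dt_ms: int = 10) -> np.ndarray:
    """Scripted velocity toward the target for open-loop calibration.

    Magnitude ``min(speed, distance/dt)`` along the cursor→target direction
    (so the cursor never overshoots in one step); zero on the target.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    cursor = np.asarray(cursor, dtype=float).reshape(2)
    target = np.asarray(target, dtype=float).reshape(2)
    delta = target - cursor
    dist = np.linalg.norm(delta)
    if dist == 0.0:
        return np.zeros(2)
    mag = min(speed, dist / (dt_ms / 1000.0))
    return delta / dist * mag


def summarize_block(outcomes: List[TrialOutcome]) -> Dict:
    """Success rate, median/quartile acquisition time, per-direction stats."""
    if not outcomes:
        raise ValueError("empty outcome log")
    times = sorted(o.acquire_time_ms for o in outcomes if o.success)
    summary: Dict = {
        "n_trials": len(outcomes),
        "n_success": len(times),
        "success_rate": len(times) / len(outcomes),
        "median_acquire_time_ms": median(times) if times else None,
    }
    if times:
        q = np.percentile(times, [25, 75])
        summary["iqr_acquire_time_ms"] = (float(q[0]), float(q[1]))
    per_dir: Dict[str, Dict] = {}
    for o in outcomes:
        key = f"{o.target[0]:+.3f},{o.target[1]:+.3f}"
        d = per_dir.setdefault(key, {"n": 0, "n_success": 0, "times": []})
        d["n"] += 1
        d["n_success"] += int(o.success)
        if o.success:
            d["times"].append(o.acquire_time_ms)
    summary["per_direction"] = {
        k: {"n": v["n"], "n_success": v["n_success"],
            "median_ms": median(v["times"]) if v["times"] else None}
        for k, v in per_dir.items()
    }
    return summary
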