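"""Synthetic end-to-end sessions: the study protocol in software.

A session mirrors the standard iBCI cursor-calibration protocol:

1. an *open-loop calibration* block, in which an autopilot moves the cursor
   through radial-8 targets while the simulator generates neural data from
   the autopilot velocity (the user's stand-in "intent");
2. an OLE decoder is fit on that block's normalized features vs. autopilot
   velocities, then drives the cursor in a *closed-loop* block;
3. the closed-loop block's data, with targets relabeled ReFIT-style, trains
   the recurrent decoder, which drives a final closed-loop block.

Durations default to the 3–4 minute block structure scaled down 6×
(30 s / 40 s / 40 s) so a full session runs at desk scale; every block is
seed-reproducible and can run accelerated (as fast as possible) or paced in
real time — stream contents are identical either way, only the embedded
write timestamps differ.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bus import Bus, InProcessBus, export_session
from .decoders import (LSTMDecoder, OLEWeights, RNNSpec, SmootherConfig,
                       fit_ole, predict_ole, relabel_intent, save_ole,
                       smooth_and_scale)
from .signal_chain import (NormalizerState, SignalChain, ThresholdState,
                           estimate_rms, fit_normalizer, normalize)
from .simulator import (SAMPLES_PER_MS, SimulatorEngine, SpikeWaveformBank,
                        TuningModel, packetize)
from .task import (CursorState, TaskConfig, TaskState, TrialOutcome,
                   autopilot_velocity, generate_target_sequence,
                   summarize_block, update_task)

__all__ = [
    "SessionConfig",
    "SessionScript",
    "TrajectorySpec",
    "generate_trajectory",
    "SessionEngine",
    "run_session",
]


@dataclass
class SessionConfig:
    """The simulated study conditions.

    96 channels per array (one array by default), cosine tuning with 10 Hz
    baseline and 40 Hz modulation depth reaching full modulation at the
    autopilot speed, −80 µV spike peaks over 10 µV RMS noise (8× SNR, so
    −3.5×RMS detection operates realistically), 10 ms bins of threshold
    crossings + spike-band power, thresholds frozen from the first 10 s.
    """

    n_channels: int = 96
    baseline_rate: float = 10.0
    modulation_depth: float = 40.0
    noise_rms: float = 10.0
    peak_uv: float = -80.0
    autopilot_speed: float = 0.8          # cursor-units/s
    rms_calibration_s: float = 10.0
    bin_width_ms: int = 10
    use_sbp: bool = True
    use_car: bool = False
    smoother_alpha: float = 0.3
    smoother_gain: float = 1.0
    task: TaskConfig = field(default_factory=TaskConfig)

    @property
    def velocity_scale(self) -> float:
        # full cosine modulation at the nominal movement speed
        return self.autopilot_speed


@dataclass
class TrajectorySpec:
    """Scripted velocity source for tests and open-loop blocks."""

    kind: str = "autopilot"  # autopilot | lissajous | random_walk
    speed: float = 0.8
    duration_s: float = 10.0
    seed: int = 0
    rate_hz: int = 100

    def __post_init__(self) -> None:
        if self.kind not in ("autopilot", "lissajous", "random_walk"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


def generate_trajectory(spec: TrajectorySpec, cfg: TaskConfig) -> np.ndarray:
    """N×3 array of (t_s, vx, vy) whose integrated path stays in-workspace."""
    n = int(round(spec.duration_s * spec.rate_hz))
    dt = 1.0 / spec.rate_hz
    t = np.arange(n) * dt
    half = cfg.workspace_half
    if spec.speed == 0:
        return np.column_stack([t, np.zeros(n), np.zeros(n)])
    if spec.kind == "lissajous":
        # amplitude bounded so positions never leave the workspace
        A = min(0.9 * half, spec.speed / (2 * np.pi * 0.5))
        f1, f2 = 0.5, 0.75
        vx = A * 2 * np.pi * f1 * np.cos(2 * np.pi * f1 * t)
        vy = A * 2 * np.pi * f2 * np.cos(2 * np.pi * f2 * t + np.pi / 3)
        return np.column_stack([t, vx, vy])
    if spec.kind == "random_walk":
        rng = np.random.default_rng(spec.seed)
        pos = np.zeros(2)
        out = np.empty((n, 2))
        v = np.zeros(2)
        for k in range(n):
            v = 0.9 * v + 0.1 * rng.normal(0, spec.speed, 2)
            nxt = pos + v * dt
            for ax in range(2):  # reflect at the workspace boundary
                if abs(nxt[ax]) > 0.95 * half:
                    v[ax] = -v[ax]
                    nxt[ax] = pos[ax] + v[ax] * dt
            pos = nxt
            out[k] = v
        return np.column_stack([t, out])
    # autopilot: run the task kinematics without any neural loop
    task = TaskState(targets=generate_target_sequence(10_000, cfg, seed=spec.seed))
    cursor = CursorState()
    out = np.empty((n, 2))
    for k in range(n):
        v = autopilot_velocity(cursor.position, task.active_target, spec.speed,
                               cfg.dt_ms)
        update_task(task, cursor, v, cfg)
        out[k] = v
    return np.column_stack([t, out])


def trajectory_to_csv(series: np.ndarray, path: str | Path) -> None:
    """Write an N×3 (t, vx, vy) series as CSV with a header row."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("series must be N x 3 (t, vx, vy)")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t", "vx", "vy"])
        w.writerows(arr.tolist())


def trajectory_from_csv(path: str | Path) -> np.ndarray:
    """Inverse of :func:`trajectory_to_csv`."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["t", "vx", "vy"]:
        raise ValueError("not a trajectory CSV (expected header t,vx,vy)")
    return np.array([[float(x) for x in row] for row in rows[1:]])


def plot_cursor_trajectories(task_entries: Sequence, path: str | Path,
                             cfg: Optional[TaskConfig] = None) -> None:
    """Headless plot of cursor paths from a logged task stream.

    Takes the entries of a task stream (JSON ``state`` field per 10 ms
    tick), draws the cursor path coloured by trial with the ring targets
    overlaid, and writes the figure to ``path``.  Requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = cfg or TaskConfig()
    states = [json.loads(e.fields["state"].decode()) for e in task_entries]
    if not states:
        raise ValueError("empty task stream")
    fig, ax = plt.subplots(figsize=(5, 5))
    trials = {}
    for s in states:
        trials.setdefault(s["trial"], []).append(s["cursor"])
    cmap = plt.get_cmap("viridis")
    for trial, pts in trials.items():
        pts = np.array(pts)
        ax.plot(pts[:, 0], pts[:, 1], lw=0.8,
                color=cmap((trial % 16) / 16))
    for k in range(cfg.n_directions):
        ang = 2 * np.pi * k / cfg.n_directions
        ax.add_patch(plt.Circle((cfg.ring_radius * np.cos(ang),
                                 cfg.ring_radius * np.sin(ang)),
                                cfg.target_radius, fill=False, color="gray"))
    ax.add_patch(plt.Circle((0, 0), cfg.target_radius, fill=False,
                            color="gray"))
    half = cfg.workspace_half
    ax.set_xlim(-half, half)
    ax.set_ylim(-half, half)
    ax.set_aspect("equal")
    ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class SessionScript:
    """Ordered block protocol plus the master seed."""

    blocks: List[Dict] = field(default_factory=lambda: [
        {"kind": "open_loop_calibration", "duration_s": 30.0},
        {"kind": "closed_loop_ole", "duration_s": 40.0},
        {"kind": "closed_loop_rnn", "duration_s": 40.0},
    ])
    seed: int = 0
    config: SessionConfig = field(default_factory=SessionConfig)

    def __post_init__(self) -> None:
        kinds = {"open_loop_calibration", "closed_loop_ole", "closed_loop_rnn"}
        for b in self.blocks:
            if b.get("kind") not in kinds:
                raise ValueError(f"unknown block kind {b.get('kind')!r}")
            if b.get("duration_s", 0) <= 0:
                raise ValueError("block durations must be positive")


class SessionEngine:
    """Wires simulator → signal chain → decoder → task into 10 ms bins.

    All components share the session bus; the engine advances the whole loop
    one bin at a time so closed-loop feedback (decoded velocity back into
    the tuning model through the cursor task) is exact at the bin rate.
    """

    def __init__(self, config: SessionConfig, seed: int = 0,
                 bus: Optional[Bus] = None, log_raw: bool = False) -> None:
        self.config = config
        self.seed = seed
        self.bus = bus
        self.log_raw = log_raw
        tuning = TuningModel.random(
            n_channels=config.n_channels,
            baseline_rate=config.baseline_rate,
            modulation_depth=config.modulation_depth,
            velocity_scale=config.velocity_scale,
            seed=seed,
        )
        bank = SpikeWaveformBank.default(config.n_channels, config.peak_uv,
                                         config.noise_rms)
        self.sim = SimulatorEngine(tuning, bank, seed=seed + 1)
        self.chain = SignalChain(config.n_channels,
                                 multiplier=-3.5,
                                 bin_width_ms=config.bin_width_ms,
                                 use_sbp=config.use_sbp,
                                 use_car=config.use_car)
        self.normalizer: Optional[NormalizerState] = None
        self._bin_index = 0

    # -- low level -----------------------------------------------------

    def _simulate_bin(self, velocity: np.ndarray) -> np.ndarray:
        """One bin (bin_width_ms milliseconds) of raw voltage at a fixed
        commanded velocity."""
        blocks = []
        for _ in range(self.config.bin_width_ms):
            seq, block = self.sim.step(velocity)
            if self.bus is not None and self.log_raw:
                self.bus.write_entry("raw_voltage",
                                     {"packet": packetize(block, seq),
                                      "seq": struct.pack("<I", seq)})
            blocks.append(block)
        return np.concatenate(blocks, axis=1)

    def calibrate_thresholds(self) -> ThresholdState:
        """Freeze −3.5×RMS thresholds from an initial quiet-cursor window."""
        n_bins = int(round(self.config.rms_calibration_s * 1000
                           / self.config.bin_width_ms))
        sumsq = np.zeros(self.config.n_channels)
        count = 0
        for _ in range(n_bins):
            raw = self._simulate_bin(np.zeros(2))
            filt = self.chain.filter_block(raw)
            sumsq += np.sum(filt ** 2, axis=1)
            count += filt.shape[1]
        rms = np.sqrt(sumsq / count)
        self.chain.threshold_state = ThresholdState(rms=rms,
                                                    multiplier=self.chain.multiplier)
        return self.chain.threshold_state

    def _features_for_bin(self, raw: np.ndarray) -> np.ndarray:
        bins = self.chain.process(raw)
        assert len(bins) == 1, "one whole bin in, one feature bin out"
        vec = bins[0].vector
        if self.bus is not None:
            self.bus.write_entry("features", {"vec": vec.astype("<f8").tobytes(),
                                              "bin": struct.pack("<Q", self._bin_index)})
        self._bin_index += 1
        return vec

    def _log_task(self, stream: str, task: TaskState, cursor: CursorState,
                  v: np.ndarray) -> None:
        if self.bus is None:
            return
        self.bus.write_entry(stream, {"state": json.dumps({
            "phase": task.phase,
            "trial": task.trial_index,
            "cursor": [float(cursor.position[0]), float(cursor.position[1])],
            "target": [float(task.active_target[0]), float(task.active_target[1])],
            "v": [float(v[0]), float(v[1])],
        }).encode()})

    # -- blocks --------------------------------------------------------

    def run_open_loop(self, duration_s: float, seed: int = 0,
                      ) -> Tuple[np.ndarray, np.ndarray, List[TrialOutcome]]:
        """Autopilot block; returns raw (unnormalized) features X and the
        autopilot velocities Y, one row per bin."""
        cfg = self.config
        n_bins = int(round(duration_s * 1000 / cfg.bin_width_ms))
        task = TaskState(targets=generate_target_sequence(10_000, cfg.task,
                                                          seed=seed))
        cursor = CursorState()
        X, Y = [], []
        for _ in range(n_bins):
            v = autopilot_velocity(cursor.position, task.active_target,
                                   cfg.autopilot_speed, cfg.task.dt_ms)
            raw = self._simulate_bin(v)
            X.append(self._features_for_bin(raw))
            Y.append(v)
            update_task(task, cursor, v, cfg.task)
            self._log_task("task_open_loop", task, cursor, v)
        return np.array(X), np.array(Y), task.outcomes

    def fit_ole_from_block(self, X: np.ndarray, Y: np.ndarray) -> OLEWeights:
        """Fit the normalizer on the block, then the ridge OLE on z-scores."""
        self.normalizer = fit_normalizer(X)
        Z = normalize(X, self.normalizer)
        return fit_ole(Z, Y, normalizer=self.normalizer)

    def run_closed_loop(self, decode: Callable[[np.ndarray], np.ndarray],
                        duration_s: Optional[float] = None,
                        n_trials: Optional[int] = None,
                        task_seed: int = 1,
                        collect_refit: bool = False,
                        stream: str = "task_closed_loop",
                        ) -> Dict:
        """Drive the cursor from decoded velocity until the trial budget or
        duration runs out.

        ``decode`` maps one raw feature vector to raw velocity; smoothing
        and gain are applied here.  The simulated user's *intent* — the
        velocity that drives the tuning model — always points from the
        cursor at the active target at the nominal movement speed, like a
        cooperative participant; the cursor itself moves only as the decoder
        commands, closing the loop.  With ``collect_refit`` the block also
        returns (features, relabeled intent) pairs for retraining.
        """
        cfg = self.config
        if duration_s is None and n_trials is None:
            raise ValueError("need duration_s or n_trials")
        max_bins = (int(round(duration_s * 1000 / cfg.bin_width_ms))
                    if duration_s is not None else 10 ** 9)
        targets = generate_target_sequence(
            n_trials if n_trials is not None else 10_000, cfg.task,
            seed=task_seed)
        task = TaskState(targets=targets)
        cursor = CursorState()
        smoother = SmootherConfig(alpha=cfg.smoother_alpha, gain=cfg.smoother_gain)
        refit_X, refit_Y = [], []
        decoded_log, bins_run = [], 0
        while bins_run < max_bins and not task.done:
            v_intent = autopilot_velocity(cursor.position, task.active_target,
                                          cfg.autopilot_speed, cfg.task.dt_ms)
            raw = self._simulate_bin(v_intent)
            vec = self._features_for_bin(raw)
            v_raw = decode(vec)
            v_out = smooth_and_scale(v_raw, smoother)
            if collect_refit:
                on_target = (np.linalg.norm(cursor.position - task.active_target)
                             <= cfg.task.target_radius)
                refit_X.append(vec)
                refit_Y.append(relabel_intent(cursor.position, task.active_target,
                                              v_raw, on_target))
            decoded_log.append(v_out)
            update_task(task, cursor, v_out, cfg.task)
            self._log_task(stream, task, cursor, v_out)
            bins_run += 1
        # trials still open when the clock ran out are not counted either way
        result = {
            "outcomes": task.outcomes,
            "summary": summarize_block(task.outcomes) if task.outcomes else None,
            "bins_run": bins_run,
            "decoded": np.array(decoded_log),
        }
        if collect_refit:
            result["refit_X"] = np.array(refit_X)
            result["refit_Y"] = np.array(refit_Y)
        return result


def _sequences(X: np.ndarray, Y: np.ndarray, seq_len: int,
               ) -> Tuple[np.ndarray, np.ndarray]:
    n = (X.shape[0] // seq_len) * seq_len
    if n == 0:
        raise ValueError("not enough bins for one training sequence")
    B = n // seq_len
    return (X[:n].reshape(B, seq_len, -1), Y[:n].reshape(B, seq_len, -1))


def run_session(script: SessionScript, out_dir: str | Path,
                log_raw: bool = False, rnn_epochs: Optional[int] = None) -> Dict:
    """Execute a full block protocol and write a self-contained archive.

    Archive layout: ``streams/`` (per-stream binary logs + JSON index),
    ``decoders/`` (each decoder with the indices of the blocks it was
    trained on), ``logs/`` (trial logs as CSV), ``manifest.json``.  A failed
    block marks the archive partial with diagnostics rather than aborting.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bus = InProcessBus()
    engine = SessionEngine(script.config, seed=script.seed, bus=bus,
                           log_raw=log_raw)
    engine.calibrate_thresholds()

    manifest: Dict = {"seed": script.seed, "blocks": [], "partial": False}
    (out / "decoders").mkdir(exist_ok=True)
    (out / "logs").mkdir(exist_ok=True)
    ole: Optional[OLEWeights] = None
    rnn: Optional[LSTMDecoder] = None
    rnn_norm: Optional[NormalizerState] = None
    refit_data: Optional[Tuple[np.ndarray, np.ndarray]] = None
    C = script.config.n_channels

    for idx, block in enumerate(script.blocks):
        kind = block["kind"]
        record: Dict = {"index": idx, "kind": kind,
                        "duration_s": block["duration_s"]}
        try:
            if kind == "open_loop_calibration":
                X, Y, outcomes = engine.run_open_loop(block["duration_s"],
                                                      seed=script.seed + idx)
                ole = engine.fit_ole_from_block(X, Y)
                save_ole(ole, out / "decoders" / f"ole_block{idx}.json")
                record["decoder"] = {"file": f"ole_block{idx}.json",
                                     "trained_on_blocks": [idx],
                                     "lambda": ole.lambda_selected}
                record["n_bins"] = int(X.shape[0])
            elif kind == "closed_loop_ole":
                if ole is None:
                    raise RuntimeError("no OLE decoder trained yet")
                w, norm = ole, engine.normalizer
                res = engine.run_closed_loop(
                    lambda vec: predict_ole(w, normalize(vec, norm)),
                    duration_s=block["duration_s"], task_seed=script.seed + idx,
                    collect_refit=True, stream=f"task_block{idx}")
                refit_data = (res["refit_X"], res["refit_Y"])
                record["summary"] = res["summary"]
                _write_trial_log(out / "logs" / f"block{idx}_trials.csv",
                                 res["outcomes"])
            elif kind == "closed_loop_rnn":
                if refit_data is None:
                    raise RuntimeError("no closed-loop data to train the RNN on")
                Xr, Yr = refit_data
                Xc = Xr[:, :C]  # the recurrent decoder consumes crossings only
                rnn_norm = fit_normalizer(Xc)
                spec = RNNSpec(input_dim=C, seed=script.seed,
                               max_epochs=rnn_epochs or 50)
                Xs, Ys = _sequences(normalize(Xc, rnn_norm), Yr, seq_len=50)
                rnn = LSTMDecoder(spec).fit(Xs, Ys)
                np.savez(out / "decoders" / f"rnn_block{idx}.npz",
                         **rnn.params,
                         norm_mean=rnn_norm.mean, norm_std=rnn_norm.std)
                (out / "decoders" / f"rnn_block{idx}.meta.json").write_text(
                    json.dumps({"trained_on_blocks": [idx - 1],
                                "hidden_units": spec.hidden_units,
                                "input_dim": spec.input_dim}))
                record["decoder"] = {"file": f"rnn_block{idx}.npz",
                                     "trained_on_blocks": [idx - 1]}

                def decode_rnn(vec: np.ndarray) -> np.ndarray:
                    return rnn.step(normalize(vec[:C], rnn_norm))

                rnn.reset_state()
                res = engine.run_closed_loop(
                    decode_rnn, duration_s=block["duration_s"],
                    task_seed=script.seed + idx, stream=f"task_block{idx}")
                record["summary"] = res["summary"]
                _write_trial_log(out / "logs" / f"block{idx}_trials.csv",
                                 res["outcomes"])
        except Exception as exc:
            record["error"] = repr(exc)
            manifest["partial"] = True
            manifest["blocks"].append(record)
            break
        manifest["blocks"].append(record)

    export_session(bus, out / "streams")
    manifest["streams"] = sorted(bus.stream_names())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_trial_log(path: Path, outcomes: Sequence[TrialOutcome]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["trial", "target_x", "target_y", "acquire_time_ms", "success"])
        for o in outcomes:
            w.writerow([o.trial, o.target[0], o.target[1],
                        o.acquire_time_ms, int(o.success)])
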