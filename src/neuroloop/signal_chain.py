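"""30 kHz voltage → binned, normalized decoder features.

The chain mirrors a standard intracortical BCI front end:

1. acquire 1 ms packets (30 samples/channel at 30 kHz), merging multiple
   sources by sequence number and zero-filling drops;
2. optional common-average reference (CAR) across channels;
3. 250 Hz high-pass Butterworth filter applied forward and backward
   (zero phase) to a sliding 4 ms buffer, emitting the newest millisecond;
4. threshold crossings at -3.5x each channel's RMS (downward edge rule) and
   spike-band power (mean squared filtered voltage) per 1 ms window;
5. 10 ms bins — crossings summed, power averaged — ordered
   ``[crossings(1..C), sbp(1..C)]``;
6. z-scoring against a previously recorded reference block.

Thresholds are calibrated once from an initial window of filtered data and
frozen; the normalizer is fit on the most recent calibration block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .simulator import SAMPLES_PER_MS, FS_HZ, NeuralPacket

__all__ = [
    "FilterSpec",
    "ThresholdState",
    "FeatureFrame1ms",
    "BinnedFeatures",
    "NormalizerState",
    "common_average_reference",
    "highpass_forward_backward",
    "estimate_rms",
    "detect_threshold_crossings",
    "spike_band_power",
    "bin_features",
    "fit_normalizer",
    "normalize",
    "FrameMerger",
    "SignalChain",
]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterSpec:
    """High-pass filter design for the spike band.

    Defaults: 4th-order 250 Hz Butterworth run forward-backward (zero phase)
    over a 4 ms sliding buffer, emitting only the newest millisecond so that
    added latency stays minimal.
    """

    cutoff_hz: float = 250.0
    order: int = 4
    design: str = "butterworth"
    buffer_ms: int = 4
    mode: str = "forward_backward"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < FS_HZ / 2:
            raise ValueError("cutoff must lie below the 15 kHz Nyquist frequency")
        if self.buffer_ms < 1:
            raise ValueError("buffer_ms must be >= 1")
        if self.design != "butterworth":
            raise ValueError(f"unsupported design {self.design!r}")
        if self.mode not in ("forward_backward", "causal"):
            raise ValueError(f"unsupported mode {self.mode!r}")

    def sos(self) -> np.ndarray:
        return sps.butter(self.order, self.cutoff_hz, btype="highpass",
                          fs=FS_HZ, output="sos")

    @property
    def buffer_samples(self) -> int:
        return self.buffer_ms * SAMPLES_PER_MS


def common_average_reference(frame: np.ndarray) -> np.ndarray:
    """Subtract the cross-channel mean at every time sample.

    Column means of the result are exactly zero (float arithmetic); a single
    channel therefore maps to all zeros.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] < 1:
        raise ValueError("frame must be C x S with C >= 1")
    return frame - frame.mean(axis=0, keepdims=True)


def highpass_forward_backward(buffer: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase filter a C×(30·buffer_ms) buffer, emit the newest 1 ms.

    The buffer is zero-padded by the caller at session start.  Deterministic:
    identical buffers give bit-identical outputs.
    """
    buffer = np.asarray(buffer, dtype=float)
    if buffer.ndim != 2 or buffer.shape[1] != spec.buffer_samples:
        raise ValueError(f"buffer must be C x {spec.buffer_samples}")
    sos = spec.sos()
    if spec.mode == "causal":
        filtered = sps.sosfilt(sos, buffer, axis=1)
    else:
        filtered = sps.sosfiltfilt(sos, buffer, axis=1)
    return filtered[:, -SAMPLES_PER_MS:]


# ---------------------------------------------------------------------------
# Thresholding and features
# ---------------------------------------------------------------------------

def estimate_rms(filtered: np.ndarray) -> np.ndarray:
    """Per-channel root-mean-square voltage over a calibration window."""
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    return np.sqrt(np.mean(filtered ** 2, axis=1))


@dataclass
class ThresholdState:
    """Per-channel spike-detection thresholds, ``multiplier * rms``.

    With the conventional negative multiplier the thresholds are non-positive
    and a *downward* crossing marks a putative spike.  ``prev_sample`` holds
    each channel's last filtered sample from the preceding block so crossings
    spanning a block boundary are counted exactly once; at session start it
    is zero, i.e. above any negative threshold.
    """

    rms: np.ndarray
    multiplier: float = -3.5
    prev_sample: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.rms = np.atleast_1d(np.asarray(self.rms, dtype=float))
        if np.any(self.rms < 0):
            raise ValueError("rms must be non-negative")
        if self.prev_sample is None:
            self.prev_sample = np.zeros_like(self.rms)

    @property
    def threshold(self) -> np.ndarray:
        return self.multiplier * self.rms


def detect_threshold_crossings(filtered_block: np.ndarray,
                               state: ThresholdState) -> np.ndarray:
    """Count downward threshold crossings per channel within one 1 ms block.

    A crossing is a sample ``x[k] <= threshold`` whose predecessor satisfied
    ``x[k-1] > threshold``; the predecessor of the first sample is the last
    sample of the previous block, kept in ``state``.  At most 30 crossings
    per millisecond by construction.
    """
    block = np.atleast_2d(np.asarray(filtered_block, dtype=float))
    thr = state.threshold[:, None]
    prev = np.concatenate([state.prev_sample[:, None], block[:, :-1]], axis=1)
    crossings = np.sum((block <= thr) & (prev > thr), axis=1)
    state.prev_sample = block[:, -1].copy()
    return crossings.astype(np.int64)


def spike_band_power(filtered_block: np.ndarray) -> np.ndarray:
    """Mean squared filtered voltage per channel over the 1 ms window (µV²)."""
    block = np.atleast_2d(np.asarray(filtered_block, dtype=float))
    return np.mean(block ** 2, axis=1)


@dataclass(frozen=True)
class FeatureFrame1ms:
    """Per-millisecond features: crossing counts and spike-band power."""

    timestamp_ns: int
    crossing_count: np.ndarray
    sbp: np.ndarray


@dataclass(frozen=True)
class BinnedFeatures:
    """One decoder input: features aggregated over a 10 ms bin.

    ``vector`` is length C (crossings only) or 2C, ordered
    ``[crossings(1..C), sbp(1..C)]``; crossings are summed over the bin,
    spike-band power averaged.
    """

    bin_timestamp_ns: int
    bin_width_ms: int
    vector: np.ndarray
    gap_frames: int = 0


def bin_features(frames: Sequence[FeatureFrame1ms], bin_width_ms: int = 10,
                 use_sbp: bool = True) -> BinnedFeatures:
    """Aggregate exactly ``bin_width_ms`` consecutive 1 ms frames.

    Missing frames (``None`` placeholders) are treated as zeros and counted
    in ``gap_frames``.
    """
    if len(frames) != bin_width_ms:
        raise ValueError(f"need exactly {bin_width_ms} frames, got {len(frames)}")
    present = [f for f in frames if f is not None]
    if not present:
        raise ValueError("bin contains no frames")
    C = present[0].crossing_count.shape[0]
    crossings = np.zeros(C)
    sbp = np.zeros(C)
    for f in present:
        crossings += f.crossing_count
        sbp += f.sbp
    sbp /= bin_width_ms  # absent frames contribute zero power
    vector = np.concatenate([crossings, sbp]) if use_sbp else crossings
    return BinnedFeatures(
        bin_timestamp_ns=present[-1].timestamp_ns,
        bin_width_ms=bin_width_ms,
        vector=vector,
        gap_frames=bin_width_ms - len(present),
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizerState:
    """Per-feature z-scoring statistics from a reference recording block."""

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.std = np.atleast_1d(np.asarray(self.std, dtype=float))
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")


def fit_normalizer(history: np.ndarray, epsilon: float = 1e-6) -> NormalizerState:
    """Sample mean/std per feature over a reference block (rows = bins)."""
    history = np.atleast_2d(np.asarray(history, dtype=float))
    if history.shape[0] == 0:
        raise ValueError("empty reference block")
    return NormalizerState(mean=history.mean(axis=0),
                           std=history.std(axis=0), epsilon=epsilon)


def normalize(vector: np.ndarray, state: NormalizerState) -> np.ndarray:
    """``z = (x - mean) / (std + epsilon)``; constant features map to ~0."""
    x = np.asarray(vector, dtype=float)
    if x.shape[-1] != state.mean.shape[0]:
        raise ValueError(f"feature dimension {x.shape[-1]} != {state.mean.shape[0]}")
    return (x - state.mean) / (state.std + state.epsilon)


# ---------------------------------------------------------------------------
# Acquisition merge
# ---------------------------------------------------------------------------

class FrameMerger:
    """Merge packets from multiple sources into combined frames by sequence.

    Two 96-channel sources with matching sequence numbers yield 192-channel
    frames.  A missing packet on any source yields a zero-filled slice and
    increments ``gap_count`` (policy: hold alignment rather than stall).
    """

    def __init__(self, channels_per_source: Sequence[int]) -> None:
        self.channels_per_source = list(channels_per_source)
        self.gap_count = 0

    @property
    def total_channels(self) -> int:
        return sum(self.channels_per_source)

    def merge(self, packets: Sequence[Optional[NeuralPacket]]) -> np.ndarray:
        if len(packets) != len(self.channels_per_source):
            raise ValueError("one packet slot per source required")
        parts = []
        for pkt, C in zip(packets, self.channels_per_source):
            if pkt is None:
                self.gap_count += 1
                parts.append(np.zeros((C, SAMPLES_PER_MS), dtype=np.int16))
            else:
                if pkt.channel_count != C:
                    raise ValueError("packet channel count mismatch")
                parts.append(pkt.samples)
        return np.concatenate(parts, axis=0)


def run_acquire_node(params: dict, bus, stop=None) -> int:
    """Acquisition node: parse and merge packet streams into raw frames.

    Subscribes to one packet stream per source (``input_streams``), aligns
    packets across sources by sequence number, zero-fills sources whose
    packet for a sequence never arrived once a later sequence shows up, and
    publishes merged C_total×30 frames to ``output_stream``.  Sequence gaps
    within a source likewise produce zero-filled frames and increment the
    gap counter, which is included in every output entry.

    Parameters: ``input_streams`` (list), ``output_stream`` (default
    ``raw_frames``), ``channels_per_source`` (list, default [96] per
    source), ``poll_ms``.  Returns the number of frames published.
    """
    import struct

    from .simulator import parse_packet

    sources = list(params["input_streams"])
    out_stream = params.get("output_stream", "raw_frames")
    channels = list(params.get("channels_per_source", [96] * len(sources)))
    poll_ms = int(params.get("poll_ms", 50))
    merger = FrameMerger(channels)
    cursors = {s: 0 for s in sources}
    pending: Dict[int, Dict[str, NeuralPacket]] = {}
    next_seq: Optional[int] = None
    published = 0
    while stop is None or not stop():
        got_any = False
        for s in sources:
            for e in bus.read_next(s, cursors[s], block_ms=0):
                cursors[s] = e.entry_id
                pkt = parse_packet(e.fields["packet"])
                pending.setdefault(pkt.sequence_number, {})[s] = pkt
                got_any = True
        if next_seq is None and pending:
            next_seq = min(pending)
        # emit a frame once every source reported this sequence, or flush
        # it zero-filled when a strictly later sequence is already complete
        while next_seq is not None and pending:
            row = pending.get(next_seq, {})
            complete = len(row) == len(sources)
            later_ready = any(seq > next_seq and len(v) == len(sources)
                              for seq, v in pending.items())
            if not complete and not later_ready:
                break
            frame = merger.merge([row.get(s) for s in sources])
            bus.write_entry(out_stream, {
                "frame": frame.astype("<i2").tobytes(),
                "seq": struct.pack("<I", next_seq),
                "gaps": struct.pack("<I", merger.gap_count),
            })
            pending.pop(next_seq, None)
            published += 1
            next_seq += 1
        if not got_any:
            if stop is None:
                break
            import time
            time.sleep(poll_ms / 1000.0)
    return published


# ---------------------------------------------------------------------------
# Stateful chain
# ---------------------------------------------------------------------------

class SignalChain:
    """Stateful raw-voltage → binned-feature pipeline.

    Keeps the sliding filter buffer (previous ``buffer_ms - 1`` milliseconds),
    the cross-block boundary sample for edge detection, frozen thresholds and
    the per-bin frame accumulator.  ``process`` accepts any whole number of
    milliseconds at once; multi-millisecond input is filtered in a single
    batched zero-phase pass (one stacked filter call over all sliding
    windows), which is numerically identical to stepping 1 ms at a time.
    """

    def __init__(self, n_channels: int, filter_spec: Optional[FilterSpec] = None,
                 multiplier: float = -3.5, bin_width_ms: int = 10,
                 use_sbp: bool = True, use_car: bool = False) -> None:
        self.C = n_channels
        self.spec = filter_spec or FilterSpec()
        self.multiplier = multiplier
        self.bin_width_ms = bin_width_ms
        self.use_sbp = use_sbp
        self.use_car = use_car
        hist_ms = self.spec.buffer_ms - 1
        self._history = np.zeros((n_channels, hist_ms * SAMPLES_PER_MS))
        self.threshold_state: Optional[ThresholdState] = None
        self._pending_frames: List[FeatureFrame1ms] = []
        self._ms_clock = 0
        self._sos = self.spec.sos()

    @property
    def feature_dim(self) -> int:
        return 2 * self.C if self.use_sbp else self.C

    def _filter_many(self, raw: np.ndarray) -> np.ndarray:
        """Filter n whole milliseconds; returns C×(30·n) of per-ms outputs."""
        n_ms = raw.shape[1] // SAMPLES_PER_MS
        buf_len = self.spec.buffer_samples
        ext = np.concatenate([self._history, raw], axis=1)
        # stack the n sliding 4 ms windows and run one zero-phase pass
        windows = np.empty((n_ms, self.C, buf_len))
        for j in range(n_ms):
            windows[j] = ext[:, j * SAMPLES_PER_MS: j * SAMPLES_PER_MS + buf_len]
        stacked = windows.reshape(n_ms * self.C, buf_len)
        if self.spec.mode == "causal":
            filt = sps.sosfilt(self._sos, stacked, axis=1)
        else:
            filt = sps.sosfiltfilt(self._sos, stacked, axis=1)
        newest = filt[:, -SAMPLES_PER_MS:].reshape(n_ms, self.C, SAMPLES_PER_MS)
        self._history = ext[:, -self._history.shape[1]:] if self._history.shape[1] else self._history
        return np.concatenate(list(newest), axis=1)

    def filter_block(self, raw: np.ndarray) -> np.ndarray:
        """CAR (if enabled) + zero-phase high-pass over whole milliseconds."""
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2 or raw.shape[0] != self.C or raw.shape[1] % SAMPLES_PER_MS:
            raise ValueError(f"raw block must be {self.C} x (30*k)")
        if self.use_car:
            raw = common_average_reference(raw)
        return self._filter_many(raw)

    def calibrate_thresholds(self, raw: np.ndarray) -> ThresholdState:
        """Estimate per-channel RMS from filtered calibration data and freeze
        thresholds at ``multiplier * rms``."""
        filtered = self.filter_block(raw)
        self.threshold_state = ThresholdState(rms=estimate_rms(filtered),
                                              multiplier=self.multiplier)
        return self.threshold_state

    def process(self, raw: np.ndarray) -> List[BinnedFeatures]:
        """Consume whole milliseconds of raw voltage; emit completed bins."""
        if self.threshold_state is None:
            raise RuntimeError("thresholds not calibrated")
        filtered = self.filter_block(raw)
        n_ms = filtered.shape[1] // SAMPLES_PER_MS
        out: List[BinnedFeatures] = []
        for j in range(n_ms):
            block = filtered[:, j * SAMPLES_PER_MS:(j + 1) * SAMPLES_PER_MS]
            frame = FeatureFrame1ms(
                timestamp_ns=self._ms_clock * 1_000_000,
                crossing_count=detect_threshold_crossings(block, self.threshold_state),
                sbp=spike_band_power(block),
            )
            self._ms_clock += 1
            self._pending_frames.append(frame)
            if len(self._pending_frames) == self.bin_width_ms:
                out.append(bin_features(self._pending_frames, self.bin_width_ms,
                                        self.use_sbp))
                self._pending_frames = []
        return out
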