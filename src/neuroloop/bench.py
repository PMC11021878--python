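"""Publisher→subscriber latency benchmarking.

Reproduces the classic dataflow benchmark for stream-based IPC: a publisher
emits 1 ms packets of 30 kHz int16 data at a fixed rate, zero or more
forwarders re-serialize them downstream, and a terminal subscriber logs
receipt.  Every node's write is timestamped immediately before the write
call (one monotonic clock domain per host), and the *per-node latency* of a
packet at hop ``i`` is the difference between node ``i+1``'s and node
``i``'s write timestamps.

Absolute latency numbers depend on the host and scheduler; this module
reports them but the test suite asserts only structural properties
(ordering, losslessness, arithmetic of the summaries).

Nodes run as threads over a shared bus by default, which keeps the
benchmark self-contained; the same node functions can be run as separate
processes through the graph runtime with a socket bus for process-isolated
measurements.
"""

from __future__ import annotations

import struct
import threading
import time
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .bus import Bus, BusConfig, InProcessBus, connect, encode_int16_block

__all__ = [
    "BenchConfig",
    "LatencyRecord",
    "run_pubsub_benchmark",
    "run_sequential_reference",
    "per_node_latency",
    "summarize_latency",
    "run_sweep",
    "median_midpoint",
    "quantile_nearest_rank",
]


@dataclass
class BenchConfig:
    """One benchmark condition.

    ``channels`` scales packet size (30 000/rate_hz samples per channel per
    packet, int16); ``n_nodes`` counts the whole chain including publisher
    and final subscriber, so there are ``n_nodes - 1`` hops.
    """

    channels: int = 128
    rate_hz: int = 1000
    n_nodes: int = 2
    n_packets: int = 1000
    bus: BusConfig = field(default_factory=BusConfig)
    stream_prefix: str = "bench"

    def __post_init__(self) -> None:
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if self.n_nodes < 2:
            raise ValueError("need at least publisher and subscriber")
        if 30_000 % self.rate_hz:
            raise ValueError("rate_hz must divide 30000 (whole samples per packet)")

    @property
    def samples_per_packet(self) -> int:
        return 30_000 // self.rate_hz

    @property
    def values_per_packet(self) -> int:
        return self.channels * self.samples_per_packet


@dataclass
class LatencyRecord:
    """Per-packet hop latencies; ``valid`` is False on loss/clock anomaly."""

    packet_index: int
    per_hop_ns: List[int]
    cumulative_ns: List[int]
    valid: bool = True


def per_node_latency(timestamps: Sequence[int]) -> LatencyRecord:
    """Hop latencies from one packet's per-node write timestamps.

    ``hop_i = t_{i+1} - t_i``; a negative hop (clock anomaly) flags the
    record invalid rather than being clipped.
    """
    ts = list(timestamps)
    if len(ts) < 2 or any(t is None for t in ts):
        return LatencyRecord(-1, [], [], valid=False)
    hops = [ts[i + 1] - ts[i] for i in range(len(ts) - 1)]
    cumulative = list(np.cumsum(hops))
    return LatencyRecord(-1, hops, [int(c) for c in cumulative],
                         valid=all(h >= 0 for h in hops))


def median_midpoint(values: Sequence[float]) -> float:
    """Median with the midpoint rule for even-sized samples."""
    v = sorted(values)
    if not v:
        raise ValueError("empty sample")
    n = len(v)
    mid = n // 2
    return float(v[mid]) if n % 2 else (v[mid - 1] + v[mid]) / 2.0


def quantile_nearest_rank(values: Sequence[float], q: float) -> float:
    """Nearest-rank quantile: the ``ceil(q*n)``-th order statistic."""
    v = sorted(values)
    if not v:
        raise ValueError("empty sample")
    rank = max(1, int(np.ceil(q * len(v))))
    return float(v[rank - 1])


def _chain_streams(cfg: BenchConfig) -> List[str]:
    return [f"{cfg.stream_prefix}:{i}" for i in range(cfg.n_nodes)]


def run_pubsub_benchmark(cfg: BenchConfig, bus: Optional[Bus] = None,
                         ) -> Dict:
    """Run one publisher→(forwarders)→subscriber chain; collect latencies.

    Returns ``{"records", "lost", "summary", "publish_intervals_ns"}``.
    Lost or out-of-order packets are excluded from the statistics but
    counted.
    """
    store_bus = bus if bus is not None else InProcessBus(
        max_stream_length=cfg.bus.max_stream_length)
    if isinstance(store_bus, InProcessBus):
        def client() -> Bus:
            return InProcessBus(store_bus.store)
    else:  # socket transports: one connection per node thread
        def client() -> Bus:
            return connect(cfg.bus)

    streams = _chain_streams(cfg)
    rng = np.random.default_rng(0)
    block = rng.integers(-1000, 1000,
                         size=(cfg.channels, cfg.samples_per_packet),
                         dtype=np.int16)
    payload = encode_int16_block(block)
    done = threading.Event()

    def run_publisher() -> None:
        b = client()
        start = time.monotonic()
        for k in range(cfg.n_packets):
            b.write_entry(streams[0], {"seq": struct.pack("<Q", k), "data": payload})
            deadline = start + (k + 1) / cfg.rate_hz
            delay = deadline - time.monotonic()
            if delay > 0:
                time.sleep(delay)

    def run_hop(i: int) -> None:
        # node i in 1..n_nodes-1 reads stream i-1, writes stream i
        b = client()
        last = 0
        seen = 0
        terminal = i == cfg.n_nodes - 1
        while seen < cfg.n_packets:
            entries = b.read_next(streams[i - 1], last, block_ms=200)
            if not entries and done.is_set():
                break
            for e in entries:
                last = e.entry_id
                seen += 1
                fields = {"seq": e.fields["seq"]}
                if not terminal:
                    fields["data"] = e.fields["data"]  # re-serialized downstream
                b.write_entry(streams[i], fields)

    threads = [threading.Thread(target=run_publisher)]
    threads += [threading.Thread(target=run_hop, args=(i,))
                for i in range(1, cfg.n_nodes)]
    for t in threads:
        t.start()
    threads[0].join()
    done.set()
    for t in threads[1:]:
        t.join(timeout=30.0)

    # assemble per-packet timestamp rows keyed by seq
    ts_by_seq: Dict[int, List[Optional[int]]] = {}
    pub_ts: List[int] = []
    for col, stream in enumerate(streams):
        for e in store_bus.read_range(stream):
            seq = struct.unpack("<Q", e.fields["seq"])[0]
            row = ts_by_seq.setdefault(seq, [None] * cfg.n_nodes)
            row[col] = e.write_timestamp_ns
            if col == 0:
                pub_ts.append(e.write_timestamp_ns)

    records: List[LatencyRecord] = []
    lost = 0
    for seq in range(cfg.n_packets):
        row = ts_by_seq.get(seq)
        if row is None or any(t is None for t in row):
            lost += 1
            records.append(LatencyRecord(seq, [], [], valid=False))
            continue
        rec = per_node_latency(row)
        rec.packet_index = seq
        records.append(rec)
    intervals = list(np.diff(sorted(pub_ts))) if len(pub_ts) > 1 else []
    return {
        "records": records,
        "lost": lost,
        "summary": summarize_latency(records),
        "publish_intervals_ns": [int(x) for x in intervals],
    }


def run_sequential_reference(cfg: BenchConfig, work_s_per_packet: float,
                             ) -> Dict:
    """Single-process reference: all per-packet work runs inline.

    Models figure-style sequential execution: each packet is published only
    after the previous packet's *entire* chain (including any slow
    downstream work, ``work_s_per_packet``) has completed, so when the work
    exceeds the publishing period the publisher falls behind and a backlog
    grows.  Returns publish intervals and the final lag behind the nominal
    schedule.
    """
    bus = InProcessBus()
    stream = f"{cfg.stream_prefix}:seq"
    payload = encode_int16_block(
        np.zeros((cfg.channels, cfg.samples_per_packet), dtype=np.int16))
    start = time.monotonic()
    pub_times = []
    for k in range(cfg.n_packets):
        bus.write_entry(stream, {"seq": struct.pack("<Q", k), "data": payload})
        pub_times.append(time.monotonic())
        time.sleep(work_s_per_packet)  # downstream work blocks the loop
        deadline = start + (k + 1) / cfg.rate_hz
        delay = deadline - time.monotonic()
        if delay > 0:
            time.sleep(delay)
    nominal = cfg.n_packets / cfg.rate_hz
    return {
        "publish_intervals_ns": [int(d * 1e9) for d in np.diff(pub_times)],
        "final_lag_s": (pub_times[-1] - start) - (nominal - 1.0 / cfg.rate_hz),
    }


def summarize_latency(records: Sequence[LatencyRecord],
                      histogram_bins: int = 50) -> Dict:
    """Order statistics per hop and cumulative, over valid records only.

    Median uses the even-sample midpoint rule; p90/p99 are nearest-rank.
    Raises if no valid record remains, reporting the loss count.
    """
    valid = [r for r in records if r.valid]
    n_excluded = len(records) - len(valid)
    if not valid:
        raise ValueError(f"no valid latency records ({n_excluded} excluded)")
    n_hops = len(valid[0].per_hop_ns)
    per_hop = np.array([r.per_hop_ns for r in valid], dtype=float)
    cumulative = np.array([r.cumulative_ns for r in valid], dtype=float)

    def stats(x: np.ndarray) -> Dict:
        return {
            "median_ns": median_midpoint(x),
            "p90_ns": quantile_nearest_rank(x, 0.90),
            "p99_ns": quantile_nearest_rank(x, 0.99),
            "max_ns": float(np.max(x)),
            "histogram": [[float(c) for c in h] for h in np.histogram(x, bins=histogram_bins)],
        }

    return {
        "n_records": len(records),
        "n_valid": len(valid),
        "n_excluded": n_excluded,
        "per_hop": [stats(per_hop[:, i]) for i in range(n_hops)],
        "cumulative": [stats(cumulative[:, i]) for i in range(n_hops)],
        "total": stats(cumulative[:, -1]),
    }


def run_sweep(axis: str, values: Sequence, base: BenchConfig) -> List[Dict]:
    """Repeat the benchmark varying channels, rate or node count."""
    if axis not in ("channels", "rate", "nodes"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    key = {"channels": "channels", "rate": "rate_hz", "nodes": "n_nodes"}[axis]
    rows = []
    for v in values:
        cfg = replace(base, **{key: int(v)})
        result = run_pubsub_benchmark(cfg)
        rows.append({
            "axis": axis,
            "value": int(v),
            "values_per_packet": cfg.values_per_packet,
            "n_hops": cfg.n_nodes - 1,
            "lost": result["lost"],
            "summary": result["summary"],
            "publish_interval_median_ns": median_midpoint(
                result["publish_intervals_ns"]) if result["publish_intervals_ns"] else None,
        })
    return rows


def plot_latency(rows: List[Dict], path: str) -> None:
    """Violin/histogram export of a sweep (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3 + 0.4 * len(rows)))
    labels, medians = [], []
    for row in rows:
        labels.append(f"{row['axis']}={row['value']}")
        medians.append(row["summary"]["total"]["median_ns"] / 1e3)
    ax.barh(labels, medians)
    ax.set_xlabel("median end-to-end latency (µs)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
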