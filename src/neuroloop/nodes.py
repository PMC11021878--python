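"""Built-in node run functions, referenced from graph YAML as
``neuroloop.nodes:<name>``.

Each function takes a :class:`~neuroloop.nodehost.NodeContext` and runs
until its stop signal.  These cover the benchmark chain (publisher /
forwarder / subscriber / sleeper), graph-runtime plumbing tests (noop,
echo_params, exit_immediately, stubborn) and the neural simulator node.
"""

from __future__ import annotations

import json
import struct
import time

import numpy as np

from .bus import encode_int16_block
from .simulator import run_simulator_node


def noop(ctx) -> None:
    """Idle until stopped."""
    while not ctx.should_stop():
        ctx.sleep(0.02)


def echo_params(ctx) -> None:
    """Write the parameter map this node observed, then idle.

    Used to verify parameter fidelity end to end: what the YAML declared is
    exactly what the run loop sees.
    """
    stream = ctx.params.get("echo_stream", f"echo:{ctx.nickname}")
    ctx.bus.write_entry(stream, {"params": json.dumps(ctx.params).encode()})
    while not ctx.should_stop():
        ctx.sleep(0.02)


def exit_immediately(ctx) -> None:
    """Return at once — exercises crash detection."""
    return


def stubborn(ctx) -> None:
    """Ignore the stop command — exercises forced termination."""
    while True:
        time.sleep(0.05)


def publisher(ctx) -> None:
    """Emit int16 packets at a fixed rate with absolute-deadline pacing.

    Parameters: ``channels`` (default 128), ``rate_hz`` (default 1000),
    ``n_packets`` (0 = until stopped), ``output_stream``.  Each packet holds
    ``30000 / rate_hz`` samples per channel — the 30 kHz contract.
    """
    channels = int(ctx.params.get("channels", 128))
    rate_hz = int(ctx.params.get("rate_hz", 1000))
    n_packets = int(ctx.params.get("n_packets", 0))
    stream = ctx.params.get("output_stream", "pub")
    samples = 30_000 // rate_hz
    rng = np.random.default_rng(int(ctx.params.get("seed", 0)))
    block = rng.integers(-1000, 1000, size=(channels, samples), dtype=np.int16)
    payload = encode_int16_block(block)
    start = time.monotonic()
    k = 0
    while (n_packets == 0 or k < n_packets) and not ctx.should_stop():
        ctx.bus.write_entry(stream, {"seq": struct.pack("<Q", k), "data": payload})
        k += 1
        delay = start + k / rate_hz - time.monotonic()
        if delay > 0:
            time.sleep(delay)


def forwarder(ctx) -> None:
    """Read packets from one stream and re-serialize them onto another."""
    src = ctx.params["input_stream"]
    dst = ctx.params.get("output_stream", f"fwd:{ctx.nickname}")
    sleep_ms = float(ctx.params.get("sleep_ms", 0))
    last = 0
    while not ctx.should_stop():
        for e in ctx.bus.read_next(src, last, block_ms=100):
            last = e.entry_id
            if sleep_ms > 0:
                time.sleep(sleep_ms / 1000.0)
            ctx.bus.write_entry(dst, {"seq": e.fields["seq"],
                                      "data": e.fields["data"]})


def subscriber(ctx) -> None:
    """Terminal node: log receipt of every packet (write-timestamped)."""
    src = ctx.params["input_stream"]
    dst = ctx.params.get("output_stream", f"sink:{ctx.nickname}")
    last = 0
    while not ctx.should_stop():
        for e in ctx.bus.read_next(src, last, block_ms=100):
            last = e.entry_id
            ctx.bus.write_entry(dst, {"seq": e.fields["seq"]})


def simulator(ctx) -> None:
    """Neural data simulator node (velocity stream → 1 ms voltage packets)."""
    run_simulator_node(ctx.params, ctx.bus, stop=ctx.should_stop)


def acquire(ctx) -> None:
    """Acquisition node: merge packet streams into raw frames by sequence."""
    from .signal_chain import run_acquire_node
    run_acquire_node(ctx.params, ctx.bus, stop=ctx.should_stop)


def velocity_player(ctx) -> None:
    """Replay a (t, vx, vy) CSV trajectory onto the velocity stream.

    Parameters: ``csv_path``, ``velocity_stream`` (default ``velocity``),
    ``realtime`` (pace by the timestamps; default true).
    """
    from .sessions import trajectory_from_csv
    series = trajectory_from_csv(ctx.params["csv_path"])
    stream = ctx.params.get("velocity_stream", "velocity")
    realtime = bool(ctx.params.get("realtime", True))
    start = time.monotonic()
    for t, vx, vy in series:
        if ctx.should_stop():
            return
        if realtime:
            delay = start + t - time.monotonic()
            if delay > 0:
                time.sleep(delay)
        ctx.bus.write_entry(stream, {"v": struct.pack("<dd", vx, vy)})
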