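"""Per-process node host: lifecycle wrapper around a node's run function.

Launched by the supervisor as ``python -m neuroloop.nodehost --nickname ...``.
Connects to the bus, reads the node's parameter entry from its control
stream, resolves the executable (``package.module:function`` or a ``.py``
file defining ``run``), publishes ``initialized``, waits for ``go``, runs
the node with a heartbeat thread, and exits when the run function returns
(normally after a ``stop`` command).
"""

from __future__ import annotations

import argparse
import importlib
import importlib.util
import json
import sys
import threading
import time
from typing import Callable, Dict, Optional

from .bus import Bus, BusConfig, connect
from .graph import HEARTBEAT_S, _ctl, _status


class NodeContext:
    """What a node's run function gets: bus access, params, stop signal."""

    def __init__(self, nickname: str, params: Dict, bus: Bus) -> None:
        self.nickname = nickname
        self.params = params
        self.bus = bus
        self._stop = threading.Event()
        self._ctl_last_id = 0

    def should_stop(self) -> bool:
        """True once a stop command has arrived on the control stream."""
        if self._stop.is_set():
            return True
        for e in self.bus.read_next(_ctl(self.nickname), self._ctl_last_id):
            self._ctl_last_id = e.entry_id
            if e.fields.get("cmd") == b"stop":
                self._stop.set()
        return self._stop.is_set()

    def sleep(self, seconds: float) -> None:
        self._stop.wait(seconds)


def _resolve(executable: str) -> Callable:
    if executable.endswith(".py"):
        spec = importlib.util.spec_from_file_location("node_executable", executable)
        if spec is None or spec.loader is None:
            raise ImportError(f"cannot load {executable}")
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        fn = getattr(mod, "run", None)
    else:
        module, _, attr = executable.partition(":")
        mod = importlib.import_module(module)
        fn = getattr(mod, attr or "run", None)
    if not callable(fn):
        raise ImportError(f"{executable!r} does not provide a run function")
    return fn


def _publish_status(bus: Bus, nickname: str, state: str) -> None:
    bus.write_entry(_status(nickname),
                    {"status": json.dumps({"state": state}).encode()})


def main(argv: Optional[list] = None) -> int:
    parser = argparse.ArgumentParser()
    parser.add_argument("--nickname", required=True)
    parser.add_argument("--transport", required=True)
    parser.add_argument("--host", default="127.0.0.1")
    parser.add_argument("--port", type=int, default=6380)
    parser.add_argument("--socket-path", default="")
    args = parser.parse_args(argv)

    bus = connect(BusConfig(transport=args.transport, host=args.host,
                            port=args.port, socket_path=args.socket_path))
    ctl = _ctl(args.nickname)

    # one cursor for the whole control phase: params, go and stop may land
    # in any interleaving and must each be seen exactly once
    params: Dict = {}
    executable = ""
    last_id = 0
    deadline = time.monotonic() + 10.0
    go = False
    stop = False
    initialized = False
    while not (go or stop):
        if time.monotonic() > deadline and not executable:
            _publish_status(bus, args.nickname, "crashed")
            return 2
        for e in bus.read_next(ctl, last_id, block_ms=500):
            last_id = e.entry_id
            cmd = e.fields.get("cmd")
            if cmd == b"params":
                executable = e.fields["executable"].decode()
                params = json.loads(e.fields["params"].decode())
            elif cmd == b"go":
                go = True
            elif cmd == b"stop":
                stop = True
        if executable and not initialized:
            _publish_status(bus, args.nickname, "initialized")
            initialized = True
    if stop or not executable:
        _publish_status(bus, args.nickname, "stopped")
        return 0

    fn = _resolve(executable)
    ctx = NodeContext(args.nickname, params, bus)
    ctx._ctl_last_id = last_id

    _publish_status(bus, args.nickname, "running")
    hb_bus = connect(BusConfig(transport=args.transport, host=args.host,
                               port=args.port, socket_path=args.socket_path))

    def heartbeat() -> None:
        while not ctx._stop.wait(HEARTBEAT_S):
            _publish_status(hb_bus, args.nickname, "running")

    threading.Thread(target=heartbeat, daemon=True).start()
    try:
        fn(ctx)
    finally:
        ctx._stop.set()
        _publish_status(bus, args.nickname, "stopped")
    return 0


if __name__ == "__main__":
    sys.exit(main())
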