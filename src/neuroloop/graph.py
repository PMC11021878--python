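"""Graph runtime: YAML-configured node graphs run as OS processes.

A *graph* is a set of *nodes* — independent processes that communicate only
through bus streams — described by a single YAML file.  The supervisor
parses the YAML, delivers each node's parameters through a per-node control
stream, launches one process per node, and starts or stops them on command.

Node lifecycle protocol (control stream ``ctl:<nickname>``):

1. supervisor writes the parameter entry, then spawns the process;
2. the node host reads its parameters, publishes ``initialized`` on
   ``status:<nickname>`` and waits for ``go``;
3. on ``go`` it enters the node's run loop, heartbeating every second;
4. on ``stop`` it exits its loop and the process terminates; the supervisor
   force-kills after a grace period if needed.

A node process that exits while never having been told to stop is reported
as crashed.  One stream has exactly one writing node (validated), which
keeps per-node latency attribution well-defined.
"""

from __future__ import annotations

import importlib.util
import json
import os
import subprocess
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .bus import Bus, BusConfig, SocketBus, connect

__all__ = [
    "NodeSpec",
    "GraphConfig",
    "NodeStatus",
    "GraphValidationError",
    "parse_graph",
    "start_graph",
    "RunningGraph",
    "apply_scheduling",
    "supervisor_listen",
    "INIT_TIMEOUT_S",
    "STOP_TIMEOUT_S",
]

INIT_TIMEOUT_S = 5.0
STOP_TIMEOUT_S = 2.0
HEARTBEAT_S = 1.0


class GraphValidationError(ValueError):
    pass


@dataclass
class NodeSpec:
    """One node: what to run, with which parameters, on which resources."""

    nickname: str
    executable: str  # "package.module:function" or path to a .py file
    parameters: Dict = field(default_factory=dict)
    machine: str = "localhost"
    run_priority: Optional[int] = None
    cpu_affinity: Optional[List[int]] = None
    input_streams: List[str] = field(default_factory=list)
    output_streams: List[str] = field(default_factory=list)


@dataclass
class GraphConfig:
    graph_name: str
    nodes: List[NodeSpec]
    bus: BusConfig = field(default_factory=BusConfig)
    external_streams: List[str] = field(default_factory=list)


@dataclass
class NodeStatus:
    nickname: str
    state: str  # initialized | running | stopped | crashed
    pid: int = -1
    last_heartbeat_ns: int = 0
    forced: bool = False


def _executable_exists(ref: str) -> bool:
    if ref.endswith(".py"):
        return Path(ref).is_file()
    module = ref.split(":")[0]
    try:
        return importlib.util.find_spec(module) is not None
    except (ImportError, ValueError):
        return False


def parse_graph(yaml_text: str) -> GraphConfig:
    """Parse and validate a graph YAML document.

    Schema: top-level ``graph_name``, ``nodes`` (list of mappings with
    ``nickname``, ``executable`` and optional ``parameters``,
    ``run_priority``, ``cpu_affinity``, ``input_streams``,
    ``output_streams``), optional ``bus`` and ``external_streams``.
    """
    doc = yaml.safe_load(yaml_text)
    if not isinstance(doc, dict):
        raise GraphValidationError("graph YAML must be a mapping")
    name = doc.get("graph_name")
    if not name:
        raise GraphValidationError("graph_name is required")
    raw_nodes = doc.get("nodes") or []
    if not raw_nodes:
        raise GraphValidationError("a graph must declare at least one node")

    nodes: List[NodeSpec] = []
    for entry in raw_nodes:
        if "nickname" not in entry or "executable" not in entry:
            raise GraphValidationError("every node needs nickname and executable")
        nodes.append(NodeSpec(
            nickname=str(entry["nickname"]),
            executable=str(entry["executable"]),
            parameters=dict(entry.get("parameters") or {}),
            machine=str(entry.get("machine", "localhost")),
            run_priority=entry.get("run_priority"),
            cpu_affinity=list(entry["cpu_affinity"]) if entry.get("cpu_affinity") else None,
            input_streams=list(entry.get("input_streams") or []),
            output_streams=list(entry.get("output_streams") or []),
        ))

    nicks = [n.nickname for n in nodes]
    if len(set(nicks)) != len(nicks):
        dupes = sorted({n for n in nicks if nicks.count(n) > 1})
        raise GraphValidationError(f"duplicate nicknames: {dupes}")
    seen_outputs: Dict[str, str] = {}
    for n in nodes:
        for s in n.output_streams:
            if s in seen_outputs:
                raise GraphValidationError(
                    f"stream {s!r} written by both {seen_outputs[s]!r} and "
                    f"{n.nickname!r} (one writer per stream)")
            seen_outputs[s] = n.nickname
    external = list(doc.get("external_streams") or [])
    produced = set(seen_outputs) | set(external)
    for n in nodes:
        missing = [s for s in n.input_streams if s not in produced]
        if missing:
            raise GraphValidationError(
                f"node {n.nickname!r} reads streams nobody produces: {missing}")
    for n in nodes:
        if not _executable_exists(n.executable):
            raise GraphValidationError(
                f"node {n.nickname!r}: unknown executable {n.executable!r}")

    bus_doc = doc.get("bus") or {}
    bus = BusConfig(**bus_doc) if bus_doc else BusConfig()
    return GraphConfig(graph_name=str(name), nodes=nodes, bus=bus,
                       external_streams=external)


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------

def apply_scheduling(spec: NodeSpec, pid: int) -> Dict:
    """Apply requested priority/affinity; report requested vs achieved.

    Priority is the Unix niceness (lower = more favorable); setting a
    negative niceness without privilege degrades gracefully to a warning.
    """
    report: Dict = {"nickname": spec.nickname, "warnings": []}
    if spec.cpu_affinity is None and spec.run_priority is None:
        report["scheduling"] = "defaults"
        return report
    if spec.cpu_affinity is not None:
        report["requested_affinity"] = sorted(spec.cpu_affinity)
        try:
            os.sched_setaffinity(pid, set(spec.cpu_affinity))
        except (PermissionError, OSError) as exc:
            report["warnings"].append(f"affinity not applied: {exc}")
        report["achieved_affinity"] = sorted(os.sched_getaffinity(pid))
    if spec.run_priority is not None:
        report["requested_priority"] = spec.run_priority
        try:
            os.setpriority(os.PRIO_PROCESS, pid, spec.run_priority)
        except (PermissionError, OSError) as exc:
            report["warnings"].append(f"priority not applied: {exc}")
        report["achieved_priority"] = os.getpriority(os.PRIO_PROCESS, pid)
    return report


# ---------------------------------------------------------------------------
# Running graphs
# ---------------------------------------------------------------------------

def _ctl(nick: str) -> str:
    return f"ctl:{nick}"


def _status(nick: str) -> str:
    return f"status:{nick}"


class RunningGraph:
    """Handle to a started graph: per-node processes plus status accessors."""

    def __init__(self, config: GraphConfig, bus: Bus,
                 processes: Dict[str, subprocess.Popen],
                 scheduling_reports: List[Dict]) -> None:
        self.config = config
        self.bus = bus
        self.processes = processes
        self.scheduling_reports = scheduling_reports
        self._stop_requested: Dict[str, bool] = {n: False for n in processes}
        self._final_status: Dict[str, NodeStatus] = {}

    def status(self) -> Dict[str, NodeStatus]:
        out: Dict[str, NodeStatus] = {}
        for nick, proc in self.processes.items():
            if nick in self._final_status:
                out[nick] = self._final_status[nick]
                continue
            entries = self.bus.read_range(_status(nick))
            last_state = "initialized"
            last_hb = 0
            for e in entries:
                doc = json.loads(e.fields["status"].decode())
                last_state = doc["state"]
                last_hb = e.write_timestamp_ns or last_hb
            rc = proc.poll()
            if rc is not None and not self._stop_requested[nick]:
                last_state = "crashed"
            elif rc is not None:
                last_state = "stopped"
            out[nick] = NodeStatus(nickname=nick, state=last_state, pid=proc.pid,
                                   last_heartbeat_ns=last_hb)
        return out

    def stop_node(self, nickname: str, timeout_s: float = STOP_TIMEOUT_S) -> NodeStatus:
        if nickname not in self.processes:
            raise ValueError(f"unknown nickname {nickname!r}")
        proc = self.processes[nickname]
        if nickname in self._final_status:
            return self._final_status[nickname]
        crashed = proc.poll() is not None and not self._stop_requested[nickname]
        self._stop_requested[nickname] = True
        self.bus.write_entry(_ctl(nickname), {"cmd": b"stop"})
        forced = False
        try:
            proc.wait(timeout=timeout_s)
        except subprocess.TimeoutExpired:
            proc.terminate()
            try:
                proc.wait(timeout=1.0)
            except subprocess.TimeoutExpired:
                proc.kill()
                proc.wait()
            forced = True
        status = NodeStatus(nickname=nickname,
                            state="crashed" if crashed else "stopped",
                            pid=proc.pid, forced=forced)
        self._final_status[nickname] = status
        return status

    def stop(self, timeout_s: float = STOP_TIMEOUT_S) -> Dict[str, NodeStatus]:
        """Stop every node; idempotent."""
        return {nick: self.stop_node(nick, timeout_s) for nick in self.processes}

    def wait_running(self, timeout_s: float = INIT_TIMEOUT_S) -> None:
        deadline = time.monotonic() + timeout_s
        pending = set(self.processes)
        while pending and time.monotonic() < deadline:
            for nick in sorted(pending):
                states = [json.loads(e.fields["status"].decode())["state"]
                          for e in self.bus.read_range(_status(nick))]
                if "running" in states:
                    pending.discard(nick)
                elif self.processes[nick].poll() is not None:
                    raise RuntimeError(f"node {nick!r} exited during startup")
            if pending:
                time.sleep(0.01)
        if pending:
            raise TimeoutError(f"nodes never reached running: {sorted(pending)}")


def start_graph(config: GraphConfig, bus: Optional[Bus] = None,
                wait: bool = False) -> RunningGraph:
    """Launch every node of a graph as a separate OS process.

    Requires a socket transport in ``config.bus`` (separate processes cannot
    share an in-process store).  Parameters are written to each node's
    control stream *before* its process is spawned, so they are guaranteed
    to precede the run loop; ``go`` is broadcast once all processes are up.
    On any launch failure all started processes are stopped.
    """
    if config.bus.transport == "inproc":
        raise GraphValidationError(
            "start_graph needs a socket bus transport; inproc streams "
            "cannot cross process boundaries")
    if bus is None:
        bus = connect(config.bus)

    processes: Dict[str, subprocess.Popen] = {}
    reports: List[Dict] = []
    try:
        for spec in config.nodes:
            bus.write_entry(_ctl(spec.nickname), {
                "cmd": b"params",
                "executable": spec.executable.encode(),
                "params": json.dumps(spec.parameters).encode(),
            })
            argv = [sys.executable, "-m", "neuroloop.nodehost",
                    "--nickname", spec.nickname,
                    "--transport", config.bus.transport,
                    "--host", config.bus.host, "--port", str(config.bus.port),
                    "--socket-path", config.bus.socket_path]
            try:
                proc = subprocess.Popen(argv)
            except OSError as exc:
                raise RuntimeError(
                    f"node {spec.nickname!r}: failed to launch: {exc}") from exc
            processes[spec.nickname] = proc
            reports.append(apply_scheduling(spec, proc.pid))
        for spec in config.nodes:
            bus.write_entry(_ctl(spec.nickname), {"cmd": b"go"})
    except Exception:
        for nick, proc in processes.items():
            bus.write_entry(_ctl(nick), {"cmd": b"stop"})
            proc.terminate()
        for proc in processes.values():
            try:
                proc.wait(timeout=2.0)
            except subprocess.TimeoutExpired:
                proc.kill()
        raise
    handle = RunningGraph(config, bus, processes, reports)
    if wait:
        handle.wait_running()
    return handle


# ---------------------------------------------------------------------------
# Supervisor command loop
# ---------------------------------------------------------------------------

SUPERVISOR_CTL = "supervisor_ctl"
SUPERVISOR_REPLY = "supervisor_reply"


def supervisor_listen(bus: Bus, max_commands: Optional[int] = None) -> None:
    """Consume ``{load_graph, start, stop, status, shutdown}`` commands.

    Commands arrive as JSON in the ``cmd`` field of the ``supervisor_ctl``
    stream; replies are published to ``supervisor_reply``.  Malformed
    commands produce an error reply and the loop continues.  ``max_commands``
    bounds the loop for testing; by default the loop never returns (until a
    ``shutdown`` command).
    """
    last_id = 0
    loaded: Optional[GraphConfig] = None
    running: Optional[RunningGraph] = None
    handled = 0

    def reply(doc: Dict) -> None:
        bus.write_entry(SUPERVISOR_REPLY, {"reply": json.dumps(doc).encode()})

    while max_commands is None or handled < max_commands:
        entries = bus.read_next(SUPERVISOR_CTL, last_id, block_ms=200)
        for e in entries:
            last_id = e.entry_id
            handled += 1
            try:
                doc = json.loads(e.fields["cmd"].decode())
                cmd = doc["command"]
            except (KeyError, ValueError, UnicodeDecodeError) as exc:
                reply({"ok": False, "error": f"malformed command: {exc}"})
                continue
            try:
                if cmd == "load_graph":
                    loaded = parse_graph(doc["yaml"])
                    reply({"ok": True, "loaded": loaded.graph_name})
                elif cmd == "start":
                    if loaded is None:
                        reply({"ok": False, "error": "no graph"})
                    else:
                        running = start_graph(loaded, bus=bus, wait=True)
                        reply({"ok": True, "started": loaded.graph_name})
                elif cmd == "stop":
                    if running is None:
                        reply({"ok": False, "error": "no graph"})
                    else:
                        statuses = running.stop()
                        reply({"ok": True, "stopped": {k: v.state
                                                       for k, v in statuses.items()}})
                        running = None
                elif cmd == "status":
                    if running is None:
                        reply({"ok": True, "nodes": {}})
                    else:
                        reply({"ok": True, "nodes": {
                            k: v.state for k, v in running.status().items()}})
                elif cmd == "shutdown":
                    if running is not None:
                        running.stop()
                    reply({"ok": True, "shutdown": True})
                    return
                else:
                    reply({"ok": False, "error": f"unknown command {cmd!r}"})
            except Exception as exc:  # keep the loop alive on any failure
                reply({"ok": False, "error": str(exc)})
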