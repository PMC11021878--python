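"""Graph runtime: YAML validation, process lifecycle, supervisor, scheduling."""

import json
import os
import threading
import time

import numpy as np
import pytest

from neuroloop.bus import BusConfig, InProcessBus, connect
from neuroloop.graph import (SUPERVISOR_CTL, SUPERVISOR_REPLY,
                             GraphValidationError, apply_scheduling,
                             parse_graph, start_graph, supervisor_listen)

THREE_NODE_YAML = """
graph_name: chain
nodes:
  - nickname: pub
    executable: neuroloop.nodes:publisher
    parameters: {channels: 8, rate_hz: 1000, n_packets: 100, output_stream: s0}
    output_streams: [s0]
  - nickname: relay
    executable: neuroloop.nodes:forwarder
    parameters: {input_stream: s0, output_stream: s1}
    input_streams: [s0]
    output_streams: [s1]
  - nickname: sub
    executable: neuroloop.nodes:subscriber
    parameters: {input_stream: s1, output_stream: s2}
    input_streams: [s1]
    output_streams: [s2]
"""


class TestParseGraph:
    def test_three_node_chain_parsed_verbatim(self):
        cfg = parse_graph(THREE_NODE_YAML)
        assert cfg.graph_name == "chain"
        assert [n.nickname for n in cfg.nodes] == ["pub", "relay", "sub"]
        assert cfg.nodes[0].parameters == {"channels": 8, "rate_hz": 1000,
                                           "n_packets": 100,
                                           "output_stream": "s0"}
        assert cfg.nodes[1].input_streams == ["s0"]

    def test_zero_nodes_rejected(self):
        with pytest.raises(GraphValidationError, match="at least one node"):
            parse_graph("graph_name: empty\nnodes: []\n")

    def test_duplicate_nicknames_rejected(self):
        yaml_text = """
graph_name: dup
nodes:
  - {nickname: a, executable: "neuroloop.nodes:noop"}
  - {nickname: a, executable: "neuroloop.nodes:noop"}
"""
        with pytest.raises(GraphValidationError, match="duplicate"):
            parse_graph(yaml_text)

    def test_two_writers_same_stream_rejected(self):
        yaml_text = """
graph_name: conflict
nodes:
  - {nickname: a, executable: "neuroloop.nodes:noop", output_streams: [s]}
  - {nickname: b, executable: "neuroloop.nodes:noop", output_streams: [s]}
"""
        with pytest.raises(GraphValidationError, match="one writer"):
            parse_graph(yaml_text)

    def test_unknown_executable_rejected(self):
        yaml_text = """
graph_name: bad
nodes:
  - {nickname: a, executable: "no.such.module:run"}
"""
        with pytest.raises(GraphValidationError, match="unknown executable"):
            parse_graph(yaml_text)

    def test_unproduced_input_stream_rejected(self):
        yaml_text = """
graph_name: dangling
nodes:
  - {nickname: a, executable: "neuroloop.nodes:noop", input_streams: [ghost]}
"""
        with pytest.raises(GraphValidationError, match="nobody produces"):
            parse_graph(yaml_text)

    def test_external_stream_declaration_accepted(self):
        yaml_text = """
graph_name: ext
external_streams: [ghost]
nodes:
  - {nickname: a, executable: "neuroloop.nodes:noop", input_streams: [ghost]}
"""
        assert parse_graph(yaml_text).external_streams == ["ghost"]


class TestScheduling:
    def test_defaults_report(self):
        from neuroloop.graph import NodeSpec
        report = apply_scheduling(NodeSpec("n", "neuroloop.nodes:noop"),
                                  os.getpid())
        assert report["scheduling"] == "defaults"

    def test_affinity_applied_or_warned(self):
        from neuroloop.graph import NodeSpec
        spec = NodeSpec("n", "neuroloop.nodes:noop", cpu_affinity=[0])
        report = apply_scheduling(spec, os.getpid())
        # on any host either it worked (affinity == {0}) or it warned
        assert report["achieved_affinity"] == [0] or report["warnings"]
        os.sched_setaffinity(os.getpid(), range(os.cpu_count()))

    def test_priority_degrades_gracefully(self):
        from neuroloop.graph import NodeSpec
        spec = NodeSpec("n", "neuroloop.nodes:noop", run_priority=-5)
        report = apply_scheduling(spec, os.getpid())
        assert "achieved_priority" in report  # warning allowed, never fatal


@pytest.mark.timeout(120)
class TestLifecycle:
    def test_full_lifecycle_parameters_crash_and_stop(self, tcp_server):
        """One multiprocess run covering parameter fidelity, crash
        detection, forced termination, partial stop and idempotency."""
        port = tcp_server.config.port
        yaml_text = f"""
graph_name: lifecycle
bus: {{transport: tcp, port: {port}}}
nodes:
  - nickname: echo
    executable: neuroloop.nodes:echo_params
    parameters: {{channels: 128, nested: {{alpha: 0.3}}, echo_stream: echo_out}}
    output_streams: [echo_out]
  - nickname: idle
    executable: neuroloop.nodes:noop
  - nickname: quitter
    executable: neuroloop.nodes:exit_immediately
  - nickname: mule
    executable: neuroloop.nodes:stubborn
"""
        cfg = parse_graph(yaml_text)
        handle = start_graph(cfg)
        bus = connect(cfg.bus)
        try:
            (entry,) = bus.read_next("echo_out", 0, block_ms=30_000)
            observed = json.loads(entry.fields["params"].decode())
            assert observed == {"channels": 128, "nested": {"alpha": 0.3},
                                "echo_stream": "echo_out"}
            deadline = time.monotonic() + 20
            while handle.status()["quitter"].state != "crashed":
                assert time.monotonic() < deadline
                time.sleep(0.1)

            idle_status = handle.stop_node("idle")
            assert idle_status.state == "stopped"
            assert handle.status()["echo"].state == "running"

            statuses = handle.stop()
            assert statuses["echo"].state == "stopped"
            assert statuses["mule"].forced  # ignored the stop command
            assert not statuses["echo"].forced
            # idempotent: a second stop is a no-op with the same result
            again = handle.stop()
            assert {k: v.state for k, v in again.items()} == \
                {k: v.state for k, v in statuses.items()}
        finally:
            handle.stop()

    def test_start_requires_socket_transport(self):
        cfg = parse_graph(THREE_NODE_YAML)
        with pytest.raises(GraphValidationError, match="socket"):
            start_graph(cfg)


@pytest.mark.timeout(120)
class TestSupervisor:
    def test_command_loop_end_to_end(self, tcp_server):
        port = tcp_server.config.port
        bus = connect(tcp_server.config)
        yaml_text = f"""
graph_name: tiny
bus: {{transport: tcp, port: {port}}}
nodes:
  - nickname: idle
    executable: neuroloop.nodes:noop
"""
        t = threading.Thread(target=supervisor_listen,
                             args=(connect(tcp_server.config),),
                             kwargs={"max_commands": 7}, daemon=True)
        t.start()

        def send(doc):
            bus.write_entry(SUPERVISOR_CTL, {"cmd": json.dumps(doc).encode()})

        def replies(n, last=0, timeout_s=60):
            out = []
            deadline = time.monotonic() + timeout_s
            while len(out) < n and time.monotonic() < deadline:
                for e in bus.read_next(SUPERVISOR_REPLY, last, block_ms=500):
                    last = e.entry_id
                    out.append(json.loads(e.fields["reply"].decode()))
            return out, last

        send({"command": "stop"})                      # no graph yet
        send({"command": "load_graph", "yaml": yaml_text})
        send({"command": "start"})
        send({"command": "status"})
        bus.write_entry(SUPERVISOR_CTL, {"cmd": b"not json"})  # malformed
        send({"command": "stop"})
        send({"command": "shutdown"})
        out, _ = replies(7)
        t.join(timeout=30)
        assert out[0] == {"ok": False, "error": "no graph"}
        assert out[1]["ok"] and out[1]["loaded"] == "tiny"
        assert out[2]["ok"]
        assert out[3] == {"ok": True, "nodes": {"idle": "running"}}
        assert not out[4]["ok"] and "malformed" in out[4]["error"]
        assert out[5] == {"ok": True, "stopped": {"idle": "stopped"}}
        assert out[6]["ok"]


@pytest.mark.timeout(180)
class TestParallelism:
    def test_parallel_chain_does_not_slow_publisher(self, tcp_server):
        """A slow terminal node must not perturb the publisher's pacing,
        unlike a sequential single-process execution of the same chain.

        Scaled for a single-core host: 200 Hz publisher, 10 ms of downstream
        work per packet.
        """
        from neuroloop.bench import BenchConfig, run_sequential_reference, \
            median_midpoint
        port = tcp_server.config.port
        rate, n_packets = 200, 300

        def run_chain(with_sleeper: bool):
            suffix = "p" if with_sleeper else "solo"
            nodes = f"""
  - nickname: pub{suffix}
    executable: neuroloop.nodes:publisher
    parameters: {{channels: 8, rate_hz: {rate}, n_packets: {n_packets},
                 output_stream: a{suffix}}}
    output_streams: [a{suffix}]
"""
            if with_sleeper:
                nodes += f"""
  - nickname: relay{suffix}
    executable: neuroloop.nodes:forwarder
    parameters: {{input_stream: a{suffix}, output_stream: b{suffix}}}
    input_streams: [a{suffix}]
    output_streams: [b{suffix}]
  - nickname: slow{suffix}
    executable: neuroloop.nodes:forwarder
    parameters: {{input_stream: b{suffix}, output_stream: c{suffix},
                 sleep_ms: 10}}
    input_streams: [b{suffix}]
    output_streams: [c{suffix}]
"""
            yaml_text = (f"graph_name: par{suffix}\n"
                         f"bus: {{transport: tcp, port: {port}}}\n"
                         f"nodes:{nodes}")
            cfg = parse_graph(yaml_text)
            handle = start_graph(cfg)
            bus = connect(cfg.bus)
            deadline = time.monotonic() + 120
            while bus.stream_length(f"a{suffix}") < n_packets:
                assert time.monotonic() < deadline, "publisher never finished"
                time.sleep(0.1)
            handle.stop()
            ts = [e.write_timestamp_ns for e in bus.read_range(f"a{suffix}")]
            return median_midpoint(np.diff(ts))

        solo = run_chain(with_sleeper=False)
        chained = run_chain(with_sleeper=True)
        nominal = 1e9 / rate
        assert abs(chained - solo) / solo < 0.05
        assert abs(solo - nominal) / nominal < 0.10

        # the sequential reference provably falls behind
        seq = run_sequential_reference(
            BenchConfig(channels=8, rate_hz=rate, n_packets=100),
            work_s_per_packet=0.010)
        assert seq["final_lag_s"] > 0.3
        assert median_midpoint(seq["publish_intervals_ns"]) > 1.5 * nominal
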