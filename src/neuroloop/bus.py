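"""Append-only stream bus: the inter-node communication layer.

Every node in a graph publishes to and subscribes from named *streams* —
append-only logs of immutable entries with strictly increasing ids.  A full
session is therefore a set of logs that can be archived and replayed
bit-exactly.

Two interchangeable backends implement one contract (:class:`Bus`):

* :class:`InProcessBus` — a thread-safe in-memory store, used when all nodes
  live in one process (unit tests, accelerated session replay, thread-based
  benchmarks).
* :class:`SocketBus` + :class:`StreamServer` — the same store served over a
  TCP or Unix-domain socket with a small length-prefixed binary protocol
  (XADD/XREAD-equivalent commands), used when nodes run as separate OS
  processes.

Write timestamps are taken from the monotonic clock *immediately before* the
write call and carried inside the entry fields (key ``_ts``), so per-node
latency arithmetic uses a single clock domain per host rather than
store-assigned ids.
"""

from __future__ import annotations

import json
import os
import socket
import socketserver
import struct
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional

import numpy as np

__all__ = [
    "StreamEntry",
    "BusConfig",
    "Bus",
    "InProcessBus",
    "StreamServer",
    "SocketBus",
    "connect",
    "now_ns",
    "encode_int16_block",
    "decode_int16_block",
    "export_session",
    "load_session",
    "BEGINNING",
]

#: Sentinel last-seen id meaning "read from the beginning of the stream".
BEGINNING = 0

#: Field key under which the writer's monotonic timestamp (int64 LE ns) is stored.
TS_FIELD = "_ts"

#: Upper bound on a single field value; larger values raise rather than stall the bus.
MAX_FIELD_BYTES = 1 << 26  # 64 MiB


def now_ns() -> int:
    """Monotonic wall-independent clock in integer nanoseconds.

    Non-decreasing across successive calls within one process; the single
    clock domain used for all latency measurements on a host.
    """
    return time.monotonic_ns()


# ---------------------------------------------------------------------------
# int16 block codec
# ---------------------------------------------------------------------------

def encode_int16_block(samples: np.ndarray) -> bytes:
    """Serialize a C×S matrix of 16-bit integers to little-endian bytes.

    The byte length is always ``C*S*2``; row-major (channel-major) order.
    """
    arr = np.asarray(samples)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    if arr.dtype != np.int16:
        if not np.array_equal(arr, arr.astype(np.int16)):
            raise ValueError("values outside the signed 16-bit range")
        arr = arr.astype(np.int16)
    return arr.astype("<i2", copy=False).tobytes(order="C")


def decode_int16_block(data: bytes, channels: int, samples_per_channel: int) -> np.ndarray:
    """Inverse of :func:`encode_int16_block`; raises on length mismatch."""
    expected = channels * samples_per_channel * 2
    if len(data) != expected:
        raise ValueError(
            f"payload length {len(data)} != {expected} "
            f"({channels} channels x {samples_per_channel} samples x 2 bytes)"
        )
    return np.frombuffer(data, dtype="<i2").reshape(channels, samples_per_channel).astype(np.int16)


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StreamEntry:
    """One immutable record in an append-only stream."""

    stream_name: str
    entry_id: int
    fields: Dict[str, bytes]

    @property
    def write_timestamp_ns(self) -> Optional[int]:
        """Writer-side monotonic timestamp, if the entry carries one."""
        raw = self.fields.get(TS_FIELD)
        if raw is None or len(raw) != 8:
            return None
        return struct.unpack("<q", raw)[0]


@dataclass
class BusConfig:
    """How to reach the stream store.

    ``transport`` selects an in-process store (``inproc``), a Unix-domain
    socket (``local_socket``; faster, single host) or TCP (``tcp``;
    multi-host capable).  ``max_stream_length`` enables ring-buffer trimming
    for long benchmarks; by default streams grow without bound so a session
    retains its complete log.
    """

    transport: str = "inproc"
    host: str = "127.0.0.1"
    port: int = 6380
    socket_path: str = ""
    max_stream_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.transport not in ("inproc", "local_socket", "tcp"):
            raise ValueError(f"unknown transport {self.transport!r}")
        if self.max_stream_length is not None and self.max_stream_length < 1:
            raise ValueError("max_stream_length must be >= 1")


class _Stream:
    __slots__ = ("entries", "next_id")

    def __init__(self) -> None:
        self.entries: List[StreamEntry] = []
        self.next_id = 1


class StreamStore:
    """Thread-safe in-memory collection of append-only streams.

    Ids are per-stream, start at 1 and increase by 1 per append, so they are
    strictly increasing in write order under any thread interleaving (the
    append happens inside the store lock).
    """

    def __init__(self, max_stream_length: Optional[int] = None) -> None:
        self._streams: Dict[str, _Stream] = {}
        self._lock = threading.Lock()
        self._cond = threading.Condition(self._lock)
        self.max_stream_length = max_stream_length

    def xadd(self, stream: str, fields: Dict[str, bytes]) -> int:
        for name, value in fields.items():
            if not isinstance(value, (bytes, bytearray, memoryview)):
                raise TypeError(f"field {name!r} must be bytes, got {type(value).__name__}")
            if len(value) > MAX_FIELD_BYTES:
                raise ValueError(f"field {name!r} exceeds {MAX_FIELD_BYTES} bytes")
        frozen = {k: bytes(v) for k, v in fields.items()}
        with self._cond:
            st = self._streams.setdefault(stream, _Stream())
            eid = st.next_id
            st.next_id += 1
            st.entries.append(StreamEntry(stream, eid, frozen))
            if self.max_stream_length is not None and len(st.entries) > self.max_stream_length:
                del st.entries[: len(st.entries) - self.max_stream_length]
            self._cond.notify_all()
            return eid

    def _collect(self, stream: str, last_id: int, count: Optional[int]) -> List[StreamEntry]:
        st = self._streams.get(stream)
        if st is None:
            return []
        # entries list may be trimmed at the front; ids stay contiguous within it
        entries = st.entries
        if not entries or entries[-1].entry_id <= last_id:
            return []
        first_id = entries[0].entry_id
        start = max(0, last_id - first_id + 1)
        out = entries[start:]
        if count is not None:
            out = out[:count]
        return list(out)

    def xread(self, stream: str, last_id: int = BEGINNING, block_ms: int = 0,
              count: Optional[int] = None) -> List[StreamEntry]:
        if last_id < 0:
            raise ValueError(f"malformed id {last_id}")
        deadline = time.monotonic() + block_ms / 1000.0
        with self._cond:
            while True:
                out = self._collect(stream, last_id, count)
                if out or block_ms <= 0:
                    return out
                remaining = deadline - time.monotonic()
                if remaining <= 0:
                    return []
                self._cond.wait(remaining)

    def xrange(self, stream: str, start: int = 1, end: Optional[int] = None) -> List[StreamEntry]:
        with self._lock:
            st = self._streams.get(stream)
            if st is None:
                return []
            return [e for e in st.entries
                    if e.entry_id >= start and (end is None or e.entry_id <= end)]

    def xlen(self, stream: str) -> int:
        with self._lock:
            st = self._streams.get(stream)
            return len(st.entries) if st else 0

    def stream_names(self) -> List[str]:
        with self._lock:
            return sorted(self._streams)


# ---------------------------------------------------------------------------
# Bus interface
# ---------------------------------------------------------------------------

class Bus:
    """Contract shared by the in-process and socket backends."""

    def write_entry(self, stream_name: str, fields: Dict[str, bytes],
                    clock: Callable[[], int] = now_ns) -> int:
        """Append ``fields`` to a stream; returns the new strictly-greater id.

        The monotonic timestamp is sampled immediately before the underlying
        write operation and stored in the ``_ts`` field.
        """
        stamped = dict(fields)
        stamped[TS_FIELD] = struct.pack("<q", clock())
        return self._xadd(stream_name, stamped)

    def read_next(self, stream_name: str, last_seen_id: int = BEGINNING,
                  block_ms: int = 0, count: Optional[int] = None) -> List[StreamEntry]:
        """All entries with id > ``last_seen_id`` in id order.

        Blocks up to ``block_ms`` when none are available; an unknown stream
        simply yields an empty list (it may not have been created yet).
        """
        return self._xread(stream_name, last_seen_id, block_ms, count)

    def read_range(self, stream_name: str, start: int = 1,
                   end: Optional[int] = None) -> List[StreamEntry]:
        return self._xrange(stream_name, start, end)

    def stream_length(self, stream_name: str) -> int:
        return self._xlen(stream_name)

    def stream_names(self) -> List[str]:
        raise NotImplementedError

    def close(self) -> None:  # pragma: no cover - trivial default
        pass

    # backend primitives
    def _xadd(self, stream: str, fields: Dict[str, bytes]) -> int:
        raise NotImplementedError

    def _xread(self, stream: str, last_id: int, block_ms: int,
               count: Optional[int]) -> List[StreamEntry]:
        raise NotImplementedError

    def _xrange(self, stream: str, start: int, end: Optional[int]) -> List[StreamEntry]:
        raise NotImplementedError

    def _xlen(self, stream: str) -> int:
        raise NotImplementedError


class InProcessBus(Bus):
    """Bus backed directly by a :class:`StreamStore` in this process.

    Multiple ``InProcessBus`` instances may share one store (one per thread
    or node object) — they then see each other's streams, mimicking separate
    clients of one server.
    """

    def __init__(self, store: Optional[StreamStore] = None,
                 max_stream_length: Optional[int] = None) -> None:
        self.store = store if store is not None else StreamStore(max_stream_length)

    def _xadd(self, stream, fields):
        return self.store.xadd(stream, fields)

    def _xread(self, stream, last_id, block_ms, count):
        return self.store.xread(stream, last_id, block_ms, count)

    def _xrange(self, stream, start, end):
        return self.store.xrange(stream, start, end)

    def _xlen(self, stream):
        return self.store.xlen(stream)

    def stream_names(self):
        return self.store.stream_names()


# ---------------------------------------------------------------------------
# Wire protocol
#
# Frame: u32 LE payload length, then payload.
# Request payload: u8 opcode, then opcode-specific encoding.
# Reply payload: u8 status (0 ok / 1 error), then body (error: utf-8 message).
# Strings are u16 LE length + utf-8; byte values are u32 LE length + raw.
# ---------------------------------------------------------------------------

OP_XADD, OP_XREAD, OP_XRANGE, OP_XLEN, OP_KEYS, OP_PING = 1, 2, 3, 4, 5, 6


def _pack_str(s: str) -> bytes:
    raw = s.encode()
    return struct.pack("<H", len(raw)) + raw


def _pack_bytes(b: bytes) -> bytes:
    return struct.pack("<I", len(b)) + b


class _Reader:
    def __init__(self, buf: bytes) -> None:
        self.buf = buf
        self.pos = 0

    def u8(self) -> int:
        v = self.buf[self.pos]
        self.pos += 1
        return v

    def _unpack(self, fmt: str, size: int):
        v = struct.unpack_from(fmt, self.buf, self.pos)[0]
        self.pos += size
        return v

    def u16(self): return self._unpack("<H", 2)
    def u32(self): return self._unpack("<I", 4)
    def u64(self): return self._unpack("<Q", 8)

    def s(self) -> str:
        n = self.u16()
        v = self.buf[self.pos:self.pos + n].decode()
        self.pos += n
        return v

    def b(self) -> bytes:
        n = self.u32()
        v = self.buf[self.pos:self.pos + n]
        self.pos += n
        return v


def _pack_entries(entries: Iterable[StreamEntry]) -> bytes:
    entries = list(entries)
    parts = [struct.pack("<I", len(entries))]
    for e in entries:
        parts.append(struct.pack("<Q", e.entry_id))
        parts.append(struct.pack("<H", len(e.fields)))
        for k, v in e.fields.items():
            parts.append(_pack_str(k))
            parts.append(_pack_bytes(v))
    return b"".join(parts)


def _unpack_entries(r: _Reader, stream: str) -> List[StreamEntry]:
    n = r.u32()
    out = []
    for _ in range(n):
        eid = r.u64()
        nf = r.u16()
        fields = {}
        for _ in range(nf):
            k = r.s()
            fields[k] = r.b()
        out.append(StreamEntry(stream, eid, fields))
    return out


def _recv_exact(sock: socket.socket, n: int) -> bytes:
    chunks = []
    while n:
        chunk = sock.recv(min(n, 1 << 20))
        if not chunk:
            raise ConnectionError("bus connection closed")
        chunks.append(chunk)
        n -= len(chunk)
    return b"".join(chunks)


def _send_frame(sock: socket.socket, payload: bytes) -> None:
    sock.sendall(struct.pack("<I", len(payload)) + payload)


def _recv_frame(sock: socket.socket) -> bytes:
    (length,) = struct.unpack("<I", _recv_exact(sock, 4))
    return _recv_exact(sock, length)


class _Handler(socketserver.BaseRequestHandler):
    def handle(self) -> None:
        store: StreamStore = self.server.store  # type: ignore[attr-defined]
        sock = self.request
        sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1) \
            if sock.family == socket.AF_INET else None
        try:
            while True:
                req = _recv_frame(sock)
                try:
                    reply = self._dispatch(store, _Reader(req))
                    _send_frame(sock, b"\x00" + reply)
                except (ValueError, TypeError) as exc:
                    _send_frame(sock, b"\x01" + str(exc).encode())
        except (ConnectionError, OSError):
            return

    @staticmethod
    def _dispatch(store: StreamStore, r: _Reader) -> bytes:
        op = r.u8()
        if op == OP_XADD:
            stream = r.s()
            nf = r.u16()
            fields = {}
            for _ in range(nf):
                k = r.s()
                fields[k] = r.b()
            return struct.pack("<Q", store.xadd(stream, fields))
        if op == OP_XREAD:
            stream = r.s()
            last_id, block_ms, count = r.u64(), r.u32(), r.u32()
            entries = store.xread(stream, last_id, block_ms,
                                  None if count == 0 else count)
            return _pack_entries(entries)
        if op == OP_XRANGE:
            stream = r.s()
            start, end = r.u64(), r.u64()
            return _pack_entries(store.xrange(stream, start, None if end == 0 else end))
        if op == OP_XLEN:
            return struct.pack("<Q", store.xlen(r.s()))
        if op == OP_KEYS:
            names = store.stream_names()
            return struct.pack("<I", len(names)) + b"".join(_pack_str(n) for n in names)
        if op == OP_PING:
            return b"pong"
        raise ValueError(f"unknown opcode {op}")


class _TCPServer(socketserver.ThreadingTCPServer):
    allow_reuse_address = True
    daemon_threads = True


class _UnixServer(socketserver.ThreadingUnixStreamServer):
    daemon_threads = True


class StreamServer:
    """Serve a :class:`StreamStore` over TCP or a Unix-domain socket."""

    def __init__(self, config: BusConfig, store: Optional[StreamStore] = None) -> None:
        if config.transport not in ("tcp", "local_socket"):
            raise ValueError("StreamServer requires a tcp or local_socket transport")
        self.config = config
        self.store = store if store is not None else StreamStore(config.max_stream_length)
        if config.transport == "tcp":
            self._server = _TCPServer((config.host, config.port), _Handler)
            # rebind config to the actual port when port 0 was requested
            self.config.port = self._server.server_address[1]
        else:
            if not config.socket_path:
                raise ValueError("local_socket transport needs socket_path")
            if os.path.exists(config.socket_path):
                os.unlink(config.socket_path)
            self._server = _UnixServer(config.socket_path, _Handler)
        self._server.store = self.store  # type: ignore[attr-defined]
        self._thread: Optional[threading.Thread] = None

    def start(self) -> "StreamServer":
        self._thread = threading.Thread(target=self._server.serve_forever,
                                        kwargs={"poll_interval": 0.05}, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        if self.config.transport == "local_socket" and os.path.exists(self.config.socket_path):
            os.unlink(self.config.socket_path)


class SocketBus(Bus):
    """Client for :class:`StreamServer`; one socket per bus instance.

    Not thread-safe across concurrent calls — use one instance per node
    thread/process, as each node would hold its own database connection.
    """

    def __init__(self, config: BusConfig) -> None:
        self.config = config
        try:
            if config.transport == "tcp":
                self._sock = socket.create_connection((config.host, config.port), timeout=30)
                self._sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
            elif config.transport == "local_socket":
                self._sock = socket.socket(socket.AF_UNIX, socket.SOCK_STREAM)
                self._sock.settimeout(30)
                self._sock.connect(config.socket_path)
            else:
                raise ValueError("SocketBus requires a tcp or local_socket transport")
        except OSError as exc:
            raise ConnectionError(f"stream bus unreachable: {exc}") from exc
        self._lock = threading.Lock()

    def _call(self, payload: bytes) -> _Reader:
        with self._lock:
            _send_frame(self._sock, payload)
            reply = _recv_frame(self._sock)
        if reply[:1] == b"\x01":
            raise ValueError(reply[1:].decode())
        return _Reader(reply[1:])

    def _xadd(self, stream, fields):
        parts = [bytes([OP_XADD]), _pack_str(stream), struct.pack("<H", len(fields))]
        for k, v in fields.items():
            if not isinstance(v, (bytes, bytearray, memoryview)):
                raise TypeError(f"field {k!r} must be bytes")
            if len(v) > MAX_FIELD_BYTES:
                raise ValueError(f"field {k!r} exceeds {MAX_FIELD_BYTES} bytes")
            parts.append(_pack_str(k))
            parts.append(_pack_bytes(bytes(v)))
        return self._call(b"".join(parts)).u64()

    def _xread(self, stream, last_id, block_ms, count):
        if last_id < 0:
            raise ValueError(f"malformed id {last_id}")
        old = self._sock.gettimeout()
        if block_ms > 0:
            self._sock.settimeout(block_ms / 1000.0 + 30)
        try:
            r = self._call(bytes([OP_XREAD]) + _pack_str(stream)
                           + struct.pack("<QII", last_id, block_ms, count or 0))
        finally:
            self._sock.settimeout(old)
        return _unpack_entries(r, stream)

    def _xrange(self, stream, start, end):
        r = self._call(bytes([OP_XRANGE]) + _pack_str(stream)
                       + struct.pack("<QQ", start, end or 0))
        return _unpack_entries(r, stream)

    def _xlen(self, stream):
        return self._call(bytes([OP_XLEN]) + _pack_str(stream)).u64()

    def stream_names(self):
        r = self._call(bytes([OP_KEYS]))
        return [r.s() for _ in range(r.u32())]

    def ping(self) -> bool:
        return self._call(bytes([OP_PING])).buf[1:] is not None

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass


def connect(config: BusConfig, store: Optional[StreamStore] = None) -> Bus:
    """Open a bus handle for the given transport.

    ``inproc`` returns an :class:`InProcessBus` (optionally sharing
    ``store``); socket transports return a connected :class:`SocketBus`.
    """
    if config.transport == "inproc":
        return InProcessBus(store, config.max_stream_length)
    return SocketBus(config)


# ---------------------------------------------------------------------------
# Session export
# ---------------------------------------------------------------------------

def export_session(bus: Bus, out_dir: str | Path) -> Path:
    """Dump every stream to ``out_dir`` as per-stream binary logs + JSON index.

    Layout: ``index.json`` maps stream name → log file + entry count; each
    log file holds concatenated frames ``u64 id, u16 nfields, (str key,
    bytes value)*``.  :func:`load_session` restores the dump bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {}
    for i, name in enumerate(bus.stream_names()):
        entries = bus.read_range(name)
        fname = f"stream_{i:04d}.log"
        with open(out / fname, "wb") as fh:
            for e in entries:
                fh.write(struct.pack("<Q", e.entry_id))
                fh.write(struct.pack("<H", len(e.fields)))
                for k, v in e.fields.items():
                    fh.write(_pack_str(k))
                    fh.write(_pack_bytes(v))
        index[name] = {"file": fname, "entries": len(entries)}
    with open(out / "index.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return out


def load_session(in_dir: str | Path) -> Dict[str, List[StreamEntry]]:
    """Reload a session dump produced by :func:`export_session`."""
    root = Path(in_dir)
    with open(root / "index.json") as fh:
        index = json.load(fh)
    streams: Dict[str, List[StreamEntry]] = {}
    for name, meta in index.items():
        data = (root / meta["file"]).read_bytes()
        r = _Reader(data)
        entries = []
        while r.pos < len(data):
            eid = r.u64()
            nf = r.u16()
            fields = {}
            for _ in range(nf):
                k = r.s()
                fields[k] = r.b()
            entries.append(StreamEntry(name, eid, fields))
        if len(entries) != meta["entries"]:
            raise ValueError(f"stream {name!r}: corrupt log "
                             f"({len(entries)} != {meta['entries']} entries)")
        streams[name] = entries
    return streams
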