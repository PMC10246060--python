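"""OpenIGTLink-subset wire codec and the real-time prediction loop.

Implements the TRANSFORM and IMAGE message types of the OpenIGTLink v2 header
layout — the two a real-time E-field viewer loop needs. Every message starts
with a 58-byte big-endian header::

    version(2) | type_name(12, null-padded) | device_name(20) |
    timestamp_ns(8) | body_size(8) | crc64(8)

followed by the body. The checksum is CRC-64/ECMA-182 (polynomial
0x42F0E1EBA9EA3693, init 0, not reflected) over the body bytes. A TRANSFORM
body is 12 IEEE-754 big-endian float32 values: the 3x3 rotation block in
column-major order, then the translation offset (mm). An IMAGE body is a
compact subset layout: dims (3 x uint16), spacing (3 x float32), dtype code
(uint8, 1=float32), then the raw voxels big-endian in C order.

The server loop answers each inbound coil-pose TRANSFORM with the magnitude
IMAGE of the surrogate's E-field prediction, recording the prediction (cnn)
and encode/transmit (vis) seconds separately per run.
"""

from __future__ import annotations

import socket
import struct
import time
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .coilmodel import CoilModel, CoilPose, dadt_field
from .fieldsolver import _crop_zerofill, scalp_projection
from .geometry import RigidTransform, VolumeGrid
from .headmodel import ConductivityVolume, HeadGeometry
from .surrogate import TrainedSurrogate, predict_efield

__all__ = [
    "HEADER_SIZE",
    "ProtocolError",
    "IntegrityError",
    "Message",
    "encode_message",
    "decode_message",
    "read_message",
    "LoopbackTransport",
    "loopback_pair",
    "TcpTransport",
    "SessionStats",
    "run_server_loop",
    "client_request",
]

HEADER_SIZE = 58
_VERSION = 2
_SUPPORTED_TYPES = ("TRANSFORM", "IMAGE")
_HEADER_FMT = ">H12s20sQQQ"  # version, type, device, timestamp, body_size, crc


class ProtocolError(ValueError):
    """Malformed, truncated, unsupported or oversized message."""


class IntegrityError(ProtocolError):
    """Body checksum mismatch."""


# --- CRC-64/ECMA-182 ------------------------------------------------------- #

_CRC64_POLY = 0x42F0E1EBA9EA3693


def _crc64_table() -> list[int]:
    table = []
    for byte in range(256):
        crc = byte << 56
        for _ in range(8):
            if crc & (1 << 63):
                crc = ((crc << 1) ^ _CRC64_POLY) & 0xFFFFFFFFFFFFFFFF
            else:
                crc = (crc << 1) & 0xFFFFFFFFFFFFFFFF
        table.append(crc)
    return table


_CRC64_TABLE = _crc64_table()


def crc64(data: bytes) -> int:
    """CRC-64/ECMA-182 (not reflected, init 0, xorout 0)."""
    crc = 0
    for b in data:
        crc = (_CRC64_TABLE[((crc >> 56) ^ b) & 0xFF] ^ (crc << 8)) & 0xFFFFFFFFFFFFFFFF
    return crc


# --- messages --------------------------------------------------------------- #


@dataclass
class Message:
    type_name: str
    device_name: str
    body: bytes
    timestamp_ns: int = 0
    version: int = _VERSION

    @property
    def body_size(self) -> int:
        return len(self.body)

    @property
    def crc(self) -> int:
        return crc64(self.body)


def _ascii_fixed(name: str, limit: int, what: str) -> bytes:
    raw = name.encode("ascii")
    if len(raw) > limit:
        raise ProtocolError(f"{what} exceeds {limit} ASCII bytes: {name!r}")
    return raw.ljust(limit, b"\x00")


def _transform_body(T: RigidTransform) -> bytes:
    m = T.matrix
    vals = [m[r, c] for c in range(3) for r in range(3)]  # rotation column-major
    vals += [m[0, 3], m[1, 3], m[2, 3]]
    return struct.pack(">12f", *vals)


def _parse_transform_body(body: bytes) -> RigidTransform:
    if len(body) != 48:
        raise ProtocolError(f"TRANSFORM body must be 48 bytes, got {len(body)}")
    vals = struct.unpack(">12f", body)
    m = np.eye(4)
    for c in range(3):
        for r in range(3):
            m[r, c] = vals[3 * c + r]
    m[:3, 3] = vals[9:12]
    # re-orthonormalize: float32 wire precision erodes the 1e-9 rigidity check
    u, _, vt = np.linalg.svd(m[:3, :3])
    m[:3, :3] = u @ vt
    return RigidTransform(m)


def _image_body(img: VolumeGrid) -> bytes:
    if img.values.ndim != 3:
        raise ProtocolError("IMAGE payload must be a scalar volume")
    dims = img.shape
    spacing = img.voxel_size
    head = struct.pack(">3H3fB", dims[0], dims[1], dims[2],
                       float(spacing[0]), float(spacing[1]), float(spacing[2]), 1)
    return head + img.values.astype(">f4").tobytes(order="C")


def _parse_image_body(body: bytes) -> VolumeGrid:
    hsize = struct.calcsize(">3H3fB")
    if len(body) < hsize:
        raise ProtocolError("IMAGE body truncated before voxel data")
    nx, ny, nz, sx, sy, sz, dtype_code = struct.unpack(">3H3fB", body[:hsize])
    if dtype_code != 1:
        raise ProtocolError(f"unsupported IMAGE dtype code {dtype_code}")
    n = nx * ny * nz
    raw = body[hsize:]
    if len(raw) != 4 * n:
        raise ProtocolError(f"IMAGE voxel payload {len(raw)} != {4 * n} bytes")
    vals = np.frombuffer(raw, dtype=">f4").reshape(nx, ny, nz).astype(np.float32)
    affine = np.diag([sx, sy, sz, 1.0])
    return VolumeGrid(vals, affine)


def encode_message(kind: str, payload, device_name: str = "tmsfield",
                   timestamp_ns: int | None = None) -> bytes:
    """Encode a TRANSFORM (RigidTransform/CoilPose) or IMAGE (scalar VolumeGrid)."""
    if kind == "TRANSFORM":
        if isinstance(payload, CoilPose):
            payload = payload.transform
        if not isinstance(payload, RigidTransform):
            try:
                payload = RigidTransform(np.asarray(payload))
            except Exception as exc:
                raise ProtocolError(f"TRANSFORM payload is not rigid: {exc}") from exc
        body = _transform_body(payload)
    elif kind == "IMAGE":
        body = _image_body(payload)
    else:
        raise ProtocolError(f"unsupported message type {kind!r}")
    if timestamp_ns is None:
        timestamp_ns = time.time_ns()
    header = struct.pack(
        _HEADER_FMT,
        _VERSION,
        _ascii_fixed(kind, 12, "type_name"),
        _ascii_fixed(device_name, 20, "device_name"),
        timestamp_ns,
        len(body),
        crc64(body),
    )
    assert len(header) == HEADER_SIZE
    return header + body


def decode_message(data: bytes) -> tuple[Message, int]:
    """Parse one message from the head of ``data``.

    Returns the message and the number of bytes consumed (framing for
    concatenated streams). Raises :class:`ProtocolError` on truncation or an
    unknown type and :class:`IntegrityError` on checksum mismatch.
    """
    if len(data) < HEADER_SIZE:
        raise ProtocolError(f"need at least {HEADER_SIZE} header bytes, got {len(data)}")
    version, type_raw, dev_raw, ts, body_size, crc = struct.unpack(
        _HEADER_FMT, data[:HEADER_SIZE])
    type_name = type_raw.rstrip(b"\x00").decode("ascii", errors="replace")
    if type_name not in _SUPPORTED_TYPES:
        raise ProtocolError(f"unsupported message type {type_name!r}")
    end = HEADER_SIZE + body_size
    if len(data) < end:
        raise ProtocolError(
            f"truncated body: header promises {body_size} bytes, {len(data) - HEADER_SIZE} present")
    body = data[HEADER_SIZE:end]
    if crc64(body) != crc:
        raise IntegrityError("body CRC-64 mismatch")
    msg = Message(type_name=type_name,
                  device_name=dev_raw.rstrip(b"\x00").decode("ascii", errors="replace"),
                  body=body, timestamp_ns=ts, version=version)
    return msg, end


def message_payload(msg: Message):
    """Decode a message body to its domain object."""
    if msg.type_name == "TRANSFORM":
        return _parse_transform_body(msg.body)
    return _parse_image_body(msg.body)


def decode_stream(data: bytes) -> list[Message]:
    """Split a byte stream of concatenated messages."""
    out = []
    off = 0
    while off < len(data):
        msg, used = decode_message(data[off:])
        out.append(msg)
        off += used
    return out


# --- transports ------------------------------------------------------------- #


class LoopbackTransport:
    """In-process, ordered, reliable byte transport (one end of a pair)."""

    def __init__(self, rx: deque, tx: deque):
        self._rx = rx
        self._tx = tx

    def send(self, data: bytes) -> None:
        self._tx.extend(data)

    def recv(self, n: int) -> bytes:
        if len(self._rx) < n:
            raise ConnectionError(
                f"transport exhausted: wanted {n} bytes, {len(self._rx)} available")
        return bytes(self._rx.popleft() for _ in range(n))

    def pending(self) -> int:
        return len(self._rx)


def loopback_pair() -> tuple[LoopbackTransport, LoopbackTransport]:
    a_to_b: deque = deque()
    b_to_a: deque = deque()
    return (LoopbackTransport(rx=b_to_a, tx=a_to_b),
            LoopbackTransport(rx=a_to_b, tx=b_to_a))


class TcpTransport:
    """Blocking TCP transport with the same send/recv-exactly contract."""

    def __init__(self, sock: socket.socket):
        self.sock = sock

    @classmethod
    def connect(cls, host: str, port: int) -> "TcpTransport":
        return cls(socket.create_connection((host, port)))

    def send(self, data: bytes) -> None:
        self.sock.sendall(data)

    def recv(self, n: int) -> bytes:
        buf = b""
        while len(buf) < n:
            chunk = self.sock.recv(n - len(buf))
            if not chunk:
                raise ConnectionError("socket closed mid-message")
            buf += chunk
        return buf

    def close(self) -> None:
        self.sock.close()


def read_message(transport) -> Message:
    """Read exactly one framed message from a transport."""
    header = transport.recv(HEADER_SIZE)
    body_size = struct.unpack(_HEADER_FMT, header)[4]
    body = transport.recv(body_size)
    msg, _ = decode_message(header + body)
    return msg


# --- the real-time loop ----------------------------------------------------- #


@dataclass
class SessionStats:
    """Per-run timing of the prediction loop (the CNN/Vis split)."""

    runs: list[dict] = field(default_factory=list)  # {cnn_seconds, vis_seconds}
    config: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def component_seconds(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.runs], dtype=float)


def run_server_loop(
    model: TrainedSurrogate,
    head: HeadGeometry,
    sigma: ConductivityVolume,
    coil: CoilModel,
    transport,
    n_runs: int,
    fov_shape: tuple[int, int, int] = (24, 24, 24),
    device_name: str = "tmsfield",
) -> SessionStats:
    """Serve ``n_runs`` pose->image rounds over a transport.

    For each inbound TRANSFORM (coil pose) the loop computes the coil's dA/dt
    over the reduced FOV around the scalp projection, runs the surrogate, and
    replies with the magnitude IMAGE. A malformed inbound message gets an
    error reply (an IMAGE with zero dims is not expressible, so the loop sends
    nothing and continues after logging) and does not count as a run; a
    transport failure aborts with the partial stats attached to the exception.
    """
    import logging

    log = logging.getLogger(__name__)
    stats = SessionStats(config={"n_runs": n_runs, "fov_shape": tuple(fov_shape)})
    fov = tuple(int(v) for v in fov_shape)
    while stats.n_runs < n_runs:
        try:
            msg = read_message(transport)
        except ProtocolError as exc:
            log.warning("dropping malformed inbound message: %s", exc)
            continue
        except ConnectionError as exc:
            exc.partial_stats = stats  # type: ignore[attr-defined]
            raise
        if msg.type_name != "TRANSFORM":
            log.warning("ignoring non-TRANSFORM inbound message %s", msg.type_name)
            continue
        pose = CoilPose(message_payload(msg))

        t0 = time.perf_counter()
        vec, mag = predict_for_pose(model, head, sigma, coil, pose, fov)
        t1 = time.perf_counter()
        reply = encode_message("IMAGE", mag, device_name=device_name)
        transport.send(reply)
        t2 = time.perf_counter()
        stats.runs.append({"cnn_seconds": t1 - t0, "vis_seconds": t2 - t1})
    return stats


def predict_for_pose(model, head, sigma, coil, pose, fov_shape):
    """FOV crop + dA/dt + surrogate prediction for one coil pose."""
    fov = tuple(int(v) for v in fov_shape)
    p = scalp_projection(head, pose)
    cidx = np.round(sigma.tensors.world_to_index(p)[0]).astype(int)
    tens_c, _ = _crop_zerofill(sigma.tensors.values, cidx, fov)
    # FOV grid affine: translate the head-grid affine to the crop origin
    affine = sigma.tensors.affine.copy()
    lo = [int(cidx[a]) - fov[a] // 2 for a in range(3)]
    affine[:3, 3] += affine[:3, :3] @ np.asarray(lo, dtype=float)
    fov_grid = VolumeGrid(np.zeros(fov + (3,)), affine)
    dadt = dadt_field(coil, pose, fov_grid)
    return predict_efield(model, VolumeGrid(tens_c, affine), dadt)


def client_request(transport, pose: CoilPose, device_name: str = "viewer") -> VolumeGrid:
    """Send one coil pose, wait for the magnitude image (client side)."""
    transport.send(encode_message("TRANSFORM", pose, device_name=device_name))
    reply = read_message(transport)
    if reply.type_name != "IMAGE":
        raise ProtocolError(f"expected IMAGE reply, got {reply.type_name}")
    return message_payload(reply)
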