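"""Wire codec: layout, CRC, framing; and the pose->image server loop."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmsfield import streaming
from tmsfield.coilmodel import CoilPose, pose_at_site
from tmsfield.geometry import RigidTransform, VolumeGrid
from tmsfield.streaming import (
    HEADER_SIZE, IntegrityError, ProtocolError, client_request, crc64,
    decode_message, decode_stream, encode_message, loopback_pair,
    message_payload, read_message, run_server_loop,
)

from conftest import random_rigid


def test_crc64_known_check_value():
    # the standard CRC-64/ECMA-182 check value for "123456789"
    assert crc64(b"123456789") == 0x6C40DF5F0B497347
    assert crc64(b"") == 0


def test_header_and_transform_body_sizes():
    msg = encode_message("TRANSFORM", RigidTransform.identity())
    assert len(msg) == HEADER_SIZE + 48
    decoded, used = decode_message(msg)
    assert used == len(msg)
    assert decoded.body_size == 48
    img = VolumeGrid(np.zeros((3, 4, 5), np.float32), np.eye(4))
    raw = encode_message("IMAGE", img)
    _, used = decode_message(raw)
    assert used == len(raw)


def test_unsupported_kind_and_oversized_names():
    with pytest.raises(ProtocolError):
        encode_message("STATUS", RigidTransform.identity())
    with pytest.raises(ProtocolError):
        encode_message("TRANSFORM", RigidTransform.identity(),
                       device_name="x" * 21)
    with pytest.raises(ProtocolError):
        encode_message("TRANSFORM", np.diag([2.0, 1.0, 1.0, 1.0]))  # non-rigid


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_transform_roundtrip_property(seed):
    T = random_rigid(np.random.default_rng(seed), max_translation=200.0)
    msg, _ = decode_message(encode_message("TRANSFORM", T, device_name="probe"))
    back = message_payload(msg)
    np.testing.assert_allclose(back.matrix, T.matrix, atol=1e-5)  # float32 wire
    assert msg.device_name == "probe"
    assert msg.type_name == "TRANSFORM"


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1),
       nx=st.integers(1, 6), ny=st.integers(1, 6), nz=st.integers(1, 6))
def test_image_roundtrip_property(seed, nx, ny, nz):
    rng = np.random.default_rng(seed)
    img = VolumeGrid(rng.standard_normal((nx, ny, nz)).astype(np.float32),
                     np.diag([1.5, 2.0, 2.5, 1.0]))
    msg, _ = decode_message(encode_message("IMAGE", img))
    back = message_payload(msg)
    np.testing.assert_array_equal(back.values, img.values)
    np.testing.assert_allclose(back.voxel_size, img.voxel_size, rtol=1e-6)


def test_corrupted_body_detected():
    raw = bytearray(encode_message("TRANSFORM", RigidTransform.identity()))
    raw[HEADER_SIZE + 5] ^= 0x01
    with pytest.raises(IntegrityError):
        decode_message(bytes(raw))


def test_truncation_and_unknown_type_errors():
    raw = encode_message("TRANSFORM", RigidTransform.identity())
    with pytest.raises(ProtocolError):
        decode_message(raw[:HEADER_SIZE - 1])
    with pytest.raises(ProtocolError):
        decode_message(raw[:HEADER_SIZE + 10])
    bad = bytearray(raw)
    bad[2:14] = b"BOGUS\x00\x00\x00\x00\x00\x00\x00"
    with pytest.raises(ProtocolError):
        decode_message(bytes(bad))


def test_concatenated_stream_frames_into_two_messages():
    a = encode_message("TRANSFORM", RigidTransform.identity())
    img = VolumeGrid(np.ones((2, 2, 2), np.float32), np.eye(4))
    b = encode_message("IMAGE", img)
    msgs = decode_stream(a + b)
    assert [m.type_name for m in msgs] == ["TRANSFORM", "IMAGE"]


# --- server loop -------------------------------------------------------------- #


@pytest.fixture()
def server_setup(tiny_model, small_head, figure8):
    cv, geom = small_head
    return tiny_model, geom, cv, figure8


def _poses(geom, n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        out.append(pose_at_site(geom, u, float(rng.uniform(0, 360))))
    return out


def test_server_replies_once_per_run_with_exact_prediction(server_setup):
    model, geom, cv, coil = server_setup
    poses = _poses(geom, 4)
    server_t, client_t = loopback_pair()
    for pose in poses:
        client_t.send(encode_message("TRANSFORM", pose))
    stats = run_server_loop(model, geom, cv, coil, server_t, n_runs=4,
                            fov_shape=(16, 16, 16))
    assert stats.n_runs == 4
    assert all(set(r) == {"cnn_seconds", "vis_seconds"} for r in stats.runs)
    assert all(r["cnn_seconds"] >= 0 and r["vis_seconds"] >= 0 for r in stats.runs)
    for pose in poses:
        reply = read_message(client_t)
        assert reply.type_name == "IMAGE"
        img = message_payload(reply)
        # compare against the pose exactly as the server decoded it (the wire
        # carries float32), so the check is bit-for-bit
        wire_pose = CoilPose(message_payload(
            decode_message(encode_message("TRANSFORM", pose))[0]))
        _, mag = streaming.predict_for_pose(model, geom, cv, coil, wire_pose,
                                            (16, 16, 16))
        np.testing.assert_array_equal(img.values, mag.values)  # bit-for-bit
    assert client_t.pending() == 0  # exactly n_runs replies


def test_server_is_pose_deterministic(server_setup):
    model, geom, cv, coil = server_setup
    poses = _poses(geom, 3, seed=7)
    images = []
    for _ in range(2):
        server_t, client_t = loopback_pair()
        for pose in poses:
            client_t.send(encode_message("TRANSFORM", pose))
        run_server_loop(model, geom, cv, coil, server_t, 3, fov_shape=(16, 16, 16))
        images.append([message_payload(read_message(client_t)).values
                       for _ in range(3)])
    for a, b in zip(*images):
        np.testing.assert_array_equal(a, b)


def test_server_skips_malformed_then_continues(server_setup, caplog):
    model, geom, cv, coil = server_setup
    pose = _poses(geom, 1)[0]
    server_t, client_t = loopback_pair()
    corrupted = bytearray(encode_message("TRANSFORM", pose))
    corrupted[HEADER_SIZE + 3] ^= 0xFF
    client_t.send(bytes(corrupted))
    client_t.send(encode_message("TRANSFORM", pose))
    with caplog.at_level("WARNING"):
        stats = run_server_loop(model, geom, cv, coil, server_t, 1,
                                fov_shape=(16, 16, 16))
    assert stats.n_runs == 1
    assert any("malformed" in r.message for r in caplog.records)


def test_server_aborts_with_partial_stats_on_transport_loss(server_setup):
    model, geom, cv, coil = server_setup
    pose = _poses(geom, 1)[0]
    server_t, client_t = loopback_pair()
    client_t.send(encode_message("TRANSFORM", pose))
    with pytest.raises(ConnectionError) as exc:
        run_server_loop(model, geom, cv, coil, server_t, n_runs=3,
                        fov_shape=(16, 16, 16))
    assert exc.value.partial_stats.n_runs == 1


def test_tcp_transport_end_to_end(server_setup):
    import socket
    import threading

    model, geom, cv, coil = server_setup
    pose = _poses(geom, 1, seed=3)[0]
    srv = socket.create_server(("127.0.0.1", 0))
    port = srv.getsockname()[1]
    result = {}

    def serve():
        conn, _ = srv.accept()
        t = streaming.TcpTransport(conn)
        result["stats"] = run_server_loop(model, geom, cv, coil, t, 1,
                                          fov_shape=(16, 16, 16))
        t.close()

    thread = threading.Thread(target=serve)
    thread.start()
    client = streaming.TcpTransport.connect("127.0.0.1", port)
    img = client_request(client, pose)
    thread.join(timeout=30)
    client.close()
    srv.close()
    assert result["stats"].n_runs == 1
    wire_pose = CoilPose(message_payload(
        decode_message(encode_message("TRANSFORM", pose))[0]))
    _, mag = streaming.predict_for_pose(model, geom, cv, coil, wire_pose,
                                        (16, 16, 16))
    np.testing.assert_array_equal(img.values, mag.values)
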