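"""Geometry: interpolation against brute-force oracles, rigid vector transforms, I/O."""

from __future__ import annotations

import numpy as np
import pytest

from tmsfield import geometry as geo
from tmsfield.geometry import (
    RigidTransform, Streamlines, TransformError, TriangleMesh, VolumeGrid,
    resample_to_grid, sample_at_points, transform_vector_volume,
)

from conftest import random_rigid


def brute_force_sample(vol: VolumeGrid, points: np.ndarray, interp: str) -> np.ndarray:
    """Direct per-point interpolation oracle (8-neighbour weighted sum)."""
    vals = vol.values if vol.values.ndim == 4 else vol.values[..., None]
    nx, ny, nz, nc = vals.shape
    out = np.zeros((len(points), nc))
    idx = vol.world_to_index(points)
    for n, (x, y, z) in enumerate(idx):
        if interp == "nearest":
            i, j, k = int(round(x)), int(round(y)), int(round(z))
            if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                out[n] = vals[i, j, k]
            continue
        i0, j0, k0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        fx, fy, fz = x - i0, y - j0, z - k0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = ((fx if di else 1 - fx)
                         * (fy if dj else 1 - fy)
                         * (fz if dk else 1 - fz))
                    i, j, k = i0 + di, j0 + dj, k0 + dk
                    if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                        out[n] += w * vals[i, j, k]
    return out if vol.values.ndim == 4 else out[:, 0]


@pytest.fixture()
def random_vol():
    rng = np.random.default_rng(42)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-7.0, -7.0, -7.0]
    return VolumeGrid(rng.standard_normal((8, 8, 8, 3)), affine)


@pytest.mark.parametrize("interp", ["nearest", "trilinear"])
@pytest.mark.parametrize("ncomp", [1, 3, 6])
def test_sample_at_points_matches_bruteforce(interp, ncomp):
    rng = np.random.default_rng(7 + ncomp)
    shape = (8, 8, 8) if ncomp == 1 else (8, 8, 8, ncomp)
    vol = VolumeGrid(rng.standard_normal(shape), np.diag([1.5, 1.5, 1.5, 1.0]))
    pts = rng.uniform(-3.0, 13.0, (100, 3))  # includes out-of-bounds points
    got = sample_at_points(vol, pts, interp=interp)
    want = brute_force_sample(vol, pts, interp)
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_sample_at_voxel_center_returns_stored_value(random_vol):
    p = random_vol.index_to_world([3, 4, 5])
    got = sample_at_points(random_vol, p, interp="trilinear")
    np.testing.assert_allclose(got[0], random_vol.values[3, 4, 5], atol=1e-12)


def test_sample_constant_volume_is_constant(random_vol):
    vol = VolumeGrid(np.full((6, 6, 6), 3.25), np.eye(4))
    pts = np.random.default_rng(0).uniform(0.2, 4.8, (50, 3))
    np.testing.assert_allclose(sample_at_points(vol, pts), 3.25)


def test_resample_identity_grid_is_exact(random_vol):
    out = resample_to_grid(random_vol, random_vol.shape, random_vol.affine,
                           interp="nearest")
    np.testing.assert_array_equal(out.values, random_vol.values)


def test_resample_constant_volume_constant_inbounds():
    vol = VolumeGrid(np.full((10, 10, 10), 2.5), np.eye(4))
    target_affine = np.diag([0.5, 0.5, 0.5, 1.0])
    target_affine[:3, 3] = [1.0, 1.0, 1.0]
    out = resample_to_grid(vol, (8, 8, 8), target_affine, interp="trilinear")
    np.testing.assert_allclose(out.values, 2.5)


def test_resample_to_finer_grid_matches_bruteforce(random_vol):
    fine_affine = random_vol.affine.copy()
    fine_affine[:3, :3] /= 2.0
    out = resample_to_grid(random_vol, (16, 16, 16), fine_affine, "trilinear")
    tgt = VolumeGrid(np.zeros((16, 16, 16)), fine_affine)
    want = brute_force_sample(random_vol, tgt.voxel_centers().reshape(-1, 3),
                              "trilinear").reshape(16, 16, 16, 3)
    np.testing.assert_allclose(out.values, want, atol=1e-12)


def test_resample_and_sample_agree_on_voxel_centers(random_vol):
    tgt_affine = np.diag([1.7, 1.7, 1.7, 1.0])
    tgt_affine[:3, 3] = [-5.0, -4.0, -6.0]
    out = resample_to_grid(random_vol, (9, 9, 9), tgt_affine, "trilinear")
    pts = out.voxel_centers().reshape(-1, 3)
    direct = sample_at_points(random_vol, pts, "trilinear")
    np.testing.assert_allclose(out.values.reshape(-1, 3), direct, atol=1e-12)


def test_singular_target_affine_rejected(random_vol):
    bad = np.zeros((4, 4))
    bad[3, 3] = 1.0
    with pytest.raises(ValueError):
        resample_to_grid(random_vol, (4, 4, 4), bad)


# --- rigid vector transforms ------------------------------------------------ #


def test_identity_transform_is_bitwise_identity(random_vol):
    out = transform_vector_volume(random_vol, RigidTransform.identity(), "nearest")
    np.testing.assert_array_equal(out.values, random_vol.values)


def test_rotation_rotates_stored_vectors():
    affine = np.eye(4)
    affine[:3, 3] = [-5.0, -5.0, -5.0]
    vals = np.zeros((11, 11, 11, 3))
    vals[..., 0] = 1.0  # uniform +x field
    fld = VolumeGrid(vals, affine)
    T = RigidTransform.about_axis([0, 0, 1], 90.0)
    out = transform_vector_volume(fld, T, interp="nearest")
    interior = out.values[2:-2, 2:-2, 2:-2]
    np.testing.assert_allclose(interior[..., 1], 1.0, atol=1e-9)   # now +y
    np.testing.assert_allclose(interior[..., 0], 0.0, atol=1e-9)
    np.testing.assert_allclose(interior[..., 2], 0.0, atol=1e-9)


def test_composed_transform_matches_pointwise_oracle(random_vol):
    """T2∘T1 applied once agrees with a direct per-voxel resampling oracle."""
    rng = np.random.default_rng(3)
    T1 = random_rigid(rng, max_translation=2.0)
    T2 = random_rigid(rng, max_translation=2.0)
    T = T2.compose(T1)
    got = transform_vector_volume(random_vol, T, "trilinear")
    # oracle: evaluate input at T^-1 x via brute-force interp, rotate by R
    pts = random_vol.voxel_centers().reshape(-1, 3)
    src = T.inverse().apply_points(pts)
    vals = brute_force_sample(random_vol, src, "trilinear")
    want = (vals @ T.rotation.T).reshape(random_vol.values.shape)
    np.testing.assert_allclose(got.values, want, atol=1e-10)


def test_two_step_transform_close_to_composed(random_vol):
    rng = np.random.default_rng(4)
    T1 = random_rigid(rng, max_translation=1.5)
    T2 = random_rigid(rng, max_translation=1.5)
    once = transform_vector_volume(random_vol, T2.compose(T1), "trilinear")
    twice = transform_vector_volume(
        transform_vector_volume(random_vol, T1, "trilinear"), T2, "trilinear")
    # interpolation is applied twice on the second path: compare loosely on
    # voxels that stayed in-bounds both ways
    sel = (np.linalg.norm(once.values, axis=-1) > 0) \
        & (np.linalg.norm(twice.values, axis=-1) > 0)
    diff = np.linalg.norm((once.values - twice.values)[sel], axis=-1)
    scale = np.abs(random_vol.values).max()
    assert np.median(diff) < 0.25 * scale


def test_rotation_preserves_vector_magnitude_nearest():
    rng = np.random.default_rng(5)
    affine = np.eye(4)
    affine[:3, 3] = [-7.0, -7.0, -7.0]
    fld = VolumeGrid(rng.standard_normal((15, 15, 15, 3)), affine)
    T = RigidTransform.about_axis([0, 0, 1], 90.0)  # lattice-aligned rotation
    out = transform_vector_volume(fld, T, "nearest")
    got = np.sort(np.linalg.norm(out.values, axis=-1).ravel())
    want = np.sort(np.linalg.norm(fld.values, axis=-1).ravel())
    np.testing.assert_allclose(got, want, atol=1e-12)


def test_roundtrip_transform_restores_interior():
    """T then T^-1 with nearest interp restores interior voxels.

    Exact for a lattice-preserving motion; within rounding jitter (checked on
    a smooth field) for a generic rotation.
    """
    rng = np.random.default_rng(6)
    affine = np.eye(4)
    affine[:3, 3] = [-7.0, -7.0, -7.0]
    vals = np.zeros((15, 15, 15, 3))
    vals[5:10, 5:10, 5:10] = rng.standard_normal((5, 5, 5, 3))  # supported centrally
    fld = VolumeGrid(vals, affine)
    T = RigidTransform.about_axis([0, 0, 1], 90.0, translation=[2.0, -1.0, 3.0])
    back = transform_vector_volume(
        transform_vector_volume(fld, T, "nearest"), T.inverse(), "nearest")
    core = (slice(5, 10),) * 3
    np.testing.assert_allclose(back.values[core], fld.values[core], atol=1e-9)

    # generic rotation: nearest-voxel jitter stays below the field's Lipschitz bound
    smooth = VolumeGrid(fld.voxel_centers() * 0.1, affine)  # linear in position
    Tg = RigidTransform.about_axis([0.3, 0.5, 0.81], 37.0, translation=[1.0, -2.0, 0.5])
    back2 = transform_vector_volume(
        transform_vector_volume(smooth, Tg, "nearest"), Tg.inverse(), "nearest")
    core2 = (slice(4, 11),) * 3
    err = np.linalg.norm((back2.values - smooth.values)[core2], axis=-1)
    assert err.max() <= 0.1 * 2 * np.sqrt(3) / 2 + 1e-9  # two half-voxel roundings


def test_nonrigid_transform_rejected(random_vol):
    m = np.eye(4)
    m[0, 0] = 2.0  # scaling, not rigid
    with pytest.raises(TransformError):
        transform_vector_volume(random_vol, m)
    with pytest.raises(TransformError):
        RigidTransform(np.diag([1.0, 1.0, -1.0, 1.0]))  # reflection


def test_scalar_volume_rejected_by_vector_transform():
    vol = VolumeGrid(np.zeros((4, 4, 4)), np.eye(4))
    with pytest.raises(ValueError):
        transform_vector_volume(vol, RigidTransform.identity())


# --- containers and file I/O ------------------------------------------------ #


def test_mesh_validation_and_face_areas():
    verts = [[0, 0, 0], [1, 0, 0], [0, 1, 0]]
    mesh = TriangleMesh(verts, [[0, 1, 2]])
    np.testing.assert_allclose(mesh.face_areas(), [0.5])
    with pytest.raises(ValueError):
        TriangleMesh(verts, [[0, 1, 3]])
    with pytest.raises(ValueError):
        TriangleMesh(verts, [[0, 1, 2]], vertex_scalar=[1.0])


def test_streamlines_validation():
    with pytest.raises(ValueError):
        Streamlines([[[0, 0, 0]]])                       # single point
    with pytest.raises(ValueError):
        Streamlines([[[0, 0, 0], [np.nan, 0, 0]]])       # non-finite


def test_volume_nifti_roundtrip(tmp_path, random_vol):
    path = tmp_path / "field.nii.gz"
    geo.save_volume_nifti(random_vol, path)
    back = geo.load_volume_nifti(path)
    np.testing.assert_allclose(back.values, random_vol.values, rtol=1e-6)
    np.testing.assert_allclose(back.affine, random_vol.affine, atol=1e-6)


@pytest.mark.parametrize("ext", ["stl", "ply"])
def test_mesh_file_roundtrip(tmp_path, ext):
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
    mesh = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    path = tmp_path / f"m.{ext}"
    geo.save_mesh(mesh, path)
    back = geo.load_mesh(path)
    assert len(back.faces) == len(mesh.faces)
    # STL de-indexes vertices; compare via sorted face centroids
    c1 = np.sort(back.vertices[back.faces].mean(axis=1), axis=0)
    c2 = np.sort(mesh.vertices[mesh.faces].mean(axis=1), axis=0)
    np.testing.assert_allclose(c1, c2, atol=1e-4)


@pytest.mark.parametrize("ext", ["trk", "json"])
def test_streamlines_roundtrip(tmp_path, ext):
    rng = np.random.default_rng(0)
    sl = Streamlines([rng.uniform(-20, 20, (n, 3)) for n in (5, 9, 2)])
    path = tmp_path / f"s.{ext}"
    geo.save_streamlines(sl, path)
    back = geo.load_streamlines(path)
    assert len(back) == 3
    for a, b in zip(back, sl):
        np.testing.assert_allclose(a, b, atol=1e-4)


def test_transform_text_roundtrip(tmp_path):
    T = random_rigid(np.random.default_rng(9))
    path = tmp_path / "pose.txt"
    geo.save_transform(T, path)
    back = geo.load_transform(path)
    np.testing.assert_allclose(back.matrix, T.matrix, atol=1e-12)
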