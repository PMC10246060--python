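"""Quasi-static solver: physics identities, invariances, and case assembly."""

from __future__ import annotations

import numpy as np
import pytest

from tmsfield import coilmodel, fieldsolver, headmodel
from tmsfield.coilmodel import CoilPose, dadt_field, make_single_loop, pose_at_site
from tmsfield.fieldsolver import (
    ScalarPotential, SolverError, ground_truth_case, solve_potential_fdm,
    total_efield,
)
from tmsfield.geometry import RigidTransform, VolumeGrid


@pytest.fixture(scope="module")
def head32():
    """Homogeneous 32^3 sphere — fast solves for invariance tests."""
    return headmodel.make_sphere_head(outer_radius_mm=42.0, shells=[(42.0, 0.33)],
                                      grid_shape=(32, 32, 32), voxel_mm=3.0)


@pytest.fixture(scope="module")
def solved(head32):
    cv, geom = head32
    coil = coilmodel.make_figure8_coil()
    pose = pose_at_site(geom, np.array([0.25, 0.4, 0.88]), 25.0)
    dadt = dadt_field(coil, pose, cv.tensors)
    pot = solve_potential_fdm(cv, dadt, tol=1e-9)
    return cv, geom, coil, pose, dadt, pot


def test_residual_contract_and_gauge(solved):
    cv, _, _, _, dadt, pot = solved
    assert pot.residual <= 1e-9
    inside = cv.mask.values > 0
    assert abs(pot.phi.values[inside].mean()) < 1e-12 * np.abs(pot.phi.values).max()
    assert np.all(pot.phi.values[~inside] == 0.0)


def test_zero_potential_gives_minus_dadt(head32):
    cv, _ = head32
    zero = ScalarPotential(
        phi=VolumeGrid(np.zeros(cv.shape), cv.affine.copy()),
        mask=cv.mask, residual=0.0, n_iter=0)
    rng = np.random.default_rng(0)
    dadt = VolumeGrid(rng.standard_normal(cv.shape + (3,)), cv.affine.copy())
    e = total_efield(dadt, zero)
    inside = cv.mask.values > 0
    np.testing.assert_array_equal(e.values[inside], -dadt.values[inside])
    np.testing.assert_array_equal(e.values[~inside], 0.0)


def test_efield_algebraic_identity(solved):
    """E + dA/dt + grad(phi) = 0 at interior voxels, with an independent stencil."""
    cv, _, _, _, dadt, pot = solved
    e = total_efield(dadt, pot)
    h_m = 3.0e-3
    phi = pot.phi.values
    g = np.stack(np.gradient(phi, h_m), axis=-1)  # central differences
    mask = cv.mask.values > 0
    # voxels whose full 6-neighbourhood is masked: both stencils are central
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(mask, iterations=1)
    resid = (e.values + dadt.values + g)[interior]
    assert np.abs(resid).max() < 1e-10 * np.abs(e.values).max()


def test_conductivity_scale_invariance(solved):
    cv, _, _, _, dadt, pot = solved
    scaled = headmodel.ConductivityVolume(
        tensors=VolumeGrid(cv.tensors.values * 7.5, cv.affine.copy()),
        mask=cv.mask, surface_sdf=cv.surface_sdf, interface_sdfs=cv.interface_sdfs)
    pot2 = solve_potential_fdm(scaled, dadt, tol=1e-9)
    scale = np.abs(pot.phi.values).max()
    assert np.abs(pot2.phi.values - pot.phi.values).max() < 1e-5 * scale


def test_linearity_in_didt(head32):
    cv, geom = head32
    pose = pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 10.0)
    c1 = coilmodel.make_figure8_coil(dIdt=1.0e6)
    c3 = coilmodel.make_figure8_coil(dIdt=3.0e6)
    e1 = total_efield(dadt_field(c1, pose, cv.tensors),
                      solve_potential_fdm(cv, dadt_field(c1, pose, cv.tensors), tol=1e-9))
    e3 = total_efield(dadt_field(c3, pose, cv.tensors),
                      solve_potential_fdm(cv, dadt_field(c3, pose, cv.tensors), tol=1e-9))
    scale = np.abs(e3.values).max()
    assert np.abs(e3.values - 3.0 * e1.values).max() < 1e-5 * scale


def test_insulated_bar_uniform_source_has_zero_field():
    """1-D limit: a uniform dA/dt along an insulated bar induces no total field."""
    shape = (20, 6, 6)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    tensors = np.zeros(shape + (6,))
    tensors[..., :3] = 0.5
    mask = np.ones(shape)
    cv = headmodel.ConductivityVolume(
        tensors=VolumeGrid(tensors, affine), mask=VolumeGrid(mask, affine.copy()))
    dadt = VolumeGrid(np.zeros(shape + (3,)), affine.copy())
    dadt.values[..., 0] = 0.2  # uniform, along the bar
    pot = solve_potential_fdm(cv, dadt, tol=1e-12)
    e = total_efield(dadt, pot)
    interior = e.values[1:-1]
    assert np.abs(interior).max() < 1e-8 * 0.2


def test_anisotropic_tensor_solve_converges():
    cv, geom = headmodel.make_sphere_head(outer_radius_mm=42.0,
                                          grid_shape=(32, 32, 32), voxel_mm=3.0)
    cv = headmodel.randomize_conductivity_tensors(
        cv, (10.0, geom.white_matter_radius), anisotropy_ratio=5.0, seed=1)
    coil = coilmodel.make_figure8_coil()
    pose = pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 0.0)
    dadt = dadt_field(coil, pose, cv.tensors)
    pot = solve_potential_fdm(cv, dadt, tol=1e-8)
    assert pot.residual <= 1e-8
    e = total_efield(dadt, pot)
    assert np.all(np.isfinite(e.values))


def test_nonconvergence_raises_with_residual(head32):
    cv, geom = head32
    coil = coilmodel.make_figure8_coil()
    pose = pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 0.0)
    dadt = dadt_field(coil, pose, cv.tensors)
    with pytest.raises(SolverError) as exc:
        solve_potential_fdm(cv, dadt, tol=1e-12, max_iter=3)
    assert exc.value.residual is not None and exc.value.residual > 1e-12


def test_misaligned_grids_rejected(head32):
    cv, _ = head32
    bad_affine = cv.affine.copy()
    bad_affine[0, 3] += 1.0
    dadt = VolumeGrid(np.zeros(cv.shape + (3,)), bad_affine)
    with pytest.raises(SolverError):
        solve_potential_fdm(cv, dadt)
    pot = ScalarPotential(
        phi=VolumeGrid(np.zeros(cv.shape), cv.affine.copy()),
        mask=cv.mask, residual=0.0, n_iter=0)
    with pytest.raises(SolverError):
        total_efield(dadt, pot)


# --- training-case assembly -------------------------------------------------- #


def test_ground_truth_case_channel_layout(small_head, figure8):
    cv, geom = small_head
    pose = pose_at_site(geom, np.array([0.1, 0.2, 0.97]), 40.0)
    s = ground_truth_case(geom, cv, figure8, pose, fov_shape=(16, 16, 16), tol=1e-7)
    assert s.input.shape == (16, 16, 16, 9)
    assert s.target.shape == (16, 16, 16, 3)
    assert s.mask.shape == (16, 16, 16)
    # channel order: 6 tensor components then 3 dA/dt components
    np.testing.assert_array_equal(
        s.input[..., :3][s.mask == 0], 0.0)  # tensors vanish outside the head
    assert np.any(s.input[..., 6:] != 0.0)   # dA/dt does not
    np.testing.assert_array_equal(s.target[s.mask == 0], 0.0)


def test_ground_truth_fov_center_at_scalp_projection(small_head, figure8):
    cv, geom = small_head
    pose = pose_at_site(geom, np.array([0.3, -0.2, 0.93]), 10.0)
    s = ground_truth_case(geom, cv, figure8, pose, fov_shape=(12, 12, 12), tol=1e-7)
    proj = fieldsolver.scalp_projection(geom, pose)
    cidx = np.round(cv.tensors.world_to_index(proj)[0]).astype(int)
    # the crop center voxel corresponds to grid voxel cidx
    lo = cidx - 6
    center_world = cv.tensors.index_to_world([cidx])[0]
    assert np.linalg.norm(proj - center_world) <= np.sqrt(3) * 4.0  # within a voxel
    # independent crop oracle: zero-pad the grid, then slice (no wrapping)
    padded = np.pad(cv.mask.values, 12)
    want = padded[lo[0] + 12:lo[0] + 24, lo[1] + 12:lo[1] + 24, lo[2] + 12:lo[2] + 24]
    np.testing.assert_array_equal(s.mask, want)


def test_paper_scale_fov_shape_supported(small_head, figure8, caplog):
    """A 70x90x50 reduced FOV crops (with zero-fill) even from a small grid."""
    cv, geom = small_head
    pose = pose_at_site(geom, np.array([0.0, 0.0, 1.0]), 0.0)
    with caplog.at_level("WARNING"):
        s = ground_truth_case(geom, cv, figure8, pose, fov_shape=(70, 90, 50),
                              tol=1e-7)
    assert s.input.shape == (70, 90, 50, 9)
    assert s.target.shape == (70, 90, 50, 3)
    assert any("zero-fill" in r.message for r in caplog.records)


def test_dataset_hdf5_roundtrip(tmp_path, tiny_dataset):
    path = tmp_path / "ds.h5"
    fieldsolver.save_dataset(tiny_dataset, path)
    back = fieldsolver.load_dataset(path)
    assert len(back) == len(tiny_dataset)
    for a, b in zip(back, tiny_dataset):
        np.testing.assert_array_equal(a.input, b.input)
        np.testing.assert_array_equal(a.target, b.target)
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.pose_matrix, b.pose_matrix)
        assert a.case_id == b.case_id
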