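"""Quasi-static E-field ground truth on voxelized volume conductors.

Under the quasi-static approximation the induced electric field splits into
``E = -dA/dt - grad(phi)`` where the scalar potential phi satisfies the
current-conservation equation ``div(sigma (grad(phi) + dA/dt)) = 0`` with zero
normal total current on the head boundary. This module discretizes that
equation with a conservative cell-centered finite-volume scheme on the head
mask and solves it iteratively, then assembles (conductivity, dA/dt) → E
training cases over a reduced field of view around the coil.

Discretization: two-point fluxes with harmonic-mean face conductivities for
the diagonal tensor entries; tensor cross terms enter through face-averaged
central differences (dropped where a neighbour leaves the mask, a consistent
order reduction at the boundary). The pure-Neumann problem is singular up to
an additive constant; the zero-mean gauge over the mask fixes it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coilmodel import CoilModel, CoilPose, dadt_field
from .geometry import VolumeGrid
from .headmodel import ConductivityVolume, HeadGeometry

__all__ = [
    "SolverError",
    "ScalarPotential",
    "TrainingSample",
    "solve_potential_fdm",
    "total_efield",
    "ground_truth_case",
    "make_dataset",
    "save_dataset",
    "load_dataset",
]

logger = logging.getLogger(__name__)

_AXPAIRS = ((0, 1), (0, 2), (1, 2))
_OFFDIAG_COMPONENT = {(0, 1): 3, (0, 2): 4, (1, 2): 5}  # xy, xz, yz


class SolverError(RuntimeError):
    """Raised on solver misuse (misaligned grids) or non-convergence."""

    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


@dataclass
class ScalarPotential:
    """Scalar potential phi (V) on a voxel grid, zero-mean over the head mask."""

    phi: VolumeGrid
    mask: VolumeGrid
    residual: float
    n_iter: int


def _check_aligned(a: VolumeGrid, b: VolumeGrid) -> None:
    if a.shape != b.shape or not np.allclose(a.affine, b.affine, atol=1e-9):
        raise SolverError("grids are misaligned (shape/affine mismatch)")


def _sigma_times_dadt(tensors: np.ndarray, dadt: np.ndarray) -> np.ndarray:
    """Per-voxel sigma @ dA/dt with packed-6 tensors (xx,yy,zz,xy,xz,yz)."""
    sxx, syy, szz = tensors[..., 0], tensors[..., 1], tensors[..., 2]
    sxy, sxz, syz = tensors[..., 3], tensors[..., 4], tensors[..., 5]
    ax, ay, az = dadt[..., 0], dadt[..., 1], dadt[..., 2]
    return np.stack(
        [
            sxx * ax + sxy * ay + sxz * az,
            sxy * ax + syy * ay + syz * az,
            sxz * ax + syz * ay + szz * az,
        ],
        axis=-1,
    )


def _assemble(sigma: ConductivityVolume, dadt: VolumeGrid):
    """Build the finite-volume operator K (so K phi = b) on masked voxels."""
    mask = sigma.mask.values > 0
    shape = mask.shape
    n = int(mask.sum())
    ids = -np.ones(shape, dtype=np.int64)
    ids[mask] = np.arange(n)

    h = float(np.mean(sigma.tensors.voxel_size)) * 1e-3  # voxel edge, meters
    area_over_h = h  # cube face: h^2 / h
    area = h * h

    tens = sigma.tensors.values
    sA = _sigma_times_dadt(tens, dadt.values)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    b = np.zeros(n)

    def slicer(axis: int, lo: int, hi: int | None):
        s = [slice(None)] * 3
        s[axis] = slice(lo, hi)
        return tuple(s)

    has_offdiag = bool(np.any(tens[..., 3:] != 0.0))
    h_mm = float(np.mean(sigma.tensors.voxel_size))
    sdf = sigma.surface_sdf.values if sigma.surface_sdf is not None else None

    for a in range(3):
        sl_i = slicer(a, 0, -1)
        sl_j = slicer(a, 1, None)
        pair = mask[sl_i] & mask[sl_j]
        I = ids[sl_i][pair]
        J = ids[sl_j][pair]
        saa_i = tens[sl_i + (a,)][pair]
        saa_j = tens[sl_j + (a,)][pair]
        # distance-weighted harmonic mean: theta = fraction of the cell-to-cell
        # link on the i side of the conductivity jump, located sub-voxel from
        # the interface signed distances when the generator provides them
        theta = np.full(saa_i.shape, 0.5)
        if sigma.interface_sdfs is not None:
            isdf = sigma.interface_sdfs.values
            if isdf.ndim == 3:
                isdf = isdf[..., None]
            for k in range(isdf.shape[3]):
                di = isdf[sl_i + (k,)][pair]
                dj = isdf[sl_j + (k,)][pair]
                crossed = di * dj < 0
                if np.any(crossed):
                    th = np.abs(di[crossed]) / np.maximum(
                        np.abs(di[crossed]) + np.abs(dj[crossed]), 1e-12
                    )
                    theta[crossed] = np.clip(th, 0.05, 0.95)
        denom = theta * saa_j + (1.0 - theta) * saa_i
        sig_h = np.where(denom > 0, saa_i * saa_j / np.maximum(denom, 1e-300), 0.0)
        w = sig_h * area_over_h
        # sub-voxel boundary treatment: weight each face by the fraction of its
        # area inside the head (height-fraction estimate from the signed
        # distance at the face center); smooths the staircase surface
        if sdf is not None:
            sdf_f = 0.5 * (sdf[sl_i][pair] + sdf[sl_j][pair])
            frac = np.clip(0.5 - sdf_f / h_mm, 0.0, 1.0)
        else:
            frac = 1.0
        w = w * frac
        rows += [I, J, I, J]
        cols += [I, J, J, I]
        vals += [w, w, -w, -w]
        # primary-source flux through the face. Flux matching at a conductivity
        # jump gives harmonic-mean sigma_aa times arithmetic-mean dA/dt for the
        # diagonal part (same weighting as the phi flux); the tensor cross part
        # is smooth inside the white matter and is face-averaged.
        a_avg = 0.5 * (dadt.values[sl_i + (a,)][pair] + dadt.values[sl_j + (a,)][pair])
        cross_i = sA[sl_i + (a,)][pair] - saa_i * dadt.values[sl_i + (a,)][pair]
        cross_j = sA[sl_j + (a,)][pair] - saa_j * dadt.values[sl_j + (a,)][pair]
        f = (sig_h * a_avg + 0.5 * (cross_i + cross_j)) * area * frac
        np.add.at(b, I, +f)
        np.add.at(b, J, -f)

        if not has_offdiag:
            continue
        # cross terms: flux_a at the face includes sigma_ab * dphi/db
        for bax in range(3):
            if bax == a:
                continue
            comp = _OFFDIAG_COMPONENT[(min(a, bax), max(a, bax))]
            sab_f = 0.5 * (tens[sl_i + (comp,)][pair] + tens[sl_j + (comp,)][pair])
            c = sab_f * area / (4.0 * h)
            # neighbour indices i±e_b and j±e_b for the face cells
            idx_i = np.stack(np.nonzero(pair), axis=1)  # index within sliced array
            base_i = idx_i.copy()
            base_j = idx_i.copy()
            base_j[:, a] += 1
            # face flux out of i: c * sum over the 4 neighbours (i±e_b, j±e_b)
            # with sign ±1; K = -divergence, so row i gets -sgn*c, row j +sgn*c
            for base in (base_i, base_j):
                for sgn in (+1, -1):
                    nb = base.copy()
                    nb[:, bax] += sgn
                    ok = (nb[:, bax] >= 0) & (nb[:, bax] < shape[bax])
                    nb_ids = np.full(len(nb), -1, dtype=np.int64)
                    nb_ids[ok] = ids[nb[ok, 0], nb[ok, 1], nb[ok, 2]]
                    ok &= nb_ids >= 0
                    coeff = -sgn * c
                    rows.append(I[ok])
                    cols.append(nb_ids[ok])
                    vals.append(coeff[ok])
                    rows.append(J[ok])
                    cols.append(nb_ids[ok])
                    vals.append(-coeff[ok])

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return K, b, ids, mask, has_offdiag


def solve_potential_fdm(
    sigma: ConductivityVolume,
    dadt: VolumeGrid,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> ScalarPotential:
    """Solve div(sigma (grad(phi) + dA/dt)) = 0 on the head mask.

    Conjugate gradients with Jacobi preconditioning for isotropic/diagonal
    tensors (symmetric positive semi-definite operator); BiCGSTAB with an ILU
    preconditioner once tensor cross terms make the stencil nonsymmetric.
    Raises :class:`SolverError` carrying the final residual on non-convergence.
    """
    _check_aligned(sigma.tensors, dadt)
    if dadt.n_components != 3:
        raise SolverError("dadt must be a 3-component field")
    K, b, ids, mask, has_offdiag = _assemble(sigma, dadt)
    n = K.shape[0]
    if max_iter is None:
        max_iter = int(10 * round(n ** (1.0 / 3.0)) * 100)

    # pure-Neumann compatibility: project out the (discretely tiny) net source
    b = b - b.mean()
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        phi_flat = np.zeros(n)
        res = 0.0
        it = 0
    else:
        it = 0

        def _count(_):
            nonlocal it
            it += 1

        diag = K.diagonal()
        if np.any(diag <= 0):
            diag = np.where(diag > 0, diag, 1.0)
        if not has_offdiag:
            M = sp.diags(1.0 / diag)
            phi_flat, info = spla.cg(K, b, rtol=tol, maxiter=max_iter, M=M,
                                     callback=_count)
        else:
            ilu = spla.spilu(K.tocsc() + 1e-12 * sp.eye(n, format="csc"),
                             drop_tol=1e-5, fill_factor=10)
            M = spla.LinearOperator((n, n), ilu.solve)
            phi_flat, info = spla.bicgstab(K, b, rtol=tol, maxiter=max_iter, M=M,
                                           callback=_count)
        res = float(np.linalg.norm(K @ phi_flat - b) / bnorm)
        if info != 0 or not np.isfinite(res) or res > tol * 10:
            raise SolverError(
                f"potential solve did not converge (info={info}, rel residual={res:.3e})",
                residual=res,
            )

    phi_flat -= phi_flat.mean()  # zero-mean gauge over the mask
    phi = np.zeros(mask.shape)
    phi[mask] = phi_flat
    return ScalarPotential(
        phi=VolumeGrid(phi, sigma.tensors.affine.copy()),
        mask=sigma.mask,
        residual=res,
        n_iter=it,
    )


def _masked_gradient(phi: np.ndarray, mask: np.ndarray, h_m: float) -> np.ndarray:
    """grad(phi) (V/m): central differences in the mask, one-sided at its boundary."""
    g = np.zeros(phi.shape + (3,))
    for a in range(3):

        def sh(arr, off):
            out = np.zeros_like(arr)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if off > 0:
                src[a] = slice(off, None)
                dst[a] = slice(0, -off)
            else:
                src[a] = slice(0, off)
                dst[a] = slice(-off, None)
            out[tuple(dst)] = arr[tuple(src)]
            return out

        m_p = sh(mask.astype(bool), +1)  # neighbour at +1 exists & masked
        m_m = sh(mask.astype(bool), -1)
        p_p = sh(phi, +1)
        p_m = sh(phi, -1)
        central = m_p & m_m
        fwd = m_p & ~m_m
        bwd = m_m & ~m_p
        ga = np.zeros_like(phi)
        ga[central] = (p_p[central] - p_m[central]) / (2.0 * h_m)
        ga[fwd] = (p_p[fwd] - phi[fwd]) / h_m
        ga[bwd] = (phi[bwd] - p_m[bwd]) / h_m
        g[..., a] = ga
    g[~mask.astype(bool)] = 0.0
    return g


def total_efield(dadt: VolumeGrid, potential: ScalarPotential,
                 mask: VolumeGrid | None = None) -> VolumeGrid:
    """E = -dA/dt - grad(phi) (V/m) on the mask; zero outside."""
    if mask is None:
        mask = potential.mask
    _check_aligned(dadt, potential.phi)
    _check_aligned(dadt, mask)
    m = mask.values > 0
    h_m = float(np.mean(dadt.voxel_size)) * 1e-3
    g = _masked_gradient(potential.phi.values, m, h_m)
    e = -dadt.values - g
    e[~m] = 0.0
    return VolumeGrid(e, dadt.affine.copy())


# --------------------------------------------------------------------------- #
# training-case assembly
# --------------------------------------------------------------------------- #


@dataclass
class TrainingSample:
    """One (input, target) pair over a reduced field of view.

    ``input``: 9 channels, the 6 conductivity-tensor components
    (xx,yy,zz,xy,xz,yz) followed by the 3 dA/dt components; ``target``: the
    3-component E-field; both channel-last ``(fx, fy, fz, c)``. ``mask`` is the
    head mask restricted to the FOV; the target is zero outside it.
    """

    input: np.ndarray
    target: np.ndarray
    mask: np.ndarray
    pose_matrix: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        if self.input.shape[:3] != self.target.shape[:3]:
            raise ValueError("input and target must share a spatial shape")
        if self.input.shape[3] != 9 or self.target.shape[3] != 3:
            raise ValueError("expected 9 input channels and 3 target channels")


def _crop_zerofill(arr: np.ndarray, center_idx: np.ndarray, fov: tuple[int, int, int]):
    """Crop ``fov`` voxels centered at ``center_idx``; zero-fill beyond the grid."""
    out_shape = tuple(fov) + arr.shape[3:]
    out = np.zeros(out_shape, dtype=arr.dtype)
    lo = [int(center_idx[a]) - fov[a] // 2 for a in range(3)]
    clipped = False
    src, dst = [], []
    for a in range(3):
        s0, s1 = lo[a], lo[a] + fov[a]
        c0, c1 = max(s0, 0), min(s1, arr.shape[a])
        if c0 != s0 or c1 != s1:
            clipped = True
        if c1 <= c0:
            return out, True
        src.append(slice(c0, c1))
        dst.append(slice(c0 - s0, c1 - s0))
    out[tuple(dst)] = arr[tuple(src)]
    return out, clipped


def scalp_projection(head: HeadGeometry, pose: CoilPose) -> np.ndarray:
    """World point where the coil center projects radially onto the scalp sphere."""
    d = pose.position - head.center
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        d, nd = np.array([0.0, 0.0, 1.0]), 1.0
    return head.center + head.outer_radius * d / nd


def ground_truth_case(
    head: HeadGeometry,
    sigma: ConductivityVolume,
    coil: CoilModel,
    pose: CoilPose,
    fov_shape: tuple[int, int, int] = (24, 24, 24),
    tol: float = 1e-8,
    case_id: str = "",
) -> TrainingSample:
    """Full ground-truth pipeline for one coil placement, cropped to the FOV.

    Computes dA/dt on the conductivity grid, solves the potential, forms E,
    and crops all channels to ``fov_shape`` voxels centered at the coil's
    scalp projection (zero-filled with a warning where the FOV leaves the
    grid).
    """
    fov = tuple(int(v) for v in fov_shape)
    dadt = dadt_field(coil, pose, sigma.tensors)
    pot = solve_potential_fdm(sigma, dadt, tol=tol)
    e = total_efield(dadt, pot)

    p = scalp_projection(head, pose)
    cidx = np.round(sigma.tensors.world_to_index(p)[0]).astype(int)
    tens_c, cl1 = _crop_zerofill(sigma.tensors.values, cidx, fov)
    dadt_c, _ = _crop_zerofill(dadt.values, cidx, fov)
    e_c, _ = _crop_zerofill(e.values, cidx, fov)
    mask_c, _ = _crop_zerofill(sigma.mask.values.astype(np.uint8), cidx, fov)
    if cl1:
        logger.warning("FOV extends beyond the head grid; zero-filled")
    return TrainingSample(
        input=np.concatenate([tens_c, dadt_c], axis=3).astype(np.float32),
        target=e_c.astype(np.float32),
        mask=mask_c.astype(np.uint8),
        pose_matrix=pose.matrix.copy(),
        case_id=case_id,
    )


def make_dataset(head, sigma, coil, placements, fov_shape=(24, 24, 24),
                 tol: float = 1e-8) -> list[TrainingSample]:
    """Ground-truth cases for every pose in a placement set."""
    samples = []
    for i, pose in enumerate(placements.poses):
        samples.append(
            ground_truth_case(
                head, sigma, coil, pose, fov_shape=fov_shape, tol=tol,
                case_id=f"{placements.site_labels[i]}_d{placements.direction_indices[i]}",
            )
        )
    return samples


def save_dataset(samples: list[TrainingSample], path) -> None:
    import h5py

    with h5py.File(str(path), "w") as f:
        for i, s in enumerate(samples):
            g = f.create_group(f"case_{i:05d}")
            g.create_dataset("input", data=s.input, compression="gzip")
            g.create_dataset("target", data=s.target, compression="gzip")
            g.create_dataset("mask", data=s.mask, compression="gzip")
            g.create_dataset("pose", data=s.pose_matrix)
            g.attrs["case_id"] = s.case_id


def load_dataset(path) -> list[TrainingSample]:
    import h5py

    out = []
    with h5py.File(str(path), "r") as f:
        for k in sorted(f.keys()):
            g = f[k]
            out.append(
                TrainingSample(
                    input=g["input"][()],
                    target=g["target"][()],
                    mask=g["mask"][()],
                    pose_matrix=g["pose"][()],
                    case_id=str(g.attrs.get("case_id", "")),
                )
            )
    return out
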