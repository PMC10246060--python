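"""Volumetric data model, rigid transforms, resampling and field projection.

World coordinates are RAS millimetres throughout; voxel indices are 0-based and
the affine maps index ``(i, j, k, 1)`` to world ``(x, y, z, 1)``. Vector-valued
volumes store their components in the *world* frame, so a rigid transform acts
on the stored components directly (the rotation block is applied per voxel in
addition to resampling the lattice). Samples falling outside a volume are zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "TransformError",
    "VolumeGrid",
    "RigidTransform",
    "TriangleMesh",
    "Streamlines",
    "vector_grid",
    "transform_vector_volume",
    "resample_to_grid",
    "sample_at_points",
]


class TransformError(ValueError):
    """Raised when a matrix fails the rigidity check (orthogonality/determinant)."""


# --------------------------------------------------------------------------- #
# data model
# --------------------------------------------------------------------------- #


@dataclass
class VolumeGrid:
    """A dense voxel grid with a fixed-length record per voxel.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)`` for scalar records or
        ``(nx, ny, nz, nc)`` for ``nc``-component records (3 for vector
        fields, 6 for symmetric conductivity tensors in xx,yy,zz,xy,xz,yz
        order).
    affine
        4x4 homogeneous matrix mapping 0-based voxel index to world mm.
    """

    values: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim not in (3, 4):
            raise ValueError("values must be 3-D (scalar) or 4-D (multi-component)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape[:3])  # type: ignore[return-value]

    @property
    def n_components(self) -> int:
        return 1 if self.values.ndim == 3 else self.values.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel along the three index axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*shape, 3)``."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.index_to_world(idx).reshape(nx, ny, nz, 3)

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.affine.copy())


def vector_grid(values: np.ndarray, affine: np.ndarray) -> VolumeGrid:
    """Construct a 3-component (vector) VolumeGrid, validating the record length."""
    vg = VolumeGrid(values, affine)
    if vg.n_components != 3:
        raise ValueError(f"vector field needs 3 components per voxel, got {vg.n_components}")
    return vg


# A VectorField is simply a VolumeGrid with 3 components; no subclass needed.
VectorField = VolumeGrid


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform (rotation + translation) in homogeneous form."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise TransformError("rigid transform must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise TransformError("rotation block is not orthogonal (RtR != I within 1e-9)")
        if np.linalg.det(R) < 0:
            raise TransformError("rotation block has det -1 (reflection, not rigid)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise TransformError("bottom row must be [0 0 0 1]")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = t
        return cls(m)

    @classmethod
    def about_axis(cls, axis: Sequence[float], angle_deg: float,
                   translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a (not necessarily unit) axis, then translate."""
        a = np.asarray(axis, dtype=float)
        a = a / np.linalg.norm(a)
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return cls.from_rotation_translation(R, np.asarray(translation, dtype=float))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation_translation(R, -R @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self∘other (apply ``other`` first)."""
        return RigidTransform(self.matrix @ other.matrix)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation.T + self.translation

    def apply_vectors(self, vecs: np.ndarray) -> np.ndarray:
        vecs = np.asarray(vecs, dtype=float)
        return vecs @ self.rotation.T


@dataclass
class TriangleMesh:
    """Triangle surface mesh in world mm, with an optional per-vertex scalar."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if self.vertex_scalar is not None:
            self.vertex_scalar = np.asarray(self.vertex_scalar, dtype=float).reshape(-1)
            if len(self.vertex_scalar) != len(self.vertices):
                raise ValueError("vertex_scalar length must match vertex count")

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        """Count how many faces share each undirected edge (2 everywhere on a closed mesh)."""
        counts: dict[tuple[int, int], int] = {}
        for f in self.faces:
            for i, j in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                e = (int(min(i, j)), int(max(i, j)))
                counts[e] = counts.get(e, 0) + 1
        return counts


@dataclass
class Streamlines:
    """An ordered bundle of polylines (world mm), e.g. white-matter tracts."""

    lines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for ln in self.lines:
            arr = np.asarray(ln, dtype=float).reshape(-1, 3)
            if len(arr) < 2:
                raise ValueError("each polyline needs at least 2 points")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline coordinates must be finite")
            cleaned.append(arr)
        self.lines = cleaned

    def __len__(self) -> int:
        return len(self.lines)

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self.lines)


# --------------------------------------------------------------------------- #
# sampling machinery
# --------------------------------------------------------------------------- #

_INTERP_ORDER = {"nearest": 0, "trilinear": 1}


def _sample_records(vol: VolumeGrid, index_coords: np.ndarray, interp: str) -> np.ndarray:
    """Sample records at fractional voxel indices, zero outside the grid.

    index_coords: (n, 3) fractional indices. Returns (n, nc) (nc=1 for scalars).
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"interp must be one of {sorted(_INTERP_ORDER)}")
    order = _INTERP_ORDER[interp]
    coords = np.asarray(index_coords, dtype=float).T  # (3, n)
    vals = vol.values if vol.values.ndim == 4 else vol.values[..., None]
    out = np.empty((coords.shape[1], vals.shape[3]), dtype=float)
    for c in range(vals.shape[3]):
        # grid-constant: the volume is zero-padded, so samples just outside the
        # grid blend toward zero instead of switching off discontinuously
        out[:, c] = map_coordinates(
            vals[..., c].astype(float), coords, order=order,
            mode="grid-constant", cval=0.0,
        )
    return out


def sample_at_points(vol: VolumeGrid, points: np.ndarray, interp: str = "trilinear") -> np.ndarray:
    """Sample a volume's records at arbitrary world-mm points.

    Serves mesh vertices and streamline points identically; out-of-bounds
    points yield a zero record. Returns ``(n,)`` for scalar volumes and
    ``(n, nc)`` otherwise.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    recs = _sample_records(vol, vol.world_to_index(points), interp)
    return recs[:, 0] if vol.values.ndim == 3 else recs


def resample_to_grid(
    vol: VolumeGrid,
    target_shape: Sequence[int],
    target_affine: np.ndarray,
    interp: str = "trilinear",
) -> VolumeGrid:
    """Resample a volume onto a new grid; out-of-bounds voxels are zero-filled."""
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValueError("target affine is singular")
    tgt = VolumeGrid(np.zeros(tuple(target_shape), dtype=float), target_affine)
    pts = tgt.voxel_centers().reshape(-1, 3)
    recs = _sample_records(vol, vol.world_to_index(pts), interp)
    if vol.values.ndim == 3:
        vals = recs[:, 0].reshape(tuple(target_shape))
    else:
        vals = recs.reshape(tuple(target_shape) + (vol.values.shape[3],))
    return VolumeGrid(vals, target_affine)


def transform_vector_volume(
    fld: VolumeGrid, T: RigidTransform, interp: str = "trilinear"
) -> VolumeGrid:
    """Apply a rigid transform to a vector field, rotating the stored vectors.

    The output lives on the *same* grid as the input. Each output voxel holds
    the input field sampled at ``T^{-1} * (voxel world position)``, with the
    3-vector additionally rotated by the rotation block of ``T`` — the field is
    moved as a physical object, so per-voxel vector direction stays consistent
    with the resampled lattice. Out-of-bounds samples are zero vectors.
    """
    if fld.n_components != 3:
        raise ValueError("transform_vector_volume expects a 3-component field")
    if not isinstance(T, RigidTransform):
        T = RigidTransform(np.asarray(T))  # raises TransformError if not rigid
    pts = fld.voxel_centers().reshape(-1, 3)
    src_pts = T.inverse().apply_points(pts)
    recs = _sample_records(fld, fld.world_to_index(src_pts), interp)
    rotated = recs @ T.rotation.T
    return VolumeGrid(rotated.reshape(fld.values.shape), fld.affine.copy())


# --------------------------------------------------------------------------- #
# file I/O (NIfTI volumes, STL/PLY meshes, TRK/JSON streamlines, text matrices)
# --------------------------------------------------------------------------- #


def save_volume_nifti(vol: VolumeGrid, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine), str(path))


def load_volume_nifti(path: str | Path) -> VolumeGrid:
    import nibabel as nib

    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine))


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as STL or PLY (chosen by extension)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def load_mesh(path: str | Path) -> TriangleMesh:
    import trimesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    return TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_streamlines(sl: Streamlines, path: str | Path) -> None:
    """Write streamlines as TRK (via nibabel) or line-per-polyline JSON."""
    path = Path(path)
    if path.suffix.lower() == ".trk":
        import nibabel as nib
        from nibabel.streamlines import Tractogram, TrkFile

        tg = Tractogram(list(sl.lines), affine_to_rasmm=np.eye(4))
        TrkFile(tg).save(str(path))
    else:
        path.write_text(json.dumps([ln.tolist() for ln in sl.lines]))


def load_streamlines(path: str | Path) -> Streamlines:
    path = Path(path)
    if path.suffix.lower() == ".trk":
        import nibabel as nib

        tf = nib.streamlines.load(str(path))
        return Streamlines([np.asarray(s) for s in tf.streamlines])
    return Streamlines([np.asarray(ln) for ln in json.loads(path.read_text())])


def save_transform(T: RigidTransform, path: str | Path) -> None:
    np.savetxt(str(path), T.matrix, fmt="%.17g")


def load_transform(path: str | Path) -> RigidTransform:
    return RigidTransform(np.loadtxt(str(path)).reshape(4, 4))
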