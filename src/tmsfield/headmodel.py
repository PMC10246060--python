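"""Synthetic multi-shell spherical head models.

Generates the inputs a volume-conductor E-field pipeline needs — a per-voxel
symmetric conductivity-tensor volume with a head mask, scalp and gray-matter
surfaces for coil placement, optional white-matter anisotropy, and synthetic
streamline bundles — as an idealized stand-in for segmentation-derived head
models. Shells are concentric spheres; each voxel takes the isotropic
conductivity of the innermost shell containing its center (a center exactly on
a shell radius belongs to the outer shell).

Default shell conductivities (S/m) are standard literature values:
scalp 0.465, skull 0.010, CSF 1.654, gray matter 0.275, white matter 0.126.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import Streamlines, TriangleMesh, VolumeGrid

__all__ = [
    "DEFAULT_SHELLS",
    "ConductivityVolume",
    "HeadGeometry",
    "make_sphere_head",
    "randomize_conductivity_tensors",
    "make_synthetic_streamlines",
    "default_head",
]

#: (relative radius, conductivity S/m) outermost→innermost; absolute radii are
#: ``relative_radius * outer_radius_mm``.
DEFAULT_SHELLS: tuple[tuple[float, float], ...] = (
    (1.00, 0.465),   # scalp
    (0.92, 0.010),   # skull
    (0.86, 1.654),   # CSF
    (0.80, 0.275),   # gray matter
    (0.70, 0.126),   # white matter
)

# tensor component order used throughout: xx, yy, zz, xy, xz, yz
_DIAG = (0, 1, 2)


@dataclass
class ConductivityVolume:
    """Per-voxel symmetric 3x3 conductivity tensors (6 components) with a head mask.

    ``surface_sdf`` optionally carries the signed distance (mm, negative
    inside) to the head surface; the field solver uses it for sub-voxel
    (cut-cell) face weighting at the staircase boundary.
    """

    tensors: VolumeGrid   # (*shape, 6), S/m, order xx,yy,zz,xy,xz,yz
    mask: VolumeGrid      # (*shape,), bool-ish (1 inside head)
    surface_sdf: VolumeGrid | None = None
    #: signed distances (mm) to each internal tissue interface, one component
    #: per interface; lets the solver place conductivity jumps sub-voxel
    interface_sdfs: VolumeGrid | None = None

    def __post_init__(self) -> None:
        if self.tensors.n_components != 6:
            raise ValueError("conductivity volume needs 6 tensor components per voxel")
        if self.tensors.shape != self.mask.shape:
            raise ValueError("tensor and mask grids must share a shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape

    @property
    def affine(self) -> np.ndarray:
        return self.tensors.affine

    def full_matrices(self) -> np.ndarray:
        """Expand the 6 packed components to dense (*shape, 3, 3) symmetric matrices."""
        t = self.tensors.values
        m = np.zeros(t.shape[:3] + (3, 3))
        m[..., 0, 0], m[..., 1, 1], m[..., 2, 2] = t[..., 0], t[..., 1], t[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
        return m


@dataclass
class HeadGeometry:
    scalp_mesh: TriangleMesh
    gm_mesh: TriangleMesh
    center: np.ndarray            # world mm
    outer_radius: float           # mm
    shell_radii: tuple[float, ...]  # mm, strictly decreasing from outer_radius

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        radii = np.asarray(self.shell_radii, dtype=float)
        if np.any(np.diff(radii) >= 0):
            raise ValueError("shell radii must be strictly decreasing")
        if abs(radii[0] - self.outer_radius) > 1e-9:
            raise ValueError("first shell radius must equal outer_radius")

    @property
    def white_matter_radius(self) -> float:
        return float(self.shell_radii[-1])


def _icosphere(radius: float, center: np.ndarray, subdivisions: int = 3) -> TriangleMesh:
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices) + center, np.asarray(tm.faces))


def make_sphere_head(
    outer_radius_mm: float = 56.0,
    shells: Sequence[tuple[float, float]] | None = None,
    grid_shape: Sequence[int] = (48, 48, 48),
    voxel_mm: float = 2.5,
    seed: int | None = None,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    gm_shell_index: int = -2,
) -> tuple[ConductivityVolume, HeadGeometry]:
    """Build a multi-shell spherical head on a voxel grid.

    Parameters
    ----------
    shells
        Outermost→innermost ``(radius_mm, conductivity)`` pairs. ``None`` takes
        :data:`DEFAULT_SHELLS` scaled by ``outer_radius_mm``.
    grid_shape, voxel_mm
        Isotropic grid; the grid is centered on ``center``.
    seed
        Unused by the deterministic construction; accepted for interface
        uniformity with the stochastic generators.
    gm_shell_index
        Which shell's radius carries the gray-matter mesh (default: the
        second-innermost shell).
    """
    if shells is None:
        shells = [(rel * outer_radius_mm, c) for rel, c in DEFAULT_SHELLS]
    radii = np.array([r for r, _ in shells], dtype=float)
    conds = np.array([c for _, c in shells], dtype=float)
    if np.any(np.diff(radii) >= 0):
        raise ValueError("shell radii must be strictly decreasing (outermost first)")
    if abs(radii[0] - outer_radius_mm) > 1e-9:
        raise ValueError("first shell radius must equal outer_radius_mm")
    if np.any(conds < 0):
        raise ValueError("conductivities must be >= 0")

    grid_shape = tuple(int(n) for n in grid_shape)
    center = np.asarray(center, dtype=float)
    # grid centered on the head center
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = center - voxel_mm * (np.asarray(grid_shape) - 1) / 2.0
    half_extent = voxel_mm * np.min(grid_shape) / 2.0
    if outer_radius_mm > half_extent:
        raise ValueError(
            f"sphere radius {outer_radius_mm} mm exceeds grid half-extent {half_extent} mm"
        )

    grid = VolumeGrid(np.zeros(grid_shape + (6,)), affine)
    r = np.linalg.norm(grid.voxel_centers() - center, axis=-1)

    tensors = np.zeros(grid_shape + (6,))
    mask = r <= radii[0]
    # innermost shell containing the voxel center; a center exactly on a shell
    # radius belongs to the outer shell (r <= radius_inner excludes it from inner)
    sigma = np.zeros(grid_shape)
    for rad, c in zip(radii, conds):  # outermost→innermost: inner shells overwrite
        sigma[r < rad] = c
    sigma[r == radii[0]] = conds[0]
    sigma[~mask] = 0.0
    for d in _DIAG:
        tensors[..., d] = sigma

    cv = ConductivityVolume(
        tensors=VolumeGrid(tensors, affine),
        mask=VolumeGrid(mask.astype(np.uint8), affine.copy()),
        surface_sdf=VolumeGrid(r - radii[0], affine.copy()),
        interface_sdfs=(
            VolumeGrid(np.stack([r - rad for rad in radii[1:]], axis=-1), affine.copy())
            if len(radii) > 1 else None
        ),
    )
    gm_radius = radii[gm_shell_index] if len(radii) > 1 else radii[0]
    geom = HeadGeometry(
        scalp_mesh=_icosphere(radii[0], center),
        gm_mesh=_icosphere(gm_radius, center),
        center=center,
        outer_radius=float(radii[0]),
        shell_radii=tuple(float(x) for x in radii),
    )
    return cv, geom


def randomize_conductivity_tensors(
    cv: ConductivityVolume,
    wm_shell: tuple[float, float],
    anisotropy_ratio: float,
    seed: int,
) -> ConductivityVolume:
    """Introduce white-matter anisotropy with random per-voxel principal directions.

    Within the radial shell ``r_in < r <= r_out`` each tensor is rebuilt as a
    cylindrically symmetric tensor with a random unit principal axis, principal
    eigenvalue lambda1 and transverse eigenvalues lambda1/ratio, scaled so the
    trace is preserved. ``anisotropy_ratio = 1`` reproduces the input exactly.
    """
    r_in, r_out = float(wm_shell[0]), float(wm_shell[1])
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy_ratio must be >= 1")
    rng = np.random.default_rng(seed)

    out = ConductivityVolume(cv.tensors.copy(), cv.mask.copy())
    center_world = cv.tensors.index_to_world(
        (np.asarray(cv.shape, dtype=float) - 1) / 2.0
    )[0]
    r = np.linalg.norm(cv.tensors.voxel_centers() - center_world, axis=-1)
    sel = (r > r_in) & (r <= r_out) & (cv.mask.values > 0)
    n = int(sel.sum())
    if n == 0:
        return out

    # random unit directions (normal deviates normalized)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    t = cv.tensors.values[sel]
    trace = t[..., 0] + t[..., 1] + t[..., 2]
    ratio = float(anisotropy_ratio)
    lam1 = trace / (1.0 + 2.0 / ratio)
    lam_t = lam1 / ratio
    # sigma = lam_t I + (lam1 - lam_t) u u^T
    diff = lam1 - lam_t
    new = np.empty_like(t)
    new[:, 0] = lam_t + diff * u[:, 0] ** 2
    new[:, 1] = lam_t + diff * u[:, 1] ** 2
    new[:, 2] = lam_t + diff * u[:, 2] ** 2
    new[:, 3] = diff * u[:, 0] * u[:, 1]
    new[:, 4] = diff * u[:, 0] * u[:, 2]
    new[:, 5] = diff * u[:, 1] * u[:, 2]
    if ratio == 1.0:
        new = t  # exactly unchanged, not merely to rounding
    out.tensors.values[sel] = new
    return out


def make_synthetic_streamlines(
    head: HeadGeometry,
    n: int = 50,
    points_per_line: int = 20,
    seed: int = 0,
) -> Streamlines:
    """Generate arc-shaped synthetic fiber bundles inside the white-matter core.

    Each streamline is a circular arc at a random radius strictly inside the
    innermost (white-matter) sphere, between 35% and 100% of its radius,
    mimicking association-fiber curvature. Purely a display/projection
    fixture; carries no diffusion physics.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r_out = head.white_matter_radius
    r_in = 0.35 * r_out
    if r_out - r_in < 1e-6:
        raise ValueError("white-matter shell too thin for streamline arcs")
    lines = []
    for _ in range(n):
        radius = rng.uniform(r_in * 1.02, r_out * 0.98)
        # random orthonormal pair spanning the arc plane
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        e1, e2 = q[:, 0], q[:, 1]
        span = rng.uniform(0.5 * np.pi, 1.5 * np.pi)
        t0 = rng.uniform(0.0, 2.0 * np.pi)
        t = t0 + np.linspace(0.0, span, points_per_line)
        pts = head.center + radius * (np.outer(np.cos(t), e1) + np.outer(np.sin(t), e2))
        lines.append(pts)
    return Streamlines(lines)


def default_head(grid_n: int = 48, voxel_mm: float = 2.5,
                 outer_radius_mm: float = 56.0) -> tuple[ConductivityVolume, HeadGeometry]:
    """Convenience: the desk-scale default head (48^3 at 2.5 mm, 56 mm sphere)."""
    return make_sphere_head(
        outer_radius_mm=outer_radius_mm,
        grid_shape=(grid_n, grid_n, grid_n),
        voxel_mm=voxel_mm,
    )
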