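"""Figure-8 TMS coil model, analytic dA/dt evaluation, and placement sampling.

The coil is discretized into straight current segments. For a straight segment
carrying dI/dt, the time derivative of the magnetic vector potential at a field
point r is the closed-form line integral

    dA/dt(r) = (mu0 dI/dt / 4 pi) * l_hat * ln((|r-a| + |r-b| + L) / (|r-a| + |r-b| - L))

where a, b are the segment endpoints, L its length and l_hat its direction.
Summed over segments this gives the primary ("incident") electric-field term
-dA/dt that drives the quasi-static volume-conductor problem. Units: the grid
is in mm; lengths cancel inside the logarithm, so dA/dt is returned in V/m.

Coil frame convention: the winding lies in the z=0 plane, -z faces the scalp,
and the handle points along +y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import RigidTransform, TransformError, VolumeGrid, transform_vector_volume
from .headmodel import HeadGeometry

__all__ = [
    "MU0",
    "CoilModel",
    "CoilPose",
    "PlacementSet",
    "make_figure8_coil",
    "dadt_field",
    "eeg_1010_sites",
    "pose_at_site",
    "sample_placements",
]

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

_GUARD_DISTANCE_MM = 0.5


@dataclass
class CoilModel:
    """Discretized coil winding: straight segments in coil-frame mm."""

    starts: np.ndarray        # (n, 3) segment start points, coil frame mm
    ends: np.ndarray          # (n, 3)
    circulation: np.ndarray   # (n,) signed winding sense (+1 / -1)
    dIdt: float               # A/s
    name: str = "figure8"

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=float).reshape(-1, 3)
        self.ends = np.asarray(self.ends, dtype=float).reshape(-1, 3)
        self.circulation = np.asarray(self.circulation, dtype=float).reshape(-1)
        if not (len(self.starts) == len(self.ends) == len(self.circulation)):
            raise ValueError("segment arrays must share a length")
        if np.any(np.linalg.norm(self.ends - self.starts, axis=1) <= 0):
            raise ValueError("zero-length segment")

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def magnetic_moment(self) -> np.ndarray:
        """Net signed loop-area vector, sum over segments of 0.5 r x dl (mm^2)."""
        mid = 0.5 * (self.starts + self.ends)
        dl = (self.ends - self.starts) * self.circulation[:, None]
        return 0.5 * np.cross(mid, dl).sum(axis=0)

    def to_mesh(self, wire_radius_mm: float = 2.0):
        """Tube mesh around the winding for display export (STL)."""
        import trimesh

        paths = []
        for s, e in zip(self.starts, self.ends):
            seg = trimesh.creation.cylinder(
                radius=wire_radius_mm,
                segment=np.stack([s, e]),
                sections=8,
            )
            paths.append(seg)
        return trimesh.util.concatenate(paths)


@dataclass(frozen=True)
class CoilPose:
    """Coil-frame → world rigid transform (coil plane z=0, -z toward scalp)."""

    transform: RigidTransform

    @classmethod
    def identity(cls) -> "CoilPose":
        return cls(RigidTransform.identity())

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "CoilPose":
        return cls(RigidTransform(np.asarray(m, dtype=float)))

    @property
    def matrix(self) -> np.ndarray:
        return self.transform.matrix

    @property
    def position(self) -> np.ndarray:
        return self.transform.translation

    @property
    def z_axis(self) -> np.ndarray:
        return self.transform.rotation[:, 2]


@dataclass
class PlacementSet:
    """Sampled coil placements: (pose, site label, handle-direction index)."""

    poses: list[CoilPose]
    site_labels: list[str]
    direction_indices: list[int]
    seed: int

    def __len__(self) -> int:
        return len(self.poses)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for pose, lab, k in zip(self.poses, self.site_labels, self.direction_indices):
            row = {"site": lab, "direction_index": k}
            row.update({f"m{i}{j}": pose.matrix[i, j] for i in range(4) for j in range(4)})
            rows.append(row)
        return pd.DataFrame(rows)


def make_figure8_coil(
    loop_radius_mm: float = 27.0,
    loop_center_offset_mm: float = 27.0,
    segments_per_loop: int = 64,
    dIdt: float = 1.0e6,
) -> CoilModel:
    """Two coplanar counter-wound circular loops at (+-offset, 0, 0).

    Default geometry approximates a 70 mm figure-8 treatment coil: 27 mm loop
    radius with loop centers 54 mm apart, 64 chords per loop, dI/dt 1e6 A/s.
    """
    if loop_radius_mm <= 0:
        raise ValueError("loop radius must be > 0")
    if loop_center_offset_mm <= 0:
        raise ValueError("loop center offset must be > 0")
    if segments_per_loop < 8:
        raise ValueError("segments_per_loop must be >= 8")

    th = np.linspace(0.0, 2.0 * np.pi, segments_per_loop + 1)
    # area-preserving chord radius: the inscribed n-gon systematically under-
    # represents the loop; matching its area to the circle cancels the leading
    # discretization error of the field
    r_eff = loop_radius_mm * np.sqrt(
        (2.0 * np.pi / segments_per_loop) / np.sin(2.0 * np.pi / segments_per_loop))
    starts, ends, circ = [], [], []
    for cx, sense in ((+loop_center_offset_mm, +1.0), (-loop_center_offset_mm, -1.0)):
        # opposite circulation: traverse one loop reversed
        ang = th if sense > 0 else th[::-1]
        pts = np.stack(
            [cx + r_eff * np.cos(ang), r_eff * np.sin(ang),
             np.zeros_like(ang)], axis=1
        )
        starts.append(pts[:-1])
        ends.append(pts[1:])
        circ.append(np.full(segments_per_loop, 1.0))
    return CoilModel(
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        circulation=np.concatenate(circ),
        dIdt=float(dIdt),
    )


def make_single_loop(radius_mm: float = 27.0, segments: int = 64, dIdt: float = 1.0e6) -> CoilModel:
    """A single circular loop centered at the coil-frame origin (test/oracle geometry)."""
    th = np.linspace(0.0, 2.0 * np.pi, segments + 1)
    radius_mm = radius_mm * np.sqrt(
        (2.0 * np.pi / segments) / np.sin(2.0 * np.pi / segments))
    pts = np.stack([radius_mm * np.cos(th), radius_mm * np.sin(th), np.zeros_like(th)], axis=1)
    return CoilModel(pts[:-1], pts[1:], np.ones(segments), float(dIdt), name="loop")


def dadt_segment_sum(points_mm: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                     dIdt: float) -> np.ndarray:
    """Closed-form dA/dt (V/m) of straight segments at world points (mm)."""
    pts = np.asarray(points_mm, dtype=float)
    out = np.zeros_like(pts)
    d = ends - starts
    L = np.linalg.norm(d, axis=1)
    lhat = d / L[:, None]
    for a, b, Li, u in zip(starts, ends, L, lhat):
        ra = np.linalg.norm(pts - a, axis=1)
        rb = np.linalg.norm(pts - b, axis=1)
        s = ra + rb
        denom = s - Li
        # guard: points on/near the wire make the log singular
        min_denom = 2.0 * _GUARD_DISTANCE_MM**2 / np.maximum(s, 1e-12)
        near = denom < min_denom
        if np.any(near):
            import logging

            logging.getLogger(__name__).warning(
                "%d evaluation points within %.2f mm of the coil wire; distance clamped",
                int(near.sum()), _GUARD_DISTANCE_MM,
            )
            denom = np.maximum(denom, min_denom)
        out += np.log((s + Li) / denom)[:, None] * u
    # mm cancels in the log argument; mu0*dIdt/(4pi) carries units of V/m * (A/s)^-1...
    # concretely mu0/(4pi) [T*m/A] * dIdt [A/s] = V/m per unit log-sum.
    return (MU0 * dIdt / (4.0 * np.pi)) * out


def dadt_field(coil: CoilModel, pose: CoilPose, grid: VolumeGrid) -> VolumeGrid:
    """Evaluate the coil's dA/dt on every voxel center of ``grid``, in world frame."""
    T = pose.transform  # validated rigid
    starts_w = T.apply_points(coil.starts)
    ends_w = T.apply_points(coil.ends)
    # circulation sign folded into segment direction
    flip = coil.circulation < 0
    starts_w[flip], ends_w[flip] = ends_w[flip].copy(), starts_w[flip].copy()

    pts = grid.voxel_centers().reshape(-1, 3)
    vals = dadt_segment_sum(pts, starts_w, ends_w, coil.dIdt)
    return VolumeGrid(vals.reshape(grid.shape + (3,)), grid.affine.copy())


# --------------------------------------------------------------------------- #
# EEG 10-10 site table and placement sampling
# --------------------------------------------------------------------------- #

_ROWS = [
    # (row label prefix pair, midline angle from vertex toward nasion, deg, labels)
    ("Fp", 72.0, ["Fp1", "Fpz", "Fp2"]),
    ("AF", 54.0, ["AF7", "AF3", "AFz", "AF4", "AF8"]),
    ("F", 36.0, ["F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8"]),
    ("FC", 18.0, ["FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"]),
    ("C", 0.0, ["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"]),
    ("CP", -18.0, ["TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8"]),
    ("P", -36.0, ["P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8"]),
    ("PO", -54.0, ["PO7", "PO3", "POz", "PO4", "PO8"]),
    ("O", -72.0, ["O1", "Oz", "O2"]),
]

# lower ring ("9/10" positions) 18 deg below the ear line, azimuth from +y (nasion)
_LOWER_RING = [
    ("F9", -36.0), ("F10", +36.0),
    ("FT9", -63.0), ("FT10", +63.0),
    ("T9", -90.0), ("T10", +90.0),
    ("TP9", -117.0), ("TP10", +117.0),
    ("P9", -144.0), ("P10", +144.0),
    ("PO9", -162.0), ("PO10", +162.0),
]


def _row_circle_point(mid_angle_deg: float, frac: float) -> np.ndarray:
    """Unit-sphere point at lateral fraction ``frac`` in [-1, 1] along a coronal row.

    The row is the circle through the left ear point (-1,0,0), the midline
    point at ``mid_angle_deg`` from the vertex toward the nasion, and the right
    ear point (1,0,0). frac=-1 is the left ear end, 0 the midline, +1 the right
    ear end; electrodes sit at equal angles along the circle.
    """
    a = np.deg2rad(mid_angle_deg)
    A = np.array([0.0, np.sin(a), np.cos(a)])  # midline point (RAS: +y anterior)
    L = np.array([-1.0, 0.0, 0.0])
    # circle center lies on the y-z plane line equidistant from A and L
    # center c = (0, cy, cz) with |A-c| = |L-c| and c in the plane of {L, A, R}
    # plane normal:
    nrm = np.cross(A - L, np.array([1.0, 0.0, 0.0]) - L)
    nn = np.linalg.norm(nrm)
    if nn < 1e-12:  # degenerate: A on the ear axis
        raise ValueError("row through the ear axis is degenerate")
    nrm /= nn
    # center of circle = projection of sphere center (origin) onto plane
    d = np.dot(nrm, L)
    c = d * nrm
    rho = float(np.sqrt(max(1.0 - d * d, 0.0)))
    e1 = (A - c) / np.linalg.norm(A - c)
    e2 = np.cross(nrm, e1)
    e2 /= np.linalg.norm(e2)
    # angle of L about the circle center
    vL = (L - c) / np.linalg.norm(L - c)
    angL = np.arctan2(np.dot(vL, e2), np.dot(vL, e1))
    # frac interpolates angle linearly from midline (0) to either end (+-angL)
    ang = abs(angL) * frac * np.sign(-angL) if angL != 0 else 0.0
    # choose sign so frac=+1 lands on the right ear (+x)
    p = c + rho * (np.cos(ang) * e1 + np.sin(ang) * e2)
    if frac != 0 and np.sign(p[0]) != np.sign(frac):
        ang = -ang
        p = c + rho * (np.cos(ang) * e1 + np.sin(ang) * e2)
    return p / np.linalg.norm(p)


def eeg_1010_sites() -> list[tuple[str, np.ndarray]]:
    """Built-in idealized 10-10 site table: 73 labelled unit directions.

    61 upper sites on nine coronal rows (18 deg midline steps, equal angular
    spacing within each row, outermost electrodes 80% of the arc toward the
    ear line) plus a 12-site lower ring 18 deg below the ear line. Positions
    are an idealized spherical layout, not a measured montage.
    """
    sites: list[tuple[str, np.ndarray]] = []
    for _, mid_angle, labels in _ROWS:
        m = len(labels)
        half = (m - 1) // 2
        for i, lab in enumerate(labels):
            frac = 0.8 * (i - half) / half if half else 0.0
            sites.append((lab, _row_circle_point(mid_angle, frac)))
    incl = np.deg2rad(108.0)  # 18 deg below the equator
    for lab, az_deg in _LOWER_RING:
        az = np.deg2rad(az_deg)
        p = np.array([np.sin(incl) * np.sin(az), np.sin(incl) * np.cos(az), np.cos(incl)])
        sites.append((lab, p))
    assert len(sites) == 73
    return sites


def pose_at_site(
    head: HeadGeometry,
    unit_dir: np.ndarray,
    handle_angle_deg: float,
    standoff_mm: float = 2.0,
) -> CoilPose:
    """Coil pose at a scalp site: -z toward the head center, handle rotated about the normal.

    Handle direction 0 is the local tangent toward the nasion (+y world),
    falling back to +x at sites collinear with +y.
    """
    u = np.asarray(unit_dir, dtype=float)
    u = u / np.linalg.norm(u)
    pos = head.center + (head.outer_radius + standoff_mm) * u
    ref = np.array([0.0, 1.0, 0.0])
    t = ref - np.dot(ref, u) * u
    if np.linalg.norm(t) < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        t = ref - np.dot(ref, u) * u
    t /= np.linalg.norm(t)
    # rotate handle tangent about u
    th = np.deg2rad(handle_angle_deg)
    y_axis = (np.cos(th) * t
              + np.sin(th) * np.cross(u, t))
    y_axis /= np.linalg.norm(y_axis)
    z_axis = u  # -z faces the scalp (z points away from the head)
    x_axis = np.cross(y_axis, z_axis)
    R = np.stack([x_axis, y_axis, z_axis], axis=1)
    return CoilPose(RigidTransform.from_rotation_translation(R, pos))


def sample_placements(
    head: HeadGeometry,
    n_cases: int = 300,
    n_directions: int = 78,
    seed: int = 0,
    standoff_mm: float = 2.0,
    sites: Sequence[tuple[str, np.ndarray]] | None = None,
) -> PlacementSet:
    """Enumerate site x handle-direction poses and draw a uniform random subset.

    At each 10-10 site the coil handle takes ``n_directions`` evenly spaced
    angles over 360 deg about the coil normal; ``n_cases`` (site, direction)
    pairs are then chosen without replacement with the given seed.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    if sites is None:
        sites = eeg_1010_sites()
    total = len(sites) * n_directions
    if n_cases > total:
        raise ValueError(f"n_cases={n_cases} exceeds enumerable set of {total}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=n_cases, replace=False)
    poses, labels, dirs = [], [], []
    step = 360.0 / n_directions
    for flat in np.sort(chosen):
        si, di = divmod(int(flat), n_directions)
        lab, u = sites[si]
        poses.append(pose_at_site(head, u, di * step, standoff_mm=standoff_mm))
        labels.append(lab)
        dirs.append(di)
    return PlacementSet(poses=poses, site_labels=labels, direction_indices=dirs, seed=seed)
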