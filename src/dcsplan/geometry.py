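"""Beam geometry, beam's-eye-view transforms, radiological depth, dose grid.

Coordinate conventions
----------------------
Patient coordinates are right-handed.  The beam's-eye-view (BEV) frame is a
rigid rotation of the patient frame: ``z_bev`` points from source to
isocenter, ``x_bev``/``y_bev`` span the isocenter plane.  Gantry rotation is
about the patient ``y`` axis and couch rotation about the patient ``z`` axis
(IEC 61217 ordering, gantry applied after couch), so gantry 0 / couch 0 is
the identity and gantry 180 deg flips the sign of ``x_bev``.

Radiological (water-equivalent) depth is the line integral of density along
the beam axis from the phantom entry surface, plus the water-equivalent
thickness of a range shifter when configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import VoxelPhantom

__all__ = ["BeamGeometry", "DoseGrid", "radiological_depth", "radiological_depth_points"]


@dataclass
class BeamGeometry:
    """One treatment beam: orientation, isocenter and projection geometry.

    ``source_axis_distance`` is the effective distance for projecting
    trimmer edges to the isocenter plane; since all positions in this
    package are kept in the isocenter plane it only matters when exporting
    to hardware frames.  ``range_shifter_wet`` is the additive
    water-equivalent thickness (mm) of an upstream degrader, 0 when absent.
    """

    gantry_angle: float = 0.0
    couch_angle: float = 0.0
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))
    source_axis_distance: float = 2000.0
    air_gap: float = 100.0
    range_shifter_wet: float = 0.0

    def __post_init__(self) -> None:
        self.gantry_angle = float(self.gantry_angle) % 360.0
        self.couch_angle = float(self.couch_angle) % 360.0
        self.isocenter = np.asarray(self.isocenter, dtype=float).reshape(3)

    @property
    def rotation(self) -> np.ndarray:
        """Orthonormal matrix whose columns are (x_bev, y_bev, z_bev)."""
        g = np.deg2rad(self.gantry_angle)
        c = np.deg2rad(self.couch_angle)
        ry = np.array(
            [[np.cos(g), 0.0, np.sin(g)], [0.0, 1.0, 0.0], [-np.sin(g), 0.0, np.cos(g)]]
        )
        rz = np.array(
            [[np.cos(c), -np.sin(c), 0.0], [np.sin(c), np.cos(c), 0.0], [0.0, 0.0, 1.0]]
        )
        return ry @ rz

    @property
    def direction(self) -> np.ndarray:
        """Unit beam direction (source towards isocenter) in patient coords."""
        return self.rotation[:, 2]

    def to_bev(self, points: np.ndarray) -> np.ndarray:
        """Map patient-coordinate points into the BEV frame.

        Returns ``(x_bev, y_bev, depth_axis)`` where ``depth_axis`` grows
        from the isocenter towards the beam exit.  Accepts a single point or
        an ``(n, 3)`` array; rigid, hence distance-preserving and invertible.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = (p - self.isocenter) @ self.rotation
        return out[0] if np.asarray(points).ndim == 1 else out

    def from_bev(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_bev`."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.isocenter
        return out[0] if np.asarray(points).ndim == 1 else out


# ---------------------------------------------------------------------------
# Radiological depth


def _entry_distance(phantom: VoxelPhantom, points: np.ndarray, direction: np.ndarray):
    """Distance from the phantom entry surface to each point along -direction.

    Returns the path length inside the phantom bounding box from the entry
    face to the point (0 when the backwards ray misses the box entirely).
    """
    lo = phantom.origin
    hi = phantom.origin + phantom.extent
    d = direction
    # Ray x(t) = p - t*d for t in [0, inf); find largest t still inside box.
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (points - lo) / d
        t2 = (points - hi) / d
    t_near = np.minimum(t1, t2)
    t_far = np.maximum(t1, t2)
    static_miss = np.zeros(len(points), dtype=bool)
    for a in range(3):
        if abs(d[a]) < 1e-12:
            inside = (points[:, a] >= lo[a]) & (points[:, a] <= hi[a])
            static_miss |= ~inside
            t_near[:, a] = -np.inf
            t_far[:, a] = np.inf
    t_exit = np.min(t_far, axis=1)  # upstream face (walking backwards)
    t_enter = np.max(t_near, axis=1)
    t_start = np.clip(t_enter, 0.0, None)
    length = np.clip(t_exit, 0.0, None) - t_start
    misses = static_miss | ~np.isfinite(length) | (t_exit < t_enter) | (t_exit < 0)
    return np.where(misses, 0.0, t_start), np.where(misses, 0.0, np.clip(length, 0.0, None))


def radiological_depth_points(
    phantom: VoxelPhantom,
    beam: BeamGeometry,
    points: np.ndarray,
    step: float | None = None,
    chunk: int = 8192,
) -> np.ndarray:
    """Water-equivalent depth of each point along the beam axis (vectorized).

    Midpoint-rule line integral of trilinearly interpolated density from the
    phantom entry surface to the point, plus the beam's range-shifter WET.
    ``step`` is the nominal integration step (mm); default half the minimum
    voxel size.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = beam.direction
    t0, seg = _entry_distance(phantom, pts, d)
    if step is None:
        step = float(phantom.spacing.min()) / 2.0
    wed = np.zeros(len(pts))
    for i0 in range(0, len(pts), chunk):
        sl = slice(i0, min(i0 + chunk, len(pts)))
        L = seg[sl]
        n = max(int(np.ceil(L.max() / step)), 1) if L.max() > 0 else 1
        # midpoint samples over the in-phantom segment, per-point length
        frac = (np.arange(n) + 0.5) / n
        ts = t0[sl, None] + L[:, None] * frac[None, :]  # distance back from the point
        sample = pts[sl, None, :] - ts[:, :, None] * d[None, None, :]
        idx = (sample - phantom.origin[None, None, :]) / phantom.spacing[None, None, :] - 0.5
        rho = map_coordinates(
            phantom.density,
            idx.reshape(-1, 3).T,
            order=1,
            mode="nearest",
        ).reshape(ts.shape)
        wed[sl] = rho.sum(axis=1) * (L / n)
    wed += beam.range_shifter_wet
    return wed if np.asarray(points).ndim > 1 else float(wed[0])


def radiological_depth(
    phantom: VoxelPhantom, beam: BeamGeometry, point, step: float | None = None
) -> float:
    """Water-equivalent depth (mm) of a single point; see module docstring."""
    return float(radiological_depth_points(phantom, beam, np.asarray(point, dtype=float)[None, :], step=step)[0])


def geometric_depth_at_wed(
    phantom: VoxelPhantom, beam: BeamGeometry, bev_xy, wed_target: float,
    step: float = 1.0,
) -> np.ndarray:
    """Patient point on the ray at BEV offset ``bev_xy`` where the
    water-equivalent depth equals ``wed_target`` (bisection on the depth
    axis).  Used to locate the R90 point of a spot."""
    bx, by = float(bev_xy[0]), float(bev_xy[1])
    diag = float(np.linalg.norm(phantom.extent))

    def wed_at(t: np.ndarray) -> np.ndarray:
        pts = beam.from_bev(np.stack([np.full_like(t, bx), np.full_like(t, by), t], axis=1))
        return radiological_depth_points(phantom, beam, pts, step=step)

    lo = np.array([-diag]); hi = np.array([diag])
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if wed_at(mid)[0] < wed_target:
            lo = mid
        else:
            hi = mid
    t = float((lo + hi)[0] / 2.0)
    return beam.from_bev(np.array([bx, by, t]))


# ---------------------------------------------------------------------------
# Variable-resolution dose grid


@dataclass
class DoseGrid:
    """Flattened variable-resolution dose grid.

    Fine cells (the phantom's native voxels) cover the target and OARs
    dilated by ``dilate_mm``; elsewhere voxels are merged into coarse
    ``block x block x block`` cells.  Structure occupancies are carried per
    cell; ``count_weight(name)`` expresses occupancy in units of fine voxels
    so that sums are invariant under the coarsening.
    """

    centers: np.ndarray          # (n, 3) cell centers, patient coords
    volumes: np.ndarray          # (n,) mm^3
    density: np.ndarray          # (n,) mean density
    zeta: dict                   # name -> (n,) occupancy fraction
    roles: dict                  # name -> role
    is_fine: np.ndarray          # (n,) bool
    fine_voxel_volume: float
    fine_spacing: np.ndarray
    phantom: VoxelPhantom | None = None

    @property
    def n_cells(self) -> int:
        return len(self.volumes)

    def count_weight(self, name: str) -> np.ndarray:
        """Occupancy of ``name`` per cell in fine-voxel-count units."""
        return self.zeta[name] * (self.volumes / self.fine_voxel_volume)

    def structure_volume(self, name: str) -> float:
        """Partial-volume structure volume in mm^3."""
        return float(np.sum(self.zeta[name] * self.volumes))


def build_dose_grid(
    phantom: VoxelPhantom,
    fine_roles: tuple = ("target", "oar"),
    dilate_mm: float = 10.0,
    coarse_block: int = 2,
) -> DoseGrid:
    """Construct the variable-resolution dose grid from a phantom.

    The phantom's native spacing is the fine resolution; voxels outside the
    dilated target/OAR region are merged into ``coarse_block``-cubed cells
    (occupancy averaged, volume summed, so zeta * volume is conserved
    exactly).
    """
    from scipy.ndimage import distance_transform_edt

    dims = phantom.dims
    fine_mask = np.zeros(dims, dtype=bool)
    for s in phantom.structures.values():
        if s.role in fine_roles:
            fine_mask |= s.zeta > 0
    if fine_mask.any() and dilate_mm > 0:
        dist = distance_transform_edt(~fine_mask, sampling=phantom.spacing)
        fine_mask = dist <= dilate_mm

    b = int(coarse_block)
    # blocks fully outside the fine region become coarse cells
    nb = [dims[a] // b for a in range(3)]
    centers = phantom.voxel_centers().reshape(dims + (3,))
    vol = phantom.voxel_volume

    coarse_sel = np.zeros(dims, dtype=bool)
    coarse_centers, coarse_density, coarse_zeta = [], [], {n: [] for n in phantom.structures}
    for ix in range(nb[0]):
        for iy in range(nb[1]):
            for iz in range(nb[2]):
                sl = (
                    slice(ix * b, (ix + 1) * b),
                    slice(iy * b, (iy + 1) * b),
                    slice(iz * b, (iz + 1) * b),
                )
                if fine_mask[sl].any():
                    continue
                coarse_sel[sl] = True
                coarse_centers.append(centers[sl].reshape(-1, 3).mean(axis=0))
                coarse_density.append(phantom.density[sl].mean())
                for name, s in phantom.structures.items():
                    coarse_zeta[name].append(s.zeta[sl].mean())

    fine_sel = ~coarse_sel
    fine_centers = centers[fine_sel]
    n_coarse = len(coarse_centers)
    all_centers = np.vstack([fine_centers] + ([np.asarray(coarse_centers)] if n_coarse else []))
    volumes = np.concatenate(
        [np.full(fine_sel.sum(), vol), np.full(n_coarse, vol * b**3)]
    )
    density = np.concatenate(
        [phantom.density[fine_sel], np.asarray(coarse_density) if n_coarse else np.empty(0)]
    )
    zeta = {}
    for name, s in phantom.structures.items():
        zeta[name] = np.concatenate(
            [s.zeta[fine_sel], np.asarray(coarse_zeta[name]) if n_coarse else np.empty(0)]
        )
    is_fine = np.concatenate(
        [np.ones(fine_sel.sum(), dtype=bool), np.zeros(n_coarse, dtype=bool)]
    )
    return DoseGrid(
        centers=all_centers,
        volumes=volumes,
        density=density,
        zeta=zeta,
        roles={n: s.role for n, s in phantom.structures.items()},
        is_fine=is_fine,
        fine_voxel_volume=vol,
        fine_spacing=phantom.spacing.copy(),
        phantom=phantom,
    )
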