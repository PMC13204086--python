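"""Geometric Adjustment (GA): per-spot trimmer initialization.

Each beam spot is classified as collimated or uncollimated from local
target / healthy-tissue geometry in a thin slab about the spot's R90 depth,
and at most one trimmer per BEV axis is activated.  Two formulations are
used depending on whether the spot axis lies inside or outside the target
periphery:

* outside the target: an inverse-square-distance weighted *collimation
  vector* eta over the marginal target voxels points towards the target;
  the active trimmer on each axis is the one eta points away from, offset
  by ``mu - |eta_component|`` (saturating at ``f_min``);
* inside the target: eta' sums inverse-square-weighted *unit* vectors
  towards nearby healthy tissue; the active trimmer is the one eta' points
  towards; the primary offset is ``f'_min`` and the secondary offset relaxes
  smoothly from fully parked to ``f'_min`` as |eta'_s| grows.

The opposing trimmers are registered as free agents (delivery-sequencing
currency) and parked at ``f'_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beamlets import Spot, TrimmerSet

__all__ = [
    "GAParams",
    "CollimationVector",
    "TrimmerAssignment",
    "GAContext",
    "marginal_voxel_set",
    "collimation_vector_outside",
    "collimation_vector_inside",
    "split_primary_secondary",
    "init_trimmers_outside",
    "init_trimmers_inside",
    "classify_spot",
    "assign_trimmers",
]


@dataclass
class GAParams:
    """GA tuning parameters (mm unless noted).

    Defaults follow the published parameter sets: ``dz=1, dr=5, f_min=1,
    mu_p=1, mu_s=5`` for spots outside the target and ``a_prime=1,
    mu_max_prime=2, f_max_prime=25, f_min_prime=1, c_s=5.657 /mm, k_s=15``
    for spots inside.  ``a_prime`` is carried but enters no formula.
    """

    dz: float = 1.0
    dr: float = 5.0
    f_min: float = 1.0
    mu_p: float = 1.0
    mu_s: float = 5.0
    a_prime: float = 1.0
    mu_max_prime: float = 2.0
    f_max_prime: float = 25.0
    f_min_prime: float = 1.0
    c_s: float = 5.657          # mm^-1
    k_s: float = 15.0           # unitless
    target_zeta_threshold: float = 0.5
    tissue_density_threshold: float = 0.05

    def __post_init__(self):
        for name in ("dz", "dr", "f_min", "mu_p", "mu_s", "mu_max_prime",
                     "f_max_prime", "f_min_prime", "c_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GA parameter {name} must be positive")
        if self.f_min_prime > self.f_max_prime:
            raise ValueError("f_min_prime must not exceed f_max_prime")


@dataclass
class CollimationVector:
    """BEV collimation vector split into primary/secondary components."""

    eta: np.ndarray            # (2,) BEV vector
    primary_axis: str          # "x" or "y"
    eta_p: float               # signed component along the primary axis
    eta_s: float               # signed component along the secondary axis


@dataclass
class TrimmerAssignment:
    """Result of GA for one spot."""

    spot_id: int
    classification: str        # "collimated-outside" | "collimated-inside" | "uncollimated"
    trimmers: TrimmerSet
    roles: dict = field(default_factory=dict)  # trimmer name -> "active"|"free"|"parked"
    vector: CollimationVector | None = None

    @property
    def collimated(self) -> bool:
        return self.classification != "uncollimated"


class GAContext:
    """Per-beam geometry cache used by GA: BEV coordinates, water-equivalent
    depths and tissue membership of every dose-grid cell.

    Target membership uses ``zeta >= target_zeta_threshold``; healthy tissue
    is any cell with density above the tissue threshold that is not target.
    """

    def __init__(self, grid, beam, target: str, params: GAParams | None = None,
                 cell_wed: np.ndarray | None = None):
        from .geometry import radiological_depth_points

        self.params = params or GAParams()
        bev = beam.to_bev(grid.centers)
        self.bev_xy = bev[:, :2]
        self.wed = (
            cell_wed
            if cell_wed is not None
            else radiological_depth_points(grid.phantom, beam, grid.centers)
        )
        tz = grid.zeta[target]
        self.target_mask = tz >= self.params.target_zeta_threshold
        self.healthy_mask = (
            (grid.density > self.params.tissue_density_threshold) & ~self.target_mask
        )
        self.target_zeta = tz


def marginal_voxel_set(ctx: GAContext, spot: Spot, params: GAParams, mode: str):
    """Qualifying voxel set phi (outside mode: target voxels) or phi'
    (inside mode: healthy-tissue voxels) for one spot.

    Membership: water-equivalent depth within ``dz`` of the spot layer's R90
    and lateral BEV distance within ``R_s = |r*| + dr`` of the spot axis,
    where ``|r*|`` is the distance to the nearest qualifying voxel in the
    slab.  Voxels exactly on the spot axis are excluded (their
    inverse-square weight would be unbounded).

    Returns ``(indices, r_star)``; an empty slab yields ``([], inf)``.
    """
    if mode not in ("outside", "inside"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = ctx.target_mask if mode == "outside" else ctx.healthy_mask
    slab = mask & (np.abs(ctx.wed - spot.layer.r90) <= params.dz + 1e-9)
    idx = np.nonzero(slab)[0]
    if len(idx) == 0:
        return np.empty(0, dtype=np.int64), np.inf
    r = ctx.bev_xy[idx] - spot.bev_position[None, :]
    dist = np.hypot(r[:, 0], r[:, 1])
    on_axis = dist <= 1e-12
    if on_axis.all():
        return np.empty(0, dtype=np.int64), 0.0
    r_star = float(dist[~on_axis].min())  # nearest excludes on-axis voxels
    keep = (~on_axis) & (dist <= r_star + params.dr + 1e-9)
    return idx[keep], r_star


def collimation_vector_outside(r_vectors: np.ndarray) -> np.ndarray:
    """Inverse-square-distance weighted mean of lateral displacement
    vectors; weights normalized to sum to 1."""
    r = np.atleast_2d(np.asarray(r_vectors, dtype=float))
    if len(r) == 0:
        raise ValueError("empty marginal voxel set")
    d2 = np.sum(r**2, axis=1)
    if np.any(d2 <= 0):
        raise ValueError("voxel on the spot axis must be excluded")
    w = (1.0 / d2) / np.sum(1.0 / d2)
    return (w[:, None] * r).sum(axis=0)


def collimation_vector_inside(r_vectors: np.ndarray) -> np.ndarray:
    """Inverse-square-distance weighted mean of *unit* displacement vectors;
    |eta'| <= 1 with equality for a single voxel."""
    r = np.atleast_2d(np.asarray(r_vectors, dtype=float))
    if len(r) == 0:
        raise ValueError("empty marginal voxel set")
    d = np.sqrt(np.sum(r**2, axis=1))
    if np.any(d <= 0):
        raise ValueError("voxel on the spot axis must be excluded")
    w = (1.0 / d**2) / np.sum(1.0 / d**2)
    return (w[:, None] * (r / d[:, None])).sum(axis=0)


def split_primary_secondary(eta: np.ndarray) -> CollimationVector:
    """Split a BEV vector into primary (larger |component|) and secondary
    parts.  On a tie the x axis is primary (the printed rule keeps x when
    ``|eta_y| <= |eta_x|``)."""
    eta = np.asarray(eta, dtype=float).reshape(2)
    if abs(eta[1]) <= abs(eta[0]):
        return CollimationVector(eta=eta, primary_axis="x", eta_p=float(eta[0]), eta_s=float(eta[1]))
    return CollimationVector(eta=eta, primary_axis="y", eta_p=float(eta[1]), eta_s=float(eta[0]))


def _axis_trimmers(axis: str):
    return ("tx1", "tx2") if axis == "x" else ("ty1", "ty2")


def _offset_outside(mag: float, mu: float, f_min: float) -> float:
    return mu - mag if mag < mu else f_min


def init_trimmers_outside(cv: CollimationVector, params: GAParams, spot: Spot) -> TrimmerAssignment:
    """Trimmer offsets for a collimated spot outside the target.

    Per axis the active trimmer is the one the collimation vector points
    *away from* (eta points from the active to the inactive trimmer), with
    offset ``mu - |eta|`` saturating at ``f_min`` when ``|eta| >= mu``.
    When a component is exactly zero the negative-side trimmer (TX1/TY1) is
    taken as active.  Free agents park at ``f'_max``.
    """
    sx, sy = spot.bev_position
    edges = dict(zip(("tx1", "tx2", "ty1", "ty2"),
                     TrimmerSet.parked(spot.bev_position, params.f_max_prime).edges()))
    roles = {t: "free" for t in edges}

    for axis, mag_mu, comp in (
        (cv.primary_axis, params.mu_p, cv.eta_p),
        ("y" if cv.primary_axis == "x" else "x", params.mu_s, cv.eta_s),
    ):
        f = _offset_outside(abs(comp), mag_mu, params.f_min)
        lo, hi = _axis_trimmers(axis)
        center = sx if axis == "x" else sy
        if comp > 0:  # eta points to +axis: active trimmer on the - side
            edges[lo] = center - f
            roles[lo] = "active"
        else:
            if comp == 0:
                edges[lo] = center - f
                roles[lo] = "active"
            else:
                edges[hi] = center + f
                roles[hi] = "active"
    return TrimmerAssignment(
        spot_id=spot.id,
        classification="collimated-outside",
        trimmers=TrimmerSet(edges["tx1"], edges["tx2"], edges["ty1"], edges["ty2"]),
        roles=roles,
        vector=cv,
    )


def _heaviside(x: float) -> float:
    return 1.0 if x >= 0 else 0.0  # H[0] := 1 (the bracket is 0 there anyway)


def secondary_offset_inside(eta_s_mag: float, params: GAParams) -> float:
    """Secondary-axis offset for an in-target spot: relaxes from fully
    parked towards ``f'_min`` as |eta'_s| grows; monotone non-increasing."""
    bracket = 1.0 - (params.c_s * eta_s_mag) ** params.k_s
    return params.f_max_prime * bracket * _heaviside(bracket) + params.f_min_prime


def init_trimmers_inside(cv: CollimationVector, params: GAParams, spot: Spot) -> TrimmerAssignment:
    """Trimmer offsets for a collimated spot inside the target.

    The active trimmer on each axis is the one eta' points *towards* (from
    the inactive to the active trimmer); the primary offset is ``f'_min``
    and the secondary offset follows :func:`secondary_offset_inside`.
    Inactive trimmers park at ``f'_max``.
    """
    sx, sy = spot.bev_position
    edges = dict(zip(("tx1", "tx2", "ty1", "ty2"),
                     TrimmerSet.parked(spot.bev_position, params.f_max_prime).edges()))
    roles = {t: "free" for t in edges}

    for axis, comp, f in (
        (cv.primary_axis, cv.eta_p, params.f_min_prime),
        ("y" if cv.primary_axis == "x" else "x", cv.eta_s,
         secondary_offset_inside(abs(cv.eta_s), params)),
    ):
        lo, hi = _axis_trimmers(axis)
        center = sx if axis == "x" else sy
        if comp > 0:  # eta' points to +axis: active trimmer on the + side
            edges[hi] = center + f
            roles[hi] = "active"
        else:  # comp <= 0: negative-side trimmer active (TX1/TY1 convention)
            edges[lo] = center - f
            roles[lo] = "active"
    return TrimmerAssignment(
        spot_id=spot.id,
        classification="collimated-inside",
        trimmers=TrimmerSet(edges["tx1"], edges["tx2"], edges["ty1"], edges["ty2"]),
        roles=roles,
        vector=cv,
    )


def classify_spot(ctx: GAContext, spot: Spot, params: GAParams | None = None):
    """Classify a spot as inside/outside the target periphery and as
    collimated or uncollimated.

    The spot is *inside* when the target occupancy of the laterally nearest
    slab cell at its axis exceeds the membership threshold.  Inside spots
    whose nearest healthy voxel is at least ``mu'_max`` away are
    uncollimated; outside spots with an empty marginal target set are
    uncollimated.
    """
    params = params or ctx.params
    slab = np.abs(ctx.wed - spot.layer.r90) <= max(params.dz, 1.0) + 1e-9
    idx = np.nonzero(slab)[0]
    if len(idx) == 0:
        return "uncollimated", "outside"
    r = ctx.bev_xy[idx] - spot.bev_position[None, :]
    nearest = idx[np.argmin(np.hypot(r[:, 0], r[:, 1]))]
    inside = ctx.target_zeta[nearest] > params.target_zeta_threshold
    if inside:
        _, r_star = marginal_voxel_set(ctx, spot, params, "inside")
        if r_star >= params.mu_max_prime:
            return "uncollimated", "inside"
        return "collimated", "inside"
    phi, _ = marginal_voxel_set(ctx, spot, params, "outside")
    if len(phi) == 0:
        return "uncollimated", "outside"
    return "collimated", "outside"


def assign_trimmers(ctx: GAContext, spot: Spot, params: GAParams | None = None) -> TrimmerAssignment:
    """Run the full GA pipeline for one spot: classify, build the
    collimation vector and set the four trimmer edges."""
    params = params or ctx.params
    status, side = classify_spot(ctx, spot, params)
    if status == "uncollimated":
        return TrimmerAssignment(
            spot_id=spot.id,
            classification="uncollimated",
            trimmers=TrimmerSet.parked(spot.bev_position, params.f_max_prime),
            roles={t: "parked" for t in ("tx1", "tx2", "ty1", "ty2")},
        )
    mode = "outside" if side == "outside" else "inside"
    idx, _ = marginal_voxel_set(ctx, spot, params, mode)
    r = ctx.bev_xy[idx] - spot.bev_position[None, :]
    if mode == "outside":
        cv = split_primary_secondary(collimation_vector_outside(r))
        return init_trimmers_outside(cv, params, spot)
    cv = split_primary_secondary(collimation_vector_inside(r))
    return init_trimmers_inside(cv, params, spot)
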