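"""Analytic pencil-beam engine: depth dose, trimmed lateral fluence,
energy-layer selection and hexagonal spot placement.

The dose model is an analytic stand-in for a dedicated trimming beamlet
dose algorithm: a parameterized Bragg depth-dose curve (entrance plateau,
Gaussian proximal shoulder, Gaussian distal falloff) multiplied by a 2D
Gaussian lateral fluence whose sigma grows with depth.  Per-spot trimming
is applied as error-function edge truncation at each active trimmer edge
with a depth-scaled penumbra blur.  Only R80/R90 fidelity and the
open-vs-trimmed lateral contrast matter to the planning logic built on top.

Ranges follow a Bragg-Kleeman power law ``R = alpha * E**p`` (alpha in
cm / MeV^p, default 0.0022, p = 1.77), giving clinically plausible ranges
for 70-160 MeV protons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.spatial import cKDTree
from scipy.special import erf

__all__ = [
    "MachineModel",
    "EnergyLayer",
    "Spot",
    "TrimmerSet",
    "range_energy_model",
    "compute_beamlet_dose",
    "select_energy_layers",
    "place_spots",
    "influence_matrix",
]

# Distal falloff geometry of a Gaussian tail with peak value 1:
_K80 = float(np.sqrt(2.0 * np.log(1.0 / 0.8)))  # (z80 - z_peak) / sigma_d
_K90 = float(np.sqrt(2.0 * np.log(1.0 / 0.9)))
_K10 = float(np.sqrt(2.0 * np.log(10.0)))


@dataclass
class MachineModel:
    """Machine and beam-model parameters (all lengths mm, energies MeV)."""

    alpha: float = 0.0022      # Bragg-Kleeman coefficient, cm / MeV**p
    p: float = 1.77            # Bragg-Kleeman exponent
    e_min: float = 70.0
    e_max: float = 160.0
    sigma_air_lo: float = 6.5  # in-air 1-sigma spot size at e_min (mm)
    sigma_air_hi: float = 3.0  # ... at e_max
    k_sigma: float = 0.03      # lateral sigma growth: sigma^2 = sa^2 + (k z)^2
    sigma_t: float = 1.0       # trimmer penumbra blur at zero depth (mm)
    k_sigma_t: float = 0.02    # depth growth of the trimmer blur
    peak_width_0: float = 1.0  # distal sigma_d = w0 + cw * r80
    peak_width_slope: float = 0.025
    proximal_factor: float = 2.5   # sigma_p / sigma_d
    entrance: float = 0.3          # entrance plateau relative to peak
    dose_per_mu: float = 0.05      # Gy/MU at the untrimmed beamlet peak
    sparsity_rel: float = 1e-5     # drop influence entries below this * colmax
    park_distance: float = 25.0    # trimmer offset beyond which it is inactive

    def sigma_air(self, energy: float) -> float:
        """In-air 1-sigma spot size at isocenter, linear in energy."""
        f = np.clip((energy - self.e_min) / (self.e_max - self.e_min), 0.0, 1.0)
        return float(self.sigma_air_lo + f * (self.sigma_air_hi - self.sigma_air_lo))


@dataclass(frozen=True)
class EnergyLayer:
    """One beam energy with its depth-dose geometry (mm water)."""

    energy: float
    r80: float
    r90: float
    z_peak: float
    sigma_d: float
    sigma_air: float

    def __post_init__(self):
        if not (self.r90 < self.r80):
            raise ValueError("expected r90 < r80")
        if self.sigma_air <= 0:
            raise ValueError("sigma_air must be positive")


@dataclass
class Spot:
    """A scanned pencil beam: energy layer, BEV position and weight (MU)."""

    id: int
    layer: EnergyLayer
    bev_position: np.ndarray  # (x_bev, y_bev) mm at the isocenter plane
    weight: float = 0.0

    def __post_init__(self):
        self.bev_position = np.asarray(self.bev_position, dtype=float).reshape(2)
        if not np.all(np.isfinite(self.bev_position)):
            raise ValueError("spot position must be finite")
        if self.weight < 0:
            raise ValueError("spot weight must be non-negative")


@dataclass(frozen=True)
class TrimmerSet:
    """Absolute BEV edge positions (mm, isocenter plane) of the 4 trimmers.

    TX1 blocks ``x < tx1``; TX2 blocks ``x > tx2``; TY1/TY2 likewise in y.
    TX1 sits at a more negative position than TX2 (non-crossing invariant).
    An edge at ``park_distance`` or more from the spot axis is parked, i.e.
    dosimetrically inactive.
    """

    tx1: float
    tx2: float
    ty1: float
    ty2: float

    def __post_init__(self):
        if self.tx1 > self.tx2 or self.ty1 > self.ty2:
            raise ValueError("crossing trimmer edges")

    @classmethod
    def parked(cls, spot_xy, park_distance: float = 25.0) -> "TrimmerSet":
        x, y = float(spot_xy[0]), float(spot_xy[1])
        f = float(park_distance)
        return cls(x - f, x + f, y - f, y + f)

    def edges(self) -> np.ndarray:
        return np.array([self.tx1, self.tx2, self.ty1, self.ty2])

    def offsets_from(self, spot_xy) -> np.ndarray:
        """Unsigned offsets |edge - spot axis| per trimmer (TX1,TX2,TY1,TY2)."""
        x, y = float(spot_xy[0]), float(spot_xy[1])
        return np.abs(self.edges() - np.array([x, x, y, y]))

    def active_mask(self, spot_xy, park_distance: float = 25.0) -> np.ndarray:
        return self.offsets_from(spot_xy) < park_distance - 1e-9

    def translated(self, delta_xy) -> "TrimmerSet":
        """Rigidly shift all four edges with the spot (relative offsets
        preserved)."""
        dx, dy = float(delta_xy[0]), float(delta_xy[1])
        return TrimmerSet(self.tx1 + dx, self.tx2 + dx, self.ty1 + dy, self.ty2 + dy)


# ---------------------------------------------------------------------------
# Range-energy model and layer construction


def range_energy_model(energy: float, machine: MachineModel | None = None):
    """Return ``(range, r80, r90)`` in mm water for a beam energy.

    ``r80`` is identified with the Bragg-Kleeman range; ``r90`` and the
    distal-10% ``range`` follow from the layer's Gaussian distal falloff
    width.  Monotone increasing in energy; energies outside the machine
    limits are rejected.
    """
    machine = machine or MachineModel()
    if not (machine.e_min <= energy <= machine.e_max):
        raise ValueError(
            f"energy {energy:.1f} MeV outside machine range "
            f"[{machine.e_min}, {machine.e_max}]"
        )
    r80 = 10.0 * machine.alpha * energy**machine.p
    sigma_d = machine.peak_width_0 + machine.peak_width_slope * r80
    z_peak = r80 - _K80 * sigma_d
    r90 = z_peak + _K90 * sigma_d
    rng = z_peak + _K10 * sigma_d
    return rng, r80, r90


def energy_from_r80(r80: float, machine: MachineModel) -> float:
    return float((r80 / (10.0 * machine.alpha)) ** (1.0 / machine.p))


def make_layer(energy: float, machine: MachineModel) -> EnergyLayer:
    _, r80, r90 = range_energy_model(energy, machine)
    sigma_d = machine.peak_width_0 + machine.peak_width_slope * r80
    return EnergyLayer(
        energy=float(energy),
        r80=r80,
        r90=r90,
        z_peak=r80 - _K80 * sigma_d,
        sigma_d=sigma_d,
        sigma_air=machine.sigma_air(energy),
    )


def peak_width_80(layer: EnergyLayer, machine: MachineModel) -> float:
    """80%-80% width of the Bragg peak (proximal shoulder to distal falloff)."""
    c0 = machine.entrance
    sigma_p = machine.proximal_factor * layer.sigma_d
    k_prox = np.sqrt(2.0 * np.log((1.0 - c0) / (0.8 - c0)))
    return float(k_prox * sigma_p + _K80 * layer.sigma_d)


def select_energy_layers(
    target_wed_min: float,
    target_wed_max: float,
    machine: MachineModel | None = None,
    distal_margin: float = 10.0,
) -> list:
    """Choose the beam's energy layers for a target depth interval.

    The deepest layer's R80 sits at the maximum target water-equivalent
    depth plus ``distal_margin``.  Marching proximally, consecutive Bragg
    peaks are spaced by 70% of the deeper layer's 80%-80% peak width, until
    the proximal target edge is covered.  Layers are returned deepest
    (highest energy) first, strictly decreasing.
    """
    machine = machine or MachineModel()
    if target_wed_max < target_wed_min:
        raise ValueError("invalid target depth interval")
    r80 = target_wed_max + distal_margin
    e = energy_from_r80(r80, machine)
    if e > machine.e_max:
        raise ValueError(
            f"target depth {target_wed_max:.1f} mm needs {e:.1f} MeV, beyond the "
            f"machine maximum {machine.e_max} MeV"
        )
    layers = [make_layer(max(e, machine.e_min), machine)]
    while layers[-1].z_peak > target_wed_min and layers[-1].energy > machine.e_min:
        prev = layers[-1]
        z_next = prev.z_peak - 0.70 * peak_width_80(prev, machine)
        # fixed point: r80 = z_next + K80 * sigma_d(r80); sigma_d affine in r80
        r80_next = prev.r80
        for _ in range(8):
            sigma_d = machine.peak_width_0 + machine.peak_width_slope * r80_next
            r80_next = z_next + _K80 * sigma_d
        e_next = energy_from_r80(r80_next, machine)
        if e_next < machine.e_min:
            break
        layers.append(make_layer(e_next, machine))
    return layers


# ---------------------------------------------------------------------------
# Dose model


def depth_dose(z, layer: EnergyLayer, machine: MachineModel) -> np.ndarray:
    """Relative depth-dose (peak = 1) at water-equivalent depths ``z`` (mm).

    Proximal of the peak: entrance plateau plus a broad Gaussian shoulder;
    distal: Gaussian falloff whose 80%/90% crossings sit at the layer's
    ``r80``/``r90`` by construction.
    """
    z = np.asarray(z, dtype=float)
    c0 = machine.entrance
    sigma_p = machine.proximal_factor * layer.sigma_d
    prox = c0 + (1.0 - c0) * np.exp(-0.5 * ((z - layer.z_peak) / sigma_p) ** 2)
    dist = np.exp(-0.5 * ((z - layer.z_peak) / layer.sigma_d) ** 2)
    out = np.where(z <= layer.z_peak, prox, dist)
    return np.where(z < 0, 0.0, out)


def lateral_sigma(z, layer: EnergyLayer, machine: MachineModel) -> np.ndarray:
    """In-patient lateral 1-sigma at depth ``z``: scatter growth on top of
    the in-air spot size."""
    z = np.asarray(z, dtype=float)
    return np.sqrt(layer.sigma_air**2 + (machine.k_sigma * np.clip(z, 0.0, None)) ** 2)


def _edge_transmission(u: np.ndarray) -> np.ndarray:
    """Blurred step: 0 deep under the trimmer, 1 in the open field, 0.5 at
    the edge (``u`` = signed distance from the edge in blur-sigma units)."""
    return 0.5 * (1.0 + erf(u / np.sqrt(2.0)))


def compute_beamlet_dose(
    spot: Spot,
    trimmers: TrimmerSet | None,
    bev_xy: np.ndarray,
    wed: np.ndarray,
    machine: MachineModel | None = None,
) -> np.ndarray:
    """Dose per MU at sample points for one (possibly trimmed) pencil beam.

    Parameters
    ----------
    spot : Spot
    trimmers : TrimmerSet or None
        ``None`` means untrimmed (all parked).
    bev_xy : (n, 2) ndarray
        Lateral BEV coordinates of the sample points (isocenter plane, mm).
    wed : (n,) ndarray
        Water-equivalent depths of the sample points (mm).

    Point-sampled analytic model (voxel averaging is the caller's concern);
    non-negative everywhere; parked trimmers reproduce the untrimmed beamlet
    exactly; moving any edge towards or through the spot axis can only
    decrease dose.
    """
    machine = machine or MachineModel()
    bev_xy = np.atleast_2d(np.asarray(bev_xy, dtype=float))
    wed = np.asarray(wed, dtype=float)
    layer = spot.layer
    sigma = lateral_sigma(wed, layer, machine)
    dx = bev_xy[:, 0] - spot.bev_position[0]
    dy = bev_xy[:, 1] - spot.bev_position[1]
    fluence = np.exp(-0.5 * (dx**2 + dy**2) / sigma**2)
    dose = machine.dose_per_mu * depth_dose(wed, layer, machine) * fluence
    if trimmers is not None:
        active = trimmers.active_mask(spot.bev_position, machine.park_distance)
        sig_t = np.sqrt(
            machine.sigma_t**2 + (machine.k_sigma_t * np.clip(wed, 0.0, None)) ** 2
        )
        x = bev_xy[:, 0]
        y = bev_xy[:, 1]
        if active[0]:
            dose = dose * _edge_transmission((x - trimmers.tx1) / sig_t)
        if active[1]:
            dose = dose * _edge_transmission((trimmers.tx2 - x) / sig_t)
        if active[2]:
            dose = dose * _edge_transmission((y - trimmers.ty1) / sig_t)
        if active[3]:
            dose = dose * _edge_transmission((trimmers.ty2 - y) / sig_t)
    return dose


# ---------------------------------------------------------------------------
# Spot placement


def _hex_lattice(xmin, xmax, ymin, ymax, pitch: float) -> np.ndarray:
    """Hexagonal lattice with the given pitch covering a bounding box,
    anchored at the origin for determinism."""
    row_h = pitch * np.sqrt(3.0) / 2.0
    rows = np.arange(np.floor(ymin / row_h) - 1, np.ceil(ymax / row_h) + 2).astype(int)
    pts = []
    for r in rows:
        y = r * row_h
        off = 0.0 if r % 2 == 0 else pitch / 2.0
        cols = np.arange(
            np.floor((xmin - off) / pitch) - 1, np.ceil((xmax - off) / pitch) + 2
        )
        xs = cols * pitch + off
        pts.append(np.stack([xs, np.full_like(xs, y)], axis=1))
    return np.vstack(pts)


def place_spots(
    target_bev_xy: np.ndarray,
    target_wed: np.ndarray,
    layers: list,
    machine: MachineModel | None = None,
    lateral_margin: float = 10.0,
    start_id: int = 0,
) -> list:
    """Place spots per energy layer on a hexagonal grid.

    For each layer, the target voxels whose water-equivalent depth falls in
    the layer's depth slab (half-way to the neighbouring layers' Bragg
    peaks, with a ``lateral_margin`` allowance at the ends) are projected to
    BEV; lattice points within ``lateral_margin`` of any projected target
    point are kept.  The lattice pitch is the layer's in-air sigma.
    """
    machine = machine or MachineModel()
    target_bev_xy = np.asarray(target_bev_xy, dtype=float)
    target_wed = np.asarray(target_wed, dtype=float)
    if len(target_bev_xy) == 0:
        raise ValueError("empty target: no spots to place")

    peaks = np.array([l.z_peak for l in layers])
    spots = []
    sid = start_id
    for li, layer in enumerate(layers):
        lo_gap = peaks[li - 1] - peaks[li] if li > 0 else 2 * lateral_margin
        hi_gap = peaks[li] - peaks[li + 1] if li < len(layers) - 1 else 2 * lateral_margin
        in_slab = (target_wed <= peaks[li] + lo_gap / 2.0 + 1e-9) & (
            target_wed >= peaks[li] - hi_gap / 2.0 - 1e-9
        )
        if not in_slab.any():
            # peak beyond the target (distal-margin layers): cover the
            # target band nearest to the peak instead
            wed_star = target_wed[np.argmin(np.abs(target_wed - peaks[li]))]
            half = max(lo_gap, hi_gap) / 2.0
            in_slab = np.abs(target_wed - wed_star) <= half + 1e-9
        if not in_slab.any():
            continue
        proj = target_bev_xy[in_slab]
        pitch = layer.sigma_air
        lat = _hex_lattice(
            proj[:, 0].min() - lateral_margin - pitch,
            proj[:, 0].max() + lateral_margin + pitch,
            proj[:, 1].min() - lateral_margin - pitch,
            proj[:, 1].max() + lateral_margin + pitch,
            pitch,
        )
        tree = cKDTree(proj)
        d, _ = tree.query(lat, k=1)
        for xy in lat[d <= lateral_margin]:
            spots.append(Spot(id=sid, layer=layer, bev_position=xy))
            sid += 1
    if not spots:
        raise ValueError("no layer reaches the target")
    return spots


# ---------------------------------------------------------------------------
# Influence matrix


def influence_matrix(
    spots: list,
    trimmer_sets: dict,
    cell_bev: np.ndarray,
    cell_wed: np.ndarray,
    machine: MachineModel | None = None,
    lateral_cutoff: float | None = None,
) -> csc_matrix:
    """Sparse dose-influence matrix ``d[i, j]``: Gy per MU from spot ``j``
    to dose-grid cell ``i``.

    ``trimmer_sets`` maps spot id -> TrimmerSet (missing ids = untrimmed).
    Entries below ``sparsity_rel`` times the column max are dropped; a
    trimmed column is elementwise <= the untrimmed column by construction.
    """
    machine = machine or MachineModel()
    n_cells = len(cell_wed)
    data, rows, cols = [], [], []
    for k, spot in enumerate(spots):
        cutoff = lateral_cutoff or (4.0 * lateral_sigma(
            spot.layer.r80, spot.layer, machine
        ) + machine.park_distance / 2.0)
        lat2 = np.sum((cell_bev - spot.bev_position[None, :]) ** 2, axis=1)
        cand = (lat2 <= cutoff**2) & (cell_wed <= spot.layer.r80 + 5 * spot.layer.sigma_d)
        idx = np.nonzero(cand)[0]
        if len(idx) == 0:
            continue
        col = compute_beamlet_dose(
            spot, trimmer_sets.get(spot.id), cell_bev[idx], cell_wed[idx], machine
        )
        keep = col > machine.sparsity_rel * (col.max() if col.size else 0.0)
        data.append(col[keep])
        rows.append(idx[keep])
        cols.append(np.full(keep.sum(), k, dtype=np.int64))
    if data:
        data = np.concatenate(data)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    return csc_matrix((data, (rows, cols)), shape=(n_cells, len(spots)))
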