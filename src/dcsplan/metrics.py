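"""Plan-quality metrics: DVH curves, conformity/gradient indices and 3D
gamma analysis.

DVH statistics are occupancy-weighted by default (each cell contributes
``zeta * volume``); a binary-mask option thresholds occupancy at 0.5.
Isodose volumes for the Paddick conformity index and the dose gradient
index are plan-level quantities counted over whole cells at their centers.
Gamma analysis uses global normalization to the reference maximum, a
low-dose exclusion threshold, and an exhaustive shifted search on a
trilinearly upsampled evaluation grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DVHCurve",
    "dvh",
    "dvh_metrics",
    "paddick_ci",
    "dgi",
    "gamma_analysis",
    "gamma_pass_rate",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    dose_bins: np.ndarray      # bin edges / evaluation doses (Gy)
    volume_fraction: np.ndarray  # fraction of structure volume receiving >= dose

    def d_at_volume(self, fraction: float) -> float:
        """Dose received by at least ``fraction`` of the volume (e.g. D95)."""
        # volume_fraction is non-increasing in dose
        idx = np.nonzero(self.volume_fraction >= fraction)[0]
        return float(self.dose_bins[idx[-1]]) if len(idx) else 0.0

    def mean_dose(self) -> float:
        """Integral of the cumulative DVH equals the mean dose."""
        return float(np.trapezoid(self.volume_fraction, self.dose_bins))


def _structure_weights(zeta: np.ndarray, volumes: np.ndarray, binary_mask: bool) -> np.ndarray:
    if binary_mask:
        return (zeta >= 0.5).astype(float) * volumes
    return zeta * volumes


def dvh(
    dose: np.ndarray,
    zeta: np.ndarray,
    volumes: np.ndarray,
    structure: str = "",
    n_bins: int = 512,
    binary_mask: bool = False,
) -> DVHCurve:
    """Cumulative DVH of a structure on the (possibly variable) dose grid."""
    w = _structure_weights(zeta, volumes, binary_mask)
    sel = w > 0
    if not sel.any():
        raise ValueError("structure has no volume")
    d = dose[sel]
    v = w[sel]
    top = max(float(d.max()) * 1.05, 1e-12)
    edges = np.linspace(0.0, top, n_bins)
    frac = np.array([v[d >= e].sum() for e in edges]) / v.sum()
    return DVHCurve(structure=structure, dose_bins=edges, volume_fraction=frac)


def dvh_metrics(
    dose: np.ndarray,
    zeta: np.ndarray,
    volumes: np.ndarray,
    binary_mask: bool = False,
) -> dict:
    """D_mean, D_max and D_2cc of a structure.

    D_2cc is the minimum dose among the hottest 2 cm^3 of structure volume,
    interpolated at the 2 cm^3 boundary.  Structures smaller than 2 cm^3
    report D_max with ``d2cc_undefined`` flagged.
    """
    w = _structure_weights(zeta, volumes, binary_mask)
    sel = w > 0
    if not sel.any():
        raise ValueError("structure has no volume")
    d = dose[sel]
    v = w[sel]
    d_mean = float(np.sum(d * v) / v.sum())
    d_max = float(d.max())
    out = {"d_mean": d_mean, "d_max": d_max, "d2cc_undefined": False}
    if v.sum() < 2000.0:
        out["d_2cc"] = d_max
        out["d2cc_undefined"] = True
        return out
    order = np.argsort(d)[::-1]
    cum = np.cumsum(v[order])
    ds = d[order]
    i = int(np.searchsorted(cum, 2000.0))
    i = min(i, len(ds) - 1)
    if i == 0:
        out["d_2cc"] = float(ds[0])
    else:
        # interpolate the dose at the exact 2 cm^3 boundary
        f = (2000.0 - cum[i - 1]) / (cum[i] - cum[i - 1])
        out["d_2cc"] = float(ds[i - 1] + f * (ds[i] - ds[i - 1]))
    return out


def paddick_ci(
    dose: np.ndarray,
    target_zeta: np.ndarray,
    volumes: np.ndarray,
    prescription: float,
) -> float:
    """Paddick conformity index ``TV_PIV^2 / (TV * PIV)``.

    TV is the occupancy-weighted target volume, PIV the prescription
    isodose volume (whole cells at their centers), TV_PIV their
    intersection.  Raises when the prescription isodose is empty.
    """
    piv_mask = dose >= prescription
    tv = float(np.sum(target_zeta * volumes))
    piv = float(np.sum(volumes[piv_mask]))
    if piv <= 0:
        raise ValueError("prescription isodose volume is empty")
    tv_piv = float(np.sum((target_zeta * volumes)[piv_mask]))
    return tv_piv**2 / (tv * piv)


def dgi(dose: np.ndarray, volumes: np.ndarray, prescription: float) -> float:
    """Dose gradient index: ratio of the 50% to 100% prescription isodose
    volumes (smaller = sharper falloff)."""
    v100 = float(np.sum(volumes[dose >= prescription]))
    if v100 <= 0:
        raise ValueError("prescription isodose volume is empty")
    v50 = float(np.sum(volumes[dose >= 0.5 * prescription]))
    return v50 / v100


# ---------------------------------------------------------------------------
# Gamma analysis


def gamma_analysis(
    ref_dose: np.ndarray,
    eval_dose: np.ndarray,
    spacing,
    dose_crit_pct: float = 3.0,
    dist_crit_mm: float = 3.0,
    threshold_pct: float = 10.0,
    subsample: int = 3,
    search_factor: float = 2.0,
) -> np.ndarray:
    """3D gamma index of an evaluated dose against a reference.

    Global normalization to the reference maximum; points below
    ``threshold_pct`` of that maximum are excluded (NaN in the returned
    map).  The distance search runs exhaustively over a trilinearly
    upsampled evaluation grid (``subsample`` points per voxel per axis)
    within ``search_factor * dist_crit_mm``.
    """
    from scipy.ndimage import map_coordinates

    ref = np.asarray(ref_dose, dtype=float)
    ev = np.asarray(eval_dose, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("dose grids must have the same shape")
    spacing = np.asarray([spacing] * 3 if np.isscalar(spacing) else spacing, dtype=float)
    ref_max = ref.max()
    if ref_max <= 0:
        raise ValueError("reference dose maximum is zero")
    dd = dose_crit_pct / 100.0 * ref_max
    mask = ref >= threshold_pct / 100.0 * ref_max

    pts = np.argwhere(mask).astype(float)  # index coords of evaluated points
    ref_vals = ref[mask]
    radius = search_factor * dist_crit_mm

    # integer shift lattice in sub-voxel units
    steps = [spacing[a] / subsample for a in range(3)]
    ranges = [np.arange(-int(radius // s), int(radius // s) + 1) for s in steps]
    gamma2 = np.full(len(pts), np.inf)
    sx, sy, sz = np.meshgrid(*ranges, indexing="ij")
    shifts = np.stack([sx.ravel(), sy.ravel(), sz.ravel()], axis=1)
    dist2 = np.sum((shifts * np.asarray(steps)[None, :]) ** 2, axis=1)
    keep = dist2 <= radius**2
    shifts, dist2 = shifts[keep], dist2[keep]
    order = np.argsort(dist2)
    shifts, dist2 = shifts[order], dist2[order]

    for shift, d2 in zip(shifts, dist2):
        dist_term = d2 / dist_crit_mm**2
        if dist_term >= gamma2.max():
            continue
        coords = pts + shift[None, :] / subsample
        vals = map_coordinates(ev, coords.T, order=1, mode="nearest")
        g2 = (vals - ref_vals) ** 2 / dd**2 + dist_term
        np.minimum(gamma2, g2, out=gamma2)

    out = np.full(ref.shape, np.nan)
    out[mask] = np.sqrt(gamma2)
    return out


def gamma_pass_rate(gamma_map: np.ndarray) -> float:
    """Percent of evaluated (non-NaN) points with gamma <= 1."""
    vals = gamma_map[np.isfinite(gamma_map)]
    if len(vals) == 0:
        raise ValueError("no points above the dose threshold")
    return float(100.0 * np.mean(vals <= 1.0))
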