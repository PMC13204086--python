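"""Spot-weight and spot-position optimization.

Weights minimize a partial-voxel one-sided least-squares objective

    O^2 = sum_tissues (1/Z) [ sum_over  zeta B_p (d - d_p)^2
                            + sum_under zeta B_n (d_n - d)^2 ]

over non-negative monitor units, where only violating voxels contribute and
``Z`` is the tissue's occupancy-weighted voxel count.  The solver is a
projected-gradient scheme with a Lipschitz step and step-halving safeguard,
so the objective is non-increasing across accepted iterates by
construction.

Spot positions are refined by a modified gradient descent (MGD): a small 2D
candidate grid of the per-spot tissue-dose objective ``F_j`` is evaluated
around the current position, and the spot moves a fixed distance
``|r*| * gamma`` along the negative normalized gradient, where ``|r*|`` is
the distance to the nearest target voxel at the spot's R90 depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix

__all__ = [
    "TissueObjective",
    "MGDParams",
    "objective_value",
    "objective_gradient_dose",
    "optimize_weights",
    "WeightResult",
    "mgd_objective",
    "mgd_step",
    "apply_mu_threshold",
    "check_plan_constraints",
]


@dataclass
class TissueObjective:
    """Dose objective for one tissue.

    ``d_p``/``d_n`` are the per-voxel overdose/underdose bounds (Gy;
    ``None`` disables the corresponding penalty); ``b_p``/``b_n`` the
    penalty factors.
    """

    structure: str
    d_p: float | None = None
    d_n: float | None = None
    b_p: float = 1.0
    b_n: float = 1.0

    def __post_init__(self):
        if self.b_p < 0 or self.b_n < 0:
            raise ValueError("penalty factors must be non-negative")
        if self.d_p is not None and self.d_n is not None and self.d_n > self.d_p:
            raise ValueError("underdose bound exceeds overdose bound")


@dataclass
class MGDParams:
    """MGD tuning: per-tissue weights ``beta``, step factor ``gamma``, the
    candidate-grid geometry and the outer iteration budget."""

    beta: dict = field(default_factory=dict)
    gamma: float = 0.3
    grid_extent: float = 2.0   # half-width of the candidate grid (mm)
    grid_points: int = 5       # points per axis (>= 3 for central differences)
    max_iters: int = 10
    grad_tol: float = 1e-12
    min_step: float = 0.2      # skip spots whose |r*|*gamma is below this (mm)

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.grid_points < 3:
            raise ValueError("candidate grid needs >= 3 points per axis")


def _tissue_weights(grid, name: str) -> np.ndarray:
    """Occupancy in fine-voxel-count units (invariant under coarsening)."""
    return grid.count_weight(name)


def objective_value(dose: np.ndarray, grid, objectives: list) -> float:
    """Evaluate the one-sided quadratic objective O^2 on a dose vector."""
    total = 0.0
    for obj in objectives:
        w = _tissue_weights(grid, obj.structure)
        z = w.sum()
        if z <= 0:
            raise ValueError(f"structure {obj.structure!r} has zero occupancy")
        term = 0.0
        if obj.d_p is not None:
            over = np.clip(dose - obj.d_p, 0.0, None)
            term += obj.b_p * float(np.sum(w * over**2))
        if obj.d_n is not None:
            under = np.clip(obj.d_n - dose, 0.0, None)
            term += obj.b_n * float(np.sum(w * under**2))
        total += term / z
    return total


def objective_gradient_dose(dose: np.ndarray, grid, objectives: list) -> np.ndarray:
    """d O^2 / d dose_i (per-voxel)."""
    g = np.zeros_like(dose)
    for obj in objectives:
        w = _tissue_weights(grid, obj.structure)
        z = w.sum()
        if obj.d_p is not None:
            g += (2.0 * obj.b_p / z) * w * np.clip(dose - obj.d_p, 0.0, None)
        if obj.d_n is not None:
            g -= (2.0 * obj.b_n / z) * w * np.clip(obj.d_n - dose, 0.0, None)
    return g


@dataclass
class WeightResult:
    weights: np.ndarray
    objective_trace: list
    converged: bool


def optimize_weights(
    influence: csc_matrix,
    grid,
    objectives: list,
    init_weights: np.ndarray | None = None,
    max_iters: int = 400,
    tol: float = 1e-7,
) -> WeightResult:
    """Minimize O^2 over non-negative spot weights.

    Projected gradient with a Lipschitz-estimate step (power iteration on
    the weighted normal matrix) and step-halving on any objective increase;
    terminates on relative objective change below ``tol``.  Raises when the
    influence matrix is all-zero.
    """
    a = influence.tocsc()
    n = a.shape[1]
    if a.nnz == 0:
        raise ValueError("all-zero influence matrix")
    col_max = np.asarray(np.abs(a).max(axis=0).todense()).ravel()
    if np.any(col_max == 0):
        raise ValueError("influence has an all-zero column (spot with no dose)")

    # curvature upper bound: c_i = sum_tissues 2 * w_i * max(Bp, Bn) / Z
    c = np.zeros(a.shape[0])
    for obj in objectives:
        w = _tissue_weights(grid, obj.structure)
        c += 2.0 * max(obj.b_p, obj.b_n) * w / w.sum()
    v = np.ones(n) / np.sqrt(n)
    lam = 1.0
    for _ in range(30):
        u = a.T @ (c * (a @ v))
        lam = float(np.linalg.norm(u))
        if lam == 0:
            break
        v = u / lam
    step0 = 1.0 / max(lam, 1e-30)

    if init_weights is None:
        # scale a flat start so mean target dose is near its bound
        w0 = np.ones(n)
        d = a @ w0
        ref = next((o for o in objectives if o.d_n is not None or o.d_p is not None), None)
        if ref is not None:
            bound = ref.d_n if ref.d_n is not None else ref.d_p
            tw = _tissue_weights(grid, ref.structure)
            mean_d = float(np.sum(tw * d) / tw.sum())
            if mean_d > 0:
                w0 *= bound / mean_d
        weights = w0
    else:
        weights = np.clip(np.asarray(init_weights, dtype=float), 0.0, None)

    dose = a @ weights
    obj_val = objective_value(dose, grid, objectives)
    trace = [obj_val]
    converged = False
    for _ in range(max_iters):
        g = a.T @ objective_gradient_dose(dose, grid, objectives)
        step = step0
        for _ in range(40):  # step halving on increase: monotone by construction
            cand = np.clip(weights - step * g, 0.0, None)
            cand_dose = a @ cand
            cand_obj = objective_value(cand_dose, grid, objectives)
            if cand_obj <= obj_val + 1e-15:
                break
            step *= 0.5
        if cand_obj > obj_val:
            converged = True
            break
        rel = (obj_val - cand_obj) / max(obj_val, 1e-30)
        weights, dose, obj_val = cand, cand_dose, cand_obj
        trace.append(obj_val)
        if rel < tol:
            converged = True
            break
    return WeightResult(weights=weights, objective_trace=trace, converged=converged)


# ---------------------------------------------------------------------------
# Modified gradient descent (spot repositioning)


def mgd_objective(dose_column: np.ndarray, grid, beta: dict) -> float:
    """Per-spot tissue-dose objective F_j = sum_t beta_t / Z_t * D_t.

    ``D_t`` is the integral (unit-weight) dose of the spot's column over the
    voxels containing tissue ``t``; counts are in fine-voxel units so fine
    and coarse cells contribute consistently.
    """
    f = 0.0
    for name, b in beta.items():
        if b == 0.0:
            continue
        w = grid.count_weight(name)
        member = w > 0
        z = w.sum()
        if z <= 0:
            raise ValueError(f"structure {name!r} has zero occupancy")
        f += b / z * float(np.sum(dose_column[member] * (grid.volumes[member] / grid.fine_voxel_volume)))
    return f


def mgd_step(
    position: np.ndarray,
    evaluate_f,
    r_star: float,
    params: MGDParams,
):
    """One MGD update of a spot's BEV position.

    ``evaluate_f(xy)`` returns F for the spot placed at BEV position
    ``xy``.  F is sampled on a ``grid_points**2`` candidate grid of
    half-width ``grid_extent`` centred on the current position; the spatial
    gradient is the central difference at the centre and the update moves
    exactly ``|r*| * gamma`` along the negative normalized gradient.
    Returns ``(new_position, converged)`` with ``converged=True`` (no move)
    when the gradient vanishes.
    """
    position = np.asarray(position, dtype=float).reshape(2)
    npts = params.grid_points
    h = 2.0 * params.grid_extent / (npts - 1)
    offs = np.linspace(-params.grid_extent, params.grid_extent, npts)
    mid = npts // 2
    fx_p = evaluate_f(position + np.array([offs[mid + 1], 0.0]))
    fx_m = evaluate_f(position + np.array([offs[mid - 1], 0.0]))
    fy_p = evaluate_f(position + np.array([0.0, offs[mid + 1]]))
    fy_m = evaluate_f(position + np.array([0.0, offs[mid - 1]]))
    grad = np.array([(fx_p - fx_m) / (2.0 * h), (fy_p - fy_m) / (2.0 * h)])
    norm = float(np.linalg.norm(grad))
    if norm <= params.grad_tol or not np.isfinite(norm):
        return position, True
    step = r_star * params.gamma
    return position - step * grad / norm, False


def sample_f_grid(position: np.ndarray, evaluate_f, params: MGDParams) -> np.ndarray:
    """Full candidate-grid sampling of F (diagnostics / visualization)."""
    offs = np.linspace(-params.grid_extent, params.grid_extent, params.grid_points)
    return np.array(
        [[evaluate_f(np.asarray(position) + np.array([ox, oy])) for oy in offs] for ox in offs]
    )


# ---------------------------------------------------------------------------
# Post-processing


def dose_volume_percentile(dose, weights, volume_fraction: float) -> float:
    """Dose received by at least ``volume_fraction`` of the (weighted)
    structure volume, interpolated on the cumulative curve."""
    dose = np.asarray(dose, dtype=float)
    weights = np.asarray(weights, dtype=float)
    sel = weights > 0
    if not sel.any():
        raise ValueError("structure has no volume")
    d = dose[sel]
    v = weights[sel]
    order = np.argsort(d)[::-1]
    d = d[order]
    cum = np.cumsum(v[order])
    target = volume_fraction * cum[-1]
    i = int(np.searchsorted(cum, target))
    return float(d[min(i, len(d) - 1)])


def apply_mu_threshold(
    weights: np.ndarray,
    influence: csc_matrix,
    grid,
    target: str,
    prescription: float,
    threshold: float = 0.015,
):
    """Remove sub-threshold spots and renormalize to target coverage.

    Weights below ``threshold`` MU are zeroed; the remainder is scaled by a
    single global factor so that D95 of the target equals the prescription.
    Raises when every spot falls below the threshold.
    """
    w = np.asarray(weights, dtype=float).copy()
    w[w < threshold] = 0.0
    if not (w > 0).any():
        raise ValueError("all spot weights below the delivery threshold")
    dose = influence @ w
    tv = grid.zeta[target] * grid.volumes
    d95 = dose_volume_percentile(dose, tv, 0.95)
    if d95 <= 0:
        raise ValueError("target D95 is zero; cannot renormalize")
    scale = prescription / d95
    return w * scale, dose * scale, scale


def check_plan_constraints(dose: np.ndarray, grid, target: str, prescription: float) -> dict:
    """Coverage and hot-spot flags: D95 >= prescription and target
    D_max <= 107% of prescription."""
    tv = grid.zeta[target] * grid.volumes
    d95 = dose_volume_percentile(dose, tv, 0.95)
    d_max = float(dose[grid.zeta[target] > 0].max())
    return {
        "d95": d95,
        "d_max": d_max,
        "coverage_ok": bool(d95 >= prescription * (1 - 1e-9)),
        "max_dose_ok": bool(d_max <= 1.07 * prescription + 1e-9),
    }
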