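"""Geometric Adjustment: collimation vectors, offsets, classification."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dcsplan import GAParams, Spot, TrimmerSet
from dcsplan.beamlets import make_layer
from dcsplan import ga as ga_mod
from dcsplan.ga import (
    classify_spot,
    collimation_vector_inside,
    collimation_vector_outside,
    init_trimmers_inside,
    init_trimmers_outside,
    marginal_voxel_set,
    secondary_offset_inside,
    split_primary_secondary,
)


@pytest.fixture(scope="module")
def params():
    return GAParams()


@pytest.fixture(scope="module")
def layer(machine):
    return make_layer(100.0, machine)


def _spot(layer, xy=(0.0, 0.0)):
    return Spot(id=0, layer=layer, bev_position=xy)


# ---------------------------------------------------------------------------
# Collimation vectors: hand values and properties


def test_outside_vector_hand_value():
    # voxels at (1,0) and (2,0): weights 0.8/0.2, eta = (1.2, 0)
    eta = collimation_vector_outside(np.array([[1.0, 0.0], [2.0, 0.0]]))
    np.testing.assert_allclose(eta, [1.2, 0.0], atol=1e-12)


def test_outside_vector_symmetry_cancels():
    eta = collimation_vector_outside(np.array([[1.0, 0.0], [-1.0, 0.0]]))
    np.testing.assert_allclose(eta, [0.0, 0.0], atol=1e-12)


def test_outside_vector_single_voxel_is_itself():
    np.testing.assert_allclose(
        collimation_vector_outside(np.array([[3.0, 4.0]])), [3.0, 4.0], atol=1e-12
    )


def test_inside_vector_single_voxel_is_unit():
    eta = collimation_vector_inside(np.array([[3.0, 4.0]]))
    np.testing.assert_allclose(eta, [0.6, 0.8], atol=1e-12)
    assert np.linalg.norm(eta) == pytest.approx(1.0, abs=1e-12)


def test_inside_vector_opposite_voxels_cancel():
    eta = collimation_vector_inside(np.array([[1.0, 0.0], [-1.0, 0.0]]))
    np.testing.assert_allclose(eta, [0.0, 0.0], atol=1e-12)


def test_inside_vector_halfplane_sign():
    rng = np.random.default_rng(0)
    r = np.stack([rng.uniform(0.5, 5, 30), rng.uniform(-5, 5, 30)], axis=1)
    assert collimation_vector_inside(r)[0] > 0


def test_on_axis_voxel_rejected():
    with pytest.raises(ValueError):
        collimation_vector_outside(np.array([[0.0, 0.0], [1.0, 0.0]]))


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(1, 30), st.integers(0, 2**31 - 1))
def test_vectors_match_per_voxel_loop_oracle(n, seed):
    """Vectorized eta/eta' equal a naive per-voxel accumulation to 1e-10."""
    rng = np.random.default_rng(seed)
    r = rng.uniform(-10, 10, size=(n, 2))
    r = r[np.hypot(r[:, 0], r[:, 1]) > 0.2]
    if len(r) == 0:
        return
    # loop oracle, outside formulation
    wsum = sum(1.0 / (x * x + y * y) for x, y in r)
    eta_loop = np.zeros(2)
    etap_loop = np.zeros(2)
    for x, y in r:
        w = (1.0 / (x * x + y * y)) / wsum
        eta_loop += w * np.array([x, y])
        d = np.hypot(x, y)
        etap_loop += w * np.array([x, y]) / d
    np.testing.assert_allclose(collimation_vector_outside(r), eta_loop, atol=1e-10)
    np.testing.assert_allclose(collimation_vector_inside(r), etap_loop, atol=1e-10)


def test_weights_sum_to_one_property():
    rng = np.random.default_rng(1)
    r = rng.uniform(1, 8, size=(50, 2))
    d2 = np.sum(r**2, axis=1)
    w = (1.0 / d2) / np.sum(1.0 / d2)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Primary/secondary split


@pytest.mark.parametrize(
    "eta,axis", [((2.0, 1.0), "x"), ((1.0, 2.0), "y"), ((1.0, 1.0), "x")]
)
def test_primary_axis_selection(eta, axis):
    cv = split_primary_secondary(np.array(eta))
    assert cv.primary_axis == axis
    assert abs(cv.eta_p) >= abs(cv.eta_s)


# ---------------------------------------------------------------------------
# Outside-target offsets


def test_outside_offset_below_threshold(params, layer):
    cv = split_primary_secondary(np.array([0.4, 0.0]))
    asg = init_trimmers_outside(cv, params, _spot(layer))
    # eta points +x: TX1 active at mu_p - 0.4 = 0.6 mm from the axis
    assert asg.roles["tx1"] == "active"
    assert asg.trimmers.tx1 == pytest.approx(-0.6, abs=1e-12)


def test_outside_offset_saturates_at_f_min(params, layer):
    cv = split_primary_secondary(np.array([3.0, 0.0]))
    asg = init_trimmers_outside(cv, params, _spot(layer))
    assert asg.trimmers.tx1 == pytest.approx(-params.f_min, abs=1e-12)


def test_outside_secondary_boundary_uses_saturation_branch(params, layer):
    # |eta_s| = mu_s exactly -> f_min branch
    cv = split_primary_secondary(np.array([7.0, 5.0]))
    asg = init_trimmers_outside(cv, params, _spot(layer))
    assert asg.roles["ty1"] == "active"
    assert asg.trimmers.ty1 == pytest.approx(-params.f_min, abs=1e-12)


def test_outside_active_side_follows_vector_sign(params, layer):
    # eta pointing -x: the +x trimmer (TX2) is active
    cv = split_primary_secondary(np.array([-0.4, 0.0]))
    asg = init_trimmers_outside(cv, params, _spot(layer))
    assert asg.roles["tx2"] == "active"
    assert asg.trimmers.tx2 == pytest.approx(0.6, abs=1e-12)


def test_outside_offsets_in_valid_range(params, layer):
    rng = np.random.default_rng(2)
    for _ in range(100):
        cv = split_primary_secondary(rng.uniform(-8, 8, 2))
        asg = init_trimmers_outside(cv, params, _spot(layer))
        offsets = asg.trimmers.offsets_from((0.0, 0.0))
        for name, role in asg.roles.items():
            off = offsets[["tx1", "tx2", "ty1", "ty2"].index(name)]
            if role == "active":
                # unsaturated branch: mu - |eta| in (0, mu]; saturated: f_min
                assert 0.0 < off <= max(params.mu_p, params.mu_s) + 1e-12
            else:
                assert off == pytest.approx(params.f_max_prime, abs=1e-12)


# ---------------------------------------------------------------------------
# Inside-target offsets


def test_inside_primary_offset_is_f_min_prime(params, layer):
    cv = split_primary_secondary(np.array([0.9, 0.05]))
    asg = init_trimmers_inside(cv, params, _spot(layer))
    # eta' points +x: TX2 (towards healthy tissue) active at f'_min
    assert asg.roles["tx2"] == "active"
    assert asg.trimmers.tx2 == pytest.approx(params.f_min_prime, abs=1e-12)


def test_inside_secondary_offset_hand_values(params):
    # c_s * 0.2 = 1.1314 > 1 -> Heaviside kills the bracket -> f'_min
    assert secondary_offset_inside(0.2, params) == pytest.approx(1.0, abs=1e-12)
    # c_s * 0.1 = 0.5657: f'_max (1 - 0.5657^15) + f'_min = 25.995...
    expected = 25.0 * (1.0 - 0.5657**15) + 1.0
    assert expected == pytest.approx(25.995, abs=5e-4)
    assert secondary_offset_inside(0.1, params) == pytest.approx(expected, rel=1e-12)


def test_inside_secondary_offset_monotone_non_increasing(params):
    mags = np.linspace(0.0, 0.5, 200)
    vals = [secondary_offset_inside(m, params) for m in mags]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
    assert all(
        params.f_min_prime - 1e-12 <= v <= params.f_max_prime + params.f_min_prime + 1e-12
        for v in vals
    )


def test_inside_inactive_trimmers_park_at_f_max_prime(params, layer):
    cv = split_primary_secondary(np.array([0.9, 0.05]))
    asg = init_trimmers_inside(cv, params, _spot(layer))
    assert asg.trimmers.tx1 == pytest.approx(-params.f_max_prime, abs=1e-12)


# ---------------------------------------------------------------------------
# Marginal sets and classification on a synthetic slab


def _slab_context(layer, params, healthy_gap=None):
    """Flat 2D slab of cells at the layer's R90 depth: target occupies
    x <= 0, healthy tissue x > 0 (optionally starting at ``healthy_gap``)."""
    xs = np.arange(-20.0, 21.0, 1.0)
    ys = np.arange(-20.0, 21.0, 1.0)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    bev = np.stack([gx.ravel(), gy.ravel()], axis=1)
    target = bev[:, 0] <= 0.0
    healthy = ~target
    if healthy_gap is not None:
        healthy = bev[:, 0] >= healthy_gap
        target = ~healthy
    return SimpleNamespace(
        params=params,
        bev_xy=bev,
        wed=np.full(len(bev), layer.r90),
        target_mask=target,
        healthy_mask=healthy,
        target_zeta=target.astype(float),
    )


def test_marginal_set_outside_matches_brute_force(layer, params):
    ctx = _slab_context(layer, params)
    spot = _spot(layer, (3.0, 0.0))  # 3 mm from the flat target edge at x=0
    idx, r_star = marginal_voxel_set(ctx, spot, params, "outside")
    assert r_star == pytest.approx(3.0, abs=1e-12)
    # brute force: target voxels within 3 + 5 mm of the axis
    d = np.hypot(ctx.bev_xy[:, 0] - 3.0, ctx.bev_xy[:, 1])
    expect = set(np.nonzero(ctx.target_mask & (d <= 8.0 + 1e-9) & (d > 0))[0])
    assert set(idx) == expect


def test_marginal_set_inside_matches_brute_force(layer, params):
    ctx = _slab_context(layer, params, healthy_gap=6.0)
    spot = _spot(layer, (-1.0, 0.0))
    idx, r_star = marginal_voxel_set(ctx, spot, params, "inside")
    assert r_star == pytest.approx(7.0, abs=1e-12)
    d = np.hypot(ctx.bev_xy[:, 0] + 1.0, ctx.bev_xy[:, 1])
    expect = set(np.nonzero(ctx.healthy_mask & (d <= 12.0 + 1e-9))[0])
    assert set(idx) == expect


def test_slab_beyond_phantom_gives_empty_set(layer, params):
    ctx = _slab_context(layer, params)
    ctx.wed = np.zeros_like(ctx.wed)  # slab nowhere near r90
    idx, r_star = marginal_voxel_set(ctx, _spot(layer), params, "outside")
    assert len(idx) == 0 and np.isinf(r_star)


def test_inside_spot_far_from_healthy_is_uncollimated(layer, params):
    ctx = _slab_context(layer, params, healthy_gap=2.5)
    status, side = classify_spot(ctx, _spot(layer, (0.0, 0.0)), params)
    assert (status, side) == ("uncollimated", "inside")


def test_inside_spot_near_healthy_is_collimated(layer, params):
    ctx = _slab_context(layer, params, healthy_gap=1.0)
    status, side = classify_spot(ctx, _spot(layer, (0.0, 0.0)), params)
    assert (status, side) == ("collimated", "inside")


def test_outside_spot_with_empty_marginal_set_is_uncollimated(layer, params):
    ctx = _slab_context(layer, params)
    ctx.target_mask = np.zeros_like(ctx.target_mask)  # no target anywhere
    status, side = classify_spot(ctx, _spot(layer, (5.0, 0.0)), params)
    assert status == "uncollimated"


def test_assign_trimmers_collimated_spot_has_one_active_per_axis(layer, params):
    ctx = _slab_context(layer, params)
    asg = ga_mod.assign_trimmers(ctx, _spot(layer, (3.0, 0.5)), params)
    assert asg.collimated
    for pair in (("tx1", "tx2"), ("ty1", "ty2")):
        active = [asg.roles[t] for t in pair].count("active")
        assert active <= 1


def test_uncollimated_assignment_parks_all_trimmers(layer, params):
    ctx = _slab_context(layer, params)
    ctx.target_mask = np.zeros_like(ctx.target_mask)
    asg = ga_mod.assign_trimmers(ctx, _spot(layer, (5.0, 0.0)), params)
    assert not asg.collimated
    np.testing.assert_allclose(
        asg.trimmers.offsets_from((5.0, 0.0)), params.f_max_prime, atol=1e-12
    )
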