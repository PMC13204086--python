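"""Delivery-time model, ACO ordering, regrouping and PLD round trips."""

import numpy as np
import pytest

from dcsplan import (
    ACOSettings,
    KinematicsModel,
    SpotGroup,
    TimeModelParams,
    TrimmerSet,
    aco_optimize,
    desirability_matrix,
    export_pld,
    group_transition_time,
    nearest_neighbor_sequence,
    read_pld,
    regroup_spots,
    total_delivery_time,
    trimmer_transition_time,
)
from dcsplan.sequencing import brute_force_sequence, evaluate_sequence, initial_groups


@pytest.fixture(scope="module")
def kin():
    return KinematicsModel()


@pytest.fixture(scope="module")
def tp():
    return TimeModelParams()


def _group(gid, energy, edges, mu=1.0, xy=(0.0, 0.0)):
    return SpotGroup(
        gid=gid,
        energy=energy,
        trimmers=TrimmerSet(*edges),
        spot_ids=[gid],
        total_mu=mu,
        spots=[(xy[0], xy[1], mu)],
    )


# ---------------------------------------------------------------------------
# Kinematics


def test_zero_move_takes_zero_time(kin):
    assert trimmer_transition_time(0.0, kin) == 0.0
    assert trimmer_transition_time(0.05, kin) == 0.0  # within settle tolerance


def test_transition_time_monotone_in_distance(kin):
    assert trimmer_transition_time(20.0, kin) > trimmer_transition_time(5.0, kin)


def test_typical_moves_cost_fraction_of_second(kin):
    for x in (5.0, 20.0, 50.0):
        tau = trimmer_transition_time(x, kin)
        assert 0.05 <= tau <= 0.5


def test_higher_jerk_never_slows_a_move(kin):
    fast = KinematicsModel(xi=2 * kin.xi)
    for x in (1.0, 5.0, 20.0, 50.0):
        assert trimmer_transition_time(x, fast) <= trimmer_transition_time(x, kin) + 1e-12


def test_negative_distance_rejected(kin):
    with pytest.raises(ValueError):
        trimmer_transition_time(-1.0, kin)


# ---------------------------------------------------------------------------
# Transition and total time


def test_same_layer_transition_is_max_of_trimmer_times(kin, tp):
    a = _group(0, 100.0, (-5.0, 5.0, -5.0, 5.0))
    b = _group(1, 100.0, (-25.0, 10.0, -8.0, 25.0))
    t = group_transition_time(a, b, kin, tp)
    taus = kin.tau(np.abs(a.trimmers.edges() - b.trimmers.edges()))
    assert t == pytest.approx(taus.max(), abs=1e-12)


def test_energy_decrease_switch_dominates_small_moves(kin, tp):
    a = _group(0, 110.0, (-5.0, 5.0, -5.0, 5.0))
    b = _group(1, 100.0, (-6.0, 6.0, -6.0, 6.0))  # sub-second trimmer moves
    assert group_transition_time(a, b, kin, tp) == pytest.approx(1.5)


def test_energy_increase_switch_dominates_small_moves(kin, tp):
    a = _group(0, 100.0, (-5.0, 5.0, -5.0, 5.0))
    b = _group(1, 110.0, (-6.0, 6.0, -6.0, 6.0))
    assert group_transition_time(a, b, kin, tp) == pytest.approx(7.0)


def test_beam_time_is_6p6_ms_per_mu(tp):
    assert tp.beam_time(1.0) == pytest.approx(0.0066)


def test_single_group_total_time_is_beam_time_only(kin, tp):
    g = _group(0, 100.0, (-5.0, 5.0, -5.0, 5.0), mu=1.0)
    assert total_delivery_time([g], kin, tp) == pytest.approx(0.0066)


def test_identical_groups_transition_free(kin, tp):
    a = _group(0, 100.0, (-5.0, 5.0, -5.0, 5.0), mu=2.0)
    b = _group(1, 100.0, (-5.0, 5.0, -5.0, 5.0), mu=3.0)
    assert total_delivery_time([a, b], kin, tp) == pytest.approx(tp.beam_time(5.0))


def test_permutation_preserves_beam_time_sum(kin, tp):
    rng = np.random.default_rng(0)
    groups = [
        _group(i, 100.0, sorted_edges(rng), mu=rng.uniform(0.5, 3)) for i in range(5)
    ]
    s1 = evaluate_sequence(groups, kin, tp)
    s2 = evaluate_sequence(groups[::-1], kin, tp)
    assert s1.beam_times.sum() == pytest.approx(s2.beam_times.sum())


def sorted_edges(rng):
    x = np.sort(rng.uniform(-20, 20, 2))
    y = np.sort(rng.uniform(-20, 20, 2))
    return (x[0], x[1], y[0], y[1])


def test_operational_delay_adds_per_transition(tp):
    kin_d = KinematicsModel(operational_delay=0.09)
    a = _group(0, 110.0, (-5.0, 5.0, -5.0, 5.0))
    b = _group(1, 100.0, (-6.0, 6.0, -6.0, 6.0))
    assert group_transition_time(a, b, kin_d, tp) == pytest.approx(1.59)


# ---------------------------------------------------------------------------
# Desirability matrix


def test_desirability_extremes_and_oracle(kin):
    rng = np.random.default_rng(1)
    groups = [_group(i, 100.0, sorted_edges(rng)) for i in range(5)]
    omega = desirability_matrix(groups, kin)
    assert omega.min() == pytest.approx(0.0)  # the slowest transition
    assert np.all((0.0 <= omega) & (omega <= 1.0))
    # per-pair loop oracle
    taus = np.zeros((5, 5))
    for i in range(5):
        for j in range(5):
            if i != j:
                moves = np.abs(groups[i].trimmers.edges() - groups[j].trimmers.edges())
                taus[i, j] = max(trimmer_transition_time(x, kin) for x in moves)
    expected = 1.0 - taus / taus.max()
    np.testing.assert_allclose(omega, expected, atol=1e-12)


def test_desirability_identical_groups_all_ones(kin):
    groups = [_group(i, 100.0, (-5.0, 5.0, -5.0, 5.0)) for i in range(3)]
    assert np.all(desirability_matrix(groups, kin) == 1.0)


# ---------------------------------------------------------------------------
# Nearest neighbour and ACO


def test_nn_walks_monotone_chain_on_a_line(kin, tp):
    # groups along a line of trimmer positions: greedy = monotone chain
    groups = [_group(i, 100.0, (-25.0 + 2 * i, 25.0 + 2 * i, -25.0, 25.0)) for i in range(4)]
    seq = nearest_neighbor_sequence(groups, kin, tp)
    assert [g.gid for g in seq.groups] == [0, 1, 2, 3]


def test_nn_single_group_per_layer_follows_energy_order(kin, tp):
    groups = [_group(i, 100.0 - 10 * i, (-5.0, 5.0, -5.0, 5.0)) for i in range(3)]
    seq = nearest_neighbor_sequence(groups[::-1], kin, tp)
    assert [g.energy for g in seq.groups] == [100.0, 90.0, 80.0]


def test_nn_beats_reversed_nn_on_toy(kin, tp):
    rng = np.random.default_rng(2)
    groups = [_group(i, 100.0, sorted_edges(rng)) for i in range(6)]
    nn = nearest_neighbor_sequence(groups, kin, tp)
    rev = evaluate_sequence(nn.groups[::-1], kin, tp)
    assert nn.total_time <= rev.total_time + 1e-12


def test_aco_matches_exhaustive_optimum_small_instance(kin, tp):
    rng = np.random.default_rng(3)
    groups = [_group(i, 100.0, sorted_edges(rng)) for i in range(5)]
    omega = desirability_matrix(groups, kin)
    best = aco_optimize(groups, omega, kin, tp, ACOSettings(), rng=0)
    exact = brute_force_sequence(groups, kin, tp)
    assert best.total_time == pytest.approx(exact.total_time, abs=1e-9)


def test_aco_is_deterministic_for_fixed_seed(kin, tp):
    rng = np.random.default_rng(4)
    groups = [_group(i, 100.0 - 10 * (i // 5), sorted_edges(rng)) for i in range(10)]
    omega = desirability_matrix(groups, kin)
    s1 = aco_optimize(groups, omega, kin, tp, ACOSettings(ants=5, iterations=5), rng=7)
    s2 = aco_optimize(groups, omega, kin, tp, ACOSettings(ants=5, iterations=5), rng=7)
    assert [g.gid for g in s1.groups] == [g.gid for g in s2.groups]
    assert s1.total_time == s2.total_time


def test_aco_never_worse_than_nearest_neighbor(kin, tp):
    rng = np.random.default_rng(5)
    groups = [_group(i, 100.0 - 10 * (i // 10), sorted_edges(rng)) for i in range(30)]
    omega = desirability_matrix(groups, kin)
    best = aco_optimize(groups, omega, kin, tp, ACOSettings(ants=8, iterations=10), rng=1)
    nn = nearest_neighbor_sequence(groups, kin, tp)
    assert best.total_time <= nn.total_time + 1e-12


def test_aco_one_ant_one_iteration_reproduces_nn(kin, tp):
    rng = np.random.default_rng(6)
    groups = [_group(i, 100.0, sorted_edges(rng)) for i in range(6)]
    omega = desirability_matrix(groups, kin)
    aco = aco_optimize(groups, omega, kin, tp, ACOSettings(ants=1, iterations=1), rng=0)
    nn = nearest_neighbor_sequence(groups, kin, tp)
    assert [g.gid for g in aco.groups] == [g.gid for g in nn.groups]


def test_aco_keeps_layers_contiguous_and_decreasing(kin, tp):
    rng = np.random.default_rng(7)
    groups = [_group(i, 100.0 - 10 * (i % 3), sorted_edges(rng)) for i in range(12)]
    omega = desirability_matrix(groups, kin)
    seq = aco_optimize(groups, omega, kin, tp, ACOSettings(ants=4, iterations=4), rng=2)
    energies = [g.energy for g in seq.groups]
    assert all(a >= b for a, b in zip(energies, energies[1:]))
    assert len(seq.groups) == 12


# ---------------------------------------------------------------------------
# Regrouping


def _assignment_rows(rng, n, energies):
    rows = []
    for i in range(n):
        x = np.sort(rng.uniform(-20, 20, 2))
        y = np.sort(rng.uniform(-20, 20, 2))
        rows.append(
            {
                "spot_id": i,
                "energy": float(rng.choice(energies)),
                "trimmers": TrimmerSet(x[0], x[1], y[0], y[1]),
                "mu": float(rng.uniform(0.5, 3.0)),
                "collimated": bool(rng.uniform() < 0.8),
                "xy": (0.0, 0.0),
            }
        )
    return rows


def test_infinite_time_goal_keeps_per_spot_groups(kin, tp):
    rng = np.random.default_rng(8)
    rows = _assignment_rows(rng, 12, [100.0, 90.0])
    seq, trace = regroup_spots(rows, np.inf, kin, tp, ACOSettings(ants=2, iterations=2), 0)
    n_coll = sum(r["collimated"] for r in rows)
    n_uncoll_layers = len({r["energy"] for r in rows if not r["collimated"]})
    assert len(seq.groups) == n_coll + n_uncoll_layers
    assert len(trace) == 1


def test_identical_trimmer_spots_merge_first():
    from dcsplan.sequencing import _coarsen

    t = TrimmerSet(-3.0, 3.0, -3.0, 3.0)
    groups = [
        _group(0, 100.0, (-3.0, 3.0, -3.0, 3.0)),
        _group(1, 100.0, (-15.0, 15.0, -15.0, 15.0)),
        _group(2, 100.0, (-3.0, 3.0, -3.0, 3.0)),
    ]
    merged, _, merged_any = _coarsen(groups, max_size=2, next_gid=3)
    assert merged_any
    # the zero-movement identical pair (0, 2) merges, leaving group 1 alone
    sizes = {tuple(sorted(g.spot_ids)) for g in merged}
    assert (0, 2) in sizes and (1,) in sizes


def test_regrouping_never_increases_total_time(kin, tp):
    rng = np.random.default_rng(9)
    rows = _assignment_rows(rng, 60, [110.0, 100.0, 90.0])
    seq, trace = regroup_spots(rows, 0.0, kin, tp, ACOSettings(ants=3, iterations=3), 1)
    assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))
    assert seq.warning is not None  # goal 0 is unreachable
    # final time never exceeds the ungrouped time
    ungrouped = regroup_spots(rows, np.inf, kin, tp, ACOSettings(ants=3, iterations=3), 1)[0]
    assert seq.total_time <= ungrouped.total_time + 1e-9


def test_merging_reduces_transition_count(kin, tp):
    rng = np.random.default_rng(10)
    rows = _assignment_rows(rng, 20, [100.0])
    full, _ = regroup_spots(rows, np.inf, kin, tp, ACOSettings(ants=1, iterations=1), 0)
    merged, _ = regroup_spots(rows, 0.0, kin, tp, ACOSettings(ants=1, iterations=1), 0)
    assert len(merged.groups) < len(full.groups)


# ---------------------------------------------------------------------------
# PLD export / import


def test_pld_round_trip_bit_exact(tmp_path, kin, tp):
    rng = np.random.default_rng(11)
    rows = _assignment_rows(rng, 15, [110.0, 100.0])
    seq, _ = regroup_spots(rows, np.inf, kin, tp, ACOSettings(ants=2, iterations=2), 0)
    path = tmp_path / "field.pld"
    export_pld(seq, path)
    back = read_pld(path)
    assert len(back) == len(seq.groups)
    for g0, g1 in zip(seq.groups, back):
        assert g0.gid == g1.gid
        assert g0.energy == g1.energy
        assert np.array_equal(g0.trimmers.edges(), g1.trimmers.edges())
        assert g0.spots == g1.spots
    # row count equals spot count
    assert sum(len(g.spots) for g in back) == len(rows)


def test_total_time_recomputable_from_exported_file(tmp_path, kin, tp):
    rng = np.random.default_rng(12)
    rows = _assignment_rows(rng, 10, [110.0, 100.0])
    seq, _ = regroup_spots(rows, np.inf, kin, tp, ACOSettings(ants=2, iterations=2), 0)
    path = tmp_path / "field.pld"
    export_pld(seq, path)
    t_again = total_delivery_time(read_pld(path), kin, tp)
    assert t_again == pytest.approx(seq.total_time, abs=1e-9)


def test_hand_written_pld_parses(tmp_path):
    text = (
        "# dcsplan-pld-1\n"
        "# columns: spot_x spot_y mu tx1 tx2 ty1 ty2\n"
        "group 0 energy 100.0 nspots 2 uncollimated 0\n"
        "1.0 2.0 0.5 -3.0 3.0 -4.0 4.0\n"
        "1.5 2.5 0.7 -3.0 3.0 -4.0 4.0\n"
    )
    path = tmp_path / "hand.pld"
    path.write_text(text)
    groups = read_pld(path)
    assert len(groups) == 1
    assert groups[0].total_mu == pytest.approx(1.2)
    assert groups[0].trimmers.edges().tolist() == [-3.0, 3.0, -4.0, 4.0]


def test_export_rejects_increasing_energy_order(tmp_path, kin, tp):
    groups = [_group(0, 90.0, (-5, 5, -5, 5)), _group(1, 100.0, (-5, 5, -5, 5))]
    seq = evaluate_sequence(groups, kin, tp)
    with pytest.raises(ValueError, match="energy order"):
        export_pld(seq, tmp_path / "bad.pld")
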