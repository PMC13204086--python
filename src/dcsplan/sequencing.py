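"""Delivery-time model, trimmer kinematics, ACO group ordering and spot
regrouping.

Treatments are delivered in *spot groups*: subsets of spots sharing an
energy layer and one set of trimmer positions.  The modeled field time is

    T = sum_m t(m, m+1) + sum_m t_beam(m)

where each group-to-group transition takes the maximum of the energy-layer
switching time and the four trimmer translation times (trimmer motion and
energy changes run concurrently; everything else is sequential), and the
beam-on time is a constant rate per monitor unit.

A single trimmer translation over distance ``x`` (mm, isocenter plane)
follows an experimentally-motivated sigmoid settling model

    tau(x) = -(1/g1) * ln(x / (x - 0.05) - 1) + g2

with 0.05 mm the settle tolerance and ``g1``/``g2`` empirical logarithmic
functions of the commanded jerk and the move distance; moves within the
settle tolerance cost nothing.

Group ordering uses ant-colony optimization over a desirability matrix
``Omega = 1 - tau/tau_max`` (pure trimmer time), constrained to deliver
complete energy layers in strictly decreasing energy order, with a
nearest-neighbour first ant each iteration.  When no ordering meets the
time goal, groups are iteratively coarsened by merging same-layer spots
with minimal shared-trimmer movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations

import numpy as np

from .beamlets import TrimmerSet

__all__ = [
    "KinematicsModel",
    "TimeModelParams",
    "ACOSettings",
    "SpotGroup",
    "DeliverySequence",
    "trimmer_transition_time",
    "group_transition_time",
    "total_delivery_time",
    "desirability_matrix",
    "nearest_neighbor_sequence",
    "aco_optimize",
    "regroup_spots",
    "export_pld",
    "read_pld",
]


@dataclass
class KinematicsModel:
    """Trimmer motion model.

    ``g1 = a1 + b1*ln(xi) - c1*ln(x+1)`` (multiplicative sigmoid rate) and
    ``g2 = a2 + b2*ln(x+1) - c2*ln(xi)`` (additive settle term), calibrated
    so typical 5-50 mm moves cost ~0.2-0.4 s at the default jerk of
    300,000 mm/s^3; raising the jerk never slows a move.  All coefficients
    are config-overridable; times are clamped at zero.
    """

    xi: float = 3.0e5             # jerk, mm/s^3
    a1: float = 5.0
    b1: float = 4.0
    c1: float = 2.0
    a2: float = 0.55
    b2: float = 0.045
    c2: float = 0.04
    settle_tolerance: float = 0.05  # mm
    operational_delay: float = 0.0  # s, per transition (hardware uses 0.090)

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("jerk must be positive")

    def tau(self, x) -> np.ndarray:
        """Vectorized settling time (s) for move distances ``x`` (mm)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("move distance must be non-negative")
        s = self.settle_tolerance
        moving = x > s
        xm = np.where(moving, x, 2 * s)  # placeholder to keep logs finite
        g1 = self.a1 + self.b1 * np.log(self.xi) - self.c1 * np.log(xm + 1.0)
        g2 = self.a2 + self.b2 * np.log(xm + 1.0) - self.c2 * np.log(self.xi)
        if np.any(g1[moving] <= 0):
            raise ValueError("kinematics coefficients give non-positive g1")
        tau = -(1.0 / g1) * np.log(xm / (xm - s) - 1.0) + g2
        return np.where(moving, np.clip(tau, 0.0, None), 0.0)


@dataclass
class TimeModelParams:
    """Beam-line timing constants: energy switches and beam rate."""

    t_down: float = 1.5           # s, energy decrease
    t_up: float = 7.0             # s, energy increase
    beam_rate_ms_per_mu: float = 6.6

    def __post_init__(self):
        if min(self.t_down, self.t_up, self.beam_rate_ms_per_mu) < 0:
            raise ValueError("time-model constants must be non-negative")

    def beam_time(self, mu: float) -> float:
        return self.beam_rate_ms_per_mu * 1e-3 * mu


@dataclass
class ACOSettings:
    ants: int = 20
    iterations: int = 50
    pheromone_exp: float = 1.0
    heuristic_exp: float = 2.0
    evaporation: float = 0.1
    deposit: float = 1.0


@dataclass
class SpotGroup:
    """Spots sharing an energy layer and one trimmer configuration."""

    gid: int
    energy: float
    trimmers: TrimmerSet
    spot_ids: list
    total_mu: float
    spots: list = field(default_factory=list)  # optional (x, y, mu) rows for export
    uncollimated: bool = False


@dataclass
class DeliverySequence:
    """An ordered delivery schedule with its modeled time budget."""

    groups: list
    transition_times: np.ndarray
    beam_times: np.ndarray
    total_time: float
    warning: str | None = None


def trimmer_transition_time(x: float, model: KinematicsModel) -> float:
    """Settling time (s) for one trimmer translating ``x`` mm; see
    :class:`KinematicsModel`."""
    return float(model.tau(np.asarray([x]))[0])


def trimmer_moves(a: SpotGroup, b: SpotGroup) -> np.ndarray:
    """Absolute isocenter-plane move distance of each of the four trimmers."""
    return np.abs(a.trimmers.edges() - b.trimmers.edges())


def tau_matrix(groups: list, kin: KinematicsModel) -> np.ndarray:
    """Pairwise max-trimmer transition time over all M x M group pairs."""
    edges = np.array([g.trimmers.edges() for g in groups])  # (M, 4)
    moves = np.abs(edges[:, None, :] - edges[None, :, :])
    return kin.tau(moves).max(axis=2)


def group_transition_time(
    a: SpotGroup, b: SpotGroup, kin: KinematicsModel, tp: TimeModelParams
) -> float:
    """Transition time between consecutive groups: the max of the energy
    switching time and the four trimmer times, plus the optional
    operational delay."""
    if b.energy == a.energy:
        e_switch = 0.0
    elif b.energy < a.energy:
        e_switch = tp.t_down
    else:
        e_switch = tp.t_up
    t_trim = float(kin.tau(trimmer_moves(a, b)).max())
    return max(e_switch, t_trim) + kin.operational_delay


def evaluate_sequence(
    order: list, kin: KinematicsModel, tp: TimeModelParams, warning: str | None = None
) -> DeliverySequence:
    trans = np.array(
        [group_transition_time(order[m], order[m + 1], kin, tp) for m in range(len(order) - 1)]
    )
    beam = np.array([tp.beam_time(g.total_mu) for g in order])
    return DeliverySequence(
        groups=list(order),
        transition_times=trans,
        beam_times=beam,
        total_time=float(trans.sum() + beam.sum()),
        warning=warning,
    )


def total_delivery_time(seq, kin: KinematicsModel, tp: TimeModelParams) -> float:
    """Total modeled time of an ordered group list (or DeliverySequence)."""
    order = seq.groups if isinstance(seq, DeliverySequence) else list(seq)
    return evaluate_sequence(order, kin, tp).total_time


class _SeqProblem:
    """Precomputed arrays for fast sequence-cost evaluation."""

    def __init__(self, groups, kin, tp, tau=None):
        self.groups = groups
        self.kin = kin
        self.tp = tp
        self.tau = tau_matrix(groups, kin) if tau is None else tau
        self.energies = np.array([g.energy for g in groups])
        self.beam = np.array([tp.beam_time(g.total_mu) for g in groups])
        # layer blocks, highest energy first
        order = sorted(set(self.energies), reverse=True)
        self.blocks = [np.nonzero(self.energies == e)[0] for e in order]
        # within blocks, stable gid order for deterministic tie-breaks
        gids = np.array([g.gid for g in groups])
        self.blocks = [b[np.argsort(gids[b])] for b in self.blocks]

    def cost(self, order_idx) -> float:
        o = np.asarray(order_idx)
        a, b = o[:-1], o[1:]
        ea, eb = self.energies[a], self.energies[b]
        es = np.where(eb == ea, 0.0, np.where(eb < ea, self.tp.t_down, self.tp.t_up))
        trans = np.maximum(es, self.tau[a, b]) + self.kin.operational_delay
        return float(trans.sum() + self.beam[o].sum())

    def nn_order(self, start: int | None = None) -> list:
        order_idx: list = []
        prev = None
        for bi, block in enumerate(self.blocks):
            rem = list(block)
            while rem:
                if prev is None:
                    nxt = start if (bi == 0 and start is not None) else rem[0]
                else:
                    costs = self.tau[prev, rem]
                    nxt = rem[int(np.argmin(costs))]
                rem.remove(nxt)
                order_idx.append(int(nxt))
                prev = nxt
        return order_idx

    def to_sequence(self, order_idx, warning=None) -> DeliverySequence:
        return evaluate_sequence(
            [self.groups[i] for i in order_idx], self.kin, self.tp, warning
        )


def desirability_matrix(groups: list, kin: KinematicsModel) -> np.ndarray:
    """Omega[m, m'] = 1 - tau(m, m') / tau_max over pure trimmer times.

    ``tau`` is the slowest of the four trimmer moves for the transition and
    ``tau_max`` the largest over all M x M transitions; all-zero moves give
    Omega = 1 everywhere.  Values lie in [0, 1]; larger means quicker.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    tau = tau_matrix(groups, kin)
    np.fill_diagonal(tau, 0.0)
    tau_max = tau.max()
    if tau_max == 0:
        return np.ones_like(tau)
    return 1.0 - tau / tau_max


def nearest_neighbor_sequence(
    groups: list,
    kin: KinematicsModel,
    tp: TimeModelParams,
    start: int | None = None,
) -> DeliverySequence:
    """Greedy chain: deliver layers highest-energy first; within each layer
    repeatedly hop to the unvisited group with the smallest trimmer
    transition time (ties broken by lowest group id).  ``start`` optionally
    fixes the first group (index into ``groups``)."""
    prob = _SeqProblem(groups, kin, tp)
    return prob.to_sequence(prob.nn_order(start))


def aco_optimize(
    groups: list,
    omega: np.ndarray,
    kin: KinematicsModel,
    tp: TimeModelParams,
    settings: ACOSettings | None = None,
    rng: np.random.Generator | int | None = None,
    _problem: "_SeqProblem | None" = None,
) -> DeliverySequence:
    """Ant-colony search for the fastest delivery order.

    Layers are delivered as contiguous blocks in strictly decreasing energy
    order.  The first ant of every iteration runs the nearest-neighbour
    heuristic from that iteration's starting group (the lowest-id group of
    the top layer for the first iteration, a randomly selected one
    afterwards); the remaining ants sample transitions with probability
    proportional to ``pheromone^a * Omega^b``.  The best-total-time
    sequence found is returned, so the result is never worse than the
    nearest-neighbour first ant.
    """
    settings = settings or ACOSettings()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    prob = _problem or _SeqProblem(groups, kin, tp)
    m = len(groups)
    if m == 1:
        return prob.to_sequence([0])
    pher = np.ones((m, m))
    eps = 1e-12
    a_exp, b_exp = settings.pheromone_exp, settings.heuristic_exp
    heur = np.maximum(omega, eps) ** b_exp

    best_idx = None
    best_cost = np.inf
    for it in range(settings.iterations):
        start = int(prob.blocks[0][0]) if it == 0 else int(rng.choice(prob.blocks[0]))
        ant_orders = [prob.nn_order(start)]
        for _ in range(settings.ants - 1):
            order_idx: list = []
            prev = None
            for bi, block in enumerate(prob.blocks):
                rem = list(block)
                while rem:
                    if prev is None:
                        nxt = start
                    else:
                        w = (pher[prev, rem] ** a_exp) * heur[prev, rem]
                        tot = w.sum()
                        if tot <= 0:
                            nxt = rem[0]
                        else:
                            nxt = rem[int(rng.choice(len(rem), p=w / tot))]
                    rem.remove(nxt)
                    order_idx.append(int(nxt))
                    prev = nxt
            ant_orders.append(order_idx)

        pher *= 1.0 - settings.evaporation
        for order_idx in ant_orders:
            cost = prob.cost(order_idx)
            if cost < best_cost:
                best_cost, best_idx = cost, order_idx
            deposit = settings.deposit / max(cost, eps)
            o = np.asarray(order_idx)
            pher[o[:-1], o[1:]] += deposit
    return prob.to_sequence(best_idx)


def brute_force_sequence(
    groups: list, kin: KinematicsModel, tp: TimeModelParams
) -> DeliverySequence:
    """Exhaustive optimum over all layer-respecting orders (small M only)."""
    prob = _SeqProblem(groups, kin, tp)
    best_idx, best_cost = None, np.inf

    def recurse(prefix, remaining_blocks):
        nonlocal best_idx, best_cost
        if not remaining_blocks:
            cost = prob.cost(prefix)
            if cost < best_cost:
                best_cost, best_idx = cost, list(prefix)
            return
        for perm in permutations(remaining_blocks[0]):
            recurse(prefix + list(perm), remaining_blocks[1:])

    recurse([], [list(b) for b in prob.blocks])
    return prob.to_sequence(best_idx)


# ---------------------------------------------------------------------------
# Regrouping


def _merge_groups(a: SpotGroup, b: SpotGroup, gid: int) -> SpotGroup:
    """Merge two same-layer groups; the merged trimmer set is, per trimmer,
    the least-collimating envelope of the members' edges so the result never
    collimates tighter than any member required."""
    ea, eb = a.trimmers.edges(), b.trimmers.edges()
    merged = TrimmerSet(
        min(ea[0], eb[0]), max(ea[1], eb[1]), min(ea[2], eb[2]), max(ea[3], eb[3])
    )
    return SpotGroup(
        gid=gid,
        energy=a.energy,
        trimmers=merged,
        spot_ids=a.spot_ids + b.spot_ids,
        total_mu=a.total_mu + b.total_mu,
        spots=a.spots + b.spots,
    )


def initial_groups(assignments: list) -> list:
    """Build the starting groups from per-spot trimmer assignments.

    ``assignments`` is a list of dicts with keys ``spot_id``, ``energy``,
    ``trimmers`` (TrimmerSet), ``mu``, ``collimated`` (bool) and optionally
    ``xy``.  Every collimated spot starts as its own group; per energy
    layer, all uncollimated spots (trimmers parked) form a single group.
    """
    groups: list = []
    gid = 0
    uncoll: dict = {}
    for a in assignments:
        row = [(*(a.get("xy", (0.0, 0.0))), a["mu"])]
        if a["collimated"]:
            groups.append(
                SpotGroup(
                    gid=gid,
                    energy=a["energy"],
                    trimmers=a["trimmers"],
                    spot_ids=[a["spot_id"]],
                    total_mu=a["mu"],
                    spots=row,
                )
            )
            gid += 1
        else:
            key = a["energy"]
            if key not in uncoll:
                uncoll[key] = SpotGroup(
                    gid=-1,
                    energy=key,
                    trimmers=a["trimmers"],
                    spot_ids=[],
                    total_mu=0.0,
                    spots=[],
                    uncollimated=True,
                )
            g = uncoll[key]
            g.spot_ids.append(a["spot_id"])
            g.total_mu += a["mu"]
            g.spots.extend(row)
    for key in sorted(uncoll):
        g = uncoll[key]
        g.gid = gid
        gid += 1
        groups.append(g)
    return groups


def _coarsen(groups: list, max_size: int, next_gid: int) -> tuple:
    """One regrouping pass: within each layer greedily merge pairs of
    collimated groups with the smallest trimmer movement (max over the four
    edges, ties by summed movement then lowest gids), subject to the merged
    size staying within ``max_size``."""
    by_layer: dict = {}
    for g in groups:
        by_layer.setdefault(g.energy, []).append(g)
    out = []
    merged_any = False
    for energy in sorted(by_layer, reverse=True):
        work = [g for g in by_layer[energy] if not g.uncollimated]
        passthrough = [g for g in by_layer[energy] if g.uncollimated]
        while True:
            best = None
            for i in range(len(work)):
                ni = len(work[i].spot_ids)
                ei = work[i].trimmers.edges()
                for j in range(i + 1, len(work)):
                    if ni + len(work[j].spot_ids) > max_size:
                        continue
                    mv = np.abs(ei - work[j].trimmers.edges())
                    key = (mv.max(), mv.sum(), work[i].gid, work[j].gid)
                    if best is None or key < best[0]:
                        best = (key, i, j)
            if best is None:
                break
            _, i, j = best
            merged = _merge_groups(work[i], work[j], next_gid)
            next_gid += 1
            work = [g for k, g in enumerate(work) if k not in (i, j)] + [merged]
            merged_any = True
        out.extend(sorted(work, key=lambda g: g.gid) + passthrough)
    return out, next_gid, merged_any


def regroup_spots(
    assignments: list,
    time_goal: float,
    kin: KinematicsModel,
    tp: TimeModelParams,
    aco_settings: ACOSettings | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Iteratively coarsen spot groups until the modeled time meets the goal.

    Starting from one group per collimated spot (plus one uncollimated
    group per layer), each iteration raises the permitted group size by one,
    merges same-layer groups with minimal shared-trimmer movement, and
    re-runs the ACO sequencer.  Stops when the best modeled total time is
    within the goal or no further merge is possible (then the best-effort
    sequence is returned with a warning flag).

    Returns ``(sequence, trace)`` where ``trace`` lists the best total time
    seen at the end of each iteration (non-increasing by construction).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    groups = initial_groups(assignments)
    next_gid = max(g.gid for g in groups) + 1
    best_seq: DeliverySequence | None = None
    trace: list = []
    max_size = 1
    while True:
        if len(groups) == 1:
            seq = evaluate_sequence(groups, kin, tp)
        else:
            prob = _SeqProblem(groups, kin, tp)
            tau = prob.tau.copy()
            np.fill_diagonal(tau, 0.0)
            tau_max = tau.max()
            omega = np.ones_like(tau) if tau_max == 0 else 1.0 - tau / tau_max
            seq = aco_optimize(groups, omega, kin, tp, aco_settings, rng, _problem=prob)
        if best_seq is None or seq.total_time < best_seq.total_time:
            best_seq = seq
        trace.append(best_seq.total_time)
        if best_seq.total_time <= time_goal:
            return best_seq, trace
        max_size += 1
        groups, next_gid, merged_any = _coarsen(groups, max_size, next_gid)
        if not merged_any:
            return replace(best_seq, warning="time goal unreachable: groups fully merged"), trace


# ---------------------------------------------------------------------------
# PLD-style export


_PLD_VERSION = "dcsplan-pld-1"


def export_pld(seq: DeliverySequence, path, machine_note: str = "") -> None:
    """Write the delivery sequence as a PLD-style plain-text file.

    One block per group in delivery order; spot rows carry BEV x, y, MU and
    the four absolute trimmer edges (mm, isocenter plane).  Floats use
    ``repr`` so the companion reader round-trips bit-exactly.
    """
    energies = [g.energy for g in seq.groups]
    if any(b > a for a, b in zip(energies, energies[1:])):
        raise ValueError("sequence not in non-increasing energy order")
    with open(path, "w") as fh:
        fh.write(f"# {_PLD_VERSION}\n")
        if machine_note:
            fh.write(f"# machine: {machine_note}\n")
        fh.write(f"# total_time_s {seq.total_time!r}\n")
        fh.write("# columns: spot_x spot_y mu tx1 tx2 ty1 ty2\n")
        for g in seq.groups:
            e = [float(v) for v in g.trimmers.edges()]
            fh.write(
                f"group {g.gid} energy {float(g.energy)!r} nspots {len(g.spots)} "
                f"uncollimated {int(g.uncollimated)}\n"
            )
            for x, y, mu in g.spots:
                fh.write(
                    f"{float(x)!r} {float(y)!r} {float(mu)!r} "
                    f"{e[0]!r} {e[1]!r} {e[2]!r} {e[3]!r}\n"
                )


def read_pld(path) -> list:
    """Read a PLD-style file back into a list of :class:`SpotGroup`."""
    groups: list = []
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("group "):
                tok = line.split()
                current = SpotGroup(
                    gid=int(tok[1]),
                    energy=float(tok[3]),
                    trimmers=TrimmerSet(0, 0, 0, 0),
                    spot_ids=[],
                    total_mu=0.0,
                    spots=[],
                    uncollimated=bool(int(tok[7])),
                )
                groups.append(current)
                continue
            vals = [float(v) for v in line.split()]
            current.spots.append((vals[0], vals[1], vals[2]))
            current.total_mu += vals[2]
            current.trimmers = TrimmerSet(*vals[3:7])
    return groups
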