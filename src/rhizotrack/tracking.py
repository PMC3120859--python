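"""Nuclear identity tracking as a multidimensional assignment problem.

Identity assignments across time are a forest of trees: nodes are
segmented nuclei, an edge (i -> j) asserts that j is the same nucleus as i
at a later time point.  A configuration is scored by an energy in µm²:

* every edge contributes its squared spatial displacement plus a penalty
  per skipped time point (isolated detection gaps are allowed);
* every node contributes ``lambda * [f(n_parents) + g(n_children)]`` where
  f(1) = g(1) = 0, f(0)/g(0) penalize trajectories that fail to continue
  backward/forward in time (waived at the first/last observed frames),
  f(2) is a finite fusion penalty so segmentation artifacts do not break
  neighbouring trajectories, and g(2) is a branching term designed to be
  negligible for true cell divisions — symmetric, anti-parallel daughter
  displacements of ~2.6 µm — and significant for division look-alikes.

The terminal penalties f(0) + g(0) must exceed the square of the largest
plausible per-step displacement (d_max = 5 µm) while staying within the
square of the typical inter-nuclear distance (d_nn = 10 µm); parameters
violating this window are rejected.

Optimization starts from a greedy nearest-neighbour configuration and
refines it by simulated annealing: move targets are sampled with
probability proportional to the energy they contribute, proposals cut,
add or change one link (optionally two serial moves), acceptance follows
the Metropolis criterion under an exponentially cooled temperature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .types import NucleusRecord

__all__ = [
    "EnergyParams",
    "AnnealSchedule",
    "AssignmentForest",
    "Trajectory",
    "TrajectorySet",
    "edge_energy",
    "node_penalty",
    "total_energy",
    "greedy_init",
    "anneal",
    "extract_trajectories",
    "brute_force_optimum",
    "propose_move",
]

_BIG = 1e12  # effectively forbidden configuration


@dataclass
class EnergyParams:
    """Coefficients of the assignment energy (all spatial terms in µm²)."""

    lambda_: float = 1.0
    f0: float = 25.0
    g0: float = 25.0
    fusion_penalty: float = 60.0
    gap_penalty_per_step: float = 10.0
    max_gap_steps: int = 1
    mu_div: float = 2.6
    delta_threshold: float = 0.6
    kappa_disp: float = 4.0
    kappa_angle: float = 25.0
    d_max: float = 5.0
    d_nn: float = 10.0
    max_children: int = 2
    max_parents: int = 2

    def __post_init__(self) -> None:
        if not (self.f0 + self.g0 > self.d_max**2):
            raise ValueError(
                "f0 + g0 must exceed d_max^2 (the largest plausible squared "
                "per-step displacement)"
            )
        if not (self.f0 + self.g0 <= self.d_nn**2):
            raise ValueError(
                "f0 + g0 must not exceed d_nn^2 (the typical squared "
                "inter-nuclear distance)"
            )
        for name in (
            "lambda_",
            "f0",
            "g0",
            "fusion_penalty",
            "gap_penalty_per_step",
            "kappa_disp",
            "kappa_angle",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.max_gap_steps < 0:
            raise ValueError("max_gap_steps must be >= 0")


@dataclass
class AnnealSchedule:
    """Annealing schedule: equilibrate at ``t_initial`` (an estimate of
    the critical temperature), then cool exponentially per move."""

    t_initial: float = 25.0
    equilibration_moves: int = 5000
    cooling_constant: float = 1e-5
    total_moves: int = 100000
    serial_move_prob: float = 0.5
    t_floor: float = 1e-3
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.t_initial <= 0:
            raise ValueError("t_initial must be > 0")
        if not (0 < self.cooling_constant < 1):
            raise ValueError("cooling_constant must be in (0, 1)")
        if self.total_moves < 1:
            raise ValueError("total_moves must be >= 1")

    @classmethod
    def for_problem(
        cls,
        n_records: int,
        moves_per_record: int = 200,
        t_initial: float = 25.0,
        t_final: float = 0.1,
        seed: int | None = 0,
    ) -> "AnnealSchedule":
        """Default schedule: 200 moves per record, cooled so the last
        move sits at ``t_final``."""
        total = max(2000, moves_per_record * n_records)
        eq = min(5000, total // 4)
        cooling = np.log(t_initial / t_final) / max(1, total - eq)
        return cls(
            t_initial=t_initial,
            equilibration_moves=eq,
            cooling_constant=float(min(0.5, cooling)),
            total_moves=total,
            seed=seed,
        )

    def temperature(self, k: int) -> float:
        if k < self.equilibration_moves:
            return self.t_initial
        return max(
            self.t_floor,
            self.t_initial
            * np.exp(-self.cooling_constant * (k - self.equilibration_moves)),
        )


@dataclass
class AssignmentForest:
    """Directed forward-in-time links between record indices."""

    links: list[tuple[int, int]]
    n_records: int

    def children_of(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_records)]
        for i, j in self.links:
            out[i].append(j)
        return out

    def parents_of(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_records)]
        for i, j in self.links:
            out[j].append(i)
        return out

    def validate(self, frames: np.ndarray, params: EnergyParams) -> None:
        children = self.children_of()
        parents = self.parents_of()
        for i, j in self.links:
            gap = frames[j] - frames[i]
            if gap < 1:
                raise ValueError(f"link ({i}, {j}) does not go forward in time")
            if gap > params.max_gap_steps + 1:
                raise ValueError(f"link ({i}, {j}) skips too many time points")
        for i in range(self.n_records):
            if len(children[i]) > params.max_children:
                raise ValueError(f"record {i} has too many children")
            if len(parents[i]) > params.max_parents:
                raise ValueError(f"record {i} has too many parents")


# ---------------------------------------------------------------------------
# energy terms

def _edge_energy_arr(
    pos: np.ndarray, frames: np.ndarray, i: int, j: int, p: EnergyParams
) -> float:
    d = pos[j] - pos[i]
    skipped = int(frames[j] - frames[i]) - 1
    return float(d @ d) + p.gap_penalty_per_step * skipped


def edge_energy(
    i: NucleusRecord, j: NucleusRecord, params: EnergyParams, time_step: float = 10.0
) -> float:
    """Energy of a single identity link, µm²: squared displacement plus a
    penalty per skipped time point."""
    steps = int(round((j.time - i.time) / time_step))
    if steps < 1:
        raise ValueError("links must go forward in time")
    if steps > params.max_gap_steps + 1:
        raise ValueError(f"link skips {steps - 1} frames, more than allowed")
    d = np.asarray(j.centroid, float) - np.asarray(i.centroid, float)
    return float(d @ d) + params.gap_penalty_per_step * (steps - 1)


def _branch_penalty(
    disp1: np.ndarray, disp2: np.ndarray, p: EnergyParams
) -> float:
    """g(2): negligible for symmetric anti-parallel displacements of
    magnitude ~mu_div, quadratic hinge + cosine otherwise."""
    n1 = float(np.linalg.norm(disp1))
    n2 = float(np.linalg.norm(disp2))
    pen = 0.0
    for n in (n1, n2):
        delta = abs(n - p.mu_div)
        if delta > p.delta_threshold:
            pen += p.kappa_disp * (delta - p.delta_threshold) ** 2
    if n1 > 1e-12 and n2 > 1e-12:
        cosphi = float(disp1 @ disp2) / (n1 * n2)
    else:
        cosphi = 1.0  # zero-length displacement: fully penalized angle
    pen += p.kappa_angle * 0.5 * (1.0 + cosphi)
    return pen


def node_penalty(
    record: NucleusRecord,
    n_prev: int,
    n_next: int,
    children_displacements: list[np.ndarray] | None,
    params: EnergyParams,
    at_first_frame: bool = False,
    at_last_frame: bool = False,
) -> float:
    """lambda * [f(n_parents) + g(n_children)] for one node, µm²."""
    pen = 0.0
    if n_prev == 0:
        pen += 0.0 if at_first_frame else params.f0
    elif n_prev == 1:
        pen += 0.0
    elif n_prev == 2:
        pen += params.fusion_penalty
    else:
        return _BIG
    if n_next == 0:
        pen += 0.0 if at_last_frame else params.g0
    elif n_next == 1:
        pen += 0.0
    elif n_next == 2:
        if children_displacements is None or len(children_displacements) != 2:
            raise ValueError("branching node needs its two daughter displacements")
        pen += _branch_penalty(
            children_displacements[0], children_displacements[1], params
        )
    else:
        return _BIG
    return params.lambda_ * pen


# ---------------------------------------------------------------------------
# internal problem/state

class _Problem:
    """Static arrays and candidate link lists for one tracking run."""

    def __init__(self, records: list[NucleusRecord], params: EnergyParams):
        self.records = records
        self.params = params
        n = len(records)
        self.pos = np.array([r.centroid for r in records], dtype=float).reshape(n, 3)
        times = np.array([r.time for r in records], dtype=float)
        self.unique_times = np.unique(times)
        self.frames = np.searchsorted(self.unique_times, times)
        self.first_frame = 0
        self.last_frame = len(self.unique_times) - 1
        by_frame: dict[int, np.ndarray] = {
            f: np.nonzero(self.frames == f)[0] for f in range(len(self.unique_times))
        }
        self.by_frame = by_frame
        trees = {
            f: cKDTree(self.pos[idx]) if len(idx) else None
            for f, idx in by_frame.items()
        }
        self.cand_next: list[list[int]] = [[] for _ in range(n)]
        self.cand_prev: list[list[int]] = [[] for _ in range(n)]
        for f in range(len(self.unique_times)):
            src = by_frame[f]
            if not len(src):
                continue
            for g in range(f + 1, min(f + params.max_gap_steps + 2, len(self.unique_times))):
                tgt = by_frame[g]
                if tgt is None or not len(tgt):
                    continue
                pairs = trees[f].query_ball_tree(trees[g], r=params.d_nn)
                for a, neigh in zip(src, pairs):
                    for b_loc in neigh:
                        b = tgt[b_loc]
                        self.cand_next[a].append(int(b))
                        self.cand_prev[int(b)].append(int(a))
        for lst in self.cand_next:
            lst.sort()
        for lst in self.cand_prev:
            lst.sort()
        # precomputed per-candidate-pair quantities for the hot loop
        self.edge_e: dict[tuple[int, int], float] = {}
        self.dvec: dict[tuple[int, int], tuple[float, float, float]] = {}
        self.dnorm: dict[tuple[int, int], float] = {}
        gp = params.gap_penalty_per_step
        for a, lst in enumerate(self.cand_next):
            pa = self.pos[a]
            fa = self.frames[a]
            for b in lst:
                d = self.pos[b] - pa
                key = (a, b)
                self.dvec[key] = (d[0], d[1], d[2])
                self.dnorm[key] = float(np.sqrt(d @ d))
                self.edge_e[key] = float(d @ d) + gp * (
                    int(self.frames[b] - fa) - 1
                )
        self.at_first = [f == self.first_frame for f in self.frames]
        self.at_last = [f == self.last_frame for f in self.frames]

    def edge(self, i: int, j: int) -> float:
        e = self.edge_e.get((i, j))
        if e is not None:
            return e
        return _edge_energy_arr(self.pos, self.frames, i, j, self.params)

    def penalty(self, i: int, parents_i: list[int], children_i: list[int]) -> float:
        """Pure-python node penalty using precomputed displacements."""
        p = self.params
        n_prev = len(parents_i)
        n_next = len(children_i)
        if n_prev > 2 or n_next > 2:
            return _BIG
        pen = 0.0
        if n_prev == 0:
            if not self.at_first[i]:
                pen += p.f0
        elif n_prev == 2:
            pen += p.fusion_penalty
        if n_next == 0:
            if not self.at_last[i]:
                pen += p.g0
        elif n_next == 2:
            c1, c2 = children_i
            n1 = self.dnorm.get((i, c1))
            n2 = self.dnorm.get((i, c2))
            if n1 is None or n2 is None:  # non-candidate link (toy fixtures)
                v1 = self.pos[c1] - self.pos[i]
                v2 = self.pos[c2] - self.pos[i]
                pen += _branch_penalty(v1, v2, p)
            else:
                b = 0.0
                d1 = abs(n1 - p.mu_div)
                if d1 > p.delta_threshold:
                    b += p.kappa_disp * (d1 - p.delta_threshold) ** 2
                d2 = abs(n2 - p.mu_div)
                if d2 > p.delta_threshold:
                    b += p.kappa_disp * (d2 - p.delta_threshold) ** 2
                v1 = self.dvec[(i, c1)]
                v2 = self.dvec[(i, c2)]
                if n1 > 1e-12 and n2 > 1e-12:
                    cosphi = (
                        v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]
                    ) / (n1 * n2)
                else:
                    cosphi = 1.0
                b += p.kappa_angle * 0.5 * (1.0 + cosphi)
                pen += b
        return p.lambda_ * pen


class _Fenwick:
    """Fenwick tree over non-negative weights with prefix sampling."""

    def __init__(self, n: int):
        self.n = n
        self.tree = [0.0] * (n + 1)
        self.vals = [0.0] * n
        self.total = 0.0

    def set(self, i: int, value: float) -> None:
        delta = value - self.vals[i]
        self.vals[i] = value
        self.total += delta
        k = i + 1
        tree = self.tree
        while k <= self.n:
            tree[k] += delta
            k += k & (-k)

    def sample(self, u: float) -> int:
        """Index i such that u falls in its weight bucket (u in [0, total))."""
        # descend the implicit tree
        pos = 0
        bitmask = 1 << (self.n.bit_length())
        tree = self.tree
        while bitmask:
            nxt = pos + bitmask
            if nxt <= self.n and tree[nxt] <= u:
                u -= tree[nxt]
                pos = nxt
            bitmask >>= 1
        return min(pos, self.n - 1)


class _State:
    """Mutable assignment configuration with incremental energies."""

    def __init__(self, problem: _Problem, weight_floor: float = 0.5):
        self.pb = problem
        n = len(problem.records)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.parents: list[list[int]] = [[] for _ in range(n)]
        self.contrib = [0.0] * n
        self.weight_floor = weight_floor
        self.fen = _Fenwick(n)
        self.energy = 0.0
        for i in range(n):
            self._set_contrib(i, problem.penalty(i, [], []))

    def _set_contrib(self, i: int, value: float) -> None:
        self.energy += value - self.contrib[i]
        self.contrib[i] = value
        self.fen.set(i, min(value, _BIG) + self.weight_floor)

    def _node_value(self, i: int, pars: list[int], chs: list[int]) -> float:
        pb = self.pb
        edge_e = pb.edge_e
        half = 0.0
        for c in chs:
            half += edge_e.get((i, c)) or pb.edge(i, c)
        for p in pars:
            half += edge_e.get((p, i)) or pb.edge(p, i)
        return pb.penalty(i, pars, chs) + 0.5 * half

    def _refresh(self, nodes) -> None:
        for i in nodes:
            self._set_contrib(
                i, self._node_value(i, self.parents[i], self.children[i])
            )

    def apply(self, ops: list[tuple[str, int, int]]) -> None:
        touched: set[int] = set()
        for kind, a, b in ops:
            if kind == "add":
                self.children[a].append(b)
                self.parents[b].append(a)
            else:  # cut
                self.children[a].remove(b)
                self.parents[b].remove(a)
            touched.add(a)
            touched.add(b)
        self._refresh(touched)

    @staticmethod
    def inverse(ops: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
        flip = {"add": "cut", "cut": "add"}
        return [(flip[k], a, b) for k, a, b in reversed(ops)]

    def delta_energy(self, ops: list[tuple[str, int, int]]) -> float:
        """Energy change of ``ops`` without mutating the configuration."""
        scratch: dict[int, tuple[list[int], list[int]]] = {}
        for kind, a, b in ops:
            if a not in scratch:
                scratch[a] = (list(self.children[a]), list(self.parents[a]))
            if b not in scratch:
                scratch[b] = (list(self.children[b]), list(self.parents[b]))
            if kind == "add":
                scratch[a][0].append(b)
                scratch[b][1].append(a)
            else:
                scratch[a][0].remove(b)
                scratch[b][1].remove(a)
        dE = 0.0
        for i, (chs, pars) in scratch.items():
            dE += self._node_value(i, pars, chs) - self.contrib[i]
        return dE

    def recompute_energy(self) -> float:
        pb = self.pb
        total = 0.0
        for i in range(len(pb.records)):
            total += pb.penalty(i, self.parents[i], self.children[i])
            total += sum(pb.edge(i, c) for c in self.children[i])
        return total

    def links(self) -> list[tuple[int, int]]:
        return [(i, j) for i in range(len(self.children)) for j in self.children[i]]

    def to_forest(self) -> AssignmentForest:
        return AssignmentForest(sorted(self.links()), len(self.pb.records))


def _enumerate_moves(
    state: _State, node: int, kind: str
) -> list[list[tuple[str, int, int]]]:
    """All atomic moves of one kind (cut/add/change) touching ``node``."""
    pb = state.pb
    p = pb.params
    moves: list[list[tuple[str, int, int]]] = []
    if kind == "cut":
        for c in state.children[node]:
            moves.append([("cut", node, c)])
        for par in state.parents[node]:
            moves.append([("cut", par, node)])
    elif kind == "add":
        if len(state.children[node]) < p.max_children:
            for c in pb.cand_next[node]:
                if c not in state.children[node] and len(state.parents[c]) < p.max_parents:
                    moves.append([("add", node, c)])
        if len(state.parents[node]) < p.max_parents:
            for par in pb.cand_prev[node]:
                if par not in state.parents[node] and len(state.children[par]) < p.max_children:
                    moves.append([("add", par, node)])
    else:  # change: replace the partner of an existing incident link
        for c in state.children[node]:
            for c2 in pb.cand_next[node]:
                if c2 != c and c2 not in state.children[node] and len(state.parents[c2]) < p.max_parents:
                    moves.append([("cut", node, c), ("add", node, c2)])
        for par in state.parents[node]:
            for p2 in pb.cand_prev[node]:
                if p2 != par and p2 not in state.parents[node] and len(state.children[p2]) < p.max_children:
                    moves.append([("cut", par, node), ("add", p2, node)])
    return moves


def propose_move(
    state: _State, rng: np.random.Generator, target: int | None = None
) -> tuple[list[tuple[str, int, int]] | None, int]:
    """Sample one candidate move.

    The target node is drawn with probability proportional to its energy
    contribution (plus a floor so zero-energy nodes stay reachable) unless
    given explicitly; the move kind is uniform among cut/add/change and a
    uniform choice is made among that kind's candidates.  The ops are
    ``None`` when the chosen kind offers no candidate (a no-op); the
    sampled target is returned either way.
    """
    if target is None:
        target = state.fen.sample(rng.random() * state.fen.total)
    kind = ("cut", "add", "change")[int(rng.random() * 3)]
    moves = _enumerate_moves(state, target, kind)
    if not moves:
        return None, target
    return moves[int(rng.random() * len(moves))], target


def greedy_init(
    records: list[NucleusRecord],
    params: EnergyParams | None = None,
    _problem: _Problem | None = None,
    _state: _State | None = None,
) -> AssignmentForest:
    """Initial configuration: each nucleus links to its nearest neighbour
    at the next time point if within d_nn and the link lowers the energy;
    ties broken by ascending record index."""
    params = params or EnergyParams()
    pb = _problem or _Problem(records, params)
    state = _state if _state is not None else _State(pb)
    _greedy_fill(state)
    return state.to_forest()


def _greedy_fill(state: _State) -> None:
    pb = state.pb
    for f in range(len(pb.unique_times) - 1):
        src = pb.by_frame[f]
        nxt = pb.by_frame[f + 1]
        if not len(src) or not len(nxt):
            continue
        tree = cKDTree(pb.pos[nxt])
        dists, locs = tree.query(pb.pos[src])
        for a, d, loc in zip(src, dists, locs):
            if d > pb.params.d_nn:
                continue
            b = int(nxt[loc])
            if len(state.parents[b]) >= pb.params.max_parents:
                continue
            ops = [("add", int(a), b)]
            if state.delta_energy(ops) < 0:
                state.apply(ops)


def total_energy(
    forest: AssignmentForest,
    records: list[NucleusRecord],
    params: EnergyParams | None = None,
) -> float:
    """Full energy of a configuration (validates the forest first)."""
    params = params or EnergyParams()
    pb = _Problem(records, params)
    forest.validate(pb.frames, params)
    children = forest.children_of()
    parents = forest.parents_of()
    total = 0.0
    for i in range(len(records)):
        total += pb.penalty(i, parents[i], children[i])
        total += sum(pb.edge(i, c) for c in children[i])
    return total


def anneal(
    records: list[NucleusRecord],
    params: EnergyParams | None = None,
    schedule: AnnealSchedule | None = None,
    self_check_every: int = 10000,
) -> AssignmentForest:
    """Optimize the assignment by Metropolis simulated annealing.

    Starts from the greedy configuration, equilibrates at ``t_initial``,
    cools exponentially, and returns the lowest-energy configuration
    visited.  Incremental energy bookkeeping is verified against a full
    recomputation every ``self_check_every`` moves.  Deterministic for a
    given schedule seed.
    """
    params = params or EnergyParams()
    pb = _Problem(records, params)
    schedule = schedule or AnnealSchedule.for_problem(len(records))
    rng = np.random.default_rng(schedule.seed)
    state = _State(pb)
    _greedy_fill(state)
    greedy_energy = state.energy

    best_energy = state.energy
    journal: list[tuple[str, int, int]] = []  # accepted ops since best
    from math import exp

    T = schedule.t_initial
    decay = float(np.exp(-schedule.cooling_constant))
    t_floor = schedule.t_floor
    eq = schedule.equilibration_moves
    rand = rng.random
    for k in range(schedule.total_moves):
        if k >= eq and T > t_floor:
            T = max(t_floor, T * decay)
        proposal = propose_move(state, rng)
        n_serial = 1 if rand() < schedule.serial_move_prob else 0
        for serial in range(1 + n_serial):
            ops, target = proposal
            if ops is None:
                break
            dE = state.delta_energy(ops)
            if dE <= 0 or rand() < exp(-dE / T):
                state.apply(ops)
                journal.extend(ops)
                if state.energy < best_energy - 1e-9:
                    best_energy = state.energy
                    journal.clear()
            if serial < n_serial:
                # second serial move targets a node touched by the first
                touched = sorted({a for _, a, b in ops} | {b for _, a, b in ops})
                proposal = propose_move(
                    state, rng, target=touched[int(rand() * len(touched))]
                )
        if self_check_every and (k + 1) % self_check_every == 0:
            full = state.recompute_energy()
            if not np.isclose(full, state.energy, rtol=1e-9, atol=1e-6):
                raise AssertionError(
                    f"incremental energy {state.energy} diverged from "
                    f"recomputed {full}"
                )

    # rewind to the best configuration ever visited
    if journal:
        state.apply(_State.inverse(journal))
    state.energy = state.recompute_energy()
    if state.energy > greedy_energy + 1e-6:
        raise AssertionError("annealing ended above the greedy energy")
    return state.to_forest()


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class Trajectory:
    """One nuclear identity: record indices in time order."""

    id: int
    record_indices: list[int]
    parent: int = -1  # trajectory id of the parent identity, -1 if none
    fusion_flagged: bool = False


@dataclass
class TrajectorySet:
    trajectories: list[Trajectory]
    #: branch points: (parent record, (daughter record, daughter record))
    division_candidates: list[tuple[int, tuple[int, int]]] = field(
        default_factory=list
    )
    #: fusion points flagged for manual review: (parent records, child record)
    fusions: list[tuple[tuple[int, ...], int]] = field(default_factory=list)

    def to_links(self) -> list[tuple[int, int]]:
        links = []
        for tr in self.trajectories:
            links.extend(zip(tr.record_indices[:-1], tr.record_indices[1:]))
        for parent_rec, daughters in self.division_candidates:
            for d in daughters:
                links.append((parent_rec, d))
        for parents, child in self.fusions:
            for p in parents:
                links.append((p, child))
        return sorted(set(links))


def extract_trajectories(
    forest: AssignmentForest, records: list[NucleusRecord]
) -> TrajectorySet:
    """Traverse the forest into per-identity time series.

    A trajectory runs along chain links; a branching node closes its
    trajectory and opens one per daughter (flagged as a division
    candidate); a node with two parents starts a fresh, fusion-flagged
    trajectory so the event can be reviewed manually.
    """
    children = forest.children_of()
    parents = forest.parents_of()
    times = np.array([r.time for r in records])
    order = np.argsort(times, kind="stable")
    traj_of_record = {}
    trajectories: list[Trajectory] = []
    divisions: list[tuple[int, tuple[int, int]]] = []
    fusions: list[tuple[tuple[int, ...], int]] = []

    for i in order:
        i = int(i)
        pars = parents[i]
        continues = (
            len(pars) == 1
            and len(children[pars[0]]) == 1
            and pars[0] in traj_of_record
        )
        if continues:
            tid = traj_of_record[pars[0]]
            trajectories[tid].record_indices.append(i)
            traj_of_record[i] = tid
        else:
            tid = len(trajectories)
            parent_tid = -1
            fusion = len(pars) >= 2
            if len(pars) == 1 and pars[0] in traj_of_record:
                parent_tid = traj_of_record[pars[0]]
            trajectories.append(
                Trajectory(tid, [i], parent=parent_tid, fusion_flagged=fusion)
            )
            traj_of_record[i] = tid
            if fusion:
                fusions.append((tuple(sorted(pars)), i))
    for i, ch in enumerate(children):
        if len(ch) == 2:
            divisions.append((i, (min(ch), max(ch))))
    return TrajectorySet(trajectories, divisions, fusions)


# ---------------------------------------------------------------------------
# exhaustive oracle (toy instances)

def brute_force_optimum(
    records: list[NucleusRecord],
    params: EnergyParams | None = None,
    max_links_per_pair: int = 18,
) -> tuple[AssignmentForest, float]:
    """Exact global optimum by exhaustive enumeration.

    Only for toy instances with ``max_gap_steps == 0``: without temporal
    gaps the energy separates over consecutive frame pairs (each node's
    parent count depends only on the earlier pair, its child count only
    on the later), so the optimum is the union of per-pair optima, each
    found by enumerating all candidate link subsets.
    """
    params = params or EnergyParams()
    if params.max_gap_steps != 0:
        raise NotImplementedError(
            "the exhaustive oracle requires max_gap_steps = 0"
        )
    pb = _Problem(records, params)
    n_frames = len(pb.unique_times)
    all_links: list[tuple[int, int]] = []
    total = 0.0
    for f in range(n_frames - 1):
        src = list(map(int, pb.by_frame[f]))
        tgt = list(map(int, pb.by_frame[f + 1]))
        cand = [
            (i, j) for i in src for j in pb.cand_next[i] if pb.frames[j] == f + 1
        ]
        if len(cand) > max_links_per_pair:
            raise ValueError(
                f"{len(cand)} candidate links between frames {f} and "
                f"{f + 1}: too many to enumerate"
            )
        best_e, best_subset = np.inf, ()
        for r_size in range(len(cand) + 1):
            for subset in itertools.combinations(cand, r_size):
                n_next = {i: 0 for i in src}
                n_prev = {j: 0 for j in tgt}
                ok = True
                for i, j in subset:
                    n_next[i] += 1
                    n_prev[j] += 1
                    if (
                        n_next[i] > params.max_children
                        or n_prev[j] > params.max_parents
                    ):
                        ok = False
                        break
                if not ok:
                    continue
                e = sum(pb.edge(i, j) for i, j in subset)
                for i in src:
                    ch = [j for (a, j) in subset if a == i]
                    e += _g_only(pb, i, ch, params)
                for j in tgt:
                    pa = [a for (a, b) in subset if b == j]
                    e += _f_only(pb, j, pa, params)
                if e < best_e:
                    best_e, best_subset = e, subset
        total += best_e
        all_links.extend(best_subset)
    forest = AssignmentForest(sorted(all_links), len(records))
    return forest, float(total)


def _g_only(pb: _Problem, i: int, children: list[int], params: EnergyParams) -> float:
    at_last = pb.frames[i] == pb.last_frame
    if len(children) == 0:
        return 0.0 if at_last else params.lambda_ * params.g0
    if len(children) == 1:
        return 0.0
    if len(children) == 2:
        disps = [pb.pos[c] - pb.pos[i] for c in children]
        return params.lambda_ * _branch_penalty(disps[0], disps[1], params)
    return _BIG


def _f_only(pb: _Problem, j: int, parents: list[int], params: EnergyParams) -> float:
    at_first = pb.frames[j] == pb.first_frame
    if len(parents) == 0:
        return 0.0 if at_first else params.lambda_ * params.f0
    if len(parents) == 1:
        return 0.0
    if len(parents) == 2:
        return params.lambda_ * params.fusion_penalty
    return _BIG
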