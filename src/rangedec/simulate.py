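"""Synthetic chronograms and range data with known ground truth.

The generator stands in for unreleased empirical data: a Yule (pure-birth)
tree, a root range drawn from the root prior, exact (Gillespie) stochastic
simulation of the anagenetic gain/loss process along branches with
epoch-aware rates, and cladogenetic draws at nodes.  Every dataset carries a
complete event log that replays from the root state to the tip ranges, so
parameter- and event-recovery can be tested against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dispersal import EpochSet, load_bundled_matrix, slice_branch
from .geography import RangeSpace, enumerate_ranges, load_bundled_area_system
from .model import DECParams, KIND_NAMES, VICARIANCE, _clado_table, build_generator
from .reconstruct import EventCounts
from .treeio import Chronogram, TipRangeTable, read_newick

__all__ = [
    "BranchEvent",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_yule",
    "simulate_dec",
    "simulate_branch",
    "make_liolaemus_like",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    return np.random.default_rng(seed)


def simulate_yule(
    n_tips: int, birth_rate: float = 1.0, seed=None, height: float | None = None
) -> Chronogram:
    """Simulate an ultrametric pure-birth tree.

    Starts from the root split (two lineages), waits Exp(k*birth_rate)
    between successive splits, picks the splitting lineage uniformly, and
    after the n-th tip appears runs a final Exp(n*birth_rate) stem to the
    present.  ``height`` optionally rescales all branch lengths so the root
    sits at exactly that age.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed)
    t = 0.0
    left, right = {"birth": 0.0}, {"birth": 0.0}
    root = {"birth": 0.0, "split": 0.0, "children": [left, right]}
    active = [left, right]
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        nd = active[int(rng.integers(k))]
        nd["split"] = t
        c1, c2 = {"birth": t}, {"birth": t}
        nd["children"] = [c1, c2]
        active[active.index(nd)] = c1
        active.append(c2)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    scale = (height / t) if height is not None else 1.0

    counter = [0]

    def nwk(nd, parent_split):
        my_time = nd.get("split", t)
        length = (my_time - parent_split) * scale
        if "children" in nd:
            inner = ",".join(nwk(c, my_time) for c in nd["children"])
            return f"({inner}):{length:.12g}"
        counter[0] += 1
        return f"t{counter[0]}:{length:.12g}"

    inner = ",".join(nwk(c, 0.0) for c in root["children"])
    return read_newick(f"({inner});")


@dataclass(frozen=True)
class BranchEvent:
    """One anagenetic event on the branch subtending ``node_id``."""

    node_id: str
    age: float
    kind: str  # "gain" | "loss"
    area: int
    from_bits: int
    to_bits: int


@dataclass
class SimulatedDataset:
    """A simulated chronogram + ranges with the full generating history."""

    chronogram: Chronogram
    tip_ranges: TipRangeTable
    space: RangeSpace
    params: DECParams
    root_bits: int
    node_states: dict[str, int]  # range on arrival at each node
    node_outcomes: dict[str, tuple[int, int, str]]  # left, right, kind
    events: list[BranchEvent] = field(repr=False)

    def true_counts(self) -> EventCounts:
        """Ground-truth global event tallies from the event log."""
        gains = sum(1 for ev in self.events if ev.kind == "gain")
        losses = sum(1 for ev in self.events if ev.kind == "loss")
        vic = sum(
            1
            for o in self.node_outcomes.values()
            if o is not None and o[2] == KIND_NAMES[VICARIANCE]
        )
        return EventCounts(dispersal=gains, vicariance=vic, extinction=losses)

    def replay(self) -> dict[str, int]:
        """Re-derive every tip range from root state + outcomes + event log.

        Used as the replay oracle: the result must equal the recorded tip
        ranges exactly.
        """
        tree = self.chronogram
        by_child: dict[str, list[BranchEvent]] = {}
        for ev in self.events:
            by_child.setdefault(ev.node_id, []).append(ev)
        tips: dict[str, int] = {}
        state = {tree.root: self.root_bits}
        for i in reversed(range(tree.n_nodes)):  # preorder
            if tree.is_tip[i]:
                tips[tree.labels[i]] = state[i]
                continue
            outcome = self.node_outcomes.get(tree.labels[i])
            if outcome is None:
                daughters = (0, 0)
            else:
                daughters = (outcome[0], outcome[1])
            for child, bits in zip(tree.children[i], daughters):
                child = int(child)
                for ev in sorted(by_child.get(tree.labels[child], []), key=lambda e: -e.age):
                    if ev.from_bits != bits:
                        raise AssertionError("event log does not chain")
                    bits = ev.to_bits
                state[child] = bits
        return tips


def _gillespie_segment(s, duration, Q, ranges, rng, events, node_id, age):
    """Exact simulation for one epoch segment; returns (state, age_at_end)."""
    remaining = duration
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            return s, age - remaining
        w = rng.exponential(1.0 / rate)
        if w >= remaining:
            return s, age - remaining
        remaining -= w
        age -= w
        row = Q[s].copy()
        row[s] = 0.0
        j = int(rng.choice(len(row), p=row / rate))
        fb, tb = ranges[s].bits, ranges[j].bits
        diff = fb ^ tb
        events.append(
            BranchEvent(
                node_id=node_id,
                age=age,
                kind="gain" if (tb & ~fb) else "loss",
                area=int(diff.bit_length() - 1) if diff else -1,
                from_bits=fb,
                to_bits=tb,
            )
        )
        s = j


def simulate_branch(
    space: RangeSpace,
    epochs: EpochSet,
    params: DECParams,
    start_bits: int,
    start_age: float,
    end_age: float,
    rng,
    events: list | None = None,
    node_id: str = "",
    Qs: list[np.ndarray] | None = None,
    connectivity_exit: str = "absorb",
) -> int:
    """Forward-simulate the anagenetic process along one branch; returns end bits."""
    rng = _rng(rng)
    if Qs is None:
        Qs = _epoch_generators(space, epochs, params, connectivity_exit)
    if events is None:
        events = []
    s = space.index_of[start_bits]
    age = start_age
    for dur, ep in slice_branch(start_age, end_age, epochs):
        s, age = _gillespie_segment(
            s, dur, Qs[ep], space.ranges, rng, events, node_id, age
        )
    return space.ranges[s].bits


def _epoch_generators(space, epochs, params, connectivity_exit="absorb"):
    built: dict[int, np.ndarray] = {}
    out = []
    for mult in epochs.multipliers:
        if id(mult) not in built:
            built[id(mult)] = build_generator(
                space, mult, params, connectivity_exit=connectivity_exit
            )
        out.append(built[id(mult)])
    return out


def simulate_dec(
    tree: Chronogram,
    space: RangeSpace,
    epochs: EpochSet,
    params: DECParams,
    seed=None,
    root_prior="uniform",
    max_retries: int = 100,
    connectivity_exit: str = "absorb",
) -> SimulatedDataset:
    """Forward-simulate ranges on a fixed chronogram under DEC.

    Lineages that reach the empty range stay extinct in place (the tree is
    given a priori); a dataset in which any tip ends empty is resampled, up
    to ``max_retries`` attempts.
    """
    rng = _rng(seed)
    if tree.height > epochs.oldest * (1 + 1e-9):
        raise ValueError("tree is older than the oldest epoch boundary")
    S = len(space)
    if isinstance(root_prior, str):
        if root_prior != "uniform":
            raise ValueError(f"unknown root prior {root_prior!r}")
        prior = np.full(S, 1.0 / (S - 1))
        prior[0] = 0.0
    else:
        prior = np.asarray(root_prior, dtype=float)
    Qs = _epoch_generators(space, epochs, params, connectivity_exit)
    anc, left, right, prob, kind = _clado_table(space)
    rows_of = {i: np.flatnonzero(anc == i) for i in range(1, S)}
    bits_arr = [r.bits for r in space.ranges]

    for _ in range(max_retries):
        events: list[BranchEvent] = []
        node_states: dict[str, int] = {}
        node_outcomes: dict[str, tuple[int, int, str] | None] = {}
        state_idx = {tree.root: int(rng.choice(S, p=prior))}
        empty_tip = False
        for i in reversed(range(tree.n_nodes)):  # preorder
            s = state_idx[i]
            if tree.is_tip[i]:
                node_states[tree.labels[i]] = bits_arr[s]
                if s == 0:
                    empty_tip = True
                continue
            node_states[tree.labels[i]] = bits_arr[s]
            if s == 0:
                node_outcomes[tree.labels[i]] = None
                daughters = (0, 0)
            else:
                rows = rows_of[s]
                o = int(rng.choice(rows, p=prob[rows] / prob[rows].sum()))
                node_outcomes[tree.labels[i]] = (
                    bits_arr[left[o]],
                    bits_arr[right[o]],
                    KIND_NAMES[int(kind[o])],
                )
                daughters = (int(left[o]), int(right[o]))
            for child, ds in zip(tree.children[i], daughters):
                child = int(child)
                age = tree.age[i]
                end = tree.age[child]
                sc = ds
                for dur, ep in slice_branch(age, end, epochs):
                    sc, age = _gillespie_segment(
                        sc, dur, Qs[ep], space.ranges, rng, events,
                        tree.labels[child], age,
                    )
                state_idx[child] = sc
        if empty_tip:
            continue
        tip_table = TipRangeTable(
            space.system,
            {lab: space.ranges[space.index_of[node_states[lab]]]
             for lab in tree.tip_labels},
        )
        return SimulatedDataset(
            chronogram=tree,
            tip_ranges=tip_table,
            space=space,
            params=params,
            root_bits=bits_arr[state_idx[tree.root]],
            node_states=node_states,
            node_outcomes=node_outcomes,
            events=events,
        )
    raise RuntimeError(
        f"simulation produced an empty-range tip in {max_retries} consecutive attempts"
    )


@dataclass
class SimulationConfig:
    """Everything needed to draw one synthetic dataset."""

    n_tips: int
    birth_rate: float
    params: DECParams
    seed: int
    height: float | None = None
    max_range_size: int | None = None
    constrained: bool = False

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")


def make_liolaemus_like(seed: int) -> SimulatedDataset:
    """The canonical end-to-end preset: 53 tips, 12 areas, height 18 Myr.

    Yule tree rescaled to 18 Myr, the bundled 12-area system, Matrix II
    multipliers in the three epochs (18-5.5, 5.5-1.25, 1.25-0 Myr), ranges
    capped at two areas, d = 0.05 and e = 0.01.  The generating process is
    the hard-constrained one (only adjacency-connected ranges arise), so
    every tip range is legal under both regimes of the scenario grid — as on
    the empirical data the preset stands in for, where both the constrained
    and the unconstrained analyses ran.
    """
    rng = _rng(seed)
    system = load_bundled_area_system()
    matrix = load_bundled_matrix("II", system)
    epochs = EpochSet.uniform([18.0, 5.5, 1.25], matrix)
    space = enumerate_ranges(system, constrained=True, max_size=2)
    tree = simulate_yule(53, birth_rate=1.0, seed=rng, height=18.0)
    return simulate_dec(
        tree, space, epochs, DECParams(d=0.05, e=0.01), seed=rng,
        connectivity_exit="drop",
    )
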