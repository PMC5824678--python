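"""Ancestral-range reconstruction and global event tallies.

The marginal probability of each ancestral range at an internal node is
obtained by combining the pruning (downpass) conditionals with an uppass
from the root prior.  Each node also gets a single best cladogenetic
scenario (ancestral range + daughter split), from which global dispersal,
vicariance and extinction events are tallied: a vicariant best split counts
one vicariance; along every branch the areas gained relative to the
inherited daughter range count as dispersals and the areas lost as
extinctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DECModel, DECParams, KIND_NAMES, VICARIANCE
from .treeio import Chronogram, TipRangeTable

__all__ = [
    "NodeReconstruction",
    "EventCounts",
    "ancestral_reconstruction",
    "count_events",
    "event_table",
    "range_probability_table",
    "summarize_clades",
]


@dataclass
class NodeReconstruction:
    """Relative ancestral-range probabilities and best split at one node."""

    node_id: str
    node_index: int
    age: float
    range_probs: np.ndarray = field(repr=False)
    labels: list[str] = field(repr=False)
    best_anc_bits: int
    best_left_bits: int
    best_right_bits: int
    best_kind: str
    best_prob: float

    @property
    def top_range_label(self) -> str:
        return self.labels[int(np.argmax(self.range_probs))]

    @property
    def top_prob(self) -> float:
        return float(self.range_probs.max())

    def top_ranges(self, k: int = 3) -> list[tuple[str, float]]:
        order = np.argsort(self.range_probs)[::-1][:k]
        return [(self.labels[int(i)], float(self.range_probs[int(i)])) for i in order]

    def formatted(self) -> str:
        """Report style ``"BL; 0.67"``: top range and its probability."""
        return f"{self.top_range_label}; {self.top_prob:.2g}"


@dataclass(frozen=True)
class EventCounts:
    """Global anagenetic/cladogenetic event tallies over the whole tree."""

    dispersal: int
    vicariance: int
    extinction: int


def ancestral_reconstruction(
    model: DECModel, params: DECParams
) -> list[NodeReconstruction]:
    """Marginal reconstruction at fixed parameters (normally the MLE).

    Returns one :class:`NodeReconstruction` per internal node, in postorder.
    The best split is the maximum-probability (ancestral range, daughter
    pair) scenario; ties are broken deterministically and symmetrically in
    the two children (larger probability, smaller ancestral range,
    lexicographic bitmask, then daughter assignment keyed on child ids).
    """
    tree = model.tree
    space = model.space
    S = len(space)
    anc, left, right, prob, kind = model._clado
    sizes = np.array([r.size for r in space.ranges])
    bits = np.array([r.bits for r in space.ranges])
    labels = space.labels()

    D, M, prop, _ = model._downpass(params)
    if D is None:
        raise ValueError("likelihood is zero at the supplied parameters")

    U: list[np.ndarray | None] = [None] * tree.n_nodes
    U[tree.root] = model.root_prior.copy()
    recons: dict[int, NodeReconstruction] = {}
    for i in reversed(range(tree.n_nodes)):  # preorder: parents before children
        if tree.is_tip[i]:
            continue
        l, r = (int(c) for c in tree.children[i])
        u = U[i]
        joint = u[anc] * prob * M[l][left] * M[r][right]
        total = joint.sum()
        if total <= 0:
            raise ValueError(f"zero posterior mass at node {tree.labels[i]}")
        # marginal over ranges
        probs = np.zeros(S)
        np.add.at(probs, anc, joint)
        probs /= total
        best = _pick_best_split(
            joint / total, anc, left, right, kind, sizes, bits, tree.labels[l], tree.labels[r]
        )
        recons[i] = NodeReconstruction(
            node_id=tree.labels[i],
            node_index=i,
            age=float(tree.age[i]),
            range_probs=probs,
            labels=labels,
            best_anc_bits=int(bits[anc[best]]),
            best_left_bits=int(bits[left[best]]),
            best_right_bits=int(bits[right[best]]),
            best_kind=KIND_NAMES[int(kind[best])],
            best_prob=float(probs.max()),
        )
        # uppass to each child: clado mixing toward that child, then the branch
        for child, sib, side in ((l, r, left), (r, l, right)):
            other = right if side is left else left
            weights = np.zeros(S)
            np.add.at(weights, side, u[anc] * prob * M[sib][other])
            down = prop.message_T(model._segments[child], weights)
            down = np.clip(down, 0.0, None)
            tot = down.sum()
            U[child] = down / tot if tot > 0 else down
    return [recons[i] for i in sorted(recons)]


def _pick_best_split(joint, anc, left, right, kind, sizes, bits, left_id, right_id):
    """Index of the best outcome under the symmetric deterministic tie-break."""
    top = joint.max()
    cand = np.flatnonzero(joint >= top * (1 - 1e-9))
    swap = left_id > right_id  # orient daughter assignment by child id order

    def key(o):
        lb, rb = int(bits[left[o]]), int(bits[right[o]])
        first, second = (rb, lb) if swap else (lb, rb)
        return (
            int(sizes[anc[o]]),
            int(bits[anc[o]]),
            min(lb, rb),
            max(lb, rb),
            first,
            second,
        )

    return int(min(cand, key=key))


def count_events(
    reconstructions: list[NodeReconstruction],
    tree: Chronogram,
    tip_ranges: TipRangeTable,
) -> EventCounts:
    """Tally global events from the best scenario at every node.

    Vicariance: best splits of vicariant kind.  Dispersal/extinction: areas
    gained/lost between the daughter range a child inherits and the child's
    own best range (its observed range for tips).
    """
    recon_by_index = {rec.node_index: rec for rec in reconstructions}
    for i in range(tree.n_nodes):
        if not tree.is_tip[i] and i not in recon_by_index:
            raise ValueError(f"reconstructions missing internal node {tree.labels[i]}")
    dispersal = extinction = vicariance = 0
    for i, rec in recon_by_index.items():
        if rec.best_kind == KIND_NAMES[VICARIANCE]:
            vicariance += 1
        l, r = (int(c) for c in tree.children[i])
        for child, inherited in ((l, rec.best_left_bits), (r, rec.best_right_bits)):
            if tree.is_tip[child]:
                child_bits = tip_ranges[tree.labels[child]].bits
            else:
                child_bits = recon_by_index[child].best_anc_bits
            dispersal += (child_bits & ~inherited).bit_count()
            extinction += (inherited & ~child_bits).bit_count()
    return EventCounts(dispersal=dispersal, vicariance=vicariance, extinction=extinction)


def event_table(
    reconstructions: list[NodeReconstruction],
    tree: Chronogram,
    tip_ranges: TipRangeTable,
) -> pd.DataFrame:
    """Per-branch event log behind :func:`count_events` (one row per child)."""
    recon_by_index = {rec.node_index: rec for rec in reconstructions}
    fmt = tip_ranges.system.format_range
    rows = []
    for i, rec in sorted(recon_by_index.items()):
        l, r = (int(c) for c in tree.children[i])
        for child, inherited in ((l, rec.best_left_bits), (r, rec.best_right_bits)):
            if tree.is_tip[child]:
                child_bits = tip_ranges[tree.labels[child]].bits
            else:
                child_bits = recon_by_index[child].best_anc_bits
            rows.append(
                {
                    "parent": rec.node_id,
                    "child": tree.labels[child],
                    "split_kind": rec.best_kind,
                    "inherited": fmt(inherited),
                    "child_range": fmt(child_bits),
                    "gains": (child_bits & ~inherited).bit_count(),
                    "losses": (inherited & ~child_bits).bit_count(),
                }
            )
    return pd.DataFrame(rows)


def range_probability_table(
    reconstructions: list[NodeReconstruction], min_prob: float = 1e-4
) -> pd.DataFrame:
    """Pie-chart-ready long table: node, age, range, probability."""
    rows = []
    for rec in reconstructions:
        for lab, p in zip(rec.labels, rec.range_probs):
            if p >= min_prob:
                rows.append(
                    {"node": rec.node_id, "age": rec.age, "range": lab, "prob": float(p)}
                )
    return pd.DataFrame(rows)


def summarize_clades(
    reconstructions: list[NodeReconstruction],
    tree: Chronogram,
    group_nodes: dict[str, list[str]],
) -> pd.DataFrame:
    """Named-clade report: node age (read from the chronogram), top range, probability.

    ``group_nodes`` maps a clade name to tip labels whose MRCA identifies the
    node.
    """
    recon_by_index = {rec.node_index: rec for rec in reconstructions}
    rows = []
    for name, tips in group_nodes.items():
        if not tips:
            raise KeyError(f"clade {name!r}: empty tip selector")
        node = tree.mrca(tips)
        if node not in recon_by_index:
            raise KeyError(f"clade {name!r}: selector matches no reconstructed node")
        rec = recon_by_index[node]
        rows.append(
            {
                "clade": name,
                "node": rec.node_id,
                "age": rec.age,
                "range": rec.top_range_label,
                "prob": rec.top_prob,
            }
        )
    return pd.DataFrame(rows, columns=["clade", "node", "age", "range", "prob"])
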