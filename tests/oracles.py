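"""Independent oracles used by the test suite.

These deliberately avoid the package's computational paths: connectivity by
networkx, branch transitions by Runge-Kutta ODE integration, cladogenetic
outcomes by plain nested loops, and the tree likelihood by exhaustive
summation over ancestral states and outcomes.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp


def nx_connected(bits: int, adjacency: np.ndarray) -> bool:
    members = [i for i in range(adjacency.shape[0]) if bits >> i & 1]
    if len(members) <= 1:
        return True
    g = nx.Graph()
    g.add_nodes_from(members)
    for i, j in itertools.combinations(members, 2):
        if adjacency[i, j]:
            g.add_edge(i, j)
    return nx.is_connected(g)


def oracle_generator(space, m: np.ndarray, d: float, e: float,
                     connectivity_exit: str = "absorb") -> np.ndarray:
    """Rate matrix by direct rule application (independent loops)."""
    S = len(space)
    n = m.shape[0]
    Q = np.zeros((S, S))
    in_space = {r.bits for r in space.ranges}
    for i, r in enumerate(space.ranges):
        if r.bits == 0:
            continue
        members = [a for a in range(n) if r.bits >> a & 1]
        for a in members:
            tgt = r.bits & ~(1 << a)
            if tgt in in_space:
                Q[i, space.index_of[tgt]] += e
            elif connectivity_exit == "absorb" and space.constrained:
                Q[i, 0] += e
        for b in range(n):
            if r.bits >> b & 1:
                continue
            tgt = r.bits | (1 << b)
            rate = d * sum(m[a, b] for a in members)
            if tgt in in_space:
                Q[i, space.index_of[tgt]] += rate
            elif (
                connectivity_exit == "absorb"
                and space.constrained
                and not (space.max_size is not None and bin(tgt).count("1") > space.max_size)
            ):
                Q[i, 0] += rate
    for i in range(S):
        Q[i, i] = -Q[i].sum() + Q[i, i]
    return Q


def ode_transition(Q: np.ndarray, t: float) -> np.ndarray:
    """Row-stochastic e^{Qt} by high-accuracy RK integration, row by row."""
    S = Q.shape[0]
    P = np.zeros((S, S))
    for i in range(S):
        if t == 0:
            P[i, i] = 1.0
            continue
        sol = solve_ivp(
            lambda _, y: y @ Q, (0.0, t), np.eye(S)[i],
            rtol=1e-11, atol=1e-14, method="DOP853",
        )
        P[i] = sol.y[:, -1]
    return P


def ode_branch(space, epochs, d: float, e: float, start_age: float, end_age: float,
               connectivity_exit: str = "absorb") -> np.ndarray:
    """Transition matrix across epochs: chained per-segment ODE solutions."""
    from rangedec.dispersal import slice_branch

    S = len(space)
    P = np.eye(S)
    for dur, ep in slice_branch(start_age, end_age, epochs):
        Q = oracle_generator(space, epochs.multipliers[ep].m, d, e, connectivity_exit)
        P = P @ ode_transition(Q, dur)
    return P


def oracle_clado(bits: int, space) -> list[tuple[int, int, float, str]]:
    """Cladogenetic (left, right, prob, kind) tuples by literal enumeration."""
    members = [a for a in range(space.system.n_areas) if bits >> a & 1]
    if len(members) == 1:
        return [(bits, bits, 1.0, "sympatry")]
    outs = set()
    for a in members:
        single = 1 << a
        rest = bits & ~single
        outs.add((single, bits, "subset_sympatry"))
        outs.add((bits, single, "subset_sympatry"))
        if rest in space:
            outs.add((single, rest, "vicariance"))
            outs.add((rest, single, "vicariance"))
    p = 1.0 / len(outs)
    return [(l, r, p, k) for l, r, k in sorted(outs)]


def bruteforce_likelihood(tree, tip_ranges, space, epochs, d, e,
                          root_prior=None) -> float:
    """-lnL by exhaustive summation over every (node state, outcome) scenario.

    Branch transition probabilities come from the ODE oracle; cladogenetic
    outcomes from the loop oracle.  Exponential in tree size: use on 2-4 tip
    trees only.
    """
    S = len(space)
    if root_prior is None:
        root_prior = np.full(S, 1.0 / (S - 1))
        root_prior[0] = 0.0
    P_edge = {}
    for i in range(tree.n_nodes):
        if tree.parent[i] >= 0:
            P_edge[i] = ode_branch(
                space, epochs, d, e, tree.age[tree.parent[i]], tree.age[i]
            )

    def below(node: int, state_idx: int) -> float:
        """P(tip data below node | state at node, pre-cladogenesis)."""
        if tree.is_tip[node]:
            obs = space.index_of[tip_ranges[tree.labels[node]].bits]
            return 1.0 if state_idx == obs else 0.0
        bits = space.ranges[state_idx].bits
        if bits == 0:
            return 0.0
        total = 0.0
        for lb, rb, p, _ in oracle_clado(bits, space):
            li, ri = space.index_of[lb], space.index_of[rb]
            lc, rc = (int(c) for c in tree.children[node])
            left_sum = sum(
                P_edge[lc][li, k] * below(lc, k) for k in range(S)
            )
            right_sum = sum(
                P_edge[rc][ri, k] * below(rc, k) for k in range(S)
            )
            total += p * left_sum * right_sum
        return total

    lik = sum(root_prior[i] * below(tree.root, i) for i in range(S))
    return -np.log(lik)


def bruteforce_root_posterior(tree, tip_ranges, space, epochs, d, e):
    """Joint posterior over (root state, outcome) for a 2-tip tree."""
    assert tree.n_tips == 2
    S = len(space)
    prior = np.full(S, 1.0 / (S - 1))
    prior[0] = 0.0
    lc, rc = (int(c) for c in tree.children[tree.root])
    Pl = ode_branch(space, epochs, d, e, tree.age[tree.root], tree.age[lc])
    Pr = ode_branch(space, epochs, d, e, tree.age[tree.root], tree.age[rc])
    ol = space.index_of[tip_ranges[tree.labels[lc]].bits]
    orr = space.index_of[tip_ranges[tree.labels[rc]].bits]
    joint = {}
    for i in range(1, S):
        for lb, rb, p, kind in oracle_clado(space.ranges[i].bits, space):
            li, ri = space.index_of[lb], space.index_of[rb]
            joint[(i, li, ri, kind)] = prior[i] * p * Pl[li, ol] * Pr[ri, orr]
    total = sum(joint.values())
    return {k: v / total for k, v in joint.items()}, total
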