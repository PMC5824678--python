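"""The Dispersal-Extinction-Cladogenesis likelihood model.

Ranges evolve along branches as a continuous-time Markov chain on the range
state space: single-area gains at rate ``d`` scaled by the dispersal
multipliers summed over occupied source areas, single-area losses at rate
``e``, and the empty range absorbing.  At every node the ancestral range is
partitioned between the daughters (sympatry for single areas; subset
sympatry and single-area vicariance for larger ranges, equally weighted).
The tree likelihood is computed by Felsenstein pruning with cladogenetic
mixing at internal nodes, and ``d``, ``e`` are estimated by maximum
likelihood.

Organised statsmodels-style: :class:`DECModel` binds the data (tree, tip
ranges, state space, epochs); :meth:`DECModel.fit` returns a
:class:`DECResults` carrying the estimates and diagnostics, from which
ancestral reconstruction and event counting are reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .dispersal import DispersalMultipliers, EpochSet, slice_branch
from .geography import Range, RangeSpace
from .treeio import Chronogram, TipRangeTable

__all__ = [
    "DECParams",
    "CladoOutcome",
    "DECModel",
    "DECResults",
    "build_generator",
    "branch_transition",
    "clado_outcomes",
    "tree_likelihood",
    "fit_dec",
]

SYMPATRY, SUBSET_SYMPATRY, VICARIANCE = 0, 1, 2
KIND_NAMES = {SYMPATRY: "sympatry", SUBSET_SYMPATRY: "subset_sympatry", VICARIANCE: "vicariance"}

#: fixed optimizer starting points (d, e), per the documented deterministic scheme
DEFAULT_STARTS = ((0.01, 0.01), (0.1, 0.01), (0.01, 0.1))
_LOG_RATE_MIN, _LOG_RATE_MAX = -30.0, 5.0


@dataclass(frozen=True)
class DECParams:
    """Dispersal rate ``d`` (per area pair per Myr) and extinction rate ``e``."""

    d: float
    e: float

    def __post_init__(self):
        if not (math.isfinite(self.d) and math.isfinite(self.e)):
            raise ValueError("rates must be finite")
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class CladoOutcome:
    """One ordered daughter-range pair with its probability and event kind."""

    left: Range
    right: Range
    prob: float
    kind: str


def build_generator(
    space: RangeSpace,
    multipliers: DispersalMultipliers,
    params: DECParams,
    connectivity_exit: str = "absorb",
) -> np.ndarray:
    """Anagenetic rate matrix over the range space.

    Gains R -> R+{b} at rate ``d * sum_{a in R} m[a, b]``; losses R -> R-{a}
    at rate ``e``; the empty range is absorbing.  A transition whose target
    is excluded by the *size* bound is dropped (rate 0).  A transition whose
    target is excluded by the adjacency *connectivity* constraint routes its
    rate into the absorbing empty range (default ``"absorb"``: the lineage
    fragments and is treated as extinct in place, which keeps the
    constrained model a sub-event of the unconstrained one), or is dropped
    with ``connectivity_exit="drop"``.
    """
    if multipliers.n_areas != space.system.n_areas:
        raise ValueError("multiplier matrix and range space use different area counts")
    if connectivity_exit not in ("absorb", "drop"):
        raise ValueError(f"unknown connectivity_exit {connectivity_exit!r}")
    m = multipliers.m
    n = space.system.n_areas
    S = len(space)
    absorb = connectivity_exit == "absorb" and space.constrained
    Q = np.zeros((S, S))
    for i in range(1, S):
        bits = space.ranges[i].bits
        members = space.ranges[i].areas()
        for a in members:
            target = bits & ~(1 << a)
            j = space.index_of.get(target)
            if j is None and absorb:
                j = 0  # fragmentation by local extinction
            if j is not None:
                Q[i, j] += params.e
        for b in range(n):
            if not bits >> b & 1:
                target = bits | (1 << b)
                j = space.index_of.get(target)
                if j is None:
                    over_size = (
                        space.max_size is not None
                        and target.bit_count() > space.max_size
                    )
                    if absorb and not over_size:
                        j = 0  # expansion into a forbidden (disconnected) range
                if j is not None:
                    Q[i, j] += params.d * sum(m[a, b] for a in members)
        Q[i, i] = -Q[i].sum()
    return Q


def _clado_table(space: RangeSpace):
    """Flat outcome arrays (anc, left, right, prob, kind) cached on the space."""
    cached = getattr(space, "_clado_cache", None)
    if cached is not None:
        return cached
    anc, left, right, prob, kind = [], [], [], [], []
    for i in range(1, len(space)):
        bits = space.ranges[i].bits
        members = space.ranges[i].areas()
        if len(members) == 1:
            outs = {(i, i, SYMPATRY)}
        else:
            outs = set()
            for a in members:
                ai = space.index_of[1 << a]
                outs.add((ai, i, SUBSET_SYMPATRY))
                outs.add((i, ai, SUBSET_SYMPATRY))
                rem = space.index_of.get(bits & ~(1 << a))
                if rem is not None and rem != 0:
                    outs.add((ai, rem, VICARIANCE))
                    outs.add((rem, ai, VICARIANCE))
        p = 1.0 / len(outs)
        for l, r, k in sorted(outs):
            anc.append(i)
            left.append(l)
            right.append(r)
            prob.append(p)
            kind.append(k)
    table = tuple(
        np.array(x) for x in (anc, left, right, prob, kind)
    )
    space._clado_cache = table
    return table


def clado_outcomes(ancestral: Range | int, space: RangeSpace) -> list[CladoOutcome]:
    """Enumerate the cladogenetic daughter-range pairs of an ancestral range.

    Size-1 ancestors copy themselves to both daughters (sympatry); larger
    ancestors yield every ordered pair in which one daughter is a single
    member area and the other is the full range (subset sympatry) or its
    complement (vicariance).  Pairs whose daughters fall outside a
    constrained space are dropped and the rest renormalized.
    """
    bits = ancestral.bits if isinstance(ancestral, Range) else int(ancestral)
    if bits == 0:
        raise ValueError("ancestral range must be non-empty")
    if bits not in space:
        raise ValueError(
            f"ancestral range {space.system.format_range(bits)} is not in the space"
        )
    anc, left, right, prob, kind = _clado_table(space)
    i = space.index_of[bits]
    sel = anc == i
    return [
        CladoOutcome(
            left=space.ranges[l], right=space.ranges[r], prob=p, kind=KIND_NAMES[k]
        )
        for l, r, p, k in zip(left[sel], right[sel], prob[sel], kind[sel])
    ]


class _EpochPropagators:
    """Fast e^{Qt} actions per epoch at fixed parameters.

    Uses an eigendecomposition of each epoch generator when it reconstructs
    the generator accurately; otherwise falls back to dense ``expm`` with a
    per-duration cache.  Both paths are exercised against an ODE oracle in
    the test battery through :func:`branch_transition`.
    """

    def __init__(self, space: RangeSpace, epochs: EpochSet, params: DECParams):
        self.epochs = epochs
        built: dict[int, np.ndarray] = {}
        self.Q: list[np.ndarray] = []
        for mult in epochs.multipliers:
            if id(mult) not in built:
                built[id(mult)] = build_generator(space, mult, params)
            self.Q.append(built[id(mult)])
        self._eig: list[tuple | None] = []
        decomposed: dict[int, tuple | None] = {}
        for mult, Q in zip(epochs.multipliers, self.Q):
            if id(mult) not in decomposed:
                decomposed[id(mult)] = self._try_eig(Q)
            self._eig.append(decomposed[id(mult)])
        self._expm_cache: dict[tuple[int, float], np.ndarray] = {}

    @staticmethod
    def _try_eig(Q: np.ndarray):
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            return None
        recon = (V * w) @ Vinv
        scale = max(1.0, float(np.abs(Q).max()))
        if np.abs(recon - Q).max() > 1e-10 * scale:
            return None
        return w, V, Vinv

    def _matrix(self, ep: int, t: float) -> np.ndarray:
        key = (ep, t)
        if key not in self._expm_cache:
            self._expm_cache[key] = expm(self.Q[ep] * t)
        return self._expm_cache[key]

    def apply(self, ep: int, t: float, vec: np.ndarray) -> np.ndarray:
        """(e^{Qt} @ vec) — propagate a conditional-likelihood message."""
        eig = self._eig[ep]
        if eig is None:
            return self._matrix(ep, t) @ vec
        w, V, Vinv = eig
        out = V @ (np.exp(w * t) * (Vinv @ vec))
        return np.ascontiguousarray(out.real)

    def apply_T(self, ep: int, t: float, vec: np.ndarray) -> np.ndarray:
        """(e^{Qt})^T @ vec — propagate an uppass weight vector."""
        eig = self._eig[ep]
        if eig is None:
            return self._matrix(ep, t).T @ vec
        w, V, Vinv = eig
        out = Vinv.T @ (np.exp(w * t) * (V.T @ vec))
        return np.ascontiguousarray(out.real)

    def message(self, segments: list[tuple[float, int]], vec: np.ndarray) -> np.ndarray:
        """Propagate child conditionals to the top of a branch (segments oldest first)."""
        out = vec
        for dur, ep in reversed(segments):
            out = self.apply(ep, dur, out)
        return out

    def message_T(self, segments: list[tuple[float, int]], vec: np.ndarray) -> np.ndarray:
        """Propagate uppass weights from the top of a branch to its child end."""
        out = vec
        for dur, ep in segments:
            out = self.apply_T(ep, dur, out)
        return out


def branch_transition(
    space: RangeSpace,
    epochs: EpochSet,
    params: DECParams,
    start_age: float,
    end_age: float,
) -> np.ndarray:
    """Transition-probability matrix across a branch, oldest to youngest.

    The product of per-epoch-segment matrix exponentials; rows sum to 1 and
    tiny negative entries are clipped to 0.
    """
    S = len(space)
    P = np.eye(S)
    if start_age > end_age:
        mults: dict[int, np.ndarray] = {}
        for dur, ep in slice_branch(start_age, end_age, epochs):
            mult = epochs.multipliers[ep]
            if id(mult) not in mults:
                mults[id(mult)] = build_generator(space, mult, params)
            seg = expm(mults[id(mult)] * dur)
            P = P @ seg
    if not np.isfinite(P).all():
        raise FloatingPointError(
            f"matrix exponential failed on branch ({start_age}, {end_age})"
        )
    if P.min() < -1e-9:
        raise FloatingPointError(
            f"transition matrix has negative entry {P.min():.3g} on branch "
            f"({start_age}, {end_age})"
        )
    P = np.clip(P, 0.0, None)
    return P


class DECModel:
    """DEC likelihood bound to one chronogram and its tip ranges.

    Parameters
    ----------
    tree
        Ultrametric bifurcating chronogram.
    tip_ranges
        Observed presence/absence ranges for every tip.
    space
        Allowed range state space (possibly adjacency-constrained).
    epochs
        Time strata with dispersal multipliers; the oldest boundary must not
        be younger than the root.
    root_prior
        ``"uniform"`` (default: uniform over non-empty ranges in the space)
        or an explicit probability vector over the space.
    """

    def __init__(
        self,
        tree: Chronogram,
        tip_ranges: TipRangeTable,
        space: RangeSpace,
        epochs: EpochSet,
        root_prior="uniform",
    ):
        if space.system is not tip_ranges.system and space.system.codes != tip_ranges.system.codes:
            raise ValueError("range space and tip ranges use different area systems")
        tip_ranges.validate_against(tree, space)
        if tree.height > epochs.oldest * (1 + 1e-9):
            raise ValueError(
                f"root age {tree.height:.6g} exceeds oldest epoch boundary "
                f"{epochs.oldest:.6g}; extend the epoch set"
            )
        self.tree = tree
        self.tip_ranges = tip_ranges
        self.space = space
        self.epochs = epochs
        S = len(space)
        if isinstance(root_prior, str):
            if root_prior != "uniform":
                raise ValueError(f"unknown root prior {root_prior!r}")
            prior = np.full(S, 1.0 / (S - 1))
            prior[0] = 0.0
        else:
            prior = np.asarray(root_prior, dtype=float)
            if prior.shape != (S,) or prior[0] != 0 or abs(prior.sum() - 1) > 1e-9:
                raise ValueError(
                    "root prior must be a length-S probability vector with 0 on the empty range"
                )
        self.root_prior = prior
        # per-node tip state index and per-edge epoch segments
        self._tip_state = np.full(tree.n_nodes, -1, dtype=int)
        for i in range(tree.n_nodes):
            if tree.is_tip[i]:
                self._tip_state[i] = space.index_of[tip_ranges[tree.labels[i]].bits]
        self._segments = [
            slice_branch(tree.age[tree.parent[i]], tree.age[i], epochs)
            if tree.parent[i] >= 0
            else []
            for i in range(tree.n_nodes)
        ]
        self._clado = _clado_table(space)

    # -- likelihood ----------------------------------------------------

    def _downpass(self, params: DECParams):
        """Pruning pass: per-node conditionals D, per-edge messages M, log scale."""
        tree = self.tree
        S = len(self.space)
        anc, left, right, prob, _ = self._clado
        prop = _EpochPropagators(self.space, self.epochs, params)
        D: list[np.ndarray | None] = [None] * tree.n_nodes
        M: list[np.ndarray | None] = [None] * tree.n_nodes
        logscale = 0.0
        for i in tree.postorder():
            if tree.is_tip[i]:
                vec = np.zeros(S)
                vec[self._tip_state[i]] = 1.0
            else:
                l, r = tree.children[i]
                M[l] = np.clip(prop.message(self._segments[l], D[l]), 0.0, None)
                M[r] = np.clip(prop.message(self._segments[r], D[r]), 0.0, None)
                vec = np.zeros(S)
                np.add.at(vec, anc, prob * M[l][left] * M[r][right])
            top = vec.max()
            if not np.isfinite(top) or top <= 0.0:
                return None, None, None, -np.inf
            D[i] = vec / top
            logscale += math.log(top)
        return D, M, prop, logscale

    def loglike(self, params: DECParams | tuple[float, float]) -> float:
        """Log-likelihood of the tip ranges at the given (d, e)."""
        if not isinstance(params, DECParams):
            params = DECParams(*params)
        D, _, _, logscale = self._downpass(params)
        if D is None:
            return -np.inf
        lik = float(self.root_prior @ D[self.tree.root])
        if lik <= 0.0:
            return -np.inf
        return math.log(lik) + logscale

    def nloglike(self, params) -> float:
        return -self.loglike(params)

    # -- fitting -------------------------------------------------------

    def fit(
        self,
        starts: tuple = DEFAULT_STARTS,
        tol: float = 1e-8,
        maxiter: int = 400,
    ) -> "DECResults":
        """Maximize the likelihood over (d, e) >= 0.

        Deterministic derivative-free search (Nelder-Mead on log rates) from
        the fixed starting points; the best of the runs is reported.  Never
        raises on non-convergence: ``converged`` is flagged instead.
        """
        n_evals = 0

        def objective(x):
            nonlocal n_evals
            n_evals += 1
            x = np.clip(x, _LOG_RATE_MIN, _LOG_RATE_MAX)
            val = self.nloglike(DECParams(float(np.exp(x[0])), float(np.exp(x[1]))))
            return val if np.isfinite(val) else 1e12

        best = None
        any_success = False
        for d0, e0 in starts:
            res = minimize(
                objective,
                x0=np.log([d0, e0]),
                method="Nelder-Mead",
                options={
                    "fatol": tol,
                    "xatol": 1e-6,
                    "maxiter": maxiter,
                    "maxfev": 4 * maxiter,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
                any_success = bool(res.success)
            elif res.fun == best.fun and res.success:
                any_success = True
        x = np.clip(best.x, _LOG_RATE_MIN, _LOG_RATE_MAX)
        params = DECParams(float(np.exp(x[0])), float(np.exp(x[1])))
        return DECResults(
            model=self,
            params=params,
            neg_log_likelihood=float(best.fun),
            converged=any_success,
            n_evals=n_evals,
        )


@dataclass
class DECResults:
    """Maximum-likelihood estimates and diagnostics for a fitted DEC model."""

    model: DECModel
    params: DECParams
    neg_log_likelihood: float
    converged: bool
    n_evals: int

    def reconstruct(self):
        """Marginal ancestral-range reconstruction at the MLE (per internal node)."""
        from .reconstruct import ancestral_reconstruction

        return ancestral_reconstruction(self.model, self.params)

    def event_counts(self):
        """Global dispersal/vicariance/extinction tallies from the reconstruction."""
        from .reconstruct import count_events

        return count_events(self.reconstruct(), self.model.tree, self.model.tip_ranges)

    def summary(self) -> str:
        m = self.model
        lines = [
            "DEC model fit",
            "=" * 46,
            f"tips                 {m.tree.n_tips}",
            f"tree height (Myr)    {m.tree.height:.4f}",
            f"areas                {''.join(m.space.system.codes)}",
            f"range states         {len(m.space)}"
            + (" (constrained)" if m.space.constrained else " (unconstrained)"),
            f"epochs               {m.epochs.n_epochs}",
            "-" * 46,
            f"dispersal rate d     {self.params.d:.6g} /area-pair/Myr",
            f"extinction rate e    {self.params.e:.6g} /area/Myr",
            f"-lnL                 {self.neg_log_likelihood:.6f}",
            f"converged            {self.converged}  ({self.n_evals} evaluations)",
            "=" * 46,
        ]
        return "\n".join(lines)


def tree_likelihood(
    tree: Chronogram,
    tip_ranges: TipRangeTable,
    space: RangeSpace,
    epochs: EpochSet,
    params: DECParams,
    root_prior="uniform",
) -> float:
    """Negative log-likelihood of the tip ranges under DEC at fixed rates."""
    return DECModel(tree, tip_ranges, space, epochs, root_prior).nloglike(params)


def fit_dec(
    tree: Chronogram,
    tip_ranges: TipRangeTable,
    space: RangeSpace,
    epochs: EpochSet,
    root_prior="uniform",
    **options,
) -> DECResults:
    """Fit d and e by maximum likelihood (see :meth:`DECModel.fit`)."""
    return DECModel(tree, tip_ranges, space, epochs, root_prior).fit(**options)
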