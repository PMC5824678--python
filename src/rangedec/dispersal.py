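"""Dispersal-multiplier matrices and time stratification.

Dispersal multipliers scale the per-pair dispersal rate ``d`` by a fixed
factor encoding geographic distance and barriers.  The distance rule maps
graph distance 1..5+ between areas to 0.8, 0.6, 0.4, 0.2, 0.08; a listed
barrier pair is set to 0.001 outright.  An :class:`EpochSet` stratifies the
time axis into intervals, each carrying its own multiplier matrix.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .geography import AreaSystem

__all__ = [
    "DispersalMultipliers",
    "EpochSet",
    "build_multipliers_from_graph",
    "load_matrix",
    "load_bundled_matrix",
    "uniform_multipliers",
    "slice_branch",
]

#: multiplier for graph distance 1, 2, 3, 4, and >= 5
DISTANCE_VALUES = (0.8, 0.6, 0.4, 0.2, 0.08)
BARRIER_VALUE = 0.001


class DispersalMultipliers:
    """A (source area, destination area) matrix of dispersal scalings."""

    def __init__(self, m: np.ndarray, label: str = "", *, validate: bool = True):
        m = np.asarray(m, dtype=float)
        if validate:
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"multiplier matrix must be square, got {m.shape}")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("multiplier diagonal entries must equal 1")
            if (m < 0).any():
                raise ValueError("multiplier entries must be non-negative")
            if (m > 1).any():
                raise ValueError("multiplier entries must be <= 1")
        self.m = m
        self.label = label

    @property
    def n_areas(self) -> int:
        return self.m.shape[0]

    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.m, self.m.T))

    def symmetrized(self) -> "DispersalMultipliers":
        """Element-wise max of the matrix and its transpose."""
        return DispersalMultipliers(np.maximum(self.m, self.m.T), f"{self.label} (sym)")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<DispersalMultipliers {self.label or 'unlabeled'} {self.m.shape}>"


def load_matrix(table_text: str, sys: AreaSystem, label: str = "") -> DispersalMultipliers:
    """Parse a whitespace-separated n x n table with area-code header and row labels.

    The table is stored exactly as printed, including asymmetric cells; a QC
    warning is emitted when asymmetry is present.
    """
    df = pd.read_csv(io.StringIO(table_text), sep=r"\s+", index_col=0)
    codes = sys.codes
    if list(df.columns) != codes or list(df.index) != codes:
        raise ValueError(
            f"matrix header/rows must match area order {''.join(codes)}, got "
            f"columns {list(df.columns)} rows {list(df.index)}"
        )
    mult = DispersalMultipliers(df.to_numpy(dtype=float), label)
    if not mult.is_symmetric():
        warnings.warn(
            f"dispersal matrix {label or '(unlabeled)'} has asymmetric cells; "
            "stored as given (row = source, column = destination)",
            stacklevel=2,
        )
    return mult


def load_bundled_matrix(name: str, sys: AreaSystem) -> DispersalMultipliers:
    """Load a fixture matrix (``"I"``, ``"II"`` or ``"III"``) shipped with the package."""
    text = resources.files("rangedec.data").joinpath(f"matrix{name}.tsv").read_text()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixture asymmetries are known
        return load_matrix(text, sys, label=f"Matrix {name}")


def uniform_multipliers(sys: AreaSystem, label: str = "Matrix I") -> DispersalMultipliers:
    """Cost-free dispersal: every multiplier equals 1."""
    return DispersalMultipliers(np.ones((sys.n_areas, sys.n_areas)), label)


def build_multipliers_from_graph(
    sys: AreaSystem,
    barriers: set[frozenset[str]] | set[tuple[str, str]] | None = None,
    label: str = "",
) -> DispersalMultipliers:
    """Build a multiplier matrix from adjacency-graph distances and barriers.

    Entry (a, b) is 0.8/0.6/0.4/0.2 for graph distance 1-4 and 0.08 for
    distance >= 5; a pair listed in ``barriers`` is set to 0.001 in both
    directions, overriding its distance value.  Diagonal entries are 1.
    """
    if sys.adjacency is None:
        raise ValueError("area system has no adjacency matrix")
    n = sys.n_areas
    graph = sys.adjacency.astype(float).copy()
    np.fill_diagonal(graph, 0.0)
    dist = shortest_path(graph, method="D", unweighted=True)
    if np.isinf(dist).any():
        i, j = np.argwhere(np.isinf(dist))[0]
        reach = {sys.codes[k] for k in range(n) if np.isfinite(dist[i, k])}
        raise ValueError(
            f"adjacency graph is disconnected: component {{{','.join(sorted(reach))}}} "
            f"cannot reach area {sys.codes[j]}"
        )
    m = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                k = min(int(dist[i, j]), 5)
                m[i, j] = DISTANCE_VALUES[k - 1]
    for pair in barriers or ():
        a, b = tuple(pair)
        ia, ib = sys.index(a), sys.index(b)
        m[ia, ib] = m[ib, ia] = BARRIER_VALUE
    return DispersalMultipliers(m, label)


@dataclass
class EpochSet:
    """Time strata (Myr before present) with one multiplier matrix each.

    ``boundaries`` are strictly decreasing ages ending implicitly at 0: with
    boundaries ``[18, 5.5, 1.25]`` epoch 0 spans 18-5.5, epoch 1 spans
    5.5-1.25 and epoch 2 spans 1.25-0.
    """

    boundaries: list[float]
    multipliers: list[DispersalMultipliers]

    def __post_init__(self):
        b = [float(x) for x in self.boundaries]
        if not b or any(x <= y for x, y in zip(b, b[1:])) or b[-1] <= 0:
            raise ValueError(
                "epoch boundaries must be strictly decreasing positive ages"
            )
        if len(self.multipliers) != len(b):
            raise ValueError(
                f"need one multiplier matrix per epoch: {len(b)} boundaries "
                f"but {len(self.multipliers)} matrices"
            )
        self.boundaries = b

    @classmethod
    def single(cls, multipliers: DispersalMultipliers, oldest: float) -> "EpochSet":
        """One epoch spanning [0, oldest]."""
        return cls([oldest], [multipliers])

    @classmethod
    def uniform(
        cls, boundaries: list[float], multipliers: DispersalMultipliers
    ) -> "EpochSet":
        """The same matrix in every epoch (the default stratification)."""
        return cls(list(boundaries), [multipliers] * len(boundaries))

    @property
    def n_epochs(self) -> int:
        return len(self.boundaries)

    @property
    def oldest(self) -> float:
        return self.boundaries[0]

    def epoch_span(self, i: int) -> tuple[float, float]:
        start = self.boundaries[i]
        end = self.boundaries[i + 1] if i + 1 < len(self.boundaries) else 0.0
        return start, end


def slice_branch(
    start_age: float, end_age: float, epochs: EpochSet
) -> list[tuple[float, int]]:
    """Split a branch (older age -> younger age) into per-epoch segments.

    Returns ``(duration, epoch_index)`` pairs ordered oldest to youngest;
    durations sum to ``start_age - end_age``.
    """
    if end_age < 0 or start_age < end_age:
        raise ValueError(f"need start_age >= end_age >= 0, got ({start_age}, {end_age})")
    if start_age > epochs.oldest * (1 + 1e-9):
        raise ValueError(
            f"branch starts at {start_age} Myr, older than the oldest epoch "
            f"boundary {epochs.oldest}; extend the epoch set"
        )
    start_age = min(start_age, epochs.oldest)
    end_age = min(end_age, start_age)
    segments = []
    for i in range(epochs.n_epochs):
        top, bottom = epochs.epoch_span(i)
        lo = max(end_age, bottom)
        hi = min(start_age, top)
        if hi > lo:
            segments.append((hi - lo, i))
    return segments
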