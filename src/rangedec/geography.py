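"""Area systems and geographic-range state spaces.

A *range* is the set of discrete areas a lineage occupies, encoded as an
integer bitmask over an ordered area list (bit ``i`` = area with index ``i``).
The DEC state space is the collection of allowed ranges: every subset of the
areas, optionally filtered by a maximum range size and/or by connectivity in
a geographic adjacency graph (the "constrained" regime).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "Area",
    "AreaSystem",
    "Range",
    "RangeSpace",
    "parse_area_system",
    "load_bundled_area_system",
    "range_is_connected",
    "enumerate_ranges",
]


@dataclass(frozen=True)
class Area:
    """A named geographic unit with a one-letter code and 0-based index."""

    code: str
    name: str
    index: int


@dataclass(frozen=True)
class Range:
    """A subset of areas encoded as a bitmask; ``size`` is its cardinality."""

    bits: int

    @property
    def size(self) -> int:
        return self.bits.bit_count()

    def areas(self) -> tuple[int, ...]:
        """Indices of the member areas, ascending."""
        return tuple(i for i in range(self.bits.bit_length()) if self.bits >> i & 1)


class AreaSystem:
    """An ordered set of areas with an optional symmetric adjacency graph."""

    def __init__(self, areas: list[Area], adjacency: np.ndarray | None = None):
        codes = [a.code for a in areas]
        if len(set(codes)) != len(codes):
            dup = next(c for c in codes if codes.count(c) > 1)
            raise ValueError(f"duplicate area code {dup!r}")
        if [a.index for a in areas] != list(range(len(areas))):
            raise ValueError("area indices must be contiguous from 0 in list order")
        self.areas = list(areas)
        if adjacency is not None:
            adjacency = np.asarray(adjacency, dtype=bool)
            n = len(areas)
            if adjacency.shape != (n, n):
                raise ValueError(
                    f"adjacency must be {n}x{n}, got {adjacency.shape}"
                )
            bad = np.argwhere(adjacency != adjacency.T)
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    "adjacency must be symmetric; differs for pair "
                    f"({codes[i]},{codes[j]})"
                )
            adjacency = adjacency.copy()
            np.fill_diagonal(adjacency, True)
        self.adjacency = adjacency

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def codes(self) -> list[str]:
        return [a.code for a in self.areas]

    def index(self, code: str) -> int:
        for a in self.areas:
            if a.code == code:
                return a.index
        raise KeyError(f"unknown area code {code!r}")

    def bits_of(self, codes: str) -> int:
        """Bitmask for a concatenated code string like ``"BL"``."""
        bits = 0
        for c in codes:
            bits |= 1 << self.index(c)
        return bits

    def format_range(self, bits: int) -> str:
        """Concatenated code letters in index order (``"BL"``); empty is ``"-"``."""
        if bits == 0:
            return "-"
        return "".join(a.code for a in self.areas if bits >> a.index & 1)

    def __repr__(self) -> str:  # pragma: no cover
        adj = "with" if self.adjacency is not None else "no"
        return f"<AreaSystem {''.join(self.codes)} ({adj} adjacency)>"


def parse_area_system(config_text: str) -> AreaSystem:
    """Parse a YAML area-system config.

    The config carries an ``areas`` list of ``"CODE  Name"`` strings and an
    optional ``adjacency`` list of whitespace-separated 0/1 row strings.
    """
    doc = yaml.safe_load(config_text)
    if not isinstance(doc, dict) or "areas" not in doc:
        raise ValueError("config must contain an 'areas' list")
    areas = []
    for i, line in enumerate(doc["areas"]):
        parts = str(line).split(None, 1)
        if not parts:
            raise ValueError(f"empty area entry at position {i}")
        code = parts[0]
        name = parts[1].strip() if len(parts) > 1 else code
        if len(code) != 1 or not code.isupper():
            raise ValueError(f"area code must be a single uppercase letter, got {code!r}")
        areas.append(Area(code=code, name=name, index=i))
    if len(areas) < 2:
        raise ValueError("config must name at least 2 areas")
    adjacency = None
    if doc.get("adjacency") is not None:
        rows = [str(r).split() for r in doc["adjacency"]]
        n = len(areas)
        if len(rows) != n or any(len(r) != n for r in rows):
            raise ValueError(f"adjacency block must be a {n}x{n} 0/1 matrix")
        adjacency = np.array([[int(x) for x in r] for r in rows], dtype=bool)
    return AreaSystem(areas, adjacency)


def load_bundled_area_system(name: str = "liolaemus12") -> AreaSystem:
    """Load a fixture area system shipped with the package."""
    text = resources.files("rangedec.data").joinpath(f"{name}.areas").read_text()
    return parse_area_system(text)


def range_is_connected(r: Range | int, sys: AreaSystem) -> bool:
    """True iff the areas of ``r`` induce a connected adjacency subgraph.

    Singletons and the empty range count as connected.
    """
    if sys.adjacency is None:
        raise ValueError("area system has no adjacency matrix")
    bits = r.bits if isinstance(r, Range) else int(r)
    members = [i for i in range(sys.n_areas) if bits >> i & 1]
    if len(members) <= 1:
        return True
    member_set = set(members)
    seen = {members[0]}
    queue = deque([members[0]])
    while queue:
        i = queue.popleft()
        for j in member_set - seen:
            if sys.adjacency[i, j]:
                seen.add(j)
                queue.append(j)
    return seen == member_set


@dataclass
class RangeSpace:
    """Ordered collection of allowed ranges; position 0 is the empty range."""

    system: AreaSystem
    ranges: list[Range]
    constrained: bool
    max_size: int | None
    index_of: dict[int, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index_of:
            self.index_of = {r.bits: i for i, r in enumerate(self.ranges)}

    def __len__(self) -> int:
        return len(self.ranges)

    def __contains__(self, bits: int) -> bool:
        return bits in self.index_of

    def labels(self) -> list[str]:
        return [self.system.format_range(r.bits) for r in self.ranges]


def enumerate_ranges(
    sys: AreaSystem, constrained: bool = False, max_size: int | None = None
) -> RangeSpace:
    """Enumerate the allowed range state space.

    Returns every subset of the areas that passes the size bound and, when
    ``constrained``, the adjacency-connectivity rule, plus the empty range at
    position 0.  Order is deterministic: by size, then bitmask.
    """
    if constrained and sys.adjacency is None:
        raise ValueError("constrained enumeration requires an adjacency matrix")
    if max_size is not None and max_size < 1:
        raise ValueError("max_size must be >= 1 or None")
    n = sys.n_areas
    keep = []
    for bits in range(1 << n):
        size = bits.bit_count()
        if size == 0:
            keep.append(bits)
            continue
        if max_size is not None and size > max_size:
            continue
        if constrained and not range_is_connected(bits, sys):
            continue
        keep.append(bits)
    keep.sort(key=lambda b: (b.bit_count(), b))
    return RangeSpace(
        system=sys,
        ranges=[Range(b) for b in keep],
        constrained=constrained,
        max_size=max_size,
    )
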