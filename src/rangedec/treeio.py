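"""Chronogram and tip-range input/output.

Trees are rooted, fully bifurcating, ultrametric chronograms with branch
lengths in absolute time (Myr); node ages are derived from branch lengths
with tips at age 0.  Tip ranges come either in the classic header+binary
string dialect (``"2 3\\nX 100\\n..."``) or as a TSV table with a header of
area codes.  Parsers reject rather than repair, and every error names the
offending element.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .geography import AreaSystem, Range, RangeSpace

__all__ = [
    "Chronogram",
    "TipRangeTable",
    "read_newick",
    "write_newick",
    "read_ranges",
    "write_ranges",
    "write_annotated",
]

#: relative tolerance on root-to-tip depth spread
ULTRAMETRIC_RTOL = 1e-4


class Chronogram:
    """An indexed, validated ultrametric tree.

    Nodes are held in postorder.  Tips carry their taxon labels as ids;
    internal nodes get ids ``"N<postorder position>"`` unless labeled in the
    source tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        nodes = list(tree.seed_node.postorder_iter())
        self._index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.children = np.full((n, 2), -1, dtype=int)
        self.edge_length = np.zeros(n)
        self.is_tip = np.zeros(n, dtype=bool)
        self.labels: list[str] = [""] * n

        for i, nd in enumerate(nodes):
            ch = nd.child_nodes()
            if len(ch) == 1 or len(ch) > 2:
                tips = [t.taxon.label for t in nd.leaf_iter() if t.taxon][:4]
                raise ValueError(
                    f"tree is not fully bifurcating: node above tips "
                    f"{{{', '.join(tips)}{', ...' if len(ch) > 2 else ''}}} has "
                    f"{len(ch)} children"
                )
            if ch:
                self.children[i] = [self._index[id(c)] for c in ch]
            else:
                self.is_tip[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("tree has an unlabeled tip")
                self.labels[i] = nd.taxon.label
            if nd.parent_node is not None:
                self.parent[i] = self._index[id(nd.parent_node)]
                if nd.edge.length is None:
                    who = self.labels[i] or f"internal node {i}"
                    raise ValueError(f"missing branch length above {who}")
                self.edge_length[i] = float(nd.edge.length)
            else:
                self.edge_length[i] = float(nd.edge.length or 0.0)

        tip_labels = [l for l, t in zip(self.labels, self.is_tip) if t]
        if len(tip_labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        if len(set(tip_labels)) != len(tip_labels):
            dup = next(l for l in tip_labels if tip_labels.count(l) > 1)
            raise ValueError(f"duplicate tip label {dup!r}")

        # depths from root, then ultrametricity and ages
        self.root = n - 1  # postorder: root last
        depth = np.zeros(n)
        for i in reversed(range(n)):
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.edge_length[i]
        tip_depth = depth[self.is_tip]
        height = float(tip_depth.max())
        spread = float(tip_depth.max() - tip_depth.min())
        if height <= 0:
            raise ValueError("tree height must be positive")
        if spread > ULTRAMETRIC_RTOL * height:
            shallow = tip_labels[int(np.argmin(tip_depth))]
            deep = tip_labels[int(np.argmax(tip_depth))]
            raise ValueError(
                f"tree is not ultrametric: root-to-tip depth ranges from "
                f"{tip_depth.min():.6g} ({shallow}) to {tip_depth.max():.6g} ({deep})"
            )
        self.height = height
        self.age = height - depth
        self.age[self.is_tip] = 0.0

        for i, nd in enumerate(nodes):
            if not self.is_tip[i]:
                self.labels[i] = (nd.label or "") or f"N{i}"
        self.node_index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_labels(self) -> list[str]:
        return [l for l, t in zip(self.labels, self.is_tip) if t]

    def postorder(self) -> range:
        """Node indices, children before parents."""
        return range(self.n_nodes)

    def mrca(self, tip_labels: list[str]) -> int:
        """Index of the most recent common ancestor of the named tips."""
        idx = []
        for lab in tip_labels:
            if lab not in self.node_index or not self.is_tip[self.node_index[lab]]:
                raise KeyError(f"unknown tip {lab!r}")
            idx.append(self.node_index[lab])
        # walk each tip's ancestor chain; intersect
        chains = []
        for i in idx:
            chain = []
            while i >= 0:
                chain.append(i)
                i = self.parent[i]
            chains.append(chain)
        common = set(chains[0]).intersection(*map(set, chains[1:])) if len(chains) > 1 else set(chains[0])
        return min(common, key=lambda i: self.age[i]) if len(chains) > 1 else idx[0]

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram {self.n_tips} tips, height {self.height:.4g} Myr>"


def read_newick(text: str) -> Chronogram:
    """Parse a Newick (or minimal Nexus) chronogram and validate it."""
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree = dendropy.Tree.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"could not parse {schema} tree: {exc}") from exc
    return Chronogram(tree)


def _write_node(chrono: Chronogram, i: int, comments: dict[int, str] | None) -> str:
    if chrono.is_tip[i]:
        s = chrono.labels[i]
    else:
        kids = ",".join(_write_node(chrono, int(c), comments) for c in chrono.children[i])
        s = f"({kids})"
    if comments and i in comments:
        s += f"[{comments[i]}]"
    if chrono.parent[i] >= 0:
        s += f":{chrono.edge_length[i]:.12g}"
    return s


def write_newick(chrono: Chronogram) -> str:
    """Newick text preserving branch lengths to 12 significant digits."""
    return _write_node(chrono, chrono.root, None) + ";"


def write_annotated(chrono: Chronogram, reconstructions) -> str:
    """Newick with ``[&range=...,p=...]`` comments at reconstructed nodes.

    ``reconstructions`` is an iterable of objects with ``node_id``,
    ``top_range_label`` and ``top_prob`` attributes (see
    :class:`rangedec.reconstruct.NodeReconstruction`).
    """
    comments = {}
    for rec in reconstructions or ():
        i = chrono.node_index[rec.node_id]
        comments[i] = f"&range={rec.top_range_label},p={rec.top_prob:.4g}"
    return _write_node(chrono, chrono.root, comments) + ";"


@dataclass
class TipRangeTable:
    """Presence/absence ranges per tip, bit order matching the area order."""

    system: AreaSystem
    ranges: dict[str, Range]

    def __post_init__(self):
        for label, r in self.ranges.items():
            if r.bits == 0:
                raise ValueError(f"taxon {label!r} has an all-zero (empty) range")
            if r.bits >> self.system.n_areas:
                raise ValueError(
                    f"taxon {label!r} range uses areas beyond the {self.system.n_areas}-area system"
                )

    def __len__(self) -> int:
        return len(self.ranges)

    def __getitem__(self, label: str) -> Range:
        return self.ranges[label]

    def validate_against(self, chrono: Chronogram, space: RangeSpace | None = None):
        """Check the table covers exactly the tree's tips (and fits the space)."""
        tips = set(chrono.tip_labels)
        missing = tips - self.ranges.keys()
        extra = self.ranges.keys() - tips
        if missing:
            raise ValueError(f"no range given for tip {sorted(missing)[0]!r}")
        if extra:
            raise ValueError(f"range table names unknown tip {sorted(extra)[0]!r}")
        if space is not None:
            for label in chrono.tip_labels:
                bits = self.ranges[label].bits
                if bits not in space:
                    raise ValueError(
                        f"tip {label!r} range {self.system.format_range(bits)} is not "
                        "in the range space (adjacency/size constraint conflict)"
                    )


def read_ranges(text: str, area_system: AreaSystem) -> TipRangeTable:
    """Parse a tip-range table, auto-detecting the dialect from the first line.

    Dialects: header+binary (``"n_taxa n_areas"`` then ``"label 010010"``
    lines) and TSV with a header of area codes.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty range table")
    first = lines[0].split()
    ranges: dict[str, Range] = {}
    n = area_system.n_areas

    def decode(label: str, vec: str) -> Range:
        if label in ranges:
            raise ValueError(f"duplicate taxon {label!r}")
        if len(vec) != n or set(vec) - {"0", "1"}:
            raise ValueError(
                f"taxon {label!r}: presence vector {vec!r} must be {n} binary digits"
            )
        bits = sum(1 << i for i, c in enumerate(vec) if c == "1")
        if bits == 0:
            raise ValueError(f"taxon {label!r} has an all-zero (empty) range")
        return Range(bits)

    if len(first) == 2 and all(p.isdigit() for p in first):
        n_taxa, n_areas = map(int, first)
        if n_areas != n:
            raise ValueError(f"header declares {n_areas} areas, system has {n}")
        body = lines[1:]
        if len(body) != n_taxa:
            raise ValueError(f"header declares {n_taxa} taxa, found {len(body)} rows")
        for ln in body:
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"bad range row {ln!r}")
            ranges[parts[0]] = decode(parts[0], parts[1])
    else:
        header = first
        if [h.upper() for h in header[:1]] != ["TAXON"] or header[1:] != area_system.codes:
            raise ValueError(
                f"TSV header must be 'taxon {' '.join(area_system.codes)}', got {lines[0]!r}"
            )
        for ln in lines[1:]:
            parts = ln.split()
            if len(parts) != n + 1:
                raise ValueError(f"taxon {parts[0]!r}: expected {n} columns")
            ranges[parts[0]] = decode(parts[0], "".join(parts[1:]))
    return TipRangeTable(area_system, ranges)


def write_ranges(table: TipRangeTable, dialect: str = "lagrange") -> str:
    """Serialize a range table (``"lagrange"`` or ``"tsv"`` dialect)."""
    n = table.system.n_areas
    items = sorted(table.ranges.items())
    if dialect == "lagrange":
        out = [f"{len(items)} {n}"]
        for label, r in items:
            vec = "".join("1" if r.bits >> i & 1 else "0" for i in range(n))
            out.append(f"{label} {vec}")
    elif dialect == "tsv":
        out = ["taxon\t" + "\t".join(table.system.codes)]
        for label, r in items:
            out.append(label + "\t" + "\t".join(str(r.bits >> i & 1) for i in range(n)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\n".join(out) + "\n"
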