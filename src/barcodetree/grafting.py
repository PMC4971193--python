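"""Placement of barcode OTUs onto a fixed backbone, plus distances and
site-rate partitions.

The backbone constraint is never re-arranged: query sequences are
inserted one at a time, each on the edge that minimizes a placement
criterion, so the restriction of the result to the backbone's leaves is
always the backbone itself. Two criteria are provided: ``parsimony``
(total Fitch length of the tree after insertion) and ``min_evolution``
(least-squares fit of the attachment point and pendant branch to the
observed pairwise distances). Full maximum-likelihood searches are out
of scope; the module instead exports the alignment, constraint and
site-rate partition files that external ML programs consume.

Distances are p-distance (proportion of differing sites) or Kimura
two-parameter (K2P), with pairwise deletion of sites containing gaps or
ambiguity codes. Site-rate classes for partitioned analyses use the
minimum number of state changes per alignment column on a guide tree
(Fitch parsimony) as the rate proxy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .trees import leaf_labels

__all__ = [
    "DistanceMatrix",
    "SiteRatePartition",
    "pairwise_distance",
    "graft",
    "assign_site_rates",
    "write_phylip",
    "write_partition_file",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
#: Fitch state bitmasks; ambiguity codes map to the union of their bases.
_FITCH_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15, "-": 15,
}
_PURINES = {0, 2}  # A, G


def _encode_plain(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 255 (excluded from comparisons)."""
    arr = np.full(len(seq), 255, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype="S1") == base.encode()] = idx
    return arr


def _encode_fitch(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = _FITCH_MASK[ch]
        except KeyError:
            raise ValueError(f"invalid character {ch!r} at position {i}") from None
    return out


def pairwise_distance(
    seq_a: str,
    seq_b: str,
    model: str = "p",
    pairwise_deletion: bool = True,
) -> float:
    """Pairwise distance between two aligned sequences.

    ``p``: mismatches / compared sites. ``K2P``:
    ``-0.5 ln(1 - 2P - Q) - 0.25 ln(1 - 2Q)`` with P and Q the transition
    and transversion proportions. Sites where either sequence carries a
    gap or ambiguity code are excluded when ``pairwise_deletion`` (they
    are always excluded from the mismatch counts, since an ambiguous
    base cannot be scored). Returns ``nan`` when no sites are
    comparable and ``inf`` when the K2P logarithm saturates.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}"
        )
    a, b = _encode_plain(seq_a), _encode_plain(seq_b)
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        return math.nan
    diff = ok & (a != b)
    if model == "p":
        return float(diff.sum()) / n
    if model != "K2P":
        raise ValueError(f"unknown distance model {model!r}")
    a_pur = (a == 0) | (a == 2)
    b_pur = (b == 0) | (b == 2)
    transitions = int((diff & (a_pur == b_pur)).sum())
    transversions = int((diff & (a_pur != b_pur)).sum())
    P, Q = transitions / n, transversions / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labeled sequences."""

    labels: list[str]
    d: np.ndarray
    model: str = "p"
    pairwise_deletion: bool = True

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise ValueError("duplicate labels in distance matrix")

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        model: str = "p",
        pairwise_deletion: bool = True,
    ) -> "DistanceMatrix":
        labels = list(sequences)
        n = len(labels)
        d = np.zeros((n, n), dtype=float)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pairwise_distance(
                    sequences[labels[i]],
                    sequences[labels[j]],
                    model,
                    pairwise_deletion,
                )
        return cls(labels, d, model, pairwise_deletion)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self._index[l] for l in labels]
        return DistanceMatrix(
            list(labels), self.d[np.ix_(idx, idx)], self.model, self.pairwise_deletion
        )

    def to_tsv(self, sink) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            sink, sep="\t"
        )


# ---------------------------------------------------------------------------
# Lightweight mutable tree used during grafting (dendropy in/out).


class _GNode:
    __slots__ = ("children", "parent", "label", "length", "mask")

    def __init__(self, label=None, length=None):
        self.children: list[_GNode] = []
        self.parent: _GNode | None = None
        self.label = label
        self.length = length
        self.mask: np.ndarray | None = None

    def add(self, child: "_GNode") -> None:
        child.parent = self
        self.children.append(child)

    def is_leaf(self) -> bool:
        return not self.children


def _from_dendropy(tree: dendropy.Tree) -> _GNode:
    def build(node) -> _GNode:
        g = _GNode(
            label=node.taxon.label if node.taxon else None,
            length=node.edge.length,
        )
        for child in node.child_nodes():
            g.add(build(child))
        return g

    return build(tree.seed_node)


def _to_dendropy(root: _GNode) -> dendropy.Tree:
    tree = dendropy.Tree()

    def build(g: _GNode, node) -> None:
        for child in g.children:
            nd = node.new_child()
            nd.edge.length = child.length
            if child.is_leaf():
                nd.taxon = tree.taxon_namespace.require_taxon(label=child.label)
            build(child, nd)

    tree.seed_node.edge.length = root.length
    if root.is_leaf():
        tree.seed_node.taxon = tree.taxon_namespace.require_taxon(label=root.label)
    build(root, tree.seed_node)
    return tree


def _postorder(root: _GNode) -> list[_GNode]:
    out, stack = [], [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            out.append(node)
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))
    return out


def _edges_postorder(root: _GNode) -> list[_GNode]:
    """Edges as their child node, in post-order (deterministic index)."""
    return [n for n in _postorder(root) if n.parent is not None]


def _fitch_length(root: _GNode, masks: dict[str, np.ndarray], n_sites: int) -> int:
    """Total Fitch parsimony length over all sites (vectorized)."""
    total = np.zeros(n_sites, dtype=np.int64)
    for node in _postorder(root):
        if node.is_leaf():
            node.mask = masks[node.label]
            continue
        acc = node.children[0].mask
        for child in node.children[1:]:
            inter = acc & child.mask
            empty = inter == 0
            total += empty
            acc = np.where(empty, acc | child.mask, inter)
        node.mask = acc
    return int(total.sum())


def _leaf_distances(root: _GNode) -> tuple[list[str], dict[int, np.ndarray]]:
    """Distance from every node to every leaf through the tree.

    Missing branch lengths count as 0.
    """
    nodes = _postorder(root)
    index = {id(n): i for i, n in enumerate(nodes)}
    leaves = [n for n in nodes if n.is_leaf()]
    leaf_order = [n.label for n in leaves]
    n_leaves = len(leaves)
    dist = {id(n): np.full(n_leaves, np.inf) for n in nodes}
    # down-pass: distances to leaves within each subtree
    for node in nodes:
        if node.is_leaf():
            dist[id(node)][leaf_order.index(node.label)] = 0.0
        else:
            for child in node.children:
                length = child.length or 0.0
                dist[id(node)] = np.minimum(
                    dist[id(node)], dist[id(child)] + length
                )
    # up-pass: distances through the parent
    order = list(reversed(nodes))  # preorder
    for node in order:
        for child in node.children:
            length = child.length or 0.0
            dist[id(child)] = np.minimum(
                dist[id(child)], dist[id(node)] + length
            )
    _ = index
    return leaf_order, dist


def _ls_edge_fit(
    deltas: np.ndarray, a: np.ndarray, s: np.ndarray, b: float
) -> tuple[float, float, float]:
    """Weighted least-squares attachment along one edge.

    Observed query-to-leaf distances ``deltas`` are modeled as
    ``a_i + s_i * t + y`` with ``t`` the position along the edge (0..b)
    and ``y >= 0`` the pendant length. Distances are weighted by
    ``1/delta^2`` (Fitch–Margoliash): large distances carry the largest
    sampling variance and would otherwise swamp the informative near
    neighbours. Returns (weighted SSQ, t, y).
    """
    finite = np.isfinite(deltas) & np.isfinite(a)
    if not finite.any():
        return math.inf, 0.0, 0.0
    dd, aa, ss = deltas[finite], a[finite], s[finite]
    w = 1.0 / np.maximum(dd, 1e-4) ** 2
    r = dd - aa
    X = np.column_stack([ss, np.ones_like(ss)])
    Xw = X * w[:, None]
    sol, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ r, rcond=None)
    t, y = float(sol[0]), float(sol[1])
    t = min(max(t, 0.0), b)
    y = max(float(np.sum(w * (r - ss * t)) / np.sum(w)), 0.0)
    resid = r - ss * t - y
    return float(np.sum(w * resid * resid)), t, y


def _fit_branch_lengths(root: _GNode, dm: DistanceMatrix) -> None:
    """Ordinary least-squares branch lengths from pairwise distances.

    Used when the backbone (a constraint tree) carries no lengths but
    the min-evolution criterion needs them.
    """
    edges = _edges_postorder(root)
    leaf_order, _ = _leaf_distances(root)
    n_leaves = len(leaf_order)
    # membership: which leaves lie below each edge
    below = []
    for child in edges:
        labels = set()
        stack = [child]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                labels.add(nd.label)
            stack.extend(nd.children)
        below.append(labels)
    rows, rhs = [], []
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            delta = dm.get(leaf_order[i], leaf_order[j])
            if not math.isfinite(delta):
                continue
            row = np.array(
                [
                    1.0 if (leaf_order[i] in bl) != (leaf_order[j] in bl) else 0.0
                    for bl in below
                ]
            )
            rows.append(row)
            rhs.append(delta)
    if not rows:
        raise ValueError("no finite distances available to fit branch lengths")
    A = np.vstack(rows)
    sol, *_ = np.linalg.lstsq(A, np.asarray(rhs), rcond=None)
    for child, length in zip(edges, sol):
        child.length = max(float(length), 0.0)


def graft(
    backbone: dendropy.Tree,
    sequences: dict[str, str],
    placement_criterion: str = "min_evolution",
    distance_model: str = "K2P",
    pairwise_deletion: bool = True,
) -> dendropy.Tree:
    """Insert every non-backbone sequence onto the fixed backbone.

    ``sequences`` maps leaf labels to aligned sequences and must cover
    all backbone leaves; labels not on the backbone are the queries.
    Queries are processed in sorted order; each is attached to the edge
    minimizing the criterion, with ties broken by the lowest post-order
    edge index. The output restricted to the backbone's leaves is
    topologically identical to the backbone — grafting never reorders
    backbone edges.

    ``min_evolution`` defaults to the K2P distance: the multiple-hit
    correction keeps distances approximately additive at depths where
    raw p-distances flatten out.
    """
    if placement_criterion not in ("parsimony", "min_evolution"):
        raise ValueError(f"unknown placement criterion {placement_criterion!r}")
    backbone_leaves = leaf_labels(backbone)
    missing = [l for l in backbone_leaves if l not in sequences]
    if missing:
        raise ValueError(f"no sequence for backbone leaves {missing[:5]}")
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences are not aligned to equal length: {sorted(lengths)}")
    queries = sorted(set(sequences) - set(backbone_leaves))
    root = _from_dendropy(backbone)
    if not queries:
        return _to_dendropy(root)

    n_sites = lengths.pop()
    if placement_criterion == "parsimony":
        masks = {lab: _encode_fitch(seq) for lab, seq in sequences.items()}
        for query in queries:
            _insert_parsimony(root, query, masks, n_sites)
    else:
        dm = DistanceMatrix.from_sequences(
            sequences, distance_model, pairwise_deletion
        )
        # Saturated (inf) corrected distances are unusable for the fit; a
        # query with no finite distance at all falls back to p-distances.
        fallback = (
            DistanceMatrix.from_sequences(sequences, "p", pairwise_deletion)
            if distance_model != "p"
            else dm
        )
        if any(n.length is None for n in _edges_postorder(root)):
            _fit_branch_lengths(root, dm if _has_finite(dm) else fallback)
        for query in queries:
            _insert_min_evolution(root, query, dm, fallback)
    return _to_dendropy(root)


def _has_finite(dm: DistanceMatrix) -> bool:
    off_diag = dm.d[~np.eye(len(dm.labels), dtype=bool)]
    return bool(np.isfinite(off_diag).any())


def _attach(child: _GNode, query: str, t: float | None, y: float | None) -> None:
    parent = child.parent
    joint = _GNode(length=None if t is None else t)
    b = child.length
    parent.children[parent.children.index(child)] = joint
    joint.parent = parent
    joint.add(child)
    if t is not None and b is not None:
        child.length = max(b - t, 0.0)
    leaf = _GNode(label=query, length=y)
    joint.add(leaf)


def _insert_parsimony(
    root: _GNode, query: str, masks: dict[str, np.ndarray], n_sites: int
) -> None:
    best = (math.inf, -1)
    edges = _edges_postorder(root)
    for idx, child in enumerate(edges):
        _attach(child, query, None, None)
        score = _fitch_length(root, masks, n_sites)
        _detach(child)
        if score < best[0]:
            best = (score, idx)
    _attach(edges[best[1]], query, None, None)


def _detach(child: _GNode) -> None:
    """Undo `_attach`: remove the joint node above ``child``."""
    joint = child.parent
    parent = joint.parent
    if joint.length is not None and child.length is not None:
        child.length += joint.length
    parent.children[parent.children.index(joint)] = child
    child.parent = parent


def _insert_min_evolution(
    root: _GNode,
    query: str,
    dm: DistanceMatrix,
    fallback: DistanceMatrix | None = None,
) -> None:
    leaf_order, dist = _leaf_distances(root)
    deltas = np.array([dm.get(query, leaf) for leaf in leaf_order])
    if fallback is not None and not np.isfinite(deltas).any():
        deltas = np.array([fallback.get(query, leaf) for leaf in leaf_order])
    edges = _edges_postorder(root)
    below_mask = {}
    for child in edges:
        labels = set()
        stack = [child]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                labels.add(nd.label)
            stack.extend(nd.children)
        below_mask[id(child)] = np.array(
            [l in labels for l in leaf_order], dtype=bool
        )
    best = (math.inf, -1, 0.0, 0.0)
    for idx, child in enumerate(edges):
        b = child.length or 0.0
        under = below_mask[id(child)]
        a = np.where(
            under,
            b + dist[id(child)],
            dist[id(child.parent)],
        )
        s = np.where(under, -1.0, 1.0)
        ssq, t, y = _ls_edge_fit(deltas, a, s, b)
        if ssq < best[0] - 1e-12:
            best = (ssq, idx, t, y)
    if best[1] < 0:
        raise ValueError(f"no placement possible for query {query!r}")
    _attach(edges[best[1]], query, best[2], best[3])


# ---------------------------------------------------------------------------
# Site-rate partitioning


@dataclass
class SiteRatePartition:
    """Per-column rate-class assignment (classes 1..k, slowest first)."""

    assignment: np.ndarray
    k: int
    rate_proxy: np.ndarray = field(default=None, repr=False)

    def columns_of(self, cls: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cls)


def assign_site_rates(
    alignment: dict[str, str], guide_tree: dendropy.Tree, k: int = 4
) -> SiteRatePartition:
    """Bin alignment columns into ``k`` rate classes.

    The per-site rate proxy is the minimum number of changes on the
    guide tree (Fitch parsimony), computed over the taxa shared between
    the alignment and the tree. Sites are assigned by quantile of the
    proxy distribution, so invariant sites always land in class 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shared = [l for l in leaf_labels(guide_tree) if l in alignment]
    if len(shared) < 2:
        raise ValueError("guide tree shares fewer than 2 taxa with the alignment")
    from .trees import restrict_tree

    sub = restrict_tree(guide_tree, set(shared))
    root = _from_dendropy(sub)
    n_sites = len(next(iter(alignment.values())))
    if any(len(s) != n_sites for s in alignment.values()):
        raise ValueError("alignment columns are ragged")
    masks = {lab: _encode_fitch(alignment[lab]) for lab in shared}
    changes = np.zeros(n_sites, dtype=np.int64)
    for node in _postorder(root):
        if node.is_leaf():
            node.mask = masks[node.label]
            continue
        acc = node.children[0].mask
        for child in node.children[1:]:
            inter = acc & child.mask
            empty = inter == 0
            changes += empty
            acc = np.where(empty, acc | child.mask, inter)
        node.mask = acc
    n_distinct = len(np.unique(changes))
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct rate value(s) observed"
        )
    # Quantile binning via midpoint ranks: a site's quantile is the
    # fraction of sites strictly slower plus half the fraction tied
    # with it, so ties land in one class and skewed distributions still
    # spread across classes. Invariant sites are always class 1.
    sorted_changes = np.sort(changes)
    below = np.searchsorted(sorted_changes, changes, side="left")
    upto = np.searchsorted(sorted_changes, changes, side="right")
    quantile = (below + 0.5 * (upto - below)) / n_sites
    assignment = np.minimum((quantile * k).astype(int) + 1, k)
    assignment[changes == 0] = 1
    return SiteRatePartition(assignment=assignment, k=k, rate_proxy=changes)


def write_phylip(alignment: dict[str, str], sink) -> None:
    """Relaxed PHYLIP writer (name, two spaces, sequence)."""
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        n = len(alignment)
        length = len(next(iter(alignment.values()))) if alignment else 0
        fh.write(f"{n} {length}\n")
        for name, seq in alignment.items():
            fh.write(f"{name}  {seq}\n")
    finally:
        if own:
            fh.close()


def write_partition_file(partition: SiteRatePartition, sink) -> None:
    """RAxML-style partition file: one DNA line per rate class with
    1-based column ranges."""
    own = isinstance(sink, str)
    fh = open(sink, "w") if own else sink
    try:
        for cls in range(1, partition.k + 1):
            cols = partition.columns_of(cls) + 1
            if cols.size == 0:
                continue
            ranges, start, prev = [], cols[0], cols[0]
            for c in cols[1:]:
                if c == prev + 1:
                    prev = c
                    continue
                ranges.append((start, prev))
                start = prev = c
            ranges.append((start, prev))
            spans = ", ".join(
                f"{a}-{b}" if a != b else f"{a}" for a, b in ranges
            )
            fh.write(f"DNA, rate{cls} = {spans}\n")
    finally:
        if own:
            fh.close()
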