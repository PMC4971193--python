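"""Shared tree helpers on top of dendropy.

All modules exchange trees as :class:`dendropy.Tree` objects with
uniquely labeled leaves. Support values live on ``node.label`` in Newick
files (the usual internal-node-label convention) and are parsed into
``node.support`` according to declared semantics — bootstrap percentages
or posterior probabilities — never guessed from magnitude.
"""

from __future__ import annotations

import io

import dendropy

__all__ = [
    "read_tree",
    "write_tree",
    "parse_supports",
    "leaf_labels",
    "clade_leaf_sets",
    "splits_of",
    "splits_compatible",
    "restrict_tree",
    "same_topology",
]


def read_tree(source, supports: str | None = None) -> dendropy.Tree:
    """Read one Newick tree from a path, stream or string.

    ``supports``: ``"bootstrap"`` or ``"posterior"`` parses internal node
    labels into ``node.support`` and tags the tree with
    ``tree.support_semantics``; ``None`` leaves labels untouched.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        text = str(source)
        if text.lstrip().startswith("(") or ";" in text:
            data = text
        else:
            with open(text) as fh:
                data = fh.read()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if supports is not None:
        parse_supports(tree, supports)
    return tree


def write_tree(tree: dendropy.Tree, sink=None, branch_lengths: bool = True) -> str:
    """Serialize to Newick; returns the string and optionally writes it."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_edge_lengths=not branch_lengths,
    )
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w") as fh:
                fh.write(text)
    return text


def parse_supports(tree: dendropy.Tree, semantics: str) -> None:
    """Attach ``node.support`` from internal node labels.

    Bootstrap supports must lie in [0, 100], posteriors in [0, 1];
    out-of-range values are a hard error.
    """
    if semantics not in ("bootstrap", "posterior"):
        raise ValueError(f"unknown support semantics {semantics!r}")
    hi = 100.0 if semantics == "bootstrap" else 1.0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        support = None
        if node.label not in (None, ""):
            try:
                support = float(node.label)
            except ValueError:
                raise ValueError(
                    f"internal node label {node.label!r} is not a support value"
                ) from None
            if not (0.0 <= support <= hi):
                raise ValueError(
                    f"support {support} outside [0, {hi}] for {semantics}"
                )
        node.support = support
    tree.support_semantics = semantics


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def clade_leaf_sets(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf-label set below every internal node (root included)."""
    out = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._leafset = frozenset([node.taxon.label])
        else:
            node._leafset = frozenset().union(*(c._leafset for c in node.child_nodes()))
            out.append(node._leafset)
    return out


def splits_of(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial splits induced by internal edges.

    Each split is reported as the side that does NOT contain the
    lexicographically smallest leaf (canonical orientation), so rooted
    and unrooted drawings of the same topology yield identical sets.
    """
    leaves = frozenset(leaf_labels(tree))
    if len(leaves) < 4:
        return set()
    anchor = min(leaves)
    splits: set[frozenset[str]] = set()
    for clade in clade_leaf_sets(tree):
        side = clade if anchor not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def splits_compatible(
    a: frozenset[str], b: frozenset[str], leaves: frozenset[str]
) -> bool:
    """Pairwise split compatibility over a common leaf universe.

    Splits A|A' and B|B' are compatible iff at least one of the four
    intersections A∩B, A∩B', A'∩B, A'∩B' is empty.
    """
    a2, b2 = leaves - a, leaves - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def restrict_tree(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Induced subtree on ``keep`` leaves, unifurcations suppressed."""
    sub = tree.extract_tree(
        node_filter_fn=lambda nd: (not nd.is_leaf()) or nd.taxon.label in keep,
        suppress_unifurcations=True,
    )
    # extract_tree keeps internal nodes whose subtree became empty; prune them
    changed = True
    while changed:
        changed = False
        for node in list(sub.leaf_node_iter()):
            if node.taxon is None or node.taxon.label not in keep:
                parent = node.parent_node
                if parent is not None:
                    parent.remove_child(node)
                    changed = True
    sub.suppress_unifurcations()
    return sub


def same_topology(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    """Topological identity in the unrooted sense (leaf sets and splits)."""
    la, lb = frozenset(leaf_labels(a)), frozenset(leaf_labels(b))
    if la != lb:
        return False
    return splits_of(a) == splits_of(b)


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Robinson–Foulds (symmetric split difference) on a shared leaf set."""
    la, lb = frozenset(leaf_labels(a)), frozenset(leaf_labels(b))
    if la != lb:
        raise ValueError("trees must share an identical leaf set")
    return len(splits_of(a) ^ splits_of(b))
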