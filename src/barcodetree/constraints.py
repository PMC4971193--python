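"""Building a multifurcating backbone constraint from published trees.

Barcode data resolve the tips of a tree well but are unreliable for deep
divergences, so tree searches are constrained by a backbone synthesized
from better-sampled analyses: only nodes passing explicit support
criteria (bootstrap strictly above a cutoff, posterior probability of
1.0, or corroboration by two or more independent loci) are retained;
everything else is collapsed into polytomies that the sequence data are
free to resolve. Family- and genus-level constraint trees are then
nested into the order-level backbone by compatible refinement — a
conflict between a sub-constraint and a resolved split of the backbone
is a hard error, not a vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .trees import (
    clade_leaf_sets,
    leaf_labels,
    parse_supports,
    read_tree,
    splits_compatible,
    splits_of,
    write_tree,
)

__all__ = [
    "SupportCriteria",
    "collapse_unsupported",
    "nest_constraints",
    "splits_of",
    "IncompatibleConstraintError",
]

#: Tolerance absorbing serialization rounding of "posterior = 1.0".
_PP_EPS = 1e-9


class IncompatibleConstraintError(ValueError):
    """A sub-constraint contradicts a resolved split of the backbone."""

    def __init__(self, split_a, split_b):
        self.split_a = frozenset(split_a)
        self.split_b = frozenset(split_b)
        super().__init__(
            "incompatible constraints: clade "
            f"{sorted(self.split_a)} conflicts with clade {sorted(self.split_b)}"
        )


@dataclass(frozen=True)
class SupportCriteria:
    """Thresholds deciding which source-tree nodes become constraints.

    ``bootstrap_min`` is strict ("above 85%" keeps 86, drops 85);
    ``pp_min`` is non-strict and defaults to 1.0, compared with a small
    epsilon so a serialized ``0.9999999999`` still counts as 1.0.
    Nodes flagged as corroborated by two or more independent loci are
    kept regardless of support when ``accept_multi_locus`` is set.
    """

    bootstrap_min: float = 85.0
    pp_min: float = 1.0
    accept_multi_locus: bool = True
    support_semantics: str = "bootstrap"

    def __post_init__(self):
        if not 0.0 <= self.bootstrap_min <= 100.0:
            raise ValueError("bootstrap_min must be in [0, 100]")
        if not 0.0 <= self.pp_min <= 1.0:
            raise ValueError("pp_min must be in [0, 1]")
        if self.support_semantics not in ("bootstrap", "posterior"):
            raise ValueError(
                f"unknown support semantics {self.support_semantics!r}"
            )

    def node_passes(self, node) -> bool:
        if self.accept_multi_locus and getattr(node, "multi_locus_corroborated", False):
            return True
        support = getattr(node, "support", None)
        if support is None:
            return False
        if self.support_semantics == "bootstrap":
            return support > self.bootstrap_min
        return support >= self.pp_min - _PP_EPS


def collapse_unsupported(
    tree: dendropy.Tree, criteria: SupportCriteria | None = None
) -> dendropy.Tree:
    """Collapse internal nodes failing the support criteria.

    Children of a failing node are promoted to its parent, producing a
    multifurcating constraint tree. Leaves and the root are never
    collapsed, and branch lengths are discarded (a constraint carries
    topology only).
    """
    if criteria is None:
        criteria = SupportCriteria()
    out = tree.clone(depth=1)
    parse_supports(out, criteria.support_semantics)
    for src, dst in zip(tree.preorder_node_iter(), out.preorder_node_iter()):
        if getattr(src, "multi_locus_corroborated", False):
            dst.multi_locus_corroborated = True
    to_collapse = [
        node
        for node in out.preorder_internal_node_iter(exclude_seed_node=True)
        if not criteria.node_passes(node)
    ]
    for node in to_collapse:
        node.edge.collapse()
    for edge in out.preorder_edge_iter():
        edge.length = None
    return out


def nest_constraints(
    order_tree: dendropy.Tree,
    sub_trees: list[tuple[set[str], dendropy.Tree]],
) -> dendropy.Tree:
    """Refine an order-level backbone with family/genus constraint trees.

    Each ``(attachment_taxon_set, sub_tree)`` pair nests one finer
    constraint: leaves shared with the backbone anchor the sub-tree's
    topology inside the clade spanned by ``attachment_taxon_set`` (or by
    the shared leaves when the attachment set is empty); leaves present
    only in the sub-tree are added. Resolved backbone structure outside
    the region is untouched. Any conflict between a sub-tree clade and a
    resolved backbone split raises :class:`IncompatibleConstraintError`.
    """
    merged = order_tree.clone(depth=1)
    for edge in merged.preorder_edge_iter():
        edge.length = None
    for attachment, sub in sub_trees:
        _nest_one(merged, set(attachment or ()), sub)
    merged.update_taxon_namespace()
    return merged


def _nest_one(tree: dendropy.Tree, attachment: set[str], sub: dendropy.Tree) -> None:
    tree_leaves = set(leaf_labels(tree))
    sub_leaves = set(leaf_labels(sub))
    shared = tree_leaves & sub_leaves
    if not shared:
        raise ValueError(
            "sub-constraint shares no leaves with the backbone; cannot anchor it"
        )
    region = attachment & tree_leaves or shared
    mrca = _mrca(tree, region)
    region_leaves = _leafset(mrca)
    if not shared <= region_leaves:
        raise ValueError(
            "shared leaves of the sub-constraint are not contained in the "
            f"attachment clade (outside: {sorted(shared - region_leaves)})"
        )

    # Clade constraints of the sub-tree, smallest first so nesting builds up.
    sub_clades = sorted(_rooted_clades(sub), key=len)
    # 1. Attach leaves that are new to the backbone.
    for leaf in sorted(sub_leaves - tree_leaves):
        anchor_clade = next(
            (c for c in sub_clades if leaf in c and c & set(leaf_labels(tree))),
            None,
        )
        if anchor_clade is None:
            anchor_nodes = shared
        else:
            anchor_nodes = anchor_clade & set(leaf_labels(tree))
        target = _mrca(tree, anchor_nodes)
        taxon = tree.taxon_namespace.get_taxon(leaf)
        if taxon is None:
            taxon = tree.taxon_namespace.new_taxon(label=leaf)
        if target.is_leaf():
            # Make the anchor leaf and the new leaf siblings.
            parent = target.parent_node
            group = parent.new_child()
            parent.remove_child(target)
            group.add_child(target)
            group.new_child(taxon=taxon)
        else:
            target.new_child(taxon=taxon)
    # 2. Impose every sub-tree clade as a grouping constraint.
    for clade in sub_clades:
        _force_clade(tree, clade)


def _force_clade(tree: dendropy.Tree, clade: frozenset[str]) -> None:
    """Group the leaves of ``clade`` into one clade, refining polytomies.

    Raises :class:`IncompatibleConstraintError` when a child of the
    relevant node straddles the clade boundary (the constraint would
    break a resolved split).
    """
    present = clade & set(leaf_labels(tree))
    if len(present) < 2:
        return
    mrca = _mrca(tree, present)
    inside, outside, straddling = [], [], []
    for child in mrca.child_nodes():
        leaves = _leafset(child)
        if leaves <= clade:
            inside.append(child)
        elif leaves & clade:
            straddling.append((child, leaves))
        else:
            outside.append(child)
    if straddling:
        child, leaves = straddling[0]
        raise IncompatibleConstraintError(present, leaves)
    if not outside:
        return  # mrca already equals the clade
    group = mrca.new_child()
    for child in inside:
        mrca.remove_child(child)
        group.add_child(child)


def _rooted_clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    # The root clade is included: a family constraint tree asserts that
    # the family itself is a clade.
    return [c for c in clade_leaf_sets(tree) if len(c) >= 2]


def _mrca(tree: dendropy.Tree, labels) -> dendropy.Node:
    labels = set(labels)
    best = None
    for node in tree.postorder_node_iter():
        if labels <= _leafset(node):
            best = node
            break
    if best is None:
        raise ValueError(f"labels {sorted(labels)} not all present in tree")
    return best


def _leafset(node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def check_compatibility(trees: list[dendropy.Tree]) -> None:
    """Verify pairwise split compatibility of trees on shared leaves."""
    for i, a in enumerate(trees):
        for b in trees[i + 1 :]:
            common = frozenset(leaf_labels(a)) & frozenset(leaf_labels(b))
            if len(common) < 4:
                continue
            from .trees import restrict_tree

            sa = splits_of(restrict_tree(a, common))
            sb = splits_of(restrict_tree(b, common))
            for x in sa:
                for y in sb:
                    if not splits_compatible(x, y, common):
                        raise IncompatibleConstraintError(x, y)


def write_constraint(tree: dendropy.Tree, sink=None) -> str:
    """Write the backbone as a support-free, length-free Newick string."""
    out = tree.clone(depth=1)
    for node in out.preorder_node_iter():
        if not node.is_leaf():
            node.label = None
    for edge in out.preorder_edge_iter():
        edge.length = None
    return write_tree(out, sink, branch_lengths=False)
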