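"""Tree-based error detection for barcode datasets.

Two complementary detectors mirror the two analysis tracks of the
pipeline. In per-family trees a contaminant or misidentified specimen
is not related to its neighbours at all, so it shows up as an extremely
long terminal branch. In the all-taxon tree the same specimen is placed
by its sequence next to what it really is, so its taxonomic label
disagrees with the labels surrounding it. Flags are reported, never
auto-deleted: resolving them requires going back to the voucher
specimen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "QCFlag",
    "QCReport",
    "long_branch_flags",
    "misplacement_report",
    "monophyly_status",
]


@dataclass(frozen=True)
class QCFlag:
    leaf_label: str
    reason: str  # "long_branch" | "label_mismatch"
    detail: str
    score: float


@dataclass
class QCReport:
    flagged: list[QCFlag] = field(default_factory=list)
    warnings: int = 0

    def __len__(self) -> int:
        return len(self.flagged)

    def labels(self, reason: str | None = None) -> set[str]:
        return {
            f.leaf_label
            for f in self.flagged
            if reason is None or f.reason == reason
        }

    def is_clean(self) -> bool:
        return not self.flagged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "leaf_label": f.leaf_label,
                    "reason": f.reason,
                    "detail": f.detail,
                    "score": f.score,
                }
                for f in self.flagged
            ],
            columns=["leaf_label", "reason", "detail", "score"],
        )

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)

    def to_json(self, sink=None) -> str:
        payload = json.dumps(
            {
                "n_flags": len(self.flagged),
                "warnings": self.warnings,
                "flags": [f.__dict__ for f in self.flagged],
            },
            indent=2,
        )
        if sink is not None:
            if hasattr(sink, "write"):
                sink.write(payload)
            else:
                with open(sink, "w") as fh:
                    fh.write(payload)
        return payload


def long_branch_flags(tree: dendropy.Tree, factor: float = 5.0) -> QCReport:
    """Flag leaves whose terminal branch exceeds ``factor`` x the median
    terminal branch length.

    Scale-invariant by construction. Trees with fewer than 4 leaves
    yield an empty report (the median is too unstable to threshold).
    Scores are the ratio to the median, sorted descending.
    """
    leaves = [l for l in tree.leaf_node_iter()]
    if len(leaves) < 4:
        return QCReport()
    lengths = []
    for leaf in leaves:
        length = leaf.edge.length
        if length is None or length < 0:
            raise ValueError(
                f"terminal branch of {leaf.taxon.label!r} missing or negative"
            )
        lengths.append(length)
    lengths_sorted = sorted(lengths)
    mid = len(lengths_sorted) // 2
    if len(lengths_sorted) % 2:
        median = lengths_sorted[mid]
    else:
        median = 0.5 * (lengths_sorted[mid - 1] + lengths_sorted[mid])
    flags = []
    for leaf, length in zip(leaves, lengths):
        if median == 0:
            ratio = math.inf if length > 0 else 0.0
        else:
            ratio = length / median
        if not math.isinf(factor) and length > factor * median:
            flags.append(
                QCFlag(
                    leaf_label=leaf.taxon.label,
                    reason="long_branch",
                    detail=f"terminal branch {length:.6g} vs median {median:.6g}",
                    score=ratio,
                )
            )
    flags.sort(key=lambda f: (-f.score, f.leaf_label))
    return QCReport(flagged=flags)


def misplacement_report(
    tree: dendropy.Tree,
    rank_labels: dict[str, str],
    min_clade: int = 3,
) -> QCReport:
    """Flag leaves whose neighbourhood majority label contradicts their own.

    For each labeled leaf, enclosing clades are examined from the
    smallest outward until one contains at least ``min_clade`` other
    labeled leaves. A leaf is flagged only when the most common label
    among the neighbours contradicts its own at every level, including
    the final ``min_clade``-sized neighbourhood — an intruder is foreign
    at all scales, whereas a member of a small family is vindicated by
    its nearest neighbours before the search widens to other families.
    Score = majority fraction in the flagging neighbourhood. Ties that
    include the leaf's own label never flag. Unlabeled leaves are
    skipped and counted as warnings.
    """
    report = QCReport()
    # Precompute labeled-leaf sets per node.
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = rank_labels.get(node.taxon.label)
            node._qc_labels = [lab] if lab is not None else []
            node._qc_leaves = [node.taxon.label] if lab is not None else []
        else:
            node._qc_labels = [
                l for c in node.child_nodes() for l in c._qc_labels
            ]
            node._qc_leaves = [
                l for c in node.child_nodes() for l in c._qc_leaves
            ]
    for leaf in tree.leaf_node_iter():
        own = rank_labels.get(leaf.taxon.label)
        if own is None:
            report.warnings += 1
            continue
        node = leaf.parent_node
        verdict = None
        while node is not None:
            others = [
                lab
                for lab, who in zip(node._qc_labels, node._qc_leaves)
                if who != leaf.taxon.label
            ]
            if others:
                counts: dict[str, int] = {}
                for lab in others:
                    counts[lab] = counts.get(lab, 0) + 1
                top_count = max(counts.values())
                top_labels = sorted(
                    l for l, c in counts.items() if c == top_count
                )
                if own in top_labels:
                    verdict = None  # vindicated by nearest neighbours
                    break
                if len(others) >= min_clade:
                    verdict = (top_labels[0], top_count / len(others))
                    break
            node = node.parent_node
        if verdict is None:
            continue
        majority, fraction = verdict
        report.flagged.append(
            QCFlag(
                leaf_label=leaf.taxon.label,
                reason="label_mismatch",
                detail=f"labelled {own}, placed among {majority}",
                score=fraction,
            )
        )
    report.flagged.sort(key=lambda f: (-f.score, f.leaf_label))
    return QCReport(flagged=report.flagged, warnings=report.warnings)


def monophyly_status(
    tree: dendropy.Tree, taxon_leaves: set[str]
) -> tuple[str, list[str]]:
    """Monophyly of a leaf set: status plus intruding leaves.

    Returns ``("monophyletic", [])`` when the smallest clade containing
    ``taxon_leaves`` contains nothing else, otherwise
    ``("paraphyletic_or_polyphyletic", intruders)``.
    """
    taxon_leaves = set(taxon_leaves)
    if not taxon_leaves:
        raise ValueError("taxon_leaves must be non-empty")
    all_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    missing = taxon_leaves - all_leaves
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)[:5]}")
    best = None
    for node in tree.postorder_node_iter():
        leafset = {l.taxon.label for l in node.leaf_iter()}
        if taxon_leaves <= leafset:
            best = leafset
            break
    intruders = sorted(best - taxon_leaves)
    if intruders:
        return "paraphyletic_or_polyphyletic", intruders
    return "monophyletic", []
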