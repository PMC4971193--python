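"""Threshold-based MOTU clustering and species-concordance auditing.

OTUs (unique haplotypes) are clustered into MOTUs — molecular
operational taxonomic units — by single linkage at a fixed distance
threshold: two OTUs share a MOTU whenever a chain of pairwise distances
strictly below the threshold connects them. The conventional threshold
of 2% p-distance is often correlated with species-level diversity, but
clusters are reported as MOTUs, never as species: an algorithmic
cluster is a hypothesis for taxonomists, not a description.

The concordance audit compares a MOTU partition with the species names
attached to the OTUs and classifies every species as ``match`` (one
pure cluster), ``split`` (several pure clusters), ``merged`` (shares
its single cluster with other species) or ``mixture`` (anything else).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .grafting import DistanceMatrix

__all__ = [
    "MOTUPartition",
    "ConcordanceReport",
    "cluster",
    "concordance",
    "candidate_species_count",
]

CATEGORIES = ("match", "split", "merged", "mixture")


@dataclass
class MOTUPartition:
    """Assignment of OTU labels to dense integer cluster ids (from 1)."""

    assignment: dict[str, int]
    threshold: float
    linkage: str = "single"
    metric: str = "p"

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for label, cid in self.assignment.items():
            out[cid].append(label)
        return {cid: sorted(members) for cid, members in sorted(out.items())}

    def to_tsv(self, sink) -> None:
        rows = [
            {"label": lab, "motu": cid}
            for lab, cid in sorted(self.assignment.items())
        ]
        pd.DataFrame(rows, columns=["label", "motu"]).to_csv(
            sink, sep="\t", index=False
        )


def cluster(distances: DistanceMatrix, threshold: float = 0.02) -> MOTUPartition:
    """Single-linkage clustering: connected components of the graph with
    an edge wherever ``d < threshold`` (strict).

    Missing distances (NaN) and saturation markers (inf) contribute no
    edge. Cluster ids are dense integers from 1, numbered by each
    cluster's smallest member label.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(distances.labels)
    if n == 0:
        return MOTUPartition({}, threshold, metric=distances.model)
    d = distances.d
    adj = np.isfinite(d) & (d < threshold)
    np.fill_diagonal(adj, False)
    n_comp, membership = connected_components(
        csr_matrix(adj), directed=False
    )
    # renumber components by smallest member label
    smallest: dict[int, str] = {}
    for label, comp in zip(distances.labels, membership):
        if comp not in smallest or label < smallest[comp]:
            smallest[comp] = label
    order = sorted(range(n_comp), key=lambda c: smallest[c])
    renumber = {comp: i + 1 for i, comp in enumerate(order)}
    assignment = {
        label: renumber[comp]
        for label, comp in zip(distances.labels, membership)
    }
    return MOTUPartition(
        assignment, threshold, linkage="single", metric=distances.model
    )


def candidate_species_count(distances: DistanceMatrix, threshold: float) -> int:
    """Number of MOTUs at the given threshold (a species-count proxy)."""
    return cluster(distances, threshold).n_clusters


@dataclass
class ConcordanceReport:
    """Species-vs-MOTU concordance: one exhaustive category per species."""

    per_species: dict[str, str]
    cluster_composition: dict[int, Counter] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for cat in self.per_species.values():
            out[cat] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"species": s, "category": c}
                for s, c in sorted(self.per_species.items())
            ],
            columns=["species", "category"],
        )

    def to_tsv(self, sink) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False)

    def to_json(self, sink=None) -> str:
        payload = json.dumps(
            {
                "counts": self.counts,
                "per_species": dict(sorted(self.per_species.items())),
                "cluster_composition": {
                    str(cid): dict(comp)
                    for cid, comp in sorted(self.cluster_composition.items())
                },
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


def concordance(
    partition: MOTUPartition, species_of: dict[str, str]
) -> ConcordanceReport:
    """Classify every species against the MOTU partition.

    match  — all of the species' OTUs share one cluster containing only
             that species;
    split  — the OTUs span two or more clusters, each pure;
    merged — all OTUs in one cluster that also holds other species;
    mixture — several clusters, at least one shared with other species.
    """
    missing = [l for l in partition.assignment if l not in species_of]
    if missing:
        raise ValueError(f"no species name for clustered OTU(s) {missing[:5]}")
    composition: dict[int, Counter] = defaultdict(Counter)
    clusters_of_species: dict[str, set[int]] = defaultdict(set)
    for label, cid in partition.assignment.items():
        sp = species_of[label]
        composition[cid][sp] += 1
        clusters_of_species[sp].add(cid)
    per_species: dict[str, str] = {}
    for sp, cids in clusters_of_species.items():
        pure = all(len(composition[c]) == 1 for c in cids)
        if len(cids) == 1:
            per_species[sp] = "match" if pure else "merged"
        else:
            per_species[sp] = "split" if pure else "mixture"
    return ConcordanceReport(
        per_species=per_species, cluster_composition=dict(composition)
    )


def annotate_newick_by_cluster(newick: str, partition: MOTUPartition) -> str:
    """Suffix every clustered leaf label with ``.MOTU<n>`` in a Newick tree."""
    from .trees import read_tree, write_tree

    tree = read_tree(newick)
    for leaf in tree.leaf_node_iter():
        cid = partition.assignment.get(leaf.taxon.label)
        if cid is not None:
            leaf.taxon.label = f"{leaf.taxon.label}.MOTU{cid}"
    return write_tree(tree)
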