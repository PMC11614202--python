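"""Interpreting trained bag classifiers through attention weights.

A prediction carries one attention weight per instance; ranking a bag's
instances by that weight orders the virus's proteins (or protein
fragments) by their importance to the host decision. Downstream helpers
select the top-k proteins per virus, tally functional annotation terms over
the selected proteins, and hierarchically cluster their feature vectors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist

from .bags import VirusBag
from .mil_core import BagPrediction

__all__ = [
    "InstanceRanking",
    "AnnotationTable",
    "rank_instances",
    "top_k",
    "annotation_counts",
    "cluster_top_vectors",
    "dendrogram_to_newick",
    "read_annotations",
    "write_rankings",
]


@dataclass
class InstanceRanking:
    """A virus's instances ordered by descending attention weight.

    Entries are ``(protein_id, fragment_index, weight)``. Ties are broken
    by (protein_id, fragment_index) lexicographic order so the ranking is
    deterministic.
    """

    virus_id: str
    entries: list[tuple[str, int, float]]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class AnnotationTable:
    """protein_id -> set of annotation term ids, with term labels."""

    terms: dict[str, set[str]]
    labels: dict[str, str]


def rank_instances(prediction: BagPrediction, bag: VirusBag,
                   aggregate: bool = False) -> InstanceRanking:
    """Order a bag's instances by attention weight, descending.

    With ``aggregate=True`` fragment weights are summed per parent protein
    (entries then carry fragment_index −1); by default each fragment is
    ranked individually.
    """
    if prediction.virus_id != bag.virus_id or len(prediction.attention) != len(bag):
        raise ValueError("prediction does not match bag")
    a = prediction.attention
    if aggregate:
        sums: dict[str, float] = {}
        for inst, w in zip(bag.instances, a):
            sums[inst.protein_id] = sums.get(inst.protein_id, 0.0) + float(w)
        items = [(pid, -1, w) for pid, w in sums.items()]
    else:
        items = [(inst.protein_id, inst.fragment_index, float(w))
                 for inst, w in zip(bag.instances, a)]
    items.sort(key=lambda t: (-t[2], t[0], t[1]))
    return InstanceRanking(virus_id=bag.virus_id, entries=items)


def top_k(ranking: InstanceRanking, k: int = 5) -> InstanceRanking:
    """First min(k, M) entries; zero-weight entries may appear within k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return InstanceRanking(virus_id=ranking.virus_id, entries=ranking.entries[:k])


def annotation_counts(rankings: list[InstanceRanking], annotations: AnnotationTable,
                      vocabulary: set[str] | None = None) -> Counter:
    """Count how many top-ranked protein occurrences carry each term.

    Counting is per occurrence: a protein appearing in two viruses' top
    lists contributes twice. Proteins without annotations contribute
    nothing. ``vocabulary`` restricts the tally to a term subset (e.g.
    viral-life-cycle GO terms); counts for vocabulary terms never observed
    are reported as 0.
    """
    counts: Counter = Counter()
    if vocabulary is not None:
        counts.update({t: 0 for t in vocabulary})  # keep zeros visible
    for ranking in rankings:
        for pid, _, _ in ranking.entries:
            for term in annotations.terms.get(pid, ()):
                if vocabulary is None or term in vocabulary:
                    counts[term] += 1
    return counts


def cluster_top_vectors(vectors: list[np.ndarray] | np.ndarray,
                        method: str = "average") -> np.ndarray:
    """Agglomerative clustering of feature vectors on Euclidean distances.

    Returns the scipy linkage matrix; merge heights are non-decreasing for
    the supported linkages (average, complete, ward).
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors of uniform dimension")
    if method not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {method!r}")
    return linkage(pdist(X, metric="euclidean"), method=method)


def dendrogram_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a tab-separated annotation export: protein_id, term_id, term_label."""
    terms: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (line_no == 1 and line.startswith("protein_id")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected at least 2 tab-separated fields")
            pid, term = parts[0], parts[1]
            terms.setdefault(pid, set()).add(term)
            if len(parts) > 2:
                labels[term] = parts[2]
    return AnnotationTable(terms=terms, labels=labels)


def write_rankings(rankings: list[InstanceRanking], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("virus_id\trank\tprotein_id\tfragment_index\tattention_weight\n")
        for r in rankings:
            for i, (pid, fi, w) in enumerate(r.entries, 1):
                fh.write(f"{r.virus_id}\t{i}\t{pid}\t{fi}\t{w:.8g}\n")
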