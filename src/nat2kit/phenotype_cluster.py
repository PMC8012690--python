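"""Acetylator-phenotype categories from 1-D clustering of activity scores.

Per drug, the ten genotype activity scores are clustered by agglomerative
hierarchical clustering with the Ward-D2 criterion on Euclidean distances.
The cluster count is selected from a candidate set (default {3, 4}) by the
Krzanowski-Lai index, with mean silhouette width breaking ties and smaller
k breaking any remaining tie; clusters ordered by decreasing mean score are
then labelled RA > IA > SA (> USA for k = 4): rapid, intermediate, slow and
ultra-slow acetylators.

The Krzanowski-Lai index is used as the primary criterion because, on
1-D score profiles of this shape, global compactness indices (mean
silhouette, Calinski-Harabasz) are insensitive to whether the slow tail
splits into a distinct ultra-slow group, whereas the KL difference ratio
DIFF(k) = (k-1)^(2/p) W(k-1) - k^(2/p) W(k), KL(k) = |DIFF(k)/DIFF(k+1)|
(p = dimensionality, W = pooled within-cluster sum of squares) measures
exactly that marginal gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

PHENOTYPE_ORDER = ("RA", "IA", "SA", "USA")
_NAMES_FOR_K = {2: ("RA", "SA"), 3: ("RA", "IA", "SA"), 4: PHENOTYPE_ORDER}


@dataclass
class Dendrogram:
    """Ward-D2 merge tree over genotype leaves.

    ``linkage`` is the scipy linkage matrix with heights on the Euclidean
    distance scale; ``merge_heights_d2`` exposes them on the squared
    (ward.D2) scale.  Leaves are ordered lexicographically so that equal
    score multisets produce byte-identical trees regardless of input order.
    """

    leaf_labels: tuple
    scores: tuple
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def merge_heights_d2(self) -> np.ndarray:
        return self.linkage[:, 2] ** 2

    @property
    def merge_sequence(self) -> list:
        """[(child_id_a, child_id_b, height_d2), ...] in merge order."""
        return [(int(a), int(b), float(h) ** 2)
                for a, b, h, _ in self.linkage]

    def cut(self, k: int) -> dict:
        """Partition into k clusters: label -> cluster id (arbitrary ids)."""
        flat = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return dict(zip(self.leaf_labels, (int(c) for c in flat)))

    def to_text(self) -> str:
        """Plain-text dump: leaves then merges with D2-scale heights."""
        lines = ["leaves\t" + "\t".join(self.leaf_labels)]
        for i, (a, b, h) in enumerate(self.merge_sequence):
            lines.append(f"merge{i}\t{a}\t{b}\t{h:.6g}")
        return "\n".join(lines) + "\n"

    def to_newick(self) -> str:
        """Newick string with branch lengths on the D2 height scale."""
        tree = hierarchy.to_tree(self.linkage)
        heights_d2 = {i + self.n_leaves: h for i, (_, _, h)
                      in enumerate(self.merge_sequence)}

        def walk(node, parent_h):
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{parent_h:.6g}"
            h = heights_d2[node.id]
            left = walk(node.left, h)
            right = walk(node.right, h)
            return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

        root_h = heights_d2[2 * self.n_leaves - 2]
        return walk(tree, root_h).rsplit(":", 1)[0] + ";"


@dataclass
class PhenotypeAssignment:
    """Genotype -> {RA, IA, SA, USA} mapping for one drug."""

    drug: str
    k: int
    labels: dict
    cluster_means: dict = field(default_factory=dict)

    def members(self, phenotype: str) -> tuple:
        return tuple(g for g, p in self.labels.items() if p == phenotype)


def ward_linkage(scores: Mapping[str, float]) -> Dendrogram:
    """Agglomerative Ward-D2 linkage of 1-D activity scores."""
    if len(scores) < 2:
        raise ValueError("need at least two genotypes")
    labels = tuple(sorted(scores))
    values = np.array([scores[g] for g in labels], dtype=float)
    if not np.all(np.isfinite(values)):
        bad = [g for g, x in zip(labels, values) if not np.isfinite(x)]
        raise ValueError(f"non-finite score(s) for {', '.join(bad)}")
    Z = hierarchy.linkage(values.reshape(-1, 1), method="ward")
    return Dendrogram(labels, tuple(values), Z)


def _pooled_wss(dendrogram: Dendrogram, k: int) -> float:
    values = np.asarray(dendrogram.scores)
    if k <= 1:
        return float(((values - values.mean()) ** 2).sum())
    if k >= dendrogram.n_leaves:
        return 0.0
    flat = hierarchy.fcluster(dendrogram.linkage, k, criterion="maxclust")
    return float(sum(((values[flat == c] - values[flat == c].mean()) ** 2).sum()
                     for c in np.unique(flat)))


def kl_index(dendrogram: Dendrogram, k: int, p: int = 1) -> float:
    """Krzanowski-Lai difference ratio |DIFF(k)| / |DIFF(k+1)|."""
    if not 2 <= k <= dendrogram.n_leaves - 1:
        raise ValueError(f"k={k} outside 2..{dendrogram.n_leaves - 1}")
    w = {j: _pooled_wss(dendrogram, j) for j in (k - 1, k, k + 1)}
    num = abs((k - 1) ** (2.0 / p) * w[k - 1] - k ** (2.0 / p) * w[k])
    den = abs(k ** (2.0 / p) * w[k] - (k + 1) ** (2.0 / p) * w[k + 1])
    if den == 0.0:
        return np.inf if num > 0 else 0.0
    return num / den


def select_cluster_count(dendrogram: Dendrogram,
                         candidates: Sequence[int] = (3, 4)) -> int:
    """Pick k from the candidates: max KL index, ties by silhouette, then min k."""
    if not candidates:
        raise ValueError("empty candidate set")
    n = dendrogram.n_leaves
    cands = sorted(set(int(k) for k in candidates))
    bad = [k for k in cands if not 2 <= k <= n - 1]
    if bad:
        raise ValueError(f"candidate k outside 2..{n - 1}: {bad}")

    kl = {k: kl_index(dendrogram, k) for k in cands}
    best = max(kl.values())
    tied = [k for k in cands if np.isclose(kl[k], best, rtol=1e-9, atol=0.0)]
    if len(tied) == 1:
        return tied[0]
    values = np.asarray(dendrogram.scores).reshape(-1, 1)
    sil = {k: silhouette_score(values,
                               hierarchy.fcluster(dendrogram.linkage, k,
                                                  criterion="maxclust"))
           for k in tied}
    best_sil = max(sil.values())
    tied = [k for k in tied if np.isclose(sil[k], best_sil, rtol=1e-9, atol=0.0)]
    return min(tied)


def assign_phenotype_labels(dendrogram: Dendrogram, k: int,
                            drug: str = "") -> PhenotypeAssignment:
    """Cut at k clusters and label them RA > IA > SA (> USA) by mean score."""
    if k not in _NAMES_FOR_K:
        raise ValueError(f"k={k} unsupported; expected one of {sorted(_NAMES_FOR_K)}")
    part = dendrogram.cut(k)
    if len(set(part.values())) != k:
        raise ValueError(
            f"cut produced {len(set(part.values()))} clusters, not {k} "
            "(duplicate merge heights)")
    values = dict(zip(dendrogram.leaf_labels, dendrogram.scores))
    means = {}
    for cid in set(part.values()):
        members = [g for g, c in part.items() if c == cid]
        means[cid] = float(np.mean([values[g] for g in members]))
    order = sorted(means, key=lambda c: means[c], reverse=True)
    names = _NAMES_FOR_K[k]
    name_of = {cid: names[i] for i, cid in enumerate(order)}
    labels = {g: name_of[part[g]] for g in dendrogram.leaf_labels}
    cluster_means = {name_of[cid]: means[cid] for cid in order}
    # ordering consistency: every member of a faster class scores above
    # every member of a slower one (guaranteed by Ward cuts in 1-D)
    for hi, lo in zip(names, names[1:]):
        hi_min = min(values[g] for g in labels if labels[g] == hi)
        lo_max = max(values[g] for g in labels if labels[g] == lo)
        if hi_min <= lo_max:
            raise AssertionError(
                f"cluster ordering violated: min({hi})={hi_min} <= "
                f"max({lo})={lo_max}")
    return PhenotypeAssignment(drug, k, labels, cluster_means)


def classify_scores(scores: Mapping[str, float], drug: str = "",
                    candidates: Sequence[int] = (3, 4),
                    ) -> tuple[Dendrogram, PhenotypeAssignment]:
    """Convenience: linkage -> k selection -> phenotype labels for one drug."""
    dendrogram = ward_linkage(scores)
    k = select_cluster_count(dendrogram, candidates)
    return dendrogram, assign_phenotype_labels(dendrogram, k, drug)
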