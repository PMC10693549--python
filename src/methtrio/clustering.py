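"""Hierarchical clustering of subjects on methylation profiles.

Samples are points in CpG space (methylation percents); CpGs with any
missing value are dropped so Euclidean distances are exact, then an
agglomerative tree is built (complete linkage by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .matrix import MethMatrix


@dataclass
class SubjectClustering:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    distances: pd.DataFrame  # sample x sample Euclidean distances
    n_cpgs_used: int

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        return _newick(tree, self.labels) + ";"


def _newick(node, labels, parent_height: float | None = None) -> str:
    length = ("" if parent_height is None
              else f":{max(parent_height - node.dist, 0.0):g}")
    if node.is_leaf():
        return f"{labels[node.id]}{length}"
    left = _newick(node.left, labels, node.dist)
    right = _newick(node.right, labels, node.dist)
    return f"({left},{right}){length}"


def cluster_subjects(meth: MethMatrix, method: str = "complete") -> SubjectClustering:
    """Cluster samples by Euclidean distance over complete CpGs."""
    if meth.n_samples < 2:
        raise ValueError("need at least two samples to cluster")
    complete = ~np.isnan(meth.meth).any(axis=1)
    if not complete.any():
        raise ValueError("no CpG is observed in every sample")
    X = meth.meth[complete].T  # samples x CpGs
    d = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(d, method=method)
    dist = pd.DataFrame(squareform(d), index=meth.samples, columns=meth.samples)
    return SubjectClustering(linkage=Z, labels=list(meth.samples),
                             distances=dist, n_cpgs_used=int(complete.sum()))
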