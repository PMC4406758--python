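"""Distance-based taxonomic units: collapse OTUs whose p-distance is < 3%.

p-distances are computed on OTU centroids from pairwise global alignments
with pairwise deletion (gap-containing columns excluded).  The collapse is
single-linkage: OTUs are nodes, an edge connects any pair strictly below
the threshold, and DTUs are the connected components; average linkage is
available as an option since the grouping rule only fixes the pairwise
cutoff, not the linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .clustering import OTU, _align_counts


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape must match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")


@dataclass
class DTUSet:
    groups: list[list[str]]

    @property
    def count(self) -> int:
        return len(self.groups)


def pairwise_distance(a: str, b: str) -> float:
    """p-distance under pairwise deletion: mismatches / compared columns."""
    if a == b:
        return 0.0
    ident, mism, _gaps = _align_counts(a, b)
    compared = ident + mism
    if compared == 0:
        return 1.0
    return mism / compared


def distance_matrix(otus: Sequence[OTU]) -> DistanceMatrix:
    """All-pairs centroid p-distance matrix for a set of OTUs."""
    labels = [f"OTU_{i+1}" for i in range(len(otus))]
    n = len(otus)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(otus[i].centroid, otus[j].centroid)
    return DistanceMatrix(labels, d)


def collapse(
    matrix: DistanceMatrix, threshold: float = 0.03, linkage_method: str = "single"
) -> DTUSet:
    """Group labels whose distance is strictly below the threshold.

    Single linkage (default) takes connected components of the
    d < threshold graph — a chain of close pairs merges even if its ends
    are distant.  Average linkage cuts a UPGMA tree at the threshold.
    """
    n = len(matrix.labels)
    if n == 0:
        return DTUSet([])
    if n == 1:
        return DTUSet([[matrix.labels[0]]])
    if linkage_method == "single":
        adj = matrix.d < threshold
        np.fill_diagonal(adj, True)
        n_comp, comp = connected_components(adj, directed=False)
        assignments = comp
    elif linkage_method == "average":
        z = linkage(squareform(matrix.d, checks=False), method="average")
        # fcluster merges at height <= t; mirror the strict '<' rule
        assignments = fcluster(z, t=np.nextafter(threshold, 0.0), criterion="distance")
    else:
        raise ValueError("linkage_method must be 'single' or 'average'")
    groups: dict[int, list[str]] = {}
    for label, g in zip(matrix.labels, assignments):
        groups.setdefault(int(g), []).append(label)
    # deterministic order: by first appearance of each group's first label
    ordered = sorted(groups.values(), key=lambda g: matrix.labels.index(g[0]))
    return DTUSet(ordered)


def collapse_otus(
    otus: Sequence[OTU], threshold: float = 0.03, linkage_method: str = "single"
) -> DTUSet:
    return collapse(distance_matrix(otus), threshold, linkage_method)
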