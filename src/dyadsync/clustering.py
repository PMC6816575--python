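"""Clustering of lag patterns into significantly distinct strategy groups.

Mean lag-correlation triplets from a sweep of coupling-weight combinations
are grouped by complete-linkage hierarchical clustering under Euclidean
distance, and a similarity-profile (SIMPROF) permutation test decides, node
by node from the root of the dendrogram, whether a group contains genuine
multivariate structure and should be split further (Clarke, Somerfield &
Gorley-style test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist


@dataclass
class PatternSet:
    """A matrix of lag patterns (rows) with one label per coupling combination."""

    patterns: np.ndarray  # (n, 3)
    labels: list

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns must not contain undefined components")
        if len(self.labels) != self.patterns.shape[0]:
            raise ValueError("one label per pattern required")
        if len(set(map(tuple_if_seq, self.labels))) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return self.patterns.shape[0]

    def mirrored(self) -> "PatternSet":
        """Lag -1 and lag +1 swapped in every pattern (unit relabelling)."""
        return PatternSet(self.patterns[:, ::-1].copy(), list(self.labels))


def tuple_if_seq(x):
    return tuple(x) if isinstance(x, (list, np.ndarray)) else x


@dataclass
class ClusterResult:
    """Dendrogram plus the significant-cluster partition of a pattern set."""

    linkage: np.ndarray  # scipy linkage matrix
    assignments: np.ndarray  # significant-cluster id (1-based) per pattern
    n_significant: int
    alpha: float
    n_permutations: tuple  # (expected-profile set, p-value set)
    node_pvalues: dict = field(default_factory=dict)  # node id -> p
    cluster_means: Optional[np.ndarray] = None  # (n_significant, 3)
    cluster_sizes: Optional[np.ndarray] = None


def complete_linkage(patterns: PatternSet) -> np.ndarray:
    """Complete-linkage merge tree under Euclidean distance on the triplets."""
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns to build a dendrogram")
    return linkage(patterns.patterns, method="complete", metric="euclidean")


def _column_permuted(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = rng.random(X.shape).argsort(axis=0)
    return X[idx, np.arange(X.shape[1])]


def _simprof_pvalue(
    X: np.ndarray,
    rng: np.random.Generator,
    n_expected: int,
    n_pvalue: int,
) -> float:
    """SIMPROF p-value for the hypothesis of no structure among rows of X.

    The similarity profile is the sorted vector of pairwise Euclidean
    distances.  The null shuffles each variable (column) independently
    across the rows: ``n_expected`` permutations build the mean null
    profile, the test statistic is the summed absolute deviation of a
    profile from that mean, and ``n_pvalue`` further permutations give the
    reference distribution.
    """
    m = X.shape[0]
    if m < 3:
        # pairwise distances are invariant under within-column swaps of two
        # rows, so a two-member group can never show excess structure
        return 1.0
    obs = np.sort(pdist(X))
    mean_profile = np.zeros_like(obs)
    for _ in range(n_expected):
        mean_profile += np.sort(pdist(_column_permuted(X, rng)))
    mean_profile /= n_expected
    pi_obs = np.abs(obs - mean_profile).sum()
    exceed = 0
    for _ in range(n_pvalue):
        pi_perm = np.abs(np.sort(pdist(_column_permuted(X, rng))) - mean_profile).sum()
        if pi_perm >= pi_obs:
            exceed += 1
    return (exceed + 1) / (n_pvalue + 1)


def simprof(
    patterns: PatternSet,
    dendrogram: np.ndarray,
    alpha: float = 0.001,
    n_expected: int = 1000,
    n_pvalue: int = 999,
    rng: Union[np.random.Generator, int, None] = None,
) -> ClusterResult:
    """Similarity-profile partition of a complete-linkage dendrogram.

    Descends from the root: each node's members are tested for internal
    structure; a significant node (p <= alpha) is split into its two
    children, a non-significant one becomes a final cluster.  Each node uses
    an independent random stream derived from its dendrogram id, so p-values
    do not depend on the recursion path (and tightening alpha can only
    reduce the cluster count).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if n_pvalue < 100:
        raise ValueError("n_pvalue must be >= 100")
    if isinstance(rng, np.random.Generator):
        base_entropy = int(rng.integers(2**63))
    elif rng is None:
        base_entropy = 0
    else:
        base_entropy = int(rng)

    X = patterns.patterns
    root = to_tree(dendrogram)
    assignments = np.zeros(len(patterns), dtype=int)
    node_pvalues: dict = {}
    clusters: list = []

    def recurse(node) -> None:
        members = node.pre_order(lambda leaf: leaf.id)
        if len(members) == 1:
            clusters.append(members)
            return
        node_rng = np.random.default_rng(
            np.random.SeedSequence([base_entropy, node.get_id()])
        )
        p = _simprof_pvalue(X[members], node_rng, n_expected, n_pvalue)
        node_pvalues[node.get_id()] = p
        if p <= alpha:
            recurse(node.get_left())
            recurse(node.get_right())
        else:
            clusters.append(members)

    recurse(root)
    # number clusters by dendrogram (leaf) order for a stable labelling
    clusters.sort(key=lambda members: min(members))
    for cid, members in enumerate(clusters, start=1):
        assignments[members] = cid
    return ClusterResult(
        linkage=dendrogram,
        assignments=assignments,
        n_significant=len(clusters),
        alpha=alpha,
        n_permutations=(n_expected, n_pvalue),
        node_pvalues=node_pvalues,
    )


def cluster_lag_patterns(
    patterns: PatternSet,
    alpha: float = 0.001,
    n_expected: int = 1000,
    n_pvalue: int = 999,
    rng: Union[np.random.Generator, int, None] = None,
) -> ClusterResult:
    """Complete linkage followed by the SIMPROF partition, with cluster means."""
    if len(patterns) == 1:
        return ClusterResult(
            linkage=np.empty((0, 4)),
            assignments=np.array([1]),
            n_significant=1,
            alpha=alpha,
            n_permutations=(n_expected, n_pvalue),
            cluster_means=patterns.patterns.copy(),
            cluster_sizes=np.array([1]),
        )
    Z = complete_linkage(patterns)
    result = simprof(patterns, Z, alpha, n_expected, n_pvalue, rng)
    k = result.n_significant
    means = np.empty((k, patterns.patterns.shape[1]))
    sizes = np.empty(k, dtype=int)
    for cid in range(1, k + 1):
        mask = result.assignments == cid
        means[cid - 1] = patterns.patterns[mask].mean(axis=0)
        sizes[cid - 1] = mask.sum()
    result.cluster_means = means
    result.cluster_sizes = sizes
    return result
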