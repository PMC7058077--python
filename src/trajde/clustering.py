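"""Clustering of fitted, standardized expression patterns.

For each converged gene the lineage smoothers are evaluated on an equally
spaced grid (100 points per lineage by default), concatenated across
lineages and standardized per gene to zero mean and unit variance. Genes
are then clustered in PCA space with a resampled consensus around
k-medoids: pairs of genes that land in the same medoid cluster in at least
a threshold fraction of resampled fits form consensus clusters; genes
without a stable partner are labelled -1. The base clusterer is pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = ["PatternMatrix", "extract_patterns", "PatternKMedoids", "cluster_patterns", "kmedoids"]


@dataclass
class PatternMatrix:
    """Standardized fitted patterns for a set of genes."""

    values: np.ndarray        # (G_kept, L * n_points), rows mean 0 / var 1
    gene_ids: np.ndarray      # kept genes
    excluded_ids: np.ndarray  # constant-pattern or non-converged genes
    means: np.ndarray
    sds: np.ndarray
    n_points: int
    n_lineages: int


def extract_patterns(model, gene_subset=None, n_points: int = 100) -> PatternMatrix:
    """Fitted log-mean patterns on per-lineage grids, standardized per gene.

    Non-converged genes and genes with a constant fitted pattern (zero
    variance) are excluded with a warning.
    """
    model._check_fitted()
    G = model.beta_.shape[0]
    if gene_subset is None:
        genes = np.arange(G)
    else:
        genes = np.asarray([model._gene_index(g) for g in np.atleast_1d(gene_subset)])
    conv = model.converged_[genes]
    if not conv.all():
        warnings.warn(
            f"{(~conv).sum()} non-converged gene(s) skipped in pattern extraction",
            stacklevel=2,
        )
    L = model.n_lineages_
    K = model.basis_.K
    blocks = []
    for l in range(L):
        grid = np.linspace(*model.lineage_ranges_[l], n_points)
        B = model.basis_.design(grid)                       # (n_points, K)
        blocks.append(model.beta_[genes][:, l * K : (l + 1) * K] @ B.T)
    raw = np.column_stack(blocks)                           # (|genes|, L*n_points)

    means = raw.mean(axis=1)
    sds = raw.std(axis=1)
    degenerate = ~conv | (sds < 1e-10) | ~np.isfinite(raw).all(axis=1)
    if (degenerate & conv).any():
        warnings.warn(
            f"{(degenerate & conv).sum()} constant-pattern gene(s) excluded from clustering",
            stacklevel=2,
        )
    keep = ~degenerate
    values = (raw[keep] - means[keep, None]) / sds[keep, None]
    return PatternMatrix(
        values=values,
        gene_ids=model.gene_ids_[genes[keep]],
        excluded_ids=model.gene_ids_[genes[~keep]],
        means=means[keep],
        sds=sds[keep],
        n_points=n_points,
        n_lineages=L,
    )


def kmedoids(X, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids (PAM-style alternation, maximin init).

    The first medoid is the most central point; the rest are added by the
    farthest-point rule, so the result does not depend on an RNG. Ties break
    toward the lowest index.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    if k > m:
        raise ValueError(f"cannot place {k} medoids among {m} points")
    D = squareform(pdist(X))
    medoids = [int(np.argmin(D.sum(axis=1)))]
    for _ in range(k - 1):
        dist_to_near = D[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(dist_to_near)))
    medoids = np.asarray(medoids)
    labels = np.argmin(D[:, medoids], axis=1)
    for _ in range(max_iter):
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        new_labels = np.argmin(D[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels


class PatternKMedoids(BaseEstimator, ClusterMixin):
    """Resampled consensus clustering of standardized patterns.

    Parameters
    ----------
    n_pcs : int, default 10
        Number of principal components of the pattern matrix to cluster in.
    k_range : iterable of int, default range(4, 13)
        Candidate numbers of medoids; the k with the best full-data
        silhouette is used for the consensus stage.
    n_resamples : int, default 20
    subsample : float, default 0.8
        Fraction of genes drawn (without replacement) per resample.
    co_cluster_threshold : float, default 0.7
        Minimum co-clustering fraction for a consensus edge.
    algorithm : callable (X, k) -> labels, optional
        Base clusterer; defaults to the deterministic k-medoids.
    seed : int, default 0

    Attributes
    ----------
    labels_ : (G,) consensus labels, -1 for unstable genes.
    best_k_ : selected number of medoids.
    consensus_ : (G, G) co-clustering fraction matrix.
    """

    def __init__(
        self,
        n_pcs: int = 10,
        k_range=range(4, 13),
        n_resamples: int = 20,
        subsample: float = 0.8,
        co_cluster_threshold: float = 0.7,
        algorithm=None,
        seed: int = 0,
    ):
        self.n_pcs = n_pcs
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample = subsample
        self.co_cluster_threshold = co_cluster_threshold
        self.algorithm = algorithm
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        m = X.shape[0]
        if m < 2:
            raise ValueError("need at least 2 patterns to cluster")
        ks = [int(k) for k in self.k_range]
        if min(ks) > m:
            raise ValueError(f"fewer genes ({m}) than the smallest k ({min(ks)})")
        ks = [k for k in ks if k <= m]
        algo = self.algorithm or (lambda Xs, k: kmedoids(Xs, k))

        n_pcs = min(self.n_pcs, X.shape[1], m)
        P = PCA(n_components=n_pcs, random_state=0).fit_transform(X)

        best_k, best_sil = ks[0], -np.inf
        for k in ks:
            if k < 2 or k >= m:
                continue
            lab = algo(P, k)
            if np.unique(lab).size < 2:
                continue
            sil = silhouette_score(P, lab)
            if sil > best_sil:
                best_k, best_sil = k, sil

        rng = np.random.default_rng([int(self.seed), 0xC105])
        size = max(best_k + 1, int(round(self.subsample * m)))
        co = np.zeros((m, m))
        present = np.zeros((m, m))
        for _ in range(self.n_resamples):
            idx = np.sort(rng.choice(m, size=min(size, m), replace=False))
            lab = np.asarray(algo(P[idx], best_k))
            same = lab[:, None] == lab[None, :]
            present[np.ix_(idx, idx)] += 1.0
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            frac = np.where(present > 0, co / np.maximum(present, 1), 0.0)
        np.fill_diagonal(frac, 1.0)

        adj = frac >= self.co_cluster_threshold
        np.fill_diagonal(adj, False)
        n_comp, comp = connected_components(csr_matrix(adj), directed=False)
        labels = np.full(m, -1, dtype=int)
        next_label = 0
        for c in range(n_comp):
            members = np.flatnonzero(comp == c)
            if members.size >= 2:
                labels[members] = next_label
                next_label += 1

        self.labels_ = labels
        self.best_k_ = best_k
        self.consensus_ = frac
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def cluster_patterns(
    patterns: PatternMatrix | np.ndarray,
    n_pcs: int = 10,
    k_range=range(4, 13),
    n_resamples: int = 20,
    co_cluster_threshold: float = 0.7,
    seed: int = 0,
    algorithm=None,
) -> np.ndarray:
    """Consensus cluster labels (-1 = unassigned) for a pattern matrix."""
    values = patterns.values if isinstance(patterns, PatternMatrix) else np.asarray(patterns)
    est = PatternKMedoids(
        n_pcs=n_pcs,
        k_range=k_range,
        n_resamples=n_resamples,
        co_cluster_threshold=co_cluster_threshold,
        seed=seed,
        algorithm=algorithm,
    )
    return est.fit_predict(values)
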