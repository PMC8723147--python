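"""Network embedding and embedding-quality checks.

The TOM graph is embedded into a low-dimensional coordinate matrix with a
weighted first-order objective trained by stochastic gradient descent:
each epoch samples edges with probability proportional to their weight and
pulls the two endpoint coordinate vectors until their dot product matches
the edge weight; a fraction ``negative_ratio`` as many uniformly random
node pairs are pushed toward dot product 0.  The learning rate decays
linearly to zero over ``max_epoch`` epochs.  This is the "global
first-order" family of ultrafast embeddings (GGVec-style): no random
walks, cost linear in the number of sampled pairs, suitable for dense
co-expression graphs with millions of edges.

Embedding quality is assessed by clustering the coordinates with k-means
(k = number of Louvain modules) and comparing per-module against
per-cluster summary statistics with a Welch t-test: if the embedding
preserves the network's trait structure, the two collections should not
differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .netio import TOMNetwork

__all__ = [
    "EmbeddingMatrix",
    "ClusterAssignment",
    "embed",
    "kmeans_clusters",
    "compare_module_cluster_stats",
]


@dataclass
class EmbeddingMatrix:
    """Genes x d coordinates, gene ids in canonical order."""

    gene_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.gene_ids):
            raise ValueError("coords must be (n_genes, d)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subspace(self, dims: list[int]) -> np.ndarray:
        return self.coords[:, list(dims)]


@dataclass
class ClusterAssignment:
    """Gene -> k-means cluster label, labels contiguous 0..k-1."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        vals = sorted(set(self.labels.values()))
        if vals != list(range(len(vals))):
            raise ValueError("cluster labels not contiguous from 0")

    @property
    def n_modules(self) -> int:  # same surface as ModuleAssignment
        return len(set(self.labels.values()))

    @property
    def k(self) -> int:
        return self.n_modules

    def members(self, cluster: int) -> list[str]:
        return sorted(g for g, c in self.labels.items() if c == cluster)


def _scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    # bincount per dimension is much faster than np.add.at for big batches
    n = out.shape[0]
    for k in range(out.shape[1]):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def embed(
    t: TOMNetwork,
    d: int = 64,
    max_epoch: int = 100,
    learning_rate: float = 0.1,
    negative_ratio: float = 0.15,
    seed: int = 0,
    samples_per_node: int = 75,
    _init: np.ndarray | None = None,
    _pair_stream: list | None = None,
) -> EmbeddingMatrix:
    """Embed the TOM graph into d dimensions (first-order, negative sampling).

    Parameters
    ----------
    samples_per_node
        Sampling budget per epoch, expressed as positive edge samples per
        node; each epoch draws ``samples_per_node * n_genes`` weighted edge
        samples plus ``negative_ratio`` times as many random negative pairs.
    _init, _pair_stream
        Testing hooks: a fixed initial coordinate matrix and a pre-drawn
        per-epoch stream of ``(pos_i, pos_j, neg_i, neg_j)`` index arrays.
        When given they replace the seeded random draws, which makes
        equivariance harnesses possible; not part of the public contract.
    """
    n = t.n_genes
    if d < 2:
        raise ValueError("d must be >= 2")
    if n < 2:
        raise ValueError("need at least 2 genes")
    iu, ju = np.triu_indices(n, k=1)
    w = t.weights[iu, ju]
    if not np.any(w > 0):
        raise ValueError("all off-diagonal weights are zero; nothing to embed")
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    cdf = np.cumsum(w)
    cdf /= cdf[-1]

    rng = np.random.default_rng(seed)
    if _init is not None:
        coords = np.array(_init, dtype=float, copy=True)
        if coords.shape != (n, d):
            raise ValueError("_init shape mismatch")
    else:
        coords = rng.standard_normal((n, d)) / np.sqrt(d)

    n_pos = max(1, int(samples_per_node * n))
    n_neg = max(1, int(round(negative_ratio * n_pos)))

    n_batches = 8  # mini-batches per epoch; mean-normalized step per batch

    def _step(pi, pj, ni, nj, lr):
        ei, ej = coords[pi], coords[pj]
        resid = np.einsum("ij,ij->i", ei, ej) - t.weights[pi, pj]
        np.clip(resid, -5.0, 5.0, out=resid)
        gi = resid[:, None] * ej
        gj = resid[:, None] * ei
        en_i, en_j = coords[ni], coords[nj]
        nresid = np.einsum("ij,ij->i", en_i, en_j)
        np.clip(nresid, -5.0, 5.0, out=nresid)
        gni = nresid[:, None] * en_j
        gnj = nresid[:, None] * en_i
        grad = np.zeros_like(coords)
        rows = np.concatenate([pi, pj, ni, nj])
        _scatter_add(grad, rows, np.concatenate([gi, gj, gni, gnj]))
        # mean per-node gradient: step size independent of sampling budget
        # and node degree
        touched = np.bincount(rows, minlength=n).astype(float)
        coords[...] -= lr * grad / np.maximum(touched, 1.0)[:, None]

    for epoch in range(max_epoch):
        if _pair_stream is not None:
            pi, pj, ni, nj = _pair_stream[epoch]
        else:
            sel = np.searchsorted(cdf, rng.random(n_pos))
            pi, pj = iu[sel], ju[sel]
            ni = rng.integers(0, n, size=n_neg)
            nj = rng.integers(0, n, size=n_neg)
            ok = ni != nj
            ni, nj = ni[ok], nj[ok]
        lr = learning_rate * (1.0 - epoch / max_epoch)
        splits = np.array_split(np.arange(len(pi)), n_batches)
        nsplits = np.array_split(np.arange(len(ni)), n_batches)
        for bs, bn in zip(splits, nsplits):
            if len(bs) == 0:
                continue
            _step(pi[bs], pj[bs], ni[bn], nj[bn], lr)

    return EmbeddingMatrix(list(t.gene_ids), coords)


def kmeans_clusters(e: EmbeddingMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """k-means on the embedding coordinates (k-means++ init, 10 restarts)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > e.n_genes:
        raise ValueError("k exceeds the number of genes")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(e.coords)
    relabel: dict[int, int] = {}
    for m in raw:
        if m not in relabel:
            relabel[m] = len(relabel)
    return ClusterAssignment({g: relabel[int(c)] for g, c in zip(e.gene_ids, raw)})


def compare_module_cluster_stats(
    stat_modules: np.ndarray | list[float],
    stat_clusters: np.ndarray | list[float],
) -> tuple[float, float]:
    """Welch two-sided t-test between per-module and per-cluster statistics.

    Used as the embedding-quality check: e.g. the %ANOVA-significant genes
    per network module vs per embedding cluster, or per-group eigengene to
    trait |r|.  A large p means the embedding preserved the property.
    Degenerate case (zero variance on both sides): p = 1 when the means are
    equal, p = 0 otherwise.
    """
    a = np.asarray(stat_modules, dtype=float)
    b = np.asarray(stat_clusters, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per side")
    tol_a = 1e-12 * max(1.0, abs(a.mean()))
    tol_b = 1e-12 * max(1.0, abs(b.mean()))
    if a.std() <= tol_a and b.std() <= tol_b:
        return (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
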