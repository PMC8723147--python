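"""Critical-gene and neighbor-gene identification.

*Critical genes* are ranked by how many impact genes lie within a
Euclidean distance cutoff sigma of them in the classifier-selected
subspace of the network embedding; the counts are computed per model
(each model contributes its own top-dimension subspace) and summed.
Because proximity is measured in the embedding rather than by
differential expression, a critical gene need not be differentially
expressed itself.

*Neighbor genes* are the non-ML baseline: a gene's count is the number of
impact genes to which its TOM edge weight exceeds a cutoff epsilon.  For
a fair comparison the epsilon cutoff can be chosen so the neighbor list
has the same size as the critical list.

Both counts exclude the gene itself (an impact gene is at distance 0 /
weight 1 from itself, which would otherwise guarantee it a count).
Rankings are sorted by count descending, ties broken lexicographically,
and contain every gene of the universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddingMatrix
from .mlrank import TopDimensions
from .netio import GeneRanking, GeneSet, TOMNetwork

__all__ = [
    "ProximityParams",
    "critical_genes",
    "neighbor_genes",
    "match_list_sizes",
]


@dataclass
class ProximityParams:
    """Distance / edge-weight cutoffs for the two ranking algorithms.

    Exactly one of the explicit value or the percentile rule is active per
    parameter.  ``sigma_percentile`` resolves sigma per model as the q-th
    percentile of all gene-to-impact distances in that model's subspace
    (self-pairs excluded), which adapts the cutoff to the geometry of each
    subspace.
    """

    sigma: float | None = None
    sigma_percentile: float | None = 5.0
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if (self.sigma is None) == (self.sigma_percentile is None):
            raise ValueError("set exactly one of sigma / sigma_percentile")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma_percentile is not None and not 0 <= self.sigma_percentile <= 100:
            raise ValueError("sigma_percentile must be in [0, 100]")
        if self.epsilon is not None and not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must be in [0, 1]")


def _rank(gene_ids: list[str], counts: np.ndarray, kind: str,
          params: dict) -> GeneRanking:
    order = sorted(range(len(gene_ids)), key=lambda i: (-counts[i], gene_ids[i]))
    return GeneRanking([(gene_ids[i], int(counts[i])) for i in order],
                       kind=kind, params=params)


def critical_genes(
    e: EmbeddingMatrix,
    impact: GeneSet,
    tops: list[TopDimensions],
    params: ProximityParams | None = None,
) -> GeneRanking:
    """Count impact genes within sigma of each gene, summed over models.

    For each model's top-dimension subspace, Euclidean distances from
    every gene to every impact gene are computed; impact genes strictly
    closer than sigma are counted (a gene never counts itself).  Counts
    are summed across models and sorted descending.
    """
    params = params or ProximityParams()
    universe = set(e.gene_ids)
    outside = impact.genes - universe
    if outside:
        raise ValueError(f"impact genes outside embedding: {sorted(outside)[:5]}")
    if not impact.genes:
        raise ValueError("empty impact set")
    gidx = {g: i for i, g in enumerate(e.gene_ids)}
    imp_idx = np.array([gidx[g] for g in sorted(impact.genes)], dtype=int)
    total = np.zeros(e.n_genes, dtype=int)
    sigmas: dict[str, float] = {}
    used_models = 0
    for top in tops:
        if not top.dims:
            import warnings

            warnings.warn(f"model {top.model_kind}: empty top-dimension set, skipped")
            continue
        sub = e.subspace(top.dims)
        dist = cdist(sub, sub[imp_idx])
        self_mask = np.zeros_like(dist, dtype=bool)
        for col, gi in enumerate(imp_idx):
            self_mask[gi, col] = True
        if params.sigma is not None:
            sigma = params.sigma
        else:
            sigma = float(np.percentile(dist[~self_mask], params.sigma_percentile))
        sigmas[top.model_kind] = sigma
        total += ((dist < sigma) & ~self_mask).sum(axis=1)
        used_models += 1
    if used_models == 0:
        raise ValueError("no model contributed a non-empty top-dimension set")
    return _rank(list(e.gene_ids), total, "critical",
                 {"sigma": sigmas, "n_models": used_models,
                  "sigma_percentile": params.sigma_percentile})


def neighbor_genes(
    t: TOMNetwork,
    impact: GeneSet,
    epsilon: float,
) -> GeneRanking:
    """Count impact genes connected with TOM weight strictly above epsilon."""
    universe = set(t.gene_ids)
    outside = impact.genes - universe
    if outside:
        raise ValueError(f"impact genes outside network: {sorted(outside)[:5]}")
    if not impact.genes:
        raise ValueError("empty impact set")
    gidx = {g: i for i, g in enumerate(t.gene_ids)}
    imp_idx = np.array([gidx[g] for g in sorted(impact.genes)], dtype=int)
    w = t.weights[:, imp_idx].copy()
    for col, gi in enumerate(imp_idx):
        w[gi, col] = 0.0  # self-exclusion (diagonal weight is 1 by definition)
    counts = (w > epsilon).sum(axis=1)
    return _rank(list(t.gene_ids), counts, "neighbor", {"epsilon": epsilon})


def match_list_sizes(
    t: TOMNetwork,
    impact: GeneSet,
    critical: GeneRanking,
    positive_count_only: bool = True,
) -> tuple[float, GeneRanking, bool]:
    """Choose epsilon so the neighbor list matches the critical list size.

    The target size is the number of critical genes with count >= 1 (or
    the full list length when *positive_count_only* is False).  Since the
    number of genes with a neighbor count >= 1 under cutoff eps equals
    ``|{g : max_j T[g, j] > eps}|`` over impact columns j (self excluded),
    the achievable sizes are determined by the sorted per-gene maxima;
    epsilon is placed between consecutive maxima.  When ties make the
    target size unreachable the nearest achievable size is used and the
    returned flag is False.

    Returns ``(epsilon, neighbor_ranking, exact_match)``.
    """
    target = len(critical.positive_set()) if positive_count_only else len(critical.entries)
    gidx = {g: i for i, g in enumerate(t.gene_ids)}
    imp_idx = np.array([gidx[g] for g in sorted(impact.genes & set(t.gene_ids))],
                       dtype=int)
    if imp_idx.size == 0:
        raise ValueError("empty impact set")
    w = t.weights[:, imp_idx].copy()
    for col, gi in enumerate(imp_idx):
        w[gi, col] = 0.0
    maxw = w.max(axis=1)
    if target <= 0:
        return 1.0, neighbor_genes(t, impact, 1.0), True
    desc = np.sort(maxw)[::-1]
    # size as a function of eps: |{maxw > eps}|; candidate cutpoints between
    # consecutive distinct maxima realize every achievable size
    candidates: list[tuple[int, float]] = [(int((maxw > 0).sum()), 0.0)]
    for s in range(1, len(desc) + 1):
        hi = desc[s - 1]
        lo = desc[s] if s < len(desc) else 0.0
        if hi > lo:  # eps in [lo, hi) gives exactly s positives
            eps = (hi + lo) / 2.0
            candidates.append((s, eps))
    best_size, best_eps = min(candidates, key=lambda c: (abs(c[0] - target), -c[1]))
    exact = best_size == target
    if not exact:
        import warnings

        warnings.warn(
            f"neighbor list size {best_size} is the nearest achievable to the "
            f"target {target} (tied edge weights)"
        )
    return best_eps, neighbor_genes(t, impact, best_eps), exact
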