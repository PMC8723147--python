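"""Co-expression network construction and module-level summaries.

The network is an unsigned weighted gene co-expression graph: soft-power
adjacency ``a_ij = |cor(x_i, x_j)|**beta`` turned into a topological
overlap matrix (TOM),

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_u a_iu * a_uj   (u != i, j),
    k_i    = sum_{u != i} a_iu,

with TOM_ii = 1.  Two genes score high when they are strongly correlated
*and* share many strong mutual neighbors.  Modules are detected on the TOM
with Louvain community detection; each module is summarized by its
eigengene (first principal component of the standardized module
submatrix), which is correlated with sample traits, and by the fraction of
member genes that differ across binned trait classes by one-way ANOVA.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy import stats

from .netio import ExpressionMatrix, GeneSet, TOMNetwork, TraitTable

__all__ = [
    "ModuleAssignment",
    "Eigengene",
    "TraitBinning",
    "build_tom",
    "louvain_modules",
    "eigengene",
    "module_trait_cor",
    "bin_trait",
    "pct_significant_by_anova",
    "pct_deg",
]


@dataclass
class ModuleAssignment:
    """Gene -> module label, labels contiguous 0..n_modules-1."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        vals = sorted(set(self.labels.values()))
        if vals != list(range(len(vals))):
            raise ValueError(f"module labels not contiguous from 0: {vals[:10]}")

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def members(self, module: int) -> list[str]:
        return sorted(g for g, m in self.labels.items() if m == module)

    def as_gene_sets(self) -> list[GeneSet]:
        return [GeneSet(f"module {m}", frozenset(self.members(m)))
                for m in range(self.n_modules)]


@dataclass
class Eigengene:
    """First principal component of a gene group's expression."""

    module: int | str
    sample_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray  # unit-norm, over member genes

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise ValueError("score length != n_samples")
        if not np.isclose(np.linalg.norm(self.loadings), 1.0):
            raise ValueError("loading vector must be unit norm")


@dataclass
class TraitBinning:
    """Per-sample ordinal class labels for one trait.

    Bins are left-closed/right-open on the interior edges; the lowest bin
    is open below and the highest open above, so every value gets a class.
    With 3 edges this yields the 4 classes used for trait ANOVA.
    """

    trait_name: str
    edges: list[float]
    classes: dict[str, int]  # sample_id -> 1..len(edges)+1

    @property
    def n_classes(self) -> int:
        return len(self.edges) + 1


def build_tom(x: ExpressionMatrix, beta: float = 6.0) -> TOMNetwork:
    """Unsigned soft-threshold adjacency + topological overlap.

    *beta* is the soft-power exponent applied to |Pearson correlation|;
    higher beta suppresses weak correlations and pushes the network toward
    scale-free topology.  Requires >= 3 samples and no zero-variance gene.
    """
    if x.n_samples < 3:
        raise ValueError("need at least 3 samples to build a network")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    sd = x.values.std(axis=1)
    if np.any(sd == 0):
        bad = [x.gene_ids[i] for i in np.flatnonzero(sd == 0)[:5]]
        raise ValueError(f"zero-variance gene(s): {bad}")
    a = np.abs(np.corrcoef(x.values)) ** beta
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_u a_iu a_uj; diag(a)=0 removes u=i,j terms
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMNetwork(list(x.gene_ids), tom)


def _tom_graph(t: TOMNetwork) -> ig.Graph:
    iu, ju = np.triu_indices(t.n_genes, k=1)
    w = t.weights[iu, ju]
    nz = w > 0
    g = ig.Graph(
        n=t.n_genes,
        edges=np.column_stack([iu[nz], ju[nz]]).tolist(),
        edge_attrs={"weight": w[nz].tolist()},
    )
    return g


def louvain_modules(t: TOMNetwork, resolution: float = 1.0, seed: int = 0) -> ModuleAssignment:
    """Louvain community detection on the weighted TOM graph.

    Deterministic for a fixed *seed*; labels are renumbered by first
    occurrence in canonical gene order.  The returned partition's
    modularity is never below that of the all-singletons partition (0 for
    singletons on a graph without self-loops; Louvain only merges when
    modularity improves).
    """
    g = _tom_graph(t)
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    membership = np.asarray(part.membership)
    relabel: dict[int, int] = {}
    for m in membership:
        if m not in relabel:
            relabel[m] = len(relabel)
    labels = {t.gene_ids[i]: relabel[int(membership[i])] for i in range(t.n_genes)}
    return ModuleAssignment(labels)


def eigengene(x: ExpressionMatrix, genes: GeneSet | list[str],
              module: int | str = "set") -> Eigengene:
    """First principal component of the standardized module submatrix.

    Each member gene is z-scored across samples; the eigengene is the
    per-sample score on the first right-singular direction.  Orientation is
    fixed so that the mean correlation with member gene profiles is >= 0.
    """
    members = sorted(genes.genes) if isinstance(genes, GeneSet) else sorted(genes)
    missing = [g for g in members if g not in set(x.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    if len(members) < 2 or x.n_samples < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    sub = x.restrict(members).values  # genes x samples
    sd = sub.std(axis=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # SVD of samples x genes: scores live in sample space
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = vt[0]
    cors = _rowwise_cor(z, scores)
    if np.nanmean(cors) < 0:
        scores, loadings = -scores, -loadings
    return Eigengene(module, list(x.sample_ids), scores, loadings)


def _rowwise_cor(z: np.ndarray, v: np.ndarray) -> np.ndarray:
    vz = (v - v.mean())
    vn = np.linalg.norm(vz)
    zc = z - z.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(zc, axis=1) * vn
    with np.errstate(invalid="ignore", divide="ignore"):
        return (zc @ vz) / denom


def module_trait_cor(e: Eigengene, traits: TraitTable) -> dict[str, tuple[float, float]]:
    """Pearson correlation of the eigengene with each trait.

    Samples missing the trait are dropped pairwise.  Returns
    ``{trait: (r, p)}`` with ``(nan, nan)`` when fewer than 3 complete
    pairs exist or either side is constant.
    """
    out: dict[str, tuple[float, float]] = {}
    for trait in traits.trait_names:
        v = traits.values_for(trait, e.sample_ids)
        ok = ~np.isnan(v)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(e.scores[ok]) == 0:
            out[trait] = (float("nan"), float("nan"))
            continue
        r, p = stats.pearsonr(e.scores[ok], v[ok])
        out[trait] = (float(r), float(p))
    return out


def bin_trait(traits: TraitTable, trait_name: str,
              edges: list[float] | tuple[float, ...]) -> TraitBinning:
    """Assign each sample with the trait to an ordinal class 1..len(edges)+1.

    Interior bins are ``[e_k, e_{k+1})``: a value exactly on an edge falls
    in the upper class.
    """
    edges = [float(e) for e in edges]
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    sub = traits.data[traits.data["trait_name"] == trait_name]
    if sub.empty:
        raise ValueError(f"trait {trait_name!r} not present")
    classes = {
        s: int(np.searchsorted(edges, v, side="right")) + 1
        for s, v in zip(sub["sample_id"], sub["value"])
    }
    return TraitBinning(trait_name, edges, classes)


def pct_significant_by_anova(
    x: ExpressionMatrix,
    groups: ModuleAssignment,
    binning: TraitBinning,
    alpha: float = 0.05,
) -> dict[int, float]:
    """Per module, the percentage of genes differing across trait classes.

    One-way ANOVA of each gene's expression across the binned trait
    classes; a gene counts as significant when p < *alpha*.  Genes with no
    within-class variance anywhere (F undefined) count as nonsignificant.
    Requires every represented class to have >= 2 samples.
    """
    sample_class = np.array([binning.classes.get(s, 0) for s in x.sample_ids])
    present = [c for c in sorted(set(sample_class)) if c > 0]
    if len(present) < 2:
        raise ValueError(f"trait {binning.trait_name!r}: fewer than 2 classes present")
    small = [c for c in present if (sample_class == c).sum() < 2]
    if small:
        raise ValueError(
            f"trait {binning.trait_name!r}: class(es) {small} have < 2 samples"
        )
    cols = [x.values[:, sample_class == c] for c in present]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(*cols, axis=1)
    sig = np.where(np.isnan(p), False, p < alpha)
    out: dict[int, float] = {}
    gene_idx = {g: i for i, g in enumerate(x.gene_ids)}
    for m in range(groups.n_modules):
        members = [gene_idx[g] for g in groups.members(m)]
        out[m] = 100.0 * float(np.mean(sig[members])) if members else 0.0
    return out


def pct_deg(groups: ModuleAssignment, degs: GeneSet) -> dict[int, float]:
    """Percentage of each module's genes that are in *degs*."""
    universe = set(groups.labels)
    outside = degs.genes - universe
    if outside:
        raise ValueError(f"DEGs outside the assigned universe: {sorted(outside)[:5]}")
    out: dict[int, float] = {}
    for m in range(groups.n_modules):
        members = groups.members(m)
        out[m] = 100.0 * len(set(members) & degs.genes) / len(members) if members else 0.0
    return out
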