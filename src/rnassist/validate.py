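"""Validation statistics for gene lists.

Three families of checks support a critical-gene run:

* overlap of a candidate list with an external reference list (known
  disease genes, regulator lists), scored with an exact upper-tail
  hypergeometric test against a declared gene universe;
* per-gene Pearson correlation of list members' expression with sample
  traits, compared across lists with a t-test (2 lists) or one-way ANOVA
  with Tukey HSD post-hoc (>2 lists) on the |r| values -- absolute values
  because the comparison targets the size, not the direction, of the
  correlations;
* cross-cohort correlation: in an independent expression cohort, the
  correlation matrix between the top genes of two lists, summarized by
  the mean absolute coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .netio import ExpressionMatrix, GeneSet, TraitTable

__all__ = [
    "OverlapResult",
    "CorComparison",
    "overlap_test",
    "gene_trait_cor",
    "compare_gene_lists_cor",
    "cross_cohort_cor",
]


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene sets in a universe."""

    list_a: str
    size_a: int
    list_b: str
    size_b: int
    universe_size: int
    overlap: list[str]
    p_value: float  # P(X >= k)

    @property
    def k(self) -> int:
        return len(self.overlap)


@dataclass
class CorComparison:
    """Per-list |r| collections and the cross-list test on them."""

    abs_cors: dict[str, np.ndarray]  # list name -> |r| values (per gene-trait)
    statistic: float
    p_value: float
    test: str  # "welch-t" | "anova"
    pairwise: pd.DataFrame | None = field(default=None)  # Tukey table for >2 lists


def overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapResult:
    """Exact upper-tail hypergeometric test for |a ∩ b|.

    Population N = |universe|, successes K = |b|, draws n = |a|, observed
    k = |a ∩ b|; returns P(X >= k), the chance of seeing k or more shared
    genes if *a* were drawn at random from the universe.
    """
    if not universe.genes:
        raise ValueError("empty universe")
    if not a.genes <= universe.genes:
        raise ValueError(f"{a.name!r} not contained in the universe")
    if not b.genes <= universe.genes:
        raise ValueError(f"{b.name!r} not contained in the universe")
    overlap = sorted(a.genes & b.genes)
    k = len(overlap)
    n_universe, n_a, n_b = len(universe), len(a), len(b)
    # sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, n_universe, n_b, n_a))
    return OverlapResult(a.name, n_a, b.name, n_b, n_universe, overlap, min(p, 1.0))


def gene_trait_cor(
    x: ExpressionMatrix, genes: GeneSet, traits: TraitTable
) -> pd.DataFrame:
    """Pearson r of each gene's expression with each trait.

    Samples missing the trait are dropped pairwise; NaN where fewer than
    3 complete pairs exist or either side is constant.  Returns a genes x
    traits DataFrame.
    """
    members = sorted(g for g in genes.genes if g in set(x.gene_ids))
    if not members:
        raise ValueError("no genes from the set are present in the expression matrix")
    sub = x.restrict(members)
    out = pd.DataFrame(index=members, columns=traits.trait_names, dtype=float)
    for trait in traits.trait_names:
        v = traits.values_for(trait, sub.sample_ids)
        ok = ~np.isnan(v)
        if ok.sum() < 3 or np.std(v[ok]) == 0:
            out[trait] = np.nan
            continue
        vals = sub.values[:, ok]
        sd = vals.std(axis=1)
        vc = v[ok] - v[ok].mean()
        xc = vals - vals.mean(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ vc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(vc))
        r[sd == 0] = np.nan
        out[trait] = r
    return out


def compare_gene_lists_cor(
    abs_cors: dict[str, np.ndarray | list[float]]
) -> CorComparison:
    """Compare |r| collections across gene lists.

    Two lists: Welch two-sided t-test.  More: one-way ANOVA plus Tukey HSD
    post-hoc for pairwise adjusted p-values.  Degenerate variance with
    equal means gives p = 1 by convention.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in abs_cors.items()}
    clean = {k: v[~np.isnan(v)] for k, v in clean.items()}
    if len(clean) < 2:
        raise ValueError("need at least two gene lists")
    for name, v in clean.items():
        if len(v) < 3:
            raise ValueError(f"list {name!r} has fewer than 3 |r| values")
    arrays = list(clean.values())
    if all(a.std() <= 1e-12 * max(1.0, abs(a.mean())) for a in arrays):
        means = [a.mean() for a in arrays]
        equal = all(np.isclose(m, means[0]) for m in means)
        return CorComparison(clean, 0.0 if equal else np.inf,
                             1.0 if equal else 0.0,
                             "welch-t" if len(clean) == 2 else "anova")
    if len(clean) == 2:
        t, p = stats.ttest_ind(*arrays, equal_var=False)
        return CorComparison(clean, float(t), float(p), "welch-t")
    f, p = stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[name] * len(v) for name, v in clean.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return CorComparison(clean, float(f), float(p), "anova", table)


def cross_cohort_cor(
    x2: ExpressionMatrix,
    list_a: GeneSet,
    list_b: GeneSet,
    top_n: int | None = 50,
    order_a: list[str] | None = None,
    order_b: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Correlation matrix between two gene lists in an independent cohort.

    Takes the top *top_n* genes per list (by the caller-supplied ranking
    orders, else lexicographic) that are present in *x2*, computes the
    Pearson correlation matrix between the two groups' expression, and
    reports the mean absolute coefficient.
    """
    present = set(x2.gene_ids)

    def _pick(s: GeneSet, order: list[str] | None) -> list[str]:
        ranked = [g for g in (order or sorted(s.genes)) if g in s.genes and g in present]
        return ranked[: top_n or len(ranked)]

    ga, gb = _pick(list_a, order_a), _pick(list_b, order_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 genes per list present in the cohort")
    va = x2.restrict(ga).values
    vb = x2.restrict(gb).values
    full = np.corrcoef(np.vstack([va, vb]))
    mat = pd.DataFrame(full[: len(ga), len(ga):], index=ga, columns=gb)
    return mat, float(np.abs(mat.to_numpy()).mean())
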