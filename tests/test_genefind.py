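import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rnassist as rn
from rnassist import genefind
from rnassist.genefind import ProximityParams, critical_genes, match_list_sizes, neighbor_genes
from rnassist.mlrank import TopDimensions

from conftest import toy_tom


def brute_force_critical(coords_by_model, impact_idx, sigma, gene_ids):
    """Double-loop reference implementation of the critical-gene count."""
    n = len(gene_ids)
    counts = [0] * n
    for coords in coords_by_model:
        for i in range(n):
            for j in impact_idx:
                if i == j:
                    continue
                dist = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
                if dist < sigma:
                    counts[i] += 1
    order = sorted(range(n), key=lambda i: (-counts[i], gene_ids[i]))
    return [(gene_ids[i], counts[i]) for i in order]


def brute_force_neighbors(weights, impact_idx, eps, gene_ids):
    n = len(gene_ids)
    counts = [0] * n
    for i in range(n):
        for j in impact_idx:
            if i != j and weights[i][j] > eps:
                counts[i] += 1
    order = sorted(range(n), key=lambda i: (-counts[i], gene_ids[i]))
    return [(gene_ids[i], counts[i]) for i in order]


class TestCriticalGenes:
    def test_hand_enumerated_1d_example(self):
        ids = ["A", "B", "C", "D"]
        e = rn.EmbeddingMatrix(ids, np.array([[0.0], [0.5], [2.0], [0.9]]))
        impact = rn.GeneSet("impact", frozenset(["A"]))
        top = TopDimensions("logistic", [0], 1.0)
        r = critical_genes(e, impact, [top], ProximityParams(sigma=1.0,
                                                             sigma_percentile=None))
        assert r.entries == [("B", 1), ("D", 1), ("A", 0), ("C", 0)]

    def test_sigma_saturation(self, rng):
        ids = [f"g{i}" for i in range(10)]
        e = rn.EmbeddingMatrix(ids, rng.standard_normal((10, 3)))
        impact = rn.GeneSet("impact", frozenset(ids[:4]))
        tops = [TopDimensions("a", [0, 1], 1.0), TopDimensions("b", [2], 1.0)]
        r = critical_genes(e, impact, tops,
                           ProximityParams(sigma=1e9, sigma_percentile=None))
        for g, c in r.entries:
            assert c == 2 * (4 - (g in impact.genes))

    def test_sigma_zero_all_counts_zero(self, rng):
        ids = [f"g{i}" for i in range(6)]
        e = rn.EmbeddingMatrix(ids, rng.standard_normal((6, 2)))
        impact = rn.GeneSet("impact", frozenset(ids[:2]))
        r = critical_genes(e, impact, [TopDimensions("a", [0, 1], 1.0)],
                           ProximityParams(sigma=0.0, sigma_percentile=None))
        assert all(c == 0 for _, c in r.entries)

    def test_empty_impact_rejected(self, rng):
        e = rn.EmbeddingMatrix(["a", "b"], rng.standard_normal((2, 2)))
        with pytest.raises(ValueError, match="empty impact"):
            critical_genes(e, rn.GeneSet("impact", frozenset()),
                           [TopDimensions("a", [0], 1.0)])

    def test_monotone_in_sigma(self, rng):
        ids = [f"g{i}" for i in range(15)]
        e = rn.EmbeddingMatrix(ids, rng.standard_normal((15, 4)))
        impact = rn.GeneSet("impact", frozenset(ids[:5]))
        tops = [TopDimensions("a", [0, 1, 2, 3], 1.0)]
        prev = None
        for sigma in (0.5, 1.0, 2.0, 4.0):
            r = critical_genes(e, impact, tops,
                               ProximityParams(sigma=sigma, sigma_percentile=None))
            counts = r.counts_by_gene()
            if prev is not None:
                assert all(counts[g] >= prev[g] for g in ids)
            prev = counts

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        d = int(rng.integers(2, 6))
        ids = sorted(f"g{i:02d}" for i in range(n))
        coords = rng.standard_normal((n, d))
        e = rn.EmbeddingMatrix(ids, coords)
        n_imp = int(rng.integers(1, max(2, n // 3)))
        impact_idx = sorted(rng.choice(n, size=n_imp, replace=False).tolist())
        impact = rn.GeneSet("impact", frozenset(ids[i] for i in impact_idx))
        dims = sorted(rng.choice(d, size=int(rng.integers(1, d + 1)),
                                 replace=False).tolist())
        sigma = float(rng.uniform(0.1, 3.0))
        tops = [TopDimensions("m1", dims, 1.0), TopDimensions("m2", [0], 1.0)]
        got = critical_genes(e, impact, tops,
                             ProximityParams(sigma=sigma, sigma_percentile=None))
        want = brute_force_critical([coords[:, dims], coords[:, [0]]],
                                    impact_idx, sigma, ids)
        assert got.entries == want


class TestNeighborGenes:
    def test_hand_counted_example(self):
        w = np.zeros((3, 3))
        w[1, 0] = w[0, 1] = 0.3
        w[2, 0] = w[0, 2] = 0.1
        t = toy_tom(w, ids=["g1", "g2", "g3"])
        r = neighbor_genes(t, rn.GeneSet("impact", frozenset(["g1"])), 0.2)
        assert r.entries == [("g2", 1), ("g1", 0), ("g3", 0)]

    def test_epsilon_one_empty(self, small_tom, small_cohort):
        _, dea, _, _ = small_cohort
        impact = rn.label_impact(dea, 8.0).impact_set
        r = neighbor_genes(small_tom, impact, 1.0)
        assert all(c == 0 for _, c in r.entries)

    def test_epsilon_zero_counts_nonzero_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.4
        w[0, 2] = w[2, 0] = 0.0
        t = toy_tom(w)
        r = neighbor_genes(t, rn.GeneSet("impact", frozenset(["g0"])), 0.0)
        counts = r.counts_by_gene()
        assert counts == {"g1": 1, "g0": 0, "g2": 0, "g3": 0}

    def test_monotone_in_epsilon(self, small_tom, small_cohort):
        _, dea, _, _ = small_cohort
        impact = rn.label_impact(dea, 8.0).impact_set
        prev = None
        for eps in (0.0, 0.05, 0.1, 0.3):
            counts = neighbor_genes(small_tom, impact, eps).counts_by_gene()
            if prev is not None:
                assert all(counts[g] <= prev[g] for g in counts)
            prev = counts

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        ids = sorted(f"g{i:02d}" for i in range(n))
        w = rng.random((n, n)) * 0.9
        w = (w + w.T) / 2
        t = toy_tom(w.copy(), ids=ids)
        n_imp = int(rng.integers(1, max(2, n // 3)))
        impact_idx = sorted(rng.choice(n, size=n_imp, replace=False).tolist())
        impact = rn.GeneSet("impact", frozenset(ids[i] for i in impact_idx))
        eps = float(rng.uniform(0.0, 0.9))
        got = neighbor_genes(t, impact, eps)
        want = brute_force_neighbors(t.weights, impact_idx, eps, ids)
        assert got.entries == want


class TestMatchListSizes:
    def _critical_with_positive(self, ids, n_positive):
        entries = [(g, 1 if i < n_positive else 0)
                   for i, g in enumerate(sorted(ids))]
        return rn.GeneRanking(entries, kind="critical")

    def test_distinct_weights_exact_match(self, rng):
        n = 20
        ids = sorted(f"g{i:02d}" for i in range(n))
        w = np.zeros((n, n))
        vals = rng.permutation(np.linspace(0.01, 0.95, n * (n - 1) // 2))
        iu, ju = np.triu_indices(n, 1)
        w[iu, ju] = vals
        w = w + w.T
        t = toy_tom(w, ids=ids)
        impact = rn.GeneSet("impact", frozenset(ids[:5]))
        for target in (0, 3, 10, 19):
            crit = self._critical_with_positive(ids, target)
            eps, ranking, exact = match_list_sizes(t, impact, crit)
            assert exact
            assert len(ranking.positive_set()) == target
            # brute-force sweep over every candidate cutoff confirms
            # no epsilon does better
            sizes = {len(neighbor_genes(t, impact, float(e)).positive_set())
                     for e in np.append(w[iu, ju], [0.0])}
            assert target in sizes or not exact

    def test_target_zero(self, small_tom, small_cohort):
        _, dea, _, _ = small_cohort
        impact = rn.label_impact(dea, 8.0).impact_set
        crit = self._critical_with_positive(small_tom.gene_ids, 0)
        eps, ranking, exact = match_list_sizes(small_tom, impact, crit)
        assert eps == 1.0 and exact
        assert len(ranking.positive_set()) == 0

    def test_tied_weights_nearest_size_flagged(self):
        # every gene's strongest impact edge is the same weight, so the
        # achievable sizes jump straight from 0 to 3
        w = np.zeros((4, 4))
        for i in (1, 2, 3):
            w[0, i] = w[i, 0] = 0.5
        t = toy_tom(w)
        impact = rn.GeneSet("impact", frozenset(["g0"]))
        crit = self._critical_with_positive(t.gene_ids, 2)
        with pytest.warns(UserWarning, match="nearest achievable"):
            eps, ranking, exact = match_list_sizes(t, impact, crit)
        assert not exact
        assert len(ranking.positive_set()) == 3
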