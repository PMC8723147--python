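import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rnassist as rn
from rnassist.network import bin_trait, pct_deg, pct_significant_by_anova

from conftest import toy_tom


def _traits_from(samples, name, values):
    return rn.TraitTable(pd.DataFrame(
        {"sample_id": samples, "trait_name": name, "value": values}))


class TestBuildTOM:
    def test_two_perfectly_correlated_genes_reach_tom_one(self):
        # a_12 = 1, no other genes: TOM_12 = (0 + 1) / (1 + 1 - 1) = 1
        s = np.array([0.0, 1.0, 2.0, 3.0])
        x = rn.ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(4)],
                                np.vstack([s, 2 * s + 1]))
        t = rn.build_tom(x, beta=6)
        assert t.weights[0, 1] == pytest.approx(1.0)

    def test_pair_without_shared_neighbors_equals_adjacency(self):
        # hand-built 3-gene adjacency: direct formula with l_12 = 0
        a12, a13, a23 = 0.3, 0.0, 0.0
        a = np.array([[0, a12, a13], [a12, 0, a23], [a13, a23, 0.0]])
        k = a.sum(axis=1)
        expect = (0 + a12) / (min(k[0], k[1]) + 1 - a12)
        # reconstruct the same arithmetic from build_tom's own path by
        # feeding expression whose |cor|^beta reproduces a
        rng = np.random.default_rng(0)
        base = rng.standard_normal(2000)
        r12 = a12 ** (1 / 6.0)
        g2 = r12 * base + np.sqrt(1 - r12**2) * rng.standard_normal(2000)
        g3 = rng.standard_normal(2000)
        x = rn.ExpressionMatrix(["g1", "g2", "g3"],
                                [f"s{i}" for i in range(2000)],
                                np.vstack([base, g2, g3]))
        t = rn.build_tom(x, beta=6)
        # empirical correlations wobble, so compare against the formula
        # evaluated at the realized adjacency
        c = np.abs(np.corrcoef(x.values)) ** 6
        np.fill_diagonal(c, 0)
        kk = c.sum(axis=1)
        want = (c[0] @ c[:, 1] + c[0, 1]) / (min(kk[0], kk[1]) + 1 - c[0, 1])
        assert t.weights[0, 1] == pytest.approx(want, rel=1e-10)

    def test_gene_permutation_equivariance(self, small_cohort):
        expr, _, _, _ = small_cohort
        sub = expr.restrict(expr.gene_ids[:30])
        t1 = rn.build_tom(sub, beta=6)
        perm = list(reversed(range(30)))
        x2 = rn.ExpressionMatrix([sub.gene_ids[i] for i in perm],
                                 sub.sample_ids, sub.values[perm])
        t2 = rn.build_tom(x2, beta=6)
        np.testing.assert_allclose(
            t2.weights, t1.weights[np.ix_(perm, perm)], atol=1e-12)

    def test_zero_variance_gene_rejected(self):
        x = rn.ExpressionMatrix(["g1", "g2"], ["s1", "s2", "s3"],
                                np.array([[1.0, 1.0, 1.0], [0, 1, 2.0]]))
        with pytest.raises(ValueError, match="g1"):
            rn.build_tom(x)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 12), st.integers(4, 10))
    def test_output_is_valid_tom_for_random_inputs(self, seed, n_genes, n_samples):
        rng = np.random.default_rng(seed)
        x = rn.ExpressionMatrix(
            [f"g{i}" for i in range(n_genes)],
            [f"s{i}" for i in range(n_samples)],
            rng.standard_normal((n_genes, n_samples)),
        )
        t = rn.build_tom(x, beta=6)  # constructor enforces the invariants
        assert t.weights.min() >= 0 and t.weights.max() <= 1
        assert np.allclose(np.diag(t.weights), 1.0)


class TestLouvain:
    def test_two_cliques_found_exactly(self):
        w = np.zeros((10, 10))
        w[:5, :5] = 1.0
        w[5:, 5:] = 1.0
        t = toy_tom(w)
        mods = rn.louvain_modules(t, seed=1)
        assert mods.n_modules == 2
        labels = [mods.labels[g] for g in t.gene_ids]
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_uniform_weights_have_no_community_structure(self):
        t = toy_tom(np.full((12, 12), 0.5))
        mods = rn.louvain_modules(t, seed=1)
        # modularity of any partition of a complete uniform graph is ~0
        import igraph as ig

        g = ig.Graph.Full(12)
        g.es["weight"] = 0.5
        labels = [mods.labels[f"g{i}"] for i in range(12)]
        assert g.modularity(labels, weights="weight") <= 0.05

    def test_recovers_planted_modules(self, small_tom, small_modules, small_cohort):
        from sklearn.metrics import adjusted_rand_score

        _, _, _, truth = small_cohort
        lab_true = [truth.module_of[g] for g in small_tom.gene_ids]
        lab_hat = [small_modules.labels[g] for g in small_tom.gene_ids]
        assert adjusted_rand_score(lab_true, lab_hat) >= 0.7

    def test_seed_reproducible(self, small_tom):
        a = rn.louvain_modules(small_tom, seed=5)
        b = rn.louvain_modules(small_tom, seed=5)
        assert a.labels == b.labels


class TestEigengene:
    def test_identical_profiles_give_perfect_correlation(self):
        prof = np.array([0.0, 1.0, 3.0, 2.0])
        x = rn.ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(4)],
                                np.vstack([prof, prof]))
        eg = rn.eigengene(x, ["g1", "g2"])
        r = np.corrcoef(eg.scores, prof)[0, 1]
        assert r == pytest.approx(1.0)

    def test_tracks_planted_module_factor(self, small_cohort):
        expr, _, traits, truth = small_cohort
        members = [g for g, m in truth.module_of.items() if m == 0]
        eg = rn.eigengene(expr, members, module=0)
        # the audit trait is a noisy copy of module 0's factor, so the
        # eigengene must correlate strongly with it
        r, _ = rn.module_trait_cor(eg, traits)["audit"]
        assert abs(r) >= 0.4
        # and near-perfectly with the factor estimate (member mean profile)
        factor_est = expr.restrict(members).values.mean(axis=0)
        assert abs(np.corrcoef(eg.scores, factor_est)[0, 1]) >= 0.9

    def test_sign_flip_symmetry(self, small_cohort):
        expr, _, traits, _ = small_cohort
        genes = expr.gene_ids[:10]
        flipped = rn.ExpressionMatrix(expr.gene_ids, expr.sample_ids, -expr.values)
        r1 = rn.module_trait_cor(rn.eigengene(expr, genes), traits)
        r2 = rn.module_trait_cor(rn.eigengene(flipped, genes), traits)
        for trait in r1:
            assert abs(r1[trait][0]) == pytest.approx(abs(r2[trait][0]), abs=1e-9)

    def test_absent_gene_rejected(self, small_cohort):
        expr, _, _, _ = small_cohort
        with pytest.raises(ValueError, match="absent"):
            rn.eigengene(expr, ["nope", expr.gene_ids[0]])


class TestModuleTraitCor:
    def test_trait_equal_to_scores_gives_r_one(self):
        x = rn.ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(5)],
                                np.vstack([np.arange(5.0), np.arange(5.0) * 2]))
        eg = rn.eigengene(x, ["g1", "g2"])
        traits = _traits_from(x.sample_ids, "t", eg.scores)
        r, p = rn.module_trait_cor(eg, traits)["t"]
        assert r == pytest.approx(1.0)

    def test_constant_trait_is_missing_not_zero(self):
        x = rn.ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(5)],
                                np.vstack([np.arange(5.0), np.arange(5.0) * 2]))
        eg = rn.eigengene(x, ["g1", "g2"])
        traits = _traits_from(x.sample_ids, "t", np.ones(5))
        r, p = rn.module_trait_cor(eg, traits)["t"]
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_pairs_missing(self):
        x = rn.ExpressionMatrix(["g1", "g2"], [f"s{i}" for i in range(5)],
                                np.vstack([np.arange(5.0), np.arange(5.0) * 2]))
        eg = rn.eigengene(x, ["g1", "g2"])
        traits = _traits_from(["s0", "s1"], "t", [1.0, 2.0])
        r, _ = rn.module_trait_cor(eg, traits)["t"]
        assert np.isnan(r)


class TestBinTrait:
    @pytest.mark.parametrize(
        "value,edges,expect",
        [
            (30.0, (25, 50, 100), 2),   # between the first two edges
            (25.0, (25, 50, 100), 2),   # boundary joins the upper class
            (15.0, (20, 30, 40), 1),    # below the lowest edge
            (120.0, (25, 50, 100), 4),  # above the top edge
        ],
    )
    def test_four_class_assignment(self, value, edges, expect):
        traits = _traits_from(["s1"], "audit", [value])
        b = bin_trait(traits, "audit", edges)
        assert b.classes["s1"] == expect
        assert b.n_classes == 4

    def test_edges_must_increase(self):
        traits = _traits_from(["s1"], "audit", [1.0])
        with pytest.raises(ValueError, match="increasing"):
            bin_trait(traits, "audit", (5, 5, 10))


class TestPctSignificantByANOVA:
    def _setup(self, values, n_samples=12):
        samples = [f"s{i}" for i in range(n_samples)]
        x = rn.ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                                samples, values)
        groups = rn.ModuleAssignment({g: 0 for g in x.gene_ids})
        trait_vals = np.repeat([10.0, 30.0, 60.0, 120.0], n_samples // 4)
        traits = _traits_from(samples, "audit", trait_vals)
        binning = bin_trait(traits, "audit", (25, 50, 100))
        return x, groups, binning

    def test_constant_genes_never_significant(self):
        x, groups, binning = self._setup(np.ones((5, 12)))
        out = pct_significant_by_anova(x, groups, binning, alpha=0.05)
        assert out == {0: 0.0}

    def test_alpha_one_everything_significant(self, rng):
        x, groups, binning = self._setup(rng.standard_normal((5, 12)))
        out = pct_significant_by_anova(x, groups, binning, alpha=1.0)
        assert out == {0: 100.0}

    def test_mapped_module_genes_more_significant(self, small_cohort):
        expr, _, traits, truth = small_cohort
        groups = rn.ModuleAssignment(truth.module_of)
        v = traits.values_for("audit", expr.sample_ids)
        qs = np.quantile(v[~np.isnan(v)], [0.25, 0.5, 0.75])
        binning = bin_trait(traits, "audit", qs)
        out = pct_significant_by_anova(expr, groups, binning, alpha=0.05)
        mapped = truth.trait_generating_modules["audit"][0]
        others = [out[m] for m in out if m != mapped]
        assert out[mapped] > max(others)

    def test_tiny_class_aborts_trait(self):
        samples = [f"s{i}" for i in range(5)]
        x = rn.ExpressionMatrix(["g1"], samples, np.ones((1, 5)))
        groups = rn.ModuleAssignment({"g1": 0})
        traits = _traits_from(samples, "t", [1.0, 1.0, 1.0, 1.0, 99.0])
        binning = bin_trait(traits, "t", (50,))
        with pytest.raises(ValueError, match="< 2 samples"):
            pct_significant_by_anova(x, groups, binning)


class TestPctDEG:
    def test_full_module_and_empty_set(self):
        groups = rn.ModuleAssignment({"a": 0, "b": 0, "c": 1, "d": 1})
        full = rn.GeneSet("degs", frozenset(["a", "b"]))
        assert pct_deg(groups, full) == {0: 100.0, 1: 0.0}
        assert pct_deg(groups, rn.GeneSet("none", frozenset())) == {0: 0.0, 1: 0.0}

    def test_hand_counted_percentages(self):
        labels = {f"a{i}": 0 for i in range(10)} | {f"b{i}": 1 for i in range(10)}
        degs = rn.GeneSet("degs", frozenset(["a0", "a1", "a2"]))
        assert pct_deg(rn.ModuleAssignment(labels), degs) == {0: 30.0, 1: 0.0}

    def test_size_weighted_sum_equals_global_percentage(self, small_cohort,
                                                        small_modules):
        _, dea, _, _ = small_cohort
        degs = rn.GeneSet("impact", frozenset(
            rn.label_impact(dea, 8.0).impact_set.genes))
        per = pct_deg(small_modules, degs)
        sizes = {m: len(small_modules.members(m))
                 for m in range(small_modules.n_modules)}
        total = sum(per[m] * sizes[m] for m in per) / sum(sizes.values())
        assert total == pytest.approx(100.0 * len(degs) / sum(sizes.values()))
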