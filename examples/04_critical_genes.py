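"""The core workflow: from expression to a critical-gene ranking.

Labels the top-8% |log2FC| genes as impact genes, trains the three
explainable classifiers on the embedding, selects each model's top
dimensions, ranks every gene by its count of impact genes nearby in
those subspaces, and checks whether the planted (non-differentially
expressed) regulator genes rise in the ranking.
"""

import numpy as np
from scipy import stats

import rnassist as rn
from rnassist import genefind, mlrank

cfg = rn.SynthConfig(n_genes=500, n_samples_per_group=50, n_modules=4,
                     n_deg=50, n_planted_regulators=15, n_deg_modules=1,
                     regulator_to_deg_cor=0.7,
                     trait_module_map={"audit": (0, 0.6)}, seed=4)
expr, dea, traits, truth = rn.generate(cfg)
tom = rn.build_tom(expr)
emb = rn.embed(tom, d=32, max_epoch=80, seed=7)

labeling = mlrank.label_impact(dea, percentile=8.0)
print(f"impact genes: {len(labeling.impact_set)} "
      f"(|log2FC| >= {labeling.threshold_log2fc:.3f})")

balanced = mlrank.balance_downsample(labeling, seed=7)
results = mlrank.train_models(emb, balanced, labeling, n_repeats=3, seed=7)
tops = []
for kind in mlrank.MODEL_KINDS:
    kind_res = [r for r in results if r.model_kind == kind]
    acc = np.mean([r.accuracy for r in kind_res])
    top = mlrank.select_top_dims(kind_res, cutoff=0.5)
    tops.append(top)
    print(f"  {kind:14s} accuracy {acc:.2f}, "
          f"{len(top.dims)} top dims hold "
          f"{top.cumulative_importance:.0%} of importance")

critical = genefind.critical_genes(emb, labeling.impact_set, tops)
eps, neighbors, exact = genefind.match_list_sizes(
    tom, labeling.impact_set, critical)
print(f"critical genes (count >= 1): {len(critical.positive_set())}")
print(f"size-matched neighbor genes at edge cutoff {eps:.3f}: "
      f"{len(neighbors.positive_set())}")

rank_of = {g: i + 1 for i, (g, _) in enumerate(critical.entries)}
reg_ranks = [rank_of[g] for g in truth.regulator_set.genes]
rng = np.random.default_rng(0)
pool = [g for g in dea.gene_ids if g not in truth.deg_set.genes
        and g not in truth.regulator_set.genes]
rand_ranks = [rank_of[g] for g in rng.choice(pool, len(reg_ranks), False)]
_, p = stats.mannwhitneyu(reg_ranks, rand_ranks, alternative="less")
print(f"planted regulators: mean rank {np.mean(reg_ranks):.0f} vs "
      f"{np.mean(rand_ranks):.0f} for random non-DEG genes "
      f"(one-sided Mann-Whitney p = {p:.3g})")
# The regulators were never differentially expressed, yet they rank ahead
# of random genes purely through their network proximity to the impact
# genes -- the hidden signal the method is built to surface.
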