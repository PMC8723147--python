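"""Synthetic cohorts with planted co-expression and regulator structure.

The generator emulates the statistical situation the critical-gene method
is designed for: block-structured co-expression (planted modules driven by
latent factors), differential expression with *small* effect sizes
(|log2FC| well under 0.4, as in post-mortem brain tissue), a handful of
planted "regulator" genes that are strongly co-expressed with the
differentially expressed genes but receive no mean shift themselves, and
sample traits generated from specific module factors.

Each gene is a noisy copy of its module's per-sample latent factor:

    x_gs = sqrt(rho) * f_{m(g), s} + sqrt(1 - rho) * eps_gs

which gives an expected within-module gene-gene correlation of ``rho``
(``within_module_cor``) and ~0 between modules.  Planted regulators load on
the factor of the first DEG-bearing module with loading
``regulator_to_deg_cor`` instead of ``sqrt(rho)``.  Values are on a log2
expression scale, so the case-group mean shift applied to DEG genes equals
the planted log2 fold change directly.

The differential-expression table is computed from the generated data by a
per-gene Welch t-test with Benjamini-Hochberg adjustment, standing in for
an upstream DESeq2/limma run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netio import DEATable, ExpressionMatrix, GeneSet, TraitTable

__all__ = ["SynthConfig", "SynthTruth", "generate", "generate_second_cohort"]


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort.

    Defaults are sized so a full network/embedding/ranking pass runs on a
    desktop in minutes while leaving the 8%-impact labeling meaningful.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 60
    n_modules: int = 8
    within_module_cor: float = 0.7
    n_deg: int = 120
    #: planted |log2FC| of case vs control for DEG genes (small on purpose)
    effect_size_log2fc: float = 0.3
    n_planted_regulators: int = 30
    #: correlation of regulator genes with the DEG module's latent factor
    regulator_to_deg_cor: float = 0.7
    #: number of modules the DEGs are planted in (the paper's data has DEG
    #: mass concentrated in very few modules)
    n_deg_modules: int = 2
    #: trait name -> (module index, target |correlation| with that factor)
    trait_module_map: dict = field(
        default_factory=lambda: {
            "audit": (0, 0.6),
            "drinks_per_day": (1, 0.6),
            "drinking_years": (2, 0.5),
        }
    )
    #: fraction of trait values dropped as missing
    trait_missing_frac: float = 0.05
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.within_module_cor < 1:
            raise ValueError("within_module_cor must be in (0, 1)")
        if not -1 < self.regulator_to_deg_cor < 1:
            raise ValueError("regulator_to_deg_cor must be in (-1, 1)")
        if self.n_deg + self.n_planted_regulators > self.n_genes:
            raise ValueError("n_deg + n_planted_regulators exceeds n_genes")
        if self.n_modules < 1 or self.n_genes < self.n_modules:
            raise ValueError("need at least one gene per module")
        if not 1 <= self.n_deg_modules <= self.n_modules:
            raise ValueError("n_deg_modules must be in [1, n_modules]")
        sizes = self._module_sizes()
        per_mod = self.n_deg // self.n_deg_modules
        if any(per_mod + (self.n_planted_regulators if m == 0 else 0) > sizes[m]
               for m in range(self.n_deg_modules)):
            raise ValueError(
                "DEGs/regulators do not fit in their modules; reduce n_deg "
                "or n_planted_regulators, or use more genes"
            )
        for t, (m, r) in self.trait_module_map.items():
            if not 0 <= m < self.n_modules:
                raise ValueError(f"trait {t!r} maps to nonexistent module {m}")
            if not -1 < r < 1:
                raise ValueError(f"trait {t!r} target correlation outside (-1, 1)")

    def _module_sizes(self) -> list[int]:
        base = self.n_genes // self.n_modules
        sizes = [base] * self.n_modules
        for i in range(self.n_genes - base * self.n_modules):
            sizes[i] += 1
        return sizes


@dataclass
class SynthTruth:
    """Ground truth of a generated cohort (for tests and benchmarks)."""

    module_of: dict[str, int]
    deg_set: GeneSet
    regulator_set: GeneSet
    trait_generating_modules: dict[str, tuple[int, float]]
    #: per-gene loading on its module factor (regulators load on module 0)
    loadings: dict[str, float]
    config: SynthConfig

    def __post_init__(self) -> None:
        if self.deg_set.genes & self.regulator_set.genes:
            raise ValueError("planted regulators must not be planted DEGs")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def _draw_expression(
    cfg: SynthConfig,
    rng: np.random.Generator,
    n_samples: int,
    module_of_idx: np.ndarray,
    loadings: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-factor draw; returns (genes x samples values, factors)."""
    factors = rng.standard_normal((cfg.n_modules, n_samples))
    noise = rng.standard_normal((cfg.n_genes, n_samples))
    lam = loadings[:, None]
    x = lam * factors[module_of_idx] + np.sqrt(1.0 - lam**2) * noise * cfg.noise_sd
    return x, factors


def _welch_bh(x: np.ndarray, is_case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene Welch t-test (case vs control) with BH adjustment."""
    case, ctrl = x[:, is_case], x[:, ~is_case]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = stats.false_discovery_control(p, method="bh")
    return log2fc, padj


def generate(
    cfg: SynthConfig,
) -> tuple[ExpressionMatrix, DEATable, TraitTable, SynthTruth]:
    """Generate one case/control cohort with planted structure.

    Returns the expression matrix, the Welch-t + BH differential-expression
    table computed from it, a trait table whose traits track the mapped
    module factors, and the ground truth of the planting.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_ids(cfg.n_genes)
    sizes = cfg._module_sizes()
    module_of_idx = np.repeat(np.arange(cfg.n_modules), sizes)

    # regulators occupy the first slots of module 0 and get a custom loading;
    # DEGs are spread over the first n_deg_modules modules, after regulators
    loadings = np.full(cfg.n_genes, np.sqrt(cfg.within_module_cor))
    reg_idx = np.arange(cfg.n_planted_regulators)
    loadings[reg_idx] = cfg.regulator_to_deg_cor
    module_starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    deg_idx = []
    per_mod = [cfg.n_deg // cfg.n_deg_modules] * cfg.n_deg_modules
    per_mod[0] += cfg.n_deg - sum(per_mod)
    for m in range(cfg.n_deg_modules):
        start = module_starts[m] + (cfg.n_planted_regulators if m == 0 else 0)
        deg_idx.extend(range(start, start + per_mod[m]))
    deg_idx = np.array(deg_idx, dtype=int)

    n_samples = 2 * cfg.n_samples_per_group
    samples = [f"s{i:03d}" for i in range(n_samples)]
    is_case = np.zeros(n_samples, dtype=bool)
    is_case[cfg.n_samples_per_group:] = True

    x, factors = _draw_expression(cfg, rng, n_samples, module_of_idx, loadings)
    shift_sign = rng.choice([-1.0, 1.0], size=len(deg_idx))
    x[deg_idx] += np.outer(shift_sign * cfg.effect_size_log2fc, is_case.astype(float))

    log2fc, padj = _welch_bh(x, is_case)

    # traits follow the mapped module factor at the target correlation,
    # rescaled to a loosely AUDIT-like positive range
    rows = []
    for trait, (m, r) in cfg.trait_module_map.items():
        f = (factors[m] - factors[m].mean()) / factors[m].std()
        vals = r * f + np.sqrt(1.0 - r**2) * rng.standard_normal(n_samples)
        vals = 50.0 + 20.0 * vals
        keep = rng.random(n_samples) >= cfg.trait_missing_frac
        rows.append(pd.DataFrame(
            {"sample_id": np.array(samples)[keep], "trait_name": trait,
             "value": vals[keep]}
        ))
    traits = TraitTable(pd.concat(rows, ignore_index=True))

    truth = SynthTruth(
        module_of={genes[i]: int(module_of_idx[i]) for i in range(cfg.n_genes)},
        deg_set=GeneSet("planted DEGs", frozenset(genes[i] for i in deg_idx)),
        regulator_set=GeneSet(
            "planted regulators", frozenset(genes[i] for i in reg_idx)
        ),
        trait_generating_modules=dict(cfg.trait_module_map),
        loadings={genes[i]: float(loadings[i]) for i in range(cfg.n_genes)},
        config=cfg,
    )
    expr = ExpressionMatrix(genes, samples, x)
    dea = DEATable(genes, log2fc, padj)
    return expr, dea, traits, truth


def generate_second_cohort(
    cfg: SynthConfig, truth: SynthTruth, n_samples: int | None = None,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Fresh samples from the same module/factor model, no case shift.

    Emulates an independent replication cohort (e.g. a general-population
    brain expression resource) that shares the co-expression architecture
    of the discovery cohort but none of its samples or disease contrast.
    """
    cfg.validate()
    if n_samples is None:
        n_samples = 2 * cfg.n_samples_per_group
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 104729)
    genes = sorted(truth.module_of)
    module_of_idx = np.array([truth.module_of[g] for g in genes])
    loadings = np.array([truth.loadings[g] for g in genes])
    x, _ = _draw_expression(cfg, rng, n_samples, module_of_idx, loadings)
    samples = [f"r{i:03d}" for i in range(n_samples)]
    return ExpressionMatrix(genes, samples, x)
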