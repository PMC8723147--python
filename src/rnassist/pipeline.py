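"""End-to-end run orchestration.

A run executes the full workflow: ingest and align the inputs, build the
TOM if only expression was given, detect Louvain modules, embed the
network, check that the embedding preserves the network's structure
(advisory quality gate), train the classifiers and select top dimensions,
rank critical genes, derive a size-matched neighbor-gene baseline, and
compute the validation statistics.  Every artifact lands in a directory
named by a hash of the configuration, together with a config snapshot and
a structured JSON log, so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import embedding as emb
from . import genefind, mlrank, network, validate
from .netio import (
    DEATable,
    ExpressionMatrix,
    GeneSet,
    TOMNetwork,
    TraitTable,
    align_universe,
    read_dea,
    read_expression,
    read_gene_list,
    read_tom,
    read_traits,
    write_gene_list,
    write_ranking,
    write_tom,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclass
class RunConfig:
    """All inputs and knobs of a pipeline run.

    Every stochastic stage has its own explicit seed; a config missing a
    seed fails validation before any compute.
    """

    expression: str | None = None
    dea: str | None = None
    traits: str | None = None
    tom: str | None = None  # precomputed network; built from expression if absent
    tom_format: str = "dense"
    regulators: str | None = None  # optional external gene list for overlap
    out_dir: str = "rnassist_run"

    beta: float = 6.0
    resolution: float = 1.0
    dims: int = 64
    max_epoch: int = 100
    learning_rate: float = 0.1
    negative_ratio: float = 0.15
    samples_per_node: int = 75
    impact_percentile: float = 8.0
    n_repeats: int = 3
    split_frac: float = 0.8
    importance_cutoff: float = 0.5
    sigma: float | None = None
    sigma_percentile: float | None = 5.0
    deg_alpha: float = 0.05
    anova_alpha: float = 0.05
    n_trait_classes: int = 4
    top_n_cor: int = 50

    louvain_seed: int | None = 7
    embed_seed: int | None = 7
    ml_seed: int | None = 7
    balance_seed: int | None = 7

    def validate(self) -> None:
        if self.dea is None:
            raise ValueError("config requires a differential-expression table")
        if self.tom is None and self.expression is None:
            raise ValueError("config needs a TOM or expression to build one from")
        for name in ("louvain_seed", "embed_seed", "ml_seed", "balance_seed"):
            if getattr(self, name) is None:
                raise ValueError(f"config missing required seed {name!r}")

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    run_dir: Path
    critical: "genefind.GeneRanking"
    neighbors: "genefind.GeneRanking"
    qc: dict
    validation: dict
    log: list = field(default_factory=list)


def _load_inputs(cfg: RunConfig):
    dea = read_dea(cfg.dea)
    expr = read_expression(cfg.expression) if cfg.expression else None
    traits = read_traits(cfg.traits) if cfg.traits else None
    tom = read_tom(cfg.tom, format=cfg.tom_format) if cfg.tom else None
    return expr, dea, traits, tom


def run_pipeline(
    cfg: RunConfig,
    *,
    expr: ExpressionMatrix | None = None,
    dea: DEATable | None = None,
    traits: TraitTable | None = None,
    tom: TOMNetwork | None = None,
) -> PipelineResult:
    """Execute the full workflow and write all artifacts.

    Inputs may be passed as in-memory objects (library use) or read from
    the paths in *cfg*.  Returns the rankings, the embedding-quality
    report, and the validation report.
    """
    cfg.validate()
    if dea is None:
        expr, dea, traits, tom = _load_inputs(cfg)
    run_dir = Path(cfg.out_dir) / f"run_{cfg.config_hash}"
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(cfg.to_yaml())
    log: list[dict] = []

    def _log(stage: str, **info) -> None:
        log.append({"stage": stage, "time": time.time(), **info})

    def _stage(stage: str, fn):
        try:
            out = fn()
        except Exception as err:  # annotate failures with the stage name
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        _log(stage)
        return out

    # -- ingest + align -----------------------------------------------------
    objs = [dea] + [o for o in (expr, tom) if o is not None]
    aligned, drop_report = _stage("align", lambda: align_universe(objs))
    dea = aligned[0]
    pos = 1
    if expr is not None:
        expr = aligned[pos]
        pos += 1
    if tom is not None:
        tom = aligned[pos]
    _log("align_report", dropped={str(k): len(v) for k, v in drop_report.items()})

    if tom is None:
        tom = _stage("build_tom", lambda: network.build_tom(expr, beta=cfg.beta))
        write_tom(run_dir / "tom.tsv", tom)

    # -- modules + embedding ------------------------------------------------
    modules = _stage(
        "louvain",
        lambda: network.louvain_modules(tom, cfg.resolution, seed=cfg.louvain_seed),
    )
    e = _stage(
        "embed",
        lambda: emb.embed(
            tom, d=cfg.dims, max_epoch=cfg.max_epoch,
            learning_rate=cfg.learning_rate, negative_ratio=cfg.negative_ratio,
            seed=cfg.embed_seed, samples_per_node=cfg.samples_per_node,
        ),
    )
    clusters = _stage(
        "kmeans", lambda: emb.kmeans_clusters(e, modules.n_modules, seed=cfg.embed_seed)
    )

    # -- embedding QC (advisory) -------------------------------------------
    degs = dea.deg_set(cfg.deg_alpha)
    qc = _stage("qc", lambda: embedding_qc(
        expr, traits, dea, tom, modules, clusters, cfg
    ))
    if not qc.get("qc_pass", True):
        _log("qc_warning", message="embedding QC failed; continuing (advisory gate)")

    # -- ML + rankings ------------------------------------------------------
    labeling = _stage("label_impact",
                      lambda: mlrank.label_impact(dea, cfg.impact_percentile))
    balanced = _stage("balance",
                      lambda: mlrank.balance_downsample(labeling, seed=cfg.balance_seed))
    results = _stage("train", lambda: mlrank.train_models(
        e, balanced, labeling, cfg.split_frac, cfg.n_repeats, seed=cfg.ml_seed
    ))
    tops = [
        mlrank.select_top_dims([r for r in results if r.model_kind == kind],
                               cfg.importance_cutoff)
        for kind in mlrank.MODEL_KINDS
    ]
    params = genefind.ProximityParams(sigma=cfg.sigma,
                                      sigma_percentile=cfg.sigma_percentile)
    critical = _stage("critical", lambda: genefind.critical_genes(
        e, labeling.impact_set, tops, params
    ))
    eps, neighbors, exact = _stage("neighbors", lambda: genefind.match_list_sizes(
        tom, labeling.impact_set, critical
    ))
    _log("neighbor_epsilon", epsilon=eps, exact_size_match=exact)

    write_ranking(run_dir / "critical.tsv", critical)
    write_ranking(run_dir / "neighbors.tsv", neighbors)
    write_gene_list(run_dir / "impact_genes.txt", labeling.impact_set)
    write_gene_list(run_dir / "degs.txt", degs)

    # -- validation ---------------------------------------------------------
    regulators = read_gene_list(cfg.regulators) if cfg.regulators else None
    validation = _stage("validate", lambda: validation_report(
        expr, traits, dea, critical, neighbors, degs, regulators, cfg
    ))

    accs = {}
    for kind in mlrank.MODEL_KINDS:
        kind_res = [r.accuracy for r in results if r.model_kind == kind]
        accs[kind] = {"mean": float(np.mean(kind_res)), "sd": float(np.std(kind_res))}
    report = {
        "config_hash": cfg.config_hash,
        "n_genes": len(dea.gene_ids),
        "n_modules": modules.n_modules,
        "model_accuracy": accs,
        "top_dimensions": {t.model_kind: t.dims for t in tops},
        "impact_threshold_log2fc": labeling.threshold_log2fc,
        "n_critical": len(critical.positive_set()),
        "n_neighbor": len(neighbors.positive_set()),
        "neighbor_epsilon": eps,
        "qc": qc,
        "validation": validation,
    }
    (run_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    (run_dir / "log.jsonl").write_text("\n".join(json.dumps(l) for l in log))
    return PipelineResult(run_dir, critical, neighbors, qc, validation, log)


def embedding_qc(
    expr: ExpressionMatrix | None,
    traits: TraitTable | None,
    dea: DEATable,
    tom: TOMNetwork,
    modules: "network.ModuleAssignment",
    clusters: "emb.ClusterAssignment",
    cfg: RunConfig,
) -> dict:
    """Does the embedding preserve the network's biological structure?

    Three checks: (i) DEG mass should concentrate in few clusters, as it
    does in few modules; (ii) per-group %ANOVA-significant genes should
    not differ between modules and clusters (Welch t per trait); (iii)
    per-group eigengene-trait |r| should not differ either.  The overall
    flag is advisory.
    """
    degs = dea.deg_set(cfg.deg_alpha)
    out: dict = {}
    pd_mod = network.pct_deg(modules, degs)
    pd_clu = network.pct_deg(clusters, degs)
    out["pct_deg_modules"] = pd_mod
    out["pct_deg_clusters"] = pd_clu
    if degs.genes:
        def _top3_mass(groups) -> float:
            sizes = {m: len(groups.members(m)) for m in range(groups.n_modules)}
            per = network.pct_deg(groups, degs)
            counts = sorted((per[m] * sizes[m] / 100.0 for m in per), reverse=True)
            return float(sum(counts[:3]) / len(degs))
        out["deg_mass_top3_modules"] = _top3_mass(modules)
        out["deg_mass_top3_clusters"] = _top3_mass(clusters)

    trait_ps: dict[str, dict[str, float]] = {}
    if expr is not None and traits is not None:
        shared = [s for s in expr.sample_ids]
        for trait in traits.trait_names:
            v = traits.values_for(trait, shared)
            vv = v[~np.isnan(v)]
            if len(vv) < 8:
                continue
            qs = np.quantile(vv, np.linspace(0, 1, cfg.n_trait_classes + 1)[1:-1])
            edges = sorted(set(np.round(qs, 10)))
            if len(edges) < 1:
                continue
            binning = network.bin_trait(traits, trait, edges)
            entry: dict[str, float] = {}
            try:
                ps_mod = network.pct_significant_by_anova(
                    expr, modules, binning, cfg.anova_alpha)
                ps_clu = network.pct_significant_by_anova(
                    expr, clusters, binning, cfg.anova_alpha)
                _, p = emb.compare_module_cluster_stats(
                    list(ps_mod.values()), list(ps_clu.values()))
                entry["anova_pct_p"] = p
            except ValueError:
                pass
            rs_mod = _group_trait_abs_r(expr, traits, modules, trait)
            rs_clu = _group_trait_abs_r(expr, traits, clusters, trait)
            if len(rs_mod) >= 2 and len(rs_clu) >= 2:
                _, p = emb.compare_module_cluster_stats(rs_mod, rs_clu)
                entry["eigengene_r_p"] = p
            if entry:
                trait_ps[trait] = entry
    out["trait_tests"] = trait_ps
    ps = [p for d in trait_ps.values() for p in d.values()]
    out["qc_pass"] = bool(all(p > 0.05 for p in ps)) if ps else True
    return out


def _group_trait_abs_r(expr, traits, groups, trait) -> list[float]:
    vals = []
    for m in range(groups.n_modules):
        members = groups.members(m)
        if len(members) < 2:
            continue
        eg = network.eigengene(expr, members, module=m)
        r, _ = network.module_trait_cor(eg, traits).get(trait, (np.nan, np.nan))
        if not np.isnan(r):
            vals.append(abs(float(r)))
    return vals


def validation_report(
    expr: ExpressionMatrix | None,
    traits: TraitTable | None,
    dea: DEATable,
    critical: "genefind.GeneRanking",
    neighbors: "genefind.GeneRanking",
    degs: GeneSet,
    regulators: GeneSet | None,
    cfg: RunConfig,
) -> dict:
    """Overlap and correlation statistics for the final gene lists."""
    universe = GeneSet("universe", frozenset(dea.gene_ids))
    crit = critical.positive_set("critical genes")
    neigh = neighbors.positive_set("neighbor genes")
    out: dict = {
        "n_critical": len(crit),
        "n_neighbor": len(neigh),
        "n_critical_and_neighbor": len(crit.genes & neigh.genes),
        "n_critical_deg": len(crit.genes & degs.genes),
        "n_critical_non_deg": len(crit.genes - degs.genes),
    }
    if len(crit):
        out["pct_critical_non_deg"] = 100.0 * out["n_critical_non_deg"] / len(crit)
    if crit.genes and neigh.genes:
        ov = validate.overlap_test(crit, neigh, universe)
        out["critical_vs_neighbor_overlap_p"] = ov.p_value
    if regulators is not None:
        reg = GeneSet("regulators", regulators.genes & universe.genes)
        for name, s in (("critical", crit), ("neighbor", neigh)):
            if s.genes:
                ov = validate.overlap_test(s, reg, universe)
                out[f"{name}_vs_regulator_overlap"] = {
                    "k": ov.k, "p": ov.p_value, "genes": ov.overlap
                }
    if expr is not None and traits is not None and degs.genes and crit.genes:
        lists = {"DEG": degs, "critical": crit, "neighbor": neigh}
        abs_cors = {}
        for name, s in lists.items():
            if not s.genes:
                continue
            r = validate.gene_trait_cor(expr, s, traits)
            abs_cors[name] = np.abs(r.to_numpy(float)).ravel()
        abs_cors = {k: v[~np.isnan(v)] for k, v in abs_cors.items()}
        abs_cors = {k: v for k, v in abs_cors.items() if len(v) >= 3}
        if len(abs_cors) >= 2:
            cmpres = validate.compare_gene_lists_cor(abs_cors)
            out["trait_cor_comparison"] = {
                "test": cmpres.test,
                "statistic": cmpres.statistic,
                "p": cmpres.p_value,
                "mean_abs_r": {k: float(v.mean()) for k, v in cmpres.abs_cors.items()},
            }
    return out
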