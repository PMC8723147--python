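"""Impact labeling, explainable classifiers and dimension selection.

Genes whose |log2 fold change| falls in the top ``percentile`` percent
(default 8%) of the differential-expression table are labeled *impact*;
the rest are non-impact.  After downsampling the non-impact class to
balance, three explainable classifiers -- logistic regression, random
forest and gradient-boosted trees (XGBoost) -- are trained to predict the
label from the embedding coordinates.  Per-dimension importances
(|coefficients| on standardized coordinates for the linear model,
impurity-based importances for the tree ensembles) are normalized to sum
to one, averaged over repeats, and the minimal prefix of dimensions whose
cumulative importance reaches 50% becomes the model's "top dimensions" --
the subspace in which critical genes are later found.  A retrain on the
top dimensions alone checks how much of the accuracy that subspace keeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .embedding import EmbeddingMatrix
from .netio import DEATable, GeneSet

__all__ = [
    "MODEL_KINDS",
    "ImpactLabeling",
    "ModelResult",
    "TopDimensions",
    "label_impact",
    "balance_downsample",
    "train_models",
    "select_top_dims",
    "retrain_on_top_dims",
]

MODEL_KINDS = ("logistic", "random_forest", "xgboost")


@dataclass
class ImpactLabeling:
    """Impact / non-impact label per gene with the |log2FC| threshold used."""

    labels: dict[str, bool]  # True = impact
    threshold_log2fc: float
    percentile: float

    @property
    def impact_set(self) -> GeneSet:
        return GeneSet("impact genes", frozenset(g for g, v in self.labels.items() if v))

    @property
    def non_impact_set(self) -> GeneSet:
        return GeneSet("non-impact genes",
                       frozenset(g for g, v in self.labels.items() if not v))


@dataclass
class ModelResult:
    model_kind: str
    accuracy: float
    importance: np.ndarray  # length d, nonnegative, sums to 1
    repeat_index: int
    seed: int

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if np.any(self.importance < -1e-12):
            raise ValueError("negative importance")
        s = self.importance.sum()
        if not np.isclose(s, 1.0, atol=1e-6):
            raise ValueError(f"importance must sum to 1, got {s}")


@dataclass
class TopDimensions:
    """Minimal importance-ranked dimension prefix reaching the cutoff."""

    model_kind: str
    dims: list[int]
    cumulative_importance: float
    cutoff: float = 0.5


def label_impact(dea: DEATable, percentile: float = 8.0) -> ImpactLabeling:
    """Label the top *percentile* percent of |log2FC| as impact genes.

    The threshold is the (100 - percentile)-th percentile of |log2FC|;
    genes tied exactly at the threshold are all included, so the impact
    set may slightly exceed the nominal fraction.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    afc = np.abs(dea.log2fc)
    if np.all(afc == afc[0]):
        raise ValueError("all |log2fc| identical; impact labeling is undefined")
    thr = float(np.percentile(afc, 100.0 - percentile))
    labels = {g: bool(a >= thr) for g, a in zip(dea.gene_ids, afc)}
    return ImpactLabeling(labels, thr, percentile)


def balance_downsample(labels: ImpactLabeling, seed: int = 0) -> list[str]:
    """Uniformly downsample non-impact genes to the impact-class size.

    Returns the union (impact genes + sampled non-impact genes), sorted,
    reproducible from *seed*.
    """
    impact = labels.impact_set.sorted()
    non_impact = labels.non_impact_set.sorted()
    if not impact or not non_impact:
        raise ValueError("both classes must be non-empty")
    if len(non_impact) < len(impact):
        raise ValueError("fewer non-impact than impact genes; cannot balance")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(len(non_impact), size=len(impact), replace=False)
    return sorted(impact + [non_impact[i] for i in sampled])


def _make_model(kind: str, seed: int):
    if kind == "logistic":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if kind == "xgboost":
        return XGBClassifier(random_state=seed, verbosity=0,
                             eval_metric="logloss", n_jobs=1)
    raise ValueError(f"unknown model kind {kind!r}")


def _importance(kind: str, model, scaler_used: bool) -> np.ndarray:
    if kind == "logistic":
        imp = np.abs(model.coef_[0])
    else:
        imp = np.asarray(model.feature_importances_, dtype=float)
    s = imp.sum()
    if s <= 0:  # constant model; spread evenly
        return np.full(imp.shape, 1.0 / len(imp))
    return imp / s


def _fit_one(
    kind: str, X: np.ndarray, y: np.ndarray, split_frac: float, seed: int
) -> tuple[float, np.ndarray]:
    for attempt in range(10):
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, train_size=split_frac, stratify=y, random_state=seed + attempt
        )
        if len(np.unique(yte)) == 2 and len(np.unique(ytr)) == 2:
            break
    else:
        raise ValueError("could not produce a two-class test fold")
    scaler_used = kind == "logistic"
    if scaler_used:
        sc = StandardScaler().fit(Xtr)
        Xtr, Xte = sc.transform(Xtr), sc.transform(Xte)
    model = _make_model(kind, seed)
    model.fit(Xtr, ytr)
    acc = float(model.score(Xte, yte))
    return acc, _importance(kind, model, scaler_used)


def train_models(
    e: EmbeddingMatrix,
    balanced: list[str],
    labels: ImpactLabeling,
    split_frac: float = 0.8,
    n_repeats: int = 3,
    seed: int = 0,
    model_kinds: tuple[str, ...] = MODEL_KINDS,
) -> list[ModelResult]:
    """Train each model kind *n_repeats* times on an 80/20 stratified split.

    Returns one :class:`ModelResult` (accuracy + normalized importance)
    per (model kind, repeat).
    """
    gidx = {g: i for i, g in enumerate(e.gene_ids)}
    missing = [g for g in balanced if g not in gidx]
    if missing:
        raise ValueError(f"balanced genes absent from embedding: {missing[:5]}")
    X = e.coords[[gidx[g] for g in balanced]]
    y = np.array([labels.labels[g] for g in balanced], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("balanced gene list must contain both classes")
    results = []
    for kind in model_kinds:
        for rep in range(n_repeats):
            rep_seed = seed + 1000 * MODEL_KINDS.index(kind) + rep
            acc, imp = _fit_one(kind, X, y, split_frac, rep_seed)
            results.append(ModelResult(kind, acc, imp, rep, rep_seed))
    return results


def select_top_dims(results: list[ModelResult], cutoff: float = 0.5) -> TopDimensions:
    """Minimal descending-importance prefix with cumulative importance >= cutoff.

    Importances are first averaged over the given repeats (all results must
    share one model kind).  Ties in importance are broken by dimension
    index for determinism.
    """
    kinds = {r.model_kind for r in results}
    if len(kinds) != 1:
        raise ValueError(f"results must be a single model kind, got {sorted(kinds)}")
    imp = np.mean([r.importance for r in results], axis=0)
    order = np.lexsort((np.arange(len(imp)), -imp))
    csum = np.cumsum(imp[order])
    n_keep = int(np.searchsorted(csum, cutoff - 1e-12) + 1)
    n_keep = min(n_keep, len(imp))
    dims = [int(i) for i in order[:n_keep]]
    return TopDimensions(kinds.pop(), dims, float(csum[n_keep - 1]), cutoff)


def retrain_on_top_dims(
    e: EmbeddingMatrix,
    balanced: list[str],
    labels: ImpactLabeling,
    top: TopDimensions,
    split_frac: float = 0.8,
    n_repeats: int = 3,
    seed: int = 0,
) -> float:
    """Accuracy ratio (top-dimension model / full-dimension model).

    Trains the same model kind with the same protocol on the full
    embedding and on the top-dimension subspace; returns the ratio of the
    mean accuracies.  A ratio near 1 means the selected subspace carries
    the information the classifier used.
    """
    if not top.dims:
        raise ValueError("empty top-dimension set")
    full = train_models(e, balanced, labels, split_frac, n_repeats, seed,
                        model_kinds=(top.model_kind,))
    sub = EmbeddingMatrix(list(e.gene_ids), e.coords[:, top.dims])
    restricted = train_models(sub, balanced, labels, split_frac, n_repeats, seed,
                              model_kinds=(top.model_kind,))
    full_acc = float(np.mean([r.accuracy for r in full]))
    sub_acc = float(np.mean([r.accuracy for r in restricted]))
    if full_acc == 0:
        raise ValueError("full-model accuracy is zero")
    return sub_acc / full_acc
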