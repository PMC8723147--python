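"""Data model, file I/O and identifier alignment.

All downstream stages operate on the small set of containers defined here:
an expression matrix (genes x samples), a differential-expression table
(log2 fold change + adjusted p-value per gene), a topological-overlap
network (symmetric weighted adjacency in [0, 1]), a long-form sample trait
table, and named gene sets.  Files are plain TSV/CSV; floats are written
with 10 significant digits so that read(write(x)) round-trips.

The canonical gene order everywhere in this package is lexicographic by
gene id; :func:`align_universe` restricts a collection of objects to their
shared gene universe in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DEATable",
    "TOMNetwork",
    "TraitTable",
    "GeneSet",
    "GeneRanking",
    "read_expression",
    "write_expression",
    "read_dea",
    "write_dea",
    "read_tom",
    "write_tom",
    "read_traits",
    "write_traits",
    "read_gene_list",
    "write_gene_list",
    "write_ranking",
    "read_ranking",
    "align_universe",
]

#: symmetry tolerance for dense TOM input
TOM_SYM_TOL = 1e-10
#: floats are serialized with this many significant digits
FLOAT_FMT = "%.10g"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen[i] = 1
    if dups:
        raise ValueError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with aligned identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def restrict(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class DEATable:
    """Per-gene differential-expression summary (log2FC, adjusted p)."""

    gene_ids: list[str]
    log2fc: np.ndarray
    padj: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.padj = np.asarray(self.padj, dtype=float)
        _check_unique(self.gene_ids, "gene ids")
        n = len(self.gene_ids)
        if self.log2fc.shape != (n,) or self.padj.shape != (n,):
            raise ValueError("log2fc/padj length does not match gene ids")
        if not np.all(np.isfinite(self.log2fc)):
            raise ValueError("non-finite log2fc")
        # missing adjusted p-values are conservatively treated as 1 (never a DEG)
        self.padj = np.where(np.isnan(self.padj), 1.0, self.padj)
        if np.any((self.padj < 0) | (self.padj > 1)):
            raise ValueError("padj outside [0, 1]")

    def deg_set(self, alpha: float = 0.05, name: str = "DEGs") -> "GeneSet":
        """Genes with adjusted p-value < *alpha*."""
        genes = [g for g, p in zip(self.gene_ids, self.padj) if p < alpha]
        return GeneSet(name, frozenset(genes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "log2fc": self.log2fc, "padj": self.padj}
        )

    def restrict(self, genes: Sequence[str]) -> "DEATable":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in genes]
        return DEATable(list(genes), self.log2fc[rows], self.padj[rows])


@dataclass
class TOMNetwork:
    """Symmetric weighted adjacency in [0, 1] with unit diagonal."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(map(str, self.gene_ids))
        self.weights = np.asarray(self.weights, dtype=float)
        _check_unique(self.gene_ids, "gene ids")
        n = len(self.gene_ids)
        if self.weights.shape != (n, n):
            raise ValueError(f"weight matrix shape {self.weights.shape} != ({n}, {n})")
        asym = np.abs(self.weights - self.weights.T).max() if n else 0.0
        if asym > TOM_SYM_TOL:
            raise ValueError(f"adjacency asymmetric: max |T - T'| = {asym:g}")
        self.weights = (self.weights + self.weights.T) / 2.0
        if n and not np.allclose(np.diag(self.weights), 1.0, atol=1e-8):
            raise ValueError("diagonal must be 1")
        np.fill_diagonal(self.weights, 1.0)
        lo, hi = self.weights.min(initial=1.0), self.weights.max(initial=0.0)
        if lo < 0.0 or hi > 1.0 + 1e-12:
            raise ValueError(f"weights outside [0, 1]: range [{lo:g}, {hi:g}]")
        np.clip(self.weights, 0.0, 1.0, out=self.weights)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def restrict(self, genes: Sequence[str]) -> "TOMNetwork":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([idx[g] for g in genes], dtype=int)
        return TOMNetwork(list(genes), self.weights[np.ix_(rows, rows)])


@dataclass
class TraitTable:
    """Long-form sample traits: one (sample, trait, value) row each.

    Missing values are simply absent rows; a wide samples x traits view
    with NaN for missing entries is available via :meth:`pivot`.
    """

    data: pd.DataFrame  # columns sample_id, trait_name, value

    def __post_init__(self) -> None:
        req = ["sample_id", "trait_name", "value"]
        if list(self.data.columns[:3]) != req:
            raise ValueError(f"trait table needs columns {req}")
        self.data = self.data.dropna(subset=["value"]).reset_index(drop=True)
        self.data["sample_id"] = self.data["sample_id"].astype(str)
        self.data["trait_name"] = self.data["trait_name"].astype(str)
        self.data["value"] = self.data["value"].astype(float)
        if self.data.duplicated(["sample_id", "trait_name"]).any():
            dup = self.data[self.data.duplicated(["sample_id", "trait_name"])]
            raise ValueError(
                "duplicate (sample, trait) pairs: "
                f"{dup[['sample_id', 'trait_name']].values.tolist()[:5]}"
            )

    @property
    def trait_names(self) -> list[str]:
        return sorted(self.data["trait_name"].unique())

    def pivot(self) -> pd.DataFrame:
        """Samples x traits wide table, NaN for missing values."""
        return self.data.pivot(index="sample_id", columns="trait_name", values="value")

    def values_for(self, trait_name: str, sample_ids: Sequence[str]) -> np.ndarray:
        """Trait values aligned to *sample_ids* (NaN where missing)."""
        sub = self.data[self.data["trait_name"] == trait_name]
        m = dict(zip(sub["sample_id"], sub["value"]))
        return np.array([m.get(s, np.nan) for s in sample_ids], dtype=float)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(map(str, self.genes)))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: str) -> bool:
        return g in self.genes

    def sorted(self) -> list[str]:
        return sorted(self.genes)

    def restrict(self, genes: Sequence[str]) -> "GeneSet":
        return GeneSet(self.name, self.genes & set(genes))


@dataclass
class GeneRanking:
    """Genes ordered by their count of nearby impact genes.

    Counts are non-increasing down the list; ties are broken
    lexicographically by gene id.  Every gene of the analysis universe is
    present, possibly with count 0.
    """

    entries: list[tuple[str, int]]
    kind: str = "critical"  # "critical" | "neighbor"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = [(str(g), int(c)) for g, c in self.entries]
        _check_unique([g for g, _ in self.entries], "ranked gene ids")
        counts = [c for _, c in self.entries]
        if any(c < 0 for c in counts):
            raise ValueError("negative count")
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("counts must be non-increasing")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def positive_set(self, name: str | None = None) -> GeneSet:
        """Genes with count >= 1 (the reported critical/neighbor list)."""
        return GeneSet(
            name or f"{self.kind} genes",
            frozenset(g for g, c in self.entries if c >= 1),
        )

    def top(self, n: int) -> list[str]:
        return [g for g, _ in self.entries[:n]]

    def counts_by_gene(self) -> dict[str, int]:
        return dict(self.entries)


# ---------------------------------------------------------------------------
# file readers / writers


def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return "," if str(path).endswith(".csv") else "\t"


def _read_numeric_table(path: str | Path, sep: str, index_col: int = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=index_col, dtype=str)
    df.index = df.index.astype(str)
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    return out


def read_expression(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a genes x samples table (first column gene ids, header samples)."""
    df = _read_numeric_table(path, _sep_for(path, dialect))
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(float))


def write_expression(path: str | Path, x: ExpressionMatrix, dialect: str | None = None) -> None:
    x.to_frame().to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FMT,
                        index_label="gene_id")


def read_dea(path: str | Path, dialect: str | None = None) -> DEATable:
    """Read a differential-expression table with columns gene_id, log2fc, padj."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("gene_id", "log2fc", "padj") if c not in cols]
    if missing:
        raise ValueError(f"DEA table missing columns {missing}; has {list(df.columns)}")
    return DEATable(
        list(df[cols["gene_id"]].astype(str)),
        df[cols["log2fc"]].to_numpy(float),
        df[cols["padj"]].to_numpy(float),
    )


def write_dea(path: str | Path, dea: DEATable, dialect: str | None = None) -> None:
    dea.to_frame().to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FMT,
                          index=False)


def read_tom(
    path: str | Path,
    format: str = "dense",
    gene_ids: Sequence[str] | None = None,
    dialect: str | None = None,
) -> TOMNetwork:
    """Read a TOM as a dense matrix or a 3-column edge triplet file.

    Triplet files store each undirected edge once (gene_a, gene_b, weight);
    the matrix is symmetrized by construction, missing edges are 0 and the
    diagonal is 1.  *gene_ids* fixes the universe for triplet input (defaults
    to the ids appearing in the file, in lexicographic order).
    """
    sep = _sep_for(path, dialect)
    if format == "dense":
        df = _read_numeric_table(path, sep)
        if list(df.index) != list(df.columns):
            raise ValueError("dense TOM row and column ids differ")
        return TOMNetwork(list(df.index), df.to_numpy(float))
    if format != "triplet":
        raise ValueError(f"unknown TOM format {format!r}")
    df = pd.read_csv(path, sep=sep, header=None, comment="#",
                     names=["a", "b", "w"], dtype={"a": str, "b": str})
    # tolerate a header row
    first = df.iloc[0]["w"] if len(df) else None
    if first is not None and pd.isna(pd.to_numeric(pd.Series([first]), errors="coerce")[0]):
        df = df.iloc[1:].reset_index(drop=True)
    w = pd.to_numeric(df["w"], errors="coerce")
    if w.isna().any():
        raise ValueError("non-numeric weight in triplet TOM")
    if ((w < 0) | (w > 1)).any():
        raise ValueError("triplet weight outside [0, 1]")
    ids = sorted(set(df["a"]) | set(df["b"])) if gene_ids is None else list(gene_ids)
    idx = {g: i for i, g in enumerate(ids)}
    unknown = (set(df["a"]) | set(df["b"])) - set(ids)
    if unknown:
        raise ValueError(f"triplet gene ids outside universe: {sorted(unknown)[:5]}")
    t = np.zeros((len(ids), len(ids)))
    ia = df["a"].map(idx).to_numpy(int)
    ib = df["b"].map(idx).to_numpy(int)
    t[ia, ib] = w.to_numpy(float)
    t[ib, ia] = w.to_numpy(float)
    np.fill_diagonal(t, 1.0)
    return TOMNetwork(ids, t)


def write_tom(path: str | Path, t: TOMNetwork, format: str = "dense",
              dialect: str | None = None) -> None:
    sep = _sep_for(path, dialect)
    if format == "dense":
        pd.DataFrame(t.weights, index=t.gene_ids, columns=t.gene_ids).to_csv(
            path, sep=sep, float_format=FLOAT_FMT, index_label="gene_id"
        )
        return
    if format != "triplet":
        raise ValueError(f"unknown TOM format {format!r}")
    iu, ju = np.triu_indices(t.n_genes, k=1)
    w = t.weights[iu, ju]
    nz = w > 0
    pd.DataFrame(
        {
            "a": np.asarray(t.gene_ids, dtype=object)[iu[nz]],
            "b": np.asarray(t.gene_ids, dtype=object)[ju[nz]],
            "w": w[nz],
        }
    ).to_csv(path, sep=sep, float_format=FLOAT_FMT, index=False, header=False)


def read_traits(path: str | Path, dialect: str | None = None) -> TraitTable:
    """Read a samples x traits wide table (first column sample ids)."""
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    df = df.rename(columns={df.columns[0]: "sample_id"})
    long = df.melt(id_vars="sample_id", var_name="trait_name", value_name="value")
    return TraitTable(long)


def write_traits(path: str | Path, traits: TraitTable, dialect: str | None = None) -> None:
    traits.pivot().to_csv(path, sep=_sep_for(path, dialect), float_format=FLOAT_FMT,
                          index_label="sample_id")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    return GeneSet(name or Path(path).stem, frozenset(genes))


def write_gene_list(path: str | Path, s: GeneSet) -> None:
    with open(path, "w") as fh:
        for g in s.sorted():
            fh.write(g + "\n")


def write_ranking(path: str | Path, r: GeneRanking, dialect: str | None = None) -> None:
    pd.DataFrame(
        {
            "gene_id": [g for g, _ in r.entries],
            "count": [c for _, c in r.entries],
            "rank": np.arange(1, len(r.entries) + 1),
        }
    ).to_csv(path, sep=_sep_for(path, dialect), index=False)


def read_ranking(path: str | Path, kind: str = "critical",
                 dialect: str | None = None) -> GeneRanking:
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    return GeneRanking(list(zip(df["gene_id"].astype(str), df["count"].astype(int))),
                       kind=kind)


# ---------------------------------------------------------------------------
# universe alignment


def align_universe(objs: Iterable) -> tuple[list, dict[int, list[str]]]:
    """Restrict gene-carrying objects to their common universe.

    Returns the aligned objects (same order as given, each restricted to the
    lexicographically sorted intersection of gene ids) and a report mapping
    each object's position to the ids dropped from it.
    """
    objs = list(objs)
    universes = []
    for o in objs:
        if isinstance(o, GeneSet):
            universes.append(set(o.genes))
        else:
            universes.append(set(o.gene_ids))
    if len(objs) < 2:
        raise ValueError("need at least two gene-carrying objects to align")
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("empty gene-id intersection across inputs")
    order = sorted(shared)
    report = {i: sorted(u - shared) for i, u in enumerate(universes)}
    return [o.restrict(order) for o in objs], report
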