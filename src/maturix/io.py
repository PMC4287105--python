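"""Tabular I/O, quantile normalization, and PCA quality control.

The on-disk dialects are the plain-text formats common in microarray work:

* expression — tab-delimited matrix, probes in rows (first column probe ids,
  header row sample ids, numeric body of log2 intensities);
* annotation — two-column TSV ``probe_id\tgene_symbol``;
* design — CSV with header ``sample_id,sow_id,age,fetal_genotype``;
* gene sets — GMT (set name, description, then member symbols, tab-separated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

AGES = ("d90", "d110")
GENOTYPES = ("LW", "MS", "LWMS", "MSLW")

#: fetal genotype -> (maternal, paternal) genotype.  Crossbreds are named
#: paternal-first: MSLW fetuses come from LW sows sired by MS boars, LWMS
#: fetuses from MS sows sired by LW boars.
PARENTAL_MAP = {
    "LW": ("LW", "LW"),
    "MS": ("MS", "MS"),
    "LWMS": ("MS", "LW"),
    "MSLW": ("LW", "MS"),
}


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 expression with optional probe annotation."""

    values: pd.DataFrame
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated probe id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicated sample id: {dup!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> pd.DataFrame:
        """Samples x probes orientation, as estimators expect."""
        return self.values.T

    def gene_of(self, probe_id: str) -> str:
        if self.annotation is None:
            return "unannotated"
        return self.annotation.get(probe_id, "unannotated")


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric expression value at probe {row!r}, sample {col!r}")
    return ExpressionMatrix(values=df.astype(float))


def write_expression(m: ExpressionMatrix, path) -> None:
    out = m.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("annotation must be a two-column TSV: probe_id<TAB>gene_symbol")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene_symbol")


def write_annotation(annotation: pd.Series, path) -> None:
    pd.DataFrame({"probe_id": annotation.index, "gene_symbol": annotation.values}).to_csv(
        path, sep="\t", index=False
    )


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "sow_id": str})
    return validate_design(df)


def write_design(design: pd.DataFrame, path) -> None:
    cols = ["sample_id", "sow_id", "age", "fetal_genotype"]
    design[cols].to_csv(path, index=False)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check design invariants and derive parental genotype columns.

    Every sample id must be unique; ages and genotypes must be from the
    2 x 4 factorial; all fetuses of a sow must share age and (implied)
    maternal genotype.
    """
    design = design.copy()
    required = {"sample_id", "sow_id", "age", "fetal_genotype"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample id in design: {dup!r}")
    bad_age = set(design["age"]) - set(AGES)
    if bad_age:
        raise ValueError(f"unknown age level(s): {sorted(bad_age)}; expected {AGES}")
    bad_g = set(design["fetal_genotype"]) - set(GENOTYPES)
    if bad_g:
        raise ValueError(f"unknown fetal genotype(s): {sorted(bad_g)}")
    design["maternal_genotype"] = design["fetal_genotype"].map(lambda g: PARENTAL_MAP[g][0])
    design["paternal_genotype"] = design["fetal_genotype"].map(lambda g: PARENTAL_MAP[g][1])
    for sow, grp in design.groupby("sow_id"):
        if grp["age"].nunique() > 1:
            raise ValueError(f"sow {sow!r} appears at more than one gestational age")
        if grp["maternal_genotype"].nunique() > 1:
            raise ValueError(f"sow {sow!r} has fetuses implying different maternal genotypes")
    return design


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicated gene-set name in GMT: {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Quantile-normalize columns so every column shares one distribution.

    Each column is replaced, rank-wise, by the mean over columns of the
    sorted values.  Ties within a column receive the mean of the target
    values over the tied ranks, which makes the operation deterministic and
    permutation-invariant.  For tie-free columns the operation is idempotent
    and leaves every column with an identical value multiset; columns with
    ties agree only up to the tie-averaging.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing or non-finite values; impute or filter first")
    target = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        # average rank (1-based); map fractional ranks onto the target by
        # interpolation, which realises tie-averaging exactly
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), target)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map each column of a matrix onto a reference distribution.

    ``fit`` learns the reference distribution (the rank-wise mean of the
    sorted columns); ``transform`` maps each column onto it.  ``fit_transform``
    on one matrix is the classical joint quantile normalization of that
    matrix.  Columns are samples (arrays), rows probes.
    """

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("missing or non-finite values; impute or filter first")
        self.reference_distribution_ = np.sort(arr, axis=0).mean(axis=1)
        self.n_rows_ = arr.shape[0]
        return self

    def transform(self, X):
        arr = np.asarray(X, dtype=float)
        if arr.shape[0] != self.n_rows_:
            raise ValueError("row count differs from the fitted reference")
        out = np.empty_like(arr, dtype=float)
        grid = np.arange(1, self.n_rows_ + 1)
        for j in range(arr.shape[1]):
            ranks = stats.rankdata(arr[:, j], method="average")
            out[:, j] = np.interp(ranks, grid, self.reference_distribution_)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


# ---------------------------------------------------------------------------
# PCA quality control


def pca_scores(m: ExpressionMatrix | pd.DataFrame | np.ndarray, n_components: int = 2):
    """Sample-space PCA for array quality control.

    Probes are variables, samples observations; variables are centered but
    not scaled (expression is already on a common log2 scale).  Returns
    ``(scores, variance_fraction)`` with one score row per sample.
    """
    if isinstance(m, ExpressionMatrix):
        X = m.values.T.to_numpy(dtype=float)
        index = m.sample_ids
    elif isinstance(m, pd.DataFrame):
        X = m.T.to_numpy(dtype=float)
        index = list(m.columns)
    else:
        X = np.asarray(m, dtype=float).T
        index = list(range(X.shape[0]))
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    max_rank = min(n_samples - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {max_rank}; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return (
        pd.DataFrame(scores, index=index, columns=[f"PC{i+1}" for i in range(n_components)]),
        pca.explained_variance_ratio_.copy(),
    )
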