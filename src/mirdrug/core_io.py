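"""Data model, TSV/GMT readers and writers, and the fixed pre-statistics transforms.

The pipeline operates on three kinds of tabular inputs: expression matrices
(features x samples, tab-separated, first column feature id, first row sample
ids), per-drug IC50 tables carrying the maximum tested concentration that
defines right-censoring, and per-sample molecular subtype labels.  Gene sets
for the pathway screen come in standard GMT format.

Scale handling is explicit: raw intensities are log10-transformed exactly once
before any statistic, and IC50 values are mapped to -log10 molar so that larger
numbers mean greater drug sensitivity.  Cell lines whose IC50 sits at the
maximum tested concentration are right-censored; they share the minimum of the
transformed vector.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: relative tolerance under which an IC50 counts as sitting at the maximum
#: tested concentration (absorbs float noise in stored tables)
AT_MAX_RTOL = 1e-9

SUBTYPES = ("basal", "luminal", "normal-like")


class Scale(enum.Enum):
    """Declared scale of an expression matrix."""

    RAW = "raw"
    LOG10 = "log10"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicated {what}: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples expression table with an explicit scale flag."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_features, n_samples)
    scale: Scale

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.scale is Scale.RAW and np.any(values <= 0):
            raise ValueError("RAW expression values must be strictly positive")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        try:
            idx = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None
        return self.values[idx]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in sample_ids]
        return replace(self, sample_ids=tuple(sample_ids), values=self.values[:, cols])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        rows = [index[f] for f in feature_ids]
        return replace(self, feature_ids=tuple(feature_ids), values=self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class DrugResponseProfile:
    """One drug's per-sample IC50 values (molar) plus the maximum tested concentration.

    ``ic50`` uses NaN for missing measurements.  Non-missing entries never
    exceed ``max_conc`` (within relative tolerance): values at the maximum are
    right-censored observations, not measurements above it.
    """

    drug_name: str
    sample_ids: tuple[str, ...]
    ic50: np.ndarray
    max_conc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        ic50 = np.asarray(self.ic50, dtype=float)
        object.__setattr__(self, "ic50", ic50)
        _check_unique(self.sample_ids, "sample id")
        if ic50.shape != (len(self.sample_ids),):
            raise ValueError("ic50 vector length does not match sample ids")
        if not (np.isfinite(self.max_conc) and self.max_conc > 0):
            raise ValueError(f"max_conc must be positive, got {self.max_conc}")
        obs = ic50[~np.isnan(ic50)]
        if np.any(obs <= 0):
            raise ValueError(f"{self.drug_name}: IC50 values must be positive")
        if np.any(obs > self.max_conc * (1 + AT_MAX_RTOL)):
            raise ValueError(
                f"{self.drug_name}: IC50 above the maximum tested concentration"
            )

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.ic50)

    @property
    def at_max(self) -> np.ndarray:
        """True where the (non-missing) IC50 sits at the maximum tested concentration."""
        with np.errstate(invalid="ignore"):
            return ~self.missing & (self.ic50 >= self.max_conc * (1 - AT_MAX_RTOL))

    @property
    def n_at_max(self) -> int:
        return int(self.at_max.sum())

    @property
    def n_variable(self) -> int:
        return int((~self.missing).sum() - self.at_max.sum())

    def subset_samples(self, sample_ids: Sequence[str]) -> "DrugResponseProfile":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        cols = [index[s] for s in sample_ids]
        return replace(self, sample_ids=tuple(sample_ids), ic50=self.ic50[cols])


@dataclass(frozen=True)
class SubtypeLabels:
    """Per-sample molecular subtype in {basal, luminal, normal-like}."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_unique(self.sample_ids, "sample id")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label required per sample")
        bad = sorted({l for l in self.labels if l not in SUBTYPES})
        if bad:
            raise ValueError(f"unknown subtype labels: {bad}; expected {SUBTYPES}")

    def indicator(self, subtype: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """0/1 vector marking membership of ``subtype`` (that subtype vs rest)."""
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype: {subtype!r}")
        mapping = dict(zip(self.sample_ids, self.labels))
        ids = self.sample_ids if sample_ids is None else sample_ids
        missing = [s for s in ids if s not in mapping]
        if missing:
            raise KeyError(f"samples without subtype label: {missing}")
        return np.array([1.0 if mapping[s] == subtype else 0.0 for s in ids])


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. Biocarta/KEGG pathways) for the global-test screen."""

    sets: Mapping[str, tuple[str, ...]]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sets", {name: tuple(genes) for name, genes in self.sets.items()}
        )
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated {what} id in {path}: {dup[0]!r}")
    dup_cols = df.columns[df.columns.duplicated()]
    if len(dup_cols):
        raise ValueError(f"duplicated sample id in {path}: {dup_cols[0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {df.index[r]!r}, column {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    # float() is correctly rounded, so decimal-representable values round-trip
    # bit-exactly (pandas' fast parser is not)
    cells = df.to_numpy()
    values = np.array(
        [[np.nan if pd.isna(v) else float(v) for v in row] for row in cells]
    )
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def read_expression_matrix(path: str | Path, scale: Scale) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, first row sample ids)."""
    df = _read_numeric_table(path, "feature")
    return ExpressionMatrix(
        feature_ids=tuple(str(i) for i in df.index),
        sample_ids=tuple(str(c) for c in df.columns),
        values=df.to_numpy(dtype=float),
        scale=scale,
    )


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_drug_response(path: str | Path) -> list[DrugResponseProfile]:
    """Read per-drug IC50 profiles from one wide TSV.

    Layout: first column ``drug``, second column ``max_conc`` (molar), remaining
    columns one per sample; empty cells are missing IC50s.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "max_conc" not in df.columns:
        raise ValueError(f"{path}: expected a 'max_conc' column")
    sample_ids = tuple(str(c) for c in df.columns if c != "max_conc")
    profiles = []
    for drug, row in df.iterrows():
        profiles.append(
            DrugResponseProfile(
                drug_name=str(drug),
                sample_ids=sample_ids,
                ic50=row[list(sample_ids)].to_numpy(dtype=float),
                max_conc=float(row["max_conc"]),
            )
        )
    return profiles


def write_drug_response(profiles: Sequence[DrugResponseProfile], path: str | Path) -> None:
    if not profiles:
        raise ValueError("no drug profiles to write")
    sample_ids = profiles[0].sample_ids
    for p in profiles:
        if p.sample_ids != sample_ids:
            raise ValueError("all profiles must share the same sample ids")
    df = pd.DataFrame(
        {p.drug_name: p.ic50 for p in profiles}, index=list(sample_ids)
    ).T
    df.insert(0, "max_conc", [p.max_conc for p in profiles])
    df.to_csv(path, sep="\t", index_label="drug")


def read_subtype_labels(path: str | Path) -> SubtypeLabels:
    """Read two-column TSV: sample id, subtype label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample, subtype")
    return SubtypeLabels(
        sample_ids=tuple(df.iloc[:, 0]), labels=tuple(df.iloc[:, 1])
    )


def write_subtype_labels(labels: SubtypeLabels, path: str | Path) -> None:
    pd.DataFrame({"sample": labels.sample_ids, "subtype": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_sets(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read gene sets from a standard GMT file (name, description, member genes)."""
    from gseapy.parser import read_gmt as _read_gmt

    sets = _read_gmt(str(path))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(
        sets={name: tuple(genes) for name, genes in sets.items()},
        source=source or str(path),
    )


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# fixed transforms
# ---------------------------------------------------------------------------


def log10_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Base-10 log of a RAW matrix; refuses to double-transform."""
    if m.scale is not Scale.RAW:
        raise ValueError("matrix is already on the log10 scale")
    if np.any(m.values <= 0):
        raise ValueError("log10 undefined: matrix contains nonpositive values")
    return replace(m, values=np.log10(m.values), scale=Scale.LOG10)


def neglog10_ic50(p: DrugResponseProfile) -> np.ndarray:
    """-log10(IC50) per sample (NaN for missing).

    Strictly antitone in IC50, so at-max (right-censored) samples share the
    minimum attainable value -log10(max_conc).
    """
    obs = p.ic50[~p.missing]
    if np.any(obs <= 0):
        raise ValueError(f"{p.drug_name}: nonpositive IC50")
    out = np.full_like(p.ic50, np.nan)
    out[~p.missing] = -np.log10(p.ic50[~p.missing])
    return out


def uncentered_correlation_distance(x: np.ndarray) -> np.ndarray:
    """Pairwise d(a, b) = 1 - (a.b) / (||a|| ||b||) between columns of ``x``.

    The cosine-style distance without mean-centering; lies in [0, 2].
    """
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero vector has undefined uncentered correlation")
    c = (x.T @ x) / np.outer(norms, norms)
    d = 1.0 - np.clip(c, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def cluster_subtypes(m: ExpressionMatrix, k: int = 3) -> dict[str, int]:
    """Average-linkage hierarchical clustering of samples, uncentered-correlation distance.

    Returns sample id -> cluster index (1..k).  Mapping clusters to subtype
    names is the caller's responsibility.
    """
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({m.n_samples})")
    d = uncentered_correlation_distance(m.values)
    z = linkage(squareform(d, checks=False), method="average")
    assignment = fcluster(z, t=k, criterion="maxclust")
    return dict(zip(m.sample_ids, (int(a) for a in assignment)))
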