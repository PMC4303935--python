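"""Expression-matrix and sample-metadata containers with text readers/writers.

The package consumes already-normalized expression matrices (RMA-style
microarray values or FPKM-style RNA-seq values) as tab-separated text with
genes in rows and samples in columns, plus a delimited metadata table with
one row per sample.  The GEO "series matrix" text dialect is also accepted
(only the table block between the begin/end markers is read).

Upstream processing — read mapping, RMA normalization, FPKM computation —
is out of scope: this module starts from the numeric matrix.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ParseError

logger = logging.getLogger(__name__)

#: float format for every table this package writes (6 significant digits)
FLOAT_FORMAT = "%.6g"

_TRANSFORMS = ("none", "log2p1")
_DUPLICATE_POLICIES = ("mean", "max", "first")


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Identifiers are opaque strings; no probe/symbol mapping
        is attempted.
    transform_log
        Record of the transform applied at load time (``"none"`` or
        ``"log2p1"``).
    allow_negative
        Set when values are on a log scale and may be negative; the
        [0, 1] guarantee of the cosine (Pearson) distance is then void.
    provenance
        Free-form notes accumulated by loaders and mergers.
    """

    values: pd.DataFrame
    transform_log: str = "none"
    allow_negative: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = sorted(idx[idx.duplicated()].unique())
            raise AlignmentError(f"duplicate gene identifiers: {dup[:10]}")
        if cols.has_duplicates:
            dup = sorted(cols[cols.duplicated()].unique())
            raise AlignmentError(f"duplicate sample identifiers: {dup[:10]}")
        if self.values.empty:
            raise ParseError("empty expression matrix")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ParseError("expression matrix contains non-finite values")
        if not self.allow_negative and (arr < 0).any():
            logger.warning(
                "negative expression values present without log-scale flag; "
                "cosine-distance range guarantees do not apply"
            )
            self.allow_negative = True

    # -- accessors -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def X(self) -> np.ndarray:
        """Values as a float array, genes in rows and samples in columns."""
        return self.values.to_numpy(dtype=float)

    def vector(self, sample_id: str) -> np.ndarray:
        """Expression vector of one sample (aligned to ``gene_ids``)."""
        return self.values[sample_id].to_numpy(dtype=float)

    def log2p1(self) -> "ExpressionMatrix":
        """A log2(x+1)-transformed copy (RMA-like scale); requires x >= 0."""
        if (self.values.to_numpy() < 0).any():
            raise ParseError("log2p1 transform requires non-negative values")
        return ExpressionMatrix(
            np.log2(self.values + 1.0),
            transform_log="log2p1",
            allow_negative=True,
            provenance=self.provenance + ["log2p1 transform"],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)],
            transform_log=self.transform_log,
            allow_negative=self.allow_negative,
            provenance=self.provenance + [f"subset to {len(genes)} genes"],
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: group label and optional survival time.

    Wraps a DataFrame indexed by ``sample_id`` with a required ``group``
    column and an optional numeric ``survival_days`` column; further
    columns are carried through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ParseError(f"duplicate sample_id in metadata: {dup}")
        if "group" not in self.table.columns:
            raise ParseError("metadata lacks required column 'group'")
        grp = self.table["group"]
        if grp.isna().any() or (grp.astype(str).str.len() == 0).any():
            raise ParseError("metadata contains empty group labels")
        self.table = self.table.copy()
        self.table["group"] = grp.astype(str)
        if "survival_days" in self.table.columns:
            surv = pd.to_numeric(self.table["survival_days"], errors="coerce")
            if (surv.dropna() < 0).any():
                raise ParseError("negative survival_days in metadata")
            self.table["survival_days"] = surv

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def labels(self) -> list[str]:
        """Distinct group labels in deterministic (lexicographic) order."""
        return sorted(self.table["group"].unique())

    def members(self, label: str) -> list[str]:
        return list(self.table.index[self.table["group"] == label])

    @property
    def survival_days(self) -> pd.Series:
        """Survival in days, NaN where absent."""
        if "survival_days" in self.table.columns:
            return self.table["survival_days"]
        return pd.Series(np.nan, index=self.table.index, name="survival_days")

    def with_survival(self, survival: pd.Series) -> "SampleMetadata":
        tab = self.table.copy()
        tab["survival_days"] = survival.reindex(tab.index)
        return SampleMetadata(tab)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _apply_transform(df: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "none":
        return df
    if transform == "log2p1":
        if (df.to_numpy() < 0).any():
            raise ParseError("log2p1 transform requires non-negative values")
        return np.log2(df + 1.0)
    raise ParseError(f"unknown transform {transform!r}; expected one of {_TRANSFORMS}")


def _collapse_duplicates(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    dup = sorted(df.index[df.index.duplicated()].unique())
    logger.warning(
        "collapsing %d duplicated gene id(s) with policy %r: %s%s",
        len(dup), policy, dup[:5], " ..." if len(dup) > 5 else "",
    )
    if policy == "mean":
        return df.groupby(level=0, sort=False).mean()
    if policy == "max":
        return df.groupby(level=0, sort=False).max()
    if policy == "first":
        return df[~df.index.duplicated(keep="first")]
    raise ParseError(
        f"unknown duplicate policy {policy!r}; expected one of {_DUPLICATE_POLICIES}"
    )


def _read_geo_series_matrix(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.strip().lower() == "!series_matrix_table_begin")
        end = next(i for i, l in enumerate(lines)
                   if l.strip().lower() == "!series_matrix_table_end")
    except StopIteration:
        raise ParseError(
            f"{path}: no !series_matrix_table_begin/end block found"
        ) from None
    block = "\n".join(lines[start + 1:end])
    from io import StringIO
    df = pd.read_csv(StringIO(block), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    return df


def read_expression(
    path: str | Path,
    format: str = "tsv",
    transform: str = "none",
    duplicate_policy: str = "mean",
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix from text.

    ``format="tsv"`` expects a header row of sample ids and gene ids in the
    first column; ``format="geo_series_matrix"`` reads the table block of a
    GEO Series Matrix file.  Duplicate gene rows are collapsed according to
    ``duplicate_policy`` (default: mean).  Genes with any missing value are
    dropped (no imputation); the count is logged.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"{path}: {exc}") from exc
    elif format == "geo_series_matrix":
        df = _read_geo_series_matrix(path)
    else:
        raise ParseError(f"unknown format {format!r}")

    if df.empty:
        raise ParseError(f"{path}: empty matrix")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]
    ]
    if len(non_numeric):
        coerced = df[non_numeric].apply(pd.to_numeric, errors="coerce")
        bad = coerced.columns[coerced.isna().any() & df[non_numeric].notna().any()]
        if len(bad):
            for col in bad:
                rows = df.index[coerced[col].isna() & df[col].notna()]
                raise ParseError(
                    f"{path}: non-numeric cell(s) in column {col!r}, "
                    f"gene row(s) {list(rows[:5])}"
                )
        df[non_numeric] = coerced

    df = _collapse_duplicates(df, duplicate_policy)

    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d gene(s) with missing values", n_missing)
        df = df.dropna(axis=0)
    if df.empty:
        raise ParseError(f"{path}: no complete gene rows remain")

    df = _apply_transform(df.astype(float), transform)
    return ExpressionMatrix(
        df,
        transform_log=transform,
        allow_negative=(transform != "none"),
        provenance=[f"read {path.name} ({format}, transform={transform}, "
                    f"duplicates={duplicate_policy})"],
    )


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a comma- or tab-separated metadata table.

    Requires columns ``sample_id`` and ``group``; ``survival_days`` is
    optional and blanks are kept as missing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMetadata(df.set_index("sample_id"))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as tab-separated text (gene ids in the first column).

    Matrices are written at near-full precision (12 significant digits) so
    a read -> write -> read round trip is lossless to 1e-9; the 6-digit
    convention applies only to derived result tables.
    """
    matrix.values.to_csv(Path(path), sep="\t", index_label="gene_id",
                         float_format="%.12g")


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.table.to_csv(Path(path), sep="\t", index_label="sample_id",
                          float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def align_datasets(matrices: Iterable[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge matrices over the (sorted) intersection of their gene ids.

    Samples are concatenated and NO cross-normalization is applied; the
    method's scale-invariant distances are expected to absorb batch scale.
    A notice is logged and per-source provenance recorded.
    """
    mats = list(matrices)
    if len(mats) < 2:
        raise AlignmentError("align_datasets needs at least 2 matrices")
    gene_sets = [set(m.gene_ids) for m in mats]
    common = set.intersection(*gene_sets)
    if not common:
        pairs = []
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                pairs.append(f"({i},{j}): {len(gene_sets[i] & gene_sets[j])}")
        raise AlignmentError(
            "no gene ids shared by all matrices; pairwise overlap counts: "
            + ", ".join(pairs)
        )
    genes = sorted(common)
    all_samples = [s for m in mats for s in m.sample_ids]
    if len(set(all_samples)) != len(all_samples):
        raise AlignmentError("sample identifiers collide across matrices")
    logger.info(
        "merging %d matrices over %d shared genes without cross-normalization",
        len(mats), len(genes),
    )
    merged = pd.concat([m.values.loc[genes] for m in mats], axis=1)
    prov = [f"merged {len(mats)} matrices over {len(genes)} shared genes; "
            "no cross-normalization"]
    for i, m in enumerate(mats):
        prov.extend(f"source {i}: {p}" for p in m.provenance)
    transform = mats[0].transform_log
    if any(m.transform_log != transform for m in mats):
        logger.warning("merging matrices with differing transforms")
        transform = "mixed"
    return ExpressionMatrix(
        merged,
        transform_log=transform,
        allow_negative=any(m.allow_negative for m in mats),
        provenance=prov,
    )


def sha256_of(path: str | Path) -> str:
    """Checksum of a file, recorded into provenance files."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
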