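"""Expression-matrix container and delimited-text I/O.

Expression files are samples-in-rows: a header row of gene identifiers and
one row per sample, with an optional leading column of sample identifiers.
A ``transpose`` flag supports genes-in-rows files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionLoadError",
    "read_expression",
    "write_expression",
    "read_gene_lengths",
]


class ExpressionLoadError(ValueError):
    """Raised when an expression file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """A samples x genes expression matrix for one group.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Expression values in arbitrary units (counts, TPM, log-TPM, ...).
    gene_ids : list of str
        Unique gene identifiers, one per column.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    group_label : str
        Name of the population the samples were drawn from.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str] = field(default_factory=list)
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes array")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.values.shape[0])]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ExpressionLoadError(f"duplicate gene ids: {sorted(dupes)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionLoadError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes``, in the given order."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        cols = [index[g] for g in genes]
        return ExpressionMatrix(
            self.values[:, cols], list(genes), list(self.sample_ids), self.group_label
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_label: str = "") -> "ExpressionMatrix":
        return cls(
            df.to_numpy(dtype=float),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
            group_label,
        )


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(
    path, group_label: str = "", sep: str = "\t", transpose: bool = False
) -> ExpressionMatrix:
    """Read a delimited expression matrix (header = gene ids, rows = samples).

    The first column is treated as sample identifiers when it is non-numeric;
    otherwise samples are numbered. ``transpose=True`` reads genes-in-rows
    files.
    """
    # check the raw header before pandas de-duplicates repeated column names
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        second = fh.readline().rstrip("\n")
    head_fields = first.split(sep)
    # a leading index-name field is present when header and data widths match
    if second and len(head_fields) == len(second.split(sep)):
        head_fields = head_fields[1:]
    dupes = _duplicates([f for f in head_fields if f])
    if dupes and not transpose:
        raise ExpressionLoadError(f"duplicate gene column(s) in {path}: {sorted(dupes)}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ExpressionLoadError(f"cannot parse {path}: {exc}") from exc
    if transpose:
        df = df.T
    header = [str(c) for c in df.columns]
    dupes = _duplicates(header)
    if dupes:
        raise ExpressionLoadError(f"duplicate gene column(s) in {path}: {sorted(dupes)}")
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ExpressionLoadError(
                        f"non-numeric cell at row {df.index[i]!r}, "
                        f"column {header[j]!r} in {path}"
                    ) from None
    if df.isna().to_numpy().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ExpressionLoadError(
            f"missing value at row {df.index[i]!r}, column {header[j]!r} in {path}"
        )
    return ExpressionMatrix.from_dataframe(df, group_label)


def write_expression(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    """Write an expression matrix as delimited text (full float precision)."""
    X.to_dataframe().to_csv(path, sep=sep, index_label="sample", float_format="%.17g")


def read_gene_lengths(path, sep: str = "\t") -> dict[str, int]:
    """Read a two-column gene_id / length table; lengths must be positive."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ExpressionLoadError(f"{path}: expected two columns (gene_id, length)")
    lengths: dict[str, int] = {}
    for gene, length in zip(df.iloc[:, 0], df.iloc[:, 1]):
        L = int(length)
        if L <= 0:
            raise ExpressionLoadError(f"non-positive length for gene {gene!r}")
        lengths[str(gene)] = L
    return lengths
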