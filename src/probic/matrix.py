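"""The genes x arrays expression matrix container and its TSV dialect.

Values are log-ratio-style real numbers; missing measurements are carried in
an explicit presence mask.  On disk the matrix is tab-separated text with
array identifiers in the first row and gene identifiers in the first column;
an empty cell or ``NA`` is missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class MatrixFormatError(ValueError):
    """Raised when an expression matrix violates the container's contract."""


@dataclass
class ExpressionMatrix:
    """Expression levels for every (gene, array) combination.

    Parameters
    ----------
    gene_ids, array_ids
        Ordered, duplicate-free identifiers for rows and columns.
    values
        Real matrix of shape ``(n_genes, n_arrays)``; entries where ``mask``
        is False are ignored everywhere and may hold NaN.
    mask
        Boolean presence matrix, True where a measurement exists.  Defaults
        to the finite entries of ``values``.
    """

    gene_ids: np.ndarray
    array_ids: np.ndarray
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.array_ids = np.asarray(self.array_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be a 2-D matrix")
        n_genes, n_arrays = self.values.shape
        if n_genes < 2 or n_arrays < 2:
            raise MatrixFormatError(
                f"need at least 2 genes and 2 arrays, got {n_genes} x {n_arrays}"
            )
        if len(self.gene_ids) != n_genes or len(self.array_ids) != n_arrays:
            raise MatrixFormatError("identifier lengths do not match values shape")
        for name, ids in (("gene", self.gene_ids), ("array", self.array_ids)):
            if len(set(ids)) != len(ids):
                raise MatrixFormatError(f"duplicate {name} identifiers")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise MatrixFormatError("mask shape does not match values shape")
            if not np.all(np.isfinite(self.values[self.mask])):
                raise MatrixFormatError("non-finite value where mask marks presence")

    # -- basic introspection ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    def gene_index(self, ids: Iterable[str]) -> np.ndarray:
        """Row indices for the given gene ids; unknown ids raise KeyError."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in lookup]
        if missing:
            raise KeyError(f"unknown gene id(s): {sorted(missing)}")
        return np.array([lookup[g] for g in ids], dtype=int)

    def array_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.array_ids)}
        missing = [a for a in ids if a not in lookup]
        if missing:
            raise KeyError(f"unknown array id(s): {sorted(missing)}")
        return np.array([lookup[a] for a in ids], dtype=int)

    # -- pandas / TSV bridge ------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.array_ids)
        )
        return df.mask(~self.mask)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        values = df.to_numpy(dtype=float)
        return cls(
            gene_ids=np.asarray(df.index, dtype=object),
            array_ids=np.asarray(df.columns, dtype=object),
            values=values,
            mask=np.isfinite(values),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA", index_label="")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                index_col=0,
                na_values=["NA", ""],
                keep_default_na=False,
            )
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise MatrixFormatError(f"{path}: cannot parse matrix TSV: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        non_numeric = df.columns[
            [not np.issubdtype(dt, np.number) for dt in df.dtypes]
        ]
        if len(non_numeric):
            # pinpoint the first bad cell for the error message
            for col in non_numeric:
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise MatrixFormatError(
                        f"{path}: line {row + 2}: non-numeric value "
                        f"{df[col].iloc[row]!r} in column {col!r}"
                    )
            df[non_numeric] = df[non_numeric].apply(pd.to_numeric)
        return cls.from_dataframe(df)


def read_seed_file(path: str | Path) -> list[str]:
    """Read a seed gene list: one id per line, '#' starts a comment."""
    seeds: list[str] = []
    seen: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line not in seen:
            seen.add(line)
            seeds.append(line)
    return seeds


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT-style annotation sets: id <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise MatrixFormatError(
                f"{path}: line {lineno}: GMT row needs id, description, >=1 gene"
            )
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def validate_seeds(matrix: ExpressionMatrix, seeds: Sequence[str]) -> list[str]:
    """Return seeds in matrix row order, raising on empty or unknown ids."""
    if len(list(seeds)) == 0:
        raise ValueError("seed set is empty")
    idx = matrix.gene_index(seeds)  # raises KeyError listing offenders
    order = np.sort(idx)
    return [matrix.gene_ids[i] for i in order]
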