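"""Data containers and delimited-text I/O.

A :class:`DataMatrix` holds one group's observations-by-variables table
together with a per-variable type mask (continuous or binary).  Binary
columns must contain only 0/1; they are interpreted as dichotomized
latent Gaussian-copula variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "read_matrix", "write_matrix", "write_edge_list"]

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class DataMatrix:
    """One group's numeric data with per-variable types.

    Parameters
    ----------
    values : (n, p) array
        Observations by variables, no missing values.
    types : sequence of {'continuous', 'binary'} or 'auto'
        Per-column type; 'auto' flags a column binary when all its values
        lie in {0, 1}.
    names : sequence of str, optional
    group_label : str, optional
    """

    values: np.ndarray
    types: object = "auto"
    names: list = None
    group_label: str = ""
    binary_mask: np.ndarray = field(init=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if values.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if np.isnan(values).any():
            raise ValueError("missing values are not supported")
        self.values = values
        n, p = values.shape
        if self.names is None:
            self.names = [f"V{j + 1}" for j in range(p)]
        else:
            self.names = [str(x) for x in self.names]
            if len(self.names) != p:
                raise ValueError("names length does not match column count")

        if isinstance(self.types, str):
            if self.types == "auto":
                mask = np.array(
                    [np.isin(values[:, j], (0.0, 1.0)).all() for j in range(p)]
                )
            elif self.types == CONTINUOUS:
                mask = np.zeros(p, dtype=bool)
            elif self.types == BINARY:
                mask = np.ones(p, dtype=bool)
            else:
                raise ValueError(f"unknown type spec {self.types!r}")
        else:
            tl = list(self.types)
            if len(tl) != p:
                raise ValueError("types length does not match column count")
            bad = set(tl) - {CONTINUOUS, BINARY}
            if bad:
                raise ValueError(f"unknown variable types: {sorted(bad)}")
            mask = np.array([t == BINARY for t in tl])
        self.binary_mask = mask
        for j in np.flatnonzero(mask):
            if not np.isin(values[:, j], (0.0, 1.0)).all():
                raise ValueError(
                    f"column {self.names[j]!r} declared binary but contains "
                    "values outside {0, 1}"
                )

    @property
    def n(self):
        return self.values.shape[0]

    @property
    def p(self):
        return self.values.shape[1]

    @property
    def n_binary(self):
        return int(self.binary_mask.sum())

    @property
    def type_list(self):
        return [BINARY if b else CONTINUOUS for b in self.binary_mask]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, types="auto", group_label=""):
        return cls(df.to_numpy(dtype=float), types=types,
                   names=list(df.columns), group_label=group_label)

    def to_dataframe(self):
        return pd.DataFrame(self.values, columns=self.names)


def _sniff_delimiter(path, delimiter):
    if delimiter is not None:
        return delimiter
    path = str(path)
    return "," if path.endswith(".csv") else "\t"


def read_matrix(path, delimiter=None, types="auto", group_label="") -> DataMatrix:
    """Read a delimited matrix file (header row = variable names)."""
    delim = _sniff_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=delim)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"{path} contains no data")
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing or ragged cells detected")
    return DataMatrix.from_dataframe(df, types=types, group_label=group_label)


def write_matrix(matrix, names, path, delimiter="\t"):
    """Write a labeled square or rectangular matrix at full precision."""
    df = pd.DataFrame(np.asarray(matrix), columns=list(names))
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_edge_list(delta_hat, names, path, threshold=0.0, delimiter="\t"):
    """Write upper-triangle nonzeros of a symmetric difference matrix as a
    TSV edge list (i, j, name_i, name_j, delta, sign), 1-based indices,
    ordered by (i, j)."""
    delta_hat = np.asarray(delta_hat)
    p = delta_hat.shape[0]
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            v = delta_hat[i, j]
            if abs(v) > threshold:
                rows.append(
                    (i + 1, j + 1, names[i], names[j], v, "+" if v > 0 else "-")
                )
    df = pd.DataFrame(rows, columns=["i", "j", "gene_i", "gene_j", "delta", "sign"])
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    return df
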