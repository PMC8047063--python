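"""Reading, writing and aligning labeled matrices.

On-disk format: a dense TSV or CSV with a header row of column identifiers
and the row identifier in the first field of every data row.  The delimiter
is auto-detected from the header (tab wins over comma), ids are opaque
UTF-8 strings, and values must be numeric.  Association matrices must be
strictly binary — anything else is an error rather than coerced, because
silent coercion hides label bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, SideNetwork
from .errors import AlignmentError, IdentifierError, MatrixParseError, ShapeError

__all__ = [
    "read_matrix",
    "read_association",
    "read_side_network",
    "write_matrix",
    "align",
    "AlignedBundle",
]

logger = logging.getLogger(__name__)


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_matrix(path: str | Path, expect_square: bool = False) -> pd.DataFrame:
    """Read a labeled matrix as a DataFrame (index = row ids, columns = col ids)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8") as fh:
        header_cols = fh.readline().rstrip("\r\n").split(sep)[1:]
    if len(set(header_cols)) != len(header_cols):
        raise IdentifierError(f"{path} contains duplicate column identifiers")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0,
                         float_precision="round_trip")
    except Exception as exc:
        raise MatrixParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise IdentifierError(f"{path} contains duplicate identifiers")
    if df.isna().any().any():
        raise MatrixParseError(f"{path} contains missing cells (ragged rows?)")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise MatrixParseError(f"{path} contains non-numeric cells: {exc}") from exc
    if expect_square and values.shape[0] != values.shape[1]:
        raise ShapeError(f"{path}: expected square matrix, got {values.shape}")
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def read_association(path: str | Path) -> AssociationMatrix:
    """Read a binary association matrix; non-binary entries are rejected."""
    df = read_matrix(path)
    return AssociationMatrix(df.to_numpy(), list(df.index), list(df.columns))


def read_side_network(path: str | Path, kind: str = "similarity") -> SideNetwork:
    """Read a side network; similarity kind enforces square + symmetric."""
    df = read_matrix(path, expect_square=(kind == "similarity"))
    return SideNetwork(df.to_numpy(), list(df.index), kind=kind)


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
    sep: str = "\t",
) -> None:
    """Write a labeled matrix; floats use shortest round-trip formatting."""
    df = pd.DataFrame(np.asarray(values, dtype=float), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep=sep, float_format=lambda x: repr(float(x)))


@dataclass
class AlignedBundle:
    """An association matrix and its side networks on a common id order."""

    assoc: AssociationMatrix
    drug_nets: list[SideNetwork]
    met_nets: list[SideNetwork]


def _intersect(axis_ids: list[str], nets: Sequence[SideNetwork], what: str) -> list[str]:
    keep = list(axis_ids)
    for net in nets:
        present = set(net.ids)
        dropped = [i for i in keep if i not in present]
        if dropped:
            logger.warning(
                "%d %s entit%s absent from a side network and dropped (e.g. %s)",
                len(dropped), what, "y" if len(dropped) == 1 else "ies", dropped[:3],
            )
        keep = [i for i in keep if i in present]
    if not keep:
        raise AlignmentError(f"no {what} identifiers shared by all inputs")
    return keep


def align(
    assoc: AssociationMatrix,
    drug_nets: Sequence[SideNetwork] = (),
    met_nets: Sequence[SideNetwork] = (),
) -> AlignedBundle:
    """Re-index every matrix to the intersection of ids, in association order.

    Entities missing from any side network are dropped from all matrices
    (with a logged warning); the operation is idempotent.
    """
    rows = _intersect(assoc.row_ids, drug_nets, "row")
    cols = _intersect(assoc.col_ids, met_nets, "column")
    ri = [assoc.row_ids.index(i) for i in rows]
    ci = [assoc.col_ids.index(j) for j in cols]
    new_assoc = AssociationMatrix(assoc.values[np.ix_(ri, ci)], rows, cols)
    return AlignedBundle(
        assoc=new_assoc,
        drug_nets=[net.reindex(rows) for net in drug_nets],
        met_nets=[net.reindex(cols) for net in met_nets],
    )
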