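"""Core labeled-matrix containers shared across the pipeline.

Two kinds of matrices flow through the method: the binary association matrix
``Y`` (rows = drugs, columns = metabolites, or any bipartite pairing) that
supplies the supervision signal, and square side networks over a single
entity class (correlation/similarity matrices, or incidence profiles such as
metabolite-by-microbe membership that are later turned into kernels).

Both carry ordered, unique string identifiers so that inputs from different
sources can be aligned by id rather than by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, IdentifierError, ShapeError

__all__ = ["AssociationMatrix", "SideNetwork"]


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IdentifierError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class AssociationMatrix:
    """Binary bipartite association matrix with row/column identifiers.

    ``values[i, j] == 1`` records an observed interaction between row entity
    ``row_ids[i]`` and column entity ``col_ids[j]``; 0 means unobserved (not
    a verified negative).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("association matrix must be 2-dimensional")
        self.row_ids = _check_ids(self.row_ids, "row")
        self.col_ids = _check_ids(self.col_ids, "column")
        n, m = self.values.shape
        if n != len(self.row_ids) or m != len(self.col_ids):
            raise ShapeError(
                f"id lists ({len(self.row_ids)}x{len(self.col_ids)}) do not match "
                f"matrix shape {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise DomainError("association matrix contains non-finite entries")
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = self.values[~np.isin(self.values, (0.0, 1.0))]
            raise DomainError(
                f"association entries must be 0 or 1; found e.g. {bad.flat[0]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())


@dataclass
class SideNetwork:
    """Square matrix over one entity class.

    ``kind`` distinguishes genuine similarity matrices (required to be
    symmetric) from incidence profiles (entity x attribute memberships whose
    rows are interaction profiles; converted to a Gaussian kernel downstream).
    For ``kind='incidence_profile'`` the matrix need not be square, and
    ``ids`` labels the rows only.
    """

    values: np.ndarray
    ids: list[str]
    kind: str = "similarity"
    symmetry_tol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("side network must be 2-dimensional")
        if self.kind not in ("similarity", "incidence_profile"):
            raise DomainError(f"unknown side-network kind: {self.kind!r}")
        self.ids = _check_ids(self.ids, "entity")
        if len(self.ids) != self.values.shape[0]:
            raise ShapeError(
                f"{len(self.ids)} ids for {self.values.shape[0]} rows"
            )
        if not np.isfinite(self.values).all():
            raise DomainError("side network contains non-finite entries")
        if self.kind == "similarity":
            n, m = self.values.shape
            if n != m:
                raise ShapeError(f"similarity network must be square, got {n}x{m}")
            if not np.allclose(self.values, self.values.T, atol=self.symmetry_tol):
                raise DomainError("similarity network is not symmetric within 1e-8")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reindex(self, ids: Sequence[str]) -> "SideNetwork":
        """Return a copy restricted/permuted to ``ids`` (must be a subset)."""
        pos = {e: i for i, e in enumerate(self.ids)}
        try:
            idx = np.array([pos[e] for e in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - guarded by align()
            raise IdentifierError(f"id {exc} absent from side network") from exc
        if self.kind == "similarity":
            vals = self.values[np.ix_(idx, idx)]
        else:
            vals = self.values[idx, :]
        return SideNetwork(vals, list(ids), kind=self.kind)
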