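"""Entity-entity similarity kernels.

The Gaussian interaction-profile (GIP) kernel measures similarity between
two entities through their interaction profiles p_i (rows of an association
or incidence matrix):

    K(i, j) = exp(-gamma * ||p_i - p_j||^2),
    gamma   = gamma' / mean_l ||p_l||^2,

so the bandwidth adapts to the overall profile density; gamma' defaults to 1
following common practice for this kernel.  Cosine similarity of fused
feature matrices provides the second similarity notion used downstream
(Vicus construction and neighbor smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import SideNetwork
from .errors import DegenerateBandwidthError, DegenerateRowError, ShapeError

__all__ = ["KernelMatrix", "gip_kernel", "cosine_matrix"]


@dataclass
class KernelMatrix:
    """A Gaussian profile kernel: symmetric, unit diagonal, entries in (0, 1]."""

    values: np.ndarray
    ids: list[str]
    gamma: float          # realized bandwidth gamma' / mean squared profile norm
    gamma_prime: float    # input bandwidth

    def as_side_network(self) -> SideNetwork:
        return SideNetwork(self.values, self.ids, kind="similarity")


def gip_kernel(
    profiles: np.ndarray,
    ids: Sequence[str] | None = None,
    gamma_prime: float = 1.0,
) -> KernelMatrix:
    """Gaussian interaction-profile kernel over the rows of ``profiles``.

    Parameters
    ----------
    profiles
        One interaction profile per entity (rows).  For a drug-metabolite
        association matrix Y, pass Y for the drug kernel and Y.T for the
        metabolite kernel.
    gamma_prime
        Bandwidth before normalization by the mean squared profile norm.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ShapeError("profiles must be a 2-d matrix with >= 2 rows")
    mean_sq_norm = float(np.mean(np.sum(P * P, axis=1)))
    if mean_sq_norm == 0.0:
        raise DegenerateBandwidthError(
            "all profiles are zero: kernel bandwidth is undefined"
        )
    gamma = gamma_prime / mean_sq_norm
    sq_dists = squareform(pdist(P, metric="sqeuclidean"))
    K = np.exp(-gamma * sq_dists)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    if ids is None:
        ids = [str(i) for i in range(P.shape[0])]
    return KernelMatrix(K, list(ids), gamma=gamma, gamma_prime=gamma_prime)


def cosine_matrix(F: np.ndarray, ids: Sequence[str] | None = None) -> SideNetwork:
    """Pairwise cosine similarity of the rows of a feature matrix.

    Raises if any row is all-zero (its cosine is undefined), naming the
    offending entity.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ShapeError("feature matrix must be 2-dimensional")
    if ids is None:
        ids = [str(i) for i in range(F.shape[0])]
    ids = list(ids)
    norms = np.linalg.norm(F, axis=1)
    if np.any(norms == 0):
        bad = ids[int(np.flatnonzero(norms == 0)[0])]
        raise DegenerateRowError(f"all-zero feature row for entity {bad!r}")
    unit = F / norms[:, None]
    S = unit @ unit.T
    S = np.clip(0.5 * (S + S.T), -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SideNetwork(S, ids, kind="similarity")
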