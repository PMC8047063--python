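"""The Vicus local spectral matrix.

Vicus is a local alternative to the graph Laplacian.  For every node i we
take its k-nearest-neighbor subnetwork (neighbors N(i) plus i itself, i
placed last), row-normalize it into a transition matrix S_i, and run label
diffusion to its terminal state: beta_i is the last row of
(1 - alpha)(I - alpha S_i)^{-1}.  Dividing the neighbor part of beta_i by
1 - beta_i[last] yields row i of a matrix B that reconstructs each node's
(virtual) label from its neighbors; the Vicus matrix is then

    Vir = (I - B)' (I - B),

a positive semidefinite operator whose quadratic form f' Vir f sums the
squared local reconstruction errors (f_i - sum_j B_ij f_j)^2.  Because each
row of B sums to 1, Vir annihilates constant vectors, exactly like a
Laplacian, while being built from purely local diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import SideNetwork
from .errors import ConfigError, ShapeError

__all__ = ["VicusMatrix", "local_propagation_row", "build_B", "vicus_matrix"]

logger = logging.getLogger(__name__)


@dataclass
class VicusMatrix:
    """Vir = (I-B)'(I-B) over one entity class; PSD with Vir @ 1 = 0."""

    values: np.ndarray
    ids: list[str]
    k: int
    alpha: float


def _check_args(net: SideNetwork, k: int, alpha: float) -> int:
    n = net.values.shape[0]
    if net.values.shape[0] != net.values.shape[1]:
        raise ShapeError("Vicus requires a square similarity network")
    if not 1 <= k < n:
        raise ConfigError(f"neighborhood size k={k} must satisfy 1 <= k < n={n}")
    if not 0 < alpha < 1:
        raise ConfigError("alpha must lie in (0, 1)")
    return n


def _neighbors(sim_row: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k most similar entities to i (excluding i).

    Ties are broken by ascending index so the construction is deterministic.
    """
    masked = sim_row.copy()
    masked[i] = -np.inf
    return np.argsort(-masked, kind="stable")[:k]


def local_propagation_row(
    net: SideNetwork, i: int, k: int, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Terminal label-diffusion row beta_i over N(i) + {i} (self placed last).

    Returns ``(beta, neighbor_indices)`` with ``beta`` of length k+1; beta
    sums to 1 because the local transition matrix is row-stochastic.
    """
    _check_args(net, k, alpha)
    nbrs = _neighbors(net.values[i], i, k)
    order = np.concatenate([nbrs, [i]])
    P_sub = np.clip(net.values[np.ix_(order, order)], 0.0, None)
    np.fill_diagonal(P_sub, 0.0)
    row_sums = P_sub.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        P_sub[zero, :] = 1.0
        np.fill_diagonal(P_sub, 0.0)
        row_sums = P_sub.sum(axis=1)
    S = P_sub / row_sums[:, None]
    # beta = last row of (1-alpha)(I - alpha S)^{-1}; solve the transposed system
    e_last = np.zeros(k + 1)
    e_last[-1] = 1.0 - alpha
    beta = np.linalg.solve((np.eye(k + 1) - alpha * S).T, e_last)
    return beta, nbrs


def build_B(net: SideNetwork, k: int, alpha: float) -> sp.csr_matrix:
    """Sparse n x n reconstruction matrix B with <= k nonzeros per row.

    B[i, j] = beta_i[pos(j)] / (1 - beta_i[last]) for j in N(i); every row
    sums to 1.  An isolated node whose self-weight beta_i[last] reaches 1
    falls back to a uniform row over its neighbors (logged).
    """
    n = _check_args(net, k, alpha)
    rows, cols, vals = [], [], []
    for i in range(n):
        beta, nbrs = local_propagation_row(net, i, k, alpha)
        denom = 1.0 - beta[-1]
        if denom <= 0:
            logger.warning("node %d is isolated in its subnetwork; uniform row used", i)
            weights = np.full(k, 1.0 / k)
        else:
            weights = beta[:-1] / denom
        rows.extend([i] * k)
        cols.extend(nbrs.tolist())
        vals.extend(weights.tolist())
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def vicus_matrix(
    net: SideNetwork, k: int | None = None, alpha: float = 0.9
) -> VicusMatrix:
    """Vicus operator Vir = (I-B)'(I-B) of a similarity network.

    ``k`` defaults to min(10, n-1).
    """
    n = net.values.shape[0]
    if k is None:
        k = min(10, n - 1)
    B = build_B(net, k, alpha)
    IB = np.eye(n) - B.toarray()
    Vir = IB.T @ IB
    return VicusMatrix(Vir, list(net.ids), k=k, alpha=alpha)
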