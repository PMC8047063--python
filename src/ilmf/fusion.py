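"""Fusing same-class networks into one low-dimensional feature matrix.

The procedure follows the diffusion-component-analysis family: run a random
walk with restart (RWR) on every network to obtain each node's diffusion
state (the stationary visiting distribution of a walk restarting at that
node), log-transform the states with pseudo-count 1/n, average across
networks, and extract a rank-k embedding from one SVD of the averaged
matrix:

    D   = p (I - (1-p) T)^{-1}          (closed-form RWR, rows = states)
    L   = log(D + 1/n)
    Abar = mean over networks of L
    Abar ~= U_k S_k V_k',   F = U_k S_k^{1/2}

Negative similarities (possible in correlation networks) are clipped to zero
before row normalization, and all-zero rows fall back to a uniform
transition (teleport), so the linear solve is always well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import SideNetwork
from .errors import AlignmentError, DimensionError, ShapeError

__all__ = ["DiffusionStateMatrix", "FeatureMatrix", "rwr_diffusion", "fuse_embed"]


@dataclass
class DiffusionStateMatrix:
    """Row-stochastic matrix of RWR stationary distributions, one row per node."""

    values: np.ndarray
    ids: list[str]
    restart_prob: float


@dataclass
class FeatureMatrix:
    """Entity x dimension embedding produced by :func:`fuse_embed`."""

    values: np.ndarray
    ids: list[str]
    dim: int


def _transition_matrix(weights: np.ndarray) -> np.ndarray:
    W = np.clip(np.asarray(weights, dtype=float), 0.0, None)
    row_sums = W.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        W = W.copy()
        W[zero, :] = 1.0  # teleport fallback for isolated nodes
        row_sums = W.sum(axis=1)
    return W / row_sums[:, None]


def rwr_diffusion(net: SideNetwork, restart_prob: float = 0.5) -> DiffusionStateMatrix:
    """Closed-form random walk with restart on one network.

    Row i solves s = (1-p) s T + p e_i, i.e. s_i = p e_i (I - (1-p) T)^{-1},
    with T the row-normalized (clipped-nonnegative) transition matrix.
    """
    if net.values.shape[0] != net.values.shape[1]:
        raise ShapeError("rwr_diffusion requires a square network")
    if not 0 < restart_prob < 1:
        raise ValueError("restart_prob must lie in (0, 1)")
    T = _transition_matrix(net.values)
    n = T.shape[0]
    M = np.eye(n) - (1.0 - restart_prob) * T
    # D[i, :] = p * e_i M^{-1}  =>  D = p * M^{-1}
    D = restart_prob * np.linalg.inv(M)
    return DiffusionStateMatrix(D, list(net.ids), restart_prob)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip singular vectors so the largest-magnitude entry is positive."""
    U = U.copy()
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def fuse_embed(
    nets: Sequence[SideNetwork],
    k: int,
    restart_prob: float = 0.5,
) -> FeatureMatrix:
    """Fuse one or more same-class networks into an n x k feature matrix.

    Averages the log-transformed diffusion states of all networks and takes
    the rank-k truncated SVD; F = U_k diag(s_k)^{1/2} with a deterministic
    sign convention.
    """
    nets = list(nets)
    if not nets:
        raise AlignmentError("fuse_embed requires at least one network")
    ids = nets[0].ids
    for net in nets[1:]:
        if net.ids != ids:
            raise AlignmentError("all networks must share one id set/order")
    n = len(ids)
    if k > n:
        raise DimensionError(f"k={k} exceeds entity count {n}")
    L = np.zeros((n, n))
    for net in nets:
        D = rwr_diffusion(net, restart_prob).values
        L += np.log(D + 1.0 / n)
    L /= len(nets)
    U, s, _ = np.linalg.svd(L, full_matrices=False)
    F = _fix_signs(U[:, :k]) * np.sqrt(s[:k])[None, :]
    return FeatureMatrix(F, list(ids), dim=k)
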