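"""Neighbor smoothing of latent vectors and final probability scoring.

Entities with no observed interaction in the training matrix have latent
vectors learned only from unobserved pairs, so their representations are
unreliable.  Such an entity borrows the latents of its K most similar
*observed* neighbors (similarity = cosine of the fused features), with a
geometric decay over the neighbor rank:

    w_bar_i = (1 / Q_i) sum_{l=1}^{K} decay^{l-1} S(i, d_l) w_{d_l},
    Q_i     = sum_{l=1}^{K} decay^{l-1} S(i, d_l),

where d_l runs over observed entities sorted by descending similarity to i.
Observed entities pass through unchanged.  The final score of a pair is
sigma(w_bar_i . h_bar_j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .containers import AssociationMatrix, SideNetwork
from .errors import ShapeError, SmoothingError

__all__ = ["SmoothedLatents", "smooth_latents", "predict"]

logger = logging.getLogger(__name__)


@dataclass
class SmoothedLatents:
    W_bar: np.ndarray
    H_bar: np.ndarray
    observed_drugs: np.ndarray      # sorted indices with >= 1 observed interaction
    observed_metabolites: np.ndarray


def _smooth_axis(
    Z: np.ndarray,
    observed: np.ndarray,
    S: np.ndarray,
    K: int,
    decay: float,
    what: str,
) -> np.ndarray:
    n = Z.shape[0]
    if observed.size == 0:
        raise SmoothingError(f"no observed {what} at all; smoothing impossible")
    Z_bar = Z.copy()
    observed_set = set(observed.tolist())
    for i in range(n):
        if i in observed_set:
            continue
        sims = np.clip(S[i, observed], 0.0, None)
        # descending similarity, ties broken by ascending index
        order = np.argsort(-sims, kind="stable")[: min(K, observed.size)]
        weights = decay ** np.arange(order.size) * sims[order]
        Q = weights.sum()
        if Q <= 0:
            logger.warning("%s %d has no positive-similarity observed neighbor; "
                           "left unsmoothed", what, i)
            continue
        Z_bar[i] = (weights / Q) @ Z[observed[order]]
    return Z_bar


def smooth_latents(
    W: np.ndarray,
    H: np.ndarray,
    Y: AssociationMatrix,
    S_d: SideNetwork,
    S_m: SideNetwork,
    K: int = 5,
    decay: float = 0.5,
) -> SmoothedLatents:
    """Smooth latents of entities with no observed interaction in ``Y``.

    ``S_d``/``S_m`` are the consensus similarity matrices (cosine of the
    fused features).  Negative similarities are clipped to zero; fewer than
    K observed entities means all of them are used.
    """
    n, m = Y.shape
    if W.shape[0] != n or H.shape[0] != m:
        raise ShapeError("W/H rows must match the association axes")
    if S_d.n != n or S_m.n != m:
        raise ShapeError("similarity matrices must match the association axes")
    if K < 1:
        raise ValueError("K must be >= 1")
    obs_d = np.flatnonzero(Y.values.sum(axis=1) > 0)
    obs_m = np.flatnonzero(Y.values.sum(axis=0) > 0)
    W_bar = _smooth_axis(W, obs_d, S_d.values, K, decay, "drug")
    H_bar = _smooth_axis(H, obs_m, S_m.values, K, decay, "metabolite")
    return SmoothedLatents(W_bar, H_bar, obs_d, obs_m)


def predict(smoothed: SmoothedLatents) -> np.ndarray:
    """Final probability matrix sigma(W_bar H_bar'); entries in (0, 1)."""
    if smoothed.W_bar.shape[1] != smoothed.H_bar.shape[1]:
        raise ShapeError("smoothed latents must share the latent dimension")
    return expit(smoothed.W_bar @ smoothed.H_bar.T)
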