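"""End-to-end fitting: from an association matrix and side networks to scores.

This is the glue the cross-validation harness and the CLI share.  Given a
training association matrix Y and optional side networks per entity class,
it (1) builds the Gaussian profile kernel of Y for both classes and converts
incidence-profile side networks to kernels, (2) fuses each class's networks
into feature matrices, (3) derives the Vicus operators from the cosine
similarity of those features, (4) trains the factorization, and (5) smooths
latents of unobserved entities before scoring.  Everything downstream of Y
is recomputed from the training matrix alone, so cross-validation through
this path is leakage-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RunConfig
from .containers import AssociationMatrix, SideNetwork
from .core import ILMFModel, TrainState, train
from .fusion import FeatureMatrix, fuse_embed
from .similarity import cosine_matrix, gip_kernel
from .smoothing import predict as _smooth_predict
from .smoothing import smooth_latents
from .vicus import VicusMatrix, vicus_matrix

__all__ = ["FitResult", "build_class_networks", "fit", "fit_predict"]


@dataclass
class FitResult:
    """A trained model plus every intermediate needed for scoring."""

    model: ILMFModel
    state: TrainState
    F_d: FeatureMatrix
    F_m: FeatureMatrix
    S_d: SideNetwork           # cosine of F_d, used for smoothing
    S_m: SideNetwork
    Vir_d: VicusMatrix
    Vir_m: VicusMatrix
    scores: np.ndarray         # smoothed probability matrix P_bar

    @property
    def row_ids(self) -> list[str]:
        return self.F_d.ids

    @property
    def col_ids(self) -> list[str]:
        return self.F_m.ids


def build_class_networks(
    profiles: np.ndarray,
    ids: Sequence[str],
    side_nets: Sequence[SideNetwork],
    gamma_prime: float,
) -> list[SideNetwork]:
    """Assemble the similarity networks of one entity class.

    The Gaussian kernel of the interaction profiles (rows of Y, or of Y' for
    the column class) always contributes; similarity side networks are used
    as-is and incidence profiles are converted via the same kernel.
    """
    nets = [gip_kernel(profiles, ids, gamma_prime).as_side_network()]
    for net in side_nets:
        if net.kind == "incidence_profile":
            nets.append(gip_kernel(net.values, net.ids, gamma_prime).as_side_network())
        else:
            nets.append(net)
    return nets


def fit(
    Y: AssociationMatrix,
    drug_nets: Sequence[SideNetwork] = (),
    met_nets: Sequence[SideNetwork] = (),
    config: RunConfig | None = None,
) -> FitResult:
    """Run the full pipeline on a (training) association matrix.

    Feature dimensions and the Vicus neighborhood are clamped to the entity
    counts so small problems remain valid.
    """
    config = (config or RunConfig()).validate()
    n, m = Y.shape
    d_nets = build_class_networks(Y.values, Y.row_ids, drug_nets, config.gamma_prime)
    m_nets = build_class_networks(Y.values.T, Y.col_ids, met_nets, config.gamma_prime)

    F_d = fuse_embed(d_nets, k=min(config.k1, n), restart_prob=config.rwr_restart)
    F_m = fuse_embed(m_nets, k=min(config.k2, m), restart_prob=config.rwr_restart)

    S_d = cosine_matrix(F_d.values, F_d.ids)
    S_m = cosine_matrix(F_m.values, F_m.ids)
    Vir_d = vicus_matrix(S_d, k=min(config.vicus_k, n - 1), alpha=config.vicus_alpha)
    Vir_m = vicus_matrix(S_m, k=min(config.vicus_k, m - 1), alpha=config.vicus_alpha)

    model, state = train(Y, F_d, F_m, Vir_d, Vir_m, config)

    smoothed = smooth_latents(
        model.W, model.H, Y, S_d, S_m, K=config.smooth_K, decay=config.smooth_decay
    )
    scores = _smooth_predict(smoothed)
    return FitResult(model, state, F_d, F_m, S_d, S_m, Vir_d, Vir_m, scores)


def fit_predict(
    Y: AssociationMatrix,
    drug_nets: Sequence[SideNetwork] = (),
    met_nets: Sequence[SideNetwork] = (),
    config: RunConfig | None = None,
) -> np.ndarray:
    """Convenience wrapper returning only the smoothed score matrix."""
    return fit(Y, drug_nets, met_nets, config).scores
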