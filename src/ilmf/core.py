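"""Inductive logistic matrix factorization with Vicus regularization.

The model scores a (drug i, metabolite j) pair through projected features:

    f_ij = F^d_i U V' F^m_j',      p_ij = sigma(f_ij),

with F^d (n x k1) and F^m (m x k2) the fused feature matrices and
U (k1 x r), V (k2 x r) the learned projections, so W = F^d U and H = F^m V
are the entity latent representations.  Training minimizes the weighted
negative log-likelihood with L2 and dual Vicus graph regularization:

    sum_ij [ (1 + c y_ij - y_ij) log(1 + exp(f_ij)) - c y_ij f_ij ]
      + lambda/2 (||U||_F^2 + ||V||_F^2)
      + phi/2 [ tr(W' Vir_d W) + tr(H' Vir_m H) ],

where c >= 1 up-weights observed pairs, Vir_d smooths the drug latents over
the drug Vicus operator and Vir_m the metabolite latents over the metabolite
one.  Optimization is alternating AdaGrad on U then V with per-parameter
step sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import RunConfig
from .containers import AssociationMatrix
from .errors import ShapeError, TrainingError
from .fusion import FeatureMatrix
from .vicus import VicusMatrix

__all__ = ["ILMFModel", "TrainState", "probability_matrix", "objective", "gradients", "train"]

_ADAGRAD_EPS = 1e-8
_REL_TOL = 1e-6


@dataclass
class ILMFModel:
    """Trained (or initialized) projections plus the features that ground them."""

    U: np.ndarray          # k1 x r
    V: np.ndarray          # k2 x r
    F_d: FeatureMatrix     # n x k1
    F_m: FeatureMatrix     # m x k2
    c: float = 2.0
    lam: float = 1.0
    phi: float = 1.0

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.shape[1] != self.V.shape[1]:
            raise ShapeError("U and V must share the latent dimension r")
        if self.F_d.values.shape[1] != self.U.shape[0]:
            raise ShapeError("F_d columns must match U rows")
        if self.F_m.values.shape[1] != self.V.shape[0]:
            raise ShapeError("F_m columns must match V rows")

    @property
    def r(self) -> int:
        return self.U.shape[1]

    @property
    def W(self) -> np.ndarray:
        """Drug latent representations F^d U."""
        return self.F_d.values @ self.U

    @property
    def H(self) -> np.ndarray:
        """Metabolite latent representations F^m V."""
        return self.F_m.values @ self.V

    def logits(self) -> np.ndarray:
        return self.W @ self.H.T


@dataclass
class TrainState:
    """AdaGrad bookkeeping and the objective trace."""

    n_iter: int = 0
    grad_sq_u: np.ndarray | None = None
    grad_sq_v: np.ndarray | None = None
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False


def probability_matrix(model: ILMFModel) -> np.ndarray:
    """Interaction probabilities sigma(F^d U V' F^m'); entries in (0, 1)."""
    return expit(model.logits())


def _weights(Y: np.ndarray, c: float) -> np.ndarray:
    return 1.0 + c * Y - Y


def objective(
    model: ILMFModel,
    Y: AssociationMatrix,
    Vir_d: VicusMatrix,
    Vir_m: VicusMatrix,
) -> float:
    """Regularized weighted negative log-likelihood (the training objective)."""
    Ymat = Y.values
    if not (np.isfinite(model.U).all() and np.isfinite(model.V).all()):
        raise TrainingError("non-finite model parameters")
    f = model.logits()
    data = float(np.sum(_weights(Ymat, model.c) * np.logaddexp(0.0, f))
                 - model.c * np.sum(Ymat * f))
    l2 = 0.5 * model.lam * (np.sum(model.U ** 2) + np.sum(model.V ** 2))
    W, H = model.W, model.H
    graph = 0.5 * model.phi * (
        float(np.trace(W.T @ Vir_d.values @ W)) + float(np.trace(H.T @ Vir_m.values @ H))
    )
    return data + l2 + graph


def gradients(
    model: ILMFModel,
    Y: AssociationMatrix,
    Vir_d: VicusMatrix,
    Vir_m: VicusMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`objective` with respect to U and V."""
    Ymat = Y.values
    Fd, Fm = model.F_d.values, model.F_m.values
    P = probability_matrix(model)
    G = _weights(Ymat, model.c) * P - model.c * Ymat   # d(objective)/d(logits)
    dU = Fd.T @ G @ (Fm @ model.V) + model.lam * model.U \
        + model.phi * Fd.T @ Vir_d.values @ Fd @ model.U
    dV = Fm.T @ G.T @ (Fd @ model.U) + model.lam * model.V \
        + model.phi * Fm.T @ Vir_m.values @ Fm @ model.V
    return dU, dV


def train(
    Y: AssociationMatrix,
    F_d: FeatureMatrix,
    F_m: FeatureMatrix,
    Vir_d: VicusMatrix,
    Vir_m: VicusMatrix,
    config: RunConfig,
) -> tuple[ILMFModel, TrainState]:
    """Fit U, V by alternating AdaGrad descent.

    U and V start i.i.d. normal with standard deviation 1/sqrt(r) (seeded);
    each iteration updates U from the current gradient, then V from the
    gradient at the updated U.  Stops at ``max_iter`` or when the relative
    objective change falls below 1e-6, and returns the model with the lowest
    objective seen along the trace.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = Y.shape
    if F_d.values.shape[0] != n or F_m.values.shape[0] != m:
        raise ShapeError("feature matrices must match the association axes")
    r = config.r
    U = rng.normal(0.0, 1.0 / np.sqrt(r), size=(F_d.values.shape[1], r))
    V = rng.normal(0.0, 1.0 / np.sqrt(r), size=(F_m.values.shape[1], r))
    model = ILMFModel(U, V, F_d, F_m, c=config.c, lam=config.lam, phi=config.phi)
    state = TrainState(
        grad_sq_u=np.zeros_like(U), grad_sq_v=np.zeros_like(V)
    )

    # Precompute the (small) regularizer cores F' Vir F once.
    Fd, Fm = F_d.values, F_m.values
    Gd = Fd.T @ Vir_d.values @ Fd
    Gm = Fm.T @ Vir_m.values @ Fm
    Ymat = Y.values
    Wt = _weights(Ymat, config.c)

    def _objective_fast() -> float:
        f = (Fd @ model.U) @ (Fm @ model.V).T
        data = float(np.sum(Wt * np.logaddexp(0.0, f)) - config.c * np.sum(Ymat * f))
        l2 = 0.5 * config.lam * (np.sum(model.U ** 2) + np.sum(model.V ** 2))
        graph = 0.5 * config.phi * (
            float(np.sum(model.U * (Gd @ model.U))) + float(np.sum(model.V * (Gm @ model.V)))
        )
        return data + l2 + graph

    obj = _objective_fast()
    state.objective_trace.append(obj)
    best_obj, best_U, best_V = obj, model.U.copy(), model.V.copy()

    for it in range(1, config.max_iter + 1):
        # U step
        P = expit((Fd @ model.U) @ (Fm @ model.V).T)
        G = Wt * P - config.c * Ymat
        dU = Fd.T @ G @ (Fm @ model.V) + config.lam * model.U + config.phi * Gd @ model.U
        state.grad_sq_u += dU ** 2
        model.U = model.U - config.learn_rate * dU / np.sqrt(state.grad_sq_u + _ADAGRAD_EPS)
        # V step (gradient at the updated U)
        P = expit((Fd @ model.U) @ (Fm @ model.V).T)
        G = Wt * P - config.c * Ymat
        dV = Fm.T @ G.T @ (Fd @ model.U) + config.lam * model.V + config.phi * Gm @ model.V
        state.grad_sq_v += dV ** 2
        model.V = model.V - config.learn_rate * dV / np.sqrt(state.grad_sq_v + _ADAGRAD_EPS)

        obj = _objective_fast()
        if not np.isfinite(obj):
            raise TrainingError(f"objective diverged at iteration {it}")
        state.objective_trace.append(obj)
        state.n_iter = it
        if obj < best_obj:
            best_obj, best_U, best_V = obj, model.U.copy(), model.V.copy()
        prev = state.objective_trace[-2]
        if abs(prev - obj) / max(abs(prev), 1e-12) < _REL_TOL:
            state.converged = True
            break

    model.U, model.V = best_U, best_V
    return model, state
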