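import numpy as np
import pytest

from ilmf.config import RunConfig
from ilmf.containers import AssociationMatrix
from ilmf.core import ILMFModel, gradients, objective, probability_matrix, train
from ilmf.errors import TrainingError
from ilmf.fusion import FeatureMatrix
from ilmf.similarity import cosine_matrix
from ilmf.vicus import vicus_matrix

from conftest import random_association, random_similarity


def make_instance(rng, n=6, m=5, k1=4, k2=3, r=2, c=2.0, lam=1.0, phi=1.0):
    Y = random_association(n, m, rng)
    Fd = FeatureMatrix(rng.normal(size=(n, k1)), Y.row_ids, k1)
    Fm = FeatureMatrix(rng.normal(size=(m, k2)), Y.col_ids, k2)
    Vir_d = vicus_matrix(random_similarity(n, rng), k=min(3, n - 1), alpha=0.9)
    Vir_m = vicus_matrix(random_similarity(m, rng), k=min(3, m - 1), alpha=0.9)
    U = rng.normal(size=(k1, r))
    V = rng.normal(size=(k2, r))
    model = ILMFModel(U, V, Fd, Fm, c=c, lam=lam, phi=phi)
    return model, Y, Vir_d, Vir_m


def naive_objective(model, Y, Vir_d, Vir_m):
    """Literal double-loop transcription of the regularized objective."""
    Fd, Fm = model.F_d.values, model.F_m.values
    n, m = Y.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            f = float(Fd[i] @ model.U @ model.V.T @ Fm[j])
            y = Y.values[i, j]
            total += (1 + model.c * y - y) * np.log1p(np.exp(f)) - model.c * y * f
    total += 0.5 * model.lam * (np.sum(model.U**2) + np.sum(model.V**2))
    W = Fd @ model.U
    H = Fm @ model.V
    total += 0.5 * model.phi * (np.trace(W.T @ Vir_d.values @ W) + np.trace(H.T @ Vir_m.values @ H))
    return total


def test_zero_projections_give_half_probabilities(rng):
    model, Y, *_ = make_instance(rng)
    model.U = np.zeros_like(model.U)
    np.testing.assert_array_equal(probability_matrix(model), np.full(Y.shape, 0.5))


def test_probabilities_match_scalar_loop(rng):
    model, Y, *_ = make_instance(rng)
    P = probability_matrix(model)
    Fd, Fm = model.F_d.values, model.F_m.values
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            f = Fd[i] @ model.U @ model.V.T @ Fm[j]
            assert P[i, j] == pytest.approx(np.exp(f) / (1 + np.exp(f)), rel=1e-12)
    assert ((P > 0) & (P < 1)).all()


def test_logistic_symmetry_under_negated_U(rng):
    model, Y, *_ = make_instance(rng)
    P = probability_matrix(model)
    model.U = -model.U
    np.testing.assert_allclose(probability_matrix(model), 1 - P, atol=1e-12)


def test_objective_closed_form_at_zero(rng):
    model, Y, Vd, Vm = make_instance(rng, c=3.0, lam=2.0, phi=5.0)
    model.U = np.zeros_like(model.U)
    model.V = np.zeros_like(model.V)
    expected = np.sum((1 + model.c * Y.values - Y.values) * np.log(2.0))
    assert objective(model, Y, Vd, Vm) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("c", [1.0, 2.0, 5.0])
@pytest.mark.parametrize("lam,phi", [(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)])
def test_objective_matches_double_loop(rng, c, lam, phi):
    model, Y, Vd, Vm = make_instance(rng, c=c, lam=lam, phi=phi)
    assert objective(model, Y, Vd, Vm) == pytest.approx(
        naive_objective(model, Y, Vd, Vm), rel=1e-10
    )


def test_c_equal_one_is_unweighted_logistic_loss(rng):
    model, Y, Vd, Vm = make_instance(rng, c=1.0, lam=0.0, phi=0.0)
    f = model.logits()
    expected = float(np.sum(np.log1p(np.exp(f)) - Y.values * f))
    assert objective(model, Y, Vd, Vm) == pytest.approx(expected, rel=1e-10)


def test_increasing_c_increases_data_term_with_positives(rng):
    model, Y, Vd, Vm = make_instance(rng, lam=0.0, phi=0.0)
    assert Y.values.sum() >= 1
    lo = objective(model, Y, Vd, Vm)
    model.c = model.c + 1
    hi = objective(model, Y, Vd, Vm)
    assert hi > lo


def finite_difference_grads(model, Y, Vd, Vm, eps=1e-6):
    dU = np.zeros_like(model.U)
    for idx in np.ndindex(*model.U.shape):
        orig = model.U[idx]
        model.U[idx] = orig + eps
        hi = objective(model, Y, Vd, Vm)
        model.U[idx] = orig - eps
        lo = objective(model, Y, Vd, Vm)
        model.U[idx] = orig
        dU[idx] = (hi - lo) / (2 * eps)
    dV = np.zeros_like(model.V)
    for idx in np.ndindex(*model.V.shape):
        orig = model.V[idx]
        model.V[idx] = orig + eps
        hi = objective(model, Y, Vd, Vm)
        model.V[idx] = orig - eps
        lo = objective(model, Y, Vd, Vm)
        model.V[idx] = orig
        dV[idx] = (hi - lo) / (2 * eps)
    return dU, dV


def test_gradients_match_finite_differences(rng):
    for _ in range(5):
        model, Y, Vd, Vm = make_instance(rng, c=2.0, lam=0.7, phi=1.3)
        dU, dV = gradients(model, Y, Vd, Vm)
        fdU, fdV = finite_difference_grads(model, Y, Vd, Vm)
        assert np.linalg.norm(dU - fdU) / max(np.linalg.norm(fdU), 1e-12) < 1e-5
        assert np.linalg.norm(dV - fdV) / max(np.linalg.norm(fdV), 1e-12) < 1e-5


def test_gradient_matches_logistic_regression_form(rng):
    """phi=0, lam=0, c=1: dU is the plain logistic-regression gradient F_d'(P-Y)F_mV."""
    model, Y, Vd, Vm = make_instance(rng, c=1.0, lam=0.0, phi=0.0)
    dU, dV = gradients(model, Y, Vd, Vm)
    P = probability_matrix(model)
    Fd, Fm = model.F_d.values, model.F_m.values
    np.testing.assert_allclose(dU, Fd.T @ (P - Y.values) @ Fm @ model.V, atol=1e-10)
    np.testing.assert_allclose(dV, Fm.T @ (P - Y.values).T @ Fd @ model.U, atol=1e-10)


def test_rotation_invariance_of_objective(rng):
    """U -> UR, V -> VR with R orthogonal leaves the objective unchanged."""
    model, Y, Vd, Vm = make_instance(rng, r=3)
    base = objective(model, Y, Vd, Vm)
    A = rng.normal(size=(3, 3))
    R, _ = np.linalg.qr(A)
    model.U = model.U @ R
    model.V = model.V @ R
    assert objective(model, Y, Vd, Vm) == pytest.approx(base, rel=1e-10)


def test_training_descends_and_is_deterministic(rng):
    model, Y, Vd, Vm = make_instance(rng)
    cfg = RunConfig(r=2, k1=4, k2=3, max_iter=50, seed=7).validate()
    m1, s1 = train(Y, model.F_d, model.F_m, Vd, Vm, cfg)
    assert s1.objective_trace[-1] <= s1.objective_trace[0]
    m2, s2 = train(Y, model.F_d, model.F_m, Vd, Vm, cfg)
    np.testing.assert_array_equal(m1.U, m2.U)
    np.testing.assert_array_equal(m1.V, m2.V)
    assert s1.objective_trace == s2.objective_trace


def test_training_recovers_planted_logits_above_chance(rng):
    """Held-out probabilities from a planted logit model beat random ranking."""
    from scipy.special import expit
    from sklearn.metrics import roc_auc_score

    n, m, r = 12, 12, 2
    A = rng.normal(size=(n, r))
    B = rng.normal(size=(m, r))
    P_star = expit(2.0 * A @ B.T)
    Y_vals = (rng.random((n, m)) < P_star).astype(float)
    Y = AssociationMatrix(Y_vals, [f"d{i}" for i in range(n)], [f"m{j}" for j in range(m)])
    Fd = FeatureMatrix(A, Y.row_ids, r)
    Fm = FeatureMatrix(B, Y.col_ids, r)
    Vd = vicus_matrix(cosine_matrix(A, Y.row_ids), k=3, alpha=0.9)
    Vm = vicus_matrix(cosine_matrix(B, Y.col_ids), k=3, alpha=0.9)
    cfg = RunConfig(r=r, c=2.0, lam=0.1, phi=0.0, max_iter=200, seed=3)
    model, _ = train(Y, Fd, Fm, Vd, Vm, cfg)
    # fresh draw from the same planted model as "held-out" data
    Y_new = (rng.random((n, m)) < P_star).astype(float)
    if 0 < Y_new.sum() < Y_new.size:
        auc = roc_auc_score(Y_new.ravel(), probability_matrix(model).ravel())
        assert auc > 0.65


def test_nan_input_rejected(rng):
    model, Y, Vd, Vm = make_instance(rng)
    model.U[0, 0] = np.nan
    with pytest.raises(TrainingError):
        objective(model, Y, Vd, Vm)
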