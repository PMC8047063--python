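"""Seeded synthetic bipartite datasets with planted low-rank logit structure.

The generator mirrors the statistical assumptions of the factorization:
latent factors A (n x q) and B (m x q) are drawn i.i.d. normal, the planted
probability matrix is P* = sigma(A B' + b0) with the intercept b0 chosen by
bisection so that mean(P*) hits a target density, Y is drawn Bernoulli(P*),
and each side network is the cosine similarity of the factors plus i.i.d.
normal noise (symmetrized, diagonal one).  The ``atlas_like`` preset
emulates a sparse drug-metabolite association atlas: 42 rows x 150 columns
at density 0.082 — the sparsity regime the method targets — with rank-5
structure and mild network noise.

The RNG stream is consumed in a fixed order (factors, Y, networks) so a
dataset regenerates bit-identically from (params, seed); the intercept
search is deterministic and uses no randomness.

A deliberately misspecified block preset (piecewise-constant P*, no low-rank
logit structure) is included for qualitative robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .containers import AssociationMatrix, SideNetwork
from .errors import GenerationError, ShapeError
from .evaluation import metrics

__all__ = ["PlantedTruth", "SyntheticDataset", "generate", "generate_block", "atlas_like", "planted_eval"]


@dataclass
class PlantedTruth:
    P_star: np.ndarray
    A: np.ndarray | None
    B: np.ndarray | None
    intercept: float


@dataclass
class SyntheticDataset:
    Y: AssociationMatrix
    drug_nets: list[SideNetwork]
    met_nets: list[SideNetwork]
    truth: PlantedTruth
    seed: int
    params: dict = field(default_factory=dict)


def _solve_intercept(logits: np.ndarray, density_target: float) -> float:
    """Bisection for b0 such that mean(sigma(logits + b0)) = density_target."""
    if not 0 < density_target < 1:
        raise GenerationError("density_target must lie in (0, 1)")
    lo, hi = -40.0, 40.0
    if not expit(logits + lo).mean() < density_target < expit(logits + hi).mean():
        raise GenerationError("density target unreachable for these factors")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(logits + mid).mean() < density_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _noisy_cosine_nets(
    factors: np.ndarray,
    ids: list[str],
    n_nets: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> list[SideNetwork]:
    norms = np.linalg.norm(factors, axis=1, keepdims=True)
    unit = factors / norms
    base = unit @ unit.T
    nets = []
    for _ in range(n_nets):
        noise = rng.normal(0.0, noise_sd, size=base.shape) if noise_sd > 0 else 0.0
        S = base + noise
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 1.0)
        nets.append(SideNetwork(S, ids, kind="similarity"))
    return nets


def generate(
    n_drugs: int = 42,
    n_metabolites: int = 150,
    true_rank: int = 5,
    density_target: float = 0.082,
    noise_sd: float = 0.1,
    n_side_nets: int = 2,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate one dataset with planted low-rank logit structure.

    Consumes the seeded RNG stream in a documented order: factors A and B,
    then the Bernoulli draw of Y, then the side-network noise (drug networks
    before metabolite networks).
    """
    if true_rank > min(n_drugs, n_metabolites):
        raise GenerationError("true_rank must not exceed min(n_drugs, n_metabolites)")
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n_drugs, true_rank))
    B = rng.normal(size=(n_metabolites, true_rank))
    logits = A @ B.T
    b0 = _solve_intercept(logits, density_target)
    P_star = expit(logits + b0)
    Y_vals = (rng.random(size=P_star.shape) < P_star).astype(float)
    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
    met_ids = [f"M{j:03d}" for j in range(n_metabolites)]
    drug_nets = _noisy_cosine_nets(A, drug_ids, n_side_nets, noise_sd, rng)
    met_nets = _noisy_cosine_nets(B, met_ids, n_side_nets, noise_sd, rng)
    return SyntheticDataset(
        Y=AssociationMatrix(Y_vals, drug_ids, met_ids),
        drug_nets=drug_nets,
        met_nets=met_nets,
        truth=PlantedTruth(P_star, A, B, b0),
        seed=seed,
        params={
            "n_drugs": n_drugs, "n_metabolites": n_metabolites,
            "true_rank": true_rank, "density_target": density_target,
            "noise_sd": noise_sd, "n_side_nets": n_side_nets,
        },
    )


def generate_block(
    n_drugs: int = 40,
    n_metabolites: int = 60,
    n_row_blocks: int = 4,
    n_col_blocks: int = 4,
    p_high: float = 0.4,
    p_low: float = 0.02,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Misspecified preset: block-constant P* instead of low-rank logits.

    Matched (row-block, col-block) pairs interact with probability
    ``p_high``, everything else with ``p_low``.  Side networks are noisy
    indicators of shared block membership.
    """
    rng = np.random.default_rng(seed)
    row_blocks = rng.integers(0, n_row_blocks, size=n_drugs)
    col_blocks = rng.integers(0, n_col_blocks, size=n_metabolites)
    match = row_blocks[:, None] == (col_blocks[None, :] % n_row_blocks)
    P_star = np.where(match, p_high, p_low)
    Y_vals = (rng.random(size=P_star.shape) < P_star).astype(float)
    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
    met_ids = [f"M{j:03d}" for j in range(n_metabolites)]
    onehot_d = np.eye(n_row_blocks)[row_blocks]
    onehot_m = np.eye(n_col_blocks)[col_blocks]
    drug_nets = _noisy_cosine_nets(onehot_d + 1e-3, drug_ids, 1, noise_sd, rng)
    met_nets = _noisy_cosine_nets(onehot_m + 1e-3, met_ids, 1, noise_sd, rng)
    return SyntheticDataset(
        Y=AssociationMatrix(Y_vals, drug_ids, met_ids),
        drug_nets=drug_nets,
        met_nets=met_nets,
        truth=PlantedTruth(P_star, None, None, 0.0),
        seed=seed,
        params={"preset": "block", "n_drugs": n_drugs, "n_metabolites": n_metabolites},
    )


def atlas_like(seed: int = 0) -> SyntheticDataset:
    """The default emulation preset: 42 x 150 at density ~0.082, rank 5."""
    return generate(seed=seed)


def planted_eval(
    dataset: SyntheticDataset,
    scores: np.ndarray,
    pairs: np.ndarray | None = None,
) -> dict:
    """Score a prediction matrix against the planted truth.

    Returns the AUC of ``scores`` for predicting Y on ``pairs`` (flat
    indices; all pairs when omitted) and the Pearson correlation between
    the scores and the planted probabilities P* on those pairs.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != dataset.Y.shape:
        raise ShapeError("score matrix must match the dataset shape")
    flat_scores = scores.ravel()
    flat_labels = dataset.Y.values.ravel()
    flat_truth = dataset.truth.P_star.ravel()
    if pairs is not None:
        flat_scores = flat_scores[pairs]
        flat_labels = flat_labels[pairs]
        flat_truth = flat_truth[pairs]
    auc, aupr, f1 = metrics(flat_scores, flat_labels)
    if np.std(flat_scores) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(flat_scores, flat_truth)[0, 1])
    return {"auc": auc, "aupr": aupr, "f1_max": f1, "truth_correlation": corr}
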