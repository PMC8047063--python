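"""Repeated five-fold pair-wise cross-validation, metrics, grid search.

CV operates on *pairs*: within each repeat, the observed (y=1) and
unobserved (y=0) pairs are independently shuffled and split into five
near-equal parts, so each fold's test set is a stratified sample of cells.
Held-out positives are zeroed in the training copy of Y, and every
Y-derived quantity (kernels, embeddings, Vicus operators, observed-entity
sets) is recomputed from that training matrix only.

Metrics: AUC (rank statistic with tie correction), AUPR in its
average-precision (stepwise) form, and the maximum F1 over all score
thresholds ("F1-max"; the threshold is otherwise arbitrary for a ranking
method).  Aggregates are means over repeats of per-repeat fold means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .config import RunConfig
from .containers import AssociationMatrix, SideNetwork
from .errors import FoldError, MetricError, ShapeError
from .pipeline import fit_predict

__all__ = [
    "FoldPlan",
    "CVReport",
    "make_folds",
    "metrics",
    "cross_validate",
    "grid_search",
    "rank_novel",
    "DEFAULT_GRIDS",
]

logger = logging.getLogger(__name__)

# Grid-search ranges: lambda, phi over powers of two from 1/8 to 8; latent
# dimension r from 5 to 12; importance level c from 2 to 8.
DEFAULT_GRIDS: dict[str, tuple] = {
    "lam": tuple(2.0 ** e for e in range(-3, 4)),
    "phi": tuple(2.0 ** e for e in range(-3, 4)),
    "c": tuple(float(c) for c in range(2, 9)),
    "r": tuple(range(5, 13)),
}


@dataclass
class FoldPlan:
    """Test-pair index sets for every (repeat, fold); flat indices into Y."""

    n_rows: int
    n_cols: int
    test_pairs: list[list[np.ndarray]]   # [repeat][fold] -> flat indices
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.test_pairs)

    @property
    def n_folds(self) -> int:
        return len(self.test_pairs[0])


@dataclass
class CVReport:
    """Per-fold metrics plus the aggregates the protocol reports."""

    fold_metrics: pd.DataFrame           # columns: repeat, fold, auc, aupr, f1
    config: RunConfig
    plan_seed: int
    mean_auc: float = field(init=False)
    mean_aupr: float = field(init=False)
    mean_f1: float = field(init=False)
    std_auc: float = field(init=False)
    std_aupr: float = field(init=False)
    std_f1: float = field(init=False)

    def __post_init__(self) -> None:
        per_repeat = self.fold_metrics.groupby("repeat")[["auc", "aupr", "f1"]].mean()
        self.mean_auc = float(per_repeat["auc"].mean())
        self.mean_aupr = float(per_repeat["aupr"].mean())
        self.mean_f1 = float(per_repeat["f1"].mean())
        self.std_auc = float(per_repeat["auc"].std(ddof=0))
        self.std_aupr = float(per_repeat["aupr"].std(ddof=0))
        self.std_f1 = float(per_repeat["f1"].std(ddof=0))

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "mean_aupr": self.mean_aupr,
            "mean_f1_max": self.mean_f1,
            "std_auc": self.std_auc,
            "std_aupr": self.std_aupr,
            "std_f1_max": self.std_f1,
            "aupr_form": "average_precision",
            "f1_form": "max_over_thresholds",
            "plan_seed": self.plan_seed,
            "config": self.config.to_dict(),
            "folds": self.fold_metrics.to_dict(orient="records"),
        }


def make_folds(
    Y: AssociationMatrix,
    n_folds: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Stratified partition of all n*m pairs, repeated ``n_repeats`` times.

    Positives and negatives are each shuffled and split into ``n_folds``
    near-equal parts, so every test set holds ~1/n_folds of each class.
    """
    flat = Y.values.ravel()
    pos = np.flatnonzero(flat == 1)
    neg = np.flatnonzero(flat == 0)
    if pos.size < n_folds or neg.size < n_folds:
        raise FoldError(
            f"need >= {n_folds} observed and unobserved pairs, "
            f"got {pos.size} / {neg.size}"
        )
    rng = np.random.default_rng(seed)
    plan: list[list[np.ndarray]] = []
    for _ in range(n_repeats):
        pos_split = np.array_split(rng.permutation(pos), n_folds)
        neg_split = np.array_split(rng.permutation(neg), n_folds)
        plan.append(
            [np.sort(np.concatenate([p, q])) for p, q in zip(pos_split, neg_split)]
        )
    return FoldPlan(Y.shape[0], Y.shape[1], plan, seed)


def metrics(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float, float]:
    """(AUC, AUPR, F1-max) for one set of scored pairs.

    AUPR is average precision (stepwise interpolation); F1-max scans all
    thresholds of the precision-recall curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ShapeError("scores and labels must have identical shape")
    if labels.min() == labels.max():
        raise MetricError("both classes must be present to compute metrics")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    with np.errstate(invalid="ignore"):
        f1 = 2 * precision * recall / (precision + recall)
    f1_max = float(np.nanmax(f1))
    return auc, aupr, f1_max


def cross_validate(
    Y: AssociationMatrix,
    drug_nets: Sequence[SideNetwork] = (),
    met_nets: Sequence[SideNetwork] = (),
    config: RunConfig | None = None,
    plan: FoldPlan | None = None,
) -> CVReport:
    """Run the full pipeline per fold and aggregate AUC/AUPR/F1-max.

    Per fold: held-out positives are zeroed in the training Y; kernels,
    embeddings, Vicus matrices and the observed-entity sets are recomputed
    from that matrix; the smoothed score matrix is evaluated on the held-out
    pairs against their true labels.
    """
    config = (config or RunConfig()).validate()
    if plan is None:
        plan = make_folds(Y, seed=config.seed)
    if (plan.n_rows, plan.n_cols) != Y.shape:
        raise ShapeError("fold plan does not match the association matrix")
    flat_truth = Y.values.ravel()
    rows = []
    for rep, folds in enumerate(plan.test_pairs):
        for fold, test_idx in enumerate(folds):
            Y_train_flat = flat_truth.copy()
            Y_train_flat[test_idx] = 0.0
            Y_train = AssociationMatrix(
                Y_train_flat.reshape(Y.shape), Y.row_ids, Y.col_ids
            )
            scores = fit_predict(Y_train, drug_nets, met_nets, config)
            auc, aupr, f1 = metrics(scores.ravel()[test_idx], flat_truth[test_idx])
            rows.append({"repeat": rep, "fold": fold, "auc": auc, "aupr": aupr, "f1": f1})
    return CVReport(pd.DataFrame(rows), config, plan.seed)


def grid_search(
    Y: AssociationMatrix,
    drug_nets: Sequence[SideNetwork] = (),
    met_nets: Sequence[SideNetwork] = (),
    plan: FoldPlan | None = None,
    grids: dict | None = None,
    base_config: RunConfig | None = None,
) -> tuple[RunConfig, pd.DataFrame]:
    """Exhaustive CV over the Cartesian grid of (lambda, phi, c, r).

    Returns the configuration maximizing mean AUPR (ties broken by mean
    AUC, then smallest r) and the full score table.
    """
    grids = dict(DEFAULT_GRIDS, **(grids or {}))
    for key in grids:
        if key not in DEFAULT_GRIDS:
            raise ValueError(f"unknown grid axis: {key!r}")
        if len(grids[key]) == 0:
            raise ValueError(f"empty grid for {key!r}")
    base = (base_config or RunConfig()).validate()
    if plan is None:
        plan = make_folds(Y, seed=base.seed)
    rows = []
    for lam, phi, c, r in product(grids["lam"], grids["phi"], grids["c"], grids["r"]):
        cfg = base.replace(lam=lam, phi=phi, c=c, r=int(r))
        report = cross_validate(Y, drug_nets, met_nets, cfg, plan)
        rows.append(
            {"lambda": lam, "phi": phi, "c": c, "r": int(r),
             "auc": report.mean_auc, "aupr": report.mean_aupr, "f1": report.mean_f1}
        )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        by=["aupr", "auc", "r"], ascending=[False, False, True], kind="stable"
    ).iloc[0]
    best_config = base.replace(
        lam=float(best["lambda"]), phi=float(best["phi"]),
        c=float(best["c"]), r=int(best["r"]),
    )
    return best_config, table


def rank_novel(
    Y: AssociationMatrix,
    scores: np.ndarray,
    top_k: int = 20,
) -> list[tuple[str, str, float]]:
    """Unknown pairs (y=0) ranked by score descending, truncated to top_k.

    Ties are broken by row index, then column index.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != Y.shape:
        raise ShapeError("score matrix must match the association matrix")
    rows_idx, cols_idx = np.nonzero(Y.values == 0)
    if top_k > rows_idx.size:
        logger.warning(
            "top_k=%d exceeds the %d unknown pairs; truncating", top_k, rows_idx.size
        )
        top_k = rows_idx.size
    vals = scores[rows_idx, cols_idx]
    order = np.lexsort((cols_idx, rows_idx, -vals))[:top_k]
    return [
        (Y.row_ids[rows_idx[o]], Y.col_ids[cols_idx[o]], float(vals[o])) for o in order
    ]
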