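import numpy as np
import pytest

from ilmf.config import RunConfig
from ilmf.containers import AssociationMatrix
from ilmf.errors import FoldError, MetricError
from ilmf.evaluation import (
    cross_validate,
    grid_search,
    make_folds,
    metrics,
    rank_novel,
)
from ilmf.synthetic import generate

from conftest import random_association

SMALL_CFG = dict(r=3, k1=6, k2=6, vicus_k=4, max_iter=40)


def test_folds_partition_all_pairs(small_assoc):
    plan = make_folds(small_assoc, seed=0)
    n_pairs = small_assoc.values.size
    for folds in plan.test_pairs:
        combined = np.concatenate(folds)
        assert combined.size == n_pairs
        assert np.array_equal(np.sort(combined), np.arange(n_pairs))


def test_folds_stratify_positives(small_assoc):
    plan = make_folds(small_assoc, seed=0)
    flat = small_assoc.values.ravel()
    P = int(flat.sum())
    for folds in plan.test_pairs:
        for test_idx in folds:
            pos = int(flat[test_idx].sum())
            assert pos in (P // 5, P // 5 + 1)


def test_folds_deterministic_and_seed_sensitive(small_assoc):
    a = make_folds(small_assoc, seed=4)
    b = make_folds(small_assoc, seed=4)
    c = make_folds(small_assoc, seed=5)
    for fa, fb in zip(a.test_pairs, b.test_pairs):
        for xa, xb in zip(fa, fb):
            np.testing.assert_array_equal(xa, xb)
    assert any(
        not np.array_equal(xa, xc)
        for fa, fc in zip(a.test_pairs, c.test_pairs)
        for xa, xc in zip(fa, fc)
    )


def test_too_few_positives_raises():
    Y = AssociationMatrix(
        np.eye(4)[:2], ["d0", "d1"], ["m0", "m1", "m2", "m3"]
    )
    with pytest.raises(FoldError):
        make_folds(Y, n_folds=5)


def pairwise_auc(scores, labels):
    """O(P*N) concordance with half credit for ties (exact integer counting)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    half_wins = sum(2 * (p > q) + (p == q) for p in pos for q in neg)
    return half_wins / (2 * len(pos) * len(neg))


def test_auc_matches_concordance_oracle(rng):
    for _ in range(100):
        scores = rng.integers(0, 8, size=20).astype(float)  # many ties
        labels = rng.integers(0, 2, size=20)
        if labels.min() == labels.max():
            continue
        auc, _, _ = metrics(scores, labels)
        assert auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


def test_perfect_separation_gives_all_ones(rng):
    labels = np.array([0] * 10 + [1] * 10)
    scores = labels + rng.uniform(0, 0.4, size=20) - 0.2
    auc, aupr, f1 = metrics(scores, labels)
    assert auc == pytest.approx(1.0, abs=1e-12)
    assert aupr == pytest.approx(1.0, abs=1e-12)
    assert f1 == pytest.approx(1.0, abs=1e-12)


def test_random_scores_near_half_auc(rng):
    labels = rng.integers(0, 2, size=4000)
    scores = rng.normal(size=4000)
    auc, _, _ = metrics(scores, labels)
    assert 0.45 < auc < 0.55


def test_single_class_rejected():
    with pytest.raises(MetricError):
        metrics([0.2, 0.8], [1, 1])


def test_cross_validate_deterministic(rng):
    ds = generate(n_drugs=10, n_metabolites=12, true_rank=2, density_target=0.3,
                  noise_sd=0.05, n_side_nets=1, seed=11)
    cfg = RunConfig(seed=2, **SMALL_CFG)
    plan = make_folds(ds.Y, n_folds=5, n_repeats=1, seed=3)
    r1 = cross_validate(ds.Y, ds.drug_nets, ds.met_nets, cfg, plan)
    r2 = cross_validate(ds.Y, ds.drug_nets, ds.met_nets, cfg, plan)
    assert r1.fold_metrics.equals(r2.fold_metrics)
    assert r1.mean_auc == r2.mean_auc


def test_cross_validate_beats_permuted_null(rng):
    """Planted structure is recovered above chance; permuted labels are not."""
    ds = generate(n_drugs=14, n_metabolites=16, true_rank=2, density_target=0.25,
                  noise_sd=0.05, n_side_nets=1, seed=5)
    cfg = RunConfig(seed=1, **SMALL_CFG)
    plan = make_folds(ds.Y, n_folds=5, n_repeats=1, seed=1)
    planted = cross_validate(ds.Y, ds.drug_nets, ds.met_nets, cfg, plan)
    flat = np.random.default_rng(9).permutation(ds.Y.values.ravel())
    Y_null = AssociationMatrix(flat.reshape(ds.Y.shape), ds.Y.row_ids, ds.Y.col_ids)
    plan_null = make_folds(Y_null, n_folds=5, n_repeats=1, seed=1)
    null = cross_validate(Y_null, ds.drug_nets, ds.met_nets, cfg, plan_null)
    assert planted.mean_auc > null.mean_auc
    assert 0.3 < null.mean_auc < 0.7


def test_training_matrix_contains_no_heldout_positives(small_assoc):
    """Leakage guard: the training Y seen by each fold has held-out positives zeroed."""
    plan = make_folds(small_assoc, seed=0)
    flat = small_assoc.values.ravel()
    for folds in plan.test_pairs:
        for test_idx in folds:
            train_flat = flat.copy()
            train_flat[test_idx] = 0.0
            assert train_flat[test_idx].sum() == 0
            # positives outside the test set are untouched
            mask = np.ones(flat.size, bool)
            mask[test_idx] = False
            np.testing.assert_array_equal(train_flat[mask], flat[mask])


def test_grid_search_singleton_equals_cross_validate(rng):
    ds = generate(n_drugs=10, n_metabolites=10, true_rank=2, density_target=0.3,
                  noise_sd=0.05, n_side_nets=1, seed=21)
    base = RunConfig(seed=2, **SMALL_CFG)
    plan = make_folds(ds.Y, n_folds=5, n_repeats=1, seed=2)
    grids = {"lam": [1.0], "phi": [0.5], "c": [2.0], "r": [3]}
    best, table = grid_search(ds.Y, ds.drug_nets, ds.met_nets, plan, grids, base)
    assert len(table) == 1
    direct = cross_validate(ds.Y, ds.drug_nets, ds.met_nets,
                            base.replace(lam=1.0, phi=0.5, c=2.0, r=3), plan)
    assert table.iloc[0]["auc"] == pytest.approx(direct.mean_auc)
    assert table.iloc[0]["aupr"] == pytest.approx(direct.mean_aupr)
    assert best.phi == 0.5 and best.lam == 1.0


def test_grid_search_best_cell_replays(rng):
    ds = generate(n_drugs=10, n_metabolites=10, true_rank=2, density_target=0.3,
                  noise_sd=0.05, n_side_nets=1, seed=22)
    base = RunConfig(seed=2, **SMALL_CFG)
    plan = make_folds(ds.Y, n_folds=5, n_repeats=1, seed=2)
    grids = {"lam": [0.5, 2.0], "phi": [0.0, 1.0], "c": [2.0], "r": [3]}
    best, table = grid_search(ds.Y, ds.drug_nets, ds.met_nets, plan, grids, base)
    assert len(table) == 4
    replay = cross_validate(ds.Y, ds.drug_nets, ds.met_nets, best, plan)
    assert replay.mean_aupr == pytest.approx(table["aupr"].max())


def test_default_grid_has_expected_cell_count():
    from ilmf.evaluation import DEFAULT_GRIDS

    cells = (len(DEFAULT_GRIDS["lam"]) * len(DEFAULT_GRIDS["phi"])
             * len(DEFAULT_GRIDS["c"]) * len(DEFAULT_GRIDS["r"]))
    assert cells == 7 * 7 * 7 * 8 == 2744


def test_rank_novel_matches_full_sort(rng):
    Y = random_association(6, 7, rng)
    scores = rng.random(Y.shape)
    ranked = rank_novel(Y, scores, top_k=10)
    zeros = [(i, j) for i in range(6) for j in range(7) if Y.values[i, j] == 0]
    expected = sorted(zeros, key=lambda t: (-scores[t], t[0], t[1]))[:10]
    assert [(Y.row_ids[i], Y.col_ids[j], float(scores[i, j])) for i, j in expected] == ranked


def test_rank_novel_edge_cases(rng):
    Y = AssociationMatrix(np.ones((3, 3)), list("abc"), list("xyz"))
    assert rank_novel(Y, np.random.default_rng(0).random((3, 3)), top_k=5) == []
    Y2 = random_association(4, 4, rng)
    n_zeros = int((Y2.values == 0).sum())
    assert len(rank_novel(Y2, rng.random((4, 4)), top_k=n_zeros + 10)) == n_zeros
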