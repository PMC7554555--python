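"""Task construction, split plans, grid search, metrics, distance profiles."""

import numpy as np
import pandas as pd
import pytest

from kinemid import (ClassificationTask, GridSearchSpec, ParameterError, SplitError,
                     TaskError, build_task_matrix, chance_accuracy, compute_metrics,
                     distance_availability, distance_profile, grid_search_cost,
                     make_split_plan, normalized_confusion, run_task)

from conftest import TINY_PROTOCOL, binomial_chance_band


# ---------------------------------------------------------------------------
# task matrices
# ---------------------------------------------------------------------------

def test_task_matrix_shapes(tiny_features):
    proto = TINY_PROTOCOL
    X, y, lab, rows = build_task_matrix(tiny_features, ClassificationTask("participant"))
    assert X.shape == (proto.n_subjects * proto.k80_kicks_per_leg, 27 * 101)
    assert len(np.unique(y)) == proto.n_subjects

    X, y, _, _ = build_task_matrix(tiny_features, ClassificationTask("participant", intensity="K100"))
    assert X.shape[0] == proto.n_subjects * proto.k100_kicks_per_leg

    X, y, _, _ = build_task_matrix(tiny_features, ClassificationTask("block", subject=0))
    assert X.shape[0] == proto.k80_kicks_per_leg
    n_classes = proto.n_sets * proto.blocks_per_set
    counts = np.bincount(y, minlength=n_classes)
    assert np.all(counts == proto.kicks_per_block)


def test_empty_selection_raises(tiny_features):
    with pytest.raises(TaskError):
        build_task_matrix(tiny_features, ClassificationTask("block", subject=99))


def test_block_classes_are_set_major(tiny_features):
    _, y, lab, _ = build_task_matrix(tiny_features, ClassificationTask("block", subject=1))
    expected = 3 * (lab["set"].to_numpy() - 1) + lab["block"].to_numpy() - 1
    assert np.array_equal(y, expected)


def test_intra_task_requires_subject():
    with pytest.raises(ParameterError):
        ClassificationTask("set")


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind, intensity, subject, expected_folds", [
    ("participant", "K80", None, TINY_PROTOCOL.n_sets),
    ("participant", "K100", None, TINY_PROTOCOL.k100_timepoints),
    ("block", "K80", 0, TINY_PROTOCOL.kicks_per_block),
    ("set", "K80", 0, TINY_PROTOCOL.kicks_per_block),
    ("block_within_set", "K80", 0, TINY_PROTOCOL.n_sets),
])
def test_split_plans_cover_each_kick_exactly_once(tiny_features, kind, intensity,
                                                  subject, expected_folds):
    task = ClassificationTask(kind, intensity=intensity, subject=subject)
    _, y, lab, _ = build_task_matrix(tiny_features, task)
    plan = make_split_plan(task, lab)
    assert plan.n_folds == expected_folds
    all_test = np.concatenate([t for _, t in plan.folds])
    assert sorted(all_test) == list(range(len(lab)))  # coverage, no duplicates
    # evenly distributed across classes within each fold
    for _, test in plan.folds:
        counts = np.bincount(y[test])
        counts = counts[counts > 0]
        assert counts.min() == counts.max()


def test_split_plan_fold_sizes_follow_structure(tiny_features):
    proto = TINY_PROTOCOL
    task = ClassificationTask("participant")
    _, _, lab, _ = build_task_matrix(tiny_features, task)
    plan = make_split_plan(task, lab)
    per_set = proto.n_subjects * proto.blocks_per_set * proto.kicks_per_block
    for train, test in plan.folds:
        assert len(test) == per_set
        assert len(train) == (proto.n_sets - 1) * per_set

    task = ClassificationTask("block", subject=0)
    _, _, lab, _ = build_task_matrix(tiny_features, task)
    plan = make_split_plan(task, lab)
    n_blocks = proto.n_sets * proto.blocks_per_set
    for train, test in plan.folds:
        assert len(test) == n_blocks
        assert len(train) == n_blocks * (proto.kicks_per_block - 1)


def test_split_plan_too_small_structure():
    lab = pd.DataFrame({"set": [1] * 4, "block": [1, 1, 2, 2], "kick": [1, 2, 1, 2],
                        "subject": 0, "leg": "left", "intensity": "K80"})
    with pytest.raises(SplitError):
        make_split_plan(ClassificationTask("block_within_set", subject=0), lab)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def test_default_grid_has_81_candidates():
    costs = GridSearchSpec().costs()
    assert len(costs) == 81
    assert costs[0] == pytest.approx(2.0 ** -5)
    assert costs[-1] == pytest.approx(2.0 ** 15)


def test_separable_blobs_tie_break_to_smallest_cost():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-20, 0.5, (20, 5)), rng.normal(20, 0.5, (20, 5))])
    y = np.repeat([0, 1], 20)
    spec = GridSearchSpec(exponent_range=(-5.0, 3.0), exponent_step=1.0)
    assert grid_search_cost(X, y, spec, seed=0) == pytest.approx(2.0 ** -5)


def test_grid_search_deterministic():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(60, 10))
    y = rng.integers(0, 3, 60)
    spec = GridSearchSpec(exponent_range=(-5.0, 5.0), exponent_step=2.0)
    assert grid_search_cost(X, y, spec, seed=7) == grid_search_cost(X, y, spec, seed=7)


def test_single_class_train_raises():
    with pytest.raises(TaskError):
        grid_search_cost(np.zeros((10, 3)), np.zeros(10, dtype=int))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def brute_force_metrics(y_true, y_pred):
    """Independent reference: two-loop macro metrics from first principles."""
    classes = sorted(set(y_true))
    precisions, recalls, f1s = [], [], []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    acc = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(y_true)
    return {"accuracy": 100 * acc, "f1": 100 * np.mean(f1s),
            "precision": 100 * np.mean(precisions), "recall": 100 * np.mean(recalls)}


def test_perfect_predictions_score_100():
    y = np.arange(12) % 4
    m = compute_metrics(y, y, 4)
    assert all(v == pytest.approx(100.0) for v in m.values())


def test_hand_computed_three_class_confusion():
    # confusion [[8,1,1],[0,10,0],[2,0,8]] (rows true, cols predicted)
    y_true = np.repeat([0, 1, 2], 10)
    y_pred = np.concatenate([[0] * 8, [1], [2], [1] * 10, [0] * 2, [2] * 8])
    m = compute_metrics(y_true, y_pred, 3)
    assert m["accuracy"] == pytest.approx(86.67, abs=0.01)
    assert m["precision"] == pytest.approx(86.60, abs=0.01)  # mean(8/10, 10/11, 8/9)
    assert m["recall"] == pytest.approx(86.67, abs=0.01)     # mean(.8, 1, .8)
    assert m["f1"] == pytest.approx(86.48, abs=0.01)         # mean(.8, .9524, .8421)
    assert m == pytest.approx(brute_force_metrics(y_true, y_pred), abs=1e-9)


def test_metrics_agree_with_brute_force_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(100):
        k = rng.integers(2, 6)
        n = rng.integers(k, 40)
        y_true = np.concatenate([np.arange(k), rng.integers(0, k, n)])  # every class present
        y_pred = rng.integers(0, k, len(y_true))
        m = compute_metrics(y_true, y_pred, k)
        assert m == pytest.approx(brute_force_metrics(y_true, y_pred), abs=1e-9)


def test_chance_accuracy_values():
    assert chance_accuracy(27) == pytest.approx(100 / 27)
    assert chance_accuracy(9) == pytest.approx(100 / 9)
    with pytest.raises(ParameterError):
        chance_accuracy(0)


def test_normalized_confusion_rows_sum_to_one():
    rng = np.random.default_rng(3)
    y_true = rng.integers(0, 5, 200)
    y_pred = rng.integers(0, 5, 200)
    cm = normalized_confusion(y_true, y_pred, 5)
    assert np.allclose(cm.sum(axis=1), 1.0, atol=1e-9)
    # pooled accuracy equals the class-frequency-weighted diagonal
    weights = np.bincount(y_true, minlength=5) / len(y_true)
    assert np.dot(weights, np.diag(cm)) == pytest.approx(np.mean(y_true == y_pred))


# ---------------------------------------------------------------------------
# distance profiles
# ---------------------------------------------------------------------------

def brute_force_profile(y_true, y_pred, n_classes):
    rows = {}
    for d in range(n_classes):
        raw, corrected = [], []
        for c in range(n_classes):
            n_at_d = sum(1 for p in range(n_classes) if abs(p - c) == d)
            if n_at_d == 0 or not np.any(y_true == c):
                continue
            mask = y_true == c
            share = np.mean(np.abs(y_pred[mask] - c) == d)
            raw.append(share)
            corrected.append(share / n_at_d)
        if raw:
            rows[d] = (np.mean(raw), np.mean(corrected))
    return rows


def test_identity_predictions_mass_at_zero(tiny_features):
    task = ClassificationTask("set", subject=0)
    y = np.repeat(np.arange(5), 4)
    prof = distance_profile(y, y, task, 5)
    assert prof.loc[prof.distance == 0, "mean"].item() == pytest.approx(1.0)
    assert np.allclose(prof.loc[prof.distance > 0, "mean"], 0.0)


def test_uniform_predictions_match_availability_closed_form():
    # exhaustive prediction multiset: every (true, predicted) pair once
    K = 27
    y_true = np.repeat(np.arange(K), K)
    y_pred = np.tile(np.arange(K), K)
    task = ClassificationTask("block", subject=0)
    prof = distance_profile(y_true, y_pred, task, K)
    avail = distance_availability(K)
    for _, row in prof.iterrows():
        d = int(row.distance)
        eligible = avail[:, d] > 0
        assert row["mean"] == pytest.approx(np.mean(avail[eligible, d]) / K, abs=1e-12)
        assert row["mean_corrected"] == pytest.approx(1.0 / K, abs=1e-12)


def test_profile_matches_brute_force_on_random_predictions():
    rng = np.random.default_rng(21)
    task = ClassificationTask("set", subject=0)
    for _ in range(20):
        K = int(rng.integers(3, 10))
        y_true = np.concatenate([np.arange(K), rng.integers(0, K, 50)])
        y_pred = rng.integers(0, K, len(y_true))
        prof = distance_profile(y_true, y_pred, task, K).set_index("distance")
        oracle = brute_force_profile(y_true, y_pred, K)
        for d, (raw, corr) in oracle.items():
            assert prof.loc[d, "mean"] == pytest.approx(raw, abs=1e-12)
            assert prof.loc[d, "mean_corrected"] == pytest.approx(corr, abs=1e-12)


def test_unordered_task_has_no_profile():
    with pytest.raises(TaskError):
        distance_profile(np.array([0, 1]), np.array([0, 1]),
                         ClassificationTask("participant"), 2)


# ---------------------------------------------------------------------------
# full task runs
# ---------------------------------------------------------------------------

def test_participant_task_with_strong_signatures_is_perfect(tiny_features, fast_grid):
    res = run_task(tiny_features, ClassificationTask("participant"),
                   grid=fast_grid, seed=0)
    assert res.mean_accuracy == pytest.approx(100.0)
    assert np.allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)
    assert len(res.fold_costs) == TINY_PROTOCOL.n_sets


def test_permuted_labels_fall_to_chance(tiny_features, single_cost_grid):
    # destroy the subject-feature link by shuffling rows' features within
    # the task matrix: equivalent to permuting labels
    task = ClassificationTask("participant")
    rng = np.random.default_rng(17)
    shuffled = tiny_features.labels.copy()
    shuffled["subject"] = rng.permutation(shuffled["subject"].to_numpy())
    from kinemid import FeatureMatrix
    fm = FeatureMatrix(values=tiny_features.values, labels=shuffled)
    res = run_task(fm, task, grid=single_cost_grid, seed=1)
    n_test = TINY_PROTOCOL.n_subjects * TINY_PROTOCOL.k80_kicks_per_leg
    band = binomial_chance_band(TINY_PROTOCOL.n_subjects, n_test)
    assert abs(res.mean_accuracy - res.chance) <= band


def test_run_task_rejects_normalized_features(tiny_features):
    from kinemid import normalize_features
    with pytest.raises(TaskError):
        run_task(normalize_features(tiny_features), ClassificationTask("participant"))
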