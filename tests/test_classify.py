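"""Split integrity, MLP training contracts and metric identities."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pulsespectra import classify
from pulsespectra.classify import (
    EvaluationReport,
    MLPConfig,
    evaluate,
    make_split,
    predict,
    train_mlp,
)
from pulsespectra.features import FEATURE_COLUMNS, ZScoreNormalizer


def blob_features(rng, n_subjects_per_class, rows_per_subject=20, sep=6.0):
    """Two Gaussian blobs 'sep' SDs apart along 5 features; subject-grouped."""
    rows = []
    for label, sign in (("AD", +1), ("control", -1)):
        for i in range(n_subjects_per_class):
            center = np.zeros(40)
            center[:5] = sign * sep / 2
            for r in range(rows_per_subject):
                rows.append(
                    dict(
                        zip(FEATURE_COLUMNS, center + rng.normal(0, 1, 40)),
                        subject_id=f"{label}-{i}",
                        label=label,
                        window_start_beat=r,
                    )
                )
    return pd.DataFrame(rows)


def null_features(rng, n_subjects_per_class, rows_per_subject=20):
    return blob_features(rng, n_subjects_per_class, rows_per_subject, sep=0.0)


# --- splits --------------------------------------------------------------


def test_split_ratio_with_cohort_like_counts():
    subjects = [f"a{i}" for i in range(87)] + [f"c{i}" for i in range(74)]
    labels = ["AD"] * 87 + ["control"] * 74
    plan = make_split(subjects, labels, seed=0)
    train_ad = sum(s.startswith("a") for s in plan.train_subjects)
    train_c = sum(s.startswith("c") for s in plan.train_subjects)
    assert (train_ad, train_c) == (58, 49)
    assert (87 - train_ad, 74 - train_c) == (29, 25)


def test_split_determinism_and_disjointness():
    subjects = [f"s{i}" for i in range(30)]
    labels = ["AD" if i % 2 else "control" for i in range(30)]
    p1 = make_split(subjects, labels, seed=9)
    p2 = make_split(subjects, labels, seed=9)
    assert p1 == p2
    assert not set(p1.train_subjects) & set(p1.test_subjects)
    for fit, val in p1.folds:
        assert not set(fit) & set(val)
        assert set(fit) | set(val) <= set(p1.train_subjects)
    assert len(p1.folds) == 3


def test_split_rejects_tiny_class():
    with pytest.raises(ValueError, match="need >= 6"):
        make_split(["a", "b", "c", "x", "y", "z"], ["AD"] * 3 + ["control"] * 3, seed=0)


# --- training and prediction --------------------------------------------


def test_separable_blobs_fit_accuracy():
    rng = np.random.default_rng(0)
    df = blob_features(rng, 10)
    norm = ZScoreNormalizer().fit(df)
    clf = train_mlp(norm.transform(df), MLPConfig(seed=1), norm)
    scores, labels = predict(clf, norm.transform(df))
    y = (df["label"] == "AD").astype(int).to_numpy()
    assert np.mean(labels == y) >= 0.99
    rep = evaluate(scores, y)
    assert rep.auc == 1.0


def test_training_determinism():
    rng = np.random.default_rng(1)
    df = blob_features(rng, 6, sep=2.0)
    norm = ZScoreNormalizer().fit(df)
    c1 = train_mlp(norm.transform(df), MLPConfig(seed=3), norm)
    c2 = train_mlp(norm.transform(df), MLPConfig(seed=3), norm)
    for a, b in zip(c1.estimator.coefs_, c2.estimator.coefs_):
        assert np.array_equal(a, b)
    s1, _ = predict(c1, norm.transform(df))
    s2, _ = predict(c2, norm.transform(df))
    assert np.array_equal(s1, s2)


def test_single_class_rejected():
    rng = np.random.default_rng(2)
    df = blob_features(rng, 4)
    df = df[df["label"] == "AD"]
    norm = ZScoreNormalizer().fit(df)
    with pytest.raises(ValueError, match="single class"):
        train_mlp(norm.transform(df), MLPConfig(seed=0), norm)


def test_permuted_labels_give_chance_validation():
    """Label-shuffled training yields ~50% validation accuracy over seeds."""
    rng = np.random.default_rng(3)
    accs = []
    for seed in range(10):
        df = null_features(np.random.default_rng(100 + seed), 12, rows_per_subject=10)
        subs = df.drop_duplicates("subject_id")
        plan = make_split(subs["subject_id"], subs["label"], seed=seed)
        fit_s, val_s = plan.folds[0]
        norm = ZScoreNormalizer().fit(df[df.subject_id.isin(fit_s)])
        clf = train_mlp(
            norm.transform(df[df.subject_id.isin(fit_s)]),
            MLPConfig(seed=seed, max_epochs=60),
            norm,
        )
        val = norm.transform(df[df.subject_id.isin(val_s)])
        _, pred = predict(clf, val)
        accs.append(np.mean(pred == (val["label"] == "AD").astype(int).to_numpy()))
    assert 0.40 <= np.mean(accs) <= 0.60


def test_prediction_row_order_invariance_and_width_check():
    rng = np.random.default_rng(4)
    df = blob_features(rng, 6)
    norm = ZScoreNormalizer().fit(df)
    clf = train_mlp(norm.transform(df), MLPConfig(seed=0, max_epochs=20), norm)
    z = norm.transform(df)
    s1, _ = predict(clf, z)
    perm = rng.permutation(len(z))
    s2, _ = predict(clf, z.iloc[perm])
    assert np.allclose(s1[perm], s2)
    with pytest.raises(ValueError, match="features"):
        predict(clf, z[FEATURE_COLUMNS[:39]].assign(subject_id="x"))


# --- evaluation ----------------------------------------------------------


def test_metric_arithmetic_identities():
    rep = EvaluationReport(tp=8, fn=2, tn=9, fp=1, auc=0.9)
    assert rep.accuracy == pytest.approx(85.0)
    assert rep.sensitivity == pytest.approx(80.0)
    assert rep.specificity == pytest.approx(90.0)


def test_threshold_tie_is_positive():
    scores = np.array([0.5, 0.49])
    y = np.array([1, 0])
    rep = evaluate(scores, y)
    assert rep.tp == 1 and rep.tn == 1 and rep.fp == 0 and rep.fn == 0


def test_perfect_ranking_auc():
    rep = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
    assert rep.auc == 1.0


def test_auc_matches_sklearn_with_ties():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 500)
    scores = np.round(rng.uniform(0, 1, 500), 2)  # force ties
    rep = evaluate(scores, y)
    assert rep.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def test_null_scores_auc_near_half():
    rng = np.random.default_rng(6)
    y = np.repeat([1, 0], 2000)
    scores = rng.uniform(0, 1, 4000)
    rep = evaluate(scores, y)
    assert 0.45 <= rep.auc <= 0.55


def test_subject_level_aggregation():
    scores = np.array([0.9, 0.2, 0.3, 0.4])
    y = np.array([1, 1, 0, 0])
    sids = ["a", "a", "b", "b"]
    rep = evaluate(scores, y, level="subject", subject_ids=sids)
    assert rep.n == 2
    assert rep.tp == 1 and rep.tn == 1  # subject a mean 0.55 -> AD; b 0.35 -> control


def test_protocol_report_structure():
    rng = np.random.default_rng(7)
    df = blob_features(rng, 9, rows_per_subject=8, sep=3.0)
    model = classify.PulseClassificationModel(df)
    res = model.fit(seed=2, config=MLPConfig(seed=2, max_epochs=30))
    assert len(res.fold_reports) == 3
    assert set(res.average_report) == {"accuracy", "sensitivity", "specificity", "auc"}
    assert res.holdout_report.n > 0
    d = res.as_dict()
    assert len(d["folds"]) == 3 and "holdout" in d and "average" in d
    txt = res.summary()
    assert "hold-out" in txt and "fold 3" in txt
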