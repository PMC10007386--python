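"""Splits, balancing, cross-validation, thresholding, metrics, MWU, pipeline."""

import numpy as np
import pytest

from beatae import nnet
from beatae.experiment import (
    EvalReport,
    SplitPlan,
    _portion_ids,
    auc_trapezoid,
    balance_classes,
    crossval_train,
    evaluate,
    lcsd_baseline,
    make_split,
    mannwhitney_u,
    roc_points,
    run_pipeline,
    select_threshold,
)
from beatae.records import AFIB, NSR, BeatMatrix


def _toy_matrix(n_units=10, beats_per_unit=5, patients=None, labels=None):
    rows = n_units * beats_per_unit
    rec_ids = np.repeat([f"r{i}" for i in range(n_units)], beats_per_unit)
    if labels is None:
        labels = [NSR if i % 2 == 0 else AFIB for i in range(n_units)]
    lab = np.repeat(labels, beats_per_unit)
    pats = (
        np.repeat([f"p{i % patients}" for i in range(n_units)], beats_per_unit)
        if patients
        else np.repeat([f"p{i}" for i in range(n_units)], beats_per_unit)
    )
    return BeatMatrix(
        samples=np.random.default_rng(0).normal(size=(rows, 8)),
        labels=lab.astype(object),
        record_ids=rec_ids.astype(object),
        patient_ids=pats.astype(object),
        r_times=np.arange(rows, dtype=float),
        fs=250.0,
    )


class TestMakeSplit:
    def test_ten_portions_split_eight_two(self):
        m = _toy_matrix(n_units=10)
        tr, te = make_split(m, SplitPlan(mode="portion", seed=1))
        tr_units = set(_portion_ids(m)[tr])
        te_units = set(_portion_ids(m)[te])
        assert len(tr_units) == 8 and len(te_units) == 2
        assert not tr_units & te_units

    def test_twentythree_patients_split_eighteen_five(self):
        m = _toy_matrix(n_units=46, beats_per_unit=2, patients=23)
        tr, te = make_split(m, SplitPlan(mode="patient", seed=2))
        tr_p = set(m.patient_ids[tr])
        te_p = set(m.patient_ids[te])
        assert len(tr_p) == 18 and len(te_p) == 5
        assert not tr_p & te_p

    def test_patient_mode_requires_two_patients(self):
        m = _toy_matrix(n_units=4, patients=1)
        with pytest.raises(ValueError, match="patient"):
            make_split(m, SplitPlan(mode="patient"))

    def test_split_is_seed_deterministic(self):
        m = _toy_matrix()
        a = make_split(m, SplitPlan(seed=3))
        b = make_split(m, SplitPlan(seed=3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            SplitPlan(mode="record")
        with pytest.raises(ValueError):
            SplitPlan(train_fraction=1.2)
        with pytest.raises(ValueError):
            SplitPlan(folds=1)


class TestBalanceClasses:
    def test_majority_undersampled_to_minority(self):
        labels = np.array([NSR] * 1000 + [AFIB] * 300, dtype=object)
        idx = balance_classes(labels, seed=0)
        assert (labels[idx] == NSR).sum() == 300
        assert (labels[idx] == AFIB).sum() == 300
        # minority untouched
        assert set(np.flatnonzero(labels == AFIB)) <= set(idx)

    def test_already_balanced_is_identity(self):
        labels = np.array([NSR] * 50 + [AFIB] * 50, dtype=object)
        assert np.array_equal(balance_classes(labels, seed=1), np.arange(100))

    def test_seed_determinism(self):
        labels = np.array([NSR] * 40 + [AFIB] * 10, dtype=object)
        a = balance_classes(labels, seed=5)
        b = balance_classes(labels, seed=5)
        assert np.array_equal(a, b)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            balance_classes(np.array([NSR] * 10, dtype=object))


class TestCrossvalTrain:
    def _data(self, n=60):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(n, 4))
        y = (x[:, 0] > 0).astype(float)
        return x, y

    def test_selected_run_has_minimum_validation_loss(self):
        x, y = self._data()
        cfg = nnet.TrainConfig(learning_rate=1e-2, max_epochs=20, patience=19, seed=1)
        best = crossval_train(nnet.mlp_spec(4), (x, y, None), folds=5, config=cfg)
        assert best["result"].best_val_loss == min(best["fold_val_losses"])

    def test_folds_partition_indices_exactly_once(self):
        x, y = self._data()
        cfg = nnet.TrainConfig(learning_rate=1e-2, max_epochs=3, patience=2, seed=1)
        best = crossval_train(nnet.mlp_spec(4), (x, y, None), folds=5, config=cfg)
        assignment = best["assignment"]
        assert assignment.size == 60
        counts = np.bincount(assignment, minlength=5)
        assert counts.sum() == 60 and np.all(counts == 12)

    def test_same_master_seed_same_assignment(self):
        x, y = self._data()
        cfg = nnet.TrainConfig(learning_rate=1e-2, max_epochs=2, patience=1, seed=9)
        a = crossval_train(nnet.mlp_spec(4), (x, y, None), folds=4, config=cfg)
        b = crossval_train(nnet.mlp_spec(4), (x, y, None), folds=4, config=cfg)
        assert np.array_equal(a["assignment"], b["assignment"])

    def test_fewer_samples_than_folds_rejected(self):
        x, y = self._data(n=5)
        with pytest.raises(ValueError, match="folds"):
            crossval_train(nnet.mlp_spec(4), (x, y, None), folds=10)


class TestSelectThreshold:
    def test_perfectly_separated_scores_yield_gap_threshold(self):
        p = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        y = np.array([0, 0, 0, 1, 1, 1])
        t = select_threshold(p, y)
        assert 0.3 < t < 0.7
        pred = p >= t
        assert np.array_equal(pred, y.astype(bool))  # J = 1

    def test_independent_scores_give_near_zero_j(self, caplog):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=2000)
        y = rng.integers(0, 2, 2000)
        with caplog.at_level("WARNING"):
            t = select_threshold(p, y)
        pred = p >= t
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        j = tp / (y == 1).sum() + ((y == 0).sum() - fp) / (y == 0).sum() - 1
        assert j < 0.1

    def test_label_swap_antisymmetry_brute_force(self):
        """Swapping the class labels maps J(t) computed with `>=` onto
        -J(t) computed on the complementary prediction; the maximal J
        over all thresholds for swapped labels equals the maximal J of
        the score-negated original problem."""
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        y = rng.integers(0, 2, 50)

        def max_j(scores, labels, flip):
            best = -np.inf
            for t in np.unique(scores):
                pred = (scores >= t) ^ flip
                tp = np.sum(pred & (labels == 1))
                fp = np.sum(pred & (labels == 0))
                n1, n0 = (labels == 1).sum(), (labels == 0).sum()
                best = max(best, tp / n1 + (n0 - fp) / n0 - 1)
            return best

        assert max_j(p, 1 - y, flip=False) == pytest.approx(
            max_j(p, y, flip=True), abs=1e-12
        )

    def test_degenerate_labels_return_half(self, caplog):
        with caplog.at_level("WARNING"):
            t = select_threshold(np.array([0.2, 0.8]), np.array([1, 1]))
        assert t == 0.5


class TestEvaluate:
    def test_closed_form_confusion_example(self):
        # TP=8, FP=2, FN=2, TN=8 at threshold 0.5
        p = np.array([0.9] * 8 + [0.1] * 2 + [0.9] * 2 + [0.1] * 8)
        y = np.array([1] * 10 + [0] * 10)
        r = evaluate(p, y, 0.5)
        assert (r.tp, r.fp, r.fn, r.tn) == (8, 2, 2, 8)
        for metric in (r.accuracy, r.precision, r.recall, r.f1):
            assert metric == pytest.approx(0.8)

    def test_perfect_predictions(self):
        p = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        r = evaluate(p, y, 0.5)
        assert r.accuracy == r.precision == r.recall == r.f1 == 1.0
        assert r.auc == 1.0

    def test_all_positive_predictor_on_balanced_data(self):
        p = np.full(20, 0.99)
        y = np.array([1] * 10 + [0] * 10)
        r = evaluate(p, y, 0.5)
        assert r.recall == 1.0 and r.accuracy == 0.5

    def test_metrics_recomputable_from_confusion_counts(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        y = (rng.uniform(size=200) < p).astype(int)
        r = evaluate(p, y, 0.4)
        n = r.tp + r.fp + r.tn + r.fn
        assert r.accuracy == pytest.approx((r.tp + r.tn) / n)
        assert r.precision == pytest.approx(r.tp / (r.tp + r.fp))
        assert r.recall == pytest.approx(r.tp / (r.tp + r.fn))
        assert r.f1 == pytest.approx(
            2 * r.precision * r.recall / (r.precision + r.recall)
        )

    def test_auc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n = int(rng.integers(10, 200))
            p = np.round(rng.uniform(size=n), 2)   # force ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            roc = roc_points(p, y)
            auc = auc_trapezoid(roc)
            pos = p[y == 1][:, None]
            neg = p[y == 0][None, :]
            conc = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (
                (y == 1).sum() * (y == 0).sum()
            )
            assert auc == pytest.approx(conc, abs=1e-12)

    def test_auc_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(4)
        p = rng.uniform(size=300)
        y = rng.integers(0, 2, 300)
        r = evaluate(p, y, 0.5)
        assert r.auc == pytest.approx(sk.roc_auc_score(y, p), abs=1e-12)

    def test_degenerate_divisions_flagged(self):
        r = evaluate(np.array([0.1, 0.2]), np.array([0, 0]), 0.5)
        assert r.degenerate
        assert r.precision == 0.0 and r.recall == 0.0


class TestMannWhitney:
    def test_fully_separated_groups(self):
        r = mannwhitney_u([1, 2, 3], [4, 5, 6])
        assert r.u == 0.0      # documented convention: U counts a > b pairs
        assert r.p < 0.1

    def test_identical_groups_give_p_near_one(self):
        r = mannwhitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p > 0.9
        assert r.u == pytest.approx(4.5)  # n1*n2/2

    def test_u_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n1 = int(rng.integers(1, 8))
            n2 = int(rng.integers(1, 8))
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            r = mannwhitney_u(a, b)
            brute = sum(
                1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
            )
            assert r.u == pytest.approx(brute, abs=1e-9)
            assert 0 <= r.u <= n1 * n2
            assert 0 < r.p <= 1

    def test_matches_scipy_asymptotic(self):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.normal(size=rng.integers(10, 40))
            b = rng.normal(0.5, 1, size=rng.integers(10, 40))
            r = mannwhitney_u(a, b)
            ref = scipy_stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            )
            assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_u([], [1.0])


class TestLcsdBaseline:
    def _matrix(self, lcsd, labels):
        n = len(lcsd)
        return BeatMatrix(
            samples=np.zeros((n, 4)),
            labels=np.asarray(labels, dtype=object),
            record_ids=np.full(n, "r", dtype=object),
            patient_ids=np.full(n, "p", dtype=object),
            r_times=np.arange(n, dtype=float),
            fs=250.0,
            lcsd=np.asarray(lcsd, dtype=float),
        )

    def test_perfectly_separated_lcsd_gives_f1_one(self):
        rng = np.random.default_rng(0)
        lcsd_tr = np.concatenate([rng.uniform(0, 0.05, 60), rng.uniform(0.4, 1.0, 60)])
        labels_tr = [NSR] * 60 + [AFIB] * 60
        lcsd_te = np.concatenate([rng.uniform(0, 0.05, 20), rng.uniform(0.4, 1.0, 20)])
        labels_te = [NSR] * 20 + [AFIB] * 20
        cfg = nnet.TrainConfig(learning_rate=0.05, max_epochs=200, patience=50, seed=0)
        report = lcsd_baseline(
            self._matrix(lcsd_tr, labels_tr), self._matrix(lcsd_te, labels_te), cfg
        )
        assert report.f1 == 1.0

    def test_constant_lcsd_flags_degenerate(self, caplog):
        lcsd = np.full(40, 0.3)
        labels = [NSR] * 20 + [AFIB] * 20
        cfg = nnet.TrainConfig(learning_rate=0.05, max_epochs=5, patience=4, seed=0)
        with caplog.at_level("WARNING"):
            lcsd_baseline(self._matrix(lcsd, labels), self._matrix(lcsd, labels), cfg)
        assert any("constant" in rec.message.lower() for rec in caplog.records)

    def test_missing_lcsd_column_rejected(self):
        m = self._matrix(np.zeros(4), [NSR, NSR, AFIB, AFIB])
        m.lcsd = None
        with pytest.raises(ValueError, match="LCSD"):
            lcsd_baseline(m, m)


SMALL_RUN = {
    "data": {"n_records_per_class": 6, "duration": 25.0, "seed": 77},
    "split": {"folds": 3, "seed": 7},
    "train": {"max_epochs": 40, "patience": 10, "seed": 7},
}


class TestRunPipeline:
    def test_grid_shares_one_test_set(self):
        """2x2 family/feature grid on one dataset: same portions end up
        in the test set of every cell (controlled comparison)."""
        bundles = []
        for family in ("ae", "supae"):
            for use_lcsd in (False, True):
                cfg = {**SMALL_RUN, "model": {"family": family, "use_lcsd": use_lcsd}}
                bundles.append(run_pipeline(cfg))
        units = [b["test_units"] for b in bundles]
        assert all(u == units[0] for u in units)
        assert all(b["n_test"] == bundles[0]["n_test"] for b in bundles)

    def test_manifest_reruns_bit_identically(self):
        cfg = {**SMALL_RUN, "model": {"family": "supae", "use_lcsd": True}}
        first = run_pipeline(cfg)
        second = run_pipeline(first["manifest"])
        assert first["report"].to_dict() == second["report"].to_dict()
        assert first["manifest"] == second["manifest"]

    def test_patient_mode_reports_patient_partition(self):
        cfg = {
            **SMALL_RUN,
            "data": {**SMALL_RUN["data"], "patients": 6},
            "split": {**SMALL_RUN["split"], "mode": "patient"},
            "model": {"family": "supae", "use_lcsd": True},
        }
        bundle = run_pipeline(cfg)
        assert len(bundle["test_patients"]) >= 1
        assert bundle["manifest"]["split"]["mode"] == "patient"

    def test_unknown_config_keys_rejected(self):
        with pytest.raises(KeyError):
            run_pipeline({"model": {"familly": "supae"}})
        with pytest.raises(KeyError):
            run_pipeline({"nonsense": {}})
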