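"""Confusion metrics, ROC/AUC, jackknife / independent-test / LG-sweep protocols."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from pssmdt import (
    ConfusionCounts,
    DistanceTransformEncoder,
    GeneratorConfig,
    LabeledDataset,
    PlantSpec,
    compute_metrics,
    generate_dataset,
    independent_test,
    jackknife,
    lg_sweep,
    roc_auc,
)
from pssmdt.evaluation import EvaluationError, EvaluationReport
from pssmdt.schema import DescriptorSchema, SchemaError

from oracles import bruteforce_auc


def toy_dataset(labels, features=None, prefix="s"):
    labels = np.asarray(labels, dtype=int)
    if features is None:
        features = labels[:, None].astype(float)
    schema = DescriptorSchema(
        scheme="toy", entries=tuple(("A", "A", k + 1) for k in range(features.shape[1]))
    )
    return LabeledDataset(
        ids=[f"{prefix}{i}" for i in range(len(labels))],
        features=features,
        labels=labels,
        schema=schema,
    )


class TestComputeMetrics:
    def test_perfect_prediction(self):
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert (sn, sp, acc, mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_inverted_prediction(self):
        *_rest, mcc = compute_metrics(ConfusionCounts(tp=0, fp=50, tn=0, fn=50))
        assert mcc == -1.0

    def test_hand_computed_case(self):
        sn, sp, acc, mcc = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
        assert mcc == pytest.approx(4 / math.sqrt(240))
        assert sn == pytest.approx(0.6)
        assert sp == pytest.approx(2 / 3)
        assert acc == pytest.approx(0.625)

    def test_zero_denominator_mcc_is_zero(self):
        # all predictions positive: TN+FN column is empty
        *_rest, mcc = compute_metrics(ConfusionCounts(tp=5, fp=5, tn=0, fn=0))
        assert mcc == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(EvaluationError):
            compute_metrics(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    def test_agrees_with_sklearn_on_random_counts(self, rng):
        for _ in range(50):
            y_true = rng.choice([-1, 1], size=30)
            y_pred = rng.choice([-1, 1], size=30)
            if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
                continue
            counts = ConfusionCounts.from_predictions(y_true, y_pred)
            *_rest, mcc = compute_metrics(counts)
            assert mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)

    def test_metrics_recount_from_prediction_lists(self, rng):
        y_true = rng.choice([-1, 1], size=40)
        y_pred = rng.choice([-1, 1], size=40)
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        assert counts.total == 40
        sn, sp, acc, _ = compute_metrics(counts)
        assert acc == pytest.approx(np.mean(y_true == y_pred))
        pos = y_true == 1
        assert sn == pytest.approx(np.mean(y_pred[pos] == 1))
        assert sp == pytest.approx(np.mean(y_pred[~pos] == -1))


class TestRocAuc:
    def test_perfect_ranking(self):
        points, auc = roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, -1, -1])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_interleaved_ranking_matches_pair_counting(self):
        _points, auc = roc_auc([0.9, 0.8, 0.3, 0.2], [1, -1, 1, -1])
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(bruteforce_auc([0.9, 0.8, 0.3, 0.2], [1, -1, 1, -1]))

    def test_all_tied_values_give_half(self):
        _points, auc = roc_auc([1.0, 1.0, 1.0, 1.0], [1, 1, -1, -1])
        assert auc == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_values(self, rng):
        for _ in range(20):
            values = rng.choice([-1.0, -0.5, 0.0, 0.5, 1.0], size=20)  # force ties
            labels = rng.choice([-1, 1], size=20)
            if len(set(labels)) < 2:
                continue
            _points, auc = roc_auc(values, labels)
            assert auc == pytest.approx(bruteforce_auc(values, labels), abs=1e-12)

    def test_label_flip_complement_without_ties(self, rng):
        values = rng.normal(size=16)
        labels = np.array([1, -1] * 8)
        auc_fwd = roc_auc(values, labels)[1]
        auc_rev = roc_auc(values, -labels)[1]
        assert auc_fwd + auc_rev == pytest.approx(1.0)

    def test_roc_points_monotone(self, rng):
        values = rng.normal(size=30)
        labels = rng.choice([-1, 1], size=30)
        points, _auc = roc_auc(values, labels)
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestJackknife:
    def test_trivially_learnable_feature(self):
        data = toy_dataset([1] * 5 + [-1] * 5)
        report = jackknife(data, C=10.0, gamma=0.5)
        assert report.acc == 1.0 and report.mcc == 1.0

    def test_each_sample_held_out_exactly_once(self):
        data = toy_dataset([1, 1, 1, -1, -1, -1])
        report = jackknife(data, C=1.0, gamma=0.5)
        assert sorted(report.ids) == sorted(data.ids)
        assert len(report.decision_values) == data.n_samples

    def test_reports_are_seed_reproducible(self):
        data = toy_dataset([1, 1, 1, -1, -1, -1])
        r1 = jackknife(data, C=1.0, gamma=0.5, seed=3)
        r2 = jackknife(data, C=1.0, gamma=0.5, seed=3)
        assert r1.to_json() == r2.to_json()

    def test_minimum_class_membership_enforced(self):
        data = toy_dataset([1, -1, -1, -1])
        with pytest.raises(EvaluationError, match="2 members"):
            jackknife(data, C=1.0, gamma=0.5)

    def test_accuracy_grows_with_planted_effect_size(self):
        """Jackknife ACC on planted synthetic data rises with the effect size."""
        accs = []
        for effect in (0.0, 3.0, 6.0):
            config = GeneratorConfig(
                n_pos=10, n_neg=10, length_range=(40, 50),
                plant=PlantSpec(effect_size=effect), seed=5,
            )
            profiles, labels = generate_dataset(config)
            encoder = DistanceTransformEncoder(scheme="dt", lg=4).fit()
            data = LabeledDataset(
                ids=[p.sequence.id for p in profiles],
                features=encoder.transform(profiles),
                labels=labels,
                schema=encoder.schema_,
            )
            accs.append(jackknife(data, C=2.0, gamma=2.0**-11).acc)
        assert accs[0] < accs[2]
        assert accs[1] <= accs[2]


class TestIndependentTest:
    def test_test_equals_train_is_resubstitution(self):
        data = toy_dataset([1, 1, 1, -1, -1, -1])
        with pytest.warns(UserWarning, match="both train and test"):
            report = independent_test(data, data, C=10.0, gamma=0.5)
        assert report.acc == 1.0
        assert report.protocol == "independent"

    def test_schema_mismatch_rejected(self):
        train_set = toy_dataset([1, 1, -1, -1])
        other_schema = DescriptorSchema(scheme="other", entries=(("R", "R", 1),))
        test_set = LabeledDataset(
            ids=["t0", "t1"], features=np.zeros((2, 1)),
            labels=np.array([1, -1]), schema=other_schema,
        )
        with pytest.raises(SchemaError):
            independent_test(train_set, test_set, C=1.0, gamma=0.5)

    def test_generator_consistent_train_test_near_jackknife(self):
        """Same generator for train and test: independent ACC tracks jackknife ACC."""
        encoder = DistanceTransformEncoder(scheme="dt", lg=4).fit()

        def build(seed, prefix):
            config = GeneratorConfig(n_pos=12, n_neg=12, length_range=(40, 50), seed=seed)
            profiles, labels = generate_dataset(config)
            return LabeledDataset(
                ids=[f"{prefix}{p.sequence.id}" for p in profiles],
                features=encoder.transform(profiles),
                labels=labels, schema=encoder.schema_,
            )

        train_set, test_set = build(1, "tr"), build(2, "te")
        ind = independent_test(train_set, test_set, C=2.0, gamma=2.0**-11)
        jack = jackknife(train_set, C=2.0, gamma=2.0**-11)
        assert abs(ind.acc - jack.acc) < 0.25  # same generator, sampling noise only

    def test_empty_test_rejected(self):
        data = toy_dataset([1, 1, -1, -1])
        empty = LabeledDataset(ids=[], features=np.zeros((0, 1)),
                               labels=np.zeros(0, dtype=int), schema=data.schema)
        with pytest.raises(EvaluationError, match="empty"):
            independent_test(data, empty, C=1.0, gamma=0.5)


class TestReportInvariants:
    def test_permuting_samples_changes_no_metric(self, rng):
        values = rng.normal(size=20)
        labels = rng.choice([-1, 1], size=20)
        labels[:2] = [1, -1]
        ids = [f"s{i}" for i in range(20)]
        base = EvaluationReport.from_predictions(ids, labels, values, protocol="kfold")
        perm = rng.permutation(20)
        shuffled = EvaluationReport.from_predictions(
            [ids[i] for i in perm], labels[perm], values[perm], protocol="kfold"
        )
        for attr in ("sn", "sp", "acc", "mcc", "auc"):
            assert getattr(base, attr) == pytest.approx(getattr(shuffled, attr))

    def test_random_balanced_predictions_have_near_zero_mean_mcc(self):
        """Label-independent coin-flip predictions center MCC at about zero."""
        rng = np.random.default_rng(42)
        labels = np.array([1] * 50 + [-1] * 50)
        mccs = []
        for _ in range(2000):
            preds = rng.choice([-1, 1], size=100)
            counts = ConfusionCounts.from_predictions(labels, preds)
            mccs.append(compute_metrics(counts)[3])
        assert abs(np.mean(mccs)) < 0.02


class TestLgSweep:
    @pytest.fixture()
    def planted_profiles(self):
        config = GeneratorConfig(
            n_pos=12, n_neg=12, length_range=(40, 50),
            plant=PlantSpec(pairs=(("R", "R", 3),), effect_size=4.0, density=0.05),
            seed=9,
        )
        return generate_dataset(config)

    def test_one_row_per_requested_lg_and_determinism(self, planted_profiles):
        profiles, labels = planted_profiles
        kwargs = dict(
            folds=3, seed=2, C_grid=[2.0, 8.0], gamma_grid=[2.0**-13, 2.0**-9]
        )
        t1 = lg_sweep(profiles, labels, [1, 3], **kwargs)
        t2 = lg_sweep(profiles, labels, [1, 3], **kwargs)
        assert list(t1["LG"]) == [1, 3]
        assert t1.equals(t2)

    def test_lg_exceeding_min_length_rejected(self, planted_profiles):
        profiles, labels = planted_profiles
        with pytest.raises(EvaluationError, match="exceed"):
            lg_sweep(profiles, labels, [1, 45])
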