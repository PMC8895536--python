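import numpy as np
import pandas as pd
import pytest

from miescreen.annotations import build_mies, cluster_mies, derive_mie_records
from miescreen.modeling import (
    ClassifierSpec,
    TrainingSet,
    accuracy,
    assemble_training_set,
    cross_validated_train,
    eligible_mies,
    predict_scores,
)
from miescreen.profiles import ExpressionMatrix
from tests.test_annotations import rec


def toy_corpus(n_chems_a=5, profiles_per_chem=10, n_chems_b=8):
    """Two disjoint MIEs in one cell line: A (the modelled one) and B (pool)."""
    records = []
    for i in range(n_chems_a):
        records.append(rec(f"a{i}", "T1", "+", 10))
    for i in range(n_chems_b):
        records.append(rec(f"b{i}", "T2", "-", 10))
    # a low-support and an opposite-mode link to T1: both must poison the pool
    records.append(rec("b0", "T1", "+", 3))
    records.append(rec("b1", "T1", "-", 20))
    rows = []
    pid = 0
    for chem in [f"a{i}" for i in range(n_chems_a)] + [
        f"b{i}" for i in range(n_chems_b)
    ]:
        for _ in range(profiles_per_chem):
            rows.append(
                {"profile_id": f"p{pid}", "chemical_id": chem, "cell_line": "X"}
            )
            pid += 1
    meta = pd.DataFrame(rows)
    clusters = cluster_mies(build_mies(derive_mie_records(records)))
    return records, meta, clusters


def gaussian_features(ts, shift, n_features=20, seed=0):
    """Feature matrix where active profiles are ``shift`` noise-sds above."""
    rng = np.random.default_rng(seed)
    ids = sorted(ts.all_profiles)
    active = set(ts.active_profiles) | set(ts.holdout_active)
    cols = {
        p: rng.normal(size=n_features) + (shift if p in active else 0.0)
        for p in ids
    }
    data = pd.DataFrame(cols, index=[f"f{i}" for i in range(n_features)])
    return ExpressionMatrix(data, pd.Series("landmark", index=data.index))


class TestEligibleMies:
    @pytest.mark.parametrize(
        "n_chems, profiles_per_chem, expect",
        [(5, 10, True), (4, 50, False), (6, 8, False)],
    )
    def test_boundaries(self, n_chems, profiles_per_chem, expect):
        _, meta, clusters = toy_corpus(n_chems, profiles_per_chem)
        out = eligible_mies(clusters, meta, "X", min_profiles=50)
        assert ("T1 (+)" in out) is expect

    def test_support_floor(self):
        records, meta, clusters = toy_corpus()
        # drop one chemical to support 4: only 4 high-support chems remain
        records = [
            rec(r.chemical_id, r.target, r.mode, 4 if r.chemical_id == "a0"
                and r.target == "T1" else r.support)
            for r in records
        ]
        clusters = cluster_mies(build_mies(derive_mie_records(records)))
        assert "T1 (+)" not in eligible_mies(clusters, meta, "X")


class TestAssembleTrainingSet:
    def get(self, seed=0, **kwargs):
        records, meta, clusters = toy_corpus(**kwargs)
        target = next(c for c in clusters if c.display_name == "T1 (+)")
        return records, meta, clusters, target, assemble_training_set(
            target, clusters, records, meta, "X", rng_seed=seed
        )

    def test_balanced_and_split_sizes(self):
        # 50 active profiles -> 10 + 10 holdout, 40 + 40 training
        *_, ts = self.get()
        assert len(ts.active_profiles) == len(ts.inactive_profiles) == 40
        assert len(ts.holdout_active) == len(ts.holdout_inactive) == 10

    def test_train_holdout_disjoint(self):
        *_, ts = self.get()
        train = set(ts.active_profiles) | set(ts.inactive_profiles)
        hold = set(ts.holdout_active) | set(ts.holdout_inactive)
        assert not train & hold

    def test_any_support_any_mode_poisons_inactive_pool(self):
        records, meta, clusters, target, ts = self.get()
        chem_of = meta.set_index("profile_id")["chemical_id"]
        inactive_chems = set(
            chem_of[ts.inactive_profiles + ts.holdout_inactive]
        )
        # b0 is linked to T1 at support 3, b1 with the opposite mode
        assert "b0" not in inactive_chems and "b1" not in inactive_chems

    def test_exemplar_chemical_fully_absent(self):
        records, meta, clusters = toy_corpus(n_chems_a=6)
        target = next(c for c in clusters if c.display_name == "T1 (+)")
        ts = assemble_training_set(
            target, clusters, records, meta, "X",
            exemplar_exclusions=frozenset({"a0"}), rng_seed=1,
        )
        chem_of = meta.set_index("profile_id")["chemical_id"]
        assert "a0" not in set(chem_of[sorted(ts.all_profiles)])

    def test_small_inactive_pool_errors_with_diagnostics(self):
        with pytest.raises(ValueError, match="inactive pool"):
            self.get(n_chems_b=2)

    def test_reproducible_for_fixed_seed(self):
        *_, a = self.get(seed=7)
        *_, b = self.get(seed=7)
        assert a == b


class TestAccuracy:
    @pytest.mark.parametrize(
        "counts, expected",
        [((3, 2, 1, 2), 0.625), ((5, 5, 0, 0), 1.0), ((0, 0, 3, 3), 0.0)],
    )
    def test_proportion_correct(self, counts, expected):
        assert accuracy(*counts) == pytest.approx(expected)

    def test_zero_counts_error(self):
        with pytest.raises(ValueError):
            accuracy(0, 0, 0, 0)


class TestCrossValidatedTrain:
    def make_ts(self, n=30):
        half = [f"p{i}" for i in range(n)]
        other = [f"p{i}" for i in range(n, 2 * n)]
        return TrainingSet(
            "T1 (+)", "X",
            active_profiles=half[: int(0.8 * n)],
            inactive_profiles=other[: int(0.8 * n)],
            holdout_active=half[int(0.8 * n) :],
            holdout_inactive=other[int(0.8 * n) :],
        )

    def test_separable_data_trains_accurately(self):
        ts = self.make_ts()
        features = gaussian_features(ts, shift=3.0, seed=1)
        result = cross_validated_train(
            ts, features, ClassifierSpec("SVM_L", seed=0)
        )
        assert result.internal_accuracy >= 0.95
        assert result.holdout_accuracy >= 0.95
        assert result.internal_accuracy == pytest.approx(
            float(np.mean(result.fold_accuracies)), abs=1e-12
        )
        assert len(result.fold_accuracies) == 5

    def test_uninformative_features_stay_near_chance(self):
        accs = []
        for rep in range(20):
            ts = self.make_ts()
            features = gaussian_features(ts, shift=0.0, seed=100 + rep)
            result = cross_validated_train(
                ts, features, ClassifierSpec("SVM_L", seed=rep)
            )
            accs.append(result.internal_accuracy)
        # 48 training profiles: one-repeat sd ~ 0.5/sqrt(48); 3 sds of the mean
        sd_mean = 0.5 / np.sqrt(48) / np.sqrt(20)
        assert abs(np.mean(accs) - 0.5) < 3 * sd_mean + 1e-9

    def test_fold_assignment_is_seeded_partition(self):
        from sklearn.model_selection import StratifiedKFold

        X = np.zeros((40, 2))
        y = np.array([0, 1] * 20)
        folds = list(
            StratifiedKFold(5, shuffle=True, random_state=3).split(X, y)
        )
        test_sets = [set(te) for _, te in folds]
        assert sorted(len(s) for s in test_sets) == [8] * 5
        assert set().union(*test_sets) == set(range(40))
        again = list(
            StratifiedKFold(5, shuffle=True, random_state=3).split(X, y)
        )
        for (_, a), (_, b) in zip(folds, again):
            np.testing.assert_array_equal(a, b)

    def test_too_few_per_class_errors(self):
        ts = TrainingSet(
            "T1 (+)", "X",
            active_profiles=["p0", "p1"], inactive_profiles=["p2", "p3"],
            holdout_active=[], holdout_inactive=[],
        )
        features = gaussian_features(ts, shift=1.0)
        with pytest.raises(ValueError, match="stratify"):
            cross_validated_train(ts, features, ClassifierSpec("SVM_L"))

    @pytest.mark.parametrize("algorithm", ["SVM_R", "KNN", "MLP", "NB"])
    def test_all_algorithms_run(self, algorithm):
        ts = self.make_ts(n=20)
        features = gaussian_features(ts, shift=3.0, seed=2)
        result = cross_validated_train(
            ts, features, ClassifierSpec(algorithm, seed=0)
        )
        assert result.internal_accuracy > 0.8
        assert result.best_hyperparameters


class TestPredictScores:
    def fit(self, algorithm="SVM_L"):
        ts = self.ts = TestCrossValidatedTrain().make_ts()
        features = gaussian_features(ts, shift=3.0, seed=4)
        result = cross_validated_train(
            ts, features, ClassifierSpec(algorithm, seed=0)
        )
        return result, features

    @pytest.mark.parametrize("algorithm", ["SVM_L", "KNN", "NB"])
    def test_scores_separate_classes_perfectly(self, algorithm):
        result, features = self.fit(algorithm)
        scores = predict_scores(result, features)
        active = set(self.ts.active_profiles) | set(self.ts.holdout_active)
        act = scores[scores.index.isin(active)]
        inact = scores[~scores.index.isin(active)]
        assert act.min() > inact.max()  # AUC 1.0 on separable training data

    def test_duplicated_profile_gets_identical_score(self):
        result, features = self.fit()
        dup = features.data.copy()
        dup["copy_of_p0"] = dup["p0"]
        dup_matrix = ExpressionMatrix(
            dup, features.feature_class
        )
        scores = predict_scores(result, dup_matrix)
        assert scores["copy_of_p0"] == scores["p0"]

    def test_missing_features_error_lists_them(self):
        result, features = self.fit()
        truncated = features.subset_features(list(features.feature_ids[:10]))
        with pytest.raises(ValueError, match="f1"):
            predict_scores(result, truncated)
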