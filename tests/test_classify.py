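"""Feature assembly and cross-validated classifier battery."""

import numpy as np
import pandas as pd
import pytest

import olfalert as oa
from conftest import synthetic_std_table
from olfalert import classify as ocl
from olfalert.stats import load_table2


@pytest.fixture(scope="module")
def fixture_features(std_table_30, table2):
    return ocl.build_features(std_table_30, table2, band_set="all")


class TestBuildFeatures:
    def test_all_bands_matrix_shape(self, fixture_features):
        assert fixture_features.X.shape == (180, 108)  # 30 subj x 3 epochs x 2 cond
        assert len(fixture_features.y) == 180
        # balanced classes
        labels, counts = np.unique(fixture_features.y, return_counts=True)
        assert set(labels) == set(oa.CONDITIONS)
        assert counts[0] == counts[1]

    def test_alpha_band_column_count(self, std_table_30, table2):
        fm = ocl.build_features(std_table_30, table2, band_set="alpha")
        assert fm.X.shape[1] == 20  # 2 + 5 + 1 + 2 + 10 across the 5 metric rows

    def test_empty_band_set_rejected(self, std_table_30, table2):
        with pytest.raises(ValueError, match="no significant features"):
            ocl.build_features(std_table_30, table2.iloc[:0], band_set="all")

    def test_rows_with_missing_features_dropped(self, table2):
        df = synthetic_std_table(n_subjects=10)
        mask = (
            (df.subject_id == "S00") & (df.epoch_group == 6)
            & (df.condition == "alerting") & (df.channel == "F3")
            & (df.band == "alpha") & (df.metric == "ND")
        )
        df.loc[mask, "value_std"] = np.nan
        fm = ocl.build_features(df, load_table2(), band_set="all")
        assert fm.n_dropped == 1
        assert fm.X.shape == (59, 108)


class TestModelContracts:
    def test_knn_memorizes_training_set(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 5))
        y = rng.integers(0, 2, 40)
        model = ocl.knn_classifier(1).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_linear_svm_separable_blobs(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.repeat([0, 1], 30)
        for C in ocl.DEFAULT_GRIDS["svm_linear"]:
            model = ocl.linear_svm(C).fit(X[::2], y[::2])
            assert (model.predict(X[1::2]) == y[1::2]).all()

    def test_rings_need_rbf_kernel(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 2 * np.pi, 400)
        radius = np.repeat([1.0, 3.0], 200) + rng.normal(0, 0.1, 400)
        X = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        y = np.repeat([0, 1], 200)
        idx = rng.permutation(400)
        train, test = idx[:300], idx[300:]
        rbf = ocl.rbf_svm(10.0, gamma=1.0).fit(X[train], y[train])
        lin = ocl.linear_svm(10.0).fit(X[train], y[train])
        rbf_acc = (rbf.predict(X[test]) == y[test]).mean()
        lin_acc = (lin.predict(X[test]) == y[test]).mean()
        assert rbf_acc > 0.9
        assert lin_acc < 0.75  # no linear separator exists for rings
        assert rbf_acc - lin_acc > 0.2

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ocl.knn_classifier(0)
        with pytest.raises(ValueError):
            ocl.linear_svm(-1.0)
        with pytest.raises(ValueError):
            ocl.rbf_svm(1.0, gamma=0.0)
        with pytest.raises(ValueError):
            ocl.xgboost_classifier(0.0)


def noise_features(n=60, p=8, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)),
                     columns=[f"f{i}" for i in range(p)])
    y = np.array(["alerting", "relaxing"] * (n // 2))
    return ocl.FeatureMatrix(
        X=X, y=y, subjects=np.repeat([f"S{i}" for i in range(n // 2)], 2),
        band_set="all",
    )


class TestGridSearchCv:
    def test_deterministic_for_fixed_seed(self, fixture_features):
        a = ocl.grid_search_cv(fixture_features, "knn", seed=3)
        b = ocl.grid_search_cv(fixture_features, "knn", seed=3)
        assert a == b

    def test_report_contract(self, fixture_features):
        rep = ocl.grid_search_cv(fixture_features, "svm_rbf", seed=0)
        assert 0 <= rep.accuracy_mean <= 100
        assert len(rep.fold_accuracies) == 10
        se = np.std(rep.fold_accuracies, ddof=1) / np.sqrt(10)
        assert rep.accuracy_se == pytest.approx(se)
        assert rep.best_params["C"] in ocl.DEFAULT_GRIDS["svm_rbf"]

    def test_chance_level_on_random_labels(self):
        accs = []
        for seed in range(20):
            fm = noise_features(seed=seed)
            rng = np.random.default_rng(seed)
            fm.y = rng.permutation(fm.y)
            if len(np.unique(fm.y[:2])) < 1:  # pragma: no cover
                continue
            rep = ocl.grid_search_cv(fm, "knn", seed=seed)
            accs.append(rep.accuracy_mean)
        assert abs(np.mean(accs) - 50.0) <= 10.0

    def test_too_few_samples_rejected(self):
        fm = noise_features(n=10)
        with pytest.raises(ValueError, match=">= 20 samples"):
            ocl.grid_search_cv(fm, "knn")

    def test_single_class_rejected(self):
        fm = noise_features()
        fm.y = np.array(["alerting"] * len(fm.y))
        with pytest.raises(ValueError, match="both classes"):
            ocl.grid_search_cv(fm, "knn")

    def test_fold_index_probe_does_not_help(self):
        # A feature equal to the row's fold index carries no label
        # information in the training folds; accuracy must stay at chance.
        from sklearn.model_selection import StratifiedKFold

        fm = noise_features(n=60, p=4, seed=5)
        y = (fm.y == "relaxing").astype(int)
        folds = np.zeros(60, dtype=int)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=7)
        for k, (_, te) in enumerate(skf.split(fm.X.to_numpy(), y)):
            folds[te] = k
        fm.X["probe"] = folds.astype(float)
        rep = ocl.grid_search_cv(fm, "knn", seed=7)
        assert abs(rep.accuracy_mean - 50.0) <= 15.0

    def test_subject_grouped_folds_keep_subjects_together(self, std_table_30, table2):
        fm = ocl.build_features(std_table_30, table2, band_set="alpha")
        rep = ocl.grid_search_cv(fm, "svm_linear", seed=0, subject_grouped=True)
        assert len(rep.fold_accuracies) == 10


class TestBandBattery:
    def test_cardinality_and_determinism(self, engineered_cohort, table2):
        std_table, _ = engineered_cohort
        reports = ocl.run_band_battery(
            std_table, table2, seed=1,
            families=("knn", "svm_linear", "svm_rbf"),
        )
        assert len(reports) == 18  # 3 classifiers x 6 band-sets
        key = {(r.classifier, r.band_set) for r in reports}
        assert len(key) == 18
        again = ocl.run_band_battery(
            std_table, table2, seed=1, families=("knn",), band_sets=("alpha",)
        )
        first = next(r for r in reports if r.classifier == "knn" and r.band_set == "alpha")
        assert again[0] == first

    def test_engineered_separation_rbf_all_bands(self, engineered_cohort, table2):
        std_table, _ = engineered_cohort
        fm = ocl.build_features(std_table, table2, band_set="all")
        rep = ocl.grid_search_cv(fm, "svm_rbf", seed=0)
        assert rep.accuracy_mean >= 90.0

    def test_xgboost_learns_engineered_effect(self, engineered_cohort, table2):
        std_table, _ = engineered_cohort
        fm = ocl.build_features(std_table, table2, band_set="alpha")
        rep = ocl.grid_search_cv(fm, "xgboost", seed=0, grid=(1, 5))
        assert rep.accuracy_mean >= 80.0
        assert rep.best_params["lambda"] in (1, 5)

    @staticmethod
    def psd_cohort(suppression, seed, n_subjects=12):
        sim = oa.SimConfig(
            n_subjects=n_subjects, fs_hz=125.0, alpha_suppression=suppression,
            rt_effect_s=0.0, artifacts_enabled=False, seed=seed,
        )
        std_table, _ = oa.pipeline.simulate_cohort_metrics(
            sim, epochs=(5, 6, 7, 8), trials_per_epoch=2, metrics="psd"
        )
        return std_table

    def test_zero_effect_cohort_at_chance_with_grouped_folds(self, table2):
        # Plain 10-fold lets epochs of one session span train and test;
        # since they share the session's baseline divisor, the classifier
        # can fingerprint the session even without any condition effect.
        # Subject-grouped folds remove that route; accuracy must be chance.
        flags = table2[table2.metric == "PSD"]
        std_table = self.psd_cohort(0.0, seed=77)
        fm = ocl.build_features(std_table, flags, band_set="all")
        rep = ocl.grid_search_cv(fm, "svm_rbf", seed=0, subject_grouped=True)
        assert abs(rep.accuracy_mean - 50.0) <= 10.0

    def test_session_fingerprint_inflates_plain_folds(self, table2):
        # The companion property: with plain folds the same null cohort
        # classifies far above chance purely via shared baselines.
        flags = table2[table2.metric == "PSD"]
        std_table = self.psd_cohort(0.0, seed=77)
        fm = ocl.build_features(std_table, flags, band_set="all")
        rep = ocl.grid_search_cv(fm, "svm_rbf", seed=0, subject_grouped=False)
        assert rep.accuracy_mean > 70.0

    def test_accuracy_monotone_in_suppression(self, table2):
        flags = table2[table2.metric == "PSD"]
        means = []
        for supp in (0.0, 0.25, 0.5):
            accs = []
            for seed in (0, 1):
                std_table = self.psd_cohort(supp, seed=seed)
                fm = ocl.build_features(std_table, flags, band_set="alpha")
                accs.append(
                    ocl.grid_search_cv(
                        fm, "svm_rbf", seed=seed, subject_grouped=True
                    ).accuracy_mean
                )
            means.append(np.mean(accs))
        assert means[0] <= means[1] + 5.0 and means[1] <= means[2] + 5.0
        assert means[2] > means[0]
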