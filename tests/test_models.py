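"""Model suite: the closed 11-configuration list, training determinism,
separability on synthetic data, permutation null, CV and leakage probe."""

import warnings

import numpy as np
import pandas as pd
import pytest

import cleavesite as cs
from cleavesite.models import (
    cross_validate,
    cv_mean,
    enumerate_model_configs,
    get_config,
    predict_scores,
    train_model,
)

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="module")
def xy(default_dataset, default_split):
    X = default_dataset.features
    y = default_dataset.labels
    train, test = default_split
    return X, y, train, test


class TestConfigEnumeration:
    def test_exactly_eleven(self):
        configs = enumerate_model_configs()
        assert len(configs) == 11
        assert len({c.model_id for c in configs}) == 11

    def test_family_counts(self):
        fams = [c.family for c in enumerate_model_configs()]
        assert fams.count("ANN") == 6 and fams.count("SVM") == 4 and fams.count("RF") == 1

    def test_printed_hyperparameters(self):
        by_id = {c.model_id: c for c in enumerate_model_configs()}
        assert by_id["ANN1-Tanh"].hyperparameters["hidden_layer_sizes"] == (25, 25, 25)
        assert by_id["ANN2-ReLU"].hyperparameters["hidden_layer_sizes"] == (30, 20, 10, 5)
        assert by_id["ANN1-Logistic"].hyperparameters["learning_rate_init"] == 0.001
        assert by_id["SVM-Polynomial"].hyperparameters["degree"] == 3
        assert by_id["RF"].hyperparameters == {
            "n_estimators": 100,
            "criterion": "gini",
            "bootstrap": True,
        }

    def test_unknown_id_refused(self):
        with pytest.raises(KeyError):
            get_config("DeepCNN")


class TestTraining:
    def test_rf_separates_synthetic_data(self, xy):
        X, y, train, test = xy
        fitted = train_model(get_config("RF"), X.loc[train], y.loc[train], seed=0)
        rep = cs.metric_suite(y.loc[test].values, predict_scores(fitted, X.loc[test]))
        assert rep.auc >= 90.0

    def test_seed_determinism_per_family(self, xy):
        X, y, train, test = xy
        for mid in ("RF", "SVM-Gaussian", "ANN1-Tanh"):
            a = predict_scores(
                train_model(get_config(mid), X.loc[train], y.loc[train], seed=3), X.loc[test]
            )
            b = predict_scores(
                train_model(get_config(mid), X.loc[train], y.loc[train], seed=3), X.loc[test]
            )
            np.testing.assert_array_equal(a, b)

    def test_permuted_labels_destroy_signal(self, xy):
        # single permutations are noisy at n=114, so the null is checked
        # on the mean over several independent permutations
        X, y, train, test = xy
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            y_perm = pd.Series(rng.permutation(y.loc[train].values), index=train)
            fitted = train_model(get_config("RF"), X.loc[train], y_perm, seed=0)
            rep = cs.metric_suite(y.loc[test].values, predict_scores(fitted, X.loc[test]))
            aucs.append(rep.auc)
        assert 40.0 <= np.mean(aucs) <= 60.0

    def test_single_class_rejected(self, xy):
        X, y, train, _ = xy
        pos = [s for s in train if y.loc[s] == 1]
        with pytest.raises(ValueError):
            train_model(get_config("RF"), X.loc[pos], y.loc[pos], seed=0)

    def test_scores_in_unit_interval_and_width_checked(self, xy):
        X, y, train, test = xy
        fitted = train_model(get_config("SVM-Linear"), X.loc[train], y.loc[train], seed=0)
        s = predict_scores(fitted, X.loc[test])
        assert np.all((0 <= s) & (s <= 1))
        with pytest.raises(ValueError):
            predict_scores(fitted, X.loc[test].iloc[:, :10])
        with pytest.raises(ValueError):
            predict_scores(fitted, X.loc[[]])

    def test_on_target_outscores_heavy_off_target(self, xy):
        # monotone signal: a forest score for a clean on-target should beat
        # a 6-mismatch off-target (median over pairs)
        X, y, train, test = xy
        fitted = train_model(get_config("RF"), X.loc[train], y.loc[train], seed=0)
        rng = np.random.default_rng(1)
        prof = cs.GenerationProfile(
            off_target_mismatch_distribution={6: 1.0}, bulge_probability=0.0
        )
        guides, sites = [], []
        for i in range(100):
            g = cs.generate_guide(rng, 20, f"g{i}")
            guides.append(g)
            sites.append(cs.embed_on_target(g, rng, prof, f"on{i}"))
            sites.append(cs.mutate_off_target(g, rng, prof, f"off{i}"))
        ds = cs.LabeledDataset(guides=guides, sites=sites)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            M = cs.featurize_dataset(ds)
        scores = predict_scores(fitted, M)
        on = scores[::2]
        off = scores[1::2]
        assert np.median(on - off) > 0


class TestCrossValidation:
    def test_five_fold_shape_on_study_train_size(self, xy):
        X, y, train, _ = xy
        assert len(train) == 265
        reports = cross_validate(get_config("RF"), X.loc[train], y.loc[train], k=5, seed=0)
        assert len(reports) == 5
        assert all(r.counts.total == 53 for r in reports)

    def test_cv_mean_close_to_holdout(self, xy):
        X, y, train, test = xy
        reports = cross_validate(get_config("RF"), X.loc[train], y.loc[train], k=5, seed=0)
        mean_auc = cv_mean(reports, "RF").auc
        fitted = train_model(get_config("RF"), X.loc[train], y.loc[train], seed=0)
        holdout_auc = cs.metric_suite(y.loc[test].values, predict_scores(fitted, X.loc[test])).auc
        assert abs(mean_auc - holdout_auc) <= 10.0

    def test_fold_assignment_deterministic(self, xy):
        X, y, train, _ = xy
        a = cross_validate(get_config("RF"), X.loc[train], y.loc[train], k=5, seed=4)
        b = cross_validate(get_config("RF"), X.loc[train], y.loc[train], k=5, seed=4)
        assert [r.auc for r in a] == [r.auc for r in b]

    def test_no_leakage_from_validation_only_feature(self, xy):
        # probe: a feature equal to the label on the rows of one fold and
        # constant elsewhere. Honest per-fold fitting never sees the
        # label-equal values while training that fold's model, so the
        # fold's metrics must not inflate; a pipeline fitting on the full
        # matrix would read the label straight off the probe.
        X, y, train, _ = xy
        from cleavesite.splits import make_cv_folds

        # weaken the matrix (drop the alignment block) so the base AUC has
        # headroom and inflation would be visible
        weak_cols = [c for c in X.columns if c.split("=")[0] not in (
            "alignment_score", "mismatches", "mismatches_17_20", "rna_bulges",
            "dna_bulges", "wobble_total", "tv_total", "rr_total", "yy_total",
        )]
        Xw = X.loc[train, weak_cols]
        folds = make_cv_folds(train, k=5, seed=9)
        base = cross_validate(get_config("RF"), Xw, y.loc[train], k=5, seed=9)
        probe = pd.Series(0.5, index=train)
        probe.loc[folds[0]] = y.loc[folds[0]].astype(float)
        Xp = Xw.copy()
        Xp["probe"] = probe
        probed = cross_validate(get_config("RF"), Xp, y.loc[train], k=5, seed=9)
        assert base[0].auc <= 90.0  # headroom sanity: weak features only
        assert probed[0].auc <= base[0].auc + 10.0
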