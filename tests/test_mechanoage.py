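"""Stacked ensemble training, ROC/DeLong evaluation, learning curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from mechanonps import (
    TrainingConfig,
    build_feature_table,
    default_cohort_spec,
    simulate_cohort,
)
from mechanonps.mechanoage import (
    _subset,
    delong_ci,
    delong_test,
    downsample_fold,
    evaluate_roc,
    learning_curve_cells,
    learning_curve_samples,
    load_bundle,
    predict,
    save_bundle,
    train,
    variable_importance,
)
from tests.conftest import make_labelled_cells


class TestDownsample:
    def test_majority_reduced_to_minority(self):
        y = np.array(["older"] * 80 + ["younger"] * 20)
        idx = downsample_fold(y, seed=1)
        kept = y[idx]
        assert (kept == "older").sum() == 20
        assert (kept == "younger").sum() == 20

    def test_balanced_input_unchanged(self):
        y = np.array(["older"] * 50 + ["younger"] * 50)
        assert len(downsample_fold(y, seed=1)) == 100

    def test_deterministic(self):
        y = np.array(["older"] * 30 + ["younger"] * 10)
        np.testing.assert_array_equal(downsample_fold(y, 3),
                                      downsample_fold(y, 3))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            downsample_fold(np.array(["older"] * 10), seed=1)


class TestTrainPredict:
    def test_separable_heldout_auc_above_09(self, separable_features,
                                            split_indices, trained_bundle):
        _, te_idx = split_indices
        pred = predict(trained_bundle,
                       separable_features.X.iloc[te_idx].reset_index(drop=True))
        y = (separable_features.label.iloc[te_idx] == "older").to_numpy(int)
        assert roc_auc_score(y, pred["prob_older"]) > 0.9

    def test_same_seed_identical_predictions(self, separable_features,
                                             split_indices, trained_bundle):
        tr_idx, te_idx = split_indices
        bundle2 = train(_subset(separable_features, tr_idx),
                        TrainingConfig.fast(1))
        X_te = separable_features.X.iloc[te_idx].reset_index(drop=True)
        p1 = predict(trained_bundle, X_te)["prob_older"]
        p2 = predict(bundle2, X_te)["prob_older"]
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())

    def test_probabilities_finite_and_bounded(self, separable_features,
                                              trained_bundle):
        pred = predict(trained_bundle, separable_features.X)
        p = pred["prob_older"].to_numpy()
        assert np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()

    def test_duplicated_row_identical_prediction(self, separable_features,
                                                 trained_bundle):
        X = pd.concat([separable_features.X.iloc[[0]]] * 2,
                      ignore_index=True)
        p = predict(trained_bundle, X)["prob_older"]
        assert p.iloc[0] == p.iloc[1]

    def test_class_matches_threshold(self, separable_features,
                                     trained_bundle):
        pred = predict(trained_bundle, separable_features.X)
        thr = trained_bundle.config.class_threshold
        assert ((pred["prob_older"] >= thr) ==
                (pred["class"] == "older")).all()

    def test_schema_mismatch_rejected(self, separable_features,
                                      trained_bundle):
        X = separable_features.X.rename(columns={"wCDI": "nope"})
        with pytest.raises(ValueError, match="schema"):
            predict(trained_bundle, X)

    def test_single_class_training_rejected(self, separable_features):
        fm = _subset(separable_features,
                     np.nonzero((separable_features.label == "older")
                                .to_numpy())[0])
        with pytest.raises(ValueError, match="both classes"):
            train(fm, TrainingConfig.fast(0))

    def test_oof_folds_cover_all_rows(self, trained_bundle):
        assert (trained_bundle.oof_fold_assignment >= 0).all()

    def test_bundle_serialisation_round_trip(self, tmp_path,
                                             separable_features,
                                             trained_bundle):
        path = tmp_path / "bundle.joblib"
        save_bundle(trained_bundle, path)
        back = load_bundle(path)
        p1 = predict(trained_bundle, separable_features.X)["prob_older"]
        p2 = predict(back, separable_features.X)["prob_older"]
        np.testing.assert_array_equal(p1.to_numpy(), p2.to_numpy())


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[["younger"] * 50, ["older"] * 50]
        assert evaluate_roc(scores, labels)["auc"] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 20_000  # SE ~ 0.004, so the band is a sharp null check
        scores = rng.normal(size=n)
        labels = np.where(rng.random(n) < 0.5, "older", "younger")
        assert 0.47 < evaluate_roc(scores, labels)["auc"] < 0.53

    def test_score_negation_symmetry(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=200)
        labels = np.where(rng.random(200) < 0.4, "older", "younger")
        a1 = evaluate_roc(scores, labels)["auc"]
        a2 = evaluate_roc(-scores, labels)["auc"]
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate_roc(np.ones(10), ["older"] * 10)

    def test_delong_ci_covers_truth_on_normal_model(self):
        # binormal model with known AUC = Phi(1/sqrt(2)) ~ 0.760
        rng = np.random.default_rng(7)
        hits = 0
        true_auc = stats.norm.cdf(1 / np.sqrt(2))
        for _ in range(100):
            pos = rng.normal(1, 1, 100)
            neg = rng.normal(0, 1, 100)
            y = np.r_[np.ones(100), np.zeros(100)]
            _, lo, hi = delong_ci(y, np.r_[pos, neg])
            hits += lo <= true_auc <= hi
        assert hits >= 85  # nominal 95%, binomial slack

    def test_delong_identical_scores_p_one(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=100)
        y = (rng.random(100) < 0.5).astype(int)
        _, p = delong_test(y, s, y, s)
        assert p == 1.0

    def test_delong_detects_auc_gap(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(300), np.zeros(300)]
        good = np.r_[rng.normal(3, 1, 300), rng.normal(0, 1, 300)]
        null = rng.normal(size=600)
        _, p = delong_test(y, good, y, null)
        assert p < 1e-3


class TestImportance:
    def test_planted_signal_outranks_noise(self, separable_features,
                                           trained_bundle):
        imp = variable_importance(trained_bundle)
        # wCDI carries the strongest planted separation in the generator
        assert imp.loc["wCDI", "consensus"] > imp.loc["dT_cont_ms", "consensus"]

    def test_each_learner_rescaled_to_100(self, trained_bundle):
        imp = variable_importance(trained_bundle)
        for col in ("bagged_trees", "random_forest", "extra_trees"):
            assert imp[col].max() == pytest.approx(100.0)

    def test_recovery_group_reported_cumulatively(self, trained_bundle):
        imp = variable_importance(trained_bundle)
        cum = imp.attrs["recovery_cumulative_consensus"]
        dummies = [c for c in imp.index if c.startswith("recovery_")]
        assert cum == pytest.approx(imp.loc[dummies, "consensus"].sum())


class TestLearningCurves:
    @pytest.fixture(scope="class")
    def small_features(self):
        return build_feature_table(make_labelled_cells(150, seed=21))

    def test_cells_curve_improves_and_stabilises(self, small_features):
        table = learning_curve_cells(small_features, sizes=[40, 120, 220],
                                     reps=3, seed=2)
        assert len(table) == 3
        rho = stats.spearmanr(table["n_cells"], table["auc_mean"]).statistic
        assert rho > 0
        assert table["auc_se"].iloc[-1] <= table["auc_se"].iloc[0]

    def test_cells_curve_reproducible(self, small_features):
        t1 = learning_curve_cells(small_features, sizes=[60], reps=1, seed=5)
        t2 = learning_curve_cells(small_features, sizes=[60], reps=1, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_request_rejected(self, small_features):
        with pytest.raises(ValueError, match="size exceeds"):
            learning_curve_cells(small_features, sizes=[10_000], reps=1,
                                 seed=1)

    @pytest.fixture(scope="class")
    def cohort_features(self):
        cells, meta = simulate_cohort(default_cohort_spec(
            n_younger=4, n_older=4, cells_per_donor=40, seed=13))
        return build_feature_table(cells, meta)

    #: lean protocol so the many leave-one-sample-out refits stay cheap
    lean = TrainingConfig(bagged_trees_resamples=10, rf_tune_length=2,
                          n_trees=30, cv_folds=3, cv_repeats=1, meta_folds=2,
                          meta_tune_length=2)

    def test_sample_curve_variability_shrinks_with_donors(self,
                                                          cohort_features):
        table = learning_curve_samples(cohort_features, orders=3, seed=3,
                                       config=self.lean)
        assert table["n_donors"].max() == 8
        # orderings disagree less once most donors are included
        assert table["auc_sd"].iloc[-1] <= table["auc_sd"].iloc[0]

    def test_smallest_evaluable_prefix_needs_two_donors_per_class(
            self, cohort_features):
        """Labels attach at donor level, so leave-one-sample-out needs at
        least two donors of each class before an AUC exists; smaller
        prefixes are skipped, not scored."""
        table = learning_curve_samples(cohort_features, orders=2, seed=4,
                                       config=self.lean)
        assert len(table) > 0
        assert table["n_donors"].min() >= 4

    def test_too_few_donors_rejected(self, separable_features):
        with pytest.raises(ValueError, match="3 donors"):
            learning_curve_samples(separable_features, orders=1, seed=1)


def test_size_feature_ablation_degrades_but_not_to_chance():
    """Removing size features on a size-confounded cohort lowers AUC yet
    keeps it above chance (the remaining mechanics still separate)."""
    from mechanonps import default_population_spec, simulate_population
    young = simulate_population(default_population_spec(
        "younger", 250, seed=31, mean_diameter=16.5, wcdi_location=4.4))
    old = simulate_population(default_population_spec(
        "older", 250, seed=32, mean_diameter=19.0, wcdi_location=3.9))
    young["donor_id"], young["age"] = "Y0", 30.0
    old["donor_id"], old["age"] = "O0", 60.0
    cells = pd.concat([young, old], ignore_index=True)
    fm = build_feature_table(cells)

    rng = np.random.default_rng(0)
    idx = rng.permutation(fm.n_cells)
    tr_idx, te_idx = idx[:350], idx[350:]
    y_te = (fm.label.iloc[te_idx] == "older").to_numpy(int)

    full = train(_subset(fm, tr_idx), TrainingConfig.fast(3))
    auc_full = roc_auc_score(
        y_te, predict(full, fm.X.iloc[te_idx].reset_index(drop=True))
        ["prob_older"])

    # ablate size-related columns by neutralising them to their median
    fm_abl = _subset(fm, np.arange(fm.n_cells))
    for col in ("D_cell_um", "L_deform_um", "delta_deform"):
        fm_abl.X[col] = fm_abl.X[col].median()
    abl = train(_subset(fm_abl, tr_idx), TrainingConfig.fast(3))
    auc_abl = roc_auc_score(
        y_te, predict(abl, fm_abl.X.iloc[te_idx].reset_index(drop=True))
        ["prob_older"])

    assert auc_abl < auc_full
    assert auc_abl > 0.6
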