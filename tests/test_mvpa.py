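import numpy as np
import pytest

from restpredict.mvpa import (
    GroupClassifier,
    SymptomPredictor,
    train_linear_classifier,
    train_linear_svr,
)

from oracles import max_margin_direction

FAST = dict(init_alff=20, n_alff=8, n_fc=6, l0=5)


class TestLinearClassifier:
    def test_separable_clouds_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(3, 0.3, (10, 2)), rng.normal(-3, 0.3, (10, 2))])
        y = np.r_[np.ones(10), -np.ones(10)]
        w, b = train_linear_classifier(X, y)
        assert np.all(np.sign(X @ w + b) == y)

    def test_label_flip_negates_decision(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.r_[np.ones(6), -np.ones(6)]
        w1, b1 = train_linear_classifier(X, y)
        w2, b2 = train_linear_classifier(X, -y)
        # agreement is limited by the solver's convergence tolerance
        assert np.allclose(w2, -w1, atol=5e-3)
        assert b2 == pytest.approx(-b1, abs=5e-3)

    def test_margin_direction_matches_grid_search_oracle(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.5], [-1.0, -0.5]])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        w, b = train_linear_classifier(X, y, C=100.0)
        w_oracle, _ = max_margin_direction(X, y)
        cosine = (w / np.linalg.norm(w)) @ w_oracle
        assert cosine > 0.999

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_linear_classifier(rng.normal(size=(5, 2)), np.ones(5))


class TestLinearSVR:
    def test_recovers_planted_line(self, rng):
        x = rng.uniform(-2, 2, size=(40, 1))
        y = 2.0 * x[:, 0] + 1.0
        w, b = train_linear_svr(x, y, C=100.0, epsilon=0.01)
        assert w[0] == pytest.approx(2.0, rel=0.05)
        assert b == pytest.approx(1.0, rel=0.05)

    def test_constant_target_flat_model(self, rng):
        X = rng.normal(size=(20, 3))
        w, b = train_linear_svr(X, np.full(20, 5.0), epsilon=0.2)
        assert np.allclose(w, 0, atol=1e-8)
        preds = X @ w + b
        assert np.allclose(preds, preds[0])

    def test_linearity_of_difference(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ rng.normal(size=4) + rng.normal(0, 0.01, 30)
        w, b = train_linear_svr(X, y)
        x1, x2 = rng.normal(size=4), rng.normal(size=4)
        assert (w @ x1 + b) - (w @ x2 + b) == pytest.approx(w @ (x1 - x2), abs=1e-10)


class TestLOOCVClassification:
    def test_every_subject_held_out_once(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        res = feats.classifier(seed=0, **FAST).fit()
        held = [f.held_out_id for f in res.fold_results]
        assert sorted(held) == sorted(feats.subject_ids.tolist())

    def test_summary_identity(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        res = feats.classifier(seed=0, **FAST).fit()
        n_surv = int((feats.labels == 1).sum())
        n_ctrl = int((feats.labels == -1).sum())
        lhs = res.accuracy * res.n
        rhs = res.sensitivity * n_surv + res.specificity * n_ctrl
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_high_snr_cohort_classified_well(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        res = feats.classifier(seed=0, **FAST).fit()
        assert res.accuracy >= 0.8

    def test_no_leakage_fold_selection_ignores_held_out_subject(self, tiny_signal_features):
        """Perturbing only subject i's features cannot change what fold i
        selects or trains on."""
        feats, _, _ = tiny_signal_features
        res_a = feats.classifier(seed=0, **FAST).fit()
        alff = feats.alff.copy()
        fc = feats.fc.copy()
        alff[0] += 100.0
        fc[0] = -fc[0]
        res_b = GroupClassifier(alff, fc, feats.labels, feats.subject_ids,
                                seed=0, **FAST).fit()
        fa, fb = res_a.fold_results[0], res_b.fold_results[0]
        assert np.array_equal(fa.selected_alff, fb.selected_alff)
        assert np.array_equal(fa.selected_fc, fb.selected_fc)
        assert np.allclose(fa.model_weights, fb.model_weights)

    def test_permuted_labels_do_not_exceed_chance(self, tiny_signal_features):
        """With labels shuffled the LOOCV cannot do better than chance on
        average (LOOCV with selection is chance or *below* under the null,
        never reliably above)."""
        feats, _, _ = tiny_signal_features
        clf = feats.classifier(seed=0, **FAST)
        rng = np.random.default_rng(0)
        accs = [clf.fit(rng.permutation(feats.labels), seed=i).accuracy
                for i in range(20)]
        n_total = 20 * feats.labels.size
        upper = 0.5 + 1.96 * 0.5 / np.sqrt(n_total)
        assert np.mean(accs) <= upper

    def test_dimension_sweep_structure(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        clf = feats.classifier(seed=0, **FAST)
        curve = clf.dimension_sweep([4, 8])
        assert list(curve["n_features"]) == [4, 8]
        assert curve["accuracy"].between(0, 1).all()
        assert clf.params["n_alff"] == FAST["n_alff"]  # sweep restores params

    def test_modalities_restrict_feature_blocks(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        res_a = feats.classifier(modality="alff", seed=0, **FAST).fit()
        res_f = feats.classifier(modality="fc", seed=0, **FAST).fit()
        assert all(f.selected_fc.size == 0 for f in res_a.fold_results)
        assert all(f.selected_alff.size == 0 for f in res_f.fold_results)


class TestLOOCVPrediction:
    @pytest.fixture(scope="class")
    def results(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        return feats.predictor("sas", seed=0, **FAST).fit()

    def test_high_snr_scores_predicted(self, results):
        assert results.r_t1 > 0.8

    def test_change_equals_difference_of_predictions(self, results):
        for f in results.fold_results:
            if f.prediction_t2 is not None:
                assert f.prediction_change == pytest.approx(
                    f.prediction - f.prediction_t2, abs=1e-8)

    def test_time2_fields_only_for_followup(self, results, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        with_t2 = {str(feats.subject_ids[feats.survivor_rows[i]])
                   for i in feats.predictor("sas").t2_index}
        for f in results.fold_results:
            assert (f.prediction_t2 is not None) == (f.held_out_id in with_t2)

    def test_permuted_scores_kill_correlation(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        pred = feats.predictor("sas", seed=0, **FAST)
        rng = np.random.default_rng(1)
        rs = [pred.fit(rng.permutation(pred.y), seed=i).r_t1 for i in range(20)]
        assert abs(np.nanmean(rs)) < 0.35

    def test_missing_scores_rejected(self, tiny_signal_features):
        feats, _, _ = tiny_signal_features
        rows = feats.survivor_rows
        bad = feats.sas[rows].copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            SymptomPredictor(feats.alff[rows], feats.fc[rows], bad)

    def test_summary_text_mentions_all_horizons(self, results):
        text = results.summary()
        assert "Time 1" in text and "Time 2" in text and "Change" in text
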