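"""Cross-validation engine, ROC/AUC, RMAE tables, localization analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tracelink as tl
from tracelink.errors import BadFoldCount, BadSubsetSize, DensityWarning, EmptyClass
from tracelink.evaluation import candidate_labels, pair_errors

from conftest import small_dataset


def auc_concordant_pairs(y, s):
    """Independent Mann-Whitney oracle: concordant pairs with half-credit ties."""
    y, s = np.asarray(y), np.asarray(s)
    pos, neg = s[y == 1], s[y == 0]
    total = len(pos) * len(neg)
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return conc / total


class TestFoldPlan:
    def test_balanced_three_fold_over_29(self):
        plan = tl.make_fold_plan(29, k=3, R=5, seed=0)
        for r in range(5):
            sizes = sorted(np.bincount(plan.assignment[r]))
            assert sizes == [9, 10, 10]

    def test_bad_fold_counts(self):
        with pytest.raises(BadFoldCount):
            tl.make_fold_plan(29, k=1)
        with pytest.raises(BadFoldCount):
            tl.make_fold_plan(5, k=6)

    def test_same_seed_reproducible(self):
        a = tl.make_fold_plan(20, k=4, R=3, seed=42)
        b = tl.make_fold_plan(20, k=4, R=3, seed=42)
        np.testing.assert_array_equal(a.assignment, b.assignment)
        c = tl.make_fold_plan(20, k=4, R=3, seed=43)
        assert not np.array_equal(a.assignment, c.assignment)


class TestRocAuc:
    def test_hand_oracle_case(self):
        """labels (1,0,1,0), scores (.9,.8,.7,.1): 3 of 4 pairs concordant."""
        y = np.array([1, 0, 1, 0])
        s = np.array([0.9, 0.8, 0.7, 0.1])
        assert tl.auc_trapezoid(y, s) == pytest.approx(0.75)
        assert auc_concordant_pairs(y, s) == pytest.approx(0.75)

    @given(st.integers(0, 5000))
    @settings(max_examples=80, deadline=None)
    def test_trapezoid_matches_concordant_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[:2] = [0, 1]
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        assert tl.auc_trapezoid(y, s) == pytest.approx(auc_concordant_pairs(y, s), abs=1e-12)

    def test_truth_as_score_is_perfect(self):
        y = np.array([0, 1, 1, 0, 1])
        assert tl.auc_trapezoid(y, y.astype(float)) == 1.0

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 25)
        if y.sum() in (0, 25):
            y[:2] = [0, 1]
        s = rng.random(25)
        for f in (lambda x: 3 * x + 1, np.exp, lambda x: x**3):
            assert tl.auc_trapezoid(y, f(s)) == pytest.approx(tl.auc_trapezoid(y, s), abs=1e-12)

    def test_roc_endpoints(self):
        y = np.array([1, 0, 1, 0, 1, 1])
        fpr, tpr, _ = tl.roc_points(y, np.random.default_rng(0).random(6))
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)

    def test_max_accuracy_beats_endpoints(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        s = np.clip(y + rng.normal(0, 0.7, 100), 0, 1)
        _, acc = tl.max_accuracy_threshold(y, s)
        base = max(y.mean(), 1 - y.mean())  # all-positive / all-negative
        assert acc >= base


class TestBinaryCV:
    def test_permuted_labels_give_chance_auc(self, small_ds):
        """A predictor scoring from a label-free permutation sits at AUC 0.5."""
        rng = np.random.default_rng(0)
        wm = tl.transform_weights(small_ds)
        y = (candidate_labels(wm) > 0).astype(int)
        aucs = [tl.auc_trapezoid(y, rng.permutation(y).astype(float)) for _ in range(200)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_classical_cv_runs_and_truth_scores_saturate(self, small_ds):
        plan = tl.make_fold_plan(small_ds.n_injected, k=3, R=2, seed=0)
        preds, rep = tl.cross_validate_binary(small_ds, "JA2", plan)
        assert 0.0 <= rep.auc_mean <= 1.0
        assert rep.auc_per_rep.shape == (2,)
        # feeding ground truth as scores is a perfect classifier
        assert tl.auc_trapezoid(preds.y_true, preds.y_true.astype(float)) == 1.0

    def test_ml_cv_beats_chance_on_edr_data(self, small_ds):
        plan = tl.make_fold_plan(small_ds.n_injected, k=3, R=2, seed=0)
        _, rep = tl.cross_validate_binary(
            small_ds, tl.PredictorConfig("KNN", "classifier", seed=0), plan
        )
        assert rep.auc_mean > 0.6

    def test_every_candidate_pair_predicted_each_repetition(self, small_ds):
        plan = tl.make_fold_plan(small_ds.n_injected, k=3, R=2, seed=0)
        preds, _ = tl.cross_validate_binary(small_ds, "CN2", plan)
        T, N = small_ds.fln.shape
        assert preds.pairs.shape[0] == T * (N - 1)
        assert np.isfinite(preds.per_rep).all()

    def test_density_warning_on_ultra_dense_data(self):
        dense = small_dataset(seed=3, lam=0.2, density=0.97)
        with pytest.warns(DensityWarning):
            tl.cross_validate_binary(
                dense, "CN2", tl.make_fold_plan(dense.n_injected, k=2, R=1, seed=0)
            )

    def test_no_leakage_from_test_fold_rows(self, small_ds):
        """Replacing a held-out row with noise leaves its predictions identical."""
        plan = tl.make_fold_plan(small_ds.n_injected, k=2, R=1, seed=5)
        cfg = tl.PredictorConfig("GB", "classifier", seed=0)
        preds, _ = tl.cross_validate_binary(small_ds, cfg, plan)

        fln2 = small_ds.fln.copy()
        test_rows = np.flatnonzero(plan.assignment[0] == 0)
        rng = np.random.default_rng(9)
        inj = small_ds.atlas.injected_indices
        for r in test_rows:
            fln2[r] = np.where(rng.random(fln2.shape[1]) < 0.5, rng.uniform(0, 1, fln2.shape[1]), 0)
            fln2[r, inj[r]] = 0.0
        ds2 = tl.TracingDataset(fln=fln2, dist=small_ds.dist, atlas=small_ds.atlas)
        preds2, _ = tl.cross_validate_binary(ds2, cfg, plan)

        changed_targets = set(inj[test_rows].tolist())
        scores1 = preds.per_rep[0]
        scores2 = preds2.per_rep[0]
        mask = np.array([v in changed_targets for _, v in preds.pairs])
        np.testing.assert_array_equal(scores1[mask], scores2[mask])


class TestWeightedCV:
    def test_exact_predictor_zero_errors(self):
        w = np.array([3.0, 5.5, 1.2, 0.0])
        tab = tl.mae_rmae_table(w, w)
        assert tab.loc["all_links", "MAE"] == 0.0
        assert tab.loc["all_links", "RMAE"] == 0.0

    def test_nonlink_rmae_substitutes_cutoff(self):
        w_true = np.array([0.0])
        w_pred = np.array([1.8])
        tab = tl.mae_rmae_table(w_true, w_pred)
        assert tab.loc["nonlinks", "MAE"] == pytest.approx(1.8)
        assert tab.loc["nonlinks", "RMAE"] == pytest.approx(abs(1.8 - 0.9) / 0.9)
        tab2 = tl.mae_rmae_table(w_true, w_pred, nonlink_rmae="denominator_only")
        assert tab2.loc["nonlinks", "RMAE"] == pytest.approx(1.8 / 0.9)

    def test_all_links_rmae_between_class_extremes(self, small_ds):
        plan = tl.make_fold_plan(small_ds.n_injected, k=3, R=1, seed=0)
        _, rep = tl.cross_validate_weighted(
            small_ds, tl.PredictorConfig("KNN", "regressor", seed=0), plan
        )
        t = rep.mae_rmae
        classes = ["weak", "weak_medium", "medium_strong", "strong"]
        present = [c for c in classes if t.loc[c, "n"] > 0]
        lo = min(t.loc[c, "RMAE"] for c in present)
        hi = max(t.loc[c, "RMAE"] for c in present)
        assert lo - 1e-12 <= t.loc["all_links", "RMAE"] <= hi + 1e-12


class TestClassRestricted:
    def test_empty_class_raises(self, small_ds):
        spec = tl.WeightClassSpec(strong_min=100.0)  # nothing is that strong
        with pytest.raises(EmptyClass):
            tl.class_restricted_cv(small_ds, "strong", "JA2", R=1, class_spec=spec)

    def test_within_class_excludes_out_of_class_links(self, small_ds):
        preds, rep = tl.class_restricted_cv(small_ds, "strong_medium", "JA2", R=2, seed=0)
        wm = tl.transform_weights(small_ds)
        w = candidate_labels(wm)
        spec = tl.WeightClassSpec()
        keep = spec.mask("strong_medium", w) | (w == 0)
        assert preds.pairs.shape[0] == int(keep.sum())
        assert rep.auc_mean > 0.5

    def test_train_class_predict_all_decomposes(self):
        ds = small_dataset(seed=2, n_areas=16, n_injected=10, spread=1.2)
        _, out = tl.class_restricted_cv(
            ds, "strong_medium", "JA2", R=2, seed=0, mode="train_class_predict_all"
        )
        # every class present in the data gets its own decomposed report
        assert set(out) <= {"strong", "strong_medium", "medium_weak", "weak"}
        assert "strong_medium" in out and "weak" in out
        for rep in out.values():
            assert 0.0 <= rep.auc_mean <= 1.0


class TestErrorLocalization:
    def test_scalar_error_definition(self):
        preds = tl.PairPrediction(
            pairs=np.array([[0, 1]]), y_true=np.array([1]),
            per_rep=np.array([[0.2]]), mean_pred=np.array([0.2]), mode="binary",
        )
        assert pair_errors(preds)[0] == pytest.approx(0.8)

    def test_constant_predictions_give_constant_regional_matrix(self, small_ds):
        plan = tl.make_fold_plan(small_ds.n_injected, k=2, R=1, seed=0)
        preds, _ = tl.cross_validate_binary(small_ds, "CN2", plan)
        preds.mean_pred = np.ones_like(preds.mean_pred)
        preds.y_true = np.ones_like(preds.y_true)
        _, regional = tl.error_matrix(preds, small_ds.atlas)
        vals = regional.to_numpy()
        assert np.allclose(vals[np.isfinite(vals)], 0.0)

    def test_error_matrix_layout(self, small_ds):
        plan = tl.make_fold_plan(small_ds.n_injected, k=2, R=1, seed=0)
        preds, _ = tl.cross_validate_binary(small_ds, "CN2", plan)
        M, _ = tl.error_matrix(preds, small_ds.atlas)
        assert M.shape == small_ds.fln.shape
        # the injected diagonal (self-pairs) stays unobserved
        for t in small_ds.atlas.injected:
            assert np.isnan(M.loc[t, t])

    def test_flat_zero_profile(self):
        prof = tl.error_profiles(np.zeros(100), np.linspace(0, 7, 100), n_bins=10)
        assert np.allclose(prof["mean"].dropna(), 0.0)
        assert (prof["n"].sum()) == 100

    def test_weaker_links_harder_on_edr_data(self):
        # wide-spread weights so the weak stratum is populated
        ds = small_dataset(seed=4, n_areas=20, n_injected=14, spread=1.2)
        plan = tl.make_fold_plan(ds.n_injected, k=3, R=2, seed=0)
        preds, rep = tl.cross_validate_weighted(
            ds, tl.PredictorConfig("GB", "regressor", seed=0), plan
        )
        t = rep.mae_rmae
        assert t.loc["weak", "RMAE"] > t.loc["strong", "RMAE"]


class TestResidualDiagnostics:
    def test_exact_predictor_featureless(self):
        w = np.linspace(0.5, 6.5, 40)
        d = tl.residual_diagnostics(w, w)
        assert d["mean_residual"] == 0.0
        assert d["featureless"]

    def test_constant_bias_detected(self):
        w = np.linspace(0.5, 6.5, 40)
        d = tl.residual_diagnostics(w + 0.5, w)
        assert d["mean_residual"] == pytest.approx(0.5)

    def test_heteroscedastic_structure_flagged(self):
        rng = np.random.default_rng(0)
        w_true = np.linspace(0.5, 6.5, 400)
        w_pred = w_true + rng.normal(0, 0.02 + 0.2 * w_true / 7.0, 400)
        d = tl.residual_diagnostics(w_pred, w_true)
        assert not d["featureless"]


class TestInternalScaling:
    def test_degenerate_full_subset_is_leave_one_out(self, small_ds):
        cfg = tl.PredictorConfig("KNN", "regressor", seed=0)
        out = tl.internal_error_scaling(
            small_ds, [small_ds.n_injected], n_rep=1, predictor=cfg, seed=0
        )
        assert out.shape[0] == 1 and np.isfinite(out.loc[small_ds.n_injected, "all_links"])

    def test_reproducible_and_bounds(self, small_ds):
        cfg = tl.PredictorConfig("KNN", "regressor", seed=0)
        a = tl.internal_error_scaling(small_ds, [3, 5], n_rep=3, predictor=cfg, seed=1)
        b = tl.internal_error_scaling(small_ds, [3, 5], n_rep=3, predictor=cfg, seed=1)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(BadSubsetSize):
            tl.internal_error_scaling(small_ds, [1], n_rep=1, predictor=cfg)
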