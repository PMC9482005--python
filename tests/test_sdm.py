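"""Pseudo-absences, learners, split evaluation, metrics, TSS-weighted ensemble."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichekit import (ClimateStack, GridGeometry, OccurrenceTable, auc,
                      confusion_metrics, ensemble_predict, evaluate_split,
                      fit_suitability_model, generate_pseudo_absences, mss_threshold)
from nichekit.learners import RIDGE_LAMBDA


def two_layer_stack(nrows, ncols, seed=0):
    geom = GridGeometry(nrows, ncols, 0.0, 0.0, 1.0)
    rng = np.random.default_rng(seed)
    return ClimateStack(geom, ["a", "b"], rng.normal(size=(2, nrows, ncols)))


class TestPseudoAbsences:
    def test_default_rule_small_presence_set(self):
        stack = two_layer_stack(40, 40)
        rng = np.random.default_rng(1)
        pres = OccurrenceTable.from_points(rng.uniform(0, 40, 500),
                                           rng.uniform(0, 40, 500), "native")
        sets = generate_pseudo_absences(stack, pres, seed=3)
        assert len(sets) == 2
        assert all(len(s.points) == 1000 for s in sets)

    def test_sets_differ_under_one_seed(self):
        stack = two_layer_stack(40, 40)
        pres = OccurrenceTable.from_points([1.5], [1.5], "native")
        s1, s2 = generate_pseudo_absences(stack, pres, n_pa=50, seed=7)
        assert not np.array_equal(s1.points, s2.points)

    def test_points_avoid_presence_cells_and_nodata(self):
        stack = two_layer_stack(10, 10)
        stack.values[:, 0, :] = np.nan  # first row nodata
        pres = OccurrenceTable.from_points([2.5, 3.5], [2.5, 2.5], "native")
        sets = generate_pseudo_absences(stack, pres, n_pa=30, seed=1)
        geom = stack.geometry
        pres_cells = set(zip(*geom.cell_of(pres.lon, pres.lat)))
        for s in sets:
            rows, cols = geom.cell_of(s.points[:, 0], s.points[:, 1])
            assert stack.valid_mask[rows, cols].all()
            assert not (set(zip(rows, cols)) & pres_cells)

    def test_exhausts_tiny_grid(self):
        stack = two_layer_stack(8, 8)
        stack.values[:, :, 2:] = np.nan  # leave a 8x2 valid strip = 16 cells
        pres = OccurrenceTable.from_points([0.5], [7.5], "native")
        sets = generate_pseudo_absences(stack, pres, n_pa=15, n_sets=1, seed=0)
        rows, cols = stack.geometry.cell_of(sets[0].points[:, 0], sets[0].points[:, 1])
        assert len(set(zip(rows, cols))) == 15

    def test_capacity_error(self):
        stack = two_layer_stack(8, 8)
        pres = OccurrenceTable.from_points([0.5], [0.5], "native")
        with pytest.raises(ValueError, match="non-presence cells"):
            generate_pseudo_absences(stack, pres, n_pa=100, seed=0)


def irls_oracle(P, A, lam=RIDGE_LAMBDA, tol=1e-12, max_iter=200):
    """Newton/IRLS solution of the class-balanced ridge logistic objective."""
    X = np.vstack([P, A])
    y = np.concatenate([np.ones(len(P)), np.zeros(len(A))])
    mean, sd = X.mean(0), X.std(0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = np.column_stack([(X - mean) / sd, np.ones(len(X))])  # intercept last
    n = len(y)
    s = np.where(y == 1, n / (2 * y.sum()), n / (2 * (n - y.sum())))
    beta = np.zeros(Z.shape[1])
    pen = lam * np.eye(Z.shape[1])
    pen[-1, -1] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        eta = Z @ beta
        p = 1 / (1 + np.exp(-eta))
        g = Z.T @ (s * (p - y)) + pen @ beta
        H = (Z * (s * p * (1 - p))[:, None]).T @ Z + pen
        step = np.linalg.solve(H, g)
        beta -= step
        if np.linalg.norm(g) < tol:
            break
    return beta[:-1], beta[-1]


class TestLearners:
    def test_envelope_scores_one_at_centroid(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(40, 3))
        A = rng.normal(loc=3, size=(40, 3))
        m = fit_suitability_model("envelope", P, A)
        assert m.predict(P.mean(0)[None, :])[0] == 1.0
        assert np.all((m.predict(A) >= 0) & (m.predict(A) <= 1))

    def test_logit_separable_training_auc_is_one(self):
        rng = np.random.default_rng(1)
        P = rng.normal(loc=4, size=(30, 2))
        A = rng.normal(loc=-4, size=(30, 2))
        m = fit_suitability_model("logit", P, A)
        scores = np.concatenate([m.predict(P), m.predict(A)])
        labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        assert auc(scores, labels) == 1.0

    def test_logit_matches_irls_oracle(self):
        rng = np.random.default_rng(2)
        P = rng.normal(loc=0.8, size=(12, 2))
        A = rng.normal(loc=-0.8, size=(8, 2))
        m = fit_suitability_model("logit", P, A)
        coef, intercept = irls_oracle(P, A)
        assert m.coef_ == pytest.approx(coef, abs=1e-6)
        assert m.intercept_ == pytest.approx(intercept, abs=1e-6)

    def test_singular_covariance_shrinks_with_warning(self):
        P = np.column_stack([np.arange(10.0), np.arange(10.0)])  # rank-1
        A = np.random.default_rng(3).normal(size=(10, 2))
        with pytest.warns(RuntimeWarning, match="singular|shrinkage"):
            m = fit_suitability_model("envelope", P, A)
        assert np.isfinite(m.predict(A)).all()

    def test_unknown_learner_rejected(self):
        with pytest.raises(ValueError, match="unknown learner"):
            fit_suitability_model("maxent", np.ones((3, 2)), np.zeros((3, 2)))


class TestAuc:
    def test_separated_scores(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_trapezoidal_roc_oracle(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.random(30), 2)  # rounding forces ties
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        # trapezoidal integration of the ROC curve over unique thresholds
        ts = np.unique(scores)[::-1]
        tpr = [0.0]
        fpr = [0.0]
        for t in ts:
            pred = scores >= t
            tpr.append((pred & labels).sum() / labels.sum())
            fpr.append((pred & ~labels).sum() / (~labels).sum())
        oracle = np.trapezoid(tpr, fpr)
        assert auc(scores, labels) == pytest.approx(oracle, abs=1e-10)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-5, 5).map(lambda v: round(v, 3)),
                    min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, raw):
        # coarsened scores keep exp() injective in floating point
        scores = np.asarray(raw)
        labels = np.arange(scores.size) % 2 == 0
        assert auc(np.exp(scores / 3), labels) == pytest.approx(auc(scores, labels))

    def test_one_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])


class TestConfusion:
    def test_perfect_prediction(self):
        sens, spec, tss, kappa = confusion_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (sens, spec, tss, kappa) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_arithmetic_2x2(self):
        labels = np.repeat([True, False], [50, 50])
        pred = np.concatenate([np.repeat([True, False], [40, 10]),
                               np.repeat([True, False], [15, 35])])
        sens, spec, tss, kappa = confusion_metrics(pred, labels)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.7)
        assert tss == pytest.approx(0.5)
        # kappa from the marginal-product expected agreement
        p_o, p_e = 0.75, (55 * 50 + 45 * 50) / 100**2
        assert kappa == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_all_positive_predictions(self):
        labels = np.array([1, 1, 1, 0, 0], bool)
        sens, spec, tss, _ = confusion_metrics(np.ones(5, bool), labels)
        assert spec == 0.0 and tss == pytest.approx(sens - 1.0)

    def test_degenerate_margin_named(self):
        with pytest.raises(ValueError, match="positive"):
            confusion_metrics([1, 0], [0, 0])


class TestMss:
    def test_separable_scores(self):
        assert mss_threshold([0.2, 0.3, 0.8, 0.9], [0, 0, 1, 1]) == 0.8

    def test_all_positive_labels_take_min_score(self):
        assert mss_threshold([0.4, 0.7, 0.9], [1, 1, 1]) == 0.4

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            scores = np.round(rng.random(40), 2)
            labels = rng.random(40) < 0.5
            if labels.all() or not labels.any():
                continue
            best_t, best_ss = None, -np.inf
            for t in sorted(set(scores)):
                pred = scores >= t
                ss = ((pred & labels).sum() / labels.sum()
                      + (~pred & ~labels).sum() / (~labels).sum())
                if ss > best_ss + 1e-12:
                    best_t, best_ss = t, ss
            assert mss_threshold(scores, labels) == best_t

    def test_no_positive_labels_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            mss_threshold([0.1, 0.2], [0, 0])


class TestEvaluateSplit:
    def test_four_rows_per_learner(self):
        rng = np.random.default_rng(6)
        P = rng.normal(1, 1, size=(60, 2))
        A = rng.normal(-1, 1, size=(60, 2))
        evals = evaluate_split("logit", P, A, repeats=4, seed=1)
        assert len(evals) == 4
        assert [e.repeat_id for e in evals] == [0, 1, 2, 3]

    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(7)
        P = rng.normal(6, 0.5, size=(40, 2))
        A = rng.normal(-6, 0.5, size=(40, 2))
        for e in evaluate_split("logit", P, A, seed=2):
            assert e.auc == 1.0 and e.tss == 1.0 and e.kappa == 1.0 and e.retained

    def test_null_data_auc_near_half(self):
        rng = np.random.default_rng(8)
        P = rng.normal(size=(500, 3))
        A = rng.normal(size=(500, 3))
        evals = evaluate_split("logit", P, A, repeats=4, seed=3)
        assert abs(np.mean([e.auc for e in evals]) - 0.5) < 0.05

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(9)
        P, A = rng.normal(1, 1, (30, 2)), rng.normal(0, 1, (30, 2))
        e1 = evaluate_split("envelope", P, A, seed=5)
        e2 = evaluate_split("envelope", P, A, seed=5)
        assert [(e.auc, e.tss, e.kappa) for e in e1] == [(e.auc, e.tss, e.kappa) for e in e2]


class FlatModel:
    def __init__(self, value, layer_names):
        self.value = value
        self.layer_names = layer_names

    def predict(self, X):
        return np.full(len(X), self.value)


class TestEnsemble:
    def test_weighted_mean_hand_arithmetic(self):
        stack = two_layer_stack(10, 10)
        models = [FlatModel(0.9, ["a", "b"]), FlatModel(0.3, ["a", "b"])]
        smap = ensemble_predict(models, [0.8, 0.4], stack)
        assert np.nanmax(np.abs(smap.values - 0.7)) < 1e-12

    def test_agreeing_models_ignore_weights(self):
        stack = two_layer_stack(8, 8)
        models = [FlatModel(0.42, ["a", "b"]), FlatModel(0.42, ["a", "b"])]
        smap = ensemble_predict(models, [5.0, 0.1], stack)
        assert np.allclose(smap.values[np.isfinite(smap.values)], 0.42)

    def test_single_model_identity(self):
        stack = two_layer_stack(8, 8, seed=2)
        rng = np.random.default_rng(0)
        m = fit_suitability_model("envelope", rng.normal(size=(20, 2)),
                                  rng.normal(2, 1, size=(20, 2)), ["a", "b"])
        smap = ensemble_predict([m], [0.9], stack)
        rows, cols = np.nonzero(stack.valid_mask)
        direct = m.predict(stack.values_at_cells(rows, cols))
        assert np.allclose(smap.values[rows, cols], direct)

    def test_values_bounded_by_members(self):
        stack = two_layer_stack(8, 8)
        smap = ensemble_predict([FlatModel(0.2, ["a", "b"]), FlatModel(0.8, ["a", "b"])],
                                [1.0, 2.0], stack)
        vals = smap.values[np.isfinite(smap.values)]
        assert np.all(vals >= 0.2 - 1e-12) and np.all(vals <= 0.8 + 1e-12)

    def test_no_models_is_error(self):
        with pytest.raises(ValueError, match="no retained models"):
            ensemble_predict([], [], two_layer_stack(8, 8))

    def test_class_bins(self):
        from nichekit.sdm import classify_suitability

        cls = classify_suitability(np.array([0.1, 0.2, 0.3, 0.45, 0.6, 0.61, np.nan]))
        assert cls.tolist() == [0, 1, 1, 2, 2, 3, -1]
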