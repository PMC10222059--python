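import numpy as np
import pytest
from scipy import stats

from popvuln.rasters import ClimateStack, GridGeometry, Raster
from popvuln.sdm import (
    EnsembleModel,
    FittedLearner,
    LogisticLearner,
    SuitabilityMap,
    best_threshold,
    binarize,
    build_ensemble,
    project,
    rasterize_occurrences,
    sample_pseudo_absences,
    split_calibration,
    tss,
)


class TestRasterizeOccurrences:
    def test_many_points_few_cells(self):
        """1615 points scattered over 14 distinct cells give 14 valid
        occurrences (the deduplication the modelling protocol relies on)."""
        geo = GridGeometry(0, 0, 1000.0, 10, 10)
        rng = np.random.default_rng(0)
        cells = [(r, c) for r, c in zip(rng.integers(0, 10, 14), rng.integers(0, 10, 14))]
        cells = list(dict.fromkeys(cells))
        while len(cells) < 14:
            cells.append((len(cells) % 10, (len(cells) * 3) % 10))
            cells = list(dict.fromkeys(cells))
        pts = []
        for i in range(1615):
            r, c = cells[i % 14]
            pts.append(
                (c * 1000 + rng.uniform(0, 1000), r * 1000 + rng.uniform(0, 1000))
            )
        occ = rasterize_occurrences(np.array(pts), geo)
        assert occ.n_valid == 14

    def test_single_cell(self, geo9):
        pts = np.array([[1.0, 1.0], [2.0, 2.0], [9.0, 9.0]])
        assert rasterize_occurrences(pts, geo9).n_valid == 1

    def test_edge_points_follow_half_open_convention(self, geo9):
        # point exactly on the shared edge x=10 belongs to column 1
        occ = rasterize_occurrences(np.array([[10.0, 5.0], [9.999, 5.0]]), geo9)
        assert occ.n_valid == 2
        expected = {(0, int(np.floor(10.0 / 10))), (0, int(np.floor(9.999 / 10)))}
        assert {tuple(c) for c in occ.presence_cells} == expected


class TestPseudoAbsences:
    def test_all_available_cells_selected_when_n_pa_exhausts_domain(self, geo9):
        occ = rasterize_occurrences(np.array([[5.0, 5.0]]), geo9)
        occ2 = sample_pseudo_absences(occ, n_pa=8, n_scenarios=1, seed=0)
        assert len(occ2.pa_cells[0]) == 8
        cells = {tuple(c) for c in occ2.pa_cells[0]}
        assert (0, 0) not in cells  # the presence cell is excluded

    def test_deterministic_and_scenarios_differ(self, geo9):
        occ = rasterize_occurrences(np.array([[5.0, 5.0]]), geo9)
        a = sample_pseudo_absences(occ, n_pa=4, n_scenarios=2, seed=1)
        b = sample_pseudo_absences(occ, n_pa=4, n_scenarios=2, seed=1)
        np.testing.assert_array_equal(a.pa_cells[0], b.pa_cells[0])
        assert not np.array_equal(a.pa_cells[0], a.pa_cells[1])

    def test_domain_too_small_rejected(self, geo9):
        occ = rasterize_occurrences(np.array([[5.0, 5.0]]), geo9)
        with pytest.raises(ValueError, match="non-presence"):
            sample_pseudo_absences(occ, n_pa=9, n_scenarios=1)

    def test_draws_uniform_over_domain(self):
        """Chi-square goodness of fit over repeated draws on a 100-cell
        domain: selection frequencies should be consistent with uniform."""
        geo = GridGeometry(0, 0, 1.0, 10, 10)
        occ = rasterize_occurrences(np.array([[0.5, 0.5]]), geo)
        counts = np.zeros(100)
        reps = 1000
        for s in range(reps):
            out = sample_pseudo_absences(occ, n_pa=10, n_scenarios=1, seed=s)
            idx = out.pa_cells[0][:, 0] * 10 + out.pa_cells[0][:, 1]
            counts[idx] += 1
        counts = np.delete(counts, 0)  # presence cell never drawn
        _, p = stats.chisquare(counts)
        assert p > 0.001


class TestSplitCalibration:
    def test_seventy_thirty_arithmetic(self):
        labels = np.array([1] * 10 + [0] * 10)
        cal, test = split_calibration(labels, 0.7, seed=0)
        assert labels[cal].sum() == 7 and len(cal) == 14
        assert labels[test].sum() == 3 and len(test) == 6
        assert sorted(np.concatenate([cal, test])) == list(range(20))

    def test_degenerate_ratio_rejected(self):
        labels = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError, match="ratio"):
            split_calibration(labels, 1.0)

    def test_protocol_yields_225_combinations(self):
        # 3 algorithms x 5 pseudo-absence scenarios x 15 repetitions
        assert 3 * 5 * 15 == 225


class TestLogisticLearner:
    def test_coefficients_match_grid_likelihood_maximizer(self):
        """8-point 1-predictor toy set: IRLS coefficients agree with a
        brute-force likelihood maximizer to 1e-3."""
        X = np.array([[-2.0], [-1.5], [-1.0], [-0.5], [0.5], [1.0], [1.5], [0.0]])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 1.0])

        def nll(beta):
            eta = beta[0] + X[:, 0] * beta[1]
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        # coarse-to-fine grid search, independent of the IRLS path
        b = np.array([0.0, 0.0])
        width = 8.0
        for _ in range(12):
            g0 = np.linspace(b[0] - width, b[0] + width, 41)
            g1 = np.linspace(b[1] - width, b[1] + width, 41)
            vals = [(nll((a0, a1)), a0, a1) for a0 in g0 for a1 in g1]
            _, b0, b1 = min(vals)
            b = np.array([b0, b1])
            width /= 4
        learner = LogisticLearner().fit(X, y)
        np.testing.assert_allclose(learner.coef_, b, atol=1e-3)

    def test_duplicated_dataset_leaves_coefficients_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 2))
        y = (X[:, 0] + rng.standard_normal(30) > 0).astype(float)
        a = LogisticLearner().fit(X, y)
        b = LogisticLearner().fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-6)

    def test_independent_labels_give_null_slopes(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((400, 2))
        y = rng.integers(0, 2, 400).astype(float)
        learner = LogisticLearner().fit(X, y)
        # Wald SE of a null logistic slope at p~0.5 is ~ 2/sqrt(n); stay within 3 SE
        assert np.all(np.abs(learner.coef_[1:]) < 3 * 2 / np.sqrt(400))

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 2))
        y = (X @ [1.0, -0.5] + rng.logistic(size=60) > 0).astype(float)
        ours = LogisticLearner().fit(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.coef_, ref.params, atol=1e-6)

    def test_perfect_separation_flagged_and_clipped(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1.0])
        with pytest.warns(UserWarning, match="separation"):
            learner = LogisticLearner().fit(X, y)
        assert learner.separation_
        p = learner.predict(X)
        assert np.all(p >= 1e-6) and np.all(p <= 1 - 1e-6)


class TestTss:
    def test_formula_on_constructed_confusion_counts(self):
        # sensitivity 8/10, specificity 7/10 -> TSS = 0.5
        scores = np.concatenate([np.full(8, 0.9), np.full(2, 0.1),
                                 np.full(3, 0.9), np.full(7, 0.1)])
        labels = np.concatenate([np.ones(10), np.zeros(10)])
        assert tss(scores, labels, 0.5) == pytest.approx(0.5)

    def test_perfect_separation_scores_one(self):
        assert tss([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5) == pytest.approx(1.0)

    def test_random_scores_near_zero(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(tss(scores, labels, 0.5)) < 0.06

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            tss([0.1, 0.9], [1, 1], 0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        t = 0.4
        assert tss(scores, labels, t) == pytest.approx(
            tss(np.exp(scores), labels, np.exp(t))
        )


class TestBestThreshold:
    def test_separable_toy_returns_midpoint(self):
        thr, score = best_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)
        assert score == pytest.approx(1.0)

    def test_constant_scores_give_zero_tss(self):
        thr, score = best_threshold([0.3, 0.3, 0.3], [0, 1, 1])
        assert thr == pytest.approx(0.3)
        assert score == pytest.approx(0.0)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(size=20)
        labels = rng.integers(0, 2, 20)
        thr, score = best_threshold(scores, labels)
        uniq = np.unique(scores)
        cands = (uniq[:-1] + uniq[1:]) / 2
        best = max(tss(scores, labels, t) for t in cands)
        assert score == pytest.approx(best)
        assert tss(scores, labels, thr) == pytest.approx(best)


def _const_learner(value):
    class _L:
        def predict(self, X):
            return np.full(len(X), value)

    return _L()


def member(tss_value, pred_value, alg="glm"):
    return FittedLearner(
        algorithm=alg, learner=_const_learner(pred_value),
        pa_scenario=0, repetition=0, tss_test=tss_value, threshold=0.5,
    )


class TestEnsemble:
    def test_equal_tss_members_average_plainly(self):
        m = build_ensemble([member(0.9, 0.2), member(0.9, 0.6)], ["x"])
        assert m.predict(np.zeros((1, 1)))[0] == pytest.approx(0.4)

    def test_inclusion_rule_is_strictly_greater(self):
        m = build_ensemble([member(0.79, 0.1), member(0.81, 0.9)], ["x"])
        assert len(m.members) == 1
        assert m.members[0].tss_test == pytest.approx(0.81)

    def test_no_member_passes_raises_with_best_tss(self):
        with pytest.raises(ValueError, match="0.750"):
            build_ensemble([member(0.75, 0.5)], ["x"])

    def test_weighted_mean_matches_hand_computation(self):
        m = build_ensemble(
            [member(0.9, 0.2), member(0.85, 0.6), member(0.82, 1.0)], ["x"]
        )
        w = np.array([0.9, 0.85, 0.82])
        expected = (w / w.sum()) @ np.array([0.2, 0.6, 1.0])
        assert m.predict(np.zeros((1, 1)))[0] == pytest.approx(expected)

    def test_ensemble_bounded_by_member_scores(self):
        rng = np.random.default_rng(7)
        members = [member(0.8 + 0.1 * rng.uniform(), rng.uniform()) for _ in range(5)]
        m = build_ensemble(members, ["x"])
        vals = [mm.predict(np.zeros((1, 1)))[0] for mm in m.members]
        p = m.predict(np.zeros((1, 1)))[0]
        assert min(vals) - 1e-12 <= p <= max(vals) + 1e-12


class TestProjectAndBinarize:
    def _stack_and_model(self):
        geo = GridGeometry(0, 0, 1.0, 4, 4)
        vals = np.linspace(-2, 2, 16).reshape(4, 4)
        stack = ClimateStack({"x": vals}, geo)
        learner = LogisticLearner()
        learner.coef_ = np.array([0.0, 2.0])
        learner.converged_ = True
        m = FittedLearner("glm", learner, 0, 0, 0.9, 0.5)
        model = EnsembleModel([m], np.array([1.0]), ["x"], 0.8)
        return stack, model

    def test_monotone_in_single_predictor(self):
        stack, model = self._stack_and_model()
        smap = project(model, stack)
        flat = smap.values.ravel()
        assert np.all(np.diff(flat) >= 0)
        assert flat.min() >= 0 and flat.max() <= 1000

    def test_missing_cells_propagate(self):
        stack, model = self._stack_and_model()
        stack.layers["x"][2, 2] = np.nan
        smap = project(model, stack)
        assert np.isnan(smap.values[2, 2])
        assert np.isfinite(np.delete(smap.values.ravel(), 10)).all()

    def test_missing_predictor_layer_rejected(self):
        stack, model = self._stack_and_model()
        model.predictors = ["x", "gone"]
        with pytest.raises(KeyError, match="gone"):
            project(model, stack)

    def test_binarize_membership_at_published_threshold(self, geo9):
        vals = np.array(
            [[740.0, 747.0, 750.0], [0.0, 1000.0, 746.9], [747.1, 300.0, 800.0]]
        )
        smap = SuitabilityMap(Raster(vals, geo9), "present")
        binary = binarize(smap, 747.0)
        np.testing.assert_array_equal(
            binary.values, (vals >= 747.0).astype(float)
        )

    def test_binarize_extremes(self, geo9):
        vals = np.arange(9.0).reshape(3, 3) * 100
        smap = SuitabilityMap(Raster(vals, geo9), "s")
        assert binarize(smap, 0).values.sum() == 9
        assert binarize(smap, 1000).values.sum() == 0


class TestFullProtocol:
    def test_separable_niche_gives_high_tss(self, pipeline_result):
        """The complete protocol (5 PA scenarios x 15 repetitions) on the
        default synthetic landscape yields a strong pooled-test ensemble."""
        model = pipeline_result.model
        assert model.ensemble_tss > 0.8
        assert all(m.tss_test > 0.8 for m in model.members)
        w = model.weights
        assert w.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(
            w, [m.tss_test for m in model.members] / np.sum([m.tss_test for m in model.members])
        )
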