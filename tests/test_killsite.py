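import numpy as np
import pandas as pd
import pytest

from conftest import build_stack, hourly_fixes
from stepsift.killsite import (
    GPSClusterDetector,
    KillSiteLogistic,
    _binned_spearman,
    buffer_covariates,
    buffer_covariates_frame,
    find_clusters,
    fit_killsite_logistic,
    kfold_spearman,
    match_clusters_to_truth,
    vif_filter,
)
from stepsift.landscape import CUT_NEW, LANDCOVER_CODES
from stepsift.models import ModelSpec, killsite_model_set
from stepsift.simulate import (
    DEFAULT_KERNEL,
    SelectionParams,
    logistic_hazard,
    plant_kill_clusters,
    simulate_killsite_points,
    simulate_trajectory,
)


class TestClusterDetector:
    def test_stationary_fixes_form_one_cluster(self):
        fx = hourly_fixes([(1000, 1000)] * 6)
        clusters = find_clusters(fx, radius_m=300, window_hours=96, min_fixes=4)
        assert len(clusters) == 1
        assert clusters[0].n_fixes == 6
        assert clusters[0].centroid_x == pytest.approx(1000.0)

    def test_dispersed_fixes_form_no_cluster(self):
        fx = hourly_fixes([(i * 1000.0, 0) for i in range(8)])
        assert find_clusters(fx, radius_m=300, window_hours=96, min_fixes=4) == []

    def test_window_limits_membership(self):
        pts = [(0, 0)] * 4 + [(0, 0)] * 4
        fx = hourly_fixes(pts)
        fx.loc[4:, "t"] += pd.Timedelta(hours=200)  # beyond the 96-h window
        clusters = find_clusters(fx, radius_m=300, window_hours=96, min_fixes=4)
        assert len(clusters) == 2

    def test_empty_input(self):
        fx = hourly_fixes([(0, 0)]).iloc[0:0]
        assert find_clusters(fx) == []

    def test_estimator_labels_align_with_clusters(self):
        fx = hourly_fixes([(0, 0)] * 5 + [(5000, 5000)] * 2)
        det = GPSClusterDetector(min_fixes=4).fit(fx)
        assert (det.labels_[:5] == 0).all()
        assert (det.labels_[5:] == -1).all()

    def test_planted_kills_recovered_with_matched_parameters(self, study_land):
        # travelling (ballistic) movement at study scale: only the planted
        # dwells should cluster
        kern = DEFAULT_KERNEL.__class__(shape=6.0, scale_km=0.15, kappa=5.0)
        traj = simulate_trajectory(
            study_land,
            kern,
            SelectionParams(beta={}),
            (15_000, 15_000),
            500,
            seed=8,
            boundary="wrap",
        )
        # ballistic control: no spurious clusters
        assert find_clusters(traj.as_fix_frame(), 300, 96, 6) == []
        hazard = np.zeros(501)
        hazard[[50, 200, 420]] = 1.0
        planted, truth = plant_kill_clusters(
            traj, hazard, study_land, dwell_hours=24, radius_m=100, seed=9
        )
        clusters = find_clusters(planted.as_fix_frame(), 300, 96, 6)
        m = match_clusters_to_truth(clusters, truth.events, radius_m=300)
        assert m["recall"] == 1.0 and m["precision"] == 1.0


class TestBufferCovariates:
    def test_uniform_new_cut_landscape(self):
        stack = build_stack(cut_class=np.full((60, 60), CUT_NEW), ndvi=0.5)
        cov = buffer_covariates((3000, 3000), stack, buffer_m=883)
        assert cov["nc"] == 1.0 and cov["rc"] == 0.0
        assert cov["ndvi"] == pytest.approx(0.5)

    def test_checkerboard_proportions(self):
        checker = np.indices((60, 60)).sum(axis=0) % 2
        lc = np.where(
            checker, LANDCOVER_CODES["deciduous"], LANDCOVER_CODES["coniferous"]
        )
        stack = build_stack(landcover=lc)
        cov = buffer_covariates((3000, 3000), stack, buffer_m=883)
        assert cov["deciduous"] == pytest.approx(0.5, abs=0.02)
        assert cov["coniferous"] == pytest.approx(0.5, abs=0.02)

    def test_proportions_bounded_and_exhaustive(self, small_land):
        rng = np.random.default_rng(0)
        xs = rng.uniform(1000, 11_000, 50)
        ys = rng.uniform(1000, 11_000, 50)
        rec = buffer_covariates_frame(xs, ys, small_land, buffer_m=600)
        classes = ["pine", "deciduous", "mixed_forest", "coniferous", "nc", "rc"]
        total = rec[classes].sum(axis=1)
        assert (total <= 1.0 + 1e-9).all()
        # landcover + cut classes partition the cells, so the summed shares
        # reach 1 only when the class set is exhaustive (non-forest is the
        # remainder here); they are always bounded by 1
        assert (rec[classes] >= 0).all().all()

    def test_zero_valid_cells_rejected(self, small_land):
        with pytest.raises(ValueError, match="valid cells|outside"):
            buffer_covariates((1e7, 1e7), small_land, buffer_m=500)


class TestVifFilter:
    def test_orthogonal_columns_kept_with_unit_vif(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.standard_normal((200, 3)))
        q = q - q.mean(axis=0)  # centre so the intercept stays orthogonal
        df = pd.DataFrame(q, columns=["a", "b", "c"])
        kept, report = vif_filter(df)
        assert kept == ["a", "b", "c"]
        assert np.allclose(report["vif"], 1.0, atol=0.05)

    def test_duplicate_column_removed_with_infinite_vif(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(100)})
        kept, report = vif_filter(df)
        assert len(kept) == 2 and "c" in kept
        assert np.isinf(report.loc[report["removed"], "vif"]).all()

    def test_vif_exactly_four_is_retained(self):
        # b = sqrt(3) a + d with a ⟂ d and equal norms gives R^2 = 3/4, VIF = 4
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        d = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        df = pd.DataFrame({"a": a, "b": np.sqrt(3.0) * a + d})
        kept, report = vif_filter(df, threshold=4.0)
        assert report["vif"].max() == pytest.approx(4.0, abs=1e-9)
        assert kept == ["a", "b"]  # strictly greater than 4 is required

    def test_vif_above_four_is_removed(self):
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        d = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        df = pd.DataFrame({"a": a, "b": 2.0 * a + d})  # R^2 = 0.8 -> VIF 5
        kept, _ = vif_filter(df, threshold=4.0)
        assert len(kept) == 1

    def test_needs_two_terms_and_enough_rows(self):
        with pytest.raises(ValueError):
            vif_filter(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(ValueError):
            vif_filter(pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]}))


class TestKillSiteLogistic:
    def test_recovery_within_monte_carlo_error(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5000, 2))
        eta = -0.5 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = rng.random(5000) < 1 / (1 + np.exp(-eta))
        est = KillSiteLogistic().fit(X, y, term_names=["a", "b"])
        assert abs(est.params_["a"] - 1.2) <= 3 * est.se_["a"]
        assert abs(est.params_["b"] + 0.7) <= 3 * est.se_["b"]

    def test_all_zero_covariates_give_prevalence_intercept(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = np.zeros((100, 2))
        with pytest.warns(UserWarning, match="constant"):
            est = KillSiteLogistic().fit(X, y, term_names=["a", "b"])
        assert est.intercept_ == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)
        assert est.params_["a"] == 0.0 and np.isnan(est.se_["a"])

    def test_z_is_beta_over_se(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((500, 1))
        y = rng.random(500) < 1 / (1 + np.exp(-X[:, 0]))
        est = KillSiteLogistic().fit(X, y, term_names=["a"])
        assert est.z_["a"] == pytest.approx(est.params_["a"] / est.se_["a"])

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="both"):
            KillSiteLogistic().fit(np.zeros((10, 1)), np.ones(10))


class TestKfoldSpearman:
    def test_random_scores_average_near_zero(self):
        rng = np.random.default_rng(5)
        rhos = [
            _binned_spearman(rng.random(100), rng.random(300), n_bins=10)
            for _ in range(200)
        ]
        assert abs(np.nanmean(rhos)) < 0.1

    def test_defaults_run_ten_folds(self, small_land):
        rec = simulate_killsite_points(
            small_land,
            {"intercept": -3.0, "nc": 3.0, "ndvi": 3.0},
            n_kill=200,
            n_random=600,
            buffer_m=400,
            seed=6,
        )
        spec = ModelSpec("t", ("nc", "ndvi"))
        out = kfold_spearman(rec, spec, seed=7)
        assert out["k"] == 10 and len(out["fold_rs"]) == 10
        assert out["mean_rs"] > 0.3  # informative model scores well above null

    def test_monotone_prediction_in_new_cut_proportion(self, small_land):
        rec = simulate_killsite_points(
            small_land,
            {"intercept": -3.0, "nc": 3.0},
            n_kill=400,
            n_random=1200,
            buffer_m=400,
            seed=8,
        )
        spec = next(s for s in killsite_model_set() if s.name == "Prey + Cutblock")
        fit = fit_killsite_logistic(rec, spec)
        assert fit.beta["nc"] > 0
        base = rec[list(spec.terms)].median().to_frame().T
        grid = pd.concat([base] * 9, ignore_index=True)
        grid["nc"] = np.linspace(0, 1, 9)
        p = fit.model.predict_proba_1(grid[list(spec.terms)].to_numpy())
        assert (np.diff(p) > 0).all()
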