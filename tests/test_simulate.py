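import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import build_stack
from stepsift.kernels import MovementKernel
from stepsift.landscape import CUT_NEW
from stepsift.simulate import (
    DEFAULT_KERNEL,
    PopulationPreset,
    SelectionParams,
    default_selection_params,
    logistic_hazard,
    study_roster_preset,
    plant_kill_clusters,
    read_fixes_csv,
    simulate_killsite_points,
    simulate_population,
    simulate_trajectory,
    strong_selection_params,
    write_fixes_csv,
)

NULL = SelectionParams(beta={})


class TestSelectionParams:
    def test_unknown_coefficient_rejected(self):
        with pytest.raises(ValueError, match="unresolvable"):
            SelectionParams(beta={"not_a_term": 1.0})

    def test_presets_resolve(self):
        assert default_selection_params().get("nc") != 0.0
        assert strong_selection_params().get("nc") >= 0.5


class TestSimulateTrajectory:
    def test_seed_determinism(self, small_land):
        a = simulate_trajectory(small_land, DEFAULT_KERNEL, NULL, (6000, 6000), 50, seed=5)
        b = simulate_trajectory(small_land, DEFAULT_KERNEL, NULL, (6000, 6000), 50, seed=5)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)

    def test_null_selection_steps_follow_the_kernel(self, small_land):
        # beta == 0: realized step lengths should match gamma(k0, theta0)
        sls = []
        rng = np.random.default_rng(1)
        for s in range(10):
            start = (rng.uniform(4000, 8000), rng.uniform(4000, 8000))
            traj = simulate_trajectory(
                small_land, DEFAULT_KERNEL, NULL, start, n_steps=500, seed=1000 + s
            )
            d = np.hypot(traj.fixes["x"].diff(), traj.fixes["y"].diff()).dropna() / 1000.0
            sls.append(d.to_numpy())
        sl = np.concatenate(sls)
        ref = DEFAULT_KERNEL.sample_steps(5000, np.random.default_rng(99))[0]
        assert stats.ks_2samp(sl, ref).pvalue > 0.01

    def test_selection_pulls_towards_linear_features(self, small_land):
        pull = SelectionParams(beta={"ln_dist_lf": -1.5})
        d_null, d_pull = [], []
        for s in range(3):
            t0 = simulate_trajectory(
                small_land, DEFAULT_KERNEL, NULL, (6000, 6000), 400, seed=40 + s
            )
            t1 = simulate_trajectory(
                small_land, DEFAULT_KERNEL, pull, (6000, 6000), 400, seed=40 + s
            )
            for t, acc in ((t0, d_null), (t1, d_pull)):
                cov = small_land.covariates_at(
                    t.fixes["x"].to_numpy(), t.fixes["y"].to_numpy(), names=["ln_dist_lf"]
                )
                acc.append(np.mean(cov["ln_dist_lf"]))
        assert np.mean(d_pull) < np.mean(d_null)

    def test_choice_probability_matches_inverse_logit(self):
        # a fine checkerboard binary covariate: candidates land on either
        # phase with equal chance, so the selection frequency of the
        # preferred phase approaches exp(b)/(1+exp(b))
        n = 80
        checker = np.indices((n, n)).sum(axis=0) % 2
        stack = build_stack(n=n, cut_class=checker * CUT_NEW)
        beta = 1.0
        params = SelectionParams(beta={"nc": beta})
        kern = MovementKernel(shape=3.0, scale_km=0.6, kappa=0.0)
        traj = simulate_trajectory(
            stack, kern, params, (4000, 4000), n_steps=4000, seed=3, boundary="reflect"
        )
        nc = stack.covariates_at(
            traj.fixes["x"].to_numpy()[1:], traj.fixes["y"].to_numpy()[1:], names=["nc"]
        )["nc"]
        expected = np.exp(beta) / (1 + np.exp(beta))
        assert nc.mean() == pytest.approx(expected, abs=0.025)

    def test_start_outside_rejected_and_min_candidates(self, small_land):
        with pytest.raises(ValueError, match="start"):
            simulate_trajectory(small_land, DEFAULT_KERNEL, NULL, (-5, 0), 10, seed=0)
        with pytest.raises(ValueError, match="candidates"):
            simulate_trajectory(
                small_land, DEFAULT_KERNEL, NULL, (6000, 6000), 10, n_candidates=5, seed=0
            )


class TestPopulationPreset:
    def test_roster_structure_matches_study_design(self):
        p = study_roster_preset()
        assert p.n_animals == 10 and p.n_packs == 5
        assert p.n_steps >= 2000  # multi-month hourly deployment

    def test_simulated_roster(self, small_land):
        fixes = simulate_population(
            small_land, preset=PopulationPreset(n_animals=4, n_packs=2, n_steps=30), seed=0
        )
        assert fixes["animal_id"].nunique() == 4
        assert fixes["pack_id"].nunique() == 2
        assert len(fixes) == 4 * 31

    def test_fixes_csv_roundtrip(self, small_land, tmp_path):
        fixes = simulate_population(
            small_land, preset=PopulationPreset(n_animals=2, n_packs=1, n_steps=10), seed=1
        )
        write_fixes_csv(fixes, tmp_path / "f.csv")
        back = read_fixes_csv(tmp_path / "f.csv")
        pd.testing.assert_frame_equal(back, fixes, check_dtype=False)


class TestPlantKillClusters:
    def traj(self, small_land, n=100, seed=2):
        return simulate_trajectory(
            small_land, DEFAULT_KERNEL, NULL, (6000, 6000), n, seed=seed
        )

    def test_zero_hazard_leaves_trajectory_unchanged(self, small_land):
        traj = self.traj(small_land)
        with pytest.warns(UserWarning, match="no kills"):
            out, truth = plant_kill_clusters(traj, 0.0, small_land, seed=0)
        assert len(truth) == 0
        pd.testing.assert_frame_equal(out.fixes, traj.fixes)

    def test_forced_kill_inserts_dwell_fixes_within_radius(self, small_land):
        traj = self.traj(small_land, n=40)
        hazard = np.zeros(41)
        hazard[5] = 1.0
        out, truth = plant_kill_clusters(
            traj, hazard, small_land, dwell_hours=24, radius_m=100, seed=1
        )
        assert len(truth) == 1
        ev = truth.events.iloc[0]
        fx = out.fixes.set_index("t")
        dwell = fx.loc[ev["t_start"] : ev["t_start"] + pd.Timedelta(hours=24)]
        assert len(dwell) == 25
        d = np.hypot(dwell["x"] - ev["x"], dwell["y"] - ev["y"])
        assert (d <= 100.0 + 1e-9).all()
        # timeline stays strictly hourly
        assert (pd.Series(fx.index).diff().dropna() == pd.Timedelta(hours=1)).all()

    def test_hazard_concentrates_kills_in_cutblocks(self, small_land):
        traj = self.traj(small_land, n=2000, seed=5)
        hz = logistic_hazard({"intercept": -3.0, "nc": 2.5})
        out, truth = plant_kill_clusters(traj, hz, small_land, seed=2)
        assert len(truth) > 5
        kill_nc = small_land.covariates_at(
            truth.events["x"].to_numpy(), truth.events["y"].to_numpy(), names=["nc"]
        )["nc"]
        traj_nc = small_land.covariates_at(
            traj.fixes["x"].to_numpy(), traj.fixes["y"].to_numpy(), names=["nc"]
        )["nc"]
        assert kill_nc.mean() > traj_nc.mean()

    def test_short_dwell_rejected(self, small_land):
        with pytest.raises(ValueError, match="dwell"):
            plant_kill_clusters(self.traj(small_land), 0.0, small_land, dwell_hours=1)


class TestSimulateKillsitePoints:
    def test_null_truth_distributions_indistinguishable(self, small_land):
        rec = simulate_killsite_points(
            small_land, {"intercept": -1.0}, n_kill=1000, n_random=1000, buffer_m=400, seed=4
        )
        for col in ("nc", "ndvi", "coniferous"):
            a = rec.loc[rec["label"] == 1, col]
            b = rec.loc[rec["label"] == 0, col]
            assert stats.ks_2samp(a, b).pvalue > 0.01, col

    def test_positive_cut_effect_shifts_kills(self, small_land):
        rec = simulate_killsite_points(
            small_land,
            {"intercept": -3.0, "nc": 4.0},
            n_kill=300,
            n_random=300,
            buffer_m=400,
            seed=5,
        )
        assert (
            rec.loc[rec["label"] == 1, "nc"].mean() > rec.loc[rec["label"] == 0, "nc"].mean()
        )

    def test_preset_count_of_158_kills(self, small_land):
        rec = simulate_killsite_points(
            small_land, {"intercept": -1.0}, n_kill=158, n_random=474, buffer_m=400, seed=6
        )
        assert int((rec["label"] == 1).sum()) == 158
        assert int((rec["label"] == 0).sum()) == 474
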