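"""Step-selection machinery: kernels, random steps, conditional logit."""

import math

import numpy as np
import pandas as pd
import pytest

from tests.conftest import T0, make_traj
from translocmove.raster import CLASS_CODES, LandscapeRaster
from translocmove.ssf import (
    EmpiricalMoveKernel,
    SSFConfig,
    annotate_habitat,
    build_kernels,
    classify_diel,
    clogit_loglik,
    design_matrix,
    fit_conditional_logit,
    generate_random_steps,
    rank_models_aic,
    solar_altitude_deg,
    weekly_selection_series,
)
from translocmove.trajectory import AnimalMeta
from translocmove.windows import PhaseAssignment


class TestClassifyDiel:
    def test_fixed_mode_noon_and_midnight(self):
        cfg = SSFConfig(diel_mode="fixed")
        assert classify_diel(pd.Timestamp("2023-06-01 12:00", tz="UTC"), cfg) == "diurnal"
        assert classify_diel(pd.Timestamp("2023-06-01 00:00", tz="UTC"), cfg) == "nocturnal"

    def test_solar_boundary_altitude_zero_is_nocturnal(self):
        # horizon altitude is not strictly positive -> nocturnal
        cfg = SSFConfig(diel_mode="solar", site_latlon=(0.0, 0.0))
        # scan around sunrise at the equator on an equinox for the sign flip
        times = pd.date_range("2023-03-20 05:30", "2023-03-20 06:30",
                              freq="1min", tz="UTC")
        labels = [classify_diel(t, cfg) for t in times]
        assert labels[0] == "nocturnal" and labels[-1] == "diurnal"
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1

    def test_summer_solstice_daylength_at_study_latitude(self):
        # standard almanac: ~14.3 h of daylight at 33.3 N on June 21
        lat, lon = 33.3, -81.7
        times = pd.date_range("2023-06-21 00:00", "2023-06-22 00:00",
                              freq="5min", tz="UTC", inclusive="left")
        up = sum(solar_altitude_deg(t, lat, lon) > 0 for t in times)
        daylength_h = up * 5 / 60
        assert 14.0 < daylength_h < 15.0

    def test_solar_mode_requires_latlon(self):
        cfg = SSFConfig(diel_mode="solar", site_latlon=None)
        with pytest.raises(ValueError, match="site_latlon"):
            classify_diel(T0, cfg)


def _traj_for(aid, status, habitat, xy, start=None):
    release = tuple(np.asarray(xy)[0])
    meta = AnimalMeta(aid, status, release_habitat=habitat,
                      release_xy=release, capture_xy=release if status == "resident" else (0.0, 0.0))
    return make_traj(xy, meta=meta, start=start or T0)


class TestBuildKernels:
    @pytest.fixture
    def cohort(self):
        rng = np.random.default_rng(0)
        trajs = []
        for aid, status, hab in [("A", "translocated", "upland_pine"),
                                 ("B", "translocated", "upland_pine"),
                                 ("r1", "resident", "upland_pine"),
                                 ("r2", "resident", "bottomland")]:
            xy = np.cumsum(rng.normal(0, 150, size=(35 * 12, 2)), axis=0) + 5000
            trajs.append(_traj_for(aid, status, hab, xy))
        return trajs

    @pytest.fixture
    def phases(self):
        return {"translocated_upland_pine": PhaseAssignment(
            "translocated_upland_pine", transition_day=30, horizon=90)}

    def test_leave_one_out_excludes_focal_animal(self, cohort, phases):
        lib = build_kernels(cohort, phases)
        kA = lib.kernel_for("translocated_upland_pine_exploration", "A")
        kB = lib.kernel_for("translocated_upland_pine_exploration", "B")
        assert kA.excluded_animal == "A"
        # A's kernel holds B's steps and vice versa; samples differ
        assert len(kA.lengths) > 0 and len(kB.lengths) > 0
        assert not np.array_equal(np.sort(kA.lengths), np.sort(kB.lengths))

    def test_exclusion_is_idempotent(self, cohort, phases):
        lib = build_kernels(cohort, phases)
        k1 = lib.kernel_for("resident", "r1")
        k2 = lib.kernel_for("resident", "r1")
        np.testing.assert_array_equal(k1.lengths, k2.lengths)

    def test_resident_kernel_pools_both_habitats(self, cohort, phases):
        lib = build_kernels(cohort, phases)
        # the pooled resident kernel for an outsider holds r1 + r2 steps
        k = lib.kernel_for("resident", "A")
        n1 = len(lib.kernel_for("resident", "r1").lengths)
        n2 = len(lib.kernel_for("resident", "r2").lengths)
        assert len(k.lengths) == (n1 + n2) // 2 * 2 or len(k.lengths) > max(n1, n2)

    def test_phase_boundary_day29_vs_30(self, cohort, phases):
        # transition_day 30: day 29 steps are exploration, day 30 exploitation
        pa = phases["translocated_upland_pine"]
        assert pa.phase_of(29) == "exploration"
        assert pa.phase_of(30) == "exploitation"
        lib = build_kernels(cohort, phases)
        assert "translocated_upland_pine_exploration" in lib.strata
        assert "translocated_upland_pine_exploitation" in lib.strata


class TestGenerateRandomSteps:
    def test_degenerate_kernel_all_steps_ahead(self):
        k = EmpiricalMoveKernel("s", "x", np.array([100.0]), np.array([0.0]))
        rng = np.random.default_rng(0)
        alts = generate_random_steps(0.0, 0.0, prev_heading=0.0, kernel=k, n=5, rng=rng)
        np.testing.assert_allclose(alts[:, 0], 100.0)
        np.testing.assert_allclose(alts[:, 1], 0.0, atol=1e-12)
        np.testing.assert_allclose(alts[:, 2], 100.0)

    def test_seeded_reproducibility(self):
        k = EmpiricalMoveKernel("s", "x", np.arange(1.0, 50.0), np.linspace(-3, 3, 49))
        a1 = generate_random_steps(5.0, 5.0, 0.3, k, 20, np.random.default_rng(7))
        a2 = generate_random_steps(5.0, 5.0, 0.3, k, 20, np.random.default_rng(7))
        np.testing.assert_array_equal(a1, a2)

    def test_sampled_length_mean_matches_kernel(self):
        rng0 = np.random.default_rng(3)
        lengths = rng0.gamma(2.0, 100.0, 500)
        k = EmpiricalMoveKernel("s", "x", lengths, np.zeros(10))
        alts = generate_random_steps(0, 0, 0.0, k, 10_000, np.random.default_rng(1))
        se = lengths.std() / math.sqrt(10_000)
        assert abs(alts[:, 2].mean() - lengths.mean()) < 2 * se * math.sqrt(10_000 / 500 + 1) * 3

    def test_undefined_heading_rejected(self):
        k = EmpiricalMoveKernel("s", "x", np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError, match="heading"):
            generate_random_steps(0, 0, np.nan, k, 5, np.random.default_rng(0))


class TestAnnotateHabitat:
    def _df(self, rows):
        base = {"animal_id": "a", "status": "resident",
                "release_habitat": "upland_pine", "group": "resident_upland_pine",
                "phase": None, "diel": "diurnal", "day": 1, "week_index": 1,
                "step_length_m": 100.0}
        return pd.DataFrame([{**base, **r} for r in rows])

    @pytest.fixture
    def landscape(self):
        grid = np.full((10, 10), CLASS_CODES["bottomland"], dtype=np.int16)
        grid[:, 5:] = CLASS_CODES["excluded"]
        return LandscapeRaster((0.0, 0.0), 30.0, grid)

    def test_endpoint_class_recorded(self, landscape):
        df = self._df([
            {"stratum_id": 0, "used": 1, "x": 15.0, "y": 15.0},
            {"stratum_id": 0, "used": 0, "x": 45.0, "y": 45.0},
        ])
        out = annotate_habitat(df, landscape)
        assert set(out["habitat"]) == {"bottomland"}
        assert len(out) == 2

    def test_used_step_in_excluded_class_drops_stratum(self, landscape):
        df = self._df([
            {"stratum_id": 0, "used": 1, "x": 200.0, "y": 15.0},  # excluded
            {"stratum_id": 0, "used": 0, "x": 15.0, "y": 15.0},
            {"stratum_id": 1, "used": 1, "x": 15.0, "y": 45.0},
            {"stratum_id": 1, "used": 0, "x": 45.0, "y": 15.0},
        ])
        out = annotate_habitat(df, landscape)
        assert set(out["stratum_id"]) == {1}

    def test_off_raster_alternative_invalid(self, landscape):
        df = self._df([
            {"stratum_id": 0, "used": 1, "x": 15.0, "y": 15.0},
            {"stratum_id": 0, "used": 0, "x": -50.0, "y": 15.0},
            {"stratum_id": 0, "used": 0, "x": 45.0, "y": 15.0},
        ])
        out = annotate_habitat(df, landscape)
        assert len(out) == 2  # used + one surviving alternative


def _toy_strata():
    """3 strata, 3 alternatives each, hand-set covariates."""
    rows = []
    rng = np.random.default_rng(5)
    habs = ["bottomland", "upland_pine", "grassland"]
    for s in range(3):
        for j in range(3):
            rows.append({
                "stratum_id": s, "animal_id": f"an{s % 2}",
                "status": "resident", "release_habitat": "upland_pine",
                "group": "resident_upland_pine", "phase": None,
                "diel": "diurnal", "day": 1, "week_index": 1,
                "used": 1 if j == s % 3 else 0,
                "habitat": habs[(j + s) % 3],
                "step_length_m": float(rng.integers(50, 500)),
            })
    return pd.DataFrame(rows)


def brute_force_loglik(df, X, beta):
    """Enumeration oracle: per-stratum conditional likelihood by direct sum."""
    ll = 0.0
    for _, g in df.groupby("stratum_id"):
        x = X.loc[g.index].to_numpy()
        eta = x @ beta
        used = g["used"].to_numpy() == 1
        ll += float(eta[used][0] - math.log(np.exp(eta).sum()))
    return ll


class TestConditionalLogit:
    def test_null_loglik_is_minus_sum_log_choicesets(self):
        df = _toy_strata()
        X = design_matrix(df, "habitat")
        ll0 = clogit_loglik(df, X, np.zeros(X.shape[1]))
        assert ll0 == pytest.approx(-3 * math.log(3), abs=1e-12)

    def test_21_alternative_null(self):
        # beta = 0 with 21 alternatives gives -n_strata * log(21)
        rows = []
        rng = np.random.default_rng(2)
        for s in range(5):
            for j in range(21):
                rows.append({"stratum_id": s, "animal_id": "a", "used": int(j == 0),
                             "habitat": ["bottomland", "upland_pine", "grassland"][rng.integers(3)],
                             "status": "resident", "release_habitat": "upland_pine",
                             "diel": "diurnal", "step_length_m": 100.0})
        df = pd.DataFrame(rows)
        X = design_matrix(df, "habitat")
        assert clogit_loglik(df, X, np.zeros(X.shape[1])) == pytest.approx(
            -5 * math.log(21), abs=1e-12)

    @pytest.mark.parametrize("beta", [
        np.array([0.3, -0.2, 0.001]),
        np.array([-1.0, 0.5, -0.004]),
    ])
    def test_loglik_matches_enumeration_oracle(self, beta):
        df = _toy_strata()
        X = design_matrix(df, "habitat")
        assert clogit_loglik(df, X, beta) == pytest.approx(
            brute_force_loglik(df, X, beta), abs=1e-10)

    def test_fit_matches_statsmodels(self):
        # independent implementation cross-check on simulated choice data
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(10)
        rows = []
        beta_true = np.array([0.8, -0.4])
        for s in range(300):
            x = rng.normal(size=(8, 2))
            p = np.exp(x @ beta_true)
            p /= p.sum()
            choice = rng.choice(8, p=p)
            for j in range(8):
                rows.append({"stratum_id": s, "animal_id": f"an{s % 5}",
                             "used": int(j == choice),
                             "x1": x[j, 0], "x2": x[j, 1]})
        df = pd.DataFrame(rows)
        X = df[["x1", "x2"]]
        fit = fit_conditional_logit(df, model="toy", X=X)
        sm_fit = ConditionalLogit(
            df["used"], X, groups=df["stratum_id"]).fit(disp=False)
        # agreement limited by statsmodels' own optimizer tolerance
        np.testing.assert_allclose(fit.params.to_numpy(), sm_fit.params, atol=5e-4)
        np.testing.assert_allclose(fit.loglik, sm_fit.llf, rtol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), sm_fit.bse, rtol=5e-3)

    def test_invariant_to_stratum_constant_shift(self):
        # adding a constant to a covariate within each stratum leaves the
        # conditional likelihood unchanged
        df = _toy_strata()
        X = design_matrix(df, "habitat")
        beta = np.array([0.4, -0.3, 0.002])
        ll1 = clogit_loglik(df, X, beta)
        X2 = X.copy()
        shift = df["stratum_id"].map({0: 5.0, 1: -2.0, 2: 0.7})
        X2["step_length_km"] = X2["step_length_km"] + shift
        ll2 = clogit_loglik(df, X2, beta)
        assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_singular_design_names_columns(self):
        df = _toy_strata()
        X = design_matrix(df, "habitat")
        X["dup"] = X["bottomland"]
        with pytest.raises(np.linalg.LinAlgError, match="dup|bottomland"):
            fit_conditional_logit(df, model="toy", X=X)

    def test_separation_reports_bound_with_warning(self, caplog):
        # bottomland always used, never available otherwise -> separation
        rows = []
        for s in range(20):
            rows.append({"stratum_id": s, "animal_id": "a", "used": 1,
                         "habitat": "bottomland", "status": "resident",
                         "release_habitat": "upland_pine", "diel": "diurnal",
                         "step_length_m": 100.0})
            rows.append({"stratum_id": s, "animal_id": "a", "used": 0,
                         "habitat": "upland_pine", "status": "resident",
                         "release_habitat": "upland_pine", "diel": "diurnal",
                         "step_length_m": 100.0})
        df = pd.DataFrame(rows)
        X = design_matrix(df, "habitat")[["bottomland"]]
        with caplog.at_level("WARNING"):
            fit = fit_conditional_logit(df, model="sep", X=X)
        assert abs(fit.params["bottomland"]) == pytest.approx(15.0)
        assert any("separation" in r.message for r in caplog.records)


class TestRankModels:
    def test_equivalence_flag_within_2_aic(self):
        tab = pd.DataFrame({"model": ["a", "b"], "aic": [100.0, 101.5]})
        # flag logic exercised through the public function below; here the
        # arithmetic contract: identical loglik and k -> identical AIC
        from translocmove.ssf import FitResult
        f1 = FitResult("a", pd.Series([0.1], index=["b1"]), pd.Series([1.0], index=["b1"]),
                       pd.Series([1.0], index=["b1"]), loglik=-50.0, n_strata=10, converged=True)
        f2 = FitResult("b", pd.Series([0.2], index=["b1"]), pd.Series([1.0], index=["b1"]),
                       pd.Series([1.0], index=["b1"]), loglik=-50.0, n_strata=10, converged=True)
        assert f1.aic == f2.aic


class TestWeeklySeries:
    def test_all_weeks_empty_returns_nan_series(self):
        df = _toy_strata()  # diurnal only -> no nocturnal strata
        out = weekly_selection_series(df, "resident_upland_pine", n_weeks=13)
        assert len(out) == 13
        assert out["beta_bottomland"].isna().all()
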