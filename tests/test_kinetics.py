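"""Kinetics: dose-response, Michaelis-Menten, mode classification, slow binding."""

import numpy as np
import pytest

from inhibikit import kinetics, synthdata
from inhibikit.kinetics import (
    FitError,
    classify_inhibition,
    eval_progress_curve,
    fit_ic50,
    fit_kobs_hyperbola,
    fit_michaelis_menten,
    fit_progress_curve,
    fit_vv0,
    kobs_hyperbola,
    ki_dixon,
    mechanism_report,
)

# reference generating parameters (uM / per-second / mM units as documented)
KM_MTYR = 180.0
KM_HTYR_LDOPA = 630.0
KI = 5.1
IC50 = 31.2
K5, K6, KI_APP = 0.04496, 0.00001103, 2.402

S_GRID = np.array([20, 45, 90, 180, 360, 700, 1100, 1500], float)
I_MM_GRID = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 16.0])  # mM, spans Ki_app


class TestMichaelisMenten:
    @pytest.mark.parametrize("km", [KM_MTYR, KM_HTYR_LDOPA])
    def test_noiseless_recovery(self, km):
        v = kinetics.michaelis_menten(S_GRID, km, 1.0)
        fit = fit_michaelis_menten(S_GRID, v)
        assert fit.Km == pytest.approx(km, rel=1e-4)
        assert fit.Vmax == pytest.approx(1.0, rel=1e-4)

    def test_lineweaver_burk_initialisation_reported(self):
        v = kinetics.michaelis_menten(S_GRID, KM_MTYR, 2.0)
        fit = fit_michaelis_menten(S_GRID, v)
        assert fit.Km_lineweaver_burk == pytest.approx(KM_MTYR, rel=1e-6)
        assert fit.Vmax_lineweaver_burk == pytest.approx(2.0, rel=1e-6)

    def test_half_saturation_at_km(self):
        v = kinetics.michaelis_menten(S_GRID, KM_MTYR, 1.0)
        fit = fit_michaelis_menten(S_GRID, v)
        assert kinetics.michaelis_menten(fit.Km, fit.Km, fit.Vmax) == pytest.approx(
            fit.Vmax / 2
        )

    def test_degenerate_grid_rejected(self):
        with pytest.raises(FitError):
            fit_michaelis_menten([100, 100, 100], [0.3, 0.3, 0.3])


class TestIC50:
    def test_noiseless_recovery(self):
        I, act = synthdata.gen_dose_response(IC50, [0, 5, 10, 20, 40, 80, 160])
        assert fit_ic50(I, act).IC50 == pytest.approx(IC50, rel=1e-6)

    def test_midpoint_activity_is_50(self):
        I, act = synthdata.gen_dose_response(IC50, [0, 10, 31.2, 100])
        fit = fit_ic50(I, act)
        assert kinetics.activity_logistic(fit.IC50, fit.IC50) == pytest.approx(50.0)

    def test_unit_covariance(self):
        I, act = synthdata.gen_dose_response(IC50, [0, 5, 10, 20, 40, 80, 160])
        scaled = fit_ic50(I * 1000.0, act)  # nM instead of uM
        assert scaled.IC50 == pytest.approx(IC50 * 1000.0, rel=1e-6)

    def test_uninformative_data_flagged(self):
        fit = fit_ic50([0.01, 0.02, 0.04], [99.9, 99.9, 99.8])
        assert fit.poorly_determined


class TestModeClassification:
    def test_competitive_recovery(self, competitive_grid):
        S, I, v = competitive_grid
        fit = classify_inhibition(S, I, v)
        assert fit.mode == "competitive"
        assert fit.Ki == pytest.approx(KI, rel=1e-4)

    @pytest.mark.parametrize("mode", ["uncompetitive", "noncompetitive"])
    def test_other_modes_recognised(self, mode):
        S, I, v = synthdata.gen_velocity_data(
            KM_MTYR, 1.0, KI, [45, 90, 180, 360, 720], [0, 2.5, 5, 10], mode
        )
        assert classify_inhibition(S, I, v).mode == mode

    def test_single_level_refused(self):
        S = np.array([45, 90, 180.0])
        v = kinetics.michaelis_menten(S, KM_MTYR, 1.0)
        with pytest.raises(FitError, match="2 inhibitor levels"):
            classify_inhibition(S, np.zeros(3), v)


class TestDixon:
    def test_competitive_intersection_at_minus_ki(self, competitive_grid):
        S, I, v = competitive_grid
        res = ki_dixon(S, I, v)
        assert res.Ki == pytest.approx(KI, rel=1e-6)
        assert res.intersection[0] == pytest.approx(-KI, rel=1e-6)

    def test_concordance_with_global_refit(self, competitive_grid):
        """Dixon Ki and the global competitive-model Ki agree within 1%."""
        S, I, v = competitive_grid
        ki_d = ki_dixon(S, I, v).Ki
        ki_g = classify_inhibition(S, I, v).Ki
        assert abs(ki_d - ki_g) / ki_g < 0.01

    def test_parallel_lines_warn_uncompetitive(self):
        S, I, v = synthdata.gen_velocity_data(
            KM_MTYR, 1.0, KI, [45, 90, 180], [0, 2.5, 5, 10], "uncompetitive"
        )
        with pytest.warns(UserWarning, match="parallel"):
            res = ki_dixon(S, I, v)
        assert res.parallel and res.Ki is None

    def test_order_invariance(self, competitive_grid, rng):
        S, I, v = competitive_grid
        perm = rng.permutation(len(S))
        assert ki_dixon(S[perm], I[perm], v[perm]).Ki == pytest.approx(
            ki_dixon(S, I, v).Ki, rel=1e-9
        )


class TestProgressCurve:
    T = np.linspace(0, 300, 40)

    def test_eval_trivials(self):
        assert eval_progress_curve(0.0, 0.01, 0.002, 0.02, A0=0.05) == pytest.approx(0.05)
        t = np.array([0.0, 10.0, 100.0])
        np.testing.assert_allclose(
            eval_progress_curve(t, 0.01, 0.01, 0.02, A0=0.0), 0.01 * t
        )
        np.testing.assert_allclose(eval_progress_curve(t, 0.01, 0.002, 0.0), 0.01 * t)

    def test_late_slope_is_vs(self):
        vs = 0.002
        t = np.array([2000.0, 2001.0])
        a = eval_progress_curve(t, 0.01, vs, 0.05)
        assert (a[1] - a[0]) == pytest.approx(vs, rel=1e-6)

    def test_noiseless_recovery_to_3sf(self):
        truth = dict(vi=0.01, vs=0.002, kobs=0.0225, A0=0.05)
        A = eval_progress_curve(self.T, **truth)
        fit = fit_progress_curve(self.T, A)
        for name, val in truth.items():
            assert getattr(fit, name) == pytest.approx(val, rel=1e-3), name

    def test_linear_data_flags_unidentifiable_kobs(self):
        fit = fit_progress_curve(self.T, 0.05 + 0.01 * self.T)
        assert fit.kobs_unidentifiable
        assert fit.vi == pytest.approx(fit.vs, rel=1e-2)

    def test_baseline_shift_moves_only_a0(self):
        A = eval_progress_curve(self.T, 0.01, 0.002, 0.0225, A0=0.0)
        f0, f1 = fit_progress_curve(self.T, A), fit_progress_curve(self.T, A + 0.7)
        assert f1.A0 - f0.A0 == pytest.approx(0.7, abs=1e-6)
        assert f1.kobs == pytest.approx(f0.kobs, rel=1e-6)

    def test_too_few_points_refused(self):
        with pytest.raises(FitError):
            fit_progress_curve([0, 1, 2], [0, 1, 2])


class TestVV0:
    def test_recovery(self):
        t = np.linspace(0, 540, 10)
        k = 0.0052
        assert fit_vv0(t, np.exp(-k * t)) == pytest.approx(k, rel=1e-6)

    def test_time_rescaling_covariance(self):
        t = np.linspace(0, 540, 10)
        r = np.exp(-0.0052 * t)
        assert fit_vv0(t / 2, r) == pytest.approx(2 * fit_vv0(t, r), rel=1e-6)

    def test_ratio_above_one_warns(self):
        with pytest.warns(UserWarning, match="above 1"):
            fit_vv0([0, 60, 120], [1.05, 0.8, 0.6])


class TestSlowBindingSecondary:
    def test_noiseless_triple_recovery_to_4sf(self):
        kobs = kobs_hyperbola(I_MM_GRID, K5, K6, KI_APP)
        fit = fit_kobs_hyperbola(I_MM_GRID, kobs)
        assert fit.k5 == pytest.approx(K5, rel=1e-4)
        assert fit.k6 == pytest.approx(K6, rel=1e-4)
        assert fit.Ki_app == pytest.approx(KI_APP, rel=1e-4)
        assert fit.r_squared >= 0.9999

    def test_midpoint_identity(self):
        assert kobs_hyperbola(KI_APP, K5, K6, KI_APP) == pytest.approx(K6 + K5 / 2)

    def test_zero_concentration_gives_k6(self):
        assert kobs_hyperbola(0.0, K5, K6, KI_APP) == pytest.approx(K6)

    def test_fewer_than_four_levels_refused(self):
        with pytest.raises(FitError):
            fit_kobs_hyperbola([1, 2, 3], [0.01, 0.02, 0.03])

    def test_linear_limit_at_large_ki_app(self):
        """Ki_app >> I makes the hyperbola approach k6 + (k5/Ki_app)*I."""
        big = 1e6
        kobs = kobs_hyperbola(I_MM_GRID, K5, K6, big)
        np.testing.assert_allclose(kobs, K6 + (K5 / big) * I_MM_GRID, rtol=1e-4)


class TestMechanismReport:
    def test_hyperbolic_data_yields_isomerisation(self):
        kobs = kobs_hyperbola(I_MM_GRID, K5, K6, KI_APP)
        assert mechanism_report(I_MM_GRID, kobs)["verdict"] == (
            "enzyme isomerisation (slow-binding)"
        )

    def test_linear_data_yields_simple_reversible(self):
        kobs = K6 + 1e-4 * I_MM_GRID  # the Ki_app -> infinity regime
        assert mechanism_report(I_MM_GRID, kobs)["verdict"] == "simple reversible"

    def test_constant_kobs_yields_simple_reversible(self):
        assert (
            mechanism_report(I_MM_GRID, np.full_like(I_MM_GRID, K6))["verdict"]
            == "simple reversible"
        )


class TestNoisyRecovery:
    """With 2% noise and 50 replicates, median relative bias stays under 5%."""

    N_REP = 50
    NOISE = 0.02

    def _bias(self, estimates, truth):
        return abs(np.median((np.asarray(estimates) - truth) / truth))

    def test_km_and_ic50_bias(self):
        kms, ic50s = [], []
        for rep in range(self.N_REP):
            S, _, v = synthdata.gen_velocity_data(
                KM_MTYR, 1.0, KI, S_GRID, [0.0], "competitive",
                noise_sd=self.NOISE, seed=1000 + rep,
            )
            kms.append(fit_michaelis_menten(S, v).Km)
            I, act = synthdata.gen_dose_response(
                IC50, [0, 5, 10, 20, 40, 80, 160], noise_sd=self.NOISE, seed=2000 + rep
            )
            ic50s.append(fit_ic50(I, act).IC50)
        assert self._bias(kms, KM_MTYR) < 0.05
        assert self._bias(ic50s, IC50) < 0.05

    def test_slow_binding_triple_bias(self):
        rng = np.random.default_rng(7)
        k5s, kis = [], []
        for _ in range(self.N_REP):
            kobs = kobs_hyperbola(I_MM_GRID, K5, K6, KI_APP)
            noisy = kobs + rng.normal(0, self.NOISE * kobs)
            fit = fit_kobs_hyperbola(I_MM_GRID, noisy)
            k5s.append(fit.k5)
            kis.append(fit.Ki_app)
        assert self._bias(k5s, K5) < 0.05
        assert self._bias(kis, KI_APP) < 0.05
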