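"""Patlak-Rutland transform, plasma fit, deconvolution, FUR/DRF, attenuation."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

import renofur as rf
from renofur.furcore import (
    AnalysisOptions,
    LUSegment,
    LUSegmentError,
    PlasmaModel,
    build_patlak,
    compute_drf,
    compute_fur,
    deconvolve_irf,
    depth_for_split,
    detect_lu_segment,
    fit_lu_slope,
    fit_plasma_monoexp,
    split_fur,
)
from renofur.tac import InjectedDose, InvalidStudyError, TimeActivityCurve, background_correct


def make_tac(values, frame_duration=5.0, name="roi"):
    values = np.asarray(values, dtype=float)
    times = (np.arange(values.size) + 0.5) * frame_duration
    return TimeActivityCurve(times, values, frame_duration, name)


def ref_integral(tac):
    """Independent cumulative plasma integral (same stated convention)."""
    return (
        cumulative_trapezoid(tac.values, tac.times, initial=0.0)
        + tac.times[0] * tac.values[0]
    )


@pytest.fixture(scope="module")
def clean_plasma(default_config):
    return rf.simulate_plasma(default_config)


class TestPatlak:
    def test_pure_integrator_identity(self, clean_plasma):
        c = 3.7e-3
        kidney = clean_plasma.with_values(c * ref_integral(clean_plasma))
        plot = build_patlak(kidney, clean_plasma)
        coef = np.polyfit(plot.x[plot.valid_mask], plot.y[plot.valid_mask], 1)
        assert coef[0] == pytest.approx(c, abs=1e-10)
        assert abs(coef[1]) < 1e-10

    def test_integrator_plus_blood_volume(self, clean_plasma):
        c, v = 2e-3, 0.15
        kidney = clean_plasma.with_values(
            c * ref_integral(clean_plasma) + v * clean_plasma.values
        )
        plot = build_patlak(kidney, clean_plasma)
        coef = np.polyfit(plot.x[plot.valid_mask], plot.y[plot.valid_mask], 1)
        assert coef[0] == pytest.approx(c, rel=1e-9)
        assert coef[1] == pytest.approx(v, rel=1e-9)

    def test_constant_plasma_closed_form(self):
        p, c = 400.0, 1.5e-3
        plasma = make_tac(np.full(40, p))
        kidney = plasma.with_values(c * p * plasma.times)
        plot = build_patlak(kidney, plasma)
        assert np.allclose(plot.x, plasma.times, rtol=1e-12)
        coef = np.polyfit(plot.x, plot.y, 1)
        assert coef[0] == pytest.approx(c, rel=1e-10)

    def test_too_few_valid_frames(self):
        values = np.full(30, 1e-9)
        values[:3] = 1000.0
        plasma = make_tac(values)
        with pytest.raises(InvalidStudyError, match="5 frames"):
            build_patlak(plasma.with_values(np.ones(30)), plasma)


class TestPlasmaFit:
    def test_exact_recovery(self):
        t = (np.arange(120) + 0.5) * 5.0
        tac = make_tac(5000.0 * np.exp(-0.005 * t))
        model = fit_plasma_monoexp(tac, (10.0, 300.0))
        assert model.p0 == pytest.approx(5000.0, rel=1e-6)
        assert model.decay_rate == pytest.approx(0.005, rel=1e-6)

    def test_constant_curve(self):
        model = fit_plasma_monoexp(make_tac(np.full(30, 750.0)), (0.0, 150.0))
        assert model.p0 == pytest.approx(750.0, rel=1e-8)
        assert abs(model.decay_rate) < 1e-10

    def test_window_too_small(self):
        with pytest.raises(InvalidStudyError):
            fit_plasma_monoexp(make_tac(np.ones(30)), (0.0, 12.0))

    def test_monte_carlo_backextrapolation(self):
        """Median |P(0) error| < 3% under 5% multiplicative Gaussian noise."""
        t = (np.arange(120) + 0.5) * 5.0
        clean = 5000.0 * np.exp(-0.005 * t)
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            noisy = np.clip(clean * (1 + 0.05 * rng.standard_normal(t.size)), 1e-6, None)
            model = fit_plasma_monoexp(make_tac(noisy), (10.0, 160.0))
            errs.append(abs(model.p0 - 5000.0) / 5000.0)
        assert np.median(errs) < 0.03


class TestDeconvolution:
    def test_delta_input_identity(self):
        """Single-frame plasma bolus: the IRF reproduces the renogram shape."""
        dt, p, c = 5.0, 800.0, 0.4
        plasma_values = np.zeros(30)
        plasma_values[0] = p
        r = c * 0.9 ** np.arange(30)
        irf = deconvolve_irf(make_tac(r, dt), make_tac(plasma_values, dt), smoothing=0.0)
        expected_tail = r[1:] / (dt * p)
        assert np.allclose(irf.irf[1:], expected_tail, rtol=1e-6, atol=1e-9)
        # only half of the first frame's input acts by its own midpoint
        assert irf.irf[0] == pytest.approx(2 * r[0] / (dt * p), rel=1e-6)

    def test_zero_renogram_flagged(self, clean_plasma):
        irf = deconvolve_irf(clean_plasma.with_values(np.zeros(120)), clean_plasma)
        assert np.all(irf.irf == 0)
        assert "zero_renogram" in irf.flags

    def test_monotone_and_nonnegative(self, noise_free_study):
        corrected, _ = background_correct(
            noise_free_study.curves["kidney_L"], noise_free_study.curves["bkg_L"]
        )
        irf = deconvolve_irf(corrected, noise_free_study.curves["heart"])
        assert np.all(irf.irf >= 0)
        assert np.all(np.diff(irf.irf) <= 1e-12)

    def test_plateau_recovers_transit_time_and_uptake(self):
        """Plateau ends near T_min and its height estimates F_k, noise-free."""
        cfg = dataclasses.replace(
            rf.SimulationConfig(), min_transit_times=(150.0, 150.0)
        )
        study = rf.simulate_study(cfg)
        plasma = study.curves["heart"]
        for side in ("L", "R"):
            corrected, _ = background_correct(
                study.curves[f"kidney_{side}"], study.curves[f"bkg_{side}"]
            )
            irf = deconvolve_irf(corrected, plasma)
            t_min_frame = 150.0 / cfg.frame_duration
            assert abs(irf.plateau_interval[1] - t_min_frame) <= 2
            f_k = cfg.uptake_constants[0 if side == "L" else 1]
            assert irf.plateau_height == pytest.approx(f_k, rel=0.05)


class TestLUSegment:
    def test_pure_integrator_extends_to_last_valid_frame(self):
        cfg = dataclasses.replace(rf.SimulationConfig(), min_transit_times=(1e9, 1e9))
        study = rf.simulate_study(cfg)
        corrected, _ = background_correct(
            study.curves["kidney_L"], study.curves["bkg_L"]
        )
        plasma = study.curves["heart"]
        plot = build_patlak(corrected, plasma)
        irf = deconvolve_irf(corrected, plasma)
        seg = detect_lu_segment(plot, irf)
        last_valid = int(np.flatnonzero(plot.valid_mask)[-1])
        assert seg.interval[1] == last_valid + 1

    def test_detected_interval_within_uptake_phase(self, noise_free_study):
        """Detected LU lies inside [bolus arrival, T_min] within 2 frames."""
        plasma = noise_free_study.curves["heart"]
        for side, t_min in zip("LR", noise_free_study.config.min_transit_times):
            corrected, _ = background_correct(
                noise_free_study.curves[f"kidney_{side}"],
                noise_free_study.curves[f"bkg_{side}"],
            )
            plot = build_patlak(corrected, plasma)
            seg = detect_lu_segment(plot, deconvolve_irf(corrected, plasma))
            t_min_frame = t_min / noise_free_study.config.frame_duration
            assert seg.interval[0] >= 2
            assert seg.interval[1] <= t_min_frame + 2

    def test_short_plateau_demands_manual_interval(self, clean_plasma):
        from renofur.furcore import IRFEstimate

        irf = IRFEstimate(
            irf=np.zeros(120), plateau_height=1.0, plateau_interval=(2, 4)
        )
        plot = build_patlak(clean_plasma.with_values(np.ones(120)), clean_plasma)
        with pytest.raises(LUSegmentError, match="manual"):
            detect_lu_segment(plot, irf)

    def test_agrees_with_brute_force_window_search(self, noise_free_study):
        """Exhaustive R^2-maximising window search finds the same slope."""
        corrected, _ = background_correct(
            noise_free_study.curves["kidney_R"], noise_free_study.curves["bkg_R"]
        )
        plasma = noise_free_study.curves["heart"]
        plot = build_patlak(corrected, plasma)
        irf = deconvolve_irf(corrected, plasma)
        seg = fit_lu_slope(plot, detect_lu_segment(plot, irf))

        i_peak = int(np.argmax(corrected.values))
        best = (None, -np.inf)
        yscale = np.nanmax(np.abs(plot.y[: i_peak + 1]))
        for i in range(2, i_peak - 6):
            for j in range(i + 6, i_peak + 1):
                xs, ys = plot.x[i:j], plot.y[i:j]
                coef = np.polyfit(xs, ys, 1)
                resid = ys - np.polyval(coef, xs)
                r2 = 1 - resid.var() / ys.var()
                if abs(coef[1]) <= 0.05 * yscale and r2 > best[1]:
                    best = (coef[0], r2)
        assert best[0] == pytest.approx(seg.slope, rel=0.05)


class TestLUSlopeFit:
    def test_collinear_through_origin(self, clean_plasma):
        c = 2.5e-3
        kidney = clean_plasma.with_values(c * ref_integral(clean_plasma))
        plot = build_patlak(kidney, clean_plasma)
        seg = fit_lu_slope(plot, LUSegment(interval=(2, 30), intercept_prior=0.0))
        assert seg.slope == pytest.approx(c, rel=1e-9)
        assert abs(seg.intercept) < 1e-12

    def test_prior_shrinks_intercept(self):
        plasma = make_tac(np.full(20, 1.0))
        kidney = plasma.with_values(2.0 + 0.5 * plasma.times)  # intercept 2
        plot = build_patlak(kidney, plasma)
        seg = fit_lu_slope(plot, LUSegment(interval=(0, 20), intercept_prior=0.0))
        assert 0.0 < seg.intercept < 2.0

    def test_matches_direct_normal_equations(self):
        """Augmented WLS equals the explicit normal-equations solution."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 31))
            x = np.sort(rng.uniform(0, 300, n))
            y = rng.normal(0.002, 0.001) * x + rng.normal(0, 0.05, n)
            prior = float(rng.uniform(0, 0.2))
            w = float(rng.uniform(0.25, 4.0))
            plasma = make_tac(np.full(n, 1.0), frame_duration=1.0)
            plot = dataclasses.replace(
                build_patlak(plasma.with_values(np.zeros(n)), plasma),
                x=x,
                y=y,
            )
            seg = fit_lu_slope(
                plot, LUSegment(interval=(0, n), intercept_prior=prior), w
            )
            xa = np.append(x, 0.0)
            ya = np.append(y, prior)
            wa = np.append(np.ones(n), w)
            design = np.column_stack([xa, np.ones(n + 1)])
            lhs = design.T @ (wa[:, None] * design)
            rhs = design.T @ (wa * ya)
            slope, intercept = np.linalg.solve(lhs, rhs)
            assert seg.slope == pytest.approx(slope, abs=1e-9)
            assert seg.intercept == pytest.approx(intercept, abs=1e-9)

    def test_constant_abscissa_rejected(self):
        plasma = make_tac(np.full(10, 1.0))
        plot = dataclasses.replace(
            build_patlak(plasma.with_values(np.zeros(10)), plasma),
            x=np.zeros(10),
        )
        with pytest.raises(ValueError, match="singular"):
            fit_lu_slope(plot, LUSegment(interval=(0, 10)))


class TestFURandDRF:
    def test_zero_slopes_give_zero_fur(self):
        fur, flags = compute_fur(
            0.0, 0.0, PlasmaModel(1e4, 0.005, (0, 100)), InjectedDose(6e4)
        )
        assert fur == 0.0 and flags == ()

    def test_closed_form(self):
        # 1e4 * (5e-4 + 5e-4) / 6e4 per second, times 6000 to reach %ID/min
        fur, _ = compute_fur(
            5e-4, 5e-4, PlasmaModel(1e4, 0.005, (0, 100)), InjectedDose(6e4)
        )
        assert fur == pytest.approx(1.0, rel=1e-12)

    def test_negative_slope_flagged(self):
        _, flags = compute_fur(
            -1e-4, 5e-4, PlasmaModel(1e4, 0.005, (0, 100)), InjectedDose(6e4)
        )
        assert "negative_slope_L" in flags

    def test_table_split_values_reconstruct_total(self):
        """Published-style baseline splits 14.7 + 18.5 sum to the total 33.2."""
        left, right = split_fur(33.2, (44.3, 55.7))
        assert round(left, 1) == 14.7
        assert round(left + right, 1) == 33.2

    def test_split_fur_edge_cases(self):
        assert split_fur(20.0, (50.0, 50.0)) == (10.0, 10.0)
        assert split_fur(20.0, (100.0, 0.0)) == (20.0, 0.0)
        with pytest.raises(ValueError):
            split_fur(20.0, (60.0, 50.0))

    def test_identical_kidneys_split_5050_by_all_methods(self):
        cfg = dataclasses.replace(
            rf.SimulationConfig(),
            uptake_constants=(0.015, 0.015),
            min_transit_times=(150.0, 150.0),
        )
        result = rf.analyze_study(rf.simulate_study(cfg).curves)
        for pair in result.drf.as_dict().values():
            assert pair[0] == pytest.approx(50.0, abs=0.2)

    def test_one_to_two_uptake_ratio(self):
        cfg = dataclasses.replace(
            rf.SimulationConfig(),
            uptake_constants=(0.011, 0.022),
            min_transit_times=(150.0, 150.0),
        )
        result = rf.analyze_study(rf.simulate_study(cfg).curves)
        for pair in result.drf.as_dict().values():
            assert 33.0 <= pair[0] <= 33.7
            assert 66.3 <= pair[1] <= 67.0

    def test_zero_uptake_drf_undefined(self, noise_free_study):
        corrected = noise_free_study.curves["heart"].with_values(np.zeros(120))
        plasma = noise_free_study.curves["heart"]
        plot = build_patlak(corrected, plasma)
        irf = deconvolve_irf(corrected, plasma)
        with pytest.raises(InvalidStudyError, match="DRF"):
            compute_drf(corrected, corrected, plot, plot, irf, irf, (2, 30))


class TestAttenuation:
    def test_one_cm_depth_skews_even_split_to_53_47(self):
        observed = rf.attenuation_drf((50.0, 50.0), depth_diff=1.0, mu=0.12)
        assert round(observed[0]) == 53 and round(observed[1]) == 47

    def test_zero_depth_is_identity(self):
        assert rf.attenuation_drf((50.0, 50.0), 0.0) == (50.0, 50.0)

    def test_observed_baseline_asymmetry_needs_nearly_2cm(self):
        depth = depth_for_split((55.7, 44.3), mu=0.12)
        assert depth == pytest.approx(1.91, abs=0.01)
        assert depth <= 2.0

    @pytest.mark.parametrize("d", [0.3, 1.0, 2.5])
    def test_forward_inverse_round_trip(self, d):
        observed = rf.attenuation_drf((50.0, 50.0), d, mu=0.12, deeper="R")
        assert depth_for_split(observed, mu=0.12) == pytest.approx(d, rel=1e-9)

    def test_degenerate_shares_rejected(self):
        with pytest.raises(ValueError):
            rf.attenuation_drf((100.0, 0.0), 1.0)
        with pytest.raises(ValueError):
            depth_for_split((0.0, 100.0))


class TestPipeline:
    def test_missing_cardiac_curve(self, noise_free_study):
        curves = {k: v for k, v in noise_free_study.curves.items() if k != "heart"}
        with pytest.raises(InvalidStudyError, match="cardiac"):
            rf.analyze_study(curves)

    def test_manual_lu_override_recorded(self, noise_free_study):
        options = AnalysisOptions(manual_lu={"L": (3, 25)})
        result = rf.analyze_study(noise_free_study.curves, options)
        assert result.lu_segments["L"].source == "manual"
        assert result.lu_segments["L"].interval == (3, 25)
        assert "manual_lu_L" in result.qc_flags

    def test_scale_invariance(self, noise_free_study, noise_free_result):
        """FUR (%ID/min) and DRF are invariant under a global count rescale."""
        scaled = {
            name: curve.with_values(7.3 * curve.values)
            for name, curve in noise_free_study.curves.items()
        }
        result = rf.analyze_study(scaled)
        assert result.fur_total == pytest.approx(noise_free_result.fur_total, rel=1e-9)
        assert result.drf_consensus[0] == pytest.approx(
            noise_free_result.drf_consensus[0], abs=1e-9
        )

    def test_pr_slope_matches_irf_plateau(self, noise_free_study, noise_free_result):
        """Noise-free consistency of the two uptake-rate estimates (<5%)."""
        plasma = noise_free_study.curves["heart"]
        for side, k in (("L", noise_free_result.k_l), ("R", noise_free_result.k_r)):
            corrected, _ = background_correct(
                noise_free_study.curves[f"kidney_{side}"],
                noise_free_study.curves[f"bkg_{side}"],
            )
            irf = deconvolve_irf(corrected, plasma)
            assert irf.plateau_height == pytest.approx(k, rel=0.05)

    def test_end_to_end_recovery(self, noise_free_result, truth):
        assert noise_free_result.fur_total == pytest.approx(
            truth.fur_total_true, rel=0.03
        )
        assert noise_free_result.drf_consensus[0] == pytest.approx(
            truth.drf_true[0], abs=1.0
        )
        assert noise_free_result.qc_flags == ()
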