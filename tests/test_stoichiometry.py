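"""Bleach correction, Chung-Kennedy filtering, brightness calibration and
stoichiometry estimation."""

import numpy as np
import pytest

from condtrack import (BrightnessCalibration, CalibrationError, EmitterModel,
                       MovieCalibration, NoiseModel, StoichConfig, Track,
                       bleach_correct, calibrate_brightness, chung_kennedy,
                       detect_bleach_steps, detect_foci, initial_intensity,
                       simulate_bleach_trace, simulate_movie, stoichiometry)
from condtrack.detect import Focus
from condtrack.stoichiometry import extend_bleach_trace, kde_mode


def chung_kennedy_oracle(trace, window, exponent):
    """Direct loop-coded reference implementation of the filter."""
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    out = np.empty(n)
    for i in range(n):
        fwd = trace[max(0, i - window + 1):i + 1]
        bwd = trace[i:min(n, i + window)]
        mf, vf = fwd.mean(), fwd.var()
        mb, vb = bwd.mean(), bwd.var()
        tol = 1e-12 * max(1.0, float(np.max(np.abs(trace))) ** 2)
        if vf <= tol and vb <= tol:
            out[i] = 0.5 * (mf + mb)
        elif vf <= tol:
            out[i] = mf
        elif vb <= tol:
            out[i] = mb
        else:
            wf, wb = vf ** -exponent, vb ** -exponent
            out[i] = (wf * mf + wb * mb) / (wf + wb)
    return out


class TestBleachCorrect:
    def test_global_exponential_decay_is_flattened(self):
        rng = np.random.default_rng(0)
        t = np.arange(60)
        base = rng.uniform(90, 110, size=(32, 32))
        movie = base[None] * np.exp(-0.01 * t)[:, None, None]
        corrected, params = bleach_correct(movie)
        assert params["corrected"]
        means = corrected.mean(axis=(1, 2))
        assert np.ptp(means) / means.mean() < 0.01

    def test_constant_movie_returned_unchanged_with_warning(self):
        movie = np.full((20, 16, 16), 50.0)
        with pytest.warns(UserWarning):
            corrected, params = bleach_correct(movie)
        assert not params["corrected"]
        assert np.array_equal(corrected, movie)

    def test_decay_rate_recovered_within_five_percent(self):
        t = np.arange(100)
        movie = 80.0 * np.exp(-0.03 * t)[:, None, None] * np.ones((1, 8, 8)) + 20.0
        _, params = bleach_correct(movie)
        assert params["rate"] == pytest.approx(0.03, rel=0.05)


class TestChungKennedy:
    def test_noiseless_step_trace_is_unchanged(self):
        trace = np.array([440.0, 440.0, 330.0, 330.0])
        assert np.allclose(chung_kennedy(trace, window=2), trace)

    def test_noise_on_a_constant_trace_is_reduced(self):
        rng = np.random.default_rng(1)
        trace = 100.0 + rng.normal(0, 5, 200)
        filtered = chung_kennedy(trace, window=8)
        assert filtered.var() < trace.var()

    def test_matches_independent_oracle_on_noisy_two_step_trace(self):
        rng = np.random.default_rng(2)
        trace = np.concatenate([np.full(40, 220.0), np.full(40, 110.0),
                                np.full(40, 0.0)]) + rng.normal(0, 8, 120)
        for window, exponent in [(5, 2.0), (10, 1.0), (3, 4.0)]:
            mine = chung_kennedy(trace, window, exponent)
            ref = chung_kennedy_oracle(trace, window, exponent)
            assert np.allclose(mine, ref, atol=1e-9)

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            chung_kennedy(np.arange(10.0), window=1)


class TestCalibrateBrightness:
    def test_identical_clean_steps_give_exact_modal_brightness(self):
        stair = np.concatenate([np.full(20, 330.0), np.full(20, 220.0),
                                np.full(20, 110.0), np.full(20, 0.0)])
        calib = calibrate_brightness([stair] * 4, late_stage_fraction=1.0)
        assert calib.b_modal == pytest.approx(110.0, abs=1e-9)
        assert calib.n_steps_used == 12

    def test_normal_steps_recover_modal_brightness_within_five(self):
        # traces whose step sizes scatter as the 110 +/- 15 calibration
        em = EmitterModel(bleach_rate=0.05)
        traces = [simulate_bleach_trace(1 + (i % 4), em, noise_sd=10.0,
                                        seed=3000 + i)[0] for i in range(200)]
        calib = calibrate_brightness(traces)
        assert calib.b_modal == pytest.approx(110.0, abs=5.0)

    def test_no_steps_is_a_calibration_failure(self):
        with pytest.raises(CalibrationError):
            calibrate_brightness([])
        flat = [np.full(50, 200.0) + 0.0]
        with pytest.raises(CalibrationError):
            calibrate_brightness(flat)

    def test_adding_stepless_tracks_leaves_calibration_unchanged(self):
        em = EmitterModel(bleach_rate=0.05)
        traces = [simulate_bleach_trace(2, em, noise_sd=5.0, seed=i)[0]
                  for i in range(60)]
        base = calibrate_brightness(traces)
        with_flat = calibrate_brightness(traces + [np.full(80, 500.0)] * 5)
        assert with_flat.b_modal == pytest.approx(base.b_modal, abs=1e-9)
        assert with_flat.n_steps_used == base.n_steps_used


class TestKdeMode:
    def test_mode_of_gaussian_sample_is_near_centre(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(110, 15, 200)
        assert kde_mode(vals) == pytest.approx(110, abs=8)

    def test_degenerate_sample_returns_common_value(self):
        assert kde_mode(np.full(7, 42.0)) == 42.0


class TestStoichiometry:
    def test_linear_bleach_ramp_extrapolates_to_first_frame(self):
        calib = BrightnessCalibration(b_modal=110.0, b_sd=15.0, n_steps_used=50)
        result = stoichiometry(np.array([440.0, 436.0, 432.0, 428.0, 424.0]),
                               calib)
        assert result.initial_intensity == pytest.approx(440.0)
        assert result.stoichiometry == pytest.approx(4.0)

    def test_two_frame_track_uses_the_line_through_both(self):
        calib = BrightnessCalibration(b_modal=110.0, b_sd=15.0, n_steps_used=50)
        result = stoichiometry(np.array([220.0, 220.0]), calib)
        assert result.stoichiometry == pytest.approx(2.0)

    def test_only_first_five_frames_enter_the_fit(self):
        vals = np.array([550.0, 545.0, 540.0, 535.0, 530.0, 100.0, 100.0])
        assert initial_intensity(vals, StoichConfig()) == pytest.approx(550.0)

    def test_scale_consistency_of_stoichiometry(self):
        vals = np.array([440.0, 430.0, 420.0])
        for k in (0.5, 3.0, 17.0):
            c1 = BrightnessCalibration(110.0, 15.0, 50)
            ck = BrightnessCalibration(110.0 * k, 15.0, 50)
            s1 = stoichiometry(vals, c1).stoichiometry
            sk = stoichiometry(vals * k, ck).stoichiometry
            assert sk == pytest.approx(s1)

    def test_nonpositive_initial_intensity_is_rejected_with_reason(self):
        calib = BrightnessCalibration(110.0, 15.0, 50)
        result = stoichiometry(np.array([-10.0, -12.0]), calib)
        assert not result.accepted
        assert result.reason == "nonpositive_initial_intensity"


def _grid_starts(n, width=12.7, height=9.7, margin=1.0):
    cols = int(np.ceil(np.sqrt(n * width / height)))
    rows = int(np.ceil(n / cols))
    xs = np.linspace(margin, width - margin, cols)
    ys = np.linspace(margin, height - margin, rows)
    return [(x, y) for y in ys for x in xs][:n]


def _calibration_traces(seed):
    """Sparse immobile 2-3-mer acquisition, detected on an early-frame
    average, with aperture traces extended to the movie end."""
    cal = MovieCalibration(frame_count=220, roi=(240, 184))
    starts = _grid_starts(60)
    specs = [{"stoichiometry": 2 + (i % 2), "d": 0.0, "start": starts[i]}
             for i in range(60)]
    movie, _ = simulate_movie(cal, specs, EmitterModel(bleach_rate=0.02),
                              NoiseModel(), seed=seed)
    foci0 = detect_foci(movie[:5].mean(axis=0), frame_index=0)
    return [extend_bleach_trace(movie, Track(id=0, foci=[f])) for f in foci0]


class TestEndToEndRecovery:
    def test_stoichiometry_recovered_across_the_oligomer_range(self):
        """Internal calibration closes the loop: with b calibrated through
        the same aperture photometry, median stoichiometry error stays
        within 1 molecule up to 16-mers and within 10% beyond."""
        base = 200
        traces = []
        for k in range(3):
            traces += _calibration_traces(base + k)
        calib = calibrate_brightness(traces)
        s_values = [4, 8, 12, 16, 32, 48]
        n_rep = 5
        starts = _grid_starts(len(s_values) * n_rep)
        estimates: dict[int, list[float]] = {}
        for k in range(2):
            cal = MovieCalibration(frame_count=30, roi=(240, 184))
            flat = [s for s in s_values for _ in range(n_rep)]
            specs = [{"stoichiometry": s, "d": 0.02, "start": starts[m]}
                     for m, s in enumerate(flat)]
            movie, truths = simulate_movie(cal, specs,
                                           EmitterModel(bleach_rate=0.01),
                                           NoiseModel(), seed=base + 10 + k)
            foci = {i: detect_foci(fr, frame_index=i)
                    for i, fr in enumerate(movie)}
            from condtrack import link_tracks
            for t in link_tracks(foci):
                if t.foci[0].frame > 2 or len(t) < 5:
                    continue
                p0 = np.array(t.foci[0].position)
                j = int(np.argmin([np.linalg.norm(
                    x.trajectory[t.foci[0].frame] - p0) for x in truths]))
                estimates.setdefault(truths[j].true_stoichiometry, []).append(
                    stoichiometry(t, calib).stoichiometry)
        for s in s_values:
            med_err = np.median(np.abs(np.array(estimates[s]) - s))
            if s <= 16:
                assert med_err <= 1.0, f"S={s}: median error {med_err:.2f}"
            else:
                assert med_err <= 0.1 * s, f"S={s}: median error {med_err:.2f}"
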