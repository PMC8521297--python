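"""Rhythm quantification: fitting, classification, circular statistics,
phase maps, treatment responses."""

import numpy as np
import pytest

from scnkit import (
    BioluminescenceTrace,
    RhythmConfig,
    RhythmFit,
    assemble_prc,
    build_phase_map,
    classify_initiated,
    detect_peaks,
    detrend_and_smooth,
    fit_rhythm,
    generate_biolum_trace,
    generate_roi_grid,
    generate_treatment_trace,
    map_ct,
    phase_shift,
    rayleigh,
    waveform_changes,
)


def _fit_stub(period, rae):
    return RhythmFit(
        period_h=period, phase_h=0.0, amplitude=1.0, damping=0.0, baseline=0.0,
        rae=rae, gof=0.9, n_obs=100,
    )


class TestDetrend:
    def test_linear_trend_removed(self):
        t = np.arange(0, 120.5, 0.5)
        tr = BioluminescenceTrace(t, 3.0 + 0.05 * t)
        out = detrend_and_smooth(tr)
        interior = (t > 15) & (t < 105)
        assert np.allclose(out.signal[interior], 0.0, atol=1e-9)

    def test_cosine_attenuation_matches_filter_response(self):
        """Moving-average chain attenuates a cosine by its Dirichlet gain."""
        period, dt = 24.0, 0.5
        t = np.arange(0, 240 + dt, dt)
        tr = BioluminescenceTrace(t, np.cos(2 * np.pi * t / period))
        out = detrend_and_smooth(tr, baseline_window_h=24.0, smooth_window_h=2.5)

        def gain(n):
            x = np.pi * dt / period
            return np.sin(n * x) / (n * np.sin(x))

        expected = (1 - gain(49)) * gain(5)  # windows are rounded up to odd counts
        interior = (t > 30) & (t < 210)
        X = np.column_stack([np.cos(2 * np.pi * t / period), np.sin(2 * np.pi * t / period)])
        coef, *_ = np.linalg.lstsq(X[interior], out.signal[interior], rcond=None)
        measured = np.hypot(*coef)
        assert measured == pytest.approx(expected, rel=1e-3)

    def test_smoothing_low_pass_property(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 120.5, 0.5)
        tr = BioluminescenceTrace(t, rng.normal(size=t.size))
        once = detrend_and_smooth(tr)
        twice = detrend_and_smooth(once)
        d1 = np.sqrt(np.mean((once.signal - tr.signal) ** 2))
        d2 = np.sqrt(np.mean((twice.signal - once.signal) ** 2))
        assert d2 < d1

    def test_window_must_exceed_sampling(self):
        t = np.arange(0, 120.5, 0.5)
        tr = BioluminescenceTrace(t, np.cos(t))
        with pytest.raises(ValueError, match="sampling interval"):
            detrend_and_smooth(tr, smooth_window_h=0.4)


class TestFit:
    def test_noiseless_recovery(self, clean_rhythm_cfg):
        fit = fit_rhythm(generate_biolum_trace(clean_rhythm_cfg))
        assert abs(fit.period_h - 24.0) < 0.01
        assert fit.rae < 0.01
        assert fit.gof > 0.999
        assert fit.initiated

    def test_damped_recovery(self, clean_rhythm_cfg):
        cfg = clean_rhythm_cfg.replace(damping_per_h=0.01, phase_h=7.0)
        fit = fit_rhythm(generate_biolum_trace(cfg))
        assert fit.period_h == pytest.approx(24.0, abs=0.01)
        assert fit.damping == pytest.approx(0.01, abs=0.001)
        assert fit.phase_h == pytest.approx(7.0, abs=0.05)

    def test_parameter_recovery_at_snr_10(self, clean_rhythm_cfg):
        errs, amps = [], []
        for seed in range(100):
            cfg = clean_rhythm_cfg.replace(noise_sd=0.1, seed=seed)
            fit = fit_rhythm(generate_biolum_trace(cfg))
            errs.append(abs(fit.period_h - 24.0))
            amps.append(fit.amplitude)
        assert np.median(errs) < 0.1
        assert abs(np.median(amps) - 1.0) < 0.1

    def test_white_noise_rarely_initiated(self):
        t = np.arange(0, 120.5, 0.5)
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            fit = fit_rhythm(BioluminescenceTrace(t, rng.normal(size=t.size)))
            hits += fit.initiated
        assert hits / 60 <= 0.05

    def test_rae_monotone_in_noise(self, clean_rhythm_cfg):
        mean_raes = []
        for ns in (0.0, 0.1, 0.3, 1.0):
            raes = [
                fit_rhythm(
                    generate_biolum_trace(clean_rhythm_cfg.replace(noise_sd=ns, seed=s))
                ).rae
                for s in range(40)
            ]
            mean_raes.append(np.mean(raes))
        assert np.all(np.diff(mean_raes) > 0)

    def test_no_spectral_peak_returns_failed_fit(self):
        # all power at 12 h, outside an 18-40 h window restricted to >= 18 h,
        # trace too short to resolve any in-window frequency
        t = np.arange(0, 50.25, 0.25)
        tr = BioluminescenceTrace(t, np.cos(2 * np.pi * t / 12))
        fit = fit_rhythm(tr, period_window_h=(60.0, 80.0))
        assert not fit.success
        assert np.isinf(fit.rae)
        assert not fit.initiated


class TestClassification:
    @pytest.mark.parametrize(
        "period,rae,expected",
        [
            (24.0, 0.1, True),
            (22.0, 0.1, False),
            (24.0, 0.3, False),   # RAE bound is strict
            (23.5, 0.29, True),   # period bounds inclusive
            (34.5, 0.29, True),
            (34.6, 0.1, False),
        ],
    )
    def test_boundary_semantics(self, period, rae, expected):
        assert classify_initiated(_fit_stub(period, rae)) is expected


class TestRayleigh:
    def test_identical_phases_full_coherence(self):
        R, p = rayleigh([3.0, 3.0, 3.0], 24.0)
        assert R == pytest.approx(1.0)
        assert p < 0.05

    def test_antipodal_phases_cancel(self):
        R, _ = rayleigh([0.0, 12.0], 24.0)
        assert R == pytest.approx(0.0, abs=1e-12)

    def test_hand_vector_sum(self):
        # angles {0, 0, pi/2} -> R = sqrt(5)/3
        R, _ = rayleigh([0.0, 0.0, 6.0], 24.0)
        assert R == pytest.approx(np.sqrt(5) / 3)

    def test_invariant_to_constant_phase_offset(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(0, 24, 20)
        R1, p1 = rayleigh(phases, 24.0)
        R2, p2 = rayleigh(phases + 5.5, 24.0)
        assert R1 == pytest.approx(R2)
        assert p1 == pytest.approx(p2)
        assert 0.0 <= R1 <= 1.0

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        phases = rng.uniform(0, 24, 30)
        R, p = rayleigh(phases, 24.0)
        z, p_ref = pingouin.circ_rayleigh(2 * np.pi * phases / 24.0)
        assert p == pytest.approx(p_ref, rel=1e-6)
        assert z == pytest.approx(30 * R**2, rel=1e-9)

    def test_needs_two_phases(self):
        with pytest.raises(ValueError):
            rayleigh([1.0], 24.0)


class TestPeaks:
    def test_noiseless_cosine_peak_times(self, clean_rhythm_cfg):
        cfg = clean_rhythm_cfg.replace(duration_h=96.0)
        peaks = detect_peaks(generate_biolum_trace(cfg))
        for expected in (0.0, 24.0, 48.0, 72.0):
            assert np.min(np.abs(peaks - expected)) <= 0.5
        interior = peaks[(peaks > 1) & (peaks < 95)]
        assert np.allclose(np.diff(interior), 24.0, atol=0.1)

    def test_noisy_damped_intervals_near_period(self):
        cfg = RhythmConfig(
            period_h=24.0, amplitude=1.0, damping_per_h=0.005, noise_sd=0.2,
            duration_h=144.0, sampling_interval_h=0.5, seed=5,
        )
        tr = detrend_and_smooth(generate_biolum_trace(cfg))
        peaks = detect_peaks(tr)
        intervals = np.diff(peaks[(peaks > 12) & (peaks < 132)])
        assert np.all(np.abs(intervals - 24.0) < 0.5)

    def test_flat_trace_no_peaks(self):
        t = np.arange(0, 100.5, 0.5)
        assert detect_peaks(BioluminescenceTrace(t, np.zeros(t.size))).size == 0


class TestPhaseShift:
    BASE = RhythmConfig(
        period_h=24.0, phase_h=6.0, amplitude=1.0, noise_sd=0.0,
        duration_h=288.0, sampling_interval_h=0.5, seed=0,
    )

    def test_unperturbed_continuation_zero_shift(self):
        tr = generate_treatment_trace(self.BASE, 144.0, phase_shift_h=0.0)
        assert abs(phase_shift(tr)) < 0.1

    @pytest.mark.parametrize("true_shift", [2.0, -1.0])
    def test_imposed_shift_recovered(self, true_shift):
        errs = [
            abs(
                phase_shift(
                    generate_treatment_trace(
                        self.BASE.replace(noise_sd=0.02, seed=s), 144.0,
                        phase_shift_h=true_shift,
                    )
                )
                - true_shift
            )
            for s in range(10)
        ]
        assert np.mean(errs) < 0.2

    def test_amplitude_change_alone_gives_no_shift(self):
        tr = generate_treatment_trace(self.BASE, 144.0, amplitude_factor=0.5)
        assert abs(phase_shift(tr)) < 0.1

    def test_insufficient_peaks_rejected(self):
        cfg = self.BASE.replace(duration_h=96.0)
        tr = generate_treatment_trace(cfg, 48.0, phase_shift_h=1.0)
        with pytest.raises(ValueError, match="peaks"):
            phase_shift(tr)


class TestWaveformChanges:
    BASE = RhythmConfig(
        period_h=24.0, phase_h=6.0, amplitude=1.0, baseline_offset=2.0,
        noise_sd=0.02, duration_h=240.0, sampling_interval_h=0.5, seed=4,
    )

    def test_identical_pre_post_all_zero(self):
        tr = generate_treatment_trace(self.BASE, 120.0)
        wc = waveform_changes(tr)
        assert abs(wc.delta_baseline_rel) < 0.05
        assert abs(wc.delta_amplitude_rel) < 0.05
        assert abs(wc.delta_period_h) < 0.3

    def test_baseline_doubling(self):
        tr = generate_treatment_trace(self.BASE, 120.0, baseline_factor=2.0)
        wc = waveform_changes(tr)
        assert wc.delta_baseline_rel == pytest.approx(1.0, abs=0.15)

    def test_amplitude_halving(self):
        tr = generate_treatment_trace(self.BASE, 120.0, amplitude_factor=0.5)
        wc = waveform_changes(tr)
        assert wc.delta_amplitude_rel == pytest.approx(-0.5, abs=0.1)

    def test_period_lengthening_detected(self):
        tr = generate_treatment_trace(self.BASE, 120.0, period_post_h=26.0)
        wc = waveform_changes(tr)
        assert wc.delta_period_h == pytest.approx(2.0, abs=0.5)


class TestPhaseMap:
    BASE = RhythmConfig(
        period_h=24.0, phase_h=6.0, amplitude=1.0, damping_per_h=0.005,
        baseline_offset=2.0, noise_sd=0.2, duration_h=120.0,
        sampling_interval_h=0.5, seed=11,
    )

    def test_zero_gradient_coherent(self):
        grid = generate_roi_grid(4, 4, 1.0, 0.0, self.BASE)
        pm = build_phase_map(grid, signal_threshold=-np.inf)
        assert pm.initiated_fraction == 1.0
        assert pm.rayleigh_R > 0.98
        assert np.nanmax(np.abs(pm.table["rel_phase_h"])) < 1.0

    def test_initiated_fraction_recovered(self):
        grid = generate_roi_grid(10, 10, 0.7, 0.0, self.BASE)
        pm = build_phase_map(grid, signal_threshold=-np.inf)
        assert abs(pm.initiated_fraction - 0.7) <= 0.07

    def test_gradient_recovered(self):
        grid = generate_roi_grid(6, 10, 1.0, 4.0, self.BASE)
        pm = build_phase_map(grid, signal_threshold=-np.inf)
        sub = pm.table[pm.table["initiated"]]
        slope = np.polyfit(sub["col"], sub["rel_phase_h"], 1)[0]
        assert slope * 9 == pytest.approx(4.0, abs=0.25)

    def test_signal_threshold_excludes_rois(self):
        grid = generate_roi_grid(2, 2, 1.0, 0.0, self.BASE)
        # dim one ROI below the threshold
        grid.traces[0] = grid.traces[0].replace_signal(grid.traces[0].signal - 10.0)
        pm = build_phase_map(grid, signal_threshold=0.0)
        assert pm.table["included"].sum() == 3
        with pytest.raises(ValueError, match="threshold"):
            build_phase_map(grid, signal_threshold=1e9)


class TestPRC:
    def test_all_zero_shifts(self):
        prc = assemble_prc([(ct, 0.0) for ct in range(0, 24, 2)])
        filled = prc[prc["n"] > 0]
        assert (filled["mean_shift_h"] == 0.0).all()

    def test_binned_means(self):
        records = [(10.0, -2.0), (10.5, -2.0), (4.0, 0.0), (16.0, 0.0)]
        prc = assemble_prc(records)
        assert prc.loc[9.0, "mean_shift_h"] == pytest.approx(-2.0)
        assert prc.loc[9.0, "n"] == 2
        assert prc.loc[3.0, "mean_shift_h"] == 0.0
        assert prc.loc[0.0, "n"] == 0

    def test_bin_anchoring_at_ct0(self):
        # CT 23.9 falls in the [21, 24) bin, CT 0.5 in [0, 3): not the same bin
        prc = assemble_prc([(23.9, 1.0), (0.5, -1.0)])
        assert prc.loc[21.0, "n"] == 1
        assert prc.loc[0.0, "n"] == 1


class TestMapCT:
    def test_reference_identity(self):
        assert map_ct(5.0, 5.0, 7.2) == pytest.approx(7.2)

    def test_reporter_registration_arithmetic(self):
        # reference CT 7.2, phase 0.9 h later -> CT 8.1
        assert map_ct(3.0, 2.1, 7.2) == pytest.approx(8.1)

    def test_wraps_modulo_period(self):
        assert map_ct(2.0, 0.0, 23.0) == pytest.approx(1.0)

    def test_period_mismatch_warns(self):
        with pytest.warns(UserWarning, match="periods differ"):
            map_ct(1.0, 0.0, 0.0, period_h=24.0, reference_period_h=26.0)
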