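"""Delayed Gillespie simulator, MS2 measurement model, interval statistics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from ms2quant import burstmodel as bm


class TestSimulator:
    def test_unregulated_intervals_exponential(self):
        # two-state telegraph promoter: mean ON = 1/k_off, mean OFF = 1/k_on,
        # both exponential
        params = replace(bm.PRESETS["none"], r_p=0.0)
        traj = bm.simulate_feedback_bursting(params, T=15000, seed=1)
        act, inact = traj.promoter_intervals()
        assert len(act) > 500
        assert act.mean() == pytest.approx(1 / 0.4, rel=0.1)
        assert inact.mean() == pytest.approx(1 / 0.055, rel=0.1)
        assert stats.kstest(act, "expon", args=(0, act.mean())).pvalue > 0.01
        assert stats.kstest(inact, "expon", args=(0, inact.mean())).pvalue > 0.01

    def test_always_on_birth_death_mean(self):
        # promoter pinned ON: stationary mRNA mean = r_m/gamma_m = 43.3
        params = replace(bm.PRESETS["none"], k_off=0.0, k_on=1e9, r_p=0.0)
        traj = bm.simulate_feedback_bursting(params, T=3000, seed=2)
        settle = traj.grid_times > 50
        assert traj.mrna[settle].mean() == pytest.approx(10.0 / 0.231, rel=0.05)

    def test_telegraph_stationary_mrna_moments(self):
        # random-telegraph transcription: mean M = r_m gamma-weighted ON
        # fraction; compare simulation to the analytic stationary mean
        params = replace(bm.PRESETS["none"], k_on=0.2, k_off=0.4, r_p=0.0)
        means = []
        for seed in range(10):
            traj = bm.simulate_feedback_bursting(params, T=2000, seed=seed)
            means.append(traj.mrna[traj.grid_times > 50].mean())
        on_frac = 0.2 / (0.2 + 0.4)
        expected = 10.0 * on_frac / 0.231
        assert np.mean(means) == pytest.approx(expected, rel=0.05)

    def test_delay_holds_back_first_mrna(self):
        params = replace(bm.PRESETS["none"], k_on=1e9, k_off=0.0, tau=7.5,
                         r_p=0.0)
        traj = bm.simulate_feedback_bursting(params, T=60, seed=3)
        first = traj.grid_times[np.argmax(traj.mrna > 0)]
        assert traj.mrna.max() > 0
        assert first >= 7.5

    def test_seeded_reproducibility(self):
        p = bm.PRESETS["frequency"]
        t1 = bm.simulate_feedback_bursting(p, T=500, seed=11)
        t2 = bm.simulate_feedback_bursting(p, T=500, seed=11)
        assert np.array_equal(t1.switch_times, t2.switch_times)
        assert np.array_equal(t1.protein, t2.protein)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            bm.BurstModelParams(n=0.5)
        with pytest.raises(ValueError):
            bm.BurstModelParams(regulation_mode="nonsense")
        with pytest.raises(ValueError):
            bm.simulate_feedback_bursting(bm.PRESETS["none"], T=0, seed=0)


class TestMS2Synthesis:
    def test_silent_promoter_silent_signal(self):
        sig = bm.synthesize_ms2_signal(np.zeros(100), np.full(100, 10.0),
                                       seed=0)
        assert np.all(sig == 0)

    def test_constant_promoter_plateau(self):
        # noiseless, thresholdless: after the ramp the signal plateaus at
        # r_m * (1 - w/2) (kernel area for ramp w then plateau to one frame)
        w = 0.29
        ms2 = bm.MS2SynthParams(w=w, sigma_ms2=0.0, detection_threshold=0.0)
        sig = bm.synthesize_ms2_signal(np.ones(50), np.full(50, 10.0), ms2,
                                       seed=0)
        assert np.allclose(sig[2:], 10.0 * (1 - w / 2), rtol=5e-3)

    def test_kernel_length_rejected_above_one(self):
        with pytest.raises(ValueError):
            bm.MS2SynthParams(w=1.5)

    def test_default_kernel_is_cassette_over_elongation(self):
        # 1.4 kb cassette / 4.8 kb/min elongation = 0.29 min dwell; at
        # 1/min sampling the normalized kernel length equals the dwell
        assert bm.MS2SynthParams().w == pytest.approx(1.4 / 4.8, abs=0.005)

    def test_detection_threshold_zeroes_weak_signal(self):
        ms2 = bm.MS2SynthParams(sigma_ms2=0.0)
        promoter = np.zeros(60)
        promoter[30] = 1  # single 1-min pulse at 3% of the maximum rate
        sig = bm.synthesize_ms2_signal(promoter, np.full(60, 0.3), ms2,
                                       seed=0, max_rate=10.0)
        assert np.all(sig == 0)  # below 0.2 * w * max r_m = 0.58


class TestIntervals:
    def test_binary_sequence_runs_with_censoring(self):
        act, inact = bm.extract_intervals(
            np.array([0, 1, 1, 0, 0, 1, 0], dtype=float))
        assert sorted(act.tolist()) == [1.0, 2.0]
        assert inact.tolist() == [2.0]

    def test_all_on_censored_empty(self):
        act, inact = bm.extract_intervals(np.ones(10))
        assert act.size == 0 and inact.size == 0

    @pytest.mark.parametrize("sigma_ms2", [0.0, 0.4])
    def test_frequency_signature_robust_to_measurement_noise(self, sigma_ms2):
        # the exponential-active / peaked-inactive fingerprint survives the
        # whole range of measurement noise levels
        traj = bm.simulate_feedback_bursting(bm.PRESETS["frequency"],
                                             T=5000, seed=71)
        sig = bm.synthesize_ms2_signal(traj.promoter, traj.rate,
                                       bm.MS2SynthParams(sigma_ms2=sigma_ms2),
                                       seed=72)
        act, inact = bm.extract_intervals(sig, binarize_threshold=1.0, kernel=3)
        assert bm.exponentiality_pvalue(act) > 0.01
        assert bm.exponentiality_pvalue(inact) < 0.01

    def test_simulation_intervals_match_rates(self):
        params = replace(bm.PRESETS["none"], r_p=0.0)
        traj = bm.simulate_feedback_bursting(params, T=15000, seed=5)
        act, inact = traj.promoter_intervals()
        assert 1 / act.mean() == pytest.approx(0.4, rel=0.1)
        assert 1 / inact.mean() == pytest.approx(0.055, rel=0.1)


class TestRegularity:
    def test_sinusoid_cv_zero(self):
        # a 40-min sinusoid peaks exactly on the 1-min grid, so every
        # measured period is identical
        t = np.arange(0, 400, 1.0)
        assert bm.protein_period_cv(np.sin(2 * np.pi * (t - 10) / 40) + 2,
                                    t) == pytest.approx(0.0, abs=1e-9)

    def test_poisson_peaks_cv_near_one(self):
        # exponential inter-peak intervals have CV 1
        from ms2quant.dynamics import measure_periods
        rng = np.random.default_rng(0)
        arrivals = np.cumsum(rng.exponential(10.0, 501))
        _, summary = measure_periods(None, peak_times=arrivals)
        assert summary["cv"] == pytest.approx(1.0, abs=0.1)

    def test_too_few_peaks_undefined(self):
        t = np.arange(0, 50, 1.0)
        assert np.isnan(bm.protein_period_cv(np.exp(-(t - 25) ** 2 / 20), t))

    def test_regulated_presets_more_regular_than_none(self):
        # feedback through amplitude, frequency, duration or both rates
        # produces quasi-regular protein oscillations: period CV below the
        # unregulated two-state model under matched measurement smoothing
        from ms2quant.traces import moving_average

        def mean_cv(preset, seeds=(100, 101, 102)):
            cvs = []
            for seed in seeds:
                traj = bm.simulate_feedback_bursting(bm.PRESETS[preset],
                                                     T=4000, seed=seed)
                cvs.append(bm.protein_period_cv(
                    moving_average(traj.protein[60:], 5),
                    traj.grid_times[60:]))
            return float(np.mean(cvs))

        cv_none = mean_cv("none")
        for preset in ("amplitude", "frequency", "duration", "freq+dur"):
            assert mean_cv(preset) < cv_none
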