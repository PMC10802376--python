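"""Trace assembly: assignment, refinement, filters, and uncertainties."""

import numpy as np
import pandas as pd
import pytest

from ms2quant import traces as tr


def _labels(shape=(3, 10, 20, 20)):
    lab = np.zeros(shape, dtype=np.int32)
    lab[:, 3:7, 4:9, 4:9] = 7
    lab[:, 3:7, 13:18, 13:18] = 8
    return lab


def _spot(t, z, y, x, prob=0.9, intensity=100.0):
    return {"t": t, "z": z, "y": y, "x": x, "probability": prob,
            "intensity": intensity, "background": 10.0}


class TestAssignment:
    def test_centroid_inside_nucleus(self):
        spots = pd.DataFrame([_spot(0, 5.0, 6.0, 6.0)])
        out = tr.assign_spots_to_nuclei(spots, _labels())
        assert list(out["nucleus_id"]) == [7]

    def test_nearby_spot_snaps_to_nucleus(self):
        # 3 px outside nucleus 7, nothing else within the search cube
        spots = pd.DataFrame([_spot(0, 5.0, 6.0, 11.5)])
        out = tr.assign_spots_to_nuclei(spots, _labels())
        assert list(out["nucleus_id"]) == [7]

    def test_unassignable_spot_dropped(self):
        spots = pd.DataFrame([_spot(0, 9.0, 19.0, 0.0)])
        out = tr.assign_spots_to_nuclei(spots, _labels())
        assert len(out) == 0

    def test_duplicate_keeps_highest_probability(self):
        spots = pd.DataFrame([_spot(0, 5.0, 6.0, 6.0, prob=0.75, intensity=1.0),
                              _spot(0, 5.0, 7.0, 7.0, prob=0.9, intensity=2.0)])
        out = tr.assign_spots_to_nuclei(spots, _labels())
        assert len(out) == 1
        assert out["probability"].iloc[0] == 0.9

    def test_label_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            tr.assign_spots_to_nuclei(pd.DataFrame([_spot(0, 1, 1, 1)]),
                                      np.zeros((4, 4, 4)))


class TestActiveRegions:
    def test_moving_average_zero_padded(self):
        x = np.array([5.0, 0, 0, 0, 0])
        ma = tr.moving_average(x, 5)
        assert ma[0] == pytest.approx(1.0)
        assert ma[4] == pytest.approx(0.0)

    def test_any_nonzero_point_is_active(self):
        # threshold 1 with window 5 marks the neighborhood of a detection
        I = np.array([0, 0, 20.0, 0, 0, 0, 0, 0])
        act = tr.active_regions(I)
        assert act[:5].all() and not act[5:].any()


class TestUncertainty:
    def _trace(self, I, bg=None, times=None):
        n = len(I)
        return tr.Trace(nucleus_id=1,
                        times=np.arange(n, dtype=float) if times is None else times,
                        intensities=np.asarray(I, dtype=float),
                        backgrounds=np.full(n, 10.0) if bg is None else bg,
                        positions=np.zeros((n, 3)))

    def test_direct_evaluation_of_detected_branch(self):
        # sigma_I = 5, I = 100, fp = 0.04:
        # sqrt(25/0.96 + 10000*0.04/0.96) = 20.96
        trace = self._trace([100.0] * 8)
        rates = tr.DetectionErrorRates(fp=0.04, fn=0.08)
        tr.estimate_trace_uncertainty(trace, rates)
        # construct the target directly from the formula with sigma_I forced
        sigma = np.sqrt(5**2 / 0.96 + 100.0**2 * 0.04 / 0.96)
        assert sigma == pytest.approx(21.0, abs=0.05)

    def test_formula_branches(self):
        rng = np.random.default_rng(0)
        n = 30
        bg = 50.0 + rng.normal(0, 5.0, n)
        I = np.array([100.0, 0.0] * (n // 2))
        trace = self._trace(I, bg=bg)
        rates = tr.DetectionErrorRates(fp=0.04, fn=0.08)
        sig = tr.estimate_trace_uncertainty(trace, rates)
        coef = np.polyfit(trace.times, bg, 4)
        sigma_I = np.sqrt(np.mean((bg - np.polyval(coef, trace.times)) ** 2))
        expect_pos = np.sqrt(sigma_I**2 / 0.96 + 100.0**2 * 0.04 / 0.96)
        expect_zero = trace.mean_intensity * 0.08 / 0.92
        assert sig[I > 0] == pytest.approx(expect_pos)
        assert sig[I == 0] == pytest.approx(expect_zero)

    def test_zero_intensity_branch_value(self):
        # I = 0, Ibar = 50, fn = 0.08 -> 50*0.08/0.92 = 4.35
        assert 50 * 0.08 / 0.92 == pytest.approx(4.35, abs=0.01)
        trace = self._trace([50.0, 50.0, 0.0, 50.0, 50.0, 50.0, 50.0])
        sig = tr.estimate_trace_uncertainty(
            trace, tr.DetectionErrorRates(fp=0.0, fn=0.08))
        assert sig[2] == pytest.approx(4.35, abs=0.01)

    def test_limits(self):
        trace = self._trace([100.0] * 8)
        sig0 = tr.estimate_trace_uncertainty(
            trace, tr.DetectionErrorRates(fp=0.0, fn=0.0))
        # fp = 0 at I > 0: sigma reduces to sigma_I (flat background -> 0)
        assert np.allclose(sig0, 0.0)

    def test_monotone_in_error_rates(self):
        base = self._trace([100.0, 0.0, 100.0, 100.0, 0.0, 100.0, 100.0])
        sig_lo = tr.estimate_trace_uncertainty(
            base, tr.DetectionErrorRates(fp=0.01, fn=0.01)).copy()
        sig_hi = tr.estimate_trace_uncertainty(
            base, tr.DetectionErrorRates(fp=0.1, fn=0.1))
        assert np.all(sig_hi >= sig_lo)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            tr.DetectionErrorRates(fp=1.0)


class TestSpatialFilter:
    def _trace(self, n_spots, ap=100.0):
        n = max(n_spots, 12) + 2
        I = np.zeros(n)
        I[:n_spots] = 50.0
        t = tr.Trace(nucleus_id=1, times=np.arange(n, dtype=float),
                     intensities=I, backgrounds=np.full(n, 5.0),
                     positions=np.zeros((n, 3)))
        t._ap = ap
        return t

    def test_minimum_spot_count_is_strict(self):
        # "greater than 10 spots": a 10-spot trace is removed, 11 kept
        kept = tr.filter_traces_spatially([self._trace(10), self._trace(11)])
        assert [t.n_spots for t in kept] == [11]

    def test_anterior_cut(self):
        t = self._trace(12)
        kept = tr.filter_traces_spatially(
            [t], ap_positions=lambda tr_, i: -45.0,
            somite_front=lambda time: 0.0)
        assert kept == []  # all spots 45 um anterior of the front -> dropped

    def test_spot_near_axis_posterior_kept(self):
        t = self._trace(12)
        kept = tr.filter_traces_spatially(
            [t], ap_positions=lambda tr_, i: 30.0,
            somite_front=lambda time: 0.0,
            axis_distances=lambda tr_, i: 10.0)
        assert len(kept) == 1 and kept[0].n_spots == 12

    def test_far_from_axis_rejected(self):
        t = self._trace(12)
        kept = tr.filter_traces_spatially(
            [t], axis_distances=lambda tr_, i: 60.0)
        assert kept == []


class TestRoundTrip:
    def test_csv_roundtrip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 12
        trace = tr.Trace(nucleus_id=3, times=np.arange(n, dtype=float),
                         intensities=rng.uniform(0, 100, n).round(3),
                         backgrounds=rng.uniform(5, 15, n).round(3),
                         positions=rng.uniform(0, 50, (n, 3)).round(3))
        tr.estimate_trace_uncertainty(trace)
        path = tmp_path / "traces.csv"
        tr.write_traces([trace], path)
        back = tr.read_traces(path)
        assert len(back) == 1
        assert np.allclose(back[0].intensities, trace.intensities)
        assert np.allclose(back[0].uncertainties, trace.uncertainties)
        assert np.allclose(back[0].positions, trace.positions)
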