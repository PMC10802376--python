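"""Anterior-posterior axis, kymographs, and tissue-scale period measurement.

The anterior-posterior (AP) axis is defined from ~10 manually placed
anchor points per keyframe, spanning the last formed somite (the origin)
to the tip of the tailbud. Each keyframe's anchors are interpolated with
a degree-2 B-spline resampled to 100 points; each of the 100 point
indices is then interpolated over time with a degree-1 B-spline. Spots
are assigned an AP position via the axis point nearest (Euclidean) to
their centroid.

Kymographs sum spot intensity (or predicted protein) in 100 equally
spaced AP bins per time point; oscillations appear as stripes whose slope
is the phase-wave speed. The tissue-scale period is measured on the
summed signal of a fixed AP window by fitting Gaussian profiles to
isolated oscillations and differencing successive fitted centers, with
uncertainties bootstrapped over the spatial bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, optimize
from scipy.signal import argrelmin


@dataclass
class APAxis:
    """Spline-interpolated AP axis: per-time point lists with arc length."""

    times: np.ndarray      # keyframe-interpolated support (observed times)
    points: np.ndarray     # (n_times, n_points, 3) um, index 0 = origin
    arc_length: np.ndarray  # (n_times, n_points) um from the origin

    def at_time(self, t: float):
        """Axis points and arc lengths at time t (linear in time)."""
        i = np.searchsorted(self.times, t)
        if self.times.size == 1 or t <= self.times[0]:
            return self.points[0], self.arc_length[0]
        if t >= self.times[-1]:
            return self.points[-1], self.arc_length[-1]
        i = np.searchsorted(self.times, t, side="right") - 1
        f = (t - self.times[i]) / (self.times[i + 1] - self.times[i])
        pts = (1 - f) * self.points[i] + f * self.points[i + 1]
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        return pts, arc

    def assign(self, t: float, position):
        """(arc position, distance to axis) of a 3D point at time t."""
        pts, arc = self.at_time(t)
        d = np.linalg.norm(pts - np.asarray(position, dtype=float), axis=1)
        k = int(np.argmin(d))
        return float(arc[k]), float(d[k])

    @property
    def length(self) -> float:
        return float(np.max(self.arc_length[:, -1]))


def build_ap_axis(anchor_points: pd.DataFrame, n_points: int = 100,
                  spatial_degree: int = 2, temporal_degree: int = 1) -> APAxis:
    """Spline-interpolate manually placed anchors into a dense AP axis.

    ``anchor_points`` has columns t, z, y, x (um), >= 2 anchors per
    keyframe, ordered from the last formed somite (origin) to the tailbud
    tip. A single keyframe yields a static axis.
    """
    keyframes = sorted(anchor_points["t"].unique())
    per_time = []
    for t in keyframes:
        pts = anchor_points.loc[anchor_points["t"] == t, ["z", "y", "x"]].to_numpy(float)
        if len(pts) < 2:
            raise ValueError(f"need >= 2 anchor points per keyframe (t={t})")
        k = min(spatial_degree, len(pts) - 1)
        tck, _ = interpolate.splprep(pts.T, k=k, s=0)
        u = np.linspace(0, 1, n_points)
        per_time.append(np.stack(interpolate.splev(u, tck), axis=1))
    per_time = np.asarray(per_time)  # (n_key, n_points, 3)
    times = np.asarray(keyframes, dtype=float)
    if len(keyframes) > 1 and temporal_degree != 1:
        # degree-1 temporal interpolation is what APAxis.at_time implements
        raise NotImplementedError("only degree-1 temporal splines are supported")
    arc = np.stack([np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(p, axis=0), axis=1))]) for p in per_time])
    return APAxis(times=times, points=per_time, arc_length=arc)


def compute_kymograph(spots: pd.DataFrame, ap_axis: APAxis,
                      n_bins: int = 100, axis_cut: float | None = None,
                      value_column: str = "intensity") -> tuple[np.ndarray, np.ndarray]:
    """AP-bin x time matrix of summed intensity.

    ``spots`` needs columns t, z, y, x (um) and ``value_column``. Bin edges
    are equally spaced over [0, axis length] (bin width = length / n_bins,
    so it scales with the dataset's axis rather than being hard-coded).
    Spots farther than ``axis_cut`` um from the axis are excluded. Returns
    ``(kymograph, bin_edges)`` with kymograph shaped (n_bins, n_times);
    render with time increasing downward (transpose).
    """
    times = np.sort(spots["t"].unique())
    edges = np.linspace(0.0, ap_axis.length, n_bins + 1)
    kymo = np.zeros((n_bins, len(times)))
    for j, t in enumerate(times):
        sub = spots[spots["t"] == t]
        for row in sub.itertuples():
            ap, dist = ap_axis.assign(t, (row.z, row.y, row.x))
            if axis_cut is not None and dist > axis_cut:
                continue
            b = min(int(np.searchsorted(edges, ap, side="right")) - 1, n_bins - 1)
            kymo[b, j] += getattr(row, value_column)
    return kymo, edges


def _gaussian(t, a, mu, sig, off):
    return a * np.exp(-((t - mu) ** 2) / (2 * sig**2)) + off


def _fit_peak_center(t, y):
    a0 = float(y.max() - y.min())
    mu0 = float(t[np.argmax(y)])
    sig0 = max((t[-1] - t[0]) / 4.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, t, y, p0=[a0, mu0, sig0, float(y.min())],
            bounds=([0, t[0], 1e-3, -np.inf], [np.inf, t[-1], t[-1] - t[0] + 1, np.inf]),
            maxfev=2000)
        return float(popt[1])
    except (RuntimeError, ValueError):
        return None


def _section_boundaries(signal: np.ndarray, smooth: int = 5) -> list[np.ndarray]:
    """Split a signal into single-oscillation sections at its minima."""
    from .traces import moving_average
    s = moving_average(signal, smooth)
    minima = argrelmin(s, order=max(2, smooth // 2))[0]
    bounds = np.concatenate([[0], minima, [len(signal) - 1]])
    return [np.arange(bounds[i], bounds[i + 1] + 1)
            for i in range(len(bounds) - 1) if bounds[i + 1] - bounds[i] >= 4]


def measure_tissue_period(kymograph: np.ndarray, bin_edges: np.ndarray,
                          times: np.ndarray,
                          region=(240.0, 315.0),
                          sections: list[np.ndarray] | None = None,
                          n_bootstrap: int = 200,
                          seed: int = 0):
    """Per-oscillation tissue-scale periods with bootstrap uncertainties.

    Sums the kymograph rows whose bins fall inside ``region`` (um along the
    AP axis), splits the summed signal into single-oscillation sections
    (automatically at signal minima, or use ``sections`` to override with
    manually defined index arrays), fits a Gaussian profile per section,
    and differences successive fitted centers. Bootstrap standard errors
    re-draw the spatial bins with replacement.

    Returns a DataFrame with columns t_mid, period_min, period_se.
    """
    times = np.asarray(times, dtype=float)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    rows = np.where((centers >= region[0]) & (centers < region[1]))[0]
    if rows.size == 0:
        raise ValueError("no kymograph bins inside the region")
    sub = kymograph[rows]

    def periods_of(signal):
        secs = sections if sections is not None else _section_boundaries(signal)
        mus = []
        for sec in secs:
            mu = _fit_peak_center(times[sec], signal[sec])
            if mu is not None:
                mus.append(mu)
        mus = np.sort(np.asarray(mus))
        return np.diff(mus), mus

    base_periods, mus = periods_of(sub.sum(axis=0))
    if base_periods.size == 0:
        return pd.DataFrame(columns=["t_mid", "period_min", "period_se"])
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_bootstrap):
        pick = rng.integers(0, len(rows), size=len(rows))
        p, _ = periods_of(sub[pick].sum(axis=0))
        if p.size == base_periods.size:
            boot.append(p)
    se = (np.std(np.asarray(boot), axis=0) if boot
          else np.full_like(base_periods, np.nan))
    t_mid = 0.5 * (mus[1:] + mus[:-1])
    return pd.DataFrame({"t_mid": t_mid, "period_min": base_periods,
                         "period_se": se})
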