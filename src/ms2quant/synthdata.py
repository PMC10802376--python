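"""Synthetic MS2 spot voxels, spot libraries, and embryo-like test movies.

The spot generator reproduces the validation imagery used to characterise
the quantification pipeline: a Gaussian point-spread function on a constant
offset, plus a structured background modelled as an exponential gradient
with a 10-pixel decay length and random 3D orientation, with per-pixel
Poisson (shot) noise. Ground truth (integrated intensity over the standard
integration ellipsoid, and the true center) is recorded before noise so
that measurement accuracy can be assessed exactly.

The movie generator renders moving nuclei with stable integer labels and
known per-nucleus promoter traces, providing an end-to-end fixture for the
detection -> classification -> quantification -> trace pipeline. It stands
in for real light-sheet data (which would come with an external nuclear
segmentation/tracking tool) and is deliberately simple: bright ellipsoidal
nuclei, heterogeneous per-nucleus MCP background, Poisson noise.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._geom import (
    ELLIPSOID_SIZE,
    VOXEL_SHAPE,
    ellipsoid_mask,
    gaussian_field,
    shell_mask,
    voxel_center,
)

#: Default PSF widths (z, y, x) in pixels, reflecting z-anisotropy of
#: light-sheet stacks sampled at 0.97 um (z) x 0.485 um (xy).
DEFAULT_SIGMA = (1.5, 1.3, 1.3)

#: Decay length of the structured-background exponential gradient (pixels).
GRADIENT_DECAY = 10.0

#: Default physical pixel size (z, y, x) in micrometers.
DEFAULT_PIXEL_SIZE = (0.97, 0.485, 0.485)


@dataclass(frozen=True)
class SpotSpec:
    """Parameters of one synthetic spot voxel."""

    amplitude: float
    sigma: tuple = DEFAULT_SIGMA
    offset: float = 100.0
    gradient_amplitude: float = 0.0
    gradient_decay: float = GRADIENT_DECAY
    gradient_direction: tuple = (0.0, 0.0, 1.0)
    poisson_noise: bool = True
    true_center: tuple | None = None  # defaults to the voxel center

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if np.any(np.asarray(self.sigma) <= 0):
            raise ValueError("sigma must be positive per axis")
        if self.gradient_decay <= 0:
            raise ValueError("gradient_decay must be positive")
        d = np.asarray(self.gradient_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValueError("gradient_direction must have unit norm")


def spot_mean_field(spec: SpotSpec, voxel_shape=VOXEL_SHAPE) -> np.ndarray:
    """Noiseless mean field: Gaussian + offset + exponential gradient.

    The gradient is ``g * exp(-(r - r0) . d / L)`` with ``r0`` the voxel
    center, so ``gradient_amplitude`` is the gradient's value at the center
    and is directly comparable to ``offset``.
    """
    shape = tuple(voxel_shape)
    center = spec.true_center if spec.true_center is not None else voxel_center(shape)
    center = np.asarray(center, dtype=float)
    if np.any(center < 0) or np.any(center > np.asarray(shape) - 1):
        raise ValueError("true_center lies outside the voxel")
    fld = gaussian_field(shape, center, spec.sigma, spec.amplitude) + spec.offset
    if spec.gradient_amplitude != 0.0:
        r0 = voxel_center(shape)
        grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
        proj = sum((g - c) * d for g, c, d in zip(grids, r0, spec.gradient_direction))
        fld = fld + spec.gradient_amplitude * np.exp(-proj / spec.gradient_decay)
    return fld


def true_integrated_intensity(spec: SpotSpec, voxel_shape=VOXEL_SHAPE,
                              ellipsoid_size=ELLIPSOID_SIZE) -> float:
    """Noiseless Gaussian summed over the standard integration ellipsoid.

    Defined over the same ellipsoid quantification integrates over, so the
    measured/true comparison isolates measurement error.
    """
    shape = tuple(voxel_shape)
    center = spec.true_center if spec.true_center is not None else voxel_center(shape)
    mask = ellipsoid_mask(shape, center, ellipsoid_size)
    return float(gaussian_field(shape, center, spec.sigma, spec.amplitude)[mask].sum())


def generate_spot_voxel(spec: SpotSpec, voxel_shape=VOXEL_SHAPE, seed=None):
    """Render one synthetic spot voxel.

    Returns ``(voxel, truth)`` where truth carries the pre-noise integrated
    intensity and the true center.
    """
    shape = tuple(voxel_shape)
    if any(s < m for s, m in zip(shape, VOXEL_SHAPE)):
        raise ValueError(f"voxel_shape must be at least {VOXEL_SHAPE}")
    mean = spot_mean_field(spec, shape)
    if spec.poisson_noise:
        rng = np.random.default_rng(seed)
        voxel = rng.poisson(mean).astype(float)
    else:
        voxel = mean
    center = spec.true_center if spec.true_center is not None else tuple(voxel_center(shape))
    truth = {
        "integrated_intensity": true_integrated_intensity(spec, shape),
        "center": tuple(float(c) for c in center),
    }
    return voxel, truth


def random_unit_vector(rng: np.random.Generator) -> tuple:
    v = rng.normal(size=3)
    return tuple(v / np.linalg.norm(v))


def generate_spot_library(amplitude_grid: Sequence[float],
                          gradient_grid: Sequence[float],
                          n_per_cell: int,
                          seed: int,
                          offset: float = 100.0,
                          sigma=DEFAULT_SIGMA,
                          voxel_shape=VOXEL_SHAPE,
                          center_jitter: float = 0.5) -> list[dict]:
    """Library of synthetic spots spanning amplitude x gradient conditions.

    Each entry is ``{"spec", "voxel", "truth"}``. Spot centers are jittered
    uniformly by up to ``center_jitter`` pixels per axis around the voxel
    center so sub-pixel localization is exercised. Deterministic given
    ``seed`` (bit-identical arrays on repeated calls).
    """
    amplitude_grid = list(amplitude_grid)
    gradient_grid = list(gradient_grid)
    if not amplitude_grid or not gradient_grid or n_per_cell < 1:
        raise ValueError("grids must be non-empty and n_per_cell >= 1")
    rng = np.random.default_rng(seed)
    library = []
    c0 = voxel_center(voxel_shape)
    for amp in amplitude_grid:
        for grad in gradient_grid:
            for _ in range(n_per_cell):
                jitter = rng.uniform(-center_jitter, center_jitter, size=3)
                spec = SpotSpec(
                    amplitude=float(amp),
                    sigma=tuple(sigma),
                    offset=float(offset),
                    gradient_amplitude=float(grad),
                    gradient_direction=random_unit_vector(rng),
                    poisson_noise=True,
                    true_center=tuple(c0 + jitter),
                )
                voxel, truth = generate_spot_voxel(
                    spec, voxel_shape, seed=rng.integers(0, 2**31 - 1))
                library.append({"spec": spec, "voxel": voxel, "truth": truth})
    return library


def predicted_operating_point(spec: SpotSpec, voxel_shape=VOXEL_SHAPE,
                              ellipsoid_size=ELLIPSOID_SIZE,
                              inner_width: float = 4, outer_width: float = 6):
    """Signal:background and structuredness implied by a spec's mean field.

    Signal is the mean background-subtracted spot pixel intensity over the
    integration ellipsoid divided by the local background; structuredness is
    the variance-to-mean ratio of the shell pixels, including the Poisson
    contribution (variance equal to the mean) on top of the spatial
    structure of the noiseless field.
    """
    shape = tuple(voxel_shape)
    center = spec.true_center if spec.true_center is not None else voxel_center(shape)
    mean = spot_mean_field(spec, shape)
    sh = shell_mask(shape, center, inner_width, outer_width)
    shell_vals = mean[sh]
    bg = float(shell_vals.mean())
    # total variance across shell pixels = spatial variance + Poisson variance
    structuredness = (float(shell_vals.var()) + bg) / bg
    ell = ellipsoid_mask(shape, center, ellipsoid_size)
    signal = float(np.clip(mean[ell] - bg, 0, None).mean())
    return signal / bg, structuredness


def operating_point_amplitudes(signal_to_background: float,
                               structuredness: float,
                               offset: float = 100.0,
                               sigma=DEFAULT_SIGMA,
                               voxel_shape=VOXEL_SHAPE,
                               n_directions: int = 32):
    """Solve for (spot amplitude, gradient amplitude) hitting an operating point.

    Inverts the noiseless mean-field predictions of
    :func:`predicted_operating_point`, averaging over a deterministic set of
    gradient directions; bisection on the gradient amplitude (structuredness
    is monotone in it), then a direct solve for the spot amplitude.
    """
    rng = np.random.default_rng(12345)  # fixed: calibration is deterministic
    directions = [random_unit_vector(rng) for _ in range(n_directions)]
    shape = tuple(voxel_shape)
    c0 = voxel_center(shape)
    ell = ellipsoid_mask(shape, c0, ELLIPSOID_SIZE)
    sh = shell_mask(shape, c0)
    unit_gauss = gaussian_field(shape, c0, sigma, 1.0)
    gauss_ell_mean = float(unit_gauss[ell].mean())   # spot signal per unit amplitude
    gauss_shell = unit_gauss[sh]                     # spot tail bleeding into the shell

    def shell_field(amp, grad, d):
        grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
        proj = sum((g - c) * di for g, c, di in zip(grids, c0, d))
        return (offset + grad * np.exp(-proj / GRADIENT_DECAY))[sh] + amp * gauss_shell

    def mean_bg_struct(amp, grad):
        bgs, sts = [], []
        for d in directions:
            vals = shell_field(amp, grad, d)
            m = float(vals.mean())
            bgs.append(m)
            sts.append((float(vals.var()) + m) / m)
        return float(np.mean(bgs)), float(np.mean(sts))

    amp = 0.0
    grad = offset
    for _ in range(8):
        # bisect the gradient amplitude for the structuredness target
        lo, hi = 0.0, max(grad, offset)
        while mean_bg_struct(amp, hi)[1] < structuredness:
            hi *= 2.0
            if hi > 1e7:
                raise ValueError("structuredness target unattainable")
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if mean_bg_struct(amp, mid)[1] < structuredness:
                lo = mid
            else:
                hi = mid
        grad = 0.5 * (lo + hi)
        # amplitude so the Gaussian's ellipsoid mean is sb * background
        bg, _ = mean_bg_struct(amp, grad)
        amp_new = signal_to_background * bg / gauss_ell_mean
        if abs(amp_new - amp) < 1e-6 * max(1.0, amp):
            amp = amp_new
            break
        amp = amp_new
    return amp, grad


def generate_regime_library(sb_targets=(0.1, 0.35, 0.7, 1.1, 1.5),
                            st_targets=(1.0, 10.0, 25.0, 40.0, 60.0, 80.0),
                            n_per_cell: int = 60,
                            seed: int = 0,
                            offset: float = 100.0,
                            sigma=DEFAULT_SIGMA,
                            voxel_shape=VOXEL_SHAPE) -> list[dict]:
    """Spot library spanning the accuracy regime diagram.

    Each (signal:background, structuredness) cell is calibrated with
    :func:`operating_point_amplitudes` and populated with ``n_per_cell``
    noise realisations (random gradient orientation, sub-pixel center
    jitter). Covers the experimental operating point (0.35, 40).
    """
    rng = np.random.default_rng(seed)
    c0 = voxel_center(voxel_shape)
    library = []
    for sb in sb_targets:
        for st in st_targets:
            amp, grad = operating_point_amplitudes(sb, st, offset=offset,
                                                   sigma=sigma,
                                                   voxel_shape=voxel_shape)
            for _ in range(n_per_cell):
                spec = SpotSpec(
                    amplitude=amp, sigma=tuple(sigma), offset=offset,
                    gradient_amplitude=grad,
                    gradient_direction=random_unit_vector(rng),
                    poisson_noise=True,
                    true_center=tuple(c0 + rng.uniform(-0.5, 0.5, 3)))
                voxel, truth = generate_spot_voxel(
                    spec, voxel_shape, seed=rng.integers(0, 2**31 - 1))
                library.append({"spec": spec, "voxel": voxel, "truth": truth,
                                "sb_target": sb, "st_target": st})
    return library


def generate_labeled_voxels(n_spots: int = 227,
                            n_nonspots: int = 1023,
                            sb_range=(0.2, 1.0),
                            st_range=(1.0, 80.0),
                            offset: float = 100.0,
                            sigma=DEFAULT_SIGMA,
                            seed: int = 0,
                            n_calib: int = 6):
    """Labeled voxel set for classifier training at realistic SNR.

    Spots are drawn across signal:background ``sb_range`` on structured
    backgrounds spanning ``st_range``; non-spots are the same structured
    backgrounds without a spot. Class balance defaults to the ~1:4.5 ratio
    of a typical hand-labeled set. Returns ``(voxels, labels)``.
    """
    rng = np.random.default_rng(seed)
    sbs = np.linspace(*sb_range, n_calib)
    sts = np.linspace(*st_range, n_calib)
    calib = {}
    for sb in sbs:
        for st in sts:
            calib[(sb, st)] = operating_point_amplitudes(
                sb, st, offset=offset, sigma=sigma)
    c0 = voxel_center(VOXEL_SHAPE)
    voxels, labels = [], []
    for i in range(n_spots + n_nonspots):
        is_spot = i < n_spots
        sb = sbs[rng.integers(n_calib)]
        st = sts[rng.integers(n_calib)]
        amp, grad = calib[(sb, st)]
        spec = SpotSpec(
            amplitude=amp if is_spot else 0.0,
            sigma=tuple(sigma), offset=offset,
            gradient_amplitude=grad,
            gradient_direction=random_unit_vector(rng),
            poisson_noise=True,
            true_center=tuple(c0 + rng.uniform(-0.5, 0.5, 3)))
        voxel, _ = generate_spot_voxel(spec, seed=rng.integers(0, 2**31 - 1))
        voxels.append(voxel)
        labels.append(int(is_spot))
    order = rng.permutation(len(voxels))
    return np.stack(voxels)[order], np.asarray(labels)[order]


# ---------------------------------------------------------------------------
# Synthetic movies


@dataclass
class SyntheticMovieTruth:
    """Ground truth accompanying a synthetic movie."""

    nucleus_tracks: pd.DataFrame  # columns: nucleus_id, t, z_um, y_um, x_um
    promoter_traces: np.ndarray   # (n_nuclei, n_timepoints) true spot intensity
    label_movie: np.ndarray       # (T, Z, Y, X) integer labels, stable per nucleus
    pixel_size: tuple = DEFAULT_PIXEL_SIZE

    def to_csv(self, path, sidecar=None, seed=None):
        self.nucleus_tracks.to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"pixel_size": list(self.pixel_size), "seed": seed}, fh)


def square_wave_promoter(period: int = 30, duty: float = 0.2, amplitude: float = 1000.0,
                         phase: int = 0) -> Callable[[int], np.ndarray]:
    """Promoter model: square wave of true integrated spot intensity."""

    def model(n_timepoints: int) -> np.ndarray:
        t = np.arange(n_timepoints)
        on = ((t + phase) % period) < duty * period
        return np.where(on, amplitude, 0.0)

    return model


def simulate_nucleus_tracks(n_nuclei: int, n_timepoints: int, motion_speed: float,
                            volume_um: tuple, nucleus_radius_um: tuple, seed,
                            dt_min: float = 1.0, max_resample: int = 200) -> pd.DataFrame:
    """Straight-line nucleus trajectories at a fixed speed (um/h).

    Positions are sampled so nuclei do not overlap at t=0; directions are
    chosen so the whole path stays inside the volume where possible
    (re-sampled otherwise, with a warning if overlap cannot be avoided).
    """
    rng = np.random.default_rng(seed)
    vol = np.asarray(volume_um, dtype=float)
    rad = np.asarray(nucleus_radius_um, dtype=float)
    step = motion_speed / 60.0 * dt_min  # um per frame
    total = step * (n_timepoints - 1)
    starts, vels = [], []
    for _ in range(n_nuclei):
        for attempt in range(max_resample):
            p0 = rng.uniform(rad, vol - rad)
            d = np.asarray(random_unit_vector(rng))
            p1 = p0 + d * total
            if np.any(p1 < rad) or np.any(p1 > vol - rad):
                continue
            if all(np.linalg.norm(p0 - q) > 2.2 * rad.max() for q in starts):
                break
        else:
            warnings.warn("could not place non-overlapping nucleus; keeping last sample")
        starts.append(p0)
        vels.append(d * step)
    rows = []
    for nid, (p0, v) in enumerate(zip(starts, vels), start=1):
        for t in range(n_timepoints):
            p = p0 + v * t
            rows.append((nid, t, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=["nucleus_id", "t", "z_um", "y_um", "x_um"])


def generate_synthetic_movie(n_nuclei: int = 5,
                             n_timepoints: int = 40,
                             motion_speed: float = 5.0,
                             promoter_model=None,
                             pixel_size=DEFAULT_PIXEL_SIZE,
                             seed: int = 0,
                             volume_shape=(16, 72, 72),
                             nucleus_radius_px=(3.0, 5.0, 5.0),
                             mcp_background: float = 100.0,
                             mcp_heterogeneity: float = 0.2,
                             outside_background: float = 20.0,
                             nuclear_amplitude: float = 400.0,
                             spot_sigma=DEFAULT_SIGMA):
    """Render an MCP + nuclear channel movie with ground truth.

    Nuclei are bright ellipsoids in the nuclear channel; each nucleus gets
    its own MCP background level (lognormal spread ``mcp_heterogeneity``
    around ``mcp_background``). Whenever a nucleus's promoter trace is
    nonzero, a Gaussian spot of that true integrated intensity is rendered
    at a fixed offset inside the nucleus. Both channels carry Poisson noise.

    Returns ``(mcp_movie, nuclear_movie, truth)`` with movies shaped
    (T, Z, Y, X) and ``truth`` a :class:`SyntheticMovieTruth`.
    """
    rng = np.random.default_rng(seed)
    if promoter_model is None:
        promoter_model = square_wave_promoter()
    pix = np.asarray(pixel_size, dtype=float)
    shape = tuple(volume_shape)
    vol_um = np.asarray(shape) * pix
    rad_px = np.asarray(nucleus_radius_px, dtype=float)
    rad_um = rad_px * pix
    # keep nuclei far enough from the borders that the 9x11x11 analysis
    # window around their spot is always extractable
    margin_um = np.maximum(rad_um, (np.asarray(VOXEL_SHAPE) // 2 + 1) * pix)
    tracks = simulate_nucleus_tracks(
        n_nuclei, n_timepoints, motion_speed, vol_um, margin_um,
        seed=rng.integers(0, 2**31 - 1))

    traces = np.stack([
        np.asarray(promoter_model(n_timepoints), dtype=float)
        if not isinstance(promoter_model, (list, tuple))
        else np.asarray(promoter_model[i], dtype=float)
        for i in range(n_nuclei)
    ])
    if traces.shape != (n_nuclei, n_timepoints):
        raise ValueError("promoter traces must have length n_timepoints per nucleus")

    mcp_levels = mcp_background * np.exp(
        rng.normal(0.0, mcp_heterogeneity, size=n_nuclei))
    # spot sits at a fixed sub-nuclear offset so it stays inside the nucleus
    spot_offset_px = rad_px * np.array([0.0, 0.3, 0.0])
    # amplitude per unit integrated intensity over the standard ellipsoid
    unit_integral = true_integrated_intensity(
        SpotSpec(amplitude=1.0, sigma=tuple(spot_sigma), poisson_noise=False))

    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")
    mcp = np.empty((n_timepoints,) + shape, dtype=float)
    nuc = np.empty_like(mcp)
    labels = np.zeros((n_timepoints,) + shape, dtype=np.int32)
    by_t = tracks.set_index("t")
    for t in range(n_timepoints):
        mcp_mean = np.full(shape, outside_background, dtype=float)
        nuc_mean = np.full(shape, outside_background, dtype=float)
        sub = by_t.loc[[t]]
        for row in sub.itertuples():
            nid = int(row.nucleus_id)
            c_px = np.array([row.z_um, row.y_um, row.x_um]) / pix
            r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, c_px, rad_px))
            inside = r2 <= 1.0
            labels[t][inside] = nid
            nuc_mean[inside] = nuclear_amplitude
            mcp_mean[inside] = mcp_levels[nid - 1]
            intensity = traces[nid - 1, t]
            if intensity > 0:
                amp = intensity / unit_integral
                mcp_mean += gaussian_field(shape, c_px + spot_offset_px,
                                           spot_sigma, amp)
        mcp[t] = rng.poisson(mcp_mean)
        nuc[t] = rng.poisson(nuc_mean)

    truth = SyntheticMovieTruth(nucleus_tracks=tracks, promoter_traces=traces,
                                label_movie=labels, pixel_size=tuple(pix))
    return mcp, nuc, truth


def label_voxels_from_movie(mcp_movie: np.ndarray, truth: SyntheticMovieTruth,
                            n_nonspots_per_frame: int = 8, seed: int = 0,
                            spot_offset_frac=(0.0, 0.3, 0.0),
                            nucleus_radius_px=(3.0, 5.0, 5.0)):
    """Generator-backed labeling tool: labeled voxels from a synthetic movie.

    Positive voxels are extracted at the true spot locations (frames where
    the promoter trace is nonzero); negatives are hard negatives — detected
    candidate locations away from any true spot (i.e. exactly the false
    candidates the classifier must reject), topped up with random in-volume
    positions if detection yields too few. Replaces the hand-labeling step
    used on real data. Returns ``(voxels, labels)``.
    """
    from .detection import (detect_candidate_spots, dog_filter_slicewise,
                            dog_threshold_from_quantile, extract_voxel)

    rng = np.random.default_rng(seed)
    pix = np.asarray(truth.pixel_size)
    rad_px = np.asarray(nucleus_radius_px, dtype=float)
    offset_px = rad_px * np.asarray(spot_offset_frac)
    voxels, labels = [], []
    by_t = truth.nucleus_tracks.set_index("t")
    n_t = mcp_movie.shape[0]
    shape = np.asarray(mcp_movie.shape[1:])
    half = np.asarray(VOXEL_SHAPE) // 2
    spot_centers = {t: [] for t in range(n_t)}
    for t in range(n_t):
        for row in by_t.loc[[t]].itertuples():
            nid = int(row.nucleus_id)
            if truth.promoter_traces[nid - 1, t] <= 0:
                continue
            c_px = np.array([row.z_um, row.y_um, row.x_um]) / pix + offset_px
            spot_centers[t].append(c_px)
            try:
                voxels.append(extract_voxel(mcp_movie[t], c_px))
                labels.append(1)
            except IndexError:
                continue
    for t in range(n_t):
        vol = np.asarray(mcp_movie[t], dtype=float)
        dog = dog_filter_slicewise(vol)
        thr = dog_threshold_from_quantile(dog, 0.999)
        cands = detect_candidate_spots(vol, dog_threshold=thr, t=t)
        taken = 0
        for row in cands.itertuples():
            if taken >= n_nonspots_per_frame:
                break
            c = np.array([row.z, row.y, row.x])
            if any(np.linalg.norm(c - s) < 6 for s in spot_centers[t]):
                continue
            try:
                voxels.append(extract_voxel(vol, c))
            except IndexError:
                continue
            labels.append(0)
            taken += 1
        while taken < n_nonspots_per_frame:
            c = rng.uniform(half, shape - half - 1)
            if any(np.linalg.norm(c - s) < 6 for s in spot_centers[t]):
                continue
            voxels.append(extract_voxel(vol, c))
            labels.append(0)
            taken += 1
    return np.stack(voxels), np.asarray(labels)
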