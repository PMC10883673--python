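"""Quantification of rendered comets: line scans, peak EB1 position,
tip:lattice ratio, Tip Specificity, tip standard deviation, split-comet
intensity, growth statistics, sweep scoring and coverage fraction.

Conventions
-----------
Raw line scans are in image coordinates (nm, increasing toward the plus
end).  Registered/averaged profiles are in *relative* coordinates: the
microtubule end — where the red channel crosses halfway between its maximum
and minimum — is position 0, and positions increase toward the minus end,
so the EB1 peak of a tip-tracking comet sits at a positive position a
little over 100 nm "distal of the tip" (inside the microtubule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.special import erfc
from skimage.filters import threshold_otsu

from .imaging import Image, Kymograph
from .lattice import DIMER_LENGTH_NM


class AnalysisError(RuntimeError):
    """A measurement could not be made on the given input."""


class FitError(AnalysisError):
    """A curve fit failed to converge or produced an invalid parameter."""


@dataclass
class LineScanProfile:
    """Axial intensity profile of one (or several averaged) microtubules."""

    positions: np.ndarray  # nm, strictly increasing
    red: np.ndarray
    green: np.ndarray
    n_averaged: int = 1
    registered: bool = False
    flagged: bool = False  # averaged from fewer profiles than recommended

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.positions) > 0):
            raise AnalysisError("profile positions must be strictly increasing")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class TipSpecificityMeasurement:
    i_tip: float
    i_lattice: float
    i_background: float

    @property
    def s(self) -> float:
        """Tip Specificity: background-subtracted tip over lattice intensity."""
        denom = self.i_lattice - self.i_background
        if denom == 0:
            raise AnalysisError("undefined Tip Specificity: I_lattice == I_background")
        return (self.i_tip - self.i_background) / denom


@dataclass
class TipFit:
    mu: float  # mean tip position, nm (image coordinates)
    sigma_tip: float  # nm; includes the PSF and the protofilament-length spread
    amplitude: float
    baseline: float
    residual: float  # RMS of fit residuals


@dataclass
class CometIntensityPair:
    summed_single: float
    summed_split: float
    summed_background: float

    @property
    def fold_change(self) -> float:
        denom = self.summed_single - self.summed_background
        if denom <= 0:
            raise AnalysisError("single-comet intensity does not exceed background")
        return (self.summed_split - self.summed_background) / denom


# --------------------------------------------------------------------- #
# line scans


def line_scan(image: Image, band_px: int = 5) -> LineScanProfile:
    """Axial profile averaged over a transverse band about the image axis."""
    h = image.red.shape[0]
    row = h // 2
    lo, hi = max(0, row - band_px // 2), min(h, row + band_px // 2 + 1)
    return LineScanProfile(
        positions=image.x_nm(),
        red=image.red[lo:hi].mean(axis=0),
        green=image.green[lo:hi].mean(axis=0),
    )


def register_and_average(profiles: list[LineScanProfile]) -> LineScanProfile:
    """Align profiles at their EB1 peak, average, and zero at the red half-max.

    Output positions increase toward the minus end with the microtubule end
    at 0 (see module docstring).  Fewer than 5 input profiles yields a
    flagged result with a warning.
    """
    if not profiles:
        raise AnalysisError("no profiles to average")
    flagged = len(profiles) < 5
    if flagged:
        warnings.warn(
            f"averaging only {len(profiles)} profiles (< 5); result flagged",
            stacklevel=2,
        )
    dx = profiles[0].spacing
    if any(abs(p.spacing - dx) > 1e-9 for p in profiles):
        raise AnalysisError("profiles have mismatched sampling")
    # per-profile EB1 peak, searched near the microtubule end so that a dim
    # comet is not out-registered by a noise maximum elsewhere
    peaks = []
    for p in profiles:
        half = 0.5 * (p.red.max() + p.red.min())
        above = np.nonzero(p.red >= half)[0]
        if above.size == 0:
            raise AnalysisError("profile has no microtubule")
        end = above[-1]
        lo = max(0, end - int(1024 / dx))
        hi = min(len(p.green), end + int(512 / dx) + 1)
        peaks.append(lo + int(np.argmax(p.green[lo:hi])))
    lo = -min(peaks)
    hi = min(len(p.positions) - k for p, k in zip(profiles, peaks))
    if hi <= lo:
        raise AnalysisError("profiles do not overlap after registration")
    rel = np.arange(lo, hi)
    red = np.mean([p.red[k + rel] for p, k in zip(profiles, peaks)], axis=0)
    green = np.mean([p.green[k + rel] for p, k in zip(profiles, peaks)], axis=0)
    x = rel * dx  # aligned frame; zero at the common green peak

    # microtubule end: red half-max crossing on the plus-end (distal) side
    half = 0.5 * (red.max() + red.min())
    above = np.nonzero(red >= half)[0]
    if above.size == 0 or above[-1] == len(red) - 1:
        raise AnalysisError("red channel has no half-max crossing")
    k = above[-1]
    frac = (red[k] - half) / (red[k] - red[k + 1])
    x_end = x[k] + frac * dx

    # relative coordinates: 0 at the end, increasing toward the minus end
    positions = (x_end - x)[::-1]
    return LineScanProfile(
        positions=positions,
        red=red[::-1],
        green=green[::-1],
        n_averaged=len(profiles),
        registered=True,
        flagged=flagged,
    )


def _refine_peak(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Sub-sample peak position by parabolic interpolation through 3 points."""
    if k == 0 or k == len(y) - 1:
        return float(x[k])
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom == 0:
        return float(x[k])
    delta = 0.5 * (y[k - 1] - y[k + 1]) / denom
    return float(x[k] + delta * (x[1] - x[0]))


def peak_eb1_position(profile: LineScanProfile, window_nm: float = 1000.0) -> float:
    """Signed distance from the microtubule end to the EB1 intensity peak, nm.

    Positive values lie toward the minus end (the comet peak sits distal of
    the tip, inside the microtubule).  Requires a registered profile.
    """
    if not profile.registered:
        raise AnalysisError("peak_eb1_position needs a registered profile")
    sel = np.abs(profile.positions) <= window_nm
    if not sel.any() or np.ptp(profile.green[sel]) == 0:
        raise AnalysisError("green profile is flat; peak undefined")
    idx = np.nonzero(sel)[0]
    k = idx[int(np.argmax(profile.green[sel]))]
    return _refine_peak(profile.positions, profile.green, k)


def tip_lattice_ratio(
    profile: LineScanProfile,
    tip_window_nm: float = 512.0,
    lattice_window_nm: tuple[float, float] = (768.0, 1024.0),
) -> float:
    """Peak EB1 intensity at the tip over the median EB1 lattice intensity.

    The lattice level is the median green intensity 768-1024 nm distal of
    the microtubule end; the tip level is the green maximum within
    +-``tip_window_nm`` of the end.
    """
    if not profile.registered:
        raise AnalysisError("tip_lattice_ratio needs a registered profile")
    if profile.positions[-1] < lattice_window_nm[1]:
        raise AnalysisError("profile does not extend 1024 nm behind the end")
    tip_sel = np.abs(profile.positions) <= tip_window_nm
    lat_sel = (profile.positions >= lattice_window_nm[0]) & (
        profile.positions <= lattice_window_nm[1]
    )
    lattice = float(np.median(profile.green[lat_sel]))
    if lattice == 0:
        raise AnalysisError("zero lattice intensity")
    return float(profile.green[tip_sel].max() / lattice)


# --------------------------------------------------------------------- #
# Tip Specificity


def tip_specificity(
    image: Image,
    tip_point: tuple[int, int] | None = None,
    lattice_point: tuple[int, int] | None = None,
    background_point: tuple[int, int] | None = None,
    box_px: int = 4,
    lattice_offset_nm: float = 1000.0,
    background_offset_px: int = 5,
) -> TipSpecificityMeasurement:
    """Tip Specificity S from summed 4x4-pixel boxes.

    ``S = (I_tip - I_background) / (I_lattice - I_background)``; S = 1 means
    the tip is no brighter than the lattice (no tip tracking).  Points are
    ``(row, col)``; when omitted, the tip box is centered on the brightest
    green pixel, the lattice box a fixed axial offset toward the minus end,
    and the background box a fixed transverse offset from the tip.
    """
    green = image.green
    if tip_point is None:
        # brightest green pixel near the growing end (the stabilized GTP
        # seed also binds EB1 and may outshine the comet globally)
        prof = line_scan(image)
        half = 0.5 * (prof.red.max() + prof.red.min())
        above = np.nonzero(prof.red >= half)[0]
        if above.size == 0:
            raise AnalysisError("no microtubule end in red channel")
        end_col = int(above[-1])
        w = int(round(512.0 / image.pixel_size_nm))
        lo = max(0, end_col - w)
        hi = min(green.shape[1], end_col + w + 1)
        sub = green[:, lo:hi]
        r0, c0 = np.unravel_index(int(np.argmax(sub)), sub.shape)
        tip_point = (int(r0), int(c0) + lo)
    r0, c0 = tip_point
    if lattice_point is None:
        lattice_point = (r0, c0 - int(round(lattice_offset_nm / image.pixel_size_nm)))
    if background_point is None:
        row_bg = r0 + background_offset_px
        if row_bg + box_px // 2 >= green.shape[0]:
            row_bg = r0 - background_offset_px
        background_point = (row_bg, c0)

    def box_sum(pt):
        r, c = pt
        lo_r, hi_r = r - box_px // 2, r - box_px // 2 + box_px
        lo_c, hi_c = c - box_px // 2, c - box_px // 2 + box_px
        if lo_r < 0 or lo_c < 0 or hi_r > green.shape[0] or hi_c > green.shape[1]:
            raise AnalysisError(f"measurement box at {pt} falls outside the image")
        return float(green[lo_r:hi_r, lo_c:hi_c].sum())

    meas = TipSpecificityMeasurement(
        i_tip=box_sum(tip_point),
        i_lattice=box_sum(lattice_point),
        i_background=box_sum(background_point),
    )
    if meas.i_lattice == meas.i_background:
        raise AnalysisError("undefined Tip Specificity: I_lattice == I_background")
    return meas


# --------------------------------------------------------------------- #
# tip standard deviation (Gaussian survival fit)


def _erfc_model(x, a, mu, sigma, b):
    return a * 0.5 * erfc((x - mu) / (sigma * np.sqrt(2.0))) + b


def tip_standard_deviation(
    source: LineScanProfile | Image,
    fit_halfwidth_nm: float = 1200.0,
    band_px: int = 5,
) -> TipFit:
    """Fit the red channel's end to a Gaussian survival (erfc) curve.

    The fitted sigma is the tip standard deviation: the convolution of the
    protofilament-length spread with the point spread function, so a blunt
    tip recovers the PSF sigma alone.  Works on a raw line scan (image
    coordinates) or directly on an image.
    """
    if isinstance(source, Image):
        source = line_scan(source, band_px=band_px)
    x = source.positions
    red = source.red
    if source.registered:
        # registered profiles run minus-end-ward; flip to image orientation
        x, red = -x[::-1], red[::-1]
    if red.max() <= red.min():
        raise FitError("red profile has no contrast; no microtubule end")
    half = 0.5 * (red.max() + red.min())
    above = np.nonzero(red >= half)[0]
    if above.size == 0:
        raise FitError("no microtubule end in profile")
    mu0 = float(x[above[-1]])
    sel = (x >= mu0 - fit_halfwidth_nm) & (x <= mu0 + fit_halfwidth_nm)
    if sel.sum() < 8:
        raise FitError("too few samples around the end to fit")
    p0 = (float(red.max() - red.min()), mu0, 150.0, float(red.min()))
    try:
        popt, _ = curve_fit(
            _erfc_model,
            x[sel],
            red[sel],
            p0=p0,
            bounds=([0, x.min(), 10.0, -np.inf], [np.inf, x.max(), 2000.0, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"erfc fit did not converge: {exc}") from exc
    a, mu, sigma, b = popt
    resid = float(np.sqrt(np.mean((_erfc_model(x[sel], *popt) - red[sel]) ** 2)))
    if sigma <= 0:
        raise FitError("nonpositive fitted sigma")
    return TipFit(mu=float(mu), sigma_tip=float(sigma), amplitude=float(a),
                  baseline=float(b), residual=resid)


# --------------------------------------------------------------------- #
# comets


def detect_comets(
    profile: LineScanProfile,
    min_separation_nm: float = 320.0,
    prominence_factor: float = 0.25,
) -> list[int]:
    """Indices of distinct EB1 comet peaks in a raw profile.

    Peaks must be separated by at least ``min_separation_nm`` and rise above
    the profile's low-level background by ``prominence_factor`` times the
    global peak-to-background contrast.
    """
    g = profile.green
    bg = float(np.percentile(g, 20))
    contrast = float(g.max() - bg)
    if contrast <= 0:
        return []
    distance = max(1, int(round(min_separation_nm / profile.spacing)))
    peaks, _ = find_peaks(g, distance=distance, prominence=prominence_factor * contrast)
    return [int(k) for k in peaks]


def comet_region(
    frames: list[Image],
    band_frac: float = 0.1,
    pad_nm: float = 260.0,
) -> tuple[int, int]:
    """Smallest column range encapsulating every comet in all given frames.

    A comet's extent is where the green profile exceeds background plus
    ``band_frac`` of the peak contrast; the union over frames is padded by
    ``pad_nm`` (about 2 PSF sigma).
    """
    lo, hi = np.inf, -np.inf
    for f in frames:
        prof = line_scan(f)
        g = prof.green
        bg = float(np.percentile(g, 20))
        peaks = detect_comets(prof)
        if not peaks:
            raise AnalysisError("no comet found in frame")
        thr = bg + band_frac * (g.max() - bg)
        for k in peaks:
            a = k
            while a > 0 and g[a] > thr:
                a -= 1
            b = k
            while b < len(g) - 1 and g[b] > thr:
                b += 1
            lo = min(lo, a)
            hi = max(hi, b)
    pad = int(round(pad_nm / frames[0].pixel_size_nm))
    lo = int(lo) - pad
    hi = int(hi) + pad
    if lo < 0 or hi >= frames[0].shape[1]:
        raise AnalysisError("comet region clipped by the frame boundary")
    return lo, hi


def split_comet_fold_change(
    single_frame: Image,
    split_frame: Image,
    background_frame: Image,
    region: tuple[int, int] | None = None,
) -> CometIntensityPair:
    """Summed, background-subtracted green intensity: split vs single comet.

    The same region — the smallest x-range encapsulating all comets in both
    comet frames — is summed in all three frames; the background frame
    (seed only, no dynamic microtubule) is subtracted from both.
    """
    for f in (split_frame, background_frame):
        if f.shape != single_frame.shape:
            raise AnalysisError("frames have mismatched geometry")
    if region is None:
        region = comet_region([single_frame, split_frame])
    lo, hi = region
    if lo < 0 or hi >= single_frame.shape[1]:
        raise AnalysisError("comet region clipped by the frame boundary")
    return CometIntensityPair(
        summed_single=float(single_frame.green[:, lo : hi + 1].sum()),
        summed_split=float(split_frame.green[:, lo : hi + 1].sum()),
        summed_background=float(background_frame.green[:, lo : hi + 1].sum()),
    )


# --------------------------------------------------------------------- #
# growth statistics


def comet_length(profile: LineScanProfile) -> float:
    """Distance from the EB1 peak to its 1/e decay toward the minus end, nm.

    Background is the median lattice level 768-1024 nm behind the end.
    """
    if not profile.registered:
        raise AnalysisError("comet_length needs a registered profile")
    peak_pos = peak_eb1_position(profile)
    k0 = int(np.argmin(np.abs(profile.positions - peak_pos)))
    lat_sel = (profile.positions >= 768.0) & (profile.positions <= 1024.0)
    bg = float(np.median(profile.green[lat_sel])) if lat_sel.any() else float(
        profile.green.min()
    )
    thresh = bg + (profile.green[k0] - bg) / np.e
    for k in range(k0, len(profile.positions)):
        if profile.green[k] <= thresh:
            return float(profile.positions[k] - peak_pos)
    raise AnalysisError("green profile never decays to the 1/e level")


def growth_stats(
    source, profile: LineScanProfile | None = None, min_growth_nm: float = 1000.0
) -> dict:
    """Growth rate, time to catastrophe, and comet length.

    ``source`` is a :class:`ebtip.engine.Trajectory` (rate from the mean
    protofilament length series up to the first catastrophe) or a
    :class:`Kymograph` (rate from the advance of the red half-max edge).
    The catastrophe time is measured from growth onset at the seed; if no
    catastrophe occurred it is reported as NaN with ``censored=True``.
    Comet length requires a registered ``profile``.
    """
    out: dict = {}
    if isinstance(source, Kymograph):
        edges = []
        for row in source.red:
            half = 0.5 * (row.max() + row.min())
            above = np.nonzero(row >= half)[0]
            edges.append(source.origin_nm + (above[-1] if above.size else 0)
                         * source.pixel_size_nm)
        t = source.times_s
        out["growth_rate_nm_s"] = float(np.polyfit(t, edges, 1)[0])
        out["time_to_catastrophe_s"] = float("nan")
        out["censored"] = True
    else:
        traj = source
        cats = traj.catastrophe_times(min_growth_nm=min_growth_nm)
        t_end = cats[0] if len(cats) else traj.times[-1]
        sel = traj.times <= t_end
        if sel.sum() < 3:
            raise AnalysisError("trajectory too short for a growth rate")
        mean_nm = traj.mean_length_nm()
        out["growth_rate_nm_s"] = float(
            np.polyfit(traj.times[sel], mean_nm[sel], 1)[0]
        )
        out["time_to_catastrophe_s"] = float(cats[0]) if len(cats) else float("nan")
        out["censored"] = not len(cats)
    if profile is not None:
        out["comet_length_nm"] = comet_length(profile)
    return out


# --------------------------------------------------------------------- #
# sweep scoring and coverage


def profile_error(
    sim_profile: LineScanProfile, reference_profile: LineScanProfile,
    channel: str = "green",
) -> float:
    """Sum of absolute differences over the profiles' common support.

    The reference is linearly resampled onto the simulated profile's grid.
    """
    lo = max(sim_profile.positions[0], reference_profile.positions[0])
    hi = min(sim_profile.positions[-1], reference_profile.positions[-1])
    if hi <= lo:
        raise AnalysisError("profiles have disjoint supports")
    sel = (sim_profile.positions >= lo) & (sim_profile.positions <= hi)
    x = sim_profile.positions[sel]
    ref = np.interp(x, reference_profile.positions, getattr(reference_profile, channel))
    return float(np.abs(getattr(sim_profile, channel)[sel] - ref).sum())


def coverage_fraction(
    red_image: np.ndarray | Image,
    green_image: np.ndarray | Image,
    green_threshold: float,
) -> float:
    """Fraction of the (Otsu-thresholded) microtubule area covered by green.

    Mirrors the damaged-microtubule binding assay: the red channel defines
    the microtubule mask automatically; the green channel is binarized at
    the user-supplied threshold; returns green-and-mask area over mask area.
    """
    red = red_image.red if isinstance(red_image, Image) else np.asarray(red_image)
    green = (
        green_image.green if isinstance(green_image, Image) else np.asarray(green_image)
    )
    if red.shape != green.shape:
        raise AnalysisError("channel shapes differ")
    mask = red > threshold_otsu(red)
    if not mask.any():
        raise AnalysisError("empty microtubule mask")
    return float((green > green_threshold)[mask].mean())
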