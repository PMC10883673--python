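"""Model-convolution rendering of simulation snapshots.

A snapshot is turned into a two-channel fluorescence image the same way the
corresponding microscope image would form: a random 15% of tubulin dimers
carry a red fluorophore (labels are drawn once per run, so label identity
persists across frames), every bound EB1 carries a green fluorophore, point
sources are deposited at their physical positions, each channel is convolved
with an isotropic 2D Gaussian point-spread function, and uniform random
noise is added last.  The PSF kernel is normalized to unit sum, so the
pre-noise summed intensity of a channel equals ``photons_per_fluorophore``
times the number of fluorophores.

The microtubule axis lies along image x; the physical origin (x = 0) is the
seed minus-end.  All 13 protofilaments are deposited on the axis row: the
25 nm tube diameter is far below the ~130 nm PSF width, so the transverse
structure is unresolvable anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .lattice import DIMER_LENGTH_NM


@dataclass
class RenderSettings:
    """Imaging parameters for model convolution."""

    label_fraction: float = 0.15  # fraction of dimers carrying a red fluorophore
    psf_sigma_nm: float = 130.0  # typical 1.49-NA TIRF at ~510 nm emission
    pixel_size_nm: float = 64.0  # camera pixel (64 or 160 nm)
    photons_per_fluorophore: float = 100.0  # integrated signal per fluorophore
    #: uniform noise amplitude; None = 10% of a single fluorophore's peak
    noise_amplitude: float | None = None
    margin_nm: float = 1600.0  # blank margin on both sides of the lattice
    image_height_px: int = 25
    frame_interval_steps: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be within [0, 1]")
        if self.pixel_size_nm <= 0 or self.psf_sigma_nm <= 0:
            raise ValueError("pixel_size_nm and psf_sigma_nm must be > 0")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    def default_noise_amplitude(self) -> float:
        # peak pixel value of one convolved fluorophore
        peak = self.photons_per_fluorophore / (2.0 * np.pi * self.psf_sigma_px**2)
        return 0.1 * peak

    def resolved_noise_amplitude(self) -> float:
        return (
            self.default_noise_amplitude()
            if self.noise_amplitude is None
            else self.noise_amplitude
        )


@dataclass
class Image:
    """Two-channel rendered frame (red = microtubule, green = EB1)."""

    red: np.ndarray
    green: np.ndarray
    pixel_size_nm: float
    origin_nm: float  # physical x of the center of pixel column 0
    time_s: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def x_nm(self) -> np.ndarray:
        """Physical x coordinate of each pixel column center, nm."""
        return self.origin_nm + np.arange(self.red.shape[1]) * self.pixel_size_nm

    def save_tiff(self, path) -> None:
        stack = np.stack([self.red, self.green]).astype(np.float32)
        tifffile.imwrite(
            path,
            stack,
            metadata={
                "axes": "CYX",
                "pixel_size_nm": self.pixel_size_nm,
                "origin_nm": self.origin_nm,
                "time_s": self.time_s,
            },
        )

    @classmethod
    def load_tiff(cls, path) -> "Image":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0]
        return cls(
            red=stack[0].astype(np.float64),
            green=stack[1].astype(np.float64),
            pixel_size_nm=float(meta["pixel_size_nm"]),
            origin_nm=float(meta["origin_nm"]),
            time_s=float(meta.get("time_s", 0.0)),
        )


@dataclass
class Kymograph:
    """Time-position intensity map: rows = frames, columns = axial position."""

    red: np.ndarray
    green: np.ndarray
    pixel_size_nm: float
    origin_nm: float
    times_s: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def save_tiff(self, path) -> None:
        stack = np.stack([self.red, self.green]).astype(np.float32)
        tifffile.imwrite(
            path,
            stack,
            metadata={
                "axes": "CYX",
                "pixel_size_nm": self.pixel_size_nm,
                "origin_nm": self.origin_nm,
            },
        )


def draw_labels(
    n_pf: int, capacity: int, label_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Random red-labeling mask over all possible dimer positions (per run)."""
    return rng.random((n_pf, capacity)) < label_fraction


def _deposit(
    acc: np.ndarray, x_nm: np.ndarray, row: int, origin_nm: float,
    pixel_size_nm: float, amplitude: float,
) -> None:
    """Deposit unit point sources with linear interpolation between columns."""
    if x_nm.size == 0:
        return
    px = (x_nm - origin_nm) / pixel_size_nm
    i0 = np.floor(px).astype(int)
    frac = px - i0
    w = acc.shape[1]
    for idx, fr in ((i0, 1.0 - frac), (i0 + 1, frac)):
        ok = (idx >= 0) & (idx < w)
        np.add.at(acc[row], idx[ok], amplitude * fr[ok])


def render_frame(
    snapshot: dict,
    settings: RenderSettings,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
    width_nm: float | None = None,
) -> Image:
    """Model-convolve one snapshot into a two-channel image.

    ``snapshot`` is a :meth:`ebtip.engine.Trajectory.snapshot` dict (or any
    mapping with ``lengths``, ``eb1_j`` and ``time`` entries).  ``labels`` is
    the per-run red-label mask from :func:`draw_labels`; if omitted it is
    drawn from ``rng`` (appropriate only for single-frame use).  ``width_nm``
    fixes the field of view (e.g. for kymographs); by default the frame is
    sized to the lattice plus margins.
    """
    lengths = np.asarray(snapshot["lengths"])
    n_pf = len(lengths)
    max_len_nm = float(lengths.max()) * DIMER_LENGTH_NM
    if width_nm is None:
        width_nm = max_len_nm + 2 * settings.margin_nm
    origin = -settings.margin_nm
    n_cols = int(np.ceil(width_nm / settings.pixel_size_nm))
    h = settings.image_height_px
    row = h // 2
    red = np.zeros((h, n_cols))
    green = np.zeros((h, n_cols))

    if labels is None:
        labels = draw_labels(n_pf, int(lengths.max()) + 1, settings.label_fraction, rng)
    for p in range(n_pf):
        js = np.nonzero(labels[p, : int(lengths[p])])[0]
        x = (js + 0.5) * DIMER_LENGTH_NM
        _deposit(red, x, row, origin, settings.pixel_size_nm,
                 settings.photons_per_fluorophore)

    eb1_j = np.asarray(snapshot.get("eb1_j", ()), dtype=float)
    # an EB1 pocket spans dimers j and j+1; place it on their boundary
    x_green = (eb1_j + 1.0) * DIMER_LENGTH_NM
    _deposit(green, x_green, row, origin, settings.pixel_size_nm,
             settings.photons_per_fluorophore)

    sig = settings.psf_sigma_px
    red = gaussian_filter(red, sigma=sig, mode="constant")
    green = gaussian_filter(green, sigma=sig, mode="constant")

    amp = settings.resolved_noise_amplitude()
    if amp > 0:
        red = red + rng.uniform(0.0, amp, red.shape)
        green = green + rng.uniform(0.0, amp, green.shape)
    return Image(
        red=red,
        green=green,
        pixel_size_nm=settings.pixel_size_nm,
        origin_nm=origin,
        time_s=float(snapshot.get("time", 0.0)),
    )


def render_trajectory(
    trajectory,
    settings: RenderSettings,
    rng: np.random.Generator,
    snapshot_indices=None,
    width_nm: float | None = None,
) -> list[Image]:
    """Render frames for a trajectory with one persistent red-label mask."""
    labels = draw_labels(
        trajectory.lengths.shape[1],
        trajectory.config.capacity,
        settings.label_fraction,
        rng,
    )
    if snapshot_indices is None:
        snapshot_indices = range(trajectory.n_snapshots)
    if width_nm is None:
        width_nm = (
            float(trajectory.lengths.max()) * DIMER_LENGTH_NM + 2 * settings.margin_nm
        )
    return [
        render_frame(trajectory.snapshot(i), settings, rng, labels=labels,
                     width_nm=width_nm)
        for i in snapshot_indices
    ]


def make_kymograph(
    frames: list[Image], band_px: int = 5, reduce: str = "mean"
) -> Kymograph:
    """Collapse frames into a kymograph over a transverse band about the axis.

    Each row is one frame's axial intensity profile (mean or max over the
    band); frame order is preserved.
    """
    if len(frames) < 2:
        raise ValueError("a kymograph needs at least 2 frames")
    geo = (frames[0].shape, frames[0].pixel_size_nm, frames[0].origin_nm)
    for f in frames[1:]:
        if (f.shape, f.pixel_size_nm, f.origin_nm) != geo:
            raise ValueError("frames have mismatched geometry")
    h = frames[0].shape[0]
    row = h // 2
    lo, hi = max(0, row - band_px // 2), min(h, row + band_px // 2 + 1)
    op = np.max if reduce == "max" else np.mean
    red = np.stack([op(f.red[lo:hi], axis=0) for f in frames])
    green = np.stack([op(f.green[lo:hi], axis=0) for f in frames])
    return Kymograph(
        red=red,
        green=green,
        pixel_size_nm=frames[0].pixel_size_nm,
        origin_nm=frames[0].origin_nm,
        times_s=np.array([f.time_s for f in frames]),
    )
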