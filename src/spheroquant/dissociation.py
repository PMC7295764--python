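"""Spheroid dissociation quantification.

The spheroid is sized from its azimuthally averaged radial intensity
profile: for each frame the mean pixel intensity in annuli around the
(fixed, frame-0) spheroid center is fitted to a Gaussian
``A * exp(-r^2 / (2 sigma^2)) + B`` and the fitted sigma is the spheroid
radius.  The normalized size sigma(t) / sigma(0) tracks dissociation over
the movie.  Dissociated singles are counted as connected components
beyond a cutoff radius with single-cell areas.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .io import ImageSeries

__all__ = [
    "RadialProfile",
    "GaussianFit",
    "SizeSeries",
    "find_spheroid_center",
    "radial_density_profile",
    "fit_gaussian_sigma",
    "size_series",
    "count_dissociated_singles",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RadialProfile:
    """Azimuthally averaged intensity vs radial distance from the center."""

    radii: np.ndarray        # µm, bin centers, strictly increasing
    density: np.ndarray      # mean intensity per annulus
    populated: np.ndarray    # bool; False where the annulus holds no pixel
    frame_index: int
    center: tuple[float, float]  # µm (x, y)
    pixel_counts: np.ndarray | None = None  # pixels per annulus

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")


@dataclasses.dataclass
class GaussianFit:
    amplitude: float
    sigma: float
    baseline: float
    residual_norm: float
    converged: bool

    def require_converged(self) -> "GaussianFit":
        if not self.converged:
            raise RuntimeError("Gaussian fit did not converge; sigma unusable")
        return self


@dataclasses.dataclass
class SizeSeries:
    """Per-frame fitted sigma and its value normalized to frame 0."""

    sigma: np.ndarray             # µm; NaN where the fit failed
    normalized_size: np.ndarray   # sigma(t) / sigma(0)
    channel: str = ""

    @property
    def final_normalized_size(self) -> float:
        valid = self.normalized_size[~np.isnan(self.normalized_size)]
        if valid.size == 0:
            raise ValueError("no converged frames")
        return float(valid[-1])


def _dark_background(frame: np.ndarray, fraction: float = 0.05) -> float:
    """Background level: median of the darkest `fraction` of pixels."""
    flat = np.sort(frame, axis=None)
    k = max(1, int(fraction * flat.size))
    return float(np.median(flat[:k]))


def find_spheroid_center(
    series: ImageSeries,
    channels: list[str] | None = None,
    frame: int = 0,
) -> tuple[float, float]:
    """Intensity-weighted centroid of the background-subtracted frame.

    Channels are summed before the centroid; the center is computed once
    (frame 0 by default) and held fixed for all frames, anchoring the
    radial coordinate to the undissociated spheroid.
    Returns (x, y) in µm.
    """
    if series.pixels.ndim == 4:
        names = channels or list(series.channel_names)
        img = sum(series.channel(n)[frame] for n in names)
    else:
        img = series.pixels[frame]
    img = np.asarray(img, dtype=float)
    img = np.clip(img - _dark_background(img), 0, None)
    total = img.sum()
    if total <= 0:
        raise ValueError("frame has no signal above background")
    rows, cols = img.shape
    r_idx = np.arange(rows)
    c_idx = np.arange(cols)
    cy = float((img.sum(axis=1) * r_idx).sum() / total)
    cx = float((img.sum(axis=0) * c_idx).sum() / total)
    return (cx * series.pixel_size, cy * series.pixel_size)


def radial_density_profile(
    frame: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    bin_width: float | None = None,
    frame_index: int = 0,
) -> RadialProfile:
    """Azimuthal mean intensity in annuli [r, r + dr) around the center.

    Density in bin k is the mean intensity over pixels whose center falls
    at distance [k dr, (k+1) dr) from `center`.  Empty annuli are flagged,
    never interpolated.  Default bin width is 2 pixels in µm.
    """
    if bin_width is None:
        bin_width = 2 * pixel_size
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    frame = np.asarray(frame, dtype=float)
    rows, cols = frame.shape
    x = (np.arange(cols) + 0.0) * pixel_size  # pixel-center x
    y = (np.arange(rows) + 0.0) * pixel_size
    dx = x[None, :] - center[0]
    dy = y[:, None] - center[1]
    r = np.sqrt(dx * dx + dy * dy)
    idx = np.floor(r / bin_width).astype(np.int64)
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    sums = np.bincount(idx.ravel(), weights=frame.ravel(), minlength=n_bins)
    populated = counts > 0
    density = np.zeros(n_bins)
    density[populated] = sums[populated] / counts[populated]
    radii = (np.arange(n_bins) + 0.5) * bin_width
    return RadialProfile(radii=radii, density=density, populated=populated,
                         frame_index=frame_index, center=tuple(center),
                         pixel_counts=counts)


def _gauss(r: np.ndarray, A: float, sigma: float, B: float) -> np.ndarray:
    return A * np.exp(-(r * r) / (2 * sigma * sigma)) + B


def fit_gaussian_sigma(
    profile: RadialProfile,
    ftol: float = 1e-8,
    max_evals: int = 1000,
) -> GaussianFit:
    """Nonlinear least squares of ``A exp(-r²/(2σ²)) + B`` to the profile.

    Initialization: A from the peak, sigma from the half-max radius, B
    from the tail median.  When the profile carries per-annulus pixel
    counts the fit is weighted by them (the variance of an annulus mean
    scales as 1 / pixel count, so narrow inner annuli, which average few
    pixels over few cells, carry little weight).  Non-convergence is
    flagged, not raised, so callers can drop the frame.
    """
    r = profile.radii[profile.populated]
    d = profile.density[profile.populated]
    if profile.pixel_counts is not None:
        point_sd = 1.0 / np.sqrt(profile.pixel_counts[profile.populated])
    else:
        point_sd = None
    if r.size < 8:
        raise ValueError("need at least 8 populated bins to fit")
    b0 = float(np.median(d[-max(3, d.size // 5):]))
    a0 = float(d.max() - b0)
    if a0 <= 0:
        a0 = max(float(d.max()), 1e-6)
    min_s = profile.radii[1] - profile.radii[0]
    # candidate 1: half-max radius (sharp, clean profiles)
    half = b0 + a0 / 2
    above = np.nonzero(d >= half)[0]
    s_half = float(r[above[-1]] / 1.177) if above.size else float(r[r.size // 4])
    # candidate 2: second moment of the excess mass (robust to a bright
    # spike near the center, which can dwarf a broad low cloud)
    w_area = (profile.pixel_counts[profile.populated]
              if profile.pixel_counts is not None else r)
    mass = np.clip(d - b0, 0, None) * w_area
    s_mom = (float(np.sqrt((mass * r**2).sum() / mass.sum() / 2.0))
             if mass.sum() > 0 else s_half)
    best: GaussianFit | None = None
    for s0 in {max(s_half, min_s), max(s_mom, min_s)}:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _gauss, r, d, p0=(a0, s0, b0), sigma=point_sd,
                    bounds=([0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                    ftol=ftol, xtol=ftol, maxfev=max_evals,
                )
            converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
        except (RuntimeError, ValueError):
            continue
        wres = (d - _gauss(r, *popt))
        if point_sd is not None:
            wres = wres / point_sd
        cand = GaussianFit(amplitude=float(popt[0]), sigma=float(popt[1]),
                           baseline=float(popt[2]),
                           residual_norm=float(np.linalg.norm(wres)),
                           converged=bool(converged))
        if best is None or cand.residual_norm < best.residual_norm:
            best = cand
    if best is None:
        return GaussianFit(np.nan, np.nan, np.nan, np.inf, False)
    return best


def size_series(
    series: ImageSeries,
    channel: str | None = None,
    bin_width: float | None = None,
    center: tuple[float, float] | None = None,
) -> SizeSeries:
    """Fitted sigma per frame, normalized to the frame-0 sigma.

    The center is the frame-0 intensity centroid unless given.  Frames
    whose fit fails carry NaN and are excluded downstream; a failed
    frame-0 fit is an error because it anchors the normalization.
    """
    stack = series.channel(channel)
    if center is None:
        center = find_spheroid_center(series, [channel] if channel else None)
    if bin_width is None:
        bin_width = 2 * series.pixel_size
    # the center is fixed, so the annulus membership of every pixel is
    # computed once and reused across frames
    rows, cols = series.frame_shape
    x = np.arange(cols) * series.pixel_size
    y = np.arange(rows) * series.pixel_size
    r = np.sqrt((x[None, :] - center[0])**2 + (y[:, None] - center[1])**2)
    idx = np.floor(r / bin_width).astype(np.int64).ravel()
    n_bins = int(idx.max()) + 1
    counts = np.bincount(idx, minlength=n_bins)
    populated = counts > 0
    radii = (np.arange(n_bins) + 0.5) * bin_width
    sigmas = np.full(series.n_frames, np.nan)
    for t in range(series.n_frames):
        sums = np.bincount(idx, weights=np.asarray(stack[t], dtype=float).ravel(),
                           minlength=n_bins)
        density = np.zeros(n_bins)
        density[populated] = sums[populated] / counts[populated]
        prof = RadialProfile(radii=radii, density=density, populated=populated,
                             frame_index=t, center=tuple(center),
                             pixel_counts=counts)
        fit = fit_gaussian_sigma(prof)
        if fit.converged:
            sigmas[t] = fit.sigma
        else:
            log.warning("frame %d: Gaussian fit failed; dropped", t)
    if np.isnan(sigmas[0]):
        raise RuntimeError("frame-0 fit failed; no normalization anchor")
    return SizeSeries(sigma=sigmas, normalized_size=sigmas / sigmas[0],
                      channel=channel or "")


def count_dissociated_singles(
    frame: np.ndarray,
    center: tuple[float, float],
    pixel_size: float,
    sigma0: float,
    k: float = 3.0,
    area_bounds: tuple[float, float] | None = None,
    cell_radius: float = 5.0,
) -> int:
    """Count single cells beyond ``k * sigma0`` from the spheroid center.

    Segmentation is Otsu on the background-subtracted frame, restricted
    to the region beyond the core cutoff (the dense core is orders of
    magnitude brighter than a single cell and would otherwise set the
    threshold above single-cell intensities), followed by connected
    components; components qualify when their centroid lies outside the
    core cutoff and their area falls within single-cell bounds (default
    [0.25, 6] x pi * cell_radius², µm²) — large enough to be a cell,
    small enough not to be a cluster.
    """
    frame = np.asarray(frame, dtype=float)
    img = np.clip(frame - _dark_background(frame), 0, None)
    if img.max() <= 0:
        log.warning("empty frame: no segmentable signal")
        return 0
    rows, cols = img.shape
    x = np.arange(cols) * pixel_size
    y = np.arange(rows) * pixel_size
    r = np.hypot(x[None, :] - center[0], y[:, None] - center[1])
    outside = r > k * sigma0
    if not outside.any():
        log.warning("cutoff radius covers the whole field: count 0")
        return 0
    try:
        thr = threshold_otsu(img[outside])
    except ValueError:
        log.warning("degenerate histogram: count 0")
        return 0
    # when no cell lies outside the core, Otsu merely splits the noise;
    # a robust noise floor (6 x MAD of the outside region) prevents that
    out_vals = img[outside]
    mad = np.median(np.abs(out_vals - np.median(out_vals)))
    thr = max(thr, 6.0 * 1.4826 * mad)
    # threshold the whole frame (cells straddling the cutoff keep their
    # full footprint); the distance and area filters decide what counts
    mask = img > thr
    if not mask.any():
        log.warning("empty segmentation: count 0")
        return 0
    if area_bounds is None:
        base = np.pi * cell_radius**2
        area_bounds = (0.25 * base, 6.0 * base)
    labels = label(mask)
    count = 0
    for rp in regionprops(labels):
        area_um2 = rp.area * pixel_size**2
        if not area_bounds[0] <= area_um2 <= area_bounds[1]:
            continue
        cy, cx = rp.centroid
        d = np.hypot(cx * pixel_size - center[0], cy * pixel_size - center[1])
        if d > k * sigma0:
            count += 1
    return count
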