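"""Image-level statistics: segmentation, molecular ratio maps, histogram modes,
orientation dispersion, and fiber density.

These are the quantities reported per image or per sample: the mode values of
chi15/chi31, chi33/chi31 and the pitch angle over all valid pixels, the
standard deviation of the fiber-orientation distribution from a Gaussian fit,
and the fraction of pixels belonging to the collagen-fiber mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidInputError, NoDataError
from .model import PROFILE_PERIOD_DEG
from .pixel_fit import FitMaps, PolarizationStack, _invert_arrays  # noqa: F401

__all__ = [
    "MolecularMaps",
    "SummaryStats",
    "normalize_and_segment",
    "ratio_maps",
    "mode_value",
    "orientation_sd",
    "fiber_density",
    "summarize",
]

#: Default histogram bin widths for mode extraction.
RATIO_BIN_WIDTH = 0.01
ANGLE_BIN_WIDTH = 0.25

#: Percentile of the polarization-mean image used as the normalization
#: reference; slightly below the max to resist isolated hot pixels.
NORMALIZATION_PERCENTILE = 99.9


@dataclass
class MolecularMaps:
    """Per-pixel susceptibility ratios and pitch angle.

    chi15_map = C/A, chi33_map = B/A (the incident-intensity factor cancels);
    theta_map in degrees, defined only where chi33/chi31 - chi15/chi31 + 1 > 0.
    Invalid pixels are NaN and excluded from ``valid_mask``.
    """

    chi15_map: np.ndarray
    chi33_map: np.ndarray
    theta_map: np.ndarray
    valid_mask: np.ndarray
    theta_valid_mask: np.ndarray


@dataclass
class SummaryStats:
    """Scalar per-image summaries."""

    mode_chi15: float
    mode_chi33: float
    mode_theta: float
    orientation_sd: float
    orientation_center: float
    orientation_fit_ok: bool
    fiber_density: float
    foreground_fraction: float
    n_valid: int
    n_foreground: int


def normalize_and_segment(
    stack: PolarizationStack, threshold: float = 0.2
) -> np.ndarray:
    """Foreground mask from the normalized polarization-mean image.

    The mean-over-polarizations image is divided by its 99.9th-percentile
    value, clipped to [0, 1]; pixels at or above ``threshold`` (default 0.2)
    are foreground.  An all-zero image yields an empty mask with a warning.
    """
    if not 0 < threshold <= 1:
        raise InvalidInputError(f"threshold must be in (0, 1], got {threshold}")
    mean_img = stack.mean_image()
    ref = np.percentile(mean_img, NORMALIZATION_PERCENTILE)
    if ref <= 0:
        warnings.warn("all-zero image: empty foreground mask", stacklevel=2)
        return np.zeros(stack.shape, dtype=bool)
    norm = np.clip(mean_img / ref, 0.0, 1.0)
    return norm >= threshold


def ratio_maps(fit: FitMaps) -> MolecularMaps:
    """Susceptibility-ratio and pitch-angle maps from per-pixel amplitudes."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = fit.valid_mask & np.isfinite(fit.A_map) & (fit.A_map > 0)
        A = np.where(ok, fit.A_map, np.nan)
        chi15 = fit.C_map / A
        chi33 = fit.B_map / A
        denom = chi33 - chi15 + 1.0
        theta_ok = ok & np.isfinite(denom) & (denom > 0)
        theta = np.where(
            theta_ok, np.rad2deg(np.arctan(np.sqrt(2.0 / np.where(theta_ok, denom, 1.0)))), np.nan
        )
    return MolecularMaps(
        chi15_map=np.where(ok, chi15, np.nan),
        chi33_map=np.where(ok, chi33, np.nan),
        theta_map=theta,
        valid_mask=ok,
        theta_valid_mask=theta_ok,
    )


def mode_value(map_values: np.ndarray, mask: np.ndarray | None = None,
               bin_width: float = RATIO_BIN_WIDTH) -> float:
    """Center of the highest histogram bin of ``map_values`` over ``mask``.

    Bin edges are anchored at integer multiples of ``bin_width``; ties break
    toward the lower bin.  Requires at least one valid pixel and warns below
    100 (the mode of a sparse histogram is unstable).
    """
    values = np.asarray(map_values, dtype=float)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise NoDataError("mode_value: no valid pixels")
    if values.size < 100:
        warnings.warn(f"mode over only {values.size} pixels is unstable", stacklevel=2)
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    k = int(np.argmax(counts))  # argmax takes the first (lowest) bin on ties
    return float(edges[k] + bin_width / 2)


def _gauss_offset(x, y0, a, mu, sigma):
    return y0 + a * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def circular_sd_axial(alpha_deg: np.ndarray) -> float:
    """Circular standard deviation of axial (180-degree periodic) angles."""
    z = np.exp(2j * np.deg2rad(alpha_deg))
    R = np.abs(np.mean(z))
    R = min(max(R, 1e-12), 1.0 - 1e-15)
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(R)) / 2.0))


def orientation_sd(
    alpha_map: np.ndarray,
    mask: np.ndarray | None = None,
    bin_width: float = 1.0,
) -> tuple[float, float, bool]:
    """Gaussian width of the fiber-orientation distribution.

    Histograms alpha over ``bin_width``-degree bins on the 180-degree periodic
    axis, recenters the axis at the circular mode so the peak sits mid-axis,
    and fits y = y0 + a*exp(-(x-mu)^2 / (2 sigma^2)) by nonlinear least
    squares.  Returns (sigma, center mapped back to [0, 180), fit_ok).  On
    non-convergence or a degenerate histogram, falls back to the circular
    standard deviation with fit_ok = False.
    """
    alpha = np.asarray(alpha_map, dtype=float)
    if mask is not None:
        alpha = alpha[np.asarray(mask, dtype=bool)]
    alpha = alpha[np.isfinite(alpha)] % PROFILE_PERIOD_DEG
    if alpha.size == 0:
        raise NoDataError("orientation_sd: no valid pixels")
    if alpha.size < 100:
        warnings.warn(
            f"orientation fit over only {alpha.size} pixels is unstable", stacklevel=2
        )

    n_bins = int(round(PROFILE_PERIOD_DEG / bin_width))
    counts, edges = np.histogram(alpha, bins=n_bins, range=(0.0, PROFILE_PERIOD_DEG))
    centers = (edges[:-1] + edges[1:]) / 2
    mode_center = centers[int(np.argmax(counts))]

    # Recenter so the peak is mid-axis: offsets in [-90, 90).
    x = (alpha - mode_center + PROFILE_PERIOD_DEG / 2) % PROFILE_PERIOD_DEG - PROFILE_PERIOD_DEG / 2
    counts, edges = np.histogram(
        x, bins=n_bins, range=(-PROFILE_PERIOD_DEG / 2, PROFILE_PERIOD_DEG / 2)
    )
    centers = (edges[:-1] + edges[1:]) / 2

    sigma0 = max(circular_sd_axial(alpha), bin_width)
    y0_0 = float(np.min(counts))
    a0_0 = max(float(np.max(counts) - y0_0), 1.0)
    try:
        if np.ptp(counts) == 0 or np.count_nonzero(counts) < 3:
            raise RuntimeError("degenerate orientation histogram")
        popt, _ = curve_fit(
            _gauss_offset,
            centers,
            counts.astype(float),
            p0=(y0_0, a0_0, 0.0, sigma0),
            maxfev=10000,
        )
        sigma = abs(float(popt[3]))
        mu = float(popt[2])
        if not np.isfinite(sigma) or sigma <= 0 or sigma > PROFILE_PERIOD_DEG:
            raise RuntimeError("implausible Gaussian width")
        center = (mode_center + mu) % PROFILE_PERIOD_DEG
        return sigma, center, True
    except (RuntimeError, ValueError):
        warnings.warn(
            "Gaussian fit failed; falling back to circular standard deviation",
            stacklevel=2,
        )
        return circular_sd_axial(alpha), float(mode_center % PROFILE_PERIOD_DEG), False


def fiber_density(
    intensity_image: np.ndarray, factor: float = 0.45
) -> tuple[float, np.ndarray]:
    """Fiber mask and density from a mean-intensity threshold.

    mask = image >= factor * mean(image); density = masked fraction of all
    image pixels.  An all-zero image gives density 0 with a warning.
    """
    img = np.asarray(intensity_image, dtype=float)
    if img.size == 0:
        raise InvalidInputError("empty intensity image")
    mean = float(img.mean())
    if mean <= 0:
        warnings.warn("all-zero image: fiber density 0", stacklevel=2)
        return 0.0, np.zeros_like(img, dtype=bool)
    mask = img >= factor * mean
    return float(mask.mean()), mask


def summarize(
    stack: PolarizationStack,
    fit: FitMaps,
    mol: MolecularMaps,
    foreground: np.ndarray,
    ratio_bin_width: float = RATIO_BIN_WIDTH,
    angle_bin_width: float = ANGLE_BIN_WIDTH,
    fiber_mask_factor: float = 0.45,
) -> SummaryStats:
    """All per-image summary statistics in one pass."""
    valid = mol.valid_mask & foreground
    theta_valid = mol.theta_valid_mask & foreground
    orient_valid = valid & ~fit.isotropic_mask
    density, _ = fiber_density(stack.mean_image(), factor=fiber_mask_factor)
    sd, center, fit_ok = orientation_sd(fit.alpha_map, orient_valid)
    return SummaryStats(
        mode_chi15=mode_value(mol.chi15_map, valid, ratio_bin_width),
        mode_chi33=mode_value(mol.chi33_map, valid, ratio_bin_width),
        mode_theta=mode_value(mol.theta_map, theta_valid, angle_bin_width),
        orientation_sd=sd,
        orientation_center=center,
        orientation_fit_ok=fit_ok,
        fiber_density=density,
        foreground_fraction=float(foreground.mean()),
        n_valid=int(valid.sum()),
        n_foreground=int(foreground.sum()),
    )
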