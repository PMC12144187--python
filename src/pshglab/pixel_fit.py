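"""Per-pixel estimation of PSHG model parameters from polarization stacks.

The measured per-pixel profile is band-limited (harmonics 0, 2phi, 4phi only),
so for P >= 5 equally spaced polarization angles covering [0, 180) the five
Fourier coefficients are recovered exactly by discrete means:

    a0 = Mean(I(phi)),  an = 2*Mean(cos(n phi) I(phi)),  bn = 2*Mean(sin(n phi) I(phi))

For unequal angle grids the module falls back to linear least squares on the
five basis functions.  The coefficients are then inverted algebraically back
to (alpha, A, B, C):

    alpha = atan2(b2, a2) / 2        (branch convention B >= A, see below)
    c2 = hypot(a2, b2)
    c4 = a4 cos(4 alpha) + b4 sin(4 alpha)      (signed projection)
    B = sqrt(a0 + c4 + c2),  A = sqrt(a0 + c4 - c2)
    C = sqrt(max(0, (B - A)^2 / 4 - 2 c4))

The 2phi harmonic determines alpha only modulo 90 degrees jointly with the
sign of c2; the module resolves the ambiguity with the convention c2 >= 0,
i.e. B >= A (chi33 >= chi31), which matches every collagen measurement this
pipeline targets.  The two branches produce the identical amplitude pair
{A, B} (a0 + c4 +/- |c2| = ((S +/- |D|)/2)^2), so the convention fixes only
which amplitude is labeled B and the corresponding alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateGridError,
    InsufficientSamplingError,
    InvalidInputError,
)
from .model import PROFILE_PERIOD_DEG, FourierCoeffs, TensorParams

__all__ = [
    "PolarizationStack",
    "FitMaps",
    "InversionResult",
    "estimate_coefficients",
    "invert_coefficients",
    "fit_stack",
]

# Relative tolerance below which c2 and c4 are treated as zero (isotropic pixel).
ISO_TOL = 1e-9
# Negative-A^2 tolerance, relative to a0^2: beyond it the pixel is unphysical.
NEG_A2_TOL = 0.05
# Negative-C^2 clamp tolerance, relative to a0^2.
NEG_C2_TOL = 0.05


@dataclass(frozen=True)
class PolarizationStack:
    """An H x W x P stack of SHG images, one page per polarization angle.

    data   : non-negative intensities (detector counts), H x W x P
    angles : P polarization angles in degrees, strictly increasing in [0, 180)
    """

    data: np.ndarray
    angles: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        if data.ndim != 3:
            raise InvalidInputError(f"stack must be H x W x P, got shape {data.shape}")
        if angles.ndim != 1 or data.shape[2] != angles.size:
            raise InvalidInputError(
                f"angle count {angles.size} does not match page count {data.shape[2]}"
            )
        if angles.size < 5:
            raise InsufficientSamplingError(
                f"need >= 5 polarization angles for 5 coefficients, got {angles.size}"
            )
        if np.any(np.diff(angles) <= 0) or angles[0] < 0 or angles[-1] >= PROFILE_PERIOD_DEG:
            raise InvalidInputError("angles must be strictly increasing within [0, 180)")
        if np.any(data < 0) or not np.all(np.isfinite(data)):
            raise InvalidInputError("stack intensities must be finite and non-negative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "angles", angles)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    def mean_image(self) -> np.ndarray:
        """Polarization-averaged intensity image (equals the a0 map)."""
        return self.data.mean(axis=2)


@dataclass
class FitMaps:
    """Per-pixel fit results over a stack.

    Coefficient maps a0..b4 are H x W; alpha_map is degrees in [0, 180);
    A_map/B_map/C_map are intensity-scaled amplitudes; residual_map is the
    relative RMS misfit; valid_mask marks pixels with a physical inversion;
    isotropic_mask marks pixels whose orientation is undefined (flat profile)
    and which must be excluded from orientation statistics.
    """

    a0: np.ndarray
    a2: np.ndarray
    b2: np.ndarray
    a4: np.ndarray
    b4: np.ndarray
    alpha_map: np.ndarray
    A_map: np.ndarray
    B_map: np.ndarray
    C_map: np.ndarray
    residual_map: np.ndarray
    valid_mask: np.ndarray
    isotropic_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.isotropic_mask is None:
            self.isotropic_mask = np.zeros_like(self.valid_mask)


@dataclass(frozen=True)
class InversionResult:
    params: TensorParams
    valid: bool
    isotropic: bool = False


def _design_matrix(phis_deg: np.ndarray) -> np.ndarray:
    p = np.deg2rad(phis_deg)
    return np.column_stack(
        [np.ones_like(p), np.cos(2 * p), np.sin(2 * p), np.cos(4 * p), np.sin(4 * p)]
    )


def _is_equally_spaced(angles: np.ndarray) -> bool:
    """True when the grid is uniform and covers [0, 180) with step 180/P."""
    step = PROFILE_PERIOD_DEG / angles.size
    expected = angles[0] + step * np.arange(angles.size)
    return bool(np.allclose(angles, expected, atol=1e-9))


def _coefficient_operator(angles: np.ndarray) -> np.ndarray:
    """P x 5 matrix M with coeffs = profile @ M.

    For a uniform grid over [0, 180) the discrete-mean formulas are exact for
    the band-limited model signal; otherwise the pseudoinverse of the basis
    design matrix gives the least-squares estimate.
    """
    X = _design_matrix(angles)
    if _is_equally_spaced(angles):
        P = angles.size
        M = X.copy()
        M[:, 0] = 1.0
        return M * np.array([1.0, 2.0, 2.0, 2.0, 2.0]) / P
    # Least-squares fallback for irregular grids.
    rank = np.linalg.matrix_rank(X)
    if rank < 5:
        raise DegenerateGridError(
            f"angle grid supports only rank {rank} of 5 basis functions"
        )
    return np.linalg.pinv(X).T


def estimate_coefficients(profile, phis) -> FourierCoeffs:
    """Fourier coefficients of one measured polarization profile.

    ``profile`` holds P intensities measured at the P angles ``phis``
    (degrees).  Exact for noise-free model profiles on uniform grids with
    P >= 5; least squares otherwise.
    """
    profile = np.asarray(profile, dtype=float)
    phis = np.asarray(phis, dtype=float)
    if phis.size < 5:
        raise InsufficientSamplingError(f"need >= 5 angles, got {phis.size}")
    if profile.shape != phis.shape:
        raise InvalidInputError("profile and angle grid have different lengths")
    if np.unique(phis).size != phis.size:
        raise DegenerateGridError("polarization angles must be distinct")
    order = np.argsort(phis)
    M = _coefficient_operator(phis[order])
    a0, a2, b2, a4, b4 = profile[order] @ M
    return FourierCoeffs(a0=a0, a2=a2, b2=b2, a4=a4, b4=b4)


def _invert_arrays(a0, a2, b2, a4, b4):
    """Vectorized coefficient inversion.

    Returns (alpha, A, B, C, valid, isotropic) arrays.  Invalid pixels are
    those with a0 <= 0 or an A^2 / C^2 estimate negative beyond tolerance.
    """
    a0, a2, b2, a4, b4 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (a0, a2, b2, a4, b4))
    )
    c2 = np.hypot(a2, b2)
    two_alpha = np.arctan2(b2, a2)  # in (-pi, pi]
    alpha = np.rad2deg(two_alpha) / 2.0 % PROFILE_PERIOD_DEG

    with np.errstate(invalid="ignore"):
        c4 = a4 * np.cos(4 * np.deg2rad(alpha)) + b4 * np.sin(4 * np.deg2rad(alpha))

        isotropic = (c2 <= ISO_TOL * np.abs(a0)) & (
            np.hypot(a4, b4) <= ISO_TOL * np.abs(a0)
        )
        alpha = np.where(isotropic, 0.0, alpha)
        c4 = np.where(isotropic, 0.0, c4)

        B2 = a0 + c4 + c2
        A2 = a0 + c4 - c2
        valid = (a0 > 0) & np.isfinite(a0)
        # Shot noise can push A^2 slightly negative; clamp small, reject large.
        a0sq = np.square(a0)
        valid &= A2 >= -NEG_A2_TOL * a0sq
        A2 = np.clip(A2, 0.0, None)
        B2 = np.clip(B2, 0.0, None)
        A = np.sqrt(A2)
        B = np.sqrt(B2)
        C2 = (B - A) ** 2 / 4.0 - 2.0 * c4
        valid &= C2 >= -NEG_C2_TOL * a0sq
        C = np.sqrt(np.clip(C2, 0.0, None))
    return alpha, A, B, C, valid, isotropic


def invert_coefficients(coeffs: FourierCoeffs) -> InversionResult:
    """Recover (alpha, A, B, C) from one coefficient set.

    Round-trips exactly with :func:`pshglab.model.coeffs_from_params` for any
    parameters with B > A > 0, C >= 0.  A constant profile (c2 = c4 = 0) has
    no orientation: alpha is reported as 0 with ``isotropic=True``.
    """
    alpha, A, B, C, valid, isotropic = _invert_arrays(
        coeffs.a0, coeffs.a2, coeffs.b2, coeffs.a4, coeffs.b4
    )
    if not valid:
        params = TensorParams(alpha=0.0, A=0.0, B=0.0, C=0.0)
    else:
        params = TensorParams(alpha=float(alpha), A=float(A), B=float(B), C=float(C))
    return InversionResult(params=params, valid=bool(valid), isotropic=bool(isotropic))


def fit_stack(
    stack: PolarizationStack,
    smooth_radius: int = 0,
    foreground: np.ndarray | None = None,
) -> FitMaps:
    """Fit the PSHG model at every (foreground) pixel of a stack.

    smooth_radius > 0 mean-filters the five coefficient maps over a
    (2r+1) x (2r+1) window before inversion — neighbor averaging on the
    coefficients, which are linear in the data, rather than on derived
    angles.  The residual map is RMS(profile - series synthesis) / a0;
    pixels with a0 = 0 (or outside ``foreground``) are invalid.
    """
    if smooth_radius < 0:
        raise InvalidInputError("smooth_radius must be >= 0")
    H, W = stack.shape
    if foreground is not None:
        foreground = np.asarray(foreground, dtype=bool)
        if foreground.shape != (H, W):
            raise InvalidInputError(
                f"foreground mask shape {foreground.shape} != image shape {(H, W)}"
            )

    M = _coefficient_operator(stack.angles)
    coeff_maps = np.tensordot(stack.data, M, axes=([2], [0]))  # H x W x 5
    if smooth_radius > 0:
        size = 2 * smooth_radius + 1
        for k in range(5):
            coeff_maps[..., k] = ndimage.uniform_filter(
                coeff_maps[..., k], size=size, mode="nearest"
            )

    a0, a2, b2, a4, b4 = np.moveaxis(coeff_maps, 2, 0)
    alpha, A, B, C, valid, isotropic = _invert_arrays(a0, a2, b2, a4, b4)
    if foreground is not None:
        valid &= foreground

    X = _design_matrix(stack.angles)
    synth = np.tensordot(coeff_maps, X.T, axes=([2], [0]))
    with np.errstate(invalid="ignore", divide="ignore"):
        rms = np.sqrt(np.mean((stack.data - synth) ** 2, axis=2))
        residual = np.where(a0 > 0, rms / np.where(a0 > 0, a0, 1.0), np.nan)

    nanmask = ~valid
    return FitMaps(
        a0=a0,
        a2=a2,
        b2=b2,
        a4=a4,
        b4=b4,
        alpha_map=np.where(nanmask, np.nan, alpha),
        A_map=np.where(nanmask, np.nan, A),
        B_map=np.where(nanmask, np.nan, B),
        C_map=np.where(nanmask, np.nan, C),
        residual_map=np.where(nanmask, np.nan, residual),
        valid_mask=valid,
        isotropic_mask=isotropic & valid,
    )
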