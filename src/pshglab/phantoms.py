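"""Synthetic PSHG phantoms with known per-pixel ground truth.

The generator emulates the two specimen classes the pipeline targets:

* "gel" — in-vitro collagen matrices of varying Col I fraction, rendered as
  straight fibril segments with uniformly random orientations.  Across the
  Col I fractions the ground-truth pitch angle interpolates linearly between
  the pure-Col-I anchor (47.72 deg) and the most Col III-rich gel measured
  (48.19 deg); fibril length and overall SHG brightness increase with Col I
  fraction (brightness constrained by the 1.7x ratio between the 80:20 and
  60:40 gels).
* "skin" — dermal collagen at the fiber scale, rendered as smooth curved
  strokes whose base orientations are wrapped-normal distributed.  Healthy
  skin is 24% more dispersed than scar (defaults sigma = 31 vs 25 degrees);
  both share a pitch angle of 46.7 degrees.

Per-pixel tensor amplitudes are stored as ground truth so every downstream
stage (coefficient estimation, inversion, ratio maps, statistics) can be
checked against the exact generating values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .model import (
    PROFILE_PERIOD_DEG,
    RatioTriple,
    TensorParams,
    chi15_from_pitch,
    pitch_angle,
)
from .pixel_fit import PolarizationStack

__all__ = [
    "Phantom",
    "PhantomGeometry",
    "NoiseModel",
    "make_fibril_phantom",
    "make_uniform_phantom",
    "render_stack",
    "scenario",
    "GEL_COL1_FRACTIONS",
]

#: Col I fractions of the gel scenarios (100:0 ... 60:40 Col I/III).
GEL_COL1_FRACTIONS = (1.0, 0.9, 0.8, 0.7, 0.6)

# Pitch-angle anchors: pure Col I and the 60:40 gel.
_GEL_THETA_PURE = 47.72
_GEL_THETA_LOW = 48.19
_GEL_CHI33 = 1.13

# Brightness(f) is linear in the Col I fraction f, constrained by
# brightness(0.8)/brightness(0.6) = 1.7 and normalized to 1 at f = 1.
_GEL_INTENSITY_X0 = 0.22 / 0.7  # zero-crossing of the linear brightness law

_SKIN_THETA = 46.7
_SKIN_CHI33 = 1.1
_SKIN_SIGMA = {"scar": 25.0, "healthy": 31.0}  # healthy/scar = 1.24


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometry metadata of a rendered phantom."""

    n_fibrils: int
    length_um: float
    thickness_um: float
    pixel_size_um: float
    orientation_center: float | None
    orientation_sd: float | None  # None = uniformly random orientations
    scenario: str = "custom"
    theta_true: float | None = None
    chi33_ratio: float | None = None
    chi15_ratio: float | None = None
    intensity_scale: float = 1.0

    @property
    def length_px(self) -> float:
        return self.length_um / self.pixel_size_um

    @property
    def thickness_px(self) -> float:
        return self.thickness_um / self.pixel_size_um


@dataclass
class Phantom:
    """Ground-truth parameter maps plus geometry metadata.

    Truth maps are defined on ``foreground``; background truth is zero
    intensity (A = B = C = 0, alpha = 0).
    """

    truth_alpha: np.ndarray
    truth_A: np.ndarray
    truth_B: np.ndarray
    truth_C: np.ndarray
    foreground: np.ndarray
    geometry: PhantomGeometry

    @property
    def shape(self) -> tuple[int, int]:
        return self.truth_alpha.shape


@dataclass(frozen=True)
class NoiseModel:
    """Detection noise: Poisson shot noise plus Gaussian read noise.

    peak_count    : expected detector counts at the brightest pixel
    read_noise_sd : Gaussian read-noise standard deviation, counts
    seed          : integer seed; identical seeds give identical stacks
    """

    peak_count: float = 1000.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_count <= 0:
            raise InvalidInputError("peak_count must be > 0")
        if self.read_noise_sd < 0:
            raise InvalidInputError("read_noise_sd must be >= 0")


def _base_amplitudes(tensor) -> tuple[float, float, float]:
    """(A, B, C) base amplitudes from a TensorParams or RatioTriple."""
    if isinstance(tensor, TensorParams):
        return tensor.A, tensor.B, tensor.C
    if isinstance(tensor, RatioTriple):
        return 1.0, tensor.chi33_over_chi31, tensor.chi15_over_chi31
    raise InvalidInputError(f"tensor must be TensorParams or RatioTriple, got {type(tensor)}")


def _draw_angles(rng, n, center, sd):
    if sd is None:
        return rng.uniform(0.0, PROFILE_PERIOD_DEG, size=n)
    return (center + rng.normal(0.0, sd, size=n)) % PROFILE_PERIOD_DEG


def make_uniform_phantom(
    size: tuple[int, int], tensor, alpha: float = 30.0, scenario: str = "uniform"
) -> Phantom:
    """Homogeneous phantom: every pixel foreground with identical parameters."""
    H, W = size
    A, B, C = _base_amplitudes(tensor)
    geom = PhantomGeometry(
        n_fibrils=0, length_um=0.0, thickness_um=0.0, pixel_size_um=1.0,
        orientation_center=alpha, orientation_sd=0.0, scenario=scenario,
        chi33_ratio=B / A, chi15_ratio=C / A,
        theta_true=pitch_angle(B / A, C / A),
    )
    return Phantom(
        truth_alpha=np.full((H, W), float(alpha) % PROFILE_PERIOD_DEG),
        truth_A=np.full((H, W), A),
        truth_B=np.full((H, W), B),
        truth_C=np.full((H, W), C),
        foreground=np.ones((H, W), dtype=bool),
        geometry=geom,
    )


def _stamp_segment(maps, center_rc, angle_deg, length_px, thickness_px, amps, intensity):
    """Stamp one straight fibril; overlapping pixels keep the brighter fibril.

    ``intensity`` is the fibril's SHG brightness factor; since the forward
    model is quadratic in the amplitudes, they scale with sqrt(intensity).
    """
    truth_alpha, truth_A, truth_B, truth_C, brightness = maps
    H, W = truth_alpha.shape
    a = np.deg2rad(angle_deg)
    # x = column, y = row (y increases downward; angle is CCW on screen).
    ux, uy = np.cos(a), -np.sin(a)
    r0, c0 = center_rc
    half = length_px / 2.0
    halfwidth = max((thickness_px - 1) / 2.0, 0.0)

    pad = halfwidth + 1
    rmin = max(int(np.floor(r0 - half - pad)), 0)
    rmax = min(int(np.ceil(r0 + half + pad)), H - 1)
    cmin = max(int(np.floor(c0 - half - pad)), 0)
    cmax = min(int(np.ceil(c0 + half + pad)), W - 1)
    if rmin > rmax or cmin > cmax:
        return
    rr, cc = np.meshgrid(np.arange(rmin, rmax + 1), np.arange(cmin, cmax + 1), indexing="ij")
    dx = cc - c0
    dy = rr - r0
    along = dx * ux + dy * uy
    perp = np.abs(-dx * uy + dy * ux)
    inside = (np.abs(along) <= half) & (perp <= halfwidth)
    write = inside & (intensity > brightness[rmin : rmax + 1, cmin : cmax + 1])
    sub = (slice(rmin, rmax + 1), slice(cmin, cmax + 1))
    A, B, C = amps
    amp = np.sqrt(intensity)
    truth_alpha[sub][write] = angle_deg % PROFILE_PERIOD_DEG
    truth_A[sub][write] = A * amp
    truth_B[sub][write] = B * amp
    truth_C[sub][write] = C * amp
    brightness[sub][write] = intensity


def make_fibril_phantom(
    size: tuple[int, int],
    n_fibrils: int,
    length_px: float,
    thickness_px: float,
    orientation_center: float = 0.0,
    orientation_sd: float | None = None,
    tensor=None,
    seed: int = 0,
    intensity_scale: float = 1.0,
    brightness_jitter: float = 0.15,
    pixel_size_um: float = 1.0,
    curved: bool = False,
    step_jitter_deg: float = 1.0,
    scenario: str = "custom",
) -> Phantom:
    """Random fibril field with wrapped-normal orientations.

    Straight line segments (``curved=False``) of the given length and
    thickness are stamped at random centers; with ``curved=True`` each fibril
    is a smooth stroke whose heading performs a small random walk
    (``step_jitter_deg`` per pixel step), and the local heading is recorded as
    that pixel's ground-truth orientation.  ``orientation_sd=None`` draws
    orientations uniformly.  Overlaps keep the brighter fibril; per-fibril
    brightness is lognormal with spread ``brightness_jitter``.  Fully
    reproducible for a given ``seed``.
    """
    if length_px <= 0 or thickness_px <= 0 or n_fibrils < 1:
        raise InvalidInputError("geometry must be positive and n_fibrils >= 1")
    if tensor is None:
        tensor = TensorParams(alpha=0.0, A=1.0, B=1.13, C=0.53)
    H, W = size
    if length_px > max(H, W):
        warnings.warn("fibril length exceeds the field; fibrils are clipped", stacklevel=2)
    rng = np.random.default_rng(seed)
    amps = _base_amplitudes(tensor)

    truth_alpha = np.zeros((H, W))
    truth_A = np.zeros((H, W))
    truth_B = np.zeros((H, W))
    truth_C = np.zeros((H, W))
    brightness = np.zeros((H, W))
    maps = (truth_alpha, truth_A, truth_B, truth_C, brightness)

    angles = _draw_angles(rng, n_fibrils, orientation_center, orientation_sd)
    # Integer centers keep stamped widths exact (a thickness-3 fibril is 3 px wide).
    centers_r = rng.integers(0, H, size=n_fibrils).astype(float)
    centers_c = rng.integers(0, W, size=n_fibrils).astype(float)
    scales = intensity_scale * rng.lognormal(mean=0.0, sigma=brightness_jitter, size=n_fibrils)

    halfwidth = max((thickness_px - 1) / 2.0, 0.0)
    if curved:
        dr = int(np.ceil(halfwidth))
        off_r, off_c = np.meshgrid(np.arange(-dr, dr + 1), np.arange(-dr, dr + 1), indexing="ij")
        disk = (off_r**2 + off_c**2) <= max(halfwidth, 0.5) ** 2
        off_r, off_c = off_r[disk], off_c[disk]

    for i in range(n_fibrils):
        if not curved:
            _stamp_segment(
                maps, (centers_r[i], centers_c[i]), angles[i],
                length_px, thickness_px, amps, scales[i],
            )
            continue
        # Curved stroke: unit steps with a slowly wandering heading.
        n_steps = int(round(length_px))
        heading = angles[i] + np.cumsum(rng.normal(0.0, step_jitter_deg, size=n_steps))
        r, c = centers_r[i], centers_c[i]
        for h in heading:
            ha = np.deg2rad(h)
            r -= np.sin(ha)
            c += np.cos(ha)
            rr = (np.round(r).astype(int) + off_r)
            cc = (np.round(c).astype(int) + off_c)
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            rr, cc = rr[ok], cc[ok]
            write = scales[i] > brightness[rr, cc]
            rr, cc = rr[write], cc[write]
            amp = np.sqrt(scales[i])
            truth_alpha[rr, cc] = h % PROFILE_PERIOD_DEG
            truth_A[rr, cc] = amps[0] * amp
            truth_B[rr, cc] = amps[1] * amp
            truth_C[rr, cc] = amps[2] * amp
            brightness[rr, cc] = scales[i]

    A0, B0, C0 = amps
    geom = PhantomGeometry(
        n_fibrils=n_fibrils,
        length_um=length_px * pixel_size_um,
        thickness_um=thickness_px * pixel_size_um,
        pixel_size_um=pixel_size_um,
        orientation_center=orientation_center if orientation_sd is not None else None,
        orientation_sd=orientation_sd,
        scenario=scenario,
        chi33_ratio=B0 / A0,
        chi15_ratio=C0 / A0,
        theta_true=pitch_angle(B0 / A0, C0 / A0),
        intensity_scale=intensity_scale,
    )
    return Phantom(
        truth_alpha=truth_alpha,
        truth_A=truth_A,
        truth_B=truth_B,
        truth_C=truth_C,
        foreground=brightness > 0,
        geometry=geom,
    )


def render_stack(phantom: Phantom, phis, noise: NoiseModel | None = None) -> PolarizationStack:
    """Render the forward model at each polarization angle.

    With ``noise=None`` the exact model intensities are returned.  With a
    :class:`NoiseModel`, the noise-free stack is scaled so its brightest pixel
    equals ``peak_count`` expected counts, then Poisson-sampled with additive
    Gaussian read noise, clipped at zero.
    """
    phis = np.asarray(phis, dtype=float)
    psi = np.deg2rad(phis[None, None, :] - phantom.truth_alpha[..., None])
    s2 = np.sin(psi) ** 2
    c2 = 1.0 - s2
    A = phantom.truth_A[..., None]
    B = phantom.truth_B[..., None]
    C = phantom.truth_C[..., None]
    clean = C**2 * np.sin(2 * psi) ** 2 + (A * s2 + B * c2) ** 2

    if noise is None:
        return PolarizationStack(data=clean, angles=phis)

    peak = float(clean.max())
    if peak <= 0:
        raise InvalidInputError("phantom renders to an all-zero stack; cannot set peak count")
    lam = clean * (noise.peak_count / peak)
    rng = np.random.default_rng(noise.seed)
    data = rng.poisson(lam).astype(float)
    if noise.read_noise_sd > 0:
        data += rng.normal(0.0, noise.read_noise_sd, size=data.shape)
    return PolarizationStack(data=np.clip(data, 0.0, None), angles=phis)


def gel_intensity_scale(col1_fraction: float) -> float:
    """Linear SHG brightness law vs Col I fraction, 1.0 at pure Col I."""
    return (col1_fraction - _GEL_INTENSITY_X0) / (1.0 - _GEL_INTENSITY_X0)


def gel_theta_true(col1_fraction: float) -> float:
    """Ground-truth pitch angle vs Col I fraction (linear between anchors)."""
    return _GEL_THETA_PURE + (_GEL_THETA_LOW - _GEL_THETA_PURE) * (1.0 - col1_fraction) / 0.4


def scenario(name: str, size: tuple[int, int] = (256, 256), seed: int = 0, **params) -> Phantom:
    """Preset phantom scenarios.

    scenario("gel", col1_fraction=f)      f in {1.0, 0.9, 0.8, 0.7, 0.6}
    scenario("skin", condition=c)         c in {"healthy", "scar"}
    """
    if name == "gel":
        f = params.pop("col1_fraction", 1.0)
        if not any(abs(f - v) < 1e-9 for v in GEL_COL1_FRACTIONS):
            raise InvalidInputError(
                f"col1_fraction must be one of {GEL_COL1_FRACTIONS}, got {f}"
            )
        theta = gel_theta_true(f)
        tensor = RatioTriple(
            chi15_over_chi31=chi15_from_pitch(_GEL_CHI33, theta),
            chi33_over_chi31=_GEL_CHI33,
            theta_p=theta,
        )
        pixel_size = params.pop("pixel_size_um", 0.3)
        length_um = 6.0 + 10.0 * (f - 0.6) / 0.4  # longer fibrils at high Col I
        thickness_um = 1.55  # mid of the observed 1.3-1.8 um fibril thickness
        return make_fibril_phantom(
            size=size,
            n_fibrils=params.pop("n_fibrils", 160),
            length_px=length_um / pixel_size,
            thickness_px=thickness_um / pixel_size,
            orientation_center=0.0,
            orientation_sd=None,  # gels are orientationally random
            tensor=tensor,
            seed=seed,
            intensity_scale=gel_intensity_scale(f),
            pixel_size_um=pixel_size,
            scenario=f"gel:{f:.1f}",
            **params,
        )
    if name == "skin":
        condition = params.pop("condition", "healthy")
        if condition not in _SKIN_SIGMA:
            raise InvalidInputError(
                f"condition must be one of {sorted(_SKIN_SIGMA)}, got {condition!r}"
            )
        theta = _SKIN_THETA
        tensor = RatioTriple(
            chi15_over_chi31=chi15_from_pitch(_SKIN_CHI33, theta),
            chi33_over_chi31=_SKIN_CHI33,
            theta_p=theta,
        )
        pixel_size = params.pop("pixel_size_um", 1.0)
        sigma = params.pop("orientation_sd", _SKIN_SIGMA[condition])
        return make_fibril_phantom(
            size=size,
            n_fibrils=params.pop("n_fibrils", 300),
            length_px=params.pop("length_px", 60.0),
            thickness_px=params.pop("thickness_px", 3.0),
            orientation_center=params.pop("orientation_center", 90.0),
            orientation_sd=sigma,
            tensor=tensor,
            seed=seed,
            curved=True,
            pixel_size_um=pixel_size,
            scenario=f"skin:{condition}",
            **params,
        )
    raise InvalidInputError(f"unknown scenario {name!r}; options: 'gel', 'skin'")
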