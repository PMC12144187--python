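"""Physical model of the polarization-resolved SHG response of a cylindrically
symmetric harmonophore assembly.

A fibril with in-plane orientation ``alpha`` illuminated with linearly polarized
light at angle ``phi`` emits second-harmonic intensity

    I(phi) = C^2 sin^2 2(phi-alpha) + [A sin^2(phi-alpha) + B cos^2(phi-alpha)]^2

where ``A = I0*chi31``, ``B = I0*chi33`` and ``C = I0*chi15`` combine the
incident intensity with the three independent elements of the second-order
susceptibility tensor under cylindrical symmetry.  The profile is 180-degree
periodic and band-limited: it is exactly a five-term Fourier series in the
2*phi and 4*phi harmonics, which is what makes fast per-pixel fitting possible.

The effective alpha-helix pitch angle of the peptide-bond harmonophores
follows from the susceptibility ratios:

    tan^2(theta_p) = 2 / (chi33/chi31 - chi15/chi31 + 1)

All angles at this interface are degrees; radians appear only internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateProfileError, InvalidInputError, UndefinedPitchError

__all__ = [
    "TensorParams",
    "FourierCoeffs",
    "RatioTriple",
    "intensity_profile",
    "coeffs_from_params",
    "pitch_angle",
    "chi15_from_pitch",
    "classify_peaks",
]

#: Period of the PSHG intensity profile in the polarization angle, degrees.
PROFILE_PERIOD_DEG = 180.0


@dataclass(frozen=True)
class TensorParams:
    """Per-pixel model parameters.

    alpha : fiber in-plane orientation in degrees, normalized to [0, 180)
    A     : amplitude I0*chi31, arbitrary intensity units, >= 0
    B     : amplitude I0*chi33, same units, >= 0
    C     : amplitude I0*chi15, same units, >= 0

    Amplitude signs are unidentifiable from intensity data, so amplitudes are
    stored as magnitudes.
    """

    alpha: float
    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.A, self.B, self.C)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite tensor parameters: {vals}")
        if self.A < 0 or self.B < 0 or self.C < 0:
            raise InvalidInputError(
                f"amplitudes must be non-negative, got A={self.A}, B={self.B}, C={self.C}"
            )
        object.__setattr__(self, "alpha", float(self.alpha) % PROFILE_PERIOD_DEG)


@dataclass(frozen=True)
class FourierCoeffs:
    """Coefficients of I(phi) = a0 + a2 cos2phi + b2 sin2phi + a4 cos4phi + b4 sin4phi.

    The profile period is 180 degrees, so the "2phi" harmonic is the
    fundamental of the series.  a0 >= 0 for any physical profile.
    """

    a0: float
    a2: float
    b2: float
    a4: float
    b4: float

    period: float = PROFILE_PERIOD_DEG

    def __post_init__(self) -> None:
        vals = (self.a0, self.a2, self.b2, self.a4, self.b4)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidInputError(f"non-finite Fourier coefficients: {vals}")

    def synthesize(self, phis) -> np.ndarray:
        """Evaluate the series at polarization angles ``phis`` (degrees)."""
        p = np.deg2rad(np.asarray(phis, dtype=float))
        return (
            self.a0
            + self.a2 * np.cos(2 * p)
            + self.b2 * np.sin(2 * p)
            + self.a4 * np.cos(4 * p)
            + self.b4 * np.sin(4 * p)
        )


@dataclass(frozen=True)
class RatioTriple:
    """Susceptibility ratios and the pitch angle they imply.

    chi15_over_chi31, chi33_over_chi31 : dimensionless tensor ratios (>= 0)
    theta_p : effective alpha-helix pitch angle, degrees, in (0, 90)
    """

    chi15_over_chi31: float
    chi33_over_chi31: float
    theta_p: float

    @classmethod
    def from_ratios(cls, chi33_over_chi31: float, chi15_over_chi31: float) -> "RatioTriple":
        return cls(
            chi15_over_chi31=chi15_over_chi31,
            chi33_over_chi31=chi33_over_chi31,
            theta_p=pitch_angle(chi33_over_chi31, chi15_over_chi31),
        )


def intensity_profile(params: TensorParams, phis) -> np.ndarray:
    """SHG intensity at polarization angles ``phis`` (degrees).

    Returns a non-negative array of the same shape as ``phis``; the profile is
    180-degree periodic in phi.
    """
    phis = np.asarray(phis, dtype=float)
    if not np.all(np.isfinite(phis)):
        raise InvalidInputError("polarization angles must be finite")
    psi = np.deg2rad(phis - params.alpha)
    s2, c2 = np.sin(psi) ** 2, np.cos(psi) ** 2
    return params.C**2 * np.sin(2 * psi) ** 2 + (params.A * s2 + params.B * c2) ** 2


def coeffs_from_params(params: TensorParams) -> FourierCoeffs:
    """Closed-form Fourier coefficients of the intensity profile.

    With S = A + B and D = B - A the profile in psi = phi - alpha is
    c0 + c2 cos2psi + c4 cos4psi with c0 = C^2/2 + S^2/4 + D^2/8,
    c2 = S*D/2 and c4 = D^2/8 - C^2/2; rotating by alpha distributes c2, c4
    over the cos/sin pairs.  Synthesizing the result reproduces
    :func:`intensity_profile` to machine precision.
    """
    S = params.A + params.B
    D = params.B - params.A
    c0 = params.C**2 / 2 + S**2 / 4 + D**2 / 8
    c2 = S * D / 2
    c4 = D**2 / 8 - params.C**2 / 2
    a = np.deg2rad(params.alpha)
    return FourierCoeffs(
        a0=c0,
        a2=c2 * np.cos(2 * a),
        b2=c2 * np.sin(2 * a),
        a4=c4 * np.cos(4 * a),
        b4=c4 * np.sin(4 * a),
    )


def pitch_angle(chi33_over_chi31: float, chi15_over_chi31: float) -> float:
    """Effective alpha-helix pitch angle, degrees in (0, 90).

    tan^2(theta_p) = 2 / (chi33/chi31 - chi15/chi31 + 1); defined only where
    the denominator is positive.  Strictly decreasing in
    (chi33/chi31 - chi15/chi31) and approaching 90 degrees as the denominator
    approaches zero from above.
    """
    denom = chi33_over_chi31 - chi15_over_chi31 + 1.0
    if not np.isfinite(denom) or denom <= 0:
        raise UndefinedPitchError(
            f"pitch angle undefined: chi33/chi31 - chi15/chi31 + 1 = {denom} <= 0"
        )
    return float(np.rad2deg(np.arctan(np.sqrt(2.0 / denom))))


def chi15_from_pitch(chi33_over_chi31: float, theta_p: float) -> float:
    """Invert the pitch-angle relation for chi15/chi31 at fixed chi33/chi31."""
    t = np.tan(np.deg2rad(theta_p))
    return float(chi33_over_chi31 + 1.0 - 2.0 / t**2)


def classify_peaks(params: TensorParams, grid_step: float = 0.1) -> str:
    """Classify the noise-free profile as "single"- or "double"-peaked.

    Counts strict local maxima over one 180-degree period on a dense grid
    (default 0.1 degrees), merging plateau runs so that flat-topped maxima
    count once.  Profiles with chi33 = chi31 (B = A) and C > 0 peak at
    psi = 45 and 135 degrees and classify as "double"; the usual collagen case
    B > A, small C has a single maximum at psi = 0.

    Raises DegenerateProfileError for a flat (e.g. all-zero) profile.
    """
    phis = np.arange(0.0, PROFILE_PERIOD_DEG, grid_step)
    y = intensity_profile(params, phis)
    ymax = float(np.max(y))
    if ymax <= 0 or np.ptp(y) < 1e-12 * max(ymax, 1.0):
        raise DegenerateProfileError("flat polarization profile; peak structure undefined")

    # Merge plateaus: keep one representative per run of equal values.
    keep = np.r_[True, np.abs(np.diff(y)) > 1e-12 * ymax]
    yr = y[keep]
    # Periodic strict local maxima on the reduced profile.
    prev = np.roll(yr, 1)
    nxt = np.roll(yr, -1)
    n_max = int(np.sum((yr > prev) & (yr > nxt)))
    return "double" if n_max >= 2 else "single"
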