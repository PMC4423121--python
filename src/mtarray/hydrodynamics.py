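"""Glycerol-gradient sedimentation analysis and frictional ratios.

A velocity gradient is calibrated with standard proteins of known
sedimentation coefficient: peak elution volume (from the top of the
gradient) is linear in S, so an ordinary least-squares line converts a
sample's peak volume into its S value.  Shape information then comes from
the frictional ratio

    f/f_min = S_max / S,      S_max = 0.00361 · M^(2/3)   (S, M in Da)

where S_max is the sedimentation coefficient of an anhydrous sphere of the
same mass: f/f_min ≈ 1 for compact globular proteins and ≫ 1 for elongated
or disordered ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, InvalidInputError

__all__ = [
    "GradientProfile",
    "SedimentationResult",
    "SMAX_COEFF",
    "calibrate",
    "peak_volume",
    "sedimentation_coefficient",
    "frictional_ratio",
    "s_max",
    "read_gradient_csv",
    "write_gradient_csv",
    "read_standards_csv",
]

SMAX_COEFF = 0.00361  # Svedberg per Da^(2/3): anhydrous-sphere S for mass M


@dataclass(frozen=True)
class GradientProfile:
    """Fraction volumes (μl from top of gradient) and signal (a.u.)."""

    volumes_ul: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_ul, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if v.shape != s.shape or v.ndim != 1:
            raise InvalidInputError("volumes and signal must be aligned 1-D arrays")
        if np.any(np.diff(v) <= 0):
            raise InvalidInputError("fraction volumes must be strictly increasing")
        if np.any(s < 0):
            raise InvalidInputError("signals must be >= 0")
        object.__setattr__(self, "volumes_ul", v)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class Calibration:
    """Linear map S = slope·volume + intercept fitted to standards."""

    slope: float      # S per μl
    intercept: float  # S
    r_squared: float


@dataclass(frozen=True)
class SedimentationResult:
    S: float
    M_da: float
    calibration: Calibration

    @property
    def S_max(self) -> float:
        return s_max(self.M_da)

    @property
    def f_ratio(self) -> float:
        return self.S_max / self.S


def calibrate(standards) -> Calibration:
    """OLS line through (peak volume, known S) standard-protein points."""
    pts = [(float(v), float(s)) for v, s in standards]
    vols = np.array([p[0] for p in pts])
    svals = np.array([p[1] for p in pts])
    if np.unique(vols).size < 2:
        raise InsufficientDataError("need >= 2 standards with distinct volumes")
    res = stats.linregress(vols, svals)
    return Calibration(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue) ** 2)


def peak_volume(profile: GradientProfile) -> float:
    """Signal-weighted centroid of the contiguous half-maximum region.

    The centroid of the fractions at >= 50% of the peak signal that are
    contiguous with the maximum is less sensitive to 250 μl fraction
    granularity than the raw argmax.
    """
    v, s = profile.volumes_ul, profile.signal
    if v.size < 3:
        raise InsufficientDataError("need >= 3 fractions")
    smax = s.max()
    if smax <= 0 or np.isclose(s.min(), smax):
        raise DegenerateInputError("flat profile has no peak")
    imax = int(np.argmax(s))
    lo = imax
    while lo > 0 and s[lo - 1] >= 0.5 * smax:
        lo -= 1
    hi = imax
    while hi < s.size - 1 and s[hi + 1] >= 0.5 * smax:
        hi += 1
    sel = slice(lo, hi + 1)
    return float(np.average(v[sel], weights=s[sel]))


def sedimentation_coefficient(profile: GradientProfile, calibration: Calibration,
                              M_da: float | None = None) -> SedimentationResult:
    """Convert a sample profile's peak volume to S via the calibration line."""
    if calibration.slope == 0:
        raise DegenerateInputError("degenerate calibration: slope is zero")
    S = calibration.slope * peak_volume(profile) + calibration.intercept
    return SedimentationResult(S=float(S), M_da=float(M_da) if M_da else float("nan"),
                               calibration=calibration)


def s_max(M_da: float) -> float:
    """Sedimentation coefficient of an anhydrous sphere of mass M (Da)."""
    if M_da <= 0:
        raise InvalidInputError("mass must be > 0")
    return SMAX_COEFF * M_da ** (2.0 / 3.0)


def frictional_ratio(M_da: float, S: float) -> float:
    """f/f_min = S_max/S for a protein of mass M (Da) sedimenting at S."""
    if S <= 0:
        raise InvalidInputError("S must be > 0")
    return s_max(M_da) / S


def read_gradient_csv(path) -> list[GradientProfile]:
    """Read `label, volume_ul, signal` CSV, one profile per label."""
    df = pd.read_csv(path)
    return [
        GradientProfile(g.sort_values("volume_ul")["volume_ul"].to_numpy(),
                        g.sort_values("volume_ul")["signal"].to_numpy(), str(label))
        for label, g in df.groupby("label", sort=True)
    ]


def write_gradient_csv(profiles, path) -> None:
    rows = [
        {"label": p.label, "volume_ul": v, "signal": s}
        for p in profiles
        for v, s in zip(p.volumes_ul, p.signal)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_standards_csv(path):
    """Read `label, volume_ul, S_svedberg` CSV into (volume, S) pairs."""
    df = pd.read_csv(path)
    return list(zip(df["volume_ul"], df["S_svedberg"]))
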