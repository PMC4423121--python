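"""Microtubule orientation statistics relative to the longitudinal cell axis.

Filament traces and plus-end (EB comet) growth tracks are reduced to angle
samples referenced to the cell's long axis; alignment is then quantified by
the Kuiper statistic K = d1 + d2 (the sum of the maximum positive and
negative deviations of the empirical angle CDF from the uniform CDF), an
asymmetry index, and band-occupancy fractions.

Angle conventions
-----------------
``undirected``
    Filament orientations have no polarity: angles are folded into
    (-90°, 90°], measured counter-clockwise from the cell axis.
``directed``
    Growth directions retain polarity: angles lie in (-180°, 180°].

The Kuiper deviations are evaluated on the fixed, axis-referenced support
((-90, 90] or (-180, 180]) rather than maximised over origin shifts as in
the classical rotation-invariant circular test: the cell axis provides a
canonical origin, so a network aligned with the axis and one aligned 90°
off it must score differently.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, EmptyInputError, InvalidInputError

__all__ = [
    "CellGeometry",
    "FilamentTrace",
    "AngularSample",
    "KuiperResult",
    "GrowthTrack",
    "angle_to_axis",
    "filament_angles",
    "kuiper_statistic",
    "fraction_within",
    "asymmetry_index",
    "track_growth_stats",
    "fold_undirected",
    "read_filaments_csv",
    "write_filaments_csv",
    "read_cell_json",
    "write_cell_json",
    "read_tracks_csv",
    "write_tracks_csv",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellGeometry:
    """Cell outline polygon and longitudinal axis, both in μm.

    ``outline`` is a closed simple polygon given as an (N, 2) vertex array
    (the closing edge is implicit).  ``axis`` is a (2, 2) array of the two
    tip points; the cell length L is their straight-line (tip-to-tip)
    distance.
    """

    outline: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        outline = np.asarray(self.outline, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        if outline.ndim != 2 or outline.shape[1] != 2 or outline.shape[0] < 3:
            raise InvalidInputError("outline must be an (N>=3, 2) polygon")
        if axis.shape != (2, 2):
            raise InvalidInputError("axis must be a (2, 2) endpoint pair")
        if not np.isfinite(outline).all() or not np.isfinite(axis).all():
            raise InvalidInputError("geometry contains non-finite coordinates")
        object.__setattr__(self, "outline", outline)
        object.__setattr__(self, "axis", axis)
        if self.length <= 0:
            raise InvalidInputError("axis endpoints coincide: cell length L must be > 0")

    @property
    def length(self) -> float:
        """Tip-to-tip cell length L in μm."""
        return float(np.hypot(*(self.axis[1] - self.axis[0])))

    @property
    def axis_angle_deg(self) -> float:
        """Direction of the axis vector (first tip -> second tip), degrees."""
        d = self.axis[1] - self.axis[0]
        return math.degrees(math.atan2(d[1], d[0]))


@dataclass(frozen=True)
class FilamentTrace:
    """A manually traced microtubule polyline (vertices in μm)."""

    id: str
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise InvalidInputError(f"filament {self.id}: need >= 2 vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0.0, axis=1)):
            raise InvalidInputError(f"filament {self.id}: consecutive vertices coincide")
        object.__setattr__(self, "vertices", v)

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.vertices, axis=0).T)

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass(frozen=True)
class AngularSample:
    """Weighted angles relative to the cell axis.

    Weights are segment lengths (μm) for filament samples and 1 per track
    for comet samples.
    """

    angles: np.ndarray
    convention: str  # "undirected" | "directed"
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        angles = np.atleast_1d(np.asarray(self.angles, dtype=float))
        if self.convention not in ("undirected", "directed"):
            raise InvalidInputError(f"unknown convention {self.convention!r}")
        w = self.weights
        w = np.ones_like(angles) if w is None else np.atleast_1d(np.asarray(w, dtype=float))
        if w.shape != angles.shape:
            raise InvalidInputError("weights must match angles in shape")
        if np.any(w < 0) or (angles.size and not w.sum() > 0):
            raise InvalidInputError("weights must be >= 0 and not all zero")
        lo, hi = self.support
        if angles.size and (np.any(angles <= lo) or np.any(angles > hi)):
            raise InvalidInputError(f"angles outside ({lo}, {hi}]")
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "weights", w)

    @property
    def support(self) -> tuple[float, float]:
        return (-90.0, 90.0) if self.convention == "undirected" else (-180.0, 180.0)

    @property
    def n_effective(self) -> float:
        return float(self.weights.sum())

    def folded(self) -> "AngularSample":
        """Return the sample with angles folded to the undirected range."""
        if self.convention == "undirected":
            return self
        return AngularSample(fold_undirected(self.angles), "undirected", self.weights)


@dataclass(frozen=True)
class KuiperResult:
    """Kuiper alignment statistic K = d1 + d2 against the uniform CDF."""

    d1: float
    d2: float
    n_effective: float

    @property
    def K(self) -> float:
        return self.d1 + self.d2


@dataclass(frozen=True)
class GrowthTrack:
    """Time-stamped (t s, x μm, y μm) positions of one growing plus end."""

    id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 2:
            raise InvalidInputError(f"track {self.id}: need >= 2 aligned samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(f"track {self.id}: t must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


# ---------------------------------------------------------------------------
# Angle extraction
# ---------------------------------------------------------------------------

def fold_undirected(angles_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold directed angles (degrees) into the axial range (-90, 90]."""
    a = np.mod(np.asarray(angles_deg, dtype=float) + 90.0, 180.0) - 90.0
    a = np.where(a == -90.0, 90.0, a)
    return float(a) if np.isscalar(angles_deg) else a


def angle_to_axis(segment, geometry: CellGeometry, convention: str = "undirected") -> float:
    """Angle of a point-pair segment relative to the cell axis, degrees.

    Undirected: folded to (-90°, 90°], sign = counter-clockwise from axis.
    Directed: (-180°, 180°] using the segment's direction of travel.
    """
    p0, p1 = (np.asarray(p, dtype=float) for p in segment)
    d = p1 - p0
    if np.hypot(*d) == 0.0:
        raise DegenerateInputError("zero-length segment has no direction")
    theta = math.degrees(math.atan2(d[1], d[0])) - geometry.axis_angle_deg
    theta = (theta + 180.0) % 360.0 - 180.0
    if theta == -180.0:
        theta = 180.0
    if convention == "directed":
        return theta
    if convention == "undirected":
        return float(fold_undirected(theta))
    raise InvalidInputError(f"unknown convention {convention!r}")


def filament_angles(filaments, geometry: CellGeometry) -> AngularSample:
    """Undirected angle sample from filament traces, length-weighted.

    Each polyline segment contributes one angle weighted by its length (μm),
    so long aligned filaments dominate the sample as they do visually.
    """
    filaments = list(filaments)
    if not filaments:
        raise EmptyInputError("no filaments")
    angles, weights = [], []
    for f in filaments:
        v = f.vertices
        for i in range(len(v) - 1):
            angles.append(angle_to_axis((v[i], v[i + 1]), geometry, "undirected"))
            weights.append(float(np.hypot(*(v[i + 1] - v[i]))))
    return AngularSample(np.array(angles), "undirected", np.array(weights))


# ---------------------------------------------------------------------------
# Alignment statistics
# ---------------------------------------------------------------------------

def kuiper_statistic(sample: AngularSample) -> KuiperResult:
    """Kuiper statistic of an angle sample against the uniform distribution.

    The weighted empirical CDF is compared with the uniform CDF F on the
    sample's declared support.  d1 = sup(ECDF - F) and d2 = sup(F - ECDF)
    are attained at jump points of the ECDF: d1 just after a jump (ECDF
    right-continuous), d2 just before it (left limit), so both are found by
    scanning the sorted unique angles once.
    """
    if sample.angles.size == 0 or sample.n_effective <= 0:
        raise EmptyInputError("empty angle sample")
    lo, hi = sample.support
    span = hi - lo
    order = np.argsort(sample.angles, kind="stable")
    theta = sample.angles[order]
    w = sample.weights[order]
    # merge ties so the ECDF has one jump per distinct angle
    uniq, inv = np.unique(theta, return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    ecdf_after = np.cumsum(wsum) / wsum.sum()
    ecdf_before = ecdf_after - wsum / wsum.sum()
    F = (uniq - lo) / span
    d1 = float(max(np.max(ecdf_after - F), 0.0))
    d2 = float(max(np.max(F - ecdf_before), 0.0))
    return KuiperResult(d1=d1, d2=d2, n_effective=sample.n_effective)


def fraction_within(sample: AngularSample, halfwidth_deg: float) -> float:
    """Weighted fraction of angles within ±halfwidth of the axis (folded)."""
    if not 0 < halfwidth_deg <= 90:
        raise InvalidInputError("halfwidth must be in (0, 90] degrees")
    s = sample.folded()
    if s.angles.size == 0:
        raise EmptyInputError("empty angle sample")
    mask = np.abs(s.angles) <= halfwidth_deg
    return float(s.weights[mask].sum() / s.weights.sum())


def asymmetry_index(sample: AngularSample) -> float:
    """Axial asymmetry A = f_axial - f_perp in [-1, 1].

    f_axial is the weighted fraction of folded angles within ±45° of the
    axis and f_perp = 1 - f_axial, mirroring the axial-vs-perpendicular
    colour coding of directionality maps.  A = 0 for uniform angles, 1 for
    a fully axial array, -1 for a fully perpendicular one.
    """
    f_axial = fraction_within(sample, 45.0)
    return 2.0 * f_axial - 1.0


def track_growth_stats(tracks) -> pd.DataFrame:
    """Per-track growth speed (μm/min), duration (s) and net direction.

    Speed uses the full path length over the track duration (robust to
    curved growth); net direction is the first-to-last displacement bearing
    in the directed convention, relative to nothing (absolute degrees) —
    pass a geometry to :func:`angle_to_axis` downstream for axis-relative
    values.  Tracks with < 2 samples are excluded with a warning.
    """
    rows = []
    for tr in tracks:
        try:
            t, x, y = tr.t, tr.x, tr.y
        except AttributeError:
            warnings.warn(f"track {getattr(tr, 'id', '?')} rejected: not a GrowthTrack")
            continue
        if t.size < 2:
            warnings.warn(f"track {tr.id} rejected: fewer than 2 samples")
            continue
        steps = np.hypot(np.diff(x), np.diff(y))
        duration = float(t[-1] - t[0])
        speed = float(steps.sum() / duration * 60.0)  # μm/s -> μm/min
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        direction = math.degrees(math.atan2(dy, dx)) if (dx, dy) != (0.0, 0.0) else float("nan")
        rows.append({"track_id": tr.id, "speed_um_min": speed,
                     "duration_s": duration, "direction_deg": direction})
    return pd.DataFrame(rows, columns=["track_id", "speed_um_min", "duration_s", "direction_deg"])


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_filaments_csv(path) -> list[FilamentTrace]:
    """Read `filament_id, vertex_index, x_um, y_um` CSV."""
    df = pd.read_csv(path)
    out = []
    for fid, g in df.groupby("filament_id", sort=True):
        g = g.sort_values("vertex_index")
        out.append(FilamentTrace(str(fid), g[["x_um", "y_um"]].to_numpy()))
    return out


def write_filaments_csv(filaments, path) -> None:
    rows = [
        {"filament_id": f.id, "vertex_index": i, "x_um": x, "y_um": y}
        for f in filaments
        for i, (x, y) in enumerate(f.vertices)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def read_cell_json(path) -> CellGeometry:
    with open(path) as fh:
        d = json.load(fh)
    return CellGeometry(np.array(d["outline"]), np.array(d["axis"]))


def write_cell_json(geometry: CellGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump({"outline": geometry.outline.tolist(),
                   "axis": geometry.axis.tolist()}, fh)


def read_tracks_csv(path) -> list[GrowthTrack]:
    """Read `track_id, frame, t_s, x_um, y_um` CSV."""
    df = pd.read_csv(path)
    out = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        out.append(GrowthTrack(str(tid), g["t_s"].to_numpy(),
                               g["x_um"].to_numpy(), g["y_um"].to_numpy()))
    return out


def write_tracks_csv(tracks, path) -> None:
    rows = [
        {"track_id": tr.id, "frame": i, "t_s": t, "x_um": x, "y_um": y}
        for tr in tracks
        for i, (t, x, y) in enumerate(zip(tr.t, tr.x, tr.y))
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
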