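"""Sliding-event scoring and fluorescence-dissipation analysis.

Photoactivated (or photoconverted) tubulin marks report two things: their
*motion* reveals motor-driven microtubule sliding, and their *intensity
loss* decomposes into depolymerisation, transport out of the region, and
photobleaching.

Sliding events are scored when a mark moves more than 0.5 μm from its rest
position; events faster than 700 nm/s (mean velocity over the event) are
flagged "fast".  Direction classes follow the live-cell scoring rules:
paraxial (net direction within 45° of the cell's long axis, orientation-
agnostic), looping (direction change exceeding 90° within the event), and
off-axis otherwise, with looping taking precedence.

Dissipation is quantified as the half-life of a single-exponential fit to
the bleach-corrected, normalised intensity; comparing the fitted rates of
drug conditions (taxol blocks depolymerisation, azide blocks motors, the
double treatment isolates bleaching) yields the three component rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    AlignmentError,
    DegenerateInputError,
    EmptyInputError,
    InvalidInputError,
)
from .orientation import CellGeometry, fold_undirected

__all__ = [
    "MarkTrajectory",
    "SlidingEvent",
    "DecayFit",
    "DISPLACEMENT_THRESHOLD_UM",
    "FAST_VELOCITY_NM_S",
    "PARAXIAL_HALFWIDTH_DEG",
    "LOOPING_TURN_DEG",
    "detect_events",
    "classify_event",
    "event_frequency",
    "bleach_correct",
    "fit_half_life",
    "dissipation_decomposition",
    "read_marks_csv",
    "write_marks_csv",
    "write_events_csv",
]

# Scoring thresholds for live-cell sliding events.
DISPLACEMENT_THRESHOLD_UM = 0.5   # a mark must leave a 0.5 μm disc to score an event
FAST_VELOCITY_NM_S = 700.0        # mean event velocity above this is a "fast" event
PARAXIAL_HALFWIDTH_DEG = 45.0     # within 45° of the long axis (either tip) = paraxial
LOOPING_TURN_DEG = 90.0           # direction change beyond 90° within an event = looping


@dataclass(frozen=True)
class MarkTrajectory:
    """Track of one photoactivated mark: (t s, x μm, y μm, intensity a.u.).

    ``condition`` is a subset of {"taxol", "azide"} recording drug
    treatments applied before imaging.
    """

    region_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    condition: frozenset = frozenset()

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if not (t.shape == x.shape == y.shape == inten.shape) or t.ndim != 1:
            raise InvalidInputError(f"mark {self.region_id}: misaligned sample arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError(f"mark {self.region_id}: t must be strictly increasing")
        if np.any(inten < 0):
            raise InvalidInputError(f"mark {self.region_id}: negative intensity")
        bad = frozenset(self.condition) - {"taxol", "azide"}
        if bad:
            raise InvalidInputError(f"mark {self.region_id}: unknown condition {bad}")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "condition", frozenset(self.condition))


@dataclass
class SlidingEvent:
    """One scored motility event of a photoactivated mark."""

    region_id: str
    t_start: float
    t_end: float
    path: np.ndarray                  # (n, 2) positions during the event, μm
    displacement_um: float            # max distance from the pre-event rest reference
    mean_velocity_nm_s: float         # path length / duration
    direction_class: str | None = None  # paraxial | off_axis | looping
    start_index: int = 0              # frame index where the event opened

    @property
    def fast(self) -> bool:
        return self.mean_velocity_nm_s > FAST_VELOCITY_NM_S


@dataclass
class DecayFit:
    """Single-exponential fit I(t) = A·exp(-k t) to a dissipation curve."""

    t: np.ndarray
    intensity: np.ndarray
    amplitude: float
    k: float                  # s^-1; <= 0 flags a non-decaying series
    residual_rms: float

    @property
    def half_life(self) -> float:
        """t1/2 = ln2 / k in seconds; inf for a non-decaying series."""
        return math.log(2.0) / self.k if self.k > 0 else math.inf

    @property
    def decaying(self) -> bool:
        return self.k > 0


# ---------------------------------------------------------------------------
# Event detection and classification
# ---------------------------------------------------------------------------

def detect_events(
    trajectory: MarkTrajectory,
    displacement_threshold_um: float = DISPLACEMENT_THRESHOLD_UM,
    noise_floor_um: float = 0.15,
    rest_frames: int = 2,
) -> list[SlidingEvent]:
    """Segment a mark trajectory into sliding events.

    An event opens at the first frame whose distance from the current rest
    reference exceeds ``displacement_threshold_um``, and closes once the
    per-frame step stays below ``noise_floor_um`` for ``rest_frames``
    consecutive frames; the rest reference then re-anchors at the current
    position.  Events are disjoint in time.  The default noise floor is 3×
    a typical 50 nm centroiding precision.

    Mean velocity is the event path length divided by the event duration
    (nm/s); displacement is the maximum excursion from the rest reference.
    """
    t, x, y = trajectory.t, trajectory.x, trajectory.y
    if t.size < 3:
        raise InvalidInputError(f"mark {trajectory.region_id}: need >= 3 samples")
    pos = np.column_stack([x, y])
    steps = np.hypot(*np.diff(pos, axis=0).T)  # steps[k] = |pos[k+1] - pos[k]|
    events: list[SlidingEvent] = []
    ref = pos[0]
    anchor = 0  # frame where the current rest reference was set
    i = 1
    n = t.size
    while i < n:
        if np.hypot(*(pos[i] - ref)) <= displacement_threshold_um:
            i += 1
            continue
        # threshold crossed at frame i: walk back to the motion onset (the
        # last rest frame before a run of supra-noise steps)
        onset = i - 1
        while onset > anchor and steps[onset - 1] >= noise_floor_um:
            onset -= 1
        # walk forward to the close: `rest_frames` consecutive quiet steps
        quiet = 0
        j = i
        while j < n - 1:
            quiet = quiet + 1 if steps[j] < noise_floor_um else 0
            j += 1
            if quiet >= rest_frames:
                break
        motion_end = max(j - quiet, i)  # trim the quiet tail off the motion
        seg = pos[onset : motion_end + 1]
        path_len = float(np.hypot(*np.diff(seg, axis=0).T).sum())
        duration = float(t[motion_end] - t[onset])
        excursion = float(np.max(np.hypot(*(seg - pos[onset]).T)))
        events.append(
            SlidingEvent(
                region_id=trajectory.region_id,
                t_start=float(t[onset]),
                t_end=float(t[motion_end]),
                path=seg,
                displacement_um=excursion,
                mean_velocity_nm_s=path_len / duration * 1000.0 if duration > 0 else 0.0,
                start_index=onset + 1,
            )
        )
        ref = pos[j]
        anchor = j
        i = j + 1
    return events


def classify_event(event: SlidingEvent, geometry: CellGeometry,
                   direction_window_um: float = 0.4) -> str:
    """Assign a direction class: looping > paraxial > off_axis.

    Looping: the maximum change between any two instantaneous direction
    estimates within the event exceeds 90°.  Otherwise paraxial if the net
    direction lies within 45° of the long axis (folded, so movement toward
    either cell tip counts), else off-axis.

    Instantaneous directions are estimated over sliding displacement
    windows of at least ``direction_window_um`` (frame-to-frame headings at
    the localisation-noise scale are dominated by noise, not motion).
    """
    path = np.asarray(event.path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise DegenerateInputError("event path needs >= 2 points")
    vecs = []
    i = 0
    while i < path.shape[0] - 1:
        j = i + 1
        while j < path.shape[0] and np.hypot(*(path[j] - path[i])) < direction_window_um:
            j += 1
        if j >= path.shape[0]:
            break
        vecs.append(path[j] - path[i])
        i = j
    if not vecs:
        # event smaller than the window: fall back to the net displacement
        vecs = [path[-1] - path[0]]
    steps = np.array(vecs)
    lengths = np.hypot(*steps.T)
    moving = lengths > 1e-9
    if not moving.any():
        raise DegenerateInputError("event path has no net motion")
    headings = np.degrees(np.arctan2(steps[moving, 1], steps[moving, 0]))
    # max pairwise angular separation on the circle
    if headings.size > 1:
        diffs = np.abs((headings[:, None] - headings[None, :] + 180.0) % 360.0 - 180.0)
        if diffs.max() > LOOPING_TURN_DEG:
            return "looping"
    net = path[-1] - path[0]
    if np.hypot(*net) <= 1e-9:
        return "looping"  # returned to origin without a net direction
    net_dir = math.degrees(math.atan2(net[1], net[0]))
    rel = abs(fold_undirected(net_dir - geometry.axis_angle_deg))
    return "paraxial" if rel <= PARAXIAL_HALFWIDTH_DEG else "off_axis"


def event_frequency(events, n_regions: int, observed_time_min: float) -> dict:
    """Event rates in events·region⁻¹·min⁻¹, overall, per class and fast-only."""
    if n_regions < 1:
        raise InvalidInputError("n_regions must be >= 1")
    if observed_time_min <= 0:
        raise InvalidInputError("observed time must be > 0")
    events = list(events)
    denom = n_regions * observed_time_min
    per_class: dict[str, float] = {}
    for ev in events:
        if ev.direction_class is not None:
            per_class[ev.direction_class] = per_class.get(ev.direction_class, 0.0) + 1
    return {
        "rate": len(events) / denom,
        "fast_rate": sum(ev.fast for ev in events) / denom,
        "per_class": {k: v / denom for k, v in sorted(per_class.items())},
    }


# ---------------------------------------------------------------------------
# Dissipation
# ---------------------------------------------------------------------------

def _normalise(series: np.ndarray) -> np.ndarray:
    series = np.asarray(series, dtype=float)
    if series[0] <= 0:
        raise InvalidInputError("series must start with positive intensity")
    return series / series[0]


def bleach_correct(t, raw, control_t, control) -> np.ndarray:
    """Restore the bleaching loss measured in a taxol+azide control.

    Both series are normalised to their t = 0 value; the control's
    fractional loss is added back: corrected(t) = raw_n(t) + (1 - ctrl_n(t)).
    With no bleaching (control ≡ 1) this is the identity, and
    corrected(0) = 1 always.
    """
    t = np.asarray(t, dtype=float)
    control_t = np.asarray(control_t, dtype=float)
    if t.shape != control_t.shape or not np.allclose(t, control_t):
        raise AlignmentError("raw and control series must share a timebase")
    return _normalise(raw) + (1.0 - _normalise(control))


def fit_half_life(t, intensity) -> DecayFit:
    """Least-squares single-exponential fit I(t) = A·exp(-k t).

    The fit is on the linear scale with free amplitude (no offset term), so
    low-intensity noise is not log-amplified.  A non-decaying optimum is
    reported with k <= 0 and half_life = inf, not raised.
    """
    t = np.asarray(t, dtype=float)
    I = np.asarray(intensity, dtype=float)
    if t.size != I.size or t.size < 5:
        raise InvalidInputError("need >= 5 aligned time points")
    if np.any(I <= 0):
        raise InvalidInputError("intensities must be > 0 for the decay fit")
    # log-linear initial guess
    slope, icept = np.polyfit(t, np.log(I), 1)
    k0, A0 = -slope, math.exp(icept)
    if k0 <= 0:
        fitted = A0 * np.exp(slope * t)
        rms = float(np.sqrt(np.mean((fitted - I) ** 2)))
        return DecayFit(t=t, intensity=I, amplitude=A0, k=k0, residual_rms=rms)
    try:
        popt, _ = curve_fit(
            lambda tt, A, k: A * np.exp(-k * tt), t, I,
            p0=(A0, k0), maxfev=10000,
        )
        A, k = float(popt[0]), float(popt[1])
    except RuntimeError:
        A, k = A0, k0
    rms = float(np.sqrt(np.mean((A * np.exp(-k * t) - I) ** 2)))
    return DecayFit(t=t, intensity=I, amplitude=A, k=k, residual_rms=rms)


def dissipation_decomposition(fits: dict) -> dict:
    """Decompose dissipation rates into depolymerisation/transport/bleach.

    ``fits`` maps condition names {"none", "taxol", "azide", "taxol+azide"}
    to :class:`DecayFit`.  Taxol suppresses depolymerisation and azide
    suppresses motor transport, so:

        k_bleach    = k(taxol+azide)
        k_transport = k(taxol) - k_bleach
        k_depoly    = k(azide) - k_bleach

    The consistency residual k(none) - (k_d + k_t + k_b) is reported; a
    component more negative than ``tol`` triggers a warning (not an error),
    since fit noise can push a true-zero rate slightly negative.
    """
    required = {"none", "taxol", "azide", "taxol+azide"}
    missing = required - set(fits)
    if missing:
        raise InvalidInputError(f"missing condition fits: {sorted(missing)}")
    k_bleach = fits["taxol+azide"].k
    k_transport = fits["taxol"].k - k_bleach
    k_depoly = fits["azide"].k - k_bleach
    residual = fits["none"].k - (k_depoly + k_transport + k_bleach)
    tol = 1e-9
    for name, val in (("k_depoly", k_depoly), ("k_transport", k_transport),
                      ("k_bleach", k_bleach)):
        if val < -tol:
            warnings.warn(f"inconsistent decomposition: {name} = {val:.3e} s^-1 < 0")
    return {
        "k_depoly": k_depoly,
        "k_transport": k_transport,
        "k_bleach": k_bleach,
        "consistency_residual": residual,
    }


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_marks_csv(path) -> list[MarkTrajectory]:
    """Read `region_id, frame, t_s, x_um, y_um, intensity, condition` CSV.

    ``condition`` holds '+'-joined drug names or is empty/NaN for untreated.
    """
    df = pd.read_csv(path)
    out = []
    for rid, g in df.groupby("region_id", sort=True):
        g = g.sort_values("t_s")
        cond = g["condition"].iloc[0] if "condition" in g else ""
        cond = "" if pd.isna(cond) else str(cond)
        parts = frozenset(p for p in cond.split("+") if p)
        out.append(
            MarkTrajectory(str(rid), g["t_s"].to_numpy(), g["x_um"].to_numpy(),
                           g["y_um"].to_numpy(), g["intensity"].to_numpy(), parts)
        )
    return out


def write_marks_csv(marks, path) -> None:
    rows = [
        {"region_id": m.region_id, "frame": i, "t_s": t, "x_um": x,
         "y_um": y, "intensity": inten,
         "condition": "+".join(sorted(m.condition))}
        for m in marks
        for i, (t, x, y, inten) in enumerate(zip(m.t, m.x, m.y, m.intensity))
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def write_events_csv(events, path) -> None:
    rows = [
        {"region_id": ev.region_id, "t_start_s": ev.t_start, "t_end_s": ev.t_end,
         "displacement_um": ev.displacement_um,
         "velocity_nm_s": ev.mean_velocity_nm_s,
         "class": ev.direction_class or "", "fast": ev.fast}
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
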