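"""In vitro assay analysis: zippering encounters, gliding mechanics, bundles.

Dynamic microtubules grown from immobilised seeds occasionally encounter
one another; a crosslinker can "zipper" the incoming filament onto the
other's lattice so that the pair co-aligns into a bundle propagating from
the contact point.  An encounter is characterised by the incident angle α
between the two growth directions at contact (α > 90° means the plus ends
point opposite ways: an antiparallel encounter) and is classified zippered
when post-contact co-alignment extends at least 2 μm from the contact.

Gliding assays (motor-coated surface) discriminate single microtubules,
which glide persistently, from crosslinked bundles, in which opposing motor
forces cancel: bundles stay static until, occasionally, they are driven
apart.  Bundle survival against motor forces is scored over an observation
horizon with censoring for bundles that leave the field or dissociate
intact.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point

from .errors import (
    AnnotationError,
    DegenerateInputError,
    EmptyInputError,
    InvalidInputError,
)

__all__ = [
    "Encounter",
    "GlidingObject",
    "MIN_COALIGN_UM",
    "COALIGN_GAP_UM",
    "BUNDLE_RATIO_THRESHOLD",
    "BUNDLE_LEN_CELL_UM",
    "BUNDLE_LEN_INVITRO_UM",
    "encounter_angle",
    "classify_outcome",
    "zippering_histogram",
    "encounter_lengths",
    "shallow_angle_filter",
    "gliding_speeds",
    "bundle_survival",
    "score_bundles",
    "read_encounters_geometry_json",
    "write_encounters_geometry_json",
    "write_encounters_csv",
    "read_gliding_csv",
    "write_gliding_csv",
]

MIN_COALIGN_UM = 2.0        # bundling must extend >= 2 μm from the contact point
COALIGN_GAP_UM = 0.15       # smoothed inter-filament distance counted as "bundled"
COALIGN_SMOOTH_UM = 0.6     # moving-average window damping tracing noise
TANGENT_ARC_UM = 0.5        # arc over which contact tangents are averaged
BUNDLE_RATIO_THRESHOLD = 3.0  # intensity ratio to a single microtubule
BUNDLE_LEN_CELL_UM = 2.3      # elongated-region length threshold, cell preset
BUNDLE_LEN_INVITRO_UM = 2.0   # in vitro preset


@dataclass
class Encounter:
    """A seed-anchored filament pair meeting at a contact point.

    Polylines run from the seed anchor (vertex 0) toward the plus end
    (last vertex); ``contact`` lies on both polylines.  Derived attributes
    (angle, orientation, outcome, co-aligned length) are filled by the
    classification operations; generators may pre-fill them as ground truth.
    """

    id: str
    filament_A: np.ndarray           # (n, 2) μm, seed -> plus end
    filament_B: np.ndarray
    contact: np.ndarray              # (2,) μm
    angle_deg: float | None = None
    orientation: str | None = None   # parallel | antiparallel
    outcome: str | None = None       # zippered | crossed
    coaligned_um: float | None = None
    crossovers_A: np.ndarray | None = None  # arc positions (μm from seed) of prior crossovers
    crossovers_B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.filament_A = np.asarray(self.filament_A, dtype=float)
        self.filament_B = np.asarray(self.filament_B, dtype=float)
        self.contact = np.asarray(self.contact, dtype=float)
        for name, poly in (("A", self.filament_A), ("B", self.filament_B)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
                raise InvalidInputError(f"encounter {self.id}: filament {name} needs >= 2 vertices")


@dataclass
class GlidingObject:
    """One tracked object in a gliding assay: a single MT or a bundle."""

    id: str
    type: str                        # single | bundle
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    separated: bool = False          # bundle driven apart by motor forces
    censored: bool = False           # left field / dissociated intact: not scored
    survival_time: float | None = None  # s; time of separation, or horizon if intact

    def __post_init__(self) -> None:
        if self.type not in ("single", "bundle"):
            raise InvalidInputError(f"object {self.id}: unknown type {self.type!r}")
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def instantaneous_speeds_nm_s(self) -> np.ndarray:
        """Frame-to-frame displacement over interval, nm/s."""
        if self.t.size < 2:
            return np.empty(0)
        d = np.hypot(np.diff(self.x), np.diff(self.y))
        return d / np.diff(self.t) * 1000.0


# ---------------------------------------------------------------------------
# Encounter geometry
# ---------------------------------------------------------------------------

def _arc_coords(poly: np.ndarray) -> np.ndarray:
    """Cumulative arc length (μm from the seed) at each vertex."""
    return np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(poly, axis=0).T))])


def _arc_of_point(poly: np.ndarray, point: np.ndarray, tol: float = 0.2) -> float:
    line = LineString(poly)
    p = Point(point)
    if line.distance(p) > tol:
        raise InvalidInputError("contact point does not lie on the polyline")
    return float(line.project(p))


def _point_at_arc(poly: np.ndarray, s: float) -> np.ndarray:
    p = LineString(poly).interpolate(s)
    return np.array([p.x, p.y])


def _tangent_before(poly: np.ndarray, s_contact: float, arc: float = TANGENT_ARC_UM) -> np.ndarray:
    """Unit growth-direction tangent averaged over the arc approaching contact.

    The incoming direction (the ``arc`` μm of lattice grown just before the
    contact) defines the incident geometry even when the filament bends at
    the contact, e.g. after zippering.
    """
    s0 = max(0.0, s_contact - arc)
    if s_contact - s0 < 1e-9:
        # contact at the seed: use the outgoing direction instead
        a, b = _point_at_arc(poly, 0.0), _point_at_arc(poly, min(arc, _arc_coords(poly)[-1]))
    else:
        a, b = _point_at_arc(poly, s0), _point_at_arc(poly, s_contact)
    d = b - a
    norm = np.hypot(*d)
    if norm == 0:
        raise DegenerateInputError("cannot define a tangent at the contact")
    return d / norm


def encounter_angle(filament_A: np.ndarray, filament_B: np.ndarray, contact) -> float:
    """Incident angle α between growth-direction tangents at contact, [0°, 180°]."""
    filament_A = np.asarray(filament_A, dtype=float)
    filament_B = np.asarray(filament_B, dtype=float)
    contact = np.asarray(contact, dtype=float)
    tA = _tangent_before(filament_A, _arc_of_point(filament_A, contact))
    tB = _tangent_before(filament_B, _arc_of_point(filament_B, contact))
    cosang = float(np.clip(np.dot(tA, tB), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _coaligned_length(follower: np.ndarray, lattice: np.ndarray, contact: np.ndarray,
                      gap_um: float = COALIGN_GAP_UM, step_um: float = 0.05,
                      smooth_um: float = COALIGN_SMOOTH_UM) -> float:
    """Arc length of the follower beyond contact staying near the lattice.

    The follower is sampled every ``step_um`` beyond the contact; the
    point-to-lattice distances are smoothed with a forward moving average
    over ``smooth_um`` (damping independent per-vertex tracing noise) and
    the run ends at the first smoothed distance above ``gap_um``.
    """
    line = LineString(lattice)
    fl = LineString(follower)
    s0 = _arc_of_point(follower, contact)
    total = _arc_coords(follower)[-1]
    if total - s0 < step_um:
        return 0.0
    ss = np.arange(s0 + step_um, total + 1e-9, step_um)
    pts = shapely.line_interpolate_point(fl, ss)
    d = shapely.distance(line, pts)
    w = max(1, int(round(smooth_um / step_um)))
    if w > 1 and d.size:
        padded = np.concatenate([d, np.full(w - 1, d[-1])])
        d = np.convolve(padded, np.ones(w) / w, mode="valid")[: d.size]
    over = np.nonzero(d > gap_um)[0]
    end = int(over[0]) if over.size else d.size
    return 0.0 if end == 0 else float(ss[end - 1] - s0)


def classify_outcome(
    encounter: Encounter,
    min_coalign_um: float = MIN_COALIGN_UM,
    gap_um: float = COALIGN_GAP_UM,
) -> Encounter:
    """Classify an encounter as zippered or crossed and fill derived fields.

    Zippering requires post-contact co-alignment (inter-filament distance
    below ``gap_um``) for at least ``min_coalign_um`` measured along the
    incoming filament from the contact point.  Orientation follows the
    incident angle: antiparallel iff α > 90°.  The polarity rule is implied
    by measuring co-alignment along each filament's growth direction: for a
    parallel pair the follower's run heads toward the partner's plus end;
    for an antiparallel pair it continues along the partner's lattice toward
    its minus end, i.e. both plus ends keep growing along the other lattice.
    """
    alpha = encounter_angle(encounter.filament_A, encounter.filament_B, encounter.contact)
    orientation = "antiparallel" if alpha > 90.0 else "parallel"
    co_B = _coaligned_length(encounter.filament_B, encounter.filament_A,
                             encounter.contact, gap_um)
    co_A = _coaligned_length(encounter.filament_A, encounter.filament_B,
                             encounter.contact, gap_um)
    coaligned = max(co_A, co_B)
    encounter.angle_deg = alpha
    encounter.orientation = orientation
    encounter.coaligned_um = coaligned
    encounter.outcome = "zippered" if coaligned >= min_coalign_um else "crossed"
    return encounter


def zippering_histogram(encounters, bin_edges=None) -> pd.DataFrame:
    """Per-angle-bin encounter counts and zippering fractions.

    Default bins: every 10° from 0° to 180°.  An empty bin's fraction is
    reported as NaN (undefined), never 0.
    """
    encounters = list(encounters)
    if bin_edges is None:
        bin_edges = np.arange(0.0, 181.0, 10.0)
    bin_edges = np.asarray(bin_edges, dtype=float)
    alphas = np.array([e.angle_deg for e in encounters], dtype=float)
    if np.any(np.isnan(alphas)):
        raise AnnotationError("classify encounters before histogramming")
    if alphas.size and (alphas.min() < 0 or alphas.max() > 180):
        raise InvalidInputError("encounter angles must lie in [0, 180] degrees")
    zipped = np.array([e.outcome == "zippered" for e in encounters])
    idx = np.clip(np.digitize(alphas, bin_edges) - 1, 0, len(bin_edges) - 2)
    n = np.bincount(idx, minlength=len(bin_edges) - 1)
    nz = np.bincount(idx, weights=zipped.astype(float), minlength=len(bin_edges) - 1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, nz / np.maximum(n, 1), np.nan)
    return pd.DataFrame({
        "bin_left_deg": bin_edges[:-1],
        "bin_right_deg": bin_edges[1:],
        "n": n.astype(int),
        "n_zippered": nz.astype(int),
        "fraction": frac,
    })


def encounter_lengths(encounter: Encounter) -> tuple[float, float]:
    """Arc length from the contact to each filament's seed or nearest prior
    crossover, whichever is closer (μm)."""
    out = []
    for poly, crossings in (
        (encounter.filament_A, encounter.crossovers_A),
        (encounter.filament_B, encounter.crossovers_B),
    ):
        s = _arc_of_point(poly, encounter.contact)
        dist = s  # to the seed
        if crossings is not None:
            prior = np.asarray(crossings, dtype=float)
            prior = prior[prior < s]
            if prior.size:
                dist = min(dist, float(s - prior.max()))
        out.append(dist)
    return out[0], out[1]


def shallow_angle_filter(encounters, lo: float = 10.0, hi: float = 30.0):
    """Select unsuccessful (crossed) encounters at shallow incident angles.

    α is folded about 90°, keeping [lo, hi] ∪ [180-hi, 180-lo]: near-parallel
    and near-antiparallel grazing encounters, the geometry where zippering
    would have been possible.
    """
    keep = []
    for e in encounters:
        if e.angle_deg is None or e.outcome is None:
            raise AnnotationError("classify encounters before filtering")
        folded = min(e.angle_deg, 180.0 - e.angle_deg)
        if e.outcome == "crossed" and lo <= folded <= hi:
            keep.append(e)
    return keep


# ---------------------------------------------------------------------------
# Gliding assay
# ---------------------------------------------------------------------------

def gliding_speeds(objects) -> dict:
    """Instantaneous speeds pooled per object type, plus per-object means.

    Single-frame tracks are excluded with a warning.
    """
    pooled: dict[str, list] = {}
    per_object = []
    for obj in objects:
        speeds = obj.instantaneous_speeds_nm_s
        if speeds.size == 0:
            warnings.warn(f"object {obj.id}: single-frame track excluded")
            continue
        pooled.setdefault(obj.type, []).append(speeds)
        per_object.append({"object_id": obj.id, "type": obj.type,
                           "mean_speed_nm_s": float(speeds.mean())})
    return {
        "speeds": {k: np.concatenate(v) for k, v in pooled.items()},
        "per_object": pd.DataFrame(per_object,
                                   columns=["object_id", "type", "mean_speed_nm_s"]),
        "mean_by_type": {k: float(np.concatenate(v).mean()) for k, v in pooled.items()},
    }


def bundle_survival(bundles, horizon_s: float) -> float | None:
    """Fraction of bundles intact at the horizon among scoreable bundles.

    Bundles that left the field or dissociated as intact bundles are
    censored and excluded from both numerator and denominator.  Returns
    None when every bundle is censored.
    """
    intact = separated = 0
    for b in bundles:
        if b.type != "bundle":
            continue
        if b.censored:
            continue
        st = b.survival_time if b.survival_time is not None else math.inf
        if b.separated and st <= horizon_s:
            separated += 1
        else:
            intact += 1
    total = intact + separated
    return intact / total if total else None


def score_bundles(
    regions,
    len_threshold_um: float = BUNDLE_LEN_CELL_UM,
    ratio_threshold: float = BUNDLE_RATIO_THRESHOLD,
) -> int:
    """Count elongated regions scoring as bundles.

    A region scores when its length exceeds ``len_threshold_um`` AND its
    intensity ratio to a single microtubule exceeds ``ratio_threshold``.
    Presets: 2.3 μm for the in-cell assay (``BUNDLE_LEN_CELL_UM``), 2 μm
    for the in vitro assay (``BUNDLE_LEN_INVITRO_UM``).
    """
    count = 0
    for length, ratio in regions:
        if ratio < 0:
            raise InvalidInputError("intensity ratio must be >= 0")
        if length > len_threshold_um and ratio > ratio_threshold:
            count += 1
    return count


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def write_encounters_geometry_json(encounters, path) -> None:
    data = [
        {
            "id": e.id,
            "filament_A": e.filament_A.tolist(),
            "filament_B": e.filament_B.tolist(),
            "contact": e.contact.tolist(),
            "crossovers_A": None if e.crossovers_A is None else np.asarray(e.crossovers_A).tolist(),
            "crossovers_B": None if e.crossovers_B is None else np.asarray(e.crossovers_B).tolist(),
        }
        for e in encounters
    ]
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_encounters_geometry_json(path) -> list[Encounter]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        Encounter(
            id=d["id"],
            filament_A=np.array(d["filament_A"]),
            filament_B=np.array(d["filament_B"]),
            contact=np.array(d["contact"]),
            crossovers_A=None if d.get("crossovers_A") is None else np.array(d["crossovers_A"]),
            crossovers_B=None if d.get("crossovers_B") is None else np.array(d["crossovers_B"]),
        )
        for d in data
    ]


def write_encounters_csv(encounters, path) -> None:
    rows = []
    for e in encounters:
        lenA, lenB = encounter_lengths(e)
        rows.append({
            "encounter_id": e.id, "angle_deg": e.angle_deg,
            "orientation": e.orientation,
            "zippered": e.outcome == "zippered",
            "coaligned_um": e.coaligned_um,
            "len_A_um": lenA, "len_B_um": lenB,
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def write_gliding_csv(objects, tracks_path, meta_path=None) -> None:
    rows = [
        {"object_id": o.id, "type": o.type, "frame": i, "t_s": t,
         "x_um": x, "y_um": y}
        for o in objects
        for i, (t, x, y) in enumerate(zip(o.t, o.x, o.y))
    ]
    pd.DataFrame(rows).to_csv(tracks_path, index=False, float_format="%.9g")
    if meta_path is not None:
        meta = {
            o.id: {"separated": o.separated, "censored": o.censored,
                   "survival_time_s": o.survival_time}
            for o in objects
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh)


def read_gliding_csv(tracks_path, meta_path=None) -> list[GlidingObject]:
    df = pd.read_csv(tracks_path)
    meta = {}
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
    out = []
    for (oid, otype), g in df.groupby(["object_id", "type"], sort=True):
        g = g.sort_values("t_s")
        m = meta.get(str(oid), {})
        out.append(GlidingObject(
            id=str(oid), type=str(otype),
            t=g["t_s"].to_numpy(), x=g["x_um"].to_numpy(), y=g["y_um"].to_numpy(),
            separated=bool(m.get("separated", False)),
            censored=bool(m.get("censored", False)),
            survival_time=m.get("survival_time_s"),
        ))
    return out
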