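"""Seeded generators for every input class the pipeline consumes.

Each generator emulates one measurement the pipeline analyses, with the
acquisition conditions of the live-cell and in vitro experiments baked into
the defaults (3 s frame interval over 120 s for plus-end imaging, 250 μl
gradient fractions from a 5 ml gradient, 7.5 min gliding observation, ...)
and returns ground-truth labels alongside the records so every downstream
operation can be tested for parameter recovery.

Randomness is controlled by one root seed: each generator draws from its
own child stream (a fixed spawn key per generator), so adding a generator
or changing the number of draws in one never perturbs the others, and an
identical config reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError
from .hydrodynamics import GradientProfile
from .invitro import Encounter, GlidingObject
from .morphology import CellRecord
from .motility import MarkTrajectory
from .orientation import CellGeometry, FilamentTrace, GrowthTrack

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "default_zipper_prob_parallel",
    "default_zipper_prob_antiparallel",
    "gen_filament_network",
    "gen_growth_tracks",
    "gen_mark_trajectories",
    "gen_encounters",
    "gen_gliding_tracks",
    "gen_gradient_profile",
    "gen_standard_profiles",
    "gen_cell_records",
]

# child-stream spawn keys, one per generator (append-only)
_STREAMS = {
    "filaments": 1,
    "growth": 2,
    "marks": 3,
    "encounters": 4,
    "gliding": 5,
    "gradient": 6,
    "cells": 7,
}


class GroundTruth(dict):
    """Ground-truth labels for one generated dataset (a keyed mapping)."""


def default_zipper_prob_parallel(alpha_deg: float) -> float:
    """Zippering probability for parallel encounters (α <= 90°).

    The crosslinker can only bend a filament by a limited angle, so
    zippering is restricted to shallow encounters: no zippering above 25°.
    Parallel zippering is the less efficient mode.
    """
    return 0.25 if alpha_deg <= 25.0 else 0.0


def default_zipper_prob_antiparallel(alpha_deg: float) -> float:
    """Zippering probability for antiparallel encounters (α > 90°).

    Shallow antiparallel geometry means α close to 180°; the crosslinker
    strongly prefers this orientation: no zippering below 150°.
    """
    return 0.85 if alpha_deg >= 150.0 else 0.0


@dataclass(frozen=True)
class SynthConfig:
    """All generator parameters, validated on construction.

    Rates are per second unless noted; lengths in μm, velocities in nm/s
    unless noted.  Identical configs (including ``seed``) yield
    bit-identical output.
    """

    seed: int = 0

    # cell geometry and filament network
    cell_length: float = 100.0        # μm, tip-to-tip (elongated 48 h myoblast scale)
    cell_aspect: float = 8.0          # length / width, >= 1
    kappa: float = 4.0                # von Mises concentration of filament orientations
    n_filaments: int = 100

    # plus-end growth tracks
    frame_interval: float = 3.0       # s (EB imaging cadence)
    duration: float = 120.0           # s
    n_tracks: int = 200
    growth_speed_mean: float = 10.0   # μm/min
    growth_speed_sd: float = 2.0      # μm/min
    aligned_fraction: float = 0.8     # fraction of tracks growing along the axis
    growth_angle_sd_deg: float = 15.0  # angular noise of aligned tracks
    loc_noise_um: float = 0.05        # isotropic centroiding noise, 50 nm

    # photoactivated marks and sliding events
    n_marks: int = 50
    mark_frame_interval: float = 1.6  # s
    mark_duration: float = 60.0       # s
    slide_rate: float = 0.5           # events per mark per minute
    velocity_logmean: float = math.log(400.0)  # ln(nm/s)
    velocity_logsd: float = 0.4
    event_duration_s: float = 15.0    # typical sliding-event duration
    class_probs: tuple = (("paraxial", 0.6), ("off_axis", 0.25), ("looping", 0.15))
    k_depoly: float = 0.010           # s^-1
    k_transport: float = 0.005        # s^-1
    k_bleach: float = 0.002           # s^-1
    intensity_noise: float = 0.01     # multiplicative, per frame

    # in vitro encounters
    n_encounters: int = 200
    encounter_angle_range: tuple = (5.0, 175.0)  # degrees; sub-5° grazes unresolvable
    zipper_prob_parallel: object = default_zipper_prob_parallel
    zipper_prob_antiparallel: object = default_zipper_prob_antiparallel
    vertex_noise_um: float = 0.0      # tracing noise on filament vertices
    vertex_spacing_um: float = 0.2

    # gliding assay
    n_singles: int = 50
    n_bundles: int = 50
    v_glide_mean: float = 600.0       # nm/s, kinesin-1 surface gliding
    v_glide_sd: float = 50.0
    glide_frame_interval: float = 5.0  # s
    glide_duration: float = 450.0     # s (7.5 min observation)
    bundle_breakup_rate: float = 5.5e-4  # s^-1 (~78% of bundles survive 450 s)
    censor_prob: float = 0.1          # bundle leaves field / dissociates intact

    # glycerol gradient
    gradient_slope: float = 0.002     # S per μl
    gradient_intercept: float = 0.35  # S
    peak_width: float = 300.0         # μl (Gaussian sigma)
    fraction_volume: float = 250.0    # μl per fraction, 5 ml gradient
    gradient_noise: float = 0.0       # multiplicative signal noise

    # morphology
    n_cells: int = 300
    cell_length_mean: float = 107.0   # μm (control condition scale)
    cell_length_sd: float = 40.0
    fusion_prob: float = 0.4

    def __post_init__(self) -> None:
        checks = [
            (self.cell_length > 0, "cell_length must be > 0"),
            (self.cell_aspect >= 1, "cell_aspect must be >= 1"),
            (self.kappa >= 0, "kappa must be >= 0"),
            (self.n_filaments >= 1, "n_filaments must be >= 1"),
            (self.frame_interval > 0, "frame_interval must be > 0"),
            (self.duration >= 2 * self.frame_interval,
             "duration must cover >= 2 frames"),
            (self.mark_duration >= 2 * self.mark_frame_interval,
             "mark_duration must cover >= 2 frames"),
            (self.slide_rate >= 0, "slide_rate must be >= 0"),
            (self.k_depoly >= 0 and self.k_transport >= 0 and self.k_bleach >= 0,
             "decay rates must be >= 0"),
            (self.v_glide_mean > 0, "v_glide_mean must be > 0"),
            (self.v_glide_sd >= 0, "v_glide_sd must be >= 0"),
            (self.bundle_breakup_rate >= 0, "bundle_breakup_rate must be >= 0"),
            (self.gradient_slope != 0, "gradient_slope must be nonzero"),
            (self.peak_width > 0, "peak_width must be > 0"),
            (0 <= self.aligned_fraction <= 1, "aligned_fraction must be in [0, 1]"),
            (self.loc_noise_um >= 0, "loc_noise_um must be >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidConfigError(msg)
        total = sum(p for _, p in self.class_probs)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise InvalidConfigError("class_probs must sum to 1")
        if any(p < 0 for _, p in self.class_probs):
            raise InvalidConfigError("class_probs must be >= 0")
        for f in (self.zipper_prob_parallel, self.zipper_prob_antiparallel):
            for a in (0.0, 45.0, 90.0, 135.0, 180.0):
                p = f(a)
                if not 0.0 <= p <= 1.0:
                    raise InvalidConfigError(f"zippering probability {p} at {a}° outside [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Child RNG for one generator, derived from the root seed."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Filament network
# ---------------------------------------------------------------------------

def _axial_von_mises(rng: np.random.Generator, kappa: float, n: int) -> np.ndarray:
    """Axial angles θ (degrees, (-90, 90]) via the doubled-angle construction.

    φ ~ VM(0, κ) on (-π, π], θ = φ/2: κ = 0 gives uniform orientations and
    large κ concentrates θ around the axis with circular SD ≈ 1/(2√κ) rad.
    """
    phi = rng.vonmises(0.0, kappa, size=n)
    theta = np.degrees(phi / 2.0)
    return np.where(theta == -90.0, 90.0, theta)


def gen_filament_network(config: SynthConfig):
    """Synthesise a traced microtubule network inside an elongated cell.

    The cell outline is an ellipse of tip-to-tip length ``cell_length`` and
    aspect ratio ``cell_aspect``, the axis its major diameter.  Filament
    orientations are axial von Mises around the axis with concentration
    ``kappa``; filaments are straight polylines (vertex every ~1 μm)
    clipped to the outline.

    Returns (CellGeometry, list[FilamentTrace], GroundTruth).
    """
    rng = config.rng("filaments")
    a = config.cell_length / 2.0
    b = a / config.cell_aspect
    phi = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
    outline = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    geometry = CellGeometry(outline=outline, axis=np.array([[-a, 0.0], [a, 0.0]]))

    thetas = _axial_von_mises(rng, config.kappa, config.n_filaments)
    filaments = []
    for i, theta in enumerate(thetas):
        c, s = math.cos(math.radians(theta)), math.sin(math.radians(theta))
        # rejection-sample a centre, then clip the segment to the ellipse
        for _ in range(1000):
            x0 = rng.uniform(-a, a)
            y0 = rng.uniform(-b, b)
            if (x0 / a) ** 2 + (y0 / b) ** 2 >= 0.95:
                continue
            # (x0 + t c)^2/a^2 + (y0 + t s)^2/b^2 = 1  ->  quadratic in t
            A = (c / a) ** 2 + (s / b) ** 2
            B = 2 * (x0 * c / a**2 + y0 * s / b**2)
            C = (x0 / a) ** 2 + (y0 / b) ** 2 - 1.0
            disc = B * B - 4 * A * C
            t_lo = (-B - math.sqrt(disc)) / (2 * A)
            t_hi = (-B + math.sqrt(disc)) / (2 * A)
            want = rng.uniform(2.0, 8.0) / 2.0
            half = min(want, 0.95 * min(-t_lo, t_hi))
            if half >= 0.5:
                break
        n_seg = max(2, int(math.ceil(2 * half)))
        ts = np.linspace(-half, half, n_seg + 1)
        verts = np.column_stack([x0 + ts * c, y0 + ts * s])
        filaments.append(FilamentTrace(id=f"f{i:04d}", vertices=verts))
    truth = GroundTruth(kappa=config.kappa, angles_deg=thetas.tolist())
    return geometry, filaments, truth


# ---------------------------------------------------------------------------
# Growth tracks
# ---------------------------------------------------------------------------

def gen_growth_tracks(config: SynthConfig):
    """Synthesise plus-end growth tracks sampled at the imaging cadence.

    Per-track speed ~ Normal(growth_speed_mean, growth_speed_sd) μm/min
    (truncated at 0.1); a fraction ``aligned_fraction`` of tracks grows
    along the axis (either tip, angular noise ``growth_angle_sd_deg``),
    the rest in uniform directions.  Positions carry isotropic
    localisation noise ``loc_noise_um``.

    Returns (list[GrowthTrack], GroundTruth).
    """
    rng = config.rng("growth")
    n_frames_max = int(config.duration / config.frame_interval)
    tracks, speeds, dirs, aligned_flags = [], [], [], []
    for i in range(config.n_tracks):
        speed = max(0.1, rng.normal(config.growth_speed_mean, config.growth_speed_sd))
        aligned = rng.random() < config.aligned_fraction
        if aligned:
            direction = rng.normal(0.0, config.growth_angle_sd_deg)
            if rng.random() < 0.5:
                direction += 180.0
        else:
            direction = rng.uniform(-180.0, 180.0)
        direction = (direction + 180.0) % 360.0 - 180.0
        n_frames = int(rng.integers(2, n_frames_max + 1))
        t = np.arange(n_frames) * config.frame_interval
        v_um_s = speed / 60.0
        dx = v_um_s * math.cos(math.radians(direction))
        dy = v_um_s * math.sin(math.radians(direction))
        x0, y0 = rng.uniform(-25.0, 25.0, size=2)
        x = x0 + dx * t + rng.normal(0.0, config.loc_noise_um, n_frames)
        y = y0 + dy * t + rng.normal(0.0, config.loc_noise_um, n_frames)
        tracks.append(GrowthTrack(id=f"t{i:04d}", t=t, x=x, y=y))
        speeds.append(speed)
        dirs.append(direction)
        aligned_flags.append(bool(aligned))
    truth = GroundTruth(speeds_um_min=speeds, directions_deg=dirs, aligned=aligned_flags)
    return tracks, truth


# ---------------------------------------------------------------------------
# Photoactivated marks
# ---------------------------------------------------------------------------

def _total_rate(config: SynthConfig, condition: frozenset) -> float:
    kd = 0.0 if "taxol" in condition else config.k_depoly
    kt = 0.0 if "azide" in condition else config.k_transport
    return kd + kt + config.k_bleach


def gen_mark_trajectories(config: SynthConfig, condition: frozenset = frozenset()):
    """Synthesise photoactivated-mark trajectories with injected events.

    Marks rest at their activation site (localisation noise only) except
    during injected sliding events: the event count per mark is
    Poisson(slide_rate × duration), velocities are log-normal, directions
    follow the class mix (paraxial along the axis, off-axis at 50–90°,
    looping with a >90° mid-event turn).  Event velocity and duration are
    floored so every injected event exceeds the 0.5 μm scoring threshold.
    Intensity decays as exp(-(k_depoly+k_transport+k_bleach)·t) with the
    drug condition zeroing the corresponding rate (taxol: depolymerisation;
    azide: transport).

    Returns (list[MarkTrajectory], GroundTruth).
    """
    rng = config.rng("marks")
    condition = frozenset(condition)
    dt = config.mark_frame_interval
    n_frames = int(config.mark_duration / dt) + 1
    t = np.arange(n_frames) * dt
    k_tot = _total_rate(config, condition)
    base_intensity = np.exp(-k_tot * t)
    gap = 3  # rest frames between events (and before the first)

    marks, truth_events = [], []
    for i in range(config.n_marks):
        duration_min = config.mark_duration / 60.0
        k = int(rng.poisson(config.slide_rate * duration_min))
        ev_frames = max(2, int(round(config.event_duration_s / dt)))
        if k > 0:
            avail = n_frames - 1 - (k + 1) * gap
            ev_frames = min(ev_frames, max(2, avail // k))
            while k > 0 and k * ev_frames + (k + 1) * gap > n_frames - 1:
                k -= 1
        # place events: choose start frames with the required gaps
        starts = []
        cursor = gap + 1
        slack = (n_frames - 1) - (k * ev_frames + (k + 1) * gap) if k else 0
        offsets = np.sort(rng.integers(0, slack + 1, size=k)) if k else np.empty(0, int)
        for j in range(k):
            start = cursor + int(offsets[j]) + j * (ev_frames + gap)
            starts.append(start)
        pos = np.zeros((n_frames, 2))
        origin = rng.uniform(-20.0, 20.0, size=2)
        pos[:] = origin
        mark_truth = []
        for start in starts:
            ev_dur = ev_frames * dt
            v_nm_s = float(rng.lognormal(config.velocity_logmean, config.velocity_logsd))
            cls = _sample_class(rng, config.class_probs)
            # floors: per-frame steps must sit clearly above the detector
            # noise floor, and the excursion (pre-turn leg for looping
            # events) must clearly exceed the 0.5 μm scoring threshold
            leg_dur = (ev_frames // 2 if cls == "looping" else ev_frames) * dt
            v_nm_s = max(v_nm_s, 280.0 / dt, 800.0 / max(leg_dur, dt))
            step_um = v_nm_s / 1000.0 * dt
            if cls == "paraxial":
                ang = rng.uniform(-40.0, 40.0) + (180.0 if rng.random() < 0.5 else 0.0)
                headings = [ang] * ev_frames
            elif cls == "off_axis":
                ang = rng.uniform(50.0, 89.0) * (1 if rng.random() < 0.5 else -1)
                ang += 180.0 if rng.random() < 0.5 else 0.0
                headings = [ang] * ev_frames
            else:  # looping: turn by 120-170° halfway through
                ang = rng.uniform(-180.0, 180.0)
                turn = rng.uniform(120.0, 170.0) * (1 if rng.random() < 0.5 else -1)
                half = ev_frames // 2
                headings = [ang] * half + [ang + turn] * (ev_frames - half)
            p = pos[start - 1].copy()
            for j, h in enumerate(headings):
                p = p + step_um * np.array([math.cos(math.radians(h)),
                                            math.sin(math.radians(h))])
                pos[start + j] = p
            pos[start + ev_frames:] = p
            # frame at which the 0.5 μm scoring rule first trips (the
            # event start as the detector defines it)
            rest = pos[start - 1]
            dists = np.hypot(*(pos[start : start + ev_frames] - rest).T)
            crossing = np.nonzero(dists > 0.5)[0]
            score_frame = start + int(crossing[0]) if crossing.size else None
            mark_truth.append({
                "t_start": float(t[start - 1]), "t_end": float(t[start + ev_frames - 1]),
                "start_frame": start, "score_frame": score_frame,
                "velocity_nm_s": v_nm_s, "class": cls,
            })
        noisy = pos + rng.normal(0.0, config.loc_noise_um, pos.shape)
        intensity = base_intensity * (1.0 + rng.normal(0.0, config.intensity_noise, n_frames))
        intensity = np.clip(intensity, 1e-9, None)
        marks.append(MarkTrajectory(
            region_id=f"m{i:04d}", t=t, x=noisy[:, 0], y=noisy[:, 1],
            intensity=intensity, condition=condition,
        ))
        truth_events.append(mark_truth)
    truth = GroundTruth(
        events=truth_events,
        n_events=sum(len(e) for e in truth_events),
        k_total=k_tot,
        half_life_s=(math.log(2.0) / k_tot if k_tot > 0 else math.inf),
        condition=sorted(condition),
    )
    return marks, truth


def _sample_class(rng: np.random.Generator, class_probs) -> str:
    names = [n for n, _ in class_probs]
    probs = np.array([p for _, p in class_probs])
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


# ---------------------------------------------------------------------------
# In vitro encounters
# ---------------------------------------------------------------------------

def gen_encounters(config: SynthConfig):
    """Synthesise seed-anchored filament encounters with known outcomes.

    Incident angles are uniform on [5°, 175°] (tangential sub-5° contacts
    are not resolvable as encounters).  The zippering outcome is Bernoulli
    with the orientation-specific probability at that angle; zippered
    geometries co-align along the partner lattice (30 nm offset) for a
    length drawn in [2.3, 3.8] μm, satisfying the 2 μm rule by
    construction; crossed filaments grow straight through.  Optional
    ``vertex_noise_um`` adds iid tracing noise to every vertex.

    Returns (list[Encounter], GroundTruth).
    """
    rng = config.rng("encounters")
    spacing = config.vertex_spacing_um
    encounters, records = [], []
    lo, hi = config.encounter_angle_range
    if not 0.0 <= lo < hi <= 180.0:
        raise InvalidConfigError("encounter_angle_range must be ordered within [0, 180]")
    for i in range(config.n_encounters):
        alpha = float(rng.uniform(lo, hi))
        orientation = "antiparallel" if alpha > 90.0 else "parallel"
        p = (config.zipper_prob_antiparallel(alpha) if orientation == "antiparallel"
             else config.zipper_prob_parallel(alpha))
        zippered = bool(rng.random() < p)
        d_a = float(rng.uniform(4.2, 7.0))    # seed -> contact along A
        ext_a = float(rng.uniform(4.2, 7.0))  # contact -> A plus end
        d_b = float(rng.uniform(4.2, 7.0))
        contact = np.zeros(2)
        # A grows along +x through the origin
        fil_a = _polyline(np.array([-d_a, 0.0]), np.array([1.0, 0.0]),
                          d_a + ext_a, spacing)
        g_b = np.array([math.cos(math.radians(alpha)), math.sin(math.radians(alpha))])
        pre_b = _polyline(-d_b * g_b, g_b, d_b, spacing)
        if zippered:
            co = float(rng.uniform(2.3, 3.8))
            run_dir = np.array([1.0, 0.0]) if orientation == "parallel" else np.array([-1.0, 0.0])
            co = min(co, (d_a if orientation == "antiparallel" else ext_a) - 0.3)
            offset = np.array([0.0, 0.03 if g_b[1] >= 0 else -0.03])
            run = _polyline(contact + offset, run_dir, co, spacing)
            fil_b = np.vstack([pre_b, run])
        else:
            through = float(rng.uniform(1.5, 3.0))
            post_b = _polyline(contact + spacing * g_b, g_b, through, spacing)
            fil_b = np.vstack([pre_b, post_b])
        if config.vertex_noise_um > 0:
            fil_a = fil_a + rng.normal(0.0, config.vertex_noise_um, fil_a.shape)
            fil_b = fil_b + rng.normal(0.0, config.vertex_noise_um, fil_b.shape)
        encounters.append(Encounter(
            id=f"e{i:04d}", filament_A=fil_a, filament_B=fil_b, contact=contact.copy(),
        ))
        records.append({
            "angle_deg": alpha, "orientation": orientation,
            "zippered": zippered,
            "len_A_um": d_a, "len_B_um": d_b,
        })
    truth = GroundTruth(encounters=records)
    return encounters, truth


def _polyline(start: np.ndarray, direction: np.ndarray, length: float,
              spacing: float) -> np.ndarray:
    n = max(1, int(math.ceil(length / spacing)))
    ts = np.linspace(0.0, length, n + 1)
    return start + np.outer(ts, direction)


# ---------------------------------------------------------------------------
# Gliding assay
# ---------------------------------------------------------------------------

def gen_gliding_tracks(config: SynthConfig):
    """Synthesise gliding-assay tracks for single MTs and bundles.

    Singles glide persistently at a per-object speed ~ Normal(v_glide_mean,
    v_glide_sd) nm/s.  Bundles are static (10 nm jitter) until an
    exponential breakup time at ``bundle_breakup_rate``; a broken bundle is
    recorded as separated with its breakup time and one fragment gliding on
    at single-MT speed.  A fraction ``censor_prob`` of bundles is censored
    (left the field or dissociated intact) and carries no score.

    Returns (list[GlidingObject], GroundTruth).
    """
    rng = config.rng("gliding")
    dt = config.glide_frame_interval
    n_frames = int(config.glide_duration / dt) + 1
    t = np.arange(n_frames) * dt
    objects, truth_singles, truth_bundles = [], [], []
    for i in range(config.n_singles):
        v = max(1.0, rng.normal(config.v_glide_mean, config.v_glide_sd))
        ang = rng.uniform(0.0, 2.0 * math.pi)
        step = v / 1000.0 * dt
        x = step * math.cos(ang) * np.arange(n_frames)
        y = step * math.sin(ang) * np.arange(n_frames)
        objects.append(GlidingObject(id=f"s{i:03d}", type="single", t=t, x=x, y=y))
        truth_singles.append(v)
    for i in range(config.n_bundles):
        breakup = (rng.exponential(1.0 / config.bundle_breakup_rate)
                   if config.bundle_breakup_rate > 0 else math.inf)
        censored = bool(rng.random() < config.censor_prob)
        separated = (not censored) and breakup <= config.glide_duration
        x = rng.normal(0.0, 0.01, n_frames)
        y = rng.normal(0.0, 0.01, n_frames)
        if separated:
            v = max(1.0, rng.normal(config.v_glide_mean, config.v_glide_sd))
            after = t > breakup
            x = x + np.where(after, (t - breakup) * v / 1000.0, 0.0)
        objects.append(GlidingObject(
            id=f"b{i:03d}", type="bundle", t=t, x=x, y=y,
            separated=separated, censored=censored,
            survival_time=(None if censored
                           else float(min(breakup, config.glide_duration))),
        ))
        truth_bundles.append({"breakup_s": float(breakup), "censored": censored})
    truth = GroundTruth(single_speeds_nm_s=truth_singles, bundles=truth_bundles,
                        breakup_rate=config.bundle_breakup_rate)
    return objects, truth


# ---------------------------------------------------------------------------
# Glycerol gradient
# ---------------------------------------------------------------------------

def _gradient_volumes(config: SynthConfig) -> np.ndarray:
    half = config.fraction_volume / 2.0
    return np.arange(half, 5000.0, config.fraction_volume)


def gen_gradient_profile(config: SynthConfig, mass_da: float, true_S: float,
                         rng: np.random.Generator | None = None):
    """Synthesise a fraction profile for a species sedimenting at true_S.

    The peak is Gaussian in volume, centred where the linear gradient map
    slope·v + intercept equals true_S, sampled at the 250 μl fraction
    centres, with optional multiplicative noise.

    Returns (GradientProfile, GroundTruth).
    """
    if rng is None:
        rng = config.rng("gradient")
    v = _gradient_volumes(config)
    centre = (true_S - config.gradient_intercept) / config.gradient_slope
    signal = np.exp(-0.5 * ((v - centre) / config.peak_width) ** 2)
    if config.gradient_noise > 0:
        signal = signal * (1.0 + rng.normal(0.0, config.gradient_noise, v.shape))
    signal = np.clip(signal, 0.0, None)
    profile = GradientProfile(volumes_ul=v, signal=signal, label=f"sample_{true_S:g}S")
    truth = GroundTruth(true_S=true_S, mass_da=mass_da, peak_centre_ul=centre,
                        slope=config.gradient_slope, intercept=config.gradient_intercept)
    return profile, truth


# standard proteins with textbook sedimentation coefficients, all eluting
# within the 5 ml gradient under the default volume->S map
STANDARD_S = (("chymotrypsinogen", 2.5), ("ovalbumin", 3.5), ("BSA", 4.3),
              ("aldolase", 7.3))


def gen_standard_profiles(config: SynthConfig, standards=STANDARD_S):
    """Fraction profiles for calibration standards on the same gradient.

    Returns (list[(label, GradientProfile, known_S)], GroundTruth).
    """
    rng = config.rng("gradient")
    out = []
    for label, s_val in standards:
        prof, _ = gen_gradient_profile(config, mass_da=float("nan"),
                                       true_S=s_val, rng=rng)
        out.append((label, GradientProfile(prof.volumes_ul, prof.signal, label), s_val))
    truth = GroundTruth(standards={label: s for label, _, s in out},
                        slope=config.gradient_slope, intercept=config.gradient_intercept)
    return out, truth


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def gen_cell_records(config: SynthConfig, condition: str = "control",
                     length_mean: float | None = None,
                     length_sd: float | None = None,
                     fusion_prob: float | None = None,
                     rng: np.random.Generator | None = None):
    """Synthesise scored cells: Normal tip-to-tip lengths + fusion labels.

    Nucleus counts are 1-2 for unfused cells and 3-8 for fused ones, with
    fusion Bernoulli(fusion_prob).

    Returns (list[CellRecord], GroundTruth).
    """
    if rng is None:
        rng = config.rng("cells")
    mean = config.cell_length_mean if length_mean is None else length_mean
    sd = config.cell_length_sd if length_sd is None else length_sd
    p_fuse = config.fusion_prob if fusion_prob is None else fusion_prob
    cells = []
    for i in range(config.n_cells):
        length = max(5.0, rng.normal(mean, sd))
        fused = rng.random() < p_fuse
        nuclei = int(rng.integers(3, 9)) if fused else int(rng.integers(1, 3))
        cells.append(CellRecord(cell_id=f"{condition}_c{i:04d}", condition=condition,
                                length_um=float(length), nuclei=nuclei))
    truth = GroundTruth(length_mean=mean, length_sd=sd, fusion_prob=p_fuse,
                        n_cells=config.n_cells)
    return cells, truth
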