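"""Pipeline orchestration: run every analysis stage from one seeded config.

A :class:`RunConfig` selects stages, carries the root seed, synthetic-data
overrides and the scoring thresholds; :func:`run` executes the selected
stages in dependency order on synthetic data (or data loaded from the
configured input paths), writes per-stage outputs plus a consolidated
``summary.json`` and a human-readable ``report.md``, and returns the
summary dictionary.  Given the same config and seed, the summary JSON is
byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import InvalidConfigError
from . import hydrodynamics as hydro
from . import invitro, morphology, motility, orientation, synthetic

logger = logging.getLogger("mtarray")

ALL_STAGES = ("orientation", "motility", "invitro", "hydrodynamics", "morphology")

# Scoring thresholds with their conventional defaults; every value can be
# overridden from the run config.
DEFAULT_THRESHOLDS = {
    "displacement_um": motility.DISPLACEMENT_THRESHOLD_UM,   # 0.5 μm event scoring
    "fast_nm_s": motility.FAST_VELOCITY_NM_S,                # 700 nm/s fast events
    "paraxial_deg": motility.PARAXIAL_HALFWIDTH_DEG,         # 45° paraxial band
    "looping_deg": motility.LOOPING_TURN_DEG,                # 90° direction change
    "min_coalign_um": invitro.MIN_COALIGN_UM,                # 2 μm zippering rule
    "bundle_ratio": invitro.BUNDLE_RATIO_THRESHOLD,          # 3× intensity
    "bundle_len_um": invitro.BUNDLE_LEN_CELL_UM,             # 2.3 μm region length
}

# morphology demo: condition -> (mean length μm, sd, fusion prob, network kappa)
DEMO_CONDITIONS = {
    "control": (107.0, 40.0, 0.40, 4.0),
    "depleted": (82.0, 39.0, 0.10, 1.5),
    "elongated": (143.0, 58.0, 0.40, 6.0),
}


@dataclass(frozen=True)
class RunConfig:
    """Stage selection, seed, synthetic overrides and threshold overrides."""

    seed: int = 0
    stages: tuple = ALL_STAGES
    out_dir: str = "mtarray_out"
    synth: dict = field(default_factory=dict)       # SynthConfig field overrides
    thresholds: dict = field(default_factory=dict)  # DEFAULT_THRESHOLDS overrides
    plots: bool = False                             # emit PNG figures (needs matplotlib)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")
        bad = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if bad:
            raise InvalidConfigError(f"unknown thresholds: {sorted(bad)}")
        for key, val in self.thresholds.items():
            if not val > 0:
                raise InvalidConfigError(f"threshold {key} must be > 0")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def resolved_thresholds(self) -> dict:
        return {**DEFAULT_THRESHOLDS, **self.thresholds}

    def synth_config(self, **extra) -> synthetic.SynthConfig:
        return synthetic.SynthConfig(seed=self.seed, **{**self.synth, **extra})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _round_floats(obj, ndigits: int = 9):
    """Round all floats for platform-stable JSON output."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_orientation(config: RunConfig, out: Path) -> dict:
    sc = config.synth_config()
    geometry, filaments, truth = synthetic.gen_filament_network(sc)
    sample = orientation.filament_angles(filaments, geometry)
    kres = orientation.kuiper_statistic(sample)
    tracks, _ = synthetic.gen_growth_tracks(sc)
    stats = orientation.track_growth_stats(tracks)
    orientation.write_filaments_csv(filaments, out / "filaments.csv")
    orientation.write_cell_json(geometry, out / "cell.json")
    orientation.write_tracks_csv(tracks, out / "tracks.csv")
    return {
        "n_filaments": len(filaments),
        "kuiper_K": kres.K, "kuiper_d1": kres.d1, "kuiper_d2": kres.d2,
        "asymmetry": orientation.asymmetry_index(sample),
        "fraction_within_15deg": orientation.fraction_within(sample, 15.0),
        "true_kappa": truth["kappa"],
        "growth_speed_mean_um_min": float(stats["speed_um_min"].mean()),
        "growth_duration_mean_s": float(stats["duration_s"].mean()),
    }


def _stage_motility(config: RunConfig, out: Path) -> dict:
    sc = config.synth_config()
    th = config.resolved_thresholds
    geometry, _, _ = synthetic.gen_filament_network(sc)
    marks, truth = synthetic.gen_mark_trajectories(sc)
    events = []
    for m in marks:
        for ev in motility.detect_events(m, th["displacement_um"]):
            ev.direction_class = motility.classify_event(ev, geometry)
            events.append(ev)
    freq = motility.event_frequency(events, n_regions=len(marks),
                                    observed_time_min=sc.mark_duration / 60.0)
    motility.write_marks_csv(marks, out / "marks.csv")
    motility.write_events_csv(events, out / "events.csv")

    # dissipation: one mark set per drug condition, shared decay model
    fits = {}
    for name, cond in (("none", frozenset()), ("taxol", frozenset({"taxol"})),
                       ("azide", frozenset({"azide"})),
                       ("taxol+azide", frozenset({"taxol", "azide"}))):
        cmarks, _ = synthetic.gen_mark_trajectories(sc, condition=cond)
        mean_I = np.mean([m.intensity / m.intensity[0] for m in cmarks], axis=0)
        fits[name] = motility.fit_half_life(cmarks[0].t, mean_I)
    decomp = motility.dissipation_decomposition(fits)
    return {
        "n_events": len(events),
        "events_per_region_per_min": freq["rate"],
        "fast_events_per_region_per_min": freq["fast_rate"],
        "per_class_rates": freq["per_class"],
        "true_events": truth["n_events"],
        "half_life_s": fits["none"].half_life,
        "decomposition": {k: decomp[k] for k in
                          ("k_depoly", "k_transport", "k_bleach")},
    }


def _stage_invitro(config: RunConfig, out: Path) -> dict:
    sc = config.synth_config()
    th = config.resolved_thresholds
    encounters, truth = synthetic.gen_encounters(sc)
    for e in encounters:
        invitro.classify_outcome(e, th["min_coalign_um"])
    hist = invitro.zippering_histogram(encounters)
    hist.to_csv(out / "zippering_histogram.csv", index=False)
    invitro.write_encounters_csv(encounters, out / "encounters.csv")
    anti = [e for e in encounters if e.orientation == "antiparallel"]
    para = [e for e in encounters if e.orientation == "parallel"]

    objects, _ = synthetic.gen_gliding_tracks(sc)
    speeds = invitro.gliding_speeds(objects)
    survival = invitro.bundle_survival(objects, horizon_s=sc.glide_duration)
    invitro.write_gliding_csv(objects, out / "gliding.csv", out / "gliding_meta.json")
    return {
        "n_encounters": len(encounters),
        "zippered_fraction_antiparallel":
            (sum(e.outcome == "zippered" for e in anti) / len(anti)) if anti else None,
        "zippered_fraction_parallel":
            (sum(e.outcome == "zippered" for e in para) / len(para)) if para else None,
        "gliding_mean_speed_nm_s": speeds["mean_by_type"],
        "bundle_survival_fraction": survival,
    }


def _stage_hydrodynamics(config: RunConfig, out: Path) -> dict:
    sc = config.synth_config()
    standards, _ = synthetic.gen_standard_profiles(sc)
    cal = hydro.calibrate([(hydro.peak_volume(p), s) for _, p, s in standards])
    profile, truth = synthetic.gen_gradient_profile(sc, mass_da=99_000.0, true_S=3.6)
    res = hydro.sedimentation_coefficient(profile, cal, M_da=99_000.0)
    hydro.write_gradient_csv([profile] + [p for _, p, _ in standards],
                             out / "gradient.csv")
    return {
        "calibration_slope_S_per_ul": cal.slope,
        "calibration_intercept_S": cal.intercept,
        "calibration_r2": cal.r_squared,
        "S": res.S, "true_S": truth["true_S"],
        "f_ratio": res.f_ratio,
    }


def _stage_morphology(config: RunConfig, out: Path) -> dict:
    cells = []
    kuiper_by_condition = {}
    for i, (cond, (mean, sd, p_fuse, kappa)) in enumerate(sorted(DEMO_CONDITIONS.items())):
        sc = config.synth_config(kappa=kappa)
        sc = replace(sc, seed=sc.seed + 1000 * (i + 1))
        recs, _ = synthetic.gen_cell_records(sc, condition=cond, length_mean=mean,
                                             length_sd=sd, fusion_prob=p_fuse)
        cells.extend(recs)
        geometry, filaments, _ = synthetic.gen_filament_network(sc)
        sample = orientation.filament_angles(filaments, geometry)
        kuiper_by_condition[cond] = orientation.kuiper_statistic(sample).K
    summaries = morphology.summarise_conditions(cells, kuiper_by_condition)
    fit = morphology.orderliness_vs_length(summaries)
    morphology.write_cells_csv(cells, out / "cells.csv")
    return {
        "conditions": {
            s.condition: {"mean_length_um": s.mean_length_um,
                          "sd_length_um": s.sd_length_um,
                          "fusion_index": s.fusion_index,
                          "kuiper_K": s.kuiper_K}
            for s in summaries
        },
        "orderliness_slope_per_um": fit["slope"],
        "orderliness_r": fit["r"],
    }


_STAGE_FUNCS = {
    "orientation": _stage_orientation,
    "motility": _stage_motility,
    "invitro": _stage_invitro,
    "hydrodynamics": _stage_hydrodynamics,
    "morphology": _stage_morphology,
}


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run(config: RunConfig) -> dict:
    """Execute the selected stages and write the consolidated outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.resolved_thresholds,
        "stages": {},
    }
    for stage in config.stages:
        logger.info("running stage %s", stage)
        try:
            summary["stages"][stage] = _STAGE_FUNCS[stage](config, out)
        except Exception:
            logger.exception("stage %s failed; partial outputs kept in %s", stage, out)
            _write_summary(summary, out)
            raise
    _write_summary(summary, out)
    (out / "report.md").write_text(write_report(summary))
    if config.plots:
        write_plots(summary, out)
    return summary


def write_plots(summary: dict, out: Path) -> list:
    """Render figures from per-stage outputs: cumulative angle curve,
    angle-resolved zippering histogram, and K-vs-length scatter with fit.

    Requires matplotlib; returns the list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out = Path(out)
    written = []
    stages = summary.get("stages", {})
    if "orientation" in stages and (out / "filaments.csv").exists():
        from . import orientation as ori
        filaments = ori.read_filaments_csv(out / "filaments.csv")
        geometry = ori.read_cell_json(out / "cell.json")
        sample = ori.filament_angles(filaments, geometry)
        order = np.argsort(sample.angles)
        cum = np.cumsum(sample.weights[order]) / sample.weights.sum()
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(sample.angles[order], cum, drawstyle="steps-post", label="observed")
        ax.plot([-90, 90], [0, 1], "k--", label="uniform")
        ax.set_xlabel("angle to cell axis (°)")
        ax.set_ylabel("cumulative frequency")
        ax.set_title(f"K = {stages['orientation']['kuiper_K']:.3f}")
        ax.legend(frameon=False)
        fig.savefig(out / "angles_cumulative.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "angles_cumulative.png")
    if "invitro" in stages and (out / "zippering_histogram.csv").exists():
        hist = pd.read_csv(out / "zippering_histogram.csv")
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(hist["bin_left_deg"], hist["fraction"], width=9.0, align="edge")
        ax.set_xlabel("encounter angle (°)")
        ax.set_ylabel("zippered fraction")
        fig.savefig(out / "zippering_histogram.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "zippering_histogram.png")
    if "morphology" in stages:
        conds = stages["morphology"]["conditions"]
        L = np.array([c["mean_length_um"] for c in conds.values()])
        K = np.array([c["kuiper_K"] for c in conds.values()])
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(L, K)
        for name, c in conds.items():
            ax.annotate(name, (c["mean_length_um"], c["kuiper_K"]), fontsize=7)
        coef = np.polyfit(L, K, 1)
        xs = np.linspace(L.min(), L.max(), 10)
        ax.plot(xs, np.polyval(coef, xs), "k--")
        ax.set_xlabel("mean cell length (μm)")
        ax.set_ylabel("Kuiper K")
        fig.savefig(out / "orderliness_vs_length.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "orderliness_vs_length.png")
    return written


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(_round_floats(summary), fh, sort_keys=True, indent=2)
        fh.write("\n")


def write_report(summary: dict) -> str:
    """Render a Markdown report from a run summary (one section per stage)."""
    lines = [
        "# Microtubule array analysis report",
        "",
        f"Package version {summary.get('version', '?')}, seed {summary.get('seed', '?')}.",
        "",
        "Thresholds: " + ", ".join(f"{k}={v:g}" for k, v in
                                   sorted(summary.get("thresholds", {}).items())),
        "",
    ]
    stages = summary.get("stages", {})
    if "orientation" in stages:
        s = stages["orientation"]
        lines += [
            "## Orientation",
            "",
            f"- Kuiper K = {s['kuiper_K']:.3f} (d1 = {s['kuiper_d1']:.3f}, "
            f"d2 = {s['kuiper_d2']:.3f}) over {s['n_filaments']} filaments",
            f"- asymmetry index = {s['asymmetry']:.3f}; "
            f"{100 * s['fraction_within_15deg']:.1f}% of filament length within ±15° of the axis",
            f"- growth: {s['growth_speed_mean_um_min']:.2f} μm/min mean speed, "
            f"{s['growth_duration_mean_s']:.1f} s mean duration",
            "",
        ]
    if "motility" in stages:
        s = stages["motility"]
        per_class = ", ".join(f"{k}: {v:.3f}" for k, v in s["per_class_rates"].items())
        lines += [
            "## Motility",
            "",
            f"- {s['n_events']} sliding events; "
            f"{s['events_per_region_per_min']:.3f} events/region/min "
            f"({s['fast_events_per_region_per_min']:.3f} fast)",
            f"- per class (events/region/min): {per_class}",
            f"- dissipation half-life {s['half_life_s']:.1f} s; component rates "
            + ", ".join(f"{k} = {v:.4g}/s" for k, v in s["decomposition"].items()),
            "",
        ]
    if "invitro" in stages:
        s = stages["invitro"]
        surv = s["bundle_survival_fraction"]
        lines += [
            "## In vitro assays",
            "",
            f"- {s['n_encounters']} encounters: zippered fraction "
            f"{s['zippered_fraction_antiparallel']:.2f} (antiparallel) vs "
            f"{s['zippered_fraction_parallel']:.2f} (parallel)",
            f"- gliding speeds (nm/s): " + ", ".join(
                f"{k}: {v:.0f}" for k, v in s["gliding_mean_speed_nm_s"].items()),
            f"- bundle survival at horizon: {surv:.2f}" if surv is not None
            else "- bundle survival: not scoreable (all censored)",
            "",
        ]
    if "hydrodynamics" in stages:
        s = stages["hydrodynamics"]
        lines += [
            "## Hydrodynamics",
            "",
            f"- calibration S = {s['calibration_slope_S_per_ul']:.4g}·v + "
            f"{s['calibration_intercept_S']:.4g} (r² = {s['calibration_r2']:.4f})",
            f"- recovered S = {s['S']:.2f} S (true {s['true_S']:.2f} S); "
            f"f/f_min = {s['f_ratio']:.2f}",
            "",
        ]
    if "morphology" in stages:
        s = stages["morphology"]
        lines += ["## Morphology", ""]
        for cond, c in sorted(s["conditions"].items()):
            lines.append(
                f"- {cond}: length {c['mean_length_um']:.0f} ± {c['sd_length_um']:.0f} μm, "
                f"fusion index {c['fusion_index']:.2f}, K = {c['kuiper_K']:.3f}")
        lines += [
            f"- orderliness vs length: slope {s['orderliness_slope_per_um']:.4g} /μm, "
            f"r = {s['orderliness_r']:.3f}",
            "",
        ]
    return "\n".join(lines)
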