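"""Generator contracts: determinism, validation, truth completeness, oracles."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import mtarray as mt
from mtarray.errors import InvalidConfigError


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"cell_length": -1.0},
        {"cell_aspect": 0.5},
        {"kappa": -0.1},
        {"slide_rate": -1.0},
        {"k_bleach": -0.001},
        {"duration": 1.0},                      # < 2 frames
        {"class_probs": (("paraxial", 0.5), ("off_axis", 0.2), ("looping", 0.2))},
        {"zipper_prob_parallel": lambda a: 1.5},
        {"gradient_slope": 0.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            mt.SynthConfig(seed=0, **kwargs)


class TestDeterminism:
    def test_identical_seed_bit_identical_everywhere(self, small_config):
        cfg2 = mt.SynthConfig(**{f.name: getattr(small_config, f.name)
                                 for f in small_config.__dataclass_fields__.values()})
        g1, f1, t1 = mt.synthetic.gen_filament_network(small_config)
        g2, f2, t2 = mt.synthetic.gen_filament_network(cfg2)
        assert all((a.vertices == b.vertices).all() for a, b in zip(f1, f2))
        assert t1 == t2
        m1, _ = mt.synthetic.gen_mark_trajectories(small_config)
        m2, _ = mt.synthetic.gen_mark_trajectories(cfg2)
        assert all((a.x == b.x).all() and (a.intensity == b.intensity).all()
                   for a, b in zip(m1, m2))
        e1, _ = mt.synthetic.gen_encounters(small_config)
        e2, _ = mt.synthetic.gen_encounters(cfg2)
        assert all((a.filament_B == b.filament_B).all() for a, b in zip(e1, e2))

    def test_child_streams_independent(self, small_config):
        # consuming one generator does not perturb another
        _, t_first = mt.synthetic.gen_gliding_tracks(small_config)
        mt.synthetic.gen_mark_trajectories(small_config)
        _, t_second = mt.synthetic.gen_gliding_tracks(small_config)
        assert t_first == t_second


class TestFilamentNetwork:
    def test_vertices_inside_outline(self, small_config):
        geo, fils, _ = mt.synthetic.gen_filament_network(small_config)
        poly = Polygon(geo.outline).buffer(1e-6)
        assert all(poly.contains(Point(p)) for f in fils for p in f.vertices)

    def test_uniform_orientations_have_no_resultant(self):
        cfg = mt.SynthConfig(seed=1, kappa=0.0, n_filaments=10_000)
        _, _, truth = mt.synthetic.gen_filament_network(cfg)
        doubled = np.radians(np.array(truth["angles_deg"])) * 2
        R = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
        assert R < 0.05

    def test_high_concentration_confines_orientations(self):
        cfg = mt.SynthConfig(seed=2, kappa=100.0, n_filaments=1000)
        _, _, truth = mt.synthetic.gen_filament_network(cfg)
        frac = np.mean(np.abs(truth["angles_deg"]) <= 15.0)
        assert frac >= 0.99

    def test_truth_completeness(self, small_config):
        _, fils, truth = mt.synthetic.gen_filament_network(small_config)
        assert len(truth["angles_deg"]) == len(fils)


class TestGrowthTracks:
    def test_zero_variance_speed(self):
        cfg = mt.SynthConfig(seed=3, n_tracks=20, growth_speed_sd=0.0,
                             loc_noise_um=0.0)
        tracks, truth = mt.synthetic.gen_growth_tracks(cfg)
        stats = mt.track_growth_stats(tracks)
        assert stats["speed_um_min"].to_numpy() == pytest.approx(np.full(20, 10.0))

    def test_fully_aligned_zero_noise_growth_angles(self):
        cfg = mt.SynthConfig(seed=4, n_tracks=30, aligned_fraction=1.0,
                             growth_angle_sd_deg=0.0, loc_noise_um=0.0)
        _, truth = mt.synthetic.gen_growth_tracks(cfg)
        folded = mt.orientation.fold_undirected(np.array(truth["directions_deg"]))
        assert folded == pytest.approx(np.zeros(30), abs=1e-9)

    def test_truth_completeness_and_min_length(self, small_config):
        tracks, truth = mt.synthetic.gen_growth_tracks(small_config)
        assert len(truth["speeds_um_min"]) == len(tracks)
        assert all(tr.t.size >= 2 for tr in tracks)


class TestMarkTrajectories:
    def test_zero_rate_marks_stay_home(self):
        cfg = mt.SynthConfig(seed=5, slide_rate=0.0, n_marks=20)
        marks, truth = mt.synthetic.gen_mark_trajectories(cfg)
        assert truth["n_events"] == 0
        for m in marks:
            wander = np.hypot(m.x - m.x[0], m.y - m.y[0])
            assert wander.max() < 6 * cfg.loc_noise_um

    def test_pure_bleach_half_life_closed_form(self):
        cfg = mt.SynthConfig(seed=6, k_depoly=0.0, k_transport=0.0,
                             k_bleach=np.log(2) / 100.0, intensity_noise=0.0,
                             mark_frame_interval=2.0, mark_duration=120.0, n_marks=2)
        for cond in (frozenset(), frozenset({"taxol"}), frozenset({"azide"}),
                     frozenset({"taxol", "azide"})):
            marks, truth = mt.synthetic.gen_mark_trajectories(cfg, condition=cond)
            m = marks[0]
            idx = int(np.argmin(np.abs(m.t - 100.0)))
            assert m.intensity[idx] / m.intensity[0] == pytest.approx(0.5, rel=1e-6)
            assert truth["half_life_s"] == pytest.approx(100.0)

    def test_condition_zeroes_matching_rate(self):
        cfg = mt.SynthConfig(seed=7, n_marks=1, intensity_noise=0.0)
        _, t_none = mt.synthetic.gen_mark_trajectories(cfg)
        _, t_taxol = mt.synthetic.gen_mark_trajectories(cfg, condition={"taxol"})
        _, t_azide = mt.synthetic.gen_mark_trajectories(cfg, condition={"azide"})
        assert t_none["k_total"] == pytest.approx(cfg.k_depoly + cfg.k_transport + cfg.k_bleach)
        assert t_taxol["k_total"] == pytest.approx(cfg.k_transport + cfg.k_bleach)
        assert t_azide["k_total"] == pytest.approx(cfg.k_depoly + cfg.k_bleach)

    def test_poisson_event_count(self):
        cfg = mt.SynthConfig(seed=8, slide_rate=2.0, mark_duration=60.0, n_marks=200)
        _, truth = mt.synthetic.gen_mark_trajectories(cfg)
        expected = 200 * 2.0
        assert abs(truth["n_events"] - expected) < 3 * np.sqrt(expected)

    def test_truth_completeness(self, small_config):
        marks, truth = mt.synthetic.gen_mark_trajectories(small_config)
        assert len(truth["events"]) == len(marks)


class TestEncounters:
    def test_zero_probability_all_crossed(self):
        cfg = mt.SynthConfig(seed=9, n_encounters=50,
                             zipper_prob_parallel=lambda a: 0.0,
                             zipper_prob_antiparallel=lambda a: 0.0)
        _, truth = mt.synthetic.gen_encounters(cfg)
        assert not any(r["zippered"] for r in truth["encounters"])

    def test_forced_zippering_at_steep_antiparallel_angle(self):
        cfg = mt.SynthConfig(seed=10, n_encounters=30,
                             encounter_angle_range=(165.0, 175.0),
                             zipper_prob_antiparallel=lambda a: 1.0 if a > 150 else 0.0)
        encounters, truth = mt.synthetic.gen_encounters(cfg)
        assert all(r["zippered"] and r["orientation"] == "antiparallel"
                   for r in truth["encounters"])
        for e in encounters:
            mt.classify_outcome(e)
            assert e.outcome == "zippered"

    def test_binomial_outcome_fraction(self):
        cfg = mt.SynthConfig(seed=11, n_encounters=500,
                             encounter_angle_range=(150.0, 175.0),
                             zipper_prob_antiparallel=lambda a: 0.6)
        _, truth = mt.synthetic.gen_encounters(cfg)
        frac = np.mean([r["zippered"] for r in truth["encounters"]])
        assert abs(frac - 0.6) < 2.576 * np.sqrt(0.6 * 0.4 / 500)


class TestGliding:
    def test_exponential_survival_oracle(self):
        cfg = mt.SynthConfig(seed=12, n_bundles=200, n_singles=0, censor_prob=0.0,
                             bundle_breakup_rate=np.log(2) / 450.0)
        objects, _ = mt.synthetic.gen_gliding_tracks(cfg)
        frac = mt.bundle_survival(objects, 450.0)
        se = np.sqrt(0.5 * 0.5 / 200)
        assert abs(frac - 0.5) < 3 * se

    def test_truth_completeness(self, small_config):
        objects, truth = mt.synthetic.gen_gliding_tracks(small_config)
        assert len(truth["single_speeds_nm_s"]) == small_config.n_singles
        assert len(truth["bundles"]) == small_config.n_bundles


class TestGradient:
    def test_noiseless_argmax_maps_back_to_true_s(self):
        cfg = mt.SynthConfig(seed=13)
        prof, truth = mt.synthetic.gen_gradient_profile(cfg, 99_000.0, 3.6)
        v_at_max = prof.volumes_ul[int(np.argmax(prof.signal))]
        assert cfg.gradient_slope * v_at_max + cfg.gradient_intercept == pytest.approx(3.6)

    def test_monte_carlo_recovery_within_tenth_svedberg(self):
        recovered = []
        for rep in range(50):
            cfg = mt.SynthConfig(seed=500 + rep, gradient_noise=0.05)
            standards, _ = mt.synthetic.gen_standard_profiles(cfg)
            cal = mt.calibrate([(mt.peak_volume(p), s) for _, p, s in standards])
            prof, _ = mt.synthetic.gen_gradient_profile(cfg, 99_000.0, 3.6)
            recovered.append(mt.sedimentation_coefficient(prof, cal).S)
        assert abs(np.mean(recovered) - 3.6) < 0.1


class TestRoundTripFormats:
    def test_csv_round_trips_preserve_values(self, small_config, tmp_path):
        geo, fils, _ = mt.synthetic.gen_filament_network(small_config)
        mt.orientation.write_filaments_csv(fils, tmp_path / "f.csv")
        mt.orientation.write_cell_json(geo, tmp_path / "c.json")
        fils2 = mt.orientation.read_filaments_csv(tmp_path / "f.csv")
        geo2 = mt.orientation.read_cell_json(tmp_path / "c.json")
        k1 = mt.kuiper_statistic(mt.filament_angles(fils, geo)).K
        k2 = mt.kuiper_statistic(mt.filament_angles(fils2, geo2)).K
        assert k2 == pytest.approx(k1, rel=1e-5)

        marks, _ = mt.synthetic.gen_mark_trajectories(small_config)
        mt.motility.write_marks_csv(marks, tmp_path / "m.csv")
        marks2 = mt.motility.read_marks_csv(tmp_path / "m.csv")
        assert len(marks2) == len(marks)
        assert marks2[0].x == pytest.approx(marks[0].x, rel=1e-5)

        encounters, _ = mt.synthetic.gen_encounters(small_config)
        mt.invitro.write_encounters_geometry_json(encounters, tmp_path / "e.json")
        encounters2 = mt.invitro.read_encounters_geometry_json(tmp_path / "e.json")
        for a, b in zip(encounters, encounters2):
            assert b.filament_A == pytest.approx(a.filament_A)

        objects, _ = mt.synthetic.gen_gliding_tracks(small_config)
        mt.invitro.write_gliding_csv(objects, tmp_path / "g.csv", tmp_path / "g.json")
        objects2 = mt.invitro.read_gliding_csv(tmp_path / "g.csv", tmp_path / "g.json")
        assert mt.bundle_survival(objects2, 450.0) == mt.bundle_survival(objects, 450.0)
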