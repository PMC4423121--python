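"""Encounter classification, gliding mechanics and bundle scoring."""

import numpy as np
import pytest

import mtarray as mt
from mtarray.invitro import shallow_angle_filter


def _straight(p0, direction_deg, length, spacing=0.2):
    d = np.array([np.cos(np.radians(direction_deg)), np.sin(np.radians(direction_deg))])
    ts = np.linspace(0.0, length, int(np.ceil(length / spacing)) + 1)
    return np.asarray(p0, float) + np.outer(ts, d)


class TestEncounterAngle:
    @pytest.mark.parametrize("dir_b, expected", [
        (0.0, 0.0),       # co-directional parallel
        (180.0, 180.0),   # head-on anti-directional
        (90.0, 90.0),     # perpendicular
        (135.0, 135.0),
    ])
    def test_tangent_angles(self, dir_b, expected):
        fil_a = _straight([-5.0, 0.0], 0.0, 10.0)
        fil_b = _straight(-5.0 * np.array([np.cos(np.radians(dir_b)),
                                           np.sin(np.radians(dir_b))]), dir_b, 10.0)
        assert mt.encounter_angle(fil_a, fil_b, [0.0, 0.0]) == pytest.approx(expected, abs=1e-6)

    def test_contact_off_both_filaments_rejected(self):
        fil = _straight([0.0, 0.0], 0.0, 5.0)
        with pytest.raises(mt.errors.InvalidInputError):
            mt.encounter_angle(fil, fil, [2.0, 3.0])


class TestClassifyOutcome:
    def test_crossing_stays_crossed(self):
        e = mt.Encounter("x", _straight([-5, 0], 0.0, 10.0),
                         _straight([-2.5, -4.33], 60.0, 10.0), np.zeros(2))
        mt.classify_outcome(e)
        assert e.outcome == "crossed"
        assert e.orientation == "parallel"

    def test_antiparallel_zippering_satisfies_two_micron_rule(self):
        # B approaches at 170 deg, bends at contact and runs 2.5 μm back
        # along A's lattice
        fil_a = _straight([-6, 0], 0.0, 12.0)
        pre = _straight(-5.0 * np.array([np.cos(np.radians(170)), np.sin(np.radians(170))]),
                        170.0, 5.0)
        run = _straight([0.0, 0.03], 180.0, 2.5)
        e = mt.Encounter("z", fil_a, np.vstack([pre, run]), np.zeros(2))
        mt.classify_outcome(e)
        assert e.outcome == "zippered"
        assert e.orientation == "antiparallel"
        assert e.coaligned_um >= 2.0

    def test_short_coalignment_is_crossed(self):
        fil_a = _straight([-6, 0], 0.0, 12.0)
        pre = _straight(-5.0 * np.array([np.cos(np.radians(170)), np.sin(np.radians(170))]),
                        170.0, 5.0)
        run = _straight([0.0, 0.03], 180.0, 1.5)
        e = mt.Encounter("s", fil_a, np.vstack([pre, run]), np.zeros(2))
        mt.classify_outcome(e)
        assert e.outcome == "crossed"

    def test_generator_ground_truth_agreement(self):
        cfg = mt.SynthConfig(seed=21, n_encounters=150)
        encounters, truth = mt.synthetic.gen_encounters(cfg)
        for e, rec in zip(encounters, truth["encounters"]):
            mt.classify_outcome(e)
            assert (e.outcome == "zippered") == rec["zippered"]
            assert e.orientation == rec["orientation"]
            assert e.angle_deg == pytest.approx(rec["angle_deg"], abs=1e-6)

    def test_mirror_symmetry(self):
        cfg = mt.SynthConfig(seed=22, n_encounters=30)
        encounters, _ = mt.synthetic.gen_encounters(cfg)
        for e in encounters:
            mt.classify_outcome(e)
            m = mt.Encounter(e.id, e.filament_A * [1, -1], e.filament_B * [1, -1],
                             e.contact * [1, -1])
            mt.classify_outcome(m)
            assert m.angle_deg == pytest.approx(e.angle_deg, abs=1e-9)
            assert m.orientation == e.orientation
            assert m.outcome == e.outcome


class TestZipperingHistogram:
    def test_all_crossed_gives_zero_fractions(self):
        cfg = mt.SynthConfig(seed=23, n_encounters=60,
                             zipper_prob_parallel=lambda a: 0.0,
                             zipper_prob_antiparallel=lambda a: 0.0)
        encounters, truth = mt.synthetic.gen_encounters(cfg)
        assert not any(r["zippered"] for r in truth["encounters"])
        for e in encounters:
            mt.classify_outcome(e)
        hist = mt.zippering_histogram(encounters)
        assert int(hist["n"].sum()) == 60
        occupied = hist[hist["n"] > 0]
        assert (occupied["fraction"] == 0.0).all()

    def test_empty_bins_reported_null(self):
        cfg = mt.SynthConfig(seed=24, n_encounters=40, encounter_angle_range=(60.0, 120.0))
        encounters, _ = mt.synthetic.gen_encounters(cfg)
        for e in encounters:
            mt.classify_outcome(e)
        hist = mt.zippering_histogram(encounters)
        empty = hist[hist["n"] == 0]
        assert len(empty) > 0
        assert empty["fraction"].isna().all()

    def test_binomial_fraction_recovery(self):
        cfg = mt.SynthConfig(seed=25, n_encounters=500,
                             encounter_angle_range=(155.0, 165.0),
                             zipper_prob_antiparallel=lambda a: 0.6)
        encounters, _ = mt.synthetic.gen_encounters(cfg)
        for e in encounters:
            mt.classify_outcome(e)
        hist = mt.zippering_histogram(encounters)
        row = hist[(hist["bin_left_deg"] == 150.0)].iloc[0]
        ci = 2.576 * np.sqrt(0.6 * 0.4 / row["n"])
        assert abs(row["fraction"] - 0.6) < ci


class TestEncounterLengths:
    def test_distance_to_seed(self):
        fil_a = _straight([-3.0, 0.0], 0.0, 5.0)   # seed 3 μm before contact
        fil_b = _straight([0.0, -2.0], 90.0, 5.0)  # seed 2 μm before contact
        e = mt.Encounter("l", fil_a, fil_b, np.zeros(2))
        assert mt.encounter_lengths(e) == pytest.approx((3.0, 2.0))

    def test_contact_at_seed_is_zero(self):
        e = mt.Encounter("l0", _straight([0, 0], 0.0, 5.0),
                         _straight([0, -2], 90.0, 5.0), np.zeros(2))
        lenA, _ = mt.encounter_lengths(e)
        assert lenA == pytest.approx(0.0, abs=1e-9)

    def test_nearest_prior_crossover_wins(self):
        e = mt.Encounter("lc", _straight([-3, 0], 0.0, 5.0),
                         _straight([0, -2], 90.0, 5.0), np.zeros(2),
                         crossovers_A=np.array([2.0]))  # crossover 1 μm before contact
        lenA, lenB = mt.encounter_lengths(e)
        assert lenA == pytest.approx(1.0)
        assert lenB == pytest.approx(2.0)

    def test_shallow_angle_filter_keeps_grazing_crossings(self):
        cfg = mt.SynthConfig(seed=26, n_encounters=200)
        encounters, _ = mt.synthetic.gen_encounters(cfg)
        for e in encounters:
            mt.classify_outcome(e)
        kept = shallow_angle_filter(encounters)
        assert all(e.outcome == "crossed" for e in kept)
        assert all(10.0 <= min(e.angle_deg, 180 - e.angle_deg) <= 30.0 for e in kept)


class TestGliding:
    def test_constant_speed_track(self):
        t = np.arange(10.0)
        obj = mt.GlidingObject("s0", "single", t, 0.5 * t, np.zeros(10))
        out = mt.gliding_speeds([obj])
        assert out["speeds"]["single"] == pytest.approx(np.full(9, 500.0))
        assert out["mean_by_type"]["single"] == pytest.approx(500.0)

    def test_zero_variance_speeds_identical(self):
        cfg = mt.SynthConfig(seed=27, v_glide_sd=0.0, n_singles=5, n_bundles=0)
        objects, _ = mt.synthetic.gen_gliding_tracks(cfg)
        out = mt.gliding_speeds(objects)
        assert out["speeds"]["single"] == pytest.approx(np.full_like(
            out["speeds"]["single"], 600.0))

    def test_single_frame_track_excluded_with_warning(self):
        obj = mt.GlidingObject("s1", "single", np.array([0.0]), np.zeros(1), np.zeros(1))
        with pytest.warns(UserWarning):
            out = mt.gliding_speeds([obj])
        assert out["per_object"].empty

    def test_speed_mean_recovery(self):
        cfg = mt.SynthConfig(seed=28, n_singles=50, n_bundles=0)
        objects, truth = mt.synthetic.gen_gliding_tracks(cfg)
        mean = mt.gliding_speeds(objects)["mean_by_type"]["single"]
        se = cfg.v_glide_sd / np.sqrt(50)
        assert abs(mean - cfg.v_glide_mean) < 3 * se


class TestBundleSurvival:
    @staticmethod
    def _bundle(i, separated=False, censored=False, st=None):
        t = np.arange(3.0)
        return mt.GlidingObject(f"b{i}", "bundle", t, np.zeros(3), np.zeros(3),
                                separated=separated, censored=censored, survival_time=st)

    def test_censoring_arithmetic(self):
        bundles = ([self._bundle(i, separated=True, st=100.0) for i in range(3)]
                   + [self._bundle(3 + i, st=450.0) for i in range(9)]
                   + [self._bundle(12 + i, censored=True) for i in range(2)])
        assert mt.bundle_survival(bundles, 450.0) == pytest.approx(0.75)

    def test_no_separations_is_one_and_all_censored_is_null(self):
        intact = [self._bundle(i, st=450.0) for i in range(5)]
        assert mt.bundle_survival(intact, 450.0) == 1.0
        censored = [self._bundle(i, censored=True) for i in range(5)]
        assert mt.bundle_survival(censored, 450.0) is None

    def test_monotone_in_horizon(self):
        cfg = mt.SynthConfig(seed=29, n_singles=0, n_bundles=100,
                             bundle_breakup_rate=np.log(2) / 200.0)
        objects, _ = mt.synthetic.gen_gliding_tracks(cfg)
        horizons = [50.0, 150.0, 300.0, 450.0]
        fracs = [mt.bundle_survival(objects, h) for h in horizons]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_zero_breakup_rate_all_intact(self):
        cfg = mt.SynthConfig(seed=30, n_bundles=30, bundle_breakup_rate=0.0,
                             censor_prob=0.0)
        objects, _ = mt.synthetic.gen_gliding_tracks(cfg)
        assert mt.bundle_survival(objects, cfg.glide_duration) == 1.0


class TestScoreBundles:
    @pytest.mark.parametrize("regions, threshold, expected", [
        ([(3.0, 4.0)], 2.3, 1),
        ([(3.0, 2.0)], 2.3, 0),
        ([(2.0, 5.0), (2.5, 3.5), (4.0, 2.9)], 2.3, 1),
        ([(2.2, 5.0)], 2.0, 1),  # in vitro preset admits shorter regions
    ])
    def test_threshold_rule(self, regions, threshold, expected):
        assert mt.score_bundles(regions, len_threshold_um=threshold) == expected
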