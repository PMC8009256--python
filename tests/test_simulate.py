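"""Generator contracts: trial structure, waveform kinematics, ground truth."""

import numpy as np
import pytest
from scipy import stats

import zapgaze as zg
from zapgaze.simulate import (
    SimulationConfig,
    inject_post_saccadic_microsaccade,
    sample_target_position,
    synthesize_saccade,
)


class TestTargetPlacement:
    def test_step_scheme_distance_is_exact(self):
        cfg = SimulationConfig(placement_scheme="step4deg")
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = sample_target_position(np.zeros(2), "step4deg", rng, cfg)
            assert np.hypot(*p) == pytest.approx(4.0, abs=1e-12)

    def test_degenerate_sector_goes_exactly_right(self):
        cfg = SimulationConfig(
            placement_scheme="step4deg", allowed_polar_sectors=((0.0, 0.0),)
        )
        rng = np.random.default_rng(0)
        p = sample_target_position(np.zeros(2), "step4deg", rng, cfg)
        assert np.allclose(p, [4.0, 0.0])

    def test_full_screen_keeps_window_on_screen(self):
        cfg = SimulationConfig()
        rng = np.random.default_rng(1)
        pts = np.array(
            [sample_target_position(np.zeros(2), "full_screen", rng, cfg) for _ in range(500)]
        )
        assert np.abs(pts[:, 0]).max() <= 31.0 / 2 - 1.5
        assert np.abs(pts[:, 1]).max() <= 22.0 / 2 - 1.5

    def test_polar_angles_respect_sectors_chi_square(self):
        """10k draws occupy only the allowed sectors, with mass proportional
        to sector width (chi-square test at alpha=0.01)."""
        cfg = SimulationConfig(placement_scheme="step4deg", screen_deg=(400.0, 400.0))
        rng = np.random.default_rng(2)
        angs = []
        for _ in range(10_000):
            p = sample_target_position(np.zeros(2), "step4deg", rng, cfg)
            angs.append(np.degrees(np.arctan2(p[1], p[0])) % 360.0)
        angs = np.asarray(angs)
        sectors = cfg.allowed_polar_sectors
        counts = np.array(
            [((angs >= lo) & (angs <= hi)).sum() for lo, hi in sectors]
        )
        assert counts.sum() == len(angs)  # nothing outside the sectors
        widths = np.array([hi - lo for lo, hi in sectors])
        expected = len(angs) * widths / widths.sum()
        assert stats.chisquare(counts, expected).pvalue > 0.01

    def test_impossible_placement_raises(self):
        cfg = SimulationConfig(placement_scheme="step4deg", step_eccentricity_deg=100.0)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_target_position(np.zeros(2), "step4deg", rng, cfg)


class TestSaccadeWaveform:
    def test_zero_amplitude_is_flat(self):
        w = synthesize_saccade(0.0, 0.0, SimulationConfig())
        assert np.all(w == 0.0)

    def test_negative_amplitude_raises(self):
        with pytest.raises(ValueError):
            synthesize_saccade(-1.0, 0.0, SimulationConfig())

    def test_displacement_equals_amplitude(self):
        cfg = SimulationConfig()
        for amp in (0.3, 1.0, 4.0, 17.3):
            w = synthesize_saccade(amp, 123.0, cfg)
            assert np.hypot(*(w[-1] - w[0])) == pytest.approx(amp, abs=1e-6)

    def test_peak_velocity_matches_main_sequence_numeric_diff(self):
        """Numerically differentiating a 10-degree waveform recovers the
        saturating main-sequence peak 750*(1-e^(-10/8)) = 535.6 deg/s."""
        cfg = SimulationConfig(main_sequence_vmax=750.0, main_sequence_c=8.0)
        w = synthesize_saccade(10.0, 0.0, cfg)
        dt_s = cfg.dt_ms / 1000.0
        speed = np.hypot(*(np.gradient(w, dt_s, axis=0).T))
        expected = 750.0 * (1 - np.exp(-10.0 / 8.0))
        assert expected == pytest.approx(535.12, abs=0.01)
        assert speed.max() == pytest.approx(expected, rel=0.02)

    def test_peak_velocity_monotone_in_amplitude(self):
        cfg = SimulationConfig()
        peaks = []
        for amp in (0.5, 1.0, 2.0, 4.0, 8.0, 16.0):
            w = synthesize_saccade(amp, 0.0, cfg)
            v = np.linalg.norm(np.diff(w, axis=0), axis=1) / (cfg.dt_ms / 1000.0)
            peaks.append(v.max())
        assert np.all(np.diff(peaks) > 0)


class TestSession:
    def test_trial_count_and_conservation(self, session, small_config):
        assert len(session.trials) == small_config.n_trials
        gt = session.ground_truth
        n_sacc = (gt["class"] == "saccade").sum()
        assert n_sacc >= len(session.trials)  # at least one saccade per trial

    def test_ground_truth_ordered_and_micro_small(self, session):
        gt = session.ground_truth
        assert (gt["offset_ms"] >= gt["onset_ms"]).all()
        assert (np.diff(gt["onset_ms"]) > 0).all()
        # events never overlap
        assert (gt["onset_ms"].to_numpy()[1:] > gt["offset_ms"].to_numpy()[:-1]).all()
        micro = gt[gt["class"] == "microsaccade"]
        disp = np.hypot(micro["x_end"] - micro["x_start"], micro["y_end"] - micro["y_start"])
        assert (disp < 1.0).all()

    def test_zero_probability_yields_no_microsaccades(self):
        cfg = SimulationConfig(
            n_blocks=1, trials_per_block=50, p_post_saccadic_microsaccade=0.0, rng_seed=5
        )
        s = zg.simulate_session(cfg)
        assert (s.ground_truth["class"] == "saccade").all()

    def test_microsaccade_probability_recovered_in_ground_truth(self):
        """With p=0.5 and no fixation noise, the fraction of trials with one
        post-saccadic microsaccade lies inside the binomial 99% CI around
        p times the launch-survival rate.  With zero screen-update jitter
        the trial-advance delay is a fixed 31 samples, and the launch
        latency is uniform over the 30 sample offsets {2..31}, of which
        only the last is suppressed: survival = 29/30 exactly."""
        cfg = SimulationConfig(
            n_blocks=2,
            trials_per_block=1000,
            p_post_saccadic_microsaccade=0.5,
            fixation_noise_sd_deg=0.0,
            screen_update_jitter_sd_ms=0.0,
            rng_seed=17,
        )
        s = zg.simulate_session(cfg)
        micro = s.ground_truth[s.ground_truth["congruent"].notna()]
        n_with = micro["trial_id"].nunique()
        n = len(s.trials)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5 * 29 / 30)
        assert lo <= n_with <= hi

    def test_microsaccade_latency_in_configured_range(self):
        cfg = SimulationConfig(
            n_blocks=1, trials_per_block=400, p_post_saccadic_microsaccade=1.0, rng_seed=3
        )
        s = zg.simulate_session(cfg)
        gt = s.ground_truth
        lat = []
        for tid, grp in gt.groupby("trial_id"):
            # injected post-saccadic microsaccades carry a congruence flag;
            # sub-degree *targeting* movements do not
            micro = grp[grp["congruent"].notna()]
            if len(micro):
                prev_off = grp.loc[grp["congruent"].isna(), "offset_ms"].max()
                lat.append(micro["onset_ms"].iloc[0] - prev_off)
        lat = np.asarray(lat)
        assert len(lat) > 200
        assert lat.min() >= 1.0 and lat.max() <= 25.0

    def test_main_sequence_holds_in_ground_truth(self, session):
        gt = session.ground_truth
        assert len(gt) >= 100
        rho = stats.spearmanr(gt["amplitude_deg"], gt["peak_velocity_dps"]).statistic
        assert rho > 0.95

    def test_targeting_rate_plausible(self, session):
        from zapgaze.metrics import targeting_rate

        rate = targeting_rate(session.trials)
        assert np.isfinite(rate) and rate > 0
        assert 2.0 < rate < 7.0  # faces per second

    def test_reproducible_bit_identical(self, small_config):
        a = zg.simulate_session(small_config)
        b = zg.simulate_session(small_config)
        assert np.array_equal(a.recording.x_deg, b.recording.x_deg)
        assert np.array_equal(a.recording.y_deg, b.recording.y_deg)
        assert a.trials.equals(b.trials)
        assert a.ground_truth.equals(b.ground_truth)

    def test_landmarks_stay_within_face_extent(self, session):
        tr = session.trials
        from zapgaze.landmarks import LANDMARK_NAMES

        for name in LANDMARK_NAMES:
            d = np.hypot(
                tr[f"lm_{name}_x"] - tr["target_x_deg"],
                tr[f"lm_{name}_y"] - tr["target_y_deg"],
            )
            assert d.max() <= 0.62 * 3.0  # within the 3-degree face's bounding box
        # face height is respected: hair-to-chin distance stays close to 3 deg
        h = np.hypot(
            tr["lm_hair_top_middle_x"] - tr["lm_chin_bottom_center_x"],
            tr["lm_hair_top_middle_y"] - tr["lm_chin_bottom_center_y"],
        )
        assert 2.5 < h.min() and h.max() < 3.5


class TestMicrosaccadeInjection:
    def _setup(self, upright=True, p=1.0):
        cfg = SimulationConfig(p_post_saccadic_microsaccade=p)
        from zapgaze.simulate import _trial_landmarks

        rng = np.random.default_rng(42)
        target = np.zeros(2)
        lms = _trial_landmarks(rng, cfg, target, upright)
        return cfg, rng, target, lms

    def test_never_emits_at_zero_probability(self):
        cfg, rng, target, lms = self._setup(p=0.0)
        for _ in range(200):
            out = inject_post_saccadic_microsaccade(
                rng, cfg, np.array([0.1, 0.1]), 0.0, target, lms, True
            )
            assert out is None

    def test_upright_endpoints_cluster_in_upper_face(self):
        """With an upright face the landmark mixture is eyes/forehead
        weighted, so the modal endpoint cluster sits in the upper face half."""
        cfg, rng, target, lms = self._setup(upright=True)
        ys = []
        for _ in range(2000):
            out = inject_post_saccadic_microsaccade(
                rng, cfg, np.array([0.0, -0.2]), 0.0, target, lms, True
            )
            ys.append(out["endpoint"][1])
        assert np.median(ys) > 0.0

    def test_inverted_endpoints_cluster_in_screen_upper_half_too(self):
        """Inverted faces put nose/chin in the screen's upper half (180-degree
        rotation), and the mixture prefers those features."""
        cfg, rng, target, lms = self._setup(upright=False)
        ys = []
        for _ in range(2000):
            out = inject_post_saccadic_microsaccade(
                rng, cfg, np.array([0.0, -0.2]), 0.0, target, lms, False
            )
            ys.append(out["endpoint"][1])
        assert np.median(ys) > 0.0

    def test_displacement_always_below_one_degree(self):
        cfg, rng, target, lms = self._setup()
        start = np.array([0.3, 0.3])
        for _ in range(500):
            out = inject_post_saccadic_microsaccade(
                rng, cfg, start, 45.0, target, lms, True
            )
            assert np.hypot(*(out["endpoint"] - start)) < 1.0
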