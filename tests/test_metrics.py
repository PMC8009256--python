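"""Anchored-analysis tests: alignment, histograms, counts, rates, direction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import zapgaze as zg
from zapgaze import metrics
from zapgaze.validation import events_from_ground_truth


def make_trials(onsets, targets=None, ecc=5.0):
    targets = targets or [(0.0, 0.0)] * len(onsets)
    return pd.DataFrame(
        {
            "subject": 0,
            "block": 0,
            "trial_id": range(len(onsets)),
            "onset_ms": onsets,
            "target_x_deg": [t[0] for t in targets],
            "target_y_deg": [t[1] for t in targets],
            "ecc_deg": ecc,
            "upright": True,
            "scene": "no_scene",
        }
    )


def make_events(rows):
    """rows: (onset, offset, klass, x_end, y_end) tuples."""
    df = pd.DataFrame(
        rows, columns=["onset_ms", "offset_ms", "class", "x_offset", "y_offset"]
    )
    df["x_onset"] = 0.0
    df["y_onset"] = 0.0
    df["polar_angle_deg"] = 0.0
    df["magnitude_deg"] = np.where(df["class"] == "saccade", 3.0, 0.5)
    df["peak_velocity_dps"] = 100.0
    df["subject"] = 0
    return df


class TestFirstSaccade:
    def test_endpoint_near_center_is_correct(self):
        trials = make_trials([0.0])
        ev = make_events([(150.0, 180.0, "saccade", 0.2, 0.0)])
        fs = metrics.first_saccade_after_onset(trials, ev)
        assert fs["resolved"].iloc[0] and fs["correct"].iloc[0]

    def test_endpoint_outside_half_width_is_incorrect(self):
        trials = make_trials([0.0])
        ev = make_events([(150.0, 180.0, "saccade", 1.6, 0.0)])
        fs = metrics.first_saccade_after_onset(trials, ev)
        assert fs["resolved"].iloc[0] and not fs["correct"].iloc[0]

    def test_boundary_is_closed(self):
        trials = make_trials([0.0])
        ev = make_events([(150.0, 180.0, "saccade", 1.5, -1.5)])
        fs = metrics.first_saccade_after_onset(trials, ev)
        assert fs["correct"].iloc[0]

    def test_trial_without_saccade_is_unresolved(self):
        trials = make_trials([0.0, 1000.0])
        ev = make_events([(1150.0, 1180.0, "saccade", 0.0, 0.0)])
        fs = metrics.first_saccade_after_onset(trials, ev)
        assert not fs["resolved"].iloc[0]
        assert fs["resolved"].iloc[1]

    def test_simulated_hit_rate_within_binomial_ci(self, session, gt_events):
        """The generator's 84% in-window endpoint rate is recovered from the
        trial-resolved first saccades (binomial 99% CI)."""
        fs = metrics.first_saccade_after_onset(session.trials, gt_events)
        n = int(fs["resolved"].sum())
        k = int(fs["correct"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.84)
        assert lo <= k <= hi


class TestAlignAndHistogram:
    def test_single_event_raster(self):
        trials = make_trials([0.0])
        ev = make_events([(10.0, 20.0, "microsaccade", 0, 0)])
        raster = metrics.align_events(trials, ev, "trial_onset", (-100, 100))
        kt = raster.kind_times("microsaccade_start")
        assert list(kt["rel_ms"]) == [10.0]

    def test_translation_invariance(self):
        trials = make_trials([0.0, 500.0])
        ev = make_events(
            [(150.0, 170.0, "saccade", 0, 0), (650.0, 670.0, "saccade", 0, 0)]
        )
        r1 = metrics.align_events(trials, ev, "trial_onset", (-100, 300))
        trials2 = trials.assign(onset_ms=trials["onset_ms"] + 500.0)
        ev2 = ev.assign(
            onset_ms=ev["onset_ms"] + 500.0, offset_ms=ev["offset_ms"] + 500.0
        )
        r2 = metrics.align_events(trials2, ev2, "trial_onset", (-100, 300))
        assert r1.times.equals(r2.times)

    def test_empty_trials_raise(self):
        with pytest.raises(ValueError):
            metrics.align_events(make_trials([]), make_events([]), "trial_onset", (0, 100))

    def test_offset_aligned_microsaccades_fall_in_latency_band(self, session, gt_events):
        fs = metrics.first_saccade_after_onset(session.trials, gt_events)
        raster = metrics.align_events(
            session.trials, gt_events, "first_saccade_offset", (0.0, 100.0), fs
        )
        rel = raster.kind_times("microsaccade_start")["rel_ms"].to_numpy()
        assert len(rel) > 10
        assert rel.min() > 0.0 and rel.max() <= 25.0 + session.recording.dt_ms

    def test_no_events_all_bins_zero(self):
        trials = make_trials([0.0])
        raster = metrics.align_events(trials, make_events([]), "trial_onset", (0, 100))
        hist = metrics.rate_histogram(raster, 4.0)
        assert (hist.to_numpy() == 0).all()

    def test_point_mass_fills_single_bin(self):
        trials = make_trials(list(np.arange(0.0, 5000.0, 500.0)))
        ev = make_events(
            [(o + 10.0, o + 18.0, "microsaccade", 0, 0) for o in trials["onset_ms"]]
        )
        raster = metrics.align_events(trials, ev, "trial_onset", (0, 100))
        hist = metrics.rate_histogram(raster, 4.0)
        col = hist["microsaccade_start"].to_numpy()
        assert col[2] == 100.0  # bin [8, 12)
        assert col.sum() == 100.0

    def test_uniform_events_match_binomial_expectation(self):
        rng = np.random.default_rng(0)
        n = 10_000
        trials = make_trials(list(np.arange(n) * 1000.0))
        onsets = trials["onset_ms"].to_numpy() + rng.uniform(0, 100, n)
        ev = make_events(
            [(o, o + 8.0, "microsaccade", 0, 0) for o in np.sort(onsets)]
        )
        raster = metrics.align_events(trials, ev, "trial_onset", (0, 100))
        hist = metrics.rate_histogram(raster, 10.0)["microsaccade_start"]
        p = 0.1  # each trial's event lands in a given 10-ms bin w.p. 0.1
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, p) / n * 100
        assert (hist >= lo).all() and (hist <= hi).all()

    def test_bad_bin_width_raises(self):
        trials = make_trials([0.0])
        raster = metrics.align_events(trials, make_events([]), "trial_onset", (0, 100))
        with pytest.raises(ValueError):
            metrics.rate_histogram(raster, -1.0)
        with pytest.raises(ValueError):
            metrics.rate_histogram(raster, 33.0)


class TestCountDistribution:
    def test_direct_count(self):
        trials = make_trials([0.0, 1000.0, 2000.0])
        ev = make_events(
            [
                (1010.0, 1020.0, "microsaccade", 0, 0),
                (2010.0, 2020.0, "microsaccade", 0, 0),
                (2030.0, 2040.0, "microsaccade", 0, 0),
            ]
        )
        cd = metrics.microsaccade_count_distribution(trials, ev, (0, 100))
        assert cd.pct_0 == pytest.approx(100 / 3)
        assert cd.pct_1 == pytest.approx(100 / 3)
        assert cd.pct_2plus == pytest.approx(100 / 3)
        assert cd.pct_0 + cd.pct_1 + cd.pct_2plus == pytest.approx(100.0, abs=1e-9)

    def test_no_microsaccades_is_all_zero_category(self):
        cfg = zg.SimulationConfig(
            n_blocks=1, trials_per_block=30, p_post_saccadic_microsaccade=0.0, rng_seed=2
        )
        s = zg.simulate_session(cfg)
        ev = events_from_ground_truth(s.ground_truth)
        cd = metrics.microsaccade_count_distribution(s.trials, ev, (0, 100))
        assert cd.pct_0 == 100.0 and cd.pct_1 == 0.0 and cd.pct_2plus == 0.0


class TestSubjectRates:
    def test_one_event_per_trial_in_one_second_window_is_one_hz(self):
        trials = make_trials(list(np.arange(0.0, 20000.0, 2000.0)))
        ev = make_events(
            [(o + 50.0, o + 60.0, "microsaccade", 0, 0) for o in trials["onset_ms"]]
        )
        out = metrics.subject_rates(trials, ev, (-200, 800), "microsaccade")
        assert out["mean_hz"] == pytest.approx(1.0)

    def test_zero_events_zero_rate(self):
        trials = make_trials([0.0, 2000.0])
        out = metrics.subject_rates(trials, make_events([]), (-200, 800))
        assert out["mean_hz"] == 0.0
        assert not out["ci_defined"]  # single subject: CI undefined

    def test_two_subject_ci_brackets_mean(self):
        trials = pd.concat(
            [make_trials([0.0, 2000.0]).assign(subject=s) for s in (0, 1)],
            ignore_index=True,
        )
        ev = make_events([(50.0, 60.0, "microsaccade", 0, 0)]).assign(subject=0)
        out = metrics.subject_rates(trials, ev, (-200, 800))
        assert out["ci_defined"]
        lo, hi = out["ci_hz"]
        assert lo <= out["mean_hz"] <= hi

    def test_rate_matches_ground_truth_rate(self, session, detected, gt_events):
        det = metrics.subject_rates(session.trials, detected, (-200, 800))
        true = metrics.subject_rates(session.trials, gt_events, (-200, 800))
        assert det["mean_hz"] == pytest.approx(true["mean_hz"], rel=0.15)


class TestEccentricityProfile:
    def test_single_bin_populated_when_all_trials_same_ecc(self):
        trials = make_trials([0.0, 1000.0], ecc=4.5)
        ev = make_events([(100.0, 120.0, "saccade", 0, 0)])
        prof = metrics.eccentricity_profile(trials, ev, window=(0, 200))
        assert prof.trials_per_bin[0] == 2
        assert prof.trials_per_bin[1:].sum() == 0
        assert len(prof.empty_bins) == 7
        assert prof.matrices["saccade_start"][1:].sum() == 0

    def test_trial_order_invariance(self, session, gt_events):
        trials = session.trials
        prof1 = metrics.eccentricity_profile(trials, gt_events)
        perm = trials.sample(frac=1.0, random_state=1).reset_index(drop=True)
        prof2 = metrics.eccentricity_profile(perm, gt_events)
        for k in prof1.matrices:
            assert np.allclose(prof1.matrices[k], prof2.matrices[k])


class TestDirectionCongruence:
    def _fs(self, offset=200.0, angle=0.0):
        return pd.DataFrame(
            {
                "trial_pos": [0],
                "resolved": [True],
                "sacc_onset_ms": [150.0],
                "sacc_offset_ms": [offset],
                "polar_angle_deg": [angle],
                "correct": [True],
            }
        )

    def test_within_45(self):
        ev = make_events([(210.0, 220.0, "microsaccade", 0, 0)]).assign(
            polar_angle_deg=30.0
        )
        dc = metrics.direction_congruence(self._fs(angle=0.0), ev)
        assert dc.frac_within_45 == 1.0 and dc.n_pairs == 1

    def test_wraparound_difference(self):
        ev = make_events([(210.0, 220.0, "microsaccade", 0, 0)]).assign(
            polar_angle_deg=350.0
        )
        dc = metrics.direction_congruence(self._fs(angle=10.0), ev)
        assert dc.frac_within_45 == 1.0  # difference is 20 degrees

    def test_no_pairs_flagged_undefined(self):
        dc = metrics.direction_congruence(self._fs(), make_events([]))
        assert not dc.defined and dc.n_pairs == 0

    def test_fractions_sum_to_one_on_simulation(self, session, gt_events, first_sacc):
        dc = metrics.direction_congruence(first_sacc, gt_events)
        assert dc.defined
        assert dc.frac_within_45 + dc.frac_beyond_45 == pytest.approx(1.0)


class TestBruteForceEquivalence:
    def test_count_distribution_matches_explicit_loops(self, session, gt_events):
        """On ground truth, the vectorized per-trial counts agree with a
        naive double loop over trials and events."""
        trials = session.trials.head(100).reset_index(drop=True)
        window = (0.0, 100.0)
        micro = gt_events[gt_events["class"] == "microsaccade"]
        naive = []
        for _, t in trials.iterrows():
            c = 0
            for _, e in micro.iterrows():
                if t["onset_ms"] + window[0] <= e["onset_ms"] <= t["onset_ms"] + window[1]:
                    c += 1
            naive.append(c)
        naive = np.array(naive)
        cd = metrics.microsaccade_count_distribution(trials, gt_events, window)
        assert cd.pct_1 == pytest.approx(100.0 * (naive == 1).mean())
        assert cd.pct_2plus == pytest.approx(100.0 * (naive >= 2).mean())
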