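"""End-to-end pipeline: simulate -> detect -> analyze -> map -> runs.

Produces a report directory with tidy CSV tables (event tables,
occurrence histograms, count distributions, rates, eccentricity profiles,
heatmap matrices, run tables) and a QC JSON (detector thresholds,
unresolved trials, heatmap boundary mass).  Outputs are deterministic
given the seed; every row is traceable to a subject and trial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, landmarks, metrics, runs, validation
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Serializable configuration for one full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    detection: detect.DetectionParams = field(default_factory=detect.DetectionParams)
    n_subjects: int = 2
    seed: int = 0
    use_ground_truth_events: bool = False  # bypass detection (identity check)
    anchor_window_ms: tuple[float, float] = (-200.0, 800.0)
    bin_width_ms: float = 4.0
    association_window_ms: float = 100.0
    ecc_edges: tuple = tuple(np.arange(4.0, 21.0, 2.0))
    write_gaze: bool = False


def save_config(config: PipelineConfig, path) -> None:
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [_plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulation", {})
    det_raw = raw.pop("detection", {})
    for key in ("screen_px", "screen_deg", "microsaccade_latency_range_ms",
                "miss_distance_range_deg", "microsaccade_amplitude_range_deg"):
        if key in sim_raw and isinstance(sim_raw[key], list):
            sim_raw[key] = tuple(sim_raw[key])
    if "conditions" in sim_raw:
        sim_raw["conditions"] = tuple(tuple(c) for c in sim_raw["conditions"])
    if "allowed_polar_sectors" in sim_raw:
        sim_raw["allowed_polar_sectors"] = tuple(
            tuple(s) for s in sim_raw["allowed_polar_sectors"]
        )
    cfg = PipelineConfig(
        simulation=SimulationConfig(**sim_raw),
        detection=detect.DetectionParams(**det_raw),
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.items()
            if k in PipelineConfig.__dataclass_fields__
        },
    )
    return cfg


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full analysis and write the figure-analog report.

    Returns the report directory path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, rng_seed=config.seed)
    sessions = simulate_cohort(sim, config.n_subjects, base_seed=config.seed)

    all_trials, all_events, all_gt = [], [], []
    qc: dict = {"subjects": {}, "detection_bypassed": config.use_ground_truth_events}
    for sess in sessions:
        if config.use_ground_truth_events:
            ev = validation.events_from_ground_truth(sess.ground_truth)
        else:
            ev = detect.detect_session(
                sess.recording, config.detection, sess.block_bounds_ms
            )
            ev["subject"] = sess.subject
            qc["subjects"][str(sess.subject)] = {
                "thresholds_per_block": [
                    [float(a), float(b)]
                    for a, b in ev.attrs.get("thresholds_per_segment", [])
                ]
            }
        all_trials.append(sess.trials)
        all_events.append(ev)
        all_gt.append(sess.ground_truth)
        if config.write_gaze:
            sess.recording.to_csv(out / f"gaze_s{sess.subject:02d}.csv")

    trials = pd.concat(all_trials, ignore_index=True)
    gt = pd.concat(all_gt, ignore_index=True)
    events_by_subject = {s.subject: e for s, e in zip(sessions, all_events)}

    trials.to_csv(out / "trials.csv", index=False)
    gt.to_csv(out / "ground_truth.csv", index=False)
    pd.concat(all_events, ignore_index=True).to_csv(out / "events.csv", index=False)
    save_config(config, out / "config.yaml")

    # Per-subject anchored analyses, pooled at the trial level.
    hists = {}
    unresolved = 0
    counts_rows = []
    dir_pairs = {"within": 0, "beyond": 0}
    flags_correct, flags_free = [], []
    run_tables = {"correct": runs.RunTable({}, 0, 0, "correct"),
                  "microsaccade_free": runs.RunTable({}, 0, 0, "microsaccade_free")}
    mapped_frames = []
    template = landmarks.TemplateFace.default()
    for sess in sessions:
        tr = sess.trials.reset_index(drop=True)
        ev = events_by_subject[sess.subject]
        fs = metrics.first_saccade_after_onset(tr, ev)
        unresolved += int((~fs["resolved"]).sum())
        for anchor in ("trial_onset", "first_saccade_onset", "first_saccade_offset"):
            raster = metrics.align_events(
                tr, ev, anchor, config.anchor_window_ms, first_sacc=fs
            )
            hist = metrics.rate_histogram(raster, config.bin_width_ms)
            hists.setdefault(anchor, []).append(hist * raster.n_trials)
        for label, window, anchor in (
            ("pre_onset_100", (-100.0, 0.0), "trial_onset"),
            ("post_onset_100", (0.0, 100.0), "trial_onset"),
            ("post_offset_100", (0.0, 100.0), "first_saccade_offset"),
        ):
            cd = metrics.microsaccade_count_distribution(
                tr, ev, window, anchor, first_sacc=fs
            )
            counts_rows.append(
                {"subject": sess.subject, "window": label,
                 "pct_0": cd.pct_0, "pct_1": cd.pct_1, "pct_2plus": cd.pct_2plus}
            )
        dc = metrics.direction_congruence(fs, ev, config.association_window_ms)
        if dc.defined:
            dir_pairs["within"] += round(dc.frac_within_45 * dc.n_pairs)
            dir_pairs["beyond"] += round(dc.frac_beyond_45 * dc.n_pairs)
        fc = runs.trial_flags(tr, ev, "correct", fs, config.anchor_window_ms)
        ff = runs.trial_flags(tr, ev, "microsaccade_free", fs, config.anchor_window_ms)
        run_tables["correct"] = run_tables["correct"].merge(
            runs.run_table_per_block(tr, fc, "correct")
        )
        run_tables["microsaccade_free"] = run_tables["microsaccade_free"].merge(
            runs.run_table_per_block(tr, ff, "microsaccade_free")
        )
        ev_assigned = metrics.assign_trials(tr, ev)
        mapped = landmarks.map_session_endpoints(tr, ev_assigned, template)
        mapped["subject"] = sess.subject
        mapped["upright"] = tr["upright"].to_numpy()[mapped["trial_pos"]]
        mapped_frames.append(mapped)

    n_trials_total = len(trials)
    for anchor, parts in hists.items():
        # parts are per-subject histograms x n_trials; renormalize to a
        # trial-weighted pooled percentage.
        pooled = sum(parts) / n_trials_total
        pooled.to_csv(out / f"rate_histogram_{anchor}.csv")
    pd.DataFrame(counts_rows).to_csv(out / "count_distributions.csv", index=False)

    rates = {}
    for kind in ("saccade", "microsaccade"):
        r = metrics.subject_rates(
            trials, pd.concat(all_events, ignore_index=True),
            config.anchor_window_ms, kind
        )
        r["per_subject"].to_csv(out / f"rates_{kind}.csv", index=False)
        rates[kind] = {"mean_hz": r["mean_hz"], "ci_hz": list(r["ci_hz"])}

    # Eccentricity profile pooled across subjects (trial onsets are
    # subject-local, so compute per subject and average with trial weights).
    ecc_parts = []
    for sess in sessions:
        prof = metrics.eccentricity_profile(
            sess.trials.reset_index(drop=True),
            events_by_subject[sess.subject],
            np.asarray(config.ecc_edges),
            window=config.anchor_window_ms,
            bin_width_ms=config.bin_width_ms,
        )
        ecc_parts.append(prof)
    for kind in metrics.EVENT_KINDS:
        weights = np.array([p.trials_per_bin for p in ecc_parts])  # (subj, ecc)
        stacked = np.array([p.matrices[kind] for p in ecc_parts])
        denom = np.maximum(weights.sum(axis=0), 1)[:, None]
        pooled = (stacked * weights[:, :, None]).sum(axis=0) / denom
        pd.DataFrame(
            pooled,
            index=pd.Index(ecc_parts[0].ecc_edges[:-1], name="ecc_bin_lo"),
            columns=ecc_parts[0].time_edges[:-1],
        ).to_csv(out / f"ecc_profile_{kind}.csv")

    mapped_all = pd.concat(mapped_frames, ignore_index=True)
    mapped_all.to_csv(out / "mapped_endpoints.csv", index=False)
    boundary_loss = {}
    for upright in (True, False):
        for klass in ("saccade", "microsaccade"):
            sel = mapped_all[
                (mapped_all["upright"] == upright) & (mapped_all["class"] == klass)
            ]
            hm = landmarks.endpoint_heatmap(
                sel[["x_template_deg", "y_template_deg"]].to_numpy()
            )
            tag = f"{klass}_{'upright' if upright else 'inverted'}"
            pd.DataFrame(hm.values).to_csv(out / f"heatmap_{tag}.csv", index=False)
            boundary_loss[tag] = hm.boundary_mass_loss

    for label, table in run_tables.items():
        table.to_frame().to_csv(out / f"runs_{label}.csv", index=False)

    n_dir = dir_pairs["within"] + dir_pairs["beyond"]
    qc.update(
        {
            "n_trials": int(n_trials_total),
            "n_unresolved_trials": int(unresolved),
            "rates_hz": rates,
            "direction_congruence": {
                "n_pairs": int(n_dir),
                "frac_beyond_45": (dir_pairs["beyond"] / n_dir) if n_dir else None,
            },
            "heatmap_boundary_mass_loss": boundary_loss,
            "longest_runs": {k: t.longest for k, t in run_tables.items()},
        }
    )
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=2, sort_keys=True)
    return out
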