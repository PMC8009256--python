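"""Synthetic gaze traces for the continuous visual-search "zapping" task.

The generator emulates a task in which an observer continuously targets
small (3-degree) upright or inverted faces: as soon as gaze has dwelled
inside the 3x3-degree window around the face for two samples, the screen
is redrawn (median update latency 18 ms) with a new face at a new
location, and the next trial begins.  Sessions consist of blocks of 500
trials in one of four conditions (scene/no-scene x upright/inverted),
with block order counterbalanced across simulated subjects.

Each trial produces a targeting saccade (latency ~ Gamma, endpoints
scattered around face landmarks so that a configurable fraction lands
in-window), optionally a corrective saccade after a miss, and - with
probability ``p_post_saccadic_microsaccade`` - a single small (< 1 degree)
post-saccadic microsaccade launched 1-25 ms after the saccade offset,
whose endpoint is drawn from a landmark-anchored mixture that prefers the
eyes/forehead for upright faces and the nose/chin for inverted ones.
Saccade kinematics obey a saturating main-sequence law with raised-cosine
velocity profiles.  Every injected movement is recorded in a ground-truth
log for detector validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmarks import CANONICAL_LANDMARKS_DEG, LANDMARK_NAMES
from .recording import GazeRecording

__all__ = [
    "SimulationConfig",
    "SessionData",
    "simulate_session",
    "simulate_cohort",
    "sample_target_position",
    "synthesize_saccade",
    "inject_post_saccadic_microsaccade",
    "CONDITIONS",
]

# (scene, upright) pairs; order matters for counterbalancing.
CONDITIONS = (
    ("no_scene", "upright"),
    ("no_scene", "inverted"),
    ("scene", "upright"),
    ("scene", "inverted"),
)

_DEFAULT_WEIGHTS_UPRIGHT = {
    "hair_top_middle": 0.05,
    "forehead_top_middle": 0.20,
    "left_eye": 0.25,
    "right_eye": 0.25,
    "nose_tip": 0.10,
    "mouth_center": 0.10,
    "chin_bottom_center": 0.05,
}
_DEFAULT_WEIGHTS_INVERTED = {
    "hair_top_middle": 0.05,
    "forehead_top_middle": 0.05,
    "left_eye": 0.10,
    "right_eye": 0.10,
    "nose_tip": 0.25,
    "mouth_center": 0.25,
    "chin_bottom_center": 0.20,
}

TRIAL_COLUMNS = (
    ["subject", "block", "trial_id", "onset_ms", "target_x_deg", "target_y_deg",
     "scene", "upright", "ecc_deg"]
    + [f"lm_{name}_{ax}" for name in LANDMARK_NAMES for ax in ("x", "y")]
)

GT_COLUMNS = [
    "subject", "trial_id", "class", "onset_ms", "offset_ms",
    "x_start", "y_start", "x_end", "y_end",
    "amplitude_deg", "peak_velocity_dps", "landmark", "congruent",
]


@dataclass
class SimulationConfig:
    """All tunable knobs of the session generator.

    Timing, geometry and probability defaults encode the task's published
    design (screen 31 x 22 degrees at 2560 x 1440 px, 3-degree faces,
    2-sample dwell, 18 ms median screen update, blocks of 500 trials, four
    conditions, microsaccades 1-25 ms after saccade offset).  Quantities
    the task description leaves open (fixation noise, saccade latency,
    endpoint scatter) default to literature-typical values; see the
    methods note.
    """

    sampling_rate: float = 1250.0
    screen_px: tuple[int, int] = (2560, 1440)
    screen_deg: tuple[float, float] = (31.0, 22.0)
    face_height_deg: float = 3.0
    target_window_deg: float = 3.0
    dwell_samples: int = 2
    screen_update_median_ms: float = 18.0
    screen_update_jitter_sd_ms: float = 1.5
    tracker_delay_ms: float = 5.0
    n_blocks: int = 8
    trials_per_block: int = 500
    conditions: tuple = CONDITIONS
    placement_scheme: str = "full_screen"  # or "step4deg"
    step_eccentricity_deg: float = 4.0
    allowed_polar_sectors: tuple = ((0.0, 45.0), (135.0, 235.0), (315.0, 360.0))
    p_post_saccadic_microsaccade: float = 0.2
    microsaccade_latency_range_ms: tuple[float, float] = (1.0, 25.0)
    fixation_noise_sd_deg: float = 0.02
    drift_sd_deg: float = 0.0
    main_sequence_vmax: float = 750.0
    main_sequence_c: float = 8.0
    saccade_latency_mean_ms: float = 150.0
    saccade_latency_sd_ms: float = 30.0
    p_target_hit: float = 0.84
    p_direction_incongruent: float = 0.84
    saccade_endpoint_jitter_sd_deg: float = 0.25
    miss_distance_range_deg: tuple[float, float] = (2.2, 3.8)
    microsaccade_amplitude_range_deg: tuple[float, float] = (0.60, 0.90)
    landmark_jitter_sd_deg: float = 0.05
    landmark_weights_upright: dict = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS_UPRIGHT)
    )
    landmark_weights_inverted: dict = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS_INVERTED)
    )
    initial_fixation_ms: float = 200.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.trials_per_block <= 0 or self.n_blocks <= 0:
            raise ValueError("n_blocks and trials_per_block must be positive")
        if not 0.0 <= self.p_post_saccadic_microsaccade <= 1.0:
            raise ValueError("p_post_saccadic_microsaccade must be in [0, 1]")
        if self.step_eccentricity_deg <= 0:
            raise ValueError("step_eccentricity_deg must be positive")
        for lo, hi in self.allowed_polar_sectors:
            if not (0.0 <= lo <= hi <= 360.0):
                raise ValueError("allowed_polar_sectors must be subsets of [0, 360]")
        if self.placement_scheme not in ("full_screen", "step4deg"):
            raise ValueError("placement_scheme must be 'full_screen' or 'step4deg'")
        lo, hi = self.microsaccade_latency_range_ms
        if not 0 < lo < hi:
            raise ValueError("microsaccade_latency_range_ms must be an increasing positive pair")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def window_half_deg(self) -> float:
        return self.target_window_deg / 2.0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def deg_per_px(self) -> tuple[float, float]:
        return (
            self.screen_deg[0] / self.screen_px[0],
            self.screen_deg[1] / self.screen_px[1],
        )


@dataclass
class SessionData:
    """One simulated subject-session: recording, trial log, ground truth."""

    recording: GazeRecording
    trials: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig
    subject: int = 0

    @property
    def block_bounds_ms(self) -> list[tuple[float, float]]:
        """Half-open time windows covering each block, for per-block detection."""
        starts = self.trials.groupby("block")["onset_ms"].min().sort_index()
        bounds = []
        t_end = float(self.recording.t_ms[-1]) + self.recording.dt_ms
        margin = self.config.initial_fixation_ms
        for i, s in enumerate(starts):
            lo = max(0.0, float(s) - margin)
            hi = max(0.0, float(starts.iloc[i + 1]) - margin) if i + 1 < len(starts) else t_end
            bounds.append((lo, hi))
        return bounds

    def write(self, out_dir, write_gaze: bool = True) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"s{self.subject:02d}"
        if write_gaze:
            self.recording.to_csv(out / f"gaze_{tag}.csv")
        self.trials.to_csv(out / f"trials_{tag}.csv", index=False)
        self.ground_truth.to_csv(out / f"ground_truth_{tag}.csv", index=False)


def _angdiff(a: float, b: float) -> float:
    """Absolute angular difference in degrees, in [0, 180]."""
    d = abs((a - b) % 360.0)
    return min(d, 360.0 - d)


def _sample_sector_angle(sectors, rng: np.random.Generator) -> float:
    widths = np.array([hi - lo for lo, hi in sectors], dtype=float)
    total = widths.sum()
    if total <= 0:  # degenerate zero-width sectors: pick an endpoint
        lo, _ = sectors[int(rng.integers(len(sectors)))]
        return float(lo)
    k = int(rng.choice(len(sectors), p=widths / total))
    lo, hi = sectors[k]
    return float(rng.uniform(lo, hi))


def sample_target_position(
    previous_center: np.ndarray,
    scheme: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Draw the next target center.

    ``full_screen``: uniform over the screen with the whole 3x3-degree
    window on-screen.  ``step4deg``: exactly ``step_eccentricity_deg`` from
    the previous center at a polar angle uniform over the allowed sectors,
    resampled until the window fits on-screen.
    """
    half_w = config.screen_deg[0] / 2.0 - config.window_half_deg
    half_h = config.screen_deg[1] / 2.0 - config.window_half_deg
    if half_w <= 0 or half_h <= 0:
        raise ValueError("target window does not fit on the screen")
    if scheme == "full_screen":
        return np.array(
            [rng.uniform(-half_w, half_w), rng.uniform(-half_h, half_h)]
        )
    if scheme != "step4deg":
        raise ValueError(f"unknown placement scheme {scheme!r}")
    prev = np.asarray(previous_center, dtype=float)
    for _ in range(max_attempts):
        ang = np.deg2rad(_sample_sector_angle(config.allowed_polar_sectors, rng))
        cand = prev + config.step_eccentricity_deg * np.array(
            [np.cos(ang), np.sin(ang)]
        )
        if abs(cand[0]) <= half_w and abs(cand[1]) <= half_h:
            return cand
    raise ValueError(
        "could not place a target on-screen with the step4deg scheme; "
        "check step_eccentricity_deg against the screen size"
    )


def _main_sequence_peak(amplitude: float, config: SimulationConfig) -> float:
    return config.main_sequence_vmax * (
        1.0 - np.exp(-amplitude / config.main_sequence_c)
    )


def synthesize_saccade(
    amplitude: float, direction_deg: float, config: SimulationConfig
) -> np.ndarray:
    """Raised-cosine saccade waveform sampled on the recording clock.

    Returns an ``(n + 1, 2)`` array of positions starting at the origin and
    ending at the commanded displacement; the displacement magnitude equals
    ``amplitude`` exactly and the peak velocity equals the main-sequence
    value ``vmax * (1 - exp(-A/C))`` up to discretization.  The duration
    follows from the raised-cosine constraint ``D = 2 A / V_peak``.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    dt = config.dt_ms
    if amplitude == 0.0:
        return np.zeros((2, 2))
    vp = _main_sequence_peak(amplitude, config)  # deg/s
    dur_ms = 2.0 * amplitude / vp * 1000.0
    n = max(int(np.ceil(dur_ms / dt)), 2)
    t = np.minimum(np.arange(0, n + 1) * dt, dur_ms)
    s = amplitude * (t / dur_ms - np.sin(2.0 * np.pi * t / dur_ms) / (2.0 * np.pi))
    u = np.array([np.cos(np.deg2rad(direction_deg)), np.sin(np.deg2rad(direction_deg))])
    return np.outer(s, u)


def _trial_landmarks(
    rng: np.random.Generator, config: SimulationConfig, center: np.ndarray, upright: bool
) -> np.ndarray:
    """Per-trial landmark positions: jittered canonical layout, rotated 180
    degrees for inverted faces (left/right labels stay on the same physical
    features, so the template correspondence needs no reflection)."""
    h = config.face_height_deg / 3.0
    base = CANONICAL_LANDMARKS_DEG * h
    jit = rng.normal(0.0, config.landmark_jitter_sd_deg, size=base.shape)
    pts = base + jit
    pts[:, 0] = np.clip(pts[:, 0], -0.75 * h, 0.75 * h)
    pts[:, 1] = np.clip(pts[:, 1], -1.5 * h, 1.5 * h)
    scale = 1.0 + float(np.clip(rng.normal(0.0, 0.03), -0.06, 0.06))
    rot = float(np.clip(rng.normal(0.0, 2.0), -5.0, 5.0))
    if not upright:
        rot += 180.0
    th = np.deg2rad(rot)
    rot_m = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return center + scale * pts @ rot_m.T


def _weighted_landmark(
    rng: np.random.Generator, weights: dict, landmarks: np.ndarray
) -> tuple[str, np.ndarray]:
    names = LANDMARK_NAMES
    w = np.array([weights[n] for n in names], dtype=float)
    w = w / w.sum()
    k = int(rng.choice(len(names), p=w))
    return names[k], landmarks[k]


def _sample_hit_endpoint(
    rng: np.random.Generator,
    config: SimulationConfig,
    target: np.ndarray,
    landmarks: np.ndarray,
    upright: bool,
) -> tuple[str, np.ndarray]:
    weights = (
        config.landmark_weights_upright if upright else config.landmark_weights_inverted
    )
    half = config.window_half_deg
    for _ in range(50):
        name, anchor = _weighted_landmark(rng, weights, landmarks)
        pt = anchor + rng.normal(0.0, config.saccade_endpoint_jitter_sd_deg, size=2)
        if np.abs(pt - target).max() <= half:
            return name, pt
    return name, target + np.clip(pt - target, -half, half)


def inject_post_saccadic_microsaccade(
    rng: np.random.Generator,
    config: SimulationConfig,
    saccade_end: np.ndarray,
    saccade_angle_deg: float,
    target: np.ndarray,
    landmarks: np.ndarray,
    upright: bool,
) -> dict | None:
    """Draw the post-saccadic microsaccade for one completed targeting saccade.

    With probability ``p_post_saccadic_microsaccade``, returns a dict with
    the onset latency (uniform over the configured 1-25 ms range, snapped
    to the sample clock), an endpoint from the orientation-weighted
    landmark mixture with amplitude clamped below 1 degree, and the
    congruence class of its direction relative to the preceding saccade
    (incongruent, i.e. more than 45 degrees away, with probability
    ``p_direction_incongruent``).  Returns None otherwise.
    """
    if rng.random() >= config.p_post_saccadic_microsaccade:
        return None
    incongruent = rng.random() < config.p_direction_incongruent
    lo_amp, hi_amp = config.microsaccade_amplitude_range_deg
    weights = (
        config.landmark_weights_upright if upright else config.landmark_weights_inverted
    )
    half = config.window_half_deg
    chosen = None
    for _ in range(200):
        name, anchor = _weighted_landmark(rng, weights, landmarks)
        pt = anchor + rng.normal(0.0, 0.08, size=2)
        d = pt - saccade_end
        amp = float(np.hypot(*d))
        if amp < 1e-9:
            continue
        amp_clamped = float(np.clip(amp, lo_amp, hi_amp))
        pt = saccade_end + d / amp * amp_clamped
        if np.abs(pt - target).max() > half:
            continue
        ang = float(np.degrees(np.arctan2(d[1], d[0])) % 360.0)
        if (_angdiff(ang, saccade_angle_deg) > 45.0) == incongruent:
            chosen = (name, pt, ang)
            break
    if chosen is None:
        # Construct the direction explicitly within the desired congruence class.
        for _ in range(50):
            if incongruent:
                off = rng.uniform(50.0, 310.0)
            else:
                off = rng.uniform(-40.0, 40.0)
            ang = (saccade_angle_deg + off) % 360.0
            amp = rng.uniform(lo_amp, hi_amp)
            pt = saccade_end + amp * np.array(
                [np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))]
            )
            if np.abs(pt - target).max() <= half:
                break
        chosen = ("none", pt, ang)
    name, pt, ang = chosen
    lo_ms, hi_ms = config.microsaccade_latency_range_ms
    dt = config.dt_ms
    gap_lo = max(1, int(np.ceil(lo_ms / dt)))
    gap_hi = max(gap_lo, int(np.floor(hi_ms / dt)))
    gap_samples = int(rng.integers(gap_lo, gap_hi + 1))
    return {
        "latency_samples": gap_samples,
        "endpoint": pt,
        "landmark": name,
        "congruent": not incongruent,
    }


def _draw_latency_samples(rng: np.random.Generator, config: SimulationConfig) -> int:
    mean, sd = config.saccade_latency_mean_ms, config.saccade_latency_sd_ms
    if sd <= 0:
        lat_ms = mean
    else:
        shape = (mean / sd) ** 2
        lat_ms = rng.gamma(shape, mean / shape)
    return max(int(round(lat_ms / config.dt_ms)), 40)


def simulate_session(config: SimulationConfig, subject: int = 0) -> SessionData:
    """Simulate one subject-session of the zapping task.

    Returns a continuous recording spanning all ``n_blocks x
    trials_per_block`` trials, the trial log (onset, target, landmarks,
    condition, eccentricity at onset) and the ground-truth event log.
    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.rng_seed)
    dt = config.dt_ms
    half = config.window_half_deg

    perms = list(itertools.permutations(range(len(config.conditions))))
    order = perms[subject % len(perms)]

    chunks: list[np.ndarray] = []
    n_written = 0

    def append(arr: np.ndarray) -> None:
        nonlocal n_written
        chunks.append(arr)
        n_written += len(arr)

    def fixate_until(idx: int, pos: np.ndarray) -> None:
        if idx > n_written:
            append(np.tile(pos, (idx - n_written, 1)))

    gaze = np.zeros(2)
    prev_center = np.zeros(2)
    onset_idx = int(round(config.initial_fixation_ms / dt))
    trial_rows: list[dict] = []
    gt_rows: list[dict] = []
    trial_id = 0

    for block in range(config.n_blocks):
        scene, orientation = config.conditions[order[block % len(config.conditions)]]
        upright = orientation == "upright"
        for _ in range(config.trials_per_block):
            target = sample_target_position(
                prev_center, config.placement_scheme, rng, config
            )
            landmarks = _trial_landmarks(rng, config, target, upright)
            prev_center = target
            anchor_idx = onset_idx
            attempts = 0
            while True:
                lat_samples = _draw_latency_samples(rng, config)
                start_idx = max(anchor_idx + lat_samples, n_written + 1)
                hit = attempts >= 2 or rng.random() < config.p_target_hit
                if hit:
                    lm_name, endpoint = _sample_hit_endpoint(
                        rng, config, target, landmarks, upright
                    )
                else:
                    lm_name = "none"
                    for _ in range(20):
                        ang = rng.uniform(0.0, 360.0)
                        dist = rng.uniform(*config.miss_distance_range_deg)
                        endpoint = target + dist * np.array(
                            [np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))]
                        )
                        endpoint[0] = np.clip(
                            endpoint[0],
                            -config.screen_deg[0] / 2 + 0.2,
                            config.screen_deg[0] / 2 - 0.2,
                        )
                        endpoint[1] = np.clip(
                            endpoint[1],
                            -config.screen_deg[1] / 2 + 0.2,
                            config.screen_deg[1] / 2 - 0.2,
                        )
                        if np.abs(endpoint - target).max() > half:
                            break
                delta = endpoint - gaze
                amplitude = max(float(np.hypot(*delta)), 0.02)
                direction = float(np.degrees(np.arctan2(delta[1], delta[0])) % 360.0)
                wave = synthesize_saccade(amplitude, direction, config)
                fixate_until(start_idx, gaze)
                append(gaze + wave[1:])
                offset_idx = n_written - 1
                gt_rows.append(
                    {
                        "subject": subject,
                        "trial_id": trial_id,
                        "class": "saccade" if amplitude >= 1.0 else "microsaccade",
                        "onset_ms": start_idx * dt,  # first moving sample
                        "offset_ms": offset_idx * dt,
                        "x_start": gaze[0],
                        "y_start": gaze[1],
                        "x_end": endpoint[0],
                        "y_end": endpoint[1],
                        "amplitude_deg": amplitude,
                        "peak_velocity_dps": _main_sequence_peak(amplitude, config),
                        "landmark": lm_name,
                        "congruent": np.nan,
                    }
                )
                gaze = endpoint.copy()
                if np.abs(endpoint - target).max() <= half:
                    break
                anchor_idx = offset_idx + 1
                attempts += 1

            # Trial advance: dwell inside the window, tracker transmission
            # delay, then the screen update.
            update_ms = max(
                float(rng.normal(config.screen_update_median_ms,
                                 config.screen_update_jitter_sd_ms)),
                5.0,
            )
            delta_samples = config.dwell_samples + int(
                round((config.tracker_delay_ms + update_ms) / dt)
            )
            next_onset_idx = offset_idx + delta_samples

            micro = inject_post_saccadic_microsaccade(
                rng, config, gaze, direction, target, landmarks, upright
            )
            # A pending microsaccade is suppressed if the next stimulus
            # appears before it launches (stimulus change cancels the plan).
            if micro is not None and offset_idx + micro["latency_samples"] < next_onset_idx:
                m_start = offset_idx + micro["latency_samples"]
                m_delta = micro["endpoint"] - gaze
                m_amp = float(np.hypot(*m_delta))
                m_dir = float(np.degrees(np.arctan2(m_delta[1], m_delta[0])) % 360.0)
                m_wave = synthesize_saccade(m_amp, m_dir, config)
                fixate_until(m_start, gaze)
                append(gaze + m_wave[1:])
                gt_rows.append(
                    {
                        "subject": subject,
                        "trial_id": trial_id,
                        "class": "microsaccade",
                        "onset_ms": m_start * dt,  # first moving sample
                        "offset_ms": (n_written - 1) * dt,
                        "x_start": gaze[0],
                        "y_start": gaze[1],
                        "x_end": micro["endpoint"][0],
                        "y_end": micro["endpoint"][1],
                        "amplitude_deg": m_amp,
                        "peak_velocity_dps": _main_sequence_peak(m_amp, config),
                        "landmark": micro["landmark"],
                        "congruent": micro["congruent"],
                    }
                )
                gaze = micro["endpoint"].copy()

            row = {
                "subject": subject,
                "block": block,
                "trial_id": trial_id,
                "onset_ms": onset_idx * dt,
                "target_x_deg": target[0],
                "target_y_deg": target[1],
                "scene": scene,
                "upright": upright,
                "ecc_deg": np.nan,  # filled from the assembled trace below
            }
            for name, (lx, ly) in zip(LANDMARK_NAMES, landmarks):
                row[f"lm_{name}_x"] = lx
                row[f"lm_{name}_y"] = ly
            trial_rows.append(row)
            trial_id += 1
            onset_idx = next_onset_idx

    fixate_until(n_written + int(round(200.0 / dt)), gaze)
    clean = np.concatenate(chunks, axis=0)
    noisy = clean + rng.normal(0.0, config.fixation_noise_sd_deg, size=clean.shape)
    if config.drift_sd_deg > 0:
        noisy += np.cumsum(
            rng.normal(0.0, config.drift_sd_deg, size=clean.shape), axis=0
        )
    t_ms = np.arange(len(clean)) * dt
    rec = GazeRecording(t_ms, noisy[:, 0], noisy[:, 1], config.sampling_rate)

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    onset_samples = np.minimum(
        np.round(trials["onset_ms"].to_numpy() / dt).astype(int), len(clean) - 1
    )
    trials["ecc_deg"] = np.hypot(
        clean[onset_samples, 0] - trials["target_x_deg"].to_numpy(),
        clean[onset_samples, 1] - trials["target_y_deg"].to_numpy(),
    )
    gt = pd.DataFrame(gt_rows, columns=GT_COLUMNS)
    return SessionData(
        recording=rec, trials=trials, ground_truth=gt, config=config, subject=subject
    )


def simulate_cohort(
    config: SimulationConfig, n_subjects: int, base_seed: int | None = None
) -> list[SessionData]:
    """Simulate several subjects with independent seeds and counterbalanced
    block orders (subject index selects one of the 24 condition orderings)."""
    if base_seed is None:
        base_seed = config.rng_seed
    seeds = np.random.SeedSequence(base_seed).generate_state(n_subjects) % (2**31)
    return [
        simulate_session(replace(config, rng_seed=int(seeds[i])), subject=i)
        for i in range(n_subjects)
    ]
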