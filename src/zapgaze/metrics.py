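"""Trial- and saccade-anchored analyses of detected events.

Events are expressed relative to one of three anchors - trial onset, the
onset of the first saccade after trial onset, or its offset - and
summarized as occurrence histograms (percent of trials with an event
onset per time bin), microsaccade count distributions, per-subject rates,
eccentricity-resolved profiles and saccade/microsaccade direction
congruence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_trials",
    "first_saccade_after_onset",
    "align_events",
    "AlignedRaster",
    "rate_histogram",
    "microsaccade_count_distribution",
    "CountDistribution",
    "subject_rates",
    "targeting_rate",
    "eccentricity_profile",
    "EccentricityProfile",
    "direction_congruence",
    "DirectionCongruence",
    "pre_saccade_microsaccade_fraction",
]

ANCHOR_KINDS = ("trial_onset", "first_saccade_onset", "first_saccade_offset")
EVENT_KINDS = ("saccade_start", "saccade_end", "microsaccade_start")


def assign_trials(trials: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``trial_pos`` column: the row position (in ``trials``) of the
    trial whose [onset, next onset) interval contains the event onset; -1
    for events before the first trial onset."""
    onsets = trials["onset_ms"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("trial onsets must be strictly increasing")
    out = events.copy()
    out["trial_pos"] = (
        np.searchsorted(onsets, events["onset_ms"].to_numpy(), side="right") - 1
    )
    return out


def first_saccade_after_onset(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    window_half_deg: float = 1.5,
) -> pd.DataFrame:
    """Resolve, per trial, the first saccade after trial onset.

    Returns one row per trial with the saccade's onset/offset, endpoint,
    direction, and a ``correct`` flag (endpoint inside the closed
    3x3-degree window around the target).  Trials with no saccade before
    the next trial's onset are flagged ``resolved = False``.
    """
    sacc = events[events["class"] == "saccade"].sort_values("onset_ms")
    s_on = sacc["onset_ms"].to_numpy()
    onsets = trials["onset_ms"].to_numpy()
    next_onsets = np.append(onsets[1:], np.inf)
    rows = []
    for i in range(len(trials)):
        j = np.searchsorted(s_on, onsets[i], side="left")
        row = {
            "trial_pos": i,
            "resolved": False,
            "sacc_onset_ms": np.nan,
            "sacc_offset_ms": np.nan,
            "x_end": np.nan,
            "y_end": np.nan,
            "polar_angle_deg": np.nan,
            "correct": False,
        }
        if j < len(s_on) and s_on[j] < next_onsets[i]:
            ev = sacc.iloc[j]
            tx = trials["target_x_deg"].iloc[i]
            ty = trials["target_y_deg"].iloc[i]
            correct = (
                abs(ev["x_offset"] - tx) <= window_half_deg + 1e-9
                and abs(ev["y_offset"] - ty) <= window_half_deg + 1e-9
            )
            row.update(
                resolved=True,
                sacc_onset_ms=ev["onset_ms"],
                sacc_offset_ms=ev["offset_ms"],
                x_end=ev["x_offset"],
                y_end=ev["y_offset"],
                polar_angle_deg=ev["polar_angle_deg"],
                correct=bool(correct),
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AlignedRaster:
    """Event times relative to a per-trial anchor, split by event kind.

    ``times`` holds one row per (trial, event) pair with the relative time
    in ms; every stored time lies inside ``window``.  ``n_trials`` counts
    trials with a resolvable anchor; unresolved trials are excluded and
    counted.
    """

    anchor: str
    window: tuple[float, float]
    times: pd.DataFrame  # columns: trial_pos, kind, rel_ms
    n_trials: int
    n_unresolved: int

    def kind_times(self, kind: str) -> pd.DataFrame:
        return self.times[self.times["kind"] == kind]


def _anchors(
    trials: pd.DataFrame,
    anchor: str,
    first_sacc: pd.DataFrame | None,
) -> np.ndarray:
    if anchor == "trial_onset":
        return trials["onset_ms"].to_numpy(dtype=float)
    if first_sacc is None:
        raise ValueError(f"anchor {anchor!r} requires the first-saccade table")
    col = "sacc_onset_ms" if anchor == "first_saccade_onset" else "sacc_offset_ms"
    if anchor not in ANCHOR_KINDS:
        raise ValueError(f"unknown anchor {anchor!r}")
    return first_sacc[col].to_numpy(dtype=float)


def align_events(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    anchor: str = "trial_onset",
    window: tuple[float, float] = (-200.0, 800.0),
    first_sacc: pd.DataFrame | None = None,
) -> AlignedRaster:
    """Express event times relative to each trial's anchor.

    All events falling inside ``window`` around a trial's anchor are
    attributed to that trial, regardless of which trial interval they
    nominally belong to (peri-event alignment across the continuous
    recording, so neighboring trials' events appear at the window edges
    just as they do in the task).
    """
    if len(trials) == 0:
        raise ValueError("align_events requires at least one trial")
    w0, w1 = window
    if not w0 < w1:
        raise ValueError("window must be an increasing (start, end) pair")
    anchors = _anchors(trials, anchor, first_sacc)
    ok = np.isfinite(anchors)
    kind_sources = {
        "saccade_start": events.loc[events["class"] == "saccade", "onset_ms"],
        "saccade_end": events.loc[events["class"] == "saccade", "offset_ms"],
        "microsaccade_start": events.loc[
            events["class"] == "microsaccade", "onset_ms"
        ],
    }
    frames = []
    for kind, series in kind_sources.items():
        t = np.sort(series.to_numpy(dtype=float))
        for pos in np.flatnonzero(ok):
            a = anchors[pos]
            lo = np.searchsorted(t, a + w0, side="left")
            hi = np.searchsorted(t, a + w1, side="right")
            if hi > lo:
                frames.append(
                    pd.DataFrame(
                        {
                            "trial_pos": pos,
                            "kind": kind,
                            "rel_ms": t[lo:hi] - a,
                        }
                    )
                )
    times = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["trial_pos", "kind", "rel_ms"])
    )
    return AlignedRaster(
        anchor=anchor,
        window=(float(w0), float(w1)),
        times=times,
        n_trials=int(ok.sum()),
        n_unresolved=int((~ok).sum()),
    )


def rate_histogram(raster: AlignedRaster, bin_width_ms: float = 4.0) -> pd.DataFrame:
    """Percent of trials with at least one event onset per time bin.

    One column per event kind; values lie in [0, 100].  ``bin_width_ms``
    must divide the window length (within rounding).
    """
    if bin_width_ms <= 0:
        raise ValueError("bin_width_ms must be positive")
    w0, w1 = raster.window
    n_bins_f = (w1 - w0) / bin_width_ms
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-6 or n_bins < 1:
        raise ValueError("bin_width_ms must divide the window length")
    edges = w0 + np.arange(n_bins + 1) * bin_width_ms
    out = pd.DataFrame(index=pd.Index(edges[:-1], name="bin_start_ms"))
    for kind in EVENT_KINDS:
        kt = raster.kind_times(kind)
        pct = np.zeros(n_bins)
        if len(kt) and raster.n_trials > 0:
            b = np.clip(
                ((kt["rel_ms"].to_numpy() - w0) / bin_width_ms).astype(int), 0, n_bins - 1
            )
            uniq = set(zip(kt["trial_pos"].to_numpy(), b))
            counts = np.zeros(n_bins)
            for _, bb in uniq:
                counts[bb] += 1
            pct = 100.0 * counts / raster.n_trials
        out[kind] = pct
    return out


@dataclass
class CountDistribution:
    """Percent of trials with 0, 1, or >= 2 microsaccade onsets in a window."""

    window: tuple[float, float]
    pct_0: float
    pct_1: float
    pct_2plus: float
    n_trials: int

    def as_dict(self) -> dict:
        return {"0": self.pct_0, "1": self.pct_1, ">=2": self.pct_2plus}


def microsaccade_count_distribution(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple[float, float],
    anchor: str = "trial_onset",
    first_sacc: pd.DataFrame | None = None,
) -> CountDistribution:
    """Count microsaccade onsets per trial in an anchored window."""
    raster = align_events(trials, events, anchor, window, first_sacc)
    if raster.n_trials == 0:
        raise ValueError("no trials with a resolvable anchor")
    kt = raster.kind_times("microsaccade_start")
    counts = kt.groupby("trial_pos").size() if len(kt) else pd.Series(dtype=int)
    n1 = int((counts == 1).sum())
    n2 = int((counts >= 2).sum())
    n0 = raster.n_trials - n1 - n2
    n = raster.n_trials
    return CountDistribution(
        window=raster.window,
        pct_0=100.0 * n0 / n,
        pct_1=100.0 * n1 / n,
        pct_2plus=100.0 * n2 / n,
        n_trials=n,
    )


def subject_rates(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    interval: tuple[float, float] = (-200.0, 800.0),
    kind: str = "microsaccade",
    confidence: float = 0.95,
) -> dict:
    """Per-subject event rate in the peri-trial interval, plus a t-CI.

    Rate per subject = total event onsets of ``kind`` inside the anchored
    interval across trials / (number of trials x interval length in s).
    The across-subject confidence interval is a two-sided t-interval; with
    a single subject the CI is undefined and flagged.
    """
    if "subject" not in trials.columns:
        trials = trials.assign(subject=0)
        events = events.assign(subject=0)
    span_s = (interval[1] - interval[0]) / 1000.0
    per_subject = []
    for subj, tr in trials.groupby("subject"):
        ev = events[events["subject"] == subj] if "subject" in events.columns else events
        raster = align_events(tr.reset_index(drop=True), ev, "trial_onset", interval)
        k = "microsaccade_start" if kind == "microsaccade" else "saccade_start"
        n_onsets = len(raster.kind_times(k))
        per_subject.append(
            {"subject": subj, "rate_hz": n_onsets / (len(tr) * span_s), "n_trials": len(tr)}
        )
    df = pd.DataFrame(per_subject)
    rates = df["rate_hz"].to_numpy()
    mean = float(rates.mean())
    if len(rates) >= 2:
        sem = rates.std(ddof=1) / np.sqrt(len(rates))
        if sem == 0.0:
            ci = (mean, mean)
        else:
            tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=len(rates) - 1)
            ci = (mean - tcrit * sem, mean + tcrit * sem)
        ci_defined = True
    else:
        ci = (np.nan, np.nan)
        ci_defined = False
    return {
        "per_subject": df,
        "mean_hz": mean,
        "ci_hz": (float(ci[0]), float(ci[1])),
        "ci_defined": ci_defined,
    }


def targeting_rate(trials: pd.DataFrame) -> float:
    """Completed trials per second of active block time (faces/s).

    Active time per block is the span of its trial onsets plus one median
    inter-onset interval; pauses between blocks are excluded.
    """
    total_time_s = 0.0
    for _, tr in trials.groupby(["subject", "block"] if "subject" in trials else "block"):
        onsets = np.sort(tr["onset_ms"].to_numpy())
        if len(onsets) < 2:
            continue
        span = onsets[-1] - onsets[0] + np.median(np.diff(onsets))
        total_time_s += span / 1000.0
    if total_time_s <= 0:
        raise ValueError("cannot compute a targeting rate from fewer than 2 trials")
    return len(trials) / total_time_s


@dataclass
class EccentricityProfile:
    """Per-eccentricity-bin occurrence histograms (one matrix per event kind)."""

    ecc_edges: np.ndarray
    time_edges: np.ndarray
    matrices: dict  # kind -> (n_ecc_bins, n_time_bins) array of percents
    trials_per_bin: np.ndarray
    empty_bins: list


def eccentricity_profile(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    ecc_edges: np.ndarray | None = None,
    anchor: str = "trial_onset",
    window: tuple[float, float] = (-200.0, 800.0),
    bin_width_ms: float = 4.0,
    first_sacc: pd.DataFrame | None = None,
) -> EccentricityProfile:
    """Occurrence histograms stratified by target eccentricity at onset.

    Trials are partitioned into eccentricity bins (default 2-degree bins
    from 4 to 20 degrees); the per-time-bin occurrence percentage is
    computed inside each bin for saccade starts, saccade ends and
    microsaccade starts.  Empty bins are reported, not silently dropped.
    Permuting trial order cannot change the result.
    """
    if ecc_edges is None:
        ecc_edges = np.arange(4.0, 21.0, 2.0)
    ecc_edges = np.asarray(ecc_edges, dtype=float)
    n_ecc = len(ecc_edges) - 1
    ecc = trials["ecc_deg"].to_numpy()
    n_time = int(round((window[1] - window[0]) / bin_width_ms))
    matrices = {k: np.zeros((n_ecc, n_time)) for k in EVENT_KINDS}
    trials_per_bin = np.zeros(n_ecc, dtype=int)
    empty = []
    for b in range(n_ecc):
        sel = (ecc >= ecc_edges[b]) & (ecc < ecc_edges[b + 1])
        trials_per_bin[b] = int(sel.sum())
        if not sel.any():
            empty.append((float(ecc_edges[b]), float(ecc_edges[b + 1])))
            continue
        sub = trials[sel].reset_index(drop=True)
        fs = first_sacc[sel].reset_index(drop=True) if first_sacc is not None else None
        raster = align_events(sub, events, anchor, window, fs)
        hist = rate_histogram(raster, bin_width_ms)
        for k in EVENT_KINDS:
            matrices[k][b] = hist[k].to_numpy()
    time_edges = window[0] + np.arange(n_time + 1) * bin_width_ms
    return EccentricityProfile(
        ecc_edges=ecc_edges,
        time_edges=time_edges,
        matrices=matrices,
        trials_per_bin=trials_per_bin,
        empty_bins=empty,
    )


@dataclass
class DirectionCongruence:
    """Fractions of saccade->microsaccade pairs by angular difference."""

    frac_within_45: float
    frac_beyond_45: float
    n_pairs: int
    defined: bool

    def __post_init__(self) -> None:
        if self.defined:
            assert abs(self.frac_within_45 + self.frac_beyond_45 - 1.0) < 1e-9


def direction_congruence(
    first_sacc: pd.DataFrame,
    events: pd.DataFrame,
    association_window_ms: float = 100.0,
) -> DirectionCongruence:
    """Direction congruence of post-saccadic microsaccades.

    Pairs each resolved first saccade with the first microsaccade whose
    onset falls within ``association_window_ms`` after the saccade offset,
    and reports the fractions of pairs whose polar-angle difference
    (wrapped to [0, 180]) is <= 45 vs > 45 degrees.
    """
    micro = events[events["class"] == "microsaccade"].sort_values("onset_ms")
    m_on = micro["onset_ms"].to_numpy(dtype=float)
    m_ang = micro["polar_angle_deg"].to_numpy(dtype=float)
    n_within = 0
    n_beyond = 0
    for _, row in first_sacc[first_sacc["resolved"]].iterrows():
        t0 = row["sacc_offset_ms"]
        j = np.searchsorted(m_on, t0, side="right")
        if j < len(m_on) and m_on[j] <= t0 + association_window_ms:
            d = abs((m_ang[j] - row["polar_angle_deg"]) % 360.0)
            d = min(d, 360.0 - d)
            if d > 45.0:
                n_beyond += 1
            else:
                n_within += 1
    n = n_within + n_beyond
    if n == 0:
        return DirectionCongruence(np.nan, np.nan, 0, defined=False)
    return DirectionCongruence(n_within / n, n_beyond / n, n, defined=True)


def pre_saccade_microsaccade_fraction(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    first_sacc: pd.DataFrame,
    ecc_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-eccentricity-bin fraction of trials with a microsaccade onset
    strictly between trial onset and the first saccade's onset.

    This quantifies whether observers ever "scan" with microsaccades
    before launching the targeting saccade.
    """
    if ecc_edges is None:
        ecc_edges = np.arange(4.0, 21.0, 2.0)
    ecc_edges = np.asarray(ecc_edges, dtype=float)
    micro = events[events["class"] == "microsaccade"].sort_values("onset_ms")
    m_on = micro["onset_ms"].to_numpy(dtype=float)
    onsets = trials["onset_ms"].to_numpy()
    s_on = first_sacc["sacc_onset_ms"].to_numpy()
    resolved = first_sacc["resolved"].to_numpy()
    has_pre = np.zeros(len(trials), dtype=bool)
    for i in range(len(trials)):
        if not resolved[i]:
            continue
        lo = np.searchsorted(m_on, onsets[i], side="right")
        hi = np.searchsorted(m_on, s_on[i], side="left")
        has_pre[i] = hi > lo
    ecc = trials["ecc_deg"].to_numpy()
    rows = []
    for b in range(len(ecc_edges) - 1):
        sel = (ecc >= ecc_edges[b]) & (ecc < ecc_edges[b + 1]) & resolved
        n = int(sel.sum())
        rows.append(
            {
                "ecc_lo": ecc_edges[b],
                "ecc_hi": ecc_edges[b + 1],
                "n_trials": n,
                "fraction": float(has_pre[sel].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
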