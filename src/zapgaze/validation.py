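"""Detector validation against simulator ground truth.

Matches detected events to ground-truth events by temporal overlap and
summarizes recall, precision and onset timing error.  Also converts a
ground-truth log into the standard event-table schema so every analysis
can be run on the true events, bypassing detection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["events_from_ground_truth", "match_events", "detection_scores"]


def events_from_ground_truth(gt: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth log -> event table (detection bypass).

    Magnitude is the start-to-end displacement; polar angle the direction
    of that displacement.
    """
    dx = gt["x_end"].to_numpy() - gt["x_start"].to_numpy()
    dy = gt["y_end"].to_numpy() - gt["y_start"].to_numpy()
    out = pd.DataFrame(
        {
            "onset_ms": gt["onset_ms"].to_numpy(),
            "offset_ms": gt["offset_ms"].to_numpy(),
            "duration_ms": gt["offset_ms"].to_numpy() - gt["onset_ms"].to_numpy(),
            "x_onset": gt["x_start"].to_numpy(),
            "y_onset": gt["y_start"].to_numpy(),
            "x_offset": gt["x_end"].to_numpy(),
            "y_offset": gt["y_end"].to_numpy(),
            "dx_deg": dx,
            "dy_deg": dy,
            "magnitude_deg": np.hypot(dx, dy),
            "peak_velocity_dps": gt["peak_velocity_dps"].to_numpy(),
            "polar_angle_deg": np.degrees(np.arctan2(dy, dx)) % 360.0,
            "class": gt["class"].to_numpy(),
        }
    )
    if "subject" in gt.columns:
        out["subject"] = gt["subject"].to_numpy()
    return out.sort_values("onset_ms", ignore_index=True)


def match_events(
    gt: pd.DataFrame, detected: pd.DataFrame, pad_ms: float = 4.0
) -> pd.DataFrame:
    """Greedy one-to-one matching of detected events to ground truth.

    A detected event matches a ground-truth event when their (padded) time
    intervals overlap; each detected event is used at most once.  Returns
    one row per ground-truth event with the matched detected index (or -1)
    and the onset error in ms.
    """
    det = detected.sort_values("onset_ms").reset_index()
    d_on = det["onset_ms"].to_numpy(dtype=float)
    d_off = det["offset_ms"].to_numpy(dtype=float)
    used = np.zeros(len(det), dtype=bool)
    rows = []
    for _, g in gt.sort_values("onset_ms").iterrows():
        lo, hi = g["onset_ms"] - pad_ms, g["offset_ms"] + pad_ms
        cand = np.flatnonzero((d_on <= hi) & (d_off >= lo) & ~used)
        if len(cand):
            # prefer the candidate with the closest onset
            j = cand[np.argmin(np.abs(d_on[cand] - g["onset_ms"]))]
            used[j] = True
            rows.append(
                {
                    "gt_onset_ms": g["onset_ms"],
                    "gt_class": g["class"],
                    "gt_amplitude_deg": g.get("amplitude_deg", np.nan),
                    "det_index": int(det["index"].iloc[j]),
                    "det_class": det["class"].iloc[j],
                    "onset_error_ms": float(d_on[j] - g["onset_ms"]),
                }
            )
        else:
            rows.append(
                {
                    "gt_onset_ms": g["onset_ms"],
                    "gt_class": g["class"],
                    "gt_amplitude_deg": g.get("amplitude_deg", np.nan),
                    "det_index": -1,
                    "det_class": "",
                    "onset_error_ms": np.nan,
                }
            )
    return pd.DataFrame(rows)


def detection_scores(
    gt: pd.DataFrame,
    detected: pd.DataFrame,
    dt_ms: float,
    saccade_min_amplitude_deg: float = 2.0,
    pad_ms: float = 4.0,
) -> dict:
    """Recall/precision for large saccades and microsaccades, onset error.

    Recall is class-aware: a ground-truth saccade counts as recovered only
    if the matched detected event is classified as a saccade (and likewise
    for microsaccades).  Precision asks whether each detected event of the
    class matches some ground-truth event of the same class.
    """
    matches = match_events(gt, detected, pad_ms)

    big = matches[
        (matches["gt_class"] == "saccade")
        & (matches["gt_amplitude_deg"] >= saccade_min_amplitude_deg)
    ]
    micro = matches[matches["gt_class"] == "microsaccade"]
    recall_sacc = float((big["det_class"] == "saccade").mean()) if len(big) else np.nan
    recall_micro = (
        float((micro["det_class"] == "microsaccade").mean()) if len(micro) else np.nan
    )

    matched_det = set(matches.loc[matches["det_index"] >= 0, "det_index"])
    cls_by_det = dict(
        zip(matches["det_index"], matches["gt_class"])
    )
    det_sacc = detected[
        (detected["class"] == "saccade")
        & (detected["magnitude_deg"] >= saccade_min_amplitude_deg)
    ]
    det_micro = detected[detected["class"] == "microsaccade"]

    def _precision(sub: pd.DataFrame, klass: str) -> float:
        if not len(sub):
            return np.nan
        ok = [
            (i in matched_det) and (cls_by_det.get(i) == klass) for i in sub.index
        ]
        return float(np.mean(ok))

    onset_err = matches["onset_error_ms"].dropna().to_numpy()
    return {
        "recall_saccade": recall_sacc,
        "precision_saccade": _precision(det_sacc, "saccade"),
        "recall_microsaccade": recall_micro,
        "precision_microsaccade": _precision(det_micro, "microsaccade"),
        "median_onset_error_samples": (
            float(np.median(np.abs(onset_err)) / dt_ms) if len(onset_err) else np.nan
        ),
        "n_gt_saccades_big": int(len(big)),
        "n_gt_microsaccades": int(len(micro)),
    }
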