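"""Container for uniformly sampled monocular gaze recordings.

Positions are in degrees of visual angle with the origin at the screen
center, x rightward and y upward; timestamps are in milliseconds on a
uniform sample clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GazeRecording"]


@dataclass
class GazeRecording:
    """A continuous, gap-free monocular gaze trace.

    Parameters
    ----------
    t_ms
        Sample timestamps in milliseconds; must be uniformly spaced.
    x_deg, y_deg
        Horizontal / vertical gaze position in degrees of visual angle.
    sampling_rate
        Nominal sampling rate in Hz (1250 for the high-speed tracker the
        task was designed around).
    """

    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    sampling_rate: float = 1250.0

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if not (len(self.t_ms) == len(self.x_deg) == len(self.y_deg)):
            raise ValueError("t_ms, x_deg and y_deg must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.t_ms) >= 2:
            dt = np.diff(self.t_ms)
            nominal = 1000.0 / self.sampling_rate
            if dt.min() <= 0:
                raise ValueError("timestamps must be strictly increasing")
            if np.abs(dt - nominal).max() > 1e-6 * max(nominal, 1.0):
                raise ValueError(
                    "timestamps must be uniformly spaced at 1000/sampling_rate ms"
                )

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y positions in degrees."""
        return np.column_stack([self.x_deg, self.y_deg])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t_ms, "x_deg": self.x_deg, "y_deg": self.y_deg}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sampling_rate: float | None = None) -> "GazeRecording":
        df = pd.read_csv(path)
        for col in ("t_ms", "x_deg", "y_deg"):
            if col not in df.columns:
                raise ValueError(f"gaze CSV is missing required column {col!r}")
        if sampling_rate is None:
            dt = np.median(np.diff(df["t_ms"].to_numpy()))
            sampling_rate = 1000.0 / dt
        return cls(
            t_ms=df["t_ms"].to_numpy(),
            x_deg=df["x_deg"].to_numpy(),
            y_deg=df["y_deg"].to_numpy(),
            sampling_rate=sampling_rate,
        )
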