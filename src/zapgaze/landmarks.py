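"""Landmark-based mapping of gaze endpoints onto a template face.

Every trial shows a different face, so its 7 labeled landmarks sit at
slightly different positions.  To pool saccade and microsaccade endpoints
across trials, each trial's landmark set is aligned to a canonical
template by a least-squares similarity transform (translation, rotation,
isotropic scale; reflection is not allowed, faces must not mirror), and
the trial's endpoints are pushed through the fitted transform.  Pooled
endpoints are rendered as disk-smoothed frequency maps or summarized by a
maximum-likelihood 2D Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import transform as sktransform

__all__ = [
    "LANDMARK_NAMES",
    "TemplateFace",
    "SimilarityTransform",
    "HeatmapGrid",
    "Heatmap",
    "procrustes_fit",
    "map_endpoints",
    "select_mappable_events",
    "map_session_endpoints",
    "endpoint_heatmap",
    "fit_endpoint_gaussian",
    "compare_landing_distributions",
    "landmarks_from_trial_row",
]

LANDMARK_NAMES = [
    "hair_top_middle",
    "forehead_top_middle",
    "left_eye",
    "right_eye",
    "nose_tip",
    "mouth_center",
    "chin_bottom_center",
]

# Canonical upright landmark geometry for a 3-degree-tall face, in degrees
# relative to the face center (x rightward, y upward).
CANONICAL_LANDMARKS_DEG = np.array(
    [
        [0.0, 1.50],   # hair top middle
        [0.0, 1.05],   # forehead top middle
        [-0.50, 0.55], # left eye
        [0.50, 0.55],  # right eye
        [0.0, -0.10],  # nose tip
        [0.0, -0.70],  # mouth center
        [0.0, -1.50],  # chin bottom center
    ]
)

# Landmarks in the upper (eyes/forehead) and lower (nose/chin) face halves.
UPPER_LANDMARKS = ["hair_top_middle", "forehead_top_middle", "left_eye", "right_eye"]
LOWER_LANDMARKS = ["nose_tip", "mouth_center", "chin_bottom_center"]


@dataclass
class TemplateFace:
    """Canonical 7-landmark geometry endpoints are mapped onto.

    ``pixel_pitch_deg`` converts template pixels to degrees; the default of
    22/1440 deg/px reproduces a display where a 5-pixel smoothing kernel
    subtends about 0.076 degrees.
    """

    points_deg: np.ndarray
    names: tuple[str, ...] = tuple(LANDMARK_NAMES)
    pixel_pitch_deg: float = 22.0 / 1440.0
    face_height_deg: float = 3.0

    def __post_init__(self) -> None:
        self.points_deg = np.asarray(self.points_deg, dtype=float)
        if self.points_deg.shape != (len(self.names), 2):
            raise ValueError("points_deg must be one (x, y) pair per landmark name")
        uniq = {tuple(p) for p in np.round(self.points_deg, 12)}
        if len(uniq) != len(self.names):
            raise ValueError("template landmarks must be pairwise distinct")

    @classmethod
    def default(cls) -> "TemplateFace":
        return cls(points_deg=CANONICAL_LANDMARKS_DEG.copy())

    def point(self, name: str) -> np.ndarray:
        return self.points_deg[self.names.index(name)]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"landmark": self.names,
             "x_deg": self.points_deg[:, 0],
             "y_deg": self.points_deg[:, 1]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TemplateFace":
        df = pd.read_csv(path).set_index("landmark")
        pts = df.loc[list(LANDMARK_NAMES), ["x_deg", "y_deg"]].to_numpy()
        return cls(points_deg=pts)


@dataclass
class SimilarityTransform:
    """Least-squares similarity transform (no reflection) plus fit residual."""

    rotation_deg: float
    scale: float
    translation: np.ndarray
    residual_rms: float
    _tform: sktransform.SimilarityTransform

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(self._tform(np.atleast_2d(points)))

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(self._tform.inverse(np.atleast_2d(points)))


def procrustes_fit(source: np.ndarray, template: np.ndarray) -> SimilarityTransform:
    """Fit the similarity transform taking ``source`` landmarks to ``template``.

    Umeyama's closed-form least-squares solution with isotropic scale and a
    proper rotation (determinant +1, so the face cannot be mirrored).  The
    residual is the root-mean-square landmark distance after the transform;
    it is generally nonzero because landmark geometry differs face to face.

    Raises ``ValueError`` for degenerate sources (all landmarks coincident
    or collinear), for which the rotation/scale is not identifiable.
    """
    source = np.asarray(source, dtype=float)
    template = np.asarray(template, dtype=float)
    if source.shape != template.shape or source.ndim != 2 or source.shape[1] != 2:
        raise ValueError("source and template must be matching (n, 2) arrays")
    if len(source) < 2:
        raise ValueError("at least 2 landmarks are required")
    centered = source - source.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[-1] <= 1e-9 * max(svals[0], 1e-12):
        raise ValueError("degenerate source landmarks (coincident or collinear)")
    tform = sktransform.estimate_transform("similarity", source, template)
    mapped = tform(source)
    residual = float(np.sqrt(np.mean(np.sum((mapped - template) ** 2, axis=1))))
    return SimilarityTransform(
        rotation_deg=float(np.degrees(tform.rotation)),
        scale=float(tform.scale),
        translation=np.asarray(tform.translation, dtype=float),
        residual_rms=residual,
        _tform=tform,
    )


def map_endpoints(transform: SimilarityTransform, points: np.ndarray) -> np.ndarray:
    """Map screen-space points into template space with a fitted transform."""
    return transform.apply(points)


def landmarks_from_trial_row(row: pd.Series) -> np.ndarray:
    """(7, 2) landmark array, in canonical order, from a trial-log row."""
    return np.array(
        [[row[f"lm_{name}_x"], row[f"lm_{name}_y"]] for name in LANDMARK_NAMES]
    )


def _in_window(x, y, cx, cy, half: float, tol: float = 1e-9) -> np.ndarray:
    """Closed-boundary membership in the square window centered on (cx, cy)."""
    return (np.abs(np.asarray(x) - cx) <= half + tol) & (
        np.abs(np.asarray(y) - cy) <= half + tol
    )


def select_mappable_events(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    window_half_deg: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split events into mappable saccades and microsaccades.

    A saccade is kept iff its endpoint lies in the 3x3-degree window around
    its trial's target; a microsaccade is kept iff both its start and end
    lie in the window.  The boundary is closed.  ``events`` must carry a
    ``trial_pos`` column (see :func:`zapgaze.metrics.assign_trials`);
    events preceding the first trial are dropped.
    """
    if "trial_pos" not in events.columns:
        raise ValueError("events must have a trial_pos column (use metrics.assign_trials)")
    ev = events[events["trial_pos"] >= 0]
    tx = trials["target_x_deg"].to_numpy()[ev["trial_pos"]]
    ty = trials["target_y_deg"].to_numpy()[ev["trial_pos"]]
    end_in = _in_window(ev["x_offset"], ev["y_offset"], tx, ty, window_half_deg)
    start_in = _in_window(ev["x_onset"], ev["y_onset"], tx, ty, window_half_deg)
    is_micro = ev["class"] == "microsaccade"
    saccades = ev[(~is_micro) & end_in]
    micros = ev[is_micro & start_in & end_in]
    return saccades.copy(), micros.copy()


def map_session_endpoints(
    trials: pd.DataFrame,
    events: pd.DataFrame,
    template: TemplateFace | None = None,
    window_half_deg: float = 1.5,
) -> pd.DataFrame:
    """Procrustes-map every mappable event endpoint into template space.

    Fits one similarity transform per trial (trial landmarks -> template)
    and applies it to that trial's kept endpoints.  Returns a tidy frame
    with template-space coordinates, event class, the trial position and
    the per-trial fit residual.
    """
    template = template or TemplateFace.default()
    saccades, micros = select_mappable_events(trials, events, window_half_deg)
    kept = pd.concat([saccades, micros], ignore_index=True)
    rows = []
    for pos, group in kept.groupby("trial_pos"):
        row = trials.iloc[int(pos)]
        tf = procrustes_fit(landmarks_from_trial_row(row), template.points_deg)
        pts = group[["x_offset", "y_offset"]].to_numpy()
        mapped = tf.apply(pts)
        for (_, ev), (mx, my) in zip(group.iterrows(), mapped):
            rows.append(
                {
                    "trial_pos": int(pos),
                    "class": ev["class"],
                    "x_template_deg": mx,
                    "y_template_deg": my,
                    "residual_rms": tf.residual_rms,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["trial_pos", "class", "x_template_deg", "y_template_deg", "residual_rms"],
    )


@dataclass
class HeatmapGrid:
    """Square pixel grid centered on the template face."""

    half_extent_deg: float = 1.6
    pitch_deg: float = 22.0 / 1440.0

    @property
    def n_px(self) -> int:
        return 2 * int(round(self.half_extent_deg / self.pitch_deg)) + 1

    @property
    def centers(self) -> np.ndarray:
        k = (self.n_px - 1) // 2
        return np.arange(-k, k + 1) * self.pitch_deg

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest-pixel (ix, iy) indices; may fall outside the grid."""
        k = (self.n_px - 1) // 2
        return np.round(np.asarray(points) / self.pitch_deg).astype(int) + k


@dataclass
class Heatmap:
    """Disk-smoothed endpoint frequency map on a template-face grid.

    ``values[iy, ix]`` with iy increasing along +y (upward) and ix along
    +x.  ``values.sum()`` equals the number of in-grid points minus the
    smoothing mass lost over the grid boundary (zero padding).
    """

    values: np.ndarray
    grid: HeatmapGrid
    n_points: int
    n_outside_grid: int
    boundary_mass_loss: float

    def peak_xy_deg(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.values), self.values.shape)
        c = self.grid.centers
        return float(c[ix]), float(c[iy])


def disk_kernel(radius_px: int = 2) -> np.ndarray:
    """Normalized discrete disk in a (2r+1)^2 window (13 cells for r=2)."""
    k = 2 * radius_px + 1
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    mask = (xx**2 + yy**2) <= radius_px**2
    kernel = mask.astype(float)
    return kernel / kernel.sum()


def endpoint_heatmap(
    points: np.ndarray,
    grid: HeatmapGrid | None = None,
    disk_radius_px: int = 2,
) -> Heatmap:
    """Count endpoints per pixel and smooth with the normalized disk kernel.

    Empty input yields an all-zero map.  Mass is conserved up to the
    zero-padding loss at the grid boundary, which is reported.
    """
    grid = grid or HeatmapGrid()
    points = np.atleast_2d(np.asarray(points, dtype=float)) if np.size(points) else np.empty((0, 2))
    n = grid.n_px
    counts = np.zeros((n, n))
    n_outside = 0
    if len(points):
        idx = grid.to_index(points)
        inside = (idx >= 0).all(axis=1) & (idx < n).all(axis=1)
        n_outside = int((~inside).sum())
        ix, iy = idx[inside, 0], idx[inside, 1]
        np.add.at(counts, (iy, ix), 1.0)
    kernel = disk_kernel(disk_radius_px)
    smoothed = ndimage.convolve(counts, kernel, mode="constant", cval=0.0)
    loss = float(counts.sum() - smoothed.sum())
    return Heatmap(
        values=smoothed,
        grid=grid,
        n_points=len(points),
        n_outside_grid=n_outside,
        boundary_mass_loss=loss,
    )


@dataclass
class GaussianFit:
    """Maximum-likelihood 2D Gaussian summary of an endpoint cloud."""

    mean: np.ndarray
    cov: np.ndarray

    @property
    def rv(self) -> stats._multivariate.multivariate_normal_frozen:
        return stats.multivariate_normal(mean=self.mean, cov=self.cov)

    def pdf(self, points: np.ndarray) -> np.ndarray:
        return self.rv.pdf(points)

    def density_on_grid(self, grid: HeatmapGrid) -> np.ndarray:
        c = grid.centers
        xx, yy = np.meshgrid(c, c)
        return self.pdf(np.dstack([xx, yy]))


def fit_endpoint_gaussian(points: np.ndarray) -> GaussianFit:
    """ML mean and covariance of endpoint positions.

    Requires at least 3 non-collinear points; a singular covariance (all
    points on a line) raises with a suggestion to add jitter.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValueError("fit_endpoint_gaussian requires >= 3 (x, y) points")
    mean = points.mean(axis=0)
    cov = np.cov(points.T, bias=True)
    if np.linalg.eigvalsh(cov).min() <= 1e-12:
        raise ValueError(
            "singular endpoint covariance (collinear points); add a small "
            "positional jitter before fitting"
        )
    return GaussianFit(mean=mean, cov=cov)


def compare_landing_distributions(map_a, map_b) -> tuple[float, float]:
    """Similarity between two landing maps on a common grid.

    Returns ``(correlation, distance)`` where correlation is the cosine
    similarity of the maps and distance is the total-variation (L1/2)
    distance between the maps normalized to unit mass.  Symmetric in its
    arguments; zero-mass maps raise ``ValueError``.
    """
    a = map_a.values if isinstance(map_a, Heatmap) else np.asarray(map_a, dtype=float)
    b = map_b.values if isinstance(map_b, Heatmap) else np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a common grid")
    ma, mb = a.sum(), b.sum()
    if ma <= 0 or mb <= 0:
        raise ValueError("cannot compare a zero-mass map")
    corr = float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))
    dist = float(0.5 * np.abs(a / ma - b / mb).sum())
    return corr, dist
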