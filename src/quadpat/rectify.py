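"""Rectification of digitized quadrat photographs into plot coordinates.

A square plot (typically 5 m x 5 m) is divided into a grid of sub-blocks
(50 cm x 50 cm) which are photographed one by one from above.  Plants are
digitized in image pixels; the four sub-block corners, whose plot-frame
positions are known, serve as control points.  A planar projective
transform (homography) fitted to the control points corrects the
perspective ("parallax") of each photograph and maps pixel coordinates
directly into plot metres.  Per-sub-block results are clipped to their cell
and concatenated into a single plot-frame point pattern.

Conventions: the plot origin is the south-west corner, x east and y north
in metres; pixels have the origin at the top-left with v increasing
downward — the fitted homography absorbs the axis flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.transform import ProjectiveTransform as _SkProjective

from .ppcore import PointPattern, Window

__all__ = [
    "SubBlockWindow",
    "ControlPointSet",
    "ProjectiveTransform",
    "AssemblyLog",
    "make_subblock_grid",
    "fit_projective",
    "transform_points",
    "clip_to_window",
    "assemble_pattern",
    "InvalidGeometryError",
    "FitError",
    "DegeneratePointError",
    "AssemblyError",
]

logger = logging.getLogger(__name__)

DUPLICATE_TOL = 1e-3  # m; merge radius for points re-digitized across a cell edge


class InvalidGeometryError(ValueError):
    """Plot dimensions are not an integer number of sub-block cells."""


class FitError(ValueError):
    """Control-point configuration is degenerate (collinear or repeated)."""


class DegeneratePointError(ValueError):
    """A point maps to the line at infinity under the transform."""


class AssemblyError(KeyError):
    """A digitized sub-block has no control-point set."""


@dataclass(frozen=True)
class SubBlockWindow:
    """One grid cell, addressed by (row, col) from the south-west corner.

    ``closed_east``/``closed_north`` mark cells on the plot's outer
    boundary, where the normally half-open high edge is closed so boundary
    points are not lost.
    """

    row: int
    col: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    closed_east: bool = False
    closed_north: bool = False

    @property
    def id(self) -> tuple[int, int]:
        return (self.row, self.col)

    def corners(self) -> np.ndarray:
        """The four vertices, counter-clockwise from the south-west."""
        return np.array(
            [
                [self.x_min, self.y_min],
                [self.x_max, self.y_min],
                [self.x_max, self.y_max],
                [self.x_min, self.y_max],
            ]
        )


@dataclass(frozen=True)
class ControlPointSet:
    """Pixel <-> plot correspondences for one sub-block (>= 4 pairs).

    Nominally the four sub-block vertices; plot coordinates are absolute
    (plot frame), so the fitted transform maps straight into the plot.
    """

    subblock: tuple[int, int]
    pixel: np.ndarray
    plot: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixel, dtype=float).reshape(-1, 2)
        pl = np.asarray(self.plot, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "pixel", px)
        object.__setattr__(self, "plot", pl)
        if px.shape != pl.shape or px.shape[0] < 4:
            raise ValueError("need >= 4 pixel/plot correspondence pairs")


@dataclass(frozen=True)
class ProjectiveTransform:
    """3x3 homogeneous mapping, normalised so matrix[2, 2] == 1.

    ``rms_error`` is the RMS reprojection error (metres) on the control
    points the transform was fitted to; NaN for transforms built directly
    from a matrix.
    """

    matrix: np.ndarray
    rms_error: float = float("nan")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if not np.all(np.isfinite(m)) or abs(np.linalg.det(m)) < 1e-15:
            raise ValueError("transform matrix must be finite and invertible")
        if abs(m[2, 2]) > 1e-15:
            m = m / m[2, 2]
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "ProjectiveTransform":
        return ProjectiveTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "ProjectiveTransform":
        return cls(np.eye(3))


def make_subblock_grid(
    plot_width: float, plot_height: float, cell: float
) -> list[SubBlockWindow]:
    """Partition [0, plot_width] x [0, plot_height] into square cells.

    Returns cells in row-major order starting at the south-west corner.
    Raises :class:`InvalidGeometryError` unless both dimensions are integer
    multiples of ``cell`` (tolerance 1e-9).
    """
    if plot_width <= 0 or plot_height <= 0 or cell <= 0:
        raise InvalidGeometryError("plot dimensions and cell size must be positive")
    ncol = plot_width / cell
    nrow = plot_height / cell
    if abs(ncol - round(ncol)) > 1e-9 or abs(nrow - round(nrow)) > 1e-9:
        raise InvalidGeometryError(
            f"plot {plot_width} x {plot_height} m is not an integer number of "
            f"{cell} m cells"
        )
    ncol, nrow = int(round(ncol)), int(round(nrow))
    grid = []
    for row in range(nrow):
        for col in range(ncol):
            grid.append(
                SubBlockWindow(
                    row=row,
                    col=col,
                    x_min=col * cell,
                    y_min=row * cell,
                    x_max=(col + 1) * cell,
                    y_max=(row + 1) * cell,
                    closed_east=(col == ncol - 1),
                    closed_north=(row == nrow - 1),
                )
            )
    return grid


def _collinear(pts: np.ndarray, tol: float = 1e-9) -> bool:
    """True if no 3 of the points span a proper triangle."""
    p = pts - pts.mean(axis=0)
    s = np.linalg.svd(p, compute_uv=False)
    return s.size < 2 or s[1] <= tol * max(s[0], 1.0)


def fit_projective(control: ControlPointSet) -> ProjectiveTransform:
    """Fit a homography pixel -> plot by the normalised direct linear
    transform (least squares when more than 4 correspondences are given).

    Exact correspondences reproject to within ~1e-9 m; degenerate
    configurations (collinear plot points, repeated pixels) raise
    :class:`FitError` naming the sub-block.
    """
    if _collinear(control.plot) or _collinear(control.pixel):
        raise FitError(
            f"sub-block {control.subblock}: control points are collinear or repeated"
        )
    result = _SkProjective.from_estimate(control.pixel, control.plot)
    if not result:
        raise FitError(f"sub-block {control.subblock}: homography estimation failed")
    matrix = result.params
    try:
        t = ProjectiveTransform(matrix)
    except ValueError as exc:
        raise FitError(f"sub-block {control.subblock}: {exc}") from exc
    mapped = transform_points(t, control.pixel)
    rms = float(np.sqrt(np.mean(np.sum((mapped - control.plot) ** 2, axis=1))))
    return ProjectiveTransform(t.matrix, rms_error=rms)


def transform_points(t: ProjectiveTransform, pts: np.ndarray) -> np.ndarray:
    """Apply the homography: homogeneous product then perspective division.

    Raises :class:`DegeneratePointError` if any point's third homogeneous
    coordinate has magnitude below 1e-12.
    """
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ t.matrix.T
    w = hom[:, 2]
    bad = np.abs(w) < 1e-12
    if np.any(bad):
        raise DegeneratePointError(
            f"{int(bad.sum())} point(s) map to the line at infinity"
        )
    return hom[:, :2] / w[:, None]


def clip_to_window(
    pts: np.ndarray, w: SubBlockWindow, tol: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split points into those belonging to the cell and rejects.

    Membership is half-open — x in [x_min - tol, x_max + tol) and likewise
    for y — except on the plot's outer east/north boundary where the high
    edge is closed; this assigns every point to exactly one cell of the
    grid.  Returns (retained mask, retained points, rejection distances),
    where the distances (0 for retained points) let callers log how far
    outside each rejected point fell.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    pts = np.asarray(pts, dtype=float).reshape(-1, 2)
    x, y = pts[:, 0], pts[:, 1]
    ok_x = x >= w.x_min - tol
    ok_x &= x <= w.x_max + tol if w.closed_east else x < w.x_max + tol
    ok_y = y >= w.y_min - tol
    ok_y &= y <= w.y_max + tol if w.closed_north else y < w.y_max + tol
    keep = ok_x & ok_y
    dx = np.maximum(np.maximum(w.x_min - x, x - w.x_max), 0.0)
    dy = np.maximum(np.maximum(w.y_min - y, y - w.y_max), 0.0)
    dist = np.hypot(dx, dy)
    dist[keep] = 0.0
    return keep, pts[keep], dist


@dataclass
class AssemblyLog:
    """Bookkeeping for one assembly run: the audit trail of the pipeline."""

    retained_per_subblock: dict[tuple[int, int], int] = field(default_factory=dict)
    rejected_per_subblock: dict[tuple[int, int], int] = field(default_factory=dict)
    merged_duplicates: int = 0

    @property
    def total_retained(self) -> int:
        return sum(self.retained_per_subblock.values())

    @property
    def total_rejected(self) -> int:
        return sum(self.rejected_per_subblock.values())


def assemble_pattern(
    records: pd.DataFrame,
    controls: dict[tuple[int, int], ControlPointSet],
    grid: list[SubBlockWindow],
    species: str,
    clip_tol: float = 0.0,
) -> tuple[PointPattern, AssemblyLog]:
    """Rectify and merge all digitized records of one species into a single
    plot-frame point pattern.

    ``records`` needs columns ``subblock_row, subblock_col, species, u_px,
    v_px``.  Per sub-block: fit the homography from its control points, map
    the species' pixel coordinates into plot metres, clip to the cell (with
    ``clip_tol`` slack), then concatenate.  Points within 1 mm of each other
    across adjacent cells — the same plant digitized in two photographs —
    are merged to one and counted in the log.

    Raises :class:`AssemblyError` naming the sub-block if a digitized cell
    has no control-point set.
    """
    by_id = {g.id: g for g in grid}
    plot_window = Window(
        min(g.x_min for g in grid),
        min(g.y_min for g in grid),
        max(g.x_max for g in grid),
        max(g.y_max for g in grid),
    )
    log = AssemblyLog()
    sp = records[records["species"] == species]
    pieces: list[np.ndarray] = []
    for (row, col), grp in sp.groupby(["subblock_row", "subblock_col"], sort=True):
        key = (int(row), int(col))
        if key not in controls:
            raise AssemblyError(f"no control-point set for sub-block {key}")
        cell = by_id[key]
        t = fit_projective(controls[key])
        mapped = transform_points(t, grp[["u_px", "v_px"]].to_numpy(float))
        keep, kept, dist = clip_to_window(mapped, cell, clip_tol)
        log.retained_per_subblock[key] = int(keep.sum())
        log.rejected_per_subblock[key] = int((~keep).sum())
        if np.any(~keep):
            logger.info(
                "sub-block %s: rejected %d point(s), max overshoot %.4f m",
                key,
                int((~keep).sum()),
                float(dist.max()),
            )
        pieces.append(kept)
    xy = np.vstack(pieces) if pieces else np.empty((0, 2))
    if len(xy) > 1:
        # same individual digitized on both sides of a shared cell edge
        pairs = cKDTree(xy).query_pairs(DUPLICATE_TOL, output_type="ndarray")
        if len(pairs):
            drop = np.zeros(len(xy), dtype=bool)
            for i, j in pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]:
                if not drop[i]:
                    drop[j] = True
            log.merged_duplicates = int(drop.sum())
            logger.info("merged %d duplicate point(s) at cell edges", log.merged_duplicates)
            xy = xy[~drop]
    xy = np.clip(
        xy,
        [plot_window.x_min, plot_window.y_min],
        [plot_window.x_max, plot_window.y_max],
    )
    return PointPattern(xy, plot_window, label=species), log
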