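"""Synthetic point processes and photo-digitization fixtures.

Generators for the canonical point-process regimes — complete spatial
randomness, Thomas (Neyman--Scott) clustering, Matérn type-II hard-core
regularity, and a linear intensity gradient — plus a fixture builder that
emulates the photograph-digitization inputs: per-sub-block pixel tables
with known homographies and optional pixel noise.  Everything is
bit-reproducible given a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nullmodels import simulate_csr
from .ppcore import PointPattern, Window
from .rectify import ControlPointSet, ProjectiveTransform, SubBlockWindow, transform_points

__all__ = [
    "gen_thomas",
    "gen_matern2",
    "gen_gradient_ipp",
    "PhotoFixture",
    "gen_photo_fixture",
]


def gen_thomas(
    window: Window,
    kappa: float,
    mu: float,
    sigma: float,
    rng: np.random.Generator,
) -> PointPattern:
    """Thomas cluster process: Poisson(kappa) parents per m^2, Poisson(mu)
    offspring per parent, isotropic Gaussian(sigma) dispersal.

    Parents are simulated on a window buffered by 4*sigma so clusters
    centred just outside still contribute offspring inside; offspring
    falling outside the window are discarded.  Expected count ~ kappa * mu
    * |W|.
    """
    if kappa <= 0 or mu <= 0 or sigma < 0:
        raise ValueError("kappa and mu must be positive, sigma non-negative")
    buf = 4.0 * sigma
    bw_win = Window(
        window.x_min - buf, window.y_min - buf, window.x_max + buf, window.y_max + buf
    )
    n_parents = rng.poisson(kappa * bw_win.area)
    parents = np.column_stack(
        [
            rng.uniform(bw_win.x_min, bw_win.x_max, n_parents),
            rng.uniform(bw_win.y_min, bw_win.y_max, n_parents),
        ]
    )
    counts = rng.poisson(mu, n_parents)
    centres = np.repeat(parents, counts, axis=0)
    pts = centres + rng.normal(0.0, sigma, size=centres.shape)
    pts = pts[window.contains(pts)]
    return PointPattern(pts, window, label="thomas")


def gen_matern2(
    window: Window,
    intensity: float,
    h: float,
    rng: np.random.Generator,
) -> PointPattern:
    """Matérn type-II hard-core process with inhibition distance h.

    A proposal Poisson(intensity) pattern receives i.i.d. uniform birth
    marks; a point survives iff no other proposal point within distance h
    has an earlier mark.  The surviving pattern has minimum pairwise
    distance >= h; as h -> 0 the thinning vanishes and the proposal
    intensity is recovered.
    """
    if intensity <= 0 or h < 0:
        raise ValueError("intensity must be positive and h non-negative")
    n0 = rng.poisson(intensity * window.area)
    prop = simulate_csr(window, n0, rng).points
    marks = rng.uniform(size=n0)
    keep = np.ones(n0, dtype=bool)
    if h > 0 and n0 > 1:
        from scipy.spatial import cKDTree

        pairs = cKDTree(prop).query_pairs(h, output_type="ndarray")
        for i, j in pairs:
            if marks[i] < marks[j]:
                keep[j] = False
            else:
                keep[i] = False
    return PointPattern(prop[keep], window, label="matern2")


def gen_gradient_ipp(
    window: Window,
    a: float,
    b: float,
    rng: np.random.Generator,
) -> PointPattern:
    """Inhomogeneous Poisson process with linear intensity a + b*x, by
    rejection sampling; b = 0 reduces to CSR."""
    lam_max = max(a + b * window.x_min, a + b * window.x_max)
    lam_min = min(a + b * window.x_min, a + b * window.x_max)
    if lam_min < 0 or lam_max <= 0:
        raise ValueError("intensity a + b*x must be non-negative, not all zero")
    mean_lam = a + b * (window.x_min + window.x_max) / 2.0
    n = rng.poisson(mean_lam * window.area)
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        x = rng.uniform(window.x_min, window.x_max, m)
        y = rng.uniform(window.y_min, window.y_max, m)
        acc = rng.uniform(0, lam_max, m) < a + b * x
        xa, ya = x[acc], y[acc]
        take = min(xa.size, n - got)
        pts[got : got + take] = np.column_stack([xa[:take], ya[:take]])
        got += take
    return PointPattern(pts, window, label="gradient-ipp")


@dataclass(frozen=True)
class PhotoFixture:
    """A synthetic digitization dataset with known ground truth.

    ``controls`` and ``records`` are the exact delimited-text tables the
    rectification pipeline consumes; ``truth`` is the generating pattern
    and ``transforms`` the per-sub-block plot->pixel homographies used to
    render it.
    """

    truth: PointPattern
    transforms: dict[tuple[int, int], ProjectiveTransform]
    controls: pd.DataFrame
    records: pd.DataFrame
    sigma_px: float


def _random_camera(
    cell: SubBlockWindow,
    px_per_m: float,
    perspective: float,
    rng: np.random.Generator,
) -> ProjectiveTransform:
    """Plot->pixel homography for one photograph.

    The nominal camera maps the cell onto an image with ~px_per_m pixels
    per metre, origin top-left and v increasing downward (southward).
    Perspective is added by displacing each image corner by up to
    ``perspective`` of the image size, then fitting the exact homography
    through the four perturbed corners.
    """
    size = (cell.x_max - cell.x_min) * px_per_m
    # nominal corners, CCW from SW in plot frame -> image with flipped v
    nominal = np.array([[0.0, size], [size, size], [size, 0.0], [0.0, 0.0]])
    jitter = rng.uniform(-perspective * size, perspective * size, size=(4, 2))
    target = nominal + jitter
    from skimage.transform import ProjectiveTransform as _SkProjective

    fit = _SkProjective.from_estimate(cell.corners(), target)
    if not fit:  # pragma: no cover - random corners are a.s. non-degenerate
        raise RuntimeError("degenerate synthetic camera")
    return ProjectiveTransform(fit.params)


def gen_photo_fixture(
    p: PointPattern,
    grid: list[SubBlockWindow],
    rng: np.random.Generator,
    sigma_px: float = 0.0,
    px_per_m: float = 1000.0,
    perspective: float = 0.03,
    species: str = "sp1",
    plot_id: str = "plot1",
) -> PhotoFixture:
    """Emulate photographing and digitizing a known pattern.

    Every point of ``p`` is assigned to its sub-block (half-open cells,
    closed on the plot's outer boundary), projected into that cell's
    synthetic camera, and perturbed by Gaussian pixel noise ``sigma_px``
    (digitization click error; control-point pixels are exact).  With
    sigma_px = 0 reassembly reproduces ``p`` to machine precision; with
    sigma_px = 1 at 1000 px/m the per-axis coordinate error is ~1 mm.
    """
    transforms: dict[tuple[int, int], ProjectiveTransform] = {}
    ctrl_rows = []
    rec_rows = []
    for cell in grid:
        t = _random_camera(cell, px_per_m, perspective, rng)
        transforms[cell.id] = t
        corners = cell.corners()
        px_corners = transform_points(t, corners)
        for cid, (pc, xc) in enumerate(zip(px_corners, corners)):
            ctrl_rows.append(
                {
                    "subblock_row": cell.row,
                    "subblock_col": cell.col,
                    "corner_id": cid,
                    "u_px": pc[0],
                    "v_px": pc[1],
                    "x_m": xc[0],
                    "y_m": xc[1],
                }
            )
    mark = 0
    for cell in grid:
        x, y = p.points[:, 0], p.points[:, 1]
        in_x = (x >= cell.x_min) & ((x <= cell.x_max) if cell.closed_east else (x < cell.x_max))
        in_y = (y >= cell.y_min) & ((y <= cell.y_max) if cell.closed_north else (y < cell.y_max))
        pts = p.points[in_x & in_y]
        if not len(pts):
            continue
        px = transform_points(transforms[cell.id], pts)
        if sigma_px > 0:
            px = px + rng.normal(0.0, sigma_px, size=px.shape)
        for u, v in px:
            rec_rows.append(
                {
                    "plot_id": plot_id,
                    "subblock_row": cell.row,
                    "subblock_col": cell.col,
                    "species": species,
                    "mark_id": mark,
                    "u_px": u,
                    "v_px": v,
                }
            )
            mark += 1
    controls = pd.DataFrame(
        ctrl_rows,
        columns=["subblock_row", "subblock_col", "corner_id", "u_px", "v_px", "x_m", "y_m"],
    )
    records = pd.DataFrame(
        rec_rows,
        columns=["plot_id", "subblock_row", "subblock_col", "species", "mark_id", "u_px", "v_px"],
    )
    return PhotoFixture(p, transforms, controls, records, sigma_px)


def controls_to_sets(controls: pd.DataFrame) -> dict[tuple[int, int], ControlPointSet]:
    """Group a control-point table into per-sub-block correspondence sets."""
    out: dict[tuple[int, int], ControlPointSet] = {}
    for (row, col), grp in controls.groupby(["subblock_row", "subblock_col"], sort=True):
        out[(int(row), int(col))] = ControlPointSet(
            (int(row), int(col)),
            grp[["u_px", "v_px"]].to_numpy(float),
            grp[["x_m", "y_m"]].to_numpy(float),
        )
    return out
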