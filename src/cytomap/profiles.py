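"""Laminar GLI profiles along cortical traverses.

Traverses run from the outer contour (layer I/II boundary, 0 % depth) to the
inner contour (layer VI / white matter, 100 % depth).  They follow the
streamlines of a harmonic depth field — the solution of Laplace's equation
with value 0 on the outer and 1 on the inner contour — which guarantees
that traverses never cross, even in strongly curved or folded cortex.
Profiles are length-normalized to a fixed depth grid so that cortical
thickness differences between brains, areas and section geometries do not
enter the downstream multivariate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree


@dataclass
class ContourPair:
    """Outer and inner cortical contour polylines, in pixel coordinates.

    Both contours must run in the same arc direction.
    """

    outer: np.ndarray  # (n, 2) float, (x, y)
    inner: np.ndarray
    pixel_size: float = 1.02  # μm

    def __post_init__(self) -> None:
        self.outer = np.asarray(self.outer, dtype=float)
        self.inner = np.asarray(self.inner, dtype=float)
        for name, c in (("outer", self.outer), ("inner", self.inner)):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
                raise ValueError(f"{name} contour needs at least 2 (x, y) points")


@dataclass
class Profile:
    """A depth-normalized GLI profile along one traverse."""

    depths: np.ndarray = field(repr=False)  # 0..100 % cortical depth
    values: np.ndarray = field(repr=False)  # GLI at each depth
    arc_position: int = 0
    raw_length: float = 0.0  # μm, cortical thickness along the traverse

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.shape != self.values.shape:
            raise ValueError("depths and values must have equal length")
        if self.depths[0] != 0 or self.depths[-1] != 100:
            raise ValueError("depth grid must span 0..100 %")


def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Points at equal arc spacing along a polyline (endpoints included)."""
    arc = _polyline_arclength(points)
    total = arc[-1]
    n = int(np.floor(total / spacing)) + 1
    targets = np.arange(n) * spacing
    x = np.interp(targets, arc, points[:, 0])
    y = np.interp(targets, arc, points[:, 1])
    return np.column_stack([x, y])


def _densify(points: np.ndarray, step: float) -> np.ndarray:
    arc = _polyline_arclength(points)
    n = max(int(np.ceil(arc[-1] / step)), 2)
    targets = np.linspace(0, arc[-1], n)
    return np.column_stack(
        [np.interp(targets, arc, points[:, 0]), np.interp(targets, arc, points[:, 1])]
    )


def _contours_valid(contours: ContourPair, grid_step: float) -> None:
    from shapely.geometry import LineString

    lo = LineString(contours.outer)
    li = LineString(contours.inner)
    if lo.crosses(li) or lo.intersects(li):
        raise ValueError("outer and inner contours cross each other")
    if lo.distance(li) < grid_step:
        raise ValueError("degenerate region: contours closer than one grid step")


def harmonic_depth_field(
    contours: ContourPair, grid_step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Solve Laplace's equation between the contours on a regular grid.

    Returns ``(field, region, origin)``: the harmonic depth field (0 at the
    outer contour, 1 at the inner, NaN outside the ribbon), the boolean
    ribbon region, and the (x, y) source coordinate of grid node (0, 0).
    Natural (no-flux) conditions hold on the open ribbon ends.
    """
    _contours_valid(contours, grid_step)
    pts = np.vstack([contours.outer, contours.inner])
    margin = 3 * grid_step
    x0, y0 = pts.min(axis=0) - margin
    x1, y1 = pts.max(axis=0) + margin
    nx = int(np.ceil((x1 - x0) / grid_step)) + 1
    ny = int(np.ceil((y1 - y0) / grid_step)) + 1
    gx, gy = np.meshgrid(
        x0 + np.arange(nx) * grid_step, y0 + np.arange(ny) * grid_step
    )
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    band = 0.75 * grid_step * np.sqrt(2)
    d_out = cKDTree(_densify(contours.outer, grid_step / 2)).query(nodes)[0]
    d_in = cKDTree(_densify(contours.inner, grid_step / 2)).query(nodes)[0]

    from matplotlib.path import Path as MplPath

    ribbon = MplPath(np.vstack([contours.outer, contours.inner[::-1]]))
    inside = ribbon.contains_points(nodes)
    region = inside | (d_out <= band) | (d_in <= band)
    region = region.reshape(ny, nx)
    fixed0 = (d_out <= band).reshape(ny, nx) & region
    fixed1 = (d_in <= band).reshape(ny, nx) & region & ~fixed0

    unknown = region & ~fixed0 & ~fixed1
    idx = -np.ones((ny, nx), dtype=np.int64)
    uy, ux = np.nonzero(unknown)
    idx[uy, ux] = np.arange(uy.size)

    field = np.full((ny, nx), np.nan)
    field[fixed0] = 0.0
    field[fixed1] = 1.0

    if uy.size:
        rows, cols, vals = [], [], []
        rhs = np.zeros(uy.size)
        deg = np.zeros(uy.size)
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nyy, nxx = uy + dy, ux + dx
            ok = (nyy >= 0) & (nyy < ny) & (nxx >= 0) & (nxx < nx)
            ok &= region[nyy % ny, nxx % nx]
            deg += ok
            nb_unknown = ok & (idx[nyy % ny, nxx % nx] >= 0)
            rows.append(np.nonzero(nb_unknown)[0])
            cols.append(idx[nyy[nb_unknown], nxx[nb_unknown]])
            vals.append(-np.ones(nb_unknown.sum()))
            nb_fixed = ok & ~nb_unknown
            np.add.at(rhs, np.nonzero(nb_fixed)[0], field[nyy[nb_fixed], nxx[nb_fixed]])
        rows.append(np.arange(uy.size))
        cols.append(np.arange(uy.size))
        vals.append(deg)
        lap = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(uy.size, uy.size),
        )
        field[uy, ux] = spsolve(lap, rhs)

    return field, region, (x0, y0)


def build_traverses(
    contours: ContourPair,
    spacing: float,
    grid_step: float = 1.0,
    step_fraction: float = 0.5,
) -> list[np.ndarray]:
    """Equidistant traverses from the outer to the inner contour.

    Traverses start at equal arc spacing (``spacing`` in μm) on the outer
    contour and follow the gradient streamlines of the harmonic depth field
    until they reach the inner contour.  Returns one (k, 2) polyline of
    (x, y) pixel coordinates per traverse; streamlines of a harmonic field
    are pairwise non-intersecting.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    field, region, (x0, y0) = harmonic_depth_field(contours, grid_step)

    # fill outside-region values by nearest valid node so interpolation
    # stays well-behaved at the ribbon boundary
    from scipy.ndimage import distance_transform_edt, map_coordinates

    invalid = ~np.isfinite(field)
    if invalid.any():
        _, (iy, ix) = distance_transform_edt(invalid, return_indices=True)
        filled = field[iy, ix]
    else:
        filled = field
    gyf, gxf = np.gradient(filled, grid_step)
    # inside the Dirichlet bands the field is constant and its gradient
    # vanishes; replace degenerate gradients by the nearest interior one so
    # streamlines can leave the outer contour
    bad = (np.hypot(gxf, gyf) < 1e-9) | invalid
    if bad.any() and not bad.all():
        _, (by, bx) = distance_transform_edt(bad, return_indices=True)
        gxf = gxf[by, bx]
        gyf = gyf[by, bx]

    def interp(arr, pts):
        return map_coordinates(
            arr,
            [(pts[:, 1] - y0) / grid_step, (pts[:, 0] - x0) / grid_step],
            order=1,
            mode="nearest",
        )

    spacing_px = spacing / contours.pixel_size
    seeds = _resample_polyline(contours.outer, spacing_px)
    inner_dense = _densify(contours.inner, grid_step / 4)
    inner_tree = cKDTree(inner_dense)
    h = step_fraction * grid_step
    thickness_px = float(
        cKDTree(_densify(contours.inner, grid_step)).query(
            _densify(contours.outer, grid_step)
        )[0].mean()
    )
    max_steps = int(20 * thickness_px / h) + 100

    # trace all streamlines in lockstep (midpoint rule)
    n = len(seeds)
    pts = seeds.copy()
    paths = [[seeds[i].copy()] for i in range(n)]
    active = np.ones(n, dtype=bool)
    for _ in range(max_steps):
        if not active.any():
            break
        cur = pts[active]
        u = interp(filled, cur)
        gx = interp(gxf, cur)
        gy = interp(gyf, cur)
        norm = np.hypot(gx, gy)
        alive = (u < 0.995) & (norm > 1e-12)
        idx_active = np.flatnonzero(active)
        active[idx_active[~alive]] = False
        if not alive.any():
            break
        cur = cur[alive]
        step1 = np.column_stack([gx[alive], gy[alive]]) / norm[alive, None]
        mid = cur + 0.5 * h * step1
        g2x = interp(gxf, mid)
        g2y = interp(gyf, mid)
        n2 = np.hypot(g2x, g2y)
        step2 = np.where(
            (n2 > 1e-12)[:, None],
            np.column_stack([g2x, g2y]) / np.maximum(n2, 1e-300)[:, None],
            step1,
        )
        nxt = cur + h * step2
        pts[idx_active[alive]] = nxt
        for j, pj in zip(idx_active[alive], nxt):
            paths[j].append(pj.copy())

    ends = inner_dense[inner_tree.query(pts)[1]]
    return [
        np.vstack([np.asarray(paths[i]), ends[i]]) for i in range(n)
    ]


def traverses_cross(traverses: list[np.ndarray]) -> bool:
    """True if any two traverse polylines properly intersect."""
    from shapely.geometry import LineString

    lines = [LineString(t) for t in traverses]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            if lines[i].crosses(lines[j]):
                return True
    return False


def extract_profile(gli, traverse: np.ndarray, D: int = 101, arc_position: int = 0) -> Profile:
    """Sample the GLI image along a traverse and length-normalize.

    The traverse is sampled bilinearly in the GLI image and resampled by
    linear interpolation to ``D`` equidistant depth points spanning
    0–100 % cortical depth.  The traverse must stay inside the GLI domain.
    """
    from cytomap.gli import sample

    traverse = np.asarray(traverse, dtype=float)
    fps = gli.field_size / gli.source_pixel_size
    h, w = gli.values.shape
    xmax = gli.origin_offset[0] + w * fps
    ymax = gli.origin_offset[1] + h * fps
    if (
        traverse[:, 0].min() < gli.origin_offset[0] - fps
        or traverse[:, 1].min() < gli.origin_offset[1] - fps
        or traverse[:, 0].max() > xmax + fps
        or traverse[:, 1].max() > ymax + fps
    ):
        raise ValueError(
            f"traverse at arc position {arc_position} exits the GLI image domain"
        )
    arc = _polyline_arclength(traverse)
    total = arc[-1]
    if total <= 0:
        raise ValueError(f"zero-length traverse at arc position {arc_position}")
    values = sample(gli, traverse)
    depths = np.linspace(0.0, 100.0, D)
    resampled = np.interp(depths, 100.0 * arc / total, values)
    return Profile(
        depths=depths,
        values=np.clip(resampled, 0.0, 100.0),
        arc_position=arc_position,
        raw_length=total * gli.source_pixel_size,
    )


# --------------------------------------------------------------------------
# Feature vectors

FEATURE_NAMES = (
    "mean",
    "cog",
    "sd",
    "skew",
    "kurt",
    "d_mean",
    "d_cog",
    "d_sd",
    "d_skew",
    "d_kurt",
)


def _weighted_shape_moments(
    values: np.ndarray, depths: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Mean, center of gravity and shape moments of one value sequence.

    The sequence is treated as a weight function over cortical depth: the
    center of gravity is the value-weighted mean depth, and SD/skewness/
    kurtosis (non-excess) are the central moments of that depth
    distribution.  A sequence that is all zero, or flat (carrying no
    laminar shape information), gets zero shape moments by convention.
    """
    total = float(values.sum())
    if total <= 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    mean = float(values.mean())
    w = values / total
    cog = float(w @ depths)
    if np.ptp(values) <= 1e-12 * max(np.abs(values).max(), 1.0):
        return mean, cog, 0.0, 0.0, 0.0
    centered = depths - cog
    var = float(w @ centered**2)
    sd = float(np.sqrt(max(var, 0.0)))
    if sd <= 0:
        return mean, cog, 0.0, 0.0, 0.0
    skew = float(w @ centered**3) / sd**3
    kurt = float(w @ centered**4) / sd**4
    return mean, cog, sd, skew, kurt


def _value_shape_moments(
    values: np.ndarray, depths: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Alternative convention: moments of the value sequence itself."""
    from scipy import stats

    total = float(values.sum())
    if total <= 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    mean = float(values.mean())
    cog = float((values / total) @ depths)
    sd = float(values.std())
    if sd <= 0:
        return mean, cog, 0.0, 0.0, 0.0
    return (
        mean,
        cog,
        sd,
        float(stats.skew(values, bias=True)),
        float(stats.kurtosis(values, bias=True, fisher=False)),
    )


def feature_vector(
    profile: Profile, rectify: bool = True, weighting: str = "depth"
) -> np.ndarray:
    """Ten-element feature vector of a laminar profile.

    Five statistics — mean GLI, center of gravity (% depth), standard
    deviation, skewness and kurtosis — of the profile, and the same five of
    its first derivative with respect to depth.  By default the derivative
    is rectified (absolute value): shape moments of a signed derivative
    with near-zero mean are numerically unstable.  ``weighting="depth"``
    (default) computes the moments of the depth distribution weighted by
    the profile; ``weighting="value"`` computes plain moments of the value
    sequence.
    """
    if weighting == "depth":
        moments = _weighted_shape_moments
    elif weighting == "value":
        moments = _value_shape_moments
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    v = np.asarray(profile.values, dtype=float)
    d = np.asarray(profile.depths, dtype=float)
    deriv = np.gradient(v, d)
    if rectify:
        deriv = np.abs(deriv)
    return np.array(list(moments(v, d)) + list(moments(deriv, d)))


def feature_matrix(profiles: list[Profile], **kwargs) -> np.ndarray:
    """Stack feature vectors of a profile sequence into an (n, 10) array."""
    return np.vstack([feature_vector(p, **kwargs) for p in profiles])


def profiles_dataframe(profiles: list[Profile]):
    """Profiles as a DataFrame (one row per traverse) for CSV export."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {"arc_position": p.arc_position, "raw_length_um": p.raw_length}
        row.update({f"d{int(d):03d}": v for d, v in zip(p.depths, p.values)})
        rows.append(row)
    return pd.DataFrame(rows)


def features_dataframe(profiles: list[Profile], **kwargs):
    """Feature vectors as a DataFrame with named columns."""
    import pandas as pd

    mat = feature_matrix(profiles, **kwargs)
    df = pd.DataFrame(mat, columns=list(FEATURE_NAMES))
    df.insert(0, "arc_position", [p.arc_position for p in profiles])
    return df
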