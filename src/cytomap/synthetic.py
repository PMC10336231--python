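"""Synthetic histology with planted ground truth.

Generates the three kinds of input the mapping pipeline consumes:

* stained-section images of a curved cortical ribbon with depth-dependent
  laminar cell densities, distinct area archetypes and a planted
  area border at a known arc position (:func:`make_section`);
* cohorts of rigidly jittered area label volumes in a shared voxel grid,
  standing in for registered multi-subject delineations
  (:func:`make_cohort_labels`);
* per-brain/hemisphere area volume tables with configurable asymmetry and
  sex effects (:func:`make_volume_table`).

All generators are deterministic given their seed.  Laminar depth is defined
as the normalized distance between the outer (layer I/II) and inner (layer
VI / white matter) contour — the same coordinate the profile-extraction
stage measures — so planted ground truth and measurement share one
coordinate system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cytomap.probmaps import LabelVolume

# Arc-length period (μm) of the columnar density modulation.
_COLUMN_PERIOD_UM = 150.0
# Gray values of the rendered stain and background, before noise.
_CELL_VALUE = 45
_BACKGROUND_VALUE = 230
# How often a dart may be re-thrown to avoid landing on an existing cell.
_OVERLAP_RETRIES = 8

_LAYER_IV = 3  # index of layer IV in a 6-layer scheme (I..VI)


@dataclass(frozen=True)
class AreaArchetype:
    """Parametric description of one cortical area's laminar cytoarchitecture.

    ``layer_boundaries`` are depth fractions in [0, 1] delimiting layers
    I–VI (7 values, strictly increasing, starting at 0 and ending at 1).
    ``layer_densities`` give the target volume fraction of stained cell
    bodies per layer in percent.  ``columnarity`` ≥ 0 sets the amplitude of
    a multiplicative sinusoidal density modulation along the arc, emulating
    vertical cell columns.
    """

    name: str
    layer_boundaries: tuple[float, ...]
    layer_densities: tuple[float, ...]
    cell_radius_range: tuple[float, float] = (4.0, 7.0)
    columnarity: float = 0.0

    def __post_init__(self) -> None:
        b = np.asarray(self.layer_boundaries, dtype=float)
        if b.size < 2 or b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ValueError(
                "layer_boundaries must be strictly increasing from 0 to 1"
            )
        d = np.asarray(self.layer_densities, dtype=float)
        if d.size != b.size - 1:
            raise ValueError("need one density per layer")
        if np.any((d < 0) | (d > 100)):
            raise ValueError("layer_densities must lie in [0, 100] percent")
        if self.cell_radius_range[0] <= 0 or (
            self.cell_radius_range[1] < self.cell_radius_range[0]
        ):
            raise ValueError("invalid cell_radius_range")
        if self.columnarity < 0:
            raise ValueError("columnarity must be >= 0")

    def density_at(self, depth: np.ndarray) -> np.ndarray:
        """Target stain volume fraction (%) at normalized depth in [0, 1]."""
        depth = np.asarray(depth, dtype=float)
        idx = np.clip(
            np.searchsorted(self.layer_boundaries, depth, side="right") - 1,
            0,
            len(self.layer_densities) - 1,
        )
        return np.asarray(self.layer_densities, dtype=float)[idx]

    @property
    def is_granular(self) -> bool:
        """True when layer IV density strictly exceeds both neighbors."""
        d = self.layer_densities
        if len(d) != 6:
            raise ValueError("granularity is defined for a 6-layer scheme")
        return d[_LAYER_IV] > d[_LAYER_IV - 1] and d[_LAYER_IV] > d[_LAYER_IV + 1]


def default_archetypes() -> dict[str, AreaArchetype]:
    """Archetypes loosely patterned on the frontal-opercular areas.

    The granular archetype has a broad, dense layer IV with well-defined
    borders to III and V; the dysgranular ones have an attenuated layer IV
    that does not rise above its neighbors.  The numeric densities are
    generator parameters on the GLI scale, not measurements of real cortex.
    """
    bounds = (0.0, 0.10, 0.25, 0.50, 0.62, 0.80, 1.0)
    return {
        "granular": AreaArchetype(
            "granular", bounds, (8.0, 22.0, 20.0, 38.0, 18.0, 24.0)
        ),
        "dysgranular_a": AreaArchetype(
            "dysgranular_a", bounds, (8.0, 20.0, 16.0, 18.0, 20.0, 22.0),
            columnarity=0.3,
        ),
        "dysgranular_b": AreaArchetype(
            "dysgranular_b", bounds, (8.0, 18.0, 22.0, 20.0, 20.0, 14.0)
        ),
    }


def clustering_archetypes() -> dict[str, AreaArchetype]:
    """Five archetypes forming two tight pairs plus one outlier.

    Built for similarity experiments: the two dysgranular opercular-like
    areas are mutually closest, the two inferior-frontal-like areas (heavy
    deep-layer pyramids) are mutually closest, and the granular archetype
    stands apart from both pairs.
    """
    bounds = (0.0, 0.10, 0.25, 0.50, 0.62, 0.80, 1.0)
    return {
        "op5_like": AreaArchetype(
            "op5_like", bounds, (8.0, 22.0, 20.0, 38.0, 18.0, 24.0)
        ),
        "op6_like": AreaArchetype(
            "op6_like", bounds, (8.0, 20.0, 16.0, 18.0, 20.0, 22.0)
        ),
        "op7_like": AreaArchetype(
            "op7_like", bounds, (8.0, 19.0, 17.0, 20.0, 21.0, 20.0)
        ),
        "a44_like": AreaArchetype(
            "a44_like", bounds, (6.0, 14.0, 30.0, 12.0, 32.0, 12.0)
        ),
        "a45_like": AreaArchetype(
            "a45_like", bounds, (6.0, 15.0, 28.0, 15.0, 30.0, 13.0)
        ),
    }


@dataclass(frozen=True)
class RibbonSpec:
    """Geometry and composition of one synthetic cortical ribbon section."""

    archetypes: tuple[AreaArchetype, ...]
    border_positions: tuple[float, ...] = ()
    geometry: str = "straight"  # straight | annulus | sinusoidal
    cortical_thickness: float = 2000.0  # μm
    arc_length: float = 8000.0  # μm
    pixel_size: float = 1.02  # μm per pixel
    noise_level: float = 6.0  # gray levels of additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("straight", "annulus", "sinusoidal"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if len(self.border_positions) != len(self.archetypes) - 1:
            raise ValueError("border count must equal archetype count - 1")
        pos = np.asarray(self.border_positions, dtype=float)
        if pos.size and (np.any(pos <= 0) or np.any(pos >= 1) or np.any(np.diff(pos) <= 0)):
            raise ValueError("border_positions must be increasing in (0, 1)")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")


@dataclass
class SyntheticSection:
    """One rendered section with its contours and planted ground truth."""

    image: np.ndarray  # uint8 grayscale, cells dark on bright background
    outer_contour: np.ndarray  # (N, 2) float, (x, y) pixel coordinates
    inner_contour: np.ndarray
    true_border_arcs: tuple[float, ...]
    pixel_size: float
    section_index: int = 0
    section_spacing: float = 300.0  # μm between mounted sections
    cell_mask: np.ndarray = field(default=None, repr=False)

    @property
    def cell_pixel_count(self) -> int:
        return int(self.cell_mask.sum())


def ribbon_coordinates(
    spec: RibbonSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel ribbon coordinates for a spec's geometry.

    Returns ``(s, d, inside, outer, inner)`` where ``s`` is the arc fraction
    in [0, 1], ``d`` the normalized depth in [0, 1] (0 = outer contour,
    1 = inner contour), ``inside`` the boolean ribbon mask — all on the image
    pixel grid — plus the sampled outer and inner contour polylines as
    ``(n, 2)`` arrays of (x, y) pixel coordinates.
    """
    t_px = spec.cortical_thickness / spec.pixel_size
    w_px = spec.arc_length / spec.pixel_size
    m = 8.0  # margin, px

    if spec.geometry == "straight":
        height = int(np.ceil(t_px + 2 * m))
        width = int(np.ceil(w_px + 2 * m))
        yy, xx = np.mgrid[0:height, 0:width].astype(float)
        s = (xx - m) / w_px
        d = (yy - m) / t_px
        n = max(int(np.ceil(w_px)), 2)
        cx = np.linspace(m, m + w_px, n)
        outer = np.column_stack([cx, np.full(n, m)])
        inner = np.column_stack([cx, np.full(n, m + t_px)])
    elif spec.geometry == "sinusoidal":
        amp = 0.5 * t_px
        lam = w_px / 2.0
        height = int(np.ceil(t_px + 2 * amp + 2 * m))
        width = int(np.ceil(w_px + 2 * m))
        yy, xx = np.mgrid[0:height, 0:width].astype(float)
        top = m + amp + amp * np.sin(2 * np.pi * (xx - m) / lam)
        s = (xx - m) / w_px
        d = (yy - top) / t_px
        n = max(int(np.ceil(w_px)), 2)
        cx = np.linspace(m, m + w_px, n)
        cy = m + amp + amp * np.sin(2 * np.pi * (cx - m) / lam)
        outer = np.column_stack([cx, cy])
        inner = np.column_stack([cx, cy + t_px])
    else:  # annulus segment; outer cortical surface on the larger radius
        dtheta = np.pi / 2
        r_mid = w_px / dtheta
        r_out = r_mid + t_px / 2
        r_in = r_mid - t_px / 2
        if r_in <= 2:
            raise ValueError("arc too short for annulus geometry at this thickness")
        # sector symmetric about the upward vertical from a center below it,
        # so the outer (pial) arc bulges toward the top of the image
        th0 = -np.pi / 2 - dtheta / 2
        half_w = r_out * np.sin(dtheta / 2)
        cx0 = m + half_w
        cy0 = m + r_out
        th = np.linspace(th0, th0 + dtheta, max(int(np.ceil(w_px)), 2))
        ox = cx0 + r_out * np.cos(th)
        oy = cy0 + r_out * np.sin(th)
        ix_ = cx0 + r_in * np.cos(th)
        iy_ = cy0 + r_in * np.sin(th)
        height = int(np.ceil(max(oy.max(), iy_.max()) + m))
        width = int(np.ceil(2 * half_w + 2 * m))
        yy, xx = np.mgrid[0:height, 0:width].astype(float)
        rr = np.hypot(xx - cx0, yy - cy0)
        ang = np.arctan2(yy - cy0, xx - cx0)
        s = (ang - th0) / dtheta
        d = (r_out - rr) / t_px
        outer = np.column_stack([ox, oy])
        inner = np.column_stack([ix_, iy_])

    eps = 1e-9
    inside = (s >= -eps) & (s <= 1 + eps) & (d >= -eps) & (d <= 1 + eps)
    return s, d, inside, outer, inner


def _segment_index(s: np.ndarray, borders: tuple[float, ...]) -> np.ndarray:
    """Archetype segment index per arc fraction."""
    return np.searchsorted(np.asarray(borders, dtype=float), s, side="right")


def make_section(spec: RibbonSpec, section_index: int = 0) -> SyntheticSection:
    """Render one stained section: dark cell disks on a bright background.

    Cells are placed by dart throwing with a limited number of re-throws to
    avoid overlap (overlap is allowed once the retries are exhausted);
    throwing stops per depth band when the band's covered stain fraction
    reaches the archetype's layer density, so the rendered volume fraction
    tracks the target to within one cell of granularity.
    """
    t_px = spec.cortical_thickness / spec.pixel_size
    if t_px < 10:
        raise ValueError(
            f"cortical thickness of {t_px:.1f} px is below the 10 px "
            "minimum needed to resolve laminar profiles"
        )
    rng = np.random.default_rng(spec.seed)
    s, d, inside, outer, inner = ribbon_coordinates(spec)
    h, w = s.shape
    seg = _segment_index(s, spec.border_positions)

    cell_mask = np.zeros((h, w), dtype=bool)

    # Depth bands per (segment, layer): pixel lists, targets, covered counts.
    band_id = np.full((h, w), -1, dtype=np.int32)
    bands: list[dict] = []
    for si, arch in enumerate(spec.archetypes):
        lb = np.asarray(arch.layer_boundaries)
        for li in range(len(arch.layer_densities)):
            sel = inside & (seg == si) & (d >= lb[li]) & (d < lb[li + 1])
            if li == len(arch.layer_densities) - 1:
                sel = inside & (seg == si) & (d >= lb[li]) & (d <= lb[li + 1])
            npix = int(sel.sum())
            if npix == 0:
                continue
            bid = len(bands)
            band_id[sel] = bid
            bands.append(
                {
                    "pixels": np.flatnonzero(sel.ravel()),
                    "target": int(round(arch.layer_densities[li] / 100.0 * npix)),
                    "covered": 0,
                    "arch": arch,
                }
            )

    s_flat = s.ravel()
    for band in bands:
        _fill_band(band, band_id, bands, cell_mask, s_flat, spec, rng)

    image = np.full((h, w), float(_BACKGROUND_VALUE))
    image[cell_mask] = _CELL_VALUE
    if spec.noise_level > 0:
        image += rng.normal(0.0, spec.noise_level, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return SyntheticSection(
        image=image,
        outer_contour=outer,
        inner_contour=inner,
        true_border_arcs=tuple(spec.border_positions),
        pixel_size=spec.pixel_size,
        section_index=section_index,
        cell_mask=cell_mask,
    )


def _fill_band(
    band: dict,
    band_id: np.ndarray,
    bands: list[dict],
    cell_mask: np.ndarray,
    s_flat: np.ndarray,
    spec: RibbonSpec,
    rng: np.random.Generator,
) -> None:
    """Throw cell darts into one depth band until its stain target is met."""
    h, w = cell_mask.shape
    if band["covered"] >= band["target"]:
        return
    arch: AreaArchetype = band["arch"]
    rmin = max(arch.cell_radius_range[0] / spec.pixel_size, 0.8)
    rmax = max(arch.cell_radius_range[1] / spec.pixel_size, rmin)
    mean_area = np.pi * ((rmin + rmax) / 2) ** 2
    max_attempts = int(50 * max(band["target"] / mean_area, 1) + 200)
    pixels = band["pixels"]
    col = arch.columnarity

    attempts = 0
    while band["covered"] < band["target"] and attempts < max_attempts:
        attempts += 1
        flat = int(pixels[rng.integers(len(pixels))])
        if col > 0:
            # multiplicative sinusoidal columnar modulation along the arc
            weight = 1.0 + col * np.sin(
                2 * np.pi * s_flat[flat] * spec.arc_length / _COLUMN_PERIOD_UM
            )
            if rng.random() * (1.0 + col) > max(weight, 0.0):
                continue
        y, x = divmod(flat, w)
        retries = 0
        while cell_mask[y, x] and retries < _OVERLAP_RETRIES:
            flat = int(pixels[rng.integers(len(pixels))])
            y, x = divmod(flat, w)
            retries += 1
        r = rng.uniform(rmin, rmax)
        ri = int(np.ceil(r))
        y0, y1 = max(y - ri, 0), min(y + ri + 1, h)
        x0, x1 = max(x - ri, 0), min(x + ri + 1, w)
        oy, ox = np.ogrid[y0 - y:y1 - y, x0 - x:x1 - x]
        disk = oy * oy + ox * ox <= r * r
        patch = cell_mask[y0:y1, x0:x1]
        new = disk & ~patch
        if not new.any():
            continue
        patch |= disk
        new_bids = band_id[y0:y1, x0:x1][new]
        new_bids = new_bids[new_bids >= 0]
        if new_bids.size:
            counts = np.bincount(new_bids, minlength=len(bands))
            for bid in np.flatnonzero(counts):
                bands[bid]["covered"] += int(counts[bid])


def make_section_series(
    spec: RibbonSpec, n_sections: int, arc_drift: float = 0.0
) -> list[SyntheticSection]:
    """A series of adjacent sections from one ribbon specification.

    Each section uses a per-section seed offset; ``arc_drift`` shifts the
    true border arc positions by that fraction per section (default 0,
    i.e. a border at identical positions across the series).
    """
    sections = []
    for k in range(n_sections):
        pos = tuple(
            float(np.clip(p + arc_drift * k, 1e-3, 1 - 1e-3))
            for p in spec.border_positions
        )
        spec_k = replace(spec, seed=spec.seed + 7919 * k, border_positions=pos)
        sections.append(make_section(spec_k, section_index=k))
    return sections


def archetype_profiles(
    archetype: AreaArchetype,
    n: int,
    D: int = 101,
    noise_sd: float = 2.0,
    smooth: float = 2.0,
    seed: int = 0,
):
    """Sample noisy laminar GLI profiles straight from an archetype.

    A fast stand-in for the image pipeline when only profile-level data are
    needed (e.g. area-similarity experiments): each profile is the
    archetype's layer-density function on the depth grid plus smoothed
    Gaussian noise, clipped to the valid GLI range.
    """
    from scipy.ndimage import gaussian_filter1d

    from cytomap.profiles import Profile

    rng = np.random.default_rng(seed)
    depths = np.linspace(0.0, 100.0, D)
    base = archetype.density_at(depths / 100.0)
    out = []
    for i in range(n):
        noise = rng.normal(0.0, noise_sd, size=D)
        if smooth > 0:
            noise = gaussian_filter1d(noise, smooth)
        values = np.clip(base + noise, 0.0, 100.0)
        out.append(Profile(depths=depths, values=values, arc_position=i))
    return out


# --------------------------------------------------------------------------
# Cohorts of jittered label volumes


@dataclass(frozen=True)
class CohortSpec:
    """Multi-subject cohort of rigidly jittered area label volumes."""

    area_templates: dict  # area id (int >= 1) -> boolean template mask
    grid_shape: tuple[int, int, int]
    n_subjects: int = 10
    voxel_size: float = 1.0  # mm
    jitter_translation_sd: float = 1.0  # mm
    jitter_rotation_sd: float = 2.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        total = np.zeros(self.grid_shape, dtype=np.int32)
        for aid, mask in self.area_templates.items():
            if int(aid) < 1:
                raise ValueError("area ids must be positive integers")
            if mask.shape != tuple(self.grid_shape):
                raise ValueError("template shape must match grid_shape")
            total += mask.astype(np.int32)
        if np.any(total > 1):
            raise ValueError("area templates must be pairwise disjoint")


def ellipsoid_template(
    grid_shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    """Boolean ellipsoid mask in voxel units — a convenient area template."""
    zz, yy, xx = np.mgrid[0:grid_shape[0], 0:grid_shape[1], 0:grid_shape[2]]
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def template_labels(spec: CohortSpec) -> np.ndarray:
    """Combined integer label grid of the (disjoint) templates."""
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    for aid, mask in sorted(spec.area_templates.items()):
        labels[mask] = int(aid)
    return labels


def make_cohort_labels(spec: CohortSpec) -> list[LabelVolume]:
    """Per-subject label volumes: templates under seeded rigid jitter.

    Each subject's labels are the template grid rotated by three small
    Euler angles about the grid center and translated, resampled with
    nearest-neighbor interpolation (which preserves per-subject label
    disjointness by construction).
    """
    from scipy import ndimage

    labels = template_labels(spec)
    center = (np.asarray(spec.grid_shape, dtype=float) - 1) / 2
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    out: list[LabelVolume] = []
    for si in range(spec.n_subjects):
        rng = np.random.default_rng(streams[si])
        ang = np.deg2rad(rng.normal(0.0, spec.jitter_rotation_sd, size=3))
        shift_vox = rng.normal(
            0.0, spec.jitter_translation_sd / spec.voxel_size, size=3
        )
        rot = _euler_matrix(*ang)
        # map output voxel -> input voxel: rotate about center, then shift
        offset = center - rot @ (center + shift_vox)
        moved = ndimage.affine_transform(
            labels, rot, offset=offset, order=0, mode="constant", cval=0,
            output=np.int16,
        )
        present = set(np.unique(moved))
        for aid in spec.area_templates:
            if int(aid) not in present:
                raise ValueError(
                    f"jitter moved area {aid} fully outside the grid "
                    f"for subject {si}"
                )
        out.append(
            LabelVolume(labels=moved, voxel_size=spec.voxel_size, subject=f"S{si:02d}")
        )
    return out


def _euler_matrix(ax: float, ay: float, az: float) -> np.ndarray:
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


# --------------------------------------------------------------------------
# Volume tables

_DEFAULT_AREA_MEANS = {"Op5": 1060.0, "Op6": 1280.0, "Op7": 525.0}


def make_volume_table(
    n_brains: int = 10,
    asymmetry_effect: float = 0.0,
    sex_effect: float = 0.0,
    noise_cv: float = 0.05,
    seed: int = 0,
    area_means: dict | None = None,
    between_brain_cv: float = 0.3,
) -> pd.DataFrame:
    """Synthetic per-brain × hemisphere × area volume table.

    Per brain and area a log-normal baseline volume is drawn (coefficient of
    variation ``between_brain_cv`` across brains); the right-hemisphere
    volume is the left times ``1 + asymmetry_effect`` before measurement
    noise, male brains are scaled by ``1 + sex_effect``, and every cell gets
    independent multiplicative log-normal noise of CV ``noise_cv``.  Sex
    labels are balanced.  ``volume_mm3`` is the histological (uncorrected)
    volume; multiply by ``shrinkage_factor`` for the corrected volume.
    """
    if n_brains < 2:
        raise ValueError("n_brains must be >= 2")
    for name, eff in (("asymmetry_effect", asymmetry_effect), ("sex_effect", sex_effect)):
        if eff <= -1:
            raise ValueError(f"{name} must be > -1")
    if noise_cv < 0 or between_brain_cv < 0:
        raise ValueError("coefficients of variation must be >= 0")
    area_means = dict(area_means or _DEFAULT_AREA_MEANS)

    rng = np.random.default_rng(seed)
    rows = []
    for bi in range(n_brains):
        brain = f"SB{bi + 1:02d}"
        sex = "f" if bi % 2 == 0 else "m"
        shrink = float(np.clip(2.0 + rng.normal(0.0, 0.1), 1.0, None))
        for area, mean in area_means.items():
            base = mean * _lognormal_factor(rng, between_brain_cv)
            if sex == "m":
                base *= 1.0 + sex_effect
            left = base * _lognormal_factor(rng, noise_cv)
            right = base * (1.0 + asymmetry_effect) * _lognormal_factor(rng, noise_cv)
            for hemi, vol in (("left", left), ("right", right)):
                rows.append(
                    {
                        "brain_id": brain,
                        "sex": sex,
                        "hemisphere": hemi,
                        "area": area,
                        "volume_mm3": vol / shrink,
                        "shrinkage_factor": shrink,
                    }
                )
    return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-sigma * sigma / 2, sigma)))


# --------------------------------------------------------------------------
# File output


def write_section(section: SyntheticSection, directory, stem: str = "section") -> dict:
    """Write a section's image (TIFF) and contours (CSV); return the paths."""
    from pathlib import Path

    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{stem}.tif"
    tifffile.imwrite(img_path, section.image)
    paths = {"image": img_path}
    for name, contour in (
        ("outer", section.outer_contour),
        ("inner", section.inner_contour),
    ):
        p = directory / f"{stem}_{name}_contour.csv"
        pd.DataFrame(contour, columns=["x", "y"]).to_csv(p, index=False)
        paths[name] = p
    meta = {
        "pixel_size": section.pixel_size,
        "section_index": section.section_index,
        "section_spacing": section.section_spacing,
        "true_border_arcs": list(section.true_border_arcs),
    }
    meta_path = directory / f"{stem}_meta.json"
    import json

    meta_path.write_text(json.dumps(meta, indent=2))
    paths["meta"] = meta_path
    return paths
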