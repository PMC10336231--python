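"""High-level glue running whole pipeline stages on section objects.

These helpers chain the per-module operations — cell segmentation, GLI
computation, traverse construction, profile extraction, feature vectors,
sliding-window Mahalanobis analysis and multi-section border acceptance —
for a single section or a series of adjacent sections.
"""

from __future__ import annotations

import numpy as np

from cytomap import borders, gli, profiles
from cytomap.synthetic import SyntheticSection


def section_feature_matrix(
    section: SyntheticSection,
    fields_per_side: int = 16,
    traverse_spacing: float | None = None,
    D: int = 101,
    grid_step: float | None = None,
) -> np.ndarray:
    """Feature vectors of all traverses of one section, ordered along the arc.

    ``traverse_spacing`` is the seed spacing on the outer contour in μm
    (default: two GLI fields); ``grid_step`` the resolution of the harmonic
    depth field in source pixels (default: half a GLI field, at least 1).
    """
    mask = gli.segment_cells(section.image, method="otsu")
    g = gli.compute_gli_image(
        mask, fields_per_side=fields_per_side, source_pixel_size=section.pixel_size
    )
    contours = profiles.ContourPair(
        outer=section.outer_contour,
        inner=section.inner_contour,
        pixel_size=section.pixel_size,
    )
    if traverse_spacing is None:
        traverse_spacing = 2 * g.field_size
    if grid_step is None:
        grid_step = max(1.0, float(fields_per_side))
    travs = profiles.build_traverses(contours, traverse_spacing, grid_step=grid_step)
    profs = [
        profiles.extract_profile(g, t, D=D, arc_position=i)
        for i, t in enumerate(travs)
    ]
    return profiles.feature_matrix(profs)


def detect_borders(
    sections: list[SyntheticSection],
    block_sizes=borders.DEFAULT_BLOCK_SIZES,
    alpha: float = 0.05,
    ridge: float = 1e-6,
    position_tolerance: int = 4,
    min_sections: int = 3,
    min_block_sizes: int = 3,
    exclusion_masks: dict | None = None,
    **feature_kwargs,
) -> tuple[list[borders.BorderCall], dict]:
    """Run the full border-detection pipeline on a series of sections.

    Returns the accepted border calls and the per-section map of
    significant maxima per block size (useful for reporting).
    """
    per_section: dict[int, dict[int, np.ndarray]] = {}
    for section in sections:
        feats = section_feature_matrix(section, **feature_kwargs)
        by_block: dict[int, np.ndarray] = {}
        mask = None
        if exclusion_masks is not None:
            mask = exclusion_masks.get(section.section_index)
        for b in block_sizes:
            if len(feats) < 2 * b:
                continue
            curve = borders.md_curve(feats, b, ridge=ridge)
            by_block[b] = borders.find_significant_maxima(curve, alpha, mask=mask)
        per_section[section.section_index] = by_block
    calls = borders.accept_borders(
        per_section,
        position_tolerance=position_tolerance,
        min_sections=min_sections,
        min_block_sizes=min_block_sizes,
    )
    return calls, per_section
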