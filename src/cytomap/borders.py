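"""Observer-independent border detection.

Adjacent blocks of profile feature vectors are compared with the
Mahalanobis distance (MD) in a sliding window moved one profile at a time
along the cortical ribbon.  A border between two areas produces a local
maximum of the MD curve; its significance is assessed with a
Bonferroni-corrected Hotelling's T² test.  A border is accepted only when
significant maxima appear at comparable positions for several block sizes
and in at least three adjacent sections — single-section, single-scale
maxima are treated as noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_BLOCK_SIZES = tuple(range(10, 25, 2))  # within the 10..24 range


@dataclass
class MDCurve:
    """Mahalanobis distance versus profile position for one block size."""

    block_size: int
    positions: np.ndarray = field(repr=False)  # candidate border indices
    md: np.ndarray = field(repr=False)
    pvals: np.ndarray = field(repr=False)  # Bonferroni-corrected
    significant_maxima: np.ndarray | None = field(default=None, repr=False)


@dataclass
class BorderCall:
    """An accepted cytoarchitectonic border with its supporting evidence."""

    position: int  # consensus profile index (median of supports)
    supporting_block_sizes: tuple[int, ...]
    supporting_sections: tuple[int, ...]
    tolerance_used: int


def mahalanobis_distance(
    left: np.ndarray, right: np.ndarray, ridge: float = 1e-6
) -> float:
    """MD between the mean feature vectors of two profile blocks.

    The pooled within-block covariance of the member vectors is regularized
    by adding ``ridge × trace(S)/dim`` to its diagonal before inversion;
    with block sizes near the feature dimension the raw pooled covariance
    is close to singular.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    diff = left.mean(axis=0) - right.mean(axis=0)
    dim = left.shape[1]
    n1, n2 = left.shape[0], right.shape[0]
    s = ((n1 - 1) * np.cov(left.T) + (n2 - 1) * np.cov(right.T)) / (n1 + n2 - 2)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    s_reg = s + np.eye(dim) * (ridge * tr / dim if tr > 0 else ridge)
    try:
        sol = np.linalg.solve(s_reg, diff)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular even after regularization; "
            "increase the ridge parameter"
        ) from exc
    md2 = float(diff @ sol)
    if not np.isfinite(md2):
        raise np.linalg.LinAlgError(
            "Mahalanobis distance not finite; increase the ridge parameter"
        )
    return float(np.sqrt(max(md2, 0.0)))


def md_curve(
    features: np.ndarray,
    block_size: int,
    ridge: float = 1e-6,
    n_tests: int | None = None,
) -> MDCurve:
    """Slide two adjacent blocks of ``block_size`` profiles along the ribbon.

    At position *i* the left block covers profiles ``[i-b, i)`` and the
    right block ``[i, i+b)``; the MD between their mean feature vectors is
    evaluated, and a Hotelling's T² p-value is attached, Bonferroni
    corrected over the ``n_tests`` positions of the curve (default: all
    positions tested for this block size).
    """
    features = np.asarray(features, dtype=float)
    n, dim = features.shape
    b = int(block_size)
    if n < 2 * b:
        raise ValueError(
            f"need at least {2 * b} profiles for block size {b}, got {n}"
        )
    positions = np.arange(b, n - b + 1)
    if n_tests is None:
        n_tests = len(positions)
    md = np.empty(len(positions))
    for k, i in enumerate(positions):
        md[k] = mahalanobis_distance(features[i - b:i], features[i:i + b], ridge)
    pvals = np.array(
        [hotelling_pvalue(m, b, b, dim, n_tests) for m in md]
    )
    return MDCurve(block_size=b, positions=positions, md=md, pvals=pvals)


def hotelling_pvalue(
    md: float, b1: int, b2: int, dim: int, n_tests: int = 1
) -> float:
    """Bonferroni-corrected two-sample Hotelling's T² p-value for an MD.

    ``T² = (b1·b2/(b1+b2)) · MD²`` follows, after scaling by
    ``(b1+b2−dim−1)/((b1+b2−2)·dim)``, an F distribution with
    ``(dim, b1+b2−dim−1)`` degrees of freedom under the null hypothesis of
    equal block means.
    """
    n = b1 + b2
    df2 = n - dim - 1
    if df2 <= 0:
        raise ValueError(
            f"Hotelling test undefined: b1+b2={n} must exceed dim+1={dim + 1}"
        )
    t2 = (b1 * b2 / n) * md * md
    f_stat = t2 * df2 / ((n - 2) * dim)
    p = float(stats.f.sf(f_stat, dim, df2))
    return min(1.0, n_tests * p)


def find_significant_maxima(
    curve: MDCurve,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
    window: int = 2,
) -> np.ndarray:
    """Profile positions with significant local MD maxima.

    A position qualifies when its MD is a strict local maximum over a
    ±``window`` neighborhood of the curve, its corrected p-value is below
    ``alpha``, and it is not excluded by the artifact mask (a per-profile
    boolean sequence, True = excluded).  Ties within a window break toward
    the lower index.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    md = curve.md
    keep = []
    for k in range(len(md)):
        lo, hi = max(0, k - window), min(len(md), k + window + 1)
        nb = md[lo:hi]
        if md[k] < nb.max():
            continue
        # strict maximum with low-index tie-break
        ties = np.flatnonzero(nb == md[k]) + lo
        if ties[0] != k:
            continue
        if len(ties) > 1 and np.all(nb == md[k]):
            continue  # flat plateau spanning the window: no maximum
        if curve.pvals[k] >= alpha:
            continue
        pos = int(curve.positions[k])
        if mask is not None and bool(np.asarray(mask)[pos]):
            continue
        keep.append(pos)
    out = np.asarray(keep, dtype=int)
    curve.significant_maxima = out
    return out


def _cluster_positions(
    items: list[tuple[int, int]], tolerance: int
) -> list[tuple[float, set[int]]]:
    """Greedy 1D clustering of (position, tag) pairs within a tolerance.

    Returns (median position, set of tags) per cluster; a gap larger than
    ``tolerance`` between sorted positions starts a new cluster.
    """
    if not items:
        return []
    items = sorted(items)
    clusters = []
    cur_pos = [items[0][0]]
    cur_tags = {items[0][1]}
    for pos, tag in items[1:]:
        if pos - cur_pos[-1] <= tolerance:
            cur_pos.append(pos)
            cur_tags.add(tag)
        else:
            clusters.append((float(np.median(cur_pos)), cur_tags))
            cur_pos, cur_tags = [pos], {tag}
    clusters.append((float(np.median(cur_pos)), cur_tags))
    return clusters


def accept_borders(
    per_section_maxima: dict,
    position_tolerance: int = 4,
    min_sections: int = 3,
    min_block_sizes: int = 3,
) -> list[BorderCall]:
    """Multi-scale, multi-section acceptance of candidate borders.

    ``per_section_maxima`` maps section index → {block size → significant
    maxima positions}.  Within each section, maxima from different block
    sizes are clustered within ``position_tolerance``; clusters supported
    by at least ``min_block_sizes`` block sizes survive.  Surviving cluster
    positions are then chained across adjacent sections (again within the
    tolerance), and a border is called when a chain spans at least
    ``min_sections`` consecutive sections.  The consensus position is the
    median over the chain.
    """
    # per-section multi-scale clustering
    section_reps: dict[int, list[tuple[float, set[int]]]] = {}
    for sec, by_block in per_section_maxima.items():
        items = [
            (int(pos), int(b)) for b, positions in by_block.items() for pos in positions
        ]
        reps = [
            (pos, blocks)
            for pos, blocks in _cluster_positions(items, position_tolerance)
            if len(blocks) >= min_block_sizes
        ]
        section_reps[sec] = reps

    # chain across adjacent sections
    calls: list[BorderCall] = []
    chains: list[dict] = []  # {"positions": [...], "sections": [...], "blocks": set}

    def close(chain: dict) -> None:
        if len(chain["sections"]) >= min_sections:
            calls.append(
                BorderCall(
                    position=int(round(float(np.median(chain["positions"])))),
                    supporting_block_sizes=tuple(sorted(chain["blocks"])),
                    supporting_sections=tuple(chain["sections"]),
                    tolerance_used=position_tolerance,
                )
            )

    for sec in sorted(section_reps):
        reps = section_reps[sec]
        still_open = []
        used = [False] * len(reps)
        for chain in chains:
            if chain["sections"][-1] != sec - 1:
                close(chain)
                continue
            ref = float(np.median(chain["positions"]))
            best, best_d = None, None
            for k, (pos, _) in enumerate(reps):
                if used[k]:
                    continue
                d = abs(pos - ref)
                if d <= position_tolerance and (best_d is None or d < best_d):
                    best, best_d = k, d
            if best is None:
                close(chain)
            else:
                used[best] = True
                pos, blocks = reps[best]
                chain["positions"].append(pos)
                chain["sections"].append(sec)
                chain["blocks"] |= blocks
                still_open.append(chain)
        for k, (pos, blocks) in enumerate(reps):
            if not used[k]:
                still_open.append(
                    {"positions": [pos], "sections": [sec], "blocks": set(blocks)}
                )
        chains = still_open
    for chain in chains:
        close(chain)
    calls.sort(key=lambda c: c.position)
    return calls
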