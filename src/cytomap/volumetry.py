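"""Shrinkage-corrected area volumetry and permutation inference.

Histological area volumes are estimated from serial delineations
(Cavalieri summation over sections), corrected by each brain's shrinkage
factor (fresh volume / post-processing volume), optionally normalized by
whole-brain volume, and compared between hemispheres and sexes with
non-parametric Monte-Carlo permutation tests under Benjamini–Hochberg
false-discovery-rate control.

The packaged fixture ``table4_volumes.csv`` carries the published
shrinkage-corrected volumes of areas Op5–Op7 in ten brains, from which the
per-area summary statistics and the hemispheric null result can be
recomputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

AREAS = ("Op5", "Op6", "Op7")
HEMISPHERES = ("left", "right")


@dataclass
class PermutationResult:
    """Outcome of one Monte-Carlo permutation test."""

    statistic: float
    pvalue: float
    iterations: int
    seed: int | None = None
    adjusted_pvalue: float | None = None


def area_volume_from_sections(
    section_areas_mm2, section_spacing_mm: float, shrinkage_factor: float = 1.0
) -> float:
    """Cavalieri volume estimate from serial delineation areas.

    volume = shrinkage factor × section spacing × Σ delineated areas.
    """
    areas = np.asarray(section_areas_mm2, dtype=float)
    if np.any(areas < 0):
        raise ValueError("delineation areas must be non-negative")
    if section_spacing_mm <= 0:
        raise ValueError("section spacing must be positive")
    if shrinkage_factor <= 0:
        raise ValueError("shrinkage factor must be positive")
    return float(shrinkage_factor * section_spacing_mm * areas.sum())


def normalize_volume(area_volume_mm3: float, whole_brain_volume_mm3: float) -> float:
    """Area volume as a fraction of the whole-brain volume."""
    if whole_brain_volume_mm3 <= 0:
        raise ValueError("whole-brain volume must be positive")
    ratio = area_volume_mm3 / whole_brain_volume_mm3
    if ratio > 1:
        raise ValueError("area volume exceeds whole-brain volume")
    return ratio


def validate_volume_table(table: pd.DataFrame) -> None:
    required = {"brain_id", "hemisphere", "area", "volume_mm3"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"volume table misses columns: {sorted(missing)}")
    if np.any(table["volume_mm3"] <= 0):
        raise ValueError("volumes must be positive")
    if "shrinkage_factor" in table.columns and np.any(
        table["shrinkage_factor"] < 1
    ):
        warnings.warn("shrinkage factors below 1 are unusual", stacklevel=2)


def apply_shrinkage(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with volumes multiplied by the shrinkage factor."""
    out = table.copy()
    if "shrinkage_factor" in out.columns:
        out["volume_mm3"] = out["volume_mm3"] * out["shrinkage_factor"]
    return out


def summarize(table: pd.DataFrame) -> dict:
    """Per-area/hemisphere means and SDs plus per-brain total volumes.

    Returns a dict with ``stats`` (DataFrame indexed by area with
    mean/SD per hemisphere, sample SD with n−1 denominator), ``brain_sums``
    (Series of each brain's total over all area × hemisphere cells) and
    ``sum_mean`` / ``sum_sd`` of those totals.  Missing cells are an error.
    """
    validate_volume_table(table)
    pivot = table.pivot_table(
        index="brain_id", columns=["area", "hemisphere"], values="volume_mm3"
    )
    if pivot.isna().any().any():
        missing = [
            f"{b}:{a}/{h}"
            for b in pivot.index
            for (a, h) in pivot.columns
            if pd.isna(pivot.loc[b, (a, h)])
        ]
        raise ValueError(f"missing volume cells: {missing}")
    if len(pivot) < 2:
        raise ValueError("need at least 2 brains for standard deviations")
    stats = pd.DataFrame(
        {
            (h, stat): getattr(pivot.xs(h, axis=1, level="hemisphere"), fn)(
                axis=0, **kw
            )
            for h in sorted({h for _, h in pivot.columns})
            for stat, fn, kw in (
                ("mean", "mean", {}),
                ("sd", "std", {"ddof": 1}),
            )
        }
    )
    brain_sums = pivot.sum(axis=1)
    return {
        "stats": stats,
        "brain_sums": brain_sums,
        "sum_mean": float(brain_sums.mean()),
        "sum_sd": float(brain_sums.std(ddof=1)),
    }


def paired_permutation_test(
    x, y, iterations: int = 1_000_000, seed: int = 0
) -> PermutationResult:
    """Sign-flip permutation test for paired samples.

    The statistic is the mean paired difference; the null distribution is
    generated by random sign flips of the differences (Monte Carlo,
    seeded).  Two-sided p = (#{|T*| ≥ |T|} + 1)/(iterations + 1); all
    differences zero gives p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    t_obs = float(d.mean())
    if np.all(d == 0):
        return PermutationResult(0.0, 1.0, iterations, seed)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(iterations, 200_000 // max(d.size // 8, 1)))
    done = 0
    thresh = abs(t_obs) - 1e-12 * abs(t_obs)
    while done < iterations:
        m = min(chunk, iterations - done)
        signs = rng.integers(0, 2, size=(m, d.size)) * 2 - 1
        t_null = (signs * d).mean(axis=1)
        count += int(np.count_nonzero(np.abs(t_null) >= thresh))
        done += m
    p = (count + 1) / (iterations + 1)
    return PermutationResult(t_obs, float(p), iterations, seed)


def two_sample_permutation_test(
    a, b, iterations: int = 1_000_000, seed: int = 0
) -> PermutationResult:
    """Label-permutation test for two independent groups.

    The statistic is the difference of group means; group labels are
    randomly reassigned in each Monte-Carlo iteration.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    na = a.size
    t_obs = float(a.mean() - b.mean())
    if np.all(pooled == pooled[0]):
        return PermutationResult(t_obs, 1.0, iterations, seed)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, 200_000 // max(pooled.size, 1))
    done = 0
    thresh = abs(t_obs) - 1e-12 * abs(t_obs)
    total = pooled.sum()
    nb = b.size
    while done < iterations:
        m = min(chunk, iterations - done)
        keys = rng.random((m, pooled.size))
        order = np.argsort(keys, axis=1)
        perm_a = pooled[order[:, :na]]
        sum_a = perm_a.sum(axis=1)
        t_null = sum_a / na - (total - sum_a) / nb
        count += int(np.count_nonzero(np.abs(t_null) >= thresh))
        done += m
    p = (count + 1) / (iterations + 1)
    return PermutationResult(t_obs, float(p), iterations, seed)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    # guard against 1-ulp rounding pushing an adjusted value below its raw p
    return np.maximum(out, p)


def hemisphere_asymmetry_tests(
    table: pd.DataFrame,
    iterations: int = 1_000_000,
    seed: int = 0,
    areas=None,
) -> dict:
    """Left-vs-right paired permutation tests per area, FDR corrected.

    Volumes are paired by brain within each area; the returned dict maps
    area → :class:`PermutationResult` with both raw and adjusted p-values
    (the FDR family is the set of areas tested in this call).
    """
    validate_volume_table(table)
    if areas is None:
        areas = sorted(table["area"].unique())
    results = {}
    child_seeds = np.random.SeedSequence(seed).generate_state(len(areas)) % (2**31)
    for k, area in enumerate(areas):
        sub = table[table["area"] == area].pivot_table(
            index="brain_id", columns="hemisphere", values="volume_mm3"
        )
        if sub.isna().any().any():
            raise ValueError(f"unpaired hemisphere volumes for area {area}")
        results[area] = paired_permutation_test(
            sub["left"].to_numpy(),
            sub["right"].to_numpy(),
            iterations=iterations,
            seed=int(child_seeds[k]),
        )
    adjusted = fdr_adjust([r.pvalue for r in results.values()])
    for r, adj in zip(results.values(), adjusted):
        r.adjusted_pvalue = float(adj)
    return results


def load_table4() -> pd.DataFrame:
    """The packaged published volume table (shrinkage-corrected, mm³).

    Long format with columns brain_id, hemisphere, area, volume_mm3.  The
    file header documents the typographic corrections applied to the
    printed source.
    """
    with resources.files("cytomap.data").joinpath("table4_volumes.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
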