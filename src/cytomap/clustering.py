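"""Hierarchical cluster analysis of area-level cytoarchitecture.

Feature vectors sampled from each area (10–15 consecutive profiles per
section, pooled over hemispheres) are compared with the Euclidean distance
and merged by Ward's linkage; the dendrogram expresses cytoarchitectonic
similarity between areas — similar areas merge at low heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy


@dataclass
class AreaSample:
    """One feature vector with its provenance labels."""

    area: str
    features: np.ndarray
    brain: str = ""
    hemisphere: str = ""
    section: int = 0


@dataclass
class Dendrogram:
    """A Ward merge tree over labeled leaves."""

    linkage: np.ndarray = field(repr=False)  # scipy linkage matrix
    labels: tuple[str, ...]
    method: str = "ward"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


RECOMMENDED_PROFILES_PER_SECTION = (10, 15)


def cluster_areas(
    samples: list[AreaSample],
    level: str = "area-mean",
    standardize: bool = True,
) -> Dendrogram:
    """Ward clustering of area feature vectors.

    ``level="area-mean"`` clusters one mean feature vector per area (leaf
    labels = area names); ``level="profile"`` clusters individual samples
    (leaf labels repeat the area name).  Features are standardized to zero
    mean and unit variance across all samples before distances are taken,
    so that no single feature dominates through its units.
    """
    if level not in ("profile", "area-mean"):
        raise ValueError(f"unknown level {level!r}")
    areas = sorted({s.area for s in samples})
    if len(areas) < 2:
        raise ValueError("need samples from at least 2 distinct areas")
    counts = {a: sum(s.area == a for s in samples) for a in areas}
    lo, hi = RECOMMENDED_PROFILES_PER_SECTION
    per_section: dict[tuple, int] = {}
    for s in samples:
        key = (s.area, s.brain, s.hemisphere, s.section)
        per_section[key] = per_section.get(key, 0) + 1
    off = sorted({k[0] for k, c in per_section.items() if not lo <= c <= hi})
    if off:
        warnings.warn(
            f"areas with profile counts outside the recommended "
            f"{lo}-{hi} per section: {off}",
            stacklevel=2,
        )
    if level == "profile":
        singles = [a for a, c in counts.items() if c == 1]
        if singles:
            warnings.warn(
                f"areas with a single sample at profile level: {singles}",
                stacklevel=2,
            )
    x = np.vstack([np.asarray(s.features, dtype=float) for s in samples])
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    if level == "profile":
        labels = tuple(s.area for s in samples)
        data = x
    else:
        idx = {a: [] for a in areas}
        for i, s in enumerate(samples):
            idx[s.area].append(i)
        data = np.vstack([x[idx[a]].mean(axis=0) for a in areas])
        labels = tuple(areas)
    z = hierarchy.linkage(data, method="ward")
    return Dendrogram(linkage=z, labels=labels)


def cophenetic_distance(dendrogram: Dendrogram, a: str, b: str) -> float:
    """Height of the lowest merge joining leaves ``a`` and ``b``.

    Requires unique leaf labels (area-mean dendrograms).
    """
    labels = dendrogram.labels
    if len(set(labels)) != len(labels):
        raise ValueError("cophenetic lookup requires unique leaf labels")
    for lab in (a, b):
        if lab not in labels:
            raise KeyError(f"unknown leaf label {lab!r}")
    if a == b:
        return 0.0
    from scipy.spatial.distance import squareform

    coph = squareform(hierarchy.cophenet(dendrogram.linkage))
    return float(coph[labels.index(a), labels.index(b)])


def to_newick(dendrogram: Dendrogram) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(dendrogram.linkage)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{dendrogram.labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def merge_table(dendrogram: Dendrogram):
    """Merge sequence as a DataFrame (children ids, height, cluster size)."""
    import pandas as pd

    z = dendrogram.linkage
    return pd.DataFrame(
        {
            "child_a": z[:, 0].astype(int),
            "child_b": z[:, 1].astype(int),
            "height": z[:, 2],
            "size": z[:, 3].astype(int),
        }
    )


def plot_dendrogram(dendrogram: Dendrogram, path=None):
    """Render the dendrogram with matplotlib; optionally save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    hierarchy.dendrogram(
        dendrogram.linkage, labels=list(dendrogram.labels), ax=ax
    )
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
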