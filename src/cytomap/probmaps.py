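"""Probabilistic maps and the maximum probability map (MPM).

Multi-subject area delineations, already aligned in a common voxel grid,
are superimposed: for each area the probability map gives the fraction of
subjects in which that area occupies each voxel.  The MPM assigns every
voxel to the area with the highest probability there, quantifying the
consensus parcellation across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LabelVolume:
    """One subject's area delineations: integer labels on a voxel grid.

    0 is background; positive integers are area ids.
    """

    labels: np.ndarray = field(repr=False)
    voxel_size: float = 1.0  # mm, isotropic
    subject: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0 (0 = background)")

    @property
    def area_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


@dataclass
class ProbabilityMap:
    """Per-area voxelwise overlap fractions across a cohort."""

    maps: dict  # area id -> float grid in [0, 1]
    n_subjects: int
    voxel_size: float = 1.0

    @property
    def area_ids(self) -> list[int]:
        return sorted(self.maps)


@dataclass
class MaximumProbabilityMap:
    """Voxelwise assignment to the area of highest probability."""

    labels: np.ndarray = field(repr=False)
    threshold: float = 0.0
    tie_rule: str = "neighbor-majority-then-lowest-id"
    voxel_size: float = 1.0


def build_probability_maps(volumes: list[LabelVolume]) -> ProbabilityMap:
    """Superimpose subject label volumes into per-area probability maps.

    For area *a*, ``p_a(v)`` is the number of subjects whose label at voxel
    *v* equals *a*, divided by the number of subjects.
    """
    if not volumes:
        raise ValueError("need at least one label volume")
    shape = volumes[0].labels.shape
    vs = volumes[0].voxel_size
    for v in volumes:
        if v.labels.shape != shape or v.voxel_size != vs:
            raise ValueError(
                f"grid mismatch: subject {v.subject!r} has shape "
                f"{v.labels.shape} / voxel {v.voxel_size}, expected {shape} / {vs}"
            )
    ids = sorted({a for v in volumes for a in v.area_ids})
    n = len(volumes)
    maps = {}
    for aid in ids:
        count = np.zeros(shape, dtype=np.int32)
        for v in volumes:
            count += v.labels == aid
        maps[aid] = count / n
    return ProbabilityMap(maps=maps, n_subjects=n, voxel_size=vs)


def compute_mpm(
    pmap: ProbabilityMap, threshold: float = 0.0
) -> MaximumProbabilityMap:
    """Assign each voxel to its most probable area.

    A voxel is assigned to ``argmax_a p_a(v)`` when that maximum is positive
    and at least ``threshold``; otherwise it stays unassigned (0).  Exact
    ties are resolved deterministically: first by the majority area among
    the tied candidates' 6-connected neighbors that already have a unique
    assignment, and any remaining tie by the lowest area id.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    ids = pmap.area_ids
    if not ids:
        raise ValueError("probability map contains no areas")
    stack = np.stack([pmap.maps[a] for a in ids])
    pmax = stack.max(axis=0)
    assigned = (pmax > 0) & (pmax >= threshold)
    is_max = stack == pmax[None]
    n_ties = is_max.sum(axis=0)

    id_arr = np.asarray(ids)
    out = np.zeros(pmap.maps[ids[0]].shape, dtype=np.int16)
    unique = assigned & (n_ties == 1)
    out[unique] = id_arr[np.argmax(stack, axis=0)[unique]]

    tie_vox = np.argwhere(assigned & (n_ties > 1))
    for vox in tie_vox:
        vox = tuple(vox)
        cands = id_arr[is_max[(slice(None),) + vox]]
        votes = {int(c): 0 for c in cands}
        for axis in range(out.ndim):
            for step in (-1, 1):
                nb = list(vox)
                nb[axis] += step
                if 0 <= nb[axis] < out.shape[axis]:
                    lab = int(out[tuple(nb)])
                    if lab in votes and unique[tuple(nb)]:
                        votes[lab] += 1
        best = max(votes.values())
        winner = min(c for c, v in votes.items() if v == best)
        out[vox] = winner
    return MaximumProbabilityMap(
        labels=out, threshold=threshold, voxel_size=pmap.voxel_size
    )


def centers_of_gravity(mpm: MaximumProbabilityMap) -> dict:
    """Unweighted mean voxel coordinate per area, in mm.

    World coordinates are voxel index × voxel size along each axis.
    """
    out = {}
    for aid in np.unique(mpm.labels):
        if aid == 0:
            continue
        idx = np.argwhere(mpm.labels == aid)
        out[int(aid)] = idx.mean(axis=0) * mpm.voxel_size
    if not out:
        raise ValueError("maximum probability map contains no assigned areas")
    return out


def center_of_gravity(mpm: MaximumProbabilityMap, area: int) -> np.ndarray:
    """Center of gravity of one area; error if the area is absent."""
    if not np.any(mpm.labels == area):
        raise ValueError(f"area {area} is empty in the maximum probability map")
    return np.argwhere(mpm.labels == area).mean(axis=0) * mpm.voxel_size


def save_nifti(grid: np.ndarray, voxel_size: float, path) -> None:
    """Write a 3D grid as NIfTI with an isotropic scaled-identity affine."""
    import nibabel as nib

    affine = np.diag([voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(grid), affine)
    nib.save(img, str(path))


def load_label_volume(path, subject: str = "") -> LabelVolume:
    """Read an integer label NIfTI written by :func:`save_nifti`."""
    import nibabel as nib

    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    data = np.asanyarray(img.dataobj).astype(np.int16)
    return LabelVolume(labels=data, voxel_size=voxel, subject=subject)
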