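"""ROI localization from the group statistic map.

Peak-level thresholding at an uncorrected one-tailed p, 3D connected-
component labeling, family-wise-error control of cluster extent via a
sign-flipping max-extent permutation null, and the minimum-size filter
(clusters below 25 voxels are discarded regardless of significance,
because multivoxel decoding needs a reasonable feature count).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .glm import StatMap, group_map

logger = logging.getLogger(__name__)

DEFAULT_MIN_VOXELS = 25
DEFAULT_CONNECTIVITY = 18


def threshold_peaks(stat_map: StatMap, p_peak: float = 0.001) -> np.ndarray:
    """Binary map of voxels with one-tailed p < ``p_peak`` under t(df)."""
    if not 0 < p_peak <= 1:
        raise ValueError("p_peak must be in (0, 1]")
    if stat_map.dof is None or stat_map.dof < 1:
        raise ValueError("stat map carries no valid degrees of freedom")
    if p_peak == 1.0:
        return np.isfinite(stat_map.values)
    t_crit = sps.t.ppf(1.0 - p_peak, stat_map.dof)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(stat_map.values, nan=-np.inf) > t_crit


def _structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


@dataclass
class Cluster:
    label: int
    size: int
    peak: tuple[int, int, int]
    peak_stat: float


@dataclass
class ClusterSet:
    labels: np.ndarray  # 3D int volume, 0 = background
    clusters: tuple[Cluster, ...]

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]


def label_clusters(
    binary_map: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    stat_map: np.ndarray | None = None,
) -> ClusterSet:
    """Connected components of a binary 3D map.

    Labels are assigned deterministically: descending size, ties broken
    by the lexicographically smallest peak coordinate. The peak is the
    in-cluster maximum of ``stat_map`` when given, else the
    lexicographically smallest cluster voxel.
    """
    binary_map = np.asarray(binary_map)
    if binary_map.dtype != bool:
        uniq = np.unique(binary_map)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("label_clusters expects a binary map")
        binary_map = binary_map.astype(bool)
    raw, n = ndimage.label(binary_map, structure=_structure(connectivity))

    entries = []
    for lab in range(1, n + 1):
        coords = np.argwhere(raw == lab)
        if stat_map is not None:
            vals = stat_map[tuple(coords.T)]
            peak = tuple(int(v) for v in coords[int(np.argmax(vals))])
            peak_stat = float(np.max(vals))
        else:
            order = np.lexsort(coords.T[::-1])
            peak = tuple(int(v) for v in coords[order[0]])
            peak_stat = 1.0
        entries.append((len(coords), peak, peak_stat, lab))
    entries.sort(key=lambda e: (-e[0], e[1]))

    labels = np.zeros_like(raw)
    clusters = []
    for new_lab, (size, peak, peak_stat, old_lab) in enumerate(entries, start=1):
        labels[raw == old_lab] = new_lab
        clusters.append(Cluster(label=new_lab, size=size, peak=peak, peak_stat=peak_stat))
    return ClusterSet(labels=labels, clusters=tuple(clusters))


def _max_extent(t_map: StatMap, p_peak: float, connectivity: int) -> int:
    binary = threshold_peaks(t_map, p_peak)
    if not binary.any():
        return 0
    raw, n = ndimage.label(binary, structure=_structure(connectivity))
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(binary, raw, index=np.arange(1, n + 1))))


def cluster_extent_threshold(
    per_subject_contrasts,
    p_peak: float = 0.001,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> int:
    """Minimum significant cluster extent from a sign-flipping null.

    Per permutation, each subject's contrast map is multiplied by a
    random sign, the group one-sample t map is rebuilt and thresholded at
    ``p_peak``, and the maximum cluster extent is recorded. The returned
    extent is the smallest integer k with P_null(max extent >= k) <=
    ``alpha``, so keeping clusters of extent >= k controls family-wise
    error at ``alpha``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: extent null is coarse", RuntimeWarning, stacklevel=2)
    vols = [np.asarray(v, float) for v in per_subject_contrasts]
    if len(vols) < 5:
        warnings.warn(
            "fewer than 5 subjects: sign-flip null is very coarse",
            RuntimeWarning,
            stacklevel=2,
        )
    data = np.stack(vols)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=len(vols))
        flipped = data * signs[:, None, None, None]
        null[i] = _max_extent(group_map(list(flipped)), p_peak, connectivity)
    # smallest k with fraction(null >= k) <= alpha
    counts = np.bincount(null)
    tail = np.cumsum(counts[::-1])[::-1]  # tail[k] = #(null >= k)
    ks = np.nonzero(tail <= alpha * n_perm)[0]
    threshold = int(ks[0]) if len(ks) else int(null.max()) + 1
    logger.info("cluster extent threshold: %d voxels (alpha=%.3f)", threshold, alpha)
    return threshold


@dataclass
class ROIEntry:
    name: str
    size: int
    peak: tuple[int, int, int]
    peak_stat: float


@dataclass
class ROISet:
    masks: dict[str, np.ndarray]
    entries: tuple[ROIEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def select_rois(
    clusters: ClusterSet,
    extent_threshold: int = 0,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    label_map: dict[int, str] | None = None,
) -> ROISet:
    """Keep clusters with extent >= max(extent_threshold, min_voxels).

    ROIs are named via ``label_map`` (cluster label -> name) when given,
    else by their peak coordinate.
    """
    cutoff = max(extent_threshold, min_voxels)
    masks: dict[str, np.ndarray] = {}
    entries = []
    for c in clusters.clusters:
        if c.size < cutoff:
            continue
        name = (label_map or {}).get(c.label) or "roi_{}_{}_{}".format(*c.peak)
        masks[name] = clusters.labels == c.label
        entries.append(ROIEntry(name=name, size=c.size, peak=c.peak, peak_stat=c.peak_stat))
    return ROISet(masks=masks, entries=tuple(entries))


def match_rois_to_reference(
    rois: ROISet, reference_masks: dict[str, np.ndarray], min_jaccard: float = 0.1
) -> ROISet:
    """Rename recovered ROIs after the best-overlapping reference mask.

    Each recovered ROI takes the name of the reference mask with the
    highest Jaccard overlap if that overlap reaches ``min_jaccard`` and
    the name is still free; otherwise the coordinate-based name stays.
    """
    taken = set()
    new_masks: dict[str, np.ndarray] = {}
    new_entries = []
    for e in rois.entries:
        mask = rois.masks[e.name]
        best_name, best_j = None, 0.0
        for ref_name, ref in reference_masks.items():
            inter = int(np.logical_and(mask, ref).sum())
            union = int(np.logical_or(mask, ref).sum())
            j = inter / union if union else 0.0
            if j > best_j:
                best_name, best_j = ref_name, j
        name = best_name if (best_name and best_j >= min_jaccard and best_name not in taken) else e.name
        taken.add(name)
        new_masks[name] = mask
        new_entries.append(ROIEntry(name=name, size=e.size, peak=e.peak, peak_stat=e.peak_stat))
    return ROISet(masks=new_masks, entries=tuple(new_entries))
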