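"""Pattern statistics of tight-junction immunostaining.

Three statistics quantify the junctional network of a thresholded image:

* **complexity index** — number of branch points of the skeletonized strand
  network divided by total strand length; a less branched, fragmented
  junction pattern has a lower index;
* **mean object size** — summed connected-component area over component
  count;
* **image entropy** — Shannon entropy of the 256-bin gray-level histogram of
  the *grayscale* image, in bits; a less ordered staining pattern has higher
  entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .errors import NormalizationError, ParameterError
from .image_io import BinaryMask, GrayImage

_NEIGH8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass
class SkeletonMetrics:
    """Length, branch points and complexity of a skeletonized network.

    ``strand_length_px`` weighs orthogonal steps 1 and diagonal steps sqrt(2);
    ``complexity_index`` is NaN (flagged undefined) for an empty skeleton.
    """

    strand_length_px: float
    n_branch_points: int
    complexity_index: float
    branch_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))


@dataclass
class ObjectStats:
    n_objects: int
    total_size_px: int
    mean_object_size: float  # NaN when n_objects == 0


@dataclass
class EntropyResult:
    p: np.ndarray  # relative bin frequencies, sums to 1
    entropy_bits: float


def skeletonize_mask(mask: BinaryMask) -> BinaryMask:
    """One-pixel-wide, topology-preserving thinning of the mask foreground."""
    skel = morphology.skeletonize(mask.pixels)
    prov = dict(mask.provenance)
    prov["skeletonized"] = True
    return BinaryMask(skel, um_per_pixel=mask.um_per_pixel, provenance=prov)


def _crossing_number(px: np.ndarray) -> np.ndarray:
    """0->1 transitions around each pixel's 8-neighbor ring.

    2 for a through pixel, 1 for an endpoint, 0 for an isolated pixel, >= 3
    at a junction.  Unlike a raw neighbor count, this classifies a one-pixel
    corner stub (whose neighbors are consecutive on the ring) as an endpoint.
    """
    p = np.pad(px.astype(np.uint8), 1)
    ring = [
        p[:-2, 1:-1], p[:-2, 2:], p[1:-1, 2:], p[2:, 2:],
        p[2:, 1:-1], p[2:, :-2], p[1:-1, :-2], p[:-2, :-2],
    ]  # N, NE, E, SE, S, SW, W, NW
    cn = np.zeros(px.shape, dtype=np.uint8)
    for i in range(8):
        cn += (ring[i] == 0) & (ring[(i + 1) % 8] == 1)
    return cn


_OFFSETS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def prune_spurs(skel: BinaryMask, min_len: int = 4) -> BinaryMask:
    """Remove terminal branches shorter than ``min_len`` pixels.

    Thinning a dilated strand leaves occasional 1-3 px spurs at junctions and
    line ends that the underlying centerline does not have; removing them
    stabilizes branch-point counts.  Each branch is traced from its endpoint
    (crossing number <= 1, which also catches one-pixel corner stubs) toward
    the network; the branch is deleted only when it reaches a junction pixel
    (or dead-ends as an isolated fragment) within ``min_len`` steps — longer
    arms are left at full length, and loops/through-paths are never broken.
    """
    px = skel.pixels.copy()
    h, w = px.shape
    # deleting a spur can expose a new stub at the junction it hung from,
    # so iterate to a fixpoint (pixel count strictly decreases each pass)
    while True:
        nb = ndimage.convolve(px.astype(np.uint8), _NEIGH8, mode="constant")
        endpoints = np.argwhere(px & (_crossing_number(px) <= 1))
        any_deleted = False
        for (er, ec) in endpoints:
            if not px[er, ec]:
                continue
            path = [(int(er), int(ec))]
            delete = False
            while len(path) <= min_len:
                cr, cc = path[-1]
                cands = [
                    (cr + dr, cc + dc)
                    for dr, dc in _OFFSETS8
                    if 0 <= cr + dr < h and 0 <= cc + dc < w
                    and px[cr + dr, cc + dc] and (cr + dr, cc + dc) not in path
                ]
                if not cands:
                    delete = True  # isolated fragment shorter than min_len
                    break
                if any(nb[r, c] >= 3 for r, c in cands):
                    delete = True  # short spur hanging off a junction
                    break
                if len(cands) > 1:
                    break  # ambiguous (thick) neighborhood: leave untouched
                path.append(cands[0])
            if delete:
                any_deleted = True
                for r, c in path:
                    px[r, c] = False
        if not any_deleted:
            break
    prov = dict(skel.provenance)
    prov["pruned_spurs_px"] = min_len
    return BinaryMask(px, um_per_pixel=skel.um_per_pixel, provenance=prov)


def _skeleton_length(px: np.ndarray, metric: str = "geodesic") -> float:
    """Total path length of a thin skeleton.

    ``geodesic``: each orthogonally adjacent pixel pair contributes 1, each
    diagonal pair sqrt(2); a diagonal pair is skipped when the two pixels
    share an orthogonal skeleton neighbor (the diagonal would double-count
    the corner of a staircase).  ``count``: raw foreground pixel count, for
    strict particle-counter-style reproduction.
    """
    if metric == "count":
        return float(px.sum())
    if metric != "geodesic":
        raise ParameterError(f"unknown length metric {metric!r}")
    horiz = int((px[:, :-1] & px[:, 1:]).sum())
    vert = int((px[:-1, :] & px[1:, :]).sum())
    # down-right diagonals, minus those shortcut by a shared 4-neighbor
    dr = px[:-1, :-1] & px[1:, 1:]
    dr &= ~(px[:-1, 1:] | px[1:, :-1])
    dl = px[:-1, 1:] & px[1:, :-1]
    dl &= ~(px[:-1, :-1] | px[1:, 1:])
    return horiz + vert + np.sqrt(2.0) * (int(dr.sum()) + int(dl.sum()))


def branch_points(px: np.ndarray, merge_radius: float = 4.0) -> np.ndarray:
    """Junction coordinates of a thin skeleton, one per merged cluster.

    A candidate is a skeleton pixel where >= 3 distinct strands meet —
    measured as a crossing number (0->1 transitions around the 8-neighbor
    ring) of at least 3, which, unlike a raw neighbor count, does not fire
    on the corner pixels of a rasterized sharp turn.  Candidate pixels are
    clustered by single linkage at ``merge_radius`` (a rasterized crossing
    can split into two Y-vertices a few pixels apart, and per-pixel counting
    over-counts at thick crossings); each cluster is one junction.  Returns
    an (n, 2) array of (row, col) cluster centroids, rounded.
    """
    px = np.asarray(px, dtype=bool)
    cand = px & (_crossing_number(px) >= 3)
    if not cand.any():
        return np.empty((0, 2), dtype=int)
    coords = np.argwhere(cand).astype(float)
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    parent = list(range(len(coords)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(merge_radius):
        parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(coords)):
        clusters.setdefault(find(i), []).append(i)
    cents = [coords[idx].mean(axis=0) for idx in clusters.values()]
    return np.rint(np.asarray(sorted(map(tuple, cents)))).astype(int)


def skeleton_metrics(skel: BinaryMask, length_metric: str = "geodesic") -> SkeletonMetrics:
    """Strand length, merged branch-point count and complexity index.

    complexity_index = n_branch_points / strand_length_px; NaN when the
    skeleton is empty (flagged undefined rather than raising, so batch runs
    can carry the flag through to the report).
    """
    px = skel.pixels
    length = _skeleton_length(px, length_metric)
    bp = branch_points(px)
    n_bp = len(bp)
    ci = n_bp / length if length > 0 else float("nan")
    return SkeletonMetrics(length, n_bp, ci, bp)


def object_stats(mask: BinaryMask, connectivity: int = 8) -> ObjectStats:
    """Connected-component count, summed area and mean object size (pixels)."""
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = np.ones((3, 3)) if connectivity == 8 else None
    lab, n = ndimage.label(mask.pixels, structure=structure)
    total = int(mask.pixels.sum())
    mean = total / n if n > 0 else float("nan")
    return ObjectStats(n_objects=n, total_size_px=total, mean_object_size=mean)


def image_entropy(img: GrayImage, n_bins: int = 256) -> EntropyResult:
    """Shannon entropy of the gray-level histogram, in bits.

    The [0, 255] intensity range is partitioned into ``n_bins`` equal bins;
    H = -sum_{p>0} p log2 p.  Zero-probability bins contribute 0 (standard
    limit convention).  Computed on the full grayscale image, not a
    thresholded mask.
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    counts, _ = np.histogram(img.pixels, bins=n_bins, range=(0, 256))
    p = counts / counts.sum()
    nz = p[p > 0]
    return EntropyResult(p=p, entropy_bits=float(-(nz * np.log2(nz)).sum() + 0.0))


def percent_of_control(
    table: pd.DataFrame,
    control_group: str,
    value_col: str = "value",
    group_col: str = "group",
) -> pd.DataFrame:
    """Express per-image values as percent of the control group's mean.

    Returns a copy of ``table`` with an added ``value_pct`` column
    (value / control mean x 100); the control group maps to mean 100% by
    construction.  Raises :class:`NormalizationError` if the control group is
    empty or its mean is zero.
    """
    ctl = table.loc[table[group_col] == control_group, value_col]
    if len(ctl) == 0:
        raise NormalizationError(f"control group {control_group!r} is empty")
    ctl_mean = float(ctl.mean())
    if ctl_mean == 0:
        raise NormalizationError(f"control group {control_group!r} has zero mean")
    out = table.copy()
    out["value_pct"] = out[value_col] / ctl_mean * 100.0
    return out
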