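"""Tumor habitat segmentation by scalar k-means and ROI intersection.

Three maps are clustered independently inside the tumor mask: post-contrast
T1w into necrotic / non-enhancing / contrast-enhanced (CE) compartments, mean
diffusivity into low/high MD (LMD/HMD), and NAWM-normalized relative CBV into
low/high perfusion (LrCBV/HrCBV).  Cluster names always bind to ascending
cluster centers, never to the arbitrary k-means labels.  The ten-ROI habitat
catalog is then derived by mask intersection, e.g. the low-diffusivity
low-perfusion habitat inside the CE compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .phantom import SubjectVolumes

#: the ten habitat ROIs, in the order used throughout the package
ROI_NAMES: Tuple[str, ...] = (
    "CE", "non_en", "necrotic", "LMD", "HMD", "LrCBV",
    "LMD_LrCBV_CE", "LMD_LrCBV_nec", "HMD_LrCBV_nec", "En_HrCBV",
)

T1C_ORDERING = ("necrotic", "non_en", "CE")   # ascending T1c intensity
MD_ORDERING = ("LMD", "HMD")                  # ascending mean diffusivity
RCBV_ORDERING = ("LrCBV", "HrCBV")            # ascending relative perfusion


class SegmentationError(RuntimeError):
    """Raised when clustering preconditions are violated."""


@dataclass
class ClusterResult:
    """Labels, ascending centers and within-cluster sum of squares."""

    labels: np.ndarray
    centers: np.ndarray
    inertia: float


@dataclass
class ROICatalog:
    """The ten named habitat masks on one voxel grid."""

    masks: Dict[str, np.ndarray]
    voxel_size: Tuple[float, float, float]

    def validate(self, tumor_mask: np.ndarray) -> None:
        for name in ROI_NAMES:
            if name not in self.masks:
                raise SegmentationError(f"catalog missing ROI {name!r}")
            if self.masks[name].shape != tumor_mask.shape:
                raise SegmentationError(f"ROI {name!r} shape mismatch")
            if np.any(self.masks[name] & ~tumor_mask):
                raise SegmentationError(f"ROI {name!r} leaves the tumor mask")
        n_tumor = int(tumor_mask.sum())
        for parts in (("CE", "non_en", "necrotic"), ("LMD", "HMD")):
            total = sum(int(self.masks[p].sum()) for p in parts)
            if total != n_tumor:
                raise SegmentationError(
                    f"masks {parts} do not partition the tumor")


def normalize_rcbv(cbv_map: np.ndarray, nawm_mask: np.ndarray) -> np.ndarray:
    """Relative CBV: divide by the mean CBV over normal-appearing white
    matter, so the NAWM mean of the output is exactly 1."""
    if cbv_map.shape != nawm_mask.shape:
        raise SegmentationError("CBV map and NAWM mask shapes differ")
    if not nawm_mask.any():
        raise SegmentationError("NAWM mask is empty")
    ref = float(np.mean(cbv_map[nawm_mask]))
    if ref <= 0:
        raise SegmentationError("NAWM mean CBV must be positive")
    return np.asarray(cbv_map, dtype=np.float64) / ref


def _kmeanspp_init(values: np.ndarray, k: int,
                   rng: np.random.Generator) -> np.ndarray:
    centers = np.empty(k)
    centers[0] = values[rng.integers(len(values))]
    d2 = (values - centers[0]) ** 2
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining mass at existing centers: pick any distinct value
            centers[j] = values[rng.integers(len(values))]
            continue
        probs = d2 / total
        centers[j] = values[rng.choice(len(values), p=probs)]
        d2 = np.minimum(d2, (values - centers[j]) ** 2)
    return centers


def _refine_boundaries(sv: np.ndarray, bounds: np.ndarray,
                       max_sweeps: int = 100) -> np.ndarray:
    """Hartigan-style single-point improvement on sorted values.

    In 1-D every Lloyd fixed point assigns sort-contiguous clusters, so the
    solution is fully described by the k-1 boundary indices; moving one
    boundary by one point and accepting strict SSE decreases escapes
    Lloyd-stable local minima at negligible cost.
    """
    pre = np.concatenate([[0.0], np.cumsum(sv)])
    pre2 = np.concatenate([[0.0], np.cumsum(sv ** 2)])

    def sse(i: int, j: int) -> float:
        # half-open [i, j)
        if j <= i:
            return np.inf
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / (j - i)

    edges = np.concatenate([[0], bounds, [len(sv)]])
    for _ in range(max_sweeps):
        improved = False
        for b in range(1, len(edges) - 1):
            lo, mid, hi = edges[b - 1], edges[b], edges[b + 1]
            cur = sse(lo, mid) + sse(mid, hi)
            for cand in (mid - 1, mid + 1):
                if lo < cand < hi:
                    alt = sse(lo, cand) + sse(cand, hi)
                    if alt < cur - 1e-12:
                        edges[b] = cand
                        cur = alt
                        improved = True
        if not improved:
            break
    return edges[1:-1]


def kmeans_scalar(values: Sequence[float], k: int, n_init: int = 10,
                  seed: int = 0, tol: float = 1e-6, max_iter: int = 300,
                  name: str = "values") -> ClusterResult:
    """1-D k-means: Lloyd iterations from k-means++ starts, each restart
    polished by a Hartigan single-point pass, best of ``n_init`` restarts by
    inertia.

    Output labels index the centers *after* sorting them ascending, so label
    ``0`` is always the lowest-intensity cluster.  Center ties are broken by
    cluster size (larger first).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if k < 2:
        raise SegmentationError("k must be >= 2")
    if len(np.unique(v)) < k:
        raise SegmentationError(
            f"{name}: fewer than {k} distinct values, cannot cluster")
    rng = np.random.default_rng(seed)
    sort_idx = np.argsort(v, kind="stable")
    sv = v[sort_idx]
    pre = np.concatenate([[0.0], np.cumsum(sv)])
    pre2 = np.concatenate([[0.0], np.cumsum(sv ** 2)])

    def segment_stats(edges: np.ndarray):
        starts, ends = edges[:-1], edges[1:]
        sums = pre[ends] - pre[starts]
        counts = ends - starts
        centers = sums / counts
        inertia = float(np.sum((pre2[ends] - pre2[starts])
                               - sums ** 2 / counts))
        return centers, inertia

    best_inertia = np.inf
    best_edges = None
    for _ in range(n_init):
        centers = np.sort(_kmeanspp_init(v, k, rng))
        for _ in range(max_iter):
            dist = np.abs(v[:, None] - centers[None, :])
            labels = np.argmin(dist, axis=1)
            new_centers = centers.copy()
            for j in range(k):
                sel = labels == j
                if sel.any():
                    new_centers[j] = v[sel].mean()
                else:  # re-seed an empty cluster at the worst-fit point
                    far = np.argmax(np.abs(v - centers[labels]))
                    new_centers[j] = v[far]
            new_centers = np.sort(new_centers)
            shift = np.max(np.abs(new_centers - centers))
            centers = new_centers
            if shift < tol:
                break
        # contiguous-cluster representation on the sorted values, then a
        # single-point polish
        bounds = np.searchsorted(sv, (centers[:-1] + centers[1:]) / 2.0)
        bounds = _refine_boundaries(sv, bounds)
        edges = np.concatenate([[0], bounds, [len(sv)]])
        if np.any(np.diff(edges) <= 0):
            continue  # degenerate restart (duplicate centers)
        _, inertia = segment_stats(edges)
        if best_edges is None or inertia < best_inertia:
            best_inertia = inertia
            best_edges = edges
    if best_edges is None:  # pragma: no cover - distinct-value guard above
        raise SegmentationError(f"{name}: clustering failed to converge")
    centers, _ = segment_stats(best_edges)
    labels_sorted = np.searchsorted(best_edges[1:-1], np.arange(len(sv)),
                                    side="right")
    labels = np.empty(len(sv), dtype=np.int64)
    labels[sort_idx] = labels_sorted
    return ClusterResult(labels=labels, centers=centers,
                         inertia=best_inertia)


def segment_map(map3d: np.ndarray, tumor_mask: np.ndarray, k: int,
                ordering: Sequence[str], seed: int = 0, n_init: int = 10,
                slicewise: bool = False, name: str = "map",
                ) -> Dict[str, np.ndarray]:
    """Cluster the within-tumor voxels of one map and name the clusters.

    Names in ``ordering`` are assigned to clusters by ascending center (e.g.
    T1c: necrotic < non-enhancing < CE).  ``slicewise=True`` clusters each
    axial slice separately and harmonizes labels by per-slice center ordering;
    slices with too few distinct values fall back to the pooled centers.
    """
    if len(ordering) != k:
        raise SegmentationError("ordering length must equal k")
    if map3d.shape != tumor_mask.shape:
        raise SegmentationError("map and tumor mask shapes differ")
    values = np.asarray(map3d, dtype=np.float64)[tumor_mask]
    pooled = kmeans_scalar(values, k, n_init=n_init, seed=seed, name=name)
    out = {nm: np.zeros(tumor_mask.shape, dtype=bool) for nm in ordering}
    if not slicewise:
        labels_vol = np.full(tumor_mask.shape, -1, dtype=np.int64)
        labels_vol[tumor_mask] = pooled.labels
        for j, nm in enumerate(ordering):
            out[nm] = labels_vol == j
        return out
    rng = np.random.default_rng(seed)
    for z in range(tumor_mask.shape[2]):
        sl = tumor_mask[:, :, z]
        if not sl.any():
            continue
        vals = np.asarray(map3d[:, :, z], dtype=np.float64)[sl]
        try:
            res = kmeans_scalar(vals, k, n_init=n_init,
                                seed=int(rng.integers(2 ** 31 - 1)),
                                name=f"{name}[z={z}]")
            labels = res.labels
        except SegmentationError:
            # thin slice: label by distance to the pooled centers
            labels = np.argmin(np.abs(vals[:, None]
                                      - pooled.centers[None, :]), axis=1)
        for j, nm in enumerate(ordering):
            plane = out[nm][:, :, z]
            plane[sl] = labels == j
            out[nm][:, :, z] = plane
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|); two empty masks count as 1."""
    if a.shape != b.shape:
        raise SegmentationError("dice: mask shapes differ")
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def build_roi_catalog(t1c_masks: Dict[str, np.ndarray],
                      md_masks: Dict[str, np.ndarray],
                      rcbv_masks: Dict[str, np.ndarray],
                      tumor_mask: np.ndarray,
                      voxel_size: Sequence[float]) -> ROICatalog:
    """Derive the ten-ROI habitat catalog by mask intersection.

    Empty intersections are permitted (a warning is emitted); downstream
    feature extraction treats them as missing values.
    """
    for d in (t1c_masks, md_masks, rcbv_masks):
        for nm, m in d.items():
            if m.shape != tumor_mask.shape:
                raise SegmentationError(f"mask {nm!r} shape mismatch")
    ce = t1c_masks["CE"]
    nec = t1c_masks["necrotic"]
    lmd, hmd = md_masks["LMD"], md_masks["HMD"]
    lr = rcbv_masks["LrCBV"]
    masks = {
        "CE": ce,
        "non_en": t1c_masks["non_en"],
        "necrotic": nec,
        "LMD": lmd,
        "HMD": hmd,
        "LrCBV": lr,
        "LMD_LrCBV_CE": lmd & lr & ce,
        "LMD_LrCBV_nec": lmd & lr & nec,
        "HMD_LrCBV_nec": hmd & lr & nec,
        "En_HrCBV": ce & tumor_mask & ~lr,
    }
    catalog = ROICatalog(masks=masks, voxel_size=tuple(voxel_size))
    catalog.validate(tumor_mask)
    empty = [nm for nm in ROI_NAMES if not masks[nm].any()]
    if empty:
        warnings.warn(f"empty habitat ROIs: {', '.join(empty)}",
                      stacklevel=2)
    return catalog


def segment_subject(volumes: SubjectVolumes, seed: int = 0,
                    n_init: int = 10, slicewise: bool = False) -> ROICatalog:
    """Full habitat segmentation of one subject (T1c, MD, rCBV clustering
    plus catalog derivation)."""
    seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=3)
    rcbv = normalize_rcbv(volumes.maps["cbv"], volumes.nawm_mask)
    t1c_masks = segment_map(volumes.maps["t1c"], volumes.tumor_mask, 3,
                            T1C_ORDERING, seed=int(seeds[0]), n_init=n_init,
                            slicewise=slicewise, name="t1c")
    md_masks = segment_map(volumes.maps["md"], volumes.tumor_mask, 2,
                           MD_ORDERING, seed=int(seeds[1]), n_init=n_init,
                           slicewise=slicewise, name="md")
    rcbv_masks = segment_map(rcbv, volumes.tumor_mask, 2, RCBV_ORDERING,
                             seed=int(seeds[2]), n_init=n_init,
                             slicewise=slicewise, name="rcbv")
    return build_roi_catalog(t1c_masks, md_masks, rcbv_masks,
                             volumes.tumor_mask, volumes.voxel_size)
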