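"""Qualitative structure analysis of nanoparticle-enhanced volumes.

Fascicles take up less cationic nanoparticle than the interfascicular matrix
(IFM), so after immersion the IFM is the brightest tissue class.  Per-slice
k=3 clustering of attenuation values separates low / intermediate / high
attenuation groups; the fascicle mask is the tissue minus the highest
(cluster 3) group, and the IFM mask is its complement within the tissue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon
from sklearn.cluster import KMeans

from .cect import _as_mask
from .io import CTVolume, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SegmentationMasks:
    """Tissue / fascicle / IFM label volumes with the ordered cluster means."""

    tissue: np.ndarray
    fascicle: np.ndarray
    ifm: np.ndarray
    cluster_means_HU: np.ndarray
    provenance: str = "clustered"

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=bool)
        self.fascicle = np.asarray(self.fascicle, dtype=bool)
        self.ifm = np.asarray(self.ifm, dtype=bool)
        if np.any(self.fascicle & ~self.tissue) or np.any(self.ifm & ~self.tissue):
            raise ValidationError("fascicle/ifm masks must lie within the tissue")
        if np.any(self.fascicle & self.ifm):
            raise ValidationError("fascicle and ifm masks overlap")
        means = np.asarray(self.cluster_means_HU, dtype=float)
        if means.size > 1 and not np.all(np.diff(means) > 0):
            raise ValidationError("cluster means must be strictly increasing")
        self.cluster_means_HU = means


@dataclass
class RegionStats:
    """First-order intensity statistics of one labeled region."""

    label: str
    mean_HU: float
    sd_HU: float
    voxel_count: int
    sd_undefined: bool = False

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValidationError(f"region {self.label!r} is empty")


# ---------------------------------------------------------------------------
# per-slice clustering
# ---------------------------------------------------------------------------

def cluster_slice(
    slice2d: np.ndarray,
    tissue_mask2d: np.ndarray | None = None,
    *,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means on the attenuation values of one slice, restricted to tissue.

    Returns an integer label image (0 = outside tissue, 1..k ascending by
    cluster mean) and the ordered cluster means.  When the slice holds fewer
    distinct values than ``k`` (but more than one), the effective k is reduced
    and the brightest group keeps the top label so downstream "subtract the
    highest cluster" logic is unaffected; a constant slice is an error.
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    mask = (
        np.ones(slice2d.shape, dtype=bool)
        if tissue_mask2d is None
        else np.asarray(tissue_mask2d, dtype=bool)
    )
    values = slice2d[mask]
    if values.size == 0:
        raise ValidationError("empty tissue mask for this slice")
    uniq = np.unique(values)
    labels_flat = np.empty(values.size, dtype=np.int32)
    if uniq.size == 1:
        raise ValidationError("constant slice: clustering is degenerate")
    if uniq.size < k:
        # exact-valued degenerate slice: group by value, brightest on top
        means = uniq
        for i, v in enumerate(uniq[:-1]):
            labels_flat[values == v] = i + 1
        labels_flat[values == uniq[-1]] = k
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw = km.fit_predict(values.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
        order = np.argsort(centers)
        remap = np.empty(k, dtype=np.int32)
        remap[order] = np.arange(1, k + 1)
        labels_flat = remap[raw]
        means = centers[order]
    labels = np.zeros(slice2d.shape, dtype=np.int32)
    labels[mask] = labels_flat
    return labels, np.asarray(means, dtype=float)


def segment_fascicles(
    volume: CTVolume,
    tissue_mask,
    *,
    seed: int = 0,
    k: int = 3,
    mode: str = "2d",
) -> SegmentationMasks:
    """Separate fascicles from the IFM by per-slice k=3 intensity clustering.

    The fascicle mask is the tissue minus the highest-attenuation cluster
    (the nanoparticle-rich IFM); the IFM mask is the remainder of the tissue.
    ``mode='3d'`` clusters the whole volume at once instead of per slice.
    """
    tissue = _as_mask(tissue_mask)
    data = volume.intensities
    if tissue.shape != data.shape:
        raise ValidationError("tissue mask shape differs from the volume")
    top = np.zeros_like(tissue)
    degenerate: list[int] = []
    n_slices = 0
    sums = np.zeros(k)
    counts = np.zeros(k, dtype=np.int64)

    if mode == "3d":
        labels, means = cluster_slice(data.reshape(1, -1), tissue.reshape(1, -1),
                                      k=k, seed=seed)
        label_vol = labels.reshape(data.shape)
        top = label_vol == k
        for j in range(min(k, means.size)):
            counts[j] = int(np.sum(label_vol == j + 1))
            sums[j] = means[j] * counts[j]
    else:
        for z in range(data.shape[0]):
            if not tissue[z].any():
                continue
            n_slices += 1
            try:
                labels, means = cluster_slice(data[z], tissue[z], k=k, seed=seed)
            except ValidationError:
                degenerate.append(z)
                continue
            top[z] = labels == k
            for j in range(k):
                sel = labels == j + 1
                c = int(sel.sum())
                if c:
                    counts[j] += c
                    sums[j] += float(data[z][sel].sum())
        if n_slices and len(degenerate) == n_slices:
            # a uniform volume has no fascicle/IFM contrast at all: report an
            # empty fascicle mask instead of failing slice-by-slice
            warnings.warn(
                "volume is uniform within the tissue: no fascicle/IFM contrast"
            )
            return SegmentationMasks(
                tissue=tissue,
                fascicle=np.zeros_like(tissue),
                ifm=tissue.copy(),
                cluster_means_HU=np.array([float(data[tissue].mean())]),
                provenance="clustered",
            )
        if n_slices and len(degenerate) > 0.1 * n_slices:
            raise ValidationError(
                f"clustering degenerate on {len(degenerate)}/{n_slices} slices: "
                f"{degenerate}"
            )

    fascicle = tissue & ~top
    ifm = tissue & top
    if not fascicle.any():
        warnings.warn("fascicle mask is empty (volume at uniform IFM-level attenuation)")
    nonzero = counts > 0
    means_all = np.sort(sums[nonzero] / counts[nonzero])
    return SegmentationMasks(
        tissue=tissue,
        fascicle=fascicle,
        ifm=ifm,
        cluster_means_HU=means_all,
        provenance="clustered",
    )


# ---------------------------------------------------------------------------
# region statistics
# ---------------------------------------------------------------------------

def _manual_roi_mask(shape, rois: Sequence[Mapping]) -> dict[str, np.ndarray]:
    """Build per-label masks from manual ROI definitions.

    Each ROI entry is ``{"label": str, "z": int, "rect": [y0, y1, x0, x1]}``
    or ``{"label": str, "z": int, "polygon": [[y, x], ...]}``.
    """
    masks: dict[str, np.ndarray] = {}
    for roi in rois:
        label = roi["label"]
        m = masks.setdefault(label, np.zeros(shape, dtype=bool))
        z = int(roi["z"])
        if "rect" in roi:
            y0, y1, x0, x1 = roi["rect"]
            m[z, y0:y1, x0:x1] = True
        elif "polygon" in roi:
            pts = np.asarray(roi["polygon"], dtype=float)
            rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=shape[1:])
            m[z, rr, cc] = True
        else:
            raise ValidationError(f"ROI for {label!r} needs a 'rect' or 'polygon'")
    return masks


def roi_stats(volume: CTVolume, regions) -> list[RegionStats]:
    """Mean, SD and voxel count per region.

    ``regions`` may be a :class:`SegmentationMasks` (fascicle/ifm/tissue), a
    mapping of label -> boolean mask, or a list of manual ROI definitions
    (per-slice rectangles or polygons, as read from a JSON sidecar).
    """
    if isinstance(regions, SegmentationMasks):
        named = {"fascicle": regions.fascicle, "ifm": regions.ifm,
                 "tissue": regions.tissue}
    elif isinstance(regions, Mapping):
        named = {str(kk): _as_mask(v) for kk, v in regions.items()}
    else:
        named = _manual_roi_mask(volume.intensities.shape, regions)
    out = []
    for label, mask in named.items():
        n = int(mask.sum())
        if n == 0:
            raise ValidationError(f"region {label!r} is empty")
        vals = volume.intensities[mask].astype(np.float64)
        out.append(
            RegionStats(
                label=label,
                mean_HU=float(vals.mean()),
                sd_HU=float(vals.std(ddof=1)) if n > 1 else float("nan"),
                voxel_count=n,
                sd_undefined=n < 2,
            )
        )
    return out


def region_contrast(
    stats_fascicle: RegionStats, stats_ifm: RegionStats
) -> tuple[float, float]:
    """IFM-to-fascicle attenuation contrast: (difference HU, ratio)."""
    if stats_fascicle.mean_HU <= 0:
        raise ValidationError("fascicle mean must be > 0 for a ratio")
    diff = stats_ifm.mean_HU - stats_fascicle.mean_HU
    return diff, stats_ifm.mean_HU / stats_fascicle.mean_HU


__all__ = [
    "RegionStats",
    "SegmentationMasks",
    "cluster_slice",
    "region_contrast",
    "roi_stats",
    "segment_fascicles",
]
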