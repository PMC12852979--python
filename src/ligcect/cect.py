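"""Quantitative contrast-enhanced CT.

Hounsfield-unit calibration against water/air reference ROIs, k=2 intensity
segmentation of the sample from the background, bulk contrast-agent partition
versus immersion time, and the two-parameter first-order uptake fit

    Partition(t) = Pmax * (1 - exp(-t / tau)),

where ``Pmax`` is the equilibrium partition (tissue attenuation gain
normalized to the bath, so 1.0 means bath concentration) and ``tau`` is the
diffusion time constant — the time to reach 63.2% of equilibrium.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans

from .io import CTVolume, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DiffusionSeries:
    """Bulk partition (fraction of bath concentration) per immersion hour.

    Partition may exceed 1 for charge-attracted agents that accumulate above
    bath concentration.
    """

    timepoints_h: np.ndarray
    partition: np.ndarray
    agent: str = "none"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.partition = np.asarray(self.partition, dtype=float)
        if self.timepoints_h.shape != self.partition.shape:
            raise ValidationError("timepoints and partition must align")
        if self.timepoints_h.size and (
            np.any(self.timepoints_h <= 0)
            or np.any(np.diff(self.timepoints_h) <= 0)
        ):
            raise ValidationError("timepoints must be strictly increasing and > 0")
        if not np.all(np.isfinite(self.partition)):
            raise ValidationError("partition values must be finite")


@dataclass
class PartitionFit:
    """Result of the first-order uptake fit."""

    Pmax: float
    tau_h: float
    rmse: float
    n_points: int

    def __post_init__(self) -> None:
        if not (self.Pmax > 0 and self.tau_h > 0):
            raise ValidationError("Pmax and tau must be > 0")

    def __call__(self, t_h):
        return uptake_model(np.asarray(t_h, dtype=float), self.Pmax, self.tau_h)


@dataclass
class TissueSegmentation:
    """Tissue mask with the clustering parameters that produced it."""

    mask: np.ndarray
    threshold: float
    seed: int

    def __array__(self, dtype=None):
        return self.mask.astype(dtype) if dtype else self.mask


def uptake_model(t, pmax, tau):
    return pmax * (1.0 - np.exp(-t / tau))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def hu_calibrate(volume: CTVolume) -> CTVolume:
    """Linearly rescale intensities so water -> 0 HU and air -> -1000 HU.

    ``bath_hu`` metadata is assumed to already be expressed in HU and is left
    untouched.
    """
    if volume.water_roi is None or not volume.water_roi.any():
        raise ValidationError("hu_calibrate requires a non-empty water_roi")
    if volume.air_roi is None or not volume.air_roi.any():
        raise ValidationError("hu_calibrate requires a non-empty air_roi")
    w = float(volume.intensities[volume.water_roi].mean())
    a = float(volume.intensities[volume.air_roi].mean())
    if abs(w - a) < 1e-12:
        raise ValidationError("degenerate calibration: water and air means equal")
    scale = 1000.0 / (w - a)
    hu = (volume.intensities.astype(np.float64) - w) * scale
    logger.info("HU calibration: raw water %.3f, air %.3f (scale %.5f)", w, a, scale)
    return replace(volume, intensities=hu.astype(np.float32), calibrated=True)


# ---------------------------------------------------------------------------
# tissue segmentation (k = 2)
# ---------------------------------------------------------------------------

def _disk_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erosion by a Euclidean disk of the given radius (EDT formulation)."""
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(mask) > radius


def _disk_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    if mask.all():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def _disk_close(mask, radius):
    return _disk_erode(_disk_dilate(mask, radius), radius)


def _disk_open(mask, radius):
    return _disk_dilate(_disk_erode(mask, radius), radius)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area
    keep[0] = False
    return keep[lab]


def kmeans_1d(values: np.ndarray, k: int, seed: int, n_init: int = 10,
              max_points: int = 100_000) -> np.ndarray:
    """k-means on scalar intensities; returns cluster centers sorted ascending.

    Fitting runs on a deterministic subsample for large inputs; assignment of
    the full data is by nearest center, which in 1-D reduces to thresholding
    at center midpoints.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < k:
        raise ValidationError(f"fewer than k={k} distinct intensity values")
    if values.size > max_points:
        rng = np.random.default_rng(seed)
        values_fit = rng.choice(values, size=max_points, replace=False)
        # guard: subsample must still expose k distinct values
        if np.unique(values_fit).size < k:
            values_fit = values
    else:
        values_fit = values
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(values_fit.reshape(-1, 1))
    return np.sort(km.cluster_centers_.ravel())


def segment_tissue(
    volume: CTVolume,
    *,
    seed: int = 0,
    smoothing_radius: int = 10,
    shrink_px: int = 10,
    min_area_px: int = 2000,
    keep_largest: bool = True,
) -> TissueSegmentation:
    """Segment the sample from background by k=2 intensity clustering.

    The volume-wide clustering is followed by per-slice cleanup: morphological
    closing then opening with a Euclidean disk (``smoothing_radius`` px),
    boundary shrink by ``shrink_px`` px, and removal of connected areas under
    ``min_area_px`` px.  Finally the largest 3D connected component is kept,
    which drops the water calibration tube.
    """
    data = volume.intensities
    centers = kmeans_1d(data, k=2, seed=seed)
    threshold = float(centers.mean())
    mask3d = data > threshold  # tissue = higher-mean cluster

    # guard against a volume with no real foreground: splitting a single
    # noise population yields clusters whose separation is comparable to
    # their internal spread, unlike genuine tissue against air
    lo, hi = data[~mask3d], data[mask3d]
    pooled_sd = float(np.sqrt((lo.var() * lo.size + hi.var() * hi.size)
                              / max(lo.size + hi.size, 1)))
    if centers[1] - centers[0] < 4.0 * max(pooled_sd, 1e-12):
        raise ValidationError(
            "no tissue/background intensity contrast: tissue mask empty"
        )

    out = np.zeros_like(mask3d)
    for z in range(mask3d.shape[0]):
        sl = mask3d[z]
        if not sl.any():
            continue
        sl = _disk_open(_disk_close(sl, smoothing_radius), smoothing_radius)
        if shrink_px:
            sl = _disk_erode(sl, shrink_px)
        sl = _remove_small(sl, min_area_px)
        out[z] = sl

    if keep_largest and out.any():
        lab, n = ndimage.label(out)
        if n > 1:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            out = lab == int(np.argmax(sizes))
    if not out.any():
        raise ValidationError("tissue mask empty after filtering")
    return TissueSegmentation(mask=out, threshold=threshold, seed=seed)


def _as_mask(m) -> np.ndarray:
    if isinstance(m, TissueSegmentation):
        return m.mask
    return np.asarray(m, dtype=bool)


# ---------------------------------------------------------------------------
# bulk partition and uptake kinetics
# ---------------------------------------------------------------------------

def bulk_partition(
    native: CTVolume,
    series: Sequence[CTVolume],
    masks,
    *,
    bath_hu: float | None = None,
    subtract_native: bool = True,
) -> DiffusionSeries:
    """Bulk partition per timepoint.

    ``partition(t) = (mean_HU_tissue(t) - mean_HU_tissue(native)) / bath_hu``
    with post-calibration water at 0 HU so the bath value is already the
    attenuation above water.  ``masks`` is either one mask applied to every
    volume or a sequence ``[native_mask, mask(t1), mask(t2), ...]``.
    """
    series = sorted(series, key=lambda v: v.timepoint_h)
    if bath_hu is None:
        bath_hu = next(
            (v.bath_hu for v in [native, *series] if v.bath_hu is not None), None
        )
    if bath_hu is None or bath_hu <= 0:
        raise ValidationError(f"bath_hu must be > 0, got {bath_hu!r}")
    if isinstance(masks, (np.ndarray, TissueSegmentation)):
        mask_list = [_as_mask(masks)] * (len(series) + 1)
    else:
        mask_list = [_as_mask(m) for m in masks]
        if len(mask_list) != len(series) + 1:
            raise ValidationError("need one mask for the native scan plus one per timepoint")
    for v in [native, *series]:
        if not v.calibrated:
            raise ValidationError("all volumes must be HU-calibrated")
    mu_native = native.roi_mean(mask_list[0]) if subtract_native else 0.0
    timepoints = np.array([v.timepoint_h for v in series], dtype=float)
    partition = np.array(
        [
            (v.roi_mean(m) - mu_native) / bath_hu
            for v, m in zip(series, mask_list[1:])
        ]
    )
    return DiffusionSeries(
        timepoints_h=timepoints,
        partition=partition,
        agent=series[0].agent if series else "none",
        sample_id=native.sample_id,
    )


def fit_uptake(series: DiffusionSeries) -> PartitionFit:
    """Nonlinear least-squares fit of ``Pmax * (1 - exp(-t/tau))``.

    Initialized at ``Pmax0`` = last observed partition and ``tau0`` = the
    interpolated time at which partition first reaches 63.2% of ``Pmax0``;
    multi-start over a tau grid guards against poor initialization.
    """
    t = series.timepoints_h
    y = series.partition
    if t.size < 3:
        raise ValidationError(f"need >= 3 timepoints, got {t.size}")
    p0_max = float(y[-1]) if y[-1] > 0 else float(max(y.max(), 1e-6))
    target = 0.632 * p0_max
    above = np.nonzero(y >= target)[0]
    if above.size and above[0] > 0:
        i = above[0]
        frac = (target - y[i - 1]) / (y[i] - y[i - 1])
        tau0 = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    elif above.size:
        tau0 = float(t[0])
    else:
        tau0 = float(t[-1])
    tau0 = max(tau0, float(t[0]) * 1e-2)

    best = None
    tried = []
    for tau_start in (tau0, tau0 * 0.3, tau0 * 3.0, float(np.median(t))):
        tried.append(tau_start)
        try:
            popt, _ = curve_fit(
                uptake_model,
                t,
                y,
                p0=[max(p0_max, 1e-6), tau_start],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((uptake_model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise ValidationError(
            f"uptake fit failed to converge (tau starts tried: {tried})"
        )
    sse, (pmax, tau) = best
    return PartitionFit(
        Pmax=float(pmax),
        tau_h=float(tau),
        rmse=float(np.sqrt(sse / t.size)),
        n_points=int(t.size),
    )


def dilution_error(partition: float, bath_to_sample_volume_ratio: float = 100.0) -> float:
    """Worst-case relative bath depletion from tissue uptake (mass balance).

    With the bath at ``ratio`` times the sample volume, equilibrium uptake of
    ``partition`` bath-equivalents of solute depletes the bath concentration
    by at most ``partition / ratio``.
    """
    if bath_to_sample_volume_ratio <= 0:
        raise ValidationError("volume ratio must be > 0")
    return float(partition) / float(bath_to_sample_volume_ratio)


__all__ = [
    "DiffusionSeries",
    "PartitionFit",
    "TissueSegmentation",
    "bulk_partition",
    "dilution_error",
    "fit_uptake",
    "hu_calibrate",
    "kmeans_1d",
    "segment_tissue",
    "uptake_model",
]
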