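"""Longitudinal voxel-differencing bone remodelling.

Two registered, segmented timepoints are compared voxel by voxel: bone
voxels present only in the older dataset are resorption, voxels present
only in the newer dataset are formation, and each is expressed as a
fraction of the union (common + unique voxels). Metric time series are
reported as percent change from the immediately preceding timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volcore import (
    DensityVolume,
    TRABECULAR_THRESHOLD,
    VOISpec,
    register_rigid,
    resolve_voi,
    segment,
)

__all__ = ["RemodelResult", "ChangeSeries", "remodel_fractions", "remodel_pipeline", "percent_change"]


@dataclass
class RemodelResult:
    n_common: int
    n_unique_old: int
    n_unique_new: int
    resorption_fraction: float
    formation_fraction: float

    @property
    def n_union(self) -> int:
        return self.n_common + self.n_unique_old + self.n_unique_new

    def to_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "n_unique_old": self.n_unique_old,
            "n_unique_new": self.n_unique_new,
            "resorption_fraction": self.resorption_fraction,
            "formation_fraction": self.formation_fraction,
        }


@dataclass
class ChangeSeries:
    labels: list
    values: np.ndarray
    percent_change: np.ndarray  # vs previous timepoint; length len(values)-1


def remodel_fractions(mask_old: np.ndarray, mask_new: np.ndarray,
                      region: np.ndarray | None = None) -> RemodelResult:
    """Formation/resorption fractions from two registered binary masks.

    Resorption counts voxels in old-but-not-new, formation voxels in
    new-but-not-old; each is divided by the size of the union. An optional
    ``region`` mask restricts the count to voxels imaged in both scans.
    """
    mask_old = np.asarray(mask_old, dtype=bool)
    mask_new = np.asarray(mask_new, dtype=bool)
    if mask_old.shape != mask_new.shape:
        raise ValueError("mask shapes differ; masks must share a common grid")
    if region is not None:
        if region.shape != mask_old.shape:
            raise ValueError("region shape differs from mask shape")
        mask_old = mask_old & region
        mask_new = mask_new & region
    n_common = int(np.count_nonzero(mask_old & mask_new))
    n_old_only = int(np.count_nonzero(mask_old & ~mask_new))
    n_new_only = int(np.count_nonzero(mask_new & ~mask_old))
    union = n_common + n_old_only + n_new_only
    if union == 0:
        raise ValueError("empty union: neither mask contains bone")
    return RemodelResult(
        n_common=n_common,
        n_unique_old=n_old_only,
        n_unique_new=n_new_only,
        resorption_fraction=n_old_only / union,
        formation_fraction=n_new_only / union,
    )


def remodel_pipeline(
    vol_old: DensityVolume,
    vol_new: DensityVolume,
    voi: VOISpec | None = None,
    threshold: float = TRABECULAR_THRESHOLD,
    register: bool = True,
) -> tuple[RemodelResult, dict]:
    """Full longitudinal stage: register the newer scan onto the older grid,
    resolve the VOI on both, segment at the global threshold and difference.

    Set ``register=False`` for pre-registered pairs. Returns the result and a
    log dict with the transform used.
    """
    import scipy.ndimage as ndi

    from .volcore import _resample

    log: dict = {"threshold": threshold}
    region = None
    if register:
        transform, resampled = register_rigid(vol_new, vol_old)
        log["transform"] = transform.to_dict()
        # only voxels imaged in both scans are comparable: exclude the part of
        # the fixed grid that maps outside the moving scan's field of view
        # (with a small safety erosion at the seam)
        sentinel = _resample(
            np.zeros(vol_new.shape), transform, vol_new.voxel_size_um,
            vol_old.shape, order=0, cval=np.nan,
        )
        region = ndi.binary_erosion(np.isfinite(sentinel), iterations=2)
        vol_new = resampled
    if voi is not None:
        rng_old, vol_old = resolve_voi(vol_old, voi)
        rng_new, vol_new = resolve_voi(vol_new, voi)
        if region is not None:
            region = region[rng_old[0]:rng_old[1]]
        log["voi_range"] = rng_old
    result = remodel_fractions(
        segment(vol_old, threshold), segment(vol_new, threshold), region
    )
    return result, log


def percent_change(values, labels=None) -> ChangeSeries:
    """Percent change of each timepoint versus the immediately preceding one
    (not versus baseline)."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least two timepoints")
    prev = values[:-1]
    if np.any(prev == 0):
        raise ValueError("zero value at a previous timepoint; percent change undefined")
    pct = 100.0 * (values[1:] - prev) / prev
    if labels is None:
        labels = list(range(len(values)))
    return ChangeSeries(labels=list(labels), values=values, percent_change=pct)
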