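"""Shared volume infrastructure: calibrated density volumes, segmentation,
rigid registration and volume-of-interest selection.

All volumes are 3D scalar grids with isotropic voxels, axis order ``(z, y, x)``
with ``z`` the scan axis. Density calibration is always an affine map of raw
gray values, anchored either on two hydroxyapatite phantoms (mg/cm^3 HA) or on
air/water standards (Hounsfield units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityVolume",
    "RigidTransform",
    "VOISpec",
    "calibrate_density",
    "hu_calibrate",
    "segment",
    "register_rigid",
    "resolve_voi",
    "round_half_away",
]

# calibration tags
CAL_RAW = "raw"
CAL_HA = "HA"  # mg/cm^3 hydroxyapatite
CAL_HU = "HU"  # Hounsfield units

#: default global segmentation thresholds (mg/cm^3 HA)
TRABECULAR_THRESHOLD = 300.0
CORTICAL_THRESHOLD = 700.0


@dataclass
class DensityVolume:
    """A 3D scalar field with voxel size and density calibration.

    Parameters
    ----------
    values
        3D array, axis order (z, y, x).
    voxel_size_um
        Isotropic voxel edge length in micrometres.
    calibration
        One of ``"raw"``, ``"HA"`` (mg/cm^3 hydroxyapatite) or ``"HU"``.
    meta
        Free-form metadata (landmark slices, phantom patch locations, ...).
    """

    values: np.ndarray
    voxel_size_um: float
    calibration: str = CAL_RAW
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("values must be a non-empty 3D array (z, y, x)")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.calibration not in (CAL_RAW, CAL_HA, CAL_HU):
            raise ValueError(f"unknown calibration {self.calibration!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def with_values(self, values: np.ndarray, calibration: str | None = None) -> "DensityVolume":
        return replace(
            self,
            values=values,
            calibration=self.calibration if calibration is None else calibration,
            meta=dict(self.meta),
        )


def calibrate_density(
    raw: DensityVolume,
    phantom_low: tuple[float, float],
    phantom_high: tuple[float, float],
) -> DensityVolume:
    """Affine two-point hydroxyapatite calibration.

    ``phantom_low``/``phantom_high`` are ``(raw_value, density_mg_cm3)`` pairs,
    conventionally the 250 and 750 mg/cm^3 HA rods. The map sends the two raw
    anchors exactly onto their densities and is applied voxelwise.
    """
    raw_lo, dens_lo = phantom_low
    raw_hi, dens_hi = phantom_high
    if raw_hi <= raw_lo:
        raise ValueError("phantom_high raw value must exceed phantom_low raw value")
    slope = (dens_hi - dens_lo) / (raw_hi - raw_lo)
    out = dens_lo + slope * (raw.values.astype(np.float64) - raw_lo)
    vol = raw.with_values(out, calibration=CAL_HA)
    vol.meta["calibration_map"] = {"slope": slope, "intercept": dens_lo - slope * raw_lo}
    return vol


def hu_calibrate(raw: DensityVolume, air_mean: float, water_mean: float) -> DensityVolume:
    """Linear Hounsfield calibration from scanned air/water standards.

    Air maps to -1000 HU, water to 0 HU.
    """
    if air_mean >= water_mean:
        raise ValueError("air_mean must be below water_mean")
    hu = 1000.0 * (raw.values.astype(np.float64) - water_mean) / (water_mean - air_mean)
    vol = raw.with_values(hu, calibration=CAL_HU)
    vol.meta["hu_map"] = {"air_mean": air_mean, "water_mean": water_mean}
    return vol


def segment(volume: DensityVolume, threshold: float = TRABECULAR_THRESHOLD) -> np.ndarray:
    """Global-threshold bone segmentation of an HA-calibrated volume.

    Returns a boolean mask ``density >= threshold``. The 300 mg/cm^3
    (trabecular) and 700 mg/cm^3 (cortical) thresholds are module defaults.
    """
    if volume.calibration != CAL_HA:
        raise ValueError(
            "segment expects an HA-calibrated volume "
            f"(got calibration={volume.calibration!r})"
        )
    return volume.values >= threshold


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Rigid transform: intrinsic rotations about z, y, x (degrees) followed by
    a translation (micrometres, (z, y, x) order), about the fixed-grid centre.

    The transform maps fixed-grid physical coordinates to moving-volume
    coordinates (pull-back convention used for resampling).
    """

    angles_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def rotation_matrix(self) -> np.ndarray:
        # scipy "zyx" intrinsic Euler; our axes are already (z, y, x) ordered,
        # so build the matrix in (x, y, z) space then permute.
        rot = Rotation.from_euler("ZYX", self.angles_deg, degrees=True).as_matrix()
        perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)  # zyx <-> xyz
        return perm @ rot @ perm.T

    def inverse(self) -> "RigidTransform":
        rot = Rotation.from_euler("ZYX", self.angles_deg, degrees=True)
        inv = rot.inv()
        angles = tuple(inv.as_euler("ZYX", degrees=True))
        rmat_inv = self.rotation_matrix().T
        t = np.asarray(self.translation_um, dtype=float)
        t_inv = tuple(-(rmat_inv @ t))
        return RigidTransform(angles, t_inv)

    def params(self) -> np.ndarray:
        return np.concatenate([self.angles_deg, self.translation_um])

    def to_dict(self) -> dict:
        return {
            "angles_deg": list(map(float, self.angles_deg)),
            "translation_um": list(map(float, self.translation_um)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["angles_deg"]), tuple(d["translation_um"]))


def _resample(
    moving: np.ndarray,
    transform: RigidTransform,
    voxel_size_um: float,
    out_shape: tuple[int, int, int],
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``moving`` onto the fixed grid under ``transform``.

    For each fixed-grid voxel x_f (in voxels), the source coordinate is
    ``R @ (x_f - c) + c + t`` with c the fixed-grid centre and t the
    translation in voxels.
    """
    rmat = transform.rotation_matrix()
    centre = (np.asarray(out_shape, dtype=float) - 1.0) / 2.0
    t_vox = np.asarray(transform.translation_um, dtype=float) / voxel_size_um
    offset = centre + t_vox - rmat @ centre
    return ndimage.affine_transform(
        moving.astype(np.float64), rmat, offset=offset,
        output_shape=out_shape, order=order, cval=cval,
    )


def apply_transform(moving: DensityVolume, transform: RigidTransform,
                    out_shape: tuple[int, int, int] | None = None,
                    order: int = 3) -> DensityVolume:
    """Resample a volume under a rigid transform (cubic spline by default)."""
    shape = moving.shape if out_shape is None else out_shape
    vals = _resample(moving.values, transform, moving.voxel_size_um, shape, order=order)
    return moving.with_values(vals)


def _ncc(a: np.ndarray, b: np.ndarray, valid: np.ndarray | None = None) -> float:
    if valid is not None:
        a = a[valid]
        b = b[valid]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a.ravel(), b.ravel()) / denom)


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid, eigenvalues (desc) and eigenvectors (columns) of the mask."""
    coords = np.argwhere(mask).astype(np.float64)
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return centroid, evals[order], evecs[:, order]


def register_rigid(
    moving: DensityVolume,
    fixed: DensityVolume,
    threshold: float | None = None,
    refine: bool = True,
) -> tuple[RigidTransform, DensityVolume]:
    """Two-stage rigid registration of ``moving`` onto ``fixed``.

    Stage 1 aligns the centroid (and, when the structure is clearly
    anisotropic, the principal axes) of the thresholded structure. Stage 2
    refines the six rigid parameters by maximising normalized
    cross-correlation (NCC) of the calibrated gray values with a local Powell
    search. If refinement does not improve NCC a warning is issued and the
    stage-1 result is returned.

    Returns the transform (fixed -> moving pull-back) and the moving volume
    resampled onto the fixed grid.
    """
    if moving.voxel_size_um != fixed.voxel_size_um:
        raise ValueError("register_rigid requires equal voxel sizes")
    vsz = fixed.voxel_size_um
    if threshold is None:
        lo = min(moving.values.min(), fixed.values.min())
        hi = max(moving.values.max(), fixed.values.max())
        threshold = 0.5 * (lo + hi)
    mask_m = moving.values >= threshold
    mask_f = fixed.values >= threshold
    if not mask_m.any() or not mask_f.any():
        raise ValueError("empty threshold mask; cannot register")

    cen_m, ev_m, vec_m = _principal_axes(mask_m)
    cen_f, ev_f, vec_f = _principal_axes(mask_f)

    centre = (np.asarray(fixed.shape, dtype=float) - 1.0) / 2.0
    rmat0 = np.eye(3)
    # Only trust principal axes when all eigenvalue gaps are clear (>5%).
    gaps_ok = np.all(np.diff(ev_f[::-1]) / np.maximum(ev_f[1:][::-1], 1e-12) > 0.05) and np.all(
        np.diff(ev_m[::-1]) / np.maximum(ev_m[1:][::-1], 1e-12) > 0.05
    )
    if gaps_ok:
        # choose axis signs closest to identity rotation
        vm = vec_m.copy()
        for k in range(3):
            if np.dot(vm[:, k], vec_f[:, k]) < 0:
                vm[:, k] = -vm[:, k]
        cand = vm @ vec_f.T  # maps fixed-frame directions into moving frame
        if np.linalg.det(cand) < 0:
            cand[:, 2] = -cand[:, 2]
        rmat0 = cand
    # translation such that R(c_f - centre) + centre + t = c_m
    t0 = cen_m - (rmat0 @ (cen_f - centre) + centre)

    def params_to_tf(p: np.ndarray) -> RigidTransform:
        return RigidTransform(tuple(p[:3]), tuple(np.asarray(p[3:]) * vsz))

    def tf_angles(rmat: np.ndarray) -> tuple[float, float, float]:
        perm = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
        return tuple(Rotation.from_matrix(perm @ rmat @ perm.T).as_euler("ZYX", degrees=True))

    tf1 = RigidTransform(tf_angles(rmat0), tuple(np.asarray(t0) * vsz))

    # NCC is scored on lightly presmoothed gray values over a fixed interior
    # core. Smoothing removes the interpolation-blur bias (an unsmoothed NCC
    # prefers net transforms snapped toward integer voxel shifts); the fixed
    # core keeps the compared voxel set independent of the trial transform.
    sm_fixed = ndimage.gaussian_filter(fixed.values.astype(np.float64), 1.0)
    sm_moving = ndimage.gaussian_filter(moving.values.astype(np.float64), 1.0)
    margin = max(4, int(round(0.15 * min(fixed.shape))))
    core = tuple(slice(margin, s - margin) for s in fixed.shape)
    fixed_core = sm_fixed[core]

    def score(p: np.ndarray) -> float:
        tf = params_to_tf(p)
        res = _resample(sm_moving, tf, vsz, fixed.shape, cval=np.nan)[core]
        valid = np.isfinite(res)
        if valid.sum() < 0.5 * valid.size:
            return 1.0
        return -_ncc(fixed_core, res, valid)

    p1 = tf1.params()
    p1[3:] /= vsz  # optimise translations in voxels
    best_p = p1
    if refine:
        res = optimize.minimize(
            score, p1, method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-10, "maxiter": 8000},
        )
        if score(res.x) <= score(p1):
            best_p = res.x
        else:  # pragma: no cover - optimizer regression guard
            warnings.warn("rigid refinement did not improve NCC; keeping stage-1 result")
    tf = params_to_tf(best_p)
    resampled = moving.with_values(_resample(moving.values, tf, vsz, fixed.shape, order=3))
    return tf, resampled


# ---------------------------------------------------------------------------
# VOI selection
# ---------------------------------------------------------------------------


def round_half_away(x: float) -> int:
    """Round half away from zero (the module-wide mm -> voxel convention)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class VOISpec:
    """Volume of interest relative to an anatomical landmark slice.

    ``offset_mm`` is measured from ``reference_slice`` along ``direction``
    (+1 = increasing z = distal/"below the growth plate" by convention).
    If ``centered`` the window of ``extent_mm`` is centred at the offset,
    otherwise it starts there.
    """

    reference_slice: int
    offset_mm: float
    extent_mm: float
    direction: int = 1
    centered: bool = False

    def __post_init__(self) -> None:
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def resolve_voi(volume: DensityVolume, spec: VOISpec) -> tuple[tuple[int, int], DensityVolume]:
    """Resolve a VOI spec to a half-open slice range and crop the volume.

    mm quantities are converted to whole slices by rounding half away from
    zero; the returned range is half-open ``[start, stop)``.
    """
    vox_mm = volume.voxel_size_mm
    offset_vox = round_half_away(spec.offset_mm / vox_mm)
    extent_vox = round_half_away(spec.extent_mm / vox_mm)
    if spec.centered:
        centre = spec.reference_slice + spec.direction * offset_vox
        start = centre - extent_vox // 2
        stop = start + extent_vox
    elif spec.direction == 1:
        start = spec.reference_slice + offset_vox
        stop = start + extent_vox
    else:
        stop = spec.reference_slice - offset_vox
        start = stop - extent_vox
    nz = volume.shape[0]
    if start < 0 or stop > nz or start >= stop:
        raise ValueError(f"VOI slice range [{start}, {stop}) exits volume of {nz} slices")
    cropped = volume.with_values(volume.values[start:stop])
    cropped.meta["voi_range"] = (start, stop)
    return (start, stop), cropped
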