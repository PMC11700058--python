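"""Synthetic phantoms with known ground truth.

Every downstream stage of the pipeline is exercised on inputs generated
here: Gaussian-random-field trabecular phantoms with a prescribed bone
volume fraction, surface-remodelled second timepoints with exactly counted
formation/resorption voxels, annular cortical phantoms with closed-form
areas and section modulus, an abdomen phantom with air/water standards and
a known adipose fraction, bone Raman spectra built from named bands, and
piecewise-linear bending curves with analytic stiffness/yield/work.

All generators are pure functions of their arguments including the seed:
one seeded ``numpy.random.Generator`` per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .biomech import LoadDisplacementCurve
from .raman import RamanParams, Spectrum
from .volcore import CAL_HA, CAL_RAW, DensityVolume

__all__ = [
    "PhantomTruth",
    "make_trabecular_phantom",
    "evolve_phantom",
    "make_cortical_phantom",
    "make_plate_phantom",
    "make_abdomen_phantom",
    "make_raman_spectrum",
    "pmma_reference",
    "default_bands",
    "make_load_curve",
]

# trabecular phantom material densities (mg/cm^3 HA). Bone sits above the
# 300 mg/cm^3 trabecular threshold and the threshold is the exact midpoint of
# the two levels, so linear resampling during registration does not bias the
# segmented boundary.
BONE_DENSITY = 600.0
BACKGROUND_DENSITY = 0.0

# abdomen phantom raw gray levels; HU = 10*(raw - 110) by construction
RAW_AIR = 10.0
RAW_WATER = 110.0
RAW_ADIPOSE = 90.0  # -> -200 HU, inside the adipose window
RAW_LEAN = 114.0  # -> +40 HU


@dataclass
class PhantomTruth:
    """Ground truth recorded at generation time."""

    seed: int | None = None
    formation_fraction: float | None = None
    resorption_fraction: float | None = None
    true_bvtv: float | None = None
    true_thickness_um: float | None = None
    adipose_fraction: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("formation_fraction", "resorption_fraction", "adipose_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        f, r = self.formation_fraction, self.resorption_fraction
        if f is not None and r is not None and f + r > 1.0 + 1e-12:
            raise ValueError("formation + resorption fractions exceed 1")


# ---------------------------------------------------------------------------
# trabecular phantom and its evolution
# ---------------------------------------------------------------------------


def make_trabecular_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_um: float = 18.0,
    target_bvtv: float = 0.25,
    seed: int = 0,
    correlation_length: float = 5.0,
) -> tuple[DensityVolume, PhantomTruth]:
    """Gaussian-random-field trabecular phantom at a prescribed BV/TV.

    A white-noise field is smoothed at ``correlation_length`` voxels and
    thresholded at the exact quantile that realises ``target_bvtv``; bone
    voxels get ``BONE_DENSITY`` and background ``BACKGROUND_DENSITY``.
    """
    if not 0.0 < target_bvtv <= 1.0:
        raise ValueError("target_bvtv must lie in (0, 1]")
    if min(shape) < 32:
        raise ValueError("phantom must be at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    if target_bvtv == 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), correlation_length / 2.0)
        thr = np.quantile(f, 1.0 - target_bvtv)
        mask = f >= thr
    realized = float(mask.mean())
    if abs(realized - target_bvtv) > 0.02:
        raise RuntimeError(
            f"threshold search could not reach BV/TV {target_bvtv} (got {realized:.3f})"
        )
    values = np.where(mask, BONE_DENSITY, BACKGROUND_DENSITY)
    vol = DensityVolume(values, voxel_size_um, CAL_HA)
    return vol, PhantomTruth(seed=seed, true_bvtv=realized)


def _bone_mask(volume: DensityVolume) -> np.ndarray:
    return volume.values >= 0.5 * (BONE_DENSITY + BACKGROUND_DENSITY)


def evolve_phantom(
    volume: DensityVolume,
    formation_fraction: float,
    resorption_fraction: float,
    seed: int = 0,
) -> tuple[DensityVolume, PhantomTruth]:
    """Second timepoint by surface remodelling with exactly counted voxels.

    Bone is removed from the surface of the old structure and new bone is
    accreted on the surface of what remains, such that relative to the union
    of the two masks, unique-new/union = formation_fraction and
    unique-old/union = resorption_fraction (up to integer rounding; exact
    realized counts are recorded in the returned truth).

    Surface voxels are picked preferentially where a smooth random field is
    high, so removal and accretion form spatially contiguous patches — the
    voxel-scale analogue of resorption pits and formation packets — rather
    than salt-and-pepper noise.
    """
    if not (0.0 <= formation_fraction < 1.0) or not (0.0 <= resorption_fraction < 1.0):
        raise ValueError("fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask_old = _bone_mask(volume)
    n_old = int(mask_old.sum())
    if n_old == 0:
        raise ValueError("phantom has no bone voxels")
    # union = old + added; solve for integer counts
    n_add = int(round(formation_fraction * n_old / (1.0 - formation_fraction)))
    n_union = n_old + n_add
    n_rem = int(round(resorption_fraction * n_union))
    struct = ndimage.generate_binary_structure(3, 1)
    shape = mask_old.shape
    # independent patch fields for resorption and formation
    field_r = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    field_f = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)

    def pick_top(cand_mask: np.ndarray, field: np.ndarray, take: int) -> np.ndarray:
        cand = np.argwhere(cand_mask)
        vals = field[cand_mask]
        idx = np.argpartition(vals, len(vals) - take)[len(vals) - take:]
        return cand[idx]

    # Formation and resorption are simultaneous processes: packets deposit on
    # the original surface while pits are excavated elsewhere. Formation is
    # accreted first, layer by layer, on the old structure; resorption then
    # peels the old structure independently of the fresh crust. The two voxel
    # sets are disjoint by construction (additions never lie in old bone,
    # removals always do), so the realized counts are exact.
    current = mask_old.copy()
    added = np.zeros_like(mask_old)
    need = n_add
    while need > 0:
        shell = ndimage.binary_dilation(current, struct) & ~current
        n_cand = int(shell.sum())
        if n_cand == 0:
            raise RuntimeError("insufficient surface voxels for requested formation")
        pick = pick_top(shell, field_f, min(need, n_cand))
        current[tuple(pick.T)] = True
        added[tuple(pick.T)] = True
        need -= len(pick)

    work = mask_old.copy()
    removed = np.zeros_like(mask_old)
    # old-bone voxels anchoring fresh crust are spared so no formation voxel
    # ends up disconnected from the remaining structure
    anchors = ndimage.binary_dilation(added, struct) & mask_old
    need = n_rem
    while need > 0:
        # border_value=1: the array boundary is a cut through the structure,
        # not a physical bone surface, so face voxels are not candidates
        surface = work & ~ndimage.binary_erosion(work, struct, border_value=1)
        cand = surface & ~anchors
        if not cand.any():
            cand = surface  # fall back rather than deadlock
        n_cand = int(cand.sum())
        if n_cand == 0:
            raise RuntimeError("insufficient surface voxels for requested resorption")
        pick = pick_top(cand, field_r, min(need, n_cand))
        work[tuple(pick.T)] = False
        removed[tuple(pick.T)] = True
        need -= len(pick)

    mask_new = (mask_old & ~removed) | added
    bone_val = float(volume.values[mask_old].mean()) if n_old else BONE_DENSITY
    bg = volume.values[~mask_old]
    bg_val = float(bg.mean()) if bg.size else BACKGROUND_DENSITY
    values = np.where(mask_new, bone_val, bg_val)
    out = volume.with_values(values)
    truth = PhantomTruth(
        seed=seed,
        formation_fraction=n_add / n_union,
        resorption_fraction=n_rem / n_union,
        true_bvtv=float(mask_new.mean()),
        extras={
            "n_unique_old": n_rem,
            "n_unique_new": n_add,
            "n_common": n_old - n_rem,
            "n_union": n_union,
        },
    )
    return out, truth


# ---------------------------------------------------------------------------
# cortical and plate phantoms
# ---------------------------------------------------------------------------


def make_cortical_phantom(
    outer_radius_mm: float = 2.0,
    inner_radius_mm: float = 1.0,
    voxel_size_um: float = 7.0,
    density: float = 1200.0,
    n_slices: int = 4,
    margin_vox: int = 4,
) -> tuple[DensityVolume, PhantomTruth]:
    """Extruded circular annulus with closed-form cross-section geometry.

    Records analytic Tt.Ar = pi*ro^2, Ct.Ar = pi*(ro^2 - ri^2),
    Ct.Th = ro - ri and section modulus pi*(ro^4 - ri^4)/(4*ro).
    """
    if inner_radius_mm >= outer_radius_mm:
        raise ValueError("inner radius must be below outer radius")
    vox_mm = voxel_size_um / 1000.0
    if outer_radius_mm / vox_mm < 3 or (
        inner_radius_mm > 0 and inner_radius_mm / vox_mm < 3
    ):
        raise ValueError("radii must span at least 3 voxels")
    ro = outer_radius_mm / vox_mm
    ri = inner_radius_mm / vox_mm
    half = int(np.ceil(ro)) + margin_vox
    n = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    r2 = xx * xx + yy * yy
    ring = (r2 <= ro * ro) & (r2 >= ri * ri)
    values = np.where(ring, density, 0.0)
    vol = DensityVolume(
        np.repeat(values[None, :, :], n_slices, axis=0), voxel_size_um, CAL_HA
    )
    truth = PhantomTruth(
        true_thickness_um=(outer_radius_mm - inner_radius_mm) * 1000.0,
        extras={
            "tt_ar_mm2": np.pi * outer_radius_mm**2,
            "ct_ar_mm2": np.pi * (outer_radius_mm**2 - inner_radius_mm**2),
            "ma_ar_mm2": np.pi * inner_radius_mm**2,
            "ct_th_mm": outer_radius_mm - inner_radius_mm,
            "section_modulus_mm3": np.pi
            * (outer_radius_mm**4 - inner_radius_mm**4)
            / (4.0 * outer_radius_mm),
        },
    )
    return vol, truth


def make_elliptical_phantom(
    major_radius_mm: float,
    minor_radius_mm: float,
    voxel_size_um: float = 14.0,
    density: float = 1200.0,
    n_slices: int = 4,
) -> DensityVolume:
    """Solid elliptical rod (major axis along y) for geometry checks."""
    vox_mm = voxel_size_um / 1000.0
    a = major_radius_mm / vox_mm
    b = minor_radius_mm / vox_mm
    half = int(np.ceil(max(a, b))) + 4
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    inside = (yy / a) ** 2 + (xx / b) ** 2 <= 1.0
    values = np.where(inside, density, 0.0)
    return DensityVolume(
        np.repeat(values[None, :, :], n_slices, axis=0), voxel_size_um, CAL_HA
    )


def make_plate_phantom(
    n_plates: int = 4,
    plate_vox: int = 10,
    gap_vox: int = 30,
    lateral: int = 48,
    voxel_size_um: float = 18.0,
) -> tuple[DensityVolume, PhantomTruth]:
    """Parallel plates stacked along z, for thickness and separation oracles:
    Tb.Th = plate_vox and Tb.Sp = gap_vox voxels.

    The stack is padded with half a gap at both z ends so that boundary
    plates and end gaps carry the same local thickness as interior ones
    (distance transforms see no structure beyond the array)."""
    half_gap = gap_vox // 2
    nz = n_plates * plate_vox + (n_plates - 1) * gap_vox + 2 * half_gap
    values = np.zeros((nz, lateral, lateral))
    z = half_gap
    for _ in range(n_plates):
        values[z : z + plate_vox] = BONE_DENSITY
        z += plate_vox + gap_vox
    vol = DensityVolume(values, voxel_size_um, CAL_HA)
    truth = PhantomTruth(
        true_bvtv=float((values > 0).mean()),
        true_thickness_um=plate_vox * voxel_size_um,
        extras={"gap_um": gap_vox * voxel_size_um},
    )
    return vol, truth


# ---------------------------------------------------------------------------
# abdomen phantom
# ---------------------------------------------------------------------------


def make_abdomen_phantom(
    adipose_fraction: float = 0.30,
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 160, 160),
    voxel_size_um: float = 200.0,
    body_radius_vox: int = 60,
    shell_vox: int = 4,
    noise_sd: float = 1.0,
    blob_sigma: float = 1.5,
) -> tuple[DensityVolume, PhantomTruth]:
    """Concentric abdomen phantom in raw (uncalibrated) gray values.

    Air background, a subcutaneous-fat shell (in the adipose HU window but
    to be excluded by masking), an inner cavity of lean tissue with adipose
    blobs whose voxel count realises ``adipose_fraction`` exactly, plus
    separate air and water standard patches whose locations are recorded in
    the metadata. Raw levels are air=10 and water=110 so HU = 10*(raw-110).
    """
    if not 0.0 <= adipose_fraction <= 1.0:
        raise ValueError("adipose_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.mgrid[:ny, :nx].astype(np.float64)
    r = np.hypot(yy - cy, xx - cx)
    body2d = r <= body_radius_vox
    cavity2d = r <= body_radius_vox - shell_vox
    shell2d = body2d & ~cavity2d

    values = np.full(shape, RAW_AIR)
    values[:, shell2d] = RAW_ADIPOSE  # skin/subcutaneous fat
    values[:, cavity2d] = RAW_LEAN

    cavity3d = np.broadcast_to(cavity2d, shape)
    n_cavity = int(cavity3d.sum())
    n_adipose = int(round(adipose_fraction * n_cavity))
    if n_adipose > 0:
        blob = ndimage.gaussian_filter(rng.standard_normal(shape), blob_sigma)
        blob_cav = blob[cavity3d]
        thr = np.partition(blob_cav, n_cavity - n_adipose)[n_cavity - n_adipose]
        adipose = np.zeros(shape, dtype=bool)
        sel = blob >= thr
        adipose[cavity3d & sel] = True
        # exact count: drop ties beyond the target
        excess = int(adipose.sum()) - n_adipose
        if excess > 0:
            idx = np.argwhere(adipose & (blob == thr))
            drop = idx[rng.choice(len(idx), size=min(excess, len(idx)), replace=False)]
            adipose[tuple(drop.T)] = False
        values[adipose] = RAW_ADIPOSE
        realized = float(adipose.sum()) / n_cavity
    else:
        realized = 0.0

    # standard patches in the air background corners
    patch = 8
    air_patch = (slice(0, nz), slice(2, 2 + patch), slice(2, 2 + patch))
    water_patch = (slice(0, nz), slice(2, 2 + patch), slice(nx - 2 - patch, nx - 2))
    values[water_patch] = RAW_WATER

    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=shape)

    vol = DensityVolume(values, voxel_size_um, CAL_RAW)
    vol.meta["air_patch"] = [[s.start, s.stop] for s in air_patch]
    vol.meta["water_patch"] = [[s.start, s.stop] for s in water_patch]
    truth = PhantomTruth(seed=seed, adipose_fraction=realized)
    return vol, truth


def abdomen_standard_means(volume: DensityVolume) -> tuple[float, float]:
    """Mean raw value of the recorded air and water standard patches."""
    def patch_mean(key: str) -> float:
        sl = tuple(slice(a, b) for a, b in volume.meta[key])
        return float(volume.values[sl].mean())

    return patch_mean("air_patch"), patch_mean("water_patch")


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

#: default bone band set: centre -> (height, FWHM cm^-1). Heights are scaled
#: so the derived ratios sit in the physiological range for rat cortical bone
#: (mineral-to-matrix ~10, carbonate/phosphate ~0.16, crystallinity ~0.106).
DEFAULT_BANDS: dict[float, tuple[float, float]] = {
    854.0: (1.2, 12.0),
    872.0: (0.78, 12.0),
    960.0: (10.0, 9.42),
    1070.0: (1.64, 14.0),
    1245.0: (1.6, 16.0),
    1375.0: (0.72, 16.0),
    1670.0: (1.0, 14.0),
    1690.0: (0.45, 14.0),
}

_SIG = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma per unit FWHM


def default_bands() -> dict[float, tuple[float, float]]:
    return dict(DEFAULT_BANDS)


def _band_sum(w: np.ndarray, bands: dict[float, tuple[float, float]]) -> np.ndarray:
    y = np.zeros_like(w)
    for centre, (height, fwhm) in bands.items():
        sigma = fwhm * _SIG
        y += height * np.exp(-((w - centre) ** 2) / (2 * sigma**2))
    return y


def pmma_reference(step: float = 1.0) -> Spectrum:
    """Synthetic pMMA embedding-resin reference, dominated by ~812 cm^-1."""
    w = np.arange(800.0, 1800.0 + step / 2, step)
    bands = {812.0: (1.0, 12.0), 1450.0: (0.35, 18.0), 1725.0: (0.25, 20.0)}
    return Spectrum(w, _band_sum(w, bands))


def make_raman_spectrum(
    band_amplitudes: dict[float, float] | None = None,
    band_widths: dict[float, float] | None = None,
    baseline_coeffs=(0.0,),
    pmma_scale: float = 2.0,
    spike_positions=(),
    spike_amplitude: float | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    step: float = 1.0,
) -> tuple[Spectrum, RamanParams]:
    """Synthetic bone spectrum: bands + polynomial baseline + resin + spikes
    + Gaussian noise, with the construction-truth parameters.

    ``noise_sd`` defaults to 0.5% of the tallest band. The truth parameters
    are evaluated with the package's own band-height/FWHM operators on the
    clean band-sum signal (plus resin for nanoporosity), so recovery error
    measures preprocessing fidelity only.
    """
    if band_amplitudes is None:
        band_amplitudes = {c: h for c, (h, _) in DEFAULT_BANDS.items()}
    widths = {c: w for c, (_, w) in DEFAULT_BANDS.items()}
    if band_widths:
        widths.update(band_widths)
    w = np.arange(800.0, 1800.0 + step / 2, step)
    for centre in band_amplitudes:
        if centre < w[0] or centre > w[-1]:
            raise ValueError(f"band centre {centre} outside the 800-1800 cm^-1 grid")
    bands = {c: (a, widths.get(c, 12.0)) for c, a in band_amplitudes.items()}
    bone = _band_sum(w, bands)
    ref = pmma_reference(step)
    clean_pre = bone + pmma_scale * ref.intensities

    # default noise: SNR ~1000 on the tallest band, representative of a
    # 20 s x 3-accumulation acquisition on embedded cortical bone
    max_height = max([a for a in band_amplitudes.values()] + [1e-12])
    if noise_sd is None:
        noise_sd = 0.001 * max_height
    u = (w - w.mean()) / (np.ptp(w) / 2)
    baseline = np.polynomial.polynomial.polyval(u, np.asarray(baseline_coeffs, dtype=float))
    rng = np.random.default_rng(seed)
    y = clean_pre + baseline
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=w.shape)
    if spike_amplitude is None:
        spike_amplitude = 50.0 * max_height
    for pos in spike_positions:
        y[int(np.argmin(np.abs(w - pos)))] += spike_amplitude

    spectrum = Spectrum(w, y)
    try:
        truth = _truth_params(Spectrum(w, bone), Spectrum(w, clean_pre), pmma_scale)
    except ValueError:
        truth = None  # degenerate construction (no phosphate band)
    return spectrum, truth


def _truth_params(clean_bone: Spectrum, clean_pre: Spectrum,
                  pmma_scale: float) -> RamanParams:
    from .raman import measure_params

    # same measurement operators as the analysis pipeline, on clean signals
    truth = measure_params(clean_pre, clean_bone, alpha=pmma_scale)
    return truth


def random_spectrum(seed: int, clean: bool = False,
                    amp_range: tuple[float, float] = (0.8, 1.25)
                    ) -> tuple[Spectrum, RamanParams]:
    """Cohort helper: default bands with randomized heights (uniform scaling
    per band), cubic baseline and default noise unless ``clean``."""
    rng = np.random.default_rng(seed)
    amps = {
        c: h * rng.uniform(*amp_range) for c, (h, _) in DEFAULT_BANDS.items()
    }
    pmma_scale = 2.0 * rng.uniform(*amp_range)
    if clean:
        return make_raman_spectrum(
            amps, pmma_scale=pmma_scale, noise_sd=0.0, seed=seed
        )
    baseline = (5.0, 2.0, -1.5, 0.8)  # cubic background, comparable to bands
    return make_raman_spectrum(
        amps, baseline_coeffs=baseline, pmma_scale=pmma_scale, seed=seed
    )


# ---------------------------------------------------------------------------
# load-displacement curves
# ---------------------------------------------------------------------------


def make_load_curve(
    stiffness: float = 650.0,
    yield_load: float = 130.0,
    postyield_slope: float = 60.0,
    ultimate_load: float = 170.0,
    failure_displacement: float = 1.2,
    sample_rate: float = 100.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    speed_mm_min: float = 0.5,
) -> tuple[LoadDisplacementCurve, dict]:
    """Piecewise elastic/plastic bending curve with analytic truth.

    Linear at ``stiffness`` to the programmed kink (``yield_load``), linear
    at ``postyield_slope`` to ``ultimate_load``, plateau to an abrupt failure
    drop at ``failure_displacement``. The truth dict records the analytic
    stiffness, ultimate, work-to-fracture and the 10%-stiffness-loss yield
    load (the quantity the yield detector estimates), alongside the kink.
    """
    S, k = stiffness, postyield_slope
    if not 0 <= k < S:
        raise ValueError("postyield_slope must lie in [0, stiffness)")
    if yield_load > ultimate_load:
        raise ValueError("yield_load must not exceed ultimate_load")
    if k == 0 and yield_load < ultimate_load:
        raise ValueError("zero post-yield slope requires yield_load == ultimate_load")
    d1 = yield_load / S
    d2 = d1 if yield_load == ultimate_load else d1 + (ultimate_load - yield_load) / k
    if failure_displacement < d2:
        raise ValueError("failure_displacement precedes the ultimate point")

    # analytic 10%-stiffness-loss yield: crossing of the 0.9*S line with the
    # post-kink curve (plateau crossing if the second segment never crosses)
    flagged = False
    if d2 > d1:
        d_star = (yield_load - k * d1) / (0.9 * S - k)
        if d_star > d2:
            d_star = ultimate_load / (0.9 * S)
            if d_star > failure_displacement:
                d_star, flagged = d2, True
    else:
        d_star = ultimate_load / (0.9 * S)
        if d_star > failure_displacement:
            d_star, flagged = d1, True
    yield_rule = ultimate_load if flagged else 0.9 * S * d_star

    def curve_load(d):
        return np.where(
            d <= d1, S * d,
            np.where(d <= d2, yield_load + k * (d - d1), ultimate_load),
        )

    # analytic work to the failure drop (piecewise trapezoids)
    work = (
        0.5 * yield_load * d1
        + 0.5 * (yield_load + ultimate_load) * (d2 - d1)
        + ultimate_load * (failure_displacement - d2)
    )

    speed = speed_mm_min / 60.0  # mm/s
    tail = 0.05  # mm recorded after the failure drop
    n = int(np.ceil((failure_displacement + tail) * sample_rate / speed)) + 1
    d = np.arange(n) * speed / sample_rate
    load = curve_load(d)
    load[d > failure_displacement] = 0.0
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        load = load + rng.normal(0.0, noise_sd, size=n)
    curve = LoadDisplacementCurve(d, load, sample_rate)
    truth = {
        "stiffness": S,
        "yield_kink": yield_load,
        "yield_load": yield_rule,
        "yield_displacement": d_star,
        "yield_flagged": flagged,
        "ultimate_load": ultimate_load,
        "failure_displacement": failure_displacement,
        "work_to_fracture": work,
        "postyield_displacement": failure_displacement - d_star,
        "seed": seed,
    }
    return curve, truth
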