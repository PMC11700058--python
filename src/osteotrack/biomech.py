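"""Three-point bending analysis of load-displacement curves.

Structural properties (stiffness, yield, ultimate, post-yield displacement,
work-to-fracture) come from the recorded curve; material properties couple
the curve to microCT section geometry: for a central load F over span L the
peak bending moment is F*L/4, and tissue strength is the peak moment divided
by the section modulus of the fractured cross-section (N*mm/mm^3 = MPa).

The yield point follows the 10%-stiffness-loss rule: a line with slope 0.9
times the measured stiffness, anchored at the zero-load intercept of the
linear region, is intersected with the measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LoadDisplacementCurve",
    "BendingResult",
    "stiffness",
    "yield_point",
    "failure_and_work",
    "bending_mechanics",
    "analyze_curve",
]

DEFAULT_SPAN_MM = 15.0  # constant support span of the three-point fixture
PRELOAD_N = 1.0  # samples below this load are machine settling


@dataclass
class LoadDisplacementCurve:
    """A bending test trace: displacement (mm, non-decreasing) vs load (N)."""

    displacement: np.ndarray
    load: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        self.load = np.asarray(self.load, dtype=np.float64)
        if self.displacement.shape != self.load.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and load must be equal-length 1D arrays")
        if len(self.displacement) < 50:
            raise ValueError("curve too short (< 50 samples)")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be monotone non-decreasing")

    def __len__(self) -> int:
        return len(self.load)

    def trim_preload(self, preload: float = PRELOAD_N) -> "LoadDisplacementCurve":
        """Drop samples before the load first exceeds the preload and re-zero
        displacement (machine-settling convention)."""
        above = np.flatnonzero(self.load > preload)
        if above.size == 0:
            raise ValueError("load never exceeds the preload threshold")
        i0 = above[0]
        return LoadDisplacementCurve(
            self.displacement[i0:] - self.displacement[i0],
            self.load[i0:],
            self.sample_rate,
        )

    def to_csv(self, path, span_mm: float = DEFAULT_SPAN_MM) -> None:
        with open(path, "w") as fh:
            fh.write(f"# span_mm={span_mm}\n# rate_hz={self.sample_rate}\n")
            pd.DataFrame(
                {"displacement_mm": self.displacement, "load_N": self.load}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> tuple["LoadDisplacementCurve", dict]:
        meta = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
        df = pd.read_csv(path, skiprows=skip)
        rate = meta.get("rate_hz", 100.0)
        return cls(df["displacement_mm"].to_numpy(), df["load_N"].to_numpy(), rate), meta


@dataclass
class BendingResult:
    ultimate_load: float
    yield_load: float
    stiffness: float
    postyield_displacement: float
    work_to_fracture: float
    span: float
    peak_moment: float = float("nan")
    section_modulus: float = float("nan")
    tissue_strength: float = float("nan")
    yield_flagged: bool = False  # no 10%-loss crossing; yield set to ultimate
    extras: dict = field(default_factory=dict)


def _smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    kernel = np.ones(width) / width
    return np.convolve(y, kernel, mode="same")


def _linear_region(curve: LoadDisplacementCurve) -> np.ndarray:
    """Sample indices between 10% and 90% of the ultimate load, pre-ultimate."""
    load = curve.load
    i_ult = int(np.argmax(load))
    ult = load[i_ult]
    sel = np.flatnonzero((load[: i_ult + 1] >= 0.10 * ult) & (load[: i_ult + 1] <= 0.90 * ult))
    return sel


def _max_window_slope(d: np.ndarray, f: np.ndarray, w: int) -> tuple[float, float]:
    """Maximum sliding-window least-squares slope and its intercept."""
    n = len(d)
    w = min(max(w, 2), n)
    cs_x = np.concatenate([[0.0], np.cumsum(d)])
    cs_y = np.concatenate([[0.0], np.cumsum(f)])
    cs_xx = np.concatenate([[0.0], np.cumsum(d * d)])
    cs_xy = np.concatenate([[0.0], np.cumsum(d * f)])
    i0 = np.arange(0, n - w + 1)
    sx = cs_x[i0 + w] - cs_x[i0]
    sy = cs_y[i0 + w] - cs_y[i0]
    sxx = cs_xx[i0 + w] - cs_xx[i0]
    sxy = cs_xy[i0 + w] - cs_xy[i0]
    denom = w * sxx - sx * sx
    slopes = np.where(denom > 0, (w * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), -np.inf)
    k = int(np.argmax(slopes))
    s = float(slopes[k])
    return s, float((sy[k] - s * sx[k]) / w)


def _crossing(c: LoadDisplacementCurve, S: float, b: float) -> tuple[float, float, bool]:
    """First downward crossing of the curve with the 0.9*S secant line."""
    d0 = -b / S
    line = 0.9 * S * (c.displacement - d0)
    diff = _smooth(c.load, 5) - line
    i_ult = int(np.argmax(c.load))
    max_load = c.load[i_ult]
    after = np.flatnonzero(c.load[i_ult:] < 0.10 * max_load)
    i_fail = i_ult + after[0] if after.size else len(c)
    # the failure cliff itself always crosses the secant; exclude it (and the
    # few samples the smoothing smears backwards)
    i_stop = max(0, i_fail - 5)
    start = int(np.argmax(diff[: i_ult + 1])) if i_ult > 0 else 0
    below = np.flatnonzero(diff[start:i_stop] < 0)
    if below.size == 0:
        return float(c.displacement[i_ult]), float(c.load[i_ult]), True
    j = start + below[0]
    if j == 0:
        d_y = c.displacement[0]
    else:
        frac = diff[j - 1] / (diff[j - 1] - diff[j])
        d_y = c.displacement[j - 1] + frac * (c.displacement[j] - c.displacement[j - 1])
    return float(d_y), float(0.9 * S * (d_y - d0)), False


def stiffness(curve: LoadDisplacementCurve, smooth_width: int = 5,
              return_intercept: bool = False, refine: bool = True):
    """Stiffness: maximum sliding-window least-squares slope (N/mm).

    First pass: the window spans 20% of the samples between 10% and 90% of
    the ultimate load on the lightly smoothed curve. Because that region can
    be dominated by the post-yield segment (shallow hardening slope, high
    ultimate/yield ratio), a refinement pass repeats the estimate with the
    window confined to the pre-yield portion located with the first-pass
    slope.
    """
    c = curve.trim_preload()
    region = _linear_region(c)
    if region.size < 10:
        raise ValueError("pre-yield region too short for stiffness estimation")
    d = c.displacement[region]
    f = _smooth(c.load, smooth_width)[region]
    s, intercept = _max_window_slope(d, f, int(round(0.20 * region.size)))
    if refine:
        d_y, _, flagged = _crossing(c, s, intercept)
        if not flagged:
            elastic = region[c.displacement[region] <= d_y]
            if elastic.size >= 20:
                s, intercept = _max_window_slope(
                    c.displacement[elastic], _smooth(c.load, smooth_width)[elastic],
                    max(10, int(round(0.5 * elastic.size))),
                )
    if return_intercept:
        return s, intercept
    return s


def yield_point(curve: LoadDisplacementCurve, S: float | None = None
                ) -> tuple[float, float, bool]:
    """Yield by the 10%-stiffness-loss rule.

    Returns ``(displacement, load, flagged)`` in the trimmed-curve frame.
    The 0.9*S line is anchored at the zero-load intercept of the linear fit;
    the first downward crossing of the measured curve (after the excess over
    the line peaks) is interpolated linearly between samples. With no
    crossing before failure, the ultimate point is returned flagged.
    """
    s_est, b = stiffness(curve, return_intercept=True)
    if S is None:
        S = s_est
    if S <= 0:
        raise ValueError("stiffness must be positive")
    return _crossing(curve.trim_preload(), S, b)


def failure_and_work(curve: LoadDisplacementCurve, yield_displacement: float,
                     drop_fraction: float = 0.10) -> tuple[float, float, float]:
    """Failure point, work-to-fracture and post-yield displacement.

    Failure is the first sample after the ultimate load where the load drops
    below ``drop_fraction`` of the running maximum (default 10%), or the last
    sample. Work is the trapezoidal integral of the raw load over
    displacement up to failure.
    """
    c = curve.trim_preload()
    i_ult = int(np.argmax(c.load))
    max_load = c.load[i_ult]
    after = np.flatnonzero(c.load[i_ult:] < drop_fraction * max_load)
    i_fail = i_ult + after[0] if after.size else len(c) - 1
    d_fail = float(c.displacement[i_fail])
    work = float(np.trapezoid(c.load[: i_fail + 1], c.displacement[: i_fail + 1]))
    postyield = max(d_fail - yield_displacement, 0.0)
    return d_fail, work, postyield


def bending_mechanics(ultimate_load: float, span: float = DEFAULT_SPAN_MM,
                      section_modulus: float | None = None
                      ) -> tuple[float, float]:
    """Peak moment F*L/4 (central load) and tissue strength M/Z in MPa."""
    if ultimate_load <= 0 or span <= 0:
        raise ValueError("ultimate load and span must be positive")
    peak_moment = ultimate_load * span / 4.0
    if section_modulus is None:
        return peak_moment, float("nan")
    if section_modulus <= 0:
        raise ValueError("section modulus must be positive")
    return peak_moment, peak_moment / section_modulus


def analyze_curve(curve: LoadDisplacementCurve, span: float = DEFAULT_SPAN_MM,
                  section_modulus: float | None = None) -> BendingResult:
    """Full structural + material analysis of one bending trace."""
    S, _ = stiffness(curve, return_intercept=True)
    d_y, f_y, flagged = yield_point(curve, S)
    d_fail, work, postyield = failure_and_work(curve, d_y)
    c = curve.trim_preload()
    ultimate = float(c.load.max())
    peak_moment, strength = bending_mechanics(ultimate, span, section_modulus)
    return BendingResult(
        ultimate_load=ultimate,
        yield_load=f_y,
        stiffness=S,
        postyield_displacement=postyield,
        work_to_fracture=work,
        span=span,
        peak_moment=peak_moment,
        section_modulus=float("nan") if section_modulus is None else section_modulus,
        tissue_strength=strength,
        yield_flagged=flagged,
        extras={"yield_displacement": d_y, "failure_displacement": d_fail},
    )
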