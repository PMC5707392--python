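"""Meta-pixel diagnostics and the SPIFF pixel-locking correction.

Pooling the fractional parts of many sub-pixel localizations into the unit
square (the "meta-pixel") reveals estimator bias: an unbiased tracker fills
the meta-pixel uniformly, while pixel locking compresses the density toward
the pixel center.  The Single-Pixel Interior Filling Function (SPIFF)
correction maps each estimated fractional position through the empirical
CDF of the meta-pixel,

    corrected_frac = F(estimated_frac),

which by the probability-integral transform makes the corrected fractional
parts uniform.  Relative to the pixel center this is ``F(x) - 1/2``, the
general (possibly asymmetric) form of the signed-integral correction; for a
density symmetric about the center the two coincide.  Axes are corrected
independently, each from its own one-dimensional meta-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .tracking import Localization

__all__ = [
    "MetaPixel",
    "SpiffMap",
    "UniformityReport",
    "build_meta_pixel",
    "uniformity_test",
    "fit_spiff_map",
    "apply_spiff",
    "DegenerateMetaPixelError",
]

DEFAULT_MIN_SAMPLES = 500
LOCKED_P_VALUE = 1e-3


class DegenerateMetaPixelError(ValueError):
    """Raised when the meta-pixel density has (near-)zero width: complete
    locking cannot be inverted."""


@dataclass
class MetaPixel:
    """Per-axis collections of localization fractional parts in [0, 1)."""

    frac_x: np.ndarray
    frac_y: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.frac_x = np.asarray(self.frac_x, dtype=float)
        self.frac_y = np.asarray(self.frac_y, dtype=float)
        if self.frac_x.shape != self.frac_y.shape:
            raise ValueError("x and y fractional collections must match in length")
        for arr in (self.frac_x, self.frac_y):
            if arr.size and (arr.min() < 0.0 or arr.max() >= 1.0):
                raise ValueError("fractional parts must lie in [0, 1)")

    @property
    def n(self) -> int:
        return self.frac_x.size


@dataclass
class UniformityReport:
    """Chi-square and Kolmogorov-Smirnov comparison of a meta-pixel axis
    against the uniform distribution; ``locked`` flags chi-square p < 1e-3
    on either axis."""

    chi2_x: float
    chi2_y: float
    dof: int
    p_x: float
    p_y: float
    ks_x: float
    ks_y: float
    n: int
    bins: int
    locked: bool

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bins": self.bins,
            "dof": self.dof,
            "x": {"chi2": self.chi2_x, "p": self.p_x, "ks": self.ks_x},
            "y": {"chi2": self.chi2_y, "p": self.p_y, "ks": self.ks_y},
            "locked": self.locked,
        }


@dataclass
class SpiffMap:
    """Per-axis monotone map [0,1) -> [0,1): the interpolated empirical CDF
    of the meta-pixel, with fixed endpoints F(0)=0 and F(1)=1."""

    knots_x: np.ndarray
    cdf_x: np.ndarray
    knots_y: np.ndarray
    cdf_y: np.ndarray
    n: int

    def _eval(self, frac: np.ndarray, axis: str) -> np.ndarray:
        knots = self.knots_x if axis == "x" else self.knots_y
        cdf = self.cdf_x if axis == "x" else self.cdf_y
        out = np.interp(frac, knots, cdf)
        # corrected fractions must stay inside [0, 1) to preserve the pixel
        return np.clip(out, 0.0, np.nextafter(1.0, 0.0))

    def map_x(self, frac: np.ndarray) -> np.ndarray:
        return self._eval(np.asarray(frac, dtype=float), "x")

    def map_y(self, frac: np.ndarray) -> np.ndarray:
        return self._eval(np.asarray(frac, dtype=float), "y")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "x": {"knots": self.knots_x.tolist(), "cdf": self.cdf_x.tolist()},
            "y": {"knots": self.knots_y.tolist(), "cdf": self.cdf_y.tolist()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpiffMap":
        return cls(
            np.asarray(d["x"]["knots"], dtype=float),
            np.asarray(d["x"]["cdf"], dtype=float),
            np.asarray(d["y"]["knots"], dtype=float),
            np.asarray(d["y"]["cdf"], dtype=float),
            int(d["n"]),
        )

    @classmethod
    def identity(cls) -> "SpiffMap":
        e = np.array([0.0, 1.0])
        return cls(e.copy(), e.copy(), e.copy(), e.copy(), 0)


def build_meta_pixel(
    localizations: list[Localization] | np.ndarray, aggregate: bool = True
) -> MetaPixel:
    """Collect the fractional parts of localization coordinates.

    Accepts a list of :class:`~spifftrack.tracking.Localization` or an
    ``(n, 2)`` array of ``(x, y)`` positions.  ``aggregate`` documents that
    all particles are pooled into a single meta-pixel (the recommended
    practice; pass per-particle subsets to build per-particle maps).
    """
    if isinstance(localizations, np.ndarray):
        pos = np.asarray(localizations, dtype=float).reshape(-1, 2)
    else:
        pos = np.array([[l.x_px, l.y_px] for l in localizations]).reshape(-1, 2)
    if pos.size == 0:
        raise ValueError("cannot build a meta-pixel from no localizations")
    if not np.all(np.isfinite(pos)):
        pos = pos[np.all(np.isfinite(pos), axis=1)]
        if pos.size == 0:
            raise ValueError("cannot build a meta-pixel from no finite localizations")
    frac = pos - np.floor(pos)
    source = "aggregated" if aggregate else "single-particle"
    return MetaPixel(frac[:, 0], frac[:, 1], source=source)


def uniformity_test(mp: MetaPixel, bins: int = 20) -> UniformityReport:
    """Chi-square (over ``bins`` equal-width bins) and KS comparison of each
    meta-pixel axis against Uniform(0, 1)."""
    if mp.n < 10 * bins:
        raise ValueError(
            f"uniformity test needs >= {10 * bins} samples for {bins} bins, got {mp.n}"
        )
    edges = np.linspace(0.0, 1.0, bins + 1)
    results = {}
    for axis, data in (("x", mp.frac_x), ("y", mp.frac_y)):
        observed = np.histogram(data, bins=edges)[0]
        chi2, p = stats.chisquare(observed)
        ks = stats.kstest(data, "uniform").statistic
        results[axis] = (float(chi2), float(p), float(ks))
    locked = results["x"][1] < LOCKED_P_VALUE or results["y"][1] < LOCKED_P_VALUE
    return UniformityReport(
        chi2_x=results["x"][0],
        chi2_y=results["y"][0],
        dof=bins - 1,
        p_x=results["x"][1],
        p_y=results["y"][1],
        ks_x=results["x"][2],
        ks_y=results["y"][2],
        n=mp.n,
        bins=bins,
        locked=locked,
    )


def _ecdf_knots(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated empirical CDF through the order statistics (Hazen
    plotting positions), pinned to (0,0) and (1,1); ties collapsed to a
    single knot at their mean CDF height so the map stays a function."""
    s = np.sort(samples)
    n = s.size
    h = (np.arange(1, n + 1) - 0.5) / n
    vals, start = np.unique(s, return_index=True)
    counts = np.diff(np.append(start, n))
    heights = np.add.reduceat(h, start) / counts
    knots = np.concatenate(([0.0], vals, [1.0]))
    cdf = np.concatenate(([0.0], heights, [1.0]))
    return knots, np.maximum.accumulate(cdf)


def fit_spiff_map(mp: MetaPixel, min_samples: int = DEFAULT_MIN_SAMPLES) -> SpiffMap:
    """Fit the per-axis SPIFF map: the interpolated empirical CDF of the
    meta-pixel fractional parts.

    Refuses to fit from fewer than ``min_samples`` points per axis (the
    sup-norm CDF noise would rival the bias being corrected) and from a
    degenerate, zero-width density (complete locking is not invertible).
    """
    if mp.n < min_samples:
        raise ValueError(
            f"SPIFF map needs >= {min_samples} samples per axis, got {mp.n}; "
            "a sparser map would be dominated by CDF noise"
        )
    for axis, data in (("x", mp.frac_x), ("y", mp.frac_y)):
        if np.ptp(data) < 1e-9:
            raise DegenerateMetaPixelError(
                f"all {axis}-fractional parts identical: complete pixel locking "
                "has a zero-width density that SPIFF cannot invert"
            )
    kx, cx = _ecdf_knots(mp.frac_x)
    ky, cy = _ecdf_knots(mp.frac_y)
    return SpiffMap(kx, cx, ky, cy, mp.n)


def apply_spiff(
    localizations: list[Localization] | np.ndarray, spiff_map: SpiffMap
):
    """Correct localizations through the SPIFF map.

    Each coordinate becomes ``floor(x) + F(frac(x))``: the integer pixel
    assignment is preserved and only the sub-pixel part is remapped.
    Accepts and returns either a list of Localization (order preserved) or
    an ``(n, 2)`` position array; NaN positions pass through unchanged.
    """
    if isinstance(localizations, np.ndarray):
        pos = np.asarray(localizations, dtype=float)
        out = pos.copy()
        flat = out.reshape(-1, 2)
        ok = np.all(np.isfinite(flat), axis=1)
        fx = np.floor(flat[ok, 0])
        fy = np.floor(flat[ok, 1])
        flat[ok, 0] = fx + spiff_map.map_x(flat[ok, 0] - fx)
        flat[ok, 1] = fy + spiff_map.map_y(flat[ok, 1] - fy)
        return out
    corrected = []
    for loc in localizations:
        fx = np.floor(loc.x_px)
        fy = np.floor(loc.y_px)
        corrected.append(
            replace(
                loc,
                x_px=float(fx + spiff_map.map_x(loc.x_px - fx)),
                y_px=float(fy + spiff_map.map_y(loc.y_px - fy)),
            )
        )
    return corrected
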