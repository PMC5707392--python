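"""Evaluation metrics for tracked trajectories.

Mean-square displacement, interparticle separation and angle series,
per-frame localization error against ground truth, and a second-tier
correction that fits the separation-dependent residual bias (apparent minus
true separation as a function of true separation) with a cubic polynomial
and subtracts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import GroundTruth
from .tracking import Trajectory

__all__ = [
    "MsdCurve",
    "PairSeries",
    "ErrorSeries",
    "BiasCurve",
    "CubicBiasFit",
    "msd",
    "pair_metrics",
    "rms_error",
    "separation_bias_curve",
    "fit_cubic_bias",
    "apply_cubic_bias",
]


@dataclass
class MsdCurve:
    """Time-averaged MSD(tau) with the number of displacement pairs per lag.

    MSD(tau) = mean over t of |x(t + tau) - x(t)|^2, using all overlapping
    pairs; ``n_pairs`` lets non-overlapping estimates be reconstructed.
    MSD(0) = 0 by convention.
    """

    lag_s: np.ndarray
    msd_px2: np.ndarray
    n_pairs: np.ndarray
    pixel_nm: float = 72.0

    @property
    def msd_nm2(self) -> np.ndarray:
        return self.msd_px2 * self.pixel_nm**2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": self.lag_s,
                "msd_px2": self.msd_px2,
                "msd_nm2": self.msd_nm2,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass
class PairSeries:
    """Per-frame interparticle separation and angle for an ordered pair.

    ``theta_deg`` is atan2(dy, dx) for the vector a -> b, in (-180, 180].
    """

    frames: np.ndarray
    d_px: np.ndarray
    theta_deg: np.ndarray
    pixel_nm: float = 72.0

    @property
    def d_nm(self) -> np.ndarray:
        return self.d_px * self.pixel_nm

    @property
    def n(self) -> int:
        return self.frames.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "d_px": self.d_px,
                "d_nm": self.d_nm,
                "theta_deg": self.theta_deg,
            }
        )


@dataclass
class ErrorSeries:
    """Per-frame Euclidean tracked-vs-true distances, in pixels."""

    frames: np.ndarray
    error_px: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.error_px)) if self.error_px.size else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.error_px)) if self.error_px.size else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frames, "error_px": self.error_px})


@dataclass
class BiasCurve:
    """Mean (apparent - true) separation per true-separation bin."""

    bin_center_px: np.ndarray
    mean_error_px: np.ndarray
    counts: np.ndarray


@dataclass
class CubicBiasFit:
    """Cubic polynomial mapping separation -> separation bias, with the
    separation domain it was fitted on; evaluation clamps to that domain."""

    coeffs: np.ndarray  # highest power first, as numpy polyval expects
    domain: tuple[float, float]
    rms_residual_px: float

    def __call__(self, d_px: np.ndarray) -> np.ndarray:
        d = np.asarray(d_px, dtype=float)
        lo, hi = self.domain
        if np.any(d < lo) or np.any(d > hi):
            warnings.warn(
                "separation outside the bias-fit domain; clamping to the edge",
                stacklevel=2,
            )
        return np.polyval(self.coeffs, np.clip(d, lo, hi))


def msd(traj: Trajectory, max_lag: int) -> MsdCurve:
    """Time-averaged MSD over all valid (gap-free) displacement pairs."""
    pos = traj.positions
    n = pos.shape[0]
    if n < max_lag + 1:
        raise ValueError(f"trajectory of {n} frames cannot support lag {max_lag}")
    lags = np.arange(max_lag + 1)
    values = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    counts[0] = n - int(np.any(np.isnan(pos), axis=1).sum())
    for lag in lags[1:]:
        disp = pos[lag:] - pos[:-lag]
        sq = np.sum(disp**2, axis=1)
        valid = np.isfinite(sq)
        counts[lag] = int(valid.sum())
        values[lag] = float(np.mean(sq[valid])) if counts[lag] else np.nan
    return MsdCurve(lags * traj.dt_s, values, counts, pixel_nm=traj.pixel_nm)


def _overlap(a: Trajectory, b: Trajectory):
    start = max(a.start_frame, b.start_frame)
    stop = min(a.start_frame + a.n_frames, b.start_frame + b.n_frames)
    if stop <= start:
        raise ValueError("trajectories share no frames")
    fa = a.positions[start - a.start_frame : stop - a.start_frame]
    fb = b.positions[start - b.start_frame : stop - b.start_frame]
    frames = np.arange(start, stop)
    ok = np.all(np.isfinite(fa), axis=1) & np.all(np.isfinite(fb), axis=1)
    if not ok.any():
        raise ValueError("no frame has both particles localized")
    return frames[ok], fa[ok], fb[ok]


def pair_metrics(traj_a: Trajectory, traj_b: Trajectory) -> PairSeries:
    """Separation and angle series for the ordered pair (a -> b), over the
    frames where both particles are present."""
    if traj_a.pixel_nm != traj_b.pixel_nm:
        raise ValueError("trajectories disagree on pixel size")
    frames, pa, pb = _overlap(traj_a, traj_b)
    delta = pb - pa
    d = np.hypot(delta[:, 0], delta[:, 1])
    theta = np.degrees(np.arctan2(delta[:, 1], delta[:, 0]))
    # atan2 returns (-180, 180]; map -180 to +180 for the stated convention
    theta[theta == -180.0] = 180.0
    return PairSeries(frames, d, theta, pixel_nm=traj_a.pixel_nm)


def rms_error(
    tracked: Trajectory, truth: GroundTruth, particle_id: int | None = None
) -> ErrorSeries:
    """Per-frame Euclidean distance between a tracked trajectory and the
    matching ground-truth particle.

    When ``particle_id`` is None the identity is established by nearest
    neighbor at the first frame both share (ties broken by smaller index).
    """
    pos = tracked.positions
    frames = tracked.frames
    inside = (frames >= 0) & (frames < truth.n_frames)
    valid = inside & np.all(np.isfinite(pos), axis=1)
    if not valid.any():
        raise ValueError("tracked trajectory shares no valid frame with the truth")
    if particle_id is None:
        first = int(np.argmax(valid))
        d0 = np.linalg.norm(
            truth.positions[frames[first]] - pos[first], axis=1
        )
        particle_id = int(np.argmin(d0))  # argmin takes the smaller index on ties
    ref = truth.positions[frames[valid], particle_id, :]
    err = np.linalg.norm(pos[valid] - ref, axis=1)
    return ErrorSeries(frames[valid], err)


def separation_bias_curve(
    pairs_tracked: PairSeries, pairs_truth: PairSeries, n_bins: int = 20
) -> BiasCurve:
    """Mean (apparent - true) separation, binned by true separation into
    equal-count bins."""
    common, ia, ib = np.intersect1d(
        pairs_tracked.frames, pairs_truth.frames, return_indices=True
    )
    if common.size < 10 * n_bins:
        raise ValueError(
            f"need >= {10 * n_bins} common frames for {n_bins} bins, got {common.size}"
        )
    apparent = pairs_tracked.d_px[ia]
    true = pairs_truth.d_px[ib]
    edges = np.quantile(true, np.linspace(0.0, 1.0, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, true, side="right") - 1, 0, n_bins - 1)
    centers, means, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        centers.append(float(np.mean(true[sel])))
        means.append(float(np.mean(apparent[sel] - true[sel])))
        counts.append(int(sel.sum()))
    return BiasCurve(np.array(centers), np.array(means), np.array(counts))


def fit_cubic_bias(curve: BiasCurve) -> CubicBiasFit:
    """Least-squares cubic fit of the binned separation bias."""
    if curve.bin_center_px.size < 4:
        raise ValueError("cubic bias fit needs at least 4 bins")
    if np.ptp(curve.bin_center_px) <= 0:
        raise ValueError("degenerate bias curve: all bins at one separation")
    coeffs = np.polyfit(curve.bin_center_px, curve.mean_error_px, deg=3)
    resid = np.polyval(coeffs, curve.bin_center_px) - curve.mean_error_px
    return CubicBiasFit(
        coeffs,
        (float(curve.bin_center_px.min()), float(curve.bin_center_px.max())),
        float(np.sqrt(np.mean(resid**2))),
    )


def apply_cubic_bias(pairs: PairSeries, fit: CubicBiasFit) -> PairSeries:
    """Subtract the fitted separation bias, evaluated at the apparent
    separation, from the separation series (angle unchanged)."""
    corrected = pairs.d_px - fit(pairs.d_px)
    return PairSeries(
        pairs.frames.copy(),
        np.clip(corrected, 0.0, None),
        pairs.theta_deg.copy(),
        pixel_nm=pairs.pixel_nm,
    )
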