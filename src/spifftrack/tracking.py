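"""Particle detection and sub-pixel refinement with a circular window.

Implements the class of single-pass trackers whose pixel-locking bias the
rest of the package diagnoses and corrects: candidate pixels are local
intensity maxima above a percentile threshold, refined either by a
background-subtracted intensity centroid or by nonlinear least-squares
fitting of a symmetric 2D Gaussian, both restricted to a circular window of
radius ``R`` (window size ``W = 2R + 1``; ``R = 1`` is the five-pixel
"Swiss cross").  Small windows keep nearby particles separable but bias
sub-pixel estimates toward pixel centers; large windows do the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.optimize import least_squares

__all__ = [
    "TrackingConfig",
    "Localization",
    "TrackedSet",
    "Trajectory",
    "detect_candidates",
    "refine_centroid",
    "refine_gaussian",
    "track_movie",
    "link_nearest",
    "identification_fraction",
    "RefinementError",
]


class RefinementError(ValueError):
    """Raised when a window cannot produce a sub-pixel estimate."""


@dataclass(frozen=True)
class TrackingConfig:
    """Detection and refinement settings.

    ``radius_px`` is the circular window radius R (window size W = 2R + 1).
    ``detection_percentile`` sets the intensity threshold for candidate
    local maxima; candidates closer than ``min_separation_px`` (default
    ``2 R``) are pruned brightest-first.  ``refiner`` selects the sub-pixel
    estimator.  ``max_candidates`` optionally keeps only the brightest k
    candidates (useful when the particle count is known).
    """

    radius_px: int = 1
    detection_percentile: float = 99.5
    min_separation_px: float | None = None
    refiner: str = "gaussian_fit"
    max_candidates: int | None = None

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not 0.0 < self.detection_percentile < 100.0:
            raise ValueError("detection_percentile must be in (0, 100)")
        if self.refiner not in ("centroid", "gaussian_fit"):
            raise ValueError("refiner must be 'centroid' or 'gaussian_fit'")

    @property
    def window_size(self) -> int:
        return 2 * self.radius_px + 1

    @property
    def separation(self) -> float:
        return (
            2.0 * self.radius_px
            if self.min_separation_px is None
            else self.min_separation_px
        )


@dataclass
class Localization:
    """One sub-pixel position estimate in one frame.

    ``quality`` is the refinement figure of merit (net window mass for the
    centroid, RMS fit residual for the Gaussian).  ``fallback`` marks
    Gaussian fits that did not converge and fell back to the centroid.
    """

    frame_index: int
    x_px: float
    y_px: float
    quality: float
    radius_used: int
    fallback: bool = False


@dataclass
class TrackedSet:
    """Per-frame localization lists plus the per-frame particle counts."""

    frames: list[list[Localization]]

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.frames], dtype=int)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def all_localizations(self) -> list[Localization]:
        return [loc for frame in self.frames for loc in frame]


@dataclass
class Trajectory:
    """Time-ordered positions of one particle at a fixed frame interval.

    ``positions`` has shape (n, 2) with NaN rows for gap frames;
    ``start_frame`` anchors it in the movie's frame numbering.
    """

    positions: np.ndarray
    dt_s: float = 1.0
    pixel_nm: float = 72.0
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def frames(self) -> np.ndarray:
        return self.start_frame + np.arange(self.n_frames)


def _circular_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets (dx, dy) with Euclidean norm <= radius."""
    r = np.arange(-radius, radius + 1)
    dx, dy = np.meshgrid(r, r)
    keep = dx**2 + dy**2 <= radius**2
    return dx[keep], dy[keep]


def detect_candidates(frame: np.ndarray, cfg: TrackingConfig) -> list[tuple[int, int]]:
    """Find candidate particle pixels: local maxima above the percentile
    threshold, greedily pruned brightest-first so that no two survivors are
    closer than the minimum separation.  Returns integer ``(x, y)`` pixel
    indices sorted brightest-first."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    thr = np.percentile(frame, cfg.detection_percentile)
    is_max = (frame == maximum_filter(frame, size=3, mode="nearest")) & (frame > thr)
    ys, xs = np.nonzero(is_max)
    if xs.size == 0:
        return []
    order = np.argsort(frame[ys, xs])[::-1]
    xs, ys = xs[order], ys[order]
    accepted: list[tuple[int, int]] = []
    min_sep2 = cfg.separation**2
    for x, y in zip(xs, ys):
        if all((x - ax) ** 2 + (y - ay) ** 2 >= min_sep2 for ax, ay in accepted):
            accepted.append((int(x), int(y)))
    if cfg.max_candidates is not None:
        accepted = accepted[: cfg.max_candidates]
    return accepted


def _window(frame: np.ndarray, candidate: tuple[int, int], radius: int):
    cx, cy = candidate
    ny, nx = frame.shape
    if cx - radius < 0 or cy - radius < 0 or cx + radius >= nx or cy + radius >= ny:
        raise RefinementError(
            f"window of radius {radius} around ({cx}, {cy}) crosses the frame edge"
        )
    dx, dy = _circular_offsets(radius)
    vals = frame[cy + dy, cx + dx]
    return dx, dy, vals


def refine_centroid(
    frame: np.ndarray, candidate: tuple[int, int], radius: int
) -> Localization:
    """Background-subtracted intensity centroid over the circular window.

    The local background is the median of the window's perimeter pixels
    (offset norm > R - 1); negative residuals are clipped before weighting.
    Raises :class:`RefinementError` when no net mass remains.
    """
    frame = np.asarray(frame, dtype=float)
    dx, dy, vals = _window(frame, candidate, radius)
    perimeter = dx**2 + dy**2 > (radius - 1) ** 2
    bg = np.median(vals[perimeter])
    w = np.clip(vals - bg, 0.0, None)
    mass = w.sum()
    if mass <= 0:
        raise RefinementError("zero net intensity in refinement window")
    cx, cy = candidate
    x = np.sum(w * (cx + dx + 0.5)) / mass
    y = np.sum(w * (cy + dy + 0.5)) / mass
    return Localization(-1, float(x), float(y), float(mass), radius)


def refine_gaussian(
    frame: np.ndarray, candidate: tuple[int, int], radius: int
) -> Localization:
    """Least-squares fit of a symmetric 2D Gaussian plus constant background
    over the circular window, initialized at the centroid estimate.

    The model is point-sampled at pixel centers, as in standard Gaussian-fit
    trackers; on small windows this truncation is exactly what produces
    pixel locking.  Non-convergent or out-of-window fits fall back to the
    centroid result with ``fallback=True``.
    """
    frame = np.asarray(frame, dtype=float)
    dx, dy, vals = _window(frame, candidate, radius)
    if vals.size < 5:
        raise RefinementError("need at least 5 pixels to fit a Gaussian")
    cx, cy = candidate
    try:
        init = refine_centroid(frame, candidate, radius)
    except RefinementError:
        init = None
    bg0 = float(np.median(vals))
    amp0 = max(float(vals.max() - bg0), 1e-6)
    x0 = init.x_px if init is not None else cx + 0.5
    y0 = init.y_px if init is not None else cy + 0.5
    px = cx + dx + 0.5
    py = cy + dy + 0.5

    def residual(p):
        x, y, a, s, b = p
        return b + a * np.exp(-((px - x) ** 2 + (py - y) ** 2) / (2.0 * s**2)) - vals

    def jac(p):
        x, y, a, s, b = p
        u = px - x
        v = py - y
        g = np.exp(-(u**2 + v**2) / (2.0 * s**2))
        J = np.empty((g.size, 5))
        J[:, 0] = a * g * u / s**2
        J[:, 1] = a * g * v / s**2
        J[:, 2] = g
        J[:, 3] = a * g * (u**2 + v**2) / s**3
        J[:, 4] = 1.0
        return J

    sol = least_squares(
        residual,
        x0=np.array([x0, y0, amp0, 1.0, bg0]),
        jac=jac,
        method="lm",
        max_nfev=100,
    )
    x, y, a, s, b = sol.x
    ok = (
        sol.success
        and np.all(np.isfinite(sol.x))
        and a > 0
        and 0.1 <= abs(s) <= 5.0 * radius
        and abs(x - (cx + 0.5)) <= radius + 0.5
        and abs(y - (cy + 0.5)) <= radius + 0.5
    )
    if not ok:
        if init is None:
            raise RefinementError("Gaussian fit failed and centroid fallback failed")
        return replace(init, fallback=True, quality=float("inf"))
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return Localization(-1, float(x), float(y), rms, radius)


_REFINERS = {"centroid": refine_centroid, "gaussian_fit": refine_gaussian}


def track_movie(frames, cfg: TrackingConfig) -> TrackedSet:
    """Detect and refine particles in every frame of a movie.

    ``frames`` may be any iterable of 2D arrays (including a lazy
    generator).  Failed refinements are dropped, reducing that frame's
    particle count.
    """
    refine = _REFINERS[cfg.refiner]
    out: list[list[Localization]] = []
    for i, frame in enumerate(frames):
        frame_locs: list[Localization] = []
        for cand in detect_candidates(frame, cfg):
            try:
                loc = refine(frame, cand, cfg.radius_px)
            except RefinementError:
                continue
            loc.frame_index = i
            frame_locs.append(loc)
        out.append(frame_locs)
    if not out:
        raise ValueError("track_movie needs at least one frame")
    return TrackedSet(out)


def identification_fraction(tracked: TrackedSet, expected_count: int) -> float:
    """Fraction of frames in which exactly ``expected_count`` particles
    were localized."""
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    return float(np.mean(tracked.counts == expected_count))


def link_nearest(
    tracked: TrackedSet,
    max_step_px: float,
    dt_s: float = 1.0,
    pixel_nm: float = 72.0,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Greedy mutual-nearest-neighbor linking of localizations into
    trajectories.

    In each frame transition, a localization joins the active trajectory
    whose last position is its nearest neighbor, provided the choice is
    mutual and the step is at most ``max_step_px``; ties are broken by
    smaller index so linking is deterministic.  Unmatched localizations
    start new trajectories.  A trajectory missing from up to ``max_gap``
    consecutive frames carries NaN gap rows; beyond that it is closed.
    """
    active: list[dict] = []
    done: list[dict] = []

    for fi, frame_locs in enumerate(tracked.frames):
        pts = np.array([[l.x_px, l.y_px] for l in frame_locs]).reshape(-1, 2)
        used = np.zeros(len(frame_locs), dtype=bool)
        still_active = []
        for traj in active:
            last = traj["pos"][traj["last_valid"]]
            matched = False
            if len(frame_locs) and not used.all():
                d = np.hypot(pts[:, 0] - last[0], pts[:, 1] - last[1])
                d[used] = np.inf
                j = int(np.argmin(d))
                if d[j] <= max_step_px:
                    # mutual check: is this trajectory the nearest active one?
                    others = [
                        np.hypot(*(pts[j] - t["pos"][t["last_valid"]]))
                        for t in active
                        if t is not traj and t["open"]
                    ]
                    if not others or d[j] <= min(others):
                        traj["pos"].append(pts[j].copy())
                        traj["last_valid"] = len(traj["pos"]) - 1
                        traj["gap"] = 0
                        used[j] = True
                        matched = True
            if not matched:
                traj["gap"] += 1
                if traj["gap"] > max_gap:
                    traj["open"] = False
                    done.append(traj)
                    continue
                traj["pos"].append(np.array([np.nan, np.nan]))
            still_active.append(traj)
        active = still_active
        for j in range(len(frame_locs)):
            if not used[j]:
                active.append(
                    {
                        "start": fi,
                        "pos": [pts[j].copy()],
                        "last_valid": 0,
                        "gap": 0,
                        "open": True,
                    }
                )
    done.extend(active)
    done.sort(key=lambda t: (t["start"],))
    out = []
    for traj in done:
        pos = np.array(traj["pos"][: traj["last_valid"] + 1])
        out.append(
            Trajectory(pos, dt_s=dt_s, pixel_nm=pixel_nm, start_frame=traj["start"])
        )
    return out
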