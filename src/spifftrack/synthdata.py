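"""Synthetic ground truth and image synthesis for sub-pixel tracking studies.

Everything downstream of the trackers is benchmarked against data produced
here: static two-particle placements, optically-trapped particle pairs
modelled as overdamped Ornstein--Uhlenbeck (OU) motion in harmonic traps,
drift--diffusion transport of a single emitter, and a renderer that turns
continuous positions into noisy camera frames with a pixel-integrated
Gaussian point-spread function (PSF).

Coordinate convention: pixel ``(i, j)`` spans ``[i, i+1) x [j, j+1)`` with
center ``(i + 0.5, j + 0.5)``; positions are ``(x, y)`` pairs and frame
arrays are indexed ``frame[y, x]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.special import ndtr

BOLTZMANN_J_PER_K = 1.380649e-23

__all__ = [
    "PsfModel",
    "PlacementModel",
    "TrapSimParams",
    "TransportSimParams",
    "GroundTruth",
    "sample_two_particle_positions",
    "simulate_trapped_pair",
    "simulate_transport",
    "downsample_trajectory",
    "render_frame",
    "render_movie",
]


@dataclass(frozen=True)
class PsfModel:
    """Diffraction-limited spot plus camera-noise model.

    amplitude
        Peak intensity (counts above background) of the continuous Gaussian
        ``amplitude * exp(-r^2 / (2 sigma_px^2))`` that is integrated over
        each pixel.  The default gives a peak signal-to-noise ratio of ~10
        against the default background noise.
    sigma_px
        PSF standard deviation in pixels.
    background_mean, background_sd
        Mean and standard deviation (Gaussian read noise) of the background,
        in counts.
    shot_noise
        Apply Poisson noise to the signal photons.
    """

    amplitude: float = 43.0
    sigma_px: float = 1.0
    background_mean: float = 100.0
    background_sd: float = 4.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be > 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")


@dataclass(frozen=True)
class PlacementModel:
    """Static two-particle placement: one anchored, one normally scattered.

    Particle 1 sits at the center of ``anchor_pixel``.  Particle 2 is drawn
    from an axis-independent bivariate normal centered ``offset_mean_px``
    pixels away (offsets are in pixel-index units, so an offset of (5, 0)
    centers particle 2 on the pixel five columns over).
    """

    anchor_pixel: tuple[int, int] = (0, 0)
    offset_mean_px: tuple[float, float] = (5.0, 0.0)
    sigma_x_px: float = 2.0
    sigma_y_px: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_x_px <= 0 or self.sigma_y_px <= 0:
            raise ValueError("placement standard deviations must be > 0")


@dataclass(frozen=True)
class TrapSimParams:
    """Parameters of the overdamped harmonic-trap (OU) pair simulation.

    The defaults emulate two 150 nm particles held in stiff optical traps
    imaged at 72 nm/pixel: stiffness is set so that the stationary per-axis
    positional spread is ~0.7 px, and friction is the Stokes drag of a
    150 nm sphere in water.
    """

    stiffness_n_per_m: float = 1.63e-6
    friction_kg_per_s: float = 1.41e-9
    temperature_k: float = 300.0
    pair_rest_separation_px: float = 6.5
    dt_s: float = 0.5e-6
    n_frames: int = 3200
    pixel_nm: float = 72.0

    def __post_init__(self) -> None:
        for name in ("stiffness_n_per_m", "friction_kg_per_s",
                     "pair_rest_separation_px", "dt_s", "pixel_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.temperature_k < 0:
            raise ValueError("temperature_k must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def stationary_sd_px(self) -> float:
        """Per-axis stationary positional SD, in pixels."""
        var_m2 = BOLTZMANN_J_PER_K * self.temperature_k / self.stiffness_n_per_m
        return float(np.sqrt(var_m2) / (self.pixel_nm * 1e-9))

    @property
    def relaxation_time_s(self) -> float:
        return self.friction_kg_per_s / self.stiffness_n_per_m


@dataclass(frozen=True)
class TransportSimParams:
    """Drift--diffusion motion of a single emitter (transport along a track)."""

    diffusion_px2_per_s: float = 10.0
    drift_px_per_s: float = 5.0
    frame_rate_fps: float = 2000.0
    n_frames: int = 10000
    pixel_nm: float = 100.0

    def __post_init__(self) -> None:
        if self.diffusion_px2_per_s < 0:
            raise ValueError("diffusion must be >= 0")
        if self.frame_rate_fps <= 0:
            raise ValueError("frame_rate_fps must be > 0")
        if self.diffusion_px2_per_s == 0 and self.drift_px_per_s == 0:
            raise ValueError("diffusion and drift cannot both be zero")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


@dataclass
class GroundTruth:
    """True particle positions per frame, in continuous pixel coordinates.

    ``positions`` has shape ``(n_frames, n_particles, 2)`` with the last
    axis ordered ``(x, y)``.
    """

    positions: np.ndarray
    dt_s: float
    pixel_nm: float = 72.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_frames, n_particles, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def shifted(self, dx: float, dy: float) -> "GroundTruth":
        """Return a copy translated by (dx, dy) pixels (e.g. into a frame)."""
        return GroundTruth(self.positions + np.array([dx, dy]), self.dt_s, self.pixel_nm)


def sample_two_particle_positions(
    n: int, placement: PlacementModel, seed: int | np.random.Generator
) -> GroundTruth:
    """Draw ``n`` independent frames of the static two-particle arrangement.

    Particle 1 is fixed at the center of the anchor pixel; particle 2 is
    normally distributed about the pixel center ``anchor + offset_mean_px``
    with independent per-axis standard deviations.
    """
    if n < 1:
        raise ValueError(f"need at least one frame, got n={n}")
    rng = np.random.default_rng(seed)
    ax, ay = placement.anchor_pixel
    p1 = np.array([ax + 0.5, ay + 0.5])
    mean2 = p1 + np.asarray(placement.offset_mean_px, dtype=float)
    p2 = mean2 + rng.normal(
        0.0, [placement.sigma_x_px, placement.sigma_y_px], size=(n, 2)
    )
    pos = np.empty((n, 2, 2))
    pos[:, 0, :] = p1
    pos[:, 1, :] = p2
    # static placements: the frame interval is nominal (1 s) and unused
    return GroundTruth(pos, dt_s=1.0, pixel_nm=72.0)


def _ou_exact(n: int, sd: float, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Exact stationary OU sample path: x_{t+1} = alpha x_t + noise.

    ``sd`` is the stationary standard deviation, ``alpha = exp(-dt/tau)``.
    Uses an AR(1) filter so long paths stay cheap.
    """
    if sd == 0.0:
        return np.zeros(n)
    x0 = rng.normal(0.0, sd)
    w = rng.normal(0.0, sd * np.sqrt(1.0 - alpha**2), size=n - 1)
    rest = _signal.lfilter([1.0], [1.0, -alpha], w, zi=np.array([alpha * x0]))[0]
    return np.concatenate(([x0], rest))


def simulate_trapped_pair(
    params: TrapSimParams, seed: int | np.random.Generator
) -> GroundTruth:
    """Simulate two particles in independent harmonic traps (OU surrogate).

    Each coordinate relaxes toward its trap minimum with time constant
    ``friction/stiffness`` and stationary variance ``k_B T / stiffness``;
    the two trap minima sit ``pair_rest_separation_px`` apart along x.
    Trap 1 is at the origin; callers translate into the camera frame.
    """
    rng = np.random.default_rng(seed)
    sd_px = params.stationary_sd_px
    alpha = float(np.exp(-params.dt_s / params.relaxation_time_s))
    minima = np.array(
        [[0.0, 0.0], [params.pair_rest_separation_px, 0.0]]
    )
    pos = np.empty((params.n_frames, 2, 2))
    for p in range(2):
        for ax in range(2):
            pos[:, p, ax] = minima[p, ax] + _ou_exact(
                params.n_frames, sd_px, alpha, rng
            )
    return GroundTruth(pos, dt_s=params.dt_s, pixel_nm=params.pixel_nm)


def simulate_transport(
    params: TransportSimParams, seed: int | np.random.Generator
) -> GroundTruth:
    """Simulate one particle undergoing drift (along x) plus 2D diffusion.

    Per-frame displacement is ``drift * dt`` along x plus an isotropic
    Gaussian step of per-axis variance ``2 D dt``.  Starts at the origin.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.frame_rate_fps
    step_sd = np.sqrt(2.0 * params.diffusion_px2_per_s * dt)
    steps = rng.normal(0.0, step_sd, size=(params.n_frames - 1, 2))
    steps[:, 0] += params.drift_px_per_s * dt
    pos = np.zeros((params.n_frames, 1, 2))
    pos[1:, 0, :] = np.cumsum(steps, axis=0)
    return GroundTruth(pos, dt_s=dt, pixel_nm=params.pixel_nm)


def downsample_trajectory(truth: GroundTruth, k: int) -> GroundTruth:
    """Keep every k-th frame and scale the frame interval by k."""
    if k < 1:
        raise ValueError("downsampling factor must be >= 1")
    if k > truth.n_frames:
        raise ValueError(
            f"downsampling factor {k} exceeds frame count {truth.n_frames}"
        )
    return GroundTruth(truth.positions[::k].copy(), truth.dt_s * k, truth.pixel_nm)


def _pixel_integrated_spot(
    x: float, y: float, psf: PsfModel, shape: tuple[int, int]
) -> np.ndarray:
    """Expected counts per pixel from one spot: the 2D Gaussian
    ``amplitude * exp(-((u-x)^2+(v-y)^2)/(2 sigma^2))`` integrated over each
    pixel's area (separable erf differences)."""
    ny, nx = shape
    s = psf.sigma_px
    ex = np.arange(nx + 1)
    ey = np.arange(ny + 1)
    # ndtr is the standard normal CDF; integral over [e_i, e_{i+1}]
    gx = np.diff(ndtr((ex - x) / s))
    gy = np.diff(ndtr((ey - y) / s))
    return (psf.amplitude * 2.0 * np.pi * s**2) * np.outer(gy, gx)


def render_frame(
    positions: np.ndarray,
    psf: PsfModel,
    shape: tuple[int, int],
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render one camera frame from continuous particle positions.

    Returns a float array ``shape = (ny, nx)`` of nonnegative counts:
    Gaussian background noise around ``background_mean`` plus, per
    particle, a pixel-integrated Gaussian spot with optional Poisson shot
    noise on the signal.  Spots whose center lies outside the grid are
    truncated (with a warning) rather than rejected.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    ny, nx = shape
    if ny < 8 or nx < 8:
        raise ValueError("frame must be at least 8x8 pixels")
    rng = np.random.default_rng(seed)
    signal_counts = np.zeros(shape)
    for x, y in positions:
        if not (0.0 <= x <= nx and 0.0 <= y <= ny):
            warnings.warn(
                f"spot center ({x:.2f}, {y:.2f}) outside {nx}x{ny} grid; truncated",
                stacklevel=2,
            )
        signal_counts += _pixel_integrated_spot(x, y, psf, shape)
    if psf.shot_noise:
        signal_counts = rng.poisson(signal_counts).astype(float)
    frame = signal_counts + psf.background_mean
    if psf.background_sd > 0:
        frame = frame + rng.normal(0.0, psf.background_sd, size=shape)
    return np.clip(frame, 0.0, None)


def render_movie(
    truth: GroundTruth,
    psf: PsfModel,
    shape: tuple[int, int],
    seed: int,
):
    """Yield one rendered frame per ground-truth frame, deterministically.

    A lazy generator: large movies never need to be held in memory.  Frame
    ``i`` is rendered from the i-th child of ``SeedSequence(seed)``, so the
    movie is reproducible regardless of how it is consumed.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(truth.n_frames)
    for i in range(truth.n_frames):
        yield render_frame(
            truth.positions[i], psf, shape, np.random.default_rng(children[i])
        )
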