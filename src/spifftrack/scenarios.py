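"""Benchmark scenarios: simulate -> render -> track -> correct -> measure.

Three end-to-end pipelines exercise the whole stack under conditions where
pixel locking matters to a different degree:

``two_particle``
    A static anchored particle plus a normally scattered neighbor, used to
    measure the window-size vs. identification tradeoff and the repair of
    the "forbidden angle" artifact.
``trapped_pair``
    Two particles jittering in stiff harmonic traps (sub-pixel motion per
    frame), used to measure the localization error before and after SPIFF
    correction and the second-tier separation-bias correction.
``transport``
    A single emitter with drift + diffusion imaged at high frame rate and
    downsampled, used to show when SPIFF does and does not improve the MSD.

All randomness descends from the single config seed; reports carry a
config hash so every number is reproducible from the stored config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from . import metrics as m
from .spiff import apply_spiff, build_meta_pixel, fit_spiff_map, uniformity_test
from .synthdata import (
    GroundTruth,
    PlacementModel,
    PsfModel,
    TransportSimParams,
    TrapSimParams,
    render_movie,
    sample_two_particle_positions,
    simulate_trapped_pair,
    simulate_transport,
)
from .tracking import TrackedSet, TrackingConfig, Trajectory, track_movie

__all__ = ["ScenarioConfig", "BenchmarkReport", "run_scenario", "snr"]

logger = logging.getLogger("spifftrack")

SCENARIOS = ("two_particle", "trapped_pair", "transport")


@dataclass
class ScenarioConfig:
    """Everything needed to run one benchmark scenario deterministically."""

    scenario: str
    seed: int = 0
    n_frames: int | None = None
    radii: tuple[int, ...] = (1, 2)
    refiner: str = "gaussian_fit"
    detection_percentile: float | None = None
    psf: PsfModel = field(default_factory=PsfModel)
    placement: PlacementModel = field(
        default_factory=lambda: PlacementModel(anchor_pixel=(10, 11))
    )
    trap: TrapSimParams = field(default_factory=TrapSimParams)
    transport: TransportSimParams = field(default_factory=TransportSimParams)
    frame_shape: tuple[int, int] | None = None
    downsample: int = 100
    out_dir: str | None = None
    save_frames: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose {SCENARIOS}")
        self.radii = tuple(int(r) for r in self.radii)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key, sub in (
            ("psf", PsfModel),
            ("placement", PlacementModel),
            ("trap", TrapSimParams),
            ("transport", TransportSimParams),
        ):
            if key in d and isinstance(d[key], dict):
                payload = dict(d[key])
                for tup in ("anchor_pixel", "offset_mean_px"):
                    if tup in payload:
                        payload[tup] = tuple(payload[tup])
                d[key] = sub(**payload)
        for tup in ("radii", "frame_shape"):
            if tup in d and d[tup] is not None:
                d[tup] = tuple(d[tup])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class BenchmarkReport:
    """Scenario results plus provenance (config hash, seed, version)."""

    scenario: str
    seed: int
    config_hash: str
    results: dict

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "results": self.results,
        }


def snr(frame: np.ndarray, position: tuple[float, float], radius: int) -> float:
    """Peak signal-to-noise ratio of a spot.

    (peak - background mean) / background SD, with the peak taken inside a
    window of radius ``radius`` around ``position`` and the background
    statistics from an annulus just outside ``3 * radius``.
    """
    frame = np.asarray(frame, dtype=float)
    ny, nx = frame.shape
    cx, cy = int(position[0]), int(position[1])
    yy, xx = np.mgrid[0:ny, 0:nx]
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    window = r2 <= radius**2
    annulus = (r2 > (3 * radius) ** 2) & (r2 <= (3 * radius + 2) ** 2)
    if not window.any() or not annulus.any():
        raise ValueError("window or background annulus falls outside the frame")
    bg_mean = float(np.mean(frame[annulus]))
    bg_sd = float(np.std(frame[annulus]))
    if bg_sd == 0.0:
        raise ValueError("undefined SNR: background has zero variance")
    return (float(frame[window].max()) - bg_mean) / bg_sd


def _assign_to_truth(tracked: TrackedSet, truth: GroundTruth) -> np.ndarray:
    """Greedily assign localizations to ground-truth particles per frame.

    Returns an (n_frames, n_particles, 2) array of assigned positions, NaN
    where a particle was not localized.  Pairings are made in increasing
    order of distance, each localization and particle used at most once.
    """
    n_frames, n_particles = truth.n_frames, truth.n_particles
    out = np.full((n_frames, n_particles, 2), np.nan)
    for fi, frame_locs in enumerate(tracked.frames[:n_frames]):
        if not frame_locs:
            continue
        pts = np.array([[l.x_px, l.y_px] for l in frame_locs])
        d = np.linalg.norm(
            pts[:, None, :] - truth.positions[fi][None, :, :], axis=2
        )
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_loc = set()
        used_p = set()
        for li, pi in order:
            if li in used_loc or pi in used_p:
                continue
            out[fi, pi] = pts[li]
            used_loc.add(li)
            used_p.add(pi)
    return out


def _masked_truth_traj(truth: GroundTruth, particle: int, mask: np.ndarray) -> Trajectory:
    pos = truth.positions[:, particle, :].copy()
    pos[~mask] = np.nan
    return Trajectory(pos, dt_s=truth.dt_s, pixel_nm=truth.pixel_nm)


def _angle_gap_stats(theta_deg: np.ndarray, lo: float = -15.0, hi: float = 15.0) -> dict:
    """Count empty 1-degree bins of the angle distribution inside (lo, hi)."""
    counts, edges = np.histogram(theta_deg, bins=np.arange(-180.0, 181.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    inside = (centers > lo) & (centers < hi)
    empty = centers[inside][counts[inside] == 0]
    return {
        "window_deg": [lo, hi],
        "n_empty_bins": int(empty.size),
        "empty_bin_centers_deg": empty.tolist(),
    }


def _spawn(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _run_two_particle(config: ScenarioConfig, artifacts: dict) -> dict:
    n = config.n_frames or 10_000
    shape = config.frame_shape or (24, 32)
    truth_ss, render_ss = _spawn(config.seed, 2)
    truth = sample_two_particle_positions(
        n, config.placement, np.random.default_rng(truth_ss)
    )
    frames = np.array(list(render_movie(truth, config.psf, shape, render_ss)))
    artifacts["truth"] = truth
    artifacts["frames"] = frames

    results: dict = {"n_frames": n, "per_radius": {}}
    for radius in config.radii:
        cfg = TrackingConfig(
            radius_px=radius,
            refiner=config.refiner,
            detection_percentile=config.detection_percentile or 99.5,
        )
        t0 = time.perf_counter()
        tracked = track_movie(frames, cfg)
        logger.info(
            "two_particle R=%d: tracked %d frames in %.1f s",
            radius, n, time.perf_counter() - t0,
        )
        ident = float(np.mean(tracked.counts == 2))
        assigned = _assign_to_truth(tracked, truth)
        both = np.all(np.isfinite(assigned).reshape(n, -1), axis=1) & (
            tracked.counts == 2
        )
        assigned[~both] = np.nan

        # SPIFF map from the mobile particle only: the anchored particle's
        # true sub-pixel position never varies, so it cannot inform the map.
        mobile = assigned[both, 1, :]
        mp = build_meta_pixel(mobile, aggregate=False)
        spiff_map = fit_spiff_map(mp)
        corrected = apply_spiff(assigned, spiff_map)

        tr_a = Trajectory(assigned[:, 0, :], truth.dt_s, truth.pixel_nm)
        tr_b = Trajectory(assigned[:, 1, :], truth.dt_s, truth.pixel_nm)
        co_a = Trajectory(corrected[:, 0, :], truth.dt_s, truth.pixel_nm)
        co_b = Trajectory(corrected[:, 1, :], truth.dt_s, truth.pixel_nm)
        pairs_tracked = m.pair_metrics(tr_a, tr_b)
        pairs_corrected = m.pair_metrics(co_a, co_b)
        pairs_truth = m.pair_metrics(
            _masked_truth_traj(truth, 0, both), _masked_truth_traj(truth, 1, both)
        )
        uni = uniformity_test(mp)
        results["per_radius"][str(radius)] = {
            "identification_fraction": ident,
            "n_both_identified": int(both.sum()),
            "meta_pixel_uniformity": uni.to_dict(),
            "angle_gaps_tracked": _angle_gap_stats(pairs_tracked.theta_deg),
            "angle_gaps_corrected": _angle_gap_stats(pairs_corrected.theta_deg),
            "angle_gaps_truth": _angle_gap_stats(pairs_truth.theta_deg),
            "mean_separation_truth_px": float(np.mean(pairs_truth.d_px)),
            "mean_separation_tracked_px": float(np.mean(pairs_tracked.d_px)),
            "mean_separation_corrected_px": float(np.mean(pairs_corrected.d_px)),
        }
        artifacts[f"tracked_R{radius}"] = tracked
        artifacts[f"assigned_R{radius}"] = assigned
        artifacts[f"corrected_R{radius}"] = corrected
        artifacts[f"pairs_R{radius}"] = {
            "truth": pairs_truth, "tracked": pairs_tracked, "corrected": pairs_corrected,
        }
    return results


def _run_trapped_pair(config: ScenarioConfig, artifacts: dict) -> dict:
    trap = config.trap
    if config.n_frames is not None:
        trap = dataclasses.replace(trap, n_frames=config.n_frames)
    shape = config.frame_shape or (24, 32)
    truth_ss, render_ss = _spawn(config.seed, 2)
    truth = simulate_trapped_pair(trap, np.random.default_rng(truth_ss)).shifted(
        13.0, 12.0
    )
    frames = np.array(list(render_movie(truth, config.psf, shape, render_ss)))
    artifacts["truth"] = truth
    artifacts["frames"] = frames

    results: dict = {
        "n_frames": trap.n_frames,
        "stationary_sd_px": trap.stationary_sd_px,
        "per_radius": {},
    }
    corrected_means = []
    for radius in config.radii:
        cfg = TrackingConfig(
            radius_px=radius,
            refiner=config.refiner,
            detection_percentile=config.detection_percentile or 99.5,
        )
        tracked = track_movie(frames, cfg)
        assigned = _assign_to_truth(tracked, truth)

        mp = build_meta_pixel(np.vstack(
            [assigned[:, p, :][np.all(np.isfinite(assigned[:, p, :]), axis=1)]
             for p in range(2)]
        ), aggregate=True)
        spiff_map = fit_spiff_map(mp)
        corrected = apply_spiff(assigned, spiff_map)

        def _errors(est: np.ndarray) -> np.ndarray:
            d = np.linalg.norm(est - truth.positions, axis=2).ravel()
            return d[np.isfinite(d)]

        err_pre = _errors(assigned)
        err_post = _errors(corrected)
        corrected_means.append(float(np.mean(err_post)))

        valid = np.all(np.isfinite(assigned[:, 0, :]), axis=1)
        max_lag = min(50, trap.n_frames - 1)
        msd_truth = m.msd(
            Trajectory(truth.positions[:, 0, :], trap.dt_s, trap.pixel_nm), max_lag
        )
        msd_tracked = m.msd(
            Trajectory(assigned[:, 0, :], trap.dt_s, trap.pixel_nm), max_lag
        )
        msd_corrected = m.msd(
            Trajectory(corrected[:, 0, :], trap.dt_s, trap.pixel_nm), max_lag
        )

        results["per_radius"][str(radius)] = {
            "identification_fraction": float(np.mean(tracked.counts == 2)),
            "mean_error_pre_px": float(np.mean(err_pre)),
            "sd_error_pre_px": float(np.std(err_pre)),
            "mean_error_post_px": float(np.mean(err_post)),
            "sd_error_post_px": float(np.std(err_post)),
            "n_localizations": int(err_pre.size),
            "meta_pixel_uniformity": uniformity_test(mp).to_dict(),
            "msd_mean_abs_err_pre_px2": float(
                np.nanmean(np.abs(msd_tracked.msd_px2[1:] - msd_truth.msd_px2[1:]))
            ),
            "msd_mean_abs_err_post_px2": float(
                np.nanmean(np.abs(msd_corrected.msd_px2[1:] - msd_truth.msd_px2[1:]))
            ),
            "fraction_frames_particle0_tracked": float(np.mean(valid)),
        }
        artifacts[f"tracked_R{radius}"] = tracked
        artifacts[f"assigned_R{radius}"] = assigned
        artifacts[f"corrected_R{radius}"] = corrected
        artifacts[f"msd_R{radius}"] = {
            "truth": msd_truth, "tracked": msd_tracked, "corrected": msd_corrected,
        }

        # second-tier correction: cubic fit of separation bias vs true separation
        both = np.all(np.isfinite(assigned).reshape(trap.n_frames, -1), axis=1)
        pairs_tracked = m.pair_metrics(
            Trajectory(assigned[:, 0, :], trap.dt_s, trap.pixel_nm),
            Trajectory(assigned[:, 1, :], trap.dt_s, trap.pixel_nm),
        )
        pairs_corrected = m.pair_metrics(
            Trajectory(corrected[:, 0, :], trap.dt_s, trap.pixel_nm),
            Trajectory(corrected[:, 1, :], trap.dt_s, trap.pixel_nm),
        )
        pairs_truth = m.pair_metrics(
            _masked_truth_traj(truth, 0, both), _masked_truth_traj(truth, 1, both)
        )
        try:
            curve = m.separation_bias_curve(pairs_corrected, pairs_truth)
            fit = m.fit_cubic_bias(curve)
            pairs_second = m.apply_cubic_bias(pairs_corrected, fit)
            common, ia, ib = np.intersect1d(
                pairs_second.frames, pairs_truth.frames, return_indices=True
            )
            results["per_radius"][str(radius)]["separation_abs_err_px"] = {
                "tracked": float(np.mean(np.abs(
                    pairs_tracked.d_px[ia] - pairs_truth.d_px[ib]))),
                "spiff": float(np.mean(np.abs(
                    pairs_corrected.d_px[ia] - pairs_truth.d_px[ib]))),
                "spiff_plus_cubic": float(np.mean(np.abs(
                    pairs_second.d_px[ia] - pairs_truth.d_px[ib]))),
            }
            artifacts[f"bias_fit_R{radius}"] = fit
        except ValueError:
            pass
    results["mean_error_post_both_radii_px"] = float(np.mean(corrected_means))
    return results


def _run_transport(config: ScenarioConfig, artifacts: dict) -> dict:
    params = config.transport
    if config.n_frames is not None:
        params = dataclasses.replace(params, n_frames=config.n_frames)
    shape = config.frame_shape or (96, 192)
    start = np.array([40.0, shape[0] / 2.0])
    truth_ss, render_ss = _spawn(config.seed, 2)
    truth = simulate_transport(params, np.random.default_rng(truth_ss)).shifted(
        *start
    )
    radius = config.radii[0]
    cfg = TrackingConfig(
        radius_px=radius,
        refiner=config.refiner,
        detection_percentile=config.detection_percentile or 99.95,
        max_candidates=1,
    )
    # stream the rendering: transport movies are long and never stored whole
    tracked = track_movie(render_movie(truth, config.psf, shape, render_ss), cfg)
    assigned = _assign_to_truth(tracked, truth)
    pos = assigned[:, 0, :]
    finite = np.all(np.isfinite(pos), axis=1)
    mp = build_meta_pixel(pos[finite], aggregate=True)
    spiff_map = fit_spiff_map(mp)
    corrected = apply_spiff(pos, spiff_map)

    def _msd_triplet(truth_pos, est, corr, dt, max_lag):
        t = m.msd(Trajectory(truth_pos, dt, params.pixel_nm), max_lag)
        e = m.msd(Trajectory(est, dt, params.pixel_nm), max_lag)
        c = m.msd(Trajectory(corr, dt, params.pixel_nm), max_lag)
        return t, e, c

    max_lag_full = 10
    t_full, e_full, c_full = _msd_triplet(
        truth.positions[:, 0, :], pos, corrected, truth.dt_s, max_lag_full
    )
    err_pre = np.abs(e_full.msd_px2[1:] - t_full.msd_px2[1:])
    err_post = np.abs(c_full.msd_px2[1:] - t_full.msd_px2[1:])

    k = config.downsample
    t_ds, e_ds, c_ds = _msd_triplet(
        truth.positions[::k, 0, :], pos[::k], corrected[::k], truth.dt_s * k,
        min(3, pos[::k].shape[0] - 1),
    )
    rel = np.abs(c_ds.msd_px2[1:] - e_ds.msd_px2[1:]) / e_ds.msd_px2[1:]

    results = {
        "n_frames": params.n_frames,
        "frame_rate_fps": params.frame_rate_fps,
        "downsample_factor": k,
        "fraction_tracked": float(np.mean(finite)),
        "meta_pixel_uniformity": uniformity_test(mp).to_dict(),
        "full_rate": {
            "msd_abs_err_pre_px2": err_pre.tolist(),
            "msd_abs_err_post_px2": err_post.tolist(),
            "msd_error_reduction_px2": float(np.nanmean(err_pre - err_post)),
        },
        "downsampled": {
            "frame_rate_fps": params.frame_rate_fps / k,
            "rel_msd_change": rel.tolist(),
            "max_rel_msd_change": float(np.nanmax(rel)),
        },
    }
    artifacts.update(
        truth=truth, tracked=tracked, assigned=assigned, corrected=corrected,
        msd_full={"truth": t_full, "tracked": e_full, "corrected": c_full},
        msd_downsampled={"truth": t_ds, "tracked": e_ds, "corrected": c_ds},
    )
    return results


_RUNNERS = {
    "two_particle": _run_two_particle,
    "trapped_pair": _run_trapped_pair,
    "transport": _run_transport,
}


def run_scenario(config: ScenarioConfig, artifacts: dict | None = None) -> BenchmarkReport:
    """Run one benchmark scenario end to end.

    Pass a dict as ``artifacts`` to receive the intermediate objects
    (ground truth, frames, tracked sets, corrected positions, MSD curves).
    With ``config.out_dir`` set, the canonical tables (truth.csv,
    localizations_R*.csv, report.json, optionally frames.tif) are written
    there.
    """
    artifacts = {} if artifacts is None else artifacts
    t0 = time.perf_counter()
    try:
        results = _RUNNERS[config.scenario](config, artifacts)
    except Exception as exc:  # attribute the failure to its stage
        raise RuntimeError(
            f"scenario {config.scenario!r} failed (seed={config.seed}): {exc}"
        ) from exc
    logger.info("scenario %s finished in %.1f s", config.scenario, time.perf_counter() - t0)
    report = BenchmarkReport(
        scenario=config.scenario,
        seed=config.seed,
        config_hash=config.hash(),
        results=results,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "truth" in artifacts:
            sio.write_truth(artifacts["truth"], out / "truth.csv")
        for key, value in artifacts.items():
            if key.startswith("tracked_R") and isinstance(value, TrackedSet):
                sio.write_localizations(value, out / f"localizations_{key[8:]}.csv")
        if isinstance(artifacts.get("tracked"), TrackedSet):
            sio.write_localizations(artifacts["tracked"], out / "localizations.csv")
        if config.save_frames and "frames" in artifacts:
            sio.write_frames_tiff(artifacts["frames"], out / "frames.tif")
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
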