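"""Localization error of a trapped particle pair, before and after SPIFF.

Simulates two particles jittering in stiff harmonic traps (overdamped
Langevin motion, sub-pixel displacement per frame), renders noisy frames,
tracks them with R = 1 and R = 2 Gaussian-fit windows, and compares the
mean tracked-vs-true error before and after the meta-pixel correction.
"""

from spifftrack import ScenarioConfig, run_scenario

report = run_scenario(
    ScenarioConfig(scenario="trapped_pair", seed=0, n_frames=1600)
)
res = report.results
print(f"trap jitter: {res['stationary_sd_px']:.2f} px SD per axis, "
      f"{res['n_frames']} frames")
for radius, r in res["per_radius"].items():
    print(
        f"R={radius}: mean error {r['mean_error_pre_px']:.3f} px tracked -> "
        f"{r['mean_error_post_px']:.3f} px after SPIFF "
        f"(meta-pixel {'locked' if r['meta_pixel_uniformity']['locked'] else 'uniform'})"
    )
    if "separation_abs_err_px" in r:
        s = r["separation_abs_err_px"]
        print(
            f"      pair separation |error|: {s['tracked']:.3f} px tracked, "
            f"{s['spiff']:.3f} px SPIFF, {s['spiff_plus_cubic']:.3f} px "
            "after the cubic separation-bias fit"
        )
print("The correction uniformizes the sub-pixel distribution; how much of the")
print("mean error it removes depends on how much of that error is systematic")
print("bias rather than photon-noise scatter (see docs/methods.md).")
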