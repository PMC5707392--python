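"""When does the correction improve the MSD?  A frame-rate experiment.

A single emitter undergoing drift + diffusion is imaged at 2000 FPS, where
per-frame displacements are sub-pixel, and the same trajectory is
downsampled 100x to 20 FPS, where displacements span multiple pixels.
Sub-pixel corrections matter only in the first regime.
"""

from spifftrack import ScenarioConfig, run_scenario

report = run_scenario(
    ScenarioConfig(scenario="transport", seed=0, n_frames=6000)
)
res = report.results
full = res["full_rate"]
ds = res["downsampled"]
print(f"{res['n_frames']} frames at {res['frame_rate_fps']:.0f} FPS, "
      f"{100*res['fraction_tracked']:.1f}% tracked")
print(f"2000 FPS: mean |MSD error| {sum(full['msd_abs_err_pre_px2'])/10:.3f} px^2 "
      f"tracked, reduction after SPIFF {full['msd_error_reduction_px2']:+.4f} px^2")
print(f"{ds['frame_rate_fps']:.0f} FPS: correction changes the MSD by at most "
      f"{100*ds['max_rel_msd_change']:.1f}%")
print("At high frame rate the sub-pixel correction measurably reduces the MSD")
print("error; once displacements are much larger than a pixel the correction")
print("is negligible relative to the MSD itself.")
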