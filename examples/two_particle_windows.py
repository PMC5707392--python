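"""Window-size tradeoff for two closely spaced particles.

Renders a static particle pair (one anchored at a pixel center, one
normally scattered ~5 px away), tracks it with circular windows R = 1 and
R = 2, and reports how often exactly two particles are identified and
whether the meta-pixel shows locking.  Small windows separate close
particles better but bias sub-pixel positions more.
"""

from spifftrack import ScenarioConfig, run_scenario

report = run_scenario(
    ScenarioConfig(scenario="two_particle", seed=0, n_frames=2000)
)
for radius, res in report.results["per_radius"].items():
    uni = res["meta_pixel_uniformity"]
    print(
        f"R={radius} (window {2*int(radius)+1}x{2*int(radius)+1}): "
        f"two particles identified in {100*res['identification_fraction']:.1f}% "
        f"of frames; meta-pixel {'locked' if uni['locked'] else 'uniform'} "
        f"(chi2_x={uni['x']['chi2']:.0f}, p={uni['x']['p']:.1e})"
    )
print("Identification drops as the window grows (close pairs merge), while")
print("the sub-pixel bias shrinks: the tradeoff that motivates correcting")
print("small-window localizations instead of enlarging the window.")
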