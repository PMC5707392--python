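# Config for `spifftrack benchmark examples/trapped_pair_benchmark.yaml`
# Short trapped-pair run: simulate -> render -> track (R=1,2) -> SPIFF ->
# error/MSD report written to the output directory.
scenario: trapped_pair
seed: 0
n_frames: 800
radii: [1, 2]
refiner: gaussian_fit
psf:
  amplitude: 43.0
  sigma_px: 1.0
  background_mean: 100.0
  background_sd: 4.0
  shot_noise: true
trap:
  stiffness_n_per_m: 1.63e-6
  friction_kg_per_s: 1.41e-9
  temperature_k: 300.0
  pair_rest_separation_px: 6.5
  dt_s: 0.5e-6
  n_frames: 800
  pixel_nm: 72.0
out_dir: scratch/trapped_benchmark
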