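# Forearm domain: gel pad / epidermis / dermis / muscle layers with embedded
# vessels, artery, vein, and bone; per-tissue parameters sampled from the
# documented uniform/Gaussian laws (dermis & muscle bvf 1%, oxygenation
# 80 +/- 10%; artery 95 +/- 5%; vein 70 +/- 10%; vessels U(0, 100)%;
# epidermis melanin 2.2 +/- 1%; bone water 19 +/- 1%); 26 wavelengths.
dataset_kind: forearm
wavelengths: {start: 700, stop: 950, step: 10}
n_spectra: 100000
grid_shape: [256, 128]
voxel_size_mm: 0.1
fluence_model: layered
noise_sigma_frac: 0.003
cnr_threshold: 2.0
lsd_profile: desk
seed: 1234
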