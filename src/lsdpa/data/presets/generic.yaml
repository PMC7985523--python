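# Generic tissue domain: random vessels (100% blood volume) in a homogeneous
# background with 0.5% blood volume fraction and mu_s' = 10 cm^-1; every
# structure shares one sO2 drawn uniformly on [0, 1]; 26 wavelengths
# 700-950 nm in 10 nm steps; slab-beam illumination.
dataset_kind: generic
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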