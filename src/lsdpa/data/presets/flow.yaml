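# Flow-phantom domain: one blood tube (150 g/L, sO2 U(0,1), radius
# U(0.5, 2.5) mm) in agar with mu_s' = 5 cm^-1 and water content U(50, 100)%;
# the 17 acquisition wavelengths; pencil-beam illumination.
dataset_kind: flow
wavelengths: [660, 664, 680, 684, 694, 700, 708, 715, 730, 735, 760, 770, 775, 779, 800, 850, 950]
n_spectra: 100000
grid_shape: [256, 128]
voxel_size_mm: 0.1
fluence_model: layered
noise_sigma_frac: 0.003
cnr_threshold: 2.0
lsd_profile: desk
seed: 1234
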