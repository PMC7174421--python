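# Stage-10 basal F-actin lattice: 9 um AP cell spacing over ten cells,
# DV-oriented fibers, central/lateral allocation 0.7, interfacial filopodia.
scene_kind: fiber
calibration: {pixel_size: 0.2, frame_interval: 1.0, axis_frame: 0.0}
n_cells_ap: 10
n_cells_dv: 6
cell_len_ap: 9.0
cell_len_dv: 10.0
director_kappa: 8.0
central_fraction: 0.7
filopodia_per_cell: 4
noise_sigma: 0.05
seed: 0
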