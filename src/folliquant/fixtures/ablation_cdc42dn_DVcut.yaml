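# Single-cell-scale ablation in the Cdc42DN regime: cut parallel to DV.
# Ground-truth AP recoil 0.02 um/s (see ablation_cdc42dn_APcut.yaml).
scene_kind: ablation
calibration: {pixel_size: 0.2, frame_interval: 2.0, axis_frame: 0.0}
n_cells_ap: 4
n_cells_dv: 4
cell_len_ap: 9.0
cell_len_dv: 10.0
director_kappa: 2.0
central_fraction: 0.45
fiber_amp: 60.0
recoil_vmax: 0.02
recoil_lambda: 40.0
cut_axis: dv
cut_length: 6.0
cut_halfwidth: 0.5
noise_sigma: 0.05
seed: 0
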