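# Tissue-scale ablation over a 100 um line parallel to DV.
# Ground truth: AP recoil 0.07 um/s.
scene_kind: ablation
calibration: {pixel_size: 0.2, frame_interval: 2.0, axis_frame: 0.0}
n_cells_ap: 10
n_cells_dv: 11
cell_len_ap: 9.0
cell_len_dv: 10.0
director_kappa: 8.0
central_fraction: 0.7
recoil_vmax: 0.07
recoil_lambda: 40.0
cut_axis: dv
cut_length: 100.0
cut_halfwidth: 0.5
noise_sigma: 0.05
seed: 0
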