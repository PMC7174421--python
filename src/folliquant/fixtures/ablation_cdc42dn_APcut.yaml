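# Single-cell-scale ablation in the Cdc42DN regime (disorganised, weaker
# fibers, little recoil): cut parallel to AP. Ground-truth DV recoil
# 0.04 um/s; paired with the DV cut (0.02 um/s) it encodes the factor-2
# DV/AP anisotropy of the perturbed genotype.
scene_kind: ablation
calibration: {pixel_size: 0.2, frame_interval: 2.0, axis_frame: 0.0}
n_cells_ap: 4
n_cells_dv: 4
cell_len_ap: 9.0
cell_len_dv: 10.0
director_kappa: 2.0
central_fraction: 0.45
fiber_amp: 60.0
recoil_vmax: 0.04
recoil_lambda: 40.0
cut_axis: ap
cut_length: 6.0
cut_halfwidth: 0.5
noise_sigma: 0.05
seed: 0
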