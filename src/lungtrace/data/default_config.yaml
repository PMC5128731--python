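# Default lungtrace pipeline configuration
align_gate_deg: 15.0
bone_threshold: 200.0
opening_radius: 3
erosion_max_iters: 20
dp_band_fraction: 0.3333333333333333
arc_step: 0.3
poly_degree: 2
half_window: 4
max_passes: 12
t1_ratio: 0.6
t2_perimeter_tol: 0.01
march_step: 5
min_lung_area_px: 50
radiological_labels: false
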