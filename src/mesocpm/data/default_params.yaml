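contact_energy:
  cell_medium: 8.0
  cell_substrate: 4.0
  cell_cell: 5.0
  medium_substrate: 7.0
  medium_medium: 0.0
lambda_volume: 2.0
v_target: 125
temperature: 24.0
lambda_tissue: 50.0
lambda_lamellipodia: 800.0
lambda_follower_substrate: 2.0
link_target_length: 5.0
substrate_link_target_length: 3.0
zeta_lamellipodia: 0.25
zeta_substrate: 0.25
zeta_tissue: 0.0
chi_lamellipodia: 12.0
kappa: 6.0
bias_toward: far
lamellipodium_reach_tolerance: 1.0
max_reformed_neighbors: 4
leader_rows: bottom
itr_gap: 40
n_mcs: 1440
mcs_per_sample: 200
seconds_per_mcs: 5.0
microns_per_voxel: 6.0
seed: 0
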