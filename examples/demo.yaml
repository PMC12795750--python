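# Desk-scale demo profile: 200 tracts across 4 metro areas plus a nonmetro
# stratum, with nonzero transport and occupational-sorting effects.
generator:
  n_metro_areas: 4
  tracts_per_metro: 40
  nonmetro_tracts: 40
  blocks_per_tract: [2, 4]
  mean_tract_population: 2500
  minority_cluster_strength: 1.0
  beta_transport: 5.0
  beta_occupation: 1.0
  redline_fraction: 0.5
  discrimination_fraction: 0.5
  seed: 1
transport_threshold: 55.0
transport_uncertainty_sd: 2.0
transport_iterations: 500
workplace_threshold: 85.0
workplace_iterations: 500
n_boot: 100
quintile_mode: per_metro
seed: 1
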