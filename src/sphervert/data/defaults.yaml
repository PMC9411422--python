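# Reference parameter set for the two morphogenetic phases.
# Mechanical parameters, cell-count schedules and thresholds follow the
# published spider-embryo model; growth rates are in um^2 per unit model
# time (the implementation's time normalisation, see docs/methods.md).

radius_um: 270.0
vertex_spring_constant: 30.0
boundary_beta0_um: 40.0

events:
  t1_min_edge_um: 3.0
  t1_new_edge_um: 3.5
  t2_min_area_um2: 50.0

germ_disc:
  t_end: 1.0
  dt: 1.0e-4
  initial_cells: 64
  target_cells: 1500
  initial_area0_um2: 6400.0
  preferred_perimeter_um: 0.0
  differentiation_time: 0.5
  abembryonic_count: 100
  cycle_mean: 0.2
  cycle_sd: 0.05
  first_division_window: 0.25
  cell_types:
    embryonic:
      alpha: 1.0
      beta0: 1.0
      gamma: 2.5
      k_fd: 0.0
      G: 0.0
      divides: true
      growth_um2_per_time: 0.0
    abembryonic:
      alpha: 1.0
      beta0: 1.0
      gamma: 0.5
      k_fd: 0.0
      G: 0.0
      divides: false
      growth_um2_per_time: 8000.0

germ_band:
  t_end: 1.0
  dt: 1.0e-3
  initial_cells: 1500
  target_cells: 6000
  initial_area0_um2: 200.0
  preferred_perimeter_um: 0.0
  extraembryonic_count: 150
  disc_area_fraction: 0.295
  dorsal_tilt_deg: 25.0
  cycle_mean: 0.5
  cycle_sd: 0.1
  first_division_window: 0.25
  cell_types:
    embryonic:
      alpha: 1.0
      beta0: 1.0
      gamma: 0.5
      k_fd: 0.1
      G: 10.0
      divides: true
      growth_um2_per_time: 0.0
    extraembryonic:
      alpha: 0.1
      beta0: 0.1
      gamma: 0.15
      k_fd: 0.0
      G: 0.0
      divides: false
      growth_um2_per_time: 4800.0
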