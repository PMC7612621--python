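# Idealized-ventricle inflation defaults with the transversely isotropic
# Fung-Guccione material.  The truncated-ellipsoid dimensions, endocardial
# pressure magnitude and active-stress ramp are configuration (desk-scale
# defaults below), not published constants.
mesh:
  geometry: ellipsoid
  r_s_endo: 7.0     # mm
  r_l_endo: 17.0    # mm
  r_s_epi: 10.0     # mm
  r_l_epi: 20.0     # mm
  truncation_z: 5.0 # mm, base plane
  resolution: 2
  helix_endo_deg: 90.0
  helix_epi_deg: -90.0

discretization:
  technology: projection

material:
  family: FUNG_GUCCIONE
  split: AS
  theta: LOG_J
  # kappa = 1000 kPa for the penalty formulation; stabilized technologies
  # run fully incompressible (1/kappa = 0)
  kappa_kPa: 1000.0
  incompressible: true
  params:
    a: 2.0      # kPa
    b_f: 8.0
    b_t: 2.0
    b_fs: 4.0

loads:
  n_steps: 10
  endo_pressure_kpa: 1.0
  active_stress_kpa: 0.0

solver:
  rtol: 1.0e-6
  max_iterations: 25
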