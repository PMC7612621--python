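# Idealized-ventricle inflation defaults with the orthotropic
# Holzapfel-Ogden material (human-myocardium parameter set; compressed
# fibers excluded by flooring the fourth invariants at 1).
mesh:
  geometry: ellipsoid
  r_s_endo: 7.0
  r_l_endo: 17.0
  r_s_epi: 10.0
  r_l_epi: 20.0
  truncation_z: 5.0
  resolution: 2
  helix_endo_deg: 90.0
  helix_epi_deg: -90.0

discretization:
  technology: projection

material:
  family: HOLZAPFEL_OGDEN
  split: AS          # or WAS: anisotropic terms on the unsplit C
  theta: LOG_J
  kappa_kPa: 1000.0
  incompressible: true
  params:
    a: 0.809      # kPa
    b: 7.474
    a_f: 1.911    # kPa
    b_f: 22.063
    a_n: 0.227    # kPa
    b_n: 34.802
    a_fs: 0.547   # kPa
    b_fs: 5.691

loads:
  n_steps: 10
  endo_pressure_kpa: 1.0
  active_stress_kpa: 0.0

solver:
  rtol: 1.0e-6
  max_iterations: 25
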