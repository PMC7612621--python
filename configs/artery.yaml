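# Artery benchmark defaults: extension + torsion + inflation of a
# thick-walled tube (R1 = 8 mm, R2 = 10 mm, H = 10 mm), two symmetric
# fiber families at 40 degrees to the circumferential axis.
mesh:
  R1: 8.0          # mm, inner radius
  R2: 10.0         # mm, outer radius
  H: 10.0          # mm, height
  level: 1         # uniform refinement level (cells = 960 * level^3 hexes)
  cells: tet       # tet | hex
  fiber_angle_deg: 40.0

discretization:
  technology: projection   # p0_penalty | equal_order | projection | mini

material:
  family: GHT_ARTERY
  split: AS
  theta: J_MINUS_1
  # kappa = 5000 kPa for the penalty technologies; the stabilized
  # technologies run fully incompressible (1/kappa = 0)
  kappa_kPa: 5000.0
  incompressible: true
  params:
    mu: 10.0       # kPa
    k1: 500.0      # kPa
    k2: 2.0        # dimensionless

loads:
  n_steps: 25
  dirichlet:
    - {tag: BOTTOM, type: fixed}
    - {tag: TOP, type: translation_rotation_z, translation: [0.0, 0.0, 2.0], angle_deg: 60.0}
  followers:
    - {tag: INNER, pressure: 500.0, units: mmHg}

solver:
  rtol: 1.0e-6
  max_iterations: 25
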