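"""Turn-key benchmark drivers and deterministic test fixtures.

The artery driver reproduces the extension-inflation-torsion benchmark of a
thick-walled cylindrical tube (R1 = 8 mm, R2 = 10 mm, H = 10 mm) with two
symmetric fiber families at +/-40 degrees to the circumferential direction:
the bottom is clamped, the top is ramped to a 2 mm axial displacement
combined with a 60 degree torsion, and a follower pressure on the inner wall
is ramped to 500 mmHg.  The material is a neo-Hookean matrix (mu = 10 kPa)
with exponential fiber reinforcement (k1 = 500 kPa, k2 = 2.0); the penalty
technologies use kappa = 5000 kPa while the stabilized saddle-point
technologies run fully incompressible (1/kappa = 0).  The default schedule
uses 25 linear load steps.

The ellipsoid driver runs passive inflation followed by a prescribed
active-stress ramp on a truncated-ellipsoid idealized ventricle, with either
the transversely isotropic Guccione material (a = 2 kPa, b_f = 8, b_t = 2,
b_fs = 4, Theta = ln J; kappa = 1000 kPa for the penalty formulation) or an
orthotropic Holzapfel-Ogden material.  The endocardial pressure magnitude
and active-tension ramp are configuration (the published benchmark
definition keeps them in a companion reference), with mild defaults chosen
for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forms import Discretization
from .materials import MaterialModel, VolumetricLaw
from .meshing import (
    Mesh,
    generate_box_hex,
    generate_truncated_ellipsoid,
    generate_tube_hex,
    hex_to_tet,
    assign_tube_fibers,
)
from .postprocess import (
    FieldReport,
    cauchy_field,
    cylindrical_components,
    deformed_centroids,
    jacobian_stats,
    probe,
)
from .solver import (
    DirichletSpec,
    FollowerSpec,
    LoadProgram,
    NewtonSettings,
    run_load_program,
)

__all__ = [
    "ArteryConfig",
    "EllipsoidConfig",
    "run_artery",
    "run_ellipsoid",
    "make_fixture",
    "FIXTURES",
]

# Artery benchmark constants (geometry mm, moduli kPa, loads as printed).
ARTERY_R1 = 8.0
ARTERY_R2 = 10.0
ARTERY_H = 10.0
ARTERY_FIBER_ANGLE_DEG = 40.0
ARTERY_MU = 10.0
ARTERY_K1 = 500.0
ARTERY_K2 = 2.0
ARTERY_KAPPA = 5000.0
ARTERY_PRESSURE_MMHG = 500.0
ARTERY_AXIAL_MM = 2.0
ARTERY_TORSION_DEG = 60.0
ARTERY_N_STEPS = 25

DESK_SCALE_MAX_LEVEL = 3
DESK_SCALE_MAX_CELLS = 100_000


@dataclass
class ArteryConfig:
    level: int = 1
    technology: str = "projection"
    cells: str = "tet"  # tet | hex
    split: str = "AS"
    n_steps: int = ARTERY_N_STEPS
    pressure_mmHg: float = ARTERY_PRESSURE_MMHG
    axial_mm: float = ARTERY_AXIAL_MM
    torsion_deg: float = ARTERY_TORSION_DEG
    allow_large: bool = False
    settings: NewtonSettings = field(default_factory=NewtonSettings)


def artery_mesh(level: int, cells: str = "tet") -> Mesh:
    mesh = generate_tube_hex(ARTERY_R1, ARTERY_R2, ARTERY_H, level)
    if cells == "tet":
        mesh = hex_to_tet(mesh)
    elif cells != "hex":
        raise ValueError("cells must be 'tet' or 'hex'")
    return assign_tube_fibers(mesh, ARTERY_FIBER_ANGLE_DEG)


def artery_material(technology: str, split: str = "AS") -> MaterialModel:
    """GHT artery material; penalty technologies get kappa = 5000 kPa,
    stabilized technologies run fully incompressible."""
    incompressible = technology in ("projection", "mini")
    return MaterialModel(
        family="GHT_ARTERY",
        split=split,
        params={"mu": ARTERY_MU, "k1": ARTERY_K1, "k2": ARTERY_K2},
        volumetric=VolumetricLaw(
            theta_kind="J_MINUS_1",
            kappa=ARTERY_KAPPA,
            incompressible=incompressible,
        ),
    )


def artery_program(config: ArteryConfig) -> LoadProgram:
    return LoadProgram(
        n_steps=config.n_steps,
        dirichlet=[
            DirichletSpec.fixed("BOTTOM"),
            DirichletSpec.translation_rotation_z(
                "TOP", [0.0, 0.0, config.axial_mm], config.torsion_deg
            ),
        ],
        followers=[FollowerSpec("INNER", config.pressure_mmHg, "mmHg")],
    )


#: Convention for the mesh-convergence evaluation points: A on the inner
#: wall at mid-height, B on the outer wall at mid-height.
POINT_A = (ARTERY_R1, 0.0, ARTERY_H / 2.0)
POINT_B = (ARTERY_R2, 0.0, ARTERY_H / 2.0)


def run_artery(config: ArteryConfig | None = None):
    """Run the artery benchmark; returns (SolveReport, FieldReport, problem,
    final state)."""
    config = config or ArteryConfig()
    if config.level > DESK_SCALE_MAX_LEVEL and not config.allow_large:
        raise ValueError(
            f"refinement level {config.level} exceeds the desk-scale guard; "
            "pass allow_large=True to override"
        )
    mesh = artery_mesh(config.level, config.cells)
    disc = Discretization(
        config.technology, mesh.cell_kind
    )
    material = artery_material(config.technology, config.split)
    program = artery_program(config)
    history, report, problem = run_load_program(
        mesh, disc, material, program, config.settings
    )
    state = history[-1]
    fr = FieldReport()
    if report.completed:
        fr.cauchy = cauchy_field(problem, state)
        mean, std, per_cell = jacobian_stats(problem, state)
        fr.det_F = per_cell
        fr.summaries["detF_mean"] = mean
        fr.summaries["detF_std"] = std
        fr.cylindrical = cylindrical_components(
            fr.cauchy, deformed_centroids(problem, state)
        )
        for name, pt in (("A", POINT_A), ("B", POINT_B)):
            fr.probes[f"u_{name}"] = probe(mesh, state.u, pt)
    return report, fr, problem, state


# --- ellipsoid -------------------------------------------------------------


@dataclass
class EllipsoidConfig:
    material: str = "FUNG_GUCCIONE"  # or HOLZAPFEL_OGDEN
    technology: str = "projection"
    split: str = "AS"
    resolution: int = 2
    endo_pressure_kpa: float = 1.0
    active_stress_kpa: float = 0.0  # peak prescribed S_a after inflation
    kappa_f_active: float = 0.0
    n_steps: int = 10
    allow_large: bool = False
    settings: NewtonSettings = field(default_factory=NewtonSettings)


def ellipsoid_material(name: str, technology: str, split: str = "AS"):
    incompressible = technology in ("projection", "mini")
    if name == "FUNG_GUCCIONE":
        return MaterialModel(
            family="FUNG_GUCCIONE",
            split="AS",
            params={"a": 2.0, "b_f": 8.0, "b_t": 2.0, "b_fs": 4.0},
            volumetric=VolumetricLaw("LOG_J", 1000.0, incompressible),
        )
    if name == "HOLZAPFEL_OGDEN":
        return MaterialModel(
            family="HOLZAPFEL_OGDEN",
            split=split,
            params={
                "a": 0.809,
                "b": 7.474,
                "a_f": 1.911,
                "b_f": 22.063,
                "a_n": 0.227,
                "b_n": 34.802,
                "a_fs": 0.547,
                "b_fs": 5.691,
            },
            volumetric=VolumetricLaw("LOG_J", 1000.0, incompressible),
        )
    raise ValueError(f"unknown ellipsoid material {name!r}")


def run_ellipsoid(config: EllipsoidConfig | None = None):
    """Passive inflation (+ optional active contraction ramp) of the
    idealized ventricle; returns (SolveReport, FieldReport, problem, state).

    The pseudo-time ramp inflates to the endocardial pressure over the first
    half of the schedule and ramps the prescribed active stress over the
    second half (when a nonzero peak is configured).
    """
    config = config or EllipsoidConfig()
    mesh = generate_truncated_ellipsoid(resolution=config.resolution)
    if mesh.n_cells > DESK_SCALE_MAX_CELLS and not config.allow_large:
        raise ValueError("ellipsoid mesh exceeds the desk-scale guard")
    disc = Discretization(config.technology, mesh.cell_kind)
    material = ellipsoid_material(config.material, config.technology, config.split)

    if config.active_stress_kpa:
        active = lambda t: config.active_stress_kpa * max(0.0, 2.0 * t - 1.0)
        pressure_ramp = lambda t: min(1.0, 2.0 * t)
    else:
        active = None
        pressure_ramp = None

    program = LoadProgram(
        n_steps=config.n_steps,
        dirichlet=[DirichletSpec.fixed("BASE")],
        followers=[FollowerSpec("ENDO", config.endo_pressure_kpa, "kPa")],
        active_stress=active,
        kappa_f_active=config.kappa_f_active,
    )
    history, report, problem = run_load_program(
        mesh, disc, material, program, config.settings
    )
    state = history[-1]
    fr = FieldReport()
    if report.completed:
        mean, std, per_cell = jacobian_stats(problem, state)
        fr.det_F = per_cell
        fr.summaries["detF_mean"] = mean
        fr.summaries["detF_std"] = std
        apex = mesh.nodes[:, 2].argmin()
        fr.probes["apex_displacement"] = state.u[apex]
    return report, fr, problem, state


def ellipsoid_cavity_volume(mesh: Mesh, u: np.ndarray | None = None) -> float:
    """Ventricular cavity volume: the deformed ENDO surface closed by a
    static fan lid over the (clamped) basal ring, evaluated with the
    Nanson-formula surface operator.

    Returns a positive volume for the reference configuration.
    """
    from .forms import cavity_volume

    endo = mesh.facet_tags["ENDO"]
    # basal ring: edges used by exactly one ENDO triangle
    edges = np.concatenate(
        [endo[:, [0, 1]], endo[:, [1, 2]], endo[:, [2, 0]]], axis=0
    )
    key = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    ring = edges[counts[inv] == 1]
    center = len(mesh.nodes)
    z_ring = mesh.nodes[ring[0, 0], 2]
    nodes = np.vstack([mesh.nodes, [0.0, 0.0, z_ring]])
    lid = np.column_stack(
        [np.full(len(ring), center), ring[:, 1], ring[:, 0]]
    )
    facets = np.vstack([endo, lid])
    if u is None:
        u_ext = None
    else:
        u_ext = np.vstack([u, np.zeros(3)])
    # ENDO facets are oriented out of the solid, i.e. into the cavity
    return -cavity_volume(nodes, facets, u_ext)


# --- fixtures --------------------------------------------------------------


def _single_tet() -> Mesh:
    nodes = np.array(
        [[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
    )
    cells = np.array([[0, 1, 2, 3]])
    mesh = Mesh(nodes=nodes, cells=cells, cell_kind="tet4")
    mesh.facet_tags = {"BOUNDARY": mesh.boundary_facets()}
    return mesh


def _single_hex() -> Mesh:
    return generate_box_hex(1, 1, 1)


def _two_hex() -> Mesh:
    return generate_box_hex(2, 1, 1, lengths=(2.0, 1.0, 1.0))


def _icosphere(subdivisions: int = 3):
    """Unit icosphere surface (nodes, triangles), outward oriented."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return np.asarray(ico.vertices), np.asarray(ico.faces, dtype=np.int64)


FIXTURES = {
    "single_tet": _single_tet,
    "single_hex": _single_hex,
    "two_hex": _two_hex,
    "two_tet": lambda: hex_to_tet(_single_hex()),
    "unit_cube_2": lambda: generate_box_hex(2, 2, 2),
    "unit_cube_3": lambda: generate_box_hex(3, 3, 3),
    "unit_cube_tet_2": lambda: hex_to_tet(generate_box_hex(2, 2, 2)),
    "unit_cube_tet_3": lambda: hex_to_tet(generate_box_hex(3, 3, 3)),
    "sphere_642": lambda: _icosphere(3),
}


def make_fixture(name: str):
    """Deterministic fixture registry used by the test suite."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    return FIXTURES[name]()
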