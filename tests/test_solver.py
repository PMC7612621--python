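"""Global assembly, Newton iteration, load stepping, patch tests."""

import numpy as np
import pytest
import scipy.optimize

from anisofem.benchmarks import make_fixture
from anisofem.forms import Discretization
from anisofem.materials import cauchy_stress, kinematics
from anisofem.meshing import generate_box_hex, hex_to_tet
from anisofem.solver import (
    DirichletSpec,
    FEProblem,
    FollowerSpec,
    LoadProgram,
    NewtonSettings,
    SingularSystemError,
    linear_solve,
    run_load_program,
)
from conftest import make_material

TECHS = ["p0_penalty", "equal_order", "projection", "mini"]


def _nan_ramp(values):
    """Dirichlet ramp prescribing only the z-component."""

    def ramp(X, t):
        g = np.full_like(X, np.nan)
        g[:, 2] = values * t
        return g

    return ramp


# --- linear_solve ----------------------------------------------------------


def test_linear_solve_identity_and_oracle(rng):
    import scipy.sparse as sp

    n = 40
    b = rng.standard_normal(n)
    assert np.allclose(linear_solve(sp.eye(n, format="csc"), b), b)
    A = rng.standard_normal((n, n))
    A = A @ A.T + n * np.eye(n)
    x = linear_solve(sp.csc_matrix(A), b)
    assert np.abs(x - np.linalg.solve(A, b)).max() < 1e-10


def test_linear_solve_singular_diagnostic():
    import scipy.sparse as sp

    A = sp.csc_matrix(np.diag([1.0, 0.0, 2.0]))
    with pytest.raises(SingularSystemError):
        linear_solve(A, np.ones(3))


def test_saddle_system_with_zero_block_solvable(rng):
    """Incompressible-limit block structure [[A, B], [B^T, 0]] with full-rank
    coupling solves with the direct backend."""
    import scipy.sparse as sp

    n, m = 12, 4
    A = rng.standard_normal((n, n))
    A = A @ A.T + n * np.eye(n)
    B = rng.standard_normal((n, m))
    K = np.block([[A, B], [B.T, np.zeros((m, m))]])
    rhs = rng.standard_normal(n + m)
    x = linear_solve(sp.csc_matrix(K), rhs)
    assert np.abs(K @ x - rhs).max() < 1e-8


# --- assembly --------------------------------------------------------------


def test_reference_assembly_zero_residual_and_symmetry():
    mesh = hex_to_tet(generate_box_hex(1, 1, 1))
    mat = make_material("NEOHOOKEAN_ISO", kappa=100.0)
    prog = LoadProgram(n_steps=1, dirichlet=[DirichletSpec.fixed("ZMIN")])
    prob = FEProblem(mesh, Discretization("projection", "tet4"), mat, prog)
    K, R, _ = prob.assemble(prob.initial_state(), 1.0)
    assert np.abs(R).max() < 1e-13
    D = (K - K.T).toarray()
    assert np.abs(D).max() < 1e-12 * max(1.0, np.abs(K.toarray()).max())


def test_global_tangent_matches_residual_fd(rng):
    """Assembled sparse tangent equals finite differences of the assembled
    residual, including the (nonsymmetric) follower-load rows."""
    mesh = hex_to_tet(generate_box_hex(1, 1, 1))
    mat = make_material("GHT_ARTERY", kappa=100.0, k1=5.0)
    prog = LoadProgram(
        n_steps=1,
        followers=[FollowerSpec("ZMAX", 2.0)],
    )
    prob = FEProblem(mesh, Discretization("projection", "tet4"), mat, prog)
    st = prob.initial_state()
    st.u += 0.02 * rng.standard_normal(st.u.shape)
    st.p += 0.3 * rng.standard_normal(st.p.shape)
    K, R, _ = prob.assemble(st, 0.8)
    K = K.toarray()
    h = 1e-7
    for k in rng.choice(prob.n_dofs, size=20, replace=False):
        sp_, sm_ = st.copy(), st.copy()
        if k < prob.n_u:
            sp_.u.reshape(-1)[k] += h
            sm_.u.reshape(-1)[k] -= h
        else:
            sp_.p[k - prob.n_u] += h
            sm_.p[k - prob.n_u] -= h
        fd = (prob.residual_only(sp_, 0.8) - prob.residual_only(sm_, 0.8)) / (2 * h)
        assert np.abs(fd - K[:, k]).max() < 1e-6 * max(1.0, np.abs(K).max())


# --- Newton ----------------------------------------------------------------


def test_zero_load_converges_without_iterating():
    mesh = hex_to_tet(generate_box_hex(1, 1, 1))
    mat = make_material("NEOHOOKEAN_ISO", kappa=100.0)
    prog = LoadProgram(n_steps=1, dirichlet=[DirichletSpec.fixed("ZMIN")])
    prob = FEProblem(mesh, Discretization("p0_penalty", "tet4"), mat, prog)
    state, report = prob.newton_solve(prob.initial_state(), 0.0, NewtonSettings())
    assert report.converged
    assert report.iterations == 0
    assert np.abs(state.u).max() == 0.0


def test_newton_quadratic_convergence():
    """Residual norms of the final iterations contract quadratically."""
    mesh = hex_to_tet(generate_box_hex(2, 2, 2))
    mat = make_material("NEOHOOKEAN_ISO", incompressible=True)
    prog = LoadProgram(
        n_steps=1,
        dirichlet=[DirichletSpec.fixed("ZMIN")],
        followers=[FollowerSpec("ZMAX", 1.5)],
    )
    prob = FEProblem(mesh, Discretization("projection", "tet4"), mat, prog)
    state, report = prob.newton_solve(
        prob.initial_state(), 0.5, NewtonSettings(rtol=1e-12, max_iterations=30)
    )
    assert report.converged
    norms = report.residual_norms
    # the last contraction step should be at least superlinear
    assert norms[-1] < 1e-3 * norms[-2]


def test_small_strain_limit_matches_linear_solve():
    """One Newton step at a tiny load reproduces the converged solution to
    O(load^2)."""
    mesh = hex_to_tet(generate_box_hex(2, 2, 2))
    mat = make_material("NEOHOOKEAN_ISO", kappa=50.0)
    eps = 1e-4
    prog = LoadProgram(
        n_steps=1,
        dirichlet=[DirichletSpec.fixed("ZMIN")],
        followers=[FollowerSpec("ZMAX", eps)],
    )
    prob = FEProblem(mesh, Discretization("p0_penalty", "tet4"), mat, prog)
    st1, rep1 = prob.newton_solve(
        prob.initial_state(), 1.0, NewtonSettings(max_iterations=1, rtol=0.5)
    )
    stc, repc = prob.newton_solve(
        prob.initial_state(), 1.0, NewtonSettings(rtol=1e-12)
    )
    assert repc.converged
    scale = np.abs(stc.u).max()
    assert np.abs(st1.u - stc.u).max() < 1e-4 * scale + 1e-12


# --- patch test ------------------------------------------------------------


@pytest.mark.parametrize("tech", TECHS)
def test_homogeneous_patch_under_end_pressure(tech):
    """A bar under uniform follower pressure on one end face deforms
    homogeneously; for the incompressible technologies the axial stretch
    matches the closed-form uniaxial solution."""
    mesh = hex_to_tet(generate_box_hex(2, 2, 2))
    mu = 10.0
    incompressible = tech in ("projection", "mini")
    mat = make_material(
        "NEOHOOKEAN_ISO", kappa=2000.0, incompressible=incompressible
    )
    p_ext = 2.0
    prog = LoadProgram(
        n_steps=2,
        dirichlet=[
            DirichletSpec("ZMIN", _nan_ramp(0.0)),
            DirichletSpec("XMIN", lambda X, t: np.column_stack(
                [np.zeros(len(X)), np.full(len(X), np.nan), np.full(len(X), np.nan)]
            )),
            DirichletSpec("YMIN", lambda X, t: np.column_stack(
                [np.full(len(X), np.nan), np.zeros(len(X)), np.full(len(X), np.nan)]
            )),
        ],
        followers=[FollowerSpec("ZMAX", p_ext)],
    )
    history, report, prob = run_load_program(
        mesh, Discretization(tech, "tet4"), mat, prog,
        NewtonSettings(rtol=1e-10),
    )
    assert report.completed
    state = history[-1]
    kin = prob.kernels.states(prob._element_u(state))
    F = kin.F.reshape(-1, 3, 3)
    # homogeneous deformation: all quadrature-point F agree
    assert np.abs(F - F[0]).max() < 1e-8
    if incompressible:
        lam = scipy.optimize.brentq(
            lambda l: mu * (l**2 - 1.0 / l) + p_ext, 0.5, 1.0
        )
        assert abs(F[0, 2, 2] - lam) < 1e-8


def test_stabilization_does_not_perturb_homogeneous_patch():
    """Adding s_h leaves the converged displacement of a homogeneous patch
    unchanged (stabilization consistency)."""
    mesh = hex_to_tet(generate_box_hex(2, 2, 2))
    mat = make_material("NEOHOOKEAN_ISO", kappa=500.0)
    prog = LoadProgram(
        n_steps=1,
        dirichlet=[
            DirichletSpec("ZMIN", _nan_ramp(0.0)),
            DirichletSpec("ZMAX", _nan_ramp(-0.1)),
            DirichletSpec("XMIN", lambda X, t: np.column_stack(
                [np.zeros(len(X)), np.full(len(X), np.nan), np.full(len(X), np.nan)]
            )),
            DirichletSpec("YMIN", lambda X, t: np.column_stack(
                [np.full(len(X), np.nan), np.zeros(len(X)), np.full(len(X), np.nan)]
            )),
        ],
    )
    out = {}
    for tech in ("equal_order", "projection"):
        history, report, prob = run_load_program(
            mesh, Discretization(tech, "tet4"), mat, prog,
            NewtonSettings(rtol=1e-12),
        )
        assert report.completed
        out[tech] = history[-1].u
    assert np.abs(out["projection"] - out["equal_order"]).max() < 1e-10


# --- load stepping ---------------------------------------------------------


def test_zero_magnitude_program_identity_history():
    mesh = hex_to_tet(generate_box_hex(1, 1, 1))
    mat = make_material("NEOHOOKEAN_ISO", kappa=100.0)
    prog = LoadProgram(n_steps=3, dirichlet=[DirichletSpec.fixed("ZMIN")])
    history, report, _ = run_load_program(
        mesh, Discretization("p0_penalty", "tet4"), mat, prog
    )
    assert report.completed
    for st in history:
        assert np.abs(st.u).max() == 0.0


def test_path_independence_under_step_refinement():
    """Doubling the number of load steps leaves the quasi-static final state
    unchanged (to solver tolerance)."""
    mesh = hex_to_tet(generate_box_hex(2, 2, 2))
    mat = make_material("GHT_ARTERY", incompressible=True, k1=5.0)

    def run(n):
        prog = LoadProgram(
            n_steps=n,
            dirichlet=[DirichletSpec.fixed("ZMIN")],
            followers=[FollowerSpec("ZMAX", 2.0)],
        )
        history, report, _ = run_load_program(
            mesh, Discretization("projection", "tet4"), mat, prog,
            NewtonSettings(rtol=1e-12),
        )
        assert report.completed
        return history[-1]

    a, b = run(2), run(4)
    scale = max(1.0, np.abs(a.u).max())
    assert np.abs(a.u - b.u).max() / scale < 1e-6


def test_step_cutting_reports_partial_history():
    """An unreachable load gives a partial history and a failure flag."""
    mesh = hex_to_tet(generate_box_hex(1, 1, 1))
    mat = make_material("NEOHOOKEAN_ISO", kappa=10.0)
    # absurd pressure so that continuation cannot complete
    prog = LoadProgram(
        n_steps=2,
        dirichlet=[DirichletSpec.fixed("ZMIN")],
        followers=[FollowerSpec("ZMAX", 1e5)],
    )
    history, report, _ = run_load_program(
        mesh, Discretization("p0_penalty", "tet4"), mat, prog,
        NewtonSettings(max_iterations=8, max_step_cuts=2),
    )
    assert not report.completed
    assert len(history) >= 1
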