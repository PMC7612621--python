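"""Element kernels: residual/tangent consistency, follower loads,
stabilization, static condensation, cavity volume."""

import numpy as np
import pytest

from anisofem.benchmarks import make_fixture
from anisofem.forms import (
    ConfigurationError,
    Discretization,
    ElementKernels,
    FollowerLoadKernel,
    TopologyError,
    cavity_volume,
    projection_stabilization,
)
from anisofem.materials import FiberTriad, VolumetricLaw
from anisofem.meshing import generate_box_hex, hex_to_tet
from conftest import make_material

TECHS = ["p0_penalty", "equal_order", "projection", "mini"]


def _kernels(tech, cell="tet4", incompressible=False, family="NEOHOEKEAN"):
    mesh = make_fixture("two_tet" if cell == "tet4" else "two_hex")
    mat = make_material(
        "GHT_ARTERY", kappa=200.0,
        incompressible=incompressible and tech in ("projection", "mini", "equal_order"),
        k1=5.0,
    )
    disc = Discretization(tech, cell)
    return mesh, ElementKernels(mesh, disc, mat), disc, mat


def _random_dofs(rng, kern, disc, scale=0.03):
    M = kern.mesh.n_cells
    nbu = kern.elem.n_basis
    u = scale * rng.standard_normal((M, nbu, 3))
    # make nodal dofs consistent across shared nodes
    nodal = scale * rng.standard_normal((kern.mesh.n_nodes, 3))
    u[:, : kern.elem.n_vertices, :] = nodal[kern.mesh.cells]
    npz = kern.p_vals.shape[1]
    if disc.technology == "p0_penalty":
        p = np.zeros((M, 0))
    else:
        nodal_p = rng.standard_normal(kern.mesh.n_nodes)
        p = nodal_p[kern.mesh.cells]
    return u, p


@pytest.mark.parametrize("tech", ["equal_order", "projection"])
def test_reference_state_zero_residual(tech, rng):
    mesh, kern, disc, mat = _kernels(tech)
    u = np.zeros((mesh.n_cells, kern.elem.n_basis, 3))
    p = np.zeros((mesh.n_cells, 4))
    r_u, r_p = kern.residual(u, p)
    assert np.abs(r_u).max() < 1e-14
    assert np.abs(r_p).max() < 1e-14


def test_p0_condensed_pressure_constant_integrand():
    """Homogeneous F with Theta = J-1: p_K = kappa (J - 1)."""
    mesh = make_fixture("two_tet")
    mat = make_material("NEOHOEKEAN_ISO".replace("HOEK", "HOOK"), kappa=1000.0)
    kern = ElementKernels(mesh, Discretization("p0_penalty", "tet4"), mat)
    J_target = 1.1
    lam = J_target ** (1.0 / 3.0)
    u_nodes = (lam - 1.0) * mesh.nodes
    u = u_nodes[mesh.cells]
    state = kern.states(u)
    p_K = kern.condensed_pressure(state)
    assert np.allclose(p_K, 1000.0 * (J_target - 1.0), rtol=1e-12)


def test_p0_affine_pressure_residual_identity():
    """For affine u the P0 residual slot returns exactly kappa Theta(J)."""
    mesh = make_fixture("two_tet")
    mat = make_material("NEOHOOKEAN_ISO", kappa=500.0)
    kern = ElementKernels(mesh, Discretization("p0_penalty", "tet4"), mat)
    A = np.array([[0.05, 0.02, 0.0], [0.0, -0.03, 0.01], [0.0, 0.0, 0.04]])
    u_nodes = mesh.nodes @ A.T
    _, p_cell = kern.residual(u_nodes[mesh.cells], np.zeros((mesh.n_cells, 0)))
    J = np.linalg.det(np.eye(3) + A)
    assert np.allclose(p_cell, 500.0 * (J - 1.0), rtol=1e-12)


def test_p0_penalty_rejects_incompressible():
    mesh = make_fixture("two_tet")
    mat = make_material("NEOHOOKEAN_ISO", incompressible=True)
    with pytest.raises(ConfigurationError):
        ElementKernels(mesh, Discretization("p0_penalty", "tet4"), mat)


@pytest.mark.parametrize("tech", ["p0_penalty", "equal_order", "projection", "mini"])
@pytest.mark.parametrize("cell", ["tet4", "hex8"])
def test_element_tangent_matches_residual_fd(tech, cell, rng):
    """Element tangent = finite difference of the element residual with
    respect to every dof (the full uncondensed system for MINI, whose
    condensation is checked separately against an uncondensed solve)."""
    mesh, kern, disc, mat = _kernels(tech, cell)
    u, p = _random_dofs(rng, kern, disc)
    if disc.n_bubbles == 0:
        u = u[:, : kern.elem.n_vertices, :]
    sys = kern.tangent(u, p, condense=False)
    nv = kern.elem.n_vertices
    nbu = kern.elem.n_basis
    np_ = kern.p_vals.shape[1] if tech != "p0_penalty" else 0
    h = 1e-7

    def residual_full(u_, p_):
        r_u, r_p = kern.residual(u_, p_)
        if tech == "p0_penalty":
            return r_u.reshape(len(u_), -1)
        return np.concatenate([r_u.reshape(len(u_), -1), r_p], axis=1)

    ndof = sys.K.shape[1]
    err = 0.0
    for k in rng.choice(ndof, size=min(12, ndof), replace=False):
        up, um = u.copy(), u.copy()
        pp, pm = p.copy(), p.copy()
        if k < 3 * nbu:
            a, d = divmod(k, 3)
            up[:, a, d] += h
            um[:, a, d] -= h
        else:
            pp[:, k - 3 * nbu] += h
            pm[:, k - 3 * nbu] -= h
        fd = (residual_full(up, pp) - residual_full(um, pm)) / (2 * h)
        err = max(
            err,
            np.abs(fd - sys.K[:, :, k]).max() / max(1.0, np.abs(sys.K).max()),
        )
    assert err < 1e-6


def test_element_system_symmetric_without_follower_loads(rng):
    mesh, kern, disc, mat = _kernels("projection")
    u, p = _random_dofs(rng, kern, disc)
    u = u[:, : kern.elem.n_vertices, :]
    sys = kern.tangent(u, p)
    assert np.abs(sys.K - np.swapaxes(sys.K, 1, 2)).max() < 1e-12 * max(
        1.0, np.abs(sys.K).max()
    )


def test_incompressible_projection_pp_block_is_stabilization_only(rng):
    mesh = make_fixture("two_tet")
    mat = make_material("NEOHOOKEAN_ISO", incompressible=True)
    kern = ElementKernels(mesh, Discretization("projection", "tet4"), mat)
    u = np.zeros((mesh.n_cells, 4, 3))
    p = np.zeros((mesh.n_cells, 4))
    sys = kern.tangent(u, p)
    K_pp = sys.K[:, 12:, 12:]
    assert np.allclose(K_pp, -kern.stab, atol=1e-14)


# --- stabilization ---------------------------------------------------------


def test_stabilization_annihilates_constants():
    mesh = hex_to_tet(generate_box_hex(2, 2, 2))
    mat = make_material("NEOHOOKEAN_ISO", incompressible=True)
    kern = ElementKernels(mesh, Discretization("projection", "tet4"), mat)
    ones = np.ones(kern.stab.shape[1])
    assert np.abs(kern.stab @ ones).max() < 1e-14
    # symmetric positive semidefinite
    eigs = np.linalg.eigvalsh(kern.stab)
    assert eigs.min() > -1e-13


def test_stabilization_matches_dense_formula_unit_tet():
    """On the unit right tet: S = (M - m m^T/|K|) / |K|^{1/3} with the P1
    mass matrix; verified against dense quadrature."""
    mesh = make_fixture("single_tet")
    mat = make_material("NEOHOOKEAN_ISO", incompressible=True)
    kern = ElementKernels(
        mesh, Discretization("projection", "tet4"), mat, quad_degree=2
    )
    V = 1.0 / 6.0
    M_exact = V / 20.0 * (np.ones((4, 4)) + np.eye(4))
    m_exact = np.full(4, V / 4.0)
    S_exact = (M_exact - np.outer(m_exact, m_exact) / V) / V ** (1.0 / 3.0)
    assert np.abs(kern.stab[0] - S_exact).max() < 1e-14


def test_stabilization_scaling_with_cell_size():
    vols = np.array([1.0])
    mass = np.array([np.eye(4) * 0.1])
    means = np.array([np.full(4, 0.25)])
    S1 = projection_stabilization(vols, mass, means)
    # scaling lengths by 2: volume x8, mass x8, means x8 -> S x 8/2 = 4
    S2 = projection_stabilization(8 * vols, 8 * mass, 8 * means)
    assert np.allclose(S2, 4.0 * S1, atol=1e-14)


# --- MINI condensation -----------------------------------------------------


def test_mini_condensation_matches_uncondensed_solve(rng):
    """Schur-complement elimination must reproduce the uncondensed linear
    solve dof-for-dof on a 2-element fixture."""
    mesh = make_fixture("two_tet")
    mat = make_material("GHT_ARTERY", incompressible=True, k1=5.0)
    kern = ElementKernels(mesh, Discretization("mini", "tet4"), mat)
    nv, nb = 4, 1
    u, p = _random_dofs(rng, kern, Discretization("mini", "tet4"))
    sys = kern.tangent(u, p)

    # uncondensed oracle: globally number bubble dofs per cell; the full
    # element system layout is [u nodes, bubbles, p nodes]
    M = mesh.n_cells
    N = mesh.n_nodes
    n_ext = 3 * N + N
    ndof = n_ext + 3 * nb * M
    K = np.zeros((ndof, ndof))
    r = np.zeros(ndof)
    full = kern.tangent(u, p, condense=False)
    for m in range(M):
        udofs = (3 * mesh.cells[m][:, None] + np.arange(3)).ravel()
        bdofs = n_ext + 3 * nb * m + np.arange(3 * nb)
        pdofs = 3 * N + mesh.cells[m]
        dofs = np.concatenate([udofs, bdofs, pdofs])
        K[np.ix_(dofs, dofs)] += full.K[m]
        r[dofs] += full.r[m]
    # condensed global system
    Kc = np.zeros((n_ext, n_ext))
    rc = np.zeros(n_ext)
    for m in range(M):
        udofs = (3 * mesh.cells[m][:, None] + np.arange(3)).ravel()
        pdofs = 3 * N + mesh.cells[m]
        dofs = np.concatenate([udofs, pdofs])
        Kc[np.ix_(dofs, dofs)] += sys.K[m]
        rc[dofs] += sys.r[m]

    # fix a few dofs to make both systems nonsingular, solve, compare
    fixed = np.arange(9)
    free = np.setdiff1d(np.arange(n_ext), fixed)
    free_full = np.concatenate([free, np.arange(n_ext, ndof)])
    d_full = np.linalg.solve(K[np.ix_(free_full, free_full)], -r[free_full])
    d_cond = np.linalg.solve(Kc[np.ix_(free, free)], -rc[free])
    n_free = len(free)
    assert np.abs(d_full[:n_free] - d_cond).max() < 1e-10 * max(
        1.0, np.abs(d_cond).max()
    )
    # bubble recovery reproduces the uncondensed bubble increments
    delta_ext = np.zeros(n_ext)
    delta_ext[free] = d_cond
    edofs = np.concatenate(
        [
            (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(M, -1),
            3 * N + mesh.cells,
        ],
        axis=1,
    )
    db = sys.recovery.bubble_increments(delta_ext[edofs])
    assert np.abs(db.ravel() - d_full[n_free:]).max() < 1e-10 * max(
        1.0, np.abs(db).max()
    )


def test_mini_zero_bubble_forcing_zero_increment(rng):
    mesh = make_fixture("two_tet")
    mat = make_material("NEOHOOKEAN_ISO", incompressible=True)
    kern = ElementKernels(mesh, Discretization("mini", "tet4"), mat)
    u = np.zeros((mesh.n_cells, 5, 3))
    p = np.zeros((mesh.n_cells, 4))
    sys = kern.tangent(u, p)
    db = sys.recovery.bubble_increments(np.zeros((mesh.n_cells, sys.K.shape[1])))
    assert np.abs(db).max() < 1e-14


# --- follower loads --------------------------------------------------------


def test_follower_closed_surface_equilibrium():
    """Uniform pressure on a closed surface sums to zero net force."""
    mesh = make_fixture("single_hex")
    mesh.facet_tags["ALL"] = mesh.boundary_facets()
    kern = FollowerLoadKernel(mesh, "ALL")
    f, _ = kern.residual_and_tangent(np.zeros_like(mesh.nodes[kern.facets]), 3.0)
    total = np.zeros(3)
    np.add.at(total, np.zeros(1, dtype=int), 0)
    F = np.zeros((mesh.n_nodes, 3))
    np.add.at(F, kern.facets.ravel(), f.reshape(-1, 3))
    assert np.abs(F.sum(axis=0)).max() < 1e-12


def test_follower_flat_face_force():
    """p_ext on one unit-square face: total force = p * area * inward
    normal."""
    mesh = make_fixture("single_hex")
    kern = FollowerLoadKernel(mesh, "ZMAX")
    f, _ = kern.residual_and_tangent(
        np.zeros_like(mesh.nodes[kern.facets]), 2.5
    )
    total = f.sum(axis=(0, 1))
    assert np.abs(total - [0.0, 0.0, -2.5]).max() < 1e-12


def test_follower_tangent_matches_fd(rng):
    mesh = make_fixture("single_hex")
    kern = FollowerLoadKernel(mesh, "ZMAX")
    u = 0.1 * rng.standard_normal(mesh.nodes[kern.facets].shape)
    f0, K = kern.residual_and_tangent(u, 1.7)
    h = 1e-7
    err = 0.0
    for b in range(u.shape[1]):
        for j in range(3):
            up, um = u.copy(), u.copy()
            up[:, b, j] += h
            um[:, b, j] -= h
            fp, _ = kern.residual_and_tangent(up, 1.7, want_tangent=False)
            fm, _ = kern.residual_and_tangent(um, 1.7, want_tangent=False)
            fd = -(fp - fm) / (2 * h)  # K is d(-f)/du
            err = max(err, np.abs(fd - K[:, :, :, b, j]).max())
    assert err < 1e-6 * max(1.0, np.abs(K).max())


def test_follower_unknown_tag():
    mesh = make_fixture("single_hex")
    with pytest.raises(TopologyError):
        FollowerLoadKernel(mesh, "NOPE")


# --- cavity volume ---------------------------------------------------------


def test_cavity_volume_sphere_and_affine():
    nodes, tris = make_fixture("sphere_642")
    V0 = cavity_volume(nodes, tris)
    # equals the polyhedral volume (divergence-theorem oracle)
    P = nodes[tris]
    V_poly = np.abs(np.einsum("kij->k", np.zeros((1, 1, 1)))) if False else (
        np.einsum("ki,ki->k", P[:, 0], np.cross(P[:, 1], P[:, 2])).sum() / 6.0
    )
    assert abs(V0 - V_poly) < 1e-12
    assert abs(V0 - 4.0 * np.pi / 3.0) / (4.0 * np.pi / 3.0) < 0.01
    # affine map F = diag(2,1,1) doubles the enclosed volume
    u = nodes @ (np.diag([2.0, 1.0, 1.0]) - np.eye(3)).T
    assert abs(cavity_volume(nodes, tris, u) - 2.0 * V0) < 1e-12 * V0
    # orientation flip changes the sign
    assert abs(cavity_volume(nodes, tris[:, ::-1]) + V0) < 1e-12 * V0


def test_cavity_volume_open_surface_rejected():
    nodes, tris = make_fixture("sphere_642")
    with pytest.raises(TopologyError):
        cavity_volume(nodes, tris[:-1])


def test_euler_characteristic_sphere_fixture():
    nodes, tris = make_fixture("sphere_642")
    E = {tuple(sorted(e)) for t in tris for e in [(t[0], t[1]), (t[1], t[2]), (t[0], t[2])]}
    chi = len(nodes) - len(E) + len(tris)
    assert chi == 2
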