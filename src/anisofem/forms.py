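"""Element-level residuals, consistent tangents, stabilization, condensation.

All kernels are vectorized over the cells of a mesh: element arrays carry a
leading cell axis ``M``.  Integrals are taken over the reference
configuration.  The per-element degree-of-freedom ordering of the dense
element systems is::

    [u-node dofs (node-major, xyz), pressure dofs, (bubble dofs)]

and bubble/per-cell-pressure dofs never reach the global system: MINI bubble
displacements are eliminated by a Schur complement (static condensation) and
the per-cell pressure of the P0-penalty technology is condensed into an
effective displacement-only penalty kernel.

Element technologies
--------------------
* ``p0_penalty`` -- P1/Q1 displacements, per-cell constant pressure,
  condensed; requires a finite bulk modulus.
* ``equal_order`` -- P1/Q1 displacements and pressures, no stabilization
  (inf-sup unstable; kept for demonstration and comparison).
* ``projection`` -- equal-order pair stabilized by the pressure-projection
  term ``s_h(p, q) = sum_K (1/mu*) int_K (p - Pi_h p)(q - Pi_h q)`` with
  ``mu* = |K|^{1/3}`` and ``Pi_h`` the elementwise mean.
* ``mini`` -- equal-order pair enriched with interior displacement bubbles,
  statically condensed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import (
    HEX8,
    TET4,
    facet_reference,
    quadrature,
    reference_element,
)
from .materials import FiberTriad, MaterialModel, kinematics
from .meshing import Mesh

__all__ = [
    "Discretization",
    "ElementKernels",
    "ElementSystem",
    "FollowerLoadKernel",
    "projection_stabilization",
    "cavity_volume",
    "ConfigurationError",
    "TopologyError",
]

P0_PENALTY = "p0_penalty"
EQUAL_ORDER = "equal_order"
PROJECTION = "projection"
MINI = "mini"

_TECHNOLOGIES = (P0_PENALTY, EQUAL_ORDER, PROJECTION, MINI)


class ConfigurationError(ValueError):
    pass


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class Discretization:
    """Element technology bound to a cell kind."""

    technology: str
    cell_kind: str

    def __post_init__(self):
        if self.technology not in _TECHNOLOGIES:
            raise ConfigurationError(
                f"unknown element technology {self.technology!r}"
            )
        if self.cell_kind not in (TET4, HEX8):
            raise ConfigurationError(f"unknown cell kind {self.cell_kind!r}")

    @property
    def enriched(self) -> bool:
        return self.technology == MINI

    @property
    def per_node_pressure(self) -> bool:
        return self.technology != P0_PENALTY

    @property
    def n_bubbles(self) -> int:
        if not self.enriched:
            return 0
        return 1 if self.cell_kind == TET4 else 2

    @property
    def quad_degree(self) -> int:
        # lowest rules integrating the stiffness/stabilization blocks without
        # rank deficiency; MINI needs more because the bubbles are higher order
        if self.cell_kind == TET4:
            return 4 if self.enriched else 2
        return 3 if self.enriched else 2


@dataclass
class ElementSystem:
    """Dense element matrices/residuals for one batch of cells.

    ``K`` is ``(M, ndof, ndof)`` and ``r`` is ``(M, ndof)`` over the
    *external* dofs (condensed layout).  ``recovery`` holds the data needed
    to reconstruct bubble increments after the global solve, or None.
    """

    K: np.ndarray
    r: np.ndarray
    n_u_dofs: int
    n_p_dofs: int
    recovery: "BubbleRecovery | None" = None


@dataclass
class BubbleRecovery:
    Kbb_inv: np.ndarray  # (M, nb, nb)
    Kbe: np.ndarray  # (M, nb, ne)
    rb: np.ndarray  # (M, nb)

    def bubble_increments(self, delta_ext: np.ndarray) -> np.ndarray:
        """``db = -Kbb^{-1} (rb + Kbe de)`` for element increments de (M, ne)."""
        rhs = self.rb + np.einsum("mbe,me->mb", self.Kbe, delta_ext)
        return -np.einsum("mab,mb->ma", self.Kbb_inv, rhs)


def projection_stabilization(volumes, mass, means):
    """Pressure-projection stabilization matrices, one per cell.

    ``S[i][j] = (1/mu*) int_K (N_i - Pi_h N_i)(N_j - Pi_h N_j) dX`` with
    ``Pi_h`` the cell mean and ``mu* = |K|^{1/3}``; equals
    ``(M - m m^T / |K|) / mu*`` in terms of the pressure mass matrix ``M``
    and the basis integrals ``m``.  Symmetric positive semidefinite with the
    constant vector in its kernel.
    """
    mu_star = volumes ** (1.0 / 3.0)
    outer = np.einsum("mi,mj->mij", means, means) / volumes[:, None, None]
    return (mass - outer) / mu_star[:, None, None]


class ElementKernels:
    """Batched residual/tangent kernels for all cells of a mesh."""

    def __init__(
        self,
        mesh: Mesh,
        disc: Discretization,
        material: MaterialModel,
        quad_degree: int | None = None,
    ):
        if disc.cell_kind != mesh.cell_kind:
            raise ConfigurationError("discretization/mesh cell kind mismatch")
        if disc.technology == P0_PENALTY and material.volumetric.incompressible:
            raise ConfigurationError(
                "fully incompressible material (1/kappa = 0) cannot be used "
                "with the condensed P0 penalty formulation"
            )
        self.mesh = mesh
        self.disc = disc
        self.material = material
        self.elem = reference_element(
            mesh.cell_kind,
            enriched=disc.enriched,
            pressure_basis="linear" if disc.per_node_pressure else "constant",
        )
        self.rule = quadrature(
            mesh.cell_kind, quad_degree or disc.quad_degree
        )
        vals, grads = self.elem.shape_functions(self.rule.points)
        self.shape_vals = vals  # (Q, nbu)
        X = mesh.nodes[mesh.cells]  # (M, nv, 3)
        nv = self.elem.n_vertices
        Jgeo = np.einsum("mai,qad->mqid", X, grads[:, :nv, :])
        self.detJ = np.linalg.det(Jgeo)
        if np.any(self.detJ <= 0):
            raise ConfigurationError("mesh contains inverted cells")
        Jinv = np.linalg.inv(Jgeo)
        # physical gradients of ALL displacement basis functions (incl bubbles)
        self.grads = np.einsum("qad,mqdi->mqai", grads, Jinv)
        self.wdetJ = self.rule.weights[None, :] * self.detJ  # (M, Q)
        self.volumes = self.wdetJ.sum(axis=1)
        self.p_vals = self.elem.pressure_shape(self.rule.points)  # (Q, np)
        self.mass_p = np.einsum(
            "mq,qi,qj->mij", self.wdetJ, self.p_vals, self.p_vals
        )
        self.int_p = np.einsum("mq,qi->mi", self.wdetJ, self.p_vals)
        if disc.technology == PROJECTION:
            self.stab = projection_stabilization(
                self.volumes, self.mass_p, self.int_p
            )
        else:
            self.stab = None
        if mesh.fibers is not None:
            self.fibers = FiberTriad(
                f0=mesh.fibers.f0[:, None, :],
                s0=mesh.fibers.s0[:, None, :],
                n0=mesh.fibers.n0[:, None, :],
            )
        else:
            self.fibers = FiberTriad.cartesian()

    # -- kinematics ---------------------------------------------------------

    def states(self, u_full: np.ndarray):
        """Kinematic states at all quadrature points.

        ``u_full`` is ``(M, nbu, 3)`` including bubble coefficients for MINI.
        """
        grad_u = np.einsum("mai,mqad->mqid", u_full, self.grads)
        return kinematics(grad_u)

    def _pressure_at_qp(self, p_dofs):
        return np.einsum("qi,mi->mq", self.p_vals, p_dofs)

    # -- kernels ------------------------------------------------------------

    def stress_and_tangent(self, state, p_qp, active_stress=None, kappa_f=0.0):
        S = self.material.pk2_stress(
            state, p_qp, self.fibers, active_stress, kappa_f
        )
        CC = self.material.material_tangent(
            state, p_qp, self.fibers, active_stress, kappa_f
        )
        return S, CC

    def residual(self, u_full, p_dofs, active_stress=None, kappa_f=0.0):
        """Element residuals ``(r_u (M, nbu, 3), r_p (M, np))``.

        For ``p0_penalty`` the pressure residual slot carries the condensed
        per-cell pressure ``p_K`` instead (it is identically condensed).
        """
        state = self.states(u_full)
        if self.disc.technology == P0_PENALTY:
            p_cell = self.condensed_pressure(state)
            p_qp = np.broadcast_to(
                p_cell[:, None], state.J.shape
            )
            S = self.material.pk2_stress(
                state, p_qp, self.fibers, active_stress, kappa_f
            )
            r_u = np.einsum(
                "mq,mqik,mqkl,mqal->mai", self.wdetJ, state.F, S, self.grads,
                optimize=True,
            )
            return r_u, p_cell
        p_qp = self._pressure_at_qp(p_dofs)
        S = self.material.pk2_stress(
            state, p_qp, self.fibers, active_stress, kappa_f
        )
        r_u = np.einsum(
            "mq,mqik,mqkl,mqal->mai", self.wdetJ, state.F, S, self.grads,
            optimize=True,
        )
        theta, _, _ = self.material.volumetric.theta(state.J)
        r_p = np.einsum("mq,qi,mq->mi", self.wdetJ, self.p_vals, theta)
        r_p -= self.material.volumetric.inv_kappa * np.einsum(
            "mij,mj->mi", self.mass_p, p_dofs
        )
        if self.stab is not None:
            r_p -= np.einsum("mij,mj->mi", self.stab, p_dofs)
        return r_u, r_p

    def condensed_pressure(self, state):
        """P0 penalty pressure ``p_K = kappa int_K Theta(J) dX / |K|``."""
        theta, _, _ = self.material.volumetric.theta(state.J)
        return (
            self.material.volumetric.kappa
            * np.einsum("mq,mq->m", self.wdetJ, theta)
            / self.volumes
        )

    def _uu_blocks(self, state, S, CC):
        g = self.grads
        w = self.wdetJ
        # geometric part: delta_ij g_a . S . g_b
        geo = np.einsum("mq,mqak,mqkl,mqbl->mab", w, g, S, g, optimize=True)
        K_geo = np.einsum("mab,ij->maibj", geo, np.eye(3))
        # material part via B_ai = sym(F^T e_i (x) g_a)
        B = np.einsum("mqik,mqal->mqaikl", state.F, g)
        B = 0.5 * (B + np.swapaxes(B, -1, -2))
        K_mat = np.einsum(
            "mq,mqaikl,mqklrs,mqbjrs->maibj", w, B, CC, B, optimize=True
        )
        return K_geo + K_mat, B

    def _up_block(self, state, pi_J):
        FinvT = np.linalg.inv(np.swapaxes(state.F, -1, -2))
        return np.einsum(
            "mq,qP,mq,mqik,mqak->maiP",
            self.wdetJ,
            self.p_vals,
            pi_J,
            FinvT,
            self.grads,
            optimize=True,
        )

    def tangent(
        self, u_full, p_dofs, active_stress=None, kappa_f=0.0,
        condense: bool = True,
    ):
        """Condensed dense element system (tangent + residual).

        Returns an :class:`ElementSystem` over the external dofs
        ``[u nodes, p nodes]`` (or u nodes only for P0 penalty).  With
        ``condense=False`` (MINI only) the full uncondensed system is
        returned in the layout ``[u nodes, bubbles, p nodes]``.
        """
        state = self.states(u_full)
        nv = self.elem.n_vertices
        nbub = self.disc.n_bubbles

        if self.disc.technology == P0_PENALTY:
            p_cell = self.condensed_pressure(state)
            p_qp = np.broadcast_to(p_cell[:, None], state.J.shape)
            S, CC = self.stress_and_tangent(state, p_qp, active_stress, kappa_f)
            K_uu, _ = self._uu_blocks(state, S, CC)
            pi_J, _ = self.material.volumetric.pressure_coeffs(state.J)
            k_vec = self._up_block(state, pi_J)[..., 0]  # (M, nv, 3)
            M = len(self.mesh.cells)
            kf = k_vec.reshape(M, -1)
            K = K_uu.reshape(M, 3 * nv, 3 * nv) + (
                self.material.volumetric.kappa / self.volumes
            )[:, None, None] * np.einsum("ma,mb->mab", kf, kf)
            r_u = np.einsum(
                "mq,mqik,mqkl,mqal->mai", self.wdetJ, state.F, S, self.grads,
                optimize=True,
            )
            return ElementSystem(
                K=K, r=r_u.reshape(M, -1), n_u_dofs=3 * nv, n_p_dofs=0
            )

        p_qp = self._pressure_at_qp(p_dofs)
        S, CC = self.stress_and_tangent(state, p_qp, active_stress, kappa_f)
        K_uu, _ = self._uu_blocks(state, S, CC)
        pi_J, _ = self.material.volumetric.pressure_coeffs(state.J)
        K_up = self._up_block(state, pi_J)  # (M, nbu, 3, np)
        np_ = self.p_vals.shape[1]
        K_pp = -self.material.volumetric.inv_kappa * self.mass_p
        if self.stab is not None:
            K_pp = K_pp - self.stab
        r_u, r_p = self.residual(u_full, p_dofs, active_stress, kappa_f)

        M = len(self.mesh.cells)
        nbu = nv + nbub
        ndof = 3 * nbu + np_
        K = np.zeros((M, ndof, ndof))
        r = np.zeros((M, ndof))
        K[:, : 3 * nbu, : 3 * nbu] = K_uu.reshape(M, 3 * nbu, 3 * nbu)
        K[:, : 3 * nbu, 3 * nbu :] = K_up.reshape(M, 3 * nbu, np_)
        K[:, 3 * nbu :, : 3 * nbu] = np.swapaxes(
            K_up.reshape(M, 3 * nbu, np_), 1, 2
        )
        K[:, 3 * nbu :, 3 * nbu :] = K_pp
        r[:, : 3 * nbu] = r_u.reshape(M, -1)
        r[:, 3 * nbu :] = r_p

        if nbub == 0:
            return ElementSystem(K=K, r=r, n_u_dofs=3 * nv, n_p_dofs=np_)
        if not condense:
            return ElementSystem(
                K=K, r=r, n_u_dofs=3 * nbu, n_p_dofs=np_
            )

        # static condensation of the bubble displacement dofs
        ext = np.concatenate(
            [np.arange(3 * nv), np.arange(3 * nbu, ndof)]
        )
        bub = np.arange(3 * nv, 3 * nbu)
        Kee = K[:, ext[:, None], ext[None, :]]
        Keb = K[:, ext[:, None], bub[None, :]]
        Kbe = K[:, bub[:, None], ext[None, :]]
        Kbb = K[:, bub[:, None], bub[None, :]]
        try:
            Kbb_inv = np.linalg.inv(Kbb)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "singular bubble block during static condensation"
            ) from exc
        re_, rb = r[:, ext], r[:, bub]
        K_cond = Kee - np.einsum("meb,mbc,mcf->mef", Keb, Kbb_inv, Kbe)
        r_cond = re_ - np.einsum("meb,mbc,mc->me", Keb, Kbb_inv, rb)
        return ElementSystem(
            K=K_cond,
            r=r_cond,
            n_u_dofs=3 * nv,
            n_p_dofs=np_,
            recovery=BubbleRecovery(Kbb_inv=Kbb_inv, Kbe=Kbe, rb=rb),
        )


# --- follower loads --------------------------------------------------------

_EPS = np.zeros((3, 3, 3))
_EPS[0, 1, 2] = _EPS[1, 2, 0] = _EPS[2, 0, 1] = 1.0
_EPS[0, 2, 1] = _EPS[2, 1, 0] = _EPS[1, 0, 2] = -1.0


class FollowerLoadKernel:
    """Pressure follower load on a batch of outward-oriented boundary facets.

    The traction is ``h = -p_ext J F^{-T} N``; on the discrete facet this is
    integrated via the deformed surface parametrization,
    ``J F^{-T} N dS = (a_1 x a_2) dxi`` with ``a_i`` the deformed tangent
    vectors, which also yields the exact (nonsymmetric) load stiffness.
    Because MINI bubbles vanish on element boundaries the facet terms have no
    bubble rows.
    """

    def __init__(self, mesh: Mesh, tag: str):
        if tag not in mesh.facet_tags:
            raise TopologyError(f"mesh has no facet tag {tag!r}")
        self.facets = mesh.facet_tags[tag]
        if len(self.facets) == 0:
            raise TopologyError(f"facet tag {tag!r} is empty")
        boundary = {tuple(sorted(f)) for f in mesh.boundary_facets().tolist()}
        for f in self.facets.tolist():
            if tuple(sorted(f)) not in boundary:
                raise TopologyError(f"facet {f} is not on the mesh boundary")
        self.X = mesh.nodes[self.facets]  # (K, fn, 3)
        self.vals, self.dvals, self.w = facet_reference(self.facets.shape[1])

    def residual_and_tangent(
        self, u_facet: np.ndarray, p_ext: float, want_tangent: bool = True
    ):
        """External force ``f (K, fn, 3)`` and the stiffness contribution
        ``dR/du = -df/du`` as ``(K, fn, 3, fn, 3)``.

        ``u_facet`` holds the displacements of the facet nodes.
        """
        x = self.X + u_facet
        a = np.einsum("qad,kai->kqdi", self.dvals, x)  # (K, Q, 2, 3)
        c = np.cross(a[:, :, 0, :], a[:, :, 1, :])  # (K, Q, 3)
        f = -p_ext * np.einsum("q,qa,kqi->kai", self.w, self.vals, c)
        if not want_tangent:
            return f, None
        # dc_i/du_bj = eps_ijm (a2_m dN_b/dxi1 - a1_m dN_b/dxi2)
        term = np.einsum(
            "ijm,kqm,qb->kqibj",
            _EPS,
            a[:, :, 1, :],
            self.dvals[:, :, 0],
        ) - np.einsum(
            "ijm,kqm,qb->kqibj",
            _EPS,
            a[:, :, 0, :],
            self.dvals[:, :, 1],
        )
        K_fol = p_ext * np.einsum(
            "q,qa,kqibj->kaibj", self.w, self.vals, term
        )
        return f, K_fol


# --- cavity volume ---------------------------------------------------------


def cavity_volume(
    nodes: np.ndarray, facets: np.ndarray, u: np.ndarray | None = None
) -> float:
    """Enclosed volume of a closed, consistently oriented deforming surface,
    ``V = (1/3) oint x . n ds`` evaluated on the deformed facets (equivalent
    to the Nanson-formula pull-back ``(1/3) int J (X+u) . F^{-T} N dS``).

    Facet normals must point out of the enclosed cavity.  With ``u = None``
    or zero this returns the reference (polyhedral) enclosed volume exactly.
    """
    facets = np.asarray(facets)
    # closed-surface check: every edge shared by exactly two facets
    fn = facets.shape[1]
    edges = np.concatenate(
        [facets[:, [i, (i + 1) % fn]] for i in range(fn)], axis=0
    )
    key = np.sort(edges, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    if np.any(counts != 2):
        raise TopologyError("surface is not closed (dangling edges found)")
    x = nodes[facets]
    if u is not None:
        x = x + u[facets]
    vals, dvals, w = facet_reference(fn)
    xq = np.einsum("qa,kai->kqi", vals, x)
    a = np.einsum("qad,kai->kqdi", dvals, x)
    c = np.cross(a[:, :, 0, :], a[:, :, 1, :])
    return float(np.einsum("q,kqi,kqi->", w, xq, c) / 3.0)
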