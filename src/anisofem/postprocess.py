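"""Stress/strain/Jacobian fields, cylindrical components, probes, statistics.

Per-cell tensor fields are quadrature-averaged (volume-weighted within the
cell) and reported element-wise, unsmoothed; distribution summaries are
volume-weighted over the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import HEX8, TET4, reference_element
from .materials import cauchy_stress
from .meshing import Mesh

__all__ = [
    "FieldReport",
    "cauchy_field",
    "cylindrical_components",
    "jacobian_stats",
    "probe",
    "directional_strains",
    "LocationError",
    "UndefinedBasisError",
]


class LocationError(ValueError):
    pass


class UndefinedBasisError(ValueError):
    pass


@dataclass
class FieldReport:
    """Bundle of element-wise results of one converged solve."""

    cauchy: np.ndarray | None = None  # (M, 3, 3)
    det_F: np.ndarray | None = None  # (M,)
    cylindrical: dict = field(default_factory=dict)  # srr/stt/szz -> (M,)
    probes: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)


def _cell_average(kernels, field_qp):
    """Volume-weighted quadrature average per cell of a (M, Q, ...) field."""
    w = kernels.wdetJ
    num = np.einsum("mq,mq...->m...", w, field_qp)
    return num / kernels.volumes.reshape((-1,) + (1,) * (field_qp.ndim - 2))


def cauchy_field(problem, state, active_stress=None, kappa_f=0.0):
    """Element-wise (quadrature-averaged) Cauchy stress of a solution state.

    Includes the pressure contribution: the per-node pressure field for the
    saddle-point technologies, or the condensed per-cell pressure for the
    P0 penalty.
    """
    ku = problem.kernels
    kin = ku.states(problem._element_u(state))
    if problem.disc.per_node_pressure:
        p_qp = np.einsum("qi,mi->mq", ku.p_vals, state.p[problem.mesh.cells])
    else:
        p_qp = np.broadcast_to(
            ku.condensed_pressure(kin)[:, None], kin.J.shape
        )
    S = problem.material.pk2_stress(
        kin, p_qp, ku.fibers, active_stress, kappa_f
    )
    sigma = cauchy_stress(kin, S)
    return _cell_average(ku, sigma)


def cylindrical_components(
    tensors: np.ndarray, centroids: np.ndarray
) -> dict[str, np.ndarray]:
    """Radial/circumferential/axial components of per-cell tensors in the
    local orthonormal cylindrical basis at the given centroids (z-axis)."""
    r = np.linalg.norm(centroids[:, :2], axis=1)
    if np.any(r < 1e-12):
        raise UndefinedBasisError("centroid on the z-axis")
    e_r = np.stack([centroids[:, 0] / r, centroids[:, 1] / r, np.zeros_like(r)], axis=1)
    e_t = np.stack([-centroids[:, 1] / r, centroids[:, 0] / r, np.zeros_like(r)], axis=1)
    e_z = np.zeros_like(e_r)
    e_z[:, 2] = 1.0
    comp = lambda e: np.einsum("mi,mij,mj->m", e, tensors, e)
    return {"srr": comp(e_r), "stt": comp(e_t), "szz": comp(e_z)}


def deformed_centroids(problem, state) -> np.ndarray:
    x = problem.mesh.nodes + state.u
    return x[problem.mesh.cells].mean(axis=1)


def jacobian_stats(problem, state):
    """Volume-weighted mean and standard deviation of the quadrature-averaged
    det F, plus the per-cell values."""
    ku = problem.kernels
    kin = ku.states(problem._element_u(state))
    per_cell = _cell_average(ku, kin.J)
    w = ku.volumes
    mean = float((w * per_cell).sum() / w.sum())
    std = float(np.sqrt((w * (per_cell - mean) ** 2).sum() / w.sum()))
    return mean, std, per_cell


# --- probing ---------------------------------------------------------------


def _tet_barycentric(X, point):
    """Barycentric coordinates of ``point`` in each tet of X (M, 4, 3)."""
    T = np.swapaxes(X[:, 1:] - X[:, :1], 1, 2)  # (M, 3, 3) columns
    lam = np.linalg.solve(T, (point - X[:, 0])[..., None])[..., 0]
    lam0 = 1.0 - lam.sum(axis=1, keepdims=True)
    return np.concatenate([lam0, lam], axis=1)


def _locate(mesh: Mesh, point, tol=1e-9):
    """(cell index, reference coordinates) of the cell containing ``point``."""
    point = np.asarray(point, dtype=float)
    X = mesh.nodes[mesh.cells]
    if mesh.cell_kind == TET4:
        lam = _tet_barycentric(X, point)
        viol = np.minimum(lam.min(axis=1), 0.0)
        best = int(np.argmax(viol))
        if viol[best] < -tol - 1e-12:
            raise LocationError(f"point {point} lies outside the mesh")
        return best, lam[best, 1:]
    # hex: Newton inversion of the trilinear map, nearest centroids first
    elem = reference_element(HEX8)
    centroids = X.mean(axis=1)
    order = np.argsort(np.linalg.norm(centroids - point, axis=1))
    for m in order[: min(32, len(order))]:
        xi = np.zeros(3)
        ok = True
        for _ in range(30):
            vals, grads = elem.shape_functions(xi[None, :], check_domain=False)
            xcur = vals[0] @ X[m]
            Jg = np.einsum("ai,ad->di", X[m], grads[0]).T
            try:
                dxi = np.linalg.solve(Jg, point - xcur)
            except np.linalg.LinAlgError:
                ok = False
                break
            xi = xi + dxi
            if np.linalg.norm(dxi) < 1e-13:
                break
        if ok and np.all(np.abs(xi) <= 1.0 + 1e-9):
            return int(m), xi
    raise LocationError(f"point {point} lies outside the mesh")


def probe(mesh: Mesh, field: np.ndarray, point) -> np.ndarray:
    """Evaluate a field at a physical point.

    Nodal fields (length ``n_nodes``) are interpolated with the cell's linear
    basis; cell fields (length ``n_cells``) return the containing cell's
    value.
    """
    m, xi = _locate(mesh, point)
    field = np.asarray(field)
    if field.shape[0] == mesh.n_cells:
        return field[m]
    if field.shape[0] != mesh.n_nodes:
        raise ValueError("field must be nodal or per-cell")
    elem = reference_element(mesh.cell_kind)
    if mesh.cell_kind == TET4:
        ref = np.asarray(xi)
    else:
        ref = xi
    vals, _ = elem.shape_functions(ref[None, :], check_domain=False)
    return np.einsum("a,a...->...", vals[0], field[mesh.cells[m]])


# --- directional strains ---------------------------------------------------


def directional_strains(problem, state, frames=None):
    """Per-cell Green-Lagrange strains along local direction triads.

    ``frames`` is a dict with keys among {"circumferential", "longitudinal",
    "radial"} mapping to (M, 3) unit direction arrays; when omitted the
    mesh's fiber triad is used as (circumferential, longitudinal, radial) =
    (f0, s0, n0) surrogates only if no cylindrical axis interpretation is
    requested -- for the tube and ellipsoid drivers pass explicit frames.
    Returns ``{name: e . E e}`` with ``E = (C - I)/2``.
    """
    ku = problem.kernels
    kin = ku.states(problem._element_u(state))
    E_qp = 0.5 * (kin.C - np.eye(3))
    E = _cell_average(ku, E_qp)
    if frames is None:
        fib = problem.mesh.fibers
        if fib is None:
            raise ValueError("no local frames available for strain extraction")
        frames = {
            "fiber": fib.f0,
            "sheet": fib.s0,
            "normal": fib.n0,
        }
    return {
        name: np.einsum("mi,mij,mj->m", e, E, e) for name, e in frames.items()
    }
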