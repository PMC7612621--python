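"""Reference elements, bubble enrichments, quadrature, isoparametric maps.

Two reference cells are supported:

* the unit tetrahedron with vertices at the origin and the unit axis points,
  barycentric-style linear basis, optional quartic interior bubble
  ``256 xi eta zeta (1 - xi - eta - zeta)``;
* the bi-unit hexahedron ``[-1, 1]^3`` with the trilinear basis in VTK node
  ordering, optionally enriched by the two interior bubbles
  ``(1 - xi^2)(1 - eta^2)(1 - zeta^2) * N_alpha`` for a body-diagonal vertex
  pair ``(alpha, beta) = (1, 7)``.

The bubbles vanish identically on the cell boundary, which is what makes the
equal-order displacement/pressure pair (MINI element) inf-sup stable and what
allows their degrees of freedom to be condensed out element by element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import roots_jacobi

__all__ = [
    "TET4",
    "HEX8",
    "ReferenceElement",
    "QuadratureRule",
    "reference_element",
    "quadrature",
    "facet_reference",
    "isoparametric_map",
]

TET4 = "tet4"
HEX8 = "hex8"

# VTK HEX8 vertex signs in reference coordinates.
_HEX_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)

#: Body-diagonal vertex pair carrying the two hex bubbles.
HEX_BUBBLE_VERTICES = (1, 7)


class DomainError(ValueError):
    """Reference point outside the reference element."""


class CapabilityError(ValueError):
    """Unsupported quadrature degree or basis request."""


class InvertedElementError(RuntimeError):
    """Non-positive geometric Jacobian; carries the offending cell index."""

    def __init__(self, msg: str, cell: int | None = None):
        super().__init__(msg)
        self.cell = cell


def _tet_linear(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    vals = np.stack([1.0 - x - y - z, x, y, z], axis=-1)
    grads = np.broadcast_to(
        np.array(
            [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        ),
        xi.shape[:-1] + (4, 3),
    ).copy()
    return vals, grads


def _tet_bubble(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    l0 = 1.0 - x - y - z
    val = 256.0 * x * y * z * l0
    g = np.stack(
        [
            256.0 * y * z * (l0 - x),
            256.0 * x * z * (l0 - y),
            256.0 * x * y * (l0 - z),
        ],
        axis=-1,
    )
    return val[..., None], g[..., None, :]


def _hex_linear(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = _HEX_SIGNS  # (8, 3)
    f = 1.0 + xi[..., None, :] * s  # (..., 8, 3)
    vals = 0.125 * f.prod(axis=-1)
    grads = np.empty(xi.shape[:-1] + (8, 3))
    for d in range(3):
        others = [k for k in range(3) if k != d]
        grads[..., d] = 0.125 * s[:, d] * f[..., others[0]] * f[..., others[1]]
    return vals, grads


def _hex_bubbles(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals_lin, grads_lin = _hex_linear(xi)
    b = (1.0 - xi[..., 0] ** 2) * (1.0 - xi[..., 1] ** 2) * (1.0 - xi[..., 2] ** 2)
    db = np.stack(
        [
            -2.0 * xi[..., 0] * (1.0 - xi[..., 1] ** 2) * (1.0 - xi[..., 2] ** 2),
            -2.0 * xi[..., 1] * (1.0 - xi[..., 0] ** 2) * (1.0 - xi[..., 2] ** 2),
            -2.0 * xi[..., 2] * (1.0 - xi[..., 0] ** 2) * (1.0 - xi[..., 1] ** 2),
        ],
        axis=-1,
    )
    idx = list(HEX_BUBBLE_VERTICES)
    vals = b[..., None] * vals_lin[..., idx]
    grads = (
        db[..., None, :] * vals_lin[..., idx, None]
        + b[..., None, None] * grads_lin[..., idx, :]
    )
    return vals, grads


def _inside_tet(xi: np.ndarray, tol: float) -> np.ndarray:
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    return (x >= -tol) & (y >= -tol) & (z >= -tol) & (x + y + z <= 1.0 + tol)


def _inside_hex(xi: np.ndarray, tol: float) -> np.ndarray:
    return (np.abs(xi) <= 1.0 + tol).all(axis=-1)


@dataclass(frozen=True)
class ReferenceElement:
    """Displacement/pressure basis bundle for one cell kind."""

    cell_kind: str
    enriched: bool = False
    #: "constant" (per-cell) or "linear" (per-vertex) pressure basis.
    pressure_basis: str = "linear"

    @property
    def n_vertices(self) -> int:
        return 4 if self.cell_kind == TET4 else 8

    @property
    def n_bubbles(self) -> int:
        if not self.enriched:
            return 0
        return 1 if self.cell_kind == TET4 else 2

    @property
    def n_basis(self) -> int:
        return self.n_vertices + self.n_bubbles

    def shape_functions(
        self, xi: np.ndarray, check_domain: bool = True
    ) -> tuple[np.ndarray, np.ndarray]:
        """Basis values ``(..., n_basis)`` and reference gradients
        ``(..., n_basis, 3)`` at reference points ``xi``."""
        xi = np.asarray(xi, dtype=float)
        if check_domain:
            inside = (
                _inside_tet(xi, 1e-12)
                if self.cell_kind == TET4
                else _inside_hex(xi, 1e-12)
            )
            if not np.all(inside):
                raise DomainError(
                    f"reference point outside the {self.cell_kind} reference element"
                )
        if self.cell_kind == TET4:
            vals, grads = _tet_linear(xi)
            if self.enriched:
                bv, bg = _tet_bubble(xi)
                vals = np.concatenate([vals, bv], axis=-1)
                grads = np.concatenate([grads, bg], axis=-2)
        elif self.cell_kind == HEX8:
            vals, grads = _hex_linear(xi)
            if self.enriched:
                bv, bg = _hex_bubbles(xi)
                vals = np.concatenate([vals, bv], axis=-1)
                grads = np.concatenate([grads, bg], axis=-2)
        else:
            raise CapabilityError(f"unknown cell kind {self.cell_kind!r}")
        return vals, grads

    def pressure_shape(self, xi: np.ndarray) -> np.ndarray:
        """Pressure basis values at ``xi``."""
        xi = np.asarray(xi, dtype=float)
        if self.pressure_basis == "constant":
            return np.ones(xi.shape[:-1] + (1,))
        vals, _ = (
            _tet_linear(xi) if self.cell_kind == TET4 else _hex_linear(xi)
        )
        return vals


def reference_element(
    cell_kind: str, enriched: bool = False, pressure_basis: str = "linear"
) -> ReferenceElement:
    if cell_kind not in (TET4, HEX8):
        raise CapabilityError(f"unknown cell kind {cell_kind!r}")
    return ReferenceElement(cell_kind, enriched, pressure_basis)


@dataclass(frozen=True)
class QuadratureRule:
    points: np.ndarray  # (Q, dim)
    weights: np.ndarray  # (Q,)

    @property
    def n_points(self) -> int:
        return len(self.weights)


def _gauss01(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _tet_conical(n: int) -> QuadratureRule:
    """Stroud conical-product rule on the unit tetrahedron, exact for total
    degree ``2n - 1``."""
    x3, w3 = _gauss01(n)
    # Gauss-Jacobi on [0,1] with weights (1-x)^2 and (1-x)^1.
    xj2, wj2 = roots_jacobi(n, 2.0, 0.0)
    xj1, wj1 = roots_jacobi(n, 1.0, 0.0)
    x1, w1 = 0.5 * (xj2 + 1.0), wj2 / 8.0  # /2^3: interval map + weight (1-x)^2
    x2, w2 = 0.5 * (xj1 + 1.0), wj1 / 4.0
    pts, wts = [], []
    for a, wa in zip(x1, w1):
        for b, wb in zip(x2, w2):
            for c, wc in zip(x3, w3):
                xi = a
                eta = b * (1.0 - a)
                zeta = c * (1.0 - a) * (1.0 - b)
                pts.append((xi, eta, zeta))
                wts.append(wa * wb * wc)
    return QuadratureRule(np.array(pts), np.array(wts))


def quadrature(cell_kind: str, degree: int) -> QuadratureRule:
    """Quadrature rule exact for polynomials of the given degree.

    Tetrahedra support total degree 1..4 (the familiar centroid and 4-point
    rules for degrees 1-2, conical-product rules above); hexahedra use
    tensor-Gauss with ``degree`` points per axis, 1..5.
    """
    if cell_kind == TET4:
        if degree == 1:
            return QuadratureRule(
                np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0])
            )
        if degree == 2:
            a = (5.0 - np.sqrt(5.0)) / 20.0
            b = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
            pts = np.full((4, 3), a)
            np.fill_diagonal(pts, b)
            return QuadratureRule(pts, np.full(4, 1.0 / 24.0))
        if degree in (3, 4):
            return _tet_conical((degree + 2) // 2)
        raise CapabilityError(f"unsupported tet quadrature degree {degree}")
    if cell_kind == HEX8:
        if not 1 <= degree <= 5:
            raise CapabilityError(f"unsupported hex quadrature order {degree}")
        x, w = np.polynomial.legendre.leggauss(degree)
        g = np.stack(np.meshgrid(x, x, x, indexing="ij"), axis=-1).reshape(-1, 3)
        gw = np.einsum("i,j,k->ijk", w, w, w).reshape(-1)
        return QuadratureRule(g, gw)
    raise CapabilityError(f"unknown cell kind {cell_kind!r}")


# --- facet (surface) reference elements -----------------------------------


def facet_reference(n_facet_nodes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Surface shape data for boundary integration.

    Returns ``(vals, dvals, weights)`` at the facet quadrature points:
    ``vals (Q, n)``, parametric derivatives ``dvals (Q, n, 2)``, weights
    ``(Q,)``.  Triangles use the degree-2 three-point rule on the unit
    triangle; quadrilaterals use 2x2 Gauss on ``[-1, 1]^2``.
    """
    if n_facet_nodes == 3:
        pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        w = np.full(3, 1.0 / 6.0)
        x, y = pts[:, 0], pts[:, 1]
        vals = np.stack([1.0 - x - y, x, y], axis=-1)
        dvals = np.broadcast_to(
            np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]), (3, 3, 2)
        ).copy()
        return vals, dvals, w
    if n_facet_nodes == 4:
        g = 1.0 / np.sqrt(3.0)
        pts = np.array([[-g, -g], [g, -g], [g, g], [-g, g]])
        w = np.ones(4)
        signs = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
        f = 1.0 + pts[:, None, :] * signs  # (Q, 4, 2)
        vals = 0.25 * f.prod(axis=-1)
        dvals = np.empty((4, 4, 2))
        dvals[..., 0] = 0.25 * signs[:, 0] * f[..., 1]
        dvals[..., 1] = 0.25 * signs[:, 1] * f[..., 0]
        return vals, dvals, w
    raise CapabilityError(f"unsupported facet with {n_facet_nodes} nodes")


def isoparametric_map(
    coords: np.ndarray,
    xi: np.ndarray,
    cell_kind: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map reference points to physical space.

    Parameters
    ----------
    coords : (..., n_vertices, 3) vertex coordinates.
    xi : (Q, 3) reference points.
    cell_kind : "tet4" or "hex8".

    Returns
    -------
    x : (..., Q, 3) physical points.
    J : (..., Q, 3, 3) geometric Jacobian ``dx/dxi``.
    detJ : (..., Q) its determinant (must be positive).
    """
    elem = reference_element(cell_kind)
    vals, grads = elem.shape_functions(xi)  # (Q, n), (Q, n, 3)
    x = np.einsum("qa,...ai->...qi", vals, coords)
    J = np.einsum("...ai,qad->...qid", coords, grads)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0.0):
        bad = np.argwhere(detJ <= 0.0)
        first = int(bad[0][0]) if bad.ndim > 1 and detJ.ndim > 1 else None
        raise InvertedElementError(
            f"non-positive geometric Jacobian (first offending cell: {first})",
            cell=first,
        )
    return x, J, detJ
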