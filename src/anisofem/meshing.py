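"""Structured meshes for the artery and ventricle benchmarks.

Geometry conventions: lengths in mm, meshes live in reference configuration,
the tube and ellipsoid axes coincide with the global z-axis.  Cells are
stored in VTK node ordering (TET4 / HEX8).  Boundary facets carried in
``facet_tags`` are oriented outward (right-hand rule normal points out of
the solid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import HEX8, TET4, quadrature, reference_element

__all__ = [
    "Mesh",
    "FiberField",
    "InvalidGeometryError",
    "WrongCellKindError",
    "generate_tube_hex",
    "generate_box_hex",
    "hex_to_tet",
    "assign_tube_fibers",
    "generate_truncated_ellipsoid",
]


class InvalidGeometryError(ValueError):
    pass


class WrongCellKindError(TypeError):
    pass


# Outward-oriented local faces (VTK ordering).
_TET_FACES = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
_HEX_FACES = [
    (0, 3, 2, 1),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (2, 3, 7, 6),
    (0, 4, 7, 3),
    (1, 2, 6, 5),
]


@dataclass
class FiberField:
    """Per-cell orthonormal material triad (fiber, sheet, sheet-normal)."""

    f0: np.ndarray  # (M, 3)
    s0: np.ndarray  # (M, 3)
    n0: np.ndarray  # (M, 3)

    def __post_init__(self):
        for v in (self.f0, self.s0, self.n0):
            norms = np.linalg.norm(v, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-12):
                raise InvalidGeometryError("fiber vectors must have unit norm")


@dataclass
class Mesh:
    nodes: np.ndarray  # (N, 3) float
    cells: np.ndarray  # (M, 4|8) int
    cell_kind: str  # TET4 | HEX8
    facet_tags: dict[str, np.ndarray] = field(default_factory=dict)
    fibers: FiberField | None = None
    cell_data: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def nodes_per_cell(self) -> int:
        return 4 if self.cell_kind == TET4 else 8

    def cell_volumes(self) -> np.ndarray:
        """Reference volumes of all cells (exact for straight tets, 2x2x2
        Gauss for trilinear hexes)."""
        X = self.nodes[self.cells]  # (M, n, 3)
        if self.cell_kind == TET4:
            v = X[:, 1:] - X[:, :1]
            return np.linalg.det(v) / 6.0
        rule = quadrature(HEX8, 2)
        _, grads = reference_element(HEX8).shape_functions(rule.points)
        J = np.einsum("mai,qad->mqid", X, grads)
        return np.einsum("q,mq->m", rule.weights, np.linalg.det(J))

    def boundary_facets(self) -> np.ndarray:
        """All boundary facets, outward oriented, as an (K, 3|4) index array."""
        faces = _TET_FACES if self.cell_kind == TET4 else _HEX_FACES
        all_faces = np.concatenate(
            [self.cells[:, f] for f in faces], axis=0
        )  # (M * nf, fn)
        key = np.sort(all_faces, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        return all_faces[counts[inv] == 1]

    def validate(self) -> None:
        """Raise if connectivity, volumes, tags, or fibers are inconsistent."""
        if self.cells.min() < 0 or self.cells.max() >= self.n_nodes:
            raise InvalidGeometryError("cell references an invalid node index")
        vols = self.cell_volumes()
        if np.any(vols <= 0.0):
            raise InvalidGeometryError(
                f"{int((vols <= 0).sum())} cells have non-positive volume"
            )
        boundary = {
            tuple(sorted(f)) for f in self.boundary_facets().tolist()
        }
        for tag, facets in self.facet_tags.items():
            for f in facets.tolist():
                if tuple(sorted(f)) not in boundary:
                    raise InvalidGeometryError(
                        f"facet tag {tag!r} contains a non-boundary facet"
                    )
        if self.fibers is not None and len(self.fibers.f0) != self.n_cells:
            raise InvalidGeometryError("fiber field length != cell count")


def _orient_facets_outward(mesh_nodes, facets, interior_point_per_facet):
    """Flip facets whose right-hand normal points toward the given interior
    points (used after geometric tag extraction)."""
    P = mesh_nodes[facets]
    n = np.cross(P[:, 1] - P[:, 0], P[:, 2] - P[:, 1])
    centroid = P.mean(axis=1)
    flip = np.einsum("ki,ki->k", n, centroid - interior_point_per_facet) < 0
    out = facets.copy()
    out[flip] = out[flip, ::-1]
    return out


# --- tube ------------------------------------------------------------------


def generate_tube_hex(R1: float, R2: float, H: float, level: int) -> Mesh:
    """Structured hexahedral thick-walled tube, centerline on the z-axis.

    Subdivisions are ``(24*level, 10*level, 4*level)`` in the circumferential,
    axial and radial directions, so the cell count is ``960 * level**3`` and
    the node count ``24*level * (10*level + 1) * (4*level + 1)``.  Facet tags:
    BOTTOM (z=0), TOP (z=H), INNER (r=R1), OUTER (r=R2).
    """
    if not (0 < R1 < R2) or H <= 0:
        raise InvalidGeometryError(
            f"need 0 < R1 < R2 and H > 0, got R1={R1}, R2={R2}, H={H}"
        )
    if level < 1 or int(level) != level:
        raise InvalidGeometryError("refinement level must be a positive integer")
    nt, nz, nr = 24 * level, 10 * level, 4 * level

    theta = 2.0 * np.pi * np.arange(nt) / nt
    z = np.linspace(0.0, H, nz + 1)
    r = np.linspace(R1, R2, nr + 1)
    # node id = (ir * (nz+1) + iz) * nt + it
    T, Z, R = np.meshgrid(theta, z, r, indexing="ij")  # (nt, nz+1, nr+1)
    nodes = np.stack(
        [R * np.cos(T), R * np.sin(T), Z], axis=-1
    ).transpose(2, 1, 0, 3).reshape(-1, 3)

    def nid(it, iz, ir):
        return (ir * (nz + 1) + iz) * nt + np.mod(it, nt)

    it, iz, ir = np.meshgrid(
        np.arange(nt), np.arange(nz), np.arange(nr), indexing="ij"
    )
    it, iz, ir = it.ravel(), iz.ravel(), ir.ravel()
    # VTK hex with (xi, eta, zeta) = (theta, z, r): right-handed.
    cells = np.stack(
        [
            nid(it, iz, ir),
            nid(it + 1, iz, ir),
            nid(it + 1, iz + 1, ir),
            nid(it, iz + 1, ir),
            nid(it, iz, ir + 1),
            nid(it + 1, iz, ir + 1),
            nid(it + 1, iz + 1, ir + 1),
            nid(it, iz + 1, ir + 1),
        ],
        axis=1,
    )
    mesh = Mesh(nodes=nodes, cells=cells, cell_kind=HEX8)
    mesh.facet_tags = _tag_tube_facets(mesh, R1, R2, H)
    return mesh


def _tag_tube_facets(mesh: Mesh, R1: float, R2: float, H: float):
    facets = mesh.boundary_facets()
    P = mesh.nodes[facets]
    rad = np.linalg.norm(P[..., :2], axis=-1)
    zc = P[..., 2]
    tol = 1e-9 * max(R2, H)
    tags = {}
    sel = {
        "BOTTOM": np.all(np.abs(zc) < tol, axis=1),
        "TOP": np.all(np.abs(zc - H) < tol, axis=1),
        "INNER": np.all(np.abs(rad - R1) < tol, axis=1),
        "OUTER": np.all(np.abs(rad - R2) < tol, axis=1),
    }
    for name, mask in sel.items():
        tags[name] = facets[mask]
    return tags


# --- unit box --------------------------------------------------------------


def generate_box_hex(
    nx: int, ny: int, nz: int, lengths=(1.0, 1.0, 1.0)
) -> Mesh:
    """Structured hexahedral box ``[0, Lx] x [0, Ly] x [0, Lz]`` with facet
    tags XMIN/XMAX/YMIN/YMAX/ZMIN/ZMAX."""
    if min(nx, ny, nz) < 1 or min(lengths) <= 0:
        raise InvalidGeometryError("box subdivisions and lengths must be positive")
    Lx, Ly, Lz = lengths
    xs = np.linspace(0, Lx, nx + 1)
    ys = np.linspace(0, Ly, ny + 1)
    zs = np.linspace(0, Lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    cells = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    )
    mesh = Mesh(nodes=nodes, cells=cells, cell_kind=HEX8)
    facets = mesh.boundary_facets()
    P = nodes[facets]
    tol = 1e-12 * max(lengths)
    sel = {
        "XMIN": np.all(np.abs(P[..., 0]) < tol, axis=1),
        "XMAX": np.all(np.abs(P[..., 0] - Lx) < tol, axis=1),
        "YMIN": np.all(np.abs(P[..., 1]) < tol, axis=1),
        "YMAX": np.all(np.abs(P[..., 1] - Ly) < tol, axis=1),
        "ZMIN": np.all(np.abs(P[..., 2]) < tol, axis=1),
        "ZMAX": np.all(np.abs(P[..., 2] - Lz) < tol, axis=1),
    }
    mesh.facet_tags = {name: facets[m] for name, m in sel.items()}
    return mesh


# --- hex -> tet ------------------------------------------------------------


def _fan_face(face_globals):
    """Split a (possibly degenerate) quad or triangle face into triangles by
    fanning from its minimum global vertex; preserves orientation."""
    g = list(face_globals)
    m = int(np.argmin(g))
    g = g[m:] + g[:m]
    tris = []
    for a, b in zip(g[1:-1], g[2:]):
        tri = (g[0], a, b)
        if len(set(tri)) == 3:
            tris.append(tri)
    return tris


def _cone_tets(cell_globals, faces):
    """Tetrahedralize one cell by coning its min-index vertex onto the fanned
    far faces.  Every resulting face diagonal passes through the min global
    vertex of that face, which makes the subdivision conforming across cells
    that apply the same rule."""
    v0 = min(set(cell_globals))
    tets = []
    for f in faces:
        fg = [cell_globals[i] for i in f]
        if v0 in fg:
            continue
        for tri in _fan_face(fg):
            tet = (v0,) + tri
            if len(set(tet)) == 4:
                tets.append(tet)
    return tets


def _cone_tets_hex_vectorized(cells: np.ndarray) -> np.ndarray:
    """Vectorized cone-from-min-vertex subdivision for non-degenerate hexes:
    (M, 8) connectivity -> (M, 6, 4) tets, same rule as :func:`_cone_tets`."""
    M = len(cells)
    out = np.empty((M, 6, 4), dtype=cells.dtype)
    v0pos = np.argmin(cells, axis=1)
    for pos in range(8):
        sel = np.flatnonzero(v0pos == pos)
        if len(sel) == 0:
            continue
        sub = cells[sel]
        v0g = sub[:, pos]
        far = [f for f in _HEX_FACES if pos not in f]
        for fi, f in enumerate(far):
            fg = sub[:, f]  # (k, 4), outward oriented
            mrot = np.argmin(fg, axis=1)
            for rot in range(4):
                rsel = np.flatnonzero(mrot == rot)
                if len(rsel) == 0:
                    continue
                order = [(rot + i) % 4 for i in range(4)]
                g = fg[rsel][:, order]
                rows = sel[rsel]
                out[rows, 2 * fi, 0] = v0g[rsel]
                out[rows, 2 * fi, 1:] = g[:, [0, 1, 2]]
                out[rows, 2 * fi + 1, 0] = v0g[rsel]
                out[rows, 2 * fi + 1, 1:] = g[:, [0, 2, 3]]
    return out


def hex_to_tet(mesh: Mesh) -> Mesh:
    """Split each hexahedron into 6 tetrahedra (conforming; volume is
    conserved exactly for planar-faced hexes such as the tube cells)."""
    if mesh.cell_kind != HEX8:
        raise WrongCellKindError("hex_to_tet requires a hexahedral mesh")
    srt = np.sort(mesh.cells, axis=1)
    if np.all(srt[:, 1:] != srt[:, :-1]):
        cells = _cone_tets_hex_vectorized(mesh.cells).reshape(-1, 4)
        tet_parent = np.repeat(np.arange(mesh.n_cells), 6).tolist()
    else:
        tets = []
        tet_parent = []
        for m, cell in enumerate(mesh.cells.tolist()):
            for t in _cone_tets(cell, _HEX_FACES):
                tets.append(t)
                tet_parent.append(m)
        cells = np.array(tets, dtype=mesh.cells.dtype)
    # enforce positive orientation
    X = mesh.nodes[cells]
    vol6 = np.linalg.det(X[:, 1:] - X[:, :1])
    swap = vol6 < 0
    cells[swap] = cells[swap][:, [0, 2, 1, 3]]

    tags = {
        name: np.array(
            [t for f in facets.tolist() for t in _fan_face(f)],
            dtype=mesh.cells.dtype,
        ).reshape(-1, 3)
        for name, facets in mesh.facet_tags.items()
    }
    out = Mesh(nodes=mesh.nodes.copy(), cells=cells, cell_kind=TET4, facet_tags=tags)
    parent = np.array(tet_parent)
    if mesh.fibers is not None:
        out.fibers = FiberField(
            mesh.fibers.f0[parent], mesh.fibers.s0[parent], mesh.fibers.n0[parent]
        )
    for name, data in mesh.cell_data.items():
        out.cell_data[name] = data[parent]
    out.cell_data["parent_cell"] = parent
    return out


# --- fibers ----------------------------------------------------------------


def assign_tube_fibers(mesh: Mesh, angle_deg: float) -> Mesh:
    """Attach the two symmetric helical fiber families of the artery
    benchmark: ``f0 = cos(a) e_theta + sin(a) e_z`` and
    ``s0 = cos(a) e_theta - sin(a) e_z`` evaluated at each cell centroid,
    with ``n0 = e_r``."""
    cent = mesh.nodes[mesh.cells].mean(axis=1)
    r = np.linalg.norm(cent[:, :2], axis=1)
    if np.any(r < 1e-12):
        raise InvalidGeometryError(
            "cell centroid on the z-axis: circumferential direction undefined"
        )
    e_t = np.stack([-cent[:, 1] / r, cent[:, 0] / r, np.zeros_like(r)], axis=1)
    e_z = np.zeros_like(e_t)
    e_z[:, 2] = 1.0
    e_r = np.stack([cent[:, 0] / r, cent[:, 1] / r, np.zeros_like(r)], axis=1)
    a = np.deg2rad(angle_deg)
    f0 = np.cos(a) * e_t + np.sin(a) * e_z
    s0 = np.cos(a) * e_t - np.sin(a) * e_z
    mesh.fibers = FiberField(f0=f0, s0=s0, n0=e_r)
    return mesh


# --- truncated ellipsoid ---------------------------------------------------


def _ellipsoid_point(rs, rl, u, phi):
    return np.stack(
        [
            rs * np.sin(u) * np.cos(phi),
            rs * np.sin(u) * np.sin(phi),
            -rl * np.cos(u),
        ],
        axis=-1,
    )


def generate_truncated_ellipsoid(
    r_s_endo: float = 7.0,
    r_l_endo: float = 17.0,
    r_s_epi: float = 10.0,
    r_l_epi: float = 20.0,
    truncation_z: float = 5.0,
    resolution: int = 2,
    helix_endo_deg: float = 90.0,
    helix_epi_deg: float = -90.0,
) -> Mesh:
    """Tetrahedral mesh of the wall between two prolate ellipsoids truncated
    by the base plane ``z = truncation_z`` (apex pointing down the negative
    z-axis, both ellipsoids centered at the origin).

    Facet tags: ENDO, EPI, BASE.  Each cell carries a fiber triad whose helix
    angle rotates linearly across the wall from ``helix_endo_deg`` at the
    endocardium to ``helix_epi_deg`` at the epicardium, in the local
    (circumferential, longitudinal, transmural) frame.
    """
    if not (0 < r_s_endo < r_s_epi and 0 < r_l_endo < r_l_epi):
        raise InvalidGeometryError("epicardial radii must exceed endocardial radii")
    if not (-r_l_endo < truncation_z < r_l_endo):
        raise InvalidGeometryError("truncation plane must cut both ellipsoids")
    if resolution < 1:
        raise InvalidGeometryError("resolution must be >= 1")

    n_t = resolution
    n_u = 4 * resolution
    n_p = 8 * resolution

    ts = np.linspace(0.0, 1.0, n_t + 1)
    rs_t = r_s_endo + (r_s_epi - r_s_endo) * ts
    rl_t = r_l_endo + (r_l_epi - r_l_endo) * ts
    umax_t = np.arccos(np.clip(-truncation_z / rl_t, -1.0, 1.0))
    phis = 2.0 * np.pi * np.arange(n_p) / n_p

    apex_ids = np.arange(n_t + 1)
    nodes = [_ellipsoid_point(rs_t, rl_t, 0.0, 0.0)]  # (n_t+1, 3) apex column

    def nid(i_u, i_p, i_t):
        # i_u in 0..n_u, 0 is the apex node of layer i_t
        if np.isscalar(i_u):
            if i_u == 0:
                return apex_ids[i_t]
        off = n_t + 1
        return off + (np.asarray(i_t) * n_u + (np.asarray(i_u) - 1)) * n_p + np.mod(
            i_p, n_p
        )

    grid = np.empty((n_t + 1, n_u, n_p, 3))
    for j in range(n_t + 1):
        us = umax_t[j] * np.arange(1, n_u + 1) / n_u
        U, P = np.meshgrid(us, phis, indexing="ij")
        grid[j] = _ellipsoid_point(rs_t[j], rl_t[j], U, P)
    nodes.append(grid.reshape(-1, 3))
    nodes = np.concatenate(nodes, axis=0)

    cells, fiber_rows, depth = [], [], []

    def centroid_params(i_u, i_p, i_t):
        return (
            (i_u + 0.5) / n_u,
            2.0 * np.pi * (i_p + 0.5) / n_p,
            (i_t + 0.5) / n_t,
        )

    for j in range(n_t):
        for i in range(n_u):
            for k in range(n_p):
                corners = [
                    nid(i, k, j),
                    nid(i + 1, k, j),
                    nid(i + 1, k + 1, j),
                    nid(i, k + 1, j),
                    nid(i, k, j + 1),
                    nid(i + 1, k, j + 1),
                    nid(i + 1, k + 1, j + 1),
                    nid(i, k + 1, j + 1),
                ]
                corners = [int(c) for c in corners]
                for t in _cone_tets(corners, _HEX_FACES):
                    cells.append(t)
                    fiber_rows.append(centroid_params(i, k, j))
                    depth.append((j + 0.5) / n_t)
    cells = np.array(cells, dtype=np.int64)
    X = nodes[cells]
    vol6 = np.linalg.det(X[:, 1:] - X[:, :1])
    swap = vol6 < 0
    cells[swap] = cells[swap][:, [0, 2, 1, 3]]

    mesh = Mesh(nodes=nodes, cells=cells, cell_kind=TET4)
    mesh.cell_data["transmural_depth"] = np.array(depth)

    # fibers from the analytic parametrization at cell centroid parameters
    su, phi, st = np.array(fiber_rows).T
    tn = np.array(depth)
    rs_c = r_s_endo + (r_s_epi - r_s_endo) * st
    rl_c = r_l_endo + (r_l_epi - r_l_endo) * st
    umax_c = np.arccos(np.clip(-truncation_z / rl_c, -1.0, 1.0))
    u = su * umax_c
    e_c = np.stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=1)
    dp_du = np.stack(
        [
            rs_c * np.cos(u) * np.cos(phi),
            rs_c * np.cos(u) * np.sin(phi),
            rl_c * np.sin(u),
        ],
        axis=1,
    )
    e_l = dp_du - np.einsum("mi,mi->m", dp_du, e_c)[:, None] * e_c
    e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)
    e_t = np.cross(e_c, e_l)
    alpha = np.deg2rad(helix_endo_deg + (helix_epi_deg - helix_endo_deg) * tn)
    f0 = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
    s0 = e_t
    n0 = np.cross(f0, s0)
    n0 /= np.linalg.norm(n0, axis=1, keepdims=True)
    mesh.fibers = FiberField(f0=f0, s0=s0, n0=n0)

    # tags: classify boundary facets geometrically
    facets = mesh.boundary_facets()
    P = nodes[facets]
    tol = 1e-9 * r_l_epi
    on_base = np.all(np.abs(P[..., 2] - truncation_z) < tol, axis=1)
    q_endo = (
        (P[..., 0] / r_s_endo) ** 2
        + (P[..., 1] / r_s_endo) ** 2
        + (P[..., 2] / r_l_endo) ** 2
    )
    q_epi = (
        (P[..., 0] / r_s_epi) ** 2
        + (P[..., 1] / r_s_epi) ** 2
        + (P[..., 2] / r_l_epi) ** 2
    )
    on_endo = np.all(np.abs(q_endo - 1.0) < 1e-9, axis=1) & ~on_base
    on_epi = np.all(np.abs(q_epi - 1.0) < 1e-9, axis=1) & ~on_base
    mesh.facet_tags = {
        "ENDO": facets[on_endo],
        "EPI": facets[on_epi],
        "BASE": facets[on_base],
    }
    return mesh
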