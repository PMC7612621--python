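"""Global assembly, Dirichlet constraints, Newton iteration, load stepping.

The global unknown vector is ``[u (3 per node); p (1 per node)]`` for the
saddle-point technologies (projection, MINI, plain equal-order) and ``[u]``
only for the condensed P0 penalty.  MINI bubble displacements live in the
solution state but never in the global system; their increments are
recovered element by element after each linear solve.

The quasi-static continuation applies all loads (Dirichlet ramps, follower
pressures, active stress) along a linear pseudo-time ramp t in [0, 1],
solving each step with Newton's method to a relative residual reduction
(default 1e-6, following common practice for these benchmarks) and halving
steps on failure (bounded retries).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .forms import (
    Discretization,
    ElementKernels,
    FollowerLoadKernel,
)
from .materials import InvertedStateError, MaterialModel
from .meshing import Mesh

__all__ = [
    "DirichletSpec",
    "FollowerSpec",
    "LoadProgram",
    "NewtonSettings",
    "SolutionState",
    "StepReport",
    "SolveReport",
    "FEProblem",
    "newton_solve",
    "run_load_program",
    "linear_solve",
    "SingularSystemError",
]


class SingularSystemError(RuntimeError):
    pass


class StepFailure(RuntimeError):
    pass


@dataclass
class DirichletSpec:
    """Prescribed displacement on a tagged surface.

    ``ramp(X, t)`` maps reference node coordinates ``(n, 3)`` and pseudo-time
    ``t in [0, 1]`` to prescribed displacements ``(n, 3)``; components set to
    NaN are left free.
    """

    tag: str
    ramp: Callable[[np.ndarray, float], np.ndarray]

    @classmethod
    def fixed(cls, tag: str):
        return cls(tag, lambda X, t: np.zeros_like(X))

    @classmethod
    def translation_rotation_z(
        cls, tag: str, translation, angle_deg: float = 0.0
    ):
        """Ramp combining an axial translation with an exact rotation about
        the z-axis (rotation of coordinates, not linearized)."""
        translation = np.asarray(translation, dtype=float)

        def ramp(X, t):
            a = np.deg2rad(angle_deg) * t
            c, s = np.cos(a), np.sin(a)
            x = c * X[:, 0] - s * X[:, 1]
            y = s * X[:, 0] + c * X[:, 1]
            u = np.stack([x - X[:, 0], y - X[:, 1], np.zeros(len(X))], axis=1)
            return u + t * translation

        return cls(tag, ramp)


MMHG_TO_KPA = 0.1333224


@dataclass
class FollowerSpec:
    """Follower pressure on a tagged surface, ramped linearly to its final
    value.  Input units may be mmHg (converted at 1 mmHg = 0.1333224 kPa)
    or kPa."""

    tag: str
    pressure: float
    units: str = "kPa"

    @property
    def pressure_kpa(self) -> float:
        if self.units.lower() == "mmhg":
            return self.pressure * MMHG_TO_KPA
        if self.units.lower() == "kpa":
            return self.pressure
        raise ValueError(f"unknown pressure units {self.units!r}")


@dataclass
class LoadProgram:
    n_steps: int
    dirichlet: list[DirichletSpec] = field(default_factory=list)
    followers: list[FollowerSpec] = field(default_factory=list)
    body_force: np.ndarray | None = None  # constant rho0*f per unit volume
    active_stress: Callable[[float], float] | None = None  # S_a(t) in kPa
    kappa_f_active: float = 0.0


@dataclass
class NewtonSettings:
    rtol: float = 1e-6
    lin_rtol: float = 1e-8
    max_iterations: int = 25
    max_step_cuts: int = 4
    atol: float = 1e-11
    #: backtracking line-search halvings per Newton iteration (0 disables);
    #: trial steps that invert elements are always backtracked
    max_line_search: int = 5

    def __post_init__(self):
        if not (0 < self.rtol < 1 and 0 < self.lin_rtol < 1):
            raise ValueError("tolerances must lie in (0, 1)")


@dataclass
class SolutionState:
    u: np.ndarray  # (N, 3)
    p: np.ndarray  # (N,) or (0,)
    bubbles: np.ndarray  # (M, n_bubbles, 3)

    def copy(self):
        return SolutionState(self.u.copy(), self.p.copy(), self.bubbles.copy())


@dataclass
class StepReport:
    t: float
    iterations: int
    residual_norms: list
    converged: bool
    n_linear_solves: int


@dataclass
class SolveReport:
    steps: list = field(default_factory=list)
    completed: bool = True

    @property
    def total_linear_solves(self):
        return sum(s.n_linear_solves for s in self.steps)


def linear_solve(A: sp.spmatrix, b: np.ndarray) -> np.ndarray:
    """Sparse direct solve with a singularity diagnostic naming the dof."""
    A = A.tocsc()
    try:
        lu = spla.splu(A)
        x = lu.solve(b)
    except RuntimeError as exc:
        raise SingularSystemError(f"linear system is singular: {exc}") from exc
    if not np.all(np.isfinite(x)):
        bad = int(np.argmax(~np.isfinite(x)))
        raise SingularSystemError(
            f"linear solve produced a non-finite value at dof {bad}"
        )
    return x


class FEProblem:
    """Binds mesh, discretization, and material into assemble/solve calls."""

    def __init__(
        self,
        mesh: Mesh,
        disc: Discretization,
        material: MaterialModel,
        program: LoadProgram,
    ):
        self.mesh = mesh
        self.disc = disc
        self.material = material
        self.program = program
        self.kernels = ElementKernels(mesh, disc, material)
        for spec in program.dirichlet:
            if spec.tag not in mesh.facet_tags:
                raise KeyError(f"unknown Dirichlet tag {spec.tag!r}")
        self.followers = [
            (FollowerLoadKernel(mesh, s.tag), s.pressure_kpa)
            for s in program.followers
        ]
        N = mesh.n_nodes
        self.n_u = 3 * N
        self.n_p = N if disc.per_node_pressure else 0
        self.n_dofs = self.n_u + self.n_p
        # element dof map (external dofs only)
        cells = mesh.cells
        udofs = (3 * cells[:, :, None] + np.arange(3)[None, None, :]).reshape(
            len(cells), -1
        )
        if self.n_p:
            self.edofs = np.concatenate([udofs, self.n_u + cells], axis=1)
        else:
            self.edofs = udofs
        self._assembly_pattern = None

    # -- state --------------------------------------------------------------

    def initial_state(self) -> SolutionState:
        return SolutionState(
            u=np.zeros((self.mesh.n_nodes, 3)),
            p=np.zeros(self.mesh.n_nodes if self.n_p else 0),
            bubbles=np.zeros((self.mesh.n_cells, self.disc.n_bubbles, 3)),
        )

    def _element_u(self, state: SolutionState) -> np.ndarray:
        u_nodes = state.u[self.mesh.cells]
        if self.disc.n_bubbles:
            return np.concatenate([u_nodes, state.bubbles], axis=1)
        return u_nodes

    def _element_p(self, state: SolutionState) -> np.ndarray:
        if self.n_p:
            return state.p[self.mesh.cells]
        return np.zeros((self.mesh.n_cells, 0))

    # -- Dirichlet ----------------------------------------------------------

    def dirichlet_arrays(self, t: float):
        """(constrained dof indices, prescribed values) at pseudo-time t."""
        idx, vals = [], []
        for spec in self.program.dirichlet:
            nodes = np.unique(self.mesh.facet_tags[spec.tag])
            g = spec.ramp(self.mesh.nodes[nodes], t)
            for d in range(3):
                keep = ~np.isnan(g[:, d])
                idx.append(3 * nodes[keep] + d)
                vals.append(g[keep, d])
        if not idx:
            return np.array([], dtype=int), np.array([])
        idx = np.concatenate(idx)
        vals = np.concatenate(vals)
        idx, order = np.unique(idx, return_index=True)
        return idx, vals[order]

    # -- assembly -----------------------------------------------------------

    def assemble(self, state: SolutionState, t: float):
        """Global sparse tangent and residual at pseudo-time t.

        Returns ``(K, R, recovery)``; ``recovery`` reconstructs bubble
        increments from the solved element increments.
        """
        prog = self.program
        Sa = prog.active_stress(t) if prog.active_stress else None
        sys = self.kernels.tangent(
            self._element_u(state),
            self._element_p(state),
            active_stress=Sa,
            kappa_f=prog.kappa_f_active,
        )
        K_el, r_el = sys.K, sys.r

        R = np.zeros(self.n_dofs)
        np.add.at(R, self.edofs.ravel(), r_el.ravel())

        rows = np.repeat(self.edofs, self.edofs.shape[1], axis=1).ravel()
        cols = np.tile(self.edofs, (1, self.edofs.shape[1])).ravel()
        data = [K_el.ravel()]
        row_list, col_list = [rows], [cols]

        for kern, p_final in self.followers:
            p_ext = t * p_final
            u_f = state.u[kern.facets]
            f, K_f = kern.residual_and_tangent(u_f, p_ext)
            fdofs = (
                3 * kern.facets[:, :, None] + np.arange(3)[None, None, :]
            ).reshape(len(kern.facets), -1)
            np.add.at(R, fdofs.ravel(), -f.ravel())
            row_list.append(
                np.repeat(fdofs, fdofs.shape[1], axis=1).ravel()
            )
            col_list.append(np.tile(fdofs, (1, fdofs.shape[1])).ravel())
            data.append(K_f.reshape(len(kern.facets), -1).ravel())

        if prog.body_force is not None:
            # constant body force: lumped via int N_a dX per node
            w = self.kernels.wdetJ
            vals = self.kernels.shape_vals[:, : self.kernels.elem.n_vertices]
            fe = np.einsum("mq,qa,i->mai", w, vals, t * prog.body_force)
            udofs = (
                3 * self.mesh.cells[:, :, None] + np.arange(3)[None, None, :]
            )
            np.add.at(R, udofs.ravel(), -fe.ravel())

        K = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(row_list), np.concatenate(col_list))),
            shape=(self.n_dofs, self.n_dofs),
        ).tocsr()
        return K, R, sys.recovery

    def residual_only(self, state: SolutionState, t: float) -> np.ndarray:
        """Global residual without tangent assembly (used by line search)."""
        prog = self.program
        Sa = prog.active_stress(t) if prog.active_stress else None
        r_u, r_p = self.kernels.residual(
            self._element_u(state),
            self._element_p(state),
            active_stress=Sa,
            kappa_f=prog.kappa_f_active,
        )
        R = np.zeros(self.n_dofs)
        cells = self.mesh.cells
        udofs = 3 * cells[:, :, None] + np.arange(3)[None, None, :]
        nv = self.kernels.elem.n_vertices
        np.add.at(R, udofs.ravel(), r_u[:, :nv, :].ravel())
        if self.n_p:
            np.add.at(R, (self.n_u + cells).ravel(), r_p.ravel())
        for kern, p_final in self.followers:
            f, _ = kern.residual_and_tangent(
                state.u[kern.facets], t * p_final, want_tangent=False
            )
            fdofs = 3 * kern.facets[:, :, None] + np.arange(3)[None, None, :]
            np.add.at(R, fdofs.ravel(), -f.ravel())
        if prog.body_force is not None:
            w = self.kernels.wdetJ
            vals = self.kernels.shape_vals[:, :nv]
            fe = np.einsum("mq,qa,i->mai", w, vals, t * prog.body_force)
            np.add.at(R, udofs.ravel(), -fe.ravel())
        return R

    # -- Newton -------------------------------------------------------------

    def newton_solve(
        self, state: SolutionState, t: float, settings: NewtonSettings
    ) -> tuple[SolutionState, StepReport]:
        """Solve the equilibrium at pseudo-time t starting from ``state``.

        Dirichlet values are imposed exactly at the start of the step, then
        Newton iterates on the free dofs until the residual norm drops below
        ``rtol`` times its initial value.
        """
        state = state.copy()
        didx, dvals = self.dirichlet_arrays(t)
        if len(didx):
            state.u.reshape(-1)[didx] = dvals
        free = np.ones(self.n_dofs, dtype=bool)
        free[didx] = False

        norms = []
        n_lin = 0
        for it in range(settings.max_iterations):
            try:
                K, R, recovery = self.assemble(state, t)
            except InvertedStateError as exc:
                raise StepFailure(str(exc)) from exc
            rnorm = float(np.linalg.norm(R[free]))
            norms.append(rnorm)
            if rnorm <= max(settings.rtol * norms[0], settings.atol):
                return state, StepReport(t, it, norms, True, n_lin)
            Kff = K[free][:, free]
            try:
                delta_f = linear_solve(Kff, -R[free])
            except SingularSystemError as exc:
                raise StepFailure(str(exc)) from exc
            delta = np.zeros(self.n_dofs)
            delta[free] = delta_f
            n_lin += 1
            db = None
            if recovery is not None:
                db = recovery.bubble_increments(delta[self.edofs])

            def apply(alpha):
                trial = state.copy()
                trial.u += alpha * delta[: self.n_u].reshape(-1, 3)
                if self.n_p:
                    trial.p += alpha * delta[self.n_u :]
                if db is not None:
                    trial.bubbles += alpha * db.reshape(trial.bubbles.shape)
                return trial

            # backtracking on the (external) residual norm; trial steps that
            # invert elements always backtrack
            alpha = 1.0
            accepted = None
            for ls in range(settings.max_line_search + 1):
                trial = apply(alpha)
                try:
                    Rt = self.residual_only(trial, t)
                except InvertedStateError:
                    alpha *= 0.5
                    continue
                tn = float(np.linalg.norm(Rt[free]))
                if not np.isfinite(tn):
                    alpha *= 0.5
                    continue
                if tn < rnorm or ls == settings.max_line_search:
                    accepted = trial
                    break
                alpha *= 0.5
            if accepted is None:
                raise StepFailure(
                    "line search could not avoid element inversion"
                )
            state = accepted
        return state, StepReport(t, len(norms), norms, False, n_lin)

    # -- continuation -------------------------------------------------------

    @staticmethod
    def _predict(state, prev, t_cur, t_next):
        """Secant extrapolation of the previous two converged states (the
        standard continuation predictor); pressure and bubbles extrapolate
        with the displacements."""
        if prev is None:
            return state
        t_prev, state_prev = prev
        if t_cur - t_prev <= 0:
            return state
        fac = (t_next - t_cur) / (t_cur - t_prev)
        guess = state.copy()
        guess.u += fac * (state.u - state_prev.u)
        if guess.p.size:
            guess.p += fac * (state.p - state_prev.p)
        guess.bubbles += fac * (state.bubbles - state_prev.bubbles)
        return guess

    def run(
        self, settings: NewtonSettings | None = None, on_step=None
    ) -> tuple[list[SolutionState], SolveReport]:
        """Load-stepping continuation over the program's pseudo-time ramp.

        Each step warm-starts Newton from a secant extrapolation of the two
        previous converged states; failed steps are halved (down to the
        configured cut limit per nominal step)."""
        settings = settings or NewtonSettings()
        state = self.initial_state()
        history = [state.copy()]
        report = SolveReport()
        pending = list(np.linspace(0.0, 1.0, self.program.n_steps + 1)[1:])
        dt_min = (1.0 / self.program.n_steps) / 2**settings.max_step_cuts
        t_cur = 0.0
        prev = None
        while pending:
            t_next = pending[0]
            converged = None
            guesses = [self._predict(state, prev, t_cur, t_next)]
            if prev is not None:
                guesses.append(state)
            for guess in guesses:
                try:
                    new_state, step = self.newton_solve(guess, t_next, settings)
                except StepFailure:
                    continue
                if step.converged:
                    converged = (new_state, step)
                    break
            if converged is None:
                dt = t_next - t_cur
                if dt / 2.0 < dt_min:
                    report.completed = False
                    return history, report
                pending.insert(0, t_cur + dt / 2.0)
                continue
            new_state, step = converged
            report.steps.append(step)
            if on_step is not None:
                on_step(step)
            prev = (t_cur, state)
            state, t_cur = new_state, t_next
            pending.pop(0)
            history.append(state.copy())
        return history, report


def newton_solve(problem: FEProblem, state, t, settings=None):
    """Functional wrapper over :meth:`FEProblem.newton_solve`."""
    return problem.newton_solve(state, t, settings or NewtonSettings())


def run_load_program(
    mesh: Mesh,
    disc: Discretization,
    material: MaterialModel,
    program: LoadProgram,
    settings: NewtonSettings | None = None,
):
    """Build an :class:`FEProblem` and run the full continuation."""
    problem = FEProblem(mesh, disc, material, program)
    history, report = problem.run(settings)
    return history, report, problem
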