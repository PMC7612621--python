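"""Hyperelastic constitutive models for fiber-reinforced soft tissue.

The framework is built around the multiplicative volumetric/isochoric split
``F = (J^{1/3} I) Fbar`` and the perturbed-Lagrangian treatment of (near)
incompressibility: the total second Piola-Kirchhoff stress is

    S_p = p * S_vol + S_isc,
    S_vol = pi(J) C^{-1},            pi(J) = J Theta'(J),
    S_isc = J^{-2/3} Dev(Sbar),      Sbar  = 2 dPsibar/dCbar,

with ``Dev(A) = A - (A : C)/3 * C^{-1}`` the Lagrangian deviatoric operator
and ``p`` the (applied hydrostatic) pressure field of the mixed formulation.
The consistent volumetric tangent is

    CC_vol = k(J) C^{-1} (x) C^{-1} - 2 pi(J) C^{-1} (.) C^{-1},
    k(J) = J^2 Theta''(J) + J Theta'(J),

and the isochoric tangent follows from the exact chain rule through
``Cbar = J^{-2/3} C`` (implemented in :func:`isochoric_push`).

Material families
-----------------
* ``NEOHOOKEAN_ISO`` -- isotropic neo-Hookean isochoric energy.
* ``GHT_ARTERY`` -- neo-Hookean matrix plus two symmetric exponential fiber
  families (the artery benchmark material).
* ``HOLZAPFEL_OGDEN`` -- exponential isotropic term, exponential fiber and
  sheet-normal families with compressed-fiber exclusion (fourth invariants
  floored at 1), and a fiber-sheet interaction term.
* ``GUELTEKIN_DISPERSION`` -- like Holzapfel-Ogden but with dispersion
  pseudo-invariants ``I4i* = kappa_i I1 + (1 - 3 kappa_i) I4i`` for the
  fiber and sheet families.
* ``FUNG_GUCCIONE`` -- transversely isotropic Fung exponential in the
  isochoric Green-Lagrange strain ``Ebar = (Cbar - I)/2``.

The anisotropic part can be evaluated on the isochoric ``Cbar`` (split mode
``AS``) or directly on the unsplit ``C`` (mode ``WAS``), in which case its
stress is added without deviatoric projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensors import I2, I4_SYM, ddot42, dyad, inv3, odot, sym, to_voigt

__all__ = [
    "VolumetricLaw",
    "volumetric_terms",
    "KinematicState",
    "kinematics",
    "dev_operator",
    "FiberTriad",
    "MaterialModel",
    "material_from_config",
    "active_stress_tensor",
    "active_stress_tangent",
    "cauchy_stress",
    "InvertedStateError",
]

J_MINUS_1 = "J_MINUS_1"
LOG_J = "LOG_J"

AS = "AS"
WAS = "WAS"


class InvertedStateError(RuntimeError):
    """det F <= 0 somewhere; the solver catches this to cut the load step."""


# --- volumetric law --------------------------------------------------------


@dataclass(frozen=True)
class VolumetricLaw:
    """Volumetric constraint function Theta with bulk modulus kappa (kPa).

    ``incompressible=True`` means 1/kappa = 0: the constraint Theta(J) = 0 is
    enforced exactly by the pressure Lagrange multiplier.  Both implemented
    choices satisfy Theta(1) = 0 and Theta'(1) = 1.
    """

    theta_kind: str = J_MINUS_1
    kappa: float = 1000.0
    incompressible: bool = False

    @property
    def inv_kappa(self) -> float:
        return 0.0 if self.incompressible else 1.0 / self.kappa

    def theta(self, J: np.ndarray):
        """Return (Theta, Theta', Theta'') at J."""
        J = np.asarray(J, dtype=float)
        if np.any(J <= 0.0):
            raise InvertedStateError("Theta evaluated at non-positive J")
        if self.theta_kind == J_MINUS_1:
            one = np.ones_like(J)
            return J - 1.0, one, np.zeros_like(J)
        if self.theta_kind == LOG_J:
            return np.log(J), 1.0 / J, -1.0 / J**2
        raise ValueError(f"unknown theta kind {self.theta_kind!r}")

    def pressure_coeffs(self, J: np.ndarray):
        """Return (pi(J), k(J)) = (J Theta', J^2 Theta'' + J Theta')."""
        _, d1, d2 = self.theta(J)
        J = np.asarray(J, dtype=float)
        return J * d1, J**2 * d2 + J * d1


def volumetric_terms(law: VolumetricLaw, J):
    """Convenience bundle (Theta, Theta', Theta'', pi(J), k(J))."""
    t, d1, d2 = law.theta(J)
    pi, k = law.pressure_coeffs(J)
    return t, d1, d2, pi, k


# --- kinematics ------------------------------------------------------------


@dataclass
class KinematicState:
    """Per-point deformation measures (batched over leading axes)."""

    F: np.ndarray
    J: np.ndarray
    C: np.ndarray
    Cbar: np.ndarray
    Cinv: np.ndarray

    def invariants(self, fibers: "FiberTriad") -> dict[str, np.ndarray]:
        f, s, n = fibers.f0, fibers.s0, fibers.n0
        quad = lambda A, a, b: np.einsum("...i,...ij,...j->...", a, A, b)
        return {
            "I1": np.einsum("...ii->...", self.C),
            "I1bar": np.einsum("...ii->...", self.Cbar),
            "I4f": quad(self.C, f, f),
            "I4s": quad(self.C, s, s),
            "I4n": quad(self.C, n, n),
            "I4fbar": quad(self.Cbar, f, f),
            "I4sbar": quad(self.Cbar, s, s),
            "I4nbar": quad(self.Cbar, n, n),
            "I8fs": quad(self.C, f, s),
            "I8fsbar": quad(self.Cbar, f, s),
        }


def kinematics(grad_u: np.ndarray) -> KinematicState:
    """Build the kinematic state from the displacement gradient."""
    grad_u = np.asarray(grad_u, dtype=float)
    F = grad_u + I2
    J = np.linalg.det(F)
    if not np.all(np.isfinite(J)) or np.any(J <= 0.0):
        raise InvertedStateError("non-positive or non-finite det F")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cbar = J[..., None, None] ** (-2.0 / 3.0) * C
    return KinematicState(F=F, J=J, C=C, Cbar=Cbar, Cinv=inv3(C))


def dev_operator(A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Lagrangian deviatoric projection ``Dev(A) = A - (A:C)/3 C^{-1}``."""
    Cinv = inv3(C)
    tr = np.einsum("...ij,...ij->...", A, C)
    return A - (tr / 3.0)[..., None, None] * Cinv


# --- fibers ----------------------------------------------------------------


@dataclass
class FiberTriad:
    """Unit fiber / sheet / sheet-normal directions (batched)."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    @classmethod
    def cartesian(cls):
        return cls(
            f0=np.array([1.0, 0.0, 0.0]),
            s0=np.array([0.0, 1.0, 0.0]),
            n0=np.array([0.0, 0.0, 1.0]),
        )

    def direction(self, name: str) -> np.ndarray:
        return getattr(self, name)


# --- energy terms ----------------------------------------------------------
# Each term returns (psi, S_term, CC_term) where S_term = 2 dpsi/dA and
# CC_term = 4 d^2 psi / dA^2 with respect to the term's own argument A
# (Cbar in AS mode, C in WAS mode for anisotropic terms).


def _outer(a, b):
    return np.einsum("...i,...j->...ij", a, b)


class NeoHookeTerm:
    """psi = mu/2 (I1 - 3)."""

    def __init__(self, mu: float):
        self.mu = mu

    def evaluate(self, A, fibers):
        I1 = np.einsum("...ii->...", A)
        psi = 0.5 * self.mu * (I1 - 3.0)
        S = self.mu * np.broadcast_to(I2, A.shape).copy()
        CC = np.zeros(A.shape + (3, 3))
        return psi, S, CC


class ExpIsoTerm:
    """psi = a/(2b) [exp(b (I1 - 3)) - 1]."""

    def __init__(self, a: float, b: float):
        self.a, self.b = a, b

    def evaluate(self, A, fibers):
        I1 = np.einsum("...ii->...", A)
        e = np.exp(self.b * (I1 - 3.0))
        psi = self.a / (2.0 * self.b) * (e - 1.0)
        d1 = 0.5 * self.a * e  # dpsi/dI1
        d2 = 0.5 * self.a * self.b * e
        S = 2.0 * d1[..., None, None] * np.broadcast_to(I2, A.shape)
        CC = 4.0 * d2[..., None, None, None, None] * dyad(
            np.broadcast_to(I2, A.shape), np.broadcast_to(I2, A.shape)
        )
        return psi, S, CC


class FiberExpTerm:
    """psi = k1/(2 k2) [exp(k2 <I4 - 1>^2) - 1] for one fiber direction.

    With ``floor=True`` the invariant is floored at 1 so compressed fibers
    contribute neither stress nor stiffness (one-sided derivative at I4 = 1).
    """

    def __init__(self, k1: float, k2: float, direction: str, floor: bool):
        self.k1, self.k2, self.direction, self.floor = k1, k2, direction, floor

    def evaluate(self, A, fibers):
        d = fibers.direction(self.direction)
        I4 = np.einsum("...i,...ij,...j->...", d, A, d)
        e = I4 - 1.0
        if self.floor:
            e = np.maximum(e, 0.0)
        g = np.exp(self.k2 * e**2)
        psi = self.k1 / (2.0 * self.k2) * (g - 1.0)
        d1 = self.k1 * e * g
        d2 = self.k1 * g * (1.0 + 2.0 * self.k2 * e**2)
        if self.floor:
            d2 = np.where(e > 0.0, d2, 0.0)
        M = _outer(d, d)
        M = np.broadcast_to(M, A.shape).copy()
        S = 2.0 * d1[..., None, None] * M
        CC = 4.0 * d2[..., None, None, None, None] * dyad(M, M)
        return psi, S, CC


class DispersionFiberTerm:
    """psi = a/(2b) [exp(b (I4* - 1)^2) - 1] with the dispersion
    pseudo-invariant ``I4* = kappa I1 + (1 - 3 kappa) I4``."""

    def __init__(self, a: float, b: float, kappa_disp: float, direction: str):
        if not 0.0 <= kappa_disp <= 1.0 / 3.0:
            raise ValueError("dispersion parameter must lie in [0, 1/3]")
        self.a, self.b, self.kd, self.direction = a, b, kappa_disp, direction

    def evaluate(self, A, fibers):
        d = fibers.direction(self.direction)
        I1 = np.einsum("...ii->...", A)
        I4 = np.einsum("...i,...ij,...j->...", d, A, d)
        Istar = self.kd * I1 + (1.0 - 3.0 * self.kd) * I4
        e = Istar - 1.0
        g = np.exp(self.b * e**2)
        psi = self.a / (2.0 * self.b) * (g - 1.0)
        d1 = self.a * e * g
        d2 = self.a * g * (1.0 + 2.0 * self.b * e**2)
        G = self.kd * np.broadcast_to(I2, A.shape) + (
            1.0 - 3.0 * self.kd
        ) * np.broadcast_to(_outer(d, d), A.shape)
        S = 2.0 * d1[..., None, None] * G
        CC = 4.0 * d2[..., None, None, None, None] * dyad(G, G)
        return psi, S, CC


class ShearExpTerm:
    """psi = a_fs/(2 b_fs) [exp(b_fs I8fs^2) - 1]."""

    def __init__(self, afs: float, bfs: float):
        self.afs, self.bfs = afs, bfs

    def evaluate(self, A, fibers):
        f, s = fibers.f0, fibers.s0
        I8 = np.einsum("...i,...ij,...j->...", f, A, s)
        g = np.exp(self.bfs * I8**2)
        psi = self.afs / (2.0 * self.bfs) * (g - 1.0)
        d1 = self.afs * I8 * g
        d2 = self.afs * g * (1.0 + 2.0 * self.bfs * I8**2)
        M = sym(_outer(f, s))
        M = np.broadcast_to(M, A.shape).copy()
        S = 2.0 * d1[..., None, None] * M
        CC = 4.0 * d2[..., None, None, None, None] * dyad(M, M)
        return psi, S, CC


class GuccioneTerm:
    """Transversely isotropic Fung exponential ``psi = a/2 (exp(Q) - 1)``
    with ``Q`` a quadratic form in the Green-Lagrange strain of the term's
    argument, ``E = (A - I)/2``, expressed in the material frame."""

    def __init__(self, a: float, bf: float, bt: float, bfs: float):
        self.a, self.bf, self.bt, self.bfs = a, bf, bt, bfs

    def _pairs(self, fibers):
        f, s, n = fibers.f0, fibers.s0, fibers.n0
        return [
            (self.bf, f, f),
            (self.bt, s, s),
            (self.bt, n, n),
            (2.0 * self.bt, s, n),
            (2.0 * self.bfs, f, s),
            (2.0 * self.bfs, f, n),
        ]

    def evaluate(self, A, fibers):
        E = 0.5 * (A - I2)
        Q = np.zeros(A.shape[:-2])
        dQ = np.zeros(A.shape)
        d2Q = np.zeros(A.shape + (3, 3))
        for c, u, v in self._pairs(fibers):
            Euv = np.einsum("...i,...ij,...j->...", u, E, v)
            M = sym(_outer(u, v))
            M = np.broadcast_to(M, A.shape).copy()
            Q = Q + c * Euv**2
            # dE_uv/dA = M/2
            dQ = dQ + c * Euv[..., None, None] * M
            d2Q = d2Q + 0.5 * c * dyad(M, M)
        g = np.exp(Q)
        psi = 0.5 * self.a * (g - 1.0)
        S = self.a * g[..., None, None] * dQ  # 2 * (a/2) e^Q dQ
        CC = 2.0 * self.a * g[..., None, None, None, None] * (
            dyad(dQ, dQ) + d2Q
        )
        return psi, S, CC


# --- isochoric projection --------------------------------------------------


def isochoric_push(C, Cinv, J, Sbar, CCbar):
    """Push a stress/tangent pair from the isochoric argument Cbar to C.

    Given ``Sbar = 2 dPsibar/dCbar`` and ``CCbar = 4 d^2Psibar/dCbar^2``,
    returns ``S_isc = J^{-2/3} Dev(Sbar)`` and the exact tangent
    ``CC_isc = 2 dS_isc/dC`` obtained from the chain rule through
    ``Cbar = J^{-2/3} C``.
    """
    g = J ** (-2.0 / 3.0)
    trSC = np.einsum("...ij,...ij->...", Sbar, C)
    S_isc = g[..., None, None] * (
        Sbar - (trSC / 3.0)[..., None, None] * Cinv
    )
    # projection tensor P_ijkl = dCbar_ij/dC_kl
    P = g[..., None, None, None, None] * (
        I4_SYM - dyad(C, Cinv) / 3.0
    )
    CC = np.einsum("...ijkl,...ijab,...abmn->...klmn", P, CCbar, P, optimize=True)
    gb = g[..., None, None, None, None]
    trb = trSC[..., None, None, None, None]
    CC = CC - (2.0 / 3.0) * gb * (dyad(Cinv, Sbar) + dyad(Sbar, Cinv))
    CC = CC + (2.0 / 9.0) * gb * trb * dyad(Cinv, Cinv)
    CC = CC + (2.0 / 3.0) * gb * trb * odot(Cinv, Cinv)
    return S_isc, CC


def volumetric_tangent(Cinv, pi, k):
    """``CC_vol = k(J) Cinv (x) Cinv - 2 pi(J) Cinv (.) Cinv``."""
    return k[..., None, None, None, None] * dyad(Cinv, Cinv) - 2.0 * pi[
        ..., None, None, None, None
    ] * odot(Cinv, Cinv)


# --- material model --------------------------------------------------------

_FAMILIES = (
    "NEOHOOKEAN_ISO",
    "GHT_ARTERY",
    "HOLZAPFEL_OGDEN",
    "GUELTEKIN_DISPERSION",
    "FUNG_GUCCIONE",
)


@dataclass
class MaterialModel:
    """A volumetric law plus isochoric/anisotropic strain-energy terms.

    ``split`` chooses whether the anisotropic terms act on the isochoric
    ``Cbar`` (``AS``) or the unsplit ``C`` (``WAS``).  In WAS mode the
    anisotropic stress is added directly, without deviatoric projection.
    """

    family: str
    split: str = AS
    params: dict = field(default_factory=dict)
    volumetric: VolumetricLaw = field(default_factory=VolumetricLaw)
    iso_terms: list = field(default_factory=list, repr=False)
    aniso_terms: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown material family {self.family!r}")
        if self.split not in (AS, WAS):
            raise ValueError(f"split must be AS or WAS, got {self.split!r}")
        p = self.params
        stress_like = [
            k for k in ("a", "mu", "a_f", "a_s", "a_n", "a_fs", "k1") if k in p
        ]
        if any(p[k] < 0 for k in stress_like):
            raise ValueError("stress-like parameters must be non-negative")
        if not self.iso_terms and not self.aniso_terms:
            self.iso_terms, self.aniso_terms = self._build_terms()
        if self.family == "FUNG_GUCCIONE" and self.split == WAS:
            raise ValueError(
                "the Fung-Guccione quadratic form does not admit a WAS split"
            )

    def _build_terms(self):
        p = self.params
        if self.family == "NEOHOOKEAN_ISO":
            return [NeoHookeTerm(p["mu"])], []
        if self.family == "GHT_ARTERY":
            # collagen fiber families bear load in extension only (tension-
            # field convention of HGO-type artery models); flooring the
            # fourth invariants at 1 also keeps the tangent stable under the
            # torsional part of the benchmark loading
            floor = bool(p.get("floor_fibers", True))
            return [NeoHookeTerm(p["mu"])], [
                FiberExpTerm(p["k1"], p["k2"], "f0", floor=floor),
                FiberExpTerm(p["k1"], p["k2"], "s0", floor=floor),
            ]
        if self.family == "HOLZAPFEL_OGDEN":
            return [ExpIsoTerm(p["a"], p["b"])], [
                FiberExpTerm(p["a_f"], p["b_f"], "f0", floor=True),
                FiberExpTerm(p["a_n"], p["b_n"], "n0", floor=True),
                ShearExpTerm(p["a_fs"], p["b_fs"]),
            ]
        if self.family == "GUELTEKIN_DISPERSION":
            return [ExpIsoTerm(p["a"], p["b"])], [
                DispersionFiberTerm(
                    p["a_f"], p["b_f"], p.get("kappa_f", 0.0), "f0"
                ),
                DispersionFiberTerm(
                    p["a_s"], p["b_s"], p.get("kappa_s", 0.0), "s0"
                ),
                ShearExpTerm(p["a_fs"], p["b_fs"]),
            ]
        if self.family == "FUNG_GUCCIONE":
            return [GuccioneTerm(p["a"], p["b_f"], p["b_t"], p["b_fs"])], []
        raise AssertionError

    # -- energies / stresses / tangents ------------------------------------

    def _sum_terms(self, terms, A, fibers):
        psi = np.zeros(A.shape[:-2])
        S = np.zeros(A.shape)
        CC = np.zeros(A.shape + (3, 3))
        # far-field trial states can overflow the exponentials; the resulting
        # non-finite residual is rejected by the solver's line search
        with np.errstate(over="ignore", invalid="ignore"):
            for t in terms:
                p_, S_, C_ = t.evaluate(A, fibers)
                psi, S, CC = psi + p_, S + S_, CC + C_
        return psi, S, CC

    def isochoric_energy(self, state: KinematicState, fibers: FiberTriad):
        """Psibar(Cbar) (+ WAS anisotropic part on C).  Used by the
        differentiation oracles."""
        psi, _, _ = self._sum_terms(self.iso_terms, state.Cbar, fibers)
        if self.aniso_terms:
            A = state.Cbar if self.split == AS else state.C
            pa, _, _ = self._sum_terms(self.aniso_terms, A, fibers)
            psi = psi + pa
        return psi

    def total_energy(self, state: KinematicState, p, fibers: FiberTriad):
        """p Theta(J) + Psibar; 2 d(.)/dC of this is pk2_stress."""
        t, _, _ = self.volumetric.theta(state.J)
        return p * t + self.isochoric_energy(state, fibers)

    def pk2_stress(
        self,
        state: KinematicState,
        p,
        fibers: FiberTriad,
        active_stress=None,
        kappa_f_active: float = 0.0,
    ) -> np.ndarray:
        """Total second Piola-Kirchhoff stress ``S = p S_vol + S_isc``
        (+ unsplit anisotropic part in WAS mode, + active stress)."""
        pi, _ = self.volumetric.pressure_coeffs(state.J)
        p = np.asarray(p, dtype=float)
        S = (p * pi)[..., None, None] * state.Cinv

        terms_bar = list(self.iso_terms)
        if self.split == AS:
            terms_bar += self.aniso_terms
        _, Sbar, _ = self._sum_terms(terms_bar, state.Cbar, fibers)
        g = state.J ** (-2.0 / 3.0)
        S = S + dev_operator(Sbar, state.C) * g[..., None, None]
        if self.split == WAS and self.aniso_terms:
            _, Sa, _ = self._sum_terms(self.aniso_terms, state.C, fibers)
            S = S + Sa
        if active_stress is not None:
            S = S + active_stress_tensor(
                active_stress, state.C, fibers.f0, kappa_f_active
            )
        return S

    def material_tangent(
        self,
        state: KinematicState,
        p,
        fibers: FiberTriad,
        active_stress=None,
        kappa_f_active: float = 0.0,
        voigt: bool = False,
    ) -> np.ndarray:
        """Consistent tangent ``CC_tot = CC_isc + p CC_vol`` (+ WAS and
        active parts), as a full (...,3,3,3,3) tensor or a Voigt 6x6."""
        pi, k = self.volumetric.pressure_coeffs(state.J)
        p = np.asarray(p, dtype=float)
        CC = (
            p[..., None, None, None, None]
            * volumetric_tangent(state.Cinv, pi, k)
        )
        terms_bar = list(self.iso_terms)
        if self.split == AS:
            terms_bar += self.aniso_terms
        _, Sbar, CCbar = self._sum_terms(terms_bar, state.Cbar, fibers)
        _, CCisc = isochoric_push(state.C, state.Cinv, state.J, Sbar, CCbar)
        CC = CC + CCisc
        if self.split == WAS and self.aniso_terms:
            _, _, CCa = self._sum_terms(self.aniso_terms, state.C, fibers)
            CC = CC + CCa
        if active_stress is not None:
            CC = CC + active_stress_tangent(
                active_stress, state.C, state.Cinv, fibers.f0, kappa_f_active
            )
        return to_voigt(CC) if voigt else CC


def material_from_config(cfg: dict) -> MaterialModel:
    """Build a material from a plain dict (YAML-friendly)::

        {family: GHT_ARTERY, split: AS, theta: J_MINUS_1,
         kappa_kPa: 5000.0 | incompressible: true,
         params: {mu: 10.0, k1: 500.0, k2: 2.0}}
    """
    law = VolumetricLaw(
        theta_kind=cfg.get("theta", J_MINUS_1),
        kappa=float(cfg.get("kappa_kPa", 1000.0)),
        incompressible=bool(cfg.get("incompressible", False)),
    )
    return MaterialModel(
        family=cfg["family"],
        split=cfg.get("split", AS),
        params=dict(cfg.get("params", {})),
        volumetric=law,
    )


# --- active stress ---------------------------------------------------------


def active_stress_tensor(S_a, C, f0, kappa_f: float = 0.0) -> np.ndarray:
    """Active second Piola-Kirchhoff stress generated by myocytes with
    orientation dispersion ``kappa_f``::

        S_act = S_a ( kf/(1-2kf) C^{-1}
                      + (1-3kf)/(1-2kf) (f0.C f0)^{-1} f0 (x) f0 ).
    """
    if not 0.0 <= kappa_f < 0.5:
        raise ValueError("active-stress dispersion must lie in [0, 1/2)")
    S_a = np.asarray(S_a, dtype=float)
    C = np.asarray(C, dtype=float)
    Cinv = inv3(C)
    I4 = np.einsum("...i,...ij,...j->...", f0, C, f0)
    ff = np.broadcast_to(_outer(f0, f0), C.shape)
    c_iso = kappa_f / (1.0 - 2.0 * kappa_f)
    c_fib = (1.0 - 3.0 * kappa_f) / (1.0 - 2.0 * kappa_f)
    return S_a[..., None, None] * (
        c_iso * Cinv + (c_fib / I4)[..., None, None] * ff
    )


def active_stress_tangent(S_a, C, Cinv, f0, kappa_f: float = 0.0) -> np.ndarray:
    """``2 dS_act/dC`` consistent with :func:`active_stress_tensor`."""
    S_a = np.asarray(S_a, dtype=float)
    I4 = np.einsum("...i,...ij,...j->...", f0, C, f0)
    ff = np.broadcast_to(_outer(f0, f0), C.shape)
    c_iso = kappa_f / (1.0 - 2.0 * kappa_f)
    c_fib = (1.0 - 3.0 * kappa_f) / (1.0 - 2.0 * kappa_f)
    Sb = S_a[..., None, None, None, None]
    return Sb * (
        -2.0 * c_iso * odot(Cinv, Cinv)
        - 2.0 * (c_fib / I4**2)[..., None, None, None, None] * dyad(ff, ff)
    )


def cauchy_stress(state: KinematicState, S: np.ndarray) -> np.ndarray:
    """Push-forward ``sigma = J^{-1} F S F^T``."""
    return (
        np.einsum("...ik,...kl,...jl->...ij", state.F, S, state.F)
        / state.J[..., None, None]
    )
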