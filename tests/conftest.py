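import numpy as np
import pytest

from anisofem.materials import (
    FiberTriad,
    KinematicState,
    MaterialModel,
    VolumetricLaw,
)


def state_from_C(C):
    """Kinematic state built directly from a right Cauchy-Green tensor
    (F left unset); enough for stress/tangent evaluations."""
    C = np.asarray(C, dtype=float)
    J = np.sqrt(np.linalg.det(C))
    return KinematicState(
        F=None, J=J, C=C, Cbar=J[..., None, None] ** (-2 / 3) * C,
        Cinv=np.linalg.inv(C),
    )


def random_states(rng, n, scale=0.15, min_J=0.4):
    """Batch of random non-degenerate kinematic states (displacement
    gradients)."""
    out = []
    while len(out) < n:
        gu = scale * rng.standard_normal((3, 3))
        if np.linalg.det(np.eye(3) + gu) > min_J:
            out.append(gu)
    return np.array(out)


HO_PARAMS = dict(
    a=0.809, b=7.474, a_f=1.911, b_f=22.063, a_n=0.227, b_n=34.802,
    a_fs=0.547, b_fs=5.691,
)
GUELTEKIN_PARAMS = dict(
    a=0.4, b=6.55, a_f=3.05, b_f=29.05, a_s=1.25, b_s=36.65,
    a_fs=0.15, b_fs=6.28, kappa_f=0.15, kappa_s=0.05,
)
GUCCIONE_PARAMS = dict(a=2.0, b_f=8.0, b_t=2.0, b_fs=4.0)
ARTERY_PARAMS = dict(mu=10.0, k1=500.0, k2=2.0)


def make_material(family, split="AS", theta="J_MINUS_1", kappa=1000.0,
                  incompressible=False, **extra):
    params = {
        "NEOHOOKEAN_ISO": dict(mu=10.0),
        "GHT_ARTERY": dict(ARTERY_PARAMS),
        "HOLZAPFEL_OGDEN": dict(HO_PARAMS),
        "GUELTEKIN_DISPERSION": dict(GUELTEKIN_PARAMS),
        "FUNG_GUCCIONE": dict(GUCCIONE_PARAMS),
    }[family]
    params.update(extra)
    return MaterialModel(
        family=family, split=split, params=params,
        volumetric=VolumetricLaw(theta, kappa, incompressible),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def cartesian_fibers():
    return FiberTriad.cartesian()
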