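import numpy as np
import pytest

from alpsnet import dti, synthcohort as sc


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless periventricular phantom (delta 0.24 on base 0.30 -> ALPS 1.8)."""
    cfg = sc.PhantomConfig()
    dwi, truth = sc.generate_dwi_phantom(cfg)
    return cfg, dwi, truth


@pytest.fixture(scope="session")
def default_tensorfield(default_phantom):
    _, dwi, _ = default_phantom
    return dti.fit_tensor(dwi)


@pytest.fixture(scope="session")
def isotropic_phantom():
    """Every voxel isotropic: analytic ALPS exactly 1."""
    cfg = sc.PhantomConfig(perivascular_delta=0.0)
    for b in cfg.bundles.values():
        b.lambda_par = b.lambda_perp = 0.8
    dwi, truth = sc.generate_dwi_phantom(cfg)
    return cfg, dwi, truth


@pytest.fixture(scope="session")
def straight_bundle():
    return sc.straight_bundle_phantom()


@pytest.fixture(scope="session")
def kinked_bundle():
    return sc.kinked_bundle_phantom()


def random_spd_tensors(rng, n):
    """Random symmetric positive semi-definite 3x3 tensors."""
    A = rng.normal(size=(n, 3, 3))
    return np.einsum("nij,nkj->nik", A, A) * 0.1
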