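import numpy as np
import pytest

import afmech as af


@pytest.fixture(scope="session")
def fibers():
    """Default two-family +/-30 degree architecture."""
    return af.FiberArchitecture.symmetric(30.0)


@pytest.fixture(scope="session")
def uniaxial_set():
    params, _ = af.uniaxial_reference()
    return params


@pytest.fixture(scope="session")
def biaxial_set():
    params, _ = af.biaxial_reference()
    return params


@pytest.fixture(scope="session")
def neo_hookean():
    """Matrix-only material (k1 = 0): closed-form reference solutions."""
    return af.MaterialParameters(c10=0.5, k1=0.0, k2=1.0, label="neo-hookean")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def fd_cauchy(f, params, fibers, kappa=0.0, h=1e-6):
    """Finite-difference oracle: sigma = (1/J) (dW/dF) F^T by central
    differences on the isochoric energy.  Independent of the analytic
    stress path (only strain_energy is exercised)."""
    p_fd = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            fp = f.copy()
            fp[i, j] += h
            fm = f.copy()
            fm[i, j] -= h
            wp = af.strain_energy(af.DeformationState.create(fp, fibers, kappa),
                                  params, fibers)
            wm = af.strain_energy(af.DeformationState.create(fm, fibers, kappa),
                                  params, fibers)
            p_fd[i, j] = (wp - wm) / (2.0 * h)
    return p_fd @ f.T / np.linalg.det(f)
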