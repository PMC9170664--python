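import numpy as np
import pytest

from affectdiffusion import AIMParameters, BoundedOUParameters, build_grid


@pytest.fixture
def flat_params():
    """All shape parameters zero: flat free energy, pure bounded diffusion."""
    return AIMParameters(D=0.01)


@pytest.fixture
def bimodal_params():
    """A structured AIM surface with wells, used as a generic nontrivial model."""
    return AIMParameters(
        lambda1=3.0, lambda2=2.0, lambda12=4.0,
        theta1=1.0, theta2=2.0, n1=1.2, n2=0.8, D=0.006,
    )


@pytest.fixture
def confined_ou_params():
    """Strongly confined bounded-OU model: boundary truncation negligible."""
    return BoundedOUParameters(mu1=0.5, mu2=0.5, a11=40.0, a22=40.0, a12=0.0, D=0.02)


@pytest.fixture
def grid30():
    return build_grid(30)


def _field_moments(field):
    """Mean and per-dimension variance of a probability field's cell centers."""
    c1, c2 = field.grid.centers()
    X, Y = np.meshgrid(c1, c2, indexing="ij")
    m = field.masses
    mean = np.array([(X * m).sum(), (Y * m).sum()])
    var = np.array([((X - mean[0]) ** 2 * m).sum(), ((Y - mean[1]) ** 2 * m).sum()])
    return mean, var


@pytest.fixture
def field_moments():
    return _field_moments
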