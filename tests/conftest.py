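import numpy as np
import pytest
from hypothesis import settings

from funnelbind import HillsRecord, Pmf

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def single_hill():
    """One Gaussian hill of the standard deposition height at (0.5, 0.0)."""
    return HillsRecord(times=[1.0], centers=[(0.5, 0.0)],
                       widths=[(0.04, 0.043)], heights=[0.1195], gamma=20.0)


def make_pmf(z, w, referenced=True, T=298.0):
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    return Pmf(z=z, w=w, sampled=np.ones(z.size, dtype=bool), T=T,
               referenced=referenced)


@pytest.fixture
def flat_pmf():
    """w = 0 everywhere on a fine grid over [0, 2] nm."""
    z = np.linspace(0.0, 2.0, 4001)
    return make_pmf(z, np.zeros_like(z))


@pytest.fixture
def square_well_pmf():
    """w = -5 kcal/mol on [0.4, 0.6] nm, 0 elsewhere, fine grid.

    The step edges fall on grid nodes; the grid is fine enough (5e-4 nm)
    that trapezoid quadrature across the discontinuity is accurate to
    ~1e-3 kcal/mol.
    """
    z = np.linspace(0.0, 2.0, 4001)
    w = np.where((z >= 0.4) & (z <= 0.6), -5.0, 0.0)
    return make_pmf(z, w)
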