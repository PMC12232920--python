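import numpy as np
import pytest

from fenet import fes as fesmod
from fenet.mbar_core import EnergyTable


def random_energy_table(rng, max_states=4, max_samples=40, beta=1.0):
    """Small random table: per-state counts >= 1, mild reduced energies."""
    K = rng.integers(2, max_states + 1)
    counts = rng.integers(1, max(2, max_samples // K) + 1, size=K)
    N = int(counts.sum())
    u = rng.normal(0.0, 1.0, size=(K, N))
    return EnergyTable.from_state_blocks(u, counts, beta)


def analytic_surface(fn, mins, widths, nbins):
    """FESGrid filled from a closed-form 2-D function (dF = 0, full grid)."""
    spec = fesmod.GridSpec(mins=mins, widths=widths, nbins=nbins)
    bins = {}
    for i in range(nbins[0]):
        for j in range(nbins[1]):
            x = spec.mins[0] + (i + 0.5) * spec.widths[0]
            y = spec.mins[1] + (j + 0.5) * spec.widths[1]
            bins[(i, j)] = fesmod.BinValue(F=fn(x, y), dF=0.0, n=100, S=1.0)
    return fesmod.FESGrid(spec=spec, bins=bins)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


@pytest.fixture
def quartic_surface():
    """(x^2-1)^2 + 2 y^2 on a 101 x 41 grid over [-1.5,1.5] x [-1,1]."""
    return analytic_surface(
        lambda x, y: (x * x - 1.0) ** 2 + 2.0 * y * y,
        [-1.5, -1.0], [3.0 / 101, 2.0 / 41], [101, 41],
    )


@pytest.fixture
def harmonic_pair_table():
    """Two 1-D harmonic states (kappa = 1 and 4 kcal/mol/A^2) at 300 K.

    The exact free energy difference is kT/2 * ln 4.
    """
    from fenet.constants import KB_KCAL
    kT = KB_KCAL * 300.0
    beta = 1.0 / kT
    rng = np.random.default_rng(17)
    n = 2000
    x0 = rng.normal(0.0, np.sqrt(kT / 1.0), n)
    x1 = rng.normal(0.0, np.sqrt(kT / 4.0), n)
    x = np.concatenate([x0, x1])
    u = np.vstack([beta * 0.5 * 1.0 * x**2, beta * 0.5 * 4.0 * x**2])
    tab = EnergyTable.from_state_blocks(u, np.array([n, n]), beta)
    return tab, 0.5 * kT * np.log(4.0)
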