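"""Synthetic umbrella-sampling and alchemical datasets with exact truth.

Every generator draws independent samples from closed-form distributions
and writes ordinary tool inputs (metafile + dumpave files, edge XML +
efep files, thermodynamic graphs), so estimator output can be compared
against analytic ground truth.  Sampling is exact rather than MD-like:
draws are independent by default, optionally AR(1)-correlated to exercise
the time-series machinery, and a burn-in shift can be prepended to test
equilibration detection end to end.

Ground truths:

* quadratic landscape U0 = (a/2) x^2 restrained by U_b = k (x - x0)^2:
  the biased density is Gaussian with mean 2 k x0 / (a + 2k) and variance
  kT / (a + 2k);
* quartic double well U0 = h (x^2 - 1)^2 (barrier height h at x = 0,
  minima at x = +-1): sampled by rejection against a uniform envelope;
* Gaussian alchemy U(x; lam) = (kappa/2)(x - lam d)^2 + lam eps: the state
  free energy is G(lam) = lam*eps + const, so each leg has exact
  dG = eps and an edge has ddG = eps_target - eps_ref.

Each generator writes a ``truth.json`` beside its data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from fenet.constants import KB_KCAL
from fenet.exceptions import DataError
from fenet.mbar_core import EnergyTable
from fenet.network import ThermoGraph

__all__ = [
    "HarmonicLandscape",
    "GaussianAlchemy",
    "gen_umbrella",
    "gen_edge",
    "gen_graph",
    "gen_burnin",
]


@dataclass(frozen=True)
class HarmonicLandscape:
    """Ground-truth 1-D free energy landscape.

    form="quadratic": U0(x) = (a/2) x^2     (stiffness a, kcal/mol/unit^2)
    form="quartic":   U0(x) = h (x^2 - 1)^2 (barrier height h, kcal/mol)
    """

    form: str = "quadratic"
    a: float = 2.0
    h: float = 3.0
    temperature: float = 300.0

    def __post_init__(self):
        if self.form not in ("quadratic", "quartic"):
            raise DataError(f"unknown landscape form '{self.form}'")
        if self.a <= 0 or self.h <= 0 or self.temperature <= 0:
            raise DataError("landscape parameters must be positive")

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "quadratic":
            return 0.5 * self.a * x**2
        return self.h * (x**2 - 1.0) ** 2

    def pmf(self, grid):
        """Analytic PMF on a grid, referenced to its minimum."""
        F = self.energy(grid)
        return F - F.min()


@dataclass(frozen=True)
class GaussianAlchemy:
    """Exactly solvable alchemical leg: U(x; lam) = (kappa/2)(x - lam d)^2 + lam eps.

    The configurational partition function is independent of the well
    position, so G(lam) = lam*eps + const and dG(0 -> 1) = eps exactly.
    """

    kappa: float = 1.0   # kcal/mol/A^2
    d: float = 0.0       # A of well displacement per unit lambda
    eps: float = 0.0     # kcal/mol of linear offset per unit lambda

    def __post_init__(self):
        if self.kappa <= 0:
            raise DataError("kappa must be positive")

    def energy(self, x, lam):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.kappa * (x - lam * self.d) ** 2 + lam * self.eps

    def sample(self, lam, n, kT, rng):
        return rng.normal(lam * self.d, np.sqrt(kT / self.kappa), size=n)


def _ar1_correlate(z: np.ndarray, rho: float, rng) -> np.ndarray:
    """Impose lag-1 autocorrelation rho on standard-normal draws.

    The stationary marginal stays N(0, 1), so Gaussian biased densities
    keep their exact mean/variance.
    """
    if rho == 0.0:
        return z
    out = np.empty_like(z)
    out[0] = z[0]
    s = np.sqrt(1.0 - rho * rho)
    for i in range(1, z.size):
        out[i] = rho * out[i - 1] + s * z[i]
    return out


def gen_umbrella(
    landscape: HarmonicLandscape,
    windows,
    n_per_window: int,
    seed: int,
    outdir,
    grid=None,
    half_k: bool = False,
    rho: float = 0.0,
    burnin_shift: float = 0.0,
    n_burnin: int = 0,
) -> dict:
    """Write a metafile + dumpave files for biased sampling of a landscape.

    Parameters
    ----------
    windows : iterable of (center, fc)
        Harmonic restraints in the U = fc (x-c)^2 convention
        (or the 1/2-convention when ``half_k``).
    rho : float
        Optional AR(1) lag-1 autocorrelation of the draws (quadratic
        landscape only; the stationary marginal is preserved).
    burnin_shift, n_burnin :
        Prepend ``n_burnin`` drifted samples offset by ``burnin_shift`` to
        emulate unequilibrated sampling.

    Returns
    -------
    dict with keys 'metafile', 'truth' (path of truth.json), 'pmf_grid',
    'pmf' (analytic PMF when ``grid`` is given), 'acceptance' (rejection
    acceptance rate, quartic only).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    kT = KB_KCAL * landscape.temperature
    fac = 0.5 if half_k else 1.0
    meta_lines = []
    acceptance = None
    if rho != 0.0 and landscape.form != "quadratic":
        raise DataError("AR(1) correlation is only exact on the quadratic "
                        "landscape")
    for i, (c, k) in enumerate(windows):
        if landscape.form == "quadratic":
            a = landscape.a
            keff = a + 2.0 * fac * k
            mu = 2.0 * fac * k * c / keff
            z = rng.standard_normal(n_per_window)
            z = _ar1_correlate(z, rho, rng)
            x = mu + np.sqrt(kT / keff) * z
        else:
            x, acceptance = _rejection_quartic(
                landscape, c, fac * k, kT, n_per_window, rng
            )
        if n_burnin > 0:
            zb = rng.standard_normal(n_burnin)
            head = x[: max(1, n_burnin)].mean() + burnin_shift + zb * np.std(
                x, ddof=0
            )
            x = np.concatenate([head, x])
        t = np.arange(1, x.size + 1, dtype=float)
        dump = outdir / f"win_{i:03d}.dat"
        np.savetxt(dump, np.column_stack([t, x]), fmt="%.10g")
        meta_lines.append(
            f"0 {dump.name} {c:.10g} {k:.10g} {landscape.temperature:.10g}"
        )
    meta = outdir / "metafile"
    meta.write_text("\n".join(meta_lines) + "\n")
    truth = {
        "form": landscape.form,
        "a": landscape.a,
        "h": landscape.h,
        "temperature": landscape.temperature,
        "half_k": half_k,
        "n_per_window": n_per_window,
        "seed": seed,
    }
    if grid is not None:
        grid = np.asarray(grid, dtype=float)
        truth["pmf_grid"] = grid.tolist()
        truth["pmf"] = landscape.pmf(grid).tolist()
    if acceptance is not None:
        truth["rejection_acceptance"] = acceptance
    tpath = outdir / "truth.json"
    tpath.write_text(json.dumps(truth, indent=1))
    out = {"metafile": str(meta), "truth": str(tpath)}
    if grid is not None:
        out["pmf_grid"] = grid
        out["pmf"] = landscape.pmf(grid)
    if acceptance is not None:
        out["acceptance"] = acceptance
    return out


def _rejection_quartic(landscape, c, keff, kT, n, rng):
    """Exact rejection sampling of exp(-U_tot/kT) against a uniform envelope."""
    def utot(x):
        return landscape.energy(x) + keff * (x - c) ** 2

    # support: scan a wide grid for the region where density is non-negligible
    xs = np.linspace(-4.0, 4.0, 4001)
    u = utot(xs)
    umin = u.min()
    keep = (u - umin) < 40.0 * kT
    lo, hi = xs[keep][0] - 0.01, xs[keep][-1] + 0.01
    out = np.empty(n)
    got, proposed = 0, 0
    while got < n:
        m = max(4 * (n - got), 256)
        xp = rng.uniform(lo, hi, size=m)
        acc = rng.random(m) < np.exp(-(utot(xp) - umin) / kT)
        take = xp[acc][: n - got]
        out[got: got + take.size] = take
        got += take.size
        proposed += m
    return out, got / proposed


def gen_edge(
    alch_ref: GaussianAlchemy,
    alch_target: GaussianAlchemy,
    lambdas,
    n_per_state: int,
    n_trials: int,
    seed: int,
    outdir,
    temperature: float = 298.0,
) -> dict:
    """Write an edge XML + efep files for a two-environment Gaussian edge.

    The hierarchy is environments (ref, target) -> one stage -> ``n_trials``
    trials -> states at the given lambdas.  Analytic ddG =
    eps_target - eps_ref.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas[0] != 0.0 or lambdas[-1] != 1.0:
        raise DataError("lambda schedule must span [0, 1]")
    rng = np.random.default_rng(seed)
    kT = KB_KCAL * temperature

    from lxml import etree
    root = etree.Element("edge", name="ligA~ligB",
                         temperature="%.10g" % temperature)
    for env_name, alch in (("ref", alch_ref), ("target", alch_target)):
        env = etree.SubElement(root, "env", name=env_name)
        stage = etree.SubElement(env, "stage", name="unified")
        for t in range(n_trials):
            tdir = outdir / env_name / "unified" / f"t{t + 1}"
            tdir.mkdir(parents=True, exist_ok=True)
            trial = etree.SubElement(
                stage, "trial", name=f"t{t + 1}",
                dir=str(tdir.relative_to(outdir)),
            )
            for lam in lambdas:
                etree.SubElement(trial, "state", **{"lambda": "%.8f" % lam})
                x = alch.sample(lam, n_per_state, kT, rng)
                tcol = np.arange(1, n_per_state + 1, dtype=float)
                for elam in lambdas:
                    fn = tdir / f"efep_{lam:.8f}_{elam:.8f}.dat"
                    np.savetxt(
                        fn,
                        np.column_stack([tcol, alch.energy(x, elam)]),
                        fmt="%.10g",
                    )
    xml_path = outdir / "edge.xml"
    etree.ElementTree(root).write(str(xml_path), pretty_print=True,
                                  xml_declaration=True, encoding="utf-8")
    ddG = alch_target.eps - alch_ref.eps
    truth = {
        "ddG": ddG,
        "dG_ref": alch_ref.eps,
        "dG_target": alch_target.eps,
        "temperature": temperature,
        "lambdas": lambdas.tolist(),
        "n_per_state": n_per_state,
        "n_trials": n_trials,
        "seed": seed,
    }
    tpath = outdir / "truth.json"
    tpath.write_text(json.dumps(truth, indent=1))
    return {"xml": str(xml_path), "truth": str(tpath), "ddG": ddG}


def gen_graph(
    n_lig: int,
    topology: str,
    true_c,
    noise_sem: float,
    seed: int,
) -> tuple:
    """Random thermodynamic graph with known ligand free energies.

    Edge estimates are g = (c_b - c_a) + N(0, noise_sem) with force
    constants k = 1/noise_sem^2 (a large constant when noise_sem = 0).

    Parameters
    ----------
    topology : 'star' | 'cycle' | 'dense'

    Returns
    -------
    (ThermoGraph, truth dict)
    """
    true_c = np.asarray(true_c, dtype=float)
    if true_c.shape != (n_lig,):
        raise DataError(f"true_c must have shape ({n_lig},)")
    names = [f"L{i:02d}" for i in range(n_lig)]
    if topology == "star":
        pairs = [(0, i) for i in range(1, n_lig)]
    elif topology == "cycle":
        pairs = [(i, (i + 1) % n_lig) for i in range(n_lig)]
    elif topology == "dense":
        pairs = [(i, j) for i in range(n_lig) for j in range(i + 1, n_lig)]
    else:
        raise DataError(f"unknown topology '{topology}'")
    rng = np.random.default_rng(seed)
    k = 1e8 if noise_sem == 0.0 else 1.0 / noise_sem**2
    edges = []
    for a, b in pairs:
        g = true_c[b] - true_c[a]
        if noise_sem > 0:
            g += rng.normal(0.0, noise_sem)
        edges.append((names[a], names[b], float(g), k, noise_sem))
    tg = ThermoGraph(ligands=names, edges=edges)
    truth = {
        "c": (true_c - true_c[0]).tolist(),
        "names": names,
        "noise_sem": noise_sem,
        "topology": topology,
        "seed": seed,
    }
    return tg, truth


def gen_burnin(
    alch: GaussianAlchemy,
    n_dense: int,
    n_per_state: int,
    seed: int,
    temperature: float = 298.0,
    position_fn=None,
):
    """Dense-grid burn-in for schedule optimization, as a BurnIn object.

    ``position_fn`` overrides the well position as a function of lambda
    (default lambda * d); a superlinear function concentrates the
    adjacency resistance near lambda = 1.
    """
    from fenet.schedule import BurnIn

    lambdas = np.linspace(0.0, 1.0, n_dense)
    rng = np.random.default_rng(seed)
    kT = KB_KCAL * temperature
    pos = position_fn or (lambda lam: lam * alch.d)
    sig = np.sqrt(kT / alch.kappa)

    def energy(x, lam):
        return (0.5 * alch.kappa * (x - pos(lam)) ** 2 + lam * alch.eps)

    xs = [rng.normal(pos(lam), sig, n_per_state) for lam in lambdas]
    x = np.concatenate(xs)
    u = np.array([energy(x, lam) / kT for lam in lambdas])
    counts = np.full(n_dense, n_per_state)
    tab = EnergyTable.from_state_blocks(u, counts, 1.0 / kT)
    return BurnIn(lambdas=lambdas, table=tab)
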