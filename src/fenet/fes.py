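"""Umbrella-sampling free energy surfaces via MBAR reweighting.

Biased simulations are described by a plain-text "metafile", one window per
line, each pointing at a "dumpave" time-series file of reaction-coordinate
samples.  The biased windows form the sampled states of an MBAR problem
whose zero-count target state is the unbiased Hamiltonian; the unbiased
per-sample weights then populate a regular multidimensional histogram with
per-bin free energy, bootstrap standard error, raw sample count, and
reweighting entropy.  Surfaces are serialized as XML.

Metafile dialect (strict, '#' comments allowed)::

    ham_idx dumpave_path center_1 fc_1 [center_2 fc_2 ...] temperature

A reader for the Grossfield-WHAM ordering (path, centers, springs, [T]) is
provided for interoperability (``dialect="wham"``; ham_idx is 0).

The default bias convention is U = sum_d fc_d * (x_d - c_d)^2 (Amber
restraint energy, no 1/2 factor); the 1/2-convention is available via
``half_k=True``.  Periodic coordinates use minimum-image displacements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from fenet import timeseries
from fenet.constants import beta_from_temperature
from fenet.exceptions import DataError
from fenet.mbar_core import EnergyTable, solve_mbar

__all__ = [
    "UmbrellaWindow",
    "GridSpec",
    "FESGrid",
    "read_metafile",
    "read_dumpave",
    "bias_energy",
    "compute_fes",
    "write_fes_xml",
    "read_fes_xml",
    "combine_windows",
    "average_fes",
]

logger = logging.getLogger(__name__)

#: Float wire format; 17 significant digits round-trip IEEE doubles exactly.
_FLT = "%.17g"


@dataclass(frozen=True)
class UmbrellaWindow:
    """One biased simulation window (one metafile line)."""

    dumpave_path: str
    center: np.ndarray
    fc: np.ndarray
    temperature: float
    ham_idx: int = 0

    def __post_init__(self):
        c = np.atleast_1d(np.asarray(self.center, dtype=float))
        k = np.atleast_1d(np.asarray(self.fc, dtype=float))
        if c.shape != k.shape:
            raise DataError("center and fc must have matching dimensionality")
        if np.any(k < 0):
            raise DataError("force constants must be non-negative")
        if self.temperature <= 0:
            raise DataError("temperature must be positive")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "fc", k)

    @property
    def ndim(self) -> int:
        return self.center.size


@dataclass(frozen=True)
class GridSpec:
    """Regular histogram grid: per-dimension origin, bin width, bin count.

    ``periods[d]`` is the coordinate period (e.g. 360 for a dihedral in
    degrees) or 0 for an aperiodic dimension.
    """

    mins: np.ndarray
    widths: np.ndarray
    nbins: np.ndarray
    periods: np.ndarray = None

    def __post_init__(self):
        mins = np.atleast_1d(np.asarray(self.mins, dtype=float))
        widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        nbins = np.atleast_1d(np.asarray(self.nbins, dtype=int))
        if not (mins.shape == widths.shape == nbins.shape):
            raise DataError("mins, widths, nbins must have equal length")
        if np.any(widths <= 0) or np.any(nbins < 1):
            raise DataError("widths must be positive and nbins >= 1")
        per = self.periods
        per = (np.zeros_like(mins) if per is None
               else np.atleast_1d(np.asarray(per, dtype=float)))
        if per.shape != mins.shape or np.any(per < 0):
            raise DataError("periods must match dimensionality and be >= 0")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "nbins", nbins)
        object.__setattr__(self, "periods", per)

    @property
    def ndim(self) -> int:
        return self.mins.size

    def bin_index(self, x: np.ndarray) -> np.ndarray:
        """Half-open bin assignment; -1 marks out-of-grid samples.

        x has shape (n, D); returns an (n, D) integer array.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x = np.array(x)
        for d in range(self.ndim):
            if self.periods[d] > 0:
                x[:, d] = self.mins[d] + np.mod(
                    x[:, d] - self.mins[d], self.periods[d]
                )
        idx = np.floor((x - self.mins) / self.widths).astype(int)
        bad = (idx < 0) | (idx >= self.nbins)
        idx[bad.any(axis=1)] = -1
        return idx

    def centers(self, d: int) -> np.ndarray:
        return self.mins[d] + (np.arange(self.nbins[d]) + 0.5) * self.widths[d]


@dataclass
class BinValue:
    """Per-bin statistics of an estimated surface."""

    F: float          # free energy, kcal/mol (min over bins = 0)
    dF: float         # bootstrap standard error, kcal/mol
    n: int            # raw sample count
    S: float          # reweighting entropy in (0, 1]


@dataclass
class FESGrid:
    """Estimated free energy surface on a regular grid (occupied bins only)."""

    spec: GridSpec
    bins: dict = field(default_factory=dict)  # tuple[int,...] -> BinValue

    @property
    def ndim(self) -> int:
        return self.spec.ndim

    def __eq__(self, other):
        if not isinstance(other, FESGrid):
            return NotImplemented
        sa, sb = self.spec, other.spec
        if not (
            np.array_equal(sa.mins, sb.mins)
            and np.array_equal(sa.widths, sb.widths)
            and np.array_equal(sa.nbins, sb.nbins)
            and np.array_equal(sa.periods, sb.periods)
        ):
            return False
        if set(self.bins) != set(other.bins):
            return False
        return all(
            self.bins[k].F == other.bins[k].F
            and self.bins[k].dF == other.bins[k].dF
            and self.bins[k].n == other.bins[k].n
            and self.bins[k].S == other.bins[k].S
            for k in self.bins
        )


# ---------------------------------------------------------------------------
# text input formats
# ---------------------------------------------------------------------------

def read_metafile(path, dialect: str = "fenet") -> list:
    """Parse a metafile into a list of :class:`UmbrellaWindow`.

    Relative dumpave paths are resolved against the metafile's directory.
    All lines must share one dimensionality.
    """
    path = Path(path)
    if dialect not in ("fenet", "wham"):
        raise DataError(f"unknown metafile dialect '{dialect}'")
    windows = []
    D = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            try:
                w = (_parse_fenet_line(tok) if dialect == "fenet"
                     else _parse_wham_line(tok))
            except DataError as e:
                raise DataError(f"{path}, line {lineno}: {e}") from None
            if D is None:
                D = w.ndim
            elif w.ndim != D:
                raise DataError(
                    f"{path}: inconsistent dimensionality at line {lineno} "
                    f"(expected D={D}, got D={w.ndim})"
                )
            dp = Path(w.dumpave_path)
            if not dp.is_absolute():
                dp = path.parent / dp
            if not dp.exists():
                raise DataError(
                    f"{path}, line {lineno}: dumpave file not found: {dp}"
                )
            windows.append(
                UmbrellaWindow(str(dp), w.center, w.fc, w.temperature,
                               w.ham_idx)
            )
    if not windows:
        raise DataError(f"{path}: no windows found")
    return windows


def _parse_fenet_line(tok) -> UmbrellaWindow:
    # ham_idx path c1 k1 [c2 k2 ...] T  -> odd token count >= 5
    if len(tok) < 5 or len(tok) % 2 == 0:
        raise DataError(
            f"expected 'ham path c1 k1 [c2 k2 ...] T' (odd count >= 5 "
            f"tokens), got {len(tok)}"
        )
    try:
        ham = int(tok[0])
    except ValueError:
        raise DataError(f"non-integer Hamiltonian index '{tok[0]}'")
    vals = _floats(tok[2:])
    pairs = vals[:-1]
    return UmbrellaWindow(tok[1], pairs[0::2], pairs[1::2], vals[-1], ham)


def _parse_wham_line(tok) -> UmbrellaWindow:
    # path c1 [c2 ...] k1 [k2 ...] [T]; odd count -> no T (default 300 K)
    if len(tok) < 3:
        raise DataError("expected 'path centers... springs... [T]'")
    has_T = len(tok) % 2 == 0
    vals = _floats(tok[1:])
    T = vals[-1] if has_T else 300.0
    body = vals[:-1] if has_T else vals
    D = len(body) // 2
    return UmbrellaWindow(tok[0], body[:D], body[D:], T, 0)


def _floats(tokens):
    out = []
    for t in tokens:
        try:
            out.append(float(t))
        except ValueError:
            raise DataError(f"non-numeric field '{t}'")
    return out


def read_dumpave(path, D: int):
    """Read a dumpave file: first column time (ps), next D columns coords.

    Extra columns (unbiased-energy columns of other analyses) are ignored
    with a logged note.

    Returns
    -------
    (times, coords) : ndarray (n,), ndarray (n, D)
    """
    times, coords = [], []
    extra_noted = False
    with open(path) as fh:
        for rowno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < 1 + D:
                raise DataError(
                    f"{path}, row {rowno}: expected >= {1 + D} columns, "
                    f"got {len(tok)}"
                )
            if len(tok) > 1 + D and not extra_noted:
                logger.info(
                    "%s: ignoring %d extra column(s) beyond time + %d "
                    "coordinates", path, len(tok) - 1 - D, D
                )
                extra_noted = True
            try:
                vals = [float(t) for t in tok[: 1 + D]]
            except ValueError:
                raise DataError(f"{path}, row {rowno}: non-numeric token")
            times.append(vals[0])
            coords.append(vals[1:])
    if not times:
        raise DataError(f"{path}: empty dumpave file")
    return np.asarray(times), np.asarray(coords)


def bias_energy(w: UmbrellaWindow, x, half_k: bool = False,
                periods=None) -> np.ndarray:
    """Harmonic restraint energy of coordinates x in window w, kcal/mol.

    Default convention U = sum_d fc_d (x_d - c_d)^2; ``half_k=True`` uses
    the 1/2-prefactor convention.  Periodic dimensions (period > 0) use the
    minimum-image displacement.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = x - w.center
    if periods is not None:
        periods = np.atleast_1d(np.asarray(periods, dtype=float))
        for j in range(w.ndim):
            if periods[j] > 0:
                d[:, j] -= periods[j] * np.round(d[:, j] / periods[j])
    e = np.sum(w.fc * d * d, axis=1)
    if half_k:
        e = 0.5 * e
    return e if e.size > 1 else float(e[0])


# ---------------------------------------------------------------------------
# surface estimation
# ---------------------------------------------------------------------------

def _reweighting_entropy(w: np.ndarray) -> float:
    """Normalized entropy of within-bin weights, in (0, 1]; 1 for one sample."""
    if w.size == 1:
        return 1.0
    p = w / w.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(w.size))


def compute_fes(
    windows,
    spec: GridSpec,
    equil: bool = False,
    boot: int = 0,
    seed: int = 0,
    half_k: bool = False,
) -> FESGrid:
    """Estimate the unbiased free energy surface from umbrella windows.

    Pipeline: (i) optional per-window equilibration trim of the bias-energy
    time series; (ii) assemble the :class:`~fenet.mbar_core.EnergyTable`
    with one biased state per window (the common unbiased part of the
    potential cancels in the reduced energies) plus a zero-count unbiased
    state; (iii) solve MBAR; (iv) histogram the unbiased per-sample weights:
    F_b = -kT ln(sum of unbiased weights in b), referenced so min F = 0,
    with the raw count n_b and the within-bin reweighting entropy;
    (v) window-stratified bootstrap for dF when ``boot > 0``.

    All windows must share one temperature and one Hamiltonian index.
    """
    windows = list(windows)
    if not windows:
        raise DataError("no umbrella windows given")
    D = windows[0].ndim
    T = windows[0].temperature
    ham = windows[0].ham_idx
    for w in windows:
        if w.ndim != D:
            raise DataError("windows have inconsistent dimensionality")
        if w.temperature != T:
            raise DataError(
                "mixed temperatures are not supported (single-temperature "
                f"analysis): {w.temperature} vs {T}"
            )
        if w.ham_idx != ham:
            raise DataError(
                f"mixed Hamiltonian indices: {w.ham_idx} vs {ham}"
            )
    if spec.ndim != D:
        raise DataError(
            f"grid dimensionality {spec.ndim} != window dimensionality {D}"
        )
    beta = beta_from_temperature(T)

    coords_per_window = []
    for w in windows:
        _, xs = read_dumpave(w.dumpave_path, D)
        if equil:
            be = bias_energy(w, xs, half_k=half_k, periods=spec.periods)
            be = np.atleast_1d(be)
            if be.size >= 20:
                rep = timeseries.detect_equilibration(be)
                xs = xs[rep.t0_index:]
        coords_per_window.append(xs)

    counts = np.array([len(xs) for xs in coords_per_window])
    X = np.vstack(coords_per_window)
    n_win = len(windows)
    u = np.empty((n_win + 1, X.shape[0]))
    for i, w in enumerate(windows):
        u[i] = beta * np.atleast_1d(
            bias_energy(w, X, half_k=half_k, periods=spec.periods)
        )
    u[n_win] = 0.0  # unbiased target state (zero reduced bias)
    full_counts = np.concatenate([counts, [0]])
    tab = EnergyTable.from_state_blocks(u, full_counts, beta)
    sol = solve_mbar(tab)
    logw_unbiased = sol.logw[n_win]

    idx = spec.bin_index(X)
    inside = idx[:, 0] >= 0
    n_out = int((~inside).sum())
    if n_out:
        logger.info("%d of %d samples fall outside the grid and were "
                    "dropped", n_out, X.shape[0])
    if not inside.any():
        raise DataError("no occupied bins: all samples fall outside the grid")

    bins = _histogram_weights(idx, inside, np.exp(logw_unbiased), beta)

    if boot > 0:
        _bootstrap_dF(bins, u, full_counts, beta, idx, inside, boot, seed,
                      n_win)
    return FESGrid(spec=spec, bins=bins)


def _histogram_weights(idx, inside, w_unb, beta):
    keys = [tuple(row) for row in idx[inside]]
    w_in = w_unb[inside]
    acc = {}
    for k, wv in zip(keys, w_in):
        acc.setdefault(k, []).append(wv)
    kT = 1.0 / beta
    bins = {}
    for k, ws in acc.items():
        ws = np.asarray(ws)
        F = -kT * np.log(ws.sum())
        bins[k] = BinValue(F=F, dF=0.0, n=len(ws), S=_reweighting_entropy(ws))
    Fmin = min(b.F for b in bins.values())
    for b in bins.values():
        b.F -= Fmin
    return bins


def _bootstrap_dF(bins, u, counts, beta, idx, inside, boot, seed, n_win):
    rng = np.random.default_rng(seed)
    offsets = np.concatenate([[0], np.cumsum(counts[:-1])])
    reps = {k: [] for k in bins}
    kT = 1.0 / beta
    for _ in range(boot):
        cols = np.concatenate([
            offsets[i] + rng.integers(0, counts[i], size=counts[i])
            for i in range(n_win)
        ])
        tab = EnergyTable.from_state_blocks(u[:, cols], counts, beta)
        sol = solve_mbar(tab, tol=1e-8)
        w_unb = np.exp(sol.logw[n_win])
        bidx = idx[cols]
        bin_in = inside[cols]
        acc = {}
        for k, wv in zip((tuple(r) for r in bidx[bin_in]), w_unb[bin_in]):
            acc[k] = acc.get(k, 0.0) + wv
        if not acc:
            continue
        Fmin = min(-kT * np.log(s) for s in acc.values())
        for k, s in acc.items():
            if k in reps:
                reps[k].append(-kT * np.log(s) - Fmin)
    for k, vals in reps.items():
        bins[k].dF = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------

def write_fes_xml(fes: FESGrid, path) -> None:
    """Write a surface as XML (round-trip exact; floats at 17 sig. digits)."""
    if not fes.bins:
        raise DataError("no occupied bins: refusing to write an empty grid")
    spec = fes.spec
    root = etree.Element("ndfes", dims=str(spec.ndim))
    for d in range(spec.ndim):
        ax = etree.SubElement(
            root, "axis",
            min=_FLT % spec.mins[d],
            width=_FLT % spec.widths[d],
            nbins=str(int(spec.nbins[d])),
        )
        if spec.periods[d] > 0:
            ax.set("period", _FLT % spec.periods[d])
    for key in sorted(fes.bins):
        b = fes.bins[key]
        etree.SubElement(
            root, "bin",
            idx=",".join(str(i) for i in key),
            F=_FLT % b.F, dF=_FLT % b.dF, n=str(int(b.n)), S=_FLT % b.S,
        )
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="utf-8")


_KNOWN_AXIS = {"min", "width", "nbins", "period"}
_KNOWN_BIN = {"idx", "F", "dF", "n", "S"}


def read_fes_xml(path) -> FESGrid:
    """Read a surface written by :func:`write_fes_xml`.

    Unknown attributes are ignored with a warning, so files from newer
    versions still load.
    """
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as e:
        raise DataError(f"cannot read FES XML {path}: {e}") from None
    if root.tag != "ndfes":
        raise DataError(f"{path}: root element must be <ndfes>")
    mins, widths, nbins, periods = [], [], [], []
    bins = {}
    for el in root:
        if el.tag == "axis":
            _warn_unknown(el, _KNOWN_AXIS, path)
            mins.append(float(el.get("min")))
            widths.append(float(el.get("width")))
            nbins.append(int(el.get("nbins")))
            periods.append(float(el.get("period", "0")))
        elif el.tag == "bin":
            _warn_unknown(el, _KNOWN_BIN, path)
            key = tuple(int(t) for t in el.get("idx").split(","))
            bins[key] = BinValue(
                F=float(el.get("F")), dF=float(el.get("dF")),
                n=int(el.get("n")), S=float(el.get("S")),
            )
        else:
            warnings.warn(f"{path}: ignoring unknown element <{el.tag}>")
    D = int(root.get("dims"))
    if len(mins) != D:
        raise DataError(f"{path}: dims={D} but {len(mins)} <axis> elements")
    spec = GridSpec(mins=np.array(mins), widths=np.array(widths),
                    nbins=np.array(nbins), periods=np.array(periods))
    for key in bins:
        if len(key) != D:
            raise DataError(f"{path}: bin index {key} has wrong arity")
    return FESGrid(spec=spec, bins=bins)


def _warn_unknown(el, known, path):
    for a in el.attrib:
        if a not in known:
            warnings.warn(
                f"{path}: ignoring unknown attribute '{a}' on <{el.tag}>"
            )


# ---------------------------------------------------------------------------
# aggregation helpers
# ---------------------------------------------------------------------------

def combine_windows(metafiles, dialect: str = "fenet") -> list:
    """Concatenate windows from several metafiles (paths re-resolved)."""
    windows = []
    for mf in metafiles:
        ws = read_metafile(mf, dialect=dialect)
        if windows and ws[0].ndim != windows[0].ndim:
            raise DataError(
                f"{mf}: dimensionality {ws[0].ndim} does not match "
                f"previous metafiles (D={windows[0].ndim})"
            )
        windows.extend(ws)
    return windows


def average_fes(grids) -> FESGrid:
    """Unweighted average of surfaces on identical grids.

    A bin present in m grids gets the mean F, the standard error over grids
    (sample sigma / sqrt(m); 0 when m = 1), and the summed count; the
    entropy is averaged.
    """
    grids = list(grids)
    if not grids:
        raise DataError("no grids to average")
    ref = grids[0].spec
    for g in grids[1:]:
        s = g.spec
        if not (
            np.array_equal(ref.mins, s.mins)
            and np.array_equal(ref.widths, s.widths)
            and np.array_equal(ref.nbins, s.nbins)
            and np.array_equal(ref.periods, s.periods)
        ):
            raise DataError("mismatched grid specs; cannot average")
    keys = set()
    for g in grids:
        keys |= set(g.bins)
    out = {}
    for k in keys:
        Fs = [g.bins[k].F for g in grids if k in g.bins]
        Ss = [g.bins[k].S for g in grids if k in g.bins]
        ns = [g.bins[k].n for g in grids if k in g.bins]
        m = len(Fs)
        dF = float(np.std(Fs, ddof=1) / np.sqrt(m)) if m > 1 else 0.0
        out[k] = BinValue(F=float(np.mean(Fs)), dF=dF, n=int(sum(ns)),
                          S=float(np.mean(Ss)))
    return FESGrid(spec=ref, bins=out)
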