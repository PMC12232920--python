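"""Minimum free energy path refinement on a fixed surface.

A discretized string of M nodes connects two points on an estimated free
energy surface.  Interior nodes relax by gradient descent on a multilinear
interpolant of the surface; after each sweep the string is resampled to
equal arclength, which prevents node clustering and makes the converged
curve a discretized minimum free energy path.  This is the fixed-surface
optimization step of the surface-accelerated string method — the outer
loop that re-estimates the surface from new sampling belongs to the
caller.

Unoccupied bins are filled with the nearest occupied value plus a penalty
offset (default 25 kcal/mol), which repels the string from regions the
simulations never visited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from fenet.exceptions import DataError
from fenet.fes import FESGrid

__all__ = [
    "PathString",
    "FESInterpolator",
    "interpolate_fes",
    "optimize_path",
    "path_profile",
]

#: Penalty added to nearest-occupied fills of unoccupied bins, kcal/mol.
DEFAULT_PENALTY = 25.0


@dataclass
class PathString:
    """Ordered string of nodes with surface values and normalized arclength."""

    nodes: np.ndarray       # (M, D)
    values: np.ndarray      # (M,) kcal/mol
    arclength: np.ndarray   # (M,) in [0, 1], strictly increasing
    converged: bool = True

    def __post_init__(self):
        nodes = np.atleast_2d(np.asarray(self.nodes, dtype=float))
        if nodes.shape[0] < 3:
            raise DataError("a path string needs at least 3 nodes")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))
        object.__setattr__(self, "arclength",
                           np.asarray(self.arclength, dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def barrier(self) -> float:
        """Highest node value along the path, kcal/mol."""
        return float(self.values.max())


class FESInterpolator:
    """Multilinear interpolant of an FESGrid over bin centers.

    The dense value array fills unoccupied bins with the nearest occupied
    bin's value plus ``penalty``.  Gradients are the analytic derivatives
    of the multilinear interpolant.  Queries outside the grid's bounding
    box raise; within the half-bin margin between the box edge and the
    outermost bin centers the interpolant is continued constantly.
    """

    def __init__(self, fes: FESGrid, penalty: float = DEFAULT_PENALTY):
        spec = fes.spec
        if not fes.bins:
            raise DataError("cannot interpolate an empty surface")
        shape = tuple(int(n) for n in spec.nbins)
        vals = np.zeros(shape)
        occ = np.zeros(shape, dtype=bool)
        for key, b in fes.bins.items():
            vals[key] = b.F
            occ[key] = True
        if not occ.all():
            # nearest-occupied fill with penalty offset
            dist_idx = ndimage.distance_transform_edt(
                ~occ, return_distances=False, return_indices=True
            )
            nearest = vals[tuple(dist_idx)]
            vals = np.where(occ, vals, nearest + penalty)
        self.spec = spec
        self.values = vals
        self.lo = spec.mins
        self.hi = spec.mins + spec.nbins * spec.widths
        self.centers0 = spec.mins + 0.5 * spec.widths
        self.D = spec.ndim

    def __call__(self, x):
        """Return (F, gradF) at point(s) x; x shape (D,) or (n, D)."""
        single = np.asarray(x, dtype=float).ndim == 1
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.D:
            raise DataError(f"query has dimension {x.shape[1]}, grid has "
                            f"{self.D}")
        eps = 1e-12
        if np.any(x < self.lo - eps) or np.any(x > self.hi + eps):
            bad = x[np.any((x < self.lo - eps) | (x > self.hi + eps), axis=1)]
            raise DataError(
                f"query point {bad[0].tolist()} lies outside the grid hull"
            )
        # fractional index in the bin-center lattice
        f = (x - self.centers0) / self.spec.widths
        nb = self.spec.nbins
        fcl = np.clip(f, 0.0, nb - 1.0)
        i0 = np.floor(fcl).astype(int)
        i0 = np.minimum(i0, nb - 2)
        i0 = np.maximum(i0, 0)
        t = fcl - i0
        if np.any(nb < 2):
            # degenerate axes: constant along that dimension
            for d in range(self.D):
                if nb[d] < 2:
                    i0[:, d] = 0
                    t[:, d] = 0.0
        n = x.shape[0]
        F = np.zeros(n)
        grad = np.zeros((n, self.D))
        for corner in range(1 << self.D):
            bits = np.array([(corner >> d) & 1 for d in range(self.D)])
            idx = i0 + bits
            for d in range(self.D):
                idx[:, d] = np.minimum(idx[:, d], nb[d] - 1)
            v = self.values[tuple(idx.T)]
            w = np.ones(n)
            for d in range(self.D):
                w *= t[:, d] if bits[d] else (1.0 - t[:, d])
            F += w * v
            for d in range(self.D):
                if nb[d] < 2:
                    continue
                wd = np.ones(n)
                for d2 in range(self.D):
                    if d2 == d:
                        wd *= 1.0 if bits[d2] else -1.0
                    else:
                        wd *= t[:, d2] if bits[d2] else (1.0 - t[:, d2])
                grad[:, d] += wd * v / self.spec.widths[d]
        # inside the clamped margin the interpolant is constant
        margin = (f != fcl)
        grad[margin] = 0.0
        if single:
            return float(F[0]), grad[0]
        return F, grad


def interpolate_fes(fes: FESGrid, x, penalty: float = DEFAULT_PENALTY):
    """Interpolated (F, gradient) of the surface at x (convenience wrapper).

    Build an :class:`FESInterpolator` once for repeated queries.
    """
    return FESInterpolator(fes, penalty=penalty)(x)


def _resample_equal_arclength(nodes: np.ndarray) -> np.ndarray:
    """Piecewise-linear resampling of the polyline to equal node spacing."""
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return nodes.copy()
    targets = np.linspace(0.0, total, nodes.shape[0])
    out = np.empty_like(nodes)
    for d in range(nodes.shape[1]):
        out[:, d] = np.interp(targets, s, nodes[:, d])
    out[0], out[-1] = nodes[0], nodes[-1]
    return out


def optimize_path(
    fes: FESGrid,
    start,
    end,
    M: int = 32,
    step: float = 0.01,
    max_iter: int = 5000,
    tol: float = 1e-6,
    penalty: float = DEFAULT_PENALTY,
    free_ends: bool = False,
) -> PathString:
    """Optimize a minimum free energy path between two points.

    The initial string is the straight line from ``start`` to ``end`` with
    M nodes.  Each iteration takes a gradient-descent step of size ``step``
    (in RC units per unit gradient) on the interior nodes, clips them to
    the grid hull, and resamples the string to equal arclength.
    Convergence requires the maximum node displacement to stay below
    ``tol`` for 3 consecutive iterations.  Endpoints are fixed unless
    ``free_ends``, in which case they relax within their own bins.

    A non-converged run returns the best string with ``converged=False``.
    """
    if M < 3:
        raise DataError(f"a path needs M >= 3 nodes, got M = {M}")
    interp = FESInterpolator(fes, penalty=penalty)
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for p, lbl in ((start, "start"), (end, "end")):
        if np.any(p < interp.lo) or np.any(p > interp.hi):
            raise DataError(f"{lbl} point {p.tolist()} is outside the grid")
    nodes = np.linspace(start, end, M)
    lo, hi = interp.lo, interp.hi
    if free_ends:
        # endpoints may slide within their own bin
        bin_lo = lo + np.floor((nodes[[0, -1]] - lo) / interp.spec.widths) \
            * interp.spec.widths
        bin_hi = bin_lo + interp.spec.widths
    streak = 0
    converged = False
    step_cur = step
    best_disp = np.inf
    stall = 0
    for _ in range(max_iter):
        prev = nodes.copy()
        _, grad = interp(nodes)
        upd = slice(0, M) if free_ends else slice(1, M - 1)
        nodes[upd] = nodes[upd] - step_cur * grad[upd]
        np.clip(nodes, lo, hi, out=nodes)
        if free_ends:
            nodes[0] = np.clip(nodes[0], bin_lo[0], bin_hi[0])
            nodes[-1] = np.clip(nodes[-1], bin_lo[1], bin_hi[1])
        nodes = _resample_equal_arclength(nodes)
        disp = float(np.max(np.linalg.norm(nodes - prev, axis=1)))
        streak = streak + 1 if disp < tol else 0
        if streak >= 3:
            converged = True
            break
        # the multilinear gradient is discontinuous at bin centers, so a
        # fixed step can orbit a kink; halve the step when progress stalls
        if disp < 0.999 * best_disp:
            best_disp = disp
            stall = 0
        else:
            stall += 1
            if stall >= 5:
                step_cur *= 0.5
                stall = 0
                best_disp = disp
    values, _ = interp(nodes)
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    arclength = s / s[-1] if s[-1] > 0 else np.linspace(0, 1, M)
    return PathString(nodes=nodes, values=np.atleast_1d(values),
                      arclength=arclength, converged=converged)


def path_profile(p: PathString) -> np.ndarray:
    """(arclength, F) table of a path, shape (M, 2)."""
    return np.column_stack([p.arclength, p.values])
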