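"""MBAR/UWHAM estimation of state free energies.

Given reduced potential energies of every sample evaluated at every state,
the multistate Bennett acceptance ratio estimate of the state free energies
is the minimizer of a convex objective

    F(G) = (1/N) sum_jk ln sum_l exp[-u_l(r_jk) - b_l] + sum_i (N_i/N) b_i,
    b_i  = -ln(N_i/N) - beta*G_i,

where u_l(r_jk) = beta*U(r_jk; lambda_l) is the reduced energy of sample
(j,k) at state l, N_i the number of samples drawn from state i, and N the
aggregate sample count.  The gauge is fixed by anchoring G[0] = 0.

States with zero counts are legal (pure reweighting targets, e.g. the
unbiased Hamiltonian of an umbrella-sampling run): they carry no objective
term and their free energies are recovered from the converged mixture
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from fenet.exceptions import ConvergenceError, DataError

__all__ = [
    "EnergyTable",
    "MBARSolution",
    "mbar_objective",
    "solve_mbar",
    "free_energy_errors",
]


@dataclass(frozen=True)
class EnergyTable:
    """Reduced energies of every sample at every state; sole input to MBAR.

    Attributes
    ----------
    u : ndarray, shape (n_states, n_samples)
        Reduced energies beta*U(r_k; lambda_l), unitless.  Column k holds one
        sample evaluated at all states.
    counts : ndarray, shape (n_states,)
        Number of samples drawn from each state; sums to n_samples.
    beta : float
        Inverse temperature in mol/kcal; converts reduced free energies to
        kcal/mol on output.
    sample_state : ndarray, shape (n_samples,)
        Originating state index of each column.
    """

    u: np.ndarray
    counts: np.ndarray
    beta: float
    sample_state: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        ss = np.asarray(self.sample_state, dtype=int)
        if u.ndim != 2:
            raise DataError("u must be a 2-D [n_states x n_samples] matrix")
        K, N = u.shape
        if counts.shape != (K,):
            raise DataError(f"counts must have shape ({K},), got {counts.shape}")
        if ss.shape != (N,):
            raise DataError(
                f"sample_state must have shape ({N},), got {ss.shape}"
            )
        if np.any(counts < 0):
            raise DataError("counts must be non-negative")
        if counts.sum() != N:
            raise DataError(
                f"counts sum to {counts.sum()} but table has {N} samples"
            )
        if not np.all(counts[ss] > 0):
            raise DataError("sample_state refers to a zero-count state")
        if N > 0 and not np.all(np.isfinite(u)):
            bad = np.argwhere(~np.isfinite(u))[0]
            raise DataError(
                f"non-finite reduced energy at state {bad[0]}, sample {bad[1]}"
            )
        if not np.any(counts > 0):
            raise DataError("at least one state must have samples")
        if self.beta <= 0:
            raise DataError(f"beta must be positive, got {self.beta}")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_state", ss)

    @property
    def n_states(self) -> int:
        return self.u.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u.shape[1]

    @staticmethod
    def from_state_blocks(u: np.ndarray, counts, beta: float) -> "EnergyTable":
        """Build a table whose columns are grouped by originating state."""
        counts = np.asarray(counts, dtype=int)
        ss = np.repeat(np.arange(counts.size), counts)
        return EnergyTable(u=u, counts=counts, beta=beta, sample_state=ss)


@dataclass(frozen=True)
class MBARSolution:
    """Converged MBAR solution.

    Attributes
    ----------
    G : ndarray, shape (n_states,)
        State free energies in kcal/mol, anchored so G[0] = 0.
    logw : ndarray, shape (n_states, n_samples)
        Per-sample log-weights of each state's reweighted ensemble;
        exp(logw[i]) sums to 1 over samples.
    overlap : ndarray, shape (n_states, n_states)
        Standard MBAR overlap matrix; rows sum to 1.
    grad_norm : float
        Infinity norm of the objective gradient at the solution.
    n_iter : int
        Total iterations (self-consistent + Newton).
    """

    G: np.ndarray
    logw: np.ndarray
    overlap: np.ndarray
    grad_norm: float
    n_iter: int

    def to_dict(self) -> dict:
        """JSON-serializable summary (for caching)."""
        return {
            "G": self.G.tolist(),
            "overlap": self.overlap.tolist(),
            "n_iter": int(self.n_iter),
            "grad_norm": float(self.grad_norm),
        }


def _log_denominator(u: np.ndarray, g: np.ndarray, counts: np.ndarray):
    """log D_k = log sum_l N_l exp(g_l - u_lk), over counted states only."""
    active = counts > 0
    a = g[active, None] - u[active, :]
    return logsumexp(a, b=counts[active, None].astype(float), axis=0)


def mbar_objective(tab: EnergyTable, G: np.ndarray):
    """Value and analytic gradient of the MBAR objective at free energies G.

    Parameters
    ----------
    tab : EnergyTable
    G : ndarray, shape (n_states,)
        Trial state free energies in kcal/mol.

    Returns
    -------
    (float, ndarray)
        Objective value (unitless, per-sample normalized) and its gradient
        with respect to G (per kcal/mol).  Components for zero-count states
        are exactly zero (their b-term weight N_i/N vanishes and they drop
        from the log-sum denominator).
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (tab.n_states,):
        raise DataError(
            f"G must have shape ({tab.n_states},), got {G.shape}"
        )
    if not np.all(np.isfinite(G)):
        raise DataError("G must be finite")
    g = tab.beta * G  # reduced free energies
    counts = tab.counts
    N = tab.n_samples
    frac = counts / N
    logD = _log_denominator(tab.u, g, counts)
    if not np.all(np.isfinite(logD)):
        k = int(np.argwhere(~np.isfinite(logD))[0])
        raise DataError(f"non-finite log-denominator at sample {k}")
    # F = (1/N) sum_k [logD_k - log N] - sum_i frac_i (log frac_i + g_i)
    active = counts > 0
    value = float(np.mean(logD)) - np.log(N)
    value -= float(np.sum(frac[active] * (np.log(frac[active]) + g[active])))
    # dF/dg_i = (1/N) sum_k N_i exp(g_i - u_ik)/D_k - frac_i ; dF/dG = beta*dF/dg
    grad_g = np.zeros(tab.n_states)
    t = np.exp(g[active, None] - tab.u[active, :] - logD[None, :])
    grad_g[active] = counts[active] * np.mean(t, axis=1) - frac[active]
    return value, tab.beta * grad_g


def _grad_hess_reduced(u, g, counts):
    """Gradient and Hessian of F w.r.t. reduced g, for counted states."""
    N = u.shape[1]
    frac = counts / N
    logD = _log_denominator(u, g, counts)
    active = counts > 0
    T = counts[active, None] * np.exp(g[active, None] - u[active, :] - logD)
    grad = T.mean(axis=1) - frac[active]
    H = np.diag(T.mean(axis=1)) - (T @ T.T) / N
    return grad, H, logD


def solve_mbar(
    tab: EnergyTable, tol: float = 1e-9, max_iter: int = 10000
) -> MBARSolution:
    """Minimize the MBAR objective; return free energies, weights, overlap.

    Strategy: self-consistent iteration on the standard fixed-point equations
    down to a gradient infinity-norm of 1e-2, then Newton polishing with the
    analytic Hessian (the objective is convex, so Newton converges
    quadratically from the self-consistent iterate).

    Parameters
    ----------
    tab : EnergyTable
    tol : float
        Convergence threshold on the gradient infinity norm (reduced units).
    max_iter : int
        Combined iteration budget.

    Returns
    -------
    MBARSolution
        Free energies in kcal/mol with G[0] = 0.
    """
    if tol <= 0:
        raise DataError("tol must be positive")
    counts = tab.counts
    active = counts > 0
    if not np.any(active):
        raise DataError("table contains only zero-count states")
    u = tab.u
    K = tab.n_states

    g = np.zeros(K)
    n_iter = 0
    grad_norm = np.inf
    # --- self-consistent stage ---
    sc_tol = max(1e-2, tol)
    while n_iter < max_iter:
        logD = _log_denominator(u, g, counts)
        g_new = np.array(g)
        g_new[active] = -logsumexp(-u[active, :] - logD[None, :], axis=1)
        g_new[active] -= g_new[np.argmax(active)]  # anchor first active state
        grad, _, _ = _grad_hess_reduced(u, g_new, counts)
        grad_norm = float(np.max(np.abs(grad))) if grad.size else 0.0
        g = g_new
        n_iter += 1
        if grad_norm <= sc_tol:
            break
    # --- Newton polishing on the anchored subspace ---
    act_idx = np.flatnonzero(active)
    free = act_idx[1:]  # first active state anchored
    while grad_norm > tol and n_iter < max_iter and free.size:
        grad, H, _ = _grad_hess_reduced(u, g, counts)
        # restrict to the free (non-anchored) coordinates
        sel = np.searchsorted(act_idx, free)
        Hf = H[np.ix_(sel, sel)]
        gf = grad[sel]
        try:
            step = np.linalg.solve(Hf + 1e-13 * np.eye(free.size), -gf)
        except np.linalg.LinAlgError:
            step = -np.linalg.lstsq(Hf, gf, rcond=None)[0]
        # backtracking on the objective for robustness
        val0, _ = mbar_objective(tab, g / tab.beta)
        alpha = 1.0
        for _ in range(40):
            g_try = np.array(g)
            g_try[free] += alpha * step
            val, _ = mbar_objective(tab, g_try / tab.beta)
            if val <= val0 + 1e-15:
                break
            alpha *= 0.5
        g = g_try
        grad, _, _ = _grad_hess_reduced(u, g, counts)
        grad_norm = float(np.max(np.abs(grad)))
        n_iter += 1
    if grad_norm > tol:
        raise ConvergenceError(
            f"MBAR did not converge in {max_iter} iterations "
            f"(|grad| = {grad_norm:.3e})",
            last_state=g / tab.beta,
            residual=grad_norm,
        )
    # free energies of zero-count states from the converged mixture weights
    logD = _log_denominator(u, g, counts)
    inactive = ~active
    if np.any(inactive):
        g[inactive] = -logsumexp(-u[inactive, :] - logD[None, :], axis=1)
    # public gauge: state 0; logD shifts with g under a uniform shift
    shift = g[0]
    g -= shift
    logD -= shift
    # per-state normalized log weights
    logw = -u - logD[None, :]
    logw -= logsumexp(logw, axis=1)[:, None]
    # standard MBAR overlap: O_ij = sum_k N_j W_ik W_jk with
    # W_ik = exp(g_i - u_ik)/D_k; rows sum to 1 because sum_j N_j W_jk = 1.
    W = np.exp(g[:, None] - u - logD[None, :])
    overlap = W @ (counts[:, None] * W).T
    return MBARSolution(
        G=g / tab.beta,
        logw=logw,
        overlap=overlap,
        grad_norm=grad_norm,
        n_iter=n_iter,
    )


def free_energy_errors(
    tab: EnergyTable, sol: MBARSolution, n_boot: int, seed: int
) -> np.ndarray:
    """Bootstrap standard errors of the state free energies.

    Samples are resampled with replacement within each originating state
    (counts preserved) and MBAR re-solved per replicate; sigma is the
    standard deviation of each G over replicates, with sigma[0] = 0 by the
    gauge choice.  Data should already be decorrelated via
    :func:`fenet.timeseries.subsample_indices` — the bootstrap treats
    columns as independent.

    Parameters
    ----------
    n_boot : int
        Number of replicates, >= 8.
    seed : int
        Seed for the resampling RNG.
    """
    if n_boot < 8:
        raise DataError(f"n_boot must be >= 8, got {n_boot}")
    rng = np.random.default_rng(seed)
    by_state = [
        np.flatnonzero(tab.sample_state == i) for i in range(tab.n_states)
    ]
    Gs = np.empty((n_boot, tab.n_states))
    for b in range(n_boot):
        cols = np.concatenate(
            [rng.choice(idx, size=idx.size, replace=True)
             for idx in by_state if idx.size]
        )
        rtab = EnergyTable(
            u=tab.u[:, cols],
            counts=tab.counts,
            beta=tab.beta,
            sample_state=tab.sample_state[cols],
        )
        Gs[b] = solve_mbar(rtab, tol=1e-8).G
    sigma = Gs.std(axis=0, ddof=1)
    sigma[0] = 0.0
    return sigma
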