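"""Per-edge alchemical free energy analysis.

An edge is one alchemical transformation (ligand a -> ligand b) simulated
in two environments (ref and target, e.g. solvated and complexed), each
decomposed into stages, each stage replicated as independent trials, each
trial a set of states spanning lambda in [0, 1].  The trial data are
"efep_<tlam>_<elam>.dat" files: the potential energy (kcal/mol) of every
sample drawn at tlam, evaluated at elam.

The whole-edge objective is the 1/N_trial-weighted sum of per-trial MBAR
objectives over environments, stages, and trials; its block structure means
the unconstrained optimum factorizes into independent per-trial MBAR
solves.  The edge free energy composes the definitional formulas
dG_trial = G(lambda=1) - G(lambda=0), dG_stage = <dG_trial>,
dG_env = sum_stages, ddG = dG_target - dG_ref.

For networkwide analysis the *effective edge objective* F~(x) — the
edge objective minimized subject to ddG(G) = x — is pretabulated at the
five points x = ddG* + {-2,-1,0,1,2} kcal/mol via Newton iterations on
the KKT system, and summarized by the quadratic surrogate
F~(x) ~= F~(ddG*) + (k/2)(x - g)^2 whose curvature k measures the
information the edge carries.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from fenet import timeseries
from fenet.constants import beta_from_temperature
from fenet.exceptions import ConvergenceError, DataError
from fenet.mbar_core import EnergyTable, mbar_objective, solve_mbar

__all__ = [
    "TrialData",
    "EdgeData",
    "EdgeResult",
    "read_edge_xml",
    "read_efep_dir",
    "edge_objective",
    "analyze_edge",
    "tabulate_objective",
    "fit_surrogate",
    "edge_diagnostics",
    "write_edge_json",
    "read_edge_json",
]

DELTAS = (-2.0, -1.0, 0.0, 1.0, 2.0)


@dataclass
class TrialData:
    """One trial: states at strictly increasing lambdas in [0, 1]."""

    name: str
    lambdas: np.ndarray
    table: EnergyTable
    times: list = field(default_factory=list)  # per-state time arrays (ps)

    def __post_init__(self):
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise DataError(
                f"trial '{self.name}': lambdas must be strictly increasing"
            )
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise DataError(
                f"trial '{self.name}': lambda=0 and lambda=1 states are "
                "required (they define the trial free energy)"
            )
        if self.table.n_states != lam.size:
            raise DataError(
                f"trial '{self.name}': table has {self.table.n_states} "
                f"states but {lam.size} lambdas"
            )
        object.__setattr__(self, "lambdas", lam)

    @property
    def n_states(self) -> int:
        return self.lambdas.size


@dataclass
class EdgeData:
    """Edge hierarchy: two environments -> stages -> trials."""

    name: str
    temperature: float
    environments: dict  # {"ref": {stage_name: [TrialData, ...]}, "target": ...}

    def __post_init__(self):
        if set(self.environments) != {"ref", "target"}:
            raise DataError(
                f"edge '{self.name}': exactly two environments named "
                f"'ref' and 'target' required, got {sorted(self.environments)}"
            )
        for env, stages in self.environments.items():
            if not stages:
                raise DataError(f"edge '{self.name}': environment '{env}' "
                                "has no stages")
            for sname, trials in stages.items():
                if not trials:
                    raise DataError(
                        f"edge '{self.name}': stage '{env}/{sname}' has no "
                        "trials"
                    )

    def iter_trials(self):
        """Yield (env, stage, TrialData) in deterministic order."""
        for env in ("ref", "target"):
            for sname in self.environments[env]:
                for tr in self.environments[env][sname]:
                    yield env, sname, tr


@dataclass
class EdgeResult:
    """Summary of one analyzed edge.

    k has units 1/(kcal/mol): the curvature of the per-sample-normalized
    effective objective with respect to the constrained ddG.
    """

    name: str
    ddG: float
    trial_sem: float
    g: float                  # surrogate center (= ddG)
    k: float                  # surrogate force constant
    tabulated: list           # [(x, F~(x))] at the five constrained points
    dG_ref: float
    dG_target: float
    trial_dGs: dict           # {"env/stage": [per-trial dG]}
    stage_sems: dict          # {"env/stage": sem}
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "ddG": self.ddG,
            "trial_sem": self.trial_sem,
            "g": self.g,
            "k": self.k,
            "tabulated": [[x, f] for x, f in self.tabulated],
            "dG_ref": self.dG_ref,
            "dG_target": self.dG_target,
            "trial_dGs": self.trial_dGs,
            "stage_sems": self.stage_sems,
            "diagnostics": self.diagnostics,
        }

    @staticmethod
    def from_dict(d: dict) -> "EdgeResult":
        return EdgeResult(
            name=d["name"], ddG=d["ddG"], trial_sem=d["trial_sem"],
            g=d["g"], k=d["k"],
            tabulated=[(x, f) for x, f in d["tabulated"]],
            dG_ref=d["dG_ref"], dG_target=d["dG_target"],
            trial_dGs=d["trial_dGs"], stage_sems=d["stage_sems"],
            diagnostics=d.get("diagnostics", {}),
        )


# ---------------------------------------------------------------------------
# input parsing
# ---------------------------------------------------------------------------

_EFEP_RE = re.compile(r"^efep_(\S+?)_(\S+?)\.dat$")


def _scan_efep_dir(directory: Path) -> dict:
    """Map (tlam, elam) float pairs -> file path for all efep files."""
    out = {}
    for p in sorted(directory.iterdir()):
        m = _EFEP_RE.match(p.name)
        if not m:
            continue
        try:
            out[(float(m.group(1)), float(m.group(2)))] = p
        except ValueError:
            continue
    return out


def _read_efep_file(path: Path):
    times, energies = [], []
    with open(path) as fh:
        for rowno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) < 2:
                raise DataError(f"{path}, row {rowno}: expected time and "
                                "energy columns")
            try:
                times.append(float(tok[0]))
                energies.append(float(tok[1]))
            except ValueError:
                raise DataError(
                    f"{path}, row {rowno}: non-numeric token"
                ) from None
    if not times:
        raise DataError(f"{path}: empty efep file")
    return np.asarray(times), np.asarray(energies)


def _lookup(files: dict, tlam: float, elam: float, directory):
    for (t, e), p in files.items():
        if abs(t - tlam) < 1e-9 and abs(e - elam) < 1e-9:
            return p
    raise DataError(
        f"missing efep file for tlam={tlam:.8f}, elam={elam:.8f} in "
        f"{directory}"
    )


def read_efep_dir(directory, lambdas, beta: float, equil: bool = False):
    """Assemble a trial's EnergyTable from a directory of efep files.

    For every sampled tlam and every evaluated elam the file
    ``efep_<tlam>_<elam>.dat`` must exist with equal row counts across elam
    (they tabulate the same samples).  Reduced energies are beta*U.

    With ``equil=True``, each sampled state is trimmed by equilibration
    detection on its lambda-neighbor energy-difference series (the
    quantity that drives the reweighting), applied consistently across all
    elam columns of that tlam.

    Returns
    -------
    (EnergyTable, times) : times is a list of per-state time arrays.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise DataError(f"efep directory not found: {directory}")
    lambdas = np.asarray(lambdas, dtype=float)
    files = _scan_efep_dir(directory)
    K = lambdas.size
    blocks = []   # per tlam: (n_j, K) energy matrix
    times_out = []
    import logging
    logger = logging.getLogger(__name__)
    for j, tlam in enumerate(lambdas):
        cols = []
        n_rows = None
        t_ref = None
        for elam in lambdas:
            p = _lookup(files, tlam, elam, directory)
            t, e = _read_efep_file(p)
            if n_rows is None:
                n_rows = e.size
                t_ref = t
                if np.any(np.diff(t) <= 0):
                    logger.warning(
                        "%s: time column is not strictly increasing; rows "
                        "kept in file order", p
                    )
            elif e.size != n_rows:
                raise DataError(
                    f"{p}: row count {e.size} does not match "
                    f"{n_rows} rows of the tlam={tlam:.8f} series"
                )
            cols.append(e)
        block = np.column_stack(cols)  # (n_j, K)
        if equil and n_rows >= 20:
            jn = j + 1 if j + 1 < K else j - 1
            series = block[:, jn] - block[:, j]
            if not timeseries.is_constant(series):
                rep = timeseries.detect_equilibration(series)
                block = block[rep.t0_index:]
                t_ref = t_ref[rep.t0_index:]
        blocks.append(block)
        times_out.append(t_ref)
    counts = np.array([b.shape[0] for b in blocks])
    u = beta * np.vstack(blocks).T  # (K, N): state l energy of all samples
    table = EnergyTable.from_state_blocks(u, counts, beta)
    return table, times_out


def read_edge_xml(path, equil: bool = False) -> EdgeData:
    """Parse an edge descriptor XML and load all referenced efep data.

    Schema::

        <edge name="ligA~ligB" [temperature="298.0"]>
          <env name="ref|target">
            <stage name="...">
              <trial name="..." dir="PATH">
                <state lambda="0.00000000"/> ...
              </trial>
            </stage>
          </env>
        </edge>

    ``dir`` is resolved relative to the XML file's directory.
    """
    path = Path(path)
    try:
        root = etree.parse(str(path)).getroot()
    except (etree.XMLSyntaxError, OSError) as e:
        raise DataError(f"cannot read edge XML {path}: {e}") from None
    if root.tag != "edge":
        raise DataError(f"{path}: root element must be <edge>")
    name = root.get("name", "edge")
    temperature = float(root.get("temperature", "298.0"))
    beta = beta_from_temperature(temperature)
    environments = {}
    for env in root.findall("env"):
        ename = env.get("name")
        if ename not in ("ref", "target"):
            raise DataError(
                f"{path}: <env name='{ename}'> must be 'ref' or 'target'"
            )
        stages = {}
        for stage in env.findall("stage"):
            sname = stage.get("name", f"stage{len(stages)}")
            trials = []
            for trial in stage.findall("trial"):
                tname = trial.get("name", f"t{len(trials) + 1}")
                tdir = trial.get("dir")
                if tdir is None:
                    raise DataError(
                        f"{path}: trial '{ename}/{sname}/{tname}' lacks a "
                        "dir attribute"
                    )
                tdir = Path(tdir)
                if not tdir.is_absolute():
                    tdir = path.parent / tdir
                lams = []
                for st in trial.findall("state"):
                    lv = st.get("lambda")
                    if lv is None:
                        raise DataError(
                            f"{path}: state without lambda in trial "
                            f"'{ename}/{sname}/{tname}'"
                        )
                    lams.append(float(lv))
                if len(set(lams)) != len(lams):
                    raise DataError(
                        f"{path}: duplicate lambda in trial "
                        f"'{ename}/{sname}/{tname}'"
                    )
                lams = np.sort(np.asarray(lams))
                if lams.size < 2 or lams[0] != 0.0 or lams[-1] != 1.0:
                    raise DataError(
                        f"{path}: trial '{ename}/{sname}/{tname}' must "
                        "contain lambda=0 and lambda=1 states"
                    )
                table, times = read_efep_dir(tdir, lams, beta, equil=equil)
                trials.append(
                    TrialData(name=tname, lambdas=lams, table=table,
                              times=times)
                )
            if trials:
                stages[sname] = trials
        if stages:
            environments[ename] = stages
    return EdgeData(name=name, temperature=temperature,
                    environments=environments)


# ---------------------------------------------------------------------------
# objective assembly
# ---------------------------------------------------------------------------

def _blocks(ed: EdgeData):
    """Flattened trial blocks with their objective weights and ddG signs."""
    out = []
    offset = 0
    for env, sname, tr in ed.iter_trials():
        n_tr = len(ed.environments[env][sname])
        sign = 1.0 if env == "target" else -1.0
        out.append({
            "env": env, "stage": sname, "trial": tr,
            "weight": 1.0 / n_tr, "sign": sign,
            "slice": slice(offset, offset + tr.n_states),
        })
        offset += tr.n_states
    return out, offset


def edge_objective(ed: EdgeData, G: np.ndarray):
    """Whole-edge objective: 1/N_trial-weighted sum of trial objectives.

    G concatenates every trial's state free energies (kcal/mol) in
    deterministic (ref stages, then target stages) order.
    """
    blocks, n = _blocks(ed)
    G = np.asarray(G, dtype=float)
    if G.shape != (n,):
        raise DataError(f"G must have shape ({n},), got {G.shape}")
    value = 0.0
    grad = np.zeros(n)
    for b in blocks:
        v, gr = mbar_objective(b["trial"].table, G[b["slice"]])
        value += b["weight"] * v
        grad[b["slice"]] = b["weight"] * gr
    return value, grad


def _ddG_coefficients(ed: EdgeData) -> np.ndarray:
    """Linear functional a with a.G = ddG(G)."""
    blocks, n = _blocks(ed)
    a = np.zeros(n)
    for b in blocks:
        sl = b["slice"]
        a[sl.start] -= b["sign"] * b["weight"]          # lambda=0 state
        a[sl.stop - 1] += b["sign"] * b["weight"]       # lambda=1 state
    return a


def analyze_edge(ed: EdgeData, deltas=DELTAS, tabulate: bool = True,
                 diagnostics: bool = True) -> EdgeResult:
    """Full per-edge analysis: trial solves, ddG, pretabulation, surrogate.

    The unconstrained edge optimum factorizes into independent per-trial
    MBAR solves because the edge objective is block diagonal.
    """
    blocks, _ = _blocks(ed)
    sols = {}
    trial_dGs = {}
    for b in blocks:
        sol = solve_mbar(b["trial"].table)
        sols[id(b["trial"])] = sol
        key = f"{b['env']}/{b['stage']}"
        trial_dGs.setdefault(key, []).append(float(sol.G[-1] - sol.G[0]))
    stage_sems = {}
    env_dG = {"ref": 0.0, "target": 0.0}
    var_total = 0.0
    for key, vals in trial_dGs.items():
        env = key.split("/", 1)[0]
        arr = np.asarray(vals)
        env_dG[env] += float(arr.mean())
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        stage_sems[key] = sem
        var_total += sem**2
    ddG = env_dG["target"] - env_dG["ref"]
    trial_sem = float(np.sqrt(var_total))
    tab = []
    k = float("nan")
    if tabulate:
        tab = tabulate_objective(ed, ddG, deltas=deltas, solutions=sols)
        _, k = fit_surrogate(tab)
    diag = {}
    if diagnostics:
        diag = edge_diagnostics(ed, sols)
    return EdgeResult(
        name=ed.name, ddG=float(ddG), trial_sem=trial_sem, g=float(ddG),
        k=float(k), tabulated=tab, dG_ref=float(env_dG["ref"]),
        dG_target=float(env_dG["target"]), trial_dGs=trial_dGs,
        stage_sems=stage_sems, diagnostics=diag,
    )


def _free_parameterization(ed: EdgeData):
    """Free variables: each trial's lambda>0 free energies (lambda=0 anchored).

    Anchoring removes the per-trial gauge freedom (a uniform shift of one
    trial's block changes neither the objective nor ddG) and makes the
    constrained problem strictly convex.
    """
    blocks, n = _blocks(ed)
    free_idx = []
    for b in blocks:
        sl = b["slice"]
        free_idx.extend(range(sl.start + 1, sl.stop))
    return blocks, n, np.asarray(free_idx, dtype=int)


def tabulate_objective(ed: EdgeData, ddG_star: float, deltas=DELTAS,
                       solutions=None, tol: float = 1e-10,
                       max_iter: int = 200) -> list:
    """Pretabulate the effective edge objective F~(x) at x = ddG* + deltas.

    Each point solves min_G F_edge(G) subject to ddG(G) = x — a single
    linear equality constraint — by Newton iterations on the KKT system
    with the analytic block-diagonal Hessian, warm-started from the
    unconstrained optimum.

    Returns a list of (x, F~(x)) pairs sorted by x.
    """
    blocks, n, free_idx = _free_parameterization(ed)
    # warm start: per-trial unconstrained solutions
    G0 = np.zeros(n)
    for b in blocks:
        sol = (solutions or {}).get(id(b["trial"]))
        if sol is None:
            sol = solve_mbar(b["trial"].table)
        G0[b["slice"]] = sol.G
    a_full = _ddG_coefficients(ed)
    a = a_full[free_idx]
    nf = free_idx.size
    out = []
    for d in sorted(deltas):
        x = ddG_star + d
        z = G0[free_idx].copy()
        mu = 0.0
        ok = False
        for _ in range(max_iter):
            val, grad_full, H = _objective_with_hessian(ed, blocks, free_idx,
                                                        z)
            r1 = grad_full + mu * a
            r2 = float(a @ z - x)
            res = max(float(np.max(np.abs(r1))), abs(r2))
            if res <= tol:
                ok = True
                break
            kkt = np.zeros((nf + 1, nf + 1))
            kkt[:nf, :nf] = H + 1e-13 * np.eye(nf)
            kkt[:nf, nf] = a
            kkt[nf, :nf] = a
            try:
                step = np.linalg.solve(kkt, -np.concatenate([r1, [r2]]))
            except np.linalg.LinAlgError:
                raise ConvergenceError(
                    f"singular KKT system at x = {x:.6f}", residual=res
                ) from None
            z = z + step[:nf]
            mu = mu + step[nf]
        if not ok:
            raise ConvergenceError(
                f"KKT Newton did not converge at x = {x:.6f} "
                f"(residual {res:.3e})", residual=res
            )
        val, _, _ = _objective_with_hessian(ed, blocks, free_idx, z)
        out.append((float(x), float(val)))
    return out


def _objective_with_hessian(ed, blocks, free_idx, z):
    """Edge objective, gradient, Hessian in the anchored free variables."""
    n = blocks[-1]["slice"].stop
    G = np.zeros(n)
    G[free_idx] = z
    value = 0.0
    grad = np.zeros(n)
    H = np.zeros((free_idx.size, free_idx.size))
    pos_of = {g_i: i for i, g_i in enumerate(free_idx)}
    for b in blocks:
        tab = b["trial"].table
        sl = b["slice"]
        v, gr = mbar_objective(tab, G[sl])
        value += b["weight"] * v
        grad[sl] = b["weight"] * gr
        Hb = _mbar_hessian(tab, G[sl])  # w.r.t. G, (K,K)
        idx = [pos_of[i] for i in range(sl.start + 1, sl.stop)]
        H[np.ix_(idx, idx)] += b["weight"] * Hb[1:, 1:]
    return value, grad[free_idx], H


def _mbar_hessian(tab: EnergyTable, G):
    """Analytic Hessian of the per-trial objective w.r.t. G (kcal/mol)."""
    from fenet.mbar_core import _log_denominator
    g = tab.beta * np.asarray(G, dtype=float)
    counts = tab.counts
    N = tab.n_samples
    logD = _log_denominator(tab.u, g, counts)
    active = counts > 0
    T = counts[:, None] * np.exp(g[:, None] - tab.u - logD[None, :])
    T[~active] = 0.0
    H = np.diag(T.mean(axis=1)) - (T @ T.T) / N
    return tab.beta**2 * H


def fit_surrogate(points) -> tuple:
    """Closed-form quadratic fit F~(x) ~= F~_c + (k/2)(x - g)^2.

    g is the x of the center (delta = 0) point; k is the least-squares
    slope over the four displaced residuals: with z_i = (x_i - g)^2 / 2 and
    y_i = F~_i - F~_center, k = sum(y z) / sum(z^2).
    """
    pts = sorted(points)
    if len(pts) != 5:
        raise DataError(f"surrogate fit needs 5 points, got {len(pts)}")
    g, Fc = pts[2]
    y = np.array([f - Fc for x, f in pts if x != g])
    z = np.array([0.5 * (x - g) ** 2 for x, f in pts if x != g])
    if np.any(y < -1e-9):
        raise DataError(
            "center is not the minimum of the tabulated objective "
            f"(min residual {y.min():.3e})"
        )
    k = float(np.dot(y, z) / np.dot(z, z))
    if k <= 0:
        raise DataError(f"fitted force constant is non-positive (k = {k:g})")
    return float(g), k


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def edge_diagnostics(ed: EdgeData, solutions=None) -> dict:
    """Adjacent-state diagnostics per trial.

    For each adjacent lambda pair (i, j): the MBAR overlap entries, the
    forward/backward energy-gap means and variances (kcal/mol), and the
    estimated replica-exchange acceptance <min(1, exp(-beta*DDelta))> from
    paired samples.  (Energy gaps between adjacent states stand in for
    dU/dlambda profiles, which generic tabulated input cannot provide.)
    """
    diag = {}
    for env, sname, tr in ed.iter_trials():
        sol = (solutions or {}).get(id(tr))
        if sol is None:
            sol = solve_mbar(tr.table)
        tab = tr.table
        pairs = []
        for i in range(tr.n_states - 1):
            j = i + 1
            ci = tab.sample_state == i
            cj = tab.sample_state == j
            du_f = (tab.u[j, ci] - tab.u[i, ci]) / tab.beta  # kcal/mol
            du_b = (tab.u[i, cj] - tab.u[j, cj]) / tab.beta
            m = min(du_f.size, du_b.size)
            dd = tab.beta * (du_f[:m] + du_b[:m])
            acc = float(np.mean(np.minimum(1.0, np.exp(-dd)))) if m else 0.0
            pairs.append({
                "lam_i": float(tr.lambdas[i]),
                "lam_j": float(tr.lambdas[j]),
                "overlap_ij": float(sol.overlap[i, j]),
                "overlap_ji": float(sol.overlap[j, i]),
                "dU_fwd_mean": float(du_f.mean()),
                "dU_fwd_var": float(du_f.var(ddof=0)),
                "dU_bwd_mean": float(du_b.mean()),
                "dU_bwd_var": float(du_b.var(ddof=0)),
                "exchange_acceptance": acc,
            })
        diag[f"{env}/{sname}/{tr.name}"] = pairs
    return diag


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_edge_json(res: EdgeResult, path) -> None:
    Path(path).write_text(json.dumps(res.to_dict(), indent=1) + "\n")


def read_edge_json(path) -> EdgeResult:
    try:
        return EdgeResult.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError) as e:
        raise DataError(f"cannot read edge JSON {path}: {e}") from None


def edge_report_text(res: EdgeResult) -> str:
    """Plain-text edge report."""
    lines = [
        f"edge {res.name}",
        f"  ddG      = {res.ddG:10.4f} +- {res.trial_sem:.4f} kcal/mol",
        f"  dG_ref   = {res.dG_ref:10.4f} kcal/mol",
        f"  dG_target= {res.dG_target:10.4f} kcal/mol",
        f"  surrogate: g = {res.g:.4f} kcal/mol, k = {res.k:.6g} 1/(kcal/mol)",
        "  tabulated objective:",
    ]
    for x, f in res.tabulated:
        lines.append(f"    x = {x:10.4f}   F~ = {f:.10f}")
    lines.append("  trials:")
    for key in sorted(res.trial_dGs):
        vals = ", ".join(f"{v:.4f}" for v in res.trial_dGs[key])
        lines.append(f"    {key}: [{vals}]  sem = {res.stage_sems[key]:.4f}")
    return "\n".join(lines) + "\n"
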