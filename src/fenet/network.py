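"""Networkwide alchemical free energy analysis.

Edges of a thermodynamic graph carry an unconstrained relative free energy
g_(ab) and a force constant k_(ab) (the curvature of the effective edge
objective).  Ligand free energies c (relative to a reference ligand with
c = 0) minimize the quadratic graph objective

    F(c) = sum_(ab) k_(ab)/2 * (c_b - c_a - g_(ab))^2,

whose exact minimizer is c = M^-1 X^T K g with X the signed edge-node
incidence matrix (reference column removed), K = diag(k), M = X^T K X.
Because the solved edge differences are gradients of node potentials, they
telescope: their sum around any closed path is identically zero — the
consistency property raw per-edge estimates lack.  Experimental reference
values for a subset of edges can be imposed as hard linear equality
constraints through a KKT block system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from fenet.exceptions import DataError

__all__ = [
    "ThermoGraph",
    "GraphSolution",
    "solve_network",
    "solve_constrained",
    "enumerate_cycles",
    "flag_outlier_trials",
    "write_graph_report",
    "load_edge_results",
]


@dataclass
class ThermoGraph:
    """Ligand nodes plus edges (a, b, g, k, trial_sem).

    Parallel edges between one pair are legal and kept distinct (each
    contributes its own quadratic term, equivalent to summing k).
    Self-edges are rejected.
    """

    ligands: list
    edges: list
    constraints: list = field(default_factory=list)  # (a, b, value_exp)

    def __post_init__(self):
        known = set(self.ligands)
        if len(known) != len(self.ligands):
            raise DataError("duplicate ligand names")
        for (a, b, g, k, sem) in self.edges:
            if a == b:
                raise DataError(f"self-edge on ligand '{a}'")
            if a not in known or b not in known:
                raise DataError(f"edge {a}~{b} references unknown ligand")
            if k <= 0:
                raise DataError(f"edge {a}~{b}: force constant must be > 0")
            if sem < 0:
                raise DataError(f"edge {a}~{b}: negative trial_sem")
        pair_set = {frozenset((a, b)) for a, b, *_ in self.edges}
        for (a, b, v) in self.constraints:
            if frozenset((a, b)) not in pair_set:
                raise DataError(
                    f"constraint {a}~{b} does not correspond to a graph edge"
                )

    def nx_graph(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.ligands)
        G.add_edges_from((a, b) for a, b, *_ in self.edges)
        return G


@dataclass
class GraphSolution:
    """Solved ligand free energies and diagnostics."""

    ref_ligand: str
    ligands: list
    c: np.ndarray             # kcal/mol, c[ref] = 0
    sigma: np.ndarray         # per-ligand standard error from trial scatter
    cov: np.ndarray           # ligand covariance, kcal^2/mol^2
    edge_residuals: np.ndarray  # (c_b - c_a) - g per edge
    cycles: list              # (node list, raw-g closure error)
    constraint_report: list   # (a, b, target, achieved)

    def c_of(self, name: str) -> float:
        return float(self.c[self.ligands.index(name)])


def _incidence(tg: ThermoGraph, ref: str):
    lig = list(tg.ligands)
    if ref not in lig:
        raise DataError(f"reference ligand '{ref}' not in graph")
    cols = [l for l in lig if l != ref]
    col_of = {l: j for j, l in enumerate(cols)}
    n_e = len(tg.edges)
    X = np.zeros((n_e, len(cols)))
    g = np.zeros(n_e)
    k = np.zeros(n_e)
    sem = np.zeros(n_e)
    for i, (a, b, gi, ki, si) in enumerate(tg.edges):
        if a in col_of:
            X[i, col_of[a]] = -1.0
        if b in col_of:
            X[i, col_of[b]] = 1.0
        g[i], k[i], sem[i] = gi, ki, si
    return X, g, k, sem, cols


def _require_connected(tg: ThermoGraph):
    G = tg.nx_graph()
    comps = list(nx.connected_components(G))
    if len(comps) > 1:
        listing = "; ".join(sorted(",".join(sorted(c)) for c in comps))
        raise DataError(
            f"graph is disconnected ({len(comps)} components: {listing}); "
            "solve each component with its own reference"
        )


def solve_network(tg: ThermoGraph, ref: str | None = None) -> GraphSolution:
    """Exact minimizer of the quadratic graph objective.

    Parameters
    ----------
    ref : str, optional
        Reference ligand (c = 0).  Defaults to the lexicographically
        smallest name, which keeps output deterministic.
    """
    if not tg.edges:
        raise DataError("graph has no edges")
    _require_connected(tg)
    if ref is None:
        ref = min(tg.ligands)
    X, g, k, sem, cols = _incidence(tg, ref)
    K = np.diag(k)
    M = X.T @ K @ X
    try:
        c_free = np.linalg.solve(M, X.T @ K @ g)
    except np.linalg.LinAlgError:
        raise DataError("singular normal matrix: graph has an isolated "
                        "ligand or degenerate edges") from None
    Minv = np.linalg.inv(M)
    Sigma = np.diag(sem**2)
    cov_free = Minv @ X.T @ K @ Sigma @ K @ X @ Minv
    return _package(tg, ref, cols, c_free, cov_free, g, X)


def solve_constrained(
    tg: ThermoGraph, ref: str | None = None, constraints=None
) -> GraphSolution:
    """Graph solve with hard equality constraints c_b - c_a = value_exp.

    The constrained minimizer solves the KKT block system
    [[M, A^T], [A, 0]] [c, mu] = [X^T K g, v].  Constraints that close a
    cycle must be mutually consistent; redundancy or inconsistency raises.
    """
    if constraints is None:
        constraints = tg.constraints
    if not constraints:
        return solve_network(tg, ref)
    if not tg.edges:
        raise DataError("graph has no edges")
    _require_connected(tg)
    if ref is None:
        ref = min(tg.ligands)
    _check_constraint_consistency(constraints)
    X, g, k, sem, cols = _incidence(tg, ref)
    col_of = {l: j for j, l in enumerate(cols)}
    n_c = len(constraints)
    A = np.zeros((n_c, len(cols)))
    v = np.zeros(n_c)
    for i, (a, b, val) in enumerate(constraints):
        if a in col_of:
            A[i, col_of[a]] = -1.0
        if b in col_of:
            A[i, col_of[b]] = 1.0
        v[i] = val
        if a not in col_of and b not in col_of:
            raise DataError(f"constraint {a}~{b} is degenerate")
    if np.linalg.matrix_rank(A) < n_c:
        raise DataError(
            "over-constrained system: constraints are linearly dependent "
            "(rank deficiency)"
        )
    K = np.diag(k)
    M = X.T @ K @ X
    n = len(cols)
    kkt = np.zeros((n + n_c, n + n_c))
    kkt[:n, :n] = M
    kkt[:n, n:] = A.T
    kkt[n:, :n] = A
    rhs = np.concatenate([X.T @ K @ g, v])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError:
        raise DataError("singular KKT system") from None
    c_free = sol[:n]
    # covariance of the constrained estimator: project the data term
    # through the KKT inverse (constraint rows carry no data noise)
    kkt_inv = np.linalg.inv(kkt)
    B = kkt_inv[:n, :n]
    Sigma = np.diag(sem**2)
    cov_free = B @ X.T @ K @ Sigma @ K @ X @ B.T
    out = _package(tg, ref, cols, c_free, cov_free, g, X)
    cmap = dict(zip(out.ligands, out.c))
    out.constraint_report.extend(
        (a, b, float(val), float(cmap[b] - cmap[a]))
        for a, b, val in constraints
    )
    return out


#: Constraint cycle-sum consistency tolerance, kcal/mol.
_CONS_TOL = 1e-8


def _check_constraint_consistency(constraints):
    """BFS potential assignment over the constraint graph; any edge that
    closes a cycle must agree with the implied difference."""
    pot = {}
    comp = {}
    for a, b, val in constraints:
        ra = comp.get(a)
        rb = comp.get(b)
        if ra is None and rb is None:
            comp[a] = comp[b] = a
            pot[a] = 0.0
            pot[b] = val
        elif ra is None:
            comp[a] = rb
            pot[a] = pot[b] - val
        elif rb is None:
            comp[b] = ra
            pot[b] = pot[a] + val
        elif ra != rb:
            delta = pot[a] + val - pot[b]
            for node, r in comp.items():
                if r == rb:
                    comp[node] = ra
                    pot[node] += delta
        else:
            err = (pot[b] - pot[a]) - val
            if abs(err) > _CONS_TOL:
                raise DataError(
                    f"inconsistent constraints: cycle through {a}~{b} "
                    f"violates closure by {err:.6g} kcal/mol"
                )
            raise DataError(
                f"over-constrained: constraint {a}~{b} is redundant with "
                "earlier constraints"
            )


def _package(tg, ref, cols, c_free, cov_free, g, X):
    ligands = list(tg.ligands)
    c = np.zeros(len(ligands))
    cov = np.zeros((len(ligands), len(ligands)))
    pos = {l: i for i, l in enumerate(ligands)}
    for j, l in enumerate(cols):
        c[pos[l]] = c_free[j]
        for j2, l2 in enumerate(cols):
            cov[pos[l], pos[l2]] = cov_free[j, j2]
    residuals = X @ c_free - g
    cycles = enumerate_cycles(tg)
    sigma = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return GraphSolution(
        ref_ligand=ref,
        ligands=ligands,
        c=c,
        sigma=sigma,
        cov=cov,
        edge_residuals=residuals,
        cycles=cycles,
        constraint_report=[],
    )


def enumerate_cycles(tg: ThermoGraph, max_len: int | None = None) -> list:
    """Cycle list with raw-g closure errors.

    Returns a minimum-weight cycle basis plus all triangles (deduplicated).
    The closure error of a cycle is the signed sum of the raw edge free
    energies around it; for parallel edges the mean g of the pair is used.
    Closure of *solved* differences is identically zero by construction and
    is not listed here.
    """
    # mean g per unordered pair (parallel edges collapse for cycle purposes)
    acc = {}
    for a, b, g, k, sem in tg.edges:
        key = (a, b) if a <= b else (b, a)
        sgn = 1.0 if a <= b else -1.0
        acc.setdefault(key, []).append(sgn * g)
    gmap = {key: float(np.mean(v)) for key, v in acc.items()}
    G = nx.Graph()
    G.add_nodes_from(tg.ligands)
    G.add_edges_from(gmap)
    try:
        basis = nx.minimum_cycle_basis(G)
    except nx.NetworkXError:
        basis = []
    cycles = {}
    for nodes in basis:
        cyc = _order_cycle(G, nodes)
        if cyc is not None:
            cycles[_canon(cyc)] = cyc
    for tri in _triangles(G):
        cycles.setdefault(_canon(tri), tri)
    out = []
    for cyc in sorted(cycles.values(), key=lambda c: (len(c), c)):
        if max_len is not None and len(cyc) > max_len:
            continue
        err = 0.0
        for i in range(len(cyc)):
            a, b = cyc[i], cyc[(i + 1) % len(cyc)]
            key = (a, b) if a <= b else (b, a)
            err += gmap[key] if a <= b else -gmap[key]
        out.append((cyc, err))
    return out


def _order_cycle(G, nodes):
    """Order a basis cycle's node set into a closed walk, if it induces one."""
    H = G.subgraph(nodes)
    if any(d != 2 for _, d in H.degree()):
        try:
            cyc_edges = nx.find_cycle(H)
        except nx.NetworkXNoCycle:
            return None
        return [a for a, _ in cyc_edges]
    start = min(nodes)
    walk = [start]
    prev = None
    cur = start
    while True:
        nbrs = [n for n in H.neighbors(cur) if n != prev]
        nxt = nbrs[0]
        if nxt == start:
            return walk
        walk.append(nxt)
        prev, cur = cur, nxt


def _triangles(G):
    tris = []
    for a in G:
        for b in G.neighbors(a):
            if b <= a:
                continue
            for c in G.neighbors(b):
                if c <= b:
                    continue
                if G.has_edge(a, c):
                    tris.append([a, b, c])
    return tris


def _canon(cyc):
    n = len(cyc)
    i = cyc.index(min(cyc))
    fwd = tuple(cyc[(i + j) % n] for j in range(n))
    bwd = tuple(cyc[(i - j) % n] for j in range(n))
    return min(fwd, bwd)


def flag_outlier_trials(trial_dGs_by_stage: dict) -> dict:
    """Flag trials whose stage free energy is irreconcilable with its peers.

    For stages with >= 4 trials a modified z-score is used:
    z = 0.6745 (x - median)/MAD, flagging |z| > 3.5.  Smaller stages fall
    back to a leave-one-out rule: a trial is flagged when removing it
    shifts the stage mean by more than 5 standard errors of the remaining
    trials.

    Parameters
    ----------
    trial_dGs_by_stage : dict
        Mapping stage label -> sequence of per-trial dG values (kcal/mol).

    Returns
    -------
    dict mapping stage label -> list of flagged trial indices.
    """
    flags = {}
    for stage, vals in trial_dGs_by_stage.items():
        x = np.asarray(vals, dtype=float)
        n = x.size
        hit = []
        if n >= 4:
            med = np.median(x)
            mad = np.median(np.abs(x - med))
            if mad > 0:
                z = 0.6745 * (x - med) / mad
                hit = list(np.flatnonzero(np.abs(z) > 3.5))
            else:
                hit = list(np.flatnonzero(x != med))
        elif n >= 2:
            mean = x.mean()
            for i in range(n):
                rest = np.delete(x, i)
                sem = (rest.std(ddof=1) / np.sqrt(rest.size)
                       if rest.size > 1 else 0.0)
                shift = abs(rest.mean() - mean)
                if sem > 0 and shift > 5.0 * sem:
                    hit.append(i)
        flags[stage] = [int(i) for i in hit]
    return flags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_edge_results(directory) -> ThermoGraph:
    """Assemble a ThermoGraph from a directory of ``*.edge.json`` files.

    Ligand names come from the edge name ``lig_a~lig_b``.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.edge.json"))
    if not files:
        raise DataError(f"no *.edge.json files in {directory}")
    edges = []
    ligands = []
    seen = set()
    for f in files:
        d = json.loads(f.read_text())
        try:
            a, b = d["name"].split("~")
            edges.append((a, b, float(d["ddG"]), float(d["k"]),
                          float(d["trial_sem"])))
        except (KeyError, ValueError) as e:
            raise DataError(f"{f}: malformed edge result ({e})") from None
        for l in (a, b):
            if l not in seen:
                seen.add(l)
                ligands.append(l)
    return ThermoGraph(ligands=sorted(ligands), edges=edges)


def read_constraints_tsv(path) -> list:
    """Read a constraints file: whitespace-separated ``ligA ligB value``."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if len(tok) != 3:
                raise DataError(
                    f"{path}, line {lineno}: expected 'ligA ligB value'"
                )
            try:
                out.append((tok[0], tok[1], float(tok[2])))
            except ValueError:
                raise DataError(
                    f"{path}, line {lineno}: non-numeric value '{tok[2]}'"
                ) from None
    return out


def graph_report_dict(sol: GraphSolution, tg: ThermoGraph) -> dict:
    """Deterministically ordered report structure (JSON-ready)."""
    rep = {
        "ref_ligand": sol.ref_ligand,
        "ligands": [
            {"name": l, "c": float(sol.c[i]), "sigma": float(sol.sigma[i])}
            for i, l in enumerate(sol.ligands)
        ],
        "edges": [
            {
                "a": a, "b": b, "g": float(g), "k": float(k),
                "trial_sem": float(sem),
                "solved": float(sol.c_of(b) - sol.c_of(a)),
                "residual": float(sol.edge_residuals[i]),
            }
            for i, (a, b, g, k, sem) in enumerate(tg.edges)
        ],
        "cycles": [
            {"nodes": list(nodes), "closure_raw": float(err),
             "closure_solved": 0.0}
            for nodes, err in sol.cycles
        ],
    }
    if sol.constraint_report:
        rep["constraints"] = [
            {"a": a, "b": b, "target": t, "achieved": ach}
            for a, b, t, ach in sol.constraint_report
        ]
    return rep


def write_graph_report(sol: GraphSolution, tg: ThermoGraph, path) -> dict:
    """Write graph.json and a plain-text graph.txt beside it."""
    rep = graph_report_dict(sol, tg)
    path = Path(path)
    path.write_text(json.dumps(rep, indent=1, sort_keys=False) + "\n")
    lines = [f"reference ligand: {rep['ref_ligand']}", "", "ligands:"]
    for row in rep["ligands"]:
        lines.append(f"  {row['name']:<12s} c = {row['c']:10.4f} "
                     f"+- {row['sigma']:.4f} kcal/mol")
    lines.append("")
    lines.append("edges (g = isolated edge estimate, solved = c_b - c_a):")
    for row in rep["edges"]:
        lines.append(
            f"  {row['a']}~{row['b']:<10s} g = {row['g']:8.4f}  "
            f"solved = {row['solved']:8.4f}  resid = {row['residual']:8.4f}"
            f"  k = {row['k']:.4g}"
        )
    if rep["cycles"]:
        lines.append("")
        lines.append("cycles (closure of raw g; solved closure is 0):")
        for row in rep["cycles"]:
            lines.append(
                "  " + "-".join(row["nodes"]) +
                f"  closure = {row['closure_raw']:8.4f} kcal/mol"
            )
    if "constraints" in rep:
        lines.append("")
        lines.append("constraints:")
        for row in rep["constraints"]:
            lines.append(
                f"  {row['a']}~{row['b']}: target {row['target']:.4f}, "
                f"achieved {row['achieved']:.6f}"
            )
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return rep
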