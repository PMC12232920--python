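import json

import numpy as np
import pytest

from fenet import network, synthgen
from fenet.exceptions import DataError
from fenet.network import (
    ThermoGraph,
    enumerate_cycles,
    flag_outlier_trials,
    solve_constrained,
    solve_network,
)


def dense_quadratic_oracle(tg, ref):
    """Independent weighted-least-squares solve of the graph objective."""
    lig = [l for l in tg.ligands if l != ref]
    col = {l: j for j, l in enumerate(lig)}
    X = np.zeros((len(tg.edges), len(lig)))
    g = np.zeros(len(tg.edges))
    k = np.zeros(len(tg.edges))
    for i, (a, b, gi, ki, s) in enumerate(tg.edges):
        if a in col:
            X[i, col[a]] = -1.0
        if b in col:
            X[i, col[b]] = 1.0
        g[i], k[i] = gi, ki
    w = np.sqrt(k)
    c, *_ = np.linalg.lstsq(w[:, None] * X, w * g, rcond=None)
    return {l: c[j] for l, j in col.items()} | {ref: 0.0}


class TestSolveNetwork:
    def test_two_ligands(self):
        tg = ThermoGraph(ligands=["A", "B"],
                         edges=[("A", "B", 1.5, 2.7, 0.1)])
        sol = solve_network(tg)
        assert sol.c_of("A") == 0.0
        assert sol.c_of("B") == pytest.approx(1.5)

    def test_consistent_triangle(self):
        tg = ThermoGraph(
            ligands=["A", "B", "C"],
            edges=[("A", "B", 1.0, 1.0, 0.0), ("B", "C", 2.0, 1.0, 0.0),
                   ("A", "C", 3.0, 1.0, 0.0)],
        )
        sol = solve_network(tg, ref="A")
        assert np.allclose(sol.edge_residuals, 0.0, atol=1e-12)
        assert sol.c_of("B") == pytest.approx(1.0)
        assert sol.c_of("C") == pytest.approx(3.0)

    def test_inconsistent_triangle_distributes_closure(self):
        tg = ThermoGraph(
            ligands=["A", "B", "C"],
            edges=[("A", "B", 1.0, 1.0, 0.0), ("B", "C", 1.0, 1.0, 0.0),
                   ("A", "C", 3.0, 1.0, 0.0)],
        )
        sol = solve_network(tg, ref="A")
        oracle = dense_quadratic_oracle(tg, "A")
        for l in tg.ligands:
            assert sol.c_of(l) == pytest.approx(oracle[l], abs=1e-8)
        # equal k: the unit closure error spreads -1/3 per edge
        assert np.allclose(np.abs(sol.edge_residuals), 1.0 / 3.0, atol=1e-10)

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = rng.integers(3, 9)
            tg, _ = synthgen.gen_graph(
                int(n), "dense", rng.normal(0, 2, int(n)), 0.4,
                int(rng.integers(1 << 30)),
            )
            # randomize force constants too
            tg = ThermoGraph(
                ligands=tg.ligands,
                edges=[(a, b, g, float(rng.uniform(0.2, 5.0)), s)
                       for a, b, g, k, s in tg.edges],
            )
            sol = solve_network(tg)
            oracle = dense_quadratic_oracle(tg, sol.ref_ligand)
            for l in tg.ligands:
                assert abs(sol.c_of(l) - oracle[l]) < 1e-8

    def test_solved_cycles_close_exactly(self):
        tg, _ = synthgen.gen_graph(7, "dense", np.arange(7.0), 0.5, 3)
        sol = solve_network(tg)
        cmap = dict(zip(sol.ligands, sol.c))
        for nodes, _raw_err in sol.cycles:
            s = sum(
                cmap[nodes[(i + 1) % len(nodes)]] - cmap[nodes[i]]
                for i in range(len(nodes))
            )
            assert abs(s) < 1e-10

    def test_disconnected_graph_rejected(self):
        tg = ThermoGraph(ligands=["A", "B", "C", "D"],
                         edges=[("A", "B", 1.0, 1.0, 0.0),
                                ("C", "D", 1.0, 1.0, 0.0)])
        with pytest.raises(DataError, match="disconnected"):
            solve_network(tg, ref="A")

    def test_noise_free_recovery(self):
        true_c = np.array([0.0, 1.0, -2.0, 0.5])
        tg, truth = synthgen.gen_graph(4, "star", true_c, 0.0, 1)
        sol = solve_network(tg, ref="L00")
        assert np.allclose(sol.c, truth["c"], atol=1e-7)

    def test_shift_gauge(self):
        tg = ThermoGraph(ligands=["A", "B", "C"],
                         edges=[("A", "B", 1.0, 2.0, 0.1),
                                ("B", "C", 0.5, 1.0, 0.1)])
        sol = solve_network(tg, ref="A")
        shifted = ThermoGraph(
            ligands=tg.ligands,
            edges=[("A", "B", 1.0 + 2.0, 2.0, 0.1),
                   ("B", "C", 0.5, 1.0, 0.1)],
        )
        sol2 = solve_network(shifted, ref="A")
        assert sol2.c_of("B") == pytest.approx(sol.c_of("B") + 2.0)
        assert sol2.c_of("C") == pytest.approx(sol.c_of("C") + 2.0)


class TestConstraints:
    def triangle(self):
        return ThermoGraph(
            ligands=["A", "B", "C"],
            edges=[("A", "B", 1.0, 1.0, 0.1), ("B", "C", 1.0, 2.0, 0.1),
                   ("A", "C", 3.0, 1.5, 0.1)],
        )

    def test_inactive_constraint_keeps_solution(self):
        tg = self.triangle()
        free = solve_network(tg, ref="A")
        d = free.c_of("B") - free.c_of("A")
        sol = solve_constrained(tg, ref="A", constraints=[("A", "B", d)])
        assert np.allclose(sol.c, free.c, atol=1e-10)

    def test_constraint_reproduced_and_oracle_match(self):
        tg = self.triangle()
        sol = solve_constrained(tg, ref="A", constraints=[("A", "B", 1.4)])
        assert sol.c_of("B") - sol.c_of("A") == pytest.approx(1.4, abs=1e-12)
        # dense KKT oracle on the 2-variable problem
        k = np.array([1.0, 2.0, 1.5])
        X = np.array([[1.0, 0.0], [-1.0, 1.0], [0.0, 1.0]])
        g = np.array([1.0, 1.0, 3.0])
        M = X.T @ np.diag(k) @ X
        A = np.array([[1.0, 0.0]])
        kkt = np.block([[M, A.T], [A, np.zeros((1, 1))]])
        rhs = np.concatenate([X.T @ (k * g), [1.4]])
        z = np.linalg.solve(kkt, rhs)
        assert sol.c_of("B") == pytest.approx(z[0], abs=1e-8)
        assert sol.c_of("C") == pytest.approx(z[1], abs=1e-8)

    def test_inconsistent_cycle_of_constraints_rejected(self):
        tg = self.triangle()
        with pytest.raises(DataError, match="constrain"):
            solve_constrained(tg, ref="A", constraints=[
                ("A", "B", 1.0), ("B", "C", 1.0), ("A", "C", 3.5),
            ])

    def test_constraint_must_be_an_edge(self):
        with pytest.raises(DataError, match="does not correspond"):
            ThermoGraph(ligands=["A", "B", "C"],
                        edges=[("A", "B", 1.0, 1.0, 0.0)],
                        constraints=[("A", "C", 2.0)])


class TestCycles:
    def test_tree_has_no_cycles(self):
        tg, _ = synthgen.gen_graph(5, "star", np.zeros(5), 0.3, 2)
        assert enumerate_cycles(tg) == []

    def test_consistent_triangle_closes(self):
        tg = ThermoGraph(
            ligands=["A", "B", "C"],
            edges=[("A", "B", 1.0, 1.0, 0.0), ("B", "C", 2.0, 1.0, 0.0),
                   ("A", "C", 3.0, 1.0, 0.0)],
        )
        cycles = enumerate_cycles(tg)
        assert len(cycles) == 1
        assert cycles[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_square_perturbation_telescopes(self):
        tg = ThermoGraph(
            ligands=["A", "B", "C", "D"],
            edges=[("A", "B", 1.0, 1.0, 0.0), ("B", "C", 1.0, 1.0, 0.0),
                   ("C", "D", 1.0, 1.0, 0.0), ("D", "A", -3.0 + 0.7, 1.0,
                                               0.0)],
        )
        cycles = enumerate_cycles(tg)
        assert len(cycles) == 1
        assert abs(cycles[0][1]) == pytest.approx(0.7, abs=1e-12)


class TestOutliers:
    def test_identical_trials_unflagged(self):
        assert flag_outlier_trials({"s": [1.0, 1.0, 1.0, 1.0]}) == {"s": []}

    def test_mad_zscore_flags_outlier(self):
        # median 1.0, MAD 0.1 -> z(9.0) = 0.6745*8/0.1 = 53.96
        flags = flag_outlier_trials({"s": [1.0, 1.1, 0.9, 1.0, 9.0]})
        assert flags == {"s": [4]}

    def test_two_trials_use_loo_only(self):
        flags = flag_outlier_trials({"s": [1.0, 3.0]})
        assert flags == {"s": []}


class TestReports:
    def test_round_trip_and_residual_balance(self, tmp_path):
        tg, _ = synthgen.gen_graph(6, "dense", np.arange(6.0), 0.4, 11)
        sol = solve_network(tg)
        rep = network.write_graph_report(sol, tg, tmp_path / "graph.json")
        loaded = json.loads((tmp_path / "graph.json").read_text())
        assert loaded == rep
        assert "constraints" not in rep  # empty section omitted
        # stationarity: k-weighted residuals balance at every node
        bal = {l: 0.0 for l in tg.ligands}
        for row in rep["edges"]:
            bal[row["b"]] += row["k"] * row["residual"]
            bal[row["a"]] -= row["k"] * row["residual"]
        for l in tg.ligands:
            if l != sol.ref_ligand:
                assert abs(bal[l]) < 1e-8
        # byte-identical rewrite
        network.write_graph_report(sol, tg, tmp_path / "g2.json")
        assert ((tmp_path / "graph.json").read_bytes()
                == (tmp_path / "g2.json").read_bytes())

    def test_load_edge_results(self, tmp_path):
        from fenet.edge import EdgeResult, write_edge_json
        for name, dd in (("a~b", 1.0), ("b~c", 0.5)):
            res = EdgeResult(name=name, ddG=dd, trial_sem=0.1, g=dd, k=2.0,
                             tabulated=[], dG_ref=0.0, dG_target=dd,
                             trial_dGs={}, stage_sems={})
            write_edge_json(res, tmp_path / f"{name}.edge.json")
        tg = network.load_edge_results(tmp_path)
        assert tg.ligands == ["a", "b", "c"]
        assert len(tg.edges) == 2
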