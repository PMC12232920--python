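import numpy as np
import pytest
from scipy.optimize import minimize

from fenet import edge, synthgen
from fenet.edge import (
    _ddG_coefficients,
    _free_parameterization,
    analyze_edge,
    edge_objective,
    fit_surrogate,
    read_edge_xml,
    tabulate_objective,
)
from fenet.exceptions import DataError


@pytest.fixture(scope="module")
def small_edge(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("edge")
    out = synthgen.gen_edge(
        synthgen.GaussianAlchemy(kappa=2.0, d=1.5, eps=0.2),
        synthgen.GaussianAlchemy(kappa=2.0, d=1.5, eps=1.5),
        np.array([0.0, 0.5, 1.0]), 120, 2, 3, tmp,
    )
    return read_edge_xml(out["xml"]), out


class TestReadEdgeXml:
    def test_minimal_edge_parses(self, small_edge):
        ed, _ = small_edge
        assert set(ed.environments) == {"ref", "target"}
        trials = list(ed.iter_trials())
        assert len(trials) == 4  # 2 envs x 1 stage x 2 trials

    def test_missing_lambda_one_rejected(self, tmp_path, small_edge):
        _, out = small_edge
        xml = tmp_path / "bad.xml"
        text = open(out["xml"]).read().replace(
            '<state lambda="1.00000000"/>', "", 1
        )
        xml.write_text(text)
        with pytest.raises(DataError, match="lambda=0 and lambda=1"):
            read_edge_xml(xml)

    def test_duplicate_lambda_rejected(self, tmp_path, small_edge):
        _, out = small_edge
        xml = tmp_path / "bad.xml"
        text = open(out["xml"]).read().replace(
            '<state lambda="0.50000000"/>',
            '<state lambda="0.50000000"/><state lambda="0.50000000"/>', 1,
        )
        xml.write_text(text)
        with pytest.raises(DataError, match="duplicate lambda"):
            read_edge_xml(xml)

    def test_missing_efep_file_named(self, tmp_path):
        from lxml import etree
        tdir = tmp_path / "t1"
        tdir.mkdir()
        root = etree.Element("edge", name="a~b")
        for env in ("ref", "target"):
            e = etree.SubElement(root, "env", name=env)
            s = etree.SubElement(e, "stage", name="s")
            t = etree.SubElement(s, "trial", name="t1", dir="t1")
            etree.SubElement(t, "state", **{"lambda": "0.0"})
            etree.SubElement(t, "state", **{"lambda": "1.0"})
        p = tmp_path / "e.xml"
        etree.ElementTree(root).write(str(p))
        with pytest.raises(DataError, match="efep"):
            read_edge_xml(p)

    def test_row_count_mismatch(self, small_edge, tmp_path):
        _, out = small_edge
        import shutil
        from pathlib import Path
        src = Path(out["xml"]).parent
        dst = tmp_path / "copy"
        shutil.copytree(src, dst)
        f = dst / "ref" / "unified" / "t1" / "efep_0.00000000_1.00000000.dat"
        lines = f.read_text().splitlines()
        f.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(DataError, match="row count"):
            read_edge_xml(dst / "edge.xml")


class TestEdgeObjective:
    def test_single_trial_equals_mbar(self, small_edge):
        ed, _ = small_edge
        tr = ed.environments["ref"]["unified"][0]
        from fenet.mbar_core import mbar_objective
        blocks, n = edge._blocks(ed)
        G = np.zeros(n)
        v_edge, _ = edge_objective(ed, G)
        # sum of per-trial objectives / n_trials (2 per stage here)
        v_sum = sum(
            0.5 * mbar_objective(t.table, np.zeros(t.n_states))[0]
            for _, _, t in ed.iter_trials()
        )
        assert v_edge == pytest.approx(v_sum, abs=1e-12)

    def test_gradient_finite_difference(self, small_edge):
        ed, _ = small_edge
        _, n = edge._blocks(ed)
        rng = np.random.default_rng(0)
        G = rng.normal(0, 0.3, n)
        v, grad = edge_objective(ed, G)
        h = 1e-5
        for i in range(0, n, 3):
            e = np.zeros(n)
            e[i] = h
            fd = (edge_objective(ed, G + e)[0]
                  - edge_objective(ed, G - e)[0]) / (2 * h)
            assert abs(fd - grad[i]) < 1e-6

    def test_trial_gauge_invariance(self, small_edge):
        # shifting one trial's block changes neither objective nor ddG
        ed, _ = small_edge
        blocks, n = edge._blocks(ed)
        rng = np.random.default_rng(1)
        G = rng.normal(0, 0.3, n)
        v0, _ = edge_objective(ed, G)
        a = _ddG_coefficients(ed)
        G2 = G.copy()
        G2[blocks[0]["slice"]] += 4.2
        v1, _ = edge_objective(ed, G2)
        assert v1 == pytest.approx(v0, abs=1e-9)
        assert a @ G2 == pytest.approx(a @ G, abs=1e-9)


class TestEdgeFreeEnergy:
    def test_recovers_analytic_ddG(self, tmp_path):
        out = synthgen.gen_edge(
            synthgen.GaussianAlchemy(kappa=2.0, d=2.0, eps=0.0),
            synthgen.GaussianAlchemy(kappa=2.0, d=2.0, eps=1.7),
            np.linspace(0, 1, 6), 250, 4, 21, tmp_path,
        )
        res = analyze_edge(read_edge_xml(out["xml"]), diagnostics=False)
        assert abs(res.ddG - 1.7) < 3.0 * res.trial_sem

    def test_identical_environments_give_zero(self, tmp_path):
        alch = synthgen.GaussianAlchemy(kappa=2.0, d=1.0, eps=0.8)
        out = synthgen.gen_edge(alch, alch, np.linspace(0, 1, 4), 150, 2,
                                5, tmp_path)
        res = analyze_edge(read_edge_xml(out["xml"]), tabulate=False,
                           diagnostics=False)
        # same eps: analytic ddG = 0 (estimates still carry sampling noise)
        assert abs(res.ddG) < max(3.0 * res.trial_sem, 0.2)

    def test_trial_sem_formula(self):
        # two trials at 1.0 and 3.0: sigma = sqrt(2), sem = 1.0
        vals = np.array([1.0, 3.0])
        sem = vals.std(ddof=1) / np.sqrt(2)
        assert sem == pytest.approx(1.0)

    def test_antisymmetry_under_environment_swap(self, small_edge):
        ed, _ = small_edge
        res = analyze_edge(ed, diagnostics=False)
        swapped = edge.EdgeData(
            name=ed.name, temperature=ed.temperature,
            environments={"ref": ed.environments["target"],
                          "target": ed.environments["ref"]},
        )
        res2 = analyze_edge(swapped, diagnostics=False)
        assert res.ddG + res2.ddG == pytest.approx(0.0, abs=1e-9)
        assert res.k == pytest.approx(res2.k, abs=1e-9)


class TestTabulation:
    def test_center_equals_unconstrained_minimum(self, small_edge):
        ed, _ = small_edge
        res = analyze_edge(ed, diagnostics=False)
        xs = [x for x, _ in res.tabulated]
        fs = [f for _, f in res.tabulated]
        center = fs[xs.index(res.ddG)]
        # unconstrained minimum: sum of per-trial minima / n_trials
        from fenet.mbar_core import mbar_objective, solve_mbar
        v_min = sum(
            0.5 * mbar_objective(t.table, solve_mbar(t.table).G)[0]
            for _, _, t in ed.iter_trials()
        )
        assert center == pytest.approx(v_min, abs=1e-9)
        assert all(f >= center - 1e-12 for f in fs)

    def test_matches_penalty_oracle(self, small_edge):
        ed, _ = small_edge
        res = analyze_edge(ed, diagnostics=False)
        blocks, n, free_idx = _free_parameterization(ed)
        a = _ddG_coefficients(ed)
        for x_target in (res.ddG - 1.0, res.ddG + 1.0):
            def pen(z):
                G = np.zeros(n)
                G[free_idx] = z
                v, gr = edge_objective(ed, G)
                c = a @ G - x_target
                return v + 0.5e6 * c * c, gr[free_idx] + 1e6 * c * a[free_idx]

            r = minimize(pen, np.zeros(free_idx.size), jac=True,
                         method="L-BFGS-B",
                         options=dict(maxiter=5000, ftol=1e-15, gtol=1e-12))
            G = np.zeros(n)
            G[free_idx] = r.x
            v_pen, _ = edge_objective(ed, G)
            mine = [f for x, f in res.tabulated
                    if abs(x - x_target) < 1e-9][0]
            assert abs(v_pen - mine) < 1e-5


class TestSurrogate:
    def test_exact_quadratic_recovered(self):
        pts = [(2.0 + d, 3.0 + 0.5 * 0.8 * d * d) for d in (-2, -1, 0, 1, 2)]
        g, k = fit_surrogate(pts)
        assert g == pytest.approx(2.0, abs=1e-12)
        assert k == pytest.approx(0.8, abs=1e-12)

    def test_flat_points_rejected(self):
        pts = [(2.0 + d, 3.0) for d in (-2, -1, 0, 1, 2)]
        with pytest.raises(DataError):
            fit_surrogate(pts)

    def test_quartic_perturbation(self):
        pts = [(d, 0.5 * d * d + 0.01 * d**4) for d in (-2, -1, 0, 1, 2)]
        g, k = fit_surrogate(pts)
        assert 1.0 <= k <= 1.2

    def test_center_not_minimum_rejected(self):
        pts = [(-2, 0.5), (-1, 0.2), (0, 0.3), (1, 0.2), (2, 0.5)]
        with pytest.raises(DataError, match="minimum"):
            fit_surrogate(pts)


class TestDiagnostics:
    def test_identical_adjacent_states(self):
        # d = 0, eps = 0: all states identical
        from fenet.constants import beta_from_temperature
        from fenet.mbar_core import EnergyTable
        beta = beta_from_temperature(298.0)
        u = np.zeros((2, 20))
        tab = EnergyTable.from_state_blocks(u, [10, 10], beta)
        tr = edge.TrialData(name="t", lambdas=np.array([0.0, 1.0]),
                            table=tab)
        ed = edge.EdgeData(name="x~y", temperature=298.0,
                           environments={"ref": {"s": [tr]},
                                         "target": {"s": [tr]}})
        diag = edge.edge_diagnostics(ed)
        d = diag["ref/s/t"][0]
        assert d["exchange_acceptance"] == pytest.approx(1.0)
        assert d["dU_fwd_var"] == 0.0
        assert d["overlap_ij"] == pytest.approx(0.5)

    def test_displaced_gaussians_acceptance(self, tmp_path):
        # exchange acceptance vs a direct two-sided Monte-Carlo estimate
        kT = 0.0019872041 * 298.0
        alch = synthgen.GaussianAlchemy(kappa=1.0, d=4.0)
        out = synthgen.gen_edge(alch, alch, np.linspace(0, 1, 11), 800, 1,
                                9, tmp_path)
        ed = read_edge_xml(out["xml"])
        diag = edge.edge_diagnostics(ed)
        rng = np.random.default_rng(123)
        for pair in diag["ref/unified/t1"][:3]:
            li, lj = pair["lam_i"], pair["lam_j"]
            xi = alch.sample(li, 40000, kT, rng)
            xj = alch.sample(lj, 40000, kT, rng)
            dd = (alch.energy(xi, lj) - alch.energy(xi, li)
                  + alch.energy(xj, li) - alch.energy(xj, lj)) / kT
            acc_mc = np.mean(np.minimum(1.0, np.exp(-dd)))
            assert abs(pair["exchange_acceptance"] - acc_mc) < 0.05


class TestSerialization:
    def test_json_round_trip(self, small_edge, tmp_path):
        ed, _ = small_edge
        res = analyze_edge(ed)
        p = tmp_path / "e.edge.json"
        edge.write_edge_json(res, p)
        res2 = edge.read_edge_json(p)
        assert res2.to_dict() == res.to_dict()
        # write-read-write is byte-identical
        p2 = tmp_path / "e2.edge.json"
        edge.write_edge_json(res2, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_report_text(self, small_edge):
        ed, _ = small_edge
        res = analyze_edge(ed, diagnostics=False)
        txt = edge.edge_report_text(res)
        assert "ddG" in txt and "surrogate" in txt
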