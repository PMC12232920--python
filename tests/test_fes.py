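import warnings

import numpy as np
import pytest

from fenet import fes, synthgen
from fenet.exceptions import DataError


@pytest.fixture
def quadratic_dataset(tmp_path):
    land = synthgen.HarmonicLandscape(form="quadratic", a=2.0,
                                      temperature=300.0)
    out = synthgen.gen_umbrella(
        land, [(c, 20.0) for c in np.linspace(-1.5, 1.5, 11)],
        1500, 7, tmp_path / "umb",
    )
    return out, land


class TestMetafile:
    def test_single_line(self, tmp_path):
        (tmp_path / "win.dat").write_text("1.0 0.5\n")
        mf = tmp_path / "meta"
        mf.write_text("0 win.dat 1.50 100.0 300.0\n")
        (w,) = fes.read_metafile(mf)
        assert w.ndim == 1
        assert w.center[0] == 1.5
        assert w.fc[0] == 100.0
        assert w.temperature == 300.0
        assert w.ham_idx == 0

    def test_two_dimensional_line(self, tmp_path):
        (tmp_path / "win.dat").write_text("1.0 0.5 0.7\n")
        mf = tmp_path / "meta"
        mf.write_text("0 win.dat 1.0 50.0 2.0 60.0 300.0\n")
        (w,) = fes.read_metafile(mf)
        assert w.ndim == 2
        assert w.fc.tolist() == [50.0, 60.0]

    def test_inconsistent_dimensionality(self, tmp_path):
        (tmp_path / "w.dat").write_text("1.0 0.5 0.7\n")
        mf = tmp_path / "meta"
        mf.write_text("0 w.dat 1.0 50.0 300.0\n"
                      "0 w.dat 1.0 50.0 2.0 60.0 300.0\n")
        with pytest.raises(DataError, match="line 2"):
            fes.read_metafile(mf)

    def test_missing_dumpave(self, tmp_path):
        mf = tmp_path / "meta"
        mf.write_text("0 nope.dat 1.0 50.0 300.0\n")
        with pytest.raises(DataError, match="nope.dat"):
            fes.read_metafile(mf)

    def test_wham_dialect(self, tmp_path):
        (tmp_path / "w.dat").write_text("1.0 0.5\n")
        mf = tmp_path / "meta"
        mf.write_text("w.dat 1.5 100.0 310.0\n")
        (w,) = fes.read_metafile(mf, dialect="wham")
        assert w.center[0] == 1.5 and w.temperature == 310.0
        mf.write_text("w.dat 1.5 100.0\n")
        (w,) = fes.read_metafile(mf, dialect="wham")
        assert w.temperature == 300.0  # default when T column absent


class TestDumpave:
    def test_basic(self, tmp_path):
        p = tmp_path / "d.dat"
        p.write_text("1.0 0.5\n2.0 0.6\n3.0 0.4\n")
        t, x = fes.read_dumpave(p, 1)
        assert t.tolist() == [1.0, 2.0, 3.0]
        assert x[:, 0].tolist() == [0.5, 0.6, 0.4]

    def test_short_row(self, tmp_path):
        p = tmp_path / "d.dat"
        p.write_text("1.0\n")
        with pytest.raises(DataError, match="row 1"):
            fes.read_dumpave(p, 1)

    def test_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "d.dat"
        p.write_text("1.0 0.5 9.9 8.8\n2.0 0.6 9.9 8.8\n")
        t, x = fes.read_dumpave(p, 1)
        assert x.shape == (2, 1)


class TestBiasEnergy:
    def test_conventions(self):
        w = fes.UmbrellaWindow("x", [1.0], [100.0], 300.0)
        assert fes.bias_energy(w, [[1.0]]) == 0.0
        assert fes.bias_energy(w, [[1.1]]) == pytest.approx(1.0)
        assert fes.bias_energy(w, [[1.1]], half_k=True) == pytest.approx(0.5)

    def test_periodic_minimum_image(self):
        w = fes.UmbrellaWindow("x", [170.0], [0.1], 300.0)
        e = fes.bias_energy(w, [[-175.0]], periods=[360.0])
        # displacement is 15 degrees through the boundary, not 345
        assert e == pytest.approx(0.1 * 15.0**2)


class TestComputeFES:
    def test_flat_sampler_gives_flat_pmf(self, tmp_path):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.0, 1.0, 4000)
        p = tmp_path / "d.dat"
        np.savetxt(p, np.column_stack([np.arange(1, 4001.0), x]))
        w = fes.UmbrellaWindow(str(p), [0.5], [0.0], 300.0)
        spec = fes.GridSpec(mins=[0.0], widths=[0.1], nbins=[10])
        grid = fes.compute_fes([w], spec, boot=8, seed=2)
        for b in grid.bins.values():
            assert b.F <= 3.0 * max(b.dF, 0.02)

    def test_curvature_recovery_and_conservation(self, quadratic_dataset):
        out, land = quadratic_dataset
        windows = fes.read_metafile(out["metafile"])
        spec = fes.GridSpec(mins=[-2.0], widths=[0.1], nbins=[40])
        grid = fes.compute_fes(windows, spec)
        xs, Fs = [], []
        total = 0
        for key, b in grid.bins.items():
            total += b.n
            x = spec.mins[0] + (key[0] + 0.5) * spec.widths[0]
            if abs(x) < 1.0 and b.n >= 50:
                xs.append(x)
                Fs.append(b.F)
        curv = 2.0 * np.polyfit(xs, Fs, 2)[0]
        assert abs(curv - land.a) / land.a < 0.10
        assert total == 11 * 1500  # every retained sample lands in a bin
        assert min(b.F for b in grid.bins.values()) == 0.0

    def test_window_split_invariance(self, tmp_path):
        land = synthgen.HarmonicLandscape(form="quadratic", a=2.0)
        out = synthgen.gen_umbrella(land, [(0.0, 5.0)], 2000, 3,
                                    tmp_path / "one")
        (w,) = fes.read_metafile(out["metafile"])
        spec = fes.GridSpec(mins=[-1.5], widths=[0.15], nbins=[20])
        full = fes.compute_fes([w], spec, boot=8, seed=1)
        # split the same samples into two identical-bias windows
        t, x = fes.read_dumpave(w.dumpave_path, 1)
        pa, pb = tmp_path / "a.dat", tmp_path / "b.dat"
        np.savetxt(pa, np.column_stack([t[:1000], x[:1000]]))
        np.savetxt(pb, np.column_stack([t[1000:], x[1000:]]))
        ws = [fes.UmbrellaWindow(str(pa), [0.0], [5.0], 300.0),
              fes.UmbrellaWindow(str(pb), [0.0], [5.0], 300.0)]
        split = fes.compute_fes(ws, spec, boot=8, seed=1)
        for key in full.bins:
            tol = 3.0 * max(full.bins[key].dF, 0.02)
            assert abs(full.bins[key].F - split.bins[key].F) <= tol

    def test_mixed_temperature_rejected(self, tmp_path):
        p = tmp_path / "d.dat"
        np.savetxt(p, np.column_stack([np.arange(25.0), np.zeros(25)]))
        ws = [fes.UmbrellaWindow(str(p), [0.0], [1.0], 300.0),
              fes.UmbrellaWindow(str(p), [0.0], [1.0], 310.0)]
        spec = fes.GridSpec(mins=[-1.0], widths=[0.5], nbins=[4])
        with pytest.raises(DataError, match="temperature"):
            fes.compute_fes(ws, spec)


class TestXmlRoundTrip:
    def test_round_trip_bitwise(self, quadratic_dataset, tmp_path):
        out, _ = quadratic_dataset
        windows = fes.read_metafile(out["metafile"])
        spec = fes.GridSpec(mins=[-1.6], widths=[0.1], nbins=[32])
        grid = fes.compute_fes(windows, spec, boot=8, seed=9)
        path = tmp_path / "f.xml"
        fes.write_fes_xml(grid, path)
        assert fes.read_fes_xml(path) == grid

    def test_single_bin_grid(self, tmp_path):
        spec = fes.GridSpec(mins=[0.0], widths=[1.0], nbins=[1])
        g = fes.FESGrid(spec=spec,
                        bins={(0,): fes.BinValue(F=0.0, dF=0.1, n=3, S=0.9)})
        fes.write_fes_xml(g, tmp_path / "f.xml")
        assert fes.read_fes_xml(tmp_path / "f.xml") == g

    def test_empty_grid_refused(self, tmp_path):
        spec = fes.GridSpec(mins=[0.0], widths=[1.0], nbins=[1])
        with pytest.raises(DataError, match="no occupied bins"):
            fes.write_fes_xml(fes.FESGrid(spec=spec, bins={}),
                              tmp_path / "f.xml")

    def test_unknown_attribute_warns(self, tmp_path):
        p = tmp_path / "f.xml"
        p.write_text(
            '<ndfes dims="1"><axis min="0" width="1" nbins="1" foo="x"/>'
            '<bin idx="0" F="0" dF="0" n="1" S="1"/></ndfes>'
        )
        with pytest.warns(UserWarning, match="foo"):
            g = fes.read_fes_xml(p)
        assert (0,) in g.bins


class TestAggregation:
    def test_average_identical_grids(self, tmp_path):
        spec = fes.GridSpec(mins=[0.0], widths=[1.0], nbins=[2])
        g = fes.FESGrid(spec=spec,
                        bins={(0,): fes.BinValue(F=1.0, dF=0.1, n=3, S=1.0)})
        avg = fes.average_fes([g, g])
        assert avg.bins[(0,)].F == 1.0
        assert avg.bins[(0,)].dF == 0.0
        assert avg.bins[(0,)].n == 6

    def test_average_stderr(self):
        spec = fes.GridSpec(mins=[0.0], widths=[1.0], nbins=[1])
        g1 = fes.FESGrid(spec=spec,
                         bins={(0,): fes.BinValue(F=0.0, dF=0, n=1, S=1)})
        g2 = fes.FESGrid(spec=spec,
                         bins={(0,): fes.BinValue(F=2.0, dF=0, n=1, S=1)})
        avg = fes.average_fes([g1, g2])
        # sample sigma of {0, 2} is sqrt(2); stderr = sqrt(2)/sqrt(2) = 1
        assert avg.bins[(0,)].F == 1.0
        assert avg.bins[(0,)].dF == pytest.approx(1.0)

    def test_combine_rejects_mixed_dimensionality(self, tmp_path):
        (tmp_path / "w.dat").write_text("1.0 0.5\n")
        (tmp_path / "w2.dat").write_text("1.0 0.5 0.6\n")
        m1 = tmp_path / "m1"
        m1.write_text("0 w.dat 0.0 1.0 300.0\n")
        m2 = tmp_path / "m2"
        m2.write_text("0 w2.dat 0.0 1.0 0.5 1.0 300.0\n")
        with pytest.raises(DataError):
            fes.combine_windows([m1, m2])

    def test_synth_outputs_parse_without_warnings(self, quadratic_dataset):
        out, _ = quadratic_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            windows = fes.read_metafile(out["metafile"])
            for w in windows:
                fes.read_dumpave(w.dumpave_path, 1)
        assert len(windows) == 11
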