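"""Config round trips, fixtures, the experiment runner, text I/O and CLI."""

import numpy as np
import pytest
from click.testing import CliRunner

import twoscale
from twoscale import canonical_config, list_experiments, load_config, make_fixture, save_config
from twoscale.cli import main as cli_main
from twoscale.workbench_io import (
    read_field,
    read_particles,
    run_experiment,
    write_field,
    write_particles,
    write_spectrum,
)


class TestConfigs:
    def test_roundtrip_through_file(self, tmp_path):
        cfg = canonical_config("continuum_spots").replace(seed=99, t_end=12.5)
        path = tmp_path / "exp.cfg"
        save_config(cfg, path)
        back = load_config(path)
        assert back.to_dict() == cfg.to_dict()  # name stored in the file wins
        assert back.params == cfg.params

    def test_all_canonical_configs_validate(self):
        names = list_experiments()
        assert {
            "particles_spots",
            "particles_labyrinth",
            "particles_homogeneous",
            "continuum_spots",
            "continuum_labyrinth",
            "dispersion_curves",
            "phase_diagram",
            "ring_1d",
        } <= set(names)
        for name in names:
            cfg = canonical_config(name)
            res = run_experiment(cfg, dry_run=True)
            assert "validated config" in res.log[-1]

    def test_include_override(self, tmp_path):
        (tmp_path / "base.cfg").write_text("D0 = 1e-4\na = 1\nb = 1e-4\nc = 1e-4\n"
                                           "R_s = 0.05\nR_l = 0.1\nL = 1\nN = 100\n")
        (tmp_path / "child.cfg").write_text("include = base.cfg\nb = 9e-4\nt_end = 1\n")
        cfg = load_config(tmp_path / "child.cfg")
        assert cfg.params.b == 9e-4 and cfg.params.c == 1e-4
        assert cfg.name == "child"

    def test_guard_violations_surface_at_load(self, tmp_path):
        (tmp_path / "bad.cfg").write_text(
            "simulator = continuum\nD0 = 1e-4\na = 1\nb = 1e-4\nc = 1e-4\n"
            "R_s = 0.05\nR_l = 0.1\nL = 1\nrho0 = 1e4\ngrid = 64\ndt = 10\nt_end = 1\n"
        )
        with pytest.raises(ValueError, match="stability bound"):
            load_config(tmp_path / "bad.cfg")


class TestFixtures:
    def test_pulse1d_mass_and_shape(self):
        f = make_fixture("pulse1d", R_l=0.75, L=6.0, dx=0.01, height=1.0)
        assert f.mass == pytest.approx(1.5)
        assert f.values.max() == 1.0
        support = (f.values > 0).sum() * f.dx
        assert support == pytest.approx(1.5)  # length 2 * R_l

    def test_uniform_particles_reproducible(self):
        a = make_fixture("uniform_particles", N=100, L=2.0, seed=7)
        b = make_fixture("uniform_particles", N=100, L=2.0, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert np.all((a.positions >= 0) & (a.positions < 2.0))

    def test_annulus_radius(self):
        st = make_fixture("annulus", n=500, r0=0.2, L=1.0, seed=1)
        r = np.linalg.norm(st.positions - 0.5, axis=1)
        np.testing.assert_allclose(r, 0.2, atol=1e-9)

    def test_unknown_fixture_lists_names(self):
        with pytest.raises(ValueError, match="pulse1d"):
            make_fixture("nonsense")


class TestRunner:
    def test_particle_experiment_byte_reproducible(self, spot_params, tmp_path):
        cfg = canonical_config("particles_spots").replace(
            params=spot_params.replace(N=200), t_end=5.0, snapshot_every=None,
            analyses=("structure_function",), seed=5,
        )
        r1 = run_experiment(cfg)
        r2 = run_experiment(cfg)
        np.testing.assert_array_equal(
            r1.snapshots[-1].positions, r2.snapshots[-1].positions
        )
        assert r1.metrics["k_c"] == r2.metrics["k_c"]

    def test_stability_experiment_metrics(self):
        res = run_experiment(canonical_config("dispersion_curves"))
        assert res.metrics["type"] == "A"
        assert res.metrics["k_c"] == pytest.approx(49.5, abs=0.5)

    def test_outputs_written(self, tmp_path, spot_params):
        cfg = canonical_config("particles_spots").replace(
            params=spot_params.replace(N=150), t_end=3.0, snapshot_every=None,
            analyses=("structure_function",),
        )
        run_experiment(cfg, out_dir=tmp_path)
        assert (tmp_path / "particles_spots_final.txt").exists()
        assert (tmp_path / "particles_spots_spectrum.txt").exists()
        assert (tmp_path / "particles_spots_metrics.txt").exists()
        # header records the seed
        head = (tmp_path / "particles_spots_final.txt").read_text().splitlines()[:8]
        assert any("seed" in line for line in head)


class TestTextIO:
    def test_particles_roundtrip(self, tmp_path):
        st = make_fixture("uniform_particles", N=50, L=1.5, seed=3)
        write_particles(tmp_path / "p.txt", st)
        back = read_particles(tmp_path / "p.txt")
        np.testing.assert_allclose(back.positions, st.positions)
        assert back.L == 1.5

    def test_field_roundtrip_2d_and_1d(self, tmp_path, rng):
        from twoscale import DensityField

        f2 = DensityField(rng.uniform(0, 2, (16, 16)), L=1.0, t=3.5)
        write_field(tmp_path / "f2.txt", f2)
        b2 = read_field(tmp_path / "f2.txt")
        np.testing.assert_allclose(b2.values, f2.values)
        assert b2.t == 3.5

        f1 = make_fixture("pulse1d", R_l=0.75)
        write_field(tmp_path / "f1.txt", f1)
        b1 = read_field(tmp_path / "f1.txt")
        assert b1.dim == 1
        np.testing.assert_allclose(b1.values, f1.values)

    def test_spectrum_export(self, tmp_path):
        st = make_fixture("lattice", n_side=6, L=1.0)
        from twoscale import structure_function_particles

        spec = structure_function_particles(st)
        write_spectrum(tmp_path / "s.txt", spec)
        data = np.loadtxt(tmp_path / "s.txt", comments="#")
        np.testing.assert_allclose(data[:, 0], spec.k)


class TestCLI:
    def test_experiment_list_and_dry_run(self):
        runner = CliRunner()
        out = runner.invoke(cli_main, ["experiment", "--list"])
        assert out.exit_code == 0 and "ring_1d" in out.output
        out = runner.invoke(cli_main, ["experiment", "continuum_spots", "--dry-run"])
        assert out.exit_code == 0 and "validated config" in out.output

    def test_analyze_snapshot(self, tmp_path):
        st = make_fixture("lattice", n_side=8, L=1.0)
        write_particles(tmp_path / "snap.txt", st)
        runner = CliRunner()
        out = runner.invoke(cli_main, ["analyze", "--in", str(tmp_path / "snap.txt")])
        assert out.exit_code == 0
        assert "k_c" in out.output

    def test_version_importable(self):
        assert twoscale.__version__
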