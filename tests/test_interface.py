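"""I/O, configuration, pipeline and CLI tests."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import porepmf as pp
from porepmf import io as pio
from porepmf.cli import main as cli_main
from porepmf.config import RunConfig
from porepmf.pipeline import run_pipeline

TINY_CONFIG = {
    "landscape": {"barrier_height_kJ_per_mol": 6.0},
    "windows": {"center_min_A": 20.0, "center_max_A": 24.0,
                "spacing_A": 0.5, "duration_ps": 200.0},
    "wham": {"n_bins": 40, "tolerance": 1e-6, "bootstraps": 10},
    "barrier": {"barrier_range_A": [21.0, 23.0],
                "reference_range_A": [20.0, 20.8]},
    "coordination": {"snapshot_stride": 20, "cutoff_A": 3.0,
                     "n_hydroxyl_near_collar": 1},
    "flux": {"rate_per_min": 0.12, "noise_sd_pct": 2.0, "n_replicates": 2},
    "seed": 7,
}


class TestWindowsIO:
    def test_roundtrip_preserves_samples_exactly(self, tmp_path):
        spec = pp.LandscapeSpec()
        pot = pp.build_potential(spec)
        specs = pp.make_window_specs([20.0, 20.5], duration=50.0, base_seed=1)
        trajs = [pp.simulate_window(pot, w) for w in specs]
        pio.write_windows(tmp_path, specs, trajs, temperature=303.15)
        windows, manifest = pio.read_windows(tmp_path)
        for w, traj, spec_w in zip(windows, trajs, specs):
            assert np.allclose(w.samples_z, traj.z, atol=1e-9)
            assert np.allclose(w.samples_aux, traj.n, atol=1e-9)
            assert w.force_constant == spec_w.force_constant
        assert manifest["windows"][0]["force_constant_kJ_per_mol_nm2"] == 3000.0

    def test_pmf_tsv_roundtrip(self, tmp_path):
        z = np.linspace(16.5, 36.5, 40)
        prof = pp.PMFProfile(bin_centers=z, free_energy=np.sin(z),
                             sem=np.full(40, 0.1))
        path = tmp_path / "pmf.tsv"
        pio.write_pmf_tsv(path, prof)
        back = pio.read_pmf_tsv(path)
        assert np.allclose(back.free_energy, prof.free_energy, atol=1e-9)
        assert np.allclose(back.sem, 0.1)


class TestXvg:
    def test_nm_positions_converted_to_angstrom(self, tmp_path):
        p = tmp_path / "pull.xvg"
        p.write_text('# gmx pull output\n@ xaxis label "Time (ps)"\n'
                     '@ yaxis label "Position (nm)"\n0 1.65\n10 1.70\n')
        t, z = pio.read_xvg(p)
        assert z[0] == pytest.approx(16.5)
        assert z[1] == pytest.approx(17.0)

    def test_angstrom_label_honored(self, tmp_path):
        p = tmp_path / "pull.xvg"
        p.write_text('@ yaxis label "Position (A)"\n0 16.5\n')
        _, z = pio.read_xvg(p)
        assert z[0] == pytest.approx(16.5)

    def test_comment_only_file_rejected(self, tmp_path):
        p = tmp_path / "empty.xvg"
        p.write_text("# nothing\n@ legend\n")
        with pytest.raises(ValueError, match="no numeric rows"):
            pio.read_xvg(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.xvg"
        p.write_text("0 1.65\nnot_a_number here\n")
        with pytest.raises(ValueError, match="bad.xvg:2"):
            pio.read_xvg(p)


class TestConfig:
    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown keys"):
            RunConfig.from_dict({"landscape": {"barrier_heigh": 6.0}})
        with pytest.raises(ValueError, match="unknown keys"):
            RunConfig.from_dict({"unexpected_section": {}})

    def test_force_constant_converted_at_parse_time(self):
        cfg = RunConfig.from_dict(
            {"windows": {"force_constant_kJ_per_mol_nm2": 3000.0,
                         "center_min_A": 20.0, "center_max_A": 21.0,
                         "spacing_A": 0.5}})
        specs = cfg.window_specs()
        assert all(w.force_constant == 30.0 for w in specs)
        assert len(specs) == 3

    def test_yaml_roundtrip_and_stable_digest(self, tmp_path):
        p = tmp_path / "config.yaml"
        p.write_text(yaml.safe_dump(TINY_CONFIG))
        c1 = RunConfig.from_yaml(p)
        c2 = RunConfig.from_yaml(p)
        assert c1.digest() == c2.digest()
        assert c1.landscape_spec().barrier_height == 6.0


class TestPipeline:
    def test_smoke_run_and_checksum_gated_skip(self, tmp_path):
        cfg = RunConfig.from_dict(TINY_CONFIG)
        out = tmp_path / "run"
        m1 = run_pipeline(cfg, out)
        assert set(m1["stages"]) == {"simulate", "wham", "coordination",
                                     "flux"}
        assert not any(s.get("skipped") for s in m1["stages"].values())
        assert (out / "pmf.tsv").exists()
        report = json.loads((out / "wham_report.json").read_text())
        assert report["tolerance"] == 1e-6
        assert report["bootstraps"] == 10
        m2 = run_pipeline(cfg, out)
        assert all(s.get("skipped") for s in m2["stages"].values())
        for name in m1["stages"]:
            assert m1["stages"][name]["outputs"] == \
                m2["stages"][name]["outputs"]

    def test_config_change_invalidates_downstream(self, tmp_path):
        cfg = RunConfig.from_dict(TINY_CONFIG)
        out = tmp_path / "run"
        run_pipeline(cfg, out)
        cfg2 = RunConfig.from_dict({**TINY_CONFIG,
                                    "wham": {"n_bins": 30, "tolerance": 1e-6,
                                             "bootstraps": 10}})
        m = run_pipeline(cfg2, out)
        assert m["stages"]["simulate"].get("skipped")
        assert not m["stages"]["wham"].get("skipped")


class TestCli:
    def test_simulate_is_byte_identical_across_invocations(self, tmp_path):
        cfgp = tmp_path / "c.yaml"
        cfgp.write_text(yaml.safe_dump(TINY_CONFIG))
        runner = CliRunner()
        for d in ("r1", "r2"):
            res = runner.invoke(cli_main, ["simulate", "--config", str(cfgp),
                                           "--outdir", str(tmp_path / d),
                                           "--seed", "5"])
            assert res.exit_code == 0, res.output
        f1 = sorted((tmp_path / "r1" / "windows").glob("*.tsv"))
        f2 = sorted((tmp_path / "r2" / "windows").glob("*.tsv"))
        for a, b in zip(f1, f2):
            assert a.read_bytes() == b.read_bytes()

    def test_wham_subcommand_writes_pmf(self, tmp_path):
        cfgp = tmp_path / "c.yaml"
        cfgp.write_text(yaml.safe_dump(TINY_CONFIG))
        runner = CliRunner()
        runner.invoke(cli_main, ["simulate", "--config", str(cfgp),
                                 "--outdir", str(tmp_path), "--seed", "5"])
        res = runner.invoke(cli_main, ["wham", "--windows", str(tmp_path),
                                       "--bootstraps", "5",
                                       "--out", str(tmp_path / "pmf.tsv")])
        assert res.exit_code == 0, res.output
        prof = pio.read_pmf_tsv(tmp_path / "pmf.tsv")
        assert np.isfinite(prof.free_energy).sum() > 10

    def test_block_subcommand_reports_fold_ratios(self, tmp_path):
        z = np.linspace(16.5, 36.5, 201)  # grid contains 21.0 exactly
        a = pp.PMFProfile(bin_centers=z, free_energy=np.zeros_like(z))
        bump = 10.0 * np.exp(-((z - 21.0) ** 2) / (2 * 0.4 ** 2))
        b = pp.PMFProfile(bin_centers=z, free_energy=bump)
        pio.write_pmf_tsv(tmp_path / "a.tsv", a)
        pio.write_pmf_tsv(tmp_path / "b.tsv", b)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["block", "--pmf-a",
                                       str(tmp_path / "a.tsv"), "--pmf-b",
                                       str(tmp_path / "b.tsv"),
                                       "--sites", "21.0"])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["fold_ratio"][0] == pytest.approx(52.8, rel=0.02)

    def test_flux_subcommand_runs_dunnett(self, tmp_path):
        rows = ["time_min,fluor,condition,replicate"]
        rng = np.random.default_rng(1)
        for cond, rate in (("liposomes_only", 0.001), ("wildtype", 0.12)):
            for rep in range(3):
                tr = pp.generate_flux_trace(rate=rate, amplitude=800.0,
                                            offset=100.0, noise_sd=5.0,
                                            seed=int(rng.integers(1e6)))
                for t, f in zip(tr.times, tr.fluorescence):
                    rows.append(f"{t},{f},{cond},{rep}")
        csv = tmp_path / "assay.csv"
        csv.write_text("\n".join(rows))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["flux", "--traces", str(csv),
                                       "--control", "liposomes_only",
                                       "--seed", "2"])
        assert res.exit_code == 0, res.output
        payload = json.loads(res.output)
        assert payload["comparisons"][0]["condition"] == "wildtype"
        assert payload["comparisons"][0]["significant"]

    def test_rmsd_subcommand_on_synthetic_pdb(self, tmp_path):
        from conftest import make_tetramer_ca

        def write_pdb(st, path):
            lines = []
            serial = 1
            for ch, residues in st.chains.items():
                for rn, xyz in sorted(residues.items()):
                    lines.append(
                        f"ATOM  {serial:5d}  CA  ALA {ch}{rn:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"  1.00 10.00           C")
                    serial += 1
            lines.append("END")
            path.write_text("\n".join(lines) + "\n")

        a = make_tetramer_ca(seed=0, n_res=40)
        write_pdb(a, tmp_path / "synthetic_ref.pdb")
        write_pdb(a, tmp_path / "synthetic_mob.pdb")
        runner = CliRunner()
        res = runner.invoke(cli_main, ["rmsd", "--ref",
                                       str(tmp_path / "synthetic_ref.pdb"),
                                       "--mobile",
                                       str(tmp_path / "synthetic_mob.pdb"),
                                       "--residues", "12-51",
                                       "--chains", "A,B,C,D"])
        assert res.exit_code == 0, res.output
        assert "RMSD 0.00 A" in res.output


class TestSnapshotTsv:
    def test_cli_coord_from_snapshot_table(self, tmp_path):
        spec = pp.LandscapeSpec()
        z = np.where(np.arange(40) % 2 == 0, 29.5, 30.5)
        traj = pp.BrownianTrajectory(times=np.arange(1.0, 41.0),
                                     z=z, n=np.full(40, 6.0))
        snaps = pp.generate_solvation_snapshots(traj, spec, seed=3)
        path = tmp_path / "snapshots.tsv"
        pio.write_snapshots_tsv(path, snaps)
        runner = CliRunner()
        out = tmp_path / "coord.tsv"
        res = runner.invoke(cli_main, ["coord", "--snapshots", str(path),
                                       "--z-edges", "29:31:1",
                                       "--out", str(out)])
        assert res.exit_code == 0, res.output
        data = np.loadtxt(out, delimiter="\t", skiprows=1, ndmin=2)
        assert data[:, 2:].sum() == pytest.approx(100.0 * 2)  # both z bins
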