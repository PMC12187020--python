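"""Scenario presets, config serialization, outputs, checkpoints and the CLI."""

import math

import numpy as np
import pytest
import yaml

from nanodyad.cli import main as cli_main
from nanodyad.io import (
    load_checkpoint,
    read_trajectory_csv,
    read_vtr,
    save_checkpoint,
    snapshot_arrays,
    write_trajectory_csv,
    write_vtr,
)
from nanodyad.observables import Trajectory
from nanodyad.scenarios import (
    Scenario,
    load_scenario,
    preset,
    preset_names,
    save_scenario,
    scenario_from_dict,
    scenario_to_dict,
    sweep_point,
)
from nanodyad.solver import ConfigurationError, run


def tiny_scenario():
    """A seconds-scale 3D scenario with one open K+ channel."""
    sc = preset("rest3d", "smoke")
    return sc.with_(
        name="tiny",
        geometry={"Ly": 120.0, "Lz": 120.0},
        units=[
            {"id": "K", "type": "channel", "ion": "K", "g": 5e9,
             "y": 60.0, "z": 60.0, "region": "main",
             "schedule": [[0.0, math.inf]]},
        ],
        solver={"dt": 1e-2, "linear_strategy": "direct"},
        duration=0.1,
        observables=[
            {"kind": "v", "unit": "K"},
            {"kind": "mass", "species": "K"},
        ],
    )


class TestPresets:
    def test_registry_and_unknown_name(self):
        assert "rest3d" in preset_names() and "ryr_sweep" in preset_names()
        with pytest.raises(ConfigurationError, match="rest3d"):
            preset("no_such_preset")

    @pytest.mark.parametrize("name", preset_names())
    def test_all_presets_validate_and_mesh(self, name):
        sc = preset(name, "smoke")
        mesh = sc.build_mesh()
        assert mesh.n_cells > 0
        sc.build_units()
        d = scenario_to_dict(sc)
        assert scenario_from_dict(d).name == sc.name

    def test_debye2d_initial_concentrations(self):
        sc = preset("debye2d", "smoke")
        mesh = sc.build_mesh()
        state = sc.initial_state(mesh)
        sub = mesh.subdomain.ravel()
        k = state.species_index("K")
        assert np.allclose(state.c[k][sub == 0], 100.1)   # left of the membrane
        assert np.allclose(state.c[k][sub == 2], 99.9)    # right of the membrane
        assert np.abs(state.rho0).max() == 0.0

    def test_ca_open_gating_schedule(self):
        sc = preset("ca_open", "smoke")
        units = {u.unit_id: u for u in sc.build_units()}
        assert units["K"].schedule.is_open(0.0)
        assert not units["Na"].schedule.is_open(0.04)
        assert units["Na"].schedule.is_open(0.05)
        assert not units["ca"].schedule.is_open(0.09)
        assert units["ca"].schedule.is_open(0.1)
        assert not units["ncx"].schedule.is_open(10.0)

    def test_sweep_point_scaling_rules(self):
        base = preset("ryr_sweep", "smoke")
        p = sweep_point(base, Li=3.0, DCa=1.5e5)
        assert p.geometry.Li == 3.0
        assert p.fine_dx == 0.25                      # refined for Li < 5 nm
        species = {s.name: s for s in p.species_list()}
        assert species["Ca"].Di == pytest.approx(1.5e5)
        # all other intracellular diffusivities scale by the same factor
        assert species["K"].Di == pytest.approx(0.55e6 * 0.75)
        assert species["K"].De == 1.96e6              # extracellular untouched
        q = sweep_point(base, Li=7.0, DCa=2e5)
        assert q.fine_dx == base.fine_dx

    def test_unknown_keys_rejected(self):
        d = scenario_to_dict(preset("rest3d", "smoke"))
        d["typo_key"] = 1
        with pytest.raises(ConfigurationError, match="typo_key"):
            scenario_from_dict(d)
        with pytest.raises(ConfigurationError, match="unit keys"):
            Scenario(name="x", units=[{"id": "a", "type": "channel",
                                       "ion": "K", "g": 1.0, "y": 1.0,
                                       "bogus": 2}])

    def test_yaml_round_trip(self, tmp_path):
        sc = preset("ca_ncx", "smoke")
        path = tmp_path / "sc.yaml"
        save_scenario(sc, path)
        back = load_scenario(path)
        assert scenario_to_dict(back) == scenario_to_dict(sc)


class TestIO:
    def test_trajectory_csv_round_trip(self, tmp_path):
        tr = Trajectory(metadata={"scenario": "demo"})
        tr.append(0.0, {"v_K": -80.0, "mass_K": 1.0})
        tr.append(0.1, {"v_K": -79.5, "mass_K": 1.0})
        path = tmp_path / "traj.csv"
        write_trajectory_csv(tr, path)
        back = read_trajectory_csv(path)
        assert back.metadata["scenario"] == "demo"
        assert back.times == tr.times
        assert back.array("v_K").tolist() == [-80.0, -79.5]

    def test_empty_trajectory_gives_header_only_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_trajectory_csv(Trajectory(), path)
        lines = path.read_text().strip().splitlines()
        assert lines[-1].startswith("t_ms")
        assert len(lines) == 1

    def test_vtr_round_trip(self, tmp_path):
        sc = tiny_scenario()
        mesh = sc.build_mesh()
        state = sc.initial_state(mesh)
        arrays = snapshot_arrays(state, mesh)
        path = tmp_path / "snap.vtr"
        write_vtr(mesh, arrays, path)
        edges, back = read_vtr(path)
        for e_in, e_out in zip(mesh.edges, edges):
            assert np.allclose(e_in, e_out)
        for name, arr in arrays.items():
            assert np.allclose(back[name], np.asarray(arr), equal_nan=True)

    def test_checkpoint_round_trip(self, tmp_path):
        sc = tiny_scenario()
        mesh = sc.build_mesh()
        state = sc.initial_state(mesh)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, state, mesh, scenario_to_dict(sc))
        s2, m2, chash = load_checkpoint(path)
        assert np.array_equal(s2.phi, state.phi)
        assert np.array_equal(s2.c, state.c)
        assert np.array_equal(s2.rho0, state.rho0)
        assert [s.name for s in s2.species] == [s.name for s in state.species]
        assert m2.shape == mesh.shape
        assert "K" in m2.unit_faces


class TestRestart:
    def test_restart_reproduces_uninterrupted_run_bit_for_bit(self, tmp_path):
        sc = tiny_scenario()
        full = run(sc)

        first = run(sc.with_(duration=0.05))
        path = tmp_path / "ck.npz"
        save_checkpoint(path, first.state, first.mesh, {})
        state, _, _ = load_checkpoint(path)
        second = run(sc.with_(duration=0.05), initial_state=state)
        assert np.array_equal(second.state.phi, full.state.phi)
        assert np.array_equal(second.state.c, full.state.c)
        assert np.array_equal(second.state.b, full.state.b)


class TestCLI:
    def test_list_presets(self, capsys):
        assert cli_main(["list-presets"]) == 0
        out = capsys.readouterr().out
        assert "rest3d" in out and "debye2d" in out

    def test_run_with_override_writes_outputs(self, tmp_path, capsys):
        sc = tiny_scenario()
        sc_path = tmp_path / "tiny.yaml"
        save_scenario(sc, sc_path)
        out = tmp_path / "out"
        rc = cli_main([
            "run", str(sc_path), "--out", str(out),
            "--set", "duration=0.02", "--set", "geometry.Li=5.0",
        ])
        assert rc == 0
        traj = read_trajectory_csv(out / "trajectory.csv")
        assert traj.times[-1] == pytest.approx(0.02)
        import json

        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["scenario"]["geometry"]["Li"] == 5.0
        assert manifest["scenario"]["duration"] == 0.02
        assert (out / "final_state.vtr").exists()
        assert (out / "checkpoint.npz").exists()

    def test_resume_matches_uninterrupted_run(self, tmp_path):
        sc = tiny_scenario()
        sc_path = tmp_path / "tiny.yaml"
        save_scenario(sc.with_(duration=0.04), sc_path)
        half_path = tmp_path / "half.yaml"
        save_scenario(sc.with_(duration=0.02), half_path)
        full_out, a_out, b_out = (tmp_path / d for d in ("full", "a", "b"))
        assert cli_main(["run", str(sc_path), "--out", str(full_out)]) == 0
        assert cli_main(["run", str(half_path), "--out", str(a_out)]) == 0
        assert cli_main(["resume", str(a_out / "checkpoint.npz"),
                         "--scenario", str(half_path), "--out", str(b_out)]) == 0
        full = read_trajectory_csv(full_out / "trajectory.csv")
        resumed = read_trajectory_csv(b_out / "trajectory.csv")
        assert resumed.array("v_K")[-1] == full.array("v_K")[-1]

    def test_invalid_override_path_fails(self, tmp_path):
        sc_path = tmp_path / "tiny.yaml"
        save_scenario(tiny_scenario(), sc_path)
        with pytest.raises(SystemExit):
            cli_main(["run", str(sc_path), "--set", "nope.deep=1",
                      "--out", str(tmp_path / "o")])

    def test_summarize_reports_activation(self, tmp_path, capsys):
        tr = Trajectory()
        for i, t in enumerate(np.linspace(0, 1, 11)):
            tr.append(float(t), {"ca_ryr_ca": 1e-4 + 1e-3 * max(0, t - 0.2)})
        path = tmp_path / "traj.csv"
        write_trajectory_csv(tr, path)
        rc = cli_main(["summarize", str(path), "--series", "ca_ryr_ca",
                       "--threshold", "6e-4", "--t-open", "0.2"])
        assert rc == 0
        out = capsys.readouterr().out
        assert "activation time" in out
        assert "0.5" in out

    def test_unknown_preset_exits_nonzero(self, capsys):
        assert cli_main(["run", "not_a_preset", "--out", "/tmp/x"]) == 1
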