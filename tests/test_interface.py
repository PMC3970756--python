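import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import afferentsim as af
from afferentsim.cli import main
from afferentsim.config import (
    ConfigError,
    RunConfig,
    config_hash,
    load_config,
    save_config,
)


@pytest.fixture()
def runner():
    return CliRunner()


class TestConfig:
    def test_yaml_round_trip_is_identity(self, tmp_path):
        cfg = RunConfig(seed=5, sections={"map": {"I_range": [0.0, 70.0]}})
        p = tmp_path / "run.yaml"
        save_config(cfg, p)
        again = load_config(p)
        assert again.to_dict() == cfg.to_dict()
        assert config_hash(again) == config_hash(cfg)

    def test_json_round_trip_is_identity(self, tmp_path):
        cfg = RunConfig()
        p = tmp_path / "run.json"
        save_config(cfg, p)
        assert load_config(p).to_dict() == cfg.to_dict()

    def test_unknown_top_level_key_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig.from_dict({"modle": {}})

    def test_unknown_section_key_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig.from_dict({"map": {"gNa_gird": [0, 1]}})

    def test_invalid_model_block_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig.from_dict({"model": {"core": {"C": -1.0}}})

    def test_hash_changes_with_content(self):
        a = RunConfig(seed=0)
        b = RunConfig(seed=1)
        assert config_hash(a) != config_hash(b)

    def test_default_model_is_the_reference_cell(self):
        assert RunConfig().build_model() == af.CellModel()


class TestCli:
    def test_stats_fixture_writes_method_and_p(self, runner, tmp_path):
        res = runner.invoke(
            main,
            ["stats", "--table", "injured-cutaneous-vs-naive",
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        data = json.loads((tmp_path / "stats.json").read_text())
        assert data["method"] == "fisher-exact"
        assert data["p"] == pytest.approx(0.28125)
        assert "config_hash" in data["provenance"]

    def test_stats_unknown_table_fails_cleanly(self, runner, tmp_path):
        res = runner.invoke(
            main, ["stats", "--table", "nope", "--out", str(tmp_path)]
        )
        assert res.exit_code != 0
        assert "unknown table" in res.output

    def test_map_boundary_is_non_decreasing(self, runner, tmp_path):
        cfg = RunConfig(sections={"map": {
            "gNa_grid": list(np.linspace(0.0, 3.0, 7)),
            "gK_grid": [0.5, 1.0, 1.5, 2.0],
        }})
        save_config(cfg, tmp_path / "cfg.yaml")
        res = runner.invoke(
            main,
            ["map", "--config", str(tmp_path / "cfg.yaml"),
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        df = pd.read_csv(tmp_path / "boundary.csv", comment="#")
        b = df["boundary_gNa_mScm2"].dropna().to_numpy()
        assert len(b) >= 3
        assert np.all(np.diff(b) >= 0)

    def test_simulate_reruns_are_byte_identical(self, runner, tmp_path):
        cfg = RunConfig(
            model=af.CellModel(noise=af.NoiseSpec(sigma=0.3)).to_dict(),
            protocol={"T_total": 200.0, "dt": 0.05, "I_hold": 0.0,
                      "steps": [[50.0, 100.0, 30.0]], "record_dt": 0.1},
            seed=4,
        )
        save_config(cfg, tmp_path / "cfg.yaml")
        outs = []
        for sub in ("a", "b"):
            res = runner.invoke(
                main,
                ["simulate", "--config", str(tmp_path / "cfg.yaml"),
                 "--out", str(tmp_path / sub)],
            )
            assert res.exit_code == 0, res.output
            outs.append((tmp_path / sub / "trace.csv").read_bytes())
        assert outs[0] == outs[1]

    def test_trace_csv_has_provenance_and_units(self, runner, tmp_path):
        cfg = RunConfig(protocol={"T_total": 50.0, "dt": 0.05, "I_hold": 0.0,
                                  "steps": [], "record_dt": 0.5})
        save_config(cfg, tmp_path / "cfg.json")
        res = runner.invoke(
            main,
            ["simulate", "--config", str(tmp_path / "cfg.json"),
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        text = (tmp_path / "trace.csv").read_text().splitlines()
        assert text[0].startswith("# config_hash=")
        assert text[1].split(",")[:2] == ["t_ms", "V_mV"]

    def test_bifurcate_reports_subcritical_hopf(self, runner, tmp_path):
        cfg = RunConfig(
            model=af.reference_model("neuropathic").to_dict(),
            sections={"bifurcate": {"n_samples": 15}},
        )
        save_config(cfg, tmp_path / "cfg.yaml")
        res = runner.invoke(
            main,
            ["bifurcate", "--config", str(tmp_path / "cfg.yaml"),
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        data = json.loads((tmp_path / "bifurcation.json").read_text())
        assert data["hopf_type"] == "subcritical"
        assert data["hopf_I_star_uAcm2"] == pytest.approx(60.8, abs=0.5)

    def test_predict_writes_six_confirmed_outcomes(self, runner, tmp_path):
        cfg = RunConfig(sections={"predict": {"classifier": "hopf"}})
        save_config(cfg, tmp_path / "cfg.yaml")
        res = runner.invoke(
            main,
            ["predict", "--config", str(tmp_path / "cfg.yaml"),
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        data = json.loads((tmp_path / "predictions.json").read_text())
        assert [p["id"] for p in data["predictions"]] == [1, 2, 3, 4, 5, 6]
        assert all(p["confirmed"] for p in data["predictions"])

    def test_cohort_command_counts_conversions(self, runner, tmp_path):
        cfg = RunConfig(seed=3, sections={"cohort": {
            "kind": "muscle", "n_cells": 6, "injury": True,
            "classifier": "hopf", "titrate": False,
        }})
        save_config(cfg, tmp_path / "cfg.yaml")
        res = runner.invoke(
            main,
            ["cohort", "--config", str(tmp_path / "cfg.yaml"),
             "--out", str(tmp_path)],
        )
        assert res.exit_code == 0, res.output
        data = json.loads((tmp_path / "cohort.json").read_text())
        assert data["n_cells"] == 6
        assert 0 <= data["converted"] <= 6
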