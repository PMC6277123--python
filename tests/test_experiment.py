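"""Configuration, grid expansion, presets, end-to-end orchestration and the
command-line interface."""

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from polyadapt import cli
from polyadapt.experiment import (ExperimentConfig, ParamSet, preset,
                                  published_config, run_experiment)

TINY = dict(
    name="tiny",
    n_anc=50,
    replicates=2,
    seed=11,
    sigma_m=[0.1],
    v_s=[1.0],
    psi=[0.0, 0.5],
    bottleneck_fraction=[1.0],
    final_multiple=[1.0],
    burn_in_generations=150,
    null_fixations=40,
)


class TestConfig:
    def test_published_grid_counts(self):
        cfg = published_config()
        sets = cfg.param_sets()
        assert len(sets) == 1200
        assert len({ps.set_id for ps in sets}) == 1200
        assert cfg.n_anc == 10_000 and cfg.replicates == 100

    def test_mini_grid_expansion(self):
        cfg = ExperimentConfig(sigma_m=[0.1, 0.3], v_s=[1.0, 5.0], psi=[0.0],
                               bottleneck_fraction=[1.0], final_multiple=[1.0, 3.0])
        assert len(cfg.param_sets()) == 8

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(TINY))
        cfg = ExperimentConfig.from_yaml(path)
        assert cfg.psi == (0.0, 0.5)
        assert cfg.burn_in_length() == 150
        assert ExperimentConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig.from_dict({"bogus": 1})

    def test_presets(self):
        t1 = preset("maize-trait1")
        assert (t1.sigma_m, t1.v_s) == ((0.01,), (1.0,))
        assert t1.bottleneck_fraction == (0.05,) and t1.final_multiple == (10.0,)
        t2 = preset("maize-trait2")
        assert (t2.sigma_m, t2.v_s) == ((0.9,), (50.0,))
        focal = preset("single-scenario")
        assert (focal.sigma_m, focal.v_s, focal.psi) == ((0.05,), (1.0,), (0.0,))
        assert focal.bottleneck_fraction == (1.0,)
        with pytest.raises(KeyError):
            preset("nope")

    def test_param_set_ids(self):
        ps = ParamSet(0.05, 1.0, 0.0, 0.05, 10.0)
        assert ps.set_id == "sm0.05_vs1_psi0_b0.05_f10"


def _hash_tree(root: Path) -> dict:
    out = {}
    for path in sorted(root.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    return out


class TestRunExperiment:
    def test_end_to_end_outputs_and_determinism(self, tmp_path):
        cfg = ExperimentConfig.from_dict(TINY)
        res1 = run_experiment(cfg, out_dir=tmp_path / "run1")
        res2 = run_experiment(cfg, out_dir=tmp_path / "run2")

        summary = res1["summary"]
        assert len(summary) == 4  # 2 parameter sets x 2 replicates
        assert set(summary["set_id"]) == {ps.set_id for ps in cfg.param_sets()}
        assert (summary["v_g0"] > 0).all()

        root = tmp_path / "run1"
        assert (root / "summary.tsv").exists()
        assert (root / "aggregate.tsv").exists()
        assert (root / "manifest.json").exists()
        assert (root / "null_b1_f1.tsv").exists()
        rep_dir = root / "sets" / cfg.param_sets()[0].set_id / "rep0"
        for name in ("trajectory.tsv", "fixations.tsv", "segregating.tsv"):
            assert (rep_dir / name).exists()

        manifest = json.loads((root / "manifest.json").read_text())
        assert manifest["n_runs"] == 4
        assert manifest["null_thresholds"]["b1_f1"] > 0

        # identical config + seed => byte-identical output tree
        assert _hash_tree(tmp_path / "run1") == _hash_tree(tmp_path / "run2")

    def test_different_seed_changes_results(self, tmp_path):
        cfg1 = ExperimentConfig.from_dict(TINY)
        cfg2 = dataclasses.replace(cfg1, seed=99)
        res1 = run_experiment(cfg1)
        res2 = run_experiment(cfg2)
        assert not res1["summary"]["v_g0"].equals(res2["summary"]["v_g0"])

    def test_worker_count_does_not_change_results(self, tmp_path):
        cfg = ExperimentConfig.from_dict(TINY)
        serial = run_experiment(cfg, out_dir=tmp_path / "serial", n_jobs=1)
        parallel = run_experiment(cfg, out_dir=tmp_path / "par", n_jobs=2)
        assert _hash_tree(tmp_path / "serial") == _hash_tree(tmp_path / "par")


class TestCli:
    def test_presets_listing(self):
        result = CliRunner().invoke(cli.main, ["presets", "--list"])
        assert result.exit_code == 0
        for name in ("single-scenario", "maize-trait1", "maize-trait2"):
            assert name in result.output

    def test_null_command(self, tmp_path):
        out = tmp_path / "null.tsv"
        result = CliRunner().invoke(cli.main, [
            "null", "--demography", "b1_f1", "--n-anc", "40", "--n", "60",
            "--seed", "3", "--out", str(out)])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(out, sep="\t")
        assert len(table) >= 60
        meta = json.loads(out.with_suffix(".json").read_text())
        assert meta["threshold_gen"] > 0

    def test_run_and_importance_commands(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(TINY))
        out_dir = tmp_path / "out"
        result = CliRunner().invoke(cli.main, [
            "run", "--config", str(cfg_path), "--out", str(out_dir)])
        assert result.exit_code == 0, result.output
        result = CliRunner().invoke(cli.main, [
            "importance", "--summaries", str(out_dir / "summary.tsv"),
            "--targets", "v_g0", "--seed", "1",
            "--out", str(tmp_path / "imp.tsv")])
        # only 4 rows -> cross-validation cannot run 10 folds
        assert result.exit_code != 0

    def test_report_command(self, tmp_path):
        cfg = ExperimentConfig.from_dict(TINY)
        run_experiment(cfg, out_dir=tmp_path)
        result = CliRunner().invoke(cli.main, ["report", "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert "set_id" in result.output
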