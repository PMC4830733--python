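"""End-to-end pipeline, file I/O round trips, and CLI behaviour."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from stressdoe import (
    AnalysisConfig,
    DataError,
    ScreeningConfig,
    run_pipeline,
)
from stressdoe import datasets, io
from stressdoe.cli import main as cli_main


def acid_config(**overrides):
    base = dict(
        label="acid",
        factors=datasets.ACID_FACTORS,
        runs=datasets.acid_responses(),
        screening=ScreeningConfig(yates_rounding="nearest-integer"),
        significant_terms=("X2", "X3"),
        paper_rounding=True,
        target_degradation=10.0,
    )
    base.update(overrides)
    return AnalysisConfig(**base)


class TestRunPipeline:
    def test_acid_study_report(self):
        report = run_pipeline(acid_config()).payload
        model = report["model"]
        assert model["equation"].startswith("Y = 18.32 - 0.67X1 + 10.26X2 + 4.56X3")
        assert model["r_squared_reduced"] == pytest.approx(0.9462, abs=5e-5)
        assert report["yates"]["error_ms"] == pytest.approx(0.25)
        assert report["yates"]["f_values"]["X3"] == pytest.approx(648.0)
        opt = report["optimum"]
        assert opt["actual_point"][0] == pytest.approx(0.055)
        assert opt["actual_point"][1] == pytest.approx(55.0)
        assert opt["actual_point"][2] == pytest.approx(59.8, abs=0.3)
        assert opt["in_domain"]
        surf = np.array(report["surface"]["solutions"])
        assert surf.shape == (5, 4)
        assert round(surf[0, 1], 2) == 0.98  # X2=-1, 10% target

    def test_alkali_study_report(self):
        report = run_pipeline(
            acid_config(
                label="alkali",
                factors=datasets.ALKALI_FACTORS,
                runs=datasets.alkali_responses(),
                significant_terms=("X2", "X3"),
                active_factors=("X2",),
            )
        ).payload
        # Nearest-integer rounding maps run 7 (32.51) to 33; the hand
        # worksheet used 32, which shifts its R^2 to 0.9770 (see the
        # alkali_yates fixture tests for that variant).
        assert report["model"]["r_squared_reduced"] == pytest.approx(0.9793, abs=5e-4)
        opt = report["optimum"]
        assert opt["coded_point"][1] == pytest.approx(-0.886, abs=0.001)
        assert opt["actual_point"][0] == pytest.approx(0.055)
        assert opt["actual_point"][2] == pytest.approx(22.5)

    def test_synthetic_noiseless_identity(self):
        """A noiseless synthetic study reports the generator's own equation."""
        from dataclasses import replace
        from stressdoe import default_acid_scenario, gen_factorial_responses

        spec = replace(default_acid_scenario(seed=2), noise_sd=0.0)
        cfg = AnalysisConfig(
            label="synthetic",
            factors=spec.design.factors,
            runs=gen_factorial_responses(spec),
            significant_terms=("X2", "X3"),
        )
        report = run_pipeline(cfg).payload
        assert report["model"]["intercept"] == pytest.approx(spec.intercept)
        for t, b in spec.coefficients.items():
            assert report["model"]["coefficients"][t] == pytest.approx(b, abs=1e-12)

    def test_report_is_deterministic(self):
        a = run_pipeline(acid_config()).to_json()
        b = run_pipeline(acid_config()).to_json()
        assert a == b

    def test_validation_block(self):
        cfg = acid_config(precision=datasets.precision_levels())
        block = run_pipeline(cfg).payload["validation"]
        fvals = [lvl["f_value"] for lvl in block["precision"]]
        assert fvals == pytest.approx([0.3086, 0.8396, 1.508], abs=5e-4)
        assert block["recovery"]["slope"] == pytest.approx(0.803, abs=0.002)

    def test_invalid_target_rejected(self):
        with pytest.raises(Exception):
            acid_config(target_degradation=150.0)


class TestIORoundTrips:
    def test_design_csv_round_trip(self, acid_design, tmp_path):
        path = tmp_path / "design.csv"
        io.write_design_csv(acid_design, path)
        df = pd.read_csv(path)
        np.testing.assert_array_equal(
            df[["X1", "X2", "X3"]].to_numpy(), acid_design.runs.astype(int)
        )
        np.testing.assert_array_equal(
            df["X1X2X3"].to_numpy(), acid_design.effect_column("X1X2X3").astype(int)
        )

    def test_run_table_round_trip(self, acid_design, tmp_path):
        path = tmp_path / "runs.csv"
        frame = acid_design.to_frame(include_interactions=False)
        frame["response_pct"] = datasets.ACID_PCT_DEGRADATION
        frame.to_csv(path, index=False)
        vec = io.responses_from_run_table(io.read_run_table(path), acid_design)
        np.testing.assert_allclose(vec.values, datasets.ACID_PCT_DEGRADATION)

    def test_shuffled_run_table_resorted(self, acid_design, tmp_path):
        """Rows in any order are re-aligned by their coded sign pattern."""
        path = tmp_path / "runs.csv"
        frame = acid_design.to_frame(include_interactions=False)
        frame["response_pct"] = datasets.ACID_PCT_DEGRADATION
        frame = frame.iloc[::-1]
        frame["run"] = range(1, 9)  # run numbers now disagree with patterns
        frame.to_csv(path, index=False)
        vec = io.responses_from_run_table(io.read_run_table(path), acid_design)
        np.testing.assert_allclose(vec.values, datasets.ACID_PCT_DEGRADATION)

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "runs.csv"
        path.write_text("run,X1,response_pct\n1,-1,7.14\n2,oops,5.03\n")
        with pytest.raises(DataError, match="line 3"):
            io.read_run_table(path)

    def test_crlf_and_lf_parse_identically(self, tmp_path):
        body = "name,low,high,units\nT,55,80,degC\nt,30,60,min\n"
        lf = tmp_path / "lf.csv"
        crlf = tmp_path / "crlf.csv"
        lf.write_text(body)
        crlf.write_bytes(body.replace("\n", "\r\n").encode())
        assert io.read_factors_csv(lf) == io.read_factors_csv(crlf)

    def test_model_json_round_trip(self, acid_model, tmp_path):
        path = tmp_path / "model.json"
        io.write_model_json(acid_model, path)
        back = io.read_model_json(path)
        assert back.intercept == acid_model.intercept
        assert back.coefficients == acid_model.coefficients

    def test_precision_csv(self, tmp_path):
        rows = []
        for level in datasets.precision_levels():
            for d, day_row in enumerate(level.values_matrix, start=1):
                for r, v in enumerate(day_row, start=1):
                    rows.append(
                        {"level": level.level_label, "nominal_mg": level.nominal_amount,
                         "day": d, "replicate": r, "found_mg": v}
                    )
        path = tmp_path / "precision.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        levels = io.read_precision_csv(path)
        assert len(levels) == 3
        assert levels[0].anova().f_value == pytest.approx(0.3086, abs=5e-4)


class TestCli:
    def _write_acid_inputs(self, tmp_path):
        factors = tmp_path / "factors.csv"
        factors.write_text(
            "name,low,high,units\n"
            "acid_strength,0.01,0.1,mol/L\ntemperature,55,80,degC\n"
            "heating_time,30,60,min\n"
        )
        runs = tmp_path / "runs.csv"
        frame = datasets.acid_design().to_frame(include_interactions=False)
        frame["response_pct"] = datasets.ACID_PCT_DEGRADATION
        frame.to_csv(runs, index=False)
        return factors, runs

    def test_screen_fit_optimize_workflow(self, tmp_path):
        runner = CliRunner()
        factors, runs = self._write_acid_inputs(tmp_path)
        out = tmp_path / "screenout"
        res = runner.invoke(cli_main, [
            "screen", "--runs", str(runs), "--factors", str(factors),
            "--paper-rounding", "--out", str(out),
        ])
        assert res.exit_code == 0, res.output
        assert "error MS 0.25" in res.output
        assert (out / "yates_report.csv").exists()

        model_json = tmp_path / "model.json"
        res = runner.invoke(cli_main, [
            "fit", "--runs", str(runs), "--factors", str(factors),
            "--significant", "X2,X3", "--out", str(model_json),
        ])
        assert res.exit_code == 0, res.output
        assert "18.32" in res.output

        opt_json = tmp_path / "optimum.json"
        res = runner.invoke(cli_main, [
            "optimize", "--model", str(model_json), "--factors", str(factors),
            "--target", "10", "--active", "X2,X3", "--paper-rounding",
            "--out", str(opt_json),
        ])
        assert res.exit_code == 0, res.output
        payload = json.loads(opt_json.read_text())
        assert payload["actual_point"][1] == pytest.approx(55.0)

    def test_simulate_then_report(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        res = runner.invoke(cli_main, [
            "simulate", "--kind", "factorial", "--seed", "3", "--out", str(sim_dir),
        ])
        assert res.exit_code == 0, res.output
        assert (sim_dir / "runs.csv").exists()
        prov = json.loads((sim_dir / "provenance.json").read_text())
        assert prov["seed"] == 3

        factors = tmp_path / "factors.csv"
        factors.write_text(
            "name,low,high,units\n"
            "acid_strength,0.01,0.1,mol/L\ntemperature,55,80,degC\n"
            "heating_time,30,60,min\n"
        )
        config = tmp_path / "config.yaml"
        config.write_text(
            "label: sim\n"
            f"factors: {factors}\n"
            f"runs: {sim_dir / 'runs.csv'}\n"
            "significant_terms: [X2, X3]\n"
        )
        out = tmp_path / "reportout"
        res = runner.invoke(cli_main, [
            "report", "--config", str(config), "--out", str(out),
        ])
        assert res.exit_code == 0, res.output
        payload = json.loads((out / "sim_report.json").read_text())
        assert payload["model"]["coefficients"]["X2"] == pytest.approx(10.26, abs=0.5)

    def test_design_command(self, tmp_path):
        runner = CliRunner()
        factors, _ = self._write_acid_inputs(tmp_path)
        out = tmp_path / "design.csv"
        res = runner.invoke(cli_main, ["design", "--factors", str(factors), "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert len(pd.read_csv(out)) == 8
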