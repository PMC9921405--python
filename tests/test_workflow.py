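"""Run configuration, report bundle, and the CLI surface."""

import json

import pytest
from click.testing import CliRunner

from hepatosim.cli import main
from hepatosim.pharmacokinetics import DOSE_GRID_MG
from hepatosim.simulation import TWO_DAYS_S
from hepatosim.workflow import ConfigError, RunConfig, run_paper_experiments


class TestRunConfig:
    def test_defaults_reproduce_study_conditions(self):
        c = RunConfig()
        assert c.doses_mg == DOSE_GRID_MG == (0.0, 1.8, 26.0, 52.0, 120.0)
        assert c.duration_s == TWO_DAYS_S == 172_800.0
        assert set(c.pathways) == {"ros", "deconjugation", "apoptosis",
                                   "bgluc_synthesis"}

    def test_empty_dose_grid_rejected_before_simulation(self):
        with pytest.raises(ConfigError, match="empty"):
            run_paper_experiments(RunConfig(doses_mg=()))

    def test_disabled_calibration_requires_parameter_dir(self):
        with pytest.raises(ConfigError, match="parameter_dir"):
            RunConfig(calibrate=False).validate()

    def test_yaml_round_trip_and_unknown_keys(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("doses_mg: [0, 26]\ncalibration_seed: 5\n")
        c = RunConfig.from_yaml(path)
        assert c.doses_mg == (0.0, 26.0) and c.calibration_seed == 5
        path.write_text("nonsense_key: 1\n")
        with pytest.raises(ConfigError, match="nonsense_key"):
            RunConfig.from_yaml(path)


class TestRunPaperExperiments:
    @pytest.fixture()
    def fitted(self, calibrated):
        return {name: result.parameters
                for name, (_, result) in calibrated.items()}

    def test_summary_contains_reported_control_and_dosed_values(
            self, tmp_path, fitted):
        config = RunConfig(calibrate=False, parameter_dir=str(tmp_path),
                           output_dir=str(tmp_path / "out"))
        bundle = run_paper_experiments(config, precalibrated=fitted)
        s = bundle.summary
        ros0 = s[(s.pathway == "ros") & (s.dose_mg_per_100mL == 0.0)]
        assert ros0.steady_state_nM.iloc[0] == pytest.approx(70.0, rel=0.01)
        bg26 = s[(s.pathway == "bgluc_synthesis")
                 & (s.dose_mg_per_100mL == 26.0)]
        assert bg26.steady_state_nM.iloc[0] == pytest.approx(1.19, rel=0.01)
        assert bundle.all_targets_met and bundle.exit_code == 0

    def test_reruns_are_byte_identical(self, tmp_path, fitted):
        outputs = []
        for sub in ("a", "b"):
            config = RunConfig(calibrate=False, parameter_dir=str(tmp_path),
                               output_dir=str(tmp_path / sub))
            run_paper_experiments(config, precalibrated=fitted)
            outputs.append((tmp_path / sub / "summary.csv").read_bytes())
        assert outputs[0] == outputs[1]

    def test_missing_parameter_file_is_actionable(self, tmp_path):
        config = RunConfig(calibrate=False, parameter_dir=str(tmp_path),
                           output_dir=str(tmp_path / "out"))
        with pytest.raises(ConfigError, match="parameter file"):
            run_paper_experiments(config)

    def test_outputs_carry_units_and_provenance(self, tmp_path, fitted):
        out = tmp_path / "out"
        config = RunConfig(calibrate=False, parameter_dir=str(tmp_path),
                           output_dir=str(out))
        run_paper_experiments(config, precalibrated=fitted)
        text = (out / "summary.csv").read_text()
        assert text.startswith("#") and "nM" in text.splitlines()[0]
        prov = json.loads((out / "provenance.json").read_text())
        assert {"config", "config_hash", "versions"} <= set(prov)


class TestCli:
    def test_build_emits_sbml_and_reaction_tables(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["build", "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "ros.sbml.xml").exists()
        assert (tmp_path / "apoptosis_reactions.tsv").exists()

    def test_dose_response_verb(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["dose-response", "ros",
                                      "--doses", "0,26",
                                      "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "ros_dose_response.csv").exists()
        assert "steady_state_nM" in result.output

    def test_make_synthetic_verb(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["make-synthetic",
                                      "--fixture", "production_degradation",
                                      "--sigma", "0.1", "--seed", "2",
                                      "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        meta = json.loads(
            (tmp_path / "production_degradation_observations.meta.json")
            .read_text())
        assert meta["seed"] == 2 and meta["noise_sigma"] == 0.1
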