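"""Model/Results layer, pipeline runs and the command-line interface."""

import numpy as np
import pytest
from click.testing import CliRunner

from stuneeg.assess import AssessmentConfig
from stuneeg.cli import main as cli_main
from stuneeg.model import CohortStudy, StunModel
from stuneeg.pipeline import PipelineConfig, run
from stuneeg.synth import BandSpectrumParams, CohortDesign

from conftest import make_animal

SMALL_DESIGN = dict(
    group_sizes={"P1-50": 3, "P1-400": 3, "P2-50": 3, "P2-400": 3},
    base_params=BandSpectrumParams(fs=128.0),
    pre_duration_range=(15.0, 20.0),
    post_duration=60.0,
)


@pytest.fixture(scope="module")
def small_results():
    study = CohortStudy.from_synthetic(CohortDesign(**SMALL_DESIGN), master_seed=5)
    return study.fit()


class TestStunModel:
    def test_fit_returns_results_with_summary(self, fast_params):
        pre, post, resp = make_animal(fast_params, "good", seed=31)
        res = StunModel(pre, post).fit()
        text = res.summary()
        assert "good stun" in text
        assert "nadir" in text
        row = res.to_row()
        assert row["sustained"]
        assert row["threshold"] == 30.0

    def test_chart_data_long_format(self, fast_params):
        pre, post, _ = make_animal(fast_params, "failed", seed=32)
        df = StunModel(pre, post).fit().db_chart_data()
        assert set(df["band"]) == {"very_low", "delta", "theta", "alpha", "beta",
                                   "total"}
        assert {"start", "db", "clean"} <= set(df.columns)


class TestCohortStudy:
    def test_group_sizes_and_accuracy(self, small_results):
        res = small_results
        assert len(res.per_animal) == 12
        counts = res.tables.counts
        assert counts["n"].sum() == 12
        acc = res.classification_accuracy()
        assert acc["sensitivity"] == 1.0
        assert acc.get("specificity", 1.0) >= 0.5

    def test_tables_shapes(self, small_results):
        t = small_results.tables
        assert set(t.percentage_power["period"]) == {"T0", "T1"}
        assert set(t.rms["period"]) == {"T0", "T1", "T2"}
        assert set(t.db_change["period"]) <= {"T1", "T2"}
        assert len(t.ranking) == 4

    def test_glm_fits_present_for_each_band(self, small_results):
        assert "delta" in small_results.glm_fits
        fit = small_results.glm_fits["delta"]
        assert fit.converged
        # every stun raises delta RMS at T1, so the period coefficient is positive
        assert fit.params["C(period)[T.T1]"] > 0

    def test_ks_contrasts_have_valid_stats(self, small_results):
        assert small_results.ks
        for r in small_results.ks.values():
            assert 0.0 <= r.d <= 1.0
            assert 0.0 <= r.pvalue <= 1.0

    def test_summary_renders(self, small_results):
        text = small_results.summary()
        assert "Good-stun counts" in text
        assert "Ranking" in text


class TestManifestLoading:
    def test_round_trip_via_simulate_and_manifest(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "cohort"
        result = runner.invoke(cli_main, ["simulate", "--seed", "3", "--out",
                                          str(out)])
        # a small design is not configurable through the CLI default, so just
        # check the manifest structure with a couple of animals loaded
        assert result.exit_code == 0
        manifest = out / "manifest.tsv"
        assert manifest.exists()
        lines = manifest.read_text().splitlines()
        assert lines[0].split("\t") == ["animal", "treatment", "phase", "file",
                                        "quality", "seed"]
        assert len(lines) == 1 + 2 * 119

    def test_missing_file_named_in_error(self, tmp_path):
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text(
            "animal\ttreatment\tphase\tfile\n"
            "A1\tP1-50\tpre-stun\tnope.csv\n"
            "A1\tP1-50\tpost-stun\talso-nope.csv\n"
        )
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            CohortStudy.from_manifest(manifest)

    def test_missing_phase_rejected(self, tmp_path, fast_params):
        from stuneeg.io import write_recording
        from stuneeg.synth import generate_baseline_trace

        rec = generate_baseline_trace(fast_params, 15.0, seed=1)
        write_recording(rec, tmp_path / "a.csv")
        manifest = tmp_path / "manifest.tsv"
        manifest.write_text("animal\ttreatment\tphase\tfile\n"
                            "A1\tP1-50\tpre-stun\ta.csv\n")
        with pytest.raises(ValueError, match="post-stun"):
            CohortStudy.from_manifest(manifest)


class TestPipelineRun:
    def test_run_twice_is_byte_identical(self, tmp_path):
        cfg = PipelineConfig(design=CohortDesign(**SMALL_DESIGN), master_seed=9)
        d1 = run(cfg, tmp_path / "r1")
        d2 = run(cfg, tmp_path / "r2")
        for f in sorted(p.name for p in d1.iterdir() if p.is_file()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_counts_sum_to_group_sizes(self, tmp_path):
        cfg = PipelineConfig(design=CohortDesign(**SMALL_DESIGN), master_seed=9)
        out = run(cfg, tmp_path / "r")
        import pandas as pd

        counts = pd.read_csv(out / "table_good_stun_counts.tsv", sep="\t")
        assert counts["n"].sum() == 12
        assert (counts["sustained"] + counts["not_sustained"]).equals(counts["n"])
        assert (out / "run_manifest.yaml").exists()
        assert (out / "report.txt").exists()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(design=CohortDesign(**SMALL_DESIGN), master_seed=4,
                             assessment=AssessmentConfig(threshold=25.0))
        import yaml

        path = tmp_path / "config.yml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = PipelineConfig.from_yaml(path)
        assert back.master_seed == 4
        assert back.assessment.threshold == 25.0
        assert back.design.base_params.fs == 128.0

    def test_files_mode_requires_manifest(self):
        with pytest.raises(ValueError, match="manifest"):
            PipelineConfig(input_mode="files")


class TestCLI:
    def test_run_and_report(self, tmp_path):
        import yaml

        cfg = PipelineConfig(design=CohortDesign(**SMALL_DESIGN), master_seed=2)
        cfg_path = tmp_path / "c.yml"
        cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))
        runner = CliRunner()
        out = tmp_path / "run"
        r = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                     "--seed", "1", "--out", str(out)])
        assert r.exit_code == 0, r.output
        r2 = runner.invoke(cli_main, ["report", "--run-dir", str(out)])
        assert r2.exit_code == 0
        assert "Ranking" in r2.output

    def test_assess_single_animal(self, tmp_path, fast_params):
        from stuneeg.io import write_recording

        pre, post, _ = make_animal(fast_params, "good", seed=41)
        write_recording(pre, tmp_path / "pre.csv")
        write_recording(post, tmp_path / "post.csv")
        runner = CliRunner()
        r = runner.invoke(cli_main, ["assess", "--pre", str(tmp_path / "pre.csv"),
                                     "--post", str(tmp_path / "post.csv")])
        assert r.exit_code == 0, r.output
        assert "good stun" in r.output

    def test_assess_missing_file_fails(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["assess", "--pre", str(tmp_path / "no.csv"),
                                     "--post", str(tmp_path / "no2.csv")])
        assert r.exit_code != 0

    def test_unknown_flag_nonzero_exit(self):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["run", "--bogus"])
        assert r.exit_code != 0

    def test_simulate_deterministic_manifest(self, tmp_path):
        import yaml

        cfg = PipelineConfig(design=CohortDesign(**SMALL_DESIGN))
        cfg_path = tmp_path / "c.yml"
        cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))
        runner = CliRunner()
        m = []
        for name in ("s1", "s2"):
            out = tmp_path / name
            r = runner.invoke(cli_main, ["simulate", "--seed", "6", "--config",
                                         str(cfg_path), "--out", str(out)])
            assert r.exit_code == 0, r.output
            m.append((out / "manifest.tsv").read_text())
        assert m[0] == m[1]
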