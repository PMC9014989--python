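"""Integration tests: SNIRF I/O, study orchestration, report bundle, CLI."""

import dataclasses
import filecmp

import numpy as np
import pytest

from flightload.errors import ValidationError
from flightload.fnirs_glm import estimate_activation
from flightload.optics import OpticsConfig
from flightload.physio_synth import (NoiseModel, add_noise, mbll_forward,
                                     synthesize_activation)
from flightload.series import HemoglobinSeries
from flightload.snirf_io import read_snirf, write_snirf
from flightload.study_io import (ANOVA_MEASURES, StudyConfig, make_report,
                                 run_study)

SMALL = dict(n_subjects=6)


@pytest.fixture(scope="module")
def small_results():
    return run_study(StudyConfig(root_seed=42, **SMALL))


class TestSnirf:
    def test_od_round_trip(self, tmp_path, optics, random_hemo):
        od = mbll_forward(random_hemo, optics)
        path = tmp_path / "run.snirf"
        write_snirf(od, optics, path)
        back, optics_back = read_snirf(path)
        np.testing.assert_allclose(back.delta_od, od.delta_od, atol=1e-12, rtol=0)
        assert back.wavelengths_nm == od.wavelengths_nm
        assert optics_back.source_detector_distance_cm == optics.source_detector_distance_cm
        assert optics_back.dpf == optics.dpf

    def test_hemoglobin_round_trip(self, tmp_path, optics, random_hemo):
        path = tmp_path / "hemo.snirf"
        write_snirf(random_hemo, optics, path)
        back, _ = read_snirf(path)
        assert isinstance(back, HemoglobinSeries)
        np.testing.assert_allclose(back.delta_hbo, random_hemo.delta_hbo, atol=1e-12, rtol=0)
        np.testing.assert_allclose(back.delta_hbr, random_hemo.delta_hbr, atol=1e-12, rtol=0)

    def test_missing_wavelengths_is_a_parse_error(self, tmp_path, optics, random_hemo):
        import h5py
        path = tmp_path / "broken.snirf"
        write_snirf(mbll_forward(random_hemo, optics), optics, path)
        with h5py.File(path, "a") as f:
            del f["nirs/probe/wavelengths"]
        with pytest.raises(ValidationError, match="wavelengths"):
            read_snirf(path)

    def test_snirf_and_csv_give_identical_analysis(self, tmp_path, optics):
        hemo = add_noise(synthesize_activation(np.full(8, 0.5), [30], [180]),
                         NoiseModel(), seed=3)
        od = mbll_forward(hemo, optics)
        path = tmp_path / "run.snirf"
        write_snirf(od, optics, path)
        from_snirf, optics_back = read_snirf(path)
        csv_path = tmp_path / "hemo.csv"
        hemo.to_csv(csv_path)
        from_csv = HemoglobinSeries.read_csv(csv_path)
        a = estimate_activation(from_snirf, optics_back, [30], [180])
        b = estimate_activation(from_csv, optics, [30], [180])
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-9)


class TestRunStudy:
    def test_table_is_complete(self, small_results):
        tab = small_results.table
        assert len(tab) == 6 * 3
        for m in ANOVA_MEASURES:
            assert tab[m].notna().all()

    def test_same_seed_gives_identical_saved_files(self, tmp_path):
        cfg = StudyConfig(root_seed=5, **SMALL)
        for name in ("a", "b"):
            run_study(cfg).save(tmp_path / name)
        for f in ("measures.csv", "anova.csv", "posthoc.csv", "correlations.csv",
                  "study.json"):
            assert filecmp.cmp(tmp_path / "a" / f, tmp_path / "b" / f, shallow=False), f

    def test_counterbalancing_is_latin_square(self):
        cfg = StudyConfig(root_seed=0, n_subjects=7)
        orders = cfg.condition_orders()
        for pos in range(3):
            counts = {c: sum(o[pos] == c for o in orders) for c in cfg.conditions}
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_fnirs_reseed_leaves_other_stages_untouched(self):
        base = run_study(StudyConfig(root_seed=9, n_subjects=4))
        moved = run_study(StudyConfig(root_seed=9, n_subjects=4,
                                      seed_offsets={"behavior": 0, "rr": 0,
                                                    "fnirs": 1234, "tlx": 0}))
        behav = ["avg_distance_mm", "n_alarms", "n_numeral_responses"]
        assert base.table[behav].equals(moved.table[behav])
        assert base.table["mean_hr_bpm"].equals(moved.table["mean_hr_bpm"])
        assert base.table["tlx_total"].equals(moved.table["tlx_total"])
        assert not np.allclose(base.table["mean_beta"], moved.table["mean_beta"])

    def test_posthoc_threshold_matches_reporting_convention(self, small_results):
        for res in small_results.posthocs.values():
            assert res.threshold_display == ".016"

    def test_excluded_correlation_families(self, small_results):
        corr = small_results.correlations
        from flightload.study_io import MEASURE_FAMILIES
        for _, row in corr.iterrows():
            assert MEASURE_FAMILIES[row["measure_x"]] != MEASURE_FAMILIES[row["measure_y"]]


class TestMakeReport:
    def test_report_has_one_anova_row_per_measure(self, small_results, tmp_path):
        import pandas as pd
        make_report(small_results, tmp_path / "rep", make_figures=False)
        anova = pd.read_csv(tmp_path / "rep" / "anova.csv")
        assert sorted(anova["measure"]) == sorted(ANOVA_MEASURES)

    def test_low_condition_cells_say_none(self, small_results, tmp_path):
        import pandas as pd
        make_report(small_results, tmp_path / "rep2", make_figures=False)
        perf = pd.read_csv(tmp_path / "rep2" / "performance_table.csv")
        perf = perf.set_index("feature")
        assert perf.loc["meter_rt_s", "low"] == "none"
        assert perf.loc["emergency_rt_s", "medium"] == "none"
        assert perf.loc["emergency_rt_s", "high"] != "none"

    def test_report_is_deterministic(self, small_results, tmp_path):
        make_report(small_results, tmp_path / "r1", make_figures=False)
        make_report(small_results, tmp_path / "r2", make_figures=False)
        assert filecmp.cmp(tmp_path / "r1" / "performance_table.csv",
                           tmp_path / "r2" / "performance_table.csv", shallow=False)

    def test_incomplete_results_rejected(self, small_results, tmp_path):
        broken = dataclasses.replace(
            small_results,
            table=small_results.table.assign(mean_beta=np.nan))
        with pytest.raises(ValidationError, match="mean_beta"):
            make_report(broken, tmp_path / "bad", make_figures=False)

    def test_figures_are_written_when_requested(self, small_results, tmp_path):
        files = make_report(small_results, tmp_path / "figs", make_figures=True)
        assert (tmp_path / "figs" / "tlx_by_condition.png").exists()


class TestCli:
    def test_simulate_command(self, tmp_path):
        from click.testing import CliRunner
        from flightload.cli import main
        runner = CliRunner()
        res = runner.invoke(main, ["--seed", "3", "--out-dir", str(tmp_path),
                                   "simulate", "--condition", "medium"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "events.jsonl").exists()
        assert (tmp_path / "performance.json").exists()

    def test_synth_and_analyze_commands(self, tmp_path):
        from click.testing import CliRunner
        from flightload.cli import main
        runner = CliRunner()
        res = runner.invoke(main, ["--seed", "2", "--out-dir", str(tmp_path),
                                   "synth-physio", "--load-step", "1"])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["--seed", "2", "--out-dir", str(tmp_path),
                                   "analyze", "--rr-csv", str(tmp_path / "rr.csv"),
                                   "--snirf", str(tmp_path / "fnirs.snirf")])
        assert res.exit_code == 0, res.output
        import json
        report = json.loads((tmp_path / "analysis.json").read_text())
        assert "hrv" in report and "activation" in report
        assert abs(report["activation"]["mean_beta"] - 0.5) < 0.15

    def test_run_study_command(self, tmp_path):
        from click.testing import CliRunner
        from flightload.cli import main
        runner = CliRunner()
        res = runner.invoke(main, ["--seed", "1", "--out-dir", str(tmp_path),
                                   "run-study", "--n-subjects", "4", "--no-figures"])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "anova.csv").exists()
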