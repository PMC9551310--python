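import math

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from periodsurv.cli import main
from periodsurv.config import RunConfig
from periodsurv.report import format_pct, render_tables, run_analysis, \
    write_outputs
from periodsurv.simulate import SimulationSpec, simulate_cohort, \
    simulate_lifetable


@pytest.fixture(scope="module")
def small_run():
    spec = SimulationSpec(periods=[(2004, 2008), (2009, 2013), (2014, 2018)],
                          n_per_period=1200, seed=4,
                          excess_hazard=np.full((1, 3), 0.06))
    lt = simulate_lifetable(spec)
    recs = simulate_cohort(spec, lt)
    return spec, lt, recs


class TestFormatting:
    @pytest.mark.parametrize("R,se,text", [
        (0.733, 0.003, "73.3 ± 0.3"),
        (0.752, None, "75.2"),
        (float("nan"), 0.01, "—"),
        (0.75249, float("nan"), "75.2"),
    ])
    def test_percent_cells(self, R, se, text):
        assert format_pct(R, se) == text


class TestRunAnalysis:
    def test_table_shape_by_sex_with_projection(self, small_run):
        _, lt, recs = small_run
        config = RunConfig(stratifiers=["sex"])
        result = run_analysis(config, lifetable=lt, records=recs)
        df = result.estimates
        crude = df[~df["standardized"]]
        # {overall, male, female} x {3 windows + 1 projection}
        assert set(crude["stratum"]) == {"overall", "male", "female"}
        assert len(crude) == 12
        proj = crude[crude["window"].str.startswith("projected")]
        assert set(proj["window"]) == {"projected:2019-2023"}
        assert proj["R"].notna().all()

    def test_empty_stratifier_list_gives_overall_only(self, small_run):
        _, lt, recs = small_run
        result = run_analysis(RunConfig(stratifiers=[]), lifetable=lt,
                              records=recs)
        assert set(result.estimates["stratum"]) == {"overall"}

    def test_standardized_rows_flagged(self, small_run):
        _, lt, recs = small_run
        config = RunConfig(stratifiers=["age_group"], standardize=True)
        result = run_analysis(config, lifetable=lt, records=recs)
        std = result.estimates[result.estimates["standardized"]]
        assert len(std) == 3  # one per window
        crude_overall = result.estimates[
            (result.estimates["stratum"] == "overall")
            & ~result.estimates["standardized"]
            & ~result.estimates["window"].str.startswith("projected")]
        # standardized and crude agree broadly but are distinct numbers
        for w, R_std in zip(std["window"], std["R"]):
            R_crude = crude_overall.loc[crude_overall["window"] == w, "R"].iloc[0]
            assert abs(R_std - R_crude) < 0.15

    def test_rerun_is_deterministic(self, small_run):
        _, lt, recs = small_run
        config = RunConfig(stratifiers=["sex"])
        a = run_analysis(config, lifetable=lt, records=recs)
        b = run_analysis(config, lifetable=lt, records=recs)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)

    def test_counts_table_partitions_cohort(self, small_run):
        _, lt, recs = small_run
        result = run_analysis(RunConfig(stratifiers=["sex"]), lifetable=lt,
                              records=recs)
        counts = result.counts
        overall = counts[counts["stratifier"] == "overall"]
        by_sex = counts[counts["stratifier"] == "sex"]
        for win in ("2004-2008", "2009-2013", "2014-2018"):
            assert by_sex[win].sum() == overall[win].iloc[0]


class TestRender:
    def test_csv_and_markdown_contain_identical_numbers(self, small_run):
        _, lt, recs = small_run
        result = run_analysis(RunConfig(stratifiers=["sex"]), lifetable=lt,
                              records=recs)
        csv_text = render_tables(result.estimates, "csv")
        md_text = render_tables(result.estimates, "markdown")
        import re
        nums = re.findall(r"\d+\.\d", csv_text)
        assert nums and all(n in md_text for n in nums)

    def test_undefined_cells_render_as_dash(self):
        df = pd.DataFrame([{"stratifier": "sex", "stratum": "male",
                            "standardized": False, "window": "2004-2008",
                            "R": math.nan, "se_R": math.nan,
                            "n_contributing": 0}])
        assert "—" in render_tables(df, "csv")


class TestCli:
    def test_simulate_then_report(self, tmp_path):
        runner = CliRunner()
        spec = {"periods": [[2009, 2013], [2014, 2018]], "n_per_period": 400,
                "seed": 9}
        spec_path = tmp_path / "spec.yaml"
        spec_path.write_text(yaml.safe_dump(spec))
        res = runner.invoke(main, ["simulate", "--spec", str(spec_path),
                                   "--out", str(tmp_path / "syn")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "syn" / "cases.csv").exists()

        config = {
            "cases": str(tmp_path / "syn" / "cases.csv"),
            "lifetable": str(tmp_path / "syn" / "lifetable.csv"),
            "output_dir": str(tmp_path / "out"),
            "windows": [{"mode": "period", "start": 2009, "end": 2013, "k": 5},
                        {"mode": "period", "start": 2014, "end": 2018, "k": 5}],
            "stratifiers": ["sex"],
        }
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        res = runner.invoke(main, ["report", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        out = tmp_path / "out"
        for name in ("estimates.csv", "table_survival.md", "table_counts.csv",
                     "filter_report.json", "config.resolved.yaml"):
            assert (out / name).exists()
        table = (out / "table_survival.md").read_text()
        assert "projected:2019-2023" in table

    def test_estimate_subcommand_prints_tidy_rows(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "--out", str(tmp_path / "s"),
                                   "--seed", "3"])
        assert res.exit_code == 0, res.output
        cfg = {"cases": str(tmp_path / "s" / "cases.csv"),
               "lifetable": str(tmp_path / "s" / "lifetable.csv"),
               "stratifiers": []}
        cfg_path = tmp_path / "c.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        res = runner.invoke(main, ["estimate", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert "2014-2018" in res.output


def test_write_outputs_round_trips_config(tmp_path, small_run):
    _, lt, recs = small_run
    config = RunConfig(stratifiers=["sex"], output_dir=str(tmp_path / "o"))
    result = run_analysis(config, lifetable=lt, records=recs)
    out = write_outputs(result, config)
    again = RunConfig.from_yaml(out / "config.resolved.yaml")
    assert again.windows == config.windows
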