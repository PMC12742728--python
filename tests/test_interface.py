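"""Ingest, descriptives, report writing and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from anthroweight import (
    IngestSchema,
    SyntheticConfig,
    describe_cohort,
    generate_cohort,
    read_records,
    run_validation,
    write_records,
    write_reports,
)
from anthroweight.cli import main as cli_main
from anthroweight.io import SchemaError
from anthroweight.records import RecordError


def write_csv(tmp_path, text, name="cohort.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


CSV_HEADER = "id,sex,age_years,weight_kg,height_cm,mac_cm,ac_cm,cc_cm,hc_cm,kh_cm,sst_mm"


class TestIngest:
    def test_clean_file_accepted(self, tmp_path):
        path = write_csv(tmp_path, "\n".join([
            CSV_HEADER,
            "p1,male,30,64.5,162.5,28.6,81.8,34.5,96.5,51.5,12",
            "p2,F,25,55.0,158.0,26.0,75.0,32.0,98.0,48.0,15",
        ]))
        records, log = read_records(path)
        assert log.n_accepted == 2 and log.n_rejected == 0
        assert list(records["sex"]) == ["male", "female"]  # F normalized

    def test_decimal_slip_height_rejected_with_reason(self, tmp_path):
        path = write_csv(tmp_path, "\n".join([
            CSV_HEADER,
            "p1,male,30,64.5,16.25,28.6,81.8,34.5,96.5,51.5,12",
            "p2,male,30,64.5,162.5,28.6,81.8,34.5,96.5,51.5,12",
        ]))
        records, log = read_records(path)
        assert log.n_accepted == 1
        (row, reason), = log.rejections
        assert row == 1 and "height" in reason and "16.25" in reason

    def test_non_numeric_and_missing_tokens(self, tmp_path):
        path = write_csv(tmp_path, "\n".join([
            CSV_HEADER,
            "p1,male,30,64.5,162.5,28.6,81.8,34.5,96.5,51.5,n/a",
            "p2,male,30,64.5,162.5,28.6,81.8,thirty,96.5,51.5,12",
        ]))
        records, log = read_records(path)
        assert log.n_accepted == 1
        assert np.isnan(records["sst"].iloc[0])  # token -> missing, row kept
        assert "cc" in log.rejections[0][1]

    def test_duplicate_ids_raise(self, tmp_path):
        path = write_csv(tmp_path, "\n".join([
            CSV_HEADER,
            "p1,male,30,64.5,162.5,28.6,81.8,34.5,96.5,51.5,12",
            "p1,female,25,55.0,158.0,26.0,75.0,32.0,98.0,48.0,15",
        ]))
        with pytest.raises(RecordError, match="duplicate"):
            read_records(path)

    def test_unmapped_required_column_is_schema_error(self, tmp_path):
        path = write_csv(tmp_path, "participant,weight\np1,60\n")
        with pytest.raises(SchemaError, match="'id'"):
            read_records(path)

    def test_custom_column_mapping(self, tmp_path):
        path = write_csv(tmp_path, "\n".join([
            "SubjID,Gender,Wt,Ht",
            "p1,2,64.5,162.5",
        ]))
        schema = IngestSchema(columns={
            "id": "SubjID", "sex": "Gender",
            "weight_kg": "Wt", "height_cm": "Ht"})
        records, log = read_records(path, schema)
        assert log.n_accepted == 1
        assert records["sex"].iloc[0] == "female"  # coded 2
        assert np.isnan(records["mac"].iloc[0])

    def test_xlsx_dialect(self, tmp_path):
        frame = pd.DataFrame({
            "id": ["p1"], "sex": ["male"], "age_years": [30],
            "weight_kg": [64.5], "height_cm": [162.5], "mac_cm": [28.6],
            "ac_cm": [81.8], "cc_cm": [34.5], "hc_cm": [96.5],
            "kh_cm": [51.5], "sst_mm": [12],
        })
        path = tmp_path / "cohort.xlsx"
        frame.to_excel(path, index=False)
        records, log = read_records(path)
        assert log.n_accepted == 1
        assert records["weight"].iloc[0] == 64.5


def test_csv_round_trip_exact(tmp_path, default_cohort):
    path = tmp_path / "out.csv"
    write_records(default_cohort, path)
    back, log = read_records(path)
    assert log.n_rejected == 0
    for col in ("weight", "height", "mac", "ac", "cc", "hc", "kh", "sst", "age"):
        assert np.array_equal(back[col].to_numpy(), default_cohort[col].to_numpy())


class TestDescribe:
    def test_single_record(self):
        df = pd.DataFrame([dict(id="a", sex="male", weight=70.0)])
        table = describe_cohort(df).set_index("variable")
        row = table.loc["weight"]
        assert row["all_median"] == row["all_q1"] == row["all_q3"] == 70.0
        assert row["female_n"] == 0 and np.isnan(row["female_median"])

    def test_linear_interpolation_quartiles(self):
        df = pd.DataFrame([
            dict(id=f"p{i}", sex="male", weight=w)
            for i, w in enumerate([1.0, 2.0, 3.0, 4.0])
        ])
        row = describe_cohort(df).set_index("variable").loc["weight"]
        assert row["all_median"] == 2.5
        assert row["all_q1"] == 1.75 and row["all_q3"] == 3.25

    def test_by_sex_split(self, default_cohort):
        table = describe_cohort(default_cohort).set_index("variable")
        assert table.loc["height", "male_n"] == 120
        assert table.loc["height", "male_median"] > table.loc[
            "height", "female_median"]


class TestReports:
    def test_bundle_shapes_and_manifest(self, default_cohort):
        bundle = run_validation(default_cohort)
        assert len(bundle.overall) == 9
        assert set(bundle.manifest["conventions"]) >= {
            "percent_error", "loa", "bmi_categories"}
        assert bundle.manifest["n_records"] == 240
        # subgroups: 2 sex + 4 nutrition strata per equation
        assert len(bundle.subgroups) == 9 * 6

    def test_written_reports_deterministic(self, tmp_path, default_cohort):
        bundle = run_validation(default_cohort)
        d1 = write_reports(bundle, tmp_path / "a")
        d2 = write_reports(bundle, tmp_path / "b")
        for name in ("overall_accuracy.csv", "subgroup_accuracy.csv",
                     "descriptives.csv", "report.json", "bland_altman_R3.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_display_rounding_two_decimals(self, tmp_path, default_cohort):
        out = write_reports(run_validation(default_cohort), tmp_path / "r")
        overall = pd.read_csv(out / "overall_accuracy.csv")
        assert ((overall["P10"] * 100).round() == overall["P10"] * 100).all()

    def test_bland_altman_export_has_reference_lines(self, tmp_path, default_cohort):
        out = write_reports(run_validation(default_cohort), tmp_path / "r")
        ba = pd.read_csv(out / "bland_altman_R3.csv")
        assert {"mean", "difference", "bias_line", "lloa_line",
                "uloa_line"} <= set(ba.columns)
        assert ba["bias_line"].nunique() == 1


class TestCli:
    def test_predict(self):
        result = CliRunner().invoke(cli_main, [
            "predict", "--equation", "R3", "--sex", "male",
            "--mac", "28.6", "--ac", "81.8", "--cc", "34.5"])
        assert result.exit_code == 0
        assert "64.69 kg" in result.output

    def test_predict_missing_variable_fails_cleanly(self):
        result = CliRunner().invoke(cli_main, [
            "predict", "--equation", "R3", "--sex", "male", "--mac", "28.6"])
        assert result.exit_code != 0
        assert "missing" in result.output

    def test_simulate_describe_validate_round_trip(self, tmp_path):
        runner = CliRunner()
        cohort_csv = tmp_path / "cohort.csv"
        result = runner.invoke(cli_main, [
            "simulate", "--seed", "3", "--out", str(cohort_csv)])
        assert result.exit_code == 0, result.output
        assert "240 records" in result.output

        result = runner.invoke(cli_main, ["describe", "--input", str(cohort_csv)])
        assert result.exit_code == 0
        assert "Weight (kg)" in result.output

        out_dir = tmp_path / "reports"
        result = runner.invoke(cli_main, [
            "validate", "--input", str(cohort_csv), "--out", str(out_dir)])
        assert result.exit_code == 0
        assert (out_dir / "overall_accuracy.csv").exists()
        assert (out_dir / "manifest.json").exists()
        manifest = json.loads((out_dir / "manifest.json").read_text())
        assert manifest["n_records"] == 240

    def test_validate_bad_file_nonzero_exit(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("foo,bar\n1,2\n")
        result = CliRunner().invoke(cli_main, [
            "validate", "--input", str(bad), "--out", str(tmp_path / "r")])
        assert result.exit_code != 0
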