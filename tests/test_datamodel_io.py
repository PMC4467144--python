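"""Domain-type invariants and tab-delimited round-trips."""

import numpy as np
import pandas as pd
import pytest

from etstargets import ExpressionMatrix, GeneSetReport, RunConfig, ValidationError
from etstargets import io as dio
from etstargets.datamodel import validate_annotations


def _frame(genes, samples, values):
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)


class TestExpressionMatrix:
    def test_shape_and_ids(self):
        m = ExpressionMatrix(_frame(["a", "b", "c"], ["s1", "s2"],
                                    np.arange(6.0).reshape(3, 2)))
        assert m.shape == (3, 2)
        assert m.gene_ids == ["a", "b", "c"]
        assert m.sample_ids == ["s1", "s2"]

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValidationError, match="duplicate gene id.*'a'"):
            ExpressionMatrix(_frame(["a", "a"], ["s1"], [[1.0], [2.0]]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            ExpressionMatrix(_frame(["a"], ["s1", "s2"], [[1.0, np.nan]]))


class TestMatrixIO:
    def test_round_trip_preserves_values_and_order(self, tmp_path):
        rng = np.random.default_rng(5)
        m = ExpressionMatrix(_frame(
            [f"g{i}" for i in range(20)], [f"s{j}" for j in range(4)],
            rng.normal(8, 2, size=(20, 4))))
        path = tmp_path / "expr.tsv"
        dio.write_expression_matrix(m, path)
        back = dio.read_expression_matrix(path)
        assert back.gene_ids == m.gene_ids
        assert back.sample_ids == m.sample_ids
        # >= 6 significant digits survive the text format
        assert np.allclose(back.data.to_numpy(), m.data.to_numpy(),
                           rtol=1e-6, atol=0)
        # loading twice yields equal objects (no hidden state)
        assert dio.read_expression_matrix(path) == back

    def test_duplicate_id_in_file(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\ts1\ng\t1.0\ng\t2.0\n")
        with pytest.raises(ValidationError, match="duplicate gene id"):
            dio.read_expression_matrix(path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ts2\nga\t1.0\t2.0\ngb\tx\t3.0\n")
        with pytest.raises(ValidationError, match="'gb'.*'s1'"):
            dio.read_expression_matrix(path)


class TestAnnotations:
    HEADER = ("sample_id\ttissue\tsubtype\tpea3_gene\tgleason_group\tstage"
              "\tage_years\tpsa_ng_ml\n")

    def test_typed_record(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(self.HEADER +
                        "S1\tPCa\tPEA3\tETV1\thigh\tpT3\t64\t8.2\n")
        table = dio.read_annotations(path)
        rec = table.loc["S1"]
        assert rec["subtype"] == "PEA3" and rec["stage"] == "pT3"
        assert rec["age_years"] == 64.0 and rec["psa_ng_ml"] == 8.2

    def test_npt_na_fields_allowed(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(self.HEADER + "N1\tNPT\tNA\tNA\tNA\tNA\t55\t1.1\n")
        table = dio.read_annotations(path)
        assert pd.isna(table.loc["N1", "stage"])

    def test_strict_category_dialect(self, tmp_path):
        path = tmp_path / "anno.tsv"
        path.write_text(self.HEADER + "S1\tPCa\tPEA3\tETV1\thigh\tT3\t64\t8.2\n")
        with pytest.raises(ValidationError, match="allowed: pT2, pT3"):
            dio.read_annotations(path)

    def test_npt_with_stage_rejected(self):
        table = pd.DataFrame(
            {"tissue": ["NPT"], "subtype": [None], "pea3_gene": [None],
             "gleason_group": [None], "stage": ["pT2"],
             "age_years": [60.0], "psa_ng_ml": [2.0]}, index=["N1"])
        with pytest.raises(ValidationError, match="must have stage = NA"):
            validate_annotations(table)


class TestGeneSetReport:
    def _report(self, rows):
        return GeneSetReport(members=pd.DataFrame(
            rows, columns=["gene", "provenance", "direction", "inverse"]))

    def test_empty_report_round_trip(self, tmp_path):
        report = self._report([])
        path = tmp_path / "empty.tsv"
        dio.write_gene_set_report(report, path)
        assert path.read_text().startswith("gene\tdirection\tprovenance")
        assert len(dio.read_gene_set_report(path).members) == 0

    def test_sorted_output_and_membership_round_trip(self, tmp_path):
        report = self._report([
            ("zz", "shared", "up", False),
            ("aa", "ETV1_specific", "down", False),
        ])
        path = tmp_path / "sets.tsv"
        dio.write_gene_set_report(report, path)
        lines = path.read_text().strip().splitlines()
        assert lines[1].startswith("aa") and lines[2].startswith("zz")
        back = dio.read_gene_set_report(path)
        assert back.gene_set("shared") == report.gene_set("shared")
        assert back.gene_set("ETV1_specific") == report.gene_set("ETV1_specific")

    def test_one_direction_per_provenance(self):
        with pytest.raises(ValidationError, match="appears twice"):
            self._report([("g", "shared", "up", False),
                          ("g", "shared", "down", False)])


class TestRunConfig:
    def test_study_defaults_valid(self):
        config = RunConfig()
        assert config.validate() == []
        assert config.non_study_settings() == []
        assert config.specific_fc == 1.5
        assert config.panel_rules == ((10.0, 1), (25.0, 2), (50.0, 4))

    def test_bad_values_aggregated(self):
        config = RunConfig(specific_fc=0.5, panel_rules=((0, 1), (25, 99)))
        errors = config.validate()
        assert any("specific_fc" in e for e in errors)
        assert any("percentile" in e for e in errors)
        assert any("exceeds panel size" in e for e in errors)

    def test_load_config_overrides_and_unknown_keys(self, tmp_path):
        path = tmp_path / "conf.yaml"
        path.write_text("specific_fc: 2.0\nalpha: 0.01\n")
        config = dio.load_config(path)
        assert config.specific_fc == 2.0 and config.alpha == 0.01
        assert set(config.non_study_settings()) == {"specific_fc", "alpha"}
        path.write_text("nonsense: 1\n")
        with pytest.raises(ValidationError, match="unknown config keys"):
            dio.load_config(path)


class TestCellLineModelIO:
    def test_round_trip(self, tmp_path, study_experiment):
        _, models, _ = study_experiment
        path = tmp_path / "models.tsv"
        dio.write_cellline_models(models, path)
        back = dio.read_cellline_models(path)
        assert sorted(m.name for m in back) == sorted(m.name for m in models)
        by_name = {m.name: m for m in back}
        for model in models:
            other = by_name[model.name]
            assert other.ets == model.ets and other.kind == model.kind
            assert set(other.control.sample_ids) == set(model.control.sample_ids)
            assert ({s for p in other.manipulated for s in p.sample_ids}
                    == {s for p in model.manipulated for s in p.sample_ids})
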