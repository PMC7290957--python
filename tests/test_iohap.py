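"""Haplotype-table I/O, QC filtering, DYS389 decomposition, built-in panels."""

from __future__ import annotations

import numpy as np
import pytest

from ystrdiff.errors import FormatError, ValidationError
from ystrdiff.iohap import (
    AlleleCall,
    HaplotypeTable,
    Locus,
    MarkerPanel,
    adjust_dys389,
    builtin_panels,
    qc_filter,
    read_haplotype_table,
)

from conftest import make_table


class TestAlleleCallParsing:
    @pytest.mark.parametrize(
        "token, kind, value",
        [
            ("13", "integer", 13),
            (14, "integer", 14),
            ("13.2", "intermediate", 13.2),
            (13.2, "intermediate", 13.2),
            ("17,18", "multi", (17, 18)),
            ("18,17", "multi", (17, 18)),  # canonical sorted order
            ("17/18/19", "multi", (17, 18, 19)),
            ("", "null", None),
            ("NA", "null", None),
            ("-", "null", None),
            ("14.0", "integer", 14),  # integral float collapses to integer
        ],
    )
    def test_cell_tokens(self, token, kind, value):
        call = AlleleCall.parse(token)
        assert call.kind == kind
        assert call.value == value

    def test_garbage_becomes_null_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            call = AlleleCall.parse("oops")
        assert call.kind == "null"
        assert "unparseable" in caplog.text

    def test_zero_repeat_count_is_rejected(self):
        with pytest.raises(ValidationError):
            AlleleCall("integer", 0)

    def test_roundtrip_through_str(self):
        for token in ("13", "13.2", "17,18", ""):
            assert str(AlleleCall.parse(str(AlleleCall.parse(token)))) == str(
                AlleleCall.parse(token)
            )


class TestReadHaplotypeTable:
    def _write(self, tmp_path, text, name="t.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_three_row_fixture(self, tmp_path):
        p = self._write(
            tmp_path,
            "sample\tpopulation\tDYS392\tDYS391\n"
            "s1\tA\t13\t10\n"
            "s2\tA\t14\t10\n"
            "s3\tB\t13\t11\n",
        )
        table = read_haplotype_table(p)
        assert table.n_samples == 3
        assert table.locus_names == ["DYS392", "DYS391"]
        assert table.populations == ["A", "B"]

    def test_intermediate_and_multi_cells(self, tmp_path):
        p = self._write(
            tmp_path,
            "sample\tpopulation\tDYS458\tDYS19\n"
            "s1\tA\t13.2\t17,18\n",
        )
        table = read_haplotype_table(p)
        assert table.calls_at("DYS458").iloc[0].kind == "intermediate"
        assert table.calls_at("DYS19").iloc[0] == AlleleCall("multi", (17, 18))

    def test_csv_dialect_from_extension(self, tmp_path):
        p = self._write(tmp_path, "sample,population,DYS392\ns1,A,13\n", "t.csv")
        assert read_haplotype_table(p).n_samples == 1

    def test_missing_header_is_format_error(self, tmp_path):
        p = self._write(tmp_path, "id\tpop\tDYS392\ns1\tA\t13\n")
        with pytest.raises(FormatError):
            read_haplotype_table(p)

    def test_duplicate_sample_id_is_validation_error(self, tmp_path):
        p = self._write(
            tmp_path,
            "sample\tpopulation\tDYS392\ns1\tA\t13\ns1\tB\t14\n",
        )
        with pytest.raises(ValidationError):
            read_haplotype_table(p)

    def test_tsv_roundtrip(self, tmp_path, messy_table):
        out = tmp_path / "round.tsv"
        messy_table.to_tsv(out)
        back = read_haplotype_table(out)
        assert back.n_samples == messy_table.n_samples
        for locus in messy_table.locus_names:
            assert list(back.calls_at(locus)) == list(messy_table.calls_at(locus))


class TestQcFilter:
    def test_clean_table_untouched(self, two_locus_table):
        panel = MarkerPanel("p", two_locus_table.locus_names)
        filtered, report = qc_filter(two_locus_table, panel)
        assert report.n_retained == report.n_input == 8
        assert all(v == 0 for v in report.removed_by_reason.values())
        assert filtered.n_samples == 8

    def test_single_null_among_clean(self, panel_two):
        rows = {
            "A": [[13, 20], [13, 21], [14, 20], [15, 20]],
        }
        table = make_table(rows, ["DYS392", "DYS448"])
        data = table.data.copy()
        data.iloc[0, data.columns.get_loc("DYS448")] = AlleleCall.null()
        table = HaplotypeTable(data, table.loci)
        filtered, report = qc_filter(table, panel_two)
        assert report.n_retained == 3
        assert report.removed_by_reason == {"null": 1, "intermediate": 0, "multi_allele": 0}

    def test_reason_precedence_null_first(self, messy_table, panel_two):
        # s5 has a null at one locus and a multi at another: counted as null
        _, report = qc_filter(messy_table, panel_two)
        assert report.removed_by_reason == {
            "null": 2,  # s2 and s5
            "intermediate": 1,  # s3
            "multi_allele": 1,  # s4
        }
        assert report.n_retained == 1

    def test_intermediate_beats_multi(self, panel_two):
        records = [
            (
                "s1",
                "A",
                {
                    "DYS392": AlleleCall("intermediate", 13.2),
                    "DYS448": AlleleCall("multi", (17, 18)),
                },
            )
        ]
        table = HaplotypeTable.from_records(records, ["DYS392", "DYS448"])
        _, report = qc_filter(table, panel_two)
        assert report.removed_by_reason["intermediate"] == 1
        assert report.removed_by_reason["multi_allele"] == 0

    def test_conservation_and_idempotence(self, messy_table, panel_two):
        filtered, report = qc_filter(messy_table, panel_two)
        assert report.n_input == report.n_retained + sum(report.removed_by_reason.values())
        refiltered, report2 = qc_filter(filtered, panel_two)
        assert report2.n_retained == report2.n_input
        assert refiltered.n_samples == filtered.n_samples

    def test_per_population_counts_sum_to_global(self, messy_table, panel_two):
        _, report = qc_filter(messy_table, panel_two)
        for reason in report.removed_by_reason:
            total = sum(c[reason] for c in report.removed_by_population.values())
            assert total == report.removed_by_reason[reason]

    def test_multi_copy_locus_is_not_a_removal_reason(self):
        records = [
            (
                "s1",
                "A",
                {
                    "DYS392": AlleleCall("integer", 13),
                    "DYS385a": AlleleCall("multi", (11, 14)),
                },
            )
        ]
        table = HaplotypeTable.from_records(records, ["DYS392", "DYS385a"])
        filtered, report = qc_filter(table, MarkerPanel("p", ["DYS392", "DYS385a"]))
        assert report.n_retained == 1

    def test_empty_panel_rejected(self, two_locus_table):
        with pytest.raises(ValidationError):
            qc_filter(two_locus_table, MarkerPanel("empty", []))

    def test_report_json_roundtrip(self, tmp_path, messy_table, panel_two):
        import json

        _, report = qc_filter(messy_table, panel_two)
        path = tmp_path / "qc.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["n_input"] == 5
        assert loaded["removed_by_reason"]["null"] == 2


class TestAdjustDys389:
    def _table(self, pairs):
        return make_table(
            {"A": [[a, b] for a, b in pairs]}, ["DYS389I", "DYS389II"]
        )

    def test_subtraction(self):
        table = self._table([(13, 29), (12, 30)])
        adjusted = adjust_dys389(table)
        vals = [c.value for c in adjusted.calls_at("DYS389II")]
        assert vals == [16, 18]
        # DYS389I untouched
        assert [c.value for c in adjusted.calls_at("DYS389I")] == [13, 12]

    def test_non_positive_difference_names_sample(self):
        table = self._table([(29, 13)])
        with pytest.raises(ValidationError, match="s0001"):
            adjust_dys389(table)

    def test_double_adjustment_refused(self):
        adjusted = adjust_dys389(self._table([(13, 29)]))
        assert adjusted.dys389_adjusted
        with pytest.raises(ValidationError):
            adjust_dys389(adjusted)

    def test_other_columns_preserved(self):
        table = make_table(
            {"A": [[13, 29, 24], [12, 28, 23]]}, ["DYS389I", "DYS389II", "DYS390"]
        )
        adjusted = adjust_dys389(table)
        assert [c.value for c in adjusted.calls_at("DYS390")] == [24, 23]
        assert adjusted.n_samples == table.n_samples


class TestBuiltinPanels:
    def test_sizes(self):
        panels = builtin_panels()
        assert len(panels["yfiler"]) == 17
        assert len(panels["yfiler_plus"]) == 27
        assert len(panels["single_copy_23"]) == 23

    def test_yfiler_single_copy_overlap_is_15(self):
        panels = builtin_panels()
        assert len(set(panels["yfiler"].loci) & set(panels["single_copy_23"].loci)) == 15

    def test_multi_copy_excluded_from_single_copy_panel(self):
        sc = builtin_panels()["single_copy_23"]
        for locus in ("DYS385a", "DYS385b", "DYF387S1a", "DYF387S1b"):
            assert locus not in sc

    def test_panel_file_roundtrip(self, tmp_path):
        panel = builtin_panels()["single_copy_23"]
        path = tmp_path / "sc.txt"
        panel.write(path)
        back = MarkerPanel.read(path)
        assert list(back) == list(panel)

    def test_duplicate_loci_rejected(self):
        with pytest.raises(ValidationError):
            MarkerPanel("bad", ["DYS392", "DYS392"])


class TestLocusValidation:
    @pytest.mark.parametrize("rate", [0.0, 1.0, -0.1])
    def test_mutation_rate_bounds(self, rate):
        with pytest.raises(ValidationError):
            Locus("DYS392", mutation_rate=rate)

    def test_valid_locus(self):
        locus = Locus("DYS392", mutation_rate=5e-4, in_yfiler=True)
        assert locus.copy_class == "single"
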