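"""Taxon-grouped coverage tables, length summaries, deterministic output."""

import pytest

from primerscope import (
    LengthSummary,
    MismatchCategory,
    ScreenResult,
    group_by_rank,
    length_summary,
    write_reports,
)
from primerscope.matching import AmpliconPrediction, PrimerSiteHit
from primerscope.report import UNASSIGNED, screen_table_tsv


def _result(tid, lineage, fwd, rev):
    return ScreenResult(
        target_id=tid, lineage=tuple(lineage),
        categories={"F": MismatchCategory(fwd), "R": MismatchCategory(rev)},
    )


def _pred(tid, insert):
    def hit(name, orient, offset, L=20):
        return PrimerSiteHit(target_id=tid, primer_name=name, orientation=orient,
                             offset=offset, footprint="A" * L, mismatch_count=0,
                             match_flags=(True,) * L)

    f = hit("F", "forward", 0)
    r = hit("R", "reverse", 20 + insert)
    return AmpliconPrediction(target_id=tid, forward=f, reverse=r,
                              insert_length=insert, total_length=insert + 40)


class TestGroupByRank:
    def test_uniform_cohort_is_one_row_at_100_percent(self):
        results = [_result(f"t{i}", ("Metazoa", "Testia"), "no_mismatch",
                           "no_mismatch") for i in range(7)]
        table = group_by_rank(results, rank=-1)
        assert table.groups == ("Testia",)
        row = table.frame.iloc[0]
        assert row["n"] == 7
        for p in ("F", "R"):
            assert row[f"{p}:no_mismatch:pct"] == 100.00
            assert row[f"{p}:no_mismatch:count"] == 7

    def test_planted_per_phylum_counts_match_generator_truth(
        self, small_dataset, small_records
    ):
        from primerscope import excise_all, screen_targets

        genes = excise_all(small_records)
        out = screen_targets(
            [small_dataset.forward_primer, small_dataset.reverse_primer],
            genes, rank=-1,
        )
        truth = small_dataset.truth
        frame = out.table.frame.set_index("group")
        for phylum, grp in truth.groupby("phylum"):
            row = frame.loc[phylum]
            assert row["n"] == len(grp)
            for col, primer in (("fwd_category", "SYNF"), ("rev_category", "SYNR")):
                for cat in ("no_mismatch", "one_mismatch", "two_or_more"):
                    assert row[f"{primer}:{cat}:count"] == (grp[col] == cat).sum()

    def test_rank_can_be_a_depth_or_a_name_collection(self):
        results = [
            _result("a", ("Metazoa", "Bilateria", "Xphora"), "no_mismatch", "one_mismatch"),
            _result("b", ("Metazoa", "Yzoa"), "no_mismatch", "no_mismatch"),
            _result("c", (), "two_or_more", "two_or_more"),
        ]
        by_depth = group_by_rank(results, rank=1)
        assert by_depth.groups == ("Bilateria", "Yzoa", UNASSIGNED)
        by_name = group_by_rank(results, rank={"Xphora", "Yzoa"})
        assert by_name.groups == ("Xphora", "Yzoa", UNASSIGNED)

    def test_grouping_partitions_the_cohort(self):
        results = [
            _result(f"t{i}", ("Metazoa", f"P{i % 3}"), "no_mismatch", "one_mismatch")
            for i in range(11)
        ]
        table = group_by_rank(results, rank=-1)
        assert table.total_n() == 11

    def test_row_percentages_sum_to_100_within_rounding(self):
        # 48-species row with a 1/4/43 split exercises the rounding bound
        results = (
            [_result(f"a{i}", ("M", "Px"), "no_mismatch", "two_or_more") for i in range(1)]
            + [_result(f"b{i}", ("M", "Px"), "one_mismatch", "two_or_more") for i in range(4)]
            + [_result(f"c{i}", ("M", "Px"), "two_or_more", "two_or_more") for i in range(43)]
        )
        table = group_by_rank(results, rank=-1)
        row = table.frame.iloc[0]
        for p in ("F", "R"):
            total = sum(row[f"{p}:{c}:pct"] for c in
                        ("no_mismatch", "one_mismatch", "two_or_more"))
            assert abs(total - 100.0) <= 0.02
        assert row["F:one_mismatch:pct"] == 8.33  # 4/48, printed to 2 decimals


class TestLengthSummary:
    def test_single_prediction(self):
        s = length_summary([_pred("t", 500)], band=(400, 600))
        assert (s.n, s.min_bp, s.max_bp, s.band_count) == (1, 500, 500, 1)

    def test_band_counts_and_extremes(self):
        s = length_summary([_pred("a", 300), _pred("b", 500), _pred("c", 700)],
                           band=(400, 600))
        assert (s.min_bp, s.max_bp, s.band_count) == (300, 700, 1)
        assert sum(s.bin_counts) == 3

    def test_planted_insert_lengths_match_generator_truth(
        self, small_dataset, small_records
    ):
        from primerscope import excise_all, screen_targets

        genes = excise_all(small_records)
        out = screen_targets(
            [small_dataset.forward_primer, small_dataset.reverse_primer],
            genes,
        )
        truth = small_dataset.truth
        assert out.lengths.n == len(truth)
        assert out.lengths.min_bp == truth["insert_length"].min()
        assert out.lengths.max_bp == truth["insert_length"].max()
        lo, hi = out.lengths.band
        assert out.lengths.band_count == truth["insert_length"].between(lo, hi).sum()

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            length_summary([])


class TestWriteReports:
    def _table(self):
        results = [
            _result("a", ("M", "P1"), "no_mismatch", "one_mismatch"),
            _result("b", ("M", "P1"), "no_mismatch", "no_mismatch"),
            _result("c", ("M", "P2"), "two_or_more", "no_mismatch"),
        ]
        return group_by_rank(results, rank=-1)

    def test_written_table_round_trips(self, tmp_path):
        import pandas as pd

        table = self._table()
        write_reports(tmp_path, table=table)
        back = pd.read_csv(tmp_path / "screen_table.tsv", sep="\t")
        assert list(back["group"]) == list(table.groups)
        assert list(back["n"]) == list(table.frame["n"])
        assert list(back["F.no_mismatch.pct"]) == [100.00, 0.00]

    def test_two_runs_are_byte_identical(self, tmp_path):
        table = self._table()
        summary = length_summary([_pred("a", 450), _pred("b", 820)])
        (tmp_path / "r1").mkdir(), (tmp_path / "r2").mkdir()
        write_reports(tmp_path / "r1", table=table, summary=summary)
        write_reports(tmp_path / "r2", table=table, summary=summary)
        for name in ("screen_table.tsv", "length_summary.tsv"):
            assert (tmp_path / "r1" / name).read_bytes() == \
                (tmp_path / "r2" / name).read_bytes()

    def test_screen_table_matches_golden_rendering(self):
        golden = (
            "group\tn\t"
            "F.no_mismatch.pct\tF.no_mismatch.count\t"
            "F.one_mismatch.pct\tF.one_mismatch.count\t"
            "F.two_or_more.pct\tF.two_or_more.count\t"
            "R.no_mismatch.pct\tR.no_mismatch.count\t"
            "R.one_mismatch.pct\tR.one_mismatch.count\t"
            "R.two_or_more.pct\tR.two_or_more.count\n"
            "P1\t2\t100.00\t2\t0.00\t0\t0.00\t0\t50.00\t1\t50.00\t1\t0.00\t0\n"
            "P2\t1\t0.00\t0\t0.00\t0\t100.00\t1\t100.00\t1\t0.00\t0\t0.00\t0\n"
        )
        assert screen_table_tsv(self._table()) == golden

    def test_profile_tsv_written_per_primer(self, tmp_path, small_dataset, small_records):
        from primerscope import excise_all, screen_targets

        genes = excise_all(small_records)
        out = screen_targets(
            [small_dataset.forward_primer, small_dataset.reverse_primer], genes
        )
        paths = write_reports(tmp_path, profiles=list(out.profiles.values()))
        names = {p.name for p in paths}
        assert {"positional_profile_SYNF.tsv", "positional_profile_SYNR.tsv"} <= names
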