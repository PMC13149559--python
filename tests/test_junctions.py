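"""Junction parsing, merging, exclusion sets, and percent-spliced values."""

import numpy as np
import pandas as pd
import pytest

from vusplice.junctions import (
    JunctionCountTable,
    SJParseError,
    SpliceJunction,
    build_exclusion_sets,
    merge_samples,
    parse_junction_tsv,
    parse_star_sj,
    percent_spliced,
    write_junction_tsv,
    write_star_sj,
)

from _oracles import brute_force_ps


def make_table(counts_by_junction, samples):
    records = [
        (j, s, c)
        for j, row in counts_by_junction.items()
        for s, c in zip(samples, row)
    ]
    return JunctionCountTable.from_records(records)


J12 = SpliceJunction("chr1", 1100, 1200, "+")
J23 = SpliceJunction("chr1", 1300, 1400, "+")
J13 = SpliceJunction("chr1", 1100, 1400, "+")


class TestStarSJ:
    def test_one_based_conversion_and_strand_codes(self, tmp_path):
        path = tmp_path / "s.SJ.out.tab"
        path.write_text("chr1\t1000\t1200\t1\t1\t1\t25\t3\t40\n")
        table = parse_star_sj(path, sample="s")
        (junction,) = table.junctions
        assert junction == SpliceJunction("chr1", 999, 1200, "+")
        assert table.counts.at[junction, "s"] == 25

    def test_multimapper_column_ignored_by_default_but_available(self, tmp_path):
        path = tmp_path / "s.SJ.out.tab"
        path.write_text("chr1\t1000\t1200\t2\t1\t1\t25\t3\t40\n")
        assert parse_star_sj(path).counts.iloc[0, 0] == 25
        assert parse_star_sj(path, include_multimappers=True).counts.iloc[0, 0] == 28

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.SJ.out.tab"
        path.write_text("")
        assert parse_star_sj(path).junctions == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.SJ.out.tab"
        path.write_text("chr1\t1000\t1200\t1\t1\t1\t25\t3\t40\nchr1\t5\t9\n")
        with pytest.raises(SJParseError, match=":2:"):
            parse_star_sj(path)

    @pytest.mark.parametrize("writer,parser", [
        (write_star_sj, parse_star_sj),
        (write_junction_tsv, parse_junction_tsv),
    ])
    def test_write_parse_round_trip(self, tmp_path, writer, parser):
        rng = np.random.default_rng(7)
        records = [
            (
                SpliceJunction("chr%d" % rng.integers(1, 4), int(a), int(a) + int(b),
                               rng.choice(["+", "-", "."])),
                "sample1",
                int(rng.integers(0, 500)),
            )
            for a, b in rng.integers(1, 10_000, size=(30, 2))
        ]
        # deduplicate junctions
        records = list({r[0]: r for r in records}.values())
        table = JunctionCountTable.from_records(records)
        path = tmp_path / "out.tab"
        writer(table, path)
        if parser is parse_star_sj:
            recovered = parser(path, sample="sample1")
        else:
            recovered = parser(path)
        assert sorted(recovered.junctions) == sorted(table.junctions)
        for j in table.junctions:
            assert recovered.counts.at[j, "sample1"] == table.counts.at[j, "sample1"]


class TestMerge:
    def test_shared_and_disjoint_junctions_zero_filled(self):
        t1 = make_table({J12: [10], J13: [5]}, ["a"])
        t2 = make_table({J12: [7], J23: [2]}, ["b"])
        merged = merge_samples([t1, t2])
        assert set(merged.junctions) == {J12, J23, J13}
        assert merged.counts.at[J23, "a"] == 0
        assert merged.counts.at[J13, "b"] == 0
        assert merged.counts.at[J12, "b"] == 7

    def test_duplicate_sample_id_rejected(self):
        t = make_table({J12: [1]}, ["a"])
        with pytest.raises(ValueError, match="duplicate sample"):
            merge_samples([t, t])

    def test_merge_preserves_per_sample_column_sums(self):
        rng = np.random.default_rng(11)
        tables = []
        for i in range(5):
            junctions = [
                SpliceJunction("chr1", int(a), int(a) + int(b))
                for a, b in rng.integers(1, 1000, size=(8, 2))
            ]
            records = [
                (j, f"s{i}", int(rng.integers(0, 99))) for j in set(junctions)
            ]
            tables.append(JunctionCountTable.from_records(records))
        merged = merge_samples(tables)
        for table in tables:
            sample = table.samples[0]
            assert merged.counts[sample].sum() == table.counts[sample].sum()


class TestExclusionSets:
    def test_adjacent_half_open_introns_do_not_overlap(self):
        a = SpliceJunction("chr1", 100, 200)
        b = SpliceJunction("chr1", 200, 300)
        exclusion = build_exclusion_sets([a, b])
        assert exclusion[a] == frozenset() and exclusion[b] == frozenset()

    def test_three_exon_gene_exclusion_structure(self):
        exclusion = build_exclusion_sets([J12, J23, J13])
        assert exclusion[J12] == frozenset({J13})
        assert exclusion[J23] == frozenset({J13})
        assert exclusion[J13] == frozenset({J12, J23})

    def test_never_self_member_and_symmetric(self):
        rng = np.random.default_rng(3)
        junctions = list({
            SpliceJunction("chr1", int(a), int(a) + int(b))
            for a, b in rng.integers(1, 300, size=(40, 2))
        })
        exclusion = build_exclusion_sets(junctions)
        for j, partners in exclusion.items():
            assert j not in partners
            for p in partners:
                assert j in exclusion[p]

    def test_opposite_strands_never_exclude_unknown_matches_both(self):
        plus = SpliceJunction("chr1", 100, 200, "+")
        minus = SpliceJunction("chr1", 150, 250, "-")
        unknown = SpliceJunction("chr1", 120, 220, ".")
        exclusion = build_exclusion_sets([plus, minus, unknown])
        assert minus not in exclusion[plus]
        assert exclusion[unknown] == frozenset({plus, minus})


class TestPercentSpliced:
    def test_no_competition_gives_ps_one(self):
        table = make_table({J12: [7]}, ["s"])
        ps = percent_spliced(table, build_exclusion_sets(table.junctions))
        assert ps.ps.at[J12, "s"] == 1.0

    def test_mutually_exclusive_pair(self):
        a = SpliceJunction("chr1", 100, 250)
        b = SpliceJunction("chr1", 200, 300)
        table = make_table({a: [30], b: [10]}, ["s"])
        ps = percent_spliced(table, build_exclusion_sets(table.junctions))
        assert ps.ps.at[a, "s"] == 0.75
        assert ps.ps.at[b, "s"] == 0.25

    def test_patient_skip_junction_usage(self):
        # exon-1-3 skip carrying 56 of 100 junction-spanning reads
        table = make_table({J13: [56], J12: [24], J23: [20]}, ["patient"])
        ps = percent_spliced(table, build_exclusion_sets(table.junctions))
        assert ps.ps.at[J13, "patient"] == pytest.approx(0.56)

    def test_zero_denominator_is_missing(self):
        table = make_table({J12: [0]}, ["s"])
        ps = percent_spliced(table, build_exclusion_sets(table.junctions))
        assert np.isnan(ps.ps.at[J12, "s"])

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(2, 50))
            keys = list({
                (
                    f"chr{rng.integers(1, 3)}",
                    int(a),
                    int(a) + int(b),
                    str(rng.choice(["+", "-", "."])),
                )
                for a, b in rng.integers(1, 500, size=(n, 2))
            })
            counts = {k: [int(c) for c in rng.integers(0, 50, size=3)] for k in keys}
            junctions = [SpliceJunction(*k) for k in keys]
            table = JunctionCountTable.from_records(
                (j, f"s{i}", counts[k][i])
                for j, k in zip(junctions, keys)
                for i in range(3)
            )
            ps = percent_spliced(table, build_exclusion_sets(junctions))
            expected = brute_force_ps(keys, counts)
            for j, k in zip(junctions, keys):
                for i, sample in enumerate(["s0", "s1", "s2"]):
                    got = ps.ps.at[j, sample]
                    want = expected[k][i]
                    assert (want is None and np.isnan(got)) or got == want

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(23)
        junctions = [J12, J23, J13]
        table = make_table({j: [int(c)] for j, c in
                            zip(junctions, rng.integers(1, 100, 3))}, ["s"])
        shuffled = JunctionCountTable(table.counts.iloc[[2, 0, 1]])
        ps1 = percent_spliced(table, build_exclusion_sets(table.junctions))
        ps2 = percent_spliced(shuffled, build_exclusion_sets(shuffled.junctions))
        for j in junctions:
            assert ps1.ps.at[j, "s"] == ps2.ps.at[j, "s"]

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(29)
        junctions = list({
            SpliceJunction("chr1", int(a), int(a) + int(b))
            for a, b in rng.integers(1, 200, size=(25, 2))
        })
        table = JunctionCountTable.from_records(
            (j, "s", int(rng.integers(0, 30))) for j in junctions
        )
        ps = percent_spliced(table, build_exclusion_sets(junctions))
        values = ps.ps.to_numpy()
        finite = values[np.isfinite(values)]
        assert ((finite >= 0) & (finite <= 1)).all()
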