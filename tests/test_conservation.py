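from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efeflux.conservation import (
    Alignment,
    AlignmentFormatError,
    column_to_ref_position,
    conserved_columns,
    find_triads,
    read_alignment,
    write_alignment,
)
from efeflux.synthetic import GeneratorConfig, gen_alignment


def aln(*rows: str, ids=None) -> Alignment:
    ids = tuple(ids or [f"s{i}" for i in range(len(rows))])
    return Alignment(ids=ids, rows=tuple(rows))


class TestReadWriteAlignment:
    def test_two_identical_records(self, tmp_path: Path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMKVLHDTTAG\n>y\nMKVLHDTTAG\n")
        a = read_alignment(p)
        assert a.length == 10 and a.n_seqs == 2

    def test_dots_normalized_and_uppercased(self, tmp_path: Path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nmk.l\n>y\nMKGL\n")
        assert read_alignment(p).rows[0] == "MK-L"

    def test_unequal_lengths_name_offender(self, tmp_path: Path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nMKVL\n>bad\nMKV\n")
        with pytest.raises(AlignmentFormatError, match="bad"):
            read_alignment(p)

    def test_empty_file_is_a_format_error(self, tmp_path: Path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(AlignmentFormatError):
            read_alignment(p)

    def test_synthetic_fixture_round_trips(self, tmp_path: Path):
        a = gen_alignment(GeneratorConfig(seed=7, n_seqs=5, length=60, n_conserved=5, triad_positions=None))
        p = tmp_path / "synth.fasta"
        write_alignment(a, p)
        assert read_alignment(p) == a


class TestConservedColumns:
    def test_identical_sequences_fully_conserved(self):
        a = aln("MKVL", "MKVL", "MKVL")
        cols = conserved_columns(a, threshold=1.0)
        assert [c for c, _, _ in cols] == [1, 2, 3, 4]

    def test_single_mismatch_excluded_at_full_threshold(self):
        a = aln("MKVL", "MKAL")
        assert [c for c, _, _ in conserved_columns(a, 1.0)] == [1, 2, 4]

    def test_gaps_do_not_count_toward_conservation(self):
        a = aln("M-VL", "MKVL", "MKVL")
        cols = dict((c, frac) for c, _, frac in conserved_columns(a, 0.5))
        assert cols[2] == 1.0  # two K over two non-gap rows

    def test_planted_fixture_returns_exactly_the_planted_columns(self):
        cfg = GeneratorConfig(
            seed=11, n_seqs=10, length=200, n_conserved=17, noise=0.4,
            triad_positions=(50, 52, 120),
        )
        a = gen_alignment(cfg)
        cols = [c for c, _, _ in conserved_columns(a, 1.0)]
        assert len(cols) == 17
        assert {50, 52, 120} <= set(cols)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_threshold_domain_error(self, bad):
        with pytest.raises(ValueError):
            conserved_columns(aln("MK"), threshold=bad)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        t_hi=st.floats(0.5, 1.0),
        t_lo=st.floats(0.05, 0.5),
    )
    def test_monotone_in_threshold(self, seed, t_hi, t_lo):
        """Lowering the threshold never removes a conserved column."""
        a = gen_alignment(GeneratorConfig(seed=seed, n_seqs=6, length=40, n_conserved=4, noise=0.3, triad_positions=None))
        hi = {c for c, _, _ in conserved_columns(a, t_hi)}
        lo = {c for c, _, _ in conserved_columns(a, t_lo)}
        assert hi <= lo


class TestColumnToRefPosition:
    def test_ungapped_reference_is_identity(self):
        a = aln("MKVL", "MKVA", ids=["ref", "s1"])
        for col in range(1, 5):
            assert column_to_ref_position(a, "ref", col) == col

    def test_gapped_reference_skips_gaps(self):
        a = aln("A-CD", "AGCD", ids=["ref", "s1"])
        assert column_to_ref_position(a, "ref", 3) == 2

    def test_gap_at_column_is_an_error(self):
        a = aln("A-CD", "AGCD", ids=["ref", "s1"])
        with pytest.raises(ValueError):
            column_to_ref_position(a, "ref", 2)

    def test_agrees_with_naive_recount_on_random_gapped_rows(self):
        from efeflux.synthetic import LCG

        rng = LCG(5)
        for _ in range(20):
            row = "".join(rng.choice("ACDEF-") for _ in range(30))
            if set(row) == {"-"}:
                continue
            a = aln(row, row.replace("-", "G"), ids=["ref", "s1"])
            for col in range(1, 31):
                if row[col - 1] == "-":
                    continue
                naive = sum(1 for c in row[:col] if c != "-")
                assert column_to_ref_position(a, "ref", col) == naive


class TestFindTriads:
    def test_recovers_planted_kudzu_style_triad(self):
        """H189 / D191 / H268: spacing 79, inside the default 40..120 window."""
        a = gen_alignment(GeneratorConfig(seed=1, triad_positions=(189, 191, 268), noise=0.3))
        hits = find_triads(a, "ref", threshold=1.0)
        assert [t.ref_positions for t in hits] == [(189, 191, 268)]
        assert hits[0].spacing == 79

    def test_accepts_petunia_style_spacing(self):
        """H177 / D179 / H234: spacing 57 also fits the default window."""
        a = gen_alignment(
            GeneratorConfig(seed=2, length=300, triad_positions=(177, 179, 234), noise=0.3)
        )
        hits = find_triads(a, "ref", threshold=1.0)
        assert [t.ref_positions for t in hits] == [(177, 179, 234)]
        assert hits[0].spacing == 57

    def test_alignment_without_histidines_yields_nothing(self):
        a = aln("MKVLDECAT" * 20, "MKVLDECAT" * 20, ids=["ref", "s1"])
        assert find_triads(a, "ref") == []

    def test_spacing_window_is_enforced(self):
        a = gen_alignment(GeneratorConfig(seed=3, triad_positions=(100, 102, 150), noise=0.0))
        assert find_triads(a, "ref", window=(60, 120)) == []
        assert len(find_triads(a, "ref", window=(40, 120))) == 1

    def test_ref_positions_respect_reference_gaps(self):
        rows = ["--HADALLLH", "GGHADALLLH"]
        a = aln(*rows, ids=["ref", "s1"])
        hits = find_triads(a, "ref", window=(1, 20), threshold=1.0)
        assert [t.ref_positions for t in hits] == [(1, 3, 8)]
        assert hits[0].his1 == 3  # alignment column, 1-based

    def test_missing_reference_raises(self):
        a = aln("HAD", "HAD")
        with pytest.raises(KeyError):
            find_triads(a, "nope")
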