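import numpy as np
import pytest

from codonscan.filters import (
    BacktranslationError,
    DegenerateAlignmentError,
    backtranslate,
    clean_gapped_columns,
    conserved_block_filter,
    singleton_window_filter,
)
from codonscan.io import SequenceRecord

from conftest import make_aa, make_codon


def _window_alignment(n_diff: int):
    """15-column alignment: five identical rows plus species X differing
    (uniquely) in ``n_diff`` columns, spread so that no 5-column run is all
    singletons (isolates the long-window rule from the short one)."""
    positions = [c for c in range(15) if c % 5 != 4][:n_diff]
    x = "".join("W" if c in positions else "A" for c in range(15))
    rows = {f"s{i}": "A" * 15 for i in range(5)}
    rows["X"] = x
    return make_aa(rows)


class TestSingletonWindows:
    def test_ten_singletons_in_window_drop_all_fifteen(self):
        keep = singleton_window_filter(_window_alignment(10))
        assert not keep.any()

    def test_nine_singletons_keep_everything(self):
        keep = singleton_window_filter(_window_alignment(9))
        assert keep.all()

    def test_five_consecutive_singleton_columns_dropped(self):
        # 5-wide alignment, each column has a singleton in a different row
        rows = {
            "a": "WAAAA",
            "b": "AWAAA",
            "c": "AAWAA",
            "d": "AAAWA",
            "e": "AAAAW",
        }
        keep = singleton_window_filter(make_aa(rows))
        assert not keep.any()

    def test_four_of_five_singletons_kept_by_short_pass(self):
        rows = {
            "a": "WAAAA",
            "b": "AWAAA",
            "c": "AAWAA",
            "d": "AAAWA",
            "e": "AAAAA",
        }
        keep = singleton_window_filter(make_aa(rows))
        assert keep.all()

    def test_window_longer_than_alignment_is_noop(self):
        rows = {"a": "WW", "b": "AA", "c": "AA"}
        assert singleton_window_filter(make_aa(rows)).all()

    def test_gap_is_not_a_singleton(self):
        rows = {
            "a": "-AAAA",
            "b": "A-AAA",
            "c": "AA-AA",
            "d": "AAA-A",
            "e": "AAAA-",
        }
        assert singleton_window_filter(make_aa(rows)).all()


class TestConservedBlocks:
    def test_identical_gapfree_alignment_kept(self):
        aln = make_aa({"a": "M" * 20, "b": "M" * 20})
        assert conserved_block_filter(aln).all()

    def test_majority_gap_column_dropped(self):
        rows = {"a": "M" * 20, "b": "M" * 20, "c": "M" * 10 + "-" * 10}
        # gap fraction per tail column is 1/3 <= 0.5: kept; push to 2/3
        rows["d"] = "M" * 10 + "-" * 10
        rows["e"] = "M" * 20
        aln = make_aa(rows)
        keep = conserved_block_filter(aln, min_block=1, max_gap_fraction=0.3)
        assert keep[:10].all() and not keep[10:].any()

    def test_short_good_run_dropped(self):
        # 9 good columns flanked by bad (all-different) columns
        good = "M" * 9
        rows = {
            "a": "A" + good + "C",
            "b": "C" + good + "D",
            "c": "D" + good + "E",
            "d": "E" + good + "F",
        }
        keep = conserved_block_filter(make_aa(rows), min_block=10)
        assert not keep.any()

    def test_run_meeting_min_block_kept(self):
        good = "M" * 10
        rows = {
            "a": "A" + good,
            "b": "C" + good,
            "c": "D" + good,
            "d": "E" + good,
        }
        keep = conserved_block_filter(make_aa(rows), min_block=10)
        assert not keep[0] and keep[1:].all()


class TestBacktranslate:
    def test_gap_becomes_triple_dash(self):
        aa = make_aa({"s": "M-K"})
        cds = {"s": SequenceRecord("s", "ATGAAA")}
        out = backtranslate(aa, cds)
        assert list(out.codons[0]) == ["ATG", "---", "AAA"]

    def test_mismatch_reports_species_and_position(self):
        aa = make_aa({"s": "MK"})
        cds = {"s": SequenceRecord("s", "ATGGGG")}
        with pytest.raises(BacktranslationError, match="s.*position 2"):
            backtranslate(aa, cds)

    def test_terminal_stop_dropped(self):
        aa = make_aa({"s": "M"})
        cds = {"s": SequenceRecord("s", "ATGTAA")}
        out = backtranslate(aa, cds)
        assert list(out.codons[0]) == ["ATG"]

    def test_out_of_frame_cds_rejected(self):
        aa = make_aa({"s": "M"})
        cds = {"s": SequenceRecord("s", "ATGA")}
        with pytest.raises(BacktranslationError, match="divisible"):
            backtranslate(aa, cds)

    def test_round_trip_translation(self):
        from Bio.Seq import Seq

        aa = make_aa({"x": "MKV-W", "y": "MR-LW"})
        cds = {
            "x": SequenceRecord("x", "ATGAAAGTGTGG"),
            "y": SequenceRecord("y", "ATGCGGCTTTGG"),
        }
        out = backtranslate(aa, cds)
        for i, taxon in enumerate(out.taxa):
            resurrected = "".join(
                str(Seq(c).translate()) if c != "---" else "-" for c in out.codons[i]
            )
            assert resurrected == aa.row(taxon)


class TestCleanGapped:
    def test_column_with_gap_removed(self):
        codon = make_codon({"a": "ATG---AAA", "b": "ATGTTTAAA"})
        out = clean_gapped_columns(codon)
        assert out.width == 2
        assert list(out.codons[0]) == ["ATG", "AAA"]

    def test_gapfree_identity(self):
        codon = make_codon({"a": "ATGAAA", "b": "ATGCCC"})
        out = clean_gapped_columns(codon)
        assert (out.codons == codon.codons).all()

    def test_all_columns_gapped_is_degenerate(self):
        codon = make_codon({"a": "---ATG", "b": "ATG---"})
        with pytest.raises(DegenerateAlignmentError):
            clean_gapped_columns(codon)

    def test_stop_codon_column_removed(self):
        codon = make_codon({"a": "TGAAAA", "b": "ATGAAA"})
        out = clean_gapped_columns(codon)
        assert out.width == 1


class TestMaskAudit:
    def test_mask_file_round_trip(self, tmp_path):
        import numpy as np
        from codonscan.filters import read_column_mask, write_column_mask

        keep = np.array([True, False, True, True, False])
        p = tmp_path / "mask.tsv"
        write_column_mask(keep, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "column\tdecision"
        assert lines[2] == "2\tdrop"
        assert (read_column_mask(p) == keep).all()


class TestMaskComposition:
    def test_union_of_drops_is_order_independent(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        chars = letters[rng.integers(0, len(letters), size=(6, 40))]
        aln = make_aa({f"s{i}": "".join(chars[i]) for i in range(6)})
        k1 = conserved_block_filter(aln)
        k2 = singleton_window_filter(aln)
        assert ((k1 & k2) == (k2 & k1)).all()

    def test_filters_only_delete_columns(self):
        aln = _window_alignment(3)
        keep = singleton_window_filter(aln)
        kept = aln.chars[:, keep]
        # every kept column appears unchanged at its original position
        j = 0
        for orig_col in range(aln.width):
            if keep[orig_col]:
                assert (kept[:, j] == aln.chars[:, orig_col]).all()
                j += 1
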