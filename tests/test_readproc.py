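import pytest

import mtasepref as mp
from mtasepref.dna import reverse_complement
from mtasepref.readproc import PAIR_TABLE
from conftest import raw_from_records


def _read(seq, q=37):
    return mp.RawRead("r0", seq, [q] * len(seq))


class TestTrim:
    def test_long_read_truncated_to_128(self):
        out = mp.trim_reads([_read("A" * 160)])
        assert len(out[0].sequence) == 128
        assert len(out[0].quality) == 128

    def test_short_read_unchanged(self):
        out = mp.trim_reads([_read("A" * 100)])
        assert out[0].sequence == "A" * 100

    def test_empty_read_passes_through(self):
        out = mp.trim_reads([mp.RawRead("e", "", [])])
        assert out[0].sequence == ""


class TestQualityFilter:
    def test_mean_quality_threshold(self):
        high = _read("A" * 10, q=37)
        low = _read("A" * 10, q=10)
        kept, removed = mp.quality_filter([high, low], min_q=20)
        assert kept == [high] and removed == 1

    def test_boundary_is_inclusive(self):
        # mean exactly 20.0 kept, 19.9 removed
        q_pass = [20] * 10
        q_fail = [20] * 9 + [19]  # mean 19.9
        passing = mp.RawRead("p", "A" * 10, q_pass)
        failing = mp.RawRead("f", "A" * 10, q_fail)
        kept, _ = mp.quality_filter([passing, failing], min_q=20)
        assert kept == [passing]

    def test_per_base_mode(self):
        mixed = mp.RawRead("m", "AAAA", [37, 37, 19, 37])
        kept, _ = mp.quality_filter([mixed], min_q=20, per_base=True)
        assert kept == []
        kept, _ = mp.quality_filter([mixed], min_q=20, per_base=False)
        assert kept == [mixed]


class TestDeduplicate:
    def test_identical_sequences_collapse_to_first(self):
        reads = [_read("ACGT"), _read("ACGT"), _read("ACGT"), _read("TTTT")]
        kept, n_dup = mp.deduplicate(reads)
        assert [r.sequence for r in kept] == ["ACGT", "TTTT"]
        assert n_dup == 2

    def test_all_distinct_unchanged(self):
        reads = [_read("AAAA"), _read("CCCC")]
        kept, n_dup = mp.deduplicate(reads)
        assert kept == reads and n_dup == 0

    def test_simulated_duplicates_match_manifest(self, gcgc_design, gcgc_model):
        reads, _ = mp.simulate_experiment(
            gcgc_design, gcgc_model, 10_000, 0.4, seed=13,
            conv_rate=1.0, duplicate_fraction=0.2, duplicate_copies=2,
        )
        raw = raw_from_records(reads)
        n_unique = len({r.sequence for r in raw})
        kept, n_dup = mp.deduplicate(raw)
        assert len(kept) == n_unique
        assert n_dup == len(raw) - n_unique


class TestReconstruction:
    def test_truth_table_is_the_documented_one(self):
        assert PAIR_TABLE[("T", "C")][0:2] == ("C", False)
        assert PAIR_TABLE[("C", "C")][0:2] == ("C", True)
        assert PAIR_TABLE[("G", "A")] == ("G", None, False)
        assert PAIR_TABLE[("G", "G")] == ("G", None, True)
        assert ("G", "T") not in PAIR_TABLE

    def _hairpin(self, design, window, meth=False, conv=True):
        """Build a noise-free hairpin read for a given original window."""
        top = design.left_arm + window + design.right_arm[: design.right_keep]
        full = top + design.stem_loop + reverse_complement(top)
        tcol = design.window_start + design.target_offset
        if conv:
            out = []
            for i, b in enumerate(full):
                if b == "C" and not (meth and i == tcol):
                    out.append("T")
                else:
                    out.append(b)
            full = "".join(out)
        return _read(full)

    def test_unmethylated_target_recovered(self, gcgc_design):
        window = "AAAAATTTT" + "GCGC" + "CCCGGGAAA"
        res = mp.reconstruct_and_call(self._hairpin(gcgc_design, window), gcgc_design)
        assert isinstance(res, mp.ProcessedRead)
        assert res.original_sequence == window
        assert res.target_methylated is False
        # non-target top-strand Cs called unmethylated
        assert res.other_c_calls == {12: False, 13: False, 14: False, 15: False}

    def test_methylated_target_recovered(self, gcgc_design):
        window = "AAAAATTTT" + "GCGC" + "AAAAAAAAA"
        read = self._hairpin(gcgc_design, window, meth=True)
        res = mp.reconstruct_and_call(read, gcgc_design)
        assert res.target_methylated is True

    def test_strand_mismatch_rejected(self, gcgc_design):
        window = "AAAAATTTT" + "GCGC" + "AAAAAAAAA"
        read = self._hairpin(gcgc_design, window)
        # corrupt one variable-window base on the top strand: (C,A) pair
        seq = list(read.sequence)
        seq[gcgc_design.window_start] = "C"  # was A; bottom still says A
        res = mp.reconstruct_and_call(mp.RawRead("r0", "".join(seq), [37] * len(seq)),
                                      gcgc_design)
        assert isinstance(res, mp.Rejection)
        assert res.reason == "mismatch"

    def test_ambiguous_base_rejected(self, gcgc_design):
        window = "AAAAATTTT" + "GCGC" + "AAAAAAAAA"
        read = self._hairpin(gcgc_design, window)
        seq = list(read.sequence)
        seq[gcgc_design.window_start + 2] = "N"
        res = mp.reconstruct_and_call(mp.RawRead("r0", "".join(seq), [37] * len(seq)),
                                      gcgc_design)
        assert isinstance(res, mp.Rejection)
        assert res.reason == "ambiguous_base"

    def test_truncated_read_rejected(self, gcgc_design):
        window = "AAAAATTTT" + "GCGC" + "AAAAAAAAA"
        read = self._hairpin(gcgc_design, window)
        short = mp.RawRead("r0", read.sequence[:100], [37] * 100)
        res = mp.reconstruct_and_call(short, gcgc_design)
        assert res.reason == "truncated"

    def test_corrupted_anchor_rejected(self, gcgc_design):
        window = "AAAAATTTT" + "GCGC" + "AAAAAAAAA"
        read = self._hairpin(gcgc_design, window)
        seq = list(read.sequence)
        seq[0], seq[1] = "T", "C"  # two mismatches in the left arm anchor
        res = mp.reconstruct_and_call(mp.RawRead("r0", "".join(seq), [37] * len(seq)),
                                      gcgc_design)
        assert isinstance(res, mp.Rejection)
        assert res.reason == "anchor_left"


class TestRoundTrip:
    def test_clean_simulation_recovers_everything(self, clean_dataset):
        """Conversion 1, no errors: every flank and methylation bit matches
        the simulator manifest."""
        man = clean_dataset["manifest"].table.set_index("molecule_id")
        processed = clean_dataset["processed"]
        stats = clean_dataset["stats"]
        assert stats.n_accepted == stats.n_input
        for p in processed:
            assert p.original_sequence == man.at[p.read_id, "window"]
            assert p.target_methylated == bool(man.at[p.read_id, "methylated"])

    def test_stage_ledger_conserved(self, gcgc_design, gcgc_model):
        reads, _ = mp.simulate_experiment(
            gcgc_design, gcgc_model, 2000, 0.4, seed=3,
            conv_rate=0.99, error_rate=0.01,
        )
        processed, s = mp.process_reads(raw_from_records(reads), gcgc_design)
        assert (
            s.n_after_trim
            == s.n_quality_fail + s.n_duplicates
            + sum(s.rejections.values()) + s.n_accepted
        )

    def test_wrong_acceptances_bounded_by_error_analysis(self, gcgc_design, gcgc_model):
        """Accepted-but-wrong reconstructions stay within the analytic
        strand-agreement bound.

        After bisulfite conversion only one substitution channel per position
        yields a valid-but-wrong pair (e.g. a top-strand A read as G mimics a
        true G), so the wrong-flank probability per read is ~ W * e/3.  A
        clean run must have zero wrong acceptances.
        """
        for e, bound in [(0.0, 0), (0.01, 4000 * 22 * (0.01 / 3) * 1.5)]:
            reads, man = mp.simulate_experiment(
                gcgc_design, gcgc_model, 4000, 0.4, seed=5,
                conv_rate=1.0, error_rate=e,
            )
            processed, _ = mp.process_reads(raw_from_records(reads), gcgc_design)
            tab = man.table.set_index("molecule_id")
            wrong = sum(
                p.original_sequence != tab.at[p.read_id, "window"]
                for p in processed
            )
            assert wrong <= bound


def test_processed_tsv_roundtrip(tmp_path, clean_dataset):
    from mtasepref.readproc import read_processed_tsv, write_processed_tsv

    processed = mp.assign_motif_variants(
        clean_dataset["processed"][:50], clean_dataset["design"], "GCGC", 2
    )
    path = tmp_path / "processed.tsv"
    write_processed_tsv(processed, path)
    back = read_processed_tsv(path)
    assert [p.original_sequence for p in back] == [
        p.original_sequence for p in processed
    ]
    assert [p.target_methylated for p in back] == [
        p.target_methylated for p in processed
    ]
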