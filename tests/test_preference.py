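import math
from collections import Counter

import numpy as np
import pytest

import mtasepref as mp
from mtasepref.preference import OEProfile, complex_effect_scan


def _processed(window, methylated, rid="r"):
    return mp.ProcessedRead(
        read_id=rid, original_sequence=window, motif_variant="",
        target_methylated=methylated,
    )


def _profile_from(oe_rows, motif="CG", target_index=1):
    """Build an OEProfile directly from an {position: (A,C,G,T)} dict."""
    import pandas as pd

    idx = list(oe_rows)
    oe = pd.DataFrame(
        [oe_rows[p] for p in idx], index=idx, columns=list("ACGT"), dtype=float
    )
    uniform = oe * 0 + 0.25
    return OEProfile(
        motif=motif, target_index=target_index, oe=oe, pool_freq=uniform,
        methylated_counts=oe * 0, total_counts=oe * 0,
        n_methylated=10, n_total=20,
    )


class TestOEProfile:
    def _toy_pool(self, cn_library_design):
        """8 CG reads uniform at position -1 (2 each base); methylated subset =
        both C reads plus one T read."""
        d = cn_library_design
        off = d.flank_offset(-1, "CG", 1)
        reads = []
        for i, base in enumerate("AACCGGTT"):
            w = list("A" * d.window_len)
            w[d.target_offset] = "C"
            w[d.target_offset + 1] = "G"
            w[off] = base
            meth = base == "C" or (base == "T" and i == 6)
            reads.append(_processed("".join(w), meth, rid=f"r{i}"))
        return reads

    def test_hand_counted_oe_values(self, cn_library_design):
        reads = self._toy_pool(cn_library_design)
        prof = mp.oe_profile(reads, cn_library_design, "CG", 1, positions=[-1])
        assert prof.n_total == 8 and prof.n_methylated == 3
        assert prof.oe.at[-1, "C"] == pytest.approx((2 / 3) / (1 / 4))
        assert prof.oe.at[-1, "T"] == pytest.approx((1 / 3) / (1 / 4))
        assert prof.oe.at[-1, "A"] == 0.0
        assert prof.oe.at[-1, "G"] == 0.0

    def test_identical_composition_gives_unit_oe(self, cn_library_design):
        d = cn_library_design
        reads = []
        for i, base in enumerate("ACGT"):
            for meth in (True, False):
                w = list("A" * d.window_len)
                w[d.target_offset], w[d.target_offset + 1] = "C", "G"
                w[d.flank_offset(+1, "CG", 1)] = base
                reads.append(_processed("".join(w), meth, rid=f"r{i}{meth}"))
        prof = mp.oe_profile(reads, d, "CG", 1, positions=[+1])
        assert np.allclose(prof.oe.loc[+1], 1.0)

    def test_weighted_mean_normalization(self, clean_dataset):
        """sum_N o/e_N * pool_freq_N = 1 at every position."""
        prof = mp.oe_profile(
            clean_dataset["processed"], clean_dataset["design"], "GCGC", 2,
            positions=mp.default_positions(6),
        )
        weighted = (prof.oe * prof.pool_freq).sum(axis=1)
        assert np.allclose(weighted, 1.0, atol=1e-9)

    def test_streaming_equals_bruteforce_recount(self, clean_dataset):
        """Count-based o/e equals an independent recount over the read list."""
        reads = clean_dataset["processed"][:1000]
        d = clean_dataset["design"]
        positions = mp.default_positions(3)
        prof = mp.oe_profile(reads, d, "GCGC", 2, positions=positions)
        for p in positions:
            off = d.flank_offset(p, "GCGC", 2)
            pool = Counter(r.original_sequence[off] for r in reads)
            meth = Counter(
                r.original_sequence[off] for r in reads if r.target_methylated
            )
            n_pool, n_meth = sum(pool.values()), sum(meth.values())
            for b in "ACGT":
                expect = (meth[b] / n_meth) / (pool[b] / n_pool)
                assert prof.oe.at[p, b] == pytest.approx(expect, abs=0)

    def test_no_methylated_reads_raises(self, cn_library_design):
        d = cn_library_design
        w = list("A" * d.window_len)
        w[d.target_offset], w[d.target_offset + 1] = "C", "G"
        reads = [_processed("".join(w), False)]
        with pytest.raises(mp.ProfileError):
            mp.oe_profile(reads, d, "CG", 1, positions=[-1])

    def test_parameter_recovery_ranks_enriched_base_first(self, gcgc_design):
        model = mp.PreferenceModel(
            motif="GCGC", target_index=2,
            flank_factors={-2: {"A": 1.0, "C": 2.0, "G": 1.0, "T": 1.0}},
        )
        reads, _ = mp.simulate_experiment(
            gcgc_design, model, 20_000, 0.5, seed=21, conv_rate=1.0
        )
        from conftest import raw_from_records

        processed, _ = mp.process_reads(raw_from_records(reads), gcgc_design)
        prof = mp.oe_profile(processed, gcgc_design, "GCGC", 2, positions=[-2])
        assert prof.oe.loc[-2].idxmax() == "C"


class TestEffectSize:
    def test_uniform_profile_has_zero_effect(self):
        prof = _profile_from({-1: (1, 1, 1, 1)})
        assert mp.effect_size(prof, -1) == 0.0

    def test_arithmetic_example(self):
        prof = _profile_from({-1: (1.5, 0.5, 1, 1)})
        assert mp.effect_size(prof, -1) == pytest.approx(math.sqrt(0.5), abs=1e-5)

    def test_printed_variant_misses_g_enrichment(self):
        # o/e (A,C,G,T) = (1,1,2,1): full formula sees the G term, the
        # printed variant (duplicated T, no G) does not
        prof = _profile_from({-1: (1, 1, 2, 1)})
        assert mp.effect_size(prof, -1) == pytest.approx(1.0)
        assert mp.effect_size(prof, -1, printed_variant=True) == 0.0

    def test_variants_agree_iff_g_is_unity(self):
        # with T at 1 the printed variant's duplicated T term vanishes, so the
        # two formulas differ exactly when G's o/e leaves 1
        for g, differs in [(1.0, False), (0.7, True), (1.3, True)]:
            prof = _profile_from({-1: (1.2, 0.9, g, 1.0)})
            full = mp.effect_size(prof, -1)
            printed = mp.effect_size(prof, -1, printed_variant=True)
            assert (abs(full - printed) > 1e-12) == differs

    def test_missing_value_raises(self):
        prof = _profile_from({-1: (1, np.nan, 1, 1)})
        with pytest.raises(mp.ProfileError):
            mp.effect_size(prof, -1)


class TestBinMethylation:
    def test_bin_table_sizes(self, clean_dataset):
        reads = clean_dataset["processed"][:500]
        d = clean_dataset["design"]
        assert len(mp.bin_methylation(reads, d, "GCGC", 2, half_width=3)) == 4096
        assert len(mp.bin_methylation(reads, d, "GCGC", 2, half_width=2)) == 256

    def test_single_context_pool(self, cn_library_design):
        d = cn_library_design
        w = list("A" * d.window_len)
        w[d.target_offset], w[d.target_offset + 1] = "C", "G"
        reads = [_processed("".join(w), m, rid=f"r{i}")
                 for i, m in enumerate([True, False, True, True])]
        table = mp.bin_methylation(reads, d, "CG", 1, half_width=2)
        covered = table[table["coverage"] > 0]
        assert len(covered) == 1
        assert covered["mean_methylation"].iloc[0] == pytest.approx(0.75)
        assert table["coverage"].sum() == 4

    def test_zero_coverage_rows_are_nan(self, cn_library_design):
        table = mp.bin_methylation([], cn_library_design, "CG", 1, half_width=2)
        assert table["mean_methylation"].isna().all()


class TestZeroBinBound:
    @pytest.mark.parametrize(
        "n, expected_pct",
        [(847, 0.35), (1149, 0.26)],
    )
    def test_reported_bounds(self, n, expected_pct):
        assert round(100 * mp.zero_bin_upper_bound(n, 0.05), 2) == expected_pct

    def test_single_read_closed_form(self):
        assert mp.zero_bin_upper_bound(1, 0.05) == pytest.approx(0.95)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mp.zero_bin_upper_bound(0, 0.05)
        with pytest.raises(ValueError):
            mp.zero_bin_upper_bound(10, 0.0)


class TestRelativeActivity:
    def test_uniform_profile_gives_unit_activity(self):
        rows = {p: (1, 1, 1, 1) for p in mp.default_positions(4)}
        act = mp.relative_activity(_profile_from(rows), half_width=4)
        assert len(act) == 65_536
        assert np.allclose(act, 1.0)

    def test_direct_product_small_case(self):
        prof = _profile_from({-1: (2, 1, 1, 1), 1: (1, 0.5, 1, 1)})
        act = mp.relative_activity(prof, half_width=1)
        assert len(act) == 16
        assert act["ACGC"] == pytest.approx(2 * 0.5)  # A(-1) x C(+1)
        assert act["ACGG"] == pytest.approx(2 * 1.0)  # A(-1) x G(+1)
        assert act["TCGT"] == pytest.approx(1.0)

    def test_missing_position_raises(self):
        prof = _profile_from({-1: (1, 1, 1, 1)})
        with pytest.raises(mp.ProfileError):
            mp.relative_activity(prof, half_width=2)


class TestComplexEffectScan:
    def _run(self, model, n=60_000, seed=31):
        d = mp.motif_design("GCGC", 2)
        t = mp.time_for_target_methylation(model, d, 0.3)
        reads, _ = mp.simulate_experiment(d, model, n, t, seed=seed, conv_rate=1.0)
        from conftest import raw_from_records

        processed, _ = mp.process_reads(raw_from_records(reads), d)
        res = mp.FlankingPreferenceModel(
            processed, d, "GCGC", 2, mp.default_positions(2)
        ).fit()
        bins = res.bins(half_width=2)
        act = res.activity(half_width=2)
        return complex_effect_scan(bins, act, "GCGC", min_coverage=50)

    def test_multiplicative_data_rank_correlates(self, gcgc_model):
        report = self._run(gcgc_model)
        assert report.attrs["spearman_r"] >= 0.95

    def test_strong_interaction_is_flagged(self):
        model = mp.PreferenceModel(
            motif="GCGC", target_index=2,
            flank_factors={
                -1: {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0},
                1: {"A": 1.0, "C": 1.0, "G": 1.0, "T": 1.0},
            },
            complex_terms={((-1, 1), ("A", "A")): 8.0},
        )
        report = self._run(model)
        flagged = report[report["flagged"]].index
        # interaction contexts have A at -1 and A at +1 (keys: NN + NN flanks)
        assert any(k[1] == "A" and k[2] == "A" for k in flagged)

    def test_empty_coverage_bins_excluded(self, clean_dataset):
        res = mp.FlankingPreferenceModel(
            clean_dataset["processed"], clean_dataset["design"], "GCGC", 2,
            mp.default_positions(3),
        ).fit()
        bins = res.bins(half_width=3)  # 4096 bins, sparse at 5k reads
        report = complex_effect_scan(bins, res.activity(3), "GCGC", min_coverage=1)
        assert (report["coverage"] >= 1).all()
        assert len(report) <= (bins["coverage"] >= 1).sum()
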