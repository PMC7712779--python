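"""Read filtering, exact-match counting, normalizations and the CDS screen."""

import numpy as np
import pandas as pd
import pytest

from amp_arsenal.diagnostics import best_offset, windows_at
from amp_arsenal.expression import (
    ExpressionMatrix,
    FilterSpec,
    ScreenParams,
    count_exact,
    filter_reads,
    heatmap_matrix,
    quantify_family,
    screen_cds,
)
from amp_arsenal.sequence_io import ReadRecord, revcomp
from amp_arsenal.synthetic_data import FamilySpec, ReadSimSpec, make_family, simulate_reads
from oracles import count_exact_naive


def _read(seq, q=40, rid="r"):
    return ReadRecord(rid, seq, tuple([q] * len(seq)))


class TestFilterReads:
    def test_mean_quality_just_below_20_dropped(self):
        # 100 bases at Q20 except one at Q10: mean 19.9
        qual = tuple([20] * 99 + [10])
        r = ReadRecord("r", "A" * 100, qual)
        assert filter_reads([r], FilterSpec()) == []

    def test_99nt_after_trimming_dropped(self):
        adapter = "AGATCGGAAGAGC"
        r = _read("A" * 99 + adapter[:10])
        assert filter_reads([r], FilterSpec(adapters=(adapter,))) == []

    def test_clean_high_quality_reads_pass_unchanged(self):
        reads = [_read("ACGT" * 30, q=40, rid=f"r{i}") for i in range(5)]
        assert filter_reads(reads, FilterSpec()) == reads

    def test_adapter_suffix_trimmed_before_filters(self):
        adapter = "AGATCGGAAGAGC"
        r = _read("C" * 150 + adapter)
        (kept,) = filter_reads([r], FilterSpec(adapters=(adapter,)))
        assert kept.seq == "C" * 150

    def test_short_adapter_overlap_not_trimmed(self):
        adapter = "AGATCGGAAGAGC"
        r = _read("C" * 150 + adapter[:5])  # below the 8-nt overlap floor
        (kept,) = filter_reads([r], FilterSpec(adapters=(adapter,)))
        assert len(kept) == 155


class TestCountExact:
    def test_read_equal_to_window(self):
        w = "ACGTACGTAC"
        assert count_exact(w, [_read(w)]) == 1

    def test_reverse_complement_embedded(self, rng):
        w = "".join(rng.choice(list("ACGT"), 150))
        pad = "".join(rng.choice(list("ACGT"), 151))
        read = _read(pad[:75] + revcomp(w) + pad[75:151 - 75])
        assert count_exact(w, [read]) == 1

    def test_read_counted_once_despite_two_occurrences(self):
        w = "ACGTACGT"
        assert count_exact(w, [_read(w + "TTTT" + w)]) == 1

    def test_too_short_reads_skipped(self):
        assert count_exact("A" * 50, [_read("A" * 20)]) == 0

    def test_matches_naive_scan_on_1000_random_pairs(self, rng):
        for _ in range(1000):
            wlen = int(rng.integers(4, 20))
            rlen = int(rng.integers(wlen, 60))
            w = "".join(rng.choice(list("ACGT"), wlen))
            r = _read("".join(rng.choice(list("ACGT"), rlen)))
            assert count_exact(w, [r]) == count_exact_naive(w, [r])


class TestQuantifyFamily:
    def test_percentages(self):
        wins = windows_at({"g1": "A" * 200, "g2": "C" * 200}, 1, 150)
        reads = [_read("A" * 150, rid=f"a{i}") for i in range(30)]
        reads += [_read("C" * 150, rid=f"c{i}") for i in range(70)]
        df = quantify_family(wins, reads, run_size_gb=1.0)
        assert df.loc["g1", "pct_within_family"] == pytest.approx(30.0)
        assert df.loc["g2", "pct_within_family"] == pytest.approx(70.0)

    def test_all_zero_family_emits_na(self):
        wins = windows_at({"g1": "A" * 200}, 1, 150)
        df = quantify_family(wins, [_read("C" * 200)], run_size_gb=1.0)
        assert np.isnan(df.loc["g1", "pct_within_family"])

    def test_clashing_windows_merged_into_joint_row(self, panel_cds):
        fam = {g: c for g, c in panel_cds.items() if g.startswith("defensin")}
        wins = windows_at(fam, 41, 150)
        df = quantify_family(wins, [], run_size_gb=1.0)
        assert "defensin_g3+5" in df.index
        assert "defensin_g3" not in df.index and "defensin_g5" not in df.index
        assert len(df) == 15  # 14 unique + 1 merged pair

    def test_doubling_run_size_halves_hits_per_gb(self):
        wins = windows_at({"g1": "A" * 200}, 1, 150)
        reads = [_read("A" * 200, rid=f"r{i}") for i in range(8)]
        a = quantify_family(wins, reads, run_size_gb=1.0)
        b = quantify_family(wins, reads, run_size_gb=2.0)
        assert a.loc["g1", "hits_per_gb"] == 2 * b.loc["g1", "hits_per_gb"]

    def test_weight_recovery_within_3_points(self):
        genes, _ = make_family(FamilySpec("defensin", 2, 0.02), seed=3)
        trs = [(g.record.name, g.mrna) for g in genes]
        sim = ReadSimSpec(n_reads=20_000, seed=11, error_rate=0.0,
                          weights={trs[0][0]: 3.0, trs[1][0]: 1.0})
        reads, gb = simulate_reads(trs, sim)
        cds = {g.record.name: g.record.cds for g in genes}
        start, _ = best_offset(cds, 150)
        df = quantify_family(windows_at(cds, start, 150), reads, gb)
        assert df["count"].sum() >= 10_000  # informative reads
        assert df.loc[trs[0][0], "pct_within_family"] == pytest.approx(75.0, abs=3.0)
        assert df.loc[trs[1][0], "pct_within_family"] == pytest.approx(25.0, abs=3.0)


class TestScreenCds:
    def test_error_free_reads_all_hit_their_cds(self):
        genes, _ = make_family(FamilySpec("termicin", 1, 0.0), seed=1)
        trs = [(g.record.name, g.mrna) for g in genes]
        reads, gb = simulate_reads(
            trs, ReadSimSpec(n_reads=300, seed=2, error_rate=0.0,
                             weights={trs[0][0]: 1.0}))
        m = screen_cds({"g": genes[0].record.cds}, reads, gb)
        assert int(m.counts.loc["g"].iloc[0]) == 300

    def test_ten_percent_divergent_paralog_rejected(self, rng):
        genes, _ = make_family(FamilySpec("attacin_like", 1, 0.0), seed=1)
        cds = genes[0].record.cds
        # diverge the query by 10%: below the 95% identity floor everywhere
        div = list(cds)
        for i in rng.choice(len(div), size=len(div) // 10, replace=False):
            div[i] = "ACGT"[("ACGT".index(div[i]) + 1) % 4]
        trs = [(genes[0].record.name, genes[0].mrna)]
        reads, gb = simulate_reads(
            trs, ReadSimSpec(n_reads=200, seed=3, error_rate=0.0,
                             weights={trs[0][0]: 1.0}))
        m = screen_cds({"div": "".join(div)}, reads, gb)
        assert int(m.counts.loc["div"].iloc[0]) == 0

    def test_hits_per_gb_arithmetic(self):
        counts = pd.DataFrame({"run1": [100]}, index=["g"])
        m = ExpressionMatrix(counts, {"run1": 2.0})
        assert m.hits_per_gb().loc["g", "run1"] == pytest.approx(50.0)

    def test_cds_length_normalization(self):
        counts = pd.DataFrame({"run1": [100]}, index=["g"])
        m = ExpressionMatrix(counts, {"run1": 2.0})
        assert m.hits_per_gb({"g": 100}).loc["g", "run1"] == pytest.approx(0.5)

    def test_hit_cap_flags_cell(self):
        genes, _ = make_family(FamilySpec("termicin", 1, 0.0), seed=4)
        trs = [(genes[0].record.name, genes[0].mrna)]
        reads, gb = simulate_reads(
            trs, ReadSimSpec(n_reads=30, seed=5, weights={trs[0][0]: 1.0}))
        params = ScreenParams(hit_cap=10)
        m = screen_cds({"g": genes[0].record.cds}, reads, gb, params)
        assert int(m.counts.loc["g"].iloc[0]) == 10
        assert ("g", "run1") in m.capped

    def test_cds_shorter_than_seed_rejected(self):
        with pytest.raises(ValueError):
            screen_cds({"g": "ACGT"}, [], 1.0)


class TestHeatmapMatrix:
    def test_order_and_na_preserved(self, tmp_path):
        mat = pd.DataFrame({"r1": [1.0, np.nan], "r2": [3.0, 4.0]}, index=["a", "b"])
        out = heatmap_matrix(mat, ["b", "a"], ["r2", "r1"], out_tsv=tmp_path / "m.tsv")
        assert list(out.index) == ["b", "a"] and list(out.columns) == ["r2", "r1"]
        assert np.isnan(out.loc["b", "r1"])
        text = (tmp_path / "m.tsv").read_text()
        assert "NA" in text

    def test_single_cell(self):
        mat = pd.DataFrame({"r": [5.0]}, index=["g"])
        assert heatmap_matrix(mat, ["g"], ["r"]).shape == (1, 1)
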