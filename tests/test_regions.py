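import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenkit as sk
from screenkit.regions import RegionError, _enrichment_score, _rank_order


# ---------------------------------------------------------------------------
# Independent oracles


def overlap_oracle(a_df, b_df, min_overlap=1):
    """All-pairs quadratic check of shared-base overlap."""
    flags = []
    for _, ra in a_df.iterrows():
        hit = False
        for _, rb in b_df.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            shared = min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
            if shared >= min_overlap:
                hit = True
                break
        flags.append(hit)
    return np.array(flags)


def window_assign_oracle(peaks_df, tss_df, half_width):
    """Quadratic peak-vs-window containment check."""
    pairs = set()
    for _, p in peaks_df.iterrows():
        for _, t in tss_df.iterrows():
            if p["chrom"] != t["chrom"]:
                continue
            t0 = t["tss"] - 1
            ws, we = max(0, t0 - half_width), t0 + half_width + 1
            if min(p["end"], we) - max(p["start"], ws) >= 1:
                pairs.add((p["region_id"], t["gene"]))
    return pairs


def es_running_sum_oracle(stats_ranked: np.ndarray, hits: np.ndarray, weight=1.0):
    """Explicit position-by-position running sum; signed max deviation."""
    n = len(stats_ranked)
    nh = int(hits.sum())
    if nh == 0:
        return 0.0
    if nh == n:
        return 1.0
    w = np.abs(stats_ranked) ** weight
    total = w[hits].sum()
    if total <= 0:
        w = np.ones(n)
        total = float(nh)
    running = 0.0
    trace = [0.0]
    for i in range(n):
        if hits[i]:
            running += w[i] / total
        else:
            running -= 1.0 / (n - nh)
        trace.append(running)
    hi, lo = max(trace), min(trace)
    return hi if hi >= -lo else lo  # exact ties resolve to the positive extreme


def random_peaks(rng, n, chroms=("c1", "c2"), span=10_000, prefix="p"):
    rows = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        end = start + int(rng.integers(1, 200))
        rows.append((chrom, start, end, f"{prefix}{i}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"])
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------


class TestIntervalsOverlap:
    @staticmethod
    def _ps(rows):
        return sk.PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id"]))

    def test_plain_overlap(self):
        a = self._ps([("c1", 100, 200, "a")])
        b = self._ps([("c1", 150, 250, "b")])
        assert sk.intervals_overlap(a, b).iloc[0]

    def test_half_open_abutment(self):
        a = self._ps([("c1", 100, 200, "a")])
        b = self._ps([("c1", 200, 300, "b")])
        assert not sk.intervals_overlap(a, b).iloc[0]

    def test_min_overlap_threshold(self):
        a = self._ps([("c1", 100, 200, "a")])
        b = self._ps([("c1", 190, 300, "b")])
        assert sk.intervals_overlap(a, b, min_overlap=10).iloc[0]
        assert not sk.intervals_overlap(a, b, min_overlap=11).iloc[0]

    def test_unsorted_input_sorted_with_warning(self):
        df = pd.DataFrame(
            [("c1", 500, 600, "x"), ("c1", 10, 20, "y")],
            columns=["chrom", "start", "end", "region_id"],
        )
        with pytest.warns(UserWarning, match="sort"):
            ps = sk.PeakSet(df)
        assert list(ps.intervals["start"]) == [10, 500]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a_df = random_peaks(rng, 500, prefix="a")
        b_df = random_peaks(rng, 500, prefix="b")
        got = sk.intervals_overlap(sk.PeakSet(a_df), sk.PeakSet(b_df))
        expected = overlap_oracle(a_df, b_df)
        assert np.array_equal(got.loc[a_df["region_id"]].to_numpy(), expected)

    @pytest.mark.parametrize("min_overlap", [1, 5, 50])
    def test_min_overlap_matches_oracle(self, min_overlap):
        rng = np.random.default_rng(99)
        a_df = random_peaks(rng, 200, prefix="a")
        b_df = random_peaks(rng, 200, prefix="b")
        got = sk.intervals_overlap(sk.PeakSet(a_df), sk.PeakSet(b_df), min_overlap=min_overlap)
        expected = overlap_oracle(a_df, b_df, min_overlap=min_overlap)
        assert np.array_equal(got.loc[a_df["region_id"]].to_numpy(), expected)


class TestTssWindowAssign:
    TSS = pd.DataFrame(
        {"gene": ["g1"], "chrom": ["c1"], "tss": [100_001], "strand": ["+"],
         "signature": ["s1"]}
    )  # 1-based 100001 -> 0-based 100000

    def _assign(self, start, end, half_width=50_000):
        peaks = sk.PeakSet(
            pd.DataFrame([("c1", start, end, "p")], columns=["chrom", "start", "end", "region_id"])
        )
        return sk.tss_window_assign(peaks, self.TSS, half_width=half_width)

    def test_peak_inside_window_end(self):
        assert len(self._assign(149_000, 149_500)) == 1

    def test_peak_past_window_end(self):
        assert len(self._assign(150_001, 150_100)) == 0

    def test_inclusive_window_endpoint(self):
        # base at tss0 + half_width = 150000 still belongs to the window
        assert len(self._assign(150_000, 150_100)) == 1

    def test_zero_half_width(self):
        assert len(self._assign(100_000, 100_001, half_width=0)) == 1
        assert len(self._assign(100_001, 100_002, half_width=0)) == 0

    def test_negative_half_width_rejected(self):
        with pytest.raises(RegionError):
            self._assign(0, 1, half_width=-1)

    def test_multi_assignment_recorded(self):
        tss = pd.DataFrame(
            {"gene": ["g1", "g2"], "chrom": "c1", "tss": [1_000, 1_500],
             "strand": "+", "signature": "s1"}
        )
        peaks = sk.PeakSet(
            pd.DataFrame([("c1", 900, 1_600, "p")], columns=["chrom", "start", "end", "region_id"])
        )
        out = sk.tss_window_assign(peaks, tss, half_width=300)
        assert set(map(tuple, out.to_numpy())) == {("p", "g1"), ("p", "g2")}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks_df = random_peaks(rng, 300, span=50_000)
        tss = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(40)],
                "chrom": [("c1", "c2")[rng.integers(2)] for _ in range(40)],
                "tss": rng.integers(1, 50_000, size=40),
                "strand": "+",
                "signature": "s1",
            }
        )
        got = sk.tss_window_assign(sk.PeakSet(peaks_df), tss, half_width=700)
        assert set(map(tuple, got.to_numpy())) == window_assign_oracle(peaks_df, tss, 700)


class TestBuildRegionSets:
    def test_all_cobound_empty(self, genomic_fixture):
        tf = genomic_fixture["tf"]
        with pytest.warns(UserWarning, match="empty"):
            sets = sk.build_signature_region_sets(tf, tf, genomic_fixture["tss"])
        assert sets.sets == {}

    def test_no_exclusion_equals_plain_window_assignment(self, genomic_fixture):
        tf, partner, tss = (
            genomic_fixture["tf"], genomic_fixture["partner"], genomic_fixture["tss"],
        )
        sets = sk.build_signature_region_sets(tf, partner, tss, exclude_cobound=False)
        assign = sk.tss_window_assign(tf, tss)
        sig_of = tss.set_index("gene")["signature"]
        for sig, members in sets.sets.items():
            genes = set(sig_of.index[sig_of == sig])
            expected = set(assign.loc[assign["gene"].isin(genes), "region_id"])
            assert set(members) == expected

    def test_matches_fixture_truth_exactly(self, genomic_fixture):
        truth = genomic_fixture["truth"]
        sets = sk.build_signature_region_sets(
            genomic_fixture["tf"], genomic_fixture["partner"], genomic_fixture["tss"]
        )
        for sig, members in sets.sets.items():
            assert set(members) == truth.window_members[sig] - truth.cobound_ids

    def test_metadata_records_window(self, genomic_fixture):
        sets = sk.build_signature_region_sets(
            genomic_fixture["tf"], genomic_fixture["partner"], genomic_fixture["tss"]
        )
        assert sets.meta["half_width"] == 50_000
        assert sets.meta["half_width_kb"] == 50.0


class TestEnrichmentScore:
    def test_top_two_hand_example(self):
        stats = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0], index=list("abcde"))
        res = sk.preranked_gsea(stats, {"top": ["a", "b"]}, n_perm=100, seed=1)
        assert res["es"].iloc[0] == pytest.approx(1.0)

    def test_bottom_two_symmetric(self):
        stats = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0], index=list("abcde"))
        res = sk.preranked_gsea(stats, {"bot": ["d", "e"]}, n_perm=100, seed=1)
        assert res["es"].iloc[0] == pytest.approx(-1.0)

    def test_full_universe_set(self):
        stats = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        res = sk.preranked_gsea(stats, {"all": list("abc")}, n_perm=100, seed=1)
        assert res["es"].iloc[0] == pytest.approx(1.0)

    def test_oversized_set_rejected(self):
        stats = pd.Series([1.0, 2.0], index=list("ab"))
        with pytest.raises(RegionError):
            sk.preranked_gsea(stats, {"big": ["a", "b", "c"]}, n_perm=100)

    def test_non_finite_stats_rejected(self):
        stats = pd.Series([1.0, np.nan], index=list("ab"))
        with pytest.raises(RegionError):
            sk.preranked_gsea(stats, {"s": ["a"]}, n_perm=100)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_running_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        stats = pd.Series(rng.normal(size=n), index=[f"r{i}" for i in range(n)])
        size = int(rng.integers(1, n + 1))
        members = list(rng.choice(stats.index, size=size, replace=False))
        weight = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
        ranked = _rank_order(stats)
        hits = ranked.index.isin(members)
        expected = es_running_sum_oracle(ranked.to_numpy(), hits, weight=weight)
        pos = np.flatnonzero(hits)
        w = np.abs(ranked.to_numpy()) ** weight
        got = _enrichment_score(w[pos], pos, n)
        assert got == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= got <= 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_es_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        pos = np.sort(rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False))
        w = rng.random(len(pos)) + 0.01
        assert -1.0 <= _enrichment_score(w, pos, n) <= 1.0


class TestGseaInference:
    def test_planted_signature_top_nes(self, genomic_fixture):
        sets = sk.build_signature_region_sets(
            genomic_fixture["tf"], genomic_fixture["partner"], genomic_fixture["tss"]
        )
        res = sk.preranked_gsea(
            genomic_fixture["stats"], sets, n_perm=1000, seed=3
        ).set_index("set")
        assert res["nes"].idxmax() == "sig3"
        assert res.loc["sig3", "nes"] > 0
        assert res.loc["sig3", "fdr"] < 0.05

    def test_null_fdr_calibration(self, rng):
        # iid normal stats, random sets: few sets at FDR < 0.05
        n = 600
        stats = pd.Series(rng.standard_normal(n), index=[f"r{i}" for i in range(n)])
        n_sets = 40
        sets = {
            f"s{j}": list(rng.choice(stats.index, size=25, replace=False))
            for j in range(n_sets)
        }
        res = sk.preranked_gsea(stats, sets, n_perm=200, seed=8)
        assert (res["fdr"] < 0.05).mean() <= 0.1

    def test_determinism(self, genomic_fixture):
        sets = sk.build_signature_region_sets(
            genomic_fixture["tf"], genomic_fixture["partner"], genomic_fixture["tss"]
        )
        a = sk.preranked_gsea(genomic_fixture["stats"], sets, n_perm=200, seed=4)
        b = sk.preranked_gsea(genomic_fixture["stats"], sets, n_perm=200, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestSimpleRegionLogfc:
    @staticmethod
    def _counts(rows, samples):
        return pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))], columns=samples)

    def test_identical_samples_zero(self):
        counts = self._counts([[10, 10], [3, 3]], ["a1", "b1"])
        stat = sk.simple_region_logfc(counts, {"a1": "A", "b1": "B"}, "A", "B")
        assert np.allclose(stat, 0.0)

    def test_hand_arithmetic(self):
        counts = self._counts([[20, 10], [80, 90]], ["a1", "b1"])
        stat = sk.simple_region_logfc(counts, {"a1": "A", "b1": "B"}, "A", "B")
        assert stat.iloc[0] == pytest.approx(np.log2(20.5 / 10.5))
        assert stat.iloc[0] == pytest.approx(0.965, abs=5e-4)

    def test_depth_doubling_invariance(self):
        counts = self._counts([[20, 10, 15], [80, 90, 85]], ["a1", "b1", "b2"])
        cond = {"a1": "A", "b1": "B", "b2": "B"}
        base = sk.simple_region_logfc(counts, cond, "A", "B")
        doubled = counts.copy()
        doubled["b2"] = doubled["b2"] * 2  # median library size unchanged
        again = sk.simple_region_logfc(doubled, cond, "A", "B")
        assert np.allclose(base, again)

    def test_zero_library_rejected(self):
        counts = self._counts([[0, 10]], ["a1", "b1"])
        with pytest.raises(RegionError, match="library"):
            sk.simple_region_logfc(counts, {"a1": "A", "b1": "B"}, "A", "B")


class TestBedIO:
    def test_round_trip(self, tmp_path, genomic_fixture):
        tf = genomic_fixture["tf"]
        sk.write_bed(tf, tmp_path / "tf.bed")
        again = sk.read_bed(tmp_path / "tf.bed")
        pd.testing.assert_frame_equal(
            tf.intervals[["chrom", "start", "end", "region_id"]],
            again.intervals[["chrom", "start", "end", "region_id"]],
        )

    def test_tss_one_based_conversion(self, tmp_path):
        (tmp_path / "tss.tsv").write_text(
            "gene\tchrom\ttss\tstrand\tsignature\ng1\tc1\t1\t+\ts1\n"
        )
        tss = sk.read_tss_table(tmp_path / "tss.tsv")
        assert tss["tss0"].iloc[0] == 0

    def test_bad_bed_rejected(self, tmp_path):
        (tmp_path / "x.bed").write_text("c1\t100\n")
        with pytest.raises(RegionError):
            sk.read_bed(tmp_path / "x.bed")
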