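"""Window building, GC matching, fold changes, segmentation, clustering."""

import numpy as np
import pandas as pd
import pytest

from clonescope.genomic_io import GenomeModel, Region
from clonescope.cnv_inference import (
    GenomicWindows,
    cluster_cells_by_cnv,
    cnv_fold_change,
    correlate_profiles,
    effective_window_size,
    gc_matched_background,
    locus_cn,
    make_windows,
    merge_regions,
    segment_profile,
    segment_profiles,
    window_coverage,
    window_gc,
)
from clonescope.synthetic_data import CloneTruth, CNVEvent, simulate_fragments
from clonescope.pipeline import cnv_profiles

from conftest import small_config

MB = 1_000_000


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,target,expected",
        [
            (10 * MB, 2 * MB, [2, 2, 2, 2, 2]),          # exact division
            (int(5.5 * MB), 2 * MB, [2, 2, 1.5]),        # remainder >= half kept
            (int(4.5 * MB), 2 * MB, [2, 2.5]),           # remainder < half merged
            (1 * MB, 2 * MB, [1]),                       # short chromosome
        ],
    )
    def test_tiling_and_remainder_rule(self, length, target, expected):
        windows = make_windows(GenomeModel({"chr1": length}), target)
        sizes = [(e - s) / MB for s, e in zip(windows.table["start"], windows.table["end"])]
        assert sizes == expected

    def test_windows_tile_without_overlap(self):
        gm = GenomeModel({"chr1": int(7.3 * MB), "chr2": 3 * MB})
        t = make_windows(gm, 2 * MB).table
        for chrom, grp in t.groupby("chrom"):
            assert grp["start"].iloc[0] == 0
            assert list(grp["start"].iloc[1:]) == list(grp["end"].iloc[:-1])
            assert grp["end"].iloc[-1] == gm.lengths[chrom]


class TestWindowGc:
    def _genome(self, seq):
        return GenomeModel({"chr1": len(seq)}, sequences={"chr1": seq})

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTACGT" * 4, 0.5),
            ("A" * 32, 0.0),
            ("N" * 16 + "GC" * 8, 1.0),  # ambiguous bases leave the denominator
        ],
    )
    def test_gc_definition(self, seq, expected):
        windows = make_windows(self._genome(seq), len(seq))
        out = window_gc(windows, genome=self._genome(seq))
        assert out.table["gc"].iloc[0] == pytest.approx(expected)

    def test_all_n_window_flagged_unusable(self):
        seq = "N" * 32
        out = window_gc(make_windows(self._genome(seq), 32), genome=self._genome(seq))
        assert np.isnan(out.table["gc"].iloc[0])
        assert not out.table["usable"].iloc[0]

    def test_track_gc_is_length_weighted(self):
        windows = make_windows(GenomeModel({"chr1": 4 * MB}), 4 * MB)
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 1 * MB], "end": [1 * MB, 4 * MB],
             "gc": [0.2, 0.6]}
        )
        out = window_gc(windows, gc_track=track)
        assert out.table["gc"].iloc[0] == pytest.approx(0.25 * 0.2 + 0.75 * 0.6)


class TestEffectiveWindowSize:
    def test_peak_bp_subtracted(self):
        windows = make_windows(GenomeModel({"chr1": 2 * MB}), 2 * MB)
        out = effective_window_size(windows, [Region("chr1", 0, 100_000)])
        assert out.table["effective_length"].iloc[0] == 2 * MB - 100_000

    def test_no_peaks_is_identity(self):
        windows = make_windows(GenomeModel({"chr1": 2 * MB}), 2 * MB)
        out = effective_window_size(windows, [])
        assert out.table["effective_length"].iloc[0] == 2 * MB

    def test_boundary_spanning_peak_split_between_windows(self):
        windows = make_windows(GenomeModel({"chr1": 4 * MB}), 2 * MB)
        out = effective_window_size(windows, [Region("chr1", 2 * MB - 300, 2 * MB + 700)])
        assert list(out.table["effective_length"]) == [2 * MB - 300, 2 * MB - 700]

    def test_interval_subtraction_matches_brute_force(self):
        rng = np.random.default_rng(3)
        windows = make_windows(GenomeModel({"chr1": 10 * MB}), 1 * MB)
        peaks = []
        for _ in range(60):
            s = int(rng.integers(0, 10 * MB - 5000))
            peaks.append(Region("chr1", s, s + int(rng.integers(100, 5000))))
        out = effective_window_size(windows, peaks)
        merged = merge_regions(peaks)
        for _, w in out.table.iterrows():
            covered = sum(
                max(0, min(p.end, w["end"]) - max(p.start, w["start"])) for p in merged
            )
            assert w["effective_length"] == (w["end"] - w["start"]) - covered

    def test_fully_covered_window_unusable(self):
        windows = make_windows(GenomeModel({"chr1": 1 * MB}), 1 * MB)
        out = effective_window_size(windows, [Region("chr1", 0, 1 * MB)])
        assert not out.table["usable"].iloc[0]


def _flat_windows(n, gc=0.5, size=MB):
    gm = GenomeModel({"chr1": n * size})
    w = make_windows(gm, size)
    t = w.table.copy()
    t["gc"] = gc
    return GenomicWindows(t)


class TestWindowCoverage:
    def _uniform_fragments(self, n_windows, per_window, barcode="c", size=MB):
        rows = []
        for w in range(n_windows):
            for i in range(per_window):
                s = w * size + 1000 * i + 10
                rows.append(("chr1", s, s + 100, barcode, 1))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])

    def test_uniform_input_gives_unit_coverage(self):
        windows = _flat_windows(10)
        frags = self._uniform_fragments(10, 50)
        cov = window_coverage(frags, windows, [])
        assert np.allclose(cov.to_numpy(), 1.0)

    def test_depth_scaling_leaves_profile_unchanged(self):
        windows = _flat_windows(10)
        frags = self._uniform_fragments(10, 30)
        rng = np.random.default_rng(0)
        frags = frags.loc[rng.random(len(frags)) < 0.9].reset_index(drop=True)
        cov1 = window_coverage(frags, windows, [])
        deeper = frags.assign(count=frags["count"] * 7)
        cov2 = window_coverage(deeper, windows, [])
        pd.testing.assert_frame_equal(cov1, cov2)

    def test_in_peak_fragments_excluded(self):
        windows = _flat_windows(4)
        frags = self._uniform_fragments(4, 20)
        peaks = [Region("chr1", 0, MB)]  # all of window 0
        windows = effective_window_size(windows, peaks)
        cov = window_coverage(frags, windows, peaks)
        # window 0 has no off-target fragments and no effective length -> NaN
        assert np.isnan(cov.to_numpy()[0, 0])
        assert np.allclose(cov.to_numpy()[0, 1:], 1.0)

    def test_effective_length_compensates_for_peak_bp(self):
        # window 2 is half peaks but keeps the same off-target per-bp rate
        windows = _flat_windows(5)
        peaks = [Region("chr1", 2 * MB, 2 * MB + MB // 2)]
        windows = effective_window_size(windows, peaks)
        rows = []
        for w in range(5):
            n = 100 if w != 2 else 50  # proportional to non-peak bp
            lo = w * MB + (MB // 2 if w == 2 else 0)
            for i in range(n):
                s = lo + i * 1000 + 5
                rows.append(("chr1", s, s + 100, "c", 1))
        frags = pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
        cov = window_coverage(frags, windows, peaks)
        assert np.allclose(cov.to_numpy(), 1.0, atol=1e-9)

    def test_fragment_assigned_to_midpoint_window(self):
        windows = _flat_windows(2)
        frags = pd.DataFrame(
            [
                ("chr1", MB - 10, MB + 200, "c", 1),   # midpoint in window 1
                ("chr1", MB - 200, MB + 10, "c", 1),   # midpoint in window 0
            ],
            columns=["chrom", "start", "end", "barcode", "count"],
        )
        cov = window_coverage(frags, windows, [])
        assert cov.to_numpy()[0, 0] == cov.to_numpy()[0, 1]

    def test_grouping_pools_barcodes(self):
        windows = _flat_windows(3)
        f1 = self._uniform_fragments(3, 10, barcode="a")
        f2 = self._uniform_fragments(3, 10, barcode="b")
        frags = pd.concat([f1, f2], ignore_index=True)
        cov = window_coverage(frags, windows, [], grouping={"a": "g", "b": "g"})
        assert list(cov.index) == ["g"]
        assert np.allclose(cov.to_numpy(), 1.0)

    def test_entity_without_fragments_warned_missing(self):
        windows = _flat_windows(3)
        frags = self._uniform_fragments(3, 10)
        peaks = [Region("chr1", 0, 2 * MB)]  # windows 0-1 unusable, 2 keeps no fragments
        windows = effective_window_size(windows, peaks)
        frags = frags[frags["start"] < 2 * MB].reset_index(drop=True)
        with pytest.warns(UserWarning, match="no off-target"):
            cov = window_coverage(frags, windows, peaks)
        assert np.isnan(cov.to_numpy()).all()


class TestGcMatchedBackground:
    def brute_force(self, table, n_match):
        """Independent nearest-|dGC| search with genomic-order tie-break."""
        order_key = list(range(len(table)))  # table already in genomic order
        out = {}
        usable = [i for i in order_key if table["usable"].iloc[i]]
        for w in usable:
            others = [i for i in usable if i != w]
            others.sort(key=lambda i: (abs(table["gc"].iloc[i] - table["gc"].iloc[w]), i))
            out[w] = others[:n_match]
        return out

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            windows = _flat_windows(n)
            t = windows.table.copy()
            t["gc"] = rng.choice(np.round(rng.random(max(n // 2, 2)), 3), size=n)
            t.loc[rng.random(n) < 0.1, "usable"] = False
            windows = GenomicWindows(t)
            n_match = int(rng.integers(1, n))
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                got = gc_matched_background(windows, n_match)
            expected = self.brute_force(t, n_match)
            for w, idx in expected.items():
                assert list(got[w]) == idx

    def test_fewer_candidates_than_requested_uses_all(self):
        windows = _flat_windows(50)
        t = windows.table.copy()
        t["gc"] = np.linspace(0.3, 0.7, 50)
        with pytest.warns(UserWarning, match="using all"):
            bg = gc_matched_background(GenomicWindows(t), 100)
        assert all(len(idx) == 49 for idx in bg)

    def test_constant_gc_tie_break_is_genomic_order(self):
        windows = _flat_windows(120, gc=0.5)
        bg = gc_matched_background(windows, 100)
        assert list(bg[0]) == list(range(1, 101))
        assert list(bg[119]) == list(range(0, 100))

    def test_query_never_matches_itself(self):
        windows = _flat_windows(150, gc=0.5)
        bg = gc_matched_background(windows, 100)
        for w, idx in enumerate(bg):
            assert w not in idx


class TestFoldChange:
    def test_uniform_coverage_gives_zero_log2fc(self):
        windows = _flat_windows(30)
        cov = pd.DataFrame(np.ones((2, 30)), columns=windows.labels, index=["a", "b"])
        bg = gc_matched_background(windows, 10)
        lfc = cnv_fold_change(cov, bg, windows)
        assert np.allclose(lfc.to_numpy(), 0.0, atol=1e-12)

    def test_doubled_window_approaches_log2fc_one(self):
        windows = _flat_windows(200)
        vals = np.ones((1, 200))
        vals[0, 50] = 2.0
        cov = pd.DataFrame(vals, columns=windows.labels, index=["a"])
        bg = gc_matched_background(windows, 100)
        lfc = cnv_fold_change(cov, bg, windows)
        assert lfc.to_numpy()[0, 50] == pytest.approx(1.0, abs=0.02)

    def test_unusable_window_missing(self):
        windows = _flat_windows(30)
        t = windows.table.copy()
        t.loc[4, "usable"] = False
        windows = GenomicWindows(t)
        cov = pd.DataFrame(np.ones((1, 30)), columns=windows.labels, index=["a"])
        cov.iloc[0, 4] = np.nan
        bg = gc_matched_background(windows, 10)
        lfc = cnv_fold_change(cov, bg, windows)
        assert np.isnan(lfc.to_numpy()[0, 4])
        assert np.isfinite(lfc.to_numpy()[0, [i for i in range(30) if i != 4]]).all()


class TestSegmentation:
    def test_noiseless_step_recovers_exact_breakpoint(self):
        segs = segment_profile(np.array([0, 0, 0, 1, 1, 1.0]), penalty=0.1)
        assert len(segs) == 2
        assert list(segs["first"]) == [0, 3]
        assert list(segs["mean"]) == [0.0, 1.0]

    def test_flat_noisy_profile_stays_one_segment(self):
        # 50 windows, noise SD 0.1: a single segment in >= 95% of seeds
        ok = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(0, 0.1, 50)
            ok += len(segment_profile(x)) == 1
        assert ok >= 38

    def test_short_profile_single_segment(self):
        segs = segment_profile(np.array([5.0, 6.0]))
        assert len(segs) == 1
        assert segs["mean"].iloc[0] == pytest.approx(5.5)

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            segment_profile(np.array([0.0, np.nan, 1.0]))

    def test_segment_profiles_partitions_each_chromosome(self):
        windows = _flat_windows(20)
        vals = np.zeros((1, 20))
        vals[0, 10:] = 1.0
        prof = pd.DataFrame(vals, columns=windows.labels, index=["e"])
        segs = segment_profiles(prof, windows, penalty=0.5)
        assert list(segs["start"]) == [0, 10 * MB]
        assert list(segs["end"]) == [10 * MB, 20 * MB]
        assert segs["n_windows"].sum() == 20


class TestClustering:
    def _profiles(self, n_per, shift_cols, rng):
        base = rng.normal(0, 0.3, (3 * n_per, 40))
        base[n_per : 2 * n_per, shift_cols] += 1.0
        base[2 * n_per :, shift_cols] -= 1.0
        idx = [f"c{i}" for i in range(3 * n_per)]
        return pd.DataFrame(base, index=idx)

    def test_recovers_three_well_separated_populations(self):
        rng = np.random.default_rng(0)
        prof = self._profiles(50, list(range(10)), rng)
        labels = cluster_cells_by_cnv(prof, k=3, seed=1)
        truth = np.repeat([0, 1, 2], 50)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, labels) > 0.95

    def test_normal_like_cluster_gets_label_zero(self):
        rng = np.random.default_rng(1)
        prof = self._profiles(30, list(range(10)), rng)
        labels = cluster_cells_by_cnv(prof, k=3, seed=1)
        flattest = labels.iloc[:30].mode()[0]
        assert flattest == 0

    def test_k_one_collapses_to_single_label(self):
        rng = np.random.default_rng(2)
        prof = self._profiles(5, [0], rng)
        labels = cluster_cells_by_cnv(prof, k=1, seed=0)
        assert set(labels) == {0}

    def test_duplicated_rows_co_cluster(self):
        rng = np.random.default_rng(3)
        prof = self._profiles(10, list(range(10)), rng)
        dup = pd.concat([prof, prof.iloc[[0]].rename(index={"c0": "c0_dup"})])
        labels = cluster_cells_by_cnv(dup, k=3, seed=0)
        assert labels["c0"] == labels["c0_dup"]

    def test_fewer_cells_than_k_fails(self):
        prof = pd.DataFrame(np.zeros((2, 5)), index=["a", "b"])
        with pytest.raises(ValueError, match="clusters"):
            cluster_cells_by_cnv(prof, k=3)


class TestCorrelateProfiles:
    def test_identity_negation_and_missing(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        prof = pd.DataFrame(
            [x, x, -x, np.full(30, np.nan)], index=["a", "a2", "neg", "empty"]
        )
        prof.iloc[3, :2] = [1.0, 2.0]  # only 2 shared windows with others
        r = correlate_profiles(prof)
        assert r.loc["a", "a2"] == pytest.approx(1.0)
        assert r.loc["a", "neg"] == pytest.approx(-1.0)
        assert np.isnan(r.loc["a", "empty"])
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T, equal_nan=True)

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            correlate_profiles(pd.DataFrame([[1.0, 2.0]], index=["a"]))


class TestParameterRecovery:
    """Planted copies {0,1,3,4} recover segment means near log2(c/2)."""

    @pytest.fixture(scope="class")
    def deep_profile(self):
        events = [
            CNVEvent(Region("chr2", 0, 10 * MB), 0),
            CNVEvent(Region("chr2", 14 * MB, 24 * MB), 1),
            CNVEvent(Region("chr2", 30 * MB, 40 * MB), 3),
            CNVEvent(Region("chr2", 44 * MB, 54 * MB), 4),
        ]
        cfg = small_config(
            seed=9,
            n_cells=50,
            fragments_per_cell=20_000,
            gc_bias_slope=0.0,
            clones=[CloneTruth("tumor", events, 1.0, "ASCL1")],
        )
        frags, truth, peaks, windows = simulate_fragments(cfg)
        grouping = {b: "tumor" for b in truth["barcode"]}
        windows, cov, lfc = cnv_profiles(frags, peaks, windows, grouping, n_match=30)
        return windows, lfc

    @pytest.mark.parametrize(
        "span,copy",
        [((0, 10 * MB), 0), ((14 * MB, 24 * MB), 1),
         ((30 * MB, 40 * MB), 3), ((44 * MB, 54 * MB), 4)],
    )
    def test_locus_mean_matches_copy_ratio(self, deep_profile, span, copy):
        windows, lfc = deep_profile
        val = locus_cn(lfc.iloc[0], windows, Region("chr2", *span))
        if copy == 0:
            assert val <= -2.0  # floored by the pseudocount, strongly negative
        else:
            assert val == pytest.approx(np.log2(copy / 2), abs=0.15)

    def test_neutral_locus_near_zero(self, deep_profile):
        windows, lfc = deep_profile
        val = locus_cn(lfc.iloc[0], windows, Region("chr1", 10 * MB, 30 * MB))
        assert abs(val) < 0.1

    def test_locus_without_usable_window_missing(self, deep_profile):
        windows, lfc = deep_profile
        row = lfc.iloc[0].copy()
        t = windows.table
        chr1_first = t[(t["chrom"] == "chr1") & (t["start"] == 0)].index[0]
        row.iloc[chr1_first] = np.nan
        assert np.isnan(locus_cn(row, windows, Region("chr1", 0, 1000)))


def test_locus_cn_is_length_weighted():
    windows = _flat_windows(3)
    row = pd.Series([0.0, 1.0, 2.0], index=windows.labels)
    # locus covers last half of window 0 and all of window 1
    val = locus_cn(row, windows, Region("chr1", MB // 2, 2 * MB))
    assert val == pytest.approx((0.5 * 0.0 + 1.0 * 1.0) / 1.5)
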