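"""Master tables, the Kendall screen, RRHO and heatmap clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from depscan.intervals import GenomicInterval
from depscan.screen import (
    MasterPeakTable,
    ScreenPairs,
    build_master_table,
    concordance_label,
    cluster_heatmap_order,
    cut_clusters,
    dependency_screen,
    filter_for_screen,
    kendall_tau,
    kendall_tau_matrix,
    rrho_map,
)


def brute_force_tau(x, y):
    """O(n^2) pairwise tau-b oracle."""
    n = len(x)
    num = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        sx = np.sign(x[j] - x[i])
        sy = np.sign(y[j] - y[i])
        num += sx * sy
        tx += sx == 0
        ty += sy == 0
    n0 = n * (n - 1) / 2
    return num / np.sqrt((n0 - tx) * (n0 - ty))


class TestMasterTable:
    def test_identical_single_peak_two_samples(self):
        peaks = {
            "a": [GenomicInterval("chrS", 100, 200, score=5.0)],
            "b": [GenomicInterval("chrS", 100, 200, score=7.0)],
        }
        t = build_master_table(peaks)
        assert len(t.loci) == 1
        assert t.presence.iloc[0].all()
        assert t.counts.iloc[0].tolist() == [5.0, 7.0]

    def test_book_ended_peaks_merge_into_one_locus(self):
        peaks = {
            "a": [GenomicInterval("chrS", 100, 200)],
            "b": [GenomicInterval("chrS", 200, 300)],
        }
        t = build_master_table(peaks)
        assert [(l.start, l.end) for l in t.loci] == [(100, 300)]
        # presence uses strict overlap with each sample's own peaks
        assert t.presence.iloc[0].tolist() == [True, True]

    def test_counts_matrix_mapped_by_overlap_and_summed(self):
        peaks = {
            "a": [GenomicInterval("chrS", 0, 100), GenomicInterval("chrS", 90, 200)],
            "b": [GenomicInterval("chrS", 50, 150)],
        }
        counts = pd.DataFrame(
            {"a": [3.0, 4.0], "b": [5.0, 6.0]},
            index=["chrS:0-100", "chrS:90-200"],
        )
        t = build_master_table(peaks, counts=counts)
        assert len(t.loci) == 1
        assert t.counts.iloc[0].tolist() == [7.0, 11.0]

    def test_every_master_locus_overlaps_a_sample_peak(self, rng):
        peaks = {
            s: [
                GenomicInterval("chrS", int(p), int(p) + int(rng.integers(50, 400)))
                for p in rng.integers(0, 100_000, 60)
            ]
            for s in ("s1", "s2", "s3")
        }
        t = build_master_table(peaks)
        assert t.presence.any(axis=1).all()


def _table(antibody, presence, counts):
    loci = [
        GenomicInterval("chrS", 1000 * i, 1000 * i + 500)
        for i in range(presence.shape[0])
    ]
    ids = [l.locus_id for l in loci]
    return MasterPeakTable(
        antibody,
        loci,
        pd.DataFrame(presence, index=ids, columns=counts.columns),
        counts.set_axis(ids, axis=0),
    )


class TestFilterForScreen:
    def make_pair(self, n_samples=5):
        cols = [f"s{i}" for i in range(n_samples)]
        presence = np.ones((3, n_samples), bool)
        presence[0, 2:] = False  # locus 0 detected in 2 samples only
        counts = pd.DataFrame(
            [[50.0] * n_samples, [10.0] * n_samples, [9.9] * n_samples], columns=cols
        )
        a = _table("H3K27ac", presence, counts.copy())
        b = _table("Brd4", np.ones((3, n_samples), bool), counts.copy())
        return a, b

    def test_under_min_samples_removed(self):
        a, b = self.make_pair()
        pairs = filter_for_screen(a, b)
        kept = [l.locus_id for l in pairs.loci_k27ac]
        assert "chrS:0-500" not in kept

    def test_max_count_exactly_ten_retained(self):
        a, b = self.make_pair()
        pairs = filter_for_screen(a, b)
        kept = [l.locus_id for l in pairs.loci_k27ac]
        assert "chrS:1000-1500" in kept  # max exactly 10: rule removes "<10"
        assert "chrS:2000-2500" not in kept  # max 9.9

    def test_cross_mark_overlap_required(self):
        cols = ["s0", "s1", "s2"]
        counts = pd.DataFrame([[50.0] * 3], columns=cols)
        a = _table("H3K27ac", np.ones((1, 3), bool), counts.copy())
        # brd4 locus far away: no overlap
        loci = [GenomicInterval("chrS", 900_000, 900_500)]
        b = MasterPeakTable(
            "Brd4",
            loci,
            pd.DataFrame(np.ones((1, 3), bool), index=[loci[0].locus_id], columns=cols),
            pd.DataFrame([[50.0] * 3], index=[loci[0].locus_id], columns=cols),
        )
        pairs = filter_for_screen(a, b)
        assert len(pairs.loci_k27ac) == 0

    def test_sample_set_mismatch_raises(self):
        a, _ = self.make_pair(5)
        _, b = self.make_pair(4)
        with pytest.raises(ValueError, match="sample set"):
            filter_for_screen(a, b)

    def test_survivor_count_matches_truth_table(self, rng):
        cols = [f"s{i}" for i in range(6)]
        n = 40
        presence = rng.random((n, 6)) < 0.6
        counts = pd.DataFrame(rng.uniform(0, 30, (n, 6)), columns=cols)
        a = _table("H3K27ac", presence, counts.copy())
        b = _table("Brd4", np.ones((n, 6), bool), counts.copy() + 20)
        pairs = filter_for_screen(a, b)
        expected = sum(
            presence[i].sum() >= 3 and counts.iloc[i].max() >= 10 for i in range(n)
        )  # co-located loci always overlap their partner here
        assert len(pairs.loci_k27ac) == expected


class TestKendallTau:
    def test_perfect_concordance_and_discordance(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x) == pytest.approx(1.0)
        assert kendall_tau(x, -x) == pytest.approx(-1.0)

    def test_textbook_four_point_example(self):
        assert kendall_tau([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(1 / 3)

    def test_matches_brute_force_oracle_with_ties(self, rng):
        for _ in range(50):
            x = rng.integers(0, 8, 19).astype(float)  # many ties
            y = rng.normal(size=19)
            assert kendall_tau(x, y) == pytest.approx(
                brute_force_tau(x, y), abs=1e-12
            )

    def test_matches_scipy_tau_b(self, rng):
        for _ in range(20):
            x = rng.normal(size=19)
            y = rng.normal(size=19)
            assert kendall_tau(x, y) == pytest.approx(
                stats.kendalltau(x, y).statistic, abs=1e-12
            )

    def test_all_tied_vector_raises(self):
        with pytest.raises(ValueError, match="all ties"):
            kendall_tau([1.0] * 5, [1, 2, 3, 4, 5])

    def test_matrix_version_consistent_with_scalar(self, rng):
        X = rng.normal(size=(20, 19))
        y = rng.normal(size=19)
        taus = kendall_tau_matrix(X, y)
        for i in range(20):
            assert taus[i] == pytest.approx(kendall_tau(X[i], y), abs=1e-14)


class TestDependencyScreen:
    @pytest.mark.parametrize(
        "taus,expected",
        [
            ((0.5, 0.2), "none"),  # one mark below cutoff
            ((0.4, -0.4), "none"),  # discordant signs
            ((0.31, 0.31), "YapD_H"),
            ((-0.31, -0.5), "YapD_L"),
            ((0.3, 0.5), "none"),  # strict inequality at the cutoff
        ],
    )
    def test_concordance_labels(self, taus, expected):
        assert concordance_label(*taus, cutoff=0.3) == expected

    def test_labels_invariant_under_monotone_score_transform(self, rng):
        n, m = 60, 19
        cols = [f"s{i}" for i in range(m)]
        loci = [GenomicInterval("chrS", 1000 * i, 1000 * i + 500) for i in range(n)]
        counts = pd.DataFrame(
            rng.poisson(30, (n, m)).astype(float),
            index=[l.locus_id for l in loci],
            columns=cols,
        )
        pairs = ScreenPairs(loci, loci, counts, counts)
        scores = pd.Series(rng.normal(size=m), index=cols)
        r1 = dependency_screen(pairs, scores)
        r2 = dependency_screen(pairs, np.exp(scores) * 3 + 1)
        assert (r1.label == r2.label).all()
        assert np.allclose(r1.tau_k27ac, r2.tau_k27ac)

    def test_high_and_low_sets_disjoint_and_bounded(self, small_panel):
        from depscan.io import read_count_matrix

        out, truth = small_panel
        counts = {
            ab: read_count_matrix(out / "counts" / f"{ab}.tsv")
            for ab in ("H3K27ac", "Brd4")
        }
        loci = list(counts["H3K27ac"].index)
        ivs = [None] * len(loci)
        from depscan.io import parse_locus_id

        ivs = [parse_locus_id(l) for l in loci]
        pairs = ScreenPairs(ivs, ivs, counts["H3K27ac"], counts["Brd4"])
        scores = pd.Series(
            truth.lines.dependency.to_numpy(), index=truth.lines.index
        )
        res = dependency_screen(pairs, scores)
        n_h = (res.label == "YapD_H").sum()
        n_l = (res.label == "YapD_L").sum()
        assert n_h + n_l <= len(res)
        assert not ((res.label == "YapD_H") & (res.label == "YapD_L")).any()

    def test_missing_score_raises(self, rng):
        loci = [GenomicInterval("chrS", 0, 500)]
        counts = pd.DataFrame(
            rng.poisson(30, (1, 4)).astype(float),
            index=["chrS:0-500"],
            columns=list("abcd"),
        )
        pairs = ScreenPairs(loci, loci, counts, counts)
        with pytest.raises(ValueError, match="missing dependency score"):
            dependency_screen(pairs, pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))


class TestRrho:
    def test_identical_rankings_match_closed_form(self):
        n = 40
        s = pd.Series(np.arange(n, 0, -1, dtype=float))
        grid = rrho_map(s, s, step=5)
        from math import comb, log10

        for i in (5, 10, 20):
            assert grid.loc[i, i] == pytest.approx(log10(comb(n, i)), rel=1e-9)

    def test_cell_matches_hypergeometric_tail_sum(self):
        # N=20, top-5 vs top-5 with overlap 2
        n = 20
        s1 = pd.Series(np.arange(n, 0, -1, dtype=float))
        order2 = [0, 1, 7, 8, 9, 2, 3, 4] + list(range(10, 20)) + [5, 6]
        r2 = np.empty(n)
        r2[order2] = np.arange(n, 0, -1)
        s2 = pd.Series(r2)
        grid = rrho_map(s1, s2, step=5)
        from math import comb

        k_overlap = len({0, 1, 2, 3, 4} & set(order2[:5]))
        assert k_overlap == 2
        tail = sum(
            comb(5, x) * comb(15, 5 - x) for x in range(2, 6)
        ) / comb(20, 5)
        assert grid.loc[5, 5] == pytest.approx(-np.log10(tail), rel=1e-9)

    def test_independent_lists_show_no_enrichment(self, rng):
        medians = []
        for _ in range(100):
            n = 100
            s1 = pd.Series(rng.permutation(n).astype(float))
            s2 = pd.Series(rng.permutation(n).astype(float))
            grid = rrho_map(s1, s2, step=2)
            medians.append(np.median(grid.to_numpy()))
        assert np.median(medians) <= 1.0

    def test_step_too_large_raises(self):
        s = pd.Series(np.arange(10.0))
        with pytest.raises(ValueError, match="step"):
            rrho_map(s, s, step=10)


class TestClustering:
    def test_identical_columns_merge_first_at_height_zero(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        m["d"] = m["a"]
        res = cluster_heatmap_order(m)
        first = res.col_linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)
        assert {int(first[0]), int(first[1])} == {0, 3}

    def test_planted_line_clusters_recovered_at_k3(self, rng):
        centers = np.array([[-8.0], [0.0], [8.0]])
        cols = []
        truth = []
        for c in range(3):
            for i in range(5):
                cols.append(centers[c, 0] + rng.normal(0, 0.3, 30))
                truth.append(c)
        mat = pd.DataFrame(np.array(cols).T + rng.normal(0, 0.3, (30, 15)))
        res = cluster_heatmap_order(mat, scale="row")
        labels = cut_clusters(res.col_linkage, 3)
        # same-truth columns share a label, different-truth don't
        for i in range(15):
            for j in range(15):
                assert (labels[i] == labels[j]) == (truth[i] == truth[j])

    def test_row_permutation_leaves_memberships_unchanged(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 6)))
        mat.iloc[:, :3] += 5.0
        res1 = cluster_heatmap_order(mat)
        perm = rng.permutation(20)
        res2 = cluster_heatmap_order(mat.iloc[perm])
        l1 = cut_clusters(res1.col_linkage, 2)
        l2 = cut_clusters(res2.col_linkage, 2)
        assert (
            [set(np.where(l1 == k)[0]) for k in (1, 2)]
            == [set(np.where(l2 == k)[0]) for k in (1, 2)]
            or [set(np.where(l1 == k)[0]) for k in (1, 2)]
            == [set(np.where(l2 == k)[0]) for k in (2, 1)]
        )

    def test_constant_row_under_row_scaling_raises(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="constant row"):
            cluster_heatmap_order(m)

    def test_ward_linkage_matches_r_ward_d2(self, rng, tmp_path):
        """Merge heights should equal R hclust(method='ward.D2') on the
        same distance matrix."""
        import subprocess

        x = rng.normal(size=(12, 5))
        csv = tmp_path / "x.tsv"
        pd.DataFrame(x).to_csv(csv, sep="\t", index=False)
        r = subprocess.run(
            [
                "Rscript",
                "-e",
                f'x <- as.matrix(read.delim("{csv}"));'
                f'h <- hclust(dist(x), method="ward.D2");'
                f"cat(sort(h$height))",
            ],
            capture_output=True,
            text=True,
            check=True,
        )
        theirs = np.array([float(v) for v in r.stdout.split()])
        res = cluster_heatmap_order(pd.DataFrame(x), scale="none")
        mine = np.sort(res.row_linkage[:, 2])
        assert np.allclose(mine, theirs, atol=1e-8)
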