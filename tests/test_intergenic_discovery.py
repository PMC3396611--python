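import numpy as np
import pandas as pd
import pytest

from prognoseq import (
    GenomicInterval,
    RefFlatRecord,
    ROI,
    build_islands,
    classify_intergenic,
    estimate_merge_cutoff,
    filter_rois,
    merge_islands,
    post_fdr_merge,
    roi_counts_per_patient,
)


def _gene(chrom, start, end, name="G"):
    return RefFlatRecord(name, f"NM_{name}", chrom, "+", start, end, start, end, 1, (start,), (end,))


def _random_reads(rng, n, chrom_len=10_000, read_len=50):
    starts = rng.integers(0, chrom_len - read_len, size=n)
    return [GenomicInterval("chr1", int(s), int(s) + read_len) for s in starts]


def _overlap_closure_oracle(reads):
    """O(n^2) oracle: connected components of the read-overlap graph
    (strict overlap; abutting reads are not connected)."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if reads[i].start < reads[j].end and reads[j].start < reads[i].end:
                parent[find(i)] = find(j)
    groups = {}
    for i, r in enumerate(reads):
        groups.setdefault(find(i), []).append(r)
    return sorted(
        ("chr1", min(r.start for r in grp), max(r.end for r in grp), len(grp))
        for grp in groups.values()
    )


class TestBuildIslands:
    def test_single_read(self):
        (isl,) = build_islands([GenomicInterval("chr1", 100, 150)])
        assert (isl.chrom, isl.start, isl.end, isl.count) == ("chr1", 100, 150, 1)

    def test_abutting_reads_stay_separate(self):
        islands = build_islands(
            [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 50, 100)]
        )
        assert [(i.start, i.end) for i in islands] == [(0, 50), (50, 100)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_overlap_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        reads = _random_reads(rng, 300)
        got = sorted((i.chrom, i.start, i.end, i.count) for i in build_islands(reads))
        assert got == _overlap_closure_oracle(reads)

    def test_base_coverage_conservation(self, rng):
        reads = _random_reads(rng, 300)
        cov = np.zeros(10_000, dtype=bool)
        for r in reads:
            cov[r.start : r.end] = True
        icov = np.zeros(10_000, dtype=bool)
        for i in build_islands(reads):
            icov[i.start : i.end] = True
        assert (cov == icov).all()


class TestMergeIslands:
    def test_strict_boundary_at_1000(self):
        a = GenomicInterval("chr1", 0, 100, count=2)
        near = GenomicInterval("chr1", 1099, 1200, count=3)  # gap 999
        far = GenomicInterval("chr1", 1100, 1200, count=3)  # gap 1000
        merged = merge_islands([a, near], 1000, inclusive=False)
        assert len(merged) == 1 and merged[0].pooled_count == 5
        assert len(merge_islands([a, far], 1000, inclusive=False)) == 2

    def test_strict_cutoff_zero_is_identity(self):
        islands = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 50, 100)]
        merged = merge_islands(islands, 0, inclusive=False)
        assert [(r.start, r.end) for r in merged] == [(0, 50), (50, 100)]

    def test_inclusive_merges_at_exact_gap(self):
        islands = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 60, 100)]
        assert len(merge_islands(islands, 10, inclusive=True)) == 1
        assert len(merge_islands(islands, 10, inclusive=False)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        islands = build_islands(_random_reads(rng, 100))
        cutoff = int(rng.integers(0, 300))
        got = merge_islands(islands, cutoff, inclusive=True)
        # O(n^2) oracle: repeatedly merge any mergeable pair until fixpoint
        groups = [[i] for i in islands]
        changed = True
        while changed:
            changed = False
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    lo_a = min(x.start for x in groups[a])
                    hi_a = max(x.end for x in groups[a])
                    lo_b = min(x.start for x in groups[b])
                    hi_b = max(x.end for x in groups[b])
                    gap = max(lo_a, lo_b) - min(hi_a, hi_b)
                    if gap <= cutoff:
                        groups[a].extend(groups.pop(b))
                        changed = True
                        break
                if changed:
                    break
        expected = sorted(
            (min(x.start for x in g), max(x.end for x in g), sum(x.count for x in g))
            for g in groups
        )
        assert [(r.start, r.end, r.pooled_count) for r in got] == expected

    def test_roi_count_non_increasing_in_cutoff(self, rng):
        islands = build_islands(_random_reads(rng, 200))
        counts = [len(merge_islands(islands, c)) for c in (0, 10, 50, 200, 1000)]
        assert counts == sorted(counts, reverse=True)


class TestEstimateMergeCutoff:
    @pytest.fixture
    def tiling_fixture(self):
        """Islands tiling three 1-kb genes with uniform 10-bp internal gaps,
        plus isolated intergenic singletons."""
        islands, genes = [], []
        for g, start in enumerate((10_000, 20_000, 30_000)):
            genes.append(_gene("chr1", start, start + 1000, name=str(g)))
            pos = start
            for _ in range(10):
                islands.append(GenomicInterval("chr1", pos, pos + 91, count=5))
                pos += 101
        for s in (50_000, 60_000, 70_000, 80_000, 90_000):
            islands.append(GenomicInterval("chr1", s, s + 100, count=1))
        return islands, genes

    def test_recovers_internal_gap_width(self, tiling_fixture):
        islands, genes = tiling_fixture
        assert estimate_merge_cutoff(islands, genes, [0, 10, 50]) == 10

    def test_single_candidate_returned(self, tiling_fixture):
        islands, genes = tiling_fixture
        assert estimate_merge_cutoff(islands, genes, [0]) == 0

    def test_deterministic(self, tiling_fixture):
        islands, genes = tiling_fixture
        a = estimate_merge_cutoff(islands, genes, [0, 10, 20, 30, 50])
        b = estimate_merge_cutoff(islands, genes, [0, 10, 20, 30, 50])
        assert a == b

    def test_empty_candidates_rejected(self, tiling_fixture):
        islands, genes = tiling_fixture
        with pytest.raises(ValueError, match="non-empty"):
            estimate_merge_cutoff(islands, genes, [])


class TestFilterRois:
    def test_boundary_roi_retained(self):
        roi = ROI("chr1", 0, 100, pooled_count=75, n_patients=10)  # avg 7.5, depth 0.075
        assert filter_rois([roi]) == [roi]

    def test_short_roi_removed(self):
        roi = ROI("chr1", 0, 99, pooled_count=1000, n_patients=1)
        assert filter_rois([roi]) == []

    def test_matches_triple_predicate_scan(self, rng):
        rois = []
        for _ in range(200):
            start = int(rng.integers(0, 10_000))
            length = int(rng.integers(50, 300))
            rois.append(
                ROI("chr1", start, start + length, int(rng.integers(0, 200)), n_patients=10)
            )
        got = filter_rois(rois)
        expected = [
            r
            for r in rois
            if r.pooled_count / 10 >= 5 and r.length >= 100 and (r.pooled_count / 10) / r.length >= 0.075
        ]
        assert got == expected

    def test_retained_count_monotone_in_thresholds(self, rng):
        rois = [
            ROI("chr1", s, s + int(l), int(c), n_patients=8)
            for s, l, c in zip(
                rng.integers(0, 10**6, 100), rng.integers(60, 400, 100), rng.integers(0, 400, 100)
            )
        ]
        base = len(filter_rois(rois))
        assert len(filter_rois(rois, min_avg_count=10)) <= base
        assert len(filter_rois(rois, min_length=200)) <= base
        assert len(filter_rois(rois, min_depth=0.15)) <= base


class TestClassifyIntergenic:
    def test_intron_interior_is_not_intergenic(self):
        gene = RefFlatRecord(
            "G", "NM_G", "chr1", "+", 1000, 5000, 1000, 5000, 2, (1000, 4000), (2000, 5000)
        )
        roi = ROI("chr1", 2500, 3000, 10)  # inside the intron, within the tx span
        assert classify_intergenic([roi], [gene]) == []

    def test_half_open_boundary_at_tx_end(self):
        gene = _gene("chr1", 1000, 2000)
        touching = ROI("chr1", 2000, 2100, 10)  # starts exactly at txEnd: no overlap
        overlapping = ROI("chr1", 1999, 2100, 10)
        assert classify_intergenic([touching], [gene]) == [touching]
        assert classify_intergenic([overlapping], [gene]) == []

    def test_matches_brute_force_intersection(self, rng):
        genes = [
            _gene("chr1", int(s), int(s) + int(l), name=str(i))
            for i, (s, l) in enumerate(zip(rng.integers(0, 90_000, 20), rng.integers(500, 5000, 20)))
        ]
        rois = [
            ROI("chr1", int(s), int(s) + int(l), 10)
            for s, l in zip(rng.integers(0, 95_000, 100), rng.integers(100, 2000, 100))
        ]
        got = classify_intergenic(rois, genes)
        expected = [
            r
            for r in rois
            if not any(r.start < g.tx_end and g.tx_start < r.end for g in genes)
        ]
        assert got == expected


class TestRoiCounts:
    def test_zero_reads_gives_zero_column(self):
        rois = [ROI("chr1", 0, 200, 0, n_patients=2)]
        cm = roi_counts_per_patient(rois, [GenomicInterval("chr1", 0, 50, label="p1")], ["p1", "p2"])
        assert cm.values.loc[rois[0].feature_id, "p2"] == 0
        assert cm.values.loc[rois[0].feature_id, "p1"] == 1

    def test_totals_conserved_against_brute_force(self, rng):
        reads = [
            GenomicInterval("chr1", int(s), int(s) + 50, label=f"p{int(p)}")
            for s, p in zip(rng.integers(0, 5000, 400), rng.integers(0, 4, 400))
        ]
        rois = [ROI("chr1", s, s + 300, 0, n_patients=4) for s in (0, 1000, 2500, 4000)]
        cm = roi_counts_per_patient(rois, reads, [f"p{i}" for i in range(4)])
        for roi in rois:
            for j in range(4):
                expected = sum(
                    1
                    for r in reads
                    if r.label == f"p{j}" and r.start < roi.end and r.end > roi.start
                )
                assert cm.values.loc[roi.feature_id, f"p{j}"] == expected

    def test_disjoint_rois_count_each_read_once(self):
        rois = [ROI("chr1", 0, 100, 0), ROI("chr1", 200, 300, 0)]
        reads = [GenomicInterval("chr1", 50, 100, label="p1")]
        cm = roi_counts_per_patient(rois, reads, ["p1"])
        assert cm.values["p1"].sum() == 1


class TestPostFdrMerge:
    def test_no_close_pairs_is_identity(self):
        rois = [ROI("chr1", 0, 100, 5), ROI("chr1", 5000, 5100, 5)]
        merged, report = post_fdr_merge(rois)
        assert [(r.start, r.end) for r in merged] == [(0, 100), (5000, 5100)]
        assert report["n_merged_transcripts"] == 2

    def test_coexpressed_neighbors_drive_merge_report(self, rng):
        """Adjacent ROI pairs simulated from one shared transcript show higher
        within-merged co-expression than scattered singletons."""
        rois, rows = [], {}
        base = 0
        for k in range(6):  # co-expressed adjacent pairs (gap 500 < 1000)
            a = ROI("chr1", base, base + 300, 10)
            b = ROI("chr1", base + 800, base + 1100, 10)
            shared = rng.standard_normal(30)
            rows[a.feature_id] = shared + rng.normal(0, 0.2, 30)
            rows[b.feature_id] = shared + rng.normal(0, 0.2, 30)
            rois += [a, b]
            base += 10_000
        for k in range(6):  # isolated, independent ROIs
            s = 200_000 + k * 10_000
            r = ROI("chr1", s, s + 300, 10)
            rows[r.feature_id] = rng.standard_normal(30)
            rois.append(r)
        expr = pd.DataFrame(rows).T
        merged, report = post_fdr_merge(rois, expr=expr)
        assert report["n_merged_transcripts"] == 12
        assert report["median_r_within_merged"] > report["median_r_between_nonmerged"]

    def test_order_independent(self, rng):
        rois = [
            ROI("chr1", int(s), int(s) + 200, 5)
            for s in rng.choice(np.arange(0, 100_000, 700), size=40, replace=False)
        ]
        fwd, _ = post_fdr_merge(rois)
        rev, _ = post_fdr_merge(list(reversed(rois)))
        assert [(r.start, r.end, r.pooled_count) for r in fwd] == [
            (r.start, r.end, r.pooled_count) for r in rev
        ]
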