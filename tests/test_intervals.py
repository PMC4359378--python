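"""Interval toolkit vs brute-force oracles and analytic expectations."""

import numpy as np
import pytest
from scipy import stats

from adipotf import intervals as itk
from adipotf.types import GenomicInterval as GI
from adipotf.types import GenomeLayout, GeneModel, PeakSet

LAYOUT = GenomeLayout({"chr1": 100_000, "chr2": 80_000})


def random_peaks(rng, n, layout=LAYOUT, max_len=400):
    ivs = []
    for i in range(n):
        chrom = list(layout.lengths)[rng.integers(len(layout.lengths))]
        length = int(rng.integers(20, max_len))
        start = int(rng.integers(0, layout[chrom] - length))
        ivs.append(GI(chrom, start, start + length, name=f"p{i}",
                      score=float(rng.uniform(0, 10)),
                      summit=start + length // 2))
    return PeakSet(ivs)


def random_genes(rng, n, layout=LAYOUT):
    genes = []
    for i in range(n):
        chrom = list(layout.lengths)[rng.integers(len(layout.lengths))]
        length = int(rng.integers(1000, 5000))
        start = int(rng.integers(0, layout[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else start + length - 1
        genes.append(GeneModel(f"g{i:03d}", chrom, strand, tss,
                               GI(chrom, start, start + length)))
    return genes


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

class TestMerge:
    def test_idempotent_on_identical_sets(self, rng):
        a = itk.merge_peak_calls(random_peaks(rng, 20), PeakSet([]))
        merged = itk.merge_peak_calls(a, a)
        assert [(i.chrom, i.start, i.end) for i in merged] == [
            (i.chrom, i.start, i.end) for i in a
        ]

    def test_overlapping_intervals_coalesce(self):
        a = PeakSet([GI("chr1", 100, 200)])
        b = PeakSet([GI("chr1", 150, 250)])
        merged = itk.merge_peak_calls(a, b)
        assert [(i.start, i.end) for i in merged] == [(100, 250)]

    def test_adjacent_intervals_coalesce(self):
        merged = itk.merge_peak_calls(
            PeakSet([GI("chr1", 100, 200)]), PeakSet([GI("chr1", 200, 300)])
        )
        assert [(i.start, i.end) for i in merged] == [(100, 300)]

    def test_disjoint_union_count(self, rng):
        a = PeakSet([GI("chr1", i * 1000, i * 1000 + 100) for i in range(5)])
        b = PeakSet([GI("chr2", i * 1000, i * 1000 + 100) for i in range(3)])
        assert len(itk.merge_peak_calls(a, b)) == 8

    def test_summit_from_higher_score_source(self):
        a = PeakSet([GI("chr1", 100, 200, score=5.0, summit=120, source="A")])
        b = PeakSet([GI("chr1", 150, 300, score=9.0, summit=280, source="B")])
        merged = itk.merge_peak_calls(a, b)
        assert merged[0].summit == 280

    def test_midpoint_summit_without_scores(self):
        merged = itk.merge_peak_calls(
            PeakSet([GI("chr1", 100, 200)]), PeakSet([GI("chr1", 180, 300)])
        )
        assert merged[0].summit == 200

    def test_output_non_overlapping(self, rng):
        merged = itk.merge_peak_calls(random_peaks(rng, 100), random_peaks(rng, 100))
        # adjacent (0-gap) pairs must have been coalesced too, hence strict <
        for x, y in zip(merged, merged[1:]):
            if x.chrom == y.chrom:
                assert x.end < y.start

    def test_unknown_chrom_errors(self):
        with pytest.raises(KeyError):
            itk.merge_peak_calls(
                PeakSet([GI("chrX", 0, 10)]), PeakSet([]), layout=LAYOUT
            )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class TestAnnotation:
    GENES = [
        GeneModel("gene1", "chr1", "+", 10_000, GI("chr1", 10_000, 20_000),
                  (GI("chr1", 10_000, 11_000), GI("chr1", 15_000, 16_000))),
    ]

    def test_tss_window_beats_exon(self):
        # overlaps both the first exon and the TSS window -> TSS
        assert itk.annotate_peak(GI("chr1", 10_200, 10_400), self.GENES) == "TSS"

    def test_exon_outside_tss_window(self):
        assert itk.annotate_peak(GI("chr1", 15_100, 15_200), self.GENES) == "exon"

    def test_intron(self):
        assert itk.annotate_peak(GI("chr1", 12_000, 12_100), self.GENES) == "intron"

    def test_proximal(self):
        assert itk.annotate_peak(GI("chr1", 25_000, 25_100), self.GENES) == "proximal"

    def test_distal_beyond_10kb(self):
        assert itk.annotate_peak(GI("chr1", 35_000, 35_100), self.GENES) == "distal"

    def test_categories_partition_peaks(self, rng):
        peaks = random_peaks(rng, 150)
        genes = random_genes(rng, 30)
        cats = itk.annotate_peaks(peaks, genes)
        assert len(cats) == len(peaks)
        assert set(cats.values()) <= set(itk.ANNOTATION_CATEGORIES)


# ---------------------------------------------------------------------------
# peak-gene assignment and closest gene vs brute force
# ---------------------------------------------------------------------------

def brute_force_assignment(peaks, genes, max_dist):
    p2g = {i: [] for i in range(len(peaks))}
    for i, iv in enumerate(peaks):
        for g in genes:
            d = iv.distance_to(g.body)
            if d is not None and d <= max_dist:
                p2g[i].append(g.gene_id)
    return p2g


class TestAssignment:
    def test_overlapping_peak_assigned_distance_zero(self):
        genes = [GeneModel("g1", "chr1", "+", 1000, GI("chr1", 1000, 5000))]
        p2g, g2p = itk.assign_peaks_to_genes(PeakSet([GI("chr1", 2000, 2100)]), genes)
        assert p2g[0] == ["g1"]
        assert g2p["g1"] == [0]

    def test_boundary_10001_bp_not_assigned(self):
        genes = [GeneModel("g1", "chr1", "+", 20_000, GI("chr1", 20_000, 25_000))]
        near = PeakSet([GI("chr1", 9_900, 10_000)])   # gap exactly 10,000
        far = PeakSet([GI("chr1", 9_899, 9_999)])     # gap 10,001
        assert itk.assign_peaks_to_genes(near, genes)[0][0] == ["g1"]
        assert itk.assign_peaks_to_genes(far, genes)[0][0] == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng, 100)
        genes = random_genes(rng, 25)
        p2g, _ = itk.assign_peaks_to_genes(peaks, genes)
        assert p2g == brute_force_assignment(peaks, genes, 10_000)


class TestClosestGene:
    def test_summit_at_tss(self):
        genes = [GeneModel("g1", "chr1", "+", 5000, GI("chr1", 5000, 8000))]
        gid, d = itk.closest_gene(GI("chr1", 4900, 5200, summit=5000), genes)
        assert (gid, d) == ("g1", 0)

    def test_tie_breaks_lexicographically(self):
        genes = [
            GeneModel("gb", "chr1", "+", 1000, GI("chr1", 1000, 2000)),
            GeneModel("ga", "chr1", "+", 3000, GI("chr1", 3000, 4000)),
        ]
        gid, _ = itk.closest_gene(GI("chr1", 1990, 2011, summit=2000), genes)
        assert gid == "ga"

    def test_sign_is_strand_aware(self):
        plus = [GeneModel("g1", "chr1", "+", 5000, GI("chr1", 5000, 8000))]
        minus = [GeneModel("g2", "chr1", "-", 7999, GI("chr1", 5000, 8000))]
        # summit at 4000: upstream of the + gene
        assert itk.closest_gene(GI("chr1", 3950, 4050, summit=4000), plus)[1] == -1000
        # summit at 9000: upstream of the - gene (negative signed distance)
        assert itk.closest_gene(GI("chr1", 8950, 9050, summit=9000), minus)[1] == -1001

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        peaks = random_peaks(rng, 50)
        genes = random_genes(rng, 20)
        for iv in peaks:
            gid, signed = itk.closest_gene(iv, genes)
            dists = sorted(
                (abs(iv.effective_summit - g.tss), g.gene_id)
                for g in genes if g.chrom == iv.chrom
            )
            assert (abs(signed), gid) == dists[0]


# ---------------------------------------------------------------------------
# shifted nulls
# ---------------------------------------------------------------------------

class TestShift:
    def test_lengths_and_chrom_counts_preserved(self, rng):
        peaks = random_peaks(rng, 50)
        shifted = itk.shift_peaks_random(peaks, LAYOUT, 3)
        for chrom in LAYOUT.lengths:
            orig = sorted(iv.length for iv in peaks if iv.chrom == chrom)
            new = sorted(iv.length for iv in shifted if iv.chrom == chrom)
            assert orig == new

    def test_deterministic_and_seed_sensitive(self, rng):
        peaks = random_peaks(rng, 30)
        s1 = itk.shift_peaks_random(peaks, LAYOUT, 5)
        s2 = itk.shift_peaks_random(peaks, LAYOUT, 5)
        s3 = itk.shift_peaks_random(peaks, LAYOUT, 6)
        assert s1 == s2
        assert s1 != s3

    def test_oversized_interval_errors(self):
        small = GenomeLayout({"chr1": 100})
        with pytest.raises(ValueError, match="exceeds chromosome length"):
            itk.shift_peaks_random(PeakSet([GI("chr1", 0, 100)]),
                                   GenomeLayout({"chr1": 50}), 0)
        itk.shift_peaks_random(PeakSet([GI("chr1", 0, 100)]), small, 0)

    def test_overlap_rate_matches_uniform_expectation(self):
        """A shifted 1-bp peak set hits a fixed feature set at the rate of
        the genome fraction the features cover."""
        layout = GenomeLayout({"chr1": 10_000})
        features = PeakSet([GI("chr1", i * 1000, i * 1000 + 200) for i in range(10)])
        covered = 10 * 200 / 10_000
        peaks = PeakSet([GI("chr1", 0, 1, name=f"x{i}") for i in range(50)])
        rates = []
        for seed in range(100):
            shifted = itk.shift_peaks_random(peaks, layout, seed)
            n, _ = itk.overlap_peaks(shifted, features)
            rates.append(n / len(peaks))
        se = np.sqrt(covered * (1 - covered) / (50 * 100))
        assert np.mean(rates) == pytest.approx(covered, abs=3 * se + 0.01)


# ---------------------------------------------------------------------------
# overlap counting and enrichment
# ---------------------------------------------------------------------------

class TestOverlap:
    def test_subset_counts_all(self, rng):
        b = random_peaks(rng, 40)
        a = PeakSet(list(b)[:10])
        n, _ = itk.overlap_peaks(a, b)
        assert n == 10

    def test_disjoint_counts_zero(self):
        a = PeakSet([GI("chr1", 0, 10)])
        b = PeakSet([GI("chr1", 10, 20)])  # book-ended, no shared bp
        assert itk.overlap_peaks(a, b)[0] == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 200)
        b = random_peaks(rng, 150)
        n, pairs = itk.overlap_peaks(a, b)
        brute = {
            (i, j)
            for i, x in enumerate(a)
            for j, y in enumerate(b)
            if x.overlaps(y)
        }
        assert set(pairs) == brute
        assert n == len({i for i, _ in brute})


class TestOverlapEnrichment:
    def test_self_overlap_is_maximal(self, rng):
        a = random_peaks(rng, 30)
        res = itk.overlap_enrichment(a, a, LAYOUT, n_shifts=19, seed=0)
        assert res["observed"] == len(a)
        assert res["fold"] > 1
        assert res["perm_p"] == pytest.approx(1 / 20)

    def test_perm_p_bounds(self, rng):
        a = random_peaks(rng, 20)
        b = random_peaks(rng, 20)
        res = itk.overlap_enrichment(a, b, LAYOUT, n_shifts=9, seed=1)
        assert 1 / 10 <= res["perm_p"] <= 1.0

    def test_independent_sets_fold_near_one(self):
        folds = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            a = random_peaks(rng, 80)
            b = random_peaks(rng, 80)
            res = itk.overlap_enrichment(a, b, LAYOUT, n_shifts=20, seed=seed)
            folds.append(res["fold"])
        assert np.mean(folds) == pytest.approx(1.0, abs=0.25)

    def test_fisher_p_equals_hypergeometric_enumeration(self):
        """Fisher's exact two-sided p on [[6,4],[2,8]] must equal the sum of
        hypergeometric probabilities of all tables at least as extreme."""
        table = np.array([[6, 4], [2, 8]])
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        n1, n2 = 10, 10
        k = 8  # first-column total
        probs = [stats.hypergeom.pmf(x, n1 + n2, k, n1)
                 for x in range(max(0, k - n2), min(k, n1) + 1)]
        p_obs = stats.hypergeom.pmf(6, n1 + n2, k, n1)
        manual = sum(p for p in probs if p <= p_obs * (1 + 1e-9))
        assert fisher_p == pytest.approx(manual, rel=1e-9)


class TestCategoryEnrichment:
    def test_extreme_enrichment_minimal_p(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        promoters = PeakSet([GI("chr1", 0, 3000)])
        peaks = PeakSet([GI("chr1", i * 100, i * 100 + 50, name=f"p{i}")
                         for i in range(20)])
        res = itk.category_enrichment(peaks, {"promoter": promoters}, layout,
                                      n_shifts=1, seed=4)
        r = res["promoter"]
        assert r["observed"] == 20  # every real peak sits in the promoter set
        assert r["p"] < 1e-4
        assert r["fold"] > 1.5

    def test_genome_wide_feature_is_null(self):
        layout = GenomeLayout({"chr1": 10_000})
        everything = PeakSet([GI("chr1", 0, 10_000)])
        peaks = PeakSet([GI("chr1", i * 500, i * 500 + 100) for i in range(10)])
        res = itk.category_enrichment(peaks, {"all": everything}, layout,
                                      n_shifts=2, seed=0)
        assert res["all"]["fold"] == pytest.approx(1.0)
        assert res["all"]["p"] == pytest.approx(1.0)

    def test_empty_feature_set(self):
        res = itk.category_enrichment(
            PeakSet([GI("chr1", 0, 100)]), {"none": PeakSet([])}, LAYOUT,
            n_shifts=1, seed=0)
        assert res["none"]["p"] == 1.0
        assert np.isnan(res["none"]["fold"])

    def test_small_instance_matches_direct_hypergeometric(self):
        layout = GenomeLayout({"chr1": 50_000})
        feature = PeakSet([GI("chr1", 0, 10_000)])
        peaks = PeakSet([GI("chr1", i * 2000, i * 2000 + 100, name=f"p{i}")
                         for i in range(10)])
        res = itk.category_enrichment(peaks, {"f": feature}, layout,
                                      n_shifts=3, seed=7)["f"]
        obs = res["observed"]
        shifted_hits = round(res["expected"] * 40 / 10) - obs
        successes = obs + shifted_hits
        expected_p = stats.hypergeom.sf(obs - 1, 40, successes, 10)
        assert res["p"] == pytest.approx(expected_p, rel=1e-9)


# ---------------------------------------------------------------------------
# summit signal matrices
# ---------------------------------------------------------------------------

class TestSignalMatrix:
    SUMMITS = PeakSet([GI("chr1", 40_000, 40_400, name="s1", summit=40_200),
                       GI("chr1", 60_000, 60_400, name="s2", summit=60_200)])

    def test_no_tags_all_zero(self):
        mats, order, flagged = itk.summit_signal_matrix(
            {"a": []}, self.SUMMITS, LAYOUT)
        assert mats["a"].shape == (2, 400)
        assert (mats["a"] == 0).all()
        assert flagged == []

    def test_single_tag_geometry(self):
        tags = [("chr1", 40_200, "+")]
        mats, order, _ = itk.summit_signal_matrix({"a": tags}, self.SUMMITS, LAYOUT)
        mat = mats["a"]
        row = mat[list(order).index(0)]
        # tag extends over [40200, 40400): bins 200..239 of the 400-bin window
        assert (row[200:240] > 0).all()
        assert (row[:200] == 0).all() and (row[240:] == 0).all()

    def test_minus_strand_extension(self):
        tags = [("chr1", 40_199, "-")]
        mats, order, _ = itk.summit_signal_matrix({"a": tags}, self.SUMMITS, LAYOUT)
        row = mats["a"][list(order).index(0)]
        # covers [40000, 40200): bins 160..199
        assert (row[160:200] > 0).all()
        assert (row[200:] == 0).all()

    def test_size_factor_invariance(self, rng):
        tags = [("chr1", int(p), "+") for p in rng.integers(39_500, 41_000, 200)]
        m1, _, _ = itk.summit_signal_matrix(
            {"a": tags}, self.SUMMITS, LAYOUT, size_factors={"a": 1.0})
        m2, _, _ = itk.summit_signal_matrix(
            {"a": tags + tags}, self.SUMMITS, LAYOUT, size_factors={"a": 2.0})
        np.testing.assert_allclose(m1["a"], m2["a"])

    def test_edge_summit_flagged(self):
        near_edge = PeakSet([GI("chr1", 0, 500, name="e", summit=100)])
        _, _, flagged = itk.summit_signal_matrix({"a": []}, near_edge, LAYOUT)
        assert flagged == [0]
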