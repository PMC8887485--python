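"""Cluster partitioning, overlap stats, gene assignment, strong genes, tests."""

import numpy as np
import pandas as pd
import pytest

from epiquant.domains import (
    ClusterPartition,
    DomainError,
    GeneModel,
    Peak,
    PeakSet,
    assign_peaks_to_genes,
    classify_strong_genes,
    cluster_peaks,
    gene_set_venn,
    overlap_fraction,
    tss_distance_distribution,
    two_group_test,
    width_stats,
)


def ps(label, intervals):
    return PeakSet(label, [Peak("chr1", s, e) for s, e in intervals])


# -- brute-force oracle -----------------------------------------------------

def brute_force_partition(set_a, set_b, min_overlap):
    """All-pairs scanner over the two sets (O(n*m) reference)."""
    def shared(p, other):
        return any(
            q.chrom == p.chrom and min(p.end, q.end) - max(p.start, q.start) >= min_overlap
            for q in other.peaks
        )

    c1 = [p for p in set_a.peaks if not shared(p, set_b)]
    c2a = [p for p in set_a.peaks if shared(p, set_b)]
    c2b = [p for p in set_b.peaks if shared(p, set_a)]
    c3 = [p for p in set_b.peaks if not shared(p, set_a)]
    return c1, c2a, c2b, c3


def brute_force_gene_assignment(peak_set, genes, flank):
    out = {}
    for g in genes:
        chrom, s, e = g.window(flank)
        hits = [p for p in peak_set.peaks if p.chrom == chrom and p.start < e and s < p.end]
        if hits:
            out[g.gene_id] = sorted(hits)
    return out


# -- cluster_peaks ----------------------------------------------------------

def test_lone_peak_is_cluster_one():
    part = cluster_peaks(ps("A", [(100, 200)]), ps("B", []), 50)
    assert part.summary() == {
        "cluster_I": 1, "cluster_II_A": 0, "cluster_II_B": 0, "cluster_III": 0
    }


def test_overlap_exactly_at_threshold_is_shared():
    part = cluster_peaks(ps("A", [(100, 200)]), ps("B", [(150, 250)]), 50)
    assert part.summary()["cluster_II_A"] == 1
    assert part.summary()["cluster_I"] == 0


def test_overlap_one_below_threshold_splits():
    part = cluster_peaks(ps("A", [(100, 200)]), ps("B", [(151, 250)]), 50)
    assert part.summary() == {
        "cluster_I": 1, "cluster_II_A": 0, "cluster_II_B": 0, "cluster_III": 1
    }


def test_partition_completeness_random_instances():
    """|I| + |II_A| = |A| and |III| + |II_B| = |B| on random interval sets."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        def random_set(label):
            n = rng.integers(0, 60)
            starts = rng.integers(0, 5000, n)
            widths = rng.integers(1, 300, n)
            return PeakSet(label, [
                Peak(rng.choice(["chr1", "chr2"]), int(s), int(s + w))
                for s, w in zip(starts, widths)
            ])
        a, b = random_set("A"), random_set("B")
        min_ov = int(rng.integers(1, 100))
        part = cluster_peaks(a, b, min_ov)
        assert len(part.cluster1) + len(part.cluster2_a) == len(a)
        assert len(part.cluster3) + len(part.cluster2_b) == len(b)


def test_cluster_matches_brute_force_scanner():
    rng = np.random.default_rng(7)
    for _ in range(50):
        def random_set(label):
            n = rng.integers(1, 40)
            starts = rng.integers(0, 3000, n)
            return PeakSet(label, [
                Peak("chr1", int(s), int(s + rng.integers(1, 200)))
                for s in starts
            ])
        a, b = random_set("A"), random_set("B")
        min_ov = int(rng.integers(1, 80))
        part = cluster_peaks(a, b, min_ov)
        c1, c2a, c2b, c3 = brute_force_partition(a, b, min_ov)
        assert sorted(part.cluster1) == sorted(c1)
        assert sorted(part.cluster2_a) == sorted(c2a)
        assert sorted(part.cluster2_b) == sorted(c2b)
        assert sorted(part.cluster3) == sorted(c3)


def test_swapping_conditions_swaps_clusters_one_and_three():
    a, b = ps("A", [(0, 100), (500, 700)]), ps("B", [(600, 800), (900, 1000)])
    ab = cluster_peaks(a, b, 50)
    ba = cluster_peaks(b, a, 50)
    assert sorted(ab.cluster1) == sorted(ba.cluster3)
    assert sorted(ab.cluster3) == sorted(ba.cluster1)


# -- overlap_fraction -------------------------------------------------------

def test_overlap_fraction_basics():
    a = ps("A", [(0, 100), (200, 300), (400, 500), (600, 700)])
    b_sub = ps("B", [(0, 100), (200, 300), (400, 500), (600, 700)])
    assert overlap_fraction(a, b_sub, 50) == 100.0
    assert overlap_fraction(a, ps("B", [(5000, 6000)]), 50) == 0.0
    three = ps("B", [(0, 100), (200, 300), (400, 500)])
    assert overlap_fraction(a, three, 50) == 75.0
    with pytest.raises(DomainError):
        overlap_fraction(ps("A", []), a, 50)


# -- width stats ------------------------------------------------------------

def test_width_stats_summary():
    assert width_stats(ps("A", [(100, 200)]))["median"] == 100.0
    stats = width_stats(ps("A", [(0, 10), (100, 120), (200, 230)]))
    assert stats["median"] == 20.0
    assert stats["total_bp"] == 60.0
    assert width_stats(ps("A", [])) == {}


def test_merging_abutting_peaks():
    merged = ps("A", [(0, 100), (100, 200)]).merged()
    assert len(merged) == 1
    assert merged.peaks[0].width == 200


# -- TSS distances ----------------------------------------------------------

def test_tss_distance_signed_and_strand_aware():
    genes = [GeneModel("g+", "chr1", "+", 10_000, 14_000),
             GeneModel("g-", "chr2", "-", 14_000, 10_000)]
    edges = [-2000, -500, 500, 2000]
    peak_on_tss = PeakSet("p", [Peak("chr1", 9_950, 10_050)])
    _, dists = tss_distance_distribution(peak_on_tss, genes, edges)
    assert dists[0] == 0
    downstream_plus = PeakSet("p", [Peak("chr1", 10_950, 11_050)])
    _, dists = tss_distance_distribution(downstream_plus, genes, edges)
    assert dists[0] == 1000
    same_pos_minus = PeakSet("p", [Peak("chr2", 14_950, 15_050)])
    _, dists = tss_distance_distribution(same_pos_minus, genes, edges)
    assert dists[0] == -1000


# -- gene assignment --------------------------------------------------------

@pytest.mark.parametrize(
    "peak,expected",
    [
        ((7_600, 7_700), True),   # window starts at 10000 - 2500 = 7500
        ((7_400, 7_499), False),
        ((12_000, 12_100), True),  # inside the gene body
    ],
)
def test_gene_window_association(peak, expected):
    gene = GeneModel("g", "chr1", "+", 10_000, 20_000)
    peaks = PeakSet("p", [Peak("chr1", *peak)])
    gene_to_peaks, _ = assign_peaks_to_genes(peaks, [gene], flank_bp=2_500)
    assert ("g" in gene_to_peaks) is expected


def test_nearest_gene_annotation_tie_breaks_lexicographically():
    genes = [GeneModel("gB", "chr1", "+", 1_000, 2_000),
             GeneModel("gA", "chr1", "+", 3_000, 4_000)]
    peaks = PeakSet("p", [Peak("chr1", 1_950, 2_050)])  # center 2000, equidistant
    _, nearest = assign_peaks_to_genes(peaks, genes)
    assert nearest[peaks.peaks[0]] == "gA"


def test_assignment_matches_brute_force():
    rng = np.random.default_rng(3)
    genes = [
        GeneModel(f"g{i}", "chr1", "+", int(s), int(s + 2_000))
        for i, s in enumerate(rng.integers(0, 80_000, 30))
    ]
    peaks = PeakSet("p", [
        Peak("chr1", int(s), int(s + rng.integers(100, 3_000)))
        for s in rng.integers(0, 80_000, 50)
    ])
    gene_to_peaks, _ = assign_peaks_to_genes(peaks, genes, 2_500)
    oracle = brute_force_gene_assignment(peaks, genes, 2_500)
    assert {g: sorted(v) for g, v in gene_to_peaks.items()} == oracle


# -- strong genes -----------------------------------------------------------

def make_signals(rows):
    return pd.DataFrame(rows, columns=["gene_id", "mean_A", "mean_B"]).set_index("gene_id")


def test_strong_gene_threshold():
    sig = make_signals([("g1", 1.0, 2.0), ("g2", 1.0, 1.9)])
    strong = classify_strong_genes(sig, fold_threshold=2.0, pseudocount=0.0)
    assert strong == {"g1"}  # exactly two-fold counts as "at least two-fold"
    zeros = make_signals([("g3", 0.0, 0.0)])
    for pc in (1e-6, 0.01, 1.0):
        assert classify_strong_genes(zeros, fold_threshold=2.0, pseudocount=pc) == set()


def test_missing_condition_excluded_with_warning():
    sig = make_signals([("g1", 1.0, 2.5), ("g2", np.nan, 3.0)])
    with pytest.warns(UserWarning, match="missing"):
        strong = classify_strong_genes(sig, pseudocount=0.01)
    assert strong == {"g1"}


def test_raising_threshold_never_enlarges_strong_set():
    rng = np.random.default_rng(0)
    sig = make_signals([
        (f"g{i}", float(a), float(b))
        for i, (a, b) in enumerate(zip(rng.gamma(2, 1, 50), rng.gamma(2, 2, 50)))
    ])
    sets = [classify_strong_genes(sig, fold_threshold=t, pseudocount=0.01)
            for t in (1.5, 2.0, 3.0, 5.0)]
    for looser, stricter in zip(sets, sets[1:]):
        assert stricter <= looser


# -- venn -------------------------------------------------------------------

def test_venn_two_sets():
    out = gene_set_venn({"X": {"a", "b", "c"}, "Y": {"b", "c", "d"}})
    assert out == {"X_only": 1, "Y_only": 1, "X&Y": 2}


def test_venn_identical_and_disjoint():
    s = {f"g{i}" for i in range(5)}
    assert gene_set_venn({"X": s, "Y": set(s)})["X&Y"] == 5
    assert gene_set_venn({"X": s, "Y": {"zz"}})["X&Y"] == 0


def test_venn_three_sets_partition_sums_to_union():
    sets = {"X": {"a", "b", "c"}, "Y": {"b", "c", "d"}, "Z": {"c", "e"}}
    out = gene_set_venn(sets)
    assert sum(out.values()) == len(set().union(*sets.values()))
    assert out["X&Y&Z"] == 1


# -- two-group tests --------------------------------------------------------

def test_paired_identical_gives_zero_statistic():
    stat, p = two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
    assert stat == 0.0 and p == 1.0


def test_location_shift_detected():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 500)
    y = rng.normal(1, 1, 500)
    _, p = two_group_test(x, y)
    assert p < 1e-10


def test_welch_agrees_with_student_on_equal_variances():
    """Textbook-formula oracle: with equal n and equal variances the Welch
    statistic coincides with the pooled Student statistic."""
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 40), rng.normal(0.3, 1, 40)
    welch_stat, _ = two_group_test(x, y)
    pooled_sd = np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2)
    student = (np.mean(x) - np.mean(y)) / (pooled_sd * np.sqrt(2 / 40))
    assert welch_stat == pytest.approx(student, rel=1e-9)


def test_insufficient_n_rejected():
    with pytest.raises(DomainError):
        two_group_test([1.0], [2.0, 3.0])
    with pytest.raises(DomainError):
        two_group_test([1.0, 2.0], [2.0, 3.0, 4.0], paired=True)
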