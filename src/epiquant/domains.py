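"""Comparative peak-domain logic for two-condition ChIP experiments.

Given called peak sets for a basal condition A and a perturbed condition B,
peaks partition into cluster I (A-only), cluster II (shared, recorded from
both sides) and cluster III (B-only), with "shared" meaning a reciprocal
overlap of at least a minimum number of bases (conventionally the sequencing
read length, so overlaps shorter than one tag are discarded).  Genes are
associated with peaks through a TSS-to-TES window extended by a flank
(default 2.5 kb); genes whose replicate-averaged normalized signal over that
window rises at least ``fold_threshold``-fold are classified "strong".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from epiquant.chiprx import GenomicTrack, interval_mean


class DomainError(ValueError):
    """Invalid input to the peak-domain analysis."""


@dataclass(frozen=True, order=True)
class Peak:
    """A scored genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise DomainError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """A labelled collection of peaks, kept sorted."""

    label: str
    peaks: list[Peak] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def merged(self) -> "PeakSet":
        """Union of overlapping or abutting peaks within the set."""
        merged: list[Peak] = []
        for chrom, peaks in self.by_chrom().items():
            cur_s, cur_e = peaks[0].start, peaks[0].end
            for p in peaks[1:]:
                if p.start <= cur_e:
                    cur_e = max(cur_e, p.end)
                else:
                    merged.append(Peak(chrom, cur_s, cur_e))
                    cur_s, cur_e = p.start, p.end
            merged.append(Peak(chrom, cur_s, cur_e))
        return PeakSet(self.label, merged, provenance=f"merged({self.provenance})")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES (TSS is the 5' end)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DomainError(f"invalid strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise DomainError(f"{self.gene_id}: plus-strand TSS after TES")
        if self.strand == "-" and self.tss < self.tes:
            raise DomainError(f"{self.gene_id}: minus-strand TSS before TES")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def window(self, flank_bp: int = 2500) -> tuple[str, int, int]:
        """TSS-TES interval extended by the flank on both sides (floored at 0)."""
        return (self.chrom, max(0, self.start - flank_bp), self.end + flank_bp)


@dataclass
class ClusterPartition:
    """Cluster I (A-only), II (shared, both sides) and III (B-only) peaks."""

    label_a: str
    label_b: str
    cluster1: list[Peak]
    cluster2_a: list[Peak]
    cluster2_b: list[Peak]
    cluster3: list[Peak]

    def summary(self) -> dict[str, int]:
        return {
            "cluster_I": len(self.cluster1),
            "cluster_II_A": len(self.cluster2_a),
            "cluster_II_B": len(self.cluster2_b),
            "cluster_III": len(self.cluster3),
        }


def _overlap_trees(peak_set: PeakSet) -> dict[str, IntervalTree]:
    return {
        chrom: IntervalTree.from_tuples((p.start, p.end) for p in peaks)
        for chrom, peaks in peak_set.by_chrom().items()
    }


def _is_shared(peak: Peak, trees: Mapping[str, IntervalTree], min_overlap_bp: int) -> bool:
    tree = trees.get(peak.chrom)
    if tree is None:
        return False
    return any(
        min(peak.end, iv.end) - max(peak.start, iv.begin) >= min_overlap_bp
        for iv in tree.overlap(peak.start, peak.end)
    )


def cluster_peaks(
    set_a: PeakSet, set_b: PeakSet, min_overlap_bp: int = 50
) -> ClusterPartition:
    """Partition two peak sets by reciprocal overlap of >= ``min_overlap_bp``.

    The default minimum should be set to the sequencing read length, so that
    overlaps shorter than one tag do not count as shared.
    """
    if min_overlap_bp < 1:
        raise DomainError("min_overlap_bp must be >= 1")
    trees_a, trees_b = _overlap_trees(set_a), _overlap_trees(set_b)
    c1 = [p for p in set_a.peaks if not _is_shared(p, trees_b, min_overlap_bp)]
    c2a = [p for p in set_a.peaks if _is_shared(p, trees_b, min_overlap_bp)]
    c2b = [p for p in set_b.peaks if _is_shared(p, trees_a, min_overlap_bp)]
    c3 = [p for p in set_b.peaks if not _is_shared(p, trees_a, min_overlap_bp)]
    return ClusterPartition(set_a.label, set_b.label, c1, c2a, c2b, c3)


def overlap_fraction(
    set_a: PeakSet, set_b: PeakSet, min_overlap_bp: int = 50
) -> float:
    """Percentage of A's peaks overlapping at least one peak of B."""
    if len(set_a) == 0:
        raise DomainError("overlap fraction undefined for an empty peak set")
    trees_b = _overlap_trees(set_b)
    shared = sum(_is_shared(p, trees_b, min_overlap_bp) for p in set_a.peaks)
    return 100.0 * shared / len(set_a)


def width_stats(peak_set: PeakSet) -> dict[str, float]:
    """Count, total bp and five-number width summary of a peak set."""
    if len(peak_set) == 0:
        return {}
    widths = np.array([p.width for p in peak_set.peaks], dtype=float)
    q = np.percentile(widths, [0, 25, 50, 75, 100])
    return {
        "count": float(len(widths)),
        "total_bp": float(widths.sum()),
        "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
    }


def tss_distance_distribution(
    peak_set: PeakSet,
    genes: Sequence[GeneModel],
    bin_edges: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed, strand-aware peak-center-to-nearest-TSS distances.

    Positive means downstream of the TSS in the gene's reading direction.
    Returns (counts, distances).
    """
    if not genes:
        raise DomainError("gene set must be non-empty")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    dists = []
    for p in peak_set.peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            continue
        nearest = min(cands, key=lambda g: (abs(p.center - g.tss), g.gene_id))
        signed = p.center - nearest.tss
        if nearest.strand == "-":
            signed = -signed
        dists.append(signed)
    dists_arr = np.array(dists, dtype=float)
    counts, _ = np.histogram(dists_arr, bins=np.asarray(bin_edges, dtype=float))
    return counts, dists_arr


def assign_peaks_to_genes(
    peak_set: PeakSet,
    genes: Sequence[GeneModel],
    flank_bp: int = 2500,
) -> tuple[dict[str, list[Peak]], dict[Peak, str]]:
    """Overlap-based gene association plus nearest-gene peak annotation.

    A gene is associated with every peak overlapping its TSS-TES window
    extended by ``flank_bp``.  Independently, each peak is annotated with
    its nearest gene by center-to-TSS distance (ties break toward the
    lexicographically smaller gene id).
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        chrom, s, e = g.window(flank_bp)
        trees.setdefault(chrom, IntervalTree()).addi(s, e, g.gene_id)

    gene_to_peaks: dict[str, list[Peak]] = {}
    for p in peak_set.peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(p.start, p.end):
            gene_to_peaks.setdefault(iv.data, []).append(p)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    nearest_gene: dict[Peak, str] = {}
    for p in peak_set.peaks:
        cands = by_chrom.get(p.chrom)
        if cands:
            nearest = min(cands, key=lambda g: (abs(p.center - g.tss), g.gene_id))
            nearest_gene[p] = nearest.gene_id
    return gene_to_peaks, nearest_gene


def gene_signal_table(
    genes: Sequence[GeneModel],
    track_a: GenomicTrack,
    track_b: GenomicTrack,
    flank_bp: int = 2500,
    pseudocount: float | None = None,
    fold_threshold: float = 2.0,
    condition_a: str = "A",
    condition_b: str = "B",
) -> pd.DataFrame:
    """Per-gene mean normalized signal per condition, fold change, strong flag.

    Means are taken over TSS - flank .. TES + flank on the replicate-averaged
    normalized tracks.  The default pseudocount is 1 % of the genome-wide
    median bin value of condition A's track (floored at a tiny positive
    number so all-zero genes never divide by zero).
    """
    if pseudocount is None:
        all_bins = np.concatenate([v for v in track_a.values.values()])
        pseudocount = max(0.01 * float(np.median(all_bins)), 1e-12)
    rows = []
    for g in genes:
        chrom, s, e = g.window(flank_bp)
        e = min(e, track_a.chrom_lengths.get(chrom, e))
        mean_a = interval_mean(track_a, chrom, s, e)
        mean_b = interval_mean(track_b, chrom, s, e)
        fold = (mean_b + pseudocount) / (mean_a + pseudocount)
        rows.append(
            {
                "gene_id": g.gene_id,
                f"mean_{condition_a}": mean_a,
                f"mean_{condition_b}": mean_b,
                "fold_change": fold,
                "strong": fold >= fold_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def classify_strong_genes(
    signals: pd.DataFrame,
    fold_threshold: float = 2.0,
    pseudocount: float = 0.0,
    mean_a: str | None = None,
    mean_b: str | None = None,
) -> set[str]:
    """Genes whose (mean_B + pc) / (mean_A + pc) >= ``fold_threshold``.

    ``signals`` is a per-gene table with two condition-mean columns (by
    default the first two columns starting with ``mean_``).  Genes with a
    missing condition are excluded with a warning.
    """
    mean_cols = [c for c in signals.columns if c.startswith("mean_")]
    col_a = mean_a or mean_cols[0]
    col_b = mean_b or mean_cols[1]
    incomplete = signals.index[signals[[col_a, col_b]].isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"genes missing a condition excluded: {sorted(incomplete)}", stacklevel=2
        )
    ok = signals.dropna(subset=[col_a, col_b])
    fold = (ok[col_b] + pseudocount) / (ok[col_a] + pseudocount)
    return set(ok.index[fold >= fold_threshold])


def gene_set_venn(sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Exact inclusion-exclusion partition counts for 2 or 3 named gene sets."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise DomainError("venn partition requires 2 or 3 sets")
    universe = set().union(*sets.values())
    counts: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask >> i & 1]
        region = set(universe)
        for i, name in enumerate(names):
            if mask >> i & 1:
                region &= sets[name]
            else:
                region -= sets[name]
        counts["&".join(members) + "_only" if len(members) < len(names) else "&".join(members)] = len(region)
    return counts


def two_group_test(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-tailed t-test on per-gene signal values.

    Unpaired uses Welch's correction (unequal variances); paired uses the
    paired Student's t-test and requires equal lengths.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomainError("each group needs n >= 2")
    if paired:
        if len(x) != len(y):
            raise DomainError("paired test requires equal-length groups")
        res = stats.ttest_rel(x, y)
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
    stat = float(res.statistic)
    pval = float(res.pvalue)
    if paired and np.allclose(x, y):
        stat, pval = 0.0, 1.0  # identical pairs: zero shift, no evidence
    return stat, pval
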