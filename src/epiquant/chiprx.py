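"""Spike-in (Rx) normalization and binned-coverage arithmetic.

ChIP with an exogenous reference genome (ChIP-Rx) adds a fixed proportion of
spike-in chromatin (e.g. Drosophila) to every sample; the per-sample count of
reads mapping to the spike-in genome then calibrates a scaling factor that
makes coverage quantitatively comparable across samples regardless of
sequencing depth.  Tracks are binned (default 20 bp), normalized by the Rx
factor, replicate-averaged, and summarized as interval means or composite
anchor/metagene profiles.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np


class ChipRxError(ValueError):
    """Invalid input to the normalization/coverage stage."""


@dataclass
class GenomicTrack:
    """Binned coverage over a genome.

    ``values[chrom]`` has ``ceil(chrom_length / bin_size)`` entries; the last
    bin may cover fewer bases.  ``normalized`` flags whether an Rx factor has
    already been applied (double normalization is rejected).
    """

    genome: str
    bin_size: int
    chrom_lengths: dict[str, int]
    values: dict[str, np.ndarray]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ChipRxError("bin size must be >= 1")
        if set(self.values) != set(self.chrom_lengths):
            raise ChipRxError("value arrays and chromosome lengths disagree")
        for chrom, arr in self.values.items():
            expected = -(-self.chrom_lengths[chrom] // self.bin_size)
            if len(arr) != expected:
                raise ChipRxError(
                    f"{chrom}: expected {expected} bins, got {len(arr)}"
                )

    @classmethod
    def zeros(cls, genome: str, chrom_lengths: Mapping[str, int], bin_size: int = 20
              ) -> "GenomicTrack":
        values = {
            c: np.zeros(-(-length // bin_size)) for c, length in chrom_lengths.items()
        }
        return cls(genome, bin_size, dict(chrom_lengths), values)

    def copy(self) -> "GenomicTrack":
        return GenomicTrack(
            self.genome,
            self.bin_size,
            dict(self.chrom_lengths),
            {c: v.copy() for c, v in self.values.items()},
            self.normalized,
        )


@dataclass(frozen=True)
class RxFactor:
    """Per-sample spike-in scaling factor."""

    sample_id: str
    factor: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor <= 0:
            raise ChipRxError("Rx factor must be finite and > 0")


@dataclass
class ChipSample:
    """One sequenced ChIP sample with its filtered read counts and raw track."""

    sample_id: str
    condition: str
    replicate: int
    primary_count: int
    spikein_count: int
    track: GenomicTrack

    def __post_init__(self) -> None:
        if self.primary_count < 0 or self.spikein_count < 0:
            raise ChipRxError("read counts must be >= 0")


def rx_factor(
    spikein_count: int,
    scale_constant: float = 1e6,
    sample_id: str = "",
    primary_count: int | None = None,
    per_primary: bool = False,
) -> RxFactor:
    """Spike-in normalization factor: ``scale_constant / spikein_count``.

    With ``scale_constant=1e6`` this is the reads-per-spike-in-million
    convention.  ``per_primary=True`` selects the alternative convention that
    additionally divides by the primary-genome depth (in millions).
    """
    if spikein_count <= 0:
        raise ChipRxError("spike-in read count must be > 0")
    factor = scale_constant / spikein_count
    if per_primary:
        if primary_count is None or primary_count <= 0:
            raise ChipRxError("per-primary convention requires primary_count > 0")
        factor /= primary_count / 1e6
    return RxFactor(sample_id, factor)


def normalize_track(track: GenomicTrack, factor: RxFactor) -> GenomicTrack:
    """Scale every bin by the Rx factor; refuses already-normalized input."""
    if track.normalized:
        raise ChipRxError("track is already Rx-normalized")
    out = track.copy()
    for arr in out.values.values():
        arr *= factor.factor
    out.normalized = True
    return out


def average_replicates(tracks: Sequence[GenomicTrack]) -> GenomicTrack:
    """Element-wise arithmetic mean of replicate tracks."""
    if not tracks:
        raise ChipRxError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if (
            t.bin_size != first.bin_size
            or t.chrom_lengths != first.chrom_lengths
            or t.genome != first.genome
        ):
            raise ChipRxError("tracks differ in genome or binning")
    out = first.copy()
    for chrom in out.values:
        out.values[chrom] = np.mean([t.values[chrom] for t in tracks], axis=0)
    return out


def _check_interval(track: GenomicTrack, chrom: str, start: int, end: int) -> None:
    if chrom not in track.values:
        raise ChipRxError(f"unknown chromosome {chrom!r}")
    if start < 0 or end > track.chrom_lengths[chrom] or start >= end:
        raise ChipRxError(
            f"interval {chrom}:{start}-{end} off chromosome "
            f"(length {track.chrom_lengths[chrom]})"
        )


def interval_mean(track: GenomicTrack, chrom: str, start: int, end: int) -> float:
    """Base-weighted mean track value over one 0-based half-open interval.

    Partial bin overlaps are weighted by the number of overlapped bases, so
    the result equals the mean of the per-base expansion of the track.
    """
    _check_interval(track, chrom, start, end)
    b = track.bin_size
    arr = track.values[chrom]
    first, last = start // b, (end - 1) // b
    if first == last:
        return float(arr[first])
    weights = np.full(last - first + 1, b, dtype=float)
    weights[0] = (first + 1) * b - start
    weights[-1] = end - last * b
    return float(np.dot(arr[first : last + 1], weights) / (end - start))


def mean_signal(
    track: GenomicTrack, intervals: Sequence[tuple[str, int, int]]
) -> dict[tuple[str, int, int], float]:
    """Base-weighted mean per interval (the multiBigwigSummary-style summary)."""
    return {
        (c, s, e): interval_mean(track, c, s, e) for c, s, e in intervals
    }


def _window_means(
    track: GenomicTrack, chrom: str, start: int, end: int, n_cols: int
) -> np.ndarray:
    """Base-weighted means of ``n_cols`` equal sub-windows of [start, end)."""
    edges = np.linspace(start, end, n_cols + 1)
    out = np.empty(n_cols)
    b = track.bin_size
    arr = track.values[chrom]
    for j in range(n_cols):
        s, e = edges[j], edges[j + 1]
        first, last = int(s // b), int(np.ceil(e / b)) - 1
        acc = 0.0
        for k in range(first, last + 1):
            lo, hi = max(s, k * b), min(e, (k + 1) * b)
            if hi > lo:
                acc += arr[k] * (hi - lo)
        out[j] = acc / (e - s)
    return out


def anchor_profile(
    track: GenomicTrack,
    anchors: Sequence[tuple],
    flank_bp: int = 5000,
    body_bins: int | None = None,
    column_bp: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Profile matrix around anchors plus its composite (column means).

    Point mode (``body_bins=None``): anchors are ``(chrom, position)`` or
    ``(chrom, position, strand)``; columns are ``column_bp``-wide windows
    (default: the track bin size) spanning position ± ``flank_bp``, flipped
    for minus-strand anchors.

    Scaled mode: anchors are ``(chrom, start, end, strand)`` regions; the
    body is rescaled to ``body_bins`` columns flanked by native-resolution
    windows of ``flank_bp`` on each side (the TSS-to-TES metagene layout).

    Anchors whose window runs off a chromosome end produce an all-missing
    row that is excluded from the composite.
    """
    if flank_bp <= 0:
        raise ChipRxError("flank must be > 0")
    col = column_bp or track.bin_size
    rows = []
    for anchor in anchors:
        if body_bins is None:
            chrom, pos = anchor[0], int(anchor[1])
            strand = anchor[2] if len(anchor) > 2 else "+"
            start, end = pos - flank_bp, pos + flank_bp
            n_cols = 2 * flank_bp // col
            if start < 0 or end > track.chrom_lengths.get(chrom, -1):
                rows.append(np.full(n_cols, np.nan))
                continue
            row = _window_means(track, chrom, start, end, n_cols)
        else:
            chrom, gstart, gend, strand = (
                anchor[0], int(anchor[1]), int(anchor[2]), anchor[3],
            )
            n_flank = flank_bp // col
            n_cols = 2 * n_flank + body_bins
            if gstart - flank_bp < 0 or gend + flank_bp > track.chrom_lengths.get(chrom, -1):
                rows.append(np.full(n_cols, np.nan))
                continue
            left = _window_means(track, chrom, gstart - flank_bp, gstart, n_flank)
            body = _window_means(track, chrom, gstart, gend, body_bins)
            right = _window_means(track, chrom, gend, gend + flank_bp, n_flank)
            row = np.concatenate([left, body, right])
        if strand == "-":
            row = row[::-1]
        rows.append(row)
    matrix = np.vstack(rows) if rows else np.empty((0, 0))
    valid = matrix[~np.isnan(matrix).any(axis=1)] if matrix.size else matrix
    composite = valid.mean(axis=0) if valid.size else np.full(matrix.shape[1] if matrix.size else 0, np.nan)
    return matrix, composite
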