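"""Strand-specific end-count peak calling and summit (CTSS/QTTS) location.

The caller is a deliberately simple, reproducible seed-and-extend rule over
pooled per-base end counts:

1. *Seed*: a position is a seed when its pooled count is at least
   ``min_seed_count`` **and** the Poisson upper-tail probability of that
   count under the genome-wide mean count per base is at most
   ``background_alpha``.
2. *Extend*: a peak spans contiguous non-zero signal around its seeds,
   tolerating internal zero-gaps of at most ``max_internal_gap`` bases.
3. *Merge*: peaks closer than ``merge_gap`` (default 50 bp, edge to edge,
   inclusive) are merged transitively.
4. *Summit*: the position of the maximum pooled count within the peak
   (tie broken toward the smallest genomic coordinate) is the called site —
   a CTSS for 5'-end data, a QTTS for 3'-end data.

Summits and expression are always computed on counts pooled across all
samples and conditions, which maximizes detection power for the downstream
pairing steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .io import FIVE_PRIME, THREE_PRIME, GenomicInterval, StrandedEndTrack

SITE_KIND = {FIVE_PRIME: "CTSS", THREE_PRIME: "QTTS"}


@dataclass(frozen=True)
class PeakParams:
    """Tuning knobs of the seed-and-extend caller."""

    min_seed_count: int = 5
    max_internal_gap: int = 10
    merge_gap: int = 50
    background_alpha: float = 1e-3

    def __post_init__(self) -> None:
        if min(self.min_seed_count, self.max_internal_gap, self.merge_gap) < 0:
            raise ValueError("peak parameters must be >= 0")
        if not (0 < self.background_alpha <= 1):
            raise ValueError("background_alpha must be in (0, 1]")


@dataclass(frozen=True)
class SiteCall:
    """A called CTSS or QTTS: the local maximum of pooled end counts."""

    chrom: str
    position: int
    strand: str
    kind: str  # "CTSS" | "QTTS"
    pooled_count: int
    sample_counts: dict = field(default_factory=dict, compare=False)
    peak: "Peak | None" = field(default=None, compare=False, repr=False)

    @property
    def expression(self) -> int:
        """Pooled peak-level expression (total tags in the source peak)."""
        if self.peak is not None:
            return self.peak.pooled_total
        return self.pooled_count


@dataclass
class Peak:
    """A called peak with its pooled per-position counts and summit."""

    interval: GenomicInterval
    positions: np.ndarray  # sorted positions with non-zero pooled counts
    counts: np.ndarray     # pooled counts at `positions`
    sample_counts: dict = field(default_factory=dict)
    summit: SiteCall | None = None

    @property
    def pooled_total(self) -> int:
        return int(self.counts.sum())


def locate_summit(peak: Peak, kind: str = "CTSS",
                  tracks: list[StrandedEndTrack] | None = None) -> SiteCall:
    """Summit = argmax of pooled counts; ties go to the smallest coordinate."""
    if peak.positions.size == 0 or peak.counts.max() <= 0:
        raise ValueError("cannot locate a summit in an all-zero peak")
    i = int(np.argmax(peak.counts))  # first (leftmost) maximum
    position = int(peak.positions[i])
    sample_counts = {}
    if tracks:
        for t in tracks:
            sample_counts[t.sample_id] = t.count_at(
                peak.interval.chrom, peak.interval.strand, position
            )
    site = SiteCall(
        chrom=peak.interval.chrom,
        position=position,
        strand=peak.interval.strand,
        kind=kind,
        pooled_count=int(peak.counts[i]),
        sample_counts=sample_counts,
        peak=peak,
    )
    return site


def _cluster(positions: np.ndarray, counts: np.ndarray, max_internal_gap: int):
    """Split sorted non-zero positions into clusters of contiguous signal."""
    if positions.size == 0:
        return []
    gaps = np.diff(positions)
    breaks = np.flatnonzero(gaps > max_internal_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [positions.size]])
    return [(positions[a:b], counts[a:b]) for a, b in zip(starts, ends)]


def call_end_peaks(tracks: list[StrandedEndTrack], params: PeakParams,
                   chrom_sizes: dict[str, int] | None = None) -> list[Peak]:
    """Call peaks on counts pooled across samples, per chromosome and strand.

    ``chrom_sizes`` supplies the genome length for the Poisson background
    rate; when absent, the span up to the last observed position is used.
    Returns peaks sorted by (chrom, strand, start); peaks of one strand are
    disjoint.
    """
    if not tracks:
        raise ValueError("call_end_peaks requires at least one track")
    kinds = {t.signal_kind for t in tracks}
    if len(kinds) > 1:
        raise ValueError(f"mixed signal kinds: {sorted(kinds)}")
    kind = SITE_KIND[tracks[0].signal_kind]

    pooled = StrandedEndTrack.pooled(tracks)
    if chrom_sizes:
        genome_len = sum(chrom_sizes.values())
    else:
        genome_len = sum(
            int(pooled.arrays(c, s)[0][-1]) + 1
            for c, s in pooled.keys()
            if pooled.arrays(c, s)[0].size
        )
        genome_len = max(genome_len, 1)
    lam = pooled.library_size / max(genome_len, 1)
    # smallest integer count that is Poisson-significant at background_alpha
    min_sig = int(stats.poisson.isf(params.background_alpha, lam)) + 1
    seed_cutoff = max(params.min_seed_count, min_sig)

    peaks: list[Peak] = []
    for chrom, strand in pooled.keys():
        pos, cnt = pooled.arrays(chrom, strand)
        for cpos, ccnt in _cluster(pos, cnt, params.max_internal_gap):
            if ccnt.max() < seed_cutoff:
                continue
            interval = GenomicInterval(chrom, int(cpos[0]), int(cpos[-1]) + 1, strand)
            sample_counts = {
                t.sample_id: t.count_in(chrom, strand, interval.start, interval.end)
                for t in tracks
            }
            peak = Peak(interval, cpos.copy(), ccnt.copy(), sample_counts)
            peaks.append(peak)
    peaks = merge_peaks(peaks, params.merge_gap)
    for peak in peaks:
        peak.summit = locate_summit(peak, kind, tracks)
    return peaks


def merge_peaks(peaks: list[Peak], merge_gap: int = 50) -> list[Peak]:
    """Transitively merge same-strand peaks whose edge gap is <= merge_gap.

    The gap between consecutive peaks is ``next.start - prev.end``; a gap of
    exactly ``merge_gap`` merges. Counts are summed and summits recomputed
    by the caller. Input must be sorted by (chrom, strand, start).
    """
    order_keys = [
        (p.interval.chrom, p.interval.strand, p.interval.start) for p in peaks
    ]
    if order_keys != sorted(order_keys):
        raise ValueError("merge_peaks requires sorted input")
    merged: list[Peak] = []
    for peak in peaks:
        if merged:
            prev = merged[-1]
            same = (
                prev.interval.chrom == peak.interval.chrom
                and prev.interval.strand == peak.interval.strand
            )
            if same and peak.interval.start - prev.interval.end <= merge_gap:
                interval = GenomicInterval(
                    prev.interval.chrom,
                    prev.interval.start,
                    max(prev.interval.end, peak.interval.end),
                    prev.interval.strand,
                )
                positions = np.concatenate([prev.positions, peak.positions])
                counts = np.concatenate([prev.counts, peak.counts])
                order = np.argsort(positions, kind="stable")
                sample_counts = dict(prev.sample_counts)
                for sid, c in peak.sample_counts.items():
                    sample_counts[sid] = sample_counts.get(sid, 0) + c
                merged[-1] = Peak(
                    interval, positions[order], counts[order], sample_counts
                )
                continue
        merged.append(peak)
    # recompute summits where they were already present
    for i, peak in enumerate(merged):
        if peak.summit is not None:
            merged[i].summit = locate_summit(peak, peak.summit.kind)
    return merged


def summits(peaks: list[Peak]) -> list[SiteCall]:
    """Summit calls of a peak list, in peak order (missing ones computed)."""
    out = []
    for p in peaks:
        out.append(p.summit if p.summit is not None else locate_summit(p))
    return out
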