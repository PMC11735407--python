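"""Genomic data model and plain-text format I/O.

All internal coordinates are 0-based, half-open, BED-style.  GTF (1-based,
closed) is converted at the read/write boundary.  Strand-specific signal is
keyed by ``(chrom, strand)`` throughout; writers emit one file per strand
following the ``{sample}.{signal}.{strand}`` naming convention used by
strand-split pipelines.

Two signal containers are used:

* :class:`StrandedEndTrack` — sparse per-base counts of read *ends*
  (5'-end tags for CAGE-like data, 3'-end tags for QuantSeq-like data),
  stored as sorted position/count arrays per ``(chrom, strand)``.
* :class:`CoverageTrack` — run-length encoded per-base read coverage
  (RNA-seq body signal).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

STRANDS = ("+", "-")
FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"

_STRAND_SUFFIX = {"+": "plus", "-": "minus"}
_SUFFIX_STRAND = {v: k for k, v in _STRAND_SUFFIX.items()}


class BedGraphParseError(ValueError):
    """Raised on a malformed bedGraph line; carries the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _as_sorted_arrays(positions, counts):
    pos = np.asarray(positions, dtype=np.int64)
    cnt = np.asarray(counts, dtype=np.int64)
    if pos.size != cnt.size:
        raise ValueError("positions and counts differ in length")
    if np.any(cnt < 0):
        raise ValueError("negative counts")
    order = np.argsort(pos, kind="stable")
    pos, cnt = pos[order], cnt[order]
    # collapse duplicate positions
    if pos.size and np.any(np.diff(pos) == 0):
        uniq, inv = np.unique(pos, return_inverse=True)
        summed = np.zeros(uniq.size, dtype=np.int64)
        np.add.at(summed, inv, cnt)
        pos, cnt = uniq, summed
    keep = cnt > 0
    return pos[keep], cnt[keep]


class StrandedEndTrack:
    """Sparse per-base counts of read ends for one sample.

    Parameters
    ----------
    sample_id : str
    signal_kind : {"five_prime", "three_prime"}
    data : mapping (chrom, strand) -> (positions, counts)
        Positions need not be sorted or unique; duplicates are summed.
    """

    def __init__(self, sample_id: str, signal_kind: str, data=None):
        if signal_kind not in (FIVE_PRIME, THREE_PRIME):
            raise ValueError(f"unknown signal_kind {signal_kind!r}")
        self.sample_id = sample_id
        self.signal_kind = signal_kind
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for key, (pos, cnt) in data.items():
                self.add_counts(key[0], key[1], pos, cnt)
        self._cumsums: dict[tuple[str, str], np.ndarray] = {}

    def add_counts(self, chrom: str, strand: str, positions, counts) -> None:
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        pos, cnt = _as_sorted_arrays(positions, counts)
        key = (chrom, strand)
        if key in self._data:
            old_pos, old_cnt = self._data[key]
            pos, cnt = _as_sorted_arrays(
                np.concatenate([old_pos, pos]), np.concatenate([old_cnt, cnt])
            )
        self._data[key] = (pos, cnt)
        self._cumsums = {}

    def keys(self):
        return sorted(self._data.keys())

    def arrays(self, chrom: str, strand: str):
        """Sorted (positions, counts) arrays; empty arrays if absent."""
        empty = np.empty(0, dtype=np.int64)
        return self._data.get((chrom, strand), (empty, empty))

    @property
    def library_size(self) -> int:
        return int(sum(cnt.sum() for _, cnt in self._data.values()))

    def count_at(self, chrom: str, strand: str, position: int) -> int:
        pos, cnt = self.arrays(chrom, strand)
        i = np.searchsorted(pos, position)
        if i < pos.size and pos[i] == position:
            return int(cnt[i])
        return 0

    def count_in(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total end-tags with position in [start, end)."""
        pos, cnt = self.arrays(chrom, strand)
        key = (chrom, strand)
        if key not in self._cumsums:
            self._cumsums[key] = np.concatenate(
                [[0], np.cumsum(cnt, dtype=np.int64)]
            )
        cs = self._cumsums[key]
        i, j = np.searchsorted(pos, [start, end])
        return int(cs[j] - cs[i])

    @classmethod
    def pooled(cls, tracks: Iterable["StrandedEndTrack"]) -> "StrandedEndTrack":
        """Sum counts position-wise across samples (union of all data)."""
        tracks = list(tracks)
        if not tracks:
            raise ValueError("cannot pool an empty track set")
        kinds = {t.signal_kind for t in tracks}
        if len(kinds) > 1:
            raise ValueError(f"mixed signal kinds: {sorted(kinds)}")
        out = cls("pooled", tracks[0].signal_kind)
        for t in tracks:
            for chrom, strand in t.keys():
                pos, cnt = t.arrays(chrom, strand)
                out.add_counts(chrom, strand, pos, cnt)
        return out


class CoverageTrack:
    """Run-length encoded per-base coverage for one sample.

    Runs are stored per ``(chrom, strand)`` as parallel sorted arrays
    ``(starts, ends, values)``; runs are non-overlapping and positive.
    """

    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_runs(cls, sample_id: str, runs_by_key: Mapping) -> "CoverageTrack":
        """Build from possibly-overlapping (start, end, depth) runs.

        Overlapping runs are summed (sweep-line flattening).
        """
        track = cls(sample_id)
        for key, runs in runs_by_key.items():
            track.add_runs(key[0], key[1], runs)
        return track

    def add_runs(self, chrom: str, strand: str, runs) -> None:
        if strand not in STRANDS:
            raise ValueError(f"invalid strand {strand!r}")
        runs = [(int(s), int(e), int(v)) for s, e, v in runs if v != 0 and e > s]
        for s, e, v in runs:
            if v < 0:
                raise ValueError("negative coverage")
        key = (chrom, strand)
        if key in self._data:
            st, en, va = self._data[key]
            runs.extend(zip(st.tolist(), en.tolist(), va.tolist()))
        if not runs:
            self._data.pop(key, None)
            return
        starts = np.array([r[0] for r in runs], dtype=np.int64)
        ends = np.array([r[1] for r in runs], dtype=np.int64)
        vals = np.array([r[2] for r in runs], dtype=np.int64)
        # sweep-line: +v at start, -v at end
        bounds = np.concatenate([starts, ends])
        deltas = np.concatenate([vals, -vals])
        order = np.argsort(bounds, kind="stable")
        bounds, deltas = bounds[order], deltas[order]
        uniq, idx = np.unique(bounds, return_index=True)
        summed = np.add.reduceat(deltas, idx)
        depth = np.cumsum(summed)
        run_starts = uniq[:-1]
        run_ends = uniq[1:]
        run_vals = depth[:-1]
        keep = run_vals > 0
        self._data[key] = (run_starts[keep], run_ends[keep], run_vals[keep])

    def keys(self):
        return sorted(self._data.keys())

    def runs(self, chrom: str, strand: str):
        empty = np.empty(0, dtype=np.int64)
        return self._data.get((chrom, strand), (empty, empty, empty))

    def sum_in(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Integral of coverage over [start, end)."""
        st, en, va = self.runs(chrom, strand)
        if st.size == 0 or end <= start:
            return 0.0
        lo = np.clip(st, start, end)
        hi = np.clip(en, start, end)
        return float(np.sum((hi - lo) * va))

    def mean_in(self, chrom: str, strand: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.sum_in(chrom, strand, start, end) / (end - start)

    def per_base(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage vector over [start, end)."""
        out = np.zeros(end - start, dtype=np.float64)
        st, en, va = self.runs(chrom, strand)
        lo = np.clip(st, start, end) - start
        hi = np.clip(en, start, end) - start
        for a, b, v in zip(lo, hi, va):
            if b > a:
                out[a:b] += v
        return out

    @classmethod
    def pooled(cls, tracks: Iterable["CoverageTrack"]) -> "CoverageTrack":
        tracks = list(tracks)
        if not tracks:
            raise ValueError("cannot pool an empty track set")
        out = cls("pooled")
        for t in tracks:
            for chrom, strand in t.keys():
                st, en, va = t.runs(chrom, strand)
                out.add_runs(chrom, strand, zip(st.tolist(), en.tolist(), va.tolist()))
        return out


def per_base_signal(track, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
    """Dense per-base signal for either track type (shared metaprofile path)."""
    if isinstance(track, CoverageTrack):
        return track.per_base(chrom, strand, start, end)
    out = np.zeros(end - start, dtype=np.float64)
    pos, cnt = track.arrays(chrom, strand)
    i, j = np.searchsorted(pos, [start, end])
    out[pos[i:j] - start] = cnt[i:j]
    return out


# ---------------------------------------------------------------------------
# bedGraph


def _parse_bedgraph(path) -> Iterator[tuple[str, int, int, float]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) != 4:
                raise BedGraphParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise BedGraphParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise BedGraphParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if start < 0:
                raise BedGraphParseError(f"{path}:{lineno}: negative start")
            if value < 0:
                raise BedGraphParseError(f"{path}:{lineno}: negative value")
            yield chrom, start, end, value


def read_bedgraph_ends(path, strand: str, signal_kind: str,
                       sample_id: str | None = None) -> StrandedEndTrack:
    """Read a per-base end-count bedGraph into a :class:`StrandedEndTrack`.

    Runs wider than one base are expanded to per-base counts.
    """
    if sample_id is None:
        sample_id = os.path.basename(str(path)).split(".")[0]
    track = StrandedEndTrack(sample_id, signal_kind)
    pos_chunks: dict[str, list[np.ndarray]] = {}
    cnt_chunks: dict[str, list[np.ndarray]] = {}
    for chrom, start, end, value in _parse_bedgraph(path):
        count = int(round(value))
        positions = np.arange(start, end, dtype=np.int64)
        pos_chunks.setdefault(chrom, []).append(positions)
        cnt_chunks.setdefault(chrom, []).append(
            np.full(positions.size, count, dtype=np.int64)
        )
    for chrom in pos_chunks:
        track.add_counts(
            chrom, strand,
            np.concatenate(pos_chunks[chrom]),
            np.concatenate(cnt_chunks[chrom]),
        )
    return track


def read_bedgraph_coverage(path, strand: str,
                           sample_id: str | None = None) -> CoverageTrack:
    """Read a coverage bedGraph into a :class:`CoverageTrack`."""
    if sample_id is None:
        sample_id = os.path.basename(str(path)).split(".")[0]
    track = CoverageTrack(sample_id)
    runs: dict[str, list] = {}
    for chrom, start, end, value in _parse_bedgraph(path):
        runs.setdefault(chrom, []).append((start, end, int(round(value))))
    for chrom, chrom_runs in runs.items():
        track.add_runs(chrom, strand, chrom_runs)
    return track


def write_bedgraph_ends(track: StrandedEndTrack, strand: str, path) -> None:
    """Write one strand of an end track as canonical sorted bedGraph.

    Adjacent positions with equal counts are collapsed into runs, giving a
    byte-stable canonical form (read-write round trips are identities).
    """
    with open(path, "w") as fh:
        for chrom, s in track.keys():
            if s != strand:
                continue
            pos, cnt = track.arrays(chrom, strand)
            if pos.size == 0:
                continue
            breaks = np.flatnonzero(
                (np.diff(pos) != 1) | (np.diff(cnt) != 0)
            )
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [pos.size - 1]])
            for a, b in zip(starts, ends):
                fh.write(f"{chrom}\t{pos[a]}\t{pos[b] + 1}\t{cnt[a]}\n")


def write_bedgraph_coverage(track: CoverageTrack, strand: str, path) -> None:
    with open(path, "w") as fh:
        for chrom, s in track.keys():
            if s != strand:
                continue
            st, en, va = track.runs(chrom, strand)
            for a, b, v in zip(st, en, va):
                fh.write(f"{chrom}\t{a}\t{b}\t{v}\n")


# ---------------------------------------------------------------------------
# Transcript annotation (GTF / BED12)


@dataclass
class TranscriptRecord:
    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        """Annotated TSS: 5' end of the transcript (0-based position)."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class TranscriptAnnotation:
    """Transcript records plus a per-(chrom, strand) sorted TSS index.

    Gene-level deduplication is deliberately not applied: every distinct
    transcript 5' end is an annotated TSS.
    """

    def __init__(self, records: Iterable[TranscriptRecord]):
        self.records = list(records)
        index: dict[tuple[str, str], list[tuple[int, str]]] = {}
        for rec in self.records:
            key = (rec.interval.chrom, rec.interval.strand)
            index.setdefault(key, []).append((rec.tss, rec.gene_id))
        self._tss_pos: dict[tuple[str, str], np.ndarray] = {}
        self._tss_gene: dict[tuple[str, str], list[str]] = {}
        for key, entries in index.items():
            entries.sort()
            self._tss_pos[key] = np.array([p for p, _ in entries], dtype=np.int64)
            self._tss_gene[key] = [g for _, g in entries]

    def __len__(self) -> int:
        return len(self.records)

    def tss_in(self, chrom: str, strand: str, start: int, end: int):
        """Annotated TSS positions (and gene ids) falling in [start, end)."""
        pos = self._tss_pos.get((chrom, strand))
        if pos is None:
            return np.empty(0, dtype=np.int64), []
        i, j = np.searchsorted(pos, [start, end])
        genes = self._tss_gene[(chrom, strand)][i:j]
        return pos[i:j], genes

    def has_tss_in(self, chrom: str, strand: str, start: int, end: int) -> bool:
        pos, _ = self.tss_in(chrom, strand, start, end)
        return pos.size > 0


def read_annotation(path) -> TranscriptAnnotation:
    """Read a GTF (1-based closed) or BED12 (0-based half-open) annotation.

    The format is chosen by extension (.gtf/.gff vs .bed); both are unified
    into the internal 0-based half-open model.
    """
    path = str(path)
    if path.endswith((".gtf", ".gff", ".gff3")):
        return _read_gtf(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    raise ValueError(f"unknown annotation format: {path}")


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def _read_gtf(path) -> TranscriptAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "transcript":
                continue
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: missing/invalid strand")
            a = _parse_gtf_attrs(attrs)
            records.append(
                TranscriptRecord(
                    gene_id=a.get("gene_id", "NA"),
                    transcript_id=a.get("transcript_id", "NA"),
                    # GTF is 1-based closed -> 0-based half-open
                    interval=GenomicInterval(chrom, int(start) - 1, int(end), strand),
                    biotype=a.get("gene_biotype", a.get("biotype", "NA")),
                )
            )
    return TranscriptAnnotation(records)


def _read_bed12(path) -> TranscriptAnnotation:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED needs >= 6 columns")
            chrom, start, end, name, _, strand = fields[:6]
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: missing/invalid strand")
            records.append(
                TranscriptRecord(
                    gene_id=name,
                    transcript_id=name,
                    interval=GenomicInterval(chrom, int(start), int(end), strand),
                )
            )
    return TranscriptAnnotation(records)


def write_gtf(records: Iterable[TranscriptRecord], path,
              source: str = "cocoprom") -> None:
    """Write gene + transcript features (0-based model -> 1-based GTF)."""
    records = sorted(
        records, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.strand)
    )
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t.\tgene_id \"{rec.gene_id}\"; "
                    f"transcript_id \"{rec.transcript_id}\"; "
                    f"gene_biotype \"{rec.biotype}\";\n"
                )


def write_bed6(rows: Iterable[tuple], path) -> None:
    """Write (chrom, start, end, name, score, strand) rows sorted BED6."""
    rows = sorted(rows, key=lambda r: (r[0], int(r[1]), r[5], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
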