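"""Annotation of downstream antisense RNAs (daRNAs).

daRNAs are 5'-overlapping cis-natural antisense transcripts initiated from
the daTSS (TSS3) of a convergent promoter.  A daRNA is annotated only when
no gene-start annotation is available at the daTSS.  Its body is grown from
the daTSS in the direction of transcription over consecutive 100 bp windows
of antisense RNA-seq coverage, requiring a per-base mean coverage of at
least ten reads per window; elongation also terminates upon reaching an
annotated same-strand TSS that is supported by a CAGE peak.  3' ends are
then assigned from QuantSeq-derived QTTSs inside the body, one transcript
per QTTS, ranked by QTTS expression (da1, da2, ...); the rank-1 transcript
is the dominant daRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import CoverageTrack, GenomicInterval, TranscriptAnnotation
from .peaks import Peak, SiteCall


@dataclass(frozen=True)
class DarnaParams:
    window_len: int = 100        # sliding window length, bp
    coverage_threshold: float = 10.0  # required reads per window
    step: int | None = None      # None -> non-overlapping (= window_len)
    mode: str = "mean"           # "mean": per-base mean >= threshold
                                 # "sum":  raw window sum >= threshold

    def __post_init__(self) -> None:
        if self.window_len <= 0:
            raise ValueError("window_len must be positive")
        if self.coverage_threshold < 0:
            raise ValueError("coverage_threshold must be >= 0")
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if self.mode not in ("mean", "sum"):
            raise ValueError("mode must be 'mean' or 'sum'")

    @property
    def effective_step(self) -> int:
        return self.window_len if self.step is None else self.step


@dataclass
class DaRNA:
    """An annotated daRNA transcript."""

    da_tss: SiteCall
    body: GenomicInterval
    qtts: SiteCall | None
    length: int
    rank: int
    dominant: bool
    host_gene_id: str | None = None
    traverses_host_tss: bool | None = None

    @property
    def name(self) -> str:
        host = self.host_gene_id or "NA"
        return f"{host}-da{self.rank}"


def _window_passes(total: float, span: int, params: DarnaParams) -> bool:
    if span <= 0:
        return False
    if params.mode == "mean":
        return total / span >= params.coverage_threshold
    return total >= params.coverage_threshold


def _terminators(da_tss: SiteCall, annotation: TranscriptAnnotation,
                 cage_peaks: list[Peak]) -> list[int]:
    """Positions of annotated same-strand TSSs supported by a CAGE peak,
    excluding any inside the daTSS's own peak."""
    own = da_tss.peak.interval if da_tss.peak is not None else None
    out = []
    for peak in cage_peaks:
        iv = peak.interval
        if iv.chrom != da_tss.chrom or iv.strand != da_tss.strand:
            continue
        if own is not None and iv.overlaps(own):
            continue
        pos, _ = annotation.tss_in(iv.chrom, iv.strand, iv.start, iv.end)
        out.extend(int(p) for p in pos)
    return sorted(out)


def extend_body(da_tss: SiteCall, coverage: CoverageTrack,
                annotation: TranscriptAnnotation,
                cage_peaks: list[Peak] | None = None,
                params: DarnaParams | None = None,
                chrom_size: int | None = None) -> GenomicInterval | None:
    """Grow the daRNA body from the daTSS by the sliding-window rule.

    Returns the covered interval, or ``None`` when the daTSS coincides with
    an annotated gene start (not a daRNA) or the very first window fails.
    The termination check precedes the coverage check within each step, so
    an annotated, CAGE-supported TSS truncates even continuous coverage.
    """
    params = params or DarnaParams()
    cage_peaks = cage_peaks or []
    chrom, strand, t = da_tss.chrom, da_tss.strand, da_tss.position

    # precondition: no gene-start annotation at the daTSS itself
    if da_tss.peak is not None:
        iv = da_tss.peak.interval
        if annotation.has_tss_in(chrom, strand, iv.start, iv.end):
            return None
    elif annotation.has_tss_in(chrom, strand, t, t + 1):
        return None

    terms = _terminators(da_tss, annotation, cage_peaks)
    step = params.effective_step
    w = params.window_len

    if strand == "+":
        end = t  # exclusive body end, grows rightward
        k = 0
        while True:
            win_start = t + k * step
            win_end = win_start + w
            if chrom_size is not None:
                win_end = min(win_end, chrom_size)
            if win_end <= win_start:
                break
            hit = [p for p in terms if win_start <= p < win_end and p > t]
            if hit:
                end = max(end, min(hit))
                break
            total = coverage.sum_in(chrom, strand, win_start, win_end)
            if not _window_passes(total, win_end - win_start, params):
                break
            end = win_end
            k += 1
        if end <= t:
            return None
        return GenomicInterval(chrom, t, end, strand)

    # minus strand: body grows leftward; windows are taken upstream of the
    # daTSS so that the daTSS base itself is the (inclusive) body 5' end
    start = t + 1  # inclusive-left bound of body, grows leftward
    k = 0
    while True:
        win_end = t + 1 - k * step
        win_start = win_end - w
        win_start = max(win_start, 0)
        if win_end <= win_start:
            break
        hit = [p for p in terms if win_start <= p < win_end and p < t]
        if hit:
            # truncate just short of the terminating TSS (mirror of the
            # + strand case, where the exclusive end excludes it)
            start = min(start, max(hit) + 1)
            break
        total = coverage.sum_in(chrom, strand, win_start, win_end)
        if not _window_passes(total, win_end - win_start, params):
            break
        start = win_start
        k += 1
        if win_start == 0:
            break
    if start > t:
        return None
    return GenomicInterval(chrom, start, t + 1, strand)


def assign_transcripts(body: GenomicInterval, qtts_sites: list[SiteCall],
                       da_tss: SiteCall,
                       host_gene_id: str | None = None,
                       edge_tolerance: int = 0) -> list[DaRNA]:
    """One daRNA per QTTS inside the body, ranked by descending QTTS
    expression (ties broken toward the longer transcript).  Without any
    QTTS the single transcript ends at the body end (``qtts=None``).

    ``edge_tolerance`` admits QTTSs up to that many bases beyond the
    body's 3' edge: the window scan quantizes the body end to the window
    grid, which would otherwise drop a termination site sitting just past
    the last full window.  A transcript assigned from such a QTTS extends
    the body to that position.
    """

    def in_body(q: SiteCall) -> bool:
        if body.strand == "+":
            return body.start <= q.position < body.end + edge_tolerance
        return body.start - edge_tolerance <= q.position < body.end

    inside = [q for q in qtts_sites
              if q.chrom == body.chrom and q.strand == body.strand
              and in_body(q) and (
                  q.position > da_tss.position if body.strand == "+"
                  else q.position < da_tss.position
              )]

    def length_to(pos: int) -> int:
        if body.strand == "+":
            return pos - da_tss.position + 1
        return da_tss.position - pos + 1

    if not inside:
        length = len(body)
        return [DaRNA(da_tss=da_tss, body=body, qtts=None, length=length,
                      rank=1, dominant=True, host_gene_id=host_gene_id)]

    ranked = sorted(
        inside, key=lambda q: (-q.pooled_count, -length_to(q.position))
    )
    out = []
    for rank, q in enumerate(ranked, start=1):
        if body.strand == "+":
            tbody = GenomicInterval(body.chrom, body.start, q.position + 1, "+")
        else:
            tbody = GenomicInterval(body.chrom, q.position, body.end, "-")
        out.append(DaRNA(da_tss=da_tss, body=tbody, qtts=q,
                         length=length_to(q.position), rank=rank,
                         dominant=(rank == 1), host_gene_id=host_gene_id))
    return out


def select_dominant(darnas: list[DaRNA]) -> DaRNA:
    """The dominant daRNA of a locus: strongest QTTS, then longest."""
    if not darnas:
        raise ValueError("select_dominant needs at least one daRNA")
    return min(darnas, key=lambda d: d.rank)


def host_traversal(darna: DaRNA, host_tss: SiteCall) -> bool:
    """True iff the daRNA body extends across the host TSS position.

    The body's end coordinate is exclusive, so a body ending exactly at the
    host TSS does not traverse it.
    """
    if host_tss.strand == darna.body.strand:
        raise ValueError("host TSS and daRNA must be on opposite strands")
    return darna.body.contains(host_tss.position)


def annotate_locus(da_tss: SiteCall, host_tss: SiteCall,
                   coverage: CoverageTrack, qtts_sites: list[SiteCall],
                   annotation: TranscriptAnnotation,
                   cage_peaks: list[Peak] | None = None,
                   params: DarnaParams | None = None,
                   host_gene_id: str | None = None,
                   chrom_size: int | None = None) -> list[DaRNA]:
    """Annotate all daRNAs of one convergent promoter locus."""
    params = params or DarnaParams()
    body = extend_body(da_tss, coverage, annotation, cage_peaks, params,
                       chrom_size=chrom_size)
    if body is None:
        return []
    darnas = assign_transcripts(body, qtts_sites, da_tss, host_gene_id,
                                edge_tolerance=params.window_len)
    for d in darnas:
        d.traverses_host_tss = host_traversal(d, host_tss)
    return darnas
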