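"""Detection of convergent promoters from called CTSS summits.

Two procedures are implemented:

* **Core set** — divergent TSS pairs (a − strand CTSS followed by a
  + strand CTSS within 400 bp) are themselves paired when the inner,
  convergent TSSs of two consecutive divergent pairs lie within 2,500 bp
  of each other.  The resulting four-TSS constellation is labeled
  TSS1..TSS4, with the most strongly expressed TSS defined as TSS2 (the
  host TSS), its divergent partner as TSS1, the convergent counterpart as
  TSS3 (the daTSS) and TSS3's divergent partner as TSS4.  Constellations
  are kept only when an annotated TSS on TSS2's strand falls inside TSS2's
  CAGE peak.

* **Extended set** — + strand CTSSs are directly paired with a downstream
  − strand CTSS within 2,500 bp (a deliberately less conservative search);
  pairs are kept when at least one member's peak overlaps an annotated TSS
  on its own strand.  The overlapping (or, on ties, the more expressed)
  member is the host TSS, the other the daTSS.

All pairings are mutual-nearest and one-to-one on summit coordinates, so
no CTSS can be a member of two pairs; distances are summit-to-summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .io import GenomicInterval, TranscriptAnnotation
from .peaks import SiteCall

QUAD_LABELS = ("TSS1", "TSS2", "TSS3", "TSS4")


@dataclass(frozen=True)
class DetectionParams:
    divergent_window: int = 400   # max -TSS -> +TSS distance of a divergent pair
    convergent_window: int = 2500  # max convergent TSS-TSS distance
    min_gap: int = 1              # forbid degenerate zero-distance pairs

    def __post_init__(self) -> None:
        if self.divergent_window <= 0 or self.convergent_window <= 0:
            raise ValueError("windows must be positive")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")


@dataclass(frozen=True)
class DivergentPair:
    """A − strand TSS followed by a + strand TSS within the divergent window."""

    minus_tss: SiteCall
    plus_tss: SiteCall

    def __post_init__(self) -> None:
        if self.minus_tss.strand != "-" or self.plus_tss.strand != "+":
            raise ValueError("divergent pair needs (-, +) strands")
        if self.minus_tss.position > self.plus_tss.position:
            raise ValueError("divergent pair needs minus <= plus position")

    @property
    def distance(self) -> int:
        return self.plus_tss.position - self.minus_tss.position

    @property
    def chrom(self) -> str:
        return self.minus_tss.chrom


@dataclass
class ConvergentQuadruple:
    """A labeled four-TSS convergent promoter constellation."""

    tss: dict  # label -> SiteCall
    host_gene_id: str | None = None
    orientation: str | None = None  # "plus_host" | "minus_host"
    upstream_pair: DivergentPair | None = None
    downstream_pair: DivergentPair | None = None

    @property
    def distance_2_3(self) -> int:
        return abs(self.tss["TSS3"].position - self.tss["TSS2"].position)

    @property
    def chrom(self) -> str:
        return self.tss["TSS2"].chrom

    @property
    def span_2_3(self) -> GenomicInterval:
        """Genomic span between the two convergent summits (inclusive)."""
        a = self.tss["TSS2"].position
        b = self.tss["TSS3"].position
        return GenomicInterval(
            self.chrom, min(a, b), max(a, b) + 1, self.tss["TSS2"].strand
        )


@dataclass
class ConvergentPair:
    """Extended-set host TSS / daTSS pair."""

    host_tss: SiteCall
    da_tss: SiteCall
    host_gene_id: str | None = None

    @property
    def distance(self) -> int:
        return abs(self.da_tss.position - self.host_tss.position)

    @property
    def chrom(self) -> str:
        return self.host_tss.chrom


def _check_sorted(sites: list[SiteCall], name: str) -> None:
    keys = [(s.chrom, s.position) for s in sites]
    if keys != sorted(keys):
        raise ValueError(f"{name} must be sorted by (chrom, position)")


def _mutual_nearest(upstream: list[SiteCall], downstream: list[SiteCall],
                    max_dist: int, min_dist: int = 0):
    """Mutual-nearest one-to-one pairing: each upstream site with the nearest
    downstream site at distance in [min_dist, max_dist], kept when the choice
    is reciprocal. Returns list of (upstream_site, downstream_site)."""
    by_chrom_up: dict[str, list[SiteCall]] = {}
    by_chrom_dn: dict[str, list[SiteCall]] = {}
    for s in upstream:
        by_chrom_up.setdefault(s.chrom, []).append(s)
    for s in downstream:
        by_chrom_dn.setdefault(s.chrom, []).append(s)

    pairs = []
    for chrom, ups in by_chrom_up.items():
        dns = by_chrom_dn.get(chrom, [])
        if not dns:
            continue
        up_pos = np.array([s.position for s in ups], dtype=np.int64)
        dn_pos = np.array([s.position for s in dns], dtype=np.int64)
        # nearest eligible downstream partner of each upstream site
        lo = np.searchsorted(dn_pos, up_pos + min_dist, side="left")
        # nearest eligible upstream partner of each downstream site
        hi = np.searchsorted(up_pos, dn_pos - min_dist, side="right") - 1
        for i, j in enumerate(lo):
            if j >= dn_pos.size:
                continue
            if dn_pos[j] - up_pos[i] > max_dist:
                continue
            # reciprocal check: is i the nearest upstream of j?
            k = hi[j]
            if k == i:
                pairs.append((ups[i], dns[j]))
    return pairs


def pair_divergent(ctss_minus: list[SiteCall], ctss_plus: list[SiteCall],
                   params: DetectionParams | None = None) -> list[DivergentPair]:
    """Pair each − strand CTSS with a downstream + strand CTSS within the
    divergent window, mutual-nearest and one-to-one."""
    params = params or DetectionParams()
    _check_sorted(ctss_minus, "ctss_minus")
    _check_sorted(ctss_plus, "ctss_plus")
    for s in ctss_minus:
        if s.strand != "-":
            raise ValueError("ctss_minus contains a non-minus site")
    for s in ctss_plus:
        if s.strand != "+":
            raise ValueError("ctss_plus contains a non-plus site")
    raw = _mutual_nearest(ctss_minus, ctss_plus, params.divergent_window, 0)
    pairs = [DivergentPair(m, p) for m, p in raw]
    pairs.sort(key=lambda d: (d.chrom, d.minus_tss.position))
    return pairs


def assemble_quadruples(pairs: list[DivergentPair],
                        params: DetectionParams | None = None
                        ) -> list[ConvergentQuadruple]:
    """Join consecutive divergent pairs whose inner convergent TSSs
    (upstream pair's +TSS, downstream pair's −TSS) are within the
    convergent window. Returns unlabeled quadruples (tss dict empty)."""
    params = params or DetectionParams()
    keys = [(p.chrom, p.minus_tss.position) for p in pairs]
    if keys != sorted(keys):
        raise ValueError("assemble_quadruples requires pairs sorted by minus TSS")
    quads = []
    for a, b in zip(pairs, pairs[1:]):
        if a.chrom != b.chrom:
            continue
        gap = b.minus_tss.position - a.plus_tss.position
        if params.min_gap <= gap <= params.convergent_window:
            quads.append(
                ConvergentQuadruple(tss={}, upstream_pair=a, downstream_pair=b)
            )
    return quads


def label_and_filter(quad: ConvergentQuadruple,
                     annotation: TranscriptAnnotation
                     ) -> ConvergentQuadruple | None:
    """Label TSS1..TSS4 by expression and filter on annotated-TSS overlap.

    The most strongly expressed of the four TSSs becomes TSS2; it must be
    one of the two inner, convergent TSSs (otherwise the constellation has
    no convergent host and is rejected).  The quadruple is retained only
    when an annotated TSS on TSS2's strand falls within TSS2's peak
    interval; ``host_gene_id`` is taken from that annotation.
    """
    a, b = quad.upstream_pair, quad.downstream_pair
    if a is None or b is None:
        raise ValueError("quadruple lacks its source divergent pairs")
    sites = [a.minus_tss, a.plus_tss, b.minus_tss, b.plus_tss]
    expr = [s.expression for s in sites]
    top = max(expr)
    candidates = [s for s, e in zip(sites, expr) if e == top]
    if len(candidates) > 1:
        # tie: prefer an annotated TSS, else the leftmost coordinate
        annotated = [s for s in candidates if _peak_gene(s, annotation)]
        pool = annotated or candidates
        dominant = min(pool, key=lambda s: s.position)
    else:
        dominant = candidates[0]

    if dominant is a.plus_tss:
        labels = {"TSS1": a.minus_tss, "TSS2": a.plus_tss,
                  "TSS3": b.minus_tss, "TSS4": b.plus_tss}
        orientation = "plus_host"
    elif dominant is b.minus_tss:
        # mirrored by strand symmetry: the dominant inner - strand TSS hosts
        labels = {"TSS1": b.plus_tss, "TSS2": b.minus_tss,
                  "TSS3": a.plus_tss, "TSS4": a.minus_tss}
        orientation = "minus_host"
    else:
        return None  # dominant TSS is an outer one: no convergent host

    gene = _peak_gene(labels["TSS2"], annotation)
    if gene is None:
        return None
    quad.tss = labels
    quad.orientation = orientation
    quad.host_gene_id = gene
    return quad


def _peak_gene(site: SiteCall, annotation: TranscriptAnnotation) -> str | None:
    """Gene id of an annotated same-strand TSS inside the site's peak, or
    at the summit position when the site carries no peak."""
    if site.peak is not None:
        start, end = site.peak.interval.start, site.peak.interval.end
    else:
        start, end = site.position, site.position + 1
    pos, genes = annotation.tss_in(site.chrom, site.strand, start, end)
    if pos.size == 0:
        return None
    # closest annotated TSS to the summit
    i = int(np.argmin(np.abs(pos - site.position)))
    return genes[i]


def detect_core(ctss_minus: list[SiteCall], ctss_plus: list[SiteCall],
                annotation: TranscriptAnnotation,
                params: DetectionParams | None = None
                ) -> list[ConvergentQuadruple]:
    """Full core-set procedure: divergent pairing, quadruple assembly,
    expression labeling and annotation filtering."""
    params = params or DetectionParams()
    pairs = pair_divergent(ctss_minus, ctss_plus, params)
    quads = assemble_quadruples(pairs, params)
    labeled = []
    for q in quads:
        out = label_and_filter(q, annotation)
        if out is not None:
            labeled.append(out)
    return labeled


def detect_extended(ctss_plus: list[SiteCall], ctss_minus: list[SiteCall],
                    annotation: TranscriptAnnotation,
                    params: DetectionParams | None = None
                    ) -> list[ConvergentPair]:
    """Extended-set procedure: direct convergent pairing of a + strand CTSS
    with a downstream − strand CTSS within the convergent window."""
    params = params or DetectionParams()
    _check_sorted(ctss_plus, "ctss_plus")
    _check_sorted(ctss_minus, "ctss_minus")
    raw = _mutual_nearest(ctss_plus, ctss_minus,
                          params.convergent_window, params.min_gap)
    out = []
    for plus, minus in raw:
        gene_plus = _peak_gene(plus, annotation)
        gene_minus = _peak_gene(minus, annotation)
        if gene_plus is None and gene_minus is None:
            continue
        if gene_plus is not None and gene_minus is None:
            host, da, gene = plus, minus, gene_plus
        elif gene_minus is not None and gene_plus is None:
            host, da, gene = minus, plus, gene_minus
        else:  # both annotated: expression defines the orientation
            if plus.expression >= minus.expression:
                host, da, gene = plus, minus, gene_plus
            else:
                host, da, gene = minus, plus, gene_minus
        out.append(ConvergentPair(host_tss=host, da_tss=da, host_gene_id=gene))
    out.sort(key=lambda p: (p.chrom, min(p.host_tss.position, p.da_tss.position)))
    return out


def quadruple_distance(quad: ConvergentQuadruple) -> int:
    """Summit-to-summit distance between the convergent TSS2 and TSS3."""
    return quad.distance_2_3


def overlap_sets(set_a: Iterable, set_b: Iterable) -> dict:
    """Compare two convergent-promoter sets by genomic intersection of
    their TSS2–TSS3 (host–daTSS) spans on the same host strand.

    Accepts ConvergentQuadruple or ConvergentPair objects. Returns counts
    of shared and unique constellations per set.
    """

    def spans(items):
        out = []
        for it in items:
            if isinstance(it, ConvergentQuadruple):
                out.append(it.span_2_3)
            else:
                a, b = it.host_tss.position, it.da_tss.position
                out.append(GenomicInterval(
                    it.chrom, min(a, b), max(a, b) + 1, it.host_tss.strand))
        return out

    spans_a, spans_b = spans(list(set_a)), spans(list(set_b))
    shared_a = sum(
        any(sa.overlaps(sb) and sa.strand == sb.strand for sb in spans_b)
        for sa in spans_a
    )
    shared_b = sum(
        any(sb.overlaps(sa) and sa.strand == sb.strand for sa in spans_a)
        for sb in spans_b
    )
    return {
        "n_a": len(spans_a),
        "n_b": len(spans_b),
        "shared_a": int(shared_a),
        "shared_b": int(shared_b),
        "unique_a": len(spans_a) - int(shared_a),
        "unique_b": len(spans_b) - int(shared_b),
    }


def quadruples_to_frame(quads: list[ConvergentQuadruple]) -> pd.DataFrame:
    """Tabular export mirroring the per-constellation supplementary layout."""
    rows = []
    for q in quads:
        row = {"chrom": q.chrom, "host_gene_id": q.host_gene_id,
               "orientation": q.orientation, "distance_2_3": q.distance_2_3}
        for label in QUAD_LABELS:
            s = q.tss[label]
            row[f"{label.lower()}_pos"] = s.position
            row[f"{label.lower()}_strand"] = s.strand
            row[f"{label.lower()}_expression"] = s.expression
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["chrom", "tss2_pos"]).reset_index(drop=True)
    return df
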