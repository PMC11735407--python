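"""daRNA body extension, transcript assignment, dominance, traversal."""

import numpy as np
import pytest

from cocoprom.darna import (
    DaRNA,
    DarnaParams,
    assign_transcripts,
    extend_body,
    host_traversal,
    select_dominant,
)
from cocoprom.io import CoverageTrack, GenomicInterval, TranscriptAnnotation, TranscriptRecord

from conftest import make_site


def empty_annotation():
    return TranscriptAnnotation([])


def annotation_with_tss(pos, strand):
    if strand == "+":
        iv = GenomicInterval("chr1", pos, pos + 500, "+")
    else:
        iv = GenomicInterval("chr1", max(pos - 499, 0), pos + 1, "-")
    return TranscriptAnnotation([TranscriptRecord("g", "t", iv)])


def coverage_from_array(strand, values, offset=0):
    cov = CoverageTrack("s")
    runs = [(offset + i, offset + i + 1, int(v)) for i, v in enumerate(values) if v > 0]
    cov.add_runs("chr1", strand, runs)
    return cov


def oracle_extend_plus(tss, per_base, params):
    """Independent window scan over a dense array (+ strand); windows are
    clipped at the chromosome end."""
    end = tss
    k = 0
    while True:
        ws = tss + k * params.effective_step
        we = min(ws + params.window_len, len(per_base))
        window = per_base[ws:we]
        if window.size == 0:
            break
        ok = (
            window.mean() >= params.coverage_threshold
            if params.mode == "mean"
            else window.sum() >= params.coverage_threshold
        )
        if not ok:
            break
        end = we
        k += 1
    return None if end <= tss else (tss, end)


class TestExtendBody:
    def test_uniform_coverage_bounded_body_matches_oracle(self):
        """Coverage 15 over 1,000 bp downstream of the daTSS, then zero:
        the body spans exactly those 1,000 bp (both strands)."""
        params = DarnaParams()
        # + strand
        dense = np.zeros(5000)
        dense[1000:2000] = 15
        cov = coverage_from_array("+", dense)
        da = make_site(1000, "+", with_peak=False)
        body = extend_body(da, cov, empty_annotation(), params=params)
        assert (body.start, body.end) == oracle_extend_plus(1000, dense, params)
        assert len(body) == 1000
        # - strand mirror: coverage upstream of the daTSS
        dense_m = np.zeros(5000)
        dense_m[1000:2000] = 15
        cov_m = coverage_from_array("-", dense_m)
        da_m = make_site(1999, "-", with_peak=False)
        body_m = extend_body(da_m, cov_m, empty_annotation(), params=params)
        assert (body_m.start, body_m.end) == (1000, 2000)

    @pytest.mark.parametrize("trial", range(25))
    def test_random_coverage_matches_window_scan_oracle(self, trial):
        rng = np.random.default_rng(1200 + trial)
        params = DarnaParams(
            window_len=int(rng.integers(20, 150)),
            coverage_threshold=float(rng.integers(2, 15)),
        )
        dense = rng.integers(0, 25, size=4000).astype(float)
        tss = int(rng.integers(0, 1000))
        cov = coverage_from_array("+", dense)
        da = make_site(tss, "+", with_peak=False)
        body = extend_body(da, cov, empty_annotation(), params=params,
                           chrom_size=4000)
        expected = oracle_extend_plus(tss, dense, params)
        if expected is None:
            assert body is None
        else:
            assert (body.start, body.end) == expected

    def test_annotated_cage_supported_tss_truncates(self):
        """A same-strand annotated TSS inside a CAGE peak 600 bp downstream
        truncates an otherwise continuous body at 600 bp."""
        dense = np.full(5000, 15.0)
        cov = coverage_from_array("+", dense)
        da = make_site(1000, "+", with_peak=False)
        term_peak_site = make_site(1600, "+")  # CAGE peak around 1600
        body = extend_body(
            da, cov, annotation_with_tss(1600, "+"),
            cage_peaks=[term_peak_site.peak],
        )
        assert (body.start, body.end) == (1000, 1600)
        assert len(body) == 600

    def test_terminator_without_cage_peak_does_not_truncate(self):
        dense = np.zeros(5000)
        dense[1000:2000] = 15
        cov = coverage_from_array("+", dense)
        da = make_site(1000, "+", with_peak=False)
        body = extend_body(da, cov, annotation_with_tss(1600, "+"),
                           cage_peaks=[])
        assert len(body) == 1000

    def test_subthreshold_coverage_yields_no_body(self):
        dense = np.full(3000, 9.0)
        cov = coverage_from_array("+", dense)
        da = make_site(500, "+", with_peak=False)
        assert extend_body(da, cov, empty_annotation()) is None

    def test_annotated_gene_start_at_datss_means_not_a_darna(self):
        dense = np.full(3000, 15.0)
        cov = coverage_from_array("+", dense)
        da = make_site(500, "+", with_peak=False)
        assert extend_body(da, cov, annotation_with_tss(500, "+")) is None

    def test_raising_threshold_never_lengthens_body(self):
        rng = np.random.default_rng(77)
        dense = rng.integers(0, 30, size=3000).astype(float)
        cov = coverage_from_array("+", dense)
        da = make_site(100, "+", with_peak=False)
        lengths = []
        for thr in (2, 5, 10, 20):
            body = extend_body(da, cov, empty_annotation(),
                               params=DarnaParams(coverage_threshold=thr),
                               chrom_size=3000)
            lengths.append(0 if body is None else len(body))
        assert lengths == sorted(lengths, reverse=True)


class TestAssignTranscripts:
    def _body_minus(self):
        return GenomicInterval("chr1", 200, 1501, "-")

    def test_ranking_by_qtts_expression(self):
        body = GenomicInterval("chr1", 0, 1001, "+")
        da = make_site(0, "+", with_peak=False)
        q1 = make_site(800, "+", count=100, kind="QTTS", with_peak=False)
        q2 = make_site(400, "+", count=20, kind="QTTS", with_peak=False)
        out = assign_transcripts(body, [q2, q1], da)
        assert [d.rank for d in out] == [1, 2]
        assert out[0].qtts.position == 800 and out[0].length == 801
        assert out[1].qtts.position == 400
        assert out[0].dominant and not out[1].dominant

    def test_no_qtts_fallback_ends_at_body_end(self):
        body = self._body_minus()
        da = make_site(1500, "-", with_peak=False)
        out = assign_transcripts(body, [], da)
        assert len(out) == 1
        assert out[0].qtts is None
        assert out[0].rank == 1 and out[0].dominant
        assert out[0].length == len(body)

    def test_equal_counts_tie_breaks_to_longer_transcript(self):
        body = self._body_minus()
        da = make_site(1500, "-", with_peak=False)
        near = make_site(1000, "-", count=50, kind="QTTS", with_peak=False)
        far = make_site(300, "-", count=50, kind="QTTS", with_peak=False)
        out = assign_transcripts(body, [near, far], da)
        assert out[0].qtts.position == 300  # longer wins the tie
        assert out[0].length == 1201

    def test_qtts_outside_body_ignored(self):
        body = self._body_minus()
        da = make_site(1500, "-", with_peak=False)
        outside = make_site(100, "-", count=50, kind="QTTS", with_peak=False)
        out = assign_transcripts(body, [outside], da)
        assert out[0].qtts is None

    def test_ranking_is_a_permutation(self, rng):
        body = GenomicInterval("chr1", 0, 2001, "+")
        da = make_site(0, "+", with_peak=False)
        sites = [
            make_site(int(p), "+", count=int(c), kind="QTTS", with_peak=False)
            for p, c in zip(rng.choice(2000, 8, replace=False),
                            rng.integers(1, 100, 8))
        ]
        out = assign_transcripts(body, sites, da)
        assert sorted(d.rank for d in out) == list(range(1, 9))
        counts = [d.qtts.pooled_count for d in out]
        assert counts == sorted(counts, reverse=True)


class TestDominantSelection:
    def test_single_transcript_is_dominant(self):
        body = GenomicInterval("chr1", 0, 100, "+")
        da = make_site(0, "+", with_peak=False)
        out = assign_transcripts(body, [], da)
        assert select_dominant(out).dominant

    def test_strongest_qtts_wins(self):
        body = GenomicInterval("chr1", 0, 1001, "+")
        da = make_site(0, "+", with_peak=False)
        weak = make_site(900, "+", count=20, kind="QTTS", with_peak=False)
        strong = make_site(500, "+", count=100, kind="QTTS", with_peak=False)
        out = assign_transcripts(body, [weak, strong], da)
        assert select_dominant(out).qtts.position == 500

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            select_dominant([])

    @pytest.mark.parametrize("trial", range(20))
    def test_randomized_counts_match_argmax_oracle(self, trial):
        rng = np.random.default_rng(640 + trial)
        body = GenomicInterval("chr1", 0, 5001, "+")
        da = make_site(0, "+", with_peak=False)
        n = int(rng.integers(1, 8))
        positions = rng.choice(np.arange(1, 5000), size=n, replace=False)
        counts = rng.integers(1, 1000, size=n)
        sites = [make_site(int(p), "+", count=int(c), kind="QTTS", with_peak=False)
                 for p, c in zip(positions, counts)]
        out = assign_transcripts(body, sites, da)
        dom = select_dominant(out)
        assert dom.qtts.pooled_count == counts.max()


class TestHostTraversal:
    def _darna(self, start, end, strand="-"):
        body = GenomicInterval("chr1", start, end, strand)
        da_pos = end - 1 if strand == "-" else start
        da = make_site(da_pos, strand, with_peak=False)
        return DaRNA(da_tss=da, body=body, qtts=None, length=len(body),
                     rank=1, dominant=True)

    def test_minus_strand_body_past_host(self):
        darna = self._darna(400, 1500, "-")
        host = make_site(500, "+", with_peak=False)
        assert host_traversal(darna, host)

    def test_exclusive_end_boundary(self):
        host = make_site(500, "-", with_peak=False)
        assert host_traversal(self._darna(0, 600, "+"), host)
        assert host_traversal(self._darna(0, 501, "+"), host)
        assert not host_traversal(self._darna(0, 500, "+"), host)

    def test_same_strand_is_error(self):
        darna = self._darna(400, 1500, "-")
        with pytest.raises(ValueError):
            host_traversal(darna, make_site(500, "-", with_peak=False))

    @pytest.mark.parametrize("trial", range(20))
    def test_random_geometries_match_containment_oracle(self, trial):
        rng = np.random.default_rng(8800 + trial)
        start = int(rng.integers(0, 1000))
        end = start + int(rng.integers(1, 2000))
        host_pos = int(rng.integers(0, 3000))
        darna = self._darna(start, end, "-")
        host = make_site(host_pos, "+", with_peak=False)
        assert host_traversal(darna, host) == (start <= host_pos < end)
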