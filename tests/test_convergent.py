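"""Divergent pairing, quadruple assembly, labeling, and the extended set."""

import numpy as np
import pytest

from cocoprom.convergent import (
    ConvergentQuadruple,
    DetectionParams,
    DivergentPair,
    assemble_quadruples,
    detect_core,
    detect_extended,
    label_and_filter,
    overlap_sets,
    pair_divergent,
    quadruple_distance,
)
from cocoprom.io import GenomicInterval, TranscriptAnnotation, TranscriptRecord

from conftest import make_site


def annotation_at(entries):
    """Annotation with one transcript TSS per (position, strand) entry."""
    records = []
    for i, (pos, strand) in enumerate(entries):
        if strand == "+":
            iv = GenomicInterval("chr1", pos, pos + 1000, "+")
        else:
            iv = GenomicInterval("chr1", max(pos - 999, 0), pos + 1, "-")
        records.append(TranscriptRecord(f"g{i}", f"t{i}", iv))
    return TranscriptAnnotation(records)


def brute_force_mutual_nearest(minus_pos, plus_pos, window, min_gap=0):
    """Exhaustive enumeration over all ordered (-, +) position pairs."""
    pairs = []
    for m in minus_pos:
        eligible_p = [p for p in plus_pos if min_gap <= p - m <= window]
        if not eligible_p:
            continue
        p = min(eligible_p, key=lambda q: q - m)
        eligible_m = [mm for mm in minus_pos if min_gap <= p - mm <= window]
        if min(eligible_m, key=lambda mm: p - mm) == m:
            pairs.append((m, p))
    return sorted(pairs)


class TestPairDivergent:
    def test_distance_exactly_window_pairs(self):
        minus = [make_site(1000, "-")]
        plus = [make_site(1400, "+")]
        pairs = pair_divergent(minus, plus)
        assert len(pairs) == 1 and pairs[0].distance == 400

    def test_distance_past_window_does_not_pair(self):
        minus = [make_site(1000, "-")]
        plus = [make_site(1401, "+")]
        assert pair_divergent(minus, plus) == []

    def test_unsorted_input_is_error(self):
        minus = [make_site(500, "-"), make_site(100, "-")]
        with pytest.raises(ValueError):
            pair_divergent(minus, [make_site(600, "+")])

    def test_wrong_strand_rejected(self):
        with pytest.raises(ValueError):
            pair_divergent([make_site(100, "+")], [make_site(200, "+")])

    def test_no_site_appears_in_two_pairs(self):
        minus = [make_site(p, "-") for p in (100, 150, 200)]
        plus = [make_site(p, "+") for p in (210, 500)]
        pairs = pair_divergent(minus, plus)
        members = [(q.minus_tss.position, q.plus_tss.position) for q in pairs]
        flat = [x for pair in members for x in pair]
        assert len(flat) == len(set(flat))

    @pytest.mark.parametrize("trial", range(25))
    def test_random_sets_match_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(50 + trial)
        minus_pos = sorted(rng.choice(5000, size=20, replace=False).tolist())
        plus_pos = sorted(rng.choice(5000, size=20, replace=False).tolist())
        minus = [make_site(p, "-", with_peak=False) for p in minus_pos]
        plus = [make_site(p, "+", with_peak=False) for p in plus_pos]
        pairs = pair_divergent(minus, plus)
        got = sorted((q.minus_tss.position, q.plus_tss.position) for q in pairs)
        assert got == brute_force_mutual_nearest(minus_pos, plus_pos, 400)


class TestAssembleQuadruples:
    def _pairs(self, coords):
        out = []
        for m, p in coords:
            out.append(DivergentPair(make_site(m, "-"), make_site(p, "+")))
        return out

    def test_direct_rule(self):
        pairs = self._pairs([(900, 1000), (1500, 1600)])
        quads = assemble_quadruples(pairs)
        assert len(quads) == 1
        gap = (quads[0].downstream_pair.minus_tss.position
               - quads[0].upstream_pair.plus_tss.position)
        assert gap == 500

    def test_gap_past_window_boundary(self):
        pairs = self._pairs([(900, 1000), (3501, 3600)])  # gap 2501
        assert assemble_quadruples(pairs) == []
        pairs = self._pairs([(900, 1000), (3500, 3600)])  # gap 2500
        assert len(assemble_quadruples(pairs)) == 1

    def test_zero_gap_is_degenerate(self):
        pairs = self._pairs([(900, 1000), (1000, 1100)])
        assert assemble_quadruples(pairs) == []

    @pytest.mark.parametrize("trial", range(25))
    def test_random_pair_sets_match_enumeration(self, trial):
        """Oracle: enumerate all ordered pair-of-pairs, keep those whose
        inner gap satisfies the window and that are consecutive."""
        rng = np.random.default_rng(400 + trial)
        coords = []
        cursor = 0
        for _ in range(int(rng.integers(0, 12))):
            cursor += int(rng.integers(1, 4000))
            m = cursor
            p = m + int(rng.integers(0, 401))
            coords.append((m, p))
            cursor = p
        pairs = self._pairs(coords)
        quads = assemble_quadruples(pairs)
        got = [
            (q.upstream_pair.minus_tss.position,
             q.downstream_pair.minus_tss.position)
            for q in quads
        ]
        expected = []
        for i, a in enumerate(coords):
            for j, b in enumerate(coords):
                if j != i + 1:
                    continue  # only consecutive pairs can join
                gap = b[0] - a[1]
                if 1 <= gap <= 2500:
                    expected.append((a[0], b[0]))
        assert got == expected


class TestLabelAndFilter:
    def _quad(self, expressions, annotated):
        """Quadruple at fixed geometry with given per-TSS peak expressions.

        expressions: dict of {"Am","Ap","Bm","Bp"} -> pooled total.
        annotated: list of (position, strand) annotated TSSs.
        """
        a = DivergentPair(
            make_site(900, "-", peak_total=expressions["Am"]),
            make_site(1000, "+", peak_total=expressions["Ap"]),
        )
        b = DivergentPair(
            make_site(1500, "-", peak_total=expressions["Bm"]),
            make_site(1600, "+", peak_total=expressions["Bp"]),
        )
        quad = ConvergentQuadruple(tss={}, upstream_pair=a, downstream_pair=b)
        return quad, annotation_at(annotated)

    def test_plus_host_labels(self):
        quad, ann = self._quad(
            {"Am": 10, "Ap": 100, "Bm": 40, "Bp": 20}, [(1000, "+")]
        )
        out = label_and_filter(quad, ann)
        assert out is not None
        assert out.orientation == "plus_host"
        assert out.tss["TSS2"].position == 1000
        assert out.tss["TSS1"].position == 900
        assert out.tss["TSS3"].position == 1500
        assert out.tss["TSS4"].position == 1600
        assert out.host_gene_id == "g0"
        assert out.distance_2_3 == 500

    def test_minus_host_labels_are_mirrored(self):
        quad, ann = self._quad(
            {"Am": 10, "Ap": 40, "Bm": 100, "Bp": 20}, [(1500, "-")]
        )
        out = label_and_filter(quad, ann)
        assert out is not None
        assert out.orientation == "minus_host"
        assert out.tss["TSS2"].position == 1500
        assert out.tss["TSS1"].position == 1600
        assert out.tss["TSS3"].position == 1000
        assert out.tss["TSS4"].position == 900

    def test_unannotated_dominant_tss_rejected(self):
        quad, ann = self._quad(
            {"Am": 10, "Ap": 100, "Bm": 40, "Bp": 20}, [(5000, "+")]
        )
        assert label_and_filter(quad, ann) is None

    def test_dominant_outer_tss_rejected(self):
        quad, ann = self._quad(
            {"Am": 100, "Ap": 10, "Bm": 40, "Bp": 20}, [(900, "-")]
        )
        assert label_and_filter(quad, ann) is None

    def test_expression_tie_resolved_toward_annotated(self):
        quad, ann = self._quad(
            {"Am": 10, "Ap": 100, "Bm": 100, "Bp": 20}, [(1500, "-")]
        )
        out = label_and_filter(quad, ann)
        assert out is not None and out.tss["TSS2"].position == 1500

    def test_strand_flip_symmetry(self):
        """Mirroring the genome must mirror the labels: a plus-host
        constellation becomes a minus-host one with identical distances."""
        L = 10_000
        quad_fwd, ann_fwd = self._quad(
            {"Am": 10, "Ap": 100, "Bm": 40, "Bp": 20}, [(1000, "+")]
        )
        out_fwd = label_and_filter(quad_fwd, ann_fwd)
        # mirrored coordinates: x -> L - 1 - x, strands swapped
        a = DivergentPair(
            make_site(L - 1 - 1600, "-", peak_total=20),
            make_site(L - 1 - 1500, "+", peak_total=40),
        )
        b = DivergentPair(
            make_site(L - 1 - 1000, "-", peak_total=100),
            make_site(L - 1 - 900, "+", peak_total=10),
        )
        quad_rev = ConvergentQuadruple(tss={}, upstream_pair=a, downstream_pair=b)
        ann_rev = annotation_at([(L - 1 - 1000, "-")])
        out_rev = label_and_filter(quad_rev, ann_rev)
        assert out_rev is not None
        assert out_rev.orientation == "minus_host"
        assert out_rev.distance_2_3 == out_fwd.distance_2_3
        assert out_rev.tss["TSS2"].position == L - 1 - out_fwd.tss["TSS2"].position


class TestDetectExtended:
    def test_host_is_annotated_member(self):
        plus = [make_site(500, "+", peak_total=10)]
        minus = [make_site(900, "-", peak_total=50)]
        ann = annotation_at([(500, "+")])
        pairs = detect_extended(plus, minus, ann)
        assert len(pairs) == 1
        assert pairs[0].host_tss.position == 500
        assert pairs[0].da_tss.position == 900
        assert pairs[0].distance == 400

    def test_both_annotated_expression_breaks_tie(self):
        plus = [make_site(500, "+", peak_total=10)]
        minus = [make_site(900, "-", peak_total=50)]
        ann = annotation_at([(500, "+"), (900, "-")])
        pairs = detect_extended(plus, minus, ann)
        assert pairs[0].host_tss.position == 900

    def test_neither_annotated_drops_pair(self):
        plus = [make_site(500, "+", peak_total=10)]
        minus = [make_site(900, "-", peak_total=50)]
        assert detect_extended(plus, minus, annotation_at([])) == []

    @pytest.mark.parametrize("trial", range(25))
    def test_random_sets_match_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(990 + trial)
        plus_pos = sorted(rng.choice(20_000, size=15, replace=False).tolist())
        minus_pos = sorted(rng.choice(20_000, size=15, replace=False).tolist())
        plus = [make_site(p, "+", peak_total=int(rng.integers(1, 100)))
                for p in plus_pos]
        minus = [make_site(p, "-", peak_total=int(rng.integers(1, 100)))
                 for p in minus_pos]
        ann = annotation_at(
            [(p, "+") for p in plus_pos] + [(p, "-") for p in minus_pos]
        )
        got = sorted(
            (p.host_tss.position if p.host_tss.strand == "+" else p.da_tss.position,
             p.da_tss.position if p.host_tss.strand == "+" else p.host_tss.position)
            for p in detect_extended(plus, minus, ann)
        )
        expected = []
        for p in plus_pos:
            eligible_m = [m for m in minus_pos if 1 <= m - p <= 2500]
            if not eligible_m:
                continue
            m = min(eligible_m, key=lambda mm: mm - p)
            eligible_p = [pp for pp in plus_pos if 1 <= m - pp <= 2500]
            if min(eligible_p, key=lambda pp: m - pp) == p:
                expected.append((p, m))
        assert got == sorted(expected)


class TestSetOperations:
    def test_distance_is_summit_to_summit(self):
        quad, ann = (None, None)
        a = DivergentPair(make_site(900, "-", peak_total=1),
                          make_site(1000, "+", peak_total=100))
        b = DivergentPair(make_site(1413, "-", peak_total=40),
                          make_site(1500, "+", peak_total=10))
        q = ConvergentQuadruple(tss={}, upstream_pair=a, downstream_pair=b)
        out = label_and_filter(q, annotation_at([(1000, "+")]))
        assert quadruple_distance(out) == 413

    def test_identical_sets_fully_shared(self):
        a = DivergentPair(make_site(900, "-", peak_total=1),
                          make_site(1000, "+", peak_total=100))
        b = DivergentPair(make_site(1500, "-", peak_total=40),
                          make_site(1600, "+", peak_total=10))
        q = ConvergentQuadruple(tss={}, upstream_pair=a, downstream_pair=b)
        q = label_and_filter(q, annotation_at([(1000, "+")]))
        res = overlap_sets([q], [q])
        assert res["shared_a"] == res["shared_b"] == 1
        assert res["unique_a"] == res["unique_b"] == 0

    def test_disjoint_chromosomes_share_nothing(self):
        def quad_on(chrom):
            a = DivergentPair(
                make_site(900, "-", chrom=chrom, peak_total=1),
                make_site(1000, "+", chrom=chrom, peak_total=100),
            )
            b = DivergentPair(
                make_site(1500, "-", chrom=chrom, peak_total=40),
                make_site(1600, "+", chrom=chrom, peak_total=10),
            )
            q = ConvergentQuadruple(tss={}, upstream_pair=a, downstream_pair=b)
            q.tss = {"TSS1": a.minus_tss, "TSS2": a.plus_tss,
                     "TSS3": b.minus_tss, "TSS4": b.plus_tss}
            q.orientation = "plus_host"
            return q

        res = overlap_sets([quad_on("chr1")], [quad_on("chr2")])
        assert res["shared_a"] == res["shared_b"] == 0


class TestCoreExtendedConsistency:
    def test_core_projection_is_subset_of_extended(self):
        """Every core quadruple's (TSS2, TSS3) pair appears in the less
        conservative extended search on the same summits."""
        rng = np.random.default_rng(5)
        sites_minus, sites_plus, ann_entries = [], [], []
        cursor = 0
        for _ in range(30):
            cursor += 6000
            m1, p1 = cursor, cursor + int(rng.integers(80, 380))
            gap = int(rng.integers(2, 2301))
            m2 = p1 + gap
            p2 = m2 + int(rng.integers(80, 380))
            sites_minus += [make_site(m1, "-", peak_total=int(rng.integers(5, 50))),
                            make_site(m2, "-", peak_total=int(rng.integers(5, 50)))]
            sites_plus += [make_site(p1, "+", peak_total=int(rng.integers(100, 200))),
                           make_site(p2, "+", peak_total=int(rng.integers(5, 50)))]
            ann_entries.append((p1, "+"))
            cursor = p2
        ann = annotation_at(ann_entries)
        key = lambda s: (s.chrom, s.position)
        sites_minus.sort(key=key)
        sites_plus.sort(key=key)
        core = detect_core(sites_minus, sites_plus, ann)
        extended = detect_extended(sites_plus, sites_minus, ann)
        core_pairs = {
            (q.tss["TSS2"].position, q.tss["TSS3"].position) for q in core
        }
        ext_pairs = {
            (p.host_tss.position, p.da_tss.position) for p in extended
        }
        assert core_pairs and core_pairs <= ext_pairs
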