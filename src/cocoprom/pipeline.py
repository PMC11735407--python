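"""End-to-end orchestration of the analysis stages.

The in-memory entry point :func:`run_end_to_end` drives peak calling,
core/extended convergent-promoter detection, daRNA annotation,
quantification and the co-regulation correlation on simulated (or loaded)
samples; :func:`evaluate_against_truth` scores a detected set against the
planted ground truth.  The file-based :func:`run_pipeline` behind the CLI
reads tracks and annotation from disk, executes the same stages and writes
tables plus a JSON manifest with a parameter hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .convergent import (
    ConvergentPair,
    ConvergentQuadruple,
    DetectionParams,
    detect_core,
    detect_extended,
    quadruples_to_frame,
)
from .darna import DaRNA, DarnaParams, annotate_locus
from .io import (
    FIVE_PRIME,
    THREE_PRIME,
    CoverageTrack,
    GenomicInterval,
    StrandedEndTrack,
    TranscriptAnnotation,
    write_tsv,
)
from .peaks import Peak, PeakParams, call_end_peaks
from .quantify import SampleInfo, build_count_matrix, log2fc
from .stats import spearman


@dataclass
class PipelineResult:
    ctss_peaks: list
    qtts_peaks: list
    quadruples: list
    extended_pairs: list
    darnas: dict            # host_gene_id -> list[DaRNA]
    diff: pd.DataFrame      # per-peak base_mean/log2fc (5'-end features)
    quad_effects: pd.DataFrame  # per-quadruple TSS2/TSS3 log2FCs
    correlation: tuple      # (rho, p) of TSS2 vs TSS3 log2FC


def split_summits(peaks: list[Peak]):
    """Summits split by strand, sorted by (chrom, position)."""
    minus = [p.summit for p in peaks if p.interval.strand == "-"]
    plus = [p.summit for p in peaks if p.interval.strand == "+"]
    key = lambda s: (s.chrom, s.position)
    return sorted(minus, key=key), sorted(plus, key=key)


def _peak_feature_id(peak: Peak) -> str:
    iv = peak.interval
    return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def quantify_peaks(peaks: list[Peak], tracks: list[StrandedEndTrack],
                   sample_info: list[SampleInfo],
                   treated: str = "treated", control: str = "control",
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Count 5'-end tags per peak and sample, normalize, compute log2FC."""
    features = [p.interval for p in peaks]
    ids = [_peak_feature_id(p) for p in peaks]
    cm = build_count_matrix(tracks, sample_info, ids, features)
    return log2fc(cm, treated, control, pseudocount)


def run_end_to_end(samples, annotation: TranscriptAnnotation,
                   chrom_sizes: dict,
                   peak_params: PeakParams | None = None,
                   detection_params: DetectionParams | None = None,
                   darna_params: DarnaParams | None = None,
                   with_darnas: bool = True,
                   with_extended: bool = True) -> PipelineResult:
    """Run every analysis stage on a list of :class:`SimulatedSample`-like
    objects (anything with five_prime/three_prime/coverage attributes and
    sample_id/condition metadata)."""
    peak_params = peak_params or PeakParams()
    detection_params = detection_params or DetectionParams()
    darna_params = darna_params or DarnaParams()

    tracks5 = [s.five_prime for s in samples]
    tracks3 = [s.three_prime for s in samples]
    info = [SampleInfo(s.sample_id, s.condition, s.replicate) for s in samples]

    ctss_peaks = call_end_peaks(tracks5, peak_params, chrom_sizes)
    qtts_peaks = call_end_peaks(tracks3, peak_params, chrom_sizes)
    minus, plus = split_summits(ctss_peaks)

    quadruples = detect_core(minus, plus, annotation, detection_params)
    extended = (
        detect_extended(plus, minus, annotation, detection_params)
        if with_extended else []
    )

    darnas: dict[str, list[DaRNA]] = {}
    if with_darnas:
        pooled_cov = CoverageTrack.pooled([s.coverage for s in samples])
        qtts_minus, qtts_plus = split_summits(qtts_peaks)
        qtts_by_strand = {"-": qtts_minus, "+": qtts_plus}
        for quad in quadruples:
            da = quad.tss["TSS3"]
            host = quad.tss["TSS2"]
            found = annotate_locus(
                da, host, pooled_cov, qtts_by_strand[da.strand], annotation,
                cage_peaks=ctss_peaks, params=darna_params,
                host_gene_id=quad.host_gene_id,
                chrom_size=chrom_sizes.get(da.chrom),
            )
            if found:
                darnas[quad.host_gene_id] = found

    diff = quantify_peaks(ctss_peaks, tracks5, info)
    lfc_by_feature = dict(zip(diff["feature_id"], diff["log2fc"]))
    base_by_feature = dict(zip(diff["feature_id"], diff["base_mean"]))

    rows = []
    for quad in quadruples:
        f2 = _peak_feature_id(quad.tss["TSS2"].peak)
        f3 = _peak_feature_id(quad.tss["TSS3"].peak)
        rows.append({
            "host_gene_id": quad.host_gene_id,
            "distance_2_3": quad.distance_2_3,
            "tss2_log2fc": lfc_by_feature[f2],
            "tss3_log2fc": lfc_by_feature[f3],
            "tss2_base_mean": base_by_feature[f2],
            "tss3_base_mean": base_by_feature[f3],
            "tss1_log2fc": lfc_by_feature[
                _peak_feature_id(quad.tss["TSS1"].peak)],
            "tss4_log2fc": lfc_by_feature[
                _peak_feature_id(quad.tss["TSS4"].peak)],
        })
    quad_effects = pd.DataFrame(rows)

    if len(quad_effects) >= 3:
        correlation = spearman(quad_effects["tss2_log2fc"],
                               quad_effects["tss3_log2fc"])
    else:
        correlation = (float("nan"), float("nan"))

    return PipelineResult(
        ctss_peaks=ctss_peaks,
        qtts_peaks=qtts_peaks,
        quadruples=quadruples,
        extended_pairs=extended,
        darnas=darnas,
        diff=diff,
        quad_effects=quad_effects,
        correlation=correlation,
    )


# ---------------------------------------------------------------------------
# truth evaluation


@dataclass
class DetectionScore:
    n_true: int
    n_detected: int
    n_matched: int
    n_label_correct: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return (
            self.n_matched / self.n_detected if self.n_detected else float("nan")
        )

    @property
    def label_accuracy(self) -> float:
        return (
            self.n_label_correct / self.n_matched
            if self.n_matched else float("nan")
        )


def evaluate_against_truth(quadruples: list[ConvergentQuadruple], truth,
                           tolerance: int = 20) -> DetectionScore:
    """Match detected quadruples to planted ones by their convergent
    TSS pair (both summits within ``tolerance`` bp of a planted TSS2/TSS3,
    as an unordered pair); a match is label-correct when the detected TSS2
    lies at the planted TSS2."""
    planted = {}
    for locus in truth.quadruples:
        _, t2, _ = locus.tss("TSS2")
        _, t3, _ = locus.tss("TSS3")
        planted[locus.host_gene_id] = (locus.chrom, t2, t3)

    matched_ids = set()
    n_matched = 0
    n_label_correct = 0
    for quad in quadruples:
        d2 = quad.tss["TSS2"].position
        d3 = quad.tss["TSS3"].position
        hit = None
        label_ok = False
        for gid, (chrom, t2, t3) in planted.items():
            if gid in matched_ids or chrom != quad.chrom:
                continue
            direct = abs(d2 - t2) <= tolerance and abs(d3 - t3) <= tolerance
            swapped = abs(d2 - t3) <= tolerance and abs(d3 - t2) <= tolerance
            if direct or swapped:
                hit = gid
                label_ok = direct
                break
        if hit is not None:
            matched_ids.add(hit)
            n_matched += 1
            n_label_correct += bool(label_ok)
    return DetectionScore(
        n_true=len(planted),
        n_detected=len(quadruples),
        n_matched=n_matched,
        n_label_correct=n_label_correct,
    )


# ---------------------------------------------------------------------------
# file-based pipeline (CLI backend)


def _params_hash(*param_objs) -> str:
    payload = json.dumps(
        [dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
         for p in param_objs],
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LoadedSample:
    sample_id: str
    condition: str
    replicate: int
    five_prime: StrandedEndTrack
    three_prime: StrandedEndTrack
    coverage: CoverageTrack | None


def load_samples(sample_sheet: pd.DataFrame, base_dir: str) -> list[LoadedSample]:
    """Load per-sample strand-split bedGraph tracks from a sample sheet.

    Expected columns: sample_id, condition, replicate, five_prime_plus,
    five_prime_minus, three_prime_plus, three_prime_minus, and optionally
    coverage_plus / coverage_minus.  Paths are relative to ``base_dir``.
    """
    from .io import read_bedgraph_coverage, read_bedgraph_ends

    required = {"sample_id", "condition", "replicate",
                "five_prime_plus", "five_prime_minus",
                "three_prime_plus", "three_prime_minus"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")

    def _resolve(p):
        p = str(p)
        return p if os.path.isabs(p) else os.path.join(base_dir, p)

    samples = []
    for _, row in sample_sheet.iterrows():
        sid = str(row["sample_id"])
        t5 = StrandedEndTrack(sid, FIVE_PRIME)
        t3 = StrandedEndTrack(sid, THREE_PRIME)
        for strand, col5, col3 in (("+", "five_prime_plus", "three_prime_plus"),
                                   ("-", "five_prime_minus", "three_prime_minus")):
            part5 = read_bedgraph_ends(_resolve(row[col5]), strand, FIVE_PRIME, sid)
            for key in part5.keys():
                t5.add_counts(*key, *part5.arrays(*key))
            part3 = read_bedgraph_ends(_resolve(row[col3]), strand, THREE_PRIME, sid)
            for key in part3.keys():
                t3.add_counts(*key, *part3.arrays(*key))
        cov = None
        if "coverage_plus" in sample_sheet.columns:
            cov = CoverageTrack(sid)
            for strand, col in (("+", "coverage_plus"), ("-", "coverage_minus")):
                part = read_bedgraph_coverage(_resolve(row[col]), strand, sid)
                for key in part.keys():
                    st, en, va = part.runs(*key)
                    cov.add_runs(*key, zip(st.tolist(), en.tolist(), va.tolist()))
        samples.append(LoadedSample(
            sid, str(row["condition"]), int(row["replicate"]), t5, t3, cov))
    return samples


def run_pipeline(annotation_path: str, sample_sheet_path: str, outdir: str,
                 chrom_sizes: dict | None = None,
                 peak_params: PeakParams | None = None,
                 detection_params: DetectionParams | None = None,
                 darna_params: DarnaParams | None = None) -> dict:
    """File-based pipeline: load inputs, run all stages, write tables and
    a JSON manifest.  Returns the manifest dict."""
    from .io import read_annotation, read_tsv

    for path in (annotation_path, sample_sheet_path):
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing input: {path}")
    peak_params = peak_params or PeakParams()
    detection_params = detection_params or DetectionParams()
    darna_params = darna_params or DarnaParams()

    annotation = read_annotation(annotation_path)
    sheet = read_tsv(sample_sheet_path)
    samples = load_samples(sheet, os.path.dirname(os.path.abspath(sample_sheet_path)))
    for s in samples:
        if s.coverage is None:
            s.coverage = CoverageTrack(s.sample_id)
    if chrom_sizes is None:
        chrom_sizes = {}
        for s in samples:
            for chrom, _ in s.five_prime.keys():
                pos, _ = s.five_prime.arrays(chrom, "+")
                neg, _ = s.five_prime.arrays(chrom, "-")
                last = max(
                    [int(pos[-1]) + 1 if pos.size else 0,
                     int(neg[-1]) + 1 if neg.size else 0,
                     chrom_sizes.get(chrom, 0)]
                )
                chrom_sizes[chrom] = last

    result = run_end_to_end(samples, annotation, chrom_sizes,
                            peak_params, detection_params, darna_params)

    os.makedirs(outdir, exist_ok=True)
    quad_path = os.path.join(outdir, "core_quadruples.tsv")
    write_tsv(quadruples_to_frame(result.quadruples), quad_path)
    eff_path = os.path.join(outdir, "quadruple_log2fc.tsv")
    write_tsv(result.quad_effects, eff_path)
    diff_path = os.path.join(outdir, "peak_log2fc.tsv")
    write_tsv(result.diff, diff_path)
    ext_rows = [{
        "chrom": p.chrom,
        "host_pos": p.host_tss.position,
        "host_strand": p.host_tss.strand,
        "da_pos": p.da_tss.position,
        "da_strand": p.da_tss.strand,
        "distance": p.distance,
        "host_gene_id": p.host_gene_id,
    } for p in result.extended_pairs]
    ext_path = os.path.join(outdir, "extended_pairs.tsv")
    write_tsv(pd.DataFrame(
        ext_rows, columns=["chrom", "host_pos", "host_strand", "da_pos",
                           "da_strand", "distance", "host_gene_id"]), ext_path)
    da_rows = [{
        "host_gene_id": d.host_gene_id,
        "name": d.name,
        "chrom": d.body.chrom,
        "body_start": d.body.start,
        "body_end": d.body.end,
        "strand": d.body.strand,
        "length": d.length,
        "rank": d.rank,
        "dominant": d.dominant,
        "traverses_host_tss": d.traverses_host_tss,
    } for ds in result.darnas.values() for d in ds]
    da_path = os.path.join(outdir, "darnas.tsv")
    write_tsv(pd.DataFrame(
        da_rows, columns=["host_gene_id", "name", "chrom", "body_start",
                          "body_end", "strand", "length", "rank", "dominant",
                          "traverses_host_tss"]), da_path)

    rho, p = result.correlation
    # manifest references tables by basename so reruns into different
    # directories stay byte-identical
    quad_path, eff_path, diff_path, ext_path, da_path = (
        os.path.basename(p)
        for p in (quad_path, eff_path, diff_path, ext_path, da_path)
    )
    manifest = {
        "version": __version__,
        "params_hash": _params_hash(peak_params, detection_params, darna_params),
        "stages": {
            "call_tss": {"n_ctss_peaks": len(result.ctss_peaks),
                         "n_qtts_peaks": len(result.qtts_peaks)},
            "detect_core": {"n_quadruples": len(result.quadruples),
                            "table": quad_path},
            "detect_extended": {"n_pairs": len(result.extended_pairs),
                                "table": ext_path},
            "annotate_darna": {"n_hosts": len(result.darnas), "table": da_path},
            "quantify": {"n_features": int(len(result.diff)), "table": diff_path},
            "correlate": {"rho": None if np.isnan(rho) else rho,
                          "p_two_sided": None if np.isnan(p) else p,
                          "table": eff_path},
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
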