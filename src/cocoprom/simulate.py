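"""Synthetic promoter architectures and the signal tracks they produce.

The generator plants three locus architectures on a toy genome:

* ``quadruple`` — the four-TSS convergent-promoter constellation
  TSS1(−) < TSS2(+) < TSS3(−) < TSS4(+): a host gene (TSS2) with its
  upstream antisense partner (TSS1), and a downstream antisense promoter
  (TSS3) with its own divergent partner (TSS4).  TSS2 carries the highest
  baseline expression (the host TSS); the TSS2–TSS3 gap is drawn uniformly
  from ``gap_range`` (default 2–2,301 bp, the empirically observed span of
  convergent TSS distances).
* ``divergent_only`` — a plain bidirectional promoter (−TSS then +TSS),
  no convergent partner.
* ``isolated`` — a single + strand TSS.

Per sample, 5'-end tags at each TSS are negative-binomial
(variance = mu + dispersion * mu^2) with the mean scaled by 2**log2FC in
treated samples; tag positions get a geometric(0.5) jitter (magnitude
capped at 10 bp) so each TSS shows a realistic peak with a unique modal
base.  Treatment log2FCs of TSS2 and TSS3 are drawn from a bivariate
normal with correlation ``effect_rho``; TSS1 and TSS4 copy the effect of
their divergent partners (divergent co-regulation is the accepted
baseline).  RNA-seq coverage spans the host body (TSS2 -> host 3' end, +
strand) and the daRNA body (TSS3 -> planted daRNA 3' end, − strand);
upstream antisense transcripts get no body coverage, reflecting their
rapid turnover.  3'-end tags pile up at the planted termination sites;
each daRNA carries one primary QTTS at the full body end plus optional
weaker internal QTTSs.  Uniform background tags are Poisson per base.

All randomness flows from ``SimConfig.seed`` through a single generator,
so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    FIVE_PRIME,
    THREE_PRIME,
    CoverageTrack,
    GenomicInterval,
    StrandedEndTrack,
    TranscriptAnnotation,
    TranscriptRecord,
    write_bed6,
    write_bedgraph_coverage,
    write_bedgraph_ends,
    write_gtf,
    write_tsv,
)

ARCHITECTURES = ("quadruple", "divergent_only", "isolated")
_STRAND_NAME = {"+": "plus", "-": "minus"}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome."""

    chrom_sizes: dict | None = None  # None -> one auto-sized chromosome
    n_quadruples: int = 200
    n_divergent_only: int = 200
    n_isolated: int = 200
    gap_range: tuple = (2, 2301)          # TSS2-TSS3 distance, bp
    divergent_range: tuple = (80, 380)    # TSS1-TSS2 / TSS3-TSS4 distance, bp
    baseline_mean_range: tuple = (50.0, 300.0)  # tags/TSS/replicate (host TSS)
    expression_margin: float = 2.0        # host TSS >= margin x other TSSs
    dispersion: float = 0.05              # NB: var = mu + dispersion * mu^2
    effect_rho: float = 0.6               # corr of TSS2/TSS3 log2FC effects
    effect_sd: float = 1.0                # SD of log2FC effects
    n_replicates: int = 3                 # per condition
    background_rate: float = 0.01         # expected background tags per bp
    coverage_depth: float = 15.0          # RNA-seq body depth per sample
    darna_length_median: float = 9568.0   # planted daRNA length, log-normal
    darna_length_sigma: float = 0.8
    darna_length_max: int = 40000
    host_body_range: tuple = (2000, 10000)
    qtts_extra_max: int = 2               # extra (weaker) QTTSs per daRNA
    min_spacing: int = 5000               # bp between planted locus extents
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_quadruples, self.n_divergent_only, self.n_isolated) < 0:
            raise ValueError("locus counts must be >= 0")
        if not (0.0 <= self.effect_rho <= 1.0):
            raise ValueError("effect_rho must be in [0, 1]")
        if self.gap_range[0] < 2:
            raise ValueError("gap_range minimum must be >= 2 bp")
        if self.gap_range[0] > self.gap_range[1]:
            raise ValueError("gap_range must be (min, max) with min <= max")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.min_spacing < 0:
            raise ValueError("min_spacing must be >= 0")


@dataclass
class PlantedLocus:
    """Ground truth for one planted promoter architecture."""

    architecture: str
    host_gene_id: str
    chrom: str
    tss_positions: dict  # label -> (chrom, position, strand)
    baseline_means: dict  # label -> expected tags per replicate
    planted_log2fc: dict  # label -> treatment effect
    darna_end: int | None = None       # primary daRNA 3' end (quadruples)
    darna_qtts: list = field(default_factory=list)  # (position, rel_strength)
    host_end: int | None = None        # host gene 3' end
    extent: tuple = (0, 0)             # (start, end) of everything planted

    def tss(self, label: str) -> tuple[str, int, str]:
        return self.tss_positions[label]


@dataclass
class TruthSet:
    """All planted loci plus the annotation records derived from them."""

    config: SimConfig
    chrom_sizes: dict
    loci: list
    annotation_records: list
    manifest: dict = field(default_factory=dict)

    @property
    def quadruples(self) -> list:
        return [l for l in self.loci if l.architecture == "quadruple"]

    def annotation(self) -> TranscriptAnnotation:
        return TranscriptAnnotation(self.annotation_records)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for locus in self.loci:
            for label, (chrom, pos, strand) in locus.tss_positions.items():
                rows.append({
                    "host_gene_id": locus.host_gene_id,
                    "architecture": locus.architecture,
                    "label": label,
                    "chrom": chrom,
                    "position": pos,
                    "strand": strand,
                    "baseline_mean": locus.baseline_means[label],
                    "log2fc": locus.planted_log2fc[label],
                    "darna_end": (
                        locus.darna_end if label == "TSS3" else ""
                    ),
                })
        columns = ["host_gene_id", "architecture", "label", "chrom",
                   "position", "strand", "baseline_mean", "log2fc",
                   "darna_end"]
        return pd.DataFrame(rows, columns=columns)


@dataclass
class SimulatedSample:
    sample_id: str
    condition: str
    replicate: int
    five_prime: StrandedEndTrack
    three_prime: StrandedEndTrack
    coverage: CoverageTrack


def _draw_locus_geometry(cfg: SimConfig, rng: np.random.Generator,
                         architecture: str, index: int) -> PlantedLocus:
    """Draw one locus's geometry and effects, anchored at coordinate 0
    for TSS2 / the main TSS; placement shifts everything later."""
    margin = 25  # keep jittered tags inside the locus extent
    log_b = rng.uniform(np.log(cfg.baseline_mean_range[0]),
                        np.log(cfg.baseline_mean_range[1]))
    b_host = float(np.exp(log_b))
    sub_max = b_host / cfg.expression_margin

    def sub_baseline(lo_frac: float, hi_frac: float) -> float:
        return float(max(8.0, sub_max * rng.uniform(lo_frac, hi_frac)))

    if architecture == "quadruple":
        div1 = int(rng.integers(cfg.divergent_range[0], cfg.divergent_range[1] + 1))
        div2 = int(rng.integers(cfg.divergent_range[0], cfg.divergent_range[1] + 1))
        gap = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
        darna_len = int(np.clip(
            rng.lognormal(np.log(cfg.darna_length_median), cfg.darna_length_sigma),
            200, cfg.darna_length_max,
        ))
        host_len = int(rng.integers(cfg.host_body_range[0], cfg.host_body_range[1] + 1))
        lfc2, lfc3 = rng.multivariate_normal(
            [0.0, 0.0],
            (cfg.effect_sd ** 2) * np.array(
                [[1.0, cfg.effect_rho], [cfg.effect_rho, 1.0]]
            ),
        )
        positions = {
            "TSS1": -div1, "TSS2": 0, "TSS3": gap, "TSS4": gap + div2,
        }
        strands = {"TSS1": "-", "TSS2": "+", "TSS3": "-", "TSS4": "+"}
        baselines = {
            "TSS1": sub_baseline(0.1, 0.8),
            "TSS2": b_host,
            "TSS3": sub_baseline(0.3, 1.0),
            "TSS4": sub_baseline(0.1, 0.8),
        }
        log2fcs = {"TSS1": float(lfc2), "TSS2": float(lfc2),
                   "TSS3": float(lfc3), "TSS4": float(lfc3)}
        darna_end = gap - darna_len
        qtts = [(darna_end, 1.0)]
        n_extra = int(rng.integers(0, cfg.qtts_extra_max + 1))
        inner_lo, inner_hi = darna_end + 200, gap - 200
        if inner_hi > inner_lo:
            for pos in rng.integers(inner_lo, inner_hi, size=n_extra):
                qtts.append((int(pos), float(rng.uniform(0.1, 0.5))))
        extent = (min(-div1, darna_end) - margin,
                  max(gap + div2, host_len) + margin)
        locus = PlantedLocus(
            architecture=architecture,
            host_gene_id=f"quad{index:05d}",
            chrom="",
            tss_positions={k: ("", v, strands[k]) for k, v in positions.items()},
            baseline_means=baselines,
            planted_log2fc=log2fcs,
            darna_end=darna_end,
            darna_qtts=qtts,
            host_end=host_len,
            extent=extent,
        )
        return locus

    if architecture == "divergent_only":
        div = int(rng.integers(cfg.divergent_range[0], cfg.divergent_range[1] + 1))
        host_len = int(rng.integers(cfg.host_body_range[0], cfg.host_body_range[1] + 1))
        lfc = float(rng.normal(0.0, cfg.effect_sd))
        locus = PlantedLocus(
            architecture=architecture,
            host_gene_id=f"div{index:05d}",
            chrom="",
            tss_positions={"TSS_minus": ("", -div, "-"),
                           "TSS_plus": ("", 0, "+")},
            baseline_means={"TSS_minus": sub_baseline(0.1, 0.8),
                            "TSS_plus": b_host},
            planted_log2fc={"TSS_minus": lfc, "TSS_plus": lfc},
            host_end=host_len,
            extent=(-div - margin, host_len + margin),
        )
        return locus

    host_len = int(rng.integers(cfg.host_body_range[0], cfg.host_body_range[1] + 1))
    lfc = float(rng.normal(0.0, cfg.effect_sd))
    return PlantedLocus(
        architecture="isolated",
        host_gene_id=f"iso{index:05d}",
        chrom="",
        tss_positions={"TSS": ("", 0, "+")},
        baseline_means={"TSS": b_host},
        planted_log2fc={"TSS": lfc},
        host_end=host_len,
        extent=(-margin, host_len + margin),
    )


def plant_loci(config: SimConfig) -> TruthSet:
    """Place all planted loci without overlap and derive the annotation.

    Architectures are interleaved in a seeded random order; consecutive
    locus extents (including RNA bodies) are separated by at least
    ``min_spacing``.  Raises when the configured chromosomes cannot hold
    all loci.
    """
    rng = np.random.default_rng(config.seed)
    kinds = (["quadruple"] * config.n_quadruples
             + ["divergent_only"] * config.n_divergent_only
             + ["isolated"] * config.n_isolated)
    rng.shuffle(kinds)
    drafts = [
        _draw_locus_geometry(config, rng, kind, i)
        for i, kind in enumerate(kinds)
    ]

    # greedy left-to-right placement
    if config.chrom_sizes is None:
        needed = sum(
            (d.extent[1] - d.extent[0]) + config.min_spacing for d in drafts
        ) + config.min_spacing
        chrom_sizes = {"chrSim": int(needed)}
    else:
        chrom_sizes = dict(config.chrom_sizes)

    chroms = sorted(chrom_sizes)
    loci: list[PlantedLocus] = []
    ci = 0
    cursor = config.min_spacing
    for draft in drafts:
        width = draft.extent[1] - draft.extent[0]
        while ci < len(chroms) and cursor + width + config.min_spacing > chrom_sizes[chroms[ci]]:
            ci += 1
            cursor = config.min_spacing
        if ci >= len(chroms):
            raise ValueError(
                "chromosomes too small to place all loci with the required spacing"
            )
        chrom = chroms[ci]
        shift = cursor - draft.extent[0]
        placed = _shift_locus(draft, chrom, shift)
        loci.append(placed)
        cursor += width + config.min_spacing

    records = []
    for locus in loci:
        if locus.architecture == "quadruple":
            _, tss2, _ = locus.tss("TSS2")
            iv = GenomicInterval(locus.chrom, tss2, locus.host_end, "+")
        elif locus.architecture == "divergent_only":
            _, tss, _ = locus.tss("TSS_plus")
            iv = GenomicInterval(locus.chrom, tss, locus.host_end, "+")
        else:
            _, tss, _ = locus.tss("TSS")
            iv = GenomicInterval(locus.chrom, tss, locus.host_end, "+")
        records.append(TranscriptRecord(
            gene_id=locus.host_gene_id,
            transcript_id=f"{locus.host_gene_id}.t1",
            interval=iv,
        ))

    return TruthSet(
        config=config,
        chrom_sizes=chrom_sizes,
        loci=loci,
        annotation_records=records,
        manifest={"n_loci": len(loci), "chrom_sizes": chrom_sizes},
    )


def _shift_locus(draft: PlantedLocus, chrom: str, shift: int) -> PlantedLocus:
    tss_positions = {
        label: (chrom, pos + shift, strand)
        for label, (_, pos, strand) in draft.tss_positions.items()
    }
    return dataclasses.replace(
        draft,
        chrom=chrom,
        tss_positions=tss_positions,
        darna_end=None if draft.darna_end is None else draft.darna_end + shift,
        darna_qtts=[(p + shift, s) for p, s in draft.darna_qtts],
        host_end=None if draft.host_end is None else draft.host_end + shift,
        extent=(draft.extent[0] + shift, draft.extent[1] + shift),
    )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size: int | None = None):
    """NB with var = mu + dispersion * mu^2 (Poisson when dispersion = 0)."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=np.int64) if size else 0
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def _jittered_positions(rng: np.random.Generator, center: int, n: int,
                        cap: int = 10) -> np.ndarray:
    """Tag positions center +- geometric(0.5) offsets, magnitude capped."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mags = np.minimum(rng.geometric(0.5, size=n) - 1, cap)
    signs = rng.integers(0, 2, size=n) * 2 - 1
    return center + mags * signs


def simulate_tracks(truth: TruthSet, config: SimConfig | None = None
                    ) -> list[SimulatedSample]:
    """Simulate per-sample 5'-end, 3'-end and coverage tracks.

    Samples are ``control_1..n`` and ``treated_1..n``; treated means are
    baseline * 2**log2FC.  Deterministic given the config seed (a separate
    stream from the one used for planting, so tracks do not depend on how
    many draws planting consumed).
    """
    cfg = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    samples_meta = [
        (f"{cond}_{r + 1}", cond, r + 1)
        for cond in ("control", "treated")
        for r in range(cfg.n_replicates)
    ]

    five = {
        sid: {} for sid, _, _ in samples_meta
    }  # sid -> (chrom,strand) -> list of position arrays
    three = {sid: {} for sid, _, _ in samples_meta}
    cov_runs = {sid: {} for sid, _, _ in samples_meta}

    def add_tags(store, sid, chrom, strand, positions):
        if positions.size:
            store[sid].setdefault((chrom, strand), []).append(positions)

    for locus in truth.loci:
        chrom = locus.chrom
        for label, (_, pos, strand) in locus.tss_positions.items():
            baseline = locus.baseline_means[label]
            lfc = locus.planted_log2fc[label]
            for sid, cond, _ in samples_meta:
                mu = baseline * (2.0 ** lfc if cond == "treated" else 1.0)
                n = int(_nb_draw(rng, mu, cfg.dispersion))
                add_tags(five, sid, chrom, strand,
                         _jittered_positions(rng, pos, n))

        # 3'-end signal and RNA-seq bodies
        if locus.architecture == "quadruple":
            _, tss2, _ = locus.tss("TSS2")
            _, tss3, _ = locus.tss("TSS3")
            b3 = locus.baseline_means["TSS3"]
            lfc2 = locus.planted_log2fc["TSS2"]
            lfc3 = locus.planted_log2fc["TSS3"]
            for sid, cond, _ in samples_meta:
                scale2 = 2.0 ** lfc2 if cond == "treated" else 1.0
                scale3 = 2.0 ** lfc3 if cond == "treated" else 1.0
                # QTTSs of the daRNA (- strand): primary at the body end
                for qpos, strength in locus.darna_qtts:
                    n = int(_nb_draw(rng, 0.8 * b3 * strength * scale3,
                                     cfg.dispersion))
                    add_tags(three, sid, chrom, "-",
                             _jittered_positions(rng, qpos, n))
                # host 3' end (+ strand)
                n = int(_nb_draw(
                    rng, 0.8 * locus.baseline_means["TSS2"] * scale2,
                    cfg.dispersion))
                add_tags(three, sid, chrom, "+",
                         _jittered_positions(rng, locus.host_end - 1, n))
                # bodies: host on +, daRNA on -
                d_host = int(_nb_draw(rng, cfg.coverage_depth * scale2,
                                      cfg.dispersion))
                if d_host > 0:
                    cov_runs[sid].setdefault((chrom, "+"), []).append(
                        (tss2, locus.host_end, d_host))
                d_da = int(_nb_draw(rng, cfg.coverage_depth * scale3,
                                    cfg.dispersion))
                if d_da > 0:
                    cov_runs[sid].setdefault((chrom, "-"), []).append(
                        (locus.darna_end, tss3 + 1, d_da))
        else:
            label = "TSS_plus" if locus.architecture == "divergent_only" else "TSS"
            _, tss, _ = locus.tss(label)
            lfc = locus.planted_log2fc[label]
            baseline = locus.baseline_means[label]
            for sid, cond, _ in samples_meta:
                scale = 2.0 ** lfc if cond == "treated" else 1.0
                n = int(_nb_draw(rng, 0.8 * baseline * scale, cfg.dispersion))
                add_tags(three, sid, chrom, "+",
                         _jittered_positions(rng, locus.host_end - 1, n))
                depth = int(_nb_draw(rng, cfg.coverage_depth * scale,
                                     cfg.dispersion))
                if depth > 0:
                    cov_runs[sid].setdefault((chrom, "+"), []).append(
                        (tss, locus.host_end, depth))

    # uniform background on every signal class
    if cfg.background_rate > 0:
        for chrom, size in sorted(truth.chrom_sizes.items()):
            lam = cfg.background_rate * size
            for sid, _, _ in samples_meta:
                for strand in ("+", "-"):
                    for store in (five, three):
                        n_bg = rng.poisson(lam)
                        add_tags(store, sid, chrom, strand,
                                 rng.integers(0, size, size=n_bg))
                    n_bg = rng.poisson(lam)
                    bg_pos = np.sort(rng.integers(0, size, size=n_bg))
                    cov_runs[sid].setdefault((chrom, strand), []).extend(
                        (int(p), int(p) + 1, 1) for p in bg_pos
                    )

    out = []
    for sid, cond, rep in samples_meta:
        t5 = StrandedEndTrack(sid, FIVE_PRIME)
        for (chrom, strand), chunks in five[sid].items():
            pos = np.concatenate(chunks)
            pos = np.clip(pos, 0, truth.chrom_sizes[chrom] - 1)
            t5.add_counts(chrom, strand, pos, np.ones(pos.size, dtype=np.int64))
        t3 = StrandedEndTrack(sid, THREE_PRIME)
        for (chrom, strand), chunks in three[sid].items():
            pos = np.concatenate(chunks)
            pos = np.clip(pos, 0, truth.chrom_sizes[chrom] - 1)
            t3.add_counts(chrom, strand, pos, np.ones(pos.size, dtype=np.int64))
        cov = CoverageTrack(sid)
        for (chrom, strand), runs in cov_runs[sid].items():
            cov.add_runs(chrom, strand, runs)
        out.append(SimulatedSample(sid, cond, rep, t5, t3, cov))
    return out


def write_truth(truth: TruthSet, outdir) -> dict:
    """Write the ground truth: BED6 of planted TSSs, a TSV truth table,
    and a minimal GTF of host genes.  Returns the file manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bed_path = os.path.join(outdir, "truth_tss.bed")
    tsv_path = os.path.join(outdir, "truth_table.tsv")
    gtf_path = os.path.join(outdir, "annotation.gtf")

    rows = []
    for locus in truth.loci:
        for label, (chrom, pos, strand) in locus.tss_positions.items():
            rows.append((chrom, pos, pos + 1,
                         f"{locus.host_gene_id}:{label}",
                         int(round(locus.baseline_means[label])), strand))
    write_bed6(rows, bed_path)
    write_tsv(truth.truth_frame(), tsv_path)
    write_gtf(truth.annotation_records, gtf_path)
    manifest = {"truth_tss": bed_path, "truth_table": tsv_path,
                "annotation": gtf_path}
    truth.manifest.update(manifest)
    return manifest


def write_tracks(samples: list[SimulatedSample], outdir) -> dict:
    """Write all per-sample tracks as `{sample}.{signal}.{strand}.bedgraph`."""
    import os

    os.makedirs(outdir, exist_ok=True)
    manifest = {}
    for s in samples:
        for strand in ("+", "-"):
            sname = _STRAND_NAME[strand]
            p5 = os.path.join(outdir, f"{s.sample_id}.five_prime.{sname}.bedgraph")
            write_bedgraph_ends(s.five_prime, strand, p5)
            p3 = os.path.join(outdir, f"{s.sample_id}.three_prime.{sname}.bedgraph")
            write_bedgraph_ends(s.three_prime, strand, p3)
            pc = os.path.join(outdir, f"{s.sample_id}.coverage.{sname}.bedgraph")
            write_bedgraph_coverage(s.coverage, strand, pc)
            manifest[f"{s.sample_id}.{sname}"] = {
                "five_prime": p5, "three_prime": p3, "coverage": pc,
            }
    return manifest
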