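# Methods

This note documents the models and procedures implemented in `cocoprom`,
the defaults and why they were chosen, what the synthetic data emulate
(and do not), and the numerical choices that affect results.

## Coordinate and data model

All internal coordinates are 0-based, half-open (BED convention); GTF is
converted at the read/write boundary, so a `+` strand transcript starting
at GTF column 4 = 1001 has its annotated TSS at internal position 1000,
and a `−` strand transcript ending at 2000 has it at 1999. Strand-specific
signal is held separately per `(chromosome, strand)`: 5′/3′-end tags as
sparse per-base counts, RNA-seq coverage as run-length intervals.
Annotated TSSs are *transcript* 5′ ends; no gene-level deduplication is
applied, since overlap tests are against individual start sites.

## CTSS/QTTS calling

End-count peaks are called on counts pooled across **all** samples and
conditions — pooling maximizes detection power, and condition-specific
quantification happens later at peak level. The caller is a seed-and-extend
rule chosen for reproducibility and oracle-testability:

* a position seeds a peak when its pooled count ≥ `min_seed_count`
  (default 5) **and** the Poisson upper-tail probability of that count
  under the genome-wide mean count per base is ≤ `background_alpha`
  (default 10⁻³);
* a peak spans contiguous non-zero signal around its seeds, tolerating
  internal zero-runs of ≤ `max_internal_gap` (10 bp);
* peaks with an edge-to-edge gap ≤ `merge_gap` (50 bp, inclusive) are
  merged transitively;
* the summit (CTSS for 5′ data, QTTS for 3′ data) is the position of the
  maximum pooled count, ties broken toward the smallest coordinate (the
  first-maximum behavior of standard max-element tooling).

Under pure background the expected number of false seeds is bounded by
`background_alpha × genome length`, which keeps spurious peaks out of the
pairing steps. No replicate-aware peak statistics or peak-level FDR are
attempted; downstream pairing is agnostic to the caller.

## Convergent promoter detection

**Core set.** Divergent pairs are formed from a `−` strand CTSS followed
by a `+` strand CTSS within `divergent_window` = 400 bp. "Paired within a
window" is operationalized as **mutual-nearest, one-to-one** pairing of
summits: each site pairs with its nearest eligible partner only when the
choice is reciprocal, which prevents one TSS joining two pairs and
thereby prevents overlapping constellations. Consecutive divergent pairs
are joined into a quadruple when the gap between their inner convergent
TSSs (upstream pair's `+`TSS → downstream pair's `−`TSS) is in
[`min_gap`, `convergent_window`] = [1, 2500] bp. All distances are
summit-to-summit, not peak-edge (a configurable choice; summit distances
are what the per-constellation tables report). The most strongly
expressed of the four TSSs (peak-level pooled tags) becomes TSS2; its
divergent partner is TSS1, the convergent counterpart TSS3, and TSS3's
partner TSS4; labels mirror by strand symmetry when the dominant TSS is
on the `−` strand. A constellation whose strongest TSS is one of the two
*outer* sites has no convergent host and is rejected. Expression ties
resolve toward the annotation-supported TSS, then the leftmost. Finally
the quadruple is kept only if an annotated same-strand TSS falls inside
TSS2's peak interval (peak overlap, not exact-position match), which also
assigns the host gene.

**Extended set.** `+` strand CTSSs are paired directly with a downstream
`−` strand CTSS within 2,500 bp (mutual-nearest again); a pair is kept
when at least one member's peak overlaps an annotated same-strand TSS.
The overlapping member is the host; if both or neither overlap, the more
expressed member is. This search does not require the flanking divergent
partners and is therefore strictly less conservative: the core set,
projected to (host TSS, daTSS) pairs, is contained in it.

`min_gap` = 1 forbids degenerate zero-distance convergent pairs.

## daRNA annotation

A daRNA is annotated only when no gene-start annotation is available at
the daTSS (checked against the daTSS's peak interval). The body grows
from the daTSS in the transcription direction over consecutive windows of
length `window_len` = 100 bp on pooled antisense RNA-seq coverage. The
coverage rule "ten reads" is interpreted as **mean per-base coverage ≥ 10
within the window** (equivalently window sum ≥ 10 × window length); a raw
10-read window sum over 100 bp would pass at 0.1× coverage, which cannot
be what a coverage threshold means. The interpretation is switchable
(`mode="mean"` vs `"sum"`). Windows advance by a full window
(non-overlapping) by default; the step is configurable. Within each step
the termination check precedes the coverage check, so an annotated,
CAGE-peak-supported same-strand TSS truncates even continuous coverage at
the TSS position (exclusive).

3′ ends come from QTTSs inside the body — one transcript per QTTS, ranked
by descending pooled QTTS count (`da1`, `da2`, …), ties broken toward the
longer transcript; the rank-1 transcript is the *dominant* daRNA. Because
the window scan quantizes the body end to the window grid, QTTS-to-body
assignment admits sites up to one window length beyond the 3′ edge and
extends the transcript to them; otherwise the genuine termination site
sitting a few bases past the last full window would be dropped. A locus
with coverage support but no QTTS still yields one transcript ending at
the body end (`qtts = None`), keeping length statistics well defined. Host
traversal is interval containment of the host TSS position in the
(half-open) daRNA body.

## Quantification and statistics

Counting is strand-aware end-tag summation inside peak intervals; features
overlapping on the same strand are counted independently. Size factors are
median-of-ratios: for feature rows positive in every sample, the ratio of
each sample's count to the row's geometric mean is formed and the
per-sample median taken. Note that scaling one sample's counts by *c*
moves the geometric-mean reference too: with *m* samples the scaled
sample's factor grows by c^((m−1)/m) and the others shrink by c^(1/m), so
normalized counts change only by a global constant and fold changes are
unaffected. Without any all-positive row the estimator falls back to
total-count scaling (normalized to geometric mean 1) with a warning.

log₂FC = log₂((mean normalized treated + ε)/(mean normalized control + ε))
with pseudocount ε = 1 normalized count; base mean is the mean normalized
count over all samples. No dispersion model, Wald test or shrinkage is
fitted — the co-regulation analyses consume the log₂FC values only.
Expression and distance groups are equal-count rank tertiles with ties
assigned to the lower group.

Spearman's ρ uses average ranks; its two-sided p value is exact (full
permutation enumeration) for n ≤ 10 and the t-approximation with n − 2 df
otherwise. The "fraction with negative correlation" summary is
operationalized as sign discordance of log₂FC pairs (zeros counted
concordant) and labeled as such. Group comparisons use the two-sided
Mann–Whitney U with normal approximation, tie and continuity correction.
BH adjustment is the standard step-up with monotonicity enforcement. The
Tau index is τ = Σᵢ(1 − xᵢ/x_max)/(n − 1) over per-tissue expression.
Scale-adjusted metaprofiles split each region into equal fractional bins
via the cumulative integral (exact for regions shorter than the bin
count), reverse `−` strand regions so bin 1 is always the 5′ anchor, and
average across regions; an anchored mode profiles a fixed ±flank window
around the 5′ anchor.

## What the simulation emulates

The generator's defaults are the study conditions under which the
pipeline is validated:

| parameter | default | meaning |
|---|---|---|
| `gap_range` | (2, 2301) bp | TSS2–TSS3 distance, uniform (observed span of convergent TSS distances) |
| `divergent_range` | (80, 380) bp | TSS1–TSS2 and TSS3–TSS4 distances (within the 400 bp pairing window with ≥ 20 bp headroom for summit jitter) |
| `baseline_mean_range` | (50, 300) tags | host-TSS expression per replicate, log-uniform |
| `expression_margin` | 2 | host TSS ≥ 2× every other TSS of its constellation |
| `dispersion` | 0.05 | NB: var = μ + 0.05 μ² |
| `effect_rho`, `effect_sd` | 0.6, 1.0 | correlation and SD of TSS2/TSS3 treatment log₂FCs (bivariate normal); TSS1/TSS4 copy their divergent partners |
| `n_replicates` | 3 per condition | control and treated |
| `background_rate` | 0.01 tags/bp | uniform Poisson background on every signal |
| `coverage_depth` | 15× per sample | RNA-seq body depth |
| `darna_length_median`, `_sigma` | 9,568 bp, 0.8 | log-normal daRNA length (typical daRNA length scale, capped at 40 kb) |
| `min_spacing` | 5,000 bp | between locus *extents* (bodies included), so no cross-locus pairing is possible under the 2,500 bp window |

5′ tags get a geometric(0.5) positional jitter capped at 10 bp
(P(offset = 0) = 0.5), which produces realistic peak shapes with a unique
modal base for summit calling. All quadruples are planted in the
`plus_host` orientation (TSS2 on `+`), matching the labeled layout;
strand-flip symmetry of the detector is covered by dedicated mirrored
unit tests instead. Upstream-antisense (TSS1) and downstream-sense (TSS4)
transcripts get 5′/no body coverage, reflecting the rapid turnover of
promoter upstream transcripts; RNA-seq bodies are simulated for the host
(TSS2 → host 3′ end) and the daRNA (TSS3 → planted 3′ end) only. Each
daRNA carries a primary QTTS at its full body end plus up to two weaker
internal QTTSs (10–50% strength) to exercise ranking and dominance.
Because the TSS expression distribution of real libraries is unknown, a
log-uniform baseline range is used rather than an attempt to match them.

Not emulated: sequence content (no FASTA/FASTQ), alignment artifacts,
splicing, PCR duplicates, mappability, chained constellations of more
than four TSSs, and antisense coverage that does not originate from the
planted daRNA. Passing tests therefore demonstrate correctness of the
detection logic and statistics under the stated noise model, not
robustness to real-library artifacts such as internal priming in 3′-end
data or multimapping.

## Numerical choices and degenerate inputs

* Seeded `numpy` generators everywhere; planting and track simulation use
  separate seed-derived streams so tracks do not depend on how many draws
  planting consumed. Identical config + seed ⇒ byte-identical outputs.
* Summit/expression ties: leftmost coordinate; QTTS ranking ties: longer
  transcript; tertile ties: lower group — all deterministic.
* Constant input to Spearman: ρ undefined, returned as NaN with a
  warning. All-zero expression vector: Tau undefined, raised.
* Windows at chromosome edges are clipped and judged on their clipped
  length; a daRNA whose first window fails yields no body.
* Empty inputs: empty truth sets, header-only tables and empty peak lists
  round-trip cleanly; pooling an empty track set is an error.

## Validation problem sizes

The acceptance checks run at 600 mixed loci (detection scoring), 1,000
quadruples × 6 samples (co-regulation recovery, with a matched null) and
500 quadruples (daRNA boundary/dominance recovery) — sizes at which the
planted-effect correlation is estimated to ±0.05 and each run completes
in well under a minute. Detected TSS2/TSS3 log₂FC Spearman ρ is expected
below the planted Pearson 0.6 even at perfect detection: the rank
correlation of a bivariate normal is (6/π)·asin(ρ/2) ≈ 0.58, further
attenuated by counting noise at the configured depths (≈ 0.52–0.56
observed).

## Known limitations

* The stand-in peak caller is not the external adaptive-mode caller used
  on real libraries; downstream sets on real data will depend on the
  caller, and that sensitivity should be reported, not assumed.
* The differential model is a pseudocounted fold change of normalized
  means, not a dispersion-aware test; it supplies no per-feature p values.
* Chains of more than two divergent pairs emit all sliding pair-of-pairs
  joins; overlapping constellations are possible on real data and are not
  deduplicated beyond the one-to-one pairing guarantees.
* Whether annotation overlap should be tested at gene or transcript level
  is an open question on real annotations; transcript level is
  implemented.
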