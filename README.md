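# cocoprom

Detection and co-regulation analysis of **convergent promoters** from
strand-specific 5′-end (CAGE-like), 3′-end (QuantSeq-like) and RNA-seq
coverage tracks — for regulatory genomicists studying antisense
transcription at gene promoters.

## The problem and the method

Many active promoters are not isolated: a second promoter sits just
downstream on the opposite strand and fires *toward* the first one,
producing a downstream antisense RNA (daRNA) that overlaps the host gene's
5′ end. In its full form this is a constellation of four transcription
start sites,

```
 TSS1(−) ◄──┐          ┌──► TSS4(+)
            │          │
     TSS2(+)├──►  ◄────┤TSS3(−)
        host RNA    daRNA
```

where TSS2 is the most strongly expressed site (the host gene TSS), TSS1
its upstream-antisense partner, TSS3 the daRNA TSS and TSS4 the daRNA's
own divergent partner. `cocoprom` implements the detection and analysis
of these structures:

1. **CTSS/QTTS calling** — strand-specific seed-and-extend peak calling
   on per-base end counts pooled across all samples (Poisson background
   test for seeds, 50 bp peak merging) with summits by local maxima.
2. **Core set** — divergent pairing (−TSS followed by +TSS within 400 bp,
   mutual-nearest, one-to-one), joining of consecutive divergent pairs
   whose inner convergent TSSs are ≤ 2,500 bp apart, expression-based
   TSS1–TSS4 labeling, and filtering on an annotated TSS inside the host
   peak.
3. **Extended set** — direct pairing of a +TSS with a downstream −TSS
   within 2,500 bp, keeping pairs with annotation support; a deliberately
   less conservative search.
4. **daRNA annotation** — transcript bodies grown from the daTSS over
   100 bp windows of antisense RNA-seq coverage (mean ≥ 10 reads/base per
   window), terminated at CAGE-supported annotated TSSs; 3′ ends assigned
   from QTTSs, transcripts ranked `da1, da2, …` by QTTS expression, with
   the strongest flagged *dominant*.
5. **Quantification & statistics** — peak-level end-tag counting,
   median-of-ratios size factors, pseudocounted log₂ fold changes
   (log₂FC) of condition means, Spearman correlation with two-tailed
   significance, OLS fits with 95% confidence bands, Wilcoxon rank-sum
   comparisons, Benjamini–Hochberg adjustment, the Tau
   tissue-specificity index τ = Σᵢ(1 − xᵢ/x_max)/(n − 1), and
   scale-adjusted metaprofiles.

A first-class synthetic-data module plants all three locus architectures
(quadruples, plain divergent promoters, isolated TSSs) on a toy genome
with negative-binomial replicate noise, correlated TSS2/TSS3 treatment
effects, RNA-seq bodies and 3′-end pile-ups, and emits machine-readable
ground truth — so the whole pipeline is exercised end to end without any
download.

## Worked example

```python
from cocoprom import SimConfig, plant_loci, simulate_tracks
from cocoprom.pipeline import run_end_to_end

cfg = SimConfig(n_quadruples=50, n_divergent_only=20, n_isolated=20,
                effect_rho=0.6, seed=4)
truth = plant_loci(cfg)
samples = simulate_tracks(truth, cfg)          # 3 control + 3 treated
res = run_end_to_end(samples, truth.annotation(), truth.chrom_sizes)

print(f"CTSS peaks: {len(res.ctss_peaks)}, QTTS peaks: {len(res.qtts_peaks)}")
print(f"core quadruples: {len(res.quadruples)}")
print(f"extended pairs:  {len(res.extended_pairs)}")

import numpy as np
dom = [d for ds in res.darnas.values() for d in ds if d.dominant]
print(f"daRNA hosts: {len(res.darnas)}, median dominant length: "
      f"{int(np.median([d.length for d in dom]))} bp")
rho, p = res.correlation
print(f"TSS2 vs TSS3 log2FC: Spearman rho = {rho:.2f} (p = {p:.1e})")
```

prints

```
CTSS peaks: 260, QTTS peaks: 194
core quadruples: 49
extended pairs:  50
daRNA hosts: 49, median dominant length: 11101 bp
TSS2 vs TSS3 log2FC: Spearman rho = 0.40 (p = 4.4e-03)
```

49 of the 50 planted four-TSS constellations are recovered as core
quadruples (none of the divergent-only or isolated loci are), every core
constellation also appears in the extended set, 49 host genes receive
annotated daRNAs, and the detected log₂FCs of the convergent TSS2/TSS3
pairs are positively correlated — the co-regulation signal planted with
correlation 0.6, attenuated by rank conversion and counting noise at this
small n.

The same analysis is available from the shell:

```bash
cocoprom simulate --outdir sim --seed 4
cocoprom run --annotation sim/annotation.gtf --samples sim/samples.tsv --outdir out
```

which writes `core_quadruples.tsv`, `extended_pairs.tsv`, `darnas.tsv`,
`peak_log2fc.tsv`, `quadruple_log2fc.tsv` and a `manifest.json` with a
parameter hash; reruns with the same inputs are byte-identical.

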