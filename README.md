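# wnttargets

Integrative inference of **direct Wnt/CTNNB1 (β-catenin) target genes** from
transcription-factor ChIP-seq peaks combined with knockdown expression
profiling, plus the downstream signature statistics: genomic-feature
annotation with permutation nulls, degenerate-motif enrichment, GSEA/KS
rank enrichment, hypergeometric set overlap, and Kaplan–Meier/log-rank
survival stratification. Everything runs on seeded synthetic data, so the
whole pipeline is testable without any download.

## Who this is for

Regulatory genomicists who have (a) a peak list (BED) for a
chromatin-associated factor, (b) a two-replicate knockdown expression table
(per-gene log10 ratio + p-value for each of two independent siRNAs), and
who want to call *direct, functional* targets — genes that are both bound
and respond to depletion of the factor — and then ask what the resulting
signature overlaps, and whether it stratifies patient survival.

## The statistics at the core

**Direct-target call.** Gene *g* is a direct functional target iff

* a peak center lies within ±20 kb of its TSS (binding), and
* *p* < 0.01 and log₁₀ ratio < −0.2 in **both** knockdown channels
  (down-regulation), all inequalities strict.

Log ratios are base-10, so the reported signed fold change is
`fc(r) = 10^r` for `r ≥ 0` and `−10^(−r)` for `r < 0` (e.g. `fc(−1.4) =
−25.11886432`).

**Feature enrichment.** Each peak is classified by its center point
(promoter = 2 kb upstream of the TSS; precedence promoter > 5′UTR > exon >
intron > 3′UTR > downstream; else intergenic). The null is built by
re-placing length- and chromosome-matched peaks uniformly; the empirical
p-value uses the add-one rule `p = (1 + #{null ≥ obs}) / (B + 1)`.

**Rank enrichment (modified KS / GSEA).** Walking the ranked list, the
running sum gains `|m_i|^w / Σ_hits |m|^w` at set members (w = 0: `1/n_hits`)
and loses `1/(N − n_hits)` at misses; ES is the extremum, and
`NES = ES / mean(|ES_null| of the same sign)` over random same-size gene
sets.

**Set overlap.** Representation factor `RF = k·N/(|A|·|B|)` and the exact
hypergeometric upper tail `P(X ≥ k)` under a fixed universe (default
N = 20000).

**Survival.** Per-sample mean expression of the signature genes (after
per-array mean-centering), median split into high/low expressers, KM
curves, and the unweighted Mantel–Haenszel log-rank test.

## Worked example

```python
import numpy as np
from wnttargets import (
    AnnotationConfig, GenomeAnnotation, feature_distribution,
    permutation_enrichment, link_peaks_to_genes, motif_enrichment_test,
    rank_by, permutation_pvalue, call_targets, overlap_report,
    stratified_survival, SimulationConfig, simulate_dataset,
)
from wnttargets.target_calling import signature

ds = simulate_dataset(SimulationConfig(seed=7))   # toy genome, peaks, knockdowns, cohort
cfg = AnnotationConfig(n_permutations=200, seed=7)
ann = GenomeAnnotation(ds.genes, cfg)

feature_distribution(ds.peaks, ann)
# {'promoter': 0.12, 'utr5': 0.007, 'exon': 0.057, 'intron': 0.197,
#  'utr3': 0.01, 'downstream': 0.093, 'intergenic': 0.517}

bound = link_peaks_to_genes(ds.peaks, ann, cfg)   # 175 genes with a peak within 20 kb

res = motif_enrichment_test(ds.peaks, ds.genome, "TGAYTCA", 10,
                            np.random.default_rng(7))
# 87/300 peaks hit; background q = 0.0753; fold 3.85; p = 2.02e-28

sig = signature(call_targets(ds.expression, bound))   # 40 genes; the planted set exactly

score = permutation_pvalue(rank_by(ds.expression, "fold_change", 2), sig,
                           n_perm=1000, rng=np.random.default_rng(7))
# ES 0.800, NES 5.42, p 0.0021 — the signature sits at the down-regulated top

ov = overlap_report(sig, set(ds.truth.target_symbols), 20000)
# k = 40, RF = 500.0, p = 7.7e-125

curves, lr, labels = stratified_survival(ds.matrix, sig, ds.clinical)
# log-rank chi2 26.02, p = 3.4e-07 — the planted hazard ratio of 2 is detected
```

The motif fold of ~3.9 reflects the one motif copy planted per target peak
over the ~7.5% chance rate of the degenerate 7-mer in uniform sequence; the
overlap and log-rank numbers quantify perfect signature recovery and the
planted survival effect in this simulation.

A command-line interface mirrors the library
(`wnttargets simulate|annotate-peaks|motif-enrich|ks-enrich|call-targets|overlap-test|survival`);
run any subcommand with `--help`.

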