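# Methods

## Problem and model

The pipeline identifies *direct, functional* targets of a chromatin-bound
transcriptional co-activator by intersecting two kinds of evidence: genomic
binding (ChIP-seq peaks) and regulatory response (expression change upon
RNAi knockdown of the factor, measured with two independent siRNAs on a
two-color array platform that reports a per-gene log₁₀ ratio and p-value).
Binding alone over-calls (many bound loci are not regulated); expression
alone cannot separate direct from secondary responses. The conjunction —
a peak near the TSS *and* concordant down-regulation under both knockdowns
— is the target-calling model.

## Coordinates and annotation

All coordinates are 0-based half-open (BED convention) end to end. The TSS
of a − strand transcript is `txEnd − 1`, the last covered base, so every
TSS is a real genomic position. Gene symbols are matched case-sensitively
after whitespace trimming; no alias resolution.

A peak is classified by its **center point** `(start + end) // 2` into
exactly one category, so category fractions always sum to 1:

* promoter — 2 kb (configurable) upstream of the TSS, strand-aware;
* 5′/3′ UTR — exonic sequence outside the CDS, strand-aware; non-coding
  transcripts (cdsStart == cdsEnd) contribute plain exon blocks instead;
* exon — exonic sequence inside the CDS;
* intron — between exons;
* downstream — 2 kb past the transcription termination site;
* intergenic — everything else.

When the center falls in windows of several transcripts the category of
highest precedence wins (promoter > utr5 > exon > intron > utr3 >
downstream). The precedence is asserted, not derived: a center-point rule
needs a total order, and promoters-first matches the emphasis on
promoter-proximal binding.

Signed TSS distance is `(center − TSS) × strand`, negative upstream. Ties
between equidistant TSSs break toward the transcript earliest in
(chrom, txStart, symbol) order — deterministic and layout-independent.

Peak–gene linking takes the peak **center** within ±20 kb of a TSS,
boundary inclusive. Whether the original analysis measured from center or
edge is not recoverable from its description; center is consistent with
the center-based distance profile, and the window is configurable.

## Permutation null

Null peaks keep their chromosome and length and draw a uniform start in
`[0, chrom_len − length]`. The empirical p-value uses the add-one
(Davison–Hinkley) form `(1 + #{fraction_null ≥ fraction_obs})/(B + 1)`,
and a result with zero exceedances is reported as the bound `< 1/(B+1)`.
No gap/blacklist masking is applied: the synthetic genomes have none, and
real-genome masking would be an input-preparation step, not a statistic.

## Motif enrichment

Motifs are IUPAC strings scanned on both strands; an `N` in the *sequence*
never matches any pattern position (an unknown base is not evidence).
A peak is a hit if it contains ≥ 1 match, making the per-peak statistic an
indicator, so the all-overlapping-matches reporting policy cannot change
results. The background per-peak hit probability `q` is estimated by
pooling `n_background_sets` (default 10) shuffled length/chromosome-matched
fragment sets, and the p-value is the binomial upper tail
`P(X ≥ hits | n_peaks, q)`. A per-peak binomial was chosen over a per-bp
model because the hit indicator is insensitive to within-peak match
multiplicity; when `q = 0` with observed hits the p-value is reported as
the resolution bound `1/n_background_fragments` with an infinite-fold flag.

## Rank enrichment (modified KS / GSEA)

The running sum adds `|m_i|^w / Σ_hits |m|^w` at members and subtracts
`1/(N − n_hits)` at misses; `w = 0` is the classic KS form used to relate
bound genes to the knockdown ranking, `w = 1` the weighted form for
signatures in external expression datasets. ES is the running-sum value of
maximal absolute deviation (first extremum on exact ties). Ranking keys:
`p_value` orders down-regulated genes by ascending p, then up-regulated by
descending p (the up-gene order is a design choice — the mirror makes the
list run most-down-significant to most-up-significant); `fold_change`
orders by ascending log ratio. Ties always break by symbol.

Significance permutes **gene labels** (random same-size sets), not
phenotypes, because the use case has a single ranked list. The p-value
conditions on sign: `(1 + #{same-sign |ES_null| ≥ |ES_obs|}) /
(n_same_sign + 1)`; NES divides ES by the same-sign null mean of |ES|.
With no same-sign nulls the p-value is reported as the bound
`1/(n_perm + 1)`.

## Target calling

Strict inequalities throughout (`p < 0.01`, `log₁₀ ratio < −0.2`, both
channels), binding required, genes without expression data never called.
Log ratios are interpreted as **base-10**: a −1.4 log ratio corresponds to
a −25.11886432 signed fold change, which pins the base. A gene with
multiple probes keeps the record with the smallest `max(p1, p2)` (the
generator emits one record per gene; the rule exists for real tables).
Output is sorted by `min(p1, p2)`.

## Set overlap

`RF = k·N/(|A|·|B|)` in exact rational arithmetic before the final
division; the p-value is the inclusive upper tail `P(X ≥ k)` of the
hypergeometric distribution, computed by a log-space library routine
(stable for universes of 10⁴–10⁵) and checked in the tests against full
rational enumeration for every universe ≤ 30. The universe defaults to
20000 (conventional protein-coding gene count) and is always overridable.

## Survival

Arrays are per-sample mean-centered (optionally after log2 when inputs are
linear intensities); the signature score is the unweighted mean over
signature genes present; the median splits samples with ties going to the
low group (a documented choice — the split rule must be deterministic).
The KM estimate is the product-limit form (delegated to lifelines); the
log-rank test is the unweighted Mantel–Haenszel form implemented directly
so per-group observed/expected totals are reported; strata with a single
subject at risk contribute `O − E = 0` and zero variance. The
implementation is cross-checked against lifelines' log-rank on random
cohorts in the tests.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions used by every test:

* **Genome** — 2 chromosomes × 2 Mb of i.i.d. uniform ACGT; 200 genes of
  5 kb (3 exons, CDS inset 150 bp) tiled on 20-kb slots, strands
  alternating.
* **Peaks** — 300 total; one peak per bound planted gene with center
  Normal(TSS, 5 kb) truncated to the ±20 kb linking window (or uniform in
  the promoter, as a placement mode for promoter-enrichment studies);
  background peaks uniform. Lengths Normal(320.6, 60) truncated ≥ 50 bp —
  the mean matches the average ChIP fragment size of the emulated
  experiment.
* **Planted roles** — 40 targets (down in both channels, bound), 20
  one-channel decoys (down in one channel, bound), 20 unbound decoys (down
  in both channels, no peak). Planted log₁₀ effects are Normal(−0.5, 0.1)
  with p ~ U(0, 10⁻³), sized to clear the calling thresholds; null genes
  are Normal(0, 0.1) with p ~ U(0, 1).
* **Cohort** — 232 samples, N(0,1) expression, half with signature genes
  shifted +1; event times exponential (baseline hazard 0.1/unit, hazard
  ratio 2 for the shifted group), censoring exponential at rate 0.04
  (≈ 30% censored in the baseline group).

Two generator design points deserve emphasis. First, with 20-kb gene slots
and a 20-kb linking window, uniform background peaks would bind unbound
decoys at high rate and make the planted truth false as labelled; both
background and planted peak placements are therefore rejection-sampled to
stay > 20 kb from every unbound-decoy TSS, and the role assignment never
lets two unbound decoys flank a common neighbour (a gene sandwiched
between two decoy windows has no legal peak position at all). Second,
planted p-values are drawn directly rather than derived from a replicate
error model: the pipeline consumes (lr, p) pairs, and the array platform's
error model is out of scope.

What passing tests on this generator do **not** show about real data:
realistic nucleotide composition or repeat structure (motif background
rates are clean binomials here), probe-level duplication, assembly gaps,
correlated expression noise between siRNA channels, or the gene-density
pattern of a real genome (the toy genome is uniformly dense, which makes
"fraction of genes bound" much higher than in real annotations).

## Numerical choices and degenerate inputs

* Empirical p-values everywhere use add-one corrections and are reported
  as bounds when no permutation reaches the observation.
* Running sums for `w = 0` end at 0 within 1e-9 (asserted); ES extremum
  ties take the first index.
* `hypergeom` inputs are validated for feasibility
  (`|A| + |B| − k ≤ N`, `k ≤ min`), and `RF` uses `Fraction` before the
  final float division.
* Degenerate splits (all scores identical), empty peak lists, empty
  gene-set intersections and all-hit gene sets raise errors rather than
  returning conventions.
* All randomness flows through `numpy.random.Generator`; the simulator
  derives one child seed per stage from the master seed, so stage outputs
  are reproducible bit-for-bit and independent of call order.

## Problem sizes used in the test suite

Calibration suites use 200–500 replicates with 99–100 permutations each on
reduced layouts (10–40 genes, 40–50 peaks, 200-gene ranked lists); recovery
uses 20 full-size simulations; survival power uses 100 cohorts of 232.
These sizes give binomial standard errors small enough for the 3·SE
acceptance bands while keeping the default test run under a minute.

## Known limitations

* Peak-calling, read mapping and de novo motif discovery are upstream of
  this package; it consumes called peaks.
* The weighted-GSEA FDR machinery across gene-set collections (multi-set
  q-values, leading-edge extraction) is not implemented; single-set
  permutation p and NES are.
* Phenotype permutation for rank enrichment is out of scope (single
  ranked list).
* Cox modelling is out of scope; survival comparison is two-group
  log-rank only.
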