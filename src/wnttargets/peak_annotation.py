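"""Peak classification, TSS-distance profiling, peak-gene linking and
permutation nulls by genomic shuffling.

A peak is assigned to exactly one genomic feature by the position of its
*center* point, with precedence promoter > 5'UTR > exon > intron > 3'UTR >
downstream; a center outside all gene-associated windows is intergenic.
The promoter is the ``promoter_bp`` (default 2 kb) window upstream of the
TSS and the downstream region the symmetric window past the TTS, both
strand-aware. Null distributions come from re-placing length-matched peaks
uniformly on their own chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneModel, GenomeIndex, Peak

__all__ = [
    "AnnotationConfig",
    "FeatureClassification",
    "TssDistanceProfile",
    "PermutationEnrichment",
    "CATEGORIES",
    "GenomeAnnotation",
    "classify_peak",
    "feature_distribution",
    "tss_distance_profile",
    "link_peaks_to_genes",
    "shuffle_peaks",
    "permutation_enrichment",
]

logger = logging.getLogger(__name__)

#: feature categories in precedence order; intergenic is the fallback.
CATEGORIES = ("promoter", "utr5", "exon", "intron", "utr3", "downstream", "intergenic")

_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class AnnotationConfig:
    """Windows and permutation settings for peak annotation."""

    promoter_bp: int = 2000
    downstream_bp: int = 2000
    link_window_bp: int = 20000
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.promoter_bp, self.downstream_bp, self.link_window_bp) <= 0:
            raise ValueError("all windows must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class FeatureClassification:
    peak: Peak
    category: str
    gene: str | None


@dataclass(frozen=True)
class TssDistanceProfile:
    """Signed peak-center-to-nearest-TSS distances with matched null.

    Distances are negative upstream of the TSS (relative to gene strand).
    ``null_counts`` is the per-bin mean over permutations, or None when no
    null was requested.
    """

    distances: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    null_counts: np.ndarray | None = None


@dataclass(frozen=True)
class PermutationEnrichment:
    category: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_exceeding: int
    n_permutations: int

    @property
    def p_label(self) -> str:
        """Report "< 1/(B+1)" when no permutation reached the observed value."""
        if self.n_exceeding == 0:
            return f"< {1.0 / (self.n_permutations + 1):g}"
        return f"{self.p_value:g}"


class GenomeAnnotation:
    """Per-chromosome feature interval trees and sorted TSS arrays.

    Built once from a transcript list and reused across classifications,
    distance profiles and permutation rounds.
    """

    def __init__(self, genes: Sequence[GeneModel], config: AnnotationConfig):
        self.config = config
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        self._tss: dict[str, np.ndarray] = {}
        self._tss_strand: dict[str, np.ndarray] = {}
        self._tss_symbol: dict[str, list[str]] = {}
        self._tss_txstart: dict[str, np.ndarray] = {}
        self._build()

    def _add(self, chrom: str, start: int, end: int, category: str, symbol: str) -> None:
        if end > start:
            self._trees.setdefault(chrom, IntervalTree()).addi(
                start, end, (_RANK[category], symbol)
            )

    def _build(self) -> None:
        for g in self.genes:
            if g.strand == "+":
                self._add(g.chrom, g.tx_start - self.config.promoter_bp, g.tx_start,
                          "promoter", g.symbol)
                self._add(g.chrom, g.tx_end, g.tx_end + self.config.downstream_bp,
                          "downstream", g.symbol)
            else:
                self._add(g.chrom, g.tx_end, g.tx_end + self.config.promoter_bp,
                          "promoter", g.symbol)
                self._add(g.chrom, g.tx_start - self.config.downstream_bp, g.tx_start,
                          "downstream", g.symbol)
            for es, ee in zip(g.exon_starts, g.exon_ends):
                if not g.is_coding:
                    self._add(g.chrom, es, ee, "exon", g.symbol)
                    continue
                # exonic sequence outside the CDS is UTR, strand-aware
                left = (max(es, g.tx_start), min(ee, g.cds_start))
                right = (max(es, g.cds_end), min(ee, g.tx_end))
                cds = (max(es, g.cds_start), min(ee, g.cds_end))
                left_cat = "utr5" if g.strand == "+" else "utr3"
                right_cat = "utr3" if g.strand == "+" else "utr5"
                self._add(g.chrom, left[0], left[1], left_cat, g.symbol)
                self._add(g.chrom, cds[0], cds[1], "exon", g.symbol)
                self._add(g.chrom, right[0], right[1], right_cat, g.symbol)
            for i in range(len(g.exon_starts) - 1):
                self._add(g.chrom, g.exon_ends[i], g.exon_starts[i + 1],
                          "intron", g.symbol)

        # deterministic nearest-TSS tie-break: (chrom, txStart, symbol) order
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tx_start, g.symbol))
            order = np.argsort([g.tss for g in gs], kind="stable")
            self._tss[chrom] = np.array([gs[i].tss for i in order])
            self._tss_strand[chrom] = np.array(
                [1 if gs[i].strand == "+" else -1 for i in order]
            )
            self._tss_symbol[chrom] = [gs[i].symbol for i in order]
            self._tss_txstart[chrom] = np.array([gs[i].tx_start for i in order])

    @property
    def chromosomes(self) -> set[str]:
        return set(self._tss)

    def classify_point(self, chrom: str, pos: int) -> tuple[str, str | None]:
        tree = self._trees.get(chrom)
        if tree is None:
            return "intergenic", None
        hits = tree[pos]
        if not hits:
            return "intergenic", None
        rank, symbol = min(h.data for h in hits)
        return CATEGORIES[rank], symbol

    def nearest_tss(self, chrom: str, pos: int) -> tuple[int, str, int] | None:
        """Signed distance to the nearest TSS, tie broken toward the gene
        earliest in (chrom, txStart, symbol) order; None if no gene on chrom."""
        tss = self._tss.get(chrom)
        if tss is None or len(tss) == 0:
            return None
        i = int(np.searchsorted(tss, pos))
        candidates = [j for j in (i - 1, i) if 0 <= j < len(tss)]
        best = min(abs(pos - int(tss[j])) for j in candidates)
        # expand candidate indices to the full runs of their TSS positions so
        # equal-position transcripts compete under the (txStart, symbol) rule
        tied: list[int] = []
        for v in {int(tss[j]) for j in candidates if abs(pos - int(tss[j])) == best}:
            lo = int(np.searchsorted(tss, v, side="left"))
            hi = int(np.searchsorted(tss, v, side="right"))
            tied.extend(range(lo, hi))
        j = min(
            tied,
            key=lambda j: (self._tss_txstart[chrom][j], self._tss_symbol[chrom][j]),
        )
        signed = (pos - tss[j]) * int(self._tss_strand[chrom][j])
        return int(signed), self._tss_symbol[chrom][j], int(tss[j])


def classify_peak(
    peak: Peak, annotation: GenomeAnnotation, config: AnnotationConfig | None = None
) -> FeatureClassification:
    """Assign one feature category to a peak by its center position."""
    if peak.chrom not in annotation.chromosomes:
        logger.warning("peak chromosome %s has no annotation; intergenic", peak.chrom)
        return FeatureClassification(peak, "intergenic", None)
    category, gene = annotation.classify_point(peak.chrom, peak.center)
    return FeatureClassification(peak, category, gene)


def feature_distribution(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    config: AnnotationConfig | None = None,
) -> dict[str, float]:
    """Fraction of peaks per category; fractions sum to 1."""
    if not peaks:
        raise ValueError("feature_distribution requires at least one peak")
    counts = dict.fromkeys(CATEGORIES, 0)
    for p in peaks:
        counts[classify_peak(p, annotation).category] += 1
    n = len(peaks)
    return {c: counts[c] / n for c in CATEGORIES}


def tss_distance_profile(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    bin_edges: np.ndarray | None = None,
    genome: GenomeIndex | None = None,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> TssDistanceProfile:
    """Signed distances from peak centers to their nearest TSS.

    Peaks on chromosomes without genes are skipped with a warning. With
    ``n_permutations > 0`` (requires ``genome`` and ``rng``) a matched null
    histogram is computed from shuffled peak sets.
    """
    if bin_edges is None:
        bin_edges = np.arange(-10000, 10001, 500)

    def _distances(ps: Sequence[Peak]) -> np.ndarray:
        out = []
        for p in ps:
            hit = annotation.nearest_tss(p.chrom, p.center)
            if hit is None:
                logger.warning("no gene on %s; peak skipped", p.chrom)
                continue
            out.append(hit[0])
        return np.asarray(out, dtype=float)

    distances = _distances(peaks)
    counts, _ = np.histogram(distances, bins=bin_edges)
    null_counts = None
    if n_permutations > 0:
        if genome is None or rng is None:
            raise ValueError("null histogram requires genome and rng")
        acc = np.zeros(len(bin_edges) - 1, dtype=float)
        for _ in range(n_permutations):
            shuffled = shuffle_peaks(peaks, genome, rng)
            acc += np.histogram(_distances(shuffled), bins=bin_edges)[0]
        null_counts = acc / n_permutations
    return TssDistanceProfile(distances, np.asarray(bin_edges, dtype=float),
                              counts, null_counts)


def link_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | GenomeAnnotation,
    config: AnnotationConfig | None = None,
) -> dict[str, list[Peak]]:
    """Genes with >= 1 peak center within ``link_window_bp`` of their TSS.

    Returns symbol -> supporting peaks; each gene appears once even when
    several transcripts or peaks support it.
    """
    config = config or (genes.config if isinstance(genes, GenomeAnnotation)
                        else AnnotationConfig())
    gene_list = genes.genes if isinstance(genes, GenomeAnnotation) else genes
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    centers = {
        c: np.sort(np.array([p.center for p in ps])) for c, ps in by_chrom.items()
    }
    bound: dict[str, list[Peak]] = {}
    w = config.link_window_bp
    for g in gene_list:
        ps = by_chrom.get(g.chrom)
        if not ps:
            continue
        cs = centers[g.chrom]
        lo = np.searchsorted(cs, g.tss - w, side="left")
        hi = np.searchsorted(cs, g.tss + w, side="right")
        if hi <= lo:
            continue
        support = [p for p in ps if abs(p.center - g.tss) <= w]
        if support:
            seen = bound.setdefault(g.symbol, [])
            for p in support:
                if p not in seen:
                    seen.append(p)
    return bound


def shuffle_peaks(
    peaks: Sequence[Peak], genome: GenomeIndex, rng: np.random.Generator
) -> list[Peak]:
    """Re-place each peak uniformly on its own chromosome, keeping length.

    The multiset of (chromosome, length) pairs is preserved exactly.
    """
    out = []
    for p in peaks:
        if p.chrom not in genome.lengths:
            raise ValueError(f"chromosome {p.chrom!r} absent from genome index")
        chrom_len = genome.lengths[p.chrom]
        if p.length > chrom_len:
            raise ValueError(
                f"peak length {p.length} exceeds {p.chrom} length {chrom_len}"
            )
        start = int(rng.integers(0, chrom_len - p.length + 1))
        out.append(Peak(p.chrom, start, start + p.length, p.name, p.score))
    return out


def permutation_enrichment(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    genome: GenomeIndex,
    category: str,
    config: AnnotationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationEnrichment:
    """Empirical enrichment of one feature category against the shuffle null.

    p = (1 + #{permutations with fraction >= observed}) / (B + 1), the
    add-one permutation p-value; a result with ``n_exceeding == 0`` is
    reported as "< 1/(B+1)".
    """
    config = config or annotation.config
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    observed = feature_distribution(peaks, annotation)[category]
    null = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        shuffled = shuffle_peaks(peaks, genome, rng)
        null[b] = feature_distribution(shuffled, annotation)[category]
    n_exceeding = int(np.sum(null >= observed))
    p = (1 + n_exceeding) / (config.n_permutations + 1)
    return PermutationEnrichment(
        category=category,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        p_value=p,
        n_exceeding=n_exceeding,
        n_permutations=config.n_permutations,
    )
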