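import numpy as np
import pytest
from scipy import stats

from wnttargets.io_formats import GenomeIndex, Peak
from wnttargets.peak_annotation import (
    CATEGORIES,
    AnnotationConfig,
    GenomeAnnotation,
    classify_peak,
    feature_distribution,
    link_peaks_to_genes,
    permutation_enrichment,
    shuffle_peaks,
    tss_distance_profile,
)
from wnttargets.synthetic_data import SimulationConfig, simulate_dataset
from tests.conftest import make_gene


@pytest.fixture
def single_gene_annotation():
    # + strand gene at [10000, 15000): promoter [8000,10000), exon1 with
    # UTR5 [10000,10100), CDS to 14900, UTR3 [14900,15000), downstream
    # [15000,17000)
    gene = make_gene(symbol="G1", tx_start=10000, tx_end=15000)
    return GenomeAnnotation([gene], AnnotationConfig())


class TestClassifyPeak:
    @pytest.mark.parametrize(
        "center,expected",
        [
            (9000, "promoter"),       # 1 kb upstream of the TSS
            (10050, "utr5"),
            (10200, "exon"),
            (12000, "intron"),
            (14950, "utr3"),
            (16000, "downstream"),
            (50000, "intergenic"),
        ],
    )
    def test_feature_windows(self, single_gene_annotation, center, expected):
        peak = Peak("chr1", center - 50, center + 50)
        assert classify_peak(peak, single_gene_annotation).category == expected

    def test_precedence_exon_over_intron(self):
        # gene A's coding exon coincides with gene B's intron at the center
        a = make_gene(symbol="A", tx_start=10000, tx_end=15000)
        b = make_gene(
            symbol="B",
            tx_start=8000,
            tx_end=20000,
            exons=[(8000, 8200), (19000, 20000)],
            cds=(8100, 19500),
        )
        ann = GenomeAnnotation([a, b], AnnotationConfig())
        cls = classify_peak(Peak("chr1", 10150, 10250), ann)
        assert cls.category == "exon"
        assert cls.gene == "A"

    def test_promoter_beats_everything(self):
        # gene B's promoter overlaps gene A's intron
        a = make_gene(symbol="A", tx_start=10000, tx_end=15000)
        b = make_gene(symbol="B", tx_start=14000, tx_end=16000,
                      exons=[(14000, 16000)], cds=(14100, 15900))
        ann = GenomeAnnotation([a, b], AnnotationConfig())
        assert classify_peak(Peak("chr1", 12950, 13050), ann).category == "promoter"

    def test_chromosome_without_genes_is_intergenic(self, single_gene_annotation):
        cls = classify_peak(Peak("chrM", 0, 100), single_gene_annotation)
        assert cls.category == "intergenic" and cls.gene is None

    def test_minus_strand_promoter(self):
        gene = make_gene(symbol="M", strand="-", tx_start=10000, tx_end=15000)
        ann = GenomeAnnotation([gene], AnnotationConfig())
        assert classify_peak(Peak("chr1", 15950, 16050), ann).category == "promoter"
        assert classify_peak(Peak("chr1", 8950, 9050), ann).category == "downstream"


class TestFeatureDistribution:
    def test_fractions_sum_to_one(self, single_gene_annotation):
        peaks = [Peak("chr1", c, c + 100) for c in (8950, 10150, 11950, 49950)]
        fr = feature_distribution(peaks, single_gene_annotation)
        assert abs(sum(fr.values()) - 1.0) < 1e-12
        for cat in ("promoter", "exon", "intron", "intergenic"):
            assert fr[cat] == 0.25

    def test_all_intergenic(self, single_gene_annotation):
        fr = feature_distribution(
            [Peak("chr1", 40000, 40100)], single_gene_annotation
        )
        assert fr["intergenic"] == 1.0

    def test_empty_peaks_error(self, single_gene_annotation):
        with pytest.raises(ValueError):
            feature_distribution([], single_gene_annotation)

    def test_planted_promoter_rate_recovered(self):
        # 30% of peaks placed in promoters; the rest land uniformly, hitting
        # promoters at about the promoter genome fraction
        config = SimulationConfig(
            seed=11, n_targets=24, n_decoys=12, n_peaks=100,
            target_placement="promoter",
        )
        ds = simulate_dataset(config)
        ann = GenomeAnnotation(ds.genes, AnnotationConfig())
        fr = feature_distribution(ds.peaks, ann)
        plant = 30 / 100  # 24 targets + 6 one-channel decoys of 100 peaks
        promoter_bp = config.n_genes * 2000
        genome_bp = config.n_chromosomes * config.chromosome_length
        expected = plant + (1 - plant) * promoter_bp / genome_bp
        se = np.sqrt(expected * (1 - expected) / 100)
        assert abs(fr["promoter"] - expected) < 4 * se


class TestTssDistance:
    def test_center_at_tss_is_zero(self, single_gene_annotation):
        prof = tss_distance_profile([Peak("chr1", 9950, 10050)],
                                    single_gene_annotation)
        assert prof.distances.tolist() == [0.0]

    def test_upstream_of_plus_strand_is_negative(self, single_gene_annotation):
        prof = tss_distance_profile([Peak("chr1", 9450, 9550)],
                                    single_gene_annotation)
        assert prof.distances.tolist() == [-500.0]

    def test_upstream_of_minus_strand_is_negative(self):
        gene = make_gene(symbol="M", strand="-", tx_start=10000, tx_end=15000)
        ann = GenomeAnnotation([gene], AnnotationConfig())
        # 500 bp 5' of the minus-strand TSS lies at larger coordinates
        prof = tss_distance_profile([Peak("chr1", 15449, 15549)], ann)
        assert prof.distances.tolist() == [-500.0]

    def test_equidistant_tie_goes_to_earlier_gene(self):
        early = make_gene(symbol="A", tx_start=10000, tx_end=12000)
        late = make_gene(symbol="B", tx_start=14000, tx_end=16000)
        ann = GenomeAnnotation([early, late], AnnotationConfig())
        # center 12000: 2000 bp from both TSSs (10000 and 14000)
        hit = ann.nearest_tss("chr1", 12000)
        assert hit[1] == "A" and hit[0] == 2000

    def test_uniform_peaks_match_permutation_null(self, default_dataset):
        """On a uniformly placed peak set the observed TSS-distance
        histogram is statistically indistinguishable from the shuffle
        null (chi-square goodness of fit)."""
        rng = np.random.default_rng(5)
        genome = default_dataset.genome
        ann = GenomeAnnotation(default_dataset.genes, AnnotationConfig())
        template = [Peak("chr1", 0, 300)] * 1000 + [Peak("chr2", 0, 300)] * 1000
        peaks = shuffle_peaks(template, genome, rng)
        prof = tss_distance_profile(
            peaks, ann, genome=genome, n_permutations=30, rng=rng
        )
        observed = prof.counts.astype(float)
        expected = prof.null_counts * observed.sum() / prof.null_counts.sum()
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01


class TestLinking:
    def test_window_boundary(self):
        gene = make_gene(symbol="G1", tx_start=100000, tx_end=105000)
        config = AnnotationConfig()
        inside = Peak("chr1", 79951, 80051)    # center 80001, 19999 away
        outside = Peak("chr1", 79949, 79949 + 100)  # center 79999, 20001 away
        assert "G1" in link_peaks_to_genes([inside], [gene], config)
        assert link_peaks_to_genes([outside], [gene], config) == {}

    def test_exact_20kb_is_bound(self):
        gene = make_gene(symbol="G1", tx_start=100000, tx_end=105000)
        peak = Peak("chr1", 79950, 80050)  # center 80000, exactly 20000
        assert "G1" in link_peaks_to_genes([peak], [gene], AnnotationConfig())

    def test_gene_counted_once_with_two_peaks(self):
        gene = make_gene(symbol="G1", tx_start=100000, tx_end=105000)
        peaks = [Peak("chr1", 99000, 99300), Peak("chr1", 101000, 101300)]
        bound = link_peaks_to_genes(peaks, [gene], AnnotationConfig())
        assert set(bound) == {"G1"} and len(bound["G1"]) == 2

    def test_monotone_in_window(self, default_dataset):
        small = AnnotationConfig(link_window_bp=5000)
        large = AnnotationConfig(link_window_bp=20000)
        bound_small = link_peaks_to_genes(default_dataset.peaks,
                                          default_dataset.genes, small)
        bound_large = link_peaks_to_genes(default_dataset.peaks,
                                          default_dataset.genes, large)
        assert set(bound_small) <= set(bound_large)


class TestShuffle:
    def test_length_multiset_preserved_and_seeded(self, flat_genome, rng):
        peaks = [Peak("chr1", 0, 300), Peak("chr1", 5000, 5170),
                 Peak("chr2", 100, 1100)]
        out1 = shuffle_peaks(peaks, flat_genome, np.random.default_rng(9))
        out2 = shuffle_peaks(peaks, flat_genome, np.random.default_rng(9))
        assert out1 == out2
        assert sorted((p.chrom, p.length) for p in out1) == sorted(
            (p.chrom, p.length) for p in peaks
        )

    def test_full_length_peak_forced_to_zero(self):
        genome = GenomeIndex({"chr1": 500})
        (out,) = shuffle_peaks([Peak("chr1", 0, 500)], genome,
                               np.random.default_rng(0))
        assert out.start == 0 and out.end == 500

    def test_oversized_peak_rejected(self):
        genome = GenomeIndex({"chr1": 100})
        with pytest.raises(ValueError, match="exceeds"):
            shuffle_peaks([Peak("chr1", 0, 500)], genome,
                          np.random.default_rng(0))

    def test_uniform_start_mean(self, rng):
        genome = GenomeIndex({"chr1": 10000})
        peak = Peak("chr1", 0, 400)
        starts = [shuffle_peaks([peak], genome, rng)[0].start for _ in range(100)]
        expect = (10000 - 400) / 2
        se = (10000 - 400) / np.sqrt(12 * 100)
        assert abs(np.mean(starts) - expect) < 3 * se


class TestPermutationEnrichment:
    def test_observed_below_all_permutations_gives_p_one(self):
        # all peaks in the promoter, so the intergenic fraction is 0 and
        # every permutation matches or beats it
        gene = make_gene(symbol="G1", tx_start=50000, tx_end=55000)
        ann = GenomeAnnotation([gene], AnnotationConfig(n_permutations=30))
        genome = GenomeIndex({"chr1": 100000})
        peaks = [Peak("chr1", 48500, 48700)] * 5
        res = permutation_enrichment(peaks, ann, genome, "intergenic",
                                     rng=np.random.default_rng(1))
        assert res.p_value == 1.0

    def test_observed_above_all_permutations(self):
        gene = make_gene(symbol="G1", tx_start=50000, tx_end=55000)
        ann = GenomeAnnotation([gene], AnnotationConfig(n_permutations=999))
        genome = GenomeIndex({"chr1": 1_000_000})
        peaks = [Peak("chr1", 48100 + 90 * i, 48300 + 90 * i) for i in range(20)]
        res = permutation_enrichment(peaks, ann, genome, "promoter",
                                     rng=np.random.default_rng(1))
        assert res.observed == 1.0
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.p_label == "< 0.001"

    def test_null_mean_matches_genome_fraction(self, default_dataset):
        """Shuffled peaks hit promoters at the promoter genome fraction."""
        config = AnnotationConfig(n_permutations=200)
        ann = GenomeAnnotation(default_dataset.genes, config)
        res = permutation_enrichment(
            default_dataset.peaks, ann, default_dataset.genome, "promoter",
            config, rng=np.random.default_rng(3),
        )
        analytic = (200 * 2000) / (2 * 2_000_000)
        assert abs(res.null_mean - analytic) < 3 * res.null_sd
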