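"""Seeded synthetic datasets with the statistical structure the pipeline
assumes: a toy genome with tiled gene models, ChIP peaks enriched near the
TSSs of a planted target set (with motif copies embedded in their
footprints), a two-knockdown expression table with planted down-regulation,
and an expression/survival cohort with a group hazard ratio.

Planted effects are sized to clear the target-calling thresholds: the
default log10 knockdown effect is -0.5 (|effect| > 0.2) with noise sd 0.1,
and planted p-values are drawn below 1e-3 (< 0.01). Decoys come in two
flavours — down-regulated in a single knockdown channel but peak-bound, and
down-regulated in both channels but deliberately unbound (background peaks
are rejection-sampled away from their TSS windows so the planted truth
stays true).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionRecord,
    GeneModel,
    GenomeIndex,
    Peak,
    SurvivalRecord,
    write_bed,
    write_clinical,
    write_expression_table,
    write_fasta,
    write_gene_models,
    write_gene_set,
    write_tsv,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_genome",
    "simulate_peaks",
    "simulate_expression",
    "simulate_cohort",
    "simulate_dataset",
    "write_dataset",
]

_GENE_SPAN = 5000
_EXONS_REL = ((0, 300), (1500, 2000), (4500, 5000))
_CDS_REL = (150, 4850)


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults define the study conditions every test and example uses."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 2_000_000
    n_genes: int = 200
    n_targets: int = 40
    n_decoys: int = 40
    n_peaks: int = 300
    peak_length_mean: float = 320.6
    peak_length_sd: float = 60.0
    peak_length_min: int = 50
    #: sd (bp) of the Normal TSS offset for target peaks, truncated so the
    #: center stays within the +/-20 kb linking window
    tss_offset_sd: float = 5000.0
    #: "tss_normal" draws target-peak centers Normal(TSS, sd); "promoter"
    #: places them uniformly inside the 2-kb promoter window
    target_placement: str = "tss_normal"
    expression_effect: float = -0.5
    expression_noise_sd: float = 0.1
    planted_p_max: float = 1e-3
    motif: str = "TGAYTCA"
    motif_plant_rate: float = 1.0
    cohort_size: int = 232
    cohort_effect: float = 1.0
    baseline_hazard: float = 0.1
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.04

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_chromosomes, self.n_peaks) < 1:
            raise ValueError("counts must be positive")
        if self.n_targets + self.n_decoys > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not (0.0 <= self.motif_plant_rate <= 1.0):
            raise ValueError("motif_plant_rate must be in [0, 1]")
        if self.target_placement not in ("tss_normal", "promoter"):
            raise ValueError("target_placement must be 'tss_normal' or 'promoter'")
        if self.chromosome_length < self.peak_length_min:
            raise ValueError("chromosome shorter than the minimum peak length")


@dataclass
class GroundTruth:
    """What was planted, for recovery checks."""

    target_symbols: tuple[str, ...] = ()
    decoy_one_channel: tuple[str, ...] = ()
    decoy_unbound: tuple[str, ...] = ()
    motif_positions: tuple[tuple[str, int], ...] = ()
    cohort_group: dict[str, str] = field(default_factory=dict)
    cohort_hazard: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: dict[str, str]
    genome: GenomeIndex
    genes: list[GeneModel]
    truth: GroundTruth
    peaks: list[Peak]
    expression: list[ExpressionRecord]
    matrix: pd.DataFrame
    clinical: list[SurvivalRecord]


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Uniform-ACGT chromosomes with evenly tiled, strand-alternating genes.

    Gene slots must leave room for the transcript plus promoter/downstream
    windows; infeasible tilings are an error. Target and decoy symbols are
    drawn without replacement.
    """
    rng = rng or _stage_rng(config, 0)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    gene_id = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        codes = rng.integers(0, 4, size=config.chromosome_length, dtype=np.uint8)
        sequences[chrom] = bases[codes].tobytes().decode("ascii")
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = config.chromosome_length // n
        if slot < _GENE_SPAN + 2 * 2500:
            raise ValueError(
                f"gene slot {slot} bp cannot fit a {_GENE_SPAN} bp transcript "
                "plus flanking windows"
            )
        for k in range(n):
            tx_start = k * slot + (slot - _GENE_SPAN) // 2
            tx_end = tx_start + _GENE_SPAN
            strand = "+" if gene_id % 2 == 0 else "-"
            genes.append(
                GeneModel(
                    symbol=f"G{gene_id:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=tx_start + _CDS_REL[0],
                    cds_end=tx_start + _CDS_REL[1],
                    exon_starts=tuple(tx_start + s for s, _ in _EXONS_REL),
                    exon_ends=tuple(tx_start + e for _, e in _EXONS_REL),
                )
            )
            gene_id += 1
    # Unbound decoys are assigned first, never two of them flanking a common
    # neighbour (index difference 2): a gene sandwiched between two decoy TSSs
    # could not receive a peak that links its own TSS while staying outside
    # both decoys' linking windows.
    n_unbound = config.n_decoys - config.n_decoys // 2
    order = rng.permutation(len(genes))
    unbound: list[int] = []
    rest: list[int] = []
    for i in order:
        i = int(i)
        if len(unbound) < n_unbound and all(abs(i - j) != 2 for j in unbound):
            unbound.append(i)
        else:
            rest.append(i)
    if len(unbound) < n_unbound:
        raise ValueError("cannot place unbound decoys with the spacing rule")
    targets = rest[: config.n_targets]
    one_channel = rest[config.n_targets : config.n_targets + config.n_decoys // 2]
    truth = GroundTruth(
        target_symbols=tuple(sorted(genes[i].symbol for i in targets)),
        decoy_one_channel=tuple(sorted(genes[i].symbol for i in one_channel)),
        decoy_unbound=tuple(sorted(genes[i].symbol for i in unbound)),
    )
    return sequences, genes, truth


def _draw_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    while True:
        ln = int(round(rng.normal(config.peak_length_mean, config.peak_length_sd)))
        if ln >= config.peak_length_min:
            return ln


def simulate_peaks(
    config: SimulationConfig,
    sequences: dict[str, str],
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[Peak], dict[str, str], GroundTruth]:
    """One TSS-proximal peak per bound planted gene plus uniform background.

    Bound planted genes are the targets and the one-channel decoys. Motif
    copies are written into the chromosome sequence inside each planted
    peak footprint at ``motif_plant_rate`` (degenerate positions resolved
    randomly); background peak centers are rejection-sampled to stay more
    than the linking window away from every unbound-decoy TSS. Returns the
    peaks, the (possibly edited) sequences and the updated truth.
    """
    from .motif_enrichment import IUPAC

    rng = rng or _stage_rng(config, 1)
    by_symbol = {g.symbol: g for g in genes}
    arrays = {c: np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
              for c, s in sequences.items()}
    peaks: list[Peak] = []
    motif_positions: list[tuple[str, int]] = []
    link_w = 20000

    avoid = {
        c: np.array(
            sorted(by_symbol[s].tss for s in truth.decoy_unbound
                   if by_symbol[s].chrom == c)
        )
        for c in sequences
    }

    def _clear_of_decoys(chrom: str, center: int) -> bool:
        tss = avoid[chrom]
        if len(tss) == 0:
            return True
        i = int(np.searchsorted(tss, center))
        near = min(
            abs(center - int(tss[j])) for j in (i - 1, i) if 0 <= j < len(tss)
        )
        return near > link_w

    bound_planted = list(truth.target_symbols) + list(truth.decoy_one_channel)
    for symbol in bound_planted:
        g = by_symbol[symbol]
        chrom_len = len(arrays[g.chrom])
        length = _draw_length(config, rng)
        for _ in range(1000):
            if config.target_placement == "promoter":
                if g.strand == "+":
                    center = int(rng.integers(g.tx_start - 2000, g.tx_start))
                else:
                    center = int(rng.integers(g.tx_end, g.tx_end + 2000))
            else:
                while True:
                    offset = rng.normal(0.0, config.tss_offset_sd)
                    if abs(offset) <= link_w - length:  # center stays linkable
                        break
                center = int(g.tss + round(offset))
            if _clear_of_decoys(g.chrom, center):
                break
        start = max(0, min(center - length // 2, chrom_len - length))
        peak = Peak(g.chrom, start, start + length, name=f"pk_{symbol}")
        peaks.append(peak)
        if rng.random() < config.motif_plant_rate:
            pos = int(rng.integers(start, start + length - len(config.motif) + 1))
            concrete = "".join(
                rng.choice(sorted(IUPAC[c])) for c in config.motif.upper()
            )
            arrays[g.chrom][pos : pos + len(concrete)] = np.frombuffer(
                concrete.encode("ascii"), dtype=np.uint8
            )
            motif_positions.append((g.chrom, pos))

    n_background = config.n_peaks - len(peaks)
    for b in range(max(0, n_background)):
        chrom = f"chr{1 + int(rng.integers(0, config.n_chromosomes))}"
        chrom_len = len(arrays[chrom])
        length = _draw_length(config, rng)
        for _ in range(1000):
            start = int(rng.integers(0, chrom_len - length + 1))
            if _clear_of_decoys(chrom, start + length // 2):
                break
        peaks.append(Peak(chrom, start, start + length, name=f"bg_{b:04d}"))

    sequences_out = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    truth_out = GroundTruth(
        target_symbols=truth.target_symbols,
        decoy_one_channel=truth.decoy_one_channel,
        decoy_unbound=truth.decoy_unbound,
        motif_positions=tuple(motif_positions),
        cohort_group=truth.cohort_group,
        cohort_hazard=truth.cohort_hazard,
    )
    return peaks, sequences_out, truth_out


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[ExpressionRecord]:
    """Two-channel knockdown table with planted down-regulation.

    Targets and unbound decoys are shifted in both channels; one-channel
    decoys in a random single channel; all other genes are null.
    """
    rng = rng or _stage_rng(config, 2)
    eff, sd = config.expression_effect, config.expression_noise_sd
    both = set(truth.target_symbols) | set(truth.decoy_unbound)
    one = set(truth.decoy_one_channel)
    records = []
    for g in genes:
        if g.symbol in both:
            lrs = rng.normal(eff, sd, 2)
            ps = rng.uniform(0.0, config.planted_p_max, 2)
        elif g.symbol in one:
            ch = int(rng.integers(0, 2))
            lrs = rng.normal(0.0, sd, 2)
            ps = rng.uniform(0.0, 1.0, 2)
            lrs[ch] = rng.normal(eff, sd)
            ps[ch] = rng.uniform(0.0, config.planted_p_max)
        else:
            lrs = rng.normal(0.0, sd, 2)
            ps = rng.uniform(0.0, 1.0, 2)
        records.append(
            ExpressionRecord(g.symbol, float(lrs[0]), float(ps[0]),
                             float(lrs[1]), float(ps[1]))
        )
    return records


def simulate_cohort(
    config: SimulationConfig,
    signature: Sequence[str],
    all_genes: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[SurvivalRecord], GroundTruth]:
    """Expression cohort with a signature shift and a planted hazard ratio.

    Half of the samples carry the signature genes shifted by
    ``cohort_effect``; their event times are exponential with hazard
    ``baseline_hazard * hazard_ratio`` (others at baseline); censoring
    times are independent exponentials at ``censoring_rate``.
    """
    if not signature:
        raise ValueError("cohort simulation requires a non-empty signature")
    rng = rng or _stage_rng(config, 3)
    sig = sorted(set(signature))
    rows = sorted(set(all_genes) | set(sig)) if all_genes is not None else sig + [
        f"N{i:04d}" for i in range(3 * len(sig))
    ]
    n = config.cohort_size
    samples = [f"S{i:04d}" for i in range(n)]
    values = rng.normal(0.0, 1.0, size=(len(rows), n))
    shifted = rng.choice(n, size=n // 2, replace=False)
    sig_idx = [i for i, r in enumerate(rows) if r in set(sig)]
    for s in shifted:
        values[sig_idx, s] += config.cohort_effect
    matrix = pd.DataFrame(values, index=rows, columns=samples)

    hazards = np.full(n, config.baseline_hazard)
    hazards[shifted] *= config.hazard_ratio
    event_t = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        censor_t = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    obs_t = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    shifted_set = set(int(s) for s in shifted)
    clinical = [
        SurvivalRecord(samples[i], float(obs_t[i]), int(event[i]))
        for i in range(n)
    ]
    truth = GroundTruth(
        cohort_group={samples[i]: ("shifted" if i in shifted_set else "baseline")
                      for i in range(n)},
        cohort_hazard={samples[i]: float(hazards[i]) for i in range(n)},
    )
    return matrix, clinical, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all four stages with seeds derived from ``config.seed``.

    The cohort is built around the *planted* target signature so that the
    dataset is self-contained; pipeline-called signatures can be rescored
    against the same matrix.
    """
    sequences, genes, truth = simulate_genome(config)
    peaks, sequences, truth = simulate_peaks(config, sequences, genes, truth)
    expression = simulate_expression(config, genes, truth)
    matrix, clinical, cohort_truth = simulate_cohort(
        config, list(truth.target_symbols), [g.symbol for g in genes]
    )
    truth.cohort_group = cohort_truth.cohort_group
    truth.cohort_hazard = cohort_truth.cohort_hazard
    return SimulatedDataset(
        config=config,
        sequences=sequences,
        genome=GenomeIndex.from_sequences(sequences),
        genes=genes,
        truth=truth,
        peaks=peaks,
        expression=expression,
        matrix=matrix,
        clinical=clinical,
    )


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "genes": out / "genes.refflat",
        "peaks": out / "peaks.bed",
        "expression": out / "expr.tsv",
        "matrix": out / "matrix.tsv",
        "clinical": out / "clinical.tsv",
        "targets": out / "truth_targets.txt",
        "truth": out / "truth_genes.tsv",
    }
    write_fasta(ds.sequences, paths["genome"])
    write_gene_models(ds.genes, paths["genes"])
    write_bed(ds.peaks, paths["peaks"])
    write_expression_table(ds.expression, paths["expression"])
    ds.matrix.to_csv(paths["matrix"], sep="\t", index_label="gene")
    write_clinical(ds.clinical, paths["clinical"])
    write_gene_set(ds.truth.target_symbols, paths["targets"])
    rows = (
        [(s, "target") for s in ds.truth.target_symbols]
        + [(s, "decoy_one_channel") for s in ds.truth.decoy_one_channel]
        + [(s, "decoy_unbound") for s in ds.truth.decoy_unbound]
    )
    write_tsv(sorted(rows), paths["truth"], header=["symbol", "role"])
    return paths
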