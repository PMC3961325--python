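"""Readers, writers and validated domain types for every external format.

All coordinates are 0-based half-open (BED convention) throughout the
package; any 1-based interchange would happen only at report writing.
Every reader rejects records that violate the type invariants instead of
silently clamping, and names the offending line in the error message.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FormatError",
    "Peak",
    "GeneModel",
    "ExpressionRecord",
    "SurvivalRecord",
    "GenomeIndex",
    "read_bed",
    "read_gene_models",
    "read_expression_table",
    "read_gene_set",
    "read_clinical",
    "write_bed",
    "write_gene_models",
    "write_expression_table",
    "write_gene_set",
    "write_clinical",
    "write_tsv",
    "write_fasta",
]

#: significant digits used by every writer; round-trips are lossless at this
#: precision.
FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Raised for malformed or invariant-violating input records."""


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


@dataclass(frozen=True)
class Peak:
    """A genomic interval from a BED record (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"peak start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise FormatError(
                f"peak end must exceed start, got [{self.start}, {self.end})"
            )
        if self.score is not None and self.score < 0:
            raise FormatError(f"peak score must be non-negative, got {self.score}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, rounded down to an integer genomic position."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware transcript model (refFlat/genePred-like).

    TSS is the first transcribed base: ``tx_start`` on ``+``, ``tx_end - 1``
    on ``-`` (the last covered base under half-open coordinates). TTS is the
    symmetric opposite end.
    """

    symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise FormatError(
                f"{self.symbol}: txStart {self.tx_start} must be < txEnd {self.tx_end}"
            )
        if len(self.exon_starts) != len(self.exon_ends):
            raise FormatError(f"{self.symbol}: exon start/end count mismatch")
        if not self.exon_starts:
            raise FormatError(f"{self.symbol}: at least one exon required")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise FormatError(
                    f"{self.symbol}: exon [{s},{e}) outside transcript span"
                )
            if prev_end is not None and s < prev_end:
                raise FormatError(f"{self.symbol}: exons overlap or are unsorted")
            prev_end = e
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise FormatError(f"{self.symbol}: CDS outside transcript span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene log10 knockdown/control ratio and p-value for two siRNAs."""

    symbol: str
    lr1: float
    p1: float
    lr2: float
    p2: float

    def __post_init__(self) -> None:
        for tag, p in (("p1", self.p1), ("p2", self.p2)):
            if not (0.0 <= p <= 1.0):
                raise FormatError(f"{self.symbol}: {tag}={p} outside [0, 1]")
        for tag, lr in (("lr1", self.lr1), ("lr2", self.lr2)):
            if not math.isfinite(lr):
                raise FormatError(f"{self.symbol}: {tag} must be finite")


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-sample follow-up time, event indicator and signature score."""

    sample: str
    time: float
    event: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise FormatError(f"{self.sample}: negative follow-up time {self.time}")
        if self.event not in (0, 1):
            raise FormatError(f"{self.sample}: event must be 0 or 1, got {self.event}")


class GenomeIndex:
    """Chromosome name -> length map with an optional sequence accessor.

    Construct from an in-memory dict of sequences (:meth:`from_sequences`),
    a FASTA file via pyfaidx (:meth:`from_fasta`), or a samtools ``.fai``
    index when only lengths are needed (:meth:`from_fai`).
    """

    def __init__(
        self,
        lengths: Mapping[str, int],
        sequences: Mapping[str, str] | None = None,
    ) -> None:
        for chrom, n in lengths.items():
            if n <= 0:
                raise FormatError(f"chromosome {chrom} has non-positive length {n}")
        self.lengths: dict[str, int] = dict(lengths)
        self._sequences = sequences

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeIndex":
        return cls({c: len(s) for c, s in sequences.items()}, sequences)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: len(fa[name]) for name in fa.keys()}, fa)

    @classmethod
    def from_fai(cls, path: str | Path) -> "GenomeIndex":
        lengths: dict[str, int] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: malformed .fai line")
            lengths[parts[0]] = int(parts[1])
        return cls(lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def sequence(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of ``chrom[start:end)``; bounds-checked."""
        if self._sequences is None:
            raise FormatError("GenomeIndex carries lengths only, no sequence")
        if chrom not in self.lengths:
            raise FormatError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or end <= start:
            raise FormatError(
                f"{chrom}:[{start},{end}) outside chromosome of length "
                f"{self.lengths[chrom]}"
            )
        return str(self._sequences[chrom][start:end]).upper()

    def validate_peak(self, peak: Peak) -> None:
        if peak.chrom not in self.lengths:
            raise FormatError(f"unknown chromosome {peak.chrom!r}")
        if peak.end > self.lengths[peak.chrom]:
            raise FormatError(
                f"peak [{peak.start},{peak.end}) exceeds {peak.chrom} length "
                f"{self.lengths[peak.chrom]}"
            )


# ---------------------------------------------------------------------------
# readers


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line


def read_bed(path: str | Path, genome: GenomeIndex | None = None) -> list[Peak]:
    """Read BED3/BED4(+score) peaks, in file order.

    With a ``genome`` supplied, every peak must fit its chromosome.
    """
    peaks: list[Peak] = []
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed coordinate: {exc}") from exc
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        score = None
        if len(cols) > 4 and cols[4] not in (".", ""):
            try:
                score = float(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed score") from exc
        try:
            peak = Peak(cols[0], start, end, name, score)
            if genome is not None:
                genome.validate_peak(peak)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        peaks.append(peak)
    return peaks


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like 10-column annotation.

    Columns: symbol, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts, exonEnds (comma-separated block lists, trailing
    comma tolerated). Duplicate symbols are retained as distinct transcripts.
    """
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 10:
            raise FormatError(f"{path}:{lineno}: expected 10 columns, got {len(cols)}")
        try:
            exon_count = int(cols[7])
            starts = tuple(int(x) for x in cols[8].rstrip(",").split(","))
            ends = tuple(int(x) for x in cols[9].rstrip(",").split(","))
            if len(starts) != exon_count or len(ends) != exon_count:
                raise FormatError(
                    f"exonCount {exon_count} does not match block lists "
                    f"({len(starts)} starts, {len(ends)} ends)"
                )
            gene = GeneModel(
                symbol=cols[0].strip(),
                chrom=cols[1],
                strand=cols[2],
                tx_start=int(cols[3]),
                tx_end=int(cols[4]),
                cds_start=int(cols[5]),
                cds_end=int(cols[6]),
                exon_starts=starts,
                exon_ends=ends,
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed field: {exc}") from exc
        genes.append(gene)
    return genes


def _read_headered_tsv(
    path: str | Path, required: Sequence[str]
) -> Iterable[tuple[int, dict[str, str]]]:
    lines = list(_data_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty table, expected header {list(required)}")
    header_no, header_line = lines[0]
    header = header_line.split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(
            f"{path}:{header_no}: missing column(s) {missing}; "
            f"expected header containing {list(required)}"
        )
    idx = {c: header.index(c) for c in header}
    for lineno, line in lines[1:]:
        cols = line.split("\t")
        if len(cols) < len(header):
            raise FormatError(f"{path}:{lineno}: short row")
        yield lineno, {c: cols[i] for c, i in idx.items()}


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read the two-knockdown expression table (symbol, lr1, p1, lr2, p2)."""
    records = []
    for lineno, row in _read_headered_tsv(path, ["symbol", "lr1", "p1", "lr2", "p2"]):
        try:
            records.append(
                ExpressionRecord(
                    symbol=row["symbol"].strip(),
                    lr1=float(row["lr1"]),
                    p1=float(row["p1"]),
                    lr2=float(row["lr2"]),
                    p2=float(row["p2"]),
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed number: {exc}") from exc
    return records


def read_gene_set(path: str | Path) -> set[str]:
    """One symbol per line; ``#`` comments; symbols matched case-sensitively
    after trimming whitespace."""
    symbols: set[str] = set()
    for _, line in _data_lines(path):
        symbols.add(line.strip())
    return symbols


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read the clinical table (sample, time, event[, score])."""
    records = []
    for lineno, row in _read_headered_tsv(path, ["sample", "time", "event"]):
        try:
            records.append(
                SurvivalRecord(
                    sample=row["sample"].strip(),
                    time=float(row["time"]),
                    event=int(row["event"]),
                    score=float(row["score"]) if "score" in row else None,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed number: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# writers


def write_tsv(
    rows: Iterable[Sequence], path: str | Path, header: Sequence[str] | None = None
) -> None:
    """Write rows as TSV; floats at 10 significant digits."""
    with open(path, "w") as fh:
        if header is not None:
            fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    _fmt(x) if isinstance(x, float) else str(x) for x in row
                )
                + "\n"
            )


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    rows = []
    for p in peaks:
        row = [p.chrom, p.start, p.end]
        if p.name is not None or p.score is not None:
            row.append(p.name if p.name is not None else ".")
        if p.score is not None:
            row.append(p.score)
        rows.append(row)
    write_tsv(rows, path)


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    rows = [
        [
            g.symbol,
            g.chrom,
            g.strand,
            g.tx_start,
            g.tx_end,
            g.cds_start,
            g.cds_end,
            len(g.exon_starts),
            ",".join(map(str, g.exon_starts)) + ",",
            ",".join(map(str, g.exon_ends)) + ",",
        ]
        for g in genes
    ]
    write_tsv(rows, path)


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    write_tsv(
        ([r.symbol, r.lr1, r.p1, r.lr2, r.p2] for r in records),
        path,
        header=["symbol", "lr1", "p1", "lr2", "p2"],
    )


def write_gene_set(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(symbols):
            fh.write(s + "\n")


def write_clinical(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    recs = list(records)
    with_score = all(r.score is not None for r in recs)
    header = ["sample", "time", "event"] + (["score"] if with_score else [])
    rows = [
        [r.sample, r.time, r.event] + ([r.score] if with_score else [])
        for r in recs
    ]
    write_tsv(rows, path, header=header)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
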