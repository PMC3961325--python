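"""Degenerate (IUPAC) motif scanning and enrichment against shuffled
genomic background fragments.

A peak counts as a *hit* when its sequence contains at least one match to
the motif on either strand (e.g. the AP-1 consensus TGAYTCA). The
background per-peak hit probability q is estimated from length- and
chromosome-matched random fragments, and enrichment is tested with a
binomial upper tail P(X >= observed | n_peaks, q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomeIndex, Peak
from .peak_annotation import shuffle_peaks

__all__ = [
    "IUPAC",
    "MotifPattern",
    "EnrichmentResult",
    "scan_sequence",
    "peak_hit_rate",
    "motif_enrichment_test",
]

#: IUPAC nucleotide codes -> allowed bases. N in a *sequence* matches no
#: pattern position (unknown base is never evidence for a motif).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A",
               "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
               "B": "V", "D": "H", "H": "D", "V": "B", "N": "N"}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class MotifPattern:
    """An IUPAC degenerate motif with its reverse complement.

    Matching is case-insensitive over {A,C,G,T,N} sequences; an N base in
    the scanned sequence never satisfies any pattern position.
    """

    def __init__(self, pattern: str):
        pattern = pattern.strip().upper()
        if len(pattern) < 4:
            raise ValueError(f"motif {pattern!r} shorter than 4 bases")
        bad = [c for c in pattern if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {bad} in motif {pattern!r}")
        self.pattern = pattern
        self.allowed: tuple[frozenset[str], ...] = tuple(IUPAC[c] for c in pattern)
        self.revcomp = "".join(_COMPLEMENT[c] for c in reversed(pattern))

    def __len__(self) -> int:
        return len(self.pattern)

    def __repr__(self) -> str:
        return f"MotifPattern({self.pattern!r})"

    def _mask(self, which: str) -> np.ndarray:
        """(len, 4) boolean matrix: position i allows base code j."""
        pat = self.pattern if which == "+" else self.revcomp
        m = np.zeros((len(pat), 4), dtype=bool)
        for i, c in enumerate(pat):
            for b in IUPAC[c]:
                m[i, _BASE_CODE[b]] = True
        return m


def _encode(seq: str) -> np.ndarray:
    """Sequence -> base codes; anything outside ACGT (incl. N) becomes 4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, code in _BASE_CODE.items():
        table[ord(b)] = code
        table[ord(b.lower())] = code
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _match_positions(codes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    k, n = mask.shape[0], len(codes)
    if n < k:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n - k + 1, dtype=bool)
    padded = np.vstack([mask.T, np.zeros((1, k), dtype=bool)])  # code 4 row
    for i in range(k):
        ok &= padded[codes[i : n - k + 1 + i], i]
    return ok


def scan_sequence(seq: str, motif: MotifPattern | str) -> list[tuple[int, str]]:
    """All (offset, strand) matches of the motif or its reverse complement.

    Offsets are 0-based positions of the match start in ``seq``; a window
    matching on both strands is reported twice (+ first).
    """
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    codes = _encode(seq)
    if len(codes) < len(motif):
        return []
    fwd = _match_positions(codes, motif._mask("+"))
    rev = _match_positions(codes, motif._mask("-"))
    hits = [(int(i), "+") for i in np.nonzero(fwd)[0]]
    hits += [(int(i), "-") for i in np.nonzero(rev)[0]]
    hits.sort()
    return hits


def sequence_has_match(seq: str, motif: MotifPattern) -> bool:
    codes = _encode(seq)
    if len(codes) < len(motif):
        return False
    if _match_positions(codes, motif._mask("+")).any():
        return True
    return bool(_match_positions(codes, motif._mask("-")).any())


@dataclass(frozen=True)
class EnrichmentResult:
    motif: str
    n_peaks: int
    hit_count: int
    hit_rate: float
    background_rate: float
    n_background_fragments: int
    fold: float
    p_value: float
    fold_is_infinite: bool = False

    @property
    def p_label(self) -> str:
        if self.fold_is_infinite:
            return f"< {1.0 / self.n_background_fragments:g}"
        return f"{self.p_value:g}"


def peak_hit_rate(
    peaks: Sequence[Peak], genome: GenomeIndex, motif: MotifPattern | str
) -> tuple[int, float]:
    """Number and fraction of peaks containing >= 1 motif match."""
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    if not peaks:
        raise ValueError("peak_hit_rate requires at least one peak")
    hits = 0
    for p in peaks:
        genome.validate_peak(p)
        if sequence_has_match(genome.sequence(p.chrom, p.start, p.end), motif):
            hits += 1
    return hits, hits / len(peaks)


def motif_enrichment_test(
    peaks: Sequence[Peak],
    genome: GenomeIndex,
    motif: MotifPattern | str,
    n_background_sets: int = 10,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Binomial test of motif presence in peaks vs shuffled fragments.

    Background fragments are drawn by re-placing the peak set uniformly
    (length/chromosome matched) ``n_background_sets`` times and pooled into
    one estimate of the per-fragment hit probability q.
    """
    if isinstance(motif, str):
        motif = MotifPattern(motif)
    if n_background_sets < 1:
        raise ValueError("n_background_sets must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    obs_hits, obs_rate = peak_hit_rate(peaks, genome, motif)
    bg_hits = 0
    n_bg = 0
    for _ in range(n_background_sets):
        frags = shuffle_peaks(peaks, genome, rng)
        h, _ = peak_hit_rate(frags, genome, motif)
        bg_hits += h
        n_bg += len(frags)
    q = bg_hits / n_bg
    if q == 0.0:
        if obs_hits > 0:
            return EnrichmentResult(motif.pattern, len(peaks), obs_hits, obs_rate,
                                    0.0, n_bg, float("inf"), 1.0 / n_bg,
                                    fold_is_infinite=True)
        return EnrichmentResult(motif.pattern, len(peaks), 0, 0.0, 0.0, n_bg,
                                1.0, 1.0)
    p = float(stats.binom.sf(obs_hits - 1, len(peaks), q))
    return EnrichmentResult(motif.pattern, len(peaks), obs_hits, obs_rate,
                            q, n_bg, obs_rate / q, p)
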