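"""Gene-set overlap statistics: representation factor and exact
hypergeometric upper tail under a fixed gene-universe size.

The representation factor is the observed overlap divided by the overlap
expected under independent random draws, k / (|A||B|/N); the p-value is
the exact hypergeometric tail P(X >= k). The universe defaults to 20000
genes, the conventional protein-coding count.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable

from scipy import stats

__all__ = [
    "DEFAULT_UNIVERSE",
    "OverlapResult",
    "representation_factor",
    "hypergeom_upper_tail",
    "overlap_report",
]

DEFAULT_UNIVERSE = 20000


@dataclass(frozen=True)
class OverlapResult:
    n_a: int
    n_b: int
    overlap: int
    universe: int
    expected: float
    representation_factor: float
    p_value: float
    intersection: tuple[str, ...]


def _check_counts(k: int, n_a: int, n_b: int, universe: int) -> None:
    if min(n_a, n_b) < 1:
        raise ValueError("both sets must be non-empty")
    if universe < max(n_a, n_b):
        raise ValueError("universe smaller than a set")
    if k < 0 or k > min(n_a, n_b):
        raise ValueError(f"overlap {k} outside [0, min(|A|,|B|)]")
    if n_a + n_b - k > universe:
        raise ValueError("sets cannot fit the universe with this overlap")


def representation_factor(k: int, n_a: int, n_b: int, universe: int = DEFAULT_UNIVERSE) -> float:
    """Observed/expected overlap, k * N / (|A| * |B|), in exact rational
    arithmetic before the final division."""
    _check_counts(k, n_a, n_b, universe)
    return float(Fraction(k * universe, n_a * n_b))


def hypergeom_upper_tail(k: int, n_a: int, n_b: int, universe: int = DEFAULT_UNIVERSE) -> float:
    """Exact P(X >= k) for the overlap of random |A|- and |B|-subsets of an
    N-gene universe; symmetric in (|A|, |B|); computed in log space."""
    _check_counts(k, n_a, n_b, universe)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, n_b, n_a))


def overlap_report(
    set_a: Iterable[str], set_b: Iterable[str], universe: int = DEFAULT_UNIVERSE
) -> OverlapResult:
    """Full overlap statistics plus the sorted intersecting symbols."""
    a, b = set(set_a), set(set_b)
    if universe < len(a | b):
        raise ValueError("universe smaller than the union of the sets")
    k = len(a & b)
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        overlap=k,
        universe=universe,
        expected=len(a) * len(b) / universe,
        representation_factor=representation_factor(k, len(a), len(b), universe),
        p_value=hypergeom_upper_tail(k, len(a), len(b), universe),
        intersection=tuple(sorted(a & b)),
    )
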