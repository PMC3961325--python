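"""Combinatorial direct-target calling and signed fold-change reporting.

A gene is called a direct functional target when it is bound (a ChIP peak
center within the linking window of its TSS) *and* down-regulated in both
knockdown channels with p < 0.01 and log10 ratio < -0.2 — all strict
inequalities. Log ratios are base-10 (Rosetta convention), so a reported
signed fold change of -25.12 corresponds to a log ratio of -1.4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import ExpressionRecord, Peak

__all__ = [
    "TargetCallConfig",
    "TargetCall",
    "signed_fold_change",
    "call_targets",
    "summarize_signature",
]


@dataclass(frozen=True)
class TargetCallConfig:
    """Thresholds for the combinatorial call (both strict)."""

    p_threshold: float = 0.01
    lr_threshold: float = -0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.lr_threshold >= 0:
            raise ValueError("lr_threshold must be negative (down-regulation)")


@dataclass(frozen=True)
class TargetCall:
    symbol: str
    bound: bool
    supporting_peaks: tuple[Peak, ...]
    lr1: float
    lr2: float
    p1: float
    p2: float
    passed: bool

    @property
    def fc1(self) -> float:
        return signed_fold_change(self.lr1)

    @property
    def fc2(self) -> float:
        return signed_fold_change(self.lr2)


def signed_fold_change(log10_ratio: float) -> float:
    """Convert a log10 expression ratio to a signed linear fold change.

    r >= 0 -> 10**r (fold up); r < 0 -> -10**(-r) (fold down), so -1.4
    becomes -25.11886432. Odd around zero: f(-r) = -f(r) for r > 0.
    """
    if log10_ratio >= 0:
        return 10.0 ** log10_ratio
    return -(10.0 ** (-log10_ratio))


def call_targets(
    expression_records: Sequence[ExpressionRecord],
    bound_genes: Mapping[str, Sequence[Peak]] | Iterable[str],
    config: TargetCallConfig | None = None,
) -> list[TargetCall]:
    """Apply the combinatorial criteria; returns calls sorted by min(p1,p2).

    ``bound_genes`` is the output of ``link_peaks_to_genes`` (symbol ->
    supporting peaks) or a bare symbol set. Genes with multiple expression
    records keep the record with the smallest max(p1, p2); genes lacking
    expression data are never called.
    """
    config = config or TargetCallConfig()
    if isinstance(bound_genes, Mapping):
        support = {s: tuple(ps) for s, ps in bound_genes.items()}
    else:
        support = {s: () for s in bound_genes}

    best: dict[str, ExpressionRecord] = {}
    for r in expression_records:
        cur = best.get(r.symbol)
        if cur is None or max(r.p1, r.p2) < max(cur.p1, cur.p2):
            best[r.symbol] = r

    calls = []
    for symbol, r in best.items():
        bound = symbol in support
        passed = (
            bound
            and r.p1 < config.p_threshold
            and r.p2 < config.p_threshold
            and r.lr1 < config.lr_threshold
            and r.lr2 < config.lr_threshold
        )
        calls.append(
            TargetCall(
                symbol=symbol,
                bound=bound,
                supporting_peaks=support.get(symbol, ()),
                lr1=r.lr1,
                lr2=r.lr2,
                p1=r.p1,
                p2=r.p2,
                passed=passed,
            )
        )
    calls.sort(key=lambda c: (min(c.p1, c.p2), c.symbol))
    return calls


def signature(calls: Iterable[TargetCall]) -> set[str]:
    """Symbols of the passing calls — the direct-target signature."""
    return {c.symbol for c in calls if c.passed}


def summarize_signature(calls: Iterable[TargetCall]) -> pd.DataFrame:
    """Report table of passing calls: symbol, signed fold changes, p-values
    and supporting peak count. Empty input yields an empty table with the
    same header."""
    rows = [
        {
            "symbol": c.symbol,
            "fc1": c.fc1,
            "fc2": c.fc2,
            "p1": c.p1,
            "p2": c.p2,
            "n_peaks": len(c.supporting_peaks),
        }
        for c in calls
        if c.passed
    ]
    return pd.DataFrame(rows, columns=["symbol", "fc1", "fc2", "p1", "p2", "n_peaks"])
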