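"""GSEA-style running-sum (modified Kolmogorov-Smirnov) enrichment of a
gene set in a ranked expression list.

Walking the ranked list, the running sum gains ``|m_i|^w / sum_hits |m|^w``
at each gene in the set (for weight w=0 this is 1/n_hits) and loses
``1/(N - n_hits)`` at each miss; the enrichment score ES is the running-sum
value of maximal absolute deviation. Significance comes from random
gene-label sets of equal size, with the normalized score NES defined
against the same-sign null mean, following the standard GSEA convention.
w=0 gives the classic KS statistic used to relate ChIP-bound genes to a
knockdown-ranked list; w=1 the weighted variant used for signatures in
external expression datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ExpressionRecord

__all__ = [
    "RankedGeneList",
    "EnrichmentScore",
    "rank_by",
    "ks_enrichment",
    "permutation_pvalue",
]

logger = logging.getLogger(__name__)

_TINY_P = 1e-300  # floor before log10 so planted p=0 stays rankable


@dataclass(frozen=True, eq=False)
class RankedGeneList:
    """Ordered gene symbols with the metric that produced the order."""

    symbols: tuple[str, ...]
    metric: np.ndarray
    key: str
    descending: bool = False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedGeneList):
            return NotImplemented
        return (
            self.symbols == other.symbols
            and np.array_equal(self.metric, other.metric)
            and self.key == other.key
            and self.descending == other.descending
        )

    def __post_init__(self) -> None:
        if len(self.symbols) != len(set(self.symbols)):
            raise ValueError("ranked list symbols must be unique")
        if len(self.symbols) != len(self.metric):
            raise ValueError("metric length must match symbol count")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")

    def __len__(self) -> int:
        return len(self.symbols)

    def reversed(self) -> "RankedGeneList":
        return RankedGeneList(
            tuple(reversed(self.symbols)),
            self.metric[::-1].copy(),
            self.key,
            not self.descending,
        )


@dataclass(frozen=True)
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    extremum_index: int
    n_hits: int
    p_value: float | None = None
    p_is_bound: bool = False
    nes: float | None = None
    n_permutations: int = 0


def rank_by(
    records: Sequence[ExpressionRecord], key: str, sirna_channel: int = 1
) -> RankedGeneList:
    """Rank expression records for one knockdown channel.

    ``key='p_value'``: down-regulated genes first by ascending p (most
    significantly down at the top), then up-regulated genes by descending p,
    so the list runs most-down-significant to most-up-significant. The
    stored metric is the signed score -sign(lr) * -log10(p).

    ``key='fold_change'``: ascending log ratio (most down first); metric is
    the log ratio. Ties always break by symbol.
    """
    if key not in ("p_value", "fold_change"):
        raise ValueError(f"unknown ranking key {key!r}")
    if sirna_channel not in (1, 2):
        raise ValueError("sirna_channel must be 1 or 2")
    lr = np.array([r.lr1 if sirna_channel == 1 else r.lr2 for r in records])
    p = np.array([r.p1 if sirna_channel == 1 else r.p2 for r in records])
    symbols = [r.symbol for r in records]
    if key == "fold_change":
        order = sorted(range(len(records)), key=lambda i: (lr[i], symbols[i]))
        metric = lr
    else:
        # down-regulated ascending p, then up-regulated descending p
        def sort_key(i: int):
            down = lr[i] < 0
            return (0, p[i], symbols[i]) if down else (1, -p[i], symbols[i])

        order = sorted(range(len(records)), key=sort_key)
        metric = np.where(lr < 0, 1.0, -1.0) * -np.log10(np.maximum(p, _TINY_P))
    return RankedGeneList(
        tuple(symbols[i] for i in order),
        metric[np.array(order)],
        key,
    )


def ks_enrichment(
    ranked_list: RankedGeneList | Sequence[str],
    gene_set: Iterable[str],
    weight_exponent: int = 0,
) -> EnrichmentScore:
    """Running-sum enrichment score of ``gene_set`` in the ranked list.

    Genes in the set but absent from the list are dropped with a warning;
    an empty intersection, or a set covering the whole list (no misses), is
    an error.
    """
    if weight_exponent not in (0, 1):
        raise ValueError("weight_exponent must be 0 or 1")
    if isinstance(ranked_list, RankedGeneList):
        symbols = ranked_list.symbols
        metric = ranked_list.metric
    else:
        symbols = tuple(ranked_list)
        metric = np.zeros(len(symbols))
    gene_set = set(gene_set)
    present = gene_set & set(symbols)
    dropped = gene_set - present
    if dropped:
        logger.warning("%d gene-set symbols absent from ranked list", len(dropped))
    if not present:
        raise ValueError("gene set does not intersect the ranked list")
    n = len(symbols)
    n_hits = len(present)
    if n_hits == n:
        raise ValueError("gene set covers the entire list; no misses to walk")
    is_hit = np.fromiter((s in present for s in symbols), dtype=bool, count=n)
    if weight_exponent == 0:
        hit_w = np.where(is_hit, 1.0 / n_hits, 0.0)
    else:
        w = np.abs(metric) * is_hit
        total = w.sum()
        if total == 0:
            # all hit metrics zero: fall back to equal weights
            hit_w = np.where(is_hit, 1.0 / n_hits, 0.0)
        else:
            hit_w = w / total
    steps = hit_w - (~is_hit) / (n - n_hits)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return EnrichmentScore(
        es=float(running[idx]),
        running_sum=running,
        extremum_index=idx,
        n_hits=n_hits,
    )


def permutation_pvalue(
    ranked_list: RankedGeneList | Sequence[str],
    gene_set: Iterable[str],
    weight_exponent: int = 0,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> EnrichmentScore:
    """Gene-label permutation p-value and NES for the enrichment score.

    Null scores come from random sets of the same size drawn from the list;
    p = (1 + #{same-sign nulls with |ES| >= |ES_obs|}) / (n_same_sign + 1)
    and NES = ES / mean(|ES_null| of the same sign). When no null shares
    the observed sign the p-value is reported as a bound 1/(n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(0)
    obs = ks_enrichment(ranked_list, gene_set, weight_exponent)
    symbols = (
        ranked_list.symbols
        if isinstance(ranked_list, RankedGeneList)
        else tuple(ranked_list)
    )
    null_es = np.empty(n_perm)
    all_symbols = np.array(symbols)
    for b in range(n_perm):
        null_set = rng.choice(all_symbols, size=obs.n_hits, replace=False)
        null_es[b] = ks_enrichment(ranked_list, null_set, weight_exponent).es
    same_sign = null_es[np.sign(null_es) == np.sign(obs.es)]
    if len(same_sign) == 0:
        return EnrichmentScore(
            es=obs.es,
            running_sum=obs.running_sum,
            extremum_index=obs.extremum_index,
            n_hits=obs.n_hits,
            p_value=1.0 / (n_perm + 1),
            p_is_bound=True,
            nes=None,
            n_permutations=n_perm,
        )
    n_extreme = int(np.sum(np.abs(same_sign) >= abs(obs.es)))
    p = (1 + n_extreme) / (len(same_sign) + 1)
    nes = obs.es / float(np.mean(np.abs(same_sign)))
    return EnrichmentScore(
        es=obs.es,
        running_sum=obs.running_sum,
        extremum_index=obs.extremum_index,
        n_hits=obs.n_hits,
        p_value=p,
        nes=nes,
        n_permutations=n_perm,
    )
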