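"""Signature-based survival stratification: mean-signature scoring,
median split, Kaplan-Meier curves and the two-group log-rank test.

The expression matrix (genes x samples) is per-sample mean-centered
(optionally log2-transformed first when inputs are linear intensities);
each sample's score is the unweighted mean of the signature genes; samples
above the median score form the high group (ties at the median go low);
the groups are compared by the unweighted Mantel-Haenszel log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .io_formats import SurvivalRecord

__all__ = [
    "KMCurve",
    "LogRankResult",
    "normalize_matrix",
    "signature_score",
    "median_split",
    "km_estimate",
    "log_rank_test",
    "stratified_survival",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate at the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def normalize_matrix(matrix: pd.DataFrame, log2_transform: bool = False) -> pd.DataFrame:
    """Per-sample (column) mean-centering, optionally after log2.

    ``log2_transform=True`` declares the input to be linear intensities;
    otherwise values are taken as already log2. Centering is idempotent.
    """
    m = matrix.astype(float)
    if log2_transform:
        if (m <= 0).any().any():
            raise ValueError("log2 transform requires positive intensities")
        m = np.log2(m)
    return m - m.mean(axis=0)


def signature_score(matrix: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Per-sample unweighted mean over the signature genes present in the
    matrix rows; absent genes are dropped with a warning."""
    genes = set(gene_set)
    present = [g for g in matrix.index if g in genes]
    missing = genes - set(present)
    if missing:
        logger.warning("%d signature genes absent from matrix", len(missing))
    if not present:
        raise ValueError("no signature gene present in the expression matrix")
    return matrix.loc[present].mean(axis=0)


def median_split(scores: pd.Series | Sequence[float]) -> pd.Series:
    """Label samples 'high' (score > median) or 'low' (score <= median)."""
    s = pd.Series(scores, dtype=float) if not isinstance(scores, pd.Series) else scores
    if len(s) < 2:
        raise ValueError("median split requires at least two samples")
    if s.nunique() == 1:
        raise ValueError("all scores identical; degenerate split")
    med = float(s.median())
    return pd.Series(np.where(s > med, "high", "low"), index=s.index)


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate over the distinct event times.

    Censored-only times reduce the risk set but do not change S.
    """
    if not records:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    mask = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    d = table["observed"].to_numpy(dtype=float)[mask]
    n = table["at_risk"].to_numpy(dtype=float)[mask]
    surv = np.array(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )
    return KMCurve(event_times=event_times, at_risk=n, events=d, survival=surv)


def _group_counts(times: np.ndarray, events: np.ndarray, grid: np.ndarray):
    """At-risk and event counts for one group at each grid time."""
    order = np.sort(times)
    at_risk = len(times) - np.searchsorted(order, grid, side="left")
    d = np.zeros(len(grid))
    ev_times = times[events == 1]
    for i, t in enumerate(grid):
        d[i] = np.sum(ev_times == t)
    return at_risk.astype(float), d


def log_rank_test(
    records_high: Sequence[SurvivalRecord], records_low: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Unweighted (Mantel-Haenszel) two-group log-rank test.

    At each distinct event time with d events, n at risk and n1 at risk in
    group 1: E1 = d*n1/n and V = d*(n1/n)*(1-n1/n)*(n-d)/(n-1); times with
    a single subject at risk carry no information and are skipped.
    """
    t1 = np.array([r.time for r in records_high], dtype=float)
    e1 = np.array([r.event for r in records_high], dtype=int)
    t2 = np.array([r.time for r in records_low], dtype=float)
    e2 = np.array([r.event for r in records_low], dtype=int)
    if e1.sum() + e2.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    grid = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    n1, d1 = _group_counts(t1, e1, grid)
    n2, d2 = _group_counts(t2, e2, grid)
    n = n1 + n2
    d = d1 + d2
    expected1 = d * n1 / n
    # a stratum with a single subject at risk carries no information:
    # its O - E is 0 and its 0/0 variance is taken as 0
    var = np.where(
        n > 1,
        d * (n1 / n) * (1 - n1 / n) * (n - d) / np.maximum(n - 1, 1),
        0.0,
    )
    v = var.sum()
    o1, o2 = d1.sum(), d2.sum()
    e1_tot, e2_tot = expected1.sum(), (d - expected1).sum()
    if v == 0:
        chi2 = 0.0
    else:
        chi2 = float((o1 - e1_tot) ** 2 / v)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(
        chi_square=chi2,
        p_value=p,
        observed=(float(o1), float(o2)),
        expected=(float(e1_tot), float(e2_tot)),
    )


def stratified_survival(
    matrix: pd.DataFrame,
    gene_set: Iterable[str],
    clinical: Sequence[SurvivalRecord],
    log2_transform: bool = False,
) -> tuple[dict[str, KMCurve], LogRankResult, pd.Series]:
    """Normalize, score, median-split and compare survival of the groups.

    Sample ids must match between the matrix columns and the clinical
    table. Returns per-group KM curves, the log-rank result and the group
    labels.
    """
    by_sample = {r.sample: r for r in clinical}
    missing = [c for c in matrix.columns if c not in by_sample]
    if missing:
        raise ValueError(f"samples without clinical data: {missing[:5]}")
    normalized = normalize_matrix(matrix, log2_transform=log2_transform)
    scores = signature_score(normalized, gene_set)
    labels = median_split(scores)
    groups: dict[str, list[SurvivalRecord]] = {"high": [], "low": []}
    for sample in sorted(matrix.columns):
        groups[labels[sample]].append(by_sample[sample])
    if min(len(groups["high"]), len(groups["low"])) < 2:
        raise ValueError("fewer than 2 samples in a group after median split")
    curves = {g: km_estimate(rs) for g, rs in groups.items()}
    result = log_rank_test(groups["high"], groups["low"])
    return curves, result, labels
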