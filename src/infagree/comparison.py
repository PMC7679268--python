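"""Comparing classifiers through their agreement structure.

Given two models scored on the same data set, each entry is either
correctly (C) or wrongly (W) classified by each model; the pair of
correctness vectors tallies into a 2 x 2 agreement table
[[CC, CW], [WC, WW]] on which kappa and IA apply directly.  When several
model pairs are compared, the resulting sequences of kappa and IA values
can be correlated (Pearson's rho for linear association, Spearman's r_s
for rank agreement, average ranks on ties) to quantify how far the two
indexes order the pairs differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .agreement import cohen_kappa, informational_agreement
from .types import ContingencyTable, DegenerateTableError

__all__ = [
    "correctness_table",
    "pearson",
    "spearman",
    "correlate",
    "CorrelationResult",
    "PairAgreement",
    "pairwise_model_agreement",
]


def correctness_table(a: Sequence[bool], b: Sequence[bool]) -> ContingencyTable:
    """Tally two equal-length correctness vectors into a 2 x 2 table.

    Row/column 1 counts correct classifications, row/column 2 wrong ones:
    cell (1,1) = both correct, (1,2) = A correct / B wrong, etc.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
        raise ValueError(f"correctness vectors must be 1-D and equal length, got {a.size} and {b.size}")
    if a.size == 0:
        raise ValueError("correctness vectors must be nonempty")
    counts = [
        [int(np.sum(a & b)), int(np.sum(a & ~b))],
        [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
    ]
    return ContingencyTable(counts, labels=("C", "W"))


def _check_paired(xs, ys) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or ys.ndim != 1 or xs.size != ys.size:
        raise ValueError("sequences must be 1-D and equal length")
    if xs.size < 3:
        raise ValueError(f"need at least 3 pairs, got {xs.size}")
    return xs, ys


def pearson(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Pearson's product-moment correlation coefficient."""
    xs, ys = _check_paired(xs, ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Pearson correlation undefined for a constant sequence")
    return float(stats.pearsonr(xs, ys).statistic)


def spearman(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Spearman's rank correlation (Pearson on average ranks)."""
    xs, ys = _check_paired(xs, ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("Spearman correlation undefined for a constant sequence")
    return float(stats.spearmanr(xs, ys).statistic)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman correlation between two index sequences."""

    rho: float
    r_s: float
    n_pairs: int


def correlate(kappas: Sequence[float], ias: Sequence[float]) -> CorrelationResult:
    """Correlate matched sequences of kappa and IA values across model pairs."""
    xs, ys = _check_paired(kappas, ias)
    return CorrelationResult(rho=pearson(xs, ys), r_s=spearman(xs, ys), n_pairs=xs.size)


@dataclass(frozen=True)
class PairAgreement:
    """Agreement indexes of one model pair; ``None`` where undefined."""

    pair: tuple[str, str]
    table: ContingencyTable
    kappa: float | None
    ia: float | None


def pairwise_model_agreement(
    correctness: Mapping[str, Sequence[bool]],
) -> list[PairAgreement]:
    """Kappa and IA for every unordered pair of models.

    ``correctness`` maps model names to equal-length correctness vectors;
    pairs are enumerated in the mapping's order.
    """
    names = list(correctness)
    if len(names) < 2:
        raise ValueError("need at least two models to compare")
    out = []
    for a, b in combinations(names, 2):
        table = correctness_table(correctness[a], correctness[b])
        try:
            kappa = cohen_kappa(table)
        except DegenerateTableError:
            kappa = None
        try:
            ia = informational_agreement(table)
        except DegenerateTableError:
            ia = None
        out.append(PairAgreement(pair=(a, b), table=table, kappa=kappa, ia=ia))
    return out
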