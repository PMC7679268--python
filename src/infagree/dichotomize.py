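"""Collapsing an ordered q-level scale into two classes.

Clinical ordinal scales (e.g. the 5-grade BI-RADS malignancy-suspicion
scale) are routinely dichotomised into "not significant" vs "significant"
at some threshold t: categories 1..t form class 1, categories t+1..q form
class 2.  ``collapse`` performs the block summation; ``threshold_scan``
evaluates kappa and IA at every possible threshold to locate the
agreement-maximising split.
"""

from __future__ import annotations

from dataclasses import dataclass

from .agreement import cohen_kappa, informational_agreement
from .types import ContingencyTable, DegenerateTableError

__all__ = ["collapse", "threshold_scan", "ScanEntry", "ThresholdScanResult"]


def collapse(table: ContingencyTable, t: int) -> ContingencyTable:
    """Collapse a q x q table to 2 x 2 at threshold ``t`` (1-based).

    Class 1 is categories 1..t, class 2 is categories t+1..q; cell (1,1) of
    the result sums the top-left t x t block, and so on.  The total count N
    is preserved.
    """
    q = table.q
    if not 1 <= t <= q - 1:
        raise ValueError(f"threshold must lie in 1..{q - 1}, got {t}")
    c = table.counts
    collapsed = [
        [int(c[:t, :t].sum()), int(c[:t, t:].sum())],
        [int(c[t:, :t].sum()), int(c[t:, t:].sum())],
    ]
    labels = None
    if table.labels is not None:
        lo, hi = table.labels[:t], table.labels[t:]
        labels = ("-".join(lo), "-".join(hi))
    return ContingencyTable(collapsed, labels)


@dataclass(frozen=True)
class ScanEntry:
    """Agreement indexes of one dichotomisation; ``None`` where undefined."""

    threshold: int
    kappa: float | None
    ia: float | None


@dataclass(frozen=True)
class ThresholdScanResult:
    """Kappa and IA at every threshold, with the argmax of each column.

    ``best_kappa_t`` / ``best_ia_t`` are ``None`` only if the index was
    undefined at every threshold.  Ties break toward the smallest
    threshold (the more conservative split).
    """

    entries: tuple[ScanEntry, ...]
    best_kappa_t: int | None
    best_ia_t: int | None


def threshold_scan(table: ContingencyTable) -> ThresholdScanResult:
    """Evaluate kappa and IA on every dichotomisation of an ordinal table.

    Requires q >= 3 (a 2 x 2 table has a single trivial collapse).  A
    threshold at which an index is undefined (degenerate collapsed table)
    is recorded as ``None`` and excluded from the argmax.
    """
    if table.q < 3:
        raise ValueError(f"threshold scan needs q >= 3, got q={table.q}")
    entries = []
    for t in range(1, table.q):
        two = collapse(table, t)
        try:
            kappa = cohen_kappa(two)
        except DegenerateTableError:
            kappa = None
        try:
            ia = informational_agreement(two)
        except DegenerateTableError:
            ia = None
        entries.append(ScanEntry(threshold=t, kappa=kappa, ia=ia))

    def argmax(key):
        defined = [(e.threshold, key(e)) for e in entries if key(e) is not None]
        if not defined:
            return None
        best = max(v for _, v in defined)
        return min(t for t, v in defined if v == best)

    return ThresholdScanResult(
        entries=tuple(entries),
        best_kappa_t=argmax(lambda e: e.kappa),
        best_ia_t=argmax(lambda e: e.ia),
    )
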