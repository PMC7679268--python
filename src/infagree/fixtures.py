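"""Bundled example tables with published reference index values.

These small contingency tables are classic demonstration cases for the
behaviour of kappa and IA:

* ``scenario1`` .. ``scenario6`` — six 2 x 2 tables engineered to exhibit
  kappa's known pathologies (near-identical kappa for very different
  tables; the symmetrically- and asymmetrically-unbalanced-marginal
  paradoxes).
* ``abvs_us_5x5`` — agreement between hand-held ultrasound (US) and the
  automated breast volume scanner (ABVS) classifying 186 breast MRI
  findings on the 5-grade BI-RADS scale; ``abvs_us_2x2`` is its standard
  dichotomisation (BI-RADS 1-2 vs 3-4-5).
* ``kb_5a`` / ``fs_5b`` — correct/wrong agreement tables of two classifier
  pairs (kNN vs naive Bayes; random forest vs SGD) on the Tic-Tac-Toe
  benchmark, the case where kappa and IA order the pairs oppositely.

Each fixture carries its published kappa and IA (3-decimal rounding, or
2-decimal where that is how they were reported); ``validate_fixtures``
recomputes both on load so any transcription drift in the count matrices
fails loudly instead of shipping a wrong table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .agreement import cohen_kappa, informational_agreement
from .types import ContingencyTable
from .util import round_half_away

__all__ = ["Fixture", "FIXTURES", "load_fixture", "validate_fixtures"]

_BIRADS = ("BR1", "BR2", "BR3", "BR4", "BR5")


@dataclass(frozen=True)
class Fixture:
    """A named table plus its published (kappa, IA) at a stated precision."""

    name: str
    table: ContingencyTable
    kappa: float
    ia: float
    decimals: int
    note: str


def _fx(name, counts, kappa, ia, note, decimals=3, labels=None):
    return Fixture(
        name=name,
        table=ContingencyTable(counts, labels),
        kappa=kappa,
        ia=ia,
        decimals=decimals,
        note=note,
    )


FIXTURES: dict[str, Fixture] = {
    f.name: f
    for f in (
        _fx("scenario1", [[3600, 2595], [65, 3740]], 0.500, 0.309,
            "balanced large sample, p_o = 0.734"),
        _fx("scenario2", [[9901, 64], [2, 33]], 0.497, 0.651,
            "p_o = 0.9934 yet kappa ~ 0.5 (same as scenario1)"),
        _fx("scenario3", [[9900, 86], [1, 13]], 0.228, 0.541,
            "symmetrically unbalanced marginals: p_o = 0.991, low kappa"),
        _fx("scenario4", [[21, 5], [3, 21]], 0.681, 0.371,
            "asymmetrically unbalanced marginals, p_o = 0.84"),
        _fx("scenario5", [[40, 5], [3, 2]], 0.245, 0.073,
            "symmetrically unbalanced marginals, p_o = 0.84"),
        _fx("scenario6", [[40, 2], [3, 5]], 0.608, 0.342,
            "scenario5 with 3 ratings moved onto the diagonal"),
        _fx("abvs_us_5x5",
            [[51, 4, 0, 1, 1],
             [3, 78, 1, 0, 0],
             [0, 0, 13, 4, 0],
             [0, 1, 1, 16, 7],
             [0, 0, 0, 0, 5]],
            0.821, 0.729,
            "US (columns) vs ABVS (rows) on 186 findings, 5-grade BI-RADS",
            labels=_BIRADS),
        _fx("abvs_us_2x2", [[136, 3], [1, 46]], 0.944, 0.836,
            "US vs ABVS dichotomised at BI-RADS 1-2 vs 3-4-5",
            labels=("BR1-2", "BR3-4-5")),
        _fx("kb_5a", [[547, 134], [120, 157]], 0.36, 0.11,
            "kNN vs naive Bayes correctness agreement (Tic-Tac-Toe)",
            decimals=2, labels=("C", "W")),
        _fx("fs_5b", [[903, 6], [39, 10]], 0.29, 0.25,
            "random forest vs SGD correctness agreement (Tic-Tac-Toe)",
            decimals=2, labels=("C", "W")),
    )
}


def validate_fixtures() -> None:
    """Recompute kappa and IA for every fixture against its published values.

    Raises ``AssertionError`` naming the first fixture whose recomputed
    index disagrees with the bundled reference at its stated precision.
    """
    for f in FIXTURES.values():
        kappa = round_half_away(cohen_kappa(f.table), f.decimals)
        ia = round_half_away(informational_agreement(f.table), f.decimals)
        if kappa != f.kappa:
            raise AssertionError(
                f"fixture {f.name!r}: recomputed kappa {kappa} != reference {f.kappa}"
            )
        if ia != f.ia:
            raise AssertionError(
                f"fixture {f.name!r}: recomputed IA {ia} != reference {f.ia}"
            )


def load_fixture(name: str) -> Fixture:
    """Return a bundled fixture by name, self-validating it first."""
    try:
        f = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    kappa = round_half_away(cohen_kappa(f.table), f.decimals)
    ia = round_half_away(informational_agreement(f.table), f.decimals)
    if kappa != f.kappa or ia != f.ia:
        raise AssertionError(f"fixture {name!r} failed self-validation")
    return f
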