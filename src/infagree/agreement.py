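"""Chance-corrected and information-based agreement indexes.

Two indexes of inter-rater agreement on a q x q contingency table:

* Cohen's kappa, (p_o - p_e) / (1 - p_e): the observed diagonal agreement
  corrected for the agreement expected under independent raters.  Ranges in
  [-1, 1] and famously misbehaves under strongly unbalanced marginals (the
  symmetric- and asymmetric-unbalance paradoxes).
* The informational agreement IA = MI(X, Y) / min{H(X), H(Y)}: the mutual
  information between the two raters' rating variables, normalised by the
  smaller marginal entropy so that it ranges in [0, 1].  IA uses the whole
  table — off-diagonal disagreement structure included — and is invariant
  to the logarithm base.

Both are symmetric under exchanging the raters.  Degenerate tables (a rater
constant on one category) make IA a 0/0 form and are reported as undefined
rather than silently coerced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .information import conditional_entropy, entropy, joint_from_table, mutual_information
from .types import ContingencyTable, DegenerateTableError

__all__ = [
    "observed_agreement",
    "expected_agreement",
    "cohen_kappa",
    "informational_agreement",
    "interpret_kappa",
    "agreement_report",
    "AgreementReport",
    "KAPPA_BANDS",
]

#: Landis & Koch-style interpretation bands for kappa, as a partition:
#: half-open below, with the top band closed at 1.
KAPPA_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.2, "none-to-slight"),
    (0.2, 0.4, "fair"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "substantial"),
    (0.8, 1.0, "almost-perfect"),
)


def observed_agreement(table: ContingencyTable) -> float:
    """p_o: fraction of subjects placed in the same category by both raters."""
    return float(np.trace(table.counts) / table.n)


def expected_agreement(table: ContingencyTable) -> float:
    """p_e: diagonal mass of the product-of-marginals (chance) distribution."""
    n = table.n
    return float(np.sum((table.row_totals / n) * (table.col_totals / n)))


def cohen_kappa(table: ContingencyTable) -> float:
    """Cohen's kappa (p_o - p_e) / (1 - p_e).

    Raises
    ------
    DegenerateTableError
        If p_e = 1 (both raters constant on the same category), where the
        index is a 0/0 form.
    """
    p_o = observed_agreement(table)
    p_e = expected_agreement(table)
    if p_e >= 1.0:
        raise DegenerateTableError(
            "kappa undefined: expected agreement is 1 "
            "(both raters constant on the same category)"
        )
    return (p_o - p_e) / (1.0 - p_e)


def informational_agreement(table: ContingencyTable) -> float:
    """IA = MI(X, Y) / min{H(X), H(Y)} in [0, 1].

    Base-invariant (numerator and denominator rescale identically), equal
    to 0 iff the raters are independent, and equal to 1 when either rater's
    rating determines the other's.

    Raises
    ------
    DegenerateTableError
        If either marginal has zero entropy (a rater using a single
        category), where IA is a 0/0 form.
    """
    joint = joint_from_table(table)
    q = table.q
    h_min = min(entropy(joint.marginal_row, base=q), entropy(joint.marginal_col, base=q))
    if h_min == 0.0:
        raise DegenerateTableError(
            "IA undefined: a rater uses a single category (zero marginal entropy)"
        )
    ia = mutual_information(joint, base=q) / h_min
    # MI <= min entropy analytically; trim float round-off at the top edge
    return min(ia, 1.0)


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value onto the conventional verbal agreement scale.

    Negative values indicate below-chance agreement and are annotated as
    such.  The scale is conventional for kappa only; no analogous scale is
    defined for IA.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa!r}")
    if kappa < 0.0:
        return "none-to-slight (below chance)"
    for lo, hi, label in KAPPA_BANDS:
        if lo <= kappa < hi:
            return label
    return KAPPA_BANDS[-1][2]  # kappa == 1.0


@dataclass(frozen=True)
class AgreementReport:
    """All agreement quantities of one contingency table, computed in one pass.

    ``kappa`` and ``ia`` are ``None`` when undefined, with the reason in the
    matching ``*_undefined_reason`` field; each index carries its own
    validity flag so one being degenerate does not suppress the other.
    Entropies and MI are reported in the units of ``base``.
    """

    q: int
    n: int
    base: float
    h_row: float
    h_col: float
    h_cond: float
    mi: float
    p_o: float
    p_e: float
    kappa: float | None
    ia: float | None
    kappa_band: str | None
    kappa_undefined_reason: str | None = None
    ia_undefined_reason: str | None = None


def agreement_report(table: ContingencyTable, base: float | None = None) -> AgreementReport:
    """Compute entropies, MI, p_o, p_e, kappa and IA for one table.

    Parameters
    ----------
    table : ContingencyTable
    base : float, optional
        Logarithm base for the reported entropies and MI; defaults to q.
        IA itself is base-invariant.
    """
    if base is None:
        base = table.q
    joint = joint_from_table(table)
    h_row = entropy(joint.marginal_row, base=base)
    h_col = entropy(joint.marginal_col, base=base)
    h_cond = conditional_entropy(joint, base=base)
    mi = mutual_information(joint, base=base)
    p_o = observed_agreement(table)
    p_e = expected_agreement(table)

    kappa = band = kappa_reason = None
    try:
        kappa = cohen_kappa(table)
        band = interpret_kappa(kappa)
    except DegenerateTableError as exc:
        kappa_reason = str(exc)

    ia = ia_reason = None
    try:
        ia = informational_agreement(table)
    except DegenerateTableError as exc:
        ia_reason = str(exc)

    return AgreementReport(
        q=table.q,
        n=table.n,
        base=float(base),
        h_row=h_row,
        h_col=h_col,
        h_cond=h_cond,
        mi=mi,
        p_o=p_o,
        p_e=p_e,
        kappa=kappa,
        ia=ia,
        kappa_band=band,
        kappa_undefined_reason=kappa_reason,
        ia_undefined_reason=ia_reason,
    )
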