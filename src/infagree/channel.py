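"""The agreement-channel view of paired ratings.

A contingency table factors into a marginal distribution P_X (the column
rater's rating frequencies, which carry the condition prevalence) and a
column-stochastic transition matrix Gamma_q of conditional probabilities
p(y|x) (the "nucleus of agreement" relating the two raters, insulated from
prevalence).  Mutual information — and hence IA — is fully determined by
the pair (P_X, Gamma_q), which makes prevalence sweeps at a fixed channel,
and generative simulation of rating pairs, straightforward.

Orientation convention: the conditioning variable X is the COLUMN rater of
the table (categories across the top), matching the usual typeset layout;
pass ``transpose=True`` to condition on the row rater instead.  Kappa and
IA are transpose-invariant, so the orientation only affects the transition
matrix itself and the sensitivity/specificity read off it.  Category 1
(index 0) is "condition present" for sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .information import entropy, mutual_information
from .types import (
    ContingencyTable,
    DegenerateTableError,
    JointDistribution,
    ProbabilityVector,
)

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "joint_from_channel",
    "mi_from_channel",
    "ia_from_channel",
    "sensitivity_specificity",
    "simulate_ratings",
]

_COL_TOL = 1e-12


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic q x q matrix; entry (y, x) is p(Y = y | X = x)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"transition matrix must be square 2-D, got shape {arr.shape}")
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        colsums = arr.sum(axis=0)
        if np.max(np.abs(colsums - 1.0)) > _COL_TOL:
            raise ValueError(f"columns must sum to 1, got sums {colsums!r}")
        object.__setattr__(self, "probs", arr)
        arr.setflags(write=False)

    @property
    def q(self) -> int:
        return self.probs.shape[0]


def transition_matrix(table: ContingencyTable, transpose: bool = False) -> TransitionMatrix:
    """Estimate the channel Gamma_q from a table by column-wise normalisation.

    Entry (y, x) is counts(y, x) / column-total(x): the empirical
    probability of the row rater saying y given the column rater said x.
    With ``transpose=True`` the roles are swapped first.
    """
    counts = table.counts.T if transpose else table.counts
    totals = counts.sum(axis=0)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        raise DegenerateTableError(
            f"cannot condition on empty categor{'y' if empty.size == 1 else 'ies'} "
            f"{[int(i) + 1 for i in empty]} (zero column total)"
        )
    return TransitionMatrix(counts / totals)


def joint_from_channel(p_x: ProbabilityVector, gamma: TransitionMatrix) -> JointDistribution:
    """Joint probabilities p(x, y) = p_X(x) * p(y|x), oriented (row=y, col=x)."""
    if p_x.q != gamma.q:
        raise ValueError(f"dimension mismatch: p_x has q={p_x.q}, gamma has q={gamma.q}")
    return JointDistribution(gamma.probs * p_x.probs[None, :])


def mi_from_channel(
    p_x: ProbabilityVector, gamma: TransitionMatrix, base: float | None = None
) -> float:
    """Mutual information from the channel decomposition.

    MI = sum_xy p_X(x) p(y|x) log[ p(y|x) / sum_z p_X(z) p(y|z) ],
    which equals the MI of the induced joint distribution.  This form makes
    explicit that MI depends only on the channel and the input distribution.
    """
    if p_x.q != gamma.q:
        raise ValueError(f"dimension mismatch: p_x has q={p_x.q}, gamma has q={gamma.q}")
    if base is None:
        base = gamma.q
    if not base > 1:
        raise ValueError(f"log base must be > 1, got {base!r}")
    g = gamma.probs
    px = p_x.probs
    p_y = g @ px  # output marginal
    joint = g * px[None, :]  # entry (y, x)
    nz = joint > 0
    ratio = g[nz] / np.broadcast_to(p_y[:, None], g.shape)[nz]
    return max(float(np.sum(joint[nz] * np.log(ratio)) / np.log(base)), 0.0)


def ia_from_channel(p_x: ProbabilityVector, gamma: TransitionMatrix) -> float:
    """IA of the joint distribution induced by (P_X, Gamma_q).

    Enables prevalence sweeps at a fixed channel.  Raises
    :class:`DegenerateTableError` when an induced marginal is degenerate.
    """
    joint = joint_from_channel(p_x, gamma)
    q = joint.q
    h_min = min(entropy(joint.marginal_row, base=q), entropy(joint.marginal_col, base=q))
    if h_min == 0.0:
        raise DegenerateTableError("IA undefined: an induced marginal is degenerate")
    return min(mutual_information(joint, base=q) / h_min, 1.0)


def sensitivity_specificity(gamma: TransitionMatrix) -> tuple[float, float]:
    """(sensitivity, specificity) of a binary channel.

    With category 1 meaning "condition present", sensitivity is
    p(Y=1 | X=1) = Gamma(1,1) and specificity is p(Y=2 | X=2) = Gamma(2,2).
    """
    if gamma.q != 2:
        raise ValueError(f"sensitivity/specificity need a binary channel, got q={gamma.q}")
    return float(gamma.probs[0, 0]), float(gamma.probs[1, 1])


def simulate_ratings(
    p_x: ProbabilityVector,
    gamma: TransitionMatrix,
    n: int,
    seed: int | np.random.Generator,
) -> ContingencyTable:
    """Draw n rating pairs from the generative channel model and tally them.

    Each subject's column-rater rating x is drawn from ``p_x`` and the
    row-rater rating y from column x of ``gamma``; the result is the
    contingency table of counts with entry (y, x).  Reproducible: the same
    seed yields the identical table (numpy's PCG64 generator, whose stream
    is stable across platforms for a given numpy version).
    """
    if n < 1:
        raise ValueError(f"need n >= 1 draws, got {n}")
    if p_x.q != gamma.q:
        raise ValueError(f"dimension mismatch: p_x has q={p_x.q}, gamma has q={gamma.q}")
    rng = np.random.default_rng(seed)
    q = gamma.q
    xs = rng.choice(q, size=n, p=p_x.probs)
    counts = np.zeros((q, q), dtype=np.int64)
    for x in range(q):
        k = int(np.sum(xs == x))
        if k == 0:
            continue
        ys = rng.choice(q, size=k, p=gamma.probs[:, x])
        np.add.at(counts, (ys, np.full(k, x)), 1)
    return ContingencyTable(counts)
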