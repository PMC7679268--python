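"""Discrete information-theoretic primitives with the log-base-q convention.

Entropies are computed with plug-in (empirical-frequency) probabilities and,
by default, with logarithms in base q — the number of rating categories — so
that a uniform marginal has entropy exactly 1.  Bits (base 2) or any base
greater than 1 can be requested explicitly; the informational agreement
ratio IA = MI / min{H(X), H(Y)} is invariant to the choice.

Zero cells follow the continuity convention 0*log(0) = 0: an empty joint
cell or an unused category contributes nothing.  This equals the right-limit
construction in which every zero count is replaced by an epsilon that is
then driven to 0+ (lim x->0+ of x*log x = 0); :func:`ia_epsilon_probe`
verifies the equivalence numerically and exists only as a validation oracle.
"""

from __future__ import annotations

import numpy as np

from .types import ContingencyTable, JointDistribution, ProbabilityVector

__all__ = [
    "joint_from_table",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "ia_epsilon_probe",
]


def joint_from_table(table: ContingencyTable) -> JointDistribution:
    """Plug-in joint distribution counts / N of a contingency table."""
    return JointDistribution(table.counts / table.n)


def _check_base(base: float) -> float:
    if base is None or not base > 1:
        raise ValueError(f"log base must be > 1, got {base!r}")
    return float(base)


def entropy(p: ProbabilityVector | np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p*log_base(p), default base = len(p).

    With the default base the entropy of a q-category marginal lies in
    [0, 1], reaching 1 only for the uniform distribution.
    """
    if not isinstance(p, ProbabilityVector):
        p = ProbabilityVector(np.asarray(p, dtype=float))
    probs = p.probs
    if base is None:
        base = p.q
    base = _check_base(base)
    nz = probs > 0
    # sum in sorted order: the result depends only on the multiset of terms,
    # making identities such as IA = 1 on diagonal tables hold exactly
    terms = np.sort(-probs[nz] * np.log(probs[nz]))
    return float(np.sum(terms) / np.log(base))


def conditional_entropy(joint: JointDistribution, base: float | None = None) -> float:
    """H(Y/X): information left in the row rater Y once the column rater X is known.

    The conditioning variable X is the column rater throughout the package
    (the same orientation as the channel transition matrix).  Computed as
    -sum_xy p(y,x) * log(p(y,x)/p_X(x)).  Cells with p(y,x) = 0 contribute
    0; a conditioning category with p_X(x) = 0 has no joint mass in its
    column and likewise contributes 0.
    """
    if base is None:
        base = joint.q
    base = _check_base(base)
    p = joint.probs
    px = joint.marginal_col.probs
    nz = p > 0
    ratio = p[nz] / np.broadcast_to(px[None, :], p.shape)[nz]
    return float(-np.sum(p[nz] * np.log(ratio)) / np.log(base))


def mutual_information(joint: JointDistribution, base: float | None = None) -> float:
    """MI = sum_xy p(x,y) * log(p(x,y) / (p_x(x) p_y(y))).

    Nonnegative, symmetric in the two raters, bounded above by
    min{H(X), H(Y)}, and equal to H(Y) - H(Y/X) = H(X) - H(X/Y).
    Zero-probability cells contribute 0.
    """
    if base is None:
        base = joint.q
    base = _check_base(base)
    p = joint.probs
    log_px = np.full(joint.q, -np.inf)
    log_py = np.full(joint.q, -np.inf)
    np.log(joint.marginal_row.probs, out=log_px, where=joint.marginal_row.probs > 0)
    np.log(joint.marginal_col.probs, out=log_py, where=joint.marginal_col.probs > 0)
    nz = p > 0
    terms = p[nz] * (np.log(p[nz]) - (log_px[:, None] + log_py[None, :])[nz])
    # summing in sorted order makes the result a function of the multiset of
    # terms only, so MI is exactly transpose-symmetric and exactly equals the
    # marginal entropy on diagonal joints (hence IA = 1 exactly there)
    mi = float(np.sum(np.sort(terms)) / np.log(base))
    # plug-in MI is >= 0 analytically; clip the round-off of near-independent joints
    return max(mi, 0.0)


def ia_epsilon_probe(table: ContingencyTable, epsilon: float) -> float:
    """IA after replacing every zero count by ``epsilon`` and renormalising.

    As epsilon -> 0+ this converges to the IA computed under the
    0*log(0) = 0 convention; it is used only to validate the zero-cell
    policy, never as the production path.
    """
    if not 0 < epsilon <= 1e-3:
        raise ValueError(f"epsilon must be in (0, 1e-3], got {epsilon!r}")
    counts = np.asarray(table.counts, dtype=float)
    counts = np.where(counts == 0, epsilon, counts)
    joint = JointDistribution(counts / counts.sum())
    h_row = entropy(joint.marginal_row, base=joint.q)
    h_col = entropy(joint.marginal_col, base=joint.q)
    return mutual_information(joint, base=joint.q) / min(h_row, h_col)
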