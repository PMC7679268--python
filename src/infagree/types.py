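"""Core value types for paired-rating agreement analysis.

A study produces a q x q contingency table of counts: entry (i, j) is the
number of subjects rated category i by the row rater and category j by the
column rater.  Everything downstream (entropies, mutual information, Cohen's
kappa, the informational agreement IA) is a function of this table, so the
table and the probability objects derived from it are the package's
universal currency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROB_TOL = 1e-12  # normalisation tolerance for probability objects


class DegenerateTableError(ValueError):
    """Raised when an index is undefined for the given table.

    Examples: a rater that uses a single category (zero marginal entropy
    makes IA a 0/0 form), or both raters constant on the same category
    (expected agreement 1 makes kappa a 0/0 form).
    """


def _as_count_matrix(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"contingency table must be square 2-D, got shape {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("contingency table needs at least 2 categories")
    if not np.issubdtype(arr.dtype, np.integer):
        as_int = np.asarray(arr, dtype=np.int64)
        if not np.array_equal(as_int, arr):
            raise ValueError("counts must be nonnegative integers (fractional weights rejected)")
        arr = as_int
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if arr.sum() == 0:
        raise ValueError("empty table: total count is zero")
    return arr


@dataclass(frozen=True)
class ContingencyTable:
    """q x q table of paired rating counts.

    Parameters
    ----------
    counts : array-like of shape (q, q)
        Nonnegative integers; entry (i, j) counts subjects rated i by the
        row rater and j by the column rater.
    labels : sequence of str, optional
        Ordered category names, length q.
    """

    counts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = _as_count_matrix(self.counts)
        object.__setattr__(self, "counts", arr)
        arr.setflags(write=False)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != arr.shape[0]:
                raise ValueError(
                    f"got {len(labels)} labels for {arr.shape[0]} categories"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def q(self) -> int:
        """Number of rating categories."""
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        """Total number of rated subjects."""
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transpose(self) -> "ContingencyTable":
        """Swap the two raters' roles."""
        return ContingencyTable(self.counts.T.copy(), self.labels)

    def permute(self, perm, *, rows: bool = True, cols: bool = True) -> "ContingencyTable":
        """Relabel categories by a permutation of 0..q-1.

        By default the same permutation is applied to both raters
        (simultaneous relabeling); either axis can be permuted alone.
        """
        perm = np.asarray(perm)
        if sorted(perm.tolist()) != list(range(self.q)):
            raise ValueError("perm must be a permutation of 0..q-1")
        arr = self.counts
        if rows:
            arr = arr[perm, :]
        if cols:
            arr = arr[:, perm]
        labels = self.labels
        if labels is not None and rows and cols:
            labels = tuple(labels[i] for i in perm)
        elif labels is not None:
            labels = None  # axis labels diverge; drop rather than mislabel
        return ContingencyTable(arr.copy(), labels)


@dataclass(frozen=True)
class ProbabilityVector:
    """Discrete distribution over q ordered categories."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("probability vector must be 1-D with length >= 2")
        if (arr < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(arr.sum() - 1.0) > PROB_TOL:
            raise ValueError(f"probabilities sum to {arr.sum()!r}, not 1")
        object.__setattr__(self, "probs", arr)
        arr.setflags(write=False)

    @property
    def q(self) -> int:
        return self.probs.size

    @classmethod
    def from_counts(cls, counts) -> "ProbabilityVector":
        arr = np.asarray(counts, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("cannot normalise an all-zero count vector")
        return cls(arr / total)


@dataclass(frozen=True)
class JointDistribution:
    """Joint distribution P_XY over rating pairs, with its marginals.

    ``probs[i, j]`` is the probability that the row rater says i and the
    column rater says j.  When built from a :class:`ContingencyTable` the
    entries are the plug-in frequencies counts / N (the observed matrix).
    """

    probs: np.ndarray
    marginal_row: ProbabilityVector = field(init=False)
    marginal_col: ProbabilityVector = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.probs, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"joint distribution must be square 2-D, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("joint probabilities must be nonnegative")
        if abs(arr.sum() - 1.0) > PROB_TOL:
            raise ValueError(f"joint probabilities sum to {arr.sum()!r}, not 1")
        object.__setattr__(self, "probs", arr)
        arr.setflags(write=False)
        object.__setattr__(self, "marginal_row", ProbabilityVector(arr.sum(axis=1)))
        object.__setattr__(self, "marginal_col", ProbabilityVector(arr.sum(axis=0)))

    @property
    def q(self) -> int:
        return self.probs.shape[0]

    def transpose(self) -> "JointDistribution":
        return JointDistribution(self.probs.T.copy())
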