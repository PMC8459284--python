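"""Graded information-theoretic degrees of monotonicity and quantity.

Each degree asks how much of the uncertainty in a quantifier's truth value
``1_Q`` (over a uniformly random structure) is removed by an auxiliary
variable: the indicator of a verifying substructure / superstructure for
monotonicity, and the count ``# = |A ∩ B|`` for quantity.  All degrees have
the form ``1 - H(1_Q | aux) / H(1_Q)`` and therefore lie in [0, 1] and do not
depend on the logarithm base (base 2 is used throughout).

A perfectly upward-monotone quantifier has degree 1 in the upward direction:
knowing that a structure has a verifying substructure removes all
uncertainty.  Constant (degenerate) quantifiers have ``H(1_Q) = 0``; by
convention every degree is then 1 — a constant function is trivially
monotone and quantitative.  The convention is isolated in
:data:`ZERO_ENTROPY_DEGREE` should the alternative be preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantifiers import (
    Quantifier,
    exists_true_substructure,
    exists_true_superstructure,
    degeneracy,
    structure_counts,
)

__all__ = [
    "MeasureResult",
    "upward_monotonicity_degree",
    "downward_monotonicity_degree",
    "monotonicity_degree",
    "quantity_degree",
    "score_table",
]

#: Degree assigned when H(1_Q) = 0, i.e. the quantifier is constant.
ZERO_ENTROPY_DEGREE = 1.0


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _binary_entropy(x: np.ndarray) -> float:
    k = int(np.count_nonzero(x))
    return _entropy_from_counts(np.array([k, x.size - k], dtype=float))


def _conditional_entropy(x: np.ndarray, cond: np.ndarray, n_classes: int) -> float:
    """H(x | cond) in bits under uniform weights; x binary, cond integer-coded."""
    joint = np.bincount(cond * 2 + x.astype(np.int64), minlength=2 * n_classes).astype(float)
    joint = joint.reshape(n_classes, 2)
    total = joint.sum()
    h = 0.0
    for row in joint:
        s = row.sum()
        if s > 0:
            h += (s / total) * _entropy_from_counts(row)
    return h


def _degree(table: np.ndarray, cond: np.ndarray, n_classes: int = 2) -> float:
    h_q = _binary_entropy(table)
    if h_q == 0.0:
        return ZERO_ENTROPY_DEGREE
    d = 1.0 - _conditional_entropy(table, cond, n_classes) / h_q
    # clamp float noise at the boundaries
    return min(1.0, max(0.0, d))


def upward_monotonicity_degree(q: Quantifier) -> float:
    """``1 - H(1_Q | 1_Q≺) / H(1_Q)`` where ``1_Q≺`` marks structures with a
    (reflexive) substructure that verifies Q.  Equals 1 iff Q is upward
    monotone or constant."""
    return _degree(q.table, exists_true_substructure(q).astype(np.int64))


def downward_monotonicity_degree(q: Quantifier) -> float:
    """Mirror of :func:`upward_monotonicity_degree` with the superstructure
    indicator ``1_Q≻``."""
    return _degree(q.table, exists_true_superstructure(q).astype(np.int64))


@dataclass(frozen=True)
class MeasureResult:
    """Combined monotonicity degree plus its directional components."""

    value: float
    upward: float
    downward: float
    entropy_bits: float


def monotonicity_degree(q: Quantifier, combination: str = "complement_max") -> MeasureResult:
    """Overall degree of monotonicity, combining the upward and downward directions.

    Combination rules (all agree on the value 1 exactly for quantifiers that
    are upward-monotone, downward-monotone, or constant):

    - ``"complement_max"`` (default): the maximum of the four degrees obtained
      by conditioning ``1_Q`` on the verifying-substructure and
      verifying-superstructure indicators of Q *and of its complement*.
      Including the complement matters for quantifiers, parity being the
      exemplar, whose own verifying-substructure indicator is constant while
      the complement's still carries information.
    - ``"max"``: max(upward, downward) of Q alone.
    - ``"mean"``: arithmetic mean of Q's upward and downward degrees.
    """
    up = upward_monotonicity_degree(q)
    down = downward_monotonicity_degree(q)
    if combination == "complement_max":
        comp = q.complement
        # H(1_Q | aux) = H(1_¬Q | aux), so conditioning the original table on
        # the complement's indicators measures ¬Q's directional degrees.
        up_c = _degree(q.table, exists_true_substructure(comp).astype(np.int64))
        down_c = _degree(q.table, exists_true_superstructure(comp).astype(np.int64))
        value = max(up, down, up_c, down_c)
    elif combination == "max":
        value = max(up, down)
    elif combination == "mean":
        value = 0.5 * (up + down)
    else:
        raise ValueError(f"unknown combination rule {combination!r}")
    return MeasureResult(value=value, upward=up, downward=down, entropy_bits=_binary_entropy(q.table))


def quantity_degree(q: Quantifier) -> float:
    """``1 - H(1_Q | #) / H(1_Q)`` with ``#`` the number of True bits.

    Equals 1 iff Q is permutation invariant (quantitative) or constant.
    """
    counts = structure_counts(q.n).astype(np.int64)
    return _degree(q.table, counts, n_classes=q.n + 1)


def score_table(q: Quantifier) -> dict[str, float]:
    """All scalar measures of one quantifier, as used in run records."""
    mon = monotonicity_degree(q)
    return {
        "upward": mon.upward,
        "downward": mon.downward,
        "monotonicity": mon.value,
        "quantity": quantity_degree(q),
        "degeneracy": degeneracy(q),
    }
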