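"""Structures, the substructure order, and quantifier truth tables.

A *structure* models the relationship between a fixed restrictor set
``A = {o_0, ..., o_{n-1}}`` and an arbitrary scope set ``B`` as a length-``n``
Boolean vector: bit ``i`` is True iff ``o_i`` belongs to ``B``.  Structures
are indexed lexicographically with False < True and the leftmost bit most
significant, so index 0 is the all-False structure and index ``2**n - 1`` is
the all-True structure.

A *quantifier* (a conservative, universe-independent determiner meaning for
the fixed ``A``) is the truth table of a Boolean function on structures: a
length-``2**n`` Boolean vector in the same index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Quantifier",
    "structure_from_index",
    "index_of_structure",
    "all_structures",
    "structure_counts",
    "is_substructure",
    "make_quantifier",
    "named_quantifier",
    "NAMED_QUANTIFIERS",
    "degeneracy",
    "is_monotone",
    "is_quantitative",
    "count_quantitative",
    "exists_true_substructure",
    "exists_true_superstructure",
]

# Full-table enumeration beyond this size is refused (2**(2**n) blowup for
# whole-space scans, 2**n tables for everything here); count-class work in
# :func:`count_quantitative` stays cheap far beyond it.
_MAX_N_TABLE = 24


def _check_n(n: int) -> None:
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"structure size n must be a positive integer, got {n!r}")
    if n > _MAX_N_TABLE:
        raise ValueError(f"structure size n={n} exceeds the supported maximum {_MAX_N_TABLE}")


def structure_from_index(i: int, n: int) -> np.ndarray:
    """Return structure ``i`` of size ``n`` as a Boolean vector.

    The leftmost bit is most significant, so ``structure_from_index(2**n - 1, n)``
    is the all-True structure.
    """
    _check_n(n)
    if not 0 <= i < 2**n:
        raise ValueError(f"structure index {i} out of range [0, {2**n}) for n={n}")
    shifts = np.arange(n - 1, -1, -1)
    return ((int(i) >> shifts) & 1).astype(bool)


def index_of_structure(bits: Sequence[bool]) -> int:
    """Inverse of :func:`structure_from_index`."""
    arr = np.asarray(bits, dtype=bool)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("a structure is a non-empty 1-D Boolean vector")
    n = arr.size
    shifts = np.arange(n - 1, -1, -1)
    return int((arr.astype(np.int64) << shifts).sum())


@lru_cache(maxsize=8)
def _structures_cached(n: int) -> np.ndarray:
    idx = np.arange(2**n, dtype=np.int64)
    shifts = np.arange(n - 1, -1, -1)
    out = ((idx[:, None] >> shifts[None, :]) & 1).astype(bool)
    out.setflags(write=False)
    return out


def all_structures(n: int) -> np.ndarray:
    """All ``2**n`` structures as a read-only ``(2**n, n)`` Boolean matrix, row ``i`` = structure ``i``."""
    _check_n(n)
    return _structures_cached(n)


@lru_cache(maxsize=8)
def _counts_cached(n: int) -> np.ndarray:
    out = _structures_cached(n).sum(axis=1)
    out.setflags(write=False)
    return out


def structure_counts(n: int) -> np.ndarray:
    """``|A ∩ B|`` (number of True bits) for every structure index, read-only."""
    _check_n(n)
    return _counts_cached(n)


def is_substructure(m1: Sequence[bool], m2: Sequence[bool]) -> bool:
    """True iff ``m1`` is a substructure of ``m2``: False everywhere ``m2`` is False.

    Equivalently the True-set of ``m1`` is contained in that of ``m2``; every
    structure is a substructure of itself.
    """
    a = np.asarray(m1, dtype=bool)
    b = np.asarray(m2, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"structures must be 1-D and of equal length, got {a.shape} and {b.shape}")
    return bool(np.all(b | ~a))


@dataclass(frozen=True)
class Quantifier:
    """Truth table of a determiner meaning on structures of size ``n``.

    ``table[i]`` is the truth value the quantifier assigns to
    ``structure_from_index(i, n)``.
    """

    table: np.ndarray
    n: int = field(default=0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=bool)
        if arr.ndim != 1 or arr.size < 2 or arr.size & (arr.size - 1):
            raise ValueError(f"quantifier table length must be a power of two >= 2, got {arr.size}")
        n = int(arr.size).bit_length() - 1
        if self.n and self.n != n:
            raise ValueError(f"table has length {arr.size} but n={self.n} was claimed")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "table", arr)
        object.__setattr__(self, "n", n)

    def __call__(self, structure: Sequence[bool]) -> bool:
        return bool(self.table[index_of_structure(structure)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Quantifier) and self.n == other.n and bool(
            np.array_equal(self.table, other.table)
        )

    def __hash__(self) -> int:
        return hash((self.n, self.table.tobytes()))

    @property
    def complement(self) -> "Quantifier":
        return Quantifier(~self.table)

    def to_bitstring(self) -> str:
        """Serialize as a string of '0'/'1' in index order."""
        return "".join("1" if b else "0" for b in self.table)

    @classmethod
    def from_bitstring(cls, s: str) -> "Quantifier":
        s = s.strip()
        if not s or set(s) - {"0", "1"}:
            raise ValueError(f"bit-string must be non-empty over '0'/'1', got {s!r}")
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) == ord("1"))


def make_quantifier(truth_condition: Callable[[np.ndarray], bool], n: int) -> Quantifier:
    """Tabulate a predicate on structures into a :class:`Quantifier`."""
    _check_n(n)
    structs = all_structures(n)
    table = np.fromiter((bool(truth_condition(m)) for m in structs), dtype=bool, count=2**n)
    return Quantifier(table)


def _from_count_predicate(pred: Callable[[np.ndarray], np.ndarray], n: int) -> Quantifier:
    return Quantifier(np.asarray(pred(structure_counts(n)), dtype=bool))


def _ultrafilter(n: int, i: int) -> Quantifier:
    if not 0 <= i < n:
        raise ValueError(f"ultrafilter index {i} out of range [0, {n})")
    return Quantifier(all_structures(n)[:, i].copy())


def _conj_ultrafilter(n: int, j: int, k: int) -> Quantifier:
    if not (0 <= j < n and 0 <= k < n) or j == k:
        raise ValueError(f"conjunction indices must be distinct and in [0, {n}), got {j}, {k}")
    s = all_structures(n)
    return Quantifier(s[:, j] & s[:, k])


def _between(n: int, lo: int, hi: int) -> Quantifier:
    if not 0 <= lo <= hi <= n:
        raise ValueError(f"need 0 <= lo <= hi <= n, got lo={lo}, hi={hi}, n={n}")
    return _from_count_predicate(lambda c: (c >= lo) & (c <= hi), n)


def _at_least(n: int, k: int) -> Quantifier:
    if not 0 <= k <= n + 1:
        raise ValueError(f"threshold k={k} out of range [0, {n + 1}]")
    return _from_count_predicate(lambda c: c >= k, n)


def _at_most(n: int, k: int) -> Quantifier:
    if not 0 <= k <= n:
        raise ValueError(f"threshold k={k} out of range [0, {n}]")
    return _from_count_predicate(lambda c: c <= k, n)


NAMED_QUANTIFIERS: dict[str, Callable[..., Quantifier]] = {
    "some": lambda n: _from_count_predicate(lambda c: c >= 1, n),
    "all": lambda n: _from_count_predicate(lambda c: c == n, n),
    "none": lambda n: _from_count_predicate(lambda c: c == 0, n),
    "at_least": _at_least,
    "at_most": _at_most,
    "between": _between,
    # parity of |A ∩ B|, with 0 counted as even
    "even": lambda n: _from_count_predicate(lambda c: c % 2 == 0, n),
    "odd": lambda n: _from_count_predicate(lambda c: c % 2 == 1, n),
    "ultrafilter": _ultrafilter,
    "conj_ultrafilter": _conj_ultrafilter,
    "const": lambda n, b: Quantifier(np.full(2**n, bool(b))),
}


def named_quantifier(name: str, n: int, *args) -> Quantifier:
    """Build a standard quantifier fixture by name.

    Examples: ``named_quantifier("some", 2)``, ``named_quantifier("between", 10, 3, 5)``,
    ``named_quantifier("ultrafilter", 3, 2)``.
    """
    _check_n(n)
    try:
        builder = NAMED_QUANTIFIERS[name]
    except KeyError:
        raise ValueError(f"unknown quantifier name {name!r}; known: {sorted(NAMED_QUANTIFIERS)}") from None
    return builder(n, *args)


def degeneracy(q: Quantifier) -> float:
    """max(share of True entries, share of False entries); 1.0 for a constant quantifier."""
    p = float(np.mean(q.table))
    return max(p, 1.0 - p)


def _as_lattice(table: np.ndarray, n: int) -> np.ndarray:
    return table.reshape((2,) * n).copy()


def exists_true_substructure(q: Quantifier) -> np.ndarray:
    """Boolean vector: entry ``i`` is True iff structure ``i`` has a (reflexive)
    substructure that the quantifier verifies.

    Computed by an OR zeta transform over the subset lattice, O(n * 2**n).
    """
    a = _as_lattice(np.asarray(q.table, bool), q.n)
    for ax in range(q.n):
        hi = [slice(None)] * q.n
        lo = [slice(None)] * q.n
        hi[ax], lo[ax] = 1, 0
        a[tuple(hi)] |= a[tuple(lo)]
    return a.reshape(-1)


def exists_true_superstructure(q: Quantifier) -> np.ndarray:
    """Mirror of :func:`exists_true_substructure` for the superstructure relation."""
    a = _as_lattice(np.asarray(q.table, bool), q.n)
    for ax in range(q.n):
        hi = [slice(None)] * q.n
        lo = [slice(None)] * q.n
        hi[ax], lo[ax] = 1, 0
        a[tuple(lo)] |= a[tuple(hi)]
    return a.reshape(-1)


def is_monotone(q: Quantifier, direction: str = "up") -> bool:
    """Binary right-monotonicity in the given direction.

    Upward: whenever ``M ⊑ M'`` and ``Q(M)``, also ``Q(M')``.  Downward is the
    mirror.  A structure lies above a verifying one exactly when it has a true
    substructure, so upward monotonicity is equivalent to the true-substructure
    indicator coinciding with the table itself.
    """
    if direction == "up":
        return bool(np.array_equal(exists_true_substructure(q), q.table))
    if direction == "down":
        return bool(np.array_equal(exists_true_superstructure(q), q.table))
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def is_quantitative(q: Quantifier) -> bool:
    """True iff the table is constant on every count class {M : |A∩B| = k}
    (permutation invariance of the quantifier)."""
    counts = structure_counts(q.n)
    t = q.table
    for k in range(q.n + 1):
        cls = t[counts == k]
        if cls.any() != cls.all():
            return False
    return True


def count_quantitative(n: int) -> tuple[int, int]:
    """(number of quantitative quantifiers, number of those that are monotone).

    A quantitative quantifier is a table on counts 0..n, so there are
    ``2**(n+1)`` of them; the monotone ones are exactly the tables that are
    non-decreasing or non-increasing in the count, counted here by
    enumerating every count table.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    if n > 20:
        raise ValueError(f"count-table enumeration supports n <= 20, got {n}")
    m = n + 1  # table length
    tables = np.arange(2**m, dtype=np.int64)
    bits = ((tables[:, None] >> np.arange(m)) & 1).astype(np.int8)
    diffs = np.diff(bits, axis=1)
    nondecreasing = (diffs >= 0).all(axis=1)
    nonincreasing = (diffs <= 0).all(axis=1)
    monotone = int((nondecreasing | nonincreasing).sum())
    return int(2**m), monotone
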