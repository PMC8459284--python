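"""Independent brute-force reference implementations used by the tests.

Everything here is written deliberately naively — explicit loops over
structures and pairs, entropies from dictionaries with ``math.log2`` — and
imports nothing from the package, so agreement with the fast implementations
is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import product


def structures_list(n: int) -> list[tuple[int, ...]]:
    """All structures of size n in lexicographic order, False < True, leftmost most significant."""
    return [tuple(bits) for bits in product((0, 1), repeat=n)]


def is_sub(m1, m2) -> bool:
    return all(b2 == 1 or b1 == 0 for b1, b2 in zip(m1, m2))


def brute_is_monotone(table, n: int, direction: str) -> bool:
    structs = structures_list(n)
    for i, mi in enumerate(structs):
        for j, mj in enumerate(structs):
            if is_sub(mi, mj):
                if direction == "up" and table[i] and not table[j]:
                    return False
                if direction == "down" and table[j] and not table[i]:
                    return False
    return True


def brute_is_quantitative(table, n: int) -> bool:
    structs = structures_list(n)
    by_count: dict[int, set] = {}
    for i, m in enumerate(structs):
        by_count.setdefault(sum(m), set()).add(bool(table[i]))
    return all(len(v) == 1 for v in by_count.values())


def _entropy(dist: dict) -> float:
    total = sum(dist.values())
    h = 0.0
    for v in dist.values():
        if v > 0:
            p = v / total
            h -= p * math.log2(p)
    return h


def _cond_entropy(pairs: list[tuple]) -> float:
    """H(first | second) from a list of (x, y) samples with uniform weight."""
    by_y: dict = {}
    for x, y in pairs:
        by_y.setdefault(y, {}).setdefault(x, 0)
        by_y[y][x] += 1
    total = len(pairs)
    h = 0.0
    for dist in by_y.values():
        h += sum(dist.values()) / total * _entropy(dist)
    return h


def _submask_indicators(table, n: int) -> tuple[list[int], list[int]]:
    """(has true substructure, has true superstructure) per structure index,
    with the reflexive order, by explicit enumeration."""
    structs = structures_list(n)
    sub_ind, sup_ind = [], []
    for m in structs:
        sub = any(table[i] for i, m2 in enumerate(structs) if is_sub(m2, m))
        sup = any(table[i] for i, m2 in enumerate(structs) if is_sub(m, m2))
        sub_ind.append(int(sub))
        sup_ind.append(int(sup))
    return sub_ind, sup_ind


def oracle_degrees(table, n: int) -> dict[str, float]:
    """up/down/combined monotonicity and quantity degrees from first principles."""
    table = [int(bool(t)) for t in table]
    hq = _entropy({0: table.count(0), 1: table.count(1)})
    if hq == 0.0:
        return {"up": 1.0, "down": 1.0, "combined": 1.0, "qua": 1.0}
    sub_ind, sup_ind = _submask_indicators(table, n)
    comp = [1 - t for t in table]
    csub, csup = _submask_indicators(comp, n)

    def deg(ind):
        return 1.0 - _cond_entropy(list(zip(table, ind))) / hq

    up, down = deg(sub_ind), deg(sup_ind)
    combined = max(up, down, deg(csub), deg(csup))
    counts = [sum(m) for m in structures_list(n)]
    qua = 1.0 - _cond_entropy(list(zip(table, counts))) / hq
    return {"up": up, "down": down, "combined": combined, "qua": qua}
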