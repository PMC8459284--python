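"""Graded monotonicity and quantity of familiar quantifiers.

Builds the truth tables of a few determiner meanings on structures of size
10 (a structure records which of the 10 objects of the restrictor set are in
the scope set) and prints each quantifier's degree of monotonicity and
quantity — one minus the normalized conditional entropy of its truth value
given, respectively, the true-sub/superstructure indicator and the size of
the intersection.  Monotone-or-constant quantifiers score exactly 1; parity
is the canonical near-zero case.
"""

from quantevo import monotonicity_degree, named_quantifier, quantity_degree, degeneracy

N = 10

QUANTIFIERS = [
    ("some", named_quantifier("some", N)),
    ("all", named_quantifier("all", N)),
    ("at least 4", named_quantifier("at_least", N, 4)),
    ("between 3 and 5", named_quantifier("between", N, 3, 5)),
    ("an even number of", named_quantifier("even", N)),
    ("ultrafilter on object 2", named_quantifier("ultrafilter", N, 2)),
]

print(f"{'quantifier':<24} {'monotonicity':>12} {'quantity':>9} {'degeneracy':>11}")
for name, q in QUANTIFIERS:
    mon = monotonicity_degree(q)
    print(f"{name:<24} {mon.value:>12.4f} {quantity_degree(q):>9.4f} {degeneracy(q):>11.4f}")
print()
print("Monotone quantifiers (some, all, at least 4, the ultrafilter) score 1.0;")
print("the count window scores in between; parity is nearly 0. Quantity is 1.0")
print("exactly for the permutation-invariant (count-based) meanings.")
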