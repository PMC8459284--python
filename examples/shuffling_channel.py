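"""The permutation channel: quantity evolves alongside monotonicity.

Identical to the plain iterated-learning run except that every training
structure's bits pass through a fresh uniform random permutation before the
child sees them.  Object identity then cannot be transmitted, so ultrafilter
("proper-noun") strategies break down and the chain is pressured toward
permutation-invariant meanings: the surviving languages are count-based
(vague thresholds) or nearly degenerate, with jointly high monotonicity and
quantity in the non-degenerate case.
"""

import numpy as np

from quantevo import ChainConfig, classify_pattern, run_chain

cfg = ChainConfig(
    n=10, population=10, bottleneck=1024, epochs=8, generations=40, master_seed=22, shuffle=True
)
snapshots = run_chain(cfg)

print("generation   mean monotonicity   mean quantity")
for snap in snapshots[::5] + [snapshots[-1]]:
    mon = np.mean([r.monotonicity for r in snap.records])
    qua = np.mean([r.quantity for r in snap.records])
    print(f"{snap.generation_index:>10}   {mon:>17.3f}   {qua:>13.3f}")

print("\nfinal-generation languages:")
for rec in snapshots[-1].records:
    label = classify_pattern(rec.quantifier).label
    print(f"  agent {rec.agent_index}: {label:<22} monotonicity {rec.monotonicity:.3f}, "
          f"quantity {rec.quantity:.3f}, degeneracy {rec.degeneracy:.3f}")
print("\nQuantity rises far above the random-agent baseline (mean ~0.05):")
print("with object identity scrambled, only count-based regularities survive")
print("transmission.")
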