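"""A single iterated-learning chain: monotone meanings take over.

Runs one chain of 40 generations at the study's default setting (structure
size 10, population 10, bottleneck 1024, 8 epochs) and prints the population
mean degree of monotonicity every few generations, then the pattern class of
every final-generation language.  Generation 0 speaks random, unstructured
languages; within a few dozen generations the population typically fixes on
single-index ("proper-noun-like") ultrafilter quantifiers, which are both
perfectly monotone and trivially learnable.
"""

import numpy as np

from quantevo import ChainConfig, classify_pattern, run_chain

cfg = ChainConfig(n=10, population=10, bottleneck=1024, epochs=8, generations=40, master_seed=21)
snapshots = run_chain(cfg)

print("generation   mean monotonicity   mean quantity   degenerate share")
for snap in snapshots[::5] + [snapshots[-1]]:
    mon = np.mean([r.monotonicity for r in snap.records])
    qua = np.mean([r.quantity for r in snap.records])
    deg = np.mean([r.degeneracy == 1.0 for r in snap.records])
    print(f"{snap.generation_index:>10}   {mon:>17.3f}   {qua:>13.3f}   {deg:>16.2f}")

print("\nfinal-generation languages:")
for rec in snapshots[-1].records:
    label = classify_pattern(rec.quantifier)
    extra = f" on object {label.indices[0]}" if label.indices else ""
    print(f"  agent {rec.agent_index}: {label.label}{extra} "
          f"(monotonicity {rec.monotonicity:.3f}, quantity {rec.quantity:.3f})")
print("\nA mean monotonicity of 1.0 with non-degenerate languages means the")
print("population has fixed on perfectly monotone meanings — compare the")
print("random-agent baseline median of about 0.15.")
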