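"""How banded alignment trades optimality for speed.

Builds a peaked 40-state model, aligns a sampled homolog fragment at
increasing band widths, and shows the banded score converging to the full
(unbanded) Viterbi score, which the forward score in turn upper-bounds.

Run:  python examples/02_alignment_and_banding.py
"""

import numpy as np

from prosaa import (banded_viterbi, forward_score, full_viterbi,
                    random_profile_hmm, sample_from_hmm, to_scoring)

model = random_profile_hmm(40, seed=3, name="BAND")
scoring = to_scoring(model)
target, _ = sample_from_hmm(model, np.random.default_rng(5))
target = target[5:30]  # a fragment, as a short read would be

full, path = full_viterbi(scoring, target)
fwd = forward_score(scoring, target)
print(f"target: {len(target)} aa  full Viterbi {full:.2f} bits  "
      f"forward {fwd:.2f} bits")
states = "".join(p[0] for p in path)
print(f"optimal parse: model {path[0][1]}..{path[-1][1]}, states {states}")

anchor = (6, 0)  # model position 6 paired with the first target residue
print(f"\nbanded scores around anchor {anchor}:")
for d in (1, 2, 4, 8, 16, 64):
    aln = banded_viterbi(scoring, target, anchor, d)
    tag = "= full" if abs(aln.score - full) < 1e-9 else ""
    print(f"  d = {d:3d}: {aln.score:8.2f} bits {tag}")
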