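"""Decide whether candidate clusters are completely captured on one read.

A cluster completely contained in a single long read must sit on a single
clone insert — the core containment criterion: one read covering >= 95% of
the region at >= 80% identity.
"""

import numpy as np

from snrcm.containment import ContainmentParams, mine_single_read_containment
from snrcm.simulate import _apply_errors
from snrcm.util import decode, encode, random_dna

rng = np.random.default_rng(7)
region = random_dna(rng, 3_000, 0.6)

# a read fully containing the region, with 5% substitution errors applied
emb, _ = _apply_errors(encode(region), {"sub": 0.05, "ins": 0.0, "del": 0.0}, rng)
containing_read = random_dna(rng, 6_000, 0.6) + decode(emb) + random_dna(rng, 6_000, 0.6)
# a read holding only the first 60% of the region
partial_read = random_dna(rng, 4_000, 0.6) + region[:1_800]

params = ContainmentParams()  # k=15, coverage >= 0.95, identity >= 0.80
for name, read in [("containing", containing_read), ("partial", partial_read)]:
    v = mine_single_read_containment(region, [(name, read)], params)
    print(f"{name:11s} call={v.call:24s} covered={v.covered_fraction:.3f} "
          f"identity={v.identity:.3f}")
# The containing read is called complete_on_single_read (coverage ~1.0,
# identity ~0.95 = 1 - error rate); the partial read stays partial.
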