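"""Plan multi-fosmid assembly of a cluster too large for one insert.

Chooses the minimal set of overlapping fosmids covering a 58 kb target
(greedy furthest-reach cover, provably minimal), then predicts the
restriction fragments a rare cutter releases from the assembled construct.
"""

import numpy as np

from snrcm.tiling import FosmidAlignment, choose_release_enzyme, find_tiling_path
from snrcm.util import random_dna

target = (8_000, 66_000)  # 58 kb cluster on the reference contig
alignments = [
    FosmidAlignment("clone_A", (2_400, 32_400)),
    FosmidAlignment("clone_B", (29_400, 59_400)),
    FosmidAlignment("clone_C", (41_700, 71_700)),
    FosmidAlignment("clone_D", (50_000, 62_000)),  # redundant, never chosen
]
path = find_tiling_path(target, alignments, min_overlap_bp=500)
print(f"tiling path: {path.clone_ids} covering {path.covered_interval}")
print(f"pairwise overlaps: {path.pairwise_overlaps_bp} bp")

# assembled construct = TAR vector + cluster, circular; pick a rare cutter
rng = np.random.default_rng(0)
construct = random_dna(rng, 15_000, 0.5) + random_dna(rng, 58_000, 0.6)
digest = choose_release_enzyme(construct)
print(f"release enzyme {digest.enzyme} ({digest.site}): "
      f"{len(digest.fragment_lengths_bp)} fragments {digest.fragment_lengths_bp} "
      f"(sum {sum(digest.fragment_lengths_bp):,} = construct {len(construct):,} bp)")
# Three clones are required (no two suffice); the digest releases two
# fragments whose lengths conserve the construct length exactly.
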