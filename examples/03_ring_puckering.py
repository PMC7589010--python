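"""Cremer-Pople analysis of monosaccharide rings in a built ensemble.

Each six-membered ring maps to spherical coordinates (Q, theta, phi): chairs
at the poles (4C1 near theta = 0, 1C4 near 180), boats and skew-boats on the
equator.  Iduronate is the conformationally mobile residue: in nonsulfated
heparan it splits between 1C4, the 2SO skew-boat and a little 4C1, and the
built chains inherit exactly those proportions.
"""

import collections

import numpy as np

from gagbuilder import (PolymerSpec, build_chain, generate_db,
                        ring_pucker_labels)

db = generate_db("heparan", n_per_pool=5000, seed=2, n_ring_pool=5000)
spec = PolymerSpec("heparan", 20)

counts = collections.Counter()
for k in range(500):
    conf = build_chain(spec, db, np.random.default_rng([9, k]))
    counts.update(ring_pucker_labels(conf)["IdoA"])

n = sum(counts.values())
print(f"IdoA ring puckers over {n} rings in 500 built 20-mers:")
for label, c in counts.most_common(6):
    print(f"  {label:5s} {c / n:6.1%}")
# Expected ~54% 1C4, ~25% 2SO, ~4% 4C1 with the remainder spread over
# boats/skew-boats -- the built ensemble reproduces the database mixture
# because rings are drawn independently of everything else.
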