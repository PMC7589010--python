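"""Build a filtered conformational ensemble of hyaluronan 20-mers.

Generates a synthetic conformer database with the solution-ensemble
statistics of hyaluronan (two glycosidic free-energy basins per linkage type,
rings overwhelmingly in the 4C1 chair), constructs chains by independent
ring/linkage sampling, relaxes each with a torsion-restrained minimization
and applies the bond-potential-energy exclusion cutoff.
"""

import numpy as np

from gagbuilder import (PolymerSpec, generate_db, generate_ensemble,
                        histogram_mode)

db = generate_db("hyaluronan", n_per_pool=1000, seed=42)
spec = PolymerSpec("hyaluronan", 20)
ens = generate_ensemble(spec, db, n_members=300, seed=7)

retained = ens.stats[ens.stats.retained]
_, mode = histogram_mode(retained.e2e, bin_width=0.5)
print(f"cutoff: {ens.cutoff.cutoff:.1f} kcal/mol "
      f"(extended-reference strain {ens.cutoff.reference_pe:.2f} + 100 buffer)")
print(f"retained {len(ens.members)} members, excluded {ens.excluded_count}")
print(f"end-to-end distance: mean {retained.e2e.mean():.1f} A, "
      f"most probable {mode:.2f} A (0.5 A bins)")
print(f"radius of gyration:  mean {retained.rg.mean():.1f} A")
print(f"post-minimization bond strain: "
      f"{retained.post_pe.mean():.1f} kcal/mol on average")
# The most probable end-to-end distance sits well below the ~99 A fully
# extended length: most chains carry a few kinks from secondary-basin
# linkage conformations, exactly the flexibility the ensemble is meant
# to capture.
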