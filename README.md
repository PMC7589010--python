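# gagbuilder

Atomic-resolution conformational ensembles of glycosaminoglycan (GAG)
polymers of arbitrary length, built by independent sampling of
monosaccharide-ring and glycosidic-linkage conformations.

GAGs — hyaluronan and the nonsulfated forms of dermatan, keratan and
heparan are built in — are linear polysaccharides of repeating disaccharide
units that can reach 200 monosaccharides.  All-atom simulation of such
polymers in explicit solvent is prohibitively expensive, but their rings and
linkages behave, to good approximation, randomly and independently.
`gagbuilder` exploits that: given a database of per-ring and per-linkage
conformations (extracted from a coordinate ensemble, or generated
synthetically with realistic solution statistics), it

1. draws a conformer for every ring and every junction independently,
2. realizes the chain in Cartesian space by internal-coordinate placement
   (every sampled bond, angle and dihedral is reproduced exactly),
3. relaxes each chain with a minimization that restrains all torsions at
   their constructed values, and
4. excludes chains whose post-minimization bond potential energy exceeds
   `E_bond(fully extended reference) + 100 kcal/mol` — geometrically
   impossible chains (overlapping bonds, a bond threading a ring) cannot
   relax under torsion restraints, so their stretched bonds betray them.

The analysis layer provides the standard descriptors: Cremer–Pople ring
puckering (Q, θ, φ) with chair/boat/skew-boat classification, glycosidic
free-energy maps ΔG(φ, ψ) = −RT ln n(φ, ψ) − k on 2.5° bins normalized to
zero at the global minimum, end-to-end distance and radius-of-gyration
distributions with most-probable values, and conditional sub-ensembles.
Audience: structural glycobiologists and molecular modellers who need
large 3-D GAG ensembles for docking, scattering-curve prediction, or
proteoglycan model building without running microsecond simulations.

## Worked example

```python
from gagbuilder import (PolymerSpec, generate_db, generate_ensemble,
                        histogram_mode)

db = generate_db("hyaluronan", n_per_pool=1000, seed=42)
ens = generate_ensemble(PolymerSpec("hyaluronan", 20), db,
                        n_members=300, seed=7)
retained = ens.stats[ens.stats.retained]
_, mode = histogram_mode(retained.e2e, bin_width=0.5)
print(ens.cutoff.cutoff, len(ens.members), ens.excluded_count, mode)
```

Running `python examples/01_build_ensemble.py` (the same computation with
printed commentary) gives:

```
cutoff: 100.6 kcal/mol (extended-reference strain 0.63 + 100 buffer)
retained 300 members, excluded 1
end-to-end distance: mean 62.3 A, most probable 59.75 A (0.5 A bins)
radius of gyration:  mean 22.0 A
post-minimization bond strain: 2.9 kcal/mol on average
```

The end-to-end distances sit well below the fully extended ~99 Å: most
chains carry a few kinks from secondary-basin linkage conformations —
exactly the backbone flexibility the ensemble is meant to capture.  (At 300
members the most-probable value is a rough estimate; `windowed_mode` gives a
stable one.)  The other examples show the free-energy-map round trip
(`02_free_energy_map.py`), ring-pucker statistics (`03_ring_puckering.py`)
and the energy screen on a planted ring-piercing defect
(`04_energy_screening.py`).

A thin CLI wraps the same library calls:

```sh
gagbuilder gen-db --gag heparan --n-per-pool 2000 --seed 1 --out hep.jsonl
gagbuilder build --gag heparan --length 200 -n 1000 --seed 1 \
    --db hep.jsonl --out-dir out/
gagbuilder analyze --pdb out/ensemble.pdb --bin-width 5 --out-dir analysis/
```

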