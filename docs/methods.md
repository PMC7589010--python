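# Methods

`gagbuilder` constructs atomic-resolution (heavy-atom) conformational
ensembles of glycosaminoglycan polymers by sampling monosaccharide-ring and
glycosidic-linkage conformations independently from a conformer database and
realizing them as Cartesian chains.  This note records the model, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Model and procedure

A polymer is a linear sequence of pyranose residues joined by glycosidic
bridges C1–O–Cn (n = 3 or 4).  Four repeat units are built in:
hyaluronan [-4GlcAβ1-3GlcNAcβ1-], nonsulfated dermatan [-4IdoAα1-3GalNAcβ1-],
nonsulfated keratan [-3Galβ1-4GlcNAcβ1-] and nonsulfated heparan
[-4IdoAα1-4GlcNAcα1-]; custom repeats follow the same machinery.  Chains are
indexed from the reducing end (free anomeric carbon, modelled with its
hydroxyl oxygen O1).

The construction algorithm:

1. **Sample.** For every residue, draw a ring conformer (internal
   coordinates of the six ring atoms and all exocyclic heavy atoms that are
   not part of a glycosidic junction) uniformly from the pool of its residue
   type; for every junction, draw a linkage conformer (C1–O and O–Cn bond
   lengths, O5–C1–O and C1–O–Cn angles, the dihedrals φ = O5-C1-O-Cn and
   ψ = C1-O-Cn-C(n−1), plus three auxiliary placement coordinates, below).
   All draws are independent — the model's core hypothesis is that rings and
   linkages behave independently in solution, so a long chain is a product of
   independent local distributions.
2. **Realize.** The first residue is rebuilt from its internal-coordinate
   record in a local frame (NeRF-style sequential placement).  At each
   junction the bridge O is placed off the acceptor ring, the donor C1 via ψ,
   the donor O5 via φ and the donor C5 via the anomeric torsion; the rest of
   the donor residue is docked rigidly onto those three anchors.  Every
   sampled internal coordinate is therefore reproduced exactly (this is
   tested to 1e-6).
3. **Relax.** A restrained minimization (below) relieves steric overlap
   while holding every placement torsion at its constructed value.
4. **Screen.** Members whose post-minimization *bond* potential energy
   exceeds `cutoff = post-minimization bond PE of the fully-extended
   reference + 100 kcal/mol` are excluded and replaced by fresh draws.
   Geometrically defective chains (overlapping bonds, or a bond threading
   another residue's ring) cannot relax under torsion restraints; their
   bonds stretch and the bond PE rises by hundreds of kcal/mol, so the
   energy screen removes them without an explicit geometry test.

### Auxiliary junction coordinates

φ, ψ, the two bridge bond lengths and the two named angles under-determine
the Cartesian reconstruction of a junction.  Three additional coordinates are
extracted and stored with each linkage conformer: the placement torsion
O-Cn-C(n−1)-C(n−2) (orients the bridge O off the acceptor ring), the angle
O-Cn-C(n−1), and the anomeric torsion C5-O5-C1-O (orients the donor ring
about its anomeric bond).  Storing them with the linkage keeps ring records
free of junction geometry; the reconstruction contract is verified by
extraction round-trips.

## Residue templates

Templates are constructed programmatically.  The six-membered ring is solved
by least squares against ideal bond lengths (C–C 1.52 Å, ring C–O 1.43 Å),
near-tetrahedral ring angles (111°, 112° at the ring oxygen) and a target
Cremer–Pople pucker: the 4C1 chair for GlcA, GlcNAc, GalNAc and Gal, the 1C4
chair for IdoA (its force-field-preferred form).  Exocyclic heavy atoms are
attached by a tetrahedral construction whose handedness sign at each
stereocenter is calibrated on the 4C1 reference frame from the standard
D-pyranose equatorial/axial table (Gal-type sugars axial at O4; IdoA the C5
epimer of GlcA).  The handedness sign is a rigid invariant, so the same
construction decorates boats and skew-boats correctly.  L-sugar anomerics:
α-L-IdoA carries the spatial C1 configuration of β-D-GlcA (C5 epimerization
never touches C1), so in the 1C4 chair its glycosidic bonds at C1 and C4 are
both axial — the well-known iduronate geometry.

The worked-example inputs (`INITIAL_DIHEDRALS`) are the classic
near-extended starting conformations: (−83.75°, −156.25°) /
(−63.75°, 118.75°) for the hyaluronan- and dermatan-type linkage pairs,
(−69°, 147°) / (77°, 30°) for heparan.  For keratan's Galβ1-4GlcNAc linkage
the first pair was determined on a 1→3 linkage, where ψ references C2; the
ψ reference carbon of a 1→4 linkage is C3, offset by 120° under the standard
proton↔heavy-atom conversions, so the table carries the equivalent
heavy-atom value ψ = +83.75°.  With these inputs the four 20-mer end-to-end
distances are reproduced to about 2% (99.0, 89.7, 85.8, 87.5 Å), which is
the level of agreement idealized templates can support; the end-to-end
endpoints are the reducing-end C1 and the nonreducing-end linkage carbon,
isolated in one function (`end_to_end_indices`) because other endpoint
conventions are plausible.

## Cremer–Pople puckering

Rings are passed in the order O5, C1, C2, C3, C4, C5.  Forward transform per
the standard sums; (Q, θ, φ) with chairs at the poles.  The label wheel
(boats at even multiples of 30° in phase, skew-boats at odd multiples) is
calibrated executably from the defining displacement patterns rather than
hard-coded.  Classification: 4C1 for θ ≤ 45°, 1C4 for θ ≥ 135°, otherwise
the nearest equator vertex (ties toward the lower phase).  The 45° band edge
is a convention; anything in (30°, 60°) separates the chair clusters from
the equator band equally well.  Envelope/half-chair fine labels are not
assigned — only chairs, boats and skew-boats are ever named here.  The
inverse transform places atoms on a circle (clockwise azimuths so the
C-P normal is +z) with the C-P out-of-plane pattern superimposed; because
the pattern contains no first harmonic, the forward transform recovers
(Q, θ, φ) exactly, making forward∘inverse an identity by construction.

## Synthetic databases

The generator emulates the statistics that microsecond explicit-solvent
simulations of GAG 20-mers produce, which is what makes the builder and the
analysis layer testable without trajectories:

- **Linkage dihedrals**: a mixture of (φ, ψ) basins with Boltzmann weights
  exp(−ΔG/RT) at T = 310 K (R = 0.0019872 kcal/mol/K) and wrapped-Gaussian
  spread σ = 15° (basin widths are not reported; 15° matches contour maps
  spanning ±30–40° at 3 kcal/mol and is documented as tunable).  Default
  basin centers and relative ΔG per GAG type are the reported 20-mer values,
  e.g. hyaluronan GlcAβ1-3GlcNAc: (−71.25°, −123.75°) at 0.00 and
  (−53.75°, 91.25°) at 3.06 kcal/mol.
- **Ring puckers**: a mixture over canonical labels realized by the inverse
  C-P transform (Q = 0.57 ± 0.03 Å, θ/φ jitter 4°/8°) and decorated with the
  template's exocyclic construction.  Heparan IdoA uses the reported
  proportions (1C4 0.54, 2SO 0.25, 4C1 0.04, remainder spread over the named
  boats/skew-boats); dermatan IdoA (0.55/0.30/0.09/0.06) and the ≥ 99.5%
  4C1 mixes for GlcNAc/GalNAc/Gal are documented assumptions consistent
  with the qualitative record.
- **Geometric jitter**: Gaussian σ = 0.02 Å on bond lengths and σ = 2° on
  exocyclic placement angles.  Ring-internal angles keep their
  pucker-consistent constructed values: independent angle noise on a
  spanning tree breaks ring closure, and the pucker sampling already
  provides the ring-shape variability.  Ring bonds are realized uniform
  (1.49 Å) by the inverse-pucker construction and relax onto their
  template equilibria during minimization.

Draws are i.i.d. — deliberately so, since the construction algorithm's
premise is conformer independence; the generator does not emulate MD time
correlation, solvent or ions, force-field-specific geometry, or any coupling
between neighboring residues.  Passing tests therefore demonstrate that the
pipeline preserves and recovers the statistical structure it samples from,
not that this structure is the true solution ensemble of any real polymer.

## Restrained potential and minimization

Energy terms (generic heavy-atom constants, not a specific force field):
harmonic bonds k_b = 300 kcal/mol/Å² around template equilibria; harmonic
angles k_θ = 60 kcal/mol/rad² around template values; harmonic restraints
k_φ = 500 kcal/mol/rad² holding every placement torsion at its value in the
input conformation; and a purely repulsive cut-and-shifted Lennard-Jones
core ε[(σ/r)¹² − 2(σ/r)⁶ + 1] for r < σ = 2.8 Å, ε = 0.15 kcal/mol, applied
to atom pairs four or more bonds apart.  The hard core matters: a bounded
soft wall (a polynomial ramp was tried first) lets a ring-piercing bond
equilibrate with only a few kcal/mol of excess strain, which defeats the
bond-stretching diagnostic; the divergent core reproduces it, while ordinary
contacts (≥ 2.3 Å) cost well under 1 kcal/mol.

The core diameter is per element pair, as the parameter design intends:
polar (O/N) pairs use 2.5 Å — their hydrogen-bonded heavy-atom contact
distance — and all other pairs 2.8 Å, so ordinary inter-residue hydrogen-bond
geometry is not penalized.

Minimization is L-BFGS with analytic gradients (a fused numba kernel; a
pure-numpy path is the fallback), converged at max |gradient| ≤ 1e-4
kcal/mol/Å or 2000 iterations.  Two robustness measures matter with a hard
core: chains built with a severe overlap start with enormous gradients that
break the Wolfe line search, so a capped-step steepest-descent pre-relaxation
(triggered above max |g| = 500 kcal/mol/Å, displacement ≤ 0.25 Å per step,
monotone in energy) clears them first; and a stall at a still-large gradient
triggers one L-BFGS restart with a fresh Hessian approximation.  The
repulsion pair list is built once from a KD-tree with a 1.2 Å margin —
positions move little under restraints.  Defect-free chains relax to < 10
kcal/mol bond PE with torsion drift ≤ 5° (typically < 0.5°); defective
chains end hundreds of kcal/mol up with larger drift, which is expected and
is exactly what the screen keys on.  On 200-mers, where independent sampling
threads a bond through a ring in roughly a tenth of the builds, almost every
excluded member carries a detector-confirmed geometric defect.

## Analysis layer

ΔG(φ, ψ) maps: 2.5° × 2.5° bins with centers at −180° + 2.5 m + 1.25°, so
reported minima like (−71.25°, −123.75°) are bin centers;
ΔG = −RT ln(n) − k with k pinning the most populated bin to exactly 0.
End-to-end distance per the endpoint convention above; radius of gyration is
mass-weighted over heavy atoms (an unweighted flag exists).  Histogram modes
use bins anchored at integer multiples of the width (0.5 Å for 20-mers,
0.25 Å for 10-mers, 5 Å for 200-mers), report the center of the
maximal-count bin, and break ties toward the lower center.  Percent
difference uses the mean denominator, |a−b|/((a+b)/2)·100 — the only form
consistent with the published table values.  The end-to-end-vs-Rg R² is an
ordinary least-squares regression.

Two low-variance companion estimators complement the raw histogram argmax,
whose location wanders by a bin or more between same-size samples whenever
the underlying density is broad (a Monte-Carlo power analysis shows the
maximal-count ΔG bin misses the true basin center by more than one bin with
probability 0.16 even at 10⁵ samples): `FreeEnergyMap.refined_minimum`
iterates a count-weighted centroid (mean shift) within a ±15° window, and
`windowed_mode` does the same for scalar distributions.  Both agree with the
argmax for sharply peaked data and estimate the mode to a fraction of a bin
otherwise; the validation suite uses them wherever a location is compared
against a reference at bin-level tolerance.

## Reproducibility

All randomness flows through numpy Generators.  Ensemble members use
counter-based streams seeded by (master seed, member index), so ensembles
are reproducible member-by-member and safe to parallelize.  Databases are
byte-identical for identical seeds.

## Problem sizes used in the test suite

The validation suite runs at desk scale, chosen as the smallest sizes at
which the statistical checks have comfortable power: conformer pools of
2,000 per type; a retained hyaluronan 20-mer ensemble of 2,500 members for
the restraint-fidelity (KS) and recovery checks (two-sample KS on ~24,000
dihedral pairs per linkage type easily resolves a 1° systematic shift);
dermatan 20-/10-mer ensembles of 2,000/1,500 members against 6,000 raw
geometric draws for the length-consistency check (dermatan's sharply peaked
end-to-end distribution is where a most-probable-value comparison has power;
bootstrap spread of the windowed mode ratio is under 2%); and a 1,000-member
hyaluronan 200-mer ensemble for the scale run and the length trend.  The
same machinery generates 10,000-member sets by changing one argument.

The fully-extended reference for long chains is found in two stages: the
homogeneous-dihedral candidate combinations (free-energy-map bin centers
within 1 kcal/mol of each basin minimum) are ranked on a 20-mer homolog,
whose helical rise orders them almost identically at any length, and the
leaders are re-scored at full length.

## Known limitations

- Heavy atoms only; hydrogen-dependent observables (NMR couplings,
  H-relative dihedral conventions) require adding hydrogens downstream.
- Idealized template geometry: bond lengths/angles are canonical values, not
  a specific biomolecular force field's equilibria, and worked-example
  distances carry ~2–3% geometry uncertainty.
- The energy model is a screen, not a thermodynamic potential: retained
  members are not re-weighted, matching the source algorithm's design.
- Sulfation, branching, and protein attachment are out of scope.
- `read_pdb_ensemble` expects files following this package's atom-naming
  conventions (it reconstructs topology from residue codes and O3/O4
  adjacency), not arbitrary glycan PDB files.
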