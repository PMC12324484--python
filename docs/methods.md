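# Methods

## Scope and model

`ligrest` treats a chemical component as an atom list (names, elements,
formal charges), a typed bond list and one Cartesian coordinate set, read
and written in the CCD `chem_comp` CIF dialect. The pipeline derives a
restraint set from that geometry, validates the geometry against reference
bond/angle distributions, and verifies by restrained minimisation that the
restraints reproduce the geometry. Quantum-chemical geometry optimisation is
deliberately outside the package: the pipeline's geometry source is a
pluggable component-in/component-out interface whose default backend passes
the input coordinates through unchanged, so any external minimiser can be
slotted in without touching the rest of the flow.

## Eligibility filters

A component enters the pipeline unless it is (in precedence order) a
single-atom entry, metal-containing, a standard residue, obsolete, or one of
the unknown-entity placeholders UNX/UNL. "Metal" is defined by a fixed
allow-list of non-metals — H, B, C, N, O, F, Si, P, S, Cl, As, Se, Br, Te, I
and the noble gases — with every other element treated as a metal. The
allow-list is a design choice (no authoritative enumeration exists for this
filtering purpose); it errs on the side of exclusion because metal
coordination cannot be described by the restraint formalism used here.

## Internal-coordinate perception

The bond graph (networkx) yields:

- **bonds** — every edge;
- **angles** — every path i–j–k, flanks ordered by name;
- **torsions** — one representative quadruple per central bond (both ends of
  degree ≥2), flanking atoms chosen heavy-before-hydrogen then
  lexicographically, **plus** one completion quadruple for each hydrogen not
  otherwise covered. The completion quads exist because riding-hydrogen
  placement needs a bond, an angle and a torsion per H; a single
  representative quad per central bond cannot cover all hydrogens of a
  methyl group. Enumeration and tie-breaking are fully deterministic.
- **planar groups** — connected clusters of sp² atoms (any double or
  aromatic bond) plus their direct substituents, accepted when the maximum
  deviation from the least-squares plane is ≤ 0.02 Å (configurable);
- **chiral centres** — atoms with four neighbours whose substituent branches
  are pairwise distinguishable. Branch identity uses a BFS-shell signature:
  remove the centre, then record the sorted element multiset of each
  shortest-path shell from the neighbour outward. Chirality is stored as the
  signed scalar triple product (Å³) of the three highest-priority
  centre→neighbour vectors rather than an R/S label, matching the restraint
  formalism; no 1/6 tetrahedron factor is applied.

Dihedrals use the right-handed (IUPAC) convention on (−180°, 180°]. Note
that under this convention the torsion is *invariant* under full reversal of
the atom order; the sign flips under mirror reflection, and both properties
are asserted in the tests (cross-checked against gemmi).

## Restraint generation

Ideals are the values measured from the input coordinates, so the generated
restraints have zero residual at the source geometry by construction — the
property the fixed-point test later verifies through the minimiser.

e.s.d. assignment:

| term | with reference entry | default |
|---|---|---|
| bond | 2 × reference s.d. | 0.02 Å |
| angle | 2 × reference s.d. | 3.0° |
| torsion (periodic) | — | 30° |
| torsion (discrete) | — | 15° |
| plane (per atom) | — | 0.02 Å |
| chiral volume | — | 0.2 Å³ |

The 2× rule reflects standard refinement practice: experimentally derived
s.d.s are too tight as refinement e.s.d.s. A matched entry whose s.d. is
zero would give an invalid e.s.d. under the 2× rule, so generation falls
back to the default there; the validation floors (below) are a separate
mechanism and are never applied to generation.

Torsion periods come from the hybridisation of the central bond, itself
derived from bond orders (any triple bond → sp, any double/aromatic → sp²,
else sp³): sp³–sp³ → 3, sp²–sp² → 2, otherwise 1. A caller-supplied
conformer list switches that torsion to **discrete** mode: the restraint
carries an explicit list of allowed ideals instead of a periodicity, for
cases where not every periodic well is a real minimum (the motivating
example being a tryptophan-like χ₂ allowed at 0°, 90°, −90° but not 180°).
The deviation of an observed torsion is the minimal wrapped distance to the
nearest well — over k·360/period offsets in periodic mode, over the listed
ideals in discrete mode.

Serialisation uses the monomer-library categories (`_chem_comp_bond`,
`_chem_comp_angle`, `_chem_comp_tor`, `_chem_comp_plane_atom`,
`_chem_comp_chir`) in a `data_comp_<ID>` block. The dialect has no
discrete-list column, so a discrete torsion is written as one row per ideal
with ids suffixed `_alt1`, `_alt2`, … and period 1; the reader groups the
suffixed rows back. The chir loop carries numeric `volume_ideal`/
`volume_esd` columns alongside the conventional `volume_sign` so round
trips are exact. The writer is deterministic (fixed float formats), so one
write normalises a file and subsequent write∘read cycles are byte-stable.

### Terminus trimming and protonation variants

For polymerisable amino-acid entities, every restraint touching the
polymerisation-terminus atoms H2, OXT or HXT is removed (planes shrink,
other terms vanish), and the atoms leave the emitted atom list; the
operation is a no-op for other component types and idempotent. For
deprotonated carboxylates (C(=O)O⁻ with a terminal singly-bonded O of
charge −1), a low-pH variant is produced with one H added per site: O–H
0.98 Å, C–O–H 106°, in the carboxyl plane and anti to the C=O. The default
policy emits a single extra variant with *all* acid sites protonated (one
low-pH entry per ligand); a combinatorial mode enumerates every non-empty
site subset. Name collisions for the added proton are resolved by appended
digits.

## Validation

Reference entries (kind, type key → ideal, s.d., n_obs) stand in for
proprietary small-molecule-database lookups and live in a plain CSV. The
type key is deterministic: per-atom token = element + degree + aromatic flag
+ sorted first-shell neighbour elements, with the bond order folded into the
bond key and into each angle arm, order-canonicalised. The first shell and
bond orders are necessary — element/degree/aromaticity alone cannot separate
a C=O from a C–O⁻ on the same carbon, and such collisions would make even a
self-referenced geometry fail to score zero.

Z = (observed − ideal)/s.d. per covered metric; metrics without reference
coverage are skipped but counted in a coverage fraction. Classification is
by max |Z| with **strict** thresholds: <2 perfect, <4 grand, <6 ok, else
fail (max |Z| exactly 2.0 is grand). Reference s.d.s below the ad-hoc floors
— 0.005 Å for bonds, 0.75° for angles — are replaced by the floor. A
geometry that passes (<6) while any metric used a floored s.d. is designated
"ok (reasonable std)" regardless of the tier its Z-scores would earn; a
floored geometry at max |Z| ≥ 6 still fails (the floors admit borderline
geometries, they do not rescue failures — this resolves an ambiguity the
scheme leaves open, and is configurable in the code). Validation restricted
to an atom subset (side-chain validation, default backbone set
{N, CA, C, O, OXT, H, H2, HA, HXT}) appends "(side chain)".

## Minimisation

The energy is a dimensionless weighted least-squares sum: for every bond,
angle, torsion, plane atom and chiral volume, ((residual)/esd)², plus a
repulsive-only nonbonded term w·max(0, r₀ − r)² between atom pairs at graph
distance ≥ 4 bonds (or in different fragments), with r₀ = 0.9 × the sum of
Bondi van der Waals radii and w = 4.0. The exclusion of 1-2/1-3/1-4 pairs
leaves those distances to the bonded terms. Angle-valued residuals are in
degrees, matching their e.s.d.s, so the coordinate gradients carry a 180/π
factor.

Gradients are analytic for every term and verified against central
differences (step 1e−5, agreement < 1e−5) on perturbed geometries of every
fixture. The plane term refits the least-squares plane at every evaluation
and differentiates with the plane parameters held fixed; because the fitted
plane minimises the same sum of squared heights that enters the energy,
this is exact (envelope theorem) whenever the atoms of one plane share an
e.s.d., which the generator always emits. The torsion gradient is smooth
within a well; the derivative is discontinuous only on the measure-zero
boundary between wells.

The driver is scipy's L-BFGS-B with the analytic Jacobian (max_iter 500,
gtol 1e−4 on the gradient infinity-norm), deterministic given its inputs;
randomness exists only in the optional start-coordinate perturbation, which
is seeded. With no active forces the minimiser returns immediately
(converged at iteration 0). `rmsd_to_start` removes rigid motion by Kabsch
superposition before measuring.

## Synthetic fixtures: what they do and do not show

The six fixtures (ethane, acetate, benzene, a tryptophan-side-chain toy, an
alanine-like dipeptide entity carrying H2/OXT/HXT, a malonate-like
dicarboxylate) are built from idealised internal coordinates — C–C 1.54 Å,
C(sp³)–C(sp²) 1.52 Å, aromatic C–C 1.39 Å, C=O 1.23 Å, carboxylate C–O
1.27 Å, C–H 1.09 Å, tetrahedral 109.47°, trigonal 120° — via deterministic
z-matrix-style placement, so output is byte-identical per name. They cover
each code path: periodic and discrete torsions, aromatic planes, a chiral
centre, terminus atoms, one and two carboxylate sites, and symmetric
environments whose reference-table pooling is exact (which is what makes
the self-validation max |Z| = 0 property testable to machine precision).

They are *not* realistic ligand geometries: no conformational strain, no
crystal-field distortion, no tautomers, no experimental noise in the
reference tables (s.d.s are set, not estimated). Passing the suite therefore
demonstrates the correctness of the machinery — measurement, typing,
classification arithmetic, serialisation, energy model and optimiser — not
the chemical accuracy of any particular restraint library built with it.
Reference tables measured from the fixtures themselves play the role of
external distribution lookups; with real data the table would come from a
curated source and coverage would be partial.

Problem sizes throughout (7–18 atoms per fixture, 3-case superposition
oracles, 200-point torsion sweeps) were chosen as the smallest sets that
exercise every branch; all suites run in seconds on one CPU.

## Known limitations

- Aromatic bond-order resolution from SMILES, tautomer enumeration and
  phosphate-specific charge handling are out of scope; SMILES strings are
  carried as annotations only.
- The hybridisation rule is bond-order-driven; exotic valences (hypervalent
  S/P, radicals) may get a period of 1 where a chemist would argue otherwise.
- Chiral-branch signatures can in principle coincide for pathological
  highly symmetric cages; for ordinary ligands they separate all genuinely
  distinct branches.
- The nonbonded model is intentionally crude (repulsive-only, fixed radii):
  it prevents collapse of unrestrained contacts but encodes no attraction
  or electrostatics.
- Only the first coordinate set of a component block is read; multi-model
  entries and the full concatenated-dictionary format are out of scope
  (callers iterate per block).
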