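# ligrest

Geometry restraints for small-molecule components in macromolecular
refinement: generation from a validated geometry, Z-score validation against
reference bond/angle distributions, and restrained re-minimisation that
verifies the restraints hold the geometry they came from.

## The problem

Macromolecular refinement leans on *a priori* chemical information: ideal
(target) values with estimated standard deviations (e.s.d.s) for bonds,
valence angles, torsions, planes and chiral volumes. Ligand entries in
CCD-style component dictionaries carry atoms, bonds and coordinates — but no
restraints — so a restraint set has to be derived from a trusted geometry
and then validated before it can be used. `ligrest` implements that
per-component pipeline for anyone building or auditing a ligand restraint
library:

- **component I/O** — read/write CCD-dialect component CIF
  (`_chem_comp_atom` / `_chem_comp_bond` loops, 1–5 character IDs) and apply
  the standard eligibility filters (single-atom entries, metal-containing
  entities, standard residues, obsolete entries, UNX/UNL unknowns);
- **restraint generation** — ideals measured from the input geometry;
  bond/angle e.s.d.s from a reference table (e.s.d. = 2 × reference s.d.,
  the usual refinement rule) or defaults; torsions periodic (period from the
  central-bond hybridisation: sp³–sp³ → 3, sp²–sp² → 2, else 1) **or
  discrete**, listing explicit allowed ideals where the periodic wells are
  not all minima (a tryptophan-like χ₂ lives at 0°, 90°, −90° but never
  180°); hydrogen restraints complete enough for riding-H placement;
  H2/OXT/HXT trimming for polymerisable amino acids; low-pH protonation
  variants of carboxylates;
- **validation** — for every covered bond/angle,
  Z = (observed − ideal)/s.d.; the geometry is classified by max |Z| with
  strict tiers **perfect** (<2), **grand** (<4), **ok** (<6), else fail;
  zero/tiny reference s.d.s are floored at 0.005 Å (bonds) and 0.75°
  (angles), and a geometry that passes only via the floors is designated
  "ok (reasonable std)"; side-chain-restricted validation appends
  "(side chain)";
- **minimisation** — weighted least-squares restraint energy
  (Σ((x−ideal)/esd)² over all term classes) with a repulsive-only nonbonded
  term, analytic gradients, and an L-BFGS driver; the fixed-point check
  (minimise from the ideal geometry, measure start→finish r.m.s.d. after
  Kabsch superposition) is the self-consistency test for a restraint file.

Synthetic fixtures (ethane, acetate, benzene, a tryptophan-side-chain toy, a
dipeptide-like entity, a dicarboxylate) and reference tables measured from
them make everything testable offline.

## Worked example

```python
from ligrest.fixtures import make_fixture, make_reference_table, perturb_coordinates
from ligrest.restraints import generate_restraints
from ligrest.validation import validate_geometry
from ligrest.minimize import EnergyModel, minimize

acetate = make_fixture("acetate")                 # CH3–COO⁻, 7 atoms
table = make_reference_table([acetate])           # self-reference table

report = validate_geometry(acetate, table)
print(report.designation, round(report.max_abs_z, 3))   # perfect 0.0

restraints = generate_restraints(acetate, reference=table)
result = minimize(acetate.coordinate_array(), restraints,
                  EnergyModel(), component=acetate)
print(round(result.rmsd_to_start, 6))                   # 0.0
```

The designation `perfect` with max |Z| = 0.0 says every measured bond and
angle sits exactly on its reference ideal; the fixed-point r.m.s.d. of 0.0 Å
says the generated restraints define an energy minimum at the geometry they
were measured from. The scripts in `examples/` walk each capability with the
numbers they print; a thin CLI (`ligrest fixtures|validate|minimize|pipeline`)
wraps the same functions for shell use.

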