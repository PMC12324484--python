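"""Enumerate protonation variants of a carboxylate-bearing ligand.

Deprotonated acid groups (C(=O)O⁻) get a low-pH variant with an added O–H
(0.98 Å, in the carboxyl plane, anti to C=O): acetate → acetic acid.
"""

from ligrest.fixtures import make_fixture
from ligrest.restraints import enumerate_protonation_variants

for name in ("acetate", "ethane", "dicarboxylate"):
    comp = make_fixture(name)
    variants = enumerate_protonation_variants(comp)
    labels = ", ".join(f"{v.variant}(q={v.net_charge():+d}, {len(v.atoms)} atoms)"
                       for v in variants)
    print(f"{name:14s} -> {labels}")

both = enumerate_protonation_variants(make_fixture("dicarboxylate"), combinatorial=True)
print(f"dicarboxylate combinatorial -> {len(both)} variants (none/site A/site B/both)")
# Default policy emits one low-pH entry per ligand (all sites protonated);
# the combinatorial flag enumerates every subset of acid sites.
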