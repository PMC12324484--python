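"""Geometry restraint construction and the monomer-library CIF dialect.

Restraints (bonds, angles, torsions, planes, chiral volumes) are built from a
validated input geometry: ideal values are measured from the coordinates,
e.s.d.s come from a reference table (twice the reference s.d., the standard
rule for refinement) or from configurable defaults.  Torsions are periodic by
default, with the period inferred from the hybridisation of the central bond;
a caller-supplied conformer list switches a torsion to discrete mode, listing
the allowed ideal values explicitly — needed where the periodic wells are not
all minima (e.g. a tryptophan chi2 at 0°, 90° and −90° but never 180°).

Hydrogen restraints are kept complete (each H has a bond, an angle and, when
a four-atom path exists, a torsion) so riding-hydrogen placement works in
refinement.  For polymerisable amino-acid entities the terminal atoms H2,
OXT and HXT are trimmed from the emitted restraints, and deprotonated
carboxylates can be enumerated into protonated variants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .components import (
    Atom,
    Bond,
    BondOrder,
    ChemicalComponent,
    ComponentIntegrityError,
    ComponentType,
)
from .geometry import (
    bond_angle,
    bond_graph,
    bond_length,
    dihedral,
    perceive_internal_coordinates,
)
from .validation import ReferenceTable, TypingContext

__all__ = [
    "BondRestraint",
    "AngleRestraint",
    "TorsionRestraint",
    "PlaneRestraint",
    "ChiralRestraint",
    "GeometryRestraints",
    "EsdDefaults",
    "generate_restraints",
    "trim_polymer_termini",
    "enumerate_protonation_variants",
    "write_restraints_cif",
    "read_restraints_cif",
    "restraints_equal",
    "POLYMER_TERMINUS_ATOMS",
]

POLYMER_TERMINUS_ATOMS = frozenset({"H2", "OXT", "HXT"})


@dataclass(frozen=True)
class BondRestraint:
    atom_1: str
    atom_2: str
    ideal: float  # Å
    esd: float  # Å

    def __post_init__(self) -> None:
        if self.esd <= 0 or self.ideal <= 0:
            raise ValueError("bond restraint requires ideal > 0 and esd > 0")

    @property
    def atoms(self) -> Tuple[str, ...]:
        return (self.atom_1, self.atom_2)


@dataclass(frozen=True)
class AngleRestraint:
    atom_1: str
    atom_2: str  # apex
    atom_3: str
    ideal: float  # degrees
    esd: float  # degrees

    def __post_init__(self) -> None:
        if self.esd <= 0:
            raise ValueError("angle restraint requires esd > 0")

    @property
    def atoms(self) -> Tuple[str, ...]:
        return (self.atom_1, self.atom_2, self.atom_3)


@dataclass(frozen=True)
class TorsionRestraint:
    id: str
    atom_1: str
    atom_2: str
    atom_3: str
    atom_4: str
    mode: str  # "periodic" | "discrete"
    esd: float  # degrees
    ideal: Optional[float] = None  # periodic mode
    ideal_list: Optional[Tuple[float, ...]] = None  # discrete mode
    period: int = 1  # periodic mode

    def __post_init__(self) -> None:
        if self.esd <= 0:
            raise ValueError("torsion restraint requires esd > 0")
        if self.mode == "periodic":
            if self.ideal is None or self.ideal_list is not None:
                raise ValueError("periodic torsion needs ideal and no ideal_list")
            if self.period < 1:
                raise ValueError("period must be ≥ 1")
        elif self.mode == "discrete":
            if self.ideal is not None or not self.ideal_list:
                raise ValueError("discrete torsion needs a non-empty ideal_list only")
            wrapped = [round(v % 360.0, 6) for v in self.ideal_list]
            if len(set(wrapped)) != len(wrapped):
                raise ValueError("discrete ideals must be pairwise distinct mod 360")
        else:
            raise ValueError(f"unknown torsion mode {self.mode!r}")

    @property
    def atoms(self) -> Tuple[str, ...]:
        return (self.atom_1, self.atom_2, self.atom_3, self.atom_4)


@dataclass(frozen=True)
class PlaneRestraint:
    id: str
    atoms: Tuple[str, ...]
    esd: float  # Å, per-atom out-of-plane deviation

    def __post_init__(self) -> None:
        if len(self.atoms) < 3:
            raise ValueError("plane restraint needs ≥ 3 atoms")
        if self.esd <= 0:
            raise ValueError("plane restraint requires esd > 0")


@dataclass(frozen=True)
class ChiralRestraint:
    id: str
    centre: str
    neighbour_1: str
    neighbour_2: str
    neighbour_3: str
    volume_ideal: float  # Å³
    esd: float  # Å³
    both_signs: bool = False

    def __post_init__(self) -> None:
        if self.esd <= 0:
            raise ValueError("chiral restraint requires esd > 0")

    @property
    def atoms(self) -> Tuple[str, ...]:
        return (self.centre, self.neighbour_1, self.neighbour_2, self.neighbour_3)


@dataclass
class GeometryRestraints:
    component_id: str
    atoms: List[Tuple[str, str]] = field(default_factory=list)  # (name, element)
    bonds: List[BondRestraint] = field(default_factory=list)
    angles: List[AngleRestraint] = field(default_factory=list)
    torsions: List[TorsionRestraint] = field(default_factory=list)
    planes: List[PlaneRestraint] = field(default_factory=list)
    chirals: List[ChiralRestraint] = field(default_factory=list)
    variant: str = "neutral"

    def all_restraints(self):
        yield from self.bonds
        yield from self.angles
        yield from self.torsions
        yield from self.planes
        yield from self.chirals

    def counts(self) -> Dict[str, int]:
        return {
            "bond": len(self.bonds),
            "angle": len(self.angles),
            "torsion": len(self.torsions),
            "plane": len(self.planes),
            "chiral": len(self.chirals),
        }

    def atoms_referenced(self) -> set:
        out = set()
        for r in self.all_restraints():
            out.update(r.atoms)
        return out


@dataclass(frozen=True)
class EsdDefaults:
    """Fallback e.s.d.s used when no reference entry covers a term.

    Bond/angle values follow conventional refinement magnitudes; the
    reference-derived path uses twice the reference s.d. instead.
    """

    bond: float = 0.02  # Å
    angle: float = 3.0  # degrees
    torsion_periodic: float = 30.0  # degrees
    torsion_discrete: float = 15.0  # degrees
    plane: float = 0.02  # Å
    chiral: float = 0.2  # Å³


def _hybridisation(component: ChemicalComponent, name: str) -> str:
    orders = [
        b.order for b in component.bonds if name in (b.atom_1, b.atom_2)
    ]
    if any(o == BondOrder.TRIPLE for o in orders):
        return "sp"
    if any(o in (BondOrder.DOUBLE, BondOrder.AROMATIC) for o in orders):
        return "sp2"
    return "sp3"


def _torsion_period(component: ChemicalComponent, j: str, k: str) -> int:
    hj = _hybridisation(component, j)
    hk = _hybridisation(component, k)
    if hj == "sp3" and hk == "sp3":
        return 3
    if hj == "sp2" and hk == "sp2":
        return 2
    return 1


def _quad_key(atoms: Sequence[str]) -> Tuple[str, ...]:
    a = tuple(atoms)
    return min(a, a[::-1])


def generate_restraints(
    component: ChemicalComponent,
    reference: Optional[ReferenceTable] = None,
    defaults: EsdDefaults = EsdDefaults(),
    discrete_torsions: Optional[Dict[Tuple[str, str, str, str], Sequence[float]]] = None,
) -> GeometryRestraints:
    """Build a full restraint set from the component's geometry.

    Ideal values are measured from the input coordinates.  Bond/angle e.s.d.s
    are twice the matching reference s.d. when the reference table covers the
    term (falling back to the defaults when it does not, or when the
    reference s.d. is zero); torsion/plane/chiral e.s.d.s come from
    *defaults*.  ``discrete_torsions`` maps a 4-atom-name tuple (either
    direction) to the list of allowed ideal values for that torsion.
    """
    if not component.has_coordinates:
        raise ComponentIntegrityError(
            f"component {component.id} has no coordinates; cannot generate restraints"
        )
    g = bond_graph(component)
    for a in component.atoms:
        if a.is_hydrogen and g.degree(a.name) == 0:
            raise ComponentIntegrityError(f"hydrogen {a.name} is disconnected")

    ics = perceive_internal_coordinates(component)
    typing = TypingContext(component)
    pos = {a.name: a.coordinates for a in component.atoms}
    discrete = {}
    if discrete_torsions:
        for quad, ideals in discrete_torsions.items():
            discrete[_quad_key(quad)] = tuple(float(v) for v in ideals)

    rs = GeometryRestraints(
        component_id=component.id,
        atoms=[(a.name, a.element) for a in component.atoms],
        variant=component.variant,
    )

    for a1, a2 in ics.bond_pairs:
        esd = defaults.bond
        if reference is not None:
            entry = reference.lookup("bond", typing.bond_key(a1, a2))
            if entry is not None and entry.sd > 0:
                esd = 2.0 * entry.sd
        rs.bonds.append(
            BondRestraint(a1, a2, bond_length(pos[a1], pos[a2]), esd)
        )

    for a1, apex, a3 in ics.angle_triples:
        esd = defaults.angle
        if reference is not None:
            entry = reference.lookup("angle", typing.angle_key(a1, apex, a3))
            if entry is not None and entry.sd > 0:
                esd = 2.0 * entry.sd
        rs.angles.append(
            AngleRestraint(a1, apex, a3, bond_angle(pos[a1], pos[apex], pos[a3]), esd)
        )

    for i, quad in enumerate(ics.torsion_quads, start=1):
        a, b, c, d = quad
        label = f"tor_{i}"
        ideals = discrete.get(_quad_key(quad))
        if ideals is not None:
            rs.torsions.append(
                TorsionRestraint(
                    label, a, b, c, d, mode="discrete",
                    ideal_list=ideals, esd=defaults.torsion_discrete,
                )
            )
        else:
            rs.torsions.append(
                TorsionRestraint(
                    label, a, b, c, d, mode="periodic",
                    ideal=dihedral(pos[a], pos[b], pos[c], pos[d]),
                    period=_torsion_period(component, b, c),
                    esd=defaults.torsion_periodic,
                )
            )

    for i, group in enumerate(ics.planar_groups, start=1):
        rs.planes.append(PlaneRestraint(f"plane_{i}", tuple(group), defaults.plane))

    for i, cc in enumerate(ics.chiral_centres, start=1):
        rs.chirals.append(
            ChiralRestraint(
                f"chir_{i}", cc.centre, cc.neighbour_1, cc.neighbour_2,
                cc.neighbour_3, cc.signed_volume, defaults.chiral,
            )
        )

    _check_hydrogen_completeness(component, rs)
    return rs


def _check_hydrogen_completeness(
    component: ChemicalComponent, rs: GeometryRestraints
) -> None:
    g = bond_graph(component)
    in_bond = {a for r in rs.bonds for a in r.atoms}
    in_angle = {a for r in rs.angles for a in r.atoms}
    in_tor = {a for r in rs.torsions for a in r.atoms}
    for atom in component.atoms:
        if not atom.is_hydrogen:
            continue
        h = atom.name
        if h not in in_bond:
            raise ComponentIntegrityError(f"hydrogen {h} lacks a bond restraint")
        parent = next(iter(g.neighbors(h)), None)
        if parent is not None and g.degree(parent) >= 2 and h not in in_angle:
            raise ComponentIntegrityError(f"hydrogen {h} lacks an angle restraint")
        # torsion required only when a 4-atom path H–parent–k–l exists
        has_path = parent is not None and any(
            any(l != parent for l in g.neighbors(k))
            for k in g.neighbors(parent)
            if k != h
        )
        if has_path and h not in in_tor:
            raise ComponentIntegrityError(f"hydrogen {h} lacks a torsion restraint")


# ---------------------------------------------------------------------------
# Terminus trimming and protonation variants
# ---------------------------------------------------------------------------

def trim_polymer_termini(
    restraints: GeometryRestraints, component: ChemicalComponent
) -> GeometryRestraints:
    """Drop restraints touching the polymerisation-terminus atoms H2/OXT/HXT.

    Applies only to polymerisable amino-acid entities (the terminal atoms are
    superfluous once the unit is linked into a chain); all other components
    pass through unchanged.  Idempotent.
    """
    if component.component_type != ComponentType.AMINO_ACID:
        return restraints
    drop = POLYMER_TERMINUS_ATOMS

    def keep(r) -> bool:
        return not (set(r.atoms) & drop)

    return GeometryRestraints(
        component_id=restraints.component_id,
        atoms=[(n, e) for n, e in restraints.atoms if n not in drop],
        bonds=[r for r in restraints.bonds if keep(r)],
        angles=[r for r in restraints.angles if keep(r)],
        torsions=[r for r in restraints.torsions if keep(r)],
        planes=[
            replace(r, atoms=tuple(a for a in r.atoms if a not in drop))
            for r in restraints.planes
            if len([a for a in r.atoms if a not in drop]) >= 3
        ],
        chirals=[r for r in restraints.chirals if keep(r)],
        variant=restraints.variant,
    )


def _carboxylate_sites(component: ChemicalComponent) -> List[Tuple[str, str, str]]:
    """Deprotonated carboxylate sites as (carbon, double-bonded O, charged O)."""
    g = bond_graph(component)
    orders = {frozenset((b.atom_1, b.atom_2)): b.order for b in component.bonds}
    sites = []
    for atom in component.atoms:
        if atom.element.upper() != "C":
            continue
        c = atom.name
        oxy = [n for n in g.neighbors(c) if component.atom(n).element.upper() == "O"]
        if len(oxy) < 2:
            continue
        dbl = [o for o in oxy if orders[frozenset((c, o))] == BondOrder.DOUBLE]
        charged = [
            o
            for o in oxy
            if orders[frozenset((c, o))] == BondOrder.SINGLE
            and component.atom(o).formal_charge == -1
            and g.degree(o) == 1
        ]
        if dbl and charged:
            sites.append((c, dbl[0], charged[0]))
    return sorted(sites)


def _place_acid_proton(
    component: ChemicalComponent, carbon: str, o_double: str, o_charged: str
) -> np.ndarray:
    """O–H 0.98 Å, C–O–H 106°, in the carboxyl plane, anti to C=O."""
    pc = component.atom(carbon).coordinates
    pd = component.atom(o_double).coordinates
    po = component.atom(o_charged).coordinates
    u = po - pc
    u /= np.linalg.norm(u)
    w = pd - pc
    w_perp = w - np.dot(w, u) * u  # in-plane component ⊥ to C–O
    w_perp /= np.linalg.norm(w_perp)
    theta = np.radians(180.0 - 106.0)  # angle from the extended C→O direction
    direction = np.cos(theta) * u - np.sin(theta) * w_perp  # anti to C=O side
    return po + 0.98 * direction


def enumerate_protonation_variants(
    component: ChemicalComponent, combinatorial: bool = False
) -> List[ChemicalComponent]:
    """Return the input plus protonated variant(s) of its carboxylates.

    Default policy: one extra variant with every deprotonated carboxylate
    protonated simultaneously (one low-pH entry per ligand).  With
    ``combinatorial=True`` every non-empty subset of sites produces a
    variant.  Components with no protonatable moiety return ``[component]``.
    """
    sites = _carboxylate_sites(component)
    if not sites:
        return [component]

    existing = {a.name for a in component.atoms}

    def protonate(subset: Sequence[Tuple[str, str, str]]) -> ChemicalComponent:
        atoms = [replace(a, coordinates=None if a.coordinates is None else a.coordinates.copy())
                 for a in component.atoms]
        bonds = list(component.bonds)
        names = set(existing)
        by_name = {a.name: a for a in atoms}
        for carbon, o_dbl, o_chg in subset:
            h_pos = (
                _place_acid_proton(component, carbon, o_dbl, o_chg)
                if component.has_coordinates
                else None
            )
            h_name = f"H{o_chg}"
            k = 1
            while h_name in names:
                h_name = f"H{o_chg}{k}"
                k += 1
            names.add(h_name)
            atoms.append(Atom(h_name, "H", 0, h_pos))
            bonds.append(Bond(o_chg, h_name, BondOrder.SINGLE))
            o_atom = by_name[o_chg]
            by_name[o_chg] = replace(o_atom, formal_charge=o_atom.formal_charge + 1)
        atoms = [by_name.get(a.name, a) for a in atoms]
        return replace(component, atoms=atoms, bonds=bonds, variant="protonated")

    variants = [component]
    if combinatorial:
        n = len(sites)
        for mask in range(1, 2 ** n):
            subset = [sites[i] for i in range(n) if mask & (1 << i)]
            variants.append(protonate(subset))
    else:
        variants.append(protonate(sites))
    return variants


# ---------------------------------------------------------------------------
# Monomer-library CIF dialect
# ---------------------------------------------------------------------------

_ALT_RE = re.compile(r"^(?P<base>.+)_alt(?P<idx>\d+)$")


def write_restraints_cif(restraints: GeometryRestraints) -> str:
    """Serialise restraints to a ``data_comp_<ID>`` monomer-library block.

    Discrete torsions are encoded as one row per ideal value with the id
    suffixed ``_alt1``, ``_alt2``, … and period 1 (the dialect has no
    discrete-list column).  The chir loop carries numeric volume columns in
    addition to the conventional sign column so round-trips are exact.
    """
    doc = gemmi.cif.Document()
    block = doc.add_new_block(f"comp_{restraints.component_id}")
    q = gemmi.cif.quote
    cid = restraints.component_id
    block.set_pair("_chem_comp.id", q(cid))
    block.set_pair("_chem_comp.ligrest_variant", q(restraints.variant))

    if restraints.atoms:
        loop = block.init_loop("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"])
        for name, element in restraints.atoms:
            loop.add_row([q(cid), q(name), q(element)])

    if restraints.bonds:
        loop = block.init_loop(
            "_chem_comp_bond.",
            ["comp_id", "atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"],
        )
        for r in restraints.bonds:
            loop.add_row([q(cid), q(r.atom_1), q(r.atom_2), f"{r.ideal:.4f}", f"{r.esd:.4f}"])

    if restraints.angles:
        loop = block.init_loop(
            "_chem_comp_angle.",
            ["comp_id", "atom_id_1", "atom_id_2", "atom_id_3",
             "value_angle", "value_angle_esd"],
        )
        for r in restraints.angles:
            loop.add_row(
                [q(cid), q(r.atom_1), q(r.atom_2), q(r.atom_3),
                 f"{r.ideal:.3f}", f"{r.esd:.3f}"]
            )

    if restraints.torsions:
        loop = block.init_loop(
            "_chem_comp_tor.",
            ["comp_id", "id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
             "value_angle", "value_angle_esd", "period"],
        )
        for r in restraints.torsions:
            if r.mode == "periodic":
                loop.add_row(
                    [q(cid), q(r.id), q(r.atom_1), q(r.atom_2), q(r.atom_3), q(r.atom_4),
                     f"{r.ideal:.3f}", f"{r.esd:.3f}", str(r.period)]
                )
            else:
                for i, v in enumerate(r.ideal_list, start=1):
                    loop.add_row(
                        [q(cid), q(f"{r.id}_alt{i}"), q(r.atom_1), q(r.atom_2),
                         q(r.atom_3), q(r.atom_4), f"{v:.3f}", f"{r.esd:.3f}", "1"]
                    )

    if restraints.planes:
        loop = block.init_loop(
            "_chem_comp_plane_atom.", ["comp_id", "plane_id", "atom_id", "dist_esd"]
        )
        for r in restraints.planes:
            for a in r.atoms:
                loop.add_row([q(cid), q(r.id), q(a), f"{r.esd:.3f}"])

    if restraints.chirals:
        loop = block.init_loop(
            "_chem_comp_chir.",
            ["comp_id", "id", "atom_id_centre", "atom_id_1", "atom_id_2", "atom_id_3",
             "volume_sign", "volume_ideal", "volume_esd"],
        )
        for r in restraints.chirals:
            sign = "both" if r.both_signs else ("positiv" if r.volume_ideal >= 0 else "negativ")
            loop.add_row(
                [q(cid), q(r.id), q(r.centre), q(r.neighbour_1), q(r.neighbour_2),
                 q(r.neighbour_3), sign, f"{r.volume_ideal:.4f}", f"{r.esd:.4f}"]
            )

    return doc.as_string(gemmi.cif.Style.Simple)


def read_restraints_cif(text: str) -> GeometryRestraints:
    """Parse a monomer-library restraints block written by this dialect.

    Torsion rows whose id carries an ``_altN`` suffix are grouped back into a
    single discrete-mode restraint; unknown categories are ignored.
    """
    doc = gemmi.cif.read_string(text)
    if len(doc) == 0:
        raise ValueError("no data block found")
    block = doc[0]
    s = gemmi.cif.as_string

    cid = block.find_value("_chem_comp.id")
    cid = s(cid) if cid else block.name.removeprefix("comp_")
    variant = block.find_value("_chem_comp.ligrest_variant")
    variant = s(variant) if variant else "neutral"

    rs = GeometryRestraints(component_id=cid, variant=variant)

    for row in block.find("_chem_comp_atom.", ["atom_id", "type_symbol"]):
        rs.atoms.append((s(row[0]), s(row[1])))

    for row in block.find(
        "_chem_comp_bond.", ["atom_id_1", "atom_id_2", "value_dist", "value_dist_esd"]
    ):
        rs.bonds.append(BondRestraint(s(row[0]), s(row[1]), float(row[2]), float(row[3])))

    for row in block.find(
        "_chem_comp_angle.",
        ["atom_id_1", "atom_id_2", "atom_id_3", "value_angle", "value_angle_esd"],
    ):
        rs.angles.append(
            AngleRestraint(s(row[0]), s(row[1]), s(row[2]), float(row[3]), float(row[4]))
        )

    discrete_rows: Dict[str, list] = {}
    tor_order: List[object] = []  # TorsionRestraint | base-id str, in file order
    for row in block.find(
        "_chem_comp_tor.",
        ["id", "atom_id_1", "atom_id_2", "atom_id_3", "atom_id_4",
         "value_angle", "value_angle_esd", "period"],
    ):
        tid = s(row[0])
        atoms = [s(row[i]) for i in (1, 2, 3, 4)]
        value, esd, period = float(row[5]), float(row[6]), int(row[7])
        m = _ALT_RE.match(tid)
        if m:
            base = m.group("base")
            if base not in discrete_rows:
                discrete_rows[base] = []
                tor_order.append(base)
            discrete_rows[base].append((int(m.group("idx")), atoms, value, esd))
        else:
            tor_order.append(
                TorsionRestraint(
                    tid, *atoms, mode="periodic", ideal=value, period=period, esd=esd
                )
            )
    for entry in tor_order:
        if isinstance(entry, TorsionRestraint):
            rs.torsions.append(entry)
        else:
            rows = sorted(discrete_rows[entry])
            rs.torsions.append(
                TorsionRestraint(
                    entry, *rows[0][1], mode="discrete",
                    ideal_list=tuple(v for _, _, v, _ in rows), esd=rows[0][3],
                )
            )

    plane_rows: Dict[str, list] = {}
    plane_order: List[str] = []
    for row in block.find("_chem_comp_plane_atom.", ["plane_id", "atom_id", "dist_esd"]):
        pid = s(row[0])
        if pid not in plane_rows:
            plane_rows[pid] = []
            plane_order.append(pid)
        plane_rows[pid].append((s(row[1]), float(row[2])))
    for pid in plane_order:
        atoms = tuple(a for a, _ in plane_rows[pid])
        rs.planes.append(PlaneRestraint(pid, atoms, plane_rows[pid][0][1]))

    for row in block.find(
        "_chem_comp_chir.",
        ["id", "atom_id_centre", "atom_id_1", "atom_id_2", "atom_id_3",
         "volume_sign", "volume_ideal", "volume_esd"],
    ):
        rs.chirals.append(
            ChiralRestraint(
                s(row[0]), s(row[1]), s(row[2]), s(row[3]), s(row[4]),
                volume_ideal=float(row[6]), esd=float(row[7]),
                both_signs=s(row[5]) == "both",
            )
        )

    return rs


def restraints_equal(a: GeometryRestraints, b: GeometryRestraints, tol: float = 5e-4) -> bool:
    """Equality with value tolerance matching the writer's printed precision."""
    if (
        a.component_id != b.component_id
        or a.variant != b.variant
        or a.atoms != b.atoms
        or a.counts() != b.counts()
    ):
        return False

    def close(x, y):
        return abs(x - y) <= tol

    for ra, rb in zip(a.bonds, b.bonds):
        if ra.atoms != rb.atoms or not close(ra.ideal, rb.ideal) or not close(ra.esd, rb.esd):
            return False
    for ra, rb in zip(a.angles, b.angles):
        if ra.atoms != rb.atoms or not close(ra.ideal, rb.ideal) or not close(ra.esd, rb.esd):
            return False
    for ra, rb in zip(a.torsions, b.torsions):
        if ra.id != rb.id or ra.atoms != rb.atoms or ra.mode != rb.mode or not close(ra.esd, rb.esd):
            return False
        if ra.mode == "periodic":
            if ra.period != rb.period or not close(ra.ideal, rb.ideal):
                return False
        else:
            if len(ra.ideal_list) != len(rb.ideal_list) or any(
                not close(x, y) for x, y in zip(ra.ideal_list, rb.ideal_list)
            ):
                return False
    for ra, rb in zip(a.planes, b.planes):
        if ra.id != rb.id or ra.atoms != rb.atoms or not close(ra.esd, rb.esd):
            return False
    for ra, rb in zip(a.chirals, b.chirals):
        if (
            ra.id != rb.id
            or ra.atoms != rb.atoms
            or ra.both_signs != rb.both_signs
            or not close(ra.volume_ideal, rb.volume_ideal)
            or not close(ra.esd, rb.esd)
        ):
            return False
    return True
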