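"""Chemical-component I/O and pipeline eligibility.

Reads and writes single-component CIF entries in the Chemical Component
Dictionary (CCD) dialect: a ``data_`` block with ``_chem_comp`` header items
and ``_chem_comp_atom`` / ``_chem_comp_bond`` loops.  Also implements the
eligibility filters applied before restraint generation: single-atom entries
(mostly metal ions), metal-containing entities, standard residues, obsolete
entries and the unknown-entity placeholders UNX/UNL are excluded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Bond",
    "BondOrder",
    "ChemicalComponent",
    "ComponentType",
    "EligibilityDecision",
    "CifParseError",
    "ComponentIntegrityError",
    "STANDARD_AMINO_ACIDS",
    "STANDARD_NUCLEOTIDES",
    "STANDARD_RESIDUE_IDS",
    "NONMETAL_ELEMENTS",
    "parse_component_cif",
    "write_component_cif",
    "assess_eligibility",
    "is_metal",
]


class CifParseError(ValueError):
    """Raised when a component CIF block is malformed."""


class ComponentIntegrityError(ValueError):
    """Raised when a component violates internal consistency (e.g. a bond
    referencing an atom absent from the atom list)."""


class BondOrder(str, enum.Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


# CCD value_order codes <-> our enum
_ORDER_FROM_CIF = {
    "SING": BondOrder.SINGLE,
    "DOUB": BondOrder.DOUBLE,
    "TRIP": BondOrder.TRIPLE,
    "AROM": BondOrder.AROMATIC,
    "SINGLE": BondOrder.SINGLE,
    "DOUBLE": BondOrder.DOUBLE,
    "TRIPLE": BondOrder.TRIPLE,
    "AROMATIC": BondOrder.AROMATIC,
}
_ORDER_TO_CIF = {
    BondOrder.SINGLE: "SING",
    BondOrder.DOUBLE: "DOUB",
    BondOrder.TRIPLE: "TRIP",
    BondOrder.AROMATIC: "AROM",
}


class ComponentType(str, enum.Enum):
    NON_POLYMER = "non-polymer"
    AMINO_ACID = "polymerisable-amino-acid"
    NUCLEIC_ACID = "polymerisable-nucleic-acid"
    SACCHARIDE = "saccharide"
    OTHER = "other"


_TYPE_TO_CIF = {
    ComponentType.NON_POLYMER: "NON-POLYMER",
    ComponentType.AMINO_ACID: "L-PEPTIDE LINKING",
    ComponentType.NUCLEIC_ACID: "RNA LINKING",
    ComponentType.SACCHARIDE: "SACCHARIDE",
    ComponentType.OTHER: "OTHER",
}


def _component_type_from_cif(text: str) -> ComponentType:
    t = text.upper()
    if "PEPTIDE" in t:
        return ComponentType.AMINO_ACID
    if "RNA" in t or "DNA" in t:
        return ComponentType.NUCLEIC_ACID
    if "SACCHARIDE" in t:
        return ComponentType.SACCHARIDE
    if t == "NON-POLYMER":
        return ComponentType.NON_POLYMER
    return ComponentType.OTHER


# Non-metal allow-list: everything outside it counts as a metal for the
# eligibility filter.  Noble gases are non-metals (single-atom noble-gas
# entries are caught by the single-atom filter first anyway).
NONMETAL_ELEMENTS = frozenset(
    {
        "H", "D", "B", "C", "N", "O", "F", "SI", "P", "S", "CL",
        "AS", "SE", "BR", "TE", "I",
        "HE", "NE", "AR", "KR", "XE", "RN",
    }
)

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
STANDARD_NUCLEOTIDES = frozenset("A C G U DA DC DG DT DU".split())
STANDARD_RESIDUE_IDS = STANDARD_AMINO_ACIDS | STANDARD_NUCLEOTIDES

_UNKNOWN_ENTITY_IDS = frozenset({"UNX", "UNL"})


def is_metal(element: str) -> bool:
    """True when *element* is treated as a metal by the eligibility filter."""
    return element.upper() not in NONMETAL_ELEMENTS


@dataclass
class Atom:
    """One atom of a component.

    ``name`` is the primary CCD atom name used as the restraint key;
    ``coordinates`` is a length-3 numpy array in Å or ``None``.
    """

    name: str
    element: str
    formal_charge: int = 0
    coordinates: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ComponentIntegrityError("atom name must be non-empty")
        if not self.element or gemmi.Element(self.element).atomic_number == 0:
            raise ComponentIntegrityError(f"unknown element symbol {self.element!r}")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (3,):
                raise ComponentIntegrityError("coordinates must be a 3-vector")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass(frozen=True)
class Bond:
    atom_1: str
    atom_2: str
    order: BondOrder = BondOrder.SINGLE

    def __post_init__(self) -> None:
        if self.atom_1 == self.atom_2:
            raise ComponentIntegrityError(
                f"bond endpoints must differ (got {self.atom_1!r} twice)"
            )

    @property
    def key(self) -> frozenset:
        return frozenset((self.atom_1, self.atom_2))


@dataclass
class ChemicalComponent:
    """A CCD-style chemical entity: atoms, bonds, coordinates, SMILES."""

    id: str
    name: str = ""
    component_type: ComponentType = ComponentType.NON_POLYMER
    atoms: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    smiles: str = ""
    obsolete: bool = False
    parent_id: Optional[str] = None
    variant: str = "neutral"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (1 <= len(self.id) <= 5) or not self.id.isalnum():
            raise ComponentIntegrityError(
                f"component id must be 1-5 alphanumeric characters, got {self.id!r}"
            )
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ComponentIntegrityError(f"duplicate atom names: {dup}")
        name_set = set(names)
        seen_pairs = set()
        for b in self.bonds:
            for end in (b.atom_1, b.atom_2):
                if end not in name_set:
                    raise ComponentIntegrityError(
                        f"bond references unknown atom {end!r}"
                    )
            if b.key in seen_pairs:
                raise ComponentIntegrityError(
                    f"duplicate bond {b.atom_1}-{b.atom_2}"
                )
            seen_pairs.add(b.key)
        with_xyz = [a for a in self.atoms if a.coordinates is not None]
        if with_xyz and len(with_xyz) != len(self.atoms):
            raise ComponentIntegrityError(
                "either all atoms must have coordinates or none"
            )

    # -- convenience accessors ------------------------------------------------

    @property
    def has_coordinates(self) -> bool:
        return bool(self.atoms) and self.atoms[0].coordinates is not None

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(name)

    def coordinate_array(self, names: Optional[Sequence[str]] = None) -> np.ndarray:
        """Coordinates stacked (n, 3), in atom-list order or the given order."""
        if not self.has_coordinates:
            raise ComponentIntegrityError(f"component {self.id} has no coordinates")
        if names is None:
            return np.stack([a.coordinates for a in self.atoms])
        return np.stack([self.atom(n).coordinates for n in names])

    def with_coordinates(self, coords: np.ndarray) -> "ChemicalComponent":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ComponentIntegrityError("coordinate array shape mismatch")
        atoms = [replace(a, coordinates=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return replace(self, atoms=atoms)

    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)


class EligibilityReason(str, enum.Enum):
    OK = "ok"
    SINGLE_ATOM = "single-atom"
    CONTAINS_METAL = "contains-metal"
    STANDARD_RESIDUE = "standard-residue"
    OBSOLETE = "obsolete"
    UNKNOWN_ENTITY = "unknown-entity"


@dataclass(frozen=True)
class EligibilityDecision:
    eligible: bool
    reason: EligibilityReason

    def __post_init__(self) -> None:
        assert self.eligible == (self.reason == EligibilityReason.OK)


def assess_eligibility(
    component: ChemicalComponent,
    standard_residue_ids: Iterable[str] = STANDARD_RESIDUE_IDS,
) -> EligibilityDecision:
    """Decide whether a component enters the restraint pipeline.

    Filters, in precedence order: single-atom entries, metal-containing
    entities, standard residues (restraints already established), obsolete
    entries, and the unknown-entity placeholders UNX/UNL.
    """
    std = {s.upper() for s in standard_residue_ids}
    if len(component.atoms) <= 1:
        return EligibilityDecision(False, EligibilityReason.SINGLE_ATOM)
    if any(is_metal(a.element) for a in component.atoms):
        return EligibilityDecision(False, EligibilityReason.CONTAINS_METAL)
    if component.id.upper() in std:
        return EligibilityDecision(False, EligibilityReason.STANDARD_RESIDUE)
    if component.obsolete:
        return EligibilityDecision(False, EligibilityReason.OBSOLETE)
    if component.id.upper() in _UNKNOWN_ENTITY_IDS:
        return EligibilityDecision(False, EligibilityReason.UNKNOWN_ENTITY)
    return EligibilityDecision(True, EligibilityReason.OK)


# ---------------------------------------------------------------------------
# CIF reading
# ---------------------------------------------------------------------------

def _loop_column(block: gemmi.cif.Block, tag: str):
    col = block.find_loop(tag)
    return list(col) if col else None


def parse_component_cif(text: str) -> ChemicalComponent:
    """Parse one CCD-style component block from CIF text.

    Expects ``_chem_comp_atom`` (atom_id, type_symbol, charge,
    model_Cartn_x/y/z) and ``_chem_comp_bond`` (atom_id_1, atom_id_2,
    value_order) loops plus ``_chem_comp`` header items.  Unrecognised
    categories are ignored.
    """
    try:
        doc = gemmi.cif.read_string(text)
    except (ValueError, RuntimeError) as exc:
        raise CifParseError(f"malformed CIF document: {exc}") from exc
    if len(doc) == 0:
        raise CifParseError("no data block found")
    block = doc[0]

    def item(tag: str, default: str = "") -> str:
        v = block.find_value(tag)
        if v is None:
            return default
        return gemmi.cif.as_string(v)

    comp_id = item("_chem_comp.id")
    if not comp_id:
        # fall back to the block name (data_<id> or data_comp_<id>)
        comp_id = block.name.removeprefix("comp_")
    comp_name = item("_chem_comp.name")
    if comp_name in ("?", "."):
        comp_name = ""
    ctype = _component_type_from_cif(item("_chem_comp.type", "OTHER"))
    obsolete = item("_chem_comp.pdbx_release_status").upper() == "OBS"
    parent = item("_chem_comp.mon_nstd_parent_comp_id") or None
    if parent in ("?", "."):
        parent = None
    variant = item("_chem_comp.ligrest_variant", "neutral")

    names = _loop_column(block, "_chem_comp_atom.atom_id")
    if names is None:
        raise CifParseError("missing _chem_comp_atom loop")
    elements = _loop_column(block, "_chem_comp_atom.type_symbol")
    if elements is None or len(elements) != len(names):
        raise CifParseError("_chem_comp_atom loop lacks consistent type_symbol column")
    charges = _loop_column(block, "_chem_comp_atom.charge") or ["0"] * len(names)
    xs = _loop_column(block, "_chem_comp_atom.model_Cartn_x")
    ys = _loop_column(block, "_chem_comp_atom.model_Cartn_y")
    zs = _loop_column(block, "_chem_comp_atom.model_Cartn_z")
    have_xyz = xs is not None and ys is not None and zs is not None

    atoms = []
    for i, nm in enumerate(names):
        nm = gemmi.cif.as_string(nm)
        el = gemmi.cif.as_string(elements[i])
        ch_raw = gemmi.cif.as_string(charges[i])
        try:
            ch = 0 if ch_raw in ("?", ".", "") else int(float(ch_raw))
        except ValueError as exc:
            raise CifParseError(
                f"_chem_comp_atom: bad charge {ch_raw!r} for atom {nm}"
            ) from exc
        coords = None
        if have_xyz and gemmi.cif.as_string(xs[i]) not in ("?", "."):
            try:
                coords = np.array(
                    [float(xs[i]), float(ys[i]), float(zs[i])], dtype=float
                )
            except ValueError as exc:
                raise CifParseError(
                    f"_chem_comp_atom: bad coordinates for atom {nm}"
                ) from exc
        atoms.append(Atom(nm, el, ch, coords))

    bonds = []
    a1s = _loop_column(block, "_chem_comp_bond.atom_id_1")
    if a1s is not None:
        a2s = _loop_column(block, "_chem_comp_bond.atom_id_2")
        orders = _loop_column(block, "_chem_comp_bond.value_order")
        if a2s is None or len(a2s) != len(a1s):
            raise CifParseError("_chem_comp_bond loop lacks atom_id_2 column")
        if orders is None:
            orders = ["SING"] * len(a1s)
        for a1, a2, o in zip(a1s, a2s, orders):
            o = gemmi.cif.as_string(o).upper()
            if o not in _ORDER_FROM_CIF:
                raise CifParseError(f"_chem_comp_bond: unknown value_order {o!r}")
            bonds.append(
                Bond(gemmi.cif.as_string(a1), gemmi.cif.as_string(a2), _ORDER_FROM_CIF[o])
            )

    smiles = item("_chem_comp.ligrest_smiles")
    if not smiles:
        # CCD stores SMILES in the descriptor loop
        dtypes = _loop_column(block, "_pdbx_chem_comp_descriptor.type")
        dvals = _loop_column(block, "_pdbx_chem_comp_descriptor.descriptor")
        if dtypes and dvals:
            by_type = {
                gemmi.cif.as_string(t).upper(): gemmi.cif.as_string(v)
                for t, v in zip(dtypes, dvals)
            }
            smiles = by_type.get("SMILES_CANONICAL", by_type.get("SMILES", ""))
    if smiles in ("?", "."):
        smiles = ""

    return ChemicalComponent(
        id=comp_id,
        name=comp_name,
        component_type=ctype,
        atoms=atoms,
        bonds=bonds,
        smiles=smiles,
        obsolete=obsolete,
        parent_id=parent,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# CIF writing
# ---------------------------------------------------------------------------

def write_component_cif(component: ChemicalComponent) -> str:
    """Serialise a component to CCD-dialect CIF text (atoms loop, then bonds).

    The output re-parses to an equal component; coordinates are written with
    four decimals, which is also the precision of equality after round-trip.
    """
    component.validate()
    doc = gemmi.cif.Document()
    block = doc.add_new_block(component.id)
    q = gemmi.cif.quote

    block.set_pair("_chem_comp.id", q(component.id))
    if component.name:
        block.set_pair("_chem_comp.name", q(component.name))
    block.set_pair("_chem_comp.type", q(_TYPE_TO_CIF[component.component_type]))
    block.set_pair(
        "_chem_comp.pdbx_release_status", "OBS" if component.obsolete else "REL"
    )
    if component.parent_id:
        block.set_pair("_chem_comp.mon_nstd_parent_comp_id", q(component.parent_id))
    if component.smiles:
        block.set_pair("_chem_comp.ligrest_smiles", q(component.smiles))
    if component.variant != "neutral":
        block.set_pair("_chem_comp.ligrest_variant", q(component.variant))

    tags = ["comp_id", "atom_id", "type_symbol", "charge"]
    if component.has_coordinates:
        tags += ["model_Cartn_x", "model_Cartn_y", "model_Cartn_z"]
    loop = block.init_loop("_chem_comp_atom.", tags)
    for a in component.atoms:
        row = [q(component.id), q(a.name), q(a.element), str(a.formal_charge)]
        if component.has_coordinates:
            row += [f"{v:.4f}" for v in a.coordinates]
        loop.add_row(row)

    if component.bonds:
        loop = block.init_loop(
            "_chem_comp_bond.", ["comp_id", "atom_id_1", "atom_id_2", "value_order"]
        )
        for b in component.bonds:
            loop.add_row([q(component.id), q(b.atom_1), q(b.atom_2), _ORDER_TO_CIF[b.order]])

    return doc.as_string(gemmi.cif.Style.Simple)


def components_equal(a: ChemicalComponent, b: ChemicalComponent, tol: float = 5e-5) -> bool:
    """Field-by-field equality with coordinate tolerance matching the
    writer's four-decimal precision."""
    if (
        a.id != b.id
        or a.name != b.name
        or a.component_type != b.component_type
        or a.smiles != b.smiles
        or a.obsolete != b.obsolete
        or a.parent_id != b.parent_id
        or a.variant != b.variant
        or len(a.atoms) != len(b.atoms)
    ):
        return False
    for x, y in zip(a.atoms, b.atoms):
        if x.name != y.name or x.element != y.element or x.formal_charge != y.formal_charge:
            return False
        if (x.coordinates is None) != (y.coordinates is None):
            return False
        if x.coordinates is not None and not np.allclose(
            x.coordinates, y.coordinates, atol=tol
        ):
            return False
    return {((b_.key), b_.order) for b_ in a.bonds} == {((b_.key), b_.order) for b_ in b.bonds}
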