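"""Deterministic synthetic components, reference tables and perturbations.

Every fixture is built from idealised internal coordinates (C–C 1.54 Å,
C=O 1.23 Å, aromatic C–C 1.39 Å, tetrahedral 109.47°, …) so the whole
pipeline is testable without downloading CCD entries.  Reference tables are
derived by measuring the fixtures themselves, standing in for Mogul/CSD
lookups.  Coordinates are exact functions of the constants — byte-identical
per fixture name — and perturbations use numpy's seeded Generator.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .components import Atom, Bond, BondOrder, ChemicalComponent, ComponentType
from .geometry import bond_angle, bond_graph, bond_length, perceive_internal_coordinates
from .validation import ReferenceEntry, ReferenceTable, TypingContext

__all__ = [
    "FIXTURE_NAMES",
    "GEOMETRY_CONSTANTS",
    "make_fixture",
    "make_reference_table",
    "perturb_coordinates",
    "place_atom",
]

# Idealised construction constants (Å, degrees)
GEOMETRY_CONSTANTS = {
    "CC_single": 1.54,
    "CC_sp3_sp2": 1.52,
    "CC_aromatic": 1.39,
    "CO_double": 1.23,
    "CO_carboxylate": 1.27,
    "CO_acid": 1.34,
    "CN_single": 1.47,
    "CH": 1.09,
    "CH_aromatic": 1.08,
    "NH": 1.01,
    "OH": 0.98,
    "tetrahedral": 109.47,
    "trigonal": 120.0,
}

_T = GEOMETRY_CONSTANTS["tetrahedral"]


def place_atom(p1, p2, p3, dist: float, angle: float, torsion: float) -> np.ndarray:
    """Position X with |X−p1| = dist, ∠(X, p1, p2) = angle and
    dihedral(X, p1, p2, p3) = torsion (degrees) — a z-matrix placement."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    b1 = p1 - p2
    b2 = p2 - p3
    n = np.cross(b2, b1)
    n /= np.linalg.norm(n)
    b1h = b1 / np.linalg.norm(b1)
    m = np.cross(n, b1h)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d = dist * np.array(
        [
            -np.cos(ang),
            np.sin(ang) * np.cos(tor),
            np.sin(ang) * np.sin(tor),
        ]
    )
    frame = np.column_stack([b1h, m, n])
    return p1 + frame @ d


def _methyl_hydrogens(carbon, axis_to, phase_deg: float, dist: float = None):
    """Three H positions on a tetrahedral carbon; *axis_to* is the heavy
    neighbour, phases at phase_deg + 0/120/240 about that axis."""
    dist = GEOMETRY_CONSTANTS["CH"] if dist is None else dist
    c = np.asarray(carbon, dtype=float)
    u = np.asarray(axis_to, dtype=float) - c
    u /= np.linalg.norm(u)
    # orthonormal frame around u
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    ang = np.radians(_T)
    out = []
    for k in range(3):
        phi = np.radians(phase_deg + 120.0 * k)
        d = np.cos(ang) * u + np.sin(ang) * (np.cos(phi) * e1 + np.sin(phi) * e2)
        out.append(c + dist * d)
    return out


def _component(cid, name, ctype, atoms, bonds) -> ChemicalComponent:
    return ChemicalComponent(
        id=cid, name=name, component_type=ctype,
        atoms=atoms, bonds=bonds,
    )


def _ethane() -> ChemicalComponent:
    cc = GEOMETRY_CONSTANTS["CC_single"]
    c1 = np.zeros(3)
    c2 = np.array([cc, 0.0, 0.0])
    h1 = _methyl_hydrogens(c1, c2, 0.0)
    h2 = _methyl_hydrogens(c2, c1, 60.0)
    atoms = [Atom("C1", "C", 0, c1), Atom("C2", "C", 0, c2)]
    atoms += [Atom(f"H1{i+1}", "H", 0, p) for i, p in enumerate(h1)]
    atoms += [Atom(f"H2{i+1}", "H", 0, p) for i, p in enumerate(h2)]
    bonds = [Bond("C1", "C2")]
    bonds += [Bond("C1", f"H1{i+1}") for i in range(3)]
    bonds += [Bond("C2", f"H2{i+1}") for i in range(3)]
    return _component("ETH0", "ethane", ComponentType.NON_POLYMER, atoms, bonds)


def _acetate() -> ChemicalComponent:
    # carboxylate carbon at origin, group in the z=0 plane
    c1 = np.zeros(3)
    c2 = np.array([GEOMETRY_CONSTANTS["CC_sp3_sp2"], 0.0, 0.0])
    ang1 = np.radians(120.0)
    ang2 = np.radians(117.0)
    o1 = c1 + GEOMETRY_CONSTANTS["CO_double"] * np.array([np.cos(ang1), np.sin(ang1), 0.0])
    o2 = c1 + GEOMETRY_CONSTANTS["CO_carboxylate"] * np.array([np.cos(ang2), -np.sin(ang2), 0.0])
    hs = _methyl_hydrogens(c2, c1, 30.0)
    atoms = [
        Atom("C1", "C", 0, c1),
        Atom("C2", "C", 0, c2),
        Atom("O1", "O", 0, o1),
        Atom("O2", "O", -1, o2),
        Atom("H21", "H", 0, hs[0]),
        Atom("H22", "H", 0, hs[1]),
        Atom("H23", "H", 0, hs[2]),
    ]
    bonds = [
        Bond("C1", "C2"),
        Bond("C1", "O1", BondOrder.DOUBLE),
        Bond("C1", "O2"),
        Bond("C2", "H21"),
        Bond("C2", "H22"),
        Bond("C2", "H23"),
    ]
    comp = _component("ACT0", "acetate", ComponentType.NON_POLYMER, atoms, bonds)
    comp.smiles = "CC(=O)[O-]"
    return comp


def _benzene() -> ChemicalComponent:
    rc = GEOMETRY_CONSTANTS["CC_aromatic"]  # ring radius equals bond length for a hexagon
    rh = rc + GEOMETRY_CONSTANTS["CH_aromatic"]
    atoms = []
    bonds = []
    for k in range(6):
        th = np.radians(60.0 * k)
        atoms.append(Atom(f"C{k+1}", "C", 0, np.array([rc * np.cos(th), rc * np.sin(th), 0.0])))
    for k in range(6):
        th = np.radians(60.0 * k)
        atoms.append(Atom(f"H{k+1}", "H", 0, np.array([rh * np.cos(th), rh * np.sin(th), 0.0])))
    for k in range(6):
        bonds.append(Bond(f"C{k+1}", f"C{(k % 6) + 2 if k < 5 else 1}", BondOrder.AROMATIC))
        bonds.append(Bond(f"C{k+1}", f"H{k+1}"))
    comp = _component("BNZ0", "benzene", ComponentType.NON_POLYMER, atoms, bonds)
    comp.smiles = "c1ccccc1"
    return comp


def _trp_sidechain() -> ChemicalComponent:
    """Side-chain toy: methyl CA – methylene CB – aromatic ring (CG..CZ),
    built with the chi2-like torsion CA–CB–CG–CD1 at 90°."""
    rc = GEOMETRY_CONSTANTS["CC_aromatic"]
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    pos: Dict[str, np.ndarray] = {}
    for k, nm in enumerate(ring_names):
        th = np.radians(60.0 * k)
        pos[nm] = np.array([rc * np.cos(th), rc * np.sin(th), 0.0])
    for nm in ring_names[1:]:
        # aromatic H radially outward
        p = pos[nm]
        pos["H" + nm[1:]] = p * ((np.linalg.norm(p) + GEOMETRY_CONSTANTS["CH_aromatic"]) / np.linalg.norm(p))
    # CB in-plane, radially outward from CG
    pg = pos["CG"]
    pos["CB"] = pg * ((rc + GEOMETRY_CONSTANTS["CC_sp3_sp2"]) / rc)
    ang_sub = 114.0
    pos["CA"] = place_atom(pos["CB"], pos["CG"], pos["CD1"], GEOMETRY_CONSTANTS["CC_single"], ang_sub, 90.0)
    pos["HB1"] = place_atom(pos["CB"], pos["CG"], pos["CD1"], GEOMETRY_CONSTANTS["CH"], 108.0, 210.0)
    pos["HB2"] = place_atom(pos["CB"], pos["CG"], pos["CD1"], GEOMETRY_CONSTANTS["CH"], 108.0, 330.0)
    for i, p in enumerate(_methyl_hydrogens(pos["CA"], pos["CB"], 15.0)):
        pos[f"HA{i+1}"] = p
    atoms = [Atom(nm, "H" if nm.startswith("H") else "C", 0, pos[nm]) for nm in pos]
    bonds = []
    for k in range(6):
        bonds.append(Bond(ring_names[k], ring_names[(k + 1) % 6], BondOrder.AROMATIC))
    for nm in ring_names[1:]:
        bonds.append(Bond(nm, "H" + nm[1:]))
    bonds += [
        Bond("CG", "CB"), Bond("CB", "CA"), Bond("CB", "HB1"), Bond("CB", "HB2"),
        Bond("CA", "HA1"), Bond("CA", "HA2"), Bond("CA", "HA3"),
    ]
    return _component("TRPSC", "tryptophan-side-chain toy", ComponentType.NON_POLYMER, atoms, bonds)


def _dipeptide_like() -> ChemicalComponent:
    """Alanine-like polymerisable entity with the terminus atoms H2, OXT, HXT."""
    K = GEOMETRY_CONSTANTS
    pos: Dict[str, np.ndarray] = {}
    pos["N"] = np.zeros(3)
    pos["CA"] = np.array([K["CN_single"], 0.0, 0.0])
    ang = np.radians(110.0)
    pos["C"] = pos["CA"] + K["CC_sp3_sp2"] * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    pos["O"] = place_atom(pos["C"], pos["CA"], pos["N"], K["CO_double"], 121.0, 0.0)
    pos["OXT"] = place_atom(pos["C"], pos["CA"], pos["N"], K["CO_acid"], 114.0, 180.0)
    pos["HXT"] = place_atom(pos["OXT"], pos["C"], pos["O"], K["OH"], 106.0, 0.0)
    pos["CB"] = place_atom(pos["CA"], pos["N"], pos["C"], K["CC_single"], 110.5, -122.0)
    pos["HA"] = place_atom(pos["CA"], pos["N"], pos["C"], K["CH"], 108.5, 118.0)
    pos["H"] = place_atom(pos["N"], pos["CA"], pos["C"], K["NH"], 109.5, 60.0)
    pos["H2"] = place_atom(pos["N"], pos["CA"], pos["C"], K["NH"], 109.5, 180.0)
    for i, p in enumerate(_methyl_hydrogens(pos["CB"], pos["CA"], 45.0)):
        pos[f"HB{i+1}"] = p
    element = {nm: ("N" if nm == "N" else "O" if nm.startswith("O") else "H" if nm.startswith("H") else "C") for nm in pos}
    atoms = [Atom(nm, element[nm], 0, pos[nm]) for nm in pos]
    bonds = [
        Bond("N", "CA"), Bond("N", "H"), Bond("N", "H2"),
        Bond("CA", "C"), Bond("CA", "CB"), Bond("CA", "HA"),
        Bond("C", "O", BondOrder.DOUBLE), Bond("C", "OXT"), Bond("OXT", "HXT"),
        Bond("CB", "HB1"), Bond("CB", "HB2"), Bond("CB", "HB3"),
    ]
    comp = _component("DPL0", "dipeptide-like entity", ComponentType.AMINO_ACID, atoms, bonds)
    comp.parent_id = "ALA"
    return comp


def _dicarboxylate() -> ChemicalComponent:
    """Malonate-like dianion: two deprotonated carboxylates on a central CH2,
    carboxyl planes perpendicular to the C–C–C plane."""
    K = GEOMETRY_CONSTANTS
    pos: Dict[str, np.ndarray] = {}
    pos["C2"] = np.zeros(3)
    pos["C1"] = np.array([K["CC_sp3_sp2"], 0.0, 0.0])
    ang = np.radians(112.0)
    pos["C3"] = K["CC_sp3_sp2"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    pos["O1"] = place_atom(pos["C1"], pos["C2"], pos["C3"], K["CO_double"], 120.0, 90.0)
    pos["O2"] = place_atom(pos["C1"], pos["C2"], pos["C3"], K["CO_carboxylate"], 117.0, -90.0)
    pos["O3"] = place_atom(pos["C3"], pos["C2"], pos["C1"], K["CO_double"], 120.0, 90.0)
    pos["O4"] = place_atom(pos["C3"], pos["C2"], pos["C1"], K["CO_carboxylate"], 117.0, -90.0)
    # methylene H's on the exact external bisector so both H–C–C(carboxyl)
    # angles are identical by symmetry
    u1 = pos["C1"] / np.linalg.norm(pos["C1"])
    u3 = pos["C3"] / np.linalg.norm(pos["C3"])
    bis = -(u1 + u3)
    bis /= np.linalg.norm(bis)
    norm = np.cross(u1, u3)
    norm /= np.linalg.norm(norm)
    beta = np.radians(_T / 2.0)
    pos["H21"] = pos["C2"] + K["CH"] * (np.cos(beta) * bis + np.sin(beta) * norm)
    pos["H22"] = pos["C2"] + K["CH"] * (np.cos(beta) * bis - np.sin(beta) * norm)
    charges = {"O2": -1, "O4": -1}
    atoms = [
        Atom(nm, "O" if nm.startswith("O") else "H" if nm.startswith("H") else "C",
             charges.get(nm, 0), pos[nm])
        for nm in pos
    ]
    bonds = [
        Bond("C2", "C1"), Bond("C2", "C3"), Bond("C2", "H21"), Bond("C2", "H22"),
        Bond("C1", "O1", BondOrder.DOUBLE), Bond("C1", "O2"),
        Bond("C3", "O3", BondOrder.DOUBLE), Bond("C3", "O4"),
    ]
    comp = _component("MLN0", "dicarboxylate toy", ComponentType.NON_POLYMER, atoms, bonds)
    comp.smiles = "C(C(=O)[O-])C(=O)[O-]"
    return comp


_BUILDERS = {
    "ethane": _ethane,
    "acetate": _acetate,
    "benzene": _benzene,
    "trp_sidechain": _trp_sidechain,
    "dipeptide_like": _dipeptide_like,
    "dicarboxylate": _dicarboxylate,
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))


def make_fixture(name: str) -> ChemicalComponent:
    """Build the named synthetic component (deterministic per name)."""
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None
    return builder()


def make_reference_table(
    components: Iterable[ChemicalComponent],
    sd_bond: float = 0.01,
    sd_angle: float = 1.5,
    zero_sd_keys: Optional[Set[str]] = None,
) -> ReferenceTable:
    """Synthetic reference table measured from the given components.

    One entry per distinct type key with ideal = mean measured value,
    s.d. as given (zero for keys listed in *zero_sd_keys*, to exercise the
    validation floors) and n_obs = occurrence count.
    """
    zero_sd_keys = zero_sd_keys or set()
    sums: Dict[tuple, List[float]] = {}
    for comp in components:
        ics = perceive_internal_coordinates(comp)
        typing = TypingContext(comp)
        for a1, a2 in ics.bond_pairs:
            key = ("bond", typing.bond_key(a1, a2))
            sums.setdefault(key, []).append(
                bond_length(comp.atom(a1).coordinates, comp.atom(a2).coordinates)
            )
        for a1, apex, a3 in ics.angle_triples:
            key = ("angle", typing.angle_key(a1, apex, a3))
            sums.setdefault(key, []).append(
                bond_angle(
                    comp.atom(a1).coordinates,
                    comp.atom(apex).coordinates,
                    comp.atom(a3).coordinates,
                )
            )
    table = ReferenceTable()
    for (kind, type_key), values in sorted(sums.items()):
        sd = 0.0 if type_key in zero_sd_keys else (sd_bond if kind == "bond" else sd_angle)
        table.add(
            ReferenceEntry(kind=kind, type_key=type_key, ideal=float(np.mean(values)),
                           sd=sd, n_obs=len(values))
        )
    return table


def perturb_coordinates(
    component: ChemicalComponent, sigma: float, seed: int
) -> np.ndarray:
    """Coordinates displaced by i.i.d. Gaussian noise of the given σ (Å);
    reproducible per seed, identity at σ = 0."""
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    coords = component.coordinate_array()
    if sigma == 0:
        return coords
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, sigma, size=coords.shape)
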