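"""Geometry measurements, internal-coordinate perception and superposition.

Angles are in degrees throughout; dihedrals follow the IUPAC right-handed
sign convention on (−180, 180].  Internal-coordinate perception walks the
bond graph (networkx) to enumerate bond pairs, angle triples, torsion
quadruples, planar groups and chiral centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .components import ChemicalComponent, ComponentIntegrityError

__all__ = [
    "DegenerateGeometryError",
    "InternalCoordinateSet",
    "bond_length",
    "bond_angle",
    "dihedral",
    "bond_graph",
    "perceive_internal_coordinates",
    "superpose_rmsd",
    "best_fit_plane",
]

PLANE_TOLERANCE = 0.02  # Å, max out-of-plane deviation accepted for a planar group


class DegenerateGeometryError(ValueError):
    """Zero-length arm or collinear triple where an angle/dihedral is undefined."""


def bond_length(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(b - a))


def bond_angle(a, b, c) -> float:
    """Angle at apex *b* in degrees, in [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length arm in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Signed torsion about b–c in degrees, right-handed, in (−180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 == 0.0 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear atoms in dihedral")
    ang = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


@dataclass
class ChiralCentre:
    centre: str
    neighbour_1: str
    neighbour_2: str
    neighbour_3: str
    signed_volume: float  # Å³, scalar triple product of centre→neighbour vectors


@dataclass
class InternalCoordinateSet:
    bond_pairs: List[Tuple[str, str]] = field(default_factory=list)
    angle_triples: List[Tuple[str, str, str]] = field(default_factory=list)
    torsion_quads: List[Tuple[str, str, str, str]] = field(default_factory=list)
    planar_groups: List[List[str]] = field(default_factory=list)
    chiral_centres: List[ChiralCentre] = field(default_factory=list)


def bond_graph(component: ChemicalComponent) -> nx.Graph:
    g = nx.Graph()
    for a in component.atoms:
        g.add_node(a.name, element=a.element.upper(), is_h=a.is_hydrogen)
    for b in component.bonds:
        g.add_edge(b.atom_1, b.atom_2, order=b.order)
    return g


def _sp2_atoms(component: ChemicalComponent) -> set:
    """Atoms flagged sp2: endpoint of any double or aromatic bond."""
    out = set()
    for b in component.bonds:
        if b.order.value in ("double", "aromatic"):
            out.add(b.atom_1)
            out.add(b.atom_2)
    return out


def best_fit_plane(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through ≥3 points: returns (unit normal, centroid)."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return vt[-1], centroid


def _flank_priority(g: nx.Graph, name: str) -> Tuple[int, str]:
    # heavy atoms before hydrogens, then lexicographic by name
    return (1 if g.nodes[name]["is_h"] else 0, name)


def _branch_signature(g: nx.Graph, centre: str, start: str) -> tuple:
    """Deterministic signature of the substituent branch rooted at *start*
    when the centre atom is removed: per-BFS-shell sorted element multisets."""
    h = g.copy()
    h.remove_node(centre)
    dist = nx.single_source_shortest_path_length(h, start)
    shells: Dict[int, list] = {}
    for node, d in dist.items():
        shells.setdefault(d, []).append(g.nodes[node]["element"])
    return tuple(tuple(sorted(shells[d])) for d in sorted(shells))


def perceive_internal_coordinates(
    component: ChemicalComponent, plane_tolerance: float = PLANE_TOLERANCE
) -> InternalCoordinateSet:
    """Enumerate internal coordinates from the bond graph and coordinates.

    - bonds: every bond, endpoints in name order;
    - angles: every bonded path i–j–k with i < k by name;
    - torsions: one representative quadruple per central bond, flanking atoms
      chosen heavy-before-hydrogen then lexicographic, plus one completion
      quadruple for each hydrogen not already covered (hydrogen completeness
      requires a torsion per H for riding-hydrogen placement);
    - planar groups: connected clusters of sp2/aromatic atoms plus direct
      substituents, accepted when the max out-of-plane deviation is within
      ``plane_tolerance``;
    - chiral centres: atoms with four neighbours whose branch signatures are
      pairwise distinct; volume is the signed triple product at the input
      coordinates.
    """
    if not component.has_coordinates:
        raise ComponentIntegrityError(
            f"component {component.id} lacks coordinates for perception"
        )
    g = bond_graph(component)
    ics = InternalCoordinateSet()

    for b in component.bonds:
        pair = tuple(sorted((b.atom_1, b.atom_2)))
        ics.bond_pairs.append(pair)
    ics.bond_pairs.sort()

    for j in sorted(g.nodes):
        nbrs = sorted(g.neighbors(j))
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                ics.angle_triples.append((nbrs[x], j, nbrs[y]))
    ics.angle_triples.sort(key=lambda t: (t[1], t[0], t[2]))

    # torsions: representative quad per central bond + hydrogen completion
    covered_h = set()
    quads: List[Tuple[str, str, str, str]] = []

    def add_quad(i, j, k, l):
        if (i, j, k, l) in quads or (l, k, j, i) in quads:
            return
        quads.append((i, j, k, l))
        for nm in (i, l):
            if g.nodes[nm]["is_h"]:
                covered_h.add(nm)

    central = []
    for j, k in sorted(tuple(sorted(e)) for e in g.edges):
        if g.degree(j) >= 2 and g.degree(k) >= 2:
            central.append((j, k))
    for j, k in central:
        flanks_j = sorted((n for n in g.neighbors(j) if n != k), key=lambda n: _flank_priority(g, n))
        flanks_k = sorted((n for n in g.neighbors(k) if n != j), key=lambda n: _flank_priority(g, n))
        if flanks_j and flanks_k:
            add_quad(flanks_j[0], j, k, flanks_k[0])
    # completion quads for hydrogens not yet sitting in any torsion
    for h in sorted(n for n in g.nodes if g.nodes[n]["is_h"]):
        if h in covered_h:
            continue
        parents = list(g.neighbors(h))
        if not parents:
            continue
        j = parents[0]
        for k in sorted((n for n in g.neighbors(j) if n != h), key=lambda n: _flank_priority(g, n)):
            flanks_k = sorted(
                (n for n in g.neighbors(k) if n != j), key=lambda n: _flank_priority(g, n)
            )
            if flanks_k:
                add_quad(h, j, k, flanks_k[0])
                break
    ics.torsion_quads = quads

    # planar groups
    sp2 = _sp2_atoms(component)
    sp2_sub = g.subgraph(sp2)
    for cluster in nx.connected_components(sp2_sub):
        group = set(cluster)
        for a in cluster:
            group.update(g.neighbors(a))
        if len(group) < 3:
            continue
        names = sorted(group)
        coords = component.coordinate_array(names)
        normal, centroid = best_fit_plane(coords)
        dev = np.abs((coords - centroid) @ normal)
        if dev.max() <= plane_tolerance:
            ics.planar_groups.append(names)
    ics.planar_groups.sort()

    # chiral centres
    for c in sorted(g.nodes):
        nbrs = sorted(g.neighbors(c), key=lambda n: _flank_priority(g, n))
        if len(nbrs) != 4:
            continue
        sigs = [_branch_signature(g, c, n) for n in nbrs]
        if len(set(sigs)) != 4:
            continue
        n1, n2, n3 = nbrs[:3]
        pc = component.atom(c).coordinates
        v1 = component.atom(n1).coordinates - pc
        v2 = component.atom(n2).coordinates - pc
        v3 = component.atom(n3).coordinates - pc
        vol = float(np.dot(v1, np.cross(v2, v3)))
        ics.chiral_centres.append(ChiralCentre(c, n1, n2, n3, vol))

    return ics


def superpose_rmsd(reference: np.ndarray, moving: np.ndarray) -> dict:
    """Optimal rigid-body superposition (Kabsch) of *moving* onto *reference*.

    Returns ``{"rmsd", "rotation", "translation"}`` where
    ``rotation @ (moving - centroid_m) + translation`` best matches
    *reference* in the least-squares sense; rotation is proper (det +1).
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(moving, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 1:
        raise ValueError("coordinate sets must both be (n, 3) with matched n ≥ 1")
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    p = ref - cr
    q = mov - cm
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = (rot @ q.T).T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return {"rmsd": rmsd, "rotation": rot, "translation": cr - rot @ cm}
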