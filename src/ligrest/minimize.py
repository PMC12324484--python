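"""Restrained geometry minimisation.

The energy is a weighted least-squares sum over the restraint terms — each
residual divided by its e.s.d., squared — plus a purely repulsive quadratic
nonbonded term between atom pairs four or more bonds apart (or in different
fragments).  Minimising from the ideal geometry of the restraints themselves
is the self-consistency check: restraints generated from a geometry should
hold that geometry in place (small r.m.s.d. between start and finish).

Angle-valued terms are evaluated in degrees, matching the units of their
e.s.d.s.  Gradients are analytic for every term; the plane term holds the
instantaneous best-fit plane fixed, which is exact (envelope theorem) when
all atoms of a plane share one e.s.d., as the generator emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import scipy.optimize

from .components import ChemicalComponent
from .geometry import best_fit_plane, bond_graph, superpose_rmsd
from .restraints import GeometryRestraints, TorsionRestraint

__all__ = [
    "EnergyModel",
    "MinimizationResult",
    "DEFAULT_RADII",
    "residual_energy",
    "torsion_deviation",
    "minimize",
    "nonbonded_pairs",
]

_RAD = np.pi / 180.0

# Bondi van der Waals radii (Å); the nonbonded contact distance is the
# radius sum scaled by EnergyModel.nonbonded_scale.
DEFAULT_RADII: Dict[str, float] = {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "B": 1.92,
    "SI": 2.10, "SE": 1.90, "AS": 1.85, "TE": 2.06,
}
_DEFAULT_RADIUS = 1.70


@dataclass
class EnergyModel:
    """Weights and the repulsive-only nonbonded model.

    Term weights are 1/esd² (set per restraint); the nonbonded term is
    ``weight · max(0, r₀ − r)²`` with r₀ the scaled sum of element radii.
    """

    nonbonded_weight: float = 4.0
    nonbonded_scale: float = 0.9
    radii: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RADII))
    min_bond_separation: int = 4  # pairs this many bonds apart (or more) interact

    def radius(self, element: str) -> float:
        return self.radii.get(element.upper(), _DEFAULT_RADIUS)


@dataclass
class MinimizationResult:
    final_coordinates: np.ndarray
    iterations: int
    final_residual: float
    rmsd_to_start: float
    converged: bool


def _wrap(angle: float) -> float:
    """Wrap degrees to (−180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return a


def torsion_deviation(observed: float, restraint: TorsionRestraint) -> float:
    """Minimal absolute deviation (degrees) of *observed* from the nearest
    allowed torsion well — periodic wells every 360/period or the discrete
    ideal list."""
    return abs(_signed_torsion_deviation(observed, restraint))


def _signed_torsion_deviation(observed: float, restraint: TorsionRestraint) -> float:
    if restraint.mode == "periodic":
        step = 360.0 / restraint.period
        base = _wrap(observed - restraint.ideal)
        # nearest multiple of the well spacing
        k = round(base / step)
        return _wrap(base - k * step)
    best = None
    for v in restraint.ideal_list:
        d = _wrap(observed - v)
        if best is None or abs(d) < abs(best):
            best = d
    return best


def nonbonded_pairs(
    component: ChemicalComponent, model: EnergyModel
) -> List[Tuple[int, int, float]]:
    """Pairs (i, j, r₀) subject to the repulsive term: graph distance ≥
    ``min_bond_separation`` bonds, or in different connected fragments."""
    g = bond_graph(component)
    names = [a.name for a in component.atoms]
    index = {n: i for i, n in enumerate(names)}
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=model.min_bond_separation - 1))
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ni, nj = names[i], names[j]
            if nj in dist.get(ni, {}):
                continue  # within the bonded exclusion range
            r0 = model.nonbonded_scale * (
                model.radius(component.atoms[i].element)
                + model.radius(component.atoms[j].element)
            )
            pairs.append((index[ni], index[nj], r0))
    return pairs


# -- analytic gradient helpers ----------------------------------------------

def _angle_and_grad(a, b, c):
    """Angle at apex b in degrees and gradients (deg/Å) wrt a, b, c."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    uh = u / nu
    vh = v / nv
    cos_t = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sin_t = max(np.sqrt(1.0 - cos_t * cos_t), 1e-8)
    theta = np.degrees(np.arccos(cos_t))
    ga = (cos_t * uh - vh) / (nu * sin_t) / _RAD
    gc = (cos_t * vh - uh) / (nv * sin_t) / _RAD
    return theta, ga, -(ga + gc), gc


def _dihedral_and_grad(a, b, c, d):
    """Signed dihedral (degrees, (−180, 180]) and gradients (deg/Å)."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq = np.dot(n1, n1)
    n2sq = np.dot(n2, n2)
    phi = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2), np.dot(n1, n2)))
    if phi <= -180.0:
        phi += 360.0
    ga = -(nb2 / n1sq) * n1
    gd = (nb2 / n2sq) * n2
    s12 = np.dot(b1, b2) / (nb2 * nb2)
    s32 = np.dot(b3, b2) / (nb2 * nb2)
    gb = -(1.0 + s12) * ga + s32 * gd
    gc = s12 * ga - (1.0 + s32) * gd
    return phi, ga / _RAD, gb / _RAD, gc / _RAD, gd / _RAD


def residual_energy(
    coordinates: np.ndarray,
    restraints: GeometryRestraints,
    model: EnergyModel,
    component: Optional[ChemicalComponent] = None,
    _nb_pairs: Optional[List[Tuple[int, int, float]]] = None,
) -> Tuple[float, np.ndarray]:
    """Weighted least-squares restraint energy and its analytic gradient.

    *coordinates* is (n, 3) in the order of ``restraints.atoms``.  The
    nonbonded term needs the bond graph, so pass *component* (or precomputed
    ``_nb_pairs``); without either, only bonded terms are evaluated.
    """
    x = np.asarray(coordinates, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite coordinates")
    index = {name: i for i, (name, _el) in enumerate(restraints.atoms)}
    energy = 0.0
    grad = np.zeros_like(x)

    def p(name: str) -> np.ndarray:
        return x[index[name]]

    for r in restraints.bonds:
        i, j = index[r.atom_1], index[r.atom_2]
        d = x[j] - x[i]
        dist = np.linalg.norm(d)
        dev = (dist - r.ideal) / r.esd
        energy += dev * dev
        gvec = (2.0 * dev / r.esd) * (d / dist)
        grad[j] += gvec
        grad[i] -= gvec

    for r in restraints.angles:
        ia, ib, ic = index[r.atom_1], index[r.atom_2], index[r.atom_3]
        theta, ga, gb, gc = _angle_and_grad(x[ia], x[ib], x[ic])
        dev = (theta - r.ideal) / r.esd
        energy += dev * dev
        f = 2.0 * dev / r.esd
        grad[ia] += f * ga
        grad[ib] += f * gb
        grad[ic] += f * gc

    for r in restraints.torsions:
        ia, ib, ic, id_ = (index[a] for a in r.atoms)
        phi, ga, gb, gc, gd = _dihedral_and_grad(x[ia], x[ib], x[ic], x[id_])
        dev = _signed_torsion_deviation(phi, r) / r.esd
        energy += dev * dev
        f = 2.0 * dev / r.esd
        grad[ia] += f * ga
        grad[ib] += f * gb
        grad[ic] += f * gc
        grad[id_] += f * gd

    for r in restraints.planes:
        idxs = [index[a] for a in r.atoms]
        coords = x[idxs]
        normal, centroid = best_fit_plane(coords)
        h = (coords - centroid) @ normal
        w = 1.0 / (r.esd * r.esd)
        energy += w * float(np.dot(h, h))
        # plane held fixed: exact via envelope theorem for a common esd
        for k, i in enumerate(idxs):
            grad[i] += 2.0 * w * h[k] * normal

    for r in restraints.chirals:
        ic_, i1, i2, i3 = (index[a] for a in r.atoms)
        u1 = x[i1] - x[ic_]
        u2 = x[i2] - x[ic_]
        u3 = x[i3] - x[ic_]
        vol = float(np.dot(u1, np.cross(u2, u3)))
        target = r.volume_ideal
        if r.both_signs and vol * target < 0:
            target = -target  # either handedness acceptable: use the nearer sign
        dev = (vol - target) / r.esd
        energy += dev * dev
        f = 2.0 * dev / r.esd
        g1 = f * np.cross(u2, u3)
        g2 = f * np.cross(u3, u1)
        g3 = f * np.cross(u1, u2)
        grad[i1] += g1
        grad[i2] += g2
        grad[i3] += g3
        grad[ic_] -= g1 + g2 + g3

    pairs = _nb_pairs
    if pairs is None and component is not None:
        pairs = nonbonded_pairs(component, model)
    if pairs:
        for i, j, r0 in pairs:
            d = x[j] - x[i]
            dist = np.linalg.norm(d)
            if dist < r0:
                overlap = r0 - dist
                energy += model.nonbonded_weight * overlap * overlap
                gvec = -2.0 * model.nonbonded_weight * overlap * (d / dist)
                grad[j] += gvec
                grad[i] -= gvec

    return float(energy), grad


def minimize(
    coordinates: np.ndarray,
    restraints: GeometryRestraints,
    model: Optional[EnergyModel] = None,
    component: Optional[ChemicalComponent] = None,
    max_iter: int = 500,
    gtol: float = 1e-4,
) -> MinimizationResult:
    """Quasi-Newton (L-BFGS) descent of the restraint energy.

    Deterministic given its inputs.  ``converged`` is true when the final
    gradient infinity-norm is below *gtol* (or there were no forces at all).
    """
    model = model or EnergyModel()
    x0 = np.array(coordinates, dtype=float)
    nb = nonbonded_pairs(component, model) if component is not None else []

    e0, g0 = residual_energy(x0, restraints, model, _nb_pairs=nb)
    if not np.isfinite(e0):
        raise ValueError("non-finite energy at start")
    if np.abs(g0).max() < gtol:
        return MinimizationResult(x0, 0, e0, 0.0, True)

    def fun(flat: np.ndarray):
        e, g = residual_energy(flat.reshape(-1, 3), restraints, model, _nb_pairs=nb)
        return e, g.ravel()

    res = scipy.optimize.minimize(
        fun, x0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    xf = res.x.reshape(-1, 3)
    ef, gf = residual_energy(xf, restraints, model, _nb_pairs=nb)
    rmsd = superpose_rmsd(x0, xf)["rmsd"]
    converged = bool(np.abs(gf).max() < gtol) or bool(res.success)
    return MinimizationResult(xf, int(res.nit), ef, rmsd, converged)
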