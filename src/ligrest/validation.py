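"""Z-score geometry validation against a reference bond/angle table.

The reference table stands in for Mogul/CSD lookups: each entry keys a typed
bond or angle to an ideal value, a standard deviation and an observation
count.  A geometry is validated by computing Z = (observed − ideal)/s.d. for
every covered bond and angle; the maximum |Z| buckets the geometry into
"perfect" (<2), "grand" (<4), "ok" (<6) or fail.  When an s.d. falls below
the ad-hoc floors (0.005 Å for bonds, 0.75° for angles) the floor is
substituted, and a geometry that passes only with floored s.d.s is labelled
"ok (reasonable std)".  Validation restricted to side-chain atoms gets a
"(side chain)" suffix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .components import ChemicalComponent
from .geometry import bond_angle, bond_graph, bond_length, perceive_internal_coordinates

__all__ = [
    "BOND_SD_FLOOR",
    "ANGLE_SD_FLOOR",
    "DEFAULT_BACKBONE_ATOMS",
    "ReferenceEntry",
    "ReferenceTable",
    "MetricRecord",
    "ValidationReport",
    "zscore",
    "apply_sd_floor",
    "classify",
    "validate_geometry",
    "bond_type_key",
    "angle_type_key",
    "atom_type_token",
]

BOND_SD_FLOOR = 0.005  # Å
ANGLE_SD_FLOOR = 0.75  # degrees

# Atoms treated as backbone when restricting validation to the side chain
DEFAULT_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "H2", "HA", "HXT"})


# ---------------------------------------------------------------------------
# Atom typing.  Mogul's proprietary fragment typing is replaced by a
# deterministic scheme: element + connection degree + aromatic flag +
# sorted first-shell neighbour elements, with the bond order folded into
# bond and angle keys so that e.g. C=O and C–O⁻ never share a key.
# ---------------------------------------------------------------------------

def atom_type_token(
    element: str, degree: int, aromatic: bool, neighbour_elements: Iterable[str] = ()
) -> str:
    shell = "".join(sorted(e.upper() for e in neighbour_elements))
    tok = f"{element.upper()}{degree}{'a' if aromatic else ''}"
    return f"{tok}({shell})" if shell else tok


def bond_type_key(token_1: str, token_2: str, order: str = "single") -> str:
    return "~".join(sorted((token_1, token_2))) + f":{order}"


def angle_type_key(
    token_1: str, apex_token: str, token_3: str,
    order_1: str = "single", order_3: str = "single",
) -> str:
    arm_a = f"{token_1}[{order_1}]"
    arm_b = f"{token_3}[{order_3}]"
    lo, hi = sorted((arm_a, arm_b))
    return f"{lo}~{apex_token}~{hi}"


class TypingContext:
    """Per-component atom tokens and bond-order lookup for key building."""

    def __init__(self, component: ChemicalComponent):
        g = bond_graph(component)
        arom = set()
        self._orders: Dict[frozenset, str] = {}
        for b in component.bonds:
            self._orders[b.key] = b.order.value
            if b.order.value == "aromatic":
                arom.add(b.atom_1)
                arom.add(b.atom_2)
        element = {a.name: a.element for a in component.atoms}
        self.tokens: Dict[str, str] = {
            a.name: atom_type_token(
                a.element, g.degree(a.name), a.name in arom,
                (element[n] for n in g.neighbors(a.name)),
            )
            for a in component.atoms
        }

    def order(self, a1: str, a2: str) -> str:
        return self._orders[frozenset((a1, a2))]

    def bond_key(self, a1: str, a2: str) -> str:
        return bond_type_key(self.tokens[a1], self.tokens[a2], self.order(a1, a2))

    def angle_key(self, a1: str, apex: str, a3: str) -> str:
        return angle_type_key(
            self.tokens[a1], self.tokens[apex], self.tokens[a3],
            self.order(a1, apex), self.order(a3, apex),
        )


def _atom_tokens(component: ChemicalComponent) -> Dict[str, str]:
    return TypingContext(component).tokens


@dataclass(frozen=True)
class ReferenceEntry:
    kind: str  # "bond" | "angle"
    type_key: str
    ideal: float
    sd: float
    n_obs: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle"):
            raise ValueError(f"kind must be bond or angle, got {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be ≥ 0")
        if self.n_obs < 1:
            raise ValueError("n_obs must be ≥ 1")


class ReferenceTable:
    """Reference entries keyed by (kind, type_key)."""

    def __init__(self, entries: Iterable[ReferenceEntry] = ()):
        self._entries: Dict[Tuple[str, str], ReferenceEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ReferenceEntry) -> None:
        key = (entry.kind, entry.type_key)
        if key in self._entries:
            raise ValueError(f"duplicate reference key {key}")
        self._entries[key] = entry

    def lookup(self, kind: str, type_key: str) -> Optional[ReferenceEntry]:
        return self._entries.get((kind, type_key))

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [
                {"kind": e.kind, "type_key": e.type_key, "ideal": e.ideal,
                 "sd": e.sd, "n_obs": e.n_obs}
                for e in sorted(self, key=lambda e: (e.kind, e.type_key))
            ]
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path)
        return cls(
            ReferenceEntry(
                kind=str(r.kind), type_key=str(r.type_key), ideal=float(r.ideal),
                sd=float(r.sd), n_obs=int(r.n_obs),
            )
            for r in df.itertuples()
        )


# ---------------------------------------------------------------------------
# Z-scores, floors, classification
# ---------------------------------------------------------------------------

def zscore(observed: float, ideal: float, sd_effective: float) -> float:
    """(observed − ideal) / s.d.; the s.d. floor must already be applied."""
    if sd_effective <= 0:
        raise ValueError("sd_effective must be > 0 (apply the floor first)")
    return (observed - ideal) / sd_effective


def apply_sd_floor(sd_raw: float, kind: str) -> Tuple[float, bool]:
    """Substitute the ad-hoc minimum s.d. (0.005 Å bonds, 0.75° angles).

    Returns (sd_effective, floored).
    """
    if sd_raw < 0:
        raise ValueError("sd_raw must be ≥ 0")
    floor = BOND_SD_FLOOR if kind == "bond" else ANGLE_SD_FLOOR
    if sd_raw < floor:
        return floor, True
    return sd_raw, False


@dataclass(frozen=True)
class Classification:
    classification: str  # perfect | grand | ok | fail
    reasonable_std: bool
    side_chain: bool

    @property
    def designation(self) -> str:
        label = self.classification
        if self.reasonable_std:
            label = "ok (reasonable std)"
        if self.side_chain:
            label += " (side chain)"
        return label


def classify(max_abs_z: float, floored_any: bool, side_chain_only: bool) -> Classification:
    """Bucket a geometry by max |Z| with strict thresholds 2/4/6.

    A geometry that passes (<6) while any metric used a floored s.d. is
    reported "ok (reasonable std)" regardless of the tier its Z would earn.
    """
    if max_abs_z < 0:
        raise ValueError("max_abs_z must be ≥ 0")
    if max_abs_z < 2.0:
        tier = "perfect"
    elif max_abs_z < 4.0:
        tier = "grand"
    elif max_abs_z < 6.0:
        tier = "ok"
    else:
        tier = "fail"
    reasonable = floored_any and tier != "fail"
    if reasonable:
        tier = "ok"
    return Classification(tier, reasonable, side_chain_only)


@dataclass
class MetricRecord:
    kind: str
    atoms: Tuple[str, ...]
    observed: float
    ideal: float
    sd_raw: float
    sd_effective: float
    floored: bool
    z: float


@dataclass
class ValidationReport:
    component_id: str
    records: List[MetricRecord] = field(default_factory=list)
    n_skipped: int = 0
    no_coverage: bool = False
    side_chain: bool = False
    max_abs_z: Optional[float] = None
    rms_z: Optional[float] = None
    classification: Classification = None  # type: ignore[assignment]

    @property
    def coverage(self) -> float:
        n = len(self.records) + self.n_skipped
        return len(self.records) / n if n else 0.0

    @property
    def designation(self) -> str:
        return self.classification.designation

    def to_dict(self) -> dict:
        return {
            "component_id": self.component_id,
            "classification": self.classification.classification,
            "designation": self.designation,
            "reasonable_std": self.classification.reasonable_std,
            "side_chain": self.side_chain,
            "max_abs_z": self.max_abs_z,
            "rms_z": self.rms_z,
            "n_metrics": len(self.records),
            "n_skipped": self.n_skipped,
            "coverage": self.coverage,
            "no_coverage": self.no_coverage,
            "records": [
                {
                    "kind": r.kind, "atoms": list(r.atoms), "observed": r.observed,
                    "ideal": r.ideal, "sd_raw": r.sd_raw,
                    "sd_effective": r.sd_effective, "floored": r.floored, "z": r.z,
                }
                for r in self.records
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def validate_geometry(
    component: ChemicalComponent,
    reference: ReferenceTable,
    restrict_to: Optional[Iterable[str]] = None,
) -> ValidationReport:
    """Validate every covered bond and angle of *component* against *reference*.

    Metrics whose type key has no reference entry are skipped and counted in
    the coverage fraction.  ``restrict_to`` limits metrics to those whose
    atoms all belong to the given set (side-chain validation) and marks the
    report "(side chain)".
    """
    if len(reference) == 0:
        raise ValueError("reference table is empty")
    ics = perceive_internal_coordinates(component)
    typing = TypingContext(component)
    allowed = set(restrict_to) if restrict_to is not None else None
    side_chain = allowed is not None

    records: List[MetricRecord] = []
    n_skipped = 0

    def want(atoms: Tuple[str, ...]) -> bool:
        return allowed is None or all(a in allowed for a in atoms)

    for a1, a2 in ics.bond_pairs:
        if not want((a1, a2)):
            continue
        entry = reference.lookup("bond", typing.bond_key(a1, a2))
        if entry is None:
            n_skipped += 1
            continue
        obs = bond_length(component.atom(a1).coordinates, component.atom(a2).coordinates)
        sd_eff, floored = apply_sd_floor(entry.sd, "bond")
        records.append(
            MetricRecord("bond", (a1, a2), obs, entry.ideal, entry.sd, sd_eff,
                         floored, zscore(obs, entry.ideal, sd_eff))
        )

    for a1, apex, a3 in ics.angle_triples:
        if not want((a1, apex, a3)):
            continue
        entry = reference.lookup("angle", typing.angle_key(a1, apex, a3))
        if entry is None:
            n_skipped += 1
            continue
        obs = bond_angle(
            component.atom(a1).coordinates,
            component.atom(apex).coordinates,
            component.atom(a3).coordinates,
        )
        sd_eff, floored = apply_sd_floor(entry.sd, "angle")
        records.append(
            MetricRecord("angle", (a1, apex, a3), obs, entry.ideal, entry.sd, sd_eff,
                         floored, zscore(obs, entry.ideal, sd_eff))
        )

    report = ValidationReport(
        component_id=component.id, records=records, n_skipped=n_skipped,
        side_chain=side_chain,
    )
    if not records:
        report.no_coverage = True
        report.classification = Classification("fail", False, side_chain)
        return report

    zs = [abs(r.z) for r in records]
    report.max_abs_z = max(zs)
    report.rms_z = (sum(z * z for z in zs) / len(zs)) ** 0.5
    floored_any = any(r.floored for r in records)
    report.classification = classify(report.max_abs_z, floored_any, side_chain)
    return report
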