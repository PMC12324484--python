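"""End-to-end per-component driver.

Mirrors the library-building flow: eligibility filter → (pluggable geometry
source) → restraint generation → Z-score validation → classification →
protonation variants → terminus trimming → restraint CIF output, with
per-component failure isolation and a JSON-lines summary.

The geometry source is an interface (component in, component with minimised
coordinates out); the default identity backend accepts the input coordinates
as the minimised geometry, keeping external QM engines out of the loop.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Union

from .components import (
    ChemicalComponent,
    ComponentType,
    assess_eligibility,
    parse_component_cif,
)
from .minimize import EnergyModel, minimize
from .restraints import (
    EsdDefaults,
    enumerate_protonation_variants,
    generate_restraints,
    trim_polymer_termini,
    write_restraints_cif,
)
from .validation import ReferenceTable, validate_geometry

__all__ = ["PipelineOptions", "PipelineSummary", "run_pipeline", "identity_geometry_source"]

logger = logging.getLogger("ligrest.pipeline")

GeometrySource = Callable[[ChemicalComponent], ChemicalComponent]


def identity_geometry_source(component: ChemicalComponent) -> ChemicalComponent:
    """Default backend: the input coordinates are taken as the minimised
    geometry (external QM engines plug in behind the same signature)."""
    return component


@dataclass
class PipelineOptions:
    variants: str = "all"  # "all" | "neutral"
    trim_termini: str = "auto"  # "auto" | "off"
    out_dir: Optional[Path] = None
    seed: int = 0
    geometry_source: GeometrySource = identity_geometry_source
    esd_defaults: EsdDefaults = field(default_factory=EsdDefaults)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    run_fixed_point: bool = True


@dataclass
class PipelineSummary:
    component_id: str
    status: str  # "ok" | "filtered" | "error"
    eligibility: str = "ok"
    classification: Optional[str] = None
    designation: Optional[str] = None
    max_abs_z: Optional[float] = None
    rms_z: Optional[float] = None
    n_restraints: Dict[str, int] = field(default_factory=dict)
    variants: List[str] = field(default_factory=list)
    rmsd_fixed_point: Optional[float] = None
    output_paths: List[str] = field(default_factory=list)
    error: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _process_component(
    component: ChemicalComponent,
    reference: ReferenceTable,
    options: PipelineOptions,
) -> PipelineSummary:
    decision = assess_eligibility(component)
    if not decision.eligible:
        logger.info("%s: filtered (%s)", component.id, decision.reason.value)
        return PipelineSummary(
            component_id=component.id, status="filtered",
            eligibility=decision.reason.value,
        )

    minimised = options.geometry_source(component)

    if options.variants == "all":
        members = enumerate_protonation_variants(minimised)
    else:
        members = [minimised]

    summary = PipelineSummary(component_id=component.id, status="ok")
    for variant in members:
        restraints = generate_restraints(variant, reference, options.esd_defaults)
        report = validate_geometry(variant, reference)
        if variant is members[0]:
            summary.classification = report.classification.classification
            summary.designation = report.designation
            summary.max_abs_z = report.max_abs_z
            summary.rms_z = report.rms_z
        if options.run_fixed_point:
            result = minimize(
                variant.coordinate_array(), restraints,
                options.energy_model, component=variant,
            )
            if variant is members[0]:
                summary.rmsd_fixed_point = result.rmsd_to_start
        if (
            options.trim_termini == "auto"
            and variant.component_type == ComponentType.AMINO_ACID
        ):
            restraints = trim_polymer_termini(restraints, variant)
        if variant is members[0]:
            summary.n_restraints = restraints.counts()
        summary.variants.append(variant.variant)
        if options.out_dir is not None:
            options.out_dir.mkdir(parents=True, exist_ok=True)
            suffix = "" if variant.variant == "neutral" else f"_{variant.variant}"
            path = options.out_dir / f"{component.id}{suffix}.restraints.cif"
            path.write_text(write_restraints_cif(restraints), encoding="utf-8")
            summary.output_paths.append(str(path))
        logger.info(
            "%s[%s]: %s", component.id, variant.variant,
            summary.designation or "generated",
        )
    return summary


def run_pipeline(
    components: Iterable[Union[ChemicalComponent, str, Path]],
    reference: ReferenceTable,
    options: Optional[PipelineOptions] = None,
    summary_path: Optional[Path] = None,
) -> List[PipelineSummary]:
    """Run the per-component flow over a batch.

    *components* may mix in-memory components with paths to component CIF
    files.  One bad entry never aborts the batch: failures become error
    records.  Output is a pure function of (inputs, options, seed).
    """
    options = options or PipelineOptions()
    summaries: List[PipelineSummary] = []
    for item in components:
        cid = "?"
        try:
            if isinstance(item, (str, Path)):
                cid = Path(item).stem
                component = parse_component_cif(Path(item).read_text(encoding="utf-8"))
            else:
                component = item
            cid = component.id
            summaries.append(_process_component(component, reference, options))
        except Exception as exc:  # isolation contract: record, continue
            logger.error("%s: %s", cid, exc)
            logger.debug("%s", traceback.format_exc())
            summaries.append(
                PipelineSummary(component_id=cid, status="error", error=str(exc))
            )
    if summary_path is not None:
        with open(summary_path, "w", encoding="utf-8") as fh:
            for s in summaries:
                fh.write(json.dumps(s.to_dict()) + "\n")
    return summaries
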