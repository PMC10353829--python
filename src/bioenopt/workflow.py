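"""High-level workflow: document -> variants -> systems -> two-stage solve."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .assembly import (
    ConstraintSystem,
    apply_bounds,
    build_thermo_constraints,
    moiety_constraints,
    overall_gibbs,
)
from .io import BreakdownRow, PathwayDocument, build_breakdown, energy_recovery_efficiency
from .model import PathwayVariant, enumerate_variants
from .optimize import (
    ParetoPoint,
    ScipyHighsBackend,
    SolutionRecord,
    VariantResult,
    evaluate_variants,
)

__all__ = ["PathwayAnalysis", "build_systems", "analyze_pathway"]


@dataclass
class PathwayAnalysis:
    """Bundle of everything one multi-variant analysis produced."""

    pathway_id: str
    variants: list[PathwayVariant]
    systems: list[ConstraintSystem]
    results: list[VariantResult]
    pareto: list[ParetoPoint]
    breakdowns: dict[str, list[BreakdownRow]] = field(default_factory=dict)
    dG_overall: dict[str, float] = field(default_factory=dict)

    def best_records(self, epsilon: int = 0) -> list[SolutionRecord]:
        """Stage-2 records of the per-epsilon best variant and its ties."""
        pt = next(p for p in self.pareto if p.epsilon == epsilon)
        ids = pt.ties or (pt.best_variant_id,)
        return [
            vr.stage2[epsilon]
            for vr in self.results
            if vr.variant_id in ids and epsilon in vr.stage2
        ]

    def efficiency(self, variant_id: str, epsilon: int = 0) -> float | None:
        vr = next(r for r in self.results if r.variant_id == variant_id)
        rec = vr.stage2.get(epsilon) or vr.stage1
        if rec.net_ATP is None:
            return None
        return energy_recovery_efficiency(
            rec.net_ATP,
            self.systems[0].env.dG_ATP,
            self.dG_overall[variant_id],
        )


def build_systems(
    doc: PathwayDocument,
    pathway_id: str | None = None,
    moiety_mode: str = "linear_safe",
    lnC_default: tuple[float, float] = (math.log(1e-6), math.log(1e-2)),
    np_default: tuple[int, int] | None = None,
) -> tuple[list[PathwayVariant], list[ConstraintSystem]]:
    """Enumerate the pathway's variants and assemble one bounded system each."""
    pathway = doc.pathway(pathway_id)
    variants = enumerate_variants(pathway, doc.carriers, doc.reactions, doc.species)
    systems = []
    for variant in variants:
        system = build_thermo_constraints(variant, doc.species, doc.env)
        system = apply_bounds(system, lnC_default=lnC_default, np_default=np_default)
        system = moiety_constraints(system, doc.moieties, mode=moiety_mode)
        systems.append(system)
    return variants, systems


def analyze_pathway(
    doc: PathwayDocument,
    pathway_id: str | None = None,
    epsilons: tuple[int, ...] = (0,),
    moiety_mode: str = "linear_safe",
    backend: ScipyHighsBackend | None = None,
    lnC_default: tuple[float, float] = (math.log(1e-6), math.log(1e-2)),
    np_default: tuple[int, int] | None = None,
) -> PathwayAnalysis:
    """Full two-stage epsilon-constraint analysis of every pathway variant."""
    variants, systems = build_systems(
        doc, pathway_id, moiety_mode, lnC_default, np_default
    )
    results, pareto = evaluate_variants(systems, list(epsilons), backend)
    analysis = PathwayAnalysis(
        pathway_id=doc.pathway(pathway_id).id,
        variants=variants,
        systems=systems,
        results=results,
        pareto=pareto,
    )
    eps0 = int(epsilons[0]) if epsilons else 0
    for system, vr in zip(systems, results):
        analysis.dG_overall[vr.variant_id] = overall_gibbs(
            system.variant, doc.species, doc.env
        )
        rec = vr.stage2.get(eps0)
        if rec is not None and rec.ok:
            analysis.breakdowns[vr.variant_id] = build_breakdown(system, rec)
    return analysis
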