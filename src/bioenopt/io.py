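"""Pathway schema I/O and result reporting.

A pathway definition is one JSON document, an Excel workbook, or a
directory of CSV files with the equivalent five tables:

``species``
    id, name, dGf0_ref (kJ/mol), dHf0 (kJ/mol, optional), role
    (intermediate | fixed_external | carrier), fixed_conc (mol/L, for fixed
    or prefixed species; ``fixed_lnC`` accepted instead), c_min, c_max
    (optional per-species concentration bounds, mol/L).
``reactions``
    id, equation (signed ``coef species`` terms joined by `` + ``, e.g.
    ``-1 pro + 1 lac + 2 e-``; JSON may give a ``stoich`` mapping instead),
    L (SLP token), translocating (bool), carrier_options
    (comma/space-separated carrier ids), dG_min (kJ/mol).
``carriers``
    id, oxidized, reduced, n_electrons, regeneration_chain (reaction ids).
``moieties``
    id, members, c_min, c_max, free_species.
``parameters``
    T, T_ref, dG_ATP, r_H_ATP, pH_in, pH_out (one name/value pair per row,
    or a JSON object).
``pathways``
    id, name, reactions (ordered core reaction ids).

Conventions applied on load (recorded in the document metadata): water
activity is fixed at 1 (ln C = 0) and protons are a fixed species with
ln C = -pH_in * ln(10); neither enters the decision vector.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    CarrierPair,
    ConservedMoiety,
    Pathway,
    Reaction,
    SchemaError,
    Species,
)
from .optimize import ParetoPoint, SolutionRecord
from .thermo import Environment

__all__ = [
    "PathwayDocument",
    "BreakdownRow",
    "read_pathway",
    "write_pathway",
    "write_results",
    "load_solutions",
    "build_breakdown",
    "energy_recovery_efficiency",
    "parse_equation",
]

SCHEMA_TAG = "bioenopt-pathway/1"

WATER_IDS = frozenset({"h2o", "H2O", "water"})
PROTON_IDS = frozenset({"h+", "H+", "proton"})


@dataclass
class PathwayDocument:
    """A fully validated pathway definition ready for analysis."""

    species: dict[str, Species]
    reactions: dict[str, Reaction]
    carriers: dict[str, CarrierPair]
    moieties: list[ConservedMoiety]
    pathways: list[Pathway]
    env: Environment
    metadata: dict = field(default_factory=dict)

    def pathway(self, pathway_id: str | None = None) -> Pathway:
        if pathway_id is None:
            if len(self.pathways) != 1:
                raise SchemaError(
                    "document defines several pathways; choose one of: "
                    + ", ".join(p.id for p in self.pathways)
                )
            return self.pathways[0]
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise SchemaError(f"no pathway {pathway_id!r} in document")


@dataclass(frozen=True)
class BreakdownRow:
    """One line of a per-reaction bioenergetic breakdown table."""

    reaction_id: str
    dG_r: float  #: kJ/mol at the solved concentrations
    cumulative_dG: float  #: running sum along the pathway, kJ/mol
    n_p: int
    L: float
    reactant_lnC: dict[str, float]
    product_lnC: dict[str, float]
    repeated: bool


_TERM_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?(?:/\d+)?)\s+(\S+)\s*$")


def parse_equation(text: str) -> dict[str, float]:
    """Parse ``-1 pro + 2 h2o + 1 ac`` into a signed stoichiometry map.

    Terms are joined by `` + `` (spaces required, so species names may
    themselves contain ``+``, e.g. ``nad+``).
    """
    stoich: dict[str, float] = {}
    for term in text.split(" + "):
        m = _TERM_RE.match(term)
        if not m:
            raise SchemaError(f"cannot parse stoichiometry term {term!r}")
        coef_s, sp = m.groups()
        coef = (
            float(coef_s.split("/")[0]) / float(coef_s.split("/")[1])
            if "/" in coef_s
            else float(coef_s)
        )
        stoich[sp] = stoich.get(sp, 0.0) + coef
    return stoich


def format_equation(stoich: dict[str, float]) -> str:
    return " + ".join(f"{coef:g} {sp}" for sp, coef in sorted(stoich.items()))


def _as_list(value) -> list[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return []
    if isinstance(value, (list, tuple)):
        return [str(v) for v in value]
    return [tok for tok in re.split(r"[,;\s]+", str(value).strip()) if tok]


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    v = float(value)
    return None if math.isnan(v) else v


def _build_document(
    species_rows, reaction_rows, carrier_rows, moiety_rows, params, pathway_rows
) -> PathwayDocument:
    errors: list[str] = []

    env_kwargs = {}
    for key in ("T", "T_ref", "dG_ATP", "r_H_ATP", "pH_in", "pH_out"):
        if key in params and params[key] is not None:
            env_kwargs[key] = float(params[key])
    try:
        env = Environment(**env_kwargs)
    except ValueError as exc:
        errors.append(f"parameters: {exc}")
        env = Environment()

    species: dict[str, Species] = {}
    for i, row in enumerate(species_rows):
        try:
            sid = str(row["id"])
            fixed_lnC = _opt_float(row.get("fixed_lnC"))
            fixed_conc = _opt_float(row.get("fixed_conc"))
            if fixed_lnC is None and fixed_conc is not None:
                fixed_lnC = math.log(fixed_conc)
            c_min, c_max = _opt_float(row.get("c_min")), _opt_float(row.get("c_max"))
            bounds = None
            if c_min is not None or c_max is not None:
                if c_min is None or c_max is None:
                    raise SchemaError("c_min and c_max must be given together")
                bounds = (math.log(c_min), math.log(c_max))
            role = str(row.get("role") or "intermediate")
            if sid in WATER_IDS:
                role, fixed_lnC = "fixed_external", 0.0
            elif sid in PROTON_IDS:
                role, fixed_lnC = "fixed_external", env.lnC_proton
            species[sid] = Species(
                id=sid,
                name=str(row.get("name") or ""),
                dGf0_ref=float(row.get("dGf0_ref") or 0.0),
                dHf0=_opt_float(row.get("dHf0")),
                role=role,
                fixed_lnC=fixed_lnC,
                lnC_bounds=bounds,
            )
        except (SchemaError, ValueError, KeyError) as exc:
            errors.append(f"species row {i + 1}: {exc}")

    reactions: dict[str, Reaction] = {}
    for i, row in enumerate(reaction_rows):
        try:
            rid = str(row["id"])
            if "stoich" in row and row["stoich"]:
                stoich = {str(k): float(v) for k, v in dict(row["stoich"]).items()}
            else:
                stoich = parse_equation(str(row["equation"]))
            reactions[rid] = Reaction(
                id=rid,
                stoich=stoich,
                L=float(row.get("L") or 0.0),
                translocating=_as_bool(row.get("translocating")),
                carrier_options=tuple(_as_list(row.get("carrier_options"))),
                dG_min=float(row.get("dG_min") or 0.0),
            )
        except (SchemaError, ValueError, KeyError) as exc:
            errors.append(f"reaction row {i + 1}: {exc}")

    carriers: dict[str, CarrierPair] = {}
    for i, row in enumerate(carrier_rows):
        try:
            cid = str(row["id"])
            carriers[cid] = CarrierPair(
                id=cid,
                oxidized_species=str(row["oxidized"]),
                reduced_species=str(row["reduced"]),
                electrons_transferred=int(row.get("n_electrons") or 2),
                regeneration_chain=tuple(_as_list(row.get("regeneration_chain"))),
            )
        except (SchemaError, ValueError, KeyError) as exc:
            errors.append(f"carrier row {i + 1}: {exc}")

    moieties: list[ConservedMoiety] = []
    for i, row in enumerate(moiety_rows):
        try:
            moieties.append(
                ConservedMoiety(
                    id=str(row["id"]),
                    member_species=tuple(_as_list(row["members"])),
                    pool_bounds=(float(row["c_min"]), float(row["c_max"])),
                    designated_free_species=(
                        str(row["free_species"]) if row.get("free_species") else None
                    ),
                )
            )
        except (SchemaError, ValueError, KeyError) as exc:
            errors.append(f"moiety row {i + 1}: {exc}")

    pathways: list[Pathway] = []
    for i, row in enumerate(pathway_rows):
        try:
            rids = _as_list(row["reactions"])
            missing = [r for r in rids if r not in reactions]
            if missing:
                raise SchemaError(f"unknown reaction ids {missing}")
            pathways.append(
                Pathway(
                    id=str(row["id"]),
                    name=str(row.get("name") or ""),
                    reactions=tuple(reactions[r] for r in rids),
                )
            )
        except (SchemaError, ValueError, KeyError) as exc:
            errors.append(f"pathway row {i + 1}: {exc}")

    # cross-validation: every reaction species must be declared (or be the
    # electron pseudo-species / auto-injected proton)
    from .model import ELECTRON

    for rid, rxn in reactions.items():
        for sp in rxn.stoich:
            if sp == ELECTRON:
                continue
            if sp in PROTON_IDS and sp not in species:
                species[sp] = Species(
                    id=sp, role="fixed_external", dGf0_ref=0.0,
                    fixed_lnC=env.lnC_proton,
                )
            if sp not in species:
                errors.append(f"reaction {rid!r}: undeclared species {sp!r}")
        for cid in rxn.carrier_options:
            if cid not in carriers:
                errors.append(f"reaction {rid!r}: unknown carrier {cid!r}")
    for cm in moieties:
        for sp in cm.member_species:
            if sp not in species:
                errors.append(f"moiety {cm.id!r}: unknown member {sp!r}")

    if errors:
        raise SchemaError(
            "pathway definition has "
            f"{len(errors)} problem(s):\n  - " + "\n  - ".join(errors)
        )
    return PathwayDocument(
        species=species,
        reactions=reactions,
        carriers=carriers,
        moieties=moieties,
        pathways=pathways,
        env=env,
        metadata={
            "schema": SCHEMA_TAG,
            "conventions": {
                "water_activity": 1.0,
                "proton_lnC": env.lnC_proton,
                "dG_ATP_sign": "positive magnitude; direction via L and n_p",
            },
        },
    )


def _records_from_frame(df) -> list[dict]:
    import pandas as pd

    return [
        {k: (None if pd.isna(v) else v) for k, v in row.items()}
        for row in df.to_dict(orient="records")
    ]


def read_pathway(path: str | Path) -> PathwayDocument:
    """Load and validate a pathway definition (JSON, XLSX or CSV directory).

    All validation failures are collected and reported together in one
    :class:`~bioenopt.model.SchemaError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        import pandas as pd

        tables = {}
        for name in ("species", "reactions", "carriers", "moieties", "pathways"):
            f = path / f"{name}.csv"
            tables[name] = _records_from_frame(pd.read_csv(f)) if f.exists() else []
        params = {}
        pf = path / "parameters.csv"
        if pf.exists():
            for row in _records_from_frame(pd.read_csv(pf)):
                params[str(row["name"])] = row["value"]
        return _build_document(
            tables["species"], tables["reactions"], tables["carriers"],
            tables["moieties"], params, tables["pathways"],
        )
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        params = doc.get("parameters", {})
        return _build_document(
            doc.get("species", []), doc.get("reactions", []),
            doc.get("carriers", []), doc.get("moieties", []),
            params, doc.get("pathways", []),
        )
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        import pandas as pd

        sheets = pd.read_excel(path, sheet_name=None)
        lower = {k.strip().lower(): v for k, v in sheets.items()}

        def rows(name):
            return _records_from_frame(lower[name]) if name in lower else []

        params = {}
        if "parameters" in lower:
            for row in _records_from_frame(lower["parameters"]):
                params[str(row["name"])] = row["value"]
        return _build_document(
            rows("species"), rows("reactions"), rows("carriers"),
            rows("moieties"), params, rows("pathways"),
        )
    raise SchemaError(f"unrecognised pathway file type: {path.name}")


def write_pathway(doc: PathwayDocument, path: str | Path) -> None:
    """Serialise a document back to the JSON schema (deterministic bytes)."""
    payload = {
        "schema": SCHEMA_TAG,
        "parameters": {
            "T": doc.env.T, "T_ref": doc.env.T_ref, "dG_ATP": doc.env.dG_ATP,
            "r_H_ATP": doc.env.r_H_ATP, "pH_in": doc.env.pH_in,
            "pH_out": doc.env.pH_out,
        },
        "species": [
            {
                "id": sp.id, "name": sp.name, "dGf0_ref": sp.dGf0_ref,
                "dHf0": sp.dHf0, "role": sp.role, "fixed_lnC": sp.fixed_lnC,
                "c_min": math.exp(sp.lnC_bounds[0]) if sp.lnC_bounds else None,
                "c_max": math.exp(sp.lnC_bounds[1]) if sp.lnC_bounds else None,
            }
            for sp in sorted(doc.species.values(), key=lambda s: s.id)
        ],
        "reactions": [
            {
                "id": r.id, "stoich": dict(sorted(r.stoich.items())), "L": r.L,
                "translocating": r.translocating,
                "carrier_options": list(r.carrier_options), "dG_min": r.dG_min,
            }
            for r in sorted(doc.reactions.values(), key=lambda r: r.id)
        ],
        "carriers": [
            {
                "id": c.id, "oxidized": c.oxidized_species,
                "reduced": c.reduced_species,
                "n_electrons": c.electrons_transferred,
                "regeneration_chain": list(c.regeneration_chain),
            }
            for c in sorted(doc.carriers.values(), key=lambda c: c.id)
        ],
        "moieties": [
            {
                "id": m.id, "members": list(m.member_species),
                "c_min": m.pool_bounds[0], "c_max": m.pool_bounds[1],
                "free_species": m.designated_free_species,
            }
            for m in doc.moieties
        ],
        "pathways": [
            {"id": p.id, "name": p.name, "reactions": [r.id for r in p.reactions]}
            for p in doc.pathways
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def energy_recovery_efficiency(
    net_ATP: float, dG_ATP: float, dG_overall: float
) -> float | None:
    """Energy recovery (or utilisation) efficiency as a percentage.

    Exergonic conversion (dG_overall < 0) with net recovery: recovered
    energy over available energy, 100 * net_ATP*dG_ATP / |dG_overall|.
    Endergonic conversion with net expenditure: required over spent,
    100 * dG_overall / |net_ATP*dG_ATP|.  Other sign combinations have no
    meaningful efficiency and return None.
    """
    net_energy = net_ATP * dG_ATP
    if dG_overall < 0 and net_energy >= 0:
        return 100.0 * net_energy / (-dG_overall)
    if dG_overall > 0 and net_energy < 0:
        return 100.0 * dG_overall / (-net_energy)
    return None


def build_breakdown(system, record: SolutionRecord) -> list[BreakdownRow]:
    """Per-reaction bioenergetic breakdown in pathway order.

    The running cumulative Gibbs energy telescopes: the last row equals the
    overall reaction Gibbs energy plus the energy recovered as ATP
    equivalents and translocated protons.
    """
    rows: list[BreakdownRow] = []
    cumulative = 0.0
    seen_stoich: list[dict] = []

    def lnC_of(sp: str) -> float:
        if sp in record.lnC:
            return record.lnC[sp]
        return system.species[sp].fixed_lnC

    for rxn in system.variant.reactions:
        dG = record.dG_by_reaction[rxn.id]
        cumulative += dG
        unit = {sp: nu / rxn.flux for sp, nu in rxn.stoich.items()}
        repeated = any(
            unit.keys() == prev.keys()
            and all(abs(unit[k] - prev[k]) < 1e-9 for k in unit)
            for prev in seen_stoich
        )
        seen_stoich.append(unit)
        rows.append(
            BreakdownRow(
                reaction_id=rxn.id,
                dG_r=dG,
                cumulative_dG=cumulative,
                n_p=record.np_by_reaction.get(rxn.id, 0),
                L=rxn.L,
                reactant_lnC={
                    sp: lnC_of(sp) for sp, nu in rxn.stoich.items() if nu < 0
                },
                product_lnC={
                    sp: lnC_of(sp) for sp, nu in rxn.stoich.items() if nu > 0
                },
                repeated=repeated,
            )
        )
    return rows


def _safe_name(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", text)


def write_results(
    records: list[SolutionRecord],
    pareto: list[ParetoPoint],
    breakdowns: dict[str, list[BreakdownRow]],
    out_dir: str | Path,
    metadata: dict | None = None,
) -> list[Path]:
    """Write solution JSON, Pareto TSV and per-variant breakdown TSVs.

    Field ordering is deterministic for diffability.  Returns the paths
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    sol_path = out_dir / "solutions.json"
    payload = {
        "metadata": metadata or {},
        "solutions": [dataclasses.asdict(r) for r in records],
    }
    sol_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    written.append(sol_path)

    pareto_path = out_dir / "pareto.tsv"
    lines = ["epsilon\tnet_energy_kJ\tMDF_kJ\tbest_variant_id\tstatus\tties"]
    for pt in pareto:
        lines.append(
            "\t".join(
                [
                    str(pt.epsilon),
                    "" if pt.net_energy_kJ is None else f"{pt.net_energy_kJ:.6g}",
                    "" if pt.MDF_kJ is None else f"{pt.MDF_kJ:.6g}",
                    pt.best_variant_id,
                    pt.status,
                    ",".join(pt.ties),
                ]
            )
        )
    pareto_path.write_text("\n".join(lines) + "\n")
    written.append(pareto_path)

    for vid, rows in sorted(breakdowns.items()):
        bpath = out_dir / f"breakdown_{_safe_name(vid)}.tsv"
        blines = [
            "reaction_id\tdG_r_kJ\tcumulative_dG_kJ\tn_p\tL\trepeated"
            "\treactant_lnC\tproduct_lnC"
        ]
        for row in rows:
            blines.append(
                "\t".join(
                    [
                        row.reaction_id,
                        f"{row.dG_r:.6g}",
                        f"{row.cumulative_dG:.6g}",
                        str(row.n_p),
                        f"{row.L:g}",
                        str(row.repeated).lower(),
                        json.dumps(row.reactant_lnC, sort_keys=True),
                        json.dumps(row.product_lnC, sort_keys=True),
                    ]
                )
            )
        bpath.write_text("\n".join(blines) + "\n")
        written.append(bpath)
    return written


def load_solutions(path: str | Path) -> list[SolutionRecord]:
    """Re-load solution records written by :func:`write_results`."""
    payload = json.loads(Path(path).read_text())
    records = []
    for d in payload["solutions"]:
        d = dict(d)
        d["np_by_reaction"] = {k: int(v) for k, v in d["np_by_reaction"].items()}
        records.append(SolutionRecord(**d))
    return records
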