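"""Domain model: species, reactions, carriers, moieties and pathway variants.

A *pathway* is an ordered list of reactions converting an external substrate
to an external product.  Redox steps are written generically in terms of an
electron pseudo-species (:data:`ELECTRON`); a *pathway variant* is obtained
by assigning one permissible electron carrier to every redox step and
appending the regeneration reactions that re-oxidise/re-reduce those
carriers against the terminal electron donor/acceptor, so that no
intermediate metabolite (or carrier) is net produced or consumed per
pathway turnover.

The total number of variants of a pathway is the product of the number of
permissible carriers over its redox steps.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ELECTRON",
    "SchemaError",
    "InfeasibleCarrierError",
    "Species",
    "Reaction",
    "CarrierPair",
    "ConservedMoiety",
    "Pathway",
    "PathwayVariant",
    "ClosureViolation",
    "net_stoichiometry",
    "validate_closure",
    "resolve_carrier",
    "enumerate_variants",
]

#: Pseudo-species standing for electrons in generically written redox steps.
ELECTRON = "e-"

#: Numerical tolerance on stoichiometric closure.
CLOSURE_TOL = 1e-9


class SchemaError(ValueError):
    """A pathway definition is internally inconsistent."""


class InfeasibleCarrierError(SchemaError):
    """A carrier cannot be regenerated against the terminal donor/acceptor."""


@dataclass(frozen=True)
class Species:
    """One chemical species of the pathway.

    ``role`` is one of ``intermediate`` (free, its ln-concentration is a
    decision variable), ``fixed_external`` (concentration set by the
    environment) or ``carrier`` (electron-carrier species; free unless
    ``fixed_lnC`` prefixes it, as is common for NAD/ferredoxin pools).
    """

    id: str
    name: str = ""
    dGf0_ref: float = 0.0
    dHf0: float | None = None
    role: str = "intermediate"
    fixed_lnC: float | None = None
    lnC_bounds: tuple[float, float] | None = None

    ROLES = ("intermediate", "fixed_external", "carrier")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise SchemaError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.role == "fixed_external" and self.fixed_lnC is None:
            raise SchemaError(
                f"species {self.id!r}: fixed_external requires fixed_lnC"
            )
        if self.role == "intermediate" and self.fixed_lnC is not None:
            raise SchemaError(
                f"species {self.id!r}: an intermediate cannot carry fixed_lnC"
            )
        if self.lnC_bounds is not None and self.lnC_bounds[0] > self.lnC_bounds[1]:
            raise SchemaError(f"species {self.id!r}: lnC_bounds low > high")

    @property
    def is_fixed(self) -> bool:
        """True iff the species is excluded from the decision vector."""
        return self.fixed_lnC is not None


@dataclass(frozen=True)
class Reaction:
    """One reaction step.

    ``stoich`` maps species id to its signed coefficient (products positive).
    ``L`` is the signed SLP token (+1 per ATP recovered through ADP, +1.5
    through AMP; ATP/ADP species themselves are tokenised away).
    ``translocating`` marks membrane-bound enzymes eligible for a non-zero
    integer proton-translocation count.  ``carrier_options`` lists the
    permissible carrier-pair ids when the reaction is written generically in
    electrons.  ``flux`` records the per-turnover multiplicity already
    folded into ``stoich`` and ``L`` (regeneration steps shared by several
    core steps are appended once, scaled by the number of carrier
    equivalents they must regenerate).
    """

    id: str
    stoich: dict[str, float]
    L: float = 0.0
    translocating: bool = False
    carrier_options: tuple[str, ...] = ()
    dG_min: float = 0.0
    flux: float = 1.0

    ALLOWED_L = (-1.5, -1.0, 0.0, 1.0, 1.5)

    def __post_init__(self) -> None:
        if not self.stoich:
            raise SchemaError(f"reaction {self.id!r}: empty stoichiometry")
        if self.flux <= 0:
            raise SchemaError(f"reaction {self.id!r}: flux must be positive")
        unit_L = self.L / self.flux
        if min(abs(unit_L - a) for a in self.ALLOWED_L) > 1e-9:
            raise SchemaError(
                f"reaction {self.id!r}: SLP token L={unit_L} not in {self.ALLOWED_L}"
            )
        if self.carrier_options and ELECTRON not in self.stoich:
            raise SchemaError(
                f"reaction {self.id!r}: carrier options given but the reaction "
                f"is not written in electrons ({ELECTRON!r} absent)"
            )
        if ELECTRON in self.stoich and not self.carrier_options:
            raise SchemaError(
                f"reaction {self.id!r}: written in electrons but no carrier options"
            )

    @property
    def is_redox(self) -> bool:
        return bool(self.carrier_options)


@dataclass(frozen=True)
class CarrierPair:
    """A redox carrier couple (e.g. NAD+/NADH) and how it is regenerated.

    ``regeneration_chain`` is the ordered list of catalogue reaction ids
    that return the couple to its resting state against the terminal
    electron donor/acceptor, including any intermediate carrier shuttles
    (e.g. FAD is re-reduced via NADH, and NAD in turn against H2).
    """

    id: str
    oxidized_species: str
    reduced_species: str
    electrons_transferred: int = 2
    regeneration_chain: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.electrons_transferred <= 0:
            raise SchemaError(f"carrier {self.id!r}: electrons_transferred <= 0")


@dataclass(frozen=True)
class ConservedMoiety:
    """A chemical group exchanged between metabolites but never net made.

    The summed concentration of ``member_species`` is bounded by
    ``pool_bounds`` (mol/L).  ``designated_free_species`` is the member
    (typically the free form, e.g. free CoA) whose concentration alone is
    held above the pool minimum in the linearised constraint mode.
    """

    id: str
    member_species: tuple[str, ...]
    pool_bounds: tuple[float, float]
    designated_free_species: str | None = None

    def __post_init__(self) -> None:
        if self.pool_bounds[0] > self.pool_bounds[1]:
            raise SchemaError(f"moiety {self.id!r}: pool bounds low > high")
        if (
            self.designated_free_species is not None
            and self.designated_free_species not in self.member_species
        ):
            raise SchemaError(
                f"moiety {self.id!r}: designated free species not a member"
            )


@dataclass(frozen=True)
class Pathway:
    """A named, ordered list of (possibly generic) reaction steps."""

    id: str
    reactions: tuple[Reaction, ...]
    name: str = ""

    @property
    def redox_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_redox)


@dataclass(frozen=True)
class PathwayVariant:
    """A carrier-resolved, regeneration-closed realisation of a pathway."""

    id: str
    reactions: tuple[Reaction, ...]
    carrier_assignment: dict[str, str] = field(default_factory=dict)
    overall_reaction: dict[str, float] = field(default_factory=dict)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)


@dataclass(frozen=True)
class ClosureViolation:
    species_id: str
    net_coefficient: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.species_id}: net {self.net_coefficient:+g}"


def net_stoichiometry(reactions) -> dict[str, float]:
    """Summed stoichiometric coefficients over reactions, per species."""
    net: dict[str, float] = {}
    for rxn in reactions:
        for sp, nu in rxn.stoich.items():
            net[sp] = net.get(sp, 0.0) + nu
    return net


def validate_closure(
    variant: PathwayVariant, species: dict[str, Species]
) -> list[ClosureViolation]:
    """Check that no intermediate metabolite is net produced or consumed.

    Returns one violation per non-fixed species with non-zero net
    stoichiometry across the variant (order-independent by construction).
    Unknown species ids raise :class:`SchemaError` naming the reaction.
    """
    for rxn in variant.reactions:
        for sp in rxn.stoich:
            if sp == ELECTRON:
                raise SchemaError(
                    f"reaction {rxn.id!r}: unresolved electron pseudo-species"
                )
            if sp not in species:
                raise SchemaError(
                    f"reaction {rxn.id!r}: unknown species {sp!r}"
                )
    net = net_stoichiometry(variant.reactions)
    return [
        ClosureViolation(sp, coeff)
        for sp, coeff in net.items()
        if abs(coeff) > CLOSURE_TOL and species[sp].role != "fixed_external"
    ]


def resolve_carrier(reaction: Reaction, carrier: CarrierPair) -> Reaction:
    """Rewrite a generic redox reaction in terms of a concrete carrier.

    ``nu_e`` electrons released (positive coefficient of the electron
    pseudo-species) reduce ``nu_e / n_e`` equivalents of the carrier:
    the reduced form appears as product, the oxidised form as reactant.
    """
    if ELECTRON not in reaction.stoich:
        raise SchemaError(f"reaction {reaction.id!r} has no electron term")
    nu_e = reaction.stoich[ELECTRON]
    scale = nu_e / carrier.electrons_transferred
    stoich = {s: c for s, c in reaction.stoich.items() if s != ELECTRON}
    for sp, delta in (
        (carrier.reduced_species, scale),
        (carrier.oxidized_species, -scale),
    ):
        stoich[sp] = stoich.get(sp, 0.0) + delta
        if abs(stoich[sp]) <= CLOSURE_TOL:
            del stoich[sp]
    return replace(
        reaction,
        id=f"{reaction.id}[{carrier.id}]",
        stoich=stoich,
        carrier_options=(),
    )


def _close_regeneration(
    core: list[Reaction],
    chain_reactions: list[Reaction],
    species: dict[str, Species],
) -> list[Reaction]:
    """Scale candidate regeneration reactions to close the carrier balance.

    Solves, by non-negative least squares, for the per-turnover multiplicity
    of each candidate so the net stoichiometry of every non-fixed species
    they touch vanishes; each needed reaction is appended once with its
    stoichiometry scaled by that multiplicity.
    """
    if not chain_reactions:
        return []
    net = net_stoichiometry(core)
    balance_species = sorted(
        {
            sp
            for rxn in chain_reactions
            for sp in rxn.stoich
            if sp in species and species[sp].role != "fixed_external"
        }
        | {
            sp
            for sp, c in net.items()
            if abs(c) > CLOSURE_TOL
            and sp in species
            and species[sp].role != "fixed_external"
        }
    )
    if not balance_species:
        return []
    A = np.array(
        [[rxn.stoich.get(sp, 0.0) for rxn in chain_reactions] for sp in balance_species]
    )
    target = -np.array([net.get(sp, 0.0) for sp in balance_species])
    from scipy.optimize import nnls

    fluxes, residual = nnls(A, target)
    if residual > 1e-7:
        raise InfeasibleCarrierError(
            "regeneration reactions "
            + ", ".join(r.id for r in chain_reactions)
            + " cannot close the carrier balance (residual "
            + f"{residual:.3g}) for species {balance_species}"
        )
    out = []
    for rxn, f in zip(chain_reactions, fluxes):
        if f <= CLOSURE_TOL:
            continue
        if abs(f - 1.0) <= CLOSURE_TOL:
            out.append(rxn)
        else:
            out.append(
                replace(
                    rxn,
                    stoich={sp: f * nu for sp, nu in rxn.stoich.items()},
                    L=rxn.L * f,
                    flux=f,
                )
            )
    return out


def enumerate_variants(
    pathway: Pathway,
    carriers: dict[str, CarrierPair],
    catalogue: dict[str, Reaction],
    species: dict[str, Species],
) -> list[PathwayVariant]:
    """All carrier-resolved, regeneration-closed variants of a pathway.

    Returns exactly ``prod(len(r.carrier_options))`` variants over the redox
    steps (one variant when the pathway has none).  Each variant appends the
    deduplicated regeneration reactions its carriers require — chained
    through intermediate carriers — scaled so every variant passes
    :func:`validate_closure`.
    """
    redox = pathway.redox_reactions
    for rxn in redox:
        for cid in rxn.carrier_options:
            if cid not in carriers:
                raise SchemaError(
                    f"reaction {rxn.id!r}: unknown carrier option {cid!r}"
                )
    option_sets = [rxn.carrier_options for rxn in redox]
    variants: list[PathwayVariant] = []
    for combo in itertools.product(*option_sets) if option_sets else [()]:
        assignment = {rxn.id: cid for rxn, cid in zip(redox, combo)}
        core: list[Reaction] = []
        for rxn in pathway.reactions:
            core.append(
                resolve_carrier(rxn, carriers[assignment[rxn.id]])
                if rxn.is_redox
                else rxn
            )
        chain_ids: list[str] = []
        for cid in combo:
            for rid in carriers[cid].regeneration_chain:
                if rid not in catalogue:
                    raise InfeasibleCarrierError(
                        f"carrier {cid!r}: regeneration reaction {rid!r} "
                        "not in the reaction catalogue"
                    )
                if rid not in chain_ids:
                    chain_ids.append(rid)
        regen = _close_regeneration(
            core, [catalogue[rid] for rid in chain_ids], species
        )
        all_rxns = tuple(core) + tuple(regen)
        net = net_stoichiometry(all_rxns)
        overall = {
            sp: c
            for sp, c in net.items()
            if abs(c) > CLOSURE_TOL
        }
        variant = PathwayVariant(
            id=pathway.id + ("__" + "+".join(combo) if combo else ""),
            reactions=all_rxns,
            carrier_assignment=assignment,
            overall_reaction=overall,
        )
        violations = validate_closure(variant, species)
        if violations:
            raise InfeasibleCarrierError(
                f"variant {variant.id!r} is not closed: "
                + "; ".join(map(str, violations))
            )
        variants.append(variant)
    return variants
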