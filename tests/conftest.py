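import math

import pytest

from bioenopt import (
    Environment,
    Pathway,
    PathwayVariant,
    Reaction,
    Species,
    apply_bounds,
    build_thermo_constraints,
)

#: Conditions of the warm (35 C) case: dG_ATP = 50 kJ/mol, r = 10/3.
ENV_35C = Environment(T=308.15, T_ref=308.15, dG_ATP=50.0, r_H_ATP=10.0 / 3.0)


def single_reaction_system(lnK=12.0, translocating=True, env=ENV_35C):
    """One reaction between two fixed species with an exact target lnK.

    With every species fixed the only decision variable is the reaction's
    integer proton count, which makes both stages solvable by hand.
    """
    # back-solve dGf of the product so that lnK comes out exactly
    dGf_B = -env.RT * lnK
    species = {
        "A": Species(id="A", role="fixed_external", fixed_lnC=0.0, dGf0_ref=0.0),
        "B": Species(id="B", role="fixed_external", fixed_lnC=0.0, dGf0_ref=dGf_B),
    }
    rxn = Reaction(id="r1", stoich={"A": -1.0, "B": 1.0}, translocating=translocating)
    variant = PathwayVariant(
        id="single", reactions=(rxn,), overall_reaction={"A": -1.0, "B": 1.0}
    )
    system = build_thermo_constraints(variant, species, env)
    return apply_bounds(system)


def chain_system(lnKs, env=ENV_35C, translocating=(), lnC_bounds=(-50.0, 0.0)):
    """Linear chain A -> X1 -> ... -> B with prescribed per-step lnK values.

    Endpoints fixed at concentration 1; generous intermediate bounds so the
    even-split optimum is not clipped unless requested.
    """
    n = len(lnKs)
    species = {"A": Species(id="A", role="fixed_external", fixed_lnC=0.0)}
    dGf = {"A": 0.0}
    ids = ["A"] + [f"X{i}" for i in range(1, n)] + ["B"]
    reactions = []
    for j, lnK in enumerate(lnKs):
        sub, prod = ids[j], ids[j + 1]
        dGf[prod] = dGf[sub] - env.RT * lnK
        role = "fixed_external" if prod == "B" else "intermediate"
        species[prod] = Species(
            id=prod,
            role=role,
            dGf0_ref=dGf[prod],
            fixed_lnC=0.0 if role == "fixed_external" else None,
            lnC_bounds=None if role == "fixed_external" else lnC_bounds,
        )
        reactions.append(
            Reaction(
                id=f"r{j + 1}",
                stoich={sub: -1.0, prod: 1.0},
                translocating=j in translocating,
            )
        )
    variant = PathwayVariant(
        id="chain", reactions=tuple(reactions),
        overall_reaction={"A": -1.0, "B": 1.0},
    )
    system = build_thermo_constraints(variant, species, env)
    return apply_bounds(system)


@pytest.fixture
def env_35c():
    return ENV_35C


@pytest.fixture
def toy_factory():
    from bioenopt.fixtures import ToySpec, generate_toy
    from bioenopt.workflow import build_systems

    def make(seed=0, **kwargs):
        doc = generate_toy(ToySpec(seed=seed, **kwargs))
        variants, systems = build_systems(doc)
        return doc, variants, systems

    return make
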