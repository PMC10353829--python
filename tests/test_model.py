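"""Pathway model: closure validation, carrier resolution, variant counts."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioenopt import (
    CarrierPair,
    InfeasibleCarrierError,
    Pathway,
    PathwayVariant,
    Reaction,
    SchemaError,
    Species,
    enumerate_variants,
    validate_closure,
)
from bioenopt.model import net_stoichiometry, resolve_carrier


def _species(*ids, fixed=(), carrier=()):
    out = {}
    for sid in ids:
        if sid in fixed:
            out[sid] = Species(id=sid, role="fixed_external", fixed_lnC=0.0)
        elif sid in carrier:
            out[sid] = Species(id=sid, role="carrier")
        else:
            out[sid] = Species(id=sid)
    return out


class TestClosure:
    def test_closed_two_step_chain(self):
        species = _species("A", "X", "B", fixed=("A", "B"))
        variant = PathwayVariant(
            id="v",
            reactions=(
                Reaction(id="r1", stoich={"A": -1.0, "X": 1.0}),
                Reaction(id="r2", stoich={"X": -1.0, "B": 1.0}),
            ),
        )
        assert validate_closure(variant, species) == []

    def test_dropped_step_reports_unbalanced_intermediate(self):
        species = _species("A", "X", "B", fixed=("A", "B"))
        variant = PathwayVariant(
            id="v", reactions=(Reaction(id="r1", stoich={"A": -1.0, "X": 1.0}),)
        )
        violations = validate_closure(variant, species)
        assert len(violations) == 1
        assert violations[0].species_id == "X"
        assert violations[0].net_coefficient == pytest.approx(1.0)

    def test_unknown_species_names_the_reaction(self):
        species = _species("A", fixed=("A",))
        variant = PathwayVariant(
            id="v", reactions=(Reaction(id="bad", stoich={"A": -1.0, "ghost": 1.0}),)
        )
        with pytest.raises(SchemaError, match="'bad'.*'ghost'"):
            validate_closure(variant, species)

    @given(perm=st.permutations(range(4)))
    @settings(derandomize=True, max_examples=24)
    def test_closure_is_order_independent(self, perm):
        species = _species("A", "X1", "X2", "X3", "B", fixed=("A", "B"))
        ids = ["A", "X1", "X2", "X3", "B"]
        rxns = [
            Reaction(id=f"r{i}", stoich={ids[i]: -1.0, ids[i + 1]: 1.0})
            for i in range(4)
        ]
        variant = PathwayVariant(id="v", reactions=tuple(rxns[i] for i in perm))
        assert validate_closure(variant, species) == []


class TestCarrierResolution:
    NAD = CarrierPair(
        id="nad", oxidized_species="nad_ox", reduced_species="nad_red",
        electrons_transferred=2,
    )

    def test_two_electron_oxidation_consumes_one_carrier_equivalent(self):
        rxn = Reaction(
            id="ox", stoich={"A": -1.0, "B": 1.0, "e-": 2.0},
            carrier_options=("nad",),
        )
        resolved = resolve_carrier(rxn, self.NAD)
        assert resolved.stoich == {
            "A": -1.0, "B": 1.0, "nad_red": 1.0, "nad_ox": -1.0
        }
        assert not resolved.is_redox

    def test_reduction_flips_the_carrier_direction(self):
        rxn = Reaction(
            id="red", stoich={"A": -1.0, "B": 1.0, "e-": -2.0},
            carrier_options=("nad",),
        )
        resolved = resolve_carrier(rxn, self.NAD)
        assert resolved.stoich["nad_ox"] == pytest.approx(1.0)
        assert resolved.stoich["nad_red"] == pytest.approx(-1.0)

    def test_electron_term_requires_carrier_options_and_vice_versa(self):
        with pytest.raises(SchemaError, match="no carrier options"):
            Reaction(id="r", stoich={"A": -1.0, "e-": 2.0})
        with pytest.raises(SchemaError, match="not written in electrons"):
            Reaction(id="r", stoich={"A": -1.0}, carrier_options=("nad",))


def _redox_fixture(option_counts):
    """Chain with len(option_counts) redox steps and shared regeneration."""
    n = len(option_counts)
    species = _species("S", "P", "W", fixed=("S", "P", "W"))
    carriers, catalogue = {}, {}
    core = []
    prev = "S"
    for k, m in enumerate(option_counts):
        opts = []
        for o in range(m):
            cid = f"c{k}_{o}"
            ox, red = f"{cid}ox", f"{cid}red"
            species.update(_species(ox, red, carrier=(ox, red)))
            rid = f"regen_{cid}"
            catalogue[rid] = Reaction(id=rid, stoich={red: -1.0, ox: 1.0, "W": 1.0})
            carriers[cid] = CarrierPair(
                id=cid, oxidized_species=ox, reduced_species=red,
                regeneration_chain=(rid,),
            )
            opts.append(cid)
        nxt = "P" if k == n - 1 else f"X{k}"
        if nxt != "P":
            species.update(_species(nxt))
        core.append(
            Reaction(
                id=f"r{k}", stoich={prev: -1.0, nxt: 1.0, "e-": 2.0},
                carrier_options=tuple(opts),
            )
        )
        prev = nxt
    catalogue.update({r.id: r for r in core})
    return Pathway(id="p", reactions=tuple(core)), carriers, catalogue, species


class TestEnumerateVariants:
    @pytest.mark.parametrize("counts, expected", [((2, 3, 1), 6), ((2, 2), 4)])
    def test_variant_count_is_product_of_options(self, counts, expected):
        pathway, carriers, catalogue, species = _redox_fixture(counts)
        variants = enumerate_variants(pathway, carriers, catalogue, species)
        assert len(variants) == expected
        assert len({tuple(sorted(v.carrier_assignment.items())) for v in variants}) \
            == expected

    def test_pathway_without_redox_steps_has_one_variant(self):
        species = _species("A", "X", "B", fixed=("A", "B"))
        pathway = Pathway(
            id="p",
            reactions=(
                Reaction(id="r1", stoich={"A": -1.0, "X": 1.0}),
                Reaction(id="r2", stoich={"X": -1.0, "B": 1.0}),
            ),
        )
        variants = enumerate_variants(pathway, {}, {}, species)
        assert len(variants) == 1
        assert variants[0].overall_reaction == {"A": -1.0, "B": 1.0}

    def test_every_variant_is_regeneration_closed(self):
        pathway, carriers, catalogue, species = _redox_fixture((2, 2, 2))
        for variant in enumerate_variants(pathway, carriers, catalogue, species):
            assert validate_closure(variant, species) == []
            net = net_stoichiometry(variant.reactions)
            for sid, sp in species.items():
                if sp.role == "carrier":
                    assert abs(net.get(sid, 0.0)) < 1e-9

    def test_shared_carrier_regeneration_appended_once_scaled(self):
        # both redox steps use the same carrier -> one regeneration step
        # carrying two equivalents
        species = _species("S", "X", "P", "W", fixed=("S", "P", "W"))
        species.update(_species("cox", "cred", carrier=("cox", "cred")))
        regen = Reaction(id="regen_c", stoich={"cred": -1.0, "cox": 1.0, "W": 1.0})
        carriers = {
            "c": CarrierPair(
                id="c", oxidized_species="cox", reduced_species="cred",
                regeneration_chain=("regen_c",),
            )
        }
        core = (
            Reaction(id="r1", stoich={"S": -1.0, "X": 1.0, "e-": 2.0},
                     carrier_options=("c",)),
            Reaction(id="r2", stoich={"X": -1.0, "P": 1.0, "e-": 2.0},
                     carrier_options=("c",)),
        )
        catalogue = {"regen_c": regen, "r1": core[0], "r2": core[1]}
        pathway = Pathway(id="p", reactions=core)
        variants = enumerate_variants(pathway, carriers, catalogue, species)
        assert len(variants) == 1
        appended = [r for r in variants[0].reactions if r.id.startswith("regen")]
        assert len(appended) == 1
        assert appended[0].flux == pytest.approx(2.0)
        assert appended[0].stoich["cred"] == pytest.approx(-2.0)

    def test_missing_regeneration_reaction_is_infeasible_carrier(self):
        pathway, carriers, catalogue, species = _redox_fixture((1,))
        carriers["c0_0"] = CarrierPair(
            id="c0_0",
            oxidized_species=carriers["c0_0"].oxidized_species,
            reduced_species=carriers["c0_0"].reduced_species,
            regeneration_chain=("nonexistent",),
        )
        with pytest.raises(InfeasibleCarrierError, match="c0_0"):
            enumerate_variants(pathway, carriers, catalogue, species)

    def test_unregenerable_carrier_is_reported(self):
        pathway, carriers, catalogue, species = _redox_fixture((1,))
        carriers["c0_0"] = CarrierPair(
            id="c0_0",
            oxidized_species=carriers["c0_0"].oxidized_species,
            reduced_species=carriers["c0_0"].reduced_species,
            regeneration_chain=(),  # no path back to the terminal acceptor
        )
        with pytest.raises(InfeasibleCarrierError):
            enumerate_variants(pathway, carriers, catalogue, species)


class TestSpeciesInvariants:
    def test_fixed_external_requires_concentration(self):
        with pytest.raises(SchemaError, match="fixed_lnC"):
            Species(id="s", role="fixed_external")

    def test_intermediate_cannot_be_prefixed(self):
        with pytest.raises(SchemaError):
            Species(id="s", role="intermediate", fixed_lnC=0.0)

    def test_prefixed_carrier_is_excluded_from_decision_vector(self):
        sp = Species(id="nadh", role="carrier", fixed_lnC=math.log(1e-3))
        assert sp.is_fixed
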