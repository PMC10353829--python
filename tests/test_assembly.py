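"""Constraint assembly: rows, bounds, moiety pools, Gibbs reconstruction."""

import math

import numpy as np
import pytest

from bioenopt import (
    ConfigurationError,
    ConservedMoiety,
    Environment,
    PathwayVariant,
    Reaction,
    Species,
    apply_bounds,
    build_thermo_constraints,
    check_moiety_pools,
    moiety_constraints,
    overall_gibbs,
)
from conftest import ENV_35C, chain_system, single_reaction_system


class TestThermoRows:
    def test_all_fixed_reaction_populates_only_np_column(self):
        system = single_reaction_system(lnK=12.0)
        assert system.n_lnC == 0
        assert system.A.shape == (1, 1)
        assert system.A[0, 0] == pytest.approx(ENV_35C.pmf_coeff)
        assert system.b[0] == pytest.approx(12.0)

    def test_hand_assembled_row_with_free_product(self):
        # A(fixed, lnC=0) -> X(free), lnK = 12, translocating, 35 C case
        env = ENV_35C
        species = {
            "A": Species(id="A", role="fixed_external", fixed_lnC=0.0),
            "X": Species(id="X", dGf0_ref=-env.RT * 12.0),
        }
        rxn = Reaction(id="r1", stoich={"A": -1.0, "X": 1.0}, translocating=True)
        variant = PathwayVariant(id="v", reactions=(rxn,))
        system = build_thermo_constraints(variant, species, env)
        col_x = system.lnC_cols["X"]
        col_np = system.np_cols[0]
        assert system.A[0, col_x] == pytest.approx(1.0)
        assert system.A[0, col_np] == pytest.approx(5.855, abs=5e-4)
        assert system.b[0] == pytest.approx(12.0)

    def test_fixed_species_shift_moves_to_rhs(self):
        env = Environment()
        species = {
            "A": Species(id="A", role="fixed_external", fixed_lnC=math.log(1e-2)),
            "X": Species(id="X"),
        }
        rxn = Reaction(id="r", stoich={"A": -2.0, "X": 1.0})
        system = build_thermo_constraints(
            PathwayVariant(id="v", reactions=(rxn,)), species, env
        )
        # b = lnK - (-2)*ln(1e-2); lnK = 0 since all dGf are zero
        assert system.b[0] == pytest.approx(2 * math.log(1e-2))
        assert system.fixed_shift[0] == pytest.approx(-2 * math.log(1e-2))

    def test_constant_formation_shift_that_cancels_leaves_system_unchanged(self):
        """Shifting all dGf by per-element constants that cancel row-wise."""
        env = Environment()

        def build(offset):
            species = {
                "A": Species(id="A", role="fixed_external", fixed_lnC=0.0,
                             dGf0_ref=-10.0 + offset),
                "B": Species(id="B", role="fixed_external", fixed_lnC=-1.0,
                             dGf0_ref=-35.0 + offset),
                "X": Species(id="X", dGf0_ref=-20.0 + offset),
            }
            rxns = (
                Reaction(id="r1", stoich={"A": -1.0, "X": 1.0}, translocating=True),
                Reaction(id="r2", stoich={"X": -1.0, "B": 1.0}),
            )
            return build_thermo_constraints(
                PathwayVariant(id="v", reactions=rxns), species, env
            )

        s0, s1 = build(0.0), build(123.456)
        np.testing.assert_allclose(s0.A, s1.A)
        np.testing.assert_allclose(s0.b, s1.b, atol=1e-9)

    def test_dG_min_threshold_tightens_rhs(self):
        base = single_reaction_system(lnK=12.0)
        env = ENV_35C
        species = {
            "A": Species(id="A", role="fixed_external", fixed_lnC=0.0),
            "B": Species(id="B", role="fixed_external", fixed_lnC=0.0,
                         dGf0_ref=-env.RT * 12.0),
        }
        rxn = Reaction(id="r1", stoich={"A": -1.0, "B": 1.0},
                       translocating=True, dG_min=2.0)
        system = build_thermo_constraints(
            PathwayVariant(id="v", reactions=(rxn,)), species, env
        )
        assert system.b[0] == pytest.approx(base.b[0] - 2.0 / env.RT)


class TestBounds:
    def test_default_concentration_window(self):
        system = chain_system([1.0, 2.0], lnC_bounds=None)
        # rebuild with defaults: all free lnC in [ln 1e-6, ln 1e-2]
        lnC_cols = list(system.lnC_cols.values())
        assert np.allclose(system.lb[lnC_cols], math.log(1e-6))
        assert np.allclose(system.ub[lnC_cols], math.log(1e-2))
        assert math.log(1e-6) == pytest.approx(-13.8155, abs=5e-4)
        assert math.log(1e-2) == pytest.approx(-4.6052, abs=5e-4)

    def test_per_species_override_survives_defaults(self):
        system = chain_system([1.0, 2.0, 3.0], lnC_bounds=(-9.0, -5.0))
        for col in system.lnC_cols.values():
            assert system.lb[col] == pytest.approx(-9.0)
            assert system.ub[col] == pytest.approx(-5.0)

    @pytest.mark.parametrize("r, bound", [(10.0 / 3.0, 3), (9.0 / 3.0, 3), (2.5, 2)])
    def test_np_bounds_floor_of_proton_ratio(self, r, bound):
        env = Environment(r_H_ATP=r)
        assert env.np_bound == bound

    def test_unbounded_variable_is_configuration_error(self):
        env = Environment()
        species = {
            "A": Species(id="A", role="fixed_external", fixed_lnC=0.0),
            "X": Species(id="X"),
        }
        system = build_thermo_constraints(
            PathwayVariant(
                id="v", reactions=(Reaction(id="r", stoich={"A": -1.0, "X": 1.0}),)
            ),
            species,
            env,
        )
        with pytest.raises(ConfigurationError, match="lnC:X"):
            system.require_bounded()

    def test_inverted_default_bounds_rejected(self):
        system = chain_system([1.0])
        with pytest.raises(ConfigurationError):
            apply_bounds(system, lnC_default=(0.0, -1.0))


class TestMoieties:
    def _two_member_system(self):
        env = Environment()
        species = {
            "S": Species(id="S", role="fixed_external", fixed_lnC=0.0),
            "coa": Species(id="coa"),
            "acoa": Species(id="acoa"),
            "P": Species(id="P", role="fixed_external", fixed_lnC=0.0),
        }
        rxns = (
            Reaction(id="r1", stoich={"S": -1.0, "coa": -1.0, "acoa": 1.0}),
            Reaction(id="r2", stoich={"acoa": -1.0, "coa": 1.0, "P": 1.0}),
        )
        system = build_thermo_constraints(
            PathwayVariant(id="v", reactions=rxns), species, env
        )
        return apply_bounds(system)

    def test_single_member_pool_reduces_to_species_bounds(self):
        system = chain_system([1.0, 2.0], lnC_bounds=None)
        system = apply_bounds(system)
        cm = ConservedMoiety(id="m", member_species=("X1",),
                             pool_bounds=(1e-5, 1e-3),
                             designated_free_species="X1")
        out = moiety_constraints(system, [cm])
        col = out.lnC_cols["X1"]
        assert out.ub[col] == pytest.approx(math.log(1e-3))
        assert out.lb[col] == pytest.approx(math.log(1e-5))

    def test_two_members_at_half_cap_pass_post_check(self):
        system = self._two_member_system()
        cm = ConservedMoiety(id="coa_pool", member_species=("coa", "acoa"),
                             pool_bounds=(0.0, 1e-2))
        out = moiety_constraints(system, [cm])
        lnC = {"coa": math.log(5e-3), "acoa": math.log(5e-3)}
        assert check_moiety_pools(out, lnC) == []
        # cap per member is C_max / 2
        for sp in ("coa", "acoa"):
            assert out.ub[out.lnC_cols[sp]] == pytest.approx(math.log(5e-3))

    def test_post_check_reports_pool_overflow_and_underflow(self):
        system = self._two_member_system()
        cm = ConservedMoiety(id="coa_pool", member_species=("coa", "acoa"),
                             pool_bounds=(1e-4, 1e-2))
        out = moiety_constraints(system, [cm], mode="off")
        over = {"coa": math.log(9e-3), "acoa": math.log(9e-3)}
        under = {"coa": math.log(1e-5), "acoa": math.log(1e-5)}
        assert any("exceeds" in v for v in check_moiety_pools(out, over))
        assert any("below" in v for v in check_moiety_pools(out, under))

    def test_unknown_mode_rejected(self):
        system = self._two_member_system()
        with pytest.raises(ConfigurationError, match="mode"):
            moiety_constraints(system, [], mode="exact")


class TestGibbsReconstruction:
    def test_row_wise_reconstruction_matches_chemical_potential_sum(self):
        """dG from the constraint algebra equals the explicit Eq-by-hand sum."""
        env = Environment(T=310.0, T_ref=298.15)
        species = {
            "A": Species(id="A", role="fixed_external", fixed_lnC=math.log(1e-2),
                         dGf0_ref=-10.0, dHf0=-3.0),
            "X": Species(id="X", dGf0_ref=-25.0, dHf0=-8.0),
            "B": Species(id="B", role="fixed_external", fixed_lnC=math.log(1e-4),
                         dGf0_ref=-60.0, dHf0=-20.0),
        }
        rxns = (
            Reaction(id="r1", stoich={"A": -1.0, "X": 1.0}, L=-1.0,
                     translocating=True),
            Reaction(id="r2", stoich={"X": -1.0, "B": 1.0}, L=1.0),
        )
        variant = PathwayVariant(id="v", reactions=rxns)
        system = apply_bounds(build_thermo_constraints(variant, species, env))
        x = np.zeros(system.n_vars)
        x[system.lnC_cols["X"]] = math.log(3e-4)
        x[system.np_cols[0]] = 2.0
        dG = system.reaction_gibbs(x)

        from bioenopt import chemical_potential, gibbs_formation_at_T

        lnC = {"A": math.log(1e-2), "X": math.log(3e-4), "B": math.log(1e-4)}
        for j, rxn in enumerate(rxns):
            mu_sum = sum(
                nu * chemical_potential(
                    gibbs_formation_at_T(
                        species[s].dGf0_ref, species[s].dHf0, env.T, env.T_ref
                    ),
                    lnC[s], env.T,
                )
                for s, nu in rxn.stoich.items()
            )
            n_p = 2.0 if j == 0 else 0.0
            expected = (
                mu_sum + rxn.L * env.dG_ATP + n_p * env.dG_ATP / env.r_H_ATP
            )
            assert dG[j] == pytest.approx(expected, abs=1e-9)


class TestOverallGibbs:
    def test_matches_telescoped_formation_difference(self):
        env = ENV_35C
        system = chain_system([3.0, 4.0, 5.0], env=env)
        dg = overall_gibbs(system.variant, system.species, env)
        # sum of lnK = 12 -> dG_overall = -RT * 12 at unit fixed concentrations
        assert dg == pytest.approx(-env.RT * 12.0, rel=1e-9)
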