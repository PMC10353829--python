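"""Assembly of the mixed-integer constraint system A x <= b.

For a pathway variant evaluated at fixed conditions, every reaction j
contributes one row

    sum_free nu_ij * lnC_i  +  pmf * n_p,j  <=  lnK_j + F_j - sum_fixed nu_ij * lnC_i

over the decision vector x = (lnC of free species..., n_p of translocating
reactions...).  ``pmf`` is the dimensionless proton-motive-force coefficient
dG_ATP/(r_H_ATP * R * T), common to all rows.  F_j = -dG_min,j/(R*T)
encodes an optional per-reaction driving-force threshold: dG_min,j is the
non-negative magnitude of dissipation required of reaction j, enforcing
dG_r,j <= -dG_min,j (0 by default, so equilibrium-feasible solutions are
accepted in the yield stage).

Conserved-moiety pool limits (sum of member concentrations within
[C_min, C_max]) are nonlinear in lnC; the default ``linear_safe`` mode
enforces a sufficient linear surrogate via bound tightening and the true
pool inequalities are always re-checked on the solved concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ConservedMoiety, PathwayVariant, SchemaError, Species
from .thermo import Environment, gibbs_formation_at_T, reaction_energetics

__all__ = [
    "ConfigurationError",
    "CapabilityError",
    "ConstraintSystem",
    "formation_energies_at_T",
    "build_thermo_constraints",
    "apply_bounds",
    "moiety_constraints",
    "check_moiety_pools",
    "overall_gibbs",
]

#: Default free-metabolite concentration window, mol/L.
DEFAULT_C_BOUNDS = (1e-6, 1e-2)

MOIETY_MODES = ("linear_safe", "nonlinear", "off")


class ConfigurationError(ValueError):
    """The constraint system is not fully specified."""


class CapabilityError(RuntimeError):
    """The selected solver cannot handle the requested constraint form."""


@dataclass
class ConstraintSystem:
    """Canonical MILP data for one pathway variant.

    Rows are reactions (in variant order); columns are the decision
    variables: free-species ln-concentrations first, then integer proton
    counts of translocating reactions.  Bounds start unset (NaN) and are
    filled by :func:`apply_bounds`.
    """

    variant: PathwayVariant
    env: Environment
    species: dict[str, Species]
    var_names: list[str]
    lnC_cols: dict[str, int]  #: species id -> column
    np_cols: dict[int, int]  #: reaction row index -> column
    A: np.ndarray
    b: np.ndarray
    row_labels: list[str]
    lnK: np.ndarray
    F: np.ndarray  #: per-row driving-force threshold term, -dG_min/RT
    fixed_shift: np.ndarray  #: per-row sum of nu * lnC over fixed species
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray  #: 1 for integer (n_p) columns, 0 otherwise
    moieties: list[ConservedMoiety] = field(default_factory=list)
    moiety_mode: str = "off"

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_lnC(self) -> int:
        return len(self.lnC_cols)

    @property
    def np_columns(self) -> np.ndarray:
        return np.array(sorted(self.np_cols.values()), dtype=int)

    def copy(self) -> "ConstraintSystem":
        return replace(
            self,
            A=self.A.copy(),
            b=self.b.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            integrality=self.integrality.copy(),
            var_names=list(self.var_names),
            row_labels=list(self.row_labels),
            moieties=list(self.moieties),
        )

    def require_bounded(self) -> None:
        if np.isnan(self.lb).any() or np.isnan(self.ub).any():
            unset = [
                name
                for name, lo, hi in zip(self.var_names, self.lb, self.ub)
                if math.isnan(lo) or math.isnan(hi)
            ]
            raise ConfigurationError(
                "unbounded decision variables (call apply_bounds): "
                + ", ".join(unset)
            )

    def reaction_gibbs(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction Gibbs energy change (kJ/mol) at decision vector x.

        Reconstructed as RT * (A_j . x + fixed_shift_j - lnK_j), which is
        algebraically identical to summing chemical potentials with the SLP
        and translocation terms.
        """
        return self.env.RT * (self.A @ x + self.fixed_shift - self.lnK)

    def to_tables(self):
        """Row/column labelled dump (pandas DataFrame + metadata dict)."""
        import pandas as pd

        df = pd.DataFrame(self.A, index=self.row_labels, columns=self.var_names)
        df["<=b"] = self.b
        meta = {
            "pmf_coeff": self.env.pmf_coeff,
            "RT": self.env.RT,
            "lnK": self.lnK.tolist(),
            "F": self.F.tolist(),
            "fixed_shift": self.fixed_shift.tolist(),
            "integrality": self.integrality.tolist(),
            "lb": self.lb.tolist(),
            "ub": self.ub.tolist(),
            "moiety_mode": self.moiety_mode,
        }
        return df, meta


def formation_energies_at_T(
    species: dict[str, Species], env: Environment
) -> dict[str, float]:
    """Van't Hoff-corrected formation Gibbs energies at env.T for all species."""
    return {
        sid: gibbs_formation_at_T(sp.dGf0_ref, sp.dHf0, env.T, env.T_ref)
        for sid, sp in species.items()
    }


def build_thermo_constraints(
    variant: PathwayVariant,
    species: dict[str, Species],
    env: Environment,
    dG_min: dict[str, float] | None = None,
) -> ConstraintSystem:
    """One thermodynamic row per variant reaction, in canonical MILP form.

    ``dG_min`` overrides the per-reaction required dissipation magnitude
    (kJ/mol, non-negative; dG_r <= -dG_min) by reaction id; reactions keep
    their own ``dG_min`` attribute otherwise.
    """
    dG_min = dG_min or {}
    for rxn in variant.reactions:
        for sp in rxn.stoich:
            if sp not in species:
                raise SchemaError(f"reaction {rxn.id!r}: unknown species {sp!r}")

    dGf_T = formation_energies_at_T(
        {
            sid: sp
            for sid, sp in species.items()
            if any(sid in r.stoich for r in variant.reactions)
        },
        env,
    )

    free_ids: list[str] = []
    for rxn in variant.reactions:
        for sp in rxn.stoich:
            if not species[sp].is_fixed and sp not in free_ids:
                free_ids.append(sp)
    lnC_cols = {sp: i for i, sp in enumerate(free_ids)}
    np_cols = {
        j: len(free_ids) + k
        for k, j in enumerate(
            j for j, r in enumerate(variant.reactions) if r.translocating
        )
    }
    var_names = ["lnC:" + sp for sp in free_ids] + [
        "np:" + variant.reactions[j].id for j in sorted(np_cols)
    ]
    n_rows, n_vars = len(variant.reactions), len(var_names)
    A = np.zeros((n_rows, n_vars))
    lnK = np.zeros(n_rows)
    F = np.zeros(n_rows)
    shift = np.zeros(n_rows)
    for j, rxn in enumerate(variant.reactions):
        energ = reaction_energetics(rxn.stoich, rxn.L, dGf_T, env)
        lnK[j] = energ.lnK
        F[j] = -dG_min.get(rxn.id, rxn.dG_min) / env.RT
        for sp, nu in rxn.stoich.items():
            if species[sp].is_fixed:
                shift[j] += nu * species[sp].fixed_lnC
            else:
                A[j, lnC_cols[sp]] += nu
        if rxn.translocating:
            A[j, np_cols[j]] = env.pmf_coeff
    b = lnK + F - shift

    lb = np.full(n_vars, np.nan)
    ub = np.full(n_vars, np.nan)
    for sp, col in lnC_cols.items():
        if species[sp].lnC_bounds is not None:
            lb[col], ub[col] = species[sp].lnC_bounds
    integrality = np.zeros(n_vars, dtype=int)
    for col in np_cols.values():
        integrality[col] = 1
    return ConstraintSystem(
        variant=variant,
        env=env,
        species=species,
        var_names=var_names,
        lnC_cols=lnC_cols,
        np_cols=np_cols,
        A=A,
        b=b,
        row_labels=[r.id for r in variant.reactions],
        lnK=lnK,
        F=F,
        fixed_shift=shift,
        lb=lb,
        ub=ub,
        integrality=integrality,
    )


def apply_bounds(
    system: ConstraintSystem,
    lnC_default: tuple[float, float] = (
        math.log(DEFAULT_C_BOUNDS[0]),
        math.log(DEFAULT_C_BOUNDS[1]),
    ),
    np_default: tuple[int, int] | None = None,
) -> ConstraintSystem:
    """Fill unset variable bounds with defaults; overrides are kept.

    Free metabolites default to ln of the physiological window
    (1e-6 .. 1e-2 mol/L); proton counts default to +-floor(r_H_ATP).
    """
    if lnC_default[0] > lnC_default[1]:
        raise ConfigurationError("lnC default bounds: lower > upper")
    if np_default is None:
        np_default = (-system.env.np_bound, system.env.np_bound)
    if np_default[0] > np_default[1]:
        raise ConfigurationError("np default bounds: lower > upper")
    out = system.copy()
    for col in range(out.n_lnC):
        if math.isnan(out.lb[col]):
            out.lb[col] = lnC_default[0]
        if math.isnan(out.ub[col]):
            out.ub[col] = lnC_default[1]
    for col in out.np_cols.values():
        if math.isnan(out.lb[col]):
            out.lb[col] = np_default[0]
        if math.isnan(out.ub[col]):
            out.ub[col] = np_default[1]
    if (out.lb > out.ub).any():
        raise ConfigurationError("variable bounds: lower > upper after defaults")
    return out


def moiety_constraints(
    system: ConstraintSystem,
    moieties: list[ConservedMoiety],
    mode: str = "linear_safe",
) -> ConstraintSystem:
    """Attach conserved-moiety pool limits C_min <= sum_i C_i <= C_max.

    ``linear_safe`` (default) enforces a sufficient linear surrogate by
    bound tightening: every free member is capped at C_max/|CM| (which
    guarantees the upper pool bound) and the designated free species is
    held at or above C_min (which guarantees the lower pool bound).  The
    exact inequalities are always re-verified on solutions via
    :func:`check_moiety_pools`.  ``nonlinear`` registers the exact
    exponential-sum constraints for solvers that accept them (the bundled
    linear backend does not and will raise :class:`CapabilityError`).
    """
    if mode not in MOIETY_MODES:
        raise ConfigurationError(f"unknown moiety mode {mode!r}")
    out = system.copy()
    out.moieties = list(moieties)
    out.moiety_mode = mode
    if mode != "linear_safe":
        return out
    for cm in moieties:
        members_in = [sp for sp in cm.member_species if sp in out.lnC_cols]
        n = len(cm.member_species)
        cap = math.log(cm.pool_bounds[1] / n)
        for sp in members_in:
            col = out.lnC_cols[sp]
            current = out.ub[col]
            out.ub[col] = cap if math.isnan(current) else min(current, cap)
        free_sp = cm.designated_free_species
        if cm.pool_bounds[0] > 0 and free_sp is not None and free_sp in out.lnC_cols:
            col = out.lnC_cols[free_sp]
            floor_ln = math.log(cm.pool_bounds[0])
            current = out.lb[col]
            out.lb[col] = floor_ln if math.isnan(current) else max(current, floor_ln)
    if (out.lb > out.ub).any():
        raise ConfigurationError(
            "moiety surrogate bounds conflict with existing variable bounds"
        )
    return out


def check_moiety_pools(
    system: ConstraintSystem, lnC_values: dict[str, float]
) -> list[str]:
    """Verify the exact pool inequalities on a solved concentration set.

    Fixed members contribute exp(fixed_lnC).  Returns human-readable
    violation strings (empty when all pools are within limits).
    """
    violations = []
    for cm in system.moieties:
        total = 0.0
        for sp in cm.member_species:
            if sp in lnC_values:
                total += math.exp(lnC_values[sp])
            elif sp in system.species and system.species[sp].is_fixed:
                total += math.exp(system.species[sp].fixed_lnC)
        lo, hi = cm.pool_bounds
        if total > hi * (1 + 1e-9):
            violations.append(
                f"moiety {cm.id}: pool {total:.4g} exceeds C_max {hi:.4g}"
            )
        if total < lo * (1 - 1e-9):
            violations.append(
                f"moiety {cm.id}: pool {total:.4g} below C_min {lo:.4g}"
            )
    return violations


def overall_gibbs(
    variant: PathwayVariant, species: dict[str, Species], env: Environment
) -> float:
    """Gibbs energy of the variant's net (overall) reaction, kJ/mol.

    Evaluated at the fixed external concentrations; every species left in
    the net stoichiometry of a closed variant is fixed by construction.
    """
    dGf_T = formation_energies_at_T(
        {s: species[s] for s in variant.overall_reaction}, env
    )
    total = 0.0
    for sp, nu in variant.overall_reaction.items():
        if not species[sp].is_fixed:
            raise ConfigurationError(
                f"overall reaction contains non-fixed species {sp!r}; "
                "variant is not closed"
            )
        total += nu * (dGf_T[sp] + env.RT * species[sp].fixed_lnC)
    return total
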