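"""Scalar thermodynamics for pathway bioenergetics.

Everything here is plain arithmetic on Gibbs energies: Van't Hoff temperature
correction of formation energies, chemical potentials, standard reaction
Gibbs energy, log-equilibrium constants including substrate-level
phosphorylation (SLP) tokens, the dimensionless proton-motive-force
coefficient, and the flux-force efficacy (FFE).

Sign conventions
----------------
* ``dG_ATP`` is stored as a *positive magnitude* (the energy released by ATP
  hydrolysis); the direction of ATP involvement in a reaction is carried by
  the signed SLP token ``L`` (+1 per ATP recovered via ADP, +1.5 via AMP).
* ``n_p`` (proton translocations) is positive when protons are pumped
  *against* their gradient (energy recovered).  Both positive ``L`` and
  positive ``n_p`` make a reaction less exergonic.
* A reaction's *driving force* is the negative of its Gibbs energy change,
  and must be non-negative for net forward flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "R_KJ",
    "Environment",
    "ReactionEnergetics",
    "gibbs_formation_at_T",
    "chemical_potential",
    "reaction_energetics",
    "flux_force_efficacy",
    "forward_fraction",
]

#: Ideal gas constant, kJ/(mol K).
R_KJ = 0.0083145


@dataclass(frozen=True)
class Environment:
    """Physicochemical conditions under which a pathway is evaluated.

    Parameters
    ----------
    T : float
        Absolute temperature in K.
    dG_ATP : float
        Magnitude of the Gibbs energy of ATP hydrolysis, kJ/mol (positive;
        typically 45–70, the case studies use 50).
    r_H_ATP : float
        Protons translocated per ATP synthesized by ATP synthase
        (10/3 by default).
    pH_in, pH_out : float
        Intra-/extracellular pH.  ``pH_in`` fixes the cytoplasmic proton
        ln-concentration; ``pH_out`` is retained for reporting.
    T_ref : float
        Reference temperature of the tabulated formation energies, K.
    """

    T: float = 298.15
    dG_ATP: float = 50.0
    r_H_ATP: float = 10.0 / 3.0
    pH_in: float = 7.0
    pH_out: float = 7.0
    T_ref: float = 298.15
    R: float = field(default=R_KJ)

    def __post_init__(self) -> None:
        if self.T <= 0 or self.T_ref <= 0:
            raise ValueError("absolute temperatures must be positive")
        if self.dG_ATP <= 0:
            raise ValueError("dG_ATP is a positive magnitude (kJ/mol)")
        if self.r_H_ATP <= 0:
            raise ValueError("r_H_ATP must be positive")

    @property
    def RT(self) -> float:
        """R*T in kJ/mol."""
        return self.R * self.T

    @property
    def pmf_coeff(self) -> float:
        """Dimensionless coefficient of n_p in the constraint matrix.

        Energy per translocated proton, dG_ATP / r_H_ATP, divided by RT.
        """
        return self.dG_ATP / (self.r_H_ATP * self.RT)

    @property
    def np_bound(self) -> int:
        """Default per-reaction proton-translocation bound, floor(r_H_ATP)."""
        return math.floor(self.r_H_ATP)

    @property
    def lnC_proton(self) -> float:
        """Cytoplasmic proton ln-concentration, -pH_in * ln(10)."""
        return -self.pH_in * math.log(10.0)


@dataclass(frozen=True)
class ReactionEnergetics:
    """Derived energetic quantities of one reaction at fixed conditions."""

    dG0: float  #: standard reaction Gibbs energy at T, kJ/mol
    lnK: float  #: -(dG0 + L*dG_ATP)/RT, includes the SLP token
    pmf_coeff: float  #: dG_ATP/(r_H_ATP * RT), common to all reactions

    def __post_init__(self) -> None:
        if not math.isfinite(self.lnK):
            raise ValueError("lnK must be finite")
        if self.pmf_coeff <= 0:
            raise ValueError("pmf_coeff must be positive")


def gibbs_formation_at_T(
    dGf0_ref: float, dHf0: float | None, T: float, T_ref: float = 298.15
) -> float:
    """Van't Hoff correction of a standard Gibbs energy of formation.

    Returns ``dGf0_ref * (T/T_ref) + dHf0 * (1 - T/T_ref)`` in kJ/mol.
    Linear in both inputs; the identity at ``T == T_ref`` never needs the
    enthalpy, so ``dHf0`` may be None in that case only.
    """
    if T <= 0 or T_ref <= 0:
        raise ValueError("temperatures must be positive (K)")
    ratio = T / T_ref
    if ratio == 1.0:
        return dGf0_ref
    if dHf0 is None:
        raise ValueError(
            "standard enthalpy of formation is required to correct a "
            f"formation energy from {T_ref} K to {T} K"
        )
    return dGf0_ref * ratio + dHf0 * (1.0 - ratio)


def chemical_potential(dGf0_T: float, lnC: float, T: float) -> float:
    """Chemical potential mu = dGf0(T) + R*T*lnC, kJ/mol (activity coeff 1)."""
    return dGf0_T + R_KJ * T * lnC


def reaction_energetics(
    stoich: dict[str, float],
    L: float,
    dGf0_at_T: dict[str, float],
    env: Environment,
) -> ReactionEnergetics:
    """Standard Gibbs, lnK and pmf coefficient of one reaction.

    Parameters
    ----------
    stoich : dict
        Signed stoichiometric coefficients keyed by species id.
    L : float
        SLP token (signed; magnitude 0, 1 or 1.5).
    dGf0_at_T : dict
        Formation Gibbs energies *already corrected to env.T*, kJ/mol.
    """
    missing = [s for s in stoich if s not in dGf0_at_T]
    if missing:
        raise KeyError(
            "no formation Gibbs energy for species: " + ", ".join(sorted(missing))
        )
    dG0 = sum(nu * dGf0_at_T[s] for s, nu in stoich.items())
    lnK = -(dG0 + L * env.dG_ATP) / env.RT
    return ReactionEnergetics(dG0=dG0, lnK=lnK, pmf_coeff=env.pmf_coeff)


def flux_force_efficacy(dG_drive: float, T: float) -> float:
    """Flux-force efficacy at dissipation magnitude ``dG_drive`` (kJ/mol).

    FFE = (e^x - 1)/(e^x + 1) with x = dG_drive/(R*T), identically
    tanh(x/2): the net-forward fraction of enzyme catalytic events.
    Strictly increasing from 0 (equilibrium) towards 1.
    """
    if dG_drive < 0:
        raise ValueError("pass the magnitude of the dissipated Gibbs energy")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    return math.tanh(dG_drive / (2.0 * R_KJ * T))


def forward_fraction(dG_drive: float, T: float) -> float:
    """Fraction of enzyme sites catalysing forward flux: (1 + FFE)/2."""
    return (1.0 + flux_force_efficacy(dG_drive, T)) / 2.0
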