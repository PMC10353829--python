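"""Synthetic toy pathways and an independent brute-force oracle.

The generator builds seeded, reproducible linear-chain pathways
(S_ext -> X1 -> ... -> P_ext) with a chosen number of translocating and
redox steps; formation energies are back-solved from sampled per-reaction
log-equilibrium constants, so the thermodynamic layer reproduces the
sampled lnK exactly.  These toys exercise every part of the machinery —
carrier resolution, regeneration closure, moiety surrogates, both
optimisation stages — at sizes where the optimum can also be found by
exhaustive enumeration.

The oracle enumerates every integer proton-translocation assignment within
bounds and solves, per assignment, the continuous max-min problem over the
ln-concentrations as a plain LP.  It shares no code path with the MILP
solve (enumeration + ``linprog`` versus ``milp`` branch-and-bound) and is
the reference against which the optimiser is certified.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .assembly import ConstraintSystem
from .io import PathwayDocument
from .model import CarrierPair, Pathway, Reaction, SchemaError, Species
from .thermo import Environment

__all__ = ["ToySpec", "generate_toy", "OracleResult", "exhaustive_solve"]


@dataclass(frozen=True)
class ToySpec:
    """Recipe for one seeded toy pathway.

    ``carrier_option_counts`` gives, per redox step, how many alternative
    electron carriers are permissible (so the pathway has
    ``prod(carrier_option_counts)`` variants).  ``slp_tokens``, when given,
    assigns the SLP token of each core reaction (length ``n_reactions``).
    """

    n_reactions: int = 6
    n_translocating: int = 2
    carrier_option_counts: tuple[int, ...] = ()
    lnK_range: tuple[float, float] = (-4.0, 14.0)
    seed: int = 0
    slp_tokens: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.n_reactions <= 10:
            raise ValueError("n_reactions must be in 1..10 for oracle use")
        if self.n_translocating > self.n_reactions:
            raise ValueError("more translocating steps than reactions")
        if len(self.carrier_option_counts) > self.n_reactions:
            raise ValueError("more redox steps than reactions")
        if self.slp_tokens is not None and len(self.slp_tokens) != self.n_reactions:
            raise ValueError("slp_tokens must have one entry per reaction")


def generate_toy(spec: ToySpec) -> PathwayDocument:
    """Build a reproducible toy pathway document from a spec.

    The chain species' formation energies are back-solved so each core
    reaction's lnK (with its first-listed carrier, for redox steps) equals
    a value sampled uniformly from ``spec.lnK_range``; regeneration steps
    get their own sampled lnK via a per-carrier fixed terminal product.
    """
    rng = np.random.default_rng(spec.seed)
    env = Environment(T=298.15, dG_ATP=50.0, r_H_ATP=10.0 / 3.0)
    n = spec.n_reactions
    slp = spec.slp_tokens or (0.0,) * n

    positions = list(range(n))
    redox_pos = sorted(
        rng.choice(positions, size=len(spec.carrier_option_counts), replace=False)
    )
    transloc_pos = set(
        rng.choice(positions, size=spec.n_translocating, replace=False).tolist()
    )

    species: dict[str, Species] = {}
    chain_ids = ["S_ext"] + [f"X{i}" for i in range(1, n)] + ["P_ext"]
    species["S_ext"] = Species(
        id="S_ext", role="fixed_external", fixed_lnC=math.log(1e-2), dGf0_ref=0.0
    )

    carriers: dict[str, CarrierPair] = {}
    catalogue: dict[str, Reaction] = {}
    dGf: dict[str, float] = {"S_ext": 0.0}

    # carriers and their regeneration reactions, per redox step
    step_options: dict[int, tuple[str, ...]] = {}
    for k, (pos, n_opt) in enumerate(zip(redox_pos, spec.carrier_option_counts)):
        opts = []
        for o in range(n_opt):
            cid = f"c{k}_{o}"
            ox, red = f"{cid}_ox", f"{cid}_red"
            dGf[ox] = 0.0
            dGf[red] = float(rng.uniform(-30.0, 30.0))
            species[ox] = Species(id=ox, role="carrier", dGf0_ref=dGf[ox])
            species[red] = Species(id=red, role="carrier", dGf0_ref=dGf[red])
            waste = f"W_{cid}"
            lnK_regen = float(rng.uniform(*spec.lnK_range))
            # red -> ox + waste with the sampled lnK
            dGf[waste] = -env.RT * lnK_regen - dGf[ox] + dGf[red]
            species[waste] = Species(
                id=waste, role="fixed_external",
                fixed_lnC=math.log(1e-4), dGf0_ref=dGf[waste],
            )
            rid = f"regen_{cid}"
            catalogue[rid] = Reaction(
                id=rid, stoich={red: -1.0, ox: 1.0, waste: 1.0}
            )
            carriers[cid] = CarrierPair(
                id=cid, oxidized_species=ox, reduced_species=red,
                electrons_transferred=2, regeneration_chain=(rid,),
            )
            opts.append(cid)
        step_options[pos] = tuple(opts)

    core: list[Reaction] = []
    for i in range(n):
        sub, prod = chain_ids[i], chain_ids[i + 1]
        lnK = float(rng.uniform(*spec.lnK_range))
        dG0 = -env.RT * lnK - slp[i] * env.dG_ATP
        stoich: dict[str, float] = {sub: -1.0, prod: 1.0}
        carrier_terms = 0.0
        opts: tuple[str, ...] = ()
        if i in step_options:
            stoich["e-"] = 2.0  # oxidation releasing one electron pair
            opts = step_options[i]
            first = carriers[opts[0]]
            carrier_terms = dGf[first.reduced_species] - dGf[first.oxidized_species]
        # dG0 = dGf(prod) - dGf(sub) + carrier_terms  (first-option carrier)
        dGf[prod] = dG0 + dGf[sub] - carrier_terms
        role = "fixed_external" if prod == "P_ext" else "intermediate"
        species[prod] = Species(
            id=prod, role=role, dGf0_ref=dGf[prod],
            fixed_lnC=math.log(1e-4) if role == "fixed_external" else None,
        )
        rxn = Reaction(
            id=f"r{i + 1}", stoich=stoich, L=slp[i],
            translocating=i in transloc_pos, carrier_options=opts,
        )
        core.append(rxn)
        catalogue[rxn.id] = rxn

    pathway = Pathway(id="toy", name="synthetic toy chain", reactions=tuple(core))
    return PathwayDocument(
        species=species,
        reactions=catalogue,
        carriers=carriers,
        moieties=[],
        pathways=[pathway],
        env=env,
        metadata={"generator": "bioenopt.fixtures.generate_toy", "seed": spec.seed},
    )


@dataclass
class OracleResult:
    feasible: bool
    np_total: int | None = None
    B_by_eps: dict[int, float | None] = field(default_factory=dict)


#: Largest number of integer assignments the oracle will enumerate.
MAX_ASSIGNMENTS = 20_000


def _maxmin_lp(A_lnC, rhs2, F_lb, lb, ub):
    """max B s.t. A x + B <= rhs2, A x <= rhs2 - F_lb, lb <= x <= ub.

    Returns B* or None if infeasible.
    """
    m, n = A_lnC.shape
    if n == 0:
        slack = rhs2 - 0.0
        if np.all(F_lb <= rhs2 + 1e-12):
            return float(np.min(slack)) if m else math.inf
        return None
    A_ub = np.hstack([A_lnC, np.ones((m, 1))])
    b_ub = rhs2.copy()
    if np.any(F_lb > 0):
        A_ub = np.vstack([A_ub, np.hstack([A_lnC, np.zeros((m, 1))])])
        b_ub = np.concatenate([b_ub, rhs2 - F_lb])
    c = np.zeros(n + 1)
    c[-1] = -1.0
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub,
        bounds=[(lo, hi) for lo, hi in zip(lb, ub)] + [(None, None)],
        method="highs",
    )
    return float(res.x[-1]) if res.status == 0 else None


def exhaustive_solve(
    system: ConstraintSystem, epsilons: tuple[int, ...] = (0,)
) -> OracleResult:
    """Both-stage optima by enumerating every integer n_p assignment.

    For each assignment a continuous max-min LP over the ln-concentrations
    yields its best minimum driving force; stage-1 feasibility is B >= 0
    under the built thresholds.  Intended for small instances only (raises
    on more than ~20k assignments).
    """
    system.require_bounded()
    np_cols = sorted(system.np_cols.values())
    lnC_cols = list(range(system.n_lnC))
    ranges = [
        range(int(system.lb[c]), int(system.ub[c]) + 1) for c in np_cols
    ]
    total = math.prod(len(r) for r in ranges) if ranges else 1
    if total > MAX_ASSIGNMENTS:
        raise ValueError(
            f"instance too large for exhaustive enumeration ({total} assignments)"
        )
    A_lnC = system.A[:, lnC_cols] if lnC_cols else np.zeros((system.n_rows, 0))
    A_np = system.A[:, np_cols] if np_cols else np.zeros((system.n_rows, 0))
    lb = system.lb[lnC_cols]
    ub = system.ub[lnC_cols]
    rhs_stage2 = system.b - system.F  # lnK - fixed shift
    F_lb = -system.F  # required per-row driving force, dG_min/RT

    best_B: dict[int, float] = {}  # np_sum -> best max-min B
    for combo in itertools.product(*ranges) if ranges else [()]:
        npv = np.array(combo, dtype=float)
        rhs = rhs_stage2 - (A_np @ npv if len(npv) else 0.0)
        B = _maxmin_lp(A_lnC, rhs, F_lb, lb, ub)
        if B is None:
            continue
        s = int(sum(combo))
        if s not in best_B or B > best_B[s]:
            best_B[s] = B
    # stage-1 feasibility: thresholds satisfiable, i.e. B >= 0 given F_lb
    feasible_sums = [s for s, B in best_B.items() if B >= -1e-9]
    if not feasible_sums:
        return OracleResult(feasible=False)
    np_star = max(feasible_sums)
    out = OracleResult(feasible=True, np_total=np_star)
    for eps in epsilons:
        target = np_star - int(eps)
        B = best_B.get(target)
        out.B_by_eps[int(eps)] = B if (B is not None and B >= -1e-9) else None
    return out
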