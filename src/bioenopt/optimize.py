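"""Two-stage epsilon-constraint solve: max ATP yield, then max-min driving force.

Stage 1 maximises the net number of proton translocations, sum(n_p), with
all driving-force thresholds at zero — the best achievable energy yield,
since SLP is stoichiometrically fixed.  Stage 2 fixes sum(n_p) to the
stage-1 optimum minus a user-chosen integer concession ``epsilon`` and
maximises the minimum driving force (MDF) via the classic minimax
construction: per-reaction driving-force variables F_j with F_j >= B and
objective max B; MDF = B * R * T in kJ/mol.  Sweeping epsilon traces the
Pareto front between energy yield and kinetic driving force.

Stage 2 leaves the individual n_p,j free (subject to the sum equality), so
alternative arrangements of the translocation sites reaching the same
optimum can be observed and enumerated with no-good cuts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .assembly import CapabilityError, ConstraintSystem, check_moiety_pools

__all__ = [
    "SolutionRecord",
    "ParetoPoint",
    "VariantResult",
    "ScipyHighsBackend",
    "stage1_max_yield",
    "stage2_max_mdf",
    "pareto_sweep",
    "enumerate_alternate_optima",
    "evaluate_variants",
]

INT_TOL = 1e-6
OBJ_TOL = 1e-9


@dataclass
class SolutionRecord:
    """Outcome of one optimisation stage on one pathway variant."""

    stage: int
    solver_status: str
    variant_id: str = ""
    np_total: int | None = None
    np_by_reaction: dict[str, int] = field(default_factory=dict)
    lnC: dict[str, float] = field(default_factory=dict)
    F: dict[str, float] = field(default_factory=dict)
    B: float | None = None
    MDF_kJ: float | None = None
    net_ATP: float | None = None
    net_energy_kJ: float | None = None
    dG_by_reaction: dict[str, float] = field(default_factory=dict)
    moiety_violations: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.solver_status == "optimal"


@dataclass(frozen=True)
class ParetoPoint:
    """One point of the yield-vs-driving-force trade-off curve."""

    epsilon: int
    net_energy_kJ: float | None
    MDF_kJ: float | None
    best_variant_id: str
    status: str = "optimal"
    ties: tuple[str, ...] = ()


@dataclass
class VariantResult:
    variant_id: str
    stage1: SolutionRecord
    stage2: dict[int, SolutionRecord] = field(default_factory=dict)


_STATUS = {0: "optimal", 1: "limit_reached", 2: "infeasible", 3: "unbounded"}


class ScipyHighsBackend:
    """Minimal MILP backend over scipy's HiGHS interface.

    Solves min c.x subject to A_ub x <= b_ub, A_eq x = b_eq and variable
    bounds/integrality.  Linear constraints only; the exact (exponential)
    conserved-moiety form is out of this backend's capability.
    """

    supports_nonlinear = False
    name = "scipy-highs"

    def solve(self, c, A_ub=None, b_ub=None, A_eq=None, b_eq=None,
              lb=None, ub=None, integrality=None):
        constraints = []
        if A_ub is not None and len(A_ub):
            constraints.append(LinearConstraint(A_ub, -np.inf, b_ub))
        if A_eq is not None and len(A_eq):
            constraints.append(LinearConstraint(A_eq, b_eq, b_eq))
        res = milp(
            c=c,
            constraints=constraints,
            bounds=Bounds(lb, ub),
            integrality=integrality,
            options={"mip_rel_gap": OBJ_TOL},
        )
        status = _STATUS.get(res.status, f"error({res.status})")
        return status, res.x, res.fun, res.message


def _prepare(system: ConstraintSystem, backend) -> None:
    if system.moiety_mode == "nonlinear" and not backend.supports_nonlinear:
        raise CapabilityError(
            f"backend {backend.name!r} is linear-only; use moiety mode "
            "'linear_safe' (sufficient surrogate + exact post-check) or 'off'"
        )
    system.require_bounded()


def _np_vector(system: ConstraintSystem, x: np.ndarray) -> dict[str, int]:
    out = {}
    for j, rxn in enumerate(system.variant.reactions):
        col = system.np_cols.get(j)
        out[rxn.id] = 0 if col is None else int(round(x[col]))
    return out


def _fill_solution(
    record: SolutionRecord, system: ConstraintSystem, x: np.ndarray
) -> SolutionRecord:
    env = system.env
    record.np_by_reaction = _np_vector(system, x)
    record.np_total = sum(record.np_by_reaction.values())
    record.lnC = {sp: float(x[col]) for sp, col in system.lnC_cols.items()}
    slp = sum(r.L for r in system.variant.reactions)
    record.net_ATP = record.np_total / env.r_H_ATP + slp
    record.net_energy_kJ = record.net_ATP * env.dG_ATP
    record.dG_by_reaction = dict(
        zip(system.row_labels, system.reaction_gibbs(x))
    )
    record.moiety_violations = check_moiety_pools(system, record.lnC)
    record.variant_id = system.variant.id
    return record


def stage1_max_yield(
    system: ConstraintSystem, backend: ScipyHighsBackend | None = None
) -> SolutionRecord:
    """Maximise the net proton translocation count sum(n_p).

    Infeasibility (the variant is thermodynamically impossible at these
    conditions) is reported as a status, not raised.
    """
    backend = backend or ScipyHighsBackend()
    _prepare(system, backend)
    if system.n_vars == 0:
        # every species fixed, nothing translocating: pure feasibility check
        feasible = bool(np.all(system.b >= -INT_TOL))
        record = SolutionRecord(
            stage=1,
            solver_status="optimal" if feasible else "infeasible",
            variant_id=system.variant.id,
        )
        if feasible:
            _fill_solution(record, system, np.zeros(0))
        return record
    c = np.zeros(system.n_vars)
    for col in system.np_cols.values():
        c[col] = -1.0  # maximise
    status, x, fun, msg = backend.solve(
        c,
        A_ub=system.A,
        b_ub=system.b,
        lb=system.lb,
        ub=system.ub,
        integrality=system.integrality,
    )
    record = SolutionRecord(
        stage=1, solver_status=status, variant_id=system.variant.id, message=msg
    )
    if status == "optimal":
        _fill_solution(record, system, x)
    return record


def _stage2_arrays(system: ConstraintSystem, np_sum: int):
    """Variable layout [x | F_rows | B] and the stage-2 constraint blocks."""
    n, m = system.n_vars, system.n_rows
    ncols = n + m + 1
    # thermo rows with explicit driving forces: A x + F <= lnK - shift
    A_ub = np.zeros((m + m, ncols))
    b_ub = np.zeros(m + m)
    A_ub[:m, :n] = system.A
    A_ub[:m, n : n + m] = np.eye(m)
    b_ub[:m] = system.b - system.F
    # minimax rows: B - F_j <= 0
    A_ub[m:, n : n + m] = -np.eye(m)
    A_ub[m:, n + m] = 1.0
    # yield-retention equality: sum n_p = np_opt - epsilon
    A_eq = np.zeros((1, ncols))
    for col in system.np_cols.values():
        A_eq[0, col] = 1.0
    b_eq = np.array([float(np_sum)])
    lb = np.concatenate([system.lb, -system.F, [-np.inf]])
    ub = np.concatenate([system.ub, np.full(m + 1, np.inf)])
    integrality = np.concatenate([system.integrality, np.zeros(m + 1, dtype=int)])
    return A_ub, b_ub, A_eq, b_eq, lb, ub, integrality


def stage2_max_mdf(
    system: ConstraintSystem,
    np_opt: int,
    epsilon: int = 0,
    backend: ScipyHighsBackend | None = None,
) -> SolutionRecord:
    """Maximise the minimum driving force at sum(n_p) = np_opt - epsilon."""
    if not float(epsilon).is_integer() or epsilon < 0:
        raise ValueError("epsilon must be a non-negative integer")
    epsilon = int(epsilon)
    backend = backend or ScipyHighsBackend()
    _prepare(system, backend)
    n, m = system.n_vars, system.n_rows
    A_ub, b_ub, A_eq, b_eq, lb, ub, integrality = _stage2_arrays(
        system, np_opt - epsilon
    )
    c = np.zeros(n + m + 1)
    c[-1] = -1.0  # maximise B
    status, x, fun, msg = backend.solve(
        c, A_ub, b_ub, A_eq, b_eq, lb, ub, integrality
    )
    record = SolutionRecord(
        stage=2, solver_status=status, variant_id=system.variant.id, message=msg
    )
    if status == "optimal":
        _fill_solution(record, system, x[:n])
        record.B = float(x[-1])
        record.MDF_kJ = record.B * system.env.RT
        record.F = dict(zip(system.row_labels, x[n : n + m]))
    return record


def pareto_sweep(
    system: ConstraintSystem,
    epsilons: list[int],
    backend: ScipyHighsBackend | None = None,
) -> list[ParetoPoint]:
    """Stage-2 sweep over epsilon values for a single variant.

    Per-point solver failures are propagated as statuses, never aborting
    the sweep.
    """
    backend = backend or ScipyHighsBackend()
    s1 = stage1_max_yield(system, backend)
    points = []
    for eps in epsilons:
        if not s1.ok:
            points.append(
                ParetoPoint(int(eps), None, None, system.variant.id, s1.solver_status)
            )
            continue
        s2 = stage2_max_mdf(system, s1.np_total, eps, backend)
        points.append(
            ParetoPoint(
                int(eps),
                s2.net_energy_kJ,
                s2.MDF_kJ,
                system.variant.id,
                s2.solver_status,
            )
        )
    return points


def enumerate_alternate_optima(
    system: ConstraintSystem,
    record: SolutionRecord,
    max_count: int = 10,
    backend: ScipyHighsBackend | None = None,
) -> list[dict[str, int]]:
    """Distinct integer n_p arrangements sharing the stage-2 optimum.

    Iteratively re-solves with a no-good cut excluding every arrangement
    found so far.  Each excluded vector v contributes, per translocating
    reaction j, two indicator binaries with big-M activation
    (n_p,j >= v_j + 1 when the 'above' indicator is on, n_p,j <= v_j - 1
    when 'below' is on) and the requirement that at least one indicator
    fires.  Returns up to ``max_count`` alternatives (empty if the
    optimum is unique).
    """
    if record.B is None or not record.ok:
        raise ValueError("record must be a solved stage-2 optimum")
    backend = backend or ScipyHighsBackend()
    _prepare(system, backend)
    np_order = [system.variant.reactions[j].id for j in sorted(system.np_cols)]
    k = len(np_order)
    if k == 0:
        return []
    base_cols = sorted(system.np_cols.values())
    big_m = max(int(system.ub[c] - system.lb[c]) for c in base_cols) + 1
    excluded = [np.array([record.np_by_reaction[r] for r in np_order], dtype=float)]
    found: list[dict[str, int]] = []
    while len(found) < max_count:
        A_ub, b_ub, A_eq, b_eq, lb, ub, integrality = _stage2_arrays(
            system, record.np_total
        )
        n_base = A_ub.shape[1]
        ncuts = len(excluded)
        ncols = n_base + 2 * k * ncuts
        rows, rhs = [], []
        for i, v in enumerate(excluded):
            off = n_base + 2 * k * i
            fire = np.zeros(ncols)  # at least one indicator per cut
            fire[off : off + 2 * k] = -1.0
            rows.append(fire)
            rhs.append(-1.0)
            for j, col in enumerate(base_cols):
                above = np.zeros(ncols)  # a=1 -> n_p >= v+1
                above[col] = -1.0
                above[off + j] = big_m
                rows.append(above)
                rhs.append(big_m - v[j] - 1.0)
                below = np.zeros(ncols)  # b=1 -> n_p <= v-1
                below[col] = 1.0
                below[off + k + j] = big_m
                rows.append(below)
                rhs.append(big_m + v[j] - 1.0)
        A_ub_full = np.vstack(
            [np.hstack([A_ub, np.zeros((A_ub.shape[0], ncols - n_base))]),
             np.array(rows)]
        )
        b_ub_full = np.concatenate([b_ub, np.array(rhs)])
        A_eq_full = np.hstack([A_eq, np.zeros((1, ncols - n_base))])
        lb_full = np.concatenate([lb, np.zeros(2 * k * ncuts)])
        ub_full = np.concatenate([ub, np.ones(2 * k * ncuts)])
        integ_full = np.concatenate(
            [integrality, np.ones(2 * k * ncuts, dtype=int)]
        )
        # hold B at the known optimum
        lb_full[system.n_vars + system.n_rows] = record.B - INT_TOL
        c = np.zeros(ncols)
        c[system.n_vars + system.n_rows] = -1.0
        status, x, fun, msg = backend.solve(
            c, A_ub_full, b_ub_full, A_eq_full, b_eq, lb_full, ub_full, integ_full
        )
        if status != "optimal":
            break
        vec = np.array([round(x[c_]) for c_ in base_cols], dtype=float)
        arrangement = {r: int(v) for r, v in zip(np_order, vec)}
        if any(np.array_equal(vec, v) for v in excluded):
            break  # numerical safety: cut failed to separate
        found.append(arrangement)
        excluded.append(vec)
    return found


def evaluate_variants(
    systems: list[ConstraintSystem],
    epsilons: list[int] = (0,),
    backend: ScipyHighsBackend | None = None,
) -> tuple[list[VariantResult], list[ParetoPoint]]:
    """Two-stage solve of every variant plus the per-epsilon best front.

    For each epsilon the best variant maximises (net energy, MDF); all ties
    within tolerance are reported, sorted by (net energy, MDF, variant id).
    """
    backend = backend or ScipyHighsBackend()
    results = []
    for system in systems:
        s1 = stage1_max_yield(system, backend)
        vr = VariantResult(variant_id=system.variant.id, stage1=s1)
        if s1.ok:
            for eps in epsilons:
                vr.stage2[int(eps)] = stage2_max_mdf(
                    system, s1.np_total, int(eps), backend
                )
        results.append(vr)
    front: list[ParetoPoint] = []
    for eps in epsilons:
        eps = int(eps)
        solved = [
            (vr.stage2[eps].net_energy_kJ, vr.stage2[eps].MDF_kJ, vr.variant_id)
            for vr in results
            if eps in vr.stage2 and vr.stage2[eps].ok
        ]
        if not solved:
            front.append(ParetoPoint(eps, None, None, "", status="infeasible"))
            continue
        solved.sort(key=lambda t: (-t[0], -(t[1] or 0.0), t[2]))
        best_e, best_m, best_id = solved[0]
        ties = tuple(
            vid
            for e, m_, vid in solved
            if abs(e - best_e) <= 1e-6 and abs((m_ or 0) - (best_m or 0)) <= 1e-6
        )
        front.append(ParetoPoint(eps, best_e, best_m, best_id, "optimal", ties))
    return results, front
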