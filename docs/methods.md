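# Methods

## Scope and model

`bioenopt` evaluates the bioenergetics of a metabolic pathway — an ordered
list of reactions converting a fixed external substrate into a fixed
external product — at steady state, in a single compartment, with
thermodynamics as the only constraint class. Enzyme kinetics, regulation
and flux-balance analysis are out of scope; the model answers what the
second law permits, not how fast an organism realises it.

Three energy currencies are tracked per reaction *j*:

- **Chemical potentials.** μᵢ = ΔG⁰_f,i(T) + RT ln Cᵢ with all activity
  coefficients fixed at 1. Formation energies tabulated at T_ref are moved
  to the working temperature by the Van't Hoff relation
  ΔG⁰(T) = ΔG⁰(T_ref)·T/T_ref + ΔH⁰·(1 − T/T_ref); requesting a
  temperature correction without formation enthalpies is an explicit
  error, never a silent fall-through.
- **Substrate-level phosphorylation.** ATP/ADP/AMP/Pi are tokenised away:
  a signed count L_j (+1 per ATP recovered through ADP, ±1.5 through AMP —
  the midpoint of the commonly quoted 40–50 % premium for the AMP bond,
  configurable) multiplies a single positive magnitude ΔG_ATP. Keeping
  ΔG_ATP positive and routing all directionality through L and n_p keeps
  every sign in one place.
- **Chemiosmosis.** Membrane-bound reactions may translocate an integer
  n_p,j protons; each is worth ΔG_ATP/r_H/ATP. Positive n_p (pumping
  against the gradient) and positive L both make a reaction less
  exergonic.

Dividing the second-law constraint ΔG_r,j ≤ −ΔG_min,j by RT gives the
canonical row Σν ln C + pmf·n_p ≤ ln K_j + F_j − (fixed-species shift),
with pmf = ΔG_ATP/(r·RT), ln K_j = −(ΔG⁰_j + L_j ΔG_ATP)/RT and
F_j = −ΔG_min,j/RT. `dG_min` is the non-negative dissipation magnitude
required of a reaction (default 0, so equilibrium-feasible solutions are
accepted in the yield stage). Rows are reactions, columns are decision
variables (free-species ln-concentrations, then integer proton counts).

## Pathway variants

Redox steps are written generically with an electron pseudo-species
(`e-`, coefficient positive when electrons are released). Assigning a
carrier couple replaces ν_e electrons by ν_e/n_e equivalents of the
couple. One variant is generated per element of the Cartesian product of
per-step carrier options; the count is exactly that product.

Each variant is then closed: the carriers' declared regeneration chains
(which may route through intermediate carriers, e.g. FAD re-reduced via
NADH and NAD in turn against H₂) are appended, deduplicated, with
per-turnover multiplicities solved by non-negative least squares on the
carrier balance. A regeneration step needed f times is included **once
with its stoichiometry and SLP token scaled by f** (the `flux` attribute
records f). This keeps closure a plain stoichiometric sum and the yield
objective the plain Σ n_p; the cost is that the lumped step's ln K and
driving force refer to f turnovers at once, which slightly understates the
per-event driving force of shared regeneration steps. Duplicate *core*
reactions in cyclic pathways are, by contrast, kept as distinct rows and
flagged `repeated` in breakdown tables. A residual in the carrier balance
means the carrier cannot be regenerated against the declared terminal
donor/acceptor and raises an infeasible-carrier error naming it.

Closure is validated on every variant: each species not fixed by the
environment must have zero net stoichiometry; the check is a sum, hence
order-independent.

## Conventions

- Water activity is 1: `h2o` is forced to a fixed species with ln C = 0.
- Protons are a fixed species with ln C = −pH_in·ln 10, auto-injected when
  referenced. Both conventions are recorded in the document metadata.
- Concentrations default to the physiological window 10⁻⁶–10⁻² mol/L
  (osmotic ceiling, molecule-count floor at ~1 µm³ cell volume),
  overridable per species. Proton counts default to ±⌊r_H/ATP⌋ = ±3 at
  the default r = 10/3: chemiosmosis exists to move quanta smaller than
  one ATP, so one step should not move more than one ATP's worth.
- ΔG_ATP defaults to 50 kJ/mol (mid-range of reported 45–70), r_H/ATP to
  10/3. MDF is reported as a positive dissipation magnitude in kJ/mol.

## Two-stage epsilon-constraint solve

Stage 1 maximises Σ n_p,j with all driving-force terms at zero — the best
achievable yield. Infeasibility here means the variant is
thermodynamically impossible at these conditions and is reported as a
status, not an exception. Stage 2 adds one continuous F_j per reaction and
a minimax variable B (F_j ≥ B), replaces the yield objective by the
constraint Σ n_p = n_p,opt − ε, and maximises B. The individual n_p,j stay
free under the sum constraint, so the solver may rearrange translocation
sites; equally-optimal arrangements are enumerable via no-good cuts
(per excluded vector, indicator binaries with big-M activation force at
least one n_p,j to differ). ε must be an integer — it counts conceded
proton translocations; fractional values are rejected.

Multi-variant runs solve every variant and report the per-ε best by
(net energy, MDF, variant id), with all ties listed — tied variants mean
the carrier choice is energetically neutral at those conditions.

The backend is scipy's HiGHS MILP behind a minimal solve interface
(integrality mask, inequality/equality blocks, bounds); integer
feasibility tolerance 10⁻⁶, relative objective gap 10⁻⁹. Reported n_p are
rounded to int; B and ln C are used as returned.

## Conserved moieties

The pool constraint C_min ≤ Σ exp(ln C_i,CM) ≤ C_max is nonlinear in the
decision variables. The default `linear_safe` mode enforces a sufficient
linear surrogate — every free member capped at C_max/|CM| (guaranteeing
the upper pool bound) and the designated free species (typically the free
form, e.g. free CoA) held at or above C_min — and the exact inequalities
are always re-evaluated on the solution, with violations attached to the
record. This keeps the problem a true MILP at the cost of conservatism:
a solution using one member near C_max is excluded by the surrogate even
though the exact pool would allow it. The `nonlinear` mode carries the
exact constraint form for backends that accept it; the bundled HiGHS
backend is linear-only and raises a capability error, which is the honest
statement of what it can certify. `off` retains the post-check only.

## Synthetic toys and the oracle

The generator builds seeded linear chains S_ext → X₁ → … → P_ext with
chosen numbers of translocating and redox steps. Per-reaction ln K values
are sampled uniformly (default window −4 to 14, spanning strained to
comfortably exergonic steps at RT ≈ 2.5 kJ/mol) and formation energies are
back-solved so the thermodynamic layer reproduces them exactly; each
carrier couple gets its own regeneration reaction against a fixed terminal
product with its own sampled ln K. Fixed concentrations use typical values
(substrate 10⁻² mol/L, products 10⁻⁴ mol/L). Generation is reproducible to
the byte for a given seed.

What the toys emulate: closure, carrier combinatorics, regeneration,
translocation placement, SLP tokens, realistic energy scales. What they do
not: branched/cyclic topologies, shared moiety pools across many steps,
measured formation energies, and correlated ln K structure of real
pathways — so passing tests certify the *optimiser and algebra*, not any
biological prediction.

The oracle enumerates every integer n_p assignment within bounds (capped
at 20 000 assignments) and solves each continuous max-min problem over
ln C as a plain LP (`linprog`/HiGHS): stage-1 feasibility is a
non-negative best minimum slack, the stage-2 value is the best B among
assignments at the target Σ n_p. Enumeration plus LP shares no code path
with the branch-and-bound MILP, making the agreement check a genuine
dual-route certification. The certification suite runs 100 seeds with 4–8
reactions, 1–3 translocating steps and 0–2 redox steps (about half a
minute end to end), checking yield and MDF agreement to 10⁻⁶, Pareto
monotonicity B(ε+1) ≥ B(ε), net energy ≤ −ΔG_overall, the even-split
bound MDF ≤ (−ΔG_overall − net energy)/n, per-reaction Gibbs
reconstruction to 10⁻⁹ kJ/mol, and closure of every generated variant.

## Numerical choices and degenerate inputs

- Closure and carrier-balance tolerance 10⁻⁹ on stoichiometric sums;
  regeneration least-squares residual tolerance 10⁻⁷.
- A system whose species are all fixed and with no translocating reaction
  has no decision variables; stage 1 degenerates to a row-wise feasibility
  check.
- Unbounded free variables are a configuration error raised before any
  solve; inverted bounds are rejected at assembly.
- Alternate-optima enumeration holds B within 10⁻⁶ of the stage-2 optimum
  and stops at the first cut that fails to separate (numerical safety).
- Energies are reported in kJ/mol, concentrations in mol/L; dimensionless
  B and F are converted via RT only at the reporting boundary.

## Limitations

- Activity coefficients are fixed at 1; no ionic-strength or
  Debye–Hückel correction, no pKa-based transforms — formation energies
  are taken as supplied, at whatever pH convention the source used (the
  schema does not currently transform them).
- Single compartment; no transport reactions or membrane potentials
  beyond the lumped pmf.
- The exact (nonconvex) lower moiety pool bound is never imposed on the
  solver, only guaranteed via the surrogate and verified post hoc.
- The published propionate-oxidation and reverse-TCA case-study tables
  (row-level stoichiometries, carrier options, formation energies) are not
  distributed with the package; the schema and workflow accept them
  unchanged once transcribed, and the acceptance test that needs them
  fails with an explicit message rather than skipping.
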