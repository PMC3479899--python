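# Methods

## Model

Monovalent TCR–pMHC binding is a birth–death process on the number of
engaged receptors `n ∈ {0, …, min(M_R, M_L)}`, with propensities

    λ_n = k_+ (M_R − n)(M_L − n)      (binding)
    μ_n = k_− n                        (unbinding)

starting from `n = 0` with `M_R` free receptors and `M_L` free ligands.
`k_+` is the per receptor–ligand-pair association rate; in solution it
relates to the molar association rate by `k_on = k_+ · V · N_A` with `V`
the reaction volume. Both receptor and ligand are depleted bilinearly in
λ_n; the constant-ligand approximation is recovered automatically whenever
`M_L ≫ n`, which holds in every solution-phase setting the package models
(`M_L` is of order 10⁶ at nanomolar doses in sub-nanolitre volumes).

### Stochastic response criterion

A binding is *productive* if it remains intact for at least the dwell time
τ; the cell responds at the first time N engagements have been productive.
Because complex lifetimes are exponential, a newly formed complex is
productive with probability `e^{−τ k_off}` independently of everything
else, so on average `N′ = N e^{τ k_off}` binding events precede the N-th
productive one. When bound receptors stay far below both `N_R` and the
ligand pool, binding events are Poisson with rate `k_on ρ N_R` and the
first-passage time is τ plus an Erlang(N′) waiting time:

    T(N, τ)   = τ + N e^{τ k_off} / (k_on ρ N_R)
    Var(N, τ) =     N e^{τ k_off} / (k_on ρ N_R)²
    CV        = √Var / T  → 1/√N  as τ → 0, and → 0 as N → ∞.

`N′` is used real-valued throughout; the criterion is a statement about
means and nothing is gained by rounding it.

### Finite-receptor correction

Keeping ρ constant but letting bound receptors be a finite fraction of
`N_R`, the mean occupancy obeys `dB/dt = k_on ρ (N_R − B) − k_off B`,
`B(0) = 0`, whose solution is `B(t) = B_eq(1 − e^{−γt})` with
`γ = k_on ρ + k_off`. New bindings accrue at `k_on ρ (N_R − B(t))`, so the
mean cumulative binding count is

    C(t) = k_on ρ [ (N_R − B_eq) t + B_eq (1 − e^{−γt})/γ ].

The corrected mean response time solves `C(T − τ) = N′`, done by bracketed
Brent root-finding (relative tolerance 1e-10) from the uncorrected waiting
time upward — `C(t) ≤ k_on ρ N_R t` guarantees the uncorrected value is a
lower bracket. When `k_off = 0`, C saturates at `N_R` and a criterion with
`N′ ≥ N_R` is reported as unreachable (a typed exception, not an overflow).
Both closed forms are tested against direct ODE integration, and the
correction is validated against simulation at a deliberately small
receptor pool (N_R = 50, N′ ≈ 27).

### Two-dimensional binding

For membrane-anchored receptor and ligand the same formulas apply with the
binding propensity replaced by `k_on^{2D} · M_R · M_L · A_c` (surface
densities M_R, M_L; contact area A_c) and `k_off` by the 2-D off-rate.
The grouping treats `k_on^{2D}` as a rate per density pair per unit
contact area, so the total pair-formation rate scales with both densities
and the contact; it lives in a single function (`propensity_2d`) so an
alternative convention is a one-line change, and the 2-D path is verified
against the 3-D path at numerically equal propensity — the only check the
functional form itself admits. Rankings over 2-D data require the user to
supply the surface context; published 2-D datasets rarely print it.

### Deterministic limit and the equilibrium criterion

Writing `z(t)` for complexes per cell and closing the moment hierarchy
with `w = z²` gives the Riccati equation `dz/dt = a(z − z1)(z − z2)`,
`a = k_on N_c/(V N_A)`, whose stationary quadratic

    z² − (N_R + L + K_d V N_A/N_c) z + N_R L = 0,   L = ρ V N_A / N_c,

has two positive roots; the smaller, `z_eq = z1`, is the stable state
reached from `z(0) = 0` (`f′(z1) < 0`). The closed-form trajectory

    z(t) = z1 z2 (1 − E)/(z2 − z1 E),   E = e^{−a(z2−z1)t},

inverts to the equilibrium-criterion time
`T_N = ln[z1(z2−N)/(z2(z1−N))]/(a(z2−z1))`, finite only when `z_eq > N`;
otherwise T_N is returned as `inf` (a value, not an exception, so
dose–response tables can carry it). The closure is exactly the mean-field
approximation, not the true master-equation mean; the two coincide at
large copy numbers, which is where the package uses it. Numerical notes:
the larger root is computed from the quadratic sum and the smaller from
the product (`z1 = P/z2`) to avoid catastrophic cancellation when
`S² ≫ 4P`; a double root falls back to the algebraic-decay limit rather
than dividing by `z2 − z1`. The per-pair rate is always derived from
`k_on/(V N_A)` rather than a table's printed `k_+`, so the trajectory and
its defining ODE agree to round-off even when the printed `k_+` carries
table rounding.

### Simulator

The Gillespie algorithm draws the next event time from the total
propensity and its type from `λ_n/(λ_n+μ_n)`. Since complexes are
exchangeable and lifetimes memoryless, the complex that dissociates at an
unbinding event is a uniform draw among those bound — this yields exact
per-binding durations without receptor identity, consistent with counting
serial engagements as distinct events. A binding open at τ after its start
is confirmed productive at that instant (even if it later unbinds);
confirmations therefore occur in increasing start order and the
realization ends the moment the N-th is confirmed, at
`FPT = start_of_Nth + τ`. Still-open bindings at that moment are ignored.
Default caps are 10⁸ events or 10⁹ simulated seconds, after which a typed
"not reached" error propagates into ensemble bookkeeping rather than
aborting the ensemble. Ensembles draw one independent child stream per
realization from a master seed (`numpy` `SeedSequence.spawn`), making
results reproducible and independent of realization order.

By default simulations are per cell (`M_R = N_R`, `M_L = ρVN_A/N_c`): the
criterion is a statement about one cell's receptors. A bulk mode pools all
cells.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| N | productive bindings required | 10 | few agonist pMHCs suffice to trigger a T cell |
| τ | dwell-time threshold (s) | 4 | supported by dwell-time estimates for productive engagement |
| N_R | TCRs per cell | 30 000 (SP), 3000 (DP) | measured surface expression |
| ρ | ligand concentration (M) | 10⁻⁸, grids 10⁻¹⁰–10⁻⁴ | physiological band ~10⁻⁹–10⁻⁵ M |
| V·N_A | volume constant (M⁻¹) | 3.0×10¹⁴ (V ≈ 4.98×10⁻¹⁰ L) | implied by the reference table's k_on/k_+ ratio, constant across rows to <0.1% |
| validation tol | redundant-column tolerance | 2% | published tables round; the reference table's worst row is ~1.7% off |
| overflow cutoff | mean reported as +inf above | 10³⁰ s | weak-ligand means are astronomically large by design; +inf with a warning beats a meaningless float |

The bundled table stores the printed values verbatim (e.g. `0.0169`, not
`ln2/41`); `k_on` and `k_−` are authoritative in all computations, with
`K_d` and `t_1/2` treated as consistency metadata — they are the columns
every formula actually consumes.

## What the validations do and do not show

The test-suite cross-checks are internal: closed forms against independent
ODE/enumeration oracles, simulation against closed forms, rankings against
monotone-transform arguments. The bundled kinetics are real measurements,
but the package contains no model of measurement error, receptor/ligand
diffusion, the intracellular origin of τ, or temperature dependence (rates
at other temperatures are new inputs, not predictions). Agreement between
the equilibrium model and published dose–response curves is qualitative:
the experimental points behind those curves are not machine-readable.
Passing tests show the mathematics is implemented correctly under the
model's assumptions — exponential waiting times, independent engagements,
well-mixed kinetics — not that those assumptions hold in any particular
experiment.

## Design choices

- Rankings use the analytic MTSI, never simulation: the ranking of means
  is deterministic, and at fixed τ it is provably independent of N (the
  N-dependence factors out of `T − τ`), so grids over N would only add
  noise. Ties are broken lexicographically by label.
- Switch points between ranking rows are solved in closed form
  (`τ* = ln(p₁/p₂)/(k₁ − k₂)`) when exactly one adjacent pair swaps;
  multi-way changes report the bracketing grid interval only.
- The default dwell-time grid is 0.5 s steps over [0.5, 10] s — fine
  enough to localize the ~5 s threshold at which 2-D and 3-D hierarchies
  reconcile, without pretending sub-half-second resolution matters.
- Simulation problem sizes in the tests (hundreds of realizations of the
  strong-ligand systems; weaker ligands tested at smaller τ so N′ stays
  simulable) were chosen so the full suite completes in well under a
  minute while keeping Monte-Carlo standard errors small enough for
  3-SE assertions to have power.

## Known limitations

- The 2-D propensity grouping is a convention (see above); users with a
  different convention for `k_on^{2D}` units must rescale inputs or edit
  `propensity_2d`.
- `mtsi_corrected` neglects ligand depletion; it corrects the receptor
  pool only. Full depletion of both species is available only through the
  simulator or the deterministic model.
- The FPT distribution beyond mean/variance/CV is available only
  empirically, via `estimate_mtsi` samples.
- No spatial structure, no rebinding memory, no temperature model.
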