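# tsi — stochastic T cell response criterion

`tsi` computes the timescales on which a T cell can mount a response from
the binding kinetics of its receptor (TCR) for a peptide–MHC ligand. It is
aimed at quantitative immunologists and modellers who have measured (or
transcribed) association/dissociation rates and want to turn them into
response times, ligand potency hierarchies, and dose–response curves.

## The criterion

Experimental evidence supports two ingredients of T cell signal initiation:
an engagement must last long enough to drive the early signalling steps, and
the cell counts engagements, accumulating signal. The *stochastic response
criterion* combines both: the cell responds at the first time **N**
receptor–ligand engagements have each lasted at least a dwell time **τ**
(such engagements are *productive*; the same receptor re-binding counts
again — serial engagement). That first time is a first-passage time of the
binding birth–death process; its mean is the **mean time to signal
initiation** (MTSI).

When bound receptors remain a small fraction of the receptor pool, binding
events are Poisson with propensity `k_on·ρ·N_R` (ligand concentration ρ,
receptors per cell N_R) and each new complex survives past τ with
probability `exp(−τ·k_off)`, giving closed forms

```
T(N, τ)   = τ + N·e^{τ·k_off} / (k_on·ρ·N_R)
Var(N, τ) =     N·e^{τ·k_off} / (k_on·ρ·N_R)²
```

The package provides, around this core:

- `tsi.params` — binding-table I/O, unit conversions (`k_off = ln2/t_1/2`,
  `K_d = k_off/k_on`, `k_on = k_+·V·N_A`) and consistency validation; a
  reference table for the T1 TCR system (ligands 4P/4A/4N on SP and DP
  thymocytes at 37 °C) ships as `bundled:table1`.
- `tsi.mtsi` — the closed forms above, their 2-D (membrane-anchored)
  counterpart, and a finite-receptor correction.
- `tsi.deterministic` — the mean-field kinetics z(t), equilibrium occupancy
  and free fraction f_eq, and the contrasting *equilibrium criterion* time
  T_N to accumulate N complexes (which fails to rank ligands the way
  selection experiments do).
- `tsi.gillespie` — exact stochastic simulation (SSA) of the binding
  process and empirical first-passage ensembles.
- `tsi.ranking` — ligand potency hierarchies (ascending MTSI) over dwell-time
  grids, with closed-form switch points.
- `tsi.cli` — a `tsi` command with `mtsi`, `simulate`, `rank`,
  `dose-response` and `validate-table` subcommands.

## Worked example: self/non-self discrimination

A foreign ligand F (`k_off = 1.0 s⁻¹`, binding propensity
`k_on·ρ·N_R = 10 s⁻¹`) competes against a self ligand S that binds five
times less stably (`k_off = 5.0 s⁻¹`) but is 100× more concentrated
(propensity `1000 s⁻¹`):

```python
>>> from tsi import discrimination_example
>>> r = discrimination_example(N=10, tau=4.0)
>>> round(r.mtsi_foreign, 1), f"{r.mtsi_self:.2e}", round(r.ratio)
(58.6, '4.85e+06', 82795)
```

F triggers the criterion in under a minute; S would need ~4.85×10⁶ s
(about two months), a ratio of ~8×10⁴ — despite S producing 100× more
binding events per second. The dwell-time filter amplifies a 5-fold
difference in off-rate into nearly five orders of magnitude in response
time, which is the essence of kinetic discrimination.

The same machinery reproduces the thymic selection hierarchy from the
bundled table:

```sh
$ tsi rank --n 10 --tau-grid 1,4,8 --out rank.csv
tau =   1.00 s : 4P (1.221 s) > 4A (1.503 s) > 4N (1293 s)
tau =   4.00 s : 4P (4.232 s) > 4A (10.77 s) > 4N (2.512e+14 s)
tau =   8.00 s : 4P (8.248 s) > 4A (224.6 s) > 4N (2.828e+29 s)
```

The negatively selecting ligand 4P is always fastest, the positively
selecting 4N always slowest, at every concentration and every (N, τ) —
the ordering a selection experiment sees.

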