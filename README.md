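# gudpeck

Estimating giving-up densities for **every** bird species visiting a
depletable seed tray — not just the last one — from video-scored peck logs.

## The problem

A giving-up density (GUD) experiment offers foragers an artificial food
patch (here: 20 g of millet mixed into sand in a tray, deployed for 24 h)
and weighs what is left when foraging stops. Optimal-foraging theory reads
that leftover mass as a behavioral indicator: a forager quits a patch when
the marginal gain of another search equals its marginal cost (predation
risk, metabolic cost, missed opportunities), so low GUDs mean cheap
foraging or poor alternatives. The classical weakness of the method is
that a sifted tray only records the decision of the *final* forager.

When the tray is filmed, the peck log contains far more. `gudpeck`
implements an analytical chain that leverages it:

1. **Event analysis** — segment each species' pecks into foraging bouts
   (a bout ends when ≥ 60 s pass without a peck), find each species'
   quitting point and the cumulative tray-wide peck count at that moment,
   and bound the number of distinct individuals per tray by summing the
   maximum simultaneous counts of distinguishable demographic classes
   (three female house sparrows at once, later two males and a female →
   at least five birds).
2. **The GUD-Peck model** — on trays with a measured final GUD, fit

   `GUD = β₀ + β_pecks · P + β_density · d + α_species`

   by ordinary least squares, where `P` is the tray's total peck count,
   `d` its total minimum individuals, and `α_species` a categorical offset
   for the final forager's identity. Each earlier visitor's GUD is then
   predicted at the cumulative peck count standing when that species quit.
   Visits with fewer than 40 own pecks are omitted (the linear model
   extrapolates poorly there), unvisited trays keep their 20 g
   provisioning, and consumption rates come from evaluating the model at a
   species' own peck total.
3. **Community statistics** — MRPP with Bray–Curtis distance on the
   row-normalized, rare-species-filtered yards × species density matrix;
   Pielou evenness; one-way ANOVA and a density-interaction ANCOVA on
   GUDs; paired bush/open microhabitat t-tests; per-species Wilcoxon and
   Kruskal–Wallis rank tests.
4. **A mechanistic simulator** — Poisson arrivals, species-specific peck
   rates and quitting thresholds, diminishing returns (`yield ∝
   remaining mass`) or exactly linear depletion, weighing noise — with an
   exact seed-mass ledger, so every estimator can be tested against known
   ground truth (the theoretical GUD of a species is `G0·q/y_max`).

It is written for behavioral and urban ecologists running seed-tray
studies across habitat treatments (here: mesic vs xeric residential yard
designs) who want per-species foraging estimates from single-tray videos.

## Worked example

```python
from gudpeck import RunConfig, run_pipeline

out = run_pipeline(RunConfig(seed=1), "results/demo", do_simulate=True)
fit = out["fit"]
print(f"n_train={fit.n_train}  r2={fit.r_squared:.3f}  "
      f"pearson={fit.obs_pred_pearson:.3f}  beta_pecks={fit.beta_pecks:.5f}")
anova = out["stats"]["gud_anova"]
print(f"ANOVA F={anova['F']:.2f}  p={anova['p']:.2g}")
print(out["stats"]["mrpp"])
```

prints

```
n_train=40  r2=0.952  pearson=0.976  beta_pecks=-0.00339
ANOVA F=21.59  p=9.7e-06
{'delta_observed': 0.31635883468332376, 'delta_expected': 0.35977380514782986,
 'A': 0.12067296129763261, 'p_value': 0.001, 'n_permutations': 999}
```

Reading this: the GUD-Peck fit on the 40 simulated trays explains 95% of
the variance in measured GUDs, and each peck removes ≈ 0.0034 g at the
margin (the simulator's per-peck yield is 0.01 g at a full tray, shrinking
as the tray depletes). Mean estimated GUDs are lower in mesic than xeric
yards (8.08 g vs 10.36 g; F = 21.6), and MRPP detects the built-in
community difference between the yard types (A = 0.12, p = 0.001). The
same pipeline runs from the shell:

```bash
gudpeck run --simulate --seed 1 --out-dir results/demo
gudpeck mrpp --matrix my_matrix.csv --group-col yard_type --n-perm 999 --seed 1
```

or on your own `pecks.csv`, `intervals.csv`, `trials.csv` (schemas in
`gudpeck.datatypes`) with `gudpeck run --in-dir DATA --out-dir OUT`.

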