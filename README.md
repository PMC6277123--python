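# polyadapt

Forward-time simulation and analysis of **polygenic adaptation to a distant
trait optimum**, for population and quantitative geneticists who want to ask:
when a trait under stabilizing selection is suddenly pushed toward a far-away
optimum, how fast does the population get there, how much of the response
runs through selective sweeps versus subtle frequency shifts, and what
genetic architecture is left behind?

The package provides, as one pipeline:

- an individual-based Wright-Fisher simulator of a diploid population with 20
  unlinked QTL regions, additive effects (genotype values 0, a/2, a), a
  heritable genomic background, Gaussian stabilizing selection
  `w = exp(-(z - z_opt)^2 / (2 V_S))`, truncation selection (top 50%) during
  the approach to the new optimum, and bottleneck + exponential-growth
  demography (`polyadapt.sim_engine`);
- a demography-matched neutral null of conditional fixation (sojourn) times
  built by single-locus binomial sampling; any fixation faster than 99% of
  neutral alleles is a selective sweep — *hard* if the mutation arose after
  the optimum shift, *from standing variation* if before
  (`polyadapt.neutral_null`, `polyadapt.sweep_classify`);
- summary statistics of the adaptive process (time to optimum, adaptation
  rate in units of `sqrt(V_G0)` per generation, variance dynamics, site
  frequency spectra, fixation and segregating-site descriptors) and the
  house-of-cards equilibrium expectations `E[V_G] = 4 U V_S` and
  `4 U V_S / (1 + V_S / (N sigma_m^2))` (`polyadapt.summaries`);
- 7 x 9 allele-frequency x effect-size genetic-architecture matrices with
  pairwise correlations across scenarios (`polyadapt.architecture`);
- random-forest regression from the five input parameters (`sigma_m`, `V_S`,
  `psi`, bottleneck fraction, final-size multiple) to any summary statistic,
  with normalized feature importances and 10-fold cross-validated R^2 /
  NRMSD (`polyadapt.importance`);
- a YAML-configured grid runner with shared burn-ins, cached nulls, seeded
  byte-identical reproducibility, and presets including two maize
  domestication traits (`polyadapt.experiment`, `polyadapt` CLI).

There are no external data inputs: the simulator is the data generator, and
every downstream stage consumes its mutation tables and trajectories.

## Worked example

```python
import numpy as np
from polyadapt import (TraitParams, QTLLayout, DemographyModel,
                       run_burn_in, run_adaptation,
                       simulate_neutral_sojourns, sweep_threshold,
                       classify_fixations, sweep_summary)
from polyadapt.summaries import time_to_optimum

rng = np.random.default_rng(7)
params = TraitParams(sigma_m=0.05, v_s=1.0, psi=0.0)   # focal trait
layout = QTLLayout()                                   # 20 x 50 kb QTL, U = 3e-3
n_anc = 500                                            # quick desk run

pop, burn = run_burn_in(params, layout, n_anc, rng)    # 10 N generations
print(f"equilibrium V_G0 = {pop.G.var():.5f}, mean fitness = {pop.mean_fitness(0.0):.3f}")

dem = DemographyModel(n_anc=n_anc, n_generations=300)  # constant N, 300-generation window
result = run_adaptation(pop, dem, rng)                 # optimum shift 0 -> 10
print(f"time to 99% of optimum = {time_to_optimum(result.trajectory, 10.0, n_anc):.3f} N_anc")

null = simulate_neutral_sojourns(dem, n_fixations=300, rng=rng)
fixations = classify_fixations(result.fixations, sweep_threshold(null))
print(sweep_summary(fixations, total_trait_change=10.0).round(3))
```

Output (seeded, reproducible):

```
equilibrium V_G0 = 0.00472, mean fitness = 0.997
time to 99% of optimum = 0.476 N_anc
n_fixations              79.000
n_sweeps                 76.000
n_hard                   68.000
n_standing                8.000
prop_sweeps               0.962
prop_standing             0.105
summed_sweep_effect       9.640
sweep_effect_fraction     0.964
```

Reading it: after the burn-in the population sits at the old optimum (mean
fitness 0.997) holding equilibrium genetic variance 0.0047, so the new
optimum is `10 / sqrt(0.0047) ~ 146` phenotypic standard deviations away. It
takes 238 generations (0.476 N) of truncation selection to close 99% of that
distance. Of the 79 mutations that fixed after the shift, 96% fixed faster
than 99% of demography-matched neutral alleles — selective sweeps — and at
this small population size most of them are hard sweeps from new mutations
(standing variation is scarce: only 10.5% of sweeps); together the sweeps
account for 96% of the trait displacement. Larger populations shift this
balance toward sweeps from standing variation.

The same pipeline runs end to end from the shell:

```bash
polyadapt presets --list
polyadapt simulate --preset single-scenario --seed 1 --out runs/focal
polyadapt null --demography b0.05_f10 --n-anc 1000 --n 10000 --seed 2 --out runs/null.tsv
polyadapt importance --summaries runs/grid/summary.tsv --targets time_to_optimum --out runs/imp.tsv
polyadapt report --out runs/focal
```

Outputs are plain TSV tables (`trajectory.tsv`, `fixations.tsv`,
`segregating.tsv`, `snapshots.tsv`, `summary.tsv`, `aggregate.tsv`,
`architecture/*.tsv`, `correlations.tsv`, `importance.tsv`) plus a
`manifest.json` recording every seed; re-running a configuration reproduces
all tables byte for byte.

`experiment.published_config()` expands the full study grid — 5 `sigma_m`
x 5 `V_S` x 4 `psi` x 12 demographies = 1,200 parameter sets, 100
replicates each at N_anc = 10,000 — which is an overnight job; the bundled
presets are desk-scale (N_anc = 1,000) with the model untouched.

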