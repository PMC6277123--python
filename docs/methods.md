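# Methods

## The model

`polyadapt` simulates a diploid, randomly mating population whose quantitative
trait first equilibrates under stabilizing selection and then adapts to a
distant new optimum. The trait is controlled by 20 unlinked QTL regions plus
an optional heritable genomic background.

**Genome and mutation.** Each QTL region is 50 kb: a 4 kb "genic" segment
centered in 46 kb of "intergenic" sequence whose per-site trait-mutation rate
is 1% of the genic rate. Rates are anchored by the total per-gamete trait
mutation rate `U = 3e-3` per generation; with these lengths ~90% of new trait
mutations are genic. Mutations occur at continuous positions under an
infinitely-many-sites model (no recurrent or back mutation). New-mutation
counts per gamete are Poisson(U); a mutation's locus is uniform, its class
genic/intergenic with probability proportional to length x class rate, its
position uniform within the class.

**Effects.** The model is purely additive: an allele of effect size `a`
contributes 0, `a/2` or `a` to the genetic value `G` for the three genotype
classes. The *allelic* effect `a/2` of a new mutation is drawn from
Normal(0, `sigma_m`^2); equivalently the stored homozygous effect is twice
the draw. This convention is pinned down by the exact neutral limit — under
pure drift the equilibrium genetic variance is `4*N*U*Var(allelic effect)`,
which the simulator reproduces to a few percent — and it is the convention
under which the house-of-cards approximations below hold with `sigma_m`
entering directly. Fixed mutations are folded into a scalar baseline and
removed from gametes; their identity, origin and fixation generations are
kept in the fixation table.

**Recombination.** QTL regions are unlinked (each offspring locus starts from
either parental gamete with probability 1/2). Within a region, crossovers are
Poisson with rate 5e-8 per site (0.0025 per region, 0.05 per gamete) and
uniform breakpoints.

**Background.** An individual's phenotype is
`P = psi * G_B + (1 - psi) * G`, where `G_B ~ Normal(G_mp, sigma^2)`,
`G_mp` is the mid-parent *trait* value and `sigma^2` is, by default, the
variance of trait values in the whole parental generation (recomputed every
generation). Using parental trait values (rather than QTL genetic values)
makes the background heritable: parents that adapted through the background
pass that gain on. A config switch (`background_variance: midparent_pair`)
instead uses the variance of each offspring's own parent pair,
`((P1 - P2)/2)^2`, for sensitivity analysis; the population-level reading is
the default because it is the only self-consistent interpretation of "the
variance of the parental trait values" that is defined for every mating.
`psi` in [0, 1] is the proportion of trait variation carried by the
background (0 = QTL only).

**Fitness and the two selection regimes.** Fitness is Gaussian,
`w = exp(-(z - z_opt)^2 / (2 V_S))`. During the burn-in (10 N generations at
the ancestral size) and after the new optimum has been reached, parents are
sampled with probability proportional to `w` (two independent draws per
offspring, selfing allowed). During adaptation toward the distant optimum,
Gaussian fitness would concentrate all reproduction in a few extreme
individuals, so the population instead undergoes truncation selection: the
top `ceil(n/2)` individuals by `w` reproduce (uniformly), the rest do not.
Ties at the median are broken by stable index order — deterministic and
testable. Truncation ends permanently at the first generation whose
pre-selection mean trait value reaches the new optimum; the separate
"time to optimum" statistic uses the 99%-of-optimum crossing. With
`z_opt_new = z_opt_initial` the truncation phase never triggers.

**Demography.** Generation 0 is the optimum shift. At generation 0 the
population is reduced instantaneously (sampling without replacement) to
`bottleneck_fraction * N_anc` and then grows exponentially, reaching
`final_multiple * N_anc` at generation `0.1 * N_anc`. The standard grid is
12 scenarios: bottleneck fraction {1.0, 0.10, 0.05, 0.01} x final multiple
{1, 3, 10}. Burn-in generations are negative; mutations with origin <= 0
constitute standing variation.

**Equilibrium variance expectations.** At mutation-selection-drift balance
the genetic variance is approximated by the house of cards,
`E[V_G] = 4 U V_S`, and its finite-population (stochastic) refinement
`E[V_G] = 4 U V_S / (1 + V_S / (N sigma_m^2))`. The simulator tracks the
stochastic form across a 3x3 (sigma_m, V_S) grid at N=500 with a
geometric-mean observed/expected ratio within 15% of 1. Two caveats are
deliberate: (i) the per-run time-averaged V_G has ~30% relative scatter
even over 2N generations, because equilibrium variance decorrelates slowly —
agreement is therefore asserted on the grid mean rather than per cell; and
(ii) the approximation itself is known to sit slightly below realized V_G in
drift-dominated regimes, consistent with the z-score distances reported by
the equilibrium runs being a few percent below `10 / sqrt(E[V_G])`.

## Burn-in sharing

Equilibria depend only on (sigma_m, V_S): burn-ins are run with `psi = 0`
and reused across all psi values and demographies of a grid, mirroring a
design in which a modest number of equilibrium traits seed a much larger
adaptation grid. `psi` and the demography take effect from the shift onward.

## The neutral null and sweep classification

Sweeps are called from fixation times alone (the model carries no linked
neutral sites). For each demography a null distribution of neutral
conditional fixation ("sojourn") times is built by single-locus binomial
sampling: single-copy mutations are injected at origins uniform over the
burn-in plus the adaptive window and propagated as
`x' ~ Binomial(2 N_next, x / (2 N_current))`; only mutations fixing inside
the final `0.1 N_anc` window — and neither fixed nor lost earlier — count.
The sampler exploits two exact facts about this chain (frequency is a
martingale): a new mutation ultimately fixes with probability equal to its
initial frequency, and conditioned on fixation the chain is again Markov
with kernel `x' = 1 + Binomial(2 N_next - 1, x / (2 N_current))` (a Doob
h-transform, valid under any size schedule). Destinies are therefore decided
by a Bernoulli coin at injection and only fixing trajectories are simulated;
the collected sojourn distribution is identical to naive propagation (the
two samplers were compared directly during development) at a fraction of the
cost. Complete calendar sweeps are always finished before the collected
count is checked, so stopping cannot bias the distribution.

The sweep threshold is the 1st percentile (linear interpolation between
order statistics; percentile configurable) of the null sojourns. A fixation
is a sweep when its sojourn is below the threshold; *hard* if it arose after
the shift, *from standing variation* otherwise. Sojourns of standing
variants are counted from their origin generation — the null measures
origin-to-fixation, so the comparison must too — with a shift-anchored
option for sensitivity analysis. Burn-in fixations are excluded from all
summaries.

One measurement caveat: sojourns collected inside a `0.1 N` window cannot
exceed `10.1 N`, which clips the long right tail of the neutral distribution
and biases the *mean* (not the 1st percentile) a few percent low. The
calibration check against the diffusion value `4N` therefore uses a constant
demography with a 10N-generation collection window, where the truncation is
negligible.

## Summary statistics

Per replicate: time to 99% of the optimum in units of `N_anc` (missing if
never reached — such replicates are excluded from time/rate means but
counted); adaptation rate = optimum displacement in units of
`sqrt(V_G0)` divided by generations to the 99% crossing; `V_G` trajectories
(always the variance of individual genetic values `G`, recorded every
generation); fixation counts and sign-partitioned mean effects; sweep counts
and proportions; segregating-site counts, sign-partitioned mean frequencies
and effects; and the binned site-frequency spectrum with a neutral `1/i`
reference scaled to the observed number of segregating sites (20 equal-width
bins by default).

## Genetic-architecture matrices

Segregating sites of a final generation are cross-tabulated into 7 fixed
allele-frequency bins (0-1e-4, 1e-4-1e-3, 1e-3-1e-2, 1e-2-0.1, 0.1-0.5,
0.5-0.9, 0.9-1; half-open, last bin closed, non-segregating sites excluded)
by 9 effect-size quantile bins, normalized to sum to one. The effect bins
are built from the pooled segregating effects of all replicates of one
parameter set (making replicate matrices comparable within the set): the
central bin is `(-q, +q)` with `q` the lower quartile of |effect|, and the
remaining negative and positive effects are each split into four
equal-count quantile bins. The quantile construction makes matrices
comparable across traits whose absolute effect scales differ by orders of
magnitude; edges scale linearly with the effects. Replicate matrices are
averaged and renormalized per parameter set; matrices are compared by
Pearson correlation over the 63 cells (undefined — reported missing — when
a matrix is constant).

## Random-forest importance

A forest of 100 regression trees (scikit-learn, fixed seed, single thread)
predicts each summary statistic from the five input parameters (sigma_m,
V_S, psi, bottleneck fraction, final-size multiple; a switch substitutes
V_G0 for V_S). Impurity-based importances are normalized to sum to one.
Accuracy is 10-fold cross-validated — the forest is refit per fold and
out-of-fold predictions are pooled — reporting R^2 and NRMSD
(RMSE / target range), the latter because mean-effect targets concentrate
near zero and make R^2 misleading. "Nested" cross-validation reduces to
plain 10-fold here since no hyperparameter search is performed. For genetic
architecture, each of the 63 cell frequencies is predicted separately and
per-cell importances are averaged (constant cells carry no signal and are
skipped).

## Orchestration and reproducibility

An experiment is a YAML-configured Cartesian grid; the published-scale
configuration (5 sigma_m x 5 V_S x 4 psi x 12 demographies = 1,200 parameter
sets, 100 replicates, N_anc = 10,000, burn-in 10N) is available via
`published_config()` and is an overnight job. Desk-scale presets
(`single-scenario`, `maize-trait1`, `maize-trait2`) default to N_anc = 1,000
and 5 replicates with every per-gamete rate unchanged — the scale is
reduced, never the model. All randomness derives from one master seed
through a fixed `SeedSequence` spawning order (burn-ins, nulls, runs), so a
rerun reproduces every table byte for byte and results are independent of
the joblib worker count. Outputs are plain TSV plus one JSON manifest that
records the seeds; the manifest contains no timestamps.

## Desk-scale behavior and what it does not show

Reducing `N_anc` preserves the model but changes which printed phenomena are
expressed, because adaptation times are set by absolute genetic variance and
mutational input while the simulated window scales with `N_anc`:

- The focal scenario (sigma_m=0.05, V_S=1, psi=0, constant N) reaches the
  optimum in ~110 generations at any `N_anc` large enough — 0.011 N at
  N_anc=10,000 but only from N_anc ~ 2,000 does this fit inside the
  0.1 N window. The acceptance script therefore runs the focal scenario at
  N_anc = 2,000, where the shift distance is ~91 z-scores of `V_G0` and the
  post-optimum high-frequency SFS fraction is ~8%.
- Smaller populations hold less standing variation, so the balance between
  hard and standing sweeps shifts toward hard sweeps relative to
  published-scale runs; sweep *totals* and proportions should be compared
  across desk-scale scenarios, not read as published-scale values.
- `maize-trait1` (sigma_m=0.01, V_S=1, mutation-limited) does not reach the
  optimum within 0.1 N at desk scale (at published scale it takes 0.073 N);
  its variance minimum, fixation counts and architecture are still
  informative.

The synthetic data emulate allele-frequency and trait dynamics under the
stated model only: no linked neutral diversity, no dominance or epistasis,
no pleiotropy, no environmental noise on the phenotype beyond the background
term. Passing tests validate the machinery and its agreement with
population-genetic theory at small N; they do not certify parameter
estimates for any real population.

## Numerical choices

- Truncation ties: stable index order; odd n keeps `ceil(n/2)` survivors.
- Parent sampling: inverse-CDF on the fitness cumulative sum.
- Mutation columns are kept sorted by (locus, position) so gamete
  transmission reduces to contiguous block copies (a numba kernel); genetic
  values are accumulated incrementally and verified against full
  recomputation in tests (agreement to ~1e-15, not bit-exact, because
  summation order differs).
- Percentiles: numpy linear interpolation.
- Empty denominators (no fixations, no sweeps, zero-range targets) are
  reported as missing (NaN), never as zero.
- Architecture edges require at least nine distinct effects with mass on
  both sides of the central bin; parameter sets that cannot satisfy this at
  desk scale are recorded in the manifest and skipped.
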