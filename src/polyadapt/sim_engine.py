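"""Individual-based forward simulation of a polygenic trait adapting to a
distant optimum.

The model
---------
A diploid, randomly mating population carries ``n_loci`` unlinked QTL regions
(50 cM apart; free recombination between regions, crossovers within).  Trait
mutations arise at a per-gamete rate ``U`` with additive effects: an allele of
effect size ``a`` contributes 0, ``a/2`` or ``a`` to the genetic value for the
three genotype classes.  The allelic effect ``a/2`` of a new mutation is
Gaussian around zero with standard deviation ``sigma_m`` (see
:func:`draw_effect_size`).  An individual's phenotype optionally mixes
its QTL genetic value ``G`` with a heritable genomic background ``G_B`` drawn
around the mid-parent trait value, weighted by ``psi``.

Fitness is Gaussian around the trait optimum with width ``V_S``
(``w = exp(-(z - z_opt)^2 / (2 V_S))``).  Populations evolve to
mutation-selection-drift equilibrium under stabilizing selection at the
initial optimum (burn-in of ``10 N`` generations), then experience an
instantaneous shift of the optimum.  While the population mean lies below the
new optimum the population undergoes truncation selection (the top half of
the Gaussian fitness distribution survives); once the mean reaches the new
optimum, stabilizing selection around the new optimum resumes.  Demography
during the adaptive phase is an instantaneous bottleneck at the shift
followed by exponential growth over ``0.1 N_anc`` generations.

Time convention: generation 0 is the optimum shift; burn-in generations are
negative, adaptive-phase generations positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

__all__ = [
    "TraitParams",
    "QTLLayout",
    "DemographyModel",
    "Mutation",
    "Gamete",
    "Population",
    "Snapshot",
    "SimulationResult",
    "gaussian_fitness",
    "truncation_fitness",
    "draw_effect_size",
    "draw_mutation_sites",
    "mutate_gamete",
    "recombine",
    "phenotype",
    "advance_generation",
    "run_burn_in",
    "run_adaptation",
    "demography_grid",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitParams:
    """Trait model parameters.

    Parameters
    ----------
    sigma_m : float
        Standard deviation of the Gaussian distribution of effect sizes of
        new mutations (trait units).
    v_s : float
        Width of the Gaussian fitness function (trait units squared); larger
        values mean weaker stabilizing selection.
    psi : float
        Proportion of the phenotype contributed by the heritable genomic
        background, in [0, 1].
    z_opt_initial, z_opt_new : float
        Trait optimum before and after the shift.
    background_variance : str
        How the variance of the background draw is computed: from the
        variance of the whole parental generation's trait values
        ("population", default) or from each offspring's own parent pair
        ("midparent_pair").
    """

    sigma_m: float
    v_s: float
    psi: float = 0.0
    z_opt_initial: float = 0.0
    z_opt_new: float = 10.0
    background_variance: str = "population"

    def __post_init__(self) -> None:
        if not self.sigma_m > 0:
            raise ValueError("sigma_m must be positive")
        if not self.v_s > 0:
            raise ValueError("v_s must be positive")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must lie in [0, 1]")
        if self.background_variance not in ("population", "midparent_pair"):
            raise ValueError("background_variance must be 'population' or "
                             "'midparent_pair'")


@dataclass(frozen=True)
class QTLLayout:
    """Genomic layout of the simulated QTL.

    Each of ``n_loci`` unlinked regions is ``locus_length`` bp long with a
    ``genic_length`` bp genic segment centered in it.  Trait mutations hit
    intergenic sites at ``intergenic_relative_rate`` times the genic per-site
    rate; the per-site rates are derived from the total per-gamete trait
    mutation rate ``u_gamete``.
    """

    n_loci: int = 20
    locus_length: float = 50_000.0
    genic_length: float = 4_000.0
    rec_rate: float = 5e-8  # crossovers per site per generation
    u_gamete: float = 3e-3  # trait mutations per gamete per generation
    intergenic_relative_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.genic_length > self.locus_length:
            raise ValueError("invalid QTL layout")
        if self.u_gamete < 0 or self.rec_rate < 0:
            raise ValueError("rates must be non-negative")

    @property
    def intergenic_length(self) -> float:
        return self.locus_length - self.genic_length

    @property
    def genic_start(self) -> float:
        return (self.locus_length - self.genic_length) / 2.0

    @property
    def genic_end(self) -> float:
        return self.genic_start + self.genic_length

    @property
    def genic_fraction(self) -> float:
        """Probability that a new trait mutation falls in the genic segment."""
        weight_genic = self.genic_length
        weight_inter = self.intergenic_relative_rate * self.intergenic_length
        return weight_genic / (weight_genic + weight_inter)

    @property
    def genic_rate_per_site(self) -> float:
        denom = self.n_loci * (
            self.genic_length + self.intergenic_relative_rate * self.intergenic_length
        )
        return self.u_gamete / denom

    @property
    def intergenic_rate_per_site(self) -> float:
        return self.intergenic_relative_rate * self.genic_rate_per_site

    @property
    def crossover_rate_per_locus(self) -> float:
        return self.locus_length * self.rec_rate

    @property
    def crossover_rate_per_gamete(self) -> float:
        return self.n_loci * self.crossover_rate_per_locus


@dataclass(frozen=True)
class DemographyModel:
    """Diploid population-size schedule for the adaptive phase.

    The ancestral size ``n_anc`` holds throughout the burn-in.  At generation
    0 (the optimum shift) the size drops instantaneously to
    ``bottleneck_fraction * n_anc`` and then grows exponentially, reaching
    ``final_multiple * n_anc`` at generation ``n_generations``
    (``0.1 * n_anc`` by default).
    """

    n_anc: int
    bottleneck_fraction: float = 1.0
    final_multiple: float = 1.0
    n_generations: int | None = None

    def __post_init__(self) -> None:
        if self.n_anc < 2:
            raise ValueError("n_anc must be at least 2")
        if self.bottleneck_fraction <= 0 or self.final_multiple <= 0:
            raise ValueError("size multipliers must be positive")
        if self.n_generations is None:
            object.__setattr__(self, "n_generations", max(1, round(0.1 * self.n_anc)))

    @classmethod
    def constant(cls, n_anc: int) -> "DemographyModel":
        return cls(n_anc=n_anc)

    @property
    def n_bottleneck(self) -> int:
        return max(2, round(self.bottleneck_fraction * self.n_anc))

    @property
    def n_final(self) -> int:
        return max(2, round(self.final_multiple * self.n_anc))

    @property
    def scenario_id(self) -> str:
        return f"b{self.bottleneck_fraction:g}_f{self.final_multiple:g}"

    def size(self, generation: int) -> int:
        """Diploid size at adaptive-phase generation ``generation`` (0..T)."""
        t = int(generation)
        if t < 0 or t > self.n_generations:
            raise ValueError("generation outside the adaptive phase")
        nb, nf = self.n_bottleneck, self.n_final
        if nb == nf:
            return nb
        return max(2, round(nb * (nf / nb) ** (t / self.n_generations)))

    def sizes(self) -> np.ndarray:
        return np.array([self.size(t) for t in range(self.n_generations + 1)], dtype=np.int64)


def demography_grid(n_anc: int,
                    bottleneck_fractions=(1.0, 0.10, 0.05, 0.01),
                    final_multiples=(1.0, 3.0, 10.0)) -> list[DemographyModel]:
    """The standard 12-scenario bottleneck x growth demography grid."""
    return [
        DemographyModel(n_anc=n_anc, bottleneck_fraction=b, final_multiple=f)
        for b in bottleneck_fractions
        for f in final_multiples
    ]


@dataclass
class Mutation:
    """A single trait-affecting variant."""

    id: int
    locus: int
    position: float
    effect: float
    origin_generation: int
    count: int = 0
    fate: str = "segregating"


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def gaussian_fitness(z, z_opt, v_s):
    """Gaussian stabilizing-selection fitness ``exp(-(z-z_opt)^2 / (2 V_S))``.

    Equals 1 iff ``z == z_opt``; strictly positive otherwise.
    """
    if not v_s > 0:
        raise ValueError("v_s must be positive")
    z = np.asarray(z, dtype=float)
    w = np.exp(-((z - z_opt) ** 2) / (2.0 * v_s))
    return float(w) if w.ndim == 0 else w


def truncation_fitness(fitnesses) -> np.ndarray:
    """Assign fitness 1 to the top half of ``fitnesses`` and 0 to the rest.

    Exactly ``ceil(n/2)`` individuals receive fitness 1.  Ties at the median
    are broken by stable index order (earlier index wins).
    """
    w = np.asarray(fitnesses, dtype=float)
    if w.size == 0:
        raise ValueError("empty fitness sequence")
    n_survivors = -(-w.size // 2)  # ceil(n/2)
    order = np.argsort(-w, kind="stable")
    out = np.zeros(w.size, dtype=np.int64)
    out[order[:n_survivors]] = 1
    return out


def draw_effect_size(sigma_m: float, rng: np.random.Generator, size=None):
    """Sample allelic effect sizes of new mutations from Normal(0, sigma_m^2).

    ``sigma_m`` parametrizes the per-allele (heterozygous) effect on the
    trait: one copy of a new allele shifts the genetic value by this draw,
    two copies by twice it.  Equivalently, the homozygous effect ``a`` stored
    in mutation tables is twice the sampled value (genotype values 0, a/2,
    a).  This is the convention under which the house-of-cards variance
    approximations hold with sigma_m entering directly (the neutral limit
    E[V_G] = 4 N U sigma_m^2 pins it down exactly).
    """
    if not sigma_m > 0:
        raise ValueError("sigma_m must be positive")
    return rng.normal(0.0, sigma_m, size=size)


def draw_mutation_sites(layout: QTLLayout, n_mutations: int, rng: np.random.Generator):
    """Place ``n_mutations`` new mutations: uniform locus, genic vs intergenic
    class weighted by length x per-site rate, continuous position within the
    class (infinitely-many-sites).

    Returns ``(locus, position)`` integer and float arrays.
    """
    locus = rng.integers(0, layout.n_loci, size=n_mutations)
    genic = rng.random(n_mutations) < layout.genic_fraction
    u = rng.random(n_mutations)
    pos_genic = layout.genic_start + u * layout.genic_length
    v = u * layout.intergenic_length
    pos_inter = np.where(v < layout.genic_start, v, v + layout.genic_length)
    position = np.where(genic, pos_genic, pos_inter)
    return locus, position


@dataclass
class Gamete:
    """A haploid genome: per-locus arrays of mutation positions and ids."""

    positions: list  # list of float ndarrays, one per locus
    ids: list  # list of int ndarrays, parallel to positions

    @classmethod
    def empty(cls, n_loci: int) -> "Gamete":
        return cls(
            positions=[np.empty(0, dtype=float) for _ in range(n_loci)],
            ids=[np.empty(0, dtype=np.int64) for _ in range(n_loci)],
        )

    def copy(self) -> "Gamete":
        return Gamete([p.copy() for p in self.positions], [i.copy() for i in self.ids])

    def all_ids(self) -> np.ndarray:
        return np.concatenate(self.ids) if self.ids else np.empty(0, dtype=np.int64)


def mutate_gamete(gamete: Gamete, layout: QTLLayout, rng: np.random.Generator,
                  next_id: int = 0):
    """Add Poisson(``U``)-many new mutations to a copy of ``gamete``.

    Returns ``(new_gamete, new_sites)`` where ``new_sites`` is a list of
    ``(id, locus, position)`` tuples; effect sizes are assigned by the caller
    (see :func:`draw_effect_size`).
    """
    n_new = rng.poisson(layout.u_gamete)
    out = gamete.copy()
    new_sites = []
    if n_new:
        locus, position = draw_mutation_sites(layout, n_new, rng)
        for k in range(n_new):
            l, p = int(locus[k]), float(position[k])
            mut_id = next_id + k
            out.positions[l] = np.append(out.positions[l], p)
            out.ids[l] = np.append(out.ids[l], mut_id)
            new_sites.append((mut_id, l, p))
    return out, new_sites


def recombine(parent_gametes, layout: QTLLayout, rng: np.random.Generator) -> Gamete:
    """Produce one recombinant gamete from a parent's two gametes.

    Loci are unlinked: each locus starts from either parental gamete with
    probability 1/2.  Within a locus the crossover count is
    Poisson(locus_length x rec_rate) with uniform breakpoints; alleles are
    copied from the gamete indicated by the parity of breakpoints to their
    left.
    """
    g0, g1 = parent_gametes
    pair = (g0, g1)
    out_pos, out_ids = [], []
    for l in range(layout.n_loci):
        start = int(rng.integers(0, 2))
        k = rng.poisson(layout.crossover_rate_per_locus)
        if k == 0:
            out_pos.append(pair[start].positions[l].copy())
            out_ids.append(pair[start].ids[l].copy())
            continue
        bp = np.sort(rng.uniform(0.0, layout.locus_length, size=k))
        pos_parts, id_parts = [], []
        for src in (0, 1):
            g = pair[src]
            parity = np.searchsorted(bp, g.positions[l]) % 2
            take = parity == (0 if src == start else 1)
            pos_parts.append(g.positions[l][take])
            id_parts.append(g.ids[l][take])
        pos = np.concatenate(pos_parts)
        ids = np.concatenate(id_parts)
        order = np.argsort(pos)
        out_pos.append(pos[order])
        out_ids.append(ids[order])
    return Gamete(out_pos, out_ids)


def phenotype(g, g_mp, sigma2_parental, psi, rng: np.random.Generator):
    """Mix the QTL genetic value with a heritable genomic background.

    ``G_B ~ Normal(G_mp, sigma2_parental)`` and
    ``P = psi * G_B + (1 - psi) * G``.
    """
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    sigma2 = np.asarray(sigma2_parental, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2_parental must be non-negative")
    g = np.asarray(g, dtype=float)
    g_mp = np.asarray(g_mp, dtype=float)
    shape = np.broadcast_shapes(g.shape, g_mp.shape, sigma2.shape)
    g_b = rng.normal(g_mp, np.sqrt(sigma2), size=shape if shape else None)
    p = psi * g_b + (1.0 - psi) * g
    return float(p) if np.ndim(p) == 0 else p


# ---------------------------------------------------------------------------
# Population state
# ---------------------------------------------------------------------------


class Population:
    """Vectorized population state.

    Gametes are rows of a boolean presence matrix over the currently
    segregating mutations (columns).  Effects of fixed mutations are folded
    into a scalar ``baseline`` and logged in the fixation table.
    """

    def __init__(self, params: TraitParams, layout: QTLLayout, generation: int,
                 geno: np.ndarray, mut_id: np.ndarray, mut_locus: np.ndarray,
                 mut_position: np.ndarray, mut_effect: np.ndarray,
                 mut_origin: np.ndarray, baseline: float, g_values: np.ndarray,
                 trait_values: np.ndarray, next_id: int, neutral: bool = False):
        self.params = params
        self.layout = layout
        self.generation = generation
        self.geno = geno
        self.mut_id = mut_id
        self.mut_locus = mut_locus
        self.mut_position = mut_position
        self.mut_effect = mut_effect
        self.mut_origin = mut_origin
        self.baseline = baseline
        self.G = g_values
        self.P = trait_values
        self.next_id = next_id
        self.neutral = neutral
        self.fixations: list[tuple] = []  # (id, locus, position, effect, origin, fix_gen)
        self.n_lost = 0

    # -- construction -------------------------------------------------------

    @classmethod
    def founder(cls, n_individuals: int, params: TraitParams, layout: QTLLayout,
                generation: int = 0, neutral: bool = False) -> "Population":
        if n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        return cls(
            params=params,
            layout=layout,
            generation=generation,
            geno=np.zeros((2 * n_individuals, 0), dtype=bool),
            mut_id=np.empty(0, dtype=np.int64),
            mut_locus=np.empty(0, dtype=np.int64),
            mut_position=np.empty(0, dtype=float),
            mut_effect=np.empty(0, dtype=float),
            mut_origin=np.empty(0, dtype=np.int64),
            baseline=0.0,
            g_values=np.zeros(n_individuals),
            trait_values=np.zeros(n_individuals),
            next_id=0,
            neutral=neutral,
        )

    def copy(self) -> "Population":
        pop = Population(
            params=self.params, layout=self.layout, generation=self.generation,
            geno=self.geno.copy(), mut_id=self.mut_id.copy(),
            mut_locus=self.mut_locus.copy(), mut_position=self.mut_position.copy(),
            mut_effect=self.mut_effect.copy(), mut_origin=self.mut_origin.copy(),
            baseline=self.baseline, g_values=self.G.copy(),
            trait_values=self.P.copy(), next_id=self.next_id, neutral=self.neutral,
        )
        pop.fixations = list(self.fixations)
        pop.n_lost = self.n_lost
        return pop

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.geno.shape[0] // 2

    @property
    def n_gametes(self) -> int:
        return self.geno.shape[0]

    @property
    def n_segregating(self) -> int:
        return self.geno.shape[1]

    def allele_counts(self) -> np.ndarray:
        return self.geno.sum(axis=0)

    def recompute_G(self) -> np.ndarray:
        """Recompute genetic values from gametes + baseline (invariant check)."""
        gv = 0.5 * (self.geno @ self.mut_effect)
        return self.baseline + gv[0::2] + gv[1::2]

    def mean_fitness(self, z_opt: float) -> float:
        return float(np.mean(gaussian_fitness(self.P, z_opt, self.params.v_s)))

    def segregating_table(self) -> pd.DataFrame:
        counts = self.allele_counts()
        return pd.DataFrame({
            "mutation_id": self.mut_id,
            "locus": self.mut_locus,
            "position": self.mut_position,
            "effect": self.mut_effect,
            "origin_generation": self.mut_origin,
            "count": counts,
            "frequency": counts / self.n_gametes,
        })

    def fixation_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fixations,
            columns=["mutation_id", "locus", "position", "effect",
                     "origin_generation", "fixation_generation"],
        )

    # -- internal helpers ---------------------------------------------------

    def _fold_absorbed(self, fix_generation: int) -> None:
        """Move fixed columns into the baseline and drop lost columns."""
        if self.n_segregating == 0:
            return
        counts = self.allele_counts()
        fixed = counts == self.n_gametes
        lost = counts == 0
        if fixed.any():
            self.baseline += float(self.mut_effect[fixed].sum())
            for j in np.nonzero(fixed)[0]:
                self.fixations.append((
                    int(self.mut_id[j]), int(self.mut_locus[j]),
                    float(self.mut_position[j]), float(self.mut_effect[j]),
                    int(self.mut_origin[j]), int(fix_generation),
                ))
        if fixed.any() or lost.any():
            keep = ~(fixed | lost)
            self.n_lost += int(lost.sum())
            self.geno = self.geno[:, keep]
            self.mut_id = self.mut_id[keep]
            self.mut_locus = self.mut_locus[keep]
            self.mut_position = self.mut_position[keep]
            self.mut_effect = self.mut_effect[keep]
            self.mut_origin = self.mut_origin[keep]

    def downsample(self, n_new: int, rng: np.random.Generator) -> None:
        """Instantaneous reduction to ``n_new`` diploids (sampling without
        replacement); alleles fixed or lost by the reduction are folded with
        the current generation as their fate generation."""
        n = self.n_individuals
        if n_new > n:
            raise ValueError("downsample cannot increase population size")
        if n_new == n:
            return
        idx = np.sort(rng.choice(n, size=n_new, replace=False))
        rows = np.empty(2 * n_new, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        self.geno = self.geno[rows]
        self.G = self.G[idx]
        self.P = self.P[idx]
        self._fold_absorbed(self.generation)


# ---------------------------------------------------------------------------
# One generation
# ---------------------------------------------------------------------------


@numba.njit(cache=True)
def _transmit_kernel(geno, effects, gamete_parents, starts, bounds, position,
                     g_s, l_s, p_s, group):  # pragma: no cover - exercised via _transmit
    n_new = gamete_parents.shape[0]
    s = geno.shape[1]
    n_loci = bounds.shape[0] - 1
    new = np.empty((n_new, s), dtype=np.bool_)
    # free recombination between loci: block-copy each locus from the
    # starting parental gamete
    for i in range(n_new):
        base = 2 * gamete_parents[i]
        for l in range(n_loci):
            row = base + starts[i, l]
            for j in range(bounds[l], bounds[l + 1]):
                new[i, j] = geno[row, j]
    # within-locus crossovers: columns are sorted by (locus, position), so
    # alleles taken from the other gamete form contiguous slices between
    # breakpoints (odd-parity segments)
    for gi in range(group.shape[0] - 1):
        a, b = group[gi], group[gi + 1]
        g, l = g_s[a], l_s[a]
        lo, hi = bounds[l], bounds[l + 1]
        other = 2 * gamete_parents[g] + (1 - starts[g, l])
        if b - a == 1:
            j0 = lo + np.searchsorted(position[lo:hi], p_s[a])
            for j in range(j0, hi):
                new[g, j] = geno[other, j]
        else:
            bp = np.sort(p_s[a:b].copy())
            k = 0
            while k < bp.shape[0]:
                j0 = lo + np.searchsorted(position[lo:hi], bp[k])
                if k + 1 < bp.shape[0]:
                    j1 = lo + np.searchsorted(position[lo:hi], bp[k + 1])
                else:
                    j1 = hi
                for j in range(j0, j1):
                    new[g, j] = geno[other, j]
                k += 2
    # per-gamete genetic value: half the summed effect of carried alleles
    values = np.zeros(n_new)
    for i in range(n_new):
        acc = 0.0
        for j in range(s):
            if new[i, j]:
                acc += effects[j]
        values[i] = 0.5 * acc
    return new, values


def _transmit(pop: Population, gamete_parents: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Build offspring gametes: free recombination between loci, Poisson
    crossovers within loci.  ``gamete_parents[i]`` is the diploid parent of
    offspring gamete ``i``.  Relies on mutation columns being sorted by
    (locus, position) -- an engine invariant -- so inheritance reduces to
    contiguous block copies."""
    layout = pop.layout
    n_new = gamete_parents.size
    starts = rng.integers(0, 2, size=(n_new, layout.n_loci), dtype=np.int64)
    s = pop.n_segregating
    if s == 0:
        return np.zeros((n_new, 0), dtype=bool), np.zeros(n_new)
    bounds = np.searchsorted(pop.mut_locus, np.arange(layout.n_loci + 1)).astype(np.int64)
    k_tot = rng.poisson(layout.crossover_rate_per_gamete, size=n_new)
    total = int(k_tot.sum())
    g_s = np.empty(0, dtype=np.int64)
    l_s = np.empty(0, dtype=np.int64)
    p_s = np.empty(0, dtype=np.float64)
    group = np.zeros(1, dtype=np.int64)
    if total:
        ev_gamete = np.repeat(np.arange(n_new), k_tot)
        ev_locus = rng.integers(0, layout.n_loci, size=total)
        ev_pos = rng.uniform(0.0, layout.locus_length, size=total)
        # crossovers at loci without segregating mutations change nothing
        keep = bounds[ev_locus + 1] > bounds[ev_locus]
        ev_gamete, ev_locus, ev_pos = ev_gamete[keep], ev_locus[keep], ev_pos[keep]
        if ev_gamete.size:
            # group events sharing the same (gamete, locus)
            key = ev_gamete * layout.n_loci + ev_locus
            order = np.argsort(key, kind="stable")
            key_s = key[order]
            g_s, l_s, p_s = ev_gamete[order], ev_locus[order], ev_pos[order]
            group = np.nonzero(np.r_[True, key_s[1:] != key_s[:-1]])[0]
            group = np.append(group, key_s.size).astype(np.int64)
    return _transmit_kernel(pop.geno, pop.mut_effect,
                            gamete_parents.astype(np.int64), starts,
                            bounds, pop.mut_position, g_s, l_s, p_s, group)


def advance_generation(pop: Population, rng: np.random.Generator, *,
                       n_next: int | None = None, z_opt: float | None = None,
                       phase: str = "stabilizing") -> Population:
    """Advance the population by one generation of selection, reproduction,
    recombination and mutation.  Modifies ``pop`` in place and returns it.

    Parents are drawn with replacement, independently for each offspring's
    two gametes (selfing allowed).  Under ``phase="stabilizing"`` sampling is
    proportional to Gaussian fitness; under ``phase="truncation"`` the top
    half by Gaussian fitness reproduces uniformly and the rest not at all.
    """
    params, layout = pop.params, pop.layout
    n = pop.n_individuals
    if n_next is None:
        n_next = n
    if z_opt is None:
        z_opt = params.z_opt_initial
    w = gaussian_fitness(pop.P, z_opt, params.v_s)
    if phase == "truncation":
        survivors = np.nonzero(truncation_fitness(w) == 1)[0]
        parents = survivors[rng.integers(0, survivors.size, size=2 * n_next)]
    elif phase == "stabilizing":
        cdf = np.cumsum(w)
        total = float(cdf[-1])
        if total <= 0.0:
            raise RuntimeError("all fitness values are zero")
        # inverse-CDF sampling proportional to fitness
        parents = np.searchsorted(cdf, rng.random(2 * n_next) * total,
                                  side="right")
    else:
        raise ValueError(f"unknown phase {phase!r}")
    p1, p2 = parents[:n_next], parents[n_next:]
    gamete_parents = np.empty(2 * n_next, dtype=np.int64)
    gamete_parents[0::2] = p1
    gamete_parents[1::2] = p2

    new_geno, gamete_values = _transmit(pop, gamete_parents, rng)

    # new mutations (infinitely-many-sites: each is a fresh column)
    gen_next = pop.generation + 1
    n_mut = rng.poisson(layout.u_gamete * 2 * n_next)
    if n_mut:
        locus, position = draw_mutation_sites(layout, n_mut, rng)
        if pop.neutral:
            effects = np.zeros(n_mut)
        else:
            # tables store the homozygous effect a = 2 x the allelic draw
            effects = 2.0 * draw_effect_size(params.sigma_m, rng, size=n_mut)
        carrier = rng.integers(0, 2 * n_next, size=n_mut)
        block = np.zeros((2 * n_next, n_mut), dtype=bool)
        block[carrier, np.arange(n_mut)] = True
        new_geno = np.concatenate([new_geno, block], axis=1)
        np.add.at(gamete_values, carrier, 0.5 * effects)
        pop.mut_id = np.concatenate([pop.mut_id, pop.next_id + np.arange(n_mut)])
        pop.mut_locus = np.concatenate([pop.mut_locus, locus])
        pop.mut_position = np.concatenate([pop.mut_position, position])
        pop.mut_effect = np.concatenate([pop.mut_effect, effects])
        pop.mut_origin = np.concatenate(
            [pop.mut_origin, np.full(n_mut, gen_next, dtype=np.int64)])
        pop.next_id += n_mut
        # restore the sorted-by-(locus, position) column invariant
        order = np.lexsort((pop.mut_position, pop.mut_locus))
        if np.any(order != np.arange(order.size)):
            new_geno = np.ascontiguousarray(new_geno[:, order])
            pop.mut_id = pop.mut_id[order]
            pop.mut_locus = pop.mut_locus[order]
            pop.mut_position = pop.mut_position[order]
            pop.mut_effect = pop.mut_effect[order]
            pop.mut_origin = pop.mut_origin[order]

    # parental values needed for the heritable background
    mid_parent = 0.5 * (pop.P[p1] + pop.P[p2])
    if params.background_variance == "midparent_pair":
        sigma2_parental = 0.25 * (pop.P[p1] - pop.P[p2]) ** 2
    else:
        sigma2_parental = float(np.var(pop.P))

    pop.geno = new_geno
    pop.generation = gen_next
    # gamete_values already include alleles that just fixed, so pair them
    # with the baseline from before folding
    baseline_before = pop.baseline
    pop._fold_absorbed(gen_next)

    pop.G = baseline_before + gamete_values[0::2] + gamete_values[1::2]
    if params.psi > 0.0:
        pop.P = phenotype(pop.G, mid_parent, sigma2_parental, params.psi, rng)
    else:
        pop.P = pop.G.copy()
    return pop


# ---------------------------------------------------------------------------
# Whole phases
# ---------------------------------------------------------------------------


def run_burn_in(params: TraitParams, layout: QTLLayout, n_anc: int,
                rng: np.random.Generator, generations: int | None = None,
                neutral: bool = False):
    """Evolve a founder population to mutation-selection-drift equilibrium
    under stabilizing selection at the initial optimum.

    Runs ``10 * n_anc`` generations by default, numbered ``-generations + 1``
    through 0 (generation 0 = end of burn-in = optimum shift).  Returns the
    equilibrated :class:`Population` and a per-generation trajectory frame
    with columns ``generation``, ``mean_trait`` and ``var_g``.
    """
    if generations is None:
        generations = 10 * n_anc
    pop = Population.founder(n_anc, params, layout,
                             generation=-generations, neutral=neutral)
    gens = np.empty(generations, dtype=np.int64)
    means = np.empty(generations)
    var_g = np.empty(generations)
    for i in range(generations):
        advance_generation(pop, rng, z_opt=params.z_opt_initial, phase="stabilizing")
        gens[i] = pop.generation
        means[i] = pop.P.mean()
        var_g[i] = pop.G.var()
    trajectory = pd.DataFrame({"generation": gens, "mean_trait": means, "var_g": var_g})
    return pop, trajectory


def _default_snapshot_generations(n_generations: int) -> list[int]:
    """Every 10 generations for the first 100 post-shift generations, every
    100 thereafter; generation 0 and the final generation always included."""
    gens = {0, n_generations}
    gens.update(g for g in range(10, min(100, n_generations) + 1, 10))
    gens.update(g for g in range(200, n_generations + 1, 100))
    return sorted(gens)


@dataclass
class Snapshot:
    generation: int
    mutations: pd.DataFrame
    g_values: np.ndarray
    trait_values: np.ndarray


@dataclass
class SimulationResult:
    """Everything recorded during one adaptive-phase run."""

    params: TraitParams
    demography: DemographyModel
    v_g0: float
    trajectory: pd.DataFrame  # generation, mean_trait, var_g, phase
    snapshots: list
    fixations: pd.DataFrame  # post-shift fixations
    segregating: pd.DataFrame  # final generation
    reached_optimum_generation: int | None  # first gen mean >= 0.99 z_opt_new

    @property
    def reached_optimum(self) -> bool:
        return self.reached_optimum_generation is not None

    def snapshot_at(self, generation: int) -> Snapshot:
        for snap in self.snapshots:
            if snap.generation == generation:
                return snap
        raise KeyError(f"no snapshot at generation {generation}")


def run_adaptation(pop: Population, demography: DemographyModel,
                   rng: np.random.Generator,
                   snapshot_generations: list[int] | None = None,
                   record_snapshots: bool = True) -> SimulationResult:
    """Run the adaptive phase on an equilibrated population.

    Applies the instantaneous bottleneck at generation 0, then evolves under
    truncation selection toward the new optimum; once the (pre-selection)
    population mean reaches ``z_opt_new``, truncation ends permanently and
    stabilizing selection around the new optimum resumes.  The population is
    modified in place; pass a copy to keep the equilibrium state.
    """
    params = pop.params
    if pop.generation != 0:
        raise ValueError("run_adaptation expects a population at generation 0 "
                         "(fresh from run_burn_in)")
    t_final = demography.n_generations
    v_g0 = float(pop.G.var())

    pop.downsample(min(demography.n_bottleneck, pop.n_individuals), rng)
    init_freq = dict(zip(pop.mut_id.tolist(),
                         (pop.allele_counts() / pop.n_gametes).tolist()))

    if snapshot_generations is None:
        snapshot_generations = _default_snapshot_generations(t_final)
    snap_set = set(snapshot_generations) if record_snapshots else set()

    def take_snapshot():
        return Snapshot(pop.generation, pop.segregating_table(),
                        pop.G.copy(), pop.P.copy())

    snapshots = [take_snapshot()] if 0 in snap_set else []

    truncation_active = bool(pop.P.mean() < params.z_opt_new)
    rows = [(0, float(pop.P.mean()), float(pop.G.var()),
             "truncation" if truncation_active else "stabilizing")]
    for t in range(1, t_final + 1):
        phase = "truncation" if truncation_active else "stabilizing"
        advance_generation(pop, rng, n_next=demography.size(t),
                           z_opt=params.z_opt_new, phase=phase)
        mean_p = float(pop.P.mean())
        rows.append((t, mean_p, float(pop.G.var()), phase))
        if truncation_active and mean_p >= params.z_opt_new:
            truncation_active = False
        if t in snap_set:
            snapshots.append(take_snapshot())

    trajectory = pd.DataFrame(rows, columns=["generation", "mean_trait",
                                             "var_g", "phase"])
    threshold = params.z_opt_initial + 0.99 * (params.z_opt_new - params.z_opt_initial)
    reached = trajectory.loc[trajectory["mean_trait"] >= threshold, "generation"]
    reached_gen = int(reached.iloc[0]) if len(reached) else None

    fixations = pop.fixation_table()
    fixations = fixations[fixations["fixation_generation"] >= 0].reset_index(drop=True)
    fixations["sojourn"] = (fixations["fixation_generation"]
                            - fixations["origin_generation"])
    fixations["initial_frequency"] = [
        init_freq.get(mid, 0.0) if og <= 0 else 0.0
        for mid, og in zip(fixations["mutation_id"], fixations["origin_generation"])
    ]

    return SimulationResult(
        params=params,
        demography=demography,
        v_g0=v_g0,
        trajectory=trajectory,
        snapshots=snapshots,
        fixations=fixations,
        segregating=pop.segregating_table(),
        reached_optimum_generation=reached_gen,
    )
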