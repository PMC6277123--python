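"""Demography-matched null distribution of neutral conditional fixation times.

Selective sweeps are called by comparing the sojourn time (origin to
fixation) of each fixed trait mutation against neutral alleles experiencing
the same demography.  Neutral sojourns are generated by single-locus binomial
sampling: single-copy mutations are injected at uniform random origin
generations across the burn-in plus the adaptive window, allele counts are
propagated as ``x' ~ Binomial(2 N_next, x / (2 N_current))``, and only
mutations fixing inside the final ``0.1 N_anc`` window (and neither fixed nor
lost earlier) contribute sojourn times.  The sweep-calling threshold is the
1st percentile of these sojourns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim_engine import DemographyModel

__all__ = ["NeutralNull", "simulate_neutral_sojourns", "sweep_threshold"]


@dataclass
class NeutralNull:
    """Empirical neutral conditional-fixation-time distribution for one
    demography."""

    demography_id: str
    n_anc: int
    sojourn_times: np.ndarray
    n_requested: int = 0
    n_injected: int = 0

    @property
    def threshold_gen(self) -> float:
        return sweep_threshold(self)


def sweep_threshold(null, percentile: float = 1.0) -> float:
    """Sweep-calling threshold: the ``percentile``-th percentile (default 1st)
    of the neutral sojourn times, with linear interpolation between order
    statistics."""
    sojourns = null.sojourn_times if isinstance(null, NeutralNull) else np.asarray(null, float)
    if np.size(sojourns) == 0:
        raise ValueError("empty null distribution")
    return float(np.percentile(sojourns, percentile))


def _calendar_sizes(demography: DemographyModel, burn_in_generations: int) -> np.ndarray:
    """Diploid size per calendar generation 0..B+T, where calendar B is the
    optimum shift (adaptive-phase generation 0)."""
    return np.concatenate([
        np.full(burn_in_generations, demography.n_anc, dtype=np.int64),
        demography.sizes(),
    ])


def simulate_neutral_sojourns(demography: DemographyModel,
                              n_fixations: int = 10_000,
                              rng: np.random.Generator | None = None,
                              burn_in_generations: int | None = None,
                              mode: str = "fixations",
                              max_sweeps: int = 60) -> NeutralNull:
    """Build the neutral null for one demography.

    Parameters
    ----------
    n_fixations : int
        In ``mode="fixations"`` (default), collect at least this many window
        fixations.  In ``mode="injections"``, inject exactly this many
        mutations and keep whatever fixes in the window.
    burn_in_generations : int, optional
        Length of the constant-size phase preceding the shift
        (default ``10 * n_anc``).

    Notes
    -----
    Origins are uniform over the whole simulated span.  Each calendar sweep
    runs to completion before the collected count is checked, so stopping
    cannot bias the sojourn distribution.  Mutations lost at any time, fixed
    before the shift, or still segregating at the end are discarded.

    The sampler exploits that under binomial resampling the allele frequency
    is a martingale, so (i) a new single-copy mutation at a generation with
    diploid size ``N`` ultimately fixes with probability exactly
    ``1 / (2 N)``, and (ii) the law of a trajectory conditioned on eventual
    fixation is again Markov with the shifted-binomial kernel
    ``x' = 1 + Binomial(2 N_next - 1, x / (2 N_current))`` (a Doob
    h-transform with the harmonic function h = frequency, valid for any
    size schedule).  Each injected mutation's destiny is therefore drawn as
    a Bernoulli(initial frequency) coin and only the fixing trajectories are
    propagated; mutations destined for loss -- which contribute nothing to
    the null -- are never simulated.  The collected sojourn distribution is
    identical to propagating every injection with the plain binomial kernel.
    """
    if rng is None:
        rng = np.random.default_rng()
    if mode not in ("fixations", "injections"):
        raise ValueError("mode must be 'fixations' or 'injections'")
    b = 10 * demography.n_anc if burn_in_generations is None else int(burn_in_generations)
    sizes = _calendar_sizes(demography, b)
    span = sizes.size - 1  # transitions; injections happen at 0..span-1
    t_window = demography.n_generations

    if mode == "injections":
        total_injections = int(n_fixations)
    else:
        # expected yield per injection ~ (1 / 2N) * (window share of span)
        expected_yield = (1.0 / (2.0 * demography.n_anc)) * (t_window / span)
        total_injections = int(np.ceil(1.25 * n_fixations / expected_yield))
    rate = total_injections / span

    sojourns: list[np.ndarray] = []
    n_collected = 0
    n_injected = 0
    for _sweep in range(max_sweeps):
        active_x = np.empty(0, dtype=np.int64)
        active_origin = np.empty(0, dtype=np.int64)
        for c in range(span):
            k = int(rng.poisson(rate))
            if k:
                n_injected += k
                # destiny coin: fixers only (h-transform, see Notes)
                f = int(rng.binomial(k, 1.0 / (2.0 * sizes[c])))
                if f:
                    active_x = np.concatenate([active_x, np.ones(f, dtype=np.int64)])
                    active_origin = np.concatenate(
                        [active_origin, np.full(f, c, dtype=np.int64)])
            if active_x.size == 0:
                continue
            two_n_next = 2 * int(sizes[c + 1])
            x = 1 + rng.binomial(two_n_next - 1, active_x / (2.0 * sizes[c]))
            fixed = x == two_n_next
            if fixed.any() and c + 1 >= b:
                times = (c + 1) - active_origin[fixed]
                sojourns.append(times.astype(np.int64))
                n_collected += times.size
            active_x = x[~fixed]
            active_origin = active_origin[~fixed]
        if mode == "injections" or n_collected >= n_fixations:
            break
    else:
        raise RuntimeError("neutral null did not collect enough fixations; "
                           "increase n_fixations budget or max_sweeps")

    times = (np.concatenate(sojourns) if sojourns else np.empty(0, dtype=np.int64))
    return NeutralNull(
        demography_id=demography.scenario_id,
        n_anc=demography.n_anc,
        sojourn_times=times,
        n_requested=int(n_fixations),
        n_injected=n_injected,
    )
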