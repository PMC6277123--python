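"""Per-simulation summary statistics: adaptation speed, variance dynamics,
site-frequency spectra, fixation and segregating-site descriptors, and the
analytic house-of-cards variance expectations."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "time_to_optimum",
    "adaptation_rate",
    "sfs",
    "high_frequency_fraction",
    "hoc_expectation",
    "stochastic_hoc_expectation",
    "fixation_stats",
    "segregating_stats",
    "summary_row",
]


def time_to_optimum(trajectory: pd.DataFrame, z_opt_new: float, n_anc: int,
                    fraction: float = 0.99) -> float:
    """First generation at which the population mean reaches ``fraction``
    (default 99%) of the new optimum, in units of ``N_anc``; NaN if never."""
    hit = trajectory.loc[trajectory["mean_trait"] >= fraction * z_opt_new,
                         "generation"]
    if len(hit) == 0:
        return float("nan")
    return float(hit.iloc[0]) / n_anc


def adaptation_rate(trajectory: pd.DataFrame, v_g0: float, z_opt_new: float) -> float:
    """Speed of adaptation corrected for the initial genetic variance:
    optimum displacement in units of the equilibrium genetic standard
    deviation, divided by the generations needed to reach 99% of the optimum.
    NaN when the optimum was never reached."""
    if not v_g0 > 0:
        raise ValueError("v_g0 must be positive")
    initial_mean = float(trajectory["mean_trait"].iloc[0])
    hit = trajectory.loc[trajectory["mean_trait"] >= 0.99 * z_opt_new, "generation"]
    if len(hit) == 0:
        return float("nan")
    generations = float(hit.iloc[0])
    if generations <= 0:
        return float("nan")
    return (z_opt_new - initial_mean) / np.sqrt(v_g0) / generations


def sfs(frequencies, n_bins: int = 20, two_n: int | None = None) -> pd.DataFrame:
    """Binned site-frequency spectrum with the neutral 1/i reference.

    The neutral reference distributes the observed number of segregating
    sites proportionally to ``1/i`` over derived-allele counts
    ``i = 1..2N-1`` (``two_n`` defaults to 200 bins worth of resolution when
    the sample size is unknown).
    """
    freqs = np.asarray(frequencies, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(freqs, bins=edges)
    if two_n is None:
        two_n = 200
    i = np.arange(1, two_n)
    weights = 1.0 / i
    neutral, _ = np.histogram(i / two_n, bins=edges, weights=weights)
    total = neutral.sum()
    neutral = neutral / total * freqs.size if total > 0 else neutral
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_right": edges[1:],
        "count": counts,
        "neutral_expected": neutral,
    })


def high_frequency_fraction(frequencies, cutoff: float = 0.5) -> float:
    """Fraction of segregating sites with derived-allele frequency above
    ``cutoff``; NaN for an empty snapshot."""
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        return float("nan")
    return float(np.mean(freqs > cutoff))


def hoc_expectation(mu_gamete: float, v_s: float) -> float:
    """House-of-cards equilibrium genetic variance, ``4 mu V_S`` with ``mu``
    the per-gamete trait mutation rate."""
    return 4.0 * mu_gamete * v_s


def stochastic_hoc_expectation(mu_gamete: float, v_s: float, n: float,
                               sigma_m: float) -> float:
    """Stochastic house-of-cards equilibrium genetic variance,
    ``4 mu V_S / (1 + V_S / (N sigma_m^2))``, which corrects the HoC value
    for finite population size."""
    return 4.0 * mu_gamete * v_s / (1.0 + v_s / (n * sigma_m ** 2))


def fixation_stats(fixations: pd.DataFrame) -> pd.Series:
    """Counts and mean effects of fixations, partitioned exactly by sign.

    Means over an empty sign class are reported as NaN (missing).
    """
    effects = fixations["effect"].to_numpy() if len(fixations) else np.empty(0)
    pos = effects[effects > 0]
    neg = effects[effects < 0]
    return pd.Series({
        "n_fixations": effects.size,
        "n_positive_fixations": pos.size,
        "n_negative_fixations": neg.size,
        "mean_effect_fixations": effects.mean() if effects.size else np.nan,
        "mean_effect_positive_fixations": pos.mean() if pos.size else np.nan,
        "mean_effect_negative_fixations": neg.mean() if neg.size else np.nan,
    })


def segregating_stats(segregating: pd.DataFrame) -> pd.Series:
    """Final-generation segregating-site descriptors: counts, mean
    frequencies and mean effects by effect sign, and the proportion of
    negative-effect sites."""
    if len(segregating):
        eff = segregating["effect"].to_numpy()
        freq = segregating["frequency"].to_numpy()
    else:
        eff = freq = np.empty(0)
    pos = eff > 0
    neg = eff < 0
    n = eff.size
    return pd.Series({
        "n_segregating": n,
        "mean_freq_positive_seg": freq[pos].mean() if pos.any() else np.nan,
        "mean_freq_negative_seg": freq[neg].mean() if neg.any() else np.nan,
        "mean_effect_positive_seg": eff[pos].mean() if pos.any() else np.nan,
        "mean_effect_negative_seg": eff[neg].mean() if neg.any() else np.nan,
        "prop_negative_seg": neg.sum() / n if n else np.nan,
    })


def summary_row(result, classified_fixations: pd.DataFrame,
                sweep_stats: pd.Series) -> pd.Series:
    """One row of the per-replicate summary table: input parameters followed
    by the adaptation, fixation, sweep and segregating-site statistics."""
    params = result.params
    demography = result.demography
    n_anc = demography.n_anc
    tto = time_to_optimum(result.trajectory, params.z_opt_new, n_anc)
    rate = (adaptation_rate(result.trajectory, result.v_g0, params.z_opt_new)
            if result.v_g0 > 0 else np.nan)
    row = pd.Series({
        "sigma_m": params.sigma_m,
        "v_s": params.v_s,
        "psi": params.psi,
        "bottleneck_fraction": demography.bottleneck_fraction,
        "final_multiple": demography.final_multiple,
        "v_g0": result.v_g0,
        "time_to_optimum": tto,
        "reached_optimum": float(result.reached_optimum),
        "adaptation_rate": rate,
        "v_g_final": float(result.trajectory["var_g"].iloc[-1]),
    })
    row = pd.concat([row, fixation_stats(classified_fixations).drop("n_fixations"),
                     sweep_stats, segregating_stats(result.segregating)])
    return row
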