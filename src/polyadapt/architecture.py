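"""Genetic-architecture matrices: the joint distribution of allele frequency
and effect size among segregating sites in the final generation.

Sites are cross-tabulated into 7 fixed allele-frequency bins
(0-1e-4, 1e-4-1e-3, 1e-3-1e-2, 1e-2-0.1, 0.1-0.5, 0.5-0.9, 0.9-1) and 9
effect-size quantile bins (a central bin spanning zero, four negative
quantile bins to its left, four positive to its right).  Entries are relative
occurrence frequencies summing to 1, which makes matrices comparable across
scenarios with very different absolute effect scales.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FREQUENCY_BIN_EDGES",
    "N_FREQ_BINS",
    "N_EFFECT_BINS",
    "effect_bin_edges",
    "build_architecture_matrix",
    "mean_matrix",
    "matrix_correlation",
    "pairwise_correlations",
]

FREQUENCY_BIN_EDGES = np.array([0.0, 1e-4, 1e-3, 1e-2, 0.1, 0.5, 0.9, 1.0])
N_FREQ_BINS = 7
N_EFFECT_BINS = 9


def effect_bin_edges(effects, central_quantile: float = 0.25) -> np.ndarray:
    """Eight interior effect-size bin edges, symmetric in construction.

    The central bin is ``(-q, +q)`` with ``q`` the ``central_quantile``-th
    quantile of the absolute effects (so by default the central bin holds the
    smallest quarter of effects in magnitude).  The remaining negative and
    positive effects are each split into four equal-count quantile bins.
    Edges scale linearly with the effects (quantile equivariance), so
    matrices built from them are comparable across effect-size scales.
    """
    a = np.asarray(effects, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no effects supplied")
    q = float(np.quantile(np.abs(a), central_quantile))
    neg = a[a <= -q]
    pos = a[a >= q]
    if neg.size == 0 or pos.size == 0:
        raise ValueError("degenerate effect distribution: need mass on both sides "
                         "of the central bin")
    inner = [0.25, 0.5, 0.75]
    edges = np.concatenate([
        np.quantile(neg, inner),
        [-q, q],
        np.quantile(pos, inner),
    ])
    if not np.all(np.diff(edges) > 0):
        raise ValueError("degenerate effect-size bins: fewer than 9 distinct "
                         "effect values")
    return edges


def _freq_bin(frequencies: np.ndarray) -> np.ndarray:
    # half-open [lo, hi); the final bin [0.9, 1] is closed but sites at
    # exactly 0 or 1 are not segregating and never reach here
    return np.searchsorted(FREQUENCY_BIN_EDGES[1:-1], frequencies, side="right")


def _effect_bin(effects: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, effects, side="right")


def build_architecture_matrix(segregating: pd.DataFrame,
                              edges: np.ndarray) -> np.ndarray:
    """7 x 9 relative-occurrence matrix of one final-generation snapshot.

    ``segregating`` needs ``frequency`` and ``effect`` columns; ``edges`` are
    the 8 interior effect-size edges from :func:`effect_bin_edges`.  The
    matrix sums to exactly 1 when any site exists, and is all zeros (flagged
    by the caller via its sum) for an empty snapshot.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size != N_EFFECT_BINS - 1 or not np.all(np.diff(edges) > 0):
        raise ValueError("need 8 strictly increasing interior effect edges")
    matrix = np.zeros((N_FREQ_BINS, N_EFFECT_BINS))
    if len(segregating) == 0:
        return matrix
    freq = segregating["frequency"].to_numpy(dtype=float)
    eff = segregating["effect"].to_numpy(dtype=float)
    if np.any((freq <= 0) | (freq >= 1)):
        raise ValueError("frequencies must be strictly inside (0, 1)")
    rows = _freq_bin(freq)
    cols = _effect_bin(eff, edges)
    np.add.at(matrix, (rows, cols), 1.0)
    return matrix / len(segregating)


def mean_matrix(matrices) -> np.ndarray:
    """Replicate aggregation: mean of per-replicate matrices, renormalized."""
    stack = np.stack([np.asarray(m, dtype=float) for m in matrices])
    mean = stack.mean(axis=0)
    total = mean.sum()
    return mean / total if total > 0 else mean


def matrix_correlation(a, b) -> float:
    """Pearson correlation of the flattened 63 cells of two matrices.

    Returns NaN (missing) when either matrix has zero variance across cells.
    """
    x = np.asarray(a, dtype=float).ravel()
    y = np.asarray(b, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("matrices must have the same shape")
    if np.ptp(x) == 0 or np.ptp(y) == 0:  # constant matrix: r undefined
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def pairwise_correlations(matrices: dict) -> pd.DataFrame:
    """Symmetric table of pairwise architecture correlations with unit
    diagonal, keyed by scenario name."""
    names = list(matrices)
    if len(names) < 2:
        raise ValueError("need at least two matrices")
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for nj in names[i + 1:]:
            r = matrix_correlation(matrices[ni], matrices[nj])
            table.loc[ni, nj] = table.loc[nj, ni] = r
    return table


def matrix_to_frame(matrix: np.ndarray, edges: np.ndarray) -> pd.DataFrame:
    """Long-format (63-row) labeled view of one architecture matrix."""
    freq_labels = [f"[{lo:g},{hi:g})" for lo, hi in
                   zip(FREQUENCY_BIN_EDGES[:-1], FREQUENCY_BIN_EDGES[1:])]
    eff_edges = np.concatenate([[-np.inf], edges, [np.inf]])
    eff_labels = [f"[{lo:.4g},{hi:.4g})" for lo, hi in
                  zip(eff_edges[:-1], eff_edges[1:])]
    rows = []
    for i, fl in enumerate(freq_labels):
        for j, el in enumerate(eff_labels):
            rows.append((fl, el, matrix[i, j]))
    return pd.DataFrame(rows, columns=["frequency_bin", "effect_bin", "value"])
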