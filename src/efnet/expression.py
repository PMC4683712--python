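"""Count normalisation and expression filters for network analysis.

Matrices are pandas DataFrames with genes as rows and samples as
columns. Filters return boolean gene masks (pure functions of the
matrix) so callers can log which rule removed which gene.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_cpm",
    "filter_min_cpm",
    "compute_fpkm",
    "qc_filter_for_network",
    "connectivity_scores",
    "select_top_connected",
]


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count / library_total * 1e6`` per sample."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts / totals * 1e6


def filter_min_cpm(
    cpm: pd.DataFrame, min_cpm: float = 1.0, min_samples: int | None = None
) -> pd.Series:
    """Keep a gene iff it has >= ``min_cpm`` in >= ``min_samples`` samples.

    ``min_samples`` defaults to half the samples, rounded up.
    """
    n = cpm.shape[1]
    if min_samples is None:
        min_samples = math.ceil(n / 2)
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds {n} samples")
    return (cpm >= min_cpm).sum(axis=1) >= min_samples


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    quartile_normalize: bool = True,
    quartile: float = 0.75,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads, quartile normalised.

    Raw FPKM is ``count / (length_kb * library_millions)``. With
    ``quartile_normalize`` each sample is then rescaled so that its
    ``quartile`` (default upper-quartile, 75th percentile) of non-zero
    FPKM equals the across-sample mean of those quantiles — the standard
    upper-quartile scheme, which makes the result invariant to uniform
    per-sample depth scaling.
    """
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {list(missing)[:5]}")
    lengths = gene_lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("non-positive gene length")
    lib_millions = counts.sum(axis=0) / 1e6
    if (lib_millions <= 0).any():
        raise ValueError("zero library size")
    fpkm = counts.div(lengths / 1e3, axis=0).div(lib_millions, axis=1)
    if not quartile_normalize:
        return fpkm
    quants = fpkm.apply(lambda col: col[col > 0].quantile(quartile), axis=0)
    if quants.isna().any() or (quants <= 0).any():
        raise ValueError("cannot quartile-normalise: a sample has no non-zero FPKM")
    return fpkm / quants * quants.mean()


def qc_filter_for_network(
    expr: pd.DataFrame,
    max_zero_samples: int = 7,
    mean_min: float = 0.5,
    sd_min: float = 0.2,
    qc_direction: str = "rationale",
) -> pd.Series:
    """Quality-control mask for co-expression input (True = keep).

    A gene is dropped when it has more than ``max_zero_samples`` samples
    with no signal, or fails the mean/SD rule. ``qc_direction`` controls
    that rule:

    * ``"rationale"`` (default): drop genes with mean < ``mean_min`` OR
      SD < ``sd_min`` — low-count genes are unreliable and near-constant
      genes carry no co-expression information.
    * ``"literal"``: drop genes with mean > ``mean_min`` AND
      SD > ``sd_min`` (the inverted reading; kept as a switch for
      comparability, it removes exactly the informative genes).
    """
    zeros = (expr == 0).sum(axis=1)
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    if qc_direction == "rationale":
        drop = (zeros > max_zero_samples) | (mean < mean_min) | (sd < sd_min)
    elif qc_direction == "literal":
        drop = (zeros > max_zero_samples) | ((mean > mean_min) & (sd > sd_min))
    else:
        raise ValueError("qc_direction must be 'rationale' or 'literal'")
    return ~drop


def connectivity_scores(
    expr: pd.DataFrame, beta: float = 1.0, absolute: bool = True
) -> pd.Series:
    """Per-gene connectivity ``K_i = sum_{j != i} |cor(i, j)|**beta``."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"zero-variance genes: {bad[:5]}")
    cor = np.corrcoef(X)
    if absolute:
        cor = np.abs(cor)
    np.fill_diagonal(cor, 0.0)
    return pd.Series((cor**beta).sum(axis=1), index=expr.index, name="K")


def select_top_connected(expr: pd.DataFrame, n_keep: int = 3500) -> pd.Index:
    """Indices of the ``n_keep`` most connected genes (ties: ascending id).

    If fewer genes than ``n_keep`` are available, all are kept with a
    warning.
    """
    if len(expr) <= n_keep:
        if len(expr) < n_keep:
            warnings.warn(
                f"only {len(expr)} genes available; keeping all "
                f"(requested top {n_keep})",
                stacklevel=2,
            )
        return expr.index
    k = connectivity_scores(expr)
    order = np.lexsort((expr.index, -k.to_numpy()))
    keep = expr.index[order[:n_keep]]
    return expr.index[expr.index.isin(keep)]  # preserve original row order
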