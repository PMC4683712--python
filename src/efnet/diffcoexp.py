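"""Differential co-expression between efficiency groups (KDiff).

For each group a sub-network is built from that group's samples only:
``K_i = sum_{j != i} |cor_ij| ** beta``, with group-specific soft
thresholds (defaults: beta = 20 for the LFE sub-network, beta = 4 for
HFE). Connectivities are normalised by the maximum within each
sub-network and the differential connectivity is

    kdiff_i = K_LFE_norm(i) - K_HFE_norm(i)        in [-1, 1]

Genes with ``kdiff > threshold`` are called LFE-connected, genes with
``kdiff < -threshold`` HFE-connected (strict inequalities).

Note the asymmetric default powers make the statistic asymmetric under
the null: with few samples per group the milder power inflates every
null connectivity in that sub-network, which biases kdiff negative. This
is inherent to the statistic with these defaults and is logged
prominently by the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import connectivity_scores

HFE_CONNECTED = "HFE-connected"
LFE_CONNECTED = "LFE-connected"
NO_FLAG = "none"

__all__ = [
    "group_connectivity",
    "normalize_connectivity",
    "kdiff_table",
    "select_differentially_connected",
]


def group_connectivity(expr_group: pd.DataFrame, beta: float) -> pd.Series:
    """Raw whole-network connectivity within one group's samples."""
    return connectivity_scores(expr_group, beta=beta, absolute=True)


def normalize_connectivity(k: pd.Series) -> pd.Series:
    """Divide every connectivity by the sub-network maximum."""
    kmax = float(k.max())
    if kmax <= 0:
        raise ValueError("all-zero connectivity vector cannot be normalised")
    return k / kmax


def kdiff_table(
    expr: pd.DataFrame,
    groups: pd.Series,
    beta_hfe: float = 4.0,
    beta_lfe: float = 20.0,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Per-gene differential connectivity between the LFE and HFE groups.

    ``groups`` maps sample id -> "HFE"/"LFE". Both groups need >= 3
    samples; the same gene set feeds both sub-networks.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    groups = groups.reindex(expr.columns)
    if groups.isna().any():
        bad = list(expr.columns[groups.isna()])
        raise ValueError(f"missing group label for samples: {bad[:5]}")
    cols_hfe = expr.columns[groups == "HFE"]
    cols_lfe = expr.columns[groups == "LFE"]
    if len(cols_hfe) < 3 or len(cols_lfe) < 3:
        raise ValueError("each group needs at least 3 samples")
    k_hfe = group_connectivity(expr[cols_hfe], beta_hfe)
    k_lfe = group_connectivity(expr[cols_lfe], beta_lfe)
    kn_hfe = normalize_connectivity(k_hfe)
    kn_lfe = normalize_connectivity(k_lfe)
    kdiff = kn_lfe - kn_hfe
    flag = pd.Series(NO_FLAG, index=expr.index, name="flag")
    flag[kdiff > threshold] = LFE_CONNECTED
    flag[kdiff < -threshold] = HFE_CONNECTED
    return pd.DataFrame(
        {
            "k_hfe": k_hfe,
            "k_lfe": k_lfe,
            "k_hfe_norm": kn_hfe,
            "k_lfe_norm": kn_lfe,
            "kdiff": kdiff,
            "flag": flag,
        }
    )


def select_differentially_connected(
    table: pd.DataFrame, threshold: float = 0.6
) -> tuple[list, list]:
    """(HFE-connected, LFE-connected) gene lists at ``|kdiff| > threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    kd = table["kdiff"]
    hfe = list(table.index[kd < -threshold])
    lfe = list(table.index[kd > threshold])
    return hfe, lfe
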