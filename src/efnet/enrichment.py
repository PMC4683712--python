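"""Over-representation analysis against a flat gene -> term annotation.

For each term the upper-tail hypergeometric probability of observing at
least the seen number of study hits is computed, then corrected across
terms with the Benjamini-Hochberg step-up FDR procedure. The annotation
is taken as-is: no ontology graph propagation is performed, so parent
terms are enriched only through their own direct annotations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeometric_p", "bh_adjust", "enrich"]


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N} "
            "(need 0 <= k <= min(n, K) and n, K <= N)"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study_genes,
    background_genes,
    annotation: pd.DataFrame,
    padj_cut: float = 0.1,
    min_hits: int = 1,
) -> pd.DataFrame:
    """Term over-representation of ``study_genes`` within ``background_genes``.

    Parameters
    ----------
    annotation
        Two columns ``gene_id``, ``term_id`` (extra columns ignored,
        except an optional ``term_name`` carried through). Rows whose
        gene is outside the background are dropped.
    min_hits
        Terms with fewer study hits are excluded from testing (and from
        the multiple-testing burden). Set to 0 to report every term.

    Returns
    -------
    One row per tested term, sorted by p ascending (ties by term id),
    with study hit count ``k``, study size ``n``, term background size
    ``K``, background size ``N``, ``p``, ``padj`` and ``significant``.
    """
    background = pd.Index(pd.unique(pd.Series(list(background_genes))))
    study = pd.Series(list(study_genes))
    if study.duplicated().any():
        warnings.warn("duplicate gene ids in study set; deduplicating", stacklevel=2)
        study = study.drop_duplicates()
    study = pd.Index(study)
    if len(study) == 0:
        raise ValueError("empty study set")
    outside = study.difference(background)
    if len(outside):
        raise ValueError(
            f"study genes outside the background universe: {list(outside)[:5]}"
        )
    if not {"gene_id", "term_id"}.issubset(annotation.columns):
        raise ValueError("annotation needs columns ['gene_id', 'term_id']")
    ann = annotation.loc[annotation["gene_id"].isin(background)].drop_duplicates(
        subset=["gene_id", "term_id"]
    )
    names = (
        ann.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in ann.columns
        else None
    )
    N = len(background)
    n = len(study)
    study_set = set(study)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        K = genes.nunique()
        k = sum(g in study_set for g in genes.unique())
        if k < min_hits:
            continue
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeometric_p(k, n, K, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p"]
    )
    if len(result):
        result["padj"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["padj"] <= padj_cut
        if names is not None:
            result.insert(1, "term_name", result["term_id"].map(names))
        result = result.sort_values(
            ["p", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        result["padj"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
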