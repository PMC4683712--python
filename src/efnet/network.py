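"""Weighted co-expression network: adjacency, TOM, modules, eigengenes.

The network is *unsigned*: adjacency is ``|Pearson correlation| ** beta``.
The soft-threshold power beta is chosen by the scale-free topology
criterion (smallest candidate whose connectivity distribution fits a
power law with R^2 above the cut). Modules are branches of the
average-linkage dendrogram of ``1 - TOM``, obtained with a simplified
dynamic cut: an eager top-down walk of the tree followed by an
eigengene-correlation merge and a kME reassignment stage. Modules are
named by
colors assigned in decreasing size order from a fixed palette; ``grey``
is reserved for unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

GREY = "grey"

# WGCNA-style ordered palette; assigned by decreasing module size.
COLOR_PALETTE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

__all__ = [
    "GREY",
    "COLOR_PALETTE",
    "SoftThresholdScan",
    "correlation_matrix",
    "scale_free_r2",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "cluster_modules",
    "detect_modules",
    "module_eigengenes",
    "module_trait_correlation",
    "select_trait_modules",
    "module_membership",
    "filter_by_membership",
]


@dataclass
class SoftThresholdScan:
    """Result of the scale-free soft-threshold scan."""

    table: pd.DataFrame  # columns: beta, r_squared, mean_k
    chosen_beta: int
    r2_cut: float
    satisfied: bool  # True if chosen beta met the R^2 cut


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation between all genes (unit diagonal)."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expr.to_numpy(float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[sd == 0])
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    cor = np.corrcoef(X)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log fit of connectivity frequency vs mean bin K.

    Connectivities are binned into ``n_bins`` equal-width bins;
    ``log10(frequency)`` is regressed on ``log10(mean K)`` over the
    non-empty bins with positive mean. NaN when the fit is degenerate
    (fewer than 3 usable bins or zero variance).
    """
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3 or np.std(xs) == 0 or np.std(ys) == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    # signed fit index: a scale-free degree distribution has a *negative*
    # log-log slope; a positive-slope fit must not count as a good fit
    return float(-np.sign(r) * r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates=range(1, 21),
    r2_cut: float = 0.9,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers; choose the smallest meeting the R^2 cut.

    If no candidate reaches the cut, the argmax-R^2 candidate is chosen
    with a warning. Candidates with degenerate (NaN) fits are skipped
    unless the candidate list is a singleton, in which case that beta is
    forced.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    cor = np.abs(correlation_matrix(expr).to_numpy())
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in candidates:
        k = (cor**beta).sum(axis=1)
        rows.append(
            {"beta": beta, "r_squared": scale_free_r2(k, n_bins), "mean_k": k.mean()}
        )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["r_squared"])
    passing = ok.loc[ok["r_squared"] >= r2_cut]
    if len(candidates) == 1:
        chosen = candidates[0]
        satisfied = bool(len(passing)) and chosen in passing["beta"].tolist()
        if not satisfied:
            warnings.warn(
                f"forced beta={chosen}: scale-free R^2 below cut "
                f"{r2_cut} (or undefined)",
                stacklevel=2,
            )
    elif len(passing):
        chosen = int(passing["beta"].iloc[0])
        satisfied = True
    else:
        if ok.empty:
            raise ValueError("scale-free fit undefined for every candidate beta")
        chosen = int(ok.loc[ok["r_squared"].idxmax(), "beta"])
        satisfied = False
        warnings.warn(
            f"no candidate reached R^2 >= {r2_cut}; using argmax beta={chosen}",
            stacklevel=2,
        )
    return SoftThresholdScan(
        table=table, chosen_beta=int(chosen), r2_cut=r2_cut, satisfied=satisfied
    )


def adjacency(cor: pd.DataFrame, beta: float, mode: str = "unsigned") -> pd.DataFrame:
    """Unsigned adjacency ``a_ij = |cor_ij| ** beta`` with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if mode != "unsigned":
        raise ValueError("only the unsigned network mode is supported")
    a = np.abs(cor.to_numpy(float)) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` for ``i != j``
    with ``L_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1 by convention. Values lie in [0, 1]: 1 means the two
    genes share all neighbors, 0 that they share none.
    """
    A = adj.to_numpy(float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A  # diag of A is 0, so u = i, j terms vanish
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _walk_tree(
    node,
    min_size: int,
    modules: list[np.ndarray],
    grey: list[int],
) -> None:
    """Top-down descent of the dendrogram (simplified dynamic cut).

    The tree is cut eagerly: while both children of a branch can still
    hold a module (>= ``min_size``) the descent continues; a branch whose
    children are both too small is appended as a candidate module; a
    too-small child is set aside as stragglers (rescued later by module
    membership) while the descent continues into the main branch.
    Over-splitting is deliberate — the eigengene-merge and kME
    reassignment stages of ``detect_modules`` consolidate fragments that
    belong to the same expression programme.
    """
    ids = np.array(node.pre_order(lambda x: x.id))
    if len(ids) < min_size or node.is_leaf():
        grey.extend(ids.tolist())
        return
    left, right = node.get_left(), node.get_right()
    la = np.array(left.pre_order(lambda x: x.id))
    lb = np.array(right.pre_order(lambda x: x.id))
    if max(len(la), len(lb)) < min_size:
        # neither child can stand alone: this branch is one candidate module
        modules.append(ids)
        return
    if min(len(la), len(lb)) < min_size:
        small_ids, big_node = (la, right) if len(la) < len(lb) else (lb, left)
        grey.extend(small_ids.tolist())
        _walk_tree(big_node, min_size, modules, grey)
        return
    _walk_tree(left, min_size, modules, grey)
    _walk_tree(right, min_size, modules, grey)


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
) -> pd.Series:
    """Cut the average-linkage TOM dendrogram into candidate modules.

    Dissimilarity is ``1 - TOM``. Because the merge heights of TOM
    dendrograms form a near-continuum, no single-height cut separates
    branches reliably; instead the tree is walked top-down and cut
    eagerly (see ``_walk_tree``). Genes in branches below
    ``min_module_size`` are assigned to ``grey``. Modules get color names
    by decreasing size (ties: the module whose first gene comes earlier
    in the input order). For the full detection pipeline, including
    eigengene merging and kME reassignment, use ``detect_modules``.
    """
    genes = tom.index
    n = len(genes)
    labels = pd.Series(GREY, index=genes, name="module")
    if n < min_module_size:
        warnings.warn(
            f"only {n} genes (< min_module_size={min_module_size}); "
            "all genes assigned to grey",
            stacklevel=2,
        )
        return labels
    diss = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(np.clip(diss, 0, None), checks=False), method="average")
    clusters: list[np.ndarray] = []
    grey_ids: list[int] = []
    _walk_tree(to_tree(Z), min_module_size, clusters, grey_ids)
    kept = [c for c in clusters if len(c) >= min_module_size]
    # decreasing size, earliest-gene tie break
    kept.sort(key=lambda c: (-len(c), int(c.min())))
    for rank, members in enumerate(kept):
        if rank < len(COLOR_PALETTE):
            name = COLOR_PALETTE[rank]
        else:
            name = f"module{rank + 1}"
        labels.iloc[members] = name
    return labels


def detect_modules(
    expr: pd.DataFrame,
    tom: pd.DataFrame,
    min_module_size: int = 30,
    merge_cor: float = 0.75,
    min_kme: float = 0.5,
) -> pd.Series:
    """Full module detection: tree cut, eigengene merge, kME reassignment.

    1. ``cluster_modules`` cuts the TOM dendrogram (deliberately eagerly;
       the following steps repair over-splitting).
    2. Modules whose eigengenes correlate above ``merge_cor`` are merged
       (they represent the same underlying expression programme).
    3. Every gene is reassigned to the module with its largest absolute
       module membership when ``|kME| > min_kme``, otherwise grey. This
       recovers peripheral members set aside by the cut.

    Modules below ``min_module_size`` after reassignment are dissolved to
    grey; color names are reassigned by decreasing final size.
    """
    labels = cluster_modules(tom, min_module_size)
    if (labels == GREY).all():
        return labels
    # iterative eigengene merge
    while True:
        mods = [m for m in labels.unique() if m != GREY]
        if len(mods) < 2:
            break
        me = module_eigengenes(expr, labels)
        cor = me.corr().abs()
        np.fill_diagonal(cor.values, 0.0)
        i, j = np.unravel_index(np.argmax(cor.values), cor.shape)
        if cor.values[i, j] <= merge_cor:
            break
        keep, absorb = cor.index[i], cor.columns[j]
        labels = labels.replace(absorb, keep)
    # kME reassignment
    me = module_eigengenes(expr, labels)
    kme = module_membership(expr, me)
    best = kme.abs().idxmax(axis=1)
    best_val = kme.abs().max(axis=1)
    labels = pd.Series(
        np.where(best_val > min_kme, best, GREY), index=labels.index, name="module"
    )
    sizes = labels.value_counts()
    for m in sizes.index:
        if m != GREY and sizes[m] < min_module_size:
            labels[labels == m] = GREY
    # stable color names by decreasing final size
    mods = [m for m in labels.unique() if m != GREY]
    order = sorted(
        mods,
        key=lambda m: (-int((labels == m).sum()), int(np.argmax(labels.values == m))),
    )
    rename = {
        m: (COLOR_PALETTE[r] if r < len(COLOR_PALETTE) else f"module{r + 1}")
        for r, m in enumerate(order)
    }
    return labels.map(lambda m: rename.get(m, GREY))


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardised expression.

    Member genes are standardised (zero mean, unit SD across samples);
    the eigengene is the unit-norm first left singular vector of the
    sample x gene submatrix, oriented so that its correlation with the
    module's mean standardised profile is non-negative.
    """
    labels = labels.reindex(expr.index)
    modules = [m for m in labels.unique() if m != GREY]
    samples = expr.columns
    cols = {}
    for m in sorted(modules):
        members = labels.index[labels == m]
        if len(members) < 2:
            raise ValueError(f"module '{m}' has fewer than 2 genes")
        X = expr.loc[members].to_numpy(float)  # genes x samples
        sd = X.std(axis=1, ddof=1)
        if (sd == 0).any():
            bad = list(members[sd == 0])
            raise ValueError(f"zero-variance gene(s) in module '{m}': {bad[:5]}")
        Xs = ((X.T - X.mean(axis=1)) / sd).T
        u, s, vt = np.linalg.svd(Xs.T, full_matrices=False)  # samples x genes
        me = u[:, 0]
        mean_profile = Xs.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        cols[m] = me
    return pd.DataFrame(cols, index=samples)


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and two-sided t-distribution p) of each ME with each trait."""
    if len(eigengenes) < 3:
        raise ValueError("need at least 3 samples")
    common = eigengenes.index.intersection(traits.index)
    if len(common) < len(eigengenes):
        raise ValueError("traits not aligned with eigengene samples")
    rows = []
    for m in eigengenes.columns:
        for t in traits.columns:
            r, p = stats.pearsonr(
                eigengenes.loc[common, m], traits.loc[common, t]
            )
            rows.append({"module": m, "trait": t, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def select_trait_modules(
    table: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 0.1,
    traits: tuple[str, ...] = ("rfi", "rig"),
) -> pd.DataFrame:
    """Modules with ``|r| > r_threshold`` (strict) and ``p <= p_threshold``.

    A module qualifies if the gate passes for any of the listed traits.
    Returns one row per selected module with its sign pattern across the
    gating traits (e.g. ``rfi+/rig-``).
    """
    sub = table.loc[table["trait"].isin(traits)]
    hit = sub.loc[(sub["r"].abs() > r_threshold) & (sub["p"] <= p_threshold)]
    out = []
    for m in sub["module"].unique():
        if m not in set(hit["module"]):
            continue
        rows = sub.loc[sub["module"] == m]
        pattern = "/".join(
            f"{t}{'+' if float(rows.loc[rows['trait'] == t, 'r'].iloc[0]) >= 0 else '-'}"
            for t in traits
            if t in set(rows["trait"])
        )
        out.append({"module": m, "sign_pattern": pattern})
    return pd.DataFrame(out, columns=["module", "sign_pattern"])


def module_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME matrix: correlation of every gene with every module eigengene."""
    X = expr.to_numpy(float)
    Xs = X - X.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xs, axis=1)
    if (xn == 0).any():
        raise ValueError("zero-variance gene in expression matrix")
    E = eigengenes.to_numpy(float)
    Es = E - E.mean(axis=0, keepdims=True)
    en = np.linalg.norm(Es, axis=0)
    kme = (Xs @ Es) / np.outer(xn, en)
    return pd.DataFrame(kme, index=expr.index, columns=eigengenes.columns)


def filter_by_membership(
    kme: pd.DataFrame,
    labels: pd.Series,
    own_min: float = 0.6,
    other_max: float = 0.6,
) -> dict[str, list]:
    """Per-module gene lists after the module-membership filter.

    A gene is retained for its own module iff ``|kME_own| > own_min`` and
    the largest ``|kME|`` with any other module is ``< other_max``
    (absolute values; both inequalities strict).
    """
    labels = labels.reindex(kme.index)
    out: dict[str, list] = {}
    for m in kme.columns:
        members = labels.index[labels == m]
        keep = []
        for g in members:
            own = abs(kme.at[g, m])
            others = kme.loc[g].drop(m).abs()
            other = float(others.max()) if len(others) else 0.0
            if own > own_min and other < other_max:
                keep.append(g)
        out[m] = keep
    return out
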