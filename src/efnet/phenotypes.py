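"""Feed-efficiency traits from feed-trial records.

The traits follow the standard residual-trait definitions used in beef
cattle feed trials:

* **ADG** (average daily gain, kg/d): per-animal ordinary least-squares
  slope of body weight on feeding day.
* **MBW^0.75** (metabolic weight, kg^0.75): mean body weight over all
  weighings, raised to the 0.75 power.
* **RFI** (residual feed intake, kg/d): residual of
  ``DMI ~ 1 + ADG + MBW^0.75``; lower is more efficient.
* **RWG** (residual body weight gain, kg/d): residual of
  ``ADG ~ 1 + DMI + MBW^0.75``; higher is more efficient.
* **RIG**: ``RWG - RFI``; the trait used to split animals into high
  (HFE) and low (LFE) feed-efficiency groups.
* **FCR**: ``DMI / ADG`` per animal.

All regressions are fit on the post-exclusion cohort: animals whose ADG
lies more than ``k`` standard deviations from the mean are flagged as
excluded before the residual traits are computed, so the residuals are
defined with respect to the cleaned cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

HFE = "HFE"
LFE = "LFE"
UNASSIGNED = "unassigned"

__all__ = [
    "RegressionFit",
    "GroupComparison",
    "compute_adg",
    "compute_mbw075",
    "build_phenotype_table",
    "remove_adg_outliers",
    "compute_residual_traits",
    "select_extreme_groups",
    "compare_groups",
]


@dataclass
class RegressionFit:
    """Ordinary least-squares fit summary for a residual-trait regression."""

    coefficients: pd.Series
    residuals: pd.Series
    r_squared: float
    n: int


@dataclass
class GroupComparison:
    """Two-group comparison routed through a Shapiro-Wilk normality check."""

    test: str  # "t" or "mannwhitney"
    statistic: float
    pvalue: float
    shapiro_pvalues: tuple[float, float]
    route_reason: str
    group_labels: tuple[str, str] = field(default=("A", "B"))


def compute_adg(days, weights) -> float:
    """OLS slope of body weight (kg) on feeding day.

    Requires at least two distinct weigh days; a single day leaves the
    slope undefined.
    """
    days = np.asarray(days, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if days.shape != weights.shape:
        raise ValueError("days and weights must have the same length")
    if np.unique(days).size < 2:
        raise ValueError("ADG slope undefined: need at least 2 distinct weigh days")
    d = days - days.mean()
    return float(d @ (weights - weights.mean()) / (d @ d))


def compute_mbw075(weights) -> float:
    """Metabolic weight: (mean body weight over weighings) ** 0.75."""
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("empty body-weight series")
    if np.any(weights <= 0):
        raise ValueError("non-positive body weight in series")
    return float(np.mean(weights) ** 0.75)


def build_phenotype_table(bw: pd.DataFrame, dmi: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-animal phenotype table from long-format records.

    Parameters
    ----------
    bw
        Long format with columns ``animal_id``, ``day``, ``bw_kg``.
    dmi
        Columns ``animal_id``, ``dmi_kg_d`` (trial mean daily dry-matter
        intake).

    Returns
    -------
    DataFrame indexed by ``animal_id`` with columns ``adg``, ``mbw075``,
    ``dmi``, ``excluded`` (False) and ``exclusion_reason`` (empty).
    """
    required = {"animal_id", "day", "bw_kg"}
    if not required.issubset(bw.columns):
        raise ValueError(f"body-weight table must have columns {sorted(required)}")
    if not {"animal_id", "dmi_kg_d"}.issubset(dmi.columns):
        raise ValueError("intake table must have columns ['animal_id', 'dmi_kg_d']")

    rows = {}
    for animal, grp in bw.groupby("animal_id", sort=True):
        rows[animal] = {
            "adg": compute_adg(grp["day"], grp["bw_kg"]),
            "mbw075": compute_mbw075(grp["bw_kg"]),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "animal_id"
    dmi_s = dmi.set_index("animal_id")["dmi_kg_d"]
    missing = table.index.difference(dmi_s.index)
    if len(missing):
        raise ValueError(f"missing intake for animals: {list(missing)[:5]}")
    table["dmi"] = dmi_s.reindex(table.index).astype(float)
    table["excluded"] = False
    table["exclusion_reason"] = ""
    return table


def remove_adg_outliers(table: pd.DataFrame, k: float = 2.5) -> pd.DataFrame:
    """Flag animals whose ADG deviates more than ``k`` SD from the mean.

    With zero ADG spread no animal is excluded (the z-score is undefined,
    so there is nothing to trim). Returns a copy; the ``excluded`` column
    is set and residual traits must be (re)computed afterwards.
    """
    out = table.copy()
    adg = out["adg"].to_numpy(dtype=float)
    sd = adg.std(ddof=1) if len(adg) > 1 else 0.0
    if sd == 0:
        return out
    z = np.abs(adg - adg.mean()) / sd
    mask = z > k
    out.loc[mask, "excluded"] = True
    out.loc[mask, "exclusion_reason"] = f"|ADG z-score| > {k}"
    return out


def _ols(y: pd.Series, X: pd.DataFrame, yname: str) -> RegressionFit:
    names = ["intercept"] + list(X.columns)
    A = np.column_stack([np.ones(len(X))] + [X[c].to_numpy(float) for c in X.columns])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # name the offending column: a regressor with no variance, or one
        # collinear with the rest of the design
        for j, c in enumerate(X.columns, start=1):
            rest = np.delete(A, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(A):
                raise np.linalg.LinAlgError(
                    f"rank-deficient design for {yname}: column '{c}' is "
                    "constant or collinear with the other regressors"
                )
        raise np.linalg.LinAlgError(f"rank-deficient design for {yname}")
    yv = y.to_numpy(float)
    beta, *_ = np.linalg.lstsq(A, yv, rcond=None)
    resid = yv - A @ beta
    tss = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else np.nan
    return RegressionFit(
        coefficients=pd.Series(beta, index=names, name=yname),
        residuals=pd.Series(resid, index=y.index, name=f"resid_{yname}"),
        r_squared=r2,
        n=len(y),
    )


def compute_residual_traits(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, RegressionFit, RegressionFit]:
    """Fit the two residual-trait regressions and derive RFI/RWG/RIG/FCR.

    Only non-excluded animals enter the fits; excluded animals get NaN
    traits. Returns the augmented table plus both fits (intake model
    first, gain model second).
    """
    inc = table.loc[~table["excluded"]]
    if len(inc) < 4:
        raise ValueError("need at least 4 included animals to fit 3-parameter models")
    fit_dmi = _ols(inc["dmi"], inc[["adg", "mbw075"]], "dmi")
    fit_adg = _ols(inc["adg"], inc[["dmi", "mbw075"]], "adg")
    out = table.copy()
    out["rfi"] = fit_dmi.residuals.reindex(out.index)
    out["rwg"] = fit_adg.residuals.reindex(out.index)
    out["rig"] = out["rwg"] - out["rfi"]
    out["fcr"] = out["dmi"] / out["adg"]
    return out, fit_dmi, fit_adg


def select_extreme_groups(table: pd.DataFrame, n_per_group: int) -> pd.DataFrame:
    """Assign the top/bottom ``n_per_group`` animals by RIG to HFE/LFE.

    Ties at the group boundary are broken by ascending animal id (the
    lower id is selected). Excluded animals never enter a group.
    """
    out = table.copy()
    out["group"] = UNASSIGNED
    inc = out.loc[~out["excluded"]].dropna(subset=["rig"])
    if 2 * n_per_group > len(inc):
        raise ValueError(
            f"cannot select 2x{n_per_group} animals from {len(inc)} included"
        )
    # lowest RIG first, ascending id on ties
    by_rig = inc.iloc[np.lexsort((inc.index, inc["rig"].to_numpy()))]
    lfe_ids = by_rig.index[:n_per_group]
    hfe_pool = by_rig.index[n_per_group:]
    # highest RIG, lower id first on ties
    desc = inc.loc[hfe_pool]
    desc = desc.iloc[np.lexsort((desc.index, -desc["rig"].to_numpy()))]
    hfe_ids = desc.index[:n_per_group]
    out.loc[lfe_ids, "group"] = LFE
    out.loc[hfe_ids, "group"] = HFE
    return out


def compare_groups(
    values,
    labels,
    alpha_normality: float = 0.05,
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison: Shapiro-Wilk routes to t-test or Mann-Whitney.

    Both groups must have n >= 3. If both pass the Shapiro-Wilk normality
    check at ``alpha_normality`` a two-sided Student's t-test (pooled
    variance by default, Welch with ``welch=True``) is used; otherwise the
    Mann-Whitney-Wilcoxon test. A zero-variance group forces the
    Mann-Whitney route with a warning, since the t statistic is undefined.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if min(len(a), len(b)) < 3:
        raise ValueError("each group needs n >= 3")
    sp_a = float(stats.shapiro(a).pvalue)
    sp_b = float(stats.shapiro(b).pvalue)
    normal = sp_a > alpha_normality and sp_b > alpha_normality
    degenerate = a.std(ddof=1) == 0 or b.std(ddof=1) == 0
    if normal and degenerate:
        warnings.warn(
            "zero-variance group: falling back to Mann-Whitney", stacklevel=2
        )
    if normal and not degenerate:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test, reason = "t", "both groups passed Shapiro-Wilk"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitney"
        reason = (
            "zero-variance group"
            if degenerate and normal
            else "Shapiro-Wilk rejected normality"
        )
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        shapiro_pvalues=(sp_a, sp_b),
        route_reason=reason,
        group_labels=(str(uniq[0]), str(uniq[1])),
    )
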