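"""Synthetic feed-trial and expression data with planted ground truth.

Every generator is deterministic given its config seed; a single global
seed is expanded into independent per-component child streams so adding
one component never perturbs another.

Feed trial
----------
Animals are weighed on a fixed day grid; body weight grows linearly with
a per-animal average daily gain (ADG) plus weighing noise. Dry-matter
intake (DMI) follows the standard energy-demand regression
``DMI = b0 + b1 ADG + b2 MBW^0.75 + eps1`` and the planted residual pair
``(eps1, eps2) = (RFI, RWG)`` is drawn from a bivariate normal with
configurable SDs and correlation. The structural coefficients linking
ADG and DMI are derived from that residual structure (see
``docs/methods.md``) so that each planted residual is orthogonal to the
regressors of its own trait regression — this makes the planted pair
recoverable by downstream least squares up to the unavoidable
finite-sample projection loss.

Expression
----------
Counts are gamma-Poisson (negative binomial) draws around an
exponential-of-Gaussian mean. Module structure enters through one latent
factor per module and sample; member genes load on the factor with a
group-specific loading ``sqrt(w_g)`` so that member pairs have latent
correlation ``w_g`` within group ``g``. A trait-linked module's factor
is a noisy copy of the standardised RIG of the sampled animals.
Differentially expressed genes shift their LFE mean by a configured
log2 fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import phenotypes as ph

BACKGROUND = "background"

__all__ = [
    "TrialSimConfig",
    "ModuleSpec",
    "ExprSimConfig",
    "SyntheticTruth",
    "FeedTrialTables",
    "draw_residual_pairs",
    "simulate_feed_trial",
    "simulate_expression",
    "simulate_annotation",
]

# DMI response to ADG used only when the derived coefficient is undefined
# (rwg_sd = 0); kg DM per kg of daily gain.
FALLBACK_DMI_ADG_COEF = 1.5


@dataclass
class TrialSimConfig:
    """Feed-trial generator settings (defaults emulate a 98-steer trial).

    ``rfi_sd``/``rwg_sd``/``resid_cor`` define the joint distribution of
    the planted (intake, gain) residual pair in kg/d. ``adg_sd`` is the
    SD of the independent growth component on top of the planted gain
    residual. ``dmi_adg_coef=None`` derives the intake-on-gain
    coefficient from the residual structure (the choice that makes the
    planted residuals recoverable); setting it manually breaks exact
    recoverability and is intended for robustness experiments only.
    """

    n_animals: int = 98
    weigh_days: tuple[int, ...] = (0, 14, 28, 42, 56, 70)
    bw0_mean: float = 376.0
    bw0_sd: float = 29.0
    adg_mean: float = 1.85
    adg_sd: float = 0.15
    bw_noise_sd: float = 3.0
    dmi_intercept: float = -1.5
    dmi_adg_coef: float | None = None
    dmi_mbw_coef: float = 0.11
    rfi_sd: float = 0.90
    rwg_sd: float = 0.35
    resid_cor: float = -0.60
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals <= 0:
            raise ValueError("n_animals must be positive")
        days = tuple(self.weigh_days)
        if len(days) < 3:
            raise ValueError("need at least 3 weigh days for a robust slope")
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("weigh_days must be strictly increasing from 0")
        for name in ("bw0_sd", "adg_sd", "bw_noise_sd", "rfi_sd", "rwg_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.resid_cor) > 1:
            raise ValueError("|resid_cor| must be <= 1")


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``within_cor`` maps group name -> latent pairwise correlation of
    member genes within that group's samples. ``trait_assoc`` is the
    signed correlation between the module factor and standardised RIG.
    """

    size: int
    within_cor: dict = field(default_factory=lambda: {"HFE": 0.8, "LFE": 0.8})
    trait_assoc: float = 0.0

    def validate(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        for g, w in self.within_cor.items():
            if not 0 <= w <= 1:
                raise ValueError(f"within-correlation for {g} must lie in [0, 1]")
        if abs(self.trait_assoc) > 1:
            raise ValueError("|trait_assoc| must be <= 1")


def default_modules() -> list[ModuleSpec]:
    """Three planted modules: trait-linked, neutral, LFE-specific."""
    return [
        ModuleSpec(50, {"HFE": 0.8, "LFE": 0.8}, trait_assoc=-0.7),
        ModuleSpec(50, {"HFE": 0.7, "LFE": 0.7}, trait_assoc=0.0),
        ModuleSpec(50, {"HFE": 0.1, "LFE": 0.9}, trait_assoc=0.0),
    ]


@dataclass
class ExprSimConfig:
    """Expression generator settings (defaults emulate 7 + 7 liver samples)."""

    n_genes: int = 2000
    n_samples_per_group: int = 7
    modules: list = field(default_factory=default_modules)
    n_de_genes: int = 20
    de_log2fc: float = 1.5
    dispersion: float = 0.05
    log_mean_loc: float = float(np.log(100.0))
    log_mean_scale: float = 1.2
    signal_sd: float = 0.8
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_group < 3:
            raise ValueError("n_samples_per_group must be >= 3")
        for m in self.modules:
            m.validate()
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"module sizes sum to {total} > n_genes={self.n_genes}"
            )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_de_genes > self.n_genes - total:
            raise ValueError("n_de_genes exceeds the background gene count")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")


@dataclass
class SyntheticTruth:
    """Planted ground truth; fields are filled by the stage that owns them."""

    residuals: pd.DataFrame | None = None  # animal_id, rfi_planted, rwg_planted
    module_labels: pd.Series | None = None  # gene -> planted module (or background)
    trait_modules: list | None = None
    connectivity_tier: pd.Series | None = None  # gene -> HFE/LFE/balanced/background
    de_genes: list | None = None
    enriched_term: str | None = None

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        out = replace(self)
        for name in (
            "residuals",
            "module_labels",
            "trait_modules",
            "connectivity_tier",
            "de_genes",
            "enriched_term",
        ):
            val = getattr(other, name)
            if val is not None:
                setattr(out, name, val)
        return out


@dataclass
class FeedTrialTables:
    """Raw trial records as they would arrive from a feed trial."""

    bw: pd.DataFrame  # animal_id, day, bw_kg (long format)
    dmi: pd.DataFrame  # animal_id, dmi_kg_d


def draw_residual_pairs(
    n: int, rfi_sd: float, rwg_sd: float, resid_cor: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the planted (intake, gain) residual pair, bivariate normal."""
    z = rng.standard_normal((2, n))
    eps1 = rfi_sd * z[0]
    eps2 = rwg_sd * (resid_cor * z[0] + np.sqrt(1 - resid_cor**2) * z[1])
    return eps1, eps2


def _structural_coefficients(cfg: TrialSimConfig) -> tuple[float, float]:
    """(dmi_adg_coef, adg_dmi_coef) consistent with the residual structure.

    Population orthogonality of each planted residual to the regressors
    of its own trait regression requires
    ``b1 = -rho * sd(RFI) / sd(RWG)`` for the intake equation and
    ``g1 = -rho * sd(RWG) / sd(RFI)`` for the gain equation.
    """
    rho, s1, s2 = cfg.resid_cor, cfg.rfi_sd, cfg.rwg_sd
    if cfg.dmi_adg_coef is not None:
        b1 = cfg.dmi_adg_coef
    elif s1 > 0 and s2 > 0:
        b1 = -rho * s1 / s2
    else:
        # no intake residual to decorrelate (or no gain residual): any
        # coefficient keeps the planted structure; use a realistic one so
        # intake still responds to gain and the designs stay full rank
        b1 = FALLBACK_DMI_ADG_COEF
    g1 = -rho * s2 / s1 if s1 > 0 else 0.0
    return b1, g1


def simulate_feed_trial(
    config: TrialSimConfig,
) -> tuple[FeedTrialTables, SyntheticTruth]:
    """Generate body-weight series and intake with planted residuals."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_animals
    days = np.asarray(config.weigh_days, dtype=float)
    ids = [f"A{i:04d}" for i in range(1, n + 1)]

    bw0 = config.bw0_mean + config.bw0_sd * rng.standard_normal(n)
    u = config.adg_sd * rng.standard_normal(n)
    eps1, eps2 = draw_residual_pairs(
        n, config.rfi_sd, config.rwg_sd, config.resid_cor, rng
    )

    b0 = config.dmi_intercept
    b1, g1 = _structural_coefficients(config)
    b2 = config.dmi_mbw_coef
    d_mean = days.mean()
    # exogenous metabolic-weight predictor used in the gain equation; the
    # realised (noisy) series feeds the intake equation below
    w_pred = (bw0 + config.adg_mean * d_mean) ** 0.75
    det = 1.0 - g1 * b1
    w_bar = (config.bw0_mean + config.adg_mean * d_mean) ** 0.75
    g0 = config.adg_mean * det - g1 * (b0 + b2 * w_bar)
    adg = (g0 + g1 * (b0 + b2 * w_pred) + u + g1 * eps1 + eps2) / det

    noise = config.bw_noise_sd * rng.standard_normal((n, days.size))
    bw = bw0[:, None] + adg[:, None] * days[None, :] + noise
    mbw075 = bw.mean(axis=1) ** 0.75
    dmi = b0 + b1 * adg + b2 * mbw075 + eps1

    bw_long = pd.DataFrame(
        {
            "animal_id": np.repeat(ids, days.size),
            "day": np.tile(days.astype(int), n),
            "bw_kg": bw.ravel(),
        }
    )
    dmi_df = pd.DataFrame({"animal_id": ids, "dmi_kg_d": dmi})
    truth = SyntheticTruth(
        residuals=pd.DataFrame(
            {"animal_id": ids, "rfi_planted": eps1, "rwg_planted": eps2}
        ).set_index("animal_id")
    )
    return FeedTrialTables(bw=bw_long, dmi=dmi_df), truth


def _select_samples(pheno: pd.DataFrame, n_per_group: int) -> pd.DataFrame:
    """The n most extreme animals by RIG within each efficiency group."""
    for col in ("group", "rig"):
        if col not in pheno.columns:
            raise ValueError("phenotype table must carry 'group' and 'rig'")
    hfe = pheno.loc[pheno["group"] == ph.HFE].nlargest(n_per_group, "rig")
    lfe = pheno.loc[pheno["group"] == ph.LFE].nsmallest(n_per_group, "rig")
    if len(hfe) < n_per_group or len(lfe) < n_per_group:
        raise ValueError(
            f"phenotype table has fewer than {n_per_group} animals in a group"
        )
    sel = pd.concat([hfe, lfe])
    return sel.sort_index()


def simulate_expression(
    config: ExprSimConfig, pheno: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate a count matrix for sampled HFE/LFE animals.

    Returns (counts genes x samples, gene lengths in bp, truth). Sample
    columns are the selected animal ids; the sample -> group mapping can
    be read back from ``pheno.loc[counts.columns, 'group']``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    sel = _select_samples(pheno, config.n_samples_per_group)
    samples = list(sel.index)
    groups = sel["group"].to_numpy()
    n_s = len(samples)
    rig = sel["rig"].to_numpy(float)
    z_rig = (rig - rig.mean()) / rig.std()

    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    module_labels = pd.Series(BACKGROUND, index=genes, name="module")
    tier = pd.Series(BACKGROUND, index=genes, name="tier")

    z = rng.standard_normal((config.n_genes, n_s))  # gene-level noise

    def _standardize(v: np.ndarray) -> np.ndarray:
        v = v - v.mean()
        return v / v.std()

    def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
        for b in basis:
            v = v - (v @ b) / (b @ b) * b
        return v

    # Module factors are realised orthogonal *in-sample* (and the trait
    # factor with exactly the requested in-sample correlation to RIG).
    # With this few samples, independently drawn factors can correlate by
    # chance strongly enough to fuse two planted modules into one genuine
    # co-expression programme, which would make the planted truth
    # unidentifiable for any method.
    start = 0
    trait_modules = []
    used_factors: list[np.ndarray] = []
    for mi, spec in enumerate(config.modules, start=1):
        name = f"M{mi}"
        members = slice(start, start + spec.size)
        start += spec.size
        module_labels.iloc[members] = name
        a = spec.trait_assoc
        eta = _standardize(
            _orthogonalize(rng.standard_normal(n_s), used_factors + [z_rig])
        )
        factor = a * z_rig + np.sqrt(1 - a**2) * eta
        used_factors.append(factor)
        if a != 0:
            trait_modules.append(name)
        load = np.sqrt(
            np.array([spec.within_cor.get(g, 0.0) for g in groups])
        )
        z[members] = load * factor + np.sqrt(1 - load**2) * z[members]
        w_h = spec.within_cor.get("HFE", 0.0)
        w_l = spec.within_cor.get("LFE", 0.0)
        if w_l - w_h >= 0.5:
            tier.iloc[members] = "LFE"
        elif w_h - w_l >= 0.5:
            tier.iloc[members] = "HFE"
        else:
            tier.iloc[members] = "balanced"

    background_idx = np.arange(start, config.n_genes)
    de_idx = rng.choice(background_idx, size=config.n_de_genes, replace=False)
    de_idx.sort()
    de_shift = np.zeros((config.n_genes, n_s))
    de_shift[np.ix_(de_idx, np.where(groups == ph.LFE)[0])] = (
        np.log(2.0) * config.de_log2fc
    )

    base = config.log_mean_loc + config.log_mean_scale * rng.standard_normal(
        config.n_genes
    )
    mu = np.exp(base[:, None] + config.signal_sd * z + de_shift)
    lam = rng.gamma(shape=1.0 / config.dispersion, scale=mu * config.dispersion)
    counts = rng.poisson(lam)

    lo, hi = config.gene_length_range
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=config.n_genes), index=genes, name="length_bp"
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = SyntheticTruth(
        module_labels=module_labels,
        trait_modules=trait_modules,
        connectivity_tier=tier,
        de_genes=[genes[i] for i in de_idx],
    )
    return counts_df, lengths, truth


def simulate_annotation(
    gene_ids,
    n_terms: int = 50,
    planted_term_genes=None,
    coverage: float = 0.8,
    seed: int = 0,
    extra_rate: float = 0.02,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Random flat gene -> term annotation with one planted enriched term.

    The designated term ``T0000`` annotates exactly the planted gene set
    plus a small random fill (``extra_rate`` per non-planted gene). Each
    gene is annotated with probability ``coverage`` and then receives one
    or more random terms.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene list")
    if not (0 < coverage <= 1):
        raise ValueError("coverage must lie in (0, 1]")
    planted = list(planted_term_genes) if planted_term_genes is not None else []
    unknown = set(planted) - set(gene_ids)
    if unknown:
        raise ValueError(f"planted genes not in gene_ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    terms = [f"T{i:04d}" for i in range(1, n_terms + 1)]
    planted_term = "T0000"
    rows: list[tuple[str, str]] = []
    planted_set = set(planted)
    for g in gene_ids:
        if g in planted_set or (planted and rng.random() < extra_rate):
            rows.append((g, planted_term))
        if rng.random() < coverage:
            k = 1 + rng.poisson(1.0)
            for t in rng.choice(terms, size=min(k, n_terms), replace=False):
                rows.append((g, t))
    ann = pd.DataFrame(rows, columns=["gene_id", "term_id"]).drop_duplicates()
    ann = ann.sort_values(["gene_id", "term_id"]).reset_index(drop=True)
    truth = SyntheticTruth(enriched_term=planted_term if planted else None)
    return ann, truth
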