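# Methods

This note documents the models behind `efnet`, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Feed-efficiency traits

Body weight is modelled as linear in feeding day; ADG is the per-animal
OLS slope over the weigh days (default grid 0, 14, …, 70 d). Metabolic
weight is `(mean BW over all weighings)^0.75` — the mean is taken before
the power, the only dimensionally sensible reading. The residual traits
are defined by two three-parameter regressions over the cohort:

- `DMI = β₀ + β₁·ADG + β₂·MBW^0.75 + ε₁`, RFI ≡ ε₁ (kg DM/d)
- `ADG = β₀ + β₁·DMI + β₂·MBW^0.75 + ε₂`, RWG ≡ ε₂ (kg/d)
- `RIG = RWG − RFI`; `FCR = DMI/ADG` per animal

Animals whose ADG deviates more than 2.5 SD from the cohort mean are
excluded *before* the trait regressions, so the residuals are defined on
the cleaned cohort (the residual-maker matrix depends on which animals
enter the fit). Both fits are solved by `numpy.linalg.lstsq`;
rank-deficient designs raise an error naming the collinear column.
By construction the residuals are zero-mean and orthogonal to their
regressors; the test suite asserts this to 1e-8 (relative) on every
simulated trial and checks the residuals against an explicit
normal-equation solve at small n.

Group comparisons first test each group with Shapiro-Wilk (α = 0.05);
if both pass, a two-sided pooled-variance Student's t-test is used
(Welch behind a flag), otherwise Mann-Whitney-Wilcoxon. A zero-variance
group forces the Mann-Whitney route with a warning because the pooled t
statistic is undefined there.

## Feed-trial generator

Per animal the generator draws initial weight `BW₀ ~ N(376, 29²)` kg, an
independent growth component `u ~ N(0, adg_sd²)` and the planted
residual pair `(ε₁, ε₂)` from a bivariate normal with SDs `rfi_sd = 0.90`
and `rwg_sd = 0.35` kg/d and correlation `resid_cor = −0.60`. The first
two moments mirror a typical 98-steer feedlot trial (initial BW
376 ± 29 kg);
the residual SDs and correlation are calibrated so that the derived
group contrasts and the RFI–RIG correlation land in the reported range
(see the acceptance script). Weighing error (`bw_noise_sd`, default
3 kg) is added to every BW record.

The structural coefficients linking intake and gain are *derived from
the residual structure* rather than set freely: writing the two trait
regressions as a simultaneous system, the planted pair is
population-orthogonal to the regressors of its own regression exactly
when

```
β₁(DMI on ADG) = −ρ σ₁ / σ₂      γ₁(ADG on DMI) = −ρ σ₂ / σ₁
```

(with the defaults, β₁ = 1.54 kg DM per kg gain — a plausible feed
response). The generator solves the reduced form of this system, which
makes the planted residuals recoverable by downstream least squares.
Recovery is still bounded by the finite-sample OLS projection: the
recovered RFI is `M ε₁` for the 3-column hat-matrix complement `M`, so
`E[cor(ε₁, RFI)] ≈ √((n−3)/(n−1)) ≈ 0.990` at n = 98 and seed-to-seed
values of 0.97–0.995 are expected, not a defect. Setting
`dmi_adg_coef` manually breaks exact recoverability and is intended for
robustness experiments. With `rfi_sd = 0` the derived coefficient is
undefined and a fixed realistic value (1.5) is used so the designs stay
full-rank.

## Expression generator

Counts are gamma-Poisson (negative binomial): gene `g` in sample `j` has
mean `μ_gj = exp(base_g + s·z_gj + DE shift)` with `base_g ~ N(log 100,
1.2²)` (library sizes then land near 0.5 M reads for 2000 genes),
signal scale `s = 0.8` on the natural-log scale (inter-animal biological
CV near 1 for programme-driven genes), NB dispersion 0.05, and
`counts ~ Poisson(Gamma(1/φ, μφ))`. Gene lengths are uniform on
500–5000 bp.

Module structure enters through one latent factor per module:
`z_gj = √w_G(j)·f_mj + √(1−w_G(j))·e_gj`, where `w_G` is the
group-specific within-module correlation requested for the sample's
group, so member pairs have latent correlation `w` within that group.
A trait-linked module's factor is `a·z_RIG + √(1−a²)·η` with `z_RIG`
the standardised RIG of the sampled animals.

Two realisation choices make the planted truth *identifiable*:

- Factors are realised orthogonal in-sample (Gram-Schmidt against the
  previously drawn factors and `z_RIG`, then re-standardised). With
  only 14 samples, independently drawn factors can sample-correlate
  above 0.7, which genuinely fuses two "planted" modules into one
  co-expression programme — no method could, or should, separate them.
- The trait factor carries exactly the requested in-sample correlation
  with RIG, so the module-trait gate is tested against a known effect
  size rather than a noisy realisation of it.

Differential expression shifts the LFE-sample log-mean of `n_de_genes`
background genes by `log2fc·ln 2`. At 7 + 7 samples the per-gene log2
ratio of group means carries sampling noise with SD ≈ 0.5, so the
planted effect is recovered in the mean across DE genes, not per gene.

What the generator does **not** emulate: read-level artefacts (GC and
length biases within a gene, mapping ambiguity), batch effects,
compositional distortion of CPM by a few dominant genes, correlated
gene lengths, ontology structure in the annotation, and any real
biology linking modules to each other. Passing recovery tests therefore
demonstrates that the analysis chain is implemented correctly and can
extract signal of the designed form at the designed strength — not that
it would find such signal in any particular real data set.

## Network construction

Correlations are Pearson on `log2(FPKM + 1)` by default
(`network_log2` flag). Raw FPKM is approximately lognormal with CV
near 1, which attenuates Pearson correlations (a latent 0.8 becomes
~0.65) and is why log transformation is the standard recommendation for
RNA-seq co-expression input; with it, planted-module recovery rises
from ARI ≈ 0.87 to 0.93–1.00 across seeds.

Adjacency is unsigned, `a = |r|^β`: the whole-network soft threshold
is typically an odd power, under which signed powering
would produce negative "adjacencies", so the unsigned network is the
only self-consistent reading. β is chosen as the smallest candidate
(1–20) whose connectivity distribution fits
`log10 p(k) ~ log10 k` with signed R² ≥ 0.9 (sign-aware because a
positive-slope fit — frequency increasing with connectivity — is not
scale-free; without the sign the criterion degenerates at high powers
where all connectivities collapse toward zero). If no candidate
reaches the cut the argmax is used with a warning.

TOM is the standard shared-neighbour overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)`,
computed by a matrix product and verified against a brute-force triple
loop to 1e-12.

**Module detection** is a simplified dynamic tree cut with three
stages:

1. an eager top-down walk of the average-linkage dendrogram of
   `1 − TOM`: descend while both children can hold a module
   (≥ `min_module_size`, default 30); a branch whose children are both
   too small becomes a candidate module; an undersized child is set
   aside while the descent continues. Single-height cuts were rejected
   because TOM merge heights form a near-continuum (between-module
   overlap exceeds the background level), so no one height separates
   branches;
2. modules whose eigengenes correlate above 0.75 (absolute) are merged —
   fragments of one expression programme;
3. every gene is assigned to the module with its largest |kME| when
   that exceeds 0.5, else grey; this rescues peripheral members set
   aside by the cut (the analogue of the PAM stage of the
   reference dynamic-tree-cut algorithm).

Known limitation: diffuse background co-variation can survive as
spurious modules of roughly minimum size; they are harmless downstream
(their eigengenes rarely pass the trait gate) but inflate the module
count. The eigengene is the unit-norm first left singular vector of the
standardised member-gene matrix, oriented to correlate non-negatively
with the module mean profile; module-trait p-values use the exact
t-transform with n − 2 df, two-sided, uncorrected (matching field
practice for module selection). kME thresholds are applied to absolute
values.

## Differential connectivity

Each group's sub-network uses only that group's samples on the QC-passed
gene set (no per-group refiltering), with the asymmetric default
powers: β = 20 (LFE) and β = 4 (HFE). Connectivity is max-normalised
per sub-network and `kdiff = K_LFE_norm − K_HFE_norm`.

The asymmetric defaults make the statistic asymmetric under the null,
and with 7 samples per group the effect is large: the null sample
correlation at n = 7 has `E|r|⁴ ≈ 0.06`, so every gene's K_HFE carries
a floor of ≈ 0.06·(G−1) and the max-normalised K_HFE concentrates in
0.4–0.7. Consequently kdiff is biased negative, HFE-connected calls
dominate, and `kdiff > +0.6` is nearly unreachable even for genes
planted as LFE-only connected — their kdiff separates cleanly from
background (≈ 0 vs ≈ −0.4) but below the symmetric threshold. The
pipeline logs the powers prominently; a permutation null would be the
principled fix and is left as an extension hook.

## Enrichment

Upper-tail hypergeometric probabilities come from
`scipy.stats.hypergeom.sf`; BH adjustment from
`statsmodels.stats.multitest`. The background universe is always
supplied explicitly by the caller (the pipeline uses the full count
matrix); terms with zero study hits are excluded from the testing
burden by default (`min_hits`). The annotation is flat — no ontology
graph propagation — a deliberate simplification; parent terms are
enriched only through their own direct annotations. Results are sorted
by p with term id as the deterministic tie-break.

## Problem sizes and determinism

Default simulated studies use 98 animals, 2000 genes and 7 + 7 liver
samples; recovery validation uses 300 genes with three 50-gene planted
modules, sizes at which the full chain runs in seconds while keeping
every per-stage statistic in its asymptotically relevant regime. One
global seed expands through `numpy.random.SeedSequence` into
per-component child streams, so identical configs give byte-identical
outputs and adding a component never perturbs the draws of another.
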