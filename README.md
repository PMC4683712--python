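# efnet

Feed-efficiency phenotypes and liver co-expression network analysis for
beef cattle feed trials.

Selecting cattle for feed efficiency requires measuring individual feed
intake and weight gain over a ~70-day trial — expensive enough that
molecular correlates of efficiency are actively sought in the liver
transcriptome. `efnet` implements the full analysis chain used in such
studies, from raw trial records to enriched gene sets, together with a
synthetic-data generator that plants known signal at every stage so the
chain can be validated end to end.

## What it computes

**Feed-efficiency traits.** From body-weight series and daily dry-matter
intake (DMI), per animal:

- ADG (average daily gain): OLS slope of body weight on feeding day, kg/d
- MBW^0.75: (mean body weight)^0.75, the metabolic weight
- RFI (residual feed intake): ε₁ in `DMI = β₀ + β₁·ADG + β₂·MBW^0.75 + ε₁`
- RWG (residual body weight gain): ε₂ in `ADG = β₀ + β₁·DMI + β₂·MBW^0.75 + ε₂`
- RIG = RWG − RFI, the index used to pick high- (HFE) and low- (LFE)
  efficiency groups; FCR = DMI/ADG

Animals with |ADG z-score| > 2.5 are removed before the trait
regressions. Group contrasts are routed by a Shapiro-Wilk check to a
Student's t-test or a Mann-Whitney-Wilcoxon test.

**Weighted co-expression network.** Counts → CPM filter (≥ 1 CPM in half
the samples) → upper-quartile-normalised FPKM → QC filter → top-3500
connectivity pre-selection → unsigned adjacency `a_ij = |cor_ij|^β` with
β picked by the scale-free topology criterion → topological overlap
matrix (TOM) → average-linkage modules (dynamic cut, minimum 30 genes,
colour names) → module eigengenes → module-trait gate (|r| > 0.5,
p ≤ 0.1 against RFI/RIG) → module-membership (kME) filtering.

**Differential co-expression.** Per-group sub-networks (β = 20 for LFE,
β = 4 for HFE), per-gene connectivity normalised by the sub-network
maximum, and `kdiff = K_LFE_norm − K_HFE_norm ∈ [−1, 1]`; |kdiff| > 0.6
flags differentially connected genes.

**Enrichment.** Upper-tail hypergeometric test of gene lists against a
flat gene→term annotation, Benjamini-Hochberg FDR, significance at
padj ≤ 0.1.

## Worked example

```python
from efnet import simulate as sim, phenotypes as ph

trial, truth = sim.simulate_feed_trial(sim.TrialSimConfig(seed=42))
table = ph.build_phenotype_table(trial.bw, trial.dmi)
table = ph.remove_adg_outliers(table)
table, fit_dmi, fit_adg = ph.compute_residual_traits(table)
table = ph.select_extreme_groups(table, n_per_group=20)
```

prints, when the group means are summarised:

```
excluded: 1
HFE  RFI -1.08  RWG +0.23  RIG +1.31  FCR 5.74
LFE  RFI +1.30  RWG -0.26  RIG -1.57  FCR 8.03
cor(RFI, RIG) = -0.98
DMI comparison: t, p = 5.16e-04
```

One animal is trimmed by the 2.5-SD ADG rule. Efficient (HFE) animals
eat less than predicted (negative RFI), gain more than predicted
(positive RWG), and convert feed better (lower FCR); RFI and RIG are
almost perfectly anticorrelated because RFI dominates the variance of
RIG = RWG − RFI. The intake difference between groups is routed to a
t-test and is strongly significant.

The whole chain runs from one config:

```sh
efnet run --config run.yaml     # simulate → traits → network → kdiff → enrichment
efnet simulate --outdir sim/    # or write the synthetic tables only
efnet traits --bw sim/bw.tsv --dmi sim/dmi.tsv --n-per-group 20 --out traits.tsv
```

Each run writes every stage table (TSV), a `report.txt` with the gene
counts surviving each filter, the chosen β, module sizes, selected trait
modules, differential-connectivity counts and significant terms, plus
the fully resolved configuration for auditability.

## Layout

- `efnet.simulate` — feed trial, module-structured counts, annotation, all with planted truth
- `efnet.phenotypes` — traits, outlier rule, group selection, group tests
- `efnet.expression` — CPM/FPKM, filters, connectivity pre-selection
- `efnet.network` — adjacency, TOM, modules, eigengenes, kME
- `efnet.diffcoexp` — per-group connectivity and kdiff
- `efnet.enrichment` — hypergeometric test + BH FDR
- `efnet.pipeline` / `efnet.cli` — orchestration and the `efnet` command

See `docs/methods.md` for the model details, parameter choices and known
limitations.
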