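"""End-to-end orchestration: simulate/load -> traits -> prep -> network ->
differential co-expression -> enrichment, with a run report.

Every stage parameter carries the analysis default (minimum 1 CPM in
half the samples, top-3500 connectivity pre-selection, scale-free R^2
cut 0.9, minimum module size 30, module-trait gate |r| > 0.5 with
p <= 0.1, kME 0.6, sub-network powers 4/20, |kdiff| > 0.6, enrichment
padj <= 0.1). The resolved configuration is written next to the outputs
so every run is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffcoexp as dc
from . import enrichment as en
from . import expression as ex
from . import io
from . import network as nw
from . import phenotypes as ph
from . import simulate as sim

log = logging.getLogger("efnet")


@dataclass
class SimulateConfig:
    enabled: bool = True
    trial: sim.TrialSimConfig = field(default_factory=sim.TrialSimConfig)
    expression: sim.ExprSimConfig = field(default_factory=sim.ExprSimConfig)
    annotation_terms: int = 50
    annotation_coverage: float = 0.8


@dataclass
class InputPaths:
    bw: str | None = None
    dmi: str | None = None
    counts: str | None = None
    lengths: str | None = None
    annotation: str | None = None


@dataclass
class RunConfig:
    outdir: str = "efnet_run"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    inputs: InputPaths = field(default_factory=InputPaths)
    # phenotypes
    n_per_group: int = 20
    adg_outlier_sd: float = 2.5
    # expression prep
    min_cpm: float = 1.0
    min_cpm_samples: int | None = None
    qc_max_zero_samples: int = 7
    qc_mean_min: float = 0.5
    qc_sd_min: float = 0.2
    qc_direction: str = "rationale"
    n_top_connected: int = 3500
    # network
    network_log2: bool = True
    beta: int | None = None  # None = scale-free scan
    beta_candidates: tuple[int, ...] = tuple(range(1, 21))
    r2_cut: float = 0.9
    min_module_size: int = 30
    trait_r_threshold: float = 0.5
    trait_p_threshold: float = 0.1
    kme_own_min: float = 0.6
    kme_other_max: float = 0.6
    # differential co-expression
    beta_hfe: float = 4.0
    beta_lfe: float = 20.0
    kdiff_threshold: float = 0.6
    # enrichment
    padj_cut: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulate" in kwargs and isinstance(kwargs["simulate"], dict):
            s = dict(kwargs["simulate"])
            if "trial" in s and isinstance(s["trial"], dict):
                s["trial"] = sim.TrialSimConfig(**s["trial"])
            if "expression" in s and isinstance(s["expression"], dict):
                e = dict(s["expression"])
                if "modules" in e:
                    e["modules"] = [
                        sim.ModuleSpec(**m) if isinstance(m, dict) else m
                        for m in e["modules"]
                    ]
                s["expression"] = sim.ExprSimConfig(**e)
            kwargs["simulate"] = SimulateConfig(**s)
        if "inputs" in kwargs and isinstance(kwargs["inputs"], dict):
            kwargs["inputs"] = InputPaths(**kwargs["inputs"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        Path(path).write_text(yaml.safe_dump(_clean(self.to_dict()), sort_keys=False))


def _seeded(config: RunConfig) -> RunConfig:
    """Expand the global seed into per-component child seeds."""
    ss = np.random.SeedSequence(config.seed)
    trial_seed, expr_seed, ann_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    cfg = dataclasses.replace(config)
    cfg.simulate = dataclasses.replace(
        config.simulate,
        trial=dataclasses.replace(config.simulate.trial, seed=trial_seed),
        expression=dataclasses.replace(config.simulate.expression, seed=expr_seed),
    )
    cfg._annotation_seed = ann_seed  # type: ignore[attr-defined]
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; write TSV outputs plus report.txt to ``outdir``.

    Returns a results bundle (dict) with the in-memory stage outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _seeded(config)
    report: list[str] = []
    results: dict = {}

    # ------------------------------------------------------------ inputs
    truth = sim.SyntheticTruth()
    if cfg.simulate.enabled:
        trial, t_truth = sim.simulate_feed_trial(cfg.simulate.trial)
        truth = truth.merge(t_truth)
        io.write_tsv(trial.bw, outdir / "bw.tsv", index=False)
        io.write_tsv(trial.dmi, outdir / "dmi.tsv", index=False)
        bw, dmi = trial.bw, trial.dmi
    else:
        for name in ("bw", "dmi", "counts", "lengths", "annotation"):
            if getattr(cfg.inputs, name) is None:
                raise ValueError(f"config field inputs.{name} is required")
        bw = io.read_bw_csv(cfg.inputs.bw)
        dmi = io.read_dmi_csv(cfg.inputs.dmi)

    # -------------------------------------------------------- phenotypes
    table = ph.build_phenotype_table(bw, dmi)
    table = ph.remove_adg_outliers(table, k=cfg.adg_outlier_sd)
    table, fit_dmi, fit_adg = ph.compute_residual_traits(table)
    table = ph.select_extreme_groups(table, cfg.n_per_group)
    io.write_tsv(table, outdir / "traits.tsv")
    results["phenotypes"] = table
    n_excl = int(table["excluded"].sum())
    report.append(f"animals: {len(table)} ({n_excl} excluded by ADG outlier rule)")
    report.append(
        f"groups: {int((table['group'] == ph.HFE).sum())} HFE / "
        f"{int((table['group'] == ph.LFE).sum())} LFE (by RIG)"
    )

    # -------------------------------------------------------- expression
    if cfg.simulate.enabled:
        counts, lengths, e_truth = sim.simulate_expression(
            cfg.simulate.expression, table
        )
        truth = truth.merge(e_truth)
        io.write_tsv(counts, outdir / "counts.tsv")
        io.write_tsv(lengths.to_frame(), outdir / "gene_lengths.tsv")
    else:
        counts = io.read_counts_tsv(cfg.inputs.counts)
        lengths = io.read_lengths_tsv(cfg.inputs.lengths)
    groups = table.loc[counts.columns, "group"]
    report.append(f"genes in count matrix: {len(counts)}")

    cpm = ex.compute_cpm(counts)
    keep_cpm = ex.filter_min_cpm(cpm, cfg.min_cpm, cfg.min_cpm_samples)
    report.append(
        f"CPM filter (>= {cfg.min_cpm} CPM in >= half samples): "
        f"{int(keep_cpm.sum())} kept"
    )
    fpkm = ex.compute_fpkm(counts.loc[keep_cpm], lengths)
    keep_qc = ex.qc_filter_for_network(
        fpkm,
        max_zero_samples=cfg.qc_max_zero_samples,
        mean_min=cfg.qc_mean_min,
        sd_min=cfg.qc_sd_min,
        qc_direction=cfg.qc_direction,
    )
    fpkm_qc = fpkm.loc[keep_qc]
    report.append(
        f"QC filter (zeros/mean/SD, direction={cfg.qc_direction}): "
        f"{len(fpkm_qc)} kept"
    )
    top = ex.select_top_connected(fpkm_qc, cfg.n_top_connected)
    expr_net = fpkm_qc.loc[top]
    if cfg.network_log2:
        expr_net = np.log2(expr_net + 1.0)
    io.write_tsv(expr_net, outdir / "expression_network.tsv")
    results["expression"] = expr_net
    report.append(f"top-connectivity pre-selection: {len(expr_net)} genes")

    # ----------------------------------------------------------- network
    if cfg.beta is not None:
        scan = nw.pick_soft_threshold(expr_net, [cfg.beta], cfg.r2_cut)
    else:
        scan = nw.pick_soft_threshold(expr_net, cfg.beta_candidates, cfg.r2_cut)
    beta = scan.chosen_beta
    report.append(
        f"soft threshold beta = {beta} "
        f"(scale-free R^2 = "
        f"{float(scan.table.loc[scan.table['beta'] == beta, 'r_squared'].iloc[0]):.3f}"
        f", cut {scan.r2_cut})"
    )
    cor = nw.correlation_matrix(expr_net)
    adj = nw.adjacency(cor, beta)
    tom = nw.topological_overlap(adj)
    labels = nw.detect_modules(expr_net, tom, cfg.min_module_size)
    sizes = labels.value_counts().drop(nw.GREY, errors="ignore")
    report.append(
        f"modules: {len(sizes)} (sizes: {', '.join(str(s) for s in sizes)}; "
        f"grey: {int((labels == nw.GREY).sum())})"
    )
    me = nw.module_eigengenes(expr_net, labels)
    traits = table.loc[me.index, ["rfi", "rig"]]
    mt = nw.module_trait_correlation(me, traits)
    selected = nw.select_trait_modules(
        mt, cfg.trait_r_threshold, cfg.trait_p_threshold
    )
    kme = nw.module_membership(expr_net, me)
    retained = nw.filter_by_membership(
        kme, labels, cfg.kme_own_min, cfg.kme_other_max
    )
    module_table = pd.DataFrame(
        {
            "module": labels,
            "kme_own": [
                kme.at[g, labels[g]] if labels[g] != nw.GREY else np.nan
                for g in labels.index
            ],
            "retained": [
                labels[g] != nw.GREY and g in retained.get(labels[g], ())
                for g in labels.index
            ],
        }
    )
    io.write_tsv(module_table, outdir / "modules.tsv")
    io.write_tsv(me, outdir / "eigengenes.tsv")
    io.write_tsv(mt, outdir / "module_trait.tsv", index=False)
    results.update(
        {
            "soft_threshold": scan,
            "modules": module_table,
            "eigengenes": me,
            "module_trait": mt,
            "trait_modules": selected,
            "kme": kme,
            "retained": retained,
        }
    )
    report.append(
        "trait-associated modules "
        f"(|r| > {cfg.trait_r_threshold}, p <= {cfg.trait_p_threshold}): "
        + (
            ", ".join(
                f"{r.module} ({r.sign_pattern})" for r in selected.itertuples()
            )
            if len(selected)
            else "none"
        )
    )

    # ------------------------------------------------ differential network
    log.info(
        "KDiff uses asymmetric powers beta_lfe=%s / beta_hfe=%s; the "
        "statistic is asymmetric under the null",
        cfg.beta_lfe,
        cfg.beta_hfe,
    )
    expr_kd = np.log2(fpkm_qc + 1.0) if cfg.network_log2 else fpkm_qc
    kd = dc.kdiff_table(
        expr_kd, groups, cfg.beta_hfe, cfg.beta_lfe, cfg.kdiff_threshold
    )
    io.write_tsv(kd, outdir / "kdiff.tsv")
    results["kdiff"] = kd
    hfe_list, lfe_list = dc.select_differentially_connected(
        kd, cfg.kdiff_threshold
    )
    report.append(
        f"differentially connected (|kdiff| > {cfg.kdiff_threshold}): "
        f"{len(hfe_list)} HFE-connected, {len(lfe_list)} LFE-connected"
    )

    # -------------------------------------------------------- enrichment
    if cfg.simulate.enabled:
        planted = (
            truth.de_genes
            if truth.de_genes
            else list(counts.index[: cfg.simulate.expression.n_de_genes])
        )
        ann, a_truth = sim.simulate_annotation(
            list(counts.index),
            n_terms=cfg.simulate.annotation_terms,
            planted_term_genes=planted,
            coverage=cfg.simulate.annotation_coverage,
            seed=cfg._annotation_seed,  # type: ignore[attr-defined]
        )
        truth = truth.merge(a_truth)
        io.write_tsv(ann, outdir / "annotation.tsv", index=False)
    else:
        ann = io.read_annotation_tsv(cfg.inputs.annotation)
    background = list(counts.index)
    enrich_results = {}
    study_sets = {f"module_{m}": genes for m, genes in retained.items() if genes}
    diffcon = sorted(set(hfe_list) | set(lfe_list))
    if diffcon:
        study_sets["diffcoexp"] = diffcon
    if cfg.simulate.enabled and truth.de_genes:
        study_sets["de_genes"] = truth.de_genes
    for name, genes in study_sets.items():
        res = en.enrich(genes, background, ann, cfg.padj_cut)
        enrich_results[name] = res
        io.write_tsv(res, outdir / f"enrichment_{name}.tsv", index=False)
        n_sig = int(res["significant"].sum()) if len(res) else 0
        report.append(
            f"enrichment [{name}]: {n_sig} significant terms "
            f"(padj <= {cfg.padj_cut})"
        )
    results["enrichment"] = enrich_results
    results["truth"] = truth

    # ------------------------------------------------------------ report
    if cfg.simulate.enabled and truth.module_labels is not None:
        io.write_tsv(
            pd.DataFrame(
                {
                    "module_planted": truth.module_labels,
                    "tier_planted": truth.connectivity_tier,
                }
            ),
            outdir / "truth_genes.tsv",
        )
        io.write_tsv(truth.residuals, outdir / "truth_residuals.tsv")
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    config.to_yaml(outdir / "resolved_config.yaml")
    results["report"] = report
    return results
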