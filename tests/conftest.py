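"""Shared fixtures: small synthetic datasets generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from efnet import expression as ex
from efnet import phenotypes as ph
from efnet import simulate as sim


@pytest.fixture(scope="session")
def trial_default():
    """Default 98-animal feed trial (seed 0) with planted residuals."""
    return sim.simulate_feed_trial(sim.TrialSimConfig(seed=0))


@pytest.fixture(scope="session")
def pheno_default(trial_default):
    """Phenotype table with traits and 20+20 efficiency groups."""
    trial, _ = trial_default
    table = ph.build_phenotype_table(trial.bw, trial.dmi)
    table = ph.remove_adg_outliers(table)
    table, _, _ = ph.compute_residual_traits(table)
    return ph.select_extreme_groups(table, 20)


@pytest.fixture(scope="session")
def expr_default(pheno_default):
    """Default expression simulation (2000 genes, 7+7 samples, seed 0)."""
    counts, lengths, truth = sim.simulate_expression(
        sim.ExprSimConfig(seed=0), pheno_default
    )
    return counts, lengths, truth


@pytest.fixture(scope="session")
def recovery_dataset(pheno_default):
    """Three tight planted modules on 300 genes, 14 samples (seed 0).

    The layout used for planted-structure recovery checks: 3 x 50 genes
    at within-correlation 0.8, one module trait-linked, 150 background
    genes.
    """
    cfg = sim.ExprSimConfig(
        n_genes=300,
        seed=0,
        modules=[
            sim.ModuleSpec(50, {"HFE": 0.8, "LFE": 0.8}, trait_assoc=-0.7),
            sim.ModuleSpec(50, {"HFE": 0.8, "LFE": 0.8}),
            sim.ModuleSpec(50, {"HFE": 0.8, "LFE": 0.8}),
        ],
        n_de_genes=10,
    )
    counts, lengths, truth = sim.simulate_expression(cfg, pheno_default)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        expr = np.log2(ex.compute_fpkm(counts, lengths) + 1.0)
    return expr, truth


@pytest.fixture()
def toy_counts():
    """Tiny count matrix with hand-checkable values."""
    return pd.DataFrame(
        {
            "s1": [10, 0, 90, 400],
            "s2": [20, 5, 75, 650],
        },
        index=["g1", "g2", "g3", "g4"],
    )
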