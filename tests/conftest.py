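"""Shared fixtures: small simulated family datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from episcan import famcorr, phenoprep, synthetic_data


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_adjusted_dataset(spec: synthetic_data.ArchitectureSpec):
    """Simulate, log-transform if needed, adjust covariates, and return
    (gm, residuals, structure, estimated_rho, pheno, truth)."""
    gm, ped = synthetic_data.simulate_genotypes(spec)
    pheno, truth = synthetic_data.simulate_phenotype(gm, ped, spec)
    y = pheno["trait"].to_numpy(dtype=float)
    if spec.trait_scale == "lognormal":
        y = phenoprep.apply_transform(y, 0.0)
    cov = pheno[[c.name for c in spec.covariates]] if spec.covariates else None
    adj = phenoprep.adjust_phenotype(y, cov, pheno["individual_id"])
    structure = famcorr.SibshipStructure.from_frame(pheno)
    icc = famcorr.estimate_icc(adj.residuals, structure)
    return gm, adj.residuals, structure, icc.rho, pheno, truth


@pytest.fixture(scope="session")
def family_dataset():
    """200 sibships of 3, rho = 0.4, 40 common SNPs, one planted additive QTL."""
    spec = synthetic_data.ArchitectureSpec(
        n_snps=40, n_sibships=200, sibship_size=3, maf_range=(0.15, 0.5),
        icc=0.4, qtl_single=[(7, 0.5, 0.0)], seed=11,
    )
    return make_adjusted_dataset(spec)
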