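import numpy as np
import pandas as pd
import pytest

from drugmr import discovery as disc
from drugmr import harmonize as hz
from drugmr import mr, sim


def make_ivw_replicate(seed, causal_beta=0.3, k=5, n_exposure=50_000, n_outcome=50_000,
                       effect_sd=0.25, pleiotropy_mode="none", pleiotropy_sd=0.0,
                       pleiotropy_mean=0.0):
    """One two-sample replicate with k independent instruments; returns kept pairs."""
    ld = sim.simulate_ld_matrix(k, [k], rho=0.0)
    truth = sim.SimTruth(
        gene_id="G", causal_beta=causal_beta, pleiotropy_mode=pleiotropy_mode,
        pleiotropy_sd=pleiotropy_sd, pleiotropy_mean=pleiotropy_mean,
        n_exposure=n_exposure, n_outcome=n_outcome, seed=seed,
    )
    exposure = sim.simulate_qtl_sumstats(truth, ld, n_causal=k, effect_sd=effect_sd, seed=seed)
    outcome = sim.simulate_outcome_gwas(truth, exposure, ld, seed=seed + 1_000_003)
    return hz.kept_pairs(hz.harmonize_pipeline(exposure, outcome))


def make_smr_region(seed, causal_beta=0.15, n_snps=20, rho=0.8, qtl_effect=0.6,
                    n_qtl=30_000, n_gwas=300_000, causal_index=8, null_outcome=False):
    """One cis region with a single shared causal variant for SMR/HEIDI tests."""
    ld = sim.simulate_ld_matrix(n_snps, [n_snps], rho)
    truth = sim.SimTruth(
        gene_id="G", causal_beta=0.0 if null_outcome else causal_beta,
        n_exposure=n_qtl, n_outcome=n_gwas, seed=seed,
    )
    qtl = sim.simulate_qtl_sumstats(
        truth, ld, n_causal=1, causal_indices=[causal_index],
        causal_effects=[qtl_effect], seed=seed,
    )
    gwas = sim.simulate_outcome_gwas(truth, qtl, ld, seed=seed + 7_000_001)
    return qtl, gwas, ld


@pytest.fixture
def small_study():
    return sim.simulate_study(
        n_genes=6, n_causal_genes=1, causal_beta=0.5,
        n_exposure=100_000, n_outcome_discovery=100_000,
        n_outcome_replication=100_000, seed=42,
    )


def study_to_gene_data(study):
    return {
        gid: disc.GeneData(
            e["gene"], e["exposure"], e["ld"], e["gwas_discovery"], e["gwas_replication"]
        )
        for gid, e in study.items()
    }


def pairs_frame(bx, sx, by, sy, ids=None):
    """Assemble a minimal harmonized-pairs frame from effect arrays."""
    k = len(bx)
    return pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"v{i}" for i in range(k)],
            "beta_exp": np.asarray(bx, float),
            "se_exp": np.asarray(sx, float),
            "beta_out": np.asarray(by, float),
            "se_out": np.asarray(sy, float),
            "action_taken": "kept",
        }
    )
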