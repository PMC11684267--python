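"""Synthetic GWAS/QTL summary statistics with block LD and known causal truth.

The generator works entirely on the summary-statistic scale. For a region of
m variants with LD correlation matrix R and per-variant true (joint) effects
b, the true marginal effect vector is ``R @ b`` (standardized genotypes and
a unit-variance quantitative trait). Estimated marginals add sampling noise
drawn from MVN(0, sigma^2 R) with sigma = 1/sqrt(n) — the correlated
estimation error structure that LD induces within a region, which downstream
heterogeneity tests (HEIDI, Cochran's Q) rely on.

Binary outcomes are simulated directly on the log-odds scale with per-variant
standard error 1/sqrt(n * phi * (1 - phi)) where phi is the case fraction;
the causal effect of the exposure enters as ``causal_beta`` times the true
exposure marginal, plus optional per-variant direct (pleiotropic) effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, LDMatrix

__all__ = [
    "SimTruth",
    "simulate_ld_matrix",
    "simulate_qtl_sumstats",
    "simulate_outcome_gwas",
    "simulate_mediation_region",
    "simulate_study",
]

PLEIOTROPY_MODES = ("none", "balanced", "directional")

# non-palindromic allele pairs used for ordinary variants
_PLAIN_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROME_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimTruth:
    """Ground truth for one simulated gene region.

    ``causal_beta`` is the effect of one SD of exposure on the outcome
    log-odds. ``mediation_chain`` is ``(b_meth_expr, b_expr_outcome)`` for
    methylation scenarios. Pleiotropy parameters describe per-variant direct
    effects on the outcome.
    """

    gene_id: str = "GENE"
    causal_beta: float = 0.0
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    mediation_chain: tuple[float, float] | None = None
    n_exposure: int = 30_000
    n_outcome: int = 250_000
    seed: int = 0

    # filled in by the generators, for recovery tests
    direct_effects: np.ndarray | None = field(default=None, repr=False)
    true_marginal_exposure: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode in ("none", "balanced") and self.pleiotropy_mean != 0:
            raise ValueError("pleiotropy_mean must be 0 unless mode is 'directional'")
        if self.pleiotropy_mode == "none" and self.pleiotropy_sd != 0:
            raise ValueError("pleiotropy_sd must be 0 when mode is 'none'")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be >= 2")


def simulate_ld_matrix(
    n_variants: int,
    block_sizes: Sequence[int],
    rho: float,
    seed: int = 0,
) -> LDMatrix:
    """Block-diagonal AR(1) LD: r_ij = rho^|i-j| within a block, 0 across.

    The construction is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic generators.
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    if sum(block_sizes) != n_variants:
        raise ValueError(
            f"block sizes sum to {sum(block_sizes)}, expected {n_variants}"
        )
    r = np.zeros((n_variants, n_variants))
    offset = 0
    for size in block_sizes:
        idx = np.arange(size)
        block = rho ** np.abs(idx[:, None] - idx[None, :])
        r[offset : offset + size, offset : offset + size] = block
        offset += size
    ids = [f"rs{i + 1}" for i in range(n_variants)]
    return LDMatrix(ids, r)


def _psd_root(r: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix, eigenvalues clipped at 0."""
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-8:
        raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():g})")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


def _assign_alleles(
    rng: np.random.Generator, m: int, palindrome_fraction: float
) -> tuple[list[str], list[str], np.ndarray]:
    n_pal = int(round(palindrome_fraction * m))
    pal_idx = set(rng.choice(m, size=n_pal, replace=False).tolist()) if n_pal else set()
    ea, oa = [], []
    eaf = rng.uniform(0.05, 0.95, size=m)
    for j in range(m):
        if j in pal_idx:
            pair = _PALINDROME_PAIRS[rng.integers(len(_PALINDROME_PAIRS))]
            eaf[j] = rng.uniform(0.44, 0.56)  # intermediate frequency
        else:
            pair = _PLAIN_PAIRS[rng.integers(len(_PLAIN_PAIRS))]
        ea.append(pair[0])
        oa.append(pair[1])
    return ea, oa, eaf


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta / se)
    return np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)


def _sumstats_frame(
    ld: LDMatrix,
    beta: np.ndarray,
    se: float,
    n: int,
    ea: list[str],
    oa: list[str],
    eaf: np.ndarray,
    chrom: str,
    pos: np.ndarray,
) -> pd.DataFrame:
    se_arr = np.full(len(beta), se)
    return pd.DataFrame(
        {
            "variant_id": ld.variant_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se_arr,
            "pval": _pvalues(beta, se_arr),
            "n": float(n),
        }
    )


def simulate_qtl_sumstats(
    truth: SimTruth,
    ld: LDMatrix,
    n_causal: int,
    effect_sd: float = 0.1,
    seed: int | None = None,
    sampling_noise: bool = True,
    palindrome_fraction: float = 0.0,
    causal_indices: Sequence[int] | None = None,
    causal_effects: Sequence[float] | None = None,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 2_000,
) -> pd.DataFrame:
    """Simulate cis-QTL marginal summary statistics for one region.

    True joint effects for the ``n_causal`` variants have random sign and
    magnitude uniform on [0.4, 1.6] x ``effect_sd`` (or are fixed via
    ``causal_indices``/``causal_effects``); marginals are
    ``R @ b_true`` plus correlated sampling noise MVN(0, R/n). The returned
    frame carries the noise-free marginals in ``attrs['true_marginal']``.
    """
    m = len(ld.variant_ids)
    if n_causal > m:
        raise ValueError(f"n_causal {n_causal} exceeds {m} variants")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    b_true = np.zeros(m)
    if causal_indices is not None:
        idx = np.asarray(causal_indices, dtype=int)
    else:
        idx = rng.choice(m, size=n_causal, replace=False) if n_causal else np.array([], int)
    if causal_effects is not None:
        b_true[idx] = np.asarray(causal_effects, dtype=float)
    elif len(idx):
        # random sign, magnitude bounded away from zero: cis-QTL sources
        # ascertain genes with genuinely significant signals, so a "causal"
        # region always carries one
        magnitude = effect_sd * rng.uniform(0.4, 1.6, size=len(idx))
        b_true[idx] = rng.choice([-1.0, 1.0], size=len(idx)) * magnitude

    true_marginal = ld.r @ b_true
    se = 1.0 / np.sqrt(truth.n_exposure)
    beta_hat = true_marginal.copy()
    if sampling_noise:
        beta_hat = beta_hat + se * (_psd_root(ld.r) @ rng.standard_normal(m))

    ea, oa, eaf = _assign_alleles(rng, m, palindrome_fraction)
    pos = pos_start + pos_step * np.arange(m)
    df = _sumstats_frame(ld, beta_hat, se, truth.n_exposure, ea, oa, eaf, chrom, pos)
    df.attrs["true_marginal"] = true_marginal
    df.attrs["b_true"] = b_true
    truth.true_marginal_exposure = true_marginal
    return df


def simulate_outcome_gwas(
    truth: SimTruth,
    exposure_table: pd.DataFrame,
    ld: LDMatrix,
    seed: int | None = None,
    sampling_noise: bool = True,
    case_fraction: float = 0.035,
) -> pd.DataFrame:
    """Simulate a binary-outcome GWAS over the exposure's variant set.

    Marginal log-odds effect at variant j:
    ``causal_beta * true_exposure_marginal_j + (R @ a)_j + noise`` where a
    are per-variant direct effects under the configured pleiotropy mode.
    Sampling noise is MVN(0, se^2 R) with se = 1/sqrt(n_outcome*phi*(1-phi)).
    """
    ids = list(exposure_table["variant_id"])
    if ids != list(ld.variant_ids):
        raise ValueError("variant set/order mismatch between exposure table and LD matrix")
    m = len(ids)
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)

    exp_marginal = exposure_table.attrs.get("true_marginal")
    if exp_marginal is None:
        exp_marginal = exposure_table["beta"].to_numpy()
    exp_marginal = np.asarray(exp_marginal, dtype=float)

    if truth.pleiotropy_mode == "none":
        direct = np.zeros(m)
    else:
        direct = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, size=m)
    truth.direct_effects = direct

    true_marginal = truth.causal_beta * exp_marginal + ld.r @ direct
    v = case_fraction * (1.0 - case_fraction)
    se = 1.0 / np.sqrt(truth.n_outcome * v)
    beta_hat = true_marginal.copy()
    if sampling_noise:
        beta_hat = beta_hat + se * (_psd_root(ld.r) @ rng.standard_normal(m))

    df = _sumstats_frame(
        ld,
        beta_hat,
        se,
        truth.n_outcome,
        list(exposure_table["effect_allele"]),
        list(exposure_table["other_allele"]),
        exposure_table["eaf"].to_numpy(),
        str(exposure_table["chrom"].iloc[0]),
        exposure_table["pos"].to_numpy(),
    )
    df.attrs["true_marginal"] = true_marginal
    df.attrs["direct_effects"] = direct
    return df


def simulate_mediation_region(
    truth: SimTruth,
    ld: LDMatrix,
    n_causal: int = 1,
    effect_sd: float = 0.3,
    seed: int | None = None,
    sampling_noise: bool = True,
    n_methylation: int | None = None,
    case_fraction: float = 0.035,
    **qtl_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a methylation -> expression -> outcome chain over one region.

    Returns (mQTL, eQTL, GWAS) tables sharing variants and alleles. With
    noise off the marginal chain is exact: expression = b_meth_expr x
    methylation, outcome = b_expr_outcome x expression, variant by variant.
    """
    if truth.mediation_chain is None:
        raise ValueError("truth.mediation_chain must be set for mediation regions")
    b_me, b_eo = truth.mediation_chain
    base_seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    m = len(ld.variant_ids)
    n_meth = truth.n_exposure if n_methylation is None else n_methylation

    meth_truth = SimTruth(
        gene_id=truth.gene_id, n_exposure=n_meth, n_outcome=truth.n_outcome,
        seed=base_seed,
    )
    mqtl = simulate_qtl_sumstats(
        meth_truth, ld, n_causal, effect_sd,
        seed=base_seed, sampling_noise=sampling_noise, **qtl_kwargs,
    )
    meth_marginal = mqtl.attrs["true_marginal"]

    expr_marginal = b_me * meth_marginal
    se_e = 1.0 / np.sqrt(truth.n_exposure)
    expr_hat = expr_marginal.copy()
    if sampling_noise:
        expr_hat = expr_hat + se_e * (_psd_root(ld.r) @ rng.standard_normal(m))
    eqtl = _sumstats_frame(
        ld, expr_hat, se_e, truth.n_exposure,
        list(mqtl["effect_allele"]), list(mqtl["other_allele"]),
        mqtl["eaf"].to_numpy(), str(mqtl["chrom"].iloc[0]), mqtl["pos"].to_numpy(),
    )
    eqtl.attrs["true_marginal"] = expr_marginal

    out_marginal = b_eo * expr_marginal
    v = case_fraction * (1.0 - case_fraction)
    se_o = 1.0 / np.sqrt(truth.n_outcome * v)
    out_hat = out_marginal.copy()
    if sampling_noise:
        out_hat = out_hat + se_o * (_psd_root(ld.r) @ rng.standard_normal(m))
    gwas = _sumstats_frame(
        ld, out_hat, se_o, truth.n_outcome,
        list(mqtl["effect_allele"]), list(mqtl["other_allele"]),
        mqtl["eaf"].to_numpy(), str(mqtl["chrom"].iloc[0]), mqtl["pos"].to_numpy(),
    )
    gwas.attrs["true_marginal"] = out_marginal
    gwas.attrs["chain_signs"] = (np.sign(b_me), np.sign(b_eo), np.sign(b_me * b_eo))
    return mqtl, eqtl, gwas


def simulate_study(
    n_genes: int = 10,
    n_causal_genes: int = 1,
    causal_beta: float = 0.3,
    n_variants: int = 30,
    n_causal_variants: int = 3,
    effect_sd: float = 0.25,
    rho: float = 0.5,
    pleiotropy_mode: str = "none",
    pleiotropy_sd: float = 0.0,
    pleiotropy_mean: float = 0.0,
    n_exposure: int = 30_000,
    n_outcome_discovery: int = 250_000,
    n_outcome_replication: int = 250_000,
    palindrome_fraction: float = 0.1,
    seed: int = 0,
) -> dict[str, dict]:
    """Simulate a whole two-cohort study: per-gene regions with known truth.

    The first ``n_causal_genes`` genes carry ``causal_beta`` (and the
    configured pleiotropy); the rest are null. Returns a dict keyed by
    gene id with entries ``gene`` (annotation), ``exposure``, ``ld``,
    ``gwas_discovery``, ``gwas_replication`` and ``truth``. Discovery and
    replication outcome cohorts are simulated independently (non-overlapping
    samples).
    """
    block = max(2, n_variants // 3)
    blocks = [block] * (n_variants // block)
    if sum(blocks) < n_variants:
        blocks[-1] += n_variants - sum(blocks)
    study: dict[str, dict] = {}
    for g in range(n_genes):
        gene_id = f"GENE{g + 1:03d}"
        beta = causal_beta if g < n_causal_genes else 0.0
        mode = pleiotropy_mode if beta != 0 else "none"
        truth = SimTruth(
            gene_id=gene_id, causal_beta=beta, pleiotropy_mode=mode,
            pleiotropy_sd=pleiotropy_sd if mode != "none" else 0.0,
            pleiotropy_mean=pleiotropy_mean if mode == "directional" else 0.0,
            n_exposure=n_exposure, n_outcome=n_outcome_discovery,
            seed=seed + 9973 * g,
        )
        ld = simulate_ld_matrix(n_variants, blocks, rho)
        pos_start = 1_000_000 + g * 10_000_000
        exposure = simulate_qtl_sumstats(
            truth, ld, n_causal_variants, effect_sd, chrom="1",
            pos_start=pos_start, palindrome_fraction=palindrome_fraction,
        )
        gwas_d = simulate_outcome_gwas(truth, exposure, ld, seed=truth.seed + 1)
        truth_rep = SimTruth(
            gene_id=gene_id, causal_beta=beta, pleiotropy_mode=mode,
            pleiotropy_sd=truth.pleiotropy_sd, pleiotropy_mean=truth.pleiotropy_mean,
            n_exposure=n_exposure, n_outcome=n_outcome_replication,
            seed=truth.seed,
        )
        gwas_r = simulate_outcome_gwas(truth_rep, exposure, ld, seed=truth.seed + 2)
        gene = GeneAnnotation(
            gene_id, "1", pos_start + 10_000, pos_start + (n_variants - 5) * 2_000
        )
        study[gene_id] = {
            "gene": gene, "exposure": exposure, "ld": ld,
            "gwas_discovery": gwas_d, "gwas_replication": gwas_r, "truth": truth,
        }
    return study
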