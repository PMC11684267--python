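"""Summary-data-based MR (SMR), the HEIDI linkage test, and mediation logic.

The SMR statistic at the region's top QTL variant is

    T_SMR = z_qtl^2 z_gwas^2 / (z_qtl^2 + z_gwas^2)  ~  chi^2_1,

with effect b_smr = b_gwas / b_qtl and delta-method standard error
|b_smr| sqrt(1/z_qtl^2 + 1/z_gwas^2). HEIDI asks whether the per-variant SMR
effects in the region are mutually consistent with a single shared causal
variant: deviations d_i = b_smr(i) - b_smr(top) are jointly tested against
their LD-induced covariance; heterogeneity (low p) indicates distinct causal
variants in linkage rather than pleiotropy.

The three-step mediation analysis chains gene expression -> outcome,
methylation -> outcome, and methylation -> expression SMR tests, requiring
nominal SMR significance at every step, genome-wide significant top
variants (p < 5e-8), and HEIDI p > 0.01 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import harmonize_tables, kept_pairs
from .io import LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SMRRecord",
    "MediationVerdict",
    "smr_test",
    "heidi_test",
    "three_step_smr",
    "protein_consistency",
]

HEIDI_P_QTL_THRESHOLD = stats.chi2.sf(10.0, 1)  # z^2 > 10, ~1.57e-3
HEIDI_MAX_SNPS = 20
HEIDI_MIN_SNPS = 3
GENOME_WIDE_P = 5e-8


@dataclass
class SMRRecord:
    probe_id: str
    top_snp: str
    b_qtl: float
    se_qtl: float
    p_qtl: float
    b_gwas: float
    se_gwas: float
    p_gwas: float
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: float | None = None
    n_heidi_snps: int = 0


@dataclass
class MediationVerdict:
    gene_id: str
    cpg_id: str
    step1: SMRRecord  # gene expression -> outcome
    step2: SMRRecord  # methylation -> outcome
    step3: SMRRecord  # methylation -> gene expression
    gw_significant: bool
    heidi_pass: bool
    sign_chain_consistent: bool
    verdict: bool


def _aligned(qtl: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    pairs = kept_pairs(harmonize_tables(qtl, gwas))
    if not len(pairs):
        raise ValueError("no shared harmonizable variants between QTL and GWAS tables")
    return pairs


def _top_index(pairs: pd.DataFrame) -> int:
    """Index of the strongest QTL variant: max |z| (avoids p-value underflow
    ties), then lexicographic variant id for determinism."""
    z = np.abs(pairs["beta_exp"].to_numpy(float) / pairs["se_exp"].to_numpy(float))
    ids = pairs["variant_id"].astype(str).to_numpy()
    return int(np.lexsort((ids, -z))[0])


def smr_statistic(z_qtl: float, z_gwas: float) -> float:
    denom = z_qtl**2 + z_gwas**2
    return 0.0 if denom == 0 else (z_qtl**2 * z_gwas**2) / denom


def smr_test(qtl: pd.DataFrame, gwas: pd.DataFrame, probe_id: str = "") -> SMRRecord:
    """SMR association test at the top QTL variant of the shared region."""
    pairs = _aligned(qtl, gwas)
    p_qtl = 2.0 * stats.norm.sf(np.abs(pairs["beta_exp"] / pairs["se_exp"]))
    top = _top_index(pairs)
    row = pairs.iloc[top]
    if row["beta_exp"] == 0:
        raise ZeroDivisionError("top variant has zero QTL effect; SMR ratio undefined")
    z_q = float(row["beta_exp"] / row["se_exp"])
    z_g = float(row["beta_out"] / row["se_out"])
    t_smr = smr_statistic(z_q, z_g)
    b_smr = float(row["beta_out"] / row["beta_exp"])
    if z_g == 0:
        se_smr = float(row["se_out"] / abs(row["beta_exp"]))
    else:
        se_smr = abs(b_smr) * float(np.sqrt(1.0 / z_q**2 + 1.0 / z_g**2))
    return SMRRecord(
        probe_id=probe_id,
        top_snp=str(row["variant_id"]),
        b_qtl=float(row["beta_exp"]), se_qtl=float(row["se_exp"]), p_qtl=float(p_qtl[top]),
        b_gwas=float(row["beta_out"]), se_gwas=float(row["se_out"]),
        p_gwas=float(2.0 * stats.norm.sf(abs(z_g))),
        b_smr=b_smr, se_smr=se_smr, p_smr=float(stats.chi2.sf(t_smr, 1)),
    )


def _heidi_covariance(pairs: pd.DataFrame, ld: LDMatrix, eligible: np.ndarray, top: int):
    """Delta-method covariance of d_i = b_smr(i) - b_smr(top) under LD."""
    ids = pairs["variant_id"].astype(str).to_list()
    sub = ld.submatrix(ids)
    bq = pairs["beta_exp"].to_numpy(float)
    sq = pairs["se_exp"].to_numpy(float)
    by = pairs["beta_out"].to_numpy(float)
    sy = pairs["se_out"].to_numpy(float)
    r = sub.r
    # cov(b_smr_i, b_smr_j) for independent QTL and GWAS samples
    cov_s = r * np.outer(sy, sy) / np.outer(bq, bq) + (
        np.outer(by, by) / np.outer(bq**2, bq**2) * r * np.outer(sq, sq)
    )
    idx = np.asarray(eligible, dtype=int)
    c_ii = cov_s[np.ix_(idx, idx)]
    c_it = cov_s[idx, top]
    c_tt = cov_s[top, top]
    return c_ii - c_it[:, None] - c_it[None, :] + c_tt


def heidi_test(
    qtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    p_qtl_threshold: float = HEIDI_P_QTL_THRESHOLD,
    max_snps: int = HEIDI_MAX_SNPS,
    min_snps: int = HEIDI_MIN_SNPS,
    method: str = "satterthwaite",
    mc_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float | None, int]:
    """HEIDI heterogeneity test; returns (p_heidi, n_snps_used).

    Eligible variants have QTL p below ``p_qtl_threshold`` (z^2 > 10),
    excluding the top variant, capped at the ``max_snps`` strongest. The sum
    of squared standardized deviations is referred to its correlated-chi^2
    null via Satterthwaite moment matching (or an eigenvalue Monte Carlo
    with ``method='eigen-mc'``). Fewer than ``min_snps`` eligible variants
    leaves p undefined (returned as None).
    """
    pairs = _aligned(qtl, gwas)
    z_qtl = np.abs(pairs["beta_exp"].to_numpy(float) / pairs["se_exp"].to_numpy(float))
    p_qtl = 2.0 * stats.norm.sf(z_qtl)
    top = _top_index(pairs)
    eligible = np.flatnonzero((p_qtl < p_qtl_threshold) & (np.arange(len(pairs)) != top))
    if len(eligible) > max_snps:
        eligible = eligible[np.argsort(-z_qtl[eligible], kind="mergesort")[:max_snps]]
    n_used = int(len(eligible))
    if n_used < min_snps:
        return None, n_used

    s = pairs["beta_out"].to_numpy(float) / pairs["beta_exp"].to_numpy(float)
    d = s[eligible] - s[top]
    cov = _heidi_covariance(pairs, ld, eligible, top)
    var = np.diag(cov).copy()
    var[var <= 0] = np.finfo(float).tiny
    z = d / np.sqrt(var)
    t = float(np.sum(z**2))
    corr = cov / np.sqrt(np.outer(var, var))
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    if method == "satterthwaite":
        s1, s2 = float(np.sum(lam)), float(np.sum(lam**2))
        if s2 == 0:
            return 1.0, n_used
        scale = s2 / s1
        df = s1**2 / s2
        p = float(stats.chi2.sf(t / scale, df))
    elif method == "eigen-mc":
        rng = np.random.default_rng(seed)
        draws = rng.chisquare(1, size=(mc_draws, len(lam))) @ lam
        p = float((np.sum(draws >= t) + 1) / (mc_draws + 1))
    else:
        raise ValueError(f"unknown HEIDI tail method {method!r}")
    return p, n_used


def smr_with_heidi(
    qtl: pd.DataFrame, gwas: pd.DataFrame, ld: LDMatrix, probe_id: str = "", **heidi_kwargs
) -> SMRRecord:
    rec = smr_test(qtl, gwas, probe_id)
    p_heidi, n_used = heidi_test(qtl, gwas, ld, **heidi_kwargs)
    rec.p_heidi = p_heidi
    rec.n_heidi_snps = n_used
    return rec


def three_step_smr(
    gene_eqtl: pd.DataFrame,
    cpg_mqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LDMatrix,
    gene_id: str = "GENE",
    cpg_id: str = "CPG",
    smr_alpha: float = 0.05,
    heidi_alpha: float = 0.01,
    gw_threshold: float = GENOME_WIDE_P,
    heidi_missing_fails: bool = True,
    **heidi_kwargs,
) -> MediationVerdict:
    """Three-step methylation-mediation SMR over one shared region.

    Step 1 tests expression -> outcome, step 2 methylation -> outcome, step 3
    methylation -> expression. The verdict requires p_SMR < 0.05 at all
    steps, genome-wide significant instruments throughout, and HEIDI p > 0.01
    (an undefined HEIDI p fails conservatively by default). The sign chain is
    consistent when sign(step3) x sign(step1) equals sign(step2).
    """
    step1 = smr_with_heidi(gene_eqtl, gwas, ld, gene_id, **heidi_kwargs)
    step2 = smr_with_heidi(cpg_mqtl, gwas, ld, cpg_id, **heidi_kwargs)
    step3 = smr_with_heidi(cpg_mqtl, gene_eqtl, ld, f"{cpg_id}->{gene_id}", **heidi_kwargs)
    steps = (step1, step2, step3)

    smr_pass = all(rec.p_smr < smr_alpha for rec in steps)
    gw = all(rec.p_qtl < gw_threshold and rec.p_gwas < gw_threshold for rec in steps)

    def heidi_ok(rec: SMRRecord) -> bool:
        if rec.p_heidi is None:
            return not heidi_missing_fails
        return rec.p_heidi > heidi_alpha

    heidi_pass = all(heidi_ok(rec) for rec in steps)
    sign_chain = bool(
        np.sign(step3.b_smr) * np.sign(step1.b_smr) == np.sign(step2.b_smr)
        and np.sign(step2.b_smr) != 0
    )
    verdict = smr_pass and gw and heidi_pass
    return MediationVerdict(
        gene_id, cpg_id, step1, step2, step3, gw, heidi_pass, sign_chain, verdict
    )


def protein_consistency(
    smr_transcript: SMRRecord,
    smr_protein: SMRRecord,
    smr_alpha: float = 0.05,
    heidi_alpha: float = 0.01,
) -> bool:
    """Direction agreement between transcript- and protein-level SMR effects.

    Both records must themselves be significant (p_SMR below ``smr_alpha``)
    and pass HEIDI (p above ``heidi_alpha``); otherwise consistency is
    undefined and reported False with a log line.
    """
    for rec in (smr_transcript, smr_protein):
        if rec.p_smr >= smr_alpha or rec.p_heidi is None or rec.p_heidi <= heidi_alpha:
            logger.info(
                "protein consistency undefined for %s (p_smr=%.3g, p_heidi=%s)",
                rec.probe_id, rec.p_smr, rec.p_heidi,
            )
            return False
    return bool(np.sign(smr_transcript.b_smr) == np.sign(smr_protein.b_smr) != 0)
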