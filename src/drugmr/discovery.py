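"""Gene-level discovery: multiplicity gating, replication, and meta-analysis.

A gene is called only when its discovery-cohort IVW p-value survives all
three multiplicity adjustments (Bonferroni, Benjamini-Hochberg, q-value),
the five auxiliary estimators agree in sign with IVW, and the fixed/random
two-cohort meta-analysis of the IVW estimates is significant at 0.05. The
meta-analysis model is chosen by I^2: fixed-effect inverse-variance pooling
when I^2 < 50%, DerSimonian-Laird random effects otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import harmonize as hz
from . import instruments as ins
from . import mr
from .io import GeneAnnotation, LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "adjust_pvalues",
    "qvalues",
    "direction_consistency",
    "meta_analyze",
    "GeneData",
    "DiscoveryConfig",
    "discovery_pipeline",
]


def qvalues(pvals: np.ndarray) -> np.ndarray:
    """Storey-style q-values with pi0 from a cubic smoother on a lambda grid.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on
    lambda in {0.05, ..., 0.95}; a cubic polynomial fit is extrapolated to
    lambda = 1 and clipped to (0, 1]. q-values are pi0 times the BH step-up
    values, so q <= BH whenever pi0 <= 1.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value vector")
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    if m < 8 or np.allclose(pi0_lam, 0):
        pi0 = 1.0
    else:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, 1.0))
    pi0 = min(1.0, max(pi0, 1.0 / m))
    bh = multipletests(p, method="fdr_bh")[1]
    return np.minimum(1.0, pi0 * bh)


def adjust_pvalues(pvals, method: str) -> np.ndarray:
    """Multiplicity adjustment: 'bonferroni', 'bh' (step-up), or 'qvalue'."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(1.0, p * len(p))
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "qvalue":
        return qvalues(p)
    raise ValueError(f"unknown adjustment method {method!r}")


def direction_consistency(
    results: dict[str, mr.MRResult], strict: bool = True
) -> bool:
    """True iff every auxiliary estimate shares the IVW estimate's sign.

    An exactly-zero beta matches no sign. With ``strict`` (default) a missing
    auxiliary method fails the check; otherwise it is skipped with a log line.
    """
    ivw = results.get("ivw")
    if ivw is None:
        raise ValueError("IVW result required for the direction check")
    s_ivw = np.sign(ivw.beta)
    if s_ivw == 0:
        return False
    for method in mr.AUXILIARY_METHODS:
        res = results.get(method)
        if res is None:
            if strict:
                return False
            logger.info("direction check: %s unavailable, skipped", method)
            continue
        if np.sign(res.beta) != s_ivw:
            return False
    return True


def meta_analyze(b1: float, se1: float, b2: float, se2: float):
    """Two-cohort meta-analysis, model chosen by I^2.

    Fixed-effect inverse-variance pooling when I^2 < 50%; otherwise
    DerSimonian-Laird random effects. Returns
    (meta_beta, meta_se, meta_pval, i_squared, model).
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    b = np.array([b1, b2])
    w = np.array([1.0 / se1**2, 1.0 / se2**2])
    beta_f = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_f) ** 2))
    i2 = max(0.0, (q - 1.0) / q) * 100.0 if q > 0 else 0.0
    if i2 < 50.0:
        beta, se, model = beta_f, float(1.0 / np.sqrt(np.sum(w))), "fixed"
    else:
        tau2 = max(0.0, (q - 1.0) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        wr = 1.0 / (1.0 / w + tau2)
        beta = float(np.sum(wr * b) / np.sum(wr))
        se = float(1.0 / np.sqrt(np.sum(wr)))
        model = "random"
    pval = float(2.0 * stats.norm.sf(abs(beta) / se))
    return beta, se, pval, i2, model


@dataclass
class GeneData:
    """All per-gene inputs the discovery pipeline needs."""

    gene: GeneAnnotation
    exposure: pd.DataFrame
    ld: LDMatrix
    gwas_discovery: pd.DataFrame
    gwas_replication: pd.DataFrame


@dataclass
class DiscoveryConfig:
    alpha: float = 0.05
    window_bp: int = ins.DEFAULT_WINDOW_BP
    r2_threshold: float = ins.DEFAULT_R2
    clump_window_kb: int = ins.DEFAULT_CLUMP_WINDOW_KB
    f_min: float = ins.DEFAULT_F_MIN
    fdr_alpha: float | None = 0.05
    maf_threshold: float = hz.DEFAULT_MAF_THRESHOLD
    steiger: bool = True
    radial_removal: bool = True
    strict_direction: bool = True
    require_replication_p: bool = False
    n_boot: int = 1000
    seed: int = 0
    run_presso: bool = False
    presso_nsim: int = 1000

    verdict_columns: tuple[str, ...] = field(
        default=(
            "gene_id", "k", "beta_ivw", "se_ivw", "pval_ivw", "ci_low", "ci_high",
            "cochran_q", "q_pval", "egger_intercept_pval",
            "p_bonferroni", "p_bh", "q_value",
            "passed_bonferroni", "passed_bh", "passed_qvalue",
            "direction_consistent",
            "beta_replication", "se_replication", "pval_replication",
            "meta_beta", "meta_se", "meta_pval", "i_squared", "meta_model",
            "final_call", "note",
        ),
        repr=False,
    )


def _fit_cohort(
    exposure_inst: pd.DataFrame, gwas: pd.DataFrame, config: DiscoveryConfig, gene_id: str
):
    pairs = hz.harmonize_pipeline(
        exposure_inst, gwas, config.maf_threshold, steiger=config.steiger
    )
    kept = hz.kept_pairs(pairs)
    if not len(kept):
        raise ValueError("no instruments survive harmonization")
    if config.radial_removal and len(kept) >= 3:
        bx, sx, by, sy, ids = mr.pairs_arrays(kept)
        report = mr.radial_outliers(bx, sx, by, sy, ids, gene_id, alpha=config.alpha)
        if report.outlier_ids and len(kept) - len(report.outlier_ids) >= 1:
            kept = kept.loc[~kept["variant_id"].isin(report.outlier_ids)].reset_index(drop=True)
    results = mr.run_mr_battery(kept, gene_id, seed=config.seed, n_boot=config.n_boot)
    return kept, results


def discovery_pipeline(
    gene_data: dict[str, GeneData], config: DiscoveryConfig | None = None
) -> pd.DataFrame:
    """Run the full two-cohort discovery workflow and return the verdict table.

    Per gene: instrument selection -> harmonization with the discovery GWAS
    -> Radial outlier removal -> estimator battery; then multiplicity gates
    across genes, replication IVW, and the I^2-gated meta-analysis. One
    gene's failure is isolated (its verdict row records the reason).
    """
    config = config or DiscoveryConfig()
    per_gene: dict[str, dict] = {}
    for gene_id, data in gene_data.items():
        entry: dict = {"note": ""}
        try:
            inst = ins.build_instruments(
                data.exposure, data.gene, data.ld,
                window_bp=config.window_bp, r2_threshold=config.r2_threshold,
                clump_window_kb=config.clump_window_kb, f_min=config.f_min,
                fdr_alpha=config.fdr_alpha,
            )
            if not len(inst):
                raise ValueError("no instruments after selection")
            kept, results = _fit_cohort(inst, data.gwas_discovery, config, gene_id)
            entry["instruments"] = inst
            entry["kept"] = kept
            entry["results"] = results
        except Exception as exc:  # noqa: BLE001 - gene-level isolation
            logger.warning("gene %s failed: %s", gene_id, exc)
            entry["note"] = f"failed: {exc}"
        per_gene[gene_id] = entry

    tested = [g for g, e in per_gene.items() if "results" in e]
    if tested:
        pvec = np.array([per_gene[g]["results"]["ivw"].pval for g in tested])
        pvec = np.clip(pvec, np.finfo(float).tiny, 1.0)
        p_bonf = adjust_pvalues(pvec, "bonferroni")
        p_bh = adjust_pvalues(pvec, "bh")
        q_val = adjust_pvalues(pvec, "qvalue")
        for i, g in enumerate(tested):
            per_gene[g]["adj"] = (p_bonf[i], p_bh[i], q_val[i])

    rows = []
    for gene_id, entry in per_gene.items():
        row = dict.fromkeys(config.verdict_columns)
        row["gene_id"] = gene_id
        row["note"] = entry["note"]
        row["final_call"] = False
        if "results" not in entry:
            rows.append(row)
            continue
        res = entry["results"]
        ivw = res["ivw"]
        row.update(
            k=ivw.k, beta_ivw=ivw.beta, se_ivw=ivw.se, pval_ivw=ivw.pval,
            ci_low=ivw.ci[0], ci_high=ivw.ci[1],
            cochran_q=ivw.cochran_q, q_pval=ivw.q_pval,
            egger_intercept_pval=res["egger"].intercept_pval if "egger" in res else None,
        )
        p_bonf, p_bh, q_val = entry["adj"]
        row.update(
            p_bonferroni=p_bonf, p_bh=p_bh, q_value=q_val,
            passed_bonferroni=bool(p_bonf < config.alpha),
            passed_bh=bool(p_bh < config.alpha),
            passed_qvalue=bool(q_val < config.alpha),
        )
        try:
            row["direction_consistent"] = direction_consistency(
                res, strict=config.strict_direction
            )
        except ValueError:
            row["direction_consistent"] = False

        gates = (
            row["passed_bonferroni"] and row["passed_bh"] and row["passed_qvalue"]
            and row["direction_consistent"]
        )
        if gates:
            data = gene_data[gene_id]
            try:
                _, res_rep = _fit_cohort(
                    entry["instruments"], data.gwas_replication, config, gene_id
                )
                ivw_rep = res_rep["ivw"]
                row.update(
                    beta_replication=ivw_rep.beta, se_replication=ivw_rep.se,
                    pval_replication=ivw_rep.pval,
                )
                mb, ms, mp, i2, model = meta_analyze(
                    ivw.beta, ivw.se, ivw_rep.beta, ivw_rep.se
                )
                row.update(meta_beta=mb, meta_se=ms, meta_pval=mp, i_squared=i2, meta_model=model)
                final = mp < config.alpha
                if config.require_replication_p:
                    final = final and ivw_rep.pval < config.alpha
                row["final_call"] = bool(final)
            except Exception as exc:  # noqa: BLE001
                logger.warning("gene %s replication failed: %s", gene_id, exc)
                row["note"] = f"replication failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=list(config.verdict_columns))
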