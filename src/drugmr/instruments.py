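"""Per-gene instrument construction: cis window, PVE/F, weak-IV and LD filters.

Instrument strength is summarized by the proportion of variance explained,

    PVE = beta^2 / (beta^2 + N * se^2)

and the single-variant F-statistic

    F = ((N - k - 1) / k) * PVE / (1 - PVE)        (k = 1 per variant).

Variants with F < 10 are excluded (strict: F = 10 is retained). LD clumping
is greedy by ascending p-value at r^2 < 0.1 within a 10,000 kb window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation, LDMatrix

DEFAULT_WINDOW_BP = 100_000
DEFAULT_R2 = 0.1
DEFAULT_CLUMP_WINDOW_KB = 10_000
DEFAULT_F_MIN = 10.0


def cis_window_filter(
    sumstats: pd.DataFrame, gene: GeneAnnotation, window_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """Keep variants on the gene's chromosome with pos in [start-w, end+w] (inclusive)."""
    lo, hi = gene.start - window_bp, gene.end + window_bp
    mask = (
        (sumstats["chrom"].astype(str) == str(gene.chrom))
        & (sumstats["pos"] >= lo)
        & (sumstats["pos"] <= hi)
    )
    return sumstats.loc[mask].reset_index(drop=True)


def compute_pve(beta, se, n):
    """Proportion of variance explained; vectorized over array inputs."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if np.any(n <= 0):
        raise ValueError("n must be > 0")
    out = beta**2 / (beta**2 + n * se**2)
    return float(out) if out.ndim == 0 else out


def compute_f_stat(pve, n, k: int = 1):
    """Instrument F-statistic from PVE and sample size (k parameters)."""
    pve = np.asarray(pve, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((pve < 0) | (pve >= 1)):
        raise ValueError("pve must lie in [0, 1)")
    if np.any(n <= k + 1):
        raise ValueError(f"n must exceed k+1 = {k + 1}")
    out = (n - k - 1) / k * pve / (1.0 - pve)
    return float(out) if out.ndim == 0 else out


def fdr_prefilter(sumstats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg significance prefilter applied within the gene."""
    if not len(sumstats):
        return sumstats
    reject, *_ = multipletests(sumstats["pval"].to_numpy(), alpha=alpha, method="fdr_bh")
    return sumstats.loc[reject].reset_index(drop=True)


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_R2,
    window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
) -> pd.DataFrame:
    """Greedy p-value clumping.

    Repeatedly retain the remaining variant with the smallest p-value and
    drop all others within ``window_kb`` that have r^2 >= threshold with it.
    Ties broken by (pval, position, variant_id) for platform determinism.
    """
    if not len(candidates):
        return candidates
    df = candidates.sort_values(
        ["pval", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = window_kb * 1_000
    remaining = list(df.index)
    kept: list[int] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        vid_b = df.at[best, "variant_id"]
        pos_b = df.at[best, "pos"]
        survivors = []
        for i in remaining:
            if abs(df.at[i, "pos"] - pos_b) <= window_bp:
                if ld.r2(vid_b, df.at[i, "variant_id"]) >= r2_threshold:
                    continue
            survivors.append(i)
        remaining = survivors
    out = df.loc[kept]
    return out.sort_values(["pos", "variant_id"], kind="mergesort").reset_index(drop=True)


def build_instruments(
    sumstats: pd.DataFrame,
    gene: GeneAnnotation,
    ld: LDMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    r2_threshold: float = DEFAULT_R2,
    clump_window_kb: int = DEFAULT_CLUMP_WINDOW_KB,
    f_min: float = DEFAULT_F_MIN,
    fdr_alpha: float | None = 0.05,
) -> pd.DataFrame:
    """Full instrument selection for one gene.

    cis window -> per-gene FDR prefilter (optional) -> PVE/F annotation ->
    weak-instrument exclusion (F < f_min) -> LD clumping. Returns the
    retained candidates with ``pve``, ``f_stat`` and ``gene_id`` columns.
    """
    df = cis_window_filter(sumstats, gene, window_bp)
    if fdr_alpha is not None:
        df = fdr_prefilter(df, fdr_alpha)
    if not len(df):
        return df.assign(pve=[], f_stat=[], gene_id=[])
    df = df.copy()
    df["pve"] = compute_pve(df["beta"], df["se"], df["n"])
    df["f_stat"] = compute_f_stat(df["pve"], df["n"], k=1)
    df = df.loc[df["f_stat"] >= f_min].reset_index(drop=True)
    df = ld_clump(df, ld, r2_threshold, clump_window_kb)
    df["gene_id"] = gene.gene_id
    return df
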