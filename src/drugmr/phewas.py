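"""Phenome-wide MR scan of fixed per-gene instruments across many outcome traits.

Each gene's instrument set is harmonized against every trait GWAS and fitted
with IVW (Wald ratio when a single instrument survives). Significance is
Bonferroni-gated at alpha / m; in strict mode (default) m is the number of
traits requested, mirroring a fixed phenome size, otherwise the number
scanned successfully. When a gene's disease-effect sign is supplied, each
significant trait is labelled beneficial or adverse: targeting the gene in
its disease-protective direction shifts the trait by
-sign(disease beta) x trait beta, and a negative shift (risk reduction) is
beneficial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import harmonize as hz
from . import mr

logger = logging.getLogger(__name__)

__all__ = ["TraitSpec", "phewas_scan"]

PHEWAS_COLUMNS = [
    "gene_id", "trait_id", "trait_category", "method", "beta", "se", "pval", "k",
    "significant", "direction_label",
]


@dataclass(frozen=True)
class TraitSpec:
    trait_id: str
    category: str
    gwas: pd.DataFrame


def _fit_one(instruments: pd.DataFrame, gwas: pd.DataFrame, gene_id: str):
    pairs = hz.kept_pairs(hz.harmonize_pipeline(instruments, gwas))
    if not len(pairs):
        raise ValueError("no instruments survive harmonization")
    bx, sx, by, sy, _ = mr.pairs_arrays(pairs)
    if len(bx) == 1:
        return mr.wald_ratio(bx, sx, by, sy, gene_id)
    return mr.ivw_mre(bx, sx, by, sy, gene_id)


def phewas_scan(
    instruments_by_gene: dict[str, pd.DataFrame],
    traits: list[TraitSpec],
    alpha: float = 0.05,
    strict_m: bool = True,
    disease_sign_by_gene: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Scan every gene x trait pair; returns a table sorted by p-value.

    Per-trait failures are isolated and logged; in non-strict mode they
    reduce the Bonferroni denominator m.
    """
    if not traits:
        raise ValueError("at least one trait is required")
    m_requested = len(traits)
    rows = []
    failed: set[str] = set()
    for gene_id, inst in instruments_by_gene.items():
        for spec in traits:
            try:
                res = _fit_one(inst, spec.gwas, gene_id)
            except Exception as exc:  # noqa: BLE001 - per-trait isolation
                logger.warning("gene %s x trait %s failed: %s", gene_id, spec.trait_id, exc)
                failed.add(spec.trait_id)
                continue
            rows.append(
                {
                    "gene_id": gene_id, "trait_id": spec.trait_id,
                    "trait_category": spec.category, "method": res.method,
                    "beta": res.beta, "se": res.se, "pval": res.pval, "k": res.k,
                }
            )
    m = m_requested if strict_m else max(1, m_requested - len(failed))
    threshold = alpha / m
    out = pd.DataFrame(rows, columns=[c for c in PHEWAS_COLUMNS if c not in ("significant", "direction_label")])
    out["significant"] = out["pval"] < threshold
    labels = []
    for _, r in out.iterrows():
        sign = (disease_sign_by_gene or {}).get(r["gene_id"])
        if sign in (None, 0) or not r["significant"]:
            labels.append("")
        else:
            shifted = -float(sign) * r["beta"]
            labels.append("beneficial" if shifted < 0 else "adverse")
    out["direction_label"] = labels
    out.attrs["bonferroni_m"] = m
    out.attrs["threshold"] = threshold
    return out.sort_values("pval", kind="mergesort").reset_index(drop=True)
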