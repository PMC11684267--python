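"""Allele harmonization, palindrome removal, and Steiger directionality filtering.

Harmonization signs both studies' effects to the exposure's effect allele:
matching allele pairs are kept as-is; swapped pairs (exposure A1/A2 equals
outcome A2/A1) flip the outcome beta sign and replace its frequency by
1 - eaf; any other allele combination is dropped as incompatible. Strand is
assumed forward in both studies, so ambiguity arises only for palindromic
(A/T, C/G) variants, which are removed when their minor-allele frequency
exceeds 0.42 in either study. Steiger filtering removes variants whose
variance explained in the outcome exceeds that in the exposure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .instruments import compute_pve

logger = logging.getLogger(__name__)

ACTIONS = ("kept", "flipped", "dropped_palindrome", "dropped_incompatible", "dropped_steiger")
PALINDROME_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
DEFAULT_MAF_THRESHOLD = 0.42

_EXP_COLS = {"beta": "beta_exp", "se": "se_exp", "n": "n_exp", "eaf": "eaf_exp"}
_OUT_COLS = {"beta": "beta_out", "se": "se_out", "n": "n_out", "eaf": "eaf_out"}


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return (effect_allele, other_allele) in PALINDROME_PAIRS


def harmonize_tables(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Merge exposure/outcome on variant_id and align to the exposure allele.

    Returns one row per shared variant with an ``action_taken`` column;
    incompatible variants are retained in the frame (action recorded), so
    kept + dropped always equals the intersection size.
    """
    exp = exposure.rename(columns=_EXP_COLS)
    out = outcome.rename(columns=_OUT_COLS)
    exp.attrs = {}  # array-valued attrs break pandas merge/concat
    out.attrs = {}
    merged = exp.merge(
        out[["variant_id", "effect_allele", "other_allele", "beta_out", "se_out", "n_out", "eaf_out"]],
        on="variant_id",
        suffixes=("", "_o"),
    )
    if not len(merged):
        merged["action_taken"] = pd.Series(dtype=str)
        return merged

    same = (merged["effect_allele"] == merged["effect_allele_o"]) & (
        merged["other_allele"] == merged["other_allele_o"]
    )
    swapped = (merged["effect_allele"] == merged["other_allele_o"]) & (
        merged["other_allele"] == merged["effect_allele_o"]
    )
    merged["action_taken"] = np.where(
        same, "kept", np.where(swapped, "flipped", "dropped_incompatible")
    )
    flip = merged["action_taken"] == "flipped"
    merged.loc[flip, "beta_out"] = -merged.loc[flip, "beta_out"]
    merged.loc[flip, "eaf_out"] = 1.0 - merged.loc[flip, "eaf_out"]
    return merged.drop(columns=["effect_allele_o", "other_allele_o"])


def palindrome_filter(
    pairs: pd.DataFrame, maf_threshold: float = DEFAULT_MAF_THRESHOLD
) -> pd.DataFrame:
    """Flag palindromic variants with intermediate MAF (> threshold) as dropped.

    The MAF criterion is applied to both studies' frequencies; a palindromic
    variant with a missing frequency is dropped conservatively.
    """
    live = pairs["action_taken"].isin(["kept", "flipped"])
    pal = pairs.apply(
        lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1
    ) if len(pairs) else pd.Series(dtype=bool)
    if not len(pairs):
        return pairs

    def maf(col: str) -> pd.Series:
        f = pairs[col]
        return np.minimum(f, 1.0 - f)

    intermediate = (maf("eaf_exp") > maf_threshold) | (maf("eaf_out") > maf_threshold)
    missing = pairs["eaf_exp"].isna() | pairs["eaf_out"].isna()
    drop = live & pal & (intermediate.fillna(False) | missing)
    pairs = pairs.copy()
    pairs.loc[drop, "action_taken"] = "dropped_palindrome"
    return pairs


def steiger_filter(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop variants that explain more variance in the outcome than the exposure.

    Deterministic comparison of the variance-explained formula on both sides;
    equality keeps the variant (strict inequality triggers the drop).
    """
    if not len(pairs):
        return pairs
    if pairs["n_exp"].isna().any() or pairs["n_out"].isna().any():
        raise ValueError("Steiger filtering requires sample sizes on both sides")
    live = pairs["action_taken"].isin(["kept", "flipped"])
    pve_exp = compute_pve(pairs["beta_exp"], pairs["se_exp"], pairs["n_exp"])
    pve_out = compute_pve(pairs["beta_out"], pairs["se_out"], pairs["n_out"])
    drop = live & (np.asarray(pve_out) > np.asarray(pve_exp))
    pairs = pairs.copy()
    pairs.loc[drop, "action_taken"] = "dropped_steiger"
    return pairs


def harmonize_pipeline(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    steiger: bool = True,
) -> pd.DataFrame:
    """Harmonize, remove ambiguous palindromes, optionally Steiger-filter.

    Returns the full per-variant table with ``action_taken``; downstream MR
    uses :func:`kept_pairs` on the result. Drop counts are logged per reason.
    """
    pairs = harmonize_tables(exposure, outcome)
    pairs = palindrome_filter(pairs, maf_threshold)
    if steiger:
        pairs = steiger_filter(pairs)
    counts = pairs["action_taken"].value_counts().to_dict()
    logger.info("harmonization actions: %s", counts)
    return pairs


def kept_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rows surviving every filter (actions ``kept`` or ``flipped``)."""
    return pairs.loc[pairs["action_taken"].isin(["kept", "flipped"])].reset_index(drop=True)
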