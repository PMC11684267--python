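"""Reading, validation and writing of summary-statistics tables and LD matrices.

All tabular inputs are tab-separated text with a ``#``-prefixed metadata
header. Coordinates are 1-based inclusive throughout (VCF convention).
Summary statistics are carried in memory as :class:`pandas.DataFrame`
objects with the canonical column set :data:`SUMSTATS_COLUMNS`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical per-variant columns for one trait. ``beta`` is the per-allele
#: effect of the effect allele: SD units for quantitative (QTL) exposures,
#: log-odds for binary outcomes. ``n`` is the association sample size.
SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float, "pval": float, "n": float}
_VALID_ALLELES = frozenset("ACGT")


class SchemaError(ValueError):
    """A required column is missing or the file layout is malformed."""


class ValidationError(ValueError):
    """A record violates a field invariant (alleles, ranges, duplicates)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Genomic footprint of one gene; ``start``/``end`` 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, not r^2) for an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise ValidationError(
                f"LD matrix shape {self.r.shape} does not match {n} variant ids"
            )
        asym = np.max(np.abs(self.r - self.r.T)) if n else 0.0
        if asym >= 1e-8:
            raise ValidationError(f"LD matrix asymmetric (max |r - r^T| = {asym:g})")
        self.r = (self.r + self.r.T) / 2.0
        if n and np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise ValidationError("LD matrix diagonal must be 1")
        if n and np.max(np.abs(self.r)) > 1.0 + 1e-8:
            raise ValidationError("LD correlations must satisfy |r| <= 1")
        if n:
            w = np.linalg.eigvalsh(self.r)
            if w.min() < -1e-8:
                raise ValidationError(
                    f"LD matrix not positive semi-definite (min eigenvalue {w.min():g})"
                )
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def submatrix(self, ids: Iterable[str]) -> "LDMatrix":
        ids = list(ids)
        try:
            idx = [self._index[v] for v in ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not present in LD matrix") from exc
        return LDMatrix(ids, self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]] ** 2)
        except KeyError as exc:
            raise KeyError(
                f"LD entry missing for pair ({a}, {b}): unknown variant {exc.args[0]!r}"
            ) from exc


def _apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def load_column_map(path: str | Path) -> dict[str, str]:
    """Load a YAML mapping {canonical name: file column name}."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise SchemaError(f"column map {path} must be a flat mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def validate_sumstats(
    df: pd.DataFrame,
    trait_kind: str = "quantitative",
    check_pval: bool = True,
) -> pd.DataFrame:
    """Validate and coerce a summary-statistics frame to the canonical schema.

    Rows with missing ``beta`` or ``se`` (or non-positive ``se``) are dropped
    with a logged count; structural problems raise.
    """
    if trait_kind not in ("quantitative", "binary"):
        raise ValueError(f"unknown trait_kind {trait_kind!r}")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[SUMSTATS_COLUMNS].copy()
    for col, typ in _NUMERIC.items():
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated variant_id(s): {', '.join(dup.unique()[:5])}")

    bad_alleles = ~(
        df["effect_allele"].isin(_VALID_ALLELES) & df["other_allele"].isin(_VALID_ALLELES)
    )
    if bad_alleles.any():
        vid = df.loc[bad_alleles, "variant_id"].iloc[0]
        raise ValidationError(f"non-ACGT allele at variant {vid}")
    same = df["effect_allele"] == df["other_allele"]
    if same.any():
        vid = df.loc[same, "variant_id"].iloc[0]
        raise ValidationError(f"effect and other allele identical at variant {vid}")

    droppable = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    if droppable.any():
        logger.warning("dropping %d row(s) with missing beta/se or se<=0", droppable.sum())
        df = df.loc[~droppable]

    if ((df["eaf"] < 0) | (df["eaf"] > 1)).any():
        raise ValidationError("eaf outside [0, 1]")
    if ((df["pval"] <= 0) | (df["pval"] > 1)).fillna(False).any():
        raise ValidationError("pval outside (0, 1]")

    if check_pval and len(df):
        z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
        expected = 2.0 * stats.norm.sf(z)
        p = df["pval"].to_numpy()
        # only judge where both are numerically representable
        ok = np.isnan(p) | (expected < 1e-280) | (np.abs(p - expected) <= 0.1 * np.maximum(expected, 1e-300))
        if not ok.all():
            vid = df.loc[~ok, "variant_id"].iloc[0]
            raise ValidationError(
                f"pval inconsistent with beta/se under the normal approximation at {vid}"
            )
    df["pos"] = df["pos"].astype(int)
    return df.reset_index(drop=True)


def read_sumstats(
    path: str | Path,
    trait_kind: str = "quantitative",
    column_map: Mapping[str, str] | None = None,
    check_pval: bool = True,
) -> pd.DataFrame:
    """Read one trait's tab-separated summary statistics and validate them."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df = _apply_column_map(df, column_map)
    return validate_sumstats(df, trait_kind=trait_kind, check_pval=check_pval)


def write_sumstats(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write summary statistics with a ``#`` metadata header, full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_ld_matrix(path: str | Path, expected_ids: Iterable[str] | None = None) -> LDMatrix:
    """Read a labelled square LD matrix (header row of variant ids)."""
    raw = pd.read_csv(path, sep=r"\s+", comment="#")
    ids = [str(c) for c in raw.columns]
    body = raw.to_numpy(dtype=float)
    if body.shape[0] != body.shape[1]:
        raise SchemaError(
            f"LD matrix not square: {body.shape[0]} rows vs {body.shape[1]} columns"
        )
    ld = LDMatrix(ids, body)
    if expected_ids is not None:
        expected = list(expected_ids)
        if set(expected) - set(ids):
            missing = sorted(set(expected) - set(ids))[:5]
            raise ValidationError(f"LD matrix missing variant id(s): {', '.join(missing)}")
    return ld


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(ld.r, columns=ld.variant_ids).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["gene_id", "chrom", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_gene_annotations(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [(g.gene_id, g.chrom, g.start, g.end) for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
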