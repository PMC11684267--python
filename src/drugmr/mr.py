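"""Two-sample MR estimators and per-gene sensitivity diagnostics.

All estimators operate on harmonized per-variant arrays: exposure effects
``bx`` with standard errors ``sx`` and outcome effects ``by`` with ``sy``,
signed to the same effect allele. The primary estimator is inverse-variance
weighting under a multiplicative random-effects model (the residual
overdispersion factor sqrt(Q/(k-1)) inflates the fixed-effect SE, floored at
1 so underdispersion never shrinks it); a single instrument falls back to
the Wald ratio. Auxiliary estimators — MR-Egger, weighted median, weighted
mode, RAPS, profile maximum likelihood — plus Radial-MR and MR-PRESSO
outlier diagnostics and leave-one-out refits complete the battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MRResult",
    "OutlierReport",
    "wald_ratio",
    "ivw_mre",
    "ivw_fixed",
    "egger_regression",
    "weighted_median",
    "weighted_mode",
    "raps_estimate",
    "max_likelihood",
    "leave_one_out",
    "radial_outliers",
    "mr_presso",
    "run_mr_battery",
    "pairs_arrays",
]

AUXILIARY_METHODS = ("egger", "weighted_median", "raps", "weighted_mode", "max_likelihood")


@dataclass
class MRResult:
    gene_id: str
    method: str
    beta: float
    se: float
    pval: float
    k: int
    cochran_q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return (self.beta - half, self.beta + half)


@dataclass
class OutlierReport:
    gene_id: str
    method: str
    outlier_ids: list[str]
    global_stat: float
    global_pval: float
    per_variant: pd.DataFrame | None = field(default=None, repr=False)


def pairs_arrays(pairs: pd.DataFrame):
    """Extract (bx, sx, by, sy, ids) arrays from a harmonized table."""
    return (
        pairs["beta_exp"].to_numpy(float),
        pairs["se_exp"].to_numpy(float),
        pairs["beta_out"].to_numpy(float),
        pairs["se_out"].to_numpy(float),
        pairs["variant_id"].astype(str).to_list(),
    )


def normal_p_from_ci(beta: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p recovered from an estimate and its 95% CI.

    Useful for checking published effect estimates: se = CI width / (2 x 1.96).
    """
    se = (ci_high - ci_low) / (2.0 * 1.959963984540054)
    if se <= 0:
        raise ValueError("empty or inverted confidence interval")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _norm_p(beta: float, se: float) -> float:
    if se <= 0 or not np.isfinite(se):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _check_k(k: int, minimum: int, method: str) -> None:
    if k < minimum:
        raise ValueError(f"{method} requires at least {minimum} variants, got {k}")


def wald_ratio(bx, sx, by, sy, gene_id: str = "") -> MRResult:
    """Single-instrument causal estimate by / bx (first-order delta-method SE)."""
    bx, by, sy = float(np.ravel(bx)[0]), float(np.ravel(by)[0]), float(np.ravel(sy)[0])
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined: exposure beta is 0")
    beta = by / bx
    se = sy / abs(bx)
    return MRResult(gene_id, "wald_ratio", beta, se, _norm_p(beta, se), k=1)


def _ivw_core(bx, by, w):
    sw = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sw
    se_fixed = 1.0 / np.sqrt(sw)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw_fixed(bx, sx, by, sy, gene_id: str = "") -> MRResult:
    """Fixed-effect IVW: origin-constrained WLS of by on bx, weights 1/sy^2."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    _check_k(len(bx), 2, "IVW")
    w = 1.0 / sy**2
    beta, se, q = _ivw_core(bx, by, w)
    k = len(bx)
    q_p = float(stats.chi2.sf(q, k - 1))
    return MRResult(gene_id, "ivw_fixed", beta, se, _norm_p(beta, se), k, q, q_p)


def ivw_mre(bx, sx, by, sy, gene_id: str = "") -> MRResult:
    """IVW under multiplicative random effects (overdispersion floored at 1)."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    k = len(bx)
    _check_k(k, 2, "IVW")
    w = 1.0 / sy**2
    beta, se_fixed, q = _ivw_core(bx, by, w)
    scale = max(1.0, np.sqrt(q / (k - 1)))
    se = se_fixed * scale
    q_p = float(stats.chi2.sf(q, k - 1))
    return MRResult(gene_id, "ivw_mre", beta, se, _norm_p(beta, se), k, q, q_p)


def egger_regression(bx, sx, by, sy, gene_id: str = "") -> MRResult:
    """MR-Egger: intercept-including WLS; the intercept tests directional pleiotropy.

    Data are oriented so exposure effects are positive (the standard InSIDE
    parameterization); slope inference uses a t-distribution with k-2 df and
    a residual dispersion factor floored at 1.
    """
    bx, by, sy = map(lambda a: np.asarray(a, float), (bx, by, sy))
    k = len(bx)
    _check_k(k, 3, "MR-Egger")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    x = bx * flip
    y = by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), x])
    xtw = X.T * w
    xtwx = xtw @ X
    if np.linalg.cond(xtwx) > 1e12:
        raise np.linalg.LinAlgError("singular Egger design (exposure betas collinear)")
    cov_unit = np.linalg.inv(xtwx)
    coef = cov_unit @ (xtw @ y)
    resid = y - X @ coef
    rss = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss / (k - 2))
    cov = cov_unit * sigma2
    intercept, slope = float(coef[0]), float(coef[1])
    se_i, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_b = float(2.0 * stats.t.sf(abs(slope) / se_b, k - 2))
    p_i = float(2.0 * stats.t.sf(abs(intercept) / se_i, k - 2))
    q = rss
    return MRResult(
        gene_id, "egger", slope, se_b, p_b, k,
        cochran_q=q, q_pval=float(stats.chi2.sf(q, k - 2)),
        egger_intercept=intercept, intercept_se=se_i, intercept_pval=p_i,
    )


def _weighted_median_of(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    bx, sx, by, sy, gene_id: str = "", n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted median of per-variant Wald ratios; SE by parametric bootstrap."""
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 3, "weighted median")
    ratios = by / bx
    w = (bx / sy) ** 2  # inverse variance of the first-order ratio
    est = _weighted_median_of(ratios, w)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r = by_b[i] / bx_b[i]
        wb = (bx_b[i] / sy) ** 2
        boots[i] = _weighted_median_of(r, wb)
    se = float(np.std(boots, ddof=1))
    return MRResult(gene_id, "weighted_median", est, se, _norm_p(est, se), k)


def _mode_of(ratios: np.ndarray, w: np.ndarray, bandwidth_factor: float = 0.9) -> float:
    wn = w / np.sum(w)
    mu = float(np.sum(wn * ratios))
    sd = float(np.sqrt(np.sum(wn * (ratios - mu) ** 2)))
    if sd == 0:
        return float(ratios[0])
    h = bandwidth_factor * len(ratios) ** (-0.2) * sd
    dens = np.sum(wn[None, :] * np.exp(-0.5 * ((ratios[:, None] - ratios[None, :]) / h) ** 2), axis=1)
    best = np.max(dens)
    tied = np.flatnonzero(dens >= best - 1e-12)
    if len(tied) > 1:  # larger local weight first, then smaller |ratio|
        tied = sorted(tied, key=lambda i: (-wn[i], abs(ratios[i])))
    return float(ratios[tied[0]])


def weighted_mode(
    bx, sx, by, sy, gene_id: str = "", n_boot: int = 1000, seed: int = 0,
    bandwidth_factor: float = 0.9,
) -> MRResult:
    """Mode of the smoothed weighted ratio density; SE by parametric bootstrap."""
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 3, "weighted mode")
    ratios = by / bx
    w = (bx / sy) ** 2
    est = _mode_of(ratios, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, k))
    by_b = rng.normal(by, sy, size=(n_boot, k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _mode_of(by_b[i] / bx_b[i], (bx_b[i] / sy) ** 2, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    pval = _norm_p(est, se) if se > 0 else (1.0 if est == 0 else 0.0)
    return MRResult(gene_id, "weighted_mode", est, se, pval, k)


def _raps_t(beta, bx, sx, by, sy, tau2=0.0):
    s = np.sqrt(sy**2 + tau2 + beta**2 * sx**2)
    t = (by - beta * bx) / s
    dt = -bx / s - t * beta * sx**2 / s**2
    return t, dt


def raps_estimate(
    bx, sx, by, sy, gene_id: str = "", psi: str = "huber", c: float = 1.345,
    overdispersion: bool = False,
) -> MRResult:
    """Robust adjusted profile score estimator.

    Solves the profile-score equation sum psi(t_j) dt_j/dbeta = 0 with
    t_j = (by_j - beta bx_j)/sqrt(sy_j^2 + beta^2 sx_j^2); psi is the
    identity ("simple") or a Huber clip ("huber", default). The sandwich of
    the score provides the SE. Optional method-of-moments overdispersion.
    """
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 2, "RAPS")
    if psi == "huber":
        def _psi(t):
            return np.clip(t, -c, c)
    elif psi == "simple":
        def _psi(t):
            return t
    else:
        raise ValueError(f"unknown psi {psi!r}")

    tau2 = 0.0
    start = ivw_fixed(bx, sx, by, sy).beta if k >= 2 else by[0] / bx[0]

    def score(beta):
        t, dt = _raps_t(beta, bx, sx, by, sy, tau2)
        return float(np.sum(_psi(t) * dt))

    def solve():
        lo, hi = start - 0.5, start + 0.5
        for _ in range(60):
            if score(lo) * score(hi) <= 0:
                return float(optimize.brentq(score, lo, hi, xtol=1e-12))
            lo, hi = start - 2 * (start - lo), start + 2 * (hi - start)
        raise RuntimeError("RAPS: no root of the profile score in the search bracket")

    beta = solve()
    if overdispersion:
        for _ in range(25):
            t, _ = _raps_t(beta, bx, sx, by, sy, tau2)
            excess = float(np.mean(t**2) - 1.0)
            step = excess * float(np.mean(sy**2 + tau2 + beta**2 * sx**2))
            new_tau2 = max(0.0, tau2 + step)
            if abs(new_tau2 - tau2) < 1e-12:
                tau2 = new_tau2
                break
            tau2 = new_tau2
            beta = solve()

    eps = 1e-6 * max(1.0, abs(beta))
    a = (score(beta + eps) - score(beta - eps)) / (2 * eps)
    t, dt = _raps_t(beta, bx, sx, by, sy, tau2)
    b = float(np.sum((_psi(t) * dt) ** 2))
    if a == 0:
        raise RuntimeError("RAPS: flat score; SE undefined")
    se = float(np.sqrt(b / a**2))
    return MRResult(gene_id, "raps", beta, se, _norm_p(beta, se), k)


def _profile_negloglik(beta, bx, sx, by, sy):
    denom = sy**2 + beta**2 * sx**2
    return 0.5 * float(np.sum((by - beta * bx) ** 2 / denom + np.log(denom)))


def max_likelihood(bx, sx, by, sy, gene_id: str = "") -> MRResult:
    """Profile maximum likelihood under bivariate-normal measurement error.

    The per-variant true exposure effects are profiled out analytically;
    the scalar profile likelihood in beta is maximized numerically and the
    SE comes from the observed information (numerical second derivative).
    """
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 2, "maximum likelihood")
    start = ivw_fixed(bx, sx, by, sy).beta

    res = optimize.minimize_scalar(
        _profile_negloglik, args=(bx, sx, by, sy),
        bracket=(start - 0.5, start, start + 0.5) if start != 0 else (-0.5, 0.0, 0.5),
        method="brent", options={"xtol": 1e-12},
    )
    if not res.success and not np.isfinite(res.x):
        raise RuntimeError("maximum likelihood failed to converge")
    beta = float(res.x)
    eps = 1e-5 * max(1.0, abs(beta))
    f0 = _profile_negloglik(beta, bx, sx, by, sy)
    fp = _profile_negloglik(beta + eps, bx, sx, by, sy)
    fm = _profile_negloglik(beta - eps, bx, sx, by, sy)
    info = (fp - 2 * f0 + fm) / eps**2
    if info <= 0:
        raise RuntimeError("maximum likelihood: non-positive observed information")
    se = float(1.0 / np.sqrt(info))
    return MRResult(gene_id, "max_likelihood", beta, se, _norm_p(beta, se), k)


def leave_one_out(bx, sx, by, sy, ids=None, gene_id: str = "") -> pd.DataFrame:
    """IVW refits each omitting one variant; flags sign flips / CI excursions."""
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 3, "leave-one-out")
    ids = list(ids) if ids is not None else [f"v{i}" for i in range(k)]
    full = ivw_mre(bx, sx, by, sy, gene_id)
    # excursions are judged against the fixed-effect CI: the random-effects
    # interval self-inflates under the very outlier this analysis hunts for
    lo, hi = ivw_fixed(bx, sx, by, sy, gene_id).ci
    rows = []
    for j in range(k):
        keep = np.arange(k) != j
        fit = ivw_mre(bx[keep], sx[keep], by[keep], sy[keep], gene_id)
        flagged = (np.sign(fit.beta) != np.sign(full.beta)) or not (lo <= fit.beta <= hi)
        rows.append((ids[j], fit.beta, fit.se, fit.pval, bool(flagged)))
    return pd.DataFrame(rows, columns=["omitted", "beta", "se", "pval", "flagged"])


def radial_outliers(
    bx, sx, by, sy, ids=None, gene_id: str = "", alpha: float = 0.05,
    bonferroni: bool = False, max_iter: int = 100,
) -> OutlierReport:
    """Radial (modified second-order weights) IVW outlier detection.

    Iterates the radial IVW estimate with weights
    w_j = 1 / (sy_j^2/bx_j^2 + beta^2 sx_j^2/bx_j^2); each variant's
    contribution Q_j = w_j (ratio_j - beta)^2 is referred to chi^2_1.
    """
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 3, "radial MR")
    ids = list(ids) if ids is not None else [f"v{i}" for i in range(k)]
    ratios = by / bx
    w = (bx / sy) ** 2  # first-order start
    beta = float(np.sum(w * ratios) / np.sum(w))
    for _ in range(max_iter):
        w = 1.0 / (sy**2 / bx**2 + beta**2 * sx**2 / bx**2)
        new_beta = float(np.sum(w * ratios) / np.sum(w))
        if abs(new_beta - beta) < 1e-12:
            beta = new_beta
            break
        beta = new_beta
    qj = w * (ratios - beta) ** 2
    q = float(np.sum(qj))
    q_p = float(stats.chi2.sf(q, k - 1))
    alpha_eff = alpha / k if bonferroni else alpha
    cut = stats.chi2.ppf(1 - alpha_eff, 1)
    out_ids = [ids[j] for j in np.flatnonzero(qj > cut)]
    per_variant = pd.DataFrame({"variant_id": ids, "q_j": qj, "outlier": qj > cut})
    return OutlierReport(gene_id, "radial", out_ids, q, q_p, per_variant)


def mr_presso(
    bx, sx, by, sy, ids=None, gene_id: str = "", n_sim: int = 1000, seed: int = 0,
    significance: float = 0.05,
) -> OutlierReport:
    """MR-PRESSO global and per-variant outlier tests.

    The observed leave-one-out residual sum of squares (weighted by 1/sy^2)
    is compared with its parametric null distribution simulated from the
    fitted no-pleiotropy model; per-variant residuals are compared with
    their own simulated distributions, Bonferroni-corrected over k.
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    bx, sx, by, sy = map(lambda a: np.asarray(a, float), (bx, sx, by, sy))
    k = len(bx)
    _check_k(k, 4, "MR-PRESSO")
    ids = list(ids) if ids is not None else [f"v{i}" for i in range(k)]
    w = 1.0 / sy**2

    def loo_betas(bxm, bym):
        num = np.sum(w * bxm * bym, axis=-1, keepdims=True) - w * bxm * bym
        den = np.sum(w * bxm**2, axis=-1, keepdims=True) - w * bxm**2
        return num / den

    b_loo = loo_betas(bx[None, :], by[None, :])[0]
    obs_res2 = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(obs_res2))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, sx, size=(n_sim, k))
    by_s = rng.normal(b_loo * bx, sy, size=(n_sim, k))
    b_loo_s = loo_betas(bx_s, by_s)
    res2_s = w * (by_s - b_loo_s * bx_s) ** 2
    rss_s = res2_s.sum(axis=1)
    global_p = float((np.sum(rss_s >= rss_obs) + 1) / (n_sim + 1))

    p_var = (np.sum(res2_s >= obs_res2[None, :], axis=0) + 1) / (n_sim + 1)
    p_var_adj = np.minimum(1.0, p_var * k)
    out_ids = [ids[j] for j in np.flatnonzero(p_var_adj < significance)]
    per_variant = pd.DataFrame(
        {"variant_id": ids, "outlier_pval": p_var_adj, "outlier": p_var_adj < significance}
    )
    return OutlierReport(gene_id, "presso", out_ids, rss_obs, global_p, per_variant)


def run_mr_battery(
    pairs: pd.DataFrame, gene_id: str = "", seed: int = 0, n_boot: int = 1000,
) -> dict[str, MRResult]:
    """Primary + auxiliary estimators with the standard routing rule.

    One instrument -> Wald ratio only; two -> IVW(+RAPS, ML); three or more
    -> the full battery. Methods whose minimum k is unmet are omitted.
    """
    bx, sx, by, sy, _ = pairs_arrays(pairs)
    k = len(bx)
    if k == 0:
        return {}
    results: dict[str, MRResult] = {}
    if k == 1:
        results["ivw"] = wald_ratio(bx, sx, by, sy, gene_id)
        return results
    results["ivw"] = ivw_mre(bx, sx, by, sy, gene_id)
    results["raps"] = raps_estimate(bx, sx, by, sy, gene_id)
    results["max_likelihood"] = max_likelihood(bx, sx, by, sy, gene_id)
    if k >= 3:
        results["egger"] = egger_regression(bx, sx, by, sy, gene_id)
        results["weighted_median"] = weighted_median(bx, sx, by, sy, gene_id, n_boot, seed)
        results["weighted_mode"] = weighted_mode(bx, sx, by, sy, gene_id, n_boot, seed + 1)
    return results
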