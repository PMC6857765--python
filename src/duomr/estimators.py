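"""Univariate two-sample MR estimators on a harmonized instrument table.

All estimators consume per-SNP exposure betas (beta_zx) and outcome betas
(beta_zy, maternal- or fetal-specific) and return an :class:`MREstimate`.
IVW and Egger use multiplicative random-effects standard errors with the
residual standard error floored at 1 (the fixed-effect SE is never
shrunk), matching common reference implementations; fixed-effect SEs are
available via ``random_effects=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import InstrumentTable

logger = logging.getLogger(__name__)

METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

#: minimum number of SNPs each method needs
MIN_SNPS = {
    "ivw": 2,
    "egger": 3,
    "weighted_median": 3,
    "simple_mode": 3,
    "weighted_mode": 3,
}

_Z975 = stats.norm.ppf(0.975)


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio: outcome beta over exposure beta."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float

    def __post_init__(self) -> None:
        if not self.se_ratio > 0:
            raise ValueError(f"{self.snp_id}: se_ratio must be positive")
        if not self.weight > 0:
            raise ValueError(f"{self.snp_id}: weight must be positive")


@dataclass
class MREstimate:
    """One estimator's causal-effect estimate (BW SD per exposure SD)."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    exposure: str | None = None
    outcome: str | None = None
    snp_set: str | None = None

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("estimate outside its own confidence interval")


def _extract(table: InstrumentTable, exposure: str | None, outcome: str):
    exposure = table.resolve_exposure(exposure)
    if outcome not in ("maternal", "fetal"):
        raise ValueError(f"outcome must be 'maternal' or 'fetal', got {outcome!r}")
    ocol = "mat" if outcome == "maternal" else "fet"
    df = table.df
    mask = df[f"beta_{exposure}"].notna() & df[f"beta_{ocol}"].notna()
    sub = df.loc[mask]
    return (
        exposure,
        sub["snp_id"].to_numpy(),
        sub[f"beta_{exposure}"].to_numpy(dtype=float),
        sub[f"se_{exposure}"].to_numpy(dtype=float),
        sub[f"beta_{ocol}"].to_numpy(dtype=float),
        sub[f"se_{ocol}"].to_numpy(dtype=float),
    )


def wald_ratios(
    table: InstrumentTable, outcome: str = "maternal", exposure: str | None = None
) -> list[RatioEstimate]:
    """Per-SNP causal-effect ratios with first-order standard errors.

    ratio = beta_zy / beta_zx, se = se_zy / |beta_zx|, weight = 1/se^2.
    SNPs with beta_zx == 0 are excluded with a warning.
    """
    _, snps, bzx, _, bzy, sezy = _extract(table, exposure, outcome)
    out = []
    for snp, x, y, sy in zip(snps, bzx, bzy, sezy):
        if x == 0.0:
            logger.warning("%s: exposure beta is 0; Wald ratio undefined, excluded", snp)
            continue
        se = sy / abs(x)
        out.append(RatioEstimate(snp_id=snp, ratio=y / x, se_ratio=se, weight=1.0 / se**2))
    return out


def _wls_through_origin(x, y, w):
    """Zero-intercept WLS slope and fixed-effect SE."""
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y)) / sxx
    return slope, 1.0 / np.sqrt(sxx)


def ivw(
    table: InstrumentTable,
    outcome: str = "maternal",
    exposure: str | None = None,
    random_effects: bool = True,
) -> MREstimate:
    """Inverse-variance weighted estimate.

    The precision-weighted average of Wald ratios with weights
    beta_zx^2 / se_zy^2, identical to the slope of a zero-intercept weighted
    regression of beta_zy on beta_zx with weights 1/se_zy^2.
    """
    exposure, snps, bzx, _, bzy, sezy = _extract(table, exposure, outcome)
    n = len(snps)
    if n < 2:
        raise ValueError(
            f"ivw needs >= 2 SNPs, got {n}; use wald_ratios for single-SNP estimates"
        )
    w = 1.0 / sezy**2
    slope, se_fixed = _wls_through_origin(bzx, bzy, w)
    resid = bzy - slope * bzx
    sigma = np.sqrt(float(np.sum(w * resid**2)) / (n - 1))
    se = se_fixed * max(1.0, sigma) if random_effects else se_fixed
    z = slope / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MREstimate(
        method="ivw",
        estimate=slope,
        se=se,
        ci_low=slope - _Z975 * se,
        ci_high=slope + _Z975 * se,
        pvalue=max(p, np.finfo(float).tiny),
        n_snps=n,
        exposure=exposure,
        outcome=outcome,
        snp_set=table.snp_set,
    )


def egger(
    table: InstrumentTable,
    outcome: str = "maternal",
    exposure: str | None = None,
    random_effects: bool = True,
) -> MREstimate:
    """MR-Egger regression: weighted regression with a free intercept.

    The slope is the pleiotropy-adjusted causal estimate (valid under
    InSIDE); the intercept, with its SE and p-value, is the test for
    directional pleiotropy.  Because the intercept's sign depends on allele
    orientation, the table must have been oriented positive on the exposure.
    """
    exposure, snps, bzx, _, bzy, sezy = _extract(table, exposure, outcome)
    n = len(snps)
    if n < 3:
        raise ValueError(f"egger needs >= 3 SNPs, got {n}")
    if table.oriented_to != exposure:
        raise ValueError(
            "egger requires a table oriented positive on the exposure "
            "(run orient_positive first); intercept sign is orientation-dependent"
        )
    w = 1.0 / sezy**2
    X = np.column_stack([np.ones(n), bzx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ bzy)
    resid = bzy - X @ coef
    dof = n - 2
    sigma = np.sqrt(float(np.sum(w * resid**2)) / dof)
    cov_fixed = np.linalg.inv(xtwx)
    infl = max(1.0, sigma) if random_effects else 1.0
    se_int = float(np.sqrt(cov_fixed[0, 0])) * infl
    se_slope = float(np.sqrt(cov_fixed[1, 1])) * infl
    slope = float(coef[1])
    intercept = float(coef[0])
    tq = stats.t.ppf(0.975, dof)
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), dof)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), dof)
    return MREstimate(
        method="egger",
        estimate=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pvalue=max(p_slope, np.finfo(float).tiny),
        n_snps=n,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=max(p_int, np.finfo(float).tiny),
        exposure=exposure,
        outcome=outcome,
        snp_set=table.snp_set,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Cumulative-weight interpolation of sorted ratios at probability 0.5."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    table: InstrumentTable,
    outcome: str = "maternal",
    exposure: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator.

    Consistent when < 50% of the total weight comes from invalid
    instruments.  The SE comes from a parametric bootstrap: per-SNP exposure
    and outcome betas are resampled from their normal sampling distributions
    and the weighted median recomputed.
    """
    exposure, snps, bzx, sezx, bzy, sezy = _extract(table, exposure, outcome)
    n = len(snps)
    if n < 3:
        raise ValueError(f"weighted_median needs >= 3 SNPs, got {n}")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; bootstrap SE will be noisy", n_boot)
    if np.isnan(sezx).any():
        raise ValueError("weighted_median bootstrap needs exposure SEs for all SNPs")
    keep = bzx != 0
    bzx, sezx, bzy, sezy = bzx[keep], sezx[keep], bzy[keep], sezy[keep]
    n_used = int(keep.sum())

    ratios = bzy / bzx
    weights = bzx**2 / sezy**2
    estimate = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        x = rng.normal(bzx, sezx)
        y = rng.normal(bzy, sezy)
        ok = x != 0
        boot[b] = _weighted_median_point(y[ok] / x[ok], x[ok] ** 2 / sezy[ok] ** 2)
    se = float(boot.std(ddof=1))
    p = 2.0 * stats.norm.sf(abs(estimate / se)) if se > 0 else 0.0
    return MREstimate(
        method="weighted_median",
        estimate=estimate,
        se=se,
        ci_low=estimate - _Z975 * se,
        ci_high=estimate + _Z975 * se,
        pvalue=max(p, np.finfo(float).tiny),
        n_snps=n_used,
        exposure=exposure,
        outcome=outcome,
        snp_set=table.snp_set,
    )


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """phi x modified Silverman rule with MAD-based spread."""
    s = np.std(ratios, ddof=1)
    mad = stats.median_abs_deviation(ratios, scale="normal")
    spread = min(s, mad) if mad > 0 else s
    return phi * 0.9 * spread * len(ratios) ** (-0.2)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    """Argmax of the weighted normal-kernel density over the ratios."""
    lo = ratios.min() - 3.0 * h
    hi = ratios.max() + 3.0 * h
    grid = np.linspace(lo, hi, 2048)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ weights
    return float(grid[int(np.argmax(dens))])


def _mode_points_batch(
    R: np.ndarray, weights: np.ndarray, phi: float, grid_size: int = 512
) -> np.ndarray:
    """Mode for each row of a (n_boot, n_snps) matrix of resampled ratios.

    Uses a binned kernel density (histogram + Gaussian filter, the classic
    FFT-density approximation) per row, which sidesteps the O(grid x snps)
    exp evaluations of the exact KDE.
    """
    from scipy.ndimage import gaussian_filter1d

    n_boot, n = R.shape
    s = R.std(axis=1, ddof=1)
    mad = stats.median_abs_deviation(R, axis=1, scale="normal")
    spread = np.where(mad > 0, np.minimum(s, mad), s)
    h = phi * 0.9 * spread * n ** (-0.2)
    out = np.empty(n_boot)
    for b in range(n_boot):
        r, hb = R[b], h[b]
        if hb == 0:
            out[b] = r[0]
            continue
        lo = r.min() - 3.0 * hb
        hi = r.max() + 3.0 * hb
        dx = (hi - lo) / (grid_size - 1)
        idx = np.clip(np.rint((r - lo) / dx).astype(int), 0, grid_size - 1)
        counts = np.bincount(idx, weights=weights, minlength=grid_size)
        dens = gaussian_filter1d(counts, hb / dx, mode="constant", truncate=6.0)
        out[b] = lo + int(np.argmax(dens)) * dx
    return out


def mode_based(
    table: InstrumentTable,
    outcome: str = "maternal",
    exposure: str | None = None,
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode-based estimator (simple or inverse-variance weighted).

    Places a normal kernel at every Wald ratio (bandwidth = phi x modified
    Silverman rule using the median absolute deviation for spread) and takes
    the density maximum; the weighted variant scales each SNP's kernel mass
    by its inverse-variance weight.  Consistent under ZEMPA: the largest
    cluster of ratios comes from valid instruments.  SE by parametric
    bootstrap of the ratios.
    """
    exposure, snps, bzx, _, bzy, sezy = _extract(table, exposure, outcome)
    if len(snps) < 3:
        raise ValueError(f"mode_based needs >= 3 SNPs, got {len(snps)}")
    keep = bzx != 0
    bzx, bzy, sezy = bzx[keep], bzy[keep], sezy[keep]
    n = int(keep.sum())

    ratios = bzy / bzx
    se_r = sezy / np.abs(bzx)
    weights = 1.0 / se_r**2 if weighted else np.full(n, 1.0 / n)
    weights = weights / weights.sum()
    method = "weighted_mode" if weighted else "simple_mode"

    h = _mode_bandwidth(ratios, phi)
    if h == 0.0:
        # all ratios identical: degenerate density
        estimate = float(ratios[0])
        se = float(1.0 / np.sqrt(np.sum(1.0 / se_r**2)))
    else:
        estimate = _mode_point(ratios, weights, h)
        rng = np.random.default_rng(seed)
        R = rng.normal(ratios[None, :], se_r[None, :], size=(n_boot, n))
        boot = _mode_points_batch(R, weights, phi)
        se = float(stats.median_abs_deviation(boot, scale="normal"))
    p = 2.0 * stats.norm.sf(abs(estimate / se)) if se > 0 else 0.0
    return MREstimate(
        method=method,
        estimate=estimate,
        se=se,
        ci_low=estimate - _Z975 * se,
        ci_high=estimate + _Z975 * se,
        pvalue=max(p, np.finfo(float).tiny),
        n_snps=n,
        exposure=exposure,
        outcome=outcome,
        snp_set=table.snp_set,
    )


_REGISTRY = {
    "ivw": ivw,
    "egger": egger,
    "weighted_median": weighted_median,
    "simple_mode": lambda table, **kw: mode_based(table, weighted=False, **kw),
    "weighted_mode": lambda table, **kw: mode_based(table, weighted=True, **kw),
}


def run_estimator(method: str, table: InstrumentTable, **kwargs) -> MREstimate:
    """Dispatch a method label to its estimator."""
    if method not in _REGISTRY:
        raise ValueError(f"unknown method {method!r}; known: {sorted(_REGISTRY)}")
    fn = _REGISTRY[method]
    if method in ("ivw", "egger"):
        kwargs.pop("n_boot", None)
        kwargs.pop("seed", None)
    return fn(table, **kwargs)


@dataclass
class ExclusionComparison:
    """Original-vs-reduced estimates after excluding named SNPs."""

    method: str
    original: MREstimate
    reduced: MREstimate


def exclude_and_rerun(
    table: InstrumentTable,
    snp_ids: list[str],
    estimators: list[str],
    outcome: str = "maternal",
    exposure: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> list[ExclusionComparison]:
    """Re-run estimators after dropping the named SNPs (outlier sensitivity).

    Estimators whose minimum instrument count is no longer met on the
    reduced table are skipped with a warning.
    """
    have = {s.lower() for s in table.df["snp_id"].str.lower()}
    missing = [s for s in snp_ids if s.lower() not in have]
    if missing:
        raise ValueError(f"snp_ids not in table: {missing}")
    reduced = table.drop_snps(snp_ids)
    out = []
    for method in estimators:
        if reduced.n_snps < MIN_SNPS.get(method, 3):
            logger.warning(
                "%s skipped: %d SNPs left after exclusion (needs >= %d)",
                method, reduced.n_snps, MIN_SNPS.get(method, 3),
            )
            continue
        kw = dict(outcome=outcome, exposure=exposure, n_boot=n_boot, seed=seed)
        out.append(
            ExclusionComparison(
                method=method,
                original=run_estimator(method, table, **kw),
                reduced=run_estimator(method, reduced, **kw),
            )
        )
    return out
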