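"""Instrument diagnostics and reporting transforms.

Covers the I2_GX regression-dilution check for MR-Egger, funnel- and
scatter-plot data (with numeric asymmetry / outlier summaries, since visual
claims should be checkable), and the SD-to-grams conversion used when
reporting birth-weight effects on an absolute scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, RatioEstimate, ivw, wald_ratios
from .summary_io import InstrumentTable

logger = logging.getLogger(__name__)


@dataclass
class I2Report:
    exposure: str
    snp_set: str | None
    q_gx: float
    i2_gx: float
    weighting: str
    n_snps: int


def i2_gx(
    table: InstrumentTable,
    exposure: str | None = None,
    weighting: str = "unweighted",
) -> I2Report:
    """I2_GX: adequacy of the NO-Measurement-Error assumption for MR-Egger.

    Q_GX = sum_j w_j (beta_zx_j - weighted mean)^2 with w_j = 1/se_zx_j^2
    ("unweighted" variant) or w_j = 1/se_zy_j^2 ("egger-weighted" variant);
    I2_GX = max(0, (Q_GX - (L-1)) / Q_GX).  Values near 1 mean the exposure
    betas are heterogeneous relative to their measurement error, so
    regression-dilution bias in the Egger slope is negligible.
    """
    if weighting not in ("unweighted", "egger-weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    exposure = table.resolve_exposure(exposure)
    df = table.df
    mask = df[f"beta_{exposure}"].notna()
    bzx = df.loc[mask, f"beta_{exposure}"].to_numpy(dtype=float)
    sezx = df.loc[mask, f"se_{exposure}"].to_numpy(dtype=float)
    if len(bzx) < 2:
        raise ValueError("i2_gx needs >= 2 SNPs")
    if np.isnan(sezx).any():
        raise ValueError("i2_gx: missing exposure SEs")
    if weighting == "unweighted":
        w = 1.0 / sezx**2
    else:
        sezy = df.loc[mask, "se_mat"].to_numpy(dtype=float)
        w = 1.0 / sezy**2
    mean_w = float(np.sum(w * bzx) / np.sum(w))
    q = float(np.sum(w * (bzx - mean_w) ** 2))
    L = len(bzx)
    i2 = max(0.0, (q - (L - 1)) / q) if q > 0 else 0.0
    return I2Report(
        exposure=exposure, snp_set=table.snp_set, q_gx=q, i2_gx=i2,
        weighting=weighting, n_snps=L,
    )


def funnel_data(ratios: list[RatioEstimate]) -> tuple[pd.DataFrame, dict]:
    """Funnel-plot table (ratio vs precision) plus a numeric symmetry test.

    The symmetry statistic is the slope of a precision-weighted regression
    of the per-SNP ratio on its standard error (Egger-style asymmetry test):
    under symmetry the slope is 0.
    """
    if len(ratios) < 3:
        raise ValueError("funnel_data needs >= 3 SNPs")
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "precision": [1.0 / r.se_ratio for r in ratios],
        }
    )
    se_r = 1.0 / df["precision"].to_numpy()
    y = df["ratio"].to_numpy()
    if np.ptp(se_r) == 0:
        logger.warning("funnel_data: all precisions identical; symmetry test degenerate")
        symmetry = {"slope": np.nan, "se": np.nan, "pvalue": np.nan, "degenerate": True}
        return df, symmetry
    w = 1.0 / se_r**2
    X = np.column_stack([np.ones(len(y)), se_r])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    dof = len(y) - 2
    sigma2 = float(np.sum(w * resid**2)) / dof
    se_slope = float(np.sqrt(max(sigma2, 1.0) * np.linalg.inv(xtwx)[1, 1]))
    slope = float(coef[1])
    p = 2.0 * stats.t.sf(abs(slope / se_slope), dof)
    symmetry = {"slope": slope, "se": se_slope, "pvalue": p, "degenerate": False}
    return df, symmetry


def leave_one_out(table: InstrumentTable, outcome: str = "maternal",
                  exposure: str | None = None) -> pd.DataFrame:
    """IVW estimate change when each SNP is dropped in turn."""
    full = ivw(table, outcome=outcome, exposure=exposure)
    rows = []
    for snp in table.snp_ids:
        reduced = table.drop_snps([snp])
        est = ivw(reduced, outcome=outcome, exposure=exposure)
        rows.append({"snp_id": snp, "estimate_without": est.estimate,
                     "delta": est.estimate - full.estimate})
    return pd.DataFrame(rows)


def scatter_data(
    table: InstrumentTable,
    fits: list[MREstimate],
    outcome: str = "maternal",
    exposure: str | None = None,
    outlier_threshold: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scatter-plot data: per-SNP points with error bars plus fit lines.

    Returns ``(points, lines)``.  Lines carry one (slope, intercept) per
    supplied estimate: zero intercept for non-Egger methods, the fitted
    intercept for Egger.  When ``outlier_threshold`` is given, SNPs whose
    leave-one-out IVW change exceeds it (in absolute value) are flagged.
    """
    exposure = table.resolve_exposure(exposure)
    ocol = "mat" if outcome == "maternal" else "fet"
    df = table.df
    points = pd.DataFrame(
        {
            "snp_id": df["snp_id"],
            "beta_zx": df[f"beta_{exposure}"],
            "se_zx": df[f"se_{exposure}"],
            "beta_zy": df[f"beta_{ocol}"],
            "se_zy": df[f"se_{ocol}"],
        }
    )
    points["loo_delta"] = np.nan
    points["is_outlier"] = False
    if outlier_threshold is not None and table.n_snps >= 3:
        loo = leave_one_out(table, outcome=outcome, exposure=exposure)
        points = points.drop(columns=["loo_delta"]).merge(
            loo[["snp_id", "delta"]].rename(columns={"delta": "loo_delta"}),
            on="snp_id", how="left",
        )
        points["is_outlier"] = points["loo_delta"].abs() > outlier_threshold

    lines = pd.DataFrame(
        {
            "method": [f.method for f in fits],
            "slope": [f.estimate for f in fits],
            "intercept": [f.intercept if f.intercept is not None else 0.0 for f in fits],
        }
    )
    return points, lines


def sd_to_grams(
    estimate: MREstimate | tuple[float, float, float],
    sd_grams: float = 454.0,
) -> tuple[float, float, float]:
    """Convert an SD-scale estimate and 95% CI to grams.

    Accepts an :class:`MREstimate` or a ``(point, ci_low, ci_high)`` triple;
    multiplies by grams-per-SD and rounds to 2 decimals for reporting.
    """
    if not sd_grams > 0:
        raise ValueError("sd_grams must be positive")
    if isinstance(estimate, MREstimate):
        triple = (estimate.estimate, estimate.ci_low, estimate.ci_high)
    else:
        triple = tuple(estimate)
    return tuple(round(v * sd_grams, 2) for v in triple)
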