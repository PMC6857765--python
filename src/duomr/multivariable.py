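"""Multivariable MR: joint regression of outcome betas on several exposures.

mv_ivw regresses the maternal (or fetal) outcome betas on the exposure-beta
matrix of all requested lipids at once through a zero intercept; mv_egger
re-orients the table on one designated exposure and frees the intercept.
SE conventions (multiplicative random effects with a floor of 1) are
inherited from the univariate estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .summary_io import InstrumentTable, orient_positive

logger = logging.getLogger(__name__)

_Z975 = stats.norm.ppf(0.975)


@dataclass
class ExposureEstimate:
    exposure: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


@dataclass
class MVMRResult:
    method: str  # "mv_ivw" | "mv_egger"
    estimates: dict[str, ExposureEstimate]
    n_snps: int
    outcome: str = "maternal"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    oriented_exposure: str | None = None

    def __getitem__(self, exposure: str) -> ExposureEstimate:
        return self.estimates[exposure]


def _design(table: InstrumentTable, exposures, outcome):
    if outcome not in ("maternal", "fetal"):
        raise ValueError(f"outcome must be 'maternal' or 'fetal', got {outcome!r}")
    for e in exposures:
        if e not in table.exposures:
            raise ValueError(f"exposure {e!r} not in table {table.exposures}")
    ocol = "mat" if outcome == "maternal" else "fet"
    df = table.df
    mask = df[f"beta_{ocol}"].notna()
    for e in exposures:
        mask &= df[f"beta_{e}"].notna()
    sub = df.loc[mask]
    X = sub[[f"beta_{e}" for e in exposures]].to_numpy(dtype=float)
    y = sub[f"beta_{ocol}"].to_numpy(dtype=float)
    w = 1.0 / sub[f"se_{ocol}"].to_numpy(dtype=float) ** 2
    return X, y, w


def _check_rank(X: np.ndarray, exposures) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        pairs = [
            (exposures[i], exposures[j])
            for i in range(len(exposures))
            for j in range(i + 1, len(exposures))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient exposure matrix; collinear exposures: {pairs}")


def _wls(X, y, w, random_effects=True):
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma = np.sqrt(float(np.sum(w * resid**2)) / dof) if dof > 0 else 1.0
    infl = max(1.0, sigma) if random_effects else 1.0
    ses = np.sqrt(np.diag(np.linalg.inv(xtwx))) * infl
    return coef, ses, dof


def mv_ivw(
    table: InstrumentTable,
    exposures,
    outcome: str = "maternal",
    random_effects: bool = True,
    free_intercept: bool = False,
) -> MVMRResult:
    """Multivariable IVW: zero-intercept weighted multiple regression.

    SNPs missing a beta for any requested exposure are excluded (no
    zero-imputation).  ``free_intercept=True`` adds an intercept column as a
    sensitivity variant.
    """
    exposures = list(exposures)
    X, y, w = _design(table, exposures, outcome)
    n, k = X.shape
    n_params = k + (1 if free_intercept else 0)
    if n < n_params + 1:
        raise ValueError(f"mv_ivw needs >= {n_params + 1} SNPs, got {n}")
    _check_rank(X, exposures)
    if free_intercept:
        Xd = np.column_stack([np.ones(n), X])
        coef, ses, _ = _wls(Xd, y, w, random_effects)
        icpt, icpt_se = float(coef[0]), float(ses[0])
        coef, ses = coef[1:], ses[1:]
    else:
        coef, ses, _ = _wls(X, y, w, random_effects)
        icpt = icpt_se = None

    estimates = {}
    for j, e in enumerate(exposures):
        b, s = float(coef[j]), float(ses[j])
        p = 2.0 * stats.norm.sf(abs(b / s))
        estimates[e] = ExposureEstimate(
            exposure=e, estimate=b, se=s,
            ci_low=b - _Z975 * s, ci_high=b + _Z975 * s,
            pvalue=max(p, np.finfo(float).tiny),
        )
    icpt_p = None
    if icpt is not None:
        icpt_p = 2.0 * stats.norm.sf(abs(icpt / icpt_se))
    return MVMRResult(
        method="mv_ivw", estimates=estimates, n_snps=n, outcome=outcome,
        intercept=icpt, intercept_se=icpt_se, intercept_p=icpt_p,
    )


def mv_egger(
    table: InstrumentTable,
    exposures,
    orient_to: str,
    outcome: str = "maternal",
    random_effects: bool = True,
) -> MVMRResult:
    """Multivariable MR-Egger: free-intercept regression after re-orienting.

    The table is oriented positive on ``orient_to``; that exposure's
    coefficient is its pleiotropy-adjusted causal estimate and the intercept
    is the directional-pleiotropy test.  Run once per exposure of interest.
    """
    exposures = list(exposures)
    if orient_to not in exposures:
        raise ValueError(f"orient_to {orient_to!r} must be among exposures {exposures}")
    oriented = orient_positive(table, orient_to)
    X, y, w = _design(oriented, exposures, outcome)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"mv_egger needs >= {k + 2} SNPs, got {n}")
    _check_rank(X, exposures)
    Xd = np.column_stack([np.ones(n), X])
    coef, ses, dof = _wls(Xd, y, w, random_effects)
    tq = stats.t.ppf(0.975, dof)

    estimates = {}
    for j, e in enumerate(exposures):
        b, s = float(coef[j + 1]), float(ses[j + 1])
        p = 2.0 * stats.t.sf(abs(b / s), dof)
        estimates[e] = ExposureEstimate(
            exposure=e, estimate=b, se=s,
            ci_low=b - tq * s, ci_high=b + tq * s,
            pvalue=max(p, np.finfo(float).tiny),
        )
    icpt, icpt_se = float(coef[0]), float(ses[0])
    icpt_p = 2.0 * stats.t.sf(abs(icpt / icpt_se), dof)
    return MVMRResult(
        method="mv_egger", estimates=estimates, n_snps=n, outcome=outcome,
        intercept=icpt, intercept_se=icpt_se,
        intercept_p=max(icpt_p, np.finfo(float).tiny),
        oriented_exposure=orient_to,
    )
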