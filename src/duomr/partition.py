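"""Partition SNP-birth-weight associations into maternal and fetal components.

A cohort member's own birth weight reflects both their own (fetal) genotype
and their mother's genotype acting through the intrauterine environment;
conversely a mother's genotype is associated with her offspring's birth
weight partly because half of it is transmitted.  Writing bm and bf for the
maternal- and fetal-specific per-allele effects, the two marginal
regressions available from biobank-style data have expectations

    E[beta_own]       = bf + bm / 2      (own BW on own genotype)
    E[beta_offspring] = bm + bf / 2      (offspring BW on maternal genotype)

because the transmission coefficient between a mother's and her child's
allele count is 1/2.  Inverting this 2x2 system gives the closed-form
partition implemented here; the duo-level conditional regression is the
individual-level oracle for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class UnpartitionedPair:
    """Marginal own-BW and offspring-BW associations for one SNP.

    ``overlap_cov`` is the sampling covariance between the two estimates
    induced by overlapping samples (0 for disjoint samples).
    """

    snp_id: str
    beta_own: float
    se_own: float
    beta_offspring: float
    se_offspring: float
    overlap_cov: float = 0.0

    def __post_init__(self) -> None:
        if not self.se_own > 0:
            raise ValueError(f"{self.snp_id}: se_own must be positive")
        if not self.se_offspring > 0:
            raise ValueError(f"{self.snp_id}: se_offspring must be positive")


@dataclass
class PartitionedEffect:
    """Maternal- and fetal-specific SNP effects on birth weight."""

    snp_id: str
    beta_mat: float
    se_mat: float
    beta_fet: float
    se_fet: float
    cov_mat_fet: float = 0.0

    def __post_init__(self) -> None:
        if not self.se_mat > 0:
            raise ValueError(f"{self.snp_id}: se_mat must be positive")
        if not self.se_fet > 0:
            raise ValueError(f"{self.snp_id}: se_fet must be positive")
        if abs(self.cov_mat_fet) > self.se_mat * self.se_fet * (1 + 1e-12):
            raise ValueError(f"{self.snp_id}: |cov_mat_fet| exceeds se_mat*se_fet")


# Inverse of the expectation map [[1/2, 1], [1, 1/2]] acting on (bm, bf):
#   bm = (4*beta_offspring - 2*beta_own) / 3
#   bf = (4*beta_own - 2*beta_offspring) / 3
_A_MAT = np.array([-2.0 / 3.0, 4.0 / 3.0])  # coefficients on (beta_own, beta_offspring)
_A_FET = np.array([4.0 / 3.0, -2.0 / 3.0])


def forward_expectations(beta_mat: float, beta_fet: float) -> tuple[float, float]:
    """Map (maternal, fetal) effects to the two marginal expectations."""
    return beta_fet + 0.5 * beta_mat, beta_mat + 0.5 * beta_fet


def partition_effects(pair: UnpartitionedPair) -> PartitionedEffect:
    """Solve the marginal-expectation system for maternal/fetal effects.

    Standard errors and the maternal-fetal covariance follow by linear error
    propagation through the (exact) inverse map, using the supplied marginal
    SEs and overlap covariance.
    """
    b = np.array([pair.beta_own, pair.beta_offspring])
    cov = np.array(
        [
            [pair.se_own**2, pair.overlap_cov],
            [pair.overlap_cov, pair.se_offspring**2],
        ]
    )
    beta_mat = float(_A_MAT @ b)
    beta_fet = float(_A_FET @ b)
    var_mat = float(_A_MAT @ cov @ _A_MAT)
    var_fet = float(_A_FET @ cov @ _A_FET)
    cov_mf = float(_A_MAT @ cov @ _A_FET)
    return PartitionedEffect(
        snp_id=pair.snp_id,
        beta_mat=beta_mat,
        se_mat=float(np.sqrt(var_mat)),
        beta_fet=beta_fet,
        se_fet=float(np.sqrt(var_fet)),
        cov_mat_fet=cov_mf,
    )


def conditional_duo_regression(
    maternal_genotype,
    offspring_genotype,
    offspring_bw,
    snp_id: str = "",
) -> PartitionedEffect:
    """Two-covariate regression of offspring BW on maternal + offspring genotype.

    The coefficient on maternal genotype is the maternal-specific effect and
    the coefficient on offspring genotype the fetal-specific effect.  This is
    the individual-level quantity that the summary-level partition emulates,
    so it serves as its oracle on simulated duos.
    """
    gm = np.asarray(maternal_genotype, dtype=float)
    go = np.asarray(offspring_genotype, dtype=float)
    y = np.asarray(offspring_bw, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 duos")
    if gm.std() == 0 or go.std() == 0:
        raise ValueError(f"{snp_id or 'SNP'}: constant genotype column")

    X = np.column_stack([np.ones(n), gm, go])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(f"{snp_id or 'SNP'}: collinear genotype columns")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - 3
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * xtx_inv
    return PartitionedEffect(
        snp_id=snp_id,
        beta_mat=float(coef[1]),
        se_mat=float(np.sqrt(cov[1, 1])),
        beta_fet=float(coef[2]),
        se_fet=float(np.sqrt(cov[2, 2])),
        cov_mat_fet=float(cov[1, 2]),
    )


# ---------------------------------------------------------------------------
# Tab-delimited IO for partitioned / unpartitioned tables

_UNPART_COLS = ["SNP", "effect_allele", "other_allele", "beta_own", "se_own",
                "beta_offspring", "se_offspring", "overlap_cov"]
_PART_COLS = ["SNP", "effect_allele", "other_allele", "beta_mat", "se_mat",
              "beta_fet", "se_fet", "cov_mat_fet"]


def read_unpartitioned(path) -> list[UnpartitionedPair]:
    df = pd.read_csv(path, sep="\t")
    pairs = []
    for row in df.itertuples(index=False):
        pairs.append(
            UnpartitionedPair(
                snp_id=str(row.SNP),
                beta_own=float(row.beta_own),
                se_own=float(row.se_own),
                beta_offspring=float(row.beta_offspring),
                se_offspring=float(row.se_offspring),
                overlap_cov=float(getattr(row, "overlap_cov", 0.0) or 0.0),
            )
        )
    return pairs


def write_partitioned(effects, path, alleles=None) -> None:
    """Write PartitionedEffect rows as TSV; `alleles` maps snp_id -> (ea, oa)."""
    rows = []
    for eff in effects:
        ea, oa = (alleles or {}).get(eff.snp_id, ("", ""))
        rows.append([eff.snp_id, ea, oa, eff.beta_mat, eff.se_mat,
                     eff.beta_fet, eff.se_fet, eff.cov_mat_fet])
    pd.DataFrame(rows, columns=_PART_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
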