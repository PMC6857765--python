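"""Synthetic mother-offspring duo data and two-sample summary statistics.

The generative model mirrors the causal diagram the analysis assumes:
maternal genotype -> maternal lipids -> offspring birth weight (the
intrauterine path), maternal genotype -> offspring genotype (Mendelian
transmission with coefficient 1/2) -> fetal lipid propensity -> own birth
weight, plus optional direct (pleiotropic) maternal-genotype effects on
birth weight.  Phenotypes are scaled to unit total variance so all effects
are in SD units.

Two sampling levels are provided: full duo-level simulation
(:func:`simulate_duos`, with GWAS-style summarisation) and a fast
summary-statistic generator (:func:`simulate_instrument_table`) that draws
per-SNP estimates directly from their asymptotic sampling distributions at
paper-scale sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import LIPIDS
from .partition import PartitionedEffect, UnpartitionedPair
from .summary_io import InstrumentTable, SummaryRecord

logger = logging.getLogger(__name__)

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside-violating")


@dataclass
class SimulationConfig:
    """Generative parameters for the duo / two-sample simulation.

    ``exposure_effects`` is an (n_snps, 3) matrix of per-allele effects on
    the three lipids (SD units); ``pleiotropy`` an optional per-SNP direct
    maternal-genotype effect on birth weight.  ``seed`` is mandatory: every
    stochastic draw goes through one generator derived from it.
    """

    n_snps: int
    allele_freqs: np.ndarray
    exposure_effects: np.ndarray
    beta_mat_true: np.ndarray = field(default_factory=lambda: np.zeros(3))
    beta_fet_true: np.ndarray = field(default_factory=lambda: np.zeros(3))
    exposure_corr: np.ndarray = field(default_factory=lambda: np.eye(3))
    pleiotropy: np.ndarray | None = None
    pleiotropy_mode: str = "none"
    n_sample1: int = 188_577
    n_sample2: int = 230_069
    n_duos: int = 20_000
    seed: int = 0
    #: variance inflation of partitioned outcome SEs relative to a marginal
    #: GWAS of the same n (20/9 = the closed-form partition with equal
    #: marginal SEs and no overlap)
    partition_se_inflation: float = 20.0 / 9.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        self.exposure_effects = np.atleast_2d(
            np.asarray(self.exposure_effects, dtype=float)
        )
        self.beta_mat_true = np.asarray(self.beta_mat_true, dtype=float)
        self.beta_fet_true = np.asarray(self.beta_fet_true, dtype=float)
        self.exposure_corr = np.asarray(self.exposure_corr, dtype=float)
        if self.allele_freqs.shape != (self.n_snps,):
            raise ValueError("allele_freqs must have shape (n_snps,)")
        if np.any(self.allele_freqs <= 0.01) or np.any(self.allele_freqs >= 0.99):
            raise ValueError("allele frequencies must lie in (0.01, 0.99)")
        if self.exposure_effects.shape != (self.n_snps, 3):
            raise ValueError("exposure_effects must have shape (n_snps, 3)")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(
                f"unknown pleiotropy mode {self.pleiotropy_mode!r}; "
                f"known: {PLEIOTROPY_MODES}"
            )
        if self.pleiotropy is not None:
            self.pleiotropy = np.asarray(self.pleiotropy, dtype=float)
            if self.pleiotropy.shape != (self.n_snps,):
                raise ValueError("pleiotropy must have shape (n_snps,)")
        try:
            np.linalg.cholesky(self.exposure_corr)
        except np.linalg.LinAlgError:
            raise ValueError("exposure_corr must be positive-definite") from None
        # fail fast on impossible variance decompositions
        self.lipid_residual_cov()
        self.bw_residual_var()

    # -- variance bookkeeping ------------------------------------------------

    def genotype_variances(self) -> np.ndarray:
        f = self.allele_freqs
        return 2.0 * f * (1.0 - f)

    def lipid_genetic_variances(self) -> np.ndarray:
        return self.genotype_variances() @ self.exposure_effects**2

    def lipid_residual_cov(self) -> np.ndarray:
        """Residual covariance scaling each lipid to unit total variance."""
        resid_var = 1.0 - self.lipid_genetic_variances()
        if np.any(resid_var <= 0):
            raise ValueError(
                "exposure effects imply negative residual lipid variance"
            )
        d = np.sqrt(resid_var)
        return d[:, None] * self.exposure_corr * d[None, :]

    def snp_effects_on_bw(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (maternal, fetal) total genotype effects on BW.

        Maternal: via maternal lipids plus any direct pleiotropic path;
        fetal: via the offspring's genetic lipid propensity.
        """
        pleio = self.pleiotropy if self.pleiotropy is not None else 0.0
        m = self.exposure_effects @ self.beta_mat_true + pleio
        f = self.exposure_effects @ self.beta_fet_true
        return m, f

    def bw_residual_var(self) -> float:
        """Residual BW variance scaling BW to unit total variance."""
        v = self.genotype_variances()
        m, f = self.snp_effects_on_bw()
        # cov(maternal, offspring genotype) = v/2 per SNP
        genetic = float(np.sum(v * (m**2 + f**2 + m * f)))
        resid_cov = self.lipid_residual_cov()
        via_noise = float(
            self.beta_mat_true @ resid_cov @ self.beta_mat_true
            + self.beta_fet_true @ resid_cov @ self.beta_fet_true
        )
        resid = 1.0 - genetic - via_noise
        if resid <= 0:
            raise ValueError("effect sizes imply negative residual BW variance")
        return resid


@dataclass
class DuoRecord:
    """One mother-offspring pair."""

    maternal_genotype: np.ndarray
    offspring_genotype: np.ndarray
    maternal_lipids: np.ndarray
    offspring_bw: float


@dataclass
class DuoData:
    """Vectorized duo sample: rows are duos, genotype columns are SNPs."""

    maternal_genotypes: np.ndarray
    offspring_genotypes: np.ndarray
    maternal_lipids: np.ndarray
    offspring_bw: np.ndarray
    mother_own_bw: np.ndarray
    config: SimulationConfig

    @property
    def n_duos(self) -> int:
        return len(self.offspring_bw)

    def records(self):
        for i in range(self.n_duos):
            yield DuoRecord(
                maternal_genotype=self.maternal_genotypes[i],
                offspring_genotype=self.offspring_genotypes[i],
                maternal_lipids=self.maternal_lipids[i],
                offspring_bw=float(self.offspring_bw[i]),
            )


def _transmitted_allele(rng, genotypes: np.ndarray) -> np.ndarray:
    """One allele drawn uniformly from a diploid genotype (0/1/2)."""
    het = genotypes == 1
    out = (genotypes == 2).astype(np.int8)
    out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def _lipids_from_genotype(rng, G, config: SimulationConfig) -> np.ndarray:
    chol = np.linalg.cholesky(config.lipid_residual_cov())
    noise = rng.standard_normal((len(G), 3)) @ chol.T
    return G @ config.exposure_effects + noise


def _bw_from(rng, mat_lipids, off_lipids, Gm, config: SimulationConfig) -> np.ndarray:
    pleio = config.pleiotropy
    direct = Gm @ pleio if pleio is not None else 0.0
    resid_sd = np.sqrt(config.bw_residual_var())
    return (
        mat_lipids @ config.beta_mat_true
        + off_lipids @ config.beta_fet_true
        + direct
        + rng.normal(0.0, resid_sd, size=len(Gm))
    )


def simulate_duos(config: SimulationConfig, rng=None) -> DuoData:
    """Simulate genotyped mother-offspring duos under the generative model.

    Maternal genotypes are Hardy-Weinberg draws; each offspring receives one
    maternal allele (uniformly among the mother's two) and one paternal
    allele drawn from the population frequency.  Mothers' own birth weights
    are generated by applying the same model one generation up, drawing
    grandmaternal genotypes conditionally on the mothers'.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, f = config.n_duos, config.allele_freqs

    Gm = rng.binomial(2, f, size=(n, config.n_snps)).astype(np.int8)
    paternal = rng.binomial(1, f, size=(n, config.n_snps)).astype(np.int8)
    Go = _transmitted_allele(rng, Gm) + paternal

    mat_lipids = _lipids_from_genotype(rng, Gm, config)
    # latent lipid propensity of the fetus; its noise only adds BW residual
    off_lipids = _lipids_from_genotype(rng, Go, config)
    bw = _bw_from(rng, mat_lipids, off_lipids, Gm, config)

    # one generation up: grandmother = allele transmitted to mother + pop allele
    grand_pat = rng.binomial(1, f, size=(n, config.n_snps)).astype(np.int8)
    Gg = _transmitted_allele(rng, Gm) + grand_pat
    grand_lipids = _lipids_from_genotype(rng, Gg, config)
    own_bw = _bw_from(rng, grand_lipids, mat_lipids, Gg, config)

    return DuoData(
        maternal_genotypes=Gm,
        offspring_genotypes=Go,
        maternal_lipids=mat_lipids,
        offspring_bw=bw,
        mother_own_bw=own_bw,
        config=config,
    )


# ---------------------------------------------------------------------------
# GWAS-style summarisation


def _marginal_regressions(G, y):
    """Per-SNP simple regression of y on each genotype column.

    Returns (beta, se, keep) arrays; `keep` is False for monomorphic SNPs.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sgg = np.einsum("ij,ij->j", gc, gc)
    keep = sgg > 0
    sgy = yc @ gc
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[keep] = sgy[keep] / sgg[keep]
        rss = syy - beta[keep] ** 2 * sgg[keep]
        se[keep] = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sgg[keep])
    return beta, se, keep


def summarize_sample1(
    config: SimulationConfig, rng=None
) -> dict[str, list[SummaryRecord]]:
    """Simulate the exposure GWAS (sample 1) and summarize it per lipid.

    An independent cohort of ``n_sample1`` unrelated individuals is drawn
    from the same generative model; each lipid is regressed on each SNP.
    Monomorphic SNPs are dropped with a warning.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_sample1
    G = rng.binomial(2, config.allele_freqs, size=(n, config.n_snps)).astype(np.int8)
    lipids = _lipids_from_genotype(rng, G, config)

    out: dict[str, list[SummaryRecord]] = {}
    for j, lipid in enumerate(LIPIDS):
        beta, se, keep = _marginal_regressions(G, lipids[:, j])
        if not keep.all():
            for k in np.flatnonzero(~keep):
                logger.warning("snp%04d monomorphic in sample 1; dropped", k)
        t = np.abs(beta[keep] / se[keep])
        p = 2.0 * stats.t.sf(t, n - 2)
        p = np.maximum(p, np.finfo(float).tiny)
        recs = []
        for idx, b, s, pv in zip(np.flatnonzero(keep), beta[keep], se[keep], p):
            recs.append(
                SummaryRecord(
                    snp_id=f"snp{idx:04d}",
                    effect_allele="A",
                    other_allele="G",
                    beta=float(b),
                    se=float(s),
                    eaf=float(config.allele_freqs[idx]),
                    pvalue=float(pv),
                    n=n,
                    trait=lipid,
                )
            )
        out[lipid] = recs
    return out


def _conditional_regressions(Gm, Go, y):
    """Vectorized per-SNP two-covariate regression of y on (Gm_k, Go_k)."""
    Gm = np.asarray(Gm, dtype=float)
    Go = np.asarray(Go, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = Gm.shape
    gm = Gm - Gm.mean(axis=0)
    go = Go - Go.mean(axis=0)
    yc = y - y.mean()
    s11 = np.einsum("ij,ij->j", gm, gm)
    s22 = np.einsum("ij,ij->j", go, go)
    s12 = np.einsum("ij,ij->j", gm, go)
    r1 = yc @ gm
    r2 = yc @ go
    det = s11 * s22 - s12**2
    keep = det > 1e-12
    bm = np.full(d, np.nan)
    bf = np.full(d, np.nan)
    se_m = np.full(d, np.nan)
    se_f = np.full(d, np.nan)
    cov_mf = np.full(d, np.nan)
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        bm[keep] = (s22[keep] * r1[keep] - s12[keep] * r2[keep]) / det[keep]
        bf[keep] = (s11[keep] * r2[keep] - s12[keep] * r1[keep]) / det[keep]
        rss = syy - bm[keep] * r1[keep] - bf[keep] * r2[keep]
        sigma2 = np.maximum(rss, 0.0) / (n - 3)
        se_m[keep] = np.sqrt(sigma2 * s22[keep] / det[keep])
        se_f[keep] = np.sqrt(sigma2 * s11[keep] / det[keep])
        cov_mf[keep] = -sigma2 * s12[keep] / det[keep]
    return bm, se_m, bf, se_f, cov_mf, keep


def summarize_sample2(
    duos: DuoData,
) -> tuple[list[UnpartitionedPair], list[PartitionedEffect]]:
    """Summarize the outcome sample per SNP.

    Emits both the two marginal regressions (own BW on own genotype via the
    mothers, offspring BW on maternal genotype) as
    :class:`UnpartitionedPair` rows, and the duo-level conditional
    regression (truth-level partition) as :class:`PartitionedEffect` rows.
    """
    Gm = duos.maternal_genotypes
    beta_own, se_own, keep_own = _marginal_regressions(Gm, duos.mother_own_bw)
    beta_off, se_off, keep_off = _marginal_regressions(Gm, duos.offspring_bw)
    bm, se_m, bf, se_f, cov_mf, keep_c = _conditional_regressions(
        Gm, duos.offspring_genotypes, duos.offspring_bw
    )
    keep = keep_own & keep_off & keep_c
    if not keep.all():
        for k in np.flatnonzero(~keep):
            logger.warning("snp%04d monomorphic/collinear in sample 2; dropped", k)
    pairs, parts = [], []
    for k in np.flatnonzero(keep):
        sid = f"snp{k:04d}"
        pairs.append(
            UnpartitionedPair(
                snp_id=sid,
                beta_own=float(beta_own[k]),
                se_own=float(se_own[k]),
                beta_offspring=float(beta_off[k]),
                se_offspring=float(se_off[k]),
            )
        )
        parts.append(
            PartitionedEffect(
                snp_id=sid,
                beta_mat=float(bm[k]),
                se_mat=float(se_m[k]),
                beta_fet=float(bf[k]),
                se_fet=float(se_f[k]),
                cov_mat_fet=float(cov_mf[k]),
            )
        )
    return pairs, parts


# ---------------------------------------------------------------------------
# Fast summary-level generator


def analytic_ses(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic (se_zx, se_zy_partitioned) per SNP at the config's sizes."""
    v = config.genotype_variances()
    se_zx = np.sqrt(1.0 / (config.n_sample1 * v))
    se_zy = np.sqrt(config.partition_se_inflation / (config.n_sample2 * v))
    return se_zx, se_zy


def simulate_instrument_table(config: SimulationConfig, rng=None) -> InstrumentTable:
    """Draw a harmonized instrument table directly at summary level.

    Per-SNP estimates are sampled from their asymptotic normal sampling
    distributions around the generative values, with exposure estimation
    errors correlated across lipids by ``exposure_corr`` (same sample).
    Orders of magnitude faster than individual-level simulation; used for
    calibration and power studies at paper-scale sample sizes.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    B = config.exposure_effects
    se_zx, se_zy = analytic_ses(config)
    chol = np.linalg.cholesky(config.exposure_corr)
    noise = rng.standard_normal((config.n_snps, 3)) @ chol.T
    beta_zx = B + noise * se_zx[:, None]
    z = np.abs(beta_zx / se_zx[:, None])
    p_zx = np.maximum(2.0 * stats.norm.sf(z), np.finfo(float).tiny)

    m, fet = config.snp_effects_on_bw()
    beta_mat = m + rng.normal(0.0, se_zy)
    beta_fet = fet + rng.normal(0.0, se_zy)

    df = pd.DataFrame(
        {
            "snp_id": [f"snp{k:04d}" for k in range(config.n_snps)],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": config.allele_freqs,
        }
    )
    for j, lipid in enumerate(LIPIDS):
        df[f"beta_{lipid}"] = beta_zx[:, j]
        df[f"se_{lipid}"] = se_zx
        df[f"p_{lipid}"] = p_zx[:, j]
    df["beta_mat"] = beta_mat
    df["se_mat"] = se_zy
    df["beta_fet"] = beta_fet
    df["se_fet"] = se_zy
    return InstrumentTable(df, exposures=list(LIPIDS))


# ---------------------------------------------------------------------------
# Scenario presets

# Overlap structure reproducing the 96/82/60 per-lipid instrument counts on
# 185 SNPs: singles per lipid + pairwise doubles (sums: 57+25+14=96,
# 43+25+14=82, 32+14+14=60). The split among doubles is arbitrary.
_MEMBER_COUNTS = {"singles": (57, 43, 32), "hdl_ldl": 25, "hdl_tg": 14, "ldl_tg": 14}
#: variance in each lipid explained by its instruments (arbitrary but
#: documented; the paper does not give effect-size distributions)
_R2_PER_LIPID = (0.12, 0.12, 0.10)

SCENARIOS = (
    "paper-null",
    "maternal-positive",
    "directional-pleiotropy",
    "inside-violation",
    "invalid-40pct",
    "invalid-60pct",
)


def _membership_matrix() -> np.ndarray:
    """185 x 3 boolean membership with per-lipid counts 96/82/60."""
    s_h, s_l, s_t = _MEMBER_COUNTS["singles"]
    blocks = (
        [(1, 0, 0)] * s_h
        + [(0, 1, 0)] * s_l
        + [(0, 0, 1)] * s_t
        + [(1, 1, 0)] * _MEMBER_COUNTS["hdl_ldl"]
        + [(1, 0, 1)] * _MEMBER_COUNTS["hdl_tg"]
        + [(0, 1, 1)] * _MEMBER_COUNTS["ldl_tg"]
    )
    return np.array(blocks, dtype=bool)


def _base_config(seed: int) -> SimulationConfig:
    rng = np.random.default_rng(seed ^ 0x5EED)
    member = _membership_matrix()
    n_snps = len(member)
    freqs = rng.uniform(0.05, 0.95, size=n_snps)
    v = 2.0 * freqs * (1.0 - freqs)
    B = np.zeros((n_snps, 3))
    for j in range(3):
        # draw on the variance-standardized scale with a magnitude floor so
        # every member SNP stays genome-wide significant at sample-1 scale
        # regardless of its allele frequency; the preset then reproduces the
        # per-lipid instrument counts
        draw = rng.standard_normal(n_snps)
        u = np.sign(np.where(draw == 0, 1.0, draw)) * (1.0 + np.abs(draw))
        u *= member[:, j]
        u *= np.sqrt(_R2_PER_LIPID[j] / float(np.sum(u**2)))
        B[:, j] = u / np.sqrt(v)
    corr = np.array([[1.0, -0.2, -0.4], [-0.2, 1.0, 0.3], [-0.4, 0.3, 1.0]])
    return SimulationConfig(
        n_snps=n_snps,
        allele_freqs=freqs,
        exposure_effects=B,
        exposure_corr=corr,
        seed=seed,
    )


def _breakdown_config(seed: int, frac_invalid: float) -> SimulationConfig:
    """Equal-strength HDL instruments with a directional ratio offset on an
    exact weight fraction of them.

    Equal instrument strength makes the invalid weight share exactly the
    invalid SNP count share, so the weighted-median breakdown point can be
    probed cleanly: valid instruments all have the same Wald-ratio precision,
    keeping the finite-sample quantile shift of the weighted median small
    relative to its bootstrap SE below 50% invalid weight.
    """
    n_snps = 15
    n_bad = int(round(frac_invalid * n_snps))
    freqs = np.full(n_snps, 0.3)
    v = 2.0 * freqs * (1.0 - freqs)
    B = np.zeros((n_snps, 3))
    B[:, 0] = np.sqrt(0.08 / n_snps / v)  # 8% of HDL variance, split evenly
    pleio = np.zeros(n_snps)
    pleio[:n_bad] = 0.3 * B[:n_bad, 0]  # +0.3 SD/SD ratio offset when invalid
    return SimulationConfig(
        n_snps=n_snps,
        allele_freqs=freqs,
        exposure_effects=B,
        pleiotropy=pleio,
        pleiotropy_mode="directional",
        seed=seed,
    )


def scenario_library(seed: int = 0) -> dict[str, SimulationConfig]:
    """Named simulation presets covering the analysis' failure modes."""
    base = _base_config(seed)
    sign_h = np.sign(np.where(base.exposure_effects[:, 0] == 0, 1.0,
                              base.exposure_effects[:, 0]))
    lib = {
        "paper-null": base,
        "maternal-positive": replace(
            base, beta_mat_true=np.array([0.1, 0.1, 0.1])
        ),
        "directional-pleiotropy": replace(
            base, pleiotropy=0.02 * sign_h, pleiotropy_mode="directional"
        ),
        "inside-violation": replace(
            base,
            pleiotropy=0.3 * base.exposure_effects[:, 0]
            + np.random.default_rng(seed ^ 0xBAD).normal(0, 0.005, base.n_snps),
            pleiotropy_mode="inside-violating",
        ),
        "invalid-40pct": _breakdown_config(seed, 0.40),
        "invalid-60pct": _breakdown_config(seed, 0.60),
    }
    return lib


def scenario(name: str, seed: int = 0) -> SimulationConfig:
    lib = scenario_library(seed)
    if name not in lib:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(lib)}")
    return lib[name]
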