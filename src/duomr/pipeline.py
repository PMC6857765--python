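"""End-to-end analysis: load -> harmonize -> select -> orient -> estimate.

Produces a long-format results table (exposure x snp_set x method x outcome)
plus diagnostics, exclusion logs and a provenance block, mirroring a
forest-plot-style report.  All randomness is routed through one seeded
generator recorded in the provenance block, so a rerun with the same config
and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import LIPIDS, __version__
from .summary_io import (
    InstrumentTable,
    SelectionRule,
    SummaryRecord,
    harmonize,
    orient_positive,
    read_summary,
    select_instruments,
)
from .partition import UnpartitionedPair, partition_effects
from .estimators import MIN_SNPS, run_estimator
from .diagnostics import i2_gx, funnel_data, sd_to_grams, wald_ratios
from .multivariable import mv_egger, mv_ivw

logger = logging.getLogger(__name__)

_RESULT_COLS = [
    "exposure", "snp_set", "outcome", "method", "n_snps", "estimate", "se",
    "ci_low", "ci_high", "pvalue", "intercept", "intercept_se", "intercept_p",
    "estimate_g", "ci_low_g", "ci_high_g", "skip_reason",
]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, besides the input files' bytes."""

    sample1_paths: dict[str, str]
    sample2_path: str
    snp_sets: tuple[str, ...] = ("unrestricted", "restricted")
    estimators: tuple[str, ...] = (
        "ivw", "egger", "weighted_median", "simple_mode", "weighted_mode",
    )
    outcomes: tuple[str, ...] = ("maternal",)
    run_multivariable: bool = True
    n_boot: int = 1000
    seed: int = 0
    sd_grams: float = 454.0
    min_instruments: int = 5
    palindromic_eaf_limit: float = 0.08
    genome_wide_threshold: float = 5.0e-8
    restricted_other_threshold: float = 0.05

    def __post_init__(self) -> None:
        stochastic = {"weighted_median", "simple_mode", "weighted_mode"}
        if stochastic & set(self.estimators) and self.seed is None:
            raise ValueError("seed required when bootstrap estimators are requested")
        unknown = set(self.snp_sets) - {"unrestricted", "restricted"}
        if unknown:
            raise ValueError(f"unknown snp_set(s): {sorted(unknown)}")

    def content_hash(self) -> str:
        payload = asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisReport:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    exclusions: list[tuple[str, str]]
    provenance: dict
    snp_usage: pd.DataFrame = field(default_factory=pd.DataFrame)


def _read_sample2(path) -> tuple[list[SummaryRecord], list[SummaryRecord]]:
    """Read the outcome table, partitioning marginal pairs if necessary.

    Accepts either a pre-partitioned table (beta_mat/se_mat/beta_fet/se_fet)
    or an unpartitioned own/offspring marginal-pair table.
    """
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    snp_col = "SNP" if "SNP" in cols else "snp_id"
    if not {"beta_mat", "se_mat"} <= cols:
        if not {"beta_own", "se_own", "beta_offspring", "se_offspring"} <= cols:
            raise ValueError(
                f"{path}: neither partitioned (beta_mat/se_mat) nor "
                "unpartitioned (beta_own/beta_offspring) columns found"
            )
        logger.info("%s: unpartitioned outcome table; applying closed-form partition", path)
        parts = []
        for row in df.itertuples(index=False):
            pair = UnpartitionedPair(
                snp_id=str(getattr(row, snp_col)),
                beta_own=float(row.beta_own),
                se_own=float(row.se_own),
                beta_offspring=float(row.beta_offspring),
                se_offspring=float(row.se_offspring),
                overlap_cov=float(getattr(row, "overlap_cov", 0.0) or 0.0),
            )
            parts.append(partition_effects(pair))
        df = df.assign(
            beta_mat=[p.beta_mat for p in parts],
            se_mat=[p.se_mat for p in parts],
            beta_fet=[p.beta_fet for p in parts],
            se_fet=[p.se_fet for p in parts],
        )
        cols = set(df.columns)

    mat, fet = [], []
    for row in df.itertuples(index=False):
        common = dict(
            snp_id=str(getattr(row, snp_col)),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            eaf=float(row.eaf) if "eaf" in cols and not pd.isna(row.eaf) else None,
        )
        mat.append(SummaryRecord(beta=float(row.beta_mat), se=float(row.se_mat),
                                 trait="bw_mat", **common))
        if "beta_fet" in cols and not pd.isna(row.beta_fet):
            fet.append(SummaryRecord(beta=float(row.beta_fet), se=float(row.se_fet),
                                     trait="bw_fet", **common))
    return mat, fet


def _skip_row(exposure, snp_set, outcome, method, reason, n_snps=0):
    row = {c: np.nan for c in _RESULT_COLS}
    row.update(exposure=exposure, snp_set=snp_set, outcome=outcome,
               method=method, n_snps=n_snps, skip_reason=reason)
    return row


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis grid described by ``config``."""
    rng = np.random.default_rng(config.seed)

    exposures = {}
    for lipid, path in config.sample1_paths.items():
        exposures[lipid] = read_summary(path, trait=lipid)
    outcome_mat, outcome_fet = _read_sample2(config.sample2_path)

    table = harmonize(
        exposures, outcome_mat, outcome_fet,
        palindromic_eaf_limit=config.palindromic_eaf_limit,
    )
    logger.info("harmonized table: %d SNPs, %d exclusions",
                table.n_snps, len(table.exclusions))

    rows, diag_rows = [], []
    for lipid in config.sample1_paths:
        for snp_set in config.snp_sets:
            rule = SelectionRule(
                genome_wide_threshold=config.genome_wide_threshold,
                restricted_other_threshold=config.restricted_other_threshold,
                mode=snp_set,
            )
            try:
                selected = select_instruments(table, lipid, rule)
            except ValueError as exc:
                for outcome in config.outcomes:
                    for method in config.estimators:
                        rows.append(_skip_row(lipid, snp_set, outcome, method,
                                              f"selection failed: {exc}"))
                continue
            if selected.n_snps < config.min_instruments:
                for outcome in config.outcomes:
                    for method in config.estimators:
                        rows.append(_skip_row(
                            lipid, snp_set, outcome, method,
                            "insufficient instruments "
                            f"({selected.n_snps} < {config.min_instruments})",
                            n_snps=selected.n_snps,
                        ))
                continue
            oriented = orient_positive(selected, lipid)

            for weighting in ("unweighted", "egger-weighted"):
                rep = i2_gx(oriented, exposure=lipid, weighting=weighting)
                diag_rows.append({
                    "exposure": lipid, "snp_set": snp_set, "kind": "i2_gx",
                    "weighting": weighting, "value": rep.i2_gx,
                    "q": rep.q_gx, "n_snps": rep.n_snps,
                })

            for outcome in config.outcomes:
                ratios = wald_ratios(oriented, outcome=outcome, exposure=lipid)
                if len(ratios) >= 3:
                    _, symmetry = funnel_data(ratios)
                    diag_rows.append({
                        "exposure": lipid, "snp_set": snp_set,
                        "kind": "funnel_symmetry", "outcome": outcome,
                        "value": symmetry["slope"], "se": symmetry["se"],
                        "pvalue": symmetry["pvalue"],
                    })
                for method in config.estimators:
                    if oriented.n_snps < MIN_SNPS.get(method, 3):
                        rows.append(_skip_row(
                            lipid, snp_set, outcome, method,
                            f"insufficient instruments for {method}",
                            n_snps=oriented.n_snps,
                        ))
                        continue
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    est = run_estimator(
                        method, oriented, outcome=outcome, exposure=lipid,
                        n_boot=config.n_boot, seed=sub_seed,
                    )
                    grams = sd_to_grams(est, config.sd_grams)
                    rows.append({
                        "exposure": lipid, "snp_set": snp_set, "outcome": outcome,
                        "method": method, "n_snps": est.n_snps,
                        "estimate": est.estimate, "se": est.se,
                        "ci_low": est.ci_low, "ci_high": est.ci_high,
                        "pvalue": est.pvalue, "intercept": est.intercept,
                        "intercept_se": est.intercept_se,
                        "intercept_p": est.intercept_p,
                        "estimate_g": grams[0], "ci_low_g": grams[1],
                        "ci_high_g": grams[2], "skip_reason": "",
                    })

    if config.run_multivariable:
        mv_lipids = [l for l in config.sample1_paths if l in LIPIDS]
        for outcome in config.outcomes:
            try:
                res = mv_ivw(table, mv_lipids, outcome=outcome)
                for lipid in mv_lipids:
                    e = res[lipid]
                    grams = sd_to_grams((e.estimate, e.ci_low, e.ci_high),
                                        config.sd_grams)
                    rows.append({
                        "exposure": lipid, "snp_set": "all", "outcome": outcome,
                        "method": "mv_ivw", "n_snps": res.n_snps,
                        "estimate": e.estimate, "se": e.se, "ci_low": e.ci_low,
                        "ci_high": e.ci_high, "pvalue": e.pvalue,
                        "intercept": np.nan, "intercept_se": np.nan,
                        "intercept_p": np.nan, "estimate_g": grams[0],
                        "ci_low_g": grams[1], "ci_high_g": grams[2],
                        "skip_reason": "",
                    })
            except ValueError as exc:
                rows.append(_skip_row("all", "all", outcome, "mv_ivw", str(exc)))
            for lipid in mv_lipids:
                try:
                    res = mv_egger(table, mv_lipids, orient_to=lipid, outcome=outcome)
                    e = res[lipid]
                    grams = sd_to_grams((e.estimate, e.ci_low, e.ci_high),
                                        config.sd_grams)
                    rows.append({
                        "exposure": lipid, "snp_set": "all", "outcome": outcome,
                        "method": "mv_egger", "n_snps": res.n_snps,
                        "estimate": e.estimate, "se": e.se, "ci_low": e.ci_low,
                        "ci_high": e.ci_high, "pvalue": e.pvalue,
                        "intercept": res.intercept,
                        "intercept_se": res.intercept_se,
                        "intercept_p": res.intercept_p,
                        "estimate_g": grams[0], "ci_low_g": grams[1],
                        "ci_high_g": grams[2], "skip_reason": "",
                    })
                except ValueError as exc:
                    rows.append(_skip_row(lipid, "all", outcome, "mv_egger", str(exc)))

    results = pd.DataFrame(rows, columns=_RESULT_COLS)
    diagnostics = pd.DataFrame(diag_rows)

    used = set(table.df["snp_id"])
    usage_rows = [{"snp_id": s, "status": "used"} for s in sorted(used)]
    usage_rows += [
        {"snp_id": s, "status": f"excluded:{reason}"}
        for s, reason in table.exclusions
    ]
    provenance = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_snps_harmonized": table.n_snps,
        "n_exclusions": len(table.exclusions),
    }
    return AnalysisReport(
        results=results,
        diagnostics=diagnostics,
        exclusions=table.exclusions,
        provenance=provenance,
        snp_usage=pd.DataFrame(usage_rows),
    )


def render_report(report: AnalysisReport, output_dir, forest: bool = True) -> list[str]:
    """Write the report tables (and forest plots) under ``output_dir``."""
    import pathlib

    out = pathlib.Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.results.empty:
        raise ValueError("empty report: nothing to render")

    written = []

    def _write(df, name):
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(str(path))

    _write(report.results, "results.tsv")
    if not report.diagnostics.empty:
        _write(report.diagnostics, "diagnostics.tsv")
    if not report.snp_usage.empty:
        _write(report.snp_usage, "snp_usage.tsv")
    with open(out / "exclusions.log", "w") as fh:
        for snp, reason in report.exclusions:
            fh.write(f"{snp}\t{reason}\n")
    written.append(str(out / "exclusions.log"))
    with open(out / "provenance.txt", "w") as fh:
        for key, val in sorted(report.provenance.items()):
            fh.write(f"{key}\t{val}\n")
    written.append(str(out / "provenance.txt"))

    if forest:
        written += _forest_plots(report, out)
    return written


def _forest_plots(report: AnalysisReport, out) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    res = report.results
    for exposure in sorted(res["exposure"].dropna().unique()):
        sub = res[(res["exposure"] == exposure) & (res["skip_reason"] == "")]
        skipped = res[(res["exposure"] == exposure) & (res["skip_reason"] != "")]
        if sub.empty and skipped.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 0.5 * (len(sub) + len(skipped)) + 1.5))
        labels, y = [], 0
        for row in sub.itertuples(index=False):
            ax.errorbar(
                row.estimate, y,
                xerr=[[row.estimate - row.ci_low], [row.ci_high - row.estimate]],
                fmt="s", color="black", capsize=3,
            )
            labels.append(f"{row.method} ({row.snp_set}, n={int(row.n_snps)})")
            y += 1
        for row in skipped.itertuples(index=False):
            ax.text(0, y, "skipped", ha="center", va="center", fontsize=8, color="grey")
            labels.append(f"{row.method} ({row.snp_set}): {row.skip_reason}")
            y += 1
        ax.axvline(0, color="grey", lw=0.8, ls="--")
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels, fontsize=8)
        ax.invert_yaxis()
        ax.set_xlabel("SD change in birth weight per SD exposure")
        ax.set_title(exposure.upper())
        fig.tight_layout()
        path = out / f"forest_{exposure}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(str(path))
    return written
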