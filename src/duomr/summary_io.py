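"""Reading, writing, harmonization and filtering of GWAS summary statistics.

Summary statistics arrive as tab-delimited text with a header row (gzip
accepted).  Column names are mapped through a configurable *dialect* so that
the many flavours of GWAS output can be consumed without editing files.

The central product of this module is the :class:`InstrumentTable`: one row
per SNP, joining per-lipid exposure associations (sample 1) with the
partitioned maternal- and fetal-specific outcome associations (sample 2),
with alleles harmonized to a common orientation.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column-name mapping for summary-statistic files.
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

#: Columns that must be present in every summary file.
_MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")


class SummaryFormatError(ValueError):
    """A summary-statistics file violates the expected format."""


@dataclass
class SummaryRecord:
    """One SNP's association with one trait in one sample.

    ``beta`` is the additive effect per copy of ``effect_allele``, in trait
    SD units.  ``eaf``, ``pvalue`` and ``n`` may be missing (``None``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        if self.effect_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.eaf is not None and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.snp_id}: pvalue {self.pvalue} outside (0, 1]")

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == _COMPLEMENT[self.effect_allele]


@dataclass(frozen=True)
class SelectionRule:
    """Instrument selection thresholds.

    ``unrestricted`` keeps SNPs genome-wide significant for the designated
    exposure; ``restricted`` additionally requires no evidence of association
    (p above ``restricted_other_threshold``) with the other two lipids.
    """

    genome_wide_threshold: float = 5.0e-8
    restricted_other_threshold: float = 0.05
    mode: str = "unrestricted"

    def __post_init__(self) -> None:
        if self.mode not in ("unrestricted", "restricted"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if not self.genome_wide_threshold < self.restricted_other_threshold:
            raise ValueError(
                "genome_wide_threshold must be below restricted_other_threshold"
            )


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, newline="" if "r" in mode else "")


def _parse_float(text: str, what: str, lineno: int) -> float | None:
    text = text.strip()
    if text in ("", "NA", "NaN", "nan", "."):
        return None
    try:
        return float(text)
    except ValueError:
        raise SummaryFormatError(f"line {lineno}: non-numeric {what}: {text!r}") from None


def read_summary(
    path,
    dialect: Mapping[str, str] | None = None,
    trait: str = "",
) -> list[SummaryRecord]:
    """Read a tab-delimited summary-statistics file into records.

    Parameters
    ----------
    path
        File path; ``.gz`` suffix triggers transparent decompression.
    dialect
        Mapping from record field names to column names in the file.
        Missing keys fall back to :data:`DEFAULT_DIALECT`.
    trait
        Trait label attached to every record.

    Raises
    ------
    SummaryFormatError
        If a mandatory column is absent, or a line has a non-numeric or
        invalid value (the error names the offending line).
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)

    with _open_text(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SummaryFormatError(f"{path}: empty file") from None
        col_index = {name: i for i, name in enumerate(header)}
        for fld in _MANDATORY_FIELDS:
            if dia[fld] not in col_index:
                raise SummaryFormatError(
                    f"{path}: missing mandatory column {dia[fld]!r} "
                    f"(have: {', '.join(header)})"
                )

        def get(row, fld):
            col = dia.get(fld)
            if col is None or col not in col_index or col_index[col] >= len(row):
                return ""
            return row[col_index[col]]

        records: list[SummaryRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            beta = _parse_float(get(row, "beta"), "beta", lineno)
            se = _parse_float(get(row, "se"), "se", lineno)
            if beta is None or se is None:
                raise SummaryFormatError(f"line {lineno}: missing beta or se")
            eaf = _parse_float(get(row, "eaf"), "eaf", lineno)
            pvalue = _parse_float(get(row, "pvalue"), "pvalue", lineno)
            n_raw = _parse_float(get(row, "n"), "n", lineno)
            try:
                records.append(
                    SummaryRecord(
                        snp_id=get(row, "snp_id").strip(),
                        effect_allele=get(row, "effect_allele").strip(),
                        other_allele=get(row, "other_allele").strip(),
                        beta=beta,
                        se=se,
                        eaf=eaf,
                        pvalue=pvalue,
                        n=int(n_raw) if n_raw is not None else None,
                        trait=trait,
                    )
                )
            except ValueError as exc:
                raise SummaryFormatError(f"line {lineno}: {exc}") from None
    return records


def write_summary(records: Iterable[SummaryRecord], path, dialect=None) -> None:
    """Write records back out in the tab-delimited dialect."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    cols = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"]
    with _open_text(path, "wt") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([dia[c] for c in cols])
        for rec in records:
            writer.writerow(
                [
                    rec.snp_id,
                    rec.effect_allele,
                    rec.other_allele,
                    "" if rec.eaf is None else repr(rec.eaf),
                    repr(rec.beta),
                    repr(rec.se),
                    "" if rec.pvalue is None else repr(rec.pvalue),
                    "" if rec.n is None else rec.n,
                ]
            )


# ---------------------------------------------------------------------------
# InstrumentTable


class InstrumentTable:
    """Harmonized per-SNP table joining exposure and outcome associations.

    Backed by a :class:`pandas.DataFrame` with one row per SNP and columns

    ``snp_id, effect_allele, other_allele, eaf,
    beta_<lipid>, se_<lipid>, p_<lipid>  (per available lipid),
    beta_mat, se_mat, beta_fet, se_fet``

    Exposure columns may be NaN where a SNP was absent from that lipid's
    summary file; ``beta_mat`` is never NaN.  ``oriented_to`` names the
    exposure whose betas have been made non-negative (or ``None``);
    ``snp_set`` records the selection rule that produced the table.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        exposures: Sequence[str],
        oriented_to: str | None = None,
        snp_set: str | None = None,
        exclusions: list[tuple[str, str]] | None = None,
    ) -> None:
        self.exposures = tuple(exposures)
        self.oriented_to = oriented_to
        self.snp_set = snp_set
        self.exclusions = list(exclusions or [])
        df = df.reset_index(drop=True)
        if df["snp_id"].str.lower().duplicated().any():
            dups = df.loc[df["snp_id"].str.lower().duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id(s): {dups}")
        beta_cols = [f"beta_{e}" for e in self.exposures]
        if len(df) and df[beta_cols].isna().all(axis=1).any():
            raise ValueError("row(s) with no exposure beta at all")
        if len(df) and df["beta_mat"].isna().any():
            raise ValueError("row(s) with missing maternal outcome beta")
        if self.oriented_to is not None:
            b = df[f"beta_{self.oriented_to}"]
            if (b.dropna() < 0).any():
                raise ValueError(f"table claims orientation to {self.oriented_to} "
                                 "but has negative exposure betas")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def copy(self) -> "InstrumentTable":
        return InstrumentTable(
            self.df.copy(), self.exposures, self.oriented_to, self.snp_set,
            list(self.exclusions),
        )

    def subset(self, mask) -> "InstrumentTable":
        return InstrumentTable(
            self.df.loc[mask].copy(), self.exposures, self.oriented_to,
            self.snp_set, list(self.exclusions),
        )

    def drop_snps(self, snp_ids: Iterable[str]) -> "InstrumentTable":
        drop = {s.lower() for s in snp_ids}
        keep = ~self.df["snp_id"].str.lower().isin(drop)
        return self.subset(keep)

    def resolve_exposure(self, exposure: str | None = None) -> str:
        """Decide which exposure an estimator should use."""
        if exposure is not None:
            if exposure not in self.exposures:
                raise ValueError(f"exposure {exposure!r} not in table {self.exposures}")
            return exposure
        if self.oriented_to is not None:
            return self.oriented_to
        present = [
            e for e in self.exposures if self.df[f"beta_{e}"].notna().any()
        ]
        if len(present) == 1:
            return present[0]
        raise ValueError(
            "ambiguous exposure: pass exposure= explicitly "
            f"(table holds {present})"
        )

    def exposure_records(self, lipid: str) -> list[SummaryRecord]:
        """Rebuild summary records for one lipid (round-trip support)."""
        recs = []
        for row in self.df.itertuples(index=False):
            beta = getattr(row, f"beta_{lipid}")
            if pd.isna(beta):
                continue
            p = getattr(row, f"p_{lipid}", float("nan"))
            recs.append(
                SummaryRecord(
                    snp_id=row.snp_id,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=float(beta),
                    se=float(getattr(row, f"se_{lipid}")),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    pvalue=None if pd.isna(p) else float(p),
                    trait=lipid,
                )
            )
        return recs

    def outcome_records(self, side: str = "maternal") -> list[SummaryRecord]:
        col = {"maternal": "mat", "fetal": "fet"}[side]
        recs = []
        for row in self.df.itertuples(index=False):
            beta = getattr(row, f"beta_{col}")
            if pd.isna(beta):
                continue
            recs.append(
                SummaryRecord(
                    snp_id=row.snp_id,
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    beta=float(beta),
                    se=float(getattr(row, f"se_{col}")),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    trait=f"bw_{col}",
                )
            )
        return recs

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def write_exclusion_log(self, path) -> None:
        with open(path, "w") as fh:
            for snp, reason in self.exclusions:
                fh.write(f"{snp}\t{reason}\n")


def _align_to_reference(
    ref_ea: str, ref_oa: str, rec: SummaryRecord
) -> float | None:
    """Return +1/-1 if rec's alleles can be aligned to (ref_ea, ref_oa).

    Tries direct match, allele swap, strand complement and swapped
    complement, in that order.  ``None`` means irreconcilable.
    """
    ea, oa = rec.effect_allele, rec.other_allele
    if (ea, oa) == (ref_ea, ref_oa):
        return 1.0
    if (oa, ea) == (ref_ea, ref_oa):
        return -1.0
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return 1.0
    if (coa, cea) == (ref_ea, ref_oa):
        return -1.0
    return None


def harmonize(
    exposure: Mapping[str, Sequence[SummaryRecord]] | Sequence[SummaryRecord],
    outcome_maternal: Sequence[SummaryRecord],
    outcome_fetal: Sequence[SummaryRecord] | None = None,
    palindromic_eaf_limit: float = 0.08,
) -> InstrumentTable:
    """Join exposure and outcome summary statistics on a common orientation.

    SNPs are matched case-insensitively on rsID.  The exposure side defines
    the reference allele orientation; outcome (and any further exposure)
    betas are sign-flipped where their effect/other alleles are swapped, with
    strand complements tried before declaring a SNP irreconcilable.

    Strand-ambiguous SNPs (A/T or C/G) whose exposure effect-allele frequency
    is missing or within ``palindromic_eaf_limit`` of 0.5 are dropped and
    logged, since their orientation cannot be inferred.

    Only SNPs present in both samples (>= 1 exposure and the maternal
    outcome) are retained.
    """
    if not isinstance(exposure, Mapping):
        grouped: dict[str, list[SummaryRecord]] = {}
        for rec in exposure:
            grouped.setdefault(rec.trait or "exposure", []).append(rec)
        exposure = grouped
    lipids = list(exposure)

    exp_by_snp: dict[str, dict[str, SummaryRecord]] = {}
    for lipid, recs in exposure.items():
        for rec in recs:
            exp_by_snp.setdefault(rec.snp_id.lower(), {})[lipid] = rec
    mat_by_snp = {r.snp_id.lower(): r for r in outcome_maternal}
    fet_by_snp = {r.snp_id.lower(): r for r in (outcome_fetal or [])}

    exclusions: list[tuple[str, str]] = []
    rows = []
    for key in exp_by_snp:
        if key not in mat_by_snp:
            continue  # not in both samples; not logged as an exclusion
        per_lipid = exp_by_snp[key]
        ref = next(iter(per_lipid.values()))
        ref_ea, ref_oa, snp_id = ref.effect_allele, ref.other_allele, ref.snp_id

        if ref.is_palindromic:
            if ref.eaf is None:
                exclusions.append((snp_id, "palindromic_missing_eaf"))
                logger.warning("%s: palindromic SNP with missing eaf dropped", snp_id)
                continue
            if abs(ref.eaf - 0.5) <= palindromic_eaf_limit:
                exclusions.append((snp_id, "palindromic_ambiguous_eaf"))
                logger.warning(
                    "%s: palindromic SNP with eaf %.3f near 0.5 dropped",
                    snp_id, ref.eaf,
                )
                continue

        row: dict[str, object] = {
            "snp_id": snp_id,
            "effect_allele": ref_ea,
            "other_allele": ref_oa,
            "eaf": np.nan if ref.eaf is None else ref.eaf,
        }
        ok = True
        for lipid in lipids:
            rec = per_lipid.get(lipid)
            if rec is None:
                row[f"beta_{lipid}"] = np.nan
                row[f"se_{lipid}"] = np.nan
                row[f"p_{lipid}"] = np.nan
                continue
            sign = _align_to_reference(ref_ea, ref_oa, rec)
            if sign is None:
                exclusions.append((snp_id, f"irreconcilable_alleles_{lipid}"))
                logger.warning(
                    "%s: alleles %s/%s irreconcilable with %s/%s; SNP dropped",
                    snp_id, rec.effect_allele, rec.other_allele, ref_ea, ref_oa,
                )
                ok = False
                break
            row[f"beta_{lipid}"] = sign * rec.beta
            row[f"se_{lipid}"] = rec.se
            row[f"p_{lipid}"] = np.nan if rec.pvalue is None else rec.pvalue
        if not ok:
            continue

        mat = mat_by_snp[key]
        sign = _align_to_reference(ref_ea, ref_oa, mat)
        if sign is None:
            exclusions.append((snp_id, "irreconcilable_alleles_outcome"))
            logger.warning("%s: outcome alleles irreconcilable; SNP dropped", snp_id)
            continue
        row["beta_mat"] = sign * mat.beta
        row["se_mat"] = mat.se

        fet = fet_by_snp.get(key)
        if fet is not None:
            fsign = _align_to_reference(ref_ea, ref_oa, fet)
            if fsign is None:
                exclusions.append((snp_id, "irreconcilable_alleles_fetal"))
                logger.warning("%s: fetal alleles irreconcilable; SNP dropped", snp_id)
                continue
            row["beta_fet"] = fsign * fet.beta
            row["se_fet"] = fet.se
        else:
            row["beta_fet"] = np.nan
            row["se_fet"] = np.nan
        rows.append(row)

    cols = ["snp_id", "effect_allele", "other_allele", "eaf"]
    for lipid in lipids:
        cols += [f"beta_{lipid}", f"se_{lipid}", f"p_{lipid}"]
    cols += ["beta_mat", "se_mat", "beta_fet", "se_fet"]
    df = pd.DataFrame(rows, columns=cols)
    return InstrumentTable(df, exposures=lipids, exclusions=exclusions)


def select_instruments(
    table: InstrumentTable, exposure: str, rule: SelectionRule | None = None
) -> InstrumentTable:
    """Filter an instrument table by the genome-wide / restricted rule.

    Unrestricted mode keeps rows with exposure p below the genome-wide
    threshold.  Restricted mode additionally requires p above the
    ``restricted_other_threshold`` for *both* other lipids; rows for which
    those p-values are unavailable make the rule unverifiable and raise.
    """
    rule = rule or SelectionRule()
    if exposure not in table.exposures:
        raise ValueError(f"exposure {exposure!r} not in table {table.exposures}")
    p_exp = table.df[f"p_{exposure}"]
    keep = p_exp.notna() & (p_exp < rule.genome_wide_threshold)

    if rule.mode == "restricted":
        others = [e for e in table.exposures if e != exposure]
        if len(others) != 2:
            raise ValueError(
                "restricted selection needs the two other lipids in the table; "
                f"have exposures {table.exposures}"
            )
        for other in others:
            p_other = table.df[f"p_{other}"]
            if (keep & p_other.isna()).any():
                bad = table.df.loc[keep & p_other.isna(), "snp_id"].tolist()
                raise ValueError(
                    f"restricted rule unverifiable: missing p_{other} for {bad}"
                )
            keep &= p_other > rule.restricted_other_threshold

    out = table.subset(keep)
    out.snp_set = rule.mode
    return out


def orient_positive(table: InstrumentTable, exposure: str) -> InstrumentTable:
    """Orient effect alleles so the designated exposure's betas are >= 0.

    Rows with a negative exposure beta have *all* betas (every lipid plus the
    maternal and fetal outcome) sign-flipped and their alleles swapped, so
    every Wald ratio is preserved exactly.  Rows with an exposure beta of
    exactly zero are dropped with a warning (orientation undefined).
    """
    if exposure not in table.exposures:
        raise ValueError(f"exposure {exposure!r} not in table {table.exposures}")
    df = table.df.copy()
    b = df[f"beta_{exposure}"]
    if b.isna().any():
        bad = df.loc[b.isna(), "snp_id"].tolist()
        raise ValueError(f"cannot orient: missing beta_{exposure} for {bad}")

    exclusions = list(table.exclusions)
    zero = b == 0.0
    if zero.any():
        for snp in df.loc[zero, "snp_id"]:
            exclusions.append((snp, "zero_exposure_beta"))
            logger.warning("%s: exposure beta is 0; orientation undefined, dropped", snp)
        df = df.loc[~zero].copy()
        b = df[f"beta_{exposure}"]

    flip = b < 0
    beta_cols = [f"beta_{e}" for e in table.exposures] + ["beta_mat", "beta_fet"]
    df.loc[flip, beta_cols] = -df.loc[flip, beta_cols]
    ea = df.loc[flip, "effect_allele"].copy()
    df.loc[flip, "effect_allele"] = df.loc[flip, "other_allele"]
    df.loc[flip, "other_allele"] = ea
    df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    return InstrumentTable(
        df, table.exposures, oriented_to=exposure, snp_set=table.snp_set,
        exclusions=exclusions,
    )
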