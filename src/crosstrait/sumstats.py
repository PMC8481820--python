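"""Reading, standardization and harmonization of GWAS summary statistics.

Two-sample analyses (genetic correlation, meta-analysis, Mendelian
randomization) require both studies' per-SNP effects to be expressed on the
same scale and oriented to the same effect allele on the same strand. This
module reads delimited summary-statistics files into a canonical tabular
form (log-odds/linear effects, Z-scores), then harmonizes each study against
a reference panel: filtering rare, non-biallelic, unresolvable or discordant
variants and re-orienting every surviving effect so that the effect allele
equals the panel's alt allele.

Columns of the canonical table: ``snp_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pval, z, n, n_cases, n_controls``.
Coordinates are 1-based fully closed; the genome build is carried as
metadata only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .panel import ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "SumStats",
    "QcParams",
    "HarmonizationReport",
    "read_sumstats",
    "to_zscores",
    "harmonize",
    "write_sumstats",
]

CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "z", "n", "n_cases", "n_controls",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: removal categories itemized by harmonize, in the order they are applied
REMOVAL_CATEGORIES = [
    "non_autosomal", "missing_rsid", "non_biallelic", "duplicate",
    "absent_from_panel", "incompatible_alleles", "rare",
    "palindromic_ambiguous", "af_discordant",
]


@dataclass
class SumStats:
    """One trait's standardized per-SNP association records."""

    trait_label: str
    table: pd.DataFrame
    build: str = "GRCh37"
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sumstats table missing columns: {missing}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def copy(self) -> "SumStats":
        return SumStats(self.trait_label, self.table.copy(), self.build, self.provenance)


@dataclass
class QcParams:
    """Thresholds of the harmonization filters.

    maf_min: minimum minor-allele frequency (study scale).
    palindrome_eaf_halfwidth: A/T and C/G SNPs with |EAF - 0.5| below this
        are strand-unresolvable and removed.
    af_discordance_max: maximum tolerated |study EAF - panel EAF| after
        orientation.
    """

    maf_min: float = 0.01
    palindrome_eaf_halfwidth: float = 0.15
    af_discordance_max: float = 0.15
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "palindrome_eaf_halfwidth", "af_discordance_max"):
            v = getattr(self, name)
            if not 0 < v <= 0.5:
                raise ConfigError(f"QcParams.{name} must be in (0, 0.5], got {v}")


@dataclass
class HarmonizationReport:
    """Per-filter removal counts for one harmonization run."""

    n_input: int
    n_output: int
    removals: dict[str, int] = field(default_factory=dict)
    n_sign_flipped: int = 0

    def __post_init__(self) -> None:
        for cat in REMOVAL_CATEGORIES:
            self.removals.setdefault(cat, 0)
        total = self.n_output + sum(self.removals.values())
        if total != self.n_input:
            raise ValueError(
                f"removal counts do not conserve SNPs: {self.n_input} in, "
                f"{self.n_output} out + {sum(self.removals.values())} removed"
            )

    def to_table(self) -> pd.DataFrame:
        rows = [("n_input", self.n_input), ("n_output", self.n_output)]
        rows += [(f"removed_{k}", v) for k, v in self.removals.items()]
        rows.append(("n_sign_flipped", self.n_sign_flipped))
        return pd.DataFrame(rows, columns=["key", "count"])


# ---------------------------------------------------------------------------
# reading

_MANDATORY = ("snp", "chrom", "pos", "effect_allele", "other_allele")


def read_sumstats(
    path: str,
    column_map: dict[str, str],
    trait_label: str,
    n_default: float | None = None,
    sep: str = "\t",
) -> SumStats:
    """Read a delimited summary-statistics file into canonical form.

    ``column_map`` maps canonical keys (``snp, chrom, pos, effect_allele,
    other_allele, eaf, beta, or, se, z, pval, n, n_cases, n_controls``) to
    the file's header names. Effects are brought onto the log-odds / linear
    scale: an ``or`` column is natural-log transformed; odds ratios are
    recognized by column mapping only, never by value magnitude. Gzip input
    is handled transparently. Rows whose mandatory fields do not parse are
    dropped and counted in the log.
    """
    try:
        raw = pd.read_csv(path, sep=sep, compression="infer")
    except pd.errors.EmptyDataError:
        raise DataError(f"empty summary-statistics file: {path}")
    if raw.empty:
        raise DataError(f"no data rows in summary-statistics file: {path}")

    for key, header in column_map.items():
        if header not in raw.columns:
            raise ConfigError(
                f"column map entry {key!r} -> {header!r} not found in header of {path}"
            )
    for key in _MANDATORY:
        if key not in column_map:
            raise ConfigError(f"column map must provide {key!r}")
    has_beta = "beta" in column_map and "se" in column_map
    has_or = "or" in column_map and "se" in column_map
    has_z = "z" in column_map and "n" in column_map
    if not (has_beta or has_or or has_z):
        raise ConfigError("column map must provide (beta,se), (or,se) or (z,n)")

    df = pd.DataFrame(index=raw.index)
    df["snp_id"] = raw[column_map["snp"]].astype(str)
    df["chrom"] = pd.to_numeric(
        raw[column_map["chrom"]].astype(str).str.replace("chr", "", regex=False),
        errors="coerce",
    )
    df["pos"] = pd.to_numeric(raw[column_map["pos"]], errors="coerce")
    df["effect_allele"] = raw[column_map["effect_allele"]].astype(str).str.upper()
    df["other_allele"] = raw[column_map["other_allele"]].astype(str).str.upper()
    for key, col in (("eaf", "eaf"), ("se", "se"), ("pval", "pval"),
                     ("n", "n"), ("n_cases", "n_cases"), ("n_controls", "n_controls")):
        df[col] = (
            pd.to_numeric(raw[column_map[key]], errors="coerce")
            if key in column_map else np.nan
        )
    if has_beta:
        df["beta"] = pd.to_numeric(raw[column_map["beta"]], errors="coerce")
    elif has_or:
        orv = pd.to_numeric(raw[column_map["or"]], errors="coerce")
        df["beta"] = np.log(orv.where(orv > 0))
    else:
        df["beta"] = np.nan
    df["z"] = (
        pd.to_numeric(raw[column_map["z"]], errors="coerce")
        if "z" in column_map else np.nan
    )
    if df["n"].isna().all() and n_default is not None:
        df["n"] = float(n_default)

    # rows must carry a usable effect: (beta, se) or (z, n)
    ok = (
        df["snp_id"].notna()
        & df["chrom"].notna()
        & df["pos"].notna()
        & (df["effect_allele"].str.len() > 0)
        & (df["other_allele"].str.len() > 0)
        & ((df["beta"].notna() & df["se"].notna()) | (df["z"].notna() & df["n"].notna()))
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows with unparseable mandatory fields", path, n_bad)
    df = df[ok].reset_index(drop=True)
    # z-only input: back out beta/se on the standardized scale
    zonly = df["beta"].isna() & df["z"].notna()
    if zonly.any():
        se = 1.0 / np.sqrt(df.loc[zonly, "n"])
        df.loc[zonly, "se"] = se
        df.loc[zonly, "beta"] = df.loc[zonly, "z"] * se
    df["chrom"] = df["chrom"].astype(int)
    df["pos"] = df["pos"].astype(int)
    return SumStats(trait_label=trait_label, table=df[CANONICAL_COLUMNS], provenance=str(path))


def to_zscores(ss: SumStats) -> SumStats:
    """Set z = beta/se on every record; fill missing p-values from z.

    Records with se <= 0 are invalid, dropped and counted in the log.
    """
    df = ss.table.copy()
    bad = ~(df["se"] > 0)
    if bad.any():
        logger.warning("%s: dropped %d records with se <= 0", ss.trait_label, int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    df["z"] = df["beta"] / df["se"]
    need_p = df["pval"].isna()
    df.loc[need_p, "pval"] = 2.0 * stats.norm.sf(np.abs(df.loc[need_p, "z"]))
    return SumStats(ss.trait_label, df, ss.build, ss.provenance)


# ---------------------------------------------------------------------------
# harmonization


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.str.translate(_COMPLEMENT)


def harmonize(
    ss: SumStats,
    panel: ReferencePanel,
    qc: QcParams | None = None,
) -> tuple[SumStats, HarmonizationReport]:
    """Filter and re-orient one study's records against the reference panel.

    Filters, applied in order (each SNP counted once, under its first
    failure): non-autosomal chromosome; missing rsID; non-biallelic alleles;
    duplicate rsID (the smallest-se record is kept); absence from the panel;
    alleles incompatible with the panel under both strands; minor-allele
    frequency < ``maf_min``; palindromic (A/T, C/G) with EAF within
    ``palindrome_eaf_halfwidth`` of 0.5 (strand unresolvable); post-
    orientation |EAF - panel AF| > ``af_discordance_max``.

    Surviving records are re-oriented so effect_allele equals the panel alt
    allele: when re-orientation is needed, beta and z change sign and eaf is
    complemented. Palindromic SNPs that pass the ambiguity filter are
    oriented by frequency match against the panel. Running harmonize on its
    own output is a no-op (zero removals, zero flips).
    """
    qc = qc or QcParams()
    df = ss.table.copy()
    n_input = len(df)
    removals = dict.fromkeys(REMOVAL_CATEGORIES, 0)

    def drop(mask: pd.Series, category: str) -> None:
        nonlocal df
        removals[category] += int(mask.sum())
        df = df[~mask]

    if qc.autosomes_only:
        drop(~df["chrom"].between(1, 22), "non_autosomal")
    drop(~df["snp_id"].str.fullmatch(r"rs\d+"), "missing_rsid")
    valid = df["effect_allele"].isin(list("ACGT")) & df["other_allele"].isin(list("ACGT"))
    drop(~valid | (df["effect_allele"] == df["other_allele"]), "non_biallelic")
    # duplicates: keep the smallest-se record per rsID (first on ties)
    order = df.sort_values("se", kind="mergesort").duplicated("snp_id")
    drop(order.reindex(df.index), "duplicate")

    pv = panel.variants.set_index("snp_id")
    drop(~df["snp_id"].isin(pv.index), "absent_from_panel")
    if df.empty:
        raise DataError("no SNPs survived harmonization; review QC thresholds")

    # attach panel columns so every later mask stays index-aligned
    df = df.assign(
        _ref=pv.loc[df["snp_id"], "ref_allele"].to_numpy(),
        _alt=pv.loc[df["snp_id"], "alt_allele"].to_numpy(),
        _af=pv.loc[df["snp_id"], "af"].to_numpy(),
    )
    ea_c, oa_c = _complement(df["effect_allele"]), _complement(df["other_allele"])
    direct = (df["effect_allele"] == df["_alt"]) & (df["other_allele"] == df["_ref"])
    swapped = (df["effect_allele"] == df["_ref"]) & (df["other_allele"] == df["_alt"])
    comp = (ea_c == df["_alt"]) & (oa_c == df["_ref"])
    comp_swapped = (ea_c == df["_ref"]) & (oa_c == df["_alt"])
    df = df.assign(_flip=(swapped | comp_swapped) & ~direct & ~comp)
    drop(~(direct | swapped | comp | comp_swapped), "incompatible_alleles")

    drop(np.minimum(df["eaf"], 1 - df["eaf"]) < qc.maf_min, "rare")

    palindromic = df["effect_allele"] == _complement(df["other_allele"])
    drop(palindromic & ((df["eaf"] - 0.5).abs() < qc.palindrome_eaf_halfwidth),
         "palindromic_ambiguous")

    # orientation: non-palindromes by allele identity; palindromes (strand
    # unresolvable) by whichever orientation best matches the panel frequency
    palindromic = df["effect_allele"] == _complement(df["other_allele"])
    freq_flip = (df["eaf"] - df["_af"]).abs() > ((1 - df["eaf"]) - df["_af"]).abs()
    df["_flip"] = np.where(palindromic, freq_flip, df["_flip"])

    oriented_eaf = np.where(df["_flip"], 1 - df["eaf"], df["eaf"])
    df = df.assign(_oeaf=oriented_eaf)
    drop((df["_oeaf"] - df["_af"]).abs() > qc.af_discordance_max, "af_discordant")

    if df.empty:
        raise DataError("no SNPs survived harmonization; review QC thresholds")

    flip = df["_flip"].to_numpy(dtype=bool)
    out = df.copy()
    out["eaf"] = out["_oeaf"]
    out["beta"] = np.where(flip, -out["beta"], out["beta"])
    out["z"] = np.where(flip, -out["z"], out["z"])
    out["effect_allele"] = out["_alt"]
    out["other_allele"] = out["_ref"]
    out = (
        out[CANONICAL_COLUMNS]
        .sort_values(["chrom", "pos", "snp_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    report = HarmonizationReport(
        n_input=n_input,
        n_output=len(out),
        removals=removals,
        n_sign_flipped=int(flip.sum()),
    )
    for key, count in removals.items():
        if count:
            logger.info("%s: removed %d SNPs (%s)", ss.trait_label, count, key)
    logger.info("%s: flipped %d SNPs to panel orientation", ss.trait_label, report.n_sign_flipped)
    return SumStats(ss.trait_label, out, ss.build, ss.provenance), report


def write_sumstats(ss: SumStats, path: str) -> None:
    """Write canonical-column TSV (gzip if the path ends in .gz)."""
    ss.table.to_csv(path, sep="\t", index=False)
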