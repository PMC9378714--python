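"""Regional GWAS summary statistics: reading, validation, harmonisation, filtering.

The central container is :class:`SumstatsTable`, a thin dataclass around a
pandas DataFrame with a fixed column schema (``ID CHR POS EA NEA EAF BETA SE P
N COVERAGE``).  Effects are per effect-allele (``EA``): standard-deviation
units for quantitative traits, log-odds for binary traits.  Coordinates are
1-based and all window arithmetic is inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: canonical column order for all tables written or exchanged by this package
COLUMNS = ["ID", "CHR", "POS", "EA", "NEA", "EAF", "BETA", "SE", "P", "N", "COVERAGE"]

_REQUIRED_KEYS = ("variant", "chrom", "pos", "ea", "nea", "eaf", "beta", "se", "p", "n")

#: column-name presets for the two summary-statistics dialects the screen was
#: designed around.  ``covid_hgi_r6`` maps ``coverage`` to the per-variant study
#: count (``all_meta_N``); pass ``coverage_denominator`` (the total number of
#: contributing studies) to :func:`read_sumstats` to convert it to a fraction.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "pgwas": {
        "variant": "rsid",
        "chrom": "chr",
        "pos": "pos",
        "ea": "Allele1",
        "nea": "Allele2",
        "eaf": "Freq1",
        "beta": "Effect",
        "se": "StdErr",
        "p": "Pvalue",
        "n": "TotalSampleSize",
    },
    "covid_hgi_r6": {
        "variant": "rsid",
        "chrom": "#CHR",
        "pos": "POS",
        "ea": "ALT",
        "nea": "REF",
        "eaf": "all_meta_AF",
        "beta": "all_inv_var_meta_beta",
        "se": "all_inv_var_meta_sebeta",
        "p": "all_inv_var_meta_p",
        "n": "all_inv_var_meta_effective",
        "coverage": "all_meta_N",
    },
}

_ACGT = frozenset("ACGT")
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


class SumstatsError(ValueError):
    """Fatal problem with a summary-statistics table."""


@dataclass(frozen=True)
class Region:
    """A 1-based, both-ends-inclusive genomic interval with an anchor label."""

    chrom: str
    start: int
    end: int
    anchor: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    ea: str
    nea: str
    eaf: float | None = None


@dataclass(frozen=True)
class AssocRecord:
    """One variant's association summary for a single trait."""

    variant: Variant
    beta: float
    se: float
    p: float
    n: float
    coverage: float = 1.0


@dataclass
class SumstatsTable:
    """Regional association summary statistics for one trait.

    ``df`` follows the :data:`COLUMNS` schema and is kept sorted by position.
    """

    trait_label: str
    trait_type: str  # "quantitative" | "binary"
    df: pd.DataFrame
    region: Region | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"table missing columns {missing}")
        if self.df["ID"].duplicated().any():
            dup = self.df.loc[self.df["ID"].duplicated(), "ID"].iloc[0]
            raise SumstatsError(f"duplicate variant id {dup!r}")
        self.df = self.df.sort_values("POS", kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["ID"].to_numpy()

    def records(self):
        """Iterate rows as :class:`AssocRecord` views."""
        for row in self.df.itertuples(index=False):
            cov = 1.0 if pd.isna(row.COVERAGE) else float(row.COVERAGE)
            eaf = None if pd.isna(row.EAF) else float(row.EAF)
            yield AssocRecord(
                Variant(row.ID, str(row.CHR), int(row.POS), row.EA, row.NEA, eaf),
                float(row.BETA), float(row.SE), float(row.P), float(row.N), cov,
            )

    def zscores(self) -> np.ndarray:
        return (self.df["BETA"] / self.df["SE"]).to_numpy()

    def sentinel(self) -> str:
        """Regional lead variant: smallest p, ties by larger |z| then lower position."""
        d = self.df
        z = np.abs(d["BETA"] / d["SE"])
        order = np.lexsort((d["POS"].to_numpy(), -z.to_numpy(), d["P"].to_numpy()))
        return str(d["ID"].iloc[order[0]])

    def min_p(self) -> float:
        return float(self.df["P"].min())

    def write_tsv(self, path) -> None:
        self.df.loc[:, COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(
    path,
    trait_label: str,
    trait_type: str,
    column_map: str | Mapping[str, str],
    coverage_denominator: float | None = None,
) -> SumstatsTable:
    """Read and validate a whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps the schema keys (variant, chrom, pos, ea, nea, eaf,
    beta, se, p, n; optional coverage) to the file's column names, or names a
    preset from :data:`COLUMN_PRESETS`.  Gzip input is handled transparently.
    Rows with non-ACGT alleles or non-positive SE are dropped with a logged
    count; a file with zero valid rows is a fatal error.
    """
    if isinstance(column_map, str):
        try:
            column_map = COLUMN_PRESETS[column_map]
        except KeyError:
            raise SumstatsError(f"unknown column preset {column_map!r}") from None
    missing = [k for k in _REQUIRED_KEYS if k not in column_map]
    if missing:
        raise SumstatsError(f"column_map missing required keys {missing}")

    raw = pd.read_csv(path, sep=r"\s+", compression="infer")
    absent = [v for k, v in column_map.items() if v not in raw.columns]
    if absent:
        raise SumstatsError(f"input {path} missing required columns {absent}")

    df = pd.DataFrame(
        {
            "ID": raw[column_map["variant"]].astype(str),
            "CHR": raw[column_map["chrom"]].astype(str),
            "POS": raw[column_map["pos"]].astype(np.int64),
            "EA": raw[column_map["ea"]].astype(str).str.upper(),
            "NEA": raw[column_map["nea"]].astype(str).str.upper(),
            "EAF": pd.to_numeric(raw[column_map["eaf"]], errors="coerce"),
            "BETA": pd.to_numeric(raw[column_map["beta"]], errors="coerce"),
            "SE": pd.to_numeric(raw[column_map["se"]], errors="coerce"),
            "P": pd.to_numeric(raw[column_map["p"]], errors="coerce"),
            "N": pd.to_numeric(raw[column_map["n"]], errors="coerce"),
        }
    )
    if "coverage" in column_map:
        cov = pd.to_numeric(raw[column_map["coverage"]], errors="coerce")
        if coverage_denominator is not None:
            cov = cov / float(coverage_denominator)
        df["COVERAGE"] = cov
    else:
        df["COVERAGE"] = np.nan

    valid = (
        df["EA"].isin(list(_ACGT))
        & df["NEA"].isin(list(_ACGT))
        & (df["EA"] != df["NEA"])
        & (df["SE"] > 0)
        & df["BETA"].notna()
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & (df["POS"] >= 1)
    )
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.info("%s: dropped %d invalid rows (alleles/SE/P)", trait_label, n_dropped)
    df = df.loc[valid].reset_index(drop=True)
    if df.empty:
        raise SumstatsError(f"{path}: zero valid rows")

    _check_p_z_consistency(df, trait_label)
    return SumstatsTable(trait_label, trait_type, df)


def _check_p_z_consistency(df: pd.DataFrame, label: str) -> None:
    # meta-analysis p-values may come from heterogeneity-adjusted tests, so a
    # p/z mismatch is reported but never fatal
    with np.errstate(divide="ignore"):
        z_from_p = stats.norm.isf(df["P"].to_numpy() / 2.0)
    z = np.abs(df["BETA"].to_numpy() / df["SE"].to_numpy())
    ok = np.isfinite(z_from_p) & (z_from_p > 0)
    bad = ok & ((z > 10 * z_from_p) | (z_from_p > 10 * z))
    if bad.any():
        log.warning(
            "%s: %d records with p inconsistent with beta/se beyond a factor of 10",
            label, int(bad.sum()),
        )


def extract_region(
    table: SumstatsTable, anchor: Region | int, flank: int = 500_000
) -> SumstatsTable:
    """Restrict a table to ``anchor ± flank`` (inclusive boundaries).

    ``anchor`` is a gene :class:`Region` or a single centre position; an empty
    result is returned as an empty table, not an error.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if isinstance(anchor, Region):
        chrom, start, end, label = anchor.chrom, anchor.start, anchor.end, anchor.anchor
    else:
        pos = int(anchor)
        chrom, start, end, label = None, pos, pos, str(pos)
    lo, hi = start - flank, end + flank
    mask = (table.df["POS"] >= lo) & (table.df["POS"] <= hi)
    if chrom is not None:
        mask &= table.df["CHR"].astype(str) == str(chrom)
    out = table.df.loc[mask].reset_index(drop=True)
    region = Region(chrom if chrom is not None else str(table.df["CHR"].iloc[0]) if len(table.df) else "NA",
                    max(1, lo), hi, label)
    return SumstatsTable(table.trait_label, table.trait_type, out, region)


def _is_palindromic(ea: str, nea: str) -> bool:
    return {ea, nea} in _PALINDROMIC


def harmonise_pair(
    t1: SumstatsTable,
    t2: SumstatsTable,
    drop_palindromic_maf_band: tuple[float, float] | None = (0.40, 0.50),
) -> tuple[SumstatsTable, SumstatsTable]:
    """Align two tables to the same variants, strand and effect allele.

    Intersects on variant id; where t2's alleles are swapped relative to t1,
    t2's beta changes sign and its EAF becomes 1−EAF.  Allele pairs that are
    neither identical nor swapped are dropped.  Strand-ambiguous A/T and C/G
    variants are dropped when the minor-allele frequency (in either table)
    falls inside ``drop_palindromic_maf_band`` — only applied when both tables
    carry EAF for the variant.  No strand flipping is attempted.
    """
    if len(t1) == 0 or len(t2) == 0:
        raise SumstatsError("harmonise_pair requires two non-empty tables")
    m = t1.df.merge(t2.df, on="ID", suffixes=("_1", "_2"))
    if m.empty:
        raise SumstatsError(
            f"no shared variants between {t1.trait_label!r} and {t2.trait_label!r}"
        )
    same = (m["EA_1"] == m["EA_2"]) & (m["NEA_1"] == m["NEA_2"])
    swap = (m["EA_1"] == m["NEA_2"]) & (m["NEA_1"] == m["EA_2"])
    m = m.loc[same | swap].copy()
    swap = (m["EA_1"] == m["NEA_2"]) & (m["NEA_1"] == m["EA_2"])
    m.loc[swap, "BETA_2"] = -m.loc[swap, "BETA_2"]
    m.loc[swap, "EAF_2"] = 1.0 - m.loc[swap, "EAF_2"]
    m.loc[swap, ["EA_2", "NEA_2"]] = m.loc[swap, ["NEA_2", "EA_2"]].to_numpy()

    if drop_palindromic_maf_band is not None:
        lo, hi = drop_palindromic_maf_band
        pal = m.apply(lambda r: _is_palindromic(r["EA_1"], r["NEA_1"]), axis=1)
        maf1 = np.minimum(m["EAF_1"], 1 - m["EAF_1"])
        maf2 = np.minimum(m["EAF_2"], 1 - m["EAF_2"])
        both_eaf = m["EAF_1"].notna() & m["EAF_2"].notna()
        in_band = ((maf1 >= lo) & (maf1 <= hi)) | ((maf2 >= lo) & (maf2 <= hi))
        drop = pal & both_eaf & in_band
        if drop.any():
            log.info("harmonise: dropped %d ambiguous palindromic variants", int(drop.sum()))
        m = m.loc[~drop]
    if m.empty:
        raise SumstatsError("no variants survive harmonisation")

    m = m.sort_values("POS_1", kind="mergesort").reset_index(drop=True)

    def _side(suffix: str, chrom_col: str, pos_col: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ID": m["ID"],
                "CHR": m[chrom_col],
                "POS": m[pos_col],
                "EA": m[f"EA_{suffix}"],
                "NEA": m[f"NEA_{suffix}"],
                "EAF": m[f"EAF_{suffix}"],
                "BETA": m[f"BETA_{suffix}"],
                "SE": m[f"SE_{suffix}"],
                "P": m[f"P_{suffix}"],
                "N": m[f"N_{suffix}"],
                "COVERAGE": m[f"COVERAGE_{suffix}"],
            }
        )

    out1 = SumstatsTable(t1.trait_label, t1.trait_type, _side("1", "CHR_1", "POS_1"), t1.region)
    out2 = SumstatsTable(t2.trait_label, t2.trait_type, _side("2", "CHR_1", "POS_1"), t2.region)
    return out1, out2


def study_coverage_filter(table: SumstatsTable, min_fraction: float = 0.8) -> SumstatsTable:
    """Drop records reported by fewer than ``min_fraction`` of contributing studies.

    Records with missing coverage are retained (single-cohort data carry no
    meta-analysis coverage).
    """
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    keep = table.df["COVERAGE"].isna() | (table.df["COVERAGE"] >= min_fraction)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("%s: coverage filter dropped %d records", table.trait_label, n_dropped)
    return replace(table, df=table.df.loc[keep].reset_index(drop=True))


def conditional_adjust(
    table: SumstatsTable,
    ld,
    lead_ids: Sequence[str],
    max_condition_number: float = 1e8,
) -> SumstatsTable:
    """Adjust marginal z-scores for a set of independent lead signals.

    Approximate conditional analysis on the standardised scale:
    ``z' = z − R[·,S] R[S,S]^{-1} z[S]`` for lead set S; betas are rebuilt as
    ``z'·se`` with SEs unchanged (a first-order approximation).  The lead
    variants themselves are set to z' = 0.  An empty lead set is the identity.
    """
    if not lead_ids:
        return table
    ids = list(table.df["ID"])
    missing = [l for l in lead_ids if l not in ids or l not in ld.ids]
    if missing:
        raise SumstatsError(f"lead ids absent from table or LD panel: {missing}")
    sub = ld.submatrix(ids)
    idx = {v: i for i, v in enumerate(ids)}
    s = np.array([idx[l] for l in lead_ids])
    R = sub.r
    Rss = R[np.ix_(s, s)]
    if np.linalg.cond(Rss) > max_condition_number:
        raise SumstatsError(
            f"collinear lead signals {list(lead_ids)}: LD submatrix is singular"
        )
    z = table.zscores()
    z_adj = z - R[:, s] @ np.linalg.solve(Rss, z[s])
    z_adj[s] = 0.0
    df = table.df.copy()
    df["BETA"] = z_adj * df["SE"].to_numpy()
    df["P"] = np.clip(2.0 * stats.norm.sf(np.abs(z_adj)), 1e-300, 1.0)
    return replace(table, df=df)


def table_from_arrays(
    trait_label: str,
    trait_type: str,
    ids: Sequence[str],
    chrom: str | Sequence[str],
    pos: Sequence[int],
    ea: Sequence[str],
    nea: Sequence[str],
    eaf,
    beta,
    se,
    p,
    n,
    coverage=None,
    region: Region | None = None,
) -> SumstatsTable:
    """Convenience constructor from parallel arrays (used by the simulator)."""
    k = len(ids)
    df = pd.DataFrame(
        {
            "ID": list(ids),
            "CHR": [chrom] * k if isinstance(chrom, str) else list(chrom),
            "POS": np.asarray(pos, dtype=np.int64),
            "EA": list(ea),
            "NEA": list(nea),
            "EAF": np.asarray(eaf, dtype=float),
            "BETA": np.asarray(beta, dtype=float),
            "SE": np.asarray(se, dtype=float),
            "P": np.asarray(p, dtype=float),
            "N": np.asarray(n, dtype=float) if np.ndim(n) else np.full(k, float(n)),
            "COVERAGE": (np.full(k, np.nan) if coverage is None
                         else np.asarray(coverage, dtype=float)),
        }
    )
    return SumstatsTable(trait_label, trait_type, df, region)
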