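"""Proteome-wide colocalisation-first screening of proteins against outcomes.

For every protein × outcome pair the screen: restricts both tables to the
±500 kb window around the protein-coding gene, applies the study-coverage
filter, harmonises alleles, skips regions without suggestive evidence
(p < 1e-5) in either trait, colocalises, applies the instrument-representation
and sentinel-concordance LD guards, and — for pairs with PP(H4) above the
posterior threshold that pass both guards — assigns a significance tier and
estimates the causal effect by single-instrument Wald-ratio Mendelian
randomisation using the lead cis-pQTL as instrument.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .coloc import (
    ColocPriors,
    ColocResult,
    abf_vector,
    coloc,
    instrument_represented,
    sentinel_concordance,
)
from .ldpanel import LDMatrix, r2
from .mr import WaldEstimate, wald_ratio
from .sumstats import (
    SumstatsTable,
    extract_region,
    harmonise_pair,
    study_coverage_filter,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """All thresholds of the screen, with the defaults used throughout."""

    window: int = 500_000
    p_sug: float = 1e-5          # suggestive-evidence prefilter
    priors: ColocPriors = field(default_factory=ColocPriors)
    pp_min: float = 0.8          # PP(H4) candidate threshold
    r2_min: float = 0.8          # LD guard threshold (strict >)
    coverage_min: float = 0.8    # study-coverage filter
    gw: float = 5e-8             # genome-wide significance
    sug_tier: float = 1e-4       # suggestive bound for tier 3
    weak_z: float = 4.0


@dataclass
class CandidateRow:
    """One emitted candidate protein × outcome pair (one report row)."""

    protein: str
    outcome: str
    pp_h3: float
    pp_h4: float
    sentinel_protein: str
    sentinel_outcome: str
    sentinel_r2: float
    instrument: str
    ea: str
    nea: str
    eaf: float
    beta_protein: float
    se_protein: float
    p_protein: float
    beta_outcome: float
    se_outcome: float
    p_outcome: float
    tier: int | None
    wald: WaldEstimate | None
    coloc_result: ColocResult | None = None


def prefilter(t1: SumstatsTable, t2: SumstatsTable, p_sug: float = 1e-5) -> bool:
    """Region worth testing: smallest p strictly below ``p_sug`` in either trait."""
    return t1.min_p() < p_sug or t2.min_p() < p_sug


def classify_tier(
    p_protein: float,
    p_outcome: float,
    gw: float = 5e-8,
    sug: float = 1e-4,
) -> int | None:
    """Three-level candidate confidence tier from the two regional p-values.

    Tier 1: genome-wide significant (p < gw) in both; tier 2: in exactly one;
    tier 3: both suggestive (gw < p < sug).  All inequalities strict — a p
    exactly at a threshold falls on the non-significant side.  A pair with one
    suggestive and one non-suggestive p is undefined by these rules and
    returns None.
    """
    gw1, gw2 = p_protein < gw, p_outcome < gw
    if gw1 and gw2:
        return 1
    if gw1 or gw2:
        return 2
    if gw < p_protein < sug and gw < p_outcome < sug:
        return 3
    return None


def _lead_among(table: SumstatsTable, ids) -> str:
    """Representative instrument: strongest protein association among ``ids``."""
    sub = table.df[table.df["ID"].isin(set(ids))]
    z = np.abs(sub["BETA"] / sub["SE"])
    order = np.lexsort((sub["POS"].to_numpy(), -z.to_numpy(), sub["P"].to_numpy()))
    return str(sub["ID"].iloc[order[0]])


def screen_pair(
    protein: SumstatsTable,
    outcome: SumstatsTable,
    ld: LDMatrix,
    config: ScreenConfig = ScreenConfig(),
) -> CandidateRow | None:
    """Run the full per-pair pipeline; None when the pair is not a candidate."""
    if protein.region is None:
        raise ValueError(f"protein table {protein.trait_label!r} has no gene region")
    if len(outcome) == 0:
        log.info("%s × %s: empty outcome table, skipped",
                 protein.trait_label, outcome.trait_label)
        return None
    p_reg = extract_region(protein, protein.region, config.window)
    o_reg = extract_region(outcome, protein.region, config.window)
    if len(p_reg) == 0 or len(o_reg) == 0:
        log.info("%s × %s: empty window, skipped",
                 protein.trait_label, outcome.trait_label)
        return None
    p_reg = study_coverage_filter(p_reg, config.coverage_min)
    o_reg = study_coverage_filter(o_reg, config.coverage_min)
    lead_pqtl = p_reg.sentinel() if len(p_reg) else None
    p_h, o_h = harmonise_pair(p_reg, o_reg)
    if not prefilter(p_h, o_h, config.p_sug):
        return None
    if len(p_h) < 2:
        return None

    res = coloc(
        abf_vector(p_h), abf_vector(o_h), config.priors,
        sentinel1=p_h.sentinel(), sentinel2=o_h.sentinel(),
    )
    shared_ids = list(p_h.variant_ids)
    flags = {
        "instrument_represented": instrument_represented(
            lead_pqtl, shared_ids, ld, config.r2_min),
        "sentinel_ld_pass": sentinel_concordance(res, ld, config.r2_min),
    }
    res.filter_flags = flags
    if res.pp["H4"] <= config.pp_min or not all(flags.values()):
        return None

    tier = classify_tier(p_h.min_p(), o_h.min_p(), config.gw, config.sug_tier)
    if tier is None:
        log.info("%s × %s: PP(H4) passes but p-value pattern matches no tier",
                 protein.trait_label, outcome.trait_label)
        return None
    instrument = _lead_among(p_h, shared_ids)
    prow = p_h.df.loc[p_h.df["ID"] == instrument].iloc[0]
    orow = o_h.df.loc[o_h.df["ID"] == instrument].iloc[0]
    wald = wald_ratio(prow["BETA"], prow["SE"], orow["BETA"], orow["SE"], config.weak_z)
    s_r2 = (1.0 if res.sentinel1 == res.sentinel2
            else r2(ld, res.sentinel1, res.sentinel2))
    return CandidateRow(
        protein=protein.trait_label,
        outcome=outcome.trait_label,
        pp_h3=res.pp["H3"],
        pp_h4=res.pp["H4"],
        sentinel_protein=res.sentinel1,
        sentinel_outcome=res.sentinel2,
        sentinel_r2=s_r2,
        instrument=instrument,
        ea=str(prow["EA"]),
        nea=str(prow["NEA"]),
        eaf=float(prow["EAF"]),
        beta_protein=float(prow["BETA"]),
        se_protein=float(prow["SE"]),
        p_protein=float(prow["P"]),
        beta_outcome=float(orow["BETA"]),
        se_outcome=float(orow["SE"]),
        p_outcome=float(orow["P"]),
        tier=tier,
        wald=wald,
        coloc_result=res,
    )


def run_screen(
    protein_tables: list[SumstatsTable],
    outcome_tables: list[SumstatsTable],
    ld: LDMatrix,
    config: ScreenConfig = ScreenConfig(),
) -> list[CandidateRow]:
    """Screen every protein × outcome pair; per-pair failures are logged, never fatal.

    Rows are sorted by descending |Wald ratio| so the largest candidate
    effects for the most severe outcomes lead the report.
    """
    rows: list[CandidateRow] = []
    for prot in protein_tables:
        for out in outcome_tables:
            try:
                row = screen_pair(prot, out, ld, config)
            except Exception as exc:  # noqa: BLE001 — screen must survive any pair
                log.warning("%s × %s failed: %s", prot.trait_label,
                            out.trait_label, exc)
                continue
            if row is not None:
                # every emitted candidate satisfies the full gate by construction
                assert row.tier is not None and row.pp_h4 > config.pp_min
                assert all(row.coloc_result.filter_flags.values())
                rows.append(row)
    rows.sort(key=lambda r: (-abs(r.wald.ratio), r.protein, r.outcome))
    return rows


_TSV_COLUMNS = [
    "protein", "outcome", "tier", "pp_h3", "pp_h4", "sentinel_protein",
    "sentinel_outcome", "sentinel_r2", "instrument", "ea", "nea", "eaf",
    "beta_protein", "se_protein", "p_protein", "beta_outcome", "se_outcome",
    "p_outcome", "wald_ratio", "wald_se", "wald_or", "wald_ci_low",
    "wald_ci_high", "wald_p", "weak_instrument",
]


def write_report(rows: list[CandidateRow], tsv_path, json_path=None) -> None:
    """Write the candidate table as TSV (and optionally full JSON)."""
    recs = []
    for r in rows:
        rec = {k: getattr(r, k) for k in _TSV_COLUMNS[:18]}
        rec.update(
            wald_ratio=r.wald.ratio, wald_se=r.wald.se, wald_or=r.wald.or_,
            wald_ci_low=r.wald.ci_low, wald_ci_high=r.wald.ci_high,
            wald_p=r.wald.p, weak_instrument=r.wald.weak_instrument,
        )
        recs.append(rec)
    pd.DataFrame(recs, columns=_TSV_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = []
        for r in rows:
            d = {k: getattr(r, k) for k in _TSV_COLUMNS[:18]}
            d["wald"] = asdict(r.wald)
            d["pp"] = r.coloc_result.pp
            d["per_snp_h4"] = r.coloc_result.per_snp_h4
            d["filter_flags"] = r.coloc_result.filter_flags
            payload.append(d)
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_report(tsv_path) -> pd.DataFrame:
    return pd.read_csv(tsv_path, sep="\t")
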