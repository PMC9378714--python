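"""Synthetic reference panels and regional GWAS summary statistics.

Panels: haplotypes follow a first-order Markov copying process — within a
block each haplotype copies its allele at the previous variant with
probability ``rho`` and otherwise draws a fresh allele at that variant's
frequency; blocks are independent.  Adjacent within-block correlation is
therefore ≈ rho and decays geometrically with distance, giving
block-structured LD with realised allele frequencies inside the requested
range (each marginal frequency is a convex combination of per-variant
targets).  Haplotypes are paired into diploid dosages.

Summary statistics are simulated directly at the z-score level: with regional
LD matrix R and standardised joint effects λ, marginal z-scores are drawn as
``z ~ MVN(√n_eff · R λ, R)``, then ``beta = z·se`` with ``se = 1/√n_eff``.
For quantitative traits ``n_eff = n``; for binary traits with case fraction φ,
``n_eff = n·φ(1−φ)`` (the usual log-odds effective sample size).  The five
regional scenarios mirror the colocalisation hypothesis space: no signal for
either trait (H0), one trait only (H1/H2), two distinct causal variants (H3),
one shared causal variant (H4).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .ldpanel import GenotypePanel, LDMatrix, compute_ld
from .sumstats import Region, SumstatsTable, table_from_arrays

log = logging.getLogger(__name__)

HYPOTHESIS_NAMES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class Scenario:
    """A two-trait regional simulation scenario.

    ``causal1``/``causal2`` map variant id → signed variance explained; under
    H4 they must name the same variant, under H3 distinct ones.
    """

    hypothesis: str
    causal1: dict[str, float] = field(default_factory=dict)
    causal2: dict[str, float] = field(default_factory=dict)
    n1: int = 10_000
    n2: int = 10_000
    trait_type1: str = "quantitative"
    trait_type2: str = "binary"
    case_fraction2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESIS_NAMES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.hypothesis == "H4" and set(self.causal1) != set(self.causal2):
            raise ValueError("H4 requires the identical causal variant for both traits")
        if self.hypothesis == "H3" and set(self.causal1) & set(self.causal2):
            raise ValueError("H3 requires distinct causal variants")


@dataclass
class TruthManifest:
    """Ground truth written alongside every simulated dataset."""

    hypothesis: str
    causal1: dict[str, float]
    causal2: dict[str, float]
    n1: int
    n2: int
    trait_type1: str
    trait_type2: str
    case_fraction2: float
    seed: int
    true_wald_ratio: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def simulate_panel(
    n_hap: int,
    n_var: int,
    block_len: int,
    rho: float,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing: int = 1_000,
) -> GenotypePanel:
    """Simulate a diploid reference panel with block LD structure.

    ``n_hap`` haplotypes (paired into ``n_hap // 2`` samples) at ``n_var``
    biallelic variants; within each block of ``block_len`` consecutive
    variants the latent process has first-order correlation ``rho``, with
    independence across blocks.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    lo, hi = maf_range
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("maf_range must lie within (0, 0.5]")
    if n_hap < 4 or n_hap % 2:
        raise ValueError("n_hap must be an even number >= 4")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_var)

    # blockwise Markov copying: copy the previous allele w.p. rho, else redraw
    fresh = (rng.random((n_hap, n_var)) < freqs).astype(float)
    copy = rng.random((n_hap, n_var)) < rho
    haps = np.empty((n_hap, n_var))
    for j in range(n_var):
        if j % block_len == 0:
            haps[:, j] = fresh[:, j]
        else:
            haps[:, j] = np.where(copy[:, j], haps[:, j - 1], fresh[:, j])

    dosages = haps[0::2] + haps[1::2]
    ids = [f"rs{start_pos + i * spacing}" for i in range(n_var)]
    import pandas as pd

    variants = pd.DataFrame(
        {
            "ID": ids,
            "CHR": chrom,
            "POS": [start_pos + i * spacing for i in range(n_var)],
            "EA": "A",
            "NEA": "G",
        }
    )
    sample_ids = [f"S{i:05d}" for i in range(n_hap // 2)]
    return GenotypePanel(sample_ids, ids, dosages, variants)


def _nearest_psd_cholesky(R: np.ndarray) -> np.ndarray:
    """Cholesky factor of R, repairing to the nearest PSD matrix if needed."""
    jitter = 1e-10
    for _ in range(6):
        try:
            return np.linalg.cholesky(R + jitter * np.eye(len(R)))
        except np.linalg.LinAlgError:
            jitter *= 100
    w, V = np.linalg.eigh(R)
    w_clip = np.clip(w, 1e-8, None)
    log.info("nearest-PSD repair: clipped %d negative eigenvalues", int((w < 0).sum()))
    R2 = (V * w_clip) @ V.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    return np.linalg.cholesky(R2 + 1e-10 * np.eye(len(R2)))


def _effective_n(n: int, trait_type: str, case_fraction: float) -> float:
    if trait_type == "binary":
        return n * case_fraction * (1.0 - case_fraction)
    return float(n)


def _draw_trait(
    panel: GenotypePanel,
    R: np.ndarray,
    chol: np.ndarray,
    causal: dict[str, float],
    n: int,
    trait_type: str,
    case_fraction: float,
    label: str,
    rng: np.random.Generator,
) -> SumstatsTable:
    ids = panel.variant_ids
    idx = {v: i for i, v in enumerate(ids)}
    lam = np.zeros(len(ids))
    for vid, ve in causal.items():
        if vid not in idx:
            raise ValueError(f"causal variant {vid!r} not in panel")
        if abs(ve) > 0.5:
            raise ValueError("per-variant variance explained must be <= 0.5")
        lam[idx[vid]] = np.sign(ve) * np.sqrt(abs(ve))
    n_eff = _effective_n(n, trait_type, case_fraction)
    mean = np.sqrt(n_eff) * (R @ lam)
    z = mean + chol @ rng.standard_normal(len(ids))
    se = np.full(len(ids), 1.0 / np.sqrt(n_eff))
    beta = z * se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    v = panel.variants
    region = Region(str(v["CHR"].iloc[0]), int(v["POS"].min()), int(v["POS"].max()),
                    anchor=label)
    return table_from_arrays(
        label, trait_type, v["ID"], v["CHR"].iloc[0], v["POS"], v["EA"], v["NEA"],
        eaf=panel.allele_freq(), beta=beta, se=se, p=p, n=n,
        coverage=np.ones(len(ids)), region=region,
    )


def simulate_sumstats(
    panel: GenotypePanel,
    scenario: Scenario,
    ld: LDMatrix | None = None,
) -> tuple[list[SumstatsTable], TruthManifest]:
    """Simulate marginal summary statistics for two traits on one panel.

    Returns one table per trait plus the :class:`TruthManifest`.  ``ld`` may
    be passed to reuse a precomputed LD matrix for the panel.
    """
    if ld is None:
        ld = compute_ld(panel)
    R = ld.r
    chol = _nearest_psd_cholesky(R)
    ss = np.random.SeedSequence(scenario.seed)
    rng1, rng2 = (np.random.default_rng(s) for s in ss.spawn(2))
    t1 = _draw_trait(panel, R, chol, scenario.causal1, scenario.n1,
                     scenario.trait_type1, 0.5, "trait1", rng1)
    t2 = _draw_trait(panel, R, chol, scenario.causal2, scenario.n2,
                     scenario.trait_type2, scenario.case_fraction2, "trait2", rng2)
    true_ratio = None
    if scenario.hypothesis == "H4" and scenario.causal1:
        (vid, ve1), = scenario.causal1.items()
        ve2 = scenario.causal2[vid]
        b1 = np.sign(ve1) * np.sqrt(abs(ve1))
        b2 = np.sign(ve2) * np.sqrt(abs(ve2))
        true_ratio = float(b2 / b1)
    manifest = TruthManifest(
        scenario.hypothesis, dict(scenario.causal1), dict(scenario.causal2),
        scenario.n1, scenario.n2, scenario.trait_type1, scenario.trait_type2,
        scenario.case_fraction2, scenario.seed, true_ratio,
    )
    return [t1, t2], manifest


def pick_causal_pair(ld: LDMatrix, max_r2: float = 0.05, rng=None) -> tuple[str, str]:
    """Choose two variants with r² below ``max_r2`` (for H3 scenarios)."""
    rng = np.random.default_rng(rng)
    q = len(ld.ids)
    order = rng.permutation(q)
    for a in order:
        for b in order:
            if a != b and ld.r[a, b] ** 2 < max_r2:
                return str(ld.ids[a]), str(ld.ids[b])
    raise ValueError("no variant pair below the r² ceiling")


@dataclass
class TwoAncestryData:
    panel1: GenotypePanel
    panel2: GenotypePanel
    tables1: list[SumstatsTable]
    tables2: list[SumstatsTable]
    manifest1: TruthManifest
    manifest2: TruthManifest


def simulate_two_ancestry(
    causal_id: str,
    variance_explained: float,
    panel_params_1: dict,
    panel_params_2: dict,
    n1: int = 10_000,
    n2: int = 2_000,
    seed: int = 0,
    ld1: LDMatrix | None = None,
    ld2: LDMatrix | None = None,
    panel1: GenotypePanel | None = None,
    panel2: GenotypePanel | None = None,
) -> TwoAncestryData:
    """Same causal variant in two ancestries with different LD block lengths.

    Ancestry 2 conventionally uses a shorter ``block_len`` (finer LD), the
    situation in which PIP-prior transfer from the better-powered ancestry 1
    pays off.  Panels share a variant catalogue; noise draws are independent.
    """
    ss = np.random.SeedSequence(seed)
    s_p1, s_p2, s_t1, s_t2 = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))
    if panel1 is None:
        panel1 = simulate_panel(seed=s_p1, **panel_params_1)
    if panel2 is None:
        panel2 = simulate_panel(seed=s_p2, **panel_params_2)
    sc1 = Scenario("H4", {causal_id: variance_explained}, {causal_id: variance_explained},
                   n1=n1, n2=n1, trait_type2="quantitative", seed=s_t1)
    sc2 = Scenario("H4", {causal_id: variance_explained}, {causal_id: variance_explained},
                   n1=n2, n2=n2, trait_type2="quantitative", seed=s_t2)
    tables1, man1 = simulate_sumstats(panel1, sc1, ld=ld1)
    tables2, man2 = simulate_sumstats(panel2, sc2, ld=ld2)
    return TwoAncestryData(panel1, panel2, tables1, tables2, man1, man2)
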