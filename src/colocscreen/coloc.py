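"""Pairwise Bayesian colocalisation from Wakefield approximate Bayes factors.

Given regional summary statistics for two traits on an identical, harmonised
variant set, the engine weighs five hypotheses about the region:

* H0 — neither trait has a causal variant,
* H1 / H2 — only trait 1 / only trait 2 has one,
* H3 — both traits have causal variants, but distinct ones,
* H4 — both traits share a single causal variant.

Per-variant evidence is the Wakefield asymptotic Bayes factor computed from
each variant's effect estimate and standard error under a normal effect-size
prior; hypothesis weights combine per-variant prior probabilities p1, p2, p12
with sums of Bayes factors, all in the log domain via log-sum-exp.

Two guards protect the single-causal-variant assumption: the lead exposure
variant (or a strong-LD proxy) must survive into the shared variant set, and
the two traits' regional sentinels must themselves be in strong LD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .ldpanel import LDMatrix, find_proxies, r2
from .sumstats import SumstatsTable

log = logging.getLogger(__name__)

#: effect-size prior standard deviation sqrt(W) by trait type: 0.15 s.d. for
#: quantitative traits, 0.2 on the log-odds scale for binary traits — the
#: conventional defaults of this model family.
DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities of association.

    p1 (p2): a given variant is causal for trait 1 (2) alone; p12: causal for
    both.  Defaults are the method family's standard 1e-4 / 1e-4 / 1e-5.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError(f"p12={self.p12} exceeds min(p1, p2)")

    def check_region_size(self, q: int) -> None:
        if q * (self.p1 + self.p2 + self.p12) >= 1:
            warnings.warn(
                f"region of {q} variants makes prior mass "
                f"Q*(p1+p2+p12) >= 1; posteriors may be distorted", stacklevel=2
            )


@dataclass
class ABFVector:
    """Per-variant log approximate Bayes factors for one trait in one region."""

    ids: np.ndarray
    log_abf: np.ndarray
    prior_sd: float

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.log_abf = np.asarray(self.log_abf, dtype=float)
        if self.ids.shape != self.log_abf.shape:
            raise ValueError("ids and log_abf must have the same length")
        if not np.all(np.isfinite(self.log_abf)):
            raise ValueError("non-finite log ABF")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ColocResult:
    pp: dict[str, float]
    per_snp_h4: dict[str, float]
    sentinel1: str | None
    sentinel2: str | None
    n_snps: int
    filter_flags: dict[str, bool | None] = field(default_factory=dict)

    @property
    def pp_h4(self) -> float:
        return self.pp["H4"]

    @property
    def pp_h3(self) -> float:
        return self.pp["H3"]


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor (natural log), vectorised.

    With V = se², W = prior_sd² and z = beta/se, the shrinkage factor is
    r = W/(V+W) and log ABF = ½·log(1−r) + z²·r/2.  A point-mass prior
    (prior_sd = 0) gives log ABF = 0 for any record.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be >= 0")
    V = se ** 2
    W = prior_sd ** 2
    shrink = W / (V + W)
    z = beta / se
    out = 0.5 * np.log1p(-shrink) + 0.5 * z ** 2 * shrink
    return out if out.ndim else float(out)


def abf_vector(table: SumstatsTable, prior_sd: float | None = None) -> ABFVector:
    """Per-variant ABFs for a whole table; prior sd defaults by trait type."""
    if prior_sd is None:
        prior_sd = DEFAULT_PRIOR_SD[table.trait_type]
    la = log_abf(table.df["BETA"].to_numpy(), table.df["SE"].to_numpy(), prior_sd)
    return ABFVector(table.variant_ids, la, prior_sd)


def _log_hypothesis_weights(la1: np.ndarray, la2: np.ndarray, priors: ColocPriors):
    """Unnormalised log weights (L0..L4); L3 guarded against cancellation."""
    lS1 = logsumexp(la1)
    lS2 = logsumexp(la2)
    lS12 = logsumexp(la1 + la2)
    lL0 = 0.0
    lL1 = np.log(priors.p1) + lS1
    lL2 = np.log(priors.p2) + lS2
    lL4 = np.log(priors.p12) + lS12
    # S1*S2 - S12 = sum over ordered pairs j != k; compute the difference of
    # exponentials in the log domain and clamp negative cancellation to zero
    a, b = lS1 + lS2, lS12
    if b >= a:
        if b > a + 1e-12:
            warnings.warn("negative H3 mass from cancellation; clamped to 0", stacklevel=2)
        lL3 = -np.inf
    else:
        lL3 = np.log(priors.p1) + np.log(priors.p2) + a + np.log1p(-np.exp(b - a))
    return np.array([lL0, lL1, lL2, lL3, lL4]), lS12


def coloc(
    abf1: ABFVector,
    abf2: ABFVector,
    priors: ColocPriors = ColocPriors(),
    sentinel1: str | None = None,
    sentinel2: str | None = None,
) -> ColocResult:
    """Five-hypothesis colocalisation of two traits on an identical variant set.

    ``abf1``/``abf2`` must be harmonised to the same ordered variants.  The
    result carries PP(H0..H4), the per-variant posterior of being the shared
    causal variant given H4, and (if supplied) each trait's sentinel.
    """
    if len(abf1) != len(abf2) or not np.array_equal(abf1.ids, abf2.ids):
        raise ValueError("ABF vectors must share an identical ordered variant set")
    if len(abf1) < 2:
        raise ValueError("colocalisation requires at least 2 shared variants")
    priors.check_region_size(len(abf1))
    la1, la2 = abf1.log_abf, abf2.log_abf
    logw, lS12 = _log_hypothesis_weights(la1, la2, priors)
    pp = np.exp(logw - logsumexp(logw))
    per_snp = np.exp(la1 + la2 - lS12)
    return ColocResult(
        pp=dict(zip(HYPOTHESES, pp.tolist())),
        per_snp_h4=dict(zip(abf1.ids.tolist(), per_snp.tolist())),
        sentinel1=sentinel1,
        sentinel2=sentinel2,
        n_snps=len(abf1),
    )


def coloc_tables(
    t1: SumstatsTable,
    t2: SumstatsTable,
    priors: ColocPriors = ColocPriors(),
    prior_sd1: float | None = None,
    prior_sd2: float | None = None,
) -> ColocResult:
    """Colocalise two harmonised tables, recording each trait's sentinel."""
    res = coloc(
        abf_vector(t1, prior_sd1),
        abf_vector(t2, prior_sd2),
        priors,
        sentinel1=t1.sentinel(),
        sentinel2=t2.sentinel(),
    )
    return res


#: the robustness grid of prior combinations explored around the defaults
DEFAULT_PRIOR_GRID: list[tuple[float, float, float]] = [
    (p1, p2, p12)
    for p1 in (1e-4, 1e-5, 1e-6)
    for p2 in (1e-4, 1e-5, 1e-6)
    for p12 in (1e-5, 5e-6, 1e-6)
]


@dataclass
class PriorSensitivityResult:
    rows: list[tuple[ColocPriors, ColocResult]]
    n_candidate: int
    n_retained: int
    robust: bool

    def pp_h4(self) -> list[float]:
        return [res.pp["H4"] for _, res in self.rows]


def prior_sensitivity(
    abf1: ABFVector,
    abf2: ABFVector,
    grid: list[tuple[float, float, float]] | None = None,
    pp_min: float = 0.8,
) -> PriorSensitivityResult:
    """Re-run colocalisation across a grid of prior combinations.

    Grid points violating p12 ≤ min(p1, p2) are skipped (with a log note), not
    clamped.  ``robust`` is true when PP(H4) exceeds ``pp_min`` at every
    retained point.
    """
    if grid is None:
        grid = DEFAULT_PRIOR_GRID
    rows: list[tuple[ColocPriors, ColocResult]] = []
    n_skipped = 0
    for p1, p2, p12 in grid:
        try:
            priors = ColocPriors(p1, p2, p12)
        except ValueError:
            n_skipped += 1
            continue
        rows.append((priors, coloc(abf1, abf2, priors)))
    if n_skipped:
        log.info("prior_sensitivity: skipped %d grid points with p12 > min(p1,p2)",
                 n_skipped)
    if not rows:
        raise ValueError("no valid prior combinations in grid")
    robust = all(res.pp["H4"] > pp_min for _, res in rows)
    return PriorSensitivityResult(rows, len(grid), len(rows), robust)


def instrument_represented(
    lead_id: str,
    shared_ids,
    ld: LDMatrix,
    r2_min: float = 0.8,
) -> bool:
    """Is the lead variant (or a proxy at r² > ``r2_min``) in the shared set?

    A lead absent from the LD panel returns False with a warning — the
    conservative verdict, since representation cannot be established.
    """
    shared = set(shared_ids)
    if lead_id in shared:
        return True
    if lead_id not in ld:
        warnings.warn(f"lead variant {lead_id!r} absent from LD panel; "
                      "treating instrument as unrepresented", stacklevel=2)
        return False
    return any(vid in shared for vid, _ in find_proxies(ld, lead_id, r2_min))


def sentinel_concordance(result: ColocResult, ld: LDMatrix, r2_min: float = 0.8) -> bool:
    """Are the two traits' regional sentinels in strong LD (r² > ``r2_min``)?

    This is the single-causal-variant guard: a high PP(H4) with discordant
    sentinels indicates the one-shared-variant assumption is violated.
    """
    s1, s2 = result.sentinel1, result.sentinel2
    if s1 is None or s2 is None:
        raise ValueError("result carries no sentinels")
    if s1 not in ld or s2 not in ld:
        warnings.warn("sentinel absent from LD panel; concordance fails", stacklevel=2)
        return False
    if s1 == s2:
        return True
    return r2(ld, s1, s2) > r2_min
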