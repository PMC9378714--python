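"""Multi-trait colocalisation with greedy divisive cluster discovery.

The hypothesis space is deliberately simplified relative to a full partition
model: a region either carries no signal, a signal for exactly one trait, or a
single variant shared by *all* traits under consideration.  Clusters of traits
that share a signal are found by greedy divisive search — start from the full
trait set and peel off the trait whose removal most improves the shared
posterior, recursing on the removed traits.  Full configuration enumeration is
available (:func:`enumerate_shared_pp`) as a cross-check for small problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .coloc import ABFVector

log = logging.getLogger(__name__)

DEFAULT_PRIOR_SINGLE = 1e-4
DEFAULT_PRIOR_SHARED = 1e-5


@dataclass
class SharedSignal:
    pp_shared: float
    regional_prob: float
    per_snp: dict[str, float]


@dataclass
class ClusterResult:
    """A set of traits judged to share one causal variant."""

    trait_labels: list[str]
    pp_shared: float
    regional_prob: float
    candidate_id: str
    prop_explained: float


@dataclass
class ClusteringResult:
    clusters: list[ClusterResult]
    unclustered: list[str]


def _validate(abfs: list[ABFVector]) -> np.ndarray:
    if len(abfs) < 2:
        raise ValueError("multi-trait colocalisation needs at least 2 traits")
    ids = abfs[0].ids
    for a in abfs[1:]:
        if not np.array_equal(a.ids, ids):
            raise ValueError("all ABF vectors must share an identical ordered variant set")
    return ids


def shared_pp(
    abfs: list[ABFVector],
    prior_shared: float = DEFAULT_PRIOR_SHARED,
    prior_single: float = DEFAULT_PRIOR_SINGLE,
) -> SharedSignal:
    """Posterior that all traits share one causal variant.

    Hypothesis weights: L_null = 1; per trait t, L_t = prior_single·Σ_j b_tj
    (that trait alone associated); L_share = prior_shared·Σ_j Π_t b_tj.  The
    shared posterior is L_share over the sum of those weights.

    ``regional_prob`` — the probability that *every* trait has some signal in
    the region — additionally admits an independent-signals configuration
    (each trait at its own variant, weight Π_t prior_single·Σ_j b_tj) and
    reports the mass of {shared, independent} within that extended weight set.
    """
    ids = _validate(abfs)
    la = np.vstack([a.log_abf for a in abfs])  # traits × variants
    l_sum_t = logsumexp(la, axis=1)  # log Σ_j b_tj per trait
    l_share_sum = logsumexp(la.sum(axis=0))  # log Σ_j Π_t b_tj
    lL_null = 0.0
    lL_t = np.log(prior_single) + l_sum_t
    lL_share = np.log(prior_shared) + l_share_sum
    denom = logsumexp(np.concatenate(([lL_null], lL_t, [lL_share])))
    pp = float(np.exp(lL_share - denom))

    lL_indep = float(np.sum(np.log(prior_single) + l_sum_t))
    denom_ext = logsumexp(np.concatenate(([lL_null], lL_t, [lL_indep, lL_share])))
    regional = float(np.exp(logsumexp([lL_indep, lL_share]) - denom_ext))

    lps = la.sum(axis=0)
    per_snp = np.exp(lps - logsumexp(lps))
    return SharedSignal(pp, regional, dict(zip(ids.tolist(), per_snp.tolist())))


def coherence_pp(
    abfs: list[ABFVector],
    prior_shared: float = DEFAULT_PRIOR_SHARED,
    prior_single: float = DEFAULT_PRIOR_SINGLE,
) -> float:
    """Shared posterior penalised by leave-one-out alternatives (search criterion).

    The plain shared posterior competes only against the null and single-trait
    hypotheses, so with several strongly associated traits the all-share
    weight can dominate even when one member does not fit the shared variant.
    For cluster *decisions* the weight set is therefore extended with, for
    each trait t, an "all but t share, t associated elsewhere" configuration
    with weight ``prior_shared·Σ_j Π_{s≠t} b_sj · prior_single·Σ_j b_tj``.
    A set is coherent only when the full-share weight also beats every
    leave-one-out alternative.
    """
    ids = _validate(abfs)
    la = np.vstack([a.log_abf for a in abfs])
    l_sum_t = logsumexp(la, axis=1)
    lL_null = 0.0
    lL_t = np.log(prior_single) + l_sum_t
    lL_share = np.log(prior_shared) + logsumexp(la.sum(axis=0))
    total = la.sum(axis=0)
    lL_loo = []
    if len(abfs) > 2:
        for t in range(len(abfs)):
            l_share_wo_t = logsumexp(total - la[t])
            lL_loo.append(np.log(prior_shared) + l_share_wo_t
                          + np.log(prior_single) + l_sum_t[t])
    denom = logsumexp(np.concatenate(([lL_null], lL_t, lL_loo, [lL_share])))
    return float(np.exp(lL_share - denom))


def candidate_attribution(per_snp: dict[str, float]) -> tuple[str, float]:
    """Variant carrying the largest share of the per-SNP posterior.

    Ties are broken by order in the mapping, which is position order for all
    posteriors produced by this package.
    """
    total = sum(per_snp.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError("per-SNP posterior must sum to 1")
    candidate = max(per_snp, key=per_snp.get)
    return candidate, float(per_snp[candidate])


def divisive_cluster(
    abfs: dict[str, ABFVector],
    tau: float = 0.8,
    prior_shared: float = DEFAULT_PRIOR_SHARED,
    prior_single: float = DEFAULT_PRIOR_SINGLE,
) -> ClusteringResult:
    """Greedy divisive discovery of trait clusters sharing a causal variant.

    Starting from all traits: while the coherent shared posterior
    (:func:`coherence_pp`, which also penalises leave-one-out alternatives)
    is below ``tau`` and more than two traits remain, drop the trait whose
    exclusion maximises the remainder's coherent posterior.  A surviving set
    passing ``tau`` is emitted as a cluster (reporting the plain shared
    posterior of its members); removed traits are re-clustered among
    themselves; anything left over is reported unclustered.  Deterministic
    given input order (ties in the drop choice resolve to the earliest trait).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    labels = list(abfs)
    clusters: list[ClusterResult] = []
    unclustered: list[str] = []

    def _coh(subset: list[str]) -> float:
        return coherence_pp([abfs[t] for t in subset], prior_shared, prior_single)

    def _recurse(subset: list[str]) -> None:
        if len(subset) < 2:
            unclustered.extend(subset)
            return
        current = list(subset)
        removed: list[str] = []
        coh = _coh(current)
        while coh < tau and len(current) > 2:
            best_t, best_coh = None, -1.0
            for t in current:
                trial = [x for x in current if x != t]
                c = _coh(trial)
                if c > best_coh:
                    best_t, best_coh = t, c
            current.remove(best_t)
            removed.append(best_t)
            coh = best_coh
        if coh >= tau:
            sig = shared_pp([abfs[t] for t in current], prior_shared, prior_single)
            cand, prop = candidate_attribution(sig.per_snp)
            clusters.append(
                ClusterResult(current, sig.pp_shared, sig.regional_prob, cand, prop)
            )
        else:
            unclustered.extend(current)
        _recurse(removed)

    _recurse(labels)
    return ClusteringResult(clusters, unclustered)


def enumerate_shared_pp(
    abfs: list[ABFVector],
    prior_shared: float = DEFAULT_PRIOR_SHARED,
    prior_single: float = DEFAULT_PRIOR_SINGLE,
) -> float:
    """Shared posterior by explicit configuration enumeration (test oracle).

    Enumerates every configuration in the simplified hypothesis space — the
    null, each single-trait/single-variant assignment, and each single shared
    variant — in plain (non-log) arithmetic.  Intended for ≤3 traits and a few
    hundred variants.
    """
    ids = _validate(abfs)
    if len(abfs) > 3 or len(ids) > 200:
        raise ValueError("enumeration oracle limited to <=3 traits, <=200 variants")
    # explicit per-configuration log weights, exponentiated on a common scale
    import math

    logw: list[float] = [0.0]  # null configuration
    kinds: list[str] = ["null"]
    for a in abfs:  # trait t alone, causal at variant j
        for j in range(len(ids)):
            logw.append(math.log(prior_single) + float(a.log_abf[j]))
            kinds.append("single")
    for j in range(len(ids)):  # all traits share variant j
        lp = sum(float(a.log_abf[j]) for a in abfs)
        logw.append(math.log(prior_shared) + lp)
        kinds.append("share")
    shift = max(logw)
    w = [math.exp(x - shift) for x in logw]
    shared_mass = sum(wi for wi, k in zip(w, kinds) if k == "share")
    return shared_mass / sum(w)
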