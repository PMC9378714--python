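"""Single-signal Bayesian fine-mapping with cross-ancestry prior transfer.

Under the assumption of exactly one causal variant in the region, the
posterior inclusion probability (PIP) of variant j is simply its prior-
weighted Bayes factor normalised over the region.  The stepwise multi-ancestry
procedure fine-maps the better-powered ancestry first with equal priors, then
re-uses those PIPs (floored so no variant is irreversibly zeroed) as priors
for the second ancestry — which pays off when the second ancestry has shorter
LD blocks and can discriminate variants the first ancestry cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .coloc import ABFVector


@dataclass
class PIPVector:
    """Per-variant posterior inclusion probabilities under one causal signal."""

    ids: np.ndarray
    pip: np.ndarray
    prior: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.pip = np.asarray(self.pip, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        for name, v in (("pip", self.pip), ("prior", self.prior)):
            if v.shape != self.ids.shape:
                raise ValueError(f"{name} length mismatch")
            if np.any(v < 0):
                raise ValueError(f"negative {name} entries")
            if not np.isclose(v.sum(), 1.0, atol=1e-10):
                raise ValueError(f"{name} must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.ids.tolist(), self.pip.tolist()))

    def top(self) -> str:
        return str(self.ids[int(np.argmax(self.pip))])


def single_signal_pips(abf: ABFVector, prior=None) -> PIPVector:
    """PIPs conditional on exactly one causal variant.

    ``pip_j = prior_j·BF_j / Σ_k prior_k·BF_k``, computed in the log domain.
    ``prior`` defaults to uniform and is normalised internally.
    """
    q = len(abf)
    if prior is None:
        prior = np.full(q, 1.0 / q)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != (q,):
        raise ValueError("prior length mismatch")
    if np.any(prior < 0) or prior.sum() <= 0:
        raise ValueError("prior must be non-negative with positive mass")
    prior = prior / prior.sum()
    with np.errstate(divide="ignore"):
        lw = np.log(prior) + abf.log_abf  # log(0) -> -inf: zero-prior variants drop out
    if not np.isfinite(lw).any():
        raise ValueError("all prior-weighted Bayes factors are zero")
    pip = np.exp(lw - logsumexp(lw))
    return PIPVector(abf.ids, pip, prior)


def transfer_priors(pips: PIPVector, floor: float | None = None) -> np.ndarray:
    """Turn stage-1 PIPs into stage-2 priors: ``prior_j ∝ pip_j + floor``.

    The floor (default 1/(10·Q)) keeps every variant's posterior support
    positive so stage 2 can rescue variants stage 1 missed.
    """
    q = len(pips.ids)
    if floor is None:
        floor = 1.0 / (10.0 * q)
    if floor < 0:
        raise ValueError("floor must be >= 0")
    prior = pips.pip + floor
    return prior / prior.sum()


def stepwise_multiancestry(
    abf_anc1: ABFVector,
    abf_anc2: ABFVector,
    floor: float | None = None,
) -> tuple[PIPVector, PIPVector]:
    """Two-stage fine-mapping: equal priors in ancestry 1, PIPs as priors in 2.

    The two ancestries may cover different variant sets; transfer acts on the
    intersection, and ancestry-2-only variants receive the floor prior
    (default 1/(10·Q₂)).
    """
    ids2 = abf_anc2.ids
    pips1 = single_signal_pips(abf_anc1)
    lookup = pips1.as_dict()
    shared = [v for v in ids2.tolist() if v in lookup]
    if not shared:
        raise ValueError("no shared variants between ancestries")
    q2 = len(ids2)
    floor2 = 1.0 / (10.0 * q2) if floor is None else floor
    prior2 = np.array([lookup.get(v, 0.0) + floor2 for v in ids2.tolist()])
    prior2 = prior2 / prior2.sum()
    pips2 = single_signal_pips(abf_anc2, prior2)
    return pips1, pips2
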