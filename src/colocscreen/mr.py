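"""Single-instrument Mendelian randomisation (Wald ratio) and OR transforms.

With a single cis instrument, the causal effect of a 1 s.d. increase in the
exposure on a binary outcome is estimated as the Wald ratio
``beta_outcome / beta_exposure`` (log-odds scale), with first-order standard
error ``|se_outcome / beta_exposure|`` — exposure uncertainty is ignored, an
approximation that is accurate for strong instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: instruments with |beta_exp/se_exp| below this are flagged as weak
WEAK_INSTRUMENT_Z = 4.0


@dataclass(frozen=True)
class WaldEstimate:
    """Wald-ratio estimate per 1 s.d. of exposure, with OR-scale 95% CI."""

    ratio: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    weak_instrument: bool = False


@dataclass(frozen=True)
class PerAlleleOR:
    or_: float
    ci_low: float
    ci_high: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Display rounding (2 decimals by default)."""
        return (round(self.or_, ndigits), round(self.ci_low, ndigits),
                round(self.ci_high, ndigits))

    def display(self) -> str:
        o, lo, hi = self.rounded()
        return f"{o:.2f} (95% CI {lo:.2f}–{hi:.2f})"


def wald_ratio(
    beta_exp: float,
    se_exp: float,
    beta_out: float,
    se_out: float,
    weak_z: float = WEAK_INSTRUMENT_Z,
) -> WaldEstimate:
    """Single-instrument Wald ratio with first-order (delta-method) SE.

    ``ratio = beta_out / beta_exp`` and ``se = |se_out / beta_exp|``; the OR
    and its 95% CI come from exponentiation, the p-value from a two-sided
    normal test of ratio/se.  A weak instrument (|beta_exp/se_exp| < weak_z)
    yields a flag, never an error — the screen must report, not silently drop.
    """
    if beta_exp == 0:
        raise ValueError("exposure effect must be non-zero")
    if se_exp <= 0 or se_out <= 0:
        raise ValueError("standard errors must be positive")
    ratio = beta_out / beta_exp
    se = abs(se_out / beta_exp)
    p = 2.0 * stats.norm.sf(abs(ratio) / se)
    weak = abs(beta_exp / se_exp) < weak_z
    return WaldEstimate(
        ratio=ratio,
        se=se,
        or_=math.exp(ratio),
        ci_low=math.exp(ratio - Z95 * se),
        ci_high=math.exp(ratio + Z95 * se),
        p=float(p),
        weak_instrument=weak,
    )


def per_allele_or(beta: float, se: float) -> PerAlleleOR:
    """Per-allele odds ratio with 95% Wald CI from a log-odds effect."""
    if se <= 0:
        raise ValueError("se must be positive")
    return PerAlleleOR(
        or_=math.exp(beta),
        ci_low=math.exp(beta - 1.96 * se),
        ci_high=math.exp(beta + 1.96 * se),
    )
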