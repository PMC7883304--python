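"""Evidence machinery for comparing a model against its null model.

Two prior-free quantities are computed from information criteria of a fitted
model (index 1) and its associated null model (index 0):

* the Akaike evidence ratio ``ER_0 = w_0 / w_1`` where the Akaike weights are
  ``w_i = exp(-0.5 (AIC_i - AIC_min)) / sum_j exp(-0.5 (AIC_j - AIC_min))``
  — for two models this collapses exactly to ``exp(0.5 (AIC_1 - AIC_0))``;
* the BIC-approximated Bayes factor ``BF_01 = exp(0.5 (BIC_1 - BIC_0))``.

Values above 1 favour the null; following Jeffreys-style guidelines, values
strictly above 3 are labelled evidence, above 10 strong, above 100 decisive.
All quantities are carried in natural-log space so astronomically large
factors (the kind a strongly preferred model produces) stay finite and exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ComparisonResult",
    "akaike_weights",
    "evidence_ratio",
    "bic_bayes_factor",
    "interpret",
    "compare_models",
    "format_factor",
]

_LOG_MAX = 700.0  # exp overflow guard for float64


def _safe_exp(x: float) -> float:
    if x > _LOG_MAX:
        return math.inf
    if x < -_LOG_MAX:
        return 0.0
    return math.exp(x)


def akaike_weights(aic_0: float, aic_1: float) -> tuple[float, float]:
    """Akaike weights (w_0, w_1) of the null and alternative model.

    Computed in log space: each weight is a two-term softmax of -AIC/2, so
    the pair always sums to 1 even for extreme AIC differences.
    """
    if not (math.isfinite(aic_0) and math.isfinite(aic_1)):
        raise ValueError("AIC values must be finite")
    m = min(aic_0, aic_1)
    e0 = math.exp(-0.5 * (aic_0 - m))
    e1 = math.exp(-0.5 * (aic_1 - m))
    s = e0 + e1
    return e0 / s, e1 / s


def evidence_ratio(w_0: float, w_1: float) -> float:
    """Evidence ratio for the null, ``ER_0 = w_0 / w_1``.

    Returns ``inf`` when the alternative's weight underflows to zero.
    """
    if w_0 < 0 or w_1 < 0:
        raise ValueError("weights must be non-negative")
    if w_1 == 0.0:
        return math.inf
    return w_0 / w_1


def bic_bayes_factor(bic_0: float, bic_1: float) -> float:
    """BIC-approximated Bayes factor for the null, ``exp(0.5 (BIC_1 - BIC_0))``.

    Use :func:`compare_models` when the log-scale value is also needed.
    """
    if not (math.isfinite(bic_0) and math.isfinite(bic_1)):
        raise ValueError("BIC values must be finite")
    return _safe_exp(0.5 * (bic_1 - bic_0))


def interpret(er_or_bf: float) -> str:
    """Jeffreys-style category of an evidence ratio or Bayes factor.

    ``<= 3`` inconclusive (the threshold itself is *not* evidence),
    ``> 3`` evidence, ``> 10`` strong, ``> 100`` decisive.
    """
    if not er_or_bf > 0:
        raise ValueError("evidence value must be positive")
    if er_or_bf > 100:
        return "decisive"
    if er_or_bf > 10:
        return "strong"
    if er_or_bf > 3:
        return "evidence"
    return "inconclusive"


@dataclass(frozen=True)
class ComparisonResult:
    """Null-vs-alternative comparison from AIC/BIC pairs.

    ``log_er_0`` and ``log_bf_01`` are exact natural logs; ``er_0`` and
    ``bf_01`` may be ``inf``/0.0 when the log magnitude exceeds float range.
    ``category`` interprets ``bf_01`` on the Jeffreys-style bands.
    """

    aic_0: float
    aic_1: float
    bic_0: float
    bic_1: float
    w_0: float
    w_1: float
    er_0: float
    log_er_0: float
    bf_01: float
    log_bf_01: float
    category: str

    @property
    def er_1(self) -> float:
        return math.inf if self.er_0 == 0.0 else 1.0 / self.er_0 if math.isfinite(self.er_0) else 0.0

    @property
    def bf_10(self) -> float:
        return _safe_exp(-self.log_bf_01)


def compare_models(aic_0: float, aic_1: float, bic_0: float, bic_1: float) -> ComparisonResult:
    """Full evidence summary for a (null, alternative) model pair."""
    w_0, w_1 = akaike_weights(aic_0, aic_1)
    log_er_0 = 0.5 * (aic_1 - aic_0)
    log_bf_01 = 0.5 * (bic_1 - bic_0)
    bf_01 = _safe_exp(log_bf_01)
    return ComparisonResult(
        aic_0=aic_0, aic_1=aic_1, bic_0=bic_0, bic_1=bic_1,
        w_0=w_0, w_1=w_1,
        er_0=_safe_exp(log_er_0), log_er_0=log_er_0,
        bf_01=bf_01, log_bf_01=log_bf_01,
        category=interpret(bf_01) if bf_01 > 0 else "inconclusive",
    )


def format_factor(log_value: float, digits: int = 2) -> str:
    """Scientific-notation string of exp(log_value), e.g. ``'3.02e+145'``.

    Works far beyond float range by splitting the base-10 log into mantissa
    and exponent.
    """
    log10 = log_value / math.log(10.0)
    expo = math.floor(log10)
    mant = 10.0 ** (log10 - expo)
    if round(mant, digits) >= 10.0:  # e.g. 9.999 rounding up
        mant /= 10.0
        expo += 1
    if -3 <= expo <= 3:
        return f"{mant * 10.0 ** expo:.{digits}f}"
    return f"{mant:.{digits}f}e{expo:+d}"
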