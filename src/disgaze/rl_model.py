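"""Rescorla-Wagner / softmax reinforcement-learning model for the two-armed
reversal bandit control task.

The model maintains associative values :math:`v_A, v_B` (both starting at 0,
so the first choice is at chance) and updates the *chosen* arm's value by a
delta rule

.. math:: v_{i} = v_{i-1} + \\eta \\,(R_{i-1} - v_{i-1})

with either a single learning rate ``eta`` or separate rates for win and
non-win outcomes (``eta_win`` applied when the previous reward was positive,
``eta_lose`` otherwise).  Choices follow a softmax with inverse temperature
``beta``:

.. math:: P(A)_i = \\frac{e^{\\beta v_{A,i}}}{e^{\\beta v_{A,i}} + e^{\\beta v_{B,i}}}

Fitting is bounded maximum likelihood with multiple random starts; the
learning rates are optimised through a logit transform and ``beta`` through a
log transform so the optimiser works on an unconstrained scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "AgentParams",
    "ChoiceData",
    "FitResult",
    "FittingError",
    "rw_update",
    "rw_update_dual",
    "softmax_prob",
    "negative_log_likelihood",
    "fit_model",
    "win_proportion",
]

#: inverse-temperature upper bound used during fitting; on an 88-trial task
#: larger values are not identifiable from binary choices.
BETA_MAX = 20.0
_ETA_EPS = 1e-9  # clip for the logit transform


class FittingError(RuntimeError):
    """Raised when no optimisation start converges."""


@dataclass(frozen=True)
class AgentParams:
    """Parameters of a single- or dual-learning-rate agent.

    Exactly the fields of the declared variant must be set: ``eta`` for
    ``variant="single"``; ``eta_win`` and ``eta_lose`` for ``variant="dual"``.
    ``beta`` (inverse choice temperature) is shared and must be >= 0.
    """

    variant: str
    beta: float
    eta: float | None = None
    eta_win: float | None = None
    eta_lose: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("single", "dual"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (self.beta >= 0.0):
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.variant == "single":
            if self.eta is None or self.eta_win is not None or self.eta_lose is not None:
                raise ValueError("single variant takes exactly the field 'eta'")
            _check_rate("eta", self.eta)
        else:
            if self.eta is not None or self.eta_win is None or self.eta_lose is None:
                raise ValueError("dual variant takes exactly 'eta_win' and 'eta_lose'")
            _check_rate("eta_win", self.eta_win)
            _check_rate("eta_lose", self.eta_lose)

    @property
    def k(self) -> int:
        """Number of free parameters (2 for single, 3 for dual)."""
        return 2 if self.variant == "single" else 3

    def rates(self) -> tuple[float, float]:
        """(win-rate, lose-rate) pair; identical for the single variant."""
        if self.variant == "single":
            assert self.eta is not None
            return self.eta, self.eta
        assert self.eta_win is not None and self.eta_lose is not None
        return self.eta_win, self.eta_lose


def _check_rate(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ChoiceData:
    """Observed choice/reward sequence for one agent (one task run).

    ``choices`` holds 0 for arm A and 1 for arm B; ``rewards`` is binary
    (1 = win, 0 = non-win).
    """

    choices: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.choices, dtype=np.int64)
        r = np.asarray(self.rewards, dtype=np.int64)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("choices and rewards must be 1-D arrays of equal length")
        if c.size == 0:
            raise ValueError("choice sequence is empty")
        if not np.isin(c, (0, 1)).all():
            raise ValueError("choices must be coded 0 (A) / 1 (B)")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("rewards must be binary")
        object.__setattr__(self, "choices", c)
        object.__setattr__(self, "rewards", r)

    def __len__(self) -> int:
        return int(self.choices.size)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceData":
        """Build from a choice table with ``choice`` ('A'/'B') and ``reward``
        columns, ordered by ``trial`` if present."""
        if "trial" in df.columns:
            df = df.sort_values("trial")
        choices = df["choice"].map({"A": 0, "B": 1})
        if choices.isna().any():
            raise ValueError("choice column must contain only 'A'/'B'")
        return cls(choices.to_numpy(), df["reward"].to_numpy())


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one agent's data."""

    params: AgentParams
    nll: float
    k: int
    n: int
    aic: float
    bic: float
    n_starts_converged: int
    at_bound: bool = False

    def criteria(self) -> tuple[float, float]:
        return self.aic, self.bic


# ----------------------------------------------------------------------------
# elementary updates
# ----------------------------------------------------------------------------

def rw_update(v: float, reward: float, eta: float) -> float:
    """Delta-rule update of the chosen arm's value: ``v + eta * (R - v)``."""
    _check_rate("eta", eta)
    return v + eta * (reward - v)


def rw_update_dual(v: float, reward: float, eta_win: float, eta_lose: float) -> float:
    """Dual-rate update: ``eta_win`` after a win (R > 0), ``eta_lose`` otherwise."""
    _check_rate("eta_win", eta_win)
    _check_rate("eta_lose", eta_lose)
    eta = eta_win if reward > 0 else eta_lose
    return v + eta * (reward - v)


def softmax_prob(v_a: float, v_b: float, beta: float) -> float:
    """Probability of choosing arm A under the softmax rule.

    Computed overflow-safely by subtracting the larger scaled value before
    exponentiating.  ``beta = 0`` (or equal values) gives exactly 0.5.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    za = beta * v_a
    zb = beta * v_b
    m = za if za > zb else zb
    ea = math.exp(za - m)
    eb = math.exp(zb - m)
    return ea / (ea + eb)


# ----------------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------------

def negative_log_likelihood(params: AgentParams, data: ChoiceData) -> float:
    """Sequential negative log-likelihood (nats) of a choice sequence.

    Values start at 0 for both arms so the first trial's choice probability
    is exactly 0.5; only the chosen arm's value is updated after each trial.
    """
    data = _coerce_data(data)
    eta_win, eta_lose = params.rates()
    return _nll_fast(data.choices.tolist(), data.rewards.tolist(),
                     eta_win, eta_lose, params.beta)


def _nll_fast(choices: list[int], rewards: list[int], eta_win: float,
              eta_lose: float, beta: float) -> float:
    # hot path for the optimiser: plain-float recursion, no array overhead
    va = 0.0
    vb = 0.0
    total = 0.0
    log1p = math.log1p
    exp = math.exp
    for c, r in zip(choices, rewards):
        if c == 0:
            d = beta * (va - vb)
        else:
            d = beta * (vb - va)
        if d < -700.0:
            total += -d
        elif d < 700.0:
            total += log1p(exp(-d))
        eta = eta_win if r > 0 else eta_lose
        if c == 0:
            va += eta * (r - va)
        else:
            vb += eta * (r - vb)
    return total


# ----------------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------------

def _logit(p: float) -> float:
    p = min(max(p, _ETA_EPS), 1.0 - _ETA_EPS)
    return math.log(p / (1.0 - p))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


_X_ETA_BOUND = 16.0  # |logit eta| bound; eta within ~1e-7 of {0, 1}
_X_BETA_LO = math.log(1e-3)
_X_BETA_HI = math.log(BETA_MAX)


def fit_model(
    data: ChoiceData | pd.DataFrame | Iterable,
    variant: str = "single",
    n_starts: int = 20,
    seed: int | np.random.Generator | None = 0,
) -> FitResult:
    """Fit the single- or dual-rate model by multi-start bounded MLE.

    Starts sample the learning rate(s) uniformly on [0, 1] (through a logit
    transform) and ``beta`` log-uniformly on [0.1, 20]; a deterministic
    mid-range start is always included, and the dual fit additionally starts
    from the best single-rate solution (which makes the dual optimum never
    worse than the single one, as the models are nested).

    Parameters
    ----------
    data : ChoiceData, DataFrame or iterable of (choice, reward)
    variant : "single" or "dual"
    n_starts : number of random optimisation starts
    seed : RNG seed (or Generator) for start sampling

    Returns
    -------
    FitResult with NLL, AIC = 2k + 2*nll and BIC = k*ln(n) + 2*nll.
    """
    data = _coerce_data(data)
    if variant not in ("single", "dual"):
        raise ValueError(f"unknown variant {variant!r}")
    if len(data) < 10:
        raise ValueError("need at least 10 trials to fit")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    choices = data.choices.tolist()
    rewards = data.rewards.tolist()

    if variant == "single":
        def obj(x):
            eta = _expit(x[0])
            beta = math.exp(x[1])
            return _nll_fast(choices, rewards, eta, eta, beta)
        bounds = [(-_X_ETA_BOUND, _X_ETA_BOUND), (_X_BETA_LO, _X_BETA_HI)]
        starts = [[0.0, 0.0]]  # eta = 0.5, beta = 1
        for _ in range(n_starts - 1):
            starts.append([
                _logit(rng.uniform(0.0, 1.0)),
                rng.uniform(math.log(0.1), math.log(BETA_MAX)),
            ])
    else:
        def obj(x):
            return _nll_fast(choices, rewards, _expit(x[0]), _expit(x[1]),
                             math.exp(x[2]))
        bounds = [(-_X_ETA_BOUND, _X_ETA_BOUND)] * 2 + [(_X_BETA_LO, _X_BETA_HI)]
        single = fit_model(data, "single", n_starts=n_starts, seed=rng)
        assert single.params.eta is not None
        x_eta = _logit(single.params.eta)
        starts = [[x_eta, x_eta, math.log(max(single.params.beta, 1e-3))],
                  [0.0, 0.0, 0.0]]
        for _ in range(n_starts - 1):
            starts.append([
                _logit(rng.uniform(0.0, 1.0)),
                _logit(rng.uniform(0.0, 1.0)),
                rng.uniform(math.log(0.1), math.log(BETA_MAX)),
            ])

    best = None
    n_conv = 0
    messages = []
    for x0 in starts:
        res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-10, "gtol": 1e-8})
        if res.success or res.fun < np.inf:
            n_conv += int(bool(res.success))
            if best is None or res.fun < best.fun:
                best = res
        else:  # pragma: no cover - L-BFGS-B always returns a point
            messages.append(str(res.message))
    if best is None or n_conv == 0:
        raise FittingError(
            f"no start converged for variant={variant!r}: {messages[:3]}")

    x = best.x
    beta = math.exp(x[-1])
    at_bound = abs(x[-1] - _X_BETA_HI) < 1e-6
    if variant == "single":
        params = AgentParams("single", beta=beta, eta=_expit(x[0]))
    else:
        params = AgentParams("dual", beta=beta, eta_win=_expit(x[0]),
                             eta_lose=_expit(x[1]))
    nll = float(best.fun)
    n = len(data)
    k = params.k
    return FitResult(params=params, nll=nll, k=k, n=n,
                     aic=2.0 * k + 2.0 * nll, bic=k * math.log(n) + 2.0 * nll,
                     n_starts_converged=n_conv, at_bound=at_bound)


def win_proportion(data: ChoiceData | pd.DataFrame | Iterable) -> float:
    """Proportion of won trials (mean of the binary rewards)."""
    data = _coerce_data(data)
    return float(np.mean(data.rewards))


def _coerce_data(data) -> ChoiceData:
    if isinstance(data, ChoiceData):
        return data
    if isinstance(data, pd.DataFrame):
        return ChoiceData.from_frame(data)
    pairs = list(data)
    choices = [c for c, _ in pairs]
    rewards = [r for _, r in pairs]
    if any(isinstance(c, str) for c in choices):
        choices = [{"A": 0, "B": 1}[c] for c in choices]
    return ChoiceData(np.asarray(choices), np.asarray(rewards))
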