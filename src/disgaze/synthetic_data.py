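"""Synthetic crossover studies with known ground truth.

Generates every data stream the analysis pipeline consumes, for a
two-visit (placebo / domperidone) crossover design with five
preferential-looking phases per visit:

* **Gaze** — per-trial dwell-time proportions over the disgusting image, the
  neutral image and non-stimulus space.  Each image's dwell share is
  generated on a logit scale — a linear predictor with a participant random
  intercept, independent per-trial Gaussian noise, a stimulus effect (a
  negative value depresses disgust dwell, producing avoidance) and an
  injectable drug x phase x stimulus interaction confined to the domperidone
  visit's post-incentive phase — and mapped through a half-scaled logistic
  ``p = 0.5 * sigmoid(lin)``, so each image's proportion lies in [0, 0.5),
  the three proportions partition 1 (non-stimulus takes the remainder), and
  the two stimulus streams stay conditionally independent given the
  participant.
  Optionally the proportions are realised as discrete fixation streams over
  the two image AOIs so the full fixation-to-dwell pipeline can run.
* **Choices** — 88-trial two-armed bandit runs under an 80/20 reversal
  schedule, played by Rescorla-Wagner / softmax agents whose true parameters
  are recorded.  The generator injects no drug effect on learning: the drug
  is peripheral by construction, which is exactly the null the evidence
  workflow should recover.
* **Self-report** — disgust ratings per stimulus category on a 0-100 visual
  analogue scale.

Identical seeds and configurations give byte-identical tables.  Each
participant draws from an independent child RNG stream spawned from
``(seed, participant)``, so any participant subset is reproducible on its
own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .gaze_metrics import AOILayout
from .rl_model import AgentParams

__all__ = [
    "ConfigError",
    "StudyDesign",
    "GazeSimConfig",
    "RLSimConfig",
    "SelfReportConfig",
    "RewardSchedule",
    "SimulatedStudy",
    "make_design",
    "make_reward_schedule",
    "simulate_agent",
    "simulate_study",
]

VISITS = ("placebo", "domperidone")
PHASES = ("baseline", "post_admin", "pre_incentive", "incentive", "post_incentive")
DEFAULT_TRIALS_PER_PHASE = (24, 24, 10, 10, 10)
#: control-task runs per visit: before drug administration and after the
#: post-incentive measurement
RL_PHASES = ("pre_admin", "post_admin")
#: self-report collection points (no rating during the incentive block)
RATING_PHASES = ("baseline", "post_admin", "pre_incentive", "post_incentive")


class ConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class StudyDesign:
    """Crossover design skeleton: who visits when, and where the disgusting
    image sits on each trial.

    ``visit_order`` maps participant id -> visit-label tuple for (session 1,
    session 2); orders are counterbalanced.  ``side_assignment`` maps
    (visit, phase) -> tuple of 'left'/'right' per trial, balanced within each
    phase up to rounding.
    """

    n_participants: int = 25
    visits: tuple[str, str] = VISITS
    phases: tuple[str, ...] = PHASES
    trials_per_phase: tuple[int, ...] = DEFAULT_TRIALS_PER_PHASE
    visit_order: Mapping[int, tuple[str, str]] = field(default_factory=dict)
    side_assignment: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.n_participants >= 2, "n_participants", "need at least 2")
        _require(set(self.visits) == set(VISITS), "visits",
                 f"must be a permutation of {VISITS}")
        _require(len(self.phases) == len(self.trials_per_phase),
                 "trials_per_phase", "must match phases in length")
        _require(all(t > 0 for t in self.trials_per_phase),
                 "trials_per_phase", "counts must be positive")
        for pid, order in self.visit_order.items():
            _require(set(order) == set(VISITS), "visit_order",
                     f"participant {pid} must get both visits in opposite order")

    def n_trials(self, phase: str) -> int:
        return self.trials_per_phase[self.phases.index(phase)]


def make_design(n_participants: int = 25, seed: int = 0,
                trials_per_phase: tuple[int, ...] = DEFAULT_TRIALS_PER_PHASE) -> StudyDesign:
    """Build a counterbalanced design with balanced, shuffled side assignment.

    Odd/even participants get opposite visit orders; within each (visit,
    phase) block half the trials (rounding down) place the disgusting image
    left, the rest right, in an order shuffled by ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    visit_order = {
        pid: VISITS if pid % 2 == 0 else VISITS[::-1]
        for pid in range(n_participants)
    }
    side_assignment = {}
    for visit in VISITS:
        for phase, n in zip(PHASES, trials_per_phase):
            sides = np.array(["left"] * (n // 2) + ["right"] * (n - n // 2))
            rng.shuffle(sides)
            side_assignment[(visit, phase)] = tuple(sides)
    return StudyDesign(n_participants=n_participants,
                       trials_per_phase=trials_per_phase,
                       visit_order=visit_order,
                       side_assignment=side_assignment)


@dataclass(frozen=True)
class GazeSimConfig:
    """Ground-truth parameters of the dwell-proportion generator.

    All effects are additive on the per-image logit scale (each image's
    dwell share is ``0.5 * sigmoid`` of its linear predictor).  Defaults
    emulate a strong baseline avoidance effect (disgust dwell well below
    neutral dwell) with no drug effect; set ``drug_phase_interaction``
    positive to reduce post-incentive avoidance on the domperidone visit.
    """

    mean_dwell_logit_neutral: float = 1.5
    stimulus_effect: float = -1.5
    drug_phase_interaction: float = 0.0
    participant_sd: float = 0.5
    trial_noise_sd: float = 0.8
    missingness_rate: float = 0.05
    trial_duration_ms: int = 15_000
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.participant_sd >= 0, "participant_sd", "must be >= 0")
        _require(self.trial_noise_sd >= 0, "trial_noise_sd", "must be >= 0")
        _require(0.0 <= self.missingness_rate <= 1.0, "missingness_rate",
                 "must be a probability in [0, 1]")
        _require(self.trial_duration_ms > 0, "trial_duration_ms", "must be positive")


@dataclass(frozen=True)
class RLSimConfig:
    """Bandit-task generator settings.

    ``true_params`` optionally fixes each participant-phase's agent; keys are
    (participant, visit, rl_phase).  When absent, each participant draws one
    parameter set (eta ~ U[0.1, 0.7], beta ~ U[1, 8]) reused across visits
    and phases — i.e. no drug or phase effect on learning.
    """

    n_trials: int = 88
    p_high: float = 0.8
    p_low: float = 0.2
    n_reversals: int = 4
    true_params: Mapping[tuple, AgentParams] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_trials >= 1, "n_trials", "must be >= 1")
        _require(0.0 <= self.p_high <= 1.0, "p_high", "must be a probability")
        _require(0.0 <= self.p_low <= 1.0, "p_low", "must be a probability")
        _require(0 <= self.n_reversals < self.n_trials, "n_reversals",
                 "must satisfy 0 <= n_reversals < n_trials")


@dataclass(frozen=True)
class SelfReportConfig:
    """Self-report rating generator (0-100 visual analogue scale)."""

    mean_disgust: float = 65.0
    mean_neutral: float = 10.0
    rating_sd: float = 12.0
    participant_sd: float = 8.0
    n_items: int = 12
    drug_phase_interaction: float = 0.0

    def __post_init__(self) -> None:
        _require(self.rating_sd >= 0, "rating_sd", "must be >= 0")
        _require(self.participant_sd >= 0, "participant_sd", "must be >= 0")
        _require(self.n_items >= 1, "n_items", "must be >= 1")


# ----------------------------------------------------------------------------
# reward schedule
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardSchedule:
    """Per-trial win probabilities of the two bandit arms.

    At every trial one arm holds ``p_high`` and the other ``p_low``; the
    assignment swaps at each index in ``reversal_points``.
    """

    p_a: np.ndarray
    p_b: np.ndarray
    reversal_points: tuple[int, ...]

    def __len__(self) -> int:
        return int(self.p_a.size)


def make_reward_schedule(cfg: RLSimConfig, seed: int | np.random.Generator | None = None) -> RewardSchedule:
    """Build the reversal schedule: ``n_reversals`` swaps at roughly even
    spacing.

    Swap points sit at ``k * n // (r + 1)`` for ``k = 1..r`` with +/-2-trial
    uniform jitter (clipped to keep points strictly inside the run and
    strictly increasing).  Which arm starts rich is a coin flip from the RNG.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed)
    n, r = cfg.n_trials, cfg.n_reversals
    base = [(k * n) // (r + 1) for k in range(1, r + 1)]
    points: list[int] = []
    for b in base:
        p = b + int(rng.integers(-2, 3))
        lo = (points[-1] + 1) if points else 1
        p = min(max(p, lo), n - 1 - (r - len(points) - 1))
        points.append(p)
    rich_is_a = bool(rng.integers(0, 2))
    p_a = np.empty(n)
    bounds = [0, *points, n]
    for seg, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:])):
        rich = rich_is_a if seg % 2 == 0 else not rich_is_a
        p_a[start:stop] = cfg.p_high if rich else cfg.p_low
    p_b = np.where(p_a == cfg.p_high, cfg.p_low, cfg.p_high)
    return RewardSchedule(p_a=p_a, p_b=p_b, reversal_points=tuple(points))


# ----------------------------------------------------------------------------
# agent simulation
# ----------------------------------------------------------------------------

def simulate_agent(params: AgentParams, schedule: RewardSchedule,
                   seed: int | np.random.Generator | None = 0) -> pd.DataFrame:
    """Play one agent through the schedule; returns trial/choice/reward rows.

    Both values start at 0 so the first choice is at exact chance; choices
    are drawn from the softmax probability and rewards from the chosen arm's
    scheduled probability.  Only the chosen arm's value is updated.
    """
    if len(schedule) < 1:
        raise ValueError("schedule must contain at least one trial")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta_win, eta_lose = params.rates()
    beta = params.beta
    v = [0.0, 0.0]
    u = rng.random(size=(len(schedule), 2))
    rows = np.empty((len(schedule), 3), dtype=np.int64)
    for i in range(len(schedule)):
        d = beta * (v[0] - v[1])
        p_a = 1.0 / (1.0 + np.exp(-d))
        choice = 0 if u[i, 0] < p_a else 1
        p_win = schedule.p_a[i] if choice == 0 else schedule.p_b[i]
        reward = 1 if u[i, 1] < p_win else 0
        eta = eta_win if reward > 0 else eta_lose
        v[choice] += eta * (reward - v[choice])
        rows[i] = (i, choice, reward)
    df = pd.DataFrame(rows, columns=["trial", "choice_idx", "reward"])
    df["choice"] = np.where(df.pop("choice_idx") == 0, "A", "B")
    return df[["trial", "choice", "reward"]]


# ----------------------------------------------------------------------------
# full study
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedStudy:
    """Bundle of generated tables plus the design that produced them."""

    design: StudyDesign
    dwell_truth: pd.DataFrame
    fixations: pd.DataFrame | None
    choices: pd.DataFrame
    self_report: pd.DataFrame
    true_rl_params: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"dwell_truth": self.dwell_truth, "choices": self.choices,
               "self_report": self.self_report, "true_rl_params": self.true_rl_params}
        if self.fixations is not None:
            out["fixations"] = self.fixations
        return out


def _dwell_props(lin_d: float, lin_n: float) -> tuple[float, float, float]:
    # half-scaled logistic per image: shares stay in [0, 0.5) each, sum < 1,
    # and the two stimulus streams remain independent given the participant
    p_d = 0.5 / (1.0 + np.exp(-lin_d))
    p_n = 0.5 / (1.0 + np.exp(-lin_n))
    return float(p_d), float(p_n), float(1.0 - p_d - p_n)


def simulate_study(design: StudyDesign, gaze_cfg: GazeSimConfig,
                   rl_cfg: RLSimConfig,
                   sr_cfg: SelfReportConfig | None = None,
                   emit_fixations: bool = True) -> SimulatedStudy:
    """Generate a complete synthetic study.

    Every participant contributes both visits, all phases.  The injected
    ``drug_phase_interaction`` is added to the disgust-dwell linear predictor
    only on domperidone-visit post-incentive trials, so a positive value
    shrinks avoidance there in expectation.

    With ``emit_fixations`` the per-trial proportions are additionally
    realised as fixation streams (chunks of <= 1500 ms placed inside the
    corresponding AOI, or between the images for non-stimulus time), scaled
    so total fixation time matches the trial's tracked time.
    """
    if sr_cfg is None:
        sr_cfg = SelfReportConfig()
    dwell_rows: list[tuple] = []
    fix_rows: list[tuple] = []
    choice_rows: list[pd.DataFrame] = []
    sr_rows: list[tuple] = []
    param_rows: list[tuple] = []

    for pid in range(design.n_participants):
        rng = np.random.default_rng(np.random.SeedSequence([gaze_cfg.seed, pid]))
        b_gaze = rng.normal(0.0, gaze_cfg.participant_sd)
        b_sr = rng.normal(0.0, sr_cfg.participant_sd)
        eta_true = rng.uniform(0.1, 0.7)
        beta_true = rng.uniform(1.0, 8.0)

        for visit in design.visit_order.get(pid, VISITS):
            # --- gaze ---
            for phase in design.phases:
                n = design.n_trials(phase)
                sides = design.side_assignment.get(
                    (visit, phase), tuple(["left", "right"] * (n // 2 + 1))[:n])
                interact = (gaze_cfg.drug_phase_interaction
                            if (visit == "domperidone" and phase == "post_incentive")
                            else 0.0)
                noise = rng.normal(0.0, gaze_cfg.trial_noise_sd, size=(n, 2))
                miss = _missing_fractions(rng, gaze_cfg.missingness_rate, n)
                for t in range(n):
                    lin_d = (gaze_cfg.mean_dwell_logit_neutral + gaze_cfg.stimulus_effect
                             + interact + b_gaze + noise[t, 0])
                    lin_n = gaze_cfg.mean_dwell_logit_neutral + b_gaze + noise[t, 1]
                    p_d, p_n, p_ns = _dwell_props(lin_d, lin_n)
                    valid = 1.0 - miss[t]
                    dwell_rows.append((pid, visit, phase, t, sides[t],
                                       p_d, p_n, p_ns, valid))
                    if emit_fixations:
                        fix_rows.extend(_realise_fixations(
                            rng, pid, visit, phase, t, sides[t],
                            (p_d, p_n, p_ns), valid, gaze_cfg.trial_duration_ms))

            # --- control task ---
            for rl_phase in RL_PHASES:
                key = (pid, visit, rl_phase)
                if rl_cfg.true_params is not None and key in rl_cfg.true_params:
                    params = rl_cfg.true_params[key]
                else:
                    params = AgentParams("single", beta=beta_true, eta=eta_true)
                schedule = make_reward_schedule(rl_cfg, seed=rng)
                run = simulate_agent(params, schedule, seed=rng)
                run.insert(0, "participant", pid)
                run.insert(1, "visit", visit)
                run.insert(2, "rl_phase", rl_phase)
                choice_rows.append(run)
                ew, el = params.rates()
                param_rows.append((pid, visit, rl_phase, params.variant,
                                   ew, el, params.beta))

            # --- self-report ---
            for phase in RATING_PHASES:
                interact = (sr_cfg.drug_phase_interaction
                            if (visit == "domperidone" and phase == "post_incentive")
                            else 0.0)
                for category, mean in (("disgust", sr_cfg.mean_disgust + interact),
                                       ("neutral", sr_cfg.mean_neutral)):
                    vals = np.clip(
                        rng.normal(mean + b_sr, sr_cfg.rating_sd, size=sr_cfg.n_items),
                        0.0, 100.0)
                    for item, val in enumerate(vals):
                        sr_rows.append((pid, visit, phase, category, item, float(val)))

    dwell = pd.DataFrame(dwell_rows, columns=[
        "participant", "visit", "phase", "trial", "disgust_side",
        "p_disgust", "p_neutral", "p_nonstim", "valid_fraction"])
    fixations = (pd.DataFrame(fix_rows, columns=[
        "participant", "visit", "phase", "trial", "onset_ms", "duration_ms",
        "x", "y", "disgust_side"]) if emit_fixations else None)
    choices = pd.concat(choice_rows, ignore_index=True)
    self_report = pd.DataFrame(sr_rows, columns=[
        "participant", "visit", "phase", "category", "item", "rating"])
    true_params = pd.DataFrame(param_rows, columns=[
        "participant", "visit", "rl_phase", "variant", "eta_win", "eta_lose", "beta"])
    return SimulatedStudy(design=design, dwell_truth=dwell, fixations=fixations,
                          choices=choices, self_report=self_report,
                          true_rl_params=true_params)


def _missing_fractions(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """Per-trial missing-data fractions with mean ``rate``.

    Drawn from Beta(2*rate, 2*(1 - rate)): most trials lose little tracking
    but a small tail exceeds the 50% drop threshold, mimicking occasional
    track loss.  A rate of 0 yields exact zeros.
    """
    if rate <= 0.0:
        return np.zeros(n)
    if rate >= 1.0:
        return np.ones(n)
    return rng.beta(2.0 * rate, 2.0 * (1.0 - rate), size=n)


_FIX_CHUNK_MS = 1500.0


def _realise_fixations(rng, pid, visit, phase, trial, side, props, valid,
                       trial_duration_ms):
    """Turn target proportions into fixation rows whose dwell recovers them."""
    layout = AOILayout(disgust_side=side)
    tracked = valid * trial_duration_ms
    if tracked <= 0:
        return []
    targets = {"disgust": layout.disgust_rect, "neutral": layout.neutral_rect}
    w, h = layout.screen_size
    rows = []
    onset = 0.0
    for label, p in zip(("disgust", "neutral", "nonstim"), props):
        remaining = p * tracked
        while remaining > 1e-9:
            d = min(_FIX_CHUNK_MS, remaining)
            remaining -= d
            if label == "nonstim":
                # central gap between the two image rectangles
                x = rng.uniform(layout.disgust_rect[2], layout.neutral_rect[0]) \
                    if side == "left" else rng.uniform(layout.neutral_rect[2],
                                                       layout.disgust_rect[0])
                y = rng.uniform(0.25 * h, 0.75 * h)
            else:
                x0, y0, x1, y1 = targets[label]
                x = rng.uniform(x0 + 1.0, x1 - 1.0)
                y = rng.uniform(y0 + 1.0, y1 - 1.0)
            rows.append((pid, visit, phase, trial, onset, d, x, y, side))
            onset += d
    return rows
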