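"""Dwell-time metrics for the two-image preferential-looking display.

Each trial shows a disgusting and a neutral image (400 x 300 px) left and
right of fixation, image centres 640 px apart on a 1280 x 1024 screen.
Fixations are classified by which image rectangle (area of interest, AOI)
their centroid falls in; dwell-time proportions are summed fixation duration
per AOI divided by total fixation duration in the trial, so the three
proportions (disgust / neutral / non-stimulus) always sum to 1.  The
avoidance score is the neutral-minus-disgust proportion difference; positive
values mean gaze avoided the disgusting image.

Pixel conventions, used everywhere: origin top-left, 0-based coordinates,
half-open rectangles (left/top edge inside, right/bottom edge outside).

Trial-level missingness is tracked separately as ``1 - valid_fraction``
(tracked time over nominal trial duration); trials with more than 50%
missing data are dropped before modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AOILayout",
    "DwellRecord",
    "assign_fixation",
    "assign_fixations",
    "compute_dwell",
    "dwell_table",
    "filter_trials",
    "avoidance",
    "avoidance_table",
]

#: dwell-record key columns identifying one trial
TRIAL_KEYS = ["participant", "visit", "phase", "trial"]


@dataclass(frozen=True)
class AOILayout:
    """Screen geometry of the two lateral image AOIs.

    ``disgust_side`` says which image holds the disgusting stimulus on this
    trial ("left" or "right").
    """

    disgust_side: str
    screen_size: tuple[int, int] = (1280, 1024)
    image_size: tuple[int, int] = (400, 300)
    center_separation: int = 640

    def __post_init__(self) -> None:
        if self.disgust_side not in ("left", "right"):
            raise ValueError(f"disgust_side must be 'left' or 'right', got {self.disgust_side!r}")
        left, right = self._rects()
        w, h = self.screen_size
        for x0, y0, x1, y1 in (left, right):
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError("image rectangle extends beyond the screen")
        if left[2] > right[0]:
            raise ValueError("image rectangles overlap")

    def _rects(self) -> tuple[tuple[float, float, float, float], ...]:
        w, h = self.screen_size
        iw, ih = self.image_size
        cy = h / 2.0
        cx_left = w / 2.0 - self.center_separation / 2.0
        cx_right = w / 2.0 + self.center_separation / 2.0
        mk = lambda cx: (cx - iw / 2.0, cy - ih / 2.0, cx + iw / 2.0, cy + ih / 2.0)
        return mk(cx_left), mk(cx_right)

    @property
    def disgust_rect(self) -> tuple[float, float, float, float]:
        """Half-open (x0, y0, x1, y1) of the disgusting image."""
        left, right = self._rects()
        return left if self.disgust_side == "left" else right

    @property
    def neutral_rect(self) -> tuple[float, float, float, float]:
        left, right = self._rects()
        return right if self.disgust_side == "left" else left


def _inside(x: float, y: float, rect: tuple[float, float, float, float]) -> bool:
    x0, y0, x1, y1 = rect
    return x0 <= x < x1 and y0 <= y < y1


def assign_fixation(x: float, y: float, layout: AOILayout) -> str:
    """AOI label of a fixation centroid: 'disgust', 'neutral' or 'nonstim'.

    Off-screen points are 'nonstim'; edge membership follows the half-open
    rectangle convention.
    """
    if _inside(x, y, layout.disgust_rect):
        return "disgust"
    if _inside(x, y, layout.neutral_rect):
        return "neutral"
    return "nonstim"


def assign_fixations(fixations: pd.DataFrame) -> pd.DataFrame:
    """Vectorised AOI labelling of a fixation table.

    Requires ``x``, ``y`` and per-trial ``disgust_side`` columns; returns a
    copy with an ``aoi`` column.  Geometry defaults are those of
    :class:`AOILayout`.
    """
    out = fixations.copy()
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    side = out["disgust_side"].to_numpy()
    layouts = {s: AOILayout(disgust_side=s) for s in ("left", "right")}
    aoi = np.full(len(out), "nonstim", dtype=object)
    for s, layout in layouts.items():
        mask = side == s
        for label, rect in (("disgust", layout.disgust_rect),
                            ("neutral", layout.neutral_rect)):
            x0, y0, x1, y1 = rect
            hit = mask & (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
            aoi[hit] = label
    out["aoi"] = aoi
    return out


@dataclass(frozen=True)
class DwellRecord:
    """Per-trial dwell-time proportions over the three fixation categories."""

    participant: object
    visit: str
    phase: str
    trial: int
    p_disgust: float
    p_neutral: float
    p_nonstim: float
    valid_fraction: float
    missing: bool = False


def compute_dwell(trial: pd.DataFrame, layout: AOILayout,
                  trial_duration_ms: float | None = None) -> DwellRecord:
    """Dwell proportions of one trial's fixations.

    ``trial`` needs ``onset_ms``, ``duration_ms``, ``x``, ``y`` columns plus
    the identifying keys.  Proportions are normalised by total fixation
    duration; a trial with no fixation time is returned flagged ``missing``
    with NaN proportions.  ``valid_fraction`` is total fixation time over
    ``trial_duration_ms`` when given (1.0 otherwise).
    """
    dur = trial["duration_ms"].to_numpy(dtype=float) if len(trial) else np.array([])
    if (dur < 0).any():
        raise ValueError("negative fixation duration")
    keys = {k: trial[k].iloc[0] if len(trial) else None for k in TRIAL_KEYS}
    total = float(dur.sum())
    if trial_duration_ms is not None:
        if trial_duration_ms <= 0:
            raise ValueError("trial_duration_ms must be positive")
        valid = min(total / trial_duration_ms, 1.0)
    else:
        valid = 1.0 if total > 0 else 0.0
    if total <= 0:
        return DwellRecord(**keys, p_disgust=math.nan, p_neutral=math.nan,
                           p_nonstim=math.nan, valid_fraction=0.0, missing=True)
    sums = {"disgust": 0.0, "neutral": 0.0, "nonstim": 0.0}
    for x, y, d in zip(trial["x"], trial["y"], dur):
        sums[assign_fixation(float(x), float(y), layout)] += d
    return DwellRecord(**keys,
                       p_disgust=sums["disgust"] / total,
                       p_neutral=sums["neutral"] / total,
                       p_nonstim=sums["nonstim"] / total,
                       valid_fraction=valid, missing=False)


def dwell_table(fixations: pd.DataFrame, trial_duration_ms: float) -> pd.DataFrame:
    """Aggregate a fixation table into one dwell record per trial.

    Fixations are AOI-labelled per the trial's ``disgust_side``; proportions
    normalise by total fixation time and ``valid_fraction`` by the nominal
    trial duration.  Trials with zero fixation time get NaN proportions and
    ``missing = True``.
    """
    if trial_duration_ms <= 0:
        raise ValueError("trial_duration_ms must be positive")
    if (fixations["duration_ms"] < 0).any():
        raise ValueError("negative fixation duration")
    lab = assign_fixations(fixations)
    pivot = (lab.pivot_table(index=TRIAL_KEYS, columns="aoi",
                             values="duration_ms", aggfunc="sum", fill_value=0.0)
             .reindex(columns=["disgust", "neutral", "nonstim"], fill_value=0.0))
    total = pivot.sum(axis=1)
    out = pivot.div(total.replace(0.0, np.nan), axis=0)
    out.columns = ["p_disgust", "p_neutral", "p_nonstim"]
    out["valid_fraction"] = (total / trial_duration_ms).clip(upper=1.0)
    out["missing"] = total <= 0
    return out.reset_index()


def filter_trials(records: pd.DataFrame, max_missing: float = 0.5) -> tuple[pd.DataFrame, int]:
    """Drop trials whose missing-data fraction strictly exceeds ``max_missing``.

    Missingness is ``1 - valid_fraction``; a trial with exactly 50% missing
    data is retained under the default threshold (the rule is strict).
    Trials flagged ``missing`` (no fixation time at all) are always dropped.
    Returns the retained records and the number dropped.
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    missingness = 1.0 - records["valid_fraction"].to_numpy(dtype=float)
    drop = missingness > max_missing
    if "missing" in records.columns:
        drop |= records["missing"].to_numpy(dtype=bool)
    kept = records.loc[~drop].reset_index(drop=True)
    return kept, int(drop.sum())


def avoidance(record: DwellRecord) -> float:
    """Avoidance score of one trial: ``p_neutral - p_disgust`` in [-1, 1]."""
    if record.missing:
        return math.nan
    return record.p_neutral - record.p_disgust


def avoidance_table(records: pd.DataFrame) -> pd.DataFrame:
    """Add an ``avoidance`` column (p_neutral - p_disgust) to a dwell table."""
    out = records.copy()
    out["avoidance"] = out["p_neutral"] - out["p_disgust"]
    return out
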