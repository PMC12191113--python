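"""Saccade detection, trial-response classification, RT tables, and the
behavioral statistics (Welch's t, Fisher's exact, stay-proportion contrast).

Saccade onsets follow the task's operational definition: the first eye-trace
sample whose 2-point central-difference speed strictly exceeds 40 deg/s
within 400 ms of target onset. No pre-smoothing is applied and no further
refinement of the onset is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EyeTrace, Session, Trial

__all__ = [
    "BehaviorParams",
    "TraceGapError",
    "eye_speed",
    "detect_saccade",
    "classify_response",
    "classify_session",
    "rt_table",
    "welch_t",
    "fisher_exact_2x2",
    "stay_contrast",
]


class TraceGapError(ValueError):
    """The eye trace does not cover the requested analysis window."""


@dataclass
class BehaviorParams:
    velocity_threshold: float = 40.0    # deg/s
    response_window_ms: float = 400.0
    hold_duration_ms: float = 400.0
    fixation_radius_deg: float = 3.0
    object_radius_deg: float = 4.0

    def __post_init__(self) -> None:
        for f in ("velocity_threshold", "response_window_ms",
                  "hold_duration_ms", "fixation_radius_deg",
                  "object_radius_deg"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def eye_speed(eye: EyeTrace) -> np.ndarray:
    """2-point central-difference gaze speed (deg/s), same length as the trace.

    Endpoints reuse the one-sided difference; interior sample i uses
    (p[i+1] - p[i-1]) / (2 dt). Invariant to adding a constant to position
    and to shifting the trace in time.
    """
    dt = 1.0 / eye.sample_rate
    vx = np.gradient(eye.x, dt)
    vy = np.gradient(eye.y, dt)
    return np.hypot(vx, vy)


def detect_saccade(eye: EyeTrace, t_ref: float,
                   params: BehaviorParams | None = None,
                   window_ms: float | None = None) -> float | None:
    """Time (s) of the first suprathreshold speed sample in
    [t_ref, t_ref + window]; ``None`` if the speed never exceeds threshold."""
    params = params or BehaviorParams()
    window_s = (params.response_window_ms if window_ms is None else window_ms) / 1e3
    i0 = eye.index_of(t_ref)
    i1 = eye.index_of(t_ref + window_s)
    if i0 < 0 or i1 > eye.x.size - 1:
        raise TraceGapError(
            f"trace does not cover [{t_ref}, {t_ref + window_s}] s")
    speed = eye_speed(eye)[i0:i1 + 1]
    above = np.flatnonzero(speed > params.velocity_threshold)
    if above.size == 0:
        return None
    return eye.t0 + (i0 + int(above[0])) / eye.sample_rate


def _gaze_at(eye: EyeTrace, t: float, half_ms: float = 10.0) -> np.ndarray:
    i = eye.index_of(t)
    h = max(1, int(half_ms / 1e3 * eye.sample_rate))
    lo, hi = max(0, i - h), min(eye.x.size, i + h + 1)
    return np.array([eye.x[lo:hi].mean(), eye.y[lo:hi].mean()])


def _saccade_end(eye: EyeTrace, onset: float,
                 params: BehaviorParams) -> float:
    """First time after onset where speed stays below threshold for 5 ms."""
    speed = eye_speed(eye)
    i = eye.index_of(onset)
    run = max(1, int(0.005 * eye.sample_rate))
    below = speed[i:] <= params.velocity_threshold
    count = 0
    for j, b in enumerate(below):
        count = count + 1 if b else 0
        if count >= run:
            return eye.t0 + (i + j) / eye.sample_rate
    return eye.t0 + (eye.x.size - 1) / eye.sample_rate


def classify_response(trial: Trial, eye: EyeTrace,
                      params: BehaviorParams | None = None,
                      task: str = "choice") -> str:
    """Classify one trial from its gaze trace.

    choice task: ``accept`` = saccade lands within the object window and gaze
    stays there for the hold duration; ``return`` = lands in the object
    window then re-enters the fixation window before the hold elapses;
    ``stay`` = no saccade and gaze within the fixation window throughout the
    response window; ``other`` = saccade landing outside both windows.
    fixation task: a saccade landing in the object window is a ``fix_break``;
    otherwise ``stay``.
    """
    params = params or BehaviorParams()
    onset = detect_saccade(eye, trial.target_on, params)
    obj = np.asarray(trial.object_xy)

    if onset is None:
        return "stay"
    end = _saccade_end(eye, onset, params)
    land = _gaze_at(eye, end + 0.01)
    in_object = float(np.hypot(*(land - obj))) <= params.object_radius_deg

    if task == "fixation":
        return "fix_break" if in_object else "stay"

    if not in_object:
        # landing inside the fixation window is a tiny corrective movement,
        # not a response saccade; treat as stay
        if float(np.hypot(*land)) <= params.fixation_radius_deg:
            return "stay"
        return "other"

    # object window reached: accept vs return depends on the hold period
    hold_s = params.hold_duration_ms / 1e3
    i_end = eye.index_of(end)
    i_hold = min(eye.x.size, eye.index_of(end + hold_s))
    seg = np.hypot(eye.x[i_end:i_hold], eye.y[i_end:i_hold])
    if np.any(seg <= params.fixation_radius_deg):
        return "return"
    return "accept"


def classify_session(session: Session,
                     params: BehaviorParams | None = None) -> pd.DataFrame:
    """Classify every trial of a session; returns trial_id -> label frame."""
    if session.eye is None:
        raise ValueError("session has no eye trace")
    rows = [{"trial_id": t.trial_id,
             "label": classify_response(t, session.eye, params, session.task)}
            for t in session.trials]
    return pd.DataFrame(rows)


def rt_table(session: Session) -> pd.DataFrame:
    """RT rows for trials with an initial saccade toward the object.

    Only ``accept`` and ``return`` responses qualify ("initial saccades
    toward objects"); stay/other/fix_break trials carry no RT row.
    """
    rows = []
    for t in session.trials:
        if t.response in ("accept", "return") and t.rt is not None:
            rows.append({"trial_id": t.trial_id, "value": t.object_value,
                         "laterality": t.laterality, "scene": t.scene,
                         "response": t.response, "rt": t.rt})
    return pd.DataFrame(rows, columns=["trial_id", "value", "laterality",
                                       "scene", "response", "rt"])


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table: (odds ratio, p)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table < 0) or np.any(table != np.floor(table)):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def stay_contrast(session: Session) -> tuple[np.ndarray, float, float]:
    """Stay-vs-other-rejection contrast between stable (scenes 1-2) and
    flexible (scenes 3-4) value conditions.

    Builds the 2x2 table rows = scene group, cols = (stay, non-stay
    rejection) over bad-object rejection trials, then applies Fisher's exact
    test. Raises if either scene group has no rejection trials.
    """
    table = np.zeros((2, 2), dtype=int)
    for t in session.trials:
        if t.object_value != "bad" or t.response not in ("return", "stay", "other"):
            continue
        row = 0 if t.scene in (1, 2) else 1
        col = 0 if t.response == "stay" else 1
        table[row, col] += 1
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("a scene group has no rejection trials")
    odds, p = fisher_exact_2x2(table)
    return table, odds, p
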