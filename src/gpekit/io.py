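"""Session data model, on-disk bundle format, validation, and analysis config.

A *session* is one behaving-and-recording block: a table of trials with their
event times and behavioral outcome, a set of simultaneously recorded
single-unit spike trains, optionally a 1 kHz eye-position trace and per-neuron
spike waveforms, plus metadata (monkey, hemisphere, task variant, injection
condition).

On disk a session is a directory of UTF-8 tab-separated tables:

    <session>/
        meta.yaml        key-value metadata
        trials.tsv       one row per trial
        spikes.tsv       long format: neuron_id <TAB> time (s)
        waveforms.tsv    long format: neuron_id <TAB> time_us <TAB> voltage
        eye.tsv          columns x, y (degrees), 1 row per sample

All times are stored in seconds from session start; analysis windows elsewhere
in the package are expressed in milliseconds relative to an event. Missing
values are empty fields. The format is plain text so bundles diff cleanly and
need no binary dependencies.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trial",
    "SpikeTrain",
    "EyeTrace",
    "Session",
    "Issue",
    "FormatError",
    "ValidationError",
    "side_of_angle",
    "laterality_of",
    "read_session",
    "write_session",
    "validate_session",
    "AnalysisParams",
    "load_params",
]

HEMISPHERES = ("left", "right")
TASKS = ("choice", "fixation")
INJECTIONS = ("none", "antagonist", "saline")
VALUES = ("good", "bad")
RESPONSES = ("accept", "return", "stay", "other", "fix_break")
#: the six peripheral target locations (degrees, 15 deg eccentricity)
OBJECT_ANGLES = (0.0, 45.0, 135.0, 180.0, 225.0, 315.0)
OBJECT_ECCENTRICITY_DEG = 15.0

# duplicate-spike resolution of the data model (0.1 ms)
_SPIKE_TOL_S = 1e-4


class FormatError(ValueError):
    """A bundle on disk does not follow the documented dialect."""


class ValidationError(ValueError):
    """A session object violates a data-model invariant."""


def side_of_angle(angle_deg: float) -> str:
    """Screen side of a target at ``angle_deg``: sign of the cosine.

    Angles {0, 45, 315} map to "right", {135, 180, 225} to "left". Vertical
    targets (cos = 0) do not occur in the six-location task and raise.
    """
    c = math.cos(math.radians(angle_deg))
    if abs(c) < 1e-9:
        raise ValueError(f"angle {angle_deg} deg has no left/right side")
    return "right" if c > 0 else "left"


def laterality_of(side: str, hemisphere: str) -> str:
    """"contra" iff the target side is opposite the recorded hemisphere."""
    if side not in HEMISPHERES or hemisphere not in HEMISPHERES:
        raise ValueError(f"bad side/hemisphere: {side!r}, {hemisphere!r}")
    return "contra" if side != hemisphere else "ipsi"


@dataclass
class Trial:
    trial_id: int
    scene: int
    scene_on: float
    fp_on: float
    target_on: float
    object_value: str
    object_angle: float
    side: str = ""
    laterality: str = ""
    response: str | None = None
    saccade_on: float | None = None
    rt: float | None = None  # ms
    rewarded: bool = False

    def derive(self, hemisphere: str) -> "Trial":
        """Populate the derived fields (side, laterality, rt) in place."""
        self.side = side_of_angle(self.object_angle)
        self.laterality = laterality_of(self.side, hemisphere)
        if self.saccade_on is not None:
            self.rt = (self.saccade_on - self.target_on) * 1000.0
        return self

    @property
    def object_xy(self) -> tuple[float, float]:
        a = math.radians(self.object_angle)
        r = OBJECT_ECCENTRICITY_DEG
        return (r * math.cos(a), r * math.sin(a))

    @property
    def scene_group(self) -> str:
        """"stable" for scenes 1-2 (fixed object values), "flexible" for 3-4."""
        return "stable" if self.scene in (1, 2) else "flexible"


@dataclass
class SpikeTrain:
    neuron_id: str
    spike_times: np.ndarray  # sorted, seconds
    waveform: np.ndarray | None = None  # (n, 2): time_us, voltage

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=float)


@dataclass
class EyeTrace:
    sample_rate: float  # Hz
    x: np.ndarray  # degrees
    y: np.ndarray
    t0: float = 0.0  # session time of sample 0, seconds

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.sample_rate

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) * self.sample_rate))


@dataclass
class Session:
    session_id: str
    monkey_id: str
    hemisphere: str
    task: str = "choice"
    injection: str = "none"
    injection_time: float | None = None
    trials: list[Trial] = field(default_factory=list)
    neurons: list[SpikeTrain] = field(default_factory=list)
    eye: EyeTrace | None = None
    scene_set_id: int = 1
    duration: float | None = None

    def neuron(self, neuron_id: str) -> SpikeTrain:
        for n in self.neurons:
            if n.neuron_id == neuron_id:
                return n
        raise KeyError(neuron_id)

    def trials_df(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials])

    def event_times(self, event: str, trials: Iterable[Trial] | None = None) -> np.ndarray:
        """Event times (s) for ``event`` in {scene, fp, target, saccade}.

        Trials lacking the event (e.g. no saccade) are skipped.
        """
        key = {"scene": "scene_on", "fp": "fp_on", "target": "target_on",
               "saccade": "saccade_on"}[event]
        out = [getattr(t, key) for t in (self.trials if trials is None else trials)]
        return np.array([t for t in out if t is not None], dtype=float)


@dataclass
class Issue:
    """One validation finding: which rule failed, where."""
    field: str
    ident: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.ident}] {self.field}: {self.rule} — {self.message}"


# ---------------------------------------------------------------------------
# validation

def validate_session(session: Session) -> list[Issue]:
    """Check every data-model invariant; report issues, never raise."""
    issues: list[Issue] = []

    def add(field_: str, ident: str, rule: str, msg: str) -> None:
        issues.append(Issue(field_, ident, rule, msg))

    if session.hemisphere not in HEMISPHERES:
        add("hemisphere", session.session_id, "hemisphere in {left,right}",
            f"got {session.hemisphere!r}")
    if session.task not in TASKS:
        add("task", session.session_id, "task in {choice,fixation}",
            f"got {session.task!r}")
    if session.injection not in INJECTIONS:
        add("injection", session.session_id,
            "injection in {none,antagonist,saline}", f"got {session.injection!r}")
    if not (1 <= session.scene_set_id <= 6):
        add("scene_set_id", session.session_id, "scene_set_id in 1..6",
            f"got {session.scene_set_id}")

    prev_on = -math.inf
    for t in session.trials:
        ident = f"trial {t.trial_id}"
        if not (t.scene_on < t.fp_on < t.target_on):
            add("scene_on/fp_on/target_on", ident,
                "scene_on < fp_on < target_on",
                f"{t.scene_on}, {t.fp_on}, {t.target_on}")
        if t.scene_on <= prev_on:
            add("scene_on", ident, "trial times strictly increasing",
                f"{t.scene_on} <= previous {prev_on}")
        prev_on = t.scene_on
        if not (1 <= t.scene <= 4):
            add("scene", ident, "scene in 1..4", f"got {t.scene}")
        if t.object_value not in VALUES:
            add("object_value", ident, "object_value in {good,bad}",
                f"got {t.object_value!r}")
        if t.object_angle not in OBJECT_ANGLES:
            add("object_angle", ident, "angle in the six task locations",
                f"got {t.object_angle}")
        else:
            if t.side != side_of_angle(t.object_angle):
                add("side", ident, "side derived from angle (cosine sign)",
                    f"got {t.side!r}")
            elif t.laterality != laterality_of(t.side, session.hemisphere):
                add("laterality", ident,
                    "laterality = contra iff side opposite hemisphere",
                    f"got {t.laterality!r}")
        if t.response is not None and t.response not in RESPONSES:
            add("response", ident, "response in documented taxonomy",
                f"got {t.response!r}")
        if t.saccade_on is not None and t.rt is not None:
            if not math.isclose(t.rt, (t.saccade_on - t.target_on) * 1e3,
                                rel_tol=0, abs_tol=1e-6):
                add("rt", ident, "rt = (saccade_on - target_on) * 1000",
                    f"rt={t.rt}, saccade_on={t.saccade_on}")

    dur = session.duration
    for n in session.neurons:
        st = n.spike_times
        ident = f"neuron {n.neuron_id}"
        if st.size and np.any(np.diff(st) <= 0):
            bad = np.flatnonzero(np.diff(st) <= 0)[0]
            add("spike_times", ident, "spike times strictly sorted",
                f"at index {bad + 1}")
        elif st.size and np.any(np.diff(st) < _SPIKE_TOL_S):
            add("spike_times", ident, "no duplicates within 0.1 ms", "")
        if st.size and st[0] < 0:
            add("spike_times", ident, "spike times non-negative", f"first {st[0]}")
        if dur is not None and st.size and st[-1] > dur:
            add("spike_times", ident, "spikes within session duration",
                f"last {st[-1]} > duration {dur}")

    if session.eye is not None:
        e = session.eye
        if e.x.size != e.y.size:
            add("eye", session.session_id, "x and y equal length",
                f"{e.x.size} vs {e.y.size}")
        if not e.sample_rate > 0:
            add("eye", session.session_id, "sample_rate > 0", f"{e.sample_rate}")
    return issues


# ---------------------------------------------------------------------------
# bundle I/O

_TRIAL_COLS = ["trial_id", "scene", "scene_on", "fp_on", "target_on",
               "object_value", "object_angle", "side", "laterality",
               "response", "saccade_on", "rt", "rewarded"]


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(float(v))  # builtin repr round-trips exactly
    return str(v)


def write_session(session: Session, path: str | os.PathLike) -> str:
    """Write ``session`` as a bundle directory; returns the path.

    ``read_session(write_session(s, p))`` reproduces ``s`` field by field
    (floats are written with full repr precision so they round-trip exactly).
    """
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)

    meta = {
        "session_id": session.session_id,
        "monkey_id": session.monkey_id,
        "hemisphere": session.hemisphere,
        "task": session.task,
        "injection": session.injection,
        "injection_time": session.injection_time,
        "scene_set_id": session.scene_set_id,
        "duration": session.duration,
    }
    if session.eye is not None:
        meta["eye_sample_rate"] = session.eye.sample_rate
        meta["eye_t0"] = session.eye.t0
    with open(os.path.join(path, "meta.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    with open(os.path.join(path, "trials.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TRIAL_COLS) + "\n")
        for t in session.trials:
            d = dataclasses.asdict(t)
            fh.write("\t".join(_fmt(d[c]) for c in _TRIAL_COLS) + "\n")

    with open(os.path.join(path, "spikes.tsv"), "w", encoding="utf-8") as fh:
        fh.write("neuron_id\ttime\n")
        for n in session.neurons:
            nid = n.neuron_id
            for s in n.spike_times:
                fh.write(f"{nid}\t{float(s)!r}\n")

    any_wf = any(n.waveform is not None for n in session.neurons)
    wf_path = os.path.join(path, "waveforms.tsv")
    if any_wf:
        with open(wf_path, "w", encoding="utf-8") as fh:
            fh.write("neuron_id\ttime_us\tvoltage\n")
            for n in session.neurons:
                if n.waveform is None:
                    continue
                for t_us, v in n.waveform:
                    fh.write(f"{n.neuron_id}\t{float(t_us)!r}\t{float(v)!r}\n")
    elif os.path.exists(wf_path):
        os.remove(wf_path)

    eye_path = os.path.join(path, "eye.tsv")
    if session.eye is not None:
        with open(eye_path, "w", encoding="utf-8") as fh:
            fh.write("x\ty\n")
            for xv, yv in zip(session.eye.x, session.eye.y):
                fh.write(f"{float(xv)!r}\t{float(yv)!r}\n")
    elif os.path.exists(eye_path):
        os.remove(eye_path)
    return path


def _require(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{table} is missing required column(s): "
                          + ", ".join(missing))


def read_session(path: str | os.PathLike, derive: bool = True) -> Session:
    """Read and validate a session bundle directory.

    Raises :class:`FormatError` for missing tables/columns and
    :class:`ValidationError` for unsorted spike trains. Derived trial fields
    (side, laterality, rt) are recomputed from their sources unless
    ``derive=False``.
    """
    path = os.fspath(path)
    meta_path = os.path.join(path, "meta.yaml")
    trials_path = os.path.join(path, "trials.tsv")
    spikes_path = os.path.join(path, "spikes.tsv")
    for p, name in [(meta_path, "meta.yaml"), (trials_path, "trials.tsv"),
                    (spikes_path, "spikes.tsv")]:
        if not os.path.exists(p):
            raise FormatError(f"bundle at {path} lacks required table {name}")

    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh) or {}

    tdf = pd.read_csv(trials_path, sep="\t", dtype={"response": "string"},
                      float_precision="round_trip")
    _require(tdf, ["trial_id", "scene", "scene_on", "fp_on", "target_on",
                   "object_value", "object_angle"], "trials.tsv")

    def opt(row, col, cast=float):
        if col not in row or pd.isna(row[col]):
            return None
        return cast(row[col])

    trials = []
    for _, row in tdf.iterrows():
        trials.append(Trial(
            trial_id=int(row["trial_id"]),
            scene=int(row["scene"]),
            scene_on=float(row["scene_on"]),
            fp_on=float(row["fp_on"]),
            target_on=float(row["target_on"]),
            object_value=str(row["object_value"]),
            object_angle=float(row["object_angle"]),
            side=str(row["side"]) if "side" in row and not pd.isna(row["side"]) else "",
            laterality=(str(row["laterality"])
                        if "laterality" in row and not pd.isna(row["laterality"]) else ""),
            response=opt(row, "response", str),
            saccade_on=opt(row, "saccade_on"),
            rt=opt(row, "rt"),
            rewarded=bool(int(row["rewarded"])) if "rewarded" in row and not pd.isna(row["rewarded"]) else False,
        ))

    sdf = pd.read_csv(spikes_path, sep="\t", float_precision="round_trip")
    _require(sdf, ["neuron_id", "time"], "spikes.tsv")
    wf: dict[str, np.ndarray] = {}
    wf_path = os.path.join(path, "waveforms.tsv")
    if os.path.exists(wf_path):
        wdf = pd.read_csv(wf_path, sep="\t", float_precision="round_trip")
        _require(wdf, ["neuron_id", "time_us", "voltage"], "waveforms.tsv")
        for nid, grp in wdf.groupby("neuron_id", sort=False):
            wf[str(nid)] = grp[["time_us", "voltage"]].to_numpy(dtype=float)

    neurons = []
    for nid, grp in sdf.groupby("neuron_id", sort=False):
        st = grp["time"].to_numpy(dtype=float)
        if st.size > 1 and np.any(np.diff(st) <= 0):
            raise ValidationError(f"neuron {nid}: spike times not sorted")
        neurons.append(SpikeTrain(str(nid), st, wf.get(str(nid))))
    # neurons present only in waveforms.tsv (no spikes) are kept too
    have = {n.neuron_id for n in neurons}
    for nid, arr in wf.items():
        if nid not in have:
            neurons.append(SpikeTrain(nid, np.empty(0), arr))

    eye = None
    eye_path = os.path.join(path, "eye.tsv")
    if os.path.exists(eye_path):
        edf = pd.read_csv(eye_path, sep="\t", float_precision="round_trip")
        _require(edf, ["x", "y"], "eye.tsv")
        eye = EyeTrace(sample_rate=float(meta.get("eye_sample_rate", 1000.0)),
                       x=edf["x"].to_numpy(dtype=float),
                       y=edf["y"].to_numpy(dtype=float),
                       t0=float(meta.get("eye_t0", 0.0)))

    session = Session(
        session_id=str(meta.get("session_id", os.path.basename(path))),
        monkey_id=str(meta.get("monkey_id", "")),
        hemisphere=str(meta.get("hemisphere", "left")),
        task=str(meta.get("task", "choice")),
        injection=str(meta.get("injection", "none")),
        injection_time=(None if meta.get("injection_time") is None
                        else float(meta["injection_time"])),
        trials=trials,
        neurons=neurons,
        eye=eye,
        scene_set_id=int(meta.get("scene_set_id", 1)),
        duration=(None if meta.get("duration") is None
                  else float(meta["duration"])),
    )
    if derive:
        for t in session.trials:
            t.derive(session.hemisphere)
    return session


# ---------------------------------------------------------------------------
# analysis configuration

@dataclass
class AnalysisParams:
    """All tunable analysis parameters, with task-convention defaults.

    Units: windows in ms relative to the aligning event; velocities in deg/s;
    radii in degrees of visual angle.
    """
    # behavior
    velocity_threshold: float = 40.0     # deg/s saccade-onset threshold
    response_window_ms: float = 400.0    # saccade must start within this
    hold_duration_ms: float = 400.0      # fixation hold to accept
    fixation_radius_deg: float = 3.0
    object_radius_deg: float = 4.0
    # PSTH
    bin_ms: float = 1.0
    smooth_sigma_ms: float = 20.0
    baseline_window_ms: tuple[float, float] = (-500.0, 0.0)
    scene_window_ms: tuple[float, float] = (-500.0, 800.0)
    target_window_ms: tuple[float, float] = (-500.0, 600.0)
    saccade_window_ms: tuple[float, float] = (-500.0, 400.0)
    sd_scope: str = "trace"              # SD over whole trace vs baseline-only
    # clustering / population windows
    feature_window_ms: tuple[float, float] = (100.0, 300.0)
    rt_corr_window_ms: tuple[float, float] = (100.0, 300.0)

    def align_window(self, event: str) -> tuple[float, float]:
        return {"scene": self.scene_window_ms, "target": self.target_window_ms,
                "saccade": self.saccade_window_ms}[event]


def load_params(path: str | os.PathLike | None = None) -> AnalysisParams:
    """Load :class:`AnalysisParams` from a YAML key-value file (or defaults)."""
    params = AnalysisParams()
    if path is None:
        return params
    with open(os.fspath(path), encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(AnalysisParams)}
    for k, v in data.items():
        if k not in valid:
            raise FormatError(f"unknown analysis parameter: {k}")
        if isinstance(v, list):
            v = tuple(v)
        setattr(params, k, v)
    return params
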