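"""Synthetic behaving-session generator with ground truth.

Generates choice-task and fixation-task session bundles whose statistical
structure matches what the downstream analyses assume: three functional
neuron clusters with distinct baseline rates and event-locked gain profiles,
value-dependent saccade reaction times, a scene-dependent rejection-strategy
policy, a shared per-trial latent drive that couples firing rate to RT, and
an injection condition that attenuates event-locked gains, lengthens RTs and
shifts rejections from "return" to "stay".

Model summary
-------------
Each trial carries a latent drive ``g ~ Normal(1, drive_sd^2)``.

* RT: a lognormal draw (per object value) scaled by ``exp(-(g-1))`` and
  normalized to unit mean over g, truncated by redrawing to the response
  window. High drive means fast saccades.
* Spiking: each neuron is an inhomogeneous Poisson process

      rate(t) = b_i * f_trial * max(0, 1 + a_scene*k(t-scene_on)
                                       + a_cond*k(t-target_on))

  where ``k`` is a half-Gaussian rise (sigma 30 ms, onset 80 ms post-event)
  followed by exponential decay (tau 150 ms), ``a_cond`` depends on the
  trial's (laterality, value), and ``f_trial = exp(-s*c_k*(g-1))``
  (mean-normalized) with per-cluster coupling ``c_k`` and drive sensitivity
  ``s``. Negative coupling therefore makes a neuron fire more on trials
  where the saccade is fast, producing the negative rate-RT correlation the
  population analysis is designed to recover; zero coupling decouples the
  neuron from RT entirely.
* Eye traces: 1 kHz, low-pass fixation jitter plus scripted saccades with
  Gaussian velocity profiles (peak well above the 40 deg/s detection
  threshold), with the profile shifted so the threshold crossing lands on
  the scripted onset time.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import (OBJECT_ANGLES, EyeTrace, Session, SpikeTrain, Trial,
                 laterality_of, side_of_angle)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ConfigError",
    "generate_session",
    "generate_spike_train",
    "generate_eye_trace",
    "generate_waveform",
    "apply_injection_effect",
    "default_choice",
    "fixation",
    "injection_pre_post",
    "study_population_configs",
]


class ConfigError(ValueError):
    """Invalid synthetic-session configuration."""


# condition index order used for per-neuron target gains
CONDITIONS = (("contra", "good"), ("contra", "bad"),
              ("ipsi", "good"), ("ipsi", "bad"))

#: per-cluster event-locked gain profiles (dimensionless multipliers on the
#: baseline rate at the kernel peak). Cluster 1: excited by both values,
#: good > bad, contra > ipsi. Cluster 2: excited by good, suppressed by bad.
#: Cluster 3: no scene response, suppressed by both (bad most).
DEFAULT_GAINS = (
    {"scene": 0.40, ("contra", "good"): 0.80, ("contra", "bad"): 0.50,
     ("ipsi", "good"): 0.40, ("ipsi", "bad"): 0.25},
    {"scene": 0.40, ("contra", "good"): 0.70, ("contra", "bad"): -0.40,
     ("ipsi", "good"): 0.50, ("ipsi", "bad"): -0.35},
    {"scene": 0.00, ("contra", "good"): -0.30, ("contra", "bad"): -0.60,
     ("ipsi", "good"): -0.25, ("ipsi", "bad"): -0.50},
)

# printed injection-experiment endpoints used to parameterize the
# perturbation (means, contralateral objects): RT good 193.5 -> 235.1 ms,
# RT bad 281.1 -> 301.9 ms, return 75.9% -> 43.2%, stay 23.9% -> 56.6%
_POST_RT_SHIFT_GOOD = 235.1 - 193.5
_POST_RT_SHIFT_BAD = 301.9 - 281.1
_POST_RETURN_TO_STAY = 0.759 - 0.432
_REFERENCE_GAIN_FACTOR = 0.4  # gain factor at which the printed shifts apply


@dataclass
class SynthConfig:
    """All knobs of the synthetic-session model (defaults = study conditions)."""
    n_neurons_per_cluster: tuple[int, int, int] = (60, 60, 60)
    n_trials: int = 480
    baseline_hz: tuple[float, float, float] = (42.9, 59.2, 58.4)
    gain_profiles: tuple[dict, dict, dict] = DEFAULT_GAINS
    rt_good_ms: tuple[float, float] = (193.5, 35.0)   # mean, SD
    rt_bad_ms: tuple[float, float] = (281.1, 60.0)
    rt_coupling: tuple[float, float, float] = (-0.4, -0.25, 0.0)
    drive_sd: float = 0.15
    drive_sensitivity: float = 5.0
    reject_policy: dict = field(default_factory=lambda: {
        "stable": {"accept": 0.01, "return": 0.69, "stay": 0.25, "other": 0.05},
        "flexible": {"accept": 0.01, "return": 0.82, "stay": 0.12, "other": 0.05},
    })
    contra_return_to_stay: float = 0.0   # policy mass moved return -> stay
    rt_shift_ms: tuple[float, float] = (0.0, 0.0)  # added to good/bad means
    injection_gain_factor: float = 1.0
    fix_break_rate: float = 0.05
    fixation_attenuation: float = 0.3    # scaling of suppressive gains in the fixation task
    baseline_jitter_sd: float = 0.3      # log-scale per-neuron baseline spread
    gain_jitter_sd: float = 0.15         # log-scale per-neuron gain spread
    waveform_t2p_us: tuple[float, float, float] = (280.0, 320.0, 300.0)
    kernel_onset_ms: float = 80.0
    kernel_rise_sigma_ms: float = 30.0
    kernel_decay_tau_ms: float = 150.0
    response_window_ms: float = 400.0
    min_rt_ms: float = 80.0
    include_eye: bool = False
    include_waveforms: bool = True
    eye_jitter_sd: float = 0.1           # degrees
    task: str = "choice"
    monkey_id: str = "M1"
    hemisphere: str = "left"
    injection: str = "none"
    scene_set_id: int = 1
    session_id: str = ""
    seed: int = 0

    def validate(self) -> None:
        if any(b <= 0 for b in self.baseline_hz):
            raise ConfigError("baseline rates must be positive")
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if any(n < 0 for n in self.n_neurons_per_cluster):
            raise ConfigError("neuron counts must be non-negative")
        if not 0 < self.injection_gain_factor <= 1:
            raise ConfigError("injection_gain_factor must be in (0, 1]")
        for grp, row in self.reject_policy.items():
            if any(p < 0 for p in row.values()):
                raise ConfigError(f"negative policy probability in {grp}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ConfigError(f"policy row {grp} does not sum to 1")
        if not 0 <= self.contra_return_to_stay <= 1:
            raise ConfigError("contra_return_to_stay must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""
    cluster_of: dict[str, int]               # neuron_id -> 1..3
    gain_of: dict[str, dict]                 # neuron_id -> jittered gain profile
    coupling_of: dict[str, float]            # neuron_id -> rt coupling
    baseline_of: dict[str, float]            # neuron_id -> true baseline (Hz)
    latent_drive: np.ndarray                 # per trial g
    config: SynthConfig | None = None


# ---------------------------------------------------------------------------
# primitives

def _kernel(dt_s: np.ndarray, onset_s: float, sigma_s: float,
            tau_s: float) -> np.ndarray:
    """Event-locked modulation kernel, peak value 1 at onset + 2 sigma."""
    peak = onset_s + 2.0 * sigma_s
    out = np.zeros_like(dt_s)
    rise = (dt_s >= onset_s) & (dt_s < peak)
    out[rise] = np.exp(-0.5 * ((dt_s[rise] - peak) / sigma_s) ** 2)
    decay = dt_s >= peak
    out[decay] = np.exp(-(dt_s[decay] - peak) / tau_s)
    return out


def generate_spike_train(rate_fn, duration: float,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None,
                         rate_max: float | None = None,
                         neuron_id: str = "n0") -> SpikeTrain:
    """Inhomogeneous-Poisson spike train by thinning.

    ``rate_fn`` maps a vector of times (s) to rates (Hz); it must be
    non-negative and bounded by ``rate_max`` (estimated on a 1-ms grid when
    not given). Counts in any window are Poisson with mean equal to the
    integral of the rate over the window.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rate_max is None:
        grid = np.arange(0.0, duration, 1e-3)
        r = np.asarray(rate_fn(grid), dtype=float)
        if r.size and r.min() < 0:
            raise ValueError("rate function is negative")
        rate_max = float(r.max() * 1.05 + 1e-12) if r.size else 0.0
    if rate_max < 0:
        raise ValueError("rate_max must be non-negative")
    if rate_max == 0:
        return SpikeTrain(neuron_id, np.empty(0))
    n = rng.poisson(rate_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    r = np.asarray(rate_fn(t), dtype=float)
    if r.size and r.min() < 0:
        raise ValueError("rate function is negative")
    if r.size and r.max() > rate_max * (1 + 1e-9):
        raise ValueError("rate function exceeds its stated bound")
    keep = rng.uniform(0.0, rate_max, n) < r
    t = t[keep]
    # 0.1 ms dead time: the spike-sorting resolution of the data model
    # (vectorized; repeat until no near-coincident pairs remain)
    while t.size > 1 and np.any(np.diff(t) < 1e-4):
        t = t[np.concatenate([[True], np.diff(t) >= 1e-4])]
    return SpikeTrain(neuron_id, t)


def generate_waveform(trough_to_peak_us: float,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      sample_rate: float = 40000.0,
                      amplitude_uv: float = 80.0,
                      noise_sd: float = 0.0,
                      duration_us: float = 1200.0) -> np.ndarray:
    """Biphasic spike-waveform template as (time_us, voltage) samples.

    The trough sits at 1/3 of the duration and the positive peak follows at
    the requested trough-to-peak interval; after :func:`standardize_waveform`
    the measured interval matches the request to within one sample at the
    given sampling rate.
    """
    if trough_to_peak_us <= 0:
        raise ValueError("trough_to_peak_us must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    step = 1e6 / sample_rate
    t = np.arange(0.0, duration_us, step)
    t_trough = round((duration_us / 3.0) / step) * step
    t_peak = t_trough + round(trough_to_peak_us / step) * step
    # narrow lobes so the extrema stay at the Gaussian centers
    s_tr, s_pk = 45.0, 90.0
    v = (-np.exp(-0.5 * ((t - t_trough) / s_tr) ** 2)
         + 0.6 * np.exp(-0.5 * ((t - t_peak) / s_pk) ** 2))
    v = amplitude_uv * v
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd * amplitude_uv, v.size)
    return np.column_stack([t, v])


def generate_eye_trace(trials: list[Trial],
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       sample_rate: float = 1000.0,
                       duration: float | None = None,
                       jitter_sd: float = 0.1,
                       return_latency_s: float = 0.25,
                       hold_s: float = 0.4,
                       saccades: list[tuple[float, tuple[float, float]]] | None = None,
                       ) -> EyeTrace:
    """Scripted 1 kHz gaze trace matching each trial's recorded response.

    Fixation is low-pass jitter around (0, 0) whose velocity stays far below
    the 40 deg/s saccade threshold; scripted saccades use Gaussian velocity
    profiles (peak >= 200 deg/s) positioned so the first threshold crossing
    falls on the scripted onset. "return" responses produce an outbound then
    an inbound saccade within the hold window; explicit ``saccades``
    (onset, target position) may be passed instead of trial scripting.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if duration is None:
        last = max((t.target_on for t in trials), default=1.0)
        duration = last + 2.0
    n = int(round(duration * sample_rate)) + 1

    # low-pass fixation jitter: white noise smoothed with a 20 ms Gaussian
    def smooth_noise() -> np.ndarray:
        w = rng.normal(0.0, 1.0, n)
        sig = 0.020 * sample_rate
        half = int(4 * sig)
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sig) ** 2)
        k /= k.sum()
        s = np.convolve(w, k, mode="same")
        sd = s.std() or 1.0
        return s / sd * jitter_sd

    x = smooth_noise()
    y = smooth_noise()

    sac_events: list[tuple[float, tuple[float, float]]] = list(saccades or [])
    if saccades is None:
        for tr in trials:
            if tr.response in (None, "stay") or tr.saccade_on is None:
                continue
            if tr.response in ("accept", "return", "fix_break"):
                dest = tr.object_xy
            elif tr.response == "other":
                a = math.radians(tr.object_angle + 150.0)
                dest = (15.0 * math.cos(a), 15.0 * math.sin(a))
            else:
                continue
            sac_events.append((tr.saccade_on, dest))
            if tr.response == "return":
                sac_events.append((tr.saccade_on + return_latency_s, (0.0, 0.0)))
            elif tr.response == "accept":
                sac_events.append((tr.saccade_on + hold_s + 0.15, (0.0, 0.0)))
            elif tr.response == "other":
                sac_events.append((tr.saccade_on + 0.5, (0.0, 0.0)))
            elif tr.response == "fix_break":
                # trial aborts; fixation re-acquired before the next sequence
                sac_events.append((tr.saccade_on + 0.5, (0.0, 0.0)))
    sac_events.sort(key=lambda e: e[0])

    pos = np.array([0.0, 0.0])
    sigma_s = 0.008  # velocity-profile width
    tgrid = np.arange(n) / sample_rate
    for onset, dest in sac_events:
        delta = np.asarray(dest) - pos
        amp = float(np.hypot(*delta))
        if amp < 1e-9:
            continue
        vpeak = amp / (sigma_s * math.sqrt(2.0 * math.pi))
        # shift the profile so speed crosses 40 deg/s exactly at `onset`
        lead = sigma_s * math.sqrt(2.0 * math.log(max(vpeak, 41.0) / 40.0))
        tc = onset + lead
        lo = max(0, int((tc - 6 * sigma_s) * sample_rate))
        hi = min(n, int((tc + 6 * sigma_s) * sample_rate) + 1)
        if lo >= n:
            continue
        from scipy.stats import norm
        prof = norm.cdf((tgrid[lo:hi] - tc) / sigma_s)
        x[lo:hi] += delta[0] * prof
        y[lo:hi] += delta[1] * prof
        x[hi:] += delta[0]
        y[hi:] += delta[1]
        pos = pos + delta
    return EyeTrace(sample_rate, x, y, 0.0)


# ---------------------------------------------------------------------------
# trial scheduling and behavior

_SCENE_TO_FP_S = 1.0     # background scene shown 1000 ms before FP
_FP_TO_TARGET_S = 0.7    # central fixation 700 ms before target
_POST_TARGET_S = 1.7     # response + hold + feedback + ITI


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    sigma2 = math.log(1.0 + var / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_rt(rng: np.random.Generator, mean: float, sd: float, g: float,
             drive_sd: float, lo: float, hi: float) -> float:
    """Truncated lognormal RT scaled by the (mean-normalized) latent drive."""
    mu, sig = _lognormal_params(mean, sd)
    factor = math.exp(-(g - 1.0) - drive_sd * drive_sd / 2.0)
    for _ in range(50):
        rt = math.exp(rng.normal(mu, sig)) * factor
        if lo < rt < hi:
            return rt
    return min(max(rt, lo + 1.0), hi - 1.0)


def _choice_trials(cfg: SynthConfig, rng: np.random.Generator,
                   g: np.ndarray) -> list[Trial]:
    trials = []
    cursor = 1.0
    # 5 ms guard below the response window so a scripted saccade's threshold
    # crossing cannot digitize past the window edge at 1 kHz
    hi = cfg.response_window_ms - 5.0
    for i in range(cfg.n_trials):
        scene = int(rng.integers(1, 5))
        value = "good" if rng.uniform() < 0.5 else "bad"
        angle = float(OBJECT_ANGLES[rng.integers(0, len(OBJECT_ANGLES))])
        side = side_of_angle(angle)
        lat = laterality_of(side, cfg.hemisphere)
        scene_on = cursor
        fp_on = scene_on + _SCENE_TO_FP_S
        target_on = fp_on + _FP_TO_TARGET_S
        cursor = target_on + _POST_TARGET_S

        if value == "good":
            response = "accept"
        else:
            grp = "stable" if scene in (1, 2) else "flexible"
            row = dict(cfg.reject_policy[grp])
            if lat == "contra" and cfg.contra_return_to_stay > 0:
                moved = min(cfg.contra_return_to_stay, row["return"])
                row["return"] -= moved
                row["stay"] += moved
            keys = ("accept", "return", "stay", "other")
            p = np.array([row[k] for k in keys])
            response = keys[rng.choice(4, p=p / p.sum())]

        saccade_on = rt = None
        if response in ("accept", "return", "other"):
            mean, sd = cfg.rt_good_ms if value == "good" else cfg.rt_bad_ms
            mean = mean + cfg.rt_shift_ms[0 if value == "good" else 1]
            rt = _draw_rt(rng, mean, sd, float(g[i]), cfg.drive_sd,
                          cfg.min_rt_ms, hi)
            saccade_on = target_on + rt / 1e3
        trials.append(Trial(i, scene, scene_on, fp_on, target_on, value,
                            angle, side, lat, response, saccade_on, rt,
                            rewarded=(value == "good" and response == "accept")
                            ).derive(cfg.hemisphere))
    return trials


def _fixation_trials(cfg: SynthConfig, rng: np.random.Generator,
                     g: np.ndarray) -> list[Trial]:
    """Object presentations (2-4 per sequence, 400 ms on / 400 ms ISI) under
    sustained central fixation; each presentation is one Trial row."""
    trials: list[Trial] = []
    cursor = 2.0
    i = 0
    while i < cfg.n_trials:
        seq_len = int(rng.integers(2, 5))
        broke = False
        for _ in range(seq_len):
            if i >= cfg.n_trials or broke:
                break
            target_on = cursor
            value = "good" if rng.uniform() < 0.5 else "bad"
            angle = 0.0 if rng.uniform() < 0.5 else 180.0
            side = side_of_angle(angle)
            lat = laterality_of(side, cfg.hemisphere)
            response, saccade_on, rt = "stay", None, None
            if rng.uniform() < cfg.fix_break_rate:
                response = "fix_break"
                rt = float(np.clip(rng.normal(220.0, 40.0), 120.0, 380.0))
                saccade_on = target_on + rt / 1e3
                broke = True
            trials.append(Trial(i, 1, target_on - _SCENE_TO_FP_S - _FP_TO_TARGET_S,
                                target_on - _FP_TO_TARGET_S, target_on, value,
                                angle, side, lat, response, saccade_on, rt,
                                rewarded=False).derive(cfg.hemisphere))
            cursor += 0.8  # 400 ms object + 400 ms inter-stimulus interval
            i += 1
        cursor += 1.5  # gap between sequences
    return trials


# ---------------------------------------------------------------------------
# session assembly

def _neuron_rate_fn(baseline: float, scene_gain: float,
                    cond_gains: np.ndarray, cfg: SynthConfig,
                    scene_on: np.ndarray, target_on: np.ndarray,
                    cond_idx: np.ndarray, f_trial: np.ndarray):
    """Vectorized rate function for one neuron over the whole session."""
    starts = scene_on - 0.7
    onset = cfg.kernel_onset_ms / 1e3
    sig = cfg.kernel_rise_sigma_ms / 1e3
    tau = cfg.kernel_decay_tau_ms / 1e3

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(starts, t, side="right") - 1
        inside = idx >= 0
        idxc = np.clip(idx, 0, len(starts) - 1)
        ks = _kernel(t - scene_on[idxc], onset, sig, tau)
        kt = _kernel(t - target_on[idxc], onset, sig, tau)
        mod = 1.0 + scene_gain * ks + cond_gains[cond_idx[idxc]] * kt
        f = np.where(inside, f_trial[idxc], 1.0)
        out = baseline * f * np.maximum(mod, 0.0)
        return np.where(inside, out, baseline)

    return rate


def generate_session(config: SynthConfig) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Deterministic: the same config (including seed) yields an identical
    session and ground truth.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_sched = cfg.n_trials
    g = 1.0 + cfg.drive_sd * rng.standard_normal(n_sched)
    if cfg.task == "choice":
        trials = _choice_trials(cfg, rng, g)
    elif cfg.task == "fixation":
        trials = _fixation_trials(cfg, rng, g)
    else:
        raise ConfigError(f"unknown task {cfg.task!r}")
    g = g[:len(trials)]

    scene_on = np.array([t.scene_on for t in trials])
    target_on = np.array([t.target_on for t in trials])
    cond_idx = np.array([CONDITIONS.index((t.laterality, t.object_value))
                         for t in trials])
    duration = float(target_on[-1] + 2.0)

    neurons: list[SpikeTrain] = []
    cluster_of: dict[str, int] = {}
    gain_of: dict[str, dict] = {}
    coupling_of: dict[str, float] = {}
    baseline_of: dict[str, float] = {}

    gf = cfg.injection_gain_factor
    for k in range(3):
        profile = cfg.gain_profiles[k]
        coupling = cfg.rt_coupling[k]
        s = cfg.drive_sensitivity
        kappa = -s * coupling
        f_trial = np.exp(kappa * (g - 1.0) - (kappa * cfg.drive_sd) ** 2 / 2.0)
        for j in range(cfg.n_neurons_per_cluster[k]):
            nid = f"c{k + 1}_{j:03d}"
            b = cfg.baseline_hz[k] * math.exp(
                rng.normal(0.0, cfg.baseline_jitter_sd)
                - cfg.baseline_jitter_sd ** 2 / 2.0)
            jit = math.exp(rng.normal(0.0, cfg.gain_jitter_sd))
            scene_gain = profile["scene"] * jit * gf
            cond = np.array([profile[c] for c in CONDITIONS]) * jit * gf
            if cfg.task == "fixation":
                cond = np.where(cond < 0, cond * cfg.fixation_attenuation, cond)
            rmax = (b * float(f_trial.max())
                    * (1.0 + max(scene_gain, 0.0) + max(float(cond.max()), 0.0))
                    + 1.0)
            fn = _neuron_rate_fn(b, scene_gain, cond, cfg, scene_on,
                                 target_on, cond_idx, f_trial)
            train = generate_spike_train(fn, duration, rng=rng,
                                         rate_max=rmax, neuron_id=nid)
            if cfg.include_waveforms:
                t2p = max(100.0, cfg.waveform_t2p_us[k] + rng.normal(0.0, 30.0))
                train.waveform = generate_waveform(t2p, rng=rng, noise_sd=0.01)
            neurons.append(train)
            cluster_of[nid] = k + 1
            gain_of[nid] = {"scene": scene_gain,
                            **{c: float(v) for c, v in zip(CONDITIONS, cond)}}
            coupling_of[nid] = coupling
            baseline_of[nid] = b

    eye = None
    if cfg.include_eye:
        eye = generate_eye_trace(trials, rng=rng, jitter_sd=cfg.eye_jitter_sd,
                                 duration=duration)

    session = Session(
        session_id=cfg.session_id or f"synth-{cfg.task}-{cfg.seed}",
        monkey_id=cfg.monkey_id, hemisphere=cfg.hemisphere, task=cfg.task,
        injection=cfg.injection,
        injection_time=None if cfg.injection == "none" else 0.0,
        trials=trials, neurons=neurons, eye=eye,
        scene_set_id=cfg.scene_set_id, duration=duration)
    truth = GroundTruth(cluster_of, gain_of, coupling_of, baseline_of, g,
                        copy.deepcopy(cfg))
    return session, truth


def apply_injection_effect(config: SynthConfig) -> SynthConfig:
    """Post-injection configuration: gains attenuated, RTs lengthened,
    contralateral rejections shifted from "return" toward "stay".

    The behavioral shifts are linear in ``1 - factor`` and reproduce the
    printed pre/post endpoint means at the reference factor 0.4; the neural
    effect is a pure multiplicative gain reduction (blocked excitatory
    drive). Fixation-task break rates are untouched. ``factor = 1`` is the
    identity.
    """
    f = config.injection_gain_factor
    if f <= 0:
        raise ConfigError("injection_gain_factor must be positive")
    scale = (1.0 - f) / (1.0 - _REFERENCE_GAIN_FACTOR)
    new = replace(
        config,
        rt_shift_ms=(config.rt_shift_ms[0] + scale * _POST_RT_SHIFT_GOOD,
                     config.rt_shift_ms[1] + scale * _POST_RT_SHIFT_BAD),
        contra_return_to_stay=min(1.0, config.contra_return_to_stay
                                  + scale * _POST_RETURN_TO_STAY),
        injection="antagonist" if f < 1 else config.injection,
    )
    new.reject_policy = copy.deepcopy(config.reject_policy)
    new.gain_profiles = copy.deepcopy(config.gain_profiles)
    return new


# ---------------------------------------------------------------------------
# presets

def default_choice(seed: int = 0, **overrides) -> SynthConfig:
    """The default choice-task session: 180 neurons (60 per cluster),
    480 trials, printed baseline rates."""
    return replace(SynthConfig(), seed=seed, **overrides)


def fixation(seed: int = 0, **overrides) -> SynthConfig:
    """Fixation-task companion session (reactive-inhibition control)."""
    overrides.setdefault("n_trials", 240)
    return replace(SynthConfig(), task="fixation", seed=seed, **overrides)


def injection_pre_post(seed: int = 0, n_sessions: int = 5,
                       monkeys: tuple[str, ...] = ("Cr", "Sp", "Ch"),
                       gain_factor: float = 0.4,
                       n_trials: int = 200,
                       n_neurons_per_cluster: tuple[int, int, int] = (0, 0, 0),
                       ) -> list[dict]:
    """Paired pre/post configs for the injection experiment.

    Returns one record per (monkey, agent, session): 3 monkeys x 5 sessions
    per agent, agents = antagonist and saline. Saline sessions use gain
    factor 1 (no effect). Neuron counts default to zero because the
    experiment's endpoints are behavioral.
    """
    records = []
    base_seed = seed * 1009
    for agent in ("antagonist", "saline"):
        f = gain_factor if agent == "antagonist" else 1.0
        for m_i, monkey in enumerate(monkeys):
            for s_i in range(n_sessions):
                sid = f"{monkey}-{agent}-{s_i}"
                pre = replace(SynthConfig(), monkey_id=monkey,
                              n_trials=n_trials,
                              n_neurons_per_cluster=n_neurons_per_cluster,
                              session_id=sid + "-pre",
                              seed=(base_seed + 7919 * m_i + 13 * s_i
                                    + (0 if agent == "antagonist" else 5000)) % (2**31))
                post = apply_injection_effect(
                    replace(pre, injection_gain_factor=f,
                            session_id=sid + "-post", seed=pre.seed + 1,
                            injection=agent))
                pre_fix = replace(pre, task="fixation", n_trials=120,
                                  session_id=sid + "-pre-fix",
                                  seed=pre.seed + 2)
                post_fix = replace(post, task="fixation", n_trials=120,
                                   session_id=sid + "-post-fix",
                                   seed=pre.seed + 3)
                records.append({"monkey": monkey, "agent": agent,
                                "session": sid, "pre": pre, "post": post,
                                "pre_fix": pre_fix, "post_fix": post_fix})
    return records


def study_population_configs(seed: int = 0,
                             **overrides) -> list[SynthConfig]:
    """Two-monkey recorded-population layout: 111 + 94 task-responsive
    neurons split over the three clusters (58/86/61 in total)."""
    layouts = [("Cr", (31, 47, 33)), ("Sp", (27, 39, 28))]
    return [replace(SynthConfig(), monkey_id=m, n_neurons_per_cluster=npc,
                    hemisphere="left" if i == 0 else "right",
                    session_id=f"{m}-population", seed=seed + i, **overrides)
            for i, (m, npc) in enumerate(layouts)]
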