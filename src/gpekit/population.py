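"""Population-level statistics: the RT-quartile firing-rate correlation and
the proactive-vs-reactive inhibition contrast.

RT-quartile correlation: for each neuron, qualifying trials of one condition
(default: accepted contralateral good objects) are split into four groups by
saccade reaction time; the mean normalized activity 100-300 ms post target is
computed per group, and the Pearson correlation between group order (1 =
fastest) and the four means summarizes the neuron. A Wilcoxon signed-rank
test asks whether the population median correlation differs from zero — a
negative median means stronger activity precedes faster saccades.

Inhibition contrast: per neuron, the mean normalized response to bad objects
rejected by "return" vs "stay" in the choice task is compared with the
response to good/bad objects under the fixation task's reactive-suppression
demand, using a random-intercept-by-neuron mixed model with the
parametric-bootstrap deviance test and Bonferroni post-hoc pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnalysisParams, Session
from .mixed import BootstrapComparison, ModelSpec, parametric_bootstrap_compare, posthoc_pairwise
from .spikes import compute_psth, event_locked_response, smooth_psth, window_mean

__all__ = [
    "RTCorrelationResult",
    "rt_quartile_groups",
    "neuron_rt_correlation",
    "population_rt_correlation",
    "condition_window_means",
    "inhibition_contrast",
]


@dataclass
class RTCorrelationResult:
    per_neuron_r: dict[str, float]
    median_r: float
    wilcoxon_p: float
    window_ms: tuple[float, float]
    condition: tuple[str, str]  # (laterality, value)
    n_neurons: int


def rt_quartile_groups(rts) -> np.ndarray:
    """Quartile group (1..4) per trial, ordered by increasing latency.

    The cut is at the 25/50/75 percentiles implemented as an equal split of
    the stable RT order, so ties keep their original trial order (all-equal
    RTs are filled round-robin into the four groups by that order).
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4:
        raise ValueError("need at least 4 trials to form quartiles")
    order = np.argsort(rts, kind="stable")
    groups = np.empty(rts.size, dtype=int)
    for q, chunk in enumerate(np.array_split(order, 4)):
        groups[chunk] = q + 1
    return groups


def neuron_rt_correlation(z_means_by_group) -> float | None:
    """Pearson r between group order (1..4) and the four z means.

    Returns ``None`` (logged) when the means have zero variance.
    """
    z = np.asarray(z_means_by_group, dtype=float)
    if z.size != 4 or np.any(~np.isfinite(z)):
        raise ValueError("need 4 finite group means")
    if np.ptp(z) == 0:
        warnings.warn("zero-variance group means; correlation undefined")
        return None
    return float(np.corrcoef(np.arange(1, 5), z)[0, 1])


def _wilcoxon_vs_zero(values: np.ndarray) -> float:
    """Two-sided signed-rank p vs 0: exact for n <= 25 (no ties/zeros),
    normal approximation with continuity correction above; zeros dropped."""
    v = values[values != 0.0]
    if v.size == 0:
        return 1.0
    method = "exact" if v.size <= 25 else "approx"
    res = stats.wilcoxon(v, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return float(res.pvalue)


def population_rt_correlation(session: Session,
                              neuron_ids: list[str] | None = None,
                              params: AnalysisParams | None = None,
                              condition: tuple[str, str] = ("contra", "good"),
                              responses: tuple[str, ...] = ("accept", "return"),
                              window_ms: tuple[float, float] | None = None,
                              min_trials: int = 4) -> RTCorrelationResult:
    """RT-quartile correlation for a set of neurons (e.g. one cluster).

    Each neuron needs at least ``min_trials`` qualifying trials (one per
    quartile); at least 5 neurons with a defined correlation are required
    for the population Wilcoxon test.
    """
    params = params or AnalysisParams()
    window_ms = window_ms or params.rt_corr_window_ms
    lat, value = condition
    trials = [t for t in session.trials
              if t.laterality == lat and t.object_value == value
              and t.response in responses and t.rt is not None]
    if neuron_ids is None:
        neuron_ids = [n.neuron_id for n in session.neurons]

    rts = np.array([t.rt for t in trials])
    rs: dict[str, float] = {}
    if rts.size >= min_trials:
        groups = rt_quartile_groups(rts)
        all_events = session.event_times("target", trials)
        events_by_group = {q: session.event_times(
            "target", [t for t, g in zip(trials, groups) if g == q])
            for q in (1, 2, 3, 4)}
        for nid in neuron_ids:
            spikes = session.neuron(nid).spike_times
            # common normalization: baseline mean and SD of the pooled PSTH,
            # so the four group means are comparable on one scale
            pooled = event_locked_response(
                spikes, all_events, params.target_window_ms, params.bin_ms,
                params.smooth_sigma_ms, params.baseline_window_ms,
                params.sd_scope, "target")
            if pooled.degenerate:
                continue
            means = []
            ok = True
            for q in (1, 2, 3, 4):
                ev = events_by_group[q]
                if ev.size == 0:
                    ok = False
                    break
                psth = smooth_psth(compute_psth(
                    spikes, ev, params.target_window_ms, params.bin_ms,
                    "target"), params.smooth_sigma_ms)
                z = (psth.rate - pooled.baseline_mean_hz) / pooled.sd_used
                means.append(float(z[psth.bin_slice(window_ms)].mean()))
            if not ok:
                continue
            r = neuron_rt_correlation(means)
            if r is not None:
                rs[nid] = r
    if len(rs) < 5:
        raise ValueError(f"only {len(rs)} neurons with a defined correlation "
                         "(need >= 5)")
    values = np.array(list(rs.values()))
    return RTCorrelationResult(rs, float(np.median(values)),
                               _wilcoxon_vs_zero(values),
                               tuple(window_ms), condition, len(rs))


# ---------------------------------------------------------------------------
# proactive vs reactive inhibition

def condition_window_means(session: Session, selector,
                           params: AnalysisParams | None = None,
                           window_ms: tuple[float, float] | None = None,
                           neuron_ids: list[str] | None = None) -> dict[str, float]:
    """Per-neuron mean z in the analysis window over trials passing
    ``selector(trial)``.

    Each neuron's condition PSTH is normalized with the baseline mean and SD
    of that neuron's pooled all-trials PSTH (same alignment), so condition
    means computed from different trial counts share one scale and remain
    comparable. Neurons with no trials or a degenerate pooled trace are
    omitted.
    """
    params = params or AnalysisParams()
    window_ms = window_ms or params.feature_window_ms
    events = session.event_times("target",
                                 [t for t in session.trials if selector(t)])
    out: dict[str, float] = {}
    if events.size == 0:
        return out
    all_events = session.event_times("target")
    ids = neuron_ids or [n.neuron_id for n in session.neurons]
    for nid in ids:
        spikes = session.neuron(nid).spike_times
        ref = event_locked_response(
            spikes, all_events, params.target_window_ms, params.bin_ms,
            params.smooth_sigma_ms, params.baseline_window_ms,
            params.sd_scope, "target")
        if ref.degenerate:
            continue
        psth = smooth_psth(compute_psth(spikes, events,
                                        params.target_window_ms,
                                        params.bin_ms, "target"),
                           params.smooth_sigma_ms)
        z = (psth.rate - ref.baseline_mean_hz) / ref.sd_used
        out[nid] = float(z[psth.bin_slice(window_ms)].mean())
    return out


def inhibition_contrast(choice: Session, fixation: Session,
                        labels: dict[str, int],
                        params: AnalysisParams | None = None,
                        window_ms: tuple[float, float] | None = None,
                        B: int = 199, seed: int = 0,
                        lateralities: tuple[str, ...] = ("contra", "ipsi"),
                        ) -> dict[tuple[int, str], dict]:
    """Choice-task rejection (return/stay) vs fixation-task (good/bad)
    normalized responses, per cluster and laterality.

    For each (cluster, laterality) a long table of per-neuron condition
    means feeds a gaussian mixed model ``mean_z ~ condition`` with a random
    intercept per neuron, compared against the intercept-only null by
    parametric bootstrap; Bonferroni pairwise t-tests localize differences.
    Conditions without any trials are skipped with a warning.
    """
    params = params or AnalysisParams()
    window_ms = window_ms or params.feature_window_ms
    shared = [nid for nid in labels
              if any(n.neuron_id == nid for n in choice.neurons)
              and any(n.neuron_id == nid for n in fixation.neurons)]

    results: dict[tuple[int, str], dict] = {}
    for lat in lateralities:
        conds = {
            "choice-return": (choice, lambda t, lat=lat:
                              t.laterality == lat and t.object_value == "bad"
                              and t.response == "return"),
            "choice-stay": (choice, lambda t, lat=lat:
                            t.laterality == lat and t.object_value == "bad"
                            and t.response == "stay"),
            "fixation-good": (fixation, lambda t, lat=lat:
                              t.laterality == lat and t.object_value == "good"
                              and t.response == "stay"),
            "fixation-bad": (fixation, lambda t, lat=lat:
                             t.laterality == lat and t.object_value == "bad"
                             and t.response == "stay"),
        }
        means: dict[str, dict[str, float]] = {}
        for cname, (sess, sel) in conds.items():
            m = condition_window_means(sess, sel, params, window_ms, shared)
            if not m:
                warnings.warn(f"no trials for condition {cname} ({lat}); "
                              "contrast skipped")
            means[cname] = m

        for cluster in sorted(set(labels.values())):
            rows = []
            for cname, m in means.items():
                for nid, v in m.items():
                    if labels.get(nid) == cluster:
                        rows.append({"neuron": nid, "condition": cname,
                                     "mean_z": v})
            df = pd.DataFrame(rows)
            if df.empty or df["condition"].nunique() < 2:
                continue
            full = ModelSpec("mean_z", "gaussian", ["condition"], ["neuron"])
            null = ModelSpec("mean_z", "gaussian", [], ["neuron"])
            comp = parametric_bootstrap_compare(df, full, null, B=B,
                                                seed=seed + cluster)
            post = posthoc_pairwise(df, "condition", "mean_z")
            results[(cluster, lat)] = {"table": df, "bootstrap": comp,
                                       "posthoc": post}
    return results
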