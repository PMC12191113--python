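"""Functional clustering of neurons by their normalized object responses.

Each neuron is summarized by two numbers: its mean Z-transformed firing rate
100-300 ms after onset of contralateral good objects and of contralateral bad
objects (pooled over scenes). k-means partitions this 2-D feature space; the
number of clusters is chosen by repeated random-restart silhouette averaging
(K = 2..6), and the chosen K is validated by a one-way ANOVA over the per-K
silhouette samples with Bonferroni-corrected pairwise t-tests
(alpha = 0.05 / 10 for five candidate K values).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .io import AnalysisParams, Session
from .spikes import event_locked_response, window_mean

__all__ = [
    "FeatureMatrix",
    "ClusterResult",
    "build_features",
    "kmeans",
    "silhouette",
    "select_k",
]


@dataclass
class FeatureMatrix:
    neuron_ids: list[str]
    features: np.ndarray  # n x 2: (contra good, contra bad) mean z
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or len(self.neuron_ids) != self.features.shape[0]:
            raise ValueError("features must be n x d with one row per neuron")
        if np.any(~np.isfinite(self.features)):
            raise ValueError("features contain missing values")


@dataclass
class ClusterResult:
    labels: dict[str, int]            # neuron_id -> 1..K
    k: int
    silhouette_mean: dict[int, float]  # per candidate K
    silhouette_samples: dict[int, np.ndarray]
    anova: tuple[float, float]        # (F, p) across per-K samples
    pairwise: pd.DataFrame
    bonferroni_alpha: float
    seed: int

    def label_array(self, neuron_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[n] for n in neuron_ids])


def build_features(session: Session,
                   params: AnalysisParams | None = None,
                   window_ms: tuple[float, float] | None = None,
                   per_scene: bool = False) -> FeatureMatrix:
    """Per-neuron (contra good, contra bad) mean-z feature rows.

    Trials are pooled across the four scenes by default (``per_scene=True``
    instead yields 8 columns, one pair per scene). Neurons that are
    degenerate (flat PSTH) or lack trials of either condition are excluded
    with a warning.
    """
    params = params or AnalysisParams()
    window_ms = window_ms or params.feature_window_ms

    def condition_events(value: str, scene: int | None) -> np.ndarray:
        trials = [t for t in session.trials
                  if t.laterality == "contra" and t.object_value == value
                  and (scene is None or t.scene == scene)]
        return session.event_times("target", trials)

    scenes = [1, 2, 3, 4] if per_scene else [None]
    events = {(v, s): condition_events(v, s)
              for v in ("good", "bad") for s in scenes}

    ids, rows, excluded = [], [], []
    for n in session.neurons:
        feats = []
        ok = True
        for s in scenes:
            for v in ("good", "bad"):
                ev = events[(v, s)]
                if ev.size == 0:
                    ok = False
                    break
                nr = event_locked_response(
                    n.spike_times, ev, params.target_window_ms,
                    params.bin_ms, params.smooth_sigma_ms,
                    params.baseline_window_ms, params.sd_scope, "target")
                if nr.degenerate:
                    ok = False
                    break
                feats.append(window_mean(nr, window_ms))
            if not ok:
                break
        if ok:
            ids.append(n.neuron_id)
            rows.append(feats)
        else:
            excluded.append(n.neuron_id)
    if excluded:
        warnings.warn(f"{len(excluded)} neuron(s) excluded from features: "
                      + ", ".join(excluded[:5])
                      + ("..." if len(excluded) > 5 else ""))
    return FeatureMatrix(ids, np.array(rows).reshape(len(ids), -1)
                         if ids else np.empty((0, 2)), excluded)


def kmeans(features: np.ndarray, k: int, seed: int | None = None,
           n_init: int = 10) -> tuple[np.ndarray, float]:
    """Lloyd k-means with k-means++ seeding, best of ``n_init`` restarts.

    Returns (labels 0..k-1, inertia). Deterministic for a given seed.
    """
    X = np.asarray(features, dtype=float)
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k={k} outside [1, n={X.shape[0]}]")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return km.labels_, float(km.inertia_)


def silhouette(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette values s(i) = (b - a) / max(a, b), Euclidean.

    a = mean intra-cluster distance (excluding self), b = smallest mean
    distance to another cluster; singleton clusters score 0. Values lie in
    [-1, 1] and are invariant to any relabeling of the clusters.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return silhouette_samples(X, labels, metric="euclidean")


def _relabel_by_response(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Renumber clusters 1..K by descending mean response over both
    conditions, so "Cluster 1/2/3" is reproducible across runs (cluster 1 =
    excited by both values, cluster 3 = suppressed by both)."""
    ks = np.unique(labels)
    means = {k: X[labels == k].mean() for k in ks}
    order = sorted(ks, key=lambda k: -means[k])
    remap = {k: i + 1 for i, k in enumerate(order)}
    return np.array([remap[k] for k in labels])


def select_k(fm: FeatureMatrix, k_range: range = range(2, 7),
             reps: int = 5000, seed: int = 0,
             alpha: float = 0.05) -> ClusterResult:
    """Silhouette-based choice of K with repeated random-restart k-means.

    For each candidate K, ``reps`` independent single-restart k-means runs
    are scored by their mean silhouette; the K with the highest average wins.
    A one-way ANOVA across the per-K silhouette samples plus all pairwise
    t-tests (Bonferroni: alpha / C(len(k_range), 2), i.e. 0.005 for K=2..6)
    validates the choice. Final labels come from the best-inertia restart at
    the selected K, renumbered by descending contra-good response.
    """
    X = fm.features
    n = X.shape[0]
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range {ks} outside [2, n-1={n - 1}]")
    rng = np.random.default_rng(seed)

    sil_samples: dict[int, np.ndarray] = {}
    best_labels: dict[int, tuple[float, np.ndarray]] = {}
    for k in ks:
        vals = np.empty(reps)
        best = (np.inf, None)
        for r in range(reps):
            rs = int(rng.integers(0, 2**31 - 1))
            km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(X)
            if np.unique(km.labels_).size < 2:
                vals[r] = 0.0
                continue
            vals[r] = float(silhouette_samples(X, km.labels_).mean())
            if km.inertia_ < best[0]:
                best = (float(km.inertia_), km.labels_.copy())
        sil_samples[k] = vals
        best_labels[k] = best

    means = {k: float(v.mean()) for k, v in sil_samples.items()}
    k_star = max(ks, key=lambda k: means[k])

    groups = [sil_samples[k] for k in ks]
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        anova = (0.0, 1.0)
    else:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # near-identical silhouette samples trip scipy's precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            f, p = stats.f_oneway(*groups)
        anova = (float(f), float(p))

    pairs = list(itertools.combinations(range(len(ks)), 2))
    m = len(pairs)
    bonf = alpha / m
    rows = []
    for i, j in pairs:
        gi, gj = groups[i], groups[j]
        if np.ptp(gi) == 0 and np.ptp(gj) == 0:
            t = 0.0 if gi[0] == gj[0] else np.inf * np.sign(gi[0] - gj[0])
            p = 1.0 if gi[0] == gj[0] else 0.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(gi, gj, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"k_a": ks[i], "k_b": ks[j], "t": t, "p_raw": p,
                     "p_adj": min(1.0, p * m), "significant": p < bonf})
    pairwise = pd.DataFrame(rows)

    labels_arr = best_labels[k_star][1]
    labels_arr = _relabel_by_response(X, labels_arr)
    labels = {nid: int(l) for nid, l in zip(fm.neuron_ids, labels_arr)}
    return ClusterResult(labels, int(k_star), means, sil_samples, anova,
                         pairwise, bonf, seed)
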