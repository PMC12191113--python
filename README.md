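# gpekit

Analysis toolkit for single-unit electrophysiology recorded from the external
segment of the globus pallidus (GPe) of behaving macaques during a sequential
choice task — plus a synthetic-session generator so the entire pipeline is
testable without animal data.

## The scientific problem

The GPe is classically cast as an inhibitory relay of the basal ganglia's
indirect pathway, yet its neurons may both *facilitate* wanted movements and
*proactively suppress* unwanted ones. Testing this requires a task that
separates the two processes: on each trial a background scene (1000 ms) and a
fixation point (700 ms) precede a peripheral object that is either "good"
(rewarded if accepted by a saccade plus a 400 ms hold) or "bad" (correctly
rejected by a brief look-and-return saccade, by staying on fixation, or by
looking elsewhere). A companion fixation task presents the same objects while
the animal must keep fixating, isolating reactive (stimulus-triggered)
inhibition.

`gpekit` implements the complete analysis chain for such sessions:

- **Saccade and response classification** — saccade onset is the first eye
  sample whose 2-point central-difference speed exceeds 40°/s within 400 ms
  of target onset; trials are classified as accept / return / stay / other
  (or fixation-break in the fixation task). RTs are compared with Welch's
  *t*; stay-proportions between stable- and flexible-value scenes with
  Fisher's exact test.
- **PSTH normalization** — 1-ms-bin peristimulus time histograms aligned to
  scene, target, or saccade onset, smoothed with a Gaussian kernel
  (σ = 20 ms), then Z-transformed:
  `z(t) = (r(t) − r̄_baseline) / SD(r)`, with the baseline mean taken over
  the 500 ms before event onset and the SD over the whole aligned trace.
- **Functional clustering** — each neuron is summarized by its mean z in the
  100–300 ms window after contralateral good and bad objects; k-means
  partitions this 2-D space, K is chosen by repeated random-restart
  silhouette averaging (K = 2…6, 5000 restarts per K), and the choice is
  validated by a one-way ANOVA over per-K silhouette samples with Bonferroni
  pairwise tests (α = 0.05/10 = 0.005).
- **RT–activity correlation** — per neuron, trials are split into four RT
  quartiles; the Pearson correlation between quartile order and mean z
  (100–300 ms post-target) is tested at the population level with a Wilcoxon
  signed-rank test against zero. Negative medians mean stronger firing on
  fast-saccade trials.
- **Proactive vs. reactive inhibition** — per-neuron condition means
  (choice-task return/stay rejections vs. fixation-task good/bad objects)
  compared with random-intercept mixed models.
- **Mixed models and the parametric bootstrap** — gaussian and binomial
  random-intercept models fit by maximum likelihood; nested models are
  compared by simulating response vectors from the fitted null, refitting,
  and computing `p = (1 + #{LR* ≥ LR}) / (B + 1)` (B = 10 000 by default).
- **Synthetic sessions** — inhomogeneous-Poisson spike trains with three
  neuron clusters (baseline rates 42.9 / 59.2 / 58.4 Hz), scripted 1 kHz eye
  traces, value-dependent lognormal RTs, a shared latent drive coupling rate
  to RT, and an injection perturbation (gain reduction + RT lengthening +
  return→stay policy shift) with full ground truth for recovery tests.

## Worked example

```python
from gpekit import synth, behavior, cluster, population

cfg = synth.default_choice(seed=1)          # 180 neurons, 480 trials
session, truth = synth.generate_session(cfg)

rt = behavior.rt_table(session)
good = rt.loc[rt.value == "good", "rt"]
bad = rt.loc[rt.value == "bad", "rt"]
t, df, p = behavior.welch_t(good, bad)
print(f"RT good {good.mean():.1f} ms vs bad {bad.mean():.1f} ms "
      f"(Welch t = {t:.1f}, p = {p:.2e})")

fm = cluster.build_features(session)
res = cluster.select_k(fm, reps=100, seed=0)
print(f"selected K = {res.k}; mean silhouette per K:",
      {k: round(v, 3) for k, v in res.silhouette_mean.items()})

c1 = [n for n, k in res.labels.items() if k == 1]
corr = population.population_rt_correlation(session, c1)
print(f"cluster 1: median RT correlation {corr.median_r:.2f} "
      f"(Wilcoxon p = {corr.wilcoxon_p:.1e}, n = {corr.n_neurons})")
```

prints

```
RT good 188.8 ms vs bad 269.5 ms (Welch t = -16.9, p = 1.43e-47)
selected K = 3; mean silhouette per K: {2: 0.69, 3: 0.954, 4: 0.815, 5: 0.692, 6: 0.604}
cluster 1: median RT correlation -0.97 (Wilcoxon p = 1.7e-11, n = 60)
```

Good objects are accepted ~80 ms faster than bad objects are rejected; the
silhouette curve peaks decisively at K = 3, recovering the three generated
clusters; and the facilitation cluster's firing is strongly anticorrelated
with saccade latency, the signature of a drive that speeds movement
initiation.

A CLI wraps the same functions for shell use:
`gpekit simulate|validate|info|behavior|psth|cluster|correlate|contrast|compare`
(see `gpekit --help`).

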