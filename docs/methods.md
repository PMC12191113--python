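# Methods

This note records the models, conventions, and numerical choices behind
`gpekit`, in the order data flow through the pipeline. Everything stated
here is either a definition or a design choice; empirical behavior is
established only by the test suite and `scripts/acceptance.py`.

## Session data model and bundle format

A session is a directory of UTF-8 TSV tables plus a YAML key-value metadata
file (`meta.yaml`): `trials.tsv` (one row per trial), `spikes.tsv`
(long-format `neuron_id`, `time`), optional `waveforms.tsv` and `eye.tsv`.
All stored times are seconds from session start; analysis windows are
milliseconds relative to an aligning event, and the conversion happens in
one place (`gpekit.io`). Floats are written with full `repr` precision and
read back with round-trip parsing, so write→read is the identity; missing
values are empty fields. The format was chosen over binary containers for
diff-ability and zero extra dependencies.

Derived trial fields are recomputed on load: the target's screen side is
the sign of the cosine of its angle (so 0°, 45°, 315° → right; 135°, 180°,
225° → left — the six-location task has no vertical targets), laterality is
"contra" iff side is opposite the recorded hemisphere, and
`rt = (saccade_on − target_on)·1000`. `validate_session` reports every
invariant violation (event ordering, sortedness and 0.1 ms separation of
spikes, spikes within session duration, label vocabularies) without
raising.

## Synthetic sessions

The generator emulates the statistical structure the analyses assume; its
defaults are the study conditions used throughout the tests.

**Trials.** Choice-task timing: scene onset, fixation point 1000 ms later,
target 700 ms after that; trials are spaced 3.4 s apart. Scene (1–4), object
value (good/bad, 1:1) and angle (6 locations) are drawn uniformly. Good
objects are accepted; bad objects are rejected according to a policy over
{accept, return, stay, other} with stay-probability 0.25 in the stable-value
scenes (1–2) and 0.12 in the flexible scenes (3–4), "other" 5%, erroneous
accepts 1%, remainder "return" — matching the dominance of the return
strategy and the scene dependence of staying. Fixation-task sessions present
objects in sequences of 2–4 (400 ms on, 400 ms inter-stimulus), each
presentation one trial row; a configurable fraction (default 5%) breaks
fixation, aborting the sequence.

**Latent drive and RTs.** Each trial carries `g ~ Normal(1, 0.15²)`. RTs
are lognormal with configurable mean/SD per value — defaults mean 193.5 ms
(SD 35) for good, 281.1 ms (SD 60) for bad — multiplied by
`exp(−(g−1))` and normalized to unit mean over g, then truncated by
redrawing to (80 ms, response window − 5 ms). The 5 ms guard keeps a
scripted saccade's threshold crossing inside the 400 ms response window
after 1 kHz digitization. Within-session RT SDs are a modeling choice (the
source endpoints report across-session SDs of means, not trial SDs).

**Spiking.** Each neuron is an inhomogeneous Poisson process generated by
thinning:

    rate(t) = b_i · f_trial · max(0, 1 + a_scene·k(t − t_scene)
                                     + a_cond·k(t − t_target))

`k` is a half-Gaussian rise (σ = 30 ms) starting 80 ms post-event, peaking
at +140 ms, then decaying exponentially (τ = 150 ms) — a parameterized
stand-in for typical visually locked GPe response shapes. Per-cluster
baseline rates default to 42.9 / 59.2 / 58.4 Hz with lognormal per-neuron
jitter (log-SD 0.3, mean-preserving); condition gains `a_cond` (by
laterality × value) encode the three cluster phenotypes: cluster 1 excited
by both values (good > bad, contra > ipsi), cluster 2 excited by good and
suppressed by bad, cluster 3 no scene response and suppressed by both (bad
most). In fixation-task sessions suppressive gains are attenuated (×0.3),
implementing the weaker reactive-inhibition dip. Spikes closer than 0.1 ms
are merged (the data model's sorting resolution; at GPe rates this removes
well under 1% of events).

**Rate–RT coupling.** `f_trial = exp(−s·c_k·(g−1))`, mean-normalized, with
per-cluster coupling `c_k` (defaults −0.4, −0.25, 0) and drive sensitivity
`s = 5`. Because g also shortens RT, negative coupling makes a neuron fire
more on fast-saccade trials (negative rate–RT correlation) and `c_k = 0`
decouples it exactly. The coupling parameter is stated per cluster while RT
is a trial-level quantity; routing both through the shared drive g is the
resolution adopted here (an alternative — conditioning RT on realized spike
counts — was rejected as much harder to control).

**Eye traces.** 1 kHz; fixation is white noise low-passed with a 20 ms
Gaussian and scaled to 0.1° SD, keeping central-difference speeds far below
the 40°/s detection threshold. Saccades use Gaussian velocity profiles
(σ = 8 ms; a 15° amplitude gives ~750°/s peak), with the profile shifted so
the analytic 40°/s crossing lands on the scripted onset. "Return" scripts
an outbound then an inbound saccade 250 ms later; fixation breaks re-acquire
fixation 500 ms after the break.

**Waveforms.** Biphasic templates (negative then positive Gaussian lobes)
sampled at 40 kHz, with per-cluster trough-to-peak defaults 280 / 320 /
300 µs (±30 µs per-neuron jitter) — cluster 1 slightly narrower, matching
the reported subtle waveform difference between functional clusters.

**Injection.** `apply_injection_effect` scales all event-locked gains by a
factor `f ∈ (0, 1]` (blocked excitatory drive as a pure gain reduction) and
shifts behavior linearly in `1 − f`, calibrated so that `f = 0.4` reproduces
the published endpoint means: contralateral good RT 193.5 → 235.1 ms, bad
281.1 → 301.9 ms, and 32.7 percentage points of contralateral rejection mass
moved from "return" to "stay". Fixation-break rates are untouched. The
`injection_pre_post` preset builds 3 monkeys × 5 sessions × {antagonist,
saline}, each with paired pre/post choice- and fixation-task configs;
saline uses `f = 1` (identity).

## Behavior analysis

Saccade onset: first sample with 2-point central-difference speed strictly
above 40°/s within 400 ms of the reference event; no pre-smoothing, no onset
refinement (the operational definition is the threshold crossing itself).
Saccade end: first 5 ms run below threshold; landing position is the 20 ms
mean gaze around 10 ms after the end. Classification: accept = landing
within 4° of the object and no re-entry of the 3° fixation window during the
400 ms hold; return = re-entry before the hold elapses; stay = no saccade;
other = landing outside both windows; a detected saccade landing back inside
the fixation window is treated as a corrective movement (stay). The 3°/4°
radii are conventions, configurable in `AnalysisParams`. RT tables keep only
initial saccades toward the object (accept and return trials). All tests
are two-sided.

## PSTH processing

1-ms, left-closed half-open bins (a spike exactly on an edge counts right;
an epsilon of 10⁻⁶ bin protects this from floating-point cancellation).
Smoothing convolves with a Gaussian truncated at ±4σ and renormalized by
the local kernel mass, so constants are preserved exactly at the edges and
the trace mean is conserved. The Z-transform subtracts the mean rate over
the (−500, 0) ms baseline bins and divides by the SD of the smoothed trace.
"The trace SD" is read as the SD over *all* bins of the aligned window
(default); a baseline-only SD is available via `sd_scope="baseline"`. With
the trace-SD reading, the baseline-window mean of z is exactly zero. Traces
with SD < 10⁻⁹ Hz are flagged degenerate and excluded from downstream
feature matrices with a warning. Default alignment windows: scene
(−500, 800), target (−500, 600), saccade (−500, 400) ms — figure extents are
not standardized, so these are configurable.

Waveform standardization maps the global trough to −1 and the subsequent
maximum to +1 (affine, hence scale- and offset-invariant); trough-to-peak
duration is the index difference over the sampling rate.

## Clustering

Features: per neuron, mean z in the 100–300 ms post-target window for
contralateral good and contralateral bad objects, pooled across scenes
(a per-scene variant is a flag). Note that because each condition's trace is
normalized by its own SD, the features encode response *polarity and shape*
more than raw amplitude — which is exactly what separates the three
phenotypes into distinct corners of the plane.

K selection runs `reps` independent single-restart k-means fits per
candidate K (2–6), scores each restart by its mean silhouette, and picks the
K with the highest average ("repeated-silhouette" reading of the 5000-fold
simulation; a bootstrap-over-neurons alternative is noted but not default).
Validation: one-way ANOVA across the per-K silhouette samples plus all 10
pairwise t-tests at Bonferroni α = 0.005. Final labels come from the
best-inertia restart at the selected K and are renumbered 1..K by descending
mean response over both conditions, making "cluster 1/2/3" reproducible
(cluster 1 = excited by both, cluster 3 = suppressed by both). Euclidean
distances on the raw 2-D features (already in z units; no rescaling).

## RT-quartile correlation

Per neuron and condition (default: accepted contralateral good objects),
trials are split into four equal groups by stable RT order (ties keep trial
order; all-equal RTs fill groups round-robin). Each group's PSTH is
normalized with the baseline mean and SD of the neuron's *pooled*
(all-qualifying-trials) PSTH rather than the group's own trace SD: a
per-group self-normalization would divide out precisely the amplitude
modulation the statistic measures (any pure gain change cancels in
mod/SD), leaving the estimator powerless by construction. The per-neuron
statistic is the Pearson correlation of the four group means against group
order 1–4 (with four equally spaced x-values Spearman and Pearson nearly
coincide); zero-variance means are logged and dropped. The population test
is a two-sided Wilcoxon signed-rank against zero — exact for n ≤ 25, normal
approximation with continuity correction above, zeros dropped.

A null property worth knowing: for a neuron with no coupling, the
correlation of four independent noisy group means is exactly Uniform(−1, 1)
regardless of noise level, so the population median over n neurons has
standard error ≈ 1/(√3·n)·√(3/4)/f(0) ≈ 0.14 at n = 50. Small-population
medians therefore scatter substantially around zero even under a perfect
null.

## Proactive vs. reactive inhibition contrast

Per neuron and laterality, mean z (100–300 ms post object) is computed for
choice-task bad-object rejections split by strategy (return, stay) and for
fixation-task good/bad presentations, using the same pooled per-neuron
normalization as above so conditions with different trial counts share one
scale. Per cluster, a gaussian mixed model `mean_z ~ condition` with a
random intercept per neuron is compared against the intercept-only null by
parametric bootstrap, with Bonferroni pairwise t-tests for localization.
Conditions with no trials are skipped with a warning.

## Mixed models and the parametric bootstrap

Both families use maximum likelihood (not REML — deviances of models with
different fixed effects are compared) and exactly one random-intercept
grouping factor, mirroring the grouping-by-monkey/neuron/session structure
of the analyses; crossed random factors are out of scope and rejected with
a clear error. Fixed effects are categorical factors with treatment coding;
`a*b` expands to main effects plus the pairwise interaction.

*Gaussian:* profiling the variance ratio λ = τ²/σ² gives closed-form GLS
estimates per λ (block-diagonal Woodbury identities on group sums), so the
fit is a 1-D bounded optimization over log λ ∈ [−14, 10] with an explicit
boundary check at τ² = 0. Each fit costs well under a millisecond at the
problem sizes used, which is what makes 10⁵ bootstrap refits feasible.
*Binomial:* logit link, Laplace approximation; for fixed τ² the joint
(β, u) mode is found by penalized IRLS with a Schur complement on the small
fixed-effects block (the fixed effects ride along with the random effects,
as in lme4's Laplace path), and the approximate marginal likelihood —
including the binomial normalizing constant — is optimized over log τ² in
one dimension with warm-started inner iterations.

The bootstrap comparison simulates B response vectors from the fitted null
(*unconditional*: new random intercepts and new observation noise/binomial
outcomes, following the standard parametric-bootstrap formulation), refits
both models reusing the cached design matrices, and reports
`p = (1 + #{LR* ≥ LR_obs}) / (B_ok + 1)`; the +1 keeps Monte-Carlo p-values
strictly positive. Simulated refits that fail are dropped and counted; more
than 1% failures aborts. B defaults to 10 000; calibration checks use
B = 199 to keep runtimes in seconds.

## Problem sizes used by tests and the acceptance script

Cluster recovery: 20 generator seeds of the default session (180 neurons,
480 trials), 100 silhouette restarts per K. RT-correlation recovery: one
coupled session (coupling −0.4, 50 neurons, 400 trials) and 100 uncoupled
seeds. Bootstrap calibration: 200 null replicates of 20 groups × 10
observations at B = 199 (binomial calibration in the unit tests uses 60
replicates of aggregated binomial data). Injection endpoints: 15 antagonist
session pairs of 200 choice trials plus 120 fixation presentations each,
B = 199. These sizes make every run reproducible in minutes on a single
core while leaving each check comfortably powered — except where the null
geometry itself forbids it (the uniform-r property above).

## Known limitations

- The generator's event-locked kernels, RT trial-level SDs, eye-movement
  profiles, and waveform templates are parameterized conveniences, not fits
  to physiology; passing recovery tests demonstrates that the *analysis
  chain* is correct under its assumed statistical structure, not that real
  GPe data look like this.
- Spike trains are (dead-time-corrected) Poisson: no refractory dynamics
  beyond 0.1 ms, no bursting, no slow nonstationarities, no correlated
  noise across neurons beyond the shared drive g.
- The binomial mixed model is a Laplace approximation; with very small
  group counts or extreme probabilities its deviances differ slightly from
  adaptive-quadrature fits.
- One random-intercept factor per model; no random slopes, no crossed
  factors, no Kenward–Roger/Satterthwaite corrections, no Bayesian fits.
- No spike sorting, microsaccade/pupil analysis, or imaging-related
  processing: inputs are assumed to be sorted single units with clean
  event tables.
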