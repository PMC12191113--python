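"""Random-intercept mixed models and the parametric-bootstrap deviance test.

Two families are supported, both fit by maximum likelihood (not REML, since
deviances of models with different fixed effects are compared):

* gaussian: a linear mixed model with a single random-intercept grouping
  factor, fit by profiling the ratio ``lambda = tau^2 / sigma^2`` — the GLS
  estimates and the residual variance have closed forms given lambda, so the
  fit reduces to a 1-D bounded optimization. This makes each fit cheap
  enough for the tens of thousands of refits a parametric bootstrap needs.
* binomial: a logistic random-intercept model fit by Laplace approximation —
  the per-group random effect is profiled out at its conditional mode
  (inner Newton iterations, vectorized over groups) and the marginal
  likelihood is maximized over the fixed effects and log tau.

Model comparison follows the parametric-bootstrap recipe: the observed
statistic is the deviance difference between nested full and null models;
its null distribution is built by simulating response vectors from the
fitted null model (redrawing random intercepts and observation noise /
binomial outcomes — an unconditional bootstrap), refitting both models, and
the Monte-Carlo p-value is ``(1 + #{null >= observed}) / (B + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "MixedFit",
    "BootstrapComparison",
    "FitError",
    "fit_mixed",
    "parametric_bootstrap_compare",
    "posthoc_pairwise",
]


class FitError(RuntimeError):
    """Model could not be fit (singular design or non-convergence)."""


@dataclass
class ModelSpec:
    """Declarative mixed-model description.

    ``fixed`` lists categorical factor names; ``"a:b"`` adds the interaction
    of two factors and ``"a*b"`` expands to both main effects plus the
    interaction. An empty list is the intercept-only (null) model.
    ``random_intercepts`` must name exactly one grouping factor (the models
    in this pipeline group by monkey, neuron, or session — one at a time).
    ``weights`` optionally names a column of binomial trial counts, in which
    case the response column holds success counts.
    """
    response: str
    family: str = "gaussian"
    fixed: list[str] = field(default_factory=list)
    random_intercepts: list[str] = field(default_factory=list)
    weights: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.random_intercepts) != 1:
            raise ValueError(
                "exactly one random-intercept grouping factor is supported "
                f"(got {self.random_intercepts!r})")

    @property
    def group_factor(self) -> str:
        return self.random_intercepts[0]

    def expanded_fixed(self) -> list[str]:
        terms: list[str] = []
        for t in self.fixed:
            if "*" in t:
                a, b = t.split("*")
                for item in (a, b, f"{a}:{b}"):
                    if item not in terms:
                        terms.append(item)
            elif t not in terms:
                terms.append(t)
        return terms


def _dummies(col: pd.Series, name: str) -> pd.DataFrame:
    levels = sorted(pd.unique(col.astype(str)))
    out = {}
    for lev in levels[1:]:  # first level is the reference
        out[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return pd.DataFrame(out, index=col.index)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Intercept + treatment-coded dummies (+ products for interactions)."""
    cols = {"Intercept": pd.Series(1.0, index=data.index)}
    pieces: dict[str, pd.DataFrame] = {}

    def factor_block(name: str) -> pd.DataFrame:
        if name not in pieces:
            if name not in data.columns:
                raise FitError(f"fixed factor {name!r} not in data")
            col = data[name]
            if pd.api.types.is_numeric_dtype(col) and col.nunique() > 8:
                pieces[name] = pd.DataFrame({name: col.astype(float)})
            else:
                pieces[name] = _dummies(col, name)
        return pieces[name]

    for term in spec.expanded_fixed():
        if ":" in term:
            a, b = term.split(":")
            da, db = factor_block(a), factor_block(b)
            for ca in da.columns:
                for cb in db.columns:
                    cols[f"{ca}:{cb}"] = da[ca] * db[cb]
        else:
            for c, s in factor_block(term).items():
                cols[c] = s
    X = pd.DataFrame(cols)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise FitError("singular design matrix; collinear terms among: "
                       + ", ".join(X.columns))
    return X


@dataclass
class MixedFit:
    spec: ModelSpec
    beta: pd.Series
    sigma2: float          # residual variance (gaussian; nan for binomial)
    tau2: float            # random-intercept variance
    loglik: float
    deviance: float
    n_obs: int
    n_groups: int
    converged: bool
    _X: np.ndarray = field(repr=False, default=None)
    _groups: np.ndarray = field(repr=False, default=None)
    _weights: np.ndarray = field(repr=False, default=None)

    def simulate(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a response vector from the fitted model (new random
        intercepts and new observation-level noise/outcomes)."""
        eta = self._X @ self.beta.to_numpy()
        u = rng.normal(0.0, math.sqrt(max(self.tau2, 0.0)), self.n_groups)
        eta = eta + u[self._groups]
        if self.spec.family == "gaussian":
            return eta + rng.normal(0.0, math.sqrt(self.sigma2), eta.size)
        p = 1.0 / (1.0 + np.exp(-eta))
        return rng.binomial(self._weights.astype(int), p).astype(float)


def _group_codes(data: pd.DataFrame, factor: str) -> np.ndarray:
    if factor not in data.columns:
        raise FitError(f"grouping factor {factor!r} not in data")
    codes, uniques = pd.factorize(data[factor], sort=True)
    if len(uniques) < 2:
        raise FitError(f"grouping factor {factor!r} needs >= 2 levels")
    return codes


# ---------------------------------------------------------------------------
# gaussian: profiled ML

def _gaussian_profile(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                      n_groups: int):
    """Return f(log_lambda) -> (-2 loglik, beta, sigma2) using group sums."""
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group sums
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, groups, X)
    Sy = np.zeros(n_groups)
    np.add.at(Sy, groups, y)
    sizes = np.bincount(groups, minlength=n_groups).astype(float)

    def evaluate(log_lam: float):
        lam = math.exp(log_lam)
        w = lam / (1.0 + sizes * lam)          # shrinkage per group
        XtVX = XtX - (Sx * w[:, None]).T @ Sx
        XtVy = Xty - Sx.T @ (w * Sy)
        ytVy = yty - float(w @ (Sy * Sy))
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular GLS system") from exc
        rss = ytVy - 2.0 * float(beta @ XtVy) + float(beta @ XtVX @ beta)
        rss = max(rss, 1e-300)
        sigma2 = rss / n
        logdet = float(np.sum(np.log1p(sizes * lam)))
        m2ll = n * math.log(2.0 * math.pi * sigma2) + logdet + n
        return m2ll, beta, sigma2

    return evaluate


def _fit_gaussian(y, X, groups, n_groups):
    evaluate = _gaussian_profile(y, X, groups, n_groups)
    res = optimize.minimize_scalar(lambda ll: evaluate(ll)[0],
                                   bounds=(-14.0, 10.0), method="bounded",
                                   options={"xatol": 1e-8})
    cands = [(evaluate(res.x)[0], res.x)]
    cands.append((evaluate(-14.0)[0], -14.0))  # boundary: variance -> 0
    m2ll, log_lam = min(cands)
    _, beta, sigma2 = evaluate(log_lam)
    lam = math.exp(log_lam)
    tau2 = 0.0 if log_lam <= -13.9 else lam * sigma2
    return beta, sigma2, tau2, -m2ll / 2.0, True


# ---------------------------------------------------------------------------
# binomial: Laplace ML

def _fit_binomial(y, X, groups, n_groups, m):
    """Laplace ML for the random-intercept logit model.

    For a fixed tau^2, the joint (beta, u) mode is found by penalized IRLS
    (the fixed effects ride along with the random effects, as in lme4's
    Laplace path); the approximate marginal log-likelihood at the mode is
    then optimized over log tau^2 in one dimension.
    """
    n, p = X.shape
    lgamma_const = float(np.sum(special.gammaln(m + 1) - special.gammaln(y + 1)
                                - special.gammaln(m - y + 1)))

    def joint_mode(tau2: float, start):
        beta, u = start
        beta, u = beta.copy(), u.copy()
        for _ in range(80):
            eta = X @ beta + u[groups]
            pr = 1.0 / (1.0 + np.exp(-eta))
            w = np.maximum(m * pr * (1.0 - pr), 1e-12)
            resid = y - m * pr
            g_beta = X.T @ resid
            g_u = np.bincount(groups, weights=resid, minlength=n_groups)
            g_u -= u / tau2
            Xw = X * w[:, None]
            A = Xw.T @ X
            Bmat = np.vstack([np.bincount(groups, weights=Xw[:, j],
                                          minlength=n_groups)
                              for j in range(p)])
            D = np.bincount(groups, weights=w, minlength=n_groups)
            D += 1.0 / tau2
            # Schur complement on the (small) beta block
            B_over_D = Bmat / D
            try:
                d_beta = np.linalg.solve(A - B_over_D @ Bmat.T,
                                         g_beta - B_over_D @ g_u)
            except np.linalg.LinAlgError as exc:
                raise FitError("singular design in binomial fit") from exc
            d_u = (g_u - Bmat.T @ d_beta) / D
            step = max(np.max(np.abs(d_beta)), np.max(np.abs(d_u)))
            scale = min(1.0, 4.0 / step) if step > 4.0 else 1.0
            beta = beta + scale * d_beta
            u = u + scale * d_u
            if step < 1e-9:
                break
        if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(u))):
            raise FitError("binomial Laplace fit diverged")
        return beta, u

    def laplace_ll(tau2: float, beta: np.ndarray, u: np.ndarray) -> float:
        eta = X @ beta + u[groups]
        pr = 1.0 / (1.0 + np.exp(-eta))
        ll_data = float(y @ eta - m @ np.log1p(np.exp(eta))) + lgamma_const
        hess = np.bincount(groups, weights=m * pr * (1.0 - pr),
                           minlength=n_groups)
        hess += 1.0 / tau2
        return (ll_data - float(u @ u) / (2.0 * tau2)
                - 0.5 * float(np.sum(np.log(tau2 * hess))))

    state = {"start": (np.zeros(p), np.zeros(n_groups)), "best": None}

    def objective(log_tau2: float) -> float:
        tau2 = math.exp(log_tau2)
        beta, u = joint_mode(tau2, state["start"])
        state["start"] = (beta, u)  # warm start for the next evaluation
        ll = laplace_ll(tau2, beta, u)
        if state["best"] is None or ll > state["best"][0]:
            state["best"] = (ll, beta, tau2)
        return -ll

    optimize.minimize_scalar(objective, bounds=(-10.0, 6.0),
                             method="bounded", options={"xatol": 1e-3})
    objective(-10.0)  # boundary: variance -> 0
    ll, beta, tau2 = state["best"]
    if math.log(tau2) <= -9.9:
        tau2 = 0.0
    if not np.isfinite(ll):
        raise FitError("binomial Laplace fit did not converge")
    return beta, float("nan"), tau2, float(ll), True


def _prepare(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix, response, group codes, and binomial sizes for a spec."""
    for col in [spec.response, spec.group_factor] + (
            [spec.weights] if spec.weights else []):
        if col not in data.columns:
            raise FitError(f"column {col!r} not in data")
        if data[col].isna().any():
            raise FitError(f"column {col!r} has missing values")
    X = build_design(data, spec)
    y = data[spec.response].to_numpy(dtype=float)
    groups = _group_codes(data, spec.group_factor)
    m = (data[spec.weights].to_numpy(dtype=float)
         if spec.family == "binomial" and spec.weights else np.ones_like(y))
    return X, y, groups, m


def _fit_core(spec: ModelSpec, Xv: np.ndarray, y: np.ndarray,
              groups: np.ndarray, n_groups: int, m: np.ndarray):
    if spec.family == "gaussian":
        return _fit_gaussian(y, Xv, groups, n_groups)
    if np.any(y < 0) or np.any(y > m):
        raise FitError("binomial response outside [0, weights]")
    return _fit_binomial(y, Xv, groups, n_groups, m)


def fit_mixed(data: pd.DataFrame, spec: ModelSpec) -> MixedFit:
    """ML fit of a random-intercept mixed model; deviance = -2 log L."""
    X, y, groups, m = _prepare(data, spec)
    n_groups = int(groups.max()) + 1
    beta, sigma2, tau2, ll, conv = _fit_core(spec, X.to_numpy(), y, groups,
                                             n_groups, m)
    return MixedFit(spec, pd.Series(beta, index=X.columns), sigma2, tau2,
                    ll, -2.0 * ll, len(y), n_groups, conv,
                    _X=X.to_numpy(), _groups=groups, _weights=m)


@dataclass
class BootstrapComparison:
    lr_observed: float
    null_lrs: np.ndarray
    p: float
    B: int
    seed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        assert self.p > 0.0


def parametric_bootstrap_compare(data: pd.DataFrame, full: ModelSpec,
                                 null: ModelSpec, B: int = 10000,
                                 seed: int = 0) -> BootstrapComparison:
    """Deviance-difference test of nested mixed models by parametric bootstrap.

    ``p = (1 + #{simulated LR >= observed LR}) / (B_ok + 1)`` — the +1 keeps
    the Monte-Carlo p strictly positive. Simulated datasets whose refit fails
    are dropped; more than 1% failures aborts.
    """
    null_terms = set(null.expanded_fixed())
    full_terms = set(full.expanded_fixed())
    if not null_terms <= full_terms:
        raise ValueError("null model is not nested in the full model")
    fit_full = fit_mixed(data, full)
    fit_null = fit_mixed(data, null)
    lr_obs = max(0.0, fit_null.deviance - fit_full.deviance)

    # the designs do not depend on the simulated response; prepare them once
    Xf, _, gf, mf = _prepare(data, full)
    Xn, _, gn, mn = _prepare(data, null)
    Xf, Xn = Xf.to_numpy(), Xn.to_numpy()
    n_gf, n_gn = int(gf.max()) + 1, int(gn.max()) + 1

    rng = np.random.default_rng(seed)
    lrs = []
    failed = 0
    for _ in range(B):
        ysim = fit_null.simulate(rng)
        try:
            ll_full = _fit_core(full, Xf, ysim, gf, n_gf, mf)[3]
            ll_null = _fit_core(null, Xn, ysim, gn, n_gn, mn)[3]
        except FitError:
            failed += 1
            continue
        lrs.append(max(0.0, 2.0 * (ll_full - ll_null)))
    if failed > max(1, B // 100):
        raise FitError(f"{failed}/{B} bootstrap refits failed")
    lrs = np.asarray(lrs)
    p = (1.0 + float(np.sum(lrs >= lr_obs))) / (lrs.size + 1.0)
    return BootstrapComparison(lr_obs, lrs, p, int(lrs.size), seed, failed)


def posthoc_pairwise(data: pd.DataFrame, factor: str, response: str,
                     correction: str = "bonferroni") -> pd.DataFrame:
    """All-pairs Welch t-tests on a factor with Bonferroni adjustment.

    Levels with fewer than 2 observations are skipped (and reported with NaN
    statistics). ``p_adj = min(1, p * n_pairs)``.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is implemented")
    levels = sorted(pd.unique(data[factor].astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has < 2 levels")
    groups = {lev: data.loc[data[factor].astype(str) == lev, response]
              .to_numpy(dtype=float) for lev in levels}
    rows = []
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        if ga.size < 2 or gb.size < 2:
            rows.append({"pair": f"{a} vs {b}", "estimate": np.nan,
                         "t": np.nan, "p_adj": np.nan, "skipped": True})
            continue
        if np.ptp(ga) == 0 and np.ptp(gb) == 0:
            t = 0.0 if ga.mean() == gb.mean() else np.inf
            p = 1.0 if ga.mean() == gb.mean() else 0.0
        else:
            res = stats.ttest_ind(ga, gb, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"pair": f"{a} vs {b}",
                     "estimate": float(ga.mean() - gb.mean()),
                     "t": t, "p_adj": min(1.0, p * m), "skipped": False})
    return pd.DataFrame(rows)
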