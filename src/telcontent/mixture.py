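"""Gaussian mixture modeling of cohort ΔT values and the ternary call.

Cohort ΔT values near zero reflect library-preparation and sequencing
noise rather than biology, so the cohort is modeled as a Gaussian mixture
and each candidate model (number of components G, equal or unequal
variance) is scored by the Bayesian information criterion

    BIC = 2·logL − p·ln(n)

with p the number of free parameters; larger is better (the model-based
clustering convention).  Under the selected two-component model a sample
is called

* ``gain``   — it rejects, at significance alpha, the hypothesis of coming
  from the lower-mean component (upper tail), and lies above that boundary
  only;
* ``loss``   — it rejects the higher-mean component (lower tail);
* ``no_change`` — neither rejection.

When the components are so well separated that the two boundaries cross,
samples between them are assigned by maximum posterior probability
(lower component → loss, upper → gain), which preserves the monotone
loss → no_change → gain ordering in ΔT.

The EM fit uses a deterministic quantile-split initialization plus seeded
random restarts, run in a single vectorized batch; the log-likelihood is
non-decreasing across iterations by construction of EM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

_LOG_2PI = np.log(2.0 * np.pi)
VARIANCE_FLOOR = 1e-6

GAIN, LOSS, NO_CHANGE = "gain", "loss", "no_change"


@dataclass
class MixtureFit:
    """A fitted G-component univariate Gaussian mixture, means ascending."""

    n_components: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    variance_model: str  # "equal" | "unequal"
    log_likelihood: float
    n_samples: int
    converged: bool
    seed: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def bic(self) -> float:
        return bic(self)


@dataclass(frozen=True)
class ClassifierConfig:
    """Significance level and tie-breaking rules for the ternary call."""

    alpha: float = 0.01
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    @property
    def z(self) -> float:
        q = 1.0 - (self.alpha / 2.0 if self.two_sided else self.alpha)
        return float(norm.ppf(q))


@dataclass(frozen=True)
class TelomereCall:
    pair_id: str
    delta_t: float
    call: str
    p_vs_lower_component: float
    p_vs_upper_component: float
    gain_boundary: float
    loss_boundary: float


def _validate_input(x: np.ndarray, G: int) -> None:
    if x.ndim != 1:
        raise ValueError("delta_ts must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("delta_ts contain NaN or infinite values")
    if len(x) < 2 * G:
        raise ValueError(f"need at least {2 * G} samples to fit G={G}")
    if G >= 2 and np.ptp(x) == 0.0:
        raise ValueError("all ΔT values identical; a multi-component "
                         "mixture is degenerate")


def _fit_single_gaussian(x: np.ndarray, seed: int) -> MixtureFit:
    # G = 1 has a closed-form maximum-likelihood solution.
    mu = float(np.mean(x))
    var = max(float(np.mean((x - mu) ** 2)), VARIANCE_FLOOR)
    ll = float(np.sum(-0.5 * (_LOG_2PI + np.log(var) + (x - mu) ** 2 / var)))
    return MixtureFit(n_components=1, means=np.array([mu]),
                      variances=np.array([var]), weights=np.array([1.0]),
                      variance_model="equal", log_likelihood=ll,
                      n_samples=len(x), converged=True, seed=seed,
                      loglik_trace=np.array([ll]))


def _initial_params(x: np.ndarray, G: int, n_init: int,
                    rng: np.random.Generator):
    """Quantile-split init plus (n_init - 1) perturbed restarts."""
    n = len(x)
    order = np.sort(x)
    blocks = np.array_split(order, G)
    base_means = np.array([b.mean() for b in blocks])
    base_weights = np.array([len(b) / n for b in blocks])
    var0 = max(float(np.var(x)), VARIANCE_FLOOR)

    means = np.tile(base_means, (n_init, 1))
    weights = np.tile(base_weights, (n_init, 1))
    if n_init > 1:
        jitter = rng.normal(0.0, 0.5 * np.sqrt(var0), size=(n_init - 1, G))
        means[1:] += jitter
        weights[1:] = 1.0 / G
    variances = np.full((n_init, G), var0)
    return means, variances, weights


def fit_mixture(delta_ts: Sequence[float], G: int, variance_model: str = "equal",
                seed: int = 0, tol: float = 1e-8, max_iter: int = 1000,
                n_init: int = 10) -> MixtureFit:
    """EM fit of a G-component univariate Gaussian mixture to ΔT values.

    All ``n_init`` restarts are iterated as one vectorized batch and the
    highest-likelihood solution is returned, components relabeled so the
    means are ascending.  Convergence is a relative log-likelihood change
    below ``tol``.
    """
    if variance_model not in ("equal", "unequal"):
        raise ValueError("variance_model must be 'equal' or 'unequal'")
    x = np.asarray(delta_ts, dtype=float)
    _validate_input(x, G)
    if G == 1:
        return _fit_single_gaussian(x, seed)

    n = len(x)
    rng = np.random.default_rng(seed)
    means, variances, weights = _initial_params(x, G, n_init, rng)
    x2 = x * x
    basis = np.stack([np.ones_like(x), x, x2], axis=1)  # (n, 3) moment basis

    def _posteriors(mu, var, w):
        """Responsibilities and per-restart log-likelihood, batched over R."""
        inv2v = 0.5 / var  # (R, G)
        a = np.log(w) - 0.5 * (_LOG_2PI + np.log(var)) - mu * mu * inv2v
        log_comp = (a[:, None, :] + x[None, :, None] * (2 * mu * inv2v)[:, None, :]
                    - x2[None, :, None] * inv2v[:, None, :])
        m = log_comp.max(axis=2, keepdims=True)
        e = np.exp(log_comp - m)
        s = e.sum(axis=2, keepdims=True)
        ll = (m[..., 0] + np.log(s[..., 0])).sum(axis=1)
        return e / s, ll

    # Converged restarts leave the active batch; stragglers iterate alone.
    final_means = means.copy()
    final_vars = variances.copy()
    final_weights = weights.copy()
    final_ll = np.full(n_init, -np.inf)
    final_conv = np.zeros(n_init, dtype=bool)
    traces: list[list[float]] = [[] for _ in range(n_init)]

    active = np.arange(n_init)
    prev_ll = np.full(n_init, -np.inf)
    for _ in range(max_iter):
        resp, ll = _posteriors(means, variances, weights)
        for r, v in zip(active, ll):
            traces[r].append(float(v))

        # M step: zeroth/first/second weighted moments in one batched matmul
        moments = resp.transpose(0, 2, 1) @ basis  # (R, G, 3)
        nk = np.maximum(moments[..., 0], 1e-12)  # (R, G)
        weights = nk / n
        sum_x = moments[..., 1]
        sum_x2 = moments[..., 2]
        means = sum_x / nk
        ss = sum_x2 - means * sum_x  # sum_i r_ig (x_i - mu_g)^2
        if variance_model == "equal":
            variances = np.maximum(ss.sum(axis=1) / n,
                                   VARIANCE_FLOOR)[:, None].repeat(G, axis=1)
        else:
            variances = np.maximum(ss / nk, VARIANCE_FLOOR)

        with np.errstate(invalid="ignore"):
            rel = np.abs(ll - prev_ll[active]) / (np.abs(prev_ll[active]) + 1e-300)
        prev_ll[active] = ll
        done = rel < tol
        if done.any():
            idx = active[done]
            final_means[idx] = means[done]
            final_vars[idx] = variances[done]
            final_weights[idx] = weights[done]
            final_conv[idx] = True
            keep = ~done
            active, means = active[keep], means[keep]
            variances, weights = variances[keep], weights[keep]
            if len(active) == 0:
                break
    if len(active):
        final_means[active] = means
        final_vars[active] = variances
        final_weights[active] = weights

    # log-likelihood of every restart under its final (post-M-step) parameters
    _, final_ll = _posteriors(final_means, final_vars, final_weights)
    for r, v in enumerate(final_ll):
        traces[r].append(float(v))
    best = int(np.argmax(final_ll))

    order = np.argsort(final_means[best])
    return MixtureFit(
        n_components=G,
        means=final_means[best][order],
        variances=final_vars[best][order],
        weights=final_weights[best][order],
        variance_model=variance_model,
        log_likelihood=float(final_ll[best]),
        n_samples=n,
        converged=bool(final_conv[best]),
        seed=seed,
        loglik_trace=np.array(traces[best]),
    )


def n_free_parameters(G: int, variance_model: str) -> int:
    return (G - 1) + G + (1 if variance_model == "equal" else G)


def bic(fit: MixtureFit) -> float:
    """2·logL − p·ln(n); larger is better."""
    p = n_free_parameters(fit.n_components, fit.variance_model)
    return 2.0 * fit.log_likelihood - p * np.log(fit.n_samples)


def select_model(delta_ts: Sequence[float], G_range: Iterable[int] = range(1, 5),
                 variance_models: Sequence[str] = ("equal", "unequal"),
                 seed: int = 0, **fit_kwargs) -> MixtureFit:
    """Fit the G × variance-model grid and return the highest-BIC fit.

    The grid is scanned in parsimony order (smaller G first, equal
    variance first) with a strict improvement rule, so exact BIC ties
    resolve to the simpler model.  G = 1 is fitted once (the variance
    models coincide).
    """
    best: MixtureFit | None = None
    best_bic = -np.inf
    errors: list[str] = []
    for G in G_range:
        models = ("equal",) if G == 1 else variance_models
        for vm in models:
            try:
                fit = fit_mixture(delta_ts, G, variance_model=vm, seed=seed,
                                  **fit_kwargs)
            except ValueError as exc:
                errors.append(f"G={G} {vm}: {exc}")
                continue
            if fit.bic > best_bic:
                best, best_bic = fit, fit.bic
    if best is None:
        raise RuntimeError("every candidate mixture fit failed: "
                           + "; ".join(errors))
    return best


def classification_boundaries(fit: MixtureFit,
                              config: ClassifierConfig | None = None
                              ) -> tuple[float, float]:
    """(gain_boundary, loss_boundary) from the two component tails.

    gain_boundary = mu_low + z·sigma_low (upper tail of the lower
    component); loss_boundary = mu_high − z·sigma_high.  Identical for
    every sample under one fitted model.
    """
    config = config or ClassifierConfig()
    if fit.n_components != 2:
        raise ValueError("classification requires a two-component fit")
    if fit.variance_model != "equal":
        warnings.warn("classifying under an unequal-variance fit; "
                      "per-component sigmas are used in the boundaries")
    sd = np.sqrt(fit.variances)
    gain_boundary = float(fit.means[0] + config.z * sd[0])
    loss_boundary = float(fit.means[1] - config.z * sd[1])
    return gain_boundary, loss_boundary


def classify(delta_ts: Sequence[float], fit: MixtureFit,
             config: ClassifierConfig | None = None,
             pair_ids: Sequence[str] | None = None) -> list[TelomereCall]:
    """Ternary gain/loss/no_change call for each ΔT under a 2-component fit."""
    config = config or ClassifierConfig()
    gain_b, loss_b = classification_boundaries(fit, config)
    x = np.asarray(delta_ts, dtype=float)
    if pair_ids is None:
        pair_ids = [f"sample_{i}" for i in range(len(x))]
    if len(pair_ids) != len(x):
        raise ValueError("pair_ids and delta_ts length mismatch")

    sd = np.sqrt(fit.variances)
    p_lower = norm.sf(x, loc=fit.means[0], scale=sd[0])  # upper tail, low comp
    p_upper = norm.cdf(x, loc=fit.means[1], scale=sd[1])  # lower tail, high comp
    if config.two_sided:
        p_lower = np.minimum(2 * np.minimum(p_lower, 1 - p_lower), 1.0)
        p_upper = np.minimum(2 * np.minimum(p_upper, 1 - p_upper), 1.0)

    above = x > gain_b
    below = x < loss_b
    both = above & below
    if both.any():
        warnings.warn("component boundaries cross; assigning "
                      f"{int(both.sum())} sample(s) by maximum posterior")
        log_post = (np.log(fit.weights)[None, :]
                    - 0.5 * np.log(fit.variances)[None, :]
                    - 0.5 * (x[:, None] - fit.means[None, :]) ** 2
                    / fit.variances[None, :])
        upper_wins = log_post[:, 1] >= log_post[:, 0]

    calls = []
    for i in range(len(x)):
        if both[i]:
            call = GAIN if upper_wins[i] else LOSS
        elif above[i]:
            call = GAIN
        elif below[i]:
            call = LOSS
        else:
            call = NO_CHANGE
        calls.append(TelomereCall(
            pair_id=str(pair_ids[i]), delta_t=float(x[i]), call=call,
            p_vs_lower_component=float(p_lower[i]),
            p_vs_upper_component=float(p_upper[i]),
            gain_boundary=gain_b, loss_boundary=loss_b))
    return calls


def concordance(calls: Sequence[TelomereCall],
                external: Mapping[str, object], mode: str) -> float:
    """Percent agreement between WGS calls and an external assay.

    ``qpcr`` mode: restricted to WGS gain/loss samples; the external value
    is a log-ratio and agreement means matching sign (gain ↔ positive,
    loss ↔ negative).  ``fish`` mode: WGS gain maps to 'abnormal', loss
    and no_change map to 'normal'; agreement is exact label match.
    """
    if mode not in ("qpcr", "fish"):
        raise ValueError("mode must be 'qpcr' or 'fish'")
    matched = [c for c in calls if c.pair_id in external]
    if not matched:
        raise ValueError("no sample ids shared with the external call set")
    if mode == "qpcr":
        matched = [c for c in matched if c.call in (GAIN, LOSS)]
        if not matched:
            raise ValueError("no gain/loss WGS calls overlap the qPCR set")
        hits = sum(1 for c in matched
                   if (c.call == GAIN) == (float(external[c.pair_id]) > 0)  # type: ignore[arg-type]
                   and float(external[c.pair_id]) != 0)  # type: ignore[arg-type]
    else:
        hits = 0
        for c in matched:
            predicted = "abnormal" if c.call == GAIN else "normal"
            hits += predicted == str(external[c.pair_id]).lower()
    return 100.0 * hits / len(matched)
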