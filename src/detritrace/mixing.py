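"""Bayesian tracer mixing model with posterior-correlation source pooling.

The model explains each mixture sample's tracer values (e.g. d13C, d15N of
a detritus sample) as a convex combination of K source distributions:

    x_ij ~ Normal( sum_k p_k (mu_jk + c_jk),
                   sum_k p_k^2 (sigma_jk^2 + tau_jk^2) + sigma_j^2 )

where p is the source-proportion vector on the K-simplex, (mu_jk, sigma_jk)
are the per-source per-tracer mean and SD, (c_jk, tau_jk) are optional
discrimination (trophic enrichment) offsets, and sigma_j is a per-tracer
residual SD. Priors: p ~ Dirichlet(alpha) (default alpha = 1, uniform on
the simplex) and sigma_j ~ half-normal(scale 1 permil).

Sampling is adaptive random-walk Metropolis on an unconstrained vector:
K-1 additive-log-ratio coordinates for p (a softmax transform with the
last coordinate pinned at zero, so the chain is identifiable) plus log
sigma_j, with the proposal covariance adapted to the empirical posterior
covariance and the step scale tuned toward a target acceptance rate.

When two sources are isotopically indistinguishable the model cannot
separate them: their proportion posteriors become strongly (negatively)
correlated. `pool_correlated_sources` automates the remedy used in
practice — fit, inspect the posterior correlation matrix, merge the most
correlated pair at the raw-sample level, refit — until no pair exceeds
the threshold or only two sources remain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from .isotopes import SourceSummary, pool_source_samples

logger = logging.getLogger(__name__)

_SUMMARY_QUANTILES = (0.025, 0.10, 0.25, 0.50, 0.75, 0.90, 0.975)


@dataclass(frozen=True)
class McmcSettings:
    """Chain length controls. Burn-in is discarded before thinning."""

    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 10
    target_acceptance: float = 0.30

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError(
                f"need iterations > burn_in >= 0, got {self.iterations}, {self.burn_in}"
            )
        if self.thin < 1:
            raise ValueError(f"thin must be >= 1, got {self.thin}")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class MixingModelSpec:
    """Fully parameterized mixing model instance.

    Arrays are (K sources x J tracers) for source parameters and
    (n samples x J tracers) for the mixture matrix, all in permil.
    """

    source_names: Sequence[str]
    mu: np.ndarray
    sigma: np.ndarray
    mixtures: np.ndarray
    disc_mean: np.ndarray | None = None
    disc_sd: np.ndarray | None = None
    alpha: float | np.ndarray = 1.0
    resid_prior_scale: float = 1.0
    tracer_names: Sequence[str] = ("d13c", "d15n")

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        self.mixtures = np.asarray(self.mixtures, dtype=float).reshape(-1, self.mu.shape[1])
        K, J = self.mu.shape
        if K < 2:
            raise ValueError(f"need at least 2 sources, got {K}")
        if len(self.source_names) != K:
            raise ValueError("source_names length must match mu rows")
        if self.sigma.shape != (K, J):
            raise ValueError("sigma shape must match mu")
        if np.any(self.sigma < 0):
            raise ValueError("source SDs must be nonnegative")
        if self.disc_mean is None:
            self.disc_mean = np.zeros((K, J))
        if self.disc_sd is None:
            self.disc_sd = np.zeros((K, J))
        self.disc_mean = np.broadcast_to(np.asarray(self.disc_mean, float), (K, J)).copy()
        self.disc_sd = np.broadcast_to(np.asarray(self.disc_sd, float), (K, J)).copy()
        if np.any(self.disc_sd < 0):
            raise ValueError("discrimination SDs must be nonnegative")
        self.alpha = np.broadcast_to(np.asarray(self.alpha, float), (K,)).copy()
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet concentration must be positive")

    @property
    def n_sources(self) -> int:
        return self.mu.shape[0]

    @property
    def n_tracers(self) -> int:
        return self.mu.shape[1]

    @property
    def n_mixtures(self) -> int:
        return self.mixtures.shape[0]


def spec_from_summaries(
    summaries: Sequence[SourceSummary],
    mixtures: np.ndarray,
    tracers: Sequence[str] = ("d13c", "d15n"),
    **kwargs,
) -> MixingModelSpec:
    """Assemble a model spec from per-source summaries and a mixture matrix."""
    mu = np.array([[s.mean(t) for t in tracers] for s in summaries])
    sigma = np.array([[s.sd(t) for t in tracers] for s in summaries])
    return MixingModelSpec(
        source_names=[s.name for s in summaries],
        mu=mu,
        sigma=sigma,
        mixtures=np.asarray(mixtures, float),
        tracer_names=tuple(tracers),
        **kwargs,
    )


def log_likelihood(spec: MixingModelSpec, p: np.ndarray, resid_sd: np.ndarray) -> float:
    """Log density of the mixture data given proportions and residual SDs.

    Sum over samples i and tracers j of Normal log-pdfs with mean
    sum_k p_k (mu_jk + c_jk) and variance
    sum_k p_k^2 (sigma_jk^2 + tau_jk^2) + sigma_j^2.
    """
    p = np.asarray(p, float)
    resid_sd = np.asarray(resid_sd, float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("p must lie on the simplex")
    if np.any(resid_sd <= 0):
        raise ValueError("residual SDs must be positive")
    mean_j = p @ (spec.mu + spec.disc_mean)
    var_j = (p**2) @ (spec.sigma**2 + spec.disc_sd**2) + resid_sd**2
    if np.any(var_j <= 0):
        raise ValueError("total variance must be positive for every tracer")
    dev = spec.mixtures - mean_j
    return float(np.sum(-0.5 * (dev**2 / var_j + np.log(2 * np.pi * var_j))))


@dataclass
class PosteriorDraws:
    """Retained MCMC draws of source proportions and residual SDs."""

    source_names: list[str]
    tracer_names: list[str]
    p: np.ndarray               # (m, K), each row on the simplex
    resid_sd: np.ndarray        # (m, J)
    log_posterior: np.ndarray   # (m,)
    acceptance_rate: float
    ess: dict[str, float]
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return self.p.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p, columns=[f"p_{s}" for s in self.source_names])
        for j, t in enumerate(self.tracer_names):
            df[f"resid_sd_{t}"] = self.resid_sd[:, j]
        df["log_posterior"] = self.log_posterior
        return df


def _softmax_last_pinned(z: np.ndarray) -> np.ndarray:
    """Map K-1 free coordinates to the K-simplex (softmax, last coord 0)."""
    full = np.concatenate([z, [0.0]])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _log_target(spec: MixingModelSpec, z: np.ndarray, u: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Log posterior in transform space, with the transform Jacobians."""
    p = _softmax_last_pinned(z)
    sd = np.exp(u)
    # Dirichlet(alpha) density plus the simplex-transform log-Jacobian
    # (prod p_k) collapse to sum_k alpha_k log p_k.
    lp = float(np.dot(spec.alpha, np.log(np.maximum(p, 1e-300))))
    # half-normal prior on sd plus log-Jacobian of sd = exp(u).
    lp += float(np.sum(-0.5 * (sd / spec.resid_prior_scale) ** 2 + u))
    if spec.n_mixtures > 0:
        mean_j = p @ spec._mu_eff
        var_j = (p**2) @ spec._var_src + sd**2
        lp += float(
            np.sum(
                -0.5 * (spec._sxx - 2 * mean_j * spec._sx + spec.n_mixtures * mean_j**2) / var_j
                - 0.5 * spec.n_mixtures * np.log(2 * np.pi * var_j)
            )
        )
    return lp, p, sd


def sample_posterior(
    spec: MixingModelSpec,
    settings: McmcSettings = McmcSettings(),
    seed: int | np.random.Generator | None = None,
) -> PosteriorDraws:
    """Draw from the posterior by adaptive random-walk Metropolis.

    The proposal is a joint Gaussian step on (alr(p), log sigma). During the
    run the step scale is tuned toward ``settings.target_acceptance`` with a
    diminishing adaptation schedule, and after an initial window the proposal
    covariance tracks the empirical covariance of the chain (scaled by
    2.38^2/d). Draws are retained after burn-in, every ``thin``-th iteration.
    """
    rng = np.random.default_rng(seed)
    K, J = spec.n_sources, spec.n_tracers
    d = (K - 1) + J

    # Sufficient statistics of the mixture matrix: likelihood cost is O(J)
    # per evaluation regardless of the number of mixture samples.
    spec._mu_eff = spec.mu + spec.disc_mean
    spec._var_src = spec.sigma**2 + spec.disc_sd**2
    spec._sx = spec.mixtures.sum(axis=0)
    spec._sxx = (spec.mixtures**2).sum(axis=0)

    theta = np.zeros(d)
    theta[K - 1:] = np.log(spec.resid_prior_scale * 0.5)
    lp, p, sd = _log_target(spec, theta[: K - 1], theta[K - 1:])
    if not np.isfinite(lp):
        raise ValueError(
            "log posterior not finite at initialization; check that source "
            "variances and mixture values are compatible"
        )

    scale = 2.38 / np.sqrt(d)
    chol = np.eye(d)
    run_mean = theta.copy()
    run_cov = np.eye(d) * 0.01
    accepted = 0
    adapt_start = 200

    m = settings.n_retained
    p_out = np.empty((m, K))
    sd_out = np.empty((m, J))
    lp_out = np.empty(m)
    idx = 0

    for t in range(settings.iterations):
        prop = theta + scale * (chol @ rng.standard_normal(d))
        lp_prop, p_prop, sd_prop = _log_target(spec, prop[: K - 1], prop[K - 1:])
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            theta, lp, p, sd = prop, lp_prop, p_prop, sd_prop
            accepted += 1

        # Diminishing-adaptation updates (Haario-style empirical covariance
        # plus acceptance-rate tuning of the global scale).
        gamma = 1.0 / (t + 10) ** 0.6
        scale *= np.exp(gamma * ((1.0 if accept else 0.0) - settings.target_acceptance))
        delta = theta - run_mean
        run_mean += gamma * delta
        run_cov += gamma * (np.outer(delta, delta) - run_cov)
        if t >= adapt_start and t % 50 == 0:
            try:
                chol = np.linalg.cholesky(run_cov + 1e-9 * np.eye(d))
            except np.linalg.LinAlgError:
                pass

        if t >= settings.burn_in and (t - settings.burn_in) % settings.thin == 0 and idx < m:
            p_out[idx] = p
            sd_out[idx] = sd
            lp_out[idx] = lp
            idx += 1

    acc_rate = accepted / settings.iterations
    ess = {}
    for k, name in enumerate(spec.source_names):
        ess[f"p_{name}"] = float(az.ess(p_out[None, :, k]))
    for j, tname in enumerate(spec.tracer_names):
        ess[f"resid_sd_{tname}"] = float(az.ess(sd_out[None, :, j]))
    low = {k: v for k, v in ess.items() if v < 100}
    if low:
        warnings.warn(
            f"effective sample size below 100 for {sorted(low)}; "
            "consider longer chains",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorDraws(
        source_names=list(spec.source_names),
        tracer_names=list(spec.tracer_names),
        p=p_out[:idx],
        resid_sd=sd_out[:idx],
        log_posterior=lp_out[:idx],
        acceptance_rate=acc_rate,
        ess=ess,
        seed=seed if isinstance(seed, int) else None,
    )


def posterior_summary(draws: PosteriorDraws, min_draws: int = 100) -> pd.DataFrame:
    """Per-source mean, SD and quantiles of the proportion posteriors."""
    if draws.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, got {draws.n_draws}")
    rows = []
    for k, name in enumerate(draws.source_names):
        col = draws.p[:, k]
        row = {"source": name, "mean": col.mean(), "sd": col.std(ddof=1)}
        for q in _SUMMARY_QUANTILES:
            row[f"q{100 * q:g}"] = np.quantile(col, q)
        rows.append(row)
    return pd.DataFrame(rows)


def posterior_correlations(draws: PosteriorDraws, min_draws: int = 100) -> pd.DataFrame:
    """Pearson correlation matrix of the proportion draws.

    A zero-variance source yields undefined (NaN) correlations with all
    others; the diagonal stays 1.
    """
    if draws.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, got {draws.n_draws}")
    K = len(draws.source_names)
    sds = draws.p.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(draws.p, rowvar=False)
    corr = np.atleast_2d(corr)
    for k in np.flatnonzero(sds == 0):
        corr[k, :] = np.nan
        corr[:, k] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(draws.source_names), columns=list(draws.source_names))


@dataclass
class PoolingRound:
    """One iteration of the pooling loop."""

    correlations: pd.DataFrame
    pooled_pair: tuple[str, str] | None
    max_abs_correlation: float
    threshold: float


@dataclass
class PoolingTrace:
    rounds: list[PoolingRound] = field(default_factory=list)
    final_summaries: list[SourceSummary] = field(default_factory=list)

    def describe(self) -> str:
        lines = []
        for i, r in enumerate(self.rounds, start=1):
            if r.pooled_pair:
                lines.append(
                    f"round {i}: max |r| = {r.max_abs_correlation:.3f} "
                    f">= {r.threshold:g}; pooled {r.pooled_pair[0]} + {r.pooled_pair[1]}"
                )
            elif r.max_abs_correlation >= r.threshold:
                lines.append(
                    f"round {i}: max |r| = {r.max_abs_correlation:.3f} "
                    f">= {r.threshold:g} but only two sources remain; stopping"
                )
            else:
                lines.append(
                    f"round {i}: max |r| = {r.max_abs_correlation:.3f} "
                    f"< {r.threshold:g}; no pooling"
                )
        lines.append("final sources: " + ", ".join(s.name for s in self.final_summaries))
        return "\n".join(lines)


def _most_correlated_pair(corr: pd.DataFrame) -> tuple[tuple[str, str], float]:
    """Off-diagonal pair with the largest |r|; lexicographic tie-break."""
    names = sorted(corr.index)
    best_pair, best = None, -np.inf
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r):
                continue
            if abs(r) > best:
                best, best_pair = abs(r), (a, b)
    if best_pair is None:
        raise ValueError("no defined off-diagonal correlations")
    return best_pair, best


def pool_correlated_sources(
    summaries: Sequence[SourceSummary],
    mixtures: np.ndarray,
    threshold: float = 0.6,
    settings: McmcSettings = McmcSettings(),
    seed: int | None = None,
    tracers: Sequence[str] = ("d13c", "d15n"),
    **spec_kwargs,
) -> tuple[PosteriorDraws, PoolingTrace]:
    """Iteratively fit, pool the most correlated source pair, and refit.

    Each round fits the model, computes the posterior correlation matrix of
    the proportions, and — if the largest |r| meets ``threshold`` and more
    than two sources remain — merges that pair at the raw-sample level and
    refits with all other settings unchanged. Ties on |r| break by
    lexicographic source-name order. Terminates when no pair reaches the
    threshold or only two sources remain.
    """
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    current = list(summaries)
    trace = PoolingTrace()
    ss = np.random.SeedSequence(seed)
    round_idx = 0
    while True:
        round_seed = np.random.default_rng(ss.spawn(1)[0]) if seed is None else np.random.default_rng([seed, round_idx])
        spec = spec_from_summaries(current, mixtures, tracers=tracers, **spec_kwargs)
        try:
            draws = sample_posterior(spec, settings, seed=round_seed)
            corr = posterior_correlations(draws)
        except Exception as exc:
            raise RuntimeError(f"pooling round {round_idx + 1} failed: {exc}") from exc
        pair, max_abs = _most_correlated_pair(corr)
        if max_abs >= threshold and len(current) > 2:
            trace.rounds.append(PoolingRound(corr, pair, max_abs, threshold))
            merged = pool_source_samples(current, pair, merged_name=f"{pair[0]}+{pair[1]}")
            current = [s for s in current if s.name not in pair] + [merged]
            logger.info("pooling round %d: merged %s (|r| = %.3f)", round_idx + 1, pair, max_abs)
            round_idx += 1
            continue
        trace.rounds.append(PoolingRound(corr, None, max_abs, threshold))
        trace.final_summaries = current
        return draws, trace
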