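"""Diet-source analysis: mixing-polygon screening and Bayesian mixing model.

Consumers whose isotope values cannot plausibly be produced by any convex
combination of the (TEF-corrected) food sources are first screened out by
a Monte-Carlo mixing-polygon test.  The retained consumers are then fed to
a Bayesian mixing model that estimates the community-level diet proportion
of each source under a flat Dirichlet prior, with the trophic enrichment
factor uncertainty and a residual error term propagated into the
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core_io import (
    InsufficientDataError,
    RunConfig,
    SourceSummary,
    TrophicEnrichment,
    ValidationError,
    logger,
    rng_for,
)
from .niche_metrics import IsoPointSet


@dataclass(frozen=True)
class PolygonTestResult:
    """Per-consumer inclusion probabilities from the mixing-polygon test."""

    inclusion_probability: np.ndarray  # (n_consumers,)
    excluded: np.ndarray               # (n_consumers,) bool
    n_iterations: int
    cutoff: float

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())


@dataclass(frozen=True)
class MixingPosterior:
    """Posterior over diet proportions for one fitted unit (community x period)."""

    source_ids: tuple[str, ...]
    p_draws: np.ndarray          # (n_retained_total, n_sources)
    eps_draws: np.ndarray        # (n_retained_total, 2) residual SD per isotope
    mean: np.ndarray
    median: np.ndarray
    ci95: np.ndarray             # (n_sources, 2)
    rhat: np.ndarray             # split-Rhat per source proportion
    ess: np.ndarray              # effective sample size per source proportion
    converged: bool
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def summary(self) -> dict[str, dict[str, float]]:
        return {
            s: {
                "mean": float(self.mean[i]),
                "median": float(self.median[i]),
                "ci95_low": float(self.ci95[i, 0]),
                "ci95_high": float(self.ci95[i, 1]),
                "rhat": float(self.rhat[i]),
                "ess": float(self.ess[i]),
            }
            for i, s in enumerate(self.source_ids)
        }


def _source_arrays(
    sources: list[SourceSummary], tef: TrophicEnrichment
) -> tuple[np.ndarray, np.ndarray]:
    """TEF-corrected source means and total SDs, shape (n_sources, 2)."""
    mu = np.array(
        [[s.mean_d13C + tef.mean_d13C, s.mean_d15N + tef.mean_d15N] for s in sources]
    )
    sd = np.array(
        [
            [
                np.sqrt(s.sd_d13C**2 + tef.sd_d13C**2),
                np.sqrt(s.sd_d15N**2 + tef.sd_d15N**2),
            ]
            for s in sources
        ]
    )
    return mu, sd


def points_in_hull(points: np.ndarray, vertices: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Boolean inside-test of points against the convex hull of ``vertices``.

    Uses the hull's half-plane representation; boundary points count as
    inside (conservative against excluding consumers that sit exactly on
    the polygon edge).
    """
    hull = ConvexHull(vertices)
    a, b = hull.equations[:, :-1], hull.equations[:, -1]
    return np.all(points @ a.T + b <= tol, axis=1)


def simulate_mixing_polygon(
    sources: list[SourceSummary],
    tef: TrophicEnrichment,
    consumers: IsoPointSet,
    n_iter: int = 10_000,
    cutoff: float = 0.05,
    seed: int = 0,
) -> PolygonTestResult:
    """A-priori Monte-Carlo mixing-polygon screening of consumers.

    Each iteration resamples every TEF-corrected source vertex from
    N(mean_src + mean_tef, sqrt(sd_src^2 + sd_tef^2)) per axis, builds the
    convex hull of the resampled vertices and tests every consumer point
    against it.  A consumer's inclusion probability is the fraction of
    iterations whose polygon contains it; consumers with probability below
    ``cutoff`` (default 0.05, i.e. outside the 95% confidence region of
    the simulated polygon) are flagged for exclusion.
    """
    if len(sources) < 3:
        raise ValidationError("mixing polygon needs >= 3 sources (hull is degenerate)")
    if n_iter < 1000:
        raise ValidationError("n_iter must be >= 1000 for a stable inclusion estimate")
    mu, sd = _source_arrays(sources, tef)
    rng = rng_for(seed, "mixing_polygon")
    pts = consumers.points
    inside_counts = np.zeros(pts.shape[0], dtype=int)
    for _ in range(n_iter):
        verts = rng.normal(mu, sd)
        try:
            inside_counts += points_in_hull(pts, verts)
        except QhullError:  # collinear draw: zero-area polygon contains nothing
            continue
    p = inside_counts / n_iter
    excluded = p < cutoff
    if np.all(inside_counts == 0):
        logger.warning("mixing polygon: no consumer ever inside; all excluded")
    logger.info(
        "simulate_mixing_polygon n_consumers=%d n_iter=%d excluded=%d seed=%d",
        pts.shape[0], n_iter, int(excluded.sum()), seed,
    )
    return PolygonTestResult(
        inclusion_probability=p, excluded=excluded, n_iterations=n_iter, cutoff=cutoff
    )


# -- Bayesian mixing model ---------------------------------------------------


def _alr_inverse(y: np.ndarray) -> np.ndarray:
    """Additive-log-ratio inverse: y in R^(S-1) -> proportions on the simplex."""
    z = np.concatenate([y, [0.0]])
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def _log_posterior(
    y: np.ndarray,
    log_eps: np.ndarray,
    x: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    include_residual: bool,
) -> float:
    p = _alr_inverse(y)
    if np.any(p <= 0):
        return -np.inf
    eps2 = np.exp(2 * log_eps) if include_residual else np.zeros(2)
    m = p @ mu                      # (2,)
    v = (p**2) @ var + eps2         # (2,)
    resid = x - m                   # (n, 2)
    loglik = -0.5 * np.sum(resid**2 / v + np.log(2 * np.pi * v))
    # Dirichlet(1,...,1) prior via the ALR Jacobian: sum(log p)
    logprior = float(np.sum(np.log(p)))
    if include_residual:
        eps = np.exp(log_eps)
        # half-Normal(0, 5) on eps, plus the log-transform Jacobian
        logprior += float(np.sum(-(eps**2) / 50.0 + log_eps))
    return float(loglik) + logprior


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat for one parameter; chains shape (m, n)."""
    m, n = chains.shape
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    k, l = segs.shape
    means = segs.mean(axis=1)
    w = segs.var(axis=1, ddof=1).mean()
    b = l * means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (l - 1) / l * w + b / l
    return float(np.sqrt(var_plus / w))


def _ess(chains: np.ndarray, max_lag: int | None = None) -> float:
    """Autocorrelation-based effective sample size; chains shape (m, n)."""
    m, n = chains.shape
    if max_lag is None:
        max_lag = n - 1
    acf = np.zeros(max_lag + 1)
    for c in chains:
        d = c - c.mean()
        denom = np.sum(d**2)
        if denom <= 0:
            return float(m * n)
        full = np.correlate(d, d, mode="full")[n - 1 :]
        acf += full[: max_lag + 1] / denom
    acf /= m
    # Geyer-style truncation at the first negative autocorrelation
    tau = 1.0
    for t in range(1, max_lag + 1):
        if acf[t] < 0:
            break
        tau += 2 * acf[t]
    return float(m * n / tau)


def fit_mixing_model(
    consumers: IsoPointSet,
    sources: list[SourceSummary],
    tef: TrophicEnrichment,
    cfg: RunConfig | None = None,
    include_residual: bool = True,
    screened: bool = True,
) -> MixingPosterior:
    """Fit the Bayesian diet-mixing model for one consumer point set.

    Likelihood per consumer j and isotope k:

        x_jk ~ Normal( sum_s p_s (mu_sk + f_k),
                       sum_s p_s^2 (sigma_sk^2 + tau_k^2) + eps_k^2 )

    with diet proportions p ~ Dirichlet(1, ..., 1) and a weakly
    informative half-Normal(0, 5) prior on each residual SD eps_k.
    Sampling is adaptive random-walk Metropolis on the additive-log-ratio
    transform of p (plus log eps), run as ``cfg.mcmc.chains`` independent
    chains with the configured iterations / burn-in / thinning schedule.
    Split-Rhat and effective sample size are reported per proportion; a
    non-convergence warning (Rhat > 1.1) is embedded in the result rather
    than raised.
    """
    if len(sources) < 2:
        if len(sources) == 1:
            # degenerate simplex: the single source must explain everything
            draws = np.ones((1, 1))
            return MixingPosterior(
                source_ids=(sources[0].source_id,),
                p_draws=draws,
                eps_draws=np.zeros((1, 2)),
                mean=np.array([1.0]),
                median=np.array([1.0]),
                ci95=np.array([[1.0, 1.0]]),
                rhat=np.array([1.0]),
                ess=np.array([1.0]),
                converged=True,
            )
        raise InsufficientDataError("need >= 1 source")
    if consumers.n < 1:
        raise InsufficientDataError("need >= 1 consumer")
    warnings: list[str] = []
    if not screened:
        warnings.append("polygon screening not applied before fitting")

    cfg = cfg or RunConfig()
    mc = cfg.mcmc
    s_count = len(sources)
    mu, sd = _source_arrays(sources, tef)
    var = sd**2
    x = consumers.points

    dim = (s_count - 1) + (2 if include_residual else 0)
    n_keep = (mc.iterations - mc.burn_in) // mc.thinning
    all_p = np.empty((mc.chains, n_keep, s_count))
    all_eps = np.empty((mc.chains, n_keep, 2))

    for chain in range(mc.chains):
        rng = rng_for(cfg.seed, "mixing_fit", chain)
        theta = np.concatenate(
            [rng.normal(0.0, 0.5, s_count - 1), rng.normal(0.0, 0.3, 2)]
        )[:dim]
        # adaptive Metropolis: scalar step tuning early, then a proposal
        # covariance learned from the burn-in history (handles the ridge
        # geometry of weakly identified many-source simplexes); the
        # proposal is frozen once burn-in ends so the retained chain is a
        # valid Markov chain
        step = 0.2
        prop_chol = np.eye(dim)
        history = np.empty((mc.burn_in, dim))
        lp = _log_posterior(
            theta[: s_count - 1], theta[s_count - 1 :], x, mu, var, include_residual
        )
        accepted_window = 0
        kept = 0
        for it in range(mc.iterations):
            prop = theta + step * (prop_chol @ rng.standard_normal(dim))
            lp_prop = _log_posterior(
                prop[: s_count - 1], prop[s_count - 1 :], x, mu, var, include_residual
            )
            if np.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accepted_window += 1
            if it < mc.burn_in:
                history[it] = theta
                if (it + 1) % 100 == 0:
                    rate = accepted_window / 100
                    if rate > 0.4:
                        step *= 1.25
                    elif rate < 0.2:
                        step /= 1.25
                    accepted_window = 0
                    if it + 1 >= max(200, mc.burn_in // 4):
                        recent = history[(it + 1) // 2 : it + 1]
                        cov = np.cov(recent.T) + 1e-6 * np.eye(dim)
                        prop_chol = np.linalg.cholesky(
                            (2.38**2 / dim) * cov / max(step**2, 1e-12)
                        )
            if it >= mc.burn_in and (it - mc.burn_in) % mc.thinning == 0 and kept < n_keep:
                all_p[chain, kept] = _alr_inverse(theta[: s_count - 1])
                all_eps[chain, kept] = (
                    np.exp(theta[s_count - 1 :]) if include_residual else 0.0
                )
                kept += 1

    p_flat = all_p.reshape(-1, s_count)
    eps_flat = all_eps.reshape(-1, 2)
    rhat = np.array([_split_rhat(all_p[:, :, s]) for s in range(s_count)])
    ess = np.array([_ess(all_p[:, :, s]) for s in range(s_count)])
    converged = bool(np.all(rhat < 1.1))
    if not converged:
        warnings.append(f"non-convergence: max split-Rhat = {rhat.max():.3f} > 1.1")
    logger.info(
        "fit_mixing_model n_consumers=%d n_sources=%d draws=%d max_rhat=%.3f seed=%d",
        consumers.n, s_count, p_flat.shape[0], float(rhat.max()), cfg.seed,
    )
    return MixingPosterior(
        source_ids=tuple(s.source_id for s in sources),
        p_draws=p_flat,
        eps_draws=eps_flat,
        mean=p_flat.mean(axis=0),
        median=np.median(p_flat, axis=0),
        ci95=np.percentile(p_flat, [2.5, 97.5], axis=0).T,
        rhat=rhat,
        ess=ess,
        converged=converged,
        warnings=tuple(warnings),
    )
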