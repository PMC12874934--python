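"""Four-level random-intercept logistic model fitted by MCMC.

Model
-----
For woman *i* in cluster *j*, district *k*, state *l*::

    logit P(Y_ijkl = 1) = beta0 + u_jkl + v_kl + f_l
    u_jkl ~ N(0, sigma2_u0),  v_kl ~ N(0, sigma2_v0),  f_l ~ N(0, sigma2_f0)

There are no covariates and, because the outcome is binary, no free
individual-level variance.  The sampler combines single-site random-walk
Metropolis updates for the intercept and every random effect (residuals at
one level are conditionally independent given the others, so each level is
updated as one vectorised block of independent scalar moves) with conjugate
inverse-gamma Gibbs draws for the three variances.  Proposal scales are
adapted toward a target acceptance rate during burn-in only and frozen
afterwards, so the monitored chain is a valid Markov chain.

Each iteration ends with three exact "recentering sweep" Gibbs moves that
translate mass between adjacent levels (intercept vs. state residuals,
state vs. district, district vs. cluster) while leaving every linear
predictor unchanged.  Without them the partition of variance between
adjacent levels mixes extremely slowly under single-site updates — the
intercept barely moves, state residuals absorb its drift and the state
variance is biased upward at practical chain lengths.  Each sweep is a
conjugate normal draw in the centred parameterisation, so the invariant
distribution is untouched.

Because no covariates enter the model, every woman in a cluster shares the
same linear predictor and the likelihood depends on the data only through
per-cluster totals (women, successes); all updates run on those sufficient
statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .hierarchy import HierarchyError, HierarchyIndex

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ChainState",
    "ChainSamples",
    "PosteriorSummary",
    "VarianceComponents",
    "build_index",
    "initialize_chain",
    "mh_update_scalar",
    "gibbs_variance_draw",
    "run_mcmc",
    "effective_sample_size",
    "summarize_posterior",
    "compute_vpc",
]

_LEVELS = ("state", "district", "cluster")


class InitializationError(ValueError):
    """Degenerate data prevent a sane starting point."""


class DivergenceError(RuntimeError):
    """The chain reached a non-finite state."""


@dataclass(frozen=True)
class ModelConfig:
    """Sampler settings.

    Defaults follow common practice for this model family: a burn-in of
    1,000 cycles, 25,000 monitored iterations, diffuse Inverse-Gamma(0.001,
    0.001) priors on each variance, an (improper) flat prior on the
    intercept, and Robbins-Monro adaptation of the random-walk proposal
    scales toward 44% acceptance during burn-in.  Parameters whose effective
    sample size falls below ``ess_threshold`` are flagged in the summary.
    ``fix_sigma2`` pins named level variances ('cluster', 'district',
    'state') at constants instead of sampling them.
    """

    burn_in: int = 1000
    n_iter: int = 25000
    prior_a: float = 0.001
    prior_b: float = 0.001
    adapt: bool = True
    target_accept: float = 0.44
    thin: int = 1
    seed: int = 0
    ess_threshold: float = 250.0
    fix_sigma2: dict | None = None
    init_proposal_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("burn_in >= 0, n_iter >= 1, thin >= 1 required")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("inverse-gamma prior parameters must be > 0")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.fix_sigma2:
            bad = set(self.fix_sigma2) - set(_LEVELS)
            if bad:
                raise ValueError(f"fix_sigma2 keys must be in {_LEVELS}, got {bad}")


@dataclass
class ChainState:
    """Current values of all model parameters."""

    beta0: float
    u: np.ndarray  # cluster residuals
    v: np.ndarray  # district residuals
    f: np.ndarray  # state residuals
    sigma2_u0: float
    sigma2_v0: float
    sigma2_f0: float


@dataclass
class ChainSamples:
    """Stored monitored draws plus sampler diagnostics."""

    beta0: np.ndarray  # (n_draws,)
    sigma2_u0: np.ndarray
    sigma2_v0: np.ndarray
    sigma2_f0: np.ndarray
    u: np.ndarray  # (n_draws, n_clusters)
    v: np.ndarray
    f: np.ndarray
    acceptance: dict
    proposal_sd: dict
    proposal_sd_monitored: np.ndarray  # (n_draws, 4): beta0, u, v, f scales
    index: HierarchyIndex
    config: ModelConfig

    @property
    def n_draws(self) -> int:
        return int(self.beta0.size)


def build_index(table: pd.DataFrame) -> HierarchyIndex:
    """Validated nesting index from a filtered, crosswalk-assigned table."""
    idx = HierarchyIndex.from_frame(table)
    log.info(
        "hierarchy: %d women, %d clusters, %d districts, %d states",
        idx.n_women,
        idx.n_clusters,
        idx.n_districts,
        idx.n_states,
    )
    return idx


def _cluster_stats(y: np.ndarray, index: HierarchyIndex):
    y = np.asarray(y, dtype=float)
    if y.size != index.n_women:
        raise ValueError("outcome vector length does not match index")
    n_j = np.bincount(index.cluster_of_woman, minlength=index.n_clusters).astype(float)
    k_j = np.bincount(index.cluster_of_woman, weights=y, minlength=index.n_clusters)
    return n_j, k_j


def initialize_chain(y, index: HierarchyIndex, variance_floor: float = 0.01) -> ChainState:
    """Deterministic starting values.

    The intercept starts at the logit of the overall prevalence, residuals
    at zero, and the variances at an empirical-logit decomposition: the
    within-district variance of cluster empirical logits, the within-state
    variance of district means and the variance of state means, each floored
    at ``variance_floor``.  This is a cheap deterministic stand-in for a
    quasi-likelihood pre-fit; starting values only shorten burn-in.
    """
    y = np.asarray(y, dtype=float)
    p = y.mean()
    if p <= 0.0 or p >= 1.0:
        raise InitializationError(
            "all outcomes identical; the intercept is unbounded for degenerate data"
        )
    n_j, k_j = _cluster_stats(y, index)
    lj = logit((k_j + 0.5) / (n_j + 1.0))

    cd = index.district_of_cluster
    ds = index.state_of_district
    d_mean = np.bincount(cd, weights=lj) / np.bincount(cd)
    s_mean = np.bincount(ds, weights=d_mean) / np.bincount(ds)
    s2u = float(np.var(lj - d_mean[cd]))
    s2v = float(np.var(d_mean - s_mean[ds]))
    s2f = float(np.var(s_mean - s_mean.mean()))
    return ChainState(
        beta0=float(logit(p)),
        u=np.zeros(index.n_clusters),
        v=np.zeros(index.n_districts),
        f=np.zeros(index.n_states),
        sigma2_u0=max(s2u, variance_floor),
        sigma2_v0=max(s2v, variance_floor),
        sigma2_f0=max(s2f, variance_floor),
    )


def mh_update_scalar(current: float, log_target, proposal_sd: float, rng: np.random.Generator):
    """One random-walk Metropolis step for a scalar parameter.

    Proposes ``N(current, proposal_sd^2)`` and accepts with probability
    ``min(1, exp(log_target(new) - log_target(current)))``.  Returns
    ``(value, accepted)``.
    """
    lp0 = log_target(current)
    if not np.isfinite(lp0):
        raise DivergenceError("log target is non-finite at the current value")
    prop = current + proposal_sd * rng.standard_normal()
    lp1 = log_target(prop)
    if np.log(rng.random()) < lp1 - lp0:
        return prop, True
    return current, False


def gibbs_variance_draw(residuals, prior_a: float, prior_b: float, rng: np.random.Generator) -> float:
    """Conjugate draw of a normal variance given zero-mean residuals.

    The full conditional is Inverse-Gamma(prior_a + n/2,
    prior_b + sum(r^2)/2).
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 1:
        raise ValueError("need at least one residual")
    shape = prior_a + r.size / 2.0
    scale = prior_b + float(r @ r) / 2.0
    return float(scale / rng.gamma(shape))


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def run_mcmc(y, index: HierarchyIndex, cfg: ModelConfig) -> ChainSamples:
    """Run the sampler and store every post-burn-in (thinned) draw.

    Per iteration: Metropolis update of the intercept, then of every
    cluster, district and state residual (each level as a vectorised block
    of independent scalar moves, using the binomial likelihood over the
    unit's descendants plus the normal prior), then Gibbs updates of the
    three variances.  Proposal scales adapt during burn-in only.
    Bit-reproducible under ``cfg.seed``.
    """
    n_j, k_j = _cluster_stats(y, index)
    state = initialize_chain(y, index)
    fixed = dict(cfg.fix_sigma2 or {})
    if "cluster" in fixed:
        state.sigma2_u0 = float(fixed["cluster"])
    if "district" in fixed:
        state.sigma2_v0 = float(fixed["district"])
    if "state" in fixed:
        state.sigma2_f0 = float(fixed["state"])

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    cd = index.district_of_cluster
    sc = index.state_of_cluster
    ds = index.state_of_district
    C, D, S = index.n_clusters, index.n_districts, index.n_states
    nd_per_state = np.bincount(ds, minlength=S).astype(float)
    nc_per_district = np.bincount(cd, minlength=D).astype(float)

    beta0 = state.beta0
    u, v, f = state.u.copy(), state.v.copy(), state.f.copy()
    s2u, s2v, s2f = state.sigma2_u0, state.sigma2_v0, state.sigma2_f0

    # per-cluster linear predictor and binomial log-likelihood
    eta = beta0 + u + v[cd] + f[sc]
    ll = k_j * eta - n_j * _log1pexp(eta)

    log_sd = {name: np.log(cfg.init_proposal_sd) for name in ("beta0", "u", "v", "f")}
    acc_count = {name: 0.0 for name in log_sd}
    acc_total = {name: 0.0 for name in log_sd}

    n_store = cfg.n_iter // cfg.thin
    store = {
        "beta0": np.empty(n_store),
        "s2u": np.empty(n_store),
        "s2v": np.empty(n_store),
        "s2f": np.empty(n_store),
        "u": np.empty((n_store, C)),
        "v": np.empty((n_store, D)),
        "f": np.empty((n_store, S)),
        "sd": np.empty((n_store, 4)),
    }
    stored = 0

    total = cfg.burn_in + cfg.n_iter
    for it in range(total):
        in_burn = it < cfg.burn_in

        # ---- intercept (flat prior) --------------------------------------
        delta = np.exp(log_sd["beta0"]) * rng.standard_normal()
        eta_p = eta + delta
        ll_p = k_j * eta_p - n_j * _log1pexp(eta_p)
        acc = np.log(rng.random()) < ll_p.sum() - ll.sum()
        if acc:
            beta0 += delta
            eta, ll = eta_p, ll_p
        a_beta = float(acc)

        # ---- cluster residuals (independent given the rest) --------------
        z = np.exp(log_sd["u"]) * rng.standard_normal(C)
        eta_p = eta + z
        ll_p = k_j * eta_p - n_j * _log1pexp(eta_p)
        u_p = u + z
        d_lp = (ll_p - ll) + (u * u - u_p * u_p) / (2.0 * s2u)
        accept = np.log(rng.random(C)) < d_lp
        u = np.where(accept, u_p, u)
        eta = np.where(accept, eta_p, eta)
        ll = np.where(accept, ll_p, ll)
        a_u = float(accept.mean())

        # ---- district residuals ------------------------------------------
        z = np.exp(log_sd["v"]) * rng.standard_normal(D)
        eta_p = eta + z[cd]
        ll_p = k_j * eta_p - n_j * _log1pexp(eta_p)
        v_p = v + z
        d_lp = np.bincount(cd, weights=ll_p - ll, minlength=D)
        d_lp += (v * v - v_p * v_p) / (2.0 * s2v)
        accept = np.log(rng.random(D)) < d_lp
        v = np.where(accept, v_p, v)
        acc_c = accept[cd]
        eta = np.where(acc_c, eta_p, eta)
        ll = np.where(acc_c, ll_p, ll)
        a_v = float(accept.mean())

        # ---- state residuals ---------------------------------------------
        z = np.exp(log_sd["f"]) * rng.standard_normal(S)
        eta_p = eta + z[sc]
        ll_p = k_j * eta_p - n_j * _log1pexp(eta_p)
        f_p = f + z
        d_lp = np.bincount(sc, weights=ll_p - ll, minlength=S)
        d_lp += (f * f - f_p * f_p) / (2.0 * s2f)
        accept = np.log(rng.random(S)) < d_lp
        f = np.where(accept, f_p, f)
        acc_c = accept[sc]
        eta = np.where(acc_c, eta_p, eta)
        ll = np.where(acc_c, ll_p, ll)
        a_f = float(accept.mean())

        # ---- recentering sweeps (exact Gibbs, likelihood-invariant) ------
        # intercept <-> states: beta0 | {beta0 + f_l} is N(mean, s2f/S)
        # under the flat intercept prior
        g = beta0 + f
        beta0_new = g.mean() + np.sqrt(s2f / S) * rng.standard_normal()
        f = g - beta0_new
        beta0 = float(beta0_new)
        # states <-> districts: f_l | {f_l + v_k} with prior N(0, s2f)
        h = f[ds] + v
        prec = 1.0 / s2f + nd_per_state / s2v
        mean = (np.bincount(ds, weights=h, minlength=S) / s2v) / prec
        f = mean + rng.standard_normal(S) / np.sqrt(prec)
        v = h - f[ds]
        # districts <-> clusters: v_k | {v_k + u_j} with prior N(0, s2v)
        h = v[cd] + u
        prec = 1.0 / s2v + nc_per_district / s2u
        mean = (np.bincount(cd, weights=h, minlength=D) / s2u) / prec
        v = mean + rng.standard_normal(D) / np.sqrt(prec)
        u = h - v[cd]

        # ---- variances (conjugate Gibbs unless pinned) -------------------
        if "cluster" not in fixed:
            s2u = gibbs_variance_draw(u, cfg.prior_a, cfg.prior_b, rng)
        if "district" not in fixed:
            s2v = gibbs_variance_draw(v, cfg.prior_a, cfg.prior_b, rng)
        if "state" not in fixed:
            s2f = gibbs_variance_draw(f, cfg.prior_a, cfg.prior_b, rng)

        if not np.isfinite(beta0) or not np.all(np.isfinite(ll)):
            raise DivergenceError(f"non-finite state at iteration {it}")

        # ---- adaptation: burn-in only ------------------------------------
        rates = {"beta0": a_beta, "u": a_u, "v": a_v, "f": a_f}
        if cfg.adapt and in_burn:
            step = min(0.1, 1.0 / np.sqrt(it + 1.0))
            for name, rate in rates.items():
                log_sd[name] += step * (rate - cfg.target_accept)
        if not in_burn:
            for name, rate in rates.items():
                acc_count[name] += rate
                acc_total[name] += 1.0
            m = it - cfg.burn_in
            if (m + 1) % cfg.thin == 0:
                store["beta0"][stored] = beta0
                store["s2u"][stored] = s2u
                store["s2v"][stored] = s2v
                store["s2f"][stored] = s2f
                store["u"][stored] = u
                store["v"][stored] = v
                store["f"][stored] = f
                store["sd"][stored] = [np.exp(log_sd[n]) for n in ("beta0", "u", "v", "f")]
                stored += 1

    acceptance = {n: acc_count[n] / max(acc_total[n], 1.0) for n in acc_count}
    log.debug("acceptance rates: %s", acceptance)
    return ChainSamples(
        beta0=store["beta0"][:stored],
        sigma2_u0=store["s2u"][:stored],
        sigma2_v0=store["s2v"][:stored],
        sigma2_f0=store["s2f"][:stored],
        u=store["u"][:stored],
        v=store["v"][:stored],
        f=store["f"][:stored],
        acceptance=acceptance,
        proposal_sd={n: float(np.exp(log_sd[n])) for n in log_sd},
        proposal_sd_monitored=store["sd"][:stored],
        index=index,
        config=cfg,
    )


def effective_sample_size(series) -> float:
    """ESS of one chain: ``n / (1 + 2*sum(rho_k))`` with the sum truncated
    by Geyer's initial positive sequence (consecutive autocorrelation pairs
    are summed and the sum stops before the first negative pair).

    A constant series carries no information about Monte Carlo error and is
    reported as 0 with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws")
    if np.ptp(x) == 0.0:
        warnings.warn("constant series: ESS undefined, reporting 0", stacklevel=2)
        return 0.0
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    ac = np.fft.irfft(np.abs(np.fft.rfft(xc, nfft)) ** 2)[:n]
    rho = ac / ac[0]

    # Geyer initial positive sequence on pair sums rho[2m] + rho[2m+1]
    n_pairs = n // 2
    pair = rho[: 2 * n_pairs].reshape(n_pairs, 2).sum(axis=1)
    neg = np.flatnonzero(pair <= 0.0)
    stop = neg[0] if neg.size else n_pairs
    tau = -1.0 + 2.0 * pair[:stop].sum()
    tau = max(tau, 1.0 / n)
    return float(n / tau)


def compute_vpc(sigma2_state: float, sigma2_district: float, sigma2_cluster: float):
    """Variance partitioning coefficients, in percent.

    Each level's share of the total geographic random-effect variance:
    ``100 * sigma2_level / (sigma2_state + sigma2_district +
    sigma2_cluster)``.  The individual-level (binary) variance is not part
    of the denominator.  Returns ``(vpc_state, vpc_district, vpc_cluster)``,
    which sum to 100.
    """
    parts = np.asarray([sigma2_state, sigma2_district, sigma2_cluster], dtype=float)
    if np.any(parts < 0):
        raise ValueError("variances must be >= 0")
    total = parts.sum()
    if total == 0:
        raise ValueError("VPC undefined when all variances are zero")
    vpc = 100.0 * parts / total
    return float(vpc[0]), float(vpc[1]), float(vpc[2])


@dataclass(frozen=True)
class VarianceComponents:
    """Posterior summary of the three geographic variances (table layout:
    level, posterior_mean, ci_low, ci_high, vpc_pct, ess)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if abs(self.frame["vpc_pct"].sum() - 100.0) > 1e-9:
            raise ValueError("VPC percentages must sum to 100")

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means, 95% credible intervals and diagnostics."""

    fixed: pd.DataFrame  # row for beta0
    variance_components: VarianceComponents
    u_mean: np.ndarray
    v_mean: np.ndarray
    f_mean: np.ndarray
    low_ess: list

    @property
    def beta0_mean(self) -> float:
        return float(self.fixed.loc[self.fixed["parameter"] == "beta0", "posterior_mean"].iloc[0])


def _mean_ci(draws: np.ndarray):
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi)


def summarize_posterior(samples: ChainSamples, cfg: ModelConfig | None = None) -> PosteriorSummary:
    """Posterior means, percentile 95% credible intervals, VPCs and ESS.

    Parameters with an effective sample size below the configured threshold
    are collected in ``low_ess`` and logged as unreliable.
    """
    cfg = cfg or samples.config
    b_mean, b_lo, b_hi = _mean_ci(samples.beta0)
    b_ess = effective_sample_size(samples.beta0)
    fixed = pd.DataFrame(
        {
            "parameter": ["beta0"],
            "posterior_mean": [b_mean],
            "ci_low": [b_lo],
            "ci_high": [b_hi],
            "ess": [b_ess],
        }
    )

    rows = []
    draws_by_level = {
        "state": samples.sigma2_f0,
        "district": samples.sigma2_v0,
        "cluster": samples.sigma2_u0,
    }
    means = {lvl: _mean_ci(d) for lvl, d in draws_by_level.items()}
    vpc = compute_vpc(means["state"][0], means["district"][0], means["cluster"][0])
    for (lvl, (m, lo, hi)), pct in zip(means.items(), vpc):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = effective_sample_size(draws_by_level[lvl])
        rows.append(
            {
                "level": lvl,
                "posterior_mean": m,
                "ci_low": lo,
                "ci_high": hi,
                "vpc_pct": pct,
                "ess": ess,
            }
        )
    vc = VarianceComponents(frame=pd.DataFrame(rows))

    low = [("beta0", b_ess)] if b_ess < cfg.ess_threshold else []
    fixed_names = set((cfg.fix_sigma2 or {}).keys())
    for row in rows:
        if row["level"] in fixed_names:
            continue
        if row["ess"] < cfg.ess_threshold:
            low.append((f"sigma2_{row['level']}", row["ess"]))
    if low:
        log.warning("parameters with ESS below %.0f: %s", cfg.ess_threshold, low)

    return PosteriorSummary(
        fixed=fixed,
        variance_components=vc,
        u_mean=samples.u.mean(axis=0),
        v_mean=samples.v.mean(axis=0),
        f_mean=samples.f.mean(axis=0),
        low_ess=low,
    )
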