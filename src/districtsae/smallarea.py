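"""Precision-weighted cluster prevalences and district-level aggregation.

Posterior random-effect residuals are pushed through the inverse logit to
give shrunken ("precision-weighted") cluster-level predicted prevalences,

    p_jkl = 100 * expit(beta0 + u_jkl + v_kl + f_l),

which are then averaged (unweighted, by default) within districts.
District 95% credible intervals come from recomputing every cluster
prevalence at each monitored draw, averaging within districts and taking
2.5th/97.5th percentiles of the resulting per-district series.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import ChainSamples, PosteriorSummary

log = logging.getLogger(__name__)

__all__ = [
    "cluster_prevalence",
    "cluster_table",
    "district_prevalence",
    "district_credible_intervals",
    "district_estimates",
    "distribution_summary",
]


def cluster_prevalence(beta0, u, v, f):
    """Predicted prevalence, in percent: ``100 * expit(beta0 + u + v + f)``.

    Accepts scalars or broadcastable arrays; strictly increasing in every
    argument.
    """
    return 100.0 * expit(np.asarray(beta0) + np.asarray(u) + np.asarray(v) + np.asarray(f))


def cluster_table(summary: PosteriorSummary, samples: ChainSamples) -> pd.DataFrame:
    """Plug-in cluster prevalences from posterior-mean residuals."""
    idx = samples.index
    cd = idx.district_of_cluster
    prev = cluster_prevalence(
        summary.beta0_mean, summary.u_mean, summary.v_mean[cd], summary.f_mean[idx.state_of_cluster]
    )
    return pd.DataFrame(
        {
            "cluster_id": idx.cluster_ids,
            "district_id": idx.district_ids[cd],
            "prevalence": prev,
            "n_women": idx.n_women_per_cluster,
        }
    )


def district_prevalence(clusters: pd.DataFrame, weighted: bool = False) -> pd.DataFrame:
    """Average cluster prevalences within each district.

    By default the unweighted arithmetic mean of the district's cluster
    prevalences; ``weighted=True`` weights clusters by their number of
    women instead.  Districts without clusters simply do not appear (they
    are logged by the caller that knows the full geography).
    """
    g = clusters.groupby("district_id", sort=True)
    if weighted:
        prev = g.apply(
            lambda x: np.average(x["prevalence"], weights=x["n_women"]),
            include_groups=False,
        )
    else:
        prev = g["prevalence"].mean()
    out = pd.DataFrame(
        {
            "district_id": prev.index,
            "prevalence": prev.to_numpy(dtype=float),
            "n_clusters": g.size().to_numpy(),
            "n_women": g["n_women"].sum().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def _per_draw_district_means(samples: ChainSamples, chunk: int = 2000) -> np.ndarray:
    """(n_draws, n_districts) matrix of per-draw district mean prevalences."""
    idx = samples.index
    cd = idx.district_of_cluster
    sc = idx.state_of_cluster
    order = np.argsort(cd, kind="stable")
    cd_sorted = cd[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cd_sorted) > 0])
    counts = np.bincount(cd, minlength=idx.n_districts).astype(float)

    out = np.empty((samples.n_draws, idx.n_districts))
    for lo in range(0, samples.n_draws, chunk):
        hi = min(lo + chunk, samples.n_draws)
        eta = (
            samples.beta0[lo:hi, None]
            + samples.u[lo:hi]
            + samples.v[lo:hi][:, cd]
            + samples.f[lo:hi][:, sc]
        )
        prev = 100.0 * expit(eta)
        out[lo:hi] = np.add.reduceat(prev[:, order], starts, axis=1) / counts
    return out


def district_credible_intervals(samples: ChainSamples) -> pd.DataFrame:
    """Per-district 95% credible intervals (and per-draw posterior means).

    Columns: district_id, ci_low, ci_high, prevalence_perdraw.  Bounds are
    percentages, necessarily within [0, 100].
    """
    means = _per_draw_district_means(samples)
    lo, hi = np.percentile(means, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "district_id": samples.index.district_ids,
            "ci_low": lo,
            "ci_high": hi,
            "prevalence_perdraw": means.mean(axis=0),
        }
    )


def district_estimates(
    summary: PosteriorSummary,
    samples: ChainSamples,
    point: str = "plugin",
    weighted: bool = False,
) -> pd.DataFrame:
    """Full district table: point estimate, credible interval, sizes.

    ``point='plugin'`` (default) uses posterior-mean residuals through the
    inverse logit; ``point='perdraw'`` averages the per-draw district
    prevalences instead.  The credible interval always comes from the
    per-draw series, so with the plug-in point estimate the interval need
    not bracket the point exactly.
    """
    if point not in ("plugin", "perdraw"):
        raise ValueError("point must be 'plugin' or 'perdraw'")
    idx = samples.index
    clusters = cluster_table(summary, samples)
    dist = district_prevalence(clusters, weighted=weighted)
    ci = district_credible_intervals(samples)
    out = dist.merge(ci, on="district_id", validate="one_to_one")
    if point == "perdraw":
        out["prevalence"] = out["prevalence_perdraw"]
    state_by_district = pd.DataFrame(
        {
            "district_id": idx.district_ids,
            "state_id": idx.state_ids[idx.state_of_district],
        }
    )
    out = out.merge(state_by_district, on="district_id", validate="one_to_one")
    return out[
        [
            "district_id",
            "state_id",
            "prevalence",
            "ci_low",
            "ci_high",
            "n_clusters",
            "n_women",
            "prevalence_perdraw",
        ]
    ]


def distribution_summary(estimates: pd.DataFrame, threshold: float = 80.0) -> dict:
    """Median, IQR, range and the count of districts below ``threshold``.

    Percentiles use linear interpolation.  The default threshold of 80%
    marks districts with relatively low participation.
    """
    if len(estimates) == 0:
        raise ValueError("no district estimates to summarise")
    p = estimates["prevalence"].to_numpy(dtype=float)
    q25, q50, q75 = np.percentile(p, [25, 50, 75])
    return {
        "n_districts": int(p.size),
        "median": float(q50),
        "iqr": float(q75 - q25),
        "min": float(p.min()),
        "max": float(p.max()),
        "threshold": float(threshold),
        "n_below_threshold": int((p < threshold).sum()),
    }
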