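"""Synthetic four-level household-survey generator.

Emulates the statistical structure of a DHS-style state-module sample of
currently married women aged 15-49: normal random intercepts at the
cluster, district and state levels on the logit scale, Bernoulli
participation outcomes, three correlated decision-domain responses on a
five-category scale, positive sampling weights, a fraction of non-eligible
(not currently married) respondents and a handful of cluster ids that are
absent from the geographic crosswalk.

The composite outcome (participation in any of the three domains) is drawn
directly from ``Bernoulli(expit(beta0 + u + v + f))`` so that the
hierarchical logistic model holds exactly for the outcome the pipeline
analyses; the three domain responses are then generated consistently with
that composite (see :func:`simulate_outcomes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierarchy import HierarchyIndex

__all__ = [
    "SimConfig",
    "SimResult",
    "generate_hierarchy",
    "simulate_outcomes",
    "simulate_survey",
    "inject_ineligibles",
    "flow_fixture",
    "write_fixture",
    "write_crosswalk",
    "crosswalk_from_index",
    "RESPONSE_PARTICIPATING",
    "RESPONSE_NONPARTICIPATING",
]

#: five-category decision-domain responses; the first two count as
#: participation ("alone or jointly with the husband/partner")
RESPONSE_PARTICIPATING = ("self", "joint")
RESPONSE_NONPARTICIPATING = ("husband", "someone_else", "other")

# fixed cosmetic splits within the participating / non-participating halves
_P_SELF_GIVEN_PART = 0.35
_P_NONPART = (0.85, 0.10, 0.05)  # husband alone / someone else / other


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Truth parameters and sizes for one simulated survey round.

    Defaults correspond to the study conditions the pipeline is exercised
    under: random-intercept variances of 0.54 (state), 0.16 (district) and
    0.94 (cluster) on the logit scale, an intercept of logit(0.84) for a
    national prevalence near 84%, and roughly 29% of sampled women not
    currently married (hence ineligible).
    """

    n_states: int = 10
    districts_per_state: int = 8
    clusters_per_district: int = 10
    women_per_cluster: int = 20
    beta0: float = 1.6582
    sigma2_state: float = 0.54
    sigma2_district: float = 0.16
    sigma2_cluster: float = 0.94
    domain_correlation: float = 0.8
    frac_ineligible: float = 0.29
    n_unmatched_clusters: int = 2
    frac_urban: float = 0.35
    seed: int = 2016

    def __post_init__(self) -> None:
        counts = (
            self.n_states,
            self.districts_per_state,
            self.clusters_per_district,
            self.women_per_cluster,
        )
        if any(int(c) != c or c < 1 for c in counts):
            raise ConfigError("all level counts must be integers >= 1")
        if min(self.sigma2_state, self.sigma2_district, self.sigma2_cluster) < 0:
            raise ConfigError("variances must be >= 0")
        if not 0.0 <= self.domain_correlation <= 1.0:
            raise ConfigError("domain_correlation must be in [0, 1]")
        if not 0.0 <= self.frac_ineligible < 1.0:
            raise ConfigError("frac_ineligible must be in [0, 1)")
        if self.n_unmatched_clusters < 0 or self.n_unmatched_clusters >= self.total_clusters:
            raise ConfigError("n_unmatched_clusters must be in [0, total clusters)")
        if not 0.0 <= self.frac_urban <= 1.0:
            raise ConfigError("frac_urban must be in [0, 1]")

    @property
    def total_clusters(self) -> int:
        return self.n_states * self.districts_per_state * self.clusters_per_district

    @property
    def total_women(self) -> int:
        return self.total_clusters * self.women_per_cluster


@dataclass(frozen=True)
class SimResult:
    """One fully simulated round: table, nesting, crosswalk and truths."""

    table: pd.DataFrame
    index: HierarchyIndex
    crosswalk: pd.DataFrame
    truth: dict
    modifications: dict = field(default_factory=dict)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_hierarchy(cfg: SimConfig) -> HierarchyIndex:
    """Build the balanced nesting map implied by the configured counts.

    Deterministic given the configuration (labels are systematic, no
    randomness is involved at this stage).
    """
    S = cfg.n_states
    D = S * cfg.districts_per_state
    C = D * cfg.clusters_per_district

    state_ids = np.array([f"S{l + 1:02d}" for l in range(S)])
    state_of_district = np.repeat(np.arange(S), cfg.districts_per_state)
    district_ids = np.array(
        [f"{state_ids[state_of_district[k]]}_D{k + 1:04d}" for k in range(D)]
    )
    district_of_cluster = np.repeat(np.arange(D), cfg.clusters_per_district)
    cluster_ids = np.array(
        [f"{district_ids[district_of_cluster[j]]}_C{j + 1:06d}" for j in range(C)]
    )
    cluster_of_woman = np.repeat(np.arange(C), cfg.women_per_cluster)
    return HierarchyIndex(
        cluster_of_woman=cluster_of_woman,
        district_of_cluster=district_of_cluster,
        state_of_district=state_of_district,
        cluster_ids=cluster_ids,
        district_ids=district_ids,
        state_ids=state_ids,
    )


def simulate_outcomes(
    index: HierarchyIndex, cfg: SimConfig, return_truth: bool = False
):
    """Draw random intercepts, outcomes and domain responses for every woman.

    Random intercepts are drawn ``f_l ~ N(0, sigma2_state)``,
    ``v_kl ~ N(0, sigma2_district)``, ``u_jkl ~ N(0, sigma2_cluster)``; each
    woman's participation indicator is ``Bernoulli(expit(beta0 + u + v + f))``.

    Domain responses are generated so that the composite coding rule holds
    exactly on every row: a non-participating woman gets non-participating
    responses in all three domains; a participating woman participates in
    each domain independently with probability ``domain_correlation`` (one
    domain forced if all three would fail).  ``domain_correlation = 1``
    therefore makes the three domains identical, while lower values spread
    participation unevenly across domains.
    """
    rng_eff, rng_out, rng_dom, rng_misc = _rng_streams(cfg.seed, 4)

    f = rng_eff.normal(0.0, np.sqrt(cfg.sigma2_state), index.n_states)
    v = rng_eff.normal(0.0, np.sqrt(cfg.sigma2_district), index.n_districts)
    u = rng_eff.normal(0.0, np.sqrt(cfg.sigma2_cluster), index.n_clusters)

    cw = index.cluster_of_woman
    eta = cfg.beta0 + u[cw] + v[index.district_of_cluster[cw]] + f[index.state_of_cluster[cw]]
    n = index.n_women
    outcome = (rng_out.random(n) < expit(eta)).astype(np.int64)

    # domain participation indicators, consistent with the composite
    part = np.zeros((n, 3), dtype=bool)
    pos = outcome.astype(bool)
    part[pos] = rng_dom.random((int(pos.sum()), 3)) < cfg.domain_correlation
    none = pos & ~part.any(axis=1)
    if none.any():
        forced = rng_dom.integers(0, 3, int(none.sum()))
        part[np.flatnonzero(none), forced] = True

    u_cat = rng_dom.random((n, 3))
    part_cat = np.where(u_cat < _P_SELF_GIVEN_PART, "self", "joint")
    cum = np.cumsum(_P_NONPART)
    non_idx = np.searchsorted(cum, u_cat, side="right").clip(max=2)
    non_cat = np.asarray(RESPONSE_NONPARTICIPATING, dtype=object)[non_idx]
    responses = np.where(part, part_cat, non_cat)

    table = pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1),
            "cluster_id": index.cluster_ids[cw],
            "district_id_true": index.district_ids[index.district_of_cluster[cw]],
            "state_id": index.state_ids[index.state_of_cluster[cw]],
            "age": rng_misc.integers(15, 50, n),
            "currently_married": np.ones(n, dtype=bool),
            "state_module": np.ones(n, dtype=bool),
            "residence": np.where(rng_misc.random(n) < cfg.frac_urban, "urban", "rural"),
            "weight": rng_misc.lognormal(0.0, 0.25, n),
            "resp_health": responses[:, 0],
            "resp_purchases": responses[:, 1],
            "resp_visits": responses[:, 2],
            "outcome_any": outcome,
        }
    )
    if return_truth:
        truth = {
            "beta0": cfg.beta0,
            "u": u,
            "v": v,
            "f": f,
            "sigma2_cluster": cfg.sigma2_cluster,
            "sigma2_district": cfg.sigma2_district,
            "sigma2_state": cfg.sigma2_state,
        }
        return table, truth
    return table


def inject_ineligibles(table: pd.DataFrame, cfg: SimConfig):
    """Flip a fraction of rows to not-currently-married and detach clusters.

    Exactly ``round(frac_ineligible * n_rows)`` rows are flipped to
    ``currently_married = False`` and ``n_unmatched_clusters`` cluster ids are
    rewritten to ids absent from any crosswalk built from the original
    hierarchy.  Returns the modified copy together with a dict of the exact
    modification counts.
    """
    clusters = table["cluster_id"].unique()
    if cfg.n_unmatched_clusters >= clusters.size:
        raise ConfigError("n_unmatched_clusters must be < number of clusters present")
    rng = _rng_streams(cfg.seed + 1, 1)[0]
    out = table.copy()

    n_flip = int(round(cfg.frac_ineligible * len(out)))
    if n_flip:
        rows = rng.choice(len(out), size=n_flip, replace=False)
        col = out.columns.get_loc("currently_married")
        out.iloc[rows, col] = False

    n_rows_recoded = 0
    if cfg.n_unmatched_clusters:
        chosen = rng.choice(clusters, size=cfg.n_unmatched_clusters, replace=False)
        mapping = {c: f"UNMATCHED_{i + 1:03d}" for i, c in enumerate(chosen)}
        mask = out["cluster_id"].isin(mapping)
        n_rows_recoded = int(mask.sum())
        out.loc[mask, "cluster_id"] = out.loc[mask, "cluster_id"].map(mapping)

    mods = {
        "n_flipped_not_married": n_flip,
        "n_clusters_unmatched": int(cfg.n_unmatched_clusters),
        "n_rows_in_unmatched_clusters": n_rows_recoded,
    }
    return out, mods


def simulate_survey(cfg: SimConfig) -> SimResult:
    """End-to-end simulation of one survey round.

    Generates the hierarchy, outcomes and responses, then applies the
    eligibility/crosswalk perturbations.  The returned crosswalk reflects
    the *original* hierarchy, so the rewritten cluster ids do not match it.
    """
    index = generate_hierarchy(cfg)
    table, truth = simulate_outcomes(index, cfg, return_truth=True)
    table, mods = inject_ineligibles(table, cfg)
    return SimResult(
        table=table,
        index=index,
        crosswalk=crosswalk_from_index(index),
        truth=truth,
        modifications=mods,
    )


def flow_fixture(
    n_initial: int,
    n_not_married: int,
    n_unmatched_women: int,
    seed: int = 0,
    clusters: int = 50,
) -> SimResult:
    """Build a table carrying an exact, prescribed exclusion flow.

    Constructs ``n_initial`` state-module rows of which exactly
    ``n_not_married`` are not currently married (in matched clusters) and
    exactly ``n_unmatched_women`` are currently married women placed in
    cluster ids absent from the crosswalk, so the eligibility filter must
    report precisely those exclusion counts.
    """
    if n_not_married + n_unmatched_women > n_initial:
        raise ConfigError("exclusion counts exceed n_initial")
    rng = np.random.Generator(np.random.PCG64(seed))
    n = n_initial
    cluster_codes = np.concatenate(
        [
            rng.integers(0, clusters, n - n_unmatched_women),
            np.full(n_unmatched_women, clusters),  # one synthetic unmatched cluster
        ]
    )
    married = np.ones(n, dtype=bool)
    married[rng.choice(n - n_unmatched_women, size=n_not_married, replace=False)] = False
    resp = rng.choice(["joint", "husband"], size=(n, 3), p=[0.8, 0.2])
    table = pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1),
            "cluster_id": np.array([f"C{c:05d}" for c in cluster_codes]),
            "district_id_true": "D001",
            "state_id": "S01",
            "age": rng.integers(15, 50, n),
            "currently_married": married,
            "state_module": np.ones(n, dtype=bool),
            "residence": "rural",
            "weight": np.ones(n),
            "resp_health": resp[:, 0],
            "resp_purchases": resp[:, 1],
            "resp_visits": resp[:, 2],
            "outcome_any": np.isin(resp, list(RESPONSE_PARTICIPATING)).any(axis=1).astype(int),
        }
    )
    xw = pd.DataFrame(
        {
            "cluster_id": [f"C{c:05d}" for c in range(clusters)],
            "district_id": [f"D{1 + c % 5:03d}" for c in range(clusters)],
            "state_id": "S01",
        }
    )
    return SimResult(table=table, index=None, crosswalk=xw, truth={}, modifications={})


def crosswalk_from_index(index: HierarchyIndex) -> pd.DataFrame:
    """Cluster -> (district, state) lookup table for the given hierarchy."""
    return pd.DataFrame(
        {
            "cluster_id": index.cluster_ids,
            "district_id": index.district_ids[index.district_of_cluster],
            "state_id": index.state_ids[index.state_of_cluster],
        }
    )


def write_fixture(table: pd.DataFrame, path) -> None:
    """Write a survey table as UTF-8 comma-delimited text with a header.

    Boolean flags are stored as 0/1; the file round-trips losslessly
    through :func:`districtsae.ingest.read_survey_table`.
    """
    out = table.copy()
    for col in ("currently_married", "state_module"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(Path(path), index=False)


def write_crosswalk(crosswalk: pd.DataFrame, path) -> None:
    crosswalk.to_csv(Path(path), index=False)
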