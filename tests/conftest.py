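import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from districtsae import ingest, mcmc, synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: simulation truths used by the shared fitted fixture
TRUTH = {"state": 0.54, "district": 0.16, "cluster": 0.94}


@pytest.fixture(scope="session")
def sim_small():
    """Moderate synthetic round (40 districts, ~4.8k eligible women)."""
    cfg = synthetic.SimConfig(
        n_states=8,
        districts_per_state=5,
        clusters_per_district=6,
        women_per_cluster=25,
        frac_ineligible=0.2,
        n_unmatched_clusters=2,
        seed=42,
    )
    return synthetic.simulate_survey(cfg)


@pytest.fixture(scope="session")
def fitted_small(sim_small):
    """One fitted model on the shared fixture: (filtered table, samples, summary)."""
    table, _ = ingest.apply_eligibility_filter(sim_small.table, sim_small.crosswalk)
    index = mcmc.build_index(table)
    cfg = mcmc.ModelConfig(burn_in=500, n_iter=2500, seed=7)
    samples = mcmc.run_mcmc(table["outcome_any"].to_numpy(), index, cfg)
    summary = mcmc.summarize_posterior(samples, cfg)
    return table, samples, summary


def two_level_table(n_per_cluster, k_per_cluster) -> pd.DataFrame:
    """Tiny single-district table with prescribed per-cluster outcomes."""
    rows = []
    for j, (n, k) in enumerate(zip(n_per_cluster, k_per_cluster)):
        for i in range(n):
            rows.append(
                {"cluster_id": f"C{j}", "district_id": "D0", "state_id": "S0", "y": int(i < k)}
            )
    return pd.DataFrame(rows)


def ar1_series(phi: float, n: int, seed: int = 123, warmup: int = 500) -> np.ndarray:
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(n + warmup)
    x = np.empty(n + warmup)
    x[0] = e[0]
    for t in range(1, n + warmup):
        x[t] = phi * x[t - 1] + e[t]
    return x[warmup:]
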