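"""Two-round comparison of district estimates.

Baseline decile classification (thresholds from the first round, reused
for the second), percentage-point change, a seven-category change taxonomy
and per-category / per-state tallies.  All statistics are descriptive —
no significance testing of district changes is attempted.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "decile_thresholds",
    "assign_decile",
    "categorize_change",
    "make_change_records",
    "category_counts",
    "low_participation_list",
]

#: change categories, ordered from largest decline to largest increase
CATEGORIES = (
    "substantial_decrease",
    "moderate_decrease",
    "small_decrease",
    "no_change",
    "small_increase",
    "moderate_increase",
    "substantial_increase",
)

# upper edges (percentage points) of the first six categories; the printed
# two-decimal bin labels (e.g. "-9.99 to -5.00") are rounded renderings of
# these continuous boundaries
_EDGES = (-10.0, -5.0, -2.5, 2.5, 5.0, 10.0)


def decile_thresholds(baseline_prevalences) -> np.ndarray:
    """Nine cut points (10th..90th percentiles, linear interpolation) of the
    baseline district distribution."""
    p = np.asarray(baseline_prevalences, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 districts to form deciles")
    return np.percentile(p, np.arange(10, 100, 10))


def assign_decile(value, cut_points) -> np.ndarray | int:
    """Decile bin 1-10 with right-closed bins: bin k is (cut_{k-1}, cut_k],
    bin 1 = (-inf, cut_1], bin 10 = (cut_9, inf).

    Follow-up values outside the baseline range therefore land in bins 1 or
    10.  Accepts scalars or arrays.
    """
    cuts = np.asarray(cut_points, dtype=float)
    if cuts.size != 9 or np.any(np.diff(cuts) < 0):
        raise ValueError("cut_points must be 9 nondecreasing values")
    bins = np.searchsorted(cuts, np.asarray(value, dtype=float), side="left") + 1
    return int(bins) if np.isscalar(value) else bins


def categorize_change(delta_pp: float) -> str:
    """Map a percentage-point change onto the seven-category taxonomy.

    Boundaries: <= -10 substantial decrease; (-10, -5] moderate decrease;
    (-5, -2.5] small decrease; (-2.5, 2.5) no change; [2.5, 5) small
    increase; [5, 10) moderate increase; >= 10 substantial increase.  These
    half-open intervals partition the real line, so every finite change
    maps to exactly one category.
    """
    d = float(delta_pp)
    if not math.isfinite(d):
        raise ValueError("change must be finite")
    if d <= -10.0:
        return "substantial_decrease"
    if d <= -5.0:
        return "moderate_decrease"
    if d <= -2.5:
        return "small_decrease"
    if d < 2.5:
        return "no_change"
    if d < 5.0:
        return "small_increase"
    if d < 10.0:
        return "moderate_increase"
    return "substantial_increase"


def make_change_records(base: pd.DataFrame, follow: pd.DataFrame) -> pd.DataFrame:
    """Join two rounds of district estimates and classify each change.

    Districts present in only one round are excluded and logged.  Decile
    thresholds are computed from the baseline round and applied to both
    rounds.  Columns: district_id, (state_id,) prevalence_base,
    prevalence_follow, delta_pp, category, decile_base, decile_follow.
    """
    only_base = set(base["district_id"]) - set(follow["district_id"])
    only_follow = set(follow["district_id"]) - set(base["district_id"])
    if only_base or only_follow:
        log.info(
            "districts present in one round only: %d baseline, %d follow-up (excluded)",
            len(only_base),
            len(only_follow),
        )
    cols_b = ["district_id", "prevalence"] + (["state_id"] if "state_id" in base.columns else [])
    merged = base[cols_b].merge(
        follow[["district_id", "prevalence"]],
        on="district_id",
        suffixes=("_base", "_follow"),
        validate="one_to_one",
    )
    if merged.empty:
        raise ValueError("no districts shared between the two rounds")
    cuts = decile_thresholds(merged["prevalence_base"])
    merged["delta_pp"] = merged["prevalence_follow"] - merged["prevalence_base"]
    merged["category"] = merged["delta_pp"].map(categorize_change)
    merged["decile_base"] = assign_decile(merged["prevalence_base"].to_numpy(), cuts)
    merged["decile_follow"] = assign_decile(merged["prevalence_follow"].to_numpy(), cuts)
    return merged


def category_counts(changes: pd.DataFrame) -> pd.Series:
    """Counts per change category plus the derived headline tallies.

    ``increase_ge_5pp`` sums moderate and substantial increases;
    ``decline_le_minus_2_5pp`` sums the three decrease categories.
    """
    if len(changes):
        counts = changes["category"].value_counts()
    else:
        counts = pd.Series(dtype=int)
    out = pd.Series({c: int(counts.get(c, 0)) for c in CATEGORIES})
    out["increase_ge_5pp"] = out["moderate_increase"] + out["substantial_increase"]
    out["decline_le_minus_2_5pp"] = (
        out["small_decrease"] + out["moderate_decrease"] + out["substantial_decrease"]
    )
    return out


def low_participation_list(estimates: pd.DataFrame, threshold: float = 80.0) -> pd.DataFrame:
    """Per-state counts of districts strictly below ``threshold`` percent,
    sorted by descending count (then state id for ties)."""
    low = estimates.loc[estimates["prevalence"] < threshold]
    if low.empty:
        return pd.DataFrame(columns=["state_id", "n_districts_below"])
    counts = (
        low.groupby("state_id")
        .size()
        .rename("n_districts_below")
        .reset_index()
        .sort_values(["n_districts_below", "state_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return counts
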