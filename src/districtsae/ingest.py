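"""Reading survey tables, outcome coding, eligibility filtering, prevalence.

The analysis sample is restricted to currently married women aged 15-49
interviewed in the state module whose cluster id matches the geographic
crosswalk; every excluded row is accounted for in a :class:`FlowReport`.
The composite outcome codes a woman as participating in household
decision-making if she decides alone or jointly with her husband/partner in
any of the three domains (own healthcare, large purchases, visits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "FlowReport",
    "RESPONSE_CATEGORIES",
    "SURVEY_COLUMNS",
    "read_survey_table",
    "read_crosswalk",
    "derive_participation",
    "domain_indicators",
    "apply_eligibility_filter",
    "weighted_prevalence",
]

RESPONSE_CATEGORIES = frozenset({"self", "joint", "husband", "someone_else", "other"})
_PARTICIPATING = frozenset({"self", "joint"})

#: required columns of a survey table file
SURVEY_COLUMNS = [
    "woman_id",
    "cluster_id",
    "district_id_true",
    "state_id",
    "age",
    "currently_married",
    "state_module",
    "weight",
    "resp_health",
    "resp_purchases",
    "resp_visits",
]

_RESP_COLS = ["resp_health", "resp_purchases", "resp_visits"]


class SchemaError(ValueError):
    """File does not carry the expected columns."""


class ValidationError(ValueError):
    """File carries invalid or missing values."""


@dataclass(frozen=True)
class FlowReport:
    """Exclusion accounting for one eligibility-filter run.

    ``n_initial`` counts the rows in the state module with an in-range age
    (the conventional starting point of the exclusion flow); the subsequent
    exclusions are attributed sequentially: marital status first, then
    unmatched cluster id.
    """

    n_initial: int
    n_excluded_not_married: int
    n_excluded_unmatched_cluster: int
    n_final: int
    n_total_rows: int = None  # type: ignore[assignment]
    n_excluded_not_state_module: int = 0
    n_excluded_age: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "n_total_rows", self.n_total_rows if self.n_total_rows is not None else self.n_initial
        )
        counts = (
            self.n_initial,
            self.n_excluded_not_married,
            self.n_excluded_unmatched_cluster,
            self.n_final,
            self.n_total_rows,
            self.n_excluded_not_state_module,
            self.n_excluded_age,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("flow counts must be non-negative")
        if (
            self.n_final
            != self.n_initial - self.n_excluded_not_married - self.n_excluded_unmatched_cluster
        ):
            raise ValidationError("flow counts do not sum")
        if (
            self.n_initial
            != self.n_total_rows - self.n_excluded_not_state_module - self.n_excluded_age
        ):
            raise ValidationError("pre-screen counts do not sum")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "total_rows",
                    "excluded_not_state_module",
                    "excluded_age_out_of_range",
                    "initial_state_module",
                    "excluded_not_currently_married",
                    "excluded_unmatched_cluster",
                    "final_sample",
                ],
                "count": [
                    self.n_total_rows,
                    self.n_excluded_not_state_module,
                    self.n_excluded_age,
                    self.n_initial,
                    self.n_excluded_not_married,
                    self.n_excluded_unmatched_cluster,
                    self.n_final,
                ],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def read_survey_table(path) -> pd.DataFrame:
    """Read and validate a delimited survey table.

    Rows with missing or unknown decision-domain responses are rejected with
    an error naming them, never silently dropped.  Boolean flags may be
    stored as 0/1 and are returned as booleans; the composite outcome column
    is (re)derived from the three responses.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cluster_id": str, "district_id_true": str, "state_id": str})
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")

    bad_rows: list[int] = []
    for col in _RESP_COLS:
        vals = df[col]
        bad = vals.isna() | ~vals.astype(str).isin(RESPONSE_CATEGORIES)
        bad_rows.extend(df.index[bad].tolist())
    if bad_rows:
        shown = sorted(set(bad_rows))[:20]
        raise ValidationError(
            f"{path.name}: {len(set(bad_rows))} row(s) with missing/unknown "
            f"decision-domain responses (file rows, 0-based after header): {shown}"
        )

    for col in ("currently_married", "state_module"):
        df[col] = df[col].astype(bool)
    df["weight"] = df["weight"].astype(float)
    df["age"] = df["age"].astype(int)
    df["outcome_any"] = derive_participation(
        df["resp_health"], df["resp_purchases"], df["resp_visits"]
    )
    return df


def read_crosswalk(path) -> pd.DataFrame:
    """Read the cluster -> district -> state crosswalk table."""
    path = Path(path)
    xw = pd.read_csv(path, dtype=str)
    missing = [c for c in ("cluster_id", "district_id", "state_id") if c not in xw.columns]
    if missing:
        raise SchemaError(f"{path.name}: crosswalk missing columns {missing}")
    if xw["cluster_id"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicate cluster ids in crosswalk")
    d2s = xw[["district_id", "state_id"]].drop_duplicates()
    if d2s["district_id"].duplicated().any():
        raise ValidationError(f"{path.name}: a district maps to more than one state")
    return xw


def _as_array(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=object))


def derive_participation(resp_health, resp_purchases, resp_visits):
    """Composite participation indicator: 1 iff any domain is decided alone
    or jointly with the husband/partner.

    Accepts scalars or array-likes; returns an int (scalars) or an int64
    array.  Unknown categories raise :class:`ValidationError`.
    """
    scalar = np.isscalar(resp_health) or isinstance(resp_health, str)
    cols = [_as_array(r) for r in (resp_health, resp_purchases, resp_visits)]
    stacked = np.stack(cols, axis=1)
    unknown = ~np.isin(stacked.astype(str), list(RESPONSE_CATEGORIES))
    if unknown.any():
        bad = sorted(set(stacked[unknown].astype(str)))
        raise ValidationError(f"unknown response categories: {bad}")
    out = np.isin(stacked.astype(str), list(_PARTICIPATING)).any(axis=1).astype(np.int64)
    return int(out[0]) if scalar else out


def domain_indicators(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-domain participation indicators (for domain-specific runs)."""
    out = table.copy()
    for col, name in zip(_RESP_COLS, ("healthcare", "purchases", "visits")):
        out[f"outcome_{name}"] = table[col].astype(str).isin(_PARTICIPATING).astype(np.int64)
    return out


def apply_eligibility_filter(table: pd.DataFrame, crosswalk: pd.DataFrame):
    """Apply the study-population filter and account for every exclusion.

    Keeps rows that are (in order of attribution) in the state module, aged
    15-49, currently married, and whose cluster id is present in the
    crosswalk.  The kept rows get ``district_id`` and ``state_id`` assigned
    from the crosswalk, which is authoritative over any ids carried in the
    input.  Returns ``(filtered_table, FlowReport)``; an empty result is
    allowed and simply reflected in the report.
    """
    n_total = len(table)
    in_module = table["state_module"].to_numpy(dtype=bool)
    age = table["age"].to_numpy()
    age_ok = (age >= 15) & (age <= 49)

    n_not_module = int((~in_module).sum())
    n_age = int((in_module & ~age_ok).sum())
    base = in_module & age_ok
    n_initial = int(base.sum())

    married = table["currently_married"].to_numpy(dtype=bool)
    n_not_married = int((base & ~married).sum())
    base = base & married

    matched = table["cluster_id"].isin(crosswalk["cluster_id"]).to_numpy()
    n_unmatched = int((base & ~matched).sum())
    base = base & matched

    kept = table.loc[base].drop(columns=["district_id", "state_id"], errors="ignore")
    kept = kept.merge(
        crosswalk[["cluster_id", "district_id", "state_id"]].rename(
            columns={"state_id": "state_id_xw"}
        ),
        on="cluster_id",
        how="left",
        validate="many_to_one",
    )
    kept["state_id"] = kept.pop("state_id_xw")

    report = FlowReport(
        n_initial=n_initial,
        n_excluded_not_married=n_not_married,
        n_excluded_unmatched_cluster=n_unmatched,
        n_final=int(base.sum()),
        n_total_rows=n_total,
        n_excluded_not_state_module=n_not_module,
        n_excluded_age=n_age,
    )
    assert report.n_final == len(kept)
    if report.n_final == 0:
        log.warning("eligibility filter left an empty table")
    return kept.reset_index(drop=True), report


def weighted_prevalence(table: pd.DataFrame, outcome_column: str = "outcome_any") -> float:
    """Design-weighted prevalence, in percent: ``100 * sum(w*y) / sum(w)``.

    Invariant to rescaling all weights by a positive constant, so it does
    not matter whether the supplied weights are raw or normalised.
    """
    w = table["weight"].to_numpy(dtype=float)
    y = table[outcome_column].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValidationError("sampling weights must be strictly positive")
    total = w.sum()
    if total == 0:
        raise ValidationError("zero total weight")
    return float(100.0 * (w * y).sum() / total)
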