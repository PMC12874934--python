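"""Four-level nesting structure: women within clusters within districts within states.

The survey design places each respondent (level 1) in exactly one primary
sampling unit ("cluster", level 2); clusters nest in districts (level 3) and
districts in states (level 4).  :class:`HierarchyIndex` is the validated
integer-coded form of that map used throughout the model code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HierarchyError", "HierarchyIndex"]


class HierarchyError(ValueError):
    """Raised when a nesting map is inconsistent (orphans, crossed units)."""


@dataclass(frozen=True)
class HierarchyIndex:
    """Integer-coded four-level nesting map.

    Attributes
    ----------
    cluster_of_woman : positions (0-based) into ``cluster_ids``, one per woman.
    district_of_cluster : positions into ``district_ids``, one per cluster.
    state_of_district : positions into ``state_ids``, one per district.
    cluster_ids, district_ids, state_ids : unit labels, sorted; position in
        these arrays is the integer code used everywhere else.
    """

    cluster_of_woman: np.ndarray
    district_of_cluster: np.ndarray
    state_of_district: np.ndarray
    cluster_ids: np.ndarray
    district_ids: np.ndarray
    state_ids: np.ndarray

    def __post_init__(self) -> None:
        c, d, s = self.n_clusters, self.n_districts, self.n_states
        if c == 0 or d == 0 or s == 0:
            raise HierarchyError("hierarchy has an empty level")
        if len(self.district_of_cluster) != c or len(self.state_of_district) != d:
            raise HierarchyError("index array lengths do not match unit labels")
        for name, arr, hi in (
            ("cluster_of_woman", self.cluster_of_woman, c),
            ("district_of_cluster", self.district_of_cluster, d),
            ("state_of_district", self.state_of_district, s),
        ):
            if arr.size and (arr.min() < 0 or arr.max() >= hi):
                raise HierarchyError(f"{name} contains out-of-range codes")
        # no orphan units: every cluster has >=1 woman, every district >=1
        # cluster, every state >=1 district
        if np.any(np.bincount(self.cluster_of_woman, minlength=c) == 0):
            raise HierarchyError("cluster with no women")
        if np.any(np.bincount(self.district_of_cluster, minlength=d) == 0):
            raise HierarchyError("district with no clusters")
        if np.any(np.bincount(self.state_of_district, minlength=s) == 0):
            raise HierarchyError("state with no districts")

    # ---- sizes ----------------------------------------------------------
    @property
    def n_women(self) -> int:
        return int(self.cluster_of_woman.size)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_ids.size)

    @property
    def n_districts(self) -> int:
        return int(self.district_ids.size)

    @property
    def n_states(self) -> int:
        return int(self.state_ids.size)

    # ---- derived maps ---------------------------------------------------
    @property
    def state_of_cluster(self) -> np.ndarray:
        return self.state_of_district[self.district_of_cluster]

    @property
    def n_women_per_cluster(self) -> np.ndarray:
        return np.bincount(self.cluster_of_woman, minlength=self.n_clusters)

    # ---- construction ---------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        cluster_col: str = "cluster_id",
        district_col: str = "district_id",
        state_col: str = "state_id",
    ) -> "HierarchyIndex":
        """Build a validated index from a respondent-level table.

        Unit codes are assigned by sorted label, so the result is invariant
        to the row order of ``frame``.

        Raises
        ------
        HierarchyError
            If a cluster appears under two districts or a district under
            two states.
        """
        for col in (cluster_col, district_col, state_col):
            if col not in frame.columns:
                raise HierarchyError(f"missing column {col!r}")
        cluster_ids, cluster_of_woman = np.unique(
            frame[cluster_col].to_numpy(), return_inverse=True
        )
        pairs = frame[[cluster_col, district_col, state_col]].drop_duplicates()
        if pairs[cluster_col].duplicated().any():
            bad = pairs.loc[pairs[cluster_col].duplicated(), cluster_col].iloc[0]
            raise HierarchyError(f"cluster {bad!r} appears under more than one district")
        dpairs = pairs[[district_col, state_col]].drop_duplicates()
        if dpairs[district_col].duplicated().any():
            bad = dpairs.loc[dpairs[district_col].duplicated(), district_col].iloc[0]
            raise HierarchyError(f"district {bad!r} appears under more than one state")

        pairs = pairs.sort_values(cluster_col)
        district_ids, district_of_cluster = np.unique(
            pairs[district_col].to_numpy(), return_inverse=True
        )
        dpairs = dpairs.sort_values(district_col)
        state_ids, state_of_district = np.unique(
            dpairs[state_col].to_numpy(), return_inverse=True
        )
        return cls(
            cluster_of_woman=np.asarray(cluster_of_woman),
            district_of_cluster=np.asarray(district_of_cluster),
            state_of_district=np.asarray(state_of_district),
            cluster_ids=cluster_ids,
            district_ids=district_ids,
            state_ids=state_ids,
        )
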