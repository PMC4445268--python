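"""Clustered ordinal response data container and CSV round-trip.

The package's raw input everywhere is a rectangular table of ordinal item
responses (codes ``1..K_m``, missing allowed) with a cluster identifier and
an optional positive sampling weight per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OrdinalDataset", "read_dataset", "write_dataset"]


@dataclass
class OrdinalDataset:
    """Ordinal item responses for respondents nested in clusters.

    Parameters
    ----------
    responses : float ndarray, shape (n_obs, n_items)
        Integer category codes in ``1..n_categories[m]``; ``NaN`` marks a
        missing response.
    cluster_id : int ndarray, shape (n_obs,)
        Cluster membership of each row (arbitrary integer labels).
    weight : float ndarray, shape (n_obs,)
        Positive sampling weights; defaults to 1.
    item_labels : list of str
    n_categories : int ndarray, shape (n_items,)
        Number of ordered categories per item.
    """

    responses: np.ndarray
    cluster_id: np.ndarray
    weight: np.ndarray = None
    item_labels: list = None
    n_categories: np.ndarray = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-d array")
        n, m = self.responses.shape
        self.cluster_id = np.asarray(self.cluster_id)
        if self.cluster_id.shape != (n,):
            raise ValueError("cluster_id length must match number of rows")
        if self.weight is None:
            self.weight = np.ones(n)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.weight.shape != (n,):
            raise ValueError("weight length must match number of rows")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be strictly positive")
        if self.item_labels is None:
            self.item_labels = [f"item_{j + 1}" for j in range(m)]
        self.item_labels = list(self.item_labels)
        if len(self.item_labels) != m:
            raise ValueError("item_labels length must match number of items")
        if self.n_categories is None:
            with np.errstate(invalid="ignore"):
                self.n_categories = np.array(
                    [int(np.nanmax(self.responses[:, j])) if np.any(~np.isnan(self.responses[:, j])) else 2
                     for j in range(m)]
                )
        self.n_categories = np.asarray(self.n_categories, dtype=int)
        if len(np.unique(self.cluster_id)) < 2:
            raise ValueError("dataset must contain at least 2 distinct clusters")
        obs = ~np.isnan(self.responses)
        for j in range(m):
            col = self.responses[obs[:, j], j]
            if col.size and (np.any(col < 1) or np.any(col > self.n_categories[j])
                             or np.any(col != np.round(col))):
                bad = np.where(obs[:, j])[0][
                    (col < 1) | (col > self.n_categories[j]) | (col != np.round(col))][0]
                raise ValueError(
                    f"item {self.item_labels[j]!r}: response {self.responses[bad, j]!r} in row "
                    f"{bad} outside 1..{self.n_categories[j]}"
                )

    @property
    def n_obs(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def clusters(self) -> np.ndarray:
        """Sorted unique cluster labels."""
        return np.unique(self.cluster_id)

    def cluster_indices(self) -> dict:
        """Row indices per cluster label, in row order."""
        order = {}
        for lab in self.clusters:
            order[lab] = np.where(self.cluster_id == lab)[0]
        return order

    def subset(self, rows) -> "OrdinalDataset":
        rows = np.asarray(rows)
        return OrdinalDataset(
            responses=self.responses[rows],
            cluster_id=self.cluster_id[rows],
            weight=self.weight[rows],
            item_labels=list(self.item_labels),
            n_categories=self.n_categories.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_labels)
        df.insert(0, "weight", self.weight)
        df.insert(0, "cluster_id", self.cluster_id)
        return df

    def __eq__(self, other):
        if not isinstance(other, OrdinalDataset):
            return NotImplemented
        return (
            np.array_equal(self.responses, other.responses, equal_nan=True)
            and np.array_equal(self.cluster_id, other.cluster_id)
            and np.allclose(self.weight, other.weight)
            and self.item_labels == other.item_labels
            and np.array_equal(self.n_categories, other.n_categories)
        )


def write_dataset(data: OrdinalDataset, path) -> None:
    """Write to CSV: ``cluster_id, weight, <item labels>``; missing as empty."""
    df = data.to_frame()
    # keep integer formatting for response codes
    for lab in data.item_labels:
        df[lab] = df[lab].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)


def read_dataset(
    path,
    item_columns=None,
    cluster_column: str = "cluster_id",
    weight_column: str = "weight",
    n_categories=None,
    recode_reverse=None,
) -> OrdinalDataset:
    """Read an :class:`OrdinalDataset` from a wide CSV.

    Parameters
    ----------
    item_columns : list of str, optional
        Columns holding the ordinal codes. Defaults to every column other
        than the cluster and weight columns.
    n_categories : int or sequence, optional
        Declared number of categories per item; codes outside ``1..K`` are
        rejected with their row number.
    recode_reverse : list of str, optional
        Item columns to reverse-code at read time (``k -> K + 1 - k``),
        e.g. negatively worded survey items.
    """
    df = pd.read_csv(path)
    if cluster_column not in df.columns:
        raise ValueError(f"cluster column {cluster_column!r} not found in {path}")
    if item_columns is None:
        item_columns = [c for c in df.columns if c not in (cluster_column, weight_column)]
    for c in item_columns:
        if c not in df.columns:
            raise ValueError(f"declared item column {c!r} not found in {path}")
    resp = df[item_columns].to_numpy(dtype=float)
    bad = ~np.isnan(resp) & (resp != np.round(resp))
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer code {resp[i, j]} in row {i} item {item_columns[j]!r}"
        )
    if n_categories is not None:
        K = np.broadcast_to(np.asarray(n_categories, dtype=int), (len(item_columns),)).copy()
        for j, c in enumerate(item_columns):
            col = resp[:, j]
            mask = ~np.isnan(col) & ((col < 1) | (col > K[j]))
            if np.any(mask):
                i = int(np.argmax(mask))
                raise ValueError(
                    f"row {i}: code {int(col[i])} on item {c!r} outside 1..{K[j]}"
                )
    else:
        K = None
    if recode_reverse:
        for c in recode_reverse:
            j = item_columns.index(c)
            kj = K[j] if K is not None else int(np.nanmax(resp[:, j]))
            resp[:, j] = kj + 1 - resp[:, j]
    weight = (
        df[weight_column].to_numpy(dtype=float)
        if weight_column in df.columns
        else np.ones(len(df))
    )
    return OrdinalDataset(
        responses=resp,
        cluster_id=df[cluster_column].to_numpy(),
        weight=weight,
        item_labels=list(item_columns),
        n_categories=K,
    )
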