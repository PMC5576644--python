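"""Group-by-individual matrices, simple-ratio association networks, and
per-individual metrics (weighted degree, mean group size).

A GBI matrix has one row per observed group and one column per individual;
entry 1 means the individual was in the group.  Under the gambit of the
group, the simple-ratio index (SRI) between two individuals is the number of
groups containing both divided by the number of groups containing either —
0 for never together, 1 for always together.  Weighted degree is the sum of
an individual's incident SRI edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import GroupObservation


class EmptyNetworkError(ValueError):
    """All individuals were filtered out; there is no network to analyse."""


@dataclass(frozen=True)
class GBIMatrix:
    """Binary groups x individuals incidence matrix."""

    entries: np.ndarray  # shape (n_groups, n_individuals), dtype uint8
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.entries)
        if m.ndim != 2:
            raise ValueError("GBI entries must be 2-D")
        if m.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("label lengths do not match matrix shape")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("GBI entries must be binary")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate group labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate individual labels")
        object.__setattr__(self, "entries", m.astype(np.uint8))

    @property
    def n_groups(self) -> int:
        return self.entries.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.entries.shape[1]

    def sighting_counts(self) -> np.ndarray:
        """Per-individual number of group memberships (column sums)."""
        return self.entries.sum(axis=0)

    def group_sizes(self) -> np.ndarray:
        """Per-group member counts (row sums)."""
        return self.entries.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric individual x individual edge weights in [0, 1], zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels), len(self.labels)):
            raise ValueError("weights must be square over labels")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    g.add_edge(self.labels[i], self.labels[j], weight=float(self.weights[i, j]))
        return g

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    rows.append(
                        {"id_i": self.labels[i], "id_j": self.labels[j],
                         "weight": float(self.weights[i, j])}
                    )
        return pd.DataFrame(rows, columns=["id_i", "id_j", "weight"])


@dataclass(frozen=True)
class NodeMetrics:
    individual_id: str
    weighted_degree: float
    mean_group_size: float
    n_sightings: int


def build_gbi(
    observations: Sequence[GroupObservation],
    min_sightings: int = 2,
    deduplicate: bool = False,
) -> GBIMatrix:
    """Build the GBI matrix, keeping only individuals seen at least
    ``min_sightings`` times.

    Filtering runs to a fixed point: dropping rare individuals can empty a
    group row, and rows that become empty are dropped.  Duplicate sightings
    of an identical group on the same day are kept as distinct rows unless
    ``deduplicate`` is set.

    Raises :class:`EmptyNetworkError` if nothing survives the filter.
    """
    if not observations:
        raise ValueError("no observations")
    if deduplicate:
        seen: set[tuple] = set()
        kept = []
        for obs in observations:
            key = (obs.obs_date, obs.members)
            if key not in seen:
                seen.add(key)
                kept.append(obs)
        observations = kept

    individuals = sorted({m for obs in observations for m in obs.members})
    col_index = {ind: j for j, ind in enumerate(individuals)}
    matrix = np.zeros((len(observations), len(individuals)), dtype=np.uint8)
    row_labels = []
    for i, obs in enumerate(observations):
        row_labels.append(obs.group_id)
        for m in obs.members:
            matrix[i, col_index[m]] = 1

    rows = np.arange(matrix.shape[0])
    cols = np.arange(matrix.shape[1])
    while True:
        col_sums = matrix[np.ix_(rows, cols)].sum(axis=0)
        keep_cols = cols[col_sums >= min_sightings]
        row_sums = matrix[np.ix_(rows, keep_cols)].sum(axis=1)
        keep_rows = rows[row_sums >= 1]
        if len(keep_cols) == len(cols) and len(keep_rows) == len(rows):
            break
        rows, cols = keep_rows, keep_cols
        if len(cols) == 0:
            raise EmptyNetworkError(
                f"no individual reaches {min_sightings} sightings; network is empty"
            )
    if len(cols) == 0:
        raise EmptyNetworkError(
            f"no individual reaches {min_sightings} sightings; network is empty"
        )
    return GBIMatrix(
        entries=matrix[np.ix_(rows, cols)],
        row_labels=tuple(row_labels[i] for i in rows),
        col_labels=tuple(individuals[j] for j in cols),
    )


def simple_ratio_index(gbi: GBIMatrix) -> AssociationMatrix:
    """Simple-ratio association weights: joint / (joint + either-alone).

    weight(i, j) = |groups with both i and j| / |groups with i or j|.
    """
    g = gbi.entries.astype(np.int64)
    joint = g.T @ g  # joint[i, j] = groups containing both
    counts = np.diag(joint).copy()
    union = counts[:, None] + counts[None, :] - joint
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(union > 0, joint / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(weights, 0.0)
    return AssociationMatrix(weights=weights, labels=gbi.col_labels)


def half_weight_index(gbi: GBIMatrix) -> AssociationMatrix:
    """Half-weight association index, the common alternative when joint
    sightings are under-recorded: joint / (joint + mean of sole counts)."""
    g = gbi.entries.astype(np.int64)
    joint = g.T @ g
    counts = np.diag(joint).copy()
    denom = 0.5 * (counts[:, None] + counts[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(denom > 0, joint / np.where(denom > 0, denom, 1), 0.0)
    weights = np.minimum(weights, 1.0)
    np.fill_diagonal(weights, 0.0)
    return AssociationMatrix(weights=weights, labels=gbi.col_labels)


ASSOCIATION_INDICES = {
    "simple_ratio": simple_ratio_index,
    "half_weight": half_weight_index,
}


def weighted_degree(assoc: AssociationMatrix) -> dict[str, float]:
    """Per-individual weighted degree: sum of incident edge weights."""
    degrees = assoc.weights.sum(axis=1)
    return {label: float(d) for label, d in zip(assoc.labels, degrees)}


def mean_group_size(gbi: GBIMatrix) -> dict[str, float]:
    """Per-individual mean size (including self) of the groups it was in."""
    sizes = gbi.group_sizes().astype(float)
    out = {}
    for j, label in enumerate(gbi.col_labels):
        mask = gbi.entries[:, j] == 1
        out[label] = float(sizes[mask].mean())
    return out


def node_metrics(
    gbi: GBIMatrix, index: Literal["simple_ratio", "half_weight"] = "simple_ratio"
) -> list[NodeMetrics]:
    """Bundle degree, mean group size and sighting count for every individual."""
    assoc = ASSOCIATION_INDICES[index](gbi)
    deg = weighted_degree(assoc)
    mgs = mean_group_size(gbi)
    counts = gbi.sighting_counts()
    return [
        NodeMetrics(
            individual_id=label,
            weighted_degree=deg[label],
            mean_group_size=mgs[label],
            n_sightings=int(counts[j]),
        )
        for j, label in enumerate(gbi.col_labels)
    ]
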