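"""Group-by-individual matrices and simple-ratio-index association networks.

The group-by-individual (GBI) matrix has one row per observed aggregation and
one binary column per retained individual.  From it, the simple ratio index
(SRI) for a dyad (i, j) is

    SRI(i, j) = x / (x + y_i + y_j)

where x is the number of aggregations containing both and y_i (y_j) the
number containing only i (only j): the proportion of observations of either
individual in which the two were together.  Weights below a threshold
(0.5 by default) are zeroed before community detection, because the detection
is far more sensitive to edge presence than to edge weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .census import CensusRecord

__all__ = [
    "GroupByIndividual",
    "AssociationNetwork",
    "build_gbi",
    "simple_ratio_index",
    "threshold_network",
    "write_edgelist",
]


@dataclass
class GroupByIndividual:
    """Binary observation-by-individual presence matrix.

    ``matrix[r, c]`` is 1 when individual ``individual_ids[c]`` was present in
    aggregation ``observation_ids[r]``.  Every row has at least one presence.
    """

    observation_ids: list[str]
    individual_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.shape != (len(self.observation_ids), len(self.individual_ids)):
            raise ValueError("matrix shape does not match id lists")


@dataclass
class AssociationNetwork:
    """Symmetric association-index matrix over an ordered individual set."""

    individual_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.individual_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over individual_ids")


def build_gbi(records: list[CensusRecord], ids: set[str]) -> GroupByIndividual:
    """Build the GBI matrix of ``records`` restricted to retained ``ids``.

    Rows containing none of the retained individuals are dropped.

    Raises
    ------
    ValueError
        If ``ids`` is empty (the matrix would have no columns).
    """
    if not ids:
        raise ValueError("cannot build a group-by-individual matrix with no individuals")
    columns = sorted(ids)
    col_index = {ind: c for c, ind in enumerate(columns)}
    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    for rec in records:
        present = rec.individual_ids & ids
        if not present:
            continue
        row = np.zeros(len(columns), dtype=np.int64)
        for ind in present:
            row[col_index[ind]] = 1
        rows.append(row)
        row_ids.append(rec.observation_id)
    matrix = np.vstack(rows) if rows else np.zeros((0, len(columns)), dtype=np.int64)
    return GroupByIndividual(row_ids, columns, matrix)


def simple_ratio_index(gbi: GroupByIndividual) -> AssociationNetwork:
    """Simple ratio index network from a GBI matrix.

    For each pair, the numerator counts rows containing both individuals and
    the denominator rows containing at least one of them.  Pairs whose
    denominator is zero get weight 0.  Both counts are small integers, and
    IEEE division is correctly rounded, so a ratio that is exactly one half
    is represented exactly and the downstream 0.5 threshold decision is exact.
    """
    if len(gbi.individual_ids) < 2:
        raise ValueError("simple ratio index requires at least 2 individuals")
    x = gbi.matrix
    together = x.T @ x
    per_ind = np.diag(together).copy()
    either = per_ind[:, None] + per_ind[None, :] - together
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(either > 0, together / np.maximum(either, 1), 0.0)
    np.fill_diagonal(weights, 0.0)
    return AssociationNetwork(list(gbi.individual_ids), weights)


def threshold_network(net: AssociationNetwork, threshold: float) -> AssociationNetwork:
    """Zero all weights strictly below ``threshold``; keep weights >= it.

    Idempotent; symmetry is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    weights = net.weights.copy()
    weights[weights < threshold] = 0.0
    return AssociationNetwork(list(net.individual_ids), weights)


def write_edgelist(net: AssociationNetwork, path: str | Path) -> None:
    """Export positive edges as CSV ``id_i,id_j,sri`` with i < j."""
    order = np.argsort(net.individual_ids)
    ids = [net.individual_ids[k] for k in order]
    w = net.weights[np.ix_(order, order)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_i,id_j,sri\n")
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if w[i, j] > 0:
                    fh.write(f"{ids[i]},{ids[j]},{float(w[i, j])!r}\n")
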