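"""Social-unit detection: walktrap communities, bootstrap meta-networks and
the oversize-splitting check.

Two detection routes are provided per focal window.  The direct route runs
walktrap community detection on the thresholded observed association network.
The bootstrap route resamples the observed aggregations with replacement,
rebuilds the network and re-detects communities in each replicate, and records
for every dyad the probability of being assigned to the same community — the
*meta-network* — on which walktrap is then run.  Because sparse census data
can leave distinct-but-co-observed units connected, any detected community
larger than the largest single field observation of the window is recursively
re-processed on the census rows of its own members (oversize splitting).

The two estimators follow scikit-learn conventions (``fit``, ``labels_``,
``get_params``/``set_params``) and operate on plain arrays; the module-level
functions wrap them for the domain objects.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace

import igraph
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .census import ApproachConfig, CensusRecord, FocalWindow, retained_individuals
from .network import AssociationNetwork, build_gbi, simple_ratio_index, threshold_network

__all__ = [
    "CommunityPartition",
    "MetaNetwork",
    "WalktrapCommunities",
    "BootstrapCommunities",
    "walktrap_communities",
    "bootstrap_metanetwork",
    "detect_units",
    "oversize_split",
]


@dataclass
class CommunityPartition:
    """Assignment of every retained individual of a window to one community."""

    window_id: str
    assignment: dict[str, str]
    method_tag: str = ""

    def communities(self) -> dict[str, set[str]]:
        """Map community label -> member set."""
        out: dict[str, set[str]] = {}
        for ind, label in self.assignment.items():
            out.setdefault(label, set()).add(ind)
        return out

    def sizes(self) -> dict[str, int]:
        return {label: len(mem) for label, mem in self.communities().items()}


@dataclass
class MetaNetwork:
    """Co-membership probabilities across bootstrap replicates.

    ``probs[i, j]`` is the fraction of replicates containing both individuals
    in which they were assigned to the same community; the diagonal is 1.
    """

    individual_ids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n = len(self.individual_ids)
        if self.probs.shape != (n, n):
            raise ValueError("probs must be square over individual_ids")


# ---------------------------------------------------------------------------
# Estimators


def _walktrap_labels(weights: np.ndarray, steps: int) -> np.ndarray:
    """Run walktrap on a symmetric non-negative weight matrix.

    Vertices with no positive-weight edge become singleton communities.
    Deterministic for fixed input and steps.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    graph = igraph.Graph.Weighted_Adjacency(
        weights.tolist(), mode="undirected", attr="weight"
    )
    if graph.ecount() == 0:
        return np.arange(n)
    dendrogram = graph.community_walktrap(weights="weight", steps=steps)
    return np.asarray(dendrogram.as_clustering().membership, dtype=int)


class WalktrapCommunities(ClusterMixin, BaseEstimator):
    """Walktrap community detection on a weighted adjacency matrix.

    Agglomerates vertices whose short random walks visit similar
    neighbourhoods and cuts the merge sequence at maximal modularity.

    Parameters
    ----------
    steps : int, default=4
        Length of the random walks.

    Attributes
    ----------
    labels_ : ndarray of shape (n_vertices,)
        Community label of each vertex.
    n_communities_ : int
    """

    def __init__(self, steps: int = 4):
        self.steps = steps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square adjacency matrix")
        if X.shape[0] and not np.allclose(X, X.T):
            raise ValueError("adjacency matrix must be symmetric")
        if X.shape[0] and X.min() < 0:
            raise ValueError("edge weights must be non-negative")
        self.labels_ = _walktrap_labels(X, self.steps)
        self.n_communities_ = int(self.labels_.max()) + 1 if len(self.labels_) else 0
        return self


class BootstrapCommunities(ClusterMixin, BaseEstimator):
    """Bootstrapped co-membership communities from a group-by-individual matrix.

    Each replicate resamples the observation rows with replacement, rebuilds
    the simple-ratio-index network over the individuals present, zeroes edges
    below ``edge_threshold`` and detects walktrap communities.  The pairwise
    co-membership frequencies form the meta-network, whose positive entries
    are clustered by a final walktrap run.

    Parameters
    ----------
    n_boot : int, default=100
        Number of bootstrap replicates.
    edge_threshold : float, default=0.5
        Association-weight threshold applied inside every replicate.
    steps : int, default=4
        Walktrap random-walk length.
    resample : bool, default=True
        Test hook: with False every replicate uses the observed rows, so
        co-membership probabilities equal the observed co-membership
        indicator.
    random_state : int, numpy Generator or SeedSequence, optional

    Attributes
    ----------
    comembership_ : ndarray of shape (n_individuals, n_individuals)
        Meta-network probabilities (unit diagonal).
    labels_ : ndarray of shape (n_individuals,)
        Final community labels from walktrap on the meta-network.
    """

    def __init__(
        self,
        n_boot: int = 100,
        edge_threshold: float = 0.5,
        steps: int = 4,
        resample: bool = True,
        random_state=None,
    ):
        self.n_boot = n_boot
        self.edge_threshold = edge_threshold
        self.steps = steps
        self.resample = resample
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.int64)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d binary group-by-individual matrix")
        n_rows, n_ind = X.shape
        if n_rows == 0 or n_ind == 0:
            raise ValueError("group-by-individual matrix must be non-empty")
        rng = np.random.default_rng(self.random_state)

        co_counts = np.zeros((n_ind, n_ind))
        present_counts = np.zeros((n_ind, n_ind))
        for _ in range(self.n_boot):
            if self.resample:
                rows = rng.integers(0, n_rows, size=n_rows)
                xb = X[rows]
            else:
                xb = X
            present = np.where(xb.sum(axis=0) > 0)[0]
            if len(present) == 0:
                continue
            sub = xb[:, present]
            sub = sub[sub.sum(axis=1) > 0]
            labels = self._replicate_labels(sub)
            same = (labels[:, None] == labels[None, :]).astype(float)
            block = np.ix_(present, present)
            co_counts[block] += same
            present_counts[block] += 1.0

        with np.errstate(divide="ignore", invalid="ignore"):
            probs = np.where(present_counts > 0, co_counts / np.maximum(present_counts, 1), 0.0)
        np.fill_diagonal(probs, 1.0)
        self.comembership_ = probs
        meta_weights = probs.copy()
        np.fill_diagonal(meta_weights, 0.0)
        self.labels_ = _walktrap_labels(meta_weights, self.steps)
        self.n_communities_ = int(self.labels_.max()) + 1 if len(self.labels_) else 0
        return self

    def _replicate_labels(self, sub: np.ndarray) -> np.ndarray:
        n = sub.shape[1]
        if n == 1:
            return np.zeros(1, dtype=int)
        together = sub.T @ sub
        per_ind = np.diag(together).copy()
        either = per_ind[:, None] + per_ind[None, :] - together
        with np.errstate(divide="ignore", invalid="ignore"):
            weights = np.where(either > 0, together / np.maximum(either, 1), 0.0)
        np.fill_diagonal(weights, 0.0)
        weights[weights < self.edge_threshold] = 0.0
        return _walktrap_labels(weights, self.steps)


# ---------------------------------------------------------------------------
# Domain-level wrappers


def _labels_to_tokens(labels: np.ndarray) -> list[str]:
    width = max(2, len(str(max(int(labels.max()), 0)))) if len(labels) else 2
    return [f"C{int(lab):0{width}d}" for lab in labels]


def walktrap_communities(
    net: AssociationNetwork,
    steps: int = 4,
    window_id: str = "",
    method_tag: str = "",
) -> CommunityPartition:
    """Walktrap partition of an association network.

    Isolated individuals become singleton communities.
    """
    if len(net.individual_ids) == 0:
        raise ValueError("network has no individuals")
    est = WalktrapCommunities(steps=steps).fit(net.weights)
    tokens = _labels_to_tokens(est.labels_)
    assignment = dict(zip(net.individual_ids, tokens))
    return CommunityPartition(window_id, assignment, method_tag)


def _derived_seed(seed: int, *tokens: str) -> np.random.SeedSequence:
    keys = [zlib.crc32(t.encode()) for t in tokens]
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys])


def bootstrap_metanetwork(
    records: list[CensusRecord],
    ids: set[str],
    config: ApproachConfig,
    random_state=None,
) -> MetaNetwork:
    """Meta-network of co-membership probabilities over bootstrap replicates.

    ``records`` must already be filtered and restricted to the window's
    sampling interval.  Pairs never present together in any replicate get 0.
    """
    gbi = build_gbi(records, ids)
    est = BootstrapCommunities(
        n_boot=config.n_boot,
        edge_threshold=config.edge_threshold,
        steps=config.walktrap_steps,
        random_state=random_state if random_state is not None else config.seed,
    ).fit(gbi.matrix)
    return MetaNetwork(list(gbi.individual_ids), est.comembership_)


def detect_units(
    records: list[CensusRecord],
    window: FocalWindow,
    config: ApproachConfig,
) -> CommunityPartition:
    """Detect the social units of one focal window.

    Restricts ``records`` (already cleaned by :func:`filter_census`) to the
    window's sampling interval, drops individuals observed fewer than
    ``config.min_obs`` times, and runs either walktrap on the thresholded
    observed network or, with ``config.bootstrap``, walktrap on the bootstrap
    meta-network followed by the oversize-splitting check.
    """
    in_window = [r for r in records if window.in_sampling(r.date)]
    ids = retained_individuals(in_window, window, config.min_obs)
    if not ids:
        warnings.warn(
            f"window {window.window_id}: no individuals retained; empty partition",
            stacklevel=2,
        )
        return CommunityPartition(window.window_id, {}, config.method_tag)

    if not config.bootstrap:
        net = simple_ratio_index(build_gbi(in_window, ids)) if len(ids) > 1 else None
        if net is None:
            assignment = {next(iter(ids)): "C00"}
            return CommunityPartition(window.window_id, assignment, config.method_tag)
        net = threshold_network(net, config.edge_threshold)
        part = walktrap_communities(
            net, config.walktrap_steps, window.window_id, config.method_tag
        )
        return part

    meta = bootstrap_metanetwork(
        in_window, ids, config, random_state=_derived_seed(config.seed, window.window_id)
    )
    weights = meta.probs.copy()
    np.fill_diagonal(weights, 0.0)
    labels = _walktrap_labels(weights, config.walktrap_steps)
    assignment = dict(zip(meta.individual_ids, _labels_to_tokens(labels)))
    part = CommunityPartition(window.window_id, assignment, config.method_tag)
    return oversize_split(part, in_window, config)


def _max_single_observation(records: list[CensusRecord]) -> int:
    sizes = [len(r.individual_ids) for r in records if r.cohesion == "single"]
    return max(sizes) if sizes else 0


def oversize_split(
    partition: CommunityPartition,
    records: list[CensusRecord],
    config: ApproachConfig,
    max_depth: int = 10,
) -> CommunityPartition:
    """Recursively split communities larger than any single field observation.

    A community cannot be larger than the largest cohesive aggregation
    actually observed in the period (counting identified individuals only);
    larger ones are artefacts of sparse co-observation and are re-processed by
    the full bootstrap procedure on the census rows of their own members.
    Recursion stops when no community is oversized, a re-run fails to split
    (fixed point), or the depth limit is reached (with a warning).
    """
    limit = _max_single_observation(records)
    if limit == 0:
        return partition

    assignment = dict(partition.assignment)
    frozen: set[str] = set()
    for depth in range(max_depth + 1):
        groups: dict[str, set[str]] = {}
        for ind, label in assignment.items():
            groups.setdefault(label, set()).add(ind)
        oversized = [
            label
            for label, members in groups.items()
            if len(members) > limit and label not in frozen
        ]
        if not oversized:
            break
        if depth == max_depth:
            warnings.warn(
                f"oversize split: depth limit {max_depth} reached in "
                f"window {partition.window_id}; accepting current partition",
                stacklevel=2,
            )
            break
        for label in sorted(oversized):
            members = groups[label]
            sub_records = []
            for rec in records:
                present = rec.individual_ids & members
                if present:
                    sub_records.append(replace(rec, individual_ids=frozenset(present)))
            seed = _derived_seed(config.seed, partition.window_id, label)
            gbi = build_gbi(sub_records, members)
            est = BootstrapCommunities(
                n_boot=config.n_boot,
                edge_threshold=config.edge_threshold,
                steps=config.walktrap_steps,
                random_state=seed,
            ).fit(gbi.matrix)
            sub_labels = est.labels_
            if est.n_communities_ <= 1:
                frozen.add(label)  # re-run failed to split: fixed point
                continue
            for ind, sub in zip(gbi.individual_ids, sub_labels):
                assignment[ind] = f"{label}.{int(sub)}"
    return CommunityPartition(partition.window_id, assignment, partition.method_tag)
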