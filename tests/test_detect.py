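import datetime as dt

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from socialunits import (
    ApproachConfig,
    AssociationNetwork,
    BootstrapCommunities,
    FocalWindow,
    WalktrapCommunities,
    bootstrap_metanetwork,
    detect_units,
    oversize_split,
    walktrap_communities,
)
from socialunits.detect import CommunityPartition

from reference_walktrap import walktrap_reference

WINDOW = FocalWindow(
    "w", dt.date(2020, 10, 1), dt.date(2020, 11, 1), dt.date(2020, 9, 1), dt.date(2020, 12, 1)
)


def clique_matrix(*cliques, n=None, bridges=()):
    size = n or sum(len(c) for c in cliques)
    w = np.zeros((size, size))
    for members in cliques:
        for i in members:
            for j in members:
                if i != j:
                    w[i, j] = 1.0
    for i, j, value in bridges:
        w[i, j] = w[j, i] = value
    return w


class TestWalktrapCommunities:
    def test_disconnected_cliques_recovered(self):
        w = clique_matrix(range(4), range(4, 8))
        labels = WalktrapCommunities().fit(w).labels_
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_complete_graph_single_community(self):
        w = clique_matrix(range(6))
        est = WalktrapCommunities().fit(w)
        assert est.n_communities_ == 1

    def test_bridged_cliques_match_reference(self):
        w = clique_matrix(range(5), range(5, 10), bridges=[(0, 5, 0.6)])
        labels = WalktrapCommunities().fit(w).labels_
        expected = walktrap_reference(w)
        assert adjusted_rand_score(labels, expected) == 1.0
        assert len(set(labels)) == 2  # the two cliques

    def test_isolated_vertices_become_singletons(self):
        w = clique_matrix(range(3), n=5)
        labels = WalktrapCommunities().fit(w).labels_
        assert labels[3] != labels[4]
        assert labels[3] not in labels[:3]

    def test_rejects_asymmetric_and_negative(self):
        with pytest.raises(ValueError, match="symmetric"):
            WalktrapCommunities().fit(np.array([[0, 1.0], [0.5, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            WalktrapCommunities().fit(np.array([[0, -1.0], [-1.0, 0]]))

    def test_sklearn_params_roundtrip(self):
        est = WalktrapCommunities(steps=6)
        assert est.get_params() == {"steps": 6}
        est.set_params(steps=3)
        assert est.steps == 3

    def test_agreement_with_reference_on_random_graphs(self, rng):
        identical = 0
        scores = []
        for _ in range(50):
            n = int(rng.integers(8, 31))
            mask = rng.random((n, n)) < 0.2
            w = np.triu(mask * rng.uniform(0.1, 1.0, (n, n)), 1)
            w = w + w.T
            for v in range(n):
                if w[v].sum() == 0:
                    u = (v + 1) % n
                    w[v, u] = w[u, v] = rng.uniform(0.1, 1.0)
            ari = adjusted_rand_score(
                WalktrapCommunities().fit(w).labels_, walktrap_reference(w)
            )
            scores.append(ari)
            identical += ari == 1.0
        # identical partitions on nearly every graph; disagreements are
        # rare near-tied merge orders (heap approximation vs exact oracle)
        assert identical >= 45
        assert np.mean(scores) >= 0.95


class TestWalktrapPartitionWrapper:
    def test_tokens_and_totality(self):
        net = AssociationNetwork(list("ABCD"), clique_matrix(range(2), range(2, 4)))
        part = walktrap_communities(net, window_id="w")
        assert set(part.assignment) == set("ABCD")
        assert part.assignment["A"] == part.assignment["B"]
        assert part.assignment["A"] != part.assignment["C"]


def block_records(make_record, unit_members, n_each=10):
    """Census records in which units are never co-observed."""
    records = []
    for day in range(n_each):
        for members in unit_members:
            records.append(make_record(members, day=day))
    return records


class TestBootstrapCommunities:
    def test_block_structure_gives_binary_probabilities(self, make_record):
        records = block_records(make_record, [{"A", "B"}, {"C", "D"}])
        ids = {"A", "B", "C", "D"}
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=25, seed=3)
        meta = bootstrap_metanetwork(records, ids, config)
        idx = {ind: k for k, ind in enumerate(meta.individual_ids)}
        assert meta.probs[idx["A"], idx["B"]] == 1.0
        assert meta.probs[idx["A"], idx["C"]] == 0.0
        assert np.all(np.isin(meta.probs, [0.0, 1.0]))

    def test_meta_network_invariants(self, make_record, rng):
        pool = [f"I{k}" for k in range(8)]
        records = [
            make_record(rng.choice(pool, size=rng.integers(2, 5), replace=False), day=d)
            for d in range(20)
        ]
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=10, seed=1)
        meta = bootstrap_metanetwork(records, set(pool), config)
        np.testing.assert_array_equal(meta.probs, meta.probs.T)
        np.testing.assert_array_equal(np.diag(meta.probs), 1.0)
        assert meta.probs.min() >= 0.0 and meta.probs.max() <= 1.0

    def test_resampling_disabled_gives_observed_indicator(self, make_record):
        records = block_records(make_record, [{"A", "B"}, {"C", "D"}], n_each=4)
        from socialunits import build_gbi

        gbi = build_gbi(records, {"A", "B", "C", "D"})
        est = BootstrapCommunities(n_boot=1, resample=False, random_state=0).fit(gbi.matrix)
        assert np.all(np.isin(est.comembership_, [0.0, 1.0]))
        same = est.labels_[:, None] == est.labels_[None, :]
        np.testing.assert_array_equal(est.comembership_ == 1.0, same)

    def test_fixed_seed_reproducible(self, make_record, rng):
        pool = [f"I{k}" for k in range(8)]
        records = [
            make_record(rng.choice(pool, size=rng.integers(2, 5), replace=False), day=d)
            for d in range(20)
        ]
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=15, seed=9)
        first = bootstrap_metanetwork(records, set(pool), config)
        second = bootstrap_metanetwork(records, set(pool), config)
        np.testing.assert_array_equal(first.probs, second.probs)


class TestDetectUnits:
    @pytest.mark.parametrize("bootstrap", [False, True])
    def test_recovers_block_structure(self, make_record, bootstrap):
        units = [
            {f"u{k}_{i}" for i in range(5)} for k in range(3)
        ]
        records = block_records(make_record, units, n_each=8)
        config = ApproachConfig(
            basis="1-month", bootstrap=bootstrap, n_boot=20, seed=4
        )
        part = detect_units(records, WINDOW, config)
        truth = {ind: k for k, members in enumerate(units) for ind in members}
        detected = [part.assignment[i] for i in sorted(truth)]
        expected = [truth[i] for i in sorted(truth)]
        assert adjusted_rand_score(detected, expected) == 1.0

    def test_single_unit_single_community(self, make_record):
        records = block_records(make_record, [{"A", "B", "C"}], n_each=6)
        config = ApproachConfig(basis="1-month", seed=0)
        part = detect_units(records, WINDOW, config)
        assert len(part.communities()) == 1
        assert set(part.assignment) == {"A", "B", "C"}

    def test_no_retained_individuals_warns_and_empties(self, make_record):
        records = [make_record({"A"}, day=0)]  # seen once < min_obs
        config = ApproachConfig(basis="1-month", seed=0)
        with pytest.warns(UserWarning, match="no individuals retained"):
            part = detect_units(records, WINDOW, config)
        assert part.assignment == {}

    def test_partition_covers_retained_exactly_once(self, make_record, rng):
        pool = [f"I{k}" for k in range(10)]
        records = [
            make_record(rng.choice(pool, size=rng.integers(2, 5), replace=False), day=d % 28)
            for d in range(40)
        ]
        from socialunits import filter_census, retained_individuals

        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=10, seed=2)
        part = detect_units(records, WINDOW, config)
        expected = retained_individuals(filter_census(records), WINDOW, config.min_obs)
        assert set(part.assignment) == expected

    def test_deterministic_replay(self, make_record, rng):
        pool = [f"I{k}" for k in range(10)]
        records = [
            make_record(rng.choice(pool, size=rng.integers(2, 5), replace=False), day=d % 28)
            for d in range(40)
        ]
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=10, seed=6)
        first = detect_units(records, WINDOW, config)
        second = detect_units(records, WINDOW, config)
        assert first.assignment == second.assignment


def planted_merged_fixture(make_record, rng):
    """Two true units plus bridging rows, with the merged 15-member
    community planted as if the meta-network path had produced it."""
    u1 = [f"a{i}" for i in range(8)]
    u2 = [f"b{i}" for i in range(7)]
    records = []
    for day in range(10):
        records.append(make_record(u1, day=day))
        records.append(make_record(u2, day=day))
    for day in range(3):  # bridging rows capped at 8 identified individuals
        ids = list(rng.choice(u1, 4, replace=False)) + list(rng.choice(u2, 4, replace=False))
        records.append(make_record(ids, day=12 + day))
    merged = CommunityPartition("w", {ind: "C00" for ind in u1 + u2}, "planted")
    return records, merged, set(u1), set(u2)


class TestOversizeSplit:
    def test_no_trigger_returns_unchanged(self, make_record):
        records = [make_record({"A", "B", "C"}, day=d) for d in range(5)]
        part = CommunityPartition("w", {"A": "C00", "B": "C00", "C": "C00"})
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=5, seed=0)
        assert oversize_split(part, records, config).assignment == part.assignment

    def test_planted_merged_units_recovered(self, make_record, rng):
        records, merged, u1, u2 = planted_merged_fixture(make_record, rng)
        assert max(len(r.individual_ids) for r in records) == 8
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=50, seed=7)
        out = oversize_split(merged, records, config)
        communities = list(out.communities().values())
        assert u1 in communities
        assert u2 in communities

    def test_unsplittable_community_is_fixed_point(self, make_record):
        # one true unit of 5 planted as one community, but the largest single
        # observation shows only 4: the re-run cannot split a clique, so the
        # partition is accepted unchanged after one recursion
        members = [f"m{i}" for i in range(5)]
        records = []
        for day in range(8):
            records.append(make_record(members[:4], day=day))
            records.append(make_record(members[1:], day=day))
        part = CommunityPartition("w", {m: "C00" for m in members})
        config = ApproachConfig(basis="1-month", bootstrap=True, n_boot=20, seed=1)
        out = oversize_split(part, records, config)
        assert set(out.assignment) == set(members)
        assert len(out.communities()) == 1
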