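"""Relative-movement matrices, network metrics and community detection."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from fmclass.metrics import compute_covariates
from fmclass.network import (
    detect_communities,
    network_metrics,
    per_fmc_networks,
    relative_movement_matrix,
)


def _detections(rows):
    """rows: (tag, minute, installation). Receivers/coords are synthesized."""
    return pd.DataFrame(
        {
            "tag_id": [r[0] for r in rows],
            "timestamp": pd.to_datetime("2015-01-01")
            + pd.to_timedelta([r[1] for r in rows], unit="m"),
            "receiver_id": [f"R_{r[2]}" for r in rows],
            "installation_id": [r[2] for r in rows],
            "latitude": [-30.0 - 0.1 * hashvalue(r[2]) for r in rows],
            "longitude": [150.0] * len(rows),
            "qc_flag": np.int64(1),
            "species": pd.NA,
        }
    )


def hashvalue(name: str) -> int:
    return sum(ord(c) for c in name) % 7


def _installations(types: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "installation_id": list(types),
            "installation_type": list(types.values()),
            "receiver_id": [f"R_{k}" for k in types],
        }
    )


INSTALLS = _installations({"A": "IMOS", "B": "non-IMOS", "C": "non-IMOS"})


class TestRelativeMovementMatrix:
    def test_hand_counted_three_transitions(self):
        det = _detections(
            [("t1", 0, "A"), ("t1", 10, "B"), ("t1", 20, "A"), ("t2", 0, "A"), ("t2", 5, "C")]
        )
        M = relative_movement_matrix(det, INSTALLS)
        assert M.n_transitions == 3
        assert M.matrix.at["A", "B"] == pytest.approx(1 / 3)
        assert M.matrix.at["B", "A"] == pytest.approx(1 / 3)
        assert M.matrix.at["A", "C"] == pytest.approx(1 / 3)
        assert M.matrix.to_numpy().sum() == pytest.approx(1.0)

    def test_repeat_detections_make_single_transition(self):
        det = _detections([("t1", 0, "A"), ("t1", 5, "A"), ("t1", 9, "B")])
        M = relative_movement_matrix(det, INSTALLS)
        assert M.n_transitions == 1
        assert M.matrix.at["A", "B"] == 1.0

    def test_no_movement_warns_and_returns_empty(self):
        det = _detections([("t1", 0, "A"), ("t1", 5, "A")])
        with pytest.warns(UserWarning, match="no between-installation"):
            M = relative_movement_matrix(det, INSTALLS)
        assert M.is_empty

    def test_diagonal_zero_and_normalisation(self, canonical_dataset):
        M = relative_movement_matrix(
            canonical_dataset.detections, canonical_dataset.installations
        )
        assert np.diag(M.matrix.to_numpy()).sum() == 0.0
        assert M.matrix.to_numpy().sum() == pytest.approx(1.0)
        assert (M.matrix.to_numpy() >= 0).all()

    def test_subset_filters_before_transitions(self):
        # A(IMOS) -> B(non) -> C(non): non-IMOS subset sees B -> C only;
        # IMOS subset sees no movement at all
        det = _detections([("t1", 0, "A"), ("t1", 10, "B"), ("t1", 20, "C")])
        non = relative_movement_matrix(det, INSTALLS, subset="NON_IMOS")
        assert non.n_transitions == 1 and non.matrix.at["B", "C"] == 1.0
        with pytest.warns(UserWarning):
            imos = relative_movement_matrix(det, INSTALLS, subset="IMOS")
        assert imos.is_empty

    def test_skip_transition_through_excluded_installation(self):
        # A(IMOS) -> B(non) -> A(IMOS): after filtering to IMOS the two A
        # detections are consecutive at the same installation: no movement
        det = _detections([("t1", 0, "A"), ("t1", 10, "B"), ("t1", 20, "A"), ("t1", 30, "B")])
        full = relative_movement_matrix(det, INSTALLS)
        assert full.n_transitions == 3
        with pytest.warns(UserWarning):
            imos = relative_movement_matrix(det, INSTALLS, subset="IMOS")
        assert imos.is_empty

    def test_tag_filter_restricts_counts(self):
        det = _detections([("t1", 0, "A"), ("t1", 10, "B"), ("t2", 0, "B"), ("t2", 9, "C")])
        M = relative_movement_matrix(det, INSTALLS, tag_filter={"t1"})
        assert M.n_transitions == 1 and M.matrix.at["A", "B"] == 1.0

    def test_removing_a_tag_never_increases_counts(self, small_dataset):
        det, inst = small_dataset.detections, small_dataset.installations
        full = relative_movement_matrix(det, inst)
        tags = set(det["tag_id"].unique())
        tags.discard(sorted(tags)[0])
        reduced = relative_movement_matrix(det, inst, tag_filter=tags)
        joint = full.counts.reindex(
            index=full.counts.index, columns=full.counts.columns, fill_value=0
        )
        red = reduced.counts.reindex_like(joint).fillna(0)
        assert (red.to_numpy() <= joint.to_numpy()).all()

    def test_per_individual_normalisation_sums_to_one(self):
        det = _detections(
            [("t1", 0, "A"), ("t1", 10, "B"), ("t1", 20, "A"),
             ("t2", 0, "A"), ("t2", 5, "C")]
        )
        M = relative_movement_matrix(det, INSTALLS, per_individual=True)
        assert M.matrix.to_numpy().sum() == pytest.approx(1.0)
        # t1 splits its weight over two edges; t2 has one edge
        assert M.matrix.at["A", "C"] > M.matrix.at["A", "B"]


class TestNetworkMetrics:
    def test_complete_directed_triangle(self):
        det = _detections(
            [("t1", i, inst) for i, inst in enumerate(["A", "B", "C", "A", "C", "B", "A"])]
        )
        M = relative_movement_matrix(det, INSTALLS)
        summary = network_metrics(M)
        net = summary.network
        assert net["n_nodes"] == 3 and net["n_edges"] == 6
        assert net["density"] == pytest.approx(1.0)
        assert net["diameter"] == 1 and net["avg_path_length"] == pytest.approx(1.0)
        assert net["reciprocity"] == pytest.approx(1.0)

    def test_directed_path_metrics(self):
        det = _detections([("t1", 0, "A"), ("t1", 10, "B"), ("t1", 20, "C")])
        summary = network_metrics(relative_movement_matrix(det, INSTALLS))
        net = summary.network
        assert net["density"] == pytest.approx(2 / 6)
        assert net["diameter"] == 2
        assert net["avg_path_length"] == pytest.approx(4 / 3)

    def test_star_centre_has_maximal_eigenvector_centrality(self):
        rows, t = [], 0
        for leaf in ("B", "C", "D", "E"):
            rows += [("t1", t, "A"), ("t1", t + 1, leaf)]
            t += 2
        installs = _installations(
            {k: "IMOS" if k == "A" else "non-IMOS" for k in "ABCDE"}
        )
        summary = network_metrics(relative_movement_matrix(_detections(rows), installs))
        eig = summary.nodes["eigenvector"]
        assert eig["A"] == pytest.approx(1.0)
        assert (eig.drop("A") < 1.0).all()

    def test_fourteen_metrics_reported(self, canonical_dataset):
        M = relative_movement_matrix(
            canonical_dataset.detections, canonical_dataset.installations
        )
        summary = network_metrics(M)
        assert len(summary.network) == 9
        assert list(summary.nodes.columns) == [
            "in_degree", "out_degree", "strength", "eigenvector", "betweenness"
        ]

    def test_strength_is_sum_of_incident_weights(self):
        det = _detections([("t1", 0, "A"), ("t1", 10, "B"), ("t1", 20, "A"), ("t2", 0, "A"), ("t2", 5, "C")])
        M = relative_movement_matrix(det, INSTALLS)
        summary = network_metrics(M)
        assert summary.nodes.loc["A", "strength"] == pytest.approx(1.0)  # 3/3 edges touch A


class TestCommunities:
    def test_disconnected_dyads_form_two_communities(self):
        installs = _installations(
            {"A": "IMOS", "B": "IMOS", "C": "non-IMOS", "D": "non-IMOS"}
        )
        det = _detections(
            [("t1", 0, "A"), ("t1", 10, "B"), ("t2", 0, "C"), ("t2", 10, "D")]
        )
        M = relative_movement_matrix(det, installs)
        clustering = detect_communities(M)
        assert sorted(map(sorted, clustering.communities)) == [["A", "B"], ["C", "D"]]

    def test_planted_two_cliques_recovered(self):
        rng = np.random.default_rng(0)
        names = [f"I{i}" for i in range(10)]
        installs = _installations({n: "non-IMOS" for n in names})
        rows, t = [], 0
        for group in (names[:5], names[5:]):
            for _ in range(40):
                a, b = rng.choice(group, size=2, replace=False)
                rows += [(f"t{t}", 0, a), (f"t{t}", 1, b)]
                t += 1
        rows += [("bridge", 0, names[0]), ("bridge", 1, names[5])]
        M = relative_movement_matrix(_detections(rows), installs)
        clustering = detect_communities(M)
        groups = sorted(map(sorted, clustering.communities))
        assert groups == [sorted(names[:5]), sorted(names[5:])]
        assert clustering.modularity > 0.3

    def test_membership_invariant_to_row_order(self, small_dataset):
        det, inst = small_dataset.detections, small_dataset.installations
        a = detect_communities(relative_movement_matrix(det, inst))
        shuffled = det.sample(frac=1.0, random_state=5).reset_index(drop=True)
        b = detect_communities(relative_movement_matrix(shuffled, inst))
        assert a.membership == b.membership


class TestPerClassNetworks:
    def test_single_moving_tag_yields_one_edge(self):
        det = _detections([("t1", 0, "A"), ("t1", 10, "B")])
        labels = pd.Series({"t1": "Roamers"})
        out = per_fmc_networks(det, INSTALLS, labels)
        M, summary, _ = out["Roamers"]
        assert summary.network["n_edges"] == 1

    def test_class_transitions_partition_full_transitions(self, canonical_dataset):
        det, inst = canonical_dataset.detections, canonical_dataset.installations
        truth = canonical_dataset.truth.set_index("tag_id")["archetype"]
        full = relative_movement_matrix(det, inst)
        nets = per_fmc_networks(det, inst, truth)
        total = sum(M.n_transitions for M, _, _ in nets.values())
        assert total == full.n_transitions

    def test_residents_move_less_than_roamers(self, canonical_dataset):
        det, inst = canonical_dataset.detections, canonical_dataset.installations
        truth = canonical_dataset.truth.set_index("tag_id")["archetype"]
        nets = per_fmc_networks(det, inst, truth)
        res_edges = nets["RESIDENT"][1].network["n_edges"]
        roam_edges = nets["ROAMER"][1].network["n_edges"]
        assert res_edges < roam_edges

    def test_imos_and_non_imos_nodes_partition_full(self, canonical_dataset):
        det, inst = canonical_dataset.detections, canonical_dataset.installations
        full = relative_movement_matrix(det, inst)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imos = relative_movement_matrix(det, inst, subset="IMOS")
            non = relative_movement_matrix(det, inst, subset="NON_IMOS")
        imos_nodes = set(imos.matrix.index)
        non_nodes = set(non.matrix.index)
        assert imos_nodes.isdisjoint(non_nodes)
        assert imos_nodes | non_nodes <= set(full.matrix.index)
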