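"""Relative-movement networks over receiver installations.

A movement is a pair of consecutive detections of one individual at two
different installations. The relative-movement matrix M is the square
installation-by-installation matrix of movement counts divided by the
total number of between-installation movements pooled over all
individuals, so its off-diagonal entries sum to 1 (the diagonal is zero:
within-installation hops are not movements between installations).
Networks are built for three installation subsets — Full, IMOS-only and
non-IMOS-only, with detections filtered to the subset *before* transitions
are formed — and per functional movement class.

Each network is summarised with 14 metrics: nine at the network level
(node count, edge count, density, diameter, average path length, number of
communities, modularity, reciprocity, transitivity) and five per
installation (in-degree, out-degree, strength, eigenvector centrality,
betweenness). Path metrics use unweighted (hop-count) shortest paths on
the directed graph restricted to the largest weakly connected component;
eigenvector centrality is computed on the symmetrised weighted graph and
normalised to a maximum of 1. The metric set is configurable through the
returned tables; this reconstruction is the package's documented default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import installation_types, sort_detections

logger = logging.getLogger(__name__)

SUBSETS = ("FULL", "IMOS", "NON_IMOS")


@dataclass
class RelativeMovementMatrix:
    """Directed, normalised movement matrix plus the raw transition counts."""

    matrix: pd.DataFrame  # installations x installations, entries sum to 1
    counts: pd.DataFrame  # raw transition counts, same shape
    n_transitions: int
    subset: str

    @property
    def installations(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def is_empty(self) -> bool:
        return self.n_transitions == 0


@dataclass
class NetworkSummary:
    """Network-level metrics plus a per-installation metric table."""

    network: dict[str, float]
    nodes: pd.DataFrame  # index installation; in_degree, out_degree, strength,
    #                      eigenvector, betweenness


@dataclass
class InstallationClustering:
    """Modularity communities of the symmetrised movement graph."""

    membership: dict[str, int]
    communities: list[list[str]]
    modularity: float

    def edges_within_between(self, M: RelativeMovementMatrix) -> pd.DataFrame:
        rows = []
        for a in M.matrix.index:
            for b in M.matrix.columns:
                w = M.matrix.at[a, b]
                if w > 0:
                    kind = "within" if self.membership[a] == self.membership[b] else "between"
                    rows.append((a, b, w, kind))
        return pd.DataFrame(rows, columns=["from", "to", "weight", "kind"])


def _transitions(detections: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-detection installation pairs per tag (post-subset)."""
    ordered = sort_detections(detections)
    inst = ordered["installation_id"]
    prev_inst = inst.shift(1)
    same_tag = ordered["tag_id"].eq(ordered["tag_id"].shift(1))
    moved = same_tag & inst.ne(prev_inst)
    return pd.DataFrame(
        {
            "tag_id": ordered.loc[moved, "tag_id"].to_numpy(),
            "from": prev_inst[moved].to_numpy(),
            "to": inst[moved].to_numpy(),
        }
    )


def relative_movement_matrix(
    detections: pd.DataFrame,
    installations: pd.DataFrame,
    subset: str = "FULL",
    tag_filter: set[str] | None = None,
    per_individual: bool = False,
) -> RelativeMovementMatrix:
    """Build the relative-movement matrix for an installation subset.

    Detections are restricted to installations of the subset type *before*
    transitions are extracted, so a tag passing through an excluded
    installation contributes a skip transition between the surviving
    detections. Installations with no retained transitions are dropped.

    ``per_individual=True`` normalises each tag's counts by that tag's own
    movement total and averages the per-tag matrices (then rescales to sum
    to 1); the default pools counts over all individuals and divides by the
    grand total.

    Zero transitions overall yield an empty-network result with a warning,
    not an error.
    """
    if subset not in SUBSETS:
        raise ValueError(f"subset must be one of {SUBSETS}")
    det = detections
    if tag_filter is not None:
        det = det[det["tag_id"].isin(tag_filter)]
    if subset != "FULL":
        types = installation_types(installations)
        wanted = "IMOS" if subset == "IMOS" else "non-IMOS"
        keep = types.index[types == wanted]
        det = det[det["installation_id"].isin(keep)]

    trans = _transitions(det) if len(det) else pd.DataFrame(columns=["tag_id", "from", "to"])
    n_trans = len(trans)
    if n_trans == 0:
        warnings.warn(f"no between-installation movements in subset {subset}", stacklevel=2)
        empty = pd.DataFrame(dtype=float)
        return RelativeMovementMatrix(
            matrix=empty, counts=empty.copy(), n_transitions=0, subset=subset
        )

    nodes = sorted(set(trans["from"]) | set(trans["to"]))
    counts = (
        trans.groupby(["from", "to"]).size().unstack(fill_value=0)
        .reindex(index=nodes, columns=nodes, fill_value=0)
        .astype(float)
    )
    if per_individual:
        mats = []
        for _, sub in trans.groupby("tag_id"):
            c = (
                sub.groupby(["from", "to"]).size().unstack(fill_value=0)
                .reindex(index=nodes, columns=nodes, fill_value=0)
                .astype(float)
            )
            mats.append(c / c.to_numpy().sum())
        M = sum(mats) / len(mats)
        M = M / M.to_numpy().sum()
    else:
        M = counts / float(n_trans)
    np.fill_diagonal(M.values, 0.0)
    return RelativeMovementMatrix(matrix=M, counts=counts, n_transitions=n_trans, subset=subset)


def _digraph(M: RelativeMovementMatrix) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(M.matrix.index)  # sorted at construction
    for a in M.matrix.index:
        row = M.matrix.loc[a]
        for b in row.index[row > 0]:
            G.add_edge(a, b, weight=float(row[b]))
    return G


def _symmetrized(M: RelativeMovementMatrix) -> nx.Graph:
    W = M.matrix + M.matrix.T
    G = nx.Graph()
    G.add_nodes_from(W.index)
    for i, a in enumerate(W.index):
        for b in W.columns[i + 1 :]:
            w = float(W.at[a, b])
            if w > 0:
                G.add_edge(a, b, weight=w)
    return G


def detect_communities(M: RelativeMovementMatrix) -> InstallationClustering:
    """Greedy modularity communities on the symmetrised weighted graph.

    Deterministic for a fixed matrix (nodes enter in sorted order); isolated
    installations form singleton communities. Communities are numbered by
    their lexicographically smallest member.
    """
    G = _symmetrized(M)
    if G.number_of_nodes() == 0:
        return InstallationClustering(membership={}, communities=[], modularity=float("nan"))
    if G.number_of_edges() == 0:
        comms = [[n] for n in sorted(G.nodes)]
    else:
        raw = nx.community.greedy_modularity_communities(G, weight="weight")
        comms = sorted((sorted(c) for c in raw), key=lambda c: c[0])
    membership = {n: i for i, comm in enumerate(comms) for n in comm}
    mod = (
        nx.community.modularity(G, [set(c) for c in comms], weight="weight")
        if G.number_of_edges()
        else float("nan")
    )
    return InstallationClustering(membership=membership, communities=[list(c) for c in comms],
                                  modularity=mod)


def network_metrics(M: RelativeMovementMatrix) -> NetworkSummary:
    """Compute the 14-metric summary of a relative-movement network."""
    if M.is_empty:
        return NetworkSummary(
            network={
                "n_nodes": 0, "n_edges": 0, "density": float("nan"),
                "diameter": float("nan"), "avg_path_length": float("nan"),
                "n_communities": 0, "modularity": float("nan"),
                "reciprocity": float("nan"), "transitivity": float("nan"),
            },
            nodes=pd.DataFrame(
                columns=["in_degree", "out_degree", "strength", "eigenvector", "betweenness"]
            ),
        )
    G = _digraph(M)
    n = G.number_of_nodes()
    e = G.number_of_edges()
    density = e / (n * (n - 1)) if n > 1 else 0.0

    # path metrics: unweighted directed shortest paths on the largest weak component
    wcc = max(nx.weakly_connected_components(G), key=lambda c: (len(c), sorted(c)[0]))
    H = G.subgraph(wcc)
    lengths = [
        d for _, targets in nx.all_pairs_shortest_path_length(H)
        for t, d in targets.items() if d > 0
    ]
    diameter = float(max(lengths)) if lengths else float("nan")
    apl = float(np.mean(lengths)) if lengths else float("nan")

    clustering = detect_communities(M)
    reciprocity = nx.overall_reciprocity(G) if e else float("nan")
    transitivity = nx.transitivity(G.to_undirected())

    W = M.matrix
    strength = W.sum(axis=1) + W.sum(axis=0)
    sym = (W + W.T).to_numpy()
    eig = _leading_eigenvector(sym)
    btw = nx.betweenness_centrality(G, normalized=True)

    nodes = pd.DataFrame(
        {
            "in_degree": pd.Series(dict(G.in_degree()), dtype=float),
            "out_degree": pd.Series(dict(G.out_degree()), dtype=float),
            "strength": strength,
            "eigenvector": pd.Series(eig, index=W.index),
            "betweenness": pd.Series(btw, dtype=float),
        }
    ).loc[list(W.index)]
    nodes.index.name = "installation_id"

    return NetworkSummary(
        network={
            "n_nodes": float(n),
            "n_edges": float(e),
            "density": float(density),
            "diameter": diameter,
            "avg_path_length": apl,
            "n_communities": float(len(clustering.communities)),
            "modularity": float(clustering.modularity),
            "reciprocity": float(reciprocity),
            "transitivity": float(transitivity),
        },
        nodes=nodes,
    )


def _leading_eigenvector(sym: np.ndarray) -> np.ndarray:
    """Leading eigenvector of a symmetric non-negative matrix, max-normalised."""
    evals, evecs = np.linalg.eigh(sym)
    v = np.abs(evecs[:, -1])
    top = v.max()
    return v / top if top > 0 else v


def per_fmc_networks(
    detections: pd.DataFrame,
    installations: pd.DataFrame,
    class_labels: pd.Series,
) -> dict[str, tuple[RelativeMovementMatrix, NetworkSummary, InstallationClustering]]:
    """One Full-subset network per functional movement class.

    ``class_labels`` maps tag_id -> class name. Classes whose tags never
    move between installations yield an empty-network entry (expected for
    strongly resident classes) with a warning.
    """
    out: dict[str, tuple[RelativeMovementMatrix, NetworkSummary, InstallationClustering]] = {}
    for name in sorted(class_labels.unique()):
        tags = set(class_labels.index[class_labels == name].astype(str))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            M = relative_movement_matrix(detections, installations, subset="FULL",
                                         tag_filter=tags)
        if M.is_empty:
            logger.warning("class %s has no between-installation movements", name)
        out[name] = (M, network_metrics(M), detect_communities(M))
    return out
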