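"""Construction of the four physician peer networks and influence weights.

Four networks link a prescriber cohort: patient-sharing (P, weighted by the
number of unique shared patients pooled across payers), medical group (G) and
hospital (H) co-affiliation projections, and training (T: same medical school
or same residency program within a +/-1 year window).  A row-normalized
influence matrix W turns each undirected network into the per-physician
weighted average used by the linear-in-means adoption model: row i holds the
weights physician i places on each peer, summing to 1 (or all-zero for
isolates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

EDGE_COLUMNS = ["physician_a", "physician_b", "weight"]


class DataError(ValueError):
    """Raised on malformed input records (e.g. self-pairs)."""


@dataclass
class PeerNetwork:
    """An undirected peer network over a fixed physician roster.

    Edges are unordered pairs with a positive integer raw weight: the pooled
    unique shared-patient count for kind "P", and 1 for the co-affiliation
    and training kinds.
    """

    kind: str
    nodes: list[str]
    edges: pd.DataFrame  # columns physician_a < physician_b, weight

    def __post_init__(self) -> None:
        if self.kind not in {"P", "G", "H", "T"}:
            raise ValueError(f"unknown network kind {self.kind!r}")
        self.edges = self.edges.reset_index(drop=True)[EDGE_COLUMNS]
        if len(self.edges):
            a = self.edges["physician_a"]
            b = self.edges["physician_b"]
            if (a == b).any():
                raise DataError("self-loop in edge list")
            node_set = set(self.nodes)
            missing = (set(a) | set(b)) - node_set
            if missing:
                raise DataError(f"edge endpoints not in node list: {sorted(missing)[:5]}")
            if self.kind != "P" and not (self.edges["weight"] == 1).all():
                raise DataError(f"network kind {self.kind} must be unweighted")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> frozenset:
        return frozenset(
            frozenset(p) for p in zip(self.edges["physician_a"], self.edges["physician_b"])
        )

    def degree(self) -> pd.Series:
        """Number of distinct peers per physician (zero for isolates)."""
        counts = pd.concat(
            [self.edges["physician_a"], self.edges["physician_b"]]
        ).value_counts()
        return counts.reindex(self.nodes, fill_value=0).astype(int).rename("degree")

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.Graph(kind=self.kind)
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.physician_a, row.physician_b, weight=float(row.weight))
        nx.write_graphml(g, path)


@dataclass
class InfluenceMatrix:
    """Row-stochastic influence weights W over an ordered physician index.

    W[i, j] is the weight physician i places on peer j; rows with at least
    one peer sum to 1, isolate rows are all-zero, the diagonal is zero.
    """

    matrix: sp.csr_matrix
    index: pd.Index
    kind: str = "P"
    no_peer: np.ndarray = field(default=None)  # boolean mask of isolates

    def __post_init__(self) -> None:
        if self.no_peer is None:
            rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
            self.no_peer = rowsum == 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def dot(self, values: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(values, dtype=float)


def _canonical_pairs(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Order each pair so physician_a < physician_b."""
    a = a.astype(str)
    b = b.astype(str)
    swap = a > b
    lo = a.where(~swap, b)
    hi = b.where(~swap, a)
    return pd.DataFrame({"physician_a": lo.values, "physician_b": hi.values})


def build_patient_sharing_network(
    records: pd.DataFrame,
    nodes: Sequence[str],
    min_shared: int = 1,
) -> PeerNetwork:
    """Build the patient-sharing network P from shared-patient records.

    Records carry one row per (unordered physician pair, payer) with the
    number of unique patients shared under that payer.  Counts are pooled
    across payers; pairs with a pooled count >= ``min_shared`` become edges
    whose raw weight is the pooled count.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be a positive integer")
    nodes = list(nodes)
    if len(records) == 0:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
        return PeerNetwork("P", nodes, edges)
    bad = records["physician_a"].astype(str) == records["physician_b"].astype(str)
    if bad.any():
        row = records.index[bad][0]
        raise DataError(f"shared-patient record {row} pairs a physician with themself")
    pairs = _canonical_pairs(records["physician_a"], records["physician_b"])
    pairs["weight"] = records["n_unique_patients"].values
    pooled = (
        pairs.groupby(["physician_a", "physician_b"], as_index=False)["weight"].sum()
    )
    pooled = pooled[pooled["weight"] >= min_shared]
    return PeerNetwork("P", nodes, pooled)


def build_affiliation_network(
    affiliations: pd.DataFrame,
    kind: str,
    nodes: Sequence[str],
) -> PeerNetwork:
    """Project an affiliation bipartite table onto physicians.

    Two physicians are connected iff they share at least one organization of
    the requested kind ("G" medical group, "H" hospital); multiple shared
    organizations still yield a single unit-weight edge (equal influence).
    """
    kind_name = {"G": "group", "H": "hospital"}.get(kind)
    if kind_name is None:
        raise ValueError(f"affiliation network kind must be 'G' or 'H', got {kind!r}")
    nodes = list(nodes)
    rows = affiliations[affiliations["organization_kind"] == kind_name]
    rows = rows.drop_duplicates(["physician_id", "organization_id"])
    if len(rows) == 0:
        return PeerNetwork(kind, nodes, pd.DataFrame(columns=EDGE_COLUMNS))
    merged = rows.merge(rows, on="organization_id", suffixes=("_a", "_b"))
    merged = merged[merged["physician_id_a"] < merged["physician_id_b"]]
    pairs = merged[["physician_id_a", "physician_id_b"]].drop_duplicates()
    edges = pd.DataFrame(
        {
            "physician_a": pairs["physician_id_a"].values,
            "physician_b": pairs["physician_id_b"].values,
            "weight": 1,
        }
    )
    return PeerNetwork(kind, nodes, edges)


def build_training_network(
    physicians: pd.DataFrame,
    year_window: int = 1,
    nodes: Sequence[str] | None = None,
) -> PeerNetwork:
    """Build the training network T from school / residency history.

    Physicians are connected iff they attended the same medical school, or
    completed the same residency program, within ``year_window`` years of
    each other (the window applies to both institution types).  Physicians
    with a missing graduation year are excluded with a logged warning.
    """
    if year_window < 0:
        raise ValueError("year_window must be nonnegative")
    if nodes is None:
        nodes = list(physicians["physician_id"])
    else:
        nodes = list(nodes)

    def pairs_for(inst_col: str, year_col: str) -> pd.DataFrame:
        cols = physicians[["physician_id", inst_col, year_col]].dropna(subset=[inst_col])
        missing = cols[year_col].isna()
        if missing.any():
            log.warning(
                "excluding %d physicians with missing %s from the training network",
                int(missing.sum()), year_col,
            )
            cols = cols[~missing]
        cols = cols.assign(**{year_col: cols[year_col].astype(int)})
        out = []
        # join year with year + offset; offset range covers the window
        for offset in range(0, year_window + 1):
            shifted = cols.assign(**{year_col: cols[year_col] + offset})
            m = cols.merge(shifted, on=[inst_col, year_col], suffixes=("_a", "_b"))
            m = m[m["physician_id_a"] != m["physician_id_b"]]
            out.append(m[["physician_id_a", "physician_id_b"]])
        both = pd.concat(out, ignore_index=True)
        return _canonical_pairs(both["physician_id_a"], both["physician_id_b"])

    school = pairs_for("school_id", "school_grad_year")
    residency = pairs_for("residency_id", "residency_year")
    pairs = pd.concat([school, residency], ignore_index=True).drop_duplicates()
    edges = pairs.assign(weight=1)
    return PeerNetwork("T", nodes, edges)


def row_normalize(network: PeerNetwork, index: Sequence[str] | None = None) -> InfluenceMatrix:
    """Turn a peer network into its row-stochastic influence matrix.

    Each physician's row distributes unit influence over their peers in
    proportion to the raw edge weights (shared-patient counts for P, equal
    shares otherwise); physicians with no peers get an all-zero row.
    """
    idx = pd.Index(index if index is not None else network.nodes)
    pos = pd.Series(np.arange(len(idx)), index=idx)
    n = len(idx)
    if network.n_edges:
        ia = pos.loc[network.edges["physician_a"]].values
        ib = pos.loc[network.edges["physician_b"]].values
        w = network.edges["weight"].values.astype(float)
        rows = np.concatenate([ia, ib])
        cols = np.concatenate([ib, ia])
        data = np.concatenate([w, w])
        mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    else:
        mat = sp.csr_matrix((n, n))
    rowsum = np.asarray(mat.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    mat = sp.diags(inv) @ mat
    return InfluenceMatrix(mat.tocsr(), idx, kind=network.kind, no_peer=rowsum == 0)


def network_overlap(networks: Mapping[str, PeerNetwork]) -> pd.DataFrame:
    """Fraction of the first network's edges also present in the second.

    Returned as a square DataFrame indexed by kind; the diagonal is 1 for
    non-empty networks.  A low overlap (< 20%) is what justifies entering all
    four peer adoption rates in one model.
    """
    if len(networks) < 2:
        raise ValueError("network_overlap requires at least two networks")
    kinds = list(networks)
    sets = {k: networks[k].edge_set() for k in kinds}
    out = pd.DataFrame(np.nan, index=kinds, columns=kinds, dtype=float)
    for k1 in kinds:
        for k2 in kinds:
            if len(sets[k1]) == 0:
                out.loc[k1, k2] = 0.0
            else:
                out.loc[k1, k2] = len(sets[k1] & sets[k2]) / len(sets[k1])
    return out


def degree(network: PeerNetwork) -> pd.Series:
    """Unweighted peer count per physician (degree centrality)."""
    return network.degree()


def write_edge_list(network: PeerNetwork, path) -> None:
    network.edges.to_csv(path, index=False)


def read_edge_list(path, kind: str, nodes: Iterable[str]) -> PeerNetwork:
    edges = pd.read_csv(path)
    if len(edges) == 0:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
    return PeerNetwork(kind, list(nodes), edges)
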