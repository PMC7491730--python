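"""Camper-travel networks: loading, normalization, reduction, and synthesis.

A travel network is a directed, weighted graph over *patches* — recreational
destinations (campgrounds, parks) together with their associated population
centres.  The central object is the trip-fraction matrix ``P``: ``P[i, j]`` is
the fraction of annual camper trips originating at patch ``j`` that end at
patch ``i``, so every column of ``P`` sums to one (column-stochastic).  Trip
fractions weight the between-patch transport of infested firewood in the
metapopulation dynamics.

Because real campground-reservation records are proprietary, the module also
provides a gravity-model generator (:func:`generate_synthetic_network`) that
emulates the salient features of such data: heavy-tailed trip volumes driven by
log-normal population weights, distance decay, and a single dominant urban
focal node where an invasion is typically seeded.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Tolerance for column-stochasticity checks.
COLUMN_TOL = 1e-9

EDGE_COLUMNS = ("origin", "destination", "trips")
NODE_COLUMNS = ("id", "x", "y", "population", "is_focal")


class NetworkError(ValueError):
    """A travel network violated a structural requirement."""


class EdgeListParseError(NetworkError):
    """An edge-list source could not be parsed; the message names the line."""


@dataclass
class NodeRecord:
    """Per-patch metadata: planar position, population weight, focal flag."""

    id: object
    x: float = float("nan")
    y: float = float("nan")
    population: float = 1.0
    is_focal: bool = False

    def __post_init__(self) -> None:
        if self.population < 0:
            raise NetworkError(f"node {self.id!r}: population must be >= 0")


@dataclass
class TravelNetwork:
    """Directed travel network with a column-stochastic trip-fraction matrix.

    Parameters
    ----------
    node_ids
        Ordered patch identifiers; row/column ``i`` of ``trip_fraction``
        corresponds to ``node_ids[i]``.
    trip_fraction
        ``N x N`` matrix ``P`` with ``P[i, j]`` the fraction of trips leaving
        patch ``j`` that arrive at patch ``i``.  Each column must sum to one.
    node_meta
        Optional per-node table indexed by id with columns
        ``x, y, population, is_focal``.
    """

    node_ids: list
    trip_fraction: np.ndarray
    node_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.node_ids = list(self.node_ids)
        P = np.asarray(self.trip_fraction, dtype=float)
        n = len(self.node_ids)
        if n < 2:
            raise NetworkError(f"a travel network needs at least 2 patches, got {n}")
        if len(set(self.node_ids)) != n:
            raise NetworkError("duplicate node ids")
        if P.shape != (n, n):
            raise NetworkError(
                f"trip_fraction shape {P.shape} does not match {n} node ids"
            )
        if np.any(P < -COLUMN_TOL) or np.any(P > 1 + COLUMN_TOL):
            raise NetworkError("trip fractions must lie in [0, 1]")
        colsums = P.sum(axis=0)
        bad = np.flatnonzero(np.abs(colsums - 1.0) > COLUMN_TOL)
        if bad.size:
            raise NetworkError(
                f"columns {bad.tolist()} are not stochastic (sums {colsums[bad]})"
            )
        if self.node_meta is not None:
            focal = self.node_meta["is_focal"].astype(bool)
            if int(focal.sum()) > 1:
                raise NetworkError("at most one node may be flagged focal")
        self.trip_fraction = P

    # -- basic queries ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise NetworkError(f"unknown node id {node_id!r}") from None

    @property
    def focal_node(self):
        """Id of the node flagged focal, or None."""
        if self.node_meta is None:
            return None
        flagged = self.node_meta.index[self.node_meta["is_focal"].astype(bool)]
        return flagged[0] if len(flagged) else None

    def fingerprint(self) -> str:
        """Short content hash of (node ids, trip fractions) for provenance."""
        h = hashlib.sha256()
        h.update(repr(self.node_ids).encode())
        h.update(np.ascontiguousarray(self.trip_fraction).tobytes())
        return h.hexdigest()[:16]

    # -- serialization ----------------------------------------------------

    def to_csv(self, edge_path, node_path=None) -> None:
        """Write the round-trippable CSV pair (fraction edge list + node table)."""
        i_idx, j_idx = np.nonzero(self.trip_fraction.T)  # iterate by origin
        rows = {
            "origin": [self.node_ids[j] for j in i_idx],
            "destination": [self.node_ids[i] for i in j_idx],
            "trips": self.trip_fraction.T[i_idx, j_idx],
        }
        pd.DataFrame(rows).to_csv(edge_path, index=False)
        if node_path is not None:
            meta = self.node_meta
            if meta is None:
                meta = pd.DataFrame(
                    {
                        "x": np.nan,
                        "y": np.nan,
                        "population": 1.0,
                        "is_focal": False,
                    },
                    index=pd.Index(self.node_ids, name="id"),
                )
            meta.reset_index().rename(columns={"index": "id"}).to_csv(
                node_path, index=False
            )

    @classmethod
    def from_csv(cls, edge_path, node_path=None, zero_trip_policy="drop"):
        return load_trip_table(edge_path, node_path, zero_trip_policy=zero_trip_policy)


def normalize_trip_fractions(count_matrix, zero_column_policy: str = "error"):
    """Convert a nonnegative trip-count matrix to column-stochastic fractions.

    Each column (one origin patch) is divided by its total outgoing trips.
    Columns with zero total are handled per ``zero_column_policy``:
    ``"error"`` raises; ``"self_loop"`` assigns the origin a unit self-loop
    (all its trips stay home).  Dropping empty origins is a network-level
    operation and is handled by :func:`load_trip_table`.
    """
    C = np.array(count_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise NetworkError(f"count matrix must be square, got shape {C.shape}")
    if np.any(C < 0):
        raise NetworkError("trip counts must be nonnegative")
    colsums = C.sum(axis=0)
    empty = np.flatnonzero(colsums <= 0)
    if empty.size:
        if zero_column_policy == "self_loop":
            C[empty, empty] = 1.0
            colsums = C.sum(axis=0)
        elif zero_column_policy == "error":
            raise NetworkError(
                f"columns {empty.tolist()} have zero outgoing trips"
            )
        else:
            raise NetworkError(
                f"unknown zero_column_policy {zero_column_policy!r} "
                "(matrix-level policies: 'error', 'self_loop')"
            )
    return C / colsums


def _drop_empty_origins(counts: np.ndarray, ids: list):
    """Iteratively remove nodes with zero outgoing trips (drops can cascade)."""
    keep = np.arange(len(ids))
    C = counts
    while True:
        colsums = C.sum(axis=0)
        alive = colsums > 0
        if alive.all():
            break
        if not alive.any():
            raise NetworkError("every node has zero outgoing trips")
        keep = keep[alive]
        C = C[np.ix_(alive, alive)]
    return C, [ids[i] for i in keep]


def load_trip_table(edge_list_source, node_table_source=None, zero_trip_policy="drop"):
    """Read a trip-count edge list (CSV ``origin,destination,trips``) into a network.

    Counts are converted to column-stochastic trip fractions.  Duplicate
    (origin, destination) rows are summed with a warning.  Nodes with zero
    total outgoing trips are handled per ``zero_trip_policy``:
    ``"drop"`` (default) removes them, ``"self_loop"`` keeps them with a unit
    self-loop, ``"error"`` raises.
    """
    if zero_trip_policy not in ("drop", "self_loop", "error"):
        raise NetworkError(f"unknown zero_trip_policy {zero_trip_policy!r}")
    edges = pd.read_csv(edge_list_source)
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise EdgeListParseError(
            f"edge list is missing columns {missing}; expected header "
            f"{','.join(EDGE_COLUMNS)}"
        )
    trips = pd.to_numeric(edges["trips"], errors="coerce")
    bad = trips.isna() | edges["origin"].isna() | edges["destination"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise EdgeListParseError(f"malformed edge-list row at line {line}")
    neg = trips < 0
    if neg.any():
        line = int(neg.idxmax()) + 2
        raise NetworkError(f"negative trip count at line {line}")
    edges = edges.assign(trips=trips)

    dup = edges.duplicated(subset=["origin", "destination"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (origin, destination) rows summed",
            stacklevel=2,
        )
        edges = edges.groupby(["origin", "destination"], as_index=False, sort=False)[
            "trips"
        ].sum()

    edge_ids = pd.unique(pd.concat([edges["origin"], edges["destination"]]))
    node_meta = None
    if node_table_source is not None:
        nodes = pd.read_csv(node_table_source)
        missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
        if missing:
            raise EdgeListParseError(f"node table is missing columns {missing}")
        if nodes["id"].duplicated().any():
            raise NetworkError("duplicate ids in node table")
        known = set(nodes["id"])
        unknown = [i for i in edge_ids if i not in known]
        if unknown:
            raise NetworkError(
                f"edge list references ids absent from node table: {unknown[:5]}"
            )
        ids = nodes["id"].tolist()
        node_meta = nodes.set_index("id")
        node_meta["is_focal"] = node_meta["is_focal"].astype(bool)
    else:
        ids = sorted(edge_ids, key=lambda v: (str(type(v)), v))

    pos = {v: i for i, v in enumerate(ids)}
    C = np.zeros((len(ids), len(ids)))
    C[
        edges["destination"].map(pos).to_numpy(),
        edges["origin"].map(pos).to_numpy(),
    ] = edges["trips"].to_numpy()

    if zero_trip_policy == "drop":
        C, ids = _drop_empty_origins(C, ids)
        if node_meta is not None:
            node_meta = node_meta.loc[ids]
        P = normalize_trip_fractions(C, zero_column_policy="error")
    else:
        P = normalize_trip_fractions(C, zero_column_policy=zero_trip_policy)
    return TravelNetwork(ids, P, node_meta)


def _undirected_support(network: TravelNetwork) -> nx.Graph:
    """Undirected support graph: an edge if trips flow either way, no self-loops."""
    P = network.trip_fraction
    G = nx.Graph()
    G.add_nodes_from(network.node_ids)
    sym = (P > 0) | (P.T > 0)
    np.fill_diagonal(sym, False)
    i_idx, j_idx = np.nonzero(np.triu(sym))
    G.add_edges_from(
        (network.node_ids[i], network.node_ids[j]) for i, j in zip(i_idx, j_idx)
    )
    return G


def k_core_reduce(network: TravelNetwork, k: int) -> TravelNetwork:
    """Restrict the network to its k-core (largest component), renormalized.

    Degree is computed on the undirected support of the graph.  The maximal
    subgraph in which every node has degree >= k is taken; if it is
    disconnected, the largest connected component is kept.  Trip fractions are
    re-normalized per column on the surviving subgraph; a surviving node whose
    out-trips were all pruned receives a unit self-loop (self-loops never enter
    the transport dynamics, which sum over j != i).
    """
    if k < 1:
        raise NetworkError(f"k must be >= 1, got {k}")
    core = nx.k_core(_undirected_support(network), k)
    if core.number_of_nodes() == 0:
        raise NetworkError(f"the {k}-core of the network is empty")
    components = sorted(
        nx.connected_components(core),
        key=lambda c: (-len(c), min(network.index_of(v) for v in c)),
    )
    keep = set(components[0])
    if len(keep) < 2:
        raise NetworkError(f"the {k}-core has fewer than 2 nodes")
    idx = [i for i, v in enumerate(network.node_ids) if v in keep]
    ids = [network.node_ids[i] for i in idx]
    sub = network.trip_fraction[np.ix_(idx, idx)]
    P = normalize_trip_fractions(sub, zero_column_policy="self_loop")
    meta = network.node_meta.loc[ids] if network.node_meta is not None else None
    return TravelNetwork(ids, P, meta)


def betweenness_scores(network: TravelNetwork) -> dict:
    """Weighted shortest-path betweenness of every node.

    Edge distances are ``max(P) + 1 - P[i, j]`` (global off-diagonal maximum),
    so heavily-travelled routes are short.  Scores are the unnormalized
    Brandes betweenness on the directed graph, endpoints excluded.
    """
    P = network.trip_fraction
    off = P.copy()
    np.fill_diagonal(off, 0.0)
    pmax = off.max()
    G = nx.DiGraph()
    G.add_nodes_from(network.node_ids)
    dst, src = np.nonzero(off)
    for i, j in zip(dst, src):
        G.add_edge(
            network.node_ids[j],
            network.node_ids[i],
            distance=pmax + 1.0 - off[i, j],
        )
    return nx.betweenness_centrality(G, normalized=False, weight="distance")


def quarantine_node_selection(network: TravelNetwork, n_nodes: int) -> list:
    """The ``n_nodes`` patches of highest betweenness centrality.

    Candidate quarantine sets target the nodes most likely to sit on
    high-traffic routes.  Ties (scores equal after rounding to 9 decimals,
    which absorbs float accumulation noise) are broken by ascending node id.
    """
    if not 0 <= n_nodes <= network.n:
        raise NetworkError(
            f"n_nodes must be in [0, {network.n}], got {n_nodes}"
        )
    if n_nodes == 0:
        return []
    scores = betweenness_scores(network)
    order = sorted(
        network.node_ids,
        key=lambda v: (-round(scores[v], 9), network.index_of(v)),
    )
    return order[:n_nodes]


def generate_synthetic_network(
    n_nodes: int = 100,
    seed: int = 0,
    gravity_exponent: float = 2.0,
    population_spread: float = 1.0,
    focal_boost: float = 50.0,
) -> TravelNetwork:
    """Synthesize a camper-travel network with a gravity trip model.

    Patches are placed uniformly in the unit square with log-normal population
    weights (``sigma = population_spread``); the largest patch is boosted by
    ``focal_boost`` and flagged focal, standing in for the dominant urban
    centre where reservation data concentrate and invasions are seeded.  Raw
    trips obey a gravity law, ``trips(i <- j) ∝ pop_i * pop_j / dist(i, j)
    ** gravity_exponent`` with no self-trips, then columns are normalized to
    trip fractions.  The same arguments always yield a bit-identical network.
    """
    if n_nodes < 2:
        raise NetworkError(f"n_nodes must be >= 2, got {n_nodes}")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(size=(n_nodes, 2))
    population = rng.lognormal(mean=0.0, sigma=population_spread, size=n_nodes)
    focal = int(np.argmax(population))
    population[focal] *= focal_boost

    delta = xy[:, None, :] - xy[None, :, :]
    dist = np.maximum(np.hypot(delta[..., 0], delta[..., 1]), 1e-6)
    with np.errstate(divide="ignore"):
        W = np.outer(population, population) / dist**gravity_exponent
    np.fill_diagonal(W, 0.0)
    P = normalize_trip_fractions(W, zero_column_policy="error")

    meta = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "population": population,
            "is_focal": np.arange(n_nodes) == focal,
        },
        index=pd.Index(range(n_nodes), name="id"),
    )
    return TravelNetwork(list(range(n_nodes)), P, meta)
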