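"""Protein structure networks and communication paths.

Residues are nodes; an edge joins two residues whose normalized interaction
strength,

    I(i, j) = 100 * n_ij / sqrt(N_i * N_j),

exceeds a cutoff I_min, where n_ij counts heavy-atom pairs (one atom from
each residue) within the contact cutoff and N_i, N_j are per-residue-type
normalization constants.  The I_min cutoff is chosen where the size of the
largest connected cluster drops most steeply as I_min is raised.  Over an
ensemble, edges present in at least a stability fraction of frames form
the dynamically stable network.  Shortest communication paths between a
source and a sink residue are computed per frame with Floyd-Warshall and
averaged; residues recurring across frames form the consensus path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structio import Ensemble, Residue, ResidueKey, Snapshot

__all__ = [
    "DEFAULT_NORMALIZATION",
    "NetworkParams",
    "ResidueNetwork",
    "EnsembleNetwork",
    "PathResult",
    "interaction_strength",
    "build_network",
    "largest_cluster_profile",
    "select_imin",
    "stable_network",
    "shortest_path",
    "ensemble_paths",
    "common_path_residues",
]

#: per-residue-type normalization constants (long-run mean numbers of
#: interacting atom pairs, literature-style magnitudes); editable via
#: NetworkParams.normalization
DEFAULT_NORMALIZATION = {
    "ALA": 55.76, "ARG": 93.79, "ASN": 73.41, "ASP": 75.15, "CYS": 54.95,
    "GLN": 78.13, "GLU": 78.76, "GLY": 47.31, "HIS": 83.73, "ILE": 67.94,
    "LEU": 72.26, "LYS": 69.63, "MET": 69.26, "PHE": 93.30, "PRO": 54.43,
    "SER": 59.39, "THR": 63.70, "TRP": 106.70, "TYR": 100.71, "VAL": 62.37,
}


class NetworkError(ValueError):
    pass


@dataclass
class NetworkParams:
    contact_cutoff: float = 4.5  # Å, heavy-atom contact distance
    i_min: float = 2.5  # % interaction strength cutoff
    exclude_neighbors: int = 2  # drop intra-chain edges with |Δseq| <= this
    normalization: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NORMALIZATION)
    )

    def __post_init__(self) -> None:
        if self.contact_cutoff <= 0:
            raise NetworkError("contact_cutoff must be positive")
        if self.i_min < 0:
            raise NetworkError("i_min must be non-negative")

    def norm_constant(self, res_name: str) -> float:
        try:
            return self.normalization[res_name]
        except KeyError:
            raise NetworkError(
                f"no normalization constant for residue type {res_name!r}"
            ) from None


@dataclass
class ResidueNetwork:
    """Undirected residue graph; edge strengths are percentages >= i_min."""

    nodes: list[ResidueKey]
    edges: dict[tuple[ResidueKey, ResidueKey], float]  # key: sorted node pair
    i_min: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), s in self.edges.items():
            g.add_edge(u, v, strength=s)
        return g

    def neighbors(self, node: ResidueKey) -> list[ResidueKey]:
        out = []
        for u, v in self.edges:
            if u == node:
                out.append(v)
            elif v == node:
                out.append(u)
        return sorted(out)


@dataclass
class EnsembleNetwork:
    per_frame: list[ResidueNetwork]
    edge_frequency: dict[tuple[ResidueKey, ResidueKey], float]
    stable_edges: dict[tuple[ResidueKey, ResidueKey], float]  # mean strength
    stability: float

    def stable(self) -> ResidueNetwork:
        nodes = self.per_frame[0].nodes if self.per_frame else []
        return ResidueNetwork(
            nodes=list(nodes),
            edges=dict(self.stable_edges),
            i_min=self.per_frame[0].i_min if self.per_frame else 0.0,
        )


@dataclass
class PathResult:
    source: ResidueKey
    sink: ResidueKey
    per_frame_paths: list[Optional[list[ResidueKey]]]
    average_length: Optional[float]  # mean hop count over frames with a path
    consensus_nodes: list[ResidueKey]  # present in >= consensus fraction of paths
    stable_path: Optional[list[ResidueKey]] = None


def _edge_key(u: ResidueKey, v: ResidueKey) -> tuple[ResidueKey, ResidueKey]:
    return (u, v) if u <= v else (v, u)


def interaction_strength(res_i: Residue, res_j: Residue, params: NetworkParams) -> float:
    """Normalized percentage interaction strength between two residues."""
    xi, xj = res_i.heavy_coords(), res_j.heavy_coords()
    d2 = ((xi[:, None, :] - xj[None, :, :]) ** 2).sum(axis=2)
    n_ij = int((d2 <= params.contact_cutoff**2).sum())
    ni = params.norm_constant(res_i.name)
    nj = params.norm_constant(res_j.name)
    return 100.0 * n_ij / np.sqrt(ni * nj)


def _all_pair_strengths(
    snapshot: Snapshot, params: NetworkParams
) -> dict[tuple[int, int], float]:
    """Contact counts for all residue pairs via one KD-tree pass."""
    coords = []
    owner = []
    for idx, res in enumerate(snapshot):
        hc = res.heavy_coords()
        coords.append(hc)
        owner.extend([idx] * len(hc))
    pts = np.concatenate(coords)
    owner = np.asarray(owner)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.contact_cutoff, output_type="ndarray")
    counts: dict[tuple[int, int], int] = {}
    if len(pairs):
        ri, rj = owner[pairs[:, 0]], owner[pairs[:, 1]]
        keep = ri != rj
        for a, b in zip(ri[keep], rj[keep]):
            key = (int(a), int(b)) if a < b else (int(b), int(a))
            counts[key] = counts.get(key, 0) + 1
    residues = snapshot.residues
    norms = np.array([params.norm_constant(r.name) for r in residues])
    return {
        (a, b): 100.0 * n / np.sqrt(norms[a] * norms[b]) for (a, b), n in counts.items()
    }


def build_network(snapshot: Snapshot, params: Optional[NetworkParams] = None) -> ResidueNetwork:
    """Residue-interaction network of one snapshot.

    Edges keep pairs with strength >= i_min, excluding intra-chain pairs
    within ``exclude_neighbors`` in sequence (covalent neighbours would
    otherwise dominate every path).
    """
    params = params or NetworkParams()
    residues = snapshot.residues
    strengths = _all_pair_strengths(snapshot, params)
    edges: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for (a, b), s in strengths.items():
        if s < params.i_min:
            continue
        ra, rb = residues[a], residues[b]
        if (
            ra.chain_id == rb.chain_id
            and abs(ra.number - rb.number) <= params.exclude_neighbors
        ):
            continue
        edges[_edge_key(ra.key, rb.key)] = s
    return ResidueNetwork(
        nodes=[r.key for r in residues], edges=edges, i_min=params.i_min
    )


def largest_cluster_profile(
    snapshot: Snapshot,
    i_min_grid: Optional[Sequence[float]] = None,
    params: Optional[NetworkParams] = None,
) -> list[tuple[float, int]]:
    """Size of the largest connected cluster at each I_min of the grid.

    Default grid: 0 to 10% in 0.5% steps.  Sizes are non-increasing along
    the (strictly increasing) grid.
    """
    params = params or NetworkParams()
    if i_min_grid is None:
        i_min_grid = [0.5 * k for k in range(21)]
    grid = list(i_min_grid)
    if not grid:
        raise NetworkError("empty I_min grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise NetworkError("I_min grid must be strictly increasing")
    strengths = _all_pair_strengths(snapshot, params)
    residues = snapshot.residues
    out = []
    for imin in grid:
        g = nx.Graph()
        g.add_nodes_from(range(len(residues)))
        for (a, b), s in strengths.items():
            ra, rb = residues[a], residues[b]
            if (
                ra.chain_id == rb.chain_id
                and abs(ra.number - rb.number) <= params.exclude_neighbors
            ):
                continue
            if s >= imin:
                g.add_edge(a, b)
        largest = max((len(c) for c in nx.connected_components(g)), default=0)
        out.append((float(imin), int(largest)))
    return out


def select_imin(profile: Sequence[tuple[float, int]]) -> Optional[float]:
    """Grid value where the largest-cluster size drops the most.

    Returns the I_min at which the decrease from the previous grid point is
    maximal (first on ties), or ``None`` when the profile is constant — the
    caller then falls back to the conventional default of 2.5.
    """
    if not profile:
        raise NetworkError("empty profile")
    best_drop = 0
    best_val: Optional[float] = None
    for (v0, s0), (v1, s1) in zip(profile, profile[1:]):
        drop = s0 - s1
        if drop > best_drop:
            best_drop = drop
            best_val = v1
    return best_val


def stable_network(
    ensemble: Ensemble,
    params: Optional[NetworkParams] = None,
    stability: float = 0.5,
) -> EnsembleNetwork:
    """Per-frame networks plus the dynamically stable edge set.

    An edge is stable when it is present (at I_min) in at least the
    ``stability`` fraction of frames (inclusive).  Stable-edge strength is
    the mean over the frames where the edge exists.
    """
    params = params or NetworkParams()
    per_frame = [build_network(s, params) for s in ensemble]
    n = len(per_frame)
    count: dict[tuple, int] = {}
    total: dict[tuple, float] = {}
    for net in per_frame:
        for e, s in net.edges.items():
            count[e] = count.get(e, 0) + 1
            total[e] = total.get(e, 0.0) + s
    freq = {e: c / n for e, c in count.items()}
    stable = {e: total[e] / count[e] for e, f in freq.items() if f >= stability}
    return EnsembleNetwork(
        per_frame=per_frame, edge_frequency=freq, stable_edges=stable, stability=stability
    )


def _floyd_warshall(n: int, adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances by Floyd-Warshall (vectorised min-plus)."""
    dist = adj.copy()
    for k in range(n):
        np.minimum(dist, dist[:, k, None] + dist[None, k, :], out=dist)
    return dist


def shortest_path(
    network: ResidueNetwork,
    source: ResidueKey,
    sink: ResidueKey,
    weighted: bool = False,
) -> Optional[list[ResidueKey]]:
    """Shortest communication path from source to sink, or None if none.

    Hop-count paths by default (the path with the least residues); with
    ``weighted=True`` edge lengths are 1/strength so stronger interactions
    are preferred.  Among equal-length shortest paths the lexicographically
    smallest residue-key sequence is returned, which makes the result
    deterministic.
    """
    source, sink = tuple(source), tuple(sink)
    nodes = sorted(network.nodes)
    index = {u: k for k, u in enumerate(nodes)}
    if source not in index or sink not in index:
        raise KeyError(f"source/sink not in network: {source}, {sink}")
    n = len(nodes)
    adj = np.full((n, n), np.inf)
    np.fill_diagonal(adj, 0.0)
    for (u, v), s in network.edges.items():
        w = (1.0 / s) if weighted else 1.0
        adj[index[u], index[v]] = w
        adj[index[v], index[u]] = w
    dist = _floyd_warshall(n, adj)
    si, ti = index[source], index[sink]
    if not np.isfinite(dist[si, ti]):
        return None
    # greedy reconstruction on the distance field: at each step take the
    # smallest-keyed neighbour that stays on a shortest path
    path = [source]
    cur = si
    while cur != ti:
        remaining = dist[cur, ti]
        nxt = None
        for v in range(n):  # nodes sorted => first hit is lexicographically least
            if np.isfinite(adj[cur, v]) and v != cur:
                if abs(adj[cur, v] + dist[v, ti] - remaining) <= 1e-9:
                    nxt = v
                    break
        if nxt is None:  # numerically unreachable; should not happen
            return None
        path.append(nodes[nxt])
        cur = nxt
    return path


def ensemble_paths(
    ensemble: Ensemble,
    source: ResidueKey,
    sink: ResidueKey,
    params: Optional[NetworkParams] = None,
    stability: float = 0.5,
    consensus_fraction: float = 0.5,
    weighted: bool = False,
) -> PathResult:
    """Shortest source→sink path in every frame, averaged and summarised.

    ``average_length`` is the mean hop count over frames that have a path
    (None when no frame does).  ``consensus_nodes`` are residues appearing
    in at least ``consensus_fraction`` of the per-frame paths.  The path on
    the dynamically stable network is reported alongside.
    """
    params = params or NetworkParams()
    ens_net = stable_network(ensemble, params, stability)
    source, sink = tuple(source), tuple(sink)
    per_frame_paths = [
        shortest_path(net, source, sink, weighted=weighted) for net in ens_net.per_frame
    ]
    lengths = [len(p) - 1 for p in per_frame_paths if p is not None]
    average = float(np.mean(lengths)) if lengths else None
    found = [p for p in per_frame_paths if p is not None]
    consensus: list[ResidueKey] = []
    if found:
        counts: dict[ResidueKey, int] = {}
        for p in found:
            for node in p:
                counts[node] = counts.get(node, 0) + 1
        consensus = sorted(
            node for node, c in counts.items() if c / len(found) >= consensus_fraction
        )
    stable_path = shortest_path(ens_net.stable(), source, sink, weighted=weighted)
    return PathResult(
        source=source,
        sink=sink,
        per_frame_paths=per_frame_paths,
        average_length=average,
        consensus_nodes=consensus,
        stable_path=stable_path,
    )


def common_path_residues(results: Sequence[PathResult]) -> set[ResidueKey]:
    """Residues shared by the consensus paths of all results.

    Sources and sinks are excluded: the interest is in shared
    intermediates — the residues every communication route passes through.
    """
    if len(results) < 2:
        raise NetworkError("need at least two path results")
    common: Optional[set] = None
    endpoints = set()
    for r in results:
        nodes = set(r.consensus_nodes)
        endpoints |= {tuple(r.source), tuple(r.sink)}
        common = nodes if common is None else (common & nodes)
    return (common or set()) - endpoints
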