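"""Protein-interaction graphs and shortest-path recurrence analysis.

The central statistic is the *recurrence count*: for a set of seed proteins,
every unordered seed pair (s, t) contributes its unweighted (hop-count)
shortest paths, and R(v) is the total number of distinct shortest seed-pair
paths that contain node v as an interior vertex (R(e) likewise for edges).
Highly recurrent non-seed nodes are "bridge" candidates: intermediaries that
repeatedly carry information flow between the seeds even when the seeds have
no direct interactions.

Counts are exact. For a pair (s, t) with shortest distance d and path count
sigma_st, a node v lies on sigma_sv * sigma_vt shortest paths whenever
d_sv + d_vt = d; an edge (u, v) lies on sigma_su * sigma_vt paths whenever
d_su + 1 + d_vt = d. Both identities are asserted against the conservation
laws sum_v = sigma_st * (d - 1) and sum_e = sigma_st * d on every run.
"""

from __future__ import annotations

import re
import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class InteractionGraph:
    """Undirected simple graph with per-edge ``strength`` in (0, 1]."""

    graph: nx.Graph
    source: str = "<memory>"
    dialect: str = "fractional"
    threshold: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class SeedSet:
    """Ordered unique protein identifiers used as path endpoints."""

    members: tuple
    origin: str = "manual"

    def __post_init__(self):
        if len(self.members) != len(set(self.members)):
            raise ValueError("seed set members must be unique")
        if len(self.members) < 2:
            raise ValueError("seed set needs at least 2 members")


@dataclass
class PairStats:
    source: str
    target: str
    distance: int
    n_paths: int
    reachable: bool


@dataclass
class PathRecurrenceReport:
    node_recurrence: dict
    edge_recurrence: dict
    pair_stats: list
    seeds_used: tuple
    seeds_missing: tuple = ()
    unreachable_pairs: tuple = ()
    empty: bool = False

    def ranked_nodes(self) -> pd.DataFrame:
        rows = [
            {"node": v, "recurrence": r, "is_seed": v in self.seeds_used}
            for v, r in self.node_recurrence.items()
        ]
        df = pd.DataFrame(rows, columns=["node", "recurrence", "is_seed"])
        return df.sort_values(
            ["recurrence", "node"], ascending=[False, True]
        ).reset_index(drop=True)


def load_edges(path, threshold: float = 0.15, dialect: str | None = None) -> InteractionGraph:
    """Read a STRING-style ``protein1 protein2 combined_score`` edge list.

    Scores on the 0-1000 STRING scale are detected automatically (any score
    above 1) and rescaled to (0, 1]; only edges with strength *strictly*
    greater than ``threshold`` are retained.  Duplicate undirected edges keep
    the maximum strength; self-loops are dropped.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1 and parts and not _is_number(parts[-1]):
                continue  # header row
            if len(parts) < 3 or not _is_number(parts[-1]):
                raise ValueError(f"{path}: unparseable edge at line {lineno}: {line!r}")
            raw.append((parts[0], parts[1], float(parts[-1])))
    if dialect is None:
        dialect = "string" if any(s > 1.0 for _, _, s in raw) else "fractional"
    scale = 1000.0 if dialect == "string" else 1.0
    G = nx.Graph()
    for a, b, score in raw:
        if a == b:
            continue
        strength = score / scale
        if strength > threshold:
            if G.has_edge(a, b):
                G[a][b]["strength"] = max(G[a][b]["strength"], strength)
            else:
                G.add_edge(a, b, strength=strength)
    if G.number_of_edges() == 0:
        warnings.warn(f"{path}: no edges retained at threshold {threshold}", stacklevel=2)
    return InteractionGraph(graph=G, source=str(path), dialect=dialect, threshold=threshold)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


_FRAGMENT_SUFFIX = re.compile(r"_\d+$")


def collapse_fragment(antigen_id: str) -> str:
    """Map an antigen-fragment identifier (e.g. ``LOXL3_2``) to its protein."""
    return _FRAGMENT_SUFFIX.sub("", antigen_id)


def seed_from_associations(assoc: pd.DataFrame, parameter: str, k: int = 10) -> SeedSet:
    """Top-``k`` proteins by descending correlation with one clinical parameter.

    Antigen fragments of the same protein are collapsed keeping the maximum
    rho.  Ties at the k-th rank are broken alphabetically (and logged).
    """
    sub = assoc[(assoc["parameter"] == parameter) & assoc["rho"].notna()].copy()
    if sub.empty:
        raise ValueError(f"no associations available for parameter {parameter!r}")
    sub["protein"] = sub["antigen"].map(collapse_fragment)
    best = sub.groupby("protein")["rho"].max().reset_index()
    best = best.sort_values(["rho", "protein"], ascending=[False, True]).reset_index(drop=True)
    if len(best) < k:
        warnings.warn(
            f"only {len(best)} distinct proteins for {parameter!r}; requested top {k}",
            stacklevel=2,
        )
        chosen = best
    else:
        kth = best["rho"].iloc[k - 1]
        if (best["rho"] == kth).sum() > 1:
            warnings.warn(
                f"tie at rank {k} (rho={kth:.4g}) broken alphabetically", stacklevel=2
            )
        chosen = best.iloc[:k]
    return SeedSet(members=tuple(chosen["protein"]), origin=f"top-{k}:{parameter}")


def _bfs_counts(adj: dict, source):
    """Hop distances and shortest-path counts from ``source`` (exact ints)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                sigma[v] = sigma[u]
                queue.append(v)
            elif dist[v] == du + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def shortest_path_recurrence(
    igraph: InteractionGraph | nx.Graph,
    seeds: SeedSet | list | tuple,
) -> PathRecurrenceReport:
    """Exact node/edge recurrence counts over all unordered seed pairs.

    Seeds absent from the graph are reported and excluded; unreachable pairs
    are skipped and listed.  Seed endpoints do not accumulate interior counts
    for their own pair but may as interiors of other pairs.
    """
    G = igraph.graph if isinstance(igraph, InteractionGraph) else igraph
    if G.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    members = seeds.members if isinstance(seeds, SeedSet) else tuple(seeds)
    present = tuple(s for s in members if s in G)
    missing = tuple(s for s in members if s not in G)
    if len(present) < 2:
        raise ValueError("fewer than 2 seeds present in the graph")

    adj = {v: list(G.neighbors(v)) for v in G}
    bfs = {s: _bfs_counts(adj, s) for s in present}
    node_R = {v: 0 for v in G}
    edge_R = {tuple(sorted(e)): 0 for e in G.edges()}
    pair_stats = []
    unreachable = []

    for i, s in enumerate(present):
        dist_s, sig_s = bfs[s]
        for t in present[i + 1 :]:
            if t not in dist_s:
                unreachable.append((s, t))
                pair_stats.append(PairStats(s, t, -1, 0, False))
                continue
            dist_t, sig_t = bfs[t]
            d = dist_s[t]
            sigma_st = sig_s[t]
            pair_stats.append(PairStats(s, t, d, sigma_st, True))
            node_sum = 0
            for v in dist_s:
                if v == s or v == t or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d:
                    c = sig_s[v] * sig_t[v]
                    node_R[v] += c
                    node_sum += c
            edge_sum = 0
            for u, v in edge_R:
                c = 0
                if u in dist_s and v in dist_t and dist_s[u] + 1 + dist_t[v] == d:
                    c += sig_s[u] * sig_t[v]
                if v in dist_s and u in dist_t and dist_s[v] + 1 + dist_t[u] == d:
                    c += sig_s[v] * sig_t[u]
                if c:
                    edge_R[(u, v)] += c
                    edge_sum += c
            # conservation identities, exact in integer arithmetic
            assert node_sum == sigma_st * (d - 1), (s, t, node_sum, sigma_st, d)
            assert edge_sum == sigma_st * d, (s, t, edge_sum, sigma_st, d)

    reachable_any = any(p.reachable for p in pair_stats)
    return PathRecurrenceReport(
        node_recurrence=node_R,
        edge_recurrence=edge_R,
        pair_stats=pair_stats,
        seeds_used=present,
        seeds_missing=missing,
        unreachable_pairs=tuple(unreachable),
        empty=not reachable_any,
    )


def enumerate_all_shortest_paths(
    igraph: InteractionGraph | nx.Graph, s, t, cap: int = 1_000_000
) -> list:
    """Every distinct shortest s-t path as a node sequence (test oracle).

    Depth-first traversal of the BFS predecessor structure; errors out (never
    truncates) if the exact path count would exceed ``cap``.
    """
    G = igraph.graph if isinstance(igraph, InteractionGraph) else igraph
    if s not in G or t not in G:
        raise ValueError("endpoints must be graph nodes")
    if s == t:
        return [[s]]
    adj = {v: list(G.neighbors(v)) for v in G}
    dist, sigma = _bfs_counts(adj, s)
    if t not in dist:
        return []
    if sigma[t] > cap:
        raise ValueError(f"{sigma[t]} shortest paths exceed cap {cap}")
    preds = {}
    for u in dist:
        for v in adj[u]:
            if v in dist and dist[v] == dist[u] + 1:
                preds.setdefault(v, []).append(u)
    paths = []
    stack = [(t, [t])]
    while stack:
        node, suffix = stack.pop()
        if node == s:
            paths.append(list(reversed(suffix)))
            continue
        for u in preds.get(node, ()):
            stack.append((u, suffix + [u]))
    return paths


def export_network(
    report: PathRecurrenceReport,
    igraph: InteractionGraph,
    graphml_path,
    table_path=None,
) -> None:
    """Write the annotated graph (GraphML) and a ranked intermediary table.

    Node attributes: ``recurrence`` and ``is_seed``; edge attributes:
    ``strength`` and ``recurrence``.
    """
    G = igraph.graph.copy()
    for v in G.nodes:
        G.nodes[v]["recurrence"] = int(report.node_recurrence.get(v, 0))
        G.nodes[v]["is_seed"] = bool(v in report.seeds_used)
    for u, v in G.edges:
        G[u][v]["recurrence"] = int(report.edge_recurrence.get(tuple(sorted((u, v))), 0))
    nx.write_graphml(G, graphml_path)
    if table_path is not None:
        report.ranked_nodes().to_csv(table_path, index=False)
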