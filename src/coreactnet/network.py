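"""Co-reactivation networks: correlation matrices, signed graphs, and topology.

Nodes are brain regions; an edge weight is the Pearson correlation, across
animals of one experimental group, of the double-labeled cell percentage
between two regions. Networks are built from the positive, the negative, or
both ("combined") correlations; no magnitude threshold is applied by default,
sign is the only filter.

Shortest-path measures (betweenness, closeness, efficiency) treat edge length
as 1/weight, the usual convention for correlation networks: a stronger
co-reactivation is a shorter functional distance. In combined (signed) mode,
path-based measures, the clustering coefficient, eigenvector centrality and
community detection operate on the absolute correlations, while node strength
uses a signed decomposition that scales the negative contribution by its share
of total connectivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import DEFAULT_REGIONS, ValidationError

CENTRALITY_NAMES = ("Str", "Eig", "Bet", "Clo")
SIGN_MODES = ("positive", "negative", "combined")


# ---------------------------------------------------------------------------
# correlation matrices


@dataclass
class GroupCorrelationMatrix:
    """Symmetric region x region Pearson matrix for one experimental group."""

    group: str
    regions: list
    r: pd.DataFrame
    n_animals: int

    @property
    def n_cells(self) -> int:
        """Total matrix cells, diagonal included (R regions -> R**2)."""
        return len(self.regions) ** 2

    @property
    def n_unique_pairs(self) -> int:
        """Unique unordered region pairs: R(R-1)/2."""
        r = len(self.regions)
        return r * (r - 1) // 2


def correlation_matrix(
    react: pd.DataFrame,
    group: str,
    *,
    regions: list | None = None,
    value: str = "double_pct",
    min_animals: int = 3,
) -> GroupCorrelationMatrix:
    """Across-animal Pearson correlation of ``value`` between all region pairs.

    Pairs with fewer than ``min_animals`` complete observations and regions
    with zero variance across animals are left missing (NaN) with a warning;
    fabricating zeros there would distort strength summaries.
    """
    sub = react[react["group"] == group]
    if sub.empty:
        raise ValidationError(f"no rows for group {group!r}")
    wide = sub.pivot_table(index="animal_id", columns="region", values=value, aggfunc="mean")
    if regions is None:
        regions = [r for r in sub["region"].unique()]
    missing_regions = [r for r in regions if r not in wide.columns]
    for r in missing_regions:
        wide[r] = np.nan
    wide = wide[list(regions)]

    n_obs = wide.notna().sum(axis=0)
    zero_var = [
        c for c in wide.columns if n_obs[c] >= min_animals and np.nanstd(wide[c].values) == 0.0
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = wide.corr(min_periods=min_animals)
    if zero_var:
        warnings.warn(
            f"group {group!r}: zero variance across animals in region(s) "
            f"{', '.join(map(str, zero_var))}; their correlations are left missing",
            stacklevel=2,
        )
        corr.loc[zero_var, :] = np.nan
        corr.loc[:, zero_var] = np.nan
    insufficient = n_obs[n_obs < min_animals].index.tolist()
    if insufficient:
        warnings.warn(
            f"group {group!r}: fewer than {min_animals} animals for region(s) "
            f"{', '.join(map(str, insufficient))}; correlations left missing",
            stacklevel=2,
        )
    np.fill_diagonal(corr.values, 1.0)
    return GroupCorrelationMatrix(
        group=group, regions=list(regions), r=corr, n_animals=wide.shape[0]
    )


def mean_group_connectivity(
    m: GroupCorrelationMatrix,
    groups_a,
    groups_b=None,
    metadata=None,
) -> float:
    """Mean correlation between two anatomical groups (or one group vs all others).

    ``groups_a``/``groups_b`` are anatomical-group names (or lists of names);
    ``groups_b=None`` selects every region outside ``groups_a``. Only cross-set
    pairs contribute; within-set pairs, the diagonal, and missing entries are
    excluded.
    """
    anat = _anat_lookup(metadata)
    if isinstance(groups_a, str):
        groups_a = [groups_a]
    set_a = [r for r in m.regions if anat.get(r) in set(groups_a)]
    if groups_b is None:
        set_b = [r for r in m.regions if r not in set_a]
    else:
        if isinstance(groups_b, str):
            groups_b = [groups_b]
        set_b = [r for r in m.regions if anat.get(r) in set(groups_b)]
    if not set_a or not set_b:
        raise ValidationError("anatomical selectors must map to non-empty region sets")
    if set(set_a) & set(set_b):
        raise ValidationError("anatomical selectors must map to disjoint region sets")
    vals = m.r.loc[set_a, set_b].values.ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError("no non-missing cross-set correlation pairs")
    return float(vals.mean())


def _anat_lookup(metadata) -> dict:
    if metadata is None:
        return dict(DEFAULT_REGIONS)
    if isinstance(metadata, pd.DataFrame):
        return dict(zip(metadata["region"], metadata["anatomical_group"]))
    return dict(metadata)


# ---------------------------------------------------------------------------
# network construction


def build_network(
    m: GroupCorrelationMatrix,
    sign_mode: str = "positive",
    *,
    metadata=None,
    threshold: float = 0.0,
) -> nx.Graph:
    """Build the co-reactivation graph for one sign mode.

    positive: edges with r > threshold at weight r; negative: edges with
    r < -threshold at weight ``|r|``; combined: all edges with ``|r|`` >
    threshold at their signed weight. Missing correlations yield no edge.
    The original signed coefficient is kept on every edge as attribute ``r``.
    """
    if sign_mode not in SIGN_MODES:
        raise ValidationError(f"sign_mode must be one of {SIGN_MODES}, got {sign_mode!r}")
    anat = _anat_lookup(metadata)
    g = nx.Graph(sign_mode=sign_mode, group=m.group, threshold=float(threshold))
    for region in m.regions:
        g.add_node(region, anatomical_group=anat.get(region, "unknown"))
    rmat = m.r.values
    for i, ri in enumerate(m.regions):
        for j in range(i + 1, len(m.regions)):
            r = rmat[i, j]
            if np.isnan(r) or abs(r) <= threshold:
                continue
            if sign_mode == "positive" and r > 0:
                g.add_edge(ri, m.regions[j], weight=float(r), r=float(r))
            elif sign_mode == "negative" and r < 0:
                g.add_edge(ri, m.regions[j], weight=float(abs(r)), r=float(r))
            elif sign_mode == "combined":
                g.add_edge(ri, m.regions[j], weight=float(r), r=float(r))
    return g


def _metric_graph(net: nx.Graph) -> nx.Graph:
    """Positive-weight view used for path, clustering, and spectral measures.

    In combined mode weights are |r|; every edge gets length = 1/weight.
    """
    h = nx.Graph()
    h.add_nodes_from(net.nodes(data=True))
    for u, v, d in net.edges(data=True):
        w = abs(d["weight"])
        if w > 0:
            h.add_edge(u, v, weight=w, length=1.0 / w)
    return h


# ---------------------------------------------------------------------------
# centralities


def _eigenvector_power(h: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000) -> dict:
    """Principal-eigenvector scores by power iteration, normalized to max 1.

    Computed on the largest connected component (other nodes score 0), with a
    warning when the graph is disconnected.
    """
    nodes = list(h.nodes)
    if h.number_of_edges() == 0:
        return {n: 0.0 for n in nodes}
    comps = sorted(nx.connected_components(h), key=lambda c: (-len(c), sorted(map(str, c))))
    if len(comps) > 1:
        warnings.warn(
            "network is disconnected; eigenvector centrality computed on the largest component",
            stacklevel=3,
        )
    comp = sorted(comps[0], key=str)
    a = nx.to_numpy_array(h, nodelist=comp, weight="weight")
    # spectral shift keeps the Perron eigenvalue strictly dominant (a bipartite
    # component has eigenvalues +/-lambda_max and would make the iteration
    # oscillate); the shift does not change the eigenvector
    a = a + np.eye(len(comp)) * max(a.sum(axis=1).max(), 1.0)
    v = np.ones(len(comp))
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        v_new = a @ v
        norm = np.linalg.norm(v_new)
        if norm == 0:
            v_new = v
            break
        v_new /= norm
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    v = np.abs(v)
    if v.max() > 0:
        v = v / v.max()
    scores = {n: 0.0 for n in nodes}
    scores.update(dict(zip(comp, map(float, v))))
    return scores


def _strength(net: nx.Graph) -> dict:
    """Node strength: average correlation of the node over the N-1 other regions.

    Edges filtered out by the sign mode (or missing) contribute 0, so in a
    sparse network a node's strength reflects both how strong and how many its
    connections are. In combined (signed) mode the positive and negative
    average strengths are merged as s* = s+ - (s- / (s+ + s-)) * s-, scaling
    the negative contribution by its share of total connectivity.
    """
    signed = net.graph.get("sign_mode") == "combined"
    denom = max(net.number_of_nodes() - 1, 1)
    out = {}
    for n in net.nodes:
        ws = [d["weight"] for _, _, d in net.edges(n, data=True)]
        if not ws:
            out[n] = 0.0
        elif not signed:
            out[n] = float(np.sum(ws)) / denom
        else:
            s_pos = float(np.sum([w for w in ws if w > 0])) / denom
            s_neg = float(np.sum([-w for w in ws if w < 0])) / denom
            total = s_pos + s_neg
            out[n] = s_pos - (s_neg / total) * s_neg if total > 0 else 0.0
    return out


def _closeness(h: nx.Graph) -> tuple[dict, dict]:
    """(Clo, mean shortest path) per node; Clo = 1 / mean weighted distance.

    Disconnected graphs are handled per component: the mean runs over the
    nodes reachable from each node. Isolated nodes score 0 (infinite path).
    """
    clo, mean_path = {}, {}
    for n in h.nodes:
        dists = nx.single_source_dijkstra_path_length(h, n, weight="length")
        del dists[n]
        if not dists:
            clo[n], mean_path[n] = 0.0, math.inf
            continue
        mp = float(np.mean(list(dists.values())))
        mean_path[n] = mp
        clo[n] = 1.0 / mp if mp > 0 else 0.0
    return clo, mean_path


def clustering_coefficient(net: nx.Graph, node) -> float:
    """Fraction of a node's neighbor pairs that are themselves connected.

    Computed on the unweighted topology of the network's sign mode; nodes with
    fewer than two neighbors score 0.
    """
    if node not in net:
        raise ValidationError(f"node {node!r} not in network")
    return float(nx.clustering(_metric_graph(net), node))


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node centrality profile: Str, Eig, Bet, Clo, CC, ranks, and hub flag.

    Bet uses unnormalized shortest-path pair counts; Clo is the inverse mean
    weighted path length (the raw mean path is exposed as ``mean_path``).
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("network has no nodes")
    h = _metric_graph(net)
    nodes = list(net.nodes)
    prof = pd.DataFrame(index=pd.Index(nodes, name="region"))
    prof["Str"] = pd.Series(_strength(net))
    prof["Eig"] = pd.Series(_eigenvector_power(h))
    prof["Bet"] = pd.Series(nx.betweenness_centrality(h, weight="length", normalized=False))
    clo, mean_path = _closeness(h)
    prof["Clo"] = pd.Series(clo)
    prof["mean_path"] = pd.Series(mean_path)
    prof["CC"] = pd.Series(nx.clustering(h))
    for c in CENTRALITY_NAMES:
        prof[f"rank_{c}"] = prof[c].rank(ascending=False, method="min").astype(int)
    prof["composite_rank"] = sum(prof[f"rank_{c}"] for c in CENTRALITY_NAMES)
    prof["hub"] = False
    prof.loc[list(identify_hubs(prof)), "hub"] = True
    return prof


def identify_hubs(
    profile: pd.DataFrame, *, top_frac: float = 0.25, min_centralities: int = 3
) -> set:
    """Hub rule: membership in the top-25% candidate set of >= 3 of 4 centralities.

    The candidate set per centrality holds the ceil(top_frac * N) top-ranked
    nodes, with all nodes tied at the cutoff score included.
    """
    n = len(profile)
    if n == 0:
        return set()
    k = math.ceil(top_frac * n)
    counts = pd.Series(0, index=profile.index)
    for c in CENTRALITY_NAMES:
        scores = profile[c]
        if scores.nunique() == 1:
            warnings.warn(
                f"degenerate centrality profile: all nodes tie on {c}; "
                "every node enters its candidate set",
                stacklevel=2,
            )
            counts += 1
            continue
        cutoff = scores.sort_values(ascending=False).iloc[k - 1]
        counts[scores >= cutoff] += 1
    return set(profile.index[counts >= min_centralities])


# ---------------------------------------------------------------------------
# communities and modularity


@dataclass
class CommunityPartition:
    """Node -> community assignment with its Newman modularity."""

    membership: dict
    q: float
    communities: list = field(default_factory=list)


def modularity_score(net: nx.Graph, partition) -> float:
    """Weighted Newman modularity Q = sum_c [W_c/W - (S_c/2W)^2].

    W is the total edge weight, W_c the within-community weight and S_c the
    summed strength of community c. Computed on the metric (|r|) weights.
    ``partition`` is a node->community mapping or an iterable of node sets.
    """
    h = _metric_graph(net)
    if isinstance(partition, dict):
        membership = partition
    else:
        membership = {n: i for i, com in enumerate(partition) for n in com}
    missing = set(h.nodes) - set(membership)
    if missing:
        raise ValidationError(f"partition does not cover node(s): {sorted(map(str, missing))}")
    w_total = h.size(weight="weight")
    if w_total == 0:
        return 0.0
    w_in: dict = {}
    s_c: dict = {}
    for u, v, d in h.edges(data=True):
        w = d["weight"]
        cu, cv = membership[u], membership[v]
        s_c[cu] = s_c.get(cu, 0.0) + w
        s_c[cv] = s_c.get(cv, 0.0) + w
        if cu == cv:
            w_in[cu] = w_in.get(cu, 0.0) + w
    q = 0.0
    for c in set(membership.values()):
        q += w_in.get(c, 0.0) / w_total - (s_c.get(c, 0.0) / (2.0 * w_total)) ** 2
    return float(q)


def _canonical_partition(communities) -> tuple:
    return tuple(sorted(tuple(sorted(map(str, c))) for c in communities))


def _refine_single_moves(net: nx.Graph, membership: dict) -> dict:
    """Greedy single-node-move hill climbing until Q is locally optimal.

    Polishes a candidate partition out of the local optima the Louvain passes
    can settle in on small graphs; deterministic (nodes and target communities
    visited in sorted order, first strictly improving move taken).
    """
    membership = dict(membership)
    q_best = modularity_score(net, membership)
    improved = True
    while improved:
        improved = False
        for n in sorted(membership, key=str):
            current = membership[n]
            comm_ids = sorted(set(membership.values()))
            fresh = max(comm_ids) + 1
            for target in comm_ids + [fresh]:
                if target == current:
                    continue
                trial = dict(membership)
                trial[n] = target
                q = modularity_score(net, trial)
                if q > q_best + 1e-12:
                    membership, q_best, improved = trial, q, True
                    break
    return membership


def detect_communities(net: nx.Graph, seed: int = 0, restarts: int = 100) -> CommunityPartition:
    """Modularity-optimizing partition (Louvain with restarts + greedy candidate).

    Runs Louvain ``restarts`` times from different RNG streams plus one
    Clauset-Newman-Moore greedy pass, keeps the maximum-Q partition, polishes
    it with single-node-move hill climbing, and breaks exact Q ties by the
    lexicographically smallest partition signature.
    An edgeless network returns singleton communities with Q = 0.
    """
    h = _metric_graph(net)
    if h.number_of_edges() == 0:
        communities = [{n} for n in h.nodes]
        return CommunityPartition(
            membership={n: i for i, n in enumerate(h.nodes)},
            q=0.0,
            communities=[set(c) for c in communities],
        )
    candidates = []
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        sub = int(rng.integers(0, 2**31 - 1))
        candidates.append(nx.community.louvain_communities(h, weight="weight", seed=sub))
    candidates.append(nx.community.greedy_modularity_communities(h, weight="weight"))
    scored = [(modularity_score(net, c), c) for c in candidates]
    best_q = max(q for q, _ in scored)
    tied = [c for q, c in scored if q >= best_q - 1e-12]
    best = min(tied, key=_canonical_partition)
    refined = _refine_single_moves(net, {n: i for i, c in enumerate(best) for n in c})
    # order communities deterministically by their smallest node label
    groups: dict = {}
    for n, c in refined.items():
        groups.setdefault(c, []).append(n)
    comms = sorted((sorted(c, key=str) for c in groups.values()), key=lambda c: str(c[0]))
    membership = {n: i for i, c in enumerate(comms) for n in c}
    return CommunityPartition(
        membership=membership,
        q=modularity_score(net, membership),
        communities=[set(c) for c in comms],
    )


# ---------------------------------------------------------------------------
# topology metrics and node deletion


def _global_efficiency(h: nx.Graph) -> float:
    n = h.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for _, dists in nx.all_pairs_dijkstra_path_length(h, weight="length"):
        for v, d in dists.items():
            if d > 0:
                total += 1.0 / d
    return total / (n * (n - 1))


def topology_metrics(net: nx.Graph) -> dict:
    """Whole-network summary metrics.

    global_efficiency: mean inverse weighted shortest-path length over ordered
    node pairs (unreachable pairs contribute 0); local_efficiency: mean over
    nodes of the global efficiency of each node's neighbor-induced subgraph;
    avg_clustering: mean per-node clustering coefficient; avg_degree /
    avg_weighted_degree: mean unweighted / weight-summed node degree.
    """
    if net.number_of_nodes() == 0:
        raise ValidationError("network has no nodes")
    h = _metric_graph(net)
    nodes = list(h.nodes)
    local = []
    for n in nodes:
        nbrs = list(h.neighbors(n))
        local.append(_global_efficiency(h.subgraph(nbrs)) if len(nbrs) >= 2 else 0.0)
    cc = nx.clustering(h)
    return {
        "global_efficiency": _global_efficiency(h),
        "local_efficiency": float(np.mean(local)),
        "avg_clustering": float(np.mean(list(cc.values()))),
        "avg_degree": float(np.mean([d for _, d in h.degree()])),
        "avg_weighted_degree": float(np.mean([d for _, d in h.degree(weight="weight")])),
    }


def node_deletion_efficiency(net: nx.Graph, profile: pd.DataFrame, mode: str) -> dict:
    """Recompute topology metrics after deleting hubs or a matched non-hub set.

    ``mode='hubs'`` deletes the hub set; ``mode='non_hubs'`` deletes the same
    number of non-hub nodes with the lowest composite centrality rank (the
    least central nodes), making the two deletions size-matched.
    """
    if mode not in ("hubs", "non_hubs"):
        raise ValidationError("mode must be 'hubs' or 'non_hubs'")
    hubs = list(profile.index[profile["hub"]])
    if not hubs:
        raise ValidationError("no hubs in profile; nothing to match against")
    if mode == "hubs":
        delete = hubs
    else:
        non_hubs = profile[~profile["hub"]].sort_values(
            "composite_rank", ascending=False, kind="stable"
        )
        delete = list(non_hubs.index[: len(hubs)])
    if len(delete) >= net.number_of_nodes():
        raise ValidationError("deletion would empty the network")
    reduced = net.copy()
    reduced.remove_nodes_from(delete)
    intact = topology_metrics(net)
    after = topology_metrics(reduced)
    return {
        "mode": mode,
        "deleted": delete,
        "intact": intact,
        "reduced": after,
        "delta": {k: after[k] - intact[k] for k in intact},
    }


# ---------------------------------------------------------------------------
# export


def export_matrix_csv(m: GroupCorrelationMatrix, path) -> None:
    """Region x region correlation matrix as CSV with header row and column."""
    m.r.to_csv(path, index_label="region")


def export_edges_tsv(net: nx.Graph, path) -> None:
    """Plain edge list: source, target, weight, sign."""
    rows = [
        (u, v, d["weight"], "positive" if d.get("r", d["weight"]) > 0 else "negative")
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def export_graphml(net: nx.Graph, path, profile: pd.DataFrame | None = None,
                   partition: CommunityPartition | None = None) -> None:
    """GraphML export with optional centrality/hub/community node attributes."""
    g = net.copy()
    if profile is not None:
        for col in ("Str", "Eig", "Bet", "Clo", "CC"):
            nx.set_node_attributes(g, {n: float(profile.loc[n, col]) for n in g.nodes}, col)
        nx.set_node_attributes(g, {n: bool(profile.loc[n, "hub"]) for n in g.nodes}, "hub")
    if partition is not None:
        nx.set_node_attributes(
            g, {n: int(partition.membership[n]) for n in g.nodes}, "community"
        )
    for u, v, d in g.edges(data=True):
        d["weight"] = float(d["weight"])
        if "r" in d:
            d["r"] = float(d["r"])
    nx.write_graphml(g, path)
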