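"""Group-label permutation tests for correlation-based network statistics.

Each test shuffles the animal group labels without replacement (group sizes
preserved, no animal duplicated), recomputes the statistic from the shuffled
labeling, and reports the one-sided p-value as the frequency with which the
resampled difference exceeds the empirical difference:

    p = #(null > empirical) / B        (B resamples, default 1000)

This literal frequency can be exactly 0; the bias-corrected estimate
(k + 1)/(B + 1) is reported alongside as ``p_corrected``. For signed
statistics the default statistic is the absolute difference. Resamples where a
shuffled group leaves the statistic undefined (a zero-variance region) are
redrawn, with the redraw count recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError
from .network import (
    GroupCorrelationMatrix,
    _anat_lookup,
    _closeness,
    _eigenvector_power,
    _metric_graph,
    _strength,
    build_network,
    correlation_matrix,
)
from .reactivation import bh_adjust

import networkx as nx

_MAX_REDRAW_ROUNDS = 100


@dataclass
class PermutationResult:
    """Outcome of one label-shuffle permutation test."""

    statistic_name: str
    empirical: float
    null_sample: np.ndarray
    B: int
    p: float
    p_corrected: float
    seed: int
    side: str = "greater"
    n_redraws: int = 0
    family_id: str | None = None

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "statistic_name": self.statistic_name,
            "empirical": self.empirical,
            "p": self.p,
            "p_corrected": self.p_corrected,
            "B": self.B,
            "seed": self.seed,
            "side": self.side,
            "n_redraws": self.n_redraws,
            "family_id": self.family_id,
        }
        if include_null:
            out["null_sample"] = [float(x) for x in self.null_sample]
        return out


def _result(name, empirical, null, seed, n_redraws=0) -> PermutationResult:
    null = np.asarray(null, dtype=float)
    b = null.size
    k = int((null > empirical).sum())
    return PermutationResult(
        statistic_name=name,
        empirical=float(empirical),
        null_sample=null,
        B=b,
        p=k / b,
        p_corrected=(k + 1) / (b + 1),
        seed=seed,
        n_redraws=n_redraws,
    )


def _group_values(rows: pd.DataFrame, regions, value: str) -> np.ndarray:
    """Animals x regions value matrix for one group; complete cases only."""
    wide = rows.pivot_table(index="animal_id", columns="region", values=value, aggfunc="mean")
    missing = [r for r in regions if r not in wide.columns]
    if missing:
        raise ValidationError(f"region(s) {missing} absent from the supplied rows")
    wide = wide[list(regions)]
    n_before = wide.shape[0]
    wide = wide.dropna()
    if wide.shape[0] < n_before:
        warnings.warn(
            f"dropped {n_before - wide.shape[0]} animal(s) with missing values",
            stacklevel=3,
        )
    return wide.values


def _shuffled_indices(n1: int, n: int, b: int, rng) -> np.ndarray:
    """(b, n) row-wise permutations; columns [:n1] form the shuffled group 1."""
    return np.argsort(rng.random((b, n)), axis=1)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally-shaped 2-d arrays."""
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    num = (xm * ym).sum(axis=1)
    den = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den == 0, np.nan, num / den)


def _check_b(b: int) -> None:
    if not isinstance(b, (int, np.integer)) or b <= 0:
        raise ValidationError(f"resample count B must be a positive integer, got {b!r}")


def permute_edge_difference(
    rows_g1: pd.DataFrame,
    rows_g2: pd.DataFrame,
    region_pair,
    b: int = 1000,
    seed: int = 0,
    value: str = "double_pct",
) -> PermutationResult:
    """Permutation test of one edge: |r_g1 - r_g2| for a region pair.

    The empirical statistic is the absolute difference between the two groups'
    across-animal Pearson correlations of ``value`` for the pair; each resample
    reassigns animals to groups (sizes preserved) and recomputes both
    correlations jointly from the shuffled labeling.
    """
    _check_b(b)
    ra, rb = region_pair
    v1 = _group_values(rows_g1, [ra, rb], value)
    v2 = _group_values(rows_g2, [ra, rb], value)
    n1, n2 = v1.shape[0], v2.shape[0]
    if n1 < 3 or n2 < 3:
        raise ValidationError("each group needs >= 3 animals with complete values for the pair")
    x = np.concatenate([v1[:, 0], v2[:, 0]])
    y = np.concatenate([v1[:, 1], v2[:, 1]])
    n = n1 + n2

    r1 = _pearson_rows(x[:n1][None, :], y[:n1][None, :])[0]
    r2 = _pearson_rows(x[n1:][None, :], y[n1:][None, :])[0]
    if np.isnan(r1) or np.isnan(r2):
        raise ValidationError("zero variance in a region for a group; correlation undefined")
    empirical = abs(r1 - r2)

    rng = np.random.default_rng(seed)
    idx = _shuffled_indices(n1, n, b, rng)

    def stat(idx):
        g1, g2 = idx[:, :n1], idx[:, n1:]
        d1 = _pearson_rows(x[g1], y[g1])
        d2 = _pearson_rows(x[g2], y[g2])
        return np.abs(d1 - d2)

    null = stat(idx)
    n_redraws = 0
    rounds = 0
    while np.isnan(null).any():
        rounds += 1
        if rounds > _MAX_REDRAW_ROUNDS:
            raise ValidationError("statistic undefined in too many resamples")
        bad = np.isnan(null)
        n_redraws += int(bad.sum())
        idx_bad = _shuffled_indices(n1, n, int(bad.sum()), rng)
        null[bad] = stat(idx_bad)

    res = _result(f"edge|{ra}-{rb}|", empirical, null, seed, n_redraws)
    return res


# ---------------------------------------------------------------------------
# centrality differences


def _single_centrality(net: nx.Graph, name: str, node):
    if name == "Str":
        return _strength(net)[node]
    h = _metric_graph(net)
    if name == "Eig":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _eigenvector_power(h)[node]
    if name == "Bet":
        return nx.betweenness_centrality(h, weight="length", normalized=False)[node]
    if name == "Clo":
        return _closeness(h)[0][node]
    raise ValidationError(f"unknown centrality {name!r}")


def _matrix_to_network(r: np.ndarray, regions, sign_mode: str, group: str) -> nx.Graph:
    m = GroupCorrelationMatrix(
        group=group, regions=list(regions), r=pd.DataFrame(r, index=regions, columns=regions),
        n_animals=0,
    )
    return build_network(m, sign_mode)


def _corr(v: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.corrcoef(v.T)


def _strength_from_matrix(r: np.ndarray, i: int, sign_mode: str) -> float:
    denom = max(r.shape[0] - 1, 1)
    row = np.delete(r[i], i)
    row = row[~np.isnan(row)]
    if sign_mode == "positive":
        return float(row[row > 0].sum()) / denom
    if sign_mode == "negative":
        return float(-row[row < 0].sum()) / denom
    s_pos = float(row[row > 0].sum()) / denom
    s_neg = float(-row[row < 0].sum()) / denom
    total = s_pos + s_neg
    return s_pos - (s_neg / total) * s_neg if total > 0 else 0.0


def permute_centrality_difference(
    rows_g1: pd.DataFrame,
    rows_g2: pd.DataFrame,
    node,
    centrality_name: str,
    sign_mode: str = "positive",
    b: int = 1000,
    seed: int = 0,
    value: str = "double_pct",
    regions=None,
) -> PermutationResult:
    """Permutation test of one node's centrality difference between two groups.

    The empirical statistic is the absolute difference of the chosen
    centrality (Str, Eig, Bet, or Clo) between the two groups' intact
    networks; the null rebuilds both correlation matrices and networks from
    each shuffled labeling.
    """
    _check_b(b)
    g1 = rows_g1["group"].iloc[0]
    g2 = rows_g2["group"].iloc[0]
    if regions is None:
        regions = [r for r in rows_g1["region"].unique()]
    if node not in regions:
        raise ValidationError(f"node {node!r} not among the network regions")
    m1 = correlation_matrix(rows_g1, g1, regions=regions, value=value)
    m2 = correlation_matrix(rows_g2, g2, regions=regions, value=value)
    net1 = build_network(m1, sign_mode)
    net2 = build_network(m2, sign_mode)
    if node not in net1 or node not in net2:
        raise ValidationError(f"node {node!r} missing from a network")
    empirical = abs(
        _single_centrality(net1, centrality_name, node)
        - _single_centrality(net2, centrality_name, node)
    )

    v1 = _group_values(rows_g1, regions, value)
    v2 = _group_values(rows_g2, regions, value)
    n1 = v1.shape[0]
    v = np.vstack([v1, v2])
    node_i = list(regions).index(node)
    rng = np.random.default_rng(seed)

    def one_stat(order):
        r1 = _corr(v[order[:n1]])
        r2 = _corr(v[order[n1:]])
        if centrality_name == "Str":
            c1 = _strength_from_matrix(r1, node_i, sign_mode)
            c2 = _strength_from_matrix(r2, node_i, sign_mode)
        else:
            c1 = _single_centrality(
                _matrix_to_network(r1, regions, sign_mode, "null1"), centrality_name, node
            )
            c2 = _single_centrality(
                _matrix_to_network(r2, regions, sign_mode, "null2"), centrality_name, node
            )
        return abs(c1 - c2)

    null = np.empty(b)
    n_redraws = 0
    for i in range(b):
        s = np.nan
        rounds = 0
        while np.isnan(s):
            if rounds > _MAX_REDRAW_ROUNDS:
                raise ValidationError("statistic undefined in too many resamples")
            order = rng.permutation(v.shape[0])
            s = one_stat(order)
            rounds += 1
        n_redraws += rounds - 1
        null[i] = s

    return _result(f"centrality|{centrality_name}|{node}", empirical, null, seed, n_redraws)


def _profile_from_matrix(r: np.ndarray, regions, sign_mode: str) -> dict:
    """All four centralities for every node of the network built from ``r``."""
    net = _matrix_to_network(r, regions, sign_mode, "null")
    h = _metric_graph(net)
    out = {}
    out["Str"] = _strength(net)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["Eig"] = _eigenvector_power(h)
    out["Bet"] = nx.betweenness_centrality(h, weight="length", normalized=False)
    out["Clo"] = _closeness(h)[0]
    return out


def permute_all_centralities(
    rows_g1: pd.DataFrame,
    rows_g2: pd.DataFrame,
    sign_mode: str = "positive",
    b: int = 1000,
    seed: int = 0,
    value: str = "double_pct",
    regions=None,
) -> list[PermutationResult]:
    """Centrality-difference permutation tests for every node and measure.

    One pass of B label shuffles rebuilds both group networks per shuffle and
    serves all node x centrality tests, so the whole family shares one null
    network ensemble (and one seed).
    """
    _check_b(b)
    g1 = rows_g1["group"].iloc[0]
    g2 = rows_g2["group"].iloc[0]
    if regions is None:
        regions = [r for r in rows_g1["region"].unique()]
    m1 = correlation_matrix(rows_g1, g1, regions=regions, value=value)
    m2 = correlation_matrix(rows_g2, g2, regions=regions, value=value)
    p1 = _profile_from_matrix(m1.r.values, regions, sign_mode)
    p2 = _profile_from_matrix(m2.r.values, regions, sign_mode)

    v1 = _group_values(rows_g1, regions, value)
    v2 = _group_values(rows_g2, regions, value)
    n1 = v1.shape[0]
    v = np.vstack([v1, v2])
    rng = np.random.default_rng(seed)

    names = [(c, node) for c in ("Str", "Eig", "Bet", "Clo") for node in regions]
    null = {key: np.empty(b) for key in names}
    for i in range(b):
        order = rng.permutation(v.shape[0])
        q1 = _profile_from_matrix(_corr(v[order[:n1]]), regions, sign_mode)
        q2 = _profile_from_matrix(_corr(v[order[n1:]]), regions, sign_mode)
        for c, node in names:
            null[(c, node)][i] = abs(q1[c][node] - q2[c][node])

    results = []
    for c, node in names:
        emp = abs(p1[c][node] - p2[c][node])
        res = _result(f"centrality|{c}|{node}", emp, null[(c, node)], seed)
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# anatomical-group connectivity differences


def permute_connectivity_difference(
    rows_g1: pd.DataFrame,
    rows_g2: pd.DataFrame,
    selector_a,
    selector_b=None,
    metadata=None,
    b: int = 1000,
    seed: int = 0,
    value: str = "double_pct",
    regions=None,
) -> PermutationResult:
    """Permutation test of mean anatomical-group connectivity between groups.

    The statistic is the absolute difference, between experimental groups, of
    the mean correlation over cross-set region pairs (anatomical selector A vs
    B, or A vs all other regions).
    """
    _check_b(b)
    if regions is None:
        regions = [r for r in rows_g1["region"].unique()]
    anat = _anat_lookup(metadata)
    sel_a = {selector_a} if isinstance(selector_a, str) else set(selector_a)
    set_a = [r for r in regions if anat.get(r) in sel_a]
    if selector_b is None:
        set_b = [r for r in regions if r not in set_a]
    else:
        sel_b = {selector_b} if isinstance(selector_b, str) else set(selector_b)
        set_b = [r for r in regions if anat.get(r) in sel_b]
    if not set_a or not set_b:
        raise ValidationError("anatomical selectors must map to non-empty region sets")
    if set(set_a) & set(set_b):
        raise ValidationError("anatomical selectors must map to disjoint region sets")

    idx = {r: i for i, r in enumerate(regions)}
    mask = np.zeros((len(regions), len(regions)), dtype=bool)
    for ra in set_a:
        for rb in set_b:
            mask[idx[ra], idx[rb]] = True

    v1 = _group_values(rows_g1, regions, value)
    v2 = _group_values(rows_g2, regions, value)
    if v1.shape[0] < 3 or v2.shape[0] < 3:
        raise ValidationError("each group needs >= 3 animals with complete values")
    n1 = v1.shape[0]
    v = np.vstack([v1, v2])

    def conn(mat):
        vals = _corr(mat)[mask]
        vals = vals[~np.isnan(vals)]
        return vals.mean() if vals.size else np.nan

    empirical = abs(conn(v[:n1]) - conn(v[n1:]))
    if np.isnan(empirical):
        raise ValidationError("connectivity undefined for the intact grouping")

    rng = np.random.default_rng(seed)
    null = np.empty(b)
    n_redraws = 0
    for i in range(b):
        s = np.nan
        rounds = 0
        while np.isnan(s):
            if rounds > _MAX_REDRAW_ROUNDS:
                raise ValidationError("statistic undefined in too many resamples")
            order = rng.permutation(v.shape[0])
            s = abs(conn(v[order[:n1]]) - conn(v[order[n1:]]))
            rounds += 1
        n_redraws += rounds - 1
        null[i] = s

    b_name = "others" if selector_b is None else "+".join(sorted(sel_b))
    name = f"connectivity|{'+'.join(sorted(sel_a))}-vs-{b_name}"
    return _result(name, empirical, null, seed, n_redraws)


def adjust_family(results: list[PermutationResult], family_id: str = "family") -> pd.DataFrame:
    """Pool permutation results into one global Benjamini-Hochberg family."""
    if not results:
        raise ValidationError("empty permutation family")
    adj = bh_adjust([r.p for r in results], labels=[r.statistic_name for r in results])
    for r in results:
        r.family_id = family_id
    out = adj.to_frame()
    out["p_corrected"] = [r.p_corrected for r in results]
    out["empirical"] = [r.empirical for r in results]
    out["family_id"] = family_id
    return out
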