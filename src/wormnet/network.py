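"""Co-occurrence network construction and module detection.

Edges are Spearman correlations between taxa across samples, retained when
|rho| exceeds the correlation threshold AND the Benjamini-Hochberg adjusted
p-value clears the significance threshold (defaults r > 0.8, q < 0.01).
Modules are found by greedy Newman-modularity agglomeration with a
deterministic node-move refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import OtuTable, SampleMetadata, as_fraction, presence_fraction

DEFAULT_R_THRESHOLD = 0.8
DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_PREVALENCE = Fraction(2, 3)


def prevalence_filter(table: OtuTable, min_fraction=DEFAULT_PREVALENCE) -> OtuTable:
    """Keep OTUs present (count > 0) in strictly more than ``min_fraction`` of samples.

    The comparison is exact (2/3 of 12 samples means presence in >= 9, not 8).
    An empty result is allowed with a warning from the caller's side; this
    function simply returns the empty table.
    """
    frac = as_fraction(min_fraction)
    if not (0 < frac <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = table.n_samples
    presence = (table.counts > 0).sum(axis=1)
    keep = [table.otu_ids[i] for i in range(table.n_otus)
            if Fraction(int(presence[i]), n) > frac]
    return table.select_otus(keep)


def spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (mid-ranks) and two-sided p for one pair of vectors.

    p comes from the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 df;
    |rho| = 1 maps to p = 0; a constant vector yields rho = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("Spearman correlation requires at least 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, _spearman_p(rho, n)


def _spearman_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_all_pairs(table: OtuTable, use_relative: bool = True
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p matrices over taxa (rows) across samples.

    Works on per-sample relative abundances by default (ranks within a taxon
    across samples; relative vs raw counts matters when depths differ).
    Constant taxa get rho 0 / p 1 against everything; the diagonal is rho 1,
    p 0.  Matrices are symmetric.
    """
    if table.n_samples < 4:
        raise ValueError("Spearman correlation requires at least 4 samples")
    data = table.relative_abundance().to_numpy() if use_relative else \
        table.counts.astype(float)
    n_taxa, n = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    sd = ranks.std(axis=1)
    constant = sd == 0
    # standardize; constant rows zeroed so their correlations come out 0
    z = np.zeros_like(ranks)
    ok = ~constant
    z[ok] = (ranks[ok] - ranks[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    rho = z @ z.T / n
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    p[constant, :] = 1.0
    p[:, constant] = 1.0
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    ids = table.otu_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order.

    q_(i) = min_{j>=i} p_(j) * m / j on the sorted p-values, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class CorrelationNetwork:
    """Nodes (all filtered taxa) plus the edges surviving the thresholds.

    ``nodes`` carries prevalence, mean relative abundance and an ``isolated``
    flag; ``edges`` one row per unordered pair with rho, raw p, BH q and sign.
    """

    nodes: pd.DataFrame  # index otu_id; prevalence, mean_rel_abund, isolated
    edges: pd.DataFrame  # source, target, rho, p, q, sign
    r_threshold: float = DEFAULT_R_THRESHOLD
    q_threshold: float = DEFAULT_Q_THRESHOLD

    @property
    def node_ids(self) -> list[str]:
        return list(self.nodes.index)

    def graph(self) -> nx.Graph:
        """Undirected graph with every node (including isolated ones)."""
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        for row in self.edges.itertuples():
            g.add_edge(row.source, row.target, rho=row.rho, p=row.p, q=row.q,
                       sign=row.sign)
        return g

    def write_edges_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def build_network(table: OtuTable, r_threshold: float = DEFAULT_R_THRESHOLD,
                  q_threshold: float = DEFAULT_Q_THRESHOLD) -> CorrelationNetwork:
    """Threshold the all-pairs Spearman matrix into a co-occurrence network.

    The table should already be prevalence-filtered.  An edge is kept iff
    |rho| > r_threshold (strict) and BH-adjusted q < q_threshold (strict);
    BH runs over all unordered pairs.  Isolated nodes stay in the node set.
    """
    rho_df, p_df = spearman_all_pairs(table)
    ids = table.otu_ids
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    rho = rho_df.to_numpy()[iu]
    p = p_df.to_numpy()[iu]
    q = bh_adjust(p) if len(p) else np.array([])
    keep = (np.abs(rho) > r_threshold) & (q < q_threshold)
    edges = pd.DataFrame(
        {
            "source": [ids[i] for i in iu[0][keep]],
            "target": [ids[j] for j in iu[1][keep]],
            "rho": rho[keep],
            "p": p[keep],
            "q": q[keep],
        }
    )
    edges["sign"] = np.where(edges["rho"] > 0, "+", "-") if len(edges) else \
        pd.Series(dtype=str)
    connected = set(edges["source"]) | set(edges["target"])
    nodes = pd.DataFrame(
        {
            "prevalence": presence_fraction(table),
            "mean_rel_abund": table.relative_abundance().mean(axis=1),
        }
    )
    nodes["isolated"] = [o not in connected for o in nodes.index]
    return CorrelationNetwork(nodes=nodes, edges=edges,
                              r_threshold=r_threshold, q_threshold=q_threshold)


@dataclass
class ModulePartition:
    """node -> module id (0..M-1) with the Newman modularity Q of the split."""

    assignment: dict
    q: float

    def modules(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, []).append(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


def modularity(net, partition) -> float:
    """Newman modularity Q = sum_s (e_ss - a_s^2) on the unweighted graph.

    ``net`` may be a CorrelationNetwork or a networkx Graph; edge signs and
    weights are ignored.  Every node must be assigned a module.  An edgeless
    graph has Q = 0.
    """
    g = net.graph() if isinstance(net, CorrelationNetwork) else net
    assignment = partition.assignment if isinstance(partition, ModulePartition) \
        else dict(partition)
    missing = [v for v in g.nodes if v not in assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    e = {}  # within-module edge fractions
    a = {}  # endpoint fractions
    for u, v in g.edges:
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            e[cu] = e.get(cu, 0.0) + 1.0 / m
        a[cu] = a.get(cu, 0.0) + 0.5 / m
        a[cv] = a.get(cv, 0.0) + 0.5 / m
    return float(sum(e.get(s, 0.0) - a[s] ** 2 for s in a))


def _greedy_agglomerate(g: nx.Graph, order: list) -> dict:
    """CNM-style greedy merging of modules by best (tie: smallest id pair) dQ."""
    m = g.number_of_edges()
    idx = {v: i for i, v in enumerate(order)}
    comm = {i: {v} for v, i in idx.items()}  # module id -> nodes
    a = {i: g.degree(v) / (2.0 * m) for v, i in idx.items()}
    e = {}  # between-module edge fractions, key (i, j) with i < j
    for u, v in g.edges:
        i, j = sorted((idx[u], idx[v]))
        if i != j:
            e[(i, j)] = e.get((i, j), 0.0) + 1.0 / m
    while True:
        best_dq, best_pair = 0.0, None
        # iterate in sorted key order so ties go to the smallest (i, j) pair;
        # eij is edges-between/m, so the merge gain is eij - 2 a_i a_j
        for (i, j), eij in sorted(e.items()):
            dq = eij - 2.0 * a[i] * a[j]
            if dq <= 1e-15:
                continue
            if best_pair is None or dq > best_dq + 1e-15:
                best_dq, best_pair = dq, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        comm[i] |= comm.pop(j)
        a[i] += a.pop(j)
        merged = {}
        for (x, y), exy in e.items():
            if (x, y) == (i, j):
                continue
            x = i if x == j else x
            y = i if y == j else y
            key = (min(x, y), max(x, y))
            merged[key] = merged.get(key, 0.0) + exy
        e = merged
    return {v: i for i, nodes in comm.items() for v in nodes}


def _refine_node_moves(g: nx.Graph, assignment: dict, order: list) -> dict:
    """Deterministic single-node moves while Q improves.

    Candidate targets are the modules of the node's neighbours plus a fresh
    singleton module (so an over-merged community can be split again).
    """
    m = g.number_of_edges()
    assignment = dict(assignment)
    deg_in = {}  # module -> sum of degrees (2m * a_s)
    for v in g.nodes:
        deg_in[assignment[v]] = deg_in.get(assignment[v], 0) + g.degree(v)
    fresh = max(assignment.values(), default=-1) + 1
    improved = True
    while improved:
        improved = False
        for v in order:
            cv = assignment[v]
            kv = g.degree(v)
            links = {}  # module -> edges from v into it
            for u in g.neighbors(v):
                links[assignment[u]] = links.get(assignment[u], 0) + 1
            base = links.get(cv, 0) / m - kv * (deg_in[cv] - kv) / (2.0 * m * m)
            best_gain, best_mod = 0.0, None
            targets = sorted(links)
            if deg_in.get(cv, 0) > kv:  # moving out to a singleton is a real split
                targets.append(fresh)
            for target in targets:
                if target == cv:
                    continue
                gain = (links.get(target, 0) / m
                        - kv * deg_in.get(target, 0) / (2.0 * m * m)) - base
                if gain > best_gain + 1e-15:
                    best_gain, best_mod = gain, target
            if best_mod is not None:
                deg_in[cv] -= kv
                deg_in[best_mod] = deg_in.get(best_mod, 0) + kv
                assignment[v] = best_mod
                if best_mod == fresh:
                    fresh += 1
                improved = True
    return assignment


def _relabel(assignment: dict, order: list) -> dict:
    seen: dict = {}
    out = {}
    for v in order:
        c = assignment[v]
        if c not in seen:
            seen[c] = len(seen)
        out[v] = seen[c]
    return out


_EXACT_SIZE_LIMIT = 8


def _exact_modules(g: nx.Graph, base_order: list) -> ModulePartition:
    """Exhaustive maximum-modularity partition (tiny graphs only).

    Enumerates set partitions of the non-isolated nodes via restricted-growth
    strings (isolated nodes stay singletons); the first partition attaining
    the maximum in enumeration order wins, so the result is deterministic.
    """
    active = [v for v in base_order if g.degree(v) > 0]
    best_q, best_codes = -1.0, [0] * len(active)

    def recurse(i: int, codes: list, n_blocks: int) -> None:
        nonlocal best_q, best_codes
        if i == len(active):
            q = modularity(g, {**{v: c for v, c in zip(active, codes)},
                               **{v: -1 - j for j, v in enumerate(base_order)
                                  if g.degree(v) == 0}})
            if q > best_q + 1e-15:
                best_q, best_codes = q, list(codes)
            return
        for c in range(n_blocks + 1):
            codes.append(c)
            recurse(i + 1, codes, max(n_blocks, c + 1))
            codes.pop()

    recurse(0, [], 0)
    assignment = {v: c for v, c in zip(active, best_codes)}
    nxt = max(assignment.values(), default=-1) + 1
    for v in base_order:
        if v not in assignment:
            assignment[v] = nxt
            nxt += 1
    return ModulePartition(_relabel(assignment, base_order),
                           modularity(g, assignment))


def detect_modules(net, seed: int = 0, n_restarts: int = 0) -> ModulePartition:
    """Modularity maximization: exact on tiny graphs, greedy elsewhere.

    Graphs with at most 8 non-isolated nodes are solved exactly by
    enumeration.  Larger graphs start from singleton modules, merge the
    module pair with the largest modularity gain (ties to the
    lexicographically smallest id pair), then run a deterministic node-move
    refinement sweep.  Deterministic for a fixed node ordering; ``seed`` only
    drives optional random-restart orderings (default none).  Isolated nodes
    remain singleton modules; an edgeless graph returns all singletons with
    Q = 0.
    """
    g = net.graph() if isinstance(net, CorrelationNetwork) else net
    base_order = sorted(g.nodes, key=str)
    if g.number_of_edges() == 0:
        return ModulePartition({v: i for i, v in enumerate(base_order)}, 0.0)
    if sum(1 for v in g.nodes if g.degree(v) > 0) <= _EXACT_SIZE_LIMIT:
        return _exact_modules(g, base_order)
    orders = [base_order]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        perm = list(base_order)
        rng.shuffle(perm)
        orders.append(perm)
    best: ModulePartition | None = None
    for order in orders:
        assignment = _greedy_agglomerate(g, order)
        assignment = _refine_node_moves(g, assignment, order)
        assignment = _relabel(assignment, base_order)
        q = modularity(g, assignment)
        if best is None or q > best.q + 1e-15:
            best = ModulePartition(assignment, q)
    assert best is not None
    return best


def per_group_tables(table: OtuTable, meta: SampleMetadata) -> dict[str, OtuTable]:
    """Split the table into one sub-table per group label."""
    return {label: table.select_samples(samples)
            for label, samples in meta.groups.items()}


def write_graphml(net: CorrelationNetwork, path, partition: ModulePartition | None = None,
                  topology: pd.DataFrame | None = None) -> None:
    """GraphML export with module / Zi / Pi / role node attributes when given."""
    g = net.graph()
    if partition is not None:
        nx.set_node_attributes(g, {n: int(m) for n, m in partition.assignment.items()},
                               "module")
    if topology is not None:
        for col in ("degree", "zi", "pi", "role"):
            if col in topology.columns:
                nx.set_node_attributes(g, topology[col].to_dict(), col)
    nx.write_graphml(g, path)
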