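"""Keystone-taxon identification from network topology.

Keystones are called from the Zi-Pi plane: Zi is the z-score of a node's
within-module degree (standardized inside its own module), Pi the
participation coefficient 1 - sum_s (k_is/k_i)^2.  Module hubs (Zi > 2.5,
Pi <= 0.62), connectors (Zi <= 2.5, Pi > 0.62) and network hubs (both high)
form the keystone set.  Network stability under keystone removal is measured
by the modularity drop against a null of random same-size removals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import OtuTable, SampleMetadata
from .network import (CorrelationNetwork, ModulePartition, bh_adjust,
                      detect_modules, modularity, spearman_pair)

DEFAULT_Z_THRESHOLD = 2.5
DEFAULT_P_THRESHOLD = 0.62

ROLE_MODULE_HUB = "module_hub"
ROLE_CONNECTOR = "connector"
ROLE_NETWORK_HUB = "network_hub"
ROLE_PERIPHERAL = "peripheral"
KEYSTONE_ROLES = frozenset({ROLE_MODULE_HUB, ROLE_CONNECTOR, ROLE_NETWORK_HUB})


def classify_role(zi: float, pi: float, z_threshold: float = DEFAULT_Z_THRESHOLD,
                  p_threshold: float = DEFAULT_P_THRESHOLD) -> str:
    """Role from the (Zi, Pi) plane; boundaries fall to the peripheral side."""
    high_z = zi > z_threshold
    high_p = pi > p_threshold
    if high_z and high_p:
        return ROLE_NETWORK_HUB
    if high_z:
        return ROLE_MODULE_HUB
    if high_p:
        return ROLE_CONNECTOR
    return ROLE_PERIPHERAL


def zi_pi(net, partition: ModulePartition,
          z_threshold: float = DEFAULT_Z_THRESHOLD,
          p_threshold: float = DEFAULT_P_THRESHOLD) -> pd.DataFrame:
    """Per-node degree, within-module degree kappa, Zi, Pi and role.

    Zi standardizes kappa_i (links into the node's own module) with the
    population mean/sd over that module's nodes; sd = 0 gives Zi = 0.
    Pi = 1 - sum_s (k_is / k_i)^2, with Pi = 0 for isolated nodes.
    """
    g = net.graph() if isinstance(net, CorrelationNetwork) else net
    assignment = partition.assignment
    missing = [v for v in g.nodes if v not in assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing}")
    nodes = sorted(g.nodes, key=str)
    kappa = {}
    links: dict = {}
    for v in nodes:
        links[v] = {}
        for u in g.neighbors(v):
            cu = assignment[u]
            links[v][cu] = links[v].get(cu, 0) + 1
        kappa[v] = links[v].get(assignment[v], 0)
    # population mean/sd of kappa per module
    by_module: dict = {}
    for v in nodes:
        by_module.setdefault(assignment[v], []).append(kappa[v])
    stats_by_module = {
        mod: (float(np.mean(ks)), float(np.std(ks)))  # population sd
        for mod, ks in by_module.items()
    }
    rows = []
    for v in nodes:
        k = g.degree(v)
        mu, sd = stats_by_module[assignment[v]]
        zi = (kappa[v] - mu) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((c / k) ** 2 for c in links[v].values()) if k > 0 else 0.0
        rows.append(
            {"node": v, "module": assignment[v], "degree": k, "kappa": kappa[v],
             "zi": zi, "pi": pi,
             "role": classify_role(zi, pi, z_threshold, p_threshold)}
        )
    return pd.DataFrame(rows).set_index("node")


def keystones_of(topology: pd.DataFrame) -> list:
    """Node ids classified in any keystone role, in topology order."""
    return list(topology.index[topology["role"].isin(KEYSTONE_ROLES)])


@dataclass
class KeystoneReport:
    """Per-group keystone taxa with lineage and abundance, plus the shared set."""

    per_group: dict[str, pd.DataFrame]  # group -> keystone table
    shared: list  # intersection of keystone OTU ids across groups
    abundance: pd.DataFrame  # per-sample summed keystone relative abundance per group

    @property
    def pooled_count(self) -> int:
        """Keystone calls pooled over all group networks (unique OTU ids)."""
        ids: set = set()
        for df in self.per_group.values():
            ids |= set(df.index)
        return len(ids)


def keystone_report(topologies: dict[str, pd.DataFrame], table: OtuTable,
                    meta: SampleMetadata) -> KeystoneReport:
    """Summarize keystone calls from per-group topologies.

    For each group: the keystone OTUs with lineage, degree, Zi, Pi, role and
    mean relative abundance over that group's samples; the summed keystone
    relative abundance per sample; and the cross-group shared keystone set.
    """
    rel = table.relative_abundance()
    per_group = {}
    abund_cols = {}
    keystone_sets = []
    for group, topo in topologies.items():
        keys = keystones_of(topo)
        keystone_sets.append(set(keys))
        samples = meta.samples_in_group(group)
        sub = topo.loc[keys, ["degree", "zi", "pi", "role"]].copy()
        sub["lineage"] = [table.lineage_of(o) for o in keys]
        sub["group"] = group
        present = [o for o in keys if o in rel.index]
        sub["mean_rel_abund"] = rel.loc[present, samples].mean(axis=1).reindex(keys)
        per_group[group] = sub
        abund_cols[group] = rel.loc[present].sum(axis=0) if present else \
            pd.Series(0.0, index=rel.columns)
    shared = sorted(set.intersection(*keystone_sets)) if keystone_sets else []
    return KeystoneReport(per_group=per_group, shared=shared,
                          abundance=pd.DataFrame(abund_cols))


@dataclass
class RemovalStabilityResult:
    """Modularity before/after keystone removal vs random same-size removals."""

    q_before: float
    q_after: float
    null_q: np.ndarray
    p_value: float
    n_null: int
    seed: int

    def summary(self) -> dict:
        return {
            "q_before": self.q_before,
            "q_after": self.q_after,
            "null_mean": float(self.null_q.mean()) if len(self.null_q) else None,
            "null_sd": float(self.null_q.std()) if len(self.null_q) else None,
            "null_q05": float(np.quantile(self.null_q, 0.05)) if len(self.null_q) else None,
            "null_q95": float(np.quantile(self.null_q, 0.95)) if len(self.null_q) else None,
            "p_value": self.p_value,
            "n_null": self.n_null,
            "seed": self.seed,
        }


def removal_stability(net, keystones, n_null: int = 199, seed: int = 0,
                      partition_fn=detect_modules) -> RemovalStabilityResult:
    """Test whether removing the keystone set degrades modularity more than chance.

    Deletes the keystones (and incident edges), re-detects modules, and
    compares the resulting Q against ``n_null`` random removals of the same
    number of nodes (each drawn without replacement, seeded).  The empirical
    one-sided p is (1 + #{null <= observed}) / (1 + n_null).
    """
    g = net.graph() if isinstance(net, CorrelationNetwork) else net
    keystones = list(keystones)
    unknown = [k for k in keystones if k not in g]
    if unknown:
        raise ValueError(f"keystones not in network: {unknown}")
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    nodes = sorted(g.nodes, key=str)
    if len(keystones) >= len(nodes):
        raise ValueError("cannot remove the entire node set")
    part_before = partition_fn(g)
    q_before = part_before.q if isinstance(part_before, ModulePartition) else part_before
    if not keystones:
        return RemovalStabilityResult(q_before, q_before, np.array([]), 1.0, 0, seed)

    def q_without(removed) -> float:
        h = g.copy()
        h.remove_nodes_from(removed)
        return partition_fn(h).q

    q_after = q_without(keystones)
    rng = np.random.default_rng(seed)
    null_q = np.array([
        q_without(rng.choice(nodes, size=len(keystones), replace=False))
        for _ in range(n_null)
    ])
    p = (1.0 + int((null_q <= q_after).sum())) / (1.0 + n_null)
    return RemovalStabilityResult(q_before, q_after, null_q, p, n_null, seed)


def keystone_env_correlation(abundance, meta: SampleMetadata,
                             metabolism: pd.DataFrame | None = None) -> pd.DataFrame:
    """Spearman correlations of keystone abundance with covariates.

    ``abundance`` is either one per-sample series (e.g. the summed keystone
    relative abundance) or a DataFrame with one column per keystone taxon
    (index = samples).  Covariates are the metadata's environmental columns
    plus, when given, the columns of ``metabolism`` (e.g. per-category AWCD,
    indexed by sample).  Raw p-values are BH-adjusted across every
    (abundance, covariate) pair tested; constant covariates get rho 0 / p 1
    and are flagged.
    """
    if isinstance(abundance, pd.Series):
        abundance = abundance.rename(abundance.name or "keystone_abundance").to_frame()
    env = meta.env().loc[abundance.index]
    cov = env if metabolism is None else env.join(metabolism, how="left")
    rows = []
    for taxon in abundance.columns:
        for name in cov.columns:
            pair = pd.concat([abundance[taxon].rename("x"), cov[name].rename("y")],
                             axis=1).dropna()
            if len(pair) < 4:
                raise ValueError(f"covariate {name!r}: fewer than 4 paired samples")
            constant = np.ptp(pair["y"].to_numpy()) == 0
            rho, p = spearman_pair(pair["x"].to_numpy(), pair["y"].to_numpy())
            rows.append({"abundance": taxon, "covariate": name, "rho": rho,
                         "p": p, "n": len(pair), "constant": bool(constant)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.set_index(["abundance", "covariate"])
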