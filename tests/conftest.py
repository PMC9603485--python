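"""Shared fixtures: small hand-built tables, metadata, plates and graphs."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wormnet.community import OtuTable, SampleMetadata
from wormnet.metabolism import BiologPlate


@pytest.fixture
def small_table() -> OtuTable:
    """3 OTUs x 4 samples with lineages."""
    return OtuTable(
        otu_ids=["O1", "O2", "O3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        counts=np.array([[5, 0, 2, 7], [1, 3, 0, 0], [4, 7, 8, 3]]),
        lineages=["Bacteria;Proteobacteria;;;;;",
                  "Bacteria;Firmicutes;Bacilli;;;;",
                  ""],
    )


@pytest.fixture
def four_group_meta() -> SampleMetadata:
    """2 samples per study group, with environmental covariates."""
    rows = []
    rng = np.random.default_rng(11)
    for label, habitat, treatment in [("HMs", "soil", "HM"), ("HMe", "gut", "HM"),
                                      ("HMLs", "soil", "HML"), ("HMLe", "gut", "HML")]:
        for r in (1, 2):
            rows.append({"sample_id": f"{label}_{r}", "habitat": habitat,
                         "treatment": treatment,
                         "pH": 6 + rng.normal(), "OM": 25 + rng.normal(),
                         "TN": 1.5, "TP": 0.8, "TK": 15.0, "MC": 30.0})
    return SampleMetadata(pd.DataFrame(rows))


def build_plate(diffs_by_category, control=0.1, times=(0.0, 12.0), sample_id="p1"):
    """Plate whose substrate wells sit at control + given offsets at all times."""
    wells, od_rows, index = [], [], []
    for i, (cat, diff) in enumerate(diffs_by_category):
        index.append(f"W{i}")
        wells.append({"carbon_source": f"c{i}", "category": cat, "is_control": False})
        od_rows.append([control + diff] * len(times))
    index.append("CTRL")
    wells.append({"carbon_source": "water", "category": "control", "is_control": True})
    od_rows.append([control] * len(times))
    return BiologPlate(
        sample_id=sample_id,
        wells=pd.DataFrame(wells, index=pd.Index(index, name="well_id")),
        od=pd.DataFrame(od_rows, index=index, columns=list(times)),
    )


@pytest.fixture
def two_cliques_with_connector() -> nx.Graph:
    """Two 4-cliques joined only through a single connector node."""
    g = nx.Graph()
    for block in (["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(block[i], block[j])
    g.add_edge("c", "a1")
    g.add_edge("c", "b1")
    return g


def all_set_partitions(items):
    """Every set partition of ``items`` (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def exhaustive_best_q(g: nx.Graph):
    """Brute-force maximum Newman modularity over all partitions."""
    from wormnet.network import modularity

    best, best_assign = -1.0, None
    for part in all_set_partitions(list(g.nodes)):
        assign = {v: i for i, block in enumerate(part) for v in block}
        q = modularity(g, assign)
        if q > best:
            best, best_assign = q, assign
    return best, best_assign
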