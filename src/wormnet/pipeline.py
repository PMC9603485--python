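"""Pipeline orchestration: configuration, validation, the full run, reporting.

``run_all`` drives community -> network -> keystone -> metabolism for a file
bundle (OTU table TSV, metadata TSV, optional Biolog CSV, optional planted
truth JSON) and writes all artifacts plus one machine-readable JSON report.
Every statistic in the report can be reproduced by rerunning the individual
stage functions with the recorded thresholds and per-stage child seeds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import child_seed
from .community import (OtuTable, SampleMetadata, alpha_diversity, depth_report,
                        group_compare, rarefy, read_metadata, read_otu_table,
                        venn_partition, write_otu_table)
from .keystone import (keystone_env_correlation, keystone_report, keystones_of,
                       removal_stability, zi_pi)
from .metabolism import awcd_table, read_plates_csv
from .network import (build_network, detect_modules, per_group_tables,
                      prevalence_filter, write_graphml)
from .synthetic_data import SyntheticTruth, hub_recall, module_recovery_ari

NETWORK_SCOPES = ("per_group", "pooled", "both")


@dataclass
class RunConfig:
    """Inputs, thresholds and seeds of one full pipeline run."""

    otu_table_path: str
    metadata_path: str
    output_dir: str
    biolog_path: str | None = None
    truth_path: str | None = None
    rarefaction_depth: int | None = None  # None -> minimum sample total
    prevalence_fraction: float = 2.0 / 3.0
    r_threshold: float = 0.8
    q_threshold: float = 0.01
    z_threshold: float = 2.5
    p_threshold: float = 0.62
    n_null: int = 199
    reference_time: float | None = None
    network_scope: str = "both"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.prevalence_fraction <= 1.0):
            raise ValueError("prevalence_fraction must be in (0, 1]")
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (0, 1)")
        if not (0.0 < self.q_threshold <= 1.0):
            raise ValueError("q_threshold must be in (0, 1]")
        if self.n_null < 99:
            raise ValueError("n_null must be at least 99")
        if self.network_scope not in NETWORK_SCOPES:
            raise ValueError(f"network_scope must be one of {NETWORK_SCOPES}")
        for path in (self.otu_table_path, self.metadata_path, self.biolog_path,
                     self.truth_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


_BOOLS = {"true": True, "false": False}


def load_run_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    values: dict = {}
    fields = RunConfig.__dataclass_fields__
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _coerce(raw, fields[key].type)
    return RunConfig(**values)


def _coerce(raw: str, annotation: str):
    if raw.lower() in ("none", ""):
        return None
    if raw.lower() in _BOOLS:
        return _BOOLS[raw.lower()]
    for caster in (int, float):
        if caster.__name__ in str(annotation):
            try:
                return caster(raw)
            except ValueError:
                pass
    return raw


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Consistency checks across the input bundle (errors vs warnings)."""
    report = ValidationReport()
    config.validate()
    table = read_otu_table(config.otu_table_path)
    meta = read_metadata(config.metadata_path)
    missing_meta = sorted(set(table.sample_ids) - set(meta.sample_ids))
    if missing_meta:
        report.errors.append(f"samples missing from metadata: {missing_meta}")
    extra_meta = sorted(set(meta.sample_ids) - set(table.sample_ids))
    if extra_meta:
        report.warnings.append(f"metadata samples absent from table: {extra_meta}")
    for label, samples in meta.groups.items():
        in_table = [s for s in samples if s in table.sample_ids]
        if len(in_table) == 1:
            report.warnings.append(
                f"group {label} has a single sample (diversity ok, Tukey disabled)")
    if config.biolog_path is not None:
        try:
            plates = read_plates_csv(config.biolog_path)
        except ValueError as exc:
            report.errors.append(str(exc))
        else:
            absent = sorted(set(table.sample_ids) - set(plates))
            if absent:
                report.warnings.append(f"samples without Biolog plates: {absent}")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="index"))
    return obj


def _venn_pairs(meta: SampleMetadata) -> list[tuple[str, str]]:
    """Soil-vs-gut pairs within each treatment (HMs/HMe, HMLs/HMLe)."""
    groups = set(meta.groups)
    pairs = []
    for treatment in sorted({lab[:-1] for lab in groups}):
        a, b = f"{treatment}s", f"{treatment}e"
        if a in groups and b in groups:
            pairs.append((a, b))
    return pairs


def _network_stage(name: str, table: OtuTable, config: RunConfig, out: Path,
                   report: dict) -> tuple:
    """Filter -> correlate -> modules -> Zi-Pi for one sample set."""
    filt = prevalence_filter(table, config.prevalence_fraction)
    if filt.n_otus == 0:
        warnings.warn(f"network {name}: no OTUs pass the prevalence filter")
        report["networks"][name] = {"n_nodes": 0, "n_edges": 0}
        return None, None, None
    net = build_network(filt, config.r_threshold, config.q_threshold)
    partition = detect_modules(net, seed=child_seed(config.seed, f"modules:{name}"))
    topo = zi_pi(net, partition, config.z_threshold, config.p_threshold)
    net.write_edges_csv(out / f"network_{name}_edges.csv")
    write_graphml(net, out / f"network_{name}.graphml", partition, topo)
    topo.to_csv(out / f"topology_{name}.tsv", sep="\t")
    report["networks"][name] = {
        "n_nodes": int(net.nodes.shape[0]),
        "n_isolated": int(net.nodes["isolated"].sum()),
        "n_edges": int(net.edges.shape[0]),
        "n_positive_edges": int((net.edges["sign"] == "+").sum()),
        "n_negative_edges": int((net.edges["sign"] == "-").sum()),
        "modularity_q": partition.q,
        "n_modules": partition.n_modules,
        "n_keystones": len(keystones_of(topo)),
        "keystones": keystones_of(topo),
    }
    return net, partition, topo


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write artifacts + report.json to the output dir.

    Deterministic for a fixed config: rerunning produces a byte-identical
    report (no timestamps; all randomness flows from ``config.seed`` through
    named per-stage child seeds).
    """
    config.validate()
    validation = validate_inputs(config)
    if not validation.ok:
        raise ValueError("invalid inputs: " + "; ".join(validation.errors))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = read_otu_table(config.otu_table_path)
    meta = read_metadata(config.metadata_path)
    report: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "validation_warnings": validation.warnings,
        "networks": {},
    }

    # --- community stage --------------------------------------------------
    depths = table.sample_depths()
    depth_target = config.rarefaction_depth or int(depths.min())
    rare = rarefy(table, depth_target, seed=child_seed(config.seed, "rarefy"))
    write_otu_table(rare, out / "otu_table_rarefied.tsv")
    report["rarefaction"] = {"depth": depth_target}
    report["sequencing_depth"] = depth_report(table, meta).to_dict(orient="index")

    diversity = alpha_diversity(rare)
    diversity.to_csv(out / "alpha_diversity.tsv", sep="\t")
    report["alpha_diversity"] = {"per_sample": _jsonable(diversity)}
    group_sizes = {g: len(s) for g, s in meta.groups.items()}
    if len(group_sizes) >= 2 and min(group_sizes.values()) >= 2:
        comparisons = {}
        for index in diversity.columns:
            values = diversity[index].dropna()
            cmp_res = group_compare(values, meta)
            comparisons[index] = {
                "anova_f": cmp_res.anova_f, "anova_p": cmp_res.anova_p,
                "group_means": _jsonable(cmp_res.group_means),
                "letters": cmp_res.letters,
            }
        report["alpha_diversity"]["group_comparison"] = comparisons

    report["venn"] = {}
    for a, b in _venn_pairs(meta):
        venn = venn_partition(table, meta, a, b)
        report["venn"][f"{a}_vs_{b}"] = {
            "shared": len(venn.shared), "unique_a": len(venn.unique_a),
            "unique_b": len(venn.unique_b), "union": venn.union_size,
            "shared_pct": venn.shared_pct_reported,
        }

    # --- network / keystone stage ----------------------------------------
    topologies = {}
    pooled_net = pooled_partition = pooled_topo = None
    if config.network_scope in ("pooled", "both"):
        pooled_net, pooled_partition, pooled_topo = _network_stage(
            "pooled", rare, config, out, report)
    if config.network_scope in ("per_group", "both"):
        for label, sub in per_group_tables(rare, meta).items():
            _, _, topo = _network_stage(label, sub, config, out, report)
            if topo is not None:
                topologies[label] = topo

    keystone_summary = None
    if topologies:
        keystone_summary = keystone_report(topologies, rare, meta)
        pd.concat(keystone_summary.per_group.values()).to_csv(
            out / "keystones_per_group.tsv", sep="\t")
        report["keystones"] = {
            "per_group_counts": {g: int(df.shape[0])
                                 for g, df in keystone_summary.per_group.items()},
            "pooled_count": keystone_summary.pooled_count,
            "shared": keystone_summary.shared,
        }

    if pooled_net is not None and pooled_topo is not None:
        pooled_keys = keystones_of(pooled_topo)
        report["networks"]["pooled"]["keystones"] = pooled_keys
        if pooled_keys and len(pooled_keys) < pooled_net.nodes.shape[0]:
            stability = removal_stability(
                pooled_net, pooled_keys, n_null=config.n_null,
                seed=child_seed(config.seed, "removal"))
            report["removal_stability"] = stability.summary()
            with open(out / "removal_stability.json", "w") as fh:
                json.dump(_jsonable(stability.summary()), fh, indent=1, sort_keys=True)
        rel = rare.relative_abundance()
        present = [k for k in pooled_keys if k in rel.index]
        if present:
            # one profile per keystone taxon plus their summed abundance,
            # BH-adjusted jointly across every (profile, covariate) pair
            profiles = rel.loc[present].T
            profiles["keystone_total"] = rel.loc[present].sum(axis=0)
            env_corr = keystone_env_correlation(profiles, meta)
            env_corr.to_csv(out / "keystone_env_correlation.tsv", sep="\t")
            sig = env_corr[env_corr["q"] < 0.05]
            report["keystone_env_correlation"] = {
                "n_tests": int(env_corr.shape[0]),
                "n_significant_q05": int(sig.shape[0]),
                "significant": _jsonable([
                    {"abundance": a, "covariate": c, "rho": r.rho, "q": r.q}
                    for (a, c), r in sig.iterrows()]),
                "keystone_total": _jsonable(
                    env_corr.xs("keystone_total", level="abundance")
                    [["rho", "p", "q"]]),
            }

    # --- metabolism stage -------------------------------------------------
    if config.biolog_path is not None:
        plates = read_plates_csv(config.biolog_path)
        awcd = awcd_table(plates, config.reference_time)
        awcd.to_csv(out / "awcd.tsv", sep="\t")
        shared_samples = [s for s in awcd.index if s in meta.sample_ids]
        overall = awcd.loc[shared_samples, "overall"]
        first = next(iter(plates.values()))
        ref_time = (config.reference_time if config.reference_time is not None
                    else float(first.times[-1]))
        report["awcd"] = {
            "reference_time": ref_time,
            "per_sample_overall": _jsonable(overall),
            "group_means": _jsonable(
                overall.groupby(meta.df.loc[shared_samples, "group_label"]).mean()),
        }
        if len(set(meta.df.loc[shared_samples, "group_label"])) >= 2:
            cmp_res = group_compare(overall, meta)
            report["awcd"]["group_comparison"] = {
                "anova_f": cmp_res.anova_f, "anova_p": cmp_res.anova_p,
                "letters": cmp_res.letters,
            }

    # --- recovery metrics when planted truth is available -----------------
    if config.truth_path is not None and pooled_partition is not None:
        truth = SyntheticTruth.from_json(config.truth_path)
        noniso = list(pooled_net.nodes.index[~pooled_net.nodes["isolated"]])
        report["recovery"] = {
            "module_ari": module_recovery_ari(truth, pooled_partition.assignment,
                                              nodes=noniso),
            "hub_recall": hub_recall(truth, keystones_of(pooled_topo)),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report
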