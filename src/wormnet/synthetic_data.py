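"""Synthetic study generator: OTU tables, metadata and Biolog plates with
planted, recoverable ground truth.

The generator emulates the 4-group paired gut/soil design (HMs, HMe, HMLs,
HMLe; 2 treatments x 2 habitats x 6 replicates = 24 samples): a gut-vs-soil
richness deficit, a shared core of taxa, planted correlation modules with hub
taxa, environmental covariates coupled to one module's abundance, and
per-group Biolog growth curves.

Model sketch.  Correlated taxa live in ``n_modules`` blocks driven by one
latent standard-normal factor per module per sample.  Members load on their
factor with ``member_loading``; hubs load near 1 (``hub_loading``) plus a
``hub_cross_loading`` tilt toward a partner module.  The loadings are chosen
so that, at 24 samples, hub-member Spearman correlations clear the network
edge threshold far more often than member-member ones, making hubs
high-within-module-degree nodes (Zi above the module-hub cutoff) after
network recovery.  One module is environment-responsive: its factor is a
linear combination of standardized pH (negative effect) and OM (positive
effect), so that module's taxa - hubs included - track the environment.
Counts are Gamma-perturbed exponentiated latents drawn multinomially at the
per-sample sequencing depth (a depth-conditioned Gamma-Poisson).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ._seeds import rng_for
from .community import GROUP_LABELS, OtuTable, SampleMetadata
from .metabolism import BiologPlate, load_substrate_catalog

#: group-mean environmental covariates the generator samples around.
#: pH rises with lime and in the gut; OM rises with lime; MC is far higher in
#: gut content; TN/TP/TK vary mildly.  Units: OM/TN/TP/TK g/kg, MC %.
DEFAULT_ENV_MEANS = {
    "pH": {"HMs": 5.8, "HMe": 6.6, "HMLs": 6.8, "HMLe": 7.4},
    "OM": {"HMs": 26.0, "HMe": 21.0, "HMLs": 31.0, "HMLe": 25.0},
    "TN": {"HMs": 1.4, "HMe": 1.5, "HMLs": 1.7, "HMLe": 1.8},
    "TP": {"HMs": 0.8, "HMe": 0.85, "HMLs": 0.8, "HMLe": 0.85},
    "TK": {"HMs": 15.0, "HMe": 15.5, "HMLs": 15.0, "HMLe": 15.5},
    "MC": {"HMs": 21.0, "HMe": 52.0, "HMLs": 23.0, "HMLe": 58.0},
}
DEFAULT_ENV_SDS = {"pH": 0.2, "OM": 1.5, "TN": 0.1, "TP": 0.05, "TK": 1.0, "MC": 3.0}

#: per-group Biolog asymptotes: the reference-time AWCD levels of the study
#: conditions (soil above gut; lime depresses the gut strongly).
DEFAULT_BIOLOG_ASYMPTOTES = {"HMs": 0.71, "HMe": 0.51, "HMLs": 0.72, "HMLe": 0.38}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; same seed means identical outputs."""

    n_per_group: int = 6
    n_taxa: int = 300
    n_modules: int = 4
    taxa_per_module: int = 70
    n_hubs: int = 2
    hub_loading: float = 0.998
    member_loading: float = 0.86
    hub_cross_loading: float = 0.05
    shared_core_fraction: float = 0.5
    gut_diversity_deficit: float = 0.7
    depth_mean_soil: float = 24202.0
    depth_mean_gut: float = 40227.0
    depth_cv: float = 0.05
    overdispersion: float = 0.005
    module_base_log_abundance: float = 3.0
    background_log_mean: float = 1.0
    background_log_sd: float = 1.5
    env_ph_effect: float = -0.35
    env_om_effect: float = 0.9
    #: amplitude of per-module group-preference offsets (habitat/treatment
    #: contrasts added to the module factors; taxa differ in where they thrive)
    module_group_amplitude: float = 0.0
    env_means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_ENV_MEANS.items()})
    env_sds: dict = field(default_factory=lambda: dict(DEFAULT_ENV_SDS))
    biolog_asymptotes: dict = field(default_factory=lambda: dict(DEFAULT_BIOLOG_ASYMPTOTES))
    biolog_rate: float = 0.08
    biolog_midpoint_h: float = 48.0
    biolog_noise_sd: float = 0.02
    biolog_times: tuple = (0.0, 12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 84.0, 96.0, 108.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.taxa_per_module > self.n_taxa:
            raise ValueError("taxa_per_module * n_modules exceeds n_taxa")
        for name in ("shared_core_fraction", "gut_diversity_deficit"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("hub_loading", "member_loading"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_hubs > self.taxa_per_module:
            raise ValueError("n_hubs cannot exceed taxa_per_module")
        if self.env_ph_effect**2 + self.env_om_effect**2 > 1.0:
            raise ValueError("squared env effect sizes must sum to at most 1")
        for name in ("n_per_group", "n_taxa", "n_modules", "taxa_per_module"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed by generated taxon/sample ids."""

    module_of: dict  # taxon id -> planted module (module taxa only)
    hubs: list  # all planted hub taxon ids
    env_module: int  # the environment-responsive module
    env_coupled_hubs: list  # hubs of that module
    env_effects: dict  # covariate -> effect size on the coupled module factor
    group_biolog_means: dict  # group label -> asymptote mean
    partner_module: dict  # module -> cross-loading partner

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["module_of"] = {k: int(v) for k, v in raw["module_of"].items()}
        raw["partner_module"] = {int(k): int(v) for k, v in raw["partner_module"].items()}
        return cls(**raw)


def _partner_map(n_modules: int) -> dict[int, int]:
    """Reciprocal module pairing (0<->1, 2<->3, ...); odd one pairs with 0."""
    out = {}
    for m in range(n_modules):
        p = m + 1 if m % 2 == 0 else m - 1
        out[m] = p if p < n_modules else 0
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_metadata(config: SimulationConfig, rng: np.random.Generator) -> SampleMetadata:
    rows = []
    for label in GROUP_LABELS:
        habitat = "soil" if label.endswith("s") else "gut"
        treatment = label[:-1]
        for r in range(config.n_per_group):
            row = {"sample_id": f"{label}_{r + 1}", "habitat": habitat,
                   "treatment": treatment}
            for cov, means in config.env_means.items():
                row[cov] = means[label] + config.env_sds[cov] * rng.standard_normal()
            rows.append(row)
    return SampleMetadata(pd.DataFrame(rows))


def generate_community(config: SimulationConfig
                       ) -> tuple[OtuTable, SampleMetadata, SyntheticTruth]:
    """Generate the OTU table, metadata, and the planted truth."""
    rng = rng_for(config.seed, "community")
    meta = generate_metadata(config, rng)
    samples = meta.sample_ids
    n_samples = len(samples)
    habitats = meta.df["habitat"].to_numpy()

    n_module_taxa = config.n_modules * config.taxa_per_module
    n_background = config.n_taxa - n_module_taxa
    width = len(str(config.n_taxa))
    otu_ids = [f"OTU_{i + 1:0{width}d}" for i in range(config.n_taxa)]

    # --- latent module factors -------------------------------------------
    z_ph = _zscore(meta.df["pH"].to_numpy(dtype=float))
    z_om = _zscore(meta.df["OM"].to_numpy(dtype=float))
    factors = rng.standard_normal((config.n_modules, n_samples))
    bp, bo = config.env_ph_effect, config.env_om_effect
    env_module = 0
    resid = np.sqrt(max(0.0, 1.0 - bp * bp - bo * bo))
    factors[env_module] = bp * z_ph + bo * z_om + resid * factors[env_module]
    # group-preference offsets: modules beyond the env-responsive one prefer
    # a habitat, a treatment, or their interaction (unit-variance contrasts),
    # which anchors each factor's between-sample spread
    a = config.module_group_amplitude
    if a > 0:
        is_gut_s = (meta.df["habitat"] == "gut").to_numpy()
        is_lime = (meta.df["treatment"] == "HML").to_numpy()
        contrasts = [
            np.where(is_gut_s, -1.0, 1.0),
            np.where(is_lime, -1.0, 1.0),
            np.where(is_gut_s ^ is_lime, -1.0, 1.0),
        ]
        for m in range(1, config.n_modules):
            pattern = contrasts[(m - 1) % len(contrasts)]
            factors[m] = (a * pattern + factors[m]) / np.sqrt(1.0 + a * a)

    partner = _partner_map(config.n_modules)
    c = config.hub_cross_loading
    log_w = np.empty((config.n_taxa, n_samples))
    module_of: dict[str, int] = {}
    hubs: list[str] = []
    lineages = []
    for m in range(config.n_modules):
        for j in range(config.taxa_per_module):
            i = m * config.taxa_per_module + j
            is_hub = j < config.n_hubs
            if is_hub:
                core = (factors[m] + c * factors[partner[m]]) / np.sqrt(1.0 + c * c)
                lam = config.hub_loading
                hubs.append(otu_ids[i])
            else:
                core = factors[m]
                lam = config.member_loading
            x = lam * core + np.sqrt(1.0 - lam * lam) * rng.standard_normal(n_samples)
            log_w[i] = config.module_base_log_abundance + x
            module_of[otu_ids[i]] = m
            role = "hub" if is_hub else "member"
            lineages.append(
                f"Bacteria;Phylum_M{m};Class_M{m};Order_M{m};"
                f"Family_M{m};Genus_{role}_M{m};"
            )
    bg_base = rng.normal(config.background_log_mean, config.background_log_sd,
                         size=n_background)
    log_w[n_module_taxa:] = bg_base[:, None] + rng.standard_normal(
        (n_background, n_samples))
    for i in range(n_background):
        lineages.append(f"Bacteria;Phylum_B{i % 12};;;;Genus_bg{i};")

    # --- habitat occupancy: shared core, habitat-specific, gut thinning ---
    mask = np.ones((config.n_taxa, n_samples), dtype=bool)
    is_gut = habitats == "gut"
    shared = rng.random(n_background) < config.shared_core_fraction
    soil_only = ~shared & (rng.random(n_background) < 0.5)
    gut_only = ~shared & ~soil_only
    gut_kept = rng.random(n_background) < config.gut_diversity_deficit
    for b in range(n_background):
        i = n_module_taxa + b
        if soil_only[b]:
            mask[i, is_gut] = False
        elif gut_only[b]:
            mask[i, ~is_gut] = False
        if (shared[b] or gut_only[b]) and not gut_kept[b]:
            mask[i, is_gut] = False

    # --- counts: Gamma-perturbed weights, multinomial at the sample depth --
    od = config.overdispersion
    gamma_noise = rng.gamma(1.0 / od, od, size=log_w.shape) if od > 0 else \
        np.ones_like(log_w)
    weights = np.exp(log_w) * gamma_noise * mask
    counts = np.zeros((config.n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        mean_depth = config.depth_mean_gut if is_gut[s] else config.depth_mean_soil
        depth = int(max(1000, round(rng.normal(mean_depth, config.depth_cv * mean_depth))))
        p = weights[:, s] / weights[:, s].sum()
        counts[:, s] = rng.multinomial(depth, p)

    table = OtuTable(otu_ids=otu_ids, sample_ids=samples, counts=counts,
                     lineages=lineages)
    truth = SyntheticTruth(
        module_of=module_of,
        hubs=hubs,
        env_module=env_module,
        env_coupled_hubs=[h for h in hubs if module_of[h] == env_module],
        env_effects={"pH": bp, "OM": bo},
        group_biolog_means=dict(config.biolog_asymptotes),
        partner_module=partner,
    )
    return table, meta, truth


def generate_biolog(config: SimulationConfig, meta: SampleMetadata
                    ) -> dict[str, BiologPlate]:
    """One Biolog plate per sample: logistic well trajectories + blank control.

    Well OD = asymptote x (1 + noise_sd * z_well) x s(t)/s(t_end) + additive
    noise, clamped at 0, where s is a logistic in time; the normalization by
    s(t_end) makes the noise-free curve reach the group asymptote exactly at
    the final time point.  The control well carries baseline noise only.
    """
    rng = rng_for(config.seed, "biolog")
    catalog = load_substrate_catalog().reset_index()
    times = np.asarray(config.biolog_times, dtype=float)
    s = 1.0 / (1.0 + np.exp(-config.biolog_rate * (times - config.biolog_midpoint_h)))
    s = s / s[-1]
    plates = {}
    for sid in meta.sample_ids:
        group = meta.df.loc[sid, "group_label"]
        asym = config.biolog_asymptotes[group]
        wells = pd.DataFrame(
            {"carbon_source": catalog["carbon_source"].to_numpy(),
             "category": catalog["category"].to_numpy(),
             "is_control": (catalog["category"] == "control").to_numpy()},
            index=pd.Index(catalog["well_id"], name="well_id"),
        )
        n_wells = len(wells)
        well_effect = 1.0 + config.biolog_noise_sd * rng.standard_normal(n_wells)
        od = np.outer(asym * well_effect, s)
        od[wells["is_control"].to_numpy()] = 0.0
        od = od + config.biolog_noise_sd * rng.standard_normal(od.shape)
        od = np.clip(od, 0.0, None)
        plates[sid] = BiologPlate(
            sample_id=sid, wells=wells,
            od=pd.DataFrame(od, index=wells.index, columns=times),
        )
    return plates


# -- recovery evaluation ------------------------------------------------------


def module_recovery_ari(truth: SyntheticTruth, assignment: dict,
                        nodes=None) -> float:
    """Adjusted Rand index between planted and detected modules.

    Evaluated over planted-module taxa that appear in ``assignment`` (and in
    ``nodes`` when given - pass the non-isolated node set so taxa carrying no
    edge signal are not counted against the detection).
    """
    eligible = [t for t in truth.module_of if t in assignment]
    if nodes is not None:
        nodes = set(nodes)
        eligible = [t for t in eligible if t in nodes]
    if not eligible:
        return float("nan")
    planted = [truth.module_of[t] for t in eligible]
    detected = [assignment[t] for t in eligible]
    return float(adjusted_rand_score(planted, detected))


def hub_recall(truth: SyntheticTruth, keystone_ids) -> float:
    """Fraction of planted hubs recovered in the keystone set."""
    keystone_ids = set(keystone_ids)
    if not truth.hubs:
        return float("nan")
    return sum(h in keystone_ids for h in truth.hubs) / len(truth.hubs)
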